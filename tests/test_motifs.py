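"""PWM IO, exact-threshold scanning, and central enrichment statistics."""

import itertools

import numpy as np
import pytest

from occushift.intervals import Interval
from occushift.motifs import (
    PWM,
    MotifInstance,
    Window,
    central_enrichment,
    dotplot_matrix,
    position_histogram,
    pwm_from_consensus,
    random_segments,
    read_pwm,
    scan,
    score_threshold,
)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq):
    return "".join(COMP[c] for c in reversed(seq.upper()))


def naive_int_scores(seq, pwm):
    """Per-position integer scores on both strands, by direct summation."""
    ints, _, _ = pwm.scaled_scores()
    w = pwm.width
    code = {b: i for i, b in enumerate("ACGT")}
    fwd, rev = [], []
    for j in range(len(seq) - w + 1):
        word = seq[j:j + w].upper()
        if any(c not in code for c in word):
            fwd.append(None)
            rev.append(None)
            continue
        fwd.append(sum(ints[i, code[c]] for i, c in enumerate(word)))
        rc = revcomp(word)
        rev.append(sum(ints[i, code[c]] for i, c in enumerate(rc)))
    return fwd, rev


class TestReadPWM:
    def test_jaspar_counts_to_probabilities(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(
            ">M1\nA [ 10 0 0 5 0 10 ]\nC [ 0 10 0 5 0 0 ]\n"
            "G [ 0 0 10 0 0 0 ]\nT [ 0 0 0 0 10 0 ]\n"
        )
        pwm = read_pwm(p, pseudocount=0.25)
        assert pwm.pwm_id == "M1"
        assert pwm.width == 6
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)

    def test_meme_and_jaspar_agree(self, tmp_path):
        probs = np.array(
            [[0.7, 0.1, 0.1, 0.1], [0.1, 0.7, 0.1, 0.1],
             [0.25, 0.25, 0.25, 0.25], [0.1, 0.1, 0.1, 0.7]]
        )
        jaspar = tmp_path / "m.jaspar"
        rows = (probs * 1000).astype(int)
        jaspar.write_text(
            ">M\n" + "\n".join(
                f"{b} [ " + " ".join(str(rows[i, bi]) for i in range(4)) + " ]"
                for bi, b in enumerate("ACGT")
            ) + "\n"
        )
        meme = tmp_path / "m.meme"
        meme.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\nMOTIF M\n"
            "letter-probability matrix: alength= 4 w= 4 nsites= 1000\n"
            + "\n".join(" ".join(f"{v:.3f}" for v in row) for row in probs)
            + "\n"
        )
        # same pseudocount per count unit: JASPAR counts are 1000× the MEME probs
        pj = read_pwm(jaspar, pseudocount=10.0)
        pm = read_pwm(meme, pseudocount=0.01)
        assert np.allclose(pj.probs, pm.probs, atol=1e-9)

    def test_zero_row_without_pseudocount_rejected(self, tmp_path):
        p = tmp_path / "z.jaspar"
        p.write_text(">Z\nA [ 1 0 1 1 ]\nC [ 0 0 0 0 ]\nG [ 0 1 0 0 ]\nT [ 0 0 0 0 ]\n")
        with pytest.raises(ValueError, match="pseudocount"):
            read_pwm(p, pseudocount=0.0)

    def test_ragged_matrix_rejected(self, tmp_path):
        p = tmp_path / "r.jaspar"
        p.write_text(">R\nA [ 1 1 1 1 ]\nC [ 1 1 1 ]\nG [ 1 1 1 1 ]\nT [ 1 1 1 1 ]\n")
        with pytest.raises(ValueError, match="ragged"):
            read_pwm(p)


class TestScoreThreshold:
    @pytest.mark.parametrize("consensus", ["GATAA", "CAGCTG", "WGATAA"])
    def test_matches_exhaustive_enumeration(self, consensus):
        pwm = pwm_from_consensus("t", consensus)
        ints, _, _ = pwm.scaled_scores()
        w = pwm.width
        # enumeration oracle: exact tail probability over all 4^w words
        score_weight = {}
        for word in itertools.product(range(4), repeat=w):
            s = int(sum(ints[i, b] for i, b in enumerate(word)))
            weight = float(np.prod([pwm.background[b] for b in word]))
            score_weight[s] = score_weight.get(s, 0.0) + weight
        for p in (1e-2, 1e-3, 1e-4):
            t = score_threshold(pwm, p=p)
            achievable = sorted(score_weight)
            tails = {
                s: sum(wt for s2, wt in score_weight.items() if s2 >= s) for s in achievable
            }
            expected = min((s for s in achievable if tails[s] <= p), default=max(achievable) + 1)
            assert t.int_threshold == expected
            assert t.pvalue_attained <= p

    def test_p_one_gives_minimum_achievable_score(self):
        pwm = pwm_from_consensus("t", "GATAA")
        t = score_threshold(pwm, p=1.0)
        assert t.int_threshold == 0
        assert t.pvalue_attained == pytest.approx(1.0)

    def test_threshold_monotone_in_p(self):
        pwm = pwm_from_consensus("t", "CAGCTG")
        thresholds = [score_threshold(pwm, p).int_threshold for p in (1.0, 0.1, 1e-2, 1e-3, 1e-5)]
        assert thresholds == sorted(thresholds)

    def test_invalid_p_rejected(self):
        pwm = pwm_from_consensus("t", "GATAA")
        with pytest.raises(ValueError):
            score_threshold(pwm, p=0.0)


class TestScan:
    def _window(self, seq, os_id="w0"):
        return Window(os_id=os_id, seq=seq, start_offset=-len(seq) // 2)

    def test_exact_consensus_found_at_planted_offset(self, rng):
        pwm = pwm_from_consensus("t", "GATAAG")
        bg = "".join(rng.choice(list("ACGT"), size=1000))
        pos = 300  # word start; offset = start_offset + pos + (w-1)/2
        seq = bg[:pos] + "GATAAG" + bg[pos + 6:]
        t = score_threshold(pwm, p=1e-3)
        hits = scan([self._window(seq)], pwm, t)
        expected_offset = -500 + pos + 2.5
        assert any(h.offset == expected_offset and h.strand == "+" for h in hits)

    def test_reverse_complement_reported_on_minus_strand(self, rng):
        pwm = pwm_from_consensus("t", "GATAAG")
        bg = "".join(rng.choice(list("ACGT"), size=400))
        pos = 100
        seq = bg[:pos] + revcomp("GATAAG") + bg[pos + 6:]
        t = score_threshold(pwm, p=1e-3)
        hits = scan([self._window(seq)], pwm, t)
        expected_offset = -200 + pos + 2.5
        assert any(h.offset == expected_offset and h.strand == "-" for h in hits)

    def test_all_n_window_yields_nothing(self):
        pwm = pwm_from_consensus("t", "GATAA")
        t = score_threshold(pwm, p=0.5)
        assert scan([self._window("N" * 200)], pwm, t) == []

    def test_matches_naive_scorer_on_both_strands(self, rng):
        pwm = pwm_from_consensus("t", "WGATAA", match_prob=0.8)
        t = score_threshold(pwm, p=5e-3)
        seq = "".join(rng.choice(list("ACGTN"), size=500, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        window = self._window(seq)
        hits = scan([window], pwm, t)
        fwd, rev = naive_int_scores(seq, pwm)
        expected = set()
        for j, s in enumerate(fwd):
            if s is not None and s >= t.int_threshold:
                expected.add((window.start_offset + j + 2.5, "+"))
        for j, s in enumerate(rev):
            if s is not None and s >= t.int_threshold:
                expected.add((window.start_offset + j + 2.5, "-"))
        assert {(h.offset, h.strand) for h in hits} == expected

    def test_strand_symmetry_under_sequence_reversal(self, rng):
        pwm = pwm_from_consensus("t", "CAGCTG", match_prob=0.8)
        t = score_threshold(pwm, p=5e-3)
        seq = "".join(rng.choice(list("ACGT"), size=401))
        hits = scan([Window("w", seq, -200)], pwm, t)
        mirrored = scan([Window("w", revcomp(seq), -200)], pwm, t)
        flip = {"+": "-", "-": "+"}
        assert {(-h.offset, flip[h.strand]) for h in hits} == {
            (h.offset, h.strand) for h in mirrored
        }


class TestEnrichment:
    def _inst(self, offsets):
        return [MotifInstance("x", o, "+", 1.0) for o in offsets]

    def test_direct_formula_arithmetic(self):
        # a=2, b=0.5, c=1, d=1 → log2((2/1)/(0.5/1)) = 2
        instances = self._inst([0, 10]) + self._inst([200])  # per 1 OS: a=2, b=1 → rescale
        result = central_enrichment(
            self._inst([0, 10, 200]),  # one OS: a=2, b=1
            n_os=1,
            random_instances=self._inst([5, 300]),  # one random: c=1, d=1
            n_random=1,
        )
        assert result.log2_odds_ratio == pytest.approx(np.log2((2 / 1) / (1 / 1)))
        assert not result.epsilon_applied

    def test_uniform_placement_gives_zero(self):
        result = central_enrichment(
            self._inst([0, 200]), 1, self._inst([25, -300]), 1
        )
        assert result.log2_odds_ratio == pytest.approx(0.0)

    def test_zero_counts_guarded_and_flagged(self):
        result = central_enrichment(self._inst([0]), 1, self._inst([200]), 1)
        assert result.epsilon_applied
        assert np.isfinite(result.log2_odds_ratio)

    def test_needs_positive_ns(self):
        with pytest.raises(ValueError):
            central_enrichment([], 0, [], 10)


class TestRandomSegments:
    def test_reproducible_and_in_bounds(self, rng):
        genome = {"chr1": "A" * 5000, "chr2": "C" * 3000}
        a = random_segments(genome, 100, length=1000, seed=5)
        b = random_segments(genome, 100, length=1000, seed=5)
        assert a == b
        for iv in a:
            assert iv.length == 1000
            assert 0 <= iv.start and iv.end <= len(genome[iv.chrom])

    def test_blacklist_avoided(self):
        genome = {"chr1": "A" * 10_000}
        bl = [Interval("chr1", 0, 8_000)]
        segs = random_segments(genome, 50, length=1000, seed=1, blacklist=bl)
        for iv in segs:
            assert iv.start >= 8_000

    def test_consensus_rate_matches_iid_expectation(self, rng):
        # closed form: P(word at fixed position) = product of base probs;
        # expected hits over both strands ≈ 2 × (L−w+1) × p_word
        pwm = pwm_from_consensus("t", "GATAAG", match_prob=0.97)
        t = score_threshold(pwm, p=1e-4)
        n, L = 400, 1000
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=300_000))}
        segs = random_segments(genome, n, length=L, seed=2)
        windows = [
            Window(f"r{i}", genome["chr1"][iv.start:iv.end], -L // 2)
            for i, iv in enumerate(segs)
        ]
        hits = scan(windows, pwm, t)
        expected_per_window = 2 * (L - 5) * t.pvalue_attained
        total_expected = n * expected_per_window
        sd = np.sqrt(total_expected)
        assert abs(len(hits) - total_expected) < 3 * sd + 1


class TestHistogramAndDotplot:
    def test_point_mass_lands_in_one_bin(self):
        inst = [MotifInstance("x", 0.0, "+", 1.0)] * 10
        edges, counts, density = position_histogram(inst, binsize=20)
        assert counts.sum() == 10
        assert (counts > 0).sum() == 1

    def test_empty_instances_zero_histogram(self):
        edges, counts, density = position_histogram([], binsize=20)
        assert counts.sum() == 0
        assert np.all(density == 0)

    def test_binsize_must_divide_window(self):
        with pytest.raises(ValueError):
            position_histogram([], binsize=30, window=1000)

    def test_density_integrates_to_one(self, rng):
        inst = [MotifInstance("x", float(o), "+", 1.0) for o in rng.integers(-400, 400, 500)]
        edges, counts, density = position_histogram(inst, binsize=20)
        grid = (edges[:-1] + edges[1:]) / 2
        assert np.trapezoid(density, grid) == pytest.approx(1.0, abs=1e-6)

    def test_dotplot_sorted_by_strength_then_id(self):
        inst = [
            MotifInstance("x", 1.0, "+", 1.0),
            MotifInstance("y", 2.0, "+", 1.0),
            MotifInstance("z", 3.0, "+", 1.0),
        ]
        df = dotplot_matrix(inst, {"x": 3.0, "y": 1.0, "z": 2.0})
        assert list(df["os_id"]) == ["y", "z", "x"]
        # permuting input order changes nothing
        df2 = dotplot_matrix(inst[::-1], {"x": 3.0, "y": 1.0, "z": 2.0})
        assert df.equals(df2)

    def test_missing_strength_lists_ids(self):
        inst = [MotifInstance("x", 0.0, "+", 1.0)]
        with pytest.raises(KeyError, match="x"):
            dotplot_matrix(inst, {})
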