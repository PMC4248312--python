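"""Synthetic fixture generator: planted structure must be recoverable."""

import dataclasses
import filecmp

import numpy as np
import pytest
from scipy import stats

from occushift.atlas import count_signal, read_bedgraph
from occushift.expression import classify_de, read_expression_table
from occushift.intervals import merge_union, read_bed
from occushift.motifs import read_pwm
from occushift.simulate import (
    FixtureConfig,
    Genome,
    MotifSpec,
    builtin_pwms,
    generate_bundle,
    generate_expression,
    generate_genome,
    generate_regulatory_annotation,
    plant_motifs,
    plant_peaks,
    synthesize_coverage,
)
from occushift.states import fate_categorize
from occushift.targets import load_epus, load_genes


def _config(**kw):
    return dataclasses.replace(FixtureConfig(), **kw)


class TestGenome:
    def test_lengths_and_determinism(self, tmp_path):
        cfg = _config(n_chroms=2, chrom_length=100_000, seed=7)
        g1 = generate_genome(cfg, np.random.default_rng(7))
        g2 = generate_genome(cfg, np.random.default_rng(7))
        assert g1.lengths() == {"chr1": 100_000, "chr2": 100_000}
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        g1.write_fasta(p1)
        g2.write_fasta(p2)
        assert filecmp.cmp(p1, p2, shallow=False)

    def test_gc_within_binomial_bound(self):
        cfg = _config(n_chroms=1, chrom_length=1_000_000, gc_fraction=0.5, seed=3)
        g = generate_genome(cfg, np.random.default_rng(3))
        seq = g.seqs["chr1"]
        gc = int(np.sum((seq == 1) | (seq == 2)))
        n = len(seq)
        sd = np.sqrt(n * 0.5 * 0.5)
        assert abs(gc - n * 0.5) < 3 * sd

    def test_fasta_round_trip(self, tmp_path):
        cfg = _config(n_chroms=1, chrom_length=5_000)
        g = generate_genome(cfg, np.random.default_rng(0))
        g.write_fasta(tmp_path / "g.fa")
        back = Genome.read_fasta(tmp_path / "g.fa")
        assert np.array_equal(back.seqs["chr1"], g.seqs["chr1"])

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            _config(chrom_length=0)


class TestPlantPeaks:
    def test_counts_forced_by_sharing_spec(self):
        cfg = _config(
            sharing_spec={("HPC7",): 50, tuple(FixtureConfig().cell_types): 5},
            n_gata1_only=0,
        )
        tal1, partners, blacklist, manifest = plant_peaks(cfg, np.random.default_rng(1))
        assert len(tal1["HPC7"]) == 55
        for ct in ("Epro", "G1E", "ER4", "Ebl", "Meg"):
            assert len(tal1[ct]) == 5
        assert len(manifest) == 55

    def test_zero_jitter_gives_identical_coordinates(self):
        cfg = _config(coord_jitter=0, peak_width_jitter=0,
                      sharing_spec={("G1E", "ER4"): 20}, n_gata1_only=0)
        tal1, *_ , manifest = plant_peaks(cfg, np.random.default_rng(2))
        for ev in manifest:
            assert ev.per_cell_type["G1E"] == ev.per_cell_type["ER4"]

    def test_genome_too_small_rejected(self):
        cfg = _config(n_chroms=1, chrom_length=10_000,
                      sharing_spec={("HPC7",): 500})
        with pytest.raises(ValueError, match="too small"):
            plant_peaks(cfg, np.random.default_rng(0))

    def test_atlas_recovers_planted_patterns_exactly(self):
        cfg = _config(seed=5)
        tal1, *_ , manifest = plant_peaks(cfg, np.random.default_rng(5))
        merged = merge_union(list(tal1.values()))
        planted = {
            (ev.chrom, ev.midpoint // 100): frozenset(ev.pattern)
            for ev in manifest if ev.pattern
        }
        assert len(merged) == sum(1 for ev in manifest if ev.pattern)
        recovered = 0
        for m in merged:
            key = (m.chrom, m.midpoint // 100)
            # planted events sit in distinct 1.2-kb slots; match by proximity
            match = [
                frozenset(ev.pattern) for ev in manifest
                if ev.pattern and ev.chrom == m.chrom and abs(ev.midpoint - m.midpoint) < 600
            ]
            assert len(match) == 1
            assert m.members == match[0]
            recovered += 1
        assert recovered == len(merged)


class TestPlantMotifs:
    def test_central_fraction_one_keeps_offsets_central(self):
        cfg = _config(motif_spec=[MotifSpec("GATA", 1.0, 1.0, 50)],
                      sharing_spec={("G1E",): 100}, n_gata1_only=0, seed=4)
        rng = np.random.default_rng(4)
        genome = generate_genome(cfg, rng)
        *_, manifest = plant_peaks(cfg, rng)
        planted = plant_motifs(genome, manifest, cfg.motif_spec, builtin_pwms(), rng)
        assert len(planted) > 90  # rate 1.0 minus capped-retry skips
        for m in planted:
            assert abs(m.offset) <= 50

    def test_uniform_offsets_pass_ks(self):
        cfg = _config(motif_spec=[MotifSpec("GATA", 1.0, 0.0, 50)],
                      sharing_spec={("G1E",): 500}, n_gata1_only=0, seed=6)
        rng = np.random.default_rng(6)
        genome = generate_genome(cfg, rng)
        *_, manifest = plant_peaks(cfg, rng)
        planted = plant_motifs(genome, manifest, cfg.motif_spec, builtin_pwms(), rng)
        offsets = np.array([m.offset for m in planted])
        w = builtin_pwms()["GATA"].width
        lo, hi = -500 + (w - 1) / 2, 500 - w + (w - 1) / 2
        stat = stats.kstest(offsets, stats.uniform(loc=lo, scale=hi - lo).cdf)
        assert stat.pvalue > 0.01

    def test_zero_planting_rate_leaves_genome_unchanged(self):
        cfg = _config(motif_spec=[MotifSpec("GATA", 0.0, 0.5, 50)],
                      sharing_spec={("G1E",): 50}, n_gata1_only=0)
        rng = np.random.default_rng(1)
        genome = generate_genome(cfg, rng)
        before = {c: s.copy() for c, s in genome.seqs.items()}
        *_, manifest = plant_peaks(cfg, rng)
        planted = plant_motifs(genome, manifest, cfg.motif_spec, builtin_pwms(), rng)
        assert planted == []
        for c in before:
            assert np.array_equal(genome.seqs[c], before[c])


class TestCoverage:
    def test_signal_enriched_inside_planted_peaks(self):
        cfg = _config(seed=8)
        rng = np.random.default_rng(8)
        tal1, *_ , manifest = plant_peaks(cfg, rng)
        tracks = synthesize_coverage(tal1, {c: cfg.chrom_length for c in cfg.chrom_names},
                                     amplitude=20.0, rng=rng)
        for ct, track in tracks.items():
            peaks = tal1[ct]
            if not len(peaks):
                continue
            inside = np.mean([
                track.mean_over(iv.chrom, iv.start, iv.end) for iv in peaks
            ])
            outside = np.mean([
                track.mean_over(iv.chrom, iv.start + 5_000, iv.end + 5_000)
                for iv in peaks.intervals[:50]
            ])
            assert inside > outside + 5

    def test_zero_amplitude_indistinguishable(self):
        cfg = _config(sharing_spec={("G1E",): 60}, n_gata1_only=0)
        pvals = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            tal1, *_ , _ = plant_peaks(cfg, rng)
            tracks = synthesize_coverage(
                tal1, {c: cfg.chrom_length for c in cfg.chrom_names},
                amplitude=0.0, rng=rng,
            )
            track = tracks["G1E"]
            inside = [track.mean_over(iv.chrom, iv.start, iv.end) for iv in tal1["G1E"]]
            outside = [
                track.mean_over(iv.chrom, iv.start + 3_000, iv.end + 3_000)
                for iv in tal1["G1E"]
            ]
            pvals.append(stats.ttest_ind(inside, outside).pvalue)
        # under the null, p < 0.01 should be rare across the 5 seeds
        assert sum(p < 0.01 for p in pvals) <= 2

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            synthesize_coverage({}, {"chr1": 1000}, amplitude=-1.0, seed=0)

    def test_empty_peakset_gives_background_over_full_length(self):
        from occushift.intervals import PeakSet

        tracks = synthesize_coverage({"x": PeakSet("x", [])}, {"chr1": 10_000},
                                     amplitude=5.0, seed=0)
        starts, ends, _ = tracks["x"].records["chr1"]
        assert starts[0] == 0 and ends[-1] == 10_000
        # contiguous tiling
        assert np.array_equal(starts[1:], ends[:-1])


class TestAnnotationAndExpression:
    def test_epus_nonoverlapping_and_states_tile(self):
        cfg = _config(seed=9)
        epus, genes, segs = generate_regulatory_annotation(cfg, np.random.default_rng(9))
        by_chrom = {}
        for e in epus:
            by_chrom.setdefault(e.interval.chrom, []).append(e.interval)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start
        for seg in segs.values():
            for chrom, (starts, ends, _) in seg.chroms.items():
                assert starts[0] == 0
                assert ends[-1] == cfg.chrom_length
                assert np.array_equal(starts[1:], ends[:-1])

    def test_genes_inside_epu_or_intergenic(self):
        cfg = _config(seed=10, intergenic_gene_fraction=0.1)
        epus, genes, _ = generate_regulatory_annotation(cfg, np.random.default_rng(10))
        from occushift.targets import _epu_index, containing_epu

        index = _epu_index(epus)
        n_inside = sum(
            1 for g in genes if containing_epu(index, g.chrom, g.tss) is not None
        )
        assert n_inside == round(cfg.n_genes * 0.9)

    def test_coupling_recovered_within_binomial_interval(self):
        # isolate group d: every OS is (T,T,+GATA1) → group d with p_induced 0.8
        cfg = _config(
            sharing_spec={("G1E", "ER4"): 400},
            gata1_prob={(True, True): 1.0},
            n_gata1_only=0,
            response_coupling={"d": (0.8, 0.05)},
            baseline_de=(0.0, 0.0),
            n_epus=200,
            epu_gap=500,
            n_genes=400,
            intergenic_gene_fraction=0.0,
        )
        rng = np.random.default_rng(12)
        *_, manifest = plant_peaks(cfg, rng)
        epus, genes, _ = generate_regulatory_annotation(cfg, rng)
        table, labels = generate_expression(cfg, manifest, epus, genes, rng)
        # genes whose EPU contains ≥1 planted event draw their label at 0.8/0.05
        from occushift.targets import _epu_index, containing_epu

        index = _epu_index(epus)
        events_in_epu = set()
        for ev in manifest:
            epu = containing_epu(index, ev.chrom, ev.midpoint)
            if epu is not None:
                events_in_epu.add(epu.epu_id)
        eligible = [
            g for g in genes
            if (e := containing_epu(index, g.chrom, g.tss)) is not None
            and e.epu_id in events_in_epu
        ]
        n = len(eligible)
        k = sum(labels[g.gene_id] == "induced" for g in eligible)
        assert n >= 200
        lo, hi = stats.binom.interval(0.99, n, 0.8)
        assert lo <= k <= hi

    def test_labels_round_trip_through_de_rule(self):
        cfg = _config(seed=13)
        rng = np.random.default_rng(13)
        *_, manifest = plant_peaks(cfg, rng)
        epus, genes, _ = generate_regulatory_annotation(cfg, rng)
        table, labels = generate_expression(cfg, manifest, epus, genes, rng)
        classified = classify_de(table).set_index("gene_id")["label"]
        assert (classified.sort_index() == labels.sort_index()).all()

    def test_invalid_coupling_rejected(self):
        with pytest.raises(ValueError, match="≤ 1"):
            _config(response_coupling={"d": (0.8, 0.5)})


class TestBundle:
    def test_every_emitted_file_parses_with_repo_readers(self, default_bundle):
        b = default_bundle
        genome = Genome.read_fasta(b.genome_fasta)
        assert set(genome.seqs) == {"chr1", "chr2"}
        for ct, path in b.peak_beds.items():
            ps = read_bed(path, ct)
            planted = sum(1 for ev in b.manifest if ct in ev.pattern)
            assert len(ps) == planted
        for path in b.partner_beds.values():
            read_bed(path)
        for path in b.coverage_bedgraphs.values():
            read_bedgraph(path)
        for path in b.pwm_files.values():
            read_pwm(path)
        assert len(load_epus(b.epu_bed)) == b.config.n_epus
        assert len(load_genes(b.tss_bed)) == b.config.n_genes
        assert len(read_expression_table(b.expression_tsv)) == b.config.n_genes
        read_bed(b.blacklist_bed)

    def test_manifest_coordinates_match_emitted_beds(self, default_bundle):
        b = default_bundle
        for ct, path in b.peak_beds.items():
            emitted = {(iv.chrom, iv.start, iv.end) for iv in read_bed(path, ct)}
            planted = {
                (ev.chrom, *ev.per_cell_type[ct])
                for ev in b.manifest if ct in ev.per_cell_type
            }
            assert emitted == planted

    def test_byte_identical_across_reruns(self, tmp_path):
        cfg = _config(seed=21, sharing_spec={("HPC7",): 30, ("G1E", "ER4"): 20},
                      n_genes=50, n_epus=10)
        b1 = generate_bundle(cfg, tmp_path / "r1")
        b2 = generate_bundle(cfg, tmp_path / "r2")
        for p1, p2 in [
            (b1.genome_fasta, b2.genome_fasta),
            (b1.expression_tsv, b2.expression_tsv),
            (b1.manifest_json, b2.manifest_json),
            *zip(sorted(b1.peak_beds.values()), sorted(b2.peak_beds.values())),
            *zip(sorted(b1.coverage_bedgraphs.values()),
                 sorted(b2.coverage_bedgraphs.values())),
        ]:
            assert filecmp.cmp(p1, p2, shallow=False), p1

    def test_inactive_everywhere_plan_gives_all_inactive_fates(self, tmp_path):
        cfg = _config(
            sharing_spec={("HPC7",): 40}, n_gata1_only=0,
            state_active_prob=0.0, seed=14, n_genes=20, n_epus=10,
        )
        b = generate_bundle(cfg, tmp_path / "inact")
        from occushift.states import load_segmentation

        segs = [load_segmentation(b.state_beds[ct], ct) for ct in cfg.state_cell_types]
        merged = merge_union([read_bed(b.peak_beds["HPC7"], "HPC7")])
        table, summary = fate_categorize(merged, segs)
        assert summary.loc["inactive_all", "percent"] == 100.0
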