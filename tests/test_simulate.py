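"""Generator bookkeeping, determinism, planted-signal separation."""

import numpy as np
import pytest

from semr import io as io_mod
from semr.calling import call_superenhancers, quantify_region_signal, stitch_peaks
from semr.simulate import (
    GenomeTooSmallError,
    SimConfig,
    generate_expression,
    generate_landscape,
)


def tiny_config(**kwargs):
    defaults = dict(
        seed=5, n_lines=4, replicates_per_line=2,
        n_ubiquitous_se=6, n_subtype_se=4, n_line_se=4, n_typical=60,
        n_genes=400, dropout_rate=0.0,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


class TestValidation:
    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="n_typical"):
            tiny_config(n_typical=-1).validate()

    def test_dropout_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="dropout"):
            tiny_config(dropout_rate=1.0).validate()

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            tiny_config(n_genes=80).validate()

    def test_unknown_subtype_rejected(self):
        cfg = tiny_config(subtype_of_line={f"L{i:02d}": "Basal"
                                           for i in range(1, 5)})
        with pytest.raises(ValueError, match="subtype"):
            cfg.validate()

    def test_genome_too_small_raises(self):
        cfg = tiny_config(genome=(("chr1", 200_000), ("chrBG", 3_000_000)))
        with pytest.raises(GenomeTooSmallError, match="too small"):
            generate_landscape(cfg)


class TestTruthBookkeeping:
    def test_nothing_planted_means_only_typicals(self):
        cfg = tiny_config(n_ubiquitous_se=0, n_subtype_se=0, n_line_se=0,
                          n_regulators=0, n_active_regulators=0, n_line_decoys=0)
        sim = generate_landscape(cfg)
        assert {r.category for r in sim.truth.planted_regions} == {"typical"}

    def test_ubiquitous_present_in_all_lines_without_dropout(self):
        cfg = SimConfig(seed=3, n_ubiquitous_se=40, n_lines=10,
                        dropout_rate=0.0)
        sim = generate_landscape(cfg)
        ub = sim.truth.regions_by_category("ubiquitous")
        assert len(ub) == 40
        assert all(len(r.lines_present) == 10 for r in ub)

    def test_line_specific_present_in_exactly_one_line(self, small_landscape):
        for r in small_landscape.truth.regions_by_category("line_specific"):
            assert len(r.lines_present) == 1

    def test_presence_matches_recount_from_generated_peaks(self, small_landscape):
        """Independent recount: a region is present in a line iff some
        sample of that line has a peak inside the region interval."""
        sim = small_landscape
        line_of = dict(zip(sim.manifest["sample"], sim.manifest["line"]))
        seen: dict[str, set] = {r.region_id: set()
                                for r in sim.truth.planted_regions}
        for sample, peaks in sim.peaks.items():
            for region in sim.truth.planted_regions:
                iv = region.interval
                hit = any(p.interval.chrom == iv.chrom
                          and p.interval.start >= iv.start
                          and p.interval.end <= iv.end for p in peaks)
                if hit:
                    seen[region.region_id].add(line_of[sample])
        for region in sim.truth.planted_regions:
            assert seen[region.region_id] == set(region.lines_present)

    def test_planted_regions_never_within_stitching_distance(self, small_landscape):
        regions = sorted(small_landscape.truth.planted_regions,
                         key=lambda r: (r.interval.chrom, r.interval.start))
        d = small_landscape.config.d_stitch
        for prev, nxt in zip(regions, regions[1:]):
            if prev.interval.chrom == nxt.interval.chrom:
                assert nxt.interval.start - prev.interval.end > d

    def test_each_region_gene_is_within_association_window(self, small_landscape):
        genes = {g.gene_id: g for g in small_landscape.annotation}
        for region in small_landscape.truth.planted_regions:
            g = genes[region.gene_id]
            assert region.interval.gap_to(g.interval) <= 10_000


class TestDeterminism:
    def test_same_seed_same_peak_files(self, tmp_path):
        cfg = tiny_config()
        files = []
        for run in ("a", "b"):
            sim = generate_landscape(cfg)
            sample = sim.manifest["sample"].iloc[0]
            out = tmp_path / f"{run}.narrowPeak"
            io_mod.write_narrowpeak(out, sim.peaks[sample])
            files.append(out.read_bytes())
        assert files[0] == files[1]

    def test_different_seed_different_landscape(self):
        a = generate_landscape(tiny_config(seed=5))
        b = generate_landscape(tiny_config(seed=6))
        starts_a = [(r.interval.chrom, r.interval.start)
                    for r in a.truth.planted_regions]
        starts_b = [(r.interval.chrom, r.interval.start)
                    for r in b.truth.planted_regions]
        assert starts_a != starts_b

    def test_expression_reproducible(self, small_landscape):
        e1 = generate_expression(small_landscape.config, small_landscape.truth)
        e2 = generate_expression(small_landscape.config, small_landscape.truth)
        assert np.array_equal(e1.expression.to_numpy(), e2.expression.to_numpy())


class TestSignalSeparation:
    def test_planted_se_signal_beats_every_typical(self, small_landscape):
        """With dropout 0 and 10x mean separation, each sample's weakest
        planted SE outshines its strongest typical enhancer."""
        sim = small_landscape
        truth_cat = {}
        for r in sim.truth.planted_regions:
            truth_cat[(r.interval.chrom, r.interval.start)] = r.category
        for sample in list(sim.peaks)[:4]:
            regions = stitch_peaks(sim.peaks[sample])
            se_sigs, typ_sigs = [], []
            for region in regions:
                s = quantify_region_signal(region)
                key = (region.interval.chrom, region.interval.start)
                if truth_cat[key] == "typical":
                    typ_sigs.append(s)
                else:
                    se_sigs.append(s)
            assert min(se_sigs) > max(typ_sigs)


class TestExpression:
    def test_null_effect_gives_symmetric_statistics(self):
        from semr.activity import contrast_signature

        cfg = tiny_config(activity_effect=0.0)
        sim = generate_landscape(cfg)
        expr = generate_expression(cfg, sim.truth)
        sig = contrast_signature(expr.expression, expr.subtype_labels, "Lum")
        t = sig.stats.to_numpy()
        se_mean = t.std(ddof=1) / np.sqrt(t.size)
        assert abs(t.mean()) < 3 * se_mean

    def test_strong_effect_shifts_every_positive_target(self):
        cfg = tiny_config(activity_effect=4.0, noise_sd=0.2)
        sim = generate_landscape(cfg)
        expr = generate_expression(cfg, sim.truth)
        reg, subtype, sign = sim.truth.planted_active_regulators[0]
        regulon = next(r for r in expr.regulons if r.regulator == reg)
        in_st = (expr.subtype_labels == subtype).to_numpy()
        log = np.log2(1 + expr.expression)
        for target, mode in zip(regulon.targets, regulon.modes):
            diff = log.loc[target].to_numpy()[in_st].mean() - \
                log.loc[target].to_numpy()[~in_st].mean()
            assert np.sign(diff) == np.sign(mode * sign)

    def test_regulon_target_pools_are_disjoint(self, small_expression):
        seen = set()
        for reg in small_expression.regulons:
            assert not (set(reg.targets) & seen)
            seen.update(reg.targets)

    def test_candidate_regulators_anchor_on_ubiquitous_genes(self, small_landscape):
        ub_genes = {r.gene_id for r in
                    small_landscape.truth.regions_by_category("ubiquitous")}
        for reg in small_landscape.truth.candidate_regulators:
            assert reg in ub_genes


class TestCallsetRecovery:
    def test_all_planted_ses_called_super_under_strong_separation(self):
        cfg = SimConfig(seed=9, dropout_rate=0.0, noise_sd=0.05,
                        input_signal_mean=0.05, n_typical=100,
                        peak_len_range=(1000, 1400))
        sim = generate_landscape(cfg)
        line_of = dict(zip(sim.manifest["sample"], sim.manifest["line"]))
        sample = sim.manifest["sample"].iloc[0]
        cs = call_superenhancers(sim.peaks[sample], sample=sample)
        n_planted = sum(1 for r in sim.truth.planted_regions
                        if r.category != "typical"
                        and line_of[sample] in r.lines_present)
        assert cs.n_super == n_planted
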