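"""Signatures, aREA-style NES, permutation null, correlation enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from semr.activity import (
    Regulon,
    Signature,
    area_nes,
    contrast_signature,
    correlation_rank_enrichment,
    permutation_nes,
    score_all,
)


def make_signature(values, prefix="g"):
    genes = [f"{prefix}{i}" for i in range(len(values))]
    return Signature("test", pd.Series(values, index=genes))


class TestRegulonValidation:
    def test_duplicate_targets_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Regulon("R", ("a", "a"), (1.0, 1.0), (1.0, 1.0))

    def test_mode_and_weight_ranges_enforced(self):
        with pytest.raises(ValueError):
            Regulon("R", ("a",), (2.0,), (1.0,))
        with pytest.raises(ValueError):
            Regulon("R", ("a",), (1.0,), (0.0,))


class TestContrastSignature:
    def _expr(self, a_vals, b_vals, n_genes=5):
        cols = [f"A{i}" for i in range(len(a_vals))] + \
               [f"B{i}" for i in range(len(b_vals))]
        data = np.tile(np.asarray(a_vals + b_vals, dtype=float), (n_genes, 1))
        expr = pd.DataFrame(data, columns=cols,
                            index=[f"g{i}" for i in range(n_genes)])
        labels = pd.Series(["X"] * len(a_vals) + ["Y"] * len(b_vals), index=cols)
        return expr, labels

    def test_equal_groups_give_zero_statistic(self):
        expr, labels = self._expr([2, 2, 2], [2, 2, 2])
        sig = contrast_signature(expr, labels, "X")
        assert np.allclose(sig.stats, 0.0)

    def test_sign_follows_group_means(self):
        expr, labels = self._expr([15, 15], [3, 3])
        sig = contrast_signature(expr, labels, "X")
        assert (sig.stats > 0).all()

    def test_swapping_groups_negates_statistic(self, rng):
        expr, labels = self._expr([1, 2, 3], [4, 5, 6])
        expr.iloc[:] = rng.gamma(2.0, 10.0, size=expr.shape)
        sx = contrast_signature(expr, labels, "X").stats
        sy = contrast_signature(expr, labels, "Y").stats
        assert np.allclose(sx, -sy)

    def test_matches_scipy_welch_on_random_data(self, rng):
        expr, labels = self._expr([0] * 4, [0] * 5, n_genes=20)
        expr.iloc[:] = rng.gamma(2.0, 20.0, size=expr.shape)
        sig = contrast_signature(expr, labels, "X", eps=0.0)
        log = np.log2(1 + expr)
        ref = stats.ttest_ind(log.iloc[:, :4], log.iloc[:, 4:], axis=1,
                              equal_var=False).statistic
        assert np.allclose(sig.stats, ref)

    def test_absent_subtype_rejected(self):
        expr, labels = self._expr([1, 1], [2, 2])
        with pytest.raises(ValueError, match="absent"):
            contrast_signature(expr, labels, "Z")


class TestAreaNES:
    def test_single_target_at_median_scores_zero(self):
        sig = make_signature(np.arange(11.0))  # median gene is g5
        reg = Regulon("R", ("g5",), (1.0,), (1.0,))
        nes, n = area_nes(sig, reg, min_size=1)
        assert nes == pytest.approx(0.0, abs=1e-12)
        assert n == 1

    def test_mirrored_pair_with_opposed_modes(self):
        n = 21
        sig = make_signature(np.arange(float(n)))
        r = 3
        q_r = stats.norm.ppf(r / (n + 1))
        reg = Regulon("R", (f"g{r-1}", f"g{n-r}"), (1.0, -1.0), (1.0, 1.0))
        nes, _ = area_nes(sig, reg, min_size=2)
        assert nes == pytest.approx(np.sqrt(2) * q_r)

    def test_flipping_modes_negates_nes(self, rng):
        sig = make_signature(rng.normal(size=200))
        idx = rng.choice(200, 20, replace=False)
        modes = tuple(float(m) for m in rng.choice([1.0, -1.0], 20))
        w = tuple(float(x) for x in rng.uniform(0.5, 1, 20))
        reg = Regulon("R", tuple(f"g{i}" for i in idx), modes, w)
        flipped = Regulon("R", reg.targets, tuple(-m for m in modes), w)
        assert area_nes(sig, flipped)[0] == pytest.approx(-area_nes(sig, reg)[0])

    def test_negating_signature_negates_nes(self, rng):
        values = rng.normal(size=151)
        sig = make_signature(values)
        neg = make_signature(-values)
        reg = Regulon("R", tuple(f"g{i}" for i in range(30)),
                      tuple([1.0] * 30), tuple([1.0] * 30))
        assert area_nes(neg, reg)[0] == pytest.approx(-area_nes(sig, reg)[0])

    def test_targets_outside_universe_dropped(self, rng):
        sig = make_signature(rng.normal(size=100))
        targets = tuple(f"g{i}" for i in range(15)) + ("absent1", "absent2")
        reg = Regulon("R", targets, tuple([1.0] * 17), tuple([1.0] * 17))
        nes, n_used = area_nes(sig, reg)
        assert n_used == 15

    def test_too_small_regulon_rejected(self):
        sig = make_signature(np.arange(50.0))
        reg = Regulon("R", ("g1", "g2"), (1.0, 1.0), (1.0, 1.0))
        with pytest.raises(ValueError, match="min size"):
            area_nes(sig, reg)


class TestPermutationNES:
    def test_seed_reproducibility(self, rng):
        sig = make_signature(rng.normal(size=300))
        reg = Regulon("R", tuple(f"g{i}" for i in range(25)),
                      tuple([1.0] * 25), tuple([1.0] * 25))
        z1, p1 = permutation_nes(sig, reg, n_perm=200, seed=5)
        z2, p2 = permutation_nes(sig, reg, n_perm=200, seed=5)
        assert (z1, p1) == (z2, p2)

    def test_propagates_small_regulon_error(self):
        sig = make_signature(np.arange(30.0))
        reg = Regulon("R", ("absent",), (1.0,), (1.0,))
        with pytest.raises(ValueError):
            permutation_nes(sig, reg, n_perm=100, seed=0)

    def test_rejects_too_few_permutations(self, rng):
        sig = make_signature(rng.normal(size=100))
        reg = Regulon("R", tuple(f"g{i}" for i in range(12)),
                      tuple([1.0] * 12), tuple([1.0] * 12))
        with pytest.raises(ValueError):
            permutation_nes(sig, reg, n_perm=10, seed=0)


class TestScoreAll:
    def test_planted_regulator_dominates_its_contrast(self, small_landscape,
                                                      small_expression):
        scores = score_all(small_expression.expression,
                           small_expression.subtype_labels,
                           small_expression.regulons)
        truth = small_landscape.truth
        for reg, subtype, sign in truth.planted_active_regulators:
            row = scores[(scores.regulator == reg) & (scores.contrast == subtype)]
            assert abs(row["nes"].iloc[0]) > 2
            assert np.sign(row["nes"].iloc[0]) == sign

    def test_regulator_without_expression_row_gets_nan_log2fc(self, rng):
        genes = [f"g{i}" for i in range(60)]
        cols = [f"s{i}" for i in range(8)]
        expr = pd.DataFrame(rng.gamma(2.0, 10.0, size=(60, 8)),
                            index=genes, columns=cols)
        labels = pd.Series(["X"] * 4 + ["Y"] * 4, index=cols)
        reg = Regulon("not_a_gene", tuple(genes[:15]),
                      tuple([1.0] * 15), tuple([1.0] * 15))
        scores = score_all(expr, labels, [reg])
        assert len(scores) == 2
        assert scores["nes"].notna().all()
        assert scores["log2fc"].isna().all()

    def test_empty_regulon_set_rejected(self):
        with pytest.raises(ValueError):
            score_all(pd.DataFrame(), pd.Series(dtype=object), [])


class TestCorrelationRankEnrichment:
    def _expr(self, rng, n_genes=60, n_samples=20):
        genes = ["anchor"] + [f"g{i}" for i in range(n_genes - 1)]
        return pd.DataFrame(rng.normal(10, 2, size=(n_genes, n_samples)),
                            index=genes,
                            columns=[f"s{i}" for i in range(n_samples)])

    def test_top_correlated_set_is_extreme(self, rng):
        expr = self._expr(rng)
        anchor = expr.loc["anchor"]
        # plant strong positive correlation for 8 genes
        planted = [f"g{i}" for i in range(8)]
        for g in planted:
            expr.loc[g] = anchor * 1.5 + rng.normal(0, 0.05, size=anchor.size)
        es, p = correlation_rank_enrichment(expr, "anchor", set(planted),
                                            n_perm=200, seed=1)
        assert es > 0
        assert p == pytest.approx(1 / 201)

    def test_negating_anchor_flips_sign(self, rng):
        expr = self._expr(rng)
        planted = [f"g{i}" for i in range(8)]
        for g in planted:
            expr.loc[g] = expr.loc["anchor"] + rng.normal(0, 0.05, size=20)
        es1, _ = correlation_rank_enrichment(expr, "anchor", set(planted),
                                             n_perm=100, seed=2)
        expr.loc["anchor"] = -expr.loc["anchor"]
        es2, _ = correlation_rank_enrichment(expr, "anchor", set(planted),
                                             n_perm=100, seed=2)
        assert es2 == pytest.approx(-es1)

    def test_uniformly_spread_set_is_null(self, rng):
        expr = self._expr(rng, n_genes=121)
        # every 12th gene along the correlation ranking -> no concentration
        corr = expr.drop(index="anchor").T.corrwith(expr.loc["anchor"],
                                                    method="spearman")
        ordered = corr.sort_values(ascending=False).index
        spread = set(ordered[::12])
        _, p = correlation_rank_enrichment(expr, "anchor", spread,
                                           n_perm=200, seed=3)
        assert p > 0.2

    def test_constant_anchor_rejected(self, rng):
        expr = self._expr(rng)
        expr.loc["anchor"] = 5.0
        with pytest.raises(ValueError, match="constant"):
            correlation_rank_enrichment(expr, "anchor", {"g1", "g2", "g3",
                                                         "g4", "g5"})

    def test_tiny_gene_set_rejected(self, rng):
        expr = self._expr(rng)
        with pytest.raises(ValueError, match=">= 5"):
            correlation_rank_enrichment(expr, "anchor", {"g1"})
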