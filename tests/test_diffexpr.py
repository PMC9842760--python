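"""Unit tests for normalisation, dispersion, the NB Wald test and BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from isgland import (
    CallThresholds,
    ContrastSpec,
    CountMatrix,
    bh_adjust,
    call_regulated,
    estimate_dispersion,
    size_factors,
    wald_contrast,
)
from isgland.simulate import SimConfig, nb_draw, simulate_counts

from conftest import make_counts


# ---------------------------------------------------------------- size factors
class TestSizeFactors:
    def test_doubled_sample_gives_sqrt2_factors(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 1000, size=50)
        cm = make_counts(
            np.column_stack([base, 2 * base]),
            ["s1", "s2"],
            ["WT", "WT"],
            ["untreated", "IFN"],
        )
        f = size_factors(cm)
        assert f.to_numpy() == pytest.approx([1 / np.sqrt(2), np.sqrt(2)], rel=1e-12)

    def test_identical_samples_give_unit_factors(self):
        base = np.arange(1, 21)
        cm = make_counts(
            np.column_stack([base, base, base]),
            ["a", "b", "c"],
            ["WT", "WT", "KO"],
            ["untreated", "IFN", "IFN"],
        )
        assert size_factors(cm).to_numpy() == pytest.approx([1, 1, 1])

    def test_single_gene_hand_example(self):
        cm = make_counts([[4, 16]], ["a", "b"], ["WT", "WT"], ["untreated", "IFN"])
        assert size_factors(cm).to_numpy() == pytest.approx([0.5, 2.0])

    def test_per_gene_scaling_leaves_factors_unchanged(self):
        rng = np.random.default_rng(1)
        base = rng.integers(5, 500, size=(30, 4))
        scale = rng.integers(1, 9, size=(30, 1))
        samples = ["a", "b", "c", "d"]
        geno = ["WT", "WT", "KO", "KO"]
        trt = ["untreated", "IFN", "untreated", "IFN"]
        f1 = size_factors(make_counts(base, samples, geno, trt))
        f2 = size_factors(make_counts(base * scale, samples, geno, trt))
        assert f1.to_numpy() == pytest.approx(f2.to_numpy())

    def test_rescaling_one_sample_scales_its_relative_factor(self):
        # geometric-mean-1 normalisation makes absolute factors shift, but the
        # factor *ratio* of the rescaled sample to any other scales by k
        rng = np.random.default_rng(2)
        base = rng.integers(5, 500, size=(40, 3))
        scaled = base.copy()
        k = 4
        scaled[:, 2] *= k
        samples, geno = ["a", "b", "c"], ["WT", "WT", "KO"]
        trt = ["untreated", "IFN", "IFN"]
        f1 = size_factors(make_counts(base, samples, geno, trt))
        f2 = size_factors(make_counts(scaled, samples, geno, trt))
        assert f2["c"] / f2["a"] == pytest.approx(k * f1["c"] / f1["a"], rel=1e-9)

    def test_no_reference_gene_raises(self):
        cm = make_counts([[0, 5], [3, 0]], ["a", "b"], ["WT", "WT"], ["untreated", "IFN"])
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(cm)


# ----------------------------------------------------------------- dispersion
class TestDispersion:
    def _cm(self, mat, n_per=3):
        samples = [f"s{i}" for i in range(mat.shape[1])]
        geno = ["WT"] * n_per + ["KO"] * (mat.shape[1] - n_per)
        trt = ["untreated"] * mat.shape[1]
        return make_counts(mat, samples, geno, trt)

    def test_poisson_like_clips_to_floor(self):
        rng = np.random.default_rng(3)
        mat = rng.poisson(50, size=(200, 6))
        cm = self._cm(mat)
        d = estimate_dispersion(cm, size_factors(cm))
        assert (d <= 0.02).mean() > 0.5  # most genes near/below floor
        assert (d >= 1e-8).all()

    def test_constant_gene_gets_floor(self):
        mat = np.vstack([np.full(6, 20), np.full(6, 7)])
        cm = self._cm(mat)
        d = estimate_dispersion(cm, pd.Series(1.0, index=cm.counts.columns))
        assert d.to_numpy() == pytest.approx([1e-8, 1e-8])

    def test_all_zero_gene_gets_floor(self):
        mat = np.vstack([np.zeros(6, dtype=int), np.full(6, 50)])
        cm = self._cm(mat)
        d = estimate_dispersion(cm, pd.Series(1.0, index=cm.counts.columns))
        assert d.iloc[0] == pytest.approx(1e-8)

    def test_mom_recovery_many_replicates(self):
        """True alpha = 0.1, 4 conditions x 50 replicates: median alpha-hat in [0.08, 0.12]."""
        rng = np.random.default_rng(4)
        n_genes, reps = 500, 50
        mu = np.exp(rng.uniform(np.log(50), np.log(500), n_genes))
        mat = nb_draw(rng, np.tile(mu[:, None], (1, 4 * reps)), 0.1)
        samples = [f"s{i}" for i in range(4 * reps)]
        geno = ["WT"] * (2 * reps) + ["KO"] * (2 * reps)
        trt = (["untreated"] * reps + ["IFN"] * reps) * 2
        cm = make_counts(mat, samples, geno, trt)
        d = estimate_dispersion(cm, size_factors(cm))
        assert 0.08 <= float(np.median(d)) <= 0.12


# ------------------------------------------------------------------ Wald test
def _two_group_cm(g1, g2):
    g1, g2 = np.asarray(g1), np.asarray(g2)
    mat = np.concatenate([g1, g2], axis=1)
    samples = [f"a{i}" for i in range(g1.shape[1])] + [f"b{i}" for i in range(g2.shape[1])]
    geno = ["WT"] * g1.shape[1] + ["KO"] * g2.shape[1]
    trt = ["IFN"] * mat.shape[1]
    return make_counts(mat, samples, geno, trt)


SPEC = ContrastSpec("KOvsWT", "KO_IFN", "WT_IFN")


class TestWaldContrast:
    def test_identical_groups_give_null_result(self):
        cm = _two_group_cm([[10, 20, 30]], [[10, 20, 30]])
        f = pd.Series(1.0, index=cm.counts.columns)
        d = pd.Series(0.1, index=cm.counts.index)
        res = wald_contrast(cm, SPEC, f, d)
        assert res["log2FC"].iloc[0] == 0
        assert res["stat"].iloc[0] == 0
        assert res["pvalue"].iloc[0] == 1

    def test_antisymmetry_under_group_swap(self, small_bundle):
        cm = small_bundle["cm"]
        f = size_factors(cm)
        d = estimate_dispersion(cm, f)
        spec = ContrastSpec.canonical("C2")
        a = wald_contrast(cm, spec, f, d)
        b = wald_contrast(cm, spec.swapped(), f, d)
        assert np.allclose(a["log2FC"], -b["log2FC"])
        assert np.allclose(a["stat"], -b["stat"])
        assert np.allclose(a["pvalue"], b["pvalue"])

    def test_all_zero_genes_excluded_from_family(self):
        cm = _two_group_cm([[0, 0, 0], [5, 9, 7]], [[0, 0, 0], [6, 8, 9]])
        f = pd.Series(1.0, index=cm.counts.columns)
        d = pd.Series(0.1, index=cm.counts.index)
        res = wald_contrast(cm, SPEC, f, d)
        assert list(res.index) == ["g1"]

    def test_empty_condition_raises(self):
        cm = _two_group_cm([[1, 2]], [[3, 4]])
        f = pd.Series(1.0, index=cm.counts.columns)
        d = pd.Series(0.1, index=cm.counts.index)
        with pytest.raises(ValueError, match="empty condition"):
            wald_contrast(cm, ContrastSpec("bad", "KO_untreated", "WT_IFN"), f, d)

    def test_null_simulation_type_i_error(self):
        """All-null NB data: raw p < 0.05 fraction matches the nominal rate."""
        rng = np.random.default_rng(5)
        n_genes, n = 5000, 3
        mu = np.exp(rng.uniform(np.log(20), np.log(2000), n_genes))
        mat = nb_draw(rng, np.tile(mu[:, None], (1, 2 * n)), 0.1)
        cm = _two_group_cm(mat[:, :n], mat[:, n:])
        f = size_factors(cm)
        d = pd.Series(0.1, index=cm.counts.index)
        res = wald_contrast(cm, SPEC, f, d)
        frac = float((res["pvalue"] < 0.05).mean())
        band = 3 * np.sqrt(0.05 * 0.95 / n_genes)
        assert abs(frac - 0.05) <= band

    def test_planted_effect_recovery(self):
        """Planted log2 effect 2.0 at alpha = 0.1, n = 3: median estimate in [1.8, 2.2]."""
        cfg = SimConfig(
            n_genes=20_000,
            seed=21,
            class_fractions={"typical": 0.05},
            dispersion=0.1,
            lfc_typical=2.0,
        )
        counts, design, truth = simulate_counts(cfg)
        cm = CountMatrix(counts, design)
        f = size_factors(cm)
        d = estimate_dispersion(cm, f)
        res = wald_contrast(cm, ContrastSpec.canonical("C1"), f, d)
        planted = truth.genes.index[truth.genes["class"] == "typical"]
        assert len(planted) == 1000
        med = float(res.loc[planted, "log2FC"].median())
        assert 1.8 <= med <= 2.2

    def test_padj_never_below_p(self, small_bundle):
        cm = small_bundle["cm"]
        f = size_factors(cm)
        d = estimate_dispersion(cm, f)
        res = wald_contrast(cm, ContrastSpec.canonical("C3"), f, d)
        assert (res["padj"] >= res["pvalue"] - 1e-15).all()


# ------------------------------------------------------------------------- BH
class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.2], [0.2]),
            ([1.0, 1.0], [1.0, 1.0]),
            ([0.03, 0.002, 0.8], [0.045, 0.006, 0.8]),
        ],
    )
    def test_small_vectors(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=60, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=40)
    )
    def test_matches_statsmodels_and_permutation_invariant(self, p):
        ours = bh_adjust(p)
        _, theirs, _, _ = multipletests(p, method="fdr_bh")
        assert ours == pytest.approx(theirs, abs=1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        assert bh_adjust(np.asarray(p)[perm]) == pytest.approx(ours[perm], abs=1e-12)


# ----------------------------------------------------------------- thresholds
class TestCallRegulated:
    def _frame(self, lfc, p, padj):
        return pd.DataFrame(
            {"log2FC": [lfc], "pvalue": [p], "padj": [padj]}, index=["g"]
        )

    def test_volcano_style_raw_p_call(self):
        th = CallThresholds(lfc_min=1.0, p_max=0.005, padj_max=None, use_adjusted=False)
        res = call_regulated(self._frame(1.2, 0.001, 0.02), th)
        assert bool(res["up"].iloc[0])

    def test_boundary_lfc_is_not_called(self):
        th = CallThresholds(lfc_min=1.0, p_max=0.005, padj_max=None, use_adjusted=False)
        res = call_regulated(self._frame(1.0, 1e-9, 1e-9), th)
        assert not bool(res["up"].iloc[0])

    def test_half_lfc_volcano_threshold(self):
        th = CallThresholds(lfc_min=0.5, p_max=0.005, padj_max=None, use_adjusted=False)
        res = call_regulated(self._frame(0.6, 0.004, 0.2), th)
        assert bool(res["up"].iloc[0])

    def test_up_down_mutually_exclusive(self):
        th = CallThresholds(lfc_min=0.5, padj_max=0.05, use_adjusted=True)
        res = call_regulated(self._frame(-2.0, 1e-5, 1e-4), th)
        assert not bool(res["up"].iloc[0]) and bool(res["down"].iloc[0])

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            CallThresholds(lfc_min=-1)
        with pytest.raises(ValueError):
            CallThresholds(p_max=None, padj_max=None, use_adjusted=False)
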