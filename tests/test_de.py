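import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hemideg import (
    CountMatrix,
    NBTwoFactorDE,
    TMMNormalizer,
    ValidationError,
    bh_adjust,
    classify_opposite_direction,
    filter_by_expression,
    interaction_followup,
    overlap_test,
    pca_qc,
)
from hemideg.simulate import SimulationConfig, generate_bulk

from conftest import make_design


def as_counts(arr, genes=None, samples=None):
    arr = np.asarray(arr)
    return CountMatrix(pd.DataFrame(
        arr,
        index=genes or [f"g{i}" for i in range(arr.shape[0])],
        columns=samples or [f"s{j}" for j in range(arr.shape[1])]))


def fit_region(counts, design, **kwargs):
    norm = TMMNormalizer().fit(counts)
    return NBTwoFactorDE(**kwargs).fit(counts, design, norm)


class TestExpressionFilter:
    def test_boundary_examples(self):
        counts = as_counts([[0, 0, 0, 0, 3],   # 1 expressed < ceil(2) -> drop
                            [1, 0, 1, 0, 0]])  # 2 expressed >= 2 -> keep
        kept = filter_by_expression(counts)
        assert kept.gene_ids == ["g1"]

    def test_zero_fraction_keeps_everything(self):
        counts = as_counts([[0, 1], [5, 5]])
        assert filter_by_expression(counts, min_fraction=0.0).n_genes == 2

    def test_matches_brute_force_enumeration(self, rng):
        mat = rng.negative_binomial(2, 0.5, size=(500, 16))
        counts = as_counts(mat)
        kept = filter_by_expression(counts)
        expected = [f"g{i}" for i in range(500)
                    if sum(1 for v in mat[i] if v >= 1) >= math.ceil(0.4 * 16)]
        assert kept.gene_ids == expected

    def test_all_removed_raises(self):
        counts = as_counts(np.zeros((3, 5), dtype=int) + np.eye(3, 5, dtype=int))
        with pytest.raises(ValidationError, match="filter"):
            filter_by_expression(counts)


class TestModelFit:
    def test_balanced_saturated_fit_recovers_group_means(self, balanced_design):
        """Sham groups at mean 10, SNL at 20 with equal offsets -> the fitted
        group means equal the sample means, so condition log2FC is exactly 1."""
        row = []
        for s in balanced_design.sample_ids:
            row.append(20 if "SNL" in s else 10)
        counts = as_counts([row, [15] * 8], samples=balanced_design.sample_ids)
        norm = TMMNormalizer().fit(counts)
        norm.offsets_ = pd.Series(0.0, index=counts.sample_ids)
        fit = NBTwoFactorDE().fit(counts, balanced_design, norm)
        pain = fit.contrast("pain_main")
        assert pain.loc["g0", "log2fc"] == pytest.approx(1.0, abs=1e-6)
        assert pain.loc["g1", "log2fc"] == pytest.approx(0.0, abs=1e-6)

    def test_all_equal_counts_give_zero_effects(self, balanced_design):
        counts = as_counts([[12] * 8, [7] * 8], samples=balanced_design.sample_ids)
        fit = fit_region(counts, balanced_design)
        fac = fit.factorial_coef_
        np.testing.assert_allclose(
            fac[["condition", "side", "condition_x_side"]].to_numpy(), 0.0, atol=1e-8)
        for name in ("pain_main", "side_main", "interaction"):
            res = fit.contrast(name)
            assert (res["F"] < 1e-9).all()
            assert (res["p"] > 0.999).all()

    def test_poisson_data_yields_small_dispersion(self):
        """phi -> 0 truth: median estimated dispersion below 0.05 at n=24."""
        medians = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            design = make_design(n_per_group=6)
            mat = rng.poisson(60.0, size=(300, 24))
            counts = as_counts(mat, samples=design.sample_ids)
            fit = fit_region(counts, design)
            medians.append(np.median(fit.raw_dispersion_))
        assert all(m < 0.05 for m in medians)

    def test_convergence_flag_recorded(self, balanced_design):
        counts = as_counts(
            np.random.default_rng(0).poisson(30, size=(20, 8)),
            samples=balanced_design.sample_ids)
        fit = fit_region(counts, balanced_design)
        assert fit.converged_.dtype == bool and fit.converged_.all()


class TestContrasts:
    def test_signed_t_definition(self, balanced_design, rng):
        counts = as_counts(rng.poisson(50, size=(100, 8)),
                           samples=balanced_design.sample_ids)
        fit = fit_region(counts, balanced_design)
        res = fit.contrast("pain_main")
        np.testing.assert_allclose(res["t_signed"] ** 2, res["F"], atol=1e-9)
        assert (np.sign(res["t_signed"]) == np.sign(res["log2fc"])).all()
        assert ((res["p"] < 0.05) == res["is_deg"]).all()

    def test_fdr_dominates_p_and_bh_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4)
        p = np.random.default_rng(1).uniform(size=200)
        fdr = bh_adjust(p)
        assert (fdr >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()

    def test_t_threshold_2_matches_p_05_for_moderate_df(self, rng):
        """|t| > 2 vs p < 0.05 agree closely once den df >= 20."""
        design = make_design(n_per_group=6)
        counts = as_counts(rng.poisson(40, size=(400, 24)),
                           samples=design.sample_ids)
        fit = fit_region(counts, design)
        res = fit.contrast("pain_main")
        assert fit.denominator_df_ >= 20
        t_call = res["t_signed"].abs() > 2
        agreement = (t_call == res["is_deg"]).mean()
        assert agreement > 0.97

    def test_unknown_contrast_rejected(self, balanced_design, rng):
        counts = as_counts(rng.poisson(30, size=(10, 8)),
                           samples=balanced_design.sample_ids)
        fit = fit_region(counts, balanced_design)
        with pytest.raises(ValueError, match="unknown contrast"):
            fit.contrast("banana")


@pytest.fixture(scope="module")
def planted_fit():
    cfg = SimulationConfig(n_genes=500, markers_per_type=10, regions=("CeA",),
                           affected_cell_types_down={}, affected_cell_types_up={},
                           effect_log2fc=0.0, n_lateralized_genes=30, seed=42)
    counts, design, truth = generate_bulk(cfg)
    rd = design.for_region("CeA")
    filtered = filter_by_expression(counts.subset_samples(rd.sample_ids))
    fit = fit_region(filtered, rd)
    return fit, truth


class TestInteractionFollowup:
    def test_followup_restricted_to_interaction_degs(self, planted_fit):
        fit, _ = planted_fit
        inter = fit.contrast("interaction")
        left, right = interaction_followup(fit, inter)
        degs = set(inter.index[inter["p"] < 0.05])
        assert set(left.index) == degs and set(right.index) == degs
        assert len(left) <= inter["is_deg"].sum()

    def test_planted_interaction_signs_recovered(self, planted_fit):
        fit, truth = planted_fit
        inter = fit.contrast("interaction")
        left, right = interaction_followup(fit, inter)
        lat = truth.index[truth["is_interaction"]].intersection(left.index)
        assert len(lat) > 0
        sign_ok = (np.sign(left.loc[lat, "log2fc"])
                   == np.sign(truth.loc[lat, "lfc_left_CeA"]))
        assert sign_ok.mean() > 0.9

    def test_empty_interaction_list_gives_empty_frames(self, planted_fit):
        fit, _ = planted_fit
        inter = fit.contrast("interaction")
        fake = inter.copy()
        fake["p"] = 0.5
        left, right = interaction_followup(fit, fake)
        assert left.empty and right.empty
        assert classify_opposite_direction(left, right).empty


class TestOppositeDirection:
    def make(self, llfc, lp, rlfc, rp):
        left = pd.DataFrame({"log2fc": [llfc], "p": [lp]}, index=["g"])
        right = pd.DataFrame({"log2fc": [rlfc], "p": [rp]}, index=["g"])
        return classify_opposite_direction(left, right)["classification"].iloc[0]

    @pytest.mark.parametrize("llfc,lp,rlfc,rp,expected", [
        (+0.8, 0.01, -0.6, 0.03, "opposite_significant"),
        (+0.8, 0.01, -0.6, 0.30, "opposite_tendency"),
        (+0.8, 0.01, +0.2, 0.90, "same_direction"),
        (-0.5, 0.04, +0.5, 0.04, "opposite_significant"),
        (-0.5, 0.50, +0.5, 0.70, "same_direction"),
    ])
    def test_classification_rules(self, llfc, lp, rlfc, rp, expected):
        assert self.make(llfc, lp, rlfc, rp) == expected

    def test_mismatched_gene_lists_rejected(self):
        left = pd.DataFrame({"log2fc": [1.0], "p": [0.01]}, index=["g1"])
        right = pd.DataFrame({"log2fc": [1.0], "p": [0.01]}, index=["g2"])
        with pytest.raises(ValidationError):
            classify_opposite_direction(left, right)


class TestPcaQc:
    def test_planted_clusters_separate_on_pc1(self, rng):
        base = rng.poisson(50, size=(200, 10)).astype(float)
        base[:100, 5:] *= 8  # half the genes shifted in samples 5..9
        counts = as_counts(base.astype(int))
        norm = TMMNormalizer().fit(counts)
        scores, var_frac = pca_qc(counts, norm)
        a, b = scores.iloc[:5, 0], scores.iloc[5:, 0]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or \
            min(a.max(), b.max()) < max(a.min(), b.min())
        assert not (set(range(5)) & set())  # clusters disjoint by construction
        assert (a.max() < b.min()) or (b.max() < a.min())
        assert var_frac[0] > var_frac[1]

    def test_duplicated_samples_get_identical_scores(self, rng):
        col = rng.poisson(30, size=60)
        mat = np.column_stack([col, col, rng.poisson(30, size=60),
                               rng.poisson(30, size=60)])
        counts = as_counts(mat)
        norm = TMMNormalizer().fit(counts)
        scores, var_frac = pca_qc(counts, norm)
        np.testing.assert_allclose(scores.iloc[0], scores.iloc[1], atol=1e-8)
        assert (np.diff(var_frac) <= 1e-12).all()
        assert ((var_frac >= 0) & (var_frac <= 1)).all() and var_frac.sum() <= 1 + 1e-9

    def test_too_few_samples_rejected(self, rng):
        counts = as_counts(rng.poisson(30, size=(10, 2)))
        with pytest.raises(ValidationError):
            pca_qc(counts, TMMNormalizer().fit(counts))


class TestOverlapTest:
    def test_exact_enumeration_example(self):
        """N=20, |A|=5, |B|=10, overlap 4: p = 28,028 / 184,756."""
        bg = [f"g{i}" for i in range(20)]
        A = bg[:5]
        B = bg[1:5] + bg[8:14]  # overlap = g1..g4
        k, p = overlap_test(A, B, bg)
        assert k == 4
        assert p == pytest.approx(28_028 / 184_756, rel=1e-12)

    def test_degenerate_full_overlap(self):
        bg = list("abcdef")
        k, p = overlap_test(bg, bg, bg)
        assert k == 6 and p == pytest.approx(1.0)

    def test_disjoint_lists_give_p_one(self):
        bg = [f"g{i}" for i in range(10)]
        k, p = overlap_test(bg[:3], bg[5:8], bg)
        assert k == 0 and p == pytest.approx(1.0)

    def test_deg_outside_background_named(self):
        with pytest.raises(ValidationError, match="zz"):
            overlap_test(["zz"], ["a"], ["a", "b"])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(5, 30), st.data())
    def test_matches_brute_force_enumeration(self, N, data):
        nA = data.draw(st.integers(0, N))
        nB = data.draw(st.integers(0, N))
        bg = [f"g{i}" for i in range(N)]
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        A = list(rng.choice(bg, size=nA, replace=False))
        B = list(rng.choice(bg, size=nB, replace=False))
        k, p = overlap_test(A, B, bg)
        expected = sum(math.comb(nA, x) * math.comb(N - nA, nB - x)
                       for x in range(k, min(nA, nB) + 1)) / math.comb(N, nB)
        assert p == pytest.approx(expected, rel=1e-10)
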