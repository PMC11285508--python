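import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nascentreg.counts_differential import (
    CountMatrix,
    SampleSheet,
    bh_fdr,
    build_design,
    filter_min_cpm,
    filter_min_initiation,
    fit_differential,
    pca_top_features,
    read_counts_tsv,
    tmm_factors,
)
from nascentreg.synthetic_data import simulate_null_counts


def _cm(arr, samples=None):
    arr = np.asarray(arr)
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(arr, [f"f{i}" for i in range(arr.shape[0])], samples)


class TestCountMatrix:
    def test_rejects_negative_and_mismatched(self):
        with pytest.raises(ValueError):
            _cm([[-1, 2]])
        with pytest.raises(ValueError):
            CountMatrix(np.ones((2, 2)), ["a"], ["s1", "s2"])

    def test_lib_sizes_recomputed(self):
        cm = _cm([[1, 2], [3, 4]])
        assert list(cm.lib_sizes) == [4, 6]

    def test_tsv_round_trip(self, tmp_path):
        cm = _cm([[1, 2], [3, 4]])
        cm.write_tsv(tmp_path / "c.tsv")
        back = read_counts_tsv(tmp_path / "c.tsv")
        assert np.array_equal(back.counts, cm.counts)
        assert list(back.sample_ids) == list(cm.sample_ids)


class TestTmmFactors:
    def test_identical_columns_give_unity(self):
        cm = _cm(np.tile([[10], [20], [30], [40]], (1, 2)))
        assert np.allclose(tmm_factors(cm), 1.0)

    def test_proportional_columns_give_unity(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(100, size=400)
        cm = _cm(np.column_stack([a, 2 * a]))
        assert np.allclose(tmm_factors(cm), 1.0)

    def test_trimming_removes_outlier_features(self):
        # 200 high-count features equal across samples; 5 low-count features
        # 16-fold up in B contribute little to library size, so after
        # trimming the factor for B stays essentially 1
        a = np.concatenate([np.full(200, 1000), np.full(5, 10)])
        b = np.concatenate([np.full(200, 1000), np.full(5, 160)])
        cm = _cm(np.column_stack([a, b]))
        f = tmm_factors(cm, ref="s0")
        assert 0.97 <= f["s1"] <= 1.0
        # frozen values from edgeR::calcNormFactors on the same matrix
        assert np.allclose(f.to_numpy(), [1.001873, 0.998131], atol=1e-5)

    @given(st.integers(1, 100), st.integers(0, 2 ** 16))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(50, size=(100, 4)) + 1
        base = tmm_factors(_cm(counts))
        scaled = counts.copy()
        scaled[:, 2] *= scale
        # invariant up to the delta-method precision weights, which depend
        # weakly on absolute counts
        assert np.allclose(tmm_factors(_cm(scaled)), base, atol=0.02)

    def test_all_zero_sample_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(_cm([[1, 0], [2, 0]]))


class TestFilters:
    def test_min_cpm_boundary_inclusive(self):
        # smallest library has exactly 1e6 reads; count 5 there -> cpm 5, kept
        counts = np.zeros((3, 3), dtype=int)
        counts[0] = [5, 100, 100]
        counts[1] = [4, 100, 100]
        counts[2] = [0, 0, 0]
        counts[0, 0] = 5
        filler = np.full((1, 3), 10**6) - counts.sum(axis=0, keepdims=True)
        cm = _cm(np.vstack([counts, filler]))
        keep = filter_min_cpm(cm, min_cpm=5, min_nonzero_samples=2)
        assert keep[0] and not keep[1] and not keep[2]

    def test_min_nonzero_samples_rule(self):
        # high cpm but nonzero in only 4 of 35 samples -> dropped
        counts = np.ones((2, 35), dtype=int)
        counts[0] = 0
        counts[0, :4] = 10**6
        cm = _cm(counts)
        keep = filter_min_cpm(cm, min_cpm=5, min_nonzero_samples=5)
        assert not keep[0] and keep[1]

    def test_min_initiation_boundary(self):
        lib = 10_000_000
        counts = np.zeros((3, 2), dtype=int)
        counts[0, 0] = 7          # exactly 7 per 10M -> kept
        counts[1, 0] = 6          # 0.6/M max -> dropped
        filler = np.full((1, 2), lib) - counts.sum(axis=0)
        cm = _cm(np.vstack([counts, filler]))
        keep = filter_min_initiation(cm, 7.0)
        assert keep[0] and not keep[1] and not keep[2]


class TestBhFdr:
    def test_hand_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_degenerate_inputs(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60), st.booleans())
    @settings(max_examples=200, deadline=None)
    def test_matches_step_up_oracle(self, pvals, _):
        p = np.asarray(pvals)
        m = p.size
        oracle = np.array(
            [min(min(pj * m / (np.sum(p <= pj)) for pj in p if pj >= pi), 1.0)
             for pi in p]
        )
        # oracle: q_i = min over {j: p_j >= p_i} of p_j * m / rank_j
        ours = bh_fdr(p)
        assert np.allclose(ours, oracle, atol=1e-12)
        assert np.all(ours >= p - 1e-15)


class TestDesign:
    def test_aliased_column_dropped_with_warning(self, sheet_6v6):
        tab = sheet_6v6.table.copy()
        # make species a perfect copy of ecotype -> aliased
        tab["species"] = np.where(tab["ecotype"] == "sulfidic", "sulphuraria", "mexicana")
        sheet = SampleSheet(tab.reset_index(drop=True))
        with pytest.warns(UserWarning, match="aliased"):
            X, names = build_design(sheet)
        assert "species_sulphuraria" not in names

    def test_species_nested_in_one_site_is_estimable(self, sheet_6v6):
        tab = sheet_6v6.table.copy()
        tab["species"] = np.where(
            (tab["ecotype"] == "sulfidic") & (tab["drainage"] == "Pichucalco"),
            "sulphuraria", "mexicana",
        )
        X, names = build_design(SampleSheet(tab.reset_index(drop=True)))
        assert "species_sulphuraria" in names
        assert np.linalg.matrix_rank(X) == X.shape[1]


class TestFitDifferential:
    def test_identical_counts_give_null_result(self, sheet_6v6):
        cm = _cm(np.full((4, 12), 50), sheet_6v6.sample_ids)
        res = fit_differential(cm, sheet_6v6)
        assert np.allclose(res["log2fc"], 0.0, atol=1e-6)
        assert np.allclose(res["pvalue"], 1.0, atol=1e-6)
        assert np.all(res["fdr"] >= res["pvalue"] - 1e-12)

    def test_sign_convention_sulfidic_positive(self, sheet_6v6):
        rng = np.random.default_rng(5)
        sulf = np.array([s.startswith("cs_sulfidic") for s in sheet_6v6.sample_ids])
        counts = rng.poisson(100, size=(300, 12))
        counts[0, sulf] = rng.poisson(400, size=sulf.sum())
        cm = _cm(counts, sheet_6v6.sample_ids)
        res = fit_differential(cm, sheet_6v6)
        assert res.loc[0, "log2fc"] > 1.0

    def test_null_pvalues_uniform(self, sheet_6v6):
        null = simulate_null_counts(5000, 12, 100, 0.1, seed=42)
        res = fit_differential(
            null.subset_samples(null.sample_ids),
            SampleSheet(sheet_6v6.table.assign(sample_id=list(null.sample_ids)).reset_index(drop=True)),
            covariates=("drainage",),
        )
        ks = stats.kstest(res["pvalue"], "uniform").statistic
        assert ks < 0.05

    def test_planted_effect_recovery(self, sheet_6v6):
        rng = np.random.default_rng(7)
        F = 5000
        mu = 100 * np.exp(rng.normal(0, 0.5, size=(F, 1))) * np.ones((1, 12))
        sulf = np.array([s.startswith("cs_sulfidic") for s in sheet_6v6.sample_ids])
        # 250 features up, 250 down at |log2fc| = 2 among a null majority
        for rows, sign in ((slice(0, 250), 1.0), (slice(250, 500), -1.0)):
            mu[rows, sulf] *= 2.0 ** (sign)
            mu[rows, ~sulf] /= 2.0 ** (sign)
        counts = rng.poisson(rng.gamma(10.0, 0.1 * mu))
        cm = _cm(counts, sheet_6v6.sample_ids)
        res = fit_differential(cm, sheet_6v6)
        assert abs(np.median(res["log2fc"][:250]) - 2.0) < 0.25
        assert abs(np.median(res["log2fc"][250:500]) + 2.0) < 0.25

    def test_qlf_mode_runs_and_is_conservative(self, sheet_6v6):
        null = simulate_null_counts(500, 12, 100, 0.1, seed=9)
        sheet = SampleSheet(
            sheet_6v6.table.assign(sample_id=list(null.sample_ids)).reset_index(drop=True)
        )
        lrt = fit_differential(null, sheet, covariates=("drainage",), test="lrt")
        qlf = fit_differential(null, sheet, covariates=("drainage",), test="qlf")
        assert (qlf["pvalue"] < 0.05).mean() <= (lrt["pvalue"] < 0.05).mean() + 0.02


class TestPca:
    def test_duplicated_samples_coincide(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(100, size=(300, 5))
        counts = np.column_stack([base, base[:, 0]])
        coords = pca_top_features(_cm(counts), n_top=100)
        assert np.allclose(coords.iloc[0], coords.iloc[5], atol=1e-8)

    def test_constant_counts_give_zero_coordinates(self):
        cm = _cm(np.full((50, 4), 30))
        coords = pca_top_features(cm, n_top=10)
        assert np.allclose(coords.to_numpy(), 0.0, atol=1e-8)

    def test_planted_clusters_separate_on_pc1(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(12)
        mu = np.full((600, 12), 100.0)
        mu[:300, :6] *= 4.0
        counts = rng.poisson(mu)
        coords = pca_top_features(_cm(counts), n_top=500)
        labels = [0] * 6 + [1] * 6
        assert silhouette_score(coords[["PC1"]], labels) > 0.8

    def test_n_top_clamped_with_warning(self):
        cm = _cm(np.random.default_rng(0).poisson(50, size=(20, 4)))
        with pytest.warns(UserWarning, match="n_top"):
            pca_top_features(cm, n_top=500)
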