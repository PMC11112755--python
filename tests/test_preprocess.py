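"""Preprocessing chain: filtering, transform, imputation, outliers,
technical denoising."""

import numpy as np
import pandas as pd
import pytest

from crossomix import preprocess as pp
from crossomix.containers import InvalidConfigError, OmicsMatrix
from crossomix import validation


def _matrix(values, scale="raw", columns=None):
    df = pd.DataFrame(
        values,
        index=[f"f{i}" for i in range(np.shape(values)[0])],
        columns=columns or [f"s{j}" for j in range(np.shape(values)[1])],
    )
    return OmicsMatrix(df, scale=scale)


class TestFilterMissingness:
    def test_graded_missingness_count(self):
        """Features at 0.0,0.1,...,0.9 missing fraction; inclusive 0.40
        cutoff keeps exactly the four below it."""
        n = 10
        vals = np.ones((10, n))
        for i in range(10):
            vals[i, :i] = np.nan
        m = _matrix(vals)
        kept, log = pp.filter_missingness(m, 0.40)
        assert kept.n_features == 4
        assert log["n_removed"] == 6

    def test_threshold_inclusive(self):
        vals = np.ones((1, 10))
        vals[0, :4] = np.nan  # exactly 40% missing
        kept, _ = pp.filter_missingness(_matrix(vals), 0.40)
        assert kept.n_features == 0

    def test_fully_observed_identity(self, small_study, small_design):
        matrix, _ = small_study
        full = matrix.copy()
        full.values = full.values.fillna(1.0)
        kept, log = pp.filter_missingness(full, 0.40, sample_meta=small_design)
        assert kept.n_features == full.n_features
        assert log["removed"] == []

    def test_participant_unit_counts_any_observation(self):
        """A feature missing in some but not all profiles of every
        participant has zero participant-level missingness."""
        meta = pd.DataFrame(
            {"participant": ["P1", "P1", "P2", "P2"]},
            index=["s0", "s1", "s2", "s3"],
        )
        vals = np.array([[np.nan, 1.0, np.nan, 1.0]])
        m = _matrix(vals, columns=list(meta.index))
        kept, log = pp.filter_missingness(m, 0.40, sample_meta=meta)
        assert kept.n_features == 1

    def test_empty_result_warns(self):
        vals = np.full((3, 4), np.nan)
        vals[:, 0] = 1.0
        with pytest.warns(pp.EmptyResultWarning):
            kept, _ = pp.filter_missingness(_matrix(vals), 0.5)
        assert kept.n_features == 0


class TestLog2:
    def test_known_values_and_roundtrip(self):
        m = _matrix([[8.0, 1.0], [2.0, 4.0]])
        out = pp.log2_transform(m)
        assert out.scale == "log2"
        assert out.values.iloc[0, 0] == 3.0
        assert out.values.iloc[0, 1] == 0.0
        back = pp.inverse_log2(out)
        assert np.allclose(back.values, m.values)

    def test_nonpositive_rejected_with_location(self):
        m = _matrix([[1.0, -2.0]])
        with pytest.raises(ValueError, match="f0.*s1"):
            pp.log2_transform(m)

    def test_requires_raw_scale(self):
        m = _matrix([[1.0]], scale="log2")
        with pytest.raises(InvalidConfigError):
            pp.log2_transform(m)

    def test_mask_unchanged(self):
        m = _matrix([[8.0, np.nan]])
        out = pp.log2_transform(m)
        assert out.values.isna().iloc[0, 1]


class TestQrilc:
    def test_identity_without_missing(self):
        m = _matrix(np.random.default_rng(0).normal(10, 1, (50, 3)), scale="log2")
        out, params = pp.impute_qrilc(m, seed=1)
        pd.testing.assert_frame_equal(out.values, m.values)
        assert params == {}

    def test_recovers_censored_normal_parameters(self):
        r = validation.qrilc_recovery(n=500, censor_fraction=0.2, seed=3)
        assert r["mu_error"] < 0.15
        assert r["sigma_error"] < 0.15

    def test_truncation_bound_respected(self):
        r = validation.qrilc_recovery(n=500, censor_fraction=0.2, seed=4)
        assert r["bound_respected"]
        assert r["max_imputed"] <= r["bound"] + 1e-9

    def test_refuses_raw_scale(self):
        m = _matrix([[1.0, np.nan]], scale="raw")
        with pytest.raises(InvalidConfigError):
            pp.impute_qrilc(m)

    def test_sparse_column_falls_back_to_half_minimum(self):
        vals = np.full((10, 1), np.nan)
        vals[:3, 0] = [8.0, 9.0, 10.0]
        m = _matrix(vals, scale="log2")
        with pytest.warns(UserWarning, match="half-minimum"):
            out, params = pp.impute_qrilc(m, seed=0)
        assert not out.values.isna().any().any()
        assert params["s0"]["fallback"]

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(10, 1, (100, 4))
        vals[vals < 9] = np.nan
        m = _matrix(vals, scale="log2")
        a, _ = pp.impute_qrilc(m, seed=11)
        b, _ = pp.impute_qrilc(m, seed=11)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestPcaOutliers:
    def test_spiked_sample_flagged(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, (100, 40))
        vals[:30, 5] += 50.0  # one profile shifted on 30% of features
        m = _matrix(vals, scale="log2")
        flags = pp.flag_pca_outliers(m)
        assert flags["s5"]
        assert flags.sum() <= 3

    def test_homogeneous_data_low_flag_rate(self):
        rng = np.random.default_rng(1)
        m = _matrix(rng.normal(0, 1, (200, 150)), scale="log2")
        flags = pp.flag_pca_outliers(m, mad_multiplier=5.0)
        assert flags.mean() < 0.01

    def test_infinite_multiplier_flags_nothing(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(0, 1, (30, 20)), scale="log2")
        flags = pp.flag_pca_outliers(m, mad_multiplier=np.inf)
        assert not flags.any()

    def test_invalid_component_count(self):
        m = _matrix(np.random.default_rng(3).normal(0, 1, (5, 4)), scale="log2")
        with pytest.raises(InvalidConfigError):
            pp.flag_pca_outliers(m, n_components=10)


class TestDenoise:
    def test_removes_planted_batch_variance(self):
        r = validation.denoise_variance_share(
            batch_sd=2.0, resid_sd=0.5, n_levels=6, per_level=20, seed=0
        )
        assert r["share_before"] > 0.5
        assert r["share_after"] < 0.05

    def test_near_identity_without_batch_structure(self):
        rng = np.random.default_rng(1)
        n = 120
        cols = [f"s{i}" for i in range(n)]
        m = _matrix(rng.normal(10, 1, (10, n)), scale="log2", columns=cols)
        tf = pd.DataFrame({"plate": np.repeat(list("ABCD"), n // 4)}, index=cols)
        out, _ = pp.denoise_technical(m, tf)
        assert np.abs(out.values.to_numpy() - m.values.to_numpy()).max() < 0.5

    def test_single_level_factor_dropped(self):
        rng = np.random.default_rng(2)
        cols = [f"s{i}" for i in range(20)]
        m = _matrix(rng.normal(0, 1, (3, 20)), scale="log2", columns=cols)
        tf = pd.DataFrame({"plate": ["only"] * 20}, index=cols)
        with pytest.warns(UserWarning, match="single level"):
            out, log = pp.denoise_technical(m, tf)
        assert log["factors"] == []
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_matches_statsmodels_mixedlm_blups(self):
        """Independent oracle: variance components and BLUPs from
        statsmodels MixedLM (single random factor) agree with the
        Woodbury REML fit."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        n_lev, per = 5, 30
        lev = np.repeat([f"L{i}" for i in range(n_lev)], per)
        y = 10 + rng.normal(0, 1.5, n_lev)[
            np.repeat(np.arange(n_lev), per)
        ] + rng.normal(0, 0.7, n_lev * per)
        cols = [f"s{i}" for i in range(n_lev * per)]
        m = _matrix(y[None, :], scale="log2", columns=cols)
        tf = pd.DataFrame({"batch": lev}, index=cols)
        out, log = pp.denoise_technical(m, tf)

        df = pd.DataFrame({"y": y, "batch": lev})
        fit = smf.mixedlm("y ~ 1", df, groups=df["batch"]).fit(reml=True)
        blups = fit.random_effects
        pred_sm = np.array([float(blups[b].iloc[0]) for b in lev])
        pred_mine = y - out.values.to_numpy()[0]
        assert np.abs(pred_sm - pred_mine).max() < 1e-3

    def test_reduces_intraclass_correlation(self, small_study, small_design):
        matrix, _ = small_study
        full = matrix.copy()
        full.values = np.log2(full.values.fillna(full.values.min().min()))
        full.scale = "log2"
        out, _ = pp.denoise_technical(full, small_design[["plate", "box"]])

        def icc(values, factor):
            shares = []
            for row in values.to_numpy():
                s = pd.Series(row, index=values.columns)
                shares.append(
                    s.groupby(small_design[factor]).mean().var(ddof=1)
                    / s.var(ddof=1)
                )
            return np.mean(shares)

        for factor in ("plate", "box"):
            assert icc(out.values, factor) <= icc(full.values, factor) + 1e-6
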