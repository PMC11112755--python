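"""Repeated-measures GLS: estimation oracles, reference distributions,
effective number of tests, multiplicity corrections and summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossomix import synthdata as sd
from crossomix.association import (
    IdentifiabilityError,
    RepeatedMeasuresGLS,
    apply_corrections,
    association_scan,
    association_summary,
    effective_number_tests,
    fit_mvn_feature,
)
from crossomix.containers import InvalidConfigError
from crossomix.synthdata import exposures_per_sample


@pytest.fixture(scope="module")
def design30():
    return sd.generate_design(sd.DesignConfig(n_participants=30, seed=21))


@pytest.fixture(scope="module")
def exposure30(design30):
    expo = sd.generate_exposures(design30, sd.ExposureModel(), seed=22)
    x = exposures_per_sample(design30, expo)["NO2"]
    return (x - x.mean()) / x.std()


class TestFit:
    def test_identity_covariance_reduces_to_ols(self, design30, exposure30):
        """With the covariance constrained proportional to the identity the
        GLS estimator equals ordinary least squares exactly; the estimated
        unstructured fit stays close."""
        rng = np.random.default_rng(0)
        y = rng.standard_normal(len(design30))
        X = np.column_stack([np.ones(len(design30)), exposure30])
        b_ols = np.linalg.lstsq(X, y, rcond=None)[0]

        model = RepeatedMeasuresGLS(
            y, design30, exposure30, covariates=(), include_bmi=False
        )
        res_id = model.fit(cov_structure="scaled_identity")
        assert np.abs(res_id.params[0] - b_ols).max() < 1e-10

        res_un = model.fit()
        assert np.abs(res_un.params[0] - b_ols).max() < 0.2

    def test_effect_recovery_unbiased(self):
        r_summary = __import__("crossomix.validation", fromlist=["beta_recovery"])
        r = r_summary.beta_recovery(n_participants=60, n_reps=100, beta=0.5, seed=5)
        assert abs(r["relative_bias"]) < 0.05

    def test_permuted_exposure_gives_uniform_pvalues(self, design30):
        """Null p-values across independent features under a permuted
        exposure pass a KS uniformity check at the 1% level."""
        rng = np.random.default_rng(33)
        F = 150
        theta = np.eye(F)
        expo = sd.generate_exposures(design30, sd.ExposureModel(), seed=34)
        _, truth = sd.generate_omics(
            design30, expo, theta, sd.EffectSpec.none(),
            batch_sd=0.0, censor_fraction=0.0, seed=35,
        )
        x = exposures_per_sample(design30, expo)["NO2"].to_numpy()
        # permute exposure at the participant-visit level
        visits = design30.reset_index().groupby(["participant", "visit"]).ngroup()
        perm = rng.permutation(visits.nunique())
        xp = pd.Series(x).groupby(visits.values).transform("first")
        xp = np.array([x[visits.values == perm[g]][0] for g in visits.values])
        res = RepeatedMeasuresGLS(truth["latent"], design30, xp).fit()
        stat, p = stats.kstest(res.exposure_pvalues, "uniform")
        assert p > 0.01

    def test_unstructured_loglik_dominates_compound_symmetry(
        self, design30, exposure30
    ):
        """Nesting: the unstructured REML optimum cannot fall below the
        compound-symmetry submodel's."""
        rng = np.random.default_rng(44)
        pidx = design30.groupby("participant").ngroup().to_numpy()
        y = (
            0.3 * exposure30.to_numpy()
            + rng.normal(0, 1, 30)[pidx]
            + rng.normal(0, 0.6, len(design30))
        )
        model = RepeatedMeasuresGLS(y, design30, exposure30)
        res_un = model.fit()
        res_cs = model.fit(cov_structure="compound_symmetry")
        assert res_un.loglik[0] >= res_cs.loglik[0] - 1e-4

    def test_constant_exposure_rejected(self, design30):
        y = np.random.default_rng(1).standard_normal(len(design30))
        with pytest.raises(IdentifiabilityError):
            RepeatedMeasuresGLS(y, design30, np.ones(len(design30)))

    def test_minimum_participants_enforced(self):
        design = sd.generate_design(sd.DesignConfig(n_participants=5, seed=1))
        y = np.zeros(len(design))
        with pytest.raises(InvalidConfigError):
            RepeatedMeasuresGLS(y, design, np.arange(len(design)))

    def test_missing_occasions_use_subvectors(self, design30, exposure30):
        """Dropping profiles leaves the fit defined and close to the
        complete-data estimate."""
        rng = np.random.default_rng(55)
        pidx = design30.groupby("participant").ngroup().to_numpy()
        y = 0.4 * exposure30.to_numpy() + rng.normal(0, 1, 30)[pidx] + rng.normal(
            0, 0.5, len(design30)
        )
        full = RepeatedMeasuresGLS(y, design30, exposure30).fit()
        keep = np.ones(len(design30), dtype=bool)
        keep[rng.choice(len(design30), size=8, replace=False)] = False
        sub = RepeatedMeasuresGLS(
            y[keep], design30[keep], exposure30[keep]
        ).fit()
        j = full._tested_index()
        assert abs(full.params[0, j] - sub.params[0, j]) < 0.15

    def test_summary_renders(self, design30, exposure30):
        y = np.random.default_rng(2).standard_normal(len(design30))
        res = RepeatedMeasuresGLS(y, design30, exposure30).fit()
        text = res.summary(0)
        assert "Repeated-measures GLS" in text
        assert "exposure" in text

    def test_fit_mvn_feature_wrapper(self, design30, exposure30):
        y = np.random.default_rng(3).standard_normal(len(design30))
        rec = fit_mvn_feature(y, design30, exposure30, exposure_name="NO2")
        assert rec.exposure == "NO2"
        assert 0 < rec.p <= 1
        assert rec.se > 0


class TestEffectiveNumberTests:
    def test_exact_rank_three(self):
        rng = np.random.default_rng(0)
        signals = rng.standard_normal((3, 50))
        mat = np.vstack([signals[i % 3] for i in range(30)])
        assert effective_number_tests(mat) == 3

    def test_iid_features_exceeding_samples(self):
        rng = np.random.default_rng(1)
        mat = rng.standard_normal((100, 20))
        assert effective_number_tests(mat) == 19

    def test_single_feature(self):
        assert effective_number_tests(np.random.default_rng(2).normal(0, 1, (1, 30))) == 1

    def test_duplication_invariance(self):
        rng = np.random.default_rng(3)
        mat = rng.standard_normal((100, 20))
        dup = np.vstack([mat, mat[:1]])
        assert effective_number_tests(dup) == effective_number_tests(mat)

    def test_zero_variance_features_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        mat = np.vstack([rng.standard_normal((5, 30)), np.ones((1, 30))])
        with pytest.warns(UserWarning, match="zero-variance"):
            ent = effective_number_tests(mat)
        assert ent <= 5

    def test_requires_complete_matrix(self):
        mat = np.ones((3, 4))
        mat[0, 0] = np.nan
        with pytest.raises(InvalidConfigError):
            effective_number_tests(mat)


class TestCorrections:
    def _frame(self, ps):
        return pd.DataFrame(
            {"feature": [f"f{i}" for i in range(len(ps))], "exposure": "NO2", "p": ps}
        )

    def test_ent_threshold_strictly_below(self):
        res = apply_corrections(self._frame([0.04 / 284]), ent=284, n_features=6040)
        assert res["significant_ent"].iloc[0]
        assert not res["significant_full"].iloc[0]

    def test_exact_threshold_not_significant(self):
        res = apply_corrections(self._frame([0.05]), ent=1, n_features=1)
        assert not res["significant_ent"].iloc[0]

    def test_flags_coincide_when_ent_equals_n(self):
        ps = [0.001, 0.01, 0.2]
        res = apply_corrections(self._frame(ps), ent=3, n_features=3)
        assert (res["significant_ent"] == res["significant_full"]).all()

    def test_full_correction_at_least_as_stringent(self):
        ps = list(np.linspace(1e-6, 0.9, 50))
        res = apply_corrections(self._frame(ps), ent=10, n_features=50)
        assert not (res["significant_full"] & ~res["significant_ent"]).any()

    def test_invalid_ent(self):
        with pytest.raises(InvalidConfigError):
            apply_corrections(self._frame([0.5]), ent=0, n_features=1)
        with pytest.raises(InvalidConfigError):
            apply_corrections(self._frame([0.5]), ent=10, n_features=5)


class TestSummary:
    def _results(self, sig_map, exposures=("NO2", "PM10")):
        rows = []
        for e in exposures:
            for f, sig_for in sig_map.items():
                rows.append(
                    {
                        "feature": f,
                        "exposure": e,
                        "p": 1e-9 if e in sig_for else 0.9,
                        "significant_ent": e in sig_for,
                    }
                )
        return pd.DataFrame(rows)

    def test_no_significant_features(self):
        res = self._results({"f1": set(), "f2": set()})
        s = association_summary(res)
        assert s["n_unique"] == 0
        assert all(v == 0 for v in s["per_exposure"].values())

    def test_combination_partition(self):
        sig = {f"a{i}": {"NO2"} for i in range(10)}
        sig.update({f"b{i}": {"NO2", "PM10"} for i in range(5)})
        s = association_summary(self._results(sig))
        combos = {
            tuple(r["exposures"]): r["n_features"]
            for _, r in s["combinations"].iterrows()
        }
        assert combos[("NO2",)] == 10
        assert combos[("NO2", "PM10")] == 5
        assert s["n_unique"] == 15
        assert s["per_exposure"] == {"NO2": 15, "PM10": 5}

    def test_feature_significant_everywhere_counted_once(self):
        exposures = ("PM10", "PM25", "NO2", "BC", "PCNT")
        res = self._results({"f1": set(exposures)}, exposures=exposures)
        s = association_summary(res)
        assert s["n_unique"] == 1


class TestScan:
    def test_scan_recovers_strong_effects(self, small_design, small_exposures):
        theta, _ = sd.generate_precision_matrix(sd.PrecisionSpec(p=12), seed=61)
        effects = sd.EffectSpec(affected=[0, 1, 2], beta=0.05, pollutant="NO2")
        m, truth = sd.generate_omics(
            small_design, small_exposures, theta, effects,
            batch_sd=0.0, censor_fraction=0.0, seed=62,
        )
        log2m = m.copy()
        log2m.values = np.log2(log2m.values)
        log2m.scale = "log2"
        results = association_scan(
            log2m, small_design, small_exposures, pollutants=["NO2"]
        )
        results = apply_corrections(results, ent=12, n_features=12)
        hits = set(results.loc[results["significant_ent"], "feature"])
        assert set(truth["affected"]) <= hits
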