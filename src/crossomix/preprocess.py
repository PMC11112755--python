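"""Preprocessing chain: missingness filter, log2, QRILC, outliers, denoising.

The stages are order-dependent and enforce it through the container's scale
flag and missingness mask: features with excessive missingness are removed
on the raw table, intensities are log2 transformed, left-censored values are
imputed by QRILC (quantile regression for left-censored data), outlying
profiles are flagged on PCA scores, and technical batch structure (e.g.
plate and box) is removed by subtracting best linear unbiased predictors
(BLUPs) of crossed random intercepts estimated per feature by REML.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import InvalidConfigError, OmicsMatrix


class EmptyResultWarning(UserWarning):
    """A filtering step removed everything."""


# ---------------------------------------------------------------------------
# missingness filter
# ---------------------------------------------------------------------------

def filter_missingness(
    m: OmicsMatrix,
    max_missing_frac: float = 0.40,
    sample_meta: pd.DataFrame | None = None,
    unit: str = "participant",
):
    """Remove features missing in at least ``max_missing_frac`` of units.

    The unit is the participant by default: a feature observed in any
    profile of a participant counts as observed for that participant.  Pass
    ``unit="sample"`` (or no metadata) for a per-profile fraction.  The
    threshold is inclusive: a feature exactly at the cutoff is removed.

    Returns ``(filtered, log)`` where ``log`` records the removed features
    and their missing fractions.
    """
    if not 0.0 < max_missing_frac <= 1.0:
        raise InvalidConfigError("max_missing_frac must lie in (0, 1]")
    mask = m.values.isna()
    if unit == "participant" and sample_meta is not None:
        groups = sample_meta.loc[m.values.columns, "participant"]
        # missing for a participant only if missing in all of their profiles
        frac = mask.T.groupby(groups.values).all().mean(axis=0)
    else:
        frac = mask.mean(axis=1)
    keep = frac < max_missing_frac
    if not keep.any():
        warnings.warn(
            "missingness filter removed every feature", EmptyResultWarning, stacklevel=2
        )
    log = {
        "removed": list(m.values.index[~keep]),
        "n_removed": int((~keep).sum()),
        "n_kept": int(keep.sum()),
        "missing_fraction": {f: float(frac[f]) for f in m.values.index[~keep]},
        "threshold": max_missing_frac,
        "unit": unit if sample_meta is not None else "sample",
    }
    return m.select_features(m.values.index[keep]), log


def log2_transform(m: OmicsMatrix) -> OmicsMatrix:
    """Log2 transform a raw-intensity table; missing mask is unchanged."""
    if m.scale != "raw":
        raise InvalidConfigError("log2_transform expects a raw-scale matrix")
    vals = m.values.to_numpy()
    bad = np.asarray((vals <= 0) & ~np.isnan(vals))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive intensity at feature {m.values.index[i]!r}, "
            f"sample {m.values.columns[j]!r}"
        )
    out = m.copy()
    out.values = np.log2(m.values)
    out.scale = "log2"
    return out


def inverse_log2(m: OmicsMatrix) -> OmicsMatrix:
    out = m.copy()
    if m.scale != "log2":
        raise InvalidConfigError("matrix is not log2-scaled")
    out.values = np.exp2(m.values)
    out.scale = "raw"
    return out


# ---------------------------------------------------------------------------
# QRILC imputation
# ---------------------------------------------------------------------------

def _qrilc_column(x: np.ndarray, tune_sigma: float, rng: np.random.Generator):
    """Impute one profile (column) assuming left-censoring below a detection
    limit.

    The latent complete distribution is assumed normal.  Observed order
    statistics occupy the upper (1 - f) portion of the distribution, so
    regressing them on the standard-normal quantiles of their plotting
    positions recovers (mu, sigma) of the full distribution; missing values
    are then drawn from N(mu, tune_sigma * sigma) truncated above at the
    estimated censoring quantile mu + sigma * Phi^-1(f).
    """
    n = x.size
    miss = np.isnan(x)
    k = int(miss.sum())
    if k == 0:
        return x, None
    obs = np.sort(x[~miss])
    if obs.size < 4:
        warnings.warn(
            "fewer than 4 observed values in a profile; falling back to "
            "half-minimum imputation",
            UserWarning,
            stacklevel=3,
        )
        fill = (obs.min() - 1.0) if obs.size else 0.0  # half-minimum on raw scale
        out = x.copy()
        out[miss] = fill
        return out, {"mu": np.nan, "sigma": np.nan, "fallback": True}
    f = k / n
    # Blom plotting positions for ranks k+1 .. n of the latent sample
    ranks = np.arange(k + 1, n + 1)
    pp = (ranks - 0.375) / (n + 0.25)
    q = stats.norm.ppf(pp)
    sigma, mu = np.polyfit(q, obs, 1)
    sigma = max(sigma, 1e-8)
    upper = mu + sigma * stats.norm.ppf(max(f, 1e-12))
    a = -np.inf
    b = (upper - mu) / (tune_sigma * sigma)
    draws = stats.truncnorm.rvs(a, b, loc=mu, scale=tune_sigma * sigma, size=k, random_state=rng)
    out = x.copy()
    out[miss] = draws
    return out, {"mu": float(mu), "sigma": float(sigma), "fallback": False}


def impute_qrilc(m: OmicsMatrix, tune_sigma: float = 1.0, seed: int = 0):
    """Column-wise QRILC imputation of a log2-scale matrix.

    Returns ``(imputed, params)``: the complete matrix and the per-sample
    estimated (mu, sigma) of the latent complete distribution.
    """
    if m.scale != "log2":
        raise InvalidConfigError("impute_qrilc requires a log2-scale matrix")
    if tune_sigma <= 0:
        raise InvalidConfigError("tune_sigma must be > 0")
    rng = np.random.default_rng(seed)
    out = m.copy()
    vals = out.values.to_numpy(dtype=float).copy()
    params = {}
    for j, sample in enumerate(out.values.columns):
        vals[:, j], info = _qrilc_column(vals[:, j], tune_sigma, rng)
        if info is not None:
            params[sample] = info
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    return out, params


def estimate_censored_normal(x: np.ndarray):
    """(mu, sigma) of a left-censored normal sample (NaN = censored), by the
    same order-statistic regression QRILC uses.  Exposed for diagnostics."""
    n = x.size
    miss = np.isnan(x)
    obs = np.sort(x[~miss])
    k = int(miss.sum())
    ranks = np.arange(k + 1, n + 1)
    pp = (ranks - 0.375) / (n + 0.25)
    sigma, mu = np.polyfit(stats.norm.ppf(pp), obs, 1)
    return float(mu), float(sigma)


# ---------------------------------------------------------------------------
# PCA outlier flagging
# ---------------------------------------------------------------------------

def flag_pca_outliers(
    m: OmicsMatrix, n_components: int = 3, mad_multiplier: float = 5.0
) -> pd.Series:
    """Flag profiles with extreme scores on leading principal components.

    Features are standardized, profiles are projected on the first
    ``n_components`` PCs, and a profile is flagged when any score deviates
    from the component median by more than ``mad_multiplier`` robust SDs
    (1.4826 * MAD).  Only flags are returned; the caller decides on removal.
    """
    if m.values.isna().any().any():
        raise InvalidConfigError("flag_pca_outliers requires an imputed matrix")
    X = m.values.to_numpy(dtype=float).T  # samples x features
    n_samp, n_feat = X.shape
    if n_components > min(n_samp, n_feat):
        raise InvalidConfigError("n_components exceeds matrix dimensions")
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    from sklearn.decomposition import PCA

    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(Xs)
    med = np.median(scores, axis=0)
    mad = np.median(np.abs(scores - med), axis=0) * 1.4826
    mad[mad == 0] = 1e-12
    flag = (np.abs(scores - med) > mad_multiplier * mad).any(axis=1)
    return pd.Series(flag, index=m.values.columns, name="pca_outlier")


# ---------------------------------------------------------------------------
# technical denoising: crossed random intercepts, REML via Woodbury
# ---------------------------------------------------------------------------

def _factor_design(levels: pd.Series) -> np.ndarray:
    cats = list(dict.fromkeys(levels))
    Z = np.zeros((len(levels), len(cats)))
    for i, v in enumerate(levels):
        Z[i, cats.index(v)] = 1.0
    return Z


class _CrossedREML:
    """Intercept-only Gaussian model with crossed random intercepts.

    y = mu + Z1 u1 + ... + Zm um + e,  uk ~ N(0, sigma^2 gamma_k I).

    The restricted likelihood is profiled over mu and sigma^2 and optimized
    over log variance ratios gamma_k.  All linear algebra runs in the
    (total number of levels)-dimensional space via the Woodbury identity,
    so per-feature fits cost O(q^3) with q ~ 10.
    """

    def __init__(self, Z_list):
        self.Z = np.hstack(Z_list)
        self.q_sizes = [Z.shape[1] for Z in Z_list]
        self.n = self.Z.shape[0]
        self.G = self.Z.T @ self.Z
        self.Zt1 = self.Z.sum(axis=0)

    def _gamma_diag(self, log_gammas):
        return np.concatenate(
            [np.full(q, np.exp(lg)) for q, lg in zip(self.q_sizes, log_gammas)]
        )

    def _core(self, log_gammas, Zty, y, sum_y, yty):
        g = self._gamma_diag(log_gammas)
        q = g.size
        # M = D^-1 + Z'Z with D = diag(g); W^-1 = I - Z M^-1 Z'
        M = self.G + np.diag(1.0 / g)
        try:
            cf = np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            return None
        def msolve(v):
            return np.linalg.solve(cf.T, np.linalg.solve(cf, v))
        # quadratic forms through W^-1
        one_W_one = self.n - self.Zt1 @ msolve(self.Zt1)
        one_W_y = sum_y - self.Zt1 @ msolve(Zty)
        y_W_y = yty - Zty @ msolve(Zty)
        mu = one_W_y / one_W_one
        qform = y_W_y - 2 * mu * one_W_y + mu**2 * one_W_one
        logdet_W = 2 * np.sum(np.log(np.diag(cf))) + np.sum(np.log(g))
        return mu, qform, logdet_W, one_W_one, msolve, g

    def neg_restricted_loglik(self, log_gammas, Zty, y, sum_y, yty):
        core = self._core(log_gammas, Zty, y, sum_y, yty)
        if core is None:
            return 1e10
        mu, qform, logdet_W, one_W_one, _, _ = core
        if qform <= 0:
            return 1e10
        sigma2 = qform / (self.n - 1)
        return 0.5 * ((self.n - 1) * np.log(sigma2) + logdet_W + np.log(one_W_one))

    def fit_feature(self, y: np.ndarray, x0=None):
        Zty = self.Z.T @ y
        sum_y, yty = y.sum(), y @ y
        m = len(self.q_sizes)
        x0 = np.zeros(m) if x0 is None else x0
        res = optimize.minimize(
            self.neg_restricted_loglik,
            x0,
            args=(Zty, y, sum_y, yty),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400},
        )
        core = self._core(res.x, Zty, y, sum_y, yty)
        if core is None:
            return None, res
        mu, qform, _, _, msolve, g = core
        # BLUP: u_hat = D Z' W^-1 r with r = y - mu
        Ztr = Zty - mu * self.Zt1
        u = g * (Ztr - self.G @ msolve(Ztr))
        return {"mu": mu, "u": u, "gammas": np.exp(res.x), "converged": bool(res.success)}, res


def denoise_technical(
    m: OmicsMatrix, technical_factors: pd.DataFrame, factors: list[str] | None = None
):
    """Subtract per-feature BLUPs of crossed technical random intercepts.

    For every feature an intercept-only linear mixed model with one random
    intercept per technical factor (e.g. plate and box, crossed) is fitted
    by REML, and each profile's predicted random effects are subtracted.
    The fixed-effect mean is retained.  Factors with a single level carry no
    information and are dropped with a warning.

    Returns ``(denoised, log)``; the log reports the estimated variance
    ratios per feature and any fallbacks.
    """
    if m.values.isna().any().any():
        raise InvalidConfigError("denoise_technical requires an imputed matrix")
    factors = list(factors or technical_factors.columns)
    tf = technical_factors.loc[m.values.columns, factors]
    usable, dropped = [], []
    for f in factors:
        if tf[f].nunique() < 2:
            dropped.append(f)
            warnings.warn(f"technical factor {f!r} has a single level; dropped", UserWarning)
        else:
            usable.append(f)
    if not usable:
        return m.copy(), {"factors": [], "dropped": dropped}

    Z_list = [_factor_design(tf[f]) for f in usable]
    model = _CrossedREML(Z_list)
    X = m.values.to_numpy(dtype=float)
    out = X.copy()
    gammas, fallbacks = {}, []
    for i, fid in enumerate(m.values.index):
        y = X[i]
        est, res = model.fit_feature(y)
        if est is None or not est["converged"]:
            # sequential one-factor-at-a-time fallback
            fallbacks.append(fid)
            resid = y.copy()
            total_pred = np.zeros_like(y)
            for Z in Z_list:
                sub = _CrossedREML([Z])
                est1, _ = sub.fit_feature(resid)
                if est1 is None:
                    continue
                pred = Z @ est1["u"]
                resid = resid - pred
                total_pred += pred
            out[i] = y - total_pred
            gammas[fid] = None
        else:
            pred = np.zeros_like(y)
            start = 0
            for Z in Z_list:
                q = Z.shape[1]
                pred += Z @ est["u"][start : start + q]
                start += q
            out[i] = y - pred
            gammas[fid] = [float(v) for v in est["gammas"]]
    if fallbacks:
        warnings.warn(
            f"{len(fallbacks)} feature(s) fell back to sequential single-factor fits",
            UserWarning,
        )
    denoised = m.copy()
    denoised.values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    log = {
        "factors": usable,
        "dropped": dropped,
        "variance_ratios": gammas,
        "fallback_features": fallbacks,
    }
    return denoised, log
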