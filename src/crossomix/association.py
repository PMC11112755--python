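"""Repeated-measures multivariate-normal association testing.

Each feature Y is modelled across a participant's six occasions (2 sites x
3 time points) as

    y_i ~ MVN(X_i beta, Sigma),   Sigma = D R D,

with an unstructured 6x6 correlation matrix R and occasion-specific SDs D —
i.e. a fully unstructured 21-parameter covariance.  Participants act as
their own controls: the within-person correlation carried by Sigma absorbs
stable individual characteristics, while age, sex, health group (and
optionally BMI) enter as fixed effects against residual confounding.

Estimation is REML.  Because beta solves a GLS normal equation at fixed
Sigma and the REML estimate of an unstructured Sigma is a closed-form
moment update at fixed beta, the fit iterates those two exact steps (an
EM-type fixed point) rather than a generic quasi-Newton search; the
restricted log-likelihood is monitored for convergence and a
compound-symmetry refit is the fallback for the rare non-converged feature.
The fitter is batched over features: a whole feature table is fitted with a
handful of einsum contractions per iteration.

Multiplicity is handled by Bonferroni at two denominators: the effective
number of tests (ENT; principal components explaining >99% of variance) and
the full feature count.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import InvalidConfigError, OmicsMatrix

__all__ = [
    "RepeatedMeasuresGLS",
    "GLSResults",
    "AssociationResult",
    "fit_mvn_feature",
    "association_scan",
    "effective_number_tests",
    "apply_corrections",
    "association_summary",
    "IdentifiabilityError",
]


class IdentifiabilityError(InvalidConfigError):
    """The design matrix is singular (e.g. a constant exposure)."""


@dataclasses.dataclass
class AssociationResult:
    feature: str
    exposure: str
    beta: float
    se: float
    stat: float
    p: float
    significant_ent: bool | None = None
    significant_full: bool | None = None
    converged: bool = True
    downgraded: bool = False


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class RepeatedMeasuresGLS:
    """GLS model for feature intensities over a crossover's six occasions.

    Parameters
    ----------
    endog
        Feature values: a Series/1-d array (one feature) or a DataFrame /
        2-d array of shape (features, samples), columns aligned with
        ``meta``'s rows.
    meta
        Sample metadata, one row per profile (participant, site,
        time_point, visit, plus any covariate columns used).
    exposure
        Per-profile exposure values of a single pollutant, aligned with
        ``meta`` (visit-level values broadcast to the visit's occasions).
    covariates
        Names of fixed-effect adjustment columns in ``meta``. ``sex`` is
        coded female=1; ``health_group`` expands to treatment dummies.
    effect_mode
        ``"main"``: the tested coefficient is the exposure main effect.
        ``"post_interaction"``: an exposure x post-walk term is added and
        tested instead.
    """

    def __init__(
        self,
        endog,
        meta: pd.DataFrame,
        exposure,
        exposure_name: str = "exposure",
        covariates: tuple = ("age", "sex", "health_group"),
        include_bmi: bool = True,
        effect_mode: str = "main",
        sites=None,
        time_points=None,
        min_participants: int = 10,
    ) -> None:
        if effect_mode not in ("main", "post_interaction"):
            raise InvalidConfigError("effect_mode must be 'main' or 'post_interaction'")
        self.meta = meta
        self.exposure_name = exposure_name
        self.effect_mode = effect_mode

        if isinstance(endog, pd.DataFrame):
            self.feature_ids = list(endog.index)
            Yflat = endog.to_numpy(dtype=float)
        else:
            arr = np.asarray(endog, dtype=float)
            if arr.ndim == 1:
                arr = arr[None, :]
                self.feature_ids = ["feature"]
            else:
                self.feature_ids = [f"f{i}" for i in range(arr.shape[0])]
            Yflat = arr
        if Yflat.shape[1] != len(meta):
            raise InvalidConfigError("endog columns must align with meta rows")

        x = np.asarray(
            exposure.to_numpy() if hasattr(exposure, "to_numpy") else exposure, dtype=float
        )
        if x.shape != (len(meta),):
            raise InvalidConfigError("exposure must align with meta rows")

        self.sites = list(sites) if sites is not None else list(dict.fromkeys(meta["site"]))
        self.time_points = (
            list(time_points)
            if time_points is not None
            else list(dict.fromkeys(meta["time_point"]))
        )
        self.participants = list(dict.fromkeys(meta["participant"]))
        if len(self.participants) < min_participants:
            raise InvalidConfigError(
                f"at least {min_participants} participants required, "
                f"got {len(self.participants)}"
            )

        occ = {
            (s, t): i
            for i, (s, t) in enumerate(
                [(s, t) for s in self.sites for t in self.time_points]
            )
        }
        pidx = {p: i for i, p in enumerate(self.participants)}
        n_p, n_occ = len(self.participants), 6

        # design matrix columns
        cols: dict[str, np.ndarray] = {"const": np.ones(len(meta))}
        cols[exposure_name] = x
        pre = self.time_points[0]
        if effect_mode == "post_interaction":
            cols[f"{exposure_name}:post"] = x * (meta["time_point"] != pre).to_numpy()
        for cov in covariates:
            if cov == "sex":
                cols["sex"] = (meta["sex"].astype(str) == "F").to_numpy(dtype=float)
            elif cov == "health_group":
                levels = sorted(set(meta["health_group"]))
                base = "Healthy" if "Healthy" in levels else levels[0]
                for lv in levels:
                    if lv != base:
                        cols[f"group_{lv}"] = (meta["health_group"] == lv).to_numpy(
                            dtype=float
                        )
            else:
                cols[cov] = meta[cov].to_numpy(dtype=float)
        if include_bmi and "bmi" in meta.columns:
            cols["bmi"] = meta["bmi"].to_numpy(dtype=float)
        self.exog_names = list(cols)
        self.tested = (
            f"{exposure_name}:post" if effect_mode == "post_interaction" else exposure_name
        )
        Xflat = np.column_stack(list(cols.values()))
        k = Xflat.shape[1]

        if np.linalg.matrix_rank(Xflat) < k:
            raise IdentifiabilityError(
                "design matrix is singular; is the exposure constant or a "
                "covariate collinear?"
            )

        # reshape to participant x occasion
        self.Y = np.full((Yflat.shape[0], n_p, n_occ), np.nan)
        self.X = np.zeros((n_p, n_occ, k))
        self.O = np.zeros((n_p, n_occ), dtype=bool)
        for row, (_, rec) in enumerate(meta.iterrows()):
            i = pidx[rec["participant"]]
            j = occ[(rec["site"], rec["time_point"])]
            if self.O[i, j]:
                raise InvalidConfigError(
                    f"duplicate occasion for participant {rec['participant']}"
                )
            self.O[i, j] = True
            self.X[i, j] = Xflat[row]
            self.Y[:, i, j] = Yflat[:, row]

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        reml: bool = True,
        max_iter: int = 500,
        tol: float = 1e-8,
        cov_structure: str = "unstructured",
        fallback: bool = True,
        reference: str = "satterthwaite",
    ) -> "GLSResults":
        """Fit by REML and return results.

        ``reference`` sets the null distribution of the Wald statistic:
        ``"satterthwaite"`` (default) uses a per-feature t with degrees of
        freedom from the delta-method variance of the contrast variance —
        the estimated 21-parameter covariance makes the statistic visibly
        heavier-tailed than normal at realistic participant counts;
        ``"residual"`` uses t with observations-minus-parameters df;
        ``"normal"`` uses the standard normal.
        """
        if cov_structure == "compound_symmetry":
            return self._fit_cs()
        if cov_structure not in ("unstructured", "scaled_identity"):
            raise InvalidConfigError(
                "cov_structure must be 'unstructured', 'scaled_identity' or "
                "'compound_symmetry'"
            )
        Y, X, O = self.Y, self.X, self.O
        F, P, m = Y.shape
        k = X.shape[2]
        complete = O.all(axis=1)
        incomplete = [
            (i, np.flatnonzero(O[i])) for i in range(P) if not complete[i]
        ]
        Xc = X[complete]
        Yc = np.nan_to_num(Y[:, complete])
        Xobs = X.copy()  # missing rows are already zero

        # init: pooled OLS residual variance on the identity covariance
        Xf = X[O]  # (N, k)
        Yf = np.nan_to_num(Y.transpose(1, 2, 0)[O]).T  # (F, N)
        beta = np.linalg.solve(Xf.T @ Xf, Xf.T @ Yf.T).T
        resid_var = np.maximum(np.var(Yf - beta @ Xf.T, axis=1), 1e-10)
        Sigma = np.einsum("f,jl->fjl", resid_var, np.eye(m))

        prev_beta = beta.copy()
        converged = np.zeros(F, dtype=bool)
        for _ in range(max_iter):
            Om = np.linalg.inv(Sigma)
            A = np.einsum("pja,fjl,plb->fab", Xc, Om, Xc, optimize=True)
            b = np.einsum("pja,fjl,fpl->fa", Xc, Om, Yc, optimize=True)
            for i, oidx in incomplete:
                Xo = X[i][oidx]
                Oo = np.linalg.inv(Sigma[:, oidx][:, :, oidx])
                A += np.einsum("ja,fjl,lb->fab", Xo, Oo, Xo, optimize=True)
                b += np.einsum("ja,fjl,fl->fa", Xo, Oo, Y[:, i, oidx], optimize=True)
            beta = np.linalg.solve(A, b[..., None])[..., 0]

            Rc = Yc - np.einsum("pjk,fk->fpj", Xc, beta, optimize=True)
            S = np.einsum("fpj,fpl->fjl", Rc, Rc, optimize=True)
            for i, oidx in incomplete:
                midx = np.setdiff1d(np.arange(m), oidx)
                ro = Y[:, i, oidx] - beta @ X[i][oidx].T
                Soo_inv = np.linalg.inv(Sigma[:, oidx][:, :, oidx])
                rt = np.zeros((F, m))
                rt[:, oidx] = ro
                if midx.size:
                    Smo = Sigma[:, midx][:, :, oidx]
                    rt[:, midx] = np.einsum(
                        "fab,fbc,fc->fa", Smo, Soo_inv, ro, optimize=True
                    )
                    C = Sigma[:, midx][:, :, midx] - np.einsum(
                        "fab,fbc,fdc->fad", Smo, Soo_inv, Smo, optimize=True
                    )
                    # conditional covariance enters only the missing block
                    for a_, ia in enumerate(midx):
                        S[:, ia, midx] += C[:, a_, :]
                S += rt[:, :, None] * rt[:, None, :]
            if reml:
                Ainv = np.linalg.inv(A)
                S += np.einsum("pja,fab,plb->fjl", Xobs, Ainv, Xobs, optimize=True)
            Sigma_new = S / P
            Sigma_new = 0.5 * (Sigma_new + Sigma_new.transpose(0, 2, 1))
            if cov_structure == "scaled_identity":
                scale = np.einsum("fjj->f", Sigma_new) / m
                Sigma_new = np.einsum("f,jl->fjl", scale, np.eye(m))

            d_sigma = np.abs(Sigma_new - Sigma).max(axis=(1, 2)) / (
                np.abs(Sigma).max(axis=(1, 2)) + 1e-12
            )
            d_beta = np.abs(beta - prev_beta).max(axis=1) / (
                np.abs(beta).max(axis=1) + 1e-12
            )
            converged = (d_sigma < tol) & (d_beta < tol)
            Sigma, prev_beta = Sigma_new, beta.copy()
            if converged.all():
                break

        Ainv = np.linalg.inv(A)
        bse = np.sqrt(np.einsum("faa->fa", Ainv))
        llr = self._restricted_loglik(beta, Sigma)
        j = self.exog_names.index(self.tested)
        if reference == "satterthwaite":
            exposure_se, df = self._small_sample_inference(Sigma, Ainv)
        elif reference == "residual":
            exposure_se = bse[:, j].copy()
            df = np.full(F, float(int(O.sum()) - k))
        else:
            exposure_se = bse[:, j].copy()
            df = np.full(F, np.inf)

        results = GLSResults(
            model=self,
            params=beta,
            bse=bse,
            sigma=Sigma,
            loglik=llr,
            converged=converged,
            downgraded=np.zeros(F, dtype=bool),
            reml=reml,
            df=df,
            exposure_se=exposure_se,
        )
        if fallback and not converged.all():
            bad = np.flatnonzero(~converged)
            warnings.warn(
                f"{bad.size} feature(s) did not converge under the unstructured "
                "covariance; refitting under compound symmetry",
                UserWarning,
            )
            cs = self._fit_cs(feature_subset=bad)
            results.params[bad] = cs.params
            results.bse[bad] = cs.bse
            results.sigma[bad] = cs.sigma
            results.loglik[bad] = cs.loglik
            results.df[bad] = cs.df
            results.exposure_se[bad] = cs.exposure_se
            results.downgraded[bad] = True
        return results

    def _small_sample_inference(self, Sigma, Ainv):
        """Adjusted SE and Satterthwaite df for the tested contrast.

        The model-based SE sqrt(c' Phi c), Phi = A^-1, ignores that the GLS
        weights use the *estimated* covariance; with 21 free parameters the
        underestimate is visible at realistic participant counts.  The
        Kackar-Harville/Kenward-Roger correction adds the leading term,

            Var_adj = c'Phi c + 2 c'Phi [ sum_rs W_rs (Q_rs - B_r Phi B_s) ] Phi c,

        with B_r = X'S^-1 E_r S^-1 X, Q_rs = X'S^-1 E_r S^-1 E_s S^-1 X
        summed over participants, E_r the symmetric basis of the covariance
        parameters and W the inverse REML expected information.  Degrees of
        freedom follow Satterthwaite: df = 2 Var_adj^2 / (g' W g) with
        g_r = c'Phi B_r Phi c the gradient of the contrast variance.
        Computed from complete participants.
        """
        X, O = self.X, self.O
        F, m, _ = Sigma.shape
        complete = O.all(axis=1)
        Xc = X[complete]
        P = int(complete.sum())
        c = self._contrast()
        se2 = np.einsum("a,fab,b->f", c, Ainv, c, optimize=True)
        if P < 2:
            return np.sqrt(se2), np.full(F, np.inf)
        basis = []
        for j in range(m):
            for l in range(j, m):
                Eb = np.zeros((m, m))
                Eb[j, l] = Eb[l, j] = 1.0
                basis.append(Eb)
        E = np.stack(basis)  # (R, m, m)
        Om = np.linalg.inv(Sigma)  # (F, m, m)
        Z = np.einsum("fjl,pla->fpja", Om, Xc, optimize=True)  # S^-1 X
        T = np.einsum("fpja,fplb->fjalb", Z, Z, optimize=True)
        B = np.einsum("rjl,fjalb->frab", E, T, optimize=True)  # (F, R, k, k)
        u = np.einsum("fab,b->fa", Ainv, c)  # Phi c
        g = np.einsum("fa,frab,fb->fr", u, B, u, optimize=True)
        # REML expected information: I = (T1 - 2 T2 + T3) / 2
        S3 = np.einsum("fpja,fab,fplb->fjl", Z, Ainv, Z, optimize=True)
        A1 = np.einsum("rab,fbc->frac", E, Om, optimize=True)
        OmEOm = np.einsum("fab,rbc,fcd->frad", Om, E, Om, optimize=True)
        T1 = P * np.einsum("frab,sba->frs", OmEOm, E, optimize=True)
        A2 = np.einsum("rab,fbc->frac", E, S3, optimize=True)
        T2 = np.einsum("frab,fsba->frs", A1, A2, optimize=True)
        C = np.einsum("fab,frbc,fcd->frad", Ainv, B, Ainv, optimize=True)
        T3 = np.einsum("frab,fsba->frs", C, B, optimize=True)
        info = 0.5 * (T1 - 2 * T2 + T3)
        # contrast-specific pieces of the variance correction
        v = np.einsum("fpja,fa->fpj", Z, u, optimize=True)  # S^-1 X Phi c
        a_r = np.einsum("fpj,rjl->fprl", v, E, optimize=True)
        b_r = np.einsum("fprl,flm->fprm", a_r, Om, optimize=True)
        q = np.einsum("fprm,fpsm->frs", b_r, a_r, optimize=True)  # u'Q_rs u
        d = np.einsum("frab,fb->fra", B, u, optimize=True)  # B_r Phi c
        dPd = np.einsum("fra,fab,fsb->frs", d, Ainv, d, optimize=True)
        se2_adj = np.empty(F)
        denom = np.empty(F)
        for f in range(F):
            try:
                W = np.linalg.inv(info[f])
            except np.linalg.LinAlgError:
                W = np.linalg.pinv(info[f])
            se2_adj[f] = se2[f] + 2.0 * np.sum(W * (q[f] - dPd[f]))
            denom[f] = g[f] @ W @ g[f]
        se2_adj = np.maximum(se2_adj, se2)  # correction is non-negative to O(1/P)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = 2.0 * se2_adj**2 / denom
        df = np.where(np.isfinite(df) & (df > 1.0), df, np.inf)
        return np.sqrt(se2_adj), np.minimum(df, 1e6)

    def _contrast(self) -> np.ndarray:
        c = np.zeros(len(self.exog_names))
        c[self.exog_names.index(self.tested)] = 1.0
        return c

    def _restricted_loglik(self, beta, Sigma):
        """Restricted log-likelihood per feature at (beta, Sigma)."""
        Y, X, O = self.Y, self.X, self.O
        F, P, m = Y.shape
        k = X.shape[2]
        ll = np.zeros(F)
        A = np.zeros((F, k, k))
        n_obs = int(O.sum())
        for i in range(P):
            oidx = np.flatnonzero(O[i])
            Xo = X[i][oidx]
            So = Sigma[:, oidx][:, :, oidx]
            sign, logdet = np.linalg.slogdet(So)
            Oo = np.linalg.inv(So)
            r = Y[:, i, oidx] - beta @ Xo.T
            ll -= 0.5 * (logdet + np.einsum("fa,fab,fb->f", r, Oo, r, optimize=True))
            A += np.einsum("ja,fjl,lb->fab", Xo, Oo, Xo, optimize=True)
        sign, logdetA = np.linalg.slogdet(A)
        ll -= 0.5 * logdetA
        ll -= 0.5 * (n_obs - k) * np.log(2 * np.pi)
        return ll

    def _fit_cs(self, feature_subset=None) -> "GLSResults":
        """Compound-symmetry covariance: Sigma = s2 [(1-rho) I + rho J]."""
        Y, X, O = self.Y, self.X, self.O
        F, P, m = Y.shape
        k = X.shape[2]
        idx = np.arange(F) if feature_subset is None else np.atleast_1d(feature_subset)
        params = np.zeros((len(idx), k))
        bse = np.zeros((len(idx), k))
        sigmas = np.zeros((len(idx), m, m))
        lls = np.zeros(len(idx))

        lo, hi = -1.0 / (m - 1) + 1e-3, 0.999

        def make_sigma(theta):
            s2 = np.exp(theta[0])
            rho = lo + (hi - lo) / (1.0 + np.exp(-theta[1]))
            return s2 * ((1 - rho) * np.eye(m) + rho * np.ones((m, m)))

        for out_i, f in enumerate(idx):
            yf = self.Y[f : f + 1]
            sub = _SingleFeatureView(self, f)

            def negll(theta):
                Sig = make_sigma(theta)
                beta = sub.gls_beta(Sig)
                if beta is None:
                    return 1e10
                return -sub.restricted_loglik(beta, Sig)

            y0 = np.nanvar(yf)
            res = optimize.minimize(
                negll,
                np.array([np.log(max(y0, 1e-8)), 0.0]),
                method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 500},
            )
            Sig = make_sigma(res.x)
            beta = sub.gls_beta(Sig)
            A = sub.information(Sig)
            params[out_i] = beta
            bse[out_i] = np.sqrt(np.diag(np.linalg.inv(A)))
            sigmas[out_i] = Sig
            lls[out_i] = sub.restricted_loglik(beta, Sig)

        return GLSResults(
            model=self,
            params=params,
            bse=bse,
            sigma=sigmas,
            loglik=lls,
            converged=np.ones(len(idx), dtype=bool),
            downgraded=np.ones(len(idx), dtype=bool),
            reml=True,
            df=np.full(len(idx), float(int(O.sum()) - k)),
            exposure_se=bse[:, self.exog_names.index(self.tested)].copy(),
            feature_subset=idx if feature_subset is not None else None,
        )


class _SingleFeatureView:
    """Scalar-feature helpers used by the compound-symmetry fallback."""

    def __init__(self, model: RepeatedMeasuresGLS, f: int):
        self.model = model
        self.f = f

    def _blocks(self, Sigma):
        mdl = self.model
        for i in range(mdl.X.shape[0]):
            oidx = np.flatnonzero(mdl.O[i])
            yield mdl.X[i][oidx], mdl.Y[self.f, i, oidx], Sigma[np.ix_(oidx, oidx)]

    def gls_beta(self, Sigma):
        k = self.model.X.shape[2]
        A = np.zeros((k, k))
        b = np.zeros(k)
        for Xo, yo, So in self._blocks(Sigma):
            Oo = np.linalg.inv(So)
            A += Xo.T @ Oo @ Xo
            b += Xo.T @ Oo @ yo
        try:
            return np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return None

    def information(self, Sigma):
        k = self.model.X.shape[2]
        A = np.zeros((k, k))
        for Xo, _, So in self._blocks(Sigma):
            A += Xo.T @ np.linalg.inv(So) @ Xo
        return A

    def restricted_loglik(self, beta, Sigma):
        k = self.model.X.shape[2]
        ll = 0.0
        A = np.zeros((k, k))
        n_obs = 0
        for Xo, yo, So in self._blocks(Sigma):
            Oo = np.linalg.inv(So)
            r = yo - Xo @ beta
            sign, logdet = np.linalg.slogdet(So)
            ll -= 0.5 * (logdet + r @ Oo @ r)
            A += Xo.T @ Oo @ Xo
            n_obs += len(yo)
        sign, logdetA = np.linalg.slogdet(A)
        ll -= 0.5 * logdetA
        ll -= 0.5 * (n_obs - k) * np.log(2 * np.pi)
        return ll


class GLSResults:
    """Fitted repeated-measures GLS results for a stack of features."""

    def __init__(
        self,
        model,
        params,
        bse,
        sigma,
        loglik,
        converged,
        downgraded,
        reml,
        df=None,
        exposure_se=None,
        feature_subset=None,
    ):
        self.model = model
        self.params = params
        self.bse = bse
        self.sigma = sigma
        self.loglik = loglik
        self.converged = converged
        self.downgraded = downgraded
        self.reml = reml
        self.df = np.full(params.shape[0], np.inf) if df is None else df
        j = model.exog_names.index(model.tested)
        self.exposure_se = bse[:, j].copy() if exposure_se is None else exposure_se
        self._subset = feature_subset

    @property
    def feature_ids(self):
        if self._subset is None:
            return self.model.feature_ids
        return [self.model.feature_ids[i] for i in self._subset]

    @property
    def exog_names(self):
        return self.model.exog_names

    def _tested_index(self) -> int:
        return self.model.exog_names.index(self.model.tested)

    @property
    def zvalues(self):
        return self.params / self.bse

    @property
    def pvalues(self):
        """Two-sided p-values; t reference with the per-feature df (a
        non-finite df falls back to the normal reference)."""
        z = np.abs(self.zvalues)
        df = self.df[:, None]
        finite = np.isfinite(df)
        p = 2.0 * stats.norm.sf(z)
        if finite.any():
            p = np.where(finite, 2.0 * stats.t.sf(z, np.where(finite, df, 2.0)), p)
        return p

    def conf_int(self, alpha: float = 0.05):
        df = self.df[:, None]
        crit = np.where(
            np.isfinite(df),
            stats.t.ppf(1 - alpha / 2, np.where(np.isfinite(df), df, 2.0)),
            stats.norm.ppf(1 - alpha / 2),
        )
        return np.stack(
            [self.params - crit * self.bse, self.params + crit * self.bse], axis=-1
        )

    @property
    def exposure_stat(self):
        """Wald statistic of the tested contrast with the adjusted SE."""
        return self.params[:, self._tested_index()] / self.exposure_se

    @property
    def exposure_pvalues(self):
        t = np.abs(self.exposure_stat)
        finite = np.isfinite(self.df)
        p = 2.0 * stats.norm.sf(t)
        return np.where(
            finite, 2.0 * stats.t.sf(t, np.where(finite, self.df, 2.0)), p
        )

    def exposure_conf_int(self, alpha: float = 0.05):
        crit = np.where(
            np.isfinite(self.df),
            stats.t.ppf(1 - alpha / 2, np.where(np.isfinite(self.df), self.df, 2.0)),
            stats.norm.ppf(1 - alpha / 2),
        )
        b = self.params[:, self._tested_index()]
        return np.stack([b - crit * self.exposure_se, b + crit * self.exposure_se], axis=-1)

    def result_frame(self, exposure_name: str | None = None) -> pd.DataFrame:
        """Tidy per-feature table for the tested exposure coefficient."""
        j = self._tested_index()
        name = exposure_name or self.model.exposure_name
        return pd.DataFrame(
            {
                "feature": self.feature_ids,
                "exposure": name,
                "beta": self.params[:, j],
                "se": self.exposure_se,
                "stat": self.exposure_stat,
                "p": self.exposure_pvalues,
                "converged": self.converged,
                "downgraded": self.downgraded,
            }
        )

    def summary(self, feature: int | str = 0) -> str:
        """Text summary for one feature, statsmodels-flavoured."""
        f = self.feature_ids.index(feature) if isinstance(feature, str) else feature
        rows = []
        ci = self.conf_int()
        for j, name in enumerate(self.exog_names):
            rows.append(
                [
                    name,
                    self.params[f, j],
                    self.bse[f, j],
                    self.zvalues[f, j],
                    self.pvalues[f, j],
                    ci[f, j, 0],
                    ci[f, j, 1],
                ]
            )
        tab = pd.DataFrame(
            rows, columns=["", "coef", "std err", "z", "P>|z|", "[0.025", "0.975]"]
        ).set_index("")
        head = (
            f"Repeated-measures GLS ({'REML' if self.reml else 'ML'}), "
            f"unstructured 6x6 covariance\n"
            f"Feature: {self.feature_ids[f]}   "
            f"Participants: {len(self.model.participants)}   "
            f"Restricted loglik: {self.loglik[f]:.3f}\n"
        )
        return head + tab.to_string(float_format=lambda v: f"{v: .4f}")


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_mvn_feature(
    y, meta: pd.DataFrame, exposure, exposure_name: str = "exposure", **model_kw
) -> AssociationResult:
    """Fit one feature and return its tidy association record."""
    model = RepeatedMeasuresGLS(y, meta, exposure, exposure_name=exposure_name, **model_kw)
    res = model.fit()
    row = res.result_frame().iloc[0]
    return AssociationResult(
        feature=row["feature"],
        exposure=exposure_name,
        beta=float(row["beta"]),
        se=float(row["se"]),
        stat=float(row["stat"]),
        p=float(row["p"]),
        converged=bool(row["converged"]),
        downgraded=bool(row["downgraded"]),
    )


def association_scan(
    m: OmicsMatrix,
    meta: pd.DataFrame,
    exposure_table: pd.DataFrame,
    pollutants=None,
    **model_kw,
) -> pd.DataFrame:
    """Fit every (feature, pollutant) pair; returns the tidy results table."""
    from .synthdata import exposures_per_sample

    if pollutants is None:
        pollutants = [
            c for c in exposure_table.columns if c not in ("participant", "visit", "site")
        ]
    per_sample = exposures_per_sample(meta, exposure_table)
    frames = []
    for pol in pollutants:
        model = RepeatedMeasuresGLS(
            m.values, meta, per_sample[pol], exposure_name=pol, **model_kw
        )
        frames.append(model.fit().result_frame())
    return pd.concat(frames, ignore_index=True)


def effective_number_tests(m, var_threshold: float = 0.99) -> int:
    """Effective number of tests: the smallest number of principal
    components of the standardized feature matrix explaining strictly more
    than ``var_threshold`` of total variance."""
    if isinstance(m, OmicsMatrix):
        values = m.values.to_numpy(dtype=float)
    elif isinstance(m, pd.DataFrame):
        values = m.to_numpy(dtype=float)
    else:
        values = np.asarray(m, dtype=float)
    if np.isnan(values).any():
        raise InvalidConfigError("effective_number_tests requires a complete matrix")
    X = values.T  # samples x features
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance feature(s) before PCA",
            UserWarning,
        )
        X = X[:, keep]
        sd = sd[keep]
    if X.shape[1] == 0:
        raise InvalidConfigError("no non-constant features")
    Xs = (X - X.mean(axis=0)) / sd
    s = np.linalg.svd(Xs, compute_uv=False)
    ev = s**2
    ratio = np.cumsum(ev) / ev.sum()
    return int(np.searchsorted(ratio > var_threshold, True) + 1)


def apply_corrections(
    results: pd.DataFrame, ent: int, n_features: int, fwer: float = 0.05
) -> pd.DataFrame:
    """Flag significance under ENT-Bonferroni and full-Bonferroni.

    Strict inequality at the threshold; the full correction is at least as
    stringent because ``ent <= n_features``.
    """
    if ent < 1:
        raise InvalidConfigError("ent must be >= 1")
    if ent > n_features:
        raise InvalidConfigError("ent cannot exceed the number of features")
    out = results.copy()
    out["significant_ent"] = out["p"] < fwer / ent
    out["significant_full"] = out["p"] < fwer / n_features
    return out


def association_summary(results: pd.DataFrame, flag: str = "significant_ent") -> dict:
    """Counts of significant features per exposure and exposure combination.

    Returns a dict with the per-exposure counts, the exact-combination
    partition (upset-style), the number of unique significant features and
    the per-exposure exclusive counts.
    """
    if flag not in results.columns:
        raise InvalidConfigError(f"results lack the {flag!r} column; run apply_corrections")
    sig = results[results[flag]]
    exposures = list(dict.fromkeys(results["exposure"]))
    per_exposure = {
        e: int(sig[sig["exposure"] == e]["feature"].nunique()) for e in exposures
    }
    feat_sets: dict[str, frozenset] = {}
    for feat, grp in sig.groupby("feature"):
        feat_sets[feat] = frozenset(grp["exposure"])
    combos: dict[frozenset, int] = {}
    for s in feat_sets.values():
        combos[s] = combos.get(s, 0) + 1
    combo_rows = [
        {"exposures": tuple(sorted(s)), "n_features": n}
        for s, n in sorted(combos.items(), key=lambda kv: (-kv[1], tuple(sorted(kv[0]))))
    ]
    exclusive = {
        e: combos.get(frozenset([e]), 0) for e in exposures
    }
    return {
        "per_exposure": per_exposure,
        "combinations": pd.DataFrame(combo_rows, columns=["exposures", "n_features"]),
        "n_unique": len(feat_sets),
        "exclusive": exclusive,
    }
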