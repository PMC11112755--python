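"""Method-validation simulations: error control, recovery, calibration.

These routines generate data with the synthetic-study generator (or
purpose-built constructions), run the corresponding estimator, and measure
operating characteristics — family-wise error under a global null,
bias/coverage of the exposure coefficient, support recovery of the
stability-calibrated network, censored-normal parameter recovery of QRILC,
batch-variance removal of the denoiser, planted-block recovery of the
consensus clustering.  They back both the test suite and the acceptance
script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import RepeatedMeasuresGLS, effective_number_tests
from .clustering import ConsensusClustering
from .containers import OmicsMatrix
from .network import stability_select_network
from .preprocess import impute_qrilc
from .synthdata import (
    DesignConfig,
    EffectSpec,
    ExposureModel,
    PrecisionSpec,
    exposures_per_sample,
    generate_design,
    generate_exposures,
    generate_omics,
    generate_precision_matrix,
)


def fwer_simulation(
    n_participants: int = 100,
    n_features: int = 200,
    n_reps: int = 200,
    density: float = 0.02,
    fwer: float = 0.05,
    seed: int = 0,
) -> dict:
    """Family-wise error of the ENT-Bonferroni correction under a global null.

    Each replicate draws a fresh feature table (correlated via a sparse
    precision matrix, within-person correlation via participant intercepts,
    no exposure effects), computes the effective number of tests on it, fits
    the repeated-measures GLS for one pollutant on every feature, and
    records whether any feature passes the ENT-Bonferroni threshold.
    """
    ss = np.random.SeedSequence(seed)
    design_seed, expo_seed, prec_seed, rep_root = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)
    ]
    design = generate_design(DesignConfig(n_participants=n_participants, seed=design_seed))
    expo = generate_exposures(design, ExposureModel(), seed=expo_seed)
    theta, _ = generate_precision_matrix(
        PrecisionSpec(p=n_features, density=density), seed=prec_seed
    )
    x = exposures_per_sample(design, expo)["NO2"]
    rejections = 0
    ents = []
    for r in range(n_reps):
        _, truth = generate_omics(
            design,
            expo,
            theta,
            EffectSpec.none(),
            batch_sd=0.0,
            censor_fraction=0.0,
            seed=(rep_root + r) % (2**31 - 1),
        )
        Y = truth["latent"]
        ent = effective_number_tests(Y)
        res = RepeatedMeasuresGLS(Y, design, x, exposure_name="NO2").fit()
        if res.exposure_pvalues.min() < fwer / ent:
            rejections += 1
        ents.append(ent)
    rate = rejections / n_reps
    mcse = float(np.sqrt(fwer * (1 - fwer) / n_reps))
    return {
        "fwer": float(rate),
        "bound": fwer + 2 * mcse,
        "mcse": mcse,
        "n_reps": n_reps,
        "mean_ent": float(np.mean(ents)),
    }


def beta_recovery(
    n_participants: int = 100,
    n_reps: int = 200,
    beta: float = 0.5,
    seed: int = 0,
) -> dict:
    """Bias and 95% Wald coverage of the exposure coefficient.

    Replicates are generated as independent features (diagonal precision)
    sharing one design, each carrying the same true effect on a unit-scale
    exposure, and fitted jointly by the batched GLS.
    """
    ss = np.random.SeedSequence(seed)
    s1, s2, s3 = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3)]
    design = generate_design(DesignConfig(n_participants=n_participants, seed=s1))
    model = ExposureModel(
        site_means={"NO2": (1.0, 0.0)}, noise_sd={"NO2": 0.5}
    )
    expo = generate_exposures(design, model, seed=s2)
    theta = np.eye(n_reps)
    effects = EffectSpec(affected=np.arange(n_reps), beta=beta, pollutant="NO2")
    _, truth = generate_omics(
        design,
        expo,
        theta,
        effects,
        batch_sd=0.0,
        censor_fraction=0.0,
        effect_mode="main",
        seed=s3,
    )
    x = exposures_per_sample(design, expo)["NO2"]
    res = RepeatedMeasuresGLS(truth["latent"], design, x, exposure_name="NO2").fit()
    bh = res.params[:, res._tested_index()]
    ci = res.exposure_conf_int()
    coverage = float(((ci[:, 0] <= beta) & (beta <= ci[:, 1])).mean())
    return {
        "mean_beta": float(bh.mean()),
        "true_beta": beta,
        "relative_bias": float((bh.mean() - beta) / beta),
        "coverage": coverage,
        "n_reps": n_reps,
    }


def _edge_f1(selected: set, true: set) -> float:
    tp = len(selected & true)
    fp = len(selected - true)
    fn = len(true - selected)
    return 2 * tp / max(2 * tp + fp + fn, 1)


def network_recovery(
    p: int = 20,
    density: float = 0.1,
    n: int = 300,
    K: int = 100,
    seed: int = 0,
) -> dict:
    """Edge F1 of the stability-calibrated network against a known support."""
    ss = np.random.SeedSequence(seed)
    s1, s2, s3 = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3)]
    theta, edges = generate_precision_matrix(PrecisionSpec(p=p, density=density), seed=s1)
    L = np.linalg.cholesky(np.linalg.inv(theta))
    X = np.random.default_rng(s2).standard_normal((n, p)) @ L.T
    net = stability_select_network(X, K=K, seed=s3)
    nodes = net.nodes
    sel = {
        tuple(sorted((nodes.index(u), nodes.index(v)))) for u, v in net.edges
    }
    return {
        "f1": _edge_f1(sel, set(edges)),
        "n_edges_true": len(edges),
        "n_edges_selected": len(sel),
        "lam_star": net.lam_star,
        "pi_star": net.pi_star,
    }


def empty_graph_edge_counts(
    n_seeds: int = 20,
    p: int = 20,
    n: int = 300,
    K: int = 100,
    seed: int = 0,
) -> list[int]:
    """Stable-edge counts of the calibrated network on structure-free data."""
    out = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed * 10_000 + s)
        X = rng.standard_normal((n, p))
        net = stability_select_network(X, K=K, seed=seed * 10_000 + s + 1)
        out.append(len(net.edges))
    return out


def qrilc_recovery(
    n: int = 500,
    censor_fraction: float = 0.2,
    mu: float = 10.0,
    sigma: float = 1.0,
    tune_sigma: float = 1.0,
    seed: int = 0,
) -> dict:
    """Parameter recovery and truncation compliance of QRILC on one profile.

    One profile of ``n`` features is drawn from N(mu, sigma), its lowest
    quantile censored, and the column imputed; reports the estimated
    latent (mu, sigma) and whether every imputed value respects the
    estimated censoring bound.
    """
    rng = np.random.default_rng(seed)
    latent = rng.normal(mu, sigma, n)
    order = np.argsort(latent)
    k = int(np.floor(censor_fraction * n))
    observed = latent.copy()
    observed[order[:k]] = np.nan
    vals = pd.DataFrame({"s1": observed}, index=[f"f{i}" for i in range(n)])
    m = OmicsMatrix(vals, scale="log2")
    imputed, params = impute_qrilc(m, tune_sigma=tune_sigma, seed=seed + 1)
    est = params["s1"]
    from scipy import stats

    bound = est["mu"] + est["sigma"] * stats.norm.ppf(censor_fraction)
    imputed_vals = imputed.values.loc[np.isnan(observed), "s1"]
    return {
        "mu_hat": est["mu"],
        "sigma_hat": est["sigma"],
        "mu_error": abs(est["mu"] - mu),
        "sigma_error": abs(est["sigma"] - sigma),
        "max_imputed": float(imputed_vals.max()),
        "bound": float(bound),
        "bound_respected": bool((imputed_vals <= bound + 1e-9).all()),
    }


def denoise_variance_share(
    batch_sd: float = 2.0,
    resid_sd: float = 0.5,
    n_levels: int = 6,
    per_level: int = 20,
    n_features: int = 20,
    seed: int = 0,
) -> dict:
    """Between-batch variance share before and after BLUP subtraction."""
    from .preprocess import denoise_technical

    rng = np.random.default_rng(seed)
    n = n_levels * per_level
    levels = np.repeat([f"L{i}" for i in range(n_levels)], per_level)
    offsets = rng.normal(0.0, batch_sd, (n_features, n_levels))
    Y = 10.0 + offsets[:, np.repeat(np.arange(n_levels), per_level)]
    Y = Y + rng.normal(0.0, resid_sd, (n_features, n))
    cols = [f"s{i}" for i in range(n)]
    m = OmicsMatrix(pd.DataFrame(Y, columns=cols), scale="log2")
    tf = pd.DataFrame({"batch": levels}, index=cols)

    def share(mat: np.ndarray) -> float:
        vals = []
        for f in range(n_features):
            s = pd.Series(mat[f])
            vals.append(s.groupby(levels).mean().var(ddof=1) / s.var(ddof=1))
        return float(np.mean(vals))

    denoised, _ = denoise_technical(m, tf)
    return {
        "share_before": share(Y),
        "share_after": share(denoised.values.to_numpy()),
    }


def planted_blocks(
    n_blocks: int = 3,
    per_block: int = 10,
    within_r: float = 0.9,
    n_samples: int = 100,
    seed: int = 0,
):
    """Feature matrix with block-constant correlation and zero across blocks."""
    rng = np.random.default_rng(seed)
    a = np.sqrt(within_r)
    b = np.sqrt(1 - within_r)
    rows = []
    for _ in range(n_blocks):
        base = rng.standard_normal(n_samples)
        rows.append(a * base[None, :] + b * rng.standard_normal((per_block, n_samples)))
    X = np.vstack(rows)
    labels = np.repeat(np.arange(n_blocks), per_block)
    return X, labels


def consensus_blocks_recovery(
    n_blocks: int = 3,
    per_block: int = 10,
    within_r: float = 0.9,
    n_samples: int = 100,
    n_subsamples: int = 500,
    G_grid=range(2, 7),
    seed: int = 0,
) -> dict:
    """Calibrated G and exactness of block recovery for planted clusters."""
    from itertools import permutations

    X, truth = planted_blocks(n_blocks, per_block, within_r, n_samples, seed)
    res = ConsensusClustering(X).fit(
        G_grid=G_grid, n_subsamples=n_subsamples, seed=seed + 1
    )
    lab = res.labels.to_numpy()
    exact = any(
        (lab == np.array([perm[t] for t in truth]) + 1).all()
        for perm in permutations(range(n_blocks))
    )
    return {"G": int(res.G), "exact": bool(exact), "pi": float(res.pi)}
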