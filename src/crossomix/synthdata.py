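"""Synthetic crossover-study data with known ground truth.

Emulates a two-site, three-occasion exposure crossover: each participant
walks once at a high-traffic site and once at a low-traffic (park) site,
with blood profiles taken 2 h before and 2 h and 24 h after each walk —
50 participants x 2 visits x 3 time points = 300 profiles by default.
Generated feature tables carry the statistical structure the downstream
analysis assumes: feature correlation induced by a sparse precision matrix,
within-person correlation via participant intercepts, sparse exposure
effects on a known feature subset, additive (log2-scale) technical batch
offsets, and left-censored low-intensity missingness.

All generators are deterministic under a fixed seed and return plain
pandas/numpy objects plus, where relevant, the ground truth needed by
recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    DimensionError,
    InvalidConfigError,
    OmicsMatrix,
)

POLLUTANTS = ("PM10", "PM25", "NO2", "BC", "PCNT")


class GenerationError(RuntimeError):
    """Random generation failed to satisfy its contract after bounded retries."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DesignConfig:
    """Crossover design: participants, health groups, sites, occasions.

    Default health-group proportions follow a three-arm recruitment
    (healthy / COPD / ischaemic heart disease) at 18:18:14.
    """

    n_participants: int = 50
    group_proportions: dict = dataclasses.field(
        default_factory=lambda: {"Healthy": 0.36, "COPD": 0.36, "IHD": 0.28}
    )
    sites: tuple = ("high_traffic", "park")
    time_points: tuple = ("pre", "post2h", "post24h")
    n_plates: int = 4
    n_boxes: int = 7
    age_mean: float = 55.0
    age_sd: float = 8.0
    female_prob: float = 0.5
    bmi_mean: float = 26.0
    bmi_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise InvalidConfigError("n_participants must be >= 1")
        if len(self.sites) != 2:
            raise InvalidConfigError("exactly 2 sites required (crossover design)")
        if len(self.time_points) != 3:
            raise InvalidConfigError("exactly 3 time points required")
        total = sum(self.group_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidConfigError(f"group proportions must sum to 1, got {total}")


@dataclasses.dataclass
class ExposureModel:
    """Per-pollutant site means/SDs plus within-site visit-level noise.

    The first site of the design is the high-exposure site; every pollutant
    mean must be strictly higher there.  Units are fixed but arbitrary
    (ug/m3 for particulate/NO2/BC-like channels, counts/cm3 for PCNT).
    """

    site_means: dict = dataclasses.field(
        default_factory=lambda: {
            "PM10": (62.0, 34.0),
            "PM25": (36.0, 21.0),
            "NO2": (88.0, 27.0),
            "BC": (11.5, 4.2),
            "PCNT": (36000.0, 16000.0),
        }
    )
    noise_sd: dict = dataclasses.field(
        default_factory=lambda: {
            "PM10": 9.0,
            "PM25": 5.0,
            "NO2": 12.0,
            "BC": 1.8,
            "PCNT": 5200.0,
        }
    )

    def __post_init__(self) -> None:
        for pol, (hi, lo) in self.site_means.items():
            if hi <= lo:
                raise InvalidConfigError(
                    f"high-exposure-site mean must exceed low-site mean for {pol}"
                )
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise InvalidConfigError("noise SDs must be non-negative")

    @property
    def pollutants(self) -> tuple:
        return tuple(self.site_means)


@dataclasses.dataclass
class EffectSpec:
    """Sparse exposure effects: which features respond, and how strongly.

    ``beta`` is the change in log2 intensity per unit of the target
    pollutant; a scalar is broadcast over the affected set.
    """

    affected: np.ndarray
    beta: np.ndarray
    pollutant: str = "NO2"

    def __post_init__(self) -> None:
        self.affected = np.asarray(self.affected, dtype=int)
        beta = np.asarray(self.beta, dtype=float)
        if beta.ndim == 0:
            beta = np.full(self.affected.shape, float(beta))
        self.beta = beta
        if self.affected.shape != self.beta.shape:
            raise InvalidConfigError("affected and beta must have equal length")
        if not np.all(np.isfinite(self.beta)):
            raise InvalidConfigError("effect sizes must be finite")

    @classmethod
    def none(cls) -> "EffectSpec":
        return cls(affected=np.array([], dtype=int), beta=np.array([], dtype=float))


@dataclasses.dataclass
class PrecisionSpec:
    """Sparse precision (inverse covariance) matrix to induce feature
    correlation with a known conditional-independence graph."""

    p: int
    density: float = 0.1
    magnitude_range: tuple = (0.2, 0.5)
    margin: float = 1.0

    def __post_init__(self) -> None:
        if self.p < 2:
            raise InvalidConfigError("precision dimension must be >= 2")
        if not 0.0 <= self.density <= 1.0:
            raise InvalidConfigError("edge density must lie in [0, 1]")
        lo, hi = self.magnitude_range
        if not 0 < lo <= hi:
            raise InvalidConfigError("magnitude range must satisfy 0 < lo <= hi")
        if self.margin <= 0:
            raise InvalidConfigError("diagonal dominance margin must be > 0")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_design(cfg: DesignConfig) -> pd.DataFrame:
    """Draw the sample-metadata table for a randomized crossover design.

    Returns one row per profile: ``n_participants x 2 visits x 3 time
    points``.  The site of the first visit is randomized per participant;
    age/sex/BMI/health group are drawn from the configured distributions and
    technical factors (plate, box) are assigned round-robin over profiles.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = list(cfg.group_proportions)
    probs = np.array([cfg.group_proportions[g] for g in groups])

    rows = []
    for i in range(cfg.n_participants):
        pid = f"P{i + 1:03d}"
        first = rng.integers(2)  # index of the first-visit site
        site_order = (cfg.sites[first], cfg.sites[1 - first])
        age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 30, 85))
        sex = "F" if rng.random() < cfg.female_prob else "M"
        bmi = float(np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd), 16, 45))
        group = groups[rng.choice(len(groups), p=probs)]
        for visit, site in enumerate(site_order, start=1):
            for tp in cfg.time_points:
                rows.append(
                    dict(
                        sample_id=f"{pid}_V{visit}_{tp}",
                        participant=pid,
                        visit=visit,
                        site=site,
                        time_point=tp,
                        age=age,
                        sex=sex,
                        bmi=bmi,
                        health_group=group,
                    )
                )
    meta = pd.DataFrame(rows)
    meta["plate"] = [f"plate{i % cfg.n_plates + 1}" for i in range(len(meta))]
    meta["box"] = [f"box{i % cfg.n_boxes + 1}" for i in range(len(meta))]
    meta = meta.set_index("sample_id")
    meta.attrs["high_site"] = cfg.sites[0]
    meta.attrs["pre_label"] = cfg.time_points[0]
    return meta


def generate_exposures(design: pd.DataFrame, model: ExposureModel, seed: int = 0) -> pd.DataFrame:
    """Draw one exposure row per (participant, visit).

    A visit's pollutant value is the site mean plus visit-level noise and is
    shared by all three profiles of that visit (the walk is a single event).
    """
    if "visit" not in design.columns:
        raise InvalidConfigError("design lacks visit identifiers")
    rng = np.random.default_rng(seed)
    visits = design.reset_index()[["participant", "visit", "site"]].drop_duplicates()
    visits = visits.sort_values(["participant", "visit"]).reset_index(drop=True)
    high = design.attrs.get("high_site", list(dict.fromkeys(design["site"]))[0])
    for pol in model.pollutants:
        hi, lo = model.site_means[pol]
        means = np.where(visits["site"] == high, hi, lo)
        visits[pol] = means + rng.normal(0.0, model.noise_sd[pol], size=len(visits))
    return visits.set_index(["participant", "visit"])


def exposures_per_sample(design: pd.DataFrame, exposures: pd.DataFrame) -> pd.DataFrame:
    """Broadcast visit-level exposures to one row per profile, aligned with
    the design index."""
    merged = design.reset_index().merge(
        exposures.reset_index().drop(columns=["site"], errors="ignore"),
        on=["participant", "visit"],
        how="left",
    )
    return merged.set_index("sample_id").loc[design.index]


def generate_precision_matrix(spec: PrecisionSpec, seed: int = 0, max_retries: int = 5):
    """Draw a sparse symmetric positive-definite precision matrix.

    Off-diagonal support is an Erdos-Renyi edge set at the requested
    density; magnitudes are uniform in ``magnitude_range`` with random sign.
    Positive definiteness is enforced by diagonal dominance: each diagonal
    entry is the absolute row sum plus ``margin``.

    Returns
    -------
    theta : (p, p) ndarray
    edges : list of (i, j) with i < j — the exact nonzero support.
    """
    rng = np.random.default_rng(seed)
    p = spec.p
    lo, hi = spec.magnitude_range
    for _ in range(max_retries):
        theta = np.zeros((p, p))
        edges = []
        for i in range(p):
            for j in range(i + 1, p):
                if rng.random() < spec.density:
                    val = rng.uniform(lo, hi) * (1 if rng.random() < 0.5 else -1)
                    theta[i, j] = theta[j, i] = val
                    edges.append((i, j))
        np.fill_diagonal(theta, np.abs(theta).sum(axis=1) + spec.margin)
        if np.linalg.eigvalsh(theta).min() > 0:
            return theta, edges
    raise GenerationError("could not draw a positive-definite precision matrix")


def generate_omics(
    design: pd.DataFrame,
    exposures: pd.DataFrame,
    precision: np.ndarray,
    effects: EffectSpec,
    batch_sd: float = 0.3,
    censor_fraction: float = 0.1,
    seed: int = 0,
    participant_sd: float = 0.5,
    effect_mode: str = "post",
    baseline_range: tuple = (14.0, 20.0),
    group_shift_sd: float = 0.0,
    kind: str = "metabolite",
    feature_prefix: str | None = None,
):
    """Draw a feature table with known correlation, effects and censoring.

    Per profile the log2 feature vector is

        baseline + participant intercept + MVN(0, precision^-1)
        + beta * exposure (on affected features / relevant occasions)
        + plate offset + box offset (additive on log2 = multiplicative raw)

    and the lowest ``censor_fraction`` quantile of every feature is then set
    missing (left-censored, missing-not-at-random).

    Parameters
    ----------
    effect_mode
        ``"post"``: effects act on post-walk occasions only (+2 h, +24 h),
        the within-person contrast a crossover exploits. ``"main"``: effects
        act on all three occasions of the visit.

    Returns
    -------
    matrix : OmicsMatrix (scale="raw", NaN = censored)
    truth : dict with ``latent`` (log2 matrix before censoring), ``affected``,
        ``beta``, ``pollutant`` and ``censored_mask``.
    """
    if not 0.0 <= censor_fraction <= 0.5:
        raise InvalidConfigError("censor_fraction must lie in [0, 0.5]")
    if effect_mode not in ("post", "main"):
        raise InvalidConfigError("effect_mode must be 'post' or 'main'")
    p = precision.shape[0]
    if precision.shape != (p, p):
        raise DimensionError("precision matrix must be square")
    n = len(design)
    expo = exposures_per_sample(design, exposures)
    if len(expo) != n:
        raise DimensionError("exposure table does not cover every profile")
    if effects.affected.size and effects.affected.max() >= p:
        raise InvalidConfigError("affected feature index outside matrix dimension")

    rng = np.random.default_rng(seed)
    cov = np.linalg.inv(precision)
    chol = np.linalg.cholesky(cov)

    baseline = rng.uniform(*baseline_range, size=p)
    participants = list(dict.fromkeys(design["participant"]))
    p_intercepts = rng.normal(0.0, participant_sd, size=(len(participants), p))
    p_index = np.array([participants.index(x) for x in design["participant"]])

    latent = baseline[None, :] + p_intercepts[p_index]
    latent = latent + rng.standard_normal((n, p)) @ chol.T

    if effects.affected.size:
        x = expo[effects.pollutant].to_numpy(dtype=float)
        if effect_mode == "post":
            pre = design.attrs.get("pre_label", design["time_point"].iloc[0])
            on = (design["time_point"] != pre).to_numpy()
        else:
            on = np.ones(n, dtype=bool)
        contrib = np.where(on, x, 0.0)
        latent[:, effects.affected] += contrib[:, None] * effects.beta[None, :]

    if group_shift_sd > 0:
        groups = list(dict.fromkeys(design["health_group"]))
        shifts = rng.normal(0.0, group_shift_sd, size=(len(groups), p))
        g_index = np.array([groups.index(g) for g in design["health_group"]])
        latent += shifts[g_index]

    for factor in ("plate", "box"):
        if factor in design.columns and batch_sd > 0:
            levels = list(dict.fromkeys(design[factor]))
            offsets = rng.normal(0.0, batch_sd, size=(len(levels), p))
            idx = np.array([levels.index(v) for v in design[factor]])
            latent += offsets[idx]

    # left-censor: exactly the k lowest values of each feature go missing
    values = latent.copy()
    censored = np.zeros_like(values, dtype=bool)
    k = int(np.floor(censor_fraction * n))
    if k > 0:
        order = np.argsort(values, axis=0, kind="stable")
        rows = order[:k, :]
        cols = np.broadcast_to(np.arange(p), rows.shape)
        censored[rows, cols] = True
    observed = np.where(censored, np.nan, values)

    sample_ids = design.index
    if feature_prefix is None:
        feature_prefix = "M" if kind == "metabolite" else "T"
    feature_ids = [f"{feature_prefix}{i + 1:04d}" for i in range(p)]
    raw = pd.DataFrame(np.exp2(observed).T, index=feature_ids, columns=sample_ids)

    if kind == "metabolite":
        meta = pd.DataFrame(
            {
                "mz": rng.uniform(80.0, 900.0, size=p),
                "rt": rng.uniform(0.5, 12.0, size=p),
            },
            index=feature_ids,
        )
    else:
        meta = pd.DataFrame(
            {"gene_symbol": [f"GENE{i + 1:04d}" for i in range(p)]}, index=feature_ids
        )

    matrix = OmicsMatrix(values=raw, feature_meta=meta, scale="raw")
    truth = {
        "latent": pd.DataFrame(values.T, index=feature_ids, columns=sample_ids),
        "affected": [feature_ids[i] for i in effects.affected],
        "beta": {feature_ids[i]: float(b) for i, b in zip(effects.affected, effects.beta)},
        "pollutant": effects.pollutant,
        "censored_mask": pd.DataFrame(censored.T, index=feature_ids, columns=sample_ids),
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# enrichment fixtures: reference masses and pathway maps keyed to features
# ---------------------------------------------------------------------------

def generate_reference(
    feature_meta: pd.DataFrame,
    n_pathways: int = 8,
    seed: int = 0,
    adduct_shifts: dict | None = None,
):
    """Build a reference mass list and toy pathway map matched to features.

    Each metabolite feature is assigned a reference compound whose
    monoisotopic mass places the feature's m/z exactly on one of the adduct
    rules; compounds are partitioned into pathways.  Gives the annotation
    and over-representation steps a fully known ground truth.

    Returns (reference DataFrame [compound, mass], pathways dict, feature->compound map).
    """
    from .enrichment import DEFAULT_ADDUCTS  # local import to avoid a cycle

    shifts = adduct_shifts or {a.name: a.mass_shift for a in DEFAULT_ADDUCTS}
    rng = np.random.default_rng(seed)
    names = list(shifts)
    compounds, masses, feat2cpd = [], [], {}
    for i, (fid, mz) in enumerate(feature_meta["mz"].items()):
        cid = f"CPD{i + 1:04d}"
        adduct = names[rng.integers(len(names))]
        compounds.append(cid)
        masses.append(mz - shifts[adduct])
        feat2cpd[fid] = cid
    reference = pd.DataFrame({"compound": compounds, "mass": masses}).set_index("compound")
    order = rng.permutation(len(compounds))
    pathways = {
        f"pathway_{k + 1}": {compounds[i] for i in order[k::n_pathways]}
        for k in range(n_pathways)
    }
    return reference, pathways, feat2cpd


# ---------------------------------------------------------------------------
# study bundle
# ---------------------------------------------------------------------------

def write_study(
    out_dir,
    design: pd.DataFrame,
    exposures: pd.DataFrame,
    matrix: OmicsMatrix,
    truth: dict,
) -> None:
    """Write the TSV dialect consumed by the pipeline plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.to_tsv(out / "features.tsv", out / "feature_meta.tsv")
    design.to_csv(out / "samples.tsv", sep="\t", index_label="sample_id")
    exposures.reset_index().to_csv(out / "exposures.tsv", sep="\t", index=False)
    slim = {
        "affected": truth["affected"],
        "beta": truth["beta"],
        "pollutant": truth["pollutant"],
    }
    if "edges" in truth:
        slim["edges"] = [list(e) for e in truth["edges"]]
    (out / "truth.json").write_text(json.dumps(slim, indent=1))
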