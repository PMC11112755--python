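"""Adduct-based m/z annotation and pathway over-representation analysis.

Positive-mode electrospray features are matched to a user-supplied neutral
monoisotopic mass list through a small set of adduct rules ([M+H]+,
[M-H2O+H]+, [M+Na]+) within a ppm mass tolerance, and compound sets are
tested for pathway over-representation with a one-sided Fisher exact test
(equivalently, the hypergeometric tail) against user-supplied pathway maps.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
from scipy import stats

from .containers import InvalidConfigError

__all__ = [
    "AdductRule",
    "DEFAULT_ADDUCTS",
    "PathwayMap",
    "match_mz",
    "ora_fisher",
    "select_significant",
    "DEFAULT_POLLUTANT_THRESHOLDS",
]

PROTON = 1.007276
WATER = 18.010565
SODIUM_ION = 22.989218


@dataclasses.dataclass(frozen=True)
class AdductRule:
    """A positive-mode ion form: observed m/z = neutral mass + shift."""

    name: str
    mass_shift: float  # Da, monoisotopic
    charge: int = 1


DEFAULT_ADDUCTS = (
    AdductRule("[M+H]+", PROTON),
    AdductRule("[M-H2O+H]+", PROTON - WATER),
    AdductRule("[M+Na]+", SODIUM_ION),
)

#: Per-pollutant p-value thresholds applied before building the selected set.
DEFAULT_POLLUTANT_THRESHOLDS = {
    "PM25": 0.05,
    "PM10": 0.05,
    "PCNT": 0.01,
    "BC": 0.01,
    "NO2": 0.005,
}


def match_mz(
    mz: float,
    reference,
    adducts=DEFAULT_ADDUCTS,
    tol_ppm: float = 8.0,
) -> list[tuple]:
    """Match one observed m/z against a reference mass list.

    For each adduct rule the implied neutral mass M = mz - shift is
    compared with every reference mass; a hit requires
    ``|M - ref| / ref * 1e6 <= tol_ppm``.

    Parameters
    ----------
    reference
        Mapping of compound id -> monoisotopic mass, or a DataFrame with a
        ``mass`` column indexed by compound id.

    Returns
    -------
    list of (compound id, adduct name, ppm error), sorted by |ppm error|.
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    if tol_ppm <= 0:
        raise InvalidConfigError("tol_ppm must be > 0")
    if isinstance(reference, pd.DataFrame):
        ref = reference["mass"]
    else:
        ref = pd.Series(reference, dtype=float)
    hits = []
    for rule in adducts:
        neutral = mz - rule.mass_shift
        ppm = (neutral - ref) / ref * 1e6
        within = ppm.abs() <= tol_ppm
        for cid, err in ppm[within].items():
            hits.append((cid, rule.name, float(err)))
    hits.sort(key=lambda h: (abs(h[2]), str(h[0]), h[1]))
    return hits


def annotate_features(
    feature_meta: pd.DataFrame, reference, adducts=DEFAULT_ADDUCTS, tol_ppm: float = 8.0
) -> pd.DataFrame:
    """Match every feature's m/z; returns a tidy (feature, compound, adduct,
    ppm_error) table keeping all candidates within tolerance."""
    rows = []
    for fid, mz in feature_meta["mz"].items():
        for cid, adduct, err in match_mz(mz, reference, adducts, tol_ppm):
            rows.append(
                {"feature": fid, "compound": cid, "adduct": adduct, "ppm_error": err}
            )
    return pd.DataFrame(rows, columns=["feature", "compound", "adduct", "ppm_error"])


@dataclasses.dataclass
class PathwayMap:
    """Named compound sets over a fixed universe of assayed compounds."""

    pathways: dict
    universe: set

    def __post_init__(self) -> None:
        if not self.universe:
            raise InvalidConfigError("pathway universe must be non-empty")
        self.universe = set(self.universe)
        self.pathways = {k: set(v) for k, v in self.pathways.items()}
        for name, members in self.pathways.items():
            extra = members - self.universe
            if extra:
                raise InvalidConfigError(
                    f"pathway {name!r} contains compounds outside the universe: "
                    f"{sorted(extra)[:5]}"
                )

    @classmethod
    def from_gmt(cls, path, universe=None) -> "PathwayMap":
        """Read a GMT file (name <tab> description <tab> members...)."""
        pathways = {}
        for line in Path(path).read_text().splitlines():
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            pathways[parts[0]] = set(parts[2:])
        if universe is None:
            universe = set().union(*pathways.values()) if pathways else set()
        return cls(pathways=pathways, universe=set(universe))

    def to_gmt(self, path) -> None:
        lines = [
            "\t".join([name, "na"] + sorted(members))
            for name, members in self.pathways.items()
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def ora_fisher(selected, pmap: PathwayMap) -> pd.DataFrame:
    """One-sided Fisher exact over-representation test per pathway.

    For each pathway the 2x2 table (in/out pathway x selected/not, over the
    universe) is tested against the over-representation alternative.
    Returns a table of (pathway, size, overlap, p) sorted by p.
    """
    selected = set(selected)
    extra = selected - pmap.universe
    if extra:
        raise InvalidConfigError(
            f"selected compounds outside the universe: {sorted(extra)[:5]}"
        )
    N = len(pmap.universe)
    n_sel = len(selected)
    rows = []
    for name, members in pmap.pathways.items():
        K = len(members)
        overlap = len(selected & members)
        table = [
            [overlap, n_sel - overlap],
            [K - overlap, N - K - (n_sel - overlap)],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append({"pathway": name, "size": K, "overlap": overlap, "p": float(p)})
    return (
        pd.DataFrame(rows, columns=["pathway", "size", "overlap", "p"])
        .sort_values(["p", "pathway"])
        .reset_index(drop=True)
    )


def select_significant(
    results: pd.DataFrame, thresholds: dict | None = None
) -> dict:
    """Per-pollutant feature sets passing the configured p-value thresholds.

    ``results`` is the tidy association table (feature, exposure, p).
    """
    thresholds = thresholds or DEFAULT_POLLUTANT_THRESHOLDS
    out = {}
    for pol, grp in results.groupby("exposure"):
        thr = thresholds.get(pol, 0.05)
        out[pol] = set(grp.loc[grp["p"] < thr, "feature"])
    return out
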