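"""Stability-calibrated consensus clustering of correlated features.

Untargeted feature tables are redundant: one analyte appears as several
ions (adducts, isotopes) with near-identical profiles.  Before network
estimation such groups are summarized by clustering features on their
correlation and representing each cluster by its medoid.

The number of clusters G and the comembership threshold pi_c are calibrated
by stability: the base clusterer (hierarchical, Ward linkage, distance
1 - |Pearson r|) is rerun on many subsamples of profiles, pairwise
comembership proportions are accumulated per candidate G, and (G, pi_c)
maximize the same binomial-null stability score used for network
calibration.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import InvalidConfigError
from .network import stability_score

__all__ = ["ConsensusClustering", "ClusterAssignment", "consensus_cluster", "cluster_medoids"]


@dataclasses.dataclass
class ClusterAssignment:
    """Feature clustering with its consensus evidence.

    ``labels`` maps each feature to a cluster id (1..G), ``comembership``
    holds pairwise comembership proportions, ``medoids`` the representative
    feature of each cluster.
    """

    labels: pd.Series
    comembership: pd.DataFrame
    G: int
    pi: float
    score: float
    medoids: dict
    score_table: pd.DataFrame | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())

    def members(self, cluster) -> list:
        return list(self.labels.index[self.labels == cluster])

    def medoid_features(self) -> list:
        return [self.medoids[c] for c in sorted(self.medoids)]

    def to_frame(self) -> pd.DataFrame:
        """clusters.tsv layout: feature, cluster, is_medoid."""
        return pd.DataFrame(
            {
                "feature": self.labels.index,
                "cluster": self.labels.to_numpy(),
                "is_medoid": [
                    self.medoids.get(c) == f for f, c in self.labels.items()
                ],
            }
        )

    def retention_time_report(self, feature_meta: pd.DataFrame) -> pd.DataFrame:
        """Per-cluster retention-time spread — a coherence report (clusters
        of ions from one analyte share retention times), not an assertion."""
        if "rt" not in feature_meta.columns:
            raise InvalidConfigError("feature metadata lacks retention times")
        rt = feature_meta.loc[self.labels.index, "rt"]
        grp = rt.groupby(self.labels)
        return pd.DataFrame(
            {"n": grp.size(), "rt_median": grp.median(), "rt_range": grp.max() - grp.min()}
        )

    def summary(self) -> str:
        sizes = self.labels.value_counts().sort_index()
        return (
            f"Consensus clustering: {len(self.labels)} features in "
            f"{self.n_clusters} clusters (calibrated G = {self.G}, "
            f"pi_c = {self.pi:.2f}, score = {self.score:.2f})\n"
            f"  sizes: {list(sizes.to_numpy())}"
        )


class ConsensusClustering:
    """Consensus clustering model over a features-by-samples matrix."""

    def __init__(self, values, feature_ids=None):
        if isinstance(values, pd.DataFrame):
            self.values = values.to_numpy(dtype=float)
            self.feature_ids = list(values.index)
        else:
            self.values = np.asarray(values, dtype=float)
            self.feature_ids = (
                list(feature_ids)
                if feature_ids is not None
                else [f"f{i}" for i in range(self.values.shape[0])]
            )
        if self.values.shape[0] < 3:
            raise InvalidConfigError("need at least 3 features to cluster")

    def fit(
        self,
        G_grid=None,
        n_subsamples: int = 500,
        subsample_frac: float = 0.8,
        seed: int = 0,
        pi_grid=None,
        linkage_method: str = "ward",
    ) -> ClusterAssignment:
        p, n = self.values.shape
        if G_grid is None:
            G_grid = range(2, min(11, p))
        original = list(G_grid)
        G_grid = [g for g in original if g <= p]
        if len(G_grid) < len(original):
            warnings.warn("G_grid trimmed to the feature count", UserWarning)
        if not G_grid:
            raise InvalidConfigError("G_grid contains no feasible cluster counts")
        if pi_grid is None:
            pi_grid = np.arange(0.51, 0.995, 0.01)
        rng = np.random.default_rng(seed)
        size = max(int(np.ceil(subsample_frac * n)), 3)
        counts = {g: np.zeros((p, p)) for g in G_grid}
        for _ in range(n_subsamples):
            cols = rng.choice(n, size=size, replace=False)
            d = _correlation_distance(self.values[:, cols])
            Z = hierarchy.linkage(squareform(d, checks=False), method=linkage_method)
            for g in G_grid:
                lab = hierarchy.fcluster(Z, t=g, criterion="maxclust")
                same = lab[:, None] == lab[None, :]
                counts[g] += same
        iu = np.triu_indices(p, 1)
        best = (-np.inf, None, None)
        rows = []
        for g in G_grid:
            c = counts[g][iu]
            q = c.sum() / (n_subsamples * c.size)
            for pi in pi_grid:
                sc = stability_score(c, n_subsamples, pi, q)
                rows.append({"G": g, "pi": pi, "score": sc})
                if sc > best[0]:
                    best = (sc, g, pi)
        score, G_star, pi_star = best
        if G_star is None:
            raise InvalidConfigError("calibration failed for every (G, pi)")
        co = counts[G_star] / n_subsamples
        np.fill_diagonal(co, 1.0)
        labels = _consensus_partition(co, G_star, pi_star)
        labels = pd.Series(labels, index=self.feature_ids, name="cluster")
        assignment = ClusterAssignment(
            labels=labels,
            comembership=pd.DataFrame(co, index=self.feature_ids, columns=self.feature_ids),
            G=G_star,
            pi=float(pi_star),
            score=float(score),
            medoids={},
            score_table=pd.DataFrame(rows),
        )
        assignment.medoids = cluster_medoids(assignment, self.values)
        return assignment


def _correlation_distance(X: np.ndarray) -> np.ndarray:
    r = np.corrcoef(X)
    r = np.nan_to_num(r, nan=0.0)
    d = 1.0 - np.abs(r)
    np.fill_diagonal(d, 0.0)
    return np.clip(0.5 * (d + d.T), 0.0, None)


def _consensus_partition(co: np.ndarray, G: int, pi: float) -> np.ndarray:
    """Partition from the thresholded comembership graph.

    Connected components at comembership >= pi form the initial clusters;
    if there are more than G components the two clusters with the highest
    mean between-cluster comembership are merged until G remain, and if
    fewer, the loosest cluster (lowest mean internal comembership) is split
    by 2-way average-linkage agglomeration until G are reached.
    """
    import networkx as nx

    p = co.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(p))
    for j in range(p):
        for k in range(j + 1, p):
            if co[j, k] >= pi:
                g.add_edge(j, k)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])

    def between(a, b):
        return co[np.ix_(a, b)].mean()

    while len(comps) > G:
        best, pair = -1.0, None
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                v = between(comps[i], comps[j])
                if v > best:
                    best, pair = v, (i, j)
        i, j = pair
        comps[i] = sorted(comps[i] + comps[j])
        del comps[j]
    while len(comps) < G:
        splittable = [c for c in comps if len(c) > 1]
        if not splittable:
            break
        loosest = min(
            splittable,
            key=lambda c: co[np.ix_(c, c)].mean(),
        )
        idx = comps.index(loosest)
        sub = np.asarray(loosest)
        d = 1.0 - co[np.ix_(sub, sub)]
        np.fill_diagonal(d, 0.0)
        Z = hierarchy.linkage(squareform(d, checks=False), method="average")
        lab = hierarchy.fcluster(Z, t=2, criterion="maxclust")
        comps[idx] = sorted(sub[lab == 1].tolist())
        comps.insert(idx + 1, sorted(sub[lab == 2].tolist()))
    labels = np.zeros(p, dtype=int)
    for ci, comp in enumerate(sorted(comps, key=lambda c: c[0]), start=1):
        labels[comp] = ci
    return labels


def consensus_cluster(values, **fit_kw) -> ClusterAssignment:
    """Functional wrapper over :class:`ConsensusClustering`."""
    return ConsensusClustering(values).fit(**fit_kw)


def cluster_medoids(assignment: ClusterAssignment, values) -> dict:
    """Representative feature per cluster.

    The medoid is the member with the highest total absolute correlation to
    its co-members on the full data; a singleton cluster is its own medoid;
    ties break to the lowest feature index.
    """
    X = values.to_numpy(dtype=float) if isinstance(values, pd.DataFrame) else np.asarray(values)
    ids = list(assignment.labels.index)
    r = np.corrcoef(X)
    r = np.nan_to_num(r, nan=0.0)
    medoids = {}
    for cluster in sorted(assignment.labels.unique()):
        members = np.flatnonzero((assignment.labels == cluster).to_numpy())
        assert members.size > 0, "empty cluster cannot occur by construction"
        if members.size == 1:
            medoids[cluster] = ids[members[0]]
            continue
        sub = np.abs(r[np.ix_(members, members)])
        np.fill_diagonal(sub, 0.0)
        totals = sub.sum(axis=1)
        best = members[int(np.argmax(totals))]  # argmax takes the first max: lowest index
        medoids[cluster] = ids[best]
    return medoids
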