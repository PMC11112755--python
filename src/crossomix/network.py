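"""Stability-calibrated graphical-LASSO conditional-independence networks.

The graphical LASSO maximizes the L1-penalized Gaussian log-likelihood

    log det Theta - trace(S Theta) - sum_{j != k} lambda_jk |Theta_jk|

over positive-definite precision matrices Theta, given a correlation matrix
S; zeros of Theta encode conditional independence.  The solver is the
classic block coordinate descent over columns, each column a lasso
subproblem solved by cyclic coordinate descent, with an elementwise penalty
matrix so that block-structured (multiomic) penalties are a special case.

Hyper-parameters are calibrated by stability: the model is refitted on K
subsamples (default 80% of participants, K = 500), per-edge selection
proportions are recorded for a penalty grid, and the penalty and the
selection-proportion threshold are chosen jointly to maximize a
likelihood-based stability score that contrasts the observed bimodality of
selection proportions against an exchangeable binomial null.
"""

from __future__ import annotations

import dataclasses
import warnings
from itertools import product

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .containers import CrossomixError, InvalidConfigError

__all__ = [
    "graphical_lasso",
    "stability_score",
    "stability_select_network",
    "multiblock_stability_network",
    "compare_networks",
    "StabilityNetwork",
    "RegularizationError",
    "AlignmentError",
]


class RegularizationError(CrossomixError, ValueError):
    """The problem needs a positive penalty (singular input)."""


class AlignmentError(CrossomixError, ValueError):
    """Node sets of compared networks do not match."""


# ---------------------------------------------------------------------------
# solver core (numba)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _glasso_cd(S, Lam, tol, max_iter, inner_tol, inner_max_iter):
    """Block coordinate descent for the penalized precision estimate.

    Returns (W, B) with W the working covariance estimate (W = Theta^-1 at
    convergence, diagonal unpenalized so diag(W) = diag(S)) and B the
    column lasso coefficients whose exact zeros define the edge set.
    """
    p = S.shape[0]
    W = S.copy()
    B = np.zeros((p, p))
    # convergence scale: mean absolute off-diagonal of S
    scale = 0.0
    for i in range(p):
        for j in range(p):
            if i != j:
                scale += abs(S[i, j])
    scale = scale / max(p * (p - 1), 1) + 1e-12

    W11 = np.empty((p - 1, p - 1))
    s12 = np.empty(p - 1)
    lam12 = np.empty(p - 1)
    beta = np.empty(p - 1)
    w12 = np.empty(p - 1)

    for _ in range(max_iter):
        dmax = 0.0
        for col in range(p):
            # gather the partitioned problem for this column
            r = 0
            for i in range(p):
                if i == col:
                    continue
                c = 0
                for j in range(p):
                    if j == col:
                        continue
                    W11[r, c] = W[i, j]
                    c += 1
                s12[r] = S[i, col]
                lam12[r] = Lam[i, col]
                beta[r] = B[i, col]
                r += 1
            # cyclic coordinate descent on
            #   0.5 b' W11 b - s12' b + sum lam12 |b|
            for _it in range(inner_max_iter):
                db = 0.0
                for j in range(p - 1):
                    old = beta[j]
                    g = s12[j]
                    for l in range(p - 1):
                        if l != j:
                            g -= W11[j, l] * beta[l]
                    if g > lam12[j]:
                        new = (g - lam12[j]) / W11[j, j]
                    elif g < -lam12[j]:
                        new = (g + lam12[j]) / W11[j, j]
                    else:
                        new = 0.0
                    beta[j] = new
                    d = abs(new - old)
                    if d > db:
                        db = d
                if db < inner_tol:
                    break
            # w12 = W11 beta
            for i in range(p - 1):
                acc = 0.0
                for l in range(p - 1):
                    acc += W11[i, l] * beta[l]
                w12[i] = acc
            r = 0
            for i in range(p):
                if i == col:
                    continue
                d = abs(W[i, col] - w12[r])
                if d > dmax:
                    dmax = d
                W[i, col] = w12[r]
                W[col, i] = w12[r]
                B[i, col] = beta[r]
                r += 1
        if dmax < tol * scale:
            break
    return W, B


def _theta_from_wb(W: np.ndarray, B: np.ndarray) -> np.ndarray:
    p = W.shape[0]
    theta = np.zeros_like(W)
    for col in range(p):
        idx = np.arange(p) != col
        beta = B[idx, col]
        denom = W[col, col] - W[idx, col] @ beta
        t22 = 1.0 / denom
        theta[col, col] = t22
        theta[idx, col] = -beta * t22
    # exact zero pattern from B; average the two directed estimates
    support = (B != 0) | (B.T != 0)
    theta = 0.5 * (theta + theta.T)
    off = ~np.eye(p, dtype=bool)
    theta[off & ~support] = 0.0
    return theta


def graphical_lasso(
    S: np.ndarray,
    lam,
    tol: float = 1e-6,
    max_iter: int = 200,
    return_working: bool = False,
):
    """Sparse precision estimate for a correlation matrix.

    Parameters
    ----------
    S
        Symmetric correlation (or covariance) matrix, positive semidefinite.
    lam
        Scalar penalty, or a (p, p) elementwise penalty matrix (the diagonal
        is ignored; it is never penalized).

    Returns
    -------
    theta : (p, p) penalized precision estimate (exact zeros off the support)
    edges : list of (j, k), j < k, the nonzero off-diagonal support
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if S.shape != (p, p) or not np.allclose(S, S.T, atol=1e-10):
        raise InvalidConfigError("S must be a symmetric square matrix")
    Lam = np.asarray(lam, dtype=float)
    if Lam.ndim == 0:
        Lam = np.full((p, p), float(Lam))
    if (Lam < 0).any():
        raise InvalidConfigError("penalties must be non-negative")
    off = ~np.eye(p, dtype=bool)
    if not Lam[off].any():
        # unpenalized: the estimate is the plain inverse
        if np.linalg.matrix_rank(S) < p or np.linalg.cond(S) > 1e12:
            raise RegularizationError(
                "S is singular at lam = 0; use a positive penalty"
            )
        theta = np.linalg.inv(S)
        edges = [(j, k) for j in range(p) for k in range(j + 1, p) if theta[j, k] != 0]
        return (theta, edges, S.copy()) if return_working else (theta, edges)

    W, B = _glasso_cd(
        np.ascontiguousarray(S),
        np.ascontiguousarray(Lam),
        tol,
        max_iter,
        tol * 0.1,
        500,
    )
    theta = _theta_from_wb(W, B)
    edges = [(j, k) for j in range(p) for k in range(j + 1, p) if theta[j, k] != 0]
    return (theta, edges, W) if return_working else (theta, edges)


def subgradient_violation(S: np.ndarray, theta: np.ndarray, lam) -> float:
    """Maximum violation of the glasso optimality conditions.

    The stationarity condition of the penalized likelihood is
    Theta^-1 = S + lam * sign(Theta) on the nonzero off-diagonal support,
    |Theta^-1 - S| <= lam where Theta_jk = 0, and Theta^-1 = S on the
    (unpenalized) diagonal.
    """
    p = S.shape[0]
    Lam = np.asarray(lam, dtype=float)
    if Lam.ndim == 0:
        Lam = np.full((p, p), float(Lam))
    G = np.linalg.inv(theta) - S
    viol = np.abs(np.diag(G)).max()
    for j in range(p):
        for k in range(p):
            if j == k:
                continue
            if theta[j, k] != 0:
                viol = max(viol, abs(G[j, k] - Lam[j, k] * np.sign(theta[j, k])))
            else:
                viol = max(viol, max(abs(G[j, k]) - Lam[j, k], 0.0))
    return float(viol)


# ---------------------------------------------------------------------------
# stability score
# ---------------------------------------------------------------------------

def stability_score(counts, K: int, pi: float, q: float | None = None) -> float:
    """Likelihood-based stability score of a selection-count configuration.

    Under the exchangeable null every edge is selected with the same
    probability ``q`` (the average selection probability at this penalty),
    so its count follows Binomial(K, q).  Each edge contributes the log
    null probability of the category its selection proportion falls in —
    stably selected (>= pi), stably unselected (<= 1 - pi), or unstable
    (in between) — and the score is minus their sum: large when the
    observed configuration is bimodal, i.e. incompatible with exchangeable
    instability.  Degenerate penalties (q in {0, 1}) score -inf.
    """
    counts = np.asarray(counts, dtype=float)
    if not 0.5 < pi < 1.0:
        raise InvalidConfigError("pi must lie in (0.5, 1)")
    if (counts < 0).any() or (counts > K).any():
        raise InvalidConfigError("counts must lie in [0, K]")
    if q is None:
        q = counts.sum() / (K * counts.size)
    if q <= 0.0 or q >= 1.0:
        return -np.inf
    k_hi = int(np.ceil(K * pi))
    k_lo = int(np.floor(K * (1.0 - pi)))
    p_hi = stats.binom.sf(k_hi - 1, K, q)
    p_lo = stats.binom.cdf(k_lo, K, q)
    p_mid = max(stats.binom.cdf(k_hi - 1, K, q) - stats.binom.cdf(k_lo, K, q), 0.0)
    prop = counts / K
    n_hi = int((prop >= pi).sum())
    n_lo = int((prop <= 1.0 - pi).sum())
    n_mid = counts.size - n_hi - n_lo
    tiny = 1e-300
    return -(
        n_hi * np.log(max(p_hi, tiny))
        + n_lo * np.log(max(p_lo, tiny))
        + n_mid * np.log(max(p_mid, tiny))
    )


# ---------------------------------------------------------------------------
# stability selection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StabilityNetwork:
    """Calibrated stable network with its selection-proportion evidence."""

    proportions: pd.DataFrame
    lam_star: float | dict
    pi_star: float
    score: float
    adjacency: pd.DataFrame
    K: int
    frac: float
    lam_grid: np.ndarray | dict
    counts: dict
    blocks: pd.Series | None = None

    @property
    def nodes(self) -> list:
        return list(self.adjacency.index)

    @property
    def edges(self) -> list:
        A = self.adjacency.to_numpy()
        nodes = self.nodes
        return [
            (nodes[j], nodes[k])
            for j in range(len(nodes))
            for k in range(j + 1, len(nodes))
            if A[j, k]
        ]

    def cross_edges(self) -> list:
        """Edges joining different blocks (multiomic networks)."""
        if self.blocks is None:
            return []
        return [
            (u, v) for u, v in self.edges if self.blocks[u] != self.blocks[v]
        ]

    def edge_table(self) -> pd.DataFrame:
        """Edge list with selection proportions, stability flag, block pair."""
        nodes = self.nodes
        P = self.proportions.to_numpy()
        A = self.adjacency.to_numpy()
        rows = []
        for j in range(len(nodes)):
            for k in range(j + 1, len(nodes)):
                if P[j, k] > 0:
                    rec = {
                        "node1": nodes[j],
                        "node2": nodes[k],
                        "selection_proportion": P[j, k],
                        "stable": bool(A[j, k]),
                    }
                    if self.blocks is not None:
                        rec["block_pair"] = "-".join(
                            sorted([str(self.blocks[nodes[j]]), str(self.blocks[nodes[k]])])
                        )
                    rows.append(rec)
        return pd.DataFrame(rows)

    def to_graph(self):
        """networkx Graph of the stable adjacency (for GraphML export)."""
        import networkx as nx

        g = nx.Graph()
        for n in self.nodes:
            attrs = {} if self.blocks is None else {"block": str(self.blocks[n])}
            g.add_node(n, **attrs)
        P = self.proportions
        for u, v in self.edges:
            g.add_edge(u, v, selection_proportion=float(P.loc[u, v]))
        return g

    def summary(self) -> str:
        lam = (
            f"{self.lam_star:.4g}"
            if np.isscalar(self.lam_star)
            else ", ".join(f"{k}={v:.4g}" for k, v in self.lam_star.items())
        )
        return (
            f"Stability-calibrated network: {len(self.nodes)} nodes, "
            f"{len(self.edges)} stable edges\n"
            f"  penalty lambda* = {lam}; threshold pi* = {self.pi_star:.2f}; "
            f"score = {self.score:.2f}\n"
            f"  K = {self.K} subsamples of fraction {self.frac}"
        )


def _subsample_indices(n_units: int, K: int, frac: float, rng) -> list[np.ndarray]:
    size = max(int(np.ceil(frac * n_units)), 2)
    return [rng.choice(n_units, size=size, replace=False) for _ in range(K)]


def _safe_corr(X: np.ndarray) -> np.ndarray:
    S = np.corrcoef(X, rowvar=False)
    S = np.nan_to_num(S, nan=0.0)
    np.fill_diagonal(S, 1.0)
    return 0.5 * (S + S.T)


def default_lambda_grid(S: np.ndarray, n_lambda: int = 25, ratio: float = 0.01):
    """Log-spaced penalty grid from the empty-graph penalty downwards."""
    off = ~np.eye(S.shape[0], dtype=bool)
    lam_max = np.abs(S[off]).max()
    lam_max = max(lam_max, 1e-3)
    return np.geomspace(lam_max, ratio * lam_max, n_lambda)


def _stability_counts(
    X: np.ndarray,
    penalty_list: list[np.ndarray],
    K: int,
    frac: float,
    seed: int,
    participants=None,
    tol: float = 1e-5,
    max_iter: int = 100,
):
    """Selection counts per penalty configuration over K subsamples.

    The subsampling unit is the participant when ``participants`` (one id
    per row of X) is given, otherwise the row.  The same subsample stream
    serves every penalty configuration, so block-structured and scalar
    penalties are directly comparable.
    """
    n, p = X.shape
    rng = np.random.default_rng(seed)
    if participants is not None:
        participants = np.asarray(participants)
        units = list(dict.fromkeys(participants))
        unit_rows = [np.flatnonzero(participants == u) for u in units]
        draws = _subsample_indices(len(units), K, frac, rng)
        row_sets = [np.concatenate([unit_rows[i] for i in d]) for d in draws]
    else:
        row_sets = _subsample_indices(n, K, frac, rng)
    if min(len(r) for r in row_sets) < p:
        warnings.warn(
            "subsample size is below the number of variables; the subsample "
            "correlation is singular and a positive penalty is required",
            UserWarning,
        )
    counts = [np.zeros((p, p)) for _ in penalty_list]
    for rows in row_sets:
        S = _safe_corr(X[rows])
        for ci, Lam in enumerate(penalty_list):
            theta, edges = graphical_lasso(S, Lam, tol=tol, max_iter=max_iter)
            for j, k in edges:
                counts[ci][j, k] += 1
                counts[ci][k, j] += 1
    return counts


def _calibrate(counts_list, configs, pi_grid, K, p, pfer_threshold=None):
    """Arg-max of the stability score over penalty configurations and pi.

    ``pfer_threshold`` optionally restricts the search to (penalty, pi)
    whose Meinshausen-Buhlmann bound on the expected number of falsely
    selected edges, (q N)^2 / ((2 pi - 1) N), stays below the threshold.
    """
    iu = np.triu_indices(p, 1)
    best = (-np.inf, None, None, None)
    for counts, cfg in zip(counts_list, configs):
        c = counts[iu]
        q = c.sum() / (K * c.size)
        q_hat = q * c.size  # average number of edges selected per subsample
        for pi in pi_grid:
            if (
                pfer_threshold is not None
                and q_hat**2 / ((2 * pi - 1) * c.size) > pfer_threshold
            ):
                continue
            sc = stability_score(c, K, pi, q)
            if sc > best[0]:
                best = (sc, cfg, pi, counts)
    return best


def stability_select_network(
    X,
    lam_grid=None,
    pi_grid=None,
    K: int = 500,
    frac: float = 0.8,
    seed: int = 0,
    participants=None,
    node_names=None,
    tol: float = 1e-5,
    max_iter: int = 100,
    pfer_threshold: float | None = None,
) -> StabilityNetwork:
    """Stability-calibrated graphical-LASSO network for one variable block.

    ``X`` is samples x variables (profiles of one time point, denoised and
    per-feature standardized upstream).  For every penalty in ``lam_grid``
    the model is refitted on K subsamples; the penalty and
    selection-proportion threshold maximizing the stability score define
    the stable adjacency (selection proportion >= pi*).
    """
    X = _as_matrix(X)
    if node_names is None:
        node_names = [f"V{i}" for i in range(X.shape[1])]
    if K < 10:
        raise InvalidConfigError(
            "stability calibration needs many subsamples; use K >= 50"
        )
    p = X.shape[1]
    S_full = _safe_corr(X)
    if lam_grid is None:
        lam_grid = default_lambda_grid(S_full)
    lam_grid = np.asarray(lam_grid, dtype=float)
    if pi_grid is None:
        pi_grid = np.arange(0.51, 0.995, 0.01)
    penalty_list = [np.full((p, p), lam) for lam in lam_grid]
    counts = _stability_counts(
        X, penalty_list, K, frac, seed, participants, tol=tol, max_iter=max_iter
    )
    score, lam_star, pi_star, best_counts = _calibrate(
        counts, list(lam_grid), pi_grid, K, p, pfer_threshold
    )
    if lam_star is None:
        raise CrossomixError("calibration failed: all penalties degenerate")
    prop = best_counts / K
    np.fill_diagonal(prop, 0.0)
    adj = prop >= pi_star
    return StabilityNetwork(
        proportions=pd.DataFrame(prop, index=node_names, columns=node_names),
        lam_star=float(lam_star),
        pi_star=float(pi_star),
        score=float(score),
        adjacency=pd.DataFrame(adj, index=node_names, columns=node_names),
        K=K,
        frac=frac,
        lam_grid=lam_grid,
        counts={float(l): c for l, c in zip(lam_grid, counts)},
    )


def multiblock_stability_network(
    X,
    block_labels,
    lam_grids: dict | None = None,
    pi_grid=None,
    K: int = 100,
    frac: float = 0.8,
    seed: int = 0,
    participants=None,
    node_names=None,
    n_lambda: int = 5,
    tol: float = 1e-5,
    max_iter: int = 100,
) -> StabilityNetwork:
    """Two-block multiomic network with block-specific penalties.

    Three penalty groups are calibrated jointly — within block 1, within
    block 2, and cross-block — over the product of their grids and the
    threshold grid, using the same stability score summed over all variable
    pairs.  A block with fewer than 2 variables has no within-block pairs
    and its penalty group is dropped.
    """
    X = _as_matrix(X)
    p = X.shape[1]
    block_labels = pd.Series(np.asarray(block_labels), index=range(p))
    blocks = list(dict.fromkeys(block_labels))
    if len(blocks) != 2:
        raise InvalidConfigError("exactly two blocks are required")
    if node_names is None:
        node_names = [f"V{i}" for i in range(p)]
    if K < 10:
        raise InvalidConfigError(
            "stability calibration needs many subsamples; use K >= 50"
        )
    b0 = (block_labels == blocks[0]).to_numpy()
    masks = {
        "within_1": np.outer(b0, b0),
        "within_2": np.outer(~b0, ~b0),
        "cross": np.outer(b0, ~b0) | np.outer(~b0, b0),
    }
    group_sizes = {"within_1": int(b0.sum()), "within_2": int((~b0).sum())}
    active = [
        g
        for g in ("within_1", "within_2", "cross")
        if g == "cross" or group_sizes[g] >= 2
    ]
    S_full = _safe_corr(X)
    if lam_grids is None:
        lam_grids = {}
        for g in active:
            off = masks[g] & ~np.eye(p, dtype=bool)
            lam_max = max(np.abs(S_full[off]).max(), 1e-3)
            lam_grids[g] = np.geomspace(lam_max, 0.05 * lam_max, n_lambda)
    if pi_grid is None:
        pi_grid = np.arange(0.51, 0.995, 0.01)

    configs = list(product(*[list(np.asarray(lam_grids[g], dtype=float)) for g in active]))
    penalty_list = []
    for combo in configs:
        Lam = np.zeros((p, p))
        for g, lam in zip(active, combo):
            Lam[masks[g]] = lam
        penalty_list.append(Lam)
    counts = _stability_counts(
        X, penalty_list, K, frac, seed, participants, tol=tol, max_iter=max_iter
    )
    score, combo_star, pi_star, best_counts = _calibrate(
        counts, configs, pi_grid, K, p
    )
    if combo_star is None:
        raise CrossomixError("calibration failed: all penalty combinations degenerate")
    prop = best_counts / K
    np.fill_diagonal(prop, 0.0)
    adj = prop >= pi_star
    names_series = pd.Series(list(block_labels), index=node_names)
    return StabilityNetwork(
        proportions=pd.DataFrame(prop, index=node_names, columns=node_names),
        lam_star={g: float(l) for g, l in zip(active, combo_star)},
        pi_star=float(pi_star),
        score=float(score),
        adjacency=pd.DataFrame(adj, index=node_names, columns=node_names),
        K=K,
        frac=frac,
        lam_grid={g: np.asarray(lam_grids[g], dtype=float) for g in active},
        counts={tuple(c): cnt for c, cnt in zip(configs, counts)},
        blocks=names_series,
    )


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


# ---------------------------------------------------------------------------
# rewiring comparison across time points
# ---------------------------------------------------------------------------

#: presence pattern (pre, +2 h, +24 h) -> edge class
_EDGE_CLASSES = {
    (True, True, True): "stable",
    (True, False, False): "baseline_only",
    (False, True, False): "acute",
    (False, True, True): "persistent",
    (False, False, True): "lagged",
    (True, True, False): "resolving",
    (True, False, True): "reverting",
}


def compare_networks(net_pre, net_post2h, net_post24h) -> dict:
    """Classify edges by their presence across the three time points.

    Classes: ``stable`` (all three), ``baseline_only`` (pre only),
    ``acute`` (+2 h only), ``persistent`` (+2 h and +24 h), ``lagged``
    (+24 h only), ``resolving`` (pre and +2 h), ``reverting`` (pre and
    +24 h — the pre-exposure pattern returns after a transient loss).
    """
    adjs = [_adjacency_frame(n) for n in (net_pre, net_post2h, net_post24h)]
    nodes = list(adjs[0].index)
    for a in adjs[1:]:
        if list(a.index) != nodes:
            missing = sorted(set(nodes) ^ set(a.index))
            raise AlignmentError(f"node sets differ between networks: {missing}")
    classes: dict[str, list] = {c: [] for c in _EDGE_CLASSES.values()}
    arr = [a.to_numpy() for a in adjs]
    for j in range(len(nodes)):
        for k in range(j + 1, len(nodes)):
            pattern = tuple(bool(a[j, k]) for a in arr)
            if any(pattern):
                classes[_EDGE_CLASSES[pattern]].append((nodes[j], nodes[k]))
    counts = {c: len(v) for c, v in classes.items()}
    return {"edges": classes, "counts": counts}


def _adjacency_frame(net) -> pd.DataFrame:
    if isinstance(net, StabilityNetwork):
        return net.adjacency
    if isinstance(net, pd.DataFrame):
        return net
    raise InvalidConfigError("expected a StabilityNetwork or adjacency DataFrame")
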