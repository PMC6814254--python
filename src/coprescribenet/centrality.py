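"""Network-prominence metrics for co-prescription graphs.

The central measure is weighted PageRank on the patient–patient graph:

    PR(i) = (1 - d)/N + d * Σ_{j in M(i)} w_ij PR(j) / s_j

with damping d = 0.85, each undirected edge treated as two directed
edges, and s_j the strength (sum of incident weights) of node j.  Raw
scores are heavily right-skewed, so they are reported as average-rank
percentiles (and, as alternates, z-scores and log degree).  Bipartite
prominence uses the generalized Co-HITS coupled fixed point on the
patient–prescriber graph with all edge weights 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import rankdata

from .network import (
    BipartiteGraph,
    CoPrescriptionGraph,
    build_bipartite,
    project_patients,
)

__all__ = [
    "CentralityParams",
    "pagerank",
    "to_percentile",
    "standardize",
    "degree_metrics",
    "cohits",
    "centrality_table",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to reach tolerance within max_iter."""


@dataclass
class CentralityParams:
    """Tuning knobs for the prominence fixed points.

    d : damping factor of the random walk (probability of following an
        edge rather than teleporting); 0.85 throughout.
    tol : L1 change between successive iterates at which iteration stops.
    dangling : 'uniform' redistributes the walk mass of strength-0 nodes
        (isolates) uniformly so that Σ PR = 1; 'literal' applies the bare
        recursion, under which isolates score (1-d)/N and mass leaks.
    tie_method : rank assignment for tied percentile scores.
    cohits_lambda_* : damping on each side of the bipartite fixed point.
    """

    d: float = 0.85
    tol: float = 1e-10
    max_iter: int = 1000
    dangling: str = "uniform"
    tie_method: str = "average"
    cohits_lambda_patient: float = 0.85
    cohits_lambda_prescriber: float = 0.85

    def __post_init__(self):
        if not 0.0 < self.d < 1.0:
            raise ValueError(f"damping d must be in (0, 1), got {self.d}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.dangling not in ("uniform", "literal"):
            raise ValueError(f"unknown dangling policy {self.dangling!r}")


def pagerank(cg: CoPrescriptionGraph, params: CentralityParams | None = None) -> pd.Series:
    """Weighted PageRank of every patient, isolates included.

    Power iteration from the uniform vector on the column-stochastic
    transition matrix P[i, j] = w_ij / s_j, with teleportation (1-d)/N and
    uniform redistribution of dangling (isolate) mass.  Deterministic:
    stops when the L1 change drops below ``params.tol``.
    """
    params = params or CentralityParams()
    nodes = list(cg.graph.nodes())
    n = len(nodes)
    if n == 0:
        return pd.Series(dtype=float)
    if n == 1:
        return pd.Series([1.0], index=nodes)

    idx = {v: k for k, v in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for a, b, dat in cg.graph.edges(data=True):
        w = float(dat.get("weight", 1.0))
        ia, ib = idx[a], idx[b]
        rows.append(ia); cols.append(ib); vals.append(w)
        rows.append(ib); cols.append(ia); vals.append(w)
    W = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    s = np.asarray(W.sum(axis=0)).ravel()          # out-strength per column
    dangling = s == 0
    inv_s = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, s))
    P = W @ sparse.diags(inv_s)                    # column-stochastic on non-dangling

    d = params.d
    x = np.full(n, 1.0 / n)
    for _ in range(params.max_iter):
        flow = P @ x
        if params.dangling == "uniform":
            flow = flow + x[dangling].sum() / n
        x_new = (1.0 - d) / n + d * flow
        resid = np.abs(x_new - x).sum()
        x = x_new
        if resid < params.tol:
            break
    else:
        raise ConvergenceError(
            f"PageRank did not converge in {params.max_iter} iterations "
            f"(final L1 residual {resid:.3e})"
        )
    return pd.Series(x, index=nodes)


def to_percentile(scores, tie_method: str = "average") -> pd.Series:
    """Map scores to the 0–100 percentile scale, pct = 100 (rank - 0.5)/N.

    Ties share their mean rank under ``tie_method='average'`` (so the mean
    percentile is exactly 50); ``'min'`` is available as an alternate.
    """
    s = pd.Series(scores, dtype=float)
    if len(s) == 0:
        raise ValueError("cannot rank an empty score vector")
    ranks = rankdata(s.to_numpy(), method=tie_method)
    return pd.Series(100.0 * (ranks - 0.5) / len(s), index=s.index)


def standardize(scores, ddof: int = 0) -> pd.Series:
    """Z-score: (x - mean)/SD with population SD by default."""
    s = pd.Series(scores, dtype=float)
    if len(s) < 2:
        raise ValueError("standardization needs at least two scores")
    sd = s.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a zero-variance score vector")
    return (s - s.mean()) / sd


def degree_metrics(cg: CoPrescriptionGraph) -> pd.DataFrame:
    """Unweighted degree (distinct co-prescribed patients) and ln(degree + 1).

    The +1 offset keeps the log defined for the many isolate patients.
    """
    deg = dict(cg.graph.degree())
    nodes = list(cg.graph.nodes())
    d = np.array([deg[v] for v in nodes], dtype=float)
    return pd.DataFrame(
        {"degree": d.astype(int), "degree_log": np.log1p(d)}, index=nodes
    )


def cohits(
    bip: BipartiteGraph, params: CentralityParams | None = None
) -> tuple[pd.Series, pd.Series]:
    """Generalized Co-HITS scores on the bipartite graph, all weights 1.

    Coupled fixed point with per-side damping λ:

        x_p = (1-λ_p)/N_p + λ_p Σ_{d in N(p)} y_d / deg(d)
        y_d = (1-λ_d)/N_d + λ_d Σ_{p in N(d)} x_p / deg(p)

    A patient scores highly when tied, directly or indirectly, to
    prominent prescribers.  Isolated patients receive the teleport
    floor (1-λ_p)/N_p.
    """
    params = params or CentralityParams()
    patients = list(bip.patients)
    prescribers = list(bip.prescribers)
    np_, nd = len(patients), len(prescribers)
    if np_ == 0:
        return pd.Series(dtype=float), pd.Series(dtype=float)
    lam_p, lam_d = params.cohits_lambda_patient, params.cohits_lambda_prescriber

    pidx = {p: i for i, p in enumerate(patients)}
    didx = {d: i for i, d in enumerate(prescribers)}
    rows, cols = [], []
    for p, ds in bip.patient_adj.items():
        for d in ds:
            rows.append(pidx[p]); cols.append(didx[d])
    if nd:
        B = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(np_, nd)
        )
        deg_p = np.asarray(B.sum(axis=1)).ravel()
        deg_d = np.asarray(B.sum(axis=0)).ravel()
        Bd = B @ sparse.diags(1.0 / np.maximum(deg_d, 1.0))   # patient <- prescriber
        Bp = B.T @ sparse.diags(1.0 / np.maximum(deg_p, 1.0))  # prescriber <- patient
    else:
        x = np.full(np_, (1.0 - lam_p) / np_)
        return pd.Series(x, index=patients), pd.Series(dtype=float)

    x = np.full(np_, 1.0 / np_)
    y = np.full(nd, 1.0 / nd)
    for _ in range(params.max_iter):
        y_new = (1.0 - lam_d) / nd + lam_d * (Bp @ x)
        x_new = (1.0 - lam_p) / np_ + lam_p * (Bd @ y_new)
        resid = np.abs(x_new - x).sum() + np.abs(y_new - y).sum()
        x, y = x_new, y_new
        if resid < params.tol:
            break
    else:
        raise ConvergenceError(
            f"Co-HITS did not converge in {params.max_iter} iterations "
            f"(final L1 residual {resid:.3e})"
        )
    return pd.Series(x, index=patients), pd.Series(y, index=prescribers)


def centrality_table(
    rx_filtered: pd.DataFrame,
    panel_quarters,
    params: CentralityParams | None = None,
    width: int = 3,
    patients=None,
    min_quarter: int = 0,
    max_quarter: int | None = None,
) -> pd.DataFrame:
    """All prominence metrics for every patient in every panel quarter.

    For each focal quarter the pooled-window bipartite graph is built,
    projected, and scored; percentiles and z-scores are computed within
    quarter.  Columns: patient_id, quarter, pr_raw, pr_pct, pr_std,
    degree, degree_log, bip_pr_raw, bip_pr_pct.
    """
    params = params or CentralityParams()
    frames = []
    for q in panel_quarters:
        bip = build_bipartite(
            rx_filtered, q, width=width, patients=patients,
            min_quarter=min_quarter, max_quarter=max_quarter,
        )
        cg = project_patients(bip)
        pr = pagerank(cg, params)
        try:
            pr_std = standardize(pr)
        except ValueError:
            # degenerate quarter (all scores equal, e.g. no edges): the
            # z-score carries no information, report 0 for everyone
            pr_std = pd.Series(0.0, index=pr.index)
        degs = degree_metrics(cg)
        bip_pr, _ = cohits(bip, params)
        frame = pd.DataFrame(
            {
                "patient_id": pr.index,
                "quarter": q,
                "pr_raw": pr.to_numpy(),
                "pr_pct": to_percentile(pr, params.tie_method).to_numpy(),
                "pr_std": pr_std.to_numpy(),
                "degree": degs["degree"].reindex(pr.index).to_numpy(),
                "degree_log": degs["degree_log"].reindex(pr.index).to_numpy(),
                "bip_pr_raw": bip_pr.reindex(pr.index).to_numpy(),
            }
        )
        frame["bip_pr_pct"] = to_percentile(
            frame["bip_pr_raw"], params.tie_method
        ).to_numpy()
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
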