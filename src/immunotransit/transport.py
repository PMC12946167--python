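"""Optimal-transport mapping of cell populations between consecutive visits.

For a source and a target cell cloud the cost matrix holds pairwise
Euclidean distances in principal-component space,

    C_ij = || x_i - y_j ||_2,

and the transport plan solves the Earth Mover (Kantorovich) linear program

    min_{pi >= 0}  sum_ij pi_ij C_ij
    s.t.  sum_j pi_ij = a_i,   sum_i pi_ij = b_j,

with uniform marginals by default.  The plan is solved exactly: a sparse
HiGHS linear program in general, or - for large equal-size uniform problems,
where an optimal vertex is a scaled permutation (Birkhoff) - the Hungarian
assignment.  Summaries turn the coupling into per-cluster arrows in a 2-D
display embedding and row-normalized target-cluster fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment, linprog
from scipy.spatial.distance import cdist

from .datamodel import CohortDataset
from .errors import AnalysisError, ValidationError
from .preprocess import compute_pc_embedding, log_normalize

__all__ = [
    "CostMatrix",
    "TransportPlan",
    "TransitionSummary",
    "build_cost_matrix",
    "solve_emd",
    "map_cells",
    "summarize_transitions",
    "transition_pipeline",
]

logger = logging.getLogger(__name__)

_MARGINAL_TOL = 1e-8
#: above this size, equal-size uniform problems use the assignment fast path
_ASSIGNMENT_CUTOFF = 64


@dataclass
class CostMatrix:
    """Pairwise Euclidean distances between source and target cells."""

    c: np.ndarray
    source_ids: list[str] | None = None
    target_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if self.c.ndim != 2:
            raise ValidationError("cost matrix must be 2-D")
        if not np.isfinite(self.c).all() or (self.c < 0).any():
            raise ValidationError("cost matrix must be finite and non-negative")


def build_cost_matrix(
    embed_src: np.ndarray,
    embed_tgt: np.ndarray,
    source_ids: list[str] | None = None,
    target_ids: list[str] | None = None,
) -> CostMatrix:
    """Euclidean cost between two embeddings of equal dimension."""
    xs = np.atleast_2d(np.asarray(embed_src, dtype=float))
    yt = np.atleast_2d(np.asarray(embed_tgt, dtype=float))
    if xs.shape[1] != yt.shape[1]:
        raise AnalysisError(
            f"embedding dimension mismatch: {xs.shape[1]} vs {yt.shape[1]}"
        )
    return CostMatrix(c=cdist(xs, yt), source_ids=source_ids, target_ids=target_ids)


@dataclass
class TransportPlan:
    """Optimal coupling with its marginals and transported cost."""

    pi: np.ndarray
    a: np.ndarray
    b: np.ndarray
    cost: np.ndarray
    total_cost: float = field(init=False)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if (self.pi < -1e-12).any():
            raise ValidationError("negative transport mass")
        self.pi = np.clip(self.pi, 0.0, None)
        row_err = np.abs(self.pi.sum(axis=1) - self.a).max()
        col_err = np.abs(self.pi.sum(axis=0) - self.b).max()
        if max(row_err, col_err) > _MARGINAL_TOL:
            raise ValidationError(
                f"marginal violation: row {row_err:.2e}, col {col_err:.2e}"
            )
        self.total_cost = float(np.sum(self.pi * self.cost))


def _solve_lp(c: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n, m = c.shape
    # row-sum constraints, plus all but the last column constraint (redundant)
    rows, cols, data = [], [], []
    for i in range(n):
        rows.extend([i] * m)
        cols.extend(range(i * m, (i + 1) * m))
        data.extend([1.0] * m)
    for j in range(m - 1):
        rows.extend([n + j] * n)
        cols.extend(range(j, n * m, m))
        data.extend([1.0] * n)
    a_eq = sp.csr_matrix((data, (rows, cols)), shape=(n + m - 1, n * m))
    b_eq = np.concatenate([a, b[:-1]])
    res = linprog(c.ravel(), A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise AnalysisError(f"transport LP infeasible or failed: {res.message}")
    return res.x.reshape(n, m)


def solve_emd(
    cost: CostMatrix | np.ndarray,
    a: np.ndarray | None = None,
    b: np.ndarray | None = None,
) -> TransportPlan:
    """Exact Earth-Mover coupling between the marginals a and b (uniform by
    default) under the given cost."""
    c = cost.c if isinstance(cost, CostMatrix) else np.asarray(cost, dtype=float)
    n, m = c.shape
    a = np.full(n, 1.0 / n) if a is None else np.asarray(a, dtype=float)
    b = np.full(m, 1.0 / m) if b is None else np.asarray(b, dtype=float)
    if a.shape != (n,) or b.shape != (m,):
        raise AnalysisError("marginal lengths must match the cost matrix")
    if (a < 0).any() or (b < 0).any():
        raise AnalysisError("marginals must be non-negative")
    if abs(a.sum() - b.sum()) > 1e-9:
        raise AnalysisError(f"unbalanced masses: {a.sum():.6g} vs {b.sum():.6g}")
    uniform = (
        n == m
        and np.allclose(a, 1.0 / n, atol=1e-12)
        and np.allclose(b, 1.0 / n, atol=1e-12)
    )
    if uniform and n > _ASSIGNMENT_CUTOFF:
        # equal-size uniform EMD is an assignment LP; its optimum is a
        # permutation scaled by 1/n
        rows, cols = linear_sum_assignment(c)
        pi = np.zeros_like(c)
        pi[rows, cols] = 1.0 / n
    else:
        pi = _solve_lp(c, a, b)
    return TransportPlan(pi=pi, a=a, b=b, cost=c)


def map_cells(plan: TransportPlan) -> pd.DataFrame:
    """Assign each source cell to the target receiving its largest mass.

    Ties are broken by smaller cost, then smaller target index.  Returns a
    frame with columns target (index) and mass (the winning entry's mass).
    """
    pi, cost = plan.pi, plan.cost
    n, m = pi.shape
    targets = np.empty(n, dtype=int)
    masses = np.empty(n)
    for i in range(n):
        row = pi[i]
        top = row.max()
        if top <= 0:
            raise AnalysisError(f"source cell {i} has zero transported mass")
        cand = np.flatnonzero(row >= top - 1e-15)
        if cand.size > 1:
            cand = cand[cost[i, cand] == cost[i, cand].min()]
        targets[i] = cand[0]
        masses[i] = row[targets[i]]
    return pd.DataFrame({"target": targets, "mass": masses})


@dataclass
class TransitionSummary:
    """Arrow and fraction summaries of one transport plan in 2-D display space."""

    cell_arrows: pd.DataFrame  # x0, y0, x1, y1 per source cell
    cluster_arrows: pd.DataFrame  # cluster, x0, y0, x1, y1, mass
    aggregate_arrow: np.ndarray  # length-2 displacement vector
    target_fractions: pd.DataFrame  # source cluster x target cluster, rows sum to 1


def summarize_transitions(
    plan: TransportPlan,
    embed2d_src: np.ndarray,
    embed2d_tgt: np.ndarray,
    src_clusters: np.ndarray,
    tgt_clusters: np.ndarray,
) -> TransitionSummary:
    """Cluster-level arrows and target-cluster fractions from a solved plan.

    A cluster arrow runs from the mean 2-D coordinate of its source cells to
    the transport-mass-weighted mean of their targets' coordinates; its mass
    is the total transported mass.  The aggregate arrow is the mass-weighted
    sum of cluster displacements.  ``target_fractions[s, t]`` is the share of
    cluster s's mass landing in target cluster t.
    """
    src_xy = np.asarray(embed2d_src, dtype=float)
    tgt_xy = np.asarray(embed2d_tgt, dtype=float)
    src_clusters = np.asarray(src_clusters)
    tgt_clusters = np.asarray(tgt_clusters)
    if src_xy.shape[0] != plan.pi.shape[0] or tgt_xy.shape[0] != plan.pi.shape[1]:
        raise AnalysisError("embedding/cluster lengths must match the plan")
    mapped = map_cells(plan)
    cell_arrows = pd.DataFrame(
        {
            "x0": src_xy[:, 0],
            "y0": src_xy[:, 1],
            "x1": tgt_xy[mapped["target"], 0],
            "y1": tgt_xy[mapped["target"], 1],
        }
    )
    tgt_labels = sorted(pd.unique(tgt_clusters))
    rows, frac_rows = [], []
    for cluster in sorted(pd.unique(src_clusters)):
        sel = src_clusters == cluster
        if not sel.any():
            logger.warning("source cluster %s has no cells; omitted", cluster)
            continue
        sub = plan.pi[sel]
        mass = sub.sum()
        tail = src_xy[sel].mean(axis=0)
        head = (sub @ tgt_xy) .sum(axis=0) / mass
        rows.append(
            {"cluster": cluster, "x0": tail[0], "y0": tail[1],
             "x1": head[0], "y1": head[1], "mass": mass}
        )
        mass_to = {
            t: sub[:, tgt_clusters == t].sum() for t in tgt_labels
        }
        frac_rows.append(pd.Series(mass_to, name=cluster) / mass)
    cluster_arrows = pd.DataFrame(rows)
    vec = cluster_arrows[["x1", "y1"]].to_numpy() - cluster_arrows[["x0", "y0"]].to_numpy()
    aggregate = (vec * cluster_arrows["mass"].to_numpy()[:, None]).sum(axis=0)
    fractions = pd.DataFrame(frac_rows)
    fractions.index.name = "source_cluster"
    return TransitionSummary(
        cell_arrows=cell_arrows,
        cluster_arrows=cluster_arrows,
        aggregate_arrow=aggregate,
        target_fractions=fractions,
    )


def transition_pipeline(
    dataset: CohortDataset,
    cell_type: str,
    tp_pairs: list[tuple[str, str]],
    cohorts: list[str] | None = None,
    n_pc: int = 75,
    seed: int = 0,
    max_cells_per_side: int | None = None,
) -> dict[str, dict[tuple[str, str], TransitionSummary]]:
    """Per-cohort transition summaries for each consecutive visit pair.

    For every cohort and (source, target) visit pair, the cell subset is
    down-sampled to a common per-side size (the smallest cohort-visit stratum,
    optionally capped), principal components are computed on the pooled pair
    so both clouds share one space, the exact transport plan is solved with
    uniform marginals, and arrows/fractions are summarized in the dataset's
    2-D display embedding.  Fully reproducible from ``seed``.
    """
    meta = dataset.cell_meta
    if not dataset.has_embedding:
        raise AnalysisError("dataset lacks a 2-D display embedding (embed_x/embed_y)")
    if cohorts is None:
        cohorts = sorted(meta["survival_group"].unique())
    timepoints = sorted({tp for pair in tp_pairs for tp in pair})
    sizes = []
    for cohort in cohorts:
        for tp in timepoints:
            n = int(((meta["survival_group"] == cohort) & (meta["timepoint"] == tp)
                     & (meta["cell_type"] == cell_type)).sum())
            if n:
                sizes.append(n)
    if not sizes:
        raise AnalysisError(f"no {cell_type!r} cells at the requested visits")
    n_side = min(sizes)
    if max_cells_per_side is not None:
        n_side = min(n_side, max_cells_per_side)
    lognorm = log_normalize(dataset)
    results: dict[str, dict[tuple[str, str], TransitionSummary]] = {}
    rng = np.random.default_rng(seed)
    for cohort in cohorts:
        results[cohort] = {}
        for tp_a, tp_b in tp_pairs:
            masks = []
            missing = False
            for tp in (tp_a, tp_b):
                sel = np.flatnonzero(
                    ((meta["survival_group"] == cohort) & (meta["timepoint"] == tp)
                     & (meta["cell_type"] == cell_type)).to_numpy()
                )
                if sel.size < 2:
                    logger.warning("cohort %s: visit %s missing; pair skipped", cohort, tp)
                    missing = True
                    break
                masks.append(np.sort(rng.choice(sel, size=min(n_side, sel.size), replace=False)))
            if missing:
                continue
            src_idx, tgt_idx = masks
            pooled = np.concatenate([src_idx, tgt_idx])
            block = lognorm[:, pooled]
            k = min(n_pc, block.shape[1] - 1, block.shape[0] - 1)
            if k < n_pc:
                logger.warning("reducing n_pc from %d to %d (small pooled pair)", n_pc, k)
            emb = compute_pc_embedding(block, n_components=k)
            n_src = src_idx.size
            plan = solve_emd(build_cost_matrix(emb.coords[:n_src], emb.coords[n_src:]))
            results[cohort][(tp_a, tp_b)] = summarize_transitions(
                plan,
                meta.loc[src_idx, ["embed_x", "embed_y"]].to_numpy(),
                meta.loc[tgt_idx, ["embed_x", "embed_y"]].to_numpy(),
                meta.loc[src_idx, "subcluster"].to_numpy(),
                meta.loc[tgt_idx, "subcluster"].to_numpy(),
            )
    return results
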