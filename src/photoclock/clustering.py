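"""Clustering of multi-condition diurnal expression profiles.

Genes putatively regulated by PIFs share condition-specific transcript
dynamics across photoperiods and clock-mutant conditions.  Profiles are
z-scored per condition, concatenated, compared by Pearson correlation, and
clustered by affinity propagation (exemplar-based message passing).  Cluster
membership is then tested for overlap enrichment against reference gene sets
(e.g. PIF-bound genes) with a hypergeometric upper tail.

Affinity propagation is implemented here directly (vectorised responsibility/
availability updates with damping, deterministic, lowest-index tie-break, and
last-iterate labels on non-convergence); scikit-learn's implementation is used
as an independent cross-check in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

_EPS_SD = 1e-12


@dataclass
class ExpressionMatrix:
    """genes x (condition, timepoint) relative-expression table.

    ``values`` has one row per gene; columns are the concatenation of each
    condition's timepoint series, described by ``conditions`` and
    ``timepoints`` (one array of ZT values per condition, same order).
    """

    genes: list[str]
    conditions: list[str]
    timepoints: dict[str, np.ndarray]
    values: np.ndarray
    standardised: bool = False

    def __post_init__(self) -> None:
        n_cols = sum(len(self.timepoints[c]) for c in self.conditions)
        if self.values.shape != (len(self.genes), n_cols):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.genes)} genes x {n_cols} (condition, timepoint) columns")

    def condition_slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for c in self.conditions:
            n = len(self.timepoints[c])
            out[c] = slice(start, start + n)
            start += n
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy (gene, condition, zt, value) frame."""
        rows = []
        for c, sl in self.condition_slices().items():
            zt = self.timepoints[c]
            block = self.values[:, sl]
            for j, g in enumerate(self.genes):
                rows.append(pd.DataFrame(
                    {"gene": g, "condition": c, "zt": zt, "value": block[j]}))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        genes = list(pd.unique(df["gene"]))
        conditions = list(pd.unique(df["condition"]))
        timepoints = {}
        blocks = []
        for c in conditions:
            sub = df[df["condition"] == c]
            zt = np.array(sorted(pd.unique(sub["zt"])), dtype=float)
            timepoints[c] = zt
            pivot = sub.pivot_table(index="gene", columns="zt", values="value")
            pivot = pivot.reindex(index=genes, columns=zt)
            if pivot.isna().any().any():
                raise ValueError(f"condition {c!r} is not rectangular")
            blocks.append(pivot.to_numpy())
        return cls(genes, conditions, timepoints, np.hstack(blocks))


def preprocess(m: ExpressionMatrix, eps: float = 1e-9) -> ExpressionMatrix:
    """Standardise each gene's series to mean 0 / variance 1 per condition.

    Genes with a near-constant series (sd < eps) in any condition are dropped
    (and logged): their shape carries no usable information.  Idempotent on
    the retained genes.
    """
    for c in m.conditions:
        if len(m.timepoints[c]) < 2:
            raise ValueError(f"condition {c!r} has < 2 timepoints")
    slices = m.condition_slices()
    keep = np.ones(len(m.genes), dtype=bool)
    for c, sl in slices.items():
        sd = m.values[:, sl].std(axis=1)
        keep &= sd >= eps
    dropped = [g for g, k in zip(m.genes, keep) if not k]
    if dropped:
        logger.info("preprocess: dropped %d near-constant gene(s): %s",
                    len(dropped), dropped[:10])
    if not np.any(keep):
        raise ValueError("all genes dropped as near-constant")
    vals = m.values[keep].copy()
    for c, sl in slices.items():
        block = vals[:, sl]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, keepdims=True)
        vals[:, sl] = (block - mu) / sd
    return ExpressionMatrix(
        [g for g, k in zip(m.genes, keep) if k],
        list(m.conditions), dict(m.timepoints), vals, standardised=True)


def similarity(m: ExpressionMatrix) -> np.ndarray:
    """Pearson correlation of concatenated per-condition z-scored profiles."""
    if not m.standardised:
        m = preprocess(m)
    v = m.values
    vc = v - v.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(vc, axis=1, keepdims=True)
    s = (vc / norm) @ (vc / norm).T
    np.fill_diagonal(s, 1.0)
    return np.clip(s, -1.0, 1.0)


@dataclass
class ClusterResult:
    labels: np.ndarray          # gene index -> cluster id (exemplar index)
    exemplars: np.ndarray       # cluster exemplar indices
    genes: list[str]
    converged: bool
    n_iter: int
    coherence: dict[int, float] = field(default_factory=dict)
    sizes: dict[int, int] = field(default_factory=dict)

    def members(self, cluster_id: int) -> list[str]:
        return [g for g, l in zip(self.genes, self.labels) if l == cluster_id]


def _coherence(S: np.ndarray, labels: np.ndarray) -> tuple[dict, dict]:
    coher, sizes = {}, {}
    for cid in np.unique(labels):
        idx = np.where(labels == cid)[0]
        sizes[int(cid)] = len(idx)
        if len(idx) == 1:
            coher[int(cid)] = 1.0
        else:
            sub = S[np.ix_(idx, idx)]
            off = sub[~np.eye(len(idx), dtype=bool)]
            coher[int(cid)] = float(off.mean())
    return coher, sizes


def affinity_propagation(
    S: np.ndarray,
    genes: list[str] | None = None,
    preference: float | None = None,
    damping: float = 0.9,
    max_iter: int = 500,
    convergence_iter: int = 15,
) -> ClusterResult:
    """Frey-Dueck affinity propagation on a precomputed similarity matrix.

    Deterministic: no noise is injected; argmax ties resolve to the lowest
    index.  ``preference`` defaults to the median off-diagonal similarity.
    On non-convergence the last labels are returned with ``converged=False``.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if S.shape != (n, n) or not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be a symmetric square matrix")
    if not 0.5 <= damping < 1.0:
        raise ValueError("damping must lie in [0.5, 1)")
    genes = genes if genes is not None else [str(i) for i in range(n)]

    S = S.copy()
    if preference is None:
        off = S[~np.eye(n, dtype=bool)]
        preference = float(np.median(off)) if off.size else 0.0
    np.fill_diagonal(S, preference)

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    last_exemplars: np.ndarray | None = None
    stable = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # responsibilities
        AS = A + S
        first = AS.argmax(axis=1)
        first_val = AS[idx, first]
        AS[idx, first] = -np.inf
        second_val = AS.max(axis=1)
        AS[idx, first] = first_val
        Rnew = S - first_val[:, None]
        Rnew[idx, first] = S[idx, first] - second_val
        R = damping * R + (1 - damping) * Rnew
        # availabilities
        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, R.diagonal())
        col = Rp.sum(axis=0)
        Anew = col[None, :] - Rp
        dA = Anew.diagonal().copy()
        Anew = np.minimum(Anew, 0.0)
        np.fill_diagonal(Anew, dA)
        A = damping * A + (1 - damping) * Anew

        exemplars = np.where((A + R).diagonal() > 0)[0]
        if last_exemplars is not None and np.array_equal(exemplars, last_exemplars):
            stable += 1
            if stable >= convergence_iter and len(exemplars) > 0:
                converged = True
                break
        else:
            stable = 0
        last_exemplars = exemplars

    exemplars = np.where((A + R).diagonal() > 0)[0]
    if len(exemplars) == 0:  # degenerate; fall back to best net self-affinity
        exemplars = np.array([int((A + R).diagonal().argmax())])
    labels = exemplars[S[:, exemplars].argmax(axis=1)]
    labels[exemplars] = exemplars
    coher, sizes = _coherence(S, labels)
    return ClusterResult(labels=labels, exemplars=exemplars, genes=list(genes),
                         converged=converged, n_iter=it,
                         coherence=coher, sizes=sizes)


def filter_coherent(c: ClusterResult, S: np.ndarray,
                    min_size: int = 20, min_coherence: float = 0.6) -> ClusterResult:
    """Drop clusters failing the size or mean within-similarity thresholds.

    Genes of removed clusters get label -1; an empty result is legal.
    """
    keep = [cid for cid in c.sizes
            if c.sizes[cid] >= min_size and c.coherence[cid] >= min_coherence]
    labels = np.where(np.isin(c.labels, keep), c.labels, -1)
    exemplars = np.array([e for e in c.exemplars if e in keep], dtype=int)
    coher = {k: c.coherence[k] for k in keep}
    sizes = {k: c.sizes[k] for k in keep}
    return ClusterResult(labels=labels, exemplars=exemplars, genes=c.genes,
                         converged=c.converged, n_iter=c.n_iter,
                         coherence=coher, sizes=sizes)


def overlap_enrichment(cluster_genes, reference_genes, universe) -> float:
    """Hypergeometric upper-tail P(overlap >= observed).

    ``universe`` is the background set (e.g. all PIF-induced genes); both
    gene sets must be subsets of it.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    cluster = set(cluster_genes)
    reference = set(reference_genes)
    if not cluster <= universe or not reference <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    M, n, N = len(universe), len(reference), len(cluster)
    k = len(cluster & reference)
    return float(hypergeom.sf(k - 1, M, n, N))
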