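"""Hierarchical clustering of speakers, model selection, and downstream tests.

Speakers are clustered on their energy-distance matrix with agglomerative
hierarchical clustering (Ward's minimum-variance method by default, complete
linkage as the alternative).  The number of clusters is chosen by minimizing
the C-index, C = (S_w - S_min) / (S_max - S_min), where S_w is the sum of
within-cluster pairwise distances, N_w their count, and S_min / S_max the sums
of the N_w smallest / largest distances overall; lower is better.  Cluster vs
cohort-group independence is tested with an exact r x c Fisher test (full
enumeration of tables with the observed margins, Monte-Carlo fallback for
large tables).  A PCA on the subject-level dissimilarity features provides the
complementary low-dimensional view with per-pair loadings, and the allocation
score counts each speaker as correct iff its group matches its cluster's
majority group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.special import gammaln

from .errors import ConfigurationError

logger = logging.getLogger(__name__)


def hclust(D: np.ndarray, linkage: str = "ward") -> np.ndarray:
    """Agglomerative merge tree (scipy linkage matrix) from a distance matrix."""
    if linkage not in ("ward", "complete"):
        raise ConfigurationError(f"unsupported linkage {linkage!r}")
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ConfigurationError("distance matrix must be square")
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ConfigurationError("distance matrix must be symmetric with zero diagonal")
    return hierarchy.linkage(squareform(D, checks=False), method=linkage)


def labels_for_k(Z: np.ndarray, k: int) -> np.ndarray:
    """Cut the merge tree into k clusters; labels in 1..k."""
    n = Z.shape[0] + 1
    if not (1 <= k <= n):
        raise ConfigurationError(f"k={k} outside [1, {n}]")
    return hierarchy.fcluster(Z, t=k, criterion="maxclust")


def cindex(D: np.ndarray, labels: np.ndarray) -> float:
    """Hubert-Levin C-index of a partition; in [0, 1], lower is better."""
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    n = D.shape[0]
    if labels.size != n:
        raise ConfigurationError("labels must match the distance matrix size")
    if np.unique(labels).size < 2:
        raise ConfigurationError("C-index needs at least 2 nonempty clusters")
    iu = np.triu_indices(n, k=1)
    d_all = D[iu]
    within = labels[iu[0]] == labels[iu[1]]
    n_w = int(within.sum())
    if n_w == 0:
        return 0.0
    s_w = float(d_all[within].sum())
    d_sorted = np.sort(d_all)
    s_min = float(d_sorted[:n_w].sum())
    s_max = float(d_sorted[-n_w:].sum())
    if s_max - s_min <= 0:
        logger.info("all pairwise distances equal; C-index defined as 0")
        return 0.0
    return (s_w - s_min) / (s_max - s_min)


def select_k(
    D: np.ndarray, k_range: tuple[int, int] = (2, 6), linkage: str = "ward"
) -> tuple[int, dict[int, float], bool]:
    """Choose the cluster count minimizing the C-index (ties: smallest k).

    Returns (k*, {k: C-index}, weak_structure_flag); the flag is set when the
    C-index spread over the range is below 0.05, indicating little evidence
    for any particular k.
    """
    n = D.shape[0]
    lo, hi = int(k_range[0]), int(k_range[1])
    lo = max(lo, 2)
    hi = min(hi, n - 1)
    if hi < lo:
        raise ConfigurationError(f"empty k range after clamping to [2, {n - 1}]")
    Z = hclust(D, linkage)
    curve = {k: cindex(D, labels_for_k(Z, k)) for k in range(lo, hi + 1)}
    k_star = min(curve, key=lambda k: (curve[k], k))
    vals = np.array(list(curve.values()))
    weak = bool(vals.max() - vals.min() < 0.05)
    if weak:
        logger.warning("weak cluster structure: C-index spread %.3f < 0.05",
                       vals.max() - vals.min())
    return k_star, curve, weak


def _log_table_prob(table: np.ndarray, log_fact_margins: float, log_fact_n: float) -> float:
    return log_fact_margins - log_fact_n - gammaln(table + 1.0).sum()


def _enumerate_tables(row_margins, col_margins):
    """Yield all nonnegative integer tables with the given margins."""
    r = len(row_margins)

    def rec(i, remaining_cols, acc):
        if i == r - 1:
            last = np.asarray(remaining_cols)
            if (last >= 0).all() and last.sum() == row_margins[-1]:
                yield acc + [last.tolist()]
            return
        target = row_margins[i]

        def comps(j, left, row):
            if j == len(remaining_cols) - 1:
                if 0 <= left <= remaining_cols[j]:
                    yield row + [left]
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                yield from comps(j + 1, left - v, row + [v])

        for row in comps(0, target, []):
            rem = [c - v for c, v in zip(remaining_cols, row)]
            yield from rec(i + 1, rem, acc + [row])

    yield from rec(0, list(col_margins), [])


def fisher_exact_rxc(
    table: np.ndarray,
    max_n: int = 200,
    n_mc: int = 200_000,
    seed: int = 0,
) -> float:
    """Exact Fisher test of independence for an r x c contingency table.

    Enumerates all tables with the observed margins and sums the hypergeometric
    probabilities of tables no more probable than the observed one (with a
    1e-7 relative slack against float ties).  Zero-margin rows/columns are
    dropped with a log message.  For totals above ``max_n`` a seeded
    Monte-Carlo estimate over ``n_mc`` margin-preserving random tables is
    returned instead.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or (t < 0).any():
        raise ConfigurationError("table must be a nonnegative integer matrix")
    rm = t.sum(axis=1)
    cm = t.sum(axis=0)
    if (rm == 0).any() or (cm == 0).any():
        logger.info("dropping zero-margin rows/columns from the contingency table")
        t = t[rm > 0][:, cm > 0]
        rm = t.sum(axis=1)
        cm = t.sum(axis=0)
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 1.0
    n = int(t.sum())
    log_fact_margins = float(gammaln(rm + 1.0).sum() + gammaln(cm + 1.0).sum())
    log_fact_n = float(gammaln(n + 1.0))
    logp_obs = _log_table_prob(t, log_fact_margins, log_fact_n)
    cutoff = logp_obs + math.log1p(1e-7)

    if n <= max_n:
        p = 0.0
        for tab in _enumerate_tables(rm.tolist(), cm.tolist()):
            lp = _log_table_prob(np.asarray(tab, dtype=float), log_fact_margins, log_fact_n)
            if lp <= cutoff:
                p += math.exp(lp)
        return float(min(p, 1.0))

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_mc):
        samp = _random_table(rm, cm, rng)
        if _log_table_prob(samp, log_fact_margins, log_fact_n) <= cutoff:
            count += 1
    return float((1 + count) / (1 + n_mc))


def _random_table(rm: np.ndarray, cm: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample a table uniformly from the hypergeometric distribution with the
    given margins (sequential conditional sampling)."""
    r, c = len(rm), len(cm)
    out = np.zeros((r, c), dtype=np.int64)
    col_left = cm.astype(np.int64).copy()
    for i in range(r):
        left = int(rm[i])
        total_left = int(col_left.sum())
        for j in range(c - 1):
            if left == 0:
                break
            x = rng.hypergeometric(int(col_left[j]), total_left - int(col_left[j]), left)
            out[i, j] = x
            left -= x
            total_left -= int(col_left[j])
            col_left[j] -= x
        out[i, c - 1] = left
        col_left[c - 1] -= left
    return out


@dataclass
class PcaResult:
    """PCA of the subject-level dissimilarity features."""

    scores: np.ndarray  # (n_subjects, n_components)
    components: np.ndarray  # (n_components, n_features), unit rows
    explained_ratio: np.ndarray
    loadings: np.ndarray  # components scaled by sd captured: V * s / sqrt(n-1)
    feature_names: list[str]
    dropped_features: list[str] = field(default_factory=list)


def pca_dissim(S: pd.DataFrame, scale: bool = False) -> PcaResult:
    """Column-centered (optionally standardized) PCA via SVD.

    The 15 pair features share units (pixel width x sqrt(frames)), so the
    default is unscaled; with ``scale=True`` constant columns are dropped
    with a log message.
    """
    if len(S) < 3:
        raise ConfigurationError("PCA needs at least 3 subjects")
    X = S.to_numpy(dtype=float)
    names = list(S.columns)
    dropped: list[str] = []
    Xc = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            dropped = [n for n, k in zip(names, keep) if not k]
            logger.info("dropping constant features before scaling: %s", dropped)
        Xc = Xc[:, keep] / sd[keep]
        names = [n for n, k in zip(names, keep) if k]
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    nm1 = max(len(S) - 1, 1)
    return PcaResult(
        scores=u * s,
        components=vt,
        explained_ratio=ratio,
        loadings=(vt.T * (s / math.sqrt(nm1))).T,
        feature_names=names,
        dropped_features=dropped,
    )


@dataclass
class AllocationResult:
    """Per-subject allocation against each cluster's majority group."""

    correct: np.ndarray  # bool per subject; ambiguous subjects False
    ambiguous: np.ndarray  # bool per subject (tied cluster majority)
    fraction: float  # correct / (total - ambiguous)
    majority: dict[int, str]  # cluster -> predominant group ('' when tied)


def allocation_accuracy(labels: np.ndarray, groups: list[str]) -> AllocationResult:
    """Score speakers as correctly allocated iff their group matches their
    cluster's predominant group; ties flag the cluster's members ambiguous and
    exclude them from the denominator."""
    labels = np.asarray(labels)
    groups_arr = np.asarray(groups)
    if labels.size != groups_arr.size:
        raise ConfigurationError("labels and groups must align")
    majority: dict[int, str] = {}
    ambiguous = np.zeros(labels.size, dtype=bool)
    for lab in np.unique(labels):
        members = groups_arr[labels == lab]
        vals, counts = np.unique(members, return_counts=True)
        top = counts.max()
        winners = vals[counts == top]
        if winners.size > 1:
            majority[int(lab)] = ""
            ambiguous[labels == lab] = True
            logger.info("cluster %s has tied group majority; members flagged ambiguous", lab)
        else:
            majority[int(lab)] = str(winners[0])
    correct = np.array(
        [
            (not ambiguous[i]) and groups_arr[i] == majority[int(labels[i])]
            for i in range(labels.size)
        ]
    )
    denom = int((~ambiguous).sum())
    fraction = float(correct.sum() / denom) if denom else float("nan")
    return AllocationResult(correct=correct, ambiguous=ambiguous, fraction=fraction,
                            majority=majority)


@dataclass
class ClusterResult:
    """Full clustering report for one cohort."""

    distance_matrix: np.ndarray
    subjects: list
    groups: list[str]
    linkage: str
    merge_tree: np.ndarray
    cindex_curve: dict[int, float]
    k: int
    labels: np.ndarray
    weak_structure: bool
    contingency: pd.DataFrame
    fisher_p: float
    allocation: AllocationResult

    def report(self) -> dict:
        """JSON-serializable summary."""
        return {
            "linkage": self.linkage,
            "k": int(self.k),
            "cindex": {str(k): v for k, v in self.cindex_curve.items()},
            "weak_structure": self.weak_structure,
            "labels": {str(s): int(l) for s, l in zip(self.subjects, self.labels)},
            "contingency": {
                str(idx): {str(c): int(v) for c, v in row.items()}
                for idx, row in self.contingency.to_dict(orient="index").items()
            },
            "fisher_p": self.fisher_p,
            "allocation_fraction": self.allocation.fraction,
            "cluster_majority": {str(k): v for k, v in self.allocation.majority.items()},
        }


def cluster_speakers(
    D: np.ndarray,
    subjects: list,
    groups: list[str],
    linkage: str = "ward",
    k_range: tuple[int, int] = (2, 6),
    fisher_seed: int = 0,
) -> ClusterResult:
    """Run the clustering chain on a precomputed subject distance matrix."""
    Z = hclust(D, linkage)
    k_star, curve, weak = select_k(D, k_range, linkage)
    labels = labels_for_k(Z, k_star)
    cont = pd.crosstab(pd.Series(labels, name="cluster"), pd.Series(groups, name="group"))
    p = fisher_exact_rxc(cont.to_numpy(), seed=fisher_seed)
    alloc = allocation_accuracy(labels, groups)
    return ClusterResult(
        distance_matrix=D,
        subjects=subjects,
        groups=list(groups),
        linkage=linkage,
        merge_tree=Z,
        cindex_curve=curve,
        k=k_star,
        labels=labels,
        weak_structure=weak,
        contingency=cont,
        fisher_p=p,
        allocation=alloc,
    )


def dendrogram_newick(Z: np.ndarray, leaf_names: list) -> str:
    """Newick export of the merge tree with merge heights as branch lengths."""
    n = Z.shape[0] + 1
    nodes: dict[int, tuple[str, float]] = {i: (str(leaf_names[i]), 0.0) for i in range(n)}
    for i, (a, b, h, _) in enumerate(Z):
        la, ha = nodes.pop(int(a))
        lb, hb = nodes.pop(int(b))
        nodes[n + i] = (f"({la}:{h - ha:.6g},{lb}:{h - hb:.6g})", float(h))
    (label, _), = nodes.values()
    return label + ";"
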