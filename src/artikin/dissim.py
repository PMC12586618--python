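"""Spatiotemporal dissimilarities between articulator trajectories.

The dissimilarity between two time-normalized gap-width curves f and g is the
L2 metric sqrt(integral (f-g)^2 dt), the integral approximated by Simpson's
rule on the common median-frame grid (dt = 1 frame by default; any absolute
time scale cancels from all label-level results downstream).  Per repetition
this yields the 15 unordered site-pair dissimilarities; averaged per subject
they form the feature table on which speakers are compared.  Between-speaker
distances are energy distances between the repetition-level 15-vectors
(mode="repetition"), or twice the Euclidean distance between subject means
(mode="mean", the degenerate single-point reduction).
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigurationError
from .grid import SITE_ORDER
from .prep import TrajectorySet

logger = logging.getLogger(__name__)

#: The 15 unordered site pairs, in canonical site order.
SITE_PAIRS: tuple[tuple[str, str], ...] = tuple(itertools.combinations(SITE_ORDER, 2))


def pair_label(a: str, b: str) -> str:
    return f"{a}:{b}"


def _simpson_odd(y: np.ndarray, dt: float) -> float:
    """Composite Simpson integral for an odd number of equally spaced points."""
    return float(dt / 3.0 * (y[0] + y[-1] + 4.0 * y[1:-1:2].sum() + 2.0 * y[2:-2:2].sum()))


def simpson_integral(y: np.ndarray, dt: float) -> float:
    """Simpson's rule; even point counts use Simpson on the first n-1 points
    plus a trapezoid on the last interval."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ConfigurationError("Simpson's rule needs at least 3 points")
    if n % 2 == 1:
        return _simpson_odd(y, dt)
    return _simpson_odd(y[:-1], dt) + float(dt * 0.5 * (y[-2] + y[-1]))


def simpson_l2(f: np.ndarray, g: np.ndarray, dt: float = 1.0) -> float:
    """L2 distance between two sampled curves via Simpson's rule."""
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != g.shape or f.ndim != 1:
        raise ConfigurationError(f"curve length mismatch: {f.shape} vs {g.shape}")
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    return float(np.sqrt(max(simpson_integral((f - g) ** 2, dt), 0.0)))


def pair_dissim(ts: TrajectorySet, dt: float = 1.0) -> pd.DataFrame:
    """All 15 pairwise site dissimilarities per (subject, repetition).

    Returns a table indexed by (subject, group, repetition) with one column
    per site pair.  Trials missing any of the six sites are skipped with a
    log entry (also recorded in ``result.attrs['excluded']``).
    """
    wide = ts.data.pivot_table(
        index=["subject", "group", "repetition", "site"], columns="frame", values="width_px"
    )
    rows = {}
    excluded = []
    for (subj, grp, rep), sub in wide.groupby(level=["subject", "group", "repetition"]):
        present = set(sub.index.get_level_values("site"))
        if not set(SITE_ORDER) <= present:
            missing = sorted(set(SITE_ORDER) - present)
            excluded.append((subj, rep, f"missing sites {missing}"))
            logger.warning("trial (%s, rep %s) skipped: missing sites %s", subj, rep, missing)
            continue
        curves = {s: sub.xs(s, level="site").to_numpy().ravel() for s in SITE_ORDER}
        rows[(subj, grp, rep)] = {
            pair_label(a, b): simpson_l2(curves[a], curves[b], dt) for a, b in SITE_PAIRS
        }
    if not rows:
        raise ConfigurationError("no complete trials for pairwise dissimilarities")
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index = pd.MultiIndex.from_tuples(out.index, names=["subject", "group", "repetition"])
    out = out[[pair_label(a, b) for a, b in SITE_PAIRS]].sort_index()
    out.attrs["excluded"] = excluded
    return out


def subject_average(tab: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of the pair dissimilarities over each subject's repetitions."""
    return tab.groupby(level=["subject", "group"], sort=True).mean()


def energy_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Energy distance between two empirical distributions of vectors.

    ``E = 2 mean||a - b|| - mean||a - a'|| - mean||b - b'||`` with Euclidean
    norms and full n^2 averaging over ordered pairs (self-pairs contribute 0
    to the within terms).  Nonnegative; 0 iff the empirical distributions
    coincide.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ConfigurationError(
            f"vector dimension mismatch: {a.shape[1]} vs {b.shape[1]}"
        )
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ConfigurationError("energy distance needs nonempty sets")
    e_ab = cdist(a, b).mean()
    e_aa = cdist(a, a).mean()
    e_bb = cdist(b, b).mean()
    return float(max(2.0 * e_ab - e_aa - e_bb, 0.0))


def subject_distance_matrix(
    tab: pd.DataFrame, mode: str = "repetition"
) -> tuple[np.ndarray, list, list]:
    """Energy-distance matrix between subjects from the pair-dissimilarity table.

    mode="repetition" (default): each subject is the empirical distribution of
    its repetition-level 15-vectors.  mode="mean": twice the Euclidean distance
    between subject mean vectors (the energy distance between the degenerate
    single-point distributions).

    Returns (distance matrix, subject labels, group labels).
    """
    if mode not in ("repetition", "mean"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    groups_by_subject: dict = {}
    vectors: dict = {}
    for (subj, grp), sub in tab.groupby(level=["subject", "group"], sort=True):
        arr = sub.to_numpy()
        if arr.shape[0] == 0:
            logger.warning("subject %s excluded: no repetitions", subj)
            continue
        vectors[subj] = arr
        groups_by_subject[subj] = grp
    subjects = list(vectors)
    n = len(subjects)
    if n < 2:
        raise ConfigurationError("need at least 2 subjects for a distance matrix")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if mode == "repetition":
                d = energy_distance(vectors[subjects[i]], vectors[subjects[j]])
            else:
                mi = vectors[subjects[i]].mean(axis=0)
                mj = vectors[subjects[j]].mean(axis=0)
                d = 2.0 * float(np.linalg.norm(mi - mj))
            D[i, j] = D[j, i] = d
    return D, subjects, [groups_by_subject[s] for s in subjects]


def ttr_only_features(ts: TrajectorySet, dt: float = 1.0) -> pd.DataFrame:
    """Per-repetition scalar feature: the integral size of the TTR profile.

    Defined as the L2 dissimilarity (Simpson's rule) between the TTR curve and
    a hypothetical gap staying closed (zero curve) throughout the utterance;
    the same energy-distance / clustering chain applies downstream.
    """
    sub = ts.data[ts.data["site"] == "TTR"]
    if sub.empty:
        raise ConfigurationError("no TTR trajectories present")
    zero = np.zeros(ts.t_star)
    rows = {}
    for (subj, grp, rep), s in sub.groupby(["subject", "group", "repetition"], sort=True):
        y = s.sort_values("frame")["width_px"].to_numpy()
        rows[(subj, grp, rep)] = {"TTR:closed": simpson_l2(y, zero, dt)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index = pd.MultiIndex.from_tuples(out.index, names=["subject", "group", "repetition"])
    return out.sort_index()
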