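"""Grey-value segmentation of line profiles and per-frame gap-width tracking.

The segmentation model is a three-component Gaussian mixture over the grey
values of one line profile, constrained to ordered means so the components
keep the interpretation *air (dark) < uncertain (grey) < matter (light)*.
The dark component sets the binarization threshold: the smallest grey value
above the dark mean at which the dark component's weighted density drops
below the combined weighted density of the two brighter components
(posterior-crossover rule).  Pixels below the threshold are air.

Air gaps along a line are maximal runs of air pixels; across frames the
retained gap is registered by pixel-index overlap with the previously
retained gap, with declarative per-frame overrides replacing the original
interactive review.  Tongue-tip retraction (TTR) is measured differently:
it is the run of *tissue* pixels from the line origin (the baseline
midpoint, inside the tongue) outward to the first tissue-to-air transition
(the tongue tip).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .errors import ConfigurationError, SegmentationError
from .grid import LineProfile

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass
class MixtureFit:
    """Constrained three-component Gaussian mixture fit to grey values."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    n_iterations: int
    converged: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class GapTrajectory:
    """Per-frame gap widths (or TTR extension) for one articulation site."""

    site: str
    width_px: np.ndarray
    start: np.ndarray  # first air index of the retained gap, -1 when closed
    end: np.ndarray  # one past the last air index, -1 when closed
    log: list[tuple[int, str]] = field(default_factory=list)
    spacing_mm: float = 1.4

    @property
    def width_mm(self) -> np.ndarray:
        return self.width_px * self.spacing_mm

    @property
    def n_frames(self) -> int:
        return self.width_px.size


def fit_gmm3(
    values: np.ndarray,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-7,
    min_sd: float = 0.5,
) -> MixtureFit:
    """EM fit of the ordered-means three-component Gaussian mixture.

    Initialization is deterministic (10/50/90th percentiles of the data), so
    the fit depends only on the data; ``seed`` is accepted for interface
    stability.  Components are relabeled into ascending-mean order after each
    M-step; standard deviations are floored at ``min_sd`` grey units to keep
    atomic (noise-free) grey-value distributions from collapsing the model.
    Convergence: relative log-likelihood change below ``tol``.
    """
    del seed
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 30:
        raise SegmentationError(f"need >= 30 grey values to fit the mixture, got {v.size}")
    if np.ptp(v) == 0.0:
        raise SegmentationError(
            "grey values have zero spread; supply a manual threshold override"
        )
    mu = np.percentile(v, [10.0, 50.0, 90.0]).astype(float)
    # Break exact ties in the percentile init so no component starts starved.
    span = np.ptp(v)
    for k in (1, 2):
        if mu[k] <= mu[k - 1]:
            mu[k] = mu[k - 1] + 1e-3 * span
    sd = np.full(3, max(np.std(v) / 3.0, min_sd))
    w = np.full(3, 1.0 / 3.0)

    ll_prev = -np.inf
    converged = False
    flags: list[str] = []
    n_it = 0
    log_resp = np.empty((3, v.size))
    for n_it in range(1, max_iter + 1):
        for k in range(3):
            log_resp[k] = (
                np.log(w[k] + 1e-300)
                - np.log(sd[k])
                - _LOG_SQRT_2PI
                - 0.5 * ((v - mu[k]) / sd[k]) ** 2
            )
        norm = logsumexp(log_resp, axis=0)
        ll = float(norm.sum())
        r = np.exp(log_resp - norm)
        nk = r.sum(axis=1)
        w = nk / v.size
        for k in range(3):
            if nk[k] <= 1e-12:
                continue  # starved component keeps its parameters
            mu[k] = float(r[k] @ v) / nk[k]
            sd[k] = math.sqrt(max(float(r[k] @ (v - mu[k]) ** 2) / nk[k], min_sd**2))
        order = np.argsort(mu, kind="stable")
        mu, sd, w = mu[order], sd[order], w[order]
        if ll_prev > -np.inf and abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1e-12):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll

    if not converged:
        flags.append("not_converged")
    if w.min() < 1e-3:
        flags.append("degenerate_component")
    if mu[2] - mu[1] < min_sd or mu[1] - mu[0] < min_sd:
        flags.append("coincident_means")
    return MixtureFit(
        weights=w, means=mu, sds=sd, loglik=ll_prev, n_iterations=n_it,
        converged=converged, flags=flags,
    )


def _weighted_logpdf(fit: MixtureFit, x: np.ndarray, k: int) -> np.ndarray:
    return (
        np.log(fit.weights[k] + 1e-300)
        - np.log(fit.sds[k])
        - _LOG_SQRT_2PI
        - 0.5 * ((x - fit.means[k]) / fit.sds[k]) ** 2
    )


def threshold_from_dark(fit: MixtureFit) -> float:
    """Binarization threshold from the dark component (air side below).

    Returns the smallest grey value above the dark mean where the dark
    component's weighted density falls below the summed weighted density of
    the two brighter components.  If no such crossover exists (e.g. the dark
    weight is vanishing), falls back to ``dark mean + 3 * dark sd`` and flags
    the fit with ``"threshold_fallback"``.
    """

    def excess(x: float) -> float:
        xa = np.asarray([x], dtype=float)
        dark = _weighted_logpdf(fit, xa, 0)
        rest = logsumexp(
            np.stack([_weighted_logpdf(fit, xa, 1), _weighted_logpdf(fit, xa, 2)]), axis=0
        )
        return float(dark[0] - rest[0])

    lo = float(fit.means[0])
    hi = float(fit.means[2] + 6.0 * fit.sds[2])
    xs = np.linspace(lo, hi, 512)
    vals = np.array([excess(x) for x in xs])
    pos = np.flatnonzero((vals[:-1] > 0) & (vals[1:] <= 0))
    if vals[0] <= 0 or pos.size == 0:
        fit.flags.append("threshold_fallback")
        return float(fit.means[0] + 3.0 * fit.sds[0])
    i = int(pos[0])
    return float(brentq(excess, xs[i], xs[i + 1], xtol=1e-9))


def binarize(profile: LineProfile | np.ndarray, threshold: float) -> np.ndarray:
    """Boolean air mask (grey value strictly below threshold)."""
    arr = profile.intensities if isinstance(profile, LineProfile) else np.asarray(profile)
    return arr < threshold


def _runs(column: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean vector as (start, stop) half-open pairs."""
    idx = np.flatnonzero(column)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return list(zip(starts.tolist(), stops.tolist()))


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def track_gap(
    binary: np.ndarray,
    site: str = "",
    init_frame_gap_choice: int | None = None,
    overrides: dict[int, int] | None = None,
    spacing_mm: float = 1.4,
) -> GapTrajectory:
    """Register air gaps over time by overlap with the previously retained gap.

    Per frame the candidate gaps are the maximal air runs of that column.  The
    retained gap is the run with the largest pixel-index overlap with the
    previously retained gap; ties prefer the longer run, then the smaller
    start index.  If no run overlaps, the gap is recorded closed (width 0) and
    the last open interval is carried; on reopening the run whose midpoint is
    nearest to the last open gap's midpoint is taken.  ``overrides`` maps a
    frame index to the candidate-run index (0-based, by start position) to
    retain at that frame, replacing the original interactive choice; every
    override is logged.
    """
    b = np.asarray(binary, dtype=bool)
    if b.size == 0:
        raise ConfigurationError("empty binary profile")
    npos, nfr = b.shape
    overrides = overrides or {}
    widths = np.zeros(nfr, dtype=float)
    starts = np.full(nfr, -1, dtype=int)
    ends = np.full(nfr, -1, dtype=int)
    log: list[tuple[int, str]] = []

    last_open: tuple[int, int] | None = None
    prev_open = False
    for t in range(nfr):
        runs = _runs(b[:, t])
        chosen: tuple[int, int] | None = None
        if t in overrides:
            ri = overrides[t]
            if not (0 <= ri < len(runs)):
                raise ConfigurationError(
                    f"override at frame {t} references run {ri} but only "
                    f"{len(runs)} run(s) detected"
                )
            chosen = runs[ri]
            log.append((t, f"override: retained run {ri} {chosen}"))
        elif not runs:
            chosen = None
        elif t == 0 or last_open is None:
            if init_frame_gap_choice is not None and t == 0:
                if not (0 <= init_frame_gap_choice < len(runs)):
                    raise ConfigurationError(
                        f"initial gap choice {init_frame_gap_choice} out of range"
                    )
                chosen = runs[init_frame_gap_choice]
            else:
                chosen = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
        elif prev_open:
            ov = [_overlap(r, last_open) for r in runs]
            if max(ov) > 0:
                chosen = max(
                    zip(ov, runs), key=lambda t_: (t_[0], t_[1][1] - t_[1][0], -t_[1][0])
                )[1]
            else:
                chosen = None  # zero overlap everywhere: record closed
                log.append((t, "gap closed (no overlapping run)"))
        else:
            mid = 0.5 * (last_open[0] + last_open[1] - 1)
            chosen = min(runs, key=lambda r: (abs(0.5 * (r[0] + r[1] - 1) - mid), r[0]))
            log.append((t, f"gap reopened at {chosen}"))

        if chosen is None:
            prev_open = False
        else:
            widths[t] = chosen[1] - chosen[0]
            starts[t], ends[t] = chosen
            last_open = chosen
            prev_open = True
    return GapTrajectory(site=site, width_px=widths, start=starts, end=ends, log=log,
                         spacing_mm=spacing_mm)


def measure_ttr(binary: np.ndarray, site: str = "TTR", spacing_mm: float = 1.4) -> GapTrajectory:
    """Tongue-tip retraction: tissue run from the line origin to the tip.

    ``binary`` is the air mask of the 0-degree line profile.  Per frame, TTR
    is the number of consecutive tissue (non-air) pixels from position 0 (the
    baseline midpoint) outward to the first tissue-to-air transition.  An air
    pixel at the origin yields 0 with a warning; a fully tissue line saturates
    at the line length and is flagged.
    """
    b = np.asarray(binary, dtype=bool)
    npos, nfr = b.shape
    widths = np.zeros(nfr, dtype=float)
    log: list[tuple[int, str]] = []
    for t in range(nfr):
        air = np.flatnonzero(b[:, t])
        if air.size and air[0] == 0:
            widths[t] = 0.0
            log.append((t, "warning: line origin is air"))
        elif air.size == 0:
            widths[t] = npos
            log.append((t, "no tip found (fully tissue line)"))
        else:
            widths[t] = air[0]
    starts = np.zeros(nfr, dtype=int)
    ends = widths.astype(int)
    return GapTrajectory(site=site, width_px=widths, start=starts, end=ends, log=log,
                         spacing_mm=spacing_mm)
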