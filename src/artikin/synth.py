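"""Synthetic vocal-tract cohort: articulator trajectories and phantom images.

The study data (midsagittal real-time MRI of speakers repeating a pseudoword)
is not publicly deposited, so this module generates a synthetic stand-in with
known ground truth that reproduces the statistical structure the analysis
assumes: two cohort groups (AWS = adults who stutter, FS = fluent speakers),
up to ten analysed repetitions per speaker, six articulator gap-width
trajectories (LA, TTR, TT-TD, TT-ARD, TB-PD1, TB-PD2), smooth subject-level
random curves, within-subject repetition noise, duration jitter, and
group-specific inter-articulator coupling.

Gesture model
-------------
Each site's curve over normalized utterance time u in [0, 1] is a baseline
aperture plus Gaussian bumps centred at phoneme-target times — the simplest
smooth gesture surrogate.  Group structure is injected through *archetypes*
that rescale and phase-shift the tongue-tip-retraction (TTR) gestures
relative to the other articulators, i.e. as altered inter-articulator
coupling: the default cohort plants one intermediate AWS archetype between
two more extreme FS archetypes (a hypo- and a hyper-articulating strategy),
the structure the speaker clustering is meant to recover.

Phantom rendering
-----------------
``render_phantom`` turns a trajectory bundle into grey-value image sequences
with three tissue classes (air dark, uncertain grey, matter light).  Frames
are constructed so that bilinear interpolation at every 1-px profile sample
point returns exactly the programmed class grey level (minimum-norm solution
of the sampling equations), which makes the programmed integer gap widths
exactly recoverable by the downstream gap detection at zero noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GeometryError
from .grid import SITE_ORDER, Line, build_grid
from .io import ImageSequence

# --------------------------------------------------------------------------
# acquisition timing

def frame_timing(n_spokes: int = 9, tr_ms: float = 2.02) -> tuple[float, int]:
    """Radial FLASH acquisition arithmetic: (ms per image, frames per second).

    One image is assembled from ``n_spokes`` radial spokes of ``tr_ms`` each;
    the frame rate is 1000 / (n_spokes * tr_ms) rounded to an integer.
    """
    ms = n_spokes * tr_ms
    return ms, int(round(1000.0 / ms))


# --------------------------------------------------------------------------
# gesture model

#: site -> (baseline aperture in px, gestures as (target time u, amplitude px,
#: temporal width as a fraction of the utterance)).  Amplitudes are free
#: parameters (no per-site ranges are published); values are chosen to give
#: plausible aperture ranges for a ~1 s pseudoword with alveolar and
#: postalveolar closures.
GESTURES: Mapping[str, tuple[float, tuple[tuple[float, float, float], ...]]] = {
    "LA": (9.0, ((0.15, 3.0, 0.06), (0.40, -4.0, 0.05), (0.52, 3.0, 0.06),
                 (0.90, 2.0, 0.06))),
    "TTR": (15.0, ((0.05, 4.0, 0.05), (0.28, 5.0, 0.04), (0.40, -3.0, 0.06),
                   (0.63, 5.0, 0.04), (0.82, 4.0, 0.04), (0.97, 4.0, 0.04))),
    "TT-TD": (7.0, ((0.05, -5.0, 0.05), (0.15, 3.0, 0.07), (0.28, -5.5, 0.04),
                    (0.52, 3.0, 0.07), (0.63, -5.5, 0.04), (0.82, -5.0, 0.04),
                    (0.97, -5.5, 0.04))),
    "TT-ARD": (8.0, ((0.05, -5.0, 0.05), (0.28, -5.0, 0.04), (0.40, -4.0, 0.06),
                     (0.63, -5.0, 0.04), (0.82, -4.5, 0.04), (0.97, -5.0, 0.04))),
    "TB-PD1": (8.0, ((0.15, 2.0, 0.07), (0.40, -6.0, 0.07), (0.52, 2.0, 0.07),
                     (0.90, 1.5, 0.07))),
    "TB-PD2": (6.0, ((0.05, 3.0, 0.08), (0.28, -2.0, 0.05), (0.63, -2.0, 0.05),
                     (0.90, 2.0, 0.07))),
}

#: Smooth random-effect basis: Gaussian bumps at these normalized times.
_RE_CENTERS = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
_RE_WIDTH = 0.09


@dataclass(frozen=True)
class GestureArchetype:
    """Inter-articulator coupling parameters of one speaking strategy.

    ``ttr_amp`` rescales the TTR gesture amplitudes, ``ttr_shift`` delays the
    TTR gesture targets by that many frames (at the mean duration), and
    ``global_amp`` rescales all gesture amplitudes.
    """

    ttr_amp: float = 1.0
    ttr_shift: float = 0.0
    global_amp: float = 1.0


#: The hypo-articulating FS strategy: attenuated, anticipatory TTR gestures.
ARCHETYPE_FS_HYPO = GestureArchetype(ttr_amp=0.35, ttr_shift=-5.0)
#: The hyper-articulating FS strategy: exaggerated, delayed TTR gestures.
ARCHETYPE_FS_HYPER = GestureArchetype(ttr_amp=1.9, ttr_shift=5.0)
#: AWS sit between the two FS strategies on the TTR coupling axis.
ARCHETYPE_AWS_INTERMEDIATE = GestureArchetype(ttr_amp=1.0, ttr_shift=0.0)

DEFAULT_ARCHETYPES: Mapping[str, tuple[GestureArchetype, ...]] = {
    "AWS": (ARCHETYPE_AWS_INTERMEDIATE,),
    "FS": (ARCHETYPE_FS_HYPO, ARCHETYPE_FS_HYPER),
}


@dataclass
class CohortDesign:
    """Design of one synthetic cohort draw."""

    n_subjects_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"AWS": 15, "FS": 17}
    )
    n_repetitions: int = 10
    n_frames_mean: float = 55.0
    duration_jitter_sd: float = 4.0
    sites: tuple[str, ...] = SITE_ORDER
    group_archetypes: Mapping[str, tuple[GestureArchetype, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    subject_sd: float = 0.4
    rep_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repetitions < 1:
            raise ConfigurationError("n_repetitions must be >= 1")
        if self.n_repetitions > 10:
            raise ConfigurationError("at most 10 repetitions are analysed per speaker")
        if min(self.subject_sd, self.rep_noise_sd, self.duration_jitter_sd) < 0:
            raise ConfigurationError("noise scales must be nonnegative")
        if tuple(sorted(self.sites)) != tuple(sorted(SITE_ORDER)):
            raise ConfigurationError(f"sites must be exactly {SITE_ORDER}")
        for g, n in self.n_subjects_per_group.items():
            if n <= 0:
                raise ConfigurationError(f"group {g!r} has non-positive subject count")
            if g not in self.group_archetypes or not self.group_archetypes[g]:
                raise ConfigurationError(f"group {g!r} has no archetype")


def cohort_design(separation: float = 1.0, **overrides) -> CohortDesign:
    """Default cohort with the archetype contrast scaled by ``separation``.

    ``separation=0`` collapses all archetypes onto the neutral gesture (no
    group difference); ``separation=1`` is the default planted structure.
    """
    archetypes = {
        g: tuple(
            GestureArchetype(
                ttr_amp=1.0 + (a.ttr_amp - 1.0) * separation,
                ttr_shift=a.ttr_shift * separation,
                global_amp=1.0 + (a.global_amp - 1.0) * separation,
            )
            for a in archs
        )
        for g, archs in DEFAULT_ARCHETYPES.items()
    }
    overrides.setdefault("group_archetypes", archetypes)
    return CohortDesign(**overrides)


@dataclass
class TrajectoryBundle:
    """Ground-truth articulator trajectories for one synthetic cohort.

    ``data`` is long format (subject, group, repetition, site, frame,
    width_px); ``trials`` holds per-trial duration and the planted archetype
    label used as ground truth for cluster recovery.
    """

    data: pd.DataFrame
    trials: pd.DataFrame
    design: CohortDesign

    def planted_labels(self) -> pd.Series:
        """Planted archetype per subject (the structure clustering should find)."""
        return self.trials.groupby("subject", sort=True)["archetype"].first()


def _bumps(u: np.ndarray, centers: np.ndarray, widths, amps) -> np.ndarray:
    out = np.zeros_like(u)
    for c, w, a in zip(np.atleast_1d(centers), np.atleast_1d(widths), np.atleast_1d(amps)):
        out += a * np.exp(-0.5 * ((u - c) / w) ** 2)
    return out


def _site_curve(u: np.ndarray, site: str, arch: GestureArchetype, mean_frames: float
                ) -> np.ndarray:
    base, gestures = GESTURES[site]
    centers = np.array([g[0] for g in gestures])
    amps = np.array([g[1] for g in gestures]) * arch.global_amp
    widths = np.array([g[2] for g in gestures])
    if site == "TTR":
        amps = amps * arch.ttr_amp
        centers = centers + arch.ttr_shift / mean_frames
    return base + _bumps(u, centers, widths, amps)


def gen_trajectories(design: CohortDesign) -> TrajectoryBundle:
    """Draw one cohort of ground-truth gap-width trajectories.

    Each trajectory is the smooth base gesture of its site, modulated by the
    subject's archetype, plus a smooth subject random curve (shared across
    repetitions) and smooth repetition noise, clipped at 0.  Durations are
    integer frame counts drawn around ``n_frames_mean`` (floor 20).  A fixed
    design seed makes the bundle bit-reproducible.
    """
    rng = np.random.default_rng(design.seed)
    data_rows: list[pd.DataFrame] = []
    trial_rows: list[dict] = []
    for group in sorted(design.n_subjects_per_group):
        archetypes = design.group_archetypes[group]
        for i in range(design.n_subjects_per_group[group]):
            subject = f"{group}{i + 1:02d}"
            ai = i % len(archetypes)
            arch = archetypes[ai]
            subj_coef = {
                site: rng.normal(0.0, design.subject_sd, _RE_CENTERS.size)
                for site in SITE_ORDER
            }
            for rep in range(1, design.n_repetitions + 1):
                dur = int(round(rng.normal(design.n_frames_mean, design.duration_jitter_sd)))
                dur = max(dur, 20)
                u = np.linspace(0.0, 1.0, dur)
                trial_rows.append(
                    {"subject": subject, "group": group, "repetition": rep,
                     "duration": dur, "archetype": f"{group}-arch{ai}"}
                )
                for site in SITE_ORDER:
                    rep_coef = rng.normal(0.0, design.rep_noise_sd, _RE_CENTERS.size)
                    w = (
                        _site_curve(u, site, arch, design.n_frames_mean)
                        + _bumps(u, _RE_CENTERS, np.full(_RE_CENTERS.size, _RE_WIDTH),
                                 subj_coef[site])
                        + _bumps(u, _RE_CENTERS, np.full(_RE_CENTERS.size, _RE_WIDTH),
                                 rep_coef)
                    )
                    np.clip(w, 0.0, None, out=w)
                    data_rows.append(
                        pd.DataFrame(
                            {"subject": subject, "group": group, "repetition": rep,
                             "site": site, "frame": np.arange(dur), "width_px": w}
                        )
                    )
    return TrajectoryBundle(
        data=pd.concat(data_rows, ignore_index=True),
        trials=pd.DataFrame(trial_rows),
        design=design,
    )


# --------------------------------------------------------------------------
# phantom rendering

@dataclass
class PhantomSpec:
    """Geometry and grey-value model of the rendered phantom."""

    image_shape: tuple[int, int] = (128, 128)
    spacing_mm: float = 1.4
    grey_air: float = 30.0
    grey_uncertain: float = 110.0
    grey_tissue: float = 200.0
    noise_sd: float = 0.0
    landmarks: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "posterior": (70.0, 95.0),  # upper frontal edge of cervical vertebra 4
            "anterior": (70.0, 35.0),  # incisor-palate transition
            "lip_upper": (52.0, 20.0),
            "lip_lower": (78.0, 20.0),
        }
    )
    #: tissue samples between the line origin and the gap on non-TTR lines
    gap_start_offset: int = 10
    #: tissue samples before the lip gap on the LA line
    lip_offset: int = 5

    def __post_init__(self) -> None:
        if not (self.grey_air < self.grey_uncertain < self.grey_tissue):
            raise ConfigurationError("class means must satisfy air < uncertain < tissue")
        nr, nc = self.image_shape
        for name, (r, c) in self.landmarks.items():
            if not (0 <= r < nr and 0 <= c < nc):
                raise ConfigurationError(f"landmark {name!r} outside the image")


class _Sampler:
    """Precomputed bilinear sampling operator for all profile lines.

    Rows are the deduplicated sample points of all six lines; columns the
    union of their 4-neighbor pixels.  ``solve`` returns the minimum-norm
    pixel adjustment that makes bilinear interpolation at every sample point
    hit the requested values exactly.
    """

    def __init__(self, lines: Mapping[str, Line], shape: tuple[int, int]):
        self.shape = shape
        point_index: dict[tuple[float, float], int] = {}
        self.line_rows: dict[str, np.ndarray] = {}
        pts: list[tuple[float, float]] = []
        for site, line in lines.items():
            rows = []
            for r, c in line.sample_points():
                key = (round(float(r), 9), round(float(c), 9))
                if key not in point_index:
                    point_index[key] = len(pts)
                    pts.append(key)
                rows.append(point_index[key])
            self.line_rows[site] = np.asarray(rows)
        nr, nc = shape
        weights: dict[int, dict[int, float]] = {}
        pix_index: dict[int, int] = {}
        pix_list: list[int] = []
        for m, (r, c) in enumerate(pts):
            r0, c0 = math.floor(r), math.floor(c)
            fr, fc = r - r0, c - c0
            for dr, wr in ((0, 1 - fr), (1, fr)):
                for dc, wc in ((0, 1 - fc), (1, fc)):
                    w = wr * wc
                    if w <= 0:
                        continue
                    rr, cc = r0 + dr, c0 + dc
                    if not (0 <= rr < nr and 0 <= cc < nc):
                        raise GeometryError(f"sample point ({r}, {c}) outside the image")
                    flat = rr * nc + cc
                    if flat not in pix_index:
                        pix_index[flat] = len(pix_list)
                        pix_list.append(flat)
                    weights.setdefault(m, {})[pix_index[flat]] = w
        self.n_points = len(pts)
        self.pixels = np.asarray(pix_list)
        W = np.zeros((self.n_points, len(pix_list)))
        for m, cols in weights.items():
            for j, w in cols.items():
                W[m, j] = w
        self.W = W
        self.W_pinv = np.linalg.pinv(W, rcond=1e-10)

    def values_vector(self, per_line: Mapping[str, np.ndarray]) -> np.ndarray:
        v = np.full(self.n_points, np.nan)
        for site, vals in per_line.items():
            rows = self.line_rows[site]
            for m, val in zip(rows, vals):
                if not np.isnan(v[m]) and v[m] != val:
                    raise GeometryError(
                        f"inconsistent class values at a shared sample point (line {site!r})"
                    )
                v[m] = val
        if np.isnan(v).any():
            raise GeometryError("not all sample points received a class value")
        return v

    def paint(self, background: np.ndarray, v: np.ndarray) -> np.ndarray:
        bg_strip = background.ravel()[self.pixels]
        resid = v - self.W @ bg_strip
        delta = self.W_pinv @ resid
        img = background.copy()
        img.ravel()[self.pixels] += delta
        check = self.W @ (bg_strip + delta) - v
        if np.abs(check).max() > 1e-6:
            raise GeometryError(
                f"phantom sampling system inconsistent (residual {np.abs(check).max():.2e})"
            )
        return img


def _background(spec: PhantomSpec) -> np.ndarray:
    """Air background, tissue head ellipse, and an off-grid uncertain band."""
    nr, nc = spec.image_shape
    img = np.full((nr, nc), spec.grey_air)
    rr, cc = np.mgrid[0:nr, 0:nc]
    head = ((rr - 64.0) / 52.0) ** 2 + ((cc - 60.0) / 52.0) ** 2 <= 1.0
    img[head] = spec.grey_tissue
    img[nr - 8:, :] = spec.grey_uncertain
    return img


def _class_values(
    site: str, width_px: int, n_samples: int, spec: PhantomSpec, where: str
) -> np.ndarray:
    """Programmed grey levels along one line for one frame."""
    air, tissue = spec.grey_air, spec.grey_tissue
    v = np.full(n_samples, tissue)
    if site == "TTR":
        # tongue tissue from the baseline midpoint out to the tip, air beyond
        if width_px > n_samples:
            raise GeometryError(f"{where}: TTR extension {width_px} exceeds line length")
        v[width_px:] = air
        return v
    offset = spec.lip_offset if site == "LA" else spec.gap_start_offset
    if width_px > 0 and offset + width_px + 1 > n_samples:
        raise GeometryError(
            f"{where}: gap width {width_px} px exceeds line capacity "
            f"({n_samples - offset - 1} px)"
        )
    v[offset:offset + width_px] = air
    return v


def render_phantom(
    bundle: TrajectoryBundle,
    spec: PhantomSpec | None = None,
    seed: int | None = None,
) -> tuple[list[ImageSequence], pd.DataFrame]:
    """Render every trial of a bundle into a grey-value image sequence.

    Returns the image sequences and the ground-truth gap table with columns
    ``subject, group, repetition, site, frame, width_px, width_true``:
    ``width_px`` is the integer programmed (rendered) width, ``width_true``
    the continuous bundle value it quantizes.  At ``noise_sd = 0`` the
    downstream gap detection recovers ``width_px`` exactly.
    """
    spec = spec or PhantomSpec()
    lm = spec.landmarks
    grid = build_grid(lm["posterior"], lm["anterior"], lm["lip_upper"], lm["lip_lower"])
    lines = grid.site_lines()
    sampler = _Sampler(lines, spec.image_shape)
    n_samples = {s: ln.sample_points().shape[0] for s, ln in lines.items()}
    background = _background(spec)
    rng = np.random.default_rng(bundle.design.seed if seed is None else seed)
    _, fps = frame_timing()

    wide = bundle.data.pivot_table(
        index=["subject", "group", "repetition", "site"], columns="frame", values="width_px"
    )
    sequences: list[ImageSequence] = []
    truth_rows: list[pd.DataFrame] = []
    for trial in bundle.trials.itertuples(index=False):
        dur = int(trial.duration)
        frames = np.empty((dur, *spec.image_shape))
        per_site_true = {
            site: wide.loc[(trial.subject, trial.group, trial.repetition, site)]
            .to_numpy()[:dur]
            for site in SITE_ORDER
        }
        per_site_px = {s: np.rint(v).astype(int) for s, v in per_site_true.items()}
        for t in range(dur):
            where = f"trial ({trial.subject}, rep {trial.repetition}), frame {t}"
            per_line = {
                site: _class_values(site, int(per_site_px[site][t]), n_samples[site],
                                    spec, where)
                for site in SITE_ORDER
            }
            frames[t] = sampler.paint(background, sampler.values_vector(per_line))
        if spec.noise_sd > 0:
            frames += rng.normal(0.0, spec.noise_sd, frames.shape)
        sequences.append(
            ImageSequence(
                frames=frames, spacing_mm=spec.spacing_mm, fps=fps,
                subject=trial.subject, group=trial.group, repetition=int(trial.repetition),
                meta={"archetype": trial.archetype},
            )
        )
        for site in SITE_ORDER:
            truth_rows.append(
                pd.DataFrame(
                    {"subject": trial.subject, "group": trial.group,
                     "repetition": trial.repetition, "site": site,
                     "frame": np.arange(dur),
                     "width_px": per_site_px[site].astype(float),
                     "width_true": per_site_true[site]}
                )
            )
    return sequences, pd.concat(truth_rows, ignore_index=True)


def phantom_grid(spec: PhantomSpec | None = None):
    """The measurement grid implied by a phantom's landmarks."""
    spec = spec or PhantomSpec()
    lm = spec.landmarks
    return build_grid(lm["posterior"], lm["anterior"], lm["lip_upper"], lm["lip_lower"])
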