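"""Measurement-line grid geometry and space x time line-profile extraction.

The grid is anchored on two anatomical landmarks in the midsagittal image: the
upper frontal edge of cervical vertebra 4 (posterior) and the transition from
the anterior incisor to the hard palate (anterior).  The segment between them
is the *baseline*; angled measurement lines of half the baseline length start
at the baseline midpoint, rotated clockwise (in image coordinates, row index
increasing downward) from the anterior baseline direction.  A separate line
connects the centers of the upper and lower lip.

Coordinates are ``(row, col)``, 0-based, floats allowed.  Intensity sampling
along a line uses bilinear interpolation at 1-pixel steps from the origin
outward.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, GeometryError

#: Site -> clockwise angle (degrees) from the anterior baseline direction.
#: The lip aperture (LA) site is measured on the dedicated lip line instead.
DEFAULT_SITE_ANGLES: Mapping[str, float] = {
    "TTR": 0.0,
    "TT-TD": 7.5,
    "TT-ARD": 15.0,
    "TB-PD1": 60.0,
    "TB-PD2": 90.0,
}

#: Angles of the original (unmodified) grid that carry no site mapping here.
EXTRA_GRID_ANGLES: tuple[float, ...] = (30.0, 120.0, 150.0)

SITE_ORDER: tuple[str, ...] = ("LA", "TTR", "TT-TD", "TT-ARD", "TB-PD1", "TB-PD2")


@dataclass(frozen=True)
class Line:
    """A measurement line: ``origin + s * direction`` for ``s in [0, length]``."""

    site: str
    origin: tuple[float, float]
    direction: tuple[float, float]  # unit vector, (row, col)
    length: float

    def sample_points(self) -> np.ndarray:
        """(n, 2) array of sample coordinates at 1-px steps from the origin."""
        n = int(math.floor(self.length)) + 1
        s = np.arange(n, dtype=float)
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        return o[None, :] + s[:, None] * d[None, :]


@dataclass
class ProfileGrid:
    """The full measurement grid built from one trial's landmarks."""

    posterior: tuple[float, float]
    anterior: tuple[float, float]
    midpoint: tuple[float, float]
    baseline_length: float
    lines: dict[str, Line]
    lip_line: Line
    extra_lines: list[Line] = field(default_factory=list)
    posterior_line: Line | None = None

    def site_lines(self) -> dict[str, Line]:
        """All six analysis lines, keyed by site label (LA = lip line)."""
        out = dict(self.lines)
        out["LA"] = self.lip_line
        return out

    def to_json(self) -> str:
        """Serializable audit dump of the grid geometry."""

        def as_dict(ln: Line) -> dict:
            return {
                "site": ln.site,
                "origin": list(ln.origin),
                "direction": list(ln.direction),
                "length": ln.length,
            }

        payload = {
            "posterior": list(self.posterior),
            "anterior": list(self.anterior),
            "midpoint": list(self.midpoint),
            "baseline_length": self.baseline_length,
            "lines": {k: as_dict(v) for k, v in self.lines.items()},
            "lip_line": as_dict(self.lip_line),
            "extra_lines": [as_dict(v) for v in self.extra_lines],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class LineProfile:
    """Space x time intensity profile of one measurement line.

    ``intensities`` has one row per position along the line (1-px steps from
    the origin) and one column per frame.
    """

    site: str
    intensities: np.ndarray
    spacing_mm: float = 1.4

    @property
    def n_positions(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[1]


def _rotate_cw(direction: Sequence[float], angle_deg: float) -> tuple[float, float]:
    """Rotate a (row, col) direction clockwise on screen (row axis downward)."""
    th = math.radians(angle_deg)
    dr, dc = direction
    return (dr * math.cos(th) + dc * math.sin(th), -dr * math.sin(th) + dc * math.cos(th))


def build_grid(
    posterior: Sequence[float],
    anterior: Sequence[float],
    lip_upper: Sequence[float],
    lip_lower: Sequence[float],
    site_angles: Mapping[str, float] = DEFAULT_SITE_ANGLES,
    extra_angles: Iterable[float] = (),
    include_posterior_line: bool = False,
) -> ProfileGrid:
    """Construct the measurement grid from one trial's landmarks.

    Parameters
    ----------
    posterior, anterior:
        Baseline endpoints, (row, col).  The 0-degree direction points from
        the baseline midpoint toward ``anterior``; positive angles rotate
        clockwise in image coordinates.
    lip_upper, lip_lower:
        Centers of the upper and lower lip; the LA line runs between them.
    site_angles:
        Site label -> angle in degrees; each line has half the baseline length.
    extra_angles:
        Additional unmapped grid angles (e.g. the original 30/120/150 lines).
    include_posterior_line:
        Also build the posterior baseline half (head-motion indicator, not a
        site); excluded from analyses by default.
    """
    p = np.asarray(posterior, dtype=float)
    a = np.asarray(anterior, dtype=float)
    base_vec = a - p
    base_len = float(np.linalg.norm(base_vec))
    if base_len == 0.0:
        raise GeometryError("baseline landmarks coincide")
    for ang in list(site_angles.values()) + list(extra_angles):
        if not (0.0 <= ang < 180.0):
            raise ConfigurationError(f"grid angle {ang} outside [0, 180)")
    mid = (p + a) / 2.0
    d0 = tuple((base_vec / base_len).tolist())
    half = base_len / 2.0

    lines = {
        site: Line(site, tuple(mid.tolist()), _rotate_cw(d0, ang), half)
        for site, ang in site_angles.items()
    }
    extra = [
        Line(f"grid-{ang:g}deg", tuple(mid.tolist()), _rotate_cw(d0, ang), half)
        for ang in extra_angles
    ]

    lu = np.asarray(lip_upper, dtype=float)
    ll = np.asarray(lip_lower, dtype=float)
    lip_vec = ll - lu
    lip_len = float(np.linalg.norm(lip_vec))
    if lip_len == 0.0:
        raise GeometryError("lip landmarks coincide")
    lip = Line("LA", tuple(lu.tolist()), tuple((lip_vec / lip_len).tolist()), lip_len)

    post = None
    if include_posterior_line:
        d_post = (-d0[0], -d0[1])
        post = Line("BASE-POST", tuple(mid.tolist()), d_post, half)

    return ProfileGrid(
        posterior=tuple(p.tolist()),
        anterior=tuple(a.tolist()),
        midpoint=tuple(mid.tolist()),
        baseline_length=base_len,
        lines=lines,
        lip_line=lip,
        extra_lines=extra,
        posterior_line=post,
    )


def extract_profile(frames: np.ndarray, line: Line, spacing_mm: float = 1.4) -> LineProfile:
    """Sample a frame stack along one line into a space x time profile.

    ``frames`` is a ``(n_frames, n_rows, n_cols)`` grey-value stack (an
    :class:`~artikin.io.ImageSequence` may be passed via its ``.frames``).
    Values are bilinearly interpolated at 1-px steps from the line origin.
    """
    frames = np.asarray(getattr(frames, "frames", frames), dtype=float)
    if frames.ndim != 3:
        raise ConfigurationError("frame stack must be (n_frames, rows, cols)")
    nfr, nr, nc = frames.shape
    pts = line.sample_points()
    if (
        pts[:, 0].min() < 0
        or pts[:, 1].min() < 0
        or pts[:, 0].max() > nr - 1
        or pts[:, 1].max() > nc - 1
    ):
        bad = pts[
            (pts[:, 0] < 0) | (pts[:, 1] < 0) | (pts[:, 0] > nr - 1) | (pts[:, 1] > nc - 1)
        ][0]
        raise GeometryError(
            f"line {line.site!r} samples outside image bounds at (row, col) = "
            f"({bad[0]:.2f}, {bad[1]:.2f})"
        )
    coords = pts.T  # (2, n_positions)
    out = np.empty((pts.shape[0], nfr), dtype=float)
    for t in range(nfr):
        out[:, t] = ndimage.map_coordinates(frames[t], coords, order=1, mode="nearest")
    return LineProfile(site=line.site, intensities=out, spacing_mm=spacing_mm)


def regrid_per_trial(
    landmarks: pd.DataFrame,
    trial_id: object,
    site_angles: Mapping[str, float] = DEFAULT_SITE_ANGLES,
) -> ProfileGrid:
    """Rebuild the grid from one trial's landmark entries.

    ``landmarks`` is a long table with columns ``trial``, ``point``
    (posterior / anterior / lip_upper / lip_lower), ``row``, ``col``.
    The grid is re-adjusted per trial because speakers may move their head
    between repetitions; the first frame of each trial is the reference.
    """
    sub = landmarks[landmarks["trial"] == trial_id]
    if sub.empty:
        raise ConfigurationError(f"no landmark entry for trial {trial_id!r}")
    pts = {}
    for point in ("posterior", "anterior", "lip_upper", "lip_lower"):
        row = sub[sub["point"] == point]
        if row.empty:
            raise ConfigurationError(f"trial {trial_id!r} missing landmark {point!r}")
        pts[point] = (float(row["row"].iloc[0]), float(row["col"].iloc[0]))
    return build_grid(
        pts["posterior"], pts["anterior"], pts["lip_upper"], pts["lip_lower"], site_angles
    )
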