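"""From image sequences to gap-width trajectories (profiles -> GMM -> gaps).

For every trial and every site line: extract the space x time line profile,
fit the constrained grey-value mixture on that profile, derive the
binarization threshold from its dark component, binarize, and track the gap
over frames (tongue-tip retraction is measured as the tissue run from the
line origin instead).  Declarative overrides replace the original interactive
review: a table of (subject, repetition, site, frame, run_index) entries
and/or per-profile forced thresholds.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .gaps import binarize, fit_gmm3, measure_ttr, threshold_from_dark, track_gap
from .grid import ProfileGrid, extract_profile
from .io import ImageSequence


def _trial_overrides(
    overrides: pd.DataFrame | None, subject, repetition, site
) -> tuple[dict[int, int], float | None]:
    if overrides is None or overrides.empty:
        return {}, None
    sub = overrides[
        (overrides["subject"] == subject)
        & (overrides["repetition"] == repetition)
        & (overrides["site"] == site)
    ]
    run_over: dict[int, int] = {}
    thr: float | None = None
    for row in sub.itertuples(index=False):
        ri = getattr(row, "run_index", None)
        if ri is not None and not pd.isna(ri):
            run_over[int(row.frame)] = int(ri)
        t = getattr(row, "threshold", None)
        if t is not None and not pd.isna(t):
            thr = float(t)
    return run_over, thr


def extract_trajectories(
    sequences: Iterable[ImageSequence],
    grid: ProfileGrid | Callable[[ImageSequence], ProfileGrid],
    gmm_kwargs: dict | None = None,
    overrides: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Measure all six site trajectories for every image sequence.

    ``grid`` is either a fixed :class:`ProfileGrid` or a callable mapping a
    sequence to its (re-adjusted) per-trial grid.  Returns the long trajectory
    table (subject, group, repetition, site, frame, width_px, width_mm).
    """
    gmm_kwargs = gmm_kwargs or {}
    rows: list[pd.DataFrame] = []
    for seq in sequences:
        g = grid(seq) if callable(grid) else grid
        for site, line in g.site_lines().items():
            profile = extract_profile(seq.frames, line, seq.spacing_mm)
            run_over, forced_thr = _trial_overrides(
                overrides, seq.subject, seq.repetition, site
            )
            if forced_thr is not None:
                thr = forced_thr
            else:
                fit = fit_gmm3(profile.intensities, **gmm_kwargs)
                thr = threshold_from_dark(fit)
            air = binarize(profile, thr)
            if site == "TTR":
                traj = measure_ttr(air, site=site, spacing_mm=seq.spacing_mm)
            else:
                traj = track_gap(air, site=site, overrides=run_over,
                                 spacing_mm=seq.spacing_mm)
            rows.append(
                pd.DataFrame(
                    {"subject": seq.subject, "group": seq.group,
                     "repetition": seq.repetition, "site": site,
                     "frame": np.arange(traj.n_frames),
                     "width_px": traj.width_px,
                     "width_mm": traj.width_mm,
                     "threshold": thr}
                )
            )
    return pd.concat(rows, ignore_index=True)
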