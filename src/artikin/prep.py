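"""Duration normalization and assembly of the analysis-ready trajectory table.

Utterance repetitions differ in duration (frame count).  Following the
analysis design, the cohort median frame count ``T*`` is computed over all
included trials and every trajectory is stretched or compressed to exactly
``T*`` frames by linear interpolation on an affinely mapped index grid.
Perceptual screening (stuttered/mispronounced trials, >250 ms pauses) is not
computable from the images; it enters as metadata flags whose bookkeeping is
handled here, together with the training-repetition rule and the cap of ten
analysed repetitions per speaker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

REQUIRED_COLUMNS = ("subject", "group", "repetition", "site", "frame", "width_px")


@dataclass
class TrajectorySet:
    """Time-normalized functional data table.

    ``data`` is a long table with columns ``subject, group, repetition, site,
    frame, width_px``; every included (subject, repetition, site) series has
    exactly ``t_star`` frames.
    """

    data: pd.DataFrame
    t_star: int
    exclusion_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["subject", "repetition", "reason"])
    )

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.data["site"]))

    @property
    def subjects(self) -> tuple:
        return tuple(pd.unique(self.data["subject"]))

    def curves(self, site: str) -> pd.DataFrame:
        """Wide (trial x frame) matrix for one site, indexed by (subject, group, repetition)."""
        sub = self.data[self.data["site"] == site]
        wide = sub.pivot_table(
            index=["subject", "group", "repetition"], columns="frame", values="width_px"
        )
        return wide.sort_index()


def median_duration(durations: Iterable[int]) -> int:
    """Sample median frame count; even counts round the midpoint half-up."""
    d = sorted(int(x) for x in durations)
    if not d:
        raise ConfigurationError("empty duration list")
    if any(x <= 0 for x in d):
        raise ConfigurationError("durations must be positive frame counts")
    n = len(d)
    if n % 2 == 1:
        return d[n // 2]
    mid = 0.5 * (d[n // 2 - 1] + d[n // 2])
    return int(math.floor(mid + 0.5))


def resample_linear(traj: Sequence[float], t_star: int) -> np.ndarray:
    """Resample a trajectory to ``t_star`` frames by linear interpolation.

    The source index grid ``[0, L-1]`` is mapped affinely onto
    ``[0, t_star-1]``; endpoints are preserved exactly.
    """
    y = np.asarray(traj, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ConfigurationError("trajectory must be 1-D with length >= 2")
    if t_star < 2:
        raise ConfigurationError("target length must be >= 2")
    if y.size == t_star:
        return y.copy()
    x_src = np.linspace(0.0, 1.0, y.size)
    x_tgt = np.linspace(0.0, 1.0, t_star)
    out = np.interp(x_tgt, x_src, y)
    out[0], out[-1] = y[0], y[-1]
    return out


def assemble(
    trajectories: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    min_reps: int = 1,
    max_reps: int = 10,
    drop_training: bool = False,
    t_star: int | None = None,
) -> TrajectorySet:
    """Filter, cap, and time-normalize raw trajectories into a TrajectorySet.

    Parameters
    ----------
    trajectories:
        Long table with columns ``subject, group, repetition, site, frame,
        width_px`` (one row per frame per site per trial).
    metadata:
        Optional per-trial flags: ``subject, repetition, include_flag,
        exclusion_reason``.  Trials with ``include_flag == False`` are
        dropped and logged (stuttered / mispronounced / long-pause trials).
    drop_training:
        Drop the two lowest repetition indices per subject (the training
        repetitions) before applying the repetition cap.
    max_reps:
        Keep at most this many repetitions per subject, by ascending
        repetition index (the "first ten fluent recordings" rule).
    min_reps:
        Subjects with fewer surviving repetitions are dropped and logged.
    t_star:
        Target frame count; defaults to the median duration of the included
        trials.
    """
    df = trajectories.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"trajectory table missing columns {missing}")
    log_rows: list[dict] = []

    trials = df[["subject", "repetition"]].drop_duplicates()
    keep = set(map(tuple, trials.itertuples(index=False)))

    if drop_training:
        for subj, grp in trials.groupby("subject"):
            for rep in sorted(grp["repetition"])[:2]:
                keep.discard((subj, rep))
                log_rows.append({"subject": subj, "repetition": rep, "reason": "training"})

    if metadata is not None:
        for row in metadata.itertuples(index=False):
            if not bool(getattr(row, "include_flag", True)):
                key = (row.subject, row.repetition)
                if key in keep:
                    keep.discard(key)
                    reason = getattr(row, "exclusion_reason", "") or "flagged"
                    log_rows.append(
                        {"subject": row.subject, "repetition": row.repetition, "reason": reason}
                    )

    # Cap at max_reps per subject, in ascending repetition order.
    by_subject: dict = {}
    for subj, rep in sorted(keep):
        by_subject.setdefault(subj, []).append(rep)
    for subj, reps in by_subject.items():
        for rep in reps[max_reps:]:
            keep.discard((subj, rep))
            log_rows.append(
                {"subject": subj, "repetition": rep, "reason": f"repetition cap ({max_reps})"}
            )
        by_subject[subj] = reps[:max_reps]
    for subj, reps in list(by_subject.items()):
        if len(reps) < min_reps:
            for rep in reps:
                keep.discard((subj, rep))
            log_rows.append(
                {"subject": subj, "repetition": None,
                 "reason": f"subject dropped (< {min_reps} repetitions)"}
            )

    mask = df.set_index(["subject", "repetition"]).index.isin(keep)
    df = df[mask]
    if df.empty:
        raise ConfigurationError("no trials survive the exclusion rules")

    durations = (
        df.groupby(["subject", "repetition"])["frame"].max().astype(int) + 1
    )
    if t_star is None:
        t_star = median_duration(durations.tolist())

    out_rows = []
    for (subj, grp, rep, site), sub in df.groupby(
        ["subject", "group", "repetition", "site"], sort=True
    ):
        y = sub.sort_values("frame")["width_px"].to_numpy()
        ry = resample_linear(y, t_star)
        out_rows.append(
            pd.DataFrame(
                {
                    "subject": subj,
                    "group": grp,
                    "repetition": rep,
                    "site": site,
                    "frame": np.arange(t_star),
                    "width_px": ry,
                }
            )
        )
    data = pd.concat(out_rows, ignore_index=True)
    log = pd.DataFrame(log_rows, columns=["subject", "repetition", "reason"])
    return TrajectorySet(data=data, t_star=int(t_star), exclusion_log=log)
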