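"""Image-stack and tabular I/O.

Image sequences (one utterance repetition each) are written either as
multi-page TIFF or as NPZ stacks, with a JSON sidecar holding pixel spacing,
frame rate, and trial identity.  All tabular outputs are plain CSV with
documented headers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import ConfigurationError


@dataclass
class ImageSequence:
    """Grey-value frame stack for one utterance repetition.

    ``frames`` is ``(n_frames, rows, cols)``; ``spacing_mm`` is the in-plane
    pixel size and ``fps`` the acquisition frame rate.
    """

    frames: np.ndarray
    spacing_mm: float = 1.4
    fps: float = 55.0
    subject: str = ""
    group: str = ""
    repetition: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _sidecar(seq: ImageSequence) -> dict:
    return {
        "spacing_mm": seq.spacing_mm,
        "fps": seq.fps,
        "subject": seq.subject,
        "group": seq.group,
        "repetition": seq.repetition,
        "n_frames": int(seq.n_frames),
        **seq.meta,
    }


def write_image_stack(seq: ImageSequence, path: str | Path) -> Path:
    """Write a frame stack as multi-page TIFF (.tif) or NPZ (.npz), plus a
    JSON metadata sidecar next to it."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, seq.frames.astype(np.float32), photometric="minisblack")
    elif path.suffix == ".npz":
        np.savez_compressed(path, frames=seq.frames)
    else:
        raise ConfigurationError(f"unsupported stack format {path.suffix!r}")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(_sidecar(seq), indent=2, sort_keys=True)
    )
    return path


def read_image_stack(path: str | Path) -> ImageSequence:
    """Read a TIFF/NPZ stack and its JSON sidecar back into an ImageSequence."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"image stack not found: {path}")
    if path.suffix in (".tif", ".tiff"):
        frames = tifffile.imread(path)
    elif path.suffix == ".npz":
        with np.load(path) as z:
            frames = z["frames"]
    else:
        raise ConfigurationError(f"unsupported stack format {path.suffix!r}")
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None, :, :]
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "n_frames" in meta and int(meta["n_frames"]) != frames.shape[0]:
            raise ConfigurationError(
                f"{path}: sidecar says {meta['n_frames']} frames, stack has {frames.shape[0]}"
            )
    return ImageSequence(
        frames=frames,
        spacing_mm=float(meta.get("spacing_mm", 1.4)),
        fps=float(meta.get("fps", 55.0)),
        subject=str(meta.get("subject", "")),
        group=str(meta.get("group", "")),
        repetition=int(meta.get("repetition", 0)),
        meta={k: v for k, v in meta.items()
              if k not in ("spacing_mm", "fps", "subject", "group", "repetition", "n_frames")},
    )
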