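"""Frame selection for photogrammetric reconstruction.

Underwater colonies are filmed as video; the reconstruction service takes
at most 70 still images per model, so frames must be picked where the
colony is well defined (sharp) while still covering the orbit around it.
Sharpness is scored as the variance of the Laplacian of the grayscale
frame — the standard focus measure — and selection greedily takes the
sharpest frames subject to a minimum ordinal spacing, which preserves
angular coverage of the circling trajectory.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "FrameScore",
    "UnreadableFrameWarning",
    "DEFAULT_CAP",
    "sharpness",
    "score_frames",
    "select_frames",
    "write_manifest",
]

DEFAULT_CAP = 70  # image ceiling of the reconstruction service


class UnreadableFrameWarning(UserWarning):
    pass


@dataclass(frozen=True)
class FrameScore:
    frame_id: int
    path: str
    sharpness: float  # variance of the Laplacian response, >= 0
    selected: bool = False


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    return img


def sharpness(image: np.ndarray) -> float:
    """Variance of the Laplacian of the grayscale image (dimensionless)."""
    lap = ndimage.laplace(_to_gray(image))
    return float(lap.var())


_ORDINAL = re.compile(r"(\d+)")


def _frame_id(path: Path, fallback: int) -> int:
    m = _ORDINAL.findall(path.stem)
    return int(m[-1]) if m else fallback


def score_frames(frames_dir, pattern: str = "*") -> list[FrameScore]:
    """Score every readable image in a directory.

    Frames are ordered by the zero-padded ordinal in the filename (falling
    back to lexicographic position); unreadable files are skipped with an
    :class:`UnreadableFrameWarning` so they appear in the run report.
    """
    paths = sorted(
        p
        for p in Path(frames_dir).glob(pattern)
        if p.is_file() and p.suffix.lower() in {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}
    )
    if not paths:
        raise FileNotFoundError(f"no image frames found in {frames_dir}")
    scores = []
    for k, p in enumerate(paths):
        try:
            img = iio.imread(p)
        except Exception as exc:  # codec/truncation errors: report, keep going
            warnings.warn(
                f"skipping unreadable frame {p.name}: {exc}",
                UnreadableFrameWarning,
                stacklevel=2,
            )
            continue
        scores.append(FrameScore(frame_id=_frame_id(p, k), path=str(p), sharpness=sharpness(img)))
    return scores


def select_frames(
    scores: Sequence[FrameScore],
    cap: int = DEFAULT_CAP,
    min_spacing: int = 0,
) -> list[FrameScore]:
    """Greedy sharpest-first selection under a count cap and ordinal spacing.

    Frames are considered in order of decreasing sharpness (ties broken by
    lower frame id); a frame is taken if it keeps at least ``min_spacing``
    ordinals from every frame already taken, until ``cap`` frames are
    selected.  Deterministic for fixed input.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    order = sorted(scores, key=lambda s: (-s.sharpness, s.frame_id))
    taken_ids: list[int] = []
    taken = set()
    for s in order:
        if len(taken_ids) >= cap:
            break
        if all(abs(s.frame_id - t) >= min_spacing for t in taken_ids):
            taken_ids.append(s.frame_id)
            taken.add(s.frame_id)
    return [replace(s, selected=(s.frame_id in taken)) for s in scores]


def write_manifest(scores: Sequence[FrameScore], path) -> None:
    """Selection manifest CSV: frame_id, sharpness, selected."""
    lines = ["frame_id,sharpness,selected"]
    for s in scores:
        lines.append(f"{s.frame_id},{s.sharpness:.6f},{int(s.selected)}")
    Path(path).write_text("\n".join(lines) + "\n")
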