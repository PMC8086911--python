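"""Exposure-bracket normalization and high-dynamic-range merging.

A scene is captured as a small bracket — typically three frames separated by
3 EV (a factor 8 in exposure) — so that every direction lands unsaturated in
at least one frame, extending the usable dynamic range of a three-frame
bracket by 2⁶ = 64 over a single exposure.

The merge is a two-step rule, not a weighted blend:

1. *Normalization*: after each frame is converted to radiance, residual
   frame-to-frame scale differences (shutter/aperture tolerances, light that
   actually changed between frames) are removed by computing each frame's
   median radiance over pixels unsaturated in every frame, and scaling each
   frame so its median matches the bracket average (geometric mean by
   default, arithmetic optional).
2. *Selection*: each output pixel takes its value from the most exposed
   (highest-EV) frame in which it is not saturated.  Pixels saturated in
   every frame keep the least-exposed value and are flagged — like the
   retina, the method simply saturates on direct views of the sun.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .projection import EquirectImage

__all__ = ["ExposureBracket", "normalize_bracket", "merge_hdr"]


@dataclass
class ExposureBracket:
    """An ordered set of radiance frames of one scene at different EV.

    Frames are stored in increasing EV order (the constructor sorts, so
    callers may supply any order); all frames must share raster geometry.
    ``saturated`` masks are per pixel per channel; ``valid`` is the shared
    geometric coverage mask.
    """

    images: list[np.ndarray]  # each M×M×3, linear radiance
    ev_offsets: list[float]
    saturated: list[np.ndarray]  # each M×M×3 bool
    valid: np.ndarray | None = None  # M×M bool

    def __post_init__(self):
        if not self.images:
            raise ValueError("bracket needs at least one exposure")
        if not (len(self.images) == len(self.ev_offsets) == len(self.saturated)):
            raise ValueError("images, ev_offsets and saturated must align")
        shape = self.images[0].shape
        if any(im.shape != shape for im in self.images) or any(
            s.shape != shape for s in self.saturated
        ):
            raise ValueError("bracket frames must share raster geometry")
        order = np.argsort(self.ev_offsets, kind="stable")
        self.images = [np.asarray(self.images[i], dtype=float) for i in order]
        self.ev_offsets = [float(self.ev_offsets[i]) for i in order]
        self.saturated = [np.asarray(self.saturated[i], bool) for i in order]
        if len(set(self.ev_offsets)) != len(self.ev_offsets):
            raise ValueError("ev_offsets must be distinct")
        if self.valid is None:
            self.valid = np.ones(shape[:2], dtype=bool)

    def __len__(self) -> int:
        return len(self.images)

    @classmethod
    def from_equirect(
        cls, frames: Sequence[EquirectImage], ev_offsets: Sequence[float]
    ) -> "ExposureBracket":
        valid = np.logical_and.reduce([f.valid for f in frames])
        sat = [
            f.saturated
            if f.saturated is not None
            else np.zeros_like(f.pixels, dtype=bool)
            for f in frames
        ]
        return cls(
            images=[f.pixels for f in frames],
            ev_offsets=list(ev_offsets),
            saturated=sat,
            valid=valid,
        )


def normalize_bracket(
    bracket: ExposureBracket, average: str = "geometric"
) -> ExposureBracket:
    """Scale each frame so its median radiance matches the bracket average.

    The median is computed only over pixels (and channels) that are valid and
    unsaturated in *every* frame, so clipping cannot bias the reference.
    ``average`` selects how the common reference is formed from the
    per-frame medians: ``"geometric"`` (default — the pipeline's statistics
    live in log space) or ``"arithmetic"``.  Frames with no usable pixels are
    dropped with a warning.
    """
    if average not in ("geometric", "arithmetic"):
        raise ValueError("average must be 'geometric' or 'arithmetic'")

    # frames with no usable pixels at all are dropped before the mutual mask,
    # so one blown exposure cannot erase the reference population
    keep = []
    for i in range(len(bracket)):
        usable = ~bracket.saturated[i] & bracket.valid[..., None]
        if usable.any():
            keep.append(i)
        else:
            warnings.warn(
                f"exposure at EV {bracket.ev_offsets[i]:+g} is fully saturated; "
                "excluded from the bracket"
            )
    if not keep:
        raise ValueError("every exposure in the bracket is fully saturated")

    unsat_everywhere = ~np.logical_or.reduce([bracket.saturated[i] for i in keep])
    good = unsat_everywhere & bracket.valid[..., None]
    if not good.any():
        raise ValueError(
            "no pixel is unsaturated in every exposure; cannot normalize bracket"
        )
    medians = np.asarray([np.median(bracket.images[i][good]) for i in keep])
    if average == "geometric":
        reference = float(np.exp(np.mean(np.log(medians))))
    else:
        reference = float(np.mean(medians))
    scales = reference / medians

    return ExposureBracket(
        images=[bracket.images[i] * s for i, s in zip(keep, scales)],
        ev_offsets=[bracket.ev_offsets[i] for i in keep],
        saturated=[bracket.saturated[i] for i in keep],
        valid=bracket.valid,
    )


def merge_hdr(bracket: ExposureBracket) -> EquirectImage:
    """Collapse a (normalized) bracket into one radiance image.

    Per pixel and channel: the value from the highest-EV frame in which the
    pixel is unsaturated.  Pixels saturated in every frame keep the
    lowest-EV value and are flagged in the returned image's ``saturated``
    mask; downstream statistics include them, mimicking the eye's own
    saturation on bright sources.
    """
    merged = bracket.images[0].copy()  # lowest EV: the all-saturated fallback
    for image, sat in zip(bracket.images[1:], bracket.saturated[1:]):
        use = ~sat
        merged[use] = image[use]
    all_saturated = np.logical_and.reduce(bracket.saturated)
    return EquirectImage(pixels=merged, valid=bracket.valid, saturated=all_saturated)
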