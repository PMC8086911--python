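"""The full analysis chain from raw bracketed exposures to the results table.

Order of operations, matching the physics of the acquisition:

1. counts → linear photon radiance per frame (calibration, exposure metadata)
2. vignetting correction, in fisheye space where the off-axis angle is native
3. equisolid → equirectangular nearest-neighbour remap per frame
4. bracket median-normalization and HDR pixel selection
5. per-3°-bin statistics and the simplified summary
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .hdr import ExposureBracket, merge_hdr, normalize_bracket
from .projection import EquirectImage, FisheyeExposure, remap_to_equirect, theta_map
from .radiometry import CameraCalibration, counts_to_radiance, vignetting_correct
from .stats import ElevationStats, SimplifiedSummary, bin_statistics, simplified_summary
from .stats import N_BINS

__all__ = ["SceneResult", "bracket_to_equirect", "process_bracket"]


@dataclass
class SceneResult:
    """Everything computed for one scene."""

    image: EquirectImage  # merged HDR radiance
    stats: ElevationStats
    summary: SimplifiedSummary
    name: str = ""


def bracket_to_equirect(
    exposures: Sequence[FisheyeExposure],
    cal: CameraCalibration,
    out_size: Optional[int] = None,
) -> ExposureBracket:
    """Steps 1–3: calibrate, devignette and remap each frame of a bracket."""
    frames, evs = [], []
    for exp in exposures:
        radiance, saturated = counts_to_radiance(exp.pixels, exp.meta, cal)
        radiance = vignetting_correct(
            radiance, theta_map(exp), cal, exp.meta.f_number
        )
        calibrated = FisheyeExposure(
            pixels=radiance,
            meta=exp.meta,
            center=exp.center,
            radius_px=exp.radius_px,
            saturated=saturated,
        )
        frames.append(remap_to_equirect(calibrated, out_size=out_size))
        evs.append(exp.meta.ev_offset)
    return ExposureBracket.from_equirect(frames, evs)


def process_bracket(
    exposures: Sequence[FisheyeExposure],
    cal: CameraCalibration,
    out_size: Optional[int] = None,
    n_bins: int = N_BINS,
    normalization: str = "geometric",
    name: str = "",
) -> SceneResult:
    """Run the complete single-scene analysis on a raw exposure bracket."""
    bracket = bracket_to_equirect(exposures, cal, out_size=out_size)
    merged = merge_hdr(normalize_bracket(bracket, average=normalization))
    stats = bin_statistics(merged, n_bins=n_bins)
    return SceneResult(
        image=merged, stats=stats, summary=simplified_summary(stats), name=name
    )
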