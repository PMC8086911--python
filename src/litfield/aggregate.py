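"""Combining single-scene results into an environment description.

An *environment* is measured as 10–40 scenes taken from different vantage
points.  Their statistics tables are combined with the log-average

    x̄ = 10^{(1/n) Σ log10 x_i}   (the geometric mean),

applied per bin and band to the medians and percentiles.  Averaging in log
space matches how brightness is perceived, and it makes every scene count
equally: a scene that happened to be dimmer (a cloud crossing the sun)
shifts the aggregate by the same number of lit as a brighter one — scaling
one of n scenes by a factor c moves the aggregate by exactly c^(1/n).

Because the statistics tables store these quantities in lit already, the
log-average is an arithmetic mean of the stored values.  Extremes (min/max)
are pooled across scenes; an aggregated standard deviation is not defined
and is reported as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .projection import EquirectImage
from .stats import STATISTICS, ElevationStats

__all__ = ["EnvironmentResult", "aggregate_scenes", "average_image"]

_LOG_AVERAGED = ("mean", "median", "p25", "p75", "p2.5", "p97.5")


@dataclass
class EnvironmentResult:
    """A whole light environment: aggregated table plus the average image."""

    n_scenes: int
    stats: ElevationStats
    image: Optional[EquirectImage] = None
    name: str = ""
    scene_names: list[str] = field(default_factory=list)


def aggregate_scenes(
    scene_stats: Sequence[ElevationStats],
    images: Optional[Sequence[EquirectImage]] = None,
    name: str = "",
    scene_names: Optional[Sequence[str]] = None,
) -> EnvironmentResult:
    """Log-average a set of per-scene tables into one environment table.

    Medians, percentiles and means are geometric-mean averaged across scenes
    (scenes with an empty bin are excluded bin-wise); min and max are pooled;
    the standard deviation has no meaningful cross-scene aggregate and is
    set to missing.  Aggregating a single scene is the identity.
    """
    if not scene_stats:
        raise ValueError("need at least one scene")
    first = scene_stats[0]
    for s in scene_stats[1:]:
        if s.n_bins != first.n_bins or not np.allclose(
            s.bin_centers, first.bin_centers
        ):
            raise ValueError("scenes have mismatched elevation-bin structures")
        if set(s.data) != set(first.data):
            raise ValueError("scenes have mismatched spectral bands")

    n = len(scene_stats)
    if n == 1:
        stats = first
    else:
        data = {}
        for band in first.data:
            stacked = np.stack([s.data[band] for s in scene_stats])  # (n, bins, 9)
            out = np.full_like(stacked[0], np.nan)
            with np.errstate(invalid="ignore"):
                for stat in _LOG_AVERAGED:
                    j = STATISTICS.index(stat)
                    out[:, j] = np.nanmean(stacked[:, :, j], axis=0)
                out[:, STATISTICS.index("min")] = np.nanmin(
                    stacked[:, :, STATISTICS.index("min")], axis=0
                )
                out[:, STATISTICS.index("max")] = np.nanmax(
                    stacked[:, :, STATISTICS.index("max")], axis=0
                )
            data[band] = out
        stats = ElevationStats(
            bin_centers=first.bin_centers.copy(),
            counts=np.sum([s.counts for s in scene_stats], axis=0),
            data=data,
            n_scenes=n,
        )

    image = average_image(images) if images else None
    return EnvironmentResult(
        n_scenes=n,
        stats=stats,
        image=image,
        name=name,
        scene_names=list(scene_names or []),
    )


def average_image(images: Sequence[EquirectImage]) -> EquirectImage:
    """Per-pixel geometric mean of the scene images (the display average).

    Consistent with the log domain of the statistics; pixels masked invalid
    in a scene are excluded from that pixel's mean, and a pixel invalid in
    every scene stays invalid.
    """
    if not images:
        raise ValueError("need at least one image")
    shape = images[0].pixels.shape
    if any(im.pixels.shape != shape for im in images):
        raise ValueError("scene images have mismatched geometry")

    logs = np.stack(
        [
            np.where(im.valid[..., None], np.log10(im.pixels), np.nan)
            for im in images
        ]
    )
    with np.errstate(invalid="ignore"):
        mean_log = np.nanmean(logs, axis=0)
    valid = np.logical_or.reduce([im.valid for im in images])
    pixels = np.where(valid[..., None], 10.0 ** mean_log, 0.0)

    sats = [im.saturated for im in images if im.saturated is not None]
    saturated = np.logical_and.reduce(sats) if len(sats) == len(images) else None
    return EquirectImage(pixels=pixels, valid=valid, saturated=saturated)
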