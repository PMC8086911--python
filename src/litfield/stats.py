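"""Elevation-binned radiance statistics, contrast-spans and the summary table.

The central description of a light environment is a table of robust
statistics per 3° slice of elevation angle — 60 bins from +90° (zenith) down
to −90° (nadir) — for four spectral bands: the red, green and blue 100-nm
slots and their white union.  Per bin and band the table holds nine
statistics: mean, standard deviation, median, 25th/75th and 2.5th/97.5th
percentiles, minimum and maximum.  The distributional statistics are stored
on the lit (log10) scale; the standard deviation, whose log-width is
ill-defined, is kept in linear radiance units.

The median, not the mean, is the headline radiance because it is insensitive
to strong light sources covering few pixels; the inter-percentile widths
p75−p25 and p97.5−p2.5 are the 50% and 95% *contrast-spans*, the scene's
intensity range at that elevation.

Rows of the equirectangular raster are stretched towards the poles, but the
statistics are deliberately not solid-angle weighted within bins: the method
characterizes the distribution of radiances *per elevation angle*, so every
elevation contributes equally by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .projection import EquirectImage, row_elevations
from .radiometry import white_from_rgb

__all__ = [
    "N_BINS",
    "STATISTICS",
    "STAT_BANDS",
    "ElevationStats",
    "FieldSummary",
    "SimplifiedSummary",
    "bin_statistics",
    "contrast_span",
    "simplified_summary",
    "median_robustness_check",
]

#: 3° elevation slices from +90° down to −90°.
N_BINS = 60

#: Column order of the statistics block, matching the results spreadsheet.
STATISTICS = ("mean", "std", "median", "p25", "p75", "p2.5", "p97.5", "min", "max")

#: Band order of the spreadsheet blocks.
STAT_BANDS = ("white", "red", "green", "blue")

#: Percentile levels backing the 50% and 95% contrast-spans.
_PERCENTILES = (50.0, 25.0, 75.0, 2.5, 97.5)

_LIT_STATS = tuple(s for s in STATISTICS if s != "std")


@dataclass
class ElevationStats:
    """The per-scene (or per-environment) statistics table.

    ``data`` maps each band to an (n_bins × 9) array in ``STATISTICS`` column
    order; every column is in lit except ``std`` (linear radiance).  Bins
    with no valid pixels hold NaN.  ``counts`` is the number of pixels per
    bin, ``n_scenes`` how many scenes were aggregated into this table.
    """

    bin_centers: np.ndarray  # (n_bins,) elevation, +88.5 … −88.5 for 60 bins
    counts: np.ndarray  # (n_bins,)
    data: dict[str, np.ndarray]  # band → (n_bins, 9)
    n_scenes: int = 1

    @property
    def n_bins(self) -> int:
        return self.bin_centers.size

    def column(self, band: str, statistic: str) -> np.ndarray:
        return self.data[band][:, STATISTICS.index(statistic)]

    def assert_ordered(self) -> None:
        """Quantile ordering: min ≤ p2.5 ≤ p25 ≤ median ≤ p75 ≤ p97.5 ≤ max."""
        chain = ("min", "p2.5", "p25", "median", "p75", "p97.5", "max")
        for band in self.data:
            cols = [self.column(band, s) for s in chain]
            for lo, hi in zip(cols, cols[1:]):
                ok = np.isnan(lo) | np.isnan(hi) | (lo <= hi + 1e-12)
                if not ok.all():
                    raise AssertionError(
                        f"quantile ordering violated in band {band!r}"
                    )

    def to_frame(self) -> pd.DataFrame:
        """The spreadsheet layout: 60 rows × 37 columns.

        Column 1 is the bin-centre elevation; then one 9-column block per
        band in ``STAT_BANDS`` order, each block in ``STATISTICS`` order.
        """
        out = {"elevation": self.bin_centers}
        for band in STAT_BANDS:
            for j, stat in enumerate(STATISTICS):
                out[f"{band}_{stat}"] = self.data[band][:, j]
        return pd.DataFrame(out)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n_scenes: int = 1) -> "ElevationStats":
        data = {
            band: np.column_stack(
                [frame[f"{band}_{stat}"].to_numpy(float) for stat in STATISTICS]
            )
            for band in STAT_BANDS
        }
        counts = (
            frame["count"].to_numpy()
            if "count" in frame
            else np.zeros(len(frame), dtype=int)
        )
        return cls(
            bin_centers=frame["elevation"].to_numpy(float),
            counts=counts,
            data=data,
            n_scenes=n_scenes,
        )


def bin_index(elevation: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Bin membership by elevation: half-open [lo, hi), top bin closed at +90°."""
    width = 180.0 / n_bins
    idx = np.floor((90.0 - np.asarray(elevation, dtype=float)) / width).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def stats_bin_centers(n_bins: int = N_BINS) -> np.ndarray:
    width = 180.0 / n_bins
    return 90.0 - width * (np.arange(n_bins) + 0.5)


def _quantiles_type7(sorted_values: np.ndarray, percentiles) -> np.ndarray:
    """Linear interpolation between closest order statistics (type 7).

    Written out explicitly — ``s[f] + (h − f)·(s[f+1] − s[f])`` with virtual
    index h = (n−1)·p/100 — so the estimator is a fixed, documented formula
    rather than a library implementation detail.
    """
    n = sorted_values.size
    h = (n - 1) * (np.asarray(percentiles, dtype=float) / 100.0)
    f = np.floor(h).astype(int)
    upper = np.minimum(f + 1, n - 1)
    lo = sorted_values[f]
    return lo + (h - f) * (sorted_values[upper] - lo)


def _one_bin(values: np.ndarray) -> np.ndarray:
    """The nine statistics for one bin/band, from linear radiances.

    Order statistics interpolate between closest order statistics (type 7) —
    a monotone transform, so computing them on linear values then taking
    log10 equals computing them on logs.
    """
    row = np.empty(len(STATISTICS))
    mean = values.mean()
    row[0] = np.log10(mean)
    row[1] = values.std(ddof=0)  # linear units; log-width is ill-defined
    s = np.sort(values)
    row[2:7] = np.log10(_quantiles_type7(s, _PERCENTILES))
    row[7] = np.log10(s[0])
    row[8] = np.log10(s[-1])
    return row


def bin_statistics(image: EquirectImage, n_bins: int = N_BINS) -> ElevationStats:
    """Compute the statistics table for one radiance image.

    The white channel is formed per pixel (the mean of the three colour
    slots) before binning, so its order statistics describe the actual white
    pixel population.  Saturated pixels are *included* — their clipped values
    mimic the eye's own saturation — while geometrically invalid cells are
    excluded.  Empty bins yield NaN rows, never zeros.
    """
    m = image.size
    rows = bin_index(row_elevations(m), n_bins)

    pixels = image.pixels
    white = white_from_rgb(pixels)
    band_values = {
        "white": white,
        "red": pixels[..., 0],
        "green": pixels[..., 1],
        "blue": pixels[..., 2],
    }

    counts = np.zeros(n_bins, dtype=int)
    data = {band: np.full((n_bins, len(STATISTICS)), np.nan) for band in STAT_BANDS}
    for b in range(n_bins):
        in_bin = image.valid[rows == b]
        counts[b] = int(in_bin.sum())
        if counts[b] == 0:
            continue
        for band in STAT_BANDS:
            values = band_values[band][rows == b][in_bin]
            data[band][b] = _one_bin(values)

    stats = ElevationStats(
        bin_centers=stats_bin_centers(n_bins), counts=counts, data=data
    )
    stats.assert_ordered()
    return stats


def contrast_span(stats: ElevationStats, level: int) -> dict[str, np.ndarray]:
    """Per-bin contrast-span widths in lit, for each band.

    Level 50 is the interquartile width p75 − p25; level 95 is
    p97.5 − p2.5.
    """
    if level == 50:
        lo, hi = "p25", "p75"
    elif level == 95:
        lo, hi = "p2.5", "p97.5"
    else:
        raise ValueError(f"contrast-span level must be 50 or 95, got {level}")
    return {
        band: stats.column(band, hi) - stats.column(band, lo) for band in stats.data
    }


# ---------------------------------------------------------------------------
# simplified upper/lower-field summary
# ---------------------------------------------------------------------------

@dataclass
class FieldSummary:
    """White median, 95% span and RGB balance of one half of the view."""

    median_lit: float
    span95_lit: float
    rgb_percent: tuple[float, float, float]  # red, green, blue; sums to 100


@dataclass
class SimplifiedSummary:
    """The four-line table: upper field (+10°…+90°) and lower (−10°…−90°).

    The horizontal band (±10°), typically cluttered and uninformative, is
    ignored.
    """

    upper: FieldSummary
    lower: FieldSummary

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, f in (("upper (+10° to +90°)", self.upper),
                        ("lower (−10° to −90°)", self.lower)):
            rows.append(
                {
                    "field": name,
                    "white_median_lit": f.median_lit,
                    "span95_lit": f.span95_lit,
                    "red_%": f.rgb_percent[0],
                    "green_%": f.rgb_percent[1],
                    "blue_%": f.rgb_percent[2],
                }
            )
        return pd.DataFrame(rows)


def _field_summary(stats: ElevationStats, sel: np.ndarray) -> FieldSummary:
    med = np.nanmean(stats.column("white", "median")[sel])  # geometric mean, in lit
    span = np.nanmean(stats.column("white", "p97.5")[sel]) - np.nanmean(
        stats.column("white", "p2.5")[sel]
    )
    linear = np.array(
        [
            np.nanmean(10.0 ** stats.column(band, "median")[sel])
            for band in ("red", "green", "blue")
        ]
    )
    percent = tuple(100.0 * linear / linear.sum())
    return FieldSummary(float(med), float(span), percent)


def simplified_summary(stats: ElevationStats) -> SimplifiedSummary:
    """Collapse the table to the upper and lower fields of view.

    Per field: white radiance as the geometric mean (equal bin weight) of
    the bin medians; the 95% span between the geometric means of the bin
    percentile bounds; RGB percentages from the linear per-field mean of each
    colour band's bin medians.
    """
    upper = stats.bin_centers > 10.0
    lower = stats.bin_centers < -10.0
    return SimplifiedSummary(
        upper=_field_summary(stats, upper), lower=_field_summary(stats, lower)
    )


# ---------------------------------------------------------------------------
# robustness check (test utility)
# ---------------------------------------------------------------------------

def median_robustness_check(
    image: EquirectImage,
    fraction_replaced: float,
    replacement_factor: float = 10.0,
    rng: Optional[np.random.Generator] = None,
) -> bool:
    """Verify the bin medians shrug off small bright contaminations.

    Replaces ``fraction_replaced`` (< 0.5) of each bin's pixels with
    ``replacement_factor`` × the image maximum and checks every bin median
    still comes from the original pixel population: replacing k of n values
    with arbitrarily bright ones can raise the median by at most k ranks,
    i.e. to the original 50 + 100·k/(n−1) percentile, never beyond.  This is
    the operational justification for reporting medians — point sources
    covering a small part of a bin cannot drag them.
    """
    if not 0.0 <= fraction_replaced < 0.5:
        raise ValueError("fraction_replaced must be in [0, 0.5)")
    rng = rng or np.random.default_rng(0)
    before = bin_statistics(image)
    m = image.size
    rows = bin_index(row_elevations(m), before.n_bins)

    pixels = image.pixels.copy()
    bright = replacement_factor * pixels.max()
    for b in range(before.n_bins):
        flat = np.flatnonzero((rows == b)[:, None] & image.valid)
        k = int(np.floor(fraction_replaced * flat.size))
        if k == 0:
            continue
        chosen = rng.choice(flat, size=k, replace=False)
        i, j = np.unravel_index(chosen, image.valid.shape)
        pixels[i, j, :] = bright
    after = bin_statistics(
        EquirectImage(pixels=pixels, valid=image.valid, saturated=image.saturated)
    )

    # exact order-statistic bound on the shifted median
    white = white_from_rgb(image.pixels)
    for b in range(before.n_bins):
        if before.counts[b] == 0:
            continue
        originals = white[rows == b][image.valid[rows == b]]
        n = originals.size
        k = int(np.floor(fraction_replaced * n))
        # one order statistic of slack for interpolation at the rank boundary
        level = 50.0 + 100.0 * (k + 1) / max(n - 1, 1)
        bound = np.log10(np.percentile(originals, min(100.0, level)))
        new = after.column("white", "median")[b]
        old = before.column("white", "median")[b]
        if not (old - 1e-9 <= new <= bound + 1e-9):
            return False
    return True
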