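"""The standard four-panel chart for one scene or environment.

Layout (landscape, sized so two charts fit an A4 page):

1. the remapped (or average) radiance image, laterally compressed;
2. the main diagram — absolute radiance (lit, x) versus elevation angle
   (degrees, y): median curves for the red, green and blue bands, a black
   curve for white light, and the white-light 50% (dark grey) and 95%
   (light grey) contrast-span envelopes, with dashed guide levels for
   typical regimes (starlight … sunlight);
3. spectral balance — each colour band's median minus the white median;
4. contrast — the 50% and 95% span widths versus elevation.

Panels 3 and 4 repeat information already present in panel 2, normalized to
the white curve so colour and contrast structure is legible independent of
absolute level.  Every number plotted is read from the results object; the
plotting code computes nothing.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .aggregate import EnvironmentResult
from .io import tone_map
from .pipeline import SceneResult
from .stats import contrast_span

__all__ = ["GUIDE_LEVELS", "make_chart"]

#: Dashed guide levels (lit) — arbitrary orientation marks, not measurements.
GUIDE_LEVELS = {
    "starlight": 9.0,
    "moonlight": 11.0,
    "twilight": 13.0,
    "overcast": 15.5,
    "sunlight": 17.0,
}

_BAND_COLORS = {"white": "black", "red": "#cc2222", "green": "#22aa22", "blue": "#2244cc"}


def make_chart(
    result: Union[SceneResult, EnvironmentResult],
    path: Optional[Union[str, Path]] = None,
    name: Optional[str] = None,
    time_label: str = "",
    guide_levels: Optional[dict[str, float]] = None,
):
    """Render the chart; optionally save as editable PDF plus a small JPG.

    ``path`` names the PDF; a JPG with the same stem is written alongside.
    Returns the matplotlib Figure (all plotted data can be inspected on it).
    """
    stats = result.stats
    guide_levels = GUIDE_LEVELS if guide_levels is None else guide_levels
    name = name or getattr(result, "name", "") or "scene"
    n_scenes = getattr(result, "n_scenes", 1)

    elev = stats.bin_centers
    span50 = contrast_span(stats, 50)
    span95 = contrast_span(stats, 95)
    white_med = stats.column("white", "median")

    fig = plt.figure(figsize=(11.0, 4.2))
    grid = fig.add_gridspec(
        2, 3, width_ratios=[1.0, 2.6, 1.3], wspace=0.32, hspace=0.35
    )
    ax_img = fig.add_subplot(grid[:, 0])
    ax_main = fig.add_subplot(grid[:, 1])
    ax_color = fig.add_subplot(grid[0, 2])
    ax_span = fig.add_subplot(grid[1, 2])

    # (i) laterally compressed image
    image = getattr(result, "image", None)
    if image is not None:
        ax_img.imshow(tone_map(image), extent=[-90, 90, -90, 90], aspect=0.45)
        ax_img.set_xticks([])
    ax_img.set_yticks([-90, 0, 90])
    ax_img.set_ylabel("elevation (°)")
    ax_img.set_title(f"{name}" + (f"  (n={n_scenes})" if n_scenes > 1 else ""),
                     fontsize=9, loc="left")
    if time_label:
        ax_img.set_xlabel(time_label, fontsize=8)

    # (ii) main diagram: radiance vs elevation with span envelopes
    ax_main.fill_betweenx(
        elev,
        stats.column("white", "p2.5"),
        stats.column("white", "p97.5"),
        color="0.85",
        label="95% span",
    )
    ax_main.fill_betweenx(
        elev,
        stats.column("white", "p25"),
        stats.column("white", "p75"),
        color="0.65",
        label="50% span",
    )
    for band in ("red", "green", "blue", "white"):
        ax_main.plot(
            stats.column(band, "median"), elev, color=_BAND_COLORS[band], lw=1.4
        )
    finite = white_med[np.isfinite(white_med)]
    for label, level in guide_levels.items():
        ax_main.axvline(level, ls="--", lw=0.6, color="0.4")
        ax_main.text(level, 91, label, rotation=45, fontsize=6, color="0.4",
                     ha="left", va="bottom")
    if finite.size:
        lo = min(finite.min(), np.nanmin(stats.column("white", "p2.5"))) - 0.4
        hi = max(finite.max(), np.nanmax(stats.column("white", "p97.5"))) + 0.4
        ax_main.set_xlim(lo, hi)
    ax_main.set_ylim(-90, 90)
    ax_main.set_yticks([-90, -45, 0, 45, 90])
    ax_main.axhline(0, color="0.7", lw=0.5)
    ax_main.set_xlabel("photon radiance (lit = log₁₀ photons s⁻¹ m⁻² sr⁻¹ nm⁻¹)")
    ax_main.set_ylabel("elevation (°)")

    # (iii) spectral balance, normalized to white
    for band in ("red", "green", "blue"):
        ax_color.plot(
            stats.column(band, "median") - white_med,
            elev,
            color=_BAND_COLORS[band],
            lw=1.2,
        )
    ax_color.axvline(0, color="0.6", lw=0.5)
    ax_color.set_ylim(-90, 90)
    ax_color.set_yticks([-90, 0, 90])
    ax_color.set_xlabel("colour − white (lit)", fontsize=8)
    ax_color.tick_params(labelsize=7)

    # (iv) contrast-span widths
    ax_span.plot(span50["white"], elev, color="0.45", lw=1.2, label="50%")
    ax_span.plot(span95["white"], elev, color="0.75", lw=1.2, label="95%")
    ax_span.set_ylim(-90, 90)
    ax_span.set_yticks([-90, 0, 90])
    ax_span.set_xlim(left=0)
    ax_span.set_xlabel("contrast-span (lit)", fontsize=8)
    ax_span.tick_params(labelsize=7)
    ax_span.legend(fontsize=6, frameon=False)

    if path is not None:
        path = Path(path)
        fig.savefig(path, format="pdf", bbox_inches="tight")
        fig.savefig(path.with_suffix(".jpg"), dpi=110, bbox_inches="tight")
    return fig
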