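import math

import numpy as np
import pytest

from litfield import (
    EquirectImage,
    bin_statistics,
    contrast_span,
    median_robustness_check,
    simplified_summary,
)
from litfield.projection import row_elevations
from litfield.stats import (
    N_BINS,
    STAT_BANDS,
    STATISTICS,
    bin_index,
)
from conftest import lognormal_image


# ---------------------------------------------------------------------------
# independent brute-force oracle: pure-Python sort + type-7 interpolation
# ---------------------------------------------------------------------------

def _percentile_type7(sorted_vals, p):
    h = (len(sorted_vals) - 1) * (p / 100.0)
    f = math.floor(h)
    if f + 1 >= len(sorted_vals):
        return sorted_vals[-1]
    return sorted_vals[f] + (h - f) * (sorted_vals[f + 1] - sorted_vals[f])


def _log10(x):
    # the same elementary log10 the package uses for the lit conversion, so
    # the comparison isolates the sorting/binning/interpolation arithmetic
    return float(np.log10(x))


def brute_force_bin_stats(image, n_bins=N_BINS):
    """Per-pixel loop, python sort, manual interpolation — no numpy stats."""
    m = image.size
    elevations = row_elevations(m)
    bins = {b: {band: [] for band in STAT_BANDS} for b in range(n_bins)}
    width = 180.0 / n_bins
    for i in range(m):
        b = min(int((90.0 - elevations[i]) // width), n_bins - 1)
        for j in range(m):
            if not image.valid[i, j]:
                continue
            r, g, bl = image.pixels[i, j]
            bins[b]["white"].append((r + g + bl) / 3.0)
            bins[b]["red"].append(r)
            bins[b]["green"].append(g)
            bins[b]["blue"].append(bl)
    out = {}
    for b, bands in bins.items():
        out[b] = {}
        for band, vals in bands.items():
            if not vals:
                out[b][band] = None
                continue
            s = sorted(vals)
            n = len(s)
            mean = math.fsum(s) / n
            var = math.fsum((x - mean) ** 2 for x in s) / n
            out[b][band] = {
                "mean": _log10(mean),
                "std": math.sqrt(var),
                "median": _log10(_percentile_type7(s, 50)),
                "p25": _log10(_percentile_type7(s, 25)),
                "p75": _log10(_percentile_type7(s, 75)),
                "p2.5": _log10(_percentile_type7(s, 2.5)),
                "p97.5": _log10(_percentile_type7(s, 97.5)),
                "min": _log10(s[0]),
                "max": _log10(s[-1]),
            }
    return out


class TestBinStatistics:
    def test_constant_image(self, constant_image):
        stats = bin_statistics(constant_image)
        assert stats.n_bins == N_BINS
        for band in STAT_BANDS:
            assert np.allclose(stats.column(band, "median"), 16.0)
            assert np.allclose(stats.column(band, "p2.5"), 16.0)
            assert np.allclose(contrast_span(stats, 95)[band], 0.0)

    def test_sixty_bins_partition_all_valid_pixels(self, rng):
        m = 120
        valid = rng.uniform(size=(m, m)) > 0.3
        image = EquirectImage(pixels=rng.uniform(1, 2, (m, m, 3)), valid=valid)
        stats = bin_statistics(image)
        assert stats.counts.sum() == valid.sum()

    def test_empty_bins_are_missing_not_zero(self, rng):
        m = 120
        valid = np.ones((m, m), dtype=bool)
        valid[:20] = False  # kill the top bins entirely
        image = EquirectImage(pixels=rng.uniform(1, 2, (m, m, 3)), valid=valid)
        stats = bin_statistics(image)
        empty = stats.counts == 0
        assert empty.any()
        assert np.isnan(stats.column("white", "median")[empty]).all()

    def test_lognormal_monte_carlo_span(self):
        # per-pixel lit ~ N(14, 0.25): 95% span = 2*1.96*0.25 = 0.98 lit
        image = lognormal_image(14.0, 0.25, size=700, seed=5)
        stats = bin_statistics(image, n_bins=4)  # >1e5 samples per bin
        span = contrast_span(stats, 95)["white"]
        assert np.all(np.abs(span - 0.98) < 0.02)
        assert np.all(np.abs(stats.column("white", "median") - 14.0) < 0.01)

    def test_quantile_ordering_invariant(self, rng):
        image = EquirectImage(
            pixels=10 ** rng.uniform(10, 18, (64, 64, 3)),
            valid=rng.uniform(size=(64, 64)) > 0.2,
        )
        bin_statistics(image).assert_ordered()  # raises on violation

    def test_matches_brute_force_oracle_exactly(self, rng):
        image = EquirectImage(
            pixels=10 ** rng.uniform(12, 17, (60, 60, 3)),
            valid=rng.uniform(size=(60, 60)) > 0.1,
        )
        stats = bin_statistics(image)
        oracle = brute_force_bin_stats(image)
        order_stats = ("median", "p25", "p75", "p2.5", "p97.5", "min", "max")
        for b in range(N_BINS):
            for band in STAT_BANDS:
                if oracle[b][band] is None:
                    assert stats.counts[b] == 0
                    continue
                for stat in order_stats:
                    got = stats.column(band, stat)[b]
                    assert got == oracle[b][band][stat], (b, band, stat)
                for stat in ("mean", "std"):
                    got = stats.column(band, stat)[b]
                    assert got == pytest.approx(oracle[b][band][stat], rel=1e-12)

    def test_resolution_stability(self, sloped_spec):
        # the same rendered scene analysed at raster sizes M and 2M must give
        # the same bin medians: the binning cannot depend on the remap grid
        from litfield import (
            SynthSceneSpec,
            make_truth,
            process_bracket,
            render_bracket,
            synthetic_calibration,
        )

        cal = synthetic_calibration(radius_px=160)
        knots = [(-90.0, 13.8), (-30.0, 14.0), (30.0, 14.6), (90.0, 14.8)]
        smooth = SynthSceneSpec(
            profiles={"red": knots, "green": list(knots), "blue": list(knots)},
            sigma=0.0,
            name="smooth",
        )
        truth = make_truth(smooth, size=320)
        exposures = render_bracket(truth, cal)
        # raster sizes divisible by the bin count, so row centres cannot
        # alias against bin edges (documented numerical guidance)
        med = {
            m: process_bracket(exposures, cal, out_size=m).stats.column(
                "white", "median"
            )
            for m in (240, 480)
        }
        assert np.nanmax(np.abs(med[240] - med[480])) < 0.02


class TestContrastSpan:
    def test_definition_and_nesting(self, rng):
        image = EquirectImage(
            pixels=10 ** rng.uniform(12, 16, (64, 64, 3)),
            valid=np.ones((64, 64), bool),
        )
        stats = bin_statistics(image)
        s50, s95 = contrast_span(stats, 50), contrast_span(stats, 95)
        for band in STAT_BANDS:
            assert np.allclose(
                s95[band],
                stats.column(band, "p97.5") - stats.column(band, "p2.5"),
            )
            assert np.all(s95[band] >= s50[band] - 1e-12)

    def test_rejects_other_levels(self, constant_image):
        stats = bin_statistics(constant_image)
        with pytest.raises(ValueError):
            contrast_span(stats, 90)


class TestMedianRobustness:
    @pytest.mark.parametrize("fraction", [0.0, 0.05, 0.49])
    def test_bright_contamination_cannot_drag_medians(self, fraction):
        image = lognormal_image(14.0, 0.2, size=180, seed=6)
        assert median_robustness_check(image, fraction)

    def test_half_replacement_is_out_of_contract(self, constant_image):
        with pytest.raises(ValueError):
            median_robustness_check(constant_image, 0.5)


class TestSimplifiedSummary:
    def test_constant_scene(self, constant_image):
        summary = simplified_summary(bin_statistics(constant_image))
        for f in (summary.upper, summary.lower):
            assert f.median_lit == pytest.approx(16.0)
            assert f.span95_lit == pytest.approx(0.0, abs=1e-9)
            assert np.allclose(f.rgb_percent, 100 / 3)
            assert sum(f.rgb_percent) == pytest.approx(100.0, abs=0.1)

    def test_horizon_symmetric_scene_gives_equal_fields(self, rng):
        m = 120
        half = 10 ** rng.uniform(13, 15, (m // 2, m, 3))
        pixels = np.concatenate([half, half[::-1]], axis=0)
        image = EquirectImage(pixels=pixels, valid=np.ones((m, m), bool))
        summary = simplified_summary(bin_statistics(image))
        assert summary.upper.median_lit == pytest.approx(summary.lower.median_lit)
        assert summary.upper.span95_lit == pytest.approx(summary.lower.span95_lit)

    def test_horizontal_band_is_ignored(self, constant_image):
        # poison the horizon band; the field summaries must not move
        # (rows within the innermost bins of the +-10 degree band)
        pixels = constant_image.pixels.copy()
        m = constant_image.size
        elev = row_elevations(m)
        pixels[np.abs(elev) < 9, :, :] = 1e20
        poisoned = EquirectImage(pixels=pixels, valid=constant_image.valid)
        summary = simplified_summary(bin_statistics(poisoned))
        assert summary.upper.median_lit == pytest.approx(16.0)
        assert summary.lower.median_lit == pytest.approx(16.0)
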