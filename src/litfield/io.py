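"""Reading exposure brackets and writing the standard result files.

The interchange format for raw input is deliberately simple: one linear
floating-point or 16-bit TIFF per exposure (3-plane, red/green/blue) plus a
JSON sidecar carrying the exposure metadata and image-circle geometry.
Camera-raw decoding is out of the package's scope; any external decoder that
produces linear 3-plane counts and the same metadata satisfies the contract
(see :func:`read_exposure`'s ``decoder`` hook).  Gamma-encoded 8-bit images
are rejected outright — the radiometric chain is meaningless without linear
data.

Results are written as the 60-row × 37-column spreadsheet (XLSX and CSV),
the merged radiance image as uncompressed TIFF (with the all-saturated mask
as a fourth plane) plus a small tone-mapped JPG preview.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .aggregate import EnvironmentResult
from .pipeline import SceneResult
from .projection import EquirectImage, FisheyeExposure
from .radiometry import CameraCalibration, ExposureMeta

__all__ = [
    "write_exposure",
    "read_exposure",
    "read_bracket",
    "write_results",
    "read_results_csv",
    "write_equirect_tiff",
    "tone_map",
]


# ---------------------------------------------------------------------------
# exposures
# ---------------------------------------------------------------------------

def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def write_exposure(path, exposure: FisheyeExposure) -> None:
    """Write one fisheye frame as linear float32 TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, exposure.pixels.astype(np.float32), photometric="rgb")
    meta = exposure.meta.to_dict()
    meta.update(
        {
            "center_xy": list(exposure.center),
            "radius_px": exposure.radius_px,
            "model": exposure.model,
        }
    )
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_exposure(
    path, decoder: Optional[Callable[[Path], np.ndarray]] = None
) -> FisheyeExposure:
    """Read one frame (linear TIFF + sidecar) back into a FisheyeExposure.

    ``decoder`` may be supplied to ingest other formats (e.g. a camera-raw
    reader); it must return linear H×W×3 counts for the given path.  8-bit
    input is refused: consumer formats are gamma-encoded and useless for
    radiometry.
    """
    path = Path(path)
    pixels = decoder(path) if decoder else tifffile.imread(path)
    pixels = np.asarray(pixels)
    if pixels.dtype == np.uint8:
        raise ValueError(
            f"{path}: 8-bit input is almost certainly gamma-encoded; the "
            "pipeline requires linear data (float or ≥16-bit TIFF)"
        )
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"{path}: expected a 3-plane (RGB) image, got {pixels.shape}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"{path}: missing metadata sidecar {sidecar.name}")
    meta_dict = json.loads(sidecar.read_text())
    meta = ExposureMeta.from_dict(meta_dict)
    for key in ("center_xy", "radius_px"):
        if key not in meta_dict:
            raise KeyError(f"{sidecar}: missing geometry field {key!r}")
    return FisheyeExposure(
        pixels=pixels.astype(float),
        meta=meta,
        center=tuple(meta_dict["center_xy"]),
        radius_px=float(meta_dict["radius_px"]),
        model=meta_dict.get("model", "equisolid"),
    )


def read_bracket(
    source, decoder: Optional[Callable[[Path], np.ndarray]] = None
) -> list[FisheyeExposure]:
    """Read a directory (or explicit list) of exposures, ordered by EV."""
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        paths = sorted(Path(source).glob("*.tif")) + sorted(
            Path(source).glob("*.tiff")
        )
    else:
        paths = [Path(p) for p in source]
    if not paths:
        raise FileNotFoundError(f"no TIFF exposures found in {source}")
    exposures = [read_exposure(p, decoder=decoder) for p in paths]
    exposures.sort(key=lambda e: e.meta.ev_offset)
    return exposures


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def tone_map(image: EquirectImage, percentile: float = 99.0) -> np.ndarray:
    """Display-only mapping of a radiance image to 8-bit sRGB-ish values."""
    pixels = image.pixels
    scale = np.percentile(pixels[image.valid], percentile) if image.valid.any() else 1.0
    x = np.clip(pixels / max(scale, np.finfo(float).tiny), 0.0, 1.0)
    x = x ** (1.0 / 2.2)
    x[~image.valid] = 0.0
    return (255.0 * x + 0.5).astype(np.uint8)


def write_equirect_tiff(path, image: EquirectImage) -> None:
    """Uncompressed float32 TIFF; the all-saturated mask rides as plane 4."""
    planes = image.pixels.astype(np.float32)
    if image.saturated is not None:
        mask = image.saturated.any(axis=-1).astype(np.float32)[..., None]
        planes = np.concatenate([planes, mask], axis=-1)
    tifffile.imwrite(Path(path), planes, photometric="rgb")


def write_results(
    result: SceneResult | EnvironmentResult, outdir, name: Optional[str] = None
) -> dict[str, Path]:
    """Write the spreadsheet (XLSX + CSV), radiance TIFF and JPG preview.

    The spreadsheet has exactly one data row per elevation bin (60 by
    default) and 37 columns; missing bins stay as empty cells.  For an
    environment an extra ``metadata`` sheet records the scene count.
    Returns the mapping of artefact kind to written path.
    """
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    name = name or getattr(result, "name", "") or "scene"
    stats = result.stats
    frame = stats.to_frame()

    paths = {
        "csv": outdir / f"{name}.csv",
        "xlsx": outdir / f"{name}.xlsx",
    }
    try:
        frame.to_csv(paths["csv"], index=False, float_format="%.6f", na_rep="")
        with pd.ExcelWriter(paths["xlsx"], engine="openpyxl") as writer:
            frame.to_excel(writer, sheet_name="elevation_stats", index=False)
            meta_rows = {"n_scenes": getattr(result, "n_scenes", 1)}
            pd.DataFrame([meta_rows]).to_excel(
                writer, sheet_name="metadata", index=False
            )
        image = result.image
        if image is not None:
            paths["tiff"] = outdir / f"{name}.tif"
            paths["jpg"] = outdir / f"{name}.jpg"
            write_equirect_tiff(paths["tiff"], image)
            iio.imwrite(paths["jpg"], tone_map(image))
    except OSError as err:
        raise OSError(f"failed writing results under {outdir}: {err}") from err
    return paths


def read_results_csv(path) -> pd.DataFrame:
    """Round-trip reader for the CSV spreadsheet."""
    return pd.read_csv(path)
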