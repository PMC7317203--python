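"""Raw cube → per-plant 31-band first-derivative profiles.

The chain is fixed: white calibration → band subsetting (619.5-983.0 nm,
93 bands) → NDVI pixel masking → per-plant averaging → 3x spectral binning
(31 bands) → first-derivative spectra.  Each step validates its input shape
so the chain cannot be re-applied to its own output by accident.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .synth_scene import (
    BACKGROUND,
    N_SUBSET_BANDS,
    SUBSET_HI_NM,
    SUBSET_LO_NM,
    SpectralCube,
    WHITE_PANEL,
    WavelengthGrid,
)

log = logging.getLogger(__name__)

#: strict NDVI inclusion windows per crop (lo < NDVI < hi)
NDVI_BOUNDS = {"bok_choy": (0.55, 0.70), "spinach": (0.54, 0.85)}

#: classical red / near-infrared wavelengths used for the NDVI filter
NDVI_RED_NM = 670.0
NDVI_NIR_NM = 800.0

CALIBRATION_CLIP = (0.0, 1.5)
BINNING_FACTOR = 3


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate(cube: SpectralCube) -> SpectralCube:
    """Convert raw digital numbers to reflectance by white-panel ratio.

    reflectance = raw / white_reference, per band; values outside
    ``CALIBRATION_CLIP`` are clipped and counted in a warning.
    """
    if cube.calibrated:
        raise ValueError("cube is already calibrated")
    if np.any(cube.white_reference <= 0):
        bad = int(np.argmax(cube.white_reference <= 0))
        raise ValueError(f"white reference non-positive in band {bad}")
    refl = cube.values / cube.white_reference
    n_out = int(np.sum((refl < CALIBRATION_CLIP[0]) | (refl > CALIBRATION_CLIP[1])))
    if n_out:
        warnings.warn(f"calibration clipped {n_out} values outside {CALIBRATION_CLIP}")
        refl = np.clip(refl, *CALIBRATION_CLIP)
    return SpectralCube(
        values=refl,
        grid=cube.grid,
        white_reference=np.ones_like(cube.white_reference),
        truth_mask=cube.truth_mask,
        calibrated=True,
    )


# ---------------------------------------------------------------------------
# Band subsetting
# ---------------------------------------------------------------------------

def _band_cols(frame: pd.DataFrame) -> list[str]:
    return [c for c in frame.columns if c.startswith("b") and c[1].isdigit()]


def frame_grid(frame: pd.DataFrame) -> np.ndarray:
    """Band centers (nm) encoded in a profile frame's column names."""
    return np.array([float(c[1:]) for c in _band_cols(frame)])


def subset_bands(data, lo_nm: float = SUBSET_LO_NM, hi_nm: float = SUBSET_HI_NM):
    """Retain bands whose centers lie in the closed interval [lo, hi].

    Accepts a :class:`SpectralCube` or a profile frame; returns the same
    type.  The defaults drop the 23 noisy blue-green bands, keeping the 93
    bands analysed downstream.
    """
    if lo_nm > hi_nm:
        raise ValueError("lo_nm must not exceed hi_nm")
    if isinstance(data, SpectralCube):
        keep = (data.grid.centers >= lo_nm) & (data.grid.centers <= hi_nm)
        if not keep.any():
            raise ValueError("band subset is empty")
        return SpectralCube(
            values=data.values[:, :, keep],
            grid=WavelengthGrid(data.grid.centers[keep]),
            white_reference=data.white_reference[keep],
            truth_mask=data.truth_mask,
            calibrated=data.calibrated,
        )
    frame = data
    centers = frame_grid(frame)
    cols = _band_cols(frame)
    keep_cols = [c for c, w in zip(cols, centers) if lo_nm <= w <= hi_nm]
    if not keep_cols:
        raise ValueError("band subset is empty")
    meta = [c for c in frame.columns if c not in cols]
    return frame[meta + keep_cols].copy()


# ---------------------------------------------------------------------------
# NDVI masking
# ---------------------------------------------------------------------------

def ndvi(reflectance: np.ndarray, red_index: int, nir_index: int) -> np.ndarray:
    """(NIR − red) / (NIR + red) along the last (band) axis.

    Pixels whose red+NIR sum is zero yield NaN and are excluded by any
    threshold comparison.
    """
    red = np.asarray(reflectance)[..., red_index]
    nir = np.asarray(reflectance)[..., nir_index]
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (nir - red) / np.where(denom > 0, denom, 1.0), np.nan)
    return out


def ndvi_band_indices(
    grid: WavelengthGrid | np.ndarray,
    red_nm: float = NDVI_RED_NM,
    nir_nm: float = NDVI_NIR_NM,
) -> tuple[int, int]:
    """Indices of the bands nearest the classical NDVI wavelengths."""
    centers = grid.centers if isinstance(grid, WavelengthGrid) else np.asarray(grid)
    return int(np.argmin(np.abs(centers - red_nm))), int(np.argmin(np.abs(centers - nir_nm)))


def mask_pixels(
    cube: SpectralCube,
    crop: str,
    bounds: tuple[float, float] | None = None,
) -> dict[int, np.ndarray]:
    """Retain plant pixels passing the strict per-crop NDVI window.

    Returns ``{plant_id: (row_idx, col_idx)}`` for retained pixels.  The
    comparison is strict at both ends.  Plants losing every pixel are
    dropped with a warning; background and panel pixels are never retained.
    """
    if not cube.calibrated:
        raise ValueError("mask_pixels expects a calibrated cube")
    if bounds is None:
        try:
            bounds = NDVI_BOUNDS[crop]
        except KeyError:
            raise ValueError(f"unknown crop {crop!r}; expected one of {list(NDVI_BOUNDS)}")
    lo, hi = bounds
    red_i, nir_i = ndvi_band_indices(cube.grid)
    values = ndvi(cube.values, red_i, nir_i)
    inside = (values > lo) & (values < hi)      # strict at both ends

    retained: dict[int, np.ndarray] = {}
    for pid in cube.plant_ids:
        sel = (cube.truth_mask == pid) & inside
        idx = np.nonzero(sel)
        if len(idx[0]) == 0:
            warnings.warn(f"plant {pid} has no pixels inside NDVI window; excluded")
            continue
        retained[int(pid)] = idx
    return retained


# ---------------------------------------------------------------------------
# Averaging
# ---------------------------------------------------------------------------

def average_profiles(
    cube: SpectralCube,
    retained: dict[int, np.ndarray],
    labels=None,
) -> pd.DataFrame:
    """Per-plant arithmetic mean reflectance over retained pixels.

    Returns a profile frame (one row per plant, band columns named by
    center); treatment metadata is joined from ``labels`` when given.
    """
    if not cube.calibrated:
        raise ValueError("average_profiles expects a calibrated cube")
    by_id = {l.plant_id: l for l in labels} if labels is not None else {}
    rows = []
    band_cols = [f"b{c:.2f}" for c in cube.grid.centers]
    for pid, idx in sorted(retained.items()):
        spec = cube.values[idx].mean(axis=0)
        row = {"plant_id": pid, "n_pixels": len(idx[0])}
        lab = by_id.get(pid)
        if lab is not None:
            row.update(
                series=lab.series,
                period=lab.period,
                fertilizer=lab.fertilizer,
                infested=lab.infested,
                assigned=lab.assigned,
            )
        row.update(dict(zip(band_cols, spec)))
        rows.append(row)
    frame = pd.DataFrame(rows)
    meta = [c for c in ("plant_id", "series", "period", "fertilizer",
                        "infested", "assigned", "n_pixels") if c in frame.columns]
    return frame[meta + band_cols]


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def bin_spectra(frame: pd.DataFrame, factor: int = BINNING_FACTOR) -> pd.DataFrame:
    """Average contiguous groups of ``factor`` bands (93 → 31 by default).

    New band centers are the mean of the member centers.  A band count not
    divisible by ``factor`` is an error: partial bins are never formed.
    """
    cols = _band_cols(frame)
    if len(cols) % factor != 0:
        raise ValueError(f"{len(cols)} bands not divisible by binning factor {factor}")
    centers = frame_grid(frame)
    values = frame[cols].to_numpy(dtype=float)
    n_out = len(cols) // factor
    binned = values.reshape(len(frame), n_out, factor).mean(axis=2)
    new_centers = centers.reshape(n_out, factor).mean(axis=1)
    meta = [c for c in frame.columns if c not in cols]
    out = frame[meta].copy().reset_index(drop=True)
    for i, c in enumerate(new_centers):
        out[f"b{c:.2f}"] = binned[:, i]
    return out


# ---------------------------------------------------------------------------
# First derivative
# ---------------------------------------------------------------------------

def first_derivative(frame: pd.DataFrame, keep_length: bool = True) -> pd.DataFrame:
    """Forward finite-difference derivative of each profile.

    d[i] = (r[i+1] − r[i]) / (λ[i+1] − λ[i]), indexed by the left band.  With
    ``keep_length=True`` (default) the last difference is repeated so the
    derivative spectrum keeps the binned band count (31), matching the
    downstream per-band analyses; otherwise the output has n−1 values.
    """
    cols = _band_cols(frame)
    if len(cols) < 2:
        raise ValueError("derivative needs at least two bands")
    centers = frame_grid(frame)
    dlam = np.diff(centers)
    if np.any(dlam == 0):
        raise ValueError("duplicate wavelengths in grid")
    values = frame[cols].to_numpy(dtype=float)
    deriv = np.diff(values, axis=1) / dlam
    out_centers = centers[:-1]
    if keep_length:
        deriv = np.column_stack([deriv, deriv[:, -1]])
        out_centers = centers
    meta = [c for c in frame.columns if c not in cols]
    out = frame[meta].copy().reset_index(drop=True)
    for i, c in enumerate(out_centers):
        out[f"d{c:.2f}"] = deriv[:, i]
    return out


def derivative_columns(frame: pd.DataFrame) -> list[str]:
    return [c for c in frame.columns if c.startswith("d") and c[1].isdigit()]


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def cube_to_derivatives(cube: SpectralCube, crop: str, labels=None) -> pd.DataFrame:
    """Run calibrate → subset → mask → average → bin → derivative on a cube."""
    refl = calibrate(cube)
    refl = subset_bands(refl)
    retained = mask_pixels(refl, crop)
    profiles = average_profiles(refl, retained, labels)
    return first_derivative(bin_spectra(profiles))


def profiles_to_derivatives(frame: pd.DataFrame) -> pd.DataFrame:
    """Subset → bin → derivative for already-averaged reflectance profiles."""
    return first_derivative(bin_spectra(subset_bands(frame)))
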