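"""File formats, run configuration, and report generation.

Tabular artifacts are plain CSV; hyperspectral cubes use the ENVI
convention (a text ``.hdr`` describing a raw band-sequential or
band-interleaved raster); configurations and serialized models are JSON.
The published true-validation confusion tables for both crops ship as
packaged CSV fixtures so table-level metrics can be recomputed without any
external data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .assessment import ConfusionTable, SweepResult, SWEEP_FRACTIONS, DEFAULT_N_ITER
from .band_screen import DEFAULT_ALPHA, ScreenMap
from .preprocess import BINNING_FACTOR, NDVI_BOUNDS, SUBSET_HI_NM, SUBSET_LO_NM
from .synth_scene import SpectralCube, WavelengthGrid

log = logging.getLogger("nightscan")

PROFILE_META_COLUMNS = (
    "plant_id", "series", "period", "fertilizer", "infested", "n_pixels",
)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated end-to-end run parameters; defaults are the study values."""

    crop: str = "bok_choy"
    ndvi_bounds: tuple[float, float] | None = None
    subset_lo_nm: float = SUBSET_LO_NM
    subset_hi_nm: float = SUBSET_HI_NM
    binning_factor: int = BINNING_FACTOR
    alpha: float = DEFAULT_ALPHA
    sweep_fractions: tuple[float, ...] = SWEEP_FRACTIONS
    sweep_n_iter: int = DEFAULT_N_ITER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crop not in NDVI_BOUNDS:
            raise ValueError(f"unknown crop {self.crop!r}")
        if self.ndvi_bounds is None:
            self.ndvi_bounds = NDVI_BOUNDS[self.crop]
        self.ndvi_bounds = tuple(self.ndvi_bounds)
        if not (len(self.ndvi_bounds) == 2 and self.ndvi_bounds[0] < self.ndvi_bounds[1]):
            raise ValueError("ndvi_bounds must be an increasing (lo, hi) pair")
        if not self.subset_lo_nm < self.subset_hi_nm:
            raise ValueError("subset bounds must be increasing")
        if self.binning_factor < 1:
            raise ValueError("binning_factor must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.sweep_fractions = tuple(self.sweep_fractions)
        if not all(0 < f < 1 for f in self.sweep_fractions):
            raise ValueError("sweep fractions must lie in (0, 1)")
        if self.sweep_n_iter < 1:
            raise ValueError("sweep_n_iter must be >= 1")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = json.load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


# ---------------------------------------------------------------------------
# Profile CSV
# ---------------------------------------------------------------------------

def write_profiles(frame: pd.DataFrame, path) -> None:
    """Write a profile frame to CSV (metadata columns, then band columns)."""
    _check_profile_schema(frame)
    frame.to_csv(path, index=False)


def read_profiles(path) -> pd.DataFrame:
    """Read a profile CSV, validating the schema and restoring dtypes."""
    frame = pd.read_csv(path)
    _check_profile_schema(frame)
    frame["infested"] = frame["infested"].astype(bool)
    if "assigned" in frame.columns:
        frame["assigned"] = frame["assigned"].astype(bool)
    return frame


def _check_profile_schema(frame: pd.DataFrame) -> None:
    missing = [c for c in PROFILE_META_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"profile table missing column(s) {missing}")
    band_cols = [
        c for c in frame.columns if c[:1] in ("b", "d") and c[1:2].isdigit()
    ]
    if not band_cols:
        raise ValueError("profile table has no band columns (b<nm> or d<nm>)")
    if frame[band_cols].isna().any().any():
        raise ValueError("profile table contains missing band values")


# ---------------------------------------------------------------------------
# ENVI cubes
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.float32, 5: np.float64}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def write_envi(cube: SpectralCube, path, interleave: str = "bsq") -> None:
    """Write a cube as ENVI raster + text header (plus truth/reference sidecars).

    ``path`` is the raster path (e.g. ``scene.bsq``); the header is written
    next to it as ``<path>.hdr``.  The white reference and truth mask go to
    ``<stem>.white.csv`` and ``<stem>.mask.csv`` so a written scene round
    trips completely.
    """
    path = Path(path)
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil"):
        raise ValueError("interleave must be 'bsq' or 'bil'")
    rows, cols, bands = cube.values.shape
    data = cube.values.astype(np.float32)
    if interleave == "bsq":
        raw = np.transpose(data, (2, 0, 1))     # band, row, col
    else:
        raw = np.transpose(data, (0, 2, 1))     # row, band, col
    raw.tofile(path)
    wavelengths = ", ".join(f"{c:.4f}" for c in cube.grid.centers)
    header = (
        "ENVI\n"
        "description = {nightscan synthetic scene}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wavelengths} }}\n"
    )
    Path(str(path) + ".hdr").write_text(header)
    stem = path.with_suffix("")
    np.savetxt(f"{stem}.white.csv", cube.white_reference, delimiter=",")
    np.savetxt(f"{stem}.mask.csv", cube.truth_mask, fmt="%d", delimiter=",")


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key, buf, in_braces = None, [], False
    for line in text.splitlines():
        if in_braces:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip().lower(), value.strip()
        if value.startswith("{") and "}" not in value:
            buf, in_braces = [value], True
        else:
            fields[key] = value
    return fields


def read_envi(path) -> SpectralCube:
    """Read an ENVI raster written by :func:`write_envi` (BSQ or BIL)."""
    path = Path(path)
    hdr_path = Path(str(path) + ".hdr")
    if not hdr_path.exists():
        hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(f"no ENVI header for {path}")
    fields = _parse_envi_header(hdr_path.read_text())
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = _ENVI_DTYPES[int(fields.get("data type", 4))]
    interleave = fields.get("interleave", "bsq").lower()
    wl_text = fields.get("wavelength", "").strip().strip("{}")
    centers = np.array([float(x) for x in wl_text.split(",") if x.strip()])
    if len(centers) != bands:
        raise ValueError(
            f"header lists {len(centers)} wavelengths for {bands} bands"
        )
    raw = np.fromfile(path, dtype=dtype)
    if raw.size != rows * cols * bands:
        raise ValueError("raster size does not match header dimensions")
    if interleave == "bsq":
        values = np.transpose(raw.reshape(bands, rows, cols), (1, 2, 0))
    elif interleave == "bil":
        values = np.transpose(raw.reshape(rows, bands, cols), (0, 2, 1))
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")

    stem = path.with_suffix("")
    white_path, mask_path = Path(f"{stem}.white.csv"), Path(f"{stem}.mask.csv")
    if white_path.exists():
        white = np.loadtxt(white_path, delimiter=",")
    else:
        white = np.ones(bands)
    if mask_path.exists():
        mask = np.loadtxt(mask_path, delimiter=",", dtype=int, ndmin=2)
    else:
        mask = np.zeros((rows, cols), dtype=int)
    return SpectralCube(
        values=values.astype(float),
        grid=WavelengthGrid(centers),
        white_reference=np.asarray(white, dtype=float),
        truth_mask=mask,
    )


# ---------------------------------------------------------------------------
# Packaged confusion-table fixtures
# ---------------------------------------------------------------------------

def load_table1(crop: str) -> ConfusionTable:
    """Load the published true-validation confusion table for a crop."""
    name = {"bok_choy": "table1_bokchoy.csv", "spinach": "table1_spinach.csv"}
    try:
        fname = name[crop]
    except KeyError:
        raise ValueError(f"unknown crop {crop!r}")
    with resources.files("nightscan.data").joinpath(fname).open() as fh:
        frame = pd.read_csv(fh)
    return ConfusionTable.from_frame(frame, crop=crop)


# ---------------------------------------------------------------------------
# Stage CSV writers
# ---------------------------------------------------------------------------

def write_screen(screen: ScreenMap, path) -> None:
    screen.to_frame().to_csv(path, index=False)


def write_sweep(sweep: SweepResult, path, summary_path=None) -> None:
    sweep.to_frame().to_csv(path, index=False)
    if summary_path is not None:
        sweep.summary().to_csv(summary_path, index=False)


def write_confusion_table(table: ConfusionTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_confusion_table(path, crop: str = "") -> ConfusionTable:
    return ConfusionTable.from_frame(pd.read_csv(path), crop=crop)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize(obj) -> str:
    """Markdown summary of a sweep, screen map, or confusion table."""
    if isinstance(obj, SweepResult):
        return _summarize_sweep(obj)
    if isinstance(obj, ScreenMap):
        return _summarize_screen(obj)
    if isinstance(obj, ConfusionTable):
        return _summarize_table(obj)
    raise TypeError(f"cannot summarize {type(obj).__name__}")


def _summarize_sweep(sweep: SweepResult) -> str:
    if not sweep.accuracies:
        return ""
    lines = [
        "| fraction | min | mean | max |",
        "|---------:|----:|-----:|----:|",
    ]
    for _, row in sweep.summary().iterrows():
        lines.append(
            f"| {row['fraction']:.2f} | {row['min']:.3f} |"
            f" {row['mean']:.3f} | {row['max']:.3f} |"
        )
    return "\n".join(lines)


def _summarize_screen(screen: ScreenMap) -> str:
    df = screen.to_frame()
    lines = ["| band (nm) | period | fertilizer | infestation |",
             "|----------:|:-------|:----------:|:-----------:|"]
    for _, row in df.iterrows():
        lines.append(
            f"| {row['band_nm']:.1f} | {row['period']} |"
            f" {'*' if row['sig_fert'] else ''} |"
            f" {'*' if row['sig_inf'] else ''} |"
        )
    return "\n".join(lines)


def _summarize_table(table: ConfusionTable) -> str:
    df = table.to_frame()
    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join("---:" for _ in df.columns) + "|"
    lines = [header, sep]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row.values) + " |")
    return "\n".join(lines)


def plot_sweep(sweep: SweepResult, path) -> None:
    """Accuracy-distribution figure (min/mean/max per training fraction)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = sweep.summary()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.fill_between(s["fraction"], s["min"], s["max"], alpha=0.3, label="min-max")
    ax.plot(s["fraction"], s["mean"], "o-", label="mean")
    ax.set_xlabel("training fraction")
    ax.set_ylabel("binary detection accuracy")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
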