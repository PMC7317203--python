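"""Synthetic night-time glasshouse scene generator.

No raw imagery from the original glasshouse trials is publicly deposited, so
this module emulates the acquisition campaign: a 116-band visible/NIR line
scanner (460-983 nm), two independently grown time series per crop, three
fertilizer regimes (nutrient solution EC low/medium/high), leafminer-infested
versus control plants, and three measurement periods (baseline before
infestation, early = 2-4 days, late = 7-10 days after infestation).

Plant reflectance is modelled as a logistic red-edge curve: a low visible
floor rising to a near-infrared plateau around 710 nm.  Treatment effects act
on interpretable curve parameters:

* plant age (period) raises the NIR plateau and shifts the red edge to longer
  wavelengths as the canopy develops;
* fertilizer level shifts the red-edge position (chlorophyll content);
* leafminer infestation depresses the NIR plateau and flattens the red-edge
  slope, with zero amplitude at baseline, a small amplitude early, and a
  larger amplitude late;
* series, plant, and pixel random effects add realistic nuisance variance.

Scenes are rendered as raw digital numbers under a smooth halogen-like
illuminant, together with a white-reference spectrum for calibration, a soil
background, and a per-pixel truth mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Constants describing the experimental design
# ---------------------------------------------------------------------------

N_BANDS = 116
BAND_MIN_NM = 460.0
BAND_MAX_NM = 983.0
SUBSET_LO_NM = 619.5          # lower edge of the low-noise band subset
SUBSET_HI_NM = 983.0
N_SUBSET_BANDS = 93

PERIODS = ("baseline", "early", "late")
FERTILIZERS = ("low", "medium", "high")
SERIES = (1, 2)
CROPS = ("bok_choy", "spinach")

# background / white-panel codes in the truth mask (plants are 1..N)
BACKGROUND = 0
WHITE_PANEL = -1

WHITE_PANEL_REFLECTANCE = 0.99

# Per-direction plant counts from the validation confusion tables, in class
# code order 1..15.  Half-integer entries arise from the two series differing
# by one plant; the preset alternates the extra plant between series so each
# series total matches the emulated design (172 bok choy, 174 spinach).
_BOK_CHOY_PLANTS = (20, 20, 20, 9, 9.5, 9, 9, 8.5, 8, 10, 10, 10, 9.5, 9.5, 10)
_SPINACH_PLANTS = (10, 10, 40, 10, 10, 9.5, 10, 10, 9, 10, 10, 9, 9, 9, 8.5)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-center wavelengths (nm) of the emulated sensor."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", c)
        if c.ndim != 1 or len(c) < 1:
            raise ValueError("grid needs at least one band center")
        if not np.all(np.diff(c) > 0):
            raise ValueError("band centers must be strictly increasing")
        if c[0] < BAND_MIN_NM - 1e-9 or c[-1] > BAND_MAX_NM + 1e-9:
            raise ValueError(
                f"band centers must lie within [{BAND_MIN_NM}, {BAND_MAX_NM}] nm"
            )

    def __len__(self) -> int:
        return len(self.centers)


def default_grid() -> WavelengthGrid:
    """The 116-band sensor grid.

    The sensor's band spacing is not uniform across its range: the 93
    low-noise bands span exactly 619.5-983.0 nm, with the remaining 23 bands
    covering 460 nm up to the subset edge.  The grid is built piecewise so
    that subsetting to [619.5, 983.0] retains exactly 93 bands.
    """
    n_low = N_BANDS - N_SUBSET_BANDS          # 23 bands below 619.5 nm
    low = BAND_MIN_NM + np.arange(n_low) * (SUBSET_LO_NM - BAND_MIN_NM) / n_low
    high = np.linspace(SUBSET_LO_NM, SUBSET_HI_NM, N_SUBSET_BANDS)
    return WavelengthGrid(np.concatenate([low, high]))


@dataclass(frozen=True)
class TreatmentLabel:
    """One plant-observation's treatment cell.

    ``assigned`` is the infestation *group* the plant was randomized to at
    the start of the trial; ``infested`` is the true status at observation
    time, which is always False at baseline (insects not yet released).  The
    group assignment is retained because the baseline band screen contrasts
    future-infested versus control plants.
    """

    series: int
    period: str
    fertilizer: str
    infested: bool
    assigned: bool
    plant_id: int = -1

    def __post_init__(self) -> None:
        if self.series not in SERIES:
            raise ValueError(f"series must be one of {SERIES}")
        if self.period not in PERIODS:
            raise ValueError(f"period must be one of {PERIODS}")
        if self.fertilizer not in FERTILIZERS:
            raise ValueError(f"fertilizer must be one of {FERTILIZERS}")
        if self.period == "baseline" and self.infested:
            raise ValueError("baseline observations cannot be infested")
        if self.period != "baseline" and self.infested != self.assigned:
            raise ValueError("after baseline, true status equals assignment")

    @property
    def class_code(self) -> int:
        from .classifier import encode_class  # local import avoids a cycle

        return encode_class(self.period, self.fertilizer, self.infested)


@dataclass
class SceneConfig:
    """Parameters of the synthetic acquisition.

    Counts default to the emulated experimental design (the validation
    table's per-class plant counts, one series' worth per entry); effect
    sizes are expressed on the reflectance scale (unitless, 0-1) or in nm
    for red-edge shifts.
    """

    crop: str = "bok_choy"
    # map (period, fertilizer, assigned) -> plants per cell per series;
    # None selects the crop preset.
    plants_per_cell: Mapping[tuple, int] | None = None
    pixels_per_plant: int = 400
    background_fraction: float = 0.5
    scene_cols: int = 64
    scene_rows: int | None = None     # None: sized to fit the plant pixels

    # reflectance model (crop-dependent defaults applied in __post_init__)
    vis_reflectance: float | None = None      # red floor
    nir_amplitude: float | None = None        # plateau rise above the floor
    red_edge_nm: float = 710.0
    red_edge_width_nm: float = 10.0

    # treatment effects
    infestation_amplitude_early: float = 0.015   # NIR plateau depression
    infestation_amplitude_late: float = 0.04
    infestation_width_early_nm: float = 1.0      # red-edge slope flattening
    infestation_width_late_nm: float = 2.5
    fertilizer_rededge_shift_per_level: float = 3.0
    age_amplitude_per_period: float = 0.02
    age_rededge_shift_per_period: float = 1.5
    # a small fraction of infested plants escape establishment (weak or no
    # spectral response despite the assignment); their effects are scaled
    # by the residual factor
    infestation_escape_rate: float = 0.05
    infestation_escape_residual: float = 0.4

    # nuisance variance
    series_offset_sd: float = 0.004        # plateau amplitude, per series
    series_edge_sd_nm: float = 0.5         # red-edge position, per series
    plant_sd: float = 0.008                # plateau amplitude, per plant
    plant_edge_sd_nm: float = 0.6
    pixel_noise_sd: float = 0.02           # multiplicative, per pixel/band

    # background and illumination
    soil_red: float = 0.22
    soil_nir: float = 0.30
    illumination_temp_k: float = 3200.0
    illumination_gain: float = 4000.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.crop not in CROPS:
            raise ValueError(f"crop must be one of {CROPS}")
        if self.vis_reflectance is None:
            self.vis_reflectance = 0.075 if self.crop == "bok_choy" else 0.06
        if self.nir_amplitude is None:
            self.nir_amplitude = 0.285 if self.crop == "bok_choy" else 0.34
        if self.plants_per_cell is None:
            self.plants_per_cell = _preset_counts(self.crop)
        for cell, n in self.plants_per_cell.items():
            if n <= 0:
                raise ValueError(f"cell {cell} has non-positive count {n}")
        if self.pixels_per_plant <= 0:
            raise ValueError("pixels_per_plant must be positive")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must be in [0, 1)")
        if self.infestation_amplitude_late < self.infestation_amplitude_early:
            raise ValueError("late infestation amplitude must be >= early")
        if not 0 <= self.infestation_escape_rate <= 1:
            raise ValueError("infestation_escape_rate must be in [0, 1]")
        if not 0 <= self.infestation_escape_residual <= 1:
            raise ValueError("infestation_escape_residual must be in [0, 1]")
        for name in ("series_offset_sd", "series_edge_sd_nm", "plant_sd",
                     "plant_edge_sd_nm", "pixel_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    # -- convenience -------------------------------------------------------

    def null_effects(self) -> "SceneConfig":
        """A copy with every treatment effect and nuisance sd set to zero."""
        return replace(
            self,
            plants_per_cell=dict(self.plants_per_cell),
            infestation_amplitude_early=0.0,
            infestation_amplitude_late=0.0,
            infestation_width_early_nm=0.0,
            infestation_width_late_nm=0.0,
            fertilizer_rededge_shift_per_level=0.0,
            age_amplitude_per_period=0.0,
            age_rededge_shift_per_period=0.0,
            infestation_escape_rate=0.0,
            series_offset_sd=0.0,
            series_edge_sd_nm=0.0,
            plant_sd=0.0,
            plant_edge_sd_nm=0.0,
            pixel_noise_sd=0.0,
        )

    def to_json(self, path) -> None:
        d = asdict(self)
        d["plants_per_cell"] = [
            {"period": k[0], "fertilizer": k[1], "assigned": k[2], "count": v}
            for k, v in self.plants_per_cell.items()
        ]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SceneConfig":
        with open(path) as fh:
            d = json.load(fh)
        cells = d.pop("plants_per_cell", None)
        if cells is not None:
            d["plants_per_cell"] = {
                (c["period"], c["fertilizer"], bool(c["assigned"])): c["count"]
                for c in cells
            }
        return cls(**d)


@dataclass
class SpectralCube:
    """Band-sequential raster of raw digital numbers with ground truth.

    ``white_reference`` is the white Teflon panel capture already corrected
    for the panel's known 0.99 reflectance, i.e. an estimate of the
    illuminant, so that ``raw / white_reference`` recovers reflectance
    directly and the panel pixels themselves calibrate to 0.99.
    """

    values: np.ndarray                # rows x cols x bands
    grid: WavelengthGrid
    white_reference: np.ndarray       # per-band
    truth_mask: np.ndarray            # rows x cols int; 0 bg, -1 panel, >0 plant
    calibrated: bool = False

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("cube values must be rows x cols x bands")
        if self.values.shape[2] != len(self.grid):
            raise ValueError("band axis does not match wavelength grid")
        if self.truth_mask.shape != self.values.shape[:2]:
            raise ValueError("truth mask shape does not match scene")
        if np.any(self.values < 0):
            raise ValueError("raw digital numbers must be non-negative")
        if np.any(self.white_reference <= 0):
            bad = int(np.argmax(self.white_reference <= 0))
            raise ValueError(f"white reference non-positive in band {bad}")

    @property
    def plant_ids(self) -> np.ndarray:
        ids = np.unique(self.truth_mask)
        return ids[ids > 0]


# ---------------------------------------------------------------------------
# Design table
# ---------------------------------------------------------------------------

def _preset_counts(crop: str) -> dict:
    """Per-series plant counts per (period, fertilizer, assigned) cell.

    Derived from the per-direction class counts of the validation table.
    Half-integer class counts are resolved by giving the extra plant to
    series 1 for every other half cell and to series 2 otherwise, preserving
    each series' total.  Baseline classes pool both assignment groups, which
    the preset splits evenly (odd counts put the extra plant in the control
    group).  Counts here are for one series; the other series swaps the
    rounding of half cells.
    """
    per_class = _BOK_CHOY_PLANTS if crop == "bok_choy" else _SPINACH_PLANTS
    from .classifier import decode_class

    counts: dict[tuple, float] = {}
    for code, n in enumerate(per_class, start=1):
        period, fert, infested = decode_class(code)
        if period == "baseline":
            # split between future-infested and control groups
            counts[(period, fert, False)] = np.ceil(n / 2)
            counts[(period, fert, True)] = np.floor(n / 2)
        else:
            counts[(period, fert, infested)] = n
    return counts


def _series_counts(counts: Mapping[tuple, float], series: int) -> dict:
    """Resolve half-integer cells, alternating the extra plant by series."""
    out = {}
    half_rank = 0
    for cell in sorted(counts):
        n = counts[cell]
        if float(n).is_integer():
            out[cell] = int(n)
        else:
            up_in_series1 = half_rank % 2 == 0
            take_ceil = up_in_series1 if series == 1 else not up_in_series1
            out[cell] = int(np.ceil(n)) if take_ceil else int(np.floor(n))
            half_rank += 1
    return out


def make_design(config: SceneConfig) -> list[TreatmentLabel]:
    """Enumerate one :class:`TreatmentLabel` per plant-observation.

    Baseline cells carry both future-infested and control assignments with
    true ``infested=False``.  Plant ids are unique across the whole design.
    """
    labels: list[TreatmentLabel] = []
    pid = 0
    for series in SERIES:
        counts = _series_counts(config.plants_per_cell, series)
        for (period, fert, assigned) in sorted(counts):
            for _ in range(counts[(period, fert, assigned)]):
                pid += 1
                labels.append(
                    TreatmentLabel(
                        series=series,
                        period=period,
                        fertilizer=fert,
                        infested=assigned and period != "baseline",
                        assigned=assigned,
                        plant_id=pid,
                    )
                )
    return labels


# ---------------------------------------------------------------------------
# Reflectance model
# ---------------------------------------------------------------------------

def _series_effects(config: SceneConfig) -> dict[int, tuple[float, float]]:
    """Per-series (amplitude offset, red-edge shift) random effects.

    Drawn from a stream derived only from the config seed so that every
    plant in a series shares the same offsets regardless of call order.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5E]))
    out = {}
    for s in SERIES:
        amp = rng.normal(0.0, config.series_offset_sd)
        edge = rng.normal(0.0, config.series_edge_sd_nm)
        out[s] = (amp, edge)
    return out


_PERIOD_STEP = {"baseline": 0, "early": 1, "late": 2}
_FERT_LEVEL = {"low": -1, "medium": 0, "high": 1}


def true_spectrum(
    label: TreatmentLabel,
    config: SceneConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Noise-free-pixel reflectance of one plant (116 values in [0, 1]).

    Plant-level random effects are drawn from ``rng``; pass ``None`` for the
    population-mean spectrum of the cell.
    """
    grid = default_grid().centers
    amp = config.nir_amplitude
    edge = config.red_edge_nm
    width = config.red_edge_width_nm

    step = _PERIOD_STEP[label.period]
    amp = amp + config.age_amplitude_per_period * step
    edge = edge + config.age_rededge_shift_per_period * step
    edge = edge + config.fertilizer_rededge_shift_per_level * _FERT_LEVEL[label.fertilizer]

    # plant-level draws happen unconditionally so the stream advances the
    # same way for every label
    if rng is not None:
        plant_amp = rng.normal(0.0, config.plant_sd)
        plant_edge = rng.normal(0.0, config.plant_edge_sd_nm)
        escaped = rng.uniform() < config.infestation_escape_rate
    else:
        plant_amp = plant_edge = 0.0
        escaped = False

    if label.infested:
        scale = config.infestation_escape_residual if escaped else 1.0
        if label.period == "early":
            amp -= scale * config.infestation_amplitude_early
            width += scale * config.infestation_width_early_nm
        else:
            amp -= scale * config.infestation_amplitude_late
            width += scale * config.infestation_width_late_nm

    s_amp, s_edge = _series_effects(config)[label.series]
    amp += s_amp + plant_amp
    edge += s_edge + plant_edge

    refl = config.vis_reflectance + amp / (1.0 + np.exp(-(grid - edge) / width))
    return np.clip(refl, 0.0, 1.0)


def soil_spectrum(config: SceneConfig) -> np.ndarray:
    """Background (soil/pot) reflectance: bright red, low red/NIR contrast."""
    grid = default_grid().centers
    frac = (grid - grid[0]) / (grid[-1] - grid[0])
    return config.soil_red + (config.soil_nir - config.soil_red) * frac


def illumination_spectrum(config: SceneConfig) -> np.ndarray:
    """Smooth halogen-like illuminant (Planck shape, peak-normalized)."""
    lam = default_grid().centers * 1e-9
    h, c, k = 6.626e-34, 2.998e8, 1.381e-23
    planck = 1.0 / (lam**5 * (np.exp(h * c / (lam * k * config.illumination_temp_k)) - 1.0))
    return config.illumination_gain * planck / planck.max()


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

def render_scene(
    labels: Sequence[TreatmentLabel],
    config: SceneConfig,
    rng: np.random.Generator,
) -> SpectralCube:
    """Render one raw-DN cube containing the given plants.

    Raw DN = reflectance x illuminant x (1 + pixel noise).  The scene is a
    ``scene_cols``-wide raster: one white-panel row, the plant pixels laid
    out contiguously, and soil background filling the remainder up to the
    requested background fraction.
    """
    if not labels:
        raise ValueError("render_scene needs at least one plant label")
    n_plant_px = len(labels) * config.pixels_per_plant
    n_total = int(np.ceil(n_plant_px / (1.0 - config.background_fraction)))
    n_bg = n_total - n_plant_px

    cols = config.scene_cols
    rows = config.scene_rows or 1 + int(np.ceil(n_total / cols))  # +1 panel row
    if rows * cols < n_total + cols:
        raise ValueError("scene too small to hold requested pixels")

    illum = illumination_spectrum(config)
    flat_mask = np.empty(rows * cols, dtype=int)
    flat_refl = np.empty((rows * cols, N_BANDS), dtype=float)

    flat_mask[:cols] = WHITE_PANEL
    flat_refl[:cols] = WHITE_PANEL_REFLECTANCE

    pos = cols
    for lab in labels:
        spec = true_spectrum(lab, config, rng)
        flat_mask[pos : pos + config.pixels_per_plant] = lab.plant_id
        flat_refl[pos : pos + config.pixels_per_plant] = spec
        pos += config.pixels_per_plant

    soil = soil_spectrum(config)
    flat_mask[pos:] = BACKGROUND
    flat_refl[pos:] = soil

    dn = flat_refl * illum
    if config.pixel_noise_sd > 0:
        noise = rng.normal(0.0, config.pixel_noise_sd, size=dn.shape)
        # panel row kept noise-free: it is the calibration reference capture
        noise[:cols] = 0.0
        dn = dn * (1.0 + noise)
    dn = np.clip(dn, 0.0, None)

    return SpectralCube(
        values=dn.reshape(rows, cols, N_BANDS),
        grid=default_grid(),
        white_reference=illum.copy(),
        truth_mask=flat_mask.reshape(rows, cols),
    )


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------

def _profile_frame(labels, spectra, n_pixels, grid) -> pd.DataFrame:
    band_cols = [f"b{c:.2f}" for c in grid.centers]
    meta = pd.DataFrame(
        {
            "plant_id": [l.plant_id for l in labels],
            "series": [l.series for l in labels],
            "period": [l.period for l in labels],
            "fertilizer": [l.fertilizer for l in labels],
            "infested": [l.infested for l in labels],
            "assigned": [l.assigned for l in labels],
            "n_pixels": n_pixels,
        }
    )
    bands = pd.DataFrame(np.asarray(spectra), columns=band_cols)
    return pd.concat([meta, bands], axis=1)


def simulate_dataset(
    config: SceneConfig,
    emit: str = "profiles",
) -> tuple[pd.DataFrame | dict[int, SpectralCube], list[TreatmentLabel]]:
    """Simulate the full two-series acquisition for one crop.

    ``emit='profiles'`` returns per-plant mean reflectance profiles on the
    native 116-band grid (the average over ``pixels_per_plant`` noisy pixels,
    drawn via the exact distribution of the pixel mean); ``emit='cubes'``
    returns one rendered :class:`SpectralCube` per series, from which the
    preprocessing chain produces the same profiles.

    Fully deterministic given ``config.seed``.
    """
    labels = make_design(config)
    if emit == "cubes":
        cubes = {}
        for s in SERIES:
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, s]))
            cubes[s] = render_scene([l for l in labels if l.series == s], config, rng)
        return cubes, labels
    if emit != "profiles":
        raise ValueError("emit must be 'profiles' or 'cubes'")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 99]))
    mean_noise_sd = config.pixel_noise_sd / np.sqrt(config.pixels_per_plant)
    spectra = []
    for lab in labels:
        spec = true_spectrum(lab, config, rng)
        if mean_noise_sd > 0:
            spec = spec * (1.0 + rng.normal(0.0, mean_noise_sd, size=spec.shape))
        spectra.append(np.clip(spec, 0.0, 1.0))
    frame = _profile_frame(labels, spectra, config.pixels_per_plant, default_grid())
    return frame, labels


def bok_choy_preset(seed: int = 0, **overrides) -> SceneConfig:
    """Default bok choy campaign: 172 profiles per series, 344 total."""
    return SceneConfig(crop="bok_choy", seed=seed, **overrides)


def spinach_preset(seed: int = 0, **overrides) -> SceneConfig:
    """Default spinach campaign: 174 profiles per series, 348 total."""
    return SceneConfig(crop="spinach", seed=seed, **overrides)
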