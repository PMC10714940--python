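"""Synthetic field layouts and class-conditioned multispectral sequences.

Real acquisitions of the study system (maize plots under three irrigation
levels, imaged by a 5-band UAV camera on 13 dates) are emulated with the
statistical structure the classifier exploits:

* class-dependent temporal reflectance trajectories — stressed canopies
  lose NIR and gain red reflectance linearly over acquisition dates;
* canopy geometry — smooth blobs on a soil background whose radii shrink
  per date under stress and which deform by a smoothed random warp
  (leaf rolling/twisting at desk scale);
* sensor noise and per-date illumination jitter.

Trajectory defaults ship in a versioned parameter file
(``params/default_trajectories.yaml``).  Variant parameter sets expose the
separability dials the ablation tests rely on: ``exchangeable_params``
makes the classes statistically identical, ``slope_only_params`` makes
them differ only through temporal slopes (identical at the first date),
``nir_only_params`` only through the NIR trajectory.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple

import numpy as np
import yaml
from scipy import ndimage

from .roi_sequences import (CANONICAL_CHANNELS, CLASS_NAMES, ImageSequence,
                            InvalidArgumentError, MultispectralFrame,
                            StressLabel, sequences_to_archive)

IRRIGATION_IW_CPE = {1: 0.6, 2: 0.8, 3: 1.2}       # IW/CPE ratio per level
NITROGEN_KG_HA = {1: 100, 2: 200, 3: 300}          # kg N per hectare
OPTIMUM_NITROGEN_LEVEL = 2

_MASK_THRESHOLD = 0.6   # Gaussian-bump field level defining the canopy mask


# ---------------------------------------------------------------------------
# field layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldLayout:
    """Split-plot factorial field: irrigation × nitrogen × replications."""
    irrigation_levels: int = 3
    nitrogen_levels: int = 3
    replications: int = 3
    plot_dims_m: tuple = (4.2, 4.8)
    row_spacing_m: float = 0.60
    plant_spacing_m: float = 0.20

    def __post_init__(self):
        for name in ("irrigation_levels", "nitrogen_levels", "replications"):
            if getattr(self, name) < 1:
                raise InvalidArgumentError(f"{name} must be >= 1")
        if self.row_spacing_m <= 0 or self.plant_spacing_m <= 0:
            raise InvalidArgumentError("spacings must be positive")

    @property
    def n_plots(self) -> int:
        return self.irrigation_levels * self.nitrogen_levels * self.replications


class PlantDensity(NamedTuple):
    exact: float
    rounded: float


def plant_density(row_spacing_m: float, plant_spacing_m: float) -> PlantDensity:
    """Plants per square meter: one plant per row-spacing × plant-spacing cell.

    0.60 m rows with 0.20 m in-row spacing give 8.33 plants/m².
    """
    if row_spacing_m <= 0 or plant_spacing_m <= 0:
        raise InvalidArgumentError("spacings must be positive")
    exact = 1.0 / (row_spacing_m * plant_spacing_m)
    return PlantDensity(exact, round(exact, 2))


def generate_field_layout(layout: FieldLayout, seed: int = 0) -> list:
    """Enumerate plot records with randomized field positions.

    Water-stress labels are assigned only to the optimum-nitrogen plots
    (the N2 column): irrigation level 1/2/3 → I1N2 (high) / I2N2 (moderate)
    / I3N2 (none).  Other plots carry ``label=None`` (agronomic metadata
    only).  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    records = []
    for i in range(1, layout.irrigation_levels + 1):
        for j in range(1, layout.nitrogen_levels + 1):
            for r in range(1, layout.replications + 1):
                label = None
                if (j == OPTIMUM_NITROGEN_LEVEL
                        and layout.irrigation_levels == len(CLASS_NAMES)):
                    label = StressLabel.from_index(i - 1)
                records.append({
                    "plot_id": f"I{i}N{j}R{r}",
                    "irrigation_level": i,
                    "nitrogen_level": j,
                    "replicate": r,
                    "iw_cpe": IRRIGATION_IW_CPE.get(i),
                    "nitrogen_kg_ha": NITROGEN_KG_HA.get(j),
                    "label": label,
                })
    positions = rng.permutation(len(records))
    for rec, pos in zip(records, positions):
        rec["field_position"] = int(pos)
    return records


# ---------------------------------------------------------------------------
# trajectory parameters
# ---------------------------------------------------------------------------

@dataclass
class ClassTrajectory:
    """Per-class generator knobs (reflectance units and pixels per date)."""
    nir_slope: float
    red_slope: float
    canopy_shrink_rate: float
    deform_amplitude: float
    noise_sd: float
    illumination_jitter_sd: float

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        if not 0 <= self.canopy_shrink_rate < 1:
            raise InvalidArgumentError("canopy_shrink_rate must be in [0, 1)")


@dataclass
class StressTrajectoryParams:
    """Class trajectories plus the shared canopy/soil reflectance bases."""
    classes: dict = field(default_factory=dict)     # class_name -> ClassTrajectory
    channel_base: dict = field(default_factory=dict)
    soil_background: dict = field(default_factory=dict)
    version: int = 1

    def __post_init__(self):
        if set(self.classes) == set(CLASS_NAMES):
            hi, mo, no = (self.classes[c].nir_slope for c in CLASS_NAMES)
            if not hi <= mo <= no:
                raise InvalidArgumentError(
                    "nir_slope must be monotone: high <= moderate <= none")

    def for_class(self, class_name: str) -> ClassTrajectory:
        if class_name not in self.classes:
            raise InvalidArgumentError(
                f"no trajectory parameters for class {class_name!r}")
        return self.classes[class_name]


def load_params(path=None) -> StressTrajectoryParams:
    """Load trajectory parameters from YAML (packaged defaults if no path)."""
    if path is None:
        text = (resources.files("stressnet") / "params"
                / "default_trajectories.yaml").read_text()
    else:
        with open(path) as f:
            text = f.read()
    raw = yaml.safe_load(text)
    classes = {name: ClassTrajectory(**vals) for name, vals in raw["classes"].items()}
    return StressTrajectoryParams(classes, dict(raw["channel_base"]),
                                  dict(raw["soil_background"]),
                                  int(raw.get("version", 1)))


def default_params() -> StressTrajectoryParams:
    return load_params()


def exchangeable_params() -> StressTrajectoryParams:
    """All classes share one trajectory: any classifier is at chance (1/3)."""
    p = default_params()
    ref = p.classes["I2N2"]
    p.classes = {name: copy.deepcopy(ref) for name in CLASS_NAMES}
    return p


def slope_only_params() -> StressTrajectoryParams:
    """Classes differ only in temporal slopes; identical at the first date
    (no shrink, equal deformation/noise), so a single-date window carries no
    class signal."""
    p = default_params()
    for name in CLASS_NAMES:
        ct = p.classes[name]
        ct.canopy_shrink_rate = 0.0
        ct.deform_amplitude = 0.20
    return p


def nir_only_params() -> StressTrajectoryParams:
    """Classes differ only through the NIR trajectory; the visible bands and
    canopy geometry are class-independent, so RGB-only input carries no
    class signal."""
    p = default_params()
    for name in CLASS_NAMES:
        ct = p.classes[name]
        ct.red_slope = 0.0
        ct.canopy_shrink_rate = 0.0
        ct.deform_amplitude = 0.20
    return p


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------

def _canopy_field(rng: np.random.Generator, H: int, W: int):
    """Random blob centers/radii for one plant canopy."""
    n_blobs = int(rng.integers(3, 7))
    cy = rng.uniform(0.2 * H, 0.8 * H, n_blobs)
    cx = rng.uniform(0.2 * W, 0.8 * W, n_blobs)
    r = rng.uniform(0.10, 0.18, n_blobs) * min(H, W)
    return cy, cx, r


def _mask_at(cy, cx, r, scale: float, H: int, W: int) -> np.ndarray:
    yy, xx = np.mgrid[0:H, 0:W]
    g = np.zeros((H, W))
    for y0, x0, r0 in zip(cy, cx, r):
        rs = max(r0 * scale, 1.0)
        g += np.exp(-((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * rs ** 2))
    return g > _MASK_THRESHOLD


def generate_sequence(label: StressLabel, T: int, H: int, W: int,
                      channels=CANONICAL_CHANNELS,
                      params: StressTrajectoryParams | None = None,
                      seed: int = 0) -> ImageSequence:
    """Generate one labeled sequence of T frames (H×W, given channels).

    Frame t shows canopy blobs whose radii scale by (1−shrink)^t, warped by
    a smoothed random displacement field of amplitude deform_amplitude·t,
    over a constant soil background.  Canopy reflectance in channel c is
    base_c + slope_c·t (slope nonzero only for nir/red); per-date
    multiplicative illumination jitter and i.i.d. Gaussian noise are applied
    last and values clipped to [0, 1].  Deterministic for a given seed.
    """
    if T < 1:
        raise InvalidArgumentError("T must be >= 1")
    if H < 8 or W < 8:
        raise InvalidArgumentError("frames must be at least 8x8")
    params = params or default_params()
    ct = params.for_class(label.class_name)
    channels = tuple(channels)
    rng = np.random.default_rng(seed)

    cy, cx, r = _canopy_field(rng, H, W)
    # fixed smooth displacement field; amplitude grows linearly with t
    dy = ndimage.gaussian_filter(rng.standard_normal((H, W)), sigma=max(H, W) / 8)
    dx = ndimage.gaussian_filter(rng.standard_normal((H, W)), sigma=max(H, W) / 8)
    for d in (dy, dx):
        m = np.abs(d).max()
        if m > 0:
            d /= m
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)

    slopes = {c: 0.0 for c in channels}
    if "nir" in slopes:
        slopes["nir"] = ct.nir_slope
    if "red" in slopes:
        slopes["red"] = ct.red_slope

    frames = []
    for t in range(T):
        mask = _mask_at(cy, cx, r, (1.0 - ct.canopy_shrink_rate) ** t, H, W)
        amp = ct.deform_amplitude * t
        if amp > 0:
            mask = ndimage.map_coordinates(mask.astype(np.float64),
                                           [yy + dy * amp, xx + dx * amp],
                                           order=0, mode="constant") > 0.5
        pix = np.empty((len(channels), H, W))
        for k, c in enumerate(channels):
            canopy_val = params.channel_base[c] + slopes[c] * t
            pix[k] = np.where(mask, canopy_val, params.soil_background[c])
        jitter = 1.0 + rng.normal(0.0, ct.illumination_jitter_sd)
        pix = pix * jitter + rng.normal(0.0, ct.noise_sd, size=pix.shape)
        frames.append(MultispectralFrame(np.clip(pix, 0.0, 1.0), channels,
                                         t, f"{label.class_name}"))
    return ImageSequence(frames, label, sequence_id=f"{label.class_name}_s{seed}")


def generate_dataset(n_per_class: int, T: int = 13, H: int = 140, W: int = 140,
                     channels=CANONICAL_CHANNELS,
                     params: StressTrajectoryParams | None = None,
                     seed: int = 0) -> dict:
    """Balanced archive of 3·n_per_class sequences.

    Per-sequence seeds are derived as ``seed + index`` so generation is a
    pure function of its arguments; the archive round-trips through the
    sequence-archive reader/writer.
    """
    if n_per_class < 2:
        raise InvalidArgumentError("n_per_class must be >= 2")
    params = params or default_params()
    sequences = []
    idx = 0
    for ci, name in enumerate(CLASS_NAMES):
        label = StressLabel.from_index(ci)
        for _ in range(n_per_class):
            seq = generate_sequence(label, T, H, W, channels, params,
                                    seed=seed + idx)
            seq.sequence_id = f"{name}_{idx:03d}"
            for f in seq.frames:
                f.plot_id = seq.sequence_id
            sequences.append(seq)
            idx += 1
    return sequences_to_archive(sequences)


def canopy_mask_of_frame(frame: MultispectralFrame,
                         params: StressTrajectoryParams,
                         channel: str = "blue") -> np.ndarray:
    """Recover the canopy mask of a noise-free generated frame by comparing
    against the soil background in a slope-free channel (diagnostic helper;
    the blue default avoids channels whose trajectory can cross the soil
    value)."""
    k = frame.channel_names.index(channel)
    return ~np.isclose(frame.pixels[k], params.soil_background[channel])
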