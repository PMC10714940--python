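"""ROI extraction and sequence assembly for multispectral plot imagery.

Reads multiband rasters (one file per plot per date, five bands in the
canonical blue/green/red/red-edge/NIR order), trims the plot border,
carves per-plant ROI patches with a sliding window, normalizes, and packs
date-ordered labeled sequences into an HDF5 archive shared by all
downstream modules.  Spectral-subset and temporal-window selection used by
the ablation experiments also live here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger("stressnet")

CANONICAL_CHANNELS = ("blue", "green", "red", "rededge", "nir")

#: wavelength (nm) of each canonical band, for reference
BAND_WAVELENGTHS_NM = {"blue": 475, "green": 560, "red": 668,
                       "rededge": 717, "nir": 842}

SPECTRAL_SUBSETS = {
    "RGB": ("blue", "green", "red"),
    "RGB-NIR": ("blue", "green", "red", "nir"),
    "RGB-Re": ("blue", "green", "red", "rededge"),
    "All": CANONICAL_CHANNELS,
}

CLASS_NAMES = ("I1N2", "I2N2", "I3N2")          # high / moderate / no stress
CLASS_DESCRIPTIONS = {"I1N2": "high water stress",
                      "I2N2": "moderate water stress",
                      "I3N2": "no water stress"}


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class InvalidArgumentError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


class MissingLabelError(KeyError):
    pass


class MissingDateError(ValueError):
    pass


class InvalidSubsetError(ValueError):
    pass


class InvalidWindowError(ValueError):
    pass


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StressLabel:
    """Water-stress class under optimum nitrogen: I1N2=high→0, I2N2=moderate→1,
    I3N2=none→2."""
    class_index: int
    class_name: str

    def __post_init__(self):
        if self.class_name not in CLASS_NAMES:
            raise InvalidArgumentError(f"unknown class name {self.class_name!r}")
        if CLASS_NAMES[self.class_index] != self.class_name:
            raise InvalidArgumentError(
                f"class_index {self.class_index} does not map to {self.class_name}")

    @classmethod
    def from_name(cls, name: str) -> "StressLabel":
        if name not in CLASS_NAMES:
            raise InvalidArgumentError(f"unknown class name {name!r}")
        return cls(CLASS_NAMES.index(name), name)

    @classmethod
    def from_index(cls, idx: int) -> "StressLabel":
        if not 0 <= idx < len(CLASS_NAMES):
            raise InvalidArgumentError(f"class index {idx} out of range")
        return cls(idx, CLASS_NAMES[idx])


@dataclass
class MultispectralFrame:
    """One co-registered multiband reflectance image of one plot ROI."""
    pixels: np.ndarray                      # (C, H, W)
    channel_names: tuple
    date_index: int
    plot_id: str

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.channel_names = tuple(self.channel_names)
        if self.pixels.ndim != 3:
            raise InvalidArgumentError("pixels must be (channels, height, width)")
        if self.pixels.shape[0] != len(self.channel_names):
            raise InvalidArgumentError("channel count != len(channel_names)")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise InvalidArgumentError("duplicate channel names")
        if self.pixels.shape[1] < 1 or self.pixels.shape[2] < 1:
            raise InvalidArgumentError("empty frame")
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidArgumentError("pixel values must be finite")

    @property
    def height(self) -> int:
        return self.pixels.shape[1]

    @property
    def width(self) -> int:
        return self.pixels.shape[2]


@dataclass
class ImageSequence:
    """Date-ordered stack of frames for one plant/plot ROI, with a label."""
    frames: list
    label: StressLabel
    sequence_id: str = ""

    def __post_init__(self):
        if not self.frames:
            raise InvalidArgumentError("sequence must contain at least one frame")
        f0 = self.frames[0]
        for f in self.frames[1:]:
            if (f.channel_names != f0.channel_names or f.height != f0.height
                    or f.width != f0.width):
                raise AlignmentError("frames differ in channels or shape")
        dates = [f.date_index for f in self.frames]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise InvalidArgumentError("date_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def channel_names(self) -> tuple:
        return self.frames[0].channel_names

    def as_array(self) -> np.ndarray:
        """(T, C, H, W) float array."""
        return np.stack([f.pixels for f in self.frames])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def trim_border(frame: MultispectralFrame, fraction: float) -> MultispectralFrame:
    """Remove a `fraction` of each edge (floor of fraction·dimension per edge).

    Used with fraction=0.05 to drop the plot perimeter where border effects
    on the crop are expected.
    """
    if not 0 <= fraction < 0.5:
        raise InvalidArgumentError(f"fraction must be in [0, 0.5), got {fraction}")
    dh = int(np.floor(fraction * frame.height))
    dw = int(np.floor(fraction * frame.width))
    h, w = frame.height - 2 * dh, frame.width - 2 * dw
    if h < 1 or w < 1:
        raise DegenerateInputError("trim would leave an empty frame")
    pix = frame.pixels[:, dh:dh + h, dw:dw + w]
    return MultispectralFrame(pix.copy(), frame.channel_names,
                              frame.date_index, frame.plot_id)


def sliding_window_rois(frame: MultispectralFrame, patch_size: int,
                        stride: int | None = None) -> list:
    """Enumerate square ROI patches row-major from the top-left corner.

    Default stride equals the patch size (non-overlapping tiling: one plant
    per patch without double counting).
    """
    if stride is None:
        stride = patch_size
    if stride < 1:
        raise InvalidArgumentError("stride must be >= 1")
    if patch_size > min(frame.height, frame.width):
        raise DegenerateInputError(
            f"patch {patch_size} larger than frame {frame.height}x{frame.width}")
    patches = []
    for i in range((frame.height - patch_size) // stride + 1):
        for j in range((frame.width - patch_size) // stride + 1):
            y, x = i * stride, j * stride
            pix = frame.pixels[:, y:y + patch_size, x:x + patch_size].copy()
            patches.append(MultispectralFrame(
                pix, frame.channel_names, frame.date_index,
                f"{frame.plot_id}/roi_{i}_{j}"))
    return patches


def channel_stats(pixels: np.ndarray, mode: str) -> dict:
    """Per-channel statistics of an array whose axis -3 is the channel axis."""
    arr = np.asarray(pixels, dtype=np.float64)
    red = tuple(ax for ax in range(arr.ndim) if ax != arr.ndim - 3)
    if mode == "minmax":
        return {"mode": mode, "min": arr.min(axis=red), "max": arr.max(axis=red)}
    if mode == "standardize":
        return {"mode": mode, "mean": arr.mean(axis=red), "std": arr.std(axis=red)}
    raise InvalidArgumentError(f"unknown normalization mode {mode!r}")


def _apply_stats(arr: np.ndarray, stats: dict) -> np.ndarray:
    def bcast(v):
        return np.asarray(v).reshape((-1,) + (1,) * 2)
    out = np.array(arr, dtype=np.float64)
    if stats["mode"] == "minmax":
        rng = np.asarray(stats["max"]) - np.asarray(stats["min"])
        degenerate = rng == 0
        safe = np.where(degenerate, 1.0, rng)
        out = (out - bcast(stats["min"])) / bcast(safe)
        if degenerate.any():
            logger.warning("minmax: zero-range channel(s) %s set to zeros",
                           np.nonzero(degenerate)[0].tolist())
            out[..., degenerate, :, :] = 0.0
    else:
        std = np.asarray(stats["std"])
        degenerate = std == 0
        safe = np.where(degenerate, 1.0, std)
        out = (out - bcast(stats["mean"])) / bcast(safe)
        if degenerate.any():
            logger.warning("standardize: zero-variance channel(s) %s set to zeros",
                           np.nonzero(degenerate)[0].tolist())
            out[..., degenerate, :, :] = 0.0
    return out


def normalize_sequence(seq: ImageSequence, mode: str = "minmax",
                       stats_scope: str = "per_sequence",
                       stats: dict | None = None):
    """Normalize every frame of a sequence per channel.

    minmax maps each channel to [0, 1]; standardize gives zero mean and unit
    (population) variance.  With ``stats_scope='dataset'`` the supplied
    ``stats`` — computed once on the training split — are applied, so
    validation data reuses training statistics; when no stats are given they
    are computed from this sequence and returned for reuse.  Returns
    ``(normalized_sequence, stats)``.
    """
    if stats_scope not in ("per_sequence", "dataset"):
        raise InvalidArgumentError(f"unknown stats_scope {stats_scope!r}")
    arr = seq.as_array()
    if stats_scope == "per_sequence" or stats is None:
        stats = channel_stats(arr, mode)
    out = _apply_stats(arr, stats)
    frames = [MultispectralFrame(out[t], f.channel_names, f.date_index, f.plot_id)
              for t, f in enumerate(seq.frames)]
    return ImageSequence(frames, seq.label, seq.sequence_id), stats


def assemble_sequences(frames: list, labels: dict) -> list:
    """Group frames by plot/ROI id into date-ascending labeled sequences.

    Every id must carry a frame for every acquisition date present in the
    input; sequences with missing dates are rejected rather than imputed.
    """
    all_dates = sorted({f.date_index for f in frames})
    by_id: dict = {}
    for f in frames:
        by_id.setdefault(f.plot_id, []).append(f)
    sequences = []
    for pid in sorted(by_id):
        group = sorted(by_id[pid], key=lambda f: f.date_index)
        base = pid.split("/")[0]
        if base not in labels and pid not in labels:
            raise MissingLabelError(f"no label for plot {base!r}")
        label = labels.get(pid, labels.get(base))
        dates = [f.date_index for f in group]
        if dates != all_dates:
            raise MissingDateError(
                f"{pid} has dates {dates}, expected {all_dates}")
        shapes = {(f.height, f.width, f.channel_names) for f in group}
        if len(shapes) != 1:
            raise AlignmentError(f"{pid}: inconsistent frame shapes across dates")
        sequences.append(ImageSequence(group, label, sequence_id=pid))
    return sequences


def select_spectral_subset(seq: ImageSequence, subset: str) -> ImageSequence:
    """Keep only the channels of a named subset, in canonical order."""
    if subset not in SPECTRAL_SUBSETS:
        raise InvalidSubsetError(f"unknown subset {subset!r}")
    wanted = SPECTRAL_SUBSETS[subset]
    missing = [c for c in wanted if c not in seq.channel_names]
    if missing:
        raise InvalidSubsetError(f"channels {missing} not present")
    idx = [seq.channel_names.index(c) for c in wanted]
    frames = [MultispectralFrame(f.pixels[idx], wanted, f.date_index, f.plot_id)
              for f in seq.frames]
    return ImageSequence(frames, seq.label, seq.sequence_id)


def select_temporal_window(seq: ImageSequence, n_days: int) -> ImageSequence:
    """Keep the first `n_days` frames (earliest acquisitions)."""
    if not 1 <= n_days <= len(seq):
        raise InvalidWindowError(
            f"n_days must be in [1, {len(seq)}], got {n_days}")
    return ImageSequence(list(seq.frames[:n_days]), seq.label, seq.sequence_id)


# ---------------------------------------------------------------------------
# archive I/O
# ---------------------------------------------------------------------------

def sequences_to_archive(sequences: list) -> dict:
    """Pack a list of equally shaped ImageSequences into archive arrays."""
    arr = np.stack([s.as_array() for s in sequences]).astype(np.float32)
    return {
        "sequences": arr,                               # (N, T, C, H, W)
        "labels": np.array([s.label.class_index for s in sequences], dtype=np.int64),
        "channel_names": list(sequences[0].channel_names),
        "date_indices": np.array([f.date_index for f in sequences[0].frames],
                                 dtype=np.int64),
        "sequence_ids": [s.sequence_id for s in sequences],
    }


def archive_to_sequences(archive: dict) -> list:
    """Unpack archive arrays back into ImageSequence objects."""
    seqs = []
    names = tuple(archive["channel_names"])
    dates = archive["date_indices"]
    ids = archive.get("sequence_ids") or [f"seq{i}" for i in range(len(archive["labels"]))]
    for i, (x, y) in enumerate(zip(archive["sequences"], archive["labels"])):
        frames = [MultispectralFrame(x[t], names, int(dates[t]), ids[i])
                  for t in range(x.shape[0])]
        seqs.append(ImageSequence(frames, StressLabel.from_index(int(y)), ids[i]))
    return seqs


def save_archive(path, archive: dict) -> None:
    """Write a sequence archive to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("sequences", data=np.asarray(archive["sequences"],
                                                      dtype=np.float32))
        f.create_dataset("labels", data=np.asarray(archive["labels"], dtype=np.int64))
        f.create_dataset("channel_names",
                         data=np.array(archive["channel_names"], dtype="S16"))
        f.create_dataset("date_indices",
                         data=np.asarray(archive["date_indices"], dtype=np.int64))
        ids = archive.get("sequence_ids")
        if ids is not None:
            f.create_dataset("sequence_ids", data=np.array(ids, dtype="S64"))


def load_archive(path) -> dict:
    """Read a sequence archive from HDF5."""
    with h5py.File(path, "r") as f:
        archive = {
            "sequences": f["sequences"][...].astype(np.float32),
            "labels": f["labels"][...],
            "channel_names": [s.decode() for s in f["channel_names"][...]],
            "date_indices": f["date_indices"][...],
        }
        if "sequence_ids" in f:
            archive["sequence_ids"] = [s.decode() for s in f["sequence_ids"][...]]
    return archive


def subset_archive(archive: dict, subset: str) -> dict:
    """Spectral-subset selection on a whole archive."""
    if subset not in SPECTRAL_SUBSETS:
        raise InvalidSubsetError(f"unknown subset {subset!r}")
    wanted = SPECTRAL_SUBSETS[subset]
    names = list(archive["channel_names"])
    missing = [c for c in wanted if c not in names]
    if missing:
        raise InvalidSubsetError(f"channels {missing} not present")
    idx = [names.index(c) for c in wanted]
    out = dict(archive)
    out["sequences"] = archive["sequences"][:, :, idx]
    out["channel_names"] = list(wanted)
    return out


def window_archive(archive: dict, n_days: int) -> dict:
    """Temporal-window selection (first n_days frames) on a whole archive."""
    T = archive["sequences"].shape[1]
    if not 1 <= n_days <= T:
        raise InvalidWindowError(f"n_days must be in [1, {T}], got {n_days}")
    out = dict(archive)
    out["sequences"] = archive["sequences"][:, :n_days]
    out["date_indices"] = archive["date_indices"][:n_days]
    return out


# ---------------------------------------------------------------------------
# raster + label-table ingestion
# ---------------------------------------------------------------------------

def read_raster_frame(path, date_index: int, plot_id: str,
                      channel_names=CANONICAL_CHANNELS) -> MultispectralFrame:
    """Read a multiband TIFF as a frame; bands are taken positionally in the
    canonical order unless ``channel_names`` overrides them."""
    import tifffile
    arr = np.asarray(tifffile.imread(path), dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 3 and arr.shape[0] > arr.shape[2] and arr.shape[2] <= 8:
        arr = np.moveaxis(arr, -1, 0)       # (H, W, C) -> (C, H, W)
    return MultispectralFrame(arr, tuple(channel_names)[:arr.shape[0]],
                              date_index, plot_id)


def load_plot_table(csv_path) -> pd.DataFrame:
    """Read the plot-label table (columns: plot_id, class_name, date, path)."""
    df = pd.read_csv(csv_path)
    required = {"plot_id", "class_name", "date", "path"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"label table missing columns {sorted(missing)}")
    return df


def build_archive_from_table(csv_path, trim_fraction: float = 0.05,
                             patch_size: int | None = None,
                             stride: int | None = None) -> dict:
    """Full ingestion pipeline: table → rasters → trim → ROIs → sequences."""
    df = load_plot_table(csv_path)
    date_rank = {d: i for i, d in enumerate(sorted(df["date"].unique()))}
    frames, labels = [], {}
    for row in df.itertuples():
        frame = read_raster_frame(row.path, date_rank[row.date], str(row.plot_id))
        if trim_fraction:
            frame = trim_border(frame, trim_fraction)
        if patch_size is not None:
            frames.extend(sliding_window_rois(frame, patch_size, stride))
        else:
            frames.append(frame)
        labels[str(row.plot_id)] = StressLabel.from_name(row.class_name)
    return sequences_to_archive(assemble_sequences(frames, labels))
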