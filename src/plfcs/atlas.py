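"""Atlas-based ROI extraction from NIfTI volumes.

Reads an integer-labelled parcellation volume plus a region lookup table,
and reduces 4D functional / 3D PET volumes to per-region mean signals.
Inputs are assumed parcel-ready (motion-corrected, normalised, resampled to
a grid congruent with the atlas); no spatial preprocessing is performed here.

The region table's row order is the canonical node order: every downstream
matrix and vector carries ``region_labels`` in exactly this order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd

PathLike = Union[str, os.PathLike]

__all__ = [
    "AtlasDefinition",
    "ParcellatedTimeSeries",
    "load_atlas",
    "extract_roi_timeseries",
    "extract_roi_means",
    "reference_mean",
    "bandpass_filter",
    "write_timeseries_tsv",
    "read_timeseries_tsv",
]


@dataclass
class AtlasDefinition:
    """An integer-labelled parcellation and its region lookup table.

    ``region_table`` must have columns ``label_id``, ``name``, ``hemisphere``;
    its row order defines the canonical node order used by every downstream
    vector and matrix.
    """

    label_volume: np.ndarray
    region_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if not np.issubdtype(self.label_volume.dtype, np.integer):
            # tolerate float-stored label maps that are integral-valued
            rounded = np.round(self.label_volume)
            if not np.allclose(self.label_volume, rounded, atol=1e-6):
                raise ValueError("atlas label volume is not integer-valued")
            self.label_volume = rounded.astype(np.int64)
        required = {"label_id", "name", "hemisphere"}
        missing = required - set(self.region_table.columns)
        if missing:
            raise ValueError(f"region table missing columns: {sorted(missing)}")
        ids = self.region_table["label_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            dupes = sorted(pd.Series(ids)[pd.Series(ids).duplicated()].unique())
            raise ValueError(f"duplicate label ids in region table: {dupes}")
        if (ids <= 0).any():
            raise ValueError("label ids must be positive integers")
        present = np.unique(self.label_volume)
        present = present[present != 0]
        unknown = sorted(set(present.tolist()) - set(ids.tolist()))
        if unknown:
            raise ValueError(
                f"voxel labels absent from region table: {unknown}"
            )

    @property
    def labels(self) -> np.ndarray:
        """Canonical node order (region_table row order)."""
        return self.region_table["label_id"].to_numpy(dtype=np.int64)

    @property
    def names(self) -> list:
        return self.region_table["name"].tolist()

    @property
    def n_regions(self) -> int:
        return len(self.region_table)


@dataclass
class ParcellatedTimeSeries:
    """One subject's T x N matrix of ROI mean signals.

    Columns follow ``region_labels`` (canonical atlas order).
    ``sampling_interval`` is the repetition time in seconds; optional because
    synthetic cohorts need no temporal filtering.
    """

    subject_id: str
    data: np.ndarray
    region_labels: np.ndarray
    sampling_interval: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.region_labels = np.asarray(self.region_labels, dtype=np.int64)
        if self.data.ndim != 2:
            raise ValueError("time series data must be 2-D (timepoints x regions)")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 timepoints")
        if self.data.shape[1] != len(self.region_labels):
            raise ValueError(
                f"data has {self.data.shape[1]} columns but "
                f"{len(self.region_labels)} region labels"
            )
        all_nan = np.all(np.isnan(self.data), axis=0)
        if all_nan.any():
            bad = self.region_labels[all_nan].tolist()
            raise ValueError(f"columns entirely NaN for regions: {bad}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


def _load_volume(path_or_img) -> np.ndarray:
    if isinstance(path_or_img, (str, os.PathLike)):
        img = nib.load(os.fspath(path_or_img))
    else:
        img = path_or_img
    return np.asarray(img.dataobj, dtype=np.float64)


def load_atlas(label_path: PathLike, table_path: PathLike) -> AtlasDefinition:
    """Load a parcellation volume and its TSV region table.

    The TSV must have a header with columns ``label_id``, ``name``,
    ``hemisphere``. Row order becomes the canonical node order.
    """
    vol = _load_volume(label_path)
    if vol.ndim != 3:
        raise ValueError(f"atlas label volume must be 3-D, got shape {vol.shape}")
    table = pd.read_csv(table_path, sep="\t")
    return AtlasDefinition(label_volume=vol, region_table=table)


def _check_congruent(vol_shape: tuple, atlas: AtlasDefinition) -> None:
    if tuple(vol_shape) != tuple(atlas.label_volume.shape):
        raise ValueError(
            f"volume grid {tuple(vol_shape)} does not match atlas grid "
            f"{tuple(atlas.label_volume.shape)}; resample to a congruent grid first"
        )


def _region_mask(atlas: AtlasDefinition, label: int) -> np.ndarray:
    mask = atlas.label_volume == label
    if not mask.any():
        raise ValueError(f"region {label} has zero voxels in the label volume")
    return mask


def extract_roi_timeseries(
    func_path: Union[PathLike, nib.spatialimages.SpatialImage],
    atlas: AtlasDefinition,
    subject_id: str,
    sampling_interval: Optional[float] = None,
) -> ParcellatedTimeSeries:
    """Mean signal per region per timepoint from a 4D functional volume.

    Voxel means are unweighted; NaN voxels are excluded from each region's
    mean (a region that is entirely NaN raises).
    """
    data = _load_volume(func_path)
    if data.ndim != 4:
        raise ValueError(f"functional volume must be 4-D, got shape {data.shape}")
    _check_congruent(data.shape[:3], atlas)
    n_t = data.shape[3]
    out = np.empty((n_t, atlas.n_regions), dtype=np.float64)
    for k, label in enumerate(atlas.labels):
        mask = _region_mask(atlas, label)
        vox = data[mask, :]  # (n_voxels, T)
        with np.errstate(invalid="ignore"):
            out[:, k] = np.nanmean(vox, axis=0)
    return ParcellatedTimeSeries(
        subject_id=subject_id,
        data=out,
        region_labels=atlas.labels,
        sampling_interval=sampling_interval,
    )


def extract_roi_means(
    pet_path: Union[PathLike, nib.spatialimages.SpatialImage],
    atlas: AtlasDefinition,
) -> pd.Series:
    """Mean uptake per region from a 3-D volume, in canonical atlas order."""
    data = _load_volume(pet_path)
    if data.ndim != 3:
        raise ValueError(f"PET volume must be 3-D, got shape {data.shape}")
    _check_congruent(data.shape, atlas)
    means = np.empty(atlas.n_regions, dtype=np.float64)
    for k, label in enumerate(atlas.labels):
        mask = _region_mask(atlas, label)
        vox = data[mask]
        vox = vox[~np.isnan(vox)]
        if vox.size == 0:
            raise ValueError(f"region {label} contains only NaN voxels")
        means[k] = vox.mean()
    return pd.Series(means, index=atlas.labels, name="mean_uptake")


def reference_mean(
    pet_path: Union[PathLike, nib.spatialimages.SpatialImage],
    mask_path: Union[PathLike, nib.spatialimages.SpatialImage],
) -> float:
    """Unweighted mean uptake over a binary reference-region mask."""
    data = _load_volume(pet_path)
    mask = _load_volume(mask_path) > 0.5
    if data.shape != mask.shape:
        raise ValueError(
            f"PET grid {data.shape} does not match mask grid {mask.shape}"
        )
    vox = data[mask]
    vox = vox[~np.isnan(vox)]
    if vox.size == 0:
        raise ValueError("reference mask selects no (finite) voxels")
    return float(vox.mean())


def bandpass_filter(
    ts: ParcellatedTimeSeries, low_hz: float, high_hz: float
) -> ParcellatedTimeSeries:
    """Zero-phase frequency-domain band-pass filter.

    Retains Fourier components with ``low_hz <= f <= high_hz`` and zeroes the
    rest (including DC whenever ``low_hz > 0``), so the filter is exactly
    zero-phase. Typical resting-state usage is 0.01-0.08 Hz.
    """
    if ts.sampling_interval is None:
        raise ValueError(
            "sampling_interval is required for band-pass filtering; "
            "set it on the time series or skip filtering"
        )
    nyquist = 0.5 / ts.sampling_interval
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyquist}"
        )
    n_t = ts.n_timepoints
    freqs = np.fft.rfftfreq(n_t, d=ts.sampling_interval)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(ts.data, axis=0)
    spec[~keep, :] = 0.0
    filtered = np.fft.irfft(spec, n=n_t, axis=0)
    return ParcellatedTimeSeries(
        subject_id=ts.subject_id,
        data=filtered,
        region_labels=ts.region_labels,
        sampling_interval=ts.sampling_interval,
    )


def write_timeseries_tsv(ts: ParcellatedTimeSeries, path: PathLike) -> None:
    """Write rows = timepoints, columns = region labels."""
    df = pd.DataFrame(ts.data, columns=ts.region_labels)
    df.to_csv(path, sep="\t", index=False)


def read_timeseries_tsv(
    path: PathLike, subject_id: str, sampling_interval: Optional[float] = None
) -> ParcellatedTimeSeries:
    df = pd.read_csv(path, sep="\t")
    labels = np.asarray([int(c) for c in df.columns], dtype=np.int64)
    return ParcellatedTimeSeries(
        subject_id=subject_id,
        data=df.to_numpy(dtype=float),
        region_labels=labels,
        sampling_interval=sampling_interval,
    )
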