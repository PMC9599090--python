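"""Association matrices and per-node connection strength.

Each parcellated subject yields an N x N Pearson correlation matrix
(optionally Fisher z-transformed); a node's functional connection strength
(FCs, i.e. weighted degree) is the sum of absolute association weights to
all other nodes:

    mu_i = sum_{j != i} |m_ij|

The diagonal is stored as 0 and excluded from strength sums: a node is not
connected to itself, and the Fisher transform of r = 1 is infinite. Negative
weights contribute through the absolute value; no thresholding is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .atlas import ParcellatedTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "StrengthVector",
    "correlation_matrix",
    "fisher_z",
    "node_strength",
    "group_mean_strength",
]

_SCALES = ("pearson_r", "fisher_z")


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N association matrix with zero diagonal.

    ``scale`` records whether entries are raw Pearson r or Fisher z values.
    """

    values: np.ndarray
    scale: str
    region_labels: np.ndarray
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_labels = np.asarray(self.region_labels, dtype=np.int64)
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        n = len(self.region_labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} region labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("association matrix is not symmetric to 1e-12")
        if np.any(np.diagonal(self.values) != 0):
            raise ValueError("diagonal must be stored as 0 by convention")
        if self.scale == "pearson_r":
            off = self.values[~np.eye(n, dtype=bool)]
            if off.size and (np.abs(off) > 1 + 1e-12).any():
                raise ValueError("pearson_r entries must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)


@dataclass
class StrengthVector:
    """Per-node connection strength mu_i (sum of absolute weights).

    ``scale`` is provenance: which matrix scale the strengths were summed on.
    ``level`` is 'subject' or 'group_mean'.
    """

    values: np.ndarray
    level: str
    scale: str
    region_labels: np.ndarray
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_labels = np.asarray(self.region_labels, dtype=np.int64)
        if self.level not in ("subject", "group_mean"):
            raise ValueError(f"level must be 'subject' or 'group_mean', got {self.level!r}")
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if self.values.ndim != 1 or len(self.values) != len(self.region_labels):
            raise ValueError("strength vector length must match region labels")
        if (self.values < 0).any():
            raise ValueError("connection strengths must be non-negative")


def correlation_matrix(ts: ParcellatedTimeSeries) -> ConnectivityMatrix:
    """Full-length Pearson correlation between all region pairs.

    Raises if any region's signal has zero variance (its correlations are
    undefined) or fewer than 3 timepoints are available.
    """
    data = ts.data
    if data.shape[0] < 3:
        raise ValueError("need at least 3 timepoints for a correlation matrix")
    sd = data.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        bad = ts.region_labels[zero].tolist()
        raise ValueError(f"zero-variance signal in regions: {bad}")
    r = np.corrcoef(data, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(
        values=r,
        scale="pearson_r",
        region_labels=ts.region_labels,
        subject_id=ts.subject_id,
    )


def fisher_z(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Variance-stabilising transform z = arctanh(r), off-diagonal only."""
    if m.scale != "pearson_r":
        raise ValueError("fisher_z expects a pearson_r matrix")
    n = m.n_regions
    off = ~np.eye(n, dtype=bool)
    sat = np.abs(m.values) >= 1.0
    sat &= off
    if sat.any():
        i, j = np.argwhere(sat)[0]
        raise ValueError(
            f"|r| = 1 between regions {m.region_labels[i]} and "
            f"{m.region_labels[j]}; Fisher z is infinite — jitter or exclude"
        )
    z = np.zeros_like(m.values)
    z[off] = np.arctanh(m.values[off])
    return ConnectivityMatrix(
        values=z,
        scale="fisher_z",
        region_labels=m.region_labels,
        subject_id=m.subject_id,
    )


def node_strength(m: ConnectivityMatrix) -> StrengthVector:
    """mu_i = sum over j != i of |m_ij| (weighted degree)."""
    mu = np.abs(m.values).sum(axis=1)  # diagonal is 0, so j == i contributes 0
    return StrengthVector(
        values=mu,
        level="subject",
        scale=m.scale,
        region_labels=m.region_labels,
        subject_id=m.subject_id,
    )


def group_mean_strength(vectors: Sequence[StrengthVector]) -> StrengthVector:
    """Element-wise mean of per-subject strengths for a diagnostic group."""
    if len(vectors) == 0:
        raise ValueError("need at least one strength vector")
    ref = vectors[0]
    for v in vectors[1:]:
        if not np.array_equal(v.region_labels, ref.region_labels):
            raise ValueError("strength vectors have mismatched region labels")
        if v.scale != ref.scale:
            raise ValueError(
                f"strength vectors mix scales: {ref.scale} vs {v.scale}"
            )
    mean = np.mean([v.values for v in vectors], axis=0)
    return StrengthVector(
        values=mean,
        level="group_mean",
        scale=ref.scale,
        region_labels=ref.region_labels,
    )
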