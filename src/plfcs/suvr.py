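"""Semi-quantitative ROI-based PET analysis (SUVR).

Regional tracer uptake is normalised by the mean uptake of a reference
region (the entire cerebellum for tau tracers, supplied as a separate
binary mask because the 246-region cortical/subcortical parcellation
excludes cerebellum):

    SUVR_k = mean uptake in region k / mean uptake in reference mask

The ratio is invariant to global multiplicative rescaling of the PET
volume, i.e. independent of injected dose and decay normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["SUVRVector", "compute_suvr", "group_mean_suvr", "global_suvr"]


@dataclass
class SUVRVector:
    """Per-region standardized uptake value ratio for one subject or group."""

    values: np.ndarray
    region_labels: np.ndarray
    reference_region: str
    subject_id: Optional[str] = None
    level: str = "subject"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_labels = np.asarray(self.region_labels, dtype=np.int64)
        if self.values.shape != self.region_labels.shape:
            raise ValueError("SUVR length must match region labels")
        if self.level not in ("subject", "group_mean"):
            raise ValueError("level must be 'subject' or 'group_mean'")
        if (self.values <= 0).any():
            bad = self.region_labels[self.values <= 0].tolist()
            raise ValueError(
                f"physically valid uptake ratios must be positive; "
                f"offending regions: {bad}"
            )


def compute_suvr(
    region_means: Union[pd.Series, np.ndarray],
    reference_mean: float,
    region_labels: Optional[np.ndarray] = None,
    reference_region: str = "cerebellum",
    subject_id: Optional[str] = None,
) -> SUVRVector:
    """SUVR_k = region mean uptake / reference-region mean uptake."""
    if reference_mean <= 0:
        raise ValueError(f"reference mean uptake must be positive, got {reference_mean}")
    if isinstance(region_means, pd.Series):
        if region_labels is None:
            region_labels = region_means.index.to_numpy(dtype=np.int64)
        values = region_means.to_numpy(dtype=float)
    else:
        values = np.asarray(region_means, dtype=float)
        if region_labels is None:
            raise ValueError("region_labels required when region_means is an array")
    return SUVRVector(
        values=values / float(reference_mean),
        region_labels=np.asarray(region_labels, dtype=np.int64),
        reference_region=reference_region,
        subject_id=subject_id,
    )


def group_mean_suvr(vectors: Sequence[SUVRVector]) -> SUVRVector:
    """Element-wise mean SUVR over a diagnostic group."""
    if len(vectors) == 0:
        raise ValueError("need at least one SUVR vector")
    ref = vectors[0]
    for v in vectors[1:]:
        if not np.array_equal(v.region_labels, ref.region_labels):
            raise ValueError("SUVR vectors have mismatched region labels")
        if v.reference_region != ref.reference_region:
            raise ValueError(
                f"SUVR vectors mix reference regions: "
                f"{ref.reference_region} vs {v.reference_region}"
            )
    mean = np.mean([v.values for v in vectors], axis=0)
    return SUVRVector(
        values=mean,
        region_labels=ref.region_labels,
        reference_region=ref.reference_region,
        level="group_mean",
    )


def global_suvr(v: SUVRVector) -> float:
    """Scalar summary: the region-mean SUVR."""
    return float(v.values.mean())
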