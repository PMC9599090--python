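"""Proportional loss of functional connectivity strength (PLFCS).

For a subject's per-node connection strength mu_i and a baseline derived
from the normal-control group, the statistic is

    Loss_i = (mu_i - sigma) / sigma

with sigma the mean connection strength over all nodes of the baseline
group (the ``global_scalar`` variant, the default). Under this convention a
positive value means the node's strength EXCEEDS the baseline reference.
Two documented alternatives exist because the literature is ambiguous about
both choices:

* ``variant="per_node"`` uses sigma_i = the baseline group's mean strength
  of node i, so Loss_i measures each node's own proportional change. The
  hub-vulnerability analysis (NC strength vs disease loss across nodes)
  is only meaningful in this variant: with a single global sigma, Loss_i
  is an affine function of mu_i and simply inherits the hub ordering.
* ``sign="inverted"`` computes (sigma - mu_i) / sigma so that loss of
  strength reads as a positive number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .connectivity import StrengthVector

__all__ = [
    "BaselineSigma",
    "PLFCSVector",
    "baseline_sigma",
    "plfcs",
    "group_mean_plfcs",
    "global_plfcs",
]

_VARIANTS = ("global_scalar", "per_node")
_SIGNS = ("as_printed", "inverted")


@dataclass
class BaselineSigma:
    """Baseline connection-strength reference sigma.

    ``global_scalar``: sigma is one number, the node-mean of the baseline
    group's mean strengths. ``per_node``: sigma is a length-N vector of the
    baseline group's per-node mean strengths.
    """

    sigma: Union[float, np.ndarray]
    variant: str
    source_group: str
    scale: str
    region_labels: np.ndarray
    n_baseline_subjects: Optional[int] = None

    def __post_init__(self) -> None:
        self.region_labels = np.asarray(self.region_labels, dtype=np.int64)
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")
        if self.variant == "global_scalar":
            self.sigma = float(self.sigma)
            if self.sigma <= 0:
                raise ValueError("global baseline sigma must be positive")
        else:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.region_labels.shape:
                raise ValueError("per-node sigma length must match region labels")
            if (self.sigma <= 0).any():
                bad = self.region_labels[self.sigma <= 0].tolist()
                raise ValueError(
                    f"per-node baseline sigma must be positive; offending regions: {bad}"
                )


@dataclass
class PLFCSVector:
    """Per-node proportional loss for one subject or a group mean."""

    values: np.ndarray
    baseline: BaselineSigma
    region_labels: np.ndarray
    subject_id: Optional[str] = None
    level: str = "subject"
    sign: str = "as_printed"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_labels = np.asarray(self.region_labels, dtype=np.int64)
        if self.level not in ("subject", "group_mean"):
            raise ValueError("level must be 'subject' or 'group_mean'")
        if self.sign not in _SIGNS:
            raise ValueError(f"sign must be one of {_SIGNS}")
        if self.values.shape != self.region_labels.shape:
            raise ValueError("PLFCS length must match region labels")
        # strengths >= 0 and a positive scalar sigma bound Loss_i below by -1
        if (
            self.baseline.variant == "global_scalar"
            and self.sign == "as_printed"
            and (self.values < -1 - 1e-12).any()
        ):
            raise ValueError("global-scalar PLFCS cannot fall below -1")


def baseline_sigma(
    nc_group_strength: StrengthVector, variant: str = "global_scalar"
) -> BaselineSigma:
    """Derive the baseline reference from the control group's mean strengths."""
    if nc_group_strength.level != "group_mean":
        raise ValueError("baseline must be computed from a group_mean strength vector")
    vals = nc_group_strength.values
    if (vals < 0).any():
        raise ValueError("baseline strengths must be non-negative")
    if not vals.any():
        raise ValueError("baseline strengths are all zero; sigma would be 0")
    if variant == "global_scalar":
        sigma = float(vals.mean())
    elif variant == "per_node":
        if (vals == 0).any():
            bad = nc_group_strength.region_labels[vals == 0].tolist()
            raise ValueError(
                f"per-node baseline has zero strength for regions: {bad}"
            )
        sigma = vals.copy()
    else:
        raise ValueError(f"variant must be one of {_VARIANTS}")
    return BaselineSigma(
        sigma=sigma,
        variant=variant,
        source_group=nc_group_strength.subject_id or "NC",
        scale=nc_group_strength.scale,
        region_labels=nc_group_strength.region_labels,
    )


def plfcs(
    subject_strength: StrengthVector,
    baseline: BaselineSigma,
    sign: str = "as_printed",
) -> PLFCSVector:
    """Loss_i = (mu_i - sigma) / sigma against the baseline reference."""
    if subject_strength.scale != baseline.scale:
        raise ValueError(
            f"scale provenance mismatch: strengths are {subject_strength.scale}, "
            f"baseline is {baseline.scale}"
        )
    if not np.array_equal(subject_strength.region_labels, baseline.region_labels):
        raise ValueError("region labels of strengths and baseline do not match")
    if sign not in _SIGNS:
        raise ValueError(f"sign must be one of {_SIGNS}")
    loss = (subject_strength.values - baseline.sigma) / baseline.sigma
    if sign == "inverted":
        loss = -loss
    return PLFCSVector(
        values=loss,
        baseline=baseline,
        region_labels=subject_strength.region_labels,
        subject_id=subject_strength.subject_id,
        level=subject_strength.level,
        sign=sign,
    )


def group_mean_plfcs(vectors: Sequence[PLFCSVector]) -> PLFCSVector:
    """Element-wise mean of subject-level PLFCS vectors sharing one baseline."""
    if len(vectors) == 0:
        raise ValueError("need at least one PLFCS vector")
    ref = vectors[0]
    for v in vectors[1:]:
        if v.baseline is not ref.baseline and not _same_baseline(v.baseline, ref.baseline):
            raise ValueError("PLFCS vectors were computed against different baselines")
        if not np.array_equal(v.region_labels, ref.region_labels):
            raise ValueError("PLFCS vectors have mismatched region labels")
        if v.sign != ref.sign:
            raise ValueError("PLFCS vectors mix sign conventions")
    mean = np.mean([v.values for v in vectors], axis=0)
    return PLFCSVector(
        values=mean,
        baseline=ref.baseline,
        region_labels=ref.region_labels,
        level="group_mean",
        sign=ref.sign,
    )


def global_plfcs(v: PLFCSVector) -> float:
    """Scalar summary: the node-mean of a PLFCS vector."""
    return float(v.values.mean())


def _same_baseline(a: BaselineSigma, b: BaselineSigma) -> bool:
    if a.variant != b.variant or a.scale != b.scale:
        return False
    if a.variant == "global_scalar":
        return a.sigma == b.sigma
    return np.array_equal(a.sigma, b.sigma)
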