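"""Rejection algorithm (RA): drop slices carrying no discriminative content.

A slice is rejected when the sum of its pixel values falls at or below a
threshold ``T_h``; at the empirically optimal ``T_h = 0`` this removes
exactly the all-zero (blank) slices that survive skull-stripped MRI volumes.
The filter runs per class, before any train/test split, and never alters
class labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .imaging_io import DatasetIndex, DatasetRecord, load_image, validate_image8

logger = logging.getLogger(__name__)


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal round-half-up (the convention used for all printed percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RejectionConfig:
    """Threshold on the pixel-value sum; slices with sum <= threshold go."""

    threshold: int = 0

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("rejection threshold must be >= 0")


@dataclass
class RejectionReport:
    kept: dict[int, int] = field(default_factory=lambda: {0: 0, 1: 0})
    rejected: dict[int, int] = field(default_factory=lambda: {0: 0, 1: 0})
    rejected_files: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)

    def reduction_pct(self, label: int) -> float:
        total = self.kept[label] + self.rejected[label]
        if total == 0:
            return 0.0
        return reduction_percentage(total, self.rejected[label])

    def to_dict(self) -> dict:
        return {
            "kept": dict(self.kept),
            "rejected": dict(self.rejected),
            "reduction_pct": {c: self.reduction_pct(c) for c in (0, 1)},
            "rejected_files": list(self.rejected_files),
            "errors": list(self.errors),
        }


def reduction_percentage(total: int, rejected: int) -> float:
    """100 * rejected / total, rounded half-up to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * rejected / total, 2)


def pixel_sum(img: np.ndarray) -> int:
    """Exact integer sum of all pixel values of an Image8."""
    return int(validate_image8(img).astype(np.int64).sum())


def apply_rejection(
    index: DatasetIndex,
    cfg: RejectionConfig | None = None,
    *,
    loader=load_image,
) -> tuple[DatasetIndex, RejectionReport]:
    """Flag every record whose pixel sum is <= the threshold as rejected.

    Unreadable files are logged, counted in ``report.errors`` and flagged
    rejected rather than silently dropped, so the count identity
    ``original = kept + rejected`` holds per class.  The operation is
    idempotent and label-preserving.
    """
    if cfg is None:
        cfg = RejectionConfig()
    if len(index) == 0:
        raise ValueError("cannot apply rejection to an empty index")
    report = RejectionReport()
    new_records = []
    for rec in index.records:
        try:
            reject = pixel_sum(loader(rec.path)) <= cfg.threshold
        except Exception as exc:  # noqa: BLE001 - unreadable file is a data defect
            logger.warning("rejecting unreadable file %s: %s", rec.path, exc)
            report.errors.append(rec.path)
            reject = True
        new_records.append(DatasetRecord(rec.path, rec.label, rejected=reject))
        if reject:
            report.rejected[rec.label] += 1
            report.rejected_files.append(rec.path)
        else:
            report.kept[rec.label] += 1
    for label in (0, 1):
        logger.info(
            "RA class %d: kept %d, rejected %d (%.2f%%)",
            label,
            report.kept[label],
            report.rejected[label],
            report.reduction_pct(label),
        )
    return DatasetIndex(new_records), report
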