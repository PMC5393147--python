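"""Array normalization, qPCR relative quantification, and survival-assay
normalization.

Array intensities are background corrected against negative controls, scaled
sample-wise to the grand mean plate intensity, then log2 transformed. qPCR CT
values are converted to fold changes by the 2^-ddCT method; when several
endogenous controls are given (e.g. miR-16 and let-7a for tissue), the control
CT is the arithmetic mean of their CTs, which equals the geometric mean of
their linear 2^-CT quantities — a naive geometric mean of the CT cycles
themselves would differ. 5-FU survival assays (nuclei counts) are expressed as
percent survival versus untreated cells, and as fold survival normalized to
vehicle and then to the non-targeting transfection control (NTC).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, _delimiter_for

logger = logging.getLogger(__name__)

__all__ = [
    "QPCRSet",
    "SurvivalAssay",
    "background_correct",
    "normalize_plate_mean",
    "log2_transform",
    "ddct_fold_change",
    "normalize_survival",
    "read_qpcr_table",
    "read_survival_table",
]


def background_correct(
    matrix: ExpressionMatrix,
    negative_ids: Sequence[str] | Mapping[str, float] | float,
) -> ExpressionMatrix:
    """Subtract the per-sample negative-control mean from a linear-scale matrix.

    ``negative_ids`` is either a set of negative-control feature IDs present
    in the matrix (removed from the output), a per-sample scalar mapping, or a
    single scalar applied to every sample. Corrected values are floored at
    eps = half the smallest positive corrected value, so a later log transform
    stays defined.
    """
    if matrix.is_log:
        raise ValueError("background correction applies to linear-scale data")
    if isinstance(negative_ids, (int, float)):
        neg_mean = np.full(matrix.n_samples, float(negative_ids))
        keep = matrix.feature_ids
    elif isinstance(negative_ids, Mapping):
        if not negative_ids:
            raise ValueError("empty negative-control set")
        neg_mean = np.array([float(negative_ids[s]) for s in matrix.sample_ids])
        keep = matrix.feature_ids
    else:
        negative_ids = list(negative_ids)
        if not negative_ids:
            raise ValueError("empty negative-control set")
        rows = [matrix.feature_index(f) for f in negative_ids]
        neg_mean = matrix.values[rows].mean(axis=0)
        keep = [f for f in matrix.feature_ids if f not in set(negative_ids)]

    rows = [matrix.feature_index(f) for f in keep]
    corrected = matrix.values[rows] - neg_mean[np.newaxis, :]
    positive = corrected[corrected > 0]
    if positive.size == 0:
        logger.warning("all background-corrected values are at the floor")
        eps = 0.0
    else:
        eps = 0.5 * positive.min()
    corrected = np.maximum(corrected, eps)
    return ExpressionMatrix(keep, matrix.sample_ids, corrected, is_log=False)


def normalize_plate_mean(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample so its mean intensity equals the grand mean of all
    sample means. Idempotent; preserves within-sample rank order."""
    if matrix.is_log:
        raise ValueError("plate-mean normalization applies to linear-scale data")
    sample_means = matrix.values.mean(axis=0)
    zero = np.nonzero(sample_means <= 0)[0]
    if zero.size:
        raise ValueError(f"sample {matrix.sample_ids[zero[0]]!r} has non-positive mean")
    grand = sample_means.mean()
    return matrix.with_values(matrix.values * (grand / sample_means)[np.newaxis, :])


def log2_transform(matrix: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """log2(value + offset); requires every shifted value to be positive."""
    if matrix.is_log:
        raise ValueError("matrix is already on log2 scale")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    shifted = matrix.values + offset
    bad = np.argwhere(shifted <= 0)
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-positive value at feature {matrix.feature_ids[r]!r}, "
            f"sample {matrix.sample_ids[c]!r} with offset {offset}"
        )
    return matrix.with_values(np.log2(shifted), is_log=True)


@dataclasses.dataclass
class QPCRSet:
    """CT values keyed by (target, sample), with endogenous-control targets and
    the calibrator samples defining the reference condition."""

    ct: dict[tuple[str, str], float]
    endo_controls: list[str]
    calibrator_samples: list[str]

    def __post_init__(self) -> None:
        if not self.endo_controls:
            raise ValueError("at least one endogenous control is required")
        if not self.calibrator_samples:
            raise ValueError("calibrator sample set is empty")
        for key, value in self.ct.items():
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"CT for {key} must be finite and > 0, got {value}")
        samples = {s for _, s in self.ct}
        for s in samples:
            for c in self.endo_controls:
                if (c, s) not in self.ct:
                    raise ValueError(f"sample {s!r} lacks CT for endogenous control {c!r}")

    def delta_ct(self, target: str, sample: str) -> float:
        """dCT = CT_target − mean CT of the endogenous controls (arithmetic
        mean of cycles = geometric mean of the linear quantities)."""
        if (target, sample) not in self.ct:
            raise KeyError(f"no CT for target {target!r} in sample {sample!r}")
        control = float(np.mean([self.ct[(c, sample)] for c in self.endo_controls]))
        return self.ct[(target, sample)] - control


def ddct_fold_change(qpcr: QPCRSet, target: str, sample: str) -> float:
    """Relative expression by the 2^-ddCT method.

    ddCT = dCT(sample) − mean dCT over the calibrator samples; the returned
    fold change is 2^-ddCT (1.0 when the sample behaves like the calibrator).
    Invariant to adding a constant to all of a sample's CTs.
    """
    dct = qpcr.delta_ct(target, sample)
    calibrator = float(np.mean([qpcr.delta_ct(target, s) for s in qpcr.calibrator_samples]))
    return float(2.0 ** (-(dct - calibrator)))


def read_qpcr_table(
    path: str | Path,
    endo_controls: Sequence[str],
    calibrator_samples: Sequence[str],
) -> QPCRSet:
    """Read a (target, sample, ct) delimited table."""
    df = pd.read_csv(path, sep=_delimiter_for(path))
    missing = {"target", "sample", "ct"} - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    ct = {
        (str(row.target), str(row.sample)): float(row.ct)
        for row in df.itertuples(index=False)
    }
    return QPCRSet(ct, list(endo_controls), list(calibrator_samples))


TREATMENTS = ("untreated", "vehicle", "5-FU")


@dataclasses.dataclass
class SurvivalAssay:
    """Nuclei counts per (condition, transfection, treatment).

    ``condition`` is the oxygen condition label (e.g. "20.9%" or "0.2%"),
    ``transfection`` the mimic/inhibitor/NTC label, ``treatment`` one of
    untreated, vehicle or 5-FU.
    """

    counts: dict[tuple[str, str, str], int]

    def __post_init__(self) -> None:
        for key, n in self.counts.items():
            if n < 0 or int(n) != n:
                raise ValueError(f"nuclei count for {key} must be a non-negative integer")

    def count(self, condition: str, transfection: str, treatment: str) -> int:
        key = (condition, transfection, treatment)
        if key not in self.counts:
            raise KeyError(f"no nuclei count for {key}")
        return int(self.counts[key])


def normalize_survival(
    assay: SurvivalAssay,
    condition: str,
    transfection: str,
    ntc_label: str,
) -> tuple[float, float]:
    """Survival normalization for one transfection under one oxygen condition.

    Returns ``(survival_pct, fold_survival)`` where
    survival_pct = 100 × 5-FU / untreated nuclei for the transfection, and
    fold_survival = (5-FU/vehicle of the transfection) divided by
    (5-FU/vehicle of its non-targeting control). An NTC measured against
    itself has fold_survival exactly 1.
    """
    def ratio(label: str, num: str, den: str) -> float:
        d = assay.count(condition, label, den)
        if d == 0:
            raise ValueError(f"zero {den!r} count for {label!r} under {condition!r}")
        return assay.count(condition, label, num) / d

    survival_pct = 100.0 * ratio(transfection, "5-FU", "untreated")
    fold_survival = ratio(transfection, "5-FU", "vehicle") / ratio(ntc_label, "5-FU", "vehicle")
    return survival_pct, fold_survival


def read_survival_table(path: str | Path) -> SurvivalAssay:
    """Read a (condition, transfection, treatment, nuclei_count) table."""
    df = pd.read_csv(path, sep=_delimiter_for(path))
    missing = {"condition", "transfection", "treatment", "nuclei_count"} - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    counts = {
        (str(r.condition), str(r.transfection), str(r.treatment)): int(r.nuclei_count)
        for r in df.itertuples(index=False)
    }
    return SurvivalAssay(counts)
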