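"""Normalization and filtering of raw intensity matrices.

The preprocessing chain for single-colour miRNA arrays is: remove features
flagged undetected, threshold raw intensities at the detection floor, move to
log2 scale, and cyclically lowess-normalize all arrays together against their
row-mean reference ("fastlo" style multi-array normalization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

logger = logging.getLogger(__name__)

RAW = "raw"
LOG2 = "log2"

#: Raw-intensity detection floor of the array platform.
DEFAULT_FLOOR = 5.0


@dataclass
class ExpressionDataset:
    """A features x samples expression matrix with sample annotation.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample.
        Raw intensities or log2 intensities, tracked by ``scale``.
    sample_annotation
        DataFrame indexed by sample id with columns ``patient``, ``tissue``
        (``tumour`` / ``peritumour``), ``subtype``, ``replicate_of`` (empty
        string for primary measurements, otherwise the sample id this column
        replicates) and ``pt_stage`` (ordinal pathological tumour stage).
    detection_flags
        Boolean DataFrame aligned with ``values``; True = detected.
    scale
        ``"raw"`` or ``"log2"``.
    """

    values: pd.DataFrame
    sample_annotation: pd.DataFrame
    detection_flags: pd.DataFrame | None = None
    scale: str = RAW

    def __post_init__(self) -> None:
        if self.scale not in (RAW, LOG2):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        if not self.values.columns.equals(self.sample_annotation.index):
            raise ValueError("sample annotation is not aligned with the value columns")
        if self.detection_flags is not None:
            if self.detection_flags.shape != self.values.shape:
                raise ValueError("detection flags shape mismatch")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            values=self.values.copy(),
            sample_annotation=self.sample_annotation.copy(),
            detection_flags=None if self.detection_flags is None else self.detection_flags.copy(),
            scale=self.scale,
        )

    def primary_samples(self) -> pd.Index:
        """Sample ids that are not technical replicates of another sample."""
        ann = self.sample_annotation
        if "replicate_of" not in ann.columns:
            return ann.index
        rep = ann["replicate_of"].fillna("")
        return ann.index[rep == ""]


def floor_and_log(dataset: ExpressionDataset, floor: float = DEFAULT_FLOOR) -> ExpressionDataset:
    """Threshold raw intensities at ``floor`` then move to log2 scale.

    Values below the detection floor carry no usable signal and are set to
    the floor before the log transform, so the minimum log2 value is
    ``log2(floor)``.
    """
    if floor < 0:
        raise ValueError("floor must be non-negative")
    if dataset.scale != RAW:
        raise ValueError("floor_and_log expects a raw-scale dataset")
    floored = dataset.values.clip(lower=floor)
    out = dataset.copy()
    out.values = np.log2(floored)
    out.scale = LOG2
    return out


def filter_undetected(
    dataset: ExpressionDataset,
    flags: pd.DataFrame | None = None,
    policy: str = "undetected-everywhere",
) -> ExpressionDataset:
    """Remove features according to their detection flags.

    policy:
      ``"undetected-everywhere"`` (default) — drop a feature only if it is
      flagged undetected in every sample.
      ``"not-detected-in-all"`` — stricter alternative reading: keep only
      features detected in every sample.

    Order of the retained features is preserved.
    """
    if flags is None:
        flags = dataset.detection_flags
    if flags is None:
        raise ValueError("no detection flags available")
    if flags.shape != dataset.values.shape:
        raise ValueError("detection flags shape mismatch")
    detected = flags.to_numpy(dtype=bool)
    if policy == "undetected-everywhere":
        keep = detected.any(axis=1)
    elif policy == "not-detected-in-all":
        keep = detected.all(axis=1)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_undetected: removed %d/%d features", n_removed, dataset.n_features)
    out = dataset.copy()
    out.values = dataset.values.loc[keep]
    out.detection_flags = flags.loc[keep]
    return out


def lowess_normalize(
    dataset: ExpressionDataset,
    span: float = 0.3,
    max_iter: int = 3,
    tol: float = 1e-3,
) -> ExpressionDataset:
    """Cyclic lowess multi-array normalization on the log2 scale.

    Each cycle recomputes the row-mean reference array A, then for every
    sample fits a lowess curve of M = sample - A against A and subtracts the
    fit, removing intensity-dependent array biases. Cycles repeat until the
    largest absolute adjustment drops below ``tol`` or ``max_iter`` cycles.
    """
    if dataset.scale != LOG2:
        raise ValueError("lowess_normalize expects a log2-scale dataset")
    if dataset.n_samples < 2:
        raise ValueError("multi-array normalization needs at least two samples")
    x = dataset.values.to_numpy(dtype=float).copy()
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in input")

    for _ in range(max_iter):
        a = x.mean(axis=1)
        max_adjust = 0.0
        for j in range(x.shape[1]):
            m = x[:, j] - a
            fit = _sm_lowess(m, a, frac=span, it=1, return_sorted=False)
            x[:, j] -= fit
            max_adjust = max(max_adjust, float(np.max(np.abs(fit))))
        if max_adjust < tol:
            break

    out = dataset.copy()
    out.values = pd.DataFrame(x, index=dataset.values.index, columns=dataset.values.columns)
    return out
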