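"""Matched-pair differential expression statistics.

The core of the pipeline: a replicate-based noise model, the comparison of
matched sample pairs (CMSP) statistic, plain paired and two-sample t-tests,
Fisher combination of the per-miR p-values, FDR-based selection with
per-test thresholds, and the directional intersection of per-subtype lists.

CMSP treats each patient's tumour - peritumour log2 difference as a z-score
against the technical noise scale and Fisher-combines the per-patient
two-sided normal p-values into one p-value per miR. The noise scale is the
standard deviation of differences between technical replicate measurements;
since a tumour - peritumour value is likewise a difference of two
measurements, that scale applies directly, with no sqrt(2) rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import LOG2, ExpressionDataset

logger = logging.getLogger(__name__)

#: Lower clip for p-values before taking logs in Fisher's statistic.
P_FLOOR = 1e-300


@dataclass(frozen=True)
class NoiseModel:
    """Technical noise scale for matched-pair differences.

    ``sigma`` is the standard deviation of the difference between two
    measurements of the same sample (log2 intensity), pooled over all miRs
    and replicate pairs.
    """

    sigma: float
    n_replicate_pairs: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("noise sigma must be positive")
        if self.n_replicate_pairs < 1:
            raise ValueError("a noise model needs at least one replicate pair")


@dataclass(frozen=True)
class MiRTestResult:
    """Per-miR test summary: the constituent p-values, the Fisher-combined
    p, the effect direction in tumour and the selection flag. The two-sample
    p is None for fully matched cohorts where that test is not used."""

    feature_id: str
    p_paired: float
    p_cmsp: float
    p_combined: float
    direction: str
    p_two_sample: float | None = None
    selected: bool = False

    def __post_init__(self) -> None:
        ps = [self.p_paired, self.p_cmsp, self.p_combined]
        if self.p_two_sample is not None:
            ps.append(self.p_two_sample)
        if any(not (0 < p <= 1) for p in ps):
            raise ValueError("p-values must lie in (0, 1]")
        if self.direction not in ("up", "down"):
            raise ValueError(f"invalid direction {self.direction!r}")


def results_as_records(results: pd.DataFrame) -> list[MiRTestResult]:
    """View a differential-tests DataFrame as MiRTestResult records."""
    records = []
    for fid, row in results.iterrows():
        records.append(MiRTestResult(
            feature_id=str(fid),
            p_paired=float(row["p_paired"]),
            p_cmsp=float(row["p_cmsp"]),
            p_combined=float(row["p_combined"]),
            direction=str(row["direction"]),
            p_two_sample=float(row["p_two_sample"]) if "p_two_sample" in row else None,
            selected=bool(row.get("selected", False)),
        ))
    return records


@dataclass(frozen=True)
class SelectionThresholds:
    """Selection rule parameters: FDR level on the combined p-value and a
    per-test threshold each constituent test must also pass."""

    fdr_level: float = 0.05
    per_test_p_threshold: float | None = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.fdr_level < 1):
            raise ValueError("fdr_level must be in (0, 1)")
        if self.per_test_p_threshold is not None and not (0 < self.per_test_p_threshold <= 1):
            raise ValueError("per_test_p_threshold must be in (0, 1]")


def estimate_noise(dataset: ExpressionDataset, replicate_pairs: Sequence[tuple[str, str]]) -> NoiseModel:
    """Noise scale from technical replicates.

    sigma is the sample standard deviation (n-1 denominator) of the
    intensity differences between replicate measurements, pooled over all
    miRs and all replicate pairs; the noise is assumed not to depend on the
    miR intensity level.
    """
    if len(replicate_pairs) == 0:
        raise ValueError("no replicate pairs provided")
    if dataset.scale != LOG2:
        raise ValueError("noise estimation expects log2-scale data")
    diffs = np.concatenate([
        (dataset.values[a] - dataset.values[b]).to_numpy(dtype=float)
        for a, b in replicate_pairs
    ])
    if np.all(diffs == 0):
        raise ValueError("all replicate differences are zero; noise is degenerate")
    sigma = float(np.std(diffs, ddof=1))
    return NoiseModel(sigma=sigma, n_replicate_pairs=len(replicate_pairs))


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's method: X = -2 sum(ln p_i) ~ chi-square with 2k df."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.log(np.clip(p, P_FLOOR, 1.0)).sum()
    return float(stats.chi2.sf(x, 2 * p.size))


def _fisher_combine_rows(p_matrix: np.ndarray) -> np.ndarray:
    """Row-wise Fisher combination for a features x tests p-value matrix."""
    x = -2.0 * np.log(np.clip(p_matrix, P_FLOOR, 1.0)).sum(axis=1)
    return stats.chi2.sf(x, 2 * p_matrix.shape[1])


def cmsp_pvalues(
    dataset: ExpressionDataset,
    matched_pairs: Sequence[tuple[str, str]],
    noise: NoiseModel,
) -> pd.Series:
    """Comparison-of-matched-sample-pairs p-value per miR.

    Per pair, z = (tumour - peritumour) / sigma with a two-sided standard
    normal tail probability; per miR the pair p-values are Fisher-combined.
    """
    if len(matched_pairs) == 0:
        raise ValueError("no matched pairs")
    if noise.sigma <= 0:
        raise ValueError("invalid noise model")
    tum = dataset.values[[t for t, _ in matched_pairs]].to_numpy(dtype=float)
    per = dataset.values[[p for _, p in matched_pairs]].to_numpy(dtype=float)
    z = (tum - per) / noise.sigma
    p_pair = 2.0 * stats.norm.sf(np.abs(z))
    return pd.Series(_fisher_combine_rows(p_pair), index=dataset.feature_ids, name="p_cmsp")


def paired_ttest(tumour: Sequence[float], peritumour: Sequence[float]) -> float:
    """Two-sided paired t-test p-value on matched differences."""
    a = np.asarray(tumour, dtype=float)
    b = np.asarray(peritumour, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired test needs two equal-length vectors of length >= 2")
    d = a - b
    if np.var(d, ddof=1) == 0:
        raise ValueError("zero variance of matched differences; p undefined")
    return float(stats.ttest_rel(a, b).pvalue)


def two_sample_ttest(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided pooled-variance two-sample t-test p-value."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    res = stats.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(res.pvalue):
        raise ValueError("zero pooled variance; p undefined")
    return float(res.pvalue)


def differential_tests(
    dataset: ExpressionDataset,
    matched_pairs: Sequence[tuple[str, str]],
    noise: NoiseModel,
    unmatched_tumour: Sequence[str] = (),
    unmatched_peritumour: Sequence[str] = (),
    include_two_sample: bool | None = None,
) -> pd.DataFrame:
    """All per-miR tests plus their Fisher-combined p-value.

    The two-sample t-test compares every tumour against every peritumour
    sample (matched and unmatched). When the cohort is fully matched the
    two-sample test adds nothing beyond the paired test and is omitted from
    both the output and the combination, mirroring how fully matched
    subtypes are analysed; ``include_two_sample`` overrides the automatic
    choice.

    Returns a DataFrame indexed by feature id with columns p_paired,
    p_two_sample (optional), p_cmsp, p_combined, mean_diff, direction.
    """
    if dataset.scale != LOG2:
        raise ValueError("differential tests expect log2-scale data")
    if len(matched_pairs) < 2:
        raise ValueError("need at least two matched pairs")
    if include_two_sample is None:
        include_two_sample = bool(unmatched_tumour) or bool(unmatched_peritumour)

    tum = dataset.values[[t for t, _ in matched_pairs]].to_numpy(dtype=float)
    per = dataset.values[[p for _, p in matched_pairs]].to_numpy(dtype=float)
    d = tum - per
    mean_diff = d.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        p_paired = stats.ttest_rel(tum, per, axis=1).pvalue
    p_paired = np.where(np.isfinite(p_paired), p_paired, 1.0)

    z = d / noise.sigma
    p_pair = 2.0 * stats.norm.sf(np.abs(z))
    p_cmsp = _fisher_combine_rows(p_pair)

    out = pd.DataFrame({"p_paired": p_paired}, index=dataset.feature_ids)
    parts = [p_paired]
    if include_two_sample:
        all_tum = dataset.values[list({t for t, _ in matched_pairs} | set(unmatched_tumour))]
        all_per = dataset.values[list({p for _, p in matched_pairs} | set(unmatched_peritumour))]
        with np.errstate(divide="ignore", invalid="ignore"):
            p_two = stats.ttest_ind(all_tum.to_numpy(dtype=float),
                                    all_per.to_numpy(dtype=float), axis=1, equal_var=True).pvalue
        p_two = np.where(np.isfinite(p_two), p_two, 1.0)
        out["p_two_sample"] = p_two
        parts.append(p_two)
    parts.append(p_cmsp)
    out["p_cmsp"] = p_cmsp
    out["p_combined"] = _fisher_combine_rows(np.column_stack(parts))
    out["mean_diff"] = mean_diff
    out["direction"] = np.where(mean_diff >= 0, "up", "down")
    return out


def benjamini_hochberg(p_values: np.ndarray, fdr_level: float) -> np.ndarray:
    """Boolean rejection mask of the BH step-up procedure."""
    reject, _, _, _ = multipletests(p_values, alpha=fdr_level, method="fdr_bh")
    return reject


def select_differential(
    results: pd.DataFrame,
    thresholds: SelectionThresholds,
    fdr_procedure: Callable[[np.ndarray, float], np.ndarray] = benjamini_hochberg,
) -> pd.DataFrame:
    """Flag differential miRs: combined p passes the FDR procedure AND every
    constituent test's p is at or below the per-test threshold.

    The per-test rule guards against miRs driven by one extremely small
    p-value in a single test, to which Fisher's combination is sensitive.
    """
    required = [c for c in ("p_paired", "p_cmsp", "p_combined") if c not in results.columns]
    if required:
        raise ValueError(f"missing p-value columns: {required}")
    out = results.copy()
    passed_fdr = fdr_procedure(out["p_combined"].to_numpy(dtype=float), thresholds.fdr_level)
    selected = np.asarray(passed_fdr, dtype=bool)
    if thresholds.per_test_p_threshold is not None:
        test_cols = [c for c in ("p_paired", "p_two_sample", "p_cmsp") if c in out.columns]
        for c in test_cols:
            selected &= out[c].to_numpy(dtype=float) <= thresholds.per_test_p_threshold
    out["selected"] = selected
    return out


def shared_mirs(per_subtype: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Directional intersection of per-subtype differential lists.

    A miR is shared when it is selected in every subtype with the same
    direction. miRs selected everywhere but with conflicting directions are
    returned flagged (``conflict=True``) rather than silently dropped.
    """
    if len(per_subtype) < 2:
        raise ValueError("need at least two subtype lists to intersect")
    sel = {
        name: df.loc[df["selected"].astype(bool), "direction"]
        for name, df in per_subtype.items()
    }
    names = list(sel)
    common = set(sel[names[0]].index)
    for name in names[1:]:
        common &= set(sel[name].index)
    rows = []
    for fid in sorted(common):
        dirs = {name: sel[name][fid] for name in names}
        uniq = set(dirs.values())
        rows.append({"feature_id": fid,
                     "direction": uniq.pop() if len(uniq) == 1 else "conflict",
                     "conflict": len({sel[n][fid] for n in names}) > 1})
    df = pd.DataFrame(rows, columns=["feature_id", "direction", "conflict"])
    return df.set_index("feature_id")
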