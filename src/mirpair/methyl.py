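"""Methylation quantification: bisulphite clone summaries, conversion QC,
tumour-vs-peritumour comparison, MeDIP percent-of-input and a CpG-island
finder.

Bisulphite sequencing reads methylation per CpG per clone; the fraction of
converted non-CpG cytosines is the per-clone chemistry QC metric and clones
failing it are discarded before any averaging. MeDIP enrichment is reported
as percent of the input DNA via the dilution-adjusted 2^dCt law. CpG islands
follow the Gardiner-Garden criteria (length >= 200 bp, GC >= 50%,
observed/expected CpG >= 0.6) with a sliding window.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class CloneMethylationMatrix:
    """Binary clones x CpG-positions call matrix (1 = methylated) with the
    CpG nucleotide offsets within the amplicon and the per-clone fraction of
    converted non-CpG cytosines."""

    calls: np.ndarray
    position_offsets: np.ndarray | None = None
    conversion_rates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if not np.isin(self.calls, (0, 1)).all():
            raise ValueError("calls must be binary")
        if self.conversion_rates is not None:
            cr = np.asarray(self.conversion_rates, dtype=float)
            if ((cr < 0) | (cr > 1)).any():
                raise ValueError("conversion rates must be in [0, 1]")
            self.conversion_rates = cr

    @property
    def n_clones(self) -> int:
        return self.calls.shape[0]


@dataclass(frozen=True)
class CpGIsland:
    """0-based half-open interval satisfying the CpG-island criteria."""

    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float

    @property
    def length(self) -> int:
        return self.end - self.start


def conversion_qc(clones: CloneMethylationMatrix, min_rate: float = 0.99) -> CloneMethylationMatrix:
    """Drop clones whose non-CpG conversion rate is not strictly above
    ``min_rate`` (incomplete bisulphite chemistry inflates methylation)."""
    if clones.conversion_rates is None:
        raise ValueError("per-clone conversion rates unavailable")
    keep = clones.conversion_rates > min_rate
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("conversion_qc: removed %d/%d clones", n_removed, clones.n_clones)
    if not keep.any():
        raise ValueError(
            f"all {clones.n_clones} clones fail conversion QC at {min_rate:.2%} "
            f"(rates {np.round(clones.conversion_rates, 3)})"
        )
    return CloneMethylationMatrix(
        calls=clones.calls[keep],
        position_offsets=clones.position_offsets,
        conversion_rates=clones.conversion_rates[keep],
    )


def methylation_summary(clones: CloneMethylationMatrix) -> tuple[np.ndarray, float]:
    """(per-CpG-position % methylation, overall % over all calls)."""
    if clones.calls.size == 0:
        raise ValueError("empty call matrix")
    per_position = clones.calls.mean(axis=0) * 100.0
    overall = float(clones.calls.mean() * 100.0)
    return per_position, overall


def compare_methylation(
    tumour: CloneMethylationMatrix,
    peritumour: CloneMethylationMatrix,
    n_permutations: int = 20000,
    seed: int = 0,
) -> tuple[float, float]:
    """Tumour-vs-peritumour overall methylation difference with a
    clone-label permutation p-value.

    The statistic is the difference of the group means of per-clone
    methylation fractions; the two-sided p-value counts permutations of the
    clone labels with |statistic| at least as large as observed (exact
    enumeration when feasible, otherwise ``n_permutations`` Monte-Carlo
    draws including the identity). Returns (delta in percentage points, p).
    """
    if tumour.n_clones < 2 or peritumour.n_clones < 2:
        raise ValueError("each side needs at least two clones")
    ft = tumour.calls.mean(axis=1)
    fp = peritumour.calls.mean(axis=1)
    delta = float((ft.mean() - fp.mean()) * 100.0)

    pooled = np.concatenate([ft, fp])
    n_t = ft.size
    n_total = pooled.size
    observed = abs(ft.mean() - fp.mean())

    from math import comb

    n_exact = comb(n_total, n_t)
    if n_exact <= n_permutations:
        # |mean_A - mean_B| is a monotone function of the group-A sum
        total = pooled.sum()
        n_p = n_total - n_t
        count = 0
        vals = pooled.tolist()
        for idx in itertools.combinations(range(n_total), n_t):
            s = sum(vals[i] for i in idx)
            stat = abs(s / n_t - (total - s) / n_p)
            if stat >= observed - 1e-12:
                count += 1
        p = count / n_exact
    else:
        rng = np.random.default_rng(seed)
        count = 1  # identity permutation
        for _ in range(n_permutations - 1):
            perm = rng.permutation(n_total)
            stat = abs(pooled[perm[:n_t]].mean() - pooled[perm[n_t:]].mean())
            if stat >= observed - 1e-12:
                count += 1
        p = count / n_permutations
    return delta, float(p)


def medip_percent_input(ct_ip: float, ct_input: float, input_fraction: float) -> float:
    """MeDIP enrichment as percent of input DNA.

    The input Ct is first adjusted for the dilution of the input aliquot
    (subtract log2(1/input_fraction)); the percent is then
    100 * 2^(adjusted input Ct - IP Ct), an exact exponential law: one extra
    IP cycle halves the percentage.
    """
    if not (0 < input_fraction <= 1):
        raise ValueError("input_fraction must be in (0, 1]")
    if not (np.isfinite(ct_ip) and np.isfinite(ct_input)):
        raise ValueError("Ct values must be finite")
    adjusted_input = ct_input - np.log2(1.0 / input_fraction)
    return float(100.0 * 2.0 ** (adjusted_input - ct_ip))


def _window_stats(counts_c, counts_g, counts_cg, start, end) -> tuple[float, float]:
    n = end - start
    c = counts_c[end] - counts_c[start]
    g = counts_g[end] - counts_g[start]
    cg = counts_cg[min(end - 1, len(counts_cg) - 1)] - counts_cg[start]
    gc_fraction = (c + g) / n
    obs_exp = (cg * n / (c * g)) if c > 0 and g > 0 else 0.0
    return gc_fraction, obs_exp


def find_cpg_islands(
    sequence: str,
    min_length: int = 200,
    min_gc: float = 0.5,
    min_obs_exp: float = 0.6,
    window: int | None = None,
    step: int = 1,
) -> list[CpGIsland]:
    """Sliding-window CpG-island scan with the Gardiner-Garden criteria.

    Windows of ``window`` bp (default ``min_length``) advancing by ``step``
    that satisfy GC >= min_gc and observed/expected CpG >= min_obs_exp are
    merged into maximal islands (0-based half-open coordinates); a merged
    island is trimmed from its ends until the whole span satisfies the
    criteria again. obs/exp = #CpG * N / (#C * #G).
    """
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence contains non-DNA characters")
    window = window or min_length
    n = len(seq)
    if n < min_length:
        return []

    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(int)
    is_g = (arr == ord("G")).astype(int)
    is_cg = np.zeros(n, dtype=int)
    if n > 1:
        is_cg[:-1] = ((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))).astype(int)
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])

    def passes(start: int, end: int) -> tuple[bool, float, float]:
        gc, oe = _window_stats(cum_c, cum_g, cum_cg, start, end)
        return (end - start >= min_length and gc >= min_gc and oe >= min_obs_exp), gc, oe

    hits = []
    for start in range(0, n - window + 1, step):
        ok, _, _ = passes(start, start + window)
        if ok:
            hits.append((start, start + window))
    if not hits:
        return []

    merged: list[list[int]] = [list(hits[0])]
    for s, e in hits[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    islands = []
    for s, e in merged:
        ok, gc, oe = passes(s, e)
        while not ok and e - s > min_length:
            # trim the worse-scoring end one step at a time
            ok_l, gc_l, oe_l = passes(s + step, e)
            ok_r, gc_r, oe_r = passes(s, e - step)
            if (gc_l + oe_l) >= (gc_r + oe_r):
                s += step
                ok, gc, oe = ok_l, gc_l, oe_l
            else:
                e -= step
                ok, gc, oe = ok_r, gc_r, oe_r
        if ok:
            islands.append(CpGIsland(start=s, end=e, gc_fraction=gc, obs_exp_cpg=oe))
    return islands
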