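"""Target prioritization: expression anti-correlation and set enrichment.

Candidate target genes of a miR (from an upstream sequence-based prediction)
are filtered by requiring their expression to be significantly negatively
correlated with the miR across a coupled miR/mRNA cohort, at a chosen FDR.
The surviving candidates are then tested for pathway enrichment with an
upper-tail hypergeometric test, BH-corrected across gene sets.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def anticorrelated_targets(
    mir_profile: pd.Series,
    mrna_values: pd.DataFrame,
    candidate_gene_ids: Sequence[str],
    fdr_level: float = 0.10,
) -> pd.DataFrame:
    """Pearson anti-correlation filter over a candidate target list.

    For each candidate gene present in the mRNA matrix, the Pearson
    correlation with the miR profile and its two-sided p-value are computed;
    BH correction is applied over the candidate list only, and a candidate
    is selected when r < 0 and q <= ``fdr_level``. Candidates absent from
    the matrix, and candidates with a constant profile (undefined r), are
    dropped with a warning and recorded in ``.attrs``.

    Returns a DataFrame sorted by ascending r with columns pearson_r,
    p_value, q_value, selected, indexed by gene id.
    """
    if not (0 < fdr_level < 1):
        raise ValueError("fdr_level must be in (0, 1)")
    shared = mir_profile.index.intersection(mrna_values.columns)
    if len(shared) < 3:
        raise ValueError("need at least three shared samples")
    mir = mir_profile[shared].to_numpy(dtype=float)
    if np.std(mir) == 0:
        raise ValueError("constant miR profile; correlation undefined")

    candidates = list(dict.fromkeys(candidate_gene_ids))
    missing = [g for g in candidates if g not in mrna_values.index]
    present = [g for g in candidates if g in mrna_values.index]
    if missing:
        logger.warning("%d candidate ids absent from the mRNA data", len(missing))

    x = mrna_values.loc[present, shared].to_numpy(dtype=float)
    constant_mask = x.std(axis=1) == 0
    dropped_constant = [g for g, c in zip(present, constant_mask) if c]
    if dropped_constant:
        logger.warning("%d candidates dropped with constant profiles", len(dropped_constant))
    kept = [g for g, c in zip(present, constant_mask) if not c]
    x = x[~constant_mask]

    n = len(shared)
    mir_z = (mir - mir.mean()) / mir.std()
    xz = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    r = (xz * mir_z).sum(axis=1) / n
    r = np.clip(r, -1.0, 1.0)
    # two-sided p from the exact t transform of Pearson's r
    t = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)

    if len(kept):
        _, q, _, _ = multipletests(p, alpha=fdr_level, method="fdr_bh")
    else:
        q = np.array([])
    out = pd.DataFrame({"pearson_r": r, "p_value": p, "q_value": q},
                       index=pd.Index(kept, name="gene_id"))
    out["selected"] = (out["pearson_r"] < 0) & (out["q_value"] <= fdr_level)
    out = out.sort_values("pearson_r", kind="stable")
    out.attrs["missing"] = missing
    out.attrs["dropped_constant"] = dropped_constant
    return out


def hypergeometric_enrichment(
    candidates: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a candidate list in gene sets.

    Each gene set is intersected with the universe first. p is the
    probability of observing at least the seen overlap when drawing
    ``len(candidates)`` genes without replacement from the universe;
    q is BH over the tested sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    cand = set(candidates)
    outside = cand - universe
    if outside:
        raise ValueError(f"{len(outside)} candidates outside the universe")
    m = len(universe)
    k_draws = len(cand)
    rows = []
    for name, genes in gene_sets.items():
        gs = set(genes) & universe
        overlap = len(gs & cand)
        # P(X >= overlap), X ~ Hypergeom(M=m, n=|set|, N=draws)
        p = float(stats.hypergeom.sf(overlap - 1, m, len(gs), k_draws))
        rows.append({"set_name": name, "overlap_count": overlap, "set_size": len(gs),
                     "universe_size": m, "candidate_count": k_draws, "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows).set_index("set_name")
    if len(df):
        _, q, _, _ = multipletests(df["p_value"].to_numpy(), method="fdr_bh")
        df["q_value"] = q
    return df.sort_values("p_value", kind="stable")


def rank_by_anticorrelation(candidates: pd.DataFrame, k: int) -> list[str]:
    """The k selected gene ids with the most negative correlation.

    Ties at equal r are broken lexicographically by gene id.
    """
    sel = candidates.loc[candidates["selected"].astype(bool)]
    if k > len(sel):
        raise ValueError(f"k={k} exceeds the {len(sel)} selected candidates")
    order = sel.reset_index().sort_values(["pearson_r", "gene_id"], kind="stable")
    return order["gene_id"].head(k).tolist()


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, ""] + sorted(genes)) + "\n")
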