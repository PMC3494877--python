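"""Seeded synthetic-data generators for every input the pipeline consumes.

The generators emulate the statistical structure of a matched tumour /
peritumour breast miRNA study: per-subtype matched pairs with a minority of
truly differential miRs, technical replicates for a subset of samples, a raw
intensity detection floor, coupled miR/mRNA cohorts with planted
anti-correlated target genes, exponential survival with tertile-dependent
hazard, and bisulphite clone calls with imperfect conversion chemistry.
Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clinsurv import tertile_split
from .methyl import CloneMethylationMatrix
from .preprocess import DEFAULT_FLOOR, LOG2, RAW, ExpressionDataset

DEFAULT_SUBTYPES = ("HER2+", "Basal-like", "Luminal")


@dataclass
class CohortConfig:
    """Study design of a synthetic matched tumour/peritumour miRNA cohort.

    ``effect_size`` is the planted tumour-vs-peritumour log2 fold change;
    ``noise_sigma`` the standard deviation of a single measurement (log2);
    ``n_replicated_samples`` the number of tumour samples measured twice.
    A small fraction of features (``frac_unexpressed``) is drawn near the
    raw-intensity floor so that flooring and detection-flag filtering are
    exercised the way they are on real arrays.
    """

    n_pairs_per_subtype: int = 20
    n_mirs: int = 800
    n_planted: int = 0
    effect_size: float = 1.0
    noise_sigma: float = 0.5
    n_replicated_samples: int = 8
    floor: float = DEFAULT_FLOOR
    seed: int = 0
    subtypes: tuple[str, ...] = DEFAULT_SUBTYPES
    n_unmatched_tumour: int = 0
    n_unmatched_peritumour: int = 0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    frac_unexpressed: float = 0.05
    unexpressed_mean: float = 2.0
    unexpressed_sd: float = 1.0
    stage_assoc_rho: float = 0.0
    stage_assoc_mir: str | None = None

    def __post_init__(self) -> None:
        if self.n_pairs_per_subtype <= 0 or self.n_mirs <= 0:
            raise ValueError("non-positive cohort dimensions")
        if self.n_planted > self.n_mirs:
            raise ValueError("n_planted exceeds n_mirs")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        total = 2 * self.n_pairs_per_subtype * len(self.subtypes)
        total += self.n_unmatched_tumour + self.n_unmatched_peritumour
        if self.n_replicated_samples > total:
            raise ValueError("more replicated samples than samples")


@dataclass
class PlantedTruth:
    """Ground truth planted by a generator, for recovery tests."""

    differential: dict[str, str] = field(default_factory=dict)  # feature id -> up/down
    target_gene_ids: set[str] = field(default_factory=set)
    survival_hazard_ratio: float = 1.0

    def __post_init__(self) -> None:
        bad = {d for d in self.differential.values()} - {"up", "down"}
        if bad:
            raise ValueError(f"invalid directions {bad}")
        if self.survival_hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")


def _stage_from_latent(latent: np.ndarray) -> np.ndarray:
    """Ordinal pT stage 1/2/3 from a latent score at 30/80% cut points."""
    q30, q80 = np.quantile(latent, [0.3, 0.8])
    return 1 + (latent > q30).astype(int) + (latent > q80).astype(int)


def generate_mir_cohort(config: CohortConfig) -> tuple[ExpressionDataset, PlantedTruth]:
    """Simulate a matched tumour/peritumour miRNA intensity cohort.

    log2 intensities are feature baseline + tissue effect (planted miRs,
    tumour samples only) + N(0, noise_sigma) per measurement; raw
    intensities are 2**log2. Matched samples share a patient id; the first
    ``n_replicated_samples`` tumour samples receive a technical replicate
    drawn with fresh measurement noise. Detection flags mark raw values at
    or above the floor.
    """
    rng = np.random.default_rng(config.seed)
    n_mirs = config.n_mirs

    feature_ids = pd.Index([f"miR-{i + 1:04d}" for i in range(n_mirs)], name="feature_id")
    n_unexpr = int(round(config.frac_unexpressed * n_mirs))
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n_mirs)
    unexpr_idx = rng.choice(n_mirs, size=n_unexpr, replace=False) if n_unexpr else np.array([], dtype=int)
    baseline[unexpr_idx] = rng.normal(config.unexpressed_mean, config.unexpressed_sd, n_unexpr)

    expressed = np.setdiff1d(np.arange(n_mirs), unexpr_idx)
    if config.n_planted > expressed.size:
        raise ValueError("not enough expressed features to plant")
    planted_idx = rng.choice(expressed, size=config.n_planted, replace=False)
    directions = rng.choice(["up", "down"], size=config.n_planted)
    effect = np.zeros(n_mirs)
    effect[planted_idx] = np.where(directions == "up", config.effect_size, -config.effect_size)

    sample_ids: list[str] = []
    ann_rows: list[dict] = []
    signal_cols: list[np.ndarray] = []

    for s_i, subtype in enumerate(config.subtypes):
        for p in range(config.n_pairs_per_subtype):
            pid = f"S{s_i + 1}P{p + 1:03d}"
            for tissue, suffix in (("tumour", "T"), ("peritumour", "PT")):
                sample_ids.append(f"{pid}_{suffix}")
                ann_rows.append(
                    {"patient": pid, "tissue": tissue, "subtype": subtype, "replicate_of": ""}
                )
                signal_cols.append(baseline + (effect if tissue == "tumour" else 0.0))
    for k in range(config.n_unmatched_tumour):
        pid = f"UT{k + 1:03d}"
        sample_ids.append(f"{pid}_T")
        ann_rows.append({"patient": pid, "tissue": "tumour",
                         "subtype": config.subtypes[k % len(config.subtypes)], "replicate_of": ""})
        signal_cols.append(baseline + effect)
    for k in range(config.n_unmatched_peritumour):
        pid = f"UP{k + 1:03d}"
        sample_ids.append(f"{pid}_PT")
        ann_rows.append({"patient": pid, "tissue": "peritumour",
                         "subtype": config.subtypes[k % len(config.subtypes)], "replicate_of": ""})
        signal_cols.append(baseline)

    ann = pd.DataFrame(ann_rows, index=pd.Index(sample_ids, name="sample_id"))

    # technical replicates: same expected signal, fresh measurement noise
    tumour_ids = [s for s in sample_ids if ann.loc[s, "tissue"] == "tumour"]
    for s in tumour_ids[: config.n_replicated_samples]:
        rep_id = f"{s}_r2"
        sample_ids.append(rep_id)
        row = ann.loc[s].to_dict()
        row["replicate_of"] = s
        ann.loc[rep_id] = row
        signal_cols.append(signal_cols[list(ann.index).index(s)])
    ann = ann.loc[sample_ids]

    signal = np.column_stack(signal_cols)
    log2_values = signal + rng.normal(0.0, config.noise_sigma, signal.shape)
    raw = np.exp2(log2_values)

    # ordinal pT stage per patient, optionally coupled to one miR's tumour expression
    patients = ann.loc[ann["replicate_of"] == "", "patient"].unique()
    if config.stage_assoc_rho != 0.0:
        mir = config.stage_assoc_mir or feature_ids[planted_idx[0] if config.n_planted else 0]
        mir_row = feature_ids.get_loc(mir)
        tum_col = {ann.loc[s, "patient"]: j for j, s in enumerate(sample_ids)
                   if ann.loc[s, "tissue"] == "tumour" and ann.loc[s, "replicate_of"] == ""}
        expr = np.array([log2_values[mir_row, tum_col.get(p, 0)] for p in patients])
        z = (expr - expr.mean()) / (expr.std() or 1.0)
        rho = config.stage_assoc_rho
        latent = rho * z + np.sqrt(1 - rho**2) * rng.normal(size=len(patients))
    else:
        latent = rng.normal(size=len(patients))
    stage = dict(zip(patients, _stage_from_latent(latent)))
    ann["pt_stage"] = [stage.get(p, 1) for p in ann["patient"]]

    values = pd.DataFrame(raw, index=feature_ids, columns=pd.Index(sample_ids, name="sample_id"))
    flags = pd.DataFrame(raw >= config.floor, index=feature_ids, columns=values.columns)
    dataset = ExpressionDataset(values=values, sample_annotation=ann,
                                detection_flags=flags, scale=RAW)
    truth = PlantedTruth(differential={feature_ids[i]: d
                                       for i, d in zip(planted_idx, directions)})
    return dataset, truth


def matched_pairs(dataset: ExpressionDataset, subtype: str | None = None) -> list[tuple[str, str]]:
    """(tumour sample, peritumour sample) id pairs per patient from annotation."""
    ann = dataset.sample_annotation
    rep = ann["replicate_of"].fillna("") if "replicate_of" in ann.columns else pd.Series("", index=ann.index)
    primary = ann.loc[rep == ""]
    if subtype is not None:
        primary = primary.loc[primary["subtype"] == subtype]
    pairs = []
    for pid, grp in primary.groupby("patient", sort=False):
        t = grp.index[grp["tissue"] == "tumour"]
        p = grp.index[grp["tissue"] == "peritumour"]
        if len(t) == 1 and len(p) == 1:
            pairs.append((t[0], p[0]))
    return pairs


def replicate_pairs(dataset: ExpressionDataset) -> list[tuple[str, str]]:
    """(primary sample, technical replicate) id pairs from annotation."""
    ann = dataset.sample_annotation
    if "replicate_of" not in ann.columns:
        return []
    rep = ann["replicate_of"].fillna("")
    return [(rep[s], s) for s in ann.index if rep[s] != ""]


def generate_coupled_mir_mrna(
    n_samples: int = 100,
    n_genes: int = 736,
    n_anticorrelated: int = 42,
    rho: float = -0.7,
    seed: int = 0,
) -> tuple[pd.Series, ExpressionDataset, PlantedTruth]:
    """Coupled miR/mRNA profiles with planted anti-correlated target genes.

    Planted genes are drawn jointly with the miR profile at population
    Pearson correlation ``rho`` (< 0); all other genes are independent of it.
    """
    if not (-1.0 < rho < 0.0):
        raise ValueError("rho must be in (-1, 0) for planted anti-correlation")
    if n_anticorrelated > n_genes:
        raise ValueError("n_anticorrelated exceeds n_genes")
    rng = np.random.default_rng(seed)
    samples = pd.Index([f"BC{i + 1:03d}" for i in range(n_samples)], name="sample_id")
    mir_z = rng.normal(size=n_samples)
    mir = pd.Series(8.0 + mir_z, index=samples, name="miR")

    gene_ids = pd.Index([f"GENE{i + 1:04d}" for i in range(n_genes)], name="feature_id")
    planted = rng.choice(n_genes, size=n_anticorrelated, replace=False)
    eps = rng.normal(size=(n_genes, n_samples))
    expr = 8.0 + eps
    expr[planted] = 8.0 + rho * mir_z + np.sqrt(1 - rho**2) * eps[planted]

    ann = pd.DataFrame({"patient": samples, "tissue": "tumour",
                        "subtype": "", "replicate_of": "", "pt_stage": 1}, index=samples)
    mrna = ExpressionDataset(values=pd.DataFrame(expr, index=gene_ids, columns=samples),
                             sample_annotation=ann, scale=LOG2)
    truth = PlantedTruth(target_gene_ids={gene_ids[i] for i in planted})
    return mir, mrna, truth


def generate_survival_cohort(
    n_patients: int,
    hazard_ratio: float,
    censor_rate: float,
    seed: int = 0,
    base_hazard: float = 0.1,
) -> pd.DataFrame:
    """Exponential survival with hazard scaled by expression tertile.

    Hazard multipliers are 1 / sqrt(HR) / HR for the low / medium / high
    expression tertiles. Censoring times are independent exponentials whose
    rate is chosen so the expected censored fraction at the baseline hazard
    is ``censor_rate``; ``censor_rate=0`` disables censoring.

    Returns a DataFrame with columns time, event, expression, group.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    expression = rng.normal(size=n_patients)
    group = tertile_split(expression)
    mult = np.select([group == "low", group == "medium"], [1.0, np.sqrt(hazard_ratio)],
                     default=hazard_ratio)
    t_event = rng.exponential(1.0 / (base_hazard * mult))
    if censor_rate > 0:
        lam_c = base_hazard * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=n_patients)
    else:
        t_cens = np.full(n_patients, np.inf)
    event = t_event <= t_cens
    return pd.DataFrame({
        "time": np.minimum(t_event, t_cens),
        "event": event.astype(int),
        "expression": expression,
        "group": group,
    }, index=pd.Index([f"PT{i + 1:04d}" for i in range(n_patients)], name="patient"))


def _build_amplicon(n_cpg: int, n_noncpg_c: int, rng: np.random.Generator) -> str:
    """Random amplicon with exactly n_cpg CpG sites and n_noncpg_c other Cs."""
    units = ["TACGAA"] * n_cpg + ["TCAA"] * n_noncpg_c
    rng.shuffle(units)
    return "".join(units)


def generate_bisulfite_clones(
    n_clones: int = 20,
    n_cpg: int = 10,
    methylation_prob: float = 0.5,
    conversion_rate: float = 1.0,
    seed: int = 0,
    n_noncpg_c: int = 60,
) -> tuple[CloneMethylationMatrix, list[SeqRecord], str]:
    """Bisulphite clone calls and converted clone sequences.

    Each CpG call is Bernoulli(methylation_prob). In the clone sequence a
    methylated CpG cytosine survives conversion as C, an unmethylated one
    reads T; each non-CpG cytosine converts to T with probability
    ``conversion_rate`` (failures remain C, lowering the clone's conversion
    QC rate). Returns the call matrix (with per-clone conversion rates),
    clone sequence records, and the unconverted template.
    """
    for name, p in (("methylation_prob", methylation_prob), ("conversion_rate", conversion_rate)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    template = _build_amplicon(n_cpg, n_noncpg_c, rng)
    cpg_pos = [i for i in range(len(template) - 1) if template[i : i + 2] == "CG"]
    noncpg_c_pos = [i for i, b in enumerate(template)
                    if b == "C" and i not in set(cpg_pos)]

    calls = (rng.random((n_clones, len(cpg_pos))) < methylation_prob).astype(np.int8)
    converted = rng.random((n_clones, len(noncpg_c_pos))) < conversion_rate

    records = []
    conv_rates = np.empty(n_clones)
    for c in range(n_clones):
        seq = list(template)
        for j, pos in enumerate(cpg_pos):
            seq[pos] = "C" if calls[c, j] else "T"
        for j, pos in enumerate(noncpg_c_pos):
            seq[pos] = "T" if converted[c, j] else "C"
        conv_rates[c] = converted[c].mean() if noncpg_c_pos else 1.0
        records.append(SeqRecord(Seq("".join(seq)), id=f"clone{c + 1:02d}", description=""))

    matrix = CloneMethylationMatrix(calls=calls, position_offsets=np.array(cpg_pos),
                                    conversion_rates=conv_rates)
    return matrix, records, template
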