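# Methods

## Generative model of the synthetic cohorts

`synthio.generate_mir_cohort` draws, per feature, a baseline log2 intensity
b ~ N(8, 1.5) — the typical scale of a single-colour array — and per
measurement an independent noise term N(0, σ) with σ = 0.5 log2 units by
default. Planted differential miRs add ±`effect_size` to the tumour sample
of every pair; matched samples share a patient id. A small fraction of
features (default 5%) is drawn "unexpressed" with baseline N(2, 1), which
puts roughly 2–4% of raw intensities below the detection floor of 5 and
gives the flooring and flag-filtering steps something real to do. A
configurable subset of tumour samples (default 8, tumour only — which
samples were replicated in a real study is rarely recorded) receives a
technical replicate with the same expected signal and fresh noise.
Detection flags mark raw values at or above the floor. Ordinal pT stage
(1–3, base probabilities 0.3/0.5/0.2) can be coupled to one miR's tumour
expression through a Gaussian-copula latent variable to exercise the
stage-association analysis.

Deliberately not modelled: probe-level chemistry, spatial array artefacts,
dye effects, patient-level random effects shared by the matched samples,
and correlated noise across miRs. Passing tests therefore demonstrate the
statistics are correct under their own assumptions (independent additive
log-normal noise), not that real arrays satisfy those assumptions.

The coupled miR/mRNA generator draws planted target genes jointly with the
miR profile at exact population correlation ρ (gene = ρ·z_miR + √(1−ρ²)·ε);
non-planted genes are independent. The survival generator assigns
expression tertiles internally and scales an exponential hazard by
1/√HR/HR for low/medium/high; censoring times are independent exponentials
whose rate yields the requested censored fraction at the baseline hazard
(0 disables censoring). The bisulphite generator emits both the binary
clone×CpG call matrix and the converted clone sequences; non-CpG cytosines
fail conversion at rate 1−conversion_rate, which is what the QC metric
measures.

## Preprocessing

Order of operations: detection-flag filter → floor at 5 → log2 → cyclic
lowess. The flag rule is deliberately literal — a feature is removed only
when flagged undetected in **every** sample — with the stricter
"keep only features detected in all samples" variant available as
`policy="not-detected-in-all"`; the two readings differ and both are
exposed rather than guessing. The lowess normalization is the "fastlo"
variant: the row-mean reference array A is recomputed each cycle, each
sample's M = sample − A is smoothed against A (span 0.3, statsmodels
lowess, one robustifying iteration) and the fit subtracted, stopping when
the largest adjustment falls below 1e−3 (max 3 cycles). Span/iterations/
tolerance are free parameters of the cited algorithm family and are exposed.

## Noise model and CMSP

σ is the sample SD (n−1) of replicate differences pooled over all miRs; the
intensity-independence of the noise justifies pooling. A tumour −
peritumour value is also a difference of two measurements, so σ applies to
it directly — no √2 rescaling. CMSP converts each pair's z to a two-sided
normal p (sidedness is not dictated by the matched design; the effect
direction is recorded separately from the p-value) and Fisher-combines
across patients. p-values are clipped at 1e−300 before logs.

## Combined testing and the two-sample rule

The paired t, the pooled two-sample t and CMSP are Fisher-combined per miR.
For a fully matched cohort the two-sample test is omitted from both the
output and the combination: it adds no information beyond the paired test
there, and because the two t statistics share their numerator they are
almost perfectly correlated, which would make the Fisher combination
anti-conservative. The paired-t and CMSP p-values are nearly independent
under the null — one measures the mean direction of the matched
differences, the other their magnitudes — so their combination is well
calibrated, which is what the calibration suite verifies (the calibration
cohort sets the unexpressed-feature fraction to zero, because floor-censored
values violate the normal noise model by construction, and skips lowess,
which the clean generator gives nothing to correct). When unmatched samples
are present the two-sample test enters the combination as published; its
correlation with the paired test then makes the combined p anti-conservative,
which is a property of the method, not of this implementation — selection
in that regime leans on the FDR level and the per-test thresholds.

Selection requires (a) the combined p to pass the FDR procedure at the
chosen level and (b) every constituent p ≤ the per-test threshold (default
0.05) — Fisher's statistic is dominated by its smallest input, and rule (b)
vetoes miRs carried by a single test. BH is the default FDR procedure; the
`fdr_procedure` argument accepts any (p-values, level) → mask callable, as
published FDR variants differ in detail. Subtype-specific levels are
configuration, not constants.

## SPIN (side-to-side)

Energy E(P) = Σᵢⱼ wᵢwⱼ D[P(i),P(j)] with wᵢ = n+1−2i. The update sorts
points by the score vector D[:,P]·w ascending; ties keep their previous
relative position (stable sort), so a single pass is fully deterministic.
Because single passes can stall in shallow local minima (observed on ~12%
of scrambled 1-D Robinson instances at n ≤ 7), `spin_order` runs five
passes — the first from the identity, the rest from permutations drawn from
the seed — and returns the lowest-energy ordering; with these restarts the
brute-force optimum was attained on every Robinson instance tested. The
reported energy trace is the winning pass's best-so-far sequence and is
non-increasing by construction. Distances default to Euclidean on
centred/unit-variance rows, matching how heat-map rows are displayed; the
metric is configurable since seriation quality depends on it.
Neighbourhood-SPIN (simulated-annealing schedule) is out of scope.

## Target filter and enrichment

Pearson r per candidate with the exact t-transform two-sided p, BH over the
candidate list only, selection = (r < 0) ∧ (q ≤ 0.10). Two-sided p with a
sign restriction was chosen over one-sided p for symmetry with the CMSP
sidedness decision; at a fixed FDR level the one-sided variant is the same
test at twice the level. Candidates missing from the expression matrix or
with constant profiles are reported, not silently dropped. Enrichment is
the upper-tail hypergeometric probability of the observed overlap with BH
across gene sets — a transparent stand-in for interactive web enrichment
tools, whose rankings it reproduces in ordering though not in their exact
reported FDR numbers.

## Survival and clinical association

Tertiles are assigned by expression rank; when n is not divisible by 3 the
extra members go to the lower groups first (a fixed, documented convention —
any deterministic remainder rule works). Ties are broken by stable input
order. The log-rank test is the unweighted variant on 1 df, two-sided, and
the medium tertile is excluded from the comparison. Kaplan–Meier estimation
and the log-rank statistic are delegated to lifelines; the tests check them
against hand-computed risk tables. Volume V = length·width²/2; if width >
length the values are swapped with a warning rather than rejected, since
caliper annotations are frequently transposed.

## Methylation utilities

Conversion QC is strict: a clone passes only if its non-CpG conversion rate
exceeds 0.99 (a rate of exactly 0.99 fails). The tumour-vs-peritumour
comparison uses the difference of group means of per-clone methylation
fractions with a clone-label permutation p-value — exact enumeration when
the number of label assignments is within budget, otherwise seeded
Monte-Carlo including the identity permutation; the choice of test behind
published clone comparisons is typically unstated, and a permutation test
makes the fewest assumptions at these clone counts (a Mann–Whitney on
per-clone fractions gives similar answers). MeDIP percent-of-input uses the
standard dilution-adjusted 2^ΔCt law. The CpG-island finder scans 200-bp
windows at step 1 against the Gardiner–Garden criteria and merges
overlapping qualifying windows, trimming merged spans until the whole
island satisfies the criteria; with AT-rich flanks a window overlapping the
island by half still qualifies, so island starts are localized to within
one window length of a planted boundary.

## Problem sizes and numerical choices

The validation suites use: 5,000 null miRs × 20 matched pairs with 8
replicate pairs (calibration); 20 cohorts of 1,000 miRs with 50 planted
(recovery); 100 coupled cohorts of 120 genes × 100 samples (target filter);
500 null and 100 alternative survival cohorts (log-rank size/power); 1-D
Robinson matrices at n ≤ 7 for exhaustive SPIN checks — sizes at which the
Monte-Carlo error of each summary is well below the margin of the property
being checked, while the whole suite runs in well under a minute apiece.
Degenerate inputs raise rather than return NaN: zero replicate differences,
zero-variance t-test inputs, all-identical expression in a tertile split,
all clones failing QC. Vectorized pipeline paths set the paired p to 1 for
zero-variance features (which the detection-flag filter normally removes
first) instead of raising, so one degenerate feature cannot abort a
5,000-feature run.
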