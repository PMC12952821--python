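# Methods

## Problem and data model

The package analyses the fate of aroma-active volatiles in cigar tobacco
across three matrices of the same material: the unburned leaf sampled by
stir-bar sorptive extraction (LEAF/SBSE), the 350 °C pyrolysate (PYROLYSIS),
and mainstream-smoke particulate (SMOKE). Inputs are compound-level tables
(name, retention time/index, odor threshold, relative content, OAV, VIP,
descriptors) and, where available, per-sample abundance matrices over a
shared sample panel. Chromatogram-level processing (peak picking, spectral
library search) is out of scope; the analysis starts from identified
compounds.

Three cell states are distinguished throughout: a measured number, the `ND`
sentinel ("not detected", or "no published odor threshold"), and a blank
(field absent). `ND` behaves as 0 in averages and ratio denominators, but an
`ND` odor threshold forces OAV = 0 rather than a division by zero — the
convention of the reference tables. One caveat inherited from those tables:
a handful of printed rows carry a nonzero OAV together with an ND threshold
(their concentrations are unpublished), so OAV/threshold consistency is only
enforced when a concentration is actually present; the ND→0 rule is enforced
on the computation path (`compute_oav`).

Compound identity across stages is by canonical name: lowercase, collapsed
whitespace, normalized prime/apostrophe characters, then a synonym table.
The shipped synonyms unify Phytol with
3,7,11,15-tetramethyl-2-hexadecen-1-ol and "nicotine" with its systematic
pyridine name. Name matching is authoritative; a retention-index
disagreement beyond `ri_tolerance` (default 30 units, a typical
inter-column spread) flags the pair but does not break the match, because
many rows carry no RI.

## Retention indices and OAV

The linear temperature-programmed retention index interpolates between the
bracketing n-alkanes (C7–C30): RI = 100·[n + (rt − rt_n)/(rt_{n+1} − rt_n)].
No extrapolation is performed outside the ladder span — the source protocol
states none — so out-of-range retention times raise an error. The published
"error less than 50 %" identification rule is not implementable as written;
instead an explicit RI tolerance is exposed and the package makes no claim
of reproducing the original identification step.

## Key-compound screening

The multi-indicator screen keeps a record when it satisfies (inclusively)
relative content ≥ 10 %, OAV ≥ 1, or VIP ≥ 1 — one criterion in `ANY` mode
(default, matching the published "satisfy one or more" phrasing), all three
in `ALL` mode. Records lacking an optional field fail only that criterion.
The reference tables deliberately contain rows below any single threshold
(e.g. nonanal: relative content 0.057 %, VIP 0.14, but OAV ≈ 605), which is
why absence must not be an error.

VIP scores come from a PLS-DA fit (scikit-learn's deterministic NIPALS
implementation, autoscaled X, one-hot class response, 2 components by
default) with the standard formula
VIP_j = sqrt(p · Σ_a w_ja² SSY_a / Σ_a SSY_a), SSY_a = |t_a|²|q_a|². Since
the weight vectors are unit-norm, Σ_j VIP_j² = p exactly, which the tests
assert to 1e-6. Zero-variance columns are rejected by name; requesting more
components than the centered matrix's rank raises rather than silently
deflating into noise.

## Transfer indices and fate labels

For per-stage averages L, P, S the indices are DTE = RIR(Smk/SBSE) = S/L,
RIR(Smk/PY) = S/P, TGF = P/L, PCI = P/S. TGF is defined as P/L as the only
reading consistent with the phenol reference row (1.1812/0.1435 ≈ 8.2
matching its "TGF > 8" annotation). DTE and RIR(Smk/SBSE) are numerically
identical; both columns are kept for schema fidelity with the reference
table. A zero denominator makes the ratio UNDEFINED (serialized `—`); a
zero numerator over a positive denominator is a defined 0. PCI·RIR(Smk/PY)
= 1 whenever both are defined.

The qualitative decision rules ("≈1", "≫1", "≪1") are quantified as
configurable bands: `near_one_band` = [0.5, 2], `high_ratio` = 5,
`low_ratio` = 0.5. The tree runs in fixed order: leaf-absent cases first
(fully thermally generated, with a partial-transfer variant when the
compound also reaches smoke; smoke-only otherwise), then TGF ≥ 5 (with or
without efficient release), then DTE bands. With these defaults all 15
reference rows land on the fate their free-text Notes describe (the shipped
notes→label mapping records this; the contract requires ≥ 13/15 because
three notes contradict their own row data — "thermal generation" claimed
for rows with zero pyrolysate signal). One addition to the tree: a compound
absent from all three stages returns `NOT_DETECTED` instead of falling
through to the moderate-transfer default, which would be plainly wrong for
an all-zero row.

Estimation from per-sample matrices uses the ratio of per-stage means (ND
as 0), not the mean of per-sample ratios, matching how the reference
averages are used; the ratio-of-means estimator is also robust to
individual near-zero denominators.

## Correlation networks

Edges connect (stage, compound) nodes with |r| > 0.8 and p < 0.01 — both
strict inequalities, as printed. p-values are two-sided from
t = r·sqrt((n−2)/(1−r²)) on n − 2 df (scipy's `pearsonr`). No
multiple-testing correction is applied by default, for fidelity to the
published filter; a Benjamini–Hochberg option exists. ND abundances enter
as 0; constant columns are skipped with a warning since their correlation
is undefined. Default pairing is inter-stage only (the cross-stage
associations are the scientific object); all-pairs is available. Tests
check the edge set against an independent brute-force oracle (covariance
formula + t tail) on every instance up to 30 compounds.

## GC-O panel consensus

Events carry onset/disappearance retention times, a free-text descriptor
and Imax on a 0–5 scale. Clustering is single-linkage on event rt centers
with link distance `rt_window` (default 0.2 min, a typical peak width);
in one dimension this is exactly "sort and cut at gaps > window". A
cluster becomes an aroma-active region when ≥ `min_detectors` (default 3,
a majority of the five-person panel) *distinct* sniffers contributed; a
sniffer detecting in either replicate counts once, with their replicates'
Imax first averaged, and the region intensity is the mean of those
per-sniffer values. Descriptor agreement affects only the region label
(modal normalized descriptor, lexicographic tie-break), never retention —
the published criterion is ambiguous on this point and the conservative
reading (majority detection is the filter) was chosen.

## Sensory profiles

Descriptor cells are tokenized (parentheticals stripped, split on commas
and slashes, lowercased, filler words trimmed) and routed through a
token→category lexicon over 15 aroma categories; unknown tokens go to
`other`. A stage profile gives each record's weight to categories in
proportion to its token counts, so total profile mass equals total weight
(an asserted conservation law). Because the aggregation behind the
published stage profiles is unstated, three weightings are offered —
COUNT, RELATIVE_CONTENT (default) and OAV (capped at 100 by default so a
single extreme low-threshold compound, e.g. a printed OAV above 13 000,
cannot saturate the profile) — and no exact figure reproduction is
claimed. On the packaged pyrolysate table the descriptor blocks are shared
by several compounds each; under OAV weighting the sweet+caramel mass
dominates fruity+citrus by >4×, the caramelized-sweet character expected
of heated tobacco, while under plain relative-content weighting the two
groups are within ~15 % of each other — a good illustration of why the
weighting choice must be explicit.

## Synthetic data generator

The generator emulates a three-stage study on a shared sample panel with
four compound classes: TRANSFERRED (true DTE drawn uniformly in
[0.8, 1.6], inside the equal-transfer band), LOST (DTE in [0.05, 0.3]),
THERMOGENIC (no leaf signal; pyrolysate level is its own base, smoke
carry-over factor in [0.3, 3]) and SMOKE_ONLY. True TGF for leaf-borne
classes is drawn in [0.02, 0.3]; all draws sit away from the fate-band
boundaries so label recovery is well-defined. Base abundances are
10^U(−1, 1.5), spanning the orders of magnitude seen in real tables.
Noise is i.i.d. lognormal per cell with mean 1 and coefficient of
variation `noise_cv`; values below the detection floor (1e-4) or hit by
`nd_fraction` masking become ND. Defaults: 14 samples (the study's leaf
panel size), 12/6/6/3 compounds per class, cv = 0.1, no random masking.

What the generator does *not* emulate: compositional closure of relative
contents, correlated noise between compounds (except via the explicit
Gaussian-copula `inject_correlation_structure`, used to plant known
network edges), batch effects, and censoring that depends on abundance
rank. Recovery tests passing on this model therefore demonstrate the
estimators' correctness under multiplicative noise, not robustness to
every artifact of real GC-O-MS data.

Statistical test conditions (fixed seeds throughout): DTE recovery within
10 % relative error for ≥ 90 % of transferred compounds at cv = 0.2,
n = 50 (40 transferred compounds for a stable proportion); fate-label
recovery ≥ 95 % at cv = 0.1, n = 14; estimator bias shrinking to zero as
cv → 0 over {0, 0.05, 0.2}; planted r = 0.95 edges recovered at n = 50
and null pairs absent.

## Pipeline and reproducibility

`run_pipeline` executes screen → match → transfer → network (when
per-sample matrices are provided) → sensory, writing each stage's CSV plus
a sorted-key `summary.json`; identical inputs and seed give byte-identical
bundles. Paths left unset fall back to the packaged reference tables, so a
bare `aromatrace run` reproduces the 13/27/20 key-compound counts, the
three-compound triple intersection and the 15-row transfer table.
`scripts/acceptance.py` recomputes the reference DTE/RIR/PCI values from
the packaged stage averages alone; it is deterministic end to end.
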