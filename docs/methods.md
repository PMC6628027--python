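# Methods

## Measurement model

All copy-number inference rests on two closed forms. A genomic segment
with `cT` total copies in a sample of tumour purity ρ ∈ (0, 1] and tumour
ploidy ψ (length-weighted mean total copies) has expected log2
tumour/reference intensity ratio

    log2R(cT) = log2( (ρ·cT + 2(1−ρ)) / (ρ·ψ + 2(1−ρ)) ),

which is 0 at `cT = ψ`, strictly increasing in `cT`, and floored at −8
for `cT = 0` at full purity. A heterozygous germline site on a segment
with major/minor allele counts `(nA, nB)` has expected B-allele fraction
`(ρ·n + (1−ρ)) / (ρ·cT + 2(1−ρ))` with `n` the copies of the carrying
haplotype; phase is unknown, so bands are mirrored to `[0.5, 1]`. The
mirrored band equals 0.5 exactly when `nA = nB` — parity of the
underlying state is readable from band position, which is the core of
the ploidy argument: a lowest-level segment with a 0.5 band in a
doubled genome is `(1,1)`, not a one-copy loss.

Assumptions: a single dominant clone per segment per sample (subclonal
mixtures are flagged, not deconvolved), no GC/wave background in the
log2 signal, and germline heterozygous sites dense enough (≥ 10 per
segment by default) to estimate a band.

## Segmentation

Recursive binary segmentation of probe-level log2 ratios per chromosome:
each candidate breakpoint is the least-squares optimum of the current
piece, accepted when ΔSS / σ̂² > penalty · log(n), with σ̂ a robust noise
scale from median absolute successive differences and `penalty = 5`. The
variance normalisation keeps the penalty meaningful at any noise level
and makes noise-free changepoints exact (σ̂ is floored at 1e−6 in s.d.).
Segments shorter than `min_probes = 10` are never created. Boundaries
are placed at inter-probe midpoints; per chromosome the segments
partition the probe span. Increasing the penalty prunes the same
recursion tree, so segment counts are monotone in the penalty.

## BAF band estimation

Averaging mirrored BAFs is biased upward at finite depth (the binomial
spread folds into the mirror), so the band deviation `d` is estimated by
variance decomposition on the unmirrored values: a clonal state yields a
symmetric two-point mixture at `0.5 ± d` blurred by binomial noise, and

    d̂ = sqrt( max(0, var(baf) − mean(b(1−b)/depth)) ),  band = 0.5 + d̂.

Parity is "even" (balanced) when `d̂ < 0.05`, "odd" otherwise, and
"indeterminate" below 10 sites; a band ≥ 0.75 raises an advisory LOH
flag. The 0.05 threshold sits several estimator standard errors above
the null for arm-scale segments while staying below the smallest
imbalance the default cohort produces (`(3,2)` at purity 0.7, d ≈ 0.085).

## Purity/ploidy grid search and its degeneracies

The fit scores every grid point (ρ step 0.01 on [0.10, 1.00]; ψ step
0.05 on [1.5, 5.0]) by the sum over autosomal segments of the best
integer-state residual, states capped at `max_cn = 8`:

    min over (nA,nB):  min((log2 obs − log2R)², cap) + w·(band − b(nA,nB))²

with `w = 4` and `cap = 0.1`. Parity is a hard constraint where
determinate (even ⇒ `nA = nB`, odd ⇒ `nA ≠ nB`). Three degeneracies are
handled explicitly; they are intrinsic to the problem, not artefacts:

- **Subclonal pull.** Mixture segments sit at half-integer levels, which
  become integers under the genome-doubled reading and would otherwise
  vote for it; capping the log2 residual bounds that vote. The BAF
  residual is never capped — band centres are robust averages over many
  sites, and the LOH band is precisely what identifies purity, so
  degenerate low-purity solutions (which compress all bands toward 0.5)
  stay expensive.
- **Shifted ladder.** At low purity the level ladder can be reproduced
  with every state shifted down, assigning large homozygous deletions.
  Solutions placing > 1% of genome length at `cT = 0` are inadmissible.
- **Doubled twin.** A diploid genome and its doubling (states ×2, purity
  remapped ρ → ρ/(2−ρ)) produce identical log2 and BAF data. After the
  global optimum is found, the halved twin at (2ρ/(1+ρ), ψ/2) is
  evaluated in a local neighbourhood and adopted, repeatedly while
  possible, unless its score is worse by more than 0.5. Halving a
  genuine post-WGD genome misfits every odd-copy chromosome (score
  penalty ≈ number of odd segments × cap, ≈ 0.9 in the default cohort)
  and is rejected; the doubled reading of a diploid genome halves at
  ≈ 0.2 cost (its subclonal segments only). A doubling with *no*
  odd-copy segment is mathematically indistinguishable from diploid and
  is reported as diploid — odd-copy segments (e.g. chromosomes at three
  copies) are exactly the evidence for tetraploidy, as in the original
  analysis.

The reported ψ̂ is the length-weighted mean assigned total copy number;
segments whose observed level sits further than 0.1 from every modelled
level are left unassigned and flagged "intermediate" (subclonal
heterogeneity). Ploidy classes: mean assigned `cT` < 2.7 near-diploid,
\> 3.3 near-tetraploid, otherwise "other"; classification requires ≥ 80%
of autosomal length assigned. The X chromosome is segmented and assigned
but excluded from fitting and classification.

## Phylogeny

Total-copy profiles are binned on a fixed 1 Mb grid (decoupling the tree
from breakpoint jitter); bins under unassigned segments are masked per
sample. The distance is the mean absolute copy difference over mutually
unmasked bins (L1-derived, metric). Trees are neighbour joining
(scikit-bio) rooted on an all-two-copy pseudo-sample standing for the
germline; negative NJ branch lengths are clamped to zero with a warning.
On additive matrices NJ provably recovers the generating topology; the
test suite verifies this against an exhaustive least-squares topology
search up to six taxa and by Robinson–Foulds identity up to eight.

## Mutation clonality

Presence per mutation and sample requires ≥ 3 alternate reads and a
one-sided binomial p < 0.01 against a 1% sequencing error rate; depth
< 20 is "insufficient" (flagged, never dropped). The cancer cell
fraction is `f̂ = vaf·(ρ·cT + 2(1−ρ))/(ρ·m)`; multiplicity m̂ is chosen in
`{1..nA}` to bring f̂ closest to 1 (clonality as the parsimonious
default), and f̂ ≥ 0.5 labels the mutation major-clone. The exact
major/minor rule of the study this emulates is not published in its main
text; this rule is a stand-in and all cutoffs are exposed in
`ClonalityThresholds`. When no local copy state is available the
classifier falls back to (cT = 2, nA = 1) and marks the fallback.
Sharing categories (trunk; present only in primaries; present only in
metastases; other) count minor-clone presence as presence by default
(configurable); percentages are reported both to one decimal and
integer-rounded half-up, matching the mixed precision conventions of
published counts. Samples whose entire column is insufficient are
excluded from categorisation; sporadic insufficient entries neither
count as present nor veto trunk status.

## Expression

Analyses run on log2(x+1) of a supplied non-negative abundance matrix
(normalisation is assumed done upstream). Sample structure uses the 500
most-variable genes, Euclidean distance and average linkage.
Differential expression compares primary versus metastasis samples —
the thrombus is excluded as unclassifiable — with Welch t-tests on log2
values (variance floored at 1e−8 for degenerate genes) and a linear
fold change computed from back-transformed group means with pseudo-count
1; reported genes satisfy |FC| > 3 and p < 0.01 with no multiple-testing
correction by default (a Benjamini–Hochberg flag exists but is off,
matching the raw-p convention of the emulated analysis).

## The synthetic cohort

The generator plants a clone tree emulating the index patient: truncal
loss of one chr3 homolog (LOH), 5q gain and focal 2q/10q losses; a
near-diploid branch whose Pr1 and Pr3 samples are 50/50 mixtures with
subclones carrying a chr2 gain and 1p+chr4 losses respectively; and a
WGD branch feeding Pr4/VT/M1–M4, followed by losses returning 1p, chr9
and chr13 to two balanced copies, single-copy losses of chr8/14/15 (odd
parity — the tetraploidy evidence) and gains of chr7, 12p and 20q, with
an extra 11q loss private to M4. VT and M3 are planted identical; Pr4
and M2 share a private event. Planted tumour ploidies are ≈ 1.9–2.0 and
≈ 3.6.

Measurements: per-probe log2 is the expectation of the fraction-weighted
copy number plus Gaussian noise (σ = 0.15 default; probes every 100 kb,
≈ 30,000 genome-wide on an hg19-like 23-chromosome frame); het sites
every 500 kb draw alternate reads binomially at Poisson(60×) depth —
60× matches exome-like coverage; somatic alt counts are binomial at the
VAF implied by planted CCF, multiplicity (2 for pre-WGD mutations on
retained alleles) and local copy number. Purities default to 0.6–0.9
per sample (the real values are unpublished; configurable).

The mutation catalogue fixes the published structure: 146 mutations, 18
truncal, 51 confined to primaries (Pr1 18, Pr3 10 private; Pr2/Pr4
private counts drawn uniform 3–6), 20 metastasis-only (per-metastasis
private counts uniform 3–6, rejection-resampled so the total closes),
a VT-private handful, two VT+all-metastases mutations, three
Pr4+VT+all-metastases mutations and the remainder on the metastatic
lineage branch. A fraction of shared mutations receives additional
CCF-0.3 (minor-clone) presences. Mutations are placed outside the
subclonal regions so every sample has a clonal local copy state.

Expression plants two gene sets among 5,000 genes: 57 primary-versus-
metastasis genes (32 up, 25 down; linear fold change uniform in
[3.5, 10]; VT receives metastasis-like levels but is excluded from
testing) and 150 lineage genes separating the near-diploid from the
post-WGD lineage (|Δlog2| uniform in [2.5, 4.5]) which drive the
clustering split; within-group σ is 0.4 on the log2 scale. The lineage
set inflates the within-primary-group variance under the 4-vs-4 DE
contrast (Pr4 is lineage-wise metastasis-like), giving Welch t ≈ 3 at
≈ 3 degrees of freedom — rarely under p = 0.01 — so it contaminates the
DE list only marginally; this sizing was chosen from that power
analysis.

What the generator does not emulate: FFPE artefacts, GC waves,
replication timing, mapping bias at het sites, clustered mutation
positions, patient-to-patient variation of event sets, treatment
effects beyond M4's extra loss, and read-level data. Passing tests
therefore demonstrate correctness of the inference machinery under its
own measurement model, not robustness to every artefact of real arrays
and exomes.

## Problem sizes and determinism

The validation suite and the reproduction script use twenty simulated
cohorts per condition (≈ 180 sample fits), ≈ 30,000 probes and ≈ 6,000
het sites per sample, and 5,000-gene expression matrices — sizes chosen
so the complete analysis of one cohort takes about two seconds. All
randomness flows from a single seed through named substreams (one per
sample and signal type), so identical seeds reproduce identical cohorts
byte for byte.

## Known limitations

- Purity below ≈ 0.3 with few CNAs leaves the grid fit weakly
  identified; the default cohort does not exercise that regime.
- Subclonal fractions are flagged (intermediate states) but not
  estimated; no multi-clone deconvolution.
- The NJ tree has no bootstrap support; with nine samples and strong
  signal the split structure is stable across seeds instead.
- Band parity for high even states with strong imbalance (e.g. (3,1))
  reads as "odd"; the hard constraint is effectively
  balanced-versus-imbalanced, which is what the data support.
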