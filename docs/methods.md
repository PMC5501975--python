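# Methods

## Overview

`mirmeta` re-implements, as an open and testable pipeline, the
computational workflow used to nominate mRNA targets of an oncogenic
miRNA from multiple patient expression cohorts, to quantify drug
synergy by the Chou–Talalay median-effect / combination-index
formalism, and to scan promoter sequences for transcription-factor
binding motifs. Because studies of this kind often do not deposit the
underlying cohort or viability data, the package ships a synthetic-data
generator with known ground truth; every claim the pipeline makes is
validated against that truth or against independent brute-force
oracles, not against any published table.

## Target prioritization

### Consensus prediction

Published target lists typically intersect several web predictors
(e.g. "predicted by at least five of six programs"). Those external
services cannot be reproduced or version-pinned, so the package
replaces them with six *seed-stringency modes* of its own scanner,
preserving the vote arithmetic: (1) 8mer; (2) 8mer/7mer-m8; (3) plus
7mer-A1; (4) plus 6mer; (5) offset-6mer (miRNA positions 3–8 — an 8mer
or 7mer-m8 contains one as a substring, a plain 6mer does not); (6)
6mer allowing one G:U wobble. A gene's vote is the number of modes
detecting ≥1 site. The default vote threshold is 5 of 6, but it is
configurable because published lists sometimes retain genes with fewer
votes. Only the seed region (miRNA positions 1–8) is modeled: no
3′-supplementary pairing, no context scores, no conservation, no ΔG.
Site coordinates are 1-based inclusive on the UTR read 5′→3′, the
convention used when designing site mutagenesis.

The site taxonomy is the canonical one (8mer, 7mer-m8, 7mer-A1, 6mer,
offset-6mer, 6mer-A1), with 6mer-A1 defined as the A1 anchor plus
pairing to miRNA positions 2–6 (length 6). The trailing A of A1-type
sites is matched as a literal adenine, never as a complement.

### Per-cohort statistics

For each gene in each cohort:

* **Tumor-vs-normal test** — a two-sided permutation test on the
  difference of group means of log2 expression. When the number of
  distinct label assignments C(n, n_tumor) is ≤ `exhaustive_limit`
  (default 20,000) the permutation distribution is enumerated exactly
  and the p-value is the exact tail fraction. Otherwise B seeded
  Monte-Carlo reassignments are drawn (default B = 10,000) and the
  add-one estimate p = (b+1)/(B+1) is reported, which is strictly
  positive — important because a downstream Fisher combination cannot
  absorb p = 0. Ties in |statistic| are counted with a 1e-12 absolute
  tolerance. Constant data yields p = 1 by convention. The difference
  of means was chosen as the statistic because it is standard, exact
  under enumeration, and directly interpretable as the log2 fold
  change.
* **FDR** — Benjamini–Hochberg step-up across the requested gene set
  (delegated to `statsmodels`; unit tests compare it against a literal
  implementation of the step-up definition).
* **log2 fold** — mean(tumor) − mean(normal) of log2 expression.
* **miRNA–mRNA correlation** — Pearson r over *matched* samples (those
  carrying both assays), two-sided p from t = r·√(n−2)/√(1−r²) on n−2
  df. With fewer than `min_matched` (default 5) pairs both fields are
  absent rather than unreliable. |r| = 1 reports the global p-value
  floor (1e-300), never 0.

In each Monte-Carlo cohort run every gene draws its permutations from
an independent child of a single `SeedSequence`, so null p-values are
independent across genes (a requirement of the Kolmogorov–Smirnov
calibration check) while the whole run stays reproducible from one
root seed.

### Evidence combination and ranking

Per-cohort correlation p-values are made one-sided in the expected
anticorrelation direction (p/2 on the expected sign, 1 − p/2
otherwise, 0.5 at a zero effect) and combined across cohorts with both
Fisher's method (−2·Σ ln p on χ² with 2k df) and Stouffer's method
(Z = Σ z_i/√k). The combined *correlation* p-value is the ranking key —
the deregulation evidence enters as a filter, not as the sort column —
with Fisher primary and Stouffer as tie-break by default (the primary
key is configurable, since either convention appears in the
literature). A supplementary Fisher combination of the T/N p-values is
written alongside. All combined p-values are floored at 1e-300; the
pipeline never prints 0 for a probability.

A gene is ranked only if it (a) reaches the vote threshold, (b) has
FDR ≤ 0.1 with the expected fold-change sign in *every* cohort, and
(c) shows the expected correlation sign in every cohort with
correlation data. Genes failing a filter stay in the report, unranked,
with their flags; genes lacking any correlation-bearing cohort are
flagged explicitly rather than dropped.

## Synthetic cohorts

Expression is generated directly on the log2 scale — the statistics
above operate on continuous expression, so no count model is needed.
Per cohort: miRNA ~ baseline + shift·is_tumor + N(0, σ); planted
targets follow baseline_g + slope·(miRNA − baseline) + N(0, σ);
decoy_down genes get the same *tumor shift* (slope·shift) without
miRNA coupling; decoy_corr genes couple to the miRNA *residual* only
(no net shift); background genes are pure noise. Noise is Gaussian and
homoscedastic. Defaults define the reference study: 3 cohorts × 500
genes, 5 shared planted targets, slope −1, miRNA shift +2 (log2), noise
sd 1, 30 tumor + 30 normal samples, 20 matched, 5% decoys of each
kind.

Matched samples default to a flagged subset of the tumor samples
(`matched_mode="tumor"`), because published matched-sample
correlations are usually computed within tumors; the pooled
tumor+normal mode is provided as well and is the mode in which
near-perfect anticorrelation of a low-noise planted target is
observable (within tumors alone the attainable correlation is bounded
by |slope|/√(slope²+1), e.g. 0.71 at slope −1, regardless of the noise
level — both the generator and the study design share the same σ).

What the generator does *not* emulate: count noise/overdispersion,
normalization and batch artefacts, correlated gene modules, indirect
(transcription-factor-mediated) miRNA effects, and non-Gaussian tails.
Passing the planted-target recovery tests therefore demonstrates that
the pipeline's statistics and plumbing are correct under its stated
model, not that the model captures every property of real tumor
cohorts.

UTR simulation plants exact site sequences at recorded coordinates in
i.i.d. background of a requested GC fraction, rejection-sampling until
no *unplanned* site of equal-or-higher stringency than the loosest
planted type survives outside the planted intervals. Empty-plan UTRs
are left untouched, so their spontaneous site rate is exactly the
i.i.d. rate — a unit test checks the observed 8mer rate against an
exact KMP-automaton Markov-chain computation.

## Drug synergy

The median-effect model fa/fu = (D/Dm)^m is fitted by unweighted
ordinary least squares on the linearized form log10(fa/(1−fa)) =
m·log10 D − m·log10 Dm, the classical procedure of the CompuSyn
program. CC50 ≡ Dm of the cytotoxicity fit. Points at fa ∈ {0, 1} have
no logit and are excluded with a warning; at least two interior points
are required. The reported "±" on Dm is a standard error propagated
from the linear fit by the delta method (including the slope–intercept
covariance) and is labelled as a fit SE — viability-assay tables often
leave the meaning of their "±" unstated, so ours is defined.

The combination index uses the mutually-exclusive (Loewe) form
CI = d1/Dx1(fa) + d2/Dx2(fa) with Dx(fa) = Dm·(fa/(1−fa))^(1/m);
CI < 1 synergy, 1 additivity, > 1 antagonism. The non-exclusive form
(adding d1·d2/(Dx1·Dx2)) is available behind a flag but is not the
default, matching standard Chou–Talalay reporting. CI is invariant
under per-drug rescaling of dose units, and the additive generator +
estimator pair recovers CI = 1 exactly without noise.

## Promoter motif scanning

A log-odds PWM scanner over both strands of the region upstream of the
translational start. Hits are reported in ATG-relative coordinates
(−1 = base immediately 5′ of the A of ATG, closed intervals, most
upstream first), the notation used for promoter binding sites such as
"−4530/−4515". The threshold is either absolute log2-odds or a
fraction of the maximum attainable score (default 0.8·max). Windows
containing N are skipped. The default matrix expands an E2F-like
consensus TTTSSCGC into probabilities 0.95 (split across degenerate
bases) vs 0.05; JASPAR-format matrices are read via Biopython with a
0.5 pseudocount. The scanner makes no claim to reproduce any
published site coordinates, which depend on the exact genomic sequence
and prediction tool used.

## Numerical choices and degenerate inputs

* p-value floor 1e-300 everywhere; combined p of 0 is treated as
  underflow, never emitted.
* Permutation tie tolerance 1e-12 (absolute, on the mean difference).
* One root seed per run; stage/gene seeds are `SeedSequence` children
  spawned in a fixed order, so reruns are byte-identical.
* Constant expression → p = 1; zero-variance correlation input →
  explicit error; all-equal doses → degenerate-design error; flat
  dose-response (m = 0) → explicit error.
* Every output file carries a `# config_hash=… seed=…` stamp.

## Problem sizes in the shipped validation

The test suite and the acceptance script run the reference study at
Monte-Carlo resolution B = 499–999 for the 50-seed AUROC benchmark
(ranking is driven by the closed-form correlation p-values; the
permutation p enters only through the FDR ≤ 0.1 filter, where 1/500
resolution is ample), B = 9,999 for the single demonstration run, and
2,000 genes × B = 1,999 for the null-calibration experiment. These
sizes were chosen as the smallest at which the Monte-Carlo error of
each check is negligible relative to its acceptance band.

## Known limitations

* The six consensus modes emulate the *arithmetic* of a multi-program
  vote, not the heterogeneous biology of six real predictors; absolute
  vote counts are not comparable to published ones.
* The permutation test assumes exchangeability under the null;
  heteroscedastic cohorts would need a studentized statistic.
* Fisher/Stouffer combination assumes independent cohorts.
* The median-effect fit is unweighted least squares on the logit scale;
  points near fa = 0 or 1 carry inflated leverage under additive
  measurement error (CompuSyn shares this property).
* No normalization or batch correction: cohorts are assumed to arrive
  as processed, comparable log2 expression.
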