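# mirmeta

Multi-cohort miRNA target prioritization, drug-synergy analysis and
promoter motif scanning — with a ground-truth synthetic-data generator
so the whole pipeline is testable without any external download.

## Who this is for

Computational biologists who want an open, reproducible version of the
analysis that typically accompanies an oncomiR study (the motivating
case is miR-21-5p in breast cancer): nominate mRNA targets by
combining seed-site prediction with tumor-vs-normal deregulation and
miRNA–mRNA anticorrelation across several patient cohorts, quantify
whether two drugs (e.g. metformin and everolimus) synergize, and locate
transcription-factor (E2F) binding motifs upstream of a promoter's
translational start.

## What it computes

**Target ranking.** For each gene g and cohort c: a permutation
p-value for the tumor/normal difference of mean log2 expression
(exhaustive enumeration when C(n, n_T) ≤ 20,000, otherwise seeded
Monte Carlo with p = (b+1)/(B+1)), its Benjamini–Hochberg FDR, the
log2 fold change, and Pearson's r between the gene and the query miRNA
over matched samples with p from t = r√(n−2)/√(1−r²). One-sided
correlation p-values (anticorrelation direction) are combined across
cohorts by Fisher's method, X² = −2Σln pᵢ ~ χ²(2k), and Stouffer's
method, Z = Σzᵢ/√k with zᵢ = Φ⁻¹(1−pᵢ). Genes predicted by ≥ 5 of 6
seed-scanner stringency modes ("votes", emulating a multi-program
consensus), downregulated at FDR ≤ 0.1 in every cohort and
anticorrelated in every cohort with matched data are ranked by the
Fisher-combined p (Stouffer as tie-break).

**Synergy.** The median-effect model fa/fu = (D/Dm)^m is fitted by
least squares on log10(fa/(1−fa)) vs log10 D (Dm ≡ CC50); the
combination index at a point (d1, d2, fa) is CI = d1/Dx1(fa) +
d2/Dx2(fa) with Dx = Dm(fa/(1−fa))^(1/m); CI < 1 synergy, = 1
additivity, > 1 antagonism.

**Motifs.** A log-odds PWM scanner (default: E2F-like consensus
TTTSSCGC) over both strands, reporting hits in ATG-relative
coordinates (−1 = base just 5′ of the A of ATG).

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

Simulate the reference three-cohort study (500 genes, 5 planted
targets, miRNA shift +2 log2 in tumors, target slope −1, noise sd 1,
30+30 samples per cohort, 20 matched), scan the simulated UTRs and
rank:

```python
import numpy as np
from mirmeta import CohortSimConfig, simulate_cohorts, simulate_utrs
from mirmeta.cohort_stats import cohort_gene_stats
from mirmeta.meta_rank import prioritize_targets
from mirmeta.seeds import consensus_votes

MIR21 = "UAGCUUAUCAGACUGAUGUUGA"
configs = [CohortSimConfig(name=f"c{i+1}", seed=101 + i) for i in range(3)]
cohorts, truth = simulate_cohorts(configs)
plan = {g: ["8mer"] for g in sorted(truth.planted_target_ids)}
records, _ = simulate_utrs(list(cohorts[0].mrna.index), MIR21, plan, seed=1)
consensus = {r.id: consensus_votes(str(r.seq), MIR21, gene_id=r.id)
             for r in records}
stats = []
for c, child in zip(cohorts, np.random.SeedSequence(1).spawn(3)):
    stats.extend(cohort_gene_stats(c, n_perm=9999, seed=child))
targets, _ = prioritize_targets(stats, consensus)
```

Output (top of the ranked table):

```
rank  gene    votes  fisher_p     stouffer_p   planted
   1  G0378      6  1.467e-09  3.943e-10  True
   2  G0035      6  9.484e-08  6.760e-08  True
   3  G0262      6  3.521e-07  1.376e-07  True
   4  G0409      6  3.199e-06  6.638e-07  True
   5  G0025      6  1.677e-05  4.830e-06  True
```

All five planted targets occupy ranks 1–5: each carries a planted 8mer
site (6/6 votes), is downregulated in tumors in all three cohorts, and
anticorrelates with the miRNA on matched samples, so its Fisher-
combined correlation p-value is orders of magnitude below any
background gene's.

Fitting a noisy dose-response generated from m = 1, Dm = 10 and
checking a Loewe-additive combination:

```
metformin: m=1.005  CC50(Dm)=9.93 +/- 0.16 (fit SE)  r=0.9999
CI at fa grid: 0.94 1.07 0.99 1.02 1.02 1.01 1.06 1.01 1.03
```

The fit recovers the true CC50 within its standard error and the
combination index hovers at 1 (additivity), as constructed.

The same workflow is available from the shell: `mirmeta simulate`,
`mirmeta scan-utrs`, `mirmeta cohort-stats`, `mirmeta rank` (via
`run-all`), `mirmeta synergy`, `mirmeta scan-promoter`, and
`mirmeta run-all <config.yaml>` for the full pipeline.

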