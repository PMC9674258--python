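# Methods

This note documents the statistical models, the simulator, the numerical
choices and the known limitations of `dnvmeta`.

## Model and null hypothesis

The unit of analysis is a (gene, variant class) pair in one analysis group
(ASD, DD, NDD = ASD∪DD, siblings, or probands split by sex). Under the
null, the DNV count in gene *g* and class *c* is Poisson with mean

λ_gc = copies × μ_gc,

where μ_gc is the per-haploid-copy per-generation mutation rate and copies
counts transmitted haploid genomes: 2(n_M + n_F) for autosomes and
n_M + 2 n_F for chromosome X (one X copy per male, two per female). The
same dosage convention is used in the sex-stratified burden test, whose
denominators are chromosome copies rather than samples.

Classes partition nonsynonymous space as LGD (frameshift, stop-gain,
splice-donor, splice-acceptor), missense (MIS), severe missense
(MIS30 = missense with CADD phred strictly greater than 30; a flagged
subset of MIS everywhere counts are reported) and synonymous (SYN).
Multi-consequence annotations resolve to the most severe term.

## The three model flavors and seven tests

* **CH** (divergence-calibrated rates): Poisson upper-tail tests of the
  LGD, MIS and MIS30 counts. Rates come from enumerating all 3L single-base
  substitutions of the CDS with transition/transversion/indel parameters,
  multiplied by a calibration constant C chosen so a genome-wide
  reference-class expectation (synonymous by default) matches a divergence
  target exactly: C = target / Σ_g 2Nμ_g. Calibration is an exact fixed
  point: recalibrating after applying C returns 1.
* **TRI** (trinucleotide-context rates): Poisson upper-tail tests of LGD
  and MIS. Each substitution contributes its (context, alt) rate from a
  64×3 table; one flanking base pads the CDS ends.
* **WPT** (weighted permutation): (i) an all-DNV statistic S = Σ weights of
  observed DNVs, with class-based severity weights
  (LGD 1.0 > MIS30 0.8 > MIS 0.5 > SYN 0.1, user-overridable); the null
  draws per-class Poisson counts and sums their weights; (ii) a missense
  test combining (Fisher's method) the weighted missense enrichment with a
  positional-clustering statistic — the mean pairwise CDS distance of the
  observed missense positions against resampled positions drawn in
  proportion to per-site missense rates (uniform when site rates are
  absent). Monte-Carlo p-values use the (r+1)/(n+1) estimator, so they are
  valid and never zero. The published severity-weight estimation from
  positive predictive values is deliberately not reproduced; the class
  weights are a transparent stand-in with the same monotone structure.

This yields seven tests: CH×{LGD, MIS, MIS30}, TRI×{LGD, MIS},
WPT×{allDNV, missense+clustering}.

In both rate flavors the frameshift contribution to μ_LGD is an indel term:
a multiplier times the nonsense SNV rate (default 1.3) for context rates,
or a per-site indel rate times CDS length for the CH flavor. μ_MIS30
defaults to a fixed fraction of μ_MIS (0.18, about the genome-wide share of
severe missense DNVs) because per-site severity scoring is out of scope.
Splice-site contributions are folded into the indel multiplier unless exon
structures are supplied.

## Multiple testing and tiers

Per model, each test's p-values receive a Benjamini–Hochberg step-up
correction with denominator m equal to the model's gene universe (which may
exceed the genes actually carrying DNVs; untested genes have p = 1). A
gene's model-level significance is the minimum across that model's tests —
by default the minimum of per-test q-values (`combine="min_q"`); taking the
minimum p first and running BH once is available behind
`combine="min_p_then_fdr"`, since either reading is defensible and they
rarely disagree in practice. Exome-wide significance uses Bonferroni:
α/(n_genes × n_tests), 3.64e−7 at the reference design (19,618 × 7).

Tiers: LC = FDR 5% in at least one model; MC = FDR 5% in all models;
HC = exome-wide p in all models — each additionally requiring a qualifying
DNV count (LGD + MIS in the analysed group) strictly greater than two.
Genes FDR-significant in the sibling analysis (run with CH and TRI only;
the weighted model is skipped for the small sibling sample) are removed
from all tiers and flagged. HC ⊆ MC ⊆ LC by construction.

## Burden comparisons

All 2×2 comparisons use Fisher's exact test. Odds ratios are cross-product
(sample) estimates; confidence intervals are exact conditional intervals,
so tables with an empty exposure cell report an infinite OR with a finite
one-sided bound. The DD-versus-ASD screen uses sample-count denominators
[count, n − count] (this reproduces the reference odds ratios; a
copies-based alternative differs only in the third decimal at these sample
sizes). Class bias compares a gene's (LGD, MIS) counts against all other
genes pooled. FDR in the genome-wide screens uses a fixed m = 20,000. The
case–control carrier burden is one-sided (greater in cases), with carrier
counts taken as given — platform and read-depth harmonization of
case–control inputs is out of scope.

## Expression statistics

Brain-expression tiers apply half-open TPM cutoffs, lower bound inclusive:
high ≥ 1,000 > medium ≥ 10 > low ≥ 0.5 > none, on the arithmetic mean of 13
brain-tissue TPM values. Intolerance-score comparisons use the two-sided
Wilcoxon rank-sum test (exact for small untied samples). Trimmed means
drop the lowest and highest 25% (floor of trim×n per side) of log₂(CPM+1)
values. Per-cell-type gene-set comparisons use the two-sample KS test with
Bonferroni correction over cell types. The bootstrap signature enrichment
draws same-size gene sets without replacement from the background (10,000
repetitions by default), reports z = (obs − null mean)/null SD and a
one-sided (over-expression) p with the (r+1)/(n+1) estimator, and corrects
across cell types by BH; depletion surfaces as negative z without a p.
Conditional enrichment (controlling for one cell type) restricts the
background to genes in the same expression decile of the conditioning type
— an approximation, flagged as such.

## The synthetic cohort generator

The generator emulates the integrated reference design: 15,560 ASD and
31,052 DD probands and 5,241 siblings by default, a 64.25% male fraction,
4% X-linked genes, and per-proband diploid DNV rates of 0.148 LGD, 0.703
missense (18.1% severe) and 0.251 synonymous — the harmonized genome-wide
class rates of that cohort. Per-gene rates are lognormal weights
(log-scale SD 1.0, a realistic one-to-two-orders-of-magnitude spread)
normalised so the diploid genome-wide sums hit the targets exactly. Risk
genes are chosen uniformly at random and receive class-specific relative
risks drawn from configured ranges (default 10–50 for LGD and missense);
severe missense inherits the missense relative risk; siblings carry no
planted risk. Counts are drawn as group totals per (gene, class, sex)
Poisson variables and assigned to children uniformly — the same joint law
as per-child draws, at a fraction of the cost. CADD scores for simulated
missense variants come from two disjoint strata (≤ 30 and > 30.5) so the
severe-missense boundary is exercised; positions are uniform over the CDS.

What the simulator does **not** emulate: cohort-specific calling artifacts
and QC structure, recurrent-site hotspots and clustered missense positions
in risk genes, pedigree structure beyond trio labels, genotype-level
case–control data (carrier counts are simulated directly), and correlation
between gene length and risk-gene status. Passing the calibration and
recovery studies therefore demonstrates the statistical machinery is
correct and well calibrated under the assumed model, not that real-cohort
QC is solved.

## Calibration under discreteness

Null p-values of the Poisson and permutation tests are super-uniform: for a
discrete test, P(p ≤ α) equals the attainable level — the largest exactly
attainable tail probability below α — which at realistic per-gene
expectations (λ of order 0.01–1) is far below α itself. The calibration
study therefore checks two things on a no-risk-gene cohort: (i) validity —
no test's significant fraction at nominal 0.05 exceeds the 99% binomial
upper bound; and (ii) for the five analytic Poisson tests, agreement of the
observed significant count with its exactly computed expectation
Σ_g P(p_g < 0.05) within a 99% normal band with Poisson-binomial variance.
Comparing the raw fraction to the nominal 0.05 would be the wrong reference
for any discrete test.

## Problem sizes and numerical choices

The bundled studies use a 2,000-gene, 6,000-trio null cohort for
calibration and a 10,000-gene, 5,000-trio cohort with 50 planted risk genes
for recovery, with 9,999 Monte-Carlo iterations for the weighted tests
(the smallest resolution at which the weighted model can contribute to
FDR 5% calls at m = 10,000). At these sizes LC recovery sits near the
low-80% range and varies by a few genes across seeds, limited by planted
genes that land on low-rate (short) genes where even a 50-fold relative
risk yields only a handful of expected DNVs — an irreducible power limit of
uniform-random planting, not a pipeline defect. HC-tier membership cannot
be reached by the weighted model at this iteration count (its minimum p is
1e−4 > 3.64e−7); exome-wide claims at full scale require larger n_iter or
analytic tails. Monte-Carlo estimators use (r+1)/(n+1); Fisher's method
combines missense enrichment and clustering p-values; ties in BH are
handled by stable sorting; zero-expectation genes return p = 1 for zero
observed counts. All generators derive independent child streams from the
single configured seed, so every output is byte-identical given seed and
config.
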