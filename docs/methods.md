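# Methods

## The analysis problem

A regulator is knocked down (two independent siRNAs plus a control
siRNA) and overexpressed (expression construct plus vector control) in
cultured cells; genomic DNA is fragmented and enriched for the
methylated fraction, and the enriched material is either sequenced or
hybridised to a promoter array alongside the input. The questions the
package answers are: which genes change methylation in response to the
regulator, in which direction, and whether the responding genes are
over-represented in externally supplied gene sets — here, polycomb group
protein target genes (PCGTs), consumed as four component target lists
(Suz12, Eed, Phc1, Rnf2) plus their intersection ("targets of all") and
union ("targets of at least one").

## Gene regions and fragment counting

A gene's region is the union of its body — TSS to the stop-codon
boundary — with a window of ±2 kb around the TSS, clipped at the
chromosome origin. The window is symmetric because promoter-proximal
methylation signal falls on both sides of the TSS; the half-width is
configurable (`window_bp`, default 2000). Coordinates are 0-based
half-open throughout; GTF input is converted on read, and for − strand
genes the TSS is the rightmost body coordinate.

Fragments are assigned to a gene when their midpoint,
floor((start+end)/2), lies in the gene's region. Midpoint assignment was
chosen over any-overlap so a long fragment spanning a region edge is
counted at most once per gene; a fragment whose midpoint falls in two
overlapping gene regions counts once for each (tallied and logged).

## The sequencing-arm caller

Counts are pooled within each condition (e.g. the two knockdown
libraries against the control library). For each gene with a non-zero
pooled total, the split of the total between conditions is tested
against the library-size proportion with a two-sided exact binomial
test; p values are Benjamini–Hochberg adjusted across genes (default
acceptance at `p_adj ≤ 0.05`) and the direction is read off the sign of
the log2 normalised-rate ratio (0.5 pseudocount per side, so a zero on
one side stays finite). Underflowed p values are floored at the smallest
positive double to keep them in (0, 1].

This is deliberately a *pooled* caller: it conditions on each gene's
total and asks only whether the split is skewed, so gene-level effects
that multiply both libraries equally (length, CpG density, capture
efficiency) cancel. It has no replicate-aware dispersion model —
biological variation between replicate libraries of the same condition
would inflate its false-positive rate — and it is validated on synthetic
data only, where the emulated design pools replicates before sequencing.

## Array peak acceptance and presence/absence

Array data arrive as one enrichment score per gene per biological
replicate, on the −log10 P scale. A gene is accepted as an enrichment
peak when its score strictly exceeds `score_cutoff` (default 2.0, i.e.
P < 0.01) in at least `min_replicates` of `replicate_count` replicates
(default 2 of 3). The inequality is strict: a score of exactly 2.0
fails. Differential methylation between two conditions is then
presence/absence: genes enriched only in control *lost* methylation,
genes enriched only in treatment *gained* it. The two siRNA peak lists
are combined by union before the comparison (intersection available via
`sirna_combine`).

## Response classes

positive = (hypo under knockdown) ∪ (hyper under overexpression);
negative = (hyper under knockdown) ∪ (hypo under overexpression);
genes with evidence in both directions are *conflicted* and excluded
from both classes, keeping the enrichment inputs disjoint — the tie case
has no principled winner, and reporting it separately preserves the
information. A gene called both hypo and hyper within a single arm is
impossible output from one caller and raises as corrupt input. The
overexpression sets may be empty (knockdown-only designs).

## Overlap statistics

For query A, target B, universe N: expected = |A|·|B|/N and
RF = observed/expected, so RF·expected = observed exactly. Significance
uses the 2×2 chi-square with Yates' continuity correction, the
convention used for published RF tables in this field; the correction
is floored at zero so a table at exact independence gives chi² = 0,
P = 1. A two-sided exact hypergeometric P (minimum-likelihood
summation, the Fisher-exact convention) is always computed alongside
and is the recommended number whenever any expected cell is below 5 (a
warning is attached automatically). The target set is intersected with
the universe before testing; the query must lie inside the universe.

N is mandatory and printed with every P value. There is no defensible
default: the same margins (1554 and 1845 genes overlapping by 139) give
P < 10⁻¹⁵ in a 40 000-gene universe but far weaker evidence in a small
platform-restricted background. The file-based pipeline's default
policy sets the universe to the genes the calling stage actually scored
(`annotation_all`), recording the policy in the manifest; an explicit
background list is the alternative.

The reported 95% interval for the RF is a Clopper–Pearson interval on
the overlap fraction observed/|A|, rescaled by N/|B| — a binomial
approximation to the hypergeometric draw, slightly conservative, which
is the desired direction for a coverage guarantee.

Raw P values are reported per target-set row; no multiple-testing
correction is applied across the six PCGT rows (matching how such
tables are conventionally printed), and a Benjamini–Hochberg column can
be added by the caller.

## qPCR arithmetic

ΔCt(sample) = Ct(target) − mean(Ct of reference amplicons); replicate
Cts are averaged before differencing, and the reference combination is
the arithmetic mean of reference Cts, i.e. the geometric mean of the
linear quantities. ΔΔCt = ΔCt(treated) − ΔCt(control) and
fold = 2^(−ΔΔCt); amplification efficiency is fixed at 2 (no
standard-curve correction). Spike-in fold enrichment of a methylated vs
an unmethylated species is
2^(ΔCt_meth)/2^(ΔCt_unmeth) with ΔCt = Ct(input) − Ct(enriched); the
quantity is invariant to adding a constant to all four Cts.

Group comparisons use one-way ANOVA followed by Dunnett's many-to-one
test. Adjusted p values come from the null distribution of the maximum
absolute pooled-variance t statistic across comparisons, estimated by
seeded Monte Carlo under equal-variance normality at the observed group
sizes (default 20 000 draws; the `+1` correction keeps the estimate
positive and adjusted p values are floored at the unadjusted t p so
adjustment can never appear anti-conservative). Monte Carlo was chosen
over quadrature because it needs no special-function machinery, is
seedable, and is directly testable against scipy's quadrature
implementation — the two agree to Monte Carlo error.

## The synthetic-data generator

The generator emulates the structure of the two-arm design above: five
conditions (two knockdown siRNAs, knockdown control, overexpression,
vector control) × two fractions (input, enriched) of sequencing counts,
three array replicates per condition, and Ct tables for spike-in QC and
an mRNA panel. Defaults are chosen as the study-scale conditions:
20 000 genes (a genome-scale annotation), 10% PCGTs, 3000 responsive
genes (≈1500 per response class, the scale of the published lists),
enrichment odds 2.0 (realised RF ≈ 1.6–1.7, mid published band),
libraries of 5×10⁶ assigned fragments, planted log2 methylation-odds
shift of 2.

Layer by layer:

* **Truth.** The number of responsive genes falling in the PCGT pool is
  drawn from Fisher's noncentral hypergeometric distribution with the
  configured odds multiplier (odds 1 ⇒ central hypergeometric ⇒ null);
  `odds_for_target_rf` inverts the distribution's mean numerically so a
  target RF can be planted exactly in expectation. Responsive genes
  split uniformly into positive and negative classes.
* **Methylation.** Baseline levels are a bimodal Beta mixture — 55%
  Beta(2, 8) (unmethylated promoters) and 45% Beta(8, 2) (methylated) —
  the bimodality real enrichment assays rely on. Responsive genes shift
  their log2 methylation odds by ±`effect_size` per condition with the
  appropriate sign per class and arm.
* **Counts.** Each gene receives one Gamma capture-efficiency factor
  (mean 1, CV² = 1/`dispersion`) shared across all ten libraries;
  per-library counts are Poisson around library-size-normalised means
  proportional to length × capture (× methylation for enriched
  fractions). Marginally the counts are negative binomial with the
  configured dispersion, emulating the overdispersion of
  methylated-DNA capture; because the factor is shared, between-library
  contrasts remain conditionally binomial, which is the regime in which
  the pooled caller is calibrated. Independent per-library biological
  noise is deliberately *not* modelled (the emulated design pools
  biological replicates before sequencing); adding it would break the
  pooled caller's calibration, and that fragility is a documented
  limitation of the caller, not of the generator.
* **Array scores.** Score = 4 × methylation level + Gaussian replicate
  noise (sd `array_noise_sd`, default 0.3), clipped at 0 — a clearly
  methylated gene sits near 4, an unmethylated one near 0, and the >2
  cutoff bisects the two modes. The default noise gives the replicate
  reproducibility that a 2-of-3 concordance rule presumes; raising it
  degrades presence/absence precision smoothly.
* **Ct tables.** Generated from log2 abundances plus N(0, 0.15) cycle
  noise; the spike-in table plants a configurable true fold preference
  (default 1000) for the methylated species.

All randomness flows from the single config seed through fixed named
substreams (one per layer), so a dataset is reproducible bit-for-bit
and layers can be regenerated independently.

What passing tests on this generator do **not** show about real data:
no probe-sequence or CpG-density effects, no alignment artefacts, no
biological replicate variance in the sequencing arm (see above), no
correlation between methylation and gene function beyond the planted
PCGT bias, and gene "regions" that never overlap. Results on real
MeDIP/array data additionally depend on the upstream caller (e.g. a
dispersion-aware model) and on the choice of universe.

## Numerical and design notes

* Two-sided exact binomial and hypergeometric p values use the
  minimum-likelihood convention, with a 1+10⁻⁷ relative tolerance when
  comparing probability atoms so floating-point ties are included.
* Under the generator's fixed-margin truth draw the overlap is exactly
  hypergeometric, so the exact test is the calibrated reference there;
  the Yates chi-square is conservative in that regime (smaller variance
  than the multinomial sampling the chi-square assumes, plus the
  continuity correction) and never rejects more often. Both rates are
  measured in the acceptance suite.
* At an exactly proportional count split the caller's effect is 0; the
  direction label is then arbitrary ("hyper") but the p value is ≈1, so
  such genes never survive any sensible acceptance threshold.
* Degenerate inputs fail loudly: zero-margin tables are rejected by the
  chi-square path (with a pointer to the exact test), zero within-group
  variance everywhere by the Dunnett path, corrupt two-direction calls
  by the classifier, and impossible overlap configurations by the RF
  arithmetic.
* Problem sizes in the test and acceptance suites — 1000 null universes
  of 5000 genes, 200 recovery simulations at 20 000 genes, one full
  end-to-end experiment at 20 000 genes, 2000 Dunnett null experiments
  at 4000 Monte Carlo draws each — were chosen to give Monte Carlo
  standard errors comfortably inside the asserted bands while keeping a
  full run in the low minutes on one CPU.

## Known limitations

* The pooled binomial caller makes no claim of replicating what a
  dispersion-aware package would call on deposited real data; it is a
  declared stand-in validated on synthetic data.
* Probe-to-gene mapping, CpG-coupling normalisation and sub-gene
  (window-level) resolution are out of scope.
* The Clopper–Pearson RF interval ignores the finiteness of the target
  set (binomial in place of hypergeometric), which widens it slightly.
* `read_gene_models` accepts GTF `gene` features and BED6 only; supply
  one record per gene.
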