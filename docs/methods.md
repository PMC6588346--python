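# Methods

## The screen and its statistic

`facscreen` analyzes pooled CRISPRi screens read out through a fluorescent
transcriptional reporter.  A library-transduced cell population is split
into two treatment arms — ER stress alone (`tm`) and ER stress plus an
ATF6α inhibitor (`tm_ceapin`) — and each arm is FACS-sorted into the top
and bottom ~30% of reporter fluorescence.  Sequencing the sgRNA-encoding
protospacers of each bin yields four count tables.

**sgRNA phenotype.**  For sgRNA *i* in one arm,

    value_i = log2[ (c_high,i + pc)/(T_high + P) / ((c_low,i + pc)/(T_low + P)) ]

with pseudocount `pc` (default 1 read), `T` the mapped reads of the bin and
`P = pc · n_sgRNAs`.  The pseudocount keeps log ratios finite when an sgRNA
drops out of one bin.  By default the median raw phenotype of the
negative-control sgRNAs is subtracted from every value
(`center_on_controls`): without centering, unequal sequencing depth between
bins shifts the entire phenotype distribution; with it, the controls define
zero.  Setting `center_on_controls=False` reproduces the uncentered ratio.

**Gene statistics.**  A gene's phenotype ρ is the mean over its (filter-
passing) sgRNA phenotypes; the library is built with one transcription
start site per gene, so gene and TSS aggregation coincide (multi-TSS
libraries can be keyed as `gene|tss` labels).  Its p-value is a two-sided
Mann-Whitney U test of the gene's sgRNA phenotypes against the full
negative-control sgRNA set.  The discriminant score is

    score = | (ρ / σ) · log10 p |,    hit ⇔ score > τ  (τ = 7),

with p clamped to `[p_floor, 1]` (`p_floor = 1e-16`) so scores stay finite.

**The σ in the score.**  σ is the standard deviation of all evaluated
reporter phenotypes in the arm.  The default (`sd_mode="all_sgrnas"`) takes
the SD over all per-sgRNA phenotypes.  Two alternatives are provided:
`"all_genes"` (SD over gene-level ρ) and `"control_pseudogenes"` (SD over
pseudogene ρ, the field-standard empirical null).  The sgRNA-level default
was chosen on calibration grounds: gene-level ρ averages k = 5 sgRNAs and
its SD is ~√5 smaller, which inflates ρ/σ for every gene and lets the
null's correlated (ρ, p) tail cross τ = 7 at an appreciable rate (~0.25% of
null genes per arm in our simulations, i.e. a few spurious drug-specific
calls per 200-gene screen).  With sgRNA-level σ the same simulations
produce no false hits at τ = 7 while spiked true effects still score an
order of magnitude above threshold.

**Mann-Whitney p-values.**  Computed through
`scipy.stats.mannwhitneyu`: the exact permutation null when the data are
tie-free and `C(n+m, n) ≤ 2×10⁵`, otherwise the normal approximation with
midranks and tie correction.  Exactness is verified in the test suite
against an independent brute-force enumeration of all labelings; two-sided
p is `2·min(P(U ≤ u), P(U ≥ u))` capped at 1.

**Pseudogenes.**  Negative-control sgRNAs are partitioned (seeded
permutation, remainder dropped) into disjoint groups of `pseudogene_size`
(default 5) and scored exactly like genes.  They provide the gray
background population in classifications and the alternative σ.

**Two-arm classification.**  Category is a pure function of the two hit
flags: hit in both arms → `ceapin_independent` (the knockdown's phenotype
does not depend on the drug); hit only with the drug present →
`ceapin_hit` (the drug's candidate target: knockdown restores the
induction the drug blocks); hit only without the drug → `tm_only_hit`
(reporter inhibitors such as ATF6α or its proteases); else `none`.  Strict
arm-exclusivity is used for `ceapin_hit` — a gene also hit in the stress
arm is not a drug-specific call.  A growth-screen annotation flags genes
with γ ≤ −0.19 (a growth defect of at least that magnitude; CRISPRi growth
phenotypes of essential genes are negative).  The flag colors genes but
never changes the arm-based category.

## The synthetic screen

The generator emulates the study conditions rather than the wet-lab
protocol: treatment arms are shift regimes, not drug concentrations, and
selection/MOI/PCR bias are not modeled.

* Library: `n_genes` (default 200) × k = 5 sgRNAs plus 100 non-targeting
  controls; random unique 20-mer protospacers, optionally spiking the ten
  individually validated protospacers (the two 21-mers among them are
  excluded from spiking because exact-match counting requires one length).
* Efficacy: `e ~ Beta(5, 1)` per targeting sgRNA (most guides active, with
  spread that exercises the rank test); controls get e = 0 exactly.
* Cells: `Poisson(coverage)` per sgRNA (default 500), fluorescence
  `log2F = mu0 + δ_arm + e·(shift − δ_arm) + ε`, `ε ~ N(0, sigma_cell)`.
  `δ_arm` is `delta_induction` (default 1.0 log2 units — the two-fold
  wild-type stress induction) in the stress arm and 0 in the inhibited
  arm.  `sigma_cell` defaults to 1.0 log2 units, a realistic FACS reporter
  spread (about one decade between distribution tails), so the two-fold
  induction moves the population by ~1 SD.
* Gates: global 30% percentile gates per arm with exactly `round(f·N)`
  cells per bin; boundary ties are broken by seeded uniform jitter so bin
  sizes are reproducible.
* Sequencing: one multinomial draw of `reads_per_bin` (default 2×10⁶)
  reads per bin over cell tallies; optional FASTQ output with a constant
  10-nt 5′ flank, the protospacer at offset 10, 50-nt reads, and an
  optional per-base substitution rate.

What the generator does **not** emulate: guide-specific off-target
effects, growth dropout during culture, PCR amplification bias,
sequencing-quality variation, and multi-TSS genes.  Passing calibration
and recovery tests therefore demonstrate the statistic's behavior under
idealized sampling noise, not robustness to these real-data artifacts.

## Problem sizes and numerical choices

Calibration and recovery runs use 20 screens of 200 genes × 5 sgRNAs +
100 controls at coverage 500 and 2×10⁶ reads per bin — small enough to run
on a laptop in about a minute while giving per-sgRNA read depths (~1800)
in the regime of a real genome-scale screen.  Counting round-trips use
bins of 8×10⁴ reads.

Degenerate inputs: identical high/low tables give all-zero phenotypes and
σ = 0; scores are then defined as 0 (consistent with `score = 0` whenever
ρ = 0) and no hits are called.  σ = 0 with any nonzero ρ raises an error.
A gene whose sgRNAs are all removed by the read filter is reported with
`n_used = 0`, score 0 and `hit = False`, and logged.  Unknown sgRNA ids in
count tables are an error by default (silent drops hide counting bugs);
`policy="drop"` moves their reads to `unmapped` with a warning.

## IP-MS module

TMT channels are normalized by dividing each channel by its own bait
(immunoprecipitated protein) intensity, making the bait row all ones and
cancelling per-channel pulldown efficiency and labeling scale
(normalization is idempotent and invariant to scaling any channel).
Treatment ratios are means of normalized intensities over a treatment's
replicate channels (arithmetic mean; with n = 2 replicates no cross-
replicate test is attempted) divided between treatments.  Candidates are
ranked by the selectivity contrast `ratio_active / ratio_inactive`
(active vs inactive analog, each over vehicle); both per-treatment ratios
and the contrast are reported, since either ranking is defensible.
Proteins undetected under the denominator get a `+inf` ratio, a flag, and
rank after all finite contrasts instead of being dropped.

## Known limitations

* Exact-match counting only; a single sequencing error in the protospacer
  unmaps the read (~18% of reads at a 1% per-base error rate).  Mismatch
  tolerance is future work.
* Single-replicate screens: no replicate-combination logic.
* The fixed-τ hit rule provides no FDR estimate; pseudogene scores give an
  empirical handle if one is needed.
* The asymptotic Mann-Whitney branch is conservative near the exact/
  asymptotic boundary; the boundary (2×10⁵ labelings) is far above any
  5-vs-controls configuration used here.
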