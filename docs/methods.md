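# Methods

## Quantities

A sperm sample is characterised by its **absolute rDNA copy number**
(copies per haploid genome) and its **presumably active copy number**:
absolute CN times the fraction of promoter epialleles with ≤ 10%
methylation over 25 CpGs.  Copies in each 10-percentage-point methylation
bin are `absolute_cn × bin_fraction`; the unrounded bin copy numbers sum
to the absolute CN exactly.  Reported per-sample integers use half-up
rounding; statistics always run on unrounded values (a `round_reported`
switch reproduces printed-table behaviour).

## ddPCR estimator

Droplet occupancy is Poisson: a well with positive fraction *p* and
dilution *d* gives λ = −ln(1 − p)·d copies per droplet at sample scale,
and concentration λ/V with V = 0.85 nL (QX200 droplet volume; it affects
only the copies/µL report, never the ratio).  The copy number is
(λ_t/λ_r)·m_ref.  `m_ref` deserves care: CNV assays conventionally
multiply by the reference-gene copies in the *diploid* genome (2 for
*TBP*), but sperm is haploid and copy numbers here are reported per
haploid genome, so the default is `m_ref = 1`; set 2 for diploid-scale
reporting.

Uncertainty: Wilson score intervals on each well's positive fraction are
pushed through the monotone map p → −ln(1−p), converted to a log-scale SE
as (ln hi − ln lo)/2z, and combined in quadrature (delta method on the
log ratio).  The Wilson/delta choice keeps small-count wells (a reference
well has ~600 positives) stable; at the study's settings (20,000
droplets, target diluted 10×, λ_ref ≈ 0.03) the estimator CV is ≈ 4% and
the 95% CI covers truth in ≈ 94% of simulated wells.  A fully positive
well raises a saturation error rather than returning an unbounded λ.
Duplex wells are supported through four-category amplitude thresholding
(strictly-greater-than per channel, operator-chosen thresholds); the
default workflow is separate wells because a ~236-copy target would
saturate a duplex well at reference-friendly loads.

## Bisulfite read processing

Reads are aligned to the amplicon with an ungapped semi-global,
bisulfite-aware scorer: read T matches reference C (conversion), both
orientations are tried (mate 2 of a pair is the reverse complement of the
converted top strand; only top-strand chemistry is modelled, as amplicon
primers select it).  Mapping identity is assessed on non-cytosine
reference columns only, so methylation state cannot bias mapping; the
floor is 80%.  Indel-tolerant alignment is out of scope — the amplicon is
short and the simulator emits no indels.

Mates are merged in reference space; conflicting overlap bases become N
(trusted never).  Per merged read:

* conversion rate = #T / (#T + #C) over covered non-CpG reference
  cytosines (other bases carry no evidence and are excluded); at least 10
  informative positions required; retention requires rate **strictly**
  greater than 0.95, so a read at exactly 95% fails;
* allele = base at the A/G variant (not a cytosine, hence untouched by
  conversion); only major-G reads are retained, so sequence variants do
  not contaminate methylation;
* CpG states: C = methylated, T = unmethylated, else ambiguous; at least
  20 of 25 analyzable states required.

Per-sample mean methylation is the pooled CpG-call fraction (total
methylated / total analyzable over retained reads); with complete
25-CpG reads this equals the mean of per-read percentages.  Bin edges:
[0,10], (10,20], …, (90,100] — the closed first edge makes bin-0
membership identical to the ≤ 10% "presumably active" rule.  Every input
read lands in the retained set or exactly one rejection bucket (first
failing filter), so read counts are conserved.

## Semen classification

WHO 5th-edition lower reference limits: volume ≥ 1.5 mL, concentration
≥ 15×10⁶/mL, total motility ≥ 40%, normal morphology ≥ 4%.  A sample
meeting all four is NSP; otherwise ASP with subtype labels
(oligo-/astheno-/teratozoospermia, OAT when all three, cryptozoospermia
below 0.1×10⁶/mL — a common andrology convention, as no universal cutoff
exists).  A preset with progressive motility ≥ 32% is provided because
clinics differ in which motility criterion they apply.  Thresholds are
inclusive (a value exactly at the limit is normal).

## Statistics

* Mann–Whitney U, two-sided.  Asymptotic: normal approximation with
  tie-corrected variance and no continuity correction — the convention of
  the major commercial packages, and the variant that reproduces p = 0.009
  on the minima-list worked example (exact permutation gives 2/252 ≈
  0.0079; both are available).  Exact: the full permutation null of the
  rank-sum with midranks, computed by a subset-sum dynamic program
  (default for combined n ≤ 25).
* Spearman's ρ with midranks and the t-approximation p.
* Normality QC: Shapiro–Wilk and Lilliefors-corrected
  Kolmogorov–Smirnov (parameters estimated from the data); group
  comparisons stay non-parametric regardless.
* Pregnancy model: binary logistic, outcome ~ CN variable +
  concentration + motility + morphology + age + BMI, covariates z-scored
  by default (per-SD log-odds), Wald two-sided p.  Quasi-separation and
  non-convergence are flagged; a separated fit reports no p-values.
* Minimum-CN analysis: the k = 5 smallest active CNs overall vs. within
  the pregnancy group, compared by Mann–Whitney; the pregnancy-group
  minimum is the empirical floor of copies observed compatible with
  pregnancy.
* α = 0.05 two-sided throughout; no multiple-testing correction is
  applied (the analysis reports a fixed, pre-specified battery).

## Synthetic cohort

The generator draws 94 NSP + 96 ASP donors:

* age ~ truncated N(39, 7²) years; BMI ~ truncated N(26.5, 4.5²) kg/m²;
* absolute CN ~ truncated N(236, 58²) on [100, 420] copies;
* each rDNA copy is active or inactive; a read samples one copy and
  methylates each of 25 CpGs with a Beta-distributed per-copy probability
  centred at 2% (active) or 60% (inactive), concentration 60 — read
  methylation is therefore a two-mode binomial mixture, and the bin-0
  probability has a closed binomial form used as an oracle in tests;
* the active fraction is f = 0.5 − a·(age − 39) − b·(CN − 236) − ASP
  offset + noise, clipped to [0.02, 0.98], with a = (0.62 pp/year)/58pp,
  b = 5.5·10⁻⁴ per copy, noise SD 0.055.  The CN coupling is dosage
  compensation (a larger repeat pool has a larger silenced share); it is
  also what makes a strong negative age/active-CN rank correlation
  (≈ −0.55 ± 0.06 at N = 190) attainable while active CN keeps a
  realistic spread (~110 ± 30).  The ASP offset is stated in percentage
  points of mean methylation (+1.8 by default) and converted through the
  58-pp spread between the modes;
* semen parameters: NSP donors sample above every WHO-5 limit; ASP
  donors draw a failure pattern (51% asthenozoospermia, 38.5% OAT, the
  rest oligo-/terato-/cryptozoospermia) mimicking a male-factor IVF/ICSI
  population;
* pregnancy ~ Bernoulli(logistic(0.10 + 0.95·z_active + 0.30·z_conc +
  0.20·z_mot + 0.35·z_morph − 0.10·z_age)) with fixed nominal
  standardisation scales; these coefficients yield a roughly balanced
  outcome and an absolute-CN gap of ≈ 24 copies between outcome groups at
  truth level.  One donor per cohort gets a blank pregnancy field
  (clinical sheets have gaps).

Droplet wells are Binomial(n, 1 − e^(−λ)) draws at the occupancy implied
by the donor's true CN (target diluted 10×); reads carry configurable
bisulfite-conversion failure (default 0.5%), uniform substitution errors
(0.1%), and a 3% minor-A-allele fraction.  Truth sidecars record every
read's generating copy class, allele, and methylation count, enabling
exact oracle tests at zero error rates.

### What the simulator does not emulate

Quality-score and error-profile realism (position-dependent errors,
adapters, PhiX), indels, bottom-strand chemistry, PCR duplicates and
amplification bias, donor-level clustering of repeated samples, and
female-side ART factors.  Passing tests therefore demonstrate estimator
and pipeline correctness under the stated generative assumptions, not
robustness to every artefact of real sequencing runs.

One deliberate level discrepancy: with the 2%/60% methylation modes and
an active fraction near 0.5, cohort mean promoter methylation sits near
32%.  Clinical reports of ~12% mean methylation alongside a ~0.49
hypomethylated-read fraction imply a much lower methylation level among
silenced copies than a single 60% mode; no two-mode model matches all
three numbers at once.  Group *offsets*, correlations, and copy-number
gaps — the quantities this package tests — are insensitive to the level.

## Problem sizes and numerics

Validation runs use 190-donor cohorts with 600 read pairs per sample and
20,000 droplets per well; calibration studies use 500 ddPCR replicates
and 2,000 Mann–Whitney null replicates — sizes chosen so the whole
battery completes in a few minutes on one core while keeping Monte-Carlo
error well below the tolerances tested.  All randomness flows from a
single seed through crc32-salted SeedSequence children, so FASTQ bytes,
droplet counts, and every downstream table are reproducible; exact
Mann–Whitney counts stay exact in float64 up to combined n ≈ 60.  Ties
in alignment scoring break toward the forward orientation and the
smallest offset, deterministically.

## Known limitations

The aligner assumes the read is a (possibly partial) copy of the single
amplicon; it is not a general bisulfite mapper.  The exact Mann–Whitney
is quadratic in total midrank mass and intended for small strata.  The
pregnancy model treats samples as independent donors.  The empirical
"floor" from the minimum-CN analysis is an order statistic and should be
read descriptively, not as a threshold estimate with a standard error.
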