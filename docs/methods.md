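# Methods

## The inference model

`selscope` treats a duplex-sequenced gene panel as a collection of
(site, alternate-allele) pairs. Each pair belongs to one of 96
trinucleotide substitution channels (pyrimidine-central, strand-collapsed)
and to a consequence class determined by codon translation on the
annotated strand: synonymous, missense, nonsense, essential splice
(the two intronic bases flanking each internal coding-exon boundary),
or non-coding. Indels are classified frameshift when their length is not
a multiple of three and they overlap coding sequence.

Mutation counts are modeled as Poisson. Under neutrality the number of
mutations observed at a (site, alt) pair is Poisson with mean
`r_c · d`, where `r_c` is the channel rate in mutations per site-genome
and `d` the duplex depth at the site in haploid genomes. Channel rates are
estimated from classes assumed selection-free (synonymous plus non-coding
by default; tumour-recurrent promoter positions are excluded from the
neutral set):

```
r_c = N_c / O_c ,   O_c = Σ_{(site,alt) neutral, channel c} d(site)
```

`O_c` is the *mutational opportunity* of the channel — the depth-weighted
count of neutral (site, alt) pairs, which simultaneously corrects for
sequence composition and for uneven depth. A pseudocount (default 0.5,
applied only when some observable channel is empty) stabilises ratios; it
is disabled wherever exact Poisson tests are computed.

Gene-level selection on class `k` is `ω_k = N_k / E_k` with
`E_k = Σ_{(site,alt): class k} r_c · d`. Confidence intervals are exact
Garwood intervals on the observed count divided by `E_k`; p-values are
two-sided exact Poisson (doubled smaller tail, capped at 1). Uncertainty
in `E_k` itself is ignored; the test suite sizes its experiments so that
the neutral mutation count makes this a second-order effect.
`max(N_k − E_k, 0)` estimates the number of driver mutations; divided by
`N_k` it is the driver fraction.

Promoter selection dichotomises promoter SNVs into *activating*
(on a whitelist of positions recurrently mutated across tumour genomes —
a property of the input file, not recomputed) versus other. The
spectrum-and-depth expectation over whitelist pairs is rescaled so the
non-activating promoter sites reproduce their observed count exactly;
this local calibration absorbs any promoter-specific mutability.

Frameshift-indel enrichment compares a gene's frameshift-indel count with
a background rate per depth-weighted coding base estimated from all other
genes (leave-one-out, so a strongly selected gene cannot dilute its own
test).

Per-sample dN/dS uses each sample's depth column, with the pooled channel
rates rescaled per sample so the sample's panel-wide neutral count is
reproduced. This keeps the channel profile (which needs cohort-level
counts to estimate) pooled while calibrating each sample's mutation
burden, so per-sample dN/dS measures selection rather than burden. A
(gene, class) combination enters downstream analyses only when its dN/dS
is computable for at least 80% of samples.

## Site, residue, exon and domain selection

The gene expectation of a class is distributed over its (site, alt) pairs
proportionally to `r_c · d`, so unit expectations sum exactly to the gene
expectation. Units are scored with the exact Poisson upper tail on raw
counts, BH-corrected within the gene (a panel-wide option exists), and a
display score `log2((obs + ε)/(exp + ε))` with ε = 0.5.

## Saturation kinetics

The theoretical curve is `fraction(D) = mean_m (1 − exp(−r_m D))` over a
gene's possible substitutions, the Poisson-process probability that
mutation `m` has been observed by cumulative depth `D`. By default each
`r_m` is additionally scaled by its site's share of the gene's cohort
depth profile (mean 1); under uniform depth this reduces exactly to
`1 − e^{−rD}`.

The observed curve downsamples the catalog. Two thinning models are
provided, reflecting two readings of "reduce the depth while respecting
the VAF":

- `molecules` (default): each of a mutation's supporting duplex
  molecules, `k = max(1, round(VAF·d))`, survives thinning to fraction
  `f` independently; retained iff ≥1 survives. At `f = 1` the observed
  set is reproduced exactly, and for single-molecule mutations retention
  equals `f` — which makes the neutral observed curve match the
  theoretical one (the identifiability property the comparison relies
  on) whenever neutral mutations are singleton-dominated.
- `binomial`: a fresh re-detection draw, retained iff
  `Binomial(round(f·d), VAF) ≥ 1`. This models re-sequencing the tissue
  at lower depth; note that even at `f = 1` a singleton is re-detected
  with probability `1 − (1 − 1/d)^d ≈ 0.63`, so this estimator does not
  preserve the full-depth endpoint. `retention_rate` exposes both models;
  its closed forms are `1 − (1 − VAF)^{round(f·d)}` and
  `1 − (1 − f)^k` respectively.

Curve divergence is summarised by the signed trapezoid area between
observed and theoretical curves and by their difference at the deepest
grid point; observed above theoretical is the positive-selection
direction, below (FGFR3-like) the negative.

## Clone fractions

With driver count `n = round(excess_missense) + round(excess_truncating)`
(round half-up), the `n` highest all-molecules-VAF protein-affecting
mutations of the gene in the sample are taken as the likely drivers (VAF
ties broken by ascending genomic position, so selection is deterministic).
Assuming independence, the fraction of sequenced genomes carrying at
least one driver is `P(G) = 1 − Π_x (1 − p_x)`, identical to the
alternating inclusion–exclusion sum. Bounds re-use the same ranking with
`n` taken from the CI endpoints of the excess. Cells-vs-genomes: two-hit
(default) equates them; one-hit doubles (capped at 1); a hemizygous
X-linked gene in a male has one copy per cell, so cells equal genomes.

## Covariate association

Responses are per-sample mutation densities (per Mb) and per-sample
dN/dS on the log scale (`log(dN/dS + 0.5)`; dN/dS is a positive ratio
with multiplicative noise and the offset keeps zero-count samples
finite). Fixed effects: age in decades, sex (M = 1), smoking (ever = 1;
samples from donors of unknown history are dropped from any smoking
design), alcohol, BMI rescaled to [0, 1], chemotherapy. For activating
promoter-mutation density the age and smoking main effects are replaced
by their interaction. Each model carries a donor-level random intercept
(statsmodels MixedLM; REML, with lbfgs and short Powell fallbacks —
fits that stay singular are reported non-converged and excluded from the
FDR family). A univariate screen (α = 0.05) precedes the multivariate
model; BH q-values are computed within each response family and
associations with q < 0.2 are called significant. The FDR family is
per-response; a global option would be a one-line change but per-response
matches how gene-level selection tracks are reported.

## The synthetic cohort generator

The generator is the package's ground-truth instrument. It emulates the
structure of an ultradeep duplex study of normal bladder urothelium:

- **Cohort**: 45 donors, 34 of them contributing two samples (dome and
  trigone), 79 samples; ages 35–90, sex, smoking (one donor of unknown
  history), alcohol, BMI, chemotherapy exposure.
- **Panel**: artificial two-exon genes (random non-stop codons; the CDS
  split lies mid-codon so codons span the junction; one gene set is
  minus-strand) with 10 bp intronic flanks and a 30 bp intron, plus a
  500 bp promoter block carrying 20 whitelist hotspot (position, alt)
  pairs. The default panel is ≈16 kb — large enough that every channel
  and consequence class is populated, while keeping replicate-based
  validation cheap; panel geometry is fully configurable.
- **Depth**: per-sample mean LogNormal with median 5,164× and σ = 0.35,
  times a per-site gamma "probe efficiency" shared across samples.
- **Spectrum**: mixture of an APOBEC-like (TpC), an ageing-like
  (CpG C>T) and a flat profile; the ageing-like loading and the total
  burden both scale with donor age (rate 2.2×10⁻⁸ mutations per site per
  haploid genome per year, i.e. ≈1.4×10⁻⁶ at the cohort's median age,
  matching a panel-wide burden of order 10³ mutations per sample at
  5,000×).
- **Selection**: per-gene multipliers on missense, truncating and
  frameshift classes (defaults span strong truncating selection, moderate
  missense selection, and one negatively selected FGFR3-like gene), with
  optional per-covariate multipliers (default: a 1.65× male effect on
  three truncating-selected genes) and a promoter-hotspot multiplier with
  an age×smoking log-linear interaction.
- **Clone sizes**: a mutation in a class with total multiplier `m` is an
  expanded driver clone with probability `(m − 1)/m`, drawing its VAF
  from a Pareto tail truncated to `[2/depth, 0.25]`; passengers carry
  their realised molecule count over depth (usually a single molecule) —
  the regime duplex sequencing of normal tissue actually reports. Truth
  driver flags are written to `truth_drivers.tsv`; all injected
  parameters to `truth.yaml`.

Counts per (site, alt, sample) are Poisson with mean
`rate × depth × ω × covariate multipliers`; multiple events collapsing
onto one record are negligible at study-like rates but can bias strong
selection estimates downward if the mutation rate is inflated — the test
suite therefore validates selection recovery at the study's rate with an
enlarged neutral block rather than at an inflated rate.

The generator's consequence labels come from its own hard-coded codon
table and splice logic, independent of the annotator's Biopython-based
translation path; the two are required to agree exactly, which is a
genuine cross-implementation check of the coding model.

What the generator does *not* emulate: sequencing artefacts and
consensus-calling errors, mapping bias, copy-number or methylation second
hits, real human sequence context (genes are random CDS), linkage between
mutations in one clone, and spatial structure within a sample. Passing
tests therefore demonstrate correctness of the inference given the
model's assumptions, not robustness to artefact-contaminated catalogs.

## Problem sizes and numerical choices

Replicate-based validation uses deliberately scaled-down designs chosen
for statistical validity: neutral calibration runs twenty 2-gene
79-sample cohorts at a burden giving ≥200 expected mutations per class;
selection-coefficient recovery runs fifty single-gene cohorts per ω at
the study's per-genome mutation rate (hot CpG channels would saturate at
inflated rates) with a 6 kb neutral block so channel-rate noise is small
against the Poisson CI width; covariate recovery runs twenty-five
45-donor cohorts. Exact Poisson machinery comes from scipy
(`chi2.ppf` for Garwood bounds, `poisson.sf/cdf` for tails); BH from
statsmodels. Degenerate inputs: zero expected counts suppress a result
rather than returning infinities; zero neutral mutations abort spectrum
fitting with guidance; ambiguous (N-context) panel sites are flagged and
excluded from rate estimation.

## Known limitations

- `E` is treated as fixed in tests and CIs; a bootstrap over mutations
  would widen intervals for small panels.
- The Poisson count model ignores overdispersion from clone structure
  (several mutations in one expanding clone are not independent events).
- MNV handling takes the worst constituent consequence and counts one
  event; site-level scores ignore MNVs.
- The promoter calibration assumes non-whitelist promoter sites are
  neutral; widespread low-level selection there would deflate ω.
- Saturation's `binomial` thinning and the theoretical curve are only
  asymptotically compatible; see the thinning-model discussion above.
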