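# Methods

## Data model and coordinates

The canonical coordinate is the signed distance `d` (nt) from the lesion
along the direction of TLS: `d > 0` downstream (synthesized after bypass),
`d < 0` upstream, `d = 0` reserved for the lesion site. Lesion-site outcomes
are stored as `TLSEvent`s, never as `MutationRecord`s, so windowed rate
calculations can never double-count the targeted change; for the UV
reversion assay the co-mutation at the adjacent +1 G is likewise encoded in
the event's codon descriptor and deliberately kept out of the flanking-rate
windows, because incorporation fidelity at that position is confounded by
the distorted template at the damaged site.

External coordinates (gene-ORF, chromosome, insert-relative numbering) are
derived views through invertible piecewise-affine maps with unit slope;
round-trip identity is enforced by tests. The plasmid assay's vector
coordinate column is not modeled: its printed values are internally
inconsistent with the distance column, which is self-consistent, so signed
distance is authoritative.

Windows are half-open `(lo, hi]` of signed distance: `d = +1` is the first
downstream nucleotide and `(0, 220]` is "the first 220 nucleotides".
Excluded intervals (the 47-nt construction-oligonucleotide footprint
`[-20, +26]` in the plasmid assay) are masked from counting and simulation;
fixture catalogs contain no records there by construction.

## Rate estimation

The window rate is the exposure-normalized count μ = m/(L·n), kept as an
exact rational so that μ·L·n = m identically; rounding to 2 significant
figures is purely presentational. `L` is the *nominal* window length even
where an excluded interval overlaps the window (plasmid assay: 26 excluded
nt inside `(0, 220]`): the published near-lesion rate is defined on the
nominal length, and an effective-length analysis is available simply by
choosing a window that avoids the exclusion (as the recovery tests do).

Background subtraction uses a matched-control rate; a negative difference
clamps to zero with an explicit `clamped` flag rather than erroring, since
the background is itself an estimate. With zero observed mutations the rate
is summarized by the bound 1/(L·n) ("fewer than one event over the
exposure"), rendered with a `<` prefix. Exact Poisson intervals use the
Garwood chi-square construction (`chi2.ppf(α/2, 2m)/2` to
`chi2.ppf(1−α/2, 2m+2)/2`, scaled by exposure), which is conservative —
simulated coverage is verified ≥ nominal.

Reference rates (genome-wide spontaneous 2.2×10⁻¹⁰/nt, genome-wide under UV
mutagenesis 0.4×10⁻⁵/nt, in-vitro extension-polymerase error rate
5.6×10⁻⁴/nt) are configurable constants used only for fold changes.

## Enrichment testing

The 2×2 contingency unit is the sequenced product (colony): products with
≥ 1 in-window mutation versus products without, TLS versus control.
Products are the independent sampling units, so this is the primary mode;
a nucleotide-level mode is provided and gives materially the same answer on
the packaged data (both ≈ 0.0045 for the plasmid assay).

The two-sided Fisher exact test uses the minimum-likelihood definition:
the p-value sums hypergeometric probabilities (margins fixed) of all tables
whose probability does not exceed the observed one within a relative
tolerance of 1+10⁻⁷ (so exact ties on the opposite tail are never lost to
rounding). It is computed in exact big-integer arithmetic — table totals
here are at most ~900 with support ≤ 20, so this is cheap — and is pinned
by two independent routes in the tests: exhaustive factorial-formula
enumeration over all tables with total ≤ 40 (agreement to 10⁻¹²), and
scipy's implementation on the real tables.

## Tract-boundary (changepoint) estimation

Downstream mutation positions pooled over products are modeled as a
piecewise-constant Poisson process with a single changepoint `b`: rate
λ_in on `(0, b]`, λ_out on `(b, D]` (D = downstream extent). For fixed `b`
the MLEs are closed-form (λ̂ = m/(n·len)), so `b̂` maximizes the profile
log-likelihood `m₁·log(m₁/(n·b)) − m₁ + m₂·log(m₂/(n·(D−b))) − m₂` (with
0·log 0 = 0) over a candidate grid. The default grid is every observed
position plus 10-nt-spaced points; ties break toward the smaller boundary
(the conservative, shorter tract). When a matched control catalog is
supplied, its downstream mutations contribute to the outside-rate term with
their own exposure, sharpening λ̂_out.

The single-changepoint model is a deliberate simplification — the biology
posits one error-prone tract per lesion — and `Δloglik` versus the
single-rate fit is calibrated by parametric bootstrap: simulate
single-rate catalogs at the pooled MLE rate, refit, and report the smoothed
exceedance `(1 + #{Δ* ≥ Δ_obs})/(n_boot + 1)`. On the packaged catalogs the
fitted boundaries are ~341 nt (plasmid) and ~968 nt (chromosomal); with
only 15–18 downstream events the boundary likelihood is flat enough that a
point a little beyond the visually chosen 220 nt can win on the plasmid
data — the simulation study below shows the estimator is accurate when the
data carry more events.

## Forward simulator

Per product: draw a lesion-site outcome from the insertion spectrum
(defaults 62% A / 20% C / 18% T, the observed spectrum opposite the abasic
analog; an optional probability of the sequence-restoring outcome simulates
products the assay cannot see, which are then dropped with the fraction
recorded); draw a tract length (fixed 220 nt by default; geometric and
uniform alternatives exist because the true tract-length distribution is
unknown — the data constrain only "at least ~200, sometimes ~1000");
mutate each non-excluded nucleotide of `(0, T]` independently with
probability ε_tract (default 5.6×10⁻⁴, the in-vitro extension-polymerase
rate; set it to ~8×10⁻⁵ to emulate the observed in-vivo scale) and each
non-excluded nucleotide of the whole region with probability ε_bg (default
1.4×10⁻⁵, the control-plasmid background: 11 mutations / 456 products /
1726 nt). Placement draws a Binomial(n_allowed, ε) count and then that many
distinct positions, which is exactly per-site Bernoulli sampling but lets
exclusion zones be handled by masking; a site hit by both processes mutates
once. Mismatch repair is modeled as inoperative in tracts (correction
efficiency 0 by default, configurable), matching the observation that
MMR-deficient strains show no increase in tract mutations.

Change descriptors are drawn from empirical spectra (in-tract:
transversion-rich; background: C→T- and single-base-deletion-biased, the
control-plasmid tallies). There is no underlying nucleotide sequence — the
simulator emulates positions, counts and descriptor labels, which is all
the analysis consumes. It therefore does not emulate sequence-context
effects, hotspots, strand asymmetry of real lesions, or replication-fork
mechanics (tract length is a distributional knob, not a mechanistic
output); passing recovery tests show the *estimators* are correct under the
assumed sampling model, not that real tracts follow it.

Determinism: identical `(params, seed)` give byte-identical catalogs
(single `numpy` Generator, fixed code path).

## Validation studies and problem sizes

* Boundary recovery: 200 replicates at n = 5000 products, fixed 220-nt
  tract, ε_tract = 8×10⁻⁵ over ε_bg = 1.4×10⁻⁵ — median |b̂ − 220| ≈ 2–3 nt
  (the acceptance threshold is ≤ 40 nt). The acceptance script runs 100
  replicates, which already gives a stable median.
* Rate calibration: one catalog at exposure ≈ 1.1×10⁷ nt (6500 products ×
  1674 allowed nt) reproduces ε_tract within well under 5%.
* Estimator bias: recovery runs with the window placed beyond the excluded
  footprint show mû/ε within 10% at moderate exposure; background-only
  runs give net rates at zero or noise level.

These sizes were chosen so each study's Monte-Carlo error is several-fold
smaller than the property being asserted.

## Numerical conventions and edge cases

* Exact rational arithmetic for rates and Fisher; floats only at I/O.
* 2-significant-figure reporting; test comparisons use unrounded values at
  5×10⁻² relative tolerance (the precision of the published numbers).
* Degenerate Fisher margins (an empty row or column) give p = 1.
* Changepoint with zero downstream mutations raises; a bootstrap replicate
  with zero simulated mutations counts as non-exceeding.
* Bootstrap with n_boot < 100 warns rather than failing.
* `d = 0` is rejected both as a record coordinate and in the chromosomal
  coordinate map (the lesion dinucleotide spans two chromosomal positions).

## Fixture provenance caveats

Two fixture files contain labelled synthetic placeholders where the source
tables print only aggregates: the per-product lesion-site outcomes of
reversion products without flanking mutations (constructed so exactly
12/165 carry the +1 co-mutation, matching the published count), and the
interior positions of the five rad30 downstream mutations (only the span
505–1026 nt is published; endpoints are kept, and the rate uses the
published m = 5, L = 1000, n = 165). Every number asserted in tests depends
only on the published aggregates, not on the placeholder details.
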