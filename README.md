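# tlstracts

Quantify error-prone **translesion synthesis (TLS) tracts** from catalogs of
mutations positioned around a site-specific DNA lesion.

When a replication-blocking lesion is bypassed in vivo, the specialized
polymerase that extends past the lesion (Pol ζ in yeast) does not always hand
the primer terminus straight back to a replicative polymerase: it can keep
copying undamaged template downstream, leaving a trail of "hitchhiking"
mutations. This package implements the statistical side of that inference for
laboratories running lesion-bypass reporter assays: given sequenced bypass
products with each mutation recorded by its signed distance *d* from the
lesion (positive = downstream in the direction of TLS), it

* classifies lesion-site outcomes (base inserted opposite an abasic-site
  analog; codon changes at a UV-photolesion dipyrimidine, including
  co-mutations at the adjacent +1 G),
* estimates per-nucleotide mutation rates in lesion-adjacent windows,

  μ = m / (L·n)

  with *m* mutation events in a window of *L* nt across *n* sequenced
  products, background subtraction from matched lesion-free controls,
  zero-count upper bounds 1/(L·n), exact Poisson (Garwood) confidence
  intervals, and fold changes over reference rates,
* tests enrichment of in-window mutations in TLS products versus controls
  with a two-sided Fisher exact test (product = sampling unit),
* estimates the hypermutated tract boundary *b* with a two-rate Poisson
  changepoint model (rate λ_in on (0, b], λ_out beyond; profile-likelihood
  grid scan; parametric-bootstrap calibration), and
* forward-simulates TLS and control catalogs (insertion spectrum, tract-length
  distribution, in-tract rate ε_tract, background rate ε_bg) so every
  estimator can be validated by parameter recovery without external data.

The mutation catalogs of the source yeast study (plasmid-borne abasic-site
bypass and chromosomal UV-lesion bypass, with their matched controls and
polymerase/MMR-mutant datasets) ship as packaged TSV fixtures.

## Worked example

```python
from tlstracts import reproduce_published
report, mismatches = reproduce_published()
for row in report.rates:
    print(row["label"], "->", row["rendered"])
```

prints

```
THF near-lesion (0,220] -> 8.1e-05
THF msh2 bound (0,220] -> < 9.7e-05
UV near-lesion (0,1000] -> 6.7e-05
UV background (Can-r controls) -> 6.2e-06
UV rad30 (0,1000] -> 3.0e-05
UV rev3 bound (0,1000] -> < 4.3e-06
```

Reading the numbers: 7 of 394 abasic-site bypass products carry a mutation in
the 220 nt downstream of the lesion, a rate of 8.1×10⁻⁵ per nucleotide —
roughly 300,000-fold above the genome-wide spontaneous rate and within an
order of magnitude of the purified extension polymerase's error rate on
undamaged DNA, while the matched control plasmids show none there (Fisher
p = 0.0045). For the chromosomal UV lesion the downstream kilobase gives
6.7×10⁻⁵ per nucleotide after subtracting the lesion-independent background
(6.2×10⁻⁶, from canavanine-resistance controls). The rate is unchanged
without the alternative TLS polymerase (rad30, 3×10⁻⁵) and collapses to a
< 4.3×10⁻⁶ bound without the extension polymerase (rev3) — the hypermutated
tract is the extension polymerase's doing. Changepoint fits put the tract
boundary at ~341 nt (plasmid assay) and ~968 nt (chromosomal assay).

The `examples/` directory holds short narrative scripts, one per capability:
published-data reanalysis, catalog/coordinate handling, enrichment and
boundary estimation, simulation and parameter recovery. A thin CLI wraps the
same functions:

```sh
tls-tracts reproduce-paper --outdir out/
tls-tracts analyze --config config.yaml --outdir out/
tls-tracts simulate --config sim.yaml --seed 42 --outdir sim-out/
```

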