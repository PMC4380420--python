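"""Rerun the complete published-data reanalysis from the packaged catalogs.

Prints the near-lesion mutation-rate table (with background subtraction and
zero-count bounds), the Fisher enrichment tests, and the estimated tract
boundaries, then checks every number against the bundled expected values.
"""

from tlstracts import reproduce_published

report, mismatches = reproduce_published()

print("Per-nucleotide mutation rates near the lesion")
print("  (mu = m/(L*n); '<' marks a zero-count upper bound)")
for row in report.rates:
    print(f"  {row['label']:35s} m={row['m']:>2d} L={row['L']:>4d} "
          f"n={row['n']:>3d}  ->  {row['rendered']}")

print("\nEnrichment vs matched controls (two-sided Fisher exact):")
for e in report.enrichment:
    print(f"  {e['label']:25s} table={e['table']}  p={e['p_two_sided']:.4f}")

print("\nHypermutated tract boundary (two-rate Poisson changepoint):")
for c in report.changepoints:
    print(f"  {c['label']:15s} b_hat={c['b_hat']:>4d} nt  "
          f"lambda_in={c['lambda_in']:.2e}  lambda_out={c['lambda_out']:.2e}")

fold = report.provenance["fold_over_genomewide_spontaneous"]
print(f"\nNear-lesion rate exceeds the genome-wide spontaneous rate "
      f"{fold:,.0f}-fold.")
print("Expected-value check:", "all reproduced" if not mismatches else mismatches)
# The near-lesion rates (~7-8e-5 per nt after background handling) are about
# 300,000x the genome-wide rate and within an order of magnitude of the
# error rate of the purified extension polymerase on undamaged DNA --
# the signature of an error-prone polymerase copying the flanking DNA.
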