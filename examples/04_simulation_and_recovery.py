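"""Forward-simulate TLS mutagenesis and recover the generating parameters.

Simulates catalogs with a known tract length and in-tract error rate, then
reruns the full analysis to check that the rate estimator and the
changepoint boundary recover the truth.
"""

from tlstracts import (
    FixedTract,
    SimParams,
    end_to_end_recovery,
    geometry_registry,
    simulate_tls_catalog,
)

geom = geometry_registry()["THF-plasmid"]
params = SimParams(
    n_products=5000,
    geometry=geom,
    tract_dist=FixedTract(220),   # every product gets a 220-nt error-prone tract
    eps_tract=8e-5,               # per-nucleotide in-tract error rate
    eps_bg=1.4e-5,                # lesion-independent background everywhere
)

cat = simulate_tls_catalog(params, seed=42)
print(f"One simulated catalog: {cat.n_products} products, "
      f"{len(cat.mutations)} mutations "
      f"({cat.count_in_window((0, 220))} within the true tract window)")

report = end_to_end_recovery(params, n_reps=20, seed=7)
print(f"\nRecovery over {report['n_reps']} replicates "
      f"(truth: tract 220 nt, eps_tract {params.eps_tract:.1e}):")
print(f"  boundary median estimate  {report['b_hat_median']:.0f} nt")
print(f"  boundary median |error|   {report['b_hat_median_abs_error']:.0f} nt")
print(f"  net-rate mean             {report['mu_net_mean']:.2e}")
print(f"  net-rate RMSE             {report['mu_net_rmse']:.2e}")
# The boundary is recovered to within a few nucleotides at this sample
# size, and the background-subtracted window rate is close to eps_tract
# (slightly above it, because background also falls inside the window).
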