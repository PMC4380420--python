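"""Fisher enrichment, rate profiles, and the two-rate changepoint model."""

import dataclasses
from fractions import Fraction
from math import factorial

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tlstracts.catalog import Catalog, MutationRecord
from tlstracts.enrichment import (
    bootstrap_changepoint_pvalue,
    changepoint_fit,
    fisher_exact_two_sided,
    nucleotide_contingency,
    product_contingency,
    rate_profile,
    window_enrichment,
)
from tlstracts.rates import round_sig


def enumeration_oracle(table):
    """Brute-force two-sided Fisher: enumerate every table with the observed
    margins, compute each probability from the factorial formula, and sum
    those not exceeding the observed one (same 1e-7 relative slack)."""
    (a, b), (c, d) = table
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    t = r1 + r2
    if t == 0 or 0 in (r1, r2) or c1 == 0 or c1 == t:
        return Fraction(1)

    def prob(x):
        # margins fixed: P = r1! r2! c1! c2! / (t! x! (r1-x)! (c1-x)! (d')!)
        y, z, w = r1 - x, c1 - x, r2 - (c1 - x)
        if min(y, z, w) < 0:
            return None
        num = factorial(r1) * factorial(r2) * factorial(c1) * factorial(c2)
        den = (factorial(t) * factorial(x) * factorial(y) * factorial(z) * factorial(w))
        return Fraction(num, den)

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(0, min(r1, c1) + 1):
        p = prob(x)
        if p is not None and p <= p_obs * Fraction(10**7 + 1, 10**7):
            total += p
    return total


class TestContingency:
    def test_thf_product_table(self, thf, thf_ctrl):
        assert product_contingency(thf, thf_ctrl, (0, 220)) == ((7, 387), (0, 456))

    def test_uv_product_table(self, uv, uv_canr):
        assert product_contingency(uv, uv_canr, (0, 1000)) == ((12, 153), (1, 160))

    def test_empty_window(self, thf, thf_ctrl):
        # (300, 330] holds no mutations in either catalog
        assert product_contingency(thf, thf_ctrl, (300, 330)) == ((0, 394), (0, 456))

    def test_cells_sum_to_product_totals(self, thf, thf_ctrl):
        (a, b), (c, d) = product_contingency(thf, thf_ctrl, (0, 220))
        assert a + b + c + d == thf.n_products + thf_ctrl.n_products

    def test_product_with_two_in_window_mutations_counts_once(self, registry):
        geom = registry["THF-plasmid"]
        tls = Catalog(geom, 3, [], [MutationRecord("P1", 50, "A → C"),
                                    MutationRecord("P1", 90, "C → T")])
        ctrl = Catalog(geom, 3, [], [])
        assert product_contingency(tls, ctrl, (0, 220)) == ((1, 2), (0, 3))

    def test_nucleotide_mode_also_significant(self, thf, thf_ctrl):
        res = window_enrichment(thf, thf_ctrl, (0, 220), unit_mode="nucleotide")
        assert res.table[0][0] == 7 and res.table[1][0] == 0
        # nucleotide-level test agrees with the product-level result
        assert res.p_two_sided == pytest.approx(0.0045, rel=0.05)


class TestFisherExact:
    def test_published_pvalue(self, thf, thf_ctrl):
        res = window_enrichment(thf, thf_ctrl, (0, 220))
        assert round_sig(res.p_two_sided) == pytest.approx(0.0045)

    @pytest.mark.parametrize("table", [((0, 10), (0, 10)), ((0, 0), (0, 0)),
                                       ((5, 0), (3, 0))])
    def test_degenerate_margins(self, table):
        assert fisher_exact_two_sided(table) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(((1, -2), (3, 4)))

    @given(st.tuples(st.integers(0, 12), st.integers(0, 12),
                     st.integers(0, 12), st.integers(0, 12)))
    def test_symmetry_under_row_and_column_swaps(self, cells):
        a, b, c, d = cells
        p = fisher_exact_two_sided(((a, b), (c, d)))
        assert fisher_exact_two_sided(((c, d), (a, b))) == pytest.approx(p, abs=1e-14)
        assert fisher_exact_two_sided(((b, a), (d, c))) == pytest.approx(p, abs=1e-14)

    def test_matches_enumeration_oracle_small_margins(self):
        for t in range(0, 13):
            for r1 in range(0, t + 1):
                for c1 in range(0, t + 1):
                    lo, hi = max(0, c1 - (t - r1)), min(c1, r1)
                    for a in range(lo, hi + 1):
                        table = ((a, r1 - a), (c1 - a, (t - r1) - (c1 - a)))
                        assert fisher_exact_two_sided(table) == pytest.approx(
                            float(enumeration_oracle(table)), abs=1e-12
                        ), table

    def test_matches_scipy_on_published_tables(self, thf, thf_ctrl, uv, uv_canr):
        from scipy.stats import fisher_exact

        for table in (product_contingency(thf, thf_ctrl, (0, 220)),
                      product_contingency(uv, uv_canr, (0, 1000))):
            assert fisher_exact_two_sided(table) == pytest.approx(
                fisher_exact(table).pvalue, rel=1e-9
            )

    def test_swapping_catalogs_leaves_p_unchanged(self, thf, thf_ctrl):
        p1 = window_enrichment(thf, thf_ctrl, (0, 220)).p_two_sided
        p2 = window_enrichment(thf_ctrl, thf, (0, 220)).p_two_sided
        assert p1 == pytest.approx(p2, abs=1e-14)


class TestRateProfile:
    def test_first_downstream_bin(self, thf):
        prof = rate_profile(thf, 220)
        down = [(w, est) for w, est in prof if w[0] >= 0]
        assert down[0][0] == (0, 220) and down[0][1].m == 7

    def test_bin_counts_sum_to_totals(self, thf):
        prof = rate_profile(thf, 220)
        assert sum(est.m for w, est in prof if w[0] >= 0) == 18
        assert sum(est.m for w, est in prof) == 23

    def test_empty_catalog_profile(self, registry):
        prof = rate_profile(Catalog(registry["THF-plasmid"], 10), 100)
        assert all(est.m == 0 for _, est in prof)

    def test_binsize_validation(self, thf):
        with pytest.raises(ValueError):
            rate_profile(thf, 0)


def _catalog_from_positions(geom, positions, n):
    muts = [MutationRecord(f"P{i}", int(d), "A → C") for i, d in enumerate(positions)]
    return Catalog(geom, n, [], muts)


class TestChangepoint:
    def test_boundary_at_last_mutation_when_rest_empty(self, registry):
        geom = registry["THF-plasmid"]
        cat = _catalog_from_positions(geom, [30, 47, 60, 88, 100], 50)
        fit = changepoint_fit(cat)
        assert fit.b_hat == 100
        assert fit.lambda_out == 0.0
        assert fit.m_in == 5 and fit.m_out == 0

    def test_matches_bruteforce_likelihood_scan(self, registry):
        # independent oracle: direct python loop over every candidate b
        geom = registry["THF-plasmid"]
        positions = [40, 55, 90, 130, 150, 400, 900, 1500]
        n, D = 80, geom.downstream_extent
        cat = _catalog_from_positions(geom, positions, n)
        grid = sorted(set(positions) | set(range(10, D, 10)))

        def loglik(b):
            m1 = sum(p <= b for p in positions)
            m2 = len(positions) - m1
            ll = 0.0
            for m, ex in ((m1, n * b), (m2, n * (D - b))):
                ll += (m * np.log(m / ex) - m) if m else 0.0
            return ll

        best = max(grid, key=lambda b: (loglik(b), -b))
        fit = changepoint_fit(cat, grid=grid)
        assert fit.b_hat == best
        m1 = sum(p <= best for p in positions)
        single = len(positions) * np.log(len(positions) / (n * D)) - len(positions)
        assert fit.delta_loglik == pytest.approx(loglik(best) - single, rel=1e-12)
        assert fit.lambda_in == pytest.approx(m1 / (n * best))

    def test_ties_break_toward_smaller_boundary(self, registry):
        geom = registry["THF-plasmid"]
        cat = _catalog_from_positions(geom, [100], 50)
        # any b in [100, ...) with m_in=1 ties on the in-part only at b=100
        fit = changepoint_fit(cat, grid=[100, 100, 200])
        assert fit.b_hat == 100

    def test_no_downstream_mutations_errors(self, registry):
        geom = registry["THF-plasmid"]
        cat = _catalog_from_positions(geom, [-100, -50], 50)
        with pytest.raises(ValueError, match="no downstream mutations"):
            changepoint_fit(cat)

    def test_simulated_recovery_single_run(self, registry):
        from tlstracts.simulate import FixedTract, SimParams, simulate_tls_catalog

        geom = registry["THF-plasmid"]
        params = SimParams(n_products=5000, geometry=geom, tract_dist=FixedTract(220),
                           eps_tract=8e-5, eps_bg=1.4e-5)
        fit = changepoint_fit(simulate_tls_catalog(params, 20240331))
        assert 180 <= fit.b_hat <= 260
        assert fit.lambda_in > fit.lambda_out


class TestBootstrap:
    def test_strong_signal_is_significant(self, registry):
        from tlstracts.simulate import FixedTract, SimParams, simulate_tls_catalog

        geom = registry["THF-plasmid"]
        params = SimParams(n_products=5000, geometry=geom, tract_dist=FixedTract(220),
                           eps_tract=8e-5, eps_bg=1.4e-5)
        fit = changepoint_fit(simulate_tls_catalog(params, 11))
        p = bootstrap_changepoint_pvalue(fit, n_boot=199, seed=5)
        assert p <= 0.05

    def test_null_data_not_significant(self, registry):
        # background-only catalog: the two-rate model should not beat the null
        from tlstracts.simulate import SimParams, simulate_control_catalog

        geom = registry["THF-plasmid"]
        params = SimParams(n_products=3000, geometry=geom, eps_bg=2e-5)
        cat = simulate_control_catalog(params, 99)
        fit = changepoint_fit(cat)
        p = bootstrap_changepoint_pvalue(fit, n_boot=199, seed=6)
        assert p > 0.05

    def test_p_monotone_in_observed_statistic(self, registry):
        from tlstracts.simulate import SimParams, simulate_control_catalog

        geom = registry["THF-plasmid"]
        cat = simulate_control_catalog(SimParams(n_products=2000, geometry=geom), 3)
        fit = changepoint_fit(cat)
        ps = [bootstrap_changepoint_pvalue(dataclasses.replace(fit, delta_loglik=d),
                                           n_boot=199, seed=42)
              for d in (0.0, 2.0, 8.0)]
        assert ps[0] >= ps[1] >= ps[2]

    def test_small_n_boot_warns(self, registry):
        geom = registry["THF-plasmid"]
        cat = _catalog_from_positions(geom, [50, 60], 50)
        fit = changepoint_fit(cat)
        with pytest.warns(UserWarning, match="n_boot"):
            bootstrap_changepoint_pvalue(fit, n_boot=20, seed=1)

    def test_reproducible_given_seed(self, registry):
        geom = registry["THF-plasmid"]
        cat = _catalog_from_positions(geom, [50, 60, 300, 700], 50)
        fit = changepoint_fit(cat)
        p1 = bootstrap_changepoint_pvalue(fit, n_boot=150, seed=8)
        p2 = bootstrap_changepoint_pvalue(fit, n_boot=150, seed=8)
        assert p1 == p2
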