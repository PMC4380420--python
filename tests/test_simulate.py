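"""Forward simulator: determinism, placement invariants, rate calibration."""

from collections import Counter

import numpy as np
import pytest

from tlstracts.catalog import catalog_to_tsv
from tlstracts.simulate import (
    FixedTract,
    GeometricTract,
    SimParams,
    UniformTract,
    end_to_end_recovery,
    simulate_control_catalog,
    simulate_tls_catalog,
)


@pytest.fixture
def thf_geom(registry):
    return registry["THF-plasmid"]


class TestDeterminism:
    def test_same_seed_byte_identical(self, thf_geom):
        params = SimParams(n_products=200, geometry=thf_geom, eps_tract=5e-4)
        a = catalog_to_tsv(simulate_tls_catalog(params, 77))
        b = catalog_to_tsv(simulate_tls_catalog(params, 77))
        assert a == b

    def test_different_seed_differs(self, thf_geom):
        params = SimParams(n_products=500, geometry=thf_geom, eps_tract=5e-4)
        a = simulate_tls_catalog(params, 1)
        b = simulate_tls_catalog(params, 2)
        assert catalog_to_tsv(a) != catalog_to_tsv(b)
        # same summary statistics within sampling error
        assert abs(len(a.mutations) - len(b.mutations)) < 6 * np.sqrt(
            max(len(a.mutations), 1)
        )


class TestPlacement:
    def test_zero_rates_give_events_only(self, thf_geom):
        params = SimParams(n_products=100, geometry=thf_geom, eps_tract=0, eps_bg=0)
        cat = simulate_tls_catalog(params, 5)
        assert len(cat.events) == 100 and cat.mutations == []

    def test_control_zero_background_empty(self, thf_geom):
        params = SimParams(n_products=100, geometry=thf_geom, eps_bg=0)
        assert simulate_control_catalog(params, 5).mutations == []

    def test_no_mutation_in_excluded_or_out_of_extent(self, thf_geom):
        params = SimParams(n_products=400, geometry=thf_geom,
                           eps_tract=5e-3, eps_bg=5e-4)
        for seed in (0, 1, 2):
            cat = simulate_tls_catalog(params, seed)
            assert cat.mutations  # rates high enough to actually exercise this
            for m in cat.mutations:
                assert thf_geom.contains(m.d) and m.d != 0
                assert not thf_geom.is_excluded(m.d)

    def test_in_window_count_near_expectation(self, thf_geom):
        # n*T*eps = 394*220*8.1e-5 ~ 7 expected in-tract mutations
        params = SimParams(n_products=394, geometry=thf_geom,
                           tract_dist=FixedTract(220), eps_tract=8.1e-5, eps_bg=0)
        cat = simulate_tls_catalog(params, 123)
        m = cat.count_in_window((0, 220))
        assert abs(m - 7) <= 3 * np.sqrt(7)

    def test_control_total_near_expectation(self, thf_geom):
        # 456 products x ~2250 allowed nt x 1.4e-5 ~ 14 background mutations;
        # over the 1726-nt downstream+oligo-free region the published 11
        params = SimParams(n_products=456, geometry=thf_geom, eps_bg=1.4e-5)
        cat = simulate_control_catalog(params, 321)
        expected = 456 * (550 + 1700 - 46) * 1.4e-5
        assert abs(len(cat.mutations) - expected) <= 3 * np.sqrt(expected)

    def test_insertion_spectrum_recovery(self, thf_geom):
        params = SimParams(n_products=10_000, geometry=thf_geom, eps_bg=0, eps_tract=0)
        cat = simulate_tls_catalog(params, 9)
        counts = Counter(e.outcome for e in cat.events)
        for base, p in params.insertion_spectrum.items():
            se = np.sqrt(p * (1 - p) * 10_000)
            assert abs(counts[base] - p * 10_000) <= 3 * se

    def test_restoring_outcomes_dropped(self, thf_geom):
        params = SimParams(n_products=2000, geometry=thf_geom, p_restoring=0.3,
                           eps_tract=0, eps_bg=0)
        cat = simulate_tls_catalog(params, 13)
        dropped = 2000 - cat.n_products
        assert abs(dropped - 600) <= 3 * np.sqrt(2000 * 0.3 * 0.7)
        assert all(e.outcome in "ACT" for e in cat.events)

    def test_tract_rate_convergence(self, thf_geom):
        # exposure ~ 2000 products x 1674 allowed in-tract nt = 3.3e6;
        # the empirical in-tract rate should track eps_tract closely
        eps = 5.6e-4
        params = SimParams(n_products=2000, geometry=thf_geom,
                           tract_dist=FixedTract(1700), eps_tract=eps, eps_bg=0)
        cat = simulate_tls_catalog(params, 17)
        allowed = 1700 - 26  # oligonucleotide footprint masked
        rate = len(cat.mutations) / (2000 * allowed)
        assert rate == pytest.approx(eps, rel=0.1)


class TestTractDistributions:
    def test_fixed_exceeding_extent_rejected(self, thf_geom):
        params = SimParams(n_products=10, geometry=thf_geom,
                           tract_dist=FixedTract(5000))
        with pytest.raises(ValueError, match="exceeds"):
            simulate_tls_catalog(params, 0)

    def test_geometric_clipped_at_extent(self, thf_geom):
        rng = np.random.default_rng(0)
        draws = GeometricTract(300).sample(rng, 5000, thf_geom.downstream_extent)
        assert draws.max() <= thf_geom.downstream_extent
        assert abs(draws.mean() - 300) < 30  # clipping barely bites at 1700

    def test_uniform_bounds(self, thf_geom):
        rng = np.random.default_rng(0)
        draws = UniformTract(200, 1000).sample(rng, 2000, 1700)
        assert draws.min() >= 200 and draws.max() <= 1000


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [{"eps_tract": 1.5}, {"eps_bg": -0.1}, {"p_restoring": 2.0},
         {"insertion_spectrum": {"A": 0.5, "C": 0.2}}, {"n_products": 0}],
    )
    def test_invalid_params_rejected_before_sampling(self, thf_geom, kwargs):
        base = dict(n_products=10, geometry=thf_geom)
        base.update(kwargs)
        with pytest.raises(ValueError):
            simulate_tls_catalog(SimParams(**base), 0)


class TestEndToEndRecovery:
    def test_rate_estimator_nearly_unbiased(self, thf_geom):
        params = SimParams(n_products=3000, geometry=thf_geom,
                           tract_dist=FixedTract(220), eps_tract=4e-4, eps_bg=0)
        rep = end_to_end_recovery(params, window=(26, 220), n_reps=8, seed=4,
                                  fit_changepoint=False)
        # window avoids the masked oligo footprint, so exposure is exact
        assert rep["mu_net_mean"] / 4e-4 == pytest.approx(1.0, abs=0.1)

    def test_background_only_net_rate_near_zero(self, thf_geom):
        params = SimParams(n_products=2000, geometry=thf_geom,
                           eps_tract=0.0, eps_bg=1.4e-5)
        rep = end_to_end_recovery(params, window=(0, 220), n_reps=8, seed=10,
                                  fit_changepoint=False)
        assert rep["mu_net_median"] <= 1e-5

    def test_boundary_recovery_summary(self, thf_geom):
        params = SimParams(n_products=4000, geometry=thf_geom,
                           tract_dist=FixedTract(220), eps_tract=8e-5, eps_bg=1.4e-5)
        rep = end_to_end_recovery(params, n_reps=10, seed=1)
        assert rep["n_changepoint_fits"] == 10
        assert rep["b_hat_median_abs_error"] <= 40
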