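"""Forward simulation of TLS-product and control mutation catalogs.

Generative model, per product: (1) a lesion-site outcome is drawn from the
insertion spectrum (optionally including the sequence-restoring outcome,
which the assay cannot see and which is then dropped); (2) a tract length T
is drawn from the configured distribution; (3) every non-excluded
nucleotide in (0, T] mutates independently with probability eps_tract (the
in-tract, error-prone-polymerase rate); (4) every non-excluded nucleotide
of the whole sequenced region mutates independently with probability
eps_bg (the lesion-independent background, e.g. spontaneous damage of
ssDNA during substrate construction).  Control products run step (4) only.

Mismatch repair is modeled as absent from TLS tracts by default (each
in-tract error survives); a correction-efficiency knob exists for
sensitivity analyses.  Change descriptors are drawn from configurable
spectra — there is no underlying nucleotide sequence, only positions and
descriptor labels, which is all the downstream analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from typing import Mapping

import numpy as np

from .catalog import AssayGeometry, Catalog, MutationRecord, TLSEvent
from .enrichment import changepoint_fit
from .rates import mutation_rate, net_rate

__all__ = [
    "TractDistribution",
    "FixedTract",
    "GeometricTract",
    "UniformTract",
    "SimParams",
    "simulate_tls_catalog",
    "simulate_control_catalog",
    "end_to_end_recovery",
]

# Empirical defaults.  The in-tract spectrum reflects the transversion-rich,
# C->T-poor pattern seen close to an abasic lesion; the background spectrum
# is C->T- and single-base-deletion-biased, as expected from spontaneous
# deamination-type damage of single-stranded DNA.
DEFAULT_INSERTION_SPECTRUM: Mapping[str, float] = {"A": 0.62, "C": 0.20, "T": 0.18}
DEFAULT_TRACT_SPECTRUM: Mapping[str, float] = {
    "A → C": 3 / 7,
    "T → A": 1 / 7,
    "G → T": 1 / 7,
    "C → T": 1 / 7,
    "GAT del": 1 / 7,
}
DEFAULT_BG_SPECTRUM: Mapping[str, float] = {
    "C → T": 6 / 17,
    "A del": 2 / 17,
    "T del": 2 / 17,
    "G del": 1 / 17,
    "C ins": 1 / 17,
    "A → G": 1 / 17,
    "T → C": 1 / 17,
    "C → G": 1 / 17,
    "G → T": 1 / 17,
    "A → C": 1 / 17,
}


class TractDistribution:
    """Distribution of error-prone tract lengths (nt downstream)."""

    def sample(self, rng: np.random.Generator, size: int, d_max: int) -> np.ndarray:
        raise NotImplementedError

    def mean(self) -> float:
        raise NotImplementedError


@dataclass(frozen=True)
class FixedTract(TractDistribution):
    length: int

    def sample(self, rng, size, d_max):
        if self.length > d_max:
            raise ValueError(f"tract length {self.length} exceeds downstream extent {d_max}")
        return np.full(size, self.length, dtype=int)

    def mean(self):
        return float(self.length)


@dataclass(frozen=True)
class GeometricTract(TractDistribution):
    """Geometric tract length (memoryless disengagement), clipped at the extent."""

    mean_length: float

    def sample(self, rng, size, d_max):
        if self.mean_length <= 0:
            raise ValueError("mean tract length must be positive")
        return np.minimum(rng.geometric(1.0 / self.mean_length, size=size), d_max)

    def mean(self):
        return self.mean_length


@dataclass(frozen=True)
class UniformTract(TractDistribution):
    low: int
    high: int

    def sample(self, rng, size, d_max):
        if not 0 < self.low <= self.high <= d_max:
            raise ValueError("need 0 < low <= high <= downstream extent")
        return rng.integers(self.low, self.high + 1, size=size)

    def mean(self):
        return (self.low + self.high) / 2


@dataclass
class SimParams:
    """Parameters of the forward TLS-mutagenesis simulator.

    eps_tract defaults to the in-vitro error rate of the extension
    polymerase on undamaged DNA (5.6e-4 per nucleotide); eps_bg defaults to
    the background rate implied by control-plasmid sequencing (11 mutations
    over 456 products x 1726 nt ~= 1.4e-5 per nucleotide).  p_restoring is
    the probability of the sequence-restoring lesion-site outcome, which is
    invisible to the assay: such products are simulated, then dropped.
    """

    n_products: int
    geometry: AssayGeometry
    insertion_spectrum: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INSERTION_SPECTRUM))
    p_restoring: float = 0.0
    tract_dist: TractDistribution = field(default_factory=lambda: FixedTract(220))
    eps_tract: float = 5.6e-4
    tract_spectrum: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRACT_SPECTRUM))
    eps_bg: float = 1.4e-5
    bg_spectrum: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BG_SPECTRUM))
    mmr_correction: float = 0.0
    control_allele: str = "control"

    def validate(self) -> None:
        if self.n_products <= 0:
            raise ValueError("n_products must be positive")
        for name in ("insertion_spectrum", "tract_spectrum", "bg_spectrum"):
            spec = getattr(self, name)
            if not spec:
                raise ValueError(f"{name} is empty")
            probs = np.array(list(spec.values()), dtype=float)
            if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability vector summing to 1")
        for name in ("eps_tract", "eps_bg", "p_restoring", "mmr_correction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _allowed_positions(geom: AssayGeometry, lo: int, hi: int) -> np.ndarray:
    """Non-excluded integer positions in [lo, hi], excluding 0."""
    pos = np.arange(lo, hi + 1, dtype=int)
    mask = pos != 0
    for a, b in geom.excluded_intervals:
        mask &= (pos < a) | (pos > b)
    return pos[mask]


def _draw_from_spectrum(rng, spectrum: Mapping[str, float], size: int) -> list[str]:
    labels = list(spectrum.keys())
    probs = np.array([spectrum[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(labels), size=size, p=probs)
    return [labels[i] for i in idx]


def _place_mutations(rng, allowed_counts, allowed_sets, eps) -> list[np.ndarray]:
    """Per-product site-wise Bernoulli placement via binomial counts.

    Drawing Binomial(n_allowed, eps) sites and then that many distinct
    positions is exactly per-nucleotide Bernoulli placement; exclusion
    zones are handled by masking the allowed-position sets.
    """
    counts = rng.binomial(allowed_counts, eps)
    out = []
    for i, k in enumerate(counts):
        if k == 0:
            out.append(np.empty(0, dtype=int))
        else:
            out.append(rng.choice(allowed_sets[i], size=k, replace=False))
    return out


def simulate_tls_catalog(params: SimParams, seed: int) -> Catalog:
    """Simulate a catalog of TLS products; reproducible given (params, seed)."""
    params.validate()
    geom = params.geometry
    rng = np.random.default_rng(seed)

    # lesion-site outcomes, including invisible sequence-restoring ones
    outcomes = np.array(_draw_from_spectrum(rng, params.insertion_spectrum,
                                            params.n_products), dtype=object)
    if params.p_restoring > 0:
        restoring = rng.random(params.n_products) < params.p_restoring
        outcomes[restoring] = None

    tracts = params.tract_dist.sample(rng, params.n_products, geom.downstream_extent)

    allowed_down = _allowed_positions(geom, 1, geom.downstream_extent)
    allowed_all = _allowed_positions(geom, -geom.upstream_extent, geom.downstream_extent)
    # number of allowed in-tract sites for each product's tract length
    n_in_tract = np.searchsorted(allowed_down, tracts, side="right")
    in_tract_sets = [allowed_down[:c] for c in n_in_tract]

    tract_hits = _place_mutations(rng, n_in_tract, in_tract_sets, params.eps_tract)
    bg_hits = _place_mutations(
        rng, np.full(params.n_products, len(allowed_all)),
        [allowed_all] * params.n_products, params.eps_bg,
    )

    events: list[TLSEvent] = []
    mutations: list[MutationRecord] = []
    kept = 0
    for i in range(params.n_products):
        th, bh = tract_hits[i], bg_hits[i]
        if params.mmr_correction > 0 and len(th):
            th = th[rng.random(len(th)) >= params.mmr_correction]
        changes = (_draw_from_spectrum(rng, params.tract_spectrum, len(th))
                   + _draw_from_spectrum(rng, params.bg_spectrum, len(bh)))
        if outcomes[i] is None:
            continue  # sequence-restoring outcome: product invisible to the assay
        kept += 1
        pid = f"SIM-{kept:05d}"
        events.append(TLSEvent(pid, str(outcomes[i])))
        seen = set()  # a site hit by both processes mutates once

        for p, ch in zip(np.concatenate([th, bh]), changes):
            if int(p) in seen:
                continue
            seen.add(int(p))
            mutations.append(MutationRecord(pid, int(p), ch, "simulated"))

    return Catalog(geometry=geom, n_products=kept, events=events, mutations=mutations)


def simulate_control_catalog(params: SimParams, seed: int) -> Catalog:
    """Simulate background-only control products (no lesion, no tract)."""
    params.validate()
    geom = params.geometry
    rng = np.random.default_rng(seed)
    allowed_all = _allowed_positions(geom, -geom.upstream_extent, geom.downstream_extent)
    bg_hits = _place_mutations(
        rng, np.full(params.n_products, len(allowed_all)),
        [allowed_all] * params.n_products, params.eps_bg,
    )
    mutations: list[MutationRecord] = []
    for i in range(params.n_products):
        pid = f"CTL-{i + 1:05d}"
        for p, ch in zip(bg_hits[i], _draw_from_spectrum(rng, params.bg_spectrum,
                                                         len(bg_hits[i]))):
            mutations.append(MutationRecord(pid, int(p), ch, "simulated"))
    return Catalog(geometry=geom, n_products=params.n_products, events=[],
                   mutations=mutations)


def end_to_end_recovery(
    params: SimParams,
    window: tuple[int, int] | None = None,
    n_reps: int = 50,
    seed: int = 0,
    n_control: int | None = None,
    fit_changepoint: bool = True,
) -> dict:
    """Simulate-and-reanalyze study: bias/RMSE of the net rate and boundary.

    Per replicate: simulate a TLS and a control catalog, estimate the
    in-window rate with control-derived background subtracted, and (when
    the replicate has downstream mutations) the tract boundary.  Truth is
    taken from params (eps_tract; mean tract length).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    params.validate()
    geom = params.geometry
    true_b = params.tract_dist.mean()
    if window is None:
        window = (0, int(round(true_b)))
    L = window[1] - window[0]
    n_control = n_control or params.n_products

    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * n_reps)
    mu_nets, b_hats = [], []
    for r in range(n_reps):
        tls = simulate_tls_catalog(params, int(seeds[2 * r]))
        ctrl_params = _dc_replace(params, n_products=n_control)
        ctrl = simulate_control_catalog(ctrl_params, int(seeds[2 * r + 1]))
        m = tls.count_in_window(window)
        est = mutation_rate(m, L, tls.n_products)
        full_region = geom.upstream_extent + geom.downstream_extent
        bg = mutation_rate(len(ctrl.mutations), full_region, ctrl.n_products)
        mu_nets.append(float(net_rate(est, bg.mu).mu_net))
        if fit_changepoint:
            try:
                b_hats.append(changepoint_fit(tls).b_hat)
            except ValueError:
                pass
    mu_nets = np.array(mu_nets)
    report = {
        "n_reps": n_reps,
        "true_eps_tract": params.eps_tract,
        "true_tract_mean": true_b,
        "window": window,
        "mu_net_mean": float(mu_nets.mean()),
        "mu_net_median": float(np.median(mu_nets)),
        "mu_net_bias": float(mu_nets.mean() - params.eps_tract),
        "mu_net_rmse": float(np.sqrt(((mu_nets - params.eps_tract) ** 2).mean())),
    }
    if fit_changepoint and b_hats:
        errs = np.abs(np.array(b_hats) - true_b)
        report.update({
            "n_changepoint_fits": len(b_hats),
            "b_hat_median": float(np.median(b_hats)),
            "b_hat_median_abs_error": float(np.median(errs)),
            "b_hat_rmse": float(np.sqrt(((np.array(b_hats) - true_b) ** 2).mean())),
        })
    return report
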