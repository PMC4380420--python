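"""Per-nucleotide mutation-rate estimation with background subtraction.

The estimator is the exposure-normalized count μ = m / (L·n): m mutation
events observed over a window of L nucleotides sequenced in each of n
independent TLS products.  Division is kept as an exact rational so that
μ·L·n == m holds identically; rounding to the 2 significant figures used
in reports happens only at presentation time.

A lesion-independent background rate (estimated from matched control
products) can be subtracted; when zero mutations are observed, the rate is
summarized by the upper bound 1/(L·n) — "fewer than one mutation over the
exposure".  Exact Poisson (Garwood) confidence intervals are available for
any count.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from math import floor, log10

from scipy.stats import chi2

__all__ = [
    "RateEstimate",
    "ReferenceRates",
    "mutation_rate",
    "net_rate",
    "zero_count_bound",
    "fold_change",
    "exact_count_ci",
    "round_sig",
    "format_rate",
]

RateLike = Fraction | float | int


@dataclass(frozen=True)
class RateEstimate:
    """A per-nucleotide mutation rate μ = m/(L·n) and its provenance.

    mu and mu_bg are exact rationals; ``mu_net = max(mu - mu_bg, 0)`` with
    ``clamped`` set when the subtraction went negative (the background is
    itself an estimate, so a small negative difference is noise, not an
    error).
    """

    m: int
    L: int
    n: int
    mu: Fraction
    mu_bg: Fraction = Fraction(0)
    ci: tuple[float, float] | None = None
    clamped: bool = False

    @property
    def exposure(self) -> int:
        return self.L * self.n

    @property
    def mu_net(self) -> Fraction:
        return max(self.mu - self.mu_bg, Fraction(0))

    def __float__(self) -> float:
        return float(self.mu)


@dataclass(frozen=True)
class ReferenceRates:
    """Published per-nucleotide reference rates used for fold comparisons.

    genomewide_spontaneous: spontaneous genome-wide rate in yeast;
    genomewide_uv: genome-wide rate in cells undergoing UV mutagenesis;
    polzeta_invitro: error rate of purified Pol zeta copying undamaged DNA.
    """

    genomewide_spontaneous: float = 2.2e-10
    genomewide_uv: float = 0.4e-5
    polzeta_invitro: float = 5.6e-4

    def __post_init__(self):
        for name in ("genomewide_spontaneous", "genomewide_uv", "polzeta_invitro"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def mutation_rate(m: int, L: int, n: int, ci_level: float | None = None) -> RateEstimate:
    """Point estimate μ = m/(L·n), optionally with an exact Poisson CI."""
    if L <= 0 or n <= 0:
        raise ValueError(f"L and n must be positive (got L={L}, n={n})")
    if m < 0:
        raise ValueError("m must be nonnegative")
    mu = Fraction(m, L * n)
    ci = exact_count_ci(m, L * n, ci_level) if ci_level is not None else None
    return RateEstimate(m=m, L=L, n=n, mu=mu, ci=ci)


def net_rate(estimate: RateEstimate, mu_bg: RateLike) -> RateEstimate:
    """Subtract a background rate; negative differences clamp to zero."""
    bg = Fraction(mu_bg)
    if bg < 0:
        raise ValueError("background rate must be nonnegative")
    return replace(estimate, mu_bg=bg, clamped=estimate.mu < bg)


def zero_count_bound(L: int, n: int) -> Fraction:
    """Upper rate bound 1/(L·n) when no mutations are observed."""
    if L <= 0 or n <= 0:
        raise ValueError(f"L and n must be positive (got L={L}, n={n})")
    return Fraction(1, L * n)


def fold_change(mu: RateLike, mu_ref: RateLike) -> float:
    """Plain ratio of a rate to a reference rate."""
    if float(mu_ref) == 0.0:
        raise ValueError("reference rate must be nonzero")
    return float(mu) / float(mu_ref)


def exact_count_ci(m: int, exposure: RateLike, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) Poisson interval on the rate, from count m over exposure.

    Lower bound is 0 when m = 0; bounds are chi-square quantiles
    chi2(level tail, 2m)/2 and chi2(upper tail, 2m+2)/2 scaled by exposure.
    """
    if float(exposure) <= 0:
        raise ValueError("exposure must be positive")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if m < 0:
        raise ValueError("m must be nonnegative")
    alpha = 1.0 - level
    lo = 0.0 if m == 0 else chi2.ppf(alpha / 2, 2 * m) / 2
    hi = chi2.ppf(1 - alpha / 2, 2 * m + 2) / 2
    ex = float(exposure)
    return (lo / ex, hi / ex)


def round_sig(x: RateLike, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    x = float(x)
    if x == 0.0:
        return 0.0
    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def format_rate(mu: RateLike, sig: int = 2, bound: bool = False) -> str:
    """Render a rate like ``8.1e-05``, with a ``<`` prefix for bounds."""
    value = round_sig(mu, sig)
    prefix = "< " if bound else ""
    return f"{prefix}{value:.{sig - 1}e}"
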