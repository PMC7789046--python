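"""Indicator-to-disease-severity risk modelling with an empirical copula.

Pairs of (agro-climate indicator value, observed disease severity %) — e.g.
wet-day counts between heading and maturity against Septoria-complex
severity — are rank-transformed to pseudo-observations on the unit square
and their dependence is captured by a kernel estimate of the copula
density.  The estimator is the probit-transformation Gaussian KDE: fit a
Gaussian KDE to (Φ⁻¹(u), Φ⁻¹(v)) and back-transform, which keeps the
density consistent at the square's boundaries.  From the fitted copula,
conditional exceedance curves P(severity > s₀ | indicator = x) and the
smallest indicator value at which that probability crosses a chosen level
(a risk threshold usable in decision rules) are derived.

Because the copula is built on ranks, any strictly monotone transform of
either margin leaves the model unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ImpactObservation",
    "CopulaModel",
    "pseudo_observations",
    "fit_copula_density",
    "conditional_exceedance",
    "risk_threshold",
    "NO_THRESHOLD",
    "generate_switchpoint_pairs",
]

#: sentinel returned when the exceedance curve never crosses the target level
NO_THRESHOLD = None

_EPS = 1e-9


@dataclass(frozen=True)
class ImpactObservation:
    """One (indicator value, disease severity %) observation."""

    indicator_value: float
    severity: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 100.0:
            raise ValueError("severity must lie in [0, 100] %")


def _as_xy(pairs: Sequence[ImpactObservation] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(pairs) and isinstance(pairs[0], ImpactObservation):
        x = np.array([p.indicator_value for p in pairs], dtype=float)
        y = np.array([p.severity for p in pairs], dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    return x, y


def pseudo_observations(pairs: Sequence[ImpactObservation] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rank-transform both margins to (0, 1): u_i = rank(x_i)/(n+1).

    Ties receive average ranks.  Requires at least two pairs.
    """
    x, y = _as_xy(pairs)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs for pseudo-observations")
    u = stats.rankdata(x, method="average") / (n + 1.0)
    v = stats.rankdata(y, method="average") / (n + 1.0)
    return u, v


class _ProbitKDE:
    """Product-Gaussian KDE in probit space with per-dimension Silverman
    bandwidths.

    A diagonal bandwidth matrix (h_j = sigma_j * n^(-1/6) for two dimensions)
    stays well defined even when the two margins are perfectly rank-correlated,
    where a full-covariance bandwidth would be singular.
    """

    def __init__(self, zu: np.ndarray, zv: np.ndarray, bw_scale: float = 1.0):
        self.zu, self.zv = zu, zv
        n = zu.size
        factor = bw_scale * n ** (-1.0 / 6.0)  # Silverman rate, d = 2
        self.hu = max(float(np.std(zu, ddof=1)) * factor, 1e-3)
        self.hv = max(float(np.std(zv, ddof=1)) * factor, 1e-3)

    def __call__(self, zu_q: np.ndarray, zv_q: np.ndarray) -> np.ndarray:
        du = (zu_q[..., None] - self.zu) / self.hu
        dv = (zv_q[..., None] - self.zv) / self.hv
        k = np.exp(-0.5 * (du**2 + dv**2))
        norm = 2.0 * np.pi * self.hu * self.hv * self.zu.size
        return k.sum(axis=-1) / norm


@dataclass
class CopulaModel:
    """Kernel copula density plus the empirical margins needed to map data
    values onto the unit square."""

    u: np.ndarray
    v: np.ndarray
    x_sorted: np.ndarray  # sorted indicator observations (empirical margin)
    y_sorted: np.ndarray  # sorted severity observations
    kde: _ProbitKDE

    @property
    def n(self) -> int:
        return int(self.u.size)

    def density(self, u, v) -> np.ndarray:
        """Copula density c(u, v) on the open unit square (vectorized)."""
        u = np.clip(np.asarray(u, dtype=float), _EPS, 1 - _EPS)
        v = np.clip(np.asarray(v, dtype=float), _EPS, 1 - _EPS)
        zu, zv = stats.norm.ppf(u), stats.norm.ppf(v)
        f = self.kde(np.atleast_1d(zu), np.atleast_1d(zv)).reshape(np.shape(zu))
        jac = stats.norm.pdf(zu) * stats.norm.pdf(zv)
        return f / jac

    def margin_u(self, x: float) -> float:
        """Empirical CDF position of an indicator value: tie-averaged Weibull
        plotting positions, interpolated between distinct observations, 0/1
        strictly outside the observed range."""
        return _empirical_u(self.x_sorted, x)

    def margin_v(self, y: float) -> float:
        return _empirical_u(self.y_sorted, y)


def _empirical_u(sorted_vals: np.ndarray, x: float) -> float:
    n = sorted_vals.size
    uniq, first = np.unique(sorted_vals, return_index=True)
    counts = np.diff(np.append(first, n))
    # average rank of each distinct value -> Weibull position
    positions = (first + 0.5 * (counts + 1)) / (n + 1.0)
    return float(np.interp(x, uniq, positions, left=0.0, right=1.0))


def fit_copula_density(
    pairs: Sequence[ImpactObservation] | np.ndarray,
    bw_scale: float = 1.0,
) -> CopulaModel:
    """Fit the probit-transformation Gaussian kernel copula density.

    Requires at least 5 pairs and non-degenerate margins (an all-tied margin
    carries no rank information).  ``bw_scale`` multiplies the Silverman
    bandwidths (values below 1 sharpen the estimate).
    """
    x, y = _as_xy(pairs)
    if x.size < 5:
        raise ValueError("need at least 5 pairs to fit the copula density")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("degenerate margin: all values tied")
    u, v = pseudo_observations(np.column_stack([x, y]))
    zu, zv = stats.norm.ppf(u), stats.norm.ppf(v)
    kde = _ProbitKDE(zu, zv, bw_scale=bw_scale)
    return CopulaModel(
        u=u, v=v, x_sorted=np.sort(x), y_sorted=np.sort(y), kde=kde
    )


def copula_integral(model: CopulaModel, n_grid: int = 80) -> float:
    """Numeric integral of the copula density over the unit square
    (midpoint quadrature); should be 1 within a couple of percent."""
    g = (np.arange(n_grid) + 0.5) / n_grid
    uu, vv = np.meshgrid(g, g)
    c = model.density(uu, vv)
    return float(c.mean())


def conditional_exceedance(
    model: CopulaModel,
    indicator_value: float,
    severity_threshold: float,
    n_grid: int = 200,
) -> float:
    """P(severity > threshold | indicator = value) from the fitted copula.

    The conditioning value and the severity threshold are mapped to the unit
    square through the empirical margins; the conditional density
    c(u0, ·) is integrated above the threshold and normalized.  Conditioning
    values outside the observed indicator range trigger an extrapolation
    warning (the empirical margin saturates there).
    """
    if not model.x_sorted[0] <= indicator_value <= model.x_sorted[-1]:
        warnings.warn(
            f"indicator value {indicator_value:g} outside observed range "
            f"[{model.x_sorted[0]:g}, {model.x_sorted[-1]:g}]; "
            "conditional probability is an extrapolation",
            stacklevel=2,
        )
    u0 = model.margin_u(indicator_value)
    v0 = model.margin_v(severity_threshold)
    grid = (np.arange(n_grid) + 0.5) / n_grid
    dens = model.density(np.full(n_grid, u0), grid)
    total = float(dens.sum())
    if total <= 0:
        return float("nan")
    above = float(dens[grid > v0].sum())
    return above / total


def risk_threshold(
    model: CopulaModel,
    severity_threshold: float,
    prob_level: float,
    scan: str = "observed",
    n_scan: int = 201,
) -> float | None:
    """Smallest indicator value at which the conditional probability of
    exceeding ``severity_threshold`` reaches ``prob_level``.

    By default the distinct observed indicator values are scanned: the
    indicators feeding this model are day counts, and operational decision
    thresholds are stated in whole days ("high risk above k wet days").
    ``scan="linear"`` scans a regular grid over the observed range instead.
    Returns the sentinel ``NO_THRESHOLD`` (None) when the curve never crosses
    the level; ``prob_level = 0`` trivially returns the smallest observed
    value.
    """
    if not 0.0 <= prob_level <= 1.0:
        raise ValueError("prob_level must lie in [0, 1]")
    lo, hi = float(model.x_sorted[0]), float(model.x_sorted[-1])
    if prob_level == 0.0:
        return lo
    if scan == "observed":
        grid = np.unique(model.x_sorted)
    elif scan == "linear":
        grid = np.linspace(lo, hi, n_scan)
    else:
        raise ValueError("scan must be 'observed' or 'linear'")
    for x in grid:
        if conditional_exceedance(model, float(x), severity_threshold) >= prob_level:
            return float(x)
    return NO_THRESHOLD


def generate_switchpoint_pairs(
    n: int = 80,
    switch_point: float = 5.0,
    indicator_max: int = 10,
    low_severity: float = 8.0,
    high_severity: float = 60.0,
    noise_sd: float = 6.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic impact data with a built-in dependence switch-point.

    Severity is low (around ``low_severity`` %) while the indicator (e.g.
    wet-day count) stays below ``switch_point`` and jumps to around
    ``high_severity`` % above it — the qualitative structure of
    Septoria-complex severity against wet-day counts, with the switch sitting
    mid-range of the observed counts.  Used to test whether
    :func:`risk_threshold` recovers the generative switch-point.
    """
    rng = np.random.default_rng(seed)
    x = rng.integers(0, indicator_max + 1, size=n).astype(float)
    base = np.where(x < switch_point, low_severity, high_severity)
    y = np.clip(base + rng.normal(0.0, noise_sd, size=n), 0.0, 100.0)
    return np.column_stack([x, y])
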