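"""Generalized exponential distribution (GED) and lower k-record marginals.

The GED has CDF ``G(w) = (1 - exp(-lambda w))**theta`` with shape ``theta > 0``
and rate ``lambda > 0``.  It is a flexible lifetime model: the hazard rate is
decreasing for ``theta < 1``, constant (exponential) at ``theta = 1`` and
increasing for ``theta > 1``.

For a continuous base CDF ``G``, the i-th lower k-record value ``W`` of an iid
stream satisfies the classical reduction

    U = -k * log G(W)  ~  Gamma(i, 1),

so every record-value probability in this package is computed through gamma
distribution functions of ``U``.  In particular the i-th lower k-record has

    pdf   f_(i)(w) = k^i / (i-1)! * (-log G)^{i-1} * G^{k-1} * g(w)
    CDF   P(W <= w) = G^k * sum_{v<i} (-k log G)^v / v!      (finite sum)
    SF    P(W >  w) = 1 - CDF                                 (infinite series)

Note the finite Poisson sum is the *CDF* of a lower record (records decrease,
so small ``w`` is the upper tail of ``U``); the complementary infinite series
is the SF.  Both are exposed here and the likelihood module fixes which one
enters each censoring block via a normalization test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GEDParams",
    "RecordSpec",
    "ged_pdf",
    "ged_cdf",
    "ged_quantile",
    "ged_hazard",
    "ged_rand",
    "neglog_ged_cdf",
    "krecord_pdf",
    "krecord_cdf",
    "krecord_sf",
]


@dataclass(frozen=True)
class GEDParams:
    """Shape ``theta`` (dimensionless) and rate ``lambda_`` (per unit time)."""

    theta: float
    lambda_: float

    def __post_init__(self) -> None:
        if not (self.theta > 0):
            raise ValueError(f"theta must be positive, got {self.theta}")
        if not (self.lambda_ > 0):
            raise ValueError(f"lambda_ must be positive, got {self.lambda_}")


@dataclass(frozen=True)
class RecordSpec:
    """Record index ``i`` (which record) and record level ``k``."""

    i: int
    k: int

    def __post_init__(self) -> None:
        if int(self.i) != self.i or self.i < 1:
            raise ValueError(f"record index i must be an integer >= 1, got {self.i}")
        if int(self.k) != self.k or self.k < 1:
            raise ValueError(f"record level k must be an integer >= 1, got {self.k}")


def _check_nonneg(w) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("lifetime values must be nonnegative")
    return w


def ged_pdf(w, p: GEDParams):
    """GED density ``theta*lambda*exp(-lambda w)*(1-exp(-lambda w))**(theta-1)``.

    At ``w = 0`` the density is 0 for ``theta > 1``, ``lambda`` for
    ``theta = 1`` and ``+inf`` for ``theta < 1`` (integrable singularity).
    """
    w = _check_nonneg(w)
    lam, th = p.lambda_, p.theta
    base = -np.expm1(-lam * w)  # 1 - exp(-lambda w), accurate near 0
    with np.errstate(divide="ignore"):
        out = th * lam * np.exp(-lam * w) * base ** (th - 1.0)
    return out


def ged_cdf(w, p: GEDParams):
    """GED CDF ``(1 - exp(-lambda w))**theta``."""
    w = _check_nonneg(w)
    return (-np.expm1(-p.lambda_ * w)) ** p.theta


def ged_quantile(prob, p: GEDParams):
    """Inverse CDF: ``-(1/lambda) * log(1 - prob**(1/theta))``."""
    prob = np.asarray(prob, dtype=float)
    if np.any(prob <= 0) or np.any(prob >= 1):
        raise ValueError("prob must lie strictly inside (0, 1)")
    return -np.log1p(-prob ** (1.0 / p.theta)) / p.lambda_


def ged_hazard(w, p: GEDParams):
    """Hazard rate ``g / (1 - G)``; constant ``lambda`` when ``theta = 1``."""
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("hazard is defined for w > 0")
    return ged_pdf(w, p) / (1.0 - ged_cdf(w, p))


def ged_rand(count: int, p: GEDParams, rng: np.random.Generator):
    """Draw ``count`` iid GED variates by inverse-CDF of uniforms."""
    if count < 1:
        raise ValueError("count must be >= 1")
    return ged_quantile(rng.uniform(size=count), p)


def neglog_ged_cdf(w, p: GEDParams):
    """The transform ``t(w) = -log(1 - exp(-lambda w))`` times ``theta``.

    Returns ``-log G(w) = theta * t(w)``, the exponential-scale coordinate in
    which lower records of the GED are gamma distributed.
    """
    w = _check_nonneg(w)
    with np.errstate(divide="ignore"):
        return -p.theta * np.log(-np.expm1(-p.lambda_ * w))


def krecord_pdf(w, rs: RecordSpec, p: GEDParams):
    """Density of the i-th lower k-record of a GED stream.

    Computed as ``gamma.pdf(u, i) * |du/dw|`` with ``u = -k log G(w)``.
    """
    w = _check_nonneg(w)
    u = rs.k * neglog_ged_cdf(w, p)
    # |du/dw| = k * g(w) / G(w)
    with np.errstate(divide="ignore", invalid="ignore"):
        jac = rs.k * ged_pdf(w, p) / ged_cdf(w, p)
        out = stats.gamma.pdf(u, rs.i) * jac
    # w -> 0 has u -> inf: density 0 in the limit for i>=1 unless theta<1 at w=0
    out = np.where(np.isnan(out), 0.0, out)
    return out


def krecord_cdf(w, rs: RecordSpec, p: GEDParams):
    """``P(record <= w)``: the finite Poisson sum ``G^k sum_{v<i}(-k log G)^v/v!``.

    Exact via the upper gamma tail ``P(U >= u)`` of ``U ~ Gamma(i, 1)``.
    """
    w = _check_nonneg(w)
    u = rs.k * neglog_ged_cdf(w, p)
    return stats.gamma.sf(u, rs.i)


def krecord_sf(w, rs: RecordSpec, p: GEDParams):
    """``P(record > w) = 1 - krecord_cdf``; the complementary infinite series.

    Never summed as a series: computed exactly as the lower gamma tail.
    """
    w = _check_nonneg(w)
    u = rs.k * neglog_ged_cdf(w, p)
    return stats.gamma.cdf(u, rs.i)
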