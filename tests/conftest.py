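import math

import numpy as np
import pytest

from omelrrss import GEDParams, RecordSpec, SchemeConfig
from omelrrss.ged import krecord_cdf, krecord_pdf, krecord_sf
from omelrrss.likelihood import permanent


@pytest.fixture
def rng():
    return np.random.default_rng(20250920)


def censored_jdf_batch(Z, scheme: SchemeConfig, p: GEDParams, r: int, s: int):
    """Censored joint density at many ascending windows Z (B, s-r+1), built
    directly from the record distribution functions (an assembly independent
    of the likelihood module's internals): left-censor rows carry
    P(record <= z_r), right-censor rows P(record > z_s)."""
    Z = np.asarray(Z, dtype=float)
    n = scheme.n
    B = Z.shape[0]
    M = np.empty((B, n, n))
    for col, i in enumerate(scheme.record_indices):
        rs = RecordSpec(i, scheme.k)
        if r > 1:
            M[:, : r - 1, col] = krecord_cdf(Z[:, 0], rs, p)[:, None]
        M[:, r - 1 : s, col] = krecord_pdf(Z, rs, p)
        if s < n:
            M[:, s:, col] = krecord_sf(Z[:, -1], rs, p)[:, None]
    return permanent(M) / (math.factorial(r - 1) * math.factorial(n - s))


def ordered_window_integral(scheme: SchemeConfig, p: GEDParams, r: int, s: int,
                            nodes: int = 64, zmax: float | None = None) -> float:
    """Integral of the censored joint density over the ordered window region,
    tensor Gauss-Legendre on nested triangles (window dimension <= 3)."""
    dim = s - r + 1
    if zmax is None:
        zmax = 15.0 / p.lambda_
    x, w = np.polynomial.legendre.leggauss(nodes)
    x = 0.5 * (x + 1.0)
    w = 0.5 * w
    if dim == 1:
        Z = (zmax * x)[:, None]
        W = zmax * w
    elif dim == 2:
        z2 = zmax * x                        # larger value
        z1 = np.multiply.outer(z2, x)        # smaller, in (0, z2)
        Z = np.stack([z1.ravel(),
                      np.broadcast_to(z2[:, None], z1.shape).ravel()], axis=1)
        W = (np.multiply.outer(zmax * w * z2, w)).ravel()
    elif dim == 3:
        z3 = zmax * x
        z2 = np.multiply.outer(z3, x)
        z1 = np.multiply.outer(z2, x)
        Z = np.stack([z1.ravel(),
                      np.broadcast_to(z2[..., None], z1.shape).ravel(),
                      np.broadcast_to(z3[:, None, None], z1.shape).ravel()],
                     axis=1)
        W3 = zmax * w * z3                       # d z3 weight * z2-range
        W23 = np.multiply.outer(W3, w) * z2      # * d z2 weight * z1-range
        W = (np.multiply.outer(W23, w)).ravel()
    else:
        raise ValueError("window dimension > 3 not supported")
    vals = censored_jdf_batch(Z, scheme, p, r, s)
    return float(np.sum(W * vals))
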