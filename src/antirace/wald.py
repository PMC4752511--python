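"""Single-boundary Wald (inverse-Gaussian) first-passage-time primitives.

A Wiener diffusion with drift ``mu`` > 0, unit diffusion coefficient and a
single absorbing threshold ``lam`` > 0 first crosses the threshold at a time
with the inverse-Gaussian (Wald) density

    f(t) = lam * (2*pi*t^3)^(-1/2) * exp(-(lam - mu*t)^2 / (2*t)),   t > 0,

with mean ``lam/mu`` and shape parameter ``lam**2``.  The diffusion
coefficient is fixed at 1: its scale is not identifiable jointly with drift
and threshold, so the convention absorbs it.

Sampling uses the Michael-Schucany-Haas transformation (a chi-square
transform of a standard normal plus a uniform acceptance branch).  Each draw
consumes exactly two uniforms, one mapped through the normal quantile
function and one for the branch choice, so comparisons across parameter
settings under common random numbers are well defined draw-for-draw.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtri
from scipy.stats import invgauss

from .params import InvalidParameterError

#: Densities below this are floored before taking logs so objectives stay finite.
DENSITY_FLOOR = 1e-10

UNIFORMS_PER_DRAW = 2


def _validate(mu: float, lam: float) -> None:
    if not mu > 0:
        raise InvalidParameterError(f"drift mu must be > 0, got {mu}")
    if not lam > 0:
        raise InvalidParameterError(f"threshold lam must be > 0, got {lam}")


def wald_fpt_density(t_rel, mu: float, lam: float):
    """First-passage-time density at ``t_rel`` (time since accumulation onset).

    Returns 0 for ``t_rel <= 0``.  Scalar in, scalar out; array in, array out.
    """
    _validate(mu, lam)
    t = np.asarray(t_rel, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    # evaluate on the log scale: near t=0 the prefactor overflows while the
    # exponential underflows, and their product is 0, not nan
    logpdf = (
        np.log(lam)
        - 0.5 * np.log(2.0 * np.pi)
        - 1.5 * np.log(tp)
        - (lam - mu * tp) ** 2 / (2.0 * tp)
    )
    out[pos] = np.exp(logpdf)
    return out if out.ndim else float(out)


def wald_fpt_logpdf(t_rel, mu: float, lam: float):
    """Log of :func:`wald_fpt_density`, floored at ``log(DENSITY_FLOOR)``."""
    _validate(mu, lam)
    t = np.asarray(t_rel, dtype=float)
    out = np.full_like(t, np.log(DENSITY_FLOOR))
    pos = t > 0
    tp = t[pos]
    logpdf = (
        np.log(lam)
        - 0.5 * np.log(2.0 * np.pi)
        - 1.5 * np.log(tp)
        - (lam - mu * tp) ** 2 / (2.0 * tp)
    )
    out[pos] = np.maximum(logpdf, np.log(DENSITY_FLOOR))
    return out if out.ndim else float(out)


def wald_fpt_cdf(t_rel, mu: float, lam: float):
    """Analytic first-passage CDF via the inverse-Gaussian distribution."""
    _validate(mu, lam)
    mean = lam / mu
    shape = lam**2
    t = np.asarray(t_rel, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = invgauss.cdf(t[pos], mean / shape, scale=shape)
    return out if out.ndim else float(out)


def wald_fpt_from_uniforms(u: np.ndarray, mu: float, lam: float) -> np.ndarray:
    """Transform uniforms of shape ``(n, 2)`` into n first-passage times.

    This is the deterministic core of the sampler: feeding identical
    uniforms for two parameter settings yields the common-random-number
    coupling used by the model's mechanism tests.
    """
    _validate(mu, lam)
    u = np.asarray(u, dtype=float)
    if u.ndim != 2 or u.shape[1] != UNIFORMS_PER_DRAW:
        raise ValueError("u must have shape (n, 2)")
    m = lam / mu  # inverse-Gaussian mean
    shape = lam**2
    y = ndtri(u[:, 0]) ** 2
    x1 = (
        m
        + (m**2) * y / (2.0 * shape)
        - (m / (2.0 * shape)) * np.sqrt(4.0 * shape * m * y + (m * y) ** 2)
    )
    return np.where(u[:, 1] <= m / (m + x1), x1, m**2 / x1)


def wald_fpt_sample(mu: float, lam: float, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw ``n`` first-passage times, reproducible for a seeded generator."""
    if n < 1:
        raise ValueError("n must be >= 1")
    u = rng.uniform(size=(n, UNIFORMS_PER_DRAW))
    return wald_fpt_from_uniforms(u, mu, lam)
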