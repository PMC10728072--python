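"""Circular statistics for respiratory-phase coupling.

Angles are radians in (-pi, pi], with 0 defined as the inhalation peak
throughout the package. The resultant vector length R of a sample of unit
phase vectors quantifies concentration (0 = uniform, 1 = identical
phases); the V-test assesses nonuniformity toward a prespecified direction
(here usually the inhalation peak); Watson's U^2 against a fitted von
Mises checks that a phase sample is unimodal von-Mises-like, which the
summary statistics above presuppose.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

__all__ = [
    "wrap_angle",
    "circ_mean",
    "resultant_length",
    "circ_summary",
    "v_test",
    "rayleigh_test",
    "vonmises_kappa_mle",
    "watson_u2",
    "watson_vonmises_check",
]


def wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    return -((-theta + np.pi) % (2 * np.pi) - np.pi)


def _moment(phases: np.ndarray) -> complex:
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("circular statistics undefined for an empty sample")
    return np.exp(1j * phases).mean()


def circ_mean(phases: np.ndarray) -> float:
    """Circular mean direction (first trigonometric moment argument)."""
    return float(np.angle(_moment(phases)))


def resultant_length(phases: np.ndarray) -> float:
    """Resultant vector length R in [0, 1]."""
    return float(np.abs(_moment(phases)))


def circ_summary(phases: np.ndarray) -> tuple[float, float]:
    """(mean angle, resultant length) of a phase sample."""
    m = _moment(phases)
    return float(np.angle(m)), float(np.abs(m))


def v_test(phases: np.ndarray, mu0: float = 0.0) -> tuple[float, float]:
    """V-test for nonuniformity with specified mean direction ``mu0``.

    V = n * R * cos(theta_bar - mu0); the p-value comes from
    u = V * sqrt(2/n) referred to the upper tail of the standard normal.
    Returns ``(V, p)``.
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < 1:
        raise ValueError("V-test needs at least one phase")
    mean, r = circ_summary(phases)
    v = n * r * np.cos(mean - mu0)
    u = v * np.sqrt(2.0 / n)
    p = float(stats.norm.sf(u))
    return float(v), p


def rayleigh_test(phases: np.ndarray) -> tuple[float, float]:
    """Rayleigh test for nonuniformity (no specified direction).

    Returns ``(z, p)`` with z = n * R^2 and the standard small-sample
    corrected p-value.
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < 1:
        raise ValueError("Rayleigh test needs at least one phase")
    r = resultant_length(phases)
    z = n * r**2
    p = np.exp(-z) * (1 + (2 * z - z**2) / (4 * n) - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n**2))
    return float(z), float(np.clip(p, 0.0, 1.0))


def vonmises_kappa_mle(phases: np.ndarray) -> float:
    """Maximum-likelihood concentration of a von Mises sample.

    Inverts A(kappa) = I1(kappa)/I0(kappa) = R with the standard
    piecewise approximation (Fisher 1993), followed by two Newton steps.
    """
    r = resultant_length(phases)
    if r < 1e-12:
        return 0.0
    if r < 0.53:
        kappa = 2 * r + r**3 + 5 * r**5 / 6
    elif r < 0.85:
        kappa = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        kappa = 1 / (r**3 - 4 * r**2 + 3 * r)
    for _ in range(2):
        if kappa <= 0 or not np.isfinite(kappa):
            break
        a = special.i1e(kappa) / special.i0e(kappa)
        da = 1 - a / kappa - a**2
        if abs(da) < 1e-14:
            break
        kappa = max(kappa - (a - r) / da, 1e-8)
    return float(kappa)


def _vonmises_cdf(theta: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    return stats.vonmises.cdf(wrap_angle(theta - mu), kappa, loc=0.0) if kappa > 0 else (
        (wrap_angle(theta - mu) + np.pi) / (2 * np.pi)
    )


def watson_u2(u: np.ndarray) -> float:
    """Watson's U^2 statistic for probability-integral-transformed data."""
    u = np.sort(np.asarray(u, dtype=float))
    n = u.size
    i = np.arange(1, n + 1)
    ubar = u.mean()
    return float(np.sum((u - (2 * i - 1) / (2 * n)) ** 2) - n * (ubar - 0.5) ** 2 + 1.0 / (12 * n))


def watson_vonmises_check(
    phases: np.ndarray,
    n_boot: int = 300,
    seed: int | np.random.Generator | None = 0,
    min_n: int = 20,
) -> float:
    """Goodness-of-fit p-value of a fitted von Mises (Watson U^2).

    Parameters (mu, kappa) are estimated from the sample, so the null
    distribution of U^2 is obtained by parametric bootstrap: ``n_boot``
    samples of the same size are drawn from the fitted distribution and
    re-fitted, and the p-value is the fraction of bootstrap statistics at
    least as large as the observed one. A large p (conventionally > 0.1)
    means the sample is consistent with a unimodal von Mises.
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < min_n:
        raise ValueError(f"need at least {min_n} phases for the Watson test, got {n}")
    rng = np.random.default_rng(seed)

    def fit_stat(sample: np.ndarray) -> float:
        mu = circ_mean(sample)
        kappa = vonmises_kappa_mle(sample)
        return watson_u2(_vonmises_cdf(sample, mu, kappa))

    observed = fit_stat(phases)
    mu_hat, kappa_hat = circ_mean(phases), vonmises_kappa_mle(phases)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        sample = rng.vonmises(mu_hat, kappa_hat, size=n) if kappa_hat > 0 else rng.uniform(-np.pi, np.pi, size=n)
        boot[b] = fit_stat(sample)
    return float((1 + np.sum(boot >= observed)) / (n_boot + 1))
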