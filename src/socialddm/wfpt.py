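"""Wiener diffusion first-passage-time machinery.

Conventions (shared by the whole package): evidence accumulates between
an absorbing lower boundary at 0 (pro-social response) and an upper
boundary at ``a`` (selfish response); the relative starting point is
``z = R0/a`` with 0 < z < 1; positive drift ``v`` pushes toward the
selfish boundary; the diffusion coefficient ``sigma`` defaults to 1 in
evidence units per sqrt(second), so thresholds of fitted subjects come
out around 3-4.

The defective first-passage density is evaluated with the classic
small-time / large-time series expansions, switching per time point to
whichever needs fewer terms for the requested truncation error.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "analytic_choice_prob",
    "mean_decision_time",
    "wiener_fpt_density",
    "defective_cdf",
]

_TWO_PI = 2.0 * np.pi


def analytic_choice_prob(v, a, z, sigma: float = 1.0):
    """Probability of absorption at the selfish (upper) boundary.

    ``(1 - exp(-2 v z a / sigma^2)) / (1 - exp(-2 v a / sigma^2))``,
    continuously extended to ``z`` at ``v = 0``.  Broadcasts over array
    arguments.
    """
    v, a, z = np.broadcast_arrays(np.asarray(v, dtype=float),
                                  np.asarray(a, dtype=float),
                                  np.asarray(z, dtype=float))
    k = 2.0 * v * a / sigma**2
    # overflow-safe: for k >= 0 all exponents are <= 0 in the direct form;
    # for k < 0 multiply through by exp(k) first.
    kn = np.where(np.abs(k) < 1e-9, 1.0, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        pos = np.expm1(-kn * z) / np.expm1(-kn)
        neg = (np.exp(kn * (1.0 - z)) - np.exp(kn)) / (-np.expm1(kn))
    p = np.where(np.abs(k) < 1e-9, z, np.where(k >= 0, pos, neg))
    out = np.clip(p, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def mean_decision_time(v, a, sigma: float = 1.0):
    """Mean first-passage time for an unbiased start (z = 0.5):
    ``(a / 2v) * tanh(v a / (2 sigma^2))``; limit ``a^2/(4 sigma^2)`` at v=0."""
    v = np.asarray(v, dtype=float)
    a = np.asarray(a, dtype=float)
    small = np.abs(v) < 1e-12
    vv = np.where(small, 1.0, v)
    out = np.where(small, a**2 / (4.0 * sigma**2),
                   (a / (2.0 * vv)) * np.tanh(vv * a / (2.0 * sigma**2)))
    return float(out) if out.ndim == 0 else out


def _f1(w: np.ndarray, z: np.ndarray, eps: float) -> np.ndarray:
    """Standardized density (a=1, v=0, sigma=1) of first passage at the
    *lower* boundary at scaled time ``w``, start ``z``; truncation error
    below ``eps``.  ``w`` and ``z`` broadcast."""
    w, z = np.broadcast_arrays(np.asarray(w, dtype=float), np.asarray(z, dtype=float))
    out = np.zeros(w.shape, dtype=float)
    pos = w > 0
    if not pos.any():
        return out
    ww = w[pos]
    zz = z[pos]

    # terms needed: small-time (ks) vs large-time (kl) per element
    with np.errstate(divide="ignore", invalid="ignore"):
        ks = 2.0 + np.sqrt(np.maximum(-2.0 * ww * np.log(2.0 * eps * np.sqrt(_TWO_PI * ww)), 0.0))
        ks = np.where(2.0 * np.sqrt(_TWO_PI * ww) * eps < 1.0, ks, 2.0)
        ks = np.maximum(ks, np.sqrt(ww) + 1.0)
        kl = np.sqrt(np.maximum(-2.0 * np.log(np.pi * ww * eps), 0.0) / (np.pi**2 * ww))
        kl = np.where(np.pi * ww * eps < 1.0, kl, 0.0)
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(ww)))

    use_small = ks < kl
    vals = np.empty(ww.shape, dtype=float)

    if use_small.any():
        w_s, z_s = ww[use_small], zz[use_small]
        K = int(min(np.ceil(ks[use_small].max()), 60))
        ks_range = np.arange(-((K - 1) // 2 + 1), (K - 1) // 2 + 2)
        terms = (z_s[:, None] + 2.0 * ks_range[None, :]) * np.exp(
            -((z_s[:, None] + 2.0 * ks_range[None, :]) ** 2) / (2.0 * w_s[:, None])
        )
        vals[use_small] = terms.sum(axis=1) / np.sqrt(_TWO_PI * w_s**3)

    if (~use_small).any():
        w_l, z_l = ww[~use_small], zz[~use_small]
        K = int(min(np.ceil(kl[~use_small].max()), 60))
        kr = np.arange(1, K + 1)
        terms = kr[None, :] * np.exp(-(kr[None, :] ** 2) * np.pi**2 * w_l[:, None] / 2.0) \
            * np.sin(kr[None, :] * np.pi * z_l[:, None])
        vals[~use_small] = np.pi * terms.sum(axis=1)

    out[pos] = np.maximum(vals, 0.0)
    return out


def _density_one_bound(t, v, a, z, sigma, eps):
    """Defective FPT density at the lower boundary, decision time t."""
    t = np.asarray(t, dtype=float)
    v = v / sigma
    a = a / sigma
    w = t / a**2
    pref = np.exp(-v * a * z - (v**2) * t / 2.0) / a**2
    return pref * _f1(w, z, eps)


def _gauss_legendre_nodes(z: float, szr: float, n: int = 11):
    x, wts = np.polynomial.legendre.leggauss(n)
    nodes = z + 0.5 * szr * x
    return nodes, wts / 2.0  # weights sum to 1


def wiener_fpt_density(t, boundary: str, *, v, a, z, t0: float = 0.0,
                       szr: float = 0.0, sigma: float = 1.0,
                       eps: float = 1e-7):
    """Defective first-passage density at ``boundary`` for response time(s)
    ``t`` (seconds, inclusive of the non-decision time ``t0``).

    ``boundary`` is ``"selfish"`` (upper) or ``"prosocial"`` (lower).
    ``szr`` is the range of uniform inter-trial variability of the
    relative start; it is integrated out with 11-node Gauss-Legendre
    quadrature.  Zero for ``t <= t0``.  ``v`` may be an array broadcast
    against ``t``.
    """
    if boundary not in ("selfish", "prosocial"):
        raise ValueError(f"unknown boundary {boundary!r}")
    if not (a > 0 and 0 < z < 1 and t0 >= 0 and szr >= 0):
        raise ValueError("invalid Wiener parameters")
    if szr > 0 and not szr < 2.0 * min(z, 1.0 - z):
        raise ValueError("szr places starting points outside the boundaries")
    t = np.asarray(t, dtype=float)
    tau = t - t0

    def one(zz):
        if boundary == "prosocial":
            return _density_one_bound(np.maximum(tau, 0.0), v, a, zz, sigma, eps)
        return _density_one_bound(np.maximum(tau, 0.0), -np.asarray(v), a, 1.0 - zz, sigma, eps)

    if szr == 0.0:
        dens = one(z)
    else:
        nodes, wts = _gauss_legendre_nodes(z, szr)
        dens = sum(wt * one(zz) for zz, wt in zip(nodes, wts))
    dens = np.where(tau > 0, dens, 0.0)
    return float(dens) if dens.ndim == 0 else dens


def defective_cdf(t_grid, boundary: str, **params):
    """Cumulative defective distribution at ``boundary`` on ``t_grid``
    (trapezoidal integration of the density; grid should start at or
    below ``t0``)."""
    from scipy.integrate import cumulative_trapezoid

    dens = wiener_fpt_density(t_grid, boundary, **params)
    return cumulative_trapezoid(dens, t_grid, initial=0.0)
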