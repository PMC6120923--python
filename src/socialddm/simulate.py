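"""Vectorized simulation of the (biased) drift-diffusion process.

The walkers follow the Euler discretization of
``R_{t+dt} = R_t + v dt + sigma sqrt(dt) N(0,1)`` between absorbing
boundaries at 0 (pro-social) and ``a`` (selfish).  Because the drift is
constant, the Gaussian increments are exact transition draws; the only
discretization artefact is undetected within-step boundary crossing.
With ``bridge=True`` that is removed by drawing the Brownian-bridge
crossing probability ``exp(-2 (b - x)(b - x') / (sigma^2 dt))`` for each
step, which makes choice fractions exact for any step size (decision
times retain a resolution of one step).

Supports heterogeneous per-trial drift, start, threshold and deadline
arrays, and linearly collapsing boundaries that meet at ``a/2`` at the
deadline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SimResult", "simulate_wiener", "simulate_ddm_trial"]


@dataclass
class SimResult:
    """Outcome of a batch of diffusion trials.

    ``choice_selfish`` is undefined (False) where ``resolved`` is False;
    ``evidence`` then holds the walker's final position so the caller can
    apply a deadline rule.  ``decision_time`` excludes non-decision time.
    """

    choice_selfish: np.ndarray
    decision_time: np.ndarray
    resolved: np.ndarray
    evidence: np.ndarray


def simulate_wiener(n: int, v, a, z, *, sigma: float = 1.0,
                    dt: float = 0.001, szr: float = 0.0,
                    deadline=None, collapse: bool = False,
                    rng: np.random.Generator, bridge: bool = False,
                    max_time: float = 60.0) -> SimResult:
    """Simulate ``n`` first-passage trials in one vectorized sweep.

    ``v``, ``z``, ``a`` and ``deadline`` may be scalars or length-``n``
    arrays, so heterogeneous batches (many subjects, many games) run in
    a single call.  Returned times are decision times (no ``t0``).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if collapse and deadline is None:
        raise ValueError("collapsing bounds require a deadline")
    v = np.broadcast_to(np.asarray(v, dtype=float), (n,)).copy()
    z = np.broadcast_to(np.asarray(z, dtype=float), (n,)).copy()
    a = np.broadcast_to(np.asarray(a, dtype=float), (n,)).copy()
    dl = None if deadline is None else \
        np.broadcast_to(np.asarray(deadline, dtype=float), (n,)).copy()
    if szr > 0:
        z = z + szr * (rng.random(n) - 0.5)
        z = np.clip(z, 1e-6, 1.0 - 1e-6)

    x = np.clip(z, 0.0, 1.0) * a
    choice = np.zeros(n, dtype=bool)
    dtime = np.full(n, np.nan)
    resolved = np.zeros(n, dtype=bool)

    # starts at or beyond a boundary are immediate decisions
    hi0 = x >= a
    lo0 = x <= 0.0
    choice[hi0] = True
    dtime[hi0 | lo0] = 0.0
    resolved[hi0 | lo0] = True

    active = np.where(~resolved)[0]
    sdt = sigma * np.sqrt(dt)
    horizon = max_time if dl is None else float(np.max(dl))
    n_steps_max = int(np.ceil(horizon / dt))
    step = 0
    while active.size and step < n_steps_max:
        step += 1
        t = step * dt
        aa = a[active]
        if collapse:
            frac = np.minimum(t / dl[active], 1.0)
            upper = aa * (1.0 - 0.5 * frac)
            lower = 0.5 * aa * frac
        else:
            upper = aa
            lower = 0.0
        x_old = x[active]
        x_new = x_old + v[active] * dt + sdt * rng.standard_normal(active.size)

        hit_up = x_new >= upper
        hit_lo = (~hit_up) & (x_new <= lower)
        if bridge:
            inside = ~(hit_up | hit_lo)
            if inside.any():
                xo, xn = x_old[inside], x_new[inside]
                up_i = upper[inside] if np.ndim(upper) else upper
                lo_i = lower[inside] if np.ndim(lower) else lower
                p_up = np.exp(-2.0 * np.maximum(up_i - xo, 0.0)
                              * np.maximum(up_i - xn, 0.0) / (sigma**2 * dt))
                p_lo = np.exp(-2.0 * np.maximum(xo - lo_i, 0.0)
                              * np.maximum(xn - lo_i, 0.0) / (sigma**2 * dt))
                u = rng.random(int(inside.sum()))
                cross_up = u < p_up
                cross_lo = (~cross_up) & (u < p_up + p_lo)
                hu = hit_up.copy()
                hl = hit_lo.copy()
                hu[inside] = cross_up
                hl[inside] = cross_lo
                hit_up, hit_lo = hu, hl

        done = hit_up | hit_lo
        if done.any():
            idx = active[done]
            choice[idx] = hit_up[done]
            dtime[idx] = t
            resolved[idx] = True
        x[active] = x_new
        active = active[~done]
        if dl is not None and active.size:
            timed_out = t >= dl[active]
            if timed_out.any():
                active = active[~timed_out]

    return SimResult(choice_selfish=choice, decision_time=dtime,
                     resolved=resolved, evidence=x)


def simulate_ddm_trial(params, game, *, dt: float = 0.001,
                       deadline: float | None = None, collapse: bool = False,
                       rng: np.random.Generator, max_time: float = 60.0):
    """Simulate a single trial under ``params`` (a :class:`~socialddm.ddm.DDMParams`)
    for ``game``; returns ``(choice, rt)`` with ``choice`` in
    {"selfish", "prosocial"} and ``rt`` including ``t0``.  ``deadline``,
    when given, bounds the full response time (decision + ``t0``).

    Raises ``RuntimeError`` if the walker is not absorbed within the time
    budget (only possible without a deadline).
    """
    from .ddm import drift_rate

    v = drift_rate(params, game)
    decision_deadline = None if deadline is None else max(deadline - params.t0, dt)
    res = simulate_wiener(1, v, params.a, params.z, sigma=params.sigma, dt=dt,
                          szr=params.szr, deadline=decision_deadline,
                          collapse=collapse, rng=rng, max_time=max_time)
    if not res.resolved[0]:
        if deadline is None:
            raise RuntimeError("no absorption within the simulation time budget")
        # deadline rule: resolve by the sign of the evidence about the midline
        mid = params.a / 2.0
        e = res.evidence[0]
        selfish = bool(e > mid) if e != mid else bool(rng.random() < 0.5)
        return ("selfish" if selfish else "prosocial", deadline)
    choice = "selfish" if res.choice_selfish[0] else "prosocial"
    return choice, float(res.decision_time[0]) + params.t0
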