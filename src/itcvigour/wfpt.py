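"""Wiener first-passage-time (WFPT) density, boundary probabilities and
diffusion simulation for the two-boundary drift diffusion model.

Parametrisation: boundary separation ``a`` (evidence units, boundaries at 0
and ``a``), non-decision time ``tau`` (s), start fraction ``z`` in (0,1)
(start point ``z*a``), drift ``v`` (evidence/s, positive towards the upper
boundary).  Stimulus coding is used throughout: the lower boundary is the
smaller-sooner (SS) choice, the upper boundary the larger-later (LL)
choice, and SS response times carry a negative sign.

The density uses the standard small-time/large-time series decomposition,
choosing per evaluation whichever series needs fewer terms for a
truncation error below ``err`` (default 1e-7).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "encode_stimulus_coding",
    "decode_stimulus_coding",
    "wfpt_logdensity",
    "upper_probability",
    "simulate_ddm_trials",
    "dataset_loglik_arrays",
]


# ---------------------------------------------------------------------------
# stimulus coding

def encode_stimulus_coding(choice, rt):
    """Signed response time: SS -> -rt, LL -> +rt.  ``choice`` may be the
    strings ``"SS"``/``"LL"`` or 0/1 (0 = SS = lower boundary)."""
    rt = np.asarray(rt, dtype=float)
    if np.any(rt <= 0):
        raise ValueError("response times must be positive")
    ch = np.asarray(choice)
    if ch.dtype.kind in "US":
        upper = ch == "LL"
        if not np.all((ch == "LL") | (ch == "SS")):
            raise ValueError("choices must be 'SS' or 'LL'")
    else:
        upper = ch.astype(bool)
    out = np.where(upper, rt, -rt)
    return out if out.ndim else float(out)


def decode_stimulus_coding(signed_rt):
    """Inverse of :func:`encode_stimulus_coding`; returns (choice, rt)."""
    srt = np.asarray(signed_rt, dtype=float)
    if np.any(srt == 0):
        raise ValueError("signed response times must be non-zero")
    choice = np.where(srt > 0, "LL", "SS")
    return (choice if srt.ndim else str(choice)), np.abs(srt) if srt.ndim else float(abs(srt))


# ---------------------------------------------------------------------------
# density

def _f_lower_norm(tt, w, err):
    """Density of the time-normalised (a=1, v=0) diffusion at the lower
    boundary, evaluated at normalised decision times ``tt`` with start
    fraction ``w``.  Vectorised small/large-time series selection."""
    tt = np.atleast_1d(np.asarray(tt, dtype=float))
    w = np.broadcast_to(np.asarray(w, dtype=float), tt.shape)
    out = np.zeros_like(tt)
    ok = tt > 0
    t = tt[ok]
    ww = w[ok]

    # number of terms needed per branch (truncation error <= err)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = 2.0 * np.sqrt(2.0 * np.pi * t) * err
        ks = np.where(arg < 1.0, 2.0 + np.sqrt(np.maximum(-2.0 * t * np.log(arg), 0.0)), 2.0)
        ks = np.maximum(ks, np.sqrt(t) + 1.0)
        argl = np.pi * t * err
        kl = np.where(
            argl < 1.0,
            np.maximum(np.sqrt(np.maximum(-2.0 * np.log(argl), 0.0) / (np.pi**2 * t)),
                       1.0 / (np.pi * np.sqrt(t))),
            1.0 / (np.pi * np.sqrt(t)),
        )

    use_small = ks < kl
    res = np.empty_like(t)

    if np.any(use_small):
        ts, ws = t[use_small], ww[use_small]
        K = int(np.ceil(ks[use_small].max()))
        kk = np.arange(-((K - 1) // 2), ((K - 1) // 2) + K % 2 + 1)
        x = ws[:, None] + 2.0 * kk[None, :]
        s = np.sum(x * np.exp(-(x**2) / (2.0 * ts[:, None])), axis=1)
        res[use_small] = s / np.sqrt(2.0 * np.pi * ts**3)

    if np.any(~use_small):
        tl, wl = t[~use_small], ww[~use_small]
        K = int(np.ceil(kl[~use_small].max()))
        kk = np.arange(1, K + 1)
        s = np.sum(
            kk[None, :]
            * np.exp(-(kk[None, :] ** 2) * np.pi**2 * tl[:, None] / 2.0)
            * np.sin(kk[None, :] * np.pi * wl[:, None]),
            axis=1,
        )
        res[~use_small] = np.pi * s

    out[ok] = np.maximum(res, 0.0)
    return out


def wfpt_logdensity(signed_rt, v, a, tau, z, err: float = 1e-7):
    """Log first-passage density of the signed response time.

    Negative ``signed_rt`` is evaluated at the lower (SS) boundary, positive
    at the upper (LL) boundary via the reflection identity
    ``f_upper(t; z, v) = f_lower(t; 1-z, -v)``.  Response times at or below
    the non-decision time get log-density ``-inf`` (zero density).
    """
    srt = np.atleast_1d(np.asarray(signed_rt, dtype=float))
    v = np.broadcast_to(np.asarray(v, dtype=float), srt.shape).copy()
    a = np.broadcast_to(np.asarray(a, dtype=float), srt.shape)
    tau = np.broadcast_to(np.asarray(tau, dtype=float), srt.shape)
    z = np.broadcast_to(np.asarray(z, dtype=float), srt.shape).copy()
    if np.any(a <= 0) or np.any(tau <= 0) or np.any((z <= 0) | (z >= 1)):
        raise ValueError("require a > 0, tau > 0, 0 < z < 1")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite drift")

    t = np.abs(srt) - tau
    upper = srt > 0
    # reflection for the upper boundary
    w = np.where(upper, 1.0 - z, z)
    vv = np.where(upper, -v, v)

    out = np.full(srt.shape, -np.inf)
    ok = t > 0
    if np.any(ok):
        tt = t[ok] / a[ok] ** 2
        f0 = _f_lower_norm(tt, w[ok], err)
        with np.errstate(divide="ignore"):
            out[ok] = (
                np.log(f0)
                - 2.0 * np.log(a[ok])
                - vv[ok] * a[ok] * w[ok]
                - vv[ok] ** 2 * t[ok] / 2.0
            )
    return out if np.asarray(signed_rt).ndim else float(out[0])


def upper_probability(v, a, z):
    """Probability of absorption at the upper (LL) boundary.

    Closed form ``(1 - exp(-2 v z a)) / (1 - exp(-2 v a))``; equals ``z``
    for zero drift.
    """
    scalar = np.ndim(v) == 0 and np.ndim(a) == 0 and np.ndim(z) == 0
    v = np.atleast_1d(np.asarray(v, dtype=float))
    a = np.broadcast_to(np.asarray(a, dtype=float), v.shape)
    z = np.broadcast_to(np.asarray(z, dtype=float), v.shape)
    out = np.empty_like(v)
    small = np.abs(v) < 1e-10
    out[small] = z[small]
    vb = v[~small]
    out[~small] = np.expm1(-2.0 * vb * z[~small] * a[~small]) / np.expm1(-2.0 * vb * a[~small])
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# simulation

@njit(cache=False)
def _simulate_core(v, a, tau, z, dt, t_max, seed):  # pragma: no cover - jitted
    n = v.shape[0]
    rts = np.empty(n)
    upper = np.empty(n, dtype=np.int64)
    np.random.seed(seed)
    sdt = np.sqrt(dt)
    for i in range(n):
        x = z[i] * a[i]
        t = 0.0
        upper[i] = -1
        while t < t_max:
            xn = x + v[i] * dt + sdt * np.random.randn()
            t += dt
            if xn >= a[i]:
                upper[i] = 1
                break
            if xn <= 0.0:
                upper[i] = 0
                break
            # Brownian-bridge correction for within-step boundary crossings
            p_up = np.exp(-2.0 * (a[i] - x) * (a[i] - xn) / dt)
            p_lo = np.exp(-2.0 * x * xn / dt)
            u = np.random.rand()
            if u < p_up:
                upper[i] = 1
                break
            if u > 1.0 - p_lo:
                upper[i] = 0
                break
            x = xn
        if upper[i] == -1:  # hit the time cap (vanishingly rare)
            upper[i] = 1 if x > a[i] / 2.0 else 0
        rts[i] = tau[i] + t
    return rts, upper


def simulate_ddm_trials(v, a, tau, z, seed: int, dt: float = 1e-3, t_max: float = 60.0):
    """Simulate first passages of the diffusion; returns signed RTs.

    Euler-Maruyama with a Brownian-bridge boundary-crossing correction,
    which removes the leading discretisation bias in first-passage times.
    All RTs exceed the non-decision time.
    """
    v = np.atleast_1d(np.asarray(v, dtype=float))
    n = v.shape[0]
    a = np.broadcast_to(np.asarray(a, dtype=float), (n,)).copy()
    tau = np.broadcast_to(np.asarray(tau, dtype=float), (n,)).copy()
    z = np.broadcast_to(np.asarray(z, dtype=float), (n,)).copy()
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite drift")
    rts, upper = _simulate_core(v, a, tau, z, dt, t_max, seed % (2**32))
    return np.where(upper == 1, rts, -rts)


# ---------------------------------------------------------------------------
# dataset likelihood

def dataset_loglik_arrays(signed_rt, v, a, tau, z, err: float = 1e-7) -> float:
    """Total log-likelihood of a set of signed RTs with per-trial
    parameters (arrays broadcast against ``signed_rt``)."""
    ll = wfpt_logdensity(signed_rt, v, a, tau, z, err=err)
    return float(np.sum(ll))
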