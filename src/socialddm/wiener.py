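"""Two-boundary Wiener (drift-diffusion) first-passage-time machinery.

The accumulator starts at ``z * a`` between an absorbing lower boundary at 0
and an upper boundary at ``a`` and evolves as ``dX = v dt + dW`` with unit
diffusion coefficient.  The defective first-passage density at each boundary
is the likelihood kernel for two-alternative choice/response-time data: its
integral over time equals the probability of responding at that boundary,
and the two boundary integrals sum to one.

By convention here the LOWER boundary is the ingroup-compliant response and
the UPPER boundary the non-compliant one.

Density evaluation uses the small-time and large-time series expansions of
the scaled density with a per-evaluation switch driven by the number of
terms each series needs for a fixed truncation error (target 1e-7).
Across-trial drift variability ``sv`` enters through the known analytic
Gaussian marginal of the exponential drift factor.  No across-trial
variability in starting point or non-decision time is modelled (every model
in the fitted space fixes them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss

__all__ = [
    "DDMParams",
    "Boundary",
    "fpt_density",
    "choice_probability",
    "absorption_probability",
    "defective_cdf_grid",
    "simulate_trials",
    "SimulatedTrials",
]

# truncation-error target per density evaluation
_SERIES_EPS = 1e-7
# Gauss-Hermite order for sv-marginal choice probabilities
_GH_ORDER = 61


class Boundary(Enum):
    """Absorbing boundary labels. LOWER = ingroup-compliant response."""

    LOWER = 0
    UPPER = 1


@dataclass(frozen=True)
class DDMParams:
    """One parameter set of the two-boundary Wiener process.

    Parameters
    ----------
    a : float
        Boundary separation (evidence units), > 0.
    z : float
        Relative starting point in (0, 1); the accumulator starts at ``z*a``.
    t0 : float
        Non-decision time in seconds, >= 0; added to the decision time.
    v : float
        Mean drift rate (evidence per second); negative values drift toward
        the lower boundary.
    sv : float
        Across-trial drift standard deviation, >= 0.  Each trial's drift is
        drawn from ``N(v, sv**2)``.
    """

    a: float
    z: float = 0.5
    t0: float = 0.0
    v: float = 0.0
    sv: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"boundary separation a must be > 0, got {self.a}")
        if not (0.0 < self.z < 1.0):
            raise ValueError(f"relative start z must lie in (0, 1), got {self.z}")
        if not (self.t0 >= 0):
            raise ValueError(f"non-decision time t0 must be >= 0, got {self.t0}")
        if not (self.sv >= 0):
            raise ValueError(f"drift variability sv must be >= 0, got {self.sv}")
        for name in ("a", "z", "t0", "v", "sv"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} must be finite")


def _scaled_density(tau: np.ndarray, w: float) -> np.ndarray:
    """Density of the scaled (a=1, v=0) process absorbing at 0, start w.

    Evaluates the small-time series where it needs fewer terms than the
    large-time series and vice versa; both truncated at the term count that
    bounds the error by ``_SERIES_EPS``.
    """
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    pos = tau > 0
    if not pos.any():
        return out
    t = tau[pos]

    # terms needed by each series (Navarro & Fuss 2009 bounds)
    with np.errstate(invalid="ignore", divide="ignore"):
        arg_s = 2.0 * np.sqrt(2.0 * np.pi * t) * _SERIES_EPS
        ks = np.where(
            arg_s < 1.0,
            2.0 + np.sqrt(-2.0 * t * np.log(arg_s)),
            np.sqrt(t) + 1.0,
        )
        ks = np.maximum(ks, np.sqrt(t) + 1.0)
        arg_l = np.pi * t * _SERIES_EPS
        kl = np.where(
            arg_l < 1.0,
            np.sqrt(-2.0 * np.log(arg_l) / (np.pi**2 * t)),
            1.0 / (np.pi * np.sqrt(t)),
        )
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(t)))

    small = ks < kl
    res = np.empty_like(t)

    if small.any():
        ts = t[small]
        K = int(np.ceil(ks[small].max()))
        k = np.arange(-K, K + 1)[:, None]
        terms = (w + 2.0 * k) * np.exp(-((w + 2.0 * k) ** 2) / (2.0 * ts[None, :]))
        res[small] = terms.sum(axis=0) / np.sqrt(2.0 * np.pi * ts**3)
    if (~small).any():
        tl = t[~small]
        K = int(np.ceil(kl[~small].max()))
        k = np.arange(1, K + 1)[:, None]
        terms = (
            k
            * np.exp(-(k**2) * np.pi**2 * tl[None, :] / 2.0)
            * np.sin(k * np.pi * w)
        )
        res[~small] = np.pi * terms.sum(axis=0)

    out[pos] = np.maximum(res, 0.0)
    return out


def _lower_density(
    t_dec: np.ndarray, a: float, z: float, v: np.ndarray, sv: float
) -> np.ndarray:
    """Defective density of absorbing at the LOWER boundary at decision time t_dec.

    ``v`` may be a scalar or an array broadcastable with ``t_dec`` (per-trial
    drift).  With ``sv > 0`` the drift factor is marginalized analytically
    over a Gaussian drift with mean ``v`` and SD ``sv``.
    """
    t_dec = np.asarray(t_dec, dtype=float)
    v = np.asarray(v, dtype=float)
    base = _scaled_density(t_dec / a**2, z) / a**2
    with np.errstate(over="ignore", invalid="ignore"):
        if sv == 0.0:
            fac = np.exp(-v * a * z - v**2 * t_dec / 2.0)
        else:
            s2t = 1.0 + sv**2 * t_dec
            fac = np.exp(
                ((a * z * sv) ** 2 - 2.0 * v * a * z - v**2 * t_dec) / (2.0 * s2t)
            ) / np.sqrt(s2t)
    out = np.where(t_dec > 0, base * fac, 0.0)
    return np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)


def fpt_density(
    t: float | np.ndarray, boundary: Boundary, params: DDMParams
) -> float | np.ndarray:
    """Defective first-passage density at ``boundary`` at total time ``t``.

    ``t`` is measured from stimulus onset; the non-decision time is handled
    internally, so the density is zero for ``t <= t0``.  Accepts scalar or
    array ``t``.

    Raises
    ------
    ValueError
        If any ``t <= 0``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("time t must be > 0")
    t_dec = t_arr - params.t0
    if boundary is Boundary.LOWER:
        out = _lower_density(t_dec, params.a, params.z, params.v, params.sv)
    else:
        # reflection: upper-boundary passage of (v, z) is lower-boundary
        # passage of (-v, 1-z)
        out = _lower_density(t_dec, params.a, 1.0 - params.z, -params.v, params.sv)
    return out if out.shape else float(out)


def absorption_probability(v: float, a: float, z: float) -> float:
    """Closed-form probability of absorbing at the LOWER boundary (sv = 0).

    For drift ``v``, separation ``a`` and relative start ``z`` under unit
    diffusion: ``(e^{-2vza} - e^{-2va}) / (1 - e^{-2va})``; the zero-drift
    limit is ``1 - z``.
    """
    x = v * a
    if abs(x) < 1e-9:
        return 1.0 - z
    # stable evaluation via expm1 for either drift sign
    num = math.exp(-2.0 * v * z * a) - math.exp(-2.0 * x)
    den = 1.0 - math.exp(-2.0 * x)
    if math.isinf(num) or math.isinf(den):
        # large negative drift: both exponentials blow up; work on logs
        # P_lower = (e^{-2vza} - e^{-2va})/(1 - e^{-2va}) -> 1 - e^{2va(z-1)}
        return 1.0 - math.exp(2.0 * v * a * (z - 1.0))
    return num / den


def choice_probability(boundary: Boundary, params: DDMParams) -> float:
    """Probability of absorbing at ``boundary``; LOWER + UPPER = 1.

    For ``sv = 0`` the closed form is used; for ``sv > 0`` the closed form is
    marginalized over the Gaussian drift distribution with fixed-order
    Gauss-Hermite quadrature.
    """
    if params.sv == 0.0:
        p_lower = absorption_probability(params.v, params.a, params.z)
    else:
        nodes, weights = hermgauss(_GH_ORDER)
        drifts = params.v + math.sqrt(2.0) * params.sv * nodes
        vals = np.array(
            [absorption_probability(u, params.a, params.z) for u in drifts]
        )
        p_lower = float((weights * vals).sum() / math.sqrt(math.pi))
    return p_lower if boundary is Boundary.LOWER else 1.0 - p_lower


def defective_cdf_grid(
    params: DDMParams,
    boundary: Boundary,
    t_max: float = 10.0,
    n: int = 4096,
) -> tuple[np.ndarray, np.ndarray]:
    """Defective CDF of ``boundary`` passage on a time grid.

    Returns ``(t, F)`` where ``F[i]`` approximates the probability of
    absorbing at ``boundary`` no later than ``t[i]`` (trapezoidal cumulative
    integral of the defective density).  ``F[-1]`` approaches the boundary's
    choice probability as ``t_max`` grows.
    """
    t = np.linspace(params.t0, t_max, n)
    # avoid the t <= 0 domain error at the first node when t0 == 0
    te = np.maximum(t, params.t0 + 1e-12)
    f = np.asarray(fpt_density(te[1:], boundary, params))
    f = np.concatenate([[0.0], f])
    from scipy.integrate import cumulative_trapezoid

    F = np.concatenate([[0.0], cumulative_trapezoid(f, t)])
    return t, F


@dataclass(frozen=True)
class SimulatedTrials:
    """Output of :func:`simulate_trials`: aligned per-trial arrays."""

    boundary: np.ndarray  # int, Boundary values (LOWER=0 / UPPER=1); -1 censored
    rt: np.ndarray  # seconds from stimulus onset; = max_t where censored
    censored: np.ndarray  # bool

    def __len__(self) -> int:
        return len(self.rt)


def simulate_trials(
    params: DDMParams,
    n: int,
    seed: int,
    max_t: float = 5.0,
    dt: float = 1e-4,
    drifts: Sequence[float] | None = None,
) -> SimulatedTrials:
    """Simulate ``n`` first passages by Euler discretization.

    Each accumulator starts at ``z*a`` and steps by ``v*dt + sqrt(dt)*N(0,1)``
    until it crosses a boundary or the response window ``max_t`` (measured
    from stimulus onset, so the decision window is ``max_t - t0``) runs out;
    unabsorbed trials are flagged censored with ``rt = max_t``.

    ``drifts`` optionally supplies a per-trial mean drift (length ``n``),
    overriding ``params.v`` — used for covariate-informed drift models.
    With ``sv > 0`` each trial's drift is first drawn from ``N(v_i, sv**2)``.
    Identical ``(params, n, seed, max_t, dt, drifts)`` reproduce identical
    output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not max_t > params.t0:
        raise ValueError(f"max_t ({max_t}) must exceed t0 ({params.t0})")
    rng = np.random.default_rng(seed)
    if drifts is None:
        v = np.full(n, params.v, dtype=float)
    else:
        v = np.asarray(drifts, dtype=float)
        if v.shape != (n,):
            raise ValueError("drifts must have length n")
    if params.sv > 0:
        v = rng.normal(v, params.sv)

    n_steps = int(math.ceil((max_t - params.t0) / dt))
    x = np.full(n, params.z * params.a)
    steps = np.zeros(n, dtype=np.int64)
    bound = np.full(n, -1, dtype=np.int8)
    active = np.arange(n)
    sq = math.sqrt(dt)
    for step in range(1, n_steps + 1):
        x[active] += v[active] * dt + sq * rng.standard_normal(active.size)
        hit_lo = x[active] <= 0.0
        hit_up = x[active] >= params.a
        done = hit_lo | hit_up
        if done.any():
            idx = active[done]
            bound[idx] = np.where(hit_lo[done], Boundary.LOWER.value, Boundary.UPPER.value)
            steps[idx] = step
            active = active[~done]
            if active.size == 0:
                break

    censored = bound < 0
    rt = np.where(censored, max_t, params.t0 + steps * dt)
    # decision resolved within the window but total RT would exceed it
    late = (~censored) & (rt > max_t)
    rt[late] = max_t
    return SimulatedTrials(boundary=bound, rt=rt, censored=censored)


def with_drift(params: DDMParams, v: float) -> DDMParams:
    """Copy ``params`` with a different mean drift."""
    return replace(params, v=v)
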