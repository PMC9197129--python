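"""Per-subject maximum-likelihood fitting and BIC model selection.

Trial tables are plain :class:`pandas.DataFrame` objects with one row per
trial and the columns

``subject, trial, stim_type, mirrored, ingroup_A, ingroup_B, outgroup_A,
outgroup_B, compliant_option, response, rt, censored``

where ``response`` is ``"lower"`` (ingroup-compliant) or ``"upper"`` and
``rt`` is in seconds from stimulus onset.

Preprocessing drops timeouts, anticipations (rt < 200 ms) and trials lying
more than three interquartile ranges outside the first/third quartile of
each subject's log-RT distribution.  The likelihood of the kept trials is
the product of defective Wiener first-passage densities at the observed
boundary and time; it is minimized with bounded quasi-Newton (L-BFGS-B)
from several deterministic-seeded start points.  Models are compared by
BIC = k*ln(n) - 2*loglik, with cohort-level selection on subject-mean BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import (
    ModelGroup,
    ModelSpec,
    TrialInfoKind,
)
from .wiener import _lower_density, _scaled_density

__all__ = [
    "TRIAL_COLUMNS",
    "FitOptions",
    "FitResult",
    "preprocess",
    "neg_loglik",
    "fit_subject",
    "fit_cohort",
    "select_model",
    "fits_frame",
]

TRIAL_COLUMNS = (
    "subject",
    "trial",
    "stim_type",
    "mirrored",
    "ingroup_A",
    "ingroup_B",
    "outgroup_A",
    "outgroup_B",
    "compliant_option",
    "response",
    "rt",
    "censored",
)

RT_FLOOR = 0.2  # seconds; anticipatory-response cutoff
IQR_MULTIPLIER = 3.0  # log-RT fence width
_PENALTY = 1e12  # returned for non-finite likelihood evaluations
_DENSITY_FLOOR = 1e-300

Z_FIXED = 0.5
SV_FIXED = 0.0
N_TYPES = 3


# ---------------------------------------------------------------------------
# preprocessing

def preprocess(
    trials: pd.DataFrame,
    rt_floor: float = RT_FLOOR,
    iqr_multiplier: float = IQR_MULTIPLIER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outlier handling, applied separately per subject.

    Drops, in order: censored trials (no response inside the window);
    trials with ``rt < rt_floor``; then trials whose log RT lies outside
    ``[Q1 - m*IQR, Q3 + m*IQR]`` of the subject's remaining log-RT
    distribution.  Returns the kept trials and a per-subject removal report
    (with an ``"overall"`` row).
    """
    if trials.empty:
        warnings.warn("preprocess called with an empty trial table")
        report = pd.DataFrame(
            columns=["subject", "n_in", "n_censored", "n_fast", "n_iqr", "n_kept", "frac_removed"]
        )
        return trials.copy(), report

    kept_parts: list[pd.DataFrame] = []
    rows = []
    for subject, df in trials.groupby("subject", sort=False):
        n_in = len(df)
        if n_in < 10:
            warnings.warn(f"subject {subject!r} has only {n_in} trials")
        resp = df[~df["censored"].astype(bool)]
        fast = resp["rt"] < rt_floor
        slowok = resp[~fast]
        if len(slowok):
            logrt = np.log(slowok["rt"].to_numpy())
            q1, q3 = np.quantile(logrt, [0.25, 0.75])
            iqr = q3 - q1
            lo, hi = q1 - iqr_multiplier * iqr, q3 + iqr_multiplier * iqr
            inside = (logrt >= lo) & (logrt <= hi)
            kept = slowok[inside]
        else:
            kept = slowok
        kept_parts.append(kept)
        rows.append(
            {
                "subject": subject,
                "n_in": n_in,
                "n_censored": n_in - len(resp),
                "n_fast": int(fast.sum()),
                "n_iqr": len(slowok) - len(kept),
                "n_kept": len(kept),
                "frac_removed": 1.0 - len(kept) / n_in,
            }
        )
    report = pd.DataFrame(rows)
    total = {
        "subject": "overall",
        **{c: report[c].sum() for c in ("n_in", "n_censored", "n_fast", "n_iqr", "n_kept")},
    }
    total["frac_removed"] = 1.0 - total["n_kept"] / total["n_in"]
    report = pd.concat([report, pd.DataFrame([total])], ignore_index=True)
    return pd.concat(kept_parts, ignore_index=True), report


# ---------------------------------------------------------------------------
# likelihood

def _info_arrays(df: pd.DataFrame, kind: TrialInfoKind) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial (ingroup, outgroup) information, oriented by compliant option."""
    comp_is_a = (df["compliant_option"] == "A").to_numpy()
    ig_a = df["ingroup_A"].to_numpy(float)
    ig_b = df["ingroup_B"].to_numpy(float)
    og_a = df["outgroup_A"].to_numpy(float)
    og_b = df["outgroup_B"].to_numpy(float)
    ig_c = np.where(comp_is_a, ig_a, ig_b)
    ig_o = np.where(comp_is_a, ig_b, ig_a)
    og_c = np.where(comp_is_a, og_a, og_b)
    og_o = np.where(comp_is_a, og_b, og_a)
    if kind is TrialInfoKind.DIFF:
        return ig_c - ig_o, og_c - og_o
    if kind is TrialInfoKind.RELDIFF:
        return ig_c / (ig_c - ig_o), og_c / (og_c - og_o)
    if kind is TrialInfoKind.RATIO:
        return ig_c / ig_o, og_c / og_o
    if kind is TrialInfoKind.PERCENT:
        return ig_c / (ig_c + ig_o), og_c / (og_c + og_o)
    if kind is TrialInfoKind.DICHOT:
        ingr = (np.maximum(ig_a, ig_b) > np.maximum(og_a, og_b)).astype(float)
        return ingr, 1.0 - ingr
    raise TypeError(f"unknown trial-information kind: {kind!r}")


@dataclass
class _LikelihoodData:
    """Immutable per-subject arrays the likelihood touches on every call."""

    rt: np.ndarray
    lower: np.ndarray  # bool: response at the lower (compliant) boundary
    type_idx: np.ndarray  # stimulus type - 1, in {0, 1, 2}
    ingr: Optional[np.ndarray]  # group-1 covariates (else None)
    outgr: Optional[np.ndarray]
    min_rt: float
    min_rt_by_type: np.ndarray

    @classmethod
    def build(cls, model: ModelSpec, trials: pd.DataFrame) -> "_LikelihoodData":
        if trials["censored"].astype(bool).any():
            raise ValueError("censored trials must be removed before fitting")
        rt = trials["rt"].to_numpy(float)
        lower = (trials["response"] == "lower").to_numpy()
        type_idx = trials["stim_type"].to_numpy(int) - 1
        ingr = outgr = None
        if model.group is ModelGroup.INFO:
            ingr, outgr = _info_arrays(trials, model.info_kind)
        by_type = np.array(
            [rt[type_idx == i].min() if (type_idx == i).any() else rt.min() for i in range(N_TYPES)]
        )
        return cls(rt, lower, type_idx, ingr, outgr, float(rt.min()), by_type)


def _unpack(model: ModelSpec, theta: np.ndarray, data: _LikelihoodData):
    """Map the optimizer vector to per-trial (a, t0, v) arrays plus (z, sv)."""
    vals = dict(zip(model.param_names, theta))
    z = vals.get("z", Z_FIXED)
    sv = vals.get("sv", SV_FIXED)
    if model.group is ModelGroup.INFO:
        a = np.full_like(data.rt, vals["a"])
        t0 = np.full_like(data.rt, vals["t0"])
        v = vals["b0"] + vals["b1"] * data.ingr
        if model.uses_outgroup:
            v = v + vals["b2"] * data.outgr
    else:
        def per_type(base: str) -> np.ndarray:
            if base in model.varying:
                levels = np.array([vals[f"{base}_{i}"] for i in range(1, N_TYPES + 1)])
            else:
                levels = np.full(N_TYPES, vals[base])
            return levels[data.type_idx]

        a, t0, v = per_type("a"), per_type("t0"), per_type("v")
    return a, t0, v, z, sv


def _defective_density(
    t_dec: np.ndarray, a: np.ndarray, w: float | np.ndarray, v: np.ndarray, sv: float
) -> np.ndarray:
    """Lower-boundary defective density with per-trial a and drift."""
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        base = _scaled_density(t_dec / a**2, w) if np.isscalar(w) else None
        if base is None:
            # two start points (observed lower vs upper responses): w is array
            base = np.empty_like(t_dec)
            for wv in np.unique(w):
                m = w == wv
                base[m] = _scaled_density(t_dec[m] / a[m] ** 2, float(wv))
        base = base / a**2
        if sv == 0.0:
            fac = np.exp(-v * a * w - v**2 * t_dec / 2.0)
        else:
            s2t = 1.0 + sv**2 * t_dec
            fac = np.exp(
                ((a * w * sv) ** 2 - 2.0 * v * a * w - v**2 * t_dec) / (2.0 * s2t)
            ) / np.sqrt(s2t)
        out = np.where(t_dec > 0, base * fac, 0.0)
    return np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)


def neg_loglik(model: ModelSpec, theta: Sequence[float], trials: pd.DataFrame) -> float:
    """Negative log-likelihood of preprocessed trials under ``model``.

    Invalid interior evaluations (e.g. an rt at or below the proposed
    non-decision time) contribute a floored log-density instead of raising,
    so the optimizer sees a large finite penalty.
    """
    data = _LikelihoodData.build(model, trials)
    return _neg_loglik_arrays(model, np.asarray(theta, float), data)


def _neg_loglik_arrays(model: ModelSpec, theta: np.ndarray, data: _LikelihoodData) -> float:
    if not np.all(np.isfinite(theta)):
        return _PENALTY
    a, t0, v, z, sv = _unpack(model, theta, data)
    t_dec = data.rt - t0
    # observed lower responses keep (z, v); upper responses reflect to (1-z, -v)
    w = np.where(data.lower, z, 1.0 - z)
    vv = np.where(data.lower, v, -v)
    dens = _defective_density(t_dec, a, w, vv, sv)
    ll = np.log(np.maximum(dens, _DENSITY_FLOOR)).sum()
    if not np.isfinite(ll):
        return _PENALTY
    return -float(ll)


# ---------------------------------------------------------------------------
# estimation

@dataclass(frozen=True)
class FitOptions:
    """Options for :func:`fit_subject`.

    ``restarts`` counts start points: one heuristic start plus
    ``restarts - 1`` uniform draws inside the bounds, seeded by ``seed``.
    """

    restarts: int = 5
    seed: int = 0
    maxiter: int = 2000
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)


_DEFAULT_BOUNDS = {
    "a": (0.3, 5.0),
    "z": (0.05, 0.95),
    "sv": (0.0, 5.0),
}
_DRIFT_BOUNDS = (-20.0, 20.0)
_T0_LOWER = 0.05


def _bounds_for(model: ModelSpec, data: _LikelihoodData, options: FitOptions):
    out = []
    for name in model.param_names:
        if name in options.bounds:
            out.append(tuple(options.bounds[name]))
            continue
        base = name.split("_")[0]
        if base in _DEFAULT_BOUNDS:
            out.append(_DEFAULT_BOUNDS[base])
        elif base == "t0":
            if "_" in name:  # type-specific non-decision time
                i = int(name.split("_")[1]) - 1
                hi = data.min_rt_by_type[i] - 0.01
            else:
                hi = data.min_rt - 0.01
            out.append((_T0_LOWER, max(hi, _T0_LOWER + 1e-3)))
        else:  # drift rates and drift coefficients
            out.append(_DRIFT_BOUNDS)
    return out


def _start_points(
    model: ModelSpec, data: _LikelihoodData, bounds, options: FitOptions
) -> list[np.ndarray]:
    heuristic = []
    for name, (lo, hi) in zip(model.param_names, bounds):
        base = name.split("_")[0]
        if base == "a":
            x = 1.5
        elif base == "t0":
            x = 0.9 * data.min_rt
        elif base == "z":
            x = 0.5
        elif base == "sv":
            x = 0.3
        else:
            x = 0.0
        heuristic.append(float(np.clip(x, lo + 1e-6, hi - 1e-6)))
    starts = [np.array(heuristic)]
    rng = np.random.default_rng(options.seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    for _ in range(max(options.restarts - 1, 0)):
        starts.append(rng.uniform(lo + 1e-6, hi - 1e-6))
    return starts


@dataclass(frozen=True)
class FitResult:
    """One (subject, model) maximum-likelihood fit."""

    subject: object
    model: ModelSpec
    estimates: dict
    loglik: float
    k: int
    n: int
    bic: float
    converged: bool
    n_restarts_used: int

    def estimate(self, name: str) -> float:
        return self.estimates[name]


def fit_subject(
    model: ModelSpec,
    trials: pd.DataFrame,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Fit one model to one subject's preprocessed trials by bounded ML.

    Runs L-BFGS-B from each start point and keeps the best converged
    solution (best penalized value with ``converged=False`` if none
    converges).  Deterministic given (trials, model, options).
    """
    subjects = trials["subject"].unique()
    if len(subjects) != 1:
        raise ValueError(f"fit_subject expects one subject, got {list(subjects)}")
    n = len(trials)
    if n < 50:
        warnings.warn(f"subject {subjects[0]!r}: only {n} trials; estimates may be unstable")
    data = _LikelihoodData.build(model, trials)
    bounds = _bounds_for(model, data, options)

    best = None
    best_ok = False
    for x0 in _start_points(model, data, bounds, options):
        res = minimize(
            lambda th: _neg_loglik_arrays(model, th, data),
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": options.maxiter},
        )
        ok = bool(res.success) and np.isfinite(res.fun) and res.fun < _PENALTY / 2
        if best is None or (ok and not best_ok) or (ok == best_ok and res.fun < best.fun):
            best, best_ok = res, ok

    loglik = -float(best.fun)
    k = model.k
    return FitResult(
        subject=subjects[0],
        model=model,
        estimates=dict(zip(model.param_names, map(float, best.x))),
        loglik=loglik,
        k=k,
        n=n,
        bic=k * np.log(n) - 2.0 * loglik,
        converged=best_ok,
        n_restarts_used=options.restarts,
    )


def fit_cohort(
    models: Iterable[ModelSpec],
    trials: pd.DataFrame,
    options: FitOptions = FitOptions(),
) -> list[FitResult]:
    """Fit every model to every subject; subject-specific restart seeds."""
    results = []
    for s_i, (subject, df) in enumerate(trials.groupby("subject", sort=False)):
        sub_options = FitOptions(
            restarts=options.restarts,
            seed=options.seed + 1000 * s_i,
            maxiter=options.maxiter,
            bounds=options.bounds,
        )
        for model in models:
            results.append(fit_subject(model, df, sub_options))
    return results


# ---------------------------------------------------------------------------
# selection

def select_model(fits: Sequence[FitResult]) -> dict[ModelGroup, ModelSpec]:
    """Lowest-BIC model per model group.

    With several subjects per model, compares subject-mean BIC (the
    cohort-level convention).  Non-converged fits are excluded with a
    warning.  Ties break by fewer free parameters, then lower model id.
    """
    usable = [f for f in fits if f.converged]
    dropped = len(fits) - len(usable)
    if dropped:
        warnings.warn(f"excluding {dropped} non-converged fits from selection")
    if not usable:
        raise ValueError("no converged fits to select from")
    by_model: dict[int, list[FitResult]] = {}
    for f in usable:
        by_model.setdefault(f.model.id, []).append(f)
    winners: dict[ModelGroup, ModelSpec] = {}
    for group in ModelGroup:
        candidates = [
            (float(np.mean([f.bic for f in fs])), fs[0].model.k, mid, fs[0].model)
            for mid, fs in by_model.items()
            if fs[0].model.group is group
        ]
        if candidates:
            winners[group] = min(candidates)[3]
    return winners


def fits_frame(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Fit results as a flat table: one row per (subject, model)."""
    rows = []
    for f in fits:
        row = {
            "subject": f.subject,
            "model": f.model.id,
            "group": f.model.group.value,
            "loglik": f.loglik,
            "k": f.k,
            "n": f.n,
            "bic": f.bic,
            "converged": f.converged,
            "n_restarts_used": f.n_restarts_used,
        }
        row.update(f.estimates)
        rows.append(row)
    return pd.DataFrame(rows)
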