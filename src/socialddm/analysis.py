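"""Behavioural summaries, strategy classification, power, goodness of fit.

The behavioural summary mirrors the study's descriptive table: per stimulus
type, the proportion of ingroup-compliant choices and the compliant /
non-compliant response-time statistics, computed per subject first and then
aggregated across subjects (the subject is the unit of analysis).

The strategy rule classifies a subject by their compliant fraction on
stimulus type 2 — the only type that forces a choice between following the
ingroup and choosing the equality option: 50% or less compliant there means
"equality driven", more than 50% "ingroup driven".

The sensitivity power computation inverts the exact noncentral-t power
function of the two-sided paired/one-sample t test to find the smallest
standardized effect detectable at given n, alpha and power.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .cohort import Strategy
from .fitting import FitResult, _LikelihoodData, _defective_density, _unpack

__all__ = [
    "summarize_behavior",
    "classify_subjects",
    "min_detectable_d",
    "quantile_gof",
    "quantile_gof_cohort",
]

GOF_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)


# ---------------------------------------------------------------------------
# behavioural summaries

def _subject_type_stats(df: pd.DataFrame) -> list[dict]:
    rows = []
    for (subject, stim_type), cell in df.groupby(["subject", "stim_type"]):
        responded = cell[~cell["censored"].astype(bool)]
        if responded.empty:
            warnings.warn(
                f"subject {subject!r} has no responses on stimulus type {stim_type}; cell omitted"
            )
            continue
        compliant = responded[responded["response"] == "lower"]
        noncompliant = responded[responded["response"] == "upper"]
        row = {
            "subject": subject,
            "stim_type": stim_type,
            "p_compliant": len(compliant) / len(responded),
        }
        for name, part in (("compliant", compliant), ("noncompliant", noncompliant)):
            if part.empty:
                row[f"rt_{name}_mean"] = np.nan
                row[f"rt_{name}_median"] = np.nan
            else:
                row[f"rt_{name}_mean"] = part["rt"].mean()
                row[f"rt_{name}_median"] = part["rt"].median()
        rows.append(row)
    return rows


def summarize_behavior(
    trials: pd.DataFrame, labels: Optional[pd.Series] = None
) -> pd.DataFrame:
    """Per-type behavioural summary, aggregated with the subject as unit.

    Returns one row per (group, stimulus type) with the cross-subject mean
    and SD of the per-subject compliant proportion and RT statistics.  With
    ``labels`` (a subject-indexed strategy Series) the summary is emitted
    for all participants and for each strategy group; without it only the
    all-participants block is produced.
    """
    per_subject = pd.DataFrame(_subject_type_stats(trials))
    if per_subject.empty:
        return per_subject

    def block(sub: pd.DataFrame, group: str) -> pd.DataFrame:
        stat_cols = [c for c in sub.columns if c not in ("subject", "stim_type")]
        agg = sub.groupby("stim_type")[stat_cols].agg(["mean", "std"])
        agg.columns = [f"{a}_{b}" for a, b in agg.columns]
        agg = agg.reset_index()
        agg.insert(0, "group", group)
        agg.insert(2, "n_subjects", sub.groupby("stim_type")["subject"].nunique().values)
        return agg

    out = [block(per_subject, "all")]
    if labels is not None:
        for strategy, members in labels.groupby(labels):
            sub = per_subject[per_subject["subject"].isin(members.index)]
            if not sub.empty:
                out.append(block(sub, str(strategy)))
    return pd.concat(out, ignore_index=True)


def classify_subjects(trials: pd.DataFrame) -> pd.Series:
    """Assign each subject a strategy from type-2 compliant behaviour.

    Compliant fraction (among responded type-2 trials) <= 0.5 means
    equality driven, > 0.5 ingroup driven.  Subjects with no type-2 trials
    are left out with a warning.  Invariant to trial order and to trials of
    other types.
    """
    labels = {}
    for subject, df in trials.groupby("subject", sort=False):
        t2 = df[(df["stim_type"] == 2) & ~df["censored"].astype(bool)]
        if t2.empty:
            warnings.warn(f"subject {subject!r} has no type-2 responses; unclassified")
            continue
        frac = (t2["response"] == "lower").mean()
        labels[subject] = (
            Strategy.EQUALITY_DRIVEN if frac <= 0.5 else Strategy.INGROUP_DRIVEN
        )
    return pd.Series(labels, name="strategy")


# ---------------------------------------------------------------------------
# sensitivity power analysis

def _t_power(d: float, n: int, alpha: float) -> float:
    """Power of the two-sided one-sample/paired t test at effect size d."""
    df = n - 1
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    nc = d * np.sqrt(n)
    upper = stats.nct.sf(tcrit, df, nc)
    lower = stats.nct.cdf(-tcrit, df, nc)
    # scipy's noncentral t loses accuracy deep in the tails; the limits are known
    if np.isnan(upper):
        upper = 1.0 if nc > tcrit else 0.0
    if np.isnan(lower):
        lower = 0.0
    return float(upper + lower)


def min_detectable_d(n: int, alpha: float = 0.05, power: float = 0.80) -> float:
    """Smallest Cohen's d a paired t test of size ``n`` detects.

    Solves power(d) = ``power`` for the two-sided test at level ``alpha``
    with ``n - 1`` degrees of freedom and noncentrality ``d * sqrt(n)``,
    using the exact noncentral t distribution and root bracketing.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ValueError("alpha and power must lie in (0, 1)")
    if power <= alpha:
        # the test rejects at rate alpha under the null already
        return 0.0
    hi = 1.0
    while _t_power(hi, n, alpha) < power:
        hi *= 2.0
        if hi > 1e3:
            raise ValueError(f"power {power} unattainable at n={n}, alpha={alpha}")
    return float(brentq(lambda d: _t_power(d, n, alpha) - power, 0.0, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# quantile goodness of fit

def quantile_gof(
    fit: FitResult,
    trials: pd.DataFrame,
    quantiles: Sequence[float] = GOF_QUANTILES,
    t_max: float = 10.0,
    grid_size: int = 1024,
) -> pd.DataFrame:
    """Observed vs model-predicted compliant-RT quantiles per stimulus type.

    Predicted quantiles come from numerical inversion of the fitted
    defective CDF at the lower (compliant) boundary, normalized within that
    response; for covariate-drift models the CDF is the mixture over the
    type's trials.  Observed quantiles are empirical quantiles of the
    compliant RTs.  Refuses non-converged fits.
    """
    if not fit.converged:
        raise ValueError(f"fit of model {fit.model.id} for subject {fit.subject} did not converge")
    sub = trials[trials["subject"] == fit.subject]
    if sub.empty:
        raise ValueError(f"no trials for subject {fit.subject!r}")
    data = _LikelihoodData.build(fit.model, sub)
    theta = np.array([fit.estimates[p] for p in fit.model.param_names])
    a, t0, v, z, sv = _unpack(fit.model, theta, data)

    rows = []
    for stim_type in sorted(sub["stim_type"].unique()):
        mask = data.type_idx == stim_type - 1
        obs_rt = data.rt[mask & data.lower]
        if obs_rt.size == 0:
            warnings.warn(
                f"subject {fit.subject!r}: no compliant responses on type {stim_type}"
            )
            continue
        t0_min = float(t0[mask].min())
        grid = np.linspace(t0_min, t_max, grid_size)
        dens = np.zeros_like(grid)
        # mixture of the type's per-trial defective densities at the lower boundary
        am, vm, t0m = a[mask], v[mask], t0[mask]
        for i in range(am.size):
            td = grid - t0m[i]
            dens += _defective_density(td, np.full_like(td, am[i]), z, np.full_like(td, vm[i]), sv)
        dens /= am.size
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0 * np.diff(grid))])
        p_lower = cdf[-1]
        cond = cdf / p_lower
        for q in quantiles:
            pred = float(np.interp(q, cond, grid))
            rows.append(
                {
                    "subject": fit.subject,
                    "stim_type": stim_type,
                    "quantile": q,
                    "observed": float(np.quantile(obs_rt, q)),
                    "predicted": pred,
                    "n_observed": int(obs_rt.size),
                    "p_compliant_predicted": float(p_lower),
                }
            )
    return pd.DataFrame(rows)


def quantile_gof_cohort(
    fits: Sequence[FitResult],
    trials: pd.DataFrame,
    quantiles: Sequence[float] = GOF_QUANTILES,
) -> pd.DataFrame:
    """Cross-subject mean and SD of per-subject observed/predicted quantiles."""
    parts = [quantile_gof(f, trials, quantiles) for f in fits]
    per_subject = pd.concat(parts, ignore_index=True)
    agg = (
        per_subject.groupby(["stim_type", "quantile"])[["observed", "predicted"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    agg.columns = ["_".join(c).rstrip("_") for c in agg.columns]
    return agg
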