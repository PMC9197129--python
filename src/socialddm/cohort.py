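"""Synthetic participants with the generative structure the analysis assumes.

Two behavioural strategies are emulated, in the empirically observed mix of
28 "ingroup driven" to 11 "equality driven" subjects out of 39:

* **Ingroup driven** agents drift toward the compliant (lower) boundary on
  every stimulus type, most strongly on type 1 where the ingroup preference
  is most obvious (all three drifts negative, ordered by magnitude).
* **Equality driven** agents drift toward the *non*-compliant boundary on
  type 2 — where the compliant and the equality option conflict — and
  toward the compliant boundary on types 1 and 3 (positive type-2 drift).

Per-subject parameters are drawn uniformly from strategy-specific boxes
centred on the fitted subgroup estimates of the stimulus-type drift model
(boundary separation near 2, non-decision time near 0.32 s, start point
near 0.5, drifts near (-2.0, -1.6, -0.9) for ingroup driven and
(-0.4, +1.0, -1.2) for equality driven).  The boxes are configuration, not
hard-coded: only point estimates are available empirically, so the widths
are a modelling choice.

A covariate-informed agent (drift linear in the compliant option's ingroup
and outgroup donor shares) generates data for selection-recovery runs on
the covariate model family.

All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .design import SessionPlan, build_session, session_frame
from .fitting import (
    FitOptions,
    fit_cohort,
    fits_frame,
    preprocess,
    select_model,
)
from .models import (
    DriftCoefficients,
    ModelGroup,
    TrialInfoKind,
    drift_value,
    get_model,
)
from .wiener import DDMParams, simulate_trials

__all__ = [
    "Strategy",
    "AgentBoxes",
    "Group1Boxes",
    "AgentSpec",
    "Group1AgentSpec",
    "make_agent",
    "make_group1_agent",
    "simulate_subject",
    "simulate_cohort",
    "RecoveryConfig",
    "recovery_experiment",
]

DEFAULT_N_INGROUP = 28
DEFAULT_N_EQUALITY = 11
RESPONSE_WINDOW = 5.0
DEFAULT_DT = 1e-4


class Strategy:
    INGROUP_DRIVEN = "ingroup_driven"
    EQUALITY_DRIVEN = "equality_driven"


@dataclass(frozen=True)
class AgentBoxes:
    """Uniform sampling boxes for stimulus-type-drift agents.

    Drift boxes are (low, high) per stimulus type, centred on the fitted
    subgroup means.  The ingroup-driven boxes are +/- 0.8 wide — the
    between-subject drift heterogeneity implied by how far the subgroup
    estimates sit apart — and draws are re-ordered by magnitude so the
    strategy invariant |v1| >= |v2| >= |v3| holds for every agent.  The
    equality-driven boxes respect the sign pattern (v2 > 0, v1 and v3 <= 0)
    for every draw.
    """

    a: tuple[float, float] = (1.7, 2.3)
    t0: tuple[float, float] = (0.27, 0.40)
    z: tuple[float, float] = (0.42, 0.55)
    sv: float = 0.0
    ingroup_drifts: tuple[tuple[float, float], ...] = (
        (-2.8, -1.2),
        (-2.4, -0.8),
        (-1.7, -0.1),
    )
    equality_drifts: tuple[tuple[float, float], ...] = (
        (-0.8, -0.05),
        (0.6, 1.4),
        (-1.6, -0.8),
    )


@dataclass(frozen=True)
class Group1Boxes:
    """Sampling boxes for covariate-drift agents (percentage information),
    centred on the aggregate fitted coefficients (b0 1.92, b1 -2.82,
    b2 -1.11)."""

    a: tuple[float, float] = (1.8, 2.2)
    t0: tuple[float, float] = (0.28, 0.38)
    z: tuple[float, float] = (0.44, 0.52)
    sv: float = 0.0
    beta0: tuple[float, float] = (1.5, 2.3)
    beta1: tuple[float, float] = (-3.2, -2.4)
    beta2: tuple[float, float] = (-1.5, -0.7)


@dataclass(frozen=True)
class AgentSpec:
    """One simulated participant: shared (a, z, t0, sv), type-specific drift."""

    strategy: str
    a: float
    z: float
    t0: float
    sv: float
    drifts: tuple[float, float, float]  # mean drift per stimulus type
    seed: int

    def params_for_type(self, stim_type: int) -> DDMParams:
        return DDMParams(
            a=self.a, z=self.z, t0=self.t0, v=self.drifts[stim_type - 1], sv=self.sv
        )


@dataclass(frozen=True)
class Group1AgentSpec:
    """A covariate-drift participant: drift linear in the trial information."""

    coeffs: DriftCoefficients
    info_kind: TrialInfoKind
    a: float
    z: float
    t0: float
    sv: float
    seed: int


def make_agent(strategy: str, seed: int, boxes: AgentBoxes = AgentBoxes()) -> AgentSpec:
    """Draw one agent's parameters uniformly from the strategy's boxes."""
    rng = np.random.default_rng(seed)
    if strategy == Strategy.INGROUP_DRIVEN:
        drift_boxes = boxes.ingroup_drifts
    elif strategy == Strategy.EQUALITY_DRIVEN:
        drift_boxes = boxes.equality_drifts
    else:
        raise ValueError(f"unknown strategy: {strategy!r}")
    drifts = [rng.uniform(lo, hi) for lo, hi in drift_boxes]
    if strategy == Strategy.INGROUP_DRIVEN:
        # enforce the strategy's difficulty ordering |v1| >= |v2| >= |v3|
        drifts = sorted(drifts)
    return AgentSpec(
        strategy=strategy,
        a=rng.uniform(*boxes.a),
        z=rng.uniform(*boxes.z),
        t0=rng.uniform(*boxes.t0),
        sv=boxes.sv,
        drifts=tuple(drifts),
        seed=seed,
    )


def make_group1_agent(
    seed: int,
    boxes: Group1Boxes = Group1Boxes(),
    info_kind: TrialInfoKind = TrialInfoKind.PERCENT,
    uses_outgroup: bool = True,
) -> Group1AgentSpec:
    """Draw one covariate-drift agent (percentage information by default)."""
    rng = np.random.default_rng(seed)
    return Group1AgentSpec(
        coeffs=DriftCoefficients(
            beta0=rng.uniform(*boxes.beta0),
            beta1=rng.uniform(*boxes.beta1),
            beta2=rng.uniform(*boxes.beta2) if uses_outgroup else None,
        ),
        info_kind=info_kind,
        a=rng.uniform(*boxes.a),
        z=rng.uniform(*boxes.z),
        t0=rng.uniform(*boxes.t0),
        sv=boxes.sv,
        seed=seed,
    )


def simulate_subject(
    agent: AgentSpec | Group1AgentSpec,
    session: SessionPlan,
    subject: object = 0,
    dt: float = DEFAULT_DT,
    contamination_rate: float = 0.0,
) -> pd.DataFrame:
    """Simulate one session: one first passage per trial, 5 s window.

    Lower-boundary passages are recorded as compliant responses
    (``response == "lower"``); trials not absorbed within the response
    window are censored with ``rt`` equal to the window.  The optional
    contamination replaces trials, at the given rate, with uniform fast
    guesses (rt ~ U(0.05, 0.3) s, random response) to exercise the outlier
    filters; it is off by default.
    """
    if isinstance(agent, Group1AgentSpec):
        drifts = np.array(
            [drift_value(agent.coeffs, s, agent.info_kind) for s in session.trials]
        )
    else:
        drifts = np.array([agent.drifts[s.stim_type - 1] for s in session.trials])
    base = DDMParams(a=agent.a, z=agent.z, t0=agent.t0, v=0.0, sv=agent.sv)
    sim = simulate_trials(
        base,
        n=len(session.trials),
        seed=agent.seed + 1,
        max_t=session.response_window,
        dt=dt,
        drifts=drifts,
    )
    df = session_frame(session)
    df.insert(0, "subject", subject)
    df["response"] = np.where(sim.censored, "none", np.where(sim.boundary == 0, "lower", "upper"))
    df["rt"] = sim.rt
    df["censored"] = sim.censored
    if contamination_rate > 0:
        rng = np.random.default_rng(agent.seed + 2)
        guess = rng.random(len(df)) < contamination_rate
        df.loc[guess, "rt"] = rng.uniform(0.05, 0.3, int(guess.sum()))
        df.loc[guess, "response"] = rng.choice(["lower", "upper"], int(guess.sum()))
        df.loc[guess, "censored"] = False
    return df


def _child_seeds(master_seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(master_seed)
    return rng.integers(0, 2**31 - 1, size=n)


def simulate_cohort(
    n_ingroup: int = DEFAULT_N_INGROUP,
    n_equality: int = DEFAULT_N_EQUALITY,
    master_seed: int = 0,
    boxes: AgentBoxes = AgentBoxes(),
    dt: float = DEFAULT_DT,
    contamination_rate: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; defaults give the 39-subject 28:11 mix.

    Returns ``(trials, truth)``: the concatenated trial table and a
    per-subject table of true strategies and parameters.  Deterministic
    given ``master_seed``.
    """
    strategies = [Strategy.INGROUP_DRIVEN] * n_ingroup + [Strategy.EQUALITY_DRIVEN] * n_equality
    seeds = _child_seeds(master_seed, 2 * len(strategies))
    trial_parts, truth_rows = [], []
    for i, strategy in enumerate(strategies):
        subject = f"s{i + 1:02d}"
        agent = make_agent(strategy, int(seeds[2 * i]), boxes)
        session = build_session(int(seeds[2 * i + 1]))
        trial_parts.append(
            simulate_subject(agent, session, subject=subject, dt=dt,
                             contamination_rate=contamination_rate)
        )
        truth_rows.append(
            {
                "subject": subject,
                "strategy": strategy,
                "a": agent.a,
                "z": agent.z,
                "t0": agent.t0,
                "sv": agent.sv,
                "v_1": agent.drifts[0],
                "v_2": agent.drifts[1],
                "v_3": agent.drifts[2],
                "agent_seed": agent.seed,
                "session_seed": session.seed,
            }
        )
    return pd.concat(trial_parts, ignore_index=True), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# recovery experiments

@dataclass(frozen=True)
class RecoveryConfig:
    """Configuration of one simulate -> preprocess -> fit -> select run.

    ``generating_model`` is 35-style (stimulus-type drifts; agents drawn
    from the ingroup-driven boxes) or 22-style (covariate drift with
    percentage information).  ``candidate_ids`` are the models fitted to
    every simulated subject.
    """

    generating_model: int = 35
    candidate_ids: tuple[int, ...] = (34, 35, 46)
    n_subjects: int = 6
    n_replicates: int = 1
    seed: int = 0
    restarts: int = 3
    dt: float = DEFAULT_DT
    n_ingroup: Optional[int] = None  # mixed-strategy cohort if set
    n_equality: Optional[int] = None


def _simulate_generating(config: RecoveryConfig, rep_seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    gen = get_model(config.generating_model)
    if gen.group is ModelGroup.STANDARD:
        n_in = config.n_subjects if config.n_ingroup is None else config.n_ingroup
        n_eq = 0 if config.n_equality is None else config.n_equality
        return simulate_cohort(n_in, n_eq, master_seed=rep_seed, dt=config.dt)
    seeds = _child_seeds(rep_seed, 2 * config.n_subjects)
    parts, rows = [], []
    for i in range(config.n_subjects):
        subject = f"s{i + 1:02d}"
        agent = make_group1_agent(int(seeds[2 * i]), uses_outgroup=gen.uses_outgroup,
                                  info_kind=gen.info_kind)
        session = build_session(int(seeds[2 * i + 1]))
        parts.append(simulate_subject(agent, session, subject=subject, dt=config.dt))
        rows.append(
            {
                "subject": subject,
                "strategy": "group1",
                "a": agent.a,
                "z": agent.z,
                "t0": agent.t0,
                "sv": agent.sv,
                "b0": agent.coeffs.beta0,
                "b1": agent.coeffs.beta1,
                "b2": agent.coeffs.beta2,
            }
        )
    return pd.concat(parts, ignore_index=True), pd.DataFrame(rows)


def recovery_experiment(config: RecoveryConfig) -> dict:
    """Run seeded replicates of the full pipeline and report recovery.

    Each replicate simulates a cohort under the generating model,
    preprocesses it, fits every candidate model per subject, and selects by
    subject-mean BIC.  The report carries the per-replicate winners, all
    fits, parameter-recovery errors for fits of the generating model
    itself, and — for mixed-strategy cohorts — classification accuracy of
    the type-2 compliance rule.  Per-subject fitting failures surface as
    non-converged fits, never as exceptions.
    """
    from .analysis import classify_subjects  # late import: analysis uses fitting

    rep_seeds = _child_seeds(config.seed, config.n_replicates)
    winners, all_fits, recovery_rows, accuracies = [], [], [], []
    for r, rep_seed in enumerate(map(int, rep_seeds)):
        trials, truth = _simulate_generating(config, rep_seed)
        kept, _ = preprocess(trials)
        models = [get_model(i) for i in config.candidate_ids]
        fits = fit_cohort(models, kept, FitOptions(restarts=config.restarts, seed=rep_seed))
        all_fits.extend(fits)
        best = select_model(fits)
        winners.append({g.name: m.id for g, m in best.items()} | {"replicate": r})
        gen = get_model(config.generating_model)
        truth_idx = truth.set_index("subject")
        for f in fits:
            if f.model.id != gen.id or not f.converged:
                continue
            for name, est in f.estimates.items():
                true_col = name if name in truth_idx.columns else None
                if true_col is None and name == "z":
                    true_col = "z"
                if true_col is not None:
                    recovery_rows.append(
                        {
                            "replicate": r,
                            "subject": f.subject,
                            "param": name,
                            "true": float(truth_idx.loc[f.subject, true_col]),
                            "estimated": est,
                        }
                    )
        if (truth["strategy"] == Strategy.EQUALITY_DRIVEN).any():
            labels = classify_subjects(kept)
            merged = truth_idx.join(labels.rename("assigned"))
            accuracies.append(float((merged["assigned"] == merged["strategy"]).mean()))
    report = {
        "config": config,
        "winners": pd.DataFrame(winners),
        "fits": fits_frame(all_fits),
        "recovery": pd.DataFrame(recovery_rows),
        "classification_accuracy": accuracies,
    }
    return report
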