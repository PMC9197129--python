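"""Trial-information functions, drift decomposition, and the model space.

Two families of drift-diffusion model variants are fitted per subject:

* **Covariate-informed models (group 1, ids 1-30).**  The drift on each
  trial is a linear function of information extracted from the stimulus
  table, ``v = b0 + b1 * ingr_info`` or ``v = b0 + b1 * ingr_info +
  b2 * outgr_info``, for each of five ways of reducing a row of the 2x2
  table to a number (direct difference, relative difference, ratio,
  percentage, dichotomous).

* **Stimulus-type models (group 2, ids 31-51).**  A standard DDM whose
  boundary separation, non-decision time and/or drift vary freely over the
  three stimulus types.

Within each family every variant appears under three fixation schemes —
drift variability ``sv`` free with start point ``z`` fixed at 0.5, ``z``
free with ``sv`` fixed at 0, or both fixed — giving 30 + 21 = 51 models.

Covariate orientation: the response boundaries are compliant/non-compliant,
so in every information formula ``A`` denotes the *compliant* option's cell
and ``B`` the other option's cell, separately for the ingroup row
(``ingr_info``) and the outgroup row (``outgr_info``).  This is the only
orientation under which a single coefficient keeps one meaning across
trials.  With the percentage information, a negative ``b1`` therefore means:
the larger the compliant option's share of ingroup donors, the more the
drift points at the lower (compliant) boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import pandas as pd

from .design import StimulusTable

__all__ = [
    "TrialInfoKind",
    "GroupRow",
    "ModelGroup",
    "DriftCoefficients",
    "ModelSpec",
    "trial_info",
    "dichot_info",
    "stimulus_info",
    "drift_value",
    "enumerate_models",
    "get_model",
    "model_table",
]


class TrialInfoKind(Enum):
    """The five ways of extracting a number from a table row (A, B)."""

    DIFF = "A-B"
    RELDIFF = "A/(A-B)"
    RATIO = "A/B"
    PERCENT = "A/(A+B)"
    DICHOT = "1 or 0"


class GroupRow(Enum):
    INGROUP = "ingroup"
    OUTGROUP = "outgroup"


class ModelGroup(Enum):
    INFO = 1  # covariate-informed drift, ids 1-30
    STANDARD = 2  # type-varying standard DDM, ids 31-51


@dataclass(frozen=True)
class DriftCoefficients:
    """Linear drift decomposition weights.

    ``beta2`` is ``None`` for models that ignore the outgroup row.
    """

    beta0: float
    beta1: float
    beta2: Optional[float] = None


def trial_info(kind: TrialInfoKind, count_A: float, count_B: float) -> float:
    """Reduce one table row to a number: A-B, A/(A-B), A/B or A/(A+B).

    The dichotomous kind is a property of the whole table, not of one row;
    use :func:`dichot_info` for it.
    """
    if count_A < 0 or count_B < 0:
        raise ValueError("donor counts must be >= 0")
    if kind is TrialInfoKind.DIFF:
        return float(count_A - count_B)
    if kind is TrialInfoKind.RELDIFF:
        if count_A == count_B:
            raise ValueError(
                f"relative difference A/(A-B) undefined for A == B == {count_A}"
            )
        return count_A / (count_A - count_B)
    if kind is TrialInfoKind.RATIO:
        if count_B == 0:
            raise ValueError(f"ratio A/B undefined for B == 0 (A = {count_A})")
        return count_A / count_B
    if kind is TrialInfoKind.PERCENT:
        if count_A + count_B == 0:
            raise ValueError("percentage A/(A+B) undefined for A == B == 0")
        return count_A / (count_A + count_B)
    if kind is TrialInfoKind.DICHOT:
        raise ValueError("dichotomous information is table-level; use dichot_info")
    raise TypeError(f"unknown trial-information kind: {kind!r}")


def dichot_info(table: StimulusTable, group_row: GroupRow) -> int:
    """1 if the largest cell of the 2x2 table lies in ``group_row``, else 0."""
    ig = max(table.ingroup_A, table.ingroup_B)
    og = max(table.outgroup_A, table.outgroup_B)
    if ig == og:
        raise ValueError(
            f"table maximum {ig} shared by both rows: dichotomous coding undefined"
        )
    in_ingroup = ig > og
    return int(in_ingroup if group_row is GroupRow.INGROUP else not in_ingroup)


def stimulus_info(
    stimulus: StimulusTable, kind: TrialInfoKind
) -> tuple[float, float]:
    """(ingroup, outgroup) trial information, oriented by the compliant option.

    ``A`` is the compliant option's cell and ``B`` the other option's cell in
    each row.  For the dichotomous kind the ingroup value is the table-wide
    maximum-row indicator and the outgroup value its complement.
    """
    if kind is TrialInfoKind.DICHOT:
        ingr = dichot_info(stimulus, GroupRow.INGROUP)
        return float(ingr), float(1 - ingr)
    comp = stimulus.compliant_option
    other = "B" if comp == "A" else "A"
    ingr = trial_info(kind, stimulus.cell("ingroup", comp), stimulus.cell("ingroup", other))
    outgr = trial_info(
        kind, stimulus.cell("outgroup", comp), stimulus.cell("outgroup", other)
    )
    return ingr, outgr


def drift_value(
    coeffs: DriftCoefficients, stimulus: StimulusTable, kind: TrialInfoKind
) -> float:
    """Mean drift for one trial: ``b0 + b1*ingr_info (+ b2*outgr_info)``."""
    ingr, outgr = stimulus_info(stimulus, kind)
    v = coeffs.beta0 + coeffs.beta1 * ingr
    if coeffs.beta2 is not None:
        v += coeffs.beta2 * outgr
    return v


# ---------------------------------------------------------------------------
# model-space enumeration

# (z_free, sv_free) in enumeration order: sv free / z free / both fixed
_FIXATION_SCHEMES = ((False, True), (True, False), (False, False))

_INFO_ORDER = (
    TrialInfoKind.DIFF,
    TrialInfoKind.RELDIFF,
    TrialInfoKind.RATIO,
    TrialInfoKind.PERCENT,
    TrialInfoKind.DICHOT,
)

_VARYING_ORDER = (
    ("a",),
    ("v",),
    ("t0",),
    ("a", "v"),
    ("a", "t0"),
    ("t0", "v"),
    ("a", "t0", "v"),
)

N_STIM_TYPES = 3


@dataclass(frozen=True)
class ModelSpec:
    """One of the 51 enumerated model variants.

    Fixed values when not free: ``z = 0.5`` and ``sv = 0``.
    """

    id: int
    group: ModelGroup
    z_free: bool
    sv_free: bool
    info_kind: Optional[TrialInfoKind] = None  # group 1 only
    uses_outgroup: bool = False  # group 1 only
    varying: frozenset = frozenset()  # group 2 only, subset of {a, t0, v}

    def __post_init__(self) -> None:
        if self.group is ModelGroup.INFO and self.info_kind is None:
            raise ValueError("covariate models need an information kind")
        if self.group is ModelGroup.STANDARD and not self.varying <= {"a", "t0", "v"}:
            raise ValueError(f"varying must be a subset of {{a, t0, v}}: {self.varying}")

    @property
    def param_names(self) -> tuple[str, ...]:
        """Ordered names of the free parameters (the optimizer's vector)."""
        names: list[str] = []
        if self.group is ModelGroup.INFO:
            names += ["a", "t0", "b0", "b1"]
            if self.uses_outgroup:
                names.append("b2")
        else:
            for base in ("a", "t0", "v"):
                if base in self.varying:
                    names += [f"{base}_{i}" for i in range(1, N_STIM_TYPES + 1)]
                else:
                    names.append(base)
        if self.z_free:
            names.append("z")
        if self.sv_free:
            names.append("sv")
        return tuple(names)

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.param_names)

    def describe(self) -> str:
        fixed = [n for n, f in (("z", self.z_free), ("sv", self.sv_free)) if not f]
        parts = [f"model {self.id}", "group " + str(self.group.value)]
        if self.group is ModelGroup.INFO:
            parts.append(f"info {self.info_kind.value}")
            parts.append("b1+b2" if self.uses_outgroup else "b1")
        elif self.varying:
            parts.append("varying " + "+".join(sorted(self.varying)))
        if fixed:
            parts.append("fixed " + "+".join(fixed))
        return ", ".join(parts)


def enumerate_models(group: ModelGroup) -> list[ModelSpec]:
    """The model space in canonical id order (30 covariate + 21 standard)."""
    specs: list[ModelSpec] = []
    if group is ModelGroup.INFO:
        next_id = 1
        for kind in _INFO_ORDER:
            for z_free, sv_free in _FIXATION_SCHEMES:
                for uses_outgroup in (False, True):
                    specs.append(
                        ModelSpec(
                            id=next_id,
                            group=group,
                            z_free=z_free,
                            sv_free=sv_free,
                            info_kind=kind,
                            uses_outgroup=uses_outgroup,
                        )
                    )
                    next_id += 1
    elif group is ModelGroup.STANDARD:
        next_id = 31
        for varying in _VARYING_ORDER:
            for z_free, sv_free in _FIXATION_SCHEMES:
                specs.append(
                    ModelSpec(
                        id=next_id,
                        group=group,
                        z_free=z_free,
                        sv_free=sv_free,
                        varying=frozenset(varying),
                    )
                )
                next_id += 1
    else:
        raise TypeError(f"unknown model group: {group!r}")
    return specs


_ALL_MODELS: dict[int, ModelSpec] = {
    m.id: m for g in ModelGroup for m in enumerate_models(g)
}


def get_model(model_id: int) -> ModelSpec:
    """Look up one of the 51 models by its canonical id."""
    try:
        return _ALL_MODELS[model_id]
    except KeyError:
        raise KeyError(f"model id must be 1..51, got {model_id}") from None


def model_table() -> pd.DataFrame:
    """Human-readable table of all 51 models (id, free/fixed, info kind)."""
    rows = []
    for m in _ALL_MODELS.values():
        rows.append(
            {
                "id": m.id,
                "group": m.group.value,
                "free": " ".join(m.param_names),
                "fixed": " ".join(
                    n for n, f in (("z", m.z_free), ("sv", m.sv_free)) if not f
                ),
                "varying": "+".join(sorted(m.varying)) if m.varying else "-",
                "info": m.info_kind.value if m.info_kind else "-",
                "k": m.k,
            }
        )
    return pd.DataFrame(rows).sort_values("id").reset_index(drop=True)
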