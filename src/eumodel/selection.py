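"""Information-criterion sub-model selection and evidence grading.

Choosing between placing a patient-level variable in the embryo (E) or the
uterus (U) sub-model is a non-nested comparison of two models with the same
number of parameters, where AIC and BIC differences coincide.  The BIC
difference approximates twice the log Bayes factor, and Raftery's rule of
thumb turns it into an evidence grade with an expected probability of correct
assignment:

====================  ==================  ===========
BIC difference        expected correct    evidence
====================  ==================  ===========
[0, 2)                50-75%              Weak
[2, 6)                75-95%              Positive
[6, 10)               95-99%              Strong
[10, inf)             >99%                Very strong
====================  ==================  ===========

Boundary values fall in the higher bin (half-open [lo, hi) bins).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .fitting import fit_eu
from .inference import lr_test
from .model import Dataset, ModelSpec

__all__ = [
    "EvidenceGrade",
    "SelectionResult",
    "placement_table",
    "raftery_grade",
    "select_four_models",
    "select_submodel",
]

_RAFTERY_BINS = (
    (0.0, 2.0, "Weak", (0.50, 0.75)),
    (2.0, 6.0, "Positive", (0.75, 0.95)),
    (6.0, 10.0, "Strong", (0.95, 0.99)),
    (10.0, float("inf"), "Very strong", (0.99, 1.0)),
)


@dataclass(frozen=True)
class EvidenceGrade:
    """A BIC-difference evidence band with its expected correct-assignment range."""

    bin_lower: float
    bin_upper: float
    label: str
    expected_correct: tuple[float, float]


@dataclass(frozen=True)
class SelectionResult:
    """IC comparison of candidate placements of one variable.

    ``candidate_ics`` maps model labels (subset of {"null","E","U","EU"}) to
    ``(aic, bic)``.  ``delta_EU_submodels`` is the absolute IC difference
    between the E- and U-placement models (identical under AIC and BIC since
    they share a parameter count); ``grade`` is its Raftery evidence grade.
    Exact IC ties (probability zero for continuous data) yield ``"tie"``.
    """

    variable: str
    candidate_ics: dict[str, tuple[float, float]]
    chosen_aic: str
    chosen_bic: str
    delta_EU_submodels: float
    grade: EvidenceGrade
    valid: bool = True
    message: str = ""


def raftery_grade(ic_difference: float) -> EvidenceGrade:
    """Grade a non-negative BIC (or equal-parameter AIC) difference."""
    if ic_difference < 0:
        raise ValueError("ic_difference must be >= 0")
    for lo, hi, label, expected in _RAFTERY_BINS:
        if lo <= ic_difference < hi:
            return EvidenceGrade(lo, hi, label, expected)
    return EvidenceGrade(10.0, float("inf"), "Very strong", (0.99, 1.0))


def _argmin_ic(ics: dict[str, tuple[float, float]], which: int) -> str:
    best = min(v[which] for v in ics.values())
    winners = [k for k, v in ics.items() if v[which] == best]
    return winners[0] if len(winners) == 1 else "tie"


def select_submodel(
    data: Dataset, base_spec: ModelSpec, variable: str
) -> SelectionResult:
    """Choose between the E- and U-placements of a variable by IC.

    Fits the two equal-parameter candidate models and picks the smaller
    information criterion (AIC and BIC agree here); reports the absolute IC
    difference and its Raftery grade.
    """
    fits = {
        "E": fit_eu(data, base_spec.with_variable(variable, "E")),
        "U": fit_eu(data, base_spec.with_variable(variable, "U")),
    }
    return _build_result(variable, fits)


def select_four_models(
    data: Dataset, base_spec: ModelSpec, variable: str, criterion: str = "bic"
) -> SelectionResult:
    """Choose among omitting the variable, placing it in E, in U, or in both.

    All four candidates are fitted; ``chosen_aic``/``chosen_bic`` each label
    the candidate minimising that criterion (BIC uses the number of cycles as
    sample size).  ``criterion`` only validates the caller's intent; both
    choices are always reported.
    """
    if criterion not in {"aic", "bic"}:
        raise ValueError("criterion must be 'aic' or 'bic'")
    fits = {
        "null": fit_eu(data, base_spec),
        "E": fit_eu(data, base_spec.with_variable(variable, "E")),
        "U": fit_eu(data, base_spec.with_variable(variable, "U")),
        "EU": fit_eu(data, base_spec.with_variable(variable, "EU")),
    }
    return _build_result(variable, fits)


def _build_result(variable: str, fits: dict) -> SelectionResult:
    bad = [name for name, fr in fits.items() if not fr.converged]
    ics = {name: (fr.aic, fr.bic) for name, fr in fits.items()}
    delta = abs(ics["E"][1] - ics["U"][1])
    if bad:
        return SelectionResult(
            variable=variable,
            candidate_ics=ics,
            chosen_aic="invalid",
            chosen_bic="invalid",
            delta_EU_submodels=delta,
            grade=raftery_grade(delta),
            valid=False,
            message=f"non-converged fit(s): {', '.join(bad)}",
        )
    return SelectionResult(
        variable=variable,
        candidate_ics=ics,
        chosen_aic=_argmin_ic(ics, 0),
        chosen_bic=_argmin_ic(ics, 1),
        delta_EU_submodels=delta,
        grade=raftery_grade(delta),
    )


def placement_table(
    data: Dataset, base_spec: ModelSpec, variables: list[str]
) -> pd.DataFrame:
    """Permute each variable across the null/E/U/E+U placements.

    For every variable in turn (others held at their base placement), fits the
    four candidate models and reports the AIC difference from the null
    placement for each, together with the 1-df LR p-values for the E and U
    placements and the 2-df p-value for E+U.  This is the model-building
    summary one would produce when screening patient-level prognostic factors.
    """
    rows = []
    for var in variables:
        null_fit = fit_eu(data, base_spec)
        fit_E = fit_eu(data, base_spec.with_variable(var, "E"))
        fit_U = fit_eu(data, base_spec.with_variable(var, "U"))
        fit_EU = fit_eu(data, base_spec.with_variable(var, "EU"))
        rows.append(
            {
                "variable": var,
                "dAIC_E": fit_E.aic - null_fit.aic,
                "dAIC_U": fit_U.aic - null_fit.aic,
                "dAIC_EU": fit_EU.aic - null_fit.aic,
                "p_E": lr_test(fit_E, null_fit).p_value,
                "p_U": lr_test(fit_U, null_fit).p_value,
                "p_EU": lr_test(fit_EU, null_fit).p_value,
            }
        )
    return pd.DataFrame(rows)
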