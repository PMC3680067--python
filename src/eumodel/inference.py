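"""Likelihood-ratio inference for patient-level covariates in EU models.

A patient-level variable can validly sit in either the uterus or the embryo
sub-model, so "is this variable associated with outcome?" is not a single
test.  Four strategies are provided for the unknown-sub-model case:

- ``found_in_either`` — two 1-df LR tests (variable in U; variable in E),
  significant if either p-value is below the nominal level (anti-conservative);
- ``found_in_both`` — same two tests, both must be below the level (conservative);
- ``bonferroni`` — either test below half the nominal level;
- ``global`` — a single 2-df LR test of the variable in both sub-models.

When prior knowledge fixes the sub-model, ``prespecified_E`` and
``prespecified_U`` perform the single 1-df test at the nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2

from .fitting import FitResult, fit_eu
from .model import Dataset, ModelSpec

__all__ = [
    "STRATEGIES",
    "LRTest",
    "StrategyResult",
    "lr_test",
    "strategy_decision",
    "test_variable",
]

STRATEGIES = (
    "found_in_either",
    "found_in_both",
    "bonferroni",
    "global",
    "prespecified_E",
    "prespecified_U",
)


@dataclass(frozen=True)
class LRTest:
    """One likelihood-ratio test: ``statistic = max(0, 2(logL_full - logL_red))``."""

    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class StrategyResult:
    """Outcome of one strategy applied to one variable on one dataset.

    ``p_E``/``p_U`` are the 1-df p-values (where the strategy computes them),
    ``p_global`` the 2-df one.  ``valid`` is False when a required fit failed
    to converge; such results must be excluded from study tallies.
    """

    strategy: str
    variable: str
    alpha: float
    significant: bool
    p_E: float | None = None
    p_U: float | None = None
    p_global: float | None = None
    valid: bool = True
    message: str = ""


def lr_test(full: FitResult, reduced: FitResult) -> LRTest:
    """LR test of a reduced model nested within a full model.

    Requires both fits converged and ``reduced.spec`` nested in ``full.spec``;
    the statistic is clipped at zero (numerical noise can make the full-model
    log-likelihood infinitesimally smaller).
    """
    if not reduced.spec.is_nested_in(full.spec):
        raise ValueError("reduced model is not nested in the full model")
    df = full.spec.p - reduced.spec.p
    if df < 1:
        raise ValueError("full model must have more parameters than reduced")
    if not (full.converged and reduced.converged):
        raise ValueError("both fits must be converged for a likelihood-ratio test")
    stat = max(0.0, 2.0 * (full.logL - reduced.logL))
    return LRTest(statistic=stat, df=df, p_value=float(chi2.sf(stat, df)))


def strategy_decision(
    strategy: str,
    alpha: float,
    p_E: float | None = None,
    p_U: float | None = None,
    p_global: float | None = None,
) -> bool:
    """Pure decision rule for each strategy given the relevant p-values."""
    if strategy == "found_in_either":
        return min(p_E, p_U) < alpha
    if strategy == "found_in_both":
        return max(p_E, p_U) < alpha
    if strategy == "bonferroni":
        return min(p_E, p_U) < alpha / 2.0
    if strategy == "global":
        return p_global < alpha
    if strategy == "prespecified_E":
        return p_E < alpha
    if strategy == "prespecified_U":
        return p_U < alpha
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


def _required_fits(strategy: str) -> tuple[str, ...]:
    return {
        "found_in_either": ("E", "U"),
        "found_in_both": ("E", "U"),
        "bonferroni": ("E", "U"),
        "global": ("EU",),
        "prespecified_E": ("E",),
        "prespecified_U": ("U",),
    }[strategy]


def test_variable(
    data: Dataset,
    base_spec: ModelSpec,
    variable: str,
    strategy: str,
    alpha: float = 0.05,
) -> StrategyResult:
    """Test a cycle-level variable not in ``base_spec`` under one strategy.

    Fits the base model plus the variable-in-E / variable-in-U / variable-in-
    both models the strategy requires, runs the LR tests and applies the
    decision rule.  If any required fit fails to converge the result is
    returned with ``valid=False`` and ``significant=False``.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if variable in base_spec.u_terms or variable in base_spec.e_terms:
        raise ValueError(f"variable {variable!r} already in the base model")

    base = fit_eu(data, base_spec)
    fits = {"base": base}
    for where in _required_fits(strategy):
        fits[where] = fit_eu(data, base_spec.with_variable(variable, where))

    bad = [name for name, fr in fits.items() if not fr.converged]
    if bad:
        return StrategyResult(
            strategy=strategy,
            variable=variable,
            alpha=alpha,
            significant=False,
            valid=False,
            message=f"non-converged fit(s): {', '.join(bad)}",
        )

    p_E = lr_test(fits["E"], base).p_value if "E" in fits else None
    p_U = lr_test(fits["U"], base).p_value if "U" in fits else None
    p_global = lr_test(fits["EU"], base).p_value if "EU" in fits else None
    return StrategyResult(
        strategy=strategy,
        variable=variable,
        alpha=alpha,
        significant=strategy_decision(strategy, alpha, p_E=p_E, p_U=p_U, p_global=p_global),
        p_E=p_E,
        p_U=p_U,
        p_global=p_global,
    )


# not a test despite the name (keeps pytest collection away from the API)
test_variable.__test__ = False  # type: ignore[attr-defined]
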