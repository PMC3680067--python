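"""Monte-Carlo replication engine for EU-model operating characteristics.

Each study simulates many datasets under a grid of scenarios and applies the
inference strategies or IC selection to every replicate, reporting rejection /
classification proportions with Monte-Carlo standard errors.  Replicates are
seeded individually from ``(base_seed, scenario_index, replication_index)``
through ``numpy``'s ``SeedSequence``, so results are reproducible and
independent of any batching.  All strategies are evaluated on the same
replicate fits (a paired design, which reduces the variance of between-
strategy comparisons).  Replicates in which any required fit fails to converge
are dropped from the denominator and counted in ``n_dropped``.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fitting import FitWarning, fit_eu
from .inference import STRATEGIES, lr_test, strategy_decision
from .model import Dataset, ModelSpec
from .selection import _RAFTERY_BINS
from .simulate import STUDY_BASE_SPEC, STUDY_VARIABLE, ScenarioConfig, simulate_dataset

__all__ = [
    "mc_precision",
    "naive_logistic_power",
    "run_classification_study",
    "run_four_model_study",
    "run_rejection_study",
]

logger = logging.getLogger(__name__)

STUDY_COLUMNS = [
    "scenario_id",
    "n_cycles",
    "beta_up",
    "beta_ep2",
    "metric",
    "strategy_or_criterion",
    "proportion",
    "mc_se",
    "n_valid",
    "n_dropped",
]


def mc_precision(p: float, reps: int) -> float:
    """Half-width of the two-sided 95% CI of a proportion from ``reps`` draws."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly in (0, 1)")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    return float(1.96 * np.sqrt(p * (1.0 - p) / reps))


def _se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / n)) if n > 0 else float("nan")


def _rep_seed(base_seed: int, scenario_index: int, rep: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(scenario_index), int(rep)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _rep_fits(
    data: Dataset,
    base_spec: ModelSpec,
    variable: str,
    which: Sequence[str],
) -> dict | None:
    """Fit the requested candidate models; None if any fails to converge.

    A fit that stalls is retried once from the base-model solution with the
    extra coefficient started at zero before the replicate is given up on.
    """
    fits = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FitWarning)
        base_fit = None
        for label in which:
            spec = base_spec if label == "null" else base_spec.with_variable(variable, label)
            fr = fit_eu(data, spec, diagnostics=False)
            if not fr.converged and label != "null":
                if base_fit is None:
                    base_fit = fit_eu(data, base_spec, diagnostics=False)
                if base_fit.converged:
                    bu = list(base_fit.theta_hat.beta_u)
                    be = list(base_fit.theta_hat.beta_e)
                    if "U" in label:
                        bu.append(0.0)
                    if "E" in label:
                        be.append(0.0)
                    fr = fit_eu(
                        data, spec, start=np.asarray(bu + be), diagnostics=False
                    )
            if not fr.converged:
                return None
            if label == "null":
                base_fit = fr
            fits[label] = fr
    return fits


def run_rejection_study(
    grid: Iterable[ScenarioConfig],
    strategies: Sequence[str] = STRATEGIES,
    reps: int = 2000,
    alpha: float = 0.05,
    base_seed: int = 0,
    base_spec: ModelSpec = STUDY_BASE_SPEC,
    variable: str = STUDY_VARIABLE,
) -> pd.DataFrame:
    """Rejection proportion of each strategy under each scenario.

    Under null scenarios (both effects of the tested variable zero) the
    proportion estimates the type-I error; otherwise it estimates power.
    """
    for s in strategies:
        if s not in STRATEGIES:
            raise ValueError(f"unknown strategy {s!r}")
    need = {"null"}
    if any(s in {"found_in_either", "found_in_both", "bonferroni", "prespecified_E"} for s in strategies):
        need.add("E")
    if any(s in {"found_in_either", "found_in_both", "bonferroni", "prespecified_U"} for s in strategies):
        need.add("U")
    if "global" in strategies:
        need.add("EU")
    # the 1-df strategies need both sides for the min/max rules
    if need & {"E", "U"} and any(
        s in {"found_in_either", "found_in_both", "bonferroni"} for s in strategies
    ):
        need |= {"E", "U"}

    rows = []
    for scen_idx, cfg in enumerate(grid):
        hits = {s: 0 for s in strategies}
        n_valid = 0
        n_dropped = 0
        for rep in range(reps):
            data = simulate_dataset(cfg.with_seed(_rep_seed(base_seed, scen_idx, rep)))
            fits = _rep_fits(data, base_spec, variable, sorted(need))
            if fits is None:
                n_dropped += 1
                continue
            n_valid += 1
            base = fits["null"]
            p_E = lr_test(fits["E"], base).p_value if "E" in fits else None
            p_U = lr_test(fits["U"], base).p_value if "U" in fits else None
            p_G = lr_test(fits["EU"], base).p_value if "EU" in fits else None
            for s in strategies:
                if strategy_decision(s, alpha, p_E=p_E, p_U=p_U, p_global=p_G):
                    hits[s] += 1
        if n_dropped:
            logger.info("scenario %d: dropped %d/%d replicates", scen_idx, n_dropped, reps)
        for s in strategies:
            p = hits[s] / n_valid if n_valid else float("nan")
            rows.append(
                {
                    "scenario_id": scen_idx,
                    "n_cycles": cfg.n_cycles,
                    "beta_up": cfg.beta_up,
                    "beta_ep2": cfg.beta_ep2,
                    "metric": "rejection",
                    "strategy_or_criterion": s,
                    "proportion": p,
                    "mc_se": _se(p, n_valid),
                    "n_valid": n_valid,
                    "n_dropped": n_dropped,
                }
            )
    return pd.DataFrame(rows, columns=STUDY_COLUMNS)


def _true_submodel(cfg: ScenarioConfig) -> str | None:
    if cfg.beta_ep2 != 0.0 and cfg.beta_up == 0.0:
        return "E"
    if cfg.beta_up != 0.0 and cfg.beta_ep2 == 0.0:
        return "U"
    if cfg.beta_up == 0.0 and cfg.beta_ep2 == 0.0:
        return None
    raise ValueError(
        "classification scenarios must place the effect in exactly one "
        "sub-model (or none)"
    )


def _bin_label(delta: float) -> str:
    for lo, hi, _, _ in _RAFTERY_BINS:
        if lo <= delta < hi:
            return f"[{lo:g},{hi:g})" if np.isfinite(hi) else ">=10"
    return ">=10"


def run_classification_study(
    grid: Iterable[ScenarioConfig],
    reps: int = 2000,
    base_seed: int = 0,
    base_spec: ModelSpec = STUDY_BASE_SPEC,
    variable: str = STUDY_VARIABLE,
) -> pd.DataFrame:
    """Two-model (E vs U placement) IC selection performance.

    Per scenario: the proportion of replicates in which the lower-IC model is
    the true sub-model (metric ``correct_classification``); for null scenarios
    the proportion selecting E is reported instead (metric ``prop_select_E``,
    expected 50%).  Replicates from scenarios with a true single-sub-model
    effect are additionally pooled, per sample size, into Raftery bins of the
    absolute BIC difference (metric ``bin_correct``) — the empirical
    calibration of the evidence grades.
    """
    rows = []
    pooled: dict[tuple[int, str], list[int]] = {}
    for scen_idx, cfg in enumerate(grid):
        truth = _true_submodel(cfg)
        n_valid = 0
        n_dropped = 0
        n_correct = 0
        n_select_E = 0
        n_tie = 0
        for rep in range(reps):
            data = simulate_dataset(cfg.with_seed(_rep_seed(base_seed, scen_idx, rep)))
            fits = _rep_fits(data, base_spec, variable, ("E", "U"))
            if fits is None:
                n_dropped += 1
                continue
            n_valid += 1
            bic_E, bic_U = fits["E"].bic, fits["U"].bic
            if bic_E == bic_U:  # probability-zero tie; excluded from tallies
                n_tie += 1
                continue
            chosen = "E" if bic_E < bic_U else "U"
            if chosen == "E":
                n_select_E += 1
            if truth is not None:
                correct = chosen == truth
                n_correct += correct
                pooled.setdefault(
                    (cfg.n_cycles, _bin_label(abs(bic_E - bic_U))), []
                ).append(int(correct))
        n_tallied = n_valid - n_tie
        if truth is None:
            metric, p = "prop_select_E", (n_select_E / n_tallied if n_tallied else float("nan"))
        else:
            metric, p = "correct_classification", (n_correct / n_tallied if n_tallied else float("nan"))
        rows.append(
            {
                "scenario_id": scen_idx,
                "n_cycles": cfg.n_cycles,
                "beta_up": cfg.beta_up,
                "beta_ep2": cfg.beta_ep2,
                "metric": metric,
                "strategy_or_criterion": "bic",
                "proportion": p,
                "mc_se": _se(p, n_tallied),
                "n_valid": n_valid,
                "n_dropped": n_dropped,
            }
        )
    for (n_cycles, label), outcomes in sorted(pooled.items()):
        m = len(outcomes)
        p = float(np.mean(outcomes))
        rows.append(
            {
                "scenario_id": -1,
                "n_cycles": n_cycles,
                "beta_up": float("nan"),
                "beta_ep2": float("nan"),
                "metric": "bin_correct",
                "strategy_or_criterion": label,
                "proportion": p,
                "mc_se": _se(p, m),
                "n_valid": m,
                "n_dropped": 0,
            }
        )
    return pd.DataFrame(rows, columns=STUDY_COLUMNS)


def run_four_model_study(
    grid: Iterable[ScenarioConfig],
    reps: int = 2000,
    criterion: str = "bic",
    base_seed: int = 0,
    base_spec: ModelSpec = STUDY_BASE_SPEC,
    variable: str = STUDY_VARIABLE,
) -> pd.DataFrame:
    """Proportions assigned to each of {null, E, U, EU} by one criterion.

    Ties (probability zero) are reported under their own label so the five
    proportions always sum to one over the valid replicates.
    """
    if criterion not in {"aic", "bic"}:
        raise ValueError("criterion must be 'aic' or 'bic'")
    which = 0 if criterion == "aic" else 1
    rows = []
    for scen_idx, cfg in enumerate(grid):
        counts = {"null": 0, "E": 0, "U": 0, "EU": 0, "tie": 0}
        n_valid = 0
        n_dropped = 0
        for rep in range(reps):
            data = simulate_dataset(cfg.with_seed(_rep_seed(base_seed, scen_idx, rep)))
            fits = _rep_fits(data, base_spec, variable, ("null", "E", "U", "EU"))
            if fits is None:
                n_dropped += 1
                continue
            n_valid += 1
            ics = {name: (fr.aic, fr.bic)[which] for name, fr in fits.items()}
            best = min(ics.values())
            winners = [name for name, v in ics.items() if v == best]
            counts[winners[0] if len(winners) == 1 else "tie"] += 1
        for label, c in counts.items():
            p = c / n_valid if n_valid else float("nan")
            rows.append(
                {
                    "scenario_id": scen_idx,
                    "n_cycles": cfg.n_cycles,
                    "beta_up": cfg.beta_up,
                    "beta_ep2": cfg.beta_ep2,
                    "metric": "assigned",
                    "strategy_or_criterion": f"{criterion}:{label}",
                    "proportion": p,
                    "mc_se": _se(p, n_valid),
                    "n_valid": n_valid,
                    "n_dropped": n_dropped,
                }
            )
    return pd.DataFrame(rows, columns=STUDY_COLUMNS)


def _event_rate_intercept(effect: float, event_rate: float) -> float:
    """Intercept making E[expit(a + effect·X)] = event_rate for X ~ N(0,1)."""
    from scipy.optimize import brentq

    t, w = np.polynomial.hermite.hermgauss(80)
    x = np.sqrt(2.0) * t
    w = w / np.sqrt(np.pi)

    def marginal(a):
        return float(w @ (1.0 / (1.0 + np.exp(-(a + effect * x))))) - event_rate

    return float(brentq(marginal, -30.0, 30.0))


def naive_logistic_power(
    effect: float,
    n: int,
    event_rate: float,
    reps: int = 2000,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> float:
    """Power of a single-level logistic model treated as if fully observed.

    Simulates ``y ~ Bernoulli(expit(a + effect·x))`` with ``x ~ N(0,1)`` and
    the intercept chosen so the marginal event rate matches ``event_rate``
    (e.g. the pregnancy rate), then tests the coefficient with a 1-df LR test.
    This is the naive power one would quote by considering a sub-model in
    isolation; it ignores the partial observability and attenuation inherent
    in the two-level model and so over-states the achievable power.
    """
    if not 0.0 < event_rate < 1.0:
        raise ValueError("event_rate must lie in (0, 1)")
    import statsmodels.api as sm

    a = _event_rate_intercept(effect, event_rate)
    rejections = 0
    n_valid = 0
    for rep in range(reps):
        rng = np.random.default_rng(_rep_seed(base_seed, 0, rep))
        x = rng.normal(size=n)
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-(a + effect * x)))).astype(float)
        if y.min() == y.max():  # degenerate sample, no information
            continue
        X = sm.add_constant(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0)
        n_valid += 1
        if res.llr_pvalue < alpha:
            rejections += 1
    return rejections / n_valid if n_valid else float("nan")
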