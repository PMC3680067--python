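"""Core probability model for Embryo-Uterus (EU) analyses of IVF cycles.

The EU model assumes that a treatment cycle succeeds only if the uterus is
receptive (a cycle-level Bernoulli with probability ``u``) and, independently,
each transferred embryo is viable (embryo-level Bernoullis with probabilities
``e_ij``).  Only the number of implantations ``k`` is observed, never which
embryos implanted, so the likelihood marginalises over the latent states.

Both ``u`` and the ``e_ij`` are given logistic-regression sub-models.  A
cycle-level covariate may enter either sub-model (or both); an embryo-level
covariate can only enter the embryo sub-model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CycleRecord",
    "Dataset",
    "ModelSpec",
    "ParameterVector",
    "SchemaError",
    "ZeroProbabilityError",
    "cycle_probabilities",
    "k_fold_probability",
    "log_likelihood",
]

#: embryo counts up to this value use explicit subset enumeration; larger
#: cycles switch to a dynamic-programming convolution (same exact result).
SUBSET_ENUMERATION_CAP = 10


class SchemaError(KeyError):
    """A covariate required by a model specification is absent or mistyped."""


class ZeroProbabilityError(ValueError):
    """Some cycle has probability 0 under the supplied parameters.

    Carries the offending cycle identifiers in :attr:`cycle_ids`.
    """

    def __init__(self, cycle_ids: Sequence) -> None:
        self.cycle_ids = list(cycle_ids)
        super().__init__(
            "zero likelihood for cycle(s): "
            + ", ".join(str(c) for c in self.cycle_ids[:10])
            + ("..." if len(self.cycle_ids) > 10 else "")
        )


from scipy.special import expit as _expit


@dataclass(frozen=True)
class CycleRecord:
    """One treatment cycle: transfer size, observed outcome and covariates.

    ``embryo_covariates`` has one mapping per transferred embryo, in transfer
    order; cycle-level covariates live in ``u_covariates`` but may be used by
    the embryo sub-model as well.
    """

    cycle_id: object
    n_transferred: int
    k_observed: int
    u_covariates: Mapping[str, float] = field(default_factory=dict)
    embryo_covariates: Sequence[Mapping[str, float]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_transferred < 1:
            raise ValueError(f"cycle {self.cycle_id}: n_transferred must be >= 1")
        if not 0 <= self.k_observed <= self.n_transferred:
            raise ValueError(
                f"cycle {self.cycle_id}: k_observed={self.k_observed} outside "
                f"[0, {self.n_transferred}]"
            )
        if len(self.embryo_covariates) not in (0, self.n_transferred):
            raise ValueError(
                f"cycle {self.cycle_id}: {len(self.embryo_covariates)} embryo "
                f"covariate rows for {self.n_transferred} embryos"
            )


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter each logistic sub-model.

    Intercepts are implicit and always present, so the total parameter count
    is ``2 + len(u_terms) + len(e_terms)``.  ``u_terms`` may reference only
    cycle-level covariates; ``e_terms`` may reference cycle- or embryo-level
    covariates (a patient-level variable can act through embryo viability).
    """

    u_terms: tuple[str, ...] = ()
    e_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for terms, side in ((self.u_terms, "u_terms"), (self.e_terms, "e_terms")):
            if len(set(terms)) != len(terms):
                raise ValueError(f"duplicate covariate in {side}: {terms}")
        object.__setattr__(self, "u_terms", tuple(self.u_terms))
        object.__setattr__(self, "e_terms", tuple(self.e_terms))

    @property
    def p(self) -> int:
        """Total number of free parameters (both intercepts included)."""
        return 2 + len(self.u_terms) + len(self.e_terms)

    def with_variable(self, name: str, where: str) -> "ModelSpec":
        """Return a spec with ``name`` appended to the U, E or both sub-models."""
        if where not in {"U", "E", "EU"}:
            raise ValueError(f"where must be 'U', 'E' or 'EU', got {where!r}")
        u = self.u_terms + ((name,) if "U" in where else ())
        e = self.e_terms + ((name,) if "E" in where else ())
        return ModelSpec(u_terms=u, e_terms=e)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.u_terms) <= set(other.u_terms) and set(self.e_terms) <= set(
            other.e_terms
        )


@dataclass(frozen=True)
class ParameterVector:
    """Coefficients for a :class:`ModelSpec`; intercept first on each side."""

    beta_u: tuple[float, ...]
    beta_e: tuple[float, ...]

    def __post_init__(self) -> None:
        bu = tuple(float(x) for x in self.beta_u)
        be = tuple(float(x) for x in self.beta_e)
        if not all(np.isfinite(bu)) or not all(np.isfinite(be)):
            raise ValueError("non-finite coefficient in ParameterVector")
        object.__setattr__(self, "beta_u", bu)
        object.__setattr__(self, "beta_e", be)

    @classmethod
    def from_flat(cls, theta: np.ndarray, spec: ModelSpec) -> "ParameterVector":
        theta = np.asarray(theta, dtype=float)
        nu = 1 + len(spec.u_terms)
        return cls(beta_u=tuple(theta[:nu]), beta_e=tuple(theta[nu:]))

    def flat(self) -> np.ndarray:
        return np.asarray(self.beta_u + self.beta_e, dtype=float)

    def conforms_to(self, spec: ModelSpec) -> bool:
        return len(self.beta_u) == 1 + len(spec.u_terms) and len(self.beta_e) == 1 + len(
            spec.e_terms
        )


class Dataset:
    """An aligned pair of cycle-level and embryo-level covariate tables.

    Parameters
    ----------
    cycles : DataFrame with columns ``cycle_id``, ``n_transferred``,
        ``k_observed`` plus numeric cycle-level covariates.
    embryos : DataFrame with columns ``cycle_id``, ``embryo_index`` (1-based
        within cycle) plus numeric embryo-level covariates, or None when no
        embryo-level covariates exist.
    """

    RESERVED_CYCLE = ("cycle_id", "n_transferred", "k_observed")
    RESERVED_EMBRYO = ("cycle_id", "embryo_index")

    def __init__(
        self,
        cycles: pd.DataFrame,
        embryos: pd.DataFrame | None = None,
        *,
        validate: bool = True,
    ):
        # validate=False is for internal construction of data known to satisfy
        # the invariants (e.g. the simulator); embryo rows must already be in
        # cycles-table order with embryo_index ascending within each cycle.
        if not validate:
            self.cycles_table = cycles
            self.embryos_table = embryos
            self.cycle_covariate_names = tuple(
                c for c in cycles.columns if c not in self.RESERVED_CYCLE
            )
            self.embryo_covariate_names = (
                tuple(c for c in embryos.columns if c not in self.RESERVED_EMBRYO)
                if embryos is not None
                else ()
            )
            return
        cycles = cycles.reset_index(drop=True)
        for col in self.RESERVED_CYCLE:
            if col not in cycles.columns:
                raise SchemaError(f"cycles table missing required column {col!r}")
        ids = cycles["cycle_id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].unique()[:5]
            raise ValueError(f"duplicate cycle_id values: {list(dups)}")
        n = cycles["n_transferred"].to_numpy()
        k = cycles["k_observed"].to_numpy()
        if (n < 1).any():
            raise ValueError("n_transferred must be >= 1 for every cycle")
        bad = (k < 0) | (k > n)
        if bad.any():
            raise ValueError(
                f"k_observed outside [0, n_transferred] for cycle_id(s) "
                f"{list(ids[bad][:5])}"
            )

        if embryos is not None:
            embryos = embryos.reset_index(drop=True)
            for col in self.RESERVED_EMBRYO:
                if col not in embryos.columns:
                    raise SchemaError(f"embryos table missing required column {col!r}")
            # each cycle must contribute embryo_index exactly 1..n_transferred
            counts = embryos.groupby("cycle_id", sort=False)["embryo_index"].agg(
                ["count", "min", "max"]
            )
            expected = cycles.set_index("cycle_id")["n_transferred"]
            merged = counts.reindex(expected.index)
            ok = (
                (merged["count"] == expected)
                & (merged["min"] == 1)
                & (merged["max"] == expected)
            )
            if not ok.fillna(False).all():
                bad_ids = list(expected.index[~ok.fillna(False)][:5])
                raise ValueError(
                    f"embryo rows do not cover 1..n_transferred for cycle_id(s) {bad_ids}"
                )
            # align embryo block order with the cycles table order
            order = {cid: i for i, cid in enumerate(ids)}
            key = embryos["cycle_id"].map(order)
            if key.isna().any():
                orphan = embryos.loc[key.isna(), "cycle_id"].unique()[:5]
                raise ValueError(f"embryo rows reference unknown cycle_id(s): {list(orphan)}")
            embryos = (
                embryos.assign(_ord=key)
                .sort_values(["_ord", "embryo_index"], kind="stable")
                .drop(columns="_ord")
                .reset_index(drop=True)
            )

        self.cycles_table = cycles
        self.embryos_table = embryos

        self.cycle_covariate_names = tuple(
            c for c in cycles.columns if c not in self.RESERVED_CYCLE
        )
        self.embryo_covariate_names = (
            tuple(c for c in embryos.columns if c not in self.RESERVED_EMBRYO)
            if embryos is not None
            else ()
        )
        for name in self.cycle_covariate_names:
            if not pd.api.types.is_numeric_dtype(cycles[name]):
                raise SchemaError(f"cycle covariate {name!r} is not numeric")
        for name in self.embryo_covariate_names:
            if not pd.api.types.is_numeric_dtype(embryos[name]):
                raise SchemaError(f"embryo covariate {name!r} is not numeric")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[CycleRecord]) -> "Dataset":
        records = list(records)
        cyc_rows = []
        emb_rows = []
        for rec in records:
            row = {
                "cycle_id": rec.cycle_id,
                "n_transferred": rec.n_transferred,
                "k_observed": rec.k_observed,
            }
            row.update(rec.u_covariates)
            cyc_rows.append(row)
            for j, cov in enumerate(rec.embryo_covariates, start=1):
                emb_rows.append({"cycle_id": rec.cycle_id, "embryo_index": j, **cov})
        cycles = pd.DataFrame(cyc_rows)
        embryos = pd.DataFrame(emb_rows) if emb_rows else None
        return cls(cycles, embryos)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles_table)

    @property
    def n_embryos(self) -> int:
        return int(self.cycles_table["n_transferred"].sum())

    @property
    def covariate_schema(self) -> dict[str, str]:
        schema = {name: "cycle" for name in self.cycle_covariate_names}
        schema.update({name: "embryo" for name in self.embryo_covariate_names})
        return schema

    def records(self) -> list[CycleRecord]:
        """Materialise the dataset as a list of :class:`CycleRecord`."""
        cov = list(self.cycle_covariate_names)
        recs = []
        emb_blocks: dict[object, list[dict]] = {}
        if self.embryos_table is not None:
            ecols = list(self.embryo_covariate_names)
            for cid, grp in self.embryos_table.groupby("cycle_id", sort=False):
                emb_blocks[cid] = grp[ecols].to_dict("records")
        for row in self.cycles_table.itertuples(index=False):
            d = row._asdict()
            recs.append(
                CycleRecord(
                    cycle_id=d["cycle_id"],
                    n_transferred=int(d["n_transferred"]),
                    k_observed=int(d["k_observed"]),
                    u_covariates={c: d[c] for c in cov},
                    embryo_covariates=tuple(emb_blocks.get(d["cycle_id"], ())),
                )
            )
        return recs

    def split(self, idx: Sequence[int]) -> "Dataset":
        """Subset by cycle positions (used by tests for additivity checks)."""
        cyc = self.cycles_table.iloc[list(idx)]
        emb = None
        if self.embryos_table is not None:
            emb = self.embryos_table[
                self.embryos_table["cycle_id"].isin(cyc["cycle_id"])
            ]
        return Dataset(cyc, emb)


# ---------------------------------------------------------------------------
# k-fold pregnancy probability
# ---------------------------------------------------------------------------


def _poisson_binomial_pmf(e: np.ndarray) -> np.ndarray:
    """PMF of the number of successes among independent Bernoulli(e_j)."""
    pmf = np.zeros(len(e) + 1)
    pmf[0] = 1.0
    for j, ej in enumerate(e):
        pmf[1 : j + 2] = pmf[1 : j + 2] * (1.0 - ej) + pmf[: j + 1] * ej
        pmf[0] *= 1.0 - ej
    return pmf


def _subset_sum(e: np.ndarray, k: int) -> float:
    """Sum over size-k subsets of prod(e in subset) * prod(1-e outside)."""
    n = len(e)
    total = 0.0
    for subset in itertools.combinations(range(n), k):
        inside = set(subset)
        term = 1.0
        for j in range(n):
            term *= e[j] if j in inside else 1.0 - e[j]
        total += term
    return total


def k_fold_probability(u: float, e: Sequence[float], k: int) -> float:
    """Probability that exactly ``k`` of the transferred embryos implant.

    ``P(k) = (1-u)·δ(k) + u·S_k(e)`` where ``δ(k)=1`` iff ``k=0`` and
    ``S_k`` sums, over all subsets of size ``k``, the product of viability
    probabilities inside the subset times non-viability outside it.  A cycle
    fails outright (k=0) if the uterus is non-receptive, whatever the embryos.

    The subset sum is evaluated exactly: by explicit enumeration for
    ``n <= SUBSET_ENUMERATION_CAP``, and by a dynamic-programming convolution
    (Poisson-binomial recursion) beyond that.
    """
    e = np.asarray(e, dtype=float)
    n = len(e)
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if not 0.0 <= u <= 1.0 or ((e < 0.0) | (e > 1.0)).any():
        raise ValueError("u and all e_j must lie in [0, 1]")
    if n <= SUBSET_ENUMERATION_CAP:
        s_k = _subset_sum(e, k)
    else:
        s_k = _poisson_binomial_pmf(e)[k]
    return (1.0 - u) * (1.0 if k == 0 else 0.0) + u * s_k


# ---------------------------------------------------------------------------
# design-matrix compilation and the vectorised likelihood
# ---------------------------------------------------------------------------


class LikelihoodEvaluator:
    """Compiled (dataset, spec) pair supporting fast likelihood and gradient.

    Embryo viabilities are laid out in a padded (n_cycles, max_n) array; the
    k-fold probabilities for every cycle come from a vectorised
    Poisson-binomial recursion over the embryo slots (padding slots carry
    e = 0 and are transparent to the recursion).
    """

    def __init__(self, data: Dataset, spec: ModelSpec):
        self.data = data
        self.spec = spec
        cycles = data.cycles_table
        n_cycles = len(cycles)
        self.k = cycles["k_observed"].to_numpy(dtype=np.int64)
        self.n_transferred = cycles["n_transferred"].to_numpy(dtype=np.int64)
        self.max_n = int(self.n_transferred.max())

        schema = data.covariate_schema
        for name in spec.u_terms:
            if schema.get(name) != "cycle":
                raise SchemaError(
                    f"uterus sub-model term {name!r} is not a cycle-level covariate"
                )
        for name in spec.e_terms:
            if name not in schema:
                raise SchemaError(f"embryo sub-model term {name!r} not in dataset")

        self.X_u = np.column_stack(
            [np.ones(n_cycles)]
            + [cycles[name].to_numpy(dtype=float) for name in spec.u_terms]
        )

        # embryo design matrix: one row per embryo, in cycles-table order;
        # cycle-level terms are broadcast down to each embryo of the cycle
        n_emb = int(self.n_transferred.sum())
        cyc_of_emb = np.repeat(np.arange(n_cycles), self.n_transferred)
        cols = [np.ones(n_emb)]
        for name in spec.e_terms:
            if schema[name] == "cycle":
                cols.append(cycles[name].to_numpy(dtype=float)[cyc_of_emb])
            else:
                cols.append(data.embryos_table[name].to_numpy(dtype=float))
        self.X_e = np.column_stack(cols)
        self.cyc_of_emb = cyc_of_emb

        # padded layout: slot (i, j) -> row index into X_e, -1 for padding
        pos_in_cycle = np.arange(n_emb) - np.repeat(
            np.cumsum(self.n_transferred) - self.n_transferred, self.n_transferred
        )
        self.pad_index = np.full((n_cycles, self.max_n), -1, dtype=np.int64)
        self.pad_index[cyc_of_emb, pos_in_cycle] = np.arange(n_emb)
        self.pad_mask = self.pad_index >= 0
        self._safe_index = np.where(self.pad_mask, self.pad_index, 0)
        self.k_is_zero = self.k == 0
        self._rows = np.arange(n_cycles)

    @property
    def p(self) -> int:
        return self.spec.p

    def _probabilities(self, theta: np.ndarray):
        nu = self.X_u.shape[1]
        u = _expit(self.X_u @ theta[:nu])
        e_emb = _expit(self.X_e @ theta[nu:])
        e_pad = np.where(self.pad_mask, e_emb[self._safe_index], 0.0)
        return u, e_emb, e_pad

    @staticmethod
    def _pb_table(e_pad: np.ndarray) -> np.ndarray:
        """Vectorised Poisson-binomial PMF table, shape (n_cycles, ncols+1).

        Padding slots (e = 0) are transparent to the recursion.
        """
        n_cycles, ncols = e_pad.shape
        pb = np.zeros((n_cycles, ncols + 1))
        pb[:, 0] = 1.0
        for j in range(ncols):
            ej = e_pad[:, j]
            pb[:, 1:] = pb[:, 1:] * (1.0 - ej)[:, None] + pb[:, :-1] * ej[:, None]
            pb[:, 0] *= 1.0 - ej
        return pb

    def cycle_likelihoods(self, theta: np.ndarray) -> np.ndarray:
        u, _, e_pad = self._probabilities(theta)
        pb = self._pb_table(e_pad)
        return np.where(self.k_is_zero, 1.0 - u, 0.0) + u * pb[self._rows, self.k]

    def value(self, theta: np.ndarray) -> float:
        lik = self.cycle_likelihoods(theta)
        tiny = np.finfo(float).tiny
        return float(np.sum(np.log(np.maximum(lik, tiny))))

    def value_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        u, e_emb, e_pad = self._probabilities(theta)
        pb = self._pb_table(e_pad)
        s_k = pb[self._rows, self.k]
        lik = np.where(self.k_is_zero, 1.0 - u, 0.0) + u * s_k
        tiny = np.finfo(float).tiny
        lik_safe = np.maximum(lik, tiny)
        logL = float(np.sum(np.log(lik_safe)))

        # d logL / d eta_u = (S_k - delta(k)) * u(1-u) / L
        w_u = (s_k - self.k_is_zero) * u * (1.0 - u) / lik_safe
        grad_u = self.X_u.T @ w_u

        # d logL / d eta_ej = u * (S'_{k-1} - S'_k) * e(1-e) / L, where S' is
        # the Poisson-binomial PMF over the other embryos of the cycle
        w_emb = np.zeros(self.X_e.shape[0])
        k = self.k
        km1 = np.maximum(k - 1, 0)
        k_pos = k > 0
        for j in range(self.max_n):
            pb_wo = self._pb_table(np.delete(e_pad, j, axis=1))
            term = np.where(k_pos, pb_wo[self._rows, km1], 0.0) - np.where(
                k <= self.max_n - 1,
                pb_wo[self._rows, np.minimum(k, self.max_n - 1)],
                0.0,
            )
            valid = self.pad_mask[:, j]
            ej = e_pad[:, j]
            c = u * term * ej * (1.0 - ej) / lik_safe
            w_emb[self.pad_index[valid, j]] = c[valid]
        grad_e = self.X_e.T @ w_emb
        return logL, np.concatenate([grad_u, grad_e])

# ---------------------------------------------------------------------------
# public, record-level API
# ---------------------------------------------------------------------------


def cycle_probabilities(
    cycle: CycleRecord, spec: ModelSpec, theta: ParameterVector
) -> tuple[float, list[float]]:
    """Uterine receptivity probability and per-embryo viability probabilities.

    Raises :class:`SchemaError` (naming the covariate and cycle) if the cycle
    lacks a covariate the spec requires.
    """
    if not theta.conforms_to(spec):
        raise ValueError("ParameterVector does not conform to ModelSpec")

    def lookup_u(name: str) -> float:
        try:
            return float(cycle.u_covariates[name])
        except KeyError:
            raise SchemaError(
                f"covariate {name!r} missing for cycle {cycle.cycle_id!r}"
            ) from None

    eta_u = theta.beta_u[0] + sum(
        b * lookup_u(name) for name, b in zip(spec.u_terms, theta.beta_u[1:])
    )
    u = float(_expit(eta_u))

    e = []
    for j in range(cycle.n_transferred):
        emb = (
            cycle.embryo_covariates[j] if len(cycle.embryo_covariates) > 0 else {}
        )
        eta = theta.beta_e[0]
        for name, b in zip(spec.e_terms, theta.beta_e[1:]):
            if name in emb:
                eta += b * float(emb[name])
            elif name in cycle.u_covariates:
                eta += b * float(cycle.u_covariates[name])
            else:
                raise SchemaError(
                    f"covariate {name!r} missing for embryo {j + 1} of cycle "
                    f"{cycle.cycle_id!r}"
                )
        e.append(float(_expit(eta)))
    return u, e


def log_likelihood(data: Dataset, spec: ModelSpec, theta: ParameterVector) -> float:
    """Dataset log-likelihood: sum over cycles of ``ln P(k_i)``.

    Raises :class:`ZeroProbabilityError` (naming the cycles) if any cycle has
    zero probability under ``theta`` — structurally impossible data.
    """
    if not theta.conforms_to(spec):
        raise ValueError("ParameterVector does not conform to ModelSpec")
    ev = LikelihoodEvaluator(data, spec)
    lik = ev.cycle_likelihoods(theta.flat())
    if (lik <= 0.0).any():
        bad = data.cycles_table["cycle_id"][lik <= 0.0]
        raise ZeroProbabilityError(list(bad))
    return float(np.sum(np.log(lik)))
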