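"""CSV input/output for EU datasets.

Datasets travel as a two-file long format: a cycles table (one row per
treatment cycle) and an optional embryos table (one row per transferred
embryo, ``embryo_index`` 1-based within its cycle).  The two-file layout
accommodates a variable number of embryos per cycle without sparse columns.
All covariates are numeric; categorical encoding is the caller's job.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .model import Dataset

__all__ = ["read_dataset", "write_dataset"]


def read_dataset(cycles_path, embryos_path=None) -> Dataset:
    """Read and validate a dataset from its CSV pair.

    The embryos file may be omitted when no embryo-level covariates are used.
    Validation failures (duplicate ``cycle_id``, ``k_observed`` exceeding
    ``n_transferred``, embryo rows not covering ``1..n_transferred``,
    non-numeric covariates) raise with the offending rows named.
    """
    cycles = pd.read_csv(cycles_path)
    embryos = pd.read_csv(embryos_path) if embryos_path is not None else None
    return Dataset(cycles, embryos)


def write_dataset(data: Dataset, cycles_path, embryos_path=None) -> None:
    """Write a dataset to its CSV pair (embryos file only if one exists)."""
    Path(cycles_path).parent.mkdir(parents=True, exist_ok=True)
    data.cycles_table.to_csv(cycles_path, index=False)
    if data.embryos_table is not None:
        if embryos_path is None:
            raise ValueError("dataset has an embryos table but no embryos_path given")
        Path(embryos_path).parent.mkdir(parents=True, exist_ok=True)
        data.embryos_table.to_csv(embryos_path, index=False)
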