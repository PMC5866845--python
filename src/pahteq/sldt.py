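"""Fraction-of-control quantification for the scalpel-load/dye-transfer assay.

Gap junctional intercellular communication (GJIC) is measured by the area of
Lucifer Yellow spread from scalpel cuts in a confluent monolayer. Areas are
nested: cuts within dishes within independent experiments. Within each
experiment the treated mean area is expressed as a percentage of the vehicle
control mean (fraction of control, FOC); FOC values are then averaged across
experiments with the SEM taken at the experiment level, matching how such
assays report n = number of experiments.

FOC may exceed 100 (enhanced communication); it is never clipped, so
% inhibition = 100 - FOC may be negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["DyeSpreadRecord", "FocResult", "compute_foc", "foc_by_experiment",
           "inhibition_from_foc"]


@dataclass(frozen=True)
class DyeSpreadRecord:
    experiment_id: str
    treatment: str
    dish_id: str
    cut_id: str
    area: float  # dye-spread area, arbitrary squared units, > 0


@dataclass(frozen=True)
class FocResult:
    treatment: str
    foc: float         # % of control
    inhibition: float  # 100 - foc
    sem: float         # experiment-level SEM, percentage points
    n: int             # number of experiments contributing


def _validate(data: pd.DataFrame) -> None:
    required = {"experiment_id", "treatment", "dish_id", "cut_id", "area"}
    missing = required - set(data.columns)
    if missing:
        raise InputError(f"dye-spread data missing columns: {sorted(missing)}")
    if len(data) == 0:
        raise InputError("dye-spread data is empty")
    if not (data["area"] > 0).all():
        raise InputError("all dye-spread areas must be strictly positive")
    keys = data[["experiment_id", "treatment", "dish_id", "cut_id"]]
    if keys.duplicated().any():
        row = int(keys[keys.duplicated()].index[0])
        raise InputError(f"duplicate (experiment, treatment, dish, cut) key at row {row}")


def foc_by_experiment(data: pd.DataFrame, control: str) -> pd.DataFrame:
    """Per-experiment FOC table (experiments as rows, treatments as columns).

    Cuts are averaged to a dish mean, dish means to an experiment mean, and
    each experiment mean is expressed as a percentage of that experiment's
    control mean. This is the experiment-level response used for ANOVA.
    """
    _validate(data)
    if control not in set(data["treatment"]):
        raise InputError(f"control treatment {control!r} not present in data")

    dish_means = (
        data.groupby(["experiment_id", "treatment", "dish_id"], sort=True)["area"]
        .mean()
        .reset_index()
    )
    exp_means = (
        dish_means.groupby(["experiment_id", "treatment"], sort=True)["area"]
        .mean()
        .unstack("treatment")
    )
    if exp_means[control].isna().any():
        raise InputError(f"control {control!r} missing in some experiments")
    return exp_means.div(exp_means[control], axis=0) * 100.0


def compute_foc(data: pd.DataFrame, control: str) -> list[FocResult]:
    """Per-treatment fraction of control from nested dye-spread areas.

    Aggregation: cuts are averaged to a dish mean, dish means to an
    experiment mean; FOC per experiment = 100 * treated mean / control mean
    within that experiment. The reported FOC is the mean of per-experiment
    FOC values, with SEM across experiments. The control's own FOC is 100 in
    every experiment by construction (SEM 0).
    """
    foc_by_exp = foc_by_experiment(data, control)

    n_experiments = len(foc_by_exp)
    results: list[FocResult] = []
    for treatment in foc_by_exp.columns:
        vals = foc_by_exp[treatment].dropna().to_numpy()
        if len(vals) < n_experiments:
            warnings.warn(
                f"treatment {treatment!r} present in only {len(vals)} of "
                f"{n_experiments} experiments; FOC computed over those",
                stacklevel=2,
            )
        foc = float(np.mean(vals))
        sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        results.append(
            FocResult(
                treatment=str(treatment),
                foc=foc,
                inhibition=100.0 - foc,
                sem=sem,
                n=int(len(vals)),
            )
        )
    return results


def inhibition_from_foc(foc: float) -> float:
    """% inhibition corresponding to a fraction-of-control percentage."""
    return 100.0 - foc
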