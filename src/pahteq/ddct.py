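"""Comparative-CT (delta-delta-CT) relative gene expression.

Fold change over the vehicle control, normalized to a reference gene
(18S rRNA in the study design this package models). Per experiment:

    dCT  = mean CT(target) - mean CT(normalizer)
    ddCT = dCT(treatment) - dCT(control)
    fold change = 2^(-ddCT)

Technical replicates are averaged on the CT scale before any delta is
formed; the reported fold change is the mean of per-experiment fold changes
with SEM across experiments (biological replication). Amplification
efficiency is fixed at 2.0 (perfect doubling), the standard comparative-CT
assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["QpcrRecord", "FoldChangeResult", "fold_change"]


@dataclass(frozen=True)
class QpcrRecord:
    experiment_id: str
    treatment: str
    gene: str
    replicate: str
    ct: float  # threshold cycle; non-detects must be flagged upstream, not NaN


@dataclass(frozen=True)
class FoldChangeResult:
    treatment: str
    gene: str
    fold_change: float  # control-relative, > 0
    sem: float
    n: int


def fold_change(
    data: pd.DataFrame, control: str, normalizer: str
) -> list[FoldChangeResult]:
    """Comparative-CT fold changes for every (treatment, target gene).

    Raises ``InputError`` when the control treatment or the normalizer gene
    is absent from any (experiment, treatment), or when CT values are
    non-finite (non-detects must be handled before quantification).
    """
    required = {"experiment_id", "treatment", "gene", "replicate", "ct"}
    missing = required - set(data.columns)
    if missing:
        raise InputError(f"qPCR data missing columns: {sorted(missing)}")
    if not np.isfinite(data["ct"]).all():
        raise InputError("non-finite CT values present; flag non-detects upstream")
    if control not in set(data["treatment"]):
        raise InputError(f"control treatment {control!r} not present")
    if normalizer not in set(data["gene"]):
        raise InputError(f"normalizer gene {normalizer!r} not present")

    # technical replicates -> mean CT per (experiment, treatment, gene)
    ct_mean = (
        data.groupby(["experiment_id", "treatment", "gene"], sort=True)["ct"]
        .mean()
        .unstack("gene")
    )
    if normalizer not in ct_mean.columns or ct_mean[normalizer].isna().any():
        raise InputError(
            f"normalizer gene {normalizer!r} missing in some (experiment, treatment)"
        )
    dct = ct_mean.drop(columns=[normalizer]).sub(ct_mean[normalizer], axis=0)
    # ddCT against the control within each experiment
    dct = dct.reset_index()
    results: list[FoldChangeResult] = []
    genes = [c for c in dct.columns if c not in ("experiment_id", "treatment")]
    control_dct = dct[dct["treatment"] == control].set_index("experiment_id")
    for treatment in sorted(dct["treatment"].unique()):
        sub = dct[dct["treatment"] == treatment].set_index("experiment_id")
        for gene in genes:
            ddct = sub[gene] - control_dct[gene].reindex(sub.index)
            fc = np.power(2.0, -ddct.dropna().to_numpy())
            if len(fc) == 0:
                raise InputError(
                    f"no paired control for treatment {treatment!r}, gene {gene!r}"
                )
            mean_fc = float(np.mean(fc))
            sem = float(np.std(fc, ddof=1) / np.sqrt(len(fc))) if len(fc) > 1 else 0.0
            results.append(
                FoldChangeResult(
                    treatment=str(treatment),
                    gene=str(gene),
                    fold_change=mean_fc,
                    sem=sem,
                    n=int(len(fc)),
                )
            )
    return results
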