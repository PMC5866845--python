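"""Anti-BPDE-DNA adduct quantification from HPLC-FLD tetrol peak responses.

The genotoxic benzo[a]pyrene diol-epoxide adduct is measured after acidic
hydrolysis of DNA as its fluorescent surrogate analyte B[a]P-tetrol I-1.
Peak responses are converted to analyte amounts through a linear calibration
curve fitted on blank-corrected standard responses, and amounts to an adduct
rate per 10^8 nucleotides by mole conversion:

    rate = (tetrol mol) / (nucleotide mol) * 10^8
         = (pg * 1e-12 / MW_tetrol) / (ug * 1e-6 / MW_nt) * 1e8

with MW_tetrol = 320.34 g/mol (C20H16O4) and a mean nucleotide weight of
330 g/mol (standard DNA convention). Hydrolysis is assumed complete (one
tetrol per adduct; no correction factor).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import CalibrationError, InputError

__all__ = [
    "MW_TETROL",
    "MW_NUCLEOTIDE",
    "HplcRecord",
    "CalibrationCurve",
    "AdductResult",
    "fit_calibration",
    "quantify_tetrol",
    "adduct_rate",
    "summarize_adducts",
    "dose_fold_change",
]

MW_TETROL = 320.34      # g/mol, B[a]P-tetrol I-1 (C20H16O4)
MW_NUCLEOTIDE = 330.0   # g/mol, mean DNA nucleotide


@dataclass(frozen=True)
class HplcRecord:
    """One HPLC-FLD injection: a standard, a blank, or a DNA sample."""

    kind: str  # "standard" | "blank" | "sample"
    response: float  # fluorescence peak response, arbitrary units
    concentration: float | None = None  # ug/L, standards only
    treatment: str | None = None        # samples only
    dna_mass: float | None = None       # ug DNA applied, samples only
    experiment_id: str | None = None
    injection_volume: float = 600.0     # uL

    def __post_init__(self) -> None:
        if self.kind not in ("standard", "blank", "sample"):
            raise InputError(f"unknown HPLC record kind {self.kind!r}")
        if self.kind == "standard" and self.concentration is None:
            raise InputError("standard record requires a concentration")
        if self.kind == "sample":
            if self.dna_mass is None or self.dna_mass <= 0:
                raise InputError("sample record requires dna_mass > 0")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear blank-corrected response vs concentration fit."""

    slope: float          # response units per (ug/L)
    intercept: float      # response units
    r_squared: float
    valid_range: tuple[float, float]  # (min, max) standard concentration, ug/L
    blank_response: float = 0.0       # mean blank response subtracted

    @property
    def acceptable(self) -> bool:
        """Quality gate: r^2 >= 0.98 for an acceptable calibration."""
        return self.r_squared >= 0.98


@dataclass(frozen=True)
class AdductResult:
    treatment: str
    adduct_rate: float  # adducts per 10^8 nucleotides
    sem: float
    n: int
    truncated: bool = False  # negative blank-corrected estimate clipped to 0


def fit_calibration(
    standards: Sequence[HplcRecord], blanks: Sequence[HplcRecord] = ()
) -> CalibrationCurve:
    """Ordinary least-squares line on blank-corrected standard responses.

    The mean blank response is subtracted from every standard response
    before the unweighted fit. Requires >= 3 distinct concentration levels
    and a positive slope.
    """
    std = [r for r in standards if r.kind == "standard"]
    conc = np.array([r.concentration for r in std], dtype=float)
    if len(np.unique(conc)) < 3:
        raise InputError("calibration requires >= 3 distinct standard concentrations")
    blank_mean = (
        float(np.mean([b.response for b in blanks])) if len(blanks) else 0.0
    )
    resp = np.array([r.response for r in std], dtype=float) - blank_mean
    fit = sps.linregress(conc, resp)
    if fit.slope <= 0:
        raise CalibrationError(f"non-positive calibration slope {fit.slope:g}")
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        valid_range=(float(conc.min()), float(conc.max())),
        blank_response=blank_mean,
    )


def quantify_tetrol(record: HplcRecord, curve: CalibrationCurve) -> float:
    """Tetrol amount (pg) in the injected volume for one sample record.

    concentration (ug/L) = (blank-corrected response - intercept) / slope;
    amount (pg) = concentration * injection volume (uL), since
    1 ug/L == 1 pg/uL. Concentrations outside the calibration range are
    still converted (the linear model extends), but callers can check
    ``curve.valid_range`` to flag them.
    """
    if not np.isfinite(record.response):
        raise InputError("non-finite peak response")
    corrected = record.response - curve.blank_response
    concentration = (corrected - curve.intercept) / curve.slope
    return concentration * record.injection_volume


def adduct_rate(tetrol_pg: float, dna_ug: float) -> float:
    """Adducts per 10^8 nucleotides from tetrol mass and DNA mass.

    Negative tetrol masses (possible after blank correction of near-zero
    signals) yield negative rates; aggregate-level truncation is the
    caller's decision (see ``summarize_adducts``).
    """
    if dna_ug <= 0:
        raise InputError("DNA mass must be positive")
    tetrol_mol = tetrol_pg * 1e-12 / MW_TETROL
    nucleotide_mol = dna_ug * 1e-6 / MW_NUCLEOTIDE
    return tetrol_mol / nucleotide_mol * 1e8


def summarize_adducts(
    samples: Sequence[HplcRecord], curve: CalibrationCurve
) -> list[AdductResult]:
    """Per-treatment adduct rates (mean, SEM over experiments).

    Each sample record is quantified through the calibration curve and
    converted to a rate with its own DNA mass; rates are averaged per
    treatment. Negative mean rates are truncated to zero and flagged.
    """
    rates: dict[str, list[float]] = {}
    for rec in samples:
        if rec.kind != "sample":
            continue
        pg = quantify_tetrol(rec, curve)
        rate = adduct_rate(pg, rec.dna_mass)
        rates.setdefault(rec.treatment or "", []).append(rate)
    results = []
    for treatment in sorted(rates):
        vals = np.array(rates[treatment])
        mean = float(np.mean(vals))
        sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        truncated = mean < 0
        results.append(
            AdductResult(
                treatment=treatment,
                adduct_rate=max(mean, 0.0),
                sem=sem,
                n=int(len(vals)),
                truncated=truncated,
            )
        )
    return results


def dose_fold_change(
    results: Sequence[AdductResult], low: str, high: str
) -> float:
    """Ratio of mean adduct rates between a high and a low dose treatment."""
    by_label = {r.treatment: r for r in results}
    for label in (low, high):
        if label not in by_label:
            raise InputError(f"treatment {label!r} missing from adduct results")
    if by_label[low].adduct_rate <= 0:
        raise InputError(f"low-dose treatment {low!r} has zero adduct rate")
    return by_label[high].adduct_rate / by_label[low].adduct_rate
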