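"""Synthetic raw-assay data with the study's replicate structure.

Generates dye-spread areas, qPCR CT values, and HPLC-FLD peak responses for
a configurable treatment panel, so the whole quantification pipeline is
testable without any experimental download. The default design mirrors the
in-vitro study this package models: 3 scalpel cuts per dish, 3 dishes per
treatment, 3 independent experiments; a DMSO vehicle control; benzo[a]pyrene
alone, a 1:1 fluoranthene / 1-methylanthracene binary mixture, and
combinations of the two.

Noise families (the assay papers state none, so these are modeling choices):
dye areas are lognormal (positive, right-skewed) with a configurable
coefficient of variation; CT values are normal on the cycle scale; HPLC
responses carry multiplicative Gaussian noise. Setting a dispersion to zero
gives the exact noiseless limit, in which every downstream estimator must
recover the configured truth exactly.

Control anchors (the study reports only control-relative quantities): control
median dye area 10,000 arbitrary units^2; normalizer CT 15; target CT 25.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .adducts import MW_NUCLEOTIDE, MW_TETROL
from .errors import ConfigurationError
from .types import Treatment

__all__ = ["SyntheticConfig", "study_config", "simulate_dye_spread",
           "simulate_qpcr", "simulate_hplc"]

CONTROL_AREA = 10_000.0   # control median dye-spread area, arbitrary units^2
NORMALIZER_CT = 15.0      # 18S rRNA-like normalizer threshold cycle
TARGET_CT = 25.0          # control-level target-gene threshold cycle
NORMALIZER_GENE = "Rn18s"
DEFAULT_SEED = 20171123


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design and truth parameters for the three generators.

    ``true_foc`` maps treatment label -> % of control GJIC (control must be
    exactly 100); ``true_fold_change`` maps (treatment, gene) -> expression
    fold change over control; ``true_adduct_rate`` maps treatment ->
    adducts per 10^8 nucleotides. Dispersions: ``area_cv`` (lognormal CV of
    dye areas), ``ct_sd`` (cycles), ``response_cv`` (HPLC peak response CV);
    zero disables noise for that assay.
    """

    treatments: tuple[Treatment, ...]
    control: str = "DMSO"
    seed: int = DEFAULT_SEED
    n_dishes: int = 3
    n_cuts_per_dish: int = 3
    n_experiments: int = 3
    n_tech_replicates: int = 3
    true_foc: Mapping[str, float] = field(default_factory=dict)
    true_fold_change: Mapping[tuple[str, str], float] = field(default_factory=dict)
    true_adduct_rate: Mapping[str, float] = field(default_factory=dict)
    area_cv: float = 0.15
    ct_sd: float = 0.15
    response_cv: float = 0.05
    calib_slope: float = 250.0   # response units per (ug/L)
    calib_intercept: float = 5.0  # blank-level response
    injection_volume: float = 600.0  # uL
    standard_range: tuple[float, float] = (0.0095, 1.52)  # ug/L
    n_standards: int = 8
    n_blanks: int = 3

    def __post_init__(self) -> None:
        labels = [t.label for t in self.treatments]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("duplicate treatment labels")
        for name in ("n_dishes", "n_cuts_per_dish", "n_experiments",
                     "n_tech_replicates"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("area_cv", "ct_sd", "response_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.calib_slope <= 0:
            raise ConfigurationError("calib_slope must be positive")
        for label, foc in self.true_foc.items():
            if not (0 < foc <= 150):
                raise ConfigurationError(
                    f"true_foc[{label!r}] = {foc} outside (0, 150]"
                )
        if self.control in self.true_foc and self.true_foc[self.control] != 100:
            raise ConfigurationError("true_foc of the control must be exactly 100")
        for key, fc in self.true_fold_change.items():
            if fc <= 0:
                raise ConfigurationError(f"true_fold_change[{key}] must be > 0")
        for label, rate in self.true_adduct_rate.items():
            if rate < 0:
                raise ConfigurationError(
                    f"true_adduct_rate[{label!r}] must be >= 0"
                )

    def treatment_labels(self) -> list[str]:
        return [t.label for t in self.treatments]


def study_config(seed: int = DEFAULT_SEED, **overrides) -> SyntheticConfig:
    """The default study design with paper-scale effect sizes.

    Combination-treatment FOC truths (53, 38, 34 %) are the study's observed
    values; B[a]P 1 uM is set at 60 % FOC (~40 % GJIC inhibition, the TEF
    anchor); the binary mixture alone is a mild inhibitor. Adduct-rate
    truths are on an arbitrary absolute scale with a 17-fold spread between
    the lowest and highest B[a]P dose.
    """
    treatments = (
        Treatment("DMSO", {}),
        Treatment("BaP_0.3", {"B[a]P": 0.3}),
        Treatment("BaP_1", {"B[a]P": 1.0}),
        Treatment("BaP_3", {"B[a]P": 3.0}),
        Treatment("mix_10", {"Flthn": 5.0, "1-MeA": 5.0}),
        Treatment("combo_1", {"B[a]P": 1.0, "Flthn": 0.5, "1-MeA": 0.5}),
        Treatment("combo_5", {"B[a]P": 1.0, "Flthn": 2.5, "1-MeA": 2.5}),
        Treatment("combo_10", {"B[a]P": 1.0, "Flthn": 5.0, "1-MeA": 5.0}),
    )
    defaults = dict(
        treatments=treatments,
        control="DMSO",
        seed=seed,
        true_foc={
            "DMSO": 100.0,
            "BaP_1": 60.0,
            "mix_10": 65.0,
            "combo_1": 53.0,
            "combo_5": 38.0,
            "combo_10": 34.0,
        },
        true_fold_change={
            ("BaP_1", "Cyp1a1"): 10.0,
            ("combo_10", "Cyp1a1"): 12.0,
            ("mix_10", "Cox2"): 3.0,
            ("combo_10", "Cox2"): 4.0,
            ("combo_10", "Gja1"): 0.7,
        },
        true_adduct_rate={"BaP_0.3": 100.0, "BaP_1": 550.0, "BaP_3": 1700.0},
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def _require_control(config: SyntheticConfig) -> None:
    if config.control not in config.treatment_labels():
        raise ConfigurationError(
            f"control treatment {config.control!r} not among treatments"
        )


def simulate_dye_spread(config: SyntheticConfig) -> pd.DataFrame:
    """Dye-spread areas: one row per (experiment, treatment, dish, cut).

    Areas are lognormal with median = control median * true_foc/100 and
    coefficient of variation ``area_cv``; treatments without a configured
    truth default to no effect (FOC 100).
    """
    _require_control(config)
    rng = np.random.default_rng(config.seed)
    sigma = math.sqrt(math.log1p(config.area_cv**2))
    rows = []
    for e in range(1, config.n_experiments + 1):
        for t in config.treatments:
            median = CONTROL_AREA * config.true_foc.get(t.label, 100.0) / 100.0
            for d in range(1, config.n_dishes + 1):
                for c in range(1, config.n_cuts_per_dish + 1):
                    area = median * math.exp(sigma * rng.standard_normal())
                    rows.append((f"E{e}", t.label, f"D{d}", f"C{c}", area))
    return pd.DataFrame(
        rows, columns=["experiment_id", "treatment", "dish_id", "cut_id", "area"]
    )


def simulate_qpcr(config: SyntheticConfig) -> pd.DataFrame:
    """CT values: one row per (experiment, treatment, gene, tech replicate).

    Target-gene mean CT is shifted by -log2(fold change) relative to the
    control anchor, so the comparative-CT estimator has expectation ~= the
    configured truth; the normalizer gene is treatment-independent.
    """
    _require_control(config)
    rng = np.random.default_rng(config.seed + 1)
    genes = sorted({g for _, g in config.true_fold_change})
    if not genes:
        genes = ["Cyp1a1"]
    # 2^(-ddCT) of normal CTs is lognormal and biased upward by
    # exp((sigma_ddCT * ln 2)^2 / 2); shift treated target means so the
    # comparative-CT estimator has expectation equal to the configured truth
    var_ddct = 4.0 * config.ct_sd**2 / config.n_tech_replicates
    bias_shift = var_ddct * math.log(2) / 2.0
    rows = []
    for e in range(1, config.n_experiments + 1):
        for t in config.treatments:
            for gene in [NORMALIZER_GENE] + genes:
                if gene == NORMALIZER_GENE:
                    mean_ct = NORMALIZER_CT
                elif t.label == config.control:
                    mean_ct = TARGET_CT
                else:
                    fc = config.true_fold_change.get((t.label, gene), 1.0)
                    mean_ct = TARGET_CT - math.log2(fc) + bias_shift
                for r in range(1, config.n_tech_replicates + 1):
                    ct = mean_ct + config.ct_sd * rng.standard_normal()
                    rows.append((f"E{e}", t.label, gene, f"R{r}", ct))
    return pd.DataFrame(
        rows, columns=["experiment_id", "treatment", "gene", "replicate", "ct"]
    )


def simulate_hplc(config: SyntheticConfig) -> pd.DataFrame:
    """HPLC-FLD records: tetrol standards, blanks, and DNA samples.

    Standards span the configured calibration range (geometric spacing);
    each treatment with a configured adduct rate contributes one sample per
    experiment, with DNA mass drawn uniformly on 20-35 ug (the scale of
    typical column yields). The sample peak response is the configured rate
    inverted through the mole-conversion and calibration line, plus noise.
    """
    rng = np.random.default_rng(config.seed + 2)

    def noisy(clean: float) -> float:
        return clean * (1.0 + config.response_cv * rng.standard_normal())

    rows = []
    lo, hi = config.standard_range
    for conc in np.geomspace(lo, hi, config.n_standards):
        clean = config.calib_intercept + config.calib_slope * conc
        rows.append(("standard", float(conc), noisy(clean), "", np.nan))
    for _ in range(config.n_blanks):
        rows.append(("blank", np.nan, noisy(config.calib_intercept), "", np.nan))
    for e in range(1, config.n_experiments + 1):
        for t in config.treatments:
            if t.label not in config.true_adduct_rate:
                continue
            rate = config.true_adduct_rate[t.label]
            dna_ug = rng.uniform(20.0, 35.0)
            # rate (per 1e8 nt) -> tetrol pg -> concentration ug/L in the
            # injected volume (1 ug/L == 1 pg/uL)
            tetrol_pg = rate / 1e8 * (dna_ug * 1e-6 / MW_NUCLEOTIDE) * MW_TETROL * 1e12
            conc = tetrol_pg / config.injection_volume
            clean = config.calib_intercept + config.calib_slope * conc
            rows.append(("sample", np.nan, noisy(clean), t.label, dna_ug))
    return pd.DataFrame(
        rows,
        columns=["kind", "concentration_ug_per_L", "response", "treatment",
                 "dna_mass_ug"],
    )
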