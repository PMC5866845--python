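"""Endpoint-specific toxic equivalency factors and additive mixture prediction.

The central analysis: rank compound potency for a co-carcinogenic endpoint
(here, inhibition of gap junctional intercellular communication, GJIC) by the
dose producing a common effect level, express potency relative to a reference
compound (benzo[a]pyrene, TEF = 1.0), collapse a mixture to a toxic-equivalent
dose TEQ = sum_i TEF_i * dose_i, and predict the mixture effect under a linear
effect-additive model anchored at the reference:

    predicted % inhibition = effect_level * TEQ / ref_dose   (capped at 100)

With the anchor (ref_dose = 1 uM, effect_level = 40 % inhibition at 24 h) the
prediction for a mixture is exactly the sum of its single-compound
predictions, which is what "effect additivity" means here.

TEFs are endpoint-specific: a TEF table derived for GJIC inhibition must not
be reused for carcinogenicity (or vice versa); ``tef_misapplication_ratio``
quantifies how far such a reuse would misstate potency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import isotonic_regression

from .errors import ConfigurationError, ExtrapolationError, InputError

__all__ = [
    "DoseResponseCurve",
    "TefTable",
    "MixtureSpec",
    "MixturePrediction",
    "PredictionComparison",
    "equieffective_dose",
    "compute_tefs",
    "teq_dose",
    "predict_additive",
    "compare_predictions",
    "tef_misapplication_ratio",
]


@dataclass(frozen=True)
class DoseResponseCurve:
    """Per-compound table of (dose uM, % inhibition) at a fixed timepoint.

    Doses must be strictly increasing and positive; an implicit (0, 0) point
    is assumed for interpolation below the lowest tested dose. Effects are
    percent inhibition of the endpoint (may be read off figures or tables).
    """

    compound: str
    points: tuple[tuple[float, float], ...]
    timepoint_h: float = 24.0

    def __post_init__(self) -> None:
        pts = tuple((float(d), float(e)) for d, e in self.points)
        object.__setattr__(self, "points", pts)
        doses = [d for d, _ in pts]
        if len([d for d in doses if d > 0]) < 1 or len(pts) < 2:
            # a single positive-dose point plus the implicit origin is the
            # degenerate minimum; require >= 2 explicit points for a curve
            if len(pts) < 2:
                raise InputError(
                    f"curve {self.compound!r}: need >= 2 dose-response points"
                )
        if any(d < 0 for d in doses):
            raise InputError(f"curve {self.compound!r}: negative dose")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise InputError(
                f"curve {self.compound!r}: doses must be strictly increasing"
            )

    @property
    def doses(self) -> np.ndarray:
        return np.array([d for d, _ in self.points], dtype=float)

    @property
    def effects(self) -> np.ndarray:
        return np.array([e for _, e in self.points], dtype=float)

    def isotonic_effects(self) -> np.ndarray:
        """Effects after pool-adjacent-violators monotone cleanup.

        The TEF concept assumes monotone pharmacology; non-monotone wiggles
        are treated as measurement noise.
        """
        return np.asarray(isotonic_regression(self.effects).x, dtype=float)


@dataclass(frozen=True)
class TefTable:
    """Reference compound plus per-compound endpoint-specific TEFs.

    ``ref_dose`` and ``effect_level`` record the anchor at which potencies
    were equated; they drive the additive prediction. ``endpoint`` is
    mandatory because TEFs are only meaningful for the endpoint they were
    derived on.
    """

    reference: str
    endpoint: str
    ref_dose: float
    effect_level: float
    tefs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.endpoint:
            raise ConfigurationError("TefTable requires an endpoint label")
        if self.reference not in self.tefs:
            raise ConfigurationError(
                f"reference {self.reference!r} missing from TEF map"
            )
        if self.tefs[self.reference] != 1.0:
            raise ConfigurationError("TEF of the reference compound must be 1.0")
        if any(t <= 0 for t in self.tefs.values()):
            raise ConfigurationError("all TEFs must be positive")
        if self.ref_dose <= 0:
            raise ConfigurationError("ref_dose must be positive")


@dataclass(frozen=True)
class MixtureSpec:
    """A mixture as compound -> dose (uM), with a display label."""

    label: str
    components: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.components.values()):
            raise InputError(f"mixture {self.label!r}: negative dose")


@dataclass(frozen=True)
class MixturePrediction:
    """Additive-model prediction for one mixture."""

    mixture: str
    teq_dose: float
    predicted_inhibition: float
    predicted_foc: float
    capped: bool = False
    observed_inhibition: float | None = None
    deviation: float | None = None


@dataclass(frozen=True)
class PredictionComparison:
    """Prediction-vs-observation table with its summary statistic."""

    rows: tuple[MixturePrediction, ...]
    mean_abs_deviation: float


def equieffective_dose(curve: DoseResponseCurve, effect_level: float) -> float:
    """Dose (uM) at which the curve reaches ``effect_level`` % inhibition.

    The curve is made monotone by isotonic regression, then the level is
    located by linear interpolation on log10(dose) between the bracketing
    observed points. An exact observed match returns that dose directly
    (the smallest such dose on a flat segment). Below the lowest tested
    dose, interpolation is linear in dose from the implicit (0, 0) point.
    Levels above the curve maximum raise ``ExtrapolationError`` — no
    extrapolation is performed.
    """
    if effect_level < 0:
        raise InputError("effect_level must be >= 0")
    if effect_level == 0:
        return 0.0
    doses = curve.doses
    effects = curve.isotonic_effects()
    if effect_level > effects.max():
        raise ExtrapolationError(
            f"curve {curve.compound!r}: effect level {effect_level} exceeds "
            f"maximum observed effect {effects.max():g}"
        )
    exact = np.flatnonzero(np.isclose(effects, effect_level, rtol=0, atol=1e-12))
    if exact.size:
        return float(doses[exact[0]])
    # first index at which the monotone curve exceeds the level
    j = int(np.searchsorted(effects, effect_level, side="left"))
    if j == 0:
        # below the lowest observed effect: linear in dose from (0, 0)
        return float(doses[0] * effect_level / effects[0])
    d_lo, d_hi = doses[j - 1], doses[j]
    e_lo, e_hi = effects[j - 1], effects[j]
    if d_lo == 0:
        return float(d_hi * (effect_level - e_lo) / (e_hi - e_lo))
    frac = (effect_level - e_lo) / (e_hi - e_lo)
    return float(10 ** (math.log10(d_lo) + frac * (math.log10(d_hi) - math.log10(d_lo))))


def compute_tefs(
    curves: Mapping[str, DoseResponseCurve],
    reference: str,
    effect_level: float = 40.0,
    endpoint: str = "GJIC inhibition, 24 h",
) -> TefTable:
    """Derive endpoint-specific TEFs from dose-response curves.

    TEF_i = equieffective_dose(reference) / equieffective_dose(i), so the
    reference has TEF 1.0 exactly and less potent compounds (larger
    equi-effective doses) get smaller TEFs.
    """
    if reference not in curves:
        raise InputError(f"reference compound {reference!r} has no curve")
    eq_doses: dict[str, float] = {}
    for compound, curve in curves.items():
        try:
            eq_doses[compound] = equieffective_dose(curve, effect_level)
        except ExtrapolationError as exc:
            raise ExtrapolationError(f"compound {compound!r}: {exc}") from exc
        if eq_doses[compound] <= 0:
            raise InputError(
                f"compound {compound!r}: non-positive equi-effective dose"
            )
    ref_dose = eq_doses[reference]
    tefs = {c: ref_dose / d for c, d in eq_doses.items()}
    tefs[reference] = 1.0
    return TefTable(
        reference=reference,
        endpoint=endpoint,
        ref_dose=ref_dose,
        effect_level=effect_level,
        tefs=tefs,
    )


def teq_dose(mixture: MixtureSpec, tefs: TefTable) -> float:
    """Toxic-equivalent dose of a mixture: TEQ = sum_i TEF_i * dose_i (uM)."""
    total = 0.0
    for compound, dose in mixture.components.items():
        if compound not in tefs.tefs:
            raise InputError(
                f"mixture {mixture.label!r}: no TEF for compound {compound!r}"
            )
        total += tefs.tefs[compound] * dose
    return total


def predict_additive(
    mixture: MixtureSpec,
    tefs: TefTable,
    observed_inhibition: float | None = None,
) -> MixturePrediction:
    """Predict mixture % inhibition under the linear effect-additive model.

    predicted = effect_level * TEQ / ref_dose, capped at 100 (with a cap
    flag); predicted FOC = 100 - predicted inhibition. If an observed
    inhibition is supplied the deviation (observed - predicted, percentage
    points) is attached.
    """
    teq = teq_dose(mixture, tefs)
    raw = tefs.effect_level * teq / tefs.ref_dose
    capped = raw > 100.0
    predicted = min(raw, 100.0)
    deviation = None
    if observed_inhibition is not None:
        deviation = observed_inhibition - predicted
    return MixturePrediction(
        mixture=mixture.label,
        teq_dose=teq,
        predicted_inhibition=predicted,
        predicted_foc=100.0 - predicted,
        capped=capped,
        observed_inhibition=observed_inhibition,
        deviation=deviation,
    )


def compare_predictions(
    predictions: Sequence[MixturePrediction],
    observed: Mapping[str, float],
) -> PredictionComparison:
    """Attach observed inhibition to predictions and summarize agreement.

    Deviation = observed - predicted in percentage points; the summary is
    the mean absolute deviation across mixtures. Labels must match exactly.
    """
    unmatched = set(observed) - {p.mixture for p in predictions}
    if unmatched:
        raise InputError(f"observed labels with no prediction: {sorted(unmatched)}")
    rows = []
    for p in predictions:
        if p.mixture not in observed:
            raise InputError(f"no observation for mixture {p.mixture!r}")
        obs = float(observed[p.mixture])
        rows.append(
            MixturePrediction(
                mixture=p.mixture,
                teq_dose=p.teq_dose,
                predicted_inhibition=p.predicted_inhibition,
                predicted_foc=p.predicted_foc,
                capped=p.capped,
                observed_inhibition=obs,
                deviation=obs - p.predicted_inhibition,
            )
        )
    mad = float(np.mean([abs(r.deviation) for r in rows])) if rows else 0.0
    return PredictionComparison(rows=tuple(rows), mean_abs_deviation=mad)


def tef_misapplication_ratio(tef_endpoint_a: float, tef_endpoint_b: float) -> float:
    """Fold factor by which endpoint-b TEFs misstate endpoint-a potency.

    E.g. fluoranthene's GJIC-inhibition TEF (0.1) vs its carcinogenicity TEF
    (0.001) gives 100: carcinogenicity TEFs would underestimate the
    co-carcinogenic potency 100-fold.
    """
    if tef_endpoint_a <= 0 or tef_endpoint_b <= 0:
        raise InputError("TEFs must be positive")
    return tef_endpoint_a / tef_endpoint_b
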