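"""Core domain types shared across assay modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import ConfigurationError


@dataclass(frozen=True)
class Treatment:
    """A named exposure condition: compound -> dose in micromolar.

    The vehicle control is a Treatment with an empty (or all-zero) dose map.
    """

    label: str
    components: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for compound, dose in self.components.items():
            if dose < 0:
                raise ConfigurationError(
                    f"treatment {self.label!r}: negative dose for {compound!r}"
                )

    @property
    def is_control(self) -> bool:
        return all(d == 0 for d in self.components.values())

    def total_dose(self) -> float:
        return float(sum(self.components.values()))
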