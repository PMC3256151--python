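"""Plasma-composition inputs: per-subject factor levels and molar conversion.

A subject's coagulation-factor panel is expressed as percent of the
population mean (100 = average healthy plasma). The simulation works in
molar units, so percentages are rescaled by the literature mean plasma
concentrations of the eight measured proteins: the procoagulant zymogens
fII (prothrombin), fV, fVII, fVIII, fIX, fX and the stoichiometric
inhibitors antithrombin (AT) and tissue factor pathway inhibitor (TFPI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

FACTOR_NAMES: tuple[str, ...] = (
    "fII", "fV", "fVII", "fVIII", "fIX", "fX", "AT", "TFPI",
)

GROUP_LABELS = ("case", "control")


class CompositionError(ValueError):
    """Invalid plasma composition (missing, negative or non-finite level)."""


class MeansError(ValueError):
    """Invalid mean-concentration table."""


@dataclass(frozen=True)
class PlasmaComposition:
    """Eight factor levels in percent-of-mean, plus optional demographics.

    ``levels`` maps each of :data:`FACTOR_NAMES` to a percent value
    (dimensionless; 100 = population mean). All eight must be present,
    finite and non-negative.
    """

    subject_id: str
    levels: Mapping[str, float]
    group: str | None = None
    sex: str | None = None
    age: float | None = None
    bmi: float | None = None
    oc_use: bool | None = None

    def __post_init__(self) -> None:
        missing = [f for f in FACTOR_NAMES if f not in self.levels]
        if missing:
            raise CompositionError(
                f"subject {self.subject_id!r}: missing factor level(s) {missing}"
            )
        for f in FACTOR_NAMES:
            v = float(self.levels[f])
            if not math.isfinite(v):
                raise CompositionError(
                    f"subject {self.subject_id!r}: non-finite {f} level {v!r}"
                )
            if v < 0:
                raise CompositionError(
                    f"subject {self.subject_id!r}: negative {f} level {v!r}"
                )
        if self.group is not None and self.group not in GROUP_LABELS:
            raise CompositionError(
                f"subject {self.subject_id!r}: group {self.group!r} "
                f"not in {GROUP_LABELS}"
            )
        object.__setattr__(
            self, "levels", {f: float(self.levels[f]) for f in FACTOR_NAMES}
        )

    def replace_levels(self, **updates: float) -> "PlasmaComposition":
        """Return a copy with some factor percentages replaced."""
        unknown = set(updates) - set(FACTOR_NAMES)
        if unknown:
            raise CompositionError(f"unknown factor name(s): {sorted(unknown)}")
        new = dict(self.levels)
        new.update(updates)
        return PlasmaComposition(
            subject_id=self.subject_id, levels=new, group=self.group,
            sex=self.sex, age=self.age, bmi=self.bmi, oc_use=self.oc_use,
        )


@dataclass(frozen=True)
class MeanConcentrationTable:
    """Molar plasma concentration corresponding to 100% for each factor."""

    concentrations: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [f for f in FACTOR_NAMES if f not in self.concentrations]
        if missing:
            raise MeansError(f"mean-concentration table missing {missing}")
        for f in FACTOR_NAMES:
            v = float(self.concentrations[f])
            if not (v > 0 and math.isfinite(v)):
                raise MeansError(f"mean concentration for {f} must be > 0, got {v!r}")
        object.__setattr__(
            self,
            "concentrations",
            {f: float(self.concentrations[f]) for f in FACTOR_NAMES},
        )

    def __getitem__(self, factor: str) -> float:
        return self.concentrations[factor]


def default_means() -> MeanConcentrationTable:
    """Load the packaged literature mean-concentration table."""
    text = (
        resources.files("coagxa.data") / "mean_concentrations.yaml"
    ).read_text()
    return MeanConcentrationTable(yaml.safe_load(text))


def percent_to_molar(
    composition: PlasmaComposition, means: MeanConcentrationTable
) -> dict[str, float]:
    """Convert percent-of-mean factor levels to molar concentrations.

    Each factor's molar value is ``(percent / 100) * mean molar value``.
    """
    return {
        f: composition.levels[f] / 100.0 * means[f] for f in FACTOR_NAMES
    }
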