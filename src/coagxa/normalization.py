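"""Which factors drive the difference between two simulated outputs?

Given a base group's mean composition and a reference (comparison) group's
mean composition, the analysis sets subsets of the base group's factors to
the reference values, re-simulates, and measures how far the generation
curve remains from the reference curve. The minimal subset whose
adjustment brings the curves together identifies the factors that drive
the group difference (e.g. fIX and TFPI for oral-contraceptive users'
elevated fXa generation).

Discrepancy between two curves is the worst relative deviation of the
scale-carrying metrics (MaxL, MaxR, AUC) from the reference; curves are
"normalized" when it falls below a threshold theta (default 5%).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .composition import FACTOR_NAMES, MeanConcentrationTable, PlasmaComposition
from .metrics import extract_metrics
from .network import ReactionNetwork, build_network
from .simulate import SimulationConfig, simulate
from . import metrics as _metrics

_SCALE_METRICS = ("MaxL", "MaxR", "AUC")


class NormalizationError(ValueError):
    """Discrepancy undefined or no subset achieves the threshold."""


@dataclass(frozen=True)
class AdjustmentScenario:
    """One evaluated factor adjustment."""

    subset: tuple[str, ...]
    discrepancy: float


@dataclass(frozen=True)
class NormalizationResult:
    """Outcome of the minimal-subset search.

    ``subset`` is the smallest factor set whose adjustment to the
    reference values brings the discrepancy to <= theta; ``trace`` holds
    the best scenario at each cardinality examined (the witness that all
    smaller cardinalities fail).
    """

    subset: tuple[str, ...]
    discrepancy: float
    theta: float
    baseline_discrepancy: float
    trace: tuple[AdjustmentScenario, ...]


def curve_discrepancy(series_a: np.ndarray, series_b: np.ndarray, step: float) -> float:
    """Worst relative metric deviation of curve A from reference curve B.

    max over {MaxL, MaxR, AUC} of |m_A - m_B| / m_B.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise NormalizationError("series must share one grid")
    ma = extract_metrics(a, step)
    mb = extract_metrics(b, step)
    worst = 0.0
    for name in _SCALE_METRICS:
        if mb[name] == 0:
            raise NormalizationError(f"reference {name} is zero; discrepancy undefined")
        worst = max(worst, abs(ma[name] - mb[name]) / mb[name])
    return worst


class _Evaluator:
    """Caches the reference curve and simulates adjusted base compositions."""

    def __init__(
        self,
        base: PlasmaComposition,
        reference: PlasmaComposition,
        analyte: str = "fXa",
        network: ReactionNetwork | None = None,
        means: MeanConcentrationTable | None = None,
        config: SimulationConfig | None = None,
    ):
        self.base = base
        self.reference = reference
        self.analyte = analyte
        self.config = config or SimulationConfig()
        self.network = network or build_network(
            include_tf_viia_at=self.config.include_tf_viia_at
        )
        self.means = means
        ref_traj = simulate(
            reference, network=self.network, means=means, config=self.config
        )
        self.ref_series = _metrics.analyte_series(ref_traj, analyte)
        self.step = ref_traj.step
        self._cache: dict[tuple[str, ...], float] = {}

    def discrepancy(self, subset: tuple[str, ...]) -> float:
        subset = tuple(sorted(subset))
        if subset not in self._cache:
            adjusted = self.base.replace_levels(
                **{f: self.reference.levels[f] for f in subset}
            )
            traj = simulate(
                adjusted, network=self.network, means=self.means, config=self.config
            )
            series = _metrics.analyte_series(traj, self.analyte)
            self._cache[subset] = curve_discrepancy(
                series, self.ref_series, self.step
            )
        return self._cache[subset]


def single_factor_effect(
    base: PlasmaComposition,
    reference: PlasmaComposition,
    factor: str,
    analyte: str = "fXa",
    **kwargs,
) -> dict[str, float]:
    """Discrepancy before vs after adjusting one factor to the reference.

    Returns {'before', 'after', 'reduction'}; a positive reduction means
    the factor moves the base output toward the reference.
    """
    if factor not in FACTOR_NAMES:
        raise NormalizationError(f"unknown factor {factor!r}")
    ev = _Evaluator(base, reference, analyte, **kwargs)
    before = ev.discrepancy(())
    after = ev.discrepancy((factor,))
    return {"before": before, "after": after, "reduction": before - after}


def normalization_search(
    base: PlasmaComposition,
    reference: PlasmaComposition,
    analyte: str = "fXa",
    theta: float = 0.05,
    network: ReactionNetwork | None = None,
    means: MeanConcentrationTable | None = None,
    config: SimulationConfig | None = None,
) -> NormalizationResult:
    """Smallest factor subset whose adjustment normalizes the output.

    Exhaustive search by increasing cardinality over the 2^8 subsets of
    the measured factors; each subset costs one simulation. The first
    cardinality containing a subset with discrepancy <= theta wins, ties
    broken by smallest discrepancy. Adjusting all eight factors makes the
    compositions identical, so the search always terminates if theta can
    be met at all.
    """
    if not theta > 0:
        raise NormalizationError("theta must be > 0")
    ev = _Evaluator(base, reference, analyte, network, means, config)
    trace: list[AdjustmentScenario] = []
    baseline = ev.discrepancy(())
    best_overall: AdjustmentScenario | None = None
    for size in range(0, len(FACTOR_NAMES) + 1):
        best_at_size: AdjustmentScenario | None = None
        for subset in combinations(FACTOR_NAMES, size):
            d = ev.discrepancy(subset)
            if best_at_size is None or d < best_at_size.discrepancy:
                best_at_size = AdjustmentScenario(tuple(subset), d)
        trace.append(best_at_size)
        if best_overall is None or best_at_size.discrepancy < best_overall.discrepancy:
            best_overall = best_at_size
        if best_at_size.discrepancy <= theta:
            return NormalizationResult(
                subset=best_at_size.subset,
                discrepancy=best_at_size.discrepancy,
                theta=theta,
                baseline_discrepancy=baseline,
                trace=tuple(trace),
            )
    raise NormalizationError(
        f"no factor subset reaches discrepancy <= {theta}; best was "
        f"{best_overall.subset} at {best_overall.discrepancy:.4g}"
    )


def best_subsets_of_size(
    base: PlasmaComposition,
    reference: PlasmaComposition,
    size: int,
    analyte: str = "fXa",
    **kwargs,
) -> list[AdjustmentScenario]:
    """All subsets of one cardinality ranked by ascending discrepancy."""
    ev = _Evaluator(base, reference, analyte, **kwargs)
    scored = [
        AdjustmentScenario(tuple(s), ev.discrepancy(s))
        for s in combinations(FACTOR_NAMES, size)
    ]
    return sorted(scored, key=lambda sc: sc.discrepancy)
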