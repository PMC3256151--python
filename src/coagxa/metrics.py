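"""Reduce a species trajectory to generation-curve parameters.

A factor Xa (or thrombin) generation curve is summarized by five numbers:
the maximum level (MaxL) and maximum rate (MaxR), the times at which each
is first attained (TMaxL, TMaxR), and the total amount generated over the
hour (AUC, a rectangle sum of the level at every grid second).

"Total active fXa" counts free fXa plus fXa resident in prothrombinase
(including the substrate-loaded complex); fXa sequestered in inhibitor or
tenase complexes is catalytically unavailable and excluded. "Total
thrombin" weights meizothrombin by a configurable activity factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import SpeciesState, Trajectory

# species included in each analyte read-out
FXA_SPECIES: tuple[str, ...] = ("Xa", "Xa:Va", "Xa:Va:II")
FXA_SPECIES_NO_SUBSTRATE: tuple[str, ...] = ("Xa", "Xa:Va")

ANALYTES = ("fXa", "thrombin")

# reporting-unit conversion from mol/L: (level, rate, auc) multipliers
_UNIT_SCALE = {
    "fXa": (1e9, 1e12, 1e6),        # nM, pM/s, uM*s
    "thrombin": (1e9, 1e9, 1e6),    # nM, nM/s, uM*s
}
UNIT_LABELS = {
    "fXa": {"MaxL": "nM", "MaxR": "pM/s", "AUC": "uM*s"},
    "thrombin": {"MaxL": "nM", "MaxR": "nM/s", "AUC": "uM*s"},
}


class GridError(ValueError):
    """Series not on a uniform grid."""


@dataclass(frozen=True)
class GenerationMetrics:
    """Generation-curve parameters for one analyte.

    Units follow the reporting convention: fXa in nM / pM s^-1 / uM*s,
    thrombin in nM / nM s^-1 / uM*s; times in seconds.
    """

    analyte: str
    MaxL: float
    TMaxL: float
    MaxR: float
    TMaxR: float
    AUC: float

    def as_dict(self) -> dict[str, float]:
        return {
            "MaxR": self.MaxR, "TMaxR": self.TMaxR,
            "MaxL": self.MaxL, "TMaxL": self.TMaxL, "AUC": self.AUC,
        }


def total_active_fxa(
    state: SpeciesState, *, include_substrate_bound: bool = True
) -> float:
    """Catalytically active fXa: free fXa + prothrombinase-resident fXa."""
    names = FXA_SPECIES if include_substrate_bound else FXA_SPECIES_NO_SUBSTRATE
    return float(sum(state[n] for n in names))


def total_thrombin(state: SpeciesState, meizothrombin_weight: float = 1.2) -> float:
    """Thrombin read-out: IIa plus weighted meizothrombin."""
    if meizothrombin_weight < 0:
        raise ValueError("meizothrombin_weight must be >= 0")
    return float(state["IIa"] + meizothrombin_weight * state["mIIa"])


def analyte_series(
    traj: Trajectory,
    analyte: str = "fXa",
    *,
    meizothrombin_weight: float = 1.2,
    include_substrate_bound: bool = True,
) -> np.ndarray:
    """The analyte concentration series (mol/L) along a trajectory."""
    if analyte == "fXa":
        names = FXA_SPECIES if include_substrate_bound else FXA_SPECIES_NO_SUBSTRATE
        return sum(traj.series(n) for n in names)
    if analyte == "thrombin":
        return traj.series("IIa") + meizothrombin_weight * traj.series("mIIa")
    raise ValueError(f"unknown analyte {analyte!r}; expected one of {ANALYTES}")


def extract_metrics(series: np.ndarray, step: float, times: np.ndarray | None = None):
    """Curve parameters of a concentration series on a uniform grid.

    Input units are preserved. Conventions: the rate series is the forward
    difference assigned to the later grid point; ties in maximum level or
    rate resolve to the earliest time; AUC is the rectangle sum
    ``sum(series) * step`` over every grid point.

    Returns a dict with keys MaxL, TMaxL, MaxR, TMaxR, AUC.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < 2:
        raise ValueError("series must be 1-D with at least two samples")
    if times is not None:
        d = np.diff(times)
        if not np.allclose(d, d[0]):
            raise GridError("non-uniform time grid")
        if not np.isclose(d[0], step):
            raise GridError("grid spacing does not match declared step")
    t = np.arange(len(series)) * step
    i_maxl = int(np.argmax(series))          # argmax takes the first maximum
    rate = np.diff(series) / step            # rate[i] belongs to t[i+1]
    i_maxr = int(np.argmax(rate))
    return {
        "MaxL": float(series[i_maxl]),
        "TMaxL": float(t[i_maxl]),
        "MaxR": float(rate[i_maxr]),
        "TMaxR": float(t[i_maxr + 1]),
        "AUC": float(series.sum() * step),
    }


def metrics_for_analyte(
    traj: Trajectory,
    analyte: str = "fXa",
    *,
    meizothrombin_weight: float = 1.2,
    include_substrate_bound: bool = True,
) -> GenerationMetrics:
    """Generation metrics of a trajectory in reporting units."""
    series = analyte_series(
        traj, analyte,
        meizothrombin_weight=meizothrombin_weight,
        include_substrate_bound=include_substrate_bound,
    )
    raw = extract_metrics(series, traj.step, times=traj.times)
    s_level, s_rate, s_auc = _UNIT_SCALE[analyte]
    return GenerationMetrics(
        analyte=analyte,
        MaxL=raw["MaxL"] * s_level,
        TMaxL=raw["TMaxL"],
        MaxR=raw["MaxR"] * s_rate,
        TMaxR=raw["TMaxR"],
        AUC=raw["AUC"] * s_auc,
    )
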