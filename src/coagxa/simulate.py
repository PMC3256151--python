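"""Integrate the tissue-factor-pathway network for one plasma composition.

The initial condition places the subject's zymogens and inhibitors at their
molar levels, tissue factor at the configured trigger concentration (5 pM
by default), circulating fVIIa at 1% of the subject's fVII, and every
enzyme, cofactor and complex at zero. The resulting stiff mass-action ODE
system is integrated over one hour and resampled onto a uniform 1-second
output grid.

Two integrators are provided: the production adaptive stiff solver
(:func:`simulate`, LSODA with an analytic Jacobian) and a deliberately
simple fixed-step 4th-order Runge-Kutta integrator
(:func:`simulate_fixed_step`) kept as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .composition import (
    FACTOR_NAMES,
    MeanConcentrationTable,
    PlasmaComposition,
    default_means,
    percent_to_molar,
)
from .network import SPECIES_INDEX, ReactionNetwork, build_network

# network species index of the initial pool of each measured factor
_ZYMOGEN_SPECIES = {
    "fII": "II", "fV": "V", "fVII": "VII", "fVIII": "VIII",
    "fIX": "IX", "fX": "X", "AT": "AT", "TFPI": "TFPI",
}


class SimulationError(RuntimeError):
    """Solver failure; carries the subject id for cohort-level reporting."""

    def __init__(self, message: str, subject_id: str | None = None):
        super().__init__(message)
        self.subject_id = subject_id


@dataclass(frozen=True)
class SimulationConfig:
    """Trigger, output-grid and solver settings.

    tf_concentration : mol/L of exposed tissue factor (default 5 pM).
    fviia_fraction_of_fvii : circulating fVIIa as a fraction of the
        subject's molar fVII (default 1%).
    t_end, output_grid_step : horizon and reporting grid, seconds.
    rtol, atol : adaptive-solver tolerances (atol in mol/L).
    include_tf_viia_at : keep the direct AT neutralization of TF:VIIa.
    """

    tf_concentration: float = 5e-12
    fviia_fraction_of_fvii: float = 0.01
    t_end: float = 3600.0
    output_grid_step: float = 1.0
    rtol: float = 1e-8
    atol: float = 1e-14
    include_tf_viia_at: bool = True

    def __post_init__(self) -> None:
        if not self.t_end > 0:
            raise ValueError("t_end must be > 0")
        if not self.output_grid_step > 0:
            raise ValueError("output_grid_step must be > 0")
        if not (self.rtol > 0 and self.atol > 0):
            raise ValueError("solver tolerances must be > 0")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)

    @property
    def time_grid(self) -> np.ndarray:
        n = int(round(self.t_end / self.output_grid_step))
        return np.arange(n + 1) * self.output_grid_step


@dataclass(frozen=True)
class SpeciesState:
    """Concentration of every network species at one time point (mol/L)."""

    time: float
    concentrations: np.ndarray
    species: tuple[str, ...]

    def __getitem__(self, name: str) -> float:
        return float(self.concentrations[self.species.index(name)])


@dataclass(frozen=True)
class Trajectory:
    """Species time courses on a uniform grid.

    ``concentrations`` has shape (n_times, n_species), clamped to be
    non-negative; ``raw_concentrations`` keeps the unclamped solver output
    for conservation checks.
    """

    times: np.ndarray
    concentrations: np.ndarray
    species: tuple[str, ...]
    subject_id: str = ""
    raw_concentrations: np.ndarray | None = None

    def __post_init__(self) -> None:
        steps = np.diff(self.times)
        if len(self.times) >= 2 and not np.allclose(steps, steps[0]):
            raise ValueError("trajectory grid must be uniform")
        if self.concentrations.shape != (len(self.times), len(self.species)):
            raise ValueError("concentration array shape mismatch")

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0])

    def series(self, name: str) -> np.ndarray:
        return self.concentrations[:, self.species.index(name)]

    def state_at(self, i: int) -> SpeciesState:
        return SpeciesState(
            time=float(self.times[i]),
            concentrations=self.concentrations[i],
            species=self.species,
        )

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.concentrations, columns=list(self.species))
        df.insert(0, "time", self.times)
        return df

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def build_initial_state(
    composition: PlasmaComposition,
    means: MeanConcentrationTable | None = None,
    config: SimulationConfig | None = None,
    network: ReactionNetwork | None = None,
) -> SpeciesState:
    """Initial condition: zymogens/inhibitors at molar levels, products at 0.

    TF is set to the trigger concentration and VIIa to the configured
    fraction of the subject's molar fVII.
    """
    means = means or default_means()
    config = config or SimulationConfig()
    network = network or build_network(include_tf_viia_at=config.include_tf_viia_at)
    molar = percent_to_molar(composition, means)
    y0 = np.zeros(network.n_species)
    y0[SPECIES_INDEX["TF"]] = config.tf_concentration
    for factor in FACTOR_NAMES:
        y0[SPECIES_INDEX[_ZYMOGEN_SPECIES[factor]]] = molar[factor]
    y0[SPECIES_INDEX["VIIa"]] = config.fviia_fraction_of_fvii * molar["fVII"]
    return SpeciesState(time=0.0, concentrations=y0, species=network.species)


def derivative(
    state: SpeciesState | np.ndarray, network: ReactionNetwork
) -> np.ndarray:
    """Mass-action rate vector dc/dt (mol/L/s) at the given state.

    Pure function: flux of reaction j is its rate constant times the
    product of its reactant concentrations; species rates are the
    stoichiometry-weighted flux sums.
    """
    y = state.concentrations if isinstance(state, SpeciesState) else np.asarray(state)
    flux = network.rates * y[network.reactant_idx[:, 0]]
    bi = network.reactant_idx[:, 1] >= 0
    flux[bi] *= y[network.reactant_idx[bi, 1]]
    return network.stoich @ flux


def jacobian(y: np.ndarray, network: ReactionNetwork) -> np.ndarray:
    """Analytic Jacobian d(dc/dt)/dc of the mass-action system."""
    n_s = network.n_species
    dflux = np.zeros((network.n_reactions, n_s))
    r0 = network.reactant_idx[:, 0]
    r1 = network.reactant_idx[:, 1]
    rows = np.arange(network.n_reactions)
    uni = r1 < 0
    dflux[rows[uni], r0[uni]] = network.rates[uni]
    bi = ~uni
    dflux[rows[bi], r0[bi]] += network.rates[bi] * y[r1[bi]]
    dflux[rows[bi], r1[bi]] += network.rates[bi] * y[r0[bi]]
    return network.stoich @ dflux


@njit(cache=True)
def _rhs_numba(y, rates, ridx, sj_ptr, sj_idx, sj_val, out):
    out[:] = 0.0
    for j in range(rates.shape[0]):
        f = rates[j] * y[ridx[j, 0]]
        if ridx[j, 1] >= 0:
            f *= y[ridx[j, 1]]
        for p in range(sj_ptr[j], sj_ptr[j + 1]):
            out[sj_idx[p]] += sj_val[p] * f
    return out


@njit(cache=True)
def _rk4_numba(y0, dt, n_steps, sample_every, rates, ridx, sj_ptr, sj_idx, sj_val):
    n = y0.shape[0]
    n_out = n_steps // sample_every + 1
    out = np.empty((n_out, n))
    out[0] = y0
    y = y0.copy()
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n); k4 = np.empty(n)
    tmp = np.empty(n)
    for step in range(1, n_steps + 1):
        _rhs_numba(y, rates, ridx, sj_ptr, sj_idx, sj_val, k1)
        for i in range(n):
            tmp[i] = y[i] + 0.5 * dt * k1[i]
        _rhs_numba(tmp, rates, ridx, sj_ptr, sj_idx, sj_val, k2)
        for i in range(n):
            tmp[i] = y[i] + 0.5 * dt * k2[i]
        _rhs_numba(tmp, rates, ridx, sj_ptr, sj_idx, sj_val, k3)
        for i in range(n):
            tmp[i] = y[i] + dt * k3[i]
        _rhs_numba(tmp, rates, ridx, sj_ptr, sj_idx, sj_val, k4)
        for i in range(n):
            y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        if step % sample_every == 0:
            out[step // sample_every] = y
    return out


def _reaction_csr(network: ReactionNetwork):
    """Per-reaction sparse net-stoichiometry (CSR over reactions)."""
    ptr = [0]
    idx: list[int] = []
    val: list[float] = []
    for j in range(network.n_reactions):
        col = network.stoich[:, j]
        nz = np.nonzero(col)[0]
        idx.extend(int(i) for i in nz)
        val.extend(float(col[i]) for i in nz)
        ptr.append(len(idx))
    return (
        np.asarray(ptr, dtype=np.int64),
        np.asarray(idx, dtype=np.int64),
        np.asarray(val),
    )


def simulate(
    composition: PlasmaComposition,
    network: ReactionNetwork | None = None,
    constants: Mapping[str, float] | None = None,
    means: MeanConcentrationTable | None = None,
    config: SimulationConfig | None = None,
) -> Trajectory:
    """Adaptive stiff integration of one subject's coagulation response.

    Returns species concentrations on the uniform output grid (default
    0..3600 s inclusive at 1 s). Negative excursions within solver
    tolerance are clamped to zero in the reported trajectory only.
    """
    config = config or SimulationConfig()
    means = means or default_means()
    if network is None:
        network = build_network(
            constants, include_tf_viia_at=config.include_tf_viia_at
        )
    state0 = build_initial_state(composition, means, config, network)
    y0 = state0.concentrations
    grid = config.time_grid

    rates, ridx = network.rates, network.reactant_idx
    sj_ptr, sj_idx, sj_val = _reaction_csr(network)
    scratch = np.empty(network.n_species)

    def rhs(t, y):
        return _rhs_numba(y, rates, ridx, sj_ptr, sj_idx, sj_val, scratch).copy()

    def jac(t, y):
        return jacobian(y, network)

    sol = solve_ivp(
        rhs,
        (0.0, float(config.t_end)),
        y0,
        method="LSODA",
        t_eval=grid,
        rtol=config.rtol,
        atol=config.atol,
        jac=jac,
    )
    if not sol.success:
        raise SimulationError(
            f"stiff solver failed for subject {composition.subject_id!r}: "
            f"{sol.message}",
            subject_id=composition.subject_id,
        )
    raw = sol.y.T.copy()
    return Trajectory(
        times=grid,
        concentrations=np.clip(raw, 0.0, None),
        species=network.species,
        subject_id=composition.subject_id,
        raw_concentrations=raw,
    )


def simulate_fixed_step(
    composition: PlasmaComposition,
    network: ReactionNetwork | None = None,
    means: MeanConcentrationTable | None = None,
    config: SimulationConfig | None = None,
    dt: float = 1e-3,
) -> Trajectory:
    """Fixed-step classical RK4 reference integration.

    Much slower than :func:`simulate`; used to cross-validate the adaptive
    solver. ``dt`` must divide the output grid step.
    """
    config = config or SimulationConfig()
    means = means or default_means()
    if network is None:
        network = build_network(include_tf_viia_at=config.include_tf_viia_at)
    sample_every = int(round(config.output_grid_step / dt))
    if not np.isclose(sample_every * dt, config.output_grid_step):
        raise ValueError("dt must divide the output grid step")
    state0 = build_initial_state(composition, means, config, network)
    grid = config.time_grid
    n_steps = (len(grid) - 1) * sample_every
    sj_ptr, sj_idx, sj_val = _reaction_csr(network)
    raw = _rk4_numba(
        state0.concentrations, dt, n_steps, sample_every,
        network.rates, network.reactant_idx, sj_ptr, sj_idx, sj_val,
    )
    return Trajectory(
        times=grid,
        concentrations=np.clip(raw, 0.0, None),
        species=network.species,
        subject_id=composition.subject_id,
        raw_concentrations=raw,
    )
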