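"""Synthetic case-control cohorts with the study's factor distributions.

The original plasma compositions (Leiden Thrombophilia Study) are not
publicly deposited; what is printed is, per factor and group, the mean,
SD and observed range, plus group sizes and a handful of subgroup mean
compositions. This module samples cohorts matching those marginals so the
whole pipeline is exercisable end to end: each factor is drawn from a
normal truncated to the printed range (via a Gaussian copula when an
inter-factor correlation matrix is supplied; independent by default,
since the study does not print correlations — synthetic odds ratios are
therefore not expected to reproduce the printed ones numerically).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .composition import FACTOR_NAMES, PlasmaComposition

COHORT_COLUMNS = (
    "subject_id", "group", "sex", "age", "bmi", "oc_use", *FACTOR_NAMES,
)


class SpecError(ValueError):
    """Invalid cohort specification."""


@dataclass(frozen=True)
class FactorDistribution:
    """Truncated-normal marginal for one factor (percent-of-mean units)."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not self.min < self.mean < self.max:
            raise SpecError(
                f"need min < mean < max, got {self.min}/{self.mean}/{self.max}"
            )
        if not self.sd > 0:
            raise SpecError(f"sd must be > 0, got {self.sd}")


@dataclass(frozen=True)
class CohortSpec:
    """Distributional parameters driving cohort sampling.

    ``factors`` maps group -> factor -> marginal; ``correlation`` is an
    optional 8x8 matrix (factor order of :data:`FACTOR_NAMES`) inducing
    rank correlation through a Gaussian copula.
    """

    factors: Mapping[str, Mapping[str, FactorDistribution]]
    group_sizes: Mapping[str, int]
    demographics: Mapping | None = None
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        for group, sz in self.group_sizes.items():
            if sz < 0:
                raise SpecError(f"group size for {group!r} must be >= 0")
            if group not in self.factors:
                raise SpecError(f"no factor distributions for group {group!r}")
        for group, dists in self.factors.items():
            missing = set(FACTOR_NAMES) - set(dists)
            if missing:
                raise SpecError(f"group {group!r} missing factors {sorted(missing)}")
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
            if corr.shape != (len(FACTOR_NAMES),) * 2:
                raise SpecError("correlation matrix must be 8x8")
            if not np.allclose(corr, corr.T):
                raise SpecError("correlation matrix must be symmetric")
            if np.linalg.eigvalsh(corr).min() < -1e-10:
                raise SpecError("correlation matrix must be positive semi-definite")
            object.__setattr__(self, "correlation", corr)


def _parse_factor_block(block: Mapping) -> dict[str, FactorDistribution]:
    return {
        f: FactorDistribution(
            mean=float(v["mean"]), sd=float(v["sd"]),
            min=float(v["min"]), max=float(v["max"]),
        )
        for f, v in block.items()
    }


def load_spec(path: str | None = None) -> CohortSpec:
    """Load a cohort spec; ``path=None`` loads the bundled study defaults."""
    if path is None:
        text = (resources.files("coagxa.data") / "lets_cohort_spec.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return CohortSpec(
        factors={g: _parse_factor_block(b) for g, b in raw["factors"].items()},
        group_sizes={g: int(n) for g, n in raw["group_sizes"].items()},
        demographics=raw.get("demographics"),
        correlation=np.asarray(raw["correlation"], dtype=float)
        if "correlation" in raw else None,
    )


def default_spec() -> CohortSpec:
    return load_spec(None)


def null_spec(spec: CohortSpec | None = None) -> CohortSpec:
    """Copy of a spec with case factor distributions set to the controls'.

    Under this null, cases and controls are exchangeable and downstream
    odds ratios should be ~1.
    """
    spec = spec or default_spec()
    factors = dict(spec.factors)
    factors["case"] = dict(spec.factors["control"])
    return CohortSpec(
        factors=factors,
        group_sizes=spec.group_sizes,
        demographics=spec.demographics,
        correlation=spec.correlation,
    )


def _truncnorm(d: FactorDistribution):
    a = (d.min - d.mean) / d.sd
    b = (d.max - d.mean) / d.sd
    return stats.truncnorm(a, b, loc=d.mean, scale=d.sd)


def _sample_factors(
    rng: np.random.Generator,
    dists: Mapping[str, FactorDistribution],
    n: int,
    correlation: np.ndarray | None,
) -> dict[str, np.ndarray]:
    """Truncated-normal margins, optionally rank-coupled by a Gaussian copula."""
    if correlation is None:
        return {f: _truncnorm(dists[f]).rvs(size=n, random_state=rng)
                for f in FACTOR_NAMES}
    chol = np.linalg.cholesky(
        correlation + 1e-12 * np.eye(len(FACTOR_NAMES))
    )
    z = rng.standard_normal((n, len(FACTOR_NAMES))) @ chol.T
    u = stats.norm.cdf(z)
    return {
        f: _truncnorm(dists[f]).ppf(u[:, i])
        for i, f in enumerate(FACTOR_NAMES)
    }


def _sample_demographics(
    rng: np.random.Generator, demo: Mapping | None, group: str, n: int
) -> dict[str, np.ndarray]:
    if not demo:
        return {
            "sex": np.full(n, None), "age": np.full(n, np.nan),
            "bmi": np.full(n, np.nan), "oc_use": np.full(n, None),
        }
    p_f = float(demo["p_female"][group])
    sex = np.where(rng.random(n) < p_f, "F", "M")
    age_d = demo["age"]
    age = _truncnorm(FactorDistribution(
        age_d["mean"], age_d["sd"], age_d["min"], age_d["max"]
    )).rvs(size=n, random_state=rng)
    bmi_d = demo["bmi"]
    bmi = _truncnorm(FactorDistribution(
        bmi_d["mean"], bmi_d["sd"], bmi_d["min"], bmi_d["max"]
    )).rvs(size=n, random_state=rng)
    p_oc = float(demo["p_oc_given_young_female"][group])
    eligible = (sex == "F") & (age < 50)
    oc = np.where(eligible, rng.random(n) < p_oc, False)
    return {
        "sex": sex, "age": np.round(age, 1), "bmi": np.round(bmi, 1),
        "oc_use": oc.astype(bool),
    }


def sample_cohort(
    spec: CohortSpec,
    seed: int,
    group: str = "control",
    *,
    id_prefix: str | None = None,
) -> pd.DataFrame:
    """Sample one group's cohort table (deterministic under seed).

    Uses numpy's PCG64 generator; the seed and algorithm are recorded in
    the frame's ``attrs`` for reproducibility.
    """
    if group not in spec.group_sizes:
        raise SpecError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    n = spec.group_sizes[group]
    factors = _sample_factors(rng, spec.factors[group], n, spec.correlation)
    demo = _sample_demographics(rng, spec.demographics, group, n)
    prefix = id_prefix if id_prefix is not None else group
    df = pd.DataFrame(
        {
            "subject_id": [f"{prefix}_{i + 1:04d}" for i in range(n)],
            "group": group,
            **demo,
            **{f: np.round(factors[f], 2) for f in FACTOR_NAMES},
        },
        columns=list(COHORT_COLUMNS),
    )
    df.attrs["rng"] = "numpy PCG64"
    df.attrs["seed"] = seed
    return df


def sample_case_control_study(spec: CohortSpec | None = None, seed: int = 0) -> pd.DataFrame:
    """Full case-control table: both groups, demographics, stable ids.

    Controls and cases get independent streams derived from the seed so
    group sizes can change without perturbing the other group's draws.
    """
    spec = spec or default_spec()
    ss = np.random.SeedSequence(seed)
    s_control, s_case = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    controls = sample_cohort(spec, s_control, "control")
    cases = sample_cohort(spec, s_case, "case")
    df = pd.concat([controls, cases], ignore_index=True)
    df.attrs["rng"] = "numpy PCG64"
    df.attrs["seed"] = seed
    return df


def fixture_compositions() -> dict[str, PlasmaComposition]:
    """The study's printed reference compositions.

    Two control individuals with near-identical simulated thrombin curves
    (but distinguishable fXa curves), and the mean compositions of
    control-group oral-contraceptive users and non-users.
    """
    raw = {
        "individual_1": dict(fII=97, fV=89, fVII=157, fVIII=137,
                             fIX=87, fX=134, AT=99, TFPI=64),
        "individual_2": dict(fII=97, fV=164, fVII=131, fVIII=188,
                             fIX=100, fX=124, AT=101, TFPI=87),
        "oc_users": dict(fII=106, fV=112, fVII=118, fVIII=124,
                         fIX=115, fX=118, AT=95, TFPI=68),
        "oc_nonusers": dict(fII=102, fV=123, fVII=104, fVIII=117,
                            fIX=92, fX=96, AT=100, TFPI=86),
    }
    return {
        name: PlasmaComposition(subject_id=name, levels=levels, group="control")
        for name, levels in raw.items()
    }
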