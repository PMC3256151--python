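"""Cohort-level risk analysis of simulated generation metrics.

Runs the kinetic model over every subject of a case-control cohort and
computes the study statistics: 90th-percentile cutoffs on the pooled
population, above-cutoff prevalence per subgroup, odds ratios with Woolf
(log-normal) confidence intervals, Fisher's exact tests, distributional
group comparisons (KS normality gate, then t-test or rank-sum), and
ordinary-least-squares covariate trends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .composition import FACTOR_NAMES, MeanConcentrationTable, PlasmaComposition
from .metrics import metrics_for_analyte
from .network import ReactionNetwork, build_network
from .simulate import SimulationConfig, SimulationError, simulate

METRIC_COLUMNS = ("MaxR", "TMaxR", "MaxL", "TMaxL", "AUC")


class CohortError(ValueError):
    """Invalid cohort input or subgroup."""


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 above/below-cutoff table with OR, Woolf 95% CI and Fisher p.

    a = cases above the cutoff, b = cases not above,
    c = controls above, d = controls not above. ``odds_ratio`` is None
    when a zero cell makes it undefined.
    """

    subgroup: str
    metric: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    fisher_p: float

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    def as_dict(self) -> dict:
        return {
            "subgroup": self.subgroup, "metric": self.metric,
            "a": self.a, "b": self.b, "c": self.c, "d": self.d,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "fisher_p": self.fisher_p,
        }


def rows_to_compositions(cohort: pd.DataFrame) -> list[PlasmaComposition]:
    """Validate cohort rows into :class:`PlasmaComposition` objects."""
    comps = []
    for _, row in cohort.iterrows():
        oc = row.get("oc_use")
        if pd.isna(oc):
            oc = None
        elif isinstance(oc, str):
            oc = oc.strip().lower() in ("1", "true", "yes", "y")
        else:
            oc = bool(oc)
        comps.append(
            PlasmaComposition(
                subject_id=str(row["subject_id"]),
                levels={f: float(row[f]) for f in FACTOR_NAMES},
                group=row.get("group"),
                sex=None if pd.isna(row.get("sex")) else str(row["sex"]),
                age=None if pd.isna(row.get("age")) else float(row["age"]),
                bmi=None if pd.isna(row.get("bmi")) else float(row["bmi"]),
                oc_use=oc,
            )
        )
    return comps


def run_cohort(
    cohort: pd.DataFrame,
    config: SimulationConfig | None = None,
    means: MeanConcentrationTable | None = None,
    network: ReactionNetwork | None = None,
    analytes: tuple[str, ...] = ("fXa",),
    *,
    strict: bool = True,
) -> pd.DataFrame:
    """Simulate every subject and extract metrics per analyte.

    Returns a tidy frame with one row per subject x analyte carrying the
    demographic columns through. Solver failures abort in strict mode;
    in lenient mode the affected subjects are dropped and counted in the
    frame's ``attrs['n_failed']``.
    """
    config = config or SimulationConfig()
    network = network or build_network(include_tf_viia_at=config.include_tf_viia_at)
    comps = rows_to_compositions(cohort)
    records = []
    failed: list[str] = []
    for comp in comps:
        try:
            traj = simulate(comp, network=network, means=means, config=config)
        except SimulationError as err:
            if strict:
                raise
            failed.append(comp.subject_id)
            continue
        for analyte in analytes:
            m = metrics_for_analyte(traj, analyte)
            records.append(
                {
                    "subject_id": comp.subject_id,
                    "group": comp.group,
                    "sex": comp.sex,
                    "age": comp.age,
                    "bmi": comp.bmi,
                    "oc_use": comp.oc_use,
                    "analyte": analyte,
                    **m.as_dict(),
                }
            )
    out = pd.DataFrame(
        records,
        columns=[
            "subject_id", "group", "sex", "age", "bmi", "oc_use", "analyte",
            *METRIC_COLUMNS,
        ],
    )
    out.attrs["n_failed"] = len(failed)
    out.attrs["failed_subjects"] = failed
    return out


def percentile_cutoff(values, q: float = 90.0) -> float:
    """Nearest-rank percentile of the pooled case+control values.

    The cutoff is the ceil(q/100 * n)-th order statistic; "above" in all
    downstream counting means strictly greater than this value.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 10:
        raise CohortError(f"need at least 10 values for a percentile cutoff, got {n}")
    if not 0 < q < 100:
        raise CohortError("percentile q must be in (0, 100)")
    rank = math.ceil(q / 100.0 * n)
    return float(np.sort(values)[rank - 1])


def prevalence_table(
    metrics: pd.DataFrame,
    metric: str,
    cutoff: float,
    subgroup: str = "whole population",
    mask: pd.Series | None = None,
) -> ContingencyResult:
    """Above-cutoff counts for cases and controls within a subgroup.

    The cutoff must come from the pooled whole population; the optional
    boolean ``mask`` restricts to a subgroup, which must still contain
    both cases and controls.
    """
    sub = metrics if mask is None else metrics[mask.reindex(metrics.index, fill_value=False)]
    if len(sub) == 0:
        raise CohortError(f"empty subgroup {subgroup!r}")
    cases = sub[sub["group"] == "case"][metric].to_numpy(dtype=float)
    controls = sub[sub["group"] == "control"][metric].to_numpy(dtype=float)
    if len(cases) == 0 or len(controls) == 0:
        raise CohortError(
            f"subgroup {subgroup!r} must contain both cases and controls"
        )
    a = int((cases > cutoff).sum())
    b = len(cases) - a
    c = int((controls > cutoff).sum())
    d = len(controls) - c
    oratio, lo, hi = odds_ratio_ci(a, b, c, d)
    return ContingencyResult(
        subgroup=subgroup, metric=metric, a=a, b=b, c=c, d=d,
        odds_ratio=oratio, ci_low=lo, ci_high=hi,
        fisher_p=fisher_exact(a, b, c, d),
    )


def odds_ratio_ci(
    a: int, b: int, c: int, d: int
) -> tuple[float | None, float | None, float | None]:
    """Odds ratio (a*d)/(b*c) with Woolf log-normal 95% CI.

    Returns (None, None, None) when any cell is zero, making the ratio or
    its CI undefined.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be non-negative integers")
    if a == 0 or b == 0 or c == 0 or d == 0:
        return None, None, None
    oratio = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(oratio)
    return (
        oratio,
        math.exp(log_or - 1.96 * se),
        math.exp(log_or + 1.96 * se),
    )


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]]."""
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def group_compare(values_a, values_b, alpha: float = 0.05) -> dict:
    """Two-group comparison with a normality gate.

    Each sample is tested for normality with a Kolmogorov-Smirnov test
    (against a normal with the sample's moments); if both pass at
    ``alpha`` a two-sample t-test with a difference-of-means 95% CI is
    used, otherwise the Mann-Whitney rank-sum test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise CohortError("each group needs at least 3 observations")
    normal = all(
        stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue > alpha
        for x in (a, b)
    )
    if normal:
        res = stats.ttest_ind(a, b)
        diff = a.mean() - b.mean()
        se = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        return {
            "test": "t-test",
            "statistic": float(res.statistic),
            "p": float(res.pvalue),
            "mean_difference": diff,
            "diff_ci": (diff - 1.96 * se, diff + 1.96 * se),
        }
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "test": "rank-sum",
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "mean_difference": float(a.mean() - b.mean()),
        "diff_ci": None,
    }


def linear_trend(metric_values, covariate_values) -> dict:
    """OLS slope of a metric on a covariate with a normal 95% CI."""
    import statsmodels.api as sm

    y = np.asarray(metric_values, dtype=float)
    x = np.asarray(covariate_values, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    if len(y) < 10:
        raise CohortError("need at least 10 paired observations")
    if np.ptp(x) == 0:
        raise CohortError("covariate has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(model.params[1])
    se = float(model.bse[1])
    return {
        "slope": slope,
        "ci": (slope - 1.96 * se, slope + 1.96 * se),
        "n": int(len(y)),
    }


def subgroup_masks(metrics: pd.DataFrame) -> dict[str, pd.Series]:
    """The study's standard stratifications as boolean masks.

    Subjects with a missing stratification field drop out of that
    stratification only. OC subgroups are restricted to women.
    """
    sex = metrics["sex"]
    age = pd.to_numeric(metrics["age"], errors="coerce")
    bmi = pd.to_numeric(metrics["bmi"], errors="coerce")
    oc = metrics["oc_use"]
    is_f = sex == "F"
    return {
        "whole population": pd.Series(True, index=metrics.index),
        "men": sex == "M",
        "women": is_f,
        "females without OC": is_f & (oc == False),  # noqa: E712
        "females with OC": is_f & (oc == True),  # noqa: E712
        "age <=45": age.notna() & (age <= 45),
        "age >45": age.notna() & (age > 45),
        "BMI <=26": bmi.notna() & (bmi <= 26),
        "BMI >26": bmi.notna() & (bmi > 26),
    }


def risk_analysis(
    metrics: pd.DataFrame,
    q: float = 90.0,
    metric_names: tuple[str, ...] = ("MaxR", "MaxL"),
    analyte: str = "fXa",
) -> tuple[dict[str, float], list[ContingencyResult]]:
    """Pooled cutoffs plus the full subgroup contingency grid.

    Returns (cutoffs per metric, contingency results per subgroup x
    metric). Subgroups lacking either group are skipped.
    """
    m = metrics[metrics["analyte"] == analyte]
    if m.empty:
        raise CohortError(f"no rows for analyte {analyte!r}")
    cutoffs = {name: percentile_cutoff(m[name], q) for name in metric_names}
    results = []
    for label, mask in subgroup_masks(m).items():
        for name in metric_names:
            try:
                results.append(
                    prevalence_table(m, name, cutoffs[name], label, mask)
                )
            except CohortError:
                continue
    return cutoffs, results
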