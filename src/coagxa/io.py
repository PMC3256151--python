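"""Cohort file I/O, validation, and the end-to-end pipeline driver.

Cohort files are plain CSV with header
``subject_id,group,sex,age,bmi,oc_use,fII,fV,fVII,fVIII,fIX,fX,AT,TFPI``;
``group`` is ``case`` or ``control`` and missing demographic values are
empty fields. ``run_all`` ties the stages together: cohort -> per-subject
metrics -> 90th-percentile risk statistics, writing a metrics CSV, a
contingency CSV, a JSON summary and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .composition import FACTOR_NAMES, default_means
from .cohort import risk_analysis, run_cohort, subgroup_masks
from .simulate import SimulationConfig
from .synthetic import COHORT_COLUMNS

REQUIRED_COLUMNS = ("subject_id", "group", *FACTOR_NAMES)
GROUP_LABELS = ("case", "control")


class CohortFormatError(ValueError):
    """Schema violation in a cohort file, with row/column context."""


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and schema-validate a cohort CSV.

    Raises :class:`CohortFormatError` naming the offending column or the
    1-based data row of the first bad value.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "sex": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(
            f"{path.name}: missing required column(s) {missing}"
        )
    bad_group = df[~df["group"].isin(GROUP_LABELS)]
    if len(bad_group):
        row = int(bad_group.index[0]) + 1
        raise CohortFormatError(
            f"{path.name} row {row}: group {bad_group['group'].iloc[0]!r} "
            f"not in allowed labels {GROUP_LABELS}"
        )
    for col in FACTOR_NAMES:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[vals.isna()]
        if len(bad):
            row = int(bad.index[0]) + 1
            raise CohortFormatError(
                f"{path.name} row {row}: non-numeric {col} value "
                f"{bad[col].iloc[0]!r}"
            )
        df[col] = vals
    for col in ("sex", "age", "bmi", "oc_use"):
        if col not in df.columns:
            df[col] = np.nan
    return df[list(COHORT_COLUMNS)]


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline settings."""

    cohort_path: str
    output_dir: str
    analyte: str = "fXa"
    q: float = 90.0
    metric_names: tuple[str, ...] = ("MaxR", "MaxL")
    seed: int = 0
    strict: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not 0 < self.q < 100:
            raise ValueError("percentile q must be in (0, 100)")


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {**asdict(config), "version": __version__}, sort_keys=True, default=str
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict[str, Path]:
    """Cohort -> metrics -> risk statistics, with artifacts on disk.

    Writes ``metrics.csv``, ``contingency.csv``, ``summary.json`` and
    ``manifest.json`` into the output directory and returns their paths.
    Deterministic (and therefore idempotent) for a fixed config.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(config.cohort_path)

    metrics = run_cohort(
        cohort,
        config=config.simulation,
        means=default_means(),
        analytes=(config.analyte,),
        strict=config.strict,
    )
    metrics_path = out / "metrics.csv"
    metrics.to_csv(metrics_path, index=False)

    cutoffs, contingency = risk_analysis(
        metrics, q=config.q, metric_names=config.metric_names,
        analyte=config.analyte,
    )
    contingency_df = pd.DataFrame([r.as_dict() for r in contingency])
    contingency_path = out / "contingency.csv"
    contingency_df.to_csv(contingency_path, index=False)

    summary = {
        "analyte": config.analyte,
        "percentile": config.q,
        "cutoffs": cutoffs,
        "n_subjects": int(cohort.shape[0]),
        "n_simulated": int(metrics["subject_id"].nunique()),
        "n_failed": int(metrics.attrs.get("n_failed", 0)),
        "subgroup_sizes": {
            label: int(mask.sum())
            for label, mask in subgroup_masks(
                metrics[metrics["analyte"] == config.analyte]
            ).items()
        },
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))

    manifest = {
        "tool": "coagxa",
        "version": __version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "artifacts": ["metrics.csv", "contingency.csv", "summary.json"],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    return {
        "metrics": metrics_path,
        "contingency": contingency_path,
        "summary": summary_path,
        "manifest": manifest_path,
    }
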