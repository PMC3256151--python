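#!/usr/bin/env python
"""fXa separates two individuals whose thrombin profiles overlap.

The two published control individuals have markedly different plasma
compositions (fV 89 vs 164%, fVIII 137 vs 188%, TFPI 64 vs 87%) yet
near-identical simulated thrombin curves. This script simulates both and
compares their thrombin vs fXa generation metrics, writing
results/individual_discrimination.csv.
"""

from pathlib import Path

import pandas as pd

from coagxa import simulate
from coagxa.metrics import metrics_for_analyte
from coagxa.synthetic import fixture_compositions


def main() -> None:
    out = Path("results")
    out.mkdir(exist_ok=True)
    fx = fixture_compositions()
    rows = []
    for name in ("individual_1", "individual_2"):
        traj = simulate(fx[name])
        for analyte in ("fXa", "thrombin"):
            m = metrics_for_analyte(traj, analyte)
            rows.append({"individual": name, "analyte": analyte, **m.as_dict()})
    df = pd.DataFrame(rows)
    df.to_csv(out / "individual_discrimination.csv", index=False)
    print(df.to_string(index=False))
    for analyte in ("fXa", "thrombin"):
        sub = df[df.analyte == analyte].set_index("individual")
        rel = {
            k: abs(sub.loc["individual_1", k] - sub.loc["individual_2", k])
            / sub.loc["individual_2", k]
            for k in ("MaxL", "MaxR", "AUC")
        }
        worst = max(rel, key=rel.get)
        print(f"{analyte}: largest metric separation {worst} "
              f"({100 * rel[worst]:.1f}%)")


if __name__ == "__main__":
    main()
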