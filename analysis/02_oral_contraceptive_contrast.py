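#!/usr/bin/env python
"""Simulated fXa generation for OC-user vs non-user mean compositions.

Control-group women on oral contraceptives have a distinctive mean plasma
composition (notably fIX 115% vs 92% and TFPI 68% vs 86%). Simulating the
two mean compositions shows the OC phenotype: faster and higher fXa
generation with an earlier peak rate. Writes the two generation curves and
a metric comparison table under results/.
"""

from pathlib import Path

import pandas as pd

from coagxa import simulate
from coagxa.metrics import analyte_series, metrics_for_analyte
from coagxa.synthetic import fixture_compositions


def main() -> None:
    out = Path("results")
    out.mkdir(exist_ok=True)
    fx = fixture_compositions()
    rows, curves = [], {}
    for name in ("oc_users", "oc_nonusers"):
        traj = simulate(fx[name])
        curves[name] = analyte_series(traj, "fXa") * 1e9  # nM
        for analyte in ("fXa", "thrombin"):
            m = metrics_for_analyte(traj, analyte)
            rows.append({"group": name, "analyte": analyte, **m.as_dict()})
        times = traj.times
    table = pd.DataFrame(rows)
    table.to_csv(out / "oc_contrast_metrics.csv", index=False)
    pd.DataFrame({"time_s": times, **{k: v for k, v in curves.items()}}).to_csv(
        out / "oc_contrast_curves.tsv", sep="\t", index=False
    )

    fxa = table[table.analyte == "fXa"].set_index("group")
    u, n = fxa.loc["oc_users"], fxa.loc["oc_nonusers"]
    print(table.to_string(index=False))
    print(
        f"\nOC users vs non-users (fXa): MaxR {u.MaxR:.1f} vs {n.MaxR:.1f} pM/s "
        f"({100 * (u.MaxR / n.MaxR - 1):.0f}% higher), MaxL {u.MaxL:.1f} vs "
        f"{n.MaxL:.1f} nM, AUC {u.AUC:.1f} vs {n.AUC:.1f} uM*s, peak rate "
        f"{n.TMaxR - u.TMaxR:.0f} s earlier in users."
    )


if __name__ == "__main__":
    main()
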