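#!/usr/bin/env python
"""Replicate-proportion summaries of the bead-inhibition experiments.

Counts of dorsal denticle rows affected by FGFR-inhibitor (SU5402) beads and
unaffected by DMSO control beads, per developmental stage, summarized as
rounded percentages.  Outputs results/replicates.json.
"""

from pathlib import Path

from denticle_rd.io import save_json
from denticle_rd.pattern_analysis import replicate_proportion

OUT = Path(__file__).resolve().parents[1] / "results"

# (stage fixed, assay, treated affected/total, control unaffected/total)
ROWS = [
    (80, "ISH", (5, 5), (5, 5)),
    (100, "ISH", (2, 2), (2, 2)),
    (125, "alizarin red", (6, 8), (7, 7)),
    (150, "alizarin red", (7, 8), (9, 9)),
]


def main() -> None:
    treated_a = sum(a for _s, _t, (a, _n), _c in ROWS)
    treated_n = sum(n for _s, _t, (_a, n), _c in ROWS)
    control_a = sum(a for _s, _t, _x, (a, _n) in ROWS)
    control_n = sum(n for _s, _t, _x, (_a, n) in ROWS)

    report = {"per_stage": [], "totals": {}}
    for stage, assay, (ta, tn), (ca, cn) in ROWS:
        report["per_stage"].append({
            "stage_dpf": stage, "assay": assay,
            "treated_affected": f"{ta}/{tn}",
            "pct_treated_affected": replicate_proportion(ta, tn),
            "control_unaffected": f"{ca}/{cn}",
            "pct_control_unaffected": replicate_proportion(ca, cn),
        })
    report["totals"] = {
        "treated": f"{treated_a}/{treated_n}",
        "pct_treated_affected": replicate_proportion(treated_a, treated_n),
        "control": f"{control_a}/{control_n}",
        "pct_control_unaffected": replicate_proportion(control_a, control_n),
        "pct_gap_maintained_50dpt": replicate_proportion(6, 8),
    }
    OUT.mkdir(exist_ok=True)
    save_json(report, OUT / "replicates.json")
    print(f"treated rows affected: {treated_a}/{treated_n} = "
          f"{report['totals']['pct_treated_affected']}%")
    print(f"control rows unaffected: {control_a}/{control_n} = "
          f"{report['totals']['pct_control_unaffected']}%")
    print(f"gap maintained at 50 dpt: 6/8 = "
          f"{report['totals']['pct_gap_maintained_50dpt']}%")
    print(f"wrote {OUT / 'replicates.json'}")


if __name__ == "__main__":
    main()
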