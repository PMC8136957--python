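#!/usr/bin/env python
"""Biomarker selection on the synthetic study: pool correlated biomarkers,
normalize each family by its smallest across-subject SD, and rank by
one-hold-out z-factor against the deep-drop endpoint.

Writes results/study/selection.json. Run 01_simulate_study.py first.
"""

import json
import sys
import warnings
from pathlib import Path

import pandas as pd

from biodyn.biomarkers import panel_from_table
from biodyn.outcomes import cohort_outcomes, label_endpoints
from biodyn.selection import normalize_panel, pool_biomarkers, rank_one_hold_out

STUDY = Path("results/study")


def main() -> int:
    panel_csv = STUDY / "panel.csv"
    if not panel_csv.exists():
        print("run analysis/01_simulate_study.py first", file=sys.stderr)
        return 1
    tidy = pd.read_csv(panel_csv, dtype={"subject_id": str})
    wide = tidy.pivot(index="subject_id", columns="biomarker", values="value")
    families = dict(zip(tidy["biomarker"], tidy["family"]))
    panel = panel_from_table(wide.reset_index(), families=families)

    cohort = pd.read_csv(STUDY / "cohort.csv", dtype={"subject_id": str})
    labels = label_endpoints(cohort_outcomes(cohort))["deep_drop"]

    pooled, pooling = pool_biomarkers(panel, correlation_threshold=0.9)
    normalized = normalize_panel(pooled)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # undefined z on degenerate noise columns
        result = rank_one_hold_out(normalized, labels, k=4)
    result.pooling = pooling

    (STUDY / "selection.json").write_text(json.dumps(result.to_json_dict(), indent=1))
    n_pools = sum(1 for v in pooling.values() if len(v) > 1)
    print(f"{len(panel.biomarkers)} biomarkers -> {len(pooled.biomarkers)} after pooling ({n_pools} pools)")
    print(f"endpoint deep_drop: {int(labels.sum())} positive / {int((~labels).sum())} negative")
    print("top of ranking (mean one-hold-out z-factor):")
    for name in result.ranking[:6]:
        z = result.mean_z[name]
        print(f"  {name:55s} z={z:+.3f}  stability={result.stability[name]:.2f}")
    print(f"stable set (stability 1.0 at k=4): {result.stable or 'none'}")
    print(f"wrote {STUDY}/selection.json")
    return 0


if __name__ == "__main__":
    sys.exit(main())
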