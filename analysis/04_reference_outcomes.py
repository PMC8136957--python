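#!/usr/bin/env python
"""Neutrophil outcomes of the bundled 10-dog doxorubicin cohort: absolute
and proportionate changes, VCOG-CTCAE grades, the grade census, and the
two binary endpoints (deep drop > 50%, grade >= 2).

Writes results/reference/outcomes.csv and endpoints.csv.
"""

import sys
from pathlib import Path

from biodyn.outcomes import (
    cohort_outcomes,
    grade_census,
    label_endpoints,
    load_reference_cohort,
)

OUT = Path("results/reference")


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    outcomes = cohort_outcomes(load_reference_cohort())
    outcomes.to_csv(OUT / "outcomes.csv", index=False, float_format="%.8g")
    labels = label_endpoints(outcomes)
    labels.to_csv(OUT / "endpoints.csv")

    print(outcomes[
        ["subject_id", "pre_count", "post_count", "absolute_change",
         "proportionate_change_3dp", "vcog_grade"]
    ].to_string(index=False))
    census = grade_census(outcomes)
    print(f"grade census: {census}")
    print(
        f"deep-drop endpoint: {int(labels.deep_drop.sum())} positive / "
        f"{int((~labels.deep_drop).sum())} negative "
        f"(negative: {sorted(labels.index[~labels.deep_drop], key=int)})"
    )
    print(
        f"grade>=2 endpoint: {int(labels.grade2plus.sum())} positive / "
        f"{int((~labels.grade2plus).sum())} negative"
    )
    print(f"wrote {OUT}/outcomes.csv, {OUT}/endpoints.csv")
    return 0


if __name__ == "__main__":
    sys.exit(main())
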