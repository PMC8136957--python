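#!/usr/bin/env python
"""Drug-response spectrograms of the demo plate: one well per condition of
subject S1, exported as CSV matrices (and heatmaps when matplotlib is
available).

The expected picture: near-zero relative change in the control well and a
dose-scaled signature (lo up, mid down, hi up) after t = 0 in the treated
wells. Run 01_simulate_study.py first.
"""

import sys
from pathlib import Path

import numpy as np

from biodyn.biomarkers import band_biomarker
from biodyn.pipeline import read_plate
from biodyn.spectrogram import compute_spectrogram, export_spectrogram_csv

STUDY = Path("results/study")
OUT = Path("results/spectrograms")


def main() -> int:
    plate_path = STUDY / "S1.h5"
    if not plate_path.exists():
        print("run analysis/01_simulate_study.py first", file=sys.stderr)
        return 1
    OUT.mkdir(parents=True, exist_ok=True)
    plate = read_plate(plate_path)
    print("condition   mean|D|   lo      mid     hi   (post-drug band means, RU)")
    for well in plate.wells:
        if well.replicate != 0:
            continue
        spec = compute_spectrogram(well, window=300.0, step=300.0)
        export_spectrogram_csv(spec, OUT / f"S1_{well.condition}.csv")
        try:
            from biodyn.spectrogram import plot_spectrogram

            plot_spectrogram(spec, OUT / f"S1_{well.condition}.png")
        except ImportError:
            pass
        bands = {b: band_biomarker(spec, b) for b in ("lo", "mid", "hi")}
        print(
            f"{well.condition:>9}   {np.abs(spec.values).mean():6.3f}  "
            f"{bands['lo']:+.3f}  {bands['mid']:+.3f}  {bands['hi']:+.3f}"
        )
    print(f"wrote spectrogram matrices under {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
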