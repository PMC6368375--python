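#!/usr/bin/env python
"""Pre-process the simulated cohort into the analysis matrix: bin in
groups of 20 points, keep 9.0-0.5 ppm minus the water and histidine
windows, normalize to the creatinine resonance at 3.05 ppm, log2.

Reads results/cohort/, writes results/matrix.txt (sample-by-bin TSV).
"""

from pathlib import Path

import pandas as pd

from nmrstress import Spectrum, preprocess_cohort

COHORT = Path("results/cohort")
OUT = Path("results/matrix.txt")


def main() -> None:
    design = pd.read_csv(COHORT / "design.tsv", sep="\t")
    spectra = [Spectrum.from_text(COHORT / f"{sid}.txt", sid)
               for sid in design["sample_id"]]
    X = preprocess_cohort(spectra, design)
    X.to_tsv(OUT)
    n, p = X.values.shape
    print(f"{n} samples x {p} retained bins "
          f"(bin width {X.provenance['points_per_bin']} points)")
    print(f"excluded windows: {X.provenance['excluded_windows']}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
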