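#!/usr/bin/env python
"""Group-sensitivity worked example.

Computes the NL -> MCI/AD percent increase of each planted group-mean
biomarker (the cohort generator's targets).  The headline comparison: GM pCSF
rises ~9.5% from the cognitively normal to the MCI/AD group, similar to the
PVS/WMV burden increase of 10.5%, while WM free water rises only ~2.5% --
pCSF and PVS burden are the more disease-sensitive measures.

Writes results/group_sensitivity.csv.
"""

from pathlib import Path

from glymap import workflows

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    summary = workflows.sensitivity_summary()
    summary.to_csv(OUT / "group_sensitivity.csv", index=False)
    print(summary.to_string(index=False))
    print("\nwrote", OUT / "group_sensitivity.csv")


if __name__ == "__main__":
    main()
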