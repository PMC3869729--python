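"""Grid search for the residence-time detector's default thresholds.

Re-runs the calibration that produced the packaged defaults: sweep the
probability-level cutoff Lc and the critical duration tc over a grid,
score each pair on the two packaged three-zone ensembles (recovered true
zones, false zones), and keep the pair maximizing recall subject to at
most one false zone per 5-trajectory ensemble (ties toward the mildest
thresholds).  Prints the feasible grid and the selected configuration.

Usage: python scripts/calibrate_residence.py
"""

import warnings

import pandas as pd

from trajmode.residence import calibrate_thresholds


def main() -> None:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        best, rows = calibrate_thresholds()
    table = pd.DataFrame(rows, columns=["Lc", "tc", "matched", "false", "feasible"])
    print(
        table[table.feasible]
        .sort_values(["matched", "false", "tc", "Lc"], ascending=[False, True, True, True])
        .to_string(index=False)
    )
    print(f"\nselected: Lc={best.Lc}, tc={best.tc} s (window {best.w}, D={best.D})")


if __name__ == "__main__":
    main()
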