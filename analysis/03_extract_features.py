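#!/usr/bin/env python
"""Extract the nine discrete joint-angle variables plus speed and stride frequency.

Initial angles (IHF, IHA, IKF, IAD, IAI) are read at 0% of the gait cycle;
peak angles (PHA, PKF, PAD, PAE) are the signed extremum within the
approximated stance phase (0-40%).  One row per participant x day x surface x
run x calibration goes to results/features.csv.
"""

import argparse
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd

from gaitrel import features, io
from gaitrel.features import DEFAULT_SPECS, extract_value


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--waveforms", type=Path,
                        default=ROOT / "scratch" / "waveforms" / "mean_waveforms.csv")
    parser.add_argument("--qc", type=Path, default=ROOT / "results" / "segmentation_qc.csv")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "features.csv")
    args = parser.parse_args()

    waves = pd.read_csv(args.waveforms)
    qc = pd.read_csv(args.qc).set_index(
        ["participant", "day", "surface", "run", "calibration"]
    )
    keys = ["participant", "day", "surface", "run", "calibration"]
    rows = []
    for key, grp in waves.groupby(keys, sort=True):
        grp = grp.sort_values("percent")
        row = dict(zip(keys, key))
        for spec in DEFAULT_SPECS:
            row[spec.name] = extract_value(grp[spec.signal].to_numpy(), spec)
        row["RS"] = qc.loc[key, "avg_speed"]
        row["SF"] = qc.loc[key, "stride_frequency"]
        rows.append(row)
    table = pd.DataFrame(rows)
    io.write_feature_table(table, args.out)
    grand = table[table["run"] == 1][list(features.ANGLE_VARIABLES) + ["RS", "SF"]].mean()
    print(f"extracted {len(table)} feature rows -> {args.out}")
    print("grand means (first runs):")
    print(grand.round(2).to_string())
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
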