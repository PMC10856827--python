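#!/usr/bin/env python
"""Segment every recording into gait cycles and average to one waveform per run.

Cycle boundaries are maxima of the right-foot AP position; the first and last
3 cycles (run transients) are trimmed, duration outliers dropped, each cycle
resampled to 101 points, and the retained cycles (about 40 per run) averaged.
Writes the per-run mean waveforms (long form, one row per percent point) and
a segmentation QC table.
"""

import argparse
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import numpy as np
import pandas as pd

from gaitrel import io, segment


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--manifest", type=Path, default=ROOT / "scratch" / "cohort" / "manifest.csv")
    parser.add_argument("--out", type=Path, default=ROOT / "scratch" / "waveforms")
    parser.add_argument("--results", type=Path, default=ROOT / "results")
    parser.add_argument("--trim", type=int, default=3)
    args = parser.parse_args()

    records = io.read_cohort(args.manifest)
    print(f"read {len(records)} recordings from {args.manifest}")

    wave_rows, qc_rows = [], []
    for rec in records:
        cs = segment.segment_recording(rec, n_trim=args.trim)
        qc_rows.append({**cs.meta, "avg_speed": rec.avg_speed,
                        "n_cycles_used": cs.n_cycles_used,
                        "n_cycles_dropped": cs.n_cycles_dropped,
                        "stride_frequency": cs.stride_frequency})
        frame = pd.DataFrame(cs.mean_waveforms)
        frame.insert(0, "percent", segment.PERCENT_GRID)
        for k, v in cs.meta.items():
            frame.insert(0, k, v)
        wave_rows.append(frame)

    qc = pd.DataFrame(qc_rows)
    args.out.mkdir(parents=True, exist_ok=True)
    args.results.mkdir(parents=True, exist_ok=True)
    pd.concat(wave_rows, ignore_index=True).to_csv(args.out / "mean_waveforms.csv", index=False)
    qc.to_csv(args.results / "segmentation_qc.csv", index=False)
    print(f"cycles used per run: median {int(qc['n_cycles_used'].median())} "
          f"(range {qc['n_cycles_used'].min()}-{qc['n_cycles_used'].max()}); "
          f"{int(qc['n_cycles_dropped'].sum())} duration outliers dropped in total")
    print(f"mean stride frequency {qc['stride_frequency'].mean():.3f} Hz; "
          f"waveforms -> {args.out / 'mean_waveforms.csv'}, QC -> {args.results / 'segmentation_qc.csv'}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
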