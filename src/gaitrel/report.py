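"""End-to-end pipeline: simulate -> segment -> features -> reliability -> association.

Assembles the result tables (ICC medians and ranges with categories, median
MDCs, mean absolute differences, mixed-model coefficients) plus a
truth-comparison table contrasting estimated median ICCs with the analytic
ICCs implied by the generator's variance components.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, features, reliability, segment, synth
from .io import SessionRecording


@dataclass
class PipelineReport:
    """All result tables of one end-to-end run, traceable to one config + seed."""

    config: synth.SimulationConfig
    feature_table: pd.DataFrame
    estimates: list
    icc_table: pd.DataFrame
    mdc_table: pd.DataFrame
    abs_diff_table: pd.DataFrame
    mixed_model_table: pd.DataFrame
    truth_comparison: pd.DataFrame
    qc: pd.DataFrame
    n_cycles_used_median: int

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.feature_table.to_csv(out / "features.csv", index=False)
        self.icc_table.to_csv(out / "icc_table.csv", index=False)
        self.mdc_table.to_csv(out / "mdc_table.csv", index=False)
        self.abs_diff_table.to_csv(out / "abs_diff_table.csv", index=False)
        self.mixed_model_table.to_csv(out / "mixed_models.csv", index=False)
        self.truth_comparison.to_csv(out / "truth_comparison.csv", index=False)
        self.qc.to_csv(out / "segmentation_qc.csv", index=False)


def segment_cohort(
    records: list[SessionRecording], n_trim: int = 3, log=None
) -> tuple[list, pd.DataFrame]:
    """Segment every recording; returns feature-table items plus a QC table."""
    items = []
    qc_rows = []
    for rec in records:
        try:
            cs = segment.segment_recording(rec, n_trim=n_trim)
        except segment.SegmentationError as exc:
            raise RuntimeError(f"segmentation failed for {rec.key}: {exc}") from exc
        items.append((cs.meta, cs, rec.avg_speed))
        qc_rows.append(
            {
                **cs.meta,
                "n_cycles_used": cs.n_cycles_used,
                "n_cycles_dropped": cs.n_cycles_dropped,
                "stride_frequency": cs.stride_frequency,
            }
        )
        if log is not None:
            print(
                f"[segment] {rec.key}: {cs.n_cycles_used} cycles used, "
                f"{cs.n_cycles_dropped} dropped",
                file=log,
            )
    return items, pd.DataFrame(qc_rows)


def run_pipeline(
    config: synth.SimulationConfig,
    n_trim: int = 3,
    out_dir: str | Path | None = None,
    records: list[SessionRecording] | None = None,
    truth: synth.SimulationTruth | None = None,
    verbose: bool = False,
) -> PipelineReport:
    """Run every stage on a (generated or supplied) cohort and assemble the report.

    Regenerating from the same config and seed is bit-identical.
    """
    log = sys.stderr if verbose else None
    if records is None:
        records, truth = synth.generate_cohort(config)
        if log:
            print(f"[synth] generated {len(records)} recordings", file=log)
    items, qc = segment_cohort(records, n_trim=n_trim, log=log)
    feature_table = features.build_feature_table(items)
    n_avg = int(np.median(qc["n_cycles_used"]))
    estimates = reliability.run_reliability(
        feature_table,
        n_days=config.n_days,
        runs=(config.runs[0], config.runs[-1]),
        calibrations=(config.calibrations[0], config.calibrations[-1]),
    )
    agg = reliability.estimates_to_frame(estimates)
    icc_table = agg[
        ["variable", "surface", "comparison_type", "icc_median", "icc_min", "icc_max",
         "icc_formatted", "category"]
    ]
    mdc_table = agg[["variable", "surface", "comparison_type", "mdc_median"]]
    abs_diff_table = agg[
        ["variable", "surface", "comparison_type", "mean_abs_diff", "sd_abs_diff"]
    ]
    mm_results = association.fit_all_variables(feature_table, n_days=config.n_days)
    mixed_model_table = association.significance_screen(mm_results)
    truth_rows = []
    if truth is not None:
        for e in estimates:
            try:
                true = synth.truth_icc(truth, e.variable, e.comparison_type, n_avg)
            except KeyError:
                continue
            truth_rows.append(
                {
                    "variable": e.variable,
                    "surface": e.surface,
                    "comparison_type": e.comparison_type,
                    "icc_median_estimated": e.icc_median,
                    "icc_true": true,
                    "error": e.icc_median - true,
                }
            )
    truth_comparison = pd.DataFrame(truth_rows)
    report = PipelineReport(
        config=config,
        feature_table=feature_table,
        estimates=estimates,
        icc_table=icc_table,
        mdc_table=mdc_table,
        abs_diff_table=abs_diff_table,
        mixed_model_table=mixed_model_table,
        truth_comparison=truth_comparison,
        qc=qc,
        n_cycles_used_median=n_avg,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


def icc_precision(
    n: int,
    k: int,
    true_icc: float,
    n_sim: int = 2000,
    seed: int = 0,
) -> float:
    """Monte-Carlo expected half-width of the 95% interval of ICC(A,1).

    Simulates ``n_sim`` studies of ``n`` subjects x ``k`` measurements under a
    pure subject + error variance model with population ICC ``true_icc`` (unit
    total variance) and returns half the central 95% spread of the sampling
    distribution of the estimator - a planning utility for choosing n and k.
    """
    if n < 2 or k < 2:
        raise ValueError("need n >= 2 and k >= 2")
    if not 0 < true_icc < 1:
        raise ValueError("true_icc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    subject = rng.normal(0.0, np.sqrt(true_icc), (n_sim, n, 1))
    error = rng.normal(0.0, np.sqrt(1.0 - true_icc), (n_sim, n, k))
    estimates = np.array([reliability.icc_a1(m).icc for m in subject + error])
    lo, hi = np.percentile(estimates, [2.5, 97.5])
    return float((hi - lo) / 2.0)
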