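"""Serialisation and plotting of run records and performance reports.

Outputs per run: one CSV per scenario record, a JSON metadata sidecar, a
JSON performance report (per scenario and whole-run), a config echo, and
optional two-panel pressure/flow figures per scenario.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .metrics import PerformanceReport, report_for_series
from .plant import MAPSeries
from .scenarios import RunRecord

__all__ = [
    "report_for_record",
    "reports_for_records",
    "write_outputs",
    "load_record_csv",
    "plot_record",
]


def report_for_record(
    record: RunRecord, scope: Optional[str] = None, include_rise_area: bool = False
) -> PerformanceReport:
    """Score one scenario record."""
    frame = record.frame
    series = MAPSeries(
        times=frame["t_scenario_s"].to_numpy(),
        values=frame["sensed_map_mmHg"].to_numpy(),
        target=record.meta["target_mmHg"],
    )
    return report_for_series(
        series,
        q_infusion=frame["q_infusion_mL_min"].to_numpy(),
        q_outflow=frame["q_outflow_mL_min"].to_numpy(),
        scope=scope or f"scenario_{record.meta['scenario_id']}",
        include_rise_area=include_rise_area,
    )


def reports_for_records(records: Sequence[RunRecord]) -> list[PerformanceReport]:
    """Per-scenario reports (rise area on the first) plus a whole-run report."""
    reports = [
        report_for_record(rec, include_rise_area=(i == 0))
        for i, rec in enumerate(records)
    ]
    frames = [r.frame for r in records]
    whole = pd.concat(frames, ignore_index=True)
    # scenario boundaries share a timestamp (the termination row does not
    # advance the clock); keep the first of each pair
    keep = whole["time_s"].diff().fillna(1.0) > 0
    whole = whole[keep]
    series = MAPSeries(
        times=whole["time_s"].to_numpy(),
        values=whole["sensed_map_mmHg"].to_numpy(),
        target=records[0].meta["target_mmHg"],
    )
    reports.append(
        report_for_series(
            series,
            q_infusion=whole["q_infusion_mL_min"].to_numpy(),
            q_outflow=whole["q_outflow_mL_min"].to_numpy(),
            scope="whole_run",
        )
    )
    return reports


def load_record_csv(path, target: float = 68.0) -> RunRecord:
    """Re-read a record CSV (or any CSV with time/MAP columns) for scoring.

    Accepts the native column names or the minimal pair
    ``(time_s, MAP_mmHg)`` with optional ``Q_infusion``/``Q_out``.
    """
    frame = pd.read_csv(path)
    rename = {
        "MAP_mmHg": "sensed_map_mmHg",
        "Q_infusion": "q_infusion_mL_min",
        "Q_out": "q_outflow_mL_min",
    }
    frame = frame.rename(columns=rename)
    if "t_scenario_s" not in frame.columns:
        frame["t_scenario_s"] = frame["time_s"] - frame["time_s"].iloc[0]
    for col in ("q_infusion_mL_min", "q_outflow_mL_min"):
        if col not in frame.columns:
            frame[col] = 0.0
    meta = {"scenario_id": int(frame.get("scenario_id", pd.Series([0])).iloc[0]),
            "target_mmHg": target}
    return RunRecord(frame=frame, meta=meta)


def write_outputs(
    records: Sequence[RunRecord],
    reports: Sequence[PerformanceReport],
    out_dir,
    config_echo: Optional[dict] = None,
    plots: bool = False,
) -> dict[str, Path]:
    """Write record CSVs, metadata, the report JSON/CSV and optional plots.

    Returns a name -> path map of everything written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for rec in records:
        sid = rec.meta["scenario_id"]
        csv_path = out / f"scenario_{sid}.csv"
        rec.to_csv(csv_path)
        written[f"scenario_{sid}_csv"] = csv_path
        meta_path = out / f"scenario_{sid}_meta.json"
        rec.write_meta(meta_path)
        written[f"scenario_{sid}_meta"] = meta_path
    report_path = out / "performance_report.json"
    report_path.write_text(
        json.dumps([r.to_dict() for r in reports], indent=2, default=float)
    )
    written["report_json"] = report_path
    tidy = pd.DataFrame(
        [
            {"scope": r.scope, "metric": k, "value": v}
            for r in reports
            for k, v in r.to_dict().items()
            if k != "scope"
        ]
    )
    tidy_path = out / "performance_report.csv"
    tidy.to_csv(tidy_path, index=False)
    written["report_csv"] = tidy_path
    if config_echo is not None:
        echo_path = out / "config_echo.json"
        echo_path.write_text(json.dumps(config_echo, indent=2, default=str))
        written["config_echo"] = echo_path
    if plots:
        for rec in records:
            sid = rec.meta["scenario_id"]
            fig_path = out / f"scenario_{sid}.png"
            plot_record(rec, fig_path)
            written[f"scenario_{sid}_png"] = fig_path
    return written


def plot_record(record: RunRecord, path) -> None:
    """Two-panel figure: sensed MAP with event markers; infusion vs outflow."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = record.frame
    t_min = frame["t_scenario_s"] / 60.0
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(8, 6))
    ax1.plot(t_min, frame["sensed_map_mmHg"], lw=1.0, color="tab:red")
    ax1.axhline(record.meta.get("target_mmHg", 68.0), ls="--", lw=0.8, color="k")
    for key, color in (
        ("event_open_time_s", "tab:orange"),
        ("event_release_time_s", "tab:green"),
    ):
        t_evt = record.meta.get(key)
        if t_evt is not None:
            ax1.axvline(t_evt / 60.0, ls=":", lw=0.8, color=color)
    ax1.set_ylabel("sensed MAP (mmHg)")
    ax2.plot(t_min, frame["q_infusion_mL_min"], lw=1.0, label="infusion")
    ax2.plot(t_min, frame["q_outflow_mL_min"], lw=1.0, label="outflow")
    ax2.set_xlabel("time (min)")
    ax2.set_ylabel("rate (mL/min)")
    ax2.legend(frameon=False)
    fig.suptitle(f"Scenario {record.meta.get('scenario_id', '?')}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
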