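"""Raster exports, summary tables and longitudinal boxplot statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bursts import ElectrodeSummary, display_round
from .errors import ConfigurationError

__all__ = ["export_raster", "summary_table", "longitudinal_stats"]


def export_raster(
    spike_trains: dict[str, np.ndarray],
    window: tuple[float, float],
) -> pd.DataFrame:
    """Spike timestamps per electrode (or unit) within a display window.

    One output row per spike: (row_id, time_s) with times relative to the
    window start — the data behind a raster plot (one line per electrode,
    one tick per spike).  A window containing no spikes yields an empty,
    still-valid frame.
    """
    lo, hi = window
    if hi < lo:
        raise ConfigurationError("window end must be >= start")
    rows = []
    for row_id in sorted(spike_trains):
        t = np.asarray(spike_trains[row_id], dtype=float)
        sel = t[(t >= lo) & (t <= hi)]
        for ts in sel:
            rows.append({"row_id": row_id, "time_s": ts - lo})
    return pd.DataFrame(rows, columns=["row_id", "time_s"])


def summary_table(summaries: list[ElectrodeSummary], rounded: bool = True) -> pd.DataFrame:
    """Flatten per-electrode summaries (with unit sub-rows) into one table.

    Mirrors the per-electrode report layout: the electrode-level columns on
    the first row of each electrode block, one extra row per sorted unit
    with its count, mean frequency and pattern label.
    """
    records = []
    for s in summaries:
        row = display_round(s.to_row()) if rounded else s.to_row()
        if s.units is None or s.units.empty:
            records.append({**row, "unit_label": "", "unit_n_spikes": np.nan,
                            "unit_mean_frequency_hz": np.nan, "unit_pattern": ""})
            continue
        for k, (_, u) in enumerate(s.units.iterrows()):
            base = row if k == 0 else {key: "" for key in row}
            freq = u["mean_frequency_hz"]
            records.append(
                {
                    **base,
                    "unit_label": u["unit_label"],
                    "unit_n_spikes": int(u["n_spikes"]),
                    "unit_mean_frequency_hz": round(float(freq), 2) if rounded else freq,
                    "unit_pattern": u["pattern"],
                }
            )
    return pd.DataFrame(records)


def _tukey_row(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    whisk_lo = float(inside.min()) if inside.size else float(med)
    whisk_hi = float(inside.max()) if inside.size else float(med)
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": whisk_lo,
        "whisker_high": whisk_hi,
        "n_electrodes": int(values.size),
    }


def longitudinal_stats(
    sessions: dict[str | int, list[ElectrodeSummary]],
    metrics: tuple[str, ...] = ("total_spikes", "mean_ptp_uv"),
) -> pd.DataFrame:
    """Boxplot statistics (Tukey convention) of per-electrode values per session.

    ``sessions`` maps a day label to that day's electrode summaries.  For
    each metric the output holds median, quartiles and whiskers of the
    per-electrode values — the numbers behind spike-count and peak-to-peak
    amplitude boxplots across recording days.
    """
    if not sessions:
        raise ConfigurationError("need at least one session")
    rows = []
    for day in sessions:
        for metric in metrics:
            values = np.array(
                [getattr(s, metric) for s in sessions[day]], dtype=float
            )
            values = values[np.isfinite(values)]
            if values.size == 0:
                continue
            rows.append({"day": day, "metric": metric, **_tukey_row(values)})
    return pd.DataFrame(rows)
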