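"""Continuous-monitoring analytics.

Long beat-table recordings are segmented into fixed intervals (default
10 min); each segment is summarized by its mean FHR, FHR variability
(within-segment sample SD of per-beat FHR), mean Doppler indices (S/D
excluding absent-EDV beats, where it is undefined), and the fraction of
beats with absent end-diastolic flow.  Per-segment metrics can then be
stratified by perinatal condition into box-plot statistics (median,
interquartile range, 5th-95th percentile whiskers; linear-interpolation
percentile rule) or paired against FHR for rank-correlation analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from fetodoppler.spectral import EDV_ZERO_THRESHOLD

__all__ = [
    "CONDITIONS",
    "MonitoringRecord",
    "segment_record",
    "stratify",
    "index_vs_fhr_scatter",
]

#: Fixed perinatal-condition vocabulary.
CONDITIONS = ("healthy", "SGA", "LGA", "diabetes", "pre-eclampsia", "hypertension")

#: Percentile rule used throughout (numpy's linear interpolation between
#: closest ranks); stated in output metadata.
PERCENTILE_RULE = "linear"


@dataclass
class MonitoringRecord:
    """One participant's continuous recording.

    ``beats`` is a BeatTable DataFrame with absolute ``start_s`` times
    and per-beat psv, edv, tav, fhr columns.
    """

    participant_id: str
    gestational_age_days: float
    condition: str
    beats: pd.DataFrame

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        starts = self.beats["start_s"].to_numpy()
        if starts.size and not np.all(np.diff(starts) > 0):
            raise ValueError("beat start times must be strictly increasing")


def segment_record(
    beats: pd.DataFrame | MonitoringRecord,
    interval: float = 600.0,
    min_beats: int = 10,
    edv_zero_threshold: float = EDV_ZERO_THRESHOLD,
) -> pd.DataFrame:
    """Summarize a beat stream over consecutive fixed intervals.

    Intervals start at the first beat and partition the covered time;
    the incomplete trailing interval is dropped.  Segments with fewer
    than ``min_beats`` beats are kept but flagged.  Returns a DataFrame
    with columns start_s, end_s, n_beats, mean_fhr, fhr_variability,
    mean_sd_ratio, mean_pi, mean_ri, absent_edv_fraction, flagged.
    """
    if isinstance(beats, MonitoringRecord):
        beats = beats.beats
    if interval <= 0:
        raise ValueError("interval must be > 0 s")
    cols = [
        "start_s", "end_s", "n_beats", "mean_fhr", "fhr_variability",
        "mean_sd_ratio", "mean_pi", "mean_ri", "absent_edv_fraction", "flagged",
    ]
    if len(beats) == 0:
        warnings.warn("empty beat table: no segments")
        return pd.DataFrame(columns=cols)

    t0 = float(beats["start_s"].iloc[0])
    t_end = float(beats["end_s"].iloc[-1]) if "end_s" in beats else float(
        beats["start_s"].iloc[-1]
    )
    n_segments = int((t_end - t0) // interval)
    if n_segments == 0:
        warnings.warn(
            f"record spans {t_end - t0:.1f} s, shorter than one "
            f"{interval:.0f}-s interval: no segments"
        )
        return pd.DataFrame(columns=cols)

    psv = beats["psv"].to_numpy(dtype=float)
    edv = beats["edv"].to_numpy(dtype=float)
    tav = beats["tav"].to_numpy(dtype=float)
    fhr = beats["fhr"].to_numpy(dtype=float)
    absent = edv <= edv_zero_threshold
    with np.errstate(divide="ignore", invalid="ignore"):
        sd = np.where(absent, np.nan, psv / edv)
        ri = (psv - edv) / psv
        pi = np.where(tav > 0, (psv - edv) / tav, np.nan)

    seg_of = ((beats["start_s"].to_numpy() - t0) // interval).astype(int)
    rows = []
    for k in range(n_segments):
        m = seg_of == k
        n = int(m.sum())
        row = {
            "start_s": t0 + k * interval,
            "end_s": t0 + (k + 1) * interval,
            "n_beats": n,
            "flagged": n < min_beats,
        }
        if n:
            fhr_k = fhr[m]
            row.update(
                mean_fhr=float(fhr_k.mean()),
                fhr_variability=float(fhr_k.std(ddof=1)) if n > 1 else 0.0,
                mean_sd_ratio=float(np.nanmean(sd[m])) if np.isfinite(sd[m]).any()
                else np.nan,
                mean_pi=float(np.nanmean(pi[m])),
                mean_ri=float(ri[m].mean()),
                absent_edv_fraction=float(absent[m].mean()),
            )
        else:
            row.update(
                mean_fhr=np.nan, fhr_variability=np.nan, mean_sd_ratio=np.nan,
                mean_pi=np.nan, mean_ri=np.nan, absent_edv_fraction=np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def stratify(
    cohort: list[MonitoringRecord],
    metric: str = "mean_pi",
    interval: float = 600.0,
    min_beats: int = 10,
) -> pd.DataFrame:
    """Per-condition box statistics of a per-segment metric.

    Returns a DataFrame indexed by condition with columns n_participants,
    n_segments, median, p25, p75, p5, p95 (linear-interpolation
    percentiles).  Conditions with no records are omitted.
    """
    if not cohort:
        raise ValueError("empty cohort")
    values: dict[str, list[np.ndarray]] = {}
    counts: dict[str, int] = {}
    for rec in cohort:
        segs = segment_record(rec, interval=interval, min_beats=min_beats)
        if len(segs) == 0:
            continue
        v = segs[metric].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if v.size:
            values.setdefault(rec.condition, []).append(v)
            counts[rec.condition] = counts.get(rec.condition, 0) + 1
    rows = []
    for cond in CONDITIONS:
        if cond not in values:
            continue
        pooled = np.concatenate(values[cond])
        p5, p25, p50, p75, p95 = np.percentile(
            pooled, [5, 25, 50, 75, 95], method=PERCENTILE_RULE
        )
        rows.append(
            {
                "condition": cond,
                "n_participants": counts[cond],
                "n_segments": pooled.size,
                "median": p50, "p25": p25, "p75": p75, "p5": p5, "p95": p95,
            }
        )
    return pd.DataFrame(rows).set_index("condition")


def index_vs_fhr_scatter(
    cohort: list[MonitoringRecord],
    metric: str = "mean_pi",
    interval: float = 600.0,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Paired per-segment (FHR, index) table with Spearman correlation.

    Returns ``(table, rho, p_value)`` where the p-value comes from a
    seeded permutation test (``n_perm`` shuffles of the index column).
    Degenerate constant series yield ``rho = nan`` and ``p = nan``.
    """
    frames = []
    for rec in cohort:
        segs = segment_record(rec, interval=interval)
        if len(segs):
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": rec.participant_id,
                        "fhr": segs["mean_fhr"],
                        metric: segs[metric],
                    }
                )
            )
    if not frames:
        raise ValueError("no segments in cohort")
    table = pd.concat(frames, ignore_index=True).dropna()
    if len(table) < 3:
        raise ValueError("need >= 3 segments for a rank correlation")
    x = table["fhr"].to_numpy()
    y = table[metric].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return table, float("nan"), float("nan")
    rho = float(spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    hits = sum(
        abs(float(spearmanr(x, rng.permutation(y)).statistic)) >= abs(rho)
        for _ in range(n_perm)
    )
    p_value = (hits + 1) / (n_perm + 1)
    return table, rho, p_value
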