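"""Normative reference ranges and longitudinal excursion flagging.

The normal range for an organ's SUV_OPT% is built from the *baseline*
scans of patients who experienced no irAE in any organ:

    CI95 = [mu - 1.96 sigma, mu + 1.96 sigma]

with mu and sigma the sample mean and (n-1) standard deviation across
patients. Longitudinal flagging uses only the upper bound — inflammation
raises uptake — with a strict inequality: a value exactly at the bound is
not a flag. Lead time is the signed difference (clinical day - first flag
day); positive when imaging flags the organ before clinical detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError

Z95 = 1.96


@dataclass(frozen=True)
class NormalRange:
    organ: str
    mu: float
    sigma: float
    n: int
    lo: float
    hi: float


@dataclass
class LongitudinalSeries:
    """Ordered (scan_day, SUV_OPT% value) pairs for one patient and organ."""

    patient_id: str
    organ: str
    days: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.size != self.values.size:
            raise ValueError("days and values must have equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("scan days must be strictly increasing")


@dataclass
class MonitorResult:
    patient_id: str
    organ: str
    flagged_days: list[int]
    first_flag_day: int | None
    clinical_day: int | None
    lead_time_days: int | None
    n_scans: int


def normal_range(baseline_values, organ: str = "") -> NormalRange:
    """CI95 band from one baseline SUV_OPT% value per irAE-free patient."""
    values = np.asarray(baseline_values, dtype=float)
    if values.size < 2:
        raise InsufficientDataError(f"normal range needs >= 2 patients, got {values.size}")
    mu = float(values.mean())
    sigma = float(values.std(ddof=1))
    return NormalRange(organ=organ, mu=mu, sigma=sigma, n=int(values.size),
                       lo=mu - Z95 * sigma, hi=mu + Z95 * sigma)


def patient_max_on_treatment(series: LongitudinalSeries) -> float:
    """Max SUV_OPT% over on-treatment scans (scan_day >= 0); baselines excluded.

    A baseline-only series cannot contribute a predictor and raises
    :class:`InsufficientDataError` so cohort builders can exclude the patient.
    """
    on = series.days >= 0
    if not on.any():
        raise InsufficientDataError(
            f"patient {series.patient_id}: no on-treatment scans for organ {series.organ}"
        )
    return float(series.values[on].max())


def monitor_series(
    series: LongitudinalSeries, rng: NormalRange, clinical_day: int | None = None
) -> MonitorResult:
    """Flag scans whose value exceeds (strictly) the normal-range upper bound."""
    flagged = series.days[series.values > rng.hi]
    first = int(flagged[0]) if flagged.size else None
    lead = None
    if first is not None and clinical_day is not None:
        lead = int(clinical_day) - first
    return MonitorResult(
        patient_id=series.patient_id,
        organ=series.organ,
        flagged_days=[int(d) for d in flagged],
        first_flag_day=first,
        clinical_day=None if clinical_day is None else int(clinical_day),
        lead_time_days=lead,
        n_scans=int(series.days.size),
    )


def cohort_monitor_report(results: list[MonitorResult], truth_labels: dict | None = None) -> dict:
    """Descriptive tabulation of flags and lead times across a cohort.

    ``truth_labels`` maps (patient_id, organ) -> irAE label (1/0); when
    given, flag rates are split into event and non-event series and the
    fraction of events flagged before clinical detection is reported.
    Purely descriptive — no inferential comparison of detection timing.
    """
    rows = []
    for r in results:
        label = None
        if truth_labels is not None:
            label = truth_labels.get((r.patient_id, r.organ), 0)
        rows.append({
            "patient_id": r.patient_id,
            "organ": r.organ,
            "n_scans": r.n_scans,
            "n_flags": len(r.flagged_days),
            "first_flag_day": r.first_flag_day,
            "clinical_day": r.clinical_day,
            "lead_time_days": r.lead_time_days,
            "label": label,
        })
    table = pd.DataFrame(rows)
    summary: dict = {"kind": "descriptive", "table": table}
    if truth_labels is not None and not table.empty:
        events = table[table["label"] == 1]
        nonevents = table[table["label"] != 1]
        with_dates = events[events["clinical_day"].notna()]
        n_led = int((with_dates["lead_time_days"] > 0).sum()) if not with_dates.empty else 0
        summary["n_events"] = int(len(events))
        summary["n_events_with_clinical_day"] = int(len(with_dates))
        summary["frac_flagged_before_clinical"] = (
            n_led / len(with_dates) if len(with_dates) else float("nan")
        )
        total_scans = int(nonevents["n_scans"].sum())
        summary["false_flag_rate_per_scan"] = (
            float(nonevents["n_flags"].sum() / total_scans) if total_scans else float("nan")
        )
    return summary


def monitor_table(results: list[MonitorResult], series_map: dict) -> pd.DataFrame:
    """Long-format per-scan monitor CSV: one row per (patient, organ, scan)."""
    rows = []
    for r in results:
        s: LongitudinalSeries = series_map[(r.patient_id, r.organ)]
        flagged = set(r.flagged_days)
        for day, value in zip(s.days, s.values):
            rows.append({
                "patient_id": r.patient_id,
                "organ": r.organ,
                "scan_day": int(day),
                "value": float(value),
                "flagged": int(day) in flagged,
                "clinical_day": r.clinical_day,
                "lead_time_days": r.lead_time_days,
            })
    return pd.DataFrame(rows)
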