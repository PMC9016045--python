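"""Model/Results facade tying the cohort statistics together.

``IrAEBiomarkerModel`` is constructed from the long-format percentile
profile table plus the per-patient-organ label table; ``fit()`` performs,
per organ: AUROC over the percentile grid, optimal-percentile selection,
ROC + Youden cutoff, the dichotomised rank-sum comparison, and the
normative baseline range. The returned ``IrAEBiomarkerResults`` carries the
estimates and exposes ``summary()``, longitudinal monitoring and plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomarker import (
    BiomarkerSelection,
    CutoffResult,
    PercentileScan,
    build_score_table,
    compare_groups,
    organ_scores,
    roc_curve,
    select_optimal_percentile,
    youden_cutoff,
)
from .errors import InsufficientDataError, SingleClassError
from .imaging import ORGANS
from .monitor import (
    LongitudinalSeries,
    MonitorResult,
    NormalRange,
    cohort_monitor_report,
    monitor_series,
    monitor_table,
    normal_range,
)

PROFILE_COLUMNS = ["patient_id", "organ", "scan_day", "percentile", "suv_gml", "n_voxels"]
LABEL_COLUMNS = ["patient_id", "organ", "label", "clinical_day"]


class IrAEBiomarkerModel:
    """Percentile-biomarker selection model for organ-specific irAE detection.

    Parameters
    ----------
    profiles : DataFrame
        Long format, columns ``patient_id, organ, scan_day, percentile,
        suv_gml, n_voxels`` — one row per scan x organ x grid percentile.
    labels : DataFrame
        One row per patient x organ: ``patient_id, organ, label (0/1),
        clinical_day`` (NaN when not applicable). Patients with irAE in
        non-target organs carry label 0 everywhere.
    censor_post_diagnosis : bool
        Exclude scans after the organ's clinical detection day from the
        per-patient max predictor (off by default: the study kept them).
    fallback_percentile : float
        Percentile at which normative ranges are built for organs whose
        selection is undefined (single-class cohort).
    """

    def __init__(self, profiles: pd.DataFrame, labels: pd.DataFrame, *,
                 censor_post_diagnosis: bool = False, fallback_percentile: float = 95.0):
        missing = set(PROFILE_COLUMNS) - set(profiles.columns)
        if missing:
            raise ValueError(f"profiles table missing columns {sorted(missing)}")
        missing = set(LABEL_COLUMNS) - set(labels.columns)
        if missing:
            raise ValueError(f"labels table missing columns {sorted(missing)}")
        self.profiles = profiles.copy()
        self.labels = labels.copy()
        self.censor_post_diagnosis = censor_post_diagnosis
        self.fallback_percentile = fallback_percentile
        self.organs = [o for o in ORGANS if o in set(profiles["organ"])]

    # alias mirroring the usual from_<container> constructor idiom
    @classmethod
    def from_profiles(cls, profiles, labels, **kwargs) -> "IrAEBiomarkerModel":
        return cls(profiles, labels, **kwargs)

    # -- normative subcohort -------------------------------------------------
    def _baseline_values(self, organ: str, percentile: float) -> np.ndarray:
        """One baseline SUV_X% per patient with no irAE of any organ.

        When a patient has several pre-treatment scans the earliest is used.
        """
        free = self.labels.groupby("patient_id")["label"].max()
        free_ids = set(free[free == 0].index)
        base = self.profiles[
            (self.profiles["scan_day"] < 0)
            & (self.profiles["organ"] == organ)
            & np.isclose(self.profiles["percentile"], percentile)
            & self.profiles["patient_id"].isin(free_ids)
        ]
        first = base.sort_values("scan_day").groupby("patient_id").first()
        return first["suv_gml"].to_numpy()

    def fit(self) -> "IrAEBiomarkerResults":
        score_table = build_score_table(
            self.profiles, self.labels, censor_post_diagnosis=self.censor_post_diagnosis
        )
        selections, scans, cutoffs, curves, comparisons, ranges, notices = {}, {}, {}, {}, {}, {}, {}
        for organ in self.organs:
            try:
                sel, scan = select_optimal_percentile(score_table, organ)
                scores = organ_scores(score_table, organ, sel.opt_percentile)
                pos = scores.loc[scores["label"] == 1, "score"].to_numpy()
                neg = scores.loc[scores["label"] == 0, "score"].to_numpy()
                curve = roc_curve(pos, neg)
                selections[organ] = sel
                scans[organ] = scan
                curves[organ] = curve
                cutoffs[organ] = youden_cutoff(curve, organ=organ)
                comparisons[organ] = compare_groups(score_table, organ, sel)
                norm_pct = sel.opt_percentile
            except SingleClassError as exc:
                notices[organ] = str(exc)
                norm_pct = self.fallback_percentile
            try:
                ranges[organ] = normal_range(self._baseline_values(organ, norm_pct), organ=organ)
            except InsufficientDataError as exc:
                notices.setdefault(organ, str(exc))
        return IrAEBiomarkerResults(
            model=self, score_table=score_table, selections=selections,
            percentile_scans=scans, cutoffs=cutoffs, roc_curves=curves,
            comparisons=comparisons, normal_ranges=ranges, notices=notices,
        )


@dataclass
class IrAEBiomarkerResults:
    """Fitted per-organ biomarker estimates and their diagnostics."""

    model: IrAEBiomarkerModel
    score_table: pd.DataFrame
    selections: dict = field(default_factory=dict)       # organ -> BiomarkerSelection
    percentile_scans: dict = field(default_factory=dict)  # organ -> PercentileScan
    cutoffs: dict = field(default_factory=dict)           # organ -> CutoffResult
    roc_curves: dict = field(default_factory=dict)        # organ -> DataFrame
    comparisons: dict = field(default_factory=dict)       # organ -> dict
    normal_ranges: dict = field(default_factory=dict)     # organ -> NormalRange
    notices: dict = field(default_factory=dict)           # organ -> skip reason

    # -- reporting -----------------------------------------------------------
    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for organ in self.model.organs:
            sel: BiomarkerSelection | None = self.selections.get(organ)
            cut: CutoffResult | None = self.cutoffs.get(organ)
            cmpres = self.comparisons.get(organ, {})
            rng: NormalRange | None = self.normal_ranges.get(organ)
            rows.append({
                "organ": organ,
                "opt_percentile": None if sel is None else sel.opt_percentile,
                "auroc": None if sel is None else sel.auroc,
                "cutoff_gml": None if cut is None else cut.threshold,
                "youden_j": None if cut is None else cut.youden_j,
                "sensitivity": None if cut is None else cut.sensitivity,
                "specificity": None if cut is None else cut.specificity,
                "p_value": cmpres.get("p_value"),
                "normal_lo": None if rng is None else rng.lo,
                "normal_hi": None if rng is None else rng.hi,
                "n_normal": None if rng is None else rng.n,
                "notice": self.notices.get(organ, ""),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.summary_frame()
        lines = ["irAE percentile-biomarker model", "=" * 80]
        for _, r in df.iterrows():
            lines.append(f"organ: {r['organ']}")
            if r["notice"]:
                lines.append(f"  notice: {r['notice']}")
            if r["opt_percentile"] is not None and not pd.isna(r["opt_percentile"]):
                lines.append(
                    f"  SUV_OPT% = {r['opt_percentile']:.0f}   AUROC = {r['auroc']:.2f}   "
                    f"T_OPT = {r['cutoff_gml']:.2f} g/mL"
                )
                lines.append(
                    f"  sensitivity = {r['sensitivity']:.2f}   specificity = {r['specificity']:.2f}   "
                    f"Youden J = {r['youden_j']:.2f}   rank-sum p = {r['p_value']:.3g}"
                )
            if r["normal_lo"] is not None and not pd.isna(r["normal_lo"]):
                lines.append(
                    f"  normal range = [{r['normal_lo']:.2f}, {r['normal_hi']:.2f}] g/mL "
                    f"(n = {int(r['n_normal'])} irAE-free baselines)"
                )
            lines.append("-" * 80)
        return "\n".join(lines)

    # -- longitudinal monitoring ----------------------------------------------
    def series_for(self, patient_id: str, organ: str) -> LongitudinalSeries:
        sel = self.selections.get(organ)
        pct = self.model.fallback_percentile if sel is None else sel.opt_percentile
        sub = self.model.profiles[
            (self.model.profiles["patient_id"] == patient_id)
            & (self.model.profiles["organ"] == organ)
            & np.isclose(self.model.profiles["percentile"], pct)
        ].sort_values("scan_day")
        return LongitudinalSeries(
            patient_id=patient_id, organ=organ,
            days=sub["scan_day"].to_numpy(), values=sub["suv_gml"].to_numpy(),
        )

    def monitor(self, organs=None) -> tuple[pd.DataFrame, dict]:
        """Flag every patient's series against the organ's normal range.

        Returns the long-format monitor table and the descriptive cohort
        report (fraction of events flagged before clinical detection,
        false-flag rate on non-event series).
        """
        organs = organs or [o for o in self.model.organs if o in self.normal_ranges]
        label_map = {
            (r.patient_id, r.organ): int(r.label)
            for r in self.model.labels.itertuples()
        }
        clin = {
            (r.patient_id, r.organ): (None if pd.isna(r.clinical_day) else int(r.clinical_day))
            for r in self.model.labels.itertuples()
        }
        results: list[MonitorResult] = []
        series_map = {}
        for organ in organs:
            rng = self.normal_ranges[organ]
            for pid in sorted(self.model.profiles["patient_id"].unique()):
                s = self.series_for(pid, organ)
                if s.days.size == 0:
                    continue
                series_map[(pid, organ)] = s
                results.append(monitor_series(s, rng, clinical_day=clin.get((pid, organ))))
        report = cohort_monitor_report(results, truth_labels=label_map)
        return monitor_table(results, series_map), report

    # -- plotting ------------------------------------------------------------
    def plot_auroc_by_percentile(self, ax=None):
        from .plots import plot_auroc_by_percentile
        return plot_auroc_by_percentile(self, ax=ax)

    def plot_roc(self, ax=None):
        from .plots import plot_roc
        return plot_roc(self, ax=ax)

    def plot_dichotomized(self, ax=None):
        from .plots import plot_dichotomized
        return plot_dichotomized(self, ax=ax)

    def plot_series(self, patient_id: str, organ: str, ax=None):
        from .plots import plot_series
        return plot_series(self, patient_id, organ, ax=ax)
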