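"""Cohort-level biomarker statistics.

For each target organ the cohort is split into patients who experienced an
immune-related adverse event (irAE) in that organ (label 1) and everyone
else (label 0; patients with irAE of other organs count as negative for
organ-specific identification). Each patient's score at percentile X is the
maximum SUV_X% over their on-treatment scans. The optimal percentile is the
argmax of AUROC(X) over the grid; the operating cutoff maximises Youden's
J = sensitivity + specificity - 1.

Classification polarity is fixed as ``score > threshold`` => irAE-positive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import SingleClassError


@dataclass
class PercentileScan:
    """AUROC as a function of percentile for one organ."""

    organ: str
    percentiles: np.ndarray
    auroc: np.ndarray


@dataclass(frozen=True)
class BiomarkerSelection:
    """The AUROC-optimal percentile (SUV_OPT%) for one organ."""

    organ: str
    opt_percentile: float
    auroc: float


@dataclass(frozen=True)
class CutoffResult:
    """Youden-optimal operating point on an ROC curve."""

    organ: str
    threshold: float   # T_OPT, g/mL
    youden_j: float
    sensitivity: float
    specificity: float


def auroc(pos_scores, neg_scores) -> float:
    """Probability a random positive outscores a random negative, ties 1/2.

    Computed from rank sums (the Mann–Whitney identity U / (n1 * n2));
    average ranks give exactly half credit to ties. Invariant under
    strictly increasing score transforms.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise SingleClassError("AUROC undefined: one of the groups is empty")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def roc_curve(pos_scores, neg_scores) -> pd.DataFrame:
    """ROC operating points for the rule ``score > threshold`` => positive.

    Thresholds are the unique observed scores plus a -inf sentinel
    (classify-everyone-positive), in ascending order, so sensitivity is
    non-increasing and specificity non-decreasing down the table.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise SingleClassError("ROC undefined: one of the groups is empty")
    thresholds = np.concatenate([[-np.inf], np.unique(np.concatenate([pos, neg]))])
    sens = np.array([(pos > t).mean() for t in thresholds])
    spec = np.array([(neg <= t).mean() for t in thresholds])
    return pd.DataFrame({"threshold": thresholds, "sensitivity": sens, "specificity": spec})


def roc_auc_trapezoid(curve: pd.DataFrame) -> float:
    """Trapezoidal area under an ROC curve returned by :func:`roc_curve`."""
    fpr = 1.0 - curve["specificity"].to_numpy()
    tpr = curve["sensitivity"].to_numpy()
    # thresholds ascend, so (fpr, tpr) runs from (1,1) down to (0,0); reverse
    return float(np.trapezoid(tpr[::-1], fpr[::-1]))


def youden_cutoff(curve: pd.DataFrame, organ: str = "") -> CutoffResult:
    """Operating point maximising J = sensitivity + specificity - 1.

    Ties are broken by higher specificity, then by lower threshold.
    """
    j = curve["sensitivity"].to_numpy() + curve["specificity"].to_numpy() - 1.0
    order = sorted(
        range(len(curve)),
        key=lambda i: (-j[i], -curve["specificity"].iloc[i], curve["threshold"].iloc[i]),
    )
    best = curve.iloc[order[0]]
    return CutoffResult(
        organ=organ,
        threshold=float(best["threshold"]),
        youden_j=float(j[order[0]]),
        sensitivity=float(best["sensitivity"]),
        specificity=float(best["specificity"]),
    )


def wilcoxon_rank_sum(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (U statistic of A, p).

    Exact enumeration of all label assignments when the combined sample
    has n <= 12 and no ties; otherwise a normal approximation with tie and
    continuity corrections. p is clipped into (0, 1].
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise SingleClassError("rank-sum test undefined: one of the groups is empty")
    combined = np.concatenate([a, b])
    n1, n2, n = a.size, b.size, a.size + b.size
    ranks = sps.rankdata(combined)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    ties = np.unique(combined).size < n

    if n <= 12 and not ties:
        sorted_ranks = np.arange(1, n + 1)
        dev = abs(u_obs - mu)
        hits = total = 0
        for comb in itertools.combinations(sorted_ranks, n1):
            u = sum(comb) - n1 * (n1 + 1) / 2
            total += 1
            if abs(u - mu) >= dev - 1e-9:
                hits += 1
        return float(u_obs), hits / total

    _, counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12 * (n + 1 - tie_term)
    if sigma2 <= 0:  # all values identical
        return float(u_obs), 1.0
    z = (abs(u_obs - mu) - 0.5) / np.sqrt(sigma2)
    p = 2 * sps.norm.sf(max(z, 0.0))
    return float(u_obs), float(min(max(p, np.nextafter(0, 1)), 1.0))


# ---------------------------------------------------------------------------
# Cohort score table and percentile selection


def build_score_table(
    profiles: pd.DataFrame,
    labels: pd.DataFrame,
    *,
    censor_post_diagnosis: bool = False,
) -> pd.DataFrame:
    """Per patient x organ x percentile: max on-treatment SUV_X% plus label.

    ``profiles`` is long-format with columns (patient_id, organ, scan_day,
    percentile, suv_gml, n_voxels); ``labels`` has one row per patient x
    organ with columns (patient_id, organ, label, clinical_day). Only scans
    with ``scan_day >= 0`` enter the predictor; when
    ``censor_post_diagnosis`` is set, scans after the clinical detection
    day of that organ's irAE are excluded too. Patients with no eligible
    on-treatment scan are dropped.
    """
    df = profiles[profiles["scan_day"] >= 0].merge(
        labels[["patient_id", "organ", "label", "clinical_day"]],
        on=["patient_id", "organ"],
        how="inner",
    )
    if censor_post_diagnosis:
        keep = df["clinical_day"].isna() | (df["scan_day"] <= df["clinical_day"])
        df = df[keep]
    if df.empty:
        raise SingleClassError("no on-treatment scans available to build a score table")
    table = (
        df.groupby(["patient_id", "organ", "percentile"], as_index=False)
        .agg(score=("suv_gml", "max"), label=("label", "first"), clinical_day=("clinical_day", "first"))
    )
    return table


def select_optimal_percentile(
    score_table: pd.DataFrame, organ: str
) -> tuple[BiomarkerSelection, PercentileScan]:
    """SUV_OPT% = argmax over the percentile grid of AUROC(X).

    AUROC ties are broken toward the smallest percentile (lower percentiles
    are more robust to segmentation error). Raises when the cohort has a
    single class for the organ.
    """
    sub = score_table[score_table["organ"] == organ]
    if sub.empty:
        raise SingleClassError(f"no rows for organ {organ!r}")
    wide = sub.pivot(index="patient_id", columns="percentile", values="score")
    lab = sub.groupby("patient_id")["label"].first().reindex(wide.index)
    if lab.nunique() < 2:
        raise SingleClassError(f"organ {organ!r}: cohort contains a single irAE class")
    grid = np.asarray(sorted(wide.columns), dtype=float)
    pos = lab.to_numpy() == 1
    aucs = np.array([auroc(wide[x].to_numpy()[pos], wide[x].to_numpy()[~pos]) for x in grid])
    best = int(np.argmax(aucs))  # first max -> smallest percentile on ties
    return (
        BiomarkerSelection(organ=organ, opt_percentile=float(grid[best]), auroc=float(aucs[best])),
        PercentileScan(organ=organ, percentiles=grid, auroc=aucs),
    )


def organ_scores(score_table: pd.DataFrame, organ: str, percentile: float) -> pd.DataFrame:
    """Per-patient (score, label, clinical_day) at one organ and percentile."""
    sub = score_table[
        (score_table["organ"] == organ) & (np.isclose(score_table["percentile"], percentile))
    ]
    return sub.set_index("patient_id")[["score", "label", "clinical_day"]]


def compare_groups(score_table: pd.DataFrame, organ: str, selection: BiomarkerSelection) -> dict:
    """Dichotomised comparison of max SUV_OPT% by irAE status.

    Returns group sizes and medians, the two-sided rank-sum p, and a
    significance flag at alpha = 0.05.
    """
    scores = organ_scores(score_table, organ, selection.opt_percentile)
    pos = scores.loc[scores["label"] == 1, "score"].to_numpy()
    neg = scores.loc[scores["label"] == 0, "score"].to_numpy()
    if pos.size == 0 or neg.size == 0:
        raise SingleClassError(f"organ {organ!r}: cannot compare groups with a single class")
    stat, p = wilcoxon_rank_sum(pos, neg)
    return {
        "organ": organ,
        "percentile": selection.opt_percentile,
        "n_pos": int(pos.size),
        "n_neg": int(neg.size),
        "median_pos": float(np.median(pos)),
        "median_neg": float(np.median(neg)),
        "statistic": stat,
        "p_value": p,
        "significant": bool(p < 0.05),
    }
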