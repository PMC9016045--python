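"""Figure builders: AUROC-vs-percentile, ROC with operating point,
dichotomised strip plot, and longitudinal series against the normal band."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

ORGAN_COLORS = {"bowel": "tab:orange", "lung": "tab:blue", "thyroid": "tab:green"}


def _axes(ax):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    return ax


def plot_auroc_by_percentile(results, ax=None):
    ax = _axes(ax)
    for organ, scan in results.percentile_scans.items():
        ax.plot(scan.percentiles, scan.auroc, marker="o", ms=3,
                color=ORGAN_COLORS.get(organ), label=organ)
        sel = results.selections[organ]
        ax.scatter([sel.opt_percentile], [sel.auroc], s=60, facecolors="none",
                   edgecolors=ORGAN_COLORS.get(organ))
    ax.set_xlabel("SUV percentile X")
    ax.set_ylabel("AUROC")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax


def plot_roc(results, ax=None):
    ax = _axes(ax)
    for organ, curve in results.roc_curves.items():
        fpr = 1 - curve["specificity"].to_numpy()
        tpr = curve["sensitivity"].to_numpy()
        ax.step(fpr[::-1], tpr[::-1], where="post", color=ORGAN_COLORS.get(organ),
                label=f"{organ} (AUROC={results.selections[organ].auroc:.2f})")
        cut = results.cutoffs[organ]
        ax.scatter([1 - cut.specificity], [cut.sensitivity], s=50,
                   color=ORGAN_COLORS.get(organ), zorder=3)
    ax.plot([0, 1], [0, 1], ls=":", color="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    return ax


def plot_dichotomized(results, ax=None):
    """Strip plot of per-patient max SUV_OPT% split by irAE status."""
    ax = _axes(ax)
    rng = np.random.default_rng(0)
    positions, labels = [], []
    for i, (organ, sel) in enumerate(results.selections.items()):
        sub = results.score_table[
            (results.score_table["organ"] == organ)
            & np.isclose(results.score_table["percentile"], sel.opt_percentile)
        ]
        for j, lab in enumerate((0, 1)):
            x0 = 2 * i + j * 0.7
            vals = sub.loc[sub["label"] == lab, "score"].to_numpy()
            jitter = rng.uniform(-0.12, 0.12, size=vals.size)
            ax.scatter(np.full(vals.size, x0) + jitter, vals, s=12,
                       color=ORGAN_COLORS.get(organ), alpha=0.5 if lab == 0 else 0.95)
            positions.append(x0)
            labels.append(f"{organ}\n{'NC' if lab == 0 else 'AE'}")
        p = results.comparisons[organ]["p_value"]
        ax.text(2 * i + 0.35, ax.get_ylim()[1], f"p={p:.3g}", ha="center", fontsize=8)
    ax.set_xticks(positions, labels, fontsize=8)
    ax.set_ylabel("max on-treatment SUV_OPT% (g/mL)")
    return ax


def plot_series(results, patient_id: str, organ: str, ax=None):
    """Longitudinal SUV_OPT% with the grey normal band and the clinical
    detection date (dashed) when known."""
    ax = _axes(ax)
    s = results.series_for(patient_id, organ)
    band = results.normal_ranges.get(organ)
    if band is not None:
        ax.axhspan(band.lo, band.hi, color="0.85", zorder=0)
    ax.plot(s.days, s.values, marker="o", color=ORGAN_COLORS.get(organ))
    lab = results.model.labels
    row = lab[(lab["patient_id"] == patient_id) & (lab["organ"] == organ)]
    if not row.empty and not np.isnan(row["clinical_day"].iloc[0]):
        ax.axvline(float(row["clinical_day"].iloc[0]), ls="--", color="k")
    ax.axvline(0, ls=":", color="grey")
    ax.set_xlabel("days from treatment start")
    ax.set_ylabel("SUV_OPT% (g/mL)")
    ax.set_title(f"{patient_id} / {organ}", fontsize=9)
    return ax
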