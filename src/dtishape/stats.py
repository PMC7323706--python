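"""ROI aggregation and group statistics for shape-metric maps.

Aggregation follows the subject-level convention: a mean of each metric
map is taken over every labelled ROI per subject, and group statistics
(mean ± SEM, one-way ANOVA with Tukey HSD post-hoc, Mann-Whitney U) are
computed across subjects.  Percent changes versus the wild-type group are
rounded half away from zero to integer percent, matching the reporting
style of the emulated study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tissue import GROUPS, LABELS, LABEL_NAMES

__all__ = [
    "roi_means",
    "percent_change",
    "subject_roi_table",
    "compare_groups",
    "build_summary_table",
    "RoiStudy",
    "RoiStudyResults",
    "MissingLabelError",
    "EmptyRoiError",
    "UndefinedChangeError",
]

METRICS = ("fa", "cl", "cp", "cs", "md")

#: composite ROIs reported in addition to the painted labels
COMPOSITES = {"SC_wm": ("Af", "Lf", "Pf")}


class MissingLabelError(KeyError):
    """Requested label absent from the label volume."""


class EmptyRoiError(ValueError):
    """Every voxel of the ROI carries the invalid-voxel sentinel."""


class UndefinedChangeError(ZeroDivisionError):
    """Percent change against a zero reference mean."""


def roi_means(
    metric_vol: np.ndarray, label_vol: np.ndarray, label: int
) -> tuple[float, int]:
    """Mean of a metric map over one ROI, ignoring NaN sentinels.

    Returns ``(mean, n_voxels_used)``.
    """
    metric_vol = np.asarray(metric_vol, dtype=float)
    label_vol = np.asarray(label_vol)
    if metric_vol.shape != label_vol.shape:
        raise ValueError(
            f"metric grid {metric_vol.shape} != label grid {label_vol.shape}"
        )
    vox = label_vol == label
    if not vox.any():
        raise MissingLabelError(f"label {label} absent from label volume")
    vals = metric_vol[vox]
    valid = np.isfinite(vals)
    if not valid.any():
        raise EmptyRoiError(f"all {vals.size} voxels of label {label} are sentinel")
    return float(vals[valid].mean()), int(valid.sum())


def percent_change(reference_mean: float, group_mean: float) -> int:
    """Signed integer percent change, rounded half away from zero.

    ``100·(group_mean − reference_mean)/reference_mean``; e.g. a drop from
    0.200 to 0.120 is −40.
    """
    if reference_mean == 0:
        raise UndefinedChangeError("percent change undefined for zero reference")
    pct = 100.0 * (group_mean - reference_mean) / reference_mean
    return int(math.copysign(math.floor(abs(pct) + 0.5), pct))


def subject_roi_table(
    metric_maps: dict[str, np.ndarray],
    label_vol: np.ndarray,
    subject: str,
    group: str,
    composites: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Per-ROI metric means for one subject, in tidy form.

    ``metric_maps`` maps metric name → 3D volume (NaN = invalid voxel).
    Composite ROIs (by default SC_wm = Af ∪ Lf ∪ Pf, when all parts are
    present) are aggregated over the union of their member labels.
    """
    if composites is None:
        composites = COMPOSITES
    label_vol = np.asarray(label_vol)
    present = {int(l) for l in np.unique(label_vol) if l != 0}
    rows = []
    targets: list[tuple[str, np.ndarray]] = [
        (LABEL_NAMES[l], label_vol == l) for l in sorted(present) if l in LABEL_NAMES
    ]
    for name, parts in composites.items():
        codes = [LABELS[p] for p in parts]
        if all(c in present for c in codes):
            targets.append((name, np.isin(label_vol, codes)))
    for name, vox in targets:
        for metric, vol in metric_maps.items():
            vals = np.asarray(vol, dtype=float)[vox]
            valid = np.isfinite(vals)
            rows.append({
                "subject": subject,
                "group": group,
                "structure": name,
                "metric": metric,
                "value": float(vals[valid].mean()) if valid.any() else np.nan,
                "n_voxels": int(valid.sum()),
            })
    return pd.DataFrame(rows)


def _group_samples(df: pd.DataFrame, groups: tuple[str, ...]) -> list[np.ndarray]:
    return [df.loc[df["group"] == g, "value"].to_numpy(dtype=float) for g in groups]


def compare_groups(
    subject_df: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise group comparisons per (structure, metric).

    ``subject_df`` is tidy with columns subject, group, structure, metric,
    value.  For each structure × metric, computes a one-way ANOVA across
    all groups present, Tukey HSD pairwise p-values, Mann-Whitney U
    pairwise p-values (exact where possible) and integer percent changes.
    Contrasts with fewer than two subjects in a group are emitted with
    NaN p-values and ``computable=False`` rather than dropped.
    """
    rows = []
    for (structure, metric), sub in subject_df.groupby(
        ["structure", "metric"], sort=True
    ):
        groups = tuple(g for g in GROUPS if g in set(sub["group"]))
        if len(groups) < 2:
            continue
        samples = _group_samples(sub, groups)
        sizes = [s.size for s in samples]
        anova_ok = len(groups) >= 2 and all(n >= 2 for n in sizes)
        if anova_ok:
            f_stat, p_anova = sps.f_oneway(*samples)
            tukey = sps.tukey_hsd(*samples)
        else:
            f_stat, p_anova, tukey = np.nan, np.nan, None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a, b = samples[i], samples[j]
                pc = (
                    percent_change(a.mean(), b.mean())
                    if a.size and b.size and a.mean() != 0 else np.nan
                )
                if a.size >= 2 and b.size >= 2:
                    try:
                        p_mw = sps.mannwhitneyu(
                            a, b, alternative="two-sided", method="exact"
                        ).pvalue
                    except ValueError:  # ties → normal approximation
                        p_mw = sps.mannwhitneyu(
                            a, b, alternative="two-sided"
                        ).pvalue
                else:
                    p_mw = np.nan
                p_tukey = tukey.pvalue[i, j] if tukey is not None else np.nan
                rows.append({
                    "structure": structure,
                    "metric": metric,
                    "contrast": f"{groups[i]} vs {groups[j]}",
                    "percent_change": pc,
                    "f_anova": float(f_stat) if anova_ok else np.nan,
                    "p_anova": float(p_anova) if anova_ok else np.nan,
                    "p_tukey": float(p_tukey) if tukey is not None else np.nan,
                    "p_mannwhitney": float(p_mw) if p_mw == p_mw else np.nan,
                    "significant": bool(
                        tukey is not None and p_tukey < alpha
                    ),
                    "computable": bool(anova_ok),
                })
    return pd.DataFrame(rows)


def _sig_mark(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def build_summary_table(
    subject_df: pd.DataFrame, reference_group: str = "WT"
) -> pd.DataFrame:
    """Group summary in the style of a per-structure DTI results table.

    One row per structure × metric × group with mean, SEM (sd/√n over
    subjects), integer percent change versus the reference group, Tukey
    and Mann-Whitney p-values for the contrast against the reference, and
    a significance mark ("*" p<.05, "**" p<.01, from the Tukey test).
    Column and row order are deterministic.
    """
    comparisons = compare_groups(subject_df)
    rows = []
    for (structure, metric), sub in subject_df.groupby(
        ["structure", "metric"], sort=True
    ):
        ref = sub.loc[sub["group"] == reference_group, "value"].to_numpy(dtype=float)
        for group in GROUPS:
            vals = sub.loc[sub["group"] == group, "value"].to_numpy(dtype=float)
            if vals.size == 0:
                continue
            n = vals.size
            mean = float(vals.mean())
            sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            if group == reference_group or ref.size == 0 or ref.mean() == 0:
                pct, p_tuk, p_mw = (0 if group == reference_group else np.nan,
                                    np.nan, np.nan)
            else:
                pct = percent_change(ref.mean(), mean)
                contrast = f"{reference_group} vs {group}"
                row = comparisons[
                    (comparisons["structure"] == structure)
                    & (comparisons["metric"] == metric)
                    & (comparisons["contrast"] == contrast)
                ]
                p_tuk = float(row["p_tukey"].iloc[0]) if len(row) else np.nan
                p_mw = float(row["p_mannwhitney"].iloc[0]) if len(row) else np.nan
            rows.append({
                "structure": structure,
                "metric": metric,
                "group": group,
                "mean": mean,
                "sem": sem,
                "n_subjects": n,
                "pct_change_vs_wt": pct,
                "p_tukey": p_tuk,
                "p_mannwhitney": p_mw,
                "significance_mark": _sig_mark(p_tuk),
            })
    out = pd.DataFrame(rows)
    order = {m: i for i, m in enumerate(METRICS)}
    gorder = {g: i for i, g in enumerate(GROUPS)}
    out = out.sort_values(
        ["structure", "metric", "group"],
        key=lambda col: (
            col.map(order) if col.name == "metric"
            else col.map(gorder) if col.name == "group"
            else col
        ),
    ).reset_index(drop=True)
    return out


class RoiStudy:
    """Group-comparison model over per-subject ROI means.

    Parameters
    ----------
    subject_df : DataFrame
        Tidy per-subject ROI means with columns subject, group,
        structure, metric, value (e.g. concatenated outputs of
        :func:`subject_roi_table`).
    reference_group : str
        Group percent changes are computed against (default "WT").
    """

    def __init__(self, subject_df: pd.DataFrame, reference_group: str = "WT"):
        required = {"subject", "group", "structure", "metric", "value"}
        missing = required - set(subject_df.columns)
        if missing:
            raise ValueError(f"subject_df lacks columns: {sorted(missing)}")
        self.subject_df = subject_df
        self.reference_group = reference_group

    def fit(self, alpha: float = 0.05) -> "RoiStudyResults":
        summary = build_summary_table(self.subject_df, self.reference_group)
        comparisons = compare_groups(self.subject_df, alpha=alpha)
        return RoiStudyResults(self, summary, comparisons, alpha)


@dataclass
class RoiStudyResults:
    """Summary table plus pairwise comparisons for an ROI study."""

    model: RoiStudy
    summary_table: pd.DataFrame
    comparisons: pd.DataFrame
    alpha: float

    def summary(self) -> str:
        t = self.summary_table
        lines = ["ROI group study", "==============="]
        n_subj = self.model.subject_df.groupby("group")["subject"].nunique()
        lines.append(
            "subjects: " + ", ".join(f"{g}={n}" for g, n in n_subj.items())
        )
        lines.append("")
        for structure, sub in t.groupby("structure", sort=True):
            lines.append(structure)
            for _, r in sub.iterrows():
                pct = ("" if r["group"] == self.model.reference_group
                       else f" ({float(r['pct_change_vs_wt']):+.0f}%)"
                       if np.isfinite(float(r["pct_change_vs_wt"])) else "")
                sem = (f"± {r['sem']:.3f}" if np.isfinite(float(r["sem"]))
                       else "")
                lines.append(
                    f"  {r['metric']:>3} {r['group']:>5}: {r['mean']:.3f} "
                    f"{sem}{pct} {r['significance_mark']}"
                )
        return "\n".join(lines)
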