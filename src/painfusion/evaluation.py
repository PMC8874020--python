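"""Evaluation machinery: cross-validation, F1 scores and ANOVA screens.

Two validation schemes mirror the study design: stratified 5-fold
cross-validation over 20-s windows, and leave-one-subject-out (LOSO)
validation that measures cross-subject generalization.  Per-class F1 is
the primary metric; macro-F1 is the single-number summary.

The significance layer tests each summary feature across the three pain
states.  The default is a repeated-measures one-way ANOVA on the
subject-by-state mean table (subjects as blocks, F = MS_state /
MS_interaction, denominator df = 2*(n_subjects - 1)), matching a
within-subject analysis with n_subjects - 1 subject degrees of freedom.
Blood-pressure deltas, which exist only as one pre/post pair per day, are
tested as a one-sample t on subject-mean deltas (reported as F = t^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .cascade import CascadeConfig, predict_label, train_cascade
from .modalities import PAIN_LABELS

_CLASS_INDEX = {c: i for i, c in enumerate(PAIN_LABELS)}


@dataclass
class EvaluationReport:
    """Results of one cross-validation run."""

    scheme: str
    per_class_f1: dict[str, float]
    macro_f1: float
    confusion: pd.DataFrame          # rows true, columns predicted
    n_folds_or_subjects: int


@dataclass
class AnovaResult:
    """One feature's test across the three pain states."""

    feature_name: str
    F: float
    dof_between: int
    dof_within: int
    p: float
    variant: str
    dof_subject: int | None = None


def f1_per_class(confusion: np.ndarray) -> dict[str, float]:
    """Per-class F1 = 2TP / (2TP + FP + FN); 0 when the denominator is 0."""
    c = np.asarray(confusion)
    if c.shape != (3, 3) or np.any(c < 0):
        raise ValueError("confusion must be a nonnegative 3x3 matrix")
    out = {}
    for i, cls in enumerate(PAIN_LABELS):
        tp = c[i, i]
        fp = c[:, i].sum() - tp
        fn = c[i, :].sum() - tp
        denom = 2 * tp + fp + fn
        out[cls] = float(2 * tp / denom) if denom > 0 else 0.0
    return out


def _empty_confusion() -> pd.DataFrame:
    return pd.DataFrame(0, index=list(PAIN_LABELS), columns=list(PAIN_LABELS))


def _accumulate(confusion: pd.DataFrame, y_true, y_pred) -> pd.DataFrame:
    fold = _empty_confusion()
    for t, p in zip(y_true, y_pred):
        fold.loc[t, p] += 1
    return confusion + fold, fold


def kfold_cv(
    X: pd.DataFrame,
    labels,
    k: int = 5,
    seed: int = 0,
    cascade_config: CascadeConfig | None = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of the cascade over windows.

    Folds are stratified by class; per-class F1 is averaged over folds and
    the pooled confusion matrix is reported.  If a random partition leaves
    a training split without one of the classes, the partition is redrawn
    once before raising.
    """
    y = np.asarray(labels, dtype=object)
    if len(y) < k:
        raise ValueError("need at least k rows")
    Xr = X.reset_index(drop=True)

    def splits(s):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=s)
        return list(skf.split(Xr, y))

    folds = splits(seed)
    if any(len(set(y[tr])) < 3 for tr, _ in folds):
        folds = splits(seed + 1)
        if any(len(set(y[tr])) < 3 for tr, _ in folds):
            raise ValueError("a class is absent from a training split")

    confusion = _empty_confusion()
    fold_f1: list[dict[str, float]] = []
    for tr, te in folds:
        model = train_cascade(Xr.iloc[tr], y[tr], cascade_config)
        pred = predict_label(model, Xr.iloc[te])
        confusion, fold = _accumulate(confusion, y[te], pred)
        fold_f1.append(f1_per_class(fold.to_numpy()))
    per_class = {
        c: float(np.mean([f[c] for f in fold_f1])) for c in PAIN_LABELS
    }
    macro = float(np.mean(list(per_class.values())))
    return EvaluationReport("kfold5" if k == 5 else f"kfold{k}",
                            per_class, macro, confusion, k)


def loso_cv(
    X: pd.DataFrame,
    labels,
    subject_ids,
    cascade_config: CascadeConfig | None = None,
) -> EvaluationReport:
    """Leave-one-subject-out validation: one fold per subject.

    Per-class F1 is averaged over the folds in which the class actually
    appears in the held-out subject's windows (a subject who never
    reported high pain contributes no HP term to that average).
    """
    y = np.asarray(labels, dtype=object)
    subjects = np.asarray(subject_ids)
    uniq = np.unique(subjects)
    if len(uniq) < 3:
        raise ValueError("LOSO needs at least 3 subjects")
    Xr = X.reset_index(drop=True)

    confusion = _empty_confusion()
    sums = {c: 0.0 for c in PAIN_LABELS}
    counts = {c: 0 for c in PAIN_LABELS}
    for s in uniq:
        te = subjects == s
        model = train_cascade(Xr[~te], y[~te], cascade_config)
        pred = predict_label(model, Xr[te])
        confusion, fold = _accumulate(confusion, y[te], pred)
        fold_f1 = f1_per_class(fold.to_numpy())
        for c in PAIN_LABELS:
            if fold.loc[c].sum() > 0:  # class present in this subject
                sums[c] += fold_f1[c]
                counts[c] += 1
    per_class = {
        c: (sums[c] / counts[c]) if counts[c] else 0.0 for c in PAIN_LABELS
    }
    macro = float(np.mean(list(per_class.values())))
    return EvaluationReport("loso", per_class, macro, confusion, len(uniq))


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def _oneway(values: np.ndarray, labels: np.ndarray, name: str) -> AnovaResult:
    groups = [values[labels == c] for c in PAIN_LABELS if np.any(labels == c)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("each group needs >= 2 observations")
    F, p = stats.f_oneway(*groups)
    n = sum(len(g) for g in groups)
    return AnovaResult(name, float(F), len(groups) - 1, n - len(groups),
                       float(p), "oneway")


def _repeated(
    values: np.ndarray, labels: np.ndarray, subjects: np.ndarray, name: str
) -> AnovaResult:
    """Within-subject one-way ANOVA on subject-by-state means.

    Subjects missing a state are dropped.  F = MS_state / MS_interaction
    with df = (s - 1, (s - 1)(n_subj - 1)) for s states.
    """
    df = pd.DataFrame({"v": values, "state": labels, "subj": subjects})
    cell = df.groupby(["subj", "state"], sort=True)["v"].mean().unstack()
    cell = cell.dropna()
    n_subj, n_state = cell.shape
    if n_subj < 2 or n_state < 2:
        raise ValueError("repeated ANOVA needs >= 2 complete subjects and states")
    M = cell.to_numpy()
    grand = M.mean()
    ss_state = n_subj * np.sum((M.mean(axis=0) - grand) ** 2)
    ss_subj = n_state * np.sum((M.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((M - grand) ** 2)
    ss_err = max(ss_total - ss_state - ss_subj, 0.0)
    df1 = n_state - 1
    df2 = (n_state - 1) * (n_subj - 1)
    ms_err = ss_err / df2
    F = (ss_state / df1) / ms_err if ms_err > 0 else np.inf
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return AnovaResult(name, float(F), df1, df2, p, "repeated",
                       dof_subject=n_subj - 1)


def anova_three_states(
    values,
    labels,
    variant: str = "oneway",
    subject_ids=None,
    feature_name: str = "feature",
) -> AnovaResult:
    """Test a feature across the B/LP/HP states.

    ``variant="oneway"`` is the classic between-window one-way ANOVA;
    ``variant="repeated"`` blocks on subject (requires ``subject_ids``)
    and reports ``dof_subject = n_subjects - 1``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if values.shape[0] != labels.shape[0] or values.size == 0:
        raise ValueError("values and labels misaligned or empty")
    if variant == "oneway":
        return _oneway(values, labels, feature_name)
    if variant == "repeated":
        if subject_ids is None:
            raise ValueError("repeated variant requires subject_ids")
        return _repeated(values, labels, np.asarray(subject_ids), feature_name)
    raise ValueError(f"unknown variant {variant!r}")


def _paired_delta_test(day_table: pd.DataFrame, col: str) -> AnovaResult:
    """One-sample t on subject-mean pre/post deltas, reported as F = t^2."""
    per_subj = day_table.groupby("subject")[col].mean().to_numpy()
    if per_subj.size < 3:
        raise ValueError("paired test needs >= 3 subjects")
    t, p = stats.ttest_1samp(per_subj, 0.0)
    return AnovaResult(col, float(t ** 2), 1, per_subj.size - 1, float(p),
                       "paired", dof_subject=per_subj.size - 1)


def add_region_aggregates(
    features: pd.DataFrame, regions: dict[str, str] | None = None
) -> pd.DataFrame:
    """Append per-region mean EEG log-power columns (``eeg.region.<R>``)."""
    from .modalities import DEFAULT_EEG_REGIONS

    regions = regions or DEFAULT_EEG_REGIONS
    out = features.copy()
    by_region: dict[str, list[str]] = {}
    for col in features.columns:
        parts = col.split(".")
        if len(parts) == 3 and parts[0] == "eeg":
            region = regions.get(parts[1])
            if region:
                by_region.setdefault(region, []).append(col)
    for region, cols in sorted(by_region.items()):
        out[f"eeg.region.{region}"] = features[cols].mean(axis=1)
    return out


def significance_screen(
    features: pd.DataFrame,
    columns=None,
    variant: str = "repeated",
    bonferroni: bool = True,
) -> pd.DataFrame:
    """ANOVA table: one row per screened feature column.

    EEG region aggregates are appended automatically when per-channel EEG
    columns are present.  ``bp.*`` delta columns are tested with the
    paired pre/post variant regardless of ``variant``.  Raw p-values are
    primary; a Bonferroni-adjusted column is appended when requested.
    """
    df = add_region_aggregates(features)
    id_cols = {"subject", "day", "window", "vrs", "label"}
    if columns is None:
        columns = [c for c in df.columns if c not in id_cols]
    rows = []
    day_table = df.drop_duplicates(subset=["subject", "day"])
    for col in columns:
        try:
            if col.startswith("bp."):
                res = _paired_delta_test(day_table, col)
            else:
                res = anova_three_states(
                    df[col], df["label"], variant=variant,
                    subject_ids=df["subject"], feature_name=col,
                )
        except ValueError:
            # feature untestable on this cohort (missing states/subjects)
            res = AnovaResult(col, np.nan, 0, 0, np.nan, variant)
        rows.append({
            "feature": res.feature_name, "variant": res.variant,
            "F": res.F, "dof_between": res.dof_between,
            "dof_within": res.dof_within, "dof_subject": res.dof_subject,
            "p": res.p,
        })
    table = pd.DataFrame(rows)
    if bonferroni:
        table["p_bonferroni"] = np.minimum(table["p"] * len(table), 1.0)
    return table
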