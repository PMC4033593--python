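"""Performance metrics, LEA threshold calibration and end-to-end evaluation.

The shockable class is the positive class throughout.  Confidence intervals
use a record-level percentile bootstrap (whole records resampled together)
to respect the clustering of consecutive windows within a record; reports
label the method so the intervals are never mistaken for model-based ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .classifier import (
    SH,
    LEAThresholds,
    ShockAdviceModel,
    Standardizer,
    TrainConfig,
    classify_features,
    classify_segment,
    svm_train,
)
from .features import (
    FEATURE_NAMES,
    SVM_FEATURE_NAMES,
    FeatureConfig,
    WindowFeatures,
    record_window_features,
)
from .cpr_filter import FilterConfig
from .signal_core import SignalRecord


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=bool)
        y_pred = np.asarray(y_pred, dtype=bool)
        return cls(
            tp=int(np.sum(y_true & y_pred)),
            fp=int(np.sum(~y_true & y_pred)),
            tn=int(np.sum(~y_true & ~y_pred)),
            fn=int(np.sum(y_true & ~y_pred)),
        )


def se_sp(counts: ConfusionCounts) -> tuple[float, float]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP)."""
    if counts.tp + counts.fn == 0:
        raise ValueError("no shockable items: sensitivity undefined")
    if counts.tn + counts.fp == 0:
        raise ValueError("no non-shockable items: specificity undefined")
    return counts.tp / (counts.tp + counts.fn), counts.tn / (counts.tn + counts.fp)


def ber(tpr: float, tnr: float) -> float:
    """Balanced error rate: 1 - (TPR + TNR)/2."""
    if not (0 <= tpr <= 1 and 0 <= tnr <= 1):
        raise ValueError("rates must lie in [0, 1]")
    return 1.0 - 0.5 * (tpr + tnr)


def ppv(se: float, sp: float, p_vf: float) -> float:
    """Positive predictive value (%) at a given VF prevalence.

    PPV = 100 * Se*Pvf / (Se*Pvf + (1-Sp)*(1-Pvf)); the probability that a
    shock advice corresponds to a truly shockable rhythm.
    """
    for name, v in (("se", se), ("sp", sp), ("p_vf", p_vf)):
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    denom = se * p_vf + (1.0 - sp) * (1.0 - p_vf)
    if denom <= 0:
        raise ValueError("degenerate denominator: no positive predictions possible")
    return 100.0 * se * p_vf / denom


def auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """ROC area via the Mann-Whitney identity with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)  # midranks for ties -> half credit
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# LEA threshold calibration
# ---------------------------------------------------------------------------


def _candidates(values: np.ndarray) -> np.ndarray:
    """Unique observed values plus midpoints, with 0 as the detect-nothing point."""
    u = np.unique(values)
    mids = (u[:-1] + u[1:]) / 2.0 if u.size > 1 else np.empty(0)
    return np.unique(np.concatenate([[0.0], u, mids]))


def calibrate_lea(
    p_lea: np.ndarray,
    l_min: np.ndarray,
    shockable: np.ndarray,
    max_shockable_loss: float = 0.05,
) -> LEAThresholds:
    """Exhaustive threshold search maximizing detected low-activity windows.

    A window is detected when p_lea < p_lea_max OR l_min < l_min_max.  Among
    threshold pairs losing at most ``max_shockable_loss`` of the shockable
    windows, the pair detecting the most non-shockable (ASY) windows wins;
    ties go to fewer shockable losses, then smaller thresholds.  If even the
    detect-nothing point is infeasible (impossible with a 0 candidate), the
    degenerate all-pass thresholds are returned with a warning flag.
    """
    p_lea = np.asarray(p_lea, dtype=float)
    l_min = np.asarray(l_min, dtype=float)
    shockable = np.asarray(shockable, dtype=bool)
    if not shockable.any() or shockable.all():
        raise ValueError("calibration needs both shockable and low-activity windows")

    cand_p = _candidates(p_lea)
    cand_l = _candidates(l_min)

    def or_counts(p_vals: np.ndarray, l_vals: np.ndarray) -> np.ndarray:
        """#(p < a or l < b) for every candidate pair (a, b)."""
        # joint cumulative counts of (p < a and l < b) on the candidate grid
        gi = np.searchsorted(cand_p, p_vals, side="right") - 1
        gj = np.searchsorted(cand_l, l_vals, side="right") - 1
        grid = np.zeros((cand_p.size + 1, cand_l.size + 1))
        np.add.at(grid, (gi + 1, gj + 1), 1.0)
        cum = grid.cumsum(axis=0).cumsum(axis=1)
        joint = cum[:-1, :-1]  # joint[i, j] = #(p < cand_p[i] and l < cand_l[j])
        mp = np.searchsorted(np.sort(p_vals), cand_p, side="left")
        ml = np.searchsorted(np.sort(l_vals), cand_l, side="left")
        return mp[:, None] + ml[None, :] - joint

    asy_detected = or_counts(p_lea[~shockable], l_min[~shockable])
    sh_lost = or_counts(p_lea[shockable], l_min[shockable])
    n_sh = int(shockable.sum())

    feasible = sh_lost <= max_shockable_loss * n_sh + 1e-9
    if not feasible.any():
        return LEAThresholds(p_lea_max=0.0, l_min_max=0.0, degenerate_all_pass=True)

    score = np.where(feasible, asy_detected, -1)
    best = score.max()
    ii, jj = np.nonzero(score == best)
    # ties: fewer shockable losses, then smaller thresholds (p first, then l)
    order = np.lexsort((cand_l[jj], cand_p[ii], sh_lost[ii, jj]))
    i, j = ii[order[0]], jj[order[0]]
    a, b = float(cand_p[i]), float(cand_l[j])
    if a <= 0 and b <= 0:
        return LEAThresholds(p_lea_max=0.0, l_min_max=0.0, degenerate_all_pass=True)
    return LEAThresholds(p_lea_max=a, l_min_max=b)


# ---------------------------------------------------------------------------
# Cluster-aware confidence intervals
# ---------------------------------------------------------------------------


def cluster_ci(
    record_ids: Sequence,
    y_true: Sequence[bool],
    y_pred: Sequence[bool],
    level: float = 0.90,
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict:
    """Record-level percentile bootstrap lower bounds for Se and Sp.

    Whole records are resampled with replacement so within-record correlation
    of consecutive windows is respected; replicates missing a class are
    dropped from that rate's distribution.  Returns point estimates and the
    one-sided lower bounds at ``level``.
    """
    record_ids = np.asarray(record_ids)
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    uniq = np.unique(record_ids)
    if uniq.size < 2:
        raise ValueError("cluster bootstrap needs at least 2 records")
    rng = np.random.default_rng(seed)

    groups = [(y_true[record_ids == r], y_pred[record_ids == r]) for r in uniq]
    tp = np.array([np.sum(t & p) for t, p in groups], dtype=float)
    fn = np.array([np.sum(t & ~p) for t, p in groups], dtype=float)
    tn = np.array([np.sum(~t & ~p) for t, p in groups], dtype=float)
    fp = np.array([np.sum(~t & p) for t, p in groups], dtype=float)

    counts = ConfusionCounts.from_predictions(y_true, y_pred)
    se_pt, sp_pt = se_sp(counts)

    idx = rng.integers(0, uniq.size, size=(n_boot, uniq.size))
    tp_b, fn_b = tp[idx].sum(axis=1), fn[idx].sum(axis=1)
    tn_b, fp_b = tn[idx].sum(axis=1), fp[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        se_b = np.where(tp_b + fn_b > 0, tp_b / (tp_b + fn_b), np.nan)
        sp_b = np.where(tn_b + fp_b > 0, tn_b / (tn_b + fp_b), np.nan)
    q = 100.0 * (1.0 - level)
    return {
        "method": "record-level percentile bootstrap",
        "level": level,
        "n_boot": n_boot,
        "se": se_pt,
        "sp": sp_pt,
        "se_lower": float(np.nanpercentile(se_b, q)),
        "sp_lower": float(np.nanpercentile(sp_b, q)),
    }


# ---------------------------------------------------------------------------
# End-to-end training and evaluation
# ---------------------------------------------------------------------------


def build_feature_table(
    records: Sequence[SignalRecord],
    filter_config: FilterConfig | None = None,
    feature_config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Filter every record and compute the six features for each 3-s window."""
    tables = [record_window_features(r, filter_config, feature_config) for r in records]
    return pd.concat(tables, ignore_index=True)


def train_shock_advice(
    table: pd.DataFrame,
    train_config: TrainConfig | None = None,
    feature_config: FeatureConfig | None = None,
    filter_config: FilterConfig | None = None,
    max_shockable_loss: float = 0.05,
):
    """Train the full shock-advice algorithm from a window feature table.

    Stage 1 calibrates the LEA thresholds on asystole vs shockable windows.
    Stage 2 trains the class-weighted Gaussian SVM on the shockable and
    organized windows that pass the LEA gate, with record-grouped stratified
    cross-validation for the (C, gamma) grid search.
    """
    cfg = train_config or TrainConfig()
    asy_or_sh = table[(table.rhythm_label == "ASY") | table.shockable]
    lea = calibrate_lea(
        asy_or_sh.p_lea.to_numpy(),
        asy_or_sh.l_min.to_numpy(),
        asy_or_sh.shockable.to_numpy(),
        max_shockable_loss=max_shockable_loss,
    )

    passed = ~(
        (table.p_lea.to_numpy() < lea.p_lea_max) | (table.l_min.to_numpy() < lea.l_min_max)
    )
    svm_rows = table[passed & (table.shockable | (table.rhythm_label == "ORG"))]
    X_raw = svm_rows[list(SVM_FEATURE_NAMES)].to_numpy(dtype=float)
    y = np.where(svm_rows.shockable.to_numpy(), 1, -1)
    stats = Standardizer.fit(X_raw, SVM_FEATURE_NAMES)
    model, report = svm_train(
        stats.transform(X_raw),
        y,
        cfg,
        groups=svm_rows.record_id.to_numpy(),
        standardizer=stats,
    )
    saa = ShockAdviceModel(
        lea=lea,
        svm=model,
        feature_config=feature_config or FeatureConfig(),
        filter_config=filter_config or FilterConfig(),
    )
    return saa, report


def diagnose_table(table: pd.DataFrame, saa: ShockAdviceModel) -> pd.DataFrame:
    """Window and segment decisions for a feature table."""
    out = table.copy()
    diagnoses = [
        classify_features(
            WindowFeatures(
                p_lea=row.p_lea, l_min=row.l_min, bS=row.bS, nP=int(row.nP),
                p_fib=row.p_fib, p_h=row.p_h,
            ),
            saa.lea,
            saa.svm,
        )
        for row in table.itertuples()
    ]
    out["decision"] = [d.decision for d in diagnoses]
    out["stage"] = [d.stage for d in diagnoses]
    out["discriminant"] = [d.discriminant for d in diagnoses]
    seg_dec = (
        out.groupby(["record_id", "segment"], sort=False)
        .decision.apply(lambda s: classify_segment(
            [_as_diag(d) for d in s]
        ))
        .rename("segment_decision")
    )
    out = out.merge(seg_dec, on=["record_id", "segment"])
    return out


def _as_diag(decision: str):
    from .classifier import Diagnosis

    return Diagnosis(decision=decision, stage="SVM" if decision == SH else "LEA")


@dataclass
class MetricReport:
    """Window- and segment-level accuracy with per-rhythm breakdown."""

    window_counts: ConfusionCounts
    segment_counts: ConfusionCounts
    window_se: float
    window_sp: float
    segment_se: float
    segment_sp: float
    ber_segments: float
    per_class: dict = field(default_factory=dict)
    ci: Optional[dict] = None

    def to_json(self) -> dict:
        return {
            "window": {
                "counts": vars(self.window_counts),
                "se": self.window_se,
                "sp": self.window_sp,
            },
            "segment": {
                "counts": vars(self.segment_counts),
                "se": self.segment_se,
                "sp": self.segment_sp,
                "ber": self.ber_segments,
            },
            "per_class": self.per_class,
            "ci": self.ci,
        }


def evaluate_records(
    records: Sequence[SignalRecord],
    saa: ShockAdviceModel,
    ci_seed: Optional[int] = None,
    ci_reps: int = 10_000,
) -> MetricReport:
    """Run the full pipeline on a corpus and report Se/Sp at both scales."""
    table = build_feature_table(records, saa.filter_config, saa.feature_config)
    return evaluate_table(table, saa, ci_seed=ci_seed, ci_reps=ci_reps)


def evaluate_table(
    table: pd.DataFrame,
    saa: ShockAdviceModel,
    ci_seed: Optional[int] = None,
    ci_reps: int = 10_000,
) -> MetricReport:
    diag = diagnose_table(table, saa)
    w_true = diag.shockable.to_numpy(dtype=bool)
    w_pred = diag.decision.to_numpy() == SH
    wc = ConfusionCounts.from_predictions(w_true, w_pred)
    w_se, w_sp = se_sp(wc)

    seg = diag.drop_duplicates(["record_id", "segment"])
    s_true = seg.shockable.to_numpy(dtype=bool)
    s_pred = seg.segment_decision.to_numpy() == SH
    sc = ConfusionCounts.from_predictions(s_true, s_pred)
    s_se, s_sp = se_sp(sc)

    per_class = {}
    for label, sub in seg.groupby("rhythm_label"):
        correct = (sub.segment_decision == SH) == sub.shockable
        per_class[label] = {
            "n_segments": int(len(sub)),
            "accuracy": float(correct.mean()),
        }

    ci = None
    if ci_seed is not None:
        ci = cluster_ci(
            seg.record_id.to_numpy(), s_true, s_pred, n_boot=ci_reps, seed=ci_seed
        )

    return MetricReport(
        window_counts=wc,
        segment_counts=sc,
        window_se=w_se,
        window_sp=w_sp,
        segment_se=s_se,
        segment_sp=s_sp,
        ber_segments=ber(s_se, s_sp),
        per_class=per_class,
        ci=ci,
    )
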