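"""Shock-advice algorithm: LEA gate, Gaussian-kernel SVM, and decision logic.

The algorithm is sequential.  A low-electrical-activity (LEA) detector first
marks windows whose high-passed energy or minimum curve length falls under
fixed thresholds as non-shockable; only the remaining windows reach the SVM,
which classifies on the four standardized slope/spectral features.  Segment
decisions combine three consecutive window decisions by majority vote.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureConfig, WindowFeatures, window_features
from .cpr_filter import FilterConfig

SH = "Sh"
NSH = "NSh"


@dataclass
class LEAThresholds:
    """Detection thresholds on the two low-electrical-activity features.

    Defaults are the operating point calibrated for ECG amplitudes in mV;
    they are replaced by :func:`cprrhythm.evaluation.calibrate_lea` when a
    training corpus is available.
    """

    p_lea_max: float = 0.44
    l_min_max: float = 0.63
    degenerate_all_pass: bool = False

    def __post_init__(self) -> None:
        # a zero threshold disables that branch (features are non-negative,
        # and the comparison is strict); negative thresholds are nonsense
        if self.p_lea_max < 0 or self.l_min_max < 0:
            raise ValueError("LEA thresholds must be non-negative")


def lea_detect(features: WindowFeatures, thresholds: LEAThresholds) -> bool:
    """True iff the window shows low electrical activity (either feature low)."""
    return features.p_lea < thresholds.p_lea_max or features.l_min < thresholds.l_min_max


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


@dataclass
class Standardizer:
    """Zero-mean unit-variance scaling with training-set statistics.

    Uses the population (divide-by-n) standard deviation so a two-point
    training column {1, 3} maps exactly to {-1, +1}.
    """

    mean: np.ndarray
    sd: np.ndarray
    feature_names: tuple[str, ...] = ()

    @classmethod
    def fit(cls, X: np.ndarray, feature_names: Sequence[str] = ()) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        sd = X.std(axis=0)  # population convention
        for j, s in enumerate(sd):
            if s <= 0:
                name = feature_names[j] if j < len(feature_names) else f"feature {j}"
                raise ValueError(f"zero-variance feature {name!r} cannot be standardized")
        return cls(mean=mean, sd=sd, feature_names=tuple(feature_names))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.sd + self.mean


def standardize(X: np.ndarray, stats: Standardizer) -> np.ndarray:
    return stats.transform(X)


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------


@dataclass
class SVMModel:
    """Frozen Gaussian-kernel SVM: everything needed to evaluate f(x).

    f(x) = sum_i alpha_i y_i exp(-gamma ||x - x_i||^2) + b, shockable iff
    f(x) > 0.  ``dual_weights`` holds the products alpha_i*y_i.
    """

    support_vectors: np.ndarray  # (N_s, 4), standardized space
    dual_weights: np.ndarray  # (N_s,)
    bias: float
    gamma: float
    C: float
    standardizer: Standardizer

    def __post_init__(self) -> None:
        self.support_vectors = np.asarray(self.support_vectors, dtype=float)
        self.dual_weights = np.asarray(self.dual_weights, dtype=float)
        if self.support_vectors.shape[0] < 1:
            raise ValueError("model needs at least one support vector")
        if not (self.gamma > 0):
            raise ValueError("kernel width gamma must be positive")

    @property
    def n_support(self) -> int:
        return self.support_vectors.shape[0]

    def decision_value(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.support_vectors.shape[1],):
            raise ValueError(
                f"feature vector has shape {x.shape}, expected "
                f"({self.support_vectors.shape[1]},)"
            )
        d2 = np.sum((self.support_vectors - x) ** 2, axis=1)
        # exact summation so symmetric contributions cancel to a true zero
        terms = self.dual_weights * np.exp(-self.gamma * d2)
        return math.fsum(terms) + self.bias

    def to_json(self) -> dict:
        return {
            "format": "cprrhythm-svm-v1",
            "support_vectors": self.support_vectors.tolist(),
            "dual_weights": self.dual_weights.tolist(),
            "bias": self.bias,
            "gamma": self.gamma,
            "C": self.C,
            "standardizer": {
                "mean": self.standardizer.mean.tolist(),
                "sd": self.standardizer.sd.tolist(),
                "feature_names": list(self.standardizer.feature_names),
            },
        }

    @classmethod
    def from_json(cls, doc: dict) -> "SVMModel":
        st = doc["standardizer"]
        return cls(
            support_vectors=np.array(doc["support_vectors"]),
            dual_weights=np.array(doc["dual_weights"]),
            bias=float(doc["bias"]),
            gamma=float(doc["gamma"]),
            C=float(doc["C"]),
            standardizer=Standardizer(
                mean=np.array(st["mean"]),
                sd=np.array(st["sd"]),
                feature_names=tuple(st["feature_names"]),
            ),
        )


@dataclass
class Diagnosis:
    """Window decision with provenance: which stage produced it."""

    decision: str  # "Sh" / "NSh"
    stage: str  # "LEA" / "SVM"
    discriminant: Optional[float] = None  # f(x) when stage == "SVM"

    def __post_init__(self) -> None:
        if self.stage == "LEA" and self.decision != NSH:
            raise ValueError("the LEA stage only issues no-shock decisions")


def svm_decide(model: SVMModel, x: np.ndarray) -> Diagnosis:
    """Evaluate the discriminant on a standardized 4-vector; Sh iff f(x) > 0."""
    f = model.decision_value(x)
    return Diagnosis(decision=SH if f > 0 else NSH, stage="SVM", discriminant=f)


def _default_grid(base: float, lo: int, hi: int) -> tuple[float, ...]:
    return tuple(float(base) ** k for k in range(lo, hi + 1))


@dataclass
class TrainConfig:
    """Grid-search setup for the class-weighted SVM.

    The default log-spaced grids bracket typical operating points for this
    problem (C around 10, gamma around 0.1 on standardized features).  Class
    weights default to inverse class frequency normalized to mean one.
    """

    c_grid: tuple[float, ...] = _default_grid(2.0, -2, 6)
    gamma_grid: tuple[float, ...] = _default_grid(2.0, -6, 2)
    folds: int = 5
    class_weights: Optional[dict] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("parameter grids must be non-empty")
        if self.folds < 2:
            raise ValueError("cross-validation needs at least 2 folds")


@dataclass
class CVReport:
    ber_grid: np.ndarray  # (len(c_grid), len(gamma_grid))
    c_grid: tuple[float, ...]
    gamma_grid: tuple[float, ...]
    best_c: float
    best_gamma: float
    best_ber: float


def _fold_ber(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    pos = y_true == 1
    tpr = np.mean(y_pred[pos] == 1) if pos.any() else np.nan
    tnr = np.mean(y_pred[~pos] == -1) if (~pos).any() else np.nan
    return 1.0 - 0.5 * (tpr + tnr)


def _class_weights(y: np.ndarray, override: Optional[dict]) -> dict:
    if override is not None:
        return dict(override)
    classes, counts = np.unique(y, return_counts=True)
    inv = len(y) / (len(classes) * counts)  # inverse frequency, mean ~1
    return {int(c): float(w) for c, w in zip(classes, inv)}

def svm_train(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
    groups: Optional[np.ndarray] = None,
    standardizer: Optional[Standardizer] = None,
) -> tuple[SVMModel, CVReport]:
    """Grid-search a class-weighted Gaussian SVM by cross-validated BER.

    ``X`` must already be standardized (pass the fitted :class:`Standardizer`
    so the returned model can transform raw features).  ``y`` uses +1 for
    shockable, -1 for non-shockable.  Folds are stratified by class and, when
    ``groups`` (record identifiers) are given, grouped so one record never
    straddles folds.  The balanced error rate is averaged over folds and ties
    are broken toward smaller C, then smaller gamma.
    """
    cfg = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")
    if not set(classes) <= {-1, 1}:
        raise ValueError("labels must be +1 (shockable) / -1 (non-shockable)")
    weights = _class_weights(y, cfg.class_weights)

    # cap the fold count by what the data can support (small corpora)
    min_class = int(np.unique(y, return_counts=True)[1].min())
    if groups is not None:
        n_groups = min(
            len(np.unique(np.asarray(groups)[y == c])) for c in classes
        )
        n_splits = min(cfg.folds, n_groups, min_class)
    else:
        n_splits = min(cfg.folds, min_class)
    if n_splits >= 2 and groups is not None:
        splitter = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=cfg.seed)
        splits = list(splitter.split(X, y, groups))
    elif n_splits >= 2:
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=cfg.seed)
        splits = list(splitter.split(X, y))
    else:
        splits = [(np.arange(len(y)), np.arange(len(y)))]  # degenerate resubstitution

    ber_grid = np.full((len(cfg.c_grid), len(cfg.gamma_grid)), np.nan)
    best = None  # (ber, C, gamma)
    for ic, c_val in enumerate(sorted(cfg.c_grid)):
        for ig, g_val in enumerate(sorted(cfg.gamma_grid)):
            fold_bers = []
            for tr, te in splits:
                if np.unique(y[tr]).size < 2:
                    fold_bers.append(np.nan)
                    continue
                clf = SVC(kernel="rbf", C=c_val, gamma=g_val, class_weight=weights)
                clf.fit(X[tr], y[tr])
                fold_bers.append(_fold_ber(y[te], clf.predict(X[te])))
            ber = float(np.nanmean(fold_bers))
            ber_grid[ic, ig] = ber
            if best is None or ber < best[0] - 1e-12:
                best = (ber, c_val, g_val)
    assert best is not None
    _, best_c, best_gamma = best

    final = SVC(kernel="rbf", C=best_c, gamma=best_gamma, class_weight=weights)
    final.fit(X, y)
    # sklearn's dual_coef_ already stores alpha_i * y_i for the binary case
    model = SVMModel(
        support_vectors=final.support_vectors_,
        dual_weights=final.dual_coef_.ravel(),
        bias=float(final.intercept_[0]),
        gamma=best_gamma,
        C=best_c,
        standardizer=standardizer
        if standardizer is not None
        else Standardizer(mean=np.zeros(X.shape[1]), sd=np.ones(X.shape[1])),
    )
    report = CVReport(
        ber_grid=ber_grid,
        c_grid=tuple(sorted(cfg.c_grid)),
        gamma_grid=tuple(sorted(cfg.gamma_grid)),
        best_c=best_c,
        best_gamma=best_gamma,
        best_ber=best[0],
    )
    return model, report


# ---------------------------------------------------------------------------
# Window / segment decisions
# ---------------------------------------------------------------------------


@dataclass
class ShockAdviceModel:
    """The complete trained shock-advice algorithm, JSON-serializable."""

    lea: LEAThresholds
    svm: SVMModel
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    filter_config: FilterConfig = field(default_factory=FilterConfig)

    def save(self, path: str | Path) -> None:
        doc = {
            "format": "cprrhythm-saa-v1",
            "lea": {
                "p_lea_max": self.lea.p_lea_max,
                "l_min_max": self.lea.l_min_max,
                "degenerate_all_pass": self.lea.degenerate_all_pass,
            },
            "svm": self.svm.to_json(),
            "feature_config": {
                "lea_highpass_cutoff": self.feature_config.lea_highpass_cutoff,
                "slope_window_ms": self.feature_config.slope_window_ms,
                "peak_threshold": self.feature_config.peak_threshold,
                "fib_band": list(self.feature_config.fib_band),
                "high_band_low_edge": self.feature_config.high_band_low_edge,
                "high_band_high_edge": self.feature_config.high_band_high_edge,
                "fft_len": self.feature_config.fft_len,
            },
            "filter_config": {
                "n_harmonics": self.filter_config.n_harmonics,
                "step_size": self.filter_config.step_size,
                "leakage": self.filter_config.leakage,
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ShockAdviceModel":
        doc = json.loads(Path(path).read_text())
        fc = doc["feature_config"]
        return cls(
            lea=LEAThresholds(
                p_lea_max=doc["lea"]["p_lea_max"],
                l_min_max=doc["lea"]["l_min_max"],
                degenerate_all_pass=doc["lea"].get("degenerate_all_pass", False),
            ),
            svm=SVMModel.from_json(doc["svm"]),
            feature_config=FeatureConfig(
                lea_highpass_cutoff=fc["lea_highpass_cutoff"],
                slope_window_ms=fc["slope_window_ms"],
                peak_threshold=fc["peak_threshold"],
                fib_band=tuple(fc["fib_band"]),
                high_band_low_edge=fc["high_band_low_edge"],
                high_band_high_edge=fc["high_band_high_edge"],
                fft_len=fc["fft_len"],
            ),
            filter_config=FilterConfig(
                n_harmonics=doc["filter_config"]["n_harmonics"],
                step_size=doc["filter_config"]["step_size"],
                leakage=doc["filter_config"].get("leakage", 0.0),
            ),
        )


def classify_features(
    feats: WindowFeatures, lea: LEAThresholds, model: SVMModel
) -> Diagnosis:
    """Sequential decision on precomputed features: LEA gate, then SVM."""
    if not lea.degenerate_all_pass and lea_detect(feats, lea):
        return Diagnosis(decision=NSH, stage="LEA")
    x = model.standardizer.transform(feats.svm_vector())
    return svm_decide(model, x)


def classify_window(
    window: np.ndarray,
    lea: LEAThresholds,
    model: SVMModel,
    config: FeatureConfig | None = None,
) -> Diagnosis:
    """Diagnose one filtered 3-s window: LEA gate first, SVM only if it passes."""
    feats = window_features(window, config)
    return classify_features(feats, lea, model)


def classify_segment(diagnoses: Sequence[Diagnosis]) -> str:
    """Majority vote over exactly three consecutive window decisions."""
    if len(diagnoses) != 3:
        raise ValueError(f"a segment holds exactly 3 window diagnoses, got {len(diagnoses)}")
    n_sh = sum(d.decision == SH for d in diagnoses)
    return SH if n_sh >= 2 else NSH
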