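"""SVM decoding of reward-seeking strategy (RR vs RI) from peri-event
Ca²⁺ features.

Protocol: per-event features (mean ΔF/F over the pre- and post-event
windows by default), class balancing by random undersampling of the
majority class repeated ``n_resamples`` times (400 by default), 4-fold
stratified cross-validation per resample with a linear maximum-margin
classifier (C = 1, features standardized on training folds only),
held-out decision values pooled into one ROC/AUC and one confusion
table per resample, and metrics averaged over resamples.  Chance-level
comparisons use two-tailed one-sample t tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .perievent import PeriEventMatrix

#: label treated as the positive class in ROC/confusion accounting
POSITIVE_LABEL = "RI"


@dataclass
class FeatureTable:
    """One row per behavioral event; binary condition labels."""

    X: np.ndarray            # (n_trials, n_features), finite
    y: np.ndarray            # condition labels, two distinct values
    event_class: str
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be 2-D with one row per label")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features contain NaN/inf")
        if len(np.unique(self.y)) != 2:
            raise ValueError("labels must take exactly two values")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class DecodingResult:
    """Per-resample metrics plus the vertically averaged ROC curve."""

    auc: np.ndarray
    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    event_class: str
    n_per_class: int
    pos_label: str

    @property
    def n_resamples(self) -> int:
        return len(self.auc)

    def summary(self) -> dict:
        out = {}
        for name in ("auc", "accuracy", "sensitivity", "specificity"):
            v = getattr(self, name)
            out[f"mean_{name}"] = float(np.mean(v))
            out[f"sd_{name}"] = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        out["n_resamples"] = self.n_resamples
        out["n_per_class"] = self.n_per_class
        return out


def build_features(pem_rr: PeriEventMatrix, pem_ri: PeriEventMatrix,
                   event_class: str,
                   input_range: tuple[float, float] = (-2.0, 2.0),
                   per_frame: bool = False) -> FeatureTable:
    """Feature table for one event class (or family: 'NP', 'M_entry', ...).

    Default features are the mean ΔF/F over the pre-event part
    [input_range[0], 0) and the post-event part [0, input_range[1]) of
    the snippet; ``per_frame=True`` keeps the raw frame vector over the
    input range instead.
    """
    lo_s, hi_s = input_range
    if not lo_s < hi_s:
        raise ValueError("input_range must be increasing")
    blocks, labels = [], []
    for cond, pem in (("RR", pem_rr), ("RI", pem_ri)):
        sub = pem.subset(event_class)
        if sub.n_events == 0:
            raise ValueError(f"class {event_class!r} absent in {cond} data")
        e = sub.event_frame
        lo = e + int(round(lo_s * sub.fps))
        hi = e + int(round(hi_s * sub.fps))
        if lo < 0 or hi > sub.n_frames:
            raise ValueError("input_range exceeds the peri-event window")
        if per_frame:
            feats = sub.snippets[:, lo:hi]
        else:
            cols = []
            if lo < e:
                cols.append(sub.snippets[:, lo:e].mean(axis=1))
            if hi > e:
                cols.append(sub.snippets[:, e:hi].mean(axis=1))
            feats = np.column_stack(cols)
        blocks.append(feats)
        labels.append(np.full(sub.n_events, cond))
    if per_frame:
        names = [f"frame_{i}" for i in range(blocks[0].shape[1])]
    else:
        names = (["pre_mean"] if lo_s < 0 else []) + \
                (["post_mean"] if hi_s > 0 else [])
    return FeatureTable(X=np.vstack(blocks), y=np.concatenate(labels),
                        event_class=event_class, feature_names=names)


def run_svm_protocol(ft: FeatureTable, k: int = 4, n_resamples: int = 400,
                     seed: int | None = None, C: float = 1.0,
                     fpr_grid_points: int = 101,
                     permute_labels: bool = False) -> DecodingResult:
    """Balanced-undersampling SVM protocol with stratified k-fold CV.

    Each of the ``n_resamples`` repeats draws a fresh balanced subsample
    (majority class undersampled without replacement) and a fresh fold
    assignment; held-out decision values are pooled into one ROC/AUC and
    one confusion table (decision threshold 0) per repeat.

    ``permute_labels=True`` shuffles the labels of every resample's
    subsample independently, giving the empirical chance distribution
    the observed metrics are compared against.
    """
    labels = np.unique(ft.y)
    pos = POSITIVE_LABEL if POSITIVE_LABEL in labels else labels[1]
    idx_pos = np.flatnonzero(ft.y == pos)
    idx_neg = np.flatnonzero(ft.y != pos)
    m = min(len(idx_pos), len(idx_neg))
    if m < k:
        raise ValueError(
            f"insufficient trials: smallest class has {m} < k={k}")

    state = np.random.SeedSequence(seed).generate_state(2 * n_resamples)
    grid = np.linspace(0.0, 1.0, fpr_grid_points)
    auc = np.empty(n_resamples)
    acc = np.empty(n_resamples)
    sen = np.empty(n_resamples)
    spe = np.empty(n_resamples)
    tprs = np.empty((n_resamples, fpr_grid_points))

    for r in range(n_resamples):
        rng = np.random.default_rng(state[2 * r])
        sel = np.concatenate([
            rng.choice(idx_pos, m, replace=False) if len(idx_pos) > m else idx_pos,
            rng.choice(idx_neg, m, replace=False) if len(idx_neg) > m else idx_neg,
        ])
        X = ft.X[sel]
        ybin = (ft.y[sel] == pos).astype(int)
        if permute_labels:
            ybin = rng.permutation(ybin)

        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(state[2 * r + 1] % (2 ** 31)))
        scores = np.empty(len(sel))
        for train, test in skf.split(X, ybin):
            scaler = StandardScaler().fit(X[train])
            clf = SVC(kernel="linear", C=C)
            clf.fit(scaler.transform(X[train]), ybin[train])
            scores[test] = clf.decision_function(scaler.transform(X[test]))

        auc[r] = roc_auc_score(ybin, scores)
        fpr, tpr, _ = roc_curve(ybin, scores)
        tprs[r] = np.interp(grid, fpr, tpr)
        tprs[r, 0] = 0.0
        pred = scores >= 0.0
        c = ConfusionCounts(
            tp=int(np.sum(pred & (ybin == 1))),
            tn=int(np.sum(~pred & (ybin == 0))),
            fp=int(np.sum(pred & (ybin == 0))),
            fn=int(np.sum(~pred & (ybin == 1))))
        mtr = metrics_from_confusion(c)
        acc[r] = mtr["accuracy"]
        sen[r] = mtr["sensitivity"]
        spe[r] = mtr["specificity"]

    return DecodingResult(auc=auc, accuracy=acc, sensitivity=sen,
                          specificity=spe, fpr_grid=grid,
                          mean_tpr=tprs.mean(axis=0),
                          event_class=ft.event_class, n_per_class=m,
                          pos_label=str(pos))


def metrics_from_confusion(c: ConfusionCounts) -> dict:
    """accuracy = (tn+tp)/total, sensitivity = tp/(tp+fn),
    specificity = tn/(tn+fp); NaN (with a warning) on zero denominators."""
    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name}: zero denominator, returning NaN",
                          RuntimeWarning, stacklevel=3)
            return float("nan")
        return num / den

    return {
        "accuracy": _ratio(c.tn + c.tp, c.total, "accuracy"),
        "sensitivity": _ratio(c.tp, c.tp + c.fn, "sensitivity"),
        "specificity": _ratio(c.tn, c.tn + c.fp, "specificity"),
    }


def compare_to_chance(values: np.ndarray, chance: float = 0.5) -> dict:
    """Two-tailed one-sample t test of per-resample metrics vs chance."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    if np.all(v == v[0]):
        raise ValueError("zero variance: t statistic undefined")
    t, p = stats.ttest_1samp(v, chance)
    return {"t": float(t), "p": float(p), "mean": float(v.mean()),
            "chance": chance, "n": len(v)}
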