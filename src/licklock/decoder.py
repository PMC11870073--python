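"""Gradient-boosted-tree decoding of licking from Purkinje-cell activity.

The session is cut into 200 ms snippets sharing a 10 ms overlap (stride
190 ms). Each snippet carries three features — simple-spike frequency,
simple-spike CV2 (local coefficient of variation of inter-spike intervals,
2|ISI_{n+1} - ISI_n| / (ISI_{n+1} + ISI_n)) and complex-spike frequency —
and a lick / no-lick label. A balanced training set draws two thirds of the
smaller class from each class; the remainder forms the test set. An XGBoost
classifier (default 4096 estimators, depth 8, histogram split finding)
reports per-class test accuracies; a cell is *predictive* when both exceed
55% and *strongly predictive* when both exceed 65%. Feature attribution is
the mean absolute per-snippet Shapley value (TreeSHAP via XGBoost's
``pred_contribs``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import xgboost as xgb

from .core_io import CellRecording, LickTrain

WINDOW_S = 0.200
OVERLAP_S = 0.010
STRIDE_S = WINDOW_S - OVERLAP_S
TRAIN_FRACTION = 2.0 / 3.0
FEATURE_NAMES = ("ss_rate", "ss_cv2", "cs_rate")
DEFAULT_MODEL_PARAMS = dict(n_estimators=4096, max_depth=8, tree_method="hist")


def cv2_series(isis: np.ndarray) -> np.ndarray:
    """CV2 per adjacent ISI pair: 2|ISI_{n+1} - ISI_n| / (ISI_{n+1} + ISI_n).

    Zero for a regular train, expectation 1 for a Poisson train; each value
    lies in [0, 2). Fewer than two ISIs yield an empty series.
    """
    isis = np.asarray(isis, dtype=float)
    if isis.size < 2:
        return np.empty(0)
    if np.any(isis <= 0):
        raise ValueError("ISIs must be positive")
    a, b = isis[:-1], isis[1:]
    return 2.0 * np.abs(b - a) / (b + a)


@dataclass
class FeatureWindow:
    """One 200 ms snippet's feature triple and label."""

    t_start: float
    t_end: float
    ss_rate: float
    ss_cv2: float
    cs_rate: float
    label: int  # 1 = lick (>= 1 detection inside), 0 = no lick
    cv2_imputed: bool = False


def extract_windows(
    licks: LickTrain,
    cell: CellRecording,
    window: float = WINDOW_S,
    overlap: float = OVERLAP_S,
    impute_cv2: bool = True,
) -> list[FeatureWindow]:
    """Tile the session into overlapping snippets with features and labels.

    Windows start at t = 0 with stride ``window - overlap``; events count
    when they fall in [t_start, t_end). A CV2 value belongs to the window
    containing the middle spike of its ISI pair; windows with fewer than
    3 SS have no own CV2 and get the cell's median in-class CV2 imputed
    (flagged), keeping class balance intact.
    """
    stride = window - overlap
    duration = licks.session_duration
    n_win = int(np.floor((duration - window) / stride)) + 1
    if n_win < 2:
        raise ValueError("session too short for two windows")
    t0 = stride * np.arange(n_win)
    t1 = t0 + window
    ss, cs, lt = cell.ss_times, cell.cs_times, licks.detect_times
    ss_counts = np.searchsorted(ss, t1, side="left") - np.searchsorted(ss, t0, side="left")
    cs_counts = np.searchsorted(cs, t1, side="left") - np.searchsorted(cs, t0, side="left")
    lick_counts = np.searchsorted(lt, t1, side="left") - np.searchsorted(lt, t0, side="left")
    labels = (lick_counts > 0).astype(int)
    # CV2 values keyed by the middle spike of each ISI pair
    cv2_vals = cv2_series(np.diff(ss)) if ss.size >= 3 else np.empty(0)
    cv2_times = ss[1:-1] if ss.size >= 3 else np.empty(0)
    cv2_sum = np.zeros(n_win)
    cv2_n = np.zeros(n_win)
    if cv2_vals.size:
        lo = np.searchsorted(cv2_times, t0, side="left")
        hi = np.searchsorted(cv2_times, t1, side="left")
        csum = np.concatenate(([0.0], np.cumsum(cv2_vals)))
        cv2_sum = csum[hi] - csum[lo]
        cv2_n = (hi - lo).astype(float)
    with np.errstate(invalid="ignore"):
        cv2_mean = cv2_sum / cv2_n
    undefined = cv2_n == 0
    out: list[FeatureWindow] = []
    if impute_cv2 and undefined.any():
        medians = {}
        for lab in (0, 1):
            vals = cv2_mean[(labels == lab) & ~undefined]
            medians[lab] = float(np.median(vals)) if vals.size else 1.0
    for i in range(n_win):
        imputed = bool(undefined[i])
        c = cv2_mean[i]
        if imputed:
            if not impute_cv2:
                continue
            c = medians[labels[i]]
        out.append(
            FeatureWindow(
                t_start=float(t0[i]),
                t_end=float(t1[i]),
                ss_rate=float(ss_counts[i] / window),
                ss_cv2=float(c),
                cs_rate=float(cs_counts[i] / window),
                label=int(labels[i]),
                cv2_imputed=imputed,
            )
        )
    return out


def windows_to_arrays(windows: Sequence[FeatureWindow]) -> tuple[np.ndarray, np.ndarray]:
    """(n, 3) feature matrix in FEATURE_NAMES order and the label vector."""
    X = np.array([[w.ss_rate, w.ss_cv2, w.cs_rate] for w in windows])
    y = np.array([w.label for w in windows])
    return X, y


def balanced_split(
    windows: Sequence[FeatureWindow],
    frac: float = TRAIN_FRACTION,
    seed_or_rng=0,
) -> tuple[list[FeatureWindow], list[FeatureWindow]]:
    """Class-balanced train set, remainder as test.

    n = floor(frac * min(class sizes)) snippets are drawn without
    replacement from each class for training; every remaining snippet goes
    to the test set.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    idx_by_class = {
        lab: np.flatnonzero([w.label == lab for w in windows]) for lab in (0, 1)
    }
    if min(len(v) for v in idx_by_class.values()) == 0:
        raise ValueError("both classes must be non-empty")
    n = int(np.floor(frac * min(len(v) for v in idx_by_class.values())))
    if n == 0:
        raise ValueError("train set would be empty")
    train_idx = np.concatenate(
        [rng.choice(v, size=n, replace=False) for v in idx_by_class.values()]
    )
    train_mask = np.zeros(len(windows), dtype=bool)
    train_mask[train_idx] = True
    train = [w for w, m in zip(windows, train_mask) if m]
    test = [w for w, m in zip(windows, train_mask) if not m]
    return train, test


@dataclass
class DecoderReport:
    """Per-class test accuracy, predictivity class and feature attribution."""

    acc_bout: float        # % correct on lick-labelled test snippets
    acc_interbout: float   # % correct on no-lick test snippets
    predictivity: str      # non_predictive | predictive | strongly_predictive
    attribution: dict      # feature -> mean |SHAP| on the test set
    n_train_per_class: int
    n_test: int
    seed: int = 0
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "acc_bout": self.acc_bout,
            "acc_interbout": self.acc_interbout,
            "predictivity": self.predictivity,
            "attribution": self.attribution,
            "n_train_per_class": self.n_train_per_class,
            "n_test": self.n_test,
            "seed": self.seed,
            "degenerate": self.degenerate,
        }


def classify_predictivity(acc_bout: float, acc_interbout: float) -> str:
    """Predictivity from the two per-class accuracies (strict > boundaries)."""
    if acc_bout > 65.0 and acc_interbout > 65.0:
        return "strongly_predictive"
    if acc_bout > 55.0 and acc_interbout > 55.0:
        return "predictive"
    return "non_predictive"


def train_eval(
    train: Sequence[FeatureWindow],
    test: Sequence[FeatureWindow],
    model_params: Optional[dict] = None,
    seed: int = 0,
) -> DecoderReport:
    """Fit the gradient-boosted-tree classifier and evaluate per class.

    Attribution is the per-feature mean of absolute per-snippet Shapley
    contributions on the test set, via XGBoost's exact TreeSHAP.
    """
    params = dict(DEFAULT_MODEL_PARAMS)
    if model_params:
        params.update(model_params)
    Xtr, ytr = windows_to_arrays(train)
    Xte, yte = windows_to_arrays(test)
    degenerate = bool(np.all(Xtr == Xtr[0], axis=0).all())
    model = xgb.XGBClassifier(
        **params,
        random_state=seed,
        n_jobs=1,
        verbosity=0,
        base_score=0.5,
    )
    model.fit(Xtr, ytr)
    pred = model.predict(Xte)
    accs = {}
    for lab, key in ((1, "bout"), (0, "interbout")):
        mask = yte == lab
        accs[key] = 100.0 * float(np.mean(pred[mask] == lab)) if mask.any() else np.nan
    booster = model.get_booster()
    contribs = booster.predict(xgb.DMatrix(Xte), pred_contribs=True)
    mean_abs = np.mean(np.abs(contribs[:, :3]), axis=0)  # last column is the bias
    attribution = {name: float(v) for name, v in zip(FEATURE_NAMES, mean_abs)}
    n_per_class = int(np.sum(ytr == 1))
    return DecoderReport(
        acc_bout=accs["bout"],
        acc_interbout=accs["interbout"],
        predictivity=classify_predictivity(accs["bout"], accs["interbout"]),
        attribution=attribution,
        n_train_per_class=n_per_class,
        n_test=len(test),
        seed=seed,
        degenerate=degenerate,
    )


def decode_cell(
    licks: LickTrain,
    cell: CellRecording,
    seed: int = 0,
    model_params: Optional[dict] = None,
) -> DecoderReport:
    """Full decoding pipeline for one cell: snippets, split, fit, report."""
    windows = extract_windows(licks, cell)
    train, test = balanced_split(windows, seed_or_rng=seed)
    return train_eval(train, test, model_params=model_params, seed=seed)
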