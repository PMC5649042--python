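"""Per-burst activity classification.

Two one-vs-rest L2-regularized logistic regressions on the 8 burst
features: a *still* detector (phone set down) and a *physical activity*
detector (walking, running, cycling). Each classifier standardizes
features with statistics captured from its own training data and selects
its penalty weight by held-subject-out grid search, so no evaluated
subject ever leaks into training or standardization.

When both classifiers fire on the same burst, still takes precedence: a
set-down phone produces near-zero deviation magnitude regardless of what
the activity model outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold, StratifiedKFold

from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

#: inverse-regularization grid for the L2 penalty
C_GRID = tuple(10.0 ** k for k in range(-3, 4))
TARGETS = ("still", "active")


@dataclass
class ClassifierModel:
    """A trained one-vs-rest burst classifier with its standardization."""

    target: str
    feature_names: tuple
    kept: np.ndarray  # boolean mask over feature_names (zero-variance dropped)
    mean: np.ndarray
    sd: np.ndarray
    coef: np.ndarray
    intercept: float
    C: float

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        """P(target) per row; rows with missing features yield NaN."""
        X = features[list(self.feature_names)].to_numpy(dtype=float)[:, self.kept]
        z = (X - self.mean) / self.sd
        logit = z @ self.coef + self.intercept
        p = 1.0 / (1.0 + np.exp(-logit))
        p[~np.isfinite(X).all(axis=1)] = np.nan
        return p

    def to_json(self) -> str:
        d = {
            "target": self.target,
            "feature_names": list(self.feature_names),
            "kept": self.kept.tolist(),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "C": self.C,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "ClassifierModel":
        d = json.loads(s)
        return cls(
            target=d["target"],
            feature_names=tuple(d["feature_names"]),
            kept=np.asarray(d["kept"], dtype=bool),
            mean=np.asarray(d["mean"], dtype=float),
            sd=np.asarray(d["sd"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            C=float(d["C"]),
        )


def _fit_standardized_logistic(X: np.ndarray, y: np.ndarray, C: float):
    # the penalty weight applies to the *mean* log-loss, so the decision
    # function is invariant to duplicating the training set
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    clf = LogisticRegression(C=C / len(y), solver="lbfgs", max_iter=2000)
    clf.fit((X - mean) / sd, y)
    return mean, sd, clf


def train_classifier(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    target: str,
    groups: np.ndarray | None = None,
    c_grid: tuple = C_GRID,
) -> ClassifierModel:
    """Fit the one-vs-rest detector for ``target`` in {'still', 'active'}.

    ``features`` and ``labels`` are joined on (participant_id, burst_id).
    The penalty weight is chosen by grouped (held-subject-out) CV accuracy
    when ``groups`` (or participant ids) provide >= 2 subjects, else by
    stratified 5-fold CV. Zero-variance features are dropped with a warning.
    """
    if target not in TARGETS:
        raise ValueError(f"target must be one of {TARGETS}")
    merged = features.merge(labels, on=["participant_id", "burst_id"], validate="one_to_one")
    X_all = merged[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = (merged["state"] == target).to_numpy()
    if groups is None:
        groups = merged["participant_id"].to_numpy()
    if y.all() or not y.any():
        raise ValueError(f"training data contains a single class for target {target!r}")

    kept = X_all.std(axis=0) > 0
    if not kept.all():
        dropped = [n for n, k in zip(FEATURE_NAMES, kept) if not k]
        logger.warning("dropping zero-variance features: %s", dropped)
    X = X_all[:, kept]

    n_groups = len(np.unique(groups))
    if n_groups >= 2:
        splitter = GroupKFold(n_splits=min(5, n_groups))
        folds = list(splitter.split(X, y, groups))
    else:
        splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        folds = list(splitter.split(X, y))

    best_C, best_acc = c_grid[0], -1.0
    for C in c_grid:
        accs = []
        for tr, te in folds:
            if len(np.unique(y[tr])) < 2:
                continue
            mean, sd, clf = _fit_standardized_logistic(X[tr], y[tr], C)
            accs.append(float((clf.predict((X[te] - mean) / sd) == y[te]).mean()))
        acc = float(np.mean(accs)) if accs else -1.0
        if acc > best_acc:
            best_C, best_acc = C, acc

    mean, sd, clf = _fit_standardized_logistic(X, y, best_C)
    return ClassifierModel(
        target=target,
        feature_names=tuple(FEATURE_NAMES),
        kept=kept,
        mean=mean,
        sd=sd,
        coef=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
        C=float(best_C),
    )


def predict_states(
    features: pd.DataFrame,
    still_model: ClassifierModel,
    active_model: ClassifierModel,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Resolve per-burst state calls from the two detectors.

    ``is_still = p_still > threshold``; ``is_active = p_active > threshold``
    and not still (still takes precedence). Bursts with missing features are
    flagged ``missing`` and excluded from downstream fractions.
    """
    p_still = still_model.predict_proba(features)
    p_active = active_model.predict_proba(features)
    missing = ~np.isfinite(p_still) | ~np.isfinite(p_active)
    is_still = np.where(missing, False, p_still > threshold)
    is_active = np.where(missing, False, (p_active > threshold) & ~is_still)
    out = features[["participant_id", "burst_id", "t_unix_s"]].copy()
    out["p_still"] = p_still
    out["p_active"] = p_active
    out["is_still"] = is_still.astype(bool)
    out["is_active"] = is_active.astype(bool)
    out["missing"] = missing
    return out


def evaluate_held_out_subjects(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    c_grid: tuple = C_GRID,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Leave-subject-out accuracy of both detectors.

    For each participant, both classifiers are trained (including penalty
    selection and standardization) on the remaining participants only, and
    scored on the held-out participant. A subject whose bursts contain a
    single class for a target gets a ``caveat`` flag (accuracy is then the
    trivial within-class rate).
    """
    merged = features.merge(labels, on=["participant_id", "burst_id"], validate="one_to_one")
    pids = sorted(merged["participant_id"].unique())
    if len(pids) < 2:
        raise ValueError("held-out evaluation needs >= 2 participants")
    rows = []
    for pid in pids:
        tr = merged[merged["participant_id"] != pid]
        te = merged[merged["participant_id"] == pid]
        row = {"participant_id": pid, "n_bursts": len(te)}
        for target in TARGETS:
            model = train_classifier(
                tr[["participant_id", "burst_id", *FEATURE_NAMES]],
                tr[["participant_id", "burst_id", "state"]],
                target,
                c_grid=c_grid,
            )
            y_true = (te["state"] == target).to_numpy()
            y_hat = model.predict_proba(te) > threshold
            row[f"accuracy_{target}"] = float((y_hat == y_true).mean())
            row[f"caveat_{target}"] = bool(y_true.all() or not y_true.any())
        rows.append(row)
    return pd.DataFrame(rows)
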