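"""Cross-validated prediction of deception/disagreement from coordination.

Twenty features per conversation — seven 1000-ms lag-bin means of the
movement lag profile for each of head and lower body (14 motor-synchrony
indices over +/- 3000 ms), plus the six speech-rate CRQA indices — enter
a dyad-grouped 5-fold cross-validation.  On each training fold an
elastic-net-penalized logistic regression (penalty strength tuned by
inner cross-validation) selects the features with nonzero coefficients;
an unpenalized logistic model refit on the selected features predicts
the held-out fold.  Confusion counts are pooled across folds and
summarized by a Bayesian balanced accuracy: sensitivity and specificity
get independent conjugate Beta posteriors (uniform priors), and
balanced accuracy is their average — a conservative summary that keeps
sensitivity and specificity at comparable weight.  The fold split is
re-randomized ``n_repeats`` times; results are means and confidence
intervals across repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.preprocessing import StandardScaler

from .core import InputError, ParameterError

__all__ = ["FEATURE_COLUMNS", "build_features", "cv_predict",
           "balanced_accuracy_posterior", "PosteriorSummary",
           "CvPredictionResult"]

FEATURE_COLUMNS = (
    [f"head_bin_{b:+d}" for b in range(-3, 4)]
    + [f"lower_bin_{b:+d}" for b in range(-3, 4)]
    + ["RR", "DET", "L", "LMAX", "T2", "ENTR"]
)

LABEL_POSITIVE = {"veracity": "deception", "conflict": "disagree"}


def build_features(metrics: pd.DataFrame) -> pd.DataFrame:
    """Assemble the 20-feature table from the real-pair metrics table.

    One row per conversation with identifier and label columns plus the
    20 feature columns; rows with any missing feature are kept but
    flagged ``complete=False`` (never silently imputed).
    """
    required = set(FEATURE_COLUMNS) | {"dyad_id", "conversation_id",
                                       "veracity", "conflict"}
    missing = required - set(metrics.columns)
    if missing:
        raise InputError(f"metrics table lacks columns {sorted(missing)}")
    cols = ["dyad_id", "conversation_id", "veracity", "conflict"]
    table = metrics[cols + FEATURE_COLUMNS].copy()
    table["complete"] = ~table[FEATURE_COLUMNS].isna().any(axis=1)
    return table.reset_index(drop=True)


@dataclass(frozen=True)
class PosteriorSummary:
    """Monte-Carlo summary of the balanced-accuracy Beta posterior."""

    mean: float
    ci_low: float
    ci_high: float
    p_le_half: float
    sensitivity: float
    specificity: float


def balanced_accuracy_posterior(
    tp: int, fn: int, tn: int, fp: int,
    n_draws: int = 100_000, seed: int = 0,
) -> PosteriorSummary:
    """Bayesian balanced accuracy from pooled confusion counts.

    sensitivity ~ Beta(tp+1, fn+1), specificity ~ Beta(tn+1, fp+1)
    (uniform priors); balanced accuracy is their mean, summarized by
    Monte-Carlo draws: posterior mean, central 95% interval, and
    P(BA <= 0.5).
    """
    if min(tp, fn, tn, fp) < 0:
        raise ParameterError("confusion counts must be nonnegative")
    if tp + fn == 0 or tn + fp == 0:
        raise InputError("each class needs at least one test example")
    rng = np.random.default_rng(seed)
    sens = rng.beta(tp + 1, fn + 1, size=n_draws)
    spec = rng.beta(tn + 1, fp + 1, size=n_draws)
    ba = 0.5 * (sens + spec)
    lo, hi = np.percentile(ba, [2.5, 97.5])
    return PosteriorSummary(
        mean=float(ba.mean()), ci_low=float(lo), ci_high=float(hi),
        p_le_half=float(np.mean(ba <= 0.5)),
        sensitivity=float(sens.mean()), specificity=float(spec.mean()))


@dataclass
class CvPredictionResult:
    """Aggregate cross-validated prediction result (percent scale)."""

    label: str
    balanced_accuracy_mean: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    p_posterior: float
    n_repeats: int
    n_rows: int
    selected_features: dict[str, int] = field(default_factory=dict)
    per_repeat: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "balanced_accuracy_mean": self.balanced_accuracy_mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "p_posterior": self.p_posterior,
            "n_repeats": self.n_repeats,
            "n_rows": self.n_rows,
            "selected_features": dict(self.selected_features),
        }


def _enet(C: float, l1_ratio: float, seed: int) -> LogisticRegression:
    return LogisticRegression(penalty="elasticnet", solver="saga",
                              C=C, l1_ratio=l1_ratio, max_iter=3000,
                              tol=1e-3, random_state=seed)


def _two_stage_loss(X_tr, y_tr, X_va, y_va, C: float, l1_ratio: float,
                    seed: int) -> float:
    """Held-out log-loss of select-then-refit at penalty strength ``C``.

    The deployed predictor is an UNPENALIZED refit on the elastic-net
    support, so the inner criterion scores exactly that two-stage
    procedure (scoring the penalized model itself would conflate
    coefficient shrinkage with subset quality and reward weak
    penalties).  An empty support predicts the training base rate.

    Probabilities are clipped to [1e-3, 1 - 1e-3]: the unpenalized refit
    diverges on separable training splits, and an unbounded log-loss
    would let a single wrong-side validation point condemn an otherwise
    excellent subset.
    """
    sel = np.abs(_enet(C, l1_ratio, seed).fit(X_tr, y_tr).coef_.ravel()) > 1e-8
    if not sel.any():
        p = np.full(len(y_va), np.clip(y_tr.mean(), 1e-3, 1 - 1e-3))
    else:
        refit = LogisticRegression(penalty=None, max_iter=2000).fit(
            X_tr[:, sel], y_tr)
        p = np.clip(refit.predict_proba(X_va[:, sel])[:, 1], 1e-3, 1 - 1e-3)
    return float(-np.mean(y_va * np.log(p) + (1 - y_va) * np.log(1 - p)))


def _fold_predict(X_tr, y_tr, X_te, l1_ratio: float, cs: int,
                  inner_folds: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Select features by elastic net on the training fold and predict.

    The penalty strength is tuned by inner cross-validation with the
    one-standard-error rule on the held-out log-loss of the full
    select-then-refit procedure: the STRONGEST penalty
    whose score is within one standard error of the best is used — the
    standard parsimony rule for selecting a minimal feature subset.  The selected features are refit unpenalized and
    used to predict the held-out fold; an empty selection falls back to
    the training-fold majority class.
    """
    from sklearn.model_selection import StratifiedKFold

    scaler = StandardScaler().fit(X_tr)
    Xs, Xt = scaler.transform(X_tr), scaler.transform(X_te)
    c_grid = np.logspace(-2.0, 1.0, cs)
    inner = StratifiedKFold(n_splits=inner_folds, shuffle=True,
                            random_state=seed)
    means = np.empty(cs)
    ses = np.empty(cs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", FutureWarning)
        for ci, C in enumerate(c_grid):
            losses = []
            for itr, ite in inner.split(Xs, y_tr):
                if len(np.unique(y_tr[itr])) < 2:
                    continue
                losses.append(_two_stage_loss(Xs[itr], y_tr[itr], Xs[ite],
                                              y_tr[ite], C, l1_ratio, seed))
            means[ci] = np.mean(losses) if losses else np.inf
            ses[ci] = (np.std(losses, ddof=1) / np.sqrt(len(losses))
                       if len(losses) > 1 else 0.0)
        best = int(np.argmin(means))
        threshold = means[best] + ses[best]
        chosen = int(np.flatnonzero(means <= threshold)[0])  # strongest penalty
        sel_model = _enet(c_grid[chosen], l1_ratio, seed).fit(Xs, y_tr)
    selected = np.abs(sel_model.coef_.ravel()) > 1e-8
    if not selected.any():
        majority = int(np.mean(y_tr) >= 0.5)
        return np.full(len(Xt), majority), selected
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", FutureWarning)
        final = LogisticRegression(penalty=None, max_iter=2000).fit(
            Xs[:, selected], y_tr)
    return final.predict(Xt[:, selected]), selected


def cv_predict(
    table: pd.DataFrame,
    label: str = "veracity",
    k_folds: int = 5,
    n_repeats: int = 100,
    enet_l1_ratio: float = 0.5,
    seed: int = 0,
    cs: int = 8,
    inner_folds: int = 3,
    n_draws: int = 20_000,
    keep_per_repeat: bool = False,
) -> CvPredictionResult:
    """Repeated dyad-grouped cross-validated prediction of a label.

    ``table`` is the output of :func:`build_features`; incomplete rows
    are dropped (their count is reflected in ``n_rows``).  Folds are
    stratified by class and grouped by dyad so no dyad ever spans
    train and test.  Per repeat, fold confusions are pooled and the
    balanced-accuracy posterior computed; the result averages posterior
    mean, CI bounds, sensitivity, specificity and P(BA <= 0.5) across
    repeats and tallies how many repeats selected each feature.
    """
    if label not in LABEL_POSITIVE:
        raise ParameterError(f"label must be one of {sorted(LABEL_POSITIVE)}")
    data = table[table.get("complete", True)].reset_index(drop=True) \
        if "complete" in table.columns else table.reset_index(drop=True)
    if data[label].nunique() < 2:
        raise InputError(f"label {label!r} has a single class")
    n_groups = data["dyad_id"].nunique()
    if n_groups < k_folds:
        raise InputError(f"need >= {k_folds} dyads, got {n_groups}")

    X = data[FEATURE_COLUMNS].to_numpy(float)
    y = (data[label] == LABEL_POSITIVE[label]).to_numpy(int)
    groups = data["dyad_id"].to_numpy()

    root = np.random.default_rng(seed)
    rep_seeds = root.integers(0, 2**31 - 1, size=n_repeats)
    posts: list[PosteriorSummary] = []
    sel_counts = np.zeros(len(FEATURE_COLUMNS), dtype=int)
    repeat_rows = []

    for rep, rs in enumerate(rep_seeds):
        cv = StratifiedGroupKFold(n_splits=k_folds, shuffle=True,
                                  random_state=int(rs))
        tp = fn = tn = fp = 0
        rep_selected = np.zeros(len(FEATURE_COLUMNS), dtype=bool)
        for train, test in cv.split(X, y, groups):
            assert not set(groups[train]) & set(groups[test])
            if len(np.unique(y[train])) < 2:
                continue  # cannot fit; fold contributes nothing
            pred, selected = _fold_predict(
                X[train], y[train], X[test], enet_l1_ratio, cs,
                inner_folds, int(rs))
            rep_selected |= selected
            yt = y[test]
            tp += int(np.sum((pred == 1) & (yt == 1)))
            fn += int(np.sum((pred == 0) & (yt == 1)))
            tn += int(np.sum((pred == 0) & (yt == 0)))
            fp += int(np.sum((pred == 1) & (yt == 0)))
        if tp + fn == 0 or tn + fp == 0:
            continue
        post = balanced_accuracy_posterior(tp, fn, tn, fp, n_draws=n_draws,
                                           seed=int(rs))
        posts.append(post)
        sel_counts += rep_selected
        if keep_per_repeat:
            repeat_rows.append({"repeat": rep, "tp": tp, "fn": fn,
                                "tn": tn, "fp": fp, "ba_mean": post.mean,
                                "ci_low": post.ci_low, "ci_high": post.ci_high})

    if not posts:
        raise InputError("no repeat produced a usable confusion matrix")
    pct = 100.0
    return CvPredictionResult(
        label=label,
        balanced_accuracy_mean=pct * float(np.mean([p.mean for p in posts])),
        ci_low=pct * float(np.mean([p.ci_low for p in posts])),
        ci_high=pct * float(np.mean([p.ci_high for p in posts])),
        sensitivity=pct * float(np.mean([p.sensitivity for p in posts])),
        specificity=pct * float(np.mean([p.specificity for p in posts])),
        p_posterior=float(np.mean([p.p_le_half for p in posts])),
        n_repeats=len(posts),
        n_rows=len(data),
        selected_features={f: int(c) for f, c in
                           zip(FEATURE_COLUMNS, sel_counts) if c > 0},
        per_repeat=pd.DataFrame(repeat_rows) if keep_per_repeat else None,
    )
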