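"""Decoding-based population geometry.

Implements the decoding battery used to characterize abstract rule coding:

* **CCGP** (cross-condition generalization performance): a linear classifier
  for a rule's rewarded/non-rewarded dichotomy is trained with one odor
  condition per class held out and tested only on the held-out conditions.
  High CCGP means the code is odor-invariant (abstract); a population that
  merely memorizes trial types decodes well within conditions but falls to
  chance here.  Chance is 0.5.
* **Rule axes and cosine geometry**: bootstrap-balanced logistic-regression
  weight vectors per rule, compared via cos(theta) = w1.w2 / (|w1||w2|)
  (0 = orthogonal subspaces, 1 = aligned, -1 = anti-aligned).
* **16-class confusion matrices** from leave-one-trial-out linear SVM
  decoding of trial type, scored against block templates (non-match rule,
  cue-identity rule, both rules) with a +/-1 scoring matrix and a
  row/column permutation test, plus the main-vs-side diagonal ratio.
* **Per-rule decoders** with label-permutation p-values, choice
  residualization, and the ignore-go statistic on incongruent trials.

The canonical trial-type ordering is fixed package-wide: non-match trials
of odors 1-8 at indices 0-7, match trials at 8-15.  "Side diagonals" are
the same-odor/other-configuration cells (offset +/-8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, cross_val_predict, cross_val_score
from sklearn.svm import LinearSVC

from .geometry import PermutationNull, rule_masks
from .taskgen import CUE_ID, NON_MATCH, N_TYPES

NM_TEMPLATE = "non_match"
CI_TEMPLATE = "cue_id"
BOTH_TEMPLATE = "both_rules"

_RIDGE_C = 1.0   # ridge penalty for decoding-accuracy classifiers
_AXIS_C = 1e-3   # strong ridge for rule-axis estimation (see rule_axis)


class UndefinedCosineError(ValueError):
    pass


@dataclass
class CCGPResult:
    rule: str
    accuracy: float               # mean over partitions
    ci_low: float                 # percentile 95% CI of partition accuracies
    ci_high: float
    n_partitions: int
    p: float                      # two-tailed tail probability of chance
    partition_accuracies: np.ndarray


@dataclass
class TemplateSimilarity:
    kind: str
    score: float
    p: float
    null: np.ndarray


def _rule_dichotomy(type_index, rule):
    a, _ = rule_masks(type_index, rule)
    return a.astype(int)


def _condition_ids(type_index, rule):
    """Within-class condition labels for CCGP splits.

    For cue identity, conditions are the odors (match and non-match trials
    of an odor belong to the same condition).  For the non-match rule, each
    class's conditions are the odors within that configuration, i.e. the
    trial types themselves.
    """
    type_index = np.asarray(type_index)
    if rule == CUE_ID:
        return type_index % 8
    if rule == NON_MATCH:
        return type_index
    raise ValueError(f"unknown rule {rule!r}")


def _linear_clf(seed=None):
    return LogisticRegression(C=_RIDGE_C, max_iter=2000, random_state=seed)


def ccgp(rates, type_index, rule, n_partitions: int = 500, seed=None) -> CCGPResult:
    """Cross-condition generalization performance for one rule's dichotomy.

    Each partition holds out one odor condition from each class, trains a
    ridge-penalized logistic classifier on the remaining conditions, and
    tests on the held-out trials only.  Partitions resample the (held-out
    pair) split uniformly with replacement.  p is the add-one two-tailed
    tail probability of chance (0.5) under the partition-accuracy
    distribution.
    """
    rates = np.asarray(rates, dtype=float)
    type_index = np.asarray(type_index)
    y = _rule_dichotomy(type_index, rule)
    cond = _condition_ids(type_index, rule)
    conds0 = np.unique(cond[y == 0])
    conds1 = np.unique(cond[y == 1])
    if len(conds0) < 2 or len(conds1) < 2:
        raise ValueError(f"CCGP undefined for rule {rule!r}: a class has <2 conditions")
    for c in np.unique(cond):
        if np.sum(cond == c) < 2:
            raise ValueError("every odor condition needs >=2 trials")
    rng = np.random.default_rng(seed)
    accs = np.empty(n_partitions)
    for i in range(n_partitions):
        h0 = rng.choice(conds0)
        h1 = rng.choice(conds1)
        test = (cond == h0) | (cond == h1)
        clf = _linear_clf(seed=int(rng.integers(2**31)))
        clf.fit(rates[~test], y[~test])
        accs[i] = clf.score(rates[test], y[test])
    p_hi = (1 + np.sum(accs <= 0.5)) / (1 + n_partitions)
    p_lo = (1 + np.sum(accs >= 0.5)) / (1 + n_partitions)
    lo, hi = np.percentile(accs, [2.5, 97.5])
    return CCGPResult(
        rule=rule, accuracy=float(accs.mean()), ci_low=float(lo),
        ci_high=float(hi), n_partitions=n_partitions,
        p=float(min(1.0, 2.0 * min(p_hi, p_lo))), partition_accuracies=accs,
    )


def rule_axis(rates, type_index, rule, n_boot: int = 1000, seed=None) -> np.ndarray:
    """Bootstrap sample of linear decision axes (weight vectors) for a rule.

    Each iteration draws a balanced bootstrap sample (equal class sizes,
    with replacement, so iterations differ even when the classes are already
    balanced), standardizes units within the sample, and fits a logistic
    classifier under a strong ridge penalty; weights are mapped back to the
    original feature (unit) space.  The strong penalty keeps the axis close
    to the class-mean-difference (coding) direction instead of the
    noise-whitened discriminant — the axis is a probe of coding geometry,
    not an accuracy-optimal decoder — and bounds the weights even under
    perfect separation.  Returns an (n_boot, n_units) array.
    """
    rates = np.asarray(rates, dtype=float)
    y = _rule_dichotomy(np.asarray(type_index), rule)
    idx0, idx1 = np.flatnonzero(y == 0), np.flatnonzero(y == 1)
    if len(idx0) == 0 or len(idx1) == 0:
        raise ValueError("both classes must be nonempty")
    n = min(len(idx0), len(idx1))
    rng = np.random.default_rng(seed)
    W = np.empty((n_boot, rates.shape[1]))
    for b in range(n_boot):
        take = np.concatenate([
            rng.choice(idx0, size=n, replace=True),
            rng.choice(idx1, size=n, replace=True),
        ])
        Xb = rates[take]
        mu, sd = Xb.mean(axis=0), Xb.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        clf = LogisticRegression(C=_AXIS_C, max_iter=5000,
                                 random_state=int(rng.integers(2**31)))
        clf.fit((Xb - mu) / sd, y[take])
        W[b] = clf.coef_[0] / sd
    return W


def axis_cosine(w1, w2) -> float:
    """cos(theta) between two decision axes; raises on a zero vector."""
    w1 = np.asarray(w1, dtype=float).ravel()
    w2 = np.asarray(w2, dtype=float).ravel()
    n1, n2 = np.linalg.norm(w1), np.linalg.norm(w2)
    if n1 == 0 or n2 == 0:
        raise UndefinedCosineError("cosine undefined for a zero vector")
    return float(np.dot(w1, w2) / (n1 * n2))


def bootstrap_axis_cosine(rates, type_index, n_boot: int = 1000, seed=None):
    """Paired bootstrap of cos(theta) between the two rules' axes.

    Returns (cosines, summary dict with mean and percentile 95% CI).
    """
    rng = np.random.default_rng(seed)
    w_nm = rule_axis(rates, type_index, NON_MATCH, n_boot=n_boot,
                     seed=int(rng.integers(2**31)))
    w_ci = rule_axis(rates, type_index, CUE_ID, n_boot=n_boot,
                     seed=int(rng.integers(2**31)))
    cosines = np.array([axis_cosine(a, b) for a, b in zip(w_nm, w_ci)])
    lo, hi = np.percentile(cosines, [2.5, 97.5])
    return cosines, dict(mean=float(cosines.mean()), ci_low=float(lo),
                         ci_high=float(hi))


def fit_confusion_matrix(rates, type_index, seed=None, soft: bool = False):
    """Leave-one-trial-out 16-class confusion matrix from a linear SVM.

    Row r gives the distribution of predicted types over trials of true
    type r (hard-vote frequencies by default; prediction probabilities via
    Platt-style decision scores when ``soft``).  Types with fewer than 2
    trials are excluded; returns (matrix, included_types).
    """
    rates = np.asarray(rates, dtype=float)
    type_index = np.asarray(type_index)
    types, cnt = np.unique(type_index, return_counts=True)
    keep_types = types[cnt >= 2]
    if len(keep_types) < len(types):
        warnings.warn(f"excluded types with <2 trials: {types[cnt < 2].tolist()}")
    mask = np.isin(type_index, keep_types)
    X, y = rates[mask], type_index[mask]
    clf = LinearSVC(C=_RIDGE_C, max_iter=5000, random_state=seed)
    if soft:
        from sklearn.calibration import CalibratedClassifierCV

        model = CalibratedClassifierCV(clf, cv=3)
        proba = cross_val_predict(model, X, y, cv=LeaveOneOut(),
                                  method="predict_proba")
        classes = np.unique(y)
        cm = np.vstack([proba[y == t].mean(axis=0) for t in keep_types])
        col_map = {c: i for i, c in enumerate(classes)}
        cm = cm[:, [col_map[t] for t in keep_types]]
    else:
        pred = cross_val_predict(clf, X, y, cv=LeaveOneOut())
        cm = np.zeros((len(keep_types), len(keep_types)))
        tpos = {t: i for i, t in enumerate(keep_types)}
        for yt, yp in zip(y, pred):
            cm[tpos[yt], tpos[yp]] += 1
    cm = cm / cm.sum(axis=1, keepdims=True)
    return cm, keep_types


def make_template(kind: str, type_index=None) -> np.ndarray:
    """Block similarity template over trial types.

    * ``non_match``: 1 within same configuration (types 0-7 vs 8-15);
    * ``cue_id``: 1 within same odor group ({1-4} vs {5-8}), merging
      configurations;
    * ``both_rules``: elementwise product of the other two (4 groups of 4).
    """
    if type_index is None:
        type_index = np.arange(N_TYPES)
    type_index = np.asarray(type_index)
    if kind == NM_TEMPLATE:
        g = (type_index < 8).astype(int)
    elif kind == CI_TEMPLATE:
        g = ((type_index % 8) < 4).astype(int)
    elif kind == BOTH_TEMPLATE:
        g = (type_index < 8).astype(int) * 2 + ((type_index % 8) < 4).astype(int)
    else:
        raise ValueError(f"unknown template kind {kind!r}")
    return (g[:, None] == g[None, :]).astype(float)


def template_similarity(cm, template) -> float:
    """Signed template score of a confusion matrix.

    Scoring matrix S is +1 on template-1 cells and -1 on template-0 cells
    with the main diagonal excluded (correct classification inflates all
    templates equally); the score is sum(cm * S) normalized by the total
    off-diagonal mass of cm, so it lies in [-1, 1].  A cm with zero
    off-diagonal mass scores 0.
    """
    cm = np.asarray(cm, dtype=float)
    template = np.asarray(template, dtype=float)
    if cm.shape != template.shape:
        raise ValueError("confusion matrix and template shapes differ")
    off = ~np.eye(cm.shape[0], dtype=bool)
    S = np.where(template > 0, 1.0, -1.0)
    mass = cm[off].sum()
    if mass <= 0:
        return 0.0
    return float((cm * S)[off].sum() / mass)


def template_permutation_test(
    cm, template, n_perm: int = 1000, seed=None, kind: str = ""
) -> TemplateSimilarity:
    """Permutation test shuffling type labels of rows and columns jointly."""
    cm = np.asarray(cm, dtype=float)
    rng = np.random.default_rng(seed)
    obs = template_similarity(cm, template)
    null = np.empty(n_perm)
    n = cm.shape[0]
    for i in range(n_perm):
        perm = rng.permutation(n)
        null[i] = template_similarity(cm[np.ix_(perm, perm)], template)
    p = (1 + np.sum(null >= obs)) / (1 + n_perm)
    return TemplateSimilarity(kind=kind, score=obs, p=float(p), null=null)


def diagonal_ratio(cm) -> float:
    """Mean main-diagonal probability over mean side-diagonal probability.

    Side diagonals are the same-odor/other-configuration cells (i, i+-8 mod
    16) in the canonical ordering.  Returns +inf when the side-diagonal mean
    is zero.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.shape != (N_TYPES, N_TYPES):
        raise ValueError("diagonal_ratio requires the full 16x16 matrix")
    i = np.arange(N_TYPES)
    main = cm[i, i].mean()
    side = cm[i, (i + 8) % N_TYPES].mean()
    if side == 0:
        warnings.warn("zero side-diagonal mass; ratio is +inf")
        return float("inf")
    return float(main / side)


def rule_decoder(
    rates, type_index, rule, n_perm: int = 1000, cv: int = 5, seed=None
):
    """Cross-validated linear decoding of a rule's dichotomy with a
    label-permutation p-value.

    Class imbalance is corrected by balanced subsampling before
    cross-validation.  Returns (accuracy, p, PermutationNull).
    """
    rates = np.asarray(rates, dtype=float)
    y = _rule_dichotomy(np.asarray(type_index), rule)
    idx0, idx1 = np.flatnonzero(y == 0), np.flatnonzero(y == 1)
    if len(idx0) < 2 or len(idx1) < 2:
        raise ValueError("both classes need >=2 trials")
    rng = np.random.default_rng(seed)
    n = min(len(idx0), len(idx1))
    take = np.concatenate([
        rng.choice(idx0, size=n, replace=False),
        rng.choice(idx1, size=n, replace=False),
    ])
    X, yb = rates[take], y[take]
    folds = min(cv, n)

    def _acc(labels, rs):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
        return float(np.mean(cross_val_score(_linear_clf(seed=rs), X, labels, cv=skf)))

    observed = _acc(yb, int(rng.integers(2**31)))
    null = np.array([
        _acc(rng.permutation(yb), int(rng.integers(2**31))) for _ in range(n_perm)
    ])
    pn = PermutationNull(f"rule_decoder[{rule}]", observed, null, n_perm)
    return observed, pn.p_upper, pn


def residualize_choice(rates, choices):
    """Regress animal choice out of every unit's rate (OLS residuals).

    ``choices`` is a binary go/no-go indicator per trial.  Residuals are
    exactly uncorrelated with choice.  A constant choice vector skips
    residualization with a warning.
    """
    rates = np.asarray(rates, dtype=float)
    c = np.asarray(choices, dtype=float)
    if np.all(c == c[0]):
        warnings.warn("constant choice vector; residualization skipped")
        return rates.copy()
    X = np.column_stack([np.ones_like(c), c])
    beta, *_ = np.linalg.lstsq(X, rates, rcond=None)
    return rates - X @ beta


def ignore_go_probability(rewarded_nm, rewarded_ci, nm_predictions, responses) -> float:
    """Probability of ignoring the old rule's "go" prediction.

    Restricted to incongruent trials (rewarded under the non-match rule but
    not under cue identity): among those the non-match decoder labels
    "rewarded", the fraction on which the agent withheld its response.
    Returns NaN (with a warning) when no trial qualifies.
    """
    rewarded_nm = np.asarray(rewarded_nm, dtype=bool)
    rewarded_ci = np.asarray(rewarded_ci, dtype=bool)
    pred = np.asarray(nm_predictions, dtype=bool)
    go = np.asarray([r == "go" if isinstance(r, str) else bool(r) for r in responses])
    qual = rewarded_nm & ~rewarded_ci & pred
    if not qual.any():
        warnings.warn("no incongruent trials predicted rewarded; ignore-go undefined")
        return float("nan")
    return float(np.mean(~go[qual]))
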