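"""BEED: boosting-ensemble-by-equalized-down-sampling for imbalanced labels.

With m majority and n minority samples (m >= n), the majority class is
shuffled and partitioned into floor(m/n) disjoint blocks of size n; each block
joined with the full minority class gives one balanced training subset, and
one base classifier is fitted per subset.  Each member i is then scored by the
AUC of its predictions on the union of the other subsets (minority samples
deduplicated), and member weights come from min-max normalising those AUCs to
[0, 1] — the best member gets weight 1, the worst 0, and if all AUCs tie every
weight is 1.  At prediction time members cast hard 0/1 votes; the weighted
vote fraction  sum(w_i * vote_i) / sum(w_i)  is compared against a decision
criterion (default 0.5, strict inequality) to call the positive class.

Despite the "boosting" in the name, members are trained in parallel on their
subsets and combined by weighted voting — there is no sequential reweighting.

`BeedClassifier` wraps the procedure as a scikit-learn estimator; the
module-level functions expose each stage for direct use and testing.  The
Dice / precision / recall / F-measure mask metrics and the confusion-matrix
accuracy / sensitivity / specificity / AUC suite live here too.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted

from .ct_io import BinaryMask

logger = logging.getLogger(__name__)

DEFAULT_CRITERION = 0.5

#: Base-learner registry; paper-compared kinds.  XGBoost is optional.
BASE_KINDS = ("LDA", "RF", "NN", "AdaBoost", "XGBoost", "SVM")


def make_base_classifier(kind: str, random_state: int | None = None):
    """Instantiate one of the supported base classifier kinds."""
    if kind == "LDA":
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        return LinearDiscriminantAnalysis()
    if kind == "RF":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(n_estimators=100, random_state=random_state)
    if kind == "NN":
        from sklearn.neural_network import MLPClassifier

        return MLPClassifier(hidden_layer_sizes=(32,), max_iter=500,
                             random_state=random_state)
    if kind == "AdaBoost":
        from sklearn.ensemble import AdaBoostClassifier

        return AdaBoostClassifier(random_state=random_state)
    if kind == "XGBoost":
        from xgboost import XGBClassifier

        return XGBClassifier(n_estimators=100, random_state=random_state or 0,
                             verbosity=0)
    if kind == "SVM":
        from sklearn.svm import SVC

        return SVC(probability=False, random_state=random_state)
    raise ValueError(f"base kind must be one of {BASE_KINDS}")


# ---------------------------------------------------------------------------
# Equalized down-sampling
# ---------------------------------------------------------------------------

def equalized_downsample(majority_ids, minority_ids, seed: int | None = None):
    """Partition the majority class into minority-sized blocks and pair each
    with the whole minority class.

    Returns a list of balanced id subsets: floor(m/n) of them, each holding n
    majority ids plus all n minority ids; the m mod n leftover majority ids
    are discarded (logged).  If m < n a single subset with all ids is returned
    with a warning.
    """
    majority_ids = list(majority_ids)
    minority_ids = list(minority_ids)
    m, n = len(majority_ids), len(minority_ids)
    if m == 0 or n == 0:
        raise ValueError("both classes must be non-empty")
    if m < n:
        warnings.warn("majority smaller than minority; single undivided subset",
                      stacklevel=2)
        return [majority_ids + minority_ids]
    rng = np.random.default_rng(seed)
    shuffled = [majority_ids[i] for i in rng.permutation(m)]
    k = m // n
    if m % n:
        logger.info("equalized down-sampling discards %d of %d majority ids", m % n, m)
    return [shuffled[i * n:(i + 1) * n] + minority_ids for i in range(k)]


def pairwise_auc(y_true, scores) -> float:
    """AUC as pairwise concordance: P(score_pos > score_neg), ties counted 1/2.

    Brute-force O(n_pos * n_neg); the independent reference the fast
    implementation is checked against.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs both classes present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def auc_score(y_true, scores) -> float:
    """AUC with ties counted 1/2 (rank-based)."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y_true, scores))


def _member_score(clf, X):
    """A ranking score from a fitted member: probability of the positive class
    when available, decision function otherwise, else the hard label."""
    if hasattr(clf, "predict_proba"):
        proba = clf.predict_proba(X)
        return proba[:, list(clf.classes_).index(1)]
    if hasattr(clf, "decision_function"):
        return clf.decision_function(X)
    return clf.predict(X).astype(float)


def member_aucs(subsets, members, X, y) -> list[float]:
    """AUC of each member on the union of the other subsets.

    ``subsets`` are lists of integer row ids into (X, y); the evaluation set
    for member i is the deduplicated union of all subsets j != i (minority
    rows appear in every subset, so deduplication matters).  With a single
    member the AUC step is skipped and [1.0] returned.
    """
    if len(members) != len(subsets):
        raise ValueError("one fitted member per subset required")
    if len(members) == 1:
        return [1.0]
    X = np.asarray(X)
    y = np.asarray(y)
    aucs = []
    for i, clf in enumerate(members):
        other = sorted(set().union(*(subsets[j] for j in range(len(subsets)) if j != i)))
        yi = y[other]
        if len(np.unique(yi)) < 2:
            raise ValueError("evaluation set for a member is single-class")
        aucs.append(auc_score(yi, _member_score(clf, X[other])))
    return aucs


def compute_weights(aucs) -> list[float]:
    """Min-max normalise member AUCs to weights in [0, 1].

    ``w_i = (auc_i - min) / (max - min)``; when all AUCs are equal every
    weight is 1 so the vote degenerates to an unweighted majority.
    """
    aucs = np.asarray(aucs, dtype=float)
    if aucs.size == 0:
        raise ValueError("need at least one AUC")
    lo, hi = aucs.min(), aucs.max()
    if hi == lo:
        return [1.0] * len(aucs)
    return [float((a - lo) / (hi - lo)) for a in aucs]


# ---------------------------------------------------------------------------
# The estimator
# ---------------------------------------------------------------------------

class BeedClassifier(BaseEstimator, ClassifierMixin):
    """Imbalance-robust ensemble classifier via equalized down-sampling.

    Parameters
    ----------
    base_kind : one of {"LDA", "RF", "NN", "AdaBoost", "XGBoost", "SVM"}, or a
        scikit-learn estimator instance to clone per subset.
    feature_method : optional filter ranker ("chi2", "anova_f", "info_gain",
        "pearson") applied to the training data only; ``None`` keeps all.
    k : number of features to keep when ``feature_method`` is set.
    criterion : decision threshold on the weighted vote fraction; the positive
        class is called when the fraction strictly exceeds it.
    soft_votes : when True members vote with positive-class probabilities
        instead of hard labels (off by default; the reference procedure sums
        hard positive votes).
    random_state : seed for the down-sampling shuffle and the base learners.

    Attributes
    ----------
    members_ : fitted base classifiers, one per balanced subset.
    subsets_ : row-id subsets each member was trained on.
    aucs_ : cross-subset AUC of each member.
    weights_ : min-max-normalised member weights.
    selected_features_ : feature names kept by the filter step.
    classes_ : [0, 1].
    """

    def __init__(self, base_kind="RF", feature_method=None, k=None,
                 criterion=DEFAULT_CRITERION, soft_votes=False, random_state=None):
        self.base_kind = base_kind
        self.feature_method = feature_method
        self.k = k
        self.criterion = criterion
        self.soft_votes = soft_votes
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    def _make_base(self):
        if isinstance(self.base_kind, str):
            return make_base_classifier(self.base_kind, self.random_state)
        return clone(self.base_kind)

    def _to_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])

    def fit(self, X, y):
        """Select features, build balanced subsets, fit members, weight them."""
        df = self._to_frame(X).reset_index(drop=True)
        y = np.asarray(y).astype(int)
        if df.shape[0] != len(y):
            raise ValueError("X and y length mismatch")
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")

        if self.feature_method is not None:
            from .radiomics import rank_features, select_top_k

            table = df.copy()
            table["label"] = y
            ranks = rank_features(table, self.feature_method)
            k = self.k if self.k is not None else df.shape[1]
            self.selected_features_ = select_top_k(ranks, k)
        else:
            self.selected_features_ = list(df.columns)
        Xs = df[self.selected_features_].to_numpy(dtype=float)

        pos_ids = np.flatnonzero(y == 1)
        neg_ids = np.flatnonzero(y == 0)
        major, minor = (pos_ids, neg_ids) if len(pos_ids) >= len(neg_ids) else (neg_ids, pos_ids)
        self.subsets_ = equalized_downsample(major.tolist(), minor.tolist(),
                                             seed=self.random_state)
        self.members_ = []
        for sub in self.subsets_:
            clf = self._make_base()
            clf.fit(Xs[sub], y[sub])
            self.members_.append(clf)
        self.aucs_ = member_aucs(self.subsets_, self.members_, Xs, y)
        self.weights_ = compute_weights(self.aucs_)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = df.shape[1]
        return self

    def _vote_fractions(self, X) -> np.ndarray:
        check_is_fitted(self, "members_")
        df = self._to_frame(X)
        missing = [f for f in self.selected_features_ if f not in df.columns]
        if missing:
            raise ValueError(f"missing features: {missing}")
        Xs = df[self.selected_features_].to_numpy(dtype=float)
        if self.soft_votes:
            votes = np.column_stack([_member_score(m, Xs) for m in self.members_])
        else:
            votes = np.column_stack([(m.predict(Xs) == 1).astype(float)
                                     for m in self.members_])
        w = np.asarray(self.weights_)
        if w.sum() == 0:
            return votes.mean(axis=1)
        return votes @ w / w.sum()

    def decision_function(self, X) -> np.ndarray:
        """Weighted vote fraction in [0, 1] for the positive class."""
        return self._vote_fractions(X)

    def predict_proba(self, X) -> np.ndarray:
        s = self._vote_fractions(X)
        return np.column_stack([1 - s, s])

    def predict(self, X) -> np.ndarray:
        """Positive iff the weighted vote fraction strictly exceeds the criterion."""
        return (self._vote_fractions(X) > self.criterion).astype(int)


def train_beed(table: pd.DataFrame, base_kind="RF", feature_method=None, k=None,
               seed: int | None = None, label_col: str = "label",
               criterion: float = DEFAULT_CRITERION) -> BeedClassifier:
    """Fit a BeedClassifier from a labelled feature table (thin wrapper)."""
    y = table[label_col].to_numpy()
    X = table.drop(columns=[label_col])
    model = BeedClassifier(base_kind=base_kind, feature_method=feature_method,
                           k=k, criterion=criterion, random_state=seed)
    return model.fit(X, y)


def predict(model: BeedClassifier, features) -> tuple[np.ndarray, np.ndarray]:
    """(labels, weighted vote fractions) for a fitted model (thin wrapper)."""
    if isinstance(features, (pd.Series, dict)):
        features = pd.DataFrame([features])
    return model.predict(features), model.decision_function(features)


# ---------------------------------------------------------------------------
# Metric suite
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metrics:
    """Count-based classification/segmentation metrics.

    accuracy = (TP+TN)/(TP+TN+FP+FN); sensitivity = TP/(TP+FN);
    specificity = TN/(TN+FP); dice = 2|P∩T|/(|P|+|T|);
    precision = |correct|/|predicted|; recall = |correct|/|truth|;
    F = harmonic mean of precision and recall.  Undefined ratios (empty
    denominators) are reported as 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    auc: float | None = None

    @staticmethod
    def _ratio(num, den) -> float:
        return float(num / den) if den else 0.0

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def precision(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def recall(self) -> float:
        return self.sensitivity

    @property
    def dice(self) -> float:
        return self._ratio(2 * self.tp, 2 * self.tp + self.fp + self.fn)

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        return self._ratio(2 * p * r, p + r)

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in
             ("accuracy", "sensitivity", "specificity", "precision", "recall",
              "dice", "f_measure")}
        d.update(tp=self.tp, fp=self.fp, fn=self.fn, tn=self.tn)
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def confusion_metrics(y_true, y_pred, scores=None) -> Metrics:
    """Metrics from binary label vectors; AUC from scores when provided."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    auc = auc_score(y_true, scores) if scores is not None else None
    return Metrics(tp, fp, fn, tn, auc)


def mask_metrics(pred: BinaryMask, truth: BinaryMask) -> Metrics:
    """Pixel-wise metrics between a predicted and a ground-truth mask."""
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    return confusion_metrics(truth.values.ravel(), pred.values.ravel())
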