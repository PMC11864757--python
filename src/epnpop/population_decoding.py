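"""Linear max-margin population decoding with permutation nulls.

Rows are time-bin population vectors (one entry per unit); labels are task
variables (context, stride index, lick index, side, outcome) or continuous
signals discretized into five states by quantile binning.  Decoding uses a
linear support-vector classifier with grouped 10-fold cross-validation
(trajectories/bouts never split across folds); chance and significance come
from label permutations with the add-one p estimator.  A component-weighted
matrix (rows multiplied elementwise by a chosen eigenvector) exposes signals
carried by low-variance population modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC


@dataclass
class LabeledPopulationMatrix:
    """Population vectors (rows) with one label per row and a grouping key."""

    X: np.ndarray  # (n_rows, n_units)
    labels: np.ndarray
    groups: np.ndarray | None = None  # trajectory/bout id for leakage-free folds

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.X):
            raise ValueError("one label per row required")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)


@dataclass
class DecoderResult:
    accuracy: float
    null_accuracies: np.ndarray
    p: float
    n_classes: int
    n_rows: int
    fold_assignments: np.ndarray | None = field(default=None, repr=False)


def discretize_labels(series: np.ndarray, k: int = 5) -> np.ndarray:
    """Quantile binning of a continuous series into k ordered states.

    Rank-based assignment guarantees near-equal class counts (+-1).
    """
    x = np.asarray(series, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if len(np.unique(x)) < k:
        raise ValueError(f"fewer than {k} distinct values")
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), int)
    ranks[order] = np.arange(len(x))
    return (ranks * k) // len(x)


class PopulationDecoder:
    """Linear SVC with grouped cross-validation and a permutation null.

    Parameters
    ----------
    folds : outer CV folds (grouped when the matrix carries groups).
    C : fixed margin penalty (not tuned, keeping permutations exchangeable).
    standardize : per-unit standardization inside each training fold; off by
        default because inputs are typically already z-scored tensors and
        component-weighted matrices must keep their weighting.
    """

    def __init__(
        self,
        folds: int = 10,
        C: float = 1.0,
        standardize: bool = False,
        random_state: int | None = 0,
    ):
        self.folds = folds
        self.C = C
        self.standardize = standardize
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "folds": self.folds,
            "C": self.C,
            "standardize": self.standardize,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "PopulationDecoder":
        for key, val in params.items():
            setattr(self, key, val)
        return self

    def _splits(
        self, X: np.ndarray, y: np.ndarray, groups: np.ndarray | None
    ):
        if groups is not None:
            cv = GroupKFold(n_splits=self.folds)
            return list(cv.split(X, y, groups))
        cv = StratifiedKFold(
            n_splits=self.folds, shuffle=True, random_state=self.random_state
        )
        return list(cv.split(X, y))

    def _clf(self) -> LinearSVC:
        return LinearSVC(C=self.C, random_state=self.random_state, max_iter=10000)

    def fit(self, m: LabeledPopulationMatrix) -> "PopulationDecoder":
        """Cross-validated accuracy; stores ``accuracy_`` and fold details."""
        y = m.labels
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes")
        if counts.min() < self.folds and m.groups is None:
            raise ValueError(
                f"class with {counts.min()} members cannot support "
                f"{self.folds}-fold CV; reduce folds"
            )
        splits = self._splits(m.X, y, m.groups)
        accs = []
        fold_assign = np.full(len(y), -1)
        for k, (train, test) in enumerate(splits):
            Xtr, Xte = m.X[train], m.X[test]
            if self.standardize:
                scaler = StandardScaler().fit(Xtr)
                Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
            clf = self._clf().fit(Xtr, y[train])
            accs.append(float(np.mean(clf.predict(Xte) == y[test])))
            fold_assign[test] = k
        self.fold_accuracies_ = np.asarray(accs)
        self.accuracy_ = float(np.mean(accs))
        self.fold_assignments_ = fold_assign
        self.n_classes_ = len(classes)
        return self

    def permutation_null(
        self, m: LabeledPopulationMatrix, n_perm: int = 1000
    ) -> DecoderResult:
        """Observed accuracy against label-shuffled accuracies.

        Labels are permuted within the grouping structure: when every group
        carries a single label, whole-group labels are permuted across
        groups; otherwise row labels are permuted freely.  Class counts are
        preserved (permutation, not resampling).  p is the add-one estimate
        of P(null >= observed), floored at 1/(1 + n_perm).
        """
        self.fit(m)
        rng = np.random.default_rng(self.random_state)
        nulls = []
        group_label = None
        if m.groups is not None:
            uniq, first = np.unique(m.groups, return_index=True)
            per_group = {g: m.labels[m.groups == g] for g in uniq}
            if all(len(np.unique(v)) == 1 for v in per_group.values()):
                group_label = (uniq, m.labels[first])
        for _ in range(n_perm):
            if group_label is not None:
                uniq, glabels = group_label
                permuted = dict(zip(uniq, rng.permutation(glabels)))
                y_perm = np.array([permuted[g] for g in m.groups])
            else:
                y_perm = rng.permutation(m.labels)
            shuffled = LabeledPopulationMatrix(m.X, y_perm, m.groups)
            dec = PopulationDecoder(**self.get_params())
            dec.fit(shuffled)
            nulls.append(dec.accuracy_)
        nulls = np.asarray(nulls)
        p = (1 + int(np.sum(nulls >= self.accuracy_ - 1e-12))) / (1 + n_perm)
        return DecoderResult(
            accuracy=self.accuracy_,
            null_accuracies=nulls,
            p=p,
            n_classes=self.n_classes_,
            n_rows=len(m.labels),
            fold_assignments=self.fold_assignments_,
        )


def decode_cv(
    m: LabeledPopulationMatrix,
    folds: int = 10,
    C: float = 1.0,
    standardize: bool = False,
    random_state: int | None = 0,
) -> float:
    """Mean held-out accuracy of the linear max-margin decoder."""
    dec = PopulationDecoder(
        folds=folds, C=C, standardize=standardize, random_state=random_state
    )
    return dec.fit(m).accuracy_


def permutation_null(
    m: LabeledPopulationMatrix,
    n_perm: int = 1000,
    folds: int = 10,
    C: float = 1.0,
    standardize: bool = False,
    random_state: int | None = 0,
) -> DecoderResult:
    """Decoder accuracy with a label-permutation null distribution."""
    dec = PopulationDecoder(
        folds=folds, C=C, standardize=standardize, random_state=random_state
    )
    return dec.permutation_null(m, n_perm=n_perm)


def pc_weighted_projection(
    m: LabeledPopulationMatrix | np.ndarray, eigenvector: np.ndarray
) -> LabeledPopulationMatrix | np.ndarray:
    """Weight each population vector elementwise by a component's
    eigenvector, emphasizing the units that carry that mode."""
    w = np.asarray(eigenvector, float)
    if isinstance(m, LabeledPopulationMatrix):
        if m.X.shape[1] != len(w):
            raise ValueError("eigenvector length must equal the unit count")
        return LabeledPopulationMatrix(m.X * w[None, :], m.labels, m.groups)
    X = np.asarray(m, float)
    if X.shape[1] != len(w):
        raise ValueError("eigenvector length must equal the unit count")
    return X * w[None, :]
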