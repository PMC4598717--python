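"""Pattern-based group classification with LOOCV and a permutation null.

Session-level t maps are masked with the pre-tutoring group-difference mask
and z-transformed per subject (in-mask demean, scale by the in-mask standard
deviation), so group discriminability reflects the *shape* of activation
patterns rather than overall activity levels.  A linear maximum-margin
classifier (C-SVC, C=1, linear kernel) is evaluated by leave-one-out
cross-validation; significance of the observed accuracy comes from
permuting group labels and recomputing the full LOOCV each time,
p = (1 + #{null >= observed}) / (1 + n_perm).

Implementation note: LOOCV uses a Gram matrix precomputed once per feature
set.  Folds are fitted through scikit-learn's low-level libsvm binding when
available (identical solver and solution path as ``sklearn.svm.SVC`` with a
precomputed kernel, without per-fit validation overhead); the public
estimator is used otherwise.  Both routes are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maps import StatMap

try:                                      # fast path: same solver, no overhead
    from sklearn.svm import _libsvm
    _libsvm.set_verbosity_wrap(0)
    _HAVE_FAST_LIBSVM = True
except Exception:                         # pragma: no cover - environment fallback
    _libsvm = None
    _HAVE_FAST_LIBSVM = False


def z_transform(map_or_values: StatMap | np.ndarray,
                mask: np.ndarray | None = None, *, ddof: int = 0) -> np.ndarray:
    """In-mask z-transform: demean and scale by the in-mask SD.

    Population convention (divisor N, ``ddof=0``) by default; the sample
    convention only rescales every feature row by a common constant.
    Raises on a constant map.
    """
    if isinstance(map_or_values, StatMap):
        if mask is None:
            raise ValueError("mask required when passing a StatMap")
        values = map_or_values.data[mask]
    else:
        arr = np.asarray(map_or_values, dtype=float)
        values = arr[mask] if (mask is not None and arr.ndim > 1) else arr.ravel()
    if values.size < 2:
        raise ValueError("need at least 2 in-mask values")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values inside mask")
    sd = values.std(ddof=ddof)
    if sd == 0:
        raise ValueError("constant map inside mask; z-transform undefined")
    return (values - values.mean()) / sd


def feature_matrix(maps: list[StatMap], mask: np.ndarray, *,
                   ddof: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stack z-transformed in-mask patterns into (subjects x voxels), with labels."""
    X = np.stack([z_transform(m, mask, ddof=ddof) for m in maps])
    labels = np.array([m.group for m in maps])
    return X, labels


@dataclass
class ClassificationResult:
    """LOOCV outcome, optionally with its permutation null."""

    accuracy: float
    predictions: np.ndarray
    true_labels: np.ndarray
    null_accuracies: np.ndarray | None = None
    p_value: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    C: float = 1.0
    classes: tuple = field(default_factory=tuple)


def _fold_cache(G: np.ndarray) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-fold training Grams, test rows and training indices, computed once.

    The Gram submatrices do not depend on the labels, so a permutation test
    reuses one cache across all label shuffles.
    """
    n = G.shape[0]
    idx = np.arange(n)
    cache = []
    for i in range(n):
        tr = idx != i
        cache.append((np.ascontiguousarray(G[np.ix_(tr, tr)]),
                      np.ascontiguousarray(G[i, tr][None, :]), tr))
    return cache


def _loocv_from_gram(G, y: np.ndarray, C: float) -> np.ndarray:
    """LOOCV predictions (encoded labels) from a precomputed Gram matrix.

    ``G`` may be the full Gram matrix or a cache from :func:`_fold_cache`.
    """
    cache = G if isinstance(G, list) else _fold_cache(np.asarray(G))
    n = len(y)
    preds = np.empty(n)
    for i, (Gtr, Xte, tr) in enumerate(cache):
        ytr = np.ascontiguousarray(y[tr])
        if _HAVE_FAST_LIBSVM:
            out = _libsvm.fit(Gtr, ytr, svm_type=0, kernel="precomputed", C=C)
            preds[i] = _libsvm.predict(Xte, out[0], out[1], out[2], out[3], out[4],
                                       out[5], out[6], svm_type=0,
                                       kernel="precomputed")[0]
        else:                             # pragma: no cover - environment fallback
            from sklearn.svm import SVC
            clf = SVC(kernel="precomputed", C=C).fit(Gtr, ytr)
            preds[i] = clf.predict(Xte)[0]
    return preds


def loocv_classify(features: np.ndarray, labels: np.ndarray, *,
                   C: float = 1.0) -> ClassificationResult:
    """Leave-one-out accuracy of a linear max-margin classifier.

    Each subject is predicted by a C-SVC trained on the remaining n-1;
    deterministic given the features (no stochastic initialization).
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"binary labels required, got classes {classes}")
    counts = [(labels == c).sum() for c in classes]
    if min(counts) < 2:
        raise ValueError("need at least 2 subjects per class (training folds "
                         "must contain both classes)")
    y = (labels == classes[1]).astype(float)
    G = X @ X.T
    preds = _loocv_from_gram(G, y, C)
    accuracy = float((preds == y).mean())
    return ClassificationResult(accuracy=accuracy, predictions=classes[preds.astype(int)],
                                true_labels=labels, C=C, classes=tuple(classes))


def permutation_test(features: np.ndarray, labels: np.ndarray, *,
                     n_perm: int = 10_000, seed: int = 0,
                     C: float = 1.0) -> ClassificationResult:
    """Permutation null for the LOOCV accuracy.

    Each permutation shuffles the group labels once (reused across folds,
    preserving exchangeability) and recomputes the full LOOCV accuracy.
    The p-value uses the +1 smoothed estimator, so p is never 0.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    observed = loocv_classify(X, labels, C=C)
    classes = np.unique(labels)
    y = (labels == classes[1]).astype(float)
    cache = _fold_cache(X @ X.T)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        preds = _loocv_from_gram(cache, yp, C)
        null[b] = (preds == yp).mean()
    p = (1.0 + np.count_nonzero(null >= observed.accuracy)) / (1.0 + n_perm)
    return ClassificationResult(accuracy=observed.accuracy,
                                predictions=observed.predictions,
                                true_labels=labels, null_accuracies=null,
                                p_value=float(p), n_permutations=n_perm,
                                seed=seed, C=C, classes=tuple(classes))
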