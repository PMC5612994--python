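"""Compact linear C-SVM solver for tiny searchlight problems.

Dual coordinate descent on the L1-loss linear SVM (the liblinear
algorithm), JIT-compiled with numba, with the bias handled as an
augmented constant feature.  A searchlight run performs tens of
thousands of fits on ~50 x ~100 problems, where the per-call overhead of
a full estimator API dominates; this solver removes it.  Statistical
agreement with libsvm's C-SVC is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["FastLinearSVC"]


@njit(cache=True)
def _dual_cd(X, y, C, max_epochs, tol):  # pragma: no cover - compiled
    n, d = X.shape
    w = np.zeros(d)
    alpha = np.zeros(n)
    Qd = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(d):
            acc += X[i, j] * X[i, j]
        Qd[i] = acc
    for _ in range(max_epochs):
        max_viol = 0.0
        for i in range(n):
            if Qd[i] <= 0.0:
                continue
            g = 0.0
            for j in range(d):
                g += w[j] * X[i, j]
            g = y[i] * g - 1.0
            pg = g
            if alpha[i] <= 0.0 and g > 0.0:
                pg = 0.0
            elif alpha[i] >= C and g < 0.0:
                pg = 0.0
            if abs(pg) > max_viol:
                max_viol = abs(pg)
            if pg != 0.0:
                old = alpha[i]
                new = old - g / Qd[i]
                if new < 0.0:
                    new = 0.0
                elif new > C:
                    new = C
                if new != old:
                    delta = (new - old) * y[i]
                    for j in range(d):
                        w[j] += delta * X[i, j]
                    alpha[i] = new
        if max_viol < tol:
            break
    return w


class FastLinearSVC:
    """Linear C-SVM with one-vs-one voting for multiclass problems.

    Ties in the vote go to the lowest class index (deterministic).
    """

    def __init__(self, C: float = 1.0, max_epochs: int = 2000, tol: float = 1e-5):
        self.C = float(C)
        self.max_epochs = max_epochs
        self.tol = tol

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FastLinearSVC":
        X = np.ascontiguousarray(X, dtype=np.float64)
        Xa = np.hstack([X, np.ones((len(X), 1))])  # bias feature
        self.classes_ = np.unique(y)
        self.weights_ = []
        self.pairs_ = []
        for a in range(len(self.classes_)):
            for b in range(a + 1, len(self.classes_)):
                sel = (y == self.classes_[a]) | (y == self.classes_[b])
                ypm = np.where(y[sel] == self.classes_[a], 1.0, -1.0)
                w = _dual_cd(np.ascontiguousarray(Xa[sel]), ypm, self.C, self.max_epochs, self.tol)
                self.weights_.append(w)
                self.pairs_.append((a, b))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float64)
        Xa = np.hstack([X, np.ones((len(X), 1))])
        votes = np.zeros((len(X), len(self.classes_)), dtype=np.int64)
        for (a, b), w in zip(self.pairs_, self.weights_):
            dec = Xa @ w
            votes[:, a] += dec > 0
            votes[:, b] += dec <= 0
        return self.classes_[np.argmax(votes, axis=1)]
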