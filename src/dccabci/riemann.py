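"""Riemannian geometry of SPD matrices and minimum-distance-to-mean decoding.

Covariance-like EEG features are symmetric positive definite (SPD) matrices
and live on a curved manifold.  Under the affine-invariant Riemannian metric
(AIRM) the distance between two SPD matrices is the Frobenius norm of the
matrix logarithm of their relative transform; it is invariant under any
congruence ``P -> W P W^T`` with invertible ``W``.  The Karcher (Riemannian)
mean of a set is the SPD matrix minimising the sum of squared AIRM
distances.  The MDM classifier stores one Karcher mean per class and
predicts the class whose prototype is nearest.

Session-to-session covariance shifts are compensated by *recentering*
(rebiasing): conjugating every matrix by the inverse square root of a
reference matrix, typically the Karcher mean of a session.  For causal
online operation the reference is updated adaptively, epoch by epoch, along
geodesics — each incoming matrix is recentred before the reference absorbs
it, so no prediction ever depends on future data.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.covariance import ledoit_wolf

__all__ = [
    "ConvergenceError",
    "check_spd",
    "sqrtm",
    "invsqrtm",
    "logm",
    "expm",
    "powm",
    "geodesic",
    "airm_distance",
    "karcher_mean",
    "shrinkage_scm",
    "trace_normalize",
    "rebias",
    "AdaptiveReference",
    "adaptive_reference_step",
    "MDM",
    "ShrinkageCovariance",
    "Recenter",
    "AdaptiveRecenter",
]

_EIG_FLOOR = 1e-12


class ConvergenceError(RuntimeError):
    """Karcher-mean iteration did not converge; carries the last iterate."""

    def __init__(self, msg: str, last: np.ndarray):
        super().__init__(msg)
        self.last = last


def check_spd(P: np.ndarray, tol: float = 1e-10, name: str = "matrix") -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"{name} must be square, got shape {P.shape}")
    sym_err = float(np.abs(P - P.T).max())
    scale = max(float(np.abs(P).max()), 1.0)
    if sym_err > tol * scale:
        raise ValueError(f"{name} not symmetric (max asymmetry {sym_err:.3e})")
    if float(np.linalg.eigvalsh(P)[0]) <= 0.0:
        raise ValueError(f"{name} is not positive definite")
    return 0.5 * (P + P.T)


def _eig_fun(P: np.ndarray, fun) -> np.ndarray:
    """Apply a scalar function to the eigenvalues of a symmetric matrix."""
    P = np.asarray(P, dtype=float)
    w, v = np.linalg.eigh(0.5 * (P + P.T))
    w = np.maximum(w, _EIG_FLOOR * max(abs(w[-1]), 1.0))
    return (v * fun(w)) @ v.T


def sqrtm(P):
    return _eig_fun(P, np.sqrt)


def invsqrtm(P):
    return _eig_fun(P, lambda w: 1.0 / np.sqrt(w))


def logm(P):
    return _eig_fun(P, np.log)


def expm(S):
    S = np.asarray(S, dtype=float)
    w, v = np.linalg.eigh(0.5 * (S + S.T))
    return (v * np.exp(w)) @ v.T


def powm(P, t: float):
    return _eig_fun(P, lambda w: w**t)


def geodesic(P1: np.ndarray, P2: np.ndarray, t: float) -> np.ndarray:
    """Point at parameter ``t`` on the AIRM geodesic from P1 to P2.

    ``gamma(t) = P1^{1/2} (P1^{-1/2} P2 P1^{-1/2})^t P1^{1/2}``;
    t = 0 gives P1, t = 1 gives P2.  No extrapolation outside [0, 1].
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t must be in [0, 1], got {t}")
    P1 = check_spd(P1, name="P1")
    P2 = check_spd(P2, name="P2")
    if P1.shape != P2.shape:
        raise ValueError("matrices must share dimension")
    h = sqrtm(P1)
    hi = invsqrtm(P1)
    mid = powm(hi @ P2 @ hi, t)
    out = h @ mid @ h
    return 0.5 * (out + out.T)


def airm_distance(P1: np.ndarray, P2: np.ndarray) -> float:
    """AIRM distance ``||log(P1^{-1/2} P2 P1^{-1/2})||_F``.

    Evaluated in the congruence-symmetric form, equal to
    ``||log(P1^{-1} P2)||_F`` but numerically symmetric in its arguments.
    """
    P1 = check_spd(P1, name="P1")
    P2 = check_spd(P2, name="P2")
    if P1.shape != P2.shape:
        raise ValueError("matrices must share dimension")
    w = eigh(P2, P1, eigvals_only=True)
    w = np.maximum(w, _EIG_FLOOR)
    return float(np.sqrt((np.log(w) ** 2).sum()))


def karcher_mean(
    mats,
    tol: float = 1e-8,
    max_iter: int = 50,
    weights=None,
    raise_on_failure: bool = True,
):
    """Karcher (Riemannian) mean of a set of SPD matrices.

    Fixed-point iteration ``P <- P^{1/2} exp(mean_i log(P^{-1/2} C_i
    P^{-1/2})) P^{1/2}`` from the arithmetic-mean initialisation, stopped
    when the Frobenius norm of the mean tangent vector drops below ``tol``.

    Returns the mean; the convergence flag is available through
    :func:`karcher_mean_info`-style usage by catching :class:`ConvergenceError`
    (raised at ``max_iter`` with the last iterate attached) or by passing
    ``raise_on_failure=False``, which returns the last iterate regardless.
    """
    mats = [check_spd(m, name=f"matrix {i}") for i, m in enumerate(mats)]
    if not mats:
        raise ValueError("need at least one matrix")
    if len({m.shape for m in mats}) != 1:
        raise ValueError("matrices must share dimension")
    if len(mats) == 1:
        return mats[0]
    if weights is None:
        weights = np.full(len(mats), 1.0 / len(mats))
    else:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
    stack = np.stack(mats)
    p = np.einsum("i,ijk->jk", weights, stack)
    for _ in range(max_iter):
        h = sqrtm(p)
        hi = invsqrtm(p)
        tangent = np.zeros_like(p)
        for wgt, c in zip(weights, stack):
            tangent += wgt * logm(hi @ c @ hi)
        if float(np.linalg.norm(tangent, "fro")) < tol:
            return 0.5 * (p + p.T)
        p = h @ expm(tangent) @ h
        p = 0.5 * (p + p.T)
    if raise_on_failure:
        raise ConvergenceError(
            f"Karcher mean did not converge in {max_iter} iterations", p
        )
    return p


def shrinkage_scm(epoch: np.ndarray) -> np.ndarray:
    """Ledoit–Wolf shrunk sample covariance of a channels x samples epoch.

    Convex combination ``(1 - lambda) S + lambda (tr S / n) I`` with the
    analytic shrinkage intensity; guaranteed positive definite even with
    fewer samples than channels.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2:
        raise ValueError("epoch must be channels x samples")
    if epoch.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    cov, _ = ledoit_wolf(epoch.T)
    return 0.5 * (cov + cov.T)


def trace_normalize(C: np.ndarray) -> np.ndarray:
    """Scale an SPD matrix to unit trace."""
    C = np.asarray(C, dtype=float)
    tr = float(np.trace(C))
    if tr <= 0.0:
        raise ValueError("trace must be positive")
    return C / tr


def rebias(C: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Recenter ``C`` by a reference: ``R^{-1/2} C R^{-1/2}``."""
    R = check_spd(R, name="reference")
    C = np.asarray(C, dtype=float)
    if C.shape != R.shape:
        raise ValueError("matrix and reference must share dimension")
    ri = invsqrtm(R)
    out = ri @ C @ ri
    return 0.5 * (out + out.T)


class AdaptiveReference:
    """Causally updated recentering reference for an incoming matrix stream.

    ``variant="reset"`` (default, the as-printed rule): the first test
    matrix is recentred with the training reference and the reference then
    resets to that first matrix; each later matrix ``C_i`` (1-based) is
    recentred with the current reference, which afterwards moves along the
    geodesic toward ``C_i`` with step ``1/(i-1)``.

    ``variant="running_mean"``: the reference starts at the training
    reference and moves toward every incoming matrix with step ``1/i``.

    Both variants recenter *before* updating, so the output for epoch ``i``
    never depends on epochs after ``i``.
    """

    def __init__(self, train_reference: np.ndarray, variant: str = "reset"):
        if variant not in ("reset", "running_mean"):
            raise ValueError("variant must be 'reset' or 'running_mean'")
        self.reference = check_spd(train_reference, name="train reference")
        self.variant = variant
        self.count = 0

    def step(self, C: np.ndarray) -> np.ndarray:
        C = check_spd(C, name="incoming matrix")
        if C.shape != self.reference.shape:
            raise ValueError("dimension mismatch with reference")
        self.count += 1
        i = self.count
        out = rebias(C, self.reference)
        if self.variant == "reset":
            if i == 1:
                self.reference = C
            else:
                self.reference = geodesic(self.reference, C, 1.0 / (i - 1))
        else:
            self.reference = geodesic(self.reference, C, 1.0 / i)
        return out


def adaptive_reference_step(state: AdaptiveReference, C: np.ndarray):
    """Functional alias: returns ``(state, rebiased matrix)``."""
    return state, state.step(C)


def _check_spd_stack(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 3 or X.shape[1] != X.shape[2]:
        raise ValueError("X must be a stack of square matrices (n, d, d)")
    return X


class MDM(BaseEstimator, ClassifierMixin):
    """Minimum-distance-to-mean classifier on SPD matrices.

    ``fit`` stores the per-class Karcher mean as the class prototype;
    ``predict`` assigns each matrix to the class of the nearest prototype
    under the AIRM distance (ties break to the first class in ``classes_``
    order).  ``predict_proba`` maps distances through a softmax over their
    negatives (temperature 1), giving a bounded, monotone probability for
    evidence accumulation.

    Parameters
    ----------
    tol, max_iter : Karcher-mean stopping rule.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 50):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = _check_spd_stack(X)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        protos = []
        for cls in self.classes_:
            members = X[y == cls]
            if members.shape[0] == 0:
                raise ValueError(f"empty class {cls!r}")
            protos.append(
                karcher_mean(list(members), tol=self.tol, max_iter=self.max_iter)
            )
        self.prototypes_ = np.stack(protos)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Per-class AIRM distances, shape (n, n_classes)."""
        X = _check_spd_stack(X)
        if X.shape[1] != self.prototypes_.shape[1]:
            raise ValueError("dimension mismatch with fitted prototypes")
        d = np.empty((X.shape[0], self.prototypes_.shape[0]))
        for i in range(X.shape[0]):
            for k in range(self.prototypes_.shape[0]):
                d[i, k] = airm_distance(self.prototypes_[k], X[i])
        return d

    def predict(self, X):
        d = self.transform(X)
        return self.classes_[np.argmin(d, axis=1)]

    def predict_proba(self, X):
        d = self.transform(X)
        e = np.exp(-(d - d.min(axis=1, keepdims=True)))
        return e / e.sum(axis=1, keepdims=True)


class ShrinkageCovariance(BaseEstimator, TransformerMixin):
    """Sklearn transformer: raw epochs -> (trace-normalised) shrunk SCMs."""

    def __init__(self, trace_norm: bool = True):
        self.trace_norm = trace_norm

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_epochs, n_channels, n_samples)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_epochs, n_channels, n_samples)")
        out = np.empty((X.shape[0], X.shape[1], X.shape[1]))
        for i in range(X.shape[0]):
            c = shrinkage_scm(X[i])
            out[i] = trace_normalize(c) if self.trace_norm else c
        return out


class Recenter(BaseEstimator, TransformerMixin):
    """Recenter SPD matrices by the Karcher mean of the fitting set.

    After ``fit`` the reference ``reference_`` is the Karcher mean of the
    training matrices; ``transform`` conjugates every matrix by its inverse
    square root.  Recentering the fitting set itself moves its Karcher mean
    to the identity.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 50):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = _check_spd_stack(X)
        self.reference_ = karcher_mean(list(X), tol=self.tol, max_iter=self.max_iter)
        return self

    def transform(self, X):
        X = _check_spd_stack(X)
        ri = invsqrtm(self.reference_)
        out = np.einsum("ab,nbc,cd->nad", ri, X, ri)
        return 0.5 * (out + out.transpose(0, 2, 1))


class AdaptiveRecenter(BaseEstimator, TransformerMixin):
    """Causal adaptive recentering for pseudo-online evaluation.

    ``fit`` computes the training reference (Karcher mean of the training
    matrices).  ``transform`` treats its input as a causally ordered test
    sequence and applies :class:`AdaptiveReference` from a fresh state, so
    each output depends only on the current and earlier matrices.
    """

    def __init__(self, variant: str = "reset", tol: float = 1e-8, max_iter: int = 50):
        self.variant = variant
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = _check_spd_stack(X)
        self.reference_ = karcher_mean(list(X), tol=self.tol, max_iter=self.max_iter)
        return self

    def transform(self, X):
        X = _check_spd_stack(X)
        state = AdaptiveReference(self.reference_, variant=self.variant)
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            out[i] = state.step(X[i])
        return out
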