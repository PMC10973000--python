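"""Detrended cross-correlation analysis (DCCA), its streaming form, DFA and DCCC.

DCCA estimates the covariance of two (possibly locally non-stationary)
signals by fitting and removing an ordinary-least-squares line inside every
window of ``s`` samples and averaging the covariance of the residuals over
windows.  Setting the two signals equal recovers detrended fluctuation
analysis (DFA); normalising the cross term by the two self-fluctuations
gives the detrended cross-correlation coefficient (DCCC), bounded in
[-1, 1].  Applied pairwise to multichannel EEG the procedure yields a
symmetric positive (semi-)definite matrix that can replace the sample
covariance matrix as input to Riemannian classification.

Two windowing modes are provided: ``sliding`` (step one sample,
K = N - s + 1 windows; the mode the streaming recursion reproduces) and
``nonoverlap`` (K = floor(N/s) disjoint windows).  Window averages use the
1/(K-1) convention; this is a pure scale factor that cancels under trace
normalisation and in DCCC.  With a single window the divisor is taken as 1
(the convention is otherwise undefined there).

The streaming estimator (:class:`DccaStream`) maintains, per channel pair,
running window sums sufficient to emit the cumulative sliding-window DCCA
matrix after every incoming sample at a per-sample cost independent of the
number of samples already seen, with memory bounded by the last ``s``
samples plus O(n_channels^2) accumulators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ScaleSpec",
    "FluctuationSet",
    "DegenerateSignalError",
    "integrate_profile",
    "detrended_cov_window",
    "dcca_pair",
    "dcca_matrix",
    "dfa_exponent",
    "dccc",
    "DccaStream",
    "stream_init",
    "stream_update",
    "DccaTransformer",
]


class DegenerateSignalError(ValueError):
    """Raised when a signal has no detrended variance at the requested scale."""


@dataclass(frozen=True)
class ScaleSpec:
    """Detrending configuration: window length, windowing mode, profile step.

    Parameters
    ----------
    s : int
        Detrending window length in samples. Must satisfy ``s >= 4`` so a
        linear fit leaves at least two residual degrees of freedom.
    mode : {"sliding", "nonoverlap"}
        ``sliding`` uses all K = N - s + 1 step-one windows (default; matches
        the streaming recursion), ``nonoverlap`` uses floor(N/s) disjoint
        windows.
    integrate : bool
        If True, cumulatively sum the series before windowing (the classic
        DFA profile step).  The classification path leaves this off and
        detrends the native signal.
    """

    s: int
    mode: str = "sliding"
    integrate: bool = False

    def __post_init__(self) -> None:
        if self.s < 4:
            raise ValueError(f"scale s must be >= 4, got {self.s}")
        if self.mode not in ("sliding", "nonoverlap"):
            raise ValueError(f"mode must be 'sliding' or 'nonoverlap', got {self.mode!r}")


@dataclass
class FluctuationSet:
    """Per-scale fluctuation values for one channel or channel pair."""

    scales: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales)
        self.values = np.asarray(self.values)
        if self.scales.shape != self.values.shape:
            raise ValueError("scales and values must have matching lengths")


def integrate_profile(x: np.ndarray) -> np.ndarray:
    """Cumulative sum of a series (the DFA 'profile')."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("integrate_profile expects a non-empty 1-D series")
    return np.cumsum(x)


def _window_starts(n: int, spec: ScaleSpec) -> np.ndarray:
    s = spec.s
    if n < s:
        raise ValueError(f"series length {n} shorter than scale {s}")
    if spec.mode == "sliding":
        return np.arange(n - s + 1)
    k_no = n // s
    if k_no < 2:
        raise ValueError(
            f"nonoverlap mode needs at least 2 windows (N={n}, s={s} gives {k_no})"
        )
    return np.arange(k_no) * s


def _norm_factor(s: int, n_windows: int) -> float:
    # 1/(K-1) window-average convention; divisor 1 when only one window exists.
    return (s - 1) * max(n_windows - 1, 1)


def _detrended_residuals(x: np.ndarray, spec: ScaleSpec) -> np.ndarray:
    """Residuals of per-window linear OLS fits, shape (K, s)."""
    s = spec.s
    starts = _window_starts(x.size, spec)
    if spec.mode == "sliding":
        w = sliding_window_view(x, s)
    else:
        w = x[: starts.size * s].reshape(starts.size, s)
    t = np.arange(1.0, s + 1.0)
    st = t.sum()
    stt = (t * t).sum()
    sx = w.sum(axis=1)
    stx = w @ t
    denom = s * stt - st * st
    slope = (s * stx - st * sx) / denom
    intercept = (sx - slope * st) / s
    return w - (intercept[:, None] + slope[:, None] * t[None, :])


def detrended_cov_window(xw: np.ndarray, yw: np.ndarray) -> float:
    """Covariance of independently line-detrended residuals in one window."""
    xw = np.asarray(xw, dtype=float)
    yw = np.asarray(yw, dtype=float)
    if xw.shape != yw.shape or xw.ndim != 1:
        raise ValueError("windows must be 1-D and of equal length")
    s = xw.size
    if s < 4:
        raise ValueError(f"window length must be >= 4, got {s}")
    spec = ScaleSpec(s=s)
    rx = _detrended_residuals(xw, spec)[0]
    ry = _detrended_residuals(yw, spec)[0]
    return float(rx @ ry) / (s - 1)


def _prepared(x: np.ndarray, spec: ScaleSpec) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    return integrate_profile(x) if spec.integrate else x


def dcca_pair(x: np.ndarray, y: np.ndarray, spec: ScaleSpec) -> float:
    """Detrended covariance F^2(s) of two equal-length series.

    With ``x is y`` (or equal content) this is the squared DFA fluctuation.
    """
    x = _prepared(x, spec)
    y = _prepared(y, spec)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    rx = _detrended_residuals(x, spec)
    ry = rx if y is x else _detrended_residuals(y, spec)
    return float((rx * ry).sum()) / _norm_factor(spec.s, rx.shape[0])


def dcca_matrix(
    epoch: np.ndarray,
    spec: ScaleSpec,
    ridge: float = 1e-10,
    return_info: bool = False,
):
    """Pairwise DCCA matrix of a channels x samples epoch.

    Entry (i, j) is ``dcca_pair(channel_i, channel_j, spec)``.  The matrix is
    a Gram matrix of flattened residual windows and hence symmetric positive
    semi-definite by construction; if the smallest eigenvalue is not strictly
    positive (rank-deficient input, e.g. duplicated channels) a ridge of
    ``ridge * mean(diagonal)`` is added to the diagonal and the repair is
    reported via a warning and, with ``return_info=True``, in the info dict.

    Raises
    ------
    DegenerateSignalError
        If any channel has zero detrended variance at this scale (constant
        or perfectly linear channel).
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2 or epoch.shape[0] < 2:
        raise ValueError("epoch must be a (n_channels >= 2) x n_samples array")
    n_ch = epoch.shape[0]
    if spec.integrate:
        epoch = np.cumsum(epoch, axis=1)
    resid = [_detrended_residuals(epoch[c], spec) for c in range(n_ch)]
    k = resid[0].shape[0]
    flat = np.stack([r.ravel() for r in resid])
    f2 = (flat @ flat.T) / _norm_factor(spec.s, k)
    f2 = 0.5 * (f2 + f2.T)
    diag = np.diag(f2)
    if np.any(diag <= 0.0):
        bad = np.flatnonzero(diag <= 0.0).tolist()
        raise DegenerateSignalError(
            f"channels {bad} have zero detrended variance at s={spec.s}"
        )
    info = {"repaired": False, "ridge_added": 0.0}
    min_eig = float(np.linalg.eigvalsh(f2)[0])
    if min_eig <= 0.0:
        add = ridge * float(diag.mean())
        # floor the repair so the result clears 0 at double precision
        add = max(add, -min_eig + ridge * float(diag.mean()))
        f2 = f2 + add * np.eye(n_ch)
        info.update(repaired=True, ridge_added=add)
        warnings.warn(
            f"DCCA matrix rank-deficient (min eigenvalue {min_eig:.3e}); "
            f"ridge {add:.3e} added",
            RuntimeWarning,
            stacklevel=2,
        )
    if return_info:
        return f2, info
    return f2


def dfa_exponent(
    x: np.ndarray,
    scales,
    mode: str = "nonoverlap",
    integrate: bool = True,
):
    """DFA scaling exponent alpha from log-log regression of F(s) on s.

    The series is cumulatively summed (profile step) by default, divided into
    windows at each scale, line-detrended, and the root-mean-square residual
    fluctuation F(s) regressed on scale in natural-log coordinates.  White
    noise gives alpha ~ 0.5; persistent fractional Gaussian noise with Hurst
    exponent H gives alpha ~ H.

    Returns
    -------
    alpha : float
    fluct : FluctuationSet
        Per-scale F(s) (signal units).
    diagnostics : dict
        ``intercept``, ``r_squared`` of the log-log fit.
    """
    scales = np.asarray(list(scales), dtype=int)
    if scales.size < 3:
        raise ValueError("need at least 3 scales for the log-log regression")
    f = np.empty(scales.size)
    for i, s in enumerate(scales):
        spec = ScaleSpec(s=int(s), mode=mode, integrate=integrate)
        f2 = dcca_pair(x, x, spec)
        if f2 <= 0.0:
            raise DegenerateSignalError(f"zero fluctuation at scale {s}")
        f[i] = np.sqrt(f2)
    logs, logf = np.log(scales), np.log(f)
    slope, intercept = np.polyfit(logs, logf, 1)
    pred = slope * logs + intercept
    ss_res = float(((logf - pred) ** 2).sum())
    ss_tot = float(((logf - logf.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), FluctuationSet(scales, f), {"intercept": float(intercept), "r_squared": r2}


def dccc(x: np.ndarray, y: np.ndarray, spec: ScaleSpec) -> float:
    """Detrended cross-correlation coefficient, bounded in [-1, 1]."""
    f2x = dcca_pair(x, x, spec)
    f2y = dcca_pair(y, y, spec)
    if f2x <= 0.0 or f2y <= 0.0:
        raise DegenerateSignalError("zero self-fluctuation; DCCC undefined")
    rho = dcca_pair(x, y, spec) / np.sqrt(f2x * f2y)
    if abs(rho) > 1.0:
        if abs(rho) - 1.0 > 1e-10:
            raise FloatingPointError(f"DCCC overshoot beyond tolerance: {rho}")
        rho = float(np.clip(rho, -1.0, 1.0))
    return float(rho)


class DccaStream:
    """One-pass sliding-window DCCA over an incoming multichannel stream.

    After each sample the emitted matrix equals :func:`dcca_matrix` (sliding
    mode, no profile step) applied to all samples seen so far, up to
    floating-point round-off.  The state holds a ring buffer of the last
    ``s`` samples per channel and O(n_channels^2) running window sums, so the
    per-sample cost and the memory footprint are independent of the total
    stream length.
    """

    def __init__(self, n_channels: int, spec: ScaleSpec, ridge: float = 1e-10):
        if spec.mode != "sliding":
            raise ValueError("streaming DCCA is defined for sliding windows only")
        if spec.integrate:
            raise ValueError("streaming DCCA operates on the native signal")
        if n_channels < 2:
            raise ValueError("need at least 2 channels")
        self.spec = spec
        self.n_channels = n_channels
        self.ridge = ridge
        s = spec.s
        t = np.arange(1.0, s + 1.0)
        st, stt = t.sum(), (t * t).sum()
        # inverse of the 2x2 normal-equations matrix of the [1, t] design
        det = s * stt - st * st
        self._ainv = np.array([[stt, -st], [-st, s]]) / det
        self._buf = np.zeros((n_channels, s))
        self._head = 0
        self.count = 0
        self._sx = np.zeros(n_channels)       # window sum
        self._stx = np.zeros(n_channels)      # window sum of t * x, t = 1..s
        self._sxy = np.zeros((n_channels, n_channels))  # window cross-products
        self._cum = np.zeros((n_channels, n_channels))  # sum over windows of x' M y

    def _window_detcov(self) -> np.ndarray:
        a = self._ainv
        sx, stx = self._sx, self._stx
        hat = (
            a[0, 0] * np.outer(sx, sx)
            + a[0, 1] * (np.outer(sx, stx) + np.outer(stx, sx))
            + a[1, 1] * np.outer(stx, stx)
        )
        return self._sxy - hat

    def update(self, packet: np.ndarray):
        """Feed new samples; return the current DCCA matrix or ``None``.

        ``packet`` is (n_channels,) or (n_channels, m).  ``None`` is returned
        while fewer than ``s`` samples have been seen; a degenerate stream
        (a channel with zero detrended variance so far) also yields ``None``.
        """
        packet = np.asarray(packet, dtype=float)
        if packet.ndim == 1:
            packet = packet[:, None]
        if packet.ndim != 2 or packet.shape[0] != self.n_channels:
            raise ValueError(
                f"packet must have {self.n_channels} channels, got shape {packet.shape}"
            )
        s = self.spec.s
        for j in range(packet.shape[1]):
            v = packet[:, j]
            if self.count < s:
                self._buf[:, self.count] = v
                self._sx += v
                self._stx += (self.count + 1) * v
                self._sxy += np.outer(v, v)
                self.count += 1
                if self.count == s:
                    self._cum += self._window_detcov()
            else:
                old = self._buf[:, self._head].copy()
                self._buf[:, self._head] = v
                self._head = (self._head + 1) % s
                self._stx += -self._sx + s * v
                self._sx += v - old
                self._sxy += np.outer(v, v) - np.outer(old, old)
                self.count += 1
                self._cum += self._window_detcov()
        return self.current_matrix()

    def current_matrix(self):
        """Cumulative DCCA matrix over all samples seen, or ``None``."""
        s = self.spec.s
        if self.count < s:
            return None
        k = self.count - s + 1
        f2 = self._cum / _norm_factor(s, k)
        f2 = 0.5 * (f2 + f2.T)
        diag = np.diag(f2)
        if np.any(diag <= 0.0):
            warnings.warn(
                "degenerate stream: a channel has zero detrended variance",
                RuntimeWarning,
                stacklevel=2,
            )
            return None
        return f2


def stream_init(n_channels: int, spec: ScaleSpec) -> DccaStream:
    """Create an empty streaming DCCA state (functional-style alias)."""
    return DccaStream(n_channels, spec)


def stream_update(state: DccaStream, packet: np.ndarray):
    """Feed a packet into a stream state; returns ``(state, matrix-or-None)``."""
    return state, state.update(packet)


class DccaTransformer(BaseEstimator, TransformerMixin):
    """Sklearn transformer: raw epochs -> DCCA matrices.

    Maps an array of shape ``(n_epochs, n_channels, n_samples)`` to a stack
    of SPD matrices ``(n_epochs, n_channels, n_channels)``.  Stateless (fit
    is a no-op) so it composes with sklearn pipelines and model selection.

    Parameters
    ----------
    scale : int
        Detrending window length in samples (0.25 s at 512 Hz for the
        default 128).
    mode : {"sliding", "nonoverlap"}
    integrate : bool
        Profile (cumulative-sum) step before detrending; off by default for
        classification.
    ridge : float
        Relative diagonal repair for rank-deficient outputs.
    trace_norm : bool
        Divide each matrix by its trace, removing the window-count scale
        convention from the features.
    """

    def __init__(
        self,
        scale: int = 128,
        mode: str = "sliding",
        integrate: bool = False,
        ridge: float = 1e-10,
        trace_norm: bool = True,
    ):
        self.scale = scale
        self.mode = mode
        self.integrate = integrate
        self.ridge = ridge
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
        spec = ScaleSpec(s=self.scale, mode=self.mode, integrate=self.integrate)
        out = np.empty((X.shape[0], X.shape[1], X.shape[1]))
        for i in range(X.shape[0]):
            c = dcca_matrix(X[i], spec, ridge=self.ridge)
            if self.trace_norm:
                c = c / np.trace(c)
            out[i] = c
        return out
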