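"""Synthetic two-class motor-imagery EEG sessions.

The generator emulates the statistical structure the decoder relies on
without any claim of biophysical realism: each trial is a band-limited
(8-30 Hz) oscillatory process with a class-dependent spatial covariance —
the class imagining the left hand has reduced variance at C4 and the right
class at C3, mimicking contralateral event-related desynchronisation — on
top of a 1/f-type fractional-Gaussian-noise background mixed across
channels.  Slow per-channel polynomial drifts model local non-stationarities
that inflate whole-epoch sample covariance but are removed by local
detrending, and an optional session-level congruence transform emulates the
between-day covariance shift that recentering compensates.

Everything is deterministic under the spec seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .preprocess import MultichannelSignal

__all__ = [
    "DEFAULT_MONTAGE",
    "GeneratorSpec",
    "Session",
    "fgn",
    "generate_session",
    "inject_blinks",
    "epochs_from_session",
]

# the 22-channel sensorimotor montage used throughout
DEFAULT_MONTAGE = [
    "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "C3", "Cz", "C4",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8", "POz",
]


def fgn(H: float, n: int, seed) -> np.ndarray:
    """Fractional Gaussian noise with Hurst exponent ``H`` (unit variance).

    Exact stationary simulation by circulant embedding (Davies-Harte): the
    fGn autocovariance sequence is embedded in a circulant matrix of size
    2n whose eigenvalues are obtained by FFT; a complex Gaussian vector
    shaped by their square roots transforms back to a sample path with
    exactly the target autocovariance.  If the embedding produces negative
    eigenvalues (it does not for fGn autocovariances, but guard anyway) they
    are clipped to zero with a warning.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if not 0.0 < H < 1.0:
        raise ValueError(f"Hurst exponent must be in (0, 1), got {H}")
    if n < 1:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = np.arange(n + 1, dtype=float)
    r = 0.5 * (
        np.abs(k + 1) ** (2 * H) - 2 * np.abs(k) ** (2 * H) + np.abs(k - 1) ** (2 * H)
    )
    c = np.concatenate([r, r[-2:0:-1]])  # circulant first row, length 2n
    lam = np.fft.fft(c).real
    if lam.min() < 0:
        if lam.min() < -1e-8:
            warnings.warn(
                "circulant embedding produced negative eigenvalues; clipping",
                RuntimeWarning,
                stacklevel=2,
            )
        lam = np.maximum(lam, 0.0)
    m = lam.size
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.fft(np.sqrt(lam / (2.0 * m)) * z)
    return x.real[:n] * np.sqrt(2.0)


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for a synthetic two-class MI session.

    Defaults follow the recording structure the decoder targets: 22
    sensorimotor channels at 512 Hz, four runs of 20 trials (10 per class,
    randomized order), 5-s active trials separated by 2-s rest gaps, an
    8-30 Hz oscillatory band, persistent (H = 0.7) background activity, and
    contralateral variance reduction of 50% at C4 / C3 for left / right
    imagery.  Drift and session-shift amplitudes parameterise the
    non-stationarities the method is designed to absorb.
    """

    n_channels: int = 22
    rate: float = 512.0
    ch_names: tuple = ()
    classes: tuple = ("left", "right")
    erd_channels: dict = field(default_factory=lambda: {"left": "C4", "right": "C3"})
    erd_factor: float = 0.5          # variance multiplier at the contralateral site
    band: tuple = (8.0, 30.0)
    osc_amp: float = 1.0             # oscillatory RMS per channel (arbitrary units)
    background_hurst: float = 0.7
    background_amp: float = 0.5      # background RMS relative to osc_amp
    drift_order: int = 3             # polynomial degree of per-channel trends
    drift_amp: float = 2.0           # drift RMS in units of osc_amp
    shift_magnitude: float = 0.3     # ||log W||_F of the between-session transform
    n_runs: int = 4
    trials_per_run: int = 20
    trial_s: float = 5.0
    gap_s: float = 2.0
    seed: int = 0

    def resolved_ch_names(self) -> list:
        if self.ch_names:
            names = list(self.ch_names)
        elif self.n_channels == 22:
            names = list(DEFAULT_MONTAGE)
        else:
            names = [f"ch{i}" for i in range(self.n_channels)]
            names[0], names[-1] = "C3", "C4"
        if len(names) != self.n_channels:
            raise ValueError("ch_names length must match n_channels")
        return names


@dataclass
class Session:
    """A generated session plus the ground truth that produced it."""

    signal: MultichannelSignal
    labels: list                  # per-trial class label
    onsets: np.ndarray            # trial onset sample indices
    trial_samples: int
    class_covs: dict              # class -> total ground-truth spatial covariance
    spec: GeneratorSpec
    session_index: int = 0


def _base_covariance(n: int, rng: np.random.Generator) -> np.ndarray:
    """A well-conditioned random SPD matrix with unit diagonal."""
    w = rng.standard_normal((n, n)) / np.sqrt(n)
    c = w @ w.T + 0.5 * np.eye(n)
    d = 1.0 / np.sqrt(np.diag(c))
    return c * np.outer(d, d)


def _class_templates(spec: GeneratorSpec, rng: np.random.Generator):
    if spec.erd_factor <= 0:
        raise ValueError("erd_factor must be positive (it scales a variance)")
    names = spec.resolved_ch_names()
    base = _base_covariance(spec.n_channels, rng)
    templates = {}
    for cls in spec.classes:
        ch = spec.erd_channels.get(cls)
        d = np.ones(spec.n_channels)
        if ch is not None:
            if ch not in names:
                raise ValueError(f"ERD channel {ch!r} not in channel names")
            d[names.index(ch)] = np.sqrt(spec.erd_factor)
        templates[cls] = base * np.outer(d, d)
    return base, templates


def _band_sources(n_ch: int, n: int, band, rate: float, rng) -> np.ndarray:
    """Independent unit-variance band-limited Gaussian sources."""
    sos = sps.butter(4, band, btype="band", fs=rate, output="sos")
    u = sps.sosfiltfilt(sos, rng.standard_normal((n_ch, n)), axis=-1)
    sd = u.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return u / sd


def _drift(n_ch: int, n: int, order: int, amp: float, rng) -> np.ndarray:
    if amp <= 0:
        return np.zeros((n_ch, n))
    t = np.linspace(-1.0, 1.0, n)
    basis = np.stack([t**k for k in range(1, order + 1)])  # no constant term
    coef = rng.standard_normal((n_ch, order))
    d = coef @ basis
    rms = d.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return amp * d / rms


def _shift_transform(n: int, magnitude: float, rng) -> np.ndarray:
    g = rng.standard_normal((n, n))
    sym = 0.5 * (g + g.T)
    sym *= magnitude / np.linalg.norm(sym, "fro")
    w, v = np.linalg.eigh(sym)
    return (v * np.exp(w)) @ v.T  # SPD with ||log W||_F = magnitude


def generate_session(spec: GeneratorSpec, session: int = 0) -> Session:
    """Generate one session of the two-class MI paradigm.

    ``session > 0`` applies the between-session congruence transform
    ``x -> W x`` (drawn once from the spec seed, shared by all non-zero
    sessions) so that spatial covariances shift as ``W Sigma W^T`` relative
    to session 0; ground-truth covariances in the returned object include
    the shift.
    """
    struct_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2**20]))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, session]))
    base, templates = _class_templates(spec, struct_rng)
    for cls, c in templates.items():
        if np.linalg.eigvalsh(c)[0] <= 0:
            raise ValueError(f"class template for {cls!r} is not SPD")
    chol = {cls: np.linalg.cholesky(c) for cls, c in templates.items()}
    bg_chol = np.linalg.cholesky(base)
    shift = (
        _shift_transform(spec.n_channels, spec.shift_magnitude, struct_rng)
        if spec.shift_magnitude > 0
        else None
    )

    nt = int(round(spec.trial_s * spec.rate))
    ng = int(round(spec.gap_s * spec.rate))
    n_trials = spec.n_runs * spec.trials_per_run
    total = ng + n_trials * (nt + ng)

    # persistent background, mixed across channels
    bg = np.stack(
        [fgn(spec.background_hurst, total, rng) for _ in range(spec.n_channels)]
    )
    data = spec.osc_amp * spec.background_amp * (bg_chol @ bg)

    labels, onsets = [], []
    half = spec.trials_per_run // 2
    pos = ng
    for _ in range(spec.n_runs):
        run_labels = [spec.classes[0]] * half + [spec.classes[1]] * (
            spec.trials_per_run - half
        )
        rng.shuffle(run_labels)
        for lab in run_labels:
            u = _band_sources(spec.n_channels, nt, spec.band, spec.rate, rng)
            osc = spec.osc_amp * (chol[lab] @ u)
            osc += spec.osc_amp * _drift(
                spec.n_channels, nt, spec.drift_order, spec.drift_amp, rng
            )
            data[:, pos : pos + nt] += osc
            labels.append(lab)
            onsets.append(pos)
            pos += nt + ng

    class_covs = {
        cls: spec.osc_amp**2 * templates[cls]
        + (spec.osc_amp * spec.background_amp) ** 2 * base
        for cls in spec.classes
    }
    if session > 0 and shift is not None:
        data = shift @ data
        class_covs = {cls: shift @ c @ shift.T for cls, c in class_covs.items()}

    sig = MultichannelSignal(data, spec.rate, spec.resolved_ch_names())
    return Session(
        signal=sig,
        labels=labels,
        onsets=np.asarray(onsets),
        trial_samples=nt,
        class_covs=class_covs,
        spec=spec,
        session_index=session,
    )


def inject_blinks(
    eog_channel: np.ndarray,
    rate_per_min: float,
    amplitude_uv: float,
    rate_hz: float = 512.0,
    seed=0,
):
    """Add stereotyped blink transients at Poisson times to an EOG trace.

    Each event is a Gaussian deflection (sigma 50 ms) of the given peak
    amplitude.  Returns ``(series, event_times_s)``.
    """
    if amplitude_uv <= 0:
        raise ValueError("amplitude must be positive")
    eog = np.asarray(eog_channel, dtype=float).copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dur_min = eog.size / rate_hz / 60.0
    n_events = rng.poisson(rate_per_min * dur_min) if rate_per_min > 0 else 0
    times = np.sort(rng.uniform(0.0, eog.size / rate_hz, size=n_events))
    t = np.arange(eog.size) / rate_hz
    for t0 in times:
        eog += amplitude_uv * np.exp(-0.5 * ((t - t0) / 0.05) ** 2)
    return eog, times


def epochs_from_session(
    session: Session, win_s: float = 1.0, step_s: float = 0.0625
):
    """Cut each trial into sliding epochs; returns ``(X, y, trial_idx)``.

    ``X`` is (n_epochs, n_channels, win) in trial order (causal), ``y`` the
    per-epoch class label and ``trial_idx`` the trial each epoch came from.
    """
    rate = session.signal.rate
    win = int(round(win_s * rate))
    step = step_s * rate
    if abs(step - round(step)) > 1e-9:
        raise ValueError("step must be an integer number of samples")
    step = int(round(step))
    xs, ys, ts = [], [], []
    for i, (onset, lab) in enumerate(zip(session.onsets, session.labels)):
        trial = session.signal.data[:, onset : onset + session.trial_samples]
        for s0 in range(0, trial.shape[1] - win + 1, step):
            xs.append(trial[:, s0 : s0 + win])
            ys.append(lab)
            ts.append(i)
    return np.stack(xs), np.asarray(ys), np.asarray(ts)
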