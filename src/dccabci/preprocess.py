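"""Band-pass filtering, epoching and EOG artifact gating.

Offline analysis uses a zero-phase (forward-backward) Butterworth band-pass
in the sensorimotor 8-30 Hz band; the online path uses a causal Butterworth
whose state is carried across packets so packet-wise filtering is sample-
exact against one-shot causal filtering.  Trials are cut into 1-s epochs
with a 62.5 ms step (32 samples at 512 Hz, 10 at 160 Hz), 0-based and
half-open in samples.  Epochs whose EOG exceeds 320 uV in absolute value
(strictly) are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "MultichannelSignal",
    "Epoch",
    "FilterSpec",
    "CausalFilter",
    "bandpass",
    "epochize",
    "eog_gate",
]


@dataclass
class MultichannelSignal:
    """Channels x samples matrix with sampling rate and channel labels."""

    data: np.ndarray
    rate: float
    ch_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not self.ch_names:
            self.ch_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("channel label count must match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class Epoch:
    """Fixed-length window cut from a signal."""

    data: np.ndarray
    rate: float
    start: int                 # sample index of the first sample, 0-based
    label: object = None
    trial_id: object = None
    session_id: object = None


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass configuration."""

    order: int = 3
    low_hz: float = 8.0
    high_hz: float = 30.0
    mode: str = "zero_phase"   # or "causal"

    def __post_init__(self) -> None:
        if not 0.0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.mode not in ("zero_phase", "causal"):
            raise ValueError("mode must be 'zero_phase' or 'causal'")

    def sos(self, rate: float) -> np.ndarray:
        if self.high_hz >= rate / 2.0:
            raise ValueError(
                f"high cutoff {self.high_hz} Hz at or above Nyquist ({rate / 2} Hz)"
            )
        return sps.butter(
            self.order, [self.low_hz, self.high_hz], btype="band", fs=rate, output="sos"
        )


class CausalFilter:
    """Stateful causal band-pass; packet-wise output equals one-shot output."""

    def __init__(self, spec: FilterSpec, rate: float, n_channels: int):
        self._sos = spec.sos(rate)
        zi = sps.sosfilt_zi(self._sos)  # (n_sections, 2)
        self._zi = np.zeros((self._sos.shape[0], n_channels, 2))
        # start from rest (zero initial conditions): online semantics, the
        # transient is part of the signal
        del zi

    def process(self, packet: np.ndarray) -> np.ndarray:
        packet = np.atleast_2d(np.asarray(packet, dtype=float))
        out, self._zi = sps.sosfilt(self._sos, packet, axis=-1, zi=self._zi)
        return out


def bandpass(sig: MultichannelSignal, spec: FilterSpec) -> MultichannelSignal:
    """Apply the configured Butterworth band-pass to every channel.

    ``zero_phase`` runs the filter forward and backward (zero group delay,
    effective order doubled, symmetric padding); ``causal`` runs forward only
    from zero initial state, matching the online path.
    """
    if not np.all(np.isfinite(sig.data)):
        raise ValueError("signal contains non-finite samples")
    sos = spec.sos(sig.rate)
    if spec.mode == "zero_phase":
        # generous symmetric padding: edge transients of the low cutoff decay
        # over several of its periods, and short padding breaks the
        # time-reversal symmetry a zero-phase filter should have
        padlen = min(sig.n_samples - 1, int(10 * sig.rate / spec.low_hz))
        out = sps.sosfiltfilt(sos, sig.data, axis=-1, padtype="odd", padlen=padlen)
    else:
        filt = CausalFilter(spec, sig.rate, sig.n_channels)
        out = filt.process(sig.data)
    return MultichannelSignal(out, sig.rate, list(sig.ch_names))


def epochize(
    sig: MultichannelSignal,
    win_s: float = 1.0,
    step_s: float = 0.0625,
    label=None,
    trial_id=None,
    session_id=None,
) -> list:
    """Cut a signal into sliding epochs of ``win_s`` seconds every ``step_s``.

    Windows are 0-based, half-open ``[start, start + win)`` in samples and
    must fit entirely inside the signal; the count is
    ``floor((N - win) / step) + 1``.  The step must resolve to an integer
    number of samples.
    """
    win = win_s * sig.rate
    step = step_s * sig.rate
    if abs(win - round(win)) > 1e-9 or abs(step - round(step)) > 1e-9:
        raise ValueError(
            f"window ({win_s}s) and step ({step_s}s) must be integer samples at "
            f"{sig.rate} Hz"
        )
    win, step = int(round(win)), int(round(step))
    if step < 1 or win < 1:
        raise ValueError("window and step must be at least one sample")
    if sig.n_samples < win:
        raise ValueError("signal shorter than one window")
    starts = range(0, sig.n_samples - win + 1, step)
    return [
        Epoch(
            data=sig.data[:, s : s + win].copy(),
            rate=sig.rate,
            start=s,
            label=label,
            trial_id=trial_id,
            session_id=session_id,
        )
        for s in starts
    ]


def eog_gate(eog_epoch: np.ndarray, threshold_uv: float = 320.0) -> bool:
    """Keep/reject flag for an EOG epoch (amplitudes in microvolts).

    Returns ``True`` (keep) unless the absolute amplitude strictly exceeds
    the threshold; an excursion exactly at threshold is kept.
    """
    eog_epoch = np.asarray(eog_epoch, dtype=float)
    return bool(np.abs(eog_epoch).max() <= threshold_uv)
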