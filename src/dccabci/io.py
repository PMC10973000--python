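"""Readers, writers and serialization: EDF, text fixtures, models, metrics.

EDF/EDF+ recordings are read through MNE and returned in microvolts with
channel labels normalised to 10-10 names.  A minimal EDF writer (16-bit,
one-second records) serialises synthetic sessions so the read path can be
exercised without external downloads; note EDF quantises to the 16-bit
digital grid, so exact round-trips use the plain-text fixture format
(full-precision CSV signal + JSON metadata) instead.  Models (MDM
prototypes, recentering reference, feature configuration) serialise to JSON.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from .preprocess import MultichannelSignal
from .riemann import MDM
from .synthetic import GeneratorSpec, Session

__all__ = [
    "read_edf",
    "write_edf",
    "save_session",
    "load_session",
    "save_model",
    "load_model",
    "write_metrics",
    "read_config",
]


def read_edf(path, channels=None, event_map=None):
    """Read an EDF/EDF+ file into a :class:`MultichannelSignal` (microvolts).

    ``channels`` optionally selects a subset, preserving the requested
    order; absent channels raise with the missing names listed.
    ``event_map`` maps annotation descriptions to labels; matching
    annotations are returned as ``(onset_seconds, label)`` pairs.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    available = raw.ch_names
    if channels is not None:
        missing = [c for c in channels if c not in available]
        if missing:
            raise ValueError(f"channels not found in {path}: {missing}")
        raw.pick(list(channels))
        raw.reorder_channels(list(channels))
    data = raw.get_data() * 1e6  # Volts -> microvolts
    sig = MultichannelSignal(data, raw.info["sfreq"], list(raw.ch_names))
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if event_map is None:
            events.append((float(onset), desc))
        elif desc in event_map:
            events.append((float(onset), event_map[desc]))
    return sig, events


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r} (max {width})")
    return s.ljust(width).encode("ascii")


def write_edf(sig: MultichannelSignal, path) -> None:
    """Write a signal (microvolts) as a minimal 16-bit EDF file.

    Uses one-second data records, so the sampling rate must be an integer;
    the signal is zero-padded to a whole number of records.  Samples are
    quantised to the per-channel physical range over the 16-bit digital
    grid.
    """
    rate = sig.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))
    n_ch = sig.n_channels
    n_rec = int(np.ceil(sig.n_samples / spr))
    data = np.zeros((n_ch, n_rec * spr))
    data[:, : sig.n_samples] = sig.data

    pmax = np.ceil(np.abs(data).max(axis=1)) + 1.0  # short ASCII, nonzero range
    # EDF affine map: phys in [-pmax, pmax] <-> digital in [-32768, 32767]
    gain = 65535.0 / (2.0 * pmax)
    digital = np.clip(
        np.round((data + pmax[:, None]) * gain[:, None]) - 32768.0, -32768, 32767
    ).astype("<i2")

    header = b""
    header += _edf_field("0", 8)
    header += _edf_field("synthetic", 80)
    header += _edf_field("dccabci", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (n_ch + 1), 8)
    header += _edf_field("", 44)
    header += _edf_field(n_rec, 8)
    header += _edf_field(1, 8)
    header += _edf_field(n_ch, 4)
    for name in sig.ch_names:
        header += _edf_field(name, 16)
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_edf_field(f"{-p:.6g}", 8) for p in pmax)
    header += b"".join(_edf_field(f"{p:.6g}", 8) for p in pmax)
    header += b"".join(_edf_field(-32768, 8) for _ in range(n_ch))
    header += b"".join(_edf_field(32767, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field(spr, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def save_session(session: Session, directory) -> None:
    """Write a session as a plain-text fixture: CSV signal + JSON metadata."""
    os.makedirs(directory, exist_ok=True)
    sig = session.signal
    np.savetxt(
        os.path.join(directory, "signal.csv"),
        sig.data.T,
        delimiter=",",
        fmt="%.17g",
        header=",".join(sig.ch_names),
        comments="",
    )
    meta = {
        "rate": sig.rate,
        "ch_names": list(sig.ch_names),
        "labels": list(session.labels),
        "onsets": session.onsets.tolist(),
        "trial_samples": session.trial_samples,
        "session_index": session.session_index,
        "class_covs": {k: v.tolist() for k, v in session.class_covs.items()},
        "spec": _spec_to_dict(session.spec),
    }
    with open(os.path.join(directory, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def _spec_to_dict(spec: GeneratorSpec) -> dict:
    d = asdict(spec)
    d["ch_names"] = list(d["ch_names"])
    d["classes"] = list(d["classes"])
    d["band"] = list(d["band"])
    return d


def load_session(directory) -> Session:
    """Read a plain-text session fixture back; exact float round-trip."""
    with open(os.path.join(directory, "meta.json")) as fh:
        meta = json.load(fh)
    data = np.loadtxt(
        os.path.join(directory, "signal.csv"), delimiter=",", skiprows=1
    ).T
    data = np.atleast_2d(data)
    spec_d = dict(meta["spec"])
    spec_d["ch_names"] = tuple(spec_d["ch_names"])
    spec_d["classes"] = tuple(spec_d["classes"])
    spec_d["band"] = tuple(spec_d["band"])
    spec = GeneratorSpec(**spec_d)
    return Session(
        signal=MultichannelSignal(data, meta["rate"], meta["ch_names"]),
        labels=meta["labels"],
        onsets=np.asarray(meta["onsets"]),
        trial_samples=meta["trial_samples"],
        class_covs={k: np.asarray(v) for k, v in meta["class_covs"].items()},
        spec=spec,
        session_index=meta["session_index"],
    )


def save_model(path, model: MDM, reference=None, feature_config=None) -> None:
    """Serialise a fitted MDM (prototypes, classes, reference, config) to JSON."""
    payload = {
        "classes": [str(c) for c in model.classes_],
        "prototypes": model.prototypes_.tolist(),
        "tol": model.tol,
        "max_iter": model.max_iter,
        "reference": None if reference is None else np.asarray(reference).tolist(),
        "feature_config": feature_config or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path):
    """Load a model saved by :func:`save_model`.

    Returns ``(mdm, reference, feature_config)``.
    """
    with open(path) as fh:
        payload = json.load(fh)
    model = MDM(tol=payload["tol"], max_iter=payload["max_iter"])
    model.classes_ = np.asarray(payload["classes"])
    model.prototypes_ = np.asarray(payload["prototypes"])
    model.n_features_in_ = model.prototypes_.shape[1]
    ref = payload["reference"]
    return model, (None if ref is None else np.asarray(ref)), payload["feature_config"]


def write_metrics(path, metrics: dict) -> None:
    """Write a flat metrics mapping as a two-column CSV."""
    pd.DataFrame(
        {"metric": list(metrics), "value": list(metrics.values())}
    ).to_csv(path, index=False)


def read_config(path) -> dict:
    """Parse a plain ``key = value`` config file (ints/floats auto-typed)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {line!r}")
            key, val = (part.strip() for part in line.split("=", 1))
            for cast in (int, float):
                try:
                    val = cast(val)
                    break
                except ValueError:
                    continue
            out[key] = val
    return out
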