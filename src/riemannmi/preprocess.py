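"""Band-pass filtering and cue-locked epoching of continuous EEG.

Motor-imagery activity is carried by the mu/beta band, so recordings are
band-pass filtered to 8-30 Hz with a 5th-order Butterworth prototype
(zero-phase by default) and cut into 2 s epochs 0.5-2.5 s after each cue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .spd import Trial, UNLABELLED

logger = logging.getLogger(__name__)

__all__ = ["ContinuousRecording", "bandpass", "bandpass_array", "epoch",
           "read_gdf", "read_mat_iiia"]


@dataclass
class ContinuousRecording:
    """Continuous multichannel EEG with cue events.

    ``events`` is a list of ``(sample_index, code)`` pairs.
    """

    data: np.ndarray  # (channels, samples)
    fs: float
    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        T = self.data.shape[1]
        for s, _ in self.events:
            if not 0 <= s < T:
                raise ValueError(f"event sample {s} outside recording")


def _design(low: float, high: float, order: int, fs: float):
    if not 0 < low < high < fs / 2:
        raise ValueError(
            f"band ({low}, {high}) Hz infeasible at fs={fs} Hz"
        )
    return scipy.signal.butter(order, [low, high], btype="bandpass",
                               fs=fs, output="sos")


def bandpass_array(
    data: np.ndarray,
    fs: float,
    low: float = 8.0,
    high: float = 30.0,
    order: int = 5,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth band-pass along the last axis.

    ``order`` is the prototype order (the band-pass has twice as many poles).
    Zero-phase forward-backward filtering by default; ``zero_phase=False``
    gives the causal single-pass filter.
    """
    sos = _design(low, high, order, fs)
    data = np.asarray(data, dtype=float)
    if zero_phase:
        return scipy.signal.sosfiltfilt(sos, data, axis=-1)
    return scipy.signal.sosfilt(sos, data, axis=-1)


def bandpass(
    recording: ContinuousRecording,
    low: float = 8.0,
    high: float = 30.0,
    order: int = 5,
    zero_phase: bool = True,
) -> ContinuousRecording:
    """Band-pass a recording, preserving shape and events."""
    out = bandpass_array(recording.data, recording.fs, low, high, order, zero_phase)
    return ContinuousRecording(data=out, fs=recording.fs,
                               events=list(recording.events))


def epoch(
    recording: ContinuousRecording,
    cue_events: list | None = None,
    start: float = 0.5,
    end: float = 2.5,
    label_map: dict | None = None,
) -> list[Trial]:
    """Cut cue-locked epochs ``[cue + round(start*fs), cue + round(end*fs))``.

    Half-open, 0-based indexing, so a 2 s window at 250 Hz yields exactly
    500 samples.  Cues whose window extends past the recording are skipped
    with a log message.  ``label_map`` translates event codes to class
    labels; unmapped codes become ``UNLABELLED``.
    """
    if end <= start:
        raise ValueError("epoch window must have positive length")
    events = recording.events if cue_events is None else cue_events
    fs = recording.fs
    T = recording.data.shape[1]
    i0 = int(round(start * fs))
    i1 = int(round(end * fs))
    trials = []
    for ev in events:
        sample, code = ev if isinstance(ev, (tuple, list)) else (ev, UNLABELLED)
        s0, s1 = sample + i0, sample + i1
        if s0 < 0 or s1 > T:
            logger.warning("cue at sample %d: window out of range, skipped", sample)
            continue
        label = label_map.get(code, UNLABELLED) if label_map else code
        trials.append(Trial(data=recording.data[:, s0:s1], fs=fs, label=label))
    return trials


# ---------------------------------------------------------------------------
# optional readers for the public competition distributions
# ---------------------------------------------------------------------------

#: Cue event codes of the four motor-imagery classes in the BCI Competition
#: IV 2a GDF distribution: left hand, right hand, foot, tongue.
GDF_2A_EVENTS = {"769": 0, "770": 1, "771": 2, "772": 3}


def read_gdf(path: str, drop_eog: bool = True) -> ContinuousRecording:
    """Read a GDF recording (BCI Competition IV 2a layout) via MNE.

    Requires the optional ``mne`` dependency.  The three EOG channels are
    dropped by default; annotation onsets become events with their
    description string as code.
    """
    try:
        import mne
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading GDF files requires the optional 'mne' dependency"
        ) from err
    raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    if drop_eog:
        eog = [ch for ch in raw.ch_names if "EOG" in ch.upper()]
        if eog:
            raw.drop_channels(eog)
    fs = float(raw.info["sfreq"])
    data = raw.get_data()
    events = [
        (int(round(onset * fs)), desc)
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
    ]
    return ContinuousRecording(data=data, fs=fs, events=events)


def read_mat_iiia(path: str) -> ContinuousRecording:
    """Read a BCI Competition III IIIa MAT container (biosig export layout)."""
    import scipy.io

    mat = scipy.io.loadmat(path, squeeze_me=True, struct_as_record=False)
    s = mat["s"]  # samples x channels
    h = mat["HDR"] if "HDR" in mat else mat.get("h")
    fs = float(getattr(h, "SampleRate", 250.0)) if h is not None else 250.0
    pos = np.atleast_1d(getattr(getattr(h, "EVENT", None), "POS", np.empty(0)))
    typ = np.atleast_1d(getattr(getattr(h, "EVENT", None), "TYP", np.empty(0)))
    data = np.asarray(s, dtype=float).T
    data = np.nan_to_num(data)
    events = [(int(p), int(t)) for p, t in zip(pos, typ)]
    return ContinuousRecording(data=data, fs=fs, events=events)
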