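"""Reading, filtering, windowing, labelling and class balancing of EEG.

The pipeline mirrors common practice for scalp-EEG seizure work:

* 0.5-40 Hz Butterworth band-pass (causal, forward-only) plus optional
  band-stop notches for mains interference, then per-channel mean removal
  (the mean is a per-recording statistic, i.e. an offline step -- it is the
  only non-causal element and is documented as such);
* 2-s sliding windows with 50 % overlap, giving one decision per second;
* consecutive seizures closer than ``merge_gap`` merged into one event whose
  onset is the earlier onset;
* detection label = window overlaps an ictal interval; prediction label =
  window entirely inside the preictal interval (positive) or entirely at
  least ``interictal_gap`` away from every seizure (negative), anything else
  is excluded from the prediction task;
* hybrid over/undersampling toward a target class ratio, applied to training
  data only.

EDF ingestion goes through :mod:`mne`; a minimal 16-bit EDF writer is
included so synthetic recordings can round-trip through the standard
clinical container.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import butter, lfilter

from .synthetic import Recording, SeizureEvent

__all__ = [
    "EXCLUDED",
    "FilterSpec",
    "WindowingSpec",
    "Window",
    "LabeledWindow",
    "read_recording",
    "write_edf",
    "preprocess_signal",
    "merge_seizure_events",
    "slide_windows",
    "label_windows",
    "balance_training_set",
    "stride_for_rate",
]

#: prediction label for windows covered by neither the preictal nor the
#: interictal rule (boundary straddlers, ictal/post-ictal proximity)
EXCLUDED = -1


@dataclass(frozen=True)
class FilterSpec:
    band: tuple[float, float] = (0.5, 40.0)
    notch_bands: tuple[tuple[float, float], ...] = ()
    order: int = 4
    causal: bool = True

    def validate(self, fs: float):
        lo, hi = self.band
        if not (0 < lo < hi < fs / 2):
            raise ValueError(f"band {self.band} infeasible at fs={fs}")
        for nlo, nhi in self.notch_bands:
            if not (0 < nlo < nhi < fs / 2):
                raise ValueError(f"notch band {(nlo, nhi)} infeasible at fs={fs}")


@dataclass(frozen=True)
class WindowingSpec:
    win_len: float = 2.0
    overlap: float = 0.5
    preictal_len: float = 1800.0
    interictal_gap: float = 1800.0
    merge_gap: float = 1800.0
    sph: float = 300.0
    sop: float = 1800.0

    def __post_init__(self):
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must lie in [0, 1)")
        if min(self.preictal_len, self.interictal_gap, self.merge_gap) <= 0:
            raise ValueError("preictal_len, interictal_gap, merge_gap must be > 0")

    @property
    def step(self) -> float:
        return self.win_len * (1.0 - self.overlap)


@dataclass
class Window:
    start: float
    data: np.ndarray  # (channels, win_len*fs), a view into the recording


@dataclass
class LabeledWindow:
    subject: str
    start: float
    data: np.ndarray
    det_label: int
    pred_label: int  # 0, 1, or EXCLUDED


# ------------------------------------------------------------------- EDF I/O


def read_recording(path: str | Path, montage: list[str] | None = None) -> Recording:
    """Read an EDF file; channels ordered as `montage` (all channels if empty)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    available = list(raw.ch_names)
    if montage:
        missing = [ch for ch in montage if ch not in available]
        if missing:
            raise KeyError(f"channels not present in {path.name}: {missing}")
        picks = montage
    else:
        picks = available
    data = raw.get_data(picks=picks) * 1e6  # mne returns volts
    return Recording(data=data.astype(np.float64), fs=float(raw.info["sfreq"]),
                     channel_labels=list(picks), t0=0.0)


def write_edf(rec: Recording, path: str | Path):
    """Write a Recording as a plain 16-bit EDF file (1-s data records)."""
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    n_ch = rec.n_channels
    n_total = rec.data.shape[1]
    n_rec = int(np.ceil(n_total / spr))
    padded = np.zeros((n_ch, n_rec * spr), dtype=np.float64)
    padded[:, :n_total] = rec.data

    pmin = np.floor(padded.min(axis=1))
    pmax = np.ceil(padded.max(axis=1))
    same = pmax <= pmin
    pmax[same] = pmin[same] + 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((padded - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    def f(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join([
        f("0", 8), f("X X X X", 80), f("X X X", 80),
        f("01.01.00", 8), f("00.00.00", 8),
        f(str(256 * (1 + n_ch)), 8), f("", 44),
        f(str(n_rec), 8), f("1", 8), f(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(f(lab, 16) for lab in rec.channel_labels),
        b"".join(f("synthetic EEG", 80) for _ in range(n_ch)),
        b"".join(f("uV", 8) for _ in range(n_ch)),
        b"".join(f(f"{pmin[c]:.0f}", 8) for c in range(n_ch)),
        b"".join(f(f"{pmax[c]:.0f}", 8) for c in range(n_ch)),
        b"".join(f(str(dmin), 8) for _ in range(n_ch)),
        b"".join(f(str(dmax), 8) for _ in range(n_ch)),
        b"".join(f("", 80) for _ in range(n_ch)),
        b"".join(f(str(spr), 8) for _ in range(n_ch)),
        b"".join(f("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header + sig)
        blocks = digital.reshape(n_ch, n_rec, spr)
        for r in range(n_rec):
            fh.write(blocks[:, r, :].tobytes())


# ---------------------------------------------------------------- filtering


def preprocess_signal(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Band-pass, notch band-stops, then per-channel mean subtraction."""
    spec.validate(rec.fs)
    nyq = rec.fs / 2.0
    data = np.asarray(rec.data, dtype=np.float64)
    if spec.causal:
        b, a = butter(spec.order, [spec.band[0] / nyq, spec.band[1] / nyq], "bandpass")
        data = lfilter(b, a, data, axis=1)
        for lo, hi in spec.notch_bands:
            b, a = butter(spec.order, [lo / nyq, hi / nyq], "bandstop")
            data = lfilter(b, a, data, axis=1)
    else:
        from scipy.signal import filtfilt

        b, a = butter(spec.order, [spec.band[0] / nyq, spec.band[1] / nyq], "bandpass")
        data = filtfilt(b, a, data, axis=1)
        for lo, hi in spec.notch_bands:
            b, a = butter(spec.order, [lo / nyq, hi / nyq], "bandstop")
            data = filtfilt(b, a, data, axis=1)
    # per-recording mean removal: the one offline (non-causal) step
    data = data - data.mean(axis=1, keepdims=True)
    return Recording(data=data, fs=rec.fs, channel_labels=list(rec.channel_labels),
                     t0=rec.t0)


# ----------------------------------------------------------- event handling


def merge_seizure_events(events: list[SeizureEvent], merge_gap: float = 1800.0
                         ) -> list[SeizureEvent]:
    """Merge consecutive seizures separated by less than `merge_gap` seconds.

    The merged event keeps the earliest onset (the clinically relevant one
    for prediction) and the latest offset.
    """
    if not events:
        return []
    onsets = [e.onset for e in events]
    if onsets != sorted(onsets):
        raise ValueError("events must be sorted by onset")
    for a, b in zip(events, events[1:]):
        if b.onset < a.offset:
            raise ValueError("events must be disjoint")
    merged = [events[0]]
    for ev in events[1:]:
        prev = merged[-1]
        if ev.onset - prev.offset < merge_gap:
            merged[-1] = SeizureEvent(prev.onset, max(prev.offset, ev.offset))
        else:
            merged.append(ev)
    return merged


# -------------------------------------------------------------- windowing


def slide_windows(rec: Recording, spec: WindowingSpec = WindowingSpec()
                  ) -> list[Window]:
    """Sliding windows at starts 0, step, 2*step, ... (views, no copies)."""
    n_win_samples = int(round(spec.win_len * rec.fs))
    step_samples = int(round(spec.step * rec.fs))
    n_total = rec.data.shape[1]
    if n_total < n_win_samples:
        return []
    count = (n_total - n_win_samples) // step_samples + 1
    out = []
    for i in range(count):
        s = i * step_samples
        out.append(Window(start=rec.t0 + s / rec.fs,
                          data=rec.data[:, s:s + n_win_samples]))
    return out


def label_windows(windows: list[Window], events: list[SeizureEvent],
                  spec: WindowingSpec = WindowingSpec(), subject: str = "S0"
                  ) -> list[LabeledWindow]:
    """Assign detection and prediction labels to each window.

    `events` must already be merged.  Windows are half-open intervals
    [start, start + win_len).
    """
    out = []
    for w in windows:
        w0, w1 = w.start, w.start + spec.win_len
        det = int(any(w0 < ev.offset and w1 > ev.onset for ev in events))
        pred = EXCLUDED
        if any(w0 >= ev.onset - spec.preictal_len and w1 <= ev.onset for ev in events):
            pred = 1
        elif all(w1 <= ev.onset - spec.interictal_gap or
                 w0 >= ev.offset + spec.interictal_gap for ev in events):
            pred = 0
        out.append(LabeledWindow(subject=subject, start=w.start, data=w.data,
                                 det_label=det, pred_label=pred))
    return out


def balance_training_set(windows: list[LabeledWindow], task: str,
                         ratio: float = 1.0, seed: int = 0) -> list[LabeledWindow]:
    """Hybrid resampling: oversample positives (duplication), undersample
    negatives, toward `ratio` positives per negative; training data only.

    Both classes are moved to the geometric mean of their counts (scaled by
    the target ratio), which leaves an already-balanced set unchanged.
    """
    if task not in ("detection", "prediction"):
        raise ValueError("task must be 'detection' or 'prediction'")
    label = (lambda w: w.det_label) if task == "detection" else (lambda w: w.pred_label)
    pos = [w for w in windows if label(w) == 1]
    neg = [w for w in windows if label(w) == 0]
    if not pos or not neg:
        raise ValueError(f"both classes required for balancing the {task} task")
    rng = np.random.default_rng(seed)
    mid = np.sqrt(len(pos) * len(neg))
    n_pos = max(int(round(mid * np.sqrt(ratio))), 1)
    n_neg = max(int(round(mid / np.sqrt(ratio))), 1)
    pos_idx = rng.choice(len(pos), size=n_pos, replace=n_pos > len(pos))
    neg_idx = rng.choice(len(neg), size=n_neg, replace=n_neg > len(neg))
    chosen = [pos[i] for i in pos_idx] + [neg[i] for i in neg_idx]
    order = rng.permutation(len(chosen))
    return [chosen[i] for i in order]


def stride_for_rate(fs: float, win_len: float = 2.0, n_tokens: int = 64) -> int:
    """Samples per token so that every window yields exactly `n_tokens` tokens
    regardless of sampling rate (8 at 256 Hz, 16 at 512 Hz for 2-s windows)."""
    total = fs * win_len
    if abs(total - round(total)) > 1e-9 or int(round(total)) % n_tokens != 0:
        nearest = round(total / n_tokens) * n_tokens / win_len
        raise ValueError(
            f"fs*win_len={total} not divisible by {n_tokens}; nearest valid fs is {nearest}"
        )
    return int(round(total)) // n_tokens
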