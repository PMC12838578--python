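"""Seeded synthetic multichannel EEG with interictal/preictal/ictal structure.

The generator produces the three regimes that scalp EEG shows around focal
seizures and that the downstream classifiers are meant to pick up:

* **interictal** background: 1/f ("pink") noise plus an alpha-band (8-12 Hz)
  oscillation with slowly drifting phase, partially shared across channels;
* **preictal** (default: the 30 minutes before onset): delta/theta power
  steps up at preictal onset and ramps linearly toward seizure onset, the
  alpha rhythm attenuates, and cross-channel synchrony increases;
* **ictal**: a rhythmic ~3 Hz spike-and-wave discharge (sharp biphasic spike
  followed by a half-sine slow wave each cycle) superimposed at several times
  the background amplitude.

Everything is driven by a single ``numpy`` generator seeded from the config,
so identical configs reproduce identical sample arrays bit for bit.  Units
are nominal microvolts; downstream preprocessing is zero-mean so the absolute
scale is irrelevant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import periodogram

logger = logging.getLogger(__name__)

__all__ = [
    "SynthConfig",
    "Recording",
    "SeizureEvent",
    "generate_recording",
    "generate_cohort",
    "default_schedule",
    "band_power",
]


@dataclass(frozen=True)
class SeizureEvent:
    """One annotated ictal interval, in seconds from the recording origin."""

    onset: float
    offset: float

    def __post_init__(self):
        if not (0 <= self.onset < self.offset):
            raise ValueError(f"invalid seizure interval [{self.onset}, {self.offset})")


@dataclass
class Recording:
    """Multichannel EEG: ``data`` is (channels, samples) in microvolts."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels, samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("channel count does not match channel_labels")
        if not np.isfinite(self.data).all():
            raise ValueError("Recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic cohort generator.

    ``preictal_lf_gain`` (amplitude units of ``noise_scale``), ``alpha_atten``
    (relative alpha amplitude remaining at onset), ``synchrony_rise`` and
    ``preictal_floor`` (the state-transition step at preictal onset, before
    the linear intensification toward seizure onset) parameterise the
    preictal effect envelope; none of them has an observed ground-truth
    value, they are effect sizes of the simulation.
    """

    n_channels: int = 22
    fs: float = 256.0
    duration: float = 3600.0
    seizure_schedule: tuple[tuple[float, float], ...] = ()
    preictal_len: float = 1800.0
    background_alpha_hz: tuple[float, float] = (8.0, 12.0)
    alpha_amp: float = 0.8
    spikewave_hz: float = 3.0
    spike_gain: float = 5.0
    preictal_lf_gain: float = 2.0
    preictal_floor: float = 0.5
    alpha_atten: float = 0.3
    synchrony_mix: float = 0.2
    synchrony_rise: float = 0.4
    noise_scale: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.preictal_len <= 0:
            raise ValueError("preictal_len must be positive")
        if not 0.0 <= self.synchrony_mix <= 1.0:
            raise ValueError("synchrony_mix must lie in [0, 1]")
        events = sorted(self.seizure_schedule)
        for (a0, a1), (b0, b1) in zip(events, events[1:]):
            if b0 < a1:
                raise ValueError("seizure intervals overlap")
        for onset, offset in events:
            if not (0 <= onset < offset <= self.duration):
                raise ValueError("seizure interval outside [0, duration)")

    @property
    def events(self) -> list[SeizureEvent]:
        return [SeizureEvent(on, off) for on, off in sorted(self.seizure_schedule)]


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with a 1/f power spectrum (spectral exponent 1)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _drifting_tone(n: int, fs: float, freq: float, rng: np.random.Generator,
                   drift: float = 0.05) -> np.ndarray:
    """Sinusoid with a random phase walk (no long-range phase locking)."""
    phase = 2 * np.pi * freq * np.arange(n) / fs + np.cumsum(rng.normal(0.0, drift, n))
    return np.sin(phase)


def _spike_wave_cycle(fs: float, freq: float) -> np.ndarray:
    """One spike-and-wave cycle: sharp biphasic spike then half-sine slow wave."""
    n_cycle = max(int(round(fs / freq)), 4)
    n_spike = max(int(round(0.07 * fs)), 2)
    cycle = np.zeros(n_cycle)
    half = n_spike // 2 or 1
    cycle[:half] = np.linspace(0.0, 1.0, half, endpoint=False)
    cycle[half:n_spike] = np.linspace(1.0, -0.4, n_spike - half)
    n_wave = n_cycle - n_spike
    # large slow wave so the train's fundamental dominates its spectrum
    cycle[n_spike:] = 1.1 * np.sin(np.pi * np.arange(n_wave) / max(n_wave, 1))
    return cycle - cycle.mean()


def _ramp_profile(cfg: SynthConfig, t: np.ndarray) -> np.ndarray:
    """Preictal ramp r(t) in [0, 1]: 0 far from onset, 1 at each onset."""
    r = np.zeros_like(t)
    for ev in cfg.events:
        start = ev.onset - cfg.preictal_len
        if start < 0:
            logger.warning(
                "preictal window of seizure at %.1f s truncated at recording start",
                ev.onset,
            )
        seg = (t >= start) & (t < ev.onset)
        r[seg] = np.maximum(r[seg], (t[seg] - start) / cfg.preictal_len)
    return r


def generate_recording(cfg: SynthConfig) -> tuple[Recording, list[SeizureEvent]]:
    """Generate one synthetic recording plus its seizure annotations."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    ramp = _ramp_profile(cfg, t)

    # the preictal regime is a state transition plus intensification: the
    # effect envelope jumps to `preictal_floor` at preictal onset and ramps
    # linearly to 1 toward seizure onset
    eff = np.where(ramp > 0, cfg.preictal_floor + (1.0 - cfg.preictal_floor) * ramp, 0.0)

    # time-varying mixing weight of the shared latent source (synchrony)
    mix = np.clip(cfg.synchrony_mix + eff * cfg.synchrony_rise, 0.0, 1.0)
    shared = _pink_noise(n, rng)
    alpha_freq = rng.uniform(*cfg.background_alpha_hz)
    alpha_env = 1.0 - eff * (1.0 - cfg.alpha_atten)

    # shared preictal slow activity (delta + theta), amplitude follows eff(t)
    lf = 0.6 * _drifting_tone(n, cfg.fs, 2.0, rng) + 0.4 * _drifting_tone(n, cfg.fs, 5.5, rng)
    lf_env = eff * cfg.preictal_lf_gain

    # ictal spike-wave train, common to all channels
    ictal = np.zeros(n)
    cycle = _spike_wave_cycle(cfg.fs, cfg.spikewave_hz)
    for ev in cfg.events:
        i0, i1 = int(round(ev.onset * cfg.fs)), int(round(ev.offset * cfg.fs))
        seg_len = i1 - i0
        reps = int(np.ceil(seg_len / len(cycle)))
        ictal[i0:i1] = np.tile(cycle, reps)[:seg_len]
    spike_amp = cfg.spike_gain * cfg.noise_scale

    data = np.empty((cfg.n_channels, n), dtype=np.float32)
    for c in range(cfg.n_channels):
        private = _pink_noise(n, rng)
        background = np.sqrt(1.0 - mix) * private + np.sqrt(mix) * shared
        alpha = cfg.alpha_amp * alpha_env * _drifting_tone(n, cfg.fs, alpha_freq, rng)
        chan_gain = rng.uniform(0.9, 1.1)
        data[c] = (
            cfg.noise_scale * (background + alpha + lf_env * lf)
            + spike_amp * chan_gain * ictal
        ).astype(np.float32)

    labels = [f"SYN{c:02d}" for c in range(cfg.n_channels)]
    rec = Recording(data=data, fs=cfg.fs, channel_labels=labels, t0=0.0)
    return rec, cfg.events


def default_schedule(duration: float, n_seizures: int = 3,
                     ictal_len: float = 30.0, tail: float = 60.0
                     ) -> tuple[tuple[float, float], ...]:
    """Evenly spaced seizures, each at the end of its cycle so that a full
    preictal ramp and an interictal stretch fit before it."""
    cycle = duration / n_seizures
    if cycle <= ictal_len + tail:
        raise ValueError("duration too short for the requested seizure count")
    schedule = []
    for i in range(n_seizures):
        offset = (i + 1) * cycle - tail
        schedule.append((offset - ictal_len, offset))
    return tuple(schedule)


def generate_cohort(n_subjects: int, base_cfg: SynthConfig, seed: int
                    ) -> list[tuple[Recording, list[SeizureEvent]]]:
    """Generate a cohort with per-subject jitter of amplitudes and frequencies.

    Every subject gets at least three seizures by default, mirroring the usual
    inclusion rule for per-patient evaluation.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    master = np.random.default_rng(seed)
    cohort = []
    for _ in range(n_subjects):
        sub_rng = np.random.default_rng(master.integers(2**31 - 1))
        schedule = base_cfg.seizure_schedule or default_schedule(base_cfg.duration)
        lo, hi = base_cfg.background_alpha_hz
        shift = sub_rng.uniform(-0.5, 0.5)
        cfg = replace(
            base_cfg,
            seizure_schedule=tuple(schedule),
            background_alpha_hz=(lo + shift, hi + shift),
            spikewave_hz=base_cfg.spikewave_hz + sub_rng.uniform(-0.25, 0.25),
            noise_scale=base_cfg.noise_scale * sub_rng.uniform(0.85, 1.15),
            preictal_lf_gain=base_cfg.preictal_lf_gain * sub_rng.uniform(0.9, 1.1),
            seed=int(sub_rng.integers(2**31 - 1)),
        )
        cohort.append(generate_recording(cfg))
    return cohort


def band_power(rec: Recording, channel: int, band: tuple[float, float],
               span: tuple[float, float]) -> float:
    """Mean periodogram power of one channel in `band` (Hz) over `span` (s)."""
    lo, hi = band
    if not (0 < lo < hi < rec.fs / 2):
        raise ValueError("band must lie within (0, fs/2)")
    i0 = int(round((span[0] - rec.t0) * rec.fs))
    i1 = int(round((span[1] - rec.t0) * rec.fs))
    if not (0 <= i0 < i1 <= rec.data.shape[1]):
        raise ValueError("span outside recording or empty")
    f, pxx = periodogram(rec.data[channel, i0:i1], fs=rec.fs)
    sel = (f >= lo) & (f <= hi)
    if not sel.any():
        raise ValueError("band contains no periodogram bins for this span")
    return float(pxx[sel].mean())
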