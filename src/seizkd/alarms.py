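"""Causal alarm post-processing.

Prediction alarms use k-of-n voting with a refractory period: an alarm
fires at the first window where at least ``k`` of the most recent ``n``
window decisions are positive, and further alarms are suppressed for
``refractory`` seconds.  Detection alarms use a trailing moving average of
the detection probability over ``smooth_len`` seconds compared against a
threshold, which filters transient single-window spikes.

Both operators are strictly causal and deterministic; windows flagged as
model warm-up are never counted as positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AlarmPolicy", "kofn_alarms", "smooth_detection_alarms"]


@dataclass(frozen=True)
class AlarmPolicy:
    k: int = 8
    n: int = 10
    prob_threshold: float = 0.5
    refractory: float = 1800.0
    smooth_len: float = 5.0
    det_threshold: float = 0.5

    def __post_init__(self):
        if not 1 <= self.k <= self.n:
            raise ValueError("need 1 <= k <= n")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")


def kofn_alarms(probs: np.ndarray, times: np.ndarray,
                policy: AlarmPolicy = AlarmPolicy(),
                warm_up: np.ndarray | None = None) -> list[float]:
    """Alarm timestamps from a time-ordered probability stream.

    A window is positive iff its probability is >= `prob_threshold` and it
    is not a warm-up window.  Fewer than `n` windows yield no alarms.
    """
    probs = np.asarray(probs, float)
    times = np.asarray(times, float)
    if len(probs) != len(times):
        raise ValueError("probs and times must have equal length")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be non-decreasing")
    pos = probs >= policy.prob_threshold
    if warm_up is not None:
        pos = pos & ~np.asarray(warm_up, bool)
    alarms: list[float] = []
    last_alarm = -np.inf
    count = 0
    for i in range(len(pos)):
        count += int(pos[i])
        if i >= policy.n:
            count -= int(pos[i - policy.n])
        if i >= policy.n - 1 and count >= policy.k:
            if times[i] - last_alarm >= policy.refractory:
                alarms.append(float(times[i]))
                last_alarm = times[i]
    return alarms


def smooth_detection_alarms(probs: np.ndarray, times: np.ndarray,
                            policy: AlarmPolicy = AlarmPolicy()
                            ) -> list[tuple[float, float]]:
    """Detection alarm intervals from the smoothed probability stream.

    The trailing average over the `smooth_len`-second span must exceed
    `det_threshold` to open an interval; it closes when the average falls
    back.  The average is only defined once a full span is available, so an
    isolated single-window spike cannot trigger.
    """
    probs = np.asarray(probs, float)
    times = np.asarray(times, float)
    if len(probs) == 0:
        return []
    if len(times) > 1:
        dt = float(np.median(np.diff(times)))
    else:
        dt = 1.0
    span = max(int(round(policy.smooth_len / dt)), 1)
    intervals: list[tuple[float, float]] = []
    open_t: float | None = None
    run = np.convolve(probs, np.ones(span) / span, mode="valid")
    for j, avg in enumerate(run):
        t = times[j + span - 1]
        if avg > policy.det_threshold and open_t is None:
            open_t = t
        elif avg <= policy.det_threshold and open_t is not None:
            intervals.append((open_t, t))
            open_t = None
    if open_t is not None:
        intervals.append((open_t, float(times[-1]) + dt))
    return intervals
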