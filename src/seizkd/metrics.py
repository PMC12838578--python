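"""Evaluation statistics for seizure prediction and detection.

Prediction follows the SPH/SOP convention: after an alarm, a seizure
prediction horizon (SPH, default 5 min) must elapse before the seizure
occurrence period (SOP, default 30 min) opens; an alarm is valid iff some
seizure onset falls inside its SOP.  Sensitivity is the fraction of
seizure events hit by at least one valid alarm, and FPR/h is the number of
invalid alarms divided by the full, unedited test duration in hours.

Statistical significance against an unspecific random predictor uses the
standard Poisson-alarm construction: the chance of a random alarm process
with the model's FPR hitting one SOP is ``P = 1 - exp(-FPR*SOP)``, and the
p-value is the binomial tail probability of achieving at least the
observed number of hits across all events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.metrics import roc_auc_score

from .alarms import AlarmPolicy, kofn_alarms
from .synthetic import SeizureEvent

__all__ = [
    "EvalProtocol",
    "MetricsReport",
    "evaluate_prediction",
    "roc_auc",
    "random_predictor_pvalue",
    "evaluate_detection",
    "loocv_folds",
    "sweep_policy",
]


@dataclass(frozen=True)
class EvalProtocol:
    sph: float = 300.0     # seizure prediction horizon, s
    sop: float = 1800.0    # seizure occurrence period, s
    alpha: float = 0.05

    def __post_init__(self):
        if self.sph < 0 or self.sop <= 0:
            raise ValueError("need sph >= 0 and sop > 0")


@dataclass
class MetricsReport:
    task: str
    auc: float = np.nan
    sen: float = np.nan
    fpr_h: float = np.nan
    acc: float = np.nan
    spe: float = np.nan
    p_value: float = np.nan
    significant: bool = False
    per_subject: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "task": self.task, "auc": self.auc, "sen": self.sen,
            "fpr_h": self.fpr_h, "acc": self.acc, "spe": self.spe,
            "p_value": self.p_value, "significant": bool(self.significant),
        }


def evaluate_prediction(alarms: list[float], events: list[SeizureEvent],
                        protocol: EvalProtocol = EvalProtocol(),
                        duration_hours: float = 1.0
                        ) -> tuple[float | None, float, pd.DataFrame]:
    """Sensitivity, FPR/h and a per-alarm table under the SPH/SOP rule.

    An alarm at time `a` is valid iff some event onset lies in
    [a + sph, a + sph + sop); a valid alarm targets only the nearest such
    onset.  With zero events sensitivity is undefined (returned as None).
    """
    if duration_hours <= 0:
        raise ValueError("duration_hours must be positive")
    rows = []
    hit = set()
    n_invalid = 0
    for a in sorted(alarms):
        lo, hi = a + protocol.sph, a + protocol.sph + protocol.sop
        candidates = [(ev.onset - a, i) for i, ev in enumerate(events)
                      if lo <= ev.onset < hi]
        if candidates:
            _, target = min(candidates)
            hit.add(target)
            rows.append({"alarm_s": a, "valid": True, "event": target})
        else:
            n_invalid += 1
            rows.append({"alarm_s": a, "valid": False, "event": -1})
    table = pd.DataFrame(rows, columns=["alarm_s", "valid", "event"])
    sen = len(hit) / len(events) if events else None
    return sen, n_invalid / duration_hours, table


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC with midrank tie handling."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def random_predictor_pvalue(fpr_h: float, sop_hours: float, n_events: int,
                            n_hits: int, alpha: float = 0.05
                            ) -> tuple[float, bool]:
    """Binomial-tail probability that a chance-level alarm process does at
    least as well as the model; significant iff p < alpha."""
    if fpr_h < 0 or not 0 <= n_hits <= n_events:
        raise ValueError("invalid arguments")
    p_chance = 1.0 - np.exp(-fpr_h * sop_hours)
    p = float(binom.sf(n_hits - 1, n_events, p_chance))
    return p, p < alpha


def evaluate_detection(labels: np.ndarray, probs: np.ndarray,
                       det_threshold: float = 0.5) -> dict:
    """Window-level detection metrics at the given operating threshold.

    Computed on the evaluation partition as-is (never rebalanced).
    """
    labels = np.asarray(labels).astype(int)
    probs = np.asarray(probs, float)
    pred = (probs >= det_threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    out = {
        "acc": (tp + tn) / max(len(labels), 1),
        "sen": tp / (tp + fn) if (tp + fn) else np.nan,
        "spe": tn / (tn + fp) if (tn + fp) else np.nan,
    }
    try:
        out["auc"] = roc_auc(labels, probs)
    except ValueError:
        out["auc"] = np.nan
    return out


def loocv_folds(pairs: list) -> list[tuple[list, object]]:
    """Leave-one-pair-out folds: every pair is the test pair exactly once."""
    if len(pairs) < 2:
        raise ValueError("leave-one-pair-out needs at least 2 pairs")
    return [([p for j, p in enumerate(pairs) if j != i], pairs[i])
            for i in range(len(pairs))]


def sweep_policy(subject_streams: dict[str, dict],
                 k_values: list[int], rp_values: list[float],
                 base_policy: AlarmPolicy = AlarmPolicy(),
                 protocol: EvalProtocol = EvalProtocol()) -> pd.DataFrame:
    """Re-apply k-of-n voting over a (k, refractory) grid on fixed model
    output streams, without re-running the model.

    `subject_streams` maps subject -> dict with keys ``probs``, ``times``,
    optionally ``warm_up``, plus ``events`` (merged SeizureEvents) and
    ``duration_hours``.  Returns per-setting mean +- sd of sensitivity and
    FPR/h across subjects.
    """
    rows = []
    for k in k_values:
        for rp in rp_values:
            policy = AlarmPolicy(k=k, n=base_policy.n,
                                 prob_threshold=base_policy.prob_threshold,
                                 refractory=rp,
                                 smooth_len=base_policy.smooth_len,
                                 det_threshold=base_policy.det_threshold)
            sens, fprs = [], []
            for subj, sd in subject_streams.items():
                alarms = kofn_alarms(sd["probs"], sd["times"], policy,
                                     sd.get("warm_up"))
                sen, fpr_h, _ = evaluate_prediction(
                    alarms, sd["events"], protocol, sd["duration_hours"])
                if sen is not None:
                    sens.append(sen)
                fprs.append(fpr_h)
            rows.append({
                "k": k, "rp_s": rp,
                "mean_sen": float(np.mean(sens)) if sens else np.nan,
                "sd_sen": float(np.std(sens)) if sens else np.nan,
                "mean_fpr_h": float(np.mean(fprs)),
                "sd_fpr_h": float(np.std(fprs)),
            })
    return pd.DataFrame(rows)
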