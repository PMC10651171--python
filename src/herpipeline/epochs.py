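"""Stimulus-locked and heartbeat-locked epoching, contrasts and summaries.

Epoch windows are half-open in samples: [lock, lock + L).  ERP epochs are
1000 ms from the 5th-sound onset, heartbeat-evoked (HER) epochs 500 ms
from the R-peak.  No baseline correction is applied by default — HER
baselines are contaminated by the preceding stimulus.

Candidate epochs are screened in a fixed order and carry exactly one
primary rejection code:

STIM20MS  5th sound within 20 ms of the nearest R-peak (either direction)
IBI500    lock R-peak's preceding or following interbeat interval < 500 ms
ECTOPIC   lock R-peak bounds an interval flagged as ectopic
AMP300    any channel exceeds 300 uV inside the epoch
EDGE      epoch would overrun the recording (or the trial has no lock beat)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .cardiac import HeartbeatSeries
from .core_io import Condition, Group, Recording
from .stats import rank_sum_z

__all__ = [
    "LockType",
    "RejectReason",
    "EpochSet",
    "EffectMap",
    "EffectLevel",
    "SignalKind",
    "epoch_stimulus",
    "epoch_heartbeat_post_stimulus",
    "epoch_all_heartbeats",
    "subject_effect",
    "her_summary_whole_protocol",
    "latency_balance_test",
]


class LockType(str, Enum):
    STIMULUS_5TH = "STIMULUS_5TH"
    RPEAK_POST_5TH = "RPEAK_POST_5TH"
    RPEAK_ALL = "RPEAK_ALL"


class RejectReason(str, Enum):
    STIM20MS = "STIM20MS"
    IBI500 = "IBI500"
    ECTOPIC = "ECTOPIC"
    AMP300 = "AMP300"
    EDGE = "EDGE"


class SignalKind(str, Enum):
    ERP = "ERP"
    HER = "HER"


class EffectLevel(str, Enum):
    LOCAL = "LOCAL"
    GLOBAL = "GLOBAL"


@dataclass
class EpochSet:
    """Accepted epochs plus the full disposition log of all candidates."""

    data: np.ndarray  # (n_epochs, n_channels, n_times) uV
    lock: LockType
    fs: float
    epoch_length_ms: float
    conditions: list[Condition | None]
    lock_samples: np.ndarray          # per accepted epoch
    rejection_log: list[dict] = field(default_factory=list)
    # per accepted HER epoch: latency from 5th sound to lock R-peak (ms)
    lock_latency_ms: np.ndarray | None = None

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def n_rejected(self, reason: RejectReason | None = None) -> int:
        rej = [r for r in self.rejection_log if not r["accepted"]]
        if reason is None:
            return len(rej)
        return sum(1 for r in rej if r["reason"] == reason.value)


@dataclass
class EffectMap:
    """Per-subject deviant-minus-standard contrast map."""

    subject_id: str
    signal: SignalKind
    level: EffectLevel
    map: np.ndarray  # (n_channels, n_times) uV
    n_deviant_epochs: int
    n_standard_epochs: int
    group: Group = Group.UNKNOWN


def _epoch_samples(epoch_length_ms: float, fs: float) -> int:
    return int(round(epoch_length_ms / 1000.0 * fs))


def _fifth_sounds(recording: Recording):
    return sorted(
        (e for e in recording.events if e.sound_index == 5),
        key=lambda e: e.onset_sample,
    )


def epoch_stimulus(
    recording: Recording,
    amp_reject_uv: float = 300.0,
    epoch_length_ms: float = 1000.0,
) -> EpochSet:
    """One candidate ERP epoch per trial, locked at the 5th-sound onset."""
    L = _epoch_samples(epoch_length_ms, recording.fs)
    data, conds, locks, log = [], [], [], []
    for ev in _fifth_sounds(recording):
        entry = {"trial_id": ev.trial_id, "lock_sample": ev.onset_sample,
                 "condition": ev.condition.value, "accepted": False, "reason": None}
        seg = recording.eeg[:, ev.onset_sample:ev.onset_sample + L]
        if np.abs(seg).max(initial=0.0) > amp_reject_uv:
            entry["reason"] = RejectReason.AMP300.value
        elif ev.onset_sample + L > recording.n_samples:
            entry["reason"] = RejectReason.EDGE.value
        else:
            entry["accepted"] = True
            data.append(seg)
            conds.append(ev.condition)
            locks.append(ev.onset_sample)
        log.append(entry)
    if not data:
        raise ValueError("no stimulus-locked epochs survived rejection")
    return EpochSet(
        data=np.stack(data), lock=LockType.STIMULUS_5TH, fs=recording.fs,
        epoch_length_ms=epoch_length_ms, conditions=conds,
        lock_samples=np.asarray(locks), rejection_log=log,
    )


def _her_candidate(
    recording: Recording,
    hb: HeartbeatSeries,
    lock_idx: int,
    L: int,
    amp_reject_uv: float,
    ibi_floor_ms: float,
    stim_guard_ms: float | None,
    stim_sample: int | None,
) -> tuple[str | None, np.ndarray | None]:
    """Screen one heartbeat-locked candidate; returns (reason, segment)."""
    peaks = hb.rpeak_samples
    lock = int(peaks[lock_idx])
    # STIM20MS: stimulus within the guard of its nearest R-peak
    if stim_guard_ms is not None and stim_sample is not None:
        nearest = np.abs(peaks - stim_sample).min() * 1000.0 / hb.fs
        if nearest < stim_guard_ms:
            return RejectReason.STIM20MS.value, None
    # IBI500: preceding or following interbeat interval too short
    ibi = hb.ibi_ms
    if lock_idx >= 1 and ibi[lock_idx - 1] < ibi_floor_ms:
        return RejectReason.IBI500.value, None
    if lock_idx < len(ibi) and ibi[lock_idx] < ibi_floor_ms:
        return RejectReason.IBI500.value, None
    # ECTOPIC: lock beat bounds a flagged interval
    prev_f, next_f = hb.ibi_flags_around(lock_idx)
    if prev_f or next_f:
        return RejectReason.ECTOPIC.value, None
    # AMP300 on the available extent, then EDGE
    seg = recording.eeg[:, lock:lock + L]
    if np.abs(seg).max(initial=0.0) > amp_reject_uv:
        return RejectReason.AMP300.value, None
    if lock + L > recording.n_samples:
        return RejectReason.EDGE.value, None
    return None, seg


def epoch_heartbeat_post_stimulus(
    recording: Recording,
    hb: HeartbeatSeries,
    amp_reject_uv: float = 300.0,
    ibi_floor_ms: float = 500.0,
    stim_guard_ms: float = 20.0,
    epoch_length_ms: float = 500.0,
) -> EpochSet:
    """One HER candidate per trial: first R-peak strictly after the 5th sound."""
    L = _epoch_samples(epoch_length_ms, recording.fs)
    peaks = hb.rpeak_samples
    data, conds, locks, lats, log = [], [], [], [], []
    for ev in _fifth_sounds(recording):
        entry = {"trial_id": ev.trial_id, "stim_sample": ev.onset_sample,
                 "condition": ev.condition.value, "accepted": False,
                 "reason": None, "lock_sample": None}
        i = int(np.searchsorted(peaks, ev.onset_sample, side="right"))
        if i >= len(peaks):
            entry["reason"] = RejectReason.EDGE.value  # trial has no lock beat
            log.append(entry)
            continue
        entry["lock_sample"] = int(peaks[i])
        reason, seg = _her_candidate(
            recording, hb, i, L, amp_reject_uv, ibi_floor_ms,
            stim_guard_ms, ev.onset_sample,
        )
        if reason is not None:
            entry["reason"] = reason
        else:
            entry["accepted"] = True
            data.append(seg)
            conds.append(ev.condition)
            locks.append(int(peaks[i]))
            lats.append((peaks[i] - ev.onset_sample) * 1000.0 / recording.fs)
        log.append(entry)
    if not data:
        raise ValueError("no heartbeat-locked epochs survived rejection")
    return EpochSet(
        data=np.stack(data), lock=LockType.RPEAK_POST_5TH, fs=recording.fs,
        epoch_length_ms=epoch_length_ms, conditions=conds,
        lock_samples=np.asarray(locks), rejection_log=log,
        lock_latency_ms=np.asarray(lats),
    )


def epoch_all_heartbeats(
    recording: Recording,
    hb: HeartbeatSeries,
    amp_reject_uv: float = 300.0,
    ibi_floor_ms: float = 500.0,
    epoch_length_ms: float = 500.0,
) -> EpochSet:
    """One candidate per R-peak over the whole protocol; no stimulus guard."""
    L = _epoch_samples(epoch_length_ms, recording.fs)
    data, locks, log = [], [], []
    for i in range(len(hb.rpeak_samples)):
        lock = int(hb.rpeak_samples[i])
        entry = {"lock_sample": lock, "accepted": False, "reason": None}
        reason, seg = _her_candidate(
            recording, hb, i, L, amp_reject_uv, ibi_floor_ms, None, None
        )
        if reason is not None:
            entry["reason"] = reason
        else:
            entry["accepted"] = True
            data.append(seg)
            locks.append(lock)
        log.append(entry)
    if not data:
        raise ValueError("no whole-protocol heartbeat epochs survived rejection")
    return EpochSet(
        data=np.stack(data), lock=LockType.RPEAK_ALL, fs=recording.fs,
        epoch_length_ms=epoch_length_ms,
        conditions=[None] * len(data),
        lock_samples=np.asarray(locks), rejection_log=log,
    )


# ---------------------------------------------------------------------------
# Contrasts and summaries
# ---------------------------------------------------------------------------

_LOCAL_DEVIANT = (Condition.LDGS, Condition.LDGD)
_LOCAL_STANDARD = (Condition.LSGS, Condition.LSGD)
_GLOBAL_DEVIANT = (Condition.LSGD, Condition.LDGD)
_GLOBAL_STANDARD = (Condition.LSGS, Condition.LDGS)


def subject_effect(
    epochs: EpochSet,
    level: EffectLevel,
    subject_id: str = "",
    group: Group = Group.UNKNOWN,
    pooling: str = "epochs",
) -> EffectMap:
    """Deviant-minus-standard contrast map.

    LOCAL: pooled mean over {LDGS, LDGD} minus pooled mean over
    {LSGS, LSGD}; GLOBAL: {LSGD, LDGD} minus {LSGS, LDGS}.  Pooling is
    epoch-weighted by default (``pooling='epochs'``); the alternative
    ``'conditions'`` averages the two condition means.
    """
    if epochs.lock == LockType.RPEAK_ALL:
        raise ValueError("whole-protocol epochs carry no conditions to contrast")
    dev_set = _LOCAL_DEVIANT if level == EffectLevel.LOCAL else _GLOBAL_DEVIANT
    std_set = _LOCAL_STANDARD if level == EffectLevel.LOCAL else _GLOBAL_STANDARD
    conds = np.asarray([c.value for c in epochs.conditions])

    def side_mean(members: tuple[Condition, Condition]) -> tuple[np.ndarray, int]:
        sel = np.isin(conds, [m.value for m in members])
        if not sel.any():
            raise ValueError(
                f"contrast side empty: no epochs in conditions {[m.value for m in members]}"
            )
        if pooling == "epochs":
            return epochs.data[sel].mean(axis=0), int(sel.sum())
        means = [
            epochs.data[conds == m.value].mean(axis=0)
            for m in members
            if (conds == m.value).any()
        ]
        return np.mean(means, axis=0), int(sel.sum())

    dev_mean, n_dev = side_mean(dev_set)
    std_mean, n_std = side_mean(std_set)
    signal = SignalKind.ERP if epochs.lock == LockType.STIMULUS_5TH else SignalKind.HER
    return EffectMap(
        subject_id=subject_id, signal=signal, level=level,
        map=dev_mean - std_mean,
        n_deviant_epochs=n_dev, n_standard_epochs=n_std, group=group,
    )


def her_summary_whole_protocol(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Mean and unbiased variance maps across all whole-protocol epochs."""
    if epochs.n_epochs < 2:
        raise ValueError("need at least 2 epochs for a variance map")
    return epochs.data.mean(axis=0), epochs.data.var(axis=0, ddof=1)


def latency_balance_test(
    latencies_by_subject: dict[str, dict[str, float]],
    groups: dict[str, Group],
) -> dict[str, tuple[float, float]]:
    """Group comparison of stimulus-to-lock-beat latencies.

    ``latencies_by_subject`` maps subject id -> {'local_standard': ms, ...}
    (subject-mean latency from the 5th sound to the lock R-peak, split by
    the four condition groupings).  Returns per grouping the unpaired
    rank-sum (Z, two-sided p) for MCS vs UWS — the control that any
    heartbeat-evoked group difference is not a latency artifact.
    """
    keys = ["local_standard", "local_deviant", "global_standard", "global_deviant"]
    mcs_ids = [s for s, g in groups.items() if g == Group.MCS]
    uws_ids = [s for s, g in groups.items() if g == Group.UWS]
    if len(mcs_ids) < 2 or len(uws_ids) < 2:
        raise ValueError("need at least 2 subjects per group")
    out: dict[str, tuple[float, float]] = {}
    for key in keys:
        a = np.array([latencies_by_subject[s][key] for s in mcs_ids])
        b = np.array([latencies_by_subject[s][key] for s in uws_ids])
        out[key] = rank_sum_z(a, b)
    return out


def condition_latency_means(epochs: EpochSet) -> dict[str, float]:
    """Subject-mean 5th-sound-to-lock latency per condition grouping (ms)."""
    if epochs.lock_latency_ms is None:
        raise ValueError("epochs carry no lock latencies")
    conds = epochs.conditions
    lat = epochs.lock_latency_ms
    sel = {
        "local_standard": [c in _LOCAL_STANDARD for c in conds],
        "local_deviant": [c in _LOCAL_DEVIANT for c in conds],
        "global_standard": [c in _GLOBAL_STANDARD for c in conds],
        "global_deviant": [c in _GLOBAL_DEVIANT for c in conds],
    }
    return {k: float(lat[np.asarray(v)].mean()) if any(v) else float("nan")
            for k, v in sel.items()}
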