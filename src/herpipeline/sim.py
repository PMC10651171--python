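"""Synthetic local-global cohorts with ground truth.

The generator emulates the recording situation the pipeline was designed
for: 250 Hz EEG on a hemispherical sensor cap, a cardiac field artifact
mixed across channels from a single ECG-like source, the XX/XY block
structure with ~80/20 frequent/rare trials, and group-dependent
stimulus-locked (ERP) and heartbeat-locked (HER) evoked components.

Planted deviant-minus-standard effects are rectangular pulses over a
channel set x latency window, so the expected subject-level effect map
equals the configured amplitude inside the window and zero outside —
a ground truth that downstream contrasts and cluster statistics can be
checked against analytically.

Group semantics (fully conscious processing vs none):

* MCS-like subjects carry local and global effects at full amplitude and
  an inflated trial-to-trial heartbeat-response variability.
* UWS-like subjects carry local effects at half amplitude and no global
  effect.
* CONTROL subjects behave like MCS but record half the number of blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .core_io import (
    AuditoryEvent,
    BlockType,
    Condition,
    Group,
    Recording,
    SensorLayout,
    save_json,
    write_recording,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "hemispherical_layout",
    "generate_event_stream",
    "simulate_cardiac",
    "simulate_subject",
    "simulate_cohort",
    "simulate_effect_maps",
    "simulate_feature_table",
]


@dataclass
class EffectSpec:
    """One planted deviant-minus-standard component."""

    amp_uv: float
    window_ms: tuple[float, float]
    n_channels: int = 8           # contiguous patch size
    center_channel: int = 0       # patch seed; neighbours by distance


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Timing defaults are the paradigm constants: five 50 ms tones per trial
    at a 150 ms stimulus-onset asynchrony, intertrial interval uniform in
    1350-1650 ms; ~90 trials make a block of roughly 200 s.  Patients get
    2 XX + 2 XY blocks, controls half of that.
    """

    n_mcs: int = 3
    n_uws: int = 3
    n_control: int = 0
    n_blocks_xx: int = 2
    n_blocks_xy: int = 2
    trials_per_block: int = 90
    fs: float = 250.0
    n_channels: int = 64
    rare_fraction: float = 0.2
    tone_duration_ms: float = 50.0
    soa_ms: float = 150.0
    iti_range_ms: tuple[float, float] = (1350.0, 1650.0)
    rr_mean_ms: float = 800.0
    rr_sd_ms: float = 50.0
    artifact_gain: float = 75.0   # uV, peak cardiac field amplitude at the worst
                                  # channel — high-density nets with inferior
                                  # (face/neck) sensors see large cardiac fields
    noise_sd_uv: float = 10.0     # per-sample noise sd after AR shaping
    noise_ar: float = 0.9         # AR(1) coefficient; 0 -> white noise
    # volume conduction: share of noise variance common across the cap,
    # smoothed over the sensor positions at this length scale
    noise_spatial_share: float = 0.93
    noise_spatial_scale_cm: float = 10.0
    # planted deviant-minus-standard effects (windows relative to lock point)
    erp_local: EffectSpec = field(default_factory=lambda: EffectSpec(5.0, (236.0, 328.0), 8, 0))
    erp_global: EffectSpec = field(default_factory=lambda: EffectSpec(5.0, (800.0, 850.0), 8, 0))
    her_local: EffectSpec = field(default_factory=lambda: EffectSpec(5.0, (400.0, 412.0), 8, 40))
    her_global: EffectSpec = field(default_factory=lambda: EffectSpec(5.0, (112.0, 130.0), 8, 40))
    uws_local_scale: float = 0.5  # UWS local amplitude relative to MCS
    her_trial_variance_ratio: float = 2.0  # MCS vs UWS heartbeat-response variability (sd ratio)
    her_var_sd_uv: float = 3.0    # baseline per-beat random HER amplitude sd (UWS level)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.rare_fraction < 1.0:
            raise ValueError("rare_fraction must lie strictly between 0 and 1")
        if self.iti_range_ms[0] > self.iti_range_ms[1]:
            raise ValueError("iti_range_ms must be ordered")
        if self.rr_sd_ms < 0:
            raise ValueError("rr_sd_ms must be non-negative")


@dataclass
class GroundTruth:
    """Simulation oracle for one subject."""

    true_rpeak_samples: np.ndarray
    cardiac_mixing: np.ndarray                 # per-channel weights
    planted_effect_windows: dict[str, dict]    # key: 'erp_local', ... value: channels/window/amp
    group: Group


# ---------------------------------------------------------------------------
# Sensor layout
# ---------------------------------------------------------------------------

def hemispherical_layout(n_channels: int = 64, radius_cm: float = 9.0) -> SensorLayout:
    """Quasi-uniform sensor positions on the upper hemisphere.

    Fibonacci-spiral placement gives realistic ~3-4 cm nearest-neighbour
    spacing at 64 sensors on a 9 cm head radius.
    """
    k = np.arange(n_channels)
    golden = (1 + 5 ** 0.5) / 2
    z = k / max(n_channels - 1, 1)             # hemisphere: z in [0, 1]
    theta = 2 * np.pi * k / golden
    r_xy = np.sqrt(np.clip(1 - z ** 2, 0, None))
    pos = radius_cm * np.column_stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z])
    names = [f"E{i + 1}" for i in range(n_channels)]
    return SensorLayout(names, pos)


def grid_layout(n_rows: int, n_cols: int, spacing_cm: float = 3.0) -> SensorLayout:
    """Planar sensor grid; 3 cm spacing keeps orthogonal neighbours inside
    the 4 cm neighbourhood while diagonals (4.24 cm) fall outside."""
    names = [f"G{r}_{c}" for r in range(n_rows) for c in range(n_cols)]
    pos = np.array([[r * spacing_cm, c * spacing_cm, 0.0]
                    for r in range(n_rows) for c in range(n_cols)])
    return SensorLayout(names, pos)


def contiguous_patch(layout: SensorLayout, center: int, k: int) -> np.ndarray:
    """Indices of the k channels nearest to ``center`` (inclusive)."""
    center = min(center, len(layout) - 1)
    d = np.linalg.norm(layout.positions - layout.positions[center], axis=1)
    return np.argsort(d)[:min(k, len(layout))]


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

def generate_event_stream(
    block_type: BlockType,
    trials_per_block: int,
    rare_fraction: float,
    fs: float = 250.0,
    soa_ms: float = 150.0,
    tone_duration_ms: float = 50.0,
    iti_range_ms: tuple[float, float] = (1350.0, 1650.0),
    seed: int = 0,
    start_sample: int = 0,
    trial_id_offset: int = 0,
) -> list[AuditoryEvent]:
    """Event list for one block.

    Condition semantics: the frequent trial of an XX block is five equal
    sounds (LSGS) and its rare trial LDGD; in XY blocks the frequent trial
    is LDGS and the rare one LSGD.  Rare count = round(rare_fraction x
    trials), positions shuffled uniformly.
    """
    if trials_per_block < 1:
        raise ValueError("trials_per_block must be >= 1")
    if not 0.0 < rare_fraction < 1.0:
        raise ValueError("rare_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n_rare = int(round(rare_fraction * trials_per_block))
    rare = np.zeros(trials_per_block, dtype=bool)
    rare[rng.choice(trials_per_block, size=n_rare, replace=False)] = True

    if block_type == BlockType.XX:
        freq_cond, rare_cond = Condition.LSGS, Condition.LDGD
    else:
        freq_cond, rare_cond = Condition.LDGS, Condition.LSGD

    soa = soa_ms / 1000.0 * fs
    events: list[AuditoryEvent] = []
    t = float(start_sample)
    for i in range(trials_per_block):
        cond = rare_cond if rare[i] else freq_cond
        onset1 = int(round(t))
        for s in range(5):
            events.append(
                AuditoryEvent(
                    onset_sample=onset1 + int(round(s * soa)),
                    trial_id=trial_id_offset + i,
                    sound_index=s + 1,
                    block_type=block_type,
                    condition=cond,
                )
            )
        iti_ms = rng.uniform(*iti_range_ms)
        # next trial starts after the 5th tone ends plus the intertrial interval
        t = onset1 + 4 * soa + (tone_duration_ms + iti_ms) / 1000.0 * fs
    return events


# ---------------------------------------------------------------------------
# Cardiac source
# ---------------------------------------------------------------------------

def qrs_template(fs: float, duration_ms: float = 80.0) -> np.ndarray:
    """Fixed biphasic QRS-like waveform whose global maximum is its centre."""
    n = int(round(duration_ms / 1000.0 * fs))
    n += (n + 1) % 2  # odd length so the peak is a single sample
    t = np.linspace(-1, 1, n)
    tpl = np.exp(-(t / 0.3) ** 2) - 0.45 * np.exp(-((t - 0.55) / 0.25) ** 2)
    tpl -= tpl[0]
    return tpl / tpl.max()


def simulate_cardiac(
    duration_s: float,
    fs: float = 250.0,
    rr_mean_ms: float = 800.0,
    rr_sd_ms: float = 50.0,
    seed: int = 0,
    noise_sd: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """ECG-like trace (arbitrary units) plus true R-peak sample indices.

    Interbeat intervals are truncated-normal: mean ``rr_mean_ms``, sd
    ``rr_sd_ms``, truncation at +-3 sd and at a 300 ms positivity floor.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if rr_mean_ms <= 0:
        raise ValueError("rr_mean_ms must be positive")
    if rr_sd_ms < 0:
        raise ValueError("rr_sd_ms must be non-negative")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * fs))
    tpl = qrs_template(fs)
    half = len(tpl) // 2

    floor_ms = max(rr_mean_ms - 3 * rr_sd_ms, 300.0)
    ceil_ms = rr_mean_ms + 3 * rr_sd_ms

    peaks = []
    t_ms = rr_mean_ms  # first beat one mean RR into the recording
    while True:
        s = int(round(t_ms / 1000.0 * fs))
        if s + half >= n_samples:
            break
        if s - half >= 0:
            peaks.append(s)
        ibi = rng.normal(rr_mean_ms, rr_sd_ms) if rr_sd_ms > 0 else rr_mean_ms
        ibi = float(np.clip(ibi, floor_ms, ceil_ms))
        t_ms += ibi
    peaks_arr = np.asarray(peaks, dtype=int)

    trace = np.zeros(n_samples)
    for p in peaks_arr:
        trace[p - half:p + half + 1] += tpl
    if noise_sd > 0:
        trace = trace + rng.normal(0, noise_sd, n_samples)
    return trace, peaks_arr


# ---------------------------------------------------------------------------
# Subject and cohort
# ---------------------------------------------------------------------------

try:
    from numba import njit

    @njit(cache=True)
    def _ar1_recurse(w: np.ndarray, a: float) -> None:
        for c in range(w.shape[0]):
            acc = np.float32(0.0)
            for t in range(w.shape[1]):
                acc = a * acc + w[c, t]
                w[c, t] = acc

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard speed dependency
    _HAVE_NUMBA = False


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int], sd: float, a: float) -> np.ndarray:
    # float32 keeps large-cohort simulation memory- and time-cheap;
    # quantisation is far below the uV noise floor
    w = rng.standard_normal(shape, dtype=np.float32)
    if a == 0:
        return sd * w
    if _HAVE_NUMBA:
        _ar1_recurse(w, np.float32(a))
        x = w
    else:
        x = lfilter([1.0], [1.0, -a], w, axis=1).astype(np.float32)
    # scale to requested stationary sd
    return np.float32(sd * np.sqrt(1 - a ** 2)) * x


def _window_samples(window_ms: tuple[float, float], fs: float) -> tuple[int, int]:
    return int(round(window_ms[0] / 1000.0 * fs)), int(round(window_ms[1] / 1000.0 * fs))


from functools import lru_cache


@lru_cache(maxsize=8)
def _field_basis(pos_bytes: bytes, n_ch: int, scale_cm: float) -> np.ndarray:
    """Low-rank square root of the spatial field kernel, unit marginals.

    The smooth field has low effective rank; only latent sources carrying
    >1e-4 of the field variance are kept.
    """
    pos = np.frombuffer(pos_bytes, dtype=float).reshape(n_ch, 3)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    K = np.exp(-d2 / (2 * scale_cm ** 2))
    lam, V = np.linalg.eigh(K)
    keep = lam > 1e-4 * lam[-1]
    L = (V[:, keep] * np.sqrt(lam[keep])).astype(np.float32)
    L /= np.sqrt((L ** 2).sum(axis=1, keepdims=True))
    return L


def _eeg_noise(rng: np.random.Generator, layout: SensorLayout, n_samples: int,
               config: "SimConfig") -> np.ndarray:
    """AR-shaped noise with a volume-conduction-like spatial component.

    A share of the variance is common across the cap (Gaussian field over
    sensor positions, RBF length scale ``noise_spatial_scale_cm``) so
    neighbouring channels correlate the way filtered EEG does; the rest
    is channel-independent sensor noise.
    """
    share = float(np.clip(config.noise_spatial_share, 0.0, 1.0))
    n_ch = len(layout)
    # both components AR-shaped: the independent part must keep in-band
    # power, or band-pass filtering leaves a near-singular channel
    # covariance that destabilises the ICA whitening
    indep = _ar1_noise(rng, (n_ch, n_samples), config.noise_sd_uv, config.noise_ar)
    if share == 0.0:
        return indep
    L = _field_basis(layout.positions.tobytes(), len(layout),
                     config.noise_spatial_scale_cm)
    common = L @ _ar1_noise(rng, (L.shape[1], n_samples),
                            config.noise_sd_uv, config.noise_ar)
    return np.sqrt(share, dtype=np.float32) * common \
        + np.sqrt(1 - share, dtype=np.float32) * indep


def simulate_subject(
    config: SimConfig, group: Group, seed: int, subject_id: str | None = None
) -> tuple[Recording, GroundTruth]:
    """One subject's EEG = AR noise + cardiac artifact + evoked components.

    Deviant-minus-standard increments are rectangular pulses added on the
    planted channel patches; heartbeat-locked increments attach to the
    first R-peak after each trial's 5th sound, with amplitude set by the
    trial's condition and the subject's group.
    """
    if group == Group.UNKNOWN:
        raise ValueError("group must be MCS, UWS or CONTROL")
    rng = np.random.default_rng(seed)
    layout = hemispherical_layout(config.n_channels)
    fs = config.fs

    n_xx = config.n_blocks_xx
    n_xy = config.n_blocks_xy
    if group == Group.CONTROL:
        n_xx = max(1, n_xx // 2)
        n_xy = max(1, n_xy // 2)

    # --- events: alternating XX / XY blocks back to back
    events: list[AuditoryEvent] = []
    block_order = [BlockType.XX] * n_xx + [BlockType.XY] * n_xy
    t0 = int(round(fs))  # 1 s lead-in
    trial_offset = 0
    for b, btype in enumerate(block_order):
        ev = generate_event_stream(
            btype, config.trials_per_block, config.rare_fraction,
            fs=fs, soa_ms=config.soa_ms, tone_duration_ms=config.tone_duration_ms,
            iti_range_ms=config.iti_range_ms,
            seed=int(rng.integers(2 ** 31)), start_sample=t0,
            trial_id_offset=trial_offset,
        )
        events.extend(ev)
        trial_offset += config.trials_per_block
        t0 = ev[-1].onset_sample + int(round(3.0 * fs))  # 3 s inter-block gap

    n_samples = events[-1].onset_sample + int(round(2.5 * fs))
    duration_s = n_samples / fs

    # --- cardiac source and field artifact
    ecg, rpeaks = simulate_cardiac(
        duration_s, fs, config.rr_mean_ms, config.rr_sd_ms,
        seed=int(rng.integers(2 ** 31)),
    )
    # cardiac field artifact: dipolar source below the cap — steep 1/d^3
    # falloff with a polarity reversal across the scalp, the pattern that
    # makes the artifact separable from smooth background activity
    src = np.array([0.0, -6.0, -6.0])  # cm
    orient = np.array([0.0, 0.6, 0.8])
    r = layout.positions - src
    d = np.linalg.norm(r, axis=1)
    mixing = (r @ orient) / d ** 3
    mixing = config.artifact_gain * mixing / np.abs(mixing).max()

    eeg = _eeg_noise(rng, layout, n_samples, config)
    tpl = qrs_template(fs)
    half = len(tpl) // 2
    train = np.zeros(n_samples)
    for p in rpeaks:
        train[p - half:p + half + 1] += tpl
    eeg += mixing[:, None] * train[None, :]

    # --- group scaling of planted effects
    if group == Group.UWS:
        local_scale, global_scale = config.uws_local_scale, 0.0
        her_var_sd = config.her_var_sd_uv
    else:  # MCS and CONTROL share the conscious-processing pattern
        local_scale, global_scale = 1.0, 1.0
        her_var_sd = config.her_var_sd_uv * (
            config.her_trial_variance_ratio if group == Group.MCS else 1.0
        )

    patches = {
        "erp_local": contiguous_patch(layout, config.erp_local.center_channel, config.erp_local.n_channels),
        "erp_global": contiguous_patch(layout, config.erp_global.center_channel, config.erp_global.n_channels),
        "her_local": contiguous_patch(layout, config.her_local.center_channel, config.her_local.n_channels),
        "her_global": contiguous_patch(layout, config.her_global.center_channel, config.her_global.n_channels),
    }

    fifth = sorted((e for e in events if e.sound_index == 5), key=lambda e: e.onset_sample)

    def add_pulse(chans: np.ndarray, lock: int, window_ms: tuple[float, float], amp: float) -> None:
        a, b = _window_samples(window_ms, fs)
        lo, hi = lock + a, min(lock + b, n_samples)
        if amp != 0.0 and hi > lo:
            eeg[np.ix_(chans, np.arange(lo, hi))] += amp

    # stimulus-locked: every 5th sound carries a common evoked response plus
    # deviant increments in the configured windows
    common_erp_amp = 2.0
    for ev in fifth:
        add_pulse(patches["erp_local"], ev.onset_sample, (80.0, 200.0), common_erp_amp)
        if ev.condition.local_deviant:
            add_pulse(patches["erp_local"], ev.onset_sample,
                      config.erp_local.window_ms, config.erp_local.amp_uv * local_scale)
        if ev.condition.global_deviant:
            add_pulse(patches["erp_global"], ev.onset_sample,
                      config.erp_global.window_ms, config.erp_global.amp_uv * global_scale)

    # heartbeat-locked: first R-peak strictly after each 5th sound
    for ev in fifth:
        i = np.searchsorted(rpeaks, ev.onset_sample, side="right")
        if i >= len(rpeaks):
            continue
        lock = int(rpeaks[i])
        if ev.condition.local_deviant:
            add_pulse(patches["her_local"], lock,
                      config.her_local.window_ms, config.her_local.amp_uv * local_scale)
        if ev.condition.global_deviant:
            add_pulse(patches["her_global"], lock,
                      config.her_global.window_ms, config.her_global.amp_uv * global_scale)

    # per-beat random heartbeat-response variability (whole protocol),
    # larger in MCS-like subjects
    if her_var_sd > 0:
        var_patch = patches["her_local"]
        amp_per_beat = rng.normal(0.0, her_var_sd, len(rpeaks))
        a, b = _window_samples((100.0, 400.0), fs)
        for p, amp in zip(rpeaks, amp_per_beat):
            lo, hi = p + a, min(p + b, n_samples)
            if hi > lo:
                eeg[np.ix_(var_patch, np.arange(lo, hi))] += amp

    rec = Recording(
        subject_id=subject_id or f"sim-{group.value.lower()}-{seed}",
        group=group,
        eeg=eeg,
        fs=fs,
        layout=layout,
        events=events,
    )
    gt = GroundTruth(
        true_rpeak_samples=rpeaks,
        cardiac_mixing=mixing,
        planted_effect_windows={
            name: {
                "channels": patches[name].tolist(),
                "window_ms": list(getattr(config, name).window_ms),
                "amp_uv": getattr(config, name).amp_uv,
            }
            for name in patches
        },
        group=group,
    )
    return rec, gt


def simulate_cohort(config: SimConfig, out_dir: str | Path | None = None) -> dict:
    """Simulate all subjects; optionally write EDF+TSV+JSON sidecars.

    Returns a manifest.  With ``out_dir`` set, each subject is written as
    ``<sid>.edf`` / ``<sid>_events.tsv`` / ``<sid>_layout.tsv`` /
    ``<sid>_truth.json`` and the manifest lists the paths; otherwise the
    manifest carries the in-memory (Recording, GroundTruth) pairs.
    """
    n_total = config.n_mcs + config.n_uws + config.n_control
    if n_total == 0:
        raise ValueError("cohort must contain at least one subject")
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_total)]

    labels = ([Group.MCS] * config.n_mcs + [Group.UWS] * config.n_uws
              + [Group.CONTROL] * config.n_control)
    manifest: dict = {"seed": config.seed, "subjects": []}
    for i, (grp, sd) in enumerate(zip(labels, seeds)):
        sid = f"sub-{i + 1:03d}-{grp.value.lower()}"
        rec, gt = simulate_subject(config, grp, sd, subject_id=sid)
        entry: dict = {"subject_id": sid, "group": grp.value, "seed": sd}
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            eeg_p = out / f"{sid}.edf"
            ev_p = out / f"{sid}_events.tsv"
            lay_p = out / f"{sid}_layout.tsv"
            gt_p = out / f"{sid}_truth.json"
            write_recording(rec, eeg_p, ev_p, lay_p)
            save_json(
                {
                    "true_rpeak_samples": gt.true_rpeak_samples,
                    "cardiac_mixing": gt.cardiac_mixing,
                    "planted_effect_windows": gt.planted_effect_windows,
                    "group": gt.group.value,
                },
                gt_p,
            )
            entry.update(eeg=str(eeg_p), events=str(ev_p), layout=str(lay_p), truth=str(gt_p))
        else:
            entry.update(recording=rec, truth=gt)
        manifest["subjects"].append(entry)
    return manifest


# ---------------------------------------------------------------------------
# Map-level and feature-level simulators (for statistics-only studies)
# ---------------------------------------------------------------------------

def simulate_effect_maps(
    n_a: int,
    n_b: int,
    layout: SensorLayout,
    n_times: int,
    seed: int,
    noise_sd: float = 1.0,
    spatial_scale_cm: float = 4.0,
    ar: float = 0.5,
    shift_a: np.ndarray | float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject effect maps with realistic spatio-temporal correlation.

    Subject maps are Gaussian noise smoothed over the sensor cap (RBF
    kernel, length scale ``spatial_scale_cm``) and over time (AR(1)),
    rescaled to unit-``noise_sd`` marginals.  ``shift_a`` (scalar or
    channels x time array) is added to group A only.  Returns
    (maps_a, maps_b) with shape (n_subjects, n_channels, n_times).
    """
    rng = np.random.default_rng(seed)
    pos = layout.positions
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    K = np.exp(-d2 / (2 * spatial_scale_cm ** 2))
    L = np.linalg.cholesky(K + 1e-8 * np.eye(len(pos)))

    def draw(n: int) -> np.ndarray:
        w = rng.standard_normal((n, len(pos), n_times))
        if ar > 0:
            w = lfilter([1.0], [1.0, -ar], w, axis=2) * np.sqrt(1 - ar ** 2)
        m = np.einsum("ij,njt->nit", L, w)
        return noise_sd * m / np.sqrt(np.diag(L @ L.T))[None, :, None]

    maps_a = draw(n_a) + shift_a
    maps_b = draw(n_b)
    return maps_a, maps_b


def simulate_feature_table(
    n_a: int,
    n_b: int,
    seed: int,
    mean_a: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
    mean_b: tuple[float, float, float, float] = (0.0, 0.5, 0.0, 0.5),
    sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Combined-effect feature quadruples for two diagnostic groups.

    Columns: (ERP_global, ERP_local, HER_global, HER_local).  The default
    means mirror the qualitative group pattern: group A (MCS-like) carries
    all four effects, group B (UWS-like) only attenuated local ones.
    Returns (X, y) with y=1 for group A.
    """
    rng = np.random.default_rng(seed)
    xa = rng.normal(mean_a, sd, size=(n_a, 4))
    xb = rng.normal(mean_b, sd, size=(n_b, 4))
    X = np.vstack([xa, xb])
    y = np.concatenate([np.ones(n_a, dtype=int), np.zeros(n_b, dtype=int)])
    return X, y
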