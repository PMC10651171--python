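"""EEG cleaning chain.

Order of operations mirrors standard clinical-EEG practice for
heartbeat-evoked analyses: band-pass filter, iterative rejection of
high-amplitude channels, ICA recovery of the cardiac field artifact (the
designated component's time course doubles as an ECG substitute,
"ICA-ECG"), interpolation of channels that decorrelate from their
neighbours, common-average re-referencing and selection of the 64-channel
analysis montage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.stats import kurtosis, rankdata

from .core_io import NeighborGraph, Recording, SensorLayout

__all__ = [
    "PreprocReport",
    "CardiacComponentError",
    "bandpass_filter",
    "reject_channels_zscore",
    "extract_ica_ecg",
    "interpolate_low_correlation_channels",
    "rereference_and_subset",
]


class CardiacComponentError(RuntimeError):
    """No independent component passed the cardiac-selection criterion.

    Advises falling back to an externally recorded ECG channel.
    """


@dataclass
class PreprocReport:
    """Tallies and parameters of each cleaning step."""

    rejected_channels_zscore: list[str] = field(default_factory=list)
    interpolated_channels: list[str] = field(default_factory=list)
    no_neighbor_channels: list[str] = field(default_factory=list)
    cardiac_component_index: int | None = None
    cardiac_component_score: float = float("nan")
    parameters: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def bandpass_filter(
    recording: Recording,
    low_hz: float = 1.0,
    high_hz: float = 25.0,
    order: int = 4,
    design: str = "butter",
) -> Recording:
    """Zero-phase band-pass per channel.

    ``design='butter'`` applies a 4th-order Butterworth forward-backward
    (the default); ``design='fir'`` a Hamming-windowed linear-phase FIR of
    ~3 low-cutoff cycles, also applied forward-backward.  Both remove DC
    and leave the passband gain near unity.
    """
    if high_hz >= recording.fs / 2:
        raise ValueError(
            f"upper cutoff {high_hz} Hz must be below Nyquist ({recording.fs / 2} Hz)"
        )
    if design == "butter":
        sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                            fs=recording.fs, output="sos")
        out = signal.sosfiltfilt(sos, recording.eeg, axis=1)
    elif design == "fir":
        numtaps = int(3 * recording.fs / low_hz) | 1
        taps = signal.firwin(numtaps, [low_hz, high_hz], pass_zero=False,
                             window="hamming", fs=recording.fs)
        out = signal.filtfilt(taps, [1.0], recording.eeg, axis=1)
    else:
        raise ValueError(f"unknown filter design {design!r}")
    rec = recording.copy_with(out)
    rec.log_step(f"bandpass_filter {low_hz}-{high_hz} Hz order={order} design={design}")
    return rec


# ---------------------------------------------------------------------------
# Iterative channel rejection
# ---------------------------------------------------------------------------

def _abs_auc(eeg: np.ndarray, fs: float) -> np.ndarray:
    """Trapezoidal integral of |signal| per channel."""
    return np.trapezoid(np.abs(eeg), dx=1.0 / fs, axis=1)


def reject_channels_zscore(
    recording: Recording, z_threshold: float = 3.0, max_iter: int = 10
) -> tuple[Recording, PreprocReport]:
    """Iteratively discard channels whose |signal| area is an outlier.

    Per iteration: integrate |x| over the recording per channel, z-score
    across channels, drop every channel above ``z_threshold``, recompute.
    Stops at a fixpoint or after ``max_iter`` iterations (warned in the
    report).  Zero across-channel variance means nothing is rejected.
    """
    if recording.n_channels < 3:
        raise ValueError("need at least 3 channels for z-score rejection")
    keep = np.arange(recording.n_channels)
    removal_order: list[str] = []
    for it in range(max_iter):
        eeg = recording.eeg[keep]
        auc = _abs_auc(eeg, recording.fs)
        sd = auc.std()
        if sd == 0:
            break
        z = (auc - auc.mean()) / sd
        bad = z > z_threshold
        if not bad.any():
            break
        if (~bad).sum() == 0:
            raise ValueError("all channels rejected; recording unusable")
        removal_order.extend(recording.layout.names[i] for i in keep[bad])
        keep = keep[~bad]
    else:
        import warnings

        warnings.warn("channel rejection hit the iteration cap", RuntimeWarning)
    if len(keep) == 0:
        raise ValueError("all channels rejected; recording unusable")

    names = [recording.layout.names[i] for i in keep]
    layout = SensorLayout(names, recording.layout.positions[keep])
    rec = recording.copy_with(recording.eeg[keep], layout)
    rec.log_step(f"reject_channels_zscore removed {len(removal_order)}: {removal_order}")
    report = PreprocReport(
        rejected_channels_zscore=removal_order,
        parameters={"z_threshold": z_threshold, "max_iter": max_iter},
    )
    return rec, report


# ---------------------------------------------------------------------------
# ICA-based cardiac recovery
# ---------------------------------------------------------------------------

def _cardiac_scores(sources: np.ndarray, fs: float,
                    lag_band_s: tuple[float, float] = (0.6, 1.5)) -> tuple[np.ndarray, np.ndarray]:
    """Periodicity and peakedness scores per component.

    Periodicity: peak normalised autocorrelation in the RR-interval lag
    band (0.6-1.5 s covers 40-100 bpm) — near 1 for a regular beat train,
    near 0 for broadband noise.  Peakedness: excess kurtosis of the
    source (a QRS train is strongly super-Gaussian).
    """
    n_comp, n = sources.shape
    max_lag = int(round(lag_band_s[1] * fs)) + 1
    lo = int(round(lag_band_s[0] * fs))
    x = sources - sources.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(n + max_lag)))
    f = np.fft.rfft(x, nfft, axis=1)
    ac = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :max_lag]
    ac = ac / ac[:, :1]  # normalise by lag-0
    periodicity = np.clip(ac[:, lo:max_lag].max(axis=1), 0.0, None)
    peakedness = kurtosis(sources, axis=1, fisher=True)
    return periodicity, peakedness


def extract_ica_ecg(
    recording: Recording,
    seed: int = 0,
    method: str = "fastica",
    min_kurtosis: float = 3.0,
    min_periodicity: float = 0.15,
    max_iter: int = 500,
) -> tuple[Recording, np.ndarray, PreprocReport]:
    """Recover the cardiac field artifact as one independent component.

    The EEG is decomposed into as many components as channels; each
    component is scored for RR-band periodicity and kurtosis, and the
    component with the best combined rank is designated cardiac.  Its
    source time course (unit variance, QRS peaks oriented positive) is
    returned as the ICA-ECG, and the cleaned Recording is rebuilt with
    that component removed.

    Raises :class:`CardiacComponentError` when the best candidate fails
    both selection floors — e.g. recordings with no cardiac artifact.
    """
    if recording.n_channels < 16:
        raise ValueError("ICA-ECG recovery needs at least 16 channels")
    if recording.n_samples < 60 * recording.fs:
        raise ValueError("ICA-ECG recovery needs at least 60 s of signal")

    X = recording.eeg
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean

    if method == "fastica":
        from sklearn.decomposition import FastICA

        ica = FastICA(n_components=recording.n_channels, random_state=seed,
                      whiten="unit-variance", max_iter=max_iter, tol=1e-3)
        import warnings

        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            sources = ica.fit_transform(Xc.T).T  # (n_comp, n_samples)
        mixing = ica.mixing_  # (n_channels, n_comp)
    elif method == "infomax":
        from mne.preprocessing import infomax

        # pre-whiten, then extended infomax on the whitened data
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        white = (Vt * np.sqrt(len(Vt.T)))  # (n_comp, n_samples), unit variance
        W = infomax(white.T, extended=True, random_state=seed, verbose="error")
        sources = W @ white
        # mixing back to channel space: Xc ~= (U @ diag(s) / sqrt(n)) @ inv(W) @ sources
        mixing = (U * s / np.sqrt(Xc.shape[1])) @ np.linalg.inv(W)
        sources = sources / sources.std(axis=1, keepdims=True)
        mixing = mixing * sources.std(axis=1)  # keep product invariant
    else:
        raise ValueError(f"unknown ICA method {method!r}")

    periodicity, peakedness = _cardiac_scores(sources, recording.fs)
    # kurtosis gates candidacy (a QRS train is strongly super-Gaussian);
    # RR variability makes fixed-lag periodicity too weak to rank on its
    # own, so it only disambiguates between several peaked components
    candidates = np.nonzero(peakedness >= min_kurtosis)[0]
    if len(candidates) == 0:
        b = int(np.argmax(peakedness))
        raise CardiacComponentError(
            "no component passed the cardiac-selection criterion "
            f"(best kurtosis={peakedness[b]:.2f}, periodicity={periodicity[b]:.2f}); "
            "fall back to an externally recorded ECG channel"
        )
    if len(candidates) > 1 and periodicity[candidates].max() >= min_periodicity:
        best = int(candidates[np.argmax(periodicity[candidates])])
    else:
        best = int(candidates[np.argmax(peakedness[candidates])])
    score = float(peakedness[best] + periodicity[best])

    ecg = sources[best].copy()
    ecg = ecg / ecg.std()
    # orient QRS upward: the heavier tail carries the R-peaks
    if np.abs(ecg.min()) > np.abs(ecg.max()):
        ecg = -ecg

    cleaned = Xc - np.outer(mixing[:, best], sources[best]) + mean
    rec = recording.copy_with(cleaned)
    rec.log_step(f"extract_ica_ecg method={method} component={best} score={score:.3f}")
    report = PreprocReport(
        cardiac_component_index=best,
        cardiac_component_score=score,
        parameters={
            "method": method,
            "seed": seed,
            "periodicity": float(periodicity[best]),
            "kurtosis": float(peakedness[best]),
        },
    )
    return rec, ecg, report


# ---------------------------------------------------------------------------
# Neighbour-correlation interpolation
# ---------------------------------------------------------------------------

def weighted_neighbor_correlation(
    recording: Recording, graph: NeighborGraph, weighting: str = "inverse"
) -> np.ndarray:
    """Per channel: distance-weighted mean Pearson correlation with neighbours.

    Weights are inverse distance (``'inverse'``) or inverse squared
    distance (``'inverse_sq'``).  Channels without neighbours get NaN.
    """
    eeg = recording.eeg
    pos = recording.layout.positions
    x = eeg - eeg.mean(axis=1, keepdims=True)
    norm = np.sqrt((x ** 2).sum(axis=1))
    out = np.full(recording.n_channels, np.nan)
    for i in range(recording.n_channels):
        nbrs = sorted(graph.neighbors(i))
        if not nbrs:
            continue
        r = np.array([
            float(x[i] @ x[j] / (norm[i] * norm[j])) if norm[i] > 0 and norm[j] > 0 else 0.0
            for j in nbrs
        ])
        d = np.linalg.norm(pos[nbrs] - pos[i], axis=1)
        w = 1.0 / d if weighting == "inverse" else 1.0 / d ** 2
        out[i] = float((w * r).sum() / w.sum())
    return out


def _spline_interpolate(pos_from: np.ndarray, pos_to: np.ndarray,
                        data_from: np.ndarray) -> np.ndarray:
    """Spherical-spline (order 4, reg 1e-5) interpolation of one channel."""
    from mne.channels.interpolation import _make_interpolation_matrix

    M = _make_interpolation_matrix(pos_from, np.atleast_2d(pos_to), alpha=1e-5)
    return M @ data_from


def interpolate_low_correlation_channels(
    recording: Recording,
    graph: NeighborGraph,
    corr_threshold: float = 0.80,
    weighting: str = "inverse",
) -> tuple[Recording, PreprocReport]:
    """Replace channels that decorrelate from their neighbourhood.

    A channel whose distance-weighted mean neighbour correlation falls
    below ``corr_threshold`` is rebuilt by spherical-spline interpolation
    from its (original) neighbours.  Channels with no neighbours are left
    untouched and logged.  More than half the montage falling below the
    threshold aborts — the recording is too degraded to repair.
    """
    wc = weighted_neighbor_correlation(recording, graph, weighting)
    has_nbrs = ~np.isnan(wc)
    bad = has_nbrs & (wc < corr_threshold)
    if bad.sum() > recording.n_channels / 2:
        raise ValueError(
            f"{bad.sum()} of {recording.n_channels} channels below the "
            "neighbour-correlation threshold; recording too degraded"
        )
    eeg = recording.eeg.copy()
    pos = recording.layout.positions
    for i in np.nonzero(bad)[0]:
        nbrs = sorted(graph.neighbors(i))
        eeg[i] = _spline_interpolate(pos[nbrs], pos[i], recording.eeg[nbrs])
    names = recording.layout.names
    rec = recording.copy_with(eeg)
    interpolated = [names[i] for i in np.nonzero(bad)[0]]
    isolated = [names[i] for i in np.nonzero(~has_nbrs)[0]]
    rec.log_step(f"interpolate_low_correlation_channels threshold={corr_threshold} "
                 f"interpolated={interpolated}")
    report = PreprocReport(
        interpolated_channels=interpolated,
        no_neighbor_channels=isolated,
        parameters={"corr_threshold": corr_threshold, "weighting": weighting},
    )
    return rec, report


# ---------------------------------------------------------------------------
# Re-referencing and montage subset
# ---------------------------------------------------------------------------

def rereference_and_subset(
    recording: Recording, subset: list[str] | None = None
) -> Recording:
    """Common-average reference over retained channels, then montage subset.

    The per-sample mean over the referencing set becomes zero; the subset
    (default: all channels) is then extracted in the given order.
    """
    eeg = recording.eeg - recording.eeg.mean(axis=0, keepdims=True)
    if subset is None:
        rec = recording.copy_with(eeg)
        rec.log_step("rereference common-average (full montage)")
        return rec
    missing = [n for n in subset if n not in recording.layout.names]
    if missing:
        raise ValueError(f"subset channels missing from recording: {missing}")
    idx = [recording.layout.index(n) for n in subset]
    layout = SensorLayout(list(subset), recording.layout.positions[idx])
    rec = recording.copy_with(eeg[idx], layout)
    rec.log_step(f"rereference common-average + subset of {len(subset)} channels")
    return rec
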