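"""Quantification of epileptiform activity in local field potential traces.

The analysis chain mirrors standard larval-zebrafish seizure quantification:
a recording is band-pass filtered (3-300 Hz) and notch-filtered (50 Hz),
epileptiform discharges are detected as excursions whose amplitude exceeds
``threshold_factor`` x a robust baseline measure for at least
``min_duration`` (defaults 3x and 100 ms), spectral content is summarized
by Welch's PSD (100 ms Hamming windows, 80% overlap), averaged over
consecutive 10-Hz bands up to 150 Hz, and the 20-50 Hz region — the band
characterizing polyspiking discharges — is reduced to a single per-subject
statistic that is finally expressed as a percentage of a reference group.

Baseline measure: 1.4826 x median absolute deviation of the conditioned
trace, a robust SD estimate insensitive to the discharges themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "LFPRecording",
    "EpileptiformEvent",
    "PSDEstimate",
    "BandPowerTable",
    "GroupSummary",
    "robust_baseline_sd",
    "bandpass_filter",
    "remove_line_noise",
    "detect_events",
    "welch_psd",
    "band_average",
    "band_range_mean",
    "normalize_to_reference",
    "quantify_recording",
]

MIN_WINDOW_S = 0.1  # one analysis window


@dataclass(frozen=True)
class LFPRecording:
    """Uniformly sampled voltage trace with its sampling rate and labels."""

    samples: np.ndarray
    sampling_rate: float
    subject_id: str = ""
    group: str = ""

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.samples) < MIN_WINDOW_S * self.sampling_rate:
            raise ValueError("trace shorter than one 100 ms analysis window")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    def replace_samples(self, samples: np.ndarray) -> "LFPRecording":
        return LFPRecording(samples, self.sampling_rate, self.subject_id, self.group)


@dataclass(frozen=True)
class EpileptiformEvent:
    """One detected discharge: [start, end) seconds and its peak amplitude
    expressed as a multiple of the baseline measure."""

    start: float
    end: float
    peak_amplitude_factor: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class PSDEstimate:
    frequencies: np.ndarray
    power: np.ndarray
    window_length: float
    overlap_fraction: float

    def __post_init__(self):
        f = np.asarray(self.frequencies, float)
        p = np.asarray(self.power, float)
        if (np.diff(f) <= 0).any() or f[0] < 0:
            raise ValueError("frequencies must be non-negative ascending")
        if (p < 0).any():
            raise ValueError("power must be non-negative")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class BandPowerTable:
    """Average spectral power per consecutive frequency band."""

    band_edges: tuple[tuple[float, float], ...]
    band_means: np.ndarray

    def __post_init__(self):
        if (np.asarray(self.band_means) < 0).any():
            raise ValueError("band means must be non-negative")


@dataclass(frozen=True)
class GroupSummary:
    group: str
    per_subject_values: tuple[float, ...]
    mean: float = field(init=False)
    sd: float = field(init=False)
    normalized_mean_percent: float | None = None

    def __post_init__(self):
        vals = np.asarray(self.per_subject_values, float)
        object.__setattr__(self, "mean", float(vals.mean()))
        object.__setattr__(self, "sd", float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)


# ---------------------------------------------------------------------------
# Conditioning
# ---------------------------------------------------------------------------

def bandpass_filter(rec: LFPRecording, low: float = 3.0, high: float = 300.0) -> LFPRecording:
    """Zero-phase Butterworth band-pass (default 3-300 Hz)."""
    nyq = rec.sampling_rate / 2
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high corner {high} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(4, [low, high], btype="bandpass", fs=rec.sampling_rate, output="sos")
    return rec.replace_samples(sps.sosfiltfilt(sos, rec.samples))


def remove_line_noise(rec: LFPRecording, freq: float = 50.0, quality: float = 30.0) -> LFPRecording:
    """Zero-phase IIR notch at ``freq`` (default 50 Hz mains)."""
    if freq >= rec.sampling_rate / 2:
        raise ValueError("notch frequency must be below Nyquist")
    b, a = sps.iirnotch(freq, quality, fs=rec.sampling_rate)
    return rec.replace_samples(sps.filtfilt(b, a, rec.samples))


def robust_baseline_sd(samples: np.ndarray) -> float:
    """1.4826 x median absolute deviation: robust SD of the noise floor."""
    x = np.asarray(samples, float)
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def _amplitude_envelope(
    samples: np.ndarray, sampling_rate: float, rms_window_s: float, noise_sd: float
) -> np.ndarray:
    """Noise-floor-corrected moving-RMS amplitude envelope.

    The mean square over a short window contains the burst's A^2/2 plus the
    noise power sigma^2; subtracting the baseline noise power and scaling by
    sqrt(2) makes the envelope an (approximately unbiased) estimate of the
    burst amplitude A itself, so the threshold rule compares amplitudes
    rather than amplitude-plus-noise.
    """
    n_win = max(int(round(rms_window_s * sampling_rate)), 1)
    kernel = np.ones(n_win) / n_win
    ms = np.convolve(samples**2, kernel, mode="same")
    return np.sqrt(2.0 * np.maximum(ms - noise_sd**2, 0.0))


def detect_events(
    rec: LFPRecording,
    threshold_factor: float = 3.0,
    min_duration: float = 0.1,
    merge_gap: float = 0.02,
    rms_window: float = 0.01,
) -> list[EpileptiformEvent]:
    """Detect epileptiform discharges in a conditioned trace.

    A discharge is a maximal run where the amplitude envelope exceeds
    ``threshold_factor`` x the robust baseline SD; runs separated by less
    than ``merge_gap`` are merged (polyspiking bursts dip between spikes)
    before the ``min_duration`` rule is applied. Events are returned
    sorted and disjoint.
    """
    if threshold_factor <= 0:
        raise ValueError("threshold_factor must be positive")
    if rec.duration < min_duration:
        raise ValueError("trace shorter than min_duration")
    baseline = robust_baseline_sd(rec.samples)
    if baseline == 0:
        return []
    env = _amplitude_envelope(rec.samples, rec.sampling_rate, rms_window, baseline)
    above = env > threshold_factor * baseline
    if not above.any():
        return []

    # maximal runs of suprathreshold samples
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)  # exclusive

    # merge runs separated by < merge_gap
    gap_n = int(round(merge_gap * rec.sampling_rate))
    merged: list[list[int]] = []
    for s, e in zip(run_starts, run_ends):
        if merged and s - merged[-1][1] < gap_n:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    fs = rec.sampling_rate
    events = []
    for s, e in merged:
        dur = (e - s) / fs
        if dur >= min_duration:
            peak = float(env[s:e].max() / baseline)
            events.append(EpileptiformEvent(start=s / fs, end=e / fs, peak_amplitude_factor=peak))
    return events


# ---------------------------------------------------------------------------
# Spectral analysis
# ---------------------------------------------------------------------------

def welch_psd(rec: LFPRecording, window: float = 0.1, overlap: float = 0.8) -> PSDEstimate:
    """One-sided Welch PSD: Hamming taper, per-segment mean removal,
    density scaling; defaults give 200-sample segments with 160-sample
    overlap at 2 kHz."""
    if window >= rec.duration:
        raise ValueError("window must be shorter than the trace")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    nperseg = int(round(window * rec.sampling_rate))
    noverlap = int(round(overlap * nperseg))
    f, p = sps.welch(
        rec.samples,
        fs=rec.sampling_rate,
        window="hamming",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        return_onesided=True,
    )
    return PSDEstimate(frequencies=f, power=p, window_length=window, overlap_fraction=overlap)


def band_average(psd: PSDEstimate, band_width: float = 10.0, f_max: float = 150.0) -> BandPowerTable:
    """Average PSD over consecutive ``band_width``-Hz bands up to ``f_max``.

    Band membership is by frequency-bin center in the half-open interval
    [low, high), so no bin is counted twice.
    """
    f = np.asarray(psd.frequencies)
    if f[-1] < f_max:
        raise ValueError(f"PSD grid covers only up to {f[-1]} Hz, need {f_max}")
    df = np.median(np.diff(f))
    if df > band_width:
        raise ValueError("frequency grid coarser than the band width")
    edges = []
    means = []
    lo = 0.0
    while lo < f_max - 1e-9:
        hi = lo + band_width
        mask = (f >= lo) & (f < hi)
        if not mask.any():
            raise ValueError(f"no frequency bins inside [{lo}, {hi}) Hz")
        edges.append((lo, hi))
        means.append(float(np.asarray(psd.power)[mask].mean()))
        lo = hi
    return BandPowerTable(band_edges=tuple(edges), band_means=np.array(means))


def band_range_mean(table: BandPowerTable, low: float = 20.0, high: float = 50.0) -> float:
    """Mean of the band means fully inside [low, high) — the 20-50 Hz
    polyspiking summary statistic by default."""
    inside = [
        m for (lo, hi), m in zip(table.band_edges, table.band_means) if lo >= low and hi <= high
    ]
    covered = sum(hi - lo for (lo, hi) in table.band_edges if lo >= low and hi <= high)
    if not inside or abs(covered - (high - low)) > 1e-9:
        raise ValueError(f"[{low}, {high}) does not align with the band edges")
    return float(np.mean(inside))


# ---------------------------------------------------------------------------
# Group normalization
# ---------------------------------------------------------------------------

def normalize_to_reference(
    groups: dict[str, list[float]], reference_group: str
) -> list[GroupSummary]:
    """Express each group's mean as a percent of the reference group's mean
    (reference = 100%)."""
    if reference_group not in groups or len(groups[reference_group]) == 0:
        raise ValueError(f"reference group {reference_group!r} absent or empty")
    ref_mean = float(np.mean(groups[reference_group]))
    if ref_mean == 0:
        raise ValueError("reference group mean is zero; cannot normalize")
    out = []
    for name, values in groups.items():
        gs = GroupSummary(
            group=name,
            per_subject_values=tuple(float(v) for v in values),
            normalized_mean_percent=100.0 * float(np.mean(values)) / ref_mean,
        )
        out.append(gs)
    return out


# ---------------------------------------------------------------------------
# Convenience: full per-recording chain
# ---------------------------------------------------------------------------

def quantify_recording(
    rec: LFPRecording,
    threshold_factor: float = 3.0,
    min_duration: float = 0.1,
    window: float = 0.1,
    overlap: float = 0.8,
    band_low: float = 20.0,
    band_high: float = 50.0,
    notch: float | None = 50.0,
) -> tuple[list[EpileptiformEvent], BandPowerTable, float]:
    """Condition a raw trace and run the full quantification chain.

    Returns (events, band power table, band-range mean summary).
    """
    cond = bandpass_filter(rec)
    if notch is not None:
        cond = remove_line_noise(cond, freq=notch)
    events = detect_events(cond, threshold_factor=threshold_factor, min_duration=min_duration)
    psd = welch_psd(cond, window=window, overlap=overlap)
    table = band_average(psd)
    summary = band_range_mean(table, low=band_low, high=band_high)
    return events, table, summary
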