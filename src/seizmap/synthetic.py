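"""Seeded generators for every input the pipeline consumes.

The generators emulate the study conditions of a larval zebrafish *sv2a*
loss-of-function epilepsy experiment:

- 10-minute, 2 kHz local field potential (LFP) traces carrying polyspiking
  bursts whose energy concentrates in the 20-50 Hz range, on a white or
  pink noise floor (:func:`simulate_lfp`);
- negative-binomial RNA-seq counts, three genotypes in quadruplicate, with
  planted log2 fold changes between a designated contrast pair
  (:func:`simulate_counts`);
- a compound x gene perturbation reference with planted signature-opposing
  and signature-matching compounds (:func:`simulate_reference`);
- genotype-dependent larval survival, deaths confined to a configured
  day window (:func:`simulate_survival`).

Every generator is a pure function of its config, including the seed:
identical inputs give identical outputs. Each generator returns ground
truth alongside the data so downstream detection/recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lfp import LFPRecording
from .transcriptomics import Signature

__all__ = [
    "LFPSimConfig",
    "EventTruth",
    "CountSimConfig",
    "ReferenceSimConfig",
    "SurvivalSimConfig",
    "simulate_lfp",
    "simulate_counts",
    "simulate_reference",
    "simulate_survival",
    "make_ortholog_table",
]

# Mechanism-of-action classes assigned to simulated compounds. The first
# entries mirror classes of compounds the pipeline is meant to surface or
# exclude; the list cycles over the reference.
MECHANISM_CLASSES = [
    "MEK inhibitor",
    "PI3K inhibitor",
    "CDK inhibitor",
    "insulin sensitizer",
    "calcium channel blocker",
    "ATPase inhibitor",
    "HDAC inhibitor",
    "GABA receptor agonist",
    "sodium channel blocker",
    "protein synthesis",
    "DNA synthesis",
    "adrenergic receptor antagonist",
]


# ---------------------------------------------------------------------------
# LFP traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LFPSimConfig:
    """Parameters of a simulated LFP recording.

    Defaults follow the recording protocol the pipeline targets: 10-minute
    traces digitized at 2 kHz, epileptiform bursts of ~150 ms whose carrier
    lies in the 20-50 Hz polyspiking band.
    """

    duration: float = 600.0          # seconds
    sampling_rate: float = 2000.0    # Hz
    baseline_sd: float = 1.0         # arbitrary voltage units
    noise_color: str = "pink"        # {"white", "pink"}
    n_events: int = 0
    event_amplitude_factor: float = 5.0   # envelope peak, multiples of baseline_sd
    event_duration: float = 0.15     # seconds
    event_carrier_band: tuple[float, float] = (20.0, 50.0)  # Hz
    line_noise_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sampling_rate <= 2 * self.event_carrier_band[1]:
            raise ValueError("sampling_rate must exceed twice the upper carrier frequency")
        if self.noise_color not in ("white", "pink"):
            raise ValueError(f"unknown noise_color {self.noise_color!r}")
        if self.event_amplitude_factor <= 1:
            raise ValueError("event_amplitude_factor must exceed 1")
        if self.n_events < 0 or self.event_duration <= 0:
            raise ValueError("n_events >= 0 and event_duration > 0 required")
        if self.n_events * self.event_duration >= self.duration:
            raise ValueError("events do not fit into the trace duration")
        lo, hi = self.event_carrier_band
        if not 0 < lo < hi:
            raise ValueError("event_carrier_band must be a positive interval")


@dataclass(frozen=True)
class EventTruth:
    """Ground-truth burst intervals: sorted, pairwise disjoint, half-open."""

    intervals: tuple[tuple[float, float], ...]
    amplitude_factors: tuple[float, ...]

    def __post_init__(self):
        prev_end = -np.inf
        for start, end in self.intervals:
            if start < prev_end:
                raise ValueError("truth intervals must be sorted and disjoint")
            prev_end = end


MIN_EVENT_GAP = 0.5  # seconds between planted bursts; keeps events separable


def _colored_noise(rng: np.random.Generator, n: int, sd: float, color: str) -> np.ndarray:
    """White or 1/f (pink) Gaussian noise with the requested overall SD.

    Pink noise is produced by spectral shaping: white noise is transformed
    to the frequency domain, amplitudes scaled by 1/sqrt(f), and transformed
    back — deterministic given the generator state.
    """
    white = rng.standard_normal(n)
    if color == "white":
        return sd * white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0  # no DC
    x = np.fft.irfft(spec * scale, n)
    return sd * x / x.std()


def _tukey(n: int, alpha: float = 0.25) -> np.ndarray:
    """Tukey (flat-top raised-cosine) window; taper fraction ``alpha``."""
    if n == 1:
        return np.ones(1)
    t = np.linspace(0, 1, n)
    w = np.ones(n)
    edge = alpha / 2
    lo = t < edge
    hi = t > 1 - edge
    w[lo] = 0.5 * (1 + np.cos(np.pi * (2 * t[lo] / alpha - 1)))
    w[hi] = 0.5 * (1 + np.cos(np.pi * (2 * (1 - t[hi]) / alpha - 1)))
    return w


def _place_events(rng: np.random.Generator, cfg: LFPSimConfig) -> list[float]:
    """Rejection-sample non-overlapping start times, >= MIN_EVENT_GAP apart."""
    starts: list[float] = []
    span = cfg.duration - cfg.event_duration
    max_tries = 10_000 * max(cfg.n_events, 1)
    tries = 0
    while len(starts) < cfg.n_events:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {cfg.n_events} non-overlapping events of "
                f"{cfg.event_duration}s (gap {MIN_EVENT_GAP}s) in {cfg.duration}s"
            )
        cand = rng.uniform(0, span)
        if all(
            abs(cand - s) >= cfg.event_duration + MIN_EVENT_GAP for s in starts
        ):
            starts.append(cand)
    return sorted(starts)


def burst_waveform(
    rng: np.random.Generator, cfg: LFPSimConfig
) -> tuple[np.ndarray, float]:
    """One amplitude-modulated burst: sinusoidal carrier under a flat-top
    raised-cosine envelope whose peak is amplitude_factor x baseline_sd.

    A burst of duration T spreads spectral energy ~1/T Hz around its
    carrier, so the carrier is drawn uniformly from the band shrunk by a
    leakage margin of 1.5/T Hz per edge (capped at 45% of the band width);
    this keeps the burst's power inside the nominal band.
    Returns (waveform, carrier_hz).
    """
    n = int(round(cfg.event_duration * cfg.sampling_rate))
    lo, hi = cfg.event_carrier_band
    width = hi - lo
    margin = min(1.5 / cfg.event_duration, 0.45 * width)
    carrier = rng.uniform(lo + margin, hi - margin)
    t = np.arange(n) / cfg.sampling_rate
    phase = rng.uniform(0, 2 * np.pi)
    env = _tukey(n, alpha=0.25)
    amp = cfg.event_amplitude_factor * cfg.baseline_sd
    return amp * env * np.sin(2 * np.pi * carrier * t + phase), carrier


def simulate_lfp(config: LFPSimConfig) -> tuple[LFPRecording, EventTruth]:
    """Simulate one LFP trace plus the ground truth of its planted bursts."""
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.sampling_rate))
    trace = _colored_noise(rng, n, config.baseline_sd, config.noise_color)

    starts = _place_events(rng, config)
    intervals = []
    factors = []
    for s in starts:
        wave, _ = burst_waveform(rng, config)
        i0 = int(round(s * config.sampling_rate))
        i1 = min(i0 + len(wave), n)
        trace[i0:i1] += wave[: i1 - i0]
        intervals.append((s, s + config.event_duration))
        factors.append(config.event_amplitude_factor)

    if config.line_noise_amplitude > 0:
        t = np.arange(n) / config.sampling_rate
        trace += config.line_noise_amplitude * np.sin(2 * np.pi * 50.0 * t)

    rec = LFPRecording(
        samples=trace, sampling_rate=config.sampling_rate,
        subject_id=f"sim-{config.seed}", group="simulated",
    )
    return rec, EventTruth(tuple(intervals), tuple(factors))


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountSimConfig:
    """Negative-binomial count simulation, 3 genotypes x 4 replicates.

    Counts follow NB(mu, alpha) in the mean-dispersion parameterization
    (variance = mu + alpha mu^2). DE genes carry the planted log2 fold
    change in the last group of ``groups`` relative to the first (the
    designated contrast pair); intermediate groups stay at baseline.
    """

    n_genes: int = 2000
    groups: tuple[tuple[str, int], ...] = (("wt", 4), ("het", 4), ("hom", 4))
    mean_log_expression: tuple[float, float] = (0.0, 1.0)  # lognormal params of gene weights
    dispersion: float = 0.05
    frac_de: float = 0.0
    log2fc_distribution: tuple[float, float] = (2.0, 0.0)  # (|log2fc| mean, sd)
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.frac_de <= 1:
            raise ValueError("frac_de must lie in [0, 1]")
        if any(n < 2 for _, n in self.groups):
            raise ValueError("each group needs >= 2 replicates")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ValueError("invalid library_size_range")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, alpha) sample via the gamma-Poisson mixture."""
    if alpha < 1e-12:
        return rng.poisson(mu)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mu)
    return rng.poisson(lam)


def simulate_counts(config: CountSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a count matrix and its DE truth table.

    Returns
    -------
    counts : DataFrame, genes x samples, int64; samples named
        ``<group>_<replicate>``.
    truth : DataFrame with columns ``gene_id, true_log2fc, is_de`` for the
        designated contrast (last group over first), one row per gene.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"gene_{i + 1:05d}" for i in range(config.n_genes)]

    mu_log, sd_log = config.mean_log_expression
    weights = rng.lognormal(mu_log, sd_log, config.n_genes)
    weights /= weights.sum()

    n_de = int(round(config.frac_de * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    fc_mean, fc_sd = config.log2fc_distribution
    magnitudes = np.abs(rng.normal(fc_mean, fc_sd, n_de)) if fc_sd > 0 else np.full(n_de, fc_mean)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    true_log2fc = np.zeros(config.n_genes)
    true_log2fc[de_idx] = signs * magnitudes

    contrast_group = config.groups[-1][0]
    cols: dict[str, np.ndarray] = {}
    for g_i, (group, n_rep) in enumerate(config.groups):
        is_contrast = group == contrast_group and g_i == len(config.groups) - 1
        gene_mu_scale = 2.0 ** true_log2fc if is_contrast else np.ones(config.n_genes)
        for r in range(n_rep):
            lib = rng.integers(config.library_size_range[0], config.library_size_range[1] + 1)
            mu = weights * gene_mu_scale
            mu = mu / mu.sum() * lib
            cols[f"{group}_{r + 1}"] = _nb_draw(rng, mu, config.dispersion)

    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"), dtype=np.int64)
    truth = pd.DataFrame(
        {"gene_id": genes, "true_log2fc": true_log2fc, "is_de": true_log2fc != 0}
    )
    return counts, truth


def design_of(counts: pd.DataFrame) -> dict[str, str]:
    """Sample -> group mapping implied by ``<group>_<replicate>`` names."""
    return {c: c.rsplit("_", 1)[0] for c in counts.columns}


# ---------------------------------------------------------------------------
# Perturbation reference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceSimConfig:
    """Compound x gene perturbation reference with planted connections.

    ``n_opposing`` compounds are built to reverse the supplied disease
    signature (its up-genes pushed to their most-negative values and
    down-genes to their most-positive); ``n_matching`` compounds mimic it;
    the rest are pure noise. ``signal_scale`` is the magnitude of the
    planted shift in z-score-like units; ``noise_sd`` is the SD of the
    additive noise and of the background profiles.
    """

    n_compounds: int = 50
    n_genes: int = 978   # landmark-sized gene space
    n_opposing: int = 3
    n_matching: int = 3
    noise_sd: float = 0.5
    signal_scale: float = 3.0
    mechanism_labels: Mapping[str, str] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_opposing + self.n_matching > self.n_compounds:
            raise ValueError("n_opposing + n_matching must not exceed n_compounds")
        if self.noise_sd < 0 or self.signal_scale <= 0:
            raise ValueError("noise_sd >= 0 and signal_scale > 0 required")


def simulate_reference(
    config: ReferenceSimConfig, disease_signature: Signature
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a perturbation reference against a disease signature.

    Returns
    -------
    reference : DataFrame, genes x compounds (differential-expression-like
        values; more positive = more up-regulated by the compound).
    truth : DataFrame with columns ``compound_id, compound_class,
        mechanism_class`` where compound_class is one of
        {"opposing", "matching", "neutral"}.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"HGENE{i + 1:04d}" for i in range(config.n_genes)]
    sig_genes = set(disease_signature.up) | set(disease_signature.down)
    extra = sorted(sig_genes - set(genes))
    if extra:
        # Signature genes outside the default namespace join it, replacing
        # tail filler genes so the dimensions stay as configured.
        if len(sig_genes) > config.n_genes - 1:
            raise ValueError("signature larger than reference gene namespace")
        filler = [g for g in genes if g not in sig_genes]
        n_filler = config.n_genes - len(sig_genes)
        genes = sorted(filler[:n_filler] + sorted(sig_genes))
    missing = sig_genes - set(genes)
    if missing:
        raise ValueError(f"signature genes missing from reference namespace: {sorted(missing)[:5]}")

    gene_index = pd.Index(genes, name="gene_id")
    up_mask = gene_index.isin(disease_signature.up)
    down_mask = gene_index.isin(disease_signature.down)

    compounds = [f"cpd_{i + 1:03d}" for i in range(config.n_compounds)]
    classes = ["opposing"] * config.n_opposing + ["matching"] * config.n_matching
    classes += ["neutral"] * (config.n_compounds - len(classes))
    order = rng.permutation(config.n_compounds)
    cls = np.array(classes)[order]

    data = np.zeros((len(genes), config.n_compounds))
    for j, c in enumerate(cls):
        profile = config.noise_sd * rng.standard_normal(len(genes))
        if c == "opposing":
            profile[up_mask] -= config.signal_scale
            profile[down_mask] += config.signal_scale
        elif c == "matching":
            profile[up_mask] += config.signal_scale
            profile[down_mask] -= config.signal_scale
        data[:, j] = profile

    reference = pd.DataFrame(data, index=gene_index, columns=compounds)

    if config.mechanism_labels is not None:
        mech = [config.mechanism_labels[c] for c in compounds]
    else:
        # Planted compounds get non-excluded classes; blocklisted classes
        # land on neutral compounds so exclusion logic is exercised.
        safe = [m for m in MECHANISM_CLASSES if m not in ("protein synthesis", "DNA synthesis")]
        mech = []
        neutral_i = 0
        for j, c in enumerate(cls):
            if c == "neutral":
                mech.append(MECHANISM_CLASSES[neutral_i % len(MECHANISM_CLASSES)])
                neutral_i += 1
            else:
                mech.append(safe[j % len(safe)])
    truth = pd.DataFrame(
        {"compound_id": compounds, "compound_class": cls, "mechanism_class": mech}
    )
    return reference, truth


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalSimConfig:
    """Genotype-dependent larval survival.

    ``groups`` maps a label to ``(death_window, n)``: subjects of a group
    with a death window die uniformly on integer days within it (inclusive);
    groups with ``None`` are censored alive at ``follow_up`` days.
    """

    groups: Mapping[str, tuple[tuple[int, int] | None, int]] = field(
        default_factory=lambda: {"wt": (None, 94), "het": (None, 208), "hom": ((8, 10), 92)}
    )
    follow_up: int = 10
    seed: int = 0

    def __post_init__(self):
        for label, (window, n) in self.groups.items():
            if n < 1:
                raise ValueError(f"group {label!r} needs n >= 1")
            if window is not None:
                lo, hi = window
                if not 0 < lo <= hi <= self.follow_up:
                    raise ValueError(f"death window of {label!r} outside follow-up")


def simulate_survival(config: SurvivalSimConfig) -> pd.DataFrame:
    """Per-subject records: columns ``subject_id, group, day, event``."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for label, (window, n) in config.groups.items():
        if window is None:
            days = np.full(n, config.follow_up)
            events = np.zeros(n, dtype=int)
        else:
            days = rng.integers(window[0], window[1] + 1, size=n)
            events = np.ones(n, dtype=int)
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{label}_{i + 1:03d}",
                    "group": label,
                    "day": int(days[i]),
                    "event": int(events[i]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ortholog table
# ---------------------------------------------------------------------------

def make_ortholog_table(
    gene_ids: Sequence[str],
    target_prefix: str = "HGENE",
    frac_unmapped: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic source -> target ortholog mapping for simulated genes.

    Maps ``gene_00017`` to ``HGENE0017``-style human-like symbols; a random
    ``frac_unmapped`` fraction of sources is left out of the table to
    emulate genes without an ortholog.
    """
    rng = np.random.default_rng(seed)
    keep = rng.random(len(gene_ids)) >= frac_unmapped
    rows = []
    for i, g in enumerate(gene_ids):
        if not keep[i]:
            continue
        digits = "".join(ch for ch in g if ch.isdigit()) or str(i + 1)
        rows.append({"source_id": g, "target_symbol": f"{target_prefix}{int(digits):04d}"})
    return pd.DataFrame(rows, columns=["source_id", "target_symbol"])
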