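"""End-to-end pipeline: simulate -> quantify LFP -> DE -> signature ->
connectivity -> candidate report.

The stage order mirrors the drug-repurposing workflow: epileptiform
activity in mutant larvae is quantified from LFP traces; a mutant-vs-
wildtype differential-expression signature is built from counts, mapped
into the human ortholog namespace and truncated to the top 50 per side by
Wald statistic; the signature is then scored against a compound reference
to nominate candidates with strongly opposing profiles (score < -90).

All randomness flows from the seeds in :class:`PipelineConfig`; a run with
the same config produces byte-identical stage outputs, recorded in a
:class:`RunManifest` with per-file SHA-256 digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from . import lfp as slfp
from . import synthetic as ssyn
from . import transcriptomics as str_
from .connectivity import DEFAULT_BLOCKLIST, score_reference, select_candidates
from .stats import log_rank, one_way_anova

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

PACKAGE_VERSION = "0.1.0"


@dataclass(frozen=True)
class PipelineConfig:
    """Every stage parameter of the end-to-end run, with field defaults
    equal to the analysis conventions of the study design.

    Unknown keys are rejected when loading from a mapping or YAML file.
    """

    # LFP quantification
    threshold_factor: float = 3.0
    min_duration: float = 0.1        # s
    welch_window: float = 0.1        # s
    welch_overlap: float = 0.8
    band_width: float = 10.0         # Hz
    summary_band: tuple[float, float] = (20.0, 50.0)
    # DE / signature
    cpm_threshold: float = 1.0
    alpha: float = 0.05
    k: int = 50
    # connectivity
    opposing_cut: float = -90.0
    similar_cut: float = 90.0
    blocklist: tuple[str, ...] = DEFAULT_BLOCKLIST
    # simulation scope
    n_subjects_per_group: int = 4
    lfp_duration: float = 60.0       # s per simulated trace
    mutant_n_events: int = 30
    n_genes: int = 2000
    frac_de: float = 0.06
    n_compounds: int = 50
    n_opposing: int = 3
    n_matching: int = 3
    reference_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.welch_overlap < 1:
            raise ValueError("welch_overlap must lie in [0, 1)")
        if self.threshold_factor <= 0 or self.min_duration <= 0:
            raise ValueError("detection parameters must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not self.opposing_cut < 0 < self.similar_cut:
            raise ValueError("cuts must straddle zero")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        m = dict(mapping)
        for key in ("summary_band", "blocklist"):
            if key in m and isinstance(m[key], list):
                m[key] = tuple(m[key])
        return cls(**m)

    @classmethod
    def from_yaml(cls, path: str | Path, overrides: dict | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if overrides:
            raw.update(overrides)
        return cls.from_mapping(raw)


@dataclass
class RunManifest:
    config: dict
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    versions: dict[str, str] = field(default_factory=dict)
    timestamp: str = ""

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulate_cohort_lfp(cfg: PipelineConfig) -> dict[str, list[float]]:
    """Simulate per-genotype traces and quantify the 20-50 Hz summary.

    Wildtype and heterozygous larvae get burst-free traces; homozygous
    mutants carry polyspiking bursts.
    """
    values: dict[str, list[float]] = {}
    for g_i, (group, n_events) in enumerate(
        [("wt", 0), ("het", 0), ("hom", cfg.mutant_n_events)]
    ):
        vals = []
        for s in range(cfg.n_subjects_per_group):
            sim = ssyn.LFPSimConfig(
                duration=cfg.lfp_duration,
                n_events=n_events,
                seed=cfg.seed * 1000 + g_i * 100 + s,
            )
            rec, _ = ssyn.simulate_lfp(sim)
            _, _, summary = slfp.quantify_recording(
                rec,
                threshold_factor=cfg.threshold_factor,
                min_duration=cfg.min_duration,
                window=cfg.welch_window,
                overlap=cfg.welch_overlap,
                band_low=cfg.summary_band[0],
                band_high=cfg.summary_band[1],
            )
            vals.append(summary)
        values[group] = vals
    return values


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute the full synthetic pipeline; write stage outputs and a
    manifest into ``out_dir``. Returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=asdict(config),
        versions={"seizmap": PACKAGE_VERSION, "numpy": np.__version__, "pandas": pd.__version__},
        timestamp=datetime.now(timezone.utc).isoformat(),
    )

    def record(path: Path) -> None:
        manifest.outputs[path.name] = _sha256(path)

    # stage 1: LFP quantification
    stage = "lfp"
    try:
        band_values = _simulate_cohort_lfp(config)
        summaries = slfp.normalize_to_reference(band_values, "wt")
        lfp_df = pd.DataFrame(
            {
                "group": [s.group for s in summaries],
                "mean_band_power": [s.mean for s in summaries],
                "sd": [s.sd for s in summaries],
                "percent_of_wt": [s.normalized_mean_percent for s in summaries],
            }
        )
        lfp_path = out / "lfp_summary.tsv"
        lfp_df.to_csv(lfp_path, sep="\t", index=False, float_format=sio.FLOAT_FMT)
        record(lfp_path)
        anova = one_way_anova(band_values)
        logger.info("lfp: one-way ANOVA F=%.3f p=%.3g", anova.statistic, anova.p_value)

        # stage 2: DE
        stage = "transcriptomics"
        counts, de_truth = ssyn.simulate_counts(
            ssyn.CountSimConfig(
                n_genes=config.n_genes, frac_de=config.frac_de, seed=config.seed + 1
            )
        )
        design = ssyn.design_of(counts)
        filtered = str_.filter_expressed(counts, design, config.cpm_threshold)
        de = str_.nb_wald_test(filtered, design, contrast=("hom", "wt"))
        de_path = out / "de_results.tsv"
        sio.write_de_tsv(de_path, de)
        record(de_path)
        n_total, n_up, n_down = str_.count_deg(de, alpha=config.alpha)
        logger.info("de: %d DEGs (%d up, %d down)", n_total, n_up, n_down)

        # stage 3: signature
        stage = "signature"
        orth = ssyn.make_ortholog_table(list(de["gene_id"]))
        mapped = str_.map_orthologs(de, orth)
        signature = str_.select_signature(mapped, k=config.k)
        sio.write_grp(out / "signature_up.grp", signature.up)
        sio.write_grp(out / "signature_down.grp", signature.down)
        record(out / "signature_up.grp")
        record(out / "signature_down.grp")

        # stage 4: connectivity
        stage = "connectivity"
        reference, cpd_truth = ssyn.simulate_reference(
            ssyn.ReferenceSimConfig(
                n_compounds=config.n_compounds,
                n_opposing=config.n_opposing,
                n_matching=config.n_matching,
                noise_sd=config.reference_noise_sd,
                seed=config.seed + 2,
            ),
            signature,
        )
        sio.write_gct(out / "reference.gct", reference)
        record(out / "reference.gct")
        results = score_reference(signature, reference)
        meta = cpd_truth[["compound_id", "mechanism_class"]]
        report = select_candidates(
            results,
            meta,
            blocklist=config.blocklist,
            opposing_cut=config.opposing_cut,
            similar_cut=config.similar_cut,
        )
        report = report.merge(cpd_truth[["compound_id", "compound_class"]], on="compound_id")
        report = report.sort_values("normalized_score").reset_index(drop=True)
        report_path = out / "candidate_report.tsv"
        report.to_csv(report_path, sep="\t", index=False, float_format=sio.FLOAT_FMT)
        record(report_path)

        # stage 5: survival
        stage = "survival"
        surv = ssyn.simulate_survival(ssyn.SurvivalSimConfig(seed=config.seed + 3))
        sio.write_survival_tsv(out / "survival.tsv", surv)
        record(out / "survival.tsv")
        lr = log_rank(surv, "wt", "hom")
        surv_stats = pd.DataFrame(
            [{"comparison": "wt vs hom", "chi_square": lr.statistic, "p_value": lr.p_value}]
        )
        surv_stats.to_csv(out / "survival_test.tsv", sep="\t", index=False,
                          float_format=sio.FLOAT_FMT)
        record(out / "survival_test.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.write(out / "manifest.json")
    return manifest
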