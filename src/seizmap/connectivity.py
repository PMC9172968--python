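"""Connectivity-map-style scoring of a disease signature against a
compound perturbation reference.

Each compound's expression profile is ranked from most up- to most
down-regulated. The signature's up- and down-sets are scored against that
ranking with the classic two-sided Kolmogorov-Smirnov enrichment statistic:
for query genes at ascending ranks V(1..t) in a list of n genes,

    a = max_j [ j/t - V(j)/n ],    b = max_j [ V(j)/n - (j-1)/t ],
    es = a  if a > b  else  -b.

The raw connectivity score combines the two enrichments as
(es_up - es_down)/2 when they disagree in sign and is set to 0 when they
agree (null connectivity). Raw scores over the whole reference are scaled
by the maximum absolute raw score onto [-100, 100]; compounds scoring
below -90 oppose the disease signature (therapeutic candidates), above
+90 mimic it, and exactly 0 show no connection (negative controls).
Compounds whose mechanism class targets master regulators of cellular
homeostasis and proliferation are excluded before candidate selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RankedProfile",
    "ConnectivityResult",
    "DEFAULT_BLOCKLIST",
    "rank_genes",
    "ks_enrichment",
    "raw_connectivity",
    "normalize_scores",
    "score_reference",
    "select_candidates",
]

DEFAULT_BLOCKLIST = (
    "DNA synthesis",
    "RNA synthesis",
    "tRNA synthetase",
    "RNA polymerase",
    "protein synthesis",
)

ZERO_TOL = 1e-9  # |normalized score| below this counts as "equaling 0"


@dataclass(frozen=True)
class RankedProfile:
    """A compound's genes ordered from most up- to most down-regulated."""

    compound_id: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if len(self.genes) < 2:
            raise ValueError("profile needs at least 2 genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in profile")

    @property
    def n(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class ConnectivityResult:
    compound_id: str
    es_up: float
    es_down: float
    raw_score: float
    normalized_score: float = np.nan
    label: str = "none"


def rank_genes(compound_id: str, values: pd.Series) -> RankedProfile:
    """Rank genes by profile value, descending; ties break lexicographically
    by gene id."""
    if values.index.duplicated().any():
        raise ValueError("duplicate gene ids in profile values")
    if not np.isfinite(values.to_numpy(float)).all():
        raise ValueError("profile values must be finite")
    order = values.to_frame("v")
    order["g"] = order.index.astype(str)
    order = order.sort_values(["v", "g"], ascending=[False, True])
    return RankedProfile(compound_id=compound_id, genes=tuple(order["g"]))


def ks_enrichment(query: set[str] | tuple[str, ...], ranked: RankedProfile) -> float:
    """Two-sided KS enrichment of a query gene set in a ranked profile.

    Near +1 when the query clusters at the top of the ranking, near -1 at
    the bottom.
    """
    qset = set(query)
    if not qset:
        raise ValueError("query set is empty")
    positions = {g: i + 1 for i, g in enumerate(ranked.genes)}
    missing = sorted(qset - positions.keys())
    if missing:
        raise ValueError(f"query genes absent from profile: {missing}")
    v = np.sort([positions[g] for g in qset])
    t = len(v)
    n = ranked.n
    j = np.arange(1, t + 1)
    a = np.max(j / t - v / n)
    b = np.max(v / n - (j - 1) / t)
    return float(a if a > b else -b)


def raw_connectivity(sig, ranked: RankedProfile) -> ConnectivityResult:
    """Combine up/down enrichments into one raw score.

    Raw = (es_up - es_down)/2 when the two enrichments have opposite signs;
    0 when they share a sign (null connectivity). Signature genes missing
    from the profile are dropped with a log notice; an error is raised if a
    side empties entirely.
    """
    present = set(ranked.genes)
    up = tuple(g for g in sig.up if g in present)
    down = tuple(g for g in sig.down if g in present)
    n_dropped = (len(sig.up) - len(up)) + (len(sig.down) - len(down))
    if n_dropped:
        logger.info(
            "raw_connectivity[%s]: dropped %d signature genes absent from profile",
            ranked.compound_id, n_dropped,
        )
    if not up or not down:
        raise ValueError("a signature side is empty after intersection with the profile")
    es_up = ks_enrichment(up, ranked)
    es_down = ks_enrichment(down, ranked)
    if np.sign(es_up) == np.sign(es_down):
        raw = 0.0
    else:
        raw = (es_up - es_down) / 2.0
    return ConnectivityResult(
        compound_id=ranked.compound_id, es_up=es_up, es_down=es_down, raw_score=raw
    )


def normalize_scores(results: list[ConnectivityResult]) -> list[ConnectivityResult]:
    """Scale raw scores by max |raw| onto [-100, 100]; zero raws stay 0."""
    raws = np.array([r.raw_score for r in results])
    max_abs = np.abs(raws).max() if len(raws) else 0.0
    if max_abs == 0:
        logger.warning("normalize_scores: all raw scores are zero")
        scale = 0.0
    else:
        scale = 100.0 / max_abs
    return [
        ConnectivityResult(
            compound_id=r.compound_id,
            es_up=r.es_up,
            es_down=r.es_down,
            raw_score=r.raw_score,
            normalized_score=r.raw_score * scale,
            label=r.label,
        )
        for r in results
    ]


def score_reference(sig, reference: pd.DataFrame) -> list[ConnectivityResult]:
    """Score a signature against every compound column of a genes x
    compounds reference matrix; returns normalized results."""
    results = []
    for compound in reference.columns:
        ranked = rank_genes(str(compound), reference[compound])
        results.append(raw_connectivity(sig, ranked))
    return normalize_scores(results)


def select_candidates(
    results: list[ConnectivityResult],
    metadata: pd.DataFrame,
    blocklist: tuple[str, ...] = DEFAULT_BLOCKLIST,
    opposing_cut: float = -90.0,
    similar_cut: float = 90.0,
) -> pd.DataFrame:
    """Label scored compounds, excluding blocklisted mechanism classes.

    ``metadata`` needs columns ``compound_id, mechanism_class`` covering
    every scored compound. Blocklist matching is case-insensitive exact.
    Labels: ``opposing_candidate`` (score < opposing_cut),
    ``similar_control`` (score > similar_cut), ``null_control``
    (|score| < 1e-9), ``excluded`` (blocklisted class), else ``none``.
    """
    meta = metadata.set_index("compound_id")["mechanism_class"]
    missing = [r.compound_id for r in results if r.compound_id not in meta.index]
    if missing:
        raise ValueError(f"compounds without metadata: {missing[:5]}")
    blocked = {b.lower() for b in blocklist}
    rows = []
    for r in results:
        mech = str(meta[r.compound_id])
        if mech.lower() in blocked:
            label = "excluded"
        elif r.normalized_score < opposing_cut:
            label = "opposing_candidate"
        elif r.normalized_score > similar_cut:
            label = "similar_control"
        elif abs(r.normalized_score) < ZERO_TOL:
            label = "null_control"
        else:
            label = "none"
        rows.append(
            {
                "compound_id": r.compound_id,
                "mechanism_class": mech,
                "es_up": r.es_up,
                "es_down": r.es_down,
                "raw_score": r.raw_score,
                "normalized_score": r.normalized_score,
                "label": label,
            }
        )
    return pd.DataFrame(rows)
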