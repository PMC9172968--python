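"""Published summary tables of the modeled *sv2a* knockout study, used as
small fixtures for threshold and ordering logic.

These are transcriptions of printed result tables, not outputs of this
package: the top-10 up- and down-regulated protein-coding genes of the
mutant-vs-wildtype contrast (sorted by Wald statistic), and the
connectivity scores of the six compounds selected for pharmacological
follow-up.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["top_regulated_genes", "selected_compound_scores"]

# gene symbol, linear fold change, Wald statistic, BH-adjusted p
_TOP_GENES = [
    # up-regulated
    ("prl2", 4.81, 9.83, 7.39e-19),
    ("npffl", 2.73, 8.90, 2.37e-15),
    ("gnrh3", 3.79, 8.22, 4.98e-13),
    ("uts1", 2.13, 7.89, 4.60e-12),
    ("npas4a", 5.18, 7.72, 1.27e-11),
    ("crhbp", 1.93, 7.44, 9.13e-11),
    ("agrp", 3.03, 7.40, 1.16e-10),
    ("crema", 2.44, 7.31, 2.18e-10),
    ("crhb", 2.00, 7.14, 4.82e-10),
    ("hsd20b2", 2.67, 7.12, 5.62e-10),
    # down-regulated
    ("sv2a", 0.16, -16.71, 2.54e-58),
    ("rbp2a", 0.23, -9.81, 7.39e-19),
    ("leg1.2", 0.12, -8.93, 2.23e-15),
    ("krtt1c19e", 0.22, -8.86, 2.91e-15),
    ("apoda.1", 0.30, -8.72, 8.53e-15),
    ("ehhadh", 0.28, -8.46, 7.35e-14),
    ("nr0b2a", 0.22, -8.20, 5.36e-13),
    ("actn3a", 0.35, -8.04, 1.83e-12),
    ("gstt1b", 0.41, -7.97, 2.93e-12),
    ("gpnmb", 0.40, -7.95, 3.23e-12),
]

# compound, mechanism class, connectivity score in [-100, 100]
_SELECTED_COMPOUNDS = [
    ("PD-98059", "MEK inhibitor", -99.08),
    ("AS-605240", "PI3K inhibitor", -93.64),
    ("Alvocidib", "CDK inhibitor", -91.48),
    ("CAY-10415", "insulin sensitizer", 0.0),
    ("Calmidazolium HCl", "calcium channel blocker", 96.39),
    ("Digoxin", "ATPase inhibitor", 96.44),
]


def top_regulated_genes() -> pd.DataFrame:
    """Top 10 up- and 10 down-regulated genes as a DE result table
    (columns ``gene_id, log2fc, fold_change, wald, pvalue, padj``; the
    printed adjusted p doubles as the raw p, which preserves ordering)."""
    df = pd.DataFrame(_TOP_GENES, columns=["gene_id", "fold_change", "wald", "padj"])
    df["log2fc"] = np.log2(df["fold_change"])
    df["pvalue"] = df["padj"]
    return df[["gene_id", "log2fc", "fold_change", "wald", "pvalue", "padj"]]


def selected_compound_scores() -> pd.DataFrame:
    """Connectivity scores of the six compounds chosen for follow-up
    (columns ``compound_id, mechanism_class, normalized_score``)."""
    return pd.DataFrame(
        _SELECTED_COMPOUNDS, columns=["compound_id", "mechanism_class", "normalized_score"]
    )
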