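"""Readers and writers for the plain-text formats used across the pipeline.

All tabular formats are tab-separated with a header row unless noted.
Numeric output uses 6 significant digits; round-trips preserve content up to
that precision.

Formats
-------
- LFP trace: 2-column CSV ``time_s,voltage`` (or single-column voltage with
  the sampling rate supplied by the caller).
- Event table: TSV ``trace_id, start_s, end_s, peak_factor``.
- Count matrix: TSV, gene rows x sample columns, first column ``gene_id``.
- Design: TSV ``sample_id, group``.
- DE results: TSV ``gene_id, log2fc, fold_change, wald, pvalue, padj``.
- Gene sets: GRP (one gene per line, ``#`` comments) and GMT (set name,
  description, then members, tab-separated).
- Reference matrix: GCT v1.3, genes as rows, compounds as columns.
- Survival: TSV ``subject_id, group, day, event`` (event 1 = death,
  0 = censored).
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "read_trace_csv",
    "write_trace_csv",
    "write_events_tsv",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_design_tsv",
    "write_design_tsv",
    "read_de_tsv",
    "write_de_tsv",
    "read_grp",
    "write_grp",
    "read_gmt",
    "write_gmt",
    "read_gct",
    "write_gct",
    "read_survival_tsv",
    "write_survival_tsv",
    "read_ortholog_tsv",
    "write_ortholog_tsv",
]

FLOAT_FMT = "%.6g"


class ParseError(ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# LFP traces and events
# ---------------------------------------------------------------------------

def write_trace_csv(path: str | Path, samples: np.ndarray, sampling_rate: float) -> None:
    t = np.arange(len(samples)) / sampling_rate
    df = pd.DataFrame({"time_s": t, "voltage": np.asarray(samples)})
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_trace_csv(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a 2-column trace CSV; returns (samples, sampling_rate).

    The rate is inferred from the median time step and must be uniform to
    within 1%.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ParseError(f"expected 2 columns (time_s, voltage), got {df.shape[1]}")
    t = df.iloc[:, 0].to_numpy(float)
    v = df.iloc[:, 1].to_numpy(float)
    if len(t) < 2:
        raise ParseError("trace needs at least 2 samples")
    dt = np.diff(t)
    if dt.min() <= 0 or dt.max() / dt.min() > 1.01:
        raise ParseError("time column is not uniformly increasing")
    return v, 1.0 / float(np.median(dt))


def write_events_tsv(path: str | Path, trace_id: str, events) -> None:
    rows = [
        {
            "trace_id": trace_id,
            "start_s": ev.start,
            "end_s": ev.end,
            "peak_factor": ev.peak_amplitude_factor,
        }
        for ev in events
    ]
    cols = ["trace_id", "start_s", "end_s", "peak_factor"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# Count matrices and designs
# ---------------------------------------------------------------------------

def write_counts_tsv(path: str | Path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate gene identifier {dup!r}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ParseError("non-numeric entries in count matrix")
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ParseError(f"negative count for gene {df.index[i]!r}", line=int(i) + 2)
    if not np.allclose(arr, np.round(arr)):
        raise ParseError("counts must be integers")
    return df.astype(np.int64)


def write_design_tsv(path: str | Path, design: dict[str, str]) -> None:
    pd.DataFrame(
        {"sample_id": list(design), "group": list(design.values())}
    ).to_csv(path, sep="\t", index=False)


def read_design_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "group"} <= set(df.columns):
        raise ParseError("design must have columns sample_id, group")
    if df["sample_id"].duplicated().any():
        raise ParseError("duplicate sample_id in design")
    return dict(zip(df["sample_id"].astype(str), df["group"].astype(str)))


# ---------------------------------------------------------------------------
# DE result tables
# ---------------------------------------------------------------------------

DE_COLUMNS = ["gene_id", "log2fc", "fold_change", "wald", "pvalue", "padj"]


def write_de_tsv(path: str | Path, results: pd.DataFrame) -> None:
    results.loc[:, DE_COLUMNS].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_de_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"DE table missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Gene sets: GRP and GMT
# ---------------------------------------------------------------------------

def write_grp(path: str | Path, genes: Sequence[str]) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_grp(path: str | Path) -> list[str]:
    genes = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            raise ParseError("GRP lines hold a single identifier", line=i)
        genes.append(line)
    return genes


def write_gmt(path: str | Path, sets: dict[str, Sequence[str]], description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError("GMT rows need name, description and >=1 member", line=i)
        name = parts[0]
        if name in sets:
            raise ParseError(f"duplicate set name {name!r}", line=i)
        sets[name] = [g for g in parts[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# GCT v1.3 (genes x compounds)
# ---------------------------------------------------------------------------

def write_gct(path: str | Path, matrix: pd.DataFrame) -> None:
    """Write a genes-as-rows, compounds-as-columns matrix as GCT v1.3."""
    n_rows, n_cols = matrix.shape
    buf = _io.StringIO()
    buf.write("#1.3\n")
    buf.write(f"{n_rows}\t{n_cols}\t0\t0\n")
    buf.write("id\t" + "\t".join(str(c) for c in matrix.columns) + "\n")
    for gene, row in matrix.iterrows():
        buf.write(str(gene) + "\t" + "\t".join(FLOAT_FMT % v for v in row) + "\n")
    Path(path).write_text(buf.getvalue())


def read_gct(path: str | Path) -> pd.DataFrame:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#1."):
        raise ParseError("missing GCT version line (#1.x)", line=1)
    try:
        dims = [int(x) for x in lines[1].split("\t")[:2]]
        n_rows, n_cols = dims
    except (IndexError, ValueError) as exc:
        raise ParseError("malformed GCT dimension line", line=2) from exc
    header = lines[2].split("\t")
    n_meta = len(header) - 1 - n_cols  # row-metadata columns between id and data
    if n_meta < 0:
        raise ParseError("GCT header has fewer columns than declared", line=3)
    col_ids = header[1 + n_meta :]
    data = {}
    index = []
    for i, line in enumerate(lines[3 : 3 + n_rows], start=4):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ParseError(
                f"ragged GCT row: {len(parts)} fields, expected {len(header)}", line=i
            )
        rid = parts[0]
        if rid in data:
            raise ParseError(f"duplicate row identifier {rid!r}", line=i)
        index.append(rid)
        data[rid] = [float(x) for x in parts[1 + n_meta :]]
    if len(index) != n_rows:
        raise ParseError(f"expected {n_rows} data rows, found {len(index)}")
    return pd.DataFrame.from_dict(data, orient="index", columns=col_ids).loc[index]


# ---------------------------------------------------------------------------
# Survival records and ortholog tables
# ---------------------------------------------------------------------------

def write_survival_tsv(path: str | Path, records: pd.DataFrame) -> None:
    records.loc[:, ["subject_id", "group", "day", "event"]].to_csv(path, sep="\t", index=False)


def read_survival_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"subject_id", "group", "day", "event"}
    if not need <= set(df.columns):
        raise ParseError(f"survival table must have columns {sorted(need)}")
    if (df["day"] <= 0).any():
        raise ParseError("survival days must be positive")
    return df


def write_ortholog_tsv(path: str | Path, table: pd.DataFrame) -> None:
    table.loc[:, ["source_id", "target_symbol"]].to_csv(path, sep="\t", index=False)


def read_ortholog_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"source_id", "target_symbol"} <= set(df.columns):
        raise ParseError("ortholog table must have columns source_id, target_symbol")
    if df.isna().any().any() or (df.astype(str) == "").any().any():
        raise ParseError("empty identifiers in ortholog table")
    if df.duplicated().any():
        df = df.drop_duplicates()
    return df.astype(str)
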