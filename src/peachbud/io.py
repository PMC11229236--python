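"""Tabular input/output, validation and basic expression transforms.

Everything downstream of read alignment enters the pipeline as plain
tab-delimited text: a gene x sample count matrix (HTSeq-style, merged),
per-sample metadata, hormone concentration tables, and an alignment-log
summary table in the layout of a sequencing facility report.  This module
owns the parsing/validation of those tables and the two standard expression
transforms used throughout (log2-CPM and RPKM).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "read_count_matrix",
    "read_sample_metadata",
    "read_alignment_summary",
    "load_bundled_alignment_summary",
    "summarize_alignment_stats",
    "cpm",
    "cpm_log_transform",
    "rpkm",
]


@dataclass
class CountMatrix:
    """Integer gene x sample count table with optional per-gene lengths (bp).

    ``counts`` is indexed by unique gene IDs with unique sample columns;
    ``lengths`` (if present) is indexed identically to ``counts``.
    """

    counts: pd.DataFrame
    lengths: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise ValueError(f"duplicate gene ID {dup!r} in count matrix")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID {dup!r} in count matrix")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("count matrix contains non-numeric values")
        if np.any(arr < 0):
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at gene {c.index[g]!r}, sample {c.columns[s]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            g, s = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ValueError(
                f"non-integer count at gene {c.index[g]!r}, sample {c.columns[s]!r}"
            )
        self.counts = c.astype(np.int64)
        if self.lengths is not None:
            L = self.lengths.reindex(c.index)
            if L.isna().any():
                raise ValueError(
                    f"missing length for gene {L.index[L.isna()][0]!r}"
                )
            if (L <= 0).any():
                raise ValueError(
                    f"non-positive length for gene {L.index[L <= 0][0]!r}"
                )
            self.lengths = L.astype(float)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)], self.lengths)

    def to_tsv(self, path, length_path=None) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")
        if length_path is not None:
            if self.lengths is None:
                raise ValueError("no lengths to write")
            L = self.lengths.rename("length_bp")
            L.index.name = "gene_id"
            L.to_csv(length_path, sep="\t")

    def __eq__(self, other) -> bool:  # round-trip friendly equality
        if not isinstance(other, CountMatrix):
            return NotImplemented
        same = self.counts.equals(other.counts)
        if self.lengths is None or other.lengths is None:
            return same and (self.lengths is None) == (other.lengths is None)
        return same and self.lengths.astype(float).equals(other.lengths.astype(float))


def read_count_matrix(path, length_path=None) -> CountMatrix:
    """Read a TSV count matrix (first column gene IDs, header row of samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    lengths = None
    if length_path is not None:
        lt = pd.read_csv(length_path, sep="\t", index_col=0)
        lengths = lt.iloc[:, 0]
        lengths.index = lengths.index.astype(str)
    return CountMatrix(df, lengths)


def read_sample_metadata(path) -> pd.DataFrame:
    """Read per-sample factors (position, timepoint, replicate, efficacy)."""
    md = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if md.index.duplicated().any():
        raise ValueError("duplicate sample ID in metadata")
    return md


# ---------------------------------------------------------------------------
# Alignment-summary QC
# ---------------------------------------------------------------------------

_ALN_COLUMNS = [
    "total_reads",
    "not_aligned_concordantly",
    "aligned_concordantly_1_time",
    "aligned_concordantly_multi",
    "overall_alignment_rate",
]


def _parse_grouped_int(value) -> int:
    # facility reports print comma-grouped integers; accept both styles
    return int(str(value).replace(",", ""))


def read_alignment_summary(path, validate: bool = True) -> pd.DataFrame:
    """Read a per-library alignment summary table.

    Expected columns: library, total reads, reads not aligned concordantly,
    aligned concordantly exactly once, aligned concordantly more than once,
    and the aligner's overall alignment rate in percent.  Integer columns may
    be comma-grouped.  The overall rate is taken as printed by the aligner
    (it also counts discordant and single-mate alignments that the tabulated
    categories do not resolve) and is never recomputed here.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(columns={df.columns[0]: "library"}).set_index("library")
    missing = [c for c in _ALN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"alignment summary missing columns: {missing}")
    out = pd.DataFrame(index=df.index)
    for col in _ALN_COLUMNS[:-1]:
        out[col] = df[col].map(_parse_grouped_int)
    out["overall_alignment_rate"] = df["overall_alignment_rate"].str.rstrip("%").astype(float)
    if validate:
        cat = (
            out["not_aligned_concordantly"]
            + out["aligned_concordantly_1_time"]
            + out["aligned_concordantly_multi"]
        )
        bad = out.index[cat != out["total_reads"]]
        if len(bad):
            raise ValueError(
                f"concordant categories do not sum to total reads for {bad[0]!r}"
            )
        rate = out["overall_alignment_rate"]
        if ((rate < 0) | (rate > 100)).any():
            raise ValueError("overall alignment rate outside [0, 100]")
    return out


def load_bundled_alignment_summary() -> pd.DataFrame:
    """The 18-library RNA-seq alignment summary shipped with the package."""
    ref = importlib.resources.files("peachbud.data") / "alignment_summary.tsv"
    with importlib.resources.as_file(ref) as p:
        return read_alignment_summary(p)


def summarize_alignment_stats(summary: pd.DataFrame) -> dict:
    """Mean sequencing depth (millions of reads) and mean alignment rate (%).

    Both are arithmetic means over libraries, reported to one decimal as in
    a sequencing QC report.
    """
    if len(summary) == 0:
        raise ValueError("empty alignment summary")
    mean_reads_millions = summary["total_reads"].mean() / 1e6
    mean_rate = summary["overall_alignment_rate"].mean()
    return {
        "n_libraries": int(len(summary)),
        "mean_total_reads_millions": round(float(mean_reads_millions), 1),
        "mean_overall_alignment_rate_pct": round(float(mean_rate), 1),
    }


# ---------------------------------------------------------------------------
# Expression transforms
# ---------------------------------------------------------------------------


def cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts per million; every column sums to 1e6."""
    lib = counts.library_sizes()
    if (lib <= 0).any():
        raise ValueError(
            f"zero library size for sample {lib.index[lib <= 0][0]!r}"
        )
    return counts.counts / lib * 1e6


def cpm_log_transform(counts: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(CPM + pseudocount), the working expression scale of the pipeline."""
    return np.log2(cpm(counts) + pseudocount)


def rpkm(counts: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase of transcript per million reads mapped."""
    if counts.lengths is None:
        raise ValueError("RPKM requires per-gene lengths")
    lib_millions = counts.library_sizes() / 1e6
    if (lib_millions <= 0).any():
        raise ValueError("zero library size")
    length_kb = counts.lengths / 1e3
    return counts.counts.div(length_kb, axis=0).div(lib_millions, axis=1)
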