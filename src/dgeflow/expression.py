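"""Tag-count containers, RPKM normalization and mapping-summary arithmetic.

Digital gene expression (DGE) libraries are vectors of per-gene tag counts.
Expression is normalized as RPKM = 1e9 * C / (N * L), with C the tag count of
a gene, N the total mapped tags of the library and L the gene length in bp.
When a gene has several transcript models, the longest transcript defines L.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

RPKM_SCALE = 1e9


@dataclass
class CountMatrix:
    """Per-gene tag counts for a set of named libraries.

    Parameters
    ----------
    counts
        DataFrame indexed by gene_id with one integer column per library.
    library_sizes
        Total mapped tags per library (the N of RPKM and the N1/N2 of the
        exact test between two libraries). Must cover every count column.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        self.library_sizes = pd.Series(self.library_sizes).astype(np.int64)
        missing = set(self.counts.columns) - set(self.library_sizes.index)
        if missing:
            raise ValidationError(f"library sizes missing for: {sorted(missing)}")
        if (self.library_sizes <= 0).any():
            raise ValidationError("library sizes must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("tag counts must be non-negative")
        totals = self.counts.sum(axis=0)
        over = totals[totals > self.library_sizes[self.counts.columns]]
        if len(over):
            raise ValidationError(
                f"summed counts exceed library size for: {list(over.index)}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @classmethod
    def from_tsv(cls, path, library_sizes: Mapping[str, int] | None = None) -> "CountMatrix":
        """Read a count matrix TSV (gene_id + one column per library).

        If ``library_sizes`` is omitted the per-library count totals are used
        (i.e. every mapped tag is assumed to hit a profiled gene).
        """
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        sizes = (
            pd.Series(library_sizes)
            if library_sizes is not None
            else df.sum(axis=0)
        )
        return cls(df, sizes)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene_id")


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more transcript lengths (bp)."""

    gene_id: str
    transcript_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.transcript_lengths) == 0:
            raise ValidationError(f"{self.gene_id}: gene model has no transcripts")
        if any(l <= 0 for l in self.transcript_lengths):
            raise ValidationError(f"{self.gene_id}: transcript lengths must be positive")


def effective_gene_length(model: GeneModel) -> int:
    """Length used for expression: the longest transcript of the gene."""
    return max(model.transcript_lengths)


def rpkm(count: int, library_size: int, length: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if library_size <= 0:
        raise ValidationError("library_size must be positive")
    if length <= 0:
        raise ValidationError("gene length must be positive")
    if count < 0:
        raise ValidationError("count must be non-negative")
    return RPKM_SCALE * count / (library_size * length)


def rpkm_matrix(matrix: CountMatrix, gene_lengths: Mapping[str, int]) -> pd.DataFrame:
    """RPKM for every gene x library, preserving gene and library order.

    Genes absent from ``gene_lengths`` are dropped with a logged warning.
    """
    lengths = pd.Series(gene_lengths)
    if (lengths <= 0).any():
        raise ValidationError("gene lengths must be positive")
    known = matrix.gene_ids.intersection(lengths.index)
    dropped = matrix.gene_ids.difference(lengths.index)
    if len(dropped):
        logger.warning(
            "rpkm_matrix: dropping %d genes without a gene model (e.g. %s)",
            len(dropped), list(dropped[:3]),
        )
    counts = matrix.counts.loc[matrix.gene_ids.isin(known)]
    sizes = matrix.library_sizes[counts.columns].to_numpy(dtype=float)
    lens = lengths[counts.index].to_numpy(dtype=float)
    values = RPKM_SCALE * counts.to_numpy(dtype=float) / (sizes[None, :] * lens[:, None])
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# Mapping summary (per-library read accounting)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryStats:
    """Read-mapping accounting of one sequencing library.

    Invariants: unique_match + multi_match = total_mapped;
    perfect_match + mismatch_le3 = total_mapped;
    total_mapped + unmapped = total_reads.
    """

    library_id: str
    total_reads: int
    total_mapped: int
    perfect_match: int
    mismatch_le3: int
    unique_match: int
    multi_match: int
    unmapped: int
    total_basepairs: int | None = None

    def __post_init__(self) -> None:
        checks = {
            "unique_match + multi_match = total_mapped":
                self.unique_match + self.multi_match == self.total_mapped,
            "perfect_match + mismatch_le3 = total_mapped":
                self.perfect_match + self.mismatch_le3 == self.total_mapped,
            "total_mapped + unmapped = total_reads":
                self.total_mapped + self.unmapped == self.total_reads,
        }
        failing = [identity for identity, ok in checks.items() if not ok]
        if failing:
            raise ValidationError(
                f"{self.library_id}: mapping accounting violated: " + "; ".join(failing)
            )
        if min(self.total_reads, self.total_mapped, self.perfect_match,
               self.mismatch_le3, self.unique_match, self.multi_match,
               self.unmapped) < 0:
            raise ValidationError(f"{self.library_id}: read counts must be non-negative")


def _pct(numerator: int, denominator: int) -> float:
    """Percentage of the library total, half-up rounded to 2 decimals."""
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


#: Row order of the published per-library summary.
SUMMARY_CATEGORIES = (
    "total_reads",
    "total_basepairs",
    "total_mapped",
    "perfect_match",
    "mismatch_le3",
    "unique_match",
    "multi_match",
    "unmapped",
)


def mapping_summary(stats: LibraryStats) -> pd.DataFrame:
    """Per-category read counts and percentages of total reads (2 decimals).

    The two "total" rows report 100.00 by definition; every other row is
    100 * count / total_reads. An optional extra column reports the unique
    match rate on the total_mapped denominator (the convention some running
    texts use instead).
    """
    rows = []
    for category in SUMMARY_CATEGORIES:
        if category == "total_basepairs":
            if stats.total_basepairs is None:
                continue
            rows.append((category, stats.total_basepairs, 100.00))
            continue
        count = getattr(stats, category)
        pct = 100.00 if category == "total_reads" else _pct(count, stats.total_reads)
        rows.append((category, count, pct))
    df = pd.DataFrame(rows, columns=["category", "count", "percent"])
    df.insert(0, "library_id", stats.library_id)
    df["percent_of_mapped"] = [
        _pct(getattr(stats, c), stats.total_mapped)
        if stats.total_mapped > 0
        and c in ("unique_match", "multi_match", "perfect_match", "mismatch_le3")
        else float("nan")
        for c in df["category"]
    ]
    return df


def library_stats_from_summary(table: pd.DataFrame, library_id: str) -> LibraryStats:
    """Build LibraryStats from a long-format summary table (fixture shape)."""
    sub = table[table["library_id"] == library_id].set_index("category")["count"]
    if sub.empty:
        raise ValidationError(f"no rows for library {library_id!r}")
    return LibraryStats(
        library_id=library_id,
        total_reads=int(sub["total_reads"]),
        total_mapped=int(sub["total_mapped"]),
        perfect_match=int(sub["perfect_match"]),
        mismatch_le3=int(sub["mismatch_le3"]),
        unique_match=int(sub["unique_match"]),
        multi_match=int(sub["multi_match"]),
        unmapped=int(sub["unmapped"]),
        total_basepairs=int(sub["total_basepairs"]) if "total_basepairs" in sub else None,
    )
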