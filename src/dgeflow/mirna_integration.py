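"""Join DE miRNAs, DE mRNAs and a target map into antagonistic pairs.

miRNAs typically repress their targets, so a differentially expressed miRNA
whose predicted target moves in the *opposite* direction between the same
two conditions forms an antagonistic (negatively correlated) pair — the
defining constraint of this module. Target prediction itself is an input:
the target map comes from an upstream small-RNA study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MiRNADERecord:
    """A differentially expressed miRNA."""

    mirna_id: str
    direction: str  # up / down
    novelty: str = "known"  # known / novel

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValidationError(f"{self.mirna_id}: direction must be up/down")
        if self.novelty not in ("known", "novel"):
            raise ValidationError(f"{self.mirna_id}: novelty must be known/novel")


@dataclass(frozen=True)
class PairRecord:
    """One (miRNA, target gene) pair with opposed regulation directions."""

    mirna_id: str
    mirna_direction: str
    gene_id: str
    gene_direction: str
    gene_description: str | None = None
    flowering: bool | None = None

    def __post_init__(self) -> None:
        if self.mirna_direction == self.gene_direction:
            raise ValidationError(
                f"({self.mirna_id}, {self.gene_id}): pair is not antagonistic "
                f"(both {self.mirna_direction})"
            )


def _normalize_direction(d: str) -> str:
    d = str(d).strip().lower()
    if d not in ("up", "down"):
        raise ValidationError(f"direction must be up/down, got {d!r}")
    return d


def _directions_by_gene(degs: pd.DataFrame) -> dict[str, set]:
    """gene_id -> set of significant directions.

    Tolerates a gene listed with conflicting directions (can happen when DE
    tables from different sources are concatenated); the conflict is logged
    and both directions are kept.
    """
    dirs: dict[str, set] = {}
    called = degs[degs["direction"].isin(("up", "down", "Up", "Down"))]
    for gene, d in zip(called["gene_id"], called["direction"]):
        dirs.setdefault(gene, set()).add(_normalize_direction(d))
    conflicted = [g for g, ds in dirs.items() if len(ds) > 1]
    if conflicted:
        logger.warning(
            "DEG table lists %d gene(s) with conflicting directions (e.g. %s); keeping both",
            len(conflicted), conflicted[:3],
        )
    return dirs


def antagonistic_pairs(
    mirnas: pd.DataFrame,
    degs: pd.DataFrame,
    targets: pd.DataFrame,
) -> list[PairRecord]:
    """Emit a pair for every target of a DE miRNA that is DE the other way.

    Parameters
    ----------
    mirnas
        DataFrame with columns mirna_id, direction (up/down).
    degs
        DE screen table with columns gene_id, direction; only up/down rows
        participate.
    targets
        Target map with columns mirna_id, gene_id, in a meaningful order;
        the order and any duplicate entries are preserved in the output.

    miRNAs in the target map but absent from the DE-miRNA table are skipped
    with a log line, not an error.
    """
    mirna_dir = {
        m: _normalize_direction(d)
        for m, d in zip(mirnas["mirna_id"], mirnas["direction"])
    }
    gene_dirs = _directions_by_gene(degs)
    opposite = {"up": "down", "down": "up"}
    pairs: list[PairRecord] = []
    skipped: set[str] = set()
    for m, g in zip(targets["mirna_id"], targets["gene_id"]):
        if m not in mirna_dir:
            if m not in skipped:
                logger.info("target map miRNA %r not in the DE-miRNA table; skipped", m)
                skipped.add(m)
            continue
        md = mirna_dir[m]
        if opposite[md] in gene_dirs.get(g, ()):  # antagonism
            pairs.append(PairRecord(m, md, g, opposite[md]))
    return pairs


def group_by_mirna(pairs: Iterable[PairRecord]) -> pd.DataFrame:
    """One row per distinct miRNA, targets kept in first-seen order
    (duplicates included). Columns: mirna_id, direction, targets, n_targets."""
    rows: dict[str, dict] = {}
    for p in pairs:
        row = rows.setdefault(
            p.mirna_id, {"mirna_id": p.mirna_id, "direction": p.mirna_direction, "targets": []}
        )
        row["targets"].append(p.gene_id)
    df = pd.DataFrame(rows.values(), columns=["mirna_id", "direction", "targets"])
    df["n_targets"] = df["targets"].map(len) if len(df) else []
    return df


def pair_summary(pairs: Iterable[PairRecord]) -> dict[str, int]:
    """Distinct-miRNA counts by direction and target-entry counts.

    Target entries are counted as listed, duplicates included — the
    convention under which a published pair table's own marginal counts are
    internally consistent.
    """
    pairs = list(pairs)
    up_mirnas = {p.mirna_id for p in pairs if p.mirna_direction == "up"}
    down_mirnas = {p.mirna_id for p in pairs if p.mirna_direction == "down"}
    return {
        "n_mirna_up": len(up_mirnas),
        "n_mirna_down": len(down_mirnas),
        "n_target_entries_with_up_mirna": sum(p.mirna_direction == "up" for p in pairs),
        "n_target_entries_with_down_mirna": sum(p.mirna_direction == "down" for p in pairs),
    }


def filter_flowering(
    pairs: Iterable[PairRecord],
    annotations: pd.DataFrame,
) -> list[PairRecord]:
    """Keep pairs whose target gene is flagged flowering-related.

    ``annotations`` has columns gene_id, description, flowering_flag.
    Targets missing from the table are treated as not flowering-related
    (logged). Descriptions are attached to the retained pairs.
    """
    ann = annotations.set_index("gene_id")
    missing: set[str] = set()
    out: list[PairRecord] = []
    for p in pairs:
        if p.gene_id not in ann.index:
            missing.add(p.gene_id)
            continue
        row = ann.loc[p.gene_id]
        if bool(row["flowering_flag"]):
            out.append(replace(p, gene_description=str(row["description"]), flowering=True))
    if missing:
        logger.warning(
            "filter_flowering: %d pair target(s) missing from the annotation table "
            "(treated as not flowering-related)", len(missing),
        )
    return out


def pairs_to_frame(pairs: Iterable[PairRecord]) -> pd.DataFrame:
    """Flat per-entry table (published pair-table shape)."""
    return pd.DataFrame(
        [
            {
                "mirna_id": p.mirna_id,
                "mirna_direction": p.mirna_direction,
                "gene_id": p.gene_id,
                "gene_direction": p.gene_direction,
                "gene_description": p.gene_description or "",
                "flowering": p.flowering,
            }
            for p in pairs
        ],
        columns=[
            "mirna_id", "mirna_direction", "gene_id", "gene_direction",
            "gene_description", "flowering",
        ],
    )
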