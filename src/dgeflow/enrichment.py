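"""Hypergeometric term enrichment (GO and KEGG) over flat term maps.

A study set of n genes drawn from a population of N is tested per term: with
K population members annotated to the term and k of them in the study set,
the enrichment p-value is the upper tail P(X >= k) of the hypergeometric
distribution. Multiple testing is corrected per namespace (BH by default,
Bonferroni optionally); a term is enriched when its corrected value is at or
below alpha.

No DAG propagation is performed: term maps are flat gene-membership tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .deg_screen import bh_adjust
from .errors import ValidationError

logger = logging.getLogger(__name__)

GO_NAMESPACES = ("biological_process", "cellular_component", "molecular_function")
NAMESPACES = GO_NAMESPACES + ("kegg_pathway",)


@dataclass
class TermMap:
    """Flat term -> member-gene map with descriptions and namespaces."""

    members: dict[str, set] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.members.items():
            if not genes:
                raise ValidationError(f"term {term!r} has no member genes")
            ns = self.namespaces.get(term)
            if ns is not None and ns not in NAMESPACES:
                raise ValidationError(f"term {term!r}: unknown namespace {ns!r}")

    @classmethod
    def from_tsv(cls, membership_path, descriptions_path=None) -> "TermMap":
        """Read a 2-column term_id -> gene_id TSV, plus an optional
        term_id / namespace / description TSV."""
        memb = pd.read_csv(membership_path, sep="\t")
        members: dict[str, set] = {}
        for term, gene in zip(memb["term_id"], memb["gene_id"]):
            members.setdefault(term, set()).add(gene)
        namespaces, descriptions = {}, {}
        if descriptions_path is not None:
            desc = pd.read_csv(descriptions_path, sep="\t")
            namespaces = dict(zip(desc["term_id"], desc["namespace"]))
            descriptions = dict(zip(desc["term_id"], desc.get("description", desc["term_id"])))
        return cls(members, namespaces, descriptions)

    def terms(self) -> list[str]:
        return list(self.members)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    namespace: str
    k: int  # study hits
    n: int  # study size
    K: int  # population hits
    N: int  # population size
    p_value: float
    q_value: float
    enriched: bool


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k)."""
    if not (0 <= k <= n <= N):
        raise ValidationError(f"need 0 <= k <= n <= N, got k={k}, n={n}, N={N}")
    if not (k <= K <= N):
        raise ValidationError(f"need k <= K <= N, got k={k}, K={K}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    study: Iterable[str],
    population: Iterable[str],
    terms: TermMap,
    alpha: float = 0.05,
    correction: str = "BH",
) -> pd.DataFrame:
    """Test every term with at least one population member.

    Terms with zero study hits are still tested (k = 0, p = 1) so the
    correction denominator does not depend on the study set. Correction is
    applied within each namespace. Returns a DataFrame sorted by
    (namespace, q_value).
    """
    study = set(study)
    population = set(population)
    if not study:
        raise ValidationError("study set is empty")
    stray = study - population
    if stray:
        raise ValidationError(
            f"study genes missing from population: {sorted(stray)[:5]}"
            + ("..." if len(stray) > 5 else "")
        )
    if correction not in ("BH", "bonferroni"):
        raise ValidationError(f"unknown correction {correction!r}")

    n, N = len(study), len(population)
    rows = []
    for term, members in terms.members.items():
        K = len(members & population)
        if K == 0:
            continue
        k = len(members & study)
        rows.append(
            {
                "term_id": term,
                "namespace": terms.namespaces.get(term, "biological_process"),
                "description": terms.descriptions.get(term, ""),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_value": hypergeom_pvalue(k, n, K, N),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "namespace", "description", "k", "n", "K", "N",
                     "p_value", "q_value", "enriched"]
        )
    df = pd.DataFrame(rows)
    df["q_value"] = 1.0
    for ns, idx in df.groupby("namespace").groups.items():
        p = df.loc[idx, "p_value"]
        if correction == "BH":
            df.loc[idx, "q_value"] = bh_adjust(p.to_numpy())
        else:
            df.loc[idx, "q_value"] = (p * len(p)).clip(upper=1.0)
    df["enriched"] = df["q_value"] <= alpha
    return df.sort_values(["namespace", "q_value", "term_id"]).reset_index(drop=True)


def category_breakdown(study: Iterable[str], terms: TermMap) -> pd.DataFrame:
    """Term-assignment counts per GO namespace among the study genes.

    Counts (gene, term) memberships — a gene annotated to three biological-
    process terms contributes three assignments — and reports each
    namespace's share of total assignments to one decimal (half-up). KEGG
    pathways are excluded; the breakdown mirrors the conventional
    three-category GO classification bar chart.
    """
    study = set(study)
    counts = {ns: 0 for ns in GO_NAMESPACES}
    for term, members in terms.members.items():
        ns = terms.namespaces.get(term)
        if ns not in GO_NAMESPACES:
            continue
        counts[ns] += len(members & study)
    total = sum(counts.values())
    if total == 0:
        logger.warning("category_breakdown: no GO assignments among study genes")
    rows = []
    for ns in GO_NAMESPACES:
        pct = (
            0.0
            if total == 0
            else float((Decimal(100 * counts[ns]) / Decimal(total)).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP))
        )
        rows.append({"namespace": ns, "n_assignments": counts[ns], "percent": pct})
    df = pd.DataFrame(rows)
    df.attrs["total_assignments"] = total
    return df
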