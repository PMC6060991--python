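"""Simulated three-library DGE studies with planted truth, plus packaged tables.

The generator emulates the structure of a three-library wild-rice flowering
study: two vegetative-stage libraries (V1, single-flowering sub-group; V2,
double-flowering sub-group) and one flowering-stage library (F2,
double-flowering sub-group), compared pairwise as V1F2, V1V2 and V2F2.

Counts are Poisson draws — the sampling model of the exact test applied
downstream; the design has one library per condition, so no biological
dispersion is simulated. Per-gene baseline expression rates are log-normal,
normalized so profiled genes absorb a fixed fraction of each library's
mapped tags. Differential expression is planted by multiplying the rate in
the *test* library of a chosen comparison by 2^(+-fold); the planted truth
(per-comparison DE status, miRNA directions, antagonistic pairs) is recorded
for recovery tests. A fold planted in F2 genuinely affects both V1F2 and
V2F2, and the truth reflects that.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, FixtureLookupError
from .expression import CountMatrix

#: Library labels, in column order, and the three pairwise comparisons
#: (reference first).
LIBRARIES = ("V1", "V2", "F2")
COMPARISONS: dict[str, tuple[str, str]] = {
    "V1F2": ("V1", "F2"),
    "V1V2": ("V1", "V2"),
    "V2F2": ("V2", "F2"),
}

#: Fraction of a library's mapped tags that land on profiled genes
#: (unambiguously assigned tags; the remainder is multi-mapping/unassigned).
UNAMBIGUOUS_FRACTION = 0.75

#: Genes above this baseline-rate quantile are never planted as DE: very
#: high-abundance transcripts are left unperturbed, which also keeps the
#: expected library totals within the library size.
_PLANT_RATE_QUANTILE = 0.95


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a simulated three-library experiment.

    Defaults emulate the real study's scale: ~27e3 detected genes, library
    sizes equal to the three libraries' total mapped reads, 44 DE miRNAs of
    which 17 are up-regulated and 38 are previously known.
    """

    n_genes: int = 27000
    library_sizes: tuple[int, int, int] = (5_859_055, 5_973_616, 5_790_541)
    frac_de_per_comparison: Mapping[str, float] = field(
        default_factory=lambda: {"V1F2": 0.05, "V1V2": 0.10, "V2F2": 0.05}
    )
    log2_fold_range: tuple[float, float] = (1.5, 3.0)
    baseline_rate_distribution: tuple[float, float] = (-4.5, 1.0)  # log10 mean, sigma
    n_mirnas: int = 44
    targets_per_mirna: tuple[int, int] = (1, 8)
    frac_targets_opposed: float = 0.6
    frac_flowering_annotated: float = 0.3
    frac_up_mirnas: float = 17 / 44
    frac_known_mirnas: float = 38 / 44
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if len(self.library_sizes) != 3 or any(n <= 0 for n in self.library_sizes):
            raise ConfigError("library_sizes must be three positive tag totals")
        unknown = set(self.frac_de_per_comparison) - set(COMPARISONS)
        if unknown:
            raise ConfigError(f"unknown comparison labels: {sorted(unknown)}")
        for label, frac in self.frac_de_per_comparison.items():
            if not (0.0 <= frac <= 1.0):
                raise ConfigError(f"frac_de[{label}] must lie in [0, 1]")
        if sum(self.frac_de_per_comparison.values()) > 1.0:
            raise ConfigError("DE fractions sum to more than 1")
        lo, hi = self.log2_fold_range
        if lo < 1.0 or hi < lo:
            raise ConfigError("log2_fold_range must satisfy 1 <= min <= max")
        for name, frac in (
            ("frac_targets_opposed", self.frac_targets_opposed),
            ("frac_flowering_annotated", self.frac_flowering_annotated),
            ("frac_up_mirnas", self.frac_up_mirnas),
            ("frac_known_mirnas", self.frac_known_mirnas),
        ):
            if not (0.0 <= frac <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.n_mirnas <= 0:
            raise ConfigError("n_mirnas must be positive")
        t_lo, t_hi = self.targets_per_mirna
        if not (1 <= t_lo <= t_hi):
            raise ConfigError("targets_per_mirna must be a positive (min, max) range")
        if t_hi > self.n_genes:
            raise ConfigError("targets_per_mirna exceeds n_genes")


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside simulated data."""

    de_status: pd.DataFrame  # gene x comparison -> up/down/null
    baseline_rates: pd.Series  # normalized per-tag expression rate per gene
    planted: pd.DataFrame  # gene_id, comparison, log2_fold (signed)
    flowering_genes: set = field(default_factory=set)
    mirna_direction: dict = field(default_factory=dict)
    true_pairs: set = field(default_factory=set)  # {(mirna_id, gene_id)}

    def to_json(self, path) -> None:
        payload = {
            "de_status": {c: self.de_status[c].to_dict() for c in self.de_status.columns},
            "baseline_rates": self.baseline_rates.to_dict(),
            "planted": self.planted.to_dict(orient="records"),
            "flowering_genes": sorted(self.flowering_genes),
            "mirna_direction": dict(self.mirna_direction),
            "true_pairs": sorted(map(list, self.true_pairs)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            de_status=pd.DataFrame(payload["de_status"]),
            baseline_rates=pd.Series(payload["baseline_rates"]),
            planted=pd.DataFrame(
                payload["planted"], columns=["gene_id", "comparison", "log2_fold"]
            ),
            flowering_genes=set(payload["flowering_genes"]),
            mirna_direction=payload["mirna_direction"],
            true_pairs={tuple(p) for p in payload["true_pairs"]},
        )


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_count_libraries(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw the three-library count matrix and its planted truth.

    Deterministic given the config (including seed): the same config yields
    bit-identical outputs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    n = config.n_genes
    genes = _gene_ids(n)

    mu, sigma = config.baseline_rate_distribution
    rates = 10.0 ** rng.normal(mu, sigma, size=n)
    rates *= UNAMBIGUOUS_FRACTION / rates.sum()

    # plant folds on a disjoint random subset per comparison, excluding the
    # highest-abundance genes
    rate_cap = np.quantile(rates, _PLANT_RATE_QUANTILE)
    eligible = np.flatnonzero(rates <= rate_cap)
    order = rng.permutation(eligible)
    lib_index = {lib: i for i, lib in enumerate(LIBRARIES)}
    rate_matrix = np.tile(rates[:, None], (1, 3))
    planted_rows = []
    cursor = 0
    for label in COMPARISONS:
        frac = config.frac_de_per_comparison.get(label, 0.0)
        k = int(round(frac * n))
        chosen = order[cursor: cursor + k]
        if len(chosen) < k:
            raise ConfigError("not enough plantable genes for the requested DE fractions")
        cursor += k
        lo, hi = config.log2_fold_range
        folds = rng.uniform(lo, hi, size=k) * rng.choice([-1.0, 1.0], size=k)
        test_lib = COMPARISONS[label][1]
        rate_matrix[chosen, lib_index[test_lib]] *= 2.0 ** folds
        for g, f in zip(chosen, folds):
            planted_rows.append({"gene_id": genes[g], "comparison": label, "log2_fold": float(f)})

    sizes = np.asarray(config.library_sizes, dtype=float)
    counts = rng.poisson(rate_matrix * sizes[None, :])
    matrix = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=list(LIBRARIES)),
        pd.Series(dict(zip(LIBRARIES, config.library_sizes))),
    )

    # truth from the true per-library rates (exact: unplanted ratios are 0)
    status = {}
    for label, (ref, test) in COMPARISONS.items():
        delta = np.log2(rate_matrix[:, lib_index[test]] / rate_matrix[:, lib_index[ref]])
        status[label] = np.where(delta > 0, "up", np.where(delta < 0, "down", "null"))
    de_status = pd.DataFrame(status, index=pd.Index(genes, name="gene_id"))
    flowering = set(
        de_status.index[
            (de_status["V1F2"] != "null")
            & (de_status["V2F2"] != "null")
            & (de_status["V1V2"] == "null")
        ]
    )
    truth = SimTruth(
        de_status=de_status,
        baseline_rates=pd.Series(rates, index=de_status.index),
        planted=pd.DataFrame(planted_rows, columns=["gene_id", "comparison", "log2_fold"]),
        flowering_genes=flowering,
    )
    return matrix, truth


def simulate_mirna_tables(
    config: SimConfig, truth: SimTruth
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """DE-miRNA table, target map and gene annotations with planted pairs.

    Each miRNA receives ``targets_per_mirna`` targets of which a fraction
    ``frac_targets_opposed`` are drawn from genes whose V1F2 status opposes
    the miRNA's direction (true antagonistic pairs, recorded in
    ``truth.true_pairs``); the rest are decoys with the same or null status.
    The annotation table flags ``frac_flowering_annotated`` of all genes as
    flowering-related.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    status = truth.de_status["V1F2"]
    pools = {
        "up": status.index[status == "up"].to_numpy(),
        "down": status.index[status == "down"].to_numpy(),
        "not_up": status.index[status != "up"].to_numpy(),
        "not_down": status.index[status != "down"].to_numpy(),
    }
    opposite = {"up": "down", "down": "up"}

    mirna_rows, target_rows = [], []
    truth.true_pairs = set()
    truth.mirna_direction = {}
    t_lo, t_hi = config.targets_per_mirna
    for i in range(config.n_mirnas):
        mid = f"sim-miR{i:03d}"
        direction = "up" if rng.random() < config.frac_up_mirnas else "down"
        novelty = "known" if rng.random() < config.frac_known_mirnas else "novel"
        truth.mirna_direction[mid] = direction
        mirna_rows.append({"mirna_id": mid, "direction": direction, "novelty": novelty})

        k = int(rng.integers(t_lo, t_hi + 1))
        n_opposed = int(round(config.frac_targets_opposed * k))
        opp_pool = pools[opposite[direction]]
        decoy_pool = pools["not_" + opposite[direction]]
        if n_opposed > len(opp_pool) or (k - n_opposed) > len(decoy_pool):
            raise ConfigError(
                f"{mid}: not enough genes to draw {k} targets "
                f"({n_opposed} opposed) without replacement"
            )
        opposed = rng.choice(opp_pool, size=n_opposed, replace=False)
        decoys = rng.choice(decoy_pool, size=k - n_opposed, replace=False)
        targets = rng.permutation(np.concatenate([opposed, decoys]))
        opposed_set = set(opposed)
        for g in targets:
            target_rows.append({"mirna_id": mid, "gene_id": g})
            if g in opposed_set:
                truth.true_pairs.add((mid, g))

    genes = truth.de_status.index
    flags = rng.random(len(genes)) < config.frac_flowering_annotated
    annotations = pd.DataFrame(
        {
            "gene_id": genes,
            "description": [
                f"flowering-related protein {g}" if fl else f"expressed protein {g}"
                for g, fl in zip(genes, flags)
            ],
            "flowering_flag": flags,
        }
    ).reset_index(drop=True)
    return (
        pd.DataFrame(mirna_rows, columns=["mirna_id", "direction", "novelty"]),
        pd.DataFrame(target_rows, columns=["mirna_id", "gene_id"]),
        annotations,
    )


def simulate_gene_models(config: SimConfig) -> pd.DataFrame:
    """Synthetic gene lengths (bp), uniform over a realistic mRNA range."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 3]))
    lengths = rng.integers(200, 5001, size=config.n_genes)
    return pd.DataFrame({"gene_id": _gene_ids(config.n_genes), "length": lengths})


# ---------------------------------------------------------------------------
# Packaged worked-example tables
# ---------------------------------------------------------------------------

_FIXTURES = {
    "table1_stats": "table1_stats.tsv",
    "table2_pairs": "table2_pairs.tsv",
    "table3_flowering": "table3_flowering.tsv",
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged worked-example table.

    ``table1_stats``: per-library read-mapping summary (long format).
    ``table2_pairs``: the 28 antagonistic miRNA-mRNA pair rows, one line per
    (miRNA, target) entry with printed order and duplicates preserved.
    ``table3_flowering``: the flowering-related subset with descriptions.
    """
    if name not in _FIXTURES:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        )
    ref = resources.files("dgeflow.data").joinpath(_FIXTURES[name])
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
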