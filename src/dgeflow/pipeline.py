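"""End-to-end orchestration: counts -> DE screens -> set logic -> enrichment
-> miRNA integration, driven by a single YAML config, with a run manifest.

Every stage reads and writes plain files (TSV/JSON), so each is also
independently runnable through the CLI subcommands.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deg_screen import ScreenThresholds, deg_summary, screen_degs
from .enrichment import GO_NAMESPACES, TermMap, category_breakdown, enrich
from .errors import ConfigError, StageError
from .expression import CountMatrix, rpkm_matrix
from .mirna_integration import (
    antagonistic_pairs,
    filter_flowering,
    group_by_mirna,
    pair_summary,
    pairs_to_frame,
)
from .set_logic import (
    DEFAULT_FLOWERING_EXPRESSION,
    ComparisonSets,
    comparison_sets_from_screens,
    flowering_exclusive_genes,
    venn_counts,
)
from .synthetic_data import (
    COMPARISONS,
    SimConfig,
    simulate_count_libraries,
    simulate_gene_models,
    simulate_mirna_tables,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run."""

    counts: str
    gene_lengths: str
    outdir: str
    library_sizes: Mapping[str, int] | None = None
    mirna_de: str | None = None
    target_map: str | None = None
    annotations: str | None = None
    term_membership: str | None = None
    term_descriptions: str | None = None
    comparisons: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: dict(COMPARISONS)
    )
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    set_expression: str = DEFAULT_FLOWERING_EXPRESSION
    enrichment_alpha: float = 0.05
    correction: str = "BH"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("counts", "gene_lengths", "mirna_de", "target_map",
                     "annotations", "term_membership", "term_descriptions"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{name} file does not exist: {path}")
        self.comparisons = {
            label: tuple(pair) for label, pair in self.comparisons.items()
        }

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thresholds = ScreenThresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thresholds, **raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["comparisons"] = {k: list(v) for k, v in self.comparisons.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    config: dict
    record_counts: dict
    version: str
    wall_time_s: float
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def _stage(name):
    """Wrap a stage so failures carry the stage name."""
    def decorate(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise StageError(name, exc) from exc
        return run
    return decorate


def run_pipeline(config: PipelineConfig, force: bool = False) -> RunManifest:
    """Execute expression -> DE screens -> set logic -> enrichment ->
    miRNA integration, writing each stage's table under ``config.outdir``.

    Refuses to overwrite a completed run (manifest present) unless
    ``force``. A stage failure leaves earlier outputs intact and raises
    :class:`StageError` naming the stage.
    """
    t0 = time.monotonic()
    outdir = Path(config.outdir)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not force:
        raise ConfigError(
            f"{manifest_path} exists; pass force=True (--force) to re-run"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    counts_of: dict[str, int] = {}

    @_stage("expression")
    def expression_stage():
        matrix = CountMatrix.from_tsv(config.counts, config.library_sizes)
        lengths_df = pd.read_csv(config.gene_lengths, sep="\t")
        lengths = dict(zip(lengths_df["gene_id"], lengths_df["length"]))
        rpkm = rpkm_matrix(matrix, lengths)
        rpkm.to_csv(outdir / "rpkm.tsv", sep="\t", index_label="gene_id")
        counts_of["rpkm_genes"] = len(rpkm)
        logger.info("[expression] RPKM for %d genes written", len(rpkm))
        return matrix, lengths

    matrix, lengths = expression_stage()

    @_stage("deg_screen")
    def deg_stage():
        screens = {}
        for label, pair in config.comparisons.items():
            table = screen_degs(matrix, pair, config.thresholds, gene_lengths=lengths)
            table.to_csv(outdir / f"deg_{label}.tsv", sep="\t", index=False)
            counts_of[f"deg_{label}"] = len(table)
            n_up, n_down = deg_summary(table)
            logger.info("[deg_screen] %s: %d up, %d down of %d tested",
                        label, n_up, n_down, len(table))
            screens[label] = table
        return screens

    screens = deg_stage()

    @_stage("set_logic")
    def sets_stage():
        sets = comparison_sets_from_screens(screens)
        regions = venn_counts(sets)
        with open(outdir / "venn.json", "w") as fh:
            json.dump(regions, fh, indent=1)
        flowering = flowering_exclusive_genes(sets, config.set_expression)
        with open(outdir / "flowering_genes.txt", "w") as fh:
            fh.writelines(f"{g}\n" for g in sorted(flowering))
        counts_of["flowering_genes"] = len(flowering)
        logger.info("[set_logic] %d genes selected by %r", len(flowering),
                    config.set_expression)
        return flowering

    flowering = sets_stage()

    @_stage("enrichment")
    def enrichment_stage():
        if config.term_membership is None:
            logger.info("[enrichment] no term map configured; stage skipped")
            return
        terms = TermMap.from_tsv(config.term_membership, config.term_descriptions)
        population = set(matrix.gene_ids[(matrix.counts.sum(axis=1) > 0)])
        study = flowering & population
        if not study:
            logger.warning("[enrichment] empty study set; stage skipped")
            return
        results = enrich(study, population, terms,
                         alpha=config.enrichment_alpha, correction=config.correction)
        results.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        breakdown = category_breakdown(study, terms)
        breakdown.to_csv(outdir / "go_breakdown.tsv", sep="\t", index=False)
        counts_of["enrichment_terms"] = len(results)
        counts_of["enriched_terms"] = int(results["enriched"].sum())
        logger.info("[enrichment] %d terms tested, %d enriched",
                    len(results), int(results["enriched"].sum()))

    enrichment_stage()

    @_stage("mirna_integration")
    def pairs_stage():
        if config.mirna_de is None or config.target_map is None:
            logger.info("[mirna_integration] no miRNA inputs configured; stage skipped")
            return
        mirnas = pd.read_csv(config.mirna_de, sep="\t")
        targets = pd.read_csv(config.target_map, sep="\t")
        pairs = antagonistic_pairs(mirnas, screens["V1F2"], targets)
        pairs_to_frame(pairs).to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        counts_of["pair_entries"] = len(pairs)
        counts_of["pair_mirnas"] = len(group_by_mirna(pairs))
        logger.info("[mirna_integration] %d antagonistic pair entries across %d miRNAs",
                    len(pairs), counts_of["pair_mirnas"])
        if config.annotations is not None:
            ann = pd.read_csv(config.annotations, sep="\t")
            flw = filter_flowering(pairs, ann)
            pairs_to_frame(flw).to_csv(outdir / "flowering_pairs.tsv", sep="\t", index=False)
            counts_of["flowering_pair_entries"] = len(flw)
            logger.info("[mirna_integration] %d pair entries flowering-annotated", len(flw))

    pairs_stage()

    manifest = RunManifest(
        config={**{k: str(v) for k, v in asdict(config).items()}},
        record_counts=counts_of,
        version=__version__,
        wall_time_s=round(time.monotonic() - t0, 3),
        seed=config.seed,
    )
    manifest.to_json(manifest_path)
    return manifest


# ---------------------------------------------------------------------------
# Demo dataset
# ---------------------------------------------------------------------------

def _demo_terms(rng: np.random.Generator, genes, flowering: set) -> pd.DataFrame:
    """Synthetic flat term map: random terms plus one planted flowering term
    per GO namespace so the enrichment stage has signal to find."""
    genes = list(genes)
    flowering = sorted(flowering)
    rows = []
    namespaces = list(GO_NAMESPACES) + ["kegg_pathway"]
    for t in range(40):
        ns = namespaces[t % len(namespaces)]
        size = int(rng.integers(10, 31))
        for g in rng.choice(genes, size=size, replace=False):
            rows.append({"term_id": f"T{t:03d}", "namespace": ns, "gene_id": g})
    if flowering:
        for i, ns in enumerate(GO_NAMESPACES):
            size = min(len(flowering), 15)
            for g in rng.choice(flowering, size=size, replace=False):
                rows.append({"term_id": f"FLW{i}", "namespace": ns, "gene_id": g})
    return pd.DataFrame(rows)


def make_demo(seed: int, outdir) -> dict[str, Path]:
    """Write a small simulated study (counts, lengths, miRNA tables, term
    map, truth and a ready pipeline config) under ``outdir``.

    Scaled to run in seconds: 2000 genes, 5e5 tags per library, otherwise
    the default study conditions.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = SimConfig(
        n_genes=2000,
        library_sizes=(500_000, 500_000, 500_000),
        n_mirnas=30,
        targets_per_mirna=(1, 5),
        seed=int(seed),
    )
    matrix, truth = simulate_count_libraries(config)
    mirnas, targets, annotations = simulate_mirna_tables(config, truth)
    lengths = simulate_gene_models(config)

    paths = {name: outdir / f"{name}.tsv" for name in
             ("counts", "gene_lengths", "mirna_de", "target_map",
              "annotations", "term_membership", "term_descriptions")}
    matrix.to_tsv(paths["counts"])
    lengths.to_csv(paths["gene_lengths"], sep="\t", index=False)
    mirnas.to_csv(paths["mirna_de"], sep="\t", index=False)
    targets.to_csv(paths["target_map"], sep="\t", index=False)
    annotations.to_csv(paths["annotations"], sep="\t", index=False)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    terms = _demo_terms(rng, matrix.gene_ids, truth.flowering_genes)
    terms[["term_id", "gene_id"]].to_csv(paths["term_membership"], sep="\t", index=False)
    (
        terms[["term_id", "namespace"]]
        .drop_duplicates()
        .assign(description=lambda d: "synthetic term " + d["term_id"])
        .to_csv(paths["term_descriptions"], sep="\t", index=False)
    )

    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)
    paths["truth"] = truth_path

    pconfig = PipelineConfig(
        counts=str(paths["counts"]),
        gene_lengths=str(paths["gene_lengths"]),
        outdir=str(outdir / "results"),
        library_sizes={lib: int(n) for lib, n in
                       zip(("V1", "V2", "F2"), config.library_sizes)},
        mirna_de=str(paths["mirna_de"]),
        target_map=str(paths["target_map"]),
        annotations=str(paths["annotations"]),
        term_membership=str(paths["term_membership"]),
        term_descriptions=str(paths["term_descriptions"]),
        seed=int(seed),
    )
    config_path = outdir / "config.yaml"
    pconfig.to_yaml(config_path)
    paths["config"] = config_path
    return paths
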