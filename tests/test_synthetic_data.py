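"""Simulator determinism, planted structure and the packaged tables."""

import numpy as np
import pandas as pd
import pytest

from dgeflow.errors import ConfigError, FixtureLookupError
from dgeflow.mirna_integration import antagonistic_pairs
from dgeflow.synthetic_data import (
    COMPARISONS,
    SimConfig,
    load_fixture,
    simulate_count_libraries,
    simulate_gene_models,
    simulate_mirna_tables,
)

NULL_FRACS = {"V1F2": 0.0, "V1V2": 0.0, "V2F2": 0.0}


def _small(seed=0, **kwargs):
    defaults = dict(
        n_genes=400,
        library_sizes=(200_000, 200_000, 200_000),
        n_mirnas=10,
        targets_per_mirna=(1, 4),
        seed=seed,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


def test_config_validation():
    with pytest.raises(ConfigError):
        _small(library_sizes=(0, 1, 1))
    with pytest.raises(ConfigError):
        _small(log2_fold_range=(0.5, 2.0))  # min below 1
    with pytest.raises(ConfigError):
        _small(frac_de_per_comparison={"V1F2": 1.5})
    with pytest.raises(ConfigError):
        _small(targets_per_mirna=(1, 10_000))  # exceeds n_genes
    with pytest.raises(ConfigError):
        _small(frac_targets_opposed=-0.1)


def test_simulation_is_deterministic_given_seed():
    m1, t1 = simulate_count_libraries(_small(seed=7))
    m2, t2 = simulate_count_libraries(_small(seed=7))
    assert m1.counts.equals(m2.counts)
    assert t1.de_status.equals(t2.de_status)
    m3, _ = simulate_count_libraries(_small(seed=8))
    assert not m1.counts.equals(m3.counts)


def test_null_simulation_has_no_planted_effects():
    cfg = _small(frac_de_per_comparison=NULL_FRACS)
    _, truth = simulate_count_libraries(cfg)
    assert (truth.de_status == "null").all().all()
    assert truth.planted.empty
    assert truth.flowering_genes == set()


def test_null_counts_track_library_size_ratio():
    """With nothing planted, summed counts per library scale with the
    library sizes (ratio 2:1 here) within Poisson error."""
    cfg = _small(
        frac_de_per_comparison=NULL_FRACS,
        library_sizes=(400_000, 200_000, 200_000),
    )
    matrix, _ = simulate_count_libraries(cfg)
    totals = matrix.counts.sum(axis=0)
    assert totals["V1"] / totals["V2"] == pytest.approx(2.0, rel=0.02)


def test_null_gene_mean_count_equals_rate_times_size():
    """Monte-Carlo check of the count model: over 100 replicate draws, the
    mean count of a null gene sits within 3 sigma of baseline_rate * N."""
    n_reps = 100
    zs = []
    for seed in range(n_reps):
        cfg = _small(n_genes=50, frac_de_per_comparison=NULL_FRACS, seed=seed)
        matrix, truth = simulate_count_libraries(cfg)
        gene = matrix.gene_ids[0]
        mu = truth.baseline_rates[gene] * cfg.library_sizes[0]
        # Poisson: z has mean 0 and variance 1 whatever this seed's rate is
        zs.append((matrix.counts.loc[gene, "V1"] - mu) / np.sqrt(mu))
    assert abs(np.mean(zs)) < 3 / np.sqrt(n_reps)


def test_planted_truth_is_consistent_across_comparisons():
    """A fold planted in the F2 library marks the gene DE in both
    stage comparisons with matching signs, and null between V1 and V2."""
    cfg = _small(frac_de_per_comparison={"V1F2": 0.2, "V1V2": 0.0, "V2F2": 0.0})
    _, truth = simulate_count_libraries(cfg)
    planted = truth.planted.set_index("gene_id")
    assert (planted["comparison"] == "V1F2").all()
    for gene, row in planted.iterrows():
        expected = "up" if row["log2_fold"] > 0 else "down"
        assert truth.de_status.loc[gene, "V1F2"] == expected
        assert truth.de_status.loc[gene, "V2F2"] == expected
        assert truth.de_status.loc[gene, "V1V2"] == "null"
    assert truth.flowering_genes == set(planted.index)


# ---------------------------------------------------------------------------
# miRNA tables
# ---------------------------------------------------------------------------

def _truth_degs(truth):
    status = truth.de_status["V1F2"]
    return pd.DataFrame({"gene_id": status.index, "direction": status.to_numpy()})


def test_all_opposed_targets_recover_exactly_true_pairs():
    cfg = _small(frac_targets_opposed=1.0,
                 frac_de_per_comparison={"V1F2": 0.3, "V1V2": 0.0, "V2F2": 0.0})
    _, truth = simulate_count_libraries(cfg)
    mirnas, targets, _ = simulate_mirna_tables(cfg, truth)
    found = {(p.mirna_id, p.gene_id)
             for p in antagonistic_pairs(mirnas, _truth_degs(truth), targets)}
    assert found == truth.true_pairs and len(found) > 0


def test_no_opposed_targets_yield_no_pairs():
    cfg = _small(frac_targets_opposed=0.0,
                 frac_de_per_comparison={"V1F2": 0.3, "V1V2": 0.0, "V2F2": 0.0})
    _, truth = simulate_count_libraries(cfg)
    mirnas, targets, _ = simulate_mirna_tables(cfg, truth)
    assert antagonistic_pairs(mirnas, _truth_degs(truth), targets) == []
    assert truth.true_pairs == set()


def test_pair_recovery_perfect_when_screen_power_removed():
    """30 miRNAs x 5 targets at 60% opposed: pairing against the exact
    planted truth recovers true pairs with precision and recall 1.0."""
    from dgeflow.evaluation import pair_recovery

    precision, recall = pair_recovery(seed=3)
    assert precision == 1.0 and recall == 1.0


def test_annotation_flag_rate_matches_config():
    cfg = _small(n_genes=2000, frac_flowering_annotated=0.3)
    _, truth = simulate_count_libraries(cfg)
    _, _, annotations = simulate_mirna_tables(cfg, truth)
    rate = annotations["flowering_flag"].mean()
    assert abs(rate - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 2000)


def test_gene_models_are_deterministic_and_positive():
    a = simulate_gene_models(_small(seed=5))
    b = simulate_gene_models(_small(seed=5))
    assert a.equals(b)
    assert (a["length"] >= 200).all()


# ---------------------------------------------------------------------------
# Packaged tables
# ---------------------------------------------------------------------------

def test_fixture_lookup_error():
    with pytest.raises(FixtureLookupError):
        load_fixture("table9_nonsense")


def test_table1_shape(table1):
    assert table1["library_id"].nunique() == 3
    assert (table1.groupby("library_id").size() == 8).all()


def test_table2_printed_counts(table2):
    assert table2["mirna_id"].nunique() == 28
    directions = table2.drop_duplicates("mirna_id")["mirna_direction"]
    assert (directions == "up").sum() == 6
    assert (directions == "down").sum() == 22


def test_table2_duplicated_entries_kept_as_printed(table2):
    row = table2[table2["mirna_id"] == "osa-miR390"]["gene_id"]
    assert len(row) == 7
    assert (row == "LOC_Os02g10100.1").sum() == 2
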