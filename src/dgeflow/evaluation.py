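"""Calibration and recovery evaluations of the screening pipeline.

These routines run the pipeline on simulated studies with planted truth and
measure how well it recovers that truth, plus independent brute-force
oracles for the exact test and the hypergeometric tail. They back both the
test suite and the reproduction script.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .deg_screen import ac_pvalue_two_sided, screen_degs
from .mirna_integration import antagonistic_pairs
from .set_logic import comparison_sets_from_screens, flowering_exclusive_genes
from .synthetic_data import COMPARISONS, SimConfig, simulate_count_libraries, simulate_mirna_tables

#: Expected reference-library count below which a ~2.8-fold change is not
#: detectable at FDR 1e-3 with single libraries; used to define the
#: "adequately expressed" stratum of recovery reports.
DETECTION_LIMIT_COUNT = 30


# ---------------------------------------------------------------------------
# Independent oracles (plain arithmetic, no shared code with the test path)
# ---------------------------------------------------------------------------

def ac_pmf_bruteforce(y: int, x: int, n1: float, n2: float) -> float:
    """P(y|x) by the direct formula with plain float arithmetic."""
    r = n2 / n1
    return math.comb(x + y, y) * r**y / (1.0 + r) ** (x + y + 1)


def ac_pvalue_bruteforce(x: int, y: int, n1: float, n2: float, extra: int = 200) -> float:
    """Two-sided p by enumerating y' = 0..x+y+extra in plain arithmetic."""
    upper_limit = x + y + extra
    pmf = [ac_pmf_bruteforce(yy, x, n1, n2) for yy in range(upper_limit + 1)]
    lower = sum(pmf[: y + 1])
    upper = sum(pmf[y:])
    return min(1.0, 2.0 * min(lower, upper))


def ac_oracle_comparison(max_count: int = 30, ratios=(0.5, 1.0, 2.0)) -> float:
    """Max |p_implementation - p_bruteforce| over the (x, y, N2/N1) grid."""
    n1 = 1_000_000.0
    worst = 0.0
    for ratio in ratios:
        n2 = ratio * n1
        for x in range(max_count + 1):
            for y in range(max_count + 1):
                dev = abs(ac_pvalue_two_sided(x, y, n1, n2) - ac_pvalue_bruteforce(x, y, n1, n2))
                worst = max(worst, dev)
    return worst


def ac_normalization_deviation(xs=(0, 1, 5, 20), ratios=(0.5, 1.0, 2.0)) -> float:
    """Max |1 - sum_y P(y|x)| with the tail bounded below 1e-12."""
    from .deg_screen import ac_probability

    worst = 0.0
    for ratio in ratios:
        n1, n2 = 1e6, ratio * 1e6
        for x in xs:
            # enough terms that the geometric tail is < 1e-13
            total = sum(ac_probability(y, x, n1, n2) for y in range(0, 40 * (x + 10)))
            worst = max(worst, abs(1.0 - total))
    return worst


def hypergeom_pvalue_bruteforce(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) as a factorial-ratio sum."""
    total = 0.0
    for kk in range(k, min(n, K) + 1):
        total += math.comb(K, kk) * math.comb(N - K, n - kk) / math.comb(N, n)
    return min(1.0, total)


# ---------------------------------------------------------------------------
# Simulation-based calibration of the screen
# ---------------------------------------------------------------------------

def null_call_rate(
    n_genes: int = 2000,
    library_size: int = 1_000_000,
    n_seeds: int = 10,
    base_seed: int = 0,
) -> float:
    """Mean fraction of genes called DE when nothing is planted.

    With FDR controlled at 1e-3, the expected rate is at most 1e-3.
    """
    rates = []
    for i in range(n_seeds):
        cfg = SimConfig(
            n_genes=n_genes,
            library_sizes=(library_size,) * 3,
            frac_de_per_comparison={"V1F2": 0.0, "V1V2": 0.0, "V2F2": 0.0},
            seed=base_seed + i,
        )
        matrix, _ = simulate_count_libraries(cfg)
        table = screen_degs(matrix, COMPARISONS["V1F2"])
        rates.append((table["direction"] != "ns").sum() / len(table))
    return float(np.mean(rates))


@dataclass
class RecoveryReport:
    """Averages over seeds of planted-DE recovery in the V1F2 comparison."""

    recall: float                 # over all planted DE genes
    recall_adequate: float        # over planted genes above the detection limit
    false_discovery_proportion: float
    flowering_jaccard: float      # flowering-exclusive set vs truth, adequate stratum
    n_genes: int
    n_seeds: int


def _recovery_config(n_genes: int, library_size: int, seed: int) -> SimConfig:
    return SimConfig(
        n_genes=n_genes,
        library_sizes=(library_size,) * 3,
        frac_de_per_comparison={"V1F2": 0.1, "V1V2": 0.1, "V2F2": 0.1},
        log2_fold_range=(1.5, 3.0),
        seed=seed,
    )


def recovery_report(
    n_genes: int = 1000,
    library_size: int = 1_000_000,
    n_seeds: int = 10,
    base_seed: int = 0,
) -> RecoveryReport:
    """Run the full screen + set logic on planted data and score recovery."""
    recalls, arecalls, fdps, jaccards = [], [], [], []
    for i in range(n_seeds):
        cfg = _recovery_config(n_genes, library_size, base_seed + i)
        matrix, truth = simulate_count_libraries(cfg)
        screens = {l: screen_degs(matrix, p) for l, p in COMPARISONS.items()}

        table = screens["V1F2"]
        called = set(table[table["direction"].isin(("up", "down"))]["gene_id"])
        truly_de = set(truth.de_status.index[truth.de_status["V1F2"] != "null"])
        adequate = set(
            truth.baseline_rates.index[
                truth.baseline_rates * library_size >= DETECTION_LIMIT_COUNT
            ]
        )
        recalls.append(len(called & truly_de) / len(truly_de))
        arecalls.append(len(called & truly_de & adequate) / len(truly_de & adequate))
        fdps.append(len(called - truly_de) / max(1, len(called)))

        found = flowering_exclusive_genes(comparison_sets_from_screens(screens)) & adequate
        planted = truth.flowering_genes & adequate
        jaccards.append(len(found & planted) / max(1, len(found | planted)))
    return RecoveryReport(
        recall=float(np.mean(recalls)),
        recall_adequate=float(np.mean(arecalls)),
        false_discovery_proportion=float(np.mean(fdps)),
        flowering_jaccard=float(np.mean(jaccards)),
        n_genes=n_genes,
        n_seeds=n_seeds,
    )


def pair_recovery(seed: int = 0) -> tuple[float, float]:
    """(precision, recall) of antagonistic_pairs against planted true pairs
    when the DE input is the exact planted truth (screen power removed)."""
    cfg = SimConfig(
        n_genes=2000,
        library_sizes=(500_000,) * 3,
        n_mirnas=30,
        targets_per_mirna=(5, 5),
        frac_targets_opposed=0.6,
        seed=seed,
    )
    _, truth = simulate_count_libraries(cfg)
    mirnas, targets, _ = simulate_mirna_tables(cfg, truth)
    import pandas as pd

    status = truth.de_status["V1F2"]
    degs = pd.DataFrame({"gene_id": status.index, "direction": status.to_numpy()})
    found = {(p.mirna_id, p.gene_id) for p in antagonistic_pairs(mirnas, degs, targets)}
    precision = len(found & truth.true_pairs) / max(1, len(found))
    recall = len(found & truth.true_pairs) / max(1, len(truth.true_pairs))
    return precision, recall


def concordance_simulation(
    population_r: float = 0.9, n_points: int = 25, n_seeds: int = 100, base_seed: int = 0
) -> float:
    """Mean sample Pearson r between simulated sequencing log2 folds and
    noisy qPCR re-measurements whose population correlation is ``population_r``."""
    from .qpcr_validation import expression_concordance

    rng = np.random.default_rng(np.random.SeedSequence([int(base_seed), 7]))
    sigma_signal = 2.0
    # r = sigma_s / sqrt(sigma_s^2 + sigma_n^2)  =>  noise for the target r
    sigma_noise = sigma_signal * math.sqrt(1.0 / population_r**2 - 1.0)
    values = []
    for _ in range(n_seeds):
        seq = rng.normal(0.0, sigma_signal, size=n_points)
        qpcr = seq + rng.normal(0.0, sigma_noise, size=n_points)
        values.append(expression_concordance(qpcr, seq))
    return float(np.mean(values))
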