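"""Desk-scale benchmark scenarios exercising the whole pipeline.

Each function simulates a documented scenario, runs the relevant part of
the pipeline and returns the headline quantities: mock-vs-informative IDI
separation, improvement over the odds-ratio baseline with the
random-addition control, synergy ablation, neighbour-vote classification
and null calibration under permuted phenotypes.  The scenarios and their
parameter choices are described in the methods note.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .cohort import PhenotypeVector
from .engine import (
    ScoringConfig,
    VariantScoringModel,
    baseline_or_selection,
    evaluate_improvement,
    synergy_ablation,
)
from .network import EvidenceType, GeneNetwork, cross_validate_classification
from .risk import auc, loocv_risks
from .simulate import (
    SimulationSpec,
    VariantGroup,
    demo_spec,
    greyzone_spec,
    impute_mock_variants,
    simulate_cohort,
    simulate_networks,
    synergy_spec,
)

__all__ = [
    "mock_separation_benchmark",
    "improvement_benchmark",
    "synergy_benchmark",
    "neighbor_vote_benchmark",
    "null_calibration_benchmark",
]


def _scored_pipeline(g, y, truth, cfg, net_seed):
    nets = simulate_networks(truth, seed=net_seed)
    res = VariantScoringModel(g, y, nets, cfg).fit()
    return res.table.set_index("variant_id")


def mock_separation_benchmark(seed: int = 0, n_mock: int = 150) -> dict:
    """Validation-panel analogue: score planted informative variants and
    frequency-matched mocks together; compare the two IDI distributions
    and the calls at the +/-0.02 cutoffs."""
    spec = demo_spec(seed=seed)
    g, y, truth = simulate_cohort(spec)
    g, mock_ids = impute_mock_variants(g, n_mock, seed=seed + 1)
    cfg = ScoringConfig(seed=seed)
    table = _scored_pipeline(g, y, truth, cfg, net_seed=seed + 2)

    idi_inf = table.loc[truth.informative_ids, "idi"].to_numpy(dtype=float)
    idi_mock = table.loc[mock_ids, "idi"].dropna().to_numpy(dtype=float)
    welch = sps.ttest_ind(idi_inf[~np.isnan(idi_inf)], idi_mock, equal_var=False)
    called_inf = np.abs(np.nan_to_num(idi_inf)) >= cfg.idi_pro_threshold
    return {
        "t_stat": float(welch.statistic),
        "t_p": float(welch.pvalue),
        "planted_sensitivity": float(np.mean(called_inf)),
        "mock_specificity": float(np.mean(np.abs(idi_mock) < cfg.idi_pro_threshold)),
        "mean_idi_informative": float(np.nanmean(idi_inf)),
        "mean_abs_idi_mock": float(np.mean(np.abs(idi_mock))),
        "n_informative": int(len(idi_inf)),
        "n_mock": int(len(idi_mock)),
        "n_samples": g.n_samples,
    }


def improvement_benchmark(
    seed: int = 0, or_threshold: float = 2.0, n_random_iterations: int = 200
) -> dict:
    """Grey-zone analogue: strong variants set the odds-ratio baseline;
    the weak synergistic module (each variant below the OR threshold) is
    added and LOOCV risk prediction compared, with the random-addition
    control."""
    spec = greyzone_spec(seed=seed)
    g, y, truth = simulate_cohort(spec)
    grey = [
        v
        for v in truth.informative_ids
        if str(truth.table.loc[v, "gene"]).startswith("GREY")
    ]
    selection = baseline_or_selection(g, y, or_threshold)
    baseline_ids = selection["selected"]
    added = [v for v in grey if v not in baseline_ids]
    cfg = ScoringConfig(n_random_iterations=n_random_iterations, seed=seed)
    report = evaluate_improvement(g, y, baseline_ids, added, cfg)
    return {
        "auc_baseline": report.auc_baseline,
        "auc_augmented": report.auc_augmented,
        "improvement_idi": report.stats.idi,
        "improvement_idi_p": report.stats.idi_p,
        "auc_random_mean": report.auc_random_mean,
        "random_gap": abs(report.auc_random_mean - report.auc_baseline),
        "n_baseline": len(baseline_ids),
        "n_added": len(added),
        "n_candidates": g.n_variants - len(baseline_ids),
        "n_samples": g.n_samples,
    }


def synergy_benchmark(seed: int = 0, n_seeds: int = 50) -> dict:
    """Synergy-ablation analogue: over ``n_seeds`` replicates, check that
    removing the strongest planted variant costs more LOOCV AUC than
    removing any null partner; on the base replicate also measure the
    group AUC and the best single-variant AUC."""
    wins = 0
    for s in range(seed, seed + n_seeds):
        spec = synergy_spec(seed=s)
        g, y, truth = simulate_cohort(spec)
        strongest = truth.groups()["group1"][0]
        nulls = truth.noise_ids[:3]
        group = [strongest] + truth.groups()["group2"] + nulls
        table = synergy_ablation(g, y, group)
        wins += (
            table.loc[strongest, "delta_auc"] > table.loc[nulls, "delta_auc"].max()
        )

    spec = synergy_spec(seed=seed)
    g, y, truth = simulate_cohort(spec)
    planted = truth.informative_ids
    group_auc = auc(loocv_risks(g, y, planted), y)
    single_aucs = [auc(loocv_risks(g, y, [v]), y) for v in planted]
    return {
        "ablation_win_fraction": wins / n_seeds,
        "group_loocv_auc": group_auc,
        "best_single_loocv_auc": float(max(single_aucs)),
        "n_seeds": n_seeds,
        "n_samples": g.n_samples,
    }


def _two_module_label_network(seed: int, n_per_module: int = 15):
    rng = np.random.default_rng(seed)
    mod_a = [f"NA{i}" for i in range(n_per_module)]
    mod_b = [f"NB{i}" for i in range(n_per_module)]
    edges = []
    for mod in (mod_a, mod_b):
        for i in range(len(mod)):
            for j in range(i + 1, len(mod)):
                if rng.random() < 0.6:
                    edges.append(
                        (mod[i], mod[j], float(rng.uniform(0.5, 1.0)), EvidenceType.COEXPRESSION)
                    )
    for a in mod_a:
        for b in mod_b:
            if rng.random() < 0.08:
                edges.append(
                    (a, b, float(rng.uniform(1e-9, 0.5)), EvidenceType.COEXPRESSION)
                )
    labels = {g: "ConditionA" for g in mod_a}
    labels.update({g: "ConditionB" for g in mod_b})
    return GeneNetwork.from_edges(edges), labels


def neighbor_vote_benchmark(seed: int = 0, n_runs: int = 100) -> dict:
    """Guilt-by-association analogue: split-half cross-validation of the
    top-2 neighbour vote on a planted two-module label network, with a
    shuffled-label chance control."""
    net, labels = _two_module_label_network(seed)
    accuracy = cross_validate_classification(
        labels, net, n_runs=n_runs, split_frac=0.5, k=2, seed=seed
    )
    rng = np.random.default_rng(seed + 1)
    genes = sorted(labels)
    shuffled = dict(zip(genes, rng.permutation([labels[g] for g in genes])))
    random_accuracy = cross_validate_classification(
        shuffled, net, n_runs=n_runs, split_frac=0.5, k=2, seed=seed
    )
    return {
        "cv_accuracy": accuracy,
        "random_label_accuracy": random_accuracy,
        "n_runs": n_runs,
        "n_genes": len(labels),
    }


def null_calibration_benchmark(seed: int = 0, n_mock: int = 50) -> dict:
    """Type-I control of the +/-0.02 cutoff rule: permute the phenotype
    labels and measure the fraction of variants still called."""
    groups = (
        VariantGroup(
            genes=tuple(f"PA{i}" for i in range(5)), variants_per_gene=2, beta=1.0, maf=0.3
        ),
        VariantGroup(
            genes=tuple(f"PB{i}" for i in range(5)), variants_per_gene=2, beta=-1.0, maf=0.3
        ),
    )
    spec = SimulationSpec(
        n_cases=150, n_controls=150, groups=groups, n_noise_variants=20, seed=seed
    )
    g, y, truth = simulate_cohort(spec)
    g, _ = impute_mock_variants(g, n_mock, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    statuses = [y[s] for s in g.samples]
    permuted = PhenotypeVector(
        dict(zip(g.samples, rng.permutation(statuses)))
    )
    cfg = ScoringConfig(seed=seed)
    table = _scored_pipeline(g, permuted, truth, cfg, net_seed=seed + 3)
    idi = table["idi"].dropna().to_numpy(dtype=float)
    return {
        "null_call_rate": float(np.mean(np.abs(idi) >= cfg.idi_pro_threshold)),
        "n_variants_scored": int(len(idi)),
        "n_samples": g.n_samples,
    }
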