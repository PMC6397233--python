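"""Variant scoring engine: paired risk models over network subnetworks.

For each candidate variant (a VUS), its host gene is placed on every
evidence network that contains it; the two-hop subnetwork around the gene
defines a pool of synergistic variants.  Two risk models are fitted per
network: Model 1 on the whole pool and Model 2 on the pool minus the VUS.
The IDI between them (on leave-one-out risks by default) scores the
variant's contribution; IDI >= +0.02 calls it pro-disease, <= -0.02
protective.  Networks whose single-network comparison is significant are
additionally merged (by common genes, keeping evidence multiplicity) into
one enriched evaluation.

The surface is statsmodels-style: ``VariantScoringModel(...).fit()``
returns a :class:`VariantScoringResults` carrying per-variant scores, the
ranked table and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix, PhenotypeVector
from .network import EvidenceType, GeneNetwork, merge_networks, select_subnetwork
from .risk import (
    DEFAULT_RIDGE_LAMBDA,
    IN_SAMPLE,
    LOOCV,
    PROTECTIVE,
    ReclassificationStats,
    RiskVector,
    auc,
    fit_risk_model,
    loocv_risks,
    predict_risk,
    reclassification_stats,
    univariate_odds_ratios,
)

__all__ = [
    "ScoringConfig",
    "ModelEval",
    "VariantScore",
    "ImprovementReport",
    "VariantScoringModel",
    "VariantScoringResults",
    "baseline_or_selection",
    "classify_idi",
    "score_variant",
    "score_all_variants",
    "evaluate_improvement",
    "synergy_ablation",
]

PRO_DISEASE = "pro_disease"
UNCLASSIFIED = "unclassified"
SKIPPED = "skipped"

SCORE_COLUMNS = [
    "variant_id",
    "gene",
    "evidence_types",
    "n_subnetwork_genes",
    "n_model_variants",
    "auc1",
    "auc2",
    "idi",
    "idi_se",
    "idi_p",
    "nri",
    "vus_coef_p",
    "classification",
]


@dataclass(frozen=True)
class ScoringConfig:
    """Tunable parameters of the scoring pipeline."""

    k_neighbors: int = 2
    idi_pro_threshold: float = 0.02
    idi_protective_threshold: float = -0.02
    merge_alpha: float = 0.05
    risk_mode: str = LOOCV
    ridge_lambda: float = DEFAULT_RIDGE_LAMBDA
    or_threshold: float = 5.0
    n_random_iterations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.idi_protective_threshold < 0.0 < self.idi_pro_threshold):
            raise ValueError("thresholds must satisfy protective < 0 < pro")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.n_random_iterations < 1:
            raise ValueError("n_random_iterations must be >= 1")
        if self.risk_mode not in (LOOCV, IN_SAMPLE):
            raise ValueError(f"unknown risk_mode {self.risk_mode!r}")
        if self.or_threshold <= 1.0:
            raise ValueError("or_threshold must exceed 1")


@dataclass
class ModelEval:
    """One paired-model evaluation of a VUS on a (possibly merged) network."""

    evidence_types: frozenset[EvidenceType]
    subnetwork_genes: set[str]
    model1_variants: list[str]
    model2_variants: list[str]
    stats: ReclassificationStats
    vus_coef_p: float

    def __post_init__(self) -> None:
        if set(self.model2_variants) | {v for v in self.model1_variants} != set(
            self.model1_variants
        ) or len(self.model1_variants) != len(self.model2_variants) + 1:
            raise ValueError("model2 must be model1 minus exactly the scored VUS")

    @property
    def evidence_key(self) -> str:
        return "+".join(sorted(e.value for e in self.evidence_types))


@dataclass
class VariantScore:
    """Per-VUS result: all evaluations, the best one, and the final call."""

    variant_id: str
    gene: str
    evals: list[ModelEval] = field(default_factory=list)
    best_eval: ModelEval | None = None
    idi: float | None = None
    classification: str = SKIPPED


def classify_idi(idi: float, cfg: ScoringConfig = ScoringConfig()) -> str:
    """Threshold an IDI score: pro-disease at >= +0.02, protective at
    <= -0.02 (defaults; configurable), otherwise unclassified."""
    if not np.isfinite(idi):
        raise ValueError("idi must be finite")
    if idi >= cfg.idi_pro_threshold:
        return PRO_DISEASE
    if idi <= cfg.idi_protective_threshold:
        return PROTECTIVE
    return UNCLASSIFIED


def baseline_or_selection(
    g: GenotypeMatrix,
    y: PhenotypeVector,
    or_threshold: float = 5.0,
    ridge_lambda: float = DEFAULT_RIDGE_LAMBDA,
) -> dict:
    """Odds-ratio baseline: select variants with OR >= t or OR <= 1/t.

    Symmetric in direction so both high-risk and protective variants pass;
    returns the selected ids, per-variant directions and the full OR table.
    """
    if or_threshold <= 1.0:
        raise ValueError("or_threshold must exceed 1")
    table = univariate_odds_ratios(g, y, ridge_lambda)
    odds = table["or"]
    selected_mask = (~table["monomorphic"]) & (
        (odds >= or_threshold) | (odds <= 1.0 / or_threshold)
    )
    selected = [v for v in g.variant_ids if selected_mask.get(v, False)]
    return {
        "selected": selected,
        "directions": table["direction"].to_dict(),
        "table": table,
    }


class _RiskCache:
    """Memoizes risk vectors by (variant pool, lambda, mode)."""

    def __init__(self, g: GenotypeMatrix, y: PhenotypeVector):
        self.g = g
        self.y = y
        self._store: dict[tuple, RiskVector] = {}

    def risks(self, pool: Sequence[str], ridge_lambda: float, mode: str) -> RiskVector:
        key = (frozenset(pool), ridge_lambda, mode)
        if key not in self._store:
            if mode == LOOCV:
                self._store[key] = loocv_risks(self.g, self.y, list(pool), ridge_lambda)
            else:
                model = fit_risk_model(self.g, self.y, list(pool), ridge_lambda)
                self._store[key] = predict_risk(model, self.g)
        return self._store[key]


def _evaluate_pool(
    g: GenotypeMatrix,
    y: PhenotypeVector,
    vus: str,
    pool: list[str],
    evidence: frozenset[EvidenceType],
    subnetwork: set[str],
    cfg: ScoringConfig,
    cache: _RiskCache,
) -> ModelEval:
    model1 = sorted(pool)
    model2 = [v for v in model1 if v != vus]
    risks1 = cache.risks(model1, cfg.ridge_lambda, cfg.risk_mode)
    risks2 = cache.risks(model2, cfg.ridge_lambda, cfg.risk_mode)
    stats = reclassification_stats(risks1, risks2, y)
    fit1 = fit_risk_model(g, y, model1, cfg.ridge_lambda)
    vus_p = float(fit1.coef_p[model1.index(vus)])
    return ModelEval(
        evidence_types=evidence,
        subnetwork_genes=subnetwork,
        model1_variants=model1,
        model2_variants=model2,
        stats=stats,
        vus_coef_p=vus_p,
    )


def score_variant(
    g: GenotypeMatrix,
    y: PhenotypeVector,
    vus: str,
    networks: Sequence[GeneNetwork],
    cfg: ScoringConfig = ScoringConfig(),
    _cache: _RiskCache | None = None,
) -> VariantScore:
    """Score one variant across all evidence networks.

    Per network containing the VUS gene: the two-hop subnetwork defines the
    Model 1 pool (every dataset variant on a subnetwork gene, always
    including the VUS); Model 2 drops the VUS.  Networks whose single-
    network ``idi_p`` falls below ``merge_alpha`` are merged (if >= 2) into
    one additional enriched evaluation.  The best evaluation (smallest
    idi_p, then largest |IDI|, then evidence name) yields the final IDI and
    the pro-disease/protective call; a gene on no network is ``skipped``.
    """
    if vus not in g:
        raise KeyError(f"variant {vus!r} not in genotype matrix")
    gene = g.variant(vus).gene
    cache = _cache if _cache is not None else _RiskCache(g, y)
    gene_variants = g.gene_to_variants()

    def pool_for(subnetwork: set[str]) -> list[str]:
        pool = {v for gn in subnetwork for v in gene_variants.get(gn, [])}
        pool.add(vus)
        return sorted(pool)

    evals: list[ModelEval] = []
    eligible: list[GeneNetwork] = []
    for net in networks:
        if gene not in net:
            continue
        sub = select_subnetwork(net, gene, cfg.k_neighbors)
        ev = _evaluate_pool(
            g, y, vus, pool_for(sub), frozenset(net.evidence_types), sub, cfg, cache
        )
        evals.append(ev)
        eligible.append(net)

    significant = [
        net for net, ev in zip(eligible, evals) if ev.stats.idi_p < cfg.merge_alpha
    ]
    if len(significant) >= 2:
        merged = merge_networks(significant)
        sub = select_subnetwork(merged, gene, cfg.k_neighbors)
        evals.append(
            _evaluate_pool(
                g, y, vus, pool_for(sub), frozenset(merged.evidence_types), sub, cfg, cache
            )
        )

    if not evals:
        return VariantScore(variant_id=vus, gene=gene, classification=SKIPPED)
    best = min(evals, key=lambda e: (e.stats.idi_p, -abs(e.stats.idi), e.evidence_key))
    return VariantScore(
        variant_id=vus,
        gene=gene,
        evals=evals,
        best_eval=best,
        idi=best.stats.idi,
        classification=classify_idi(best.stats.idi, cfg),
    )


@dataclass
class ImprovementReport:
    """Baseline-vs-augmented risk prediction with a random-addition control."""

    baseline_ids: list[str]
    added_ids: list[str]
    auc_baseline: float
    auc_augmented: float
    stats: ReclassificationStats
    random_aucs: list[float]
    auc_random_mean: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "auc_baseline",
                    "auc_augmented",
                    "idi",
                    "idi_se",
                    "idi_p",
                    "nri",
                    "auc_random_mean",
                    "n_baseline",
                    "n_added",
                    "n_random_iterations",
                ],
                "value": [
                    self.auc_baseline,
                    self.auc_augmented,
                    self.stats.idi,
                    self.stats.idi_se,
                    self.stats.idi_p,
                    self.stats.nri_continuous,
                    np.nan if self.auc_random_mean is None else self.auc_random_mean,
                    len(self.baseline_ids),
                    len(self.added_ids),
                    len(self.random_aucs),
                ],
            }
        )


def evaluate_improvement(
    g: GenotypeMatrix,
    y: PhenotypeVector,
    baseline_ids: Sequence[str],
    added_ids: Sequence[str],
    cfg: ScoringConfig = ScoringConfig(),
    run_random_control: bool = True,
) -> ImprovementReport:
    """Assess risk-prediction improvement from adding selected variants to
    the odds-ratio baseline.

    Baseline and augmented models are compared on LOOCV risks.  The random
    control redraws ``len(added_ids)`` variants uniformly from the
    non-baseline variants ``cfg.n_random_iterations`` times and reports the
    AUC of the per-sample average of the LOOCV risks across iterations.
    """
    baseline_ids = list(baseline_ids)
    added_ids = list(added_ids)
    if not baseline_ids:
        raise ValueError("baseline variant list is empty")
    if set(baseline_ids) & set(added_ids):
        raise ValueError("added variants must be disjoint from the baseline")
    base_risks = loocv_risks(g, y, baseline_ids, cfg.ridge_lambda)
    if added_ids:
        aug_risks = loocv_risks(g, y, baseline_ids + added_ids, cfg.ridge_lambda)
    else:
        aug_risks = base_risks
    stats = reclassification_stats(aug_risks, base_risks, y)

    random_aucs: list[float] = []
    auc_random_mean = None
    if run_random_control and added_ids:
        rng = np.random.default_rng(cfg.seed)
        candidates = [v for v in g.variant_ids if v not in set(baseline_ids)]
        n_draw = min(len(added_ids), len(candidates))
        risk_sum = np.zeros(g.n_samples)
        for _ in range(cfg.n_random_iterations):
            picks = list(rng.choice(candidates, size=n_draw, replace=False))
            r = loocv_risks(g, y, baseline_ids + picks, cfg.ridge_lambda)
            risk_sum += r.risks
            random_aucs.append(auc(r, y))
        mean_risks = RiskVector(
            list(g.samples), risk_sum / cfg.n_random_iterations, LOOCV
        )
        auc_random_mean = auc(mean_risks, y)
    return ImprovementReport(
        baseline_ids=baseline_ids,
        added_ids=added_ids,
        auc_baseline=stats.auc_old,
        auc_augmented=stats.auc_new,
        stats=stats,
        random_aucs=random_aucs,
        auc_random_mean=auc_random_mean,
    )


def synergy_ablation(
    g: GenotypeMatrix,
    y: PhenotypeVector,
    group: Sequence[str],
    cfg: ScoringConfig = ScoringConfig(),
) -> pd.DataFrame:
    """Incremental single-variant removal from a synergistic group.

    For each member v, LOOCV metrics of the full group are compared with
    the group without v: ``delta_auc`` = AUC(full) - AUC(without v) and
    ``delta_idi`` the IDI of full vs ablated.  Large drops mark variants
    the group's predictive power depends on.
    """
    group = list(group)
    if len(group) < 2:
        raise ValueError("synergy ablation needs a group of >= 2 variants")
    full_risks = loocv_risks(g, y, group, cfg.ridge_lambda)
    full_auc = auc(full_risks, y)
    rows = []
    for v in group:
        ablated = [w for w in group if w != v]
        abl_risks = loocv_risks(g, y, ablated, cfg.ridge_lambda)
        stats = reclassification_stats(full_risks, abl_risks, y)
        rows.append((v, full_auc - stats.auc_old, stats.idi))
    return pd.DataFrame(rows, columns=["variant_id", "delta_auc", "delta_idi"]).set_index(
        "variant_id"
    )


# -- whole-dataset scoring ------------------------------------------------------


def score_all_variants(
    g: GenotypeMatrix,
    y: PhenotypeVector,
    networks: Sequence[GeneNetwork],
    cfg: ScoringConfig = ScoringConfig(),
) -> "VariantScoringResults":
    """Score every variant in the dataset; equivalent to
    ``VariantScoringModel(g, y, networks, cfg).fit()``."""
    return VariantScoringModel(g, y, networks, cfg).fit()


class VariantScoringModel:
    """Whole-dataset scoring model (statsmodels-style surface).

    Built from a complete genotype matrix, phenotypes and one or more
    evidence networks; ``fit()`` scores every variant and returns a
    :class:`VariantScoringResults`.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        phenotypes: PhenotypeVector,
        networks: Sequence[GeneNetwork],
        config: ScoringConfig = ScoringConfig(),
    ):
        if genotypes.has_missing():
            raise ValueError("genotype matrix has missing entries; run handle_missing first")
        phenotypes.require_both_classes()
        missing = [s for s in genotypes.samples if s not in phenotypes]
        if missing:
            raise ValueError(f"samples without phenotype: {missing}")
        if not networks:
            raise ValueError("at least one network required")
        self.genotypes = genotypes
        self.phenotypes = phenotypes
        self.networks = list(networks)
        self.config = config

    def fit(self, variants: Sequence[str] | None = None) -> "VariantScoringResults":
        ids = list(variants) if variants is not None else self.genotypes.variant_ids
        cache = _RiskCache(self.genotypes, self.phenotypes)
        scores = [
            score_variant(
                self.genotypes, self.phenotypes, v, self.networks, self.config, _cache=cache
            )
            for v in ids
        ]
        return VariantScoringResults(self, scores)


class VariantScoringResults:
    """Ranked per-variant scores with classification counts."""

    def __init__(self, model: VariantScoringModel, scores: list[VariantScore]):
        self.model = model
        self.scores = scores
        self.by_variant = {s.variant_id: s for s in scores}
        self.table = self._build_table()

    def _build_table(self) -> pd.DataFrame:
        rows = []
        for s in self.scores:
            if s.best_eval is None:
                rows.append(
                    (s.variant_id, s.gene, "", 0, 0, *(np.nan,) * 7, SKIPPED)
                )
                continue
            st = s.best_eval.stats
            rows.append(
                (
                    s.variant_id,
                    s.gene,
                    s.best_eval.evidence_key,
                    len(s.best_eval.subnetwork_genes),
                    len(s.best_eval.model1_variants),
                    st.auc_new,
                    st.auc_old,
                    st.idi,
                    st.idi_se,
                    st.idi_p,
                    st.nri_continuous,
                    s.best_eval.vus_coef_p,
                    s.classification,
                )
            )
        df = pd.DataFrame(rows, columns=SCORE_COLUMNS)
        df["abs_idi"] = df["idi"].abs()
        df = df.sort_values(
            by=["abs_idi", "idi_p", "variant_id"],
            ascending=[False, True, True],
            na_position="last",
            kind="mergesort",
        ).drop(columns="abs_idi")
        return df.reset_index(drop=True)

    @property
    def classification_counts(self) -> dict[str, int]:
        counts = {PRO_DISEASE: 0, PROTECTIVE: 0, UNCLASSIFIED: 0, SKIPPED: 0}
        for s in self.scores:
            counts[s.classification] += 1
        return counts

    @property
    def n_risk_models(self) -> int:
        return sum(len(s.evals) for s in self.scores)

    def top_variants(self, classification: str) -> list[str]:
        return [
            row.variant_id
            for row in self.table.itertuples()
            if row.classification == classification
        ]

    def summary(self) -> str:
        counts = self.classification_counts
        cfg = self.model.config
        lines = [
            "Variant scoring results",
            "=" * 57,
            f"variants scored:        {len(self.scores)}",
            f"risk models evaluated:  {self.n_risk_models}",
            f"unique genes:           {len(set(s.gene for s in self.scores))}",
            f"pro-disease (IDI >= {cfg.idi_pro_threshold:+.2f}): {counts[PRO_DISEASE]}",
            f"protective  (IDI <= {cfg.idi_protective_threshold:+.2f}): {counts[PROTECTIVE]}",
            f"unclassified:           {counts[UNCLASSIFIED]}",
            f"skipped (gene off-network): {counts[SKIPPED]}",
            "-" * 57,
            "top 10 by |IDI|:",
            self.table.head(10).to_string(index=False, float_format=lambda x: f"{x:.4g}"),
        ]
        return "\n".join(lines)

    def write_table(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")
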