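"""Synthetic case-control cohorts, evidence networks, mock variants and
knowledge-base fixtures.

The generator emulates the statistical structure the scoring pipeline
assumes: Hardy-Weinberg genotypes at stated minor-allele frequencies, an
additive logistic disease model with planted pro-disease and protective
effects grouped into gene modules, evidence networks in which each planted
module forms a clique, and per-sample frequency-matched mock variants that
are uninformative by construction.

Two documented standard scenarios:

- :func:`demo_spec` - the validation-panel analogue: a balanced 200/200
  cohort, five modules of five genes with two variants each (three
  pro-disease, two protective), per-variant effect |beta| = 1.0 log-odds
  per allele copy (allelic OR ~ 2.7, panel-grade documented disease
  variants) at MAF 0.3.
- :func:`greyzone_spec` - the improvement-over-baseline analogue: a small
  set of strong baseline variants (|beta| = 1.2) plus a module of weak
  synergistic variants (|beta| = 0.35, allelic OR ~ 1.4, individually
  below typical odds-ratio selection thresholds) among many null variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import CASE, CONTROL, GenotypeMatrix, PhenotypeVector, VariantRecord
from .knowledge import ClinicalRecord
from .network import EvidenceType, GeneNetwork

__all__ = [
    "VariantGroup",
    "SimulationSpec",
    "SimulationTruth",
    "demo_spec",
    "greyzone_spec",
    "synergy_spec",
    "simulate_cohort",
    "simulate_networks",
    "impute_mock_variants",
    "simulate_kb",
]

ROLE_PRO = "informative_pro"
ROLE_PROTECTIVE = "informative_protective"
ROLE_NOISE = "noise"
ROLE_MOCK = "mock"


@dataclass(frozen=True)
class VariantGroup:
    """A planted module: genes carrying variants with a shared effect size."""

    genes: tuple[str, ...]
    variants_per_gene: int
    beta: float  # log-odds per allele copy; sign gives direction
    maf: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(g.upper() for g in self.genes))
        if not self.genes:
            raise ValueError("group needs at least one gene")
        if self.variants_per_gene < 1:
            raise ValueError("variants_per_gene must be >= 1")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")


@dataclass(frozen=True)
class SimulationSpec:
    n_cases: int
    n_controls: int
    groups: tuple[VariantGroup, ...]
    baseline_log_odds: float = 0.0
    n_noise_variants: int = 0
    noise_maf_range: tuple[float, float] = (0.05, 0.5)
    n_noise_genes: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need positive case and control counts")
        seen: set[str] = set()
        for grp in self.groups:
            overlap = seen & set(grp.genes)
            if overlap:
                raise ValueError(f"group genes not disjoint: {sorted(overlap)}")
            seen |= set(grp.genes)
        lo, hi = self.noise_maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("noise_maf_range must be within (0, 0.5]")


@dataclass
class SimulationTruth:
    """Per-variant ground truth: role, effect, group membership, MAF."""

    table: pd.DataFrame  # indexed by variant_id: role, beta, group, gene, maf

    @property
    def informative_ids(self) -> list[str]:
        mask = self.table["role"].isin([ROLE_PRO, ROLE_PROTECTIVE])
        return list(self.table.index[mask])

    @property
    def mock_ids(self) -> list[str]:
        return list(self.table.index[self.table["role"] == ROLE_MOCK])

    @property
    def noise_ids(self) -> list[str]:
        return list(self.table.index[self.table["role"] == ROLE_NOISE])

    def role(self, variant_id: str) -> str:
        return str(self.table.loc[variant_id, "role"])

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for vid, row in self.table.iterrows():
            if row["group"]:
                out.setdefault(str(row["group"]), []).append(str(vid))
        return out


def demo_spec(seed: int = 0) -> SimulationSpec:
    """The documented validation scenario (see module docstring)."""
    groups = []
    for i in range(5):
        genes = tuple(f"MOD{i + 1}G{j + 1}" for j in range(5))
        beta = 1.0 if i < 3 else -1.0
        groups.append(VariantGroup(genes=genes, variants_per_gene=2, beta=beta, maf=0.3))
    return SimulationSpec(
        n_cases=200,
        n_controls=200,
        groups=tuple(groups),
        baseline_log_odds=0.0,
        n_noise_variants=50,
        noise_maf_range=(0.05, 0.5),
        seed=seed,
    )


def greyzone_spec(seed: int = 0) -> SimulationSpec:
    """The documented improvement scenario: strong baseline variants that
    pass an odds-ratio threshold plus a weak synergistic module whose
    variants individually sit below it, among many null variants."""
    baseline = VariantGroup(
        genes=("BASE1", "BASE2", "BASE3", "BASE4", "BASE5"),
        variants_per_gene=2,
        beta=1.2,
        maf=0.2,
    )
    greyzone = VariantGroup(
        genes=("GREY1", "GREY2", "GREY3", "GREY4", "GREY5"),
        variants_per_gene=2,
        beta=0.35,
        maf=0.3,
    )
    return SimulationSpec(
        n_cases=200,
        n_controls=200,
        groups=(baseline, greyzone),
        baseline_log_odds=0.0,
        n_noise_variants=1000,
        noise_maf_range=(0.05, 0.5),
        n_noise_genes=500,
        seed=seed,
    )


def synergy_spec(seed: int = 0) -> SimulationSpec:
    """The documented synergy-ablation scenario: one dominant planted
    structure (a clearly strongest variant plus a supporting module that is
    jointly, not individually, informative) and a handful of null partner
    variants."""
    strongest = VariantGroup(genes=("HUB1",), variants_per_gene=1, beta=1.4, maf=0.3)
    partners = VariantGroup(
        genes=("SYN1", "SYN2", "SYN3"), variants_per_gene=3, beta=0.85, maf=0.3
    )
    return SimulationSpec(
        n_cases=200,
        n_controls=200,
        groups=(strongest, partners),
        baseline_log_odds=0.0,
        n_noise_variants=10,
        noise_maf_range=(0.1, 0.5),
        seed=seed,
    )


def _spec_variants(spec: SimulationSpec, rng: np.random.Generator):
    """Expand the spec into per-variant (id, gene, beta, maf, role, group)."""
    rows = []
    idx = 0
    for gi, grp in enumerate(spec.groups, start=1):
        role = ROLE_PRO if grp.beta > 0 else (ROLE_PROTECTIVE if grp.beta < 0 else ROLE_NOISE)
        for gene in grp.genes:
            for _ in range(grp.variants_per_gene):
                idx += 1
                rows.append((f"var{idx:04d}", gene, grp.beta, grp.maf, role, f"group{gi}"))
    n_bg_genes = (
        spec.n_noise_genes
        if spec.n_noise_genes is not None
        else max(1, spec.n_noise_variants // 2)
    )
    bg_genes = [f"BG{j + 1:03d}" for j in range(n_bg_genes)]
    lo, hi = spec.noise_maf_range
    for j in range(spec.n_noise_variants):
        idx += 1
        maf = float(rng.uniform(lo, hi))
        gene = bg_genes[j % n_bg_genes]
        rows.append((f"var{idx:04d}", gene, 0.0, maf, ROLE_NOISE, ""))
    return rows


def simulate_cohort(
    spec: SimulationSpec,
) -> tuple[GenotypeMatrix, PhenotypeVector, SimulationTruth]:
    """Draw a case-control cohort under the planted additive-logistic model.

    Genotypes are Binomial(2, maf) per variant (HWE, independent variants);
    disease status follows ``logit P(case) = baseline + sum_j beta_j *
    (dosage_j - 2*maf_j)`` (centered dosages, so the baseline is the
    population log-odds).  Samples are drawn in batches and kept until the
    case and control quotas are met; fully reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    rows = _spec_variants(spec, rng)
    betas = np.array([r[2] for r in rows])
    mafs = np.array([r[3] for r in rows])
    n_var = len(rows)

    need_case, need_ctrl = spec.n_cases, spec.n_controls
    got_case: list[np.ndarray] = []
    got_ctrl: list[np.ndarray] = []
    batch = max(64, need_case + need_ctrl)
    max_draws = 200 * (need_case + need_ctrl)
    drawn = 0
    while (len(got_case) < need_case or len(got_ctrl) < need_ctrl) and drawn < max_draws:
        G = rng.binomial(2, mafs[:, None], size=(n_var, batch)).astype(float)
        eta = spec.baseline_log_odds + betas @ (G - 2.0 * mafs[:, None])
        status = rng.random(batch) < expit(eta)
        for j in range(batch):
            if status[j] and len(got_case) < need_case:
                got_case.append(G[:, j])
            elif not status[j] and len(got_ctrl) < need_ctrl:
                got_ctrl.append(G[:, j])
        drawn += batch
    if len(got_case) < need_case or len(got_ctrl) < need_ctrl:
        raise RuntimeError(
            "case/control quota unattainable: prevalence too extreme under "
            f"baseline_log_odds={spec.baseline_log_odds}"
        )
    dosages = np.column_stack(got_case + got_ctrl)
    samples = [f"S{i + 1:04d}" for i in range(need_case + need_ctrl)]
    status_map = {
        s: (CASE if i < need_case else CONTROL) for i, s in enumerate(samples)
    }
    variants = [VariantRecord(vid, gene) for vid, gene, *_ in rows]
    g = GenotypeMatrix(variants, samples, dosages)
    truth = SimulationTruth(
        pd.DataFrame(
            {
                "role": [r[4] for r in rows],
                "beta": betas,
                "group": [r[5] for r in rows],
                "gene": [r[1] for r in rows],
                "maf": mafs,
            },
            index=pd.Index([r[0] for r in rows], name="variant_id"),
        )
    )
    return g, PhenotypeVector(status_map), truth


def simulate_networks(
    truth: SimulationTruth,
    background_density: float = 0.05,
    seed: int = 0,
    evidence_types: Sequence[EvidenceType] = tuple(EvidenceType),
) -> list[GeneNetwork]:
    """One evidence network per requested type.

    Planted groups are assigned to evidence types round-robin; each group's
    genes form a clique in its designated network with edge weights
    U(0.5, 1] (functional evidence is stronger than noise).  Background
    (non-module) genes are wired as an Erdos-Renyi graph at
    ``background_density`` with weights U(0, 0.5] in every network.
    """
    if not 0.0 <= background_density <= 1.0:
        raise ValueError("background_density must be in [0, 1]")
    group_genes = {
        gname: sorted(set(truth.table.loc[vids, "gene"]))
        for gname, vids in truth.groups().items()
    }
    if not group_genes:
        raise ValueError("truth contains no planted groups")
    bg_genes = sorted(
        set(truth.table.loc[truth.table["group"] == "", "gene"])
    )
    rng = np.random.default_rng(seed)
    evidence_types = [EvidenceType(e) for e in evidence_types]
    nets: list[GeneNetwork] = []
    group_names = sorted(group_genes)
    for ti, ev in enumerate(evidence_types):
        edges: list[tuple[str, str, float, EvidenceType]] = []
        for gi, gname in enumerate(group_names):
            if gi % len(evidence_types) != ti:
                continue
            genes = group_genes[gname]
            for a_i in range(len(genes)):
                for b_i in range(a_i + 1, len(genes)):
                    w = 0.5 + 0.5 * rng.random()
                    edges.append((genes[a_i], genes[b_i], w, ev))
        for a_i in range(len(bg_genes)):
            for b_i in range(a_i + 1, len(bg_genes)):
                if rng.random() < background_density:
                    w = max(1e-9, 0.5 * rng.random())
                    edges.append((bg_genes[a_i], bg_genes[b_i], w, ev))
        if not edges:  # keep the network non-empty and loadable
            if len(bg_genes) >= 2:
                edges.append((bg_genes[0], bg_genes[1], 0.25, ev))
            else:
                genes = group_genes[group_names[ti % len(group_names)]]
                edges.append((genes[0], genes[1], 0.75, ev))
        net = GeneNetwork.from_edges(edges)
        nets.append(net)
    return nets


def impute_mock_variants(
    g: GenotypeMatrix, n_mock: int, seed: int = 0
) -> tuple[GenotypeMatrix, list[str]]:
    """Append per-sample frequency-matched mock (uninformative) variants.

    For each sample, the multinomial proportions of genotypes {0, 1, 2}
    across the observed variants are estimated, and each mock genotype for
    that sample is drawn independently from that multinomial.  Mock
    variants are assigned to genes drawn uniformly from the genes already
    present, so they are placed on the networks exactly like true variants.
    """
    if n_mock < 1:
        raise ValueError("n_mock must be >= 1")
    if g.n_variants == 0:
        raise ValueError("empty genotype matrix")
    if g.has_missing():
        raise ValueError("genotype matrix has missing entries")
    rng = np.random.default_rng(seed)
    props = np.stack(
        [(g.dosages == code).mean(axis=0) for code in (0.0, 1.0, 2.0)], axis=0
    )  # 3 x n_samples
    cum = np.cumsum(props, axis=0)
    u = rng.random(size=(n_mock, g.n_samples))
    mock_dosages = (u[None, :, :] > cum[:, None, :]).sum(axis=0).astype(float)
    genes = sorted(set(g.genes))
    mock_genes = rng.choice(genes, size=n_mock, replace=True)
    mock_ids = [f"mock{i + 1:04d}" for i in range(n_mock)]
    mock_records = [VariantRecord(vid, gene) for vid, gene in zip(mock_ids, mock_genes)]
    mock_matrix = GenotypeMatrix(mock_records, g.samples, mock_dosages)
    return g.append(mock_matrix), mock_ids


def simulate_kb(
    truth: SimulationTruth,
    condition_names: Mapping[str, str],
    seed: int = 0,
    decoy_condition: str | None = None,
) -> list[ClinicalRecord]:
    """Knowledge-base fixture: one record per informative variant carrying
    its group's condition.  Noise variants are omitted unless
    ``decoy_condition`` is given, in which case they carry that unrelated
    condition."""
    records: list[ClinicalRecord] = []
    for vid, row in truth.table.iterrows():
        role = row["role"]
        if role in (ROLE_PRO, ROLE_PROTECTIVE):
            group = str(row["group"])
            if group not in condition_names:
                raise ValueError(f"group {group!r} has no condition name")
            significance = "risk factor" if role == ROLE_PRO else "protective"
            records.append(
                ClinicalRecord(
                    variant_id=str(vid),
                    gene=str(row["gene"]),
                    condition=condition_names[group],
                    clinical_significance=significance,
                )
            )
        elif role == ROLE_NOISE and decoy_condition:
            records.append(
                ClinicalRecord(
                    variant_id=str(vid),
                    gene=str(row["gene"]),
                    condition=decoy_condition,
                    clinical_significance="Uncertain significance",
                )
            )
    return records
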