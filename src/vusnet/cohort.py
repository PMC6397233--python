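"""Case-control genotype cohorts in 0/1/2 allele-dosage coding.

The pipeline operates on a variants x samples dosage matrix where each
entry counts copies of the alternate allele: 0 homozygote reference,
1 heterozygote, 2 homozygote alternate.  Missing entries are carried as
NaN until :func:`handle_missing` resolves them; every modelling routine
downstream requires a complete matrix.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "PhenotypeVector",
    "GenotypeMatrix",
    "read_genotype_table",
    "write_genotype_table",
    "read_phenotypes",
    "write_phenotypes",
    "read_vcf_cohort",
    "handle_missing",
]

_MISSING_TOKENS = {"NA", "."}

CASE = "case"
CONTROL = "control"


@dataclass(frozen=True)
class VariantRecord:
    """A single variant: identifier, host gene and optional coordinates."""

    variant_id: str
    gene: str
    chrom: str | None = None
    pos: int | None = None
    ref: str | None = None
    alt: str | None = None

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ValueError("variant_id must be non-empty")
        if self.pos is not None and self.pos < 1:
            raise ValueError(f"pos must be >= 1 (variant {self.variant_id})")
        object.__setattr__(self, "gene", self.gene.upper())


class PhenotypeVector:
    """Mapping from sample id to case/control status."""

    def __init__(self, status: Mapping[str, str]):
        bad = {s: v for s, v in status.items() if v not in (CASE, CONTROL)}
        if bad:
            raise ValueError(f"invalid phenotype status values: {bad}")
        self._status = dict(status)

    def __getitem__(self, sample: str) -> str:
        return self._status[sample]

    def __contains__(self, sample: str) -> bool:
        return sample in self._status

    def __len__(self) -> int:
        return len(self._status)

    def items(self):
        return self._status.items()

    @property
    def samples(self) -> list[str]:
        return list(self._status)

    @property
    def cases(self) -> list[str]:
        return [s for s, v in self._status.items() if v == CASE]

    @property
    def controls(self) -> list[str]:
        return [s for s, v in self._status.items() if v == CONTROL]

    def align(self, samples: Sequence[str]) -> np.ndarray:
        """Return a 0/1 array (1 = case) ordered like ``samples``.

        Raises if any sample lacks a phenotype, listing the missing ids.
        """
        missing = [s for s in samples if s not in self._status]
        if missing:
            raise ValueError(f"samples without phenotype: {missing}")
        return np.array([1 if self._status[s] == CASE else 0 for s in samples], dtype=int)

    def require_both_classes(self) -> None:
        if not self.cases or not self.controls:
            raise ValueError("phenotype must contain at least one case and one control")


class GenotypeMatrix:
    """Variants x samples dosage matrix with variant metadata.

    ``dosages`` is a float array where missing entries are NaN and every
    non-missing entry is 0, 1 or 2.
    """

    def __init__(
        self,
        variants: Sequence[VariantRecord],
        samples: Sequence[str],
        dosages: np.ndarray,
    ):
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(variants), len(samples)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(variants)} variants x {len(samples)} samples"
            )
        ids = [v.variant_id for v in variants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate variant ids: {dupes}")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids")
        finite = dosages[~np.isnan(dosages)]
        bad = ~np.isin(finite, [0.0, 1.0, 2.0])
        if bad.any():
            rows, cols = np.where(
                ~(np.isnan(dosages) | np.isin(dosages, [0.0, 1.0, 2.0]))
            )
            r, c = rows[0], cols[0]
            raise ValueError(
                f"dosage {dosages[r, c]!r} for variant {ids[r]!r}, sample "
                f"{samples[c]!r} is outside {{0,1,2,missing}}"
            )
        self.variants = list(variants)
        self.samples = list(samples)
        self.dosages = dosages
        self._index = {v.variant_id: i for i, v in enumerate(self.variants)}

    # -- basic introspection -------------------------------------------------

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def genes(self) -> list[str]:
        return [v.gene for v in self.variants]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def variant(self, variant_id: str) -> VariantRecord:
        return self.variants[self._index[variant_id]]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def gene_to_variants(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for v in self.variants:
            out.setdefault(v.gene, []).append(v.variant_id)
        return out

    # -- subsetting and model input ------------------------------------------

    def rows(self, variant_ids: Sequence[str]) -> np.ndarray:
        """Samples x variants dosage array for ``variant_ids`` (model design)."""
        unknown = [v for v in variant_ids if v not in self._index]
        if unknown:
            raise KeyError(f"unknown variants: {unknown}")
        idx = [self._index[v] for v in variant_ids]
        return self.dosages[idx, :].T.copy()

    def subset(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        unknown = [v for v in variant_ids if v not in self._index]
        if unknown:
            raise KeyError(f"unknown variants: {unknown}")
        idx = [self._index[v] for v in variant_ids]
        return GenotypeMatrix(
            [self.variants[i] for i in idx], self.samples, self.dosages[idx, :]
        )

    def append(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        if other.samples != self.samples:
            raise ValueError("sample lists differ")
        return GenotypeMatrix(
            self.variants + other.variants,
            self.samples,
            np.vstack([self.dosages, other.dosages]),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosages, index=self.variant_ids, columns=self.samples)
        df.insert(0, "gene", self.genes)
        df.index.name = "variant_id"
        return df

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.variant_ids == other.variant_ids
            and self.genes == other.genes
            and self.samples == other.samples
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )


# -- flat-file dialect -------------------------------------------------------


def read_genotype_table(path) -> GenotypeMatrix:
    """Read the genotype TSV dialect: header ``variant_id gene <samples...>``,
    one variant per row, cells in {0,1,2,NA,.}.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if len(header) < 3 or header[0] != "variant_id" or header[1] != "gene":
            raise ValueError(
                f"{path}: malformed header; expected 'variant_id<TAB>gene<TAB>"
                f"<sample ids...>', got {header[:3]}"
            )
        samples = header[2:]
        variants: list[VariantRecord] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} columns, got {len(row)}")
            vid, gene = row[0], row[1]
            values: list[float] = []
            for sample, cell in zip(samples, row[2:]):
                if cell in _MISSING_TOKENS:
                    values.append(np.nan)
                elif cell in ("0", "1", "2"):
                    values.append(float(cell))
                else:
                    raise ValueError(
                        f"{path}:{lineno}: invalid dosage {cell!r} for variant "
                        f"{vid!r}, sample {sample!r}"
                    )
            variants.append(VariantRecord(vid, gene))
            rows.append(values)
    if not variants:
        raise ValueError(f"{path}: no variant rows")
    return GenotypeMatrix(variants, samples, np.array(rows, dtype=float))


def write_genotype_table(g: GenotypeMatrix, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["variant_id", "gene", *g.samples])
        for rec, row in zip(g.variants, g.dosages):
            cells = ["NA" if np.isnan(x) else str(int(x)) for x in row]
            writer.writerow([rec.variant_id, rec.gene, *cells])


_STATUS_TOKENS = {"1": CASE, "0": CONTROL, "case": CASE, "control": CONTROL}


def read_phenotypes(path) -> PhenotypeVector:
    """Read a two-column sample/status TSV; status in {1,0,case,control}."""
    status: dict[str, str] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row:
                continue
            if lineno == 1 and row[0].lower() in ("sample_id", "sample"):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            sample, token = row[0], row[1].strip().lower()
            if token not in _STATUS_TOKENS:
                raise ValueError(f"{path}:{lineno}: unknown status {row[1]!r}")
            if sample in status:
                raise ValueError(f"{path}:{lineno}: duplicate sample id {sample!r}")
            status[sample] = _STATUS_TOKENS[token]
    if not status:
        raise ValueError(f"{path}: no phenotype rows")
    return PhenotypeVector(status)


def write_phenotypes(y: PhenotypeVector, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "status"])
        for sample, value in y.items():
            writer.writerow([sample, value])


# -- VCF ingestion -----------------------------------------------------------


def read_vcf_cohort(path, gene_map: Mapping[str, str]) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Convert a multi-sample VCF into ALT-dosage coding.

    ``gene_map`` maps variant keys (the VCF ID, or ``chrom:pos:ref:alt``) to
    gene symbols.  Biallelic records become dosages counting ALT alleles in
    the GT field; half-missing genotypes are treated as missing.  Multiallelic
    records and records absent from ``gene_map`` are excluded; their counts
    are returned in the exclusion report.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise ValueError(f"unreadable VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    report = {"multiallelic": 0, "unmapped": 0}
    for rec in vcf:
        if len(rec.ALT) != 1:
            report["multiallelic"] += 1
            continue
        key_coord = f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        vid = rec.ID if rec.ID and rec.ID != "." else key_coord
        gene = gene_map.get(vid, gene_map.get(key_coord))
        if gene is None:
            report["unmapped"] += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        dosage = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        variants.append(
            VariantRecord(vid, gene, chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=rec.ALT[0])
        )
        rows.append(dosage)
    if not variants:
        raise ValueError(f"{path}: zero variants retained (report: {report})")
    return GenotypeMatrix(variants, samples, np.array(rows, dtype=float)), report


# -- missingness -------------------------------------------------------------


def handle_missing(
    g: GenotypeMatrix,
    strategy: str = "drop_variant",
    max_missing_frac: float = 0.05,
) -> GenotypeMatrix:
    """Resolve missing dosages.

    ``drop_variant`` removes variants whose missing fraction exceeds
    ``max_missing_frac`` and mode-imputes the remainder; ``mode_impute``
    fills every missing entry with the variant's most frequent dosage.
    Ties between dosage modes break toward the lower code.
    """
    if strategy not in ("drop_variant", "mode_impute"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in [0, 1]")
    dosages = g.dosages.copy()
    keep = np.ones(g.n_variants, dtype=bool)
    if strategy == "drop_variant":
        miss_frac = np.isnan(dosages).mean(axis=1)
        keep = miss_frac <= max_missing_frac
        if not keep.any():
            raise ValueError("all variants exceed the missingness threshold")
        dosages = dosages[keep]
    for row in dosages:
        nan = np.isnan(row)
        if not nan.any():
            continue
        observed = row[~nan]
        if observed.size == 0:
            mode = 0.0
        else:
            counts = [(row == code).sum() for code in (0.0, 1.0, 2.0)]
            mode = float(int(np.argmax(counts)))  # argmax ties -> lowest code
        row[nan] = mode
    variants = [v for v, k in zip(g.variants, keep) if k]
    return GenotypeMatrix(variants, g.samples, dosages)
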