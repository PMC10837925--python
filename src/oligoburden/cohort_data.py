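"""Domain types and file I/O for case-control variant-panel cohorts.

A cohort is described by three files:

* a multi-sample VCF 4.2 with per-variant annotations in INFO
  (``GENE``, ``CSQ``, ``DP``, ``AF_GNOMAD``, ``AF_EXAC``, ``AF_1KG``,
  ``REVEL``, ``SPLICE``, ``SCSNV``; ``.`` = missing) and per-sample GT
  fields,
* a two-column gene-panel TSV ``gene<TAB>category`` (header required),
* a phenotype CSV with columns ``sample_id, group, onset_age, fsh``.

The central in-memory container is :class:`CarrierMatrix`, a
sample x gene boolean incidence of qualifying heterozygous variants plus
per-sample qualifying-variant counts, from which every downstream burden
statistic is computed.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("oligoburden")

CATEGORIES = (
    "meiosis_dna_repair",
    "gonadal_formation",
    "ovarian_development",
    "signaling_transcription",
)

CASE = "case"
CONTROL = "control"


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant call: locus, gene, consequence and filter inputs."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    depth: int | None
    af_gnomad: float | None = None
    af_exac: float | None = None
    af_1kg: float | None = None
    revel: float | None = None
    splice_score: float | None = None
    scsnv: float | None = None
    hgvs: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for name in ("af_gnomad", "af_exac", "af_1kg", "revel", "splice_score", "scsnv"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1] at {self.chrom}:{self.pos}")

    @property
    def population_afs(self) -> list[float]:
        """Allele frequencies present in any reference population."""
        return [v for v in (self.af_gnomad, self.af_exac, self.af_1kg) if v is not None]


@dataclass(frozen=True)
class GenePanel:
    """Gene symbol -> biological-function category mapping (four categories)."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.entries.values()} - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown panel categories: {sorted(bad)}")

    @property
    def size(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return list(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def category(self, gene: str) -> str:
        return self.entries[gene]

    def genes_in_category(self, category: str) -> list[str]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return [g for g, c in self.entries.items() if c == category]


@dataclass(frozen=True)
class SampleRecord:
    """One cohort member: id, case/control label and phenotype values."""

    sample_id: str
    group: str
    onset_age: float | None = None
    fsh: float | None = None

    def __post_init__(self) -> None:
        if self.group not in (CASE, CONTROL):
            raise ValueError(f"group must be {CASE!r} or {CONTROL!r}, got {self.group!r}")
        if self.fsh is not None and self.fsh <= 0:
            raise ValueError(f"fsh must be > 0, got {self.fsh}")


@dataclass
class CarrierMatrix:
    """Sample x gene incidence of qualifying heterozygous variants.

    ``carries[i, j]`` is True iff sample *i* has at least one qualifying
    variant in gene *j*; ``variant_count[i]`` is the total number of
    qualifying variants of sample *i* across the whole panel (two variants
    in one gene count twice here but once in ``carries``).
    """

    samples: list[SampleRecord]
    genes: list[str]
    carries: np.ndarray
    variant_count: np.ndarray
    variant_details: dict[tuple[str, str], list[VariantRecord]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.carries = np.asarray(self.carries, dtype=bool)
        self.variant_count = np.asarray(self.variant_count, dtype=int)
        if self.carries.shape != (len(self.samples), len(self.genes)):
            raise ValueError("carries shape does not match samples x genes")
        if self.variant_count.shape != (len(self.samples),):
            raise ValueError("variant_count length does not match samples")
        deficit = self.variant_count < self.carries.sum(axis=1)
        if deficit.any():
            bad = [self.samples[i].sample_id for i in np.flatnonzero(deficit)]
            raise ValueError(f"variant_count below carried-gene count for samples {bad}")

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([s.group == CASE for s in self.samples], dtype=bool)

    @property
    def n_cases(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_controls(self) -> int:
        return len(self.samples) - self.n_cases

    def carrier_counts(self, gene: str) -> tuple[int, int]:
        """(case carriers, control carriers) of ``gene``."""
        j = self.genes.index(gene)
        col = self.carries[:, j]
        mask = self.case_mask
        return int(col[mask].sum()), int(col[~mask].sum())

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        return np.array([self.genes.index(g) for g in genes], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-sample summary: id, group, variant_count, carried genes."""
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "group": [s.group for s in self.samples],
                "variant_count": self.variant_count,
                "carried_genes": [
                    ",".join(g for g, c in zip(self.genes, row) if c) for row in self.carries
                ],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, genes: Sequence[str]) -> "CarrierMatrix":
        """Rebuild carrier incidence from a :meth:`to_tsv` file.

        Variant-level detail is not stored in the TSV, so ``variant_details``
        is empty; carrier incidence and variant counts round-trip exactly.
        """
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        genes = list(genes)
        carries = np.zeros((len(df), len(genes)), dtype=bool)
        for i, cell in enumerate(df["carried_genes"]):
            for g in str(cell).split(","):
                if g:
                    carries[i, genes.index(g)] = True
        samples = [
            SampleRecord(sample_id=str(r.sample_id), group=str(r.group))
            for r in df.itertuples()
        ]
        return cls(samples=samples, genes=genes, carries=carries,
                   variant_count=df["variant_count"].to_numpy())


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_INFO_FLOATS = {
    "AF_GNOMAD": "af_gnomad",
    "AF_EXAC": "af_exac",
    "AF_1KG": "af_1kg",
    "REVEL": "revel",
    "SPLICE": "splice_score",
    "SCSNV": "scsnv",
}


def _info_float(variant, key: str) -> float | None:
    raw = variant.INFO.get(key)
    if raw is None or raw == ".":
        return None
    val = float(raw)
    if math.isnan(val):
        return None
    # htslib stores Float INFO as float32; renormalise to the 6-significant-
    # digit precision the writer emits
    return float(f"{val:.6g}")


def read_variants(
    path: str | Path,
    panel: GenePanel,
    *,
    include_hom_alt: bool = False,
) -> list[tuple[str, VariantRecord]]:
    """Read a multi-sample VCF into (sample_id, VariantRecord) carrier tuples.

    Emits one tuple per heterozygous alternate call per sample. Variants in
    genes absent from ``panel`` are dropped (a count is logged). Homozygous
    alternate calls are excluded by default; ``include_hom_alt=True`` counts
    them as carriers too. Multi-allelic records must be pre-split and are
    rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    tuples: list[tuple[str, VariantRecord]] = []
    off_panel = 0
    hom_alt_seen = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {variant.CHROM}:{variant.POS}; "
                "split multi-allelic sites before reading"
            )
        gene = variant.INFO.get("GENE")
        if gene is None:
            raise ValueError(f"record at {variant.CHROM}:{variant.POS} lacks INFO/GENE")
        if gene not in panel:
            off_panel += 1
            continue
        dp = variant.INFO.get("DP")
        rec = VariantRecord(
            chrom=variant.CHROM,
            pos=variant.POS,
            ref=variant.REF,
            alt=variant.ALT[0],
            gene=gene,
            consequence=str(variant.INFO.get("CSQ", "")),
            depth=None if dp in (None, ".") else int(dp),
            hgvs=variant.INFO.get("HGVS"),
            **{attr: _info_float(variant, key) for key, attr in _INFO_FLOATS.items()},
        )
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        for i, gt in enumerate(variant.gt_types):
            if gt == 1:
                tuples.append((sample_ids[i], rec))
            elif gt == 3:
                hom_alt_seen += 1
                if include_hom_alt:
                    tuples.append((sample_ids[i], rec))
    if off_panel:
        logger.info("read_variants: dropped %d off-panel records", off_panel)
    if hom_alt_seen:
        logger.info(
            "read_variants: %d homozygous-alternate calls %s",
            hom_alt_seen,
            "included" if include_hom_alt else "excluded (het-only analysis)",
        )
    return tuples


def read_panel(path: str | Path) -> GenePanel:
    """Read a ``gene<TAB>category`` TSV (header required) into a GenePanel."""
    entries: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[0].lower() != "gene":
            raise ValueError(f"panel file {path} must start with a 'gene<TAB>category' header")
        for lineno, row in enumerate(reader, start=2):
            if not row or not row[0].strip():
                continue
            gene, category = row[0].strip(), row[1].strip()
            if gene in entries:
                raise ValueError(f"duplicate panel gene {gene!r} at line {lineno}")
            entries[gene] = category
    return GenePanel(entries=entries)


def write_panel(panel: GenePanel, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("gene\tcategory\n")
        for gene, category in panel.entries.items():
            fh.write(f"{gene}\t{category}\n")


def read_phenotypes(path: str | Path) -> list[SampleRecord]:
    """Read the phenotype CSV (sample_id, group, onset_age, fsh; '' = missing)."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    records = []
    for r in df.itertuples():
        records.append(
            SampleRecord(
                sample_id=r.sample_id,
                group=r.group,
                onset_age=None if pd.isna(r.onset_age) else float(r.onset_age),
                fsh=None if pd.isna(r.fsh) else float(r.fsh),
            )
        )
    return records


def write_phenotypes(samples: Iterable[SampleRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "group", "onset_age", "fsh"])
        for s in samples:
            writer.writerow(
                [
                    s.sample_id,
                    s.group,
                    "" if s.onset_age is None else s.onset_age,
                    "" if s.fsh is None else s.fsh,
                ]
            )


def build_carrier_matrix(
    tuples: Iterable[tuple[str, VariantRecord]],
    samples: Sequence[SampleRecord],
    panel: GenePanel,
) -> CarrierMatrix:
    """Assemble the CarrierMatrix from qualified (sample, variant) tuples.

    ``carries[s, g]`` is set iff sample *s* has >=1 tuple in gene *g*;
    ``variant_count`` counts every tuple, so two variants in one gene add
    two to the count but one carried gene.
    """
    tuples = list(tuples)
    samples = list(samples)
    index = {s.sample_id: i for i, s in enumerate(samples)}
    genes = panel.genes
    gidx = {g: j for j, g in enumerate(genes)}
    carries = np.zeros((len(samples), len(genes)), dtype=bool)
    counts = np.zeros(len(samples), dtype=int)
    details: dict[tuple[str, str], list[VariantRecord]] = {}
    unknown = sorted({sid for sid, _ in tuples if sid not in index})
    if unknown:
        raise ValueError(f"variant tuples reference unknown samples: {unknown}")
    for sid, rec in tuples:
        i = index[sid]
        j = gidx[rec.gene]
        carries[i, j] = True
        counts[i] += 1
        details.setdefault((sid, rec.gene), []).append(rec)
    return CarrierMatrix(
        samples=samples, genes=genes, carries=carries,
        variant_count=counts, variant_details=details,
    )
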