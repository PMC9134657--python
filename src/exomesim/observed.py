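"""Per-patient, per-gene tallies of observed somatic mutation calls.

Mutations arrive as a MAF-dialect TSV (one record per called variant).
A record is counted toward a gene by its gene-symbol column — the public
per-patient mutation lists are taken as given, not re-intersected with the
reduced library — and every record counts once, SNVs and indels alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Variant_Type",
    "Tumor_Sample_Barcode",
)


@dataclass
class ObservedCohort:
    """Mutation counts per (gene, patient) with the patient roster."""

    patients: list[str] = field(default_factory=list)
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    n_records: int = 0
    n_skipped: int = 0

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def genes(self) -> list[str]:
        return sorted({g for g, _ in self.counts})

    def gene_patient_count(self, gene: str, patient: str) -> int:
        return self.counts.get((gene, patient), 0)


@dataclass
class ObservedGeneCounts:
    """Per-gene totals after the >=1-mutation inclusion filter."""

    totals: pd.Series  # index: gene symbol, values: O_g
    n_patients_mutated: pd.Series

    @property
    def genes(self) -> list[str]:
        return list(self.totals.index)


def parse_maf(path: str | Path, barcode_prefix: int | None = None) -> ObservedCohort:
    """Tally a MAF-dialect TSV into an :class:`ObservedCohort`.

    Tolerates extra columns and ``#`` comment lines. ``barcode_prefix``
    truncates sample barcodes to that many characters so aliquot-level
    TCGA barcodes collapse to patients; default keeps full barcodes.
    Records with a blank gene symbol are skipped (counted and logged).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required MAF column(s): {', '.join(missing)}")
    cohort = ObservedCohort()
    cohort.n_records = len(df)
    if len(df) == 0:
        return cohort
    barcodes = df["Tumor_Sample_Barcode"]
    if barcode_prefix is not None:
        barcodes = barcodes.str.slice(0, barcode_prefix)
    genes = df["Hugo_Symbol"].str.strip()
    blank = genes == ""
    cohort.n_skipped = int(blank.sum())
    if cohort.n_skipped:
        log.warning("%s: skipped %d records with blank gene symbol", path, cohort.n_skipped)
    kept = pd.DataFrame({"gene": genes[~blank], "patient": barcodes[~blank]})
    cohort.patients = sorted(barcodes.unique())
    for (g, p), n in kept.groupby(["gene", "patient"]).size().items():
        cohort.counts[(g, p)] = int(n)
    return cohort


def filter_observed(cohort: ObservedCohort,
                    library_genes: list[str] | None = None,
                    drop_missing_from_library: bool = True) -> ObservedGeneCounts:
    """Collapse a cohort to per-gene totals, keeping genes mutated >=1 time.

    When ``library_genes`` is given, genes absent from the exon library are
    dropped by default (a ratio needs an expected count); pass
    ``drop_missing_from_library=False`` to retain them.
    """
    per_gene: dict[str, int] = {}
    patients_mutated: dict[str, set[str]] = {}
    for (g, p), n in cohort.counts.items():
        per_gene[g] = per_gene.get(g, 0) + n
        patients_mutated.setdefault(g, set()).add(p)
    kept = {g: n for g, n in per_gene.items() if n >= 1}
    if library_genes is not None and drop_missing_from_library:
        lib = set(library_genes)
        missing = sorted(set(kept) - lib)
        if missing:
            log.info("dropping %d mutated genes absent from the library: %s",
                     len(missing), ",".join(missing[:20]) + ("..." if len(missing) > 20 else ""))
        kept = {g: n for g, n in kept.items() if g in lib}
    if not kept:
        raise ValueError("no genes with at least one observed mutation remain; "
                         "check gene symbols against the library")
    genes = sorted(kept)
    return ObservedGeneCounts(
        totals=pd.Series({g: kept[g] for g in genes}, name="O_g", dtype=int),
        n_patients_mutated=pd.Series(
            {g: len(patients_mutated[g]) for g in genes}, name="n_patients_mutated", dtype=int),
    )


def write_observed(counts: ObservedGeneCounts, path: str | Path) -> None:
    df = pd.DataFrame({"gene": counts.genes,
                       "O_g": counts.totals.values,
                       "n_patients_mutated": counts.n_patients_mutated.values})
    df.to_csv(path, sep="\t", index=False)


def read_observed(path: str | Path) -> ObservedGeneCounts:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    return ObservedGeneCounts(totals=df["O_g"], n_patients_mutated=df["n_patients_mutated"])
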