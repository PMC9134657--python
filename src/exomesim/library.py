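"""Reduced exon sequence library: gene models ∩ capture probes, with a
per-base mutation-category mask.

The library is the substrate of the mutagenesis simulation. Exome capture
interrogates only the bases covered by the probe design, so gene exons are
intersected with the probe intervals before any sequence is extracted.
Every retained base is then classified into one of four mutation-rate
categories:

* ``AT``    — adenine or thymine,
* ``CG``    — cytosine or guanine outside a CpG dinucleotide,
* ``CPG``   — either member of a CpG dinucleotide (elevated rate via
  deamination of methylated cytosine; the category is strand-symmetric),
* ``OTHER`` — ambiguity codes (N etc.), never mutated.

CpG context is resolved against the genome one base beyond interval ends:
mutation context is a property of the genome, not of probe boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils.iterators
import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .intervals import Interval, intersect, merge, total_length

log = logging.getLogger(__name__)

# mask codes
AT, CG, CPG, OTHER = 0, 1, 2, 3
CATEGORY_NAMES = ("AT", "CG", "CPG", "OTHER")
_MASK_LETTERS = np.array(list("ACPO"))
_LETTER_TO_CODE = {"A": AT, "C": CG, "P": CPG, "O": OTHER}


@dataclass
class GeneModelSet:
    """Exon records grouped by gene symbol; 0-based half-open coordinates."""

    exons: dict[str, list[tuple[str, int, int, str]]] = field(default_factory=dict)

    def add(self, gene: str, chrom: str, start: int, end: int, strand: str = "+") -> None:
        if start >= end:
            raise ValueError(f"{gene}: empty or inverted exon ({start}, {end})")
        self.exons.setdefault(gene, []).append((chrom, start, end, strand))

    @property
    def genes(self) -> list[str]:
        return sorted(self.exons)

    def merged_intervals(self, gene: str) -> dict[str, list[Interval]]:
        """Union of the gene's exons per chromosome (transcript overlaps collapsed)."""
        per_chrom: dict[str, list[Interval]] = {}
        for chrom, s, e, _ in self.exons[gene]:
            per_chrom.setdefault(chrom, []).append((s, e))
        return {c: merge(ivs) for c, ivs in per_chrom.items()}


@dataclass
class ProbeSet:
    """Capture-probe intervals per chromosome (0-based half-open)."""

    intervals: dict[str, list[Interval]] = field(default_factory=dict)

    def merged(self) -> dict[str, list[Interval]]:
        return {c: merge(ivs) for c, ivs in self.intervals.items()}


@dataclass
class GeneEntry:
    gene: str
    chrom: str
    intervals: list[Interval]
    sequence: str = ""
    mask: np.ndarray | None = None  # uint8 codes, one per base

    @property
    def length(self) -> int:
        return total_length(self.intervals)

    def category_counts(self) -> np.ndarray:
        """Counts over (AT, CG, CPG, OTHER); sums to length."""
        if self.mask is None:
            raise ValueError(f"{self.gene}: mask not populated")
        return np.bincount(self.mask, minlength=4)[:4]


@dataclass
class ExonLibrary:
    """Per-gene probe-intersected intervals, sequence and category mask.

    Bases shared by two genes are stored once per gene: per-gene tallies are
    aggregated by gene symbol with no cross-gene deduplication, mirroring
    how per-gene mutation counts are accumulated downstream.
    """

    entries: dict[str, GeneEntry] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return sorted(self.entries)

    @property
    def total_bases(self) -> int:
        return sum(e.length for e in self.entries.values())

    def category_matrix(self) -> pd.DataFrame:
        """Genes × (AT, CG, CPG, OTHER) base counts, rows sorted by gene."""
        rows = {g: self.entries[g].category_counts() for g in self.genes}
        return pd.DataFrame.from_dict(rows, orient="index", columns=CATEGORY_NAMES)

    # ------------------------------------------------------------------ io
    def save(self, libdir: str | Path) -> None:
        libdir = Path(libdir)
        libdir.mkdir(parents=True, exist_ok=True)
        rows = []
        with open(libdir / "library.fa", "w") as fa, open(libdir / "masks.tsv", "w") as mf:
            mf.write("gene\tmask\n")
            for g in self.genes:
                e = self.entries[g]
                counts = e.category_counts()
                rows.append(
                    {
                        "gene": g,
                        "chromosome": e.chrom,
                        "intervals": ",".join(f"{s}-{t}" for s, t in e.intervals),
                        "length": e.length,
                        **{f"n_{n}": int(c) for n, c in zip(CATEGORY_NAMES, counts)},
                    }
                )
                fa.write(f">{g}\n{e.sequence}\n")
                mf.write(f"{g}\t{''.join(_MASK_LETTERS[e.mask])}\n")
        pd.DataFrame(rows).to_csv(libdir / "manifest.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, libdir: str | Path) -> "ExonLibrary":
        libdir = Path(libdir)
        manifest = pd.read_csv(libdir / "manifest.tsv", sep="\t")
        seqs = {name: seq for name, seq in _iter_fasta(libdir / "library.fa")}
        masks = pd.read_csv(libdir / "masks.tsv", sep="\t", index_col="gene")["mask"]
        lib = cls()
        for _, row in manifest.iterrows():
            ivs = [tuple(map(int, p.split("-"))) for p in str(row["intervals"]).split(",")]
            mask = np.array([_LETTER_TO_CODE[c] for c in masks[row["gene"]]], dtype=np.uint8)
            lib.entries[row["gene"]] = GeneEntry(
                gene=row["gene"], chrom=row["chromosome"], intervals=ivs,
                sequence=seqs[row["gene"]], mask=mask,
            )
        return lib


def _iter_fasta(path: Path):
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        yield name, "".join(chunks)


# ---------------------------------------------------------------- loaders
def load_gene_models(path: str | Path, fmt: str | None = None) -> GeneModelSet:
    """Read gene models from a GTF or BED12 file into 0-based half-open exons.

    ``fmt`` is inferred from the extension when not given. GTF coordinates
    (1-based closed) are converted on read; BED12 is consumed natively.
    Records without a gene symbol are skipped with a logged warning.
    """
    path = Path(path)
    if fmt is None:
        fmt = "bed12" if path.suffix.lower() in (".bed", ".bed12") else "gtf"
    if fmt == "gtf":
        return _load_gtf(path)
    if fmt == "bed12":
        return _load_bed12(path)
    raise ValueError(f"unknown gene-model format {fmt!r}")


def _load_gtf(path: Path) -> GeneModelSet:
    models = GeneModelSet()
    skipped = 0
    for feat in gffutils.iterators.DataIterator(str(path)):
        if feat.featuretype != "exon":
            continue
        attrs = feat.attributes
        symbol = (attrs.get("gene_name") or attrs.get("gene_id") or [None])[0]
        if not symbol:
            skipped += 1
            continue
        # GTF is 1-based closed: [start, end] -> [start-1, end)
        models.add(symbol, feat.seqid, feat.start - 1, feat.end, feat.strand or "+")
    if skipped:
        log.warning("%s: skipped %d exon records without a gene symbol", path, skipped)
    return models


def _load_bed12(path: Path) -> GeneModelSet:
    models = GeneModelSet()
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED fields, got {len(f)}")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            if not name:
                skipped += 1
                continue
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != len(starts):
                raise ValueError(f"{path}:{lineno}: blockSizes/blockStarts length mismatch")
            for sz, st in zip(sizes, starts):
                models.add(name, chrom, start + st, start + st + sz, strand)
    if skipped:
        log.warning("%s: skipped %d records without a name", path, skipped)
    return models


def load_probes(path: str | Path) -> ProbeSet:
    """Read a BED3(+) probe file; extra columns ignored."""
    probes = ProbeSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED fields")
            probes.intervals.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    return probes


# ------------------------------------------------------------- operations
def intersect_with_probes(models: GeneModelSet, probes: ProbeSet) -> ExonLibrary:
    """Restrict merged per-gene exons to the probe-covered base set.

    Genes with zero probe overlap are dropped (logged). Chromosomes present
    in the models but absent from the probe set contribute zero overlap,
    logged once per chromosome.
    """
    merged_probes = probes.merged()
    lib = ExonLibrary()
    dropped: list[str] = []
    missing_chroms: set[str] = set()
    for gene in models.genes:
        pieces: dict[str, list[Interval]] = {}
        for chrom, ivs in models.merged_intervals(gene).items():
            if chrom not in merged_probes:
                missing_chroms.add(chrom)
                continue
            hit = intersect(ivs, merged_probes[chrom])
            if hit:
                pieces[chrom] = hit
        if not pieces:
            dropped.append(gene)
            continue
        if len(pieces) > 1:
            # keep the chromosome carrying most overlap; cross-chromosome
            # symbols are a annotation artefact at this stage
            chrom = max(pieces, key=lambda c: total_length(pieces[c]))
            log.warning("%s: exons on multiple chromosomes, keeping %s", gene, chrom)
        else:
            chrom = next(iter(pieces))
        lib.entries[gene] = GeneEntry(gene=gene, chrom=chrom, intervals=pieces[chrom])
    for chrom in sorted(missing_chroms):
        log.warning("chromosome %s absent from probe set; genes there get zero overlap", chrom)
    if dropped:
        log.info("dropped %d genes with no probe overlap: %s", len(dropped),
                 ",".join(dropped[:20]) + ("..." if len(dropped) > 20 else ""))
    return lib


def classify_bases(lib: ExonLibrary, genome: Fasta | Mapping[str, str]) -> ExonLibrary:
    """Extract sequences and fill the per-base category mask, in place.

    A cytosine immediately followed by guanine in the *genome* (or a guanine
    immediately preceded by cytosine) is CPG, even when the partner base
    falls outside the interval. At a chromosome edge the missing context
    base is treated as non-C/non-G.
    """
    for gene in lib.genes:
        entry = lib.entries[gene]
        seq_parts: list[str] = []
        mask_parts: list[np.ndarray] = []
        chrom_len = _chrom_length(genome, entry.chrom)
        for s, e in entry.intervals:
            ctx_s, ctx_e = max(s - 1, 0), min(e + 1, chrom_len)
            window = _fetch(genome, entry.chrom, ctx_s, ctx_e).upper()
            off = s - ctx_s  # 1 when a left-context base exists, else 0
            bases = window[off : off + (e - s)]
            mask_parts.append(_classify_window(window, off, e - s))
            seq_parts.append(bases)
        entry.sequence = "".join(seq_parts)
        entry.mask = np.concatenate(mask_parts) if mask_parts else np.zeros(0, np.uint8)
        if len(entry.sequence) != entry.length:
            raise ValueError(
                f"{gene}: extracted {len(entry.sequence)} bases for "
                f"{entry.length}-base intervals; genome/annotation mismatch")
    return lib


def _classify_window(window: str, off: int, n: int) -> np.ndarray:
    arr = np.frombuffer(window.encode(), dtype="S1")
    mask = np.full(len(arr), OTHER, dtype=np.uint8)
    mask[np.isin(arr, [b"A", b"T"])] = AT
    is_c, is_g = arr == b"C", arr == b"G"
    mask[is_c | is_g] = CG
    cpg_c = is_c.copy()
    cpg_c[:-1] &= is_g[1:]
    cpg_c[-1] = False  # no right context in window -> non-G
    cpg_g = is_g.copy()
    cpg_g[1:] &= is_c[:-1]
    cpg_g[0] = False
    mask[cpg_c | cpg_g] = CPG
    return mask[off : off + n]


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    if isinstance(genome, Fasta):
        return str(genome[chrom][start:end])
    return genome[chrom][start:end]


def _chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])


def build_library(genome_path: str | Path, genes_path: str | Path,
                  probes_path: str | Path, fmt: str | None = None) -> ExonLibrary:
    """End-to-end: gene models ∩ probes, sequences extracted, mask filled."""
    models = load_gene_models(genes_path, fmt=fmt)
    probes = load_probes(probes_path)
    lib = intersect_with_probes(models, probes)
    with Fasta(str(genome_path)) as genome:
        classify_bases(lib, genome)
    return lib
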