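"""Shared fixtures: tiny in-memory libraries and generated toy datasets."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from exomesim.library import AT, CG, CPG, OTHER, ExonLibrary, GeneEntry

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

_CODE = {"A": AT, "C": CG, "P": CPG, "O": OTHER}
_SEQ_FOR = {AT: "A", CG: "C", CPG: "C", OTHER: "N"}


def make_entry(gene: str, mask_letters: str, chrom: str = "chrT",
               start: int = 0) -> GeneEntry:
    """GeneEntry from a mask string ('A'=A/T, 'C'=non-CpG C/G, 'P'=CpG, 'O'=N)."""
    mask = np.array([_CODE[c] for c in mask_letters], dtype=np.uint8)
    seq = "".join(_SEQ_FOR[c] for c in mask)
    return GeneEntry(gene=gene, chrom=chrom,
                     intervals=[(start, start + len(mask))],
                     sequence=seq, mask=mask)


def make_library(spec: dict[str, tuple[int, int, int]]) -> ExonLibrary:
    """Library from {gene: (n_AT, n_CG, n_CPG)} category counts."""
    lib = ExonLibrary()
    pos = 0
    for gene, (n_at, n_cg, n_cpg) in spec.items():
        letters = "A" * n_at + "C" * n_cg + "P" * n_cpg
        lib.entries[gene] = make_entry(gene, letters, start=pos)
        pos += len(letters) + 10
    return lib


@pytest.fixture(scope="session")
def toy_dataset(tmp_path_factory):
    """A small generated genome + library shared across tests (read-only)."""
    from exomesim import build_library, generate_genome

    d = tmp_path_factory.mktemp("toy")
    files = generate_genome(d, n_genes=30, exons_per_gene=2,
                            exon_length_range=(80, 160), gc_fraction=0.4,
                            cpg_enrichment=2.0, seed=11)
    lib = build_library(files.fasta, files.gtf, files.probes)
    return files, lib
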