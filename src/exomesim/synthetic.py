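"""Synthetic genomes, cohorts and omics matrices with planted structure.

Everything the pipeline consumes can be generated here with known ground
truth: a toy chromosome with controlled base composition and CpG content,
gene models and capture probes over it, per-patient somatic mutation calls
drawn at category-specific rates modulated by per-gene selection factors,
and omics matrices in which designated gene sets carry planted shifts
(higher expression, lower methylation, higher copy number for negatively
selected genes — the configuration the real cohort analysis reports).

Selection is modelled as a rate multiplier s_g: a gene with s_g < 1 is
under negative selection (mutations depleted), s_g > 1 positive, s_g = 1
neutral. The cohort generator flips every base with an explicit Bernoulli
draw and deliberately shares no sampling code with
:mod:`exomesim.simulate`, so agreement between the two is a genuine
cross-module calibration check, not a tautology.

Base composition uses a first-order Markov chain whose stationary
distribution equals the requested marginal (gc_fraction split equally
between C and G) while the C→G transition is inflated so the expected CpG
dinucleotide frequency is exactly ``cpg_enrichment * (gc/2)**2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .library import ExonLibrary
from .simulate import EffectiveRates

log = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))
_A, _C, _G, _T = 0, 1, 2, 3


@dataclass
class SyntheticTruth:
    """Planted ground truth written alongside every generated dataset."""

    selection: pd.Series  # gene -> s_g
    nonmutated_set: list[str] = field(default_factory=list)
    mutated_set: list[str] = field(default_factory=list)
    expression_delta: float = 0.0
    methylation_delta: float = 0.0
    copy_number_delta: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if (self.selection < 0).any():
            raise ValueError("selection factors must be non-negative")

    def save(self, path: str | Path) -> None:
        df = pd.DataFrame({"gene": self.selection.index, "s_g": self.selection.values})
        df["in_nonmutated_set"] = df["gene"].isin(self.nonmutated_set)
        df["in_mutated_set"] = df["gene"].isin(self.mutated_set)
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed} expression_delta={self.expression_delta} "
                     f"methylation_delta={self.methylation_delta} "
                     f"copy_number_delta={self.copy_number_delta}\n")
            df.to_csv(fh, sep="\t", index=False)


# ------------------------------------------------------------------ genome
def _transition_matrix(gc_fraction: float, cpg_enrichment: float) -> np.ndarray:
    """Markov transitions with stationary marginal p and P(CpG) = rho*pC*pG."""
    if gc_fraction == 0.0:  # degenerate A/T-only chain
        M = np.zeros((4, 4))
        M[:, _A] = M[:, _T] = 0.5
        return M
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must lie in [0, 1)")
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    rho, pC, pG = cpg_enrichment, p[_C], p[_G]
    if rho * pG > 1 or rho * pC > 1:
        raise ValueError(f"cpg_enrichment={rho} infeasible at gc_fraction={gc_fraction}")
    M = np.empty((4, 4))
    for b in range(4):
        g_prob = rho * pG if b == _C else pG * (1 - rho * pC) / (1 - pC)
        M[b, _G] = g_prob
        for x in (_A, _C, _T):
            M[b, x] = p[x] * (1 - g_prob) / (1 - pG)
    return M


def expected_cpg_frequency(gc_fraction: float, cpg_enrichment: float) -> float:
    """Closed-form expected CpG dinucleotide frequency of the chain."""
    return cpg_enrichment * (gc_fraction / 2) ** 2


def _sample_chain(n: int, M: np.ndarray, p0: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    from bisect import bisect_right

    cum = [list(M[b].cumsum()) for b in range(4)]
    u = rng.random(n).tolist()
    seq = np.empty(n, dtype=np.int8)
    prev = bisect_right(list(p0.cumsum()), u[0])
    seq[0] = prev
    for i in range(1, n):
        prev = bisect_right(cum[prev], u[i])
        seq[i] = prev
    return seq


@dataclass
class GenomeFiles:
    fasta: Path
    gtf: Path
    probes: Path
    chrom: str
    gene_exons: dict[str, list[tuple[int, int]]]  # 0-based half-open


def generate_genome(outdir: str | Path, n_genes: int = 1000,
                    exons_per_gene: int = 2,
                    exon_length_range: tuple[int, int] = (300, 700),
                    gc_fraction: float = 0.4, cpg_enrichment: float = 2.0,
                    probe_fraction: float = 1.0, intron_length: int = 50,
                    intergenic_length: int = 100, chrom: str = "chrS",
                    chrom_length: int | None = None, seed: int = 0) -> GenomeFiles:
    """Write a toy chromosome (FASTA), gene models (GTF) and probes (BED).

    Genes are laid out non-overlapping left to right; probes tile
    ``probe_fraction`` of each exon from its 5' end. When ``chrom_length``
    is given and the layout does not fit, packing fails with an error.
    """
    if n_genes < 1 or exons_per_gene < 1:
        raise ValueError("n_genes and exons_per_gene must be positive")
    lo, hi = exon_length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"bad exon_length_range {exon_length_range}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    gene_exons: dict[str, list[tuple[int, int]]] = {}
    pos = intergenic_length
    width = len(str(n_genes))
    for i in range(n_genes):
        name = f"GENE{i + 1:0{width}d}"
        exons = []
        for j in range(exons_per_gene):
            L = int(rng.integers(lo, hi + 1))
            exons.append((pos, pos + L))
            pos += L + (intron_length if j < exons_per_gene - 1 else 0)
        gene_exons[name] = exons
        pos += intergenic_length
    total_len = pos
    if chrom_length is not None:
        if chrom_length < total_len:
            raise ValueError(f"genes need {total_len} bases but chrom_length={chrom_length}")
        total_len = chrom_length

    M = _transition_matrix(gc_fraction, cpg_enrichment)
    p0 = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                   gc_fraction / 2, (1 - gc_fraction) / 2])
    seq = BASES[_sample_chain(total_len, M, p0, rng)]

    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{chrom}\n")
        s = "".join(seq)
        for k in range(0, len(s), 80):
            fh.write(s[k:k + 80] + "\n")

    gtf = outdir / "genes.gtf"
    with open(gtf, "w") as fh:
        for name, exons in gene_exons.items():
            for s0, e0 in exons:
                fh.write(f"{chrom}\texomesim\texon\t{s0 + 1}\t{e0}\t.\t+\t.\t"
                         f'gene_id "{name}"; gene_name "{name}"; '
                         f'transcript_id "{name}.t1";\n')

    probes = outdir / "probes.bed"
    with open(probes, "w") as fh:
        for name, exons in gene_exons.items():
            for s0, e0 in exons:
                cover = max(1, int(round((e0 - s0) * probe_fraction)))
                fh.write(f"{chrom}\t{s0}\t{s0 + cover}\n")

    log.info("generated %d genes over a %d-base chromosome", n_genes, total_len)
    return GenomeFiles(fasta=fasta, gtf=gtf, probes=probes, chrom=chrom,
                       gene_exons=gene_exons)


# ------------------------------------------------------------------ cohort
def generate_cohort(library: ExonLibrary, rates: EffectiveRates,
                    truth: SyntheticTruth, n_patients: int,
                    out_maf: str | Path, seed: int = 0) -> dict[str, int]:
    """Draw per-patient mutation calls and write them as a MAF-dialect TSV.

    Each base of gene g mutates with probability ``s_g * eff_rate(category)``
    via an explicit per-base uniform draw (independent of the simulator's
    binomial shortcut). Returns the truth ledger of per-gene emitted counts;
    the MAF holds genuine coordinates, alleles and sample barcodes.
    """
    genes = library.genes
    p_cat = rates.as_array()
    # concatenated per-base arrays across genes (sorted gene order)
    gene_idx_parts, pos_parts, pbase_parts, ref_parts = [], [], [], []
    for gi, g in enumerate(genes):
        e = library.entries[g]
        if e.mask is None:
            raise ValueError(f"{g}: library mask not populated")
        s_g = float(truth.selection.get(g, 1.0))
        pb = np.zeros(e.mask.size)
        mutable = e.mask < 3
        pb[mutable] = np.minimum(1.0, s_g * p_cat[e.mask[mutable]])
        pbase_parts.append(pb)
        gene_idx_parts.append(np.full(e.mask.size, gi, dtype=np.int32))
        pos = np.concatenate([np.arange(s0, e0) for s0, e0 in e.intervals])
        pos_parts.append(pos)
        ref_parts.append(np.frombuffer(e.sequence.upper().encode(), dtype="S1"))
    p_base = np.concatenate(pbase_parts)
    gene_idx = np.concatenate(gene_idx_parts)
    genome_pos = np.concatenate(pos_parts)
    ref = np.concatenate(ref_parts)
    chroms = np.array([library.entries[g].chrom for g in genes])

    rng_root = np.random.SeedSequence(entropy=seed, spawn_key=(1,))
    ledger: dict[str, int] = {g: 0 for g in genes}
    rows: list[tuple] = []
    n_width = len(str(max(n_patients, 1)))
    alt_choices = {b"A": "CGT", b"C": "AGT", b"G": "ACT", b"T": "ACG", b"N": "ACGT"}
    for pidx in range(n_patients):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(1, pidx)))
        hits = np.nonzero(rng.random(p_base.size) < p_base)[0]
        barcode = f"SYN-{pidx + 1:0{n_width}d}"
        for h in hits:
            g = genes[gene_idx[h]]
            r = ref[h].tobytes()
            alt = alt_choices.get(r, "ACGT")[int(rng.integers(0, 3))]
            rows.append((g, chroms[gene_idx[h]], int(genome_pos[h]) + 1,
                         int(genome_pos[h]) + 1, r.decode(), alt, "SNP", barcode))
            ledger[g] += 1
    df = pd.DataFrame(rows, columns=["Hugo_Symbol", "Chromosome", "Start_Position",
                                     "End_Position", "Reference_Allele",
                                     "Tumor_Seq_Allele2", "Variant_Type",
                                     "Tumor_Sample_Barcode"])
    out_maf = Path(out_maf)
    out_maf.parent.mkdir(parents=True, exist_ok=True)
    with open(out_maf, "w") as fh:
        fh.write("#version exomesim-synthetic\n")
        df.to_csv(fh, sep="\t", index=False)
    ledger["__n_records__"] = len(df)
    return ledger


# ------------------------------------------------------------------- omics
@dataclass
class OmicsParams:
    expression_mean: float = 8.0  # log2-scale RMA-like baseline
    expression_sd: float = 1.0
    methylation_mean: float = 0.5
    methylation_concentration: float = 10.0
    copy_number_center: float = 2.0
    copy_number_sd: float = 0.6
    sites_per_gene: tuple[int, int] = (1, 3)


def generate_omics(genes: list[str], nonmutated_set: list[str],
                   mutated_set: list[str], outdir: str | Path,
                   n_samples: int = 300,
                   params: OmicsParams | None = None,
                   expression_delta: float = 1.0,
                   methylation_delta: float = -0.2,
                   copy_number_delta: float = 0.5,
                   kinds: tuple[str, ...] = ("expression", "methylation",
                                             "copy_number"),
                   seed: int = 0) -> dict[str, Path]:
    """Write expression / methylation / copy-number TSVs with planted shifts.

    Deltas apply to the non-mutated set relative to everything else
    (positive expression and copy-number deltas, negative methylation delta
    reproduce the directions the cohort analysis reports). Expression is
    Normal(base + delta, sd); methylation beta is Beta-distributed with a
    set-shifted mean; copy number is an integer distribution centred at 2
    with set-shifted mass.
    """
    if set(nonmutated_set) & set(mutated_set):
        raise ValueError("nonmutated and mutated sets must be disjoint")
    params = params or OmicsParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nonmut = set(nonmutated_set)
    samples = [f"SYN-{i + 1:0{len(str(n_samples))}d}" for i in range(n_samples)]

    def delta_for(g: str, d: float) -> float:
        return d if g in nonmut else 0.0

    # one substream per kind, so a kind's output is identical whether or
    # not the other kinds were requested
    def kind_rng(j: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(2, j)))

    paths: dict[str, Path] = {}
    if "expression" in kinds:
        rng = kind_rng(0)
        expr_mu = np.array([params.expression_mean + delta_for(g, expression_delta)
                            for g in genes])
        expr = pd.DataFrame(
            rng.normal(expr_mu[:, None], params.expression_sd,
                       size=(len(genes), n_samples)),
            index=pd.Index(genes, name="gene"), columns=samples)
        paths["expression"] = outdir / "expression.tsv"
        expr.to_csv(paths["expression"], sep="\t")

    if "methylation" in kinds:
        rng = kind_rng(1)
        site_rows, meth_rows, meth_index = [], [], []
        kappa = params.methylation_concentration
        site_counter = 0
        for g in genes:
            m = float(np.clip(params.methylation_mean + delta_for(g, methylation_delta),
                              0.02, 0.98))
            for _ in range(int(rng.integers(params.sites_per_gene[0],
                                            params.sites_per_gene[1] + 1))):
                site_counter += 1
                sid = f"cg{site_counter:07d}"
                site_rows.append((sid, g))
                meth_index.append(sid)
                meth_rows.append(rng.beta(m * kappa, (1 - m) * kappa, size=n_samples))
        meth = pd.DataFrame(np.vstack(meth_rows),
                            index=pd.Index(meth_index, name="site"), columns=samples)
        paths["methylation"] = outdir / "methylation.tsv"
        meth.to_csv(paths["methylation"], sep="\t")
        paths["site_map"] = outdir / "methylation_sites.tsv"
        pd.DataFrame(site_rows, columns=["site", "gene"]).to_csv(
            paths["site_map"], sep="\t", index=False)

    if "copy_number" in kinds:
        rng = kind_rng(2)
        cn_mu = np.array([params.copy_number_center + delta_for(g, copy_number_delta)
                          for g in genes])
        cn_draws = np.clip(np.rint(rng.normal(cn_mu[:, None], params.copy_number_sd,
                                              size=(len(genes), n_samples))), 0, 8)
        cn = pd.DataFrame(cn_draws, index=pd.Index(genes, name="gene"),
                          columns=samples)
        paths["copy_number"] = outdir / "copy_number.tsv"
        cn.to_csv(paths["copy_number"], sep="\t")

    return paths


# ---------------------------------------------------------------- presets
def benchmark_truth(genes: list[str], n_low: int = 20, n_high: int = 20,
                    s_low: float = 0.1, s_high: float = 10.0,
                    seed: int = 0) -> SyntheticTruth:
    """Planted-selection benchmark: n_low genes at s_low, n_high at s_high."""
    if n_low + n_high > len(genes):
        raise ValueError("more planted genes than genes available")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,)))
    chosen = rng.choice(len(genes), size=n_low + n_high, replace=False)
    s = pd.Series(1.0, index=genes)
    low = [genes[i] for i in chosen[:n_low]]
    high = [genes[i] for i in chosen[n_low:]]
    s.loc[low] = s_low
    s.loc[high] = s_high
    return SyntheticTruth(selection=s, nonmutated_set=sorted(low),
                          mutated_set=sorted(high), seed=seed)
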