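"""Distribution comparison of omics values between gene sets.

Expression (RMA or RPKM), methylation beta values and gene-level copy
number are consumed as plain genes-or-sites × samples TSV matrices. For a
gene set, every individual (gene, sample[, site]) value is pooled into one
flat vector — distributions are compared over raw values, not per-gene
summaries — and two pooled vectors are compared with the two-sample
Kolmogorov–Smirnov test. Pooled values are treated as independent
observations; the within-gene correlation this ignores is a known caveat
(see docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .observed import ObservedCohort

log = logging.getLogger(__name__)

MATRIX_KINDS = ("expression_RMA", "expression_RPKM", "methylation_beta", "copy_number")


@dataclass
class OmicsMatrix:
    """A genes-or-sites × samples value table.

    For methylation the rows are sites and ``site_to_gene`` maps many sites
    to one gene; otherwise rows are genes and the map is the identity.
    """

    kind: str
    values: pd.DataFrame
    site_to_gene: pd.Series | None = None

    def __post_init__(self):
        if self.kind not in MATRIX_KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if self.kind == "methylation_beta":
            v = self.values.values
            finite = v[np.isfinite(v)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("methylation beta values must lie in [0, 1]")

    def rows_for_gene(self, gene: str) -> pd.DataFrame:
        if self.site_to_gene is None:
            return self.values.loc[[gene]] if gene in self.values.index else self.values.iloc[0:0]
        sites = self.site_to_gene.index[self.site_to_gene == gene]
        return self.values.loc[self.values.index.intersection(sites)]

    @classmethod
    def read(cls, path: str | Path, kind: str,
             site_map_path: str | Path | None = None) -> "OmicsMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        site_to_gene = None
        if site_map_path is not None:
            m = pd.read_csv(site_map_path, sep="\t")
            site_to_gene = pd.Series(m.iloc[:, 1].values, index=m.iloc[:, 0].values)
        return cls(kind=kind, values=values, site_to_gene=site_to_gene)


@dataclass
class KSResult:
    D: float
    p_value: float
    n_x: int
    n_y: int


def pool_gene_set(matrix: OmicsMatrix, genes: Sequence[str],
                  average_sites: bool = False) -> np.ndarray:
    """Flatten all (gene, sample[, site]) values for matched genes.

    Missing cells are dropped. For methylation every site of a gene
    contributes its raw values; ``average_sites=True`` averages sites per
    gene and sample first. Partial matches are normal (the matched count is
    logged); zero matches is an error listing the unmatched symbols.
    """
    pieces, matched = [], 0
    for g in genes:
        rows = matrix.rows_for_gene(g)
        if rows.empty:
            continue
        matched += 1
        block = rows.mean(axis=0).to_frame().T if average_sites else rows
        pieces.append(block.values.ravel())
    if matched == 0:
        raise ValueError(f"no genes of the set matched matrix rows; set: {list(genes)}")
    log.info("pooled %d/%d genes of the set", matched, len(genes))
    pooled = np.concatenate(pieces)
    return pooled[np.isfinite(pooled)]


def ks_two_sample(x: np.ndarray, y: np.ndarray, method: str = "auto") -> KSResult:
    """Two-sample Kolmogorov–Smirnov test on pooled value vectors.

    D is the maximum absolute ECDF difference; the p-value is asymptotic
    for the large pooled samples this pipeline produces, exact for small
    ones (``method='auto'``, scipy semantics).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test requires non-empty samples")
    res = stats.ks_2samp(x, y, method=method)
    return KSResult(D=float(res.statistic), p_value=float(res.pvalue),
                    n_x=x.size, n_y=y.size)


@dataclass
class SetComparison:
    ks: KSResult
    direction: str  # 'nonmutated higher' | 'mutated higher' | 'none'
    median_nonmutated: float
    median_mutated: float
    ecdf: pd.DataFrame  # serialized cumulative-density curves


def compare_sets(matrix: OmicsMatrix, nonmutated: Sequence[str],
                 mutated: Sequence[str], average_sites: bool = False) -> SetComparison:
    """KS comparison of the two pooled distributions plus shift direction."""
    x = pool_gene_set(matrix, nonmutated, average_sites=average_sites)
    y = pool_gene_set(matrix, mutated, average_sites=average_sites)
    ks = ks_two_sample(x, y)
    mx, my = float(np.median(x)), float(np.median(y))
    # medians decide the shift direction; on discrete data (copy number)
    # medians often tie, so means break the tie
    ax, ay = (mx, my) if mx != my else (float(np.mean(x)), float(np.mean(y)))
    if ax > ay:
        direction = "nonmutated higher"
    elif ay > ax:
        direction = "mutated higher"
    else:
        direction = "none"
    grid = np.unique(np.concatenate([x, y]))
    ecdf = pd.DataFrame({
        "value": grid,
        "cdf_nonmutated": np.searchsorted(np.sort(x), grid, side="right") / x.size,
        "cdf_mutated": np.searchsorted(np.sort(y), grid, side="right") / y.size,
    })
    return SetComparison(ks=ks, direction=direction,
                         median_nonmutated=mx, median_mutated=my, ecdf=ecdf)


@dataclass
class StatusSplit:
    gene: str
    mutated_values: np.ndarray
    nonmutated_values: np.ndarray
    ks: KSResult | None  # None when underpowered
    underpowered: bool


def expression_by_mutation_status(matrix: OmicsMatrix, cohort: ObservedCohort,
                                  gene: str, barcode_prefix: int | None = None
                                  ) -> StatusSplit:
    """Split one gene's per-sample expression by that gene's mutation status.

    Samples are matched to matrix columns by an optional barcode prefix.
    With fewer than two samples in either stratum the split is flagged
    underpowered and no test is run.
    """
    rows = matrix.rows_for_gene(gene)
    if rows.empty:
        raise KeyError(f"gene {gene!r} not present in the matrix")
    expr = rows.mean(axis=0)  # one value per sample

    def key(s: str) -> str:
        return s[:barcode_prefix] if barcode_prefix else s

    mutated_patients = {key(p) for (g, p), n in cohort.counts.items()
                        if g == gene and n > 0}
    is_mut = np.array([key(c) in mutated_patients for c in expr.index])
    mut_vals = expr.values[is_mut].astype(float)
    non_vals = expr.values[~is_mut].astype(float)
    mut_vals, non_vals = mut_vals[np.isfinite(mut_vals)], non_vals[np.isfinite(non_vals)]
    if min(mut_vals.size, non_vals.size) < 2:
        return StatusSplit(gene, mut_vals, non_vals, ks=None, underpowered=True)
    return StatusSplit(gene, mut_vals, non_vals,
                       ks=ks_two_sample(mut_vals, non_vals), underpowered=False)


def rpkm(counts: pd.DataFrame, gene_lengths: pd.Series) -> OmicsMatrix:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM_{g,s} = count_{g,s} / ((length_g / 1e3) * (total_s / 1e6)).
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()][:10])
        raise ValueError(f"missing gene lengths for {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0][:10])
        raise ValueError(f"zero library size for sample(s) {bad}")
    values = counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)
    return OmicsMatrix(kind="expression_RPKM", values=values)


def write_comparison(cmp: SetComparison, outdir: str | Path, label: str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{
        "comparison": label, "D": cmp.ks.D, "p_value": cmp.ks.p_value,
        "n_nonmutated": cmp.ks.n_x, "n_mutated": cmp.ks.n_y,
        "median_nonmutated": cmp.median_nonmutated,
        "median_mutated": cmp.median_mutated, "direction": cmp.direction,
    }]).to_csv(outdir / f"{label}_ks.tsv", sep="\t", index=False)
    cmp.ecdf.to_csv(outdir / f"{label}_ecdf.tsv", sep="\t", index=False)
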