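"""Benchmark studies on synthetic data with planted ground truth.

These functions define the package's standard evaluation conditions:

* the study-design run count (316 patients × 100 replicates),
* simulator calibration against the analytic expectation,
* equivalence of binomial-shortcut and per-base Bernoulli sampling,
* recovery of planted negative/positive selection by ratio ranking,
* power and null calibration of the pooled KS comparison, and
* qualitative shift directions on planted omics matrices.

Each takes an integer seed and returns plain dicts/DataFrames, so the
analysis scripts, the test suite and the acceptance script all run the
same computations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .library import ExonLibrary, build_library
from .observed import filter_observed, parse_maf
from .omics import OmicsMatrix, SetComparison, compare_sets
from .ranking import compute_ratios, select_tails
from .simulate import (BMRConfig, EffectiveRates, SimulationConfig,
                       fold_indel_rate, simulate_patient, simulate_replicates)
from .synthetic import SyntheticTruth, benchmark_truth, generate_cohort, generate_genome, generate_omics


def _subseed(seed: int, *key: int) -> int:
    """Derived seed below 2**31, stable in (seed, key)."""
    return int(np.random.SeedSequence(entropy=seed, spawn_key=key)
               .generate_state(1)[0] % (2 ** 31))


def _tiny_library(n_genes: int, bases_per_gene: tuple[int, int, int],
                  ) -> ExonLibrary:
    """In-memory library of identical genes with fixed category counts."""
    from .library import GeneEntry
    n_at, n_cg, n_cpg = bases_per_gene
    lib = ExonLibrary()
    width = len(str(n_genes))
    pos = 0
    mask = np.array([0] * n_at + [1] * n_cg + [2] * n_cpg, dtype=np.uint8)
    seq = "A" * n_at + "C" * (n_cg + n_cpg)
    n = mask.size
    for i in range(n_genes):
        g = f"GENE{i + 1:0{width}d}"
        lib.entries[g] = GeneEntry(gene=g, chrom="chrT",
                                   intervals=[(pos, pos + n)],
                                   sequence=seq, mask=mask.copy())
        pos += n + 10
    return lib


# ------------------------------------------------------- study run count
def study_design_run_count(seed: int, n_genes: int = 20) -> dict:
    """Execute the full study design (316 × 100) on a small library and
    report the number of patient-level simulation runs actually executed."""
    lib = _tiny_library(n_genes, (15, 7, 3))
    rates = fold_indel_rate(BMRConfig.tcga_ov().scaled(1000))
    sim = simulate_replicates(lib, rates, SimulationConfig(316, 100, seed))
    return {"total_runs": sim.total_runs, "n_genes": n_genes,
            "n_patients": 316, "n_replicates": 100}


# ----------------------------------------------------------- calibration
def calibration_study(seed: int, n_genes: int = 200,
                      n_patients: int = 316, n_replicates: int = 100
                      ) -> pd.DataFrame:
    """Replicate-mean counts vs the analytic expectation, per gene.

    Genes carry 25 bases (15 A/T, 7 C/G, 3 CpG); published rates ×1000
    give expected cohort counts around 11. Returns one row per gene with
    the z-score (mean − analytic) / SE, SE from the binomial variance over
    replicates.
    """
    lib = _tiny_library(n_genes, (15, 7, 3))
    rates = fold_indel_rate(BMRConfig.tcga_ov().scaled(1000))
    sim = simulate_replicates(lib, rates,
                              SimulationConfig(n_patients, n_replicates, seed))
    p = rates.as_array()
    var_per_patient = float(15 * p[0] * (1 - p[0]) + 7 * p[1] * (1 - p[1])
                            + 3 * p[2] * (1 - p[2]))
    se = np.sqrt(n_patients * var_per_patient / n_replicates)
    df = pd.DataFrame({"gene": sim.genes,
                       "mean_count": sim.expected.values,
                       "analytic": sim.analytic_expectation.values})
    df["se"] = se
    df["z"] = (df["mean_count"] - df["analytic"]) / se
    return df


# --------------------------------------------------- sampler equivalence
def sampler_equivalence(seed: int, n_draws: int = 10_000,
                        gene_bases: int = 100, rate: float = 0.05) -> dict:
    """Chi-square comparison of binomial-shortcut vs per-base Bernoulli
    count distributions on a single 100-base A/T gene."""
    lib = _tiny_library(1, (gene_bases, 0, 0))
    rates = EffectiveRates(rate, 0.0, 0.0)
    rng_b = np.random.default_rng(_subseed(seed, 5, 0))
    rng_o = np.random.default_rng(_subseed(seed, 5, 1))
    binom = np.array([simulate_patient(lib, rates, rng_b)[0]
                      for _ in range(n_draws)])
    bern = np.array([simulate_patient(lib, rates, rng_o, method="bernoulli")[0]
                     for _ in range(n_draws)])
    hi = int(max(binom.max(), bern.max())) + 1
    table = np.vstack([np.bincount(binom, minlength=hi),
                       np.bincount(bern, minlength=hi)])
    table = table[:, table.sum(axis=0) >= 5]
    chi2 = stats.chi2_contingency(table)
    mu = gene_bases * rate
    se_mean = np.sqrt(gene_bases * rate * (1 - rate) / n_draws)
    return {"chi2_p": float(chi2.pvalue), "n_draws": n_draws,
            "binomial_mean": float(binom.mean()),
            "bernoulli_mean": float(bern.mean()),
            "expected_mean": mu,
            "mean_z": float((binom.mean() - mu) / se_mean)}


# ------------------------------------------------------ planted recovery
@dataclass
class BenchmarkRun:
    """Everything the planted-selection benchmark produced."""

    library: ExonLibrary
    truth: SyntheticTruth
    table: pd.DataFrame  # ratio table, planted run
    tails_nonmutated: list[str]
    tails_mutated: list[str]
    null_table: pd.DataFrame  # ratio table under the all-neutral cohort
    workdir: Path

    @property
    def recovery_nonmutated(self) -> float:
        hit = set(self.truth.nonmutated_set) & set(self.tails_nonmutated)
        return len(hit) / len(self.truth.nonmutated_set)

    @property
    def recovery_mutated(self) -> float:
        hit = set(self.truth.mutated_set) & set(self.tails_mutated)
        return len(hit) / len(self.truth.mutated_set)


def planted_recovery(seed: int, workdir: str | Path,
                     n_genes: int = 1000, n_patients: int = 300,
                     n_replicates: int = 100, k: int = 50,
                     n_low: int = 20, n_high: int = 20,
                     s_low: float = 0.1, s_high: float = 10.0,
                     rate_scale: float = 100.0) -> BenchmarkRun:
    """Generate the benchmark cohort, rank, and select tails.

    Default geometry (1000 genes × ~1 kb, published rates ×100, 300
    patients) gives neutral expected cohort counts around 40, comfortably
    above the ≥20 the recovery benchmark requires. Also runs an all-neutral
    cohort against the same simulation for the chance-level null.
    """
    workdir = Path(workdir)
    files = generate_genome(workdir / "genome", n_genes=n_genes,
                            exons_per_gene=2, exon_length_range=(300, 700),
                            gc_fraction=0.4, cpg_enrichment=2.0, seed=seed)
    lib = build_library(files.fasta, files.gtf, files.probes)
    rates = fold_indel_rate(BMRConfig.tcga_ov().scaled(rate_scale))
    truth = benchmark_truth(lib.genes, n_low=n_low, n_high=n_high,
                            s_low=s_low, s_high=s_high, seed=seed)
    sim = simulate_replicates(lib, rates,
                              SimulationConfig(n_patients, n_replicates, seed))

    def rank_cohort(t: SyntheticTruth, cohort_seed: int, name: str):
        maf = workdir / f"{name}.maf"
        generate_cohort(lib, rates, t, n_patients, maf, seed=cohort_seed)
        observed = filter_observed(parse_maf(maf), library_genes=lib.genes)
        return compute_ratios(observed, sim)

    table = rank_cohort(truth, seed, "cohort")
    tails = select_tails(table, k)
    neutral = SyntheticTruth(selection=pd.Series(1.0, index=lib.genes), seed=seed)
    null_table = rank_cohort(neutral, _subseed(seed, 7), "cohort_null")
    return BenchmarkRun(library=lib, truth=truth, table=table,
                        tails_nonmutated=tails.nonmutated,
                        tails_mutated=tails.mutated,
                        null_table=null_table, workdir=workdir)


def null_overlap_interval(n_genes: int, n_planted: int, k: int,
                          level: float = 0.95) -> tuple[int, int]:
    """Central hypergeometric interval for |planted ∩ k-tail| by chance."""
    h = stats.hypergeom(n_genes, n_planted, k)
    alpha = (1 - level) / 2
    return int(h.ppf(alpha)), int(h.ppf(1 - alpha))


# ------------------------------------------------------------- KS studies
def omics_direction_study(run: BenchmarkRun, n_samples: int = 300,
                          seed: int = 0) -> dict[str, SetComparison]:
    """Planted omics for the benchmark truth, compared over the *selected*
    tails (as the cohort analysis does), one comparison per data kind."""
    paths = generate_omics(run.library.genes, run.truth.nonmutated_set,
                           run.truth.mutated_set, run.workdir / "omics",
                           n_samples=n_samples, seed=seed)
    out: dict[str, SetComparison] = {}
    for label, kind, site_map in (("expression", "expression_RMA", None),
                                  ("methylation", "methylation_beta",
                                   paths.get("site_map")),
                                  ("copy_number", "copy_number", None)):
        matrix = OmicsMatrix.read(paths[label], kind, site_map_path=site_map)
        out[label] = compare_sets(matrix, run.tails_nonmutated,
                                  run.tails_mutated)
    return out


def ks_power_study(seed: int, workdir: str | Path, n_runs: int = 100,
                   n_genes_per_set: int = 50, n_samples: int = 300,
                   expression_delta: float = 1.0) -> pd.DataFrame:
    """Detection of a +delta·sd expression shift over repeated generations.

    Returns one row per run with the KS p-value and shift direction for a
    pooled comparison of two 50-gene sets across ``n_samples`` samples.
    """
    workdir = Path(workdir)
    genes = [f"G{i:03d}" for i in range(2 * n_genes_per_set)]
    nonmut, mut = genes[:n_genes_per_set], genes[n_genes_per_set:]
    rows = []
    for i in range(n_runs):
        paths = generate_omics(genes, nonmut, mut, workdir,
                               n_samples=n_samples,
                               expression_delta=expression_delta,
                               kinds=("expression",),
                               seed=_subseed(seed, 11, i))
        matrix = OmicsMatrix.read(paths["expression"], "expression_RMA")
        cmp = compare_sets(matrix, nonmut, mut)
        rows.append({"run": i, "p_value": cmp.ks.p_value, "D": cmp.ks.D,
                     "direction": cmp.direction})
    return pd.DataFrame(rows)


def ks_null_calibration(seed: int, workdir: str | Path, n_runs: int = 200,
                        n_genes_per_set: int = 50, n_samples: int = 300
                        ) -> dict:
    """With no planted shift the KS p-values should be uniform; returns the
    p-values and a meta-KS uniformity p."""
    df = ks_power_study(seed, workdir, n_runs=n_runs,
                        n_genes_per_set=n_genes_per_set, n_samples=n_samples,
                        expression_delta=0.0)
    meta = stats.kstest(df["p_value"].values, "uniform")
    return {"p_values": df["p_value"].values, "meta_ks_p": float(meta.pvalue)}
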