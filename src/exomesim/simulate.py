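"""Monte-Carlo mutagenesis of the exon library at category-specific
background mutation rates.

Model
-----
Each base of the library belongs to one of three mutable categories (A/T,
non-CpG C/G, CpG-context C/G), each with its own per-base background
mutation rate. Because no sequence specificity is published for indels,
the indel rate is folded into each substitution category. Per simulated
patient, every base mutates independently with its category's effective
rate and at most once; a cohort is the sum over patients; a replicate is
one cohort draw, and the per-gene expected count is the mean over
replicates.

Sampling per (gene, category) block draws a binomial count — the sum of
independent per-base Bernoulli trials is exactly Binomial(n_bases, rate),
so the shortcut is distributionally identical to flipping every base (a
per-base mode is kept for cross-checking). RNG substreams are derived
deterministically from ``(seed, replicate, patient)`` so results are
reproducible regardless of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .library import ExonLibrary

# published exome-wide background mutation rates (per base, per patient)
TCGA_OV_BMR = dict(rate_AT=8.54e-7, rate_CG=1.2e-6, rate_CPG=4.31e-6, rate_indel=2.2e-7)


@dataclass(frozen=True)
class BMRConfig:
    """Background mutation rates: three substitution categories plus indels."""

    rate_AT: float
    rate_CG: float
    rate_CPG: float
    rate_indel: float = 0.0

    def __post_init__(self):
        for name in ("rate_AT", "rate_CG", "rate_CPG", "rate_indel"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def scaled(self, factor: float) -> "BMRConfig":
        return BMRConfig(*(min(1.0, r * factor) for r in
                           (self.rate_AT, self.rate_CG, self.rate_CPG, self.rate_indel)))

    @classmethod
    def tcga_ov(cls) -> "BMRConfig":
        return cls(**TCGA_OV_BMR)


@dataclass(frozen=True)
class EffectiveRates:
    """Per-category rates after indel folding, ordered (AT, CG, CPG)."""

    eff_AT: float
    eff_CG: float
    eff_CPG: float

    def as_array(self) -> np.ndarray:
        return np.array([self.eff_AT, self.eff_CG, self.eff_CPG])


def fold_indel_rate(bmr: BMRConfig, mode: str = "add") -> EffectiveRates:
    """Fold the indel rate into the substitution categories.

    ``mode='add'`` (default) adds the full indel rate to every category;
    ``mode='split'`` apportions it equally among the three. Results are
    clamped at 1.
    """
    if mode == "add":
        extra = bmr.rate_indel
    elif mode == "split":
        extra = bmr.rate_indel / 3.0
    else:
        raise ValueError(f"unknown indel folding mode {mode!r}")
    return EffectiveRates(*(min(1.0, r + extra)
                            for r in (bmr.rate_AT, bmr.rate_CG, bmr.rate_CPG)))


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 316
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1 or self.n_replicates < 1:
            raise ValueError("n_patients and n_replicates must be >= 1")

    @property
    def total_runs(self) -> int:
        return self.n_patients * self.n_replicates


@dataclass
class SimulatedGeneCounts:
    """Genes × replicates matrix of cohort-level simulated mutation counts."""

    genes: list[str]
    counts: np.ndarray  # (n_genes, n_replicates) int
    n_patients: int
    total_runs: int  # patient-level simulation runs executed
    analytic_expectation: pd.Series  # n_patients * Σ_base eff rate, per gene

    @property
    def expected(self) -> pd.Series:
        """Replicate-mean simulated count S_g — the ratio denominator."""
        return pd.Series(self.counts.mean(axis=1), index=self.genes, name="S_g")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=pd.Index(self.genes, name="gene"),
                          columns=[f"rep{r}" for r in range(self.counts.shape[1])])
        return df

    def save(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(outdir / "counts.tsv", sep="\t")
        pd.DataFrame({"gene": self.genes,
                      "S_g": self.expected.values,
                      "analytic": self.analytic_expectation.values,
                      "n_patients": self.n_patients,
                      "total_runs": self.total_runs}).to_csv(
            outdir / "summary.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, outdir) -> "SimulatedGeneCounts":
        from pathlib import Path
        outdir = Path(outdir)
        df = pd.read_csv(outdir / "counts.tsv", sep="\t", index_col="gene")
        summary = pd.read_csv(outdir / "summary.tsv", sep="\t", index_col="gene")
        return cls(genes=list(df.index), counts=df.values,
                   n_patients=int(summary["n_patients"].iloc[0]),
                   total_runs=int(summary["total_runs"].iloc[0]),
                   analytic_expectation=summary["analytic"])


def _patient_rng(seed: int, replicate: int, patient: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(replicate, patient)))


def simulate_patient(library: ExonLibrary, rates: EffectiveRates,
                     rng: np.random.Generator, method: str = "binomial") -> np.ndarray:
    """One patient draw: per-gene mutation counts (genes in sorted order).

    ``method='binomial'`` draws one count per (gene, category);
    ``method='bernoulli'`` flips every base individually. The two are
    distributionally identical; the latter exists as a slow cross-check.
    """
    cat = library.category_matrix().values[:, :3]  # (G, 3), OTHER never mutates
    p = rates.as_array()
    if method == "binomial":
        return rng.binomial(cat, p[None, :]).sum(axis=1)
    if method == "bernoulli":
        out = np.zeros(cat.shape[0], dtype=np.int64)
        for i, g in enumerate(library.genes):
            mask = library.entries[g].mask
            mutable = mask < 3
            out[i] = int((rng.random(mask.size)[mutable] < p[mask[mutable]]).sum())
        return out
    raise ValueError(f"unknown sampling method {method!r}")


def simulate_cohort(library: ExonLibrary, rates: EffectiveRates, n_patients: int,
                    seed: int = 0, replicate: int = 0,
                    cat_matrix: np.ndarray | None = None) -> np.ndarray:
    """Sum of ``n_patients`` independent patient draws for one replicate."""
    total, _ = _run_cohort(library, rates, n_patients, seed, replicate, cat_matrix)
    return total


def _run_cohort(library, rates, n_patients, seed, replicate, cat_matrix=None):
    if cat_matrix is None:
        cat_matrix = library.category_matrix().values[:, :3]
    p = rates.as_array()
    total = np.zeros(cat_matrix.shape[0], dtype=np.int64)
    executed = 0
    for patient in range(n_patients):
        rng = _patient_rng(seed, replicate, patient)
        total += rng.binomial(cat_matrix, p[None, :]).sum(axis=1)
        executed += 1
    return total, executed


def simulate_replicates(library: ExonLibrary, rates: EffectiveRates,
                        config: SimulationConfig) -> SimulatedGeneCounts:
    """Full design: ``n_replicates`` independent cohorts of ``n_patients``.

    ``total_runs`` on the result is a tally of patient-level draws actually
    executed (316 patients × 100 replicates in the study design = 31,600).
    """
    genes = library.genes
    cat = library.category_matrix().values[:, :3]
    counts = np.empty((len(genes), config.n_replicates), dtype=np.int64)
    executed = 0
    for r in range(config.n_replicates):
        counts[:, r], n = _run_cohort(library, rates, config.n_patients,
                                      config.seed, r, cat_matrix=cat)
        executed += n
    per_patient = cat @ rates.as_array()
    analytic = pd.Series(config.n_patients * per_patient, index=genes, name="analytic")
    return SimulatedGeneCounts(genes=genes, counts=counts,
                               n_patients=config.n_patients,
                               total_runs=executed,
                               analytic_expectation=analytic)
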