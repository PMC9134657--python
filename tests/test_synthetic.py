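"""Generator ground truth: composition, reproducibility, calibration."""

import numpy as np
import pandas as pd
import pytest

from exomesim import (build_library, fold_indel_rate, generate_cohort,
                      generate_genome, generate_omics, parse_maf,
                      simulate_replicates)
from exomesim.simulate import BMRConfig, SimulationConfig
from exomesim.synthetic import (SyntheticTruth, benchmark_truth,
                                expected_cpg_frequency)


def test_two_single_exon_genes_fully_probed_give_200_base_library(tmp_path):
    files = generate_genome(tmp_path, n_genes=2, exons_per_gene=1,
                            exon_length_range=(100, 100), seed=0)
    lib = build_library(files.fasta, files.gtf, files.probes)
    assert lib.total_bases == 200
    assert len(lib.genes) == 2


def test_zero_gc_genome_has_no_cg_bases(tmp_path):
    files = generate_genome(tmp_path, n_genes=3, exons_per_gene=1,
                            exon_length_range=(200, 200), gc_fraction=0.0,
                            cpg_enrichment=1.0, seed=2)
    lib = build_library(files.fasta, files.gtf, files.probes)
    counts = lib.category_matrix().sum()
    assert counts["CG"] + counts["CPG"] == 0
    assert counts["AT"] == lib.total_bases


def test_cpg_dinucleotide_frequency_matches_chain_expectation(tmp_path):
    """Observed CpG frequency within 3 SE of rho * (gc/2)^2 at 100 kb."""
    gc, rho = 0.5, 2.0
    files = generate_genome(tmp_path, n_genes=1, exons_per_gene=1,
                            exon_length_range=(100_000, 100_000),
                            gc_fraction=gc, cpg_enrichment=rho, seed=4)
    seq = "".join(line.strip() for line in
                  open(files.fasta).read().splitlines()[1:])
    n_pairs = len(seq) - 1
    obs = sum(1 for i in range(n_pairs) if seq[i:i + 2] == "CG") / n_pairs
    expect = expected_cpg_frequency(gc, rho)
    assert expect == pytest.approx(2 * 0.25 * gc**2)
    se = np.sqrt(expect * (1 - expect) / n_pairs)
    # adjacent pairs overlap, inflating the variance; allow 2x
    assert abs(obs - expect) <= 6 * se


def test_marginal_gc_content_is_preserved_under_enrichment(tmp_path):
    files = generate_genome(tmp_path, n_genes=1, exons_per_gene=1,
                            exon_length_range=(100_000, 100_000),
                            gc_fraction=0.4, cpg_enrichment=2.0, seed=6)
    seq = "".join(line.strip() for line in
                  open(files.fasta).read().splitlines()[1:])
    gc = (seq.count("C") + seq.count("G")) / len(seq)
    assert abs(gc - 0.4) <= 6 * np.sqrt(0.4 * 0.6 / len(seq))


def test_infeasible_packing_is_an_error(tmp_path):
    with pytest.raises(ValueError, match="chrom_length"):
        generate_genome(tmp_path, n_genes=10, exons_per_gene=2,
                        exon_length_range=(100, 100), chrom_length=50, seed=0)


def test_infeasible_cpg_enrichment_rejected(tmp_path):
    with pytest.raises(ValueError, match="cpg_enrichment"):
        generate_genome(tmp_path, n_genes=1, exons_per_gene=1,
                        exon_length_range=(100, 100), gc_fraction=0.8,
                        cpg_enrichment=5.0, seed=0)


def test_generation_is_bit_reproducible(tmp_path):
    a = generate_genome(tmp_path / "a", n_genes=5, exons_per_gene=2,
                        exon_length_range=(50, 90), seed=21)
    b = generate_genome(tmp_path / "b", n_genes=5, exons_per_gene=2,
                        exon_length_range=(50, 90), seed=21)
    assert a.fasta.read_text() == b.fasta.read_text()
    assert a.gtf.read_text() == b.gtf.read_text()
    assert a.probes.read_text() == b.probes.read_text()


def test_negative_selection_factor_rejected():
    with pytest.raises(ValueError):
        SyntheticTruth(selection=pd.Series({"A": -0.5}))


def test_all_zero_selection_gives_header_only_maf(tmp_path, toy_dataset):
    _, lib = toy_dataset
    rates = fold_indel_rate(BMRConfig.tcga_ov().scaled(1000))
    truth = SyntheticTruth(selection=pd.Series(0.0, index=lib.genes))
    ledger = generate_cohort(lib, rates, truth, n_patients=5,
                             out_maf=tmp_path / "c.maf", seed=0)
    assert ledger["__n_records__"] == 0
    cohort = parse_maf(tmp_path / "c.maf")
    assert cohort.counts == {}


def test_cohort_coordinates_refer_to_real_genome_bases(tmp_path, toy_dataset):
    """Every MAF record's reference allele matches the genome sequence."""
    files, lib = toy_dataset
    rates = fold_indel_rate(BMRConfig.tcga_ov().scaled(3000))
    truth = SyntheticTruth(selection=pd.Series(1.0, index=lib.genes))
    generate_cohort(lib, rates, truth, n_patients=3,
                    out_maf=tmp_path / "c.maf", seed=9)
    seq = "".join(line.strip() for line in
                  open(files.fasta).read().splitlines()[1:])
    maf = pd.read_csv(tmp_path / "c.maf", sep="\t", comment="#")
    assert len(maf) > 0
    for _, row in maf.iterrows():
        assert seq[row["Start_Position"] - 1] == row["Reference_Allele"]
        assert row["Tumor_Seq_Allele2"] != row["Reference_Allele"]


def test_cohort_generator_calibrates_against_simulator(tmp_path, toy_dataset):
    """Independent per-base Bernoulli cohort totals agree with the binomial
    simulator's expectation within 3 SE at neutral selection."""
    _, lib = toy_dataset
    rates = fold_indel_rate(BMRConfig.tcga_ov().scaled(2000))
    n_patients = 40
    truth = SyntheticTruth(selection=pd.Series(1.0, index=lib.genes))
    ledger = generate_cohort(lib, rates, truth, n_patients,
                             out_maf=tmp_path / "c.maf", seed=31)
    sim = simulate_replicates(lib, rates,
                              SimulationConfig(n_patients, 1, seed=1))
    mu = sim.analytic_expectation
    total_mu, total_obs = float(mu.sum()), sum(ledger[g] for g in lib.genes)
    assert abs(total_obs - total_mu) <= 3 * np.sqrt(total_mu)
    for g in lib.genes:  # per-gene: Poisson-scale 4-sigma guard
        assert abs(ledger[g] - mu[g]) <= 4 * np.sqrt(mu[g]) + 3


def test_planted_selection_suppresses_counts(tmp_path, toy_dataset):
    _, lib = toy_dataset
    rates = fold_indel_rate(BMRConfig.tcga_ov().scaled(3000))
    s = pd.Series(1.0, index=lib.genes)
    target = lib.genes[0]
    s[target] = 0.1
    truth = SyntheticTruth(selection=s)
    ledger = generate_cohort(lib, rates, truth, 50,
                             out_maf=tmp_path / "c.maf", seed=17)
    sim = simulate_replicates(lib, rates, SimulationConfig(50, 1, seed=1))
    neutral_mu = float(sim.analytic_expectation[target])
    assert neutral_mu >= 20  # powered comparison
    ratio = ledger[target] / neutral_mu
    assert 0.02 <= ratio <= 0.35


def test_omics_truth_directions(tmp_path):
    genes = [f"G{i:03d}" for i in range(60)]
    nonmut, mut = genes[:10], genes[10:20]
    paths = generate_omics(genes, nonmut, mut, tmp_path, n_samples=80,
                           expression_delta=1.0, methylation_delta=-0.2,
                           copy_number_delta=0.5, seed=3)
    expr = pd.read_csv(paths["expression"], sep="\t", index_col=0)
    assert expr.loc[nonmut].values.mean() > expr.loc[mut].values.mean()
    meth = pd.read_csv(paths["methylation"], sep="\t", index_col=0)
    sites = pd.read_csv(paths["site_map"], sep="\t", index_col=0)["gene"]
    beta = meth.values
    assert beta.min() >= 0 and beta.max() <= 1
    m_non = meth.loc[sites.index[sites.isin(nonmut)]].values.mean()
    m_mut = meth.loc[sites.index[sites.isin(mut)]].values.mean()
    assert m_non < m_mut
    cn = pd.read_csv(paths["copy_number"], sep="\t", index_col=0)
    assert cn.loc[nonmut].values.mean() > cn.loc[mut].values.mean()


def test_omics_sets_must_be_disjoint(tmp_path):
    with pytest.raises(ValueError, match="disjoint"):
        generate_omics(["A", "B"], ["A"], ["A"], tmp_path, n_samples=5)


def test_benchmark_truth_plants_requested_sets():
    genes = [f"G{i}" for i in range(100)]
    truth = benchmark_truth(genes, n_low=5, n_high=7, s_low=0.1, s_high=10,
                            seed=2)
    assert len(truth.nonmutated_set) == 5 and len(truth.mutated_set) == 7
    assert (truth.selection[truth.nonmutated_set] == 0.1).all()
    assert (truth.selection[truth.mutated_set] == 10).all()
    neutral = truth.selection.drop(truth.nonmutated_set + truth.mutated_set)
    assert (neutral == 1.0).all()
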