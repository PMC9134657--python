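"""Pooling, the two-sample KS test, set comparison and RPKM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exomesim.observed import ObservedCohort
from exomesim.omics import (OmicsMatrix, compare_sets,
                            expression_by_mutation_status, ks_two_sample,
                            pool_gene_set, rpkm)


def matrix_of(data: dict, kind="expression_RMA", site_to_gene=None):
    df = pd.DataFrame(data).T
    df.columns = [f"S{i}" for i in range(df.shape[1])]
    return OmicsMatrix(kind=kind, values=df,
                       site_to_gene=pd.Series(site_to_gene) if site_to_gene else None)


def brute_force_ks(x, y):
    """Max |ECDF_x - ECDF_y| evaluated at every pooled point."""
    pts = np.concatenate([x, y])
    return max(abs((x <= t).mean() - (y <= t).mean()) for t in pts)


# ---------------------------------------------------------------- pooling
def test_pooling_flattens_gene_by_sample_values():
    m = matrix_of({"A": [0.5] * 3, "B": [0.5] * 3})
    pooled = pool_gene_set(m, ["A", "B"])
    assert pooled.tolist() == [0.5] * 6


def test_methylation_sites_all_contribute():
    m = matrix_of({"s1": [0.1, 0.2], "s2": [0.3, 0.4]},
                  kind="methylation_beta", site_to_gene={"s1": "G", "s2": "G"})
    pooled = pool_gene_set(m, ["G"])
    assert sorted(pooled.tolist()) == [0.1, 0.2, 0.3, 0.4]
    averaged = pool_gene_set(m, ["G"], average_sites=True)
    assert sorted(np.round(averaged, 6).tolist()) == [0.2, 0.3]


def test_partial_match_is_allowed_zero_match_is_fatal():
    m = matrix_of({"A": [1.0, 2.0]})
    assert pool_gene_set(m, ["A", "MISSING"]).size == 2
    with pytest.raises(ValueError, match="no genes"):
        pool_gene_set(m, ["MISSING"])


def test_missing_cells_are_dropped():
    m = matrix_of({"A": [1.0, np.nan, 3.0]})
    assert pool_gene_set(m, ["A"]).tolist() == [1.0, 3.0]


def test_pooling_conservation_with_sites():
    m = matrix_of({"s1": [0.1, 0.2], "s2": [0.3, 0.4], "s3": [0.5, 0.6]},
                  kind="methylation_beta",
                  site_to_gene={"s1": "G1", "s2": "G1", "s3": "G2"})
    assert pool_gene_set(m, ["G1", "G2"]).size == 3 * 2


def test_beta_values_outside_unit_interval_rejected():
    with pytest.raises(ValueError, match="beta"):
        matrix_of({"s1": [1.4]}, kind="methylation_beta")


# -------------------------------------------------------------------- KS
def test_identical_samples_have_zero_D():
    x = np.array([1.0, 2.0, 3.0])
    res = ks_two_sample(x, x.copy())
    assert res.D == 0.0 and res.p_value == pytest.approx(1.0)


def test_disjoint_supports_have_D_one():
    res = ks_two_sample(np.zeros(5), np.ones(5))
    assert res.D == 1.0


def test_ks_matches_exhaustive_ecdf_oracle():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([3.0, 4.0, 5.0, 6.0])
    assert ks_two_sample(x, y).D == pytest.approx(brute_force_ks(x, y))


def test_empty_sample_is_error():
    with pytest.raises(ValueError):
        ks_two_sample(np.array([]), np.array([1.0]))


@given(st.lists(st.floats(-50, 50), min_size=1, max_size=25),
       st.lists(st.floats(-50, 50), min_size=1, max_size=25))
def test_ks_symmetry_and_oracle_on_random_samples(xs, ys):
    x, y = np.array(xs), np.array(ys)
    a, b = ks_two_sample(x, y), ks_two_sample(y, x)
    assert a.D == pytest.approx(b.D)
    assert a.D == pytest.approx(brute_force_ks(x, y))


def test_D_invariant_under_strictly_monotone_transform():
    rng = np.random.default_rng(8)
    x, y = rng.normal(size=40), rng.normal(0.7, 1.2, size=30)
    d0 = ks_two_sample(x, y).D
    d1 = ks_two_sample(np.exp(x), np.exp(y)).D
    assert d0 == pytest.approx(d1)


# ---------------------------------------------------------- set comparison
def test_identical_sets_show_no_shift():
    m = matrix_of({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]})
    cmp = compare_sets(m, ["A"], ["B"])
    assert cmp.ks.D == 0.0 and cmp.direction == "none"


def test_planted_shift_detected_with_direction():
    rng = np.random.default_rng(3)
    data = {f"N{i}": rng.normal(1.0, 1.0, 50) for i in range(10)}
    data.update({f"M{i}": rng.normal(0.0, 1.0, 50) for i in range(10)})
    m = matrix_of(data)
    cmp = compare_sets(m, [f"N{i}" for i in range(10)],
                       [f"M{i}" for i in range(10)])
    assert cmp.direction == "nonmutated higher"
    assert cmp.ks.p_value < 1e-6
    # ECDF curves cover both pooled sample sizes
    assert cmp.ks.n_x == cmp.ks.n_y == 500
    assert (cmp.ecdf["cdf_nonmutated"].iloc[-1], cmp.ecdf["cdf_mutated"].iloc[-1]) == (1, 1)


def test_discrete_tie_on_median_falls_back_to_mean():
    m = matrix_of({"A": [2, 2, 2, 3, 3], "B": [1, 1, 2, 2, 2]},
                  kind="copy_number")
    cmp = compare_sets(m, ["A"], ["B"])
    assert cmp.direction == "nonmutated higher"


# ----------------------------------------- per-gene mutation-status split
def cohort_of(counts: dict, patients):
    c = ObservedCohort(patients=list(patients))
    c.counts = dict(counts)
    return c


def test_gene_mutated_in_no_samples_is_underpowered():
    m = matrix_of({"G": [1.0, 2.0, 3.0]})
    split = expression_by_mutation_status(m, cohort_of({}, ["S0", "S1", "S2"]), "G")
    assert split.underpowered and split.ks is None
    assert split.mutated_values.size == 0


def test_identical_strata_give_zero_D():
    m = matrix_of({"G": [5.0, 5.0, 5.0, 5.0]})
    cohort = cohort_of({("G", "S0"): 1, ("G", "S1"): 1}, ["S0", "S1", "S2", "S3"])
    split = expression_by_mutation_status(m, cohort, "G")
    assert not split.underpowered
    assert split.ks.D == 0.0


def test_status_split_respects_barcode_prefix():
    df = pd.DataFrame({"G": [1.0, 2.0]}).T
    df.columns = ["TCGA-01-01A", "TCGA-02-01A"]
    m = OmicsMatrix(kind="expression_RMA", values=df)
    cohort = cohort_of({("G", "TCGA-01-99Z"): 1}, ["TCGA-01-99Z"])
    split = expression_by_mutation_status(m, cohort, "G", barcode_prefix=7)
    assert split.mutated_values.tolist() == [1.0]


def test_null_status_split_rejects_at_nominal_rate():
    """Mutation status independent of expression: ~5% rejections at alpha=.05."""
    rng = np.random.default_rng(12)
    n_genes, n_samples = 300, 60
    samples = [f"S{i}" for i in range(n_samples)]
    rejections = 0
    tested = 0
    values = rng.normal(size=(n_genes, n_samples))
    df = pd.DataFrame(values, index=[f"G{i}" for i in range(n_genes)],
                      columns=samples)
    m = OmicsMatrix(kind="expression_RMA", values=df)
    for i in range(n_genes):
        mutated = rng.choice(samples, size=8, replace=False)
        cohort = cohort_of({(f"G{i}", s): 1 for s in mutated}, samples)
        split = expression_by_mutation_status(m, cohort, f"G{i}")
        tested += 1
        if split.ks.p_value < 0.05:
            rejections += 1
    rate = rejections / tested
    ci = 3 * np.sqrt(0.05 * 0.95 / tested)
    assert abs(rate - 0.05) <= max(ci, 0.03)


# ------------------------------------------------------------------ RPKM
def test_rpkm_formula_worked_example():
    counts = pd.DataFrame({"S0": [10, 999990]}, index=["G", "REST"])
    lengths = pd.Series({"G": 1000, "REST": 1000})
    m = rpkm(counts, lengths)
    assert m.values.loc["G", "S0"] == pytest.approx(10.0)


def test_rpkm_zero_count_is_zero():
    counts = pd.DataFrame({"S0": [0, 100]}, index=["G", "REST"])
    m = rpkm(counts, pd.Series({"G": 500, "REST": 1000}))
    assert m.values.loc["G", "S0"] == 0.0


def test_rpkm_matches_per_cell_oracle():
    rng = np.random.default_rng(5)
    counts = pd.DataFrame(rng.integers(0, 500, size=(5, 3)),
                          index=[f"G{i}" for i in range(5)],
                          columns=[f"S{j}" for j in range(3)])
    lengths = pd.Series(rng.integers(200, 5000, size=5),
                        index=counts.index).astype(float)
    m = rpkm(counts, lengths)
    for g in counts.index:
        for s in counts.columns:
            expect = counts.loc[g, s] / ((lengths[g] / 1e3) *
                                         (counts[s].sum() / 1e6))
            assert m.values.loc[g, s] == pytest.approx(expect)


def test_rpkm_zero_library_size_is_error():
    counts = pd.DataFrame({"S0": [0, 0]}, index=["A", "B"])
    with pytest.raises(ValueError, match="library size"):
        rpkm(counts, pd.Series({"A": 100, "B": 100}))
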