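"""Observed/expected ratio ranking and tail gene-set selection.

For every gene with at least one observed mutation and a positive simulated
expectation, the ratio r_g = O_g / S_g measures departure from the neutral
background: r_g << 1 suggests selection against mutation ("non-mutated"
genes), r_g >> 1 an excess (e.g. positive selection on drivers). Selection
of candidate sets is purely rank-based: the k smallest and k largest
ratios. A per-gene Poisson tail probability is available as an optional
diagnostic; it plays no part in selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .observed import ObservedGeneCounts
from .simulate import SimulatedGeneCounts

log = logging.getLogger(__name__)


@dataclass
class TailSelection:
    k: int
    nonmutated: list[str]  # the k genes with the smallest ratios
    mutated: list[str]  # the k genes with the largest ratios
    low_quantile: float
    high_quantile: float


def compute_ratios(observed: ObservedGeneCounts, simulated: SimulatedGeneCounts,
                   pseudocount: float = 0.0,
                   poisson_diagnostic: bool = False) -> pd.DataFrame:
    """Per-gene ratio table: O_g, S_g, r_g, log10 ratio, both rank columns.

    Only genes present in both inputs are retained; genes with S_g == 0 are
    excluded (logged) unless a ``pseudocount`` is supplied. Ranks use
    1 = most mutations, ties broken by gene symbol for determinism.
    """
    expected = simulated.expected
    common = observed.totals.index.intersection(expected.index)
    if len(common) == 0:
        raise ValueError(
            "no genes shared between observed and simulated counts; "
            f"observed e.g. {list(observed.totals.index[:5])}, "
            f"simulated e.g. {list(expected.index[:5])}")
    common = sorted(common)
    O = observed.totals.loc[common].astype(float)
    S = expected.loc[common].astype(float) + pseudocount
    zero = S == 0
    if zero.any():
        log.info("excluding %d genes with zero simulated expectation: %s",
                 int(zero.sum()), ",".join(S.index[zero][:20]))
        O, S = O[~zero], S[~zero]
    table = pd.DataFrame({"O_g": O, "S_g": S})
    table["ratio"] = table["O_g"] / table["S_g"]
    table["log_ratio"] = np.log10(table["ratio"])
    table["obs_rank"] = _dense_rank(table, "O_g")
    table["sim_rank"] = _dense_rank(table, "S_g")
    if poisson_diagnostic:
        # non-selection diagnostic: two-sided Poisson tail prob of O_g given S_g
        lower = stats.poisson.cdf(table["O_g"], table["S_g"])
        upper = stats.poisson.sf(table["O_g"] - 1, table["S_g"])
        table["poisson_p"] = np.minimum(1.0, 2 * np.minimum(lower, upper))
    table.index.name = "gene"
    return table


def _dense_rank(table: pd.DataFrame, col: str) -> np.ndarray:
    # 1 = most mutations; ties broken by ascending gene symbol
    order = sorted(table.index, key=lambda g: (-table.at[g, col], g))
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order)
    return ranks.loc[table.index].values


def select_tails(table: pd.DataFrame, k: int) -> TailSelection:
    """The k smallest-ratio (non-mutated) and k largest-ratio (mutated) genes.

    Ties are broken by larger observed count first, then gene symbol, so
    re-runs are identical. When 2k exceeds the table size both tails clamp
    to floor(N/2) with a logged warning.
    """
    if table.empty:
        raise ValueError("ratio table is empty")
    n = len(table)
    if 2 * k > n:
        k_eff = n // 2
        log.warning("2k=%d exceeds table size %d; clamping tails to %d", 2 * k, n, k_eff)
        k = k_eff
    low = sorted(table.index, key=lambda g: (table.at[g, "ratio"], -table.at[g, "O_g"], g))
    high = sorted(table.index, key=lambda g: (-table.at[g, "ratio"], -table.at[g, "O_g"], g))
    nonmutated = low[:k]
    taken = set(nonmutated)
    # massive ties could otherwise land one gene in both tails
    mutated = [g for g in high if g not in taken][:k]
    return TailSelection(
        k=k,
        nonmutated=nonmutated,
        mutated=mutated,
        low_quantile=k / n,
        high_quantile=(n - k) / n,
    )


def log_ratio_distribution(table: pd.DataFrame, n_bins: int = 60,
                           tails: TailSelection | None = None) -> pd.DataFrame:
    """Histogram of log10 ratios, ready for plotting or serialization."""
    if table.empty:
        raise ValueError("ratio table is empty")
    values = table["log_ratio"].values
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:  # all ratios identical: a single bin around the value
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
    if tails is not None:
        low_cut = table.loc[tails.nonmutated, "log_ratio"].max() if tails.nonmutated else np.nan
        high_cut = table.loc[tails.mutated, "log_ratio"].min() if tails.mutated else np.nan
        hist.attrs["low_tail_cut"] = float(low_cut)
        hist.attrs["high_tail_cut"] = float(high_cut)
    return hist


def write_ranking(table: pd.DataFrame, tails: TailSelection, outdir: str | Path,
                  hist: pd.DataFrame | None = None) -> None:
    """Serialize the ratio table, tail gene lists, and histogram."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ordered = table.sort_values(["ratio", "gene"]).reset_index()
    ordered.insert(0, "rank", np.arange(1, len(ordered) + 1))
    ordered.to_csv(outdir / "ratios.tsv", sep="\t", index=False,
                   float_format="%.6g")
    (outdir / "nonmutated.txt").write_text("".join(g + "\n" for g in tails.nonmutated))
    (outdir / "mutated.txt").write_text("".join(g + "\n" for g in tails.mutated))
    if hist is not None:
        hist.to_csv(outdir / "log_ratio_hist.tsv", sep="\t", index=False)
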