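"""Parallel locus-specific divergence across replicated elevational contrasts.

For each transect, a locus-specific Hudson F_ST contrasts the high- and
low-elevation sites.  Loci strictly above the 97th/98th/99th empirical
quantile of each contrast's F_ST distribution form three outlier sets; the
statistic of interest is how many loci are outliers in exactly two and
exactly three contrasts.  The null — outlier sets are random, independent
subsets of the loci — is realized both by permutation (independent uniform
subset draws, 10 000 by default) and in closed form:

    E[exactly 3] = m1*m2*m3 / L^2
    E[exactly 2] = [m1*m2*(L-m3) + m1*m3*(L-m2) + m2*m3*(L-m1)] / L^2

where m_i are the set sizes and L the number of loci.  The closed form is
the independent oracle the permutation engine is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix, SampleTable, ValidationError
from .differentiation import hudson_fst_components


@dataclass
class ContrastFstTable:
    """Locus-specific F_ST per transect's high-vs-low contrast."""

    locus_ids: list[str]
    transects: list[str]
    fst: np.ndarray          # L x 3, NaN where undefined
    defined: np.ndarray      # L x 3 boolean


@dataclass
class ParallelDivergenceResult:
    quantile: float
    set_sizes: tuple[int, int, int]
    n_loci: int
    observed_exactly2: int
    observed_exactly3: int
    expected2_mean: float
    expected2_lo95: float
    expected2_hi95: float
    expected3_mean: float
    expected3_lo95: float
    expected3_hi95: float
    analytic_expected2: float
    analytic_expected3: float

    def to_record(self) -> dict:
        return {
            "quantile": self.quantile,
            "set_size_1": self.set_sizes[0],
            "set_size_2": self.set_sizes[1],
            "set_size_3": self.set_sizes[2],
            "n_loci": self.n_loci,
            "observed_2transects": self.observed_exactly2,
            "observed_3transects": self.observed_exactly3,
            "expected_2transects": self.expected2_mean,
            "expected_2transects_lo95": self.expected2_lo95,
            "expected_2transects_hi95": self.expected2_hi95,
            "expected_3transects": self.expected3_mean,
            "expected_3transects_lo95": self.expected3_lo95,
            "expected_3transects_hi95": self.expected3_hi95,
            "analytic_2transects": self.analytic_expected2,
            "analytic_3transects": self.analytic_expected3,
        }


def contrast_fst(gm: GenotypeMatrix, samples: SampleTable) -> ContrastFstTable:
    """Per-locus Hudson F_ST between the high and low site of each transect,
    from composite-genotype allele frequencies."""
    st = samples.site_table()
    transects = samples.transects
    site_of = samples.site_of()
    rows_of_site = {
        s: [i for i, ind in enumerate(gm.individuals) if site_of.get(ind) == s]
        for s in samples.sites
    }
    L = len(gm.loci)
    fst = np.full((L, len(transects)), np.nan)
    defined = np.zeros((L, len(transects)), dtype=bool)
    for t, tr in enumerate(transects):
        sites = st[st["transect_id"] == tr]
        try:
            hi = sites[sites["elevation_class"] == "high"].index[0]
            lo = sites[sites["elevation_class"] == "low"].index[0]
        except IndexError:
            raise ValidationError(f"transect {tr} lacks a high/low contrast")
        rows_hi, rows_lo = rows_of_site[hi], rows_of_site[lo]
        if len(rows_hi) < 2 or len(rows_lo) < 2:
            raise ValidationError(f"contrast {tr}: a site has < 2 individuals")
        p_hi = gm.composite[rows_hi].mean(axis=0) / 2.0
        p_lo = gm.composite[rows_lo].mean(axis=0) / 2.0
        num, den = hudson_fst_components(
            p_hi, 2 * len(rows_hi), p_lo, 2 * len(rows_lo)
        )
        ok = den > 0
        fst[ok, t] = num[ok] / den[ok]
        defined[:, t] = ok
    return ContrastFstTable(
        locus_ids=gm.locus_ids, transects=list(transects), fst=fst, defined=defined
    )


def outlier_sets(
    table: ContrastFstTable, q: float, min_defined: int = 100
) -> list[set[str]]:
    """Loci strictly above each contrast's empirical F_ST quantile.

    The threshold interpolates linearly between order statistics at rank
    1 + (L-1)q over that contrast's defined loci.
    """
    if not 0 < q < 1:
        raise ValidationError("quantile must lie in (0, 1)")
    ids = np.asarray(table.locus_ids)
    sets: list[set[str]] = []
    for t in range(table.fst.shape[1]):
        ok = table.defined[:, t]
        vals = table.fst[ok, t]
        if vals.size < min_defined:
            raise ValidationError(
                f"contrast {table.transects[t]}: only {vals.size} defined loci"
            )
        threshold = np.quantile(vals, q, method="linear")
        above = ok.copy()
        above[ok] = vals > threshold
        sets.append(set(ids[above]))
    return sets


def count_shared(sets: list[set]) -> tuple[int, int]:
    """(exactly-2, exactly-3) sharing counts over three sets."""
    a, b, c = sets
    exactly3 = len(a & b & c)
    in_pair = (a & b) | (a & c) | (b & c)
    exactly2 = len(in_pair) - exactly3
    return exactly2, exactly3


def analytic_expectation(m1: int, m2: int, m3: int, L: int) -> tuple[float, float]:
    """Closed-form null expectations for independent uniform subsets."""
    for m in (m1, m2, m3):
        if m > L:
            raise ValidationError("set size exceeds number of loci")
    L2 = float(L) ** 2
    e3 = m1 * m2 * m3 / L2
    e2 = (m1 * m2 * (L - m3) + m1 * m3 * (L - m2) + m2 * m3 * (L - m1)) / L2
    return e2, e3


def permutation_null(
    set_sizes: tuple[int, int, int],
    L: int,
    n_perm: int = 10_000,
    seed: int = 0,
    chunk: int = 500,
) -> dict:
    """Permutation null for sharing counts: per permutation, draw three
    independent uniform subsets of the given sizes from L loci and count
    exactly-2 / exactly-3 sharing.  Returns means and empirical 95% CIs.
    """
    m1, m2, m3 = set_sizes
    for m in set_sizes:
        if m > L:
            raise ValidationError("set size exceeds number of loci")
    rng = np.random.default_rng(seed)
    e2 = np.empty(n_perm, dtype=np.int64)
    e3 = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        members = np.zeros((3, b, L), dtype=bool)
        for k, m in enumerate((m1, m2, m3)):
            if m == 0:
                continue
            ranks = np.argpartition(rng.random((b, L)), m - 1, axis=1)[:, :m]
            np.put_along_axis(members[k], ranks, True, axis=1)
        count = members.sum(axis=0)                # b x L in {0..3}
        e3[done:done + b] = (count == 3).sum(axis=1)
        e2[done:done + b] = (count == 2).sum(axis=1)
        done += b
    lo2, hi2 = np.percentile(e2, [2.5, 97.5])
    lo3, hi3 = np.percentile(e3, [2.5, 97.5])
    return {
        "exactly2_mean": float(e2.mean()),
        "exactly2_lo95": float(lo2),
        "exactly2_hi95": float(hi2),
        "exactly2_se": float(e2.std(ddof=1) / np.sqrt(n_perm)),
        "exactly3_mean": float(e3.mean()),
        "exactly3_lo95": float(lo3),
        "exactly3_hi95": float(hi3),
        "exactly3_se": float(e3.std(ddof=1) / np.sqrt(n_perm)),
        "n_perm": n_perm,
    }


def parallel_divergence_test(
    gm: GenotypeMatrix,
    samples: SampleTable,
    quantiles: tuple[float, ...] = (0.97, 0.98, 0.99),
    n_perm: int = 10_000,
    seed: int = 0,
    min_defined: int = 100,
) -> list[ParallelDivergenceResult]:
    """Full parallel-divergence test over the requested quantiles."""
    table = contrast_fst(gm, samples)
    # L for the null: loci defined in all three contrasts
    L = int(table.defined.all(axis=1).sum())
    results = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(quantiles))
    for q, child in zip(quantiles, children):
        sets = outlier_sets(table, q, min_defined=min_defined)
        sizes = tuple(len(s) for s in sets)
        obs2, obs3 = count_shared(sets)
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        null = permutation_null(sizes, L, n_perm=n_perm, seed=sub_seed)
        ana2, ana3 = analytic_expectation(*sizes, L)
        results.append(
            ParallelDivergenceResult(
                quantile=q,
                set_sizes=sizes,
                n_loci=L,
                observed_exactly2=obs2,
                observed_exactly3=obs3,
                expected2_mean=null["exactly2_mean"],
                expected2_lo95=null["exactly2_lo95"],
                expected2_hi95=null["exactly2_hi95"],
                expected3_mean=null["exactly3_mean"],
                expected3_lo95=null["exactly3_lo95"],
                expected3_hi95=null["exactly3_hi95"],
                analytic_expected2=ana2,
                analytic_expected3=ana3,
            )
        )
    return results
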