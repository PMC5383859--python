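"""Pairwise differentiation: Hudson's F_ST, Nei's D, permutation tests.

Hudson's method-of-moments F_ST estimator for a biallelic locus with sample
allele frequencies p1, p2 and allele counts n1, n2:

    N = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    D = p1(1-p2) + p2(1-p1)
    F_ST = N / D

Genome-wide values combine loci as a ratio of averages (sum of numerators
over sum of denominators), the recommended way to aggregate this estimator;
loci monomorphic for the same allele in both samples (D = 0) are skipped.
Negative estimates are retained — the pairwise permutation test is
two-sided, and truncation would bias the null.

Nei's standard genetic distance D = -ln(Jxy / sqrt(Jx * Jy)) from the
normalized identity of biallelic allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import GenotypeMatrix, SampleTable, ValidationError


@dataclass
class PairwiseResult:
    """One site pair's observed genome-wide F_ST against its permutation
    null (mirrors the pairwise-differentiation report table)."""

    site_a: str
    site_b: str
    observed_fst: float
    null_mean: float
    null_sd: float
    null_lo95: float
    null_hi95: float
    verdict: str  # "greater", "smaller", "ns"
    nei_d: float
    null_values: np.ndarray | None = None

    def to_record(self) -> dict:
        return {
            "site_1": self.site_a,
            "site_2": self.site_b,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "null_lo95": self.null_lo95,
            "null_hi95": self.null_hi95,
            "observed_fst": self.observed_fst,
            "verdict": self.verdict,
            "nei_d": self.nei_d,
        }


def hudson_fst_components(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus numerator and denominator of the Hudson estimator."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if (n1 <= 1).any() or (n2 <= 1).any():
        raise ValidationError("allele counts must exceed 1 for the finite-sample correction")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def hudson_fst_locus(p1: float, n1: float, p2: float, n2: float) -> float:
    """Hudson F_ST at one locus; NaN when the denominator is zero
    (monomorphic for the same allele in both samples)."""
    num, den = hudson_fst_components(p1, n1, p2, n2)
    if den == 0:
        return float("nan")
    return float(num / den)


def hudson_fst_genomewide(
    p1: np.ndarray, n1, p2: np.ndarray, n2
) -> float:
    """Ratio-of-averages genome-wide Hudson F_ST over defined loci."""
    p1 = np.atleast_1d(np.asarray(p1, dtype=float))
    p2 = np.atleast_1d(np.asarray(p2, dtype=float))
    n1 = np.broadcast_to(np.asarray(n1, dtype=float), p1.shape)
    n2 = np.broadcast_to(np.asarray(n2, dtype=float), p2.shape)
    num, den = hudson_fst_components(p1, n1, p2, n2)
    defined = den > 0
    if not defined.any():
        raise ValidationError("all loci undefined (monomorphic in both samples)")
    return float(num[defined].sum() / den[defined].sum())


def nei_distance(p1: np.ndarray, p2: np.ndarray) -> float:
    """Nei's standard genetic distance between two biallelic frequency
    vectors (alternate-allele frequencies per locus)."""
    p1 = np.atleast_1d(np.asarray(p1, dtype=float))
    p2 = np.atleast_1d(np.asarray(p2, dtype=float))
    if p1.size == 0:
        raise ValidationError("zero loci")
    jxy = float(np.mean(p1 * p2 + (1 - p1) * (1 - p2)))
    jx = float(np.mean(p1**2 + (1 - p1) ** 2))
    jy = float(np.mean(p2**2 + (1 - p2) ** 2))
    if jxy == 0:
        return float("inf")
    return float(-np.log(jxy / np.sqrt(jx * jy)))


def _site_freqs_from_composite(
    gm: GenotypeMatrix, samples: SampleTable, site: str
) -> tuple[np.ndarray, int]:
    rows = [i for i, ind in enumerate(gm.individuals)
            if samples.site_of().get(ind) == site]
    if len(rows) < 2:
        raise ValidationError(f"site {site} has fewer than 2 individuals")
    comp = gm.composite[rows]
    return comp.mean(axis=0) / 2.0, len(rows)


def fst_permutation_test(
    gm: GenotypeMatrix,
    samples: SampleTable,
    site_a: str,
    site_b: str,
    n_perm: int = 100,
    seed: int = 0,
) -> PairwiseResult:
    """Genome-wide Hudson F_ST between two sites against a site-identity
    permutation null.

    Allele frequencies come from composite genotypes (p = mean composite / 2,
    allele count = 2 x individuals); the null shuffles the pooled
    individuals' site labels preserving group sizes, and the 95% bounds are
    the empirical 2.5th/97.5th percentiles of the permuted statistics.
    """
    import warnings

    if n_perm < 20:
        warnings.warn("n_perm < 20: null percentiles will be unstable")
    site_of = samples.site_of()
    rows_a = [i for i, ind in enumerate(gm.individuals) if site_of.get(ind) == site_a]
    rows_b = [i for i, ind in enumerate(gm.individuals) if site_of.get(ind) == site_b]
    if len(rows_a) < 2 or len(rows_b) < 2:
        raise ValidationError("both sites need >= 2 individuals")
    na, nb = len(rows_a), len(rows_b)
    pool = gm.composite[rows_a + rows_b]          # (na+nb) x L
    p_a = pool[:na].mean(axis=0) / 2.0
    p_b = pool[na:].mean(axis=0) / 2.0
    observed = hudson_fst_genomewide(p_a, 2 * na, p_b, 2 * nb)
    nei = nei_distance(p_a, p_b)

    rng = np.random.default_rng(seed)
    n_tot = na + nb
    perms = np.argsort(rng.random((n_perm, n_tot)), axis=1)
    q_a = pool[perms[:, :na]].mean(axis=1) / 2.0      # n_perm x L
    q_b = pool[perms[:, na:]].mean(axis=1) / 2.0
    num = (
        (q_a - q_b) ** 2
        - q_a * (1 - q_a) / (2 * na - 1)
        - q_b * (1 - q_b) / (2 * nb - 1)
    )
    den = q_a * (1 - q_b) + q_b * (1 - q_a)
    defined = den > 0
    null = np.where(defined, num, 0.0).sum(axis=1) / np.where(
        defined, den, 0.0
    ).sum(axis=1)
    lo, hi = np.percentile(null, [2.5, 97.5])
    if observed > hi:
        verdict = "greater"
    elif observed < lo:
        verdict = "smaller"
    else:
        verdict = "ns"
    return PairwiseResult(
        site_a=site_a,
        site_b=site_b,
        observed_fst=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        null_lo95=float(lo),
        null_hi95=float(hi),
        verdict=verdict,
        nei_d=nei,
        null_values=null,
    )


def all_pairwise(
    gm: GenotypeMatrix,
    samples: SampleTable,
    n_perm: int = 100,
    seed: int = 0,
) -> list[PairwiseResult]:
    """Permutation-tested F_ST and Nei's D for every site pair."""
    sites = samples.sites
    results = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(sites) * (len(sites) - 1) // 2)
    k = 0
    for i, a in enumerate(sites):
        for b in sites[i + 1:]:
            sub_seed = int(children[k].generate_state(1)[0] % (2**31))
            results.append(
                fst_permutation_test(gm, samples, a, b, n_perm=n_perm, seed=sub_seed)
            )
            k += 1
    return results
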