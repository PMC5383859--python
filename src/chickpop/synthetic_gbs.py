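"""Synthetic genotyping-by-sequencing data with replicated-transect structure.

Emulates the study design the downstream statistics assume: six sampling
sites arranged as three transects, each with one high- and one low-elevation
site; weak hierarchical allele-frequency structure (Balding-Nichols drift
around a shared ancestral frequency); low, overdispersed read coverage; and
an optional set of loci whose allele frequencies are shifted in parallel
between elevation classes across all transects (the alternative hypothesis
of the parallel-divergence test).

Site frequencies follow the Balding-Nichols model: given ancestral
frequency p and drift parameter F, each site's frequency is Beta with shape
parameters p(1-F)/F and (1-p)(1-F)/F, i.e. mean p and variance F*p*(1-p),
so pairwise Hudson F_ST between sites is approximately F. Genotypes are
Hardy-Weinberg draws from the site frequency; read depths are negative
binomial; read counts of the alternate allele are binomial with genotype-
dependent success probability (error rate epsilon at the homozygotes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .data_io import (
    GenotypeLikelihoodMatrix,
    LocusRecord,
    SampleTable,
    ValidationError,
)
import pandas as pd

# Site layout fixed by the study design: 3 transects x {high, low}.
DEFAULT_SITES = pd.DataFrame(
    {
        "site_id": ["SH_H", "SH_L", "MR_H", "MR_L", "RL_H", "RL_L"],
        "transect_id": ["SH", "SH", "MR", "MR", "RL", "RL"],
        "elevation_class": ["high", "low"] * 3,
        "latitude": [39.41881, 39.44510, 39.31992, 39.35778, 38.69641, 38.54683],
        "longitude": [-120.30687, -120.21723, -119.89655, -119.85749,
                      -120.00704, -120.30694],
        "elevation_m": [2428.0, 1952.0, 2590.8, 1891.59, 2535.33, 1973.58],
    }
)


@dataclass
class SimConfig:
    """Parameters of the synthetic GBS generator.

    Defaults are the study's regime scaled to desk size: weak structure
    (F = 0.02, the genome-wide mean the analysis operates at), low coverage
    (mean depth 6x within the 3-10x per-individual window), 1% sequencing
    error, and no elevation-divergent loci unless requested.
    """

    n_loci: int = 2000
    samples_per_site: int | Sequence[int] = 25
    fst_total: float = 0.02
    n_outlier_loci: int = 0
    outlier_delta: float = 0.3
    depth_mean: float = 6.0
    depth_dispersion: float = 2.0
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fst_total < 1:
            raise ValidationError("fst_total must lie in [0, 1)")
        if not 0 <= self.n_outlier_loci <= self.n_loci:
            raise ValidationError("n_outlier_loci must lie in [0, n_loci]")
        if not 0 < self.outlier_delta < 1:
            raise ValidationError("outlier_delta must lie in (0, 1)")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValidationError("depth parameters must be positive")
        if not 0 < self.error_rate < 0.5:
            raise ValidationError("error_rate must lie in (0, 0.5)")

    def site_sample_sizes(self) -> list[int]:
        k = len(DEFAULT_SITES)
        if isinstance(self.samples_per_site, (int, np.integer)):
            return [int(self.samples_per_site)] * k
        sizes = [int(v) for v in self.samples_per_site]
        if len(sizes) != k:
            raise ValidationError(f"need {k} per-site sample sizes, got {len(sizes)}")
        return sizes


@dataclass
class TruthSet:
    """Ground truth behind a simulated dataset (for parameter recovery)."""

    config: SimConfig
    ancestral_freqs: np.ndarray            # L
    site_freqs: np.ndarray                 # 6 x L
    outlier_locus_ids: set[str] = field(default_factory=set)
    true_genotypes: np.ndarray | None = None  # N x L ints in {0,1,2}
    samples: SampleTable | None = None

    @property
    def locus_ids(self) -> list[str]:
        return [f"contig{j:06d}:50" for j in range(len(self.ancestral_freqs))]


def simulate_site_frequencies(config: SimConfig) -> TruthSet:
    """Draw ancestral and per-site allele frequencies.

    Ancestral frequencies are uniform on (0.05, 0.95) (mimicking an upstream
    minor-allele-frequency filter); site frequencies are Balding-Nichols
    draws with drift ``fst_total``.  The first ``n_outlier_loci`` loci are
    designated elevation-divergent: within every transect the high site's
    frequency is shifted by +outlier_delta and the low site's by
    -outlier_delta, clipped to [0.01, 0.99].
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    L = config.n_loci
    p = rng.uniform(0.05, 0.95, size=L)
    F = config.fst_total
    n_sites = len(DEFAULT_SITES)
    if F == 0:
        site = np.tile(p, (n_sites, 1))
    else:
        a = p * (1 - F) / F
        b = (1 - p) * (1 - F) / F
        site = rng.beta(a[None, :], b[None, :], size=(n_sites, L))
    outlier_ids: set[str] = set()
    if config.n_outlier_loci:
        idx = np.arange(config.n_outlier_loci)
        high = DEFAULT_SITES["elevation_class"].to_numpy() == "high"
        site[np.ix_(high, idx)] = np.clip(
            site[np.ix_(high, idx)] + config.outlier_delta, 0.01, 0.99
        )
        site[np.ix_(~high, idx)] = np.clip(
            site[np.ix_(~high, idx)] - config.outlier_delta, 0.01, 0.99
        )
        all_ids = [f"contig{j:06d}:50" for j in range(L)]
        outlier_ids = {all_ids[j] for j in idx}
    return TruthSet(
        config=config, ancestral_freqs=p, site_freqs=site,
        outlier_locus_ids=outlier_ids,
    )


def _build_sample_table(config: SimConfig) -> SampleTable:
    rows = []
    for (_, site), n in zip(DEFAULT_SITES.iterrows(), config.site_sample_sizes()):
        for k in range(n):
            rows.append(
                {
                    "individual_id": f"{site.site_id}_{k:03d}",
                    "site_id": site.site_id,
                    "transect_id": site.transect_id,
                    "elevation_class": site.elevation_class,
                    "latitude": site.latitude,
                    "longitude": site.longitude,
                    "elevation_m": site.elevation_m,
                }
            )
    return SampleTable(pd.DataFrame(rows))


def simulate_genotypes(truth: TruthSet, config: SimConfig | None = None) -> TruthSet:
    """Fill in Hardy-Weinberg genotypes: g ~ Binomial(2, p_site)."""
    config = config or truth.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    samples = _build_sample_table(config)
    site_ids = DEFAULT_SITES["site_id"].tolist()
    site_index = {s: i for i, s in enumerate(site_ids)}
    site_of = samples.frame["site_id"].map(site_index).to_numpy()
    p_ind = truth.site_freqs[site_of, :]        # N x L
    truth.true_genotypes = rng.binomial(2, p_ind)
    truth.samples = samples
    return truth


def simulate_likelihoods(
    truth: TruthSet, config: SimConfig | None = None
) -> GenotypeLikelihoodMatrix:
    """Simulate read depths and genotype likelihoods from true genotypes.

    Depth ~ NegativeBinomial(mean=depth_mean, dispersion=depth_dispersion)
    (parameterized so variance = mean + mean^2/dispersion); alternate-read
    count ~ Binomial(depth, mu_g) with mu = (eps, 0.5, 1-eps); the
    likelihood of each genotype is the binomial pmf of the read count, and
    triples are max-normalized with depth 0 mapping to (1, 1, 1).
    """
    config = config or truth.config
    if truth.true_genotypes is None:
        raise ValidationError("genotypes not simulated yet")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    g = truth.true_genotypes
    n, L = g.shape
    r = config.depth_dispersion
    p_nb = r / (r + config.depth_mean)
    depths = rng.negative_binomial(r, p_nb, size=(n, L))
    eps = config.error_rate
    mu = np.array([eps, 0.5, 1.0 - eps])
    k = rng.binomial(depths, mu[g])
    lik = np.stack(
        [stats.binom.pmf(k, depths, m) for m in mu], axis=-1
    )
    peak = lik.max(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        lik = np.where(peak > 0, lik / peak, 1.0)
    lik[depths == 0] = 1.0
    loci = [
        LocusRecord(f"contig{j:06d}:50", f"contig{j:06d}", 50, "A", "G")
        for j in range(L)
    ]
    assert truth.samples is not None
    return GenotypeLikelihoodMatrix(
        individuals=truth.samples.individuals,
        loci=loci,
        likelihoods=lik,
        depths=depths,
    )


def likelihood_triple(depth: int, alt_reads: int, error_rate: float) -> np.ndarray:
    """Max-normalized genotype-likelihood triple for one read pileup.

    The likelihood of genotype g is the binomial pmf of ``alt_reads`` out of
    ``depth`` at success probability (eps, 0.5, 1-eps) for g = (0, 1, 2).
    Zero depth returns the uninformative (1, 1, 1).
    """
    if depth == 0:
        return np.ones(3)
    mu = np.array([error_rate, 0.5, 1.0 - error_rate])
    lik = stats.binom.pmf(alt_reads, depth, mu)
    return lik / lik.max()


def simulate_dataset(
    config: SimConfig,
) -> tuple[GenotypeLikelihoodMatrix, SampleTable, TruthSet]:
    """Run the full generator: frequencies -> genotypes -> likelihoods."""
    truth = simulate_site_frequencies(config)
    truth = simulate_genotypes(truth, config)
    gl = simulate_likelihoods(truth, config)
    assert truth.samples is not None
    return gl, truth.samples, truth
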