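"""Hierarchical Bayesian genotype calling from genotype likelihoods.

A Gibbs sampler per locus and group (by default, per sampling site)
alternates two conjugate updates:

  (i)  given the group's current alternate-allele frequency p, each
       individual's genotype g in {0, 1, 2} is drawn with probability
       proportional to likelihood(reads | g) x HWE(g | p), where
       HWE = ((1-p)^2, 2p(1-p), p^2);
  (ii) given the genotypes, p is drawn from
       Beta(1 + #alt alleles, 1 + #ref alleles) (a flat Beta(1, 1) prior).

Averages over retained (post-burn-in, thinned) samples give the posterior
genotype probabilities, the composite genotype on the 0-2 scale, and the
posterior-mean allele frequency per group x locus.  Individuals with low
coverage at a locus are thereby pulled toward the group allele-frequency
prior, while well-covered genotypes are driven by their likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import (
    GenotypeLikelihoodMatrix,
    GenotypeMatrix,
    SampleTable,
    ValidationError,
)


@dataclass
class McmcSettings:
    """Sampler schedule; defaults match the analysis's published run length."""

    n_steps: int = 10_000
    burn_in: int = 6_000
    thin: int = 2
    seed: int = 0
    grouping: str = "per_site"  # or "pooled"

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_steps:
            raise ValidationError("burn_in must be smaller than n_steps")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if self.n_retained < 100:
            raise ValidationError(
                f"retained samples {self.n_retained} < 100; lengthen the chain"
            )
        if self.grouping not in ("per_site", "pooled"):
            raise ValidationError("grouping must be 'per_site' or 'pooled'")

    @property
    def n_retained(self) -> int:
        return (self.n_steps - self.burn_in) // self.thin


def _group_assignments(
    gl: GenotypeLikelihoodMatrix, samples: SampleTable, grouping: str
) -> tuple[list[str], np.ndarray]:
    if grouping == "pooled":
        return ["pooled"], np.zeros(gl.n_individuals, dtype=int)
    site_of = samples.site_of()
    missing = [ind for ind in gl.individuals if ind not in site_of]
    if missing:
        raise ValidationError(f"individuals missing from metadata: {missing[:5]}")
    groups = sorted({site_of[ind] for ind in gl.individuals})
    index = {g: i for i, g in enumerate(groups)}
    assign = np.array([index[site_of[ind]] for ind in gl.individuals])
    counts = np.bincount(assign, minlength=len(groups))
    if (counts == 0).any():
        empty = [g for g, c in zip(groups, counts) if c == 0]
        raise ValidationError(f"groups with zero individuals: {empty}")
    return groups, assign


def fit_genotype_model(
    gl: GenotypeLikelihoodMatrix,
    samples: SampleTable,
    settings: McmcSettings | None = None,
) -> GenotypeMatrix:
    """Run the Gibbs sampler and return posterior genotype summaries."""
    settings = settings or McmcSettings()
    groups, assign = _group_assignments(gl, samples, settings.grouping)
    rng = np.random.default_rng(settings.seed)
    lik = gl.likelihoods                       # N x L x 3
    n, L, _ = lik.shape
    n_groups = len(groups)
    group_rows = [np.flatnonzero(assign == s) for s in range(n_groups)]
    group_sizes = np.array([len(r) for r in group_rows])

    # init: likelihood-argmax genotypes, naive per-group frequencies
    g = lik.argmax(axis=2)
    p = np.empty((n_groups, L))
    for s, rows in enumerate(group_rows):
        p[s] = g[rows].mean(axis=0) / 2.0
    p = np.clip(p, 1e-6, 1 - 1e-6)

    post_counts = np.zeros((3, n, L))
    p_sum = np.zeros((n_groups, L))
    retained = 0
    gidx = assign  # alias: group of each individual

    for step in range(settings.n_steps):
        # (i) genotype update
        q = p[gidx]                                        # N x L
        hwe = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=-1)
        w = lik * hwe
        w_sum = w.sum(axis=2, keepdims=True)
        # guard: all-zero weights cannot occur since hwe>0 when p in (0,1)
        w /= w_sum
        u = rng.random((n, L))
        c0 = w[:, :, 0]
        g = (u >= c0).astype(np.int8) + (u >= c0 + w[:, :, 1])
        # (ii) frequency update
        for s, rows in enumerate(group_rows):
            alt = g[rows].sum(axis=0)
            ref = 2 * group_sizes[s] - alt
            p[s] = rng.beta(1.0 + alt, 1.0 + ref)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        if step >= settings.burn_in and (step - settings.burn_in) % settings.thin == 0:
            for val in range(3):
                post_counts[val] += g == val
            p_sum += p
            retained += 1

    posterior = np.moveaxis(post_counts, 0, -1) / retained
    composite = posterior[:, :, 1] + 2.0 * posterior[:, :, 2]
    allele_freqs = pd.DataFrame(
        p_sum / retained, index=groups, columns=gl.locus_ids
    )
    return GenotypeMatrix(
        individuals=list(gl.individuals),
        loci=list(gl.loci),
        composite=composite,
        posterior=posterior,
        allele_freqs=allele_freqs,
    )


def genotype_certainty_mask(gm: GenotypeMatrix, tol: float = 0.1) -> np.ndarray:
    """Boolean N x L mask: True where the composite genotype is within
    ``tol`` of an integer genotype (0, 1 or 2), boundary inclusive.

    Entries failing the test are treated as missing data downstream (the
    hierarchical variance analysis uses only high-certainty genotypes).
    """
    if tol >= 0.5:
        raise ValidationError("tol >= 0.5 would make certainty bands overlap")
    comp = gm.composite
    dist = np.min(
        np.abs(comp[:, :, None] - np.array([0.0, 1.0, 2.0])[None, None, :]),
        axis=2,
    )
    return dist <= tol + 1e-12  # boundary inclusive up to float rounding
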