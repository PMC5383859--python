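"""SNP retention rules applied to genotype-likelihood data.

Three stages, applied in order: (1) presence and minor-allele-frequency
screening (a locus must be covered by at least one read in >=90% of
individuals and have a naive MAF >= 5%); (2) random selection of a single
SNP per contig to reduce linkage; (3) coverage-depth windows (mean depth
per locus in [4, 15]x, then mean depth per individual over retained loci in
[3, 10]x, inclusive at both ends).  The naive allele frequency is computed
from likelihood-weighted expected genotypes, upstream of the Bayesian
genotype model, preserving the filter -> model ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import GenotypeLikelihoodMatrix, ValidationError


@dataclass
class FilterConfig:
    min_presence: float = 0.90
    min_maf: float = 0.05
    locus_depth_min: float = 4.0
    locus_depth_max: float = 15.0
    individual_depth_min: float = 3.0
    individual_depth_max: float = 10.0
    one_per_contig: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_presence <= 1:
            raise ValidationError("min_presence must lie in (0, 1]")
        if not 0 <= self.min_maf < 0.5:
            raise ValidationError("min_maf must lie in [0, 0.5)")
        if self.locus_depth_min >= self.locus_depth_max:
            raise ValidationError("locus depth window inverted")
        if self.individual_depth_min >= self.individual_depth_max:
            raise ValidationError("individual depth window inverted")


@dataclass
class RemovalLog:
    """Per-rule removal counts; every input locus is attributed to the
    first rule that removed it (or retained)."""

    n_input_loci: int = 0
    removed_presence: int = 0
    removed_maf: int = 0
    removed_contig_dedup: int = 0
    removed_locus_depth: int = 0
    n_retained_loci: int = 0
    n_input_individuals: int = 0
    removed_individual_depth: int = 0
    n_retained_individuals: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"rule": k, "count": v} for k, v in self.__dict__.items()]
        )


def expected_genotypes(gl: GenotypeLikelihoodMatrix) -> np.ndarray:
    """Likelihood-weighted expected genotype per individual x locus.

    Triples are normalized to sum to one; a depth-0 (uninformative) triple
    yields the flat expectation 1.0.
    """
    lik = gl.likelihoods
    total = lik.sum(axis=2)
    return (lik[:, :, 1] + 2.0 * lik[:, :, 2]) / total


def naive_allele_freq(gl: GenotypeLikelihoodMatrix) -> np.ndarray:
    """Naive alternate-allele frequency per locus over covered individuals."""
    eg = expected_genotypes(gl)
    observed = gl.depths >= 1
    n_obs = observed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, (eg * observed).sum(axis=0) / (2.0 * n_obs), np.nan)
    return p


def filter_presence_maf(
    gl: GenotypeLikelihoodMatrix, cfg: FilterConfig, log: RemovalLog | None = None
) -> tuple[GenotypeLikelihoodMatrix, RemovalLog]:
    """Retain loci covered in >= min_presence of individuals with naive
    MAF >= min_maf (boundary inclusive)."""
    if gl.n_loci == 0 or gl.n_individuals == 0:
        raise ValidationError("empty genotype-likelihood matrix")
    log = log or RemovalLog(
        n_input_loci=gl.n_loci, n_input_individuals=gl.n_individuals
    )
    presence = (gl.depths >= 1).mean(axis=0)
    present_ok = presence >= cfg.min_presence
    p = naive_allele_freq(gl)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    maf_ok = np.where(np.isnan(maf), False, maf >= cfg.min_maf)
    keep = present_ok & maf_ok
    log.removed_presence += int((~present_ok).sum())
    log.removed_maf += int((present_ok & ~maf_ok).sum())
    return gl.take_loci(np.flatnonzero(keep)), log


def select_one_snp_per_contig(
    gl: GenotypeLikelihoodMatrix, seed: int, log: RemovalLog | None = None
) -> tuple[GenotypeLikelihoodMatrix, RemovalLog]:
    """Keep exactly one SNP per contig, chosen uniformly at random."""
    rng = np.random.default_rng(seed)
    log = log or RemovalLog(
        n_input_loci=gl.n_loci, n_input_individuals=gl.n_individuals
    )
    by_contig: dict[str, list[int]] = {}
    for j, rec in enumerate(gl.loci):
        by_contig.setdefault(rec.contig_id, []).append(j)
    keep = sorted(
        idx[rng.integers(len(idx))] if len(idx) > 1 else idx[0]
        for idx in by_contig.values()
    )
    log.removed_contig_dedup += gl.n_loci - len(keep)
    return gl.take_loci(np.asarray(keep, dtype=int)), log


def filter_depth_windows(
    gl: GenotypeLikelihoodMatrix, cfg: FilterConfig, log: RemovalLog | None = None
) -> tuple[GenotypeLikelihoodMatrix, RemovalLog]:
    """Apply the mean-depth windows: loci first, then individuals."""
    log = log or RemovalLog(
        n_input_loci=gl.n_loci, n_input_individuals=gl.n_individuals
    )
    locus_mean = gl.depths.mean(axis=0)
    locus_ok = (locus_mean >= cfg.locus_depth_min) & (locus_mean <= cfg.locus_depth_max)
    log.removed_locus_depth += int((~locus_ok).sum())
    if not locus_ok.any():
        raise ValidationError(
            "depth window removed every locus "
            f"(mean locus depth range {locus_mean.min():.2f}-{locus_mean.max():.2f}, "
            f"window [{cfg.locus_depth_min}, {cfg.locus_depth_max}])"
        )
    out = gl.take_loci(np.flatnonzero(locus_ok))
    ind_mean = out.depths.mean(axis=1)
    ind_ok = (ind_mean >= cfg.individual_depth_min) & (
        ind_mean <= cfg.individual_depth_max
    )
    log.removed_individual_depth += int((~ind_ok).sum())
    if not ind_ok.any():
        raise ValidationError("depth window removed every individual")
    out = out.take_individuals(np.flatnonzero(ind_ok))
    log.n_retained_loci = out.n_loci
    log.n_retained_individuals = out.n_individuals
    return out, log


def apply_all_filters(
    gl: GenotypeLikelihoodMatrix, cfg: FilterConfig
) -> tuple[GenotypeLikelihoodMatrix, RemovalLog]:
    """Full filter chain: presence/MAF -> one-per-contig -> depth windows."""
    log = RemovalLog(n_input_loci=gl.n_loci, n_input_individuals=gl.n_individuals)
    out, log = filter_presence_maf(gl, cfg, log)
    if cfg.one_per_contig:
        out, log = select_one_snp_per_contig(out, cfg.seed, log)
    out, log = filter_depth_windows(out, cfg, log)
    return out, log
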