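"""End-to-end pipeline: ingest or simulate -> filters -> genotype model ->
structure, differentiation, AMOVA, distance regression, parallel test.

A single master seed deterministically derives a seed per stage (via
``numpy.random.SeedSequence`` spawn keys), so any stage can be re-run
independently and the whole bundle is reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io
from .data_io import GenotypeLikelihoodMatrix, SampleTable
from .differentiation import all_pairwise
from .genotype_model import McmcSettings, fit_genotype_model, genotype_certainty_mask
from .hierarchy_amova import amova, amova_permutation_test
from .locus_filters import FilterConfig, apply_all_filters
from .parallel_divergence import parallel_divergence_test
from .spatial_regression import mrm, pairwise_distance_matrices
from .structure_ordination import (
    dapc_assign,
    dapc_find_clusters,
    pca_genotypes,
    permanova,
)
from .synthetic_gbs import SimConfig, simulate_dataset
from .data_io import DistanceMatrix

logger = logging.getLogger("chickpop")

STAGES = (
    "simulate", "filters", "genotype_model", "structure",
    "pairwise", "amova", "mrm", "parallel",
)


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed from the master seed and stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Everything a full run needs; defaults follow the published analysis
    settings (100 pairwise permutations, 999 for PERMANOVA/AMOVA/MRM,
    10 000 for the parallel test; MCMC 10 000/6 000/thin 2; certainty 0.1)."""

    sim: SimConfig | None = None
    gl_path: str | None = None
    gl_dialect: str = "matrix_tsv"
    metadata_path: str | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    # pooled allele-frequency prior by default: building priors from the
    # site labels that the downstream structure tests then examine would
    # shrink individuals toward their site means and bias those tests
    mcmc: McmcSettings = field(
        default_factory=lambda: McmcSettings(grouping="pooled")
    )
    n_perm_pairwise: int = 100
    n_perm_structure: int = 999
    n_perm_amova: int = 999
    n_perm_mrm: int = 999
    n_perm_parallel: int = 10_000
    quantiles: tuple[float, ...] = (0.97, 0.98, 0.99)
    certainty_tol: float = 0.1
    dapc_n_pcs: int = 1          # PCs retained for the discriminant step
    dapc_cluster_n_pcs: int = 60  # PCs for the k-means cluster search
    dapc_k_max: int = 6
    master_seed: int = 0

    def resolve_inputs(self) -> tuple[GenotypeLikelihoodMatrix, SampleTable]:
        if self.sim is not None:
            sim = self.sim
            if sim.seed != derive_seed(self.master_seed, "simulate"):
                sim = SimConfig(**{**asdict(sim), "seed": derive_seed(self.master_seed, "simulate")})
            gl, samples, _ = simulate_dataset(sim)
            return gl, samples
        if self.gl_path is None or self.metadata_path is None:
            raise data_io.ValidationError(
                "provide either a SimConfig or genotype-likelihood + metadata paths"
            )
        gl = data_io.read_genotype_likelihoods(self.gl_path, self.gl_dialect)
        samples = data_io.read_metadata(self.metadata_path)
        return gl, samples


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write the report bundle to ``out_dir``.

    Emits: pairwise differentiation table, parallel-divergence table, PCA
    scores, DAPC BIC/assignments, PERMANOVA summaries, AMOVA summary, MRM
    summaries, and a manifest JSON.  Returns the in-memory results dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "master_seed": config.master_seed,
        "stage_seeds": {s: derive_seed(config.master_seed, s) for s in STAGES},
        "parameters": {
            "n_perm_pairwise": config.n_perm_pairwise,
            "n_perm_structure": config.n_perm_structure,
            "n_perm_amova": config.n_perm_amova,
            "n_perm_mrm": config.n_perm_mrm,
            "n_perm_parallel": config.n_perm_parallel,
            "quantiles": list(config.quantiles),
            "certainty_tol": config.certainty_tol,
            "mcmc": asdict(config.mcmc),
            "filters": asdict(config.filters),
            "sim": asdict(config.sim) if config.sim else None,
        },
        "timings_s": {},
    }
    results: dict = {}

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                logger.info("stage %s", name)
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                manifest["timings_s"][name] = round(
                    time.perf_counter() - self_inner.t0, 3
                )
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                    data_io.write_manifest(manifest, out / "manifest.json")
                return False

        return _Timer()

    with stage("simulate"):
        gl, samples = config.resolve_inputs()
        manifest["n_input_individuals"] = gl.n_individuals
        manifest["n_input_loci"] = gl.n_loci

    with stage("filters"):
        cfg = config.filters
        if cfg.seed != derive_seed(config.master_seed, "filters"):
            cfg = FilterConfig(**{**asdict(cfg), "seed": derive_seed(config.master_seed, "filters")})
        gl, removal_log = apply_all_filters(gl, cfg)
        samples = samples.subset(gl.individuals)
        removal_log.to_frame().to_csv(out / "removals.tsv", sep="\t", index=False)
        manifest["n_retained_individuals"] = gl.n_individuals
        manifest["n_retained_loci"] = gl.n_loci

    with stage("genotype_model"):
        mcmc = config.mcmc
        if mcmc.seed != derive_seed(config.master_seed, "genotype_model"):
            mcmc = McmcSettings(**{**asdict(mcmc), "seed": derive_seed(config.master_seed, "genotype_model")})
        gm = fit_genotype_model(gl, samples, mcmc)
        pd.DataFrame(
            gm.composite, index=gm.individuals, columns=gm.locus_ids
        ).to_csv(out / "composite.tsv", sep="\t")
        gm.allele_freqs.to_csv(out / "allele_freqs.tsv", sep="\t")
        results["genotypes"] = gm

    with stage("structure"):
        seed = derive_seed(config.master_seed, "structure")
        pca = pca_genotypes(gm)
        site_labels = [samples.site_of()[ind] for ind in gm.individuals]
        elev_of = dict(zip(samples.frame["individual_id"], samples.frame["elevation_class"]))
        elev_labels = [elev_of[ind] for ind in gm.individuals]
        perm_sites = permanova(
            pca.scores[:, :2], site_labels, n_perm=config.n_perm_structure, seed=seed
        )
        perm_elev = permanova(
            pca.scores[:, :2], elev_labels, n_perm=config.n_perm_structure,
            seed=seed + 1,
        )
        # cluster search over many PCs (a near-lossless transform of the
        # data); the low-dimensional retained-PC choice applies only to the
        # discriminant step
        cluster_pcs = min(config.dapc_cluster_n_pcs, pca.scores.shape[1])
        clusters = dapc_find_clusters(
            pca.scores, n_pcs=cluster_pcs, k_max=config.dapc_k_max, seed=seed
        )
        if clusters.best_k >= 2:
            dapc = dapc_assign(pca.scores, clusters.cluster_labels, config.dapc_n_pcs)
            pd.DataFrame(
                dapc.assignments, index=gm.individuals
            ).to_csv(out / "dapc_assignments.tsv", sep="\t")
        scores = pd.DataFrame(
            pca.scores[:, :10], index=gm.individuals,
            columns=[f"PC{i+1}" for i in range(min(10, pca.scores.shape[1]))],
        )
        scores.insert(0, "site", site_labels)
        scores.to_csv(out / "pca_scores.tsv", sep="\t")
        pd.DataFrame(
            {"k": list(clusters.bic_by_k), "bic": list(clusters.bic_by_k.values())}
        ).to_csv(out / "dapc_bic.tsv", sep="\t", index=False)
        data_io.write_results_tables(
            [
                {"test": "permanova_sites", **perm_sites.to_record()},
                {"test": "permanova_elevation", **perm_elev.to_record()},
            ],
            out / "permanova.tsv",
        )
        results["pca"] = pca
        results["permanova_sites"] = perm_sites
        results["permanova_elevation"] = perm_elev
        results["dapc"] = clusters

    with stage("pairwise"):
        seed = derive_seed(config.master_seed, "pairwise")
        pairwise = all_pairwise(gm, samples, n_perm=config.n_perm_pairwise, seed=seed)
        data_io.write_results_tables(pairwise, out / "pairwise_fst.tsv")
        results["pairwise"] = pairwise

    with stage("amova"):
        seed = derive_seed(config.master_seed, "amova")
        mask = genotype_certainty_mask(gm, config.certainty_tol)
        am = amova(gm, samples, mask)
        am = amova_permutation_test(
            gm, samples, mask, n_perm=config.n_perm_amova, seed=seed, result=am
        )
        data_io.write_results_tables([am.to_record()], out / "amova.tsv")
        results["amova"] = am

    with stage("mrm"):
        seed = derive_seed(config.master_seed, "mrm")
        geo, elev = pairwise_distance_matrices(samples)
        sites = geo.labels
        idx = {s: i for i, s in enumerate(sites)}
        k = len(sites)
        nei = np.zeros((k, k))
        fstm = np.zeros((k, k))
        for pr in results["pairwise"]:
            i, j = idx[pr.site_a], idx[pr.site_b]
            nei[i, j] = nei[j, i] = pr.nei_d
            fstm[i, j] = fstm[j, i] = pr.observed_fst
        nei_dm = DistanceMatrix(sites, nei, kind="nei")
        fst_dm = DistanceMatrix(sites, fstm, kind="fst")
        mrm_nei = mrm(nei_dm, [geo, elev], n_perm=config.n_perm_mrm, seed=seed)
        mrm_fst = mrm(fst_dm, [geo, elev], n_perm=config.n_perm_mrm, seed=seed + 1)
        mantel_geo = mrm(nei_dm, [geo], n_perm=config.n_perm_mrm, seed=seed + 2)
        mantel_elev = mrm(nei_dm, [elev], n_perm=config.n_perm_mrm, seed=seed + 3)
        data_io.write_results_tables(
            [
                {"model": "nei~geo+elev", **mrm_nei.to_record()},
                {"model": "fst~geo+elev", **mrm_fst.to_record()},
                {"model": "nei~geo", **mantel_geo.to_record()},
                {"model": "nei~elev", **mantel_elev.to_record()},
            ],
            out / "mrm.tsv",
        )
        results["mrm_nei"] = mrm_nei
        results["mrm_fst"] = mrm_fst
        results["mantel_geo"] = mantel_geo
        results["mantel_elev"] = mantel_elev

    with stage("parallel"):
        seed = derive_seed(config.master_seed, "parallel")
        min_defined = min(100, max(10, gl.n_loci // 10))
        parallel = parallel_divergence_test(
            gm, samples, quantiles=config.quantiles,
            n_perm=config.n_perm_parallel, seed=seed, min_defined=min_defined,
        )
        data_io.write_results_tables(parallel, out / "parallel_divergence.tsv")
        results["parallel"] = parallel

    data_io.write_manifest(manifest, out / "manifest.json")
    results["manifest"] = manifest
    return results
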