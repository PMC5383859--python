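"""Gibbs genotype model: limits, shrinkage behavior, and an exact oracle."""

import numpy as np
import pandas as pd
import pytest

from chickpop.data_io import GenotypeMatrix, ValidationError
from chickpop.genotype_model import (
    McmcSettings,
    fit_genotype_model,
    genotype_certainty_mask,
)
from chickpop.synthetic_gbs import SimConfig, likelihood_triple, simulate_dataset

from conftest import make_gl, make_sample_table

SHORT = dict(n_steps=1500, burn_in=700, thin=2)


def _single_site_table(n):
    table = make_sample_table(n_per_site=n)
    return table


class TestSettings:
    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValidationError):
            McmcSettings(n_steps=100, burn_in=200)
        with pytest.raises(ValidationError):
            McmcSettings(thin=0)
        with pytest.raises(ValidationError):
            McmcSettings(n_steps=300, burn_in=200, thin=2)  # < 100 retained

    def test_default_schedule_retains_2000_samples(self):
        assert McmcSettings().n_retained == 2000


class TestLimits:
    def test_no_data_locus_is_prior_driven(self):
        # every individual depth 0 -> p mixes over its flat prior, so the
        # posterior genotype mass is E[HWE(g|p)] = (1/3, 1/3, 1/3); the
        # frequency chain is a slow random walk here, hence the long run
        n = 8
        lik = np.ones((n, 2, 3))
        depths = np.zeros((n, 2), dtype=int)
        # second locus has strong alt-homozygote data (anchors nothing at locus 0)
        lik[:, 1] = likelihood_triple(20, 20, 0.01)
        depths[:, 1] = 20
        gl = make_gl(lik, depths, individuals=[f"SH_H_{i}" for i in range(n)])
        samples = pd.DataFrame(
            dict(individual_id=gl.individuals, site_id="SH_H", transect_id="SH",
                 elevation_class="high", latitude=39.4, longitude=-120.3,
                 elevation_m=2428.0)
        )
        # complete the 6-site hierarchy with placeholder sites
        extra = make_sample_table(1).frame
        extra = extra[extra["site_id"] != "SH_H"]
        from chickpop.data_io import SampleTable
        table = SampleTable(pd.concat([samples, extra], ignore_index=True))
        settings = McmcSettings(n_steps=30_000, burn_in=3_000, thin=1, seed=1)
        gm = fit_genotype_model(gl, table, settings)
        rows = [gm.individuals.index(i) for i in samples["individual_id"]]
        assert gm.composite[rows, 0].mean() == pytest.approx(1.0, abs=0.05)
        assert gm.posterior[rows, 0, :].mean(axis=0) == pytest.approx(
            np.full(3, 1 / 3), abs=0.05
        )
        assert gm.composite[rows, 1].min() > 1.95

    def test_overwhelming_likelihood_dominates_prior(self):
        # one alt-homozygote individual among many ref-homozygotes
        n = 12
        lik = np.tile(likelihood_triple(20, 0, 0.01), (n, 1, 1)).reshape(n, 1, 3)
        lik[0, 0] = likelihood_triple(50, 50, 0.01)
        depths = np.full((n, 1), 20)
        depths[0, 0] = 50
        gl = make_gl(lik, depths)
        table = make_sample_table(2)
        gl.individuals[:] = table.individuals[:n]
        settings = McmcSettings(seed=2, grouping="pooled", **SHORT)
        gm = fit_genotype_model(gl, table, settings)
        assert gm.composite[0, 0] >= 1.98
        assert gm.composite[1:, 0].max() <= 0.02

    def test_low_coverage_individual_shrinks_to_group_frequency(self):
        # 23 individuals nearly fixed for alt; one with no reads should sit
        # near 2*p_group, not at the flat-prior value 1
        n = 24
        lik = np.tile(likelihood_triple(20, 20, 0.01), (n, 1, 1)).reshape(n, 1, 3)
        lik[0, 0] = 1.0
        depths = np.full((n, 1), 20)
        depths[0, 0] = 0
        gl = make_gl(lik, depths, individuals=[f"ind{i}" for i in range(n)])
        table = make_sample_table(4)
        gl.individuals[:] = table.individuals[:n]
        settings = McmcSettings(seed=3, grouping="pooled", **SHORT)
        gm = fit_genotype_model(gl, table, settings)
        # p_group ~ (1 + 46)/(48 + ...) ~ 0.96 -> composite ~ 1.9
        assert gm.composite[0, 0] > 1.7

    def test_deep_coverage_converges_to_true_genotype(self):
        lik = np.tile(likelihood_triple(100, 100, 0.01), (8, 1, 1)).reshape(8, 1, 3)
        depths = np.full((8, 1), 100)
        gl = make_gl(lik, depths)
        table = make_sample_table(2)
        gl.individuals[:] = table.individuals[:8]
        gm = fit_genotype_model(gl, table, McmcSettings(seed=4, grouping="pooled", **SHORT))
        assert np.abs(gm.composite - 2.0).max() < 0.01


class TestProperties:
    def test_posterior_sums_and_composite_identity(self):
        cfg = SimConfig(n_loci=40, samples_per_site=4, seed=8)
        gl, samples, _ = simulate_dataset(cfg)
        gm = fit_genotype_model(gl, samples, McmcSettings(seed=5, **SHORT))
        np.testing.assert_allclose(gm.posterior.sum(axis=2), 1.0, atol=1e-8)
        np.testing.assert_allclose(
            gm.composite, gm.posterior[:, :, 1] + 2 * gm.posterior[:, :, 2],
            atol=1e-8,
        )

    def test_monotonic_in_alt_reads(self):
        # composites for one individual with k = 0..6 alt reads out of 6
        composites = []
        table = make_sample_table(2)
        for k in range(7):
            lik = np.tile(likelihood_triple(6, 3, 0.01), (8, 1, 1)).reshape(8, 1, 3)
            lik[0, 0] = likelihood_triple(6, k, 0.01)
            gl = make_gl(lik, np.full((8, 1), 6))
            gl.individuals[:] = table.individuals[:8]
            gm = fit_genotype_model(
                gl, table, McmcSettings(seed=6, grouping="pooled", **SHORT)
            )
            composites.append(gm.composite[0, 0])
        diffs = np.diff(composites)
        assert (diffs > -0.02).all()  # non-decreasing up to MCMC error

    def test_seed_stability_rms(self):
        cfg = SimConfig(n_loci=120, samples_per_site=4, depth_mean=6.0, seed=9)
        gl, samples, _ = simulate_dataset(cfg)
        long = dict(n_steps=5000, burn_in=1000, thin=2)
        a = fit_genotype_model(gl, samples, McmcSettings(seed=10, **long))
        b = fit_genotype_model(gl, samples, McmcSettings(seed=11, **long))
        rms = np.sqrt(((a.composite - b.composite) ** 2).mean())
        assert rms < 0.02

    def test_gibbs_matches_exact_grid_posterior(self):
        # 3 individuals, 1 locus: integrate the joint posterior over p on a
        # fine grid and compare marginal genotype probabilities
        triples = np.array(
            [
                likelihood_triple(4, 2, 0.01),
                likelihood_triple(2, 0, 0.01),
                likelihood_triple(1, 1, 0.01),
            ]
        )
        grid = np.linspace(1e-4, 1 - 1e-4, 10_000)
        hwe = np.stack(
            [(1 - grid) ** 2, 2 * grid * (1 - grid), grid**2], axis=1
        )  # G x 3
        per_ind = triples[:, None, :] * hwe[None, :, :]     # 3 x G x 3
        marg = per_ind.sum(axis=2)                          # P(data_i | p)
        post_p = marg.prod(axis=0)                          # flat prior on p
        oracle = np.empty((3, 3))
        for i in range(3):
            others = post_p / marg[i]
            weights = per_ind[i] * others[:, None]
            oracle[i] = weights.sum(axis=0) / weights.sum()

        lik = triples.reshape(3, 1, 3)
        gl = make_gl(lik, np.array([[4], [2], [1]]))
        table = make_sample_table(1)
        gl.individuals[:] = table.individuals[:3]
        gm = fit_genotype_model(
            gl, table,
            McmcSettings(n_steps=40_000, burn_in=5_000, thin=1, seed=12,
                         grouping="pooled"),
        )
        np.testing.assert_allclose(gm.posterior[:, 0, :], oracle, atol=0.01)


class TestCertaintyMask:
    def _gm(self, composites):
        comp = np.asarray(composites, dtype=float).reshape(1, -1)
        # build a consistent posterior for each composite value
        post = np.zeros((1, comp.shape[1], 3))
        for j, c in enumerate(comp[0]):
            if c <= 1:
                post[0, j] = [1 - c, c, 0.0]
            else:
                post[0, j] = [0.0, 2 - c, c - 1]
        loci = make_gl(np.ones((1, comp.shape[1], 3)),
                       np.ones((1, comp.shape[1]), dtype=int)).loci
        freqs = pd.DataFrame(
            comp / 2, index=["pooled"], columns=[r.locus_id for r in loci]
        )
        return GenotypeMatrix(["i0"], loci, comp, post, freqs)

    def test_boundary_inclusive_band(self):
        gm = self._gm([0.08, 0.50, 1.10, 1.90, 0.11])
        mask = genotype_certainty_mask(gm, tol=0.1)
        np.testing.assert_array_equal(mask[0], [True, False, True, True, False])

    def test_overlapping_bands_rejected(self):
        gm = self._gm([0.5])
        with pytest.raises(ValidationError):
            genotype_certainty_mask(gm, tol=0.5)
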