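"""Hierarchical analysis of molecular variance (AMOVA).

Partitions genetic variance over the nested hierarchy transect > site >
individual using squared Euclidean distances between individuals'
composite-genotype vectors.  Genotypes failing the certainty mask are
treated as missing; distances are pairwise-complete, rescaled by the
fraction of loci both individuals share.

Sums of squares follow the standard distance-based decomposition
(SS of a stratum = sum over within-stratum pairs of d^2 / stratum size),
and variance components come from the nested moment equations with
unequal-sample-size coefficients:

    n1 = (N - sum_g sum_{s in g} n_s^2 / N_g) / (S - G)
    n2 = (sum_g sum_{s in g} n_s^2 / N_g - sum_s n_s^2 / N) / (G - 1)
    n3 = (N - sum_g N_g^2 / N) / (G - 1)

with sigma2_within = MS_within, sigma2_sites = (MS_sites - MS_within)/n1,
sigma2_transects = (MS_transects - MS_within - n2*sigma2_sites)/n3.
phi_CT = s2_a/total, phi_SC = s2_b/(s2_b+s2_c), phi_ST = (s2_a+s2_b)/total.
Negative components are reported as-is with a flag (truncation would bias
the percentages).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import GenotypeMatrix, SampleTable, ValidationError


@dataclass
class AmovaResult:
    sigma2_among_transects: float
    sigma2_among_sites_within: float
    sigma2_within: float
    pct: tuple[float, float, float]
    phi_CT: float
    phi_SC: float
    phi_ST: float
    p_CT: float | None = None
    p_SC: float | None = None
    p_ST: float | None = None
    degenerate: bool = False
    negative_components: bool = False

    def to_record(self) -> dict:
        return {
            "sigma2_among_transects": self.sigma2_among_transects,
            "sigma2_among_sites_within": self.sigma2_among_sites_within,
            "sigma2_within": self.sigma2_within,
            "pct_among_transects": self.pct[0],
            "pct_among_sites_within": self.pct[1],
            "pct_within": self.pct[2],
            "phi_CT": self.phi_CT, "phi_SC": self.phi_SC, "phi_ST": self.phi_ST,
            "p_CT": self.p_CT, "p_SC": self.p_SC, "p_ST": self.p_ST,
            "negative_components": self.negative_components,
        }


def pairwise_complete_sqdist(composite: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances over shared non-missing loci, rescaled
    by L / L_shared so sparsely-compared pairs are comparable."""
    x = np.where(mask, composite, 0.0)
    m = mask.astype(float)
    L = composite.shape[1]
    # sum over shared loci of (xi - xj)^2, computed via expansion
    sq = x**2
    shared = m @ m.T
    cross = x @ x.T
    si = sq @ m.T          # sum_i over loci shared with j of x_i^2
    d2 = si + si.T - 2 * cross
    if (shared == 0).any():
        off_diag = shared + np.eye(shared.shape[0]) * L
        if (off_diag == 0).any():
            raise ValidationError("some individual pairs share zero loci")
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = d2 * (L / np.maximum(shared, 1))
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def _amova_components(
    d2: np.ndarray, site_enc: np.ndarray, transect_of_site: np.ndarray
) -> tuple[float, float, float, float, float, float]:
    """Return (s2_a, s2_b, s2_c, phi_CT, phi_SC, phi_ST) for one labeling."""
    n = d2.shape[0]
    n_sites = transect_of_site.size
    n_transects = int(transect_of_site.max()) + 1
    tr_enc = transect_of_site[site_enc]

    site_sizes = np.bincount(site_enc, minlength=n_sites).astype(float)
    tr_sizes = np.bincount(tr_enc, minlength=n_transects).astype(float)

    def strata_ss(enc: np.ndarray, sizes: np.ndarray) -> float:
        total = 0.0
        for g in range(sizes.size):
            idx = np.flatnonzero(enc == g)
            if idx.size:
                total += d2[np.ix_(idx, idx)].sum() / (2.0 * sizes[g])
        return total

    ss_total = d2.sum() / (2.0 * n)
    ss_wp = strata_ss(site_enc, site_sizes)       # within sites
    ss_wt = strata_ss(tr_enc, tr_sizes)           # within transects
    ss_ap = ss_wt - ss_wp                         # among sites within transects
    ss_ag = ss_total - ss_wt                      # among transects

    df_ag = n_transects - 1
    df_ap = n_sites - n_transects
    df_wp = n - n_sites
    ms_wp = ss_wp / df_wp
    ms_ap = ss_ap / df_ap
    ms_ag = ss_ag / df_ag

    sum_ns2_over_Ng = 0.0
    for g in range(n_transects):
        sites_g = np.flatnonzero(transect_of_site == g)
        sum_ns2_over_Ng += (site_sizes[sites_g] ** 2).sum() / tr_sizes[g]
    n1 = (n - sum_ns2_over_Ng) / df_ap
    n2 = (sum_ns2_over_Ng - (site_sizes**2).sum() / n) / df_ag
    n3 = (n - (tr_sizes**2).sum() / n) / df_ag

    s2_c = ms_wp
    s2_b = (ms_ap - s2_c) / n1
    s2_a = (ms_ag - s2_c - n2 * s2_b) / n3
    total = s2_a + s2_b + s2_c
    phi_ct = s2_a / total
    phi_sc = s2_b / (s2_b + s2_c)
    phi_st = (s2_a + s2_b) / total
    return s2_a, s2_b, s2_c, phi_ct, phi_sc, phi_st


def _encode(gm: GenotypeMatrix, samples: SampleTable):
    site_of = samples.site_of()
    sites = samples.sites
    site_index = {s: i for i, s in enumerate(sites)}
    try:
        site_enc = np.array([site_index[site_of[ind]] for ind in gm.individuals])
    except KeyError as exc:
        raise ValidationError(f"individual missing from metadata: {exc}") from exc
    st = samples.site_table()
    transects = samples.transects
    tr_index = {t: i for i, t in enumerate(transects)}
    transect_of_site = np.array([tr_index[st.loc[s, "transect_id"]] for s in sites])
    return site_enc, transect_of_site


def amova(
    gm: GenotypeMatrix,
    samples: SampleTable,
    mask: np.ndarray | None = None,
) -> AmovaResult:
    """Nested AMOVA of composite genotypes over transects > sites > within.

    ``mask`` flags high-certainty genotypes (True = use); masked-out
    entries are missing and handled pairwise-complete.
    """
    site_enc, transect_of_site = _encode(gm, samples)
    counts = np.bincount(site_enc, minlength=transect_of_site.size)
    if (counts < 2).any():
        bad = [samples.sites[i] for i in np.flatnonzero(counts < 2)]
        raise ValidationError(f"sites with < 2 individuals: {bad}")
    if mask is None:
        mask = np.ones_like(gm.composite, dtype=bool)
    d2 = pairwise_complete_sqdist(gm.composite, mask)
    if d2.max() == 0:
        return AmovaResult(
            0.0, 0.0, 0.0, (float("nan"),) * 3,
            float("nan"), float("nan"), float("nan"), degenerate=True,
        )
    s2_a, s2_b, s2_c, phi_ct, phi_sc, phi_st = _amova_components(
        d2, site_enc, transect_of_site
    )
    total = s2_a + s2_b + s2_c
    pct = (100 * s2_a / total, 100 * s2_b / total, 100 * s2_c / total)
    return AmovaResult(
        sigma2_among_transects=s2_a,
        sigma2_among_sites_within=s2_b,
        sigma2_within=s2_c,
        pct=pct,
        phi_CT=phi_ct,
        phi_SC=phi_sc,
        phi_ST=phi_st,
        negative_components=bool(s2_a < 0 or s2_b < 0),
    )


def amova_permutation_test(
    gm: GenotypeMatrix,
    samples: SampleTable,
    mask: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int = 0,
    result: AmovaResult | None = None,
) -> AmovaResult:
    """Permutation p-values for the phi statistics.

    phi_ST: permute individuals across all sites; phi_SC: permute
    individuals among sites within their transect; phi_CT: permute whole
    sites among transects.  p = (1 + #{phi_perm >= phi_obs}) / (1 + n_perm).
    """
    site_enc, transect_of_site = _encode(gm, samples)
    if mask is None:
        mask = np.ones_like(gm.composite, dtype=bool)
    d2 = pairwise_complete_sqdist(gm.composite, mask)
    if result is None:
        result = amova(gm, samples, mask)
    if result.degenerate:
        return result
    rng = np.random.default_rng(seed)
    tr_enc = transect_of_site[site_enc]

    count_st = count_sc = count_ct = 0
    for _ in range(n_perm):
        # phi_ST null: free shuffle of site labels
        enc = rng.permutation(site_enc)
        st = _amova_components(d2, enc, transect_of_site)[5]
        if st >= result.phi_ST:
            count_st += 1
        # phi_SC null: shuffle site labels within each transect
        enc = site_enc.copy()
        for t in range(int(transect_of_site.max()) + 1):
            rows = np.flatnonzero(tr_enc == t)
            enc[rows] = rng.permutation(site_enc[rows])
        sc = _amova_components(d2, enc, transect_of_site)[4]
        if sc >= result.phi_SC:
            count_sc += 1
        # phi_CT null: shuffle whole sites among transects
        tr_perm = rng.permutation(transect_of_site)
        ct = _amova_components(d2, site_enc, tr_perm)[3]
        if ct >= result.phi_CT:
            count_ct += 1
    result.p_ST = (1 + count_st) / (1 + n_perm)
    result.p_SC = (1 + count_sc) / (1 + n_perm)
    result.p_CT = (1 + count_ct) / (1 + n_perm)
    return result
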