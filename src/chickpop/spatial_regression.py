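"""Geographic/elevational distances and regression on distance matrices.

Great-circle (Haversine) distances between sites, absolute elevation
differences, and multiple regression on distance matrices (MRM): ordinary
least squares on the unfolded lower triangles with Mantel-type inference —
the response matrix's rows and columns are permuted jointly, so permuted
response vectors remain valid distance-matrix unfoldings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import DistanceMatrix, SampleTable, ValidationError

EARTH_RADIUS_KM = 6371.0


@dataclass
class MrmResult:
    coefficients: np.ndarray     # intercept first
    r2: float
    p_overall: float
    p_per_coefficient: np.ndarray  # aligned with coefficients[1:]
    n_perm: int

    def to_record(self) -> dict:
        rec = {"R2": self.r2, "p_overall": self.p_overall, "n_perm": self.n_perm,
               "intercept": float(self.coefficients[0])}
        for i, (b, p) in enumerate(
            zip(self.coefficients[1:], self.p_per_coefficient), start=1
        ):
            rec[f"beta{i}"] = float(b)
            rec[f"p_beta{i}"] = float(p)
        return rec


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (mean Earth radius 6371.0 km)."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def pairwise_distance_matrices(
    samples: SampleTable,
) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Site-level geographic (km) and elevational (m) distance matrices."""
    st = samples.site_table()
    sites = list(st.index)
    if len(sites) != len(set(sites)):
        raise ValidationError("duplicate site rows")
    k = len(sites)
    geo = np.zeros((k, k))
    elev = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = st.iloc[i], st.iloc[j]
            geo[i, j] = geo[j, i] = haversine_km(
                a.latitude, a.longitude, b.latitude, b.longitude
            )
            elev[i, j] = elev[j, i] = abs(a.elevation_m - b.elevation_m)
    return (
        DistanceMatrix(sites, geo, kind="geographic_km"),
        DistanceMatrix(sites, elev, kind="elevation_m"),
    )


def mrm(
    response: DistanceMatrix,
    predictors: list[DistanceMatrix],
    n_perm: int = 999,
    seed: int = 0,
) -> MrmResult:
    """Multiple regression on distance matrices with matrix permutation.

    OLS of the response's lower triangle on the predictors'; overall
    significance from the permutation distribution of R^2, per-coefficient
    two-sided tests from |beta| under the same permutations.
    """
    labels = response.labels
    k = len(labels)
    if k < 4:
        raise ValidationError("need >= 4 labels for distance-matrix regression")
    for pred in predictors:
        if pred.labels != labels:
            raise ValidationError("predictor labels do not match response labels")
    iu = np.triu_indices(k, 1)
    y = response.values[iu]
    X = np.column_stack(
        [np.ones(y.size)] + [p.values[iu] for p in predictors]
    )
    cond = np.linalg.cond(X)
    if cond > 1e10:
        raise ValidationError(f"collinear predictors (condition number {cond:.3g})")

    def fit(yvec: np.ndarray) -> tuple[np.ndarray, float]:
        beta, *_ = np.linalg.lstsq(X, yvec, rcond=None)
        resid = yvec - X @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yvec - yvec.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        return beta, r2

    beta_obs, r2_obs = fit(y)
    rng = np.random.default_rng(seed)
    count_r2 = 0
    count_beta = np.zeros(len(predictors), dtype=int)
    for _ in range(n_perm):
        order = rng.permutation(k)
        y_perm = response.values[np.ix_(order, order)][iu]
        beta_p, r2_p = fit(y_perm)
        if r2_p >= r2_obs:
            count_r2 += 1
        count_beta += np.abs(beta_p[1:]) >= np.abs(beta_obs[1:])
    p_overall = (1 + count_r2) / (1 + n_perm)
    p_coef = (1 + count_beta) / (1 + n_perm)
    return MrmResult(
        coefficients=beta_obs,
        r2=float(r2_obs),
        p_overall=float(p_overall),
        p_per_coefficient=p_coef,
        n_perm=n_perm,
    )
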