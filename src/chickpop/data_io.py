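"""Core data model and file I/O.

The pipeline's entry point is a matrix of per-individual, per-locus genotype
likelihoods with read depths, together with a sample-metadata table mapping
individuals to sites, transects and elevation classes.  Likelihoods are
stored scaled so the maximum of each triple is 1 (a likelihood is only
defined up to a multiplicative constant); a triple at zero read depth is
forced to the uninformative (1, 1, 1).

Two on-disk dialects are supported: a read-only subset of VCF 4.x (CHROM,
POS, REF, ALT, per-sample GL or PL and DP) and a plain tab-separated
"matrix" layout with one row per individual x locus.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ELEVATION_CLASSES = ("high", "low")

MATRIX_TSV_COLUMNS = [
    "individual", "locus", "contig", "pos", "ref", "alt",
    "depth", "L0", "L1", "L2",
]

METADATA_COLUMNS = [
    "individual_id", "site_id", "transect_id", "elevation_class",
    "latitude", "longitude", "elevation_m",
]


class ValidationError(ValueError):
    """Input violates a structural invariant of the data model."""


class CoordinateParseError(ValueError):
    """A latitude/longitude string could not be interpreted."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusRecord:
    """A biallelic SNP: identifier, contig, 1-based position, alleles."""

    locus_id: str
    contig_id: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValidationError(
                f"locus {self.locus_id}: ref and alt alleles are identical "
                f"({self.ref_allele}); loci must be biallelic"
            )
        if self.position < 1:
            raise ValidationError(
                f"locus {self.locus_id}: position must be 1-based, got "
                f"{self.position}"
            )


@dataclass
class SampleTable:
    """Individual -> site/transect/elevation-class/coordinate mapping.

    Wraps a DataFrame with the seven canonical columns.  Each of the six
    sites belongs to exactly one transect and one elevation class, and each
    transect has exactly one high and one low site.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata is missing columns: {missing}")
        if df["individual_id"].duplicated().any():
            dups = df.loc[df["individual_id"].duplicated(), "individual_id"]
            raise ValidationError(
                f"duplicate individual_id values: {sorted(set(dups))}"
            )
        bad_class = set(df["elevation_class"]) - set(ELEVATION_CLASSES)
        if bad_class:
            raise ValidationError(
                f"elevation_class must be one of {ELEVATION_CLASSES}, "
                f"got {sorted(bad_class)}"
            )
        site_map = df.drop_duplicates("site_id")
        per_site = df.groupby("site_id")[["transect_id", "elevation_class"]].nunique()
        if (per_site > 1).any().any():
            offenders = per_site[(per_site > 1).any(axis=1)].index.tolist()
            raise ValidationError(
                f"sites mapped to multiple transects or elevation classes: "
                f"{offenders}"
            )
        for tr, grp in site_map.groupby("transect_id"):
            classes = sorted(grp["elevation_class"])
            if classes != ["high", "low"]:
                raise ValidationError(
                    f"transect {tr} must have exactly one high and one low "
                    f"site, found classes {classes}"
                )
        if not df["latitude"].between(-90, 90).all():
            raise ValidationError("latitudes must lie in [-90, 90]")
        if not df["longitude"].between(-180, 180).all():
            raise ValidationError("longitudes must lie in [-180, 180]")
        self.frame = df.reset_index(drop=True)

    @property
    def individuals(self) -> list[str]:
        return self.frame["individual_id"].tolist()

    @property
    def sites(self) -> list[str]:
        return self.frame["site_id"].drop_duplicates().tolist()

    @property
    def transects(self) -> list[str]:
        return self.frame["transect_id"].drop_duplicates().tolist()

    def site_of(self) -> dict[str, str]:
        return dict(zip(self.frame["individual_id"], self.frame["site_id"]))

    def site_table(self) -> pd.DataFrame:
        """One row per site (coordinates, elevation, transect, class)."""
        return (
            self.frame.drop_duplicates("site_id")
            .set_index("site_id")[
                ["transect_id", "elevation_class", "latitude", "longitude",
                 "elevation_m"]
            ]
        )

    def individuals_at(self, site_id: str) -> list[str]:
        df = self.frame
        return df.loc[df["site_id"] == site_id, "individual_id"].tolist()

    def subset(self, individual_ids: Sequence[str]) -> "SampleTable":
        keep = self.frame["individual_id"].isin(set(individual_ids))
        return SampleTable(self.frame.loc[keep].reset_index(drop=True))


@dataclass
class GenotypeLikelihoodMatrix:
    """N x L x 3 genotype likelihoods plus N x L read depths.

    ``likelihoods[i, l, g]`` is the likelihood of individual *i*'s reads at
    locus *l* given genotype *g* (copies of the alternate allele), scaled so
    each triple's maximum is 1.  Depth-0 triples are (1, 1, 1).
    """

    individuals: list[str]
    loci: list[LocusRecord]
    likelihoods: np.ndarray
    depths: np.ndarray

    def __post_init__(self) -> None:
        n, l_ = len(self.individuals), len(self.loci)
        self.likelihoods = np.asarray(self.likelihoods, dtype=float)
        self.depths = np.asarray(self.depths, dtype=int)
        if self.likelihoods.shape != (n, l_, 3):
            raise ValidationError(
                f"likelihoods shape {self.likelihoods.shape} != ({n}, {l_}, 3)"
            )
        if self.depths.shape != (n, l_):
            raise ValidationError(
                f"depths shape {self.depths.shape} != ({n}, {l_})"
            )
        if np.isnan(self.likelihoods).any():
            raise ValidationError("likelihoods contain NaN")
        if (self.depths < 0).any():
            raise ValidationError("negative read depths")
        seen: set[tuple[str, int]] = set()
        for rec in self.loci:
            key = (rec.contig_id, rec.position)
            if key in seen:
                raise ValidationError(f"duplicate locus coordinate {key}")
            seen.add(key)
        zero = self.depths == 0
        if zero.any():
            trip = self.likelihoods[zero]
            if not np.allclose(trip, trip[:, :1]):
                raise ValidationError(
                    "depth-0 triples must be uninformative (all equal)"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [rec.locus_id for rec in self.loci]

    def take_loci(self, index: np.ndarray) -> "GenotypeLikelihoodMatrix":
        index = np.asarray(index)
        return GenotypeLikelihoodMatrix(
            individuals=list(self.individuals),
            loci=[self.loci[i] for i in index],
            likelihoods=self.likelihoods[:, index, :],
            depths=self.depths[:, index],
        )

    def take_individuals(self, index: np.ndarray) -> "GenotypeLikelihoodMatrix":
        index = np.asarray(index)
        return GenotypeLikelihoodMatrix(
            individuals=[self.individuals[i] for i in index],
            loci=list(self.loci),
            likelihoods=self.likelihoods[index, :, :],
            depths=self.depths[index, :],
        )


@dataclass
class GenotypeMatrix:
    """Posterior composite genotypes in [0, 2] with per-genotype posteriors.

    ``composite[i, l] = 0*P(g=0) + 1*P(g=1) + 2*P(g=2)``; ``allele_freqs``
    holds the posterior-mean alternate-allele frequency per group x locus.
    """

    individuals: list[str]
    loci: list[LocusRecord]
    composite: np.ndarray
    posterior: np.ndarray
    allele_freqs: pd.DataFrame  # index = group (site) ids, columns = locus ids

    def __post_init__(self) -> None:
        n, l_ = len(self.individuals), len(self.loci)
        self.composite = np.asarray(self.composite, dtype=float)
        self.posterior = np.asarray(self.posterior, dtype=float)
        if self.composite.shape != (n, l_):
            raise ValidationError("composite shape mismatch")
        if self.posterior.shape != (n, l_, 3):
            raise ValidationError("posterior shape mismatch")
        sums = self.posterior.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValidationError("posterior triples must sum to 1")
        expected = self.posterior[:, :, 1] + 2.0 * self.posterior[:, :, 2]
        if not np.allclose(self.composite, expected, atol=1e-8):
            raise ValidationError(
                "composite must equal the posterior-weighted genotype"
            )
        af = self.allele_freqs.to_numpy(dtype=float)
        if ((af < -1e-12) | (af > 1 + 1e-12)).any():
            raise ValidationError("allele frequencies must lie in [0, 1]")

    @property
    def locus_ids(self) -> list[str]:
        return [rec.locus_id for rec in self.loci]


@dataclass
class DistanceMatrix:
    """Symmetric K x K matrix with zero diagonal and fixed label order.

    Entries are non-negative except when ``kind == "fst"`` (finite-sample
    corrected F_ST may be slightly negative).
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValidationError("distance matrix diagonal must be zero")
        finite = self.values[np.isfinite(self.values)]
        if self.kind != "fst" and (finite < -1e-10).any():
            raise ValidationError("negative distances")

    def condensed(self) -> np.ndarray:
        """Lower-triangle unfolding in (row-major) pair order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# Coordinate parsing
# ---------------------------------------------------------------------------

_DMS_RE = re.compile(
    r"""^\s*([+-]?\d+(?:\.\d+)?)\s*[°d:\s]\s*
        (?:(\d+(?:\.\d+)?)\s*[′'m:\s]\s*)?
        (?:(\d+(?:\.\d+)?)\s*[″"s]?\s*)?
        ([NSEW])?\s*$""",
    re.VERBOSE | re.IGNORECASE,
)


def parse_coordinate(text: str | float, *, west_negative: bool = False) -> float:
    """Parse a decimal-degree or DMS coordinate string to decimal degrees.

    DMS strings like ``39° 25′ 7.73″`` are converted as deg + min/60 +
    sec/3600.  A trailing hemisphere letter (N/S/E/W) sets the sign; absent
    one, ``west_negative=True`` negates the value (this study's longitudes
    are all west of Greenwich but Table-style metadata omits the sign).
    """
    if isinstance(text, (int, float)):
        return float(text)
    s = str(text).strip().replace("′", "′").replace("″", "″")
    try:
        return float(s)
    except ValueError:
        pass
    m = _DMS_RE.match(s)
    if m is None:
        raise CoordinateParseError(f"cannot parse coordinate {text!r}")
    deg = float(m.group(1))
    minutes = float(m.group(2) or 0.0)
    seconds = float(m.group(3) or 0.0)
    hemi = (m.group(4) or "").upper()
    value = abs(deg) + minutes / 60.0 + seconds / 3600.0
    sign = -1.0 if deg < 0 else 1.0
    if hemi in ("S", "W"):
        sign = -1.0
    elif hemi in ("N", "E"):
        sign = 1.0
    elif west_negative:
        sign = -1.0
    return sign * value


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path, *, west_negative_longitude: bool = True) -> SampleTable:
    """Read a tab-separated sample-metadata table.

    Coordinates may be decimal degrees or DMS strings; longitudes without an
    explicit hemisphere are treated as west (negative) by default.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata at {path} missing columns {missing}")
    out = df.copy()
    for col, west in (("latitude", False), ("longitude", west_negative_longitude)):
        parsed = []
        for idx, raw in enumerate(df[col]):
            try:
                parsed.append(parse_coordinate(raw, west_negative=west))
            except CoordinateParseError as exc:
                raise CoordinateParseError(
                    f"row {idx} ({df['individual_id'].iloc[idx]}): {exc}"
                ) from exc
        out[col] = parsed
    out["elevation_m"] = out["elevation_m"].astype(float)
    return SampleTable(out)


def _normalize_triples(lik: np.ndarray, depths: np.ndarray) -> np.ndarray:
    """Scale each likelihood triple so its maximum is 1; depth 0 -> (1,1,1)."""
    lik = np.asarray(lik, dtype=float)
    peak = lik.max(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(peak > 0, lik / peak, 1.0)
    out[depths == 0] = 1.0
    return out


def read_genotype_likelihoods(
    path: str | Path, dialect: str = "matrix_tsv"
) -> GenotypeLikelihoodMatrix:
    """Read genotype likelihoods from VCF (``vcf_gl``) or ``matrix_tsv``.

    VCF records must carry per-sample GL (log10) or PL (phred) fields;
    non-biallelic records are skipped (count reported via logging).  Raw
    likelihoods are max-normalized per triple; zero-depth triples become
    (1, 1, 1).
    """
    if dialect == "matrix_tsv":
        return _read_matrix_tsv(path)
    if dialect == "vcf_gl":
        return _read_vcf_gl(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_matrix_tsv(path: str | Path) -> GenotypeLikelihoodMatrix:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MATRIX_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"matrix_tsv missing columns {missing}")
    individuals = df["individual"].drop_duplicates().tolist()
    locus_rows = df.drop_duplicates("locus")
    loci = [
        LocusRecord(str(r.locus), str(r.contig), int(r.pos), str(r.ref), str(r.alt))
        for r in locus_rows.itertuples()
    ]
    ind_idx = {v: i for i, v in enumerate(individuals)}
    loc_idx = {rec.locus_id: j for j, rec in enumerate(loci)}
    n, l_ = len(individuals), len(loci)
    lik = np.full((n, l_, 3), np.nan)
    depths = np.zeros((n, l_), dtype=int)
    i = df["individual"].map(ind_idx).to_numpy()
    j = df["locus"].map(loc_idx).to_numpy()
    lik[i, j, 0] = df["L0"].to_numpy(dtype=float)
    lik[i, j, 1] = df["L1"].to_numpy(dtype=float)
    lik[i, j, 2] = df["L2"].to_numpy(dtype=float)
    depths[i, j] = df["depth"].to_numpy(dtype=int)
    if np.isnan(lik).any():
        raise ValidationError("matrix_tsv does not cover every individual x locus cell")
    return GenotypeLikelihoodMatrix(
        individuals, loci, _normalize_triples(lik, depths), depths
    )


def _read_vcf_gl(path: str | Path) -> GenotypeLikelihoodMatrix:
    import logging

    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    loci: list[LocusRecord] = []
    lik_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        def _fmt(field: str):
            try:
                return var.format(field)
            except KeyError:
                return None

        gl = _fmt("GL")
        if gl is not None:
            raw = np.power(10.0, np.asarray(gl, dtype=float))
        else:
            pl = _fmt("PL")
            if pl is None:
                raise ValidationError(
                    f"record {var.CHROM}:{var.POS} has neither GL nor PL"
                )
            raw = np.power(10.0, -np.asarray(pl, dtype=float) / 10.0)
        if raw.shape[1] != 3:
            skipped += 1
            continue
        dp = _fmt("DP")
        if dp is not None:
            depth = np.asarray(dp, dtype=float).reshape(-1)
        else:
            ad = _fmt("AD")
            if ad is not None:
                depth = np.asarray(ad, dtype=float).sum(axis=1)
            else:
                depth = np.zeros(len(individuals))
        depth = np.where(np.isfinite(depth) & (depth > 0), depth, 0).astype(int)
        loci.append(
            LocusRecord(
                locus_id=f"{var.CHROM}:{var.POS}",
                contig_id=var.CHROM,
                position=var.POS,
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
            )
        )
        lik_rows.append(raw)
        depth_rows.append(depth)
    if skipped:
        logging.getLogger(__name__).info(
            "skipped %d non-biallelic/malformed VCF records", skipped
        )
    lik = np.stack(lik_rows, axis=1)  # N x L x 3
    depths = np.stack(depth_rows, axis=1)
    return GenotypeLikelihoodMatrix(
        individuals, loci, _normalize_triples(lik, depths), depths
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_matrix_tsv(gl: GenotypeLikelihoodMatrix, path: str | Path) -> None:
    """Write the matrix_tsv dialect (one row per individual x locus)."""
    n, l_ = gl.n_individuals, gl.n_loci
    ind = np.repeat(gl.individuals, l_)
    recs = gl.loci
    frame = pd.DataFrame(
        {
            "individual": ind,
            "locus": np.tile([r.locus_id for r in recs], n),
            "contig": np.tile([r.contig_id for r in recs], n),
            "pos": np.tile([r.position for r in recs], n),
            "ref": np.tile([r.ref_allele for r in recs], n),
            "alt": np.tile([r.alt_allele for r in recs], n),
            "depth": gl.depths.reshape(-1),
            "L0": gl.likelihoods[:, :, 0].reshape(-1),
            "L1": gl.likelihoods[:, :, 1].reshape(-1),
            "L2": gl.likelihoods[:, :, 2].reshape(-1),
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_metadata(samples: SampleTable, path: str | Path) -> None:
    samples.frame[METADATA_COLUMNS].to_csv(path, sep="\t", index=False)


def write_results_tables(results, path: str | Path, columns: list[str] | None = None) -> None:
    """Write a result object (or list of row-records) as a TSV table.

    Pairwise-differentiation results map to the site-pair table layout
    (site pair, null mean/s.d./95% bounds, observed mean, verdict, Nei's D);
    parallel-divergence results map to the quantile-sharing layout.  An
    empty list yields a header-only file when a schema can be inferred from
    an accompanying ``columns`` attribute, else the generic empty table.
    """
    rows: list[dict]
    if hasattr(results, "to_records"):
        rows = results.to_records()
    elif isinstance(results, Iterable) and not isinstance(results, (str, bytes)):
        rows = []
        for item in results:
            if hasattr(item, "to_record"):
                rows.append(item.to_record())
            elif isinstance(item, dict):
                rows.append(item)
            else:
                raise TypeError(f"cannot serialize {type(item)!r}")
    else:
        raise TypeError(f"cannot serialize {type(results)!r}")
    frame = pd.DataFrame(rows, columns=columns if (columns and not rows) else None)
    frame.to_csv(path, sep="\t", index=False)


def write_manifest(manifest: dict, path: str | Path) -> None:
    """Write a run manifest (seeds, parameters, versions) as JSON."""
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, Path):
            return str(obj)
        raise TypeError(f"not JSON-serializable: {type(obj)!r}")

    Path(path).write_text(json.dumps(manifest, indent=2, default=_default, sort_keys=True))
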