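"""Per-species population-structure metrics from SNP genotypes and mtDNA.

Implements pairwise individual-level Hudson-type Fst, nucleotide diversity,
allele-sharing and Euclidean genotype distances, mtDNA p-distances,
great-circle geographic distances, and the isolation-by-distance slope
(beta_IBD: linearized Fst regressed on log distance) with Mantel-permutation
significance.

Genotypes are alt-allele dosages in {0, 1, 2}; missing calls are NaN and are
excluded from every statistic (all estimators work on the co-typed site set
of each pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "GenotypeMatrix",
    "IBDResult",
    "read_vcf",
    "filter_missingness",
    "pairwise_fst",
    "nucleotide_diversity",
    "genetic_and_euclidean",
    "mtdna_distances",
    "geographic_km",
    "linearize_fst",
    "ibd_slope",
]


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic sites dosage matrix with coordinates.

    ``calls`` is float with entries in {0, 1, 2} or NaN (missing).
    ``coords`` has one row per individual: individual_id, species,
    latitude, longitude (decimal degrees).
    """

    individuals: list[str]
    calls: np.ndarray
    species: str
    coords: pd.DataFrame
    dropped_multiallelic: int = 0
    dropped_all_missing: int = 0

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.ndim != 2 or self.calls.shape[0] != len(self.individuals):
            raise ValueError("calls must be n_individuals x n_sites")
        ok = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        lat = self.coords["latitude"].to_numpy(float)
        lon = self.coords["longitude"].to_numpy(float)
        if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
            raise ValueError("coordinates outside [-90,90] x [-180,180]")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]


@dataclass
class IBDResult:
    """Isolation-by-distance regression summary for one species and metric."""

    species: str
    metric: str
    beta: float
    intercept: float
    p_perm: float
    p_ols: float
    n_individuals: int
    n_pairs: int
    mean_geo_km: float
    capped_pairs: int = 0
    dropped_zero_distance_pairs: int = 0
    pi: float | None = None
    mean_mtdna_dist: float | None = None


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------
def read_vcf(path, coords_path, species: str | None = None) -> GenotypeMatrix:
    """Read a VCF (v4.2, GT field) plus a coordinates CSV into a GenotypeMatrix.

    Keeps biallelic sites only (multiallelic sites are dropped and counted);
    half-calls are treated as missing; sites missing in every individual are
    dropped and counted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    dropped_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            dropped_multi += 1
            continue
        dos = np.full(len(samples), np.nan)
        for i, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            if a < 0 or b < 0:  # missing or half-call
                continue
            dos[i] = float((a > 0) + (b > 0))
        rows.append(dos)
    vcf.close()
    calls = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    all_missing = np.isnan(calls).all(axis=0) if calls.size else np.array([], bool)
    dropped_empty = int(all_missing.sum())
    calls = calls[:, ~all_missing] if calls.size else calls

    coords = pd.read_csv(coords_path)
    need = {"individual_id", "latitude", "longitude"}
    if not need.issubset(coords.columns):
        raise ValueError(f"coordinates CSV must have columns {sorted(need)}")
    missing_ids = sorted(set(samples) - set(coords["individual_id"].astype(str)))
    if missing_ids:
        raise ValueError(f"VCF samples missing from coordinates CSV: {missing_ids}")
    coords = (
        coords.set_index(coords["individual_id"].astype(str))
        .loc[samples]
        .reset_index(drop=True)
    )
    if species is None:
        species = str(coords["species"].iloc[0]) if "species" in coords else "unknown"
    return GenotypeMatrix(
        individuals=samples,
        calls=calls,
        species=species,
        coords=coords,
        dropped_multiallelic=dropped_multi,
        dropped_all_missing=dropped_empty,
    )


def filter_missingness(g: GenotypeMatrix, max_missing: float) -> GenotypeMatrix:
    """Keep sites whose missing-call fraction is <= ``max_missing``.

    Mirrors the usual SNP-matrix site filter applied after variant calling
    (the analysis this package supports used a 20% threshold after checking
    15%–60% gave similar structure).
    """
    if not 0 <= max_missing < 1:
        raise ValueError("max_missing must be in [0, 1)")
    frac = np.isnan(g.calls).mean(axis=0)
    keep = frac <= max_missing
    if not keep.any():
        raise ValueError(
            f"all {g.n_sites} sites exceed missingness {max_missing}; raise the threshold"
        )
    out = GenotypeMatrix(
        individuals=list(g.individuals),
        calls=g.calls[:, keep],
        species=g.species,
        coords=g.coords.copy(),
        dropped_multiallelic=g.dropped_multiallelic,
        dropped_all_missing=g.dropped_all_missing,
    )
    out.sites_in = g.n_sites
    out.sites_kept = int(keep.sum())
    return out


# ----------------------------------------------------------------------
# distance matrices
# ----------------------------------------------------------------------
def _pair_masks(calls: np.ndarray):
    return ~np.isnan(calls)


def pairwise_fst(g: GenotypeMatrix, min_cotyped: int = 50) -> np.ndarray:
    """Hudson-type ratio-of-sums Fst between every pair of individuals.

    Each diploid individual is treated as a two-allele sample from its own
    deme.  Per co-typed site with within-individual allele frequencies
    ``p1, p2`` (in {0, .5, 1}) and ``n1 = n2 = 2`` alleles:

        num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        den = p1(1-p2) + p2(1-p1)

    and ``Fst = sum(num) / sum(den)`` over sites with ``den > 0``.  Pairs
    sharing fewer than ``min_cotyped`` sites get NaN (flagged, not computed).
    """
    n = g.n_individuals
    if n < 2:
        raise ValueError("need at least 2 individuals")
    p = g.calls / 2.0  # allele frequency within individual, NaN if missing
    fst = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p1, p2 = p[i], p[j]
            ok = ~np.isnan(p1) & ~np.isnan(p2)
            if ok.sum() < min_cotyped:
                fst[i, j] = fst[j, i] = np.nan
                continue
            a, b = p1[ok], p2[ok]
            num = (a - b) ** 2 - a * (1 - a) - b * (1 - b)
            den = a * (1 - b) + b * (1 - a)
            use = den > 0
            dsum = den[use].sum()
            if dsum > 0:
                val = num[use].sum() / dsum
            else:
                # no informative site: identical fixed genotypes are Fst = 0
                val = 0.0 if np.array_equal(a, b) else np.nan
            fst[i, j] = fst[j, i] = val
    return fst


def nucleotide_diversity(g: GenotypeMatrix) -> float:
    """Unbiased nucleotide diversity over variant sites.

    Per site with ``m`` non-missing allele copies (2 per typed individual)
    and alt count ``a``: ``pi_site = 2 (a/m)(1 - a/m) m/(m-1)``; sites with
    fewer than 2 copies are excluded; the returned pi is the mean over
    included sites.
    """
    calls = g.calls
    typed = ~np.isnan(calls)
    m = 2 * typed.sum(axis=0)
    a = np.nansum(calls, axis=0)
    ok = m >= 2
    if not ok.any():
        raise ValueError("no site has >= 2 typed allele copies")
    m, a = m[ok].astype(float), a[ok]
    freq = a / m
    pi_site = 2 * freq * (1 - freq) * m / (m - 1)
    return float(pi_site.mean())


def genetic_and_euclidean(
    g: GenotypeMatrix, min_cotyped: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Allele-sharing genetic distance and per-site RMS Euclidean dosage distance.

    genetic = 1 - (shared alleles)/(2 * co-typed sites), where two genotypes
    with dosages a, b share ``2 - |a - b|`` alleles; euclidean is the
    root-mean-square dosage difference over co-typed sites (per-site
    normalization keeps pairs with different missingness comparable).
    """
    n = g.n_individuals
    gen = np.zeros((n, n))
    euc = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = g.calls[i], g.calls[j]
            ok = ~np.isnan(a) & ~np.isnan(b)
            if ok.sum() < min_cotyped:
                gen[i, j] = gen[j, i] = euc[i, j] = euc[j, i] = np.nan
                continue
            diff = np.abs(a[ok] - b[ok])
            gen[i, j] = gen[j, i] = diff.sum() / (2 * ok.sum())
            euc[i, j] = euc[j, i] = float(np.sqrt(np.mean(diff**2)))
    return gen, euc


def mtdna_distances(fasta_path_or_records) -> tuple[np.ndarray, list[str], float]:
    """Pairwise p-distances from an aligned FASTA; returns (matrix, ids, mean).

    Only positions where both sequences carry A/C/G/T are compared; gaps and
    ambiguity codes are excluded.  A pair with zero comparable positions is
    NaN (flagged).
    """
    if isinstance(fasta_path_or_records, (str, bytes)) or hasattr(
        fasta_path_or_records, "__fspath__"
    ):
        records = list(SeqIO.parse(str(fasta_path_or_records), "fasta"))
    else:
        records = list(fasta_path_or_records)
    if len(records) < 2:
        raise ValueError("need at least 2 aligned sequences")
    seqs = [str(r.seq).upper() for r in records]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences are not aligned (unequal lengths)")
    arr = np.array([list(s) for s in seqs])
    valid = np.isin(arr, list("ACGT"))
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            if not ok.any():
                D[i, j] = D[j, i] = np.nan
                continue
            D[i, j] = D[j, i] = float(np.mean(arr[i, ok] != arr[j, ok]))
    iu = np.triu_indices(n, 1)
    mean_d = float(np.nanmean(D[iu]))
    return D, [r.id for r in records], mean_d


def geographic_km(coords: pd.DataFrame) -> np.ndarray:
    """Great-circle (haversine) distance matrix in km, Earth radius 6371.0088."""
    lat = np.radians(coords["latitude"].to_numpy(float))
    lon = np.radians(coords["longitude"].to_numpy(float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    h = np.clip(h, 0.0, 1.0)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


# ----------------------------------------------------------------------
# isolation by distance
# ----------------------------------------------------------------------
def linearize_fst(fst: np.ndarray, cap: float = 0.999) -> tuple[np.ndarray, int]:
    """Fst/(1-Fst) with entries >= cap capped first; returns (matrix, n_capped)."""
    f = fst.copy()
    iu = np.triu_indices(f.shape[0], 1)
    n_capped = int(np.sum(f[iu] >= cap))
    f = np.minimum(f, cap)
    return f / (1 - f), n_capped


def ibd_slope(
    dist: np.ndarray,
    geo_km: np.ndarray,
    permutations: int = 999,
    seed: int | None = None,
    species: str = "",
    metric: str = "linearized_fst",
    capped_pairs: int = 0,
) -> IBDResult:
    """Slope of a pairwise distance metric on ln(geographic km), with Mantel p.

    OLS over the n(n-1)/2 unordered pairs of y = dist vs x = ln(km).  Pairs
    with zero geographic distance or missing metric are dropped (counted).
    Significance comes from a Mantel-style permutation of individual labels
    (p = (1 + #{|b_perm| >= |b_obs|}) / (1 + permutations)); pairwise
    distances are non-independent, so the naive OLS p is reported alongside
    but should not be trusted.
    """
    n = dist.shape[0]
    if n < 3:
        raise ValueError("need at least 3 individuals for an IBD slope")
    iu = np.triu_indices(n, 1)
    geo = geo_km[iu]
    y_all = dist[iu]
    zero_d = geo <= 0
    usable = ~zero_d & ~np.isnan(y_all)
    if np.ptp(geo[usable]) == 0:
        raise ValueError("all pairwise geographic distances equal; slope undefined")
    x = np.log(geo[usable])
    y = y_all[usable]

    def _slope(xv, yv):
        xm, ym = xv - xv.mean(), yv - yv.mean()
        b = float(xm @ ym / (xm @ xm))
        return b, float(yv.mean() - b * xv.mean())

    beta, intercept = _slope(x, y)

    # naive OLS p for the slope (pairs treated as independent)
    from scipy import stats

    if len(x) > 2 and np.ptp(y) > 0:
        p_ols = float(stats.linregress(x, y).pvalue)
    else:
        p_ols = 1.0

    rng = np.random.default_rng(seed)
    ge_count = 0
    lngeo = np.full((n, n), np.nan)
    with np.errstate(divide="ignore"):
        lg = np.where(geo_km > 0, np.log(np.maximum(geo_km, 1e-300)), np.nan)
    lngeo = lg
    for _ in range(permutations):
        perm = rng.permutation(n)
        xp_all = lngeo[np.ix_(perm, perm)][iu]
        ok = ~np.isnan(xp_all) & ~np.isnan(y_all)
        xp, yp = xp_all[ok], y_all[ok]
        if np.ptp(xp) == 0:
            continue
        bp, _ = _slope(xp, yp)
        if abs(bp) >= abs(beta):
            ge_count += 1
    p_perm = (1 + ge_count) / (1 + permutations)

    return IBDResult(
        species=species,
        metric=metric,
        beta=beta,
        intercept=intercept,
        p_perm=float(p_perm),
        p_ols=p_ols,
        n_individuals=n,
        n_pairs=int(usable.sum()),
        mean_geo_km=float(geo[usable].mean()),
        capped_pairs=capped_pairs,
        dropped_zero_distance_pairs=int(zero_d.sum()),
    )
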