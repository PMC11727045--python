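"""Distances, clustering, ordination and structure diagnostics.

Implements the population-genetics toolchain downstream of the band
matrix: Nei (1972) genetic distance, UPGMA with deterministic
tie-breaking, PCA of centered band vectors, the Evanno delta-K statistic
for choosing the number of clusters from STRUCTURE-style ln P(D)
replicate tables, and pairwise kinship (allele-sharing or Ritland
frequency-weighted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._util import logger
from .band_matrix import BandMatrix
from .marker_stats import allele_frequencies, bands_to_genotypes

NEI_DISTANCE_CAP = 10.0

# allele-frequency profiles: unit -> locus -> allele -> frequency
FreqProfiles = dict[str, dict[str, dict[str, float]]]


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray
    method: str

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class UPGMAResult:
    tree: TreeNode
    ids: tuple[str, ...]
    merge_heights: list[float]

    def newick(self) -> str:
        return str(self.tree).strip()


@dataclass(frozen=True)
class DeltaKResult:
    k_values: tuple[int, ...]
    mean_lnp: dict[int, float]
    sd_lnp: dict[int, float]
    delta_k: dict[int, float]
    optimal_k: int


@dataclass(frozen=True)
class KinshipMatrix:
    ids: tuple[str, ...]
    values: np.ndarray
    estimator: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass(frozen=True)
class PCAResult:
    ids: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    explained: np.ndarray


def individual_freq_profiles(matrix: BandMatrix) -> FreqProfiles:
    """Treat each individual as a two-allele-sample population:
    a homozygote contributes frequency 1 to its allele, a heterozygote
    0.5 to each.  Missing genotypes leave the locus absent."""
    profiles: FreqProfiles = {ind: {} for ind in matrix.individual_ids}
    for m in matrix.marker_ids:
        for ind, gt in bands_to_genotypes(matrix, m).items():
            if gt is None:
                continue
            a, b = gt
            profiles[ind][m] = {a: 1.0} if a == b else {a: 0.5, b: 0.5}
    return profiles


def nei_distance(freqs: FreqProfiles, cap: float = NEI_DISTANCE_CAP) -> DistanceMatrix:
    """Nei (1972) standard genetic distance D = -ln(Jxy / sqrt(Jx Jy)).

    Jxy is the mean over shared loci of sum_a x_a y_a; Jx and Jy are the
    corresponding mean homozygosities over the same loci.  Pairs with
    Jxy = 0 (no shared alleles anywhere) are set to ``cap`` with a
    warning.
    """
    ids = tuple(freqs)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            fx, fy = freqs[ids[i]], freqs[ids[j]]
            shared = [loc for loc in fx if loc in fy]
            if not shared:
                raise ValueError(f"no shared loci between {ids[i]} and {ids[j]}")
            jxy = jx = jy = 0.0
            for loc in shared:
                x, y = fx[loc], fy[loc]
                jxy += sum(x.get(a, 0.0) * y.get(a, 0.0) for a in set(x) | set(y))
                jx += sum(v * v for v in x.values())
                jy += sum(v * v for v in y.values())
            jxy /= len(shared)
            jx /= len(shared)
            jy /= len(shared)
            if jxy == 0.0:
                logger.warning(
                    "Nei distance %s/%s: no shared alleles, capped at %g",
                    ids[i], ids[j], cap,
                )
                dij = cap
            else:
                dij = max(0.0, -np.log(jxy / np.sqrt(jx * jy)))
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(ids=ids, values=d, method="nei1972")


def dice_binary_distance(matrix: BandMatrix) -> DistanceMatrix:
    """1 - Dice similarity of raw band-presence vectors (NTSYS-style)."""
    ids = tuple(matrix.individual_ids)
    X = matrix.scores.to_numpy(dtype=float).T  # individuals x bands
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(X[i]) & ~np.isnan(X[j])
            a, b = X[i, ok], X[j, ok]
            denom = a.sum() + b.sum()
            sim = 2 * np.sum((a == 1) & (b == 1)) / denom if denom else 0.0
            d[i, j] = d[j, i] = 1.0 - sim
    return DistanceMatrix(ids=ids, values=d, method="dice_binary")


def upgma(d: DistanceMatrix) -> UPGMAResult:
    """Average-linkage agglomeration into an ultrametric rooted tree.

    Cluster heights are half the merge distance, so every root-to-leaf
    path length equals half the final merge distance.  Ties are broken
    by the smallest (i, j) pair of active-cluster indices (creation
    order: leaves first, in input order).
    """
    if np.isnan(d.values).any():
        raise ValueError("NaN in distance matrix")
    n = len(d.ids)
    if n < 2:
        raise ValueError("UPGMA requires >= 2 leaves")
    nodes = [TreeNode(name=str(name)) for name in d.ids]
    heights = [0.0] * n
    sizes = [1] * n
    active = list(range(n))
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d.values[i, j])
    merge_heights: list[float] = []
    next_id = n
    while len(active) > 1:
        best = min(
            ((dist[(min(i, j), max(i, j))], i, j)
             for ii, i in enumerate(active) for j in active[ii + 1:]),
        )
        dij, i, j = best
        h = dij / 2.0
        merge_heights.append(h)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = h - heights[i]
        child_j.length = h - heights[j]
        parent = TreeNode(children=[child_i, child_j])
        nodes.append(parent)
        heights.append(h)
        sizes.append(sizes[i] + sizes[j])
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dnew = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            dist[(min(k, next_id), max(k, next_id))] = dnew
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    root = nodes[active[0]]
    root.length = None
    return UPGMAResult(tree=root, ids=d.ids, merge_heights=merge_heights)


def pca_binary(matrix: BandMatrix, n_components: int | None = None) -> PCAResult:
    """PCA of centered band-presence vectors (NA imputed by band mean).

    Deterministic up to machine precision: for each component the
    loading of largest magnitude is made positive.
    """
    X = matrix.scores.to_numpy(dtype=float).T.copy()  # individuals x bands
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA requires >= 2 individuals")
    col_mean = np.nanmean(X, axis=0)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = np.take(col_mean, nan_idx[1])
    Xc = X - X.mean(axis=0)
    if not Xc.any():
        raise ValueError("zero-variance band matrix")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for k in range(Vt.shape[0]):
        idx = np.argmax(np.abs(Vt[k]))
        if Vt[k, idx] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    eigvals = S**2 / (n - 1)
    total_var = Xc.var(axis=0, ddof=1).sum()
    k = n_components or min(n - 1, Xc.shape[1])
    return PCAResult(
        ids=tuple(matrix.individual_ids),
        coordinates=U[:, :k] * S[:k],
        eigenvalues=eigvals[:k],
        explained=eigvals[:k] / total_var,
    )


def evanno_delta_k(lnp: pd.DataFrame) -> DeltaKResult:
    """Evanno et al. delta-K from a replicates-by-K ln P(D) table.

    delta_K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)),
    defined for interior K with positive replicate sd; the optimal K is
    the argmax.  Columns are K values; rows are independent replicates.
    """
    ks = sorted(int(k) for k in lnp.columns)
    if len(ks) < 3:
        raise ValueError("delta-K needs >= 3 consecutive K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K values must be consecutive")
    cols = {int(c): c for c in lnp.columns}
    mean = {k: float(lnp[cols[k]].mean()) for k in ks}
    sd = {k: float(lnp[cols[k]].std(ddof=1)) for k in ks}
    if any(lnp[cols[k]].count() < 2 for k in ks):
        raise ValueError("delta-K needs >= 2 replicates per K")
    delta: dict[int, float] = {}
    for k in ks[1:-1]:
        if sd[k] == 0:
            logger.warning("delta-K undefined at K=%d (sd = 0), excluded", k)
            continue
        delta[k] = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1]) / sd[k]
    if not delta:
        raise ValueError("delta-K undefined at every interior K (all sd = 0)")
    optimal = max(delta, key=lambda k: (delta[k], -k))
    return DeltaKResult(
        k_values=tuple(ks), mean_lnp=mean, sd_lnp=sd, delta_k=delta, optimal_k=optimal
    )


def structure_pseudo_lnp(
    matrix: BandMatrix,
    k_values: range | list[int] = range(1, 11),
    n_replicates: int = 10,
    seed: int = 0,
    subsample_frac: float = 0.8,
) -> pd.DataFrame:
    """Replicates-by-K model log-likelihood table for delta-K selection.

    Bayesian admixture inference itself is out of scope; this surrogate
    assigns individuals to K clusters by k-means on their imputed band
    vectors and scores each K with the profile log-likelihood of an
    isotropic Gaussian mixture with hard assignments,
    -0.5 N D (ln(2 pi sigma^2) + 1) with sigma^2 the within-cluster mean
    squared deviation.  Replicate variation comes from bootstrapping a
    fraction of the band columns, mirroring run-to-run spread of
    ln P(D).  Output columns are K values, rows replicates.
    """
    from sklearn.cluster import KMeans

    X = matrix.scores.to_numpy(dtype=float).T.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = np.take(col_mean, nan_idx[1])
    rng = np.random.default_rng(seed)
    n, d_full = X.shape
    table = {}
    cols = max(2, int(round(subsample_frac * d_full)))
    for k in list(k_values):
        table[k] = []
    for _ in range(n_replicates):
        idx = rng.choice(d_full, size=cols, replace=True)
        Xr = X[:, idx]
        for k in table:
            if k == 1:
                sse = float(((Xr - Xr.mean(axis=0)) ** 2).sum())
            else:
                km = KMeans(
                    n_clusters=k, n_init=4, random_state=int(rng.integers(2**31 - 1))
                ).fit(Xr)
                sse = float(km.inertia_)
            nd = Xr.size
            sigma2 = max(sse / nd, 1e-12)
            table[k].append(-0.5 * nd * (np.log(2 * np.pi * sigma2) + 1.0))
    return pd.DataFrame(table)


def _present_band_sets(matrix: BandMatrix) -> dict[str, dict[str, set[str] | None]]:
    out: dict[str, dict[str, set[str] | None]] = {}
    for m in matrix.marker_ids:
        sub = matrix.bands_for(m)
        per_ind: dict[str, set[str] | None] = {}
        for ind in sub.columns:
            col = sub[ind]
            per_ind[ind] = None if col.isna().all() else {str(b) for b, v in col.items() if v == 1.0}
        out[m] = per_ind
    return out


def kinship(matrix: BandMatrix, estimator: str = "allele_sharing") -> KinshipMatrix:
    """Pairwise kinship from the band matrix.

    allele_sharing: mean over markers of the Dice shared-band fraction,
    rescaled so the minimum off-diagonal is 0 and self-kinship 1.
    ritland: Ritland (1996) frequency-weighted multilocus estimator
    using the codominant genotypes and panel allele frequencies.
    """
    ids = tuple(matrix.individual_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("kinship requires >= 2 individuals")
    if estimator == "allele_sharing":
        sets = _present_band_sets(matrix)
        k = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                sims = []
                for m in matrix.marker_ids:
                    a, b = sets[m][ids[i]], sets[m][ids[j]]
                    if a is None or b is None or (not a and not b):
                        continue
                    sims.append(2 * len(a & b) / (len(a) + len(b)))
                if not sims:
                    raise ValueError(f"no shared markers for {ids[i]}/{ids[j]}")
                k[i, j] = k[j, i] = float(np.mean(sims))
        off = k[~np.eye(n, dtype=bool)]
        kmin = off.min()
        if kmin < 1.0:
            k = (k - kmin) / (1.0 - kmin)
        np.fill_diagonal(k, 1.0)
        return KinshipMatrix(ids=ids, values=k, estimator="allele_sharing")
    if estimator == "ritland":
        return _ritland_kinship(matrix)
    raise ValueError(f"unknown kinship estimator {estimator!r}")


def _ritland_kinship(matrix: BandMatrix) -> KinshipMatrix:
    ids = tuple(matrix.individual_ids)
    n = len(ids)
    per_locus = []
    for m in matrix.marker_ids:
        genotypes = bands_to_genotypes(matrix, m)
        try:
            p = allele_frequencies(genotypes)
        except ValueError:
            continue
        alleles = [a for a, v in p.items() if v > 0]
        if len(alleles) < 2:
            continue
        S = np.full((n, len(alleles)), np.nan)
        for ii, ind in enumerate(ids):
            gt = genotypes.get(ind)
            if gt is None:
                continue
            S[ii] = 0.0
            for a in gt:
                S[ii, alleles.index(a)] += 0.5
        pv = np.array([p[a] for a in alleles])
        per_locus.append((S, pv, len(alleles)))
    if not per_locus:
        raise ValueError("no polymorphic locus for Ritland kinship")
    k = np.zeros((n, n))
    counts = np.zeros((n, n))
    for S, pv, na in per_locus:
        ok = ~np.isnan(S[:, 0])
        f = (S / pv) @ S.T  # sum_a S_ia S_ja / p_a
        est = (f - 1.0) / (na - 1)
        mask = np.outer(ok, ok)
        k[mask] += est[mask]
        counts[mask] += 1
    if (counts == 0).any():
        raise ValueError("individual pair with no shared polymorphic locus")
    k = k / counts
    k = (k + k.T) / 2
    return KinshipMatrix(ids=ids, values=k, estimator="ritland")
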