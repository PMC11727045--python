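"""Trait summaries and marker-trait association (GLM, MLM(K), MLM(K+Q)).

Traits live in a long table with columns ``individual_id``, ``trait``,
``year``, ``value`` (years are analyzed separately, never pooled).
Marker genotypes enter as band-allele dosage columns (0/1/2 per allele,
last allele dropped for identifiability) from the codominant reading of
the band matrix.

GLM: ordinary least squares of the trait on the marker dosage block
plus optional structure covariates (Q minus one column); the marker is
tested with a partial F-test and R^2 is the incremental variance
explained.

MLM: y = Xb + u + e with u ~ N(0, sigma_u^2 K), fitted EMMA-style — one
spectral decomposition of K per trait, REML profile over the variance
ratio delta = sigma_e^2/sigma_u^2 on a log grid, then per-marker
generalized least squares with a partial F-test.  By default variance
components are fixed at the null model (the P3D approximation); exact
per-marker REML is available via ``p3d=False``.  Narrow-sense
heritability is reported as sigma_u^2/(sigma_u^2 + sigma_e^2) =
1/(1 + delta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._util import logger
from .band_matrix import BandMatrix
from .io_formats import GeneRecord
from .diversity import KinshipMatrix
from .marker_stats import bands_to_genotypes

TRAIT_COLUMNS = ["individual_id", "trait", "year", "value"]

_DELTA_LOG_BOUNDS = (np.log(1e-5), np.log(1e5))


@dataclass(frozen=True)
class MixedModelFit:
    beta: np.ndarray
    sigma2_u: float
    sigma2_e: float
    delta: float
    reml_ll: float

    @property
    def heritability(self) -> float:
        return self.sigma2_u / (self.sigma2_u + self.sigma2_e)


def _check_traits(traits: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRAIT_COLUMNS if c not in traits.columns]
    if missing:
        raise ValueError(f"trait table lacks columns {missing}")
    return traits


def trait_summaries(traits: pd.DataFrame) -> pd.DataFrame:
    """Per trait x year: mean, sd, range, CV (%), Shapiro-Wilk W and p,
    plus a between-year one-way ANOVA p per trait (repeated on each of
    its year rows)."""
    traits = _check_traits(traits)
    rows = []
    for (trait, year), grp in traits.groupby(["trait", "year"], sort=True):
        v = grp["value"].dropna().to_numpy(dtype=float)
        if v.size < 3:
            raise ValueError(f"trait {trait} year {year}: fewer than 3 values")
        mean, sd = float(v.mean()), float(v.std(ddof=1))
        if sd == 0:
            w, p = np.nan, np.nan
        else:
            w, p = (float(x) for x in stats.shapiro(v))
        rows.append(
            {
                "trait": trait, "year": year, "n": v.size,
                "mean": mean, "sd": sd, "range": float(v.max() - v.min()),
                "cv_pct": 100.0 * sd / mean if mean else np.nan,
                "shapiro_w": w, "shapiro_p": p,
            }
        )
    df = pd.DataFrame(rows)
    anova_p = {}
    for trait, grp in traits.groupby("trait"):
        groups = [
            g["value"].dropna().to_numpy(dtype=float)
            for _, g in grp.groupby("year")
        ]
        groups = [g for g in groups if g.size >= 2]
        if len(groups) >= 2:
            anova_p[trait] = float(stats.f_oneway(*groups).pvalue)
        else:
            anova_p[trait] = np.nan
    df["anova_between_years_p"] = df["trait"].map(anova_p)
    return df


def trait_correlations(
    traits: pd.DataFrame, year: int | str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p matrices among traits within one year,
    pairwise-complete."""
    traits = _check_traits(traits)
    wide = (
        traits[traits["year"] == year]
        .pivot(index="individual_id", columns="trait", values="value")
    )
    names = list(wide.columns)
    k = len(names)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = wide[[names[i], names[j]]].dropna()
            res = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (
        pd.DataFrame(r, index=names, columns=names),
        pd.DataFrame(p, index=names, columns=names),
    )


def marker_dosage(matrix: BandMatrix, marker_id: str) -> pd.DataFrame:
    """Band-allele dosage columns (0/1/2) per individual; NaN missing."""
    genotypes = bands_to_genotypes(matrix, marker_id)
    alleles = sorted({a for gt in genotypes.values() if gt for a in gt})
    rows = {}
    for ind, gt in genotypes.items():
        if gt is None:
            rows[ind] = [np.nan] * len(alleles)
        else:
            rows[ind] = [float(gt.count(a)) for a in alleles]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"{marker_id}:{a}" for a in alleles]
    )


def _q_covariates(q: pd.DataFrame | None, individuals: pd.Index) -> np.ndarray | None:
    if q is None:
        return None
    sub = q.reindex(individuals)
    if sub.isna().any().any():
        raise ValueError("Q matrix missing individuals present in the traits")
    if sub.shape[1] < 2:
        raise ValueError("Q matrix needs >= 2 columns (one is dropped)")
    if not np.allclose(sub.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("Q matrix rows must sum to 1")
    return sub.iloc[:, :-1].to_numpy(dtype=float)


def _drop_collinear(X0: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Drop marker columns adding no rank beyond X0 (warn per drop)."""
    keep = []
    base = X0
    for j in range(D.shape[1]):
        trial = np.column_stack([base, D[:, j]])
        if np.linalg.matrix_rank(trial) > np.linalg.matrix_rank(base):
            keep.append(j)
            base = trial
        else:
            logger.warning("collinear marker column %d dropped", j)
    return D[:, keep]


def _partial_f(y: np.ndarray, X0: np.ndarray, D: np.ndarray):
    """Partial F-test of the D block given X0; returns (p, r2, beta_D)."""
    D = _drop_collinear(X0, D)
    if D.shape[1] == 0:
        raise ValueError("marker block collinear with covariates (no variation)")
    X = np.column_stack([X0, D])
    n = y.size
    beta_f, _, rank_f, _ = np.linalg.lstsq(X, y, rcond=None)
    sse_f = float(np.sum((y - X @ beta_f) ** 2))
    beta_r, _, rank_r, _ = np.linalg.lstsq(X0, y, rcond=None)
    sse_r = float(np.sum((y - X0 @ beta_r) ** 2))
    df1 = rank_f - rank_r
    df2 = n - rank_f
    if df1 < 1 or df2 < 1:
        raise ValueError("not enough residual degrees of freedom")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sse_f <= 0:
        return 0.0 if sse_r > sse_f else 1.0, (sse_r - sse_f) / sst if sst else 0.0, beta_f[X0.shape[1]:]
    f = ((sse_r - sse_f) / df1) / (sse_f / df2)
    p = float(stats.f.sf(max(f, 0.0), df1, df2))
    r2 = (sse_r - sse_f) / sst if sst > 0 else 0.0
    return p, max(0.0, min(1.0, r2)), beta_f[X0.shape[1]:]


def _assoc_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["marker_id", "trait", "year", "model", "p_value", "r2", "effects"]
    )


def glm_assoc(
    matrix: BandMatrix,
    traits: pd.DataFrame,
    q: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """GLM association: per marker x trait x year partial-F p and R^2."""
    traits = _check_traits(traits)
    dosages = {m: marker_dosage(matrix, m) for m in matrix.marker_ids}
    rows = []
    for (trait, year), grp in traits.groupby(["trait", "year"], sort=True):
        yser = grp.set_index("individual_id")["value"].dropna()
        for m, dose in dosages.items():
            joint = dose.reindex(yser.index).dropna()
            y = yser.loc[joint.index].to_numpy(dtype=float)
            n = y.size
            X0 = np.ones((n, 1))
            qcov = _q_covariates(q, joint.index)
            if qcov is not None:
                X0 = np.column_stack([X0, qcov])
            D = joint.iloc[:, :-1].to_numpy(dtype=float)  # drop last allele column
            if D.shape[1] == 0 or n < X0.shape[1] + D.shape[1] + 2:
                continue
            try:
                p, r2, beta = _partial_f(y, X0, D)
            except ValueError as exc:
                logger.warning("GLM %s/%s/%s skipped: %s", m, trait, year, exc)
                continue
            rows.append(
                {
                    "marker_id": m, "trait": trait, "year": year, "model": "GLM",
                    "p_value": p, "r2": r2, "effects": tuple(np.round(beta, 6)),
                }
            )
    return _assoc_frame(rows)


def _reml_fit(y: np.ndarray, X: np.ndarray, d: np.ndarray, Ut: np.ndarray) -> MixedModelFit:
    """REML over delta given the eigendecomposition K = U diag(d) U'."""
    ys = Ut @ y
    Xs = Ut @ X
    n, p = X.shape
    _, logdet_xx = np.linalg.slogdet(X.T @ X)

    def neg_reml(log_delta: float) -> float:
        w = d + np.exp(log_delta)
        Xw = Xs / w[:, None]
        xhx = Xw.T @ Xs  # X' W^-1 X
        beta = np.linalg.solve(xhx, Xw.T @ ys)
        r = ys - Xs @ beta
        q = float(np.sum(r**2 / w))
        s2 = q / (n - p)
        _, logdet_xhx = np.linalg.slogdet(xhx)
        ll = -0.5 * (
            (n - p) * (np.log(2 * np.pi * s2) + 1)
            + float(np.sum(np.log(w)))
            + logdet_xhx
            - logdet_xx
        )
        return -ll

    res = optimize.minimize_scalar(
        neg_reml, bounds=_DELTA_LOG_BOUNDS, method="bounded",
        options={"xatol": 1e-8},
    )
    delta = float(np.exp(res.x))
    w = d + delta
    Xw = Xs / w[:, None]
    xhx = Xw.T @ Xs
    beta = np.linalg.solve(xhx, Xw.T @ ys)
    r = ys - Xs @ beta
    s2u = float(np.sum(r**2 / w)) / (n - p)
    return MixedModelFit(
        beta=beta, sigma2_u=s2u, sigma2_e=delta * s2u, delta=delta,
        reml_ll=float(-res.fun),
    )


def fit_null_mlm(
    y: np.ndarray, X0: np.ndarray, k_values: np.ndarray
) -> tuple[MixedModelFit, np.ndarray, np.ndarray]:
    """Null mixed model; returns (fit, eigenvalues, U') for reuse."""
    d, U = np.linalg.eigh(k_values)
    if d.min() < -1e-6 * max(1.0, d.max()):
        raise ValueError(f"kinship matrix not PSD (min eigenvalue {d.min():.3g})")
    if d.min() < -1e-10 * max(1.0, d.max()):
        logger.warning("clipping %d slightly negative kinship eigenvalues", int((d < 0).sum()))
    d = np.clip(d, 0.0, None)
    Ut = U.T
    return _reml_fit(y, X0, d, Ut), d, Ut


def mlm_assoc(
    matrix: BandMatrix,
    traits: pd.DataFrame,
    k: KinshipMatrix,
    q: pd.DataFrame | None = None,
    p3d: bool = True,
) -> pd.DataFrame:
    """Mixed-model association: MLM(K) without Q, MLM(K+Q) with it.

    Missing marker dosages are mean-imputed so the trait's eigen
    transform (and, under P3D, its null variance components) can be
    reused across markers.
    """
    traits = _check_traits(traits)
    model = "MLM_KQ" if q is not None else "MLM_K"
    dosages = {m: marker_dosage(matrix, m) for m in matrix.marker_ids}
    kf = k.to_frame()
    rows = []
    for (trait, year), grp in traits.groupby(["trait", "year"], sort=True):
        yser = grp.set_index("individual_id")["value"].dropna()
        ids = [i for i in yser.index if i in kf.index]
        y = yser.loc[ids].to_numpy(dtype=float)
        n = y.size
        X0 = np.ones((n, 1))
        qcov = _q_covariates(q, pd.Index(ids))
        if qcov is not None:
            X0 = np.column_stack([X0, qcov])
        ksub = kf.loc[ids, ids].to_numpy(dtype=float)
        null_fit, d, Ut = fit_null_mlm(y, X0, ksub)
        ys = Ut @ y
        for m, dose in dosages.items():
            D = dose.reindex(ids).to_numpy(dtype=float)[:, :-1]
            if D.shape[1] == 0:
                continue
            col_mean = np.nanmean(D, axis=0)
            nan_idx = np.where(np.isnan(D))
            D[nan_idx] = np.take(col_mean, nan_idx[1])
            if n < X0.shape[1] + D.shape[1] + 2:
                continue
            X = np.column_stack([X0, D])
            if p3d:
                delta = null_fit.delta
            else:
                delta = _reml_fit(y, X, d, Ut).delta
            w = np.sqrt(d + delta)
            yt = ys / w
            X0t = (Ut @ X0) / w[:, None]
            Dt = (Ut @ D) / w[:, None]
            try:
                p, r2, beta = _partial_f(yt, X0t, Dt)
            except ValueError as exc:
                logger.warning("%s %s/%s/%s skipped: %s", model, m, trait, year, exc)
                continue
            rows.append(
                {
                    "marker_id": m, "trait": trait, "year": year, "model": model,
                    "p_value": p, "r2": r2, "effects": tuple(np.round(beta, 6)),
                }
            )
    return _assoc_frame(rows)


def significant_markers(
    results: pd.DataFrame,
    alpha: float = 0.05,
    min_models: int = 2,
    min_years: int = 1,
) -> pd.DataFrame:
    """Markers significant in >= min_models models for a trait/year,
    in >= min_years years for that trait."""
    if results.empty:
        return pd.DataFrame(columns=["marker_id", "trait", "years", "models"])
    sig = results[results["p_value"] < alpha]
    if sig.empty:
        return pd.DataFrame(columns=["marker_id", "trait", "years", "models"])
    per_year = (
        sig.groupby(["marker_id", "trait", "year"])["model"]
        .agg(lambda s: tuple(sorted(set(s))))
        .reset_index()
    )
    per_year = per_year[per_year["model"].map(len) >= min_models]
    rows = []
    for (m, t), grp in per_year.groupby(["marker_id", "trait"]):
        if grp["year"].nunique() >= min_years:
            rows.append(
                {
                    "marker_id": m, "trait": t,
                    "years": tuple(sorted(grp["year"].unique())),
                    "models": tuple(sorted({mod for tup in grp["model"] for mod in tup})),
                }
            )
    return pd.DataFrame(rows, columns=["marker_id", "trait", "years", "models"])


def association_counts(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Counts of significant marker-trait pairs per trait x model x year."""
    sig = results[results["p_value"] < alpha]
    if sig.empty:
        return pd.DataFrame()
    tab = sig.pivot_table(
        index="trait", columns=["model", "year"], values="marker_id",
        aggfunc="count", fill_value=0,
    )
    tab.loc["SUM"] = tab.sum(axis=0)
    return tab


def candidate_gene_window(
    marker_chrom: str,
    marker_anchor_pos: int,
    genes: list[GeneRecord],
    window_total: int = 1_000_000,
    full_width_each_side: bool = False,
) -> list[GeneRecord]:
    """Genes overlapping the window around a significant marker.

    The default reads "a 1 Mb region surrounding the marker" as a TOTAL
    1 Mb window (+/- 500 kb); ``full_width_each_side=True`` switches to
    +/- window_total.  ``marker_anchor_pos`` is 1-based.  Results are
    sorted by distance to the anchor.
    """
    half = window_total if full_width_each_side else window_total // 2
    lo = max(1, marker_anchor_pos - half)
    hi = marker_anchor_pos + half

    def dist(g: GeneRecord) -> int:
        if g.start <= marker_anchor_pos <= g.end:
            return 0
        return min(abs(g.start - marker_anchor_pos), abs(g.end - marker_anchor_pos))

    hits = [
        g for g in genes
        if g.chrom_id == marker_chrom and g.start <= hi and g.end >= lo
    ]
    return sorted(hits, key=lambda g: (dist(g), g.start, g.gene_id))
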