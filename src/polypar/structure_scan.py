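"""Population structure and genome scans of the base-composition phenotype.

The phenotype (typically [A] across polymorphic sites) is treated as a
quantitative trait. Two scans are provided:

* ``linear_scan`` — per-SNP OLS F test of the genotype term, optionally with
  principal-component covariates (PC2-PC6 by default elsewhere, because PC1
  is nearly collinear with the trait);
* ``mixed_scan`` — EMMAX/P3D-style two-stage mixed model: variance
  components are estimated once on the null model by REML using the
  eigendecomposition of the kinship matrix, then each SNP is tested by
  generalized least squares with the variance structure held fixed.

Significance thresholds come either from Bonferroni correction or from the
allele-switching simulation: start from a pseudo-SNP perfectly fixed between
the two groups and randomly flip the genotype in an increasing proportion of
samples, tracing how the F statistic decays; 1000 replicates per proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .poly_composition import GenotypeMatrix

__all__ = [
    "PCAResult",
    "ThresholdConfig",
    "compute_kinship",
    "pca",
    "corr_phenotype_pc",
    "linear_scan",
    "mixed_scan",
    "bonferroni_threshold",
    "allele_switch_threshold",
    "subsample_variance",
    "flag_tas",
]


def _imputed_dosage(genotypes: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Float dosage matrix with missing entries replaced by the variant mean."""
    dos = genotypes.dosage if isinstance(genotypes, GenotypeMatrix) else genotypes
    X = np.asarray(dos, dtype=np.float64)
    miss = X < 0
    if miss.any():
        X = X.copy()
        X[miss] = np.nan
        col_mean = np.nanmean(X, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(miss)
        X[idx] = col_mean[idx[1]]
    return X


def compute_kinship(genotypes: GenotypeMatrix | np.ndarray, method: str = "vanraden") -> np.ndarray:
    """Genomic relationship matrix from the dosage matrix.

    ``vanraden``: centered cross-product Z Z' / (2 * sum p(1-p)) with
    Z = M - 2p. ``allele_sharing``: mean proportion of shared alleles per
    pair, 2*(1 - |d_i - d_j|/2) averaged over variants — a simple cross-check
    metric. Missing dosages are mean-imputed per variant for this
    computation only.
    """
    X = _imputed_dosage(genotypes)
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("kinship requires at least one polymorphic variant")
    if method == "vanraden":
        Z = X[:, poly] - 2.0 * p[poly]
        denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
        K = (Z @ Z.T) / denom
    elif method == "allele_sharing":
        D = X[:, poly]
        n = D.shape[0]
        K = np.empty((n, n))
        for i in range(n):
            K[i] = 1.0 - np.abs(D[i] - D).mean(axis=1) / 2.0
    else:
        raise ValueError(f"unknown kinship method {method!r}")
    return (K + K.T) / 2.0


@dataclass
class PCAResult:
    scores: np.ndarray  # (n_samples, k)
    eigenvalues: np.ndarray  # (k,)
    samples: list[str] | None = None

    def pc(self, which: int) -> np.ndarray:
        """1-based principal-component scores."""
        return self.scores[:, which - 1]


def pca(genotypes: GenotypeMatrix | np.ndarray, k: int = 6) -> PCAResult:
    """Top-k principal components of the column-standardized dosage matrix."""
    X = _imputed_dosage(genotypes)
    n, m = X.shape
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds min(n_samples, n_variants)={min(n, m)}")
    sd = X.std(axis=0)
    keep = sd > 0
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :k] * S[:k]
    eigenvalues = S[:k] ** 2 / (n - 1)
    samples = genotypes.samples if isinstance(genotypes, GenotypeMatrix) else None
    return PCAResult(scores=scores, eigenvalues=eigenvalues, samples=samples)


def corr_phenotype_pc(phenotype: np.ndarray | pd.Series, pcs: PCAResult, which_pc: int = 1) -> float:
    """Pearson correlation between the phenotype and one PC's scores."""
    y = np.asarray(phenotype, dtype=float)
    x = pcs.pc(which_pc)
    if y.shape[0] != x.shape[0]:
        raise ValueError("phenotype and PCA sample counts differ")
    if np.std(y) == 0 or np.std(x) == 0:
        raise ValueError("zero-variance input to correlation")
    return float(np.corrcoef(y, x)[0, 1])


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    """Intercept + covariates, with a collinearity check naming the offender."""
    if covariates is None:
        return np.ones((n, 1))
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != n:
        C = C.T
    X = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                raise ValueError(f"covariate {j} is collinear with the preceding design columns")
    return X


def _residualize(M: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of the columns of M on the column space of X (via lstsq)."""
    beta, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ beta


def _per_variant_f(
    y: np.ndarray, G: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized 1-df F tests for each column of G added to the design X."""
    n, p = X.shape
    df2 = n - p - 1
    if df2 <= 0:
        raise ValueError(f"not enough samples: need n > {p + 1}")
    ry = _residualize(y[:, None], X)[:, 0]
    RG = _residualize(G, X)
    rss0 = float(ry @ ry)
    gg = np.einsum("ij,ij->j", RG, RG)
    gy = RG.T @ ry
    with np.errstate(invalid="ignore", divide="ignore"):
        explained = np.where(gg > 1e-12, gy**2 / gg, 0.0)
        rss1 = np.maximum(rss0 - explained, 0.0)
        F = np.where(rss1 > 0, explained / (rss1 / df2), np.inf)
    F = np.where(gg > 1e-12, F, 0.0)
    pvals = stats.f.sf(F, 1, df2)
    return F, pvals, df2


def linear_scan(
    phenotype: np.ndarray | pd.Series,
    genotypes: GenotypeMatrix | np.ndarray,
    covariates: np.ndarray | None = None,
    variants: pd.DataFrame | None = None,
    report_p: bool = True,
) -> pd.DataFrame:
    """Per-SNP F statistic for the genotype term in an OLS model.

    The F statistic is the primary output; p-values (F with 1 and n-p-1 df)
    can be suppressed with ``report_p=False`` for very large samples where
    the distributional p-values are not meaningful.
    """
    y = np.asarray(phenotype, dtype=float)
    G = _imputed_dosage(genotypes)
    if G.shape[0] != y.shape[0]:
        raise ValueError("phenotype and genotype sample counts differ")
    X = _design(y.shape[0], covariates)
    F, pvals, _ = _per_variant_f(y, G, X)
    model = "linear" if covariates is None else "linear+PC"
    return _scan_frame(F, pvals if report_p else None, model, variants)


def _scan_frame(
    F: np.ndarray, pvals: np.ndarray | None, model: str, variants: pd.DataFrame | None
) -> pd.DataFrame:
    out = pd.DataFrame({"F": F})
    out["p"] = pvals if pvals is not None else np.nan
    out["model"] = model
    if variants is not None:
        out = pd.concat(
            [variants[["chrom", "pos", "id"]].reset_index(drop=True), out], axis=1
        )
    return out


def _reml_neg_loglik(h2: float, lam: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    """Negative restricted log-likelihood (profiled over the scale) in the
    eigenbasis of the kinship matrix. lam are kinship eigenvalues."""
    n, p = Xt.shape
    w = h2 * lam + (1.0 - h2)
    if np.any(w <= 0):
        return np.inf
    Xw = Xt / w[:, None]
    XtX = Xt.T @ Xw
    try:
        beta = np.linalg.solve(XtX, Xw.T @ yt)
    except np.linalg.LinAlgError:
        return np.inf
    r = yt - Xt @ beta
    q = float(r @ (r / w))
    sign, logdet_xtx = np.linalg.slogdet(XtX)
    if sign <= 0 or q <= 0:
        return np.inf
    return 0.5 * ((n - p) * np.log(q) + np.log(w).sum() + logdet_xtx)


def mixed_scan(
    phenotype: np.ndarray | pd.Series,
    genotypes: GenotypeMatrix | np.ndarray,
    kinship: np.ndarray,
    covariates: np.ndarray | None = None,
    variants: pd.DataFrame | None = None,
    h2: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Two-stage mixed-model scan (EMMAX/P3D style).

    Null model: y = X b + u + e with u ~ N(0, sg^2 K), e ~ N(0, se^2 I).
    The heritability ratio h2 = sg^2/(sg^2+se^2) is estimated once by REML
    on the null model (no SNP term); every SNP is then tested by GLS with
    V = h2 K + (1-h2) I held fixed. Pass ``h2`` to skip estimation (h2=0
    reproduces the covariate-adjusted linear scan exactly).

    Returns (scan table, variance-component dict with keys h2, sigma_g2,
    sigma_e2, converged).
    """
    y = np.asarray(phenotype, dtype=float)
    G = _imputed_dosage(genotypes)
    n = y.shape[0]
    if kinship.shape != (n, n):
        raise ValueError("kinship dimensions do not match the sample count")
    if not np.allclose(kinship, kinship.T, atol=1e-8):
        raise ValueError("kinship matrix is not symmetric")
    lam, U = np.linalg.eigh(kinship)
    if lam.min() < -1e-6 * max(1.0, abs(lam.max())):
        # standard diagonal shift; refuse only if still indefinite
        shift = -lam.min() + 1e-10
        lam = lam + shift
        if lam.min() < 0:
            raise ValueError("kinship matrix is not positive semidefinite after shifting")
    lam = np.maximum(lam, 0.0)

    X = _design(n, covariates)
    yt = U.T @ y
    Xt = U.T @ X
    converged = True
    if h2 is None:
        # coarse grid to bracket, then bounded refinement (REML surface can be flat)
        grid = np.linspace(0.0, 0.999, 41)
        vals = np.array([_reml_neg_loglik(g, lam, yt, Xt) for g in grid])
        if not np.isfinite(vals).any():
            raise ValueError("restricted likelihood is degenerate for every h2")
        g0 = grid[int(np.argmin(vals))]
        lo, hi = max(0.0, g0 - 0.05), min(0.999, g0 + 0.05)
        res = optimize.minimize_scalar(
            _reml_neg_loglik, bounds=(lo, hi), args=(lam, yt, Xt), method="bounded",
            options={"xatol": 1e-8},
        )
        if res.success:
            h2 = float(res.x) if res.fun <= vals.min() else float(g0)
        else:
            h2, converged = float(g0), False
    w = h2 * lam + (1.0 - h2)
    sw = 1.0 / np.sqrt(w)
    ys = yt * sw
    Xs = Xt * sw[:, None]
    Gs = (U.T @ G) * sw[:, None]
    F, pvals, df2 = _per_variant_f(ys, Gs, Xs)
    # residual scale of the null model on the whitened data
    r = _residualize(ys[:, None], Xs)[:, 0]
    s2 = float(r @ r) / (n - Xs.shape[1])
    vc = {
        "h2": float(h2),
        "sigma_g2": float(h2 * s2),
        "sigma_e2": float((1.0 - h2) * s2),
        "converged": converged,
    }
    return _scan_frame(F, pvals, "mixed", variants), vc


def bonferroni_threshold(m: int, alpha: float = 0.05) -> tuple[float, float]:
    """Per-test p-value threshold alpha/m and its -log10."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    thr = alpha / m
    return thr, float(-np.log10(thr))


@dataclass
class ThresholdConfig:
    """Allele-switching simulation settings.

    ``proportions``: fractions of samples whose pseudo-SNP genotype is
    flipped (must be <= 0.5; flipping more than half is the mirror image).
    ``percentile``: upper percentile of the F distribution used as the
    threshold at the chosen proportion.
    """

    proportions: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
    reps: int = 1000
    percentile: float = 97.5
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(p < 0 or p > 0.5 for p in self.proportions):
            raise ValueError("switching proportions must be in [0, 0.5]")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


def _simple_f(y: np.ndarray, g: np.ndarray) -> float:
    """1-df F of a single regressor with intercept."""
    gc = g - g.mean()
    yc = y - y.mean()
    gg = float(gc @ gc)
    if gg <= 1e-12:
        return 0.0
    rss0 = float(yc @ yc)
    explained = float(gc @ yc) ** 2 / gg
    rss1 = rss0 - explained
    df2 = y.shape[0] - 2
    return float(explained / (rss1 / df2)) if rss1 > 0 else np.inf


def allele_switch_threshold(
    phenotype: np.ndarray | pd.Series,
    groups: pd.Series | np.ndarray,
    config: ThresholdConfig | None = None,
    basal: str = "basal",
    derived: str = "derived",
) -> dict:
    """Threshold F from the allele-switching simulation.

    A pseudo-SNP perfectly fixed between the two groups (dosage 0 in basal,
    2 in derived) is the starting point; for each configured proportion p,
    ``reps`` randomizations flip the genotype (0 <-> 2) in a uniformly chosen
    fraction p of samples and record the F of the flipped pseudo-SNP against
    the real phenotype.

    The returned threshold is the configured percentile of the F
    distribution at the largest proportion at which the switched SNP remains
    distinguishable from a fully randomized one (lower ``alpha/2`` percentile
    above the upper ``1-alpha/2`` percentile at p = 0.5); the full
    per-proportion distribution table is always returned so users can apply
    their own rule.
    """
    cfg = config or ThresholdConfig()
    y = np.asarray(phenotype, dtype=float)
    glab = pd.Series(np.asarray(groups)).astype(str)
    if not {basal, derived} <= set(glab.unique()):
        raise ValueError(f"groups must contain labels {basal!r} and {derived!r}")
    g0 = np.where(glab.to_numpy() == derived, 2.0, 0.0)
    n = y.shape[0]
    rng = np.random.default_rng(cfg.seed)

    dists: dict[float, np.ndarray] = {}
    for prop in cfg.proportions:
        k = int(round(prop * n))
        Fs = np.empty(cfg.reps)
        for r in range(cfg.reps):
            g = g0.copy()
            if k:
                flip = rng.choice(n, size=k, replace=False)
                g[flip] = 2.0 - g[flip]
            Fs[r] = _simple_f(y, g)
        dists[prop] = Fs

    # reference null: fully randomized pseudo-SNP (p = 0.5)
    if 0.5 in dists:
        null = dists[0.5]
    else:
        null = np.empty(cfg.reps)
        for r in range(cfg.reps):
            g = g0.copy()
            flip = rng.choice(n, size=n // 2, replace=False)
            g[flip] = 2.0 - g[flip]
            null[r] = _simple_f(y, g)
    null_hi = float(np.percentile(null, 100 * (1 - cfg.alpha / 2)))

    chosen = None
    for prop in sorted(p for p in dists if p < 0.5):
        lo = float(np.percentile(dists[prop], 100 * cfg.alpha / 2))
        if lo > null_hi:
            chosen = prop
    if chosen is None:
        chosen = min(dists)
    threshold = float(np.percentile(dists[chosen], cfg.percentile))

    table = pd.DataFrame(
        [
            {
                "proportion": prop,
                "mean_F": float(Fs.mean()),
                "median_F": float(np.median(Fs)),
                "p2.5_F": float(np.percentile(Fs, 2.5)),
                "p97.5_F": float(np.percentile(Fs, 97.5)),
            }
            for prop, Fs in sorted(dists.items())
        ]
    )
    return {
        "threshold_F": threshold,
        "chosen_proportion": chosen,
        "percentile": cfg.percentile,
        "unswitched_F": float(dists[min(dists)][0]) if 0.0 in dists else None,
        "table": table,
        "distributions": dists,
        "seed": cfg.seed,
        "reps": cfg.reps,
    }


def flag_tas(scan: pd.DataFrame, threshold: float, on: str = "F") -> pd.DataFrame:
    """Add an ``is_tas`` flag: F >= threshold (on='F') or p <= threshold (on='p')."""
    out = scan.copy()
    if on == "F":
        out["is_tas"] = out["F"] >= threshold
    elif on == "p":
        out["is_tas"] = out["p"] <= threshold
    else:
        raise ValueError("on must be 'F' or 'p'")
    out.attrs["threshold"] = threshold
    out.attrs["threshold_on"] = on
    return out


def _variance_fraction(values: np.ndarray, labels: np.ndarray) -> float:
    """Between-group fraction of variance via the one-way random-effects
    (method-of-moments) decomposition, clipped to [0, 1]."""
    groups = [values[labels == g] for g in np.unique(labels)]
    a = len(groups)
    if a < 2:
        raise ValueError("need at least two groups")
    ns = np.array([len(g) for g in groups], dtype=float)
    N = ns.sum()
    grand = values.mean()
    msb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups) / (a - 1)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msw = ssw / (N - a)
    n0 = (N - (ns**2).sum() / N) / (a - 1)
    sb2 = max((msb - msw) / n0, 0.0)
    tot = sb2 + msw
    return float(sb2 / tot) if tot > 0 else 0.0


def subsample_variance(
    variants: pd.DataFrame,
    genotypes: GenotypeMatrix,
    groups: pd.Series,
    site_counts: list[int],
    reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Between-group variance fraction of frac_a as a function of the number
    of polymorphic sites used for the calculation.

    For each k: resample k variants without replacement, recompute frac_a,
    and estimate between/(between+within) variance by the one-way
    random-effects decomposition; mean and sd over ``reps`` resamples.
    """
    from .poly_composition import base_phenotype

    m = genotypes.n_variants
    labels = groups.reindex(genotypes.samples).to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for k in site_counts:
        if k < 2:
            raise ValueError("site counts must be >= 2")
        if k > m:
            raise ValueError(f"site count {k} exceeds the {m} available variants")
        n_rep = 1 if k == m else reps
        fracs = np.empty(n_rep)
        for r in range(n_rep):
            idx = rng.choice(m, size=k, replace=False) if k < m else np.arange(m)
            pheno = base_phenotype(variants.iloc[idx].reset_index(drop=True),
                                   genotypes.subset_variants(idx))
            fracs[r] = _variance_fraction(pheno["frac_a"].to_numpy(), labels)
        rows.append({"n_sites": k, "mean_fraction": float(fracs.mean()),
                     "sd_fraction": float(fracs.std(ddof=1)) if n_rep > 1 else 0.0,
                     "reps": n_rep})
    return pd.DataFrame(rows)
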