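"""Kinship estimation and linear mixed-model association.

Single-variant association under the model

    y = W alpha + x beta + u + e,   u ~ N(0, sg^2 K),   e ~ N(0, se^2 I)

fitted by maximum likelihood.  The variance ratio lambda = sg^2 / se^2 is
profiled on the eigendecomposition of the kinship matrix K and optimised by
a bounded one-dimensional search on log10(lambda) in [-5, 5]; p-values come
from the likelihood-ratio test (chi-square, 1 df) against the model without
the variant.  ML (not REML) is used throughout so that likelihood-ratio
statistics are directly comparable between nested models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .containers import MISSING, GenotypeMatrix

LOG10_LAMBDA_BOUNDS = (-5.0, 5.0)


@dataclass
class KinshipMatrix:
    values: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix must be square")
        if len(self.samples) != n:
            raise ValueError("sample list must match matrix dimension")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def check_psd(self, tol: float = 1e-8) -> None:
        if getattr(self, "_psd_checked", False):
            return
        if np.count_nonzero(self.values - np.diag(np.diag(self.values))) == 0:
            w = np.diag(self.values)
        else:
            w = np.linalg.eigvalsh(self.values)
        if w.min() < -tol * max(1.0, abs(w.max())):
            raise ValueError("kinship matrix is not positive semi-definite")
        self._psd_checked = True


@dataclass
class AssocResult:
    variant_id: str
    effect_allele: str
    effect_allele_freq: float
    beta: float
    se: float
    p_lrt: float
    variance_explained: float
    n: int
    loglik_alt: float = np.nan
    loglik_null: float = np.nan
    lambda_hat: float = np.nan
    odds_ratio: float | None = None
    odds_ratio_ci: tuple[float, float] | None = None


def kinship_centered(g: GenotypeMatrix) -> KinshipMatrix:
    """Centered genotype relatedness matrix: K = W W^T / p with columns
    x - 2f, missing genotypes mean-imputed per variant (for this computation
    only)."""
    geno = g.genotypes.astype(float)
    geno[geno == MISSING] = np.nan
    freq = np.nanmean(geno, axis=0) / 2.0
    poly = (freq > 0) & (freq < 1) & ~np.isnan(freq)
    if poly.sum() == 0:
        raise ValueError("no polymorphic variants for kinship estimation")
    w = geno[:, poly] - 2.0 * freq[poly]
    w = np.nan_to_num(w, nan=0.0)  # mean-imputed values are exactly centered
    k = w @ w.T / poly.sum()
    return KinshipMatrix(k, list(g.samples))


# ---------------------------------------------------------------------------
# profiled ML machinery
# ---------------------------------------------------------------------------


class _EigenLMM:
    """Profiled ML log-likelihood on the rotated problem.

    Computes, for a fixed design X, the profile log-likelihood of
    log10(lambda) after rotating y and X by the eigenvectors of K.
    """

    def __init__(self, eigvals: np.ndarray, y_rot: np.ndarray, x_rot: np.ndarray):
        self.s = eigvals
        self.y = y_rot
        self.X = x_rot
        self.n = len(y_rot)

    def loglik(self, log10_lam: float) -> float:
        lam = 10.0**log10_lam
        d = lam * self.s + 1.0
        w = 1.0 / d
        Xw = self.X * w[:, None]
        xtx = self.X.T @ Xw
        xty = Xw.T @ self.y
        try:
            beta = np.linalg.solve(xtx, xty)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(self.X, self.y, rcond=None)[0]
        r = self.y - self.X @ beta
        rss = float((r * r * w).sum())
        n = self.n
        sigma2 = max(rss / n, 1e-300)
        return -0.5 * (
            n * np.log(2 * np.pi) + n * np.log(sigma2) + n + np.log(d).sum()
        )

    def fit(self, coarse: int = 21) -> tuple[float, float]:
        """Maximise over log10(lambda): coarse grid bracketing followed by a
        bounded scalar search.  Returns (log10_lambda_hat, loglik)."""
        lo, hi = LOG10_LAMBDA_BOUNDS
        grid = np.linspace(lo, hi, coarse)
        vals = np.array([self.loglik(x) for x in grid])
        i = int(np.argmax(vals))
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, coarse - 1)]
        res = optimize.minimize_scalar(
            lambda x: -self.loglik(x), bounds=(a, b), method="bounded",
            options={"xatol": 1e-8},
        )
        best_x, best_ll = float(res.x), -float(res.fun)
        # keep the boundary if the interior search did not beat the grid
        if vals[i] > best_ll:
            best_x, best_ll = float(grid[i]), float(vals[i])
        return best_x, best_ll

    def gls_beta_se(self, log10_lam: float) -> tuple[np.ndarray, np.ndarray]:
        lam = 10.0**log10_lam
        w = 1.0 / (lam * self.s + 1.0)
        Xw = self.X * w[:, None]
        xtx = self.X.T @ Xw
        # pinv tolerates a singular design (e.g. conditioning on the tested
        # variant itself); the corresponding se is then only nominal
        xtx_inv = np.linalg.pinv(xtx)
        beta = xtx_inv @ (Xw.T @ self.y)
        r = self.y - self.X @ beta
        sigma2 = float((r * r * w).sum()) / self.n  # ML variance estimate
        cov = sigma2 * xtx_inv
        return beta, np.sqrt(np.maximum(np.diag(cov), 0.0))


def _eigen_cached(K: KinshipMatrix, ok: np.ndarray, Ksub: np.ndarray):
    """Eigendecomposition of the complete-case kinship submatrix, cached on
    the KinshipMatrix per complete-case pattern (it is reused across variants
    and replicate fits).  Returns (eigenvalues, eigenvectors-or-None)."""
    cache = getattr(K, "_eigen_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(K, "_eigen_cache", cache)
    key = ok.tobytes()
    if key not in cache:
        if np.count_nonzero(Ksub - np.diag(np.diag(Ksub))) == 0:
            cache[key] = (np.diag(Ksub).copy(), None)
        else:
            s, U = np.linalg.eigh(Ksub)
            cache[key] = (np.clip(s, 0.0, None), U)
        if len(cache) > 8:  # bound memory across many missingness patterns
            cache.pop(next(iter(cache)))
    return cache[key]


def _prepare(y, x, covariates, K: KinshipMatrix):
    y = np.asarray(y, dtype=float)
    x = None if x is None else np.asarray(x, dtype=float)
    n = len(y)
    if K.n != n:
        raise ValueError("kinship dimension does not match trait length")
    if covariates is None:
        W = np.ones((n, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        W = np.column_stack([np.ones(n), covariates])
    ok = ~np.isnan(y) & ~np.isnan(W).any(axis=1)
    if x is not None:
        ok &= ~np.isnan(x) & (x != MISSING)
    return y, x, W, ok


def lmm_fit(
    y,
    x,
    K: KinshipMatrix,
    covariates=None,
    variant_id: str = "variant",
    effect_allele: str = "ALT",
) -> AssocResult:
    """Single-variant LMM association with likelihood-ratio p-value.

    Rows with missing trait, covariate or dosage values are dropped (complete
    cases).  Returns effect size, standard error, LRT p-value and the trait
    variance explained by the variant.
    """
    K.check_psd()
    y, x, W, ok = _prepare(y, x, covariates, K)
    n_drop = int((~ok).sum())
    if n_drop:
        warnings.warn(f"dropping {n_drop} incomplete rows")
    y, x, W = y[ok], x[ok], W[ok]
    Ksub = K.values[np.ix_(ok, ok)]
    n = len(y)
    if n < W.shape[1] + 2:
        raise ValueError("too few complete cases")

    f = float(np.mean(x) / 2.0)
    if np.all(x == x[0]):
        warnings.warn("constant dosage; association undefined")
        return AssocResult(
            variant_id, effect_allele, f, 0.0, np.inf, 1.0, 0.0, n
        )

    s, U = _eigen_cached(K, ok, Ksub)
    if U is None:  # diagonal kinship: rotation is the identity
        y_rot, W_rot, x_rot = y, W, x
    else:
        y_rot = U.T @ y
        W_rot = U.T @ W
        x_rot = U.T @ x

    alt = _EigenLMM(s, y_rot, np.column_stack([W_rot, x_rot]))
    null = _EigenLMM(s, y_rot, W_rot)
    lam_alt, ll_alt = alt.fit()
    lam_null, ll_null = null.fit()
    lrt = max(0.0, 2.0 * (ll_alt - ll_null))
    p = float(stats.chi2.sf(lrt, 1))
    beta_vec, se_vec = alt.gls_beta_se(lam_alt)
    beta = float(beta_vec[-1])
    se = float(se_vec[-1])
    ve = variance_explained(beta, f, float(np.var(y)))
    return AssocResult(
        variant_id,
        effect_allele,
        f,
        beta,
        se,
        p,
        ve,
        n,
        loglik_alt=ll_alt,
        loglik_null=ll_null,
        lambda_hat=10.0**lam_alt,
    )


def variance_explained(beta: float, f: float, var_y: float) -> float:
    """Fraction of trait variance from an additive biallelic variant:
    2 f (1-f) beta^2 / var_y, clamped to [0, 1)."""
    if var_y <= 0:
        raise ValueError("trait variance must be positive")
    ve = 2.0 * f * (1.0 - f) * beta**2 / var_y
    return float(np.clip(ve, 0.0, 1.0 - 1e-12))


def conditional_fit(
    y,
    x_test,
    x_condition,
    K: KinshipMatrix,
    covariates=None,
    variant_id: str = "variant",
) -> AssocResult:
    """Association of ``x_test`` conditional on ``x_condition`` (added to the
    covariates).  Warns on near-collinear test/conditioning dosages."""
    xt = np.asarray(x_test, dtype=float)
    xc = np.atleast_2d(np.asarray(x_condition, dtype=float))
    if xc.shape[0] != len(xt):
        xc = xc.T
    for k in range(xc.shape[1]):
        ok = ~np.isnan(xt) & ~np.isnan(xc[:, k])
        if ok.sum() > 2 and np.std(xt[ok]) > 0 and np.std(xc[ok, k]) > 0:
            r2 = float(np.corrcoef(xt[ok], xc[ok, k])[0, 1] ** 2)
            if r2 > 0.999:
                warnings.warn("test and conditioning variants are collinear")
    cov = xc if covariates is None else np.column_stack(
        [np.atleast_2d(np.asarray(covariates, float).T).T, xc]
    )
    return lmm_fit(y, xt, K, covariates=cov, variant_id=variant_id)


def binary_trait_fit(
    y01,
    x,
    K: KinshipMatrix,
    covariates=None,
    variant_id: str = "variant",
) -> AssocResult:
    """Mixed-model association for a 0/1 trait.

    The linear mixed model is fitted directly on the binary scale, so beta is
    a per-allele risk difference; an exponentiated effect with a Wald 95%
    interval is also reported for odds-ratio-style presentation.
    """
    y = np.asarray(y01, dtype=float)
    vals = set(np.unique(y[~np.isnan(y)]))
    if not vals <= {0.0, 1.0}:
        raise ValueError("binary trait must be coded 0/1")
    if len(vals) < 2:
        raise ValueError("binary trait has a single class")
    res = lmm_fit(y, x, K, covariates=covariates, variant_id=variant_id)
    if np.isfinite(res.se):
        res.odds_ratio = float(np.exp(res.beta))
        res.odds_ratio_ci = (
            float(np.exp(res.beta - 1.96 * res.se)),
            float(np.exp(res.beta + 1.96 * res.se)),
        )
    return res


def association_scan(
    y, g: GenotypeMatrix, K: KinshipMatrix, covariates=None
):
    """Fit every variant in a genotype matrix; yields AssocResult objects."""
    for j in range(g.n_variants):
        x = g.genotypes[:, j].astype(float)
        x[x == MISSING] = np.nan
        row = g.variants.iloc[j]
        try:
            yield lmm_fit(
                y, x, K, covariates=covariates,
                variant_id=str(row["id"]), effect_allele=str(row["alt"]),
            )
        except ValueError:
            continue
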