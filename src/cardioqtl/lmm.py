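"""Linear mixed model engine for kinship-aware association scans.

The model for one feature is

    y = W g + x b + u + e,   u ~ N(0, s2_g K),  e ~ N(0, s2_e I)

with W the fixed covariates (intercept, genotype PCs, latent factors,
technical covariates) and x a candidate variant's standardized dosage.
One eigendecomposition K = U S U' per kinship matrix rotates the problem
into independent observations with variances s2_g * s_i + s2_e. Variance
components are estimated once per feature by REML under the null model
(no genotype) and reused for every cis variant of that feature, which is
the approximation family used by the standard eQTL scan tools.

Wald tests are used throughout. After whitening by the null-model
weights, each variant's test is an ordinary regression in the rotated
space, so the per-variant residual scale is re-estimated there and the
statistic is referred to a t distribution with n - p - 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["LMMEngine", "NullModel"]


@dataclass
class NullModel:
    """Null-model (covariates-only) REML fit for one response."""

    h2: float                  # variance fraction on the kinship eigenspectrum
    sigma2: float              # total residual scale
    weights: np.ndarray        # 1 / (h2 * s_i + (1 - h2)), up to sigma2
    y_rot: np.ndarray
    w_rot: np.ndarray
    q_white: np.ndarray        # orthonormal basis of whitened covariates
    y_resid: np.ndarray        # whitened response residualized on covariates
    rss: float
    df: int


class LMMEngine:
    """Reusable eigendecomposition of one kinship matrix."""

    def __init__(self, kinship: np.ndarray | None, n: int | None = None) -> None:
        if kinship is None:
            if n is None:
                raise ValueError("need n when kinship is None")
            self.n = n
            self.eigvals = np.ones(n)
            self.eigvecs = None  # identity rotation
            return
        kinship = np.asarray(kinship, dtype=float)
        self.n = kinship.shape[0]
        k = 0.5 * (kinship + kinship.T)
        s, u = np.linalg.eigh(k)
        neg = s < 0
        if np.any(s < -1e-8 * max(s.max(), 1.0)):
            import warnings

            warnings.warn("kinship matrix not PSD; clipping negative eigenvalues at 0")
        s = np.where(neg, 0.0, s)
        # scale so the mean eigenvalue is 1: h2 then has a variance-fraction reading
        scale = s.mean()
        if scale <= 0:
            raise ValueError("kinship matrix has zero trace")
        self.eigvals = s / scale
        self.eigvecs = u

    def rotate(self, a: np.ndarray) -> np.ndarray:
        if self.eigvecs is None:
            return np.asarray(a, dtype=float)
        return self.eigvecs.T @ np.asarray(a, dtype=float)

    # ---------------------------------------------------------------- REML

    def _reml_neg_ll(self, h2: float, y_rot: np.ndarray, w_rot: np.ndarray) -> float:
        v = h2 * self.eigvals + (1.0 - h2)
        w = 1.0 / v
        sw = np.sqrt(w)
        ww = w_rot * sw[:, None]
        yw = y_rot * sw
        q, r = np.linalg.qr(ww)
        resid = yw - q @ (q.T @ yw)
        rss = float(resid @ resid)
        n, p = w_rot.shape
        df = n - p
        if rss <= 0:
            return np.inf
        logdet_v = float(np.sum(np.log(v)))
        logdet_wvw = 2.0 * float(np.sum(np.log(np.abs(np.diag(r)))))
        return df * np.log(rss / df) + logdet_v + logdet_wvw

    def fit_null(self, y: np.ndarray, covariates: np.ndarray | None) -> NullModel:
        """REML fit of the covariates-only model; covariates get an intercept
        prepended if no constant column is present."""
        y = np.asarray(y, dtype=float)
        w = _with_intercept(covariates, self.n)
        w = _drop_collinear(w)
        y_rot = self.rotate(y)
        w_rot = self.rotate(w)

        if self.eigvecs is None or np.allclose(self.eigvals, self.eigvals[0]):
            h2 = 0.0  # homogeneous spectrum: weights are constant, GLS = OLS
        else:
            obj = lambda h2: self._reml_neg_ll(h2, y_rot, w_rot)
            grid = np.linspace(0.0, 0.99, 12)
            vals = [obj(g) for g in grid]
            i = int(np.argmin(vals))
            lo = grid[max(i - 1, 0)]
            hi = grid[min(i + 1, len(grid) - 1)]
            if hi > lo:
                res = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded")
                h2 = float(res.x)
            else:
                h2 = float(grid[i])

        v = h2 * self.eigvals + (1.0 - h2)
        weights = 1.0 / v
        sw = np.sqrt(weights)
        ww = w_rot * sw[:, None]
        yw = y_rot * sw
        q, _ = np.linalg.qr(ww)
        y_resid = yw - q @ (q.T @ yw)
        rss = float(y_resid @ y_resid)
        df = self.n - w.shape[1]
        return NullModel(
            h2=h2,
            sigma2=rss / df,
            weights=weights,
            y_rot=y_rot,
            w_rot=w_rot,
            q_white=q,
            y_resid=y_resid,
            rss=rss,
            df=df,
        )

    # ---------------------------------------------------------------- scans

    def scan(self, null: NullModel, genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Wald statistics for each column of ``genotypes`` added singly to the
        null model. Genotype columns are standardized; zero-variance columns
        return NaN. Returns (beta, se, p)."""
        g = np.asarray(genotypes, dtype=float)
        if g.ndim == 1:
            g = g[:, None]
        sd = g.std(axis=0)
        ok = sd > 0
        gz = np.zeros_like(g)
        gz[:, ok] = (g[:, ok] - g[:, ok].mean(axis=0)) / sd[ok]

        sw = np.sqrt(null.weights)
        gw = self.rotate(gz) * sw[:, None]
        gw -= null.q_white @ (null.q_white.T @ gw)

        gtg = np.einsum("ij,ij->j", gw, gw)
        gty = gw.T @ null.y_resid
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = gty / gtg
            df = null.df - 1
            rss = null.rss - beta * gty
            rss = np.maximum(rss, 0.0)
            sigma2 = rss / df
            se = np.sqrt(sigma2 / gtg)
            tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
        beta = np.where(ok & (gtg > 1e-12), beta, np.nan)
        se = np.where(ok & (gtg > 1e-12), se, np.nan)
        p = np.where(ok & (gtg > 1e-12), p, np.nan)
        return beta, se, p

    def fit_terms(
        self, y: np.ndarray, covariates: np.ndarray | None, terms: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Joint GLS fit of ``terms`` (n x k, not standardized) on top of the
        covariates; variance components from the covariates-only null.
        Returns (coef, se, p) for the k term columns."""
        null = self.fit_null(y, covariates)
        t = np.asarray(terms, dtype=float)
        if t.ndim == 1:
            t = t[:, None]
        k = t.shape[1]
        sw = np.sqrt(null.weights)
        tw = self.rotate(t) * sw[:, None]
        x = np.column_stack([null.w_rot * sw[:, None], tw])
        coef, _, rank, _ = np.linalg.lstsq(x, null.y_rot * sw, rcond=None)
        resid = null.y_rot * sw - x @ coef
        df = self.n - rank
        sigma2 = float(resid @ resid) / df
        xtx_inv = np.linalg.pinv(x.T @ x)
        se_all = np.sqrt(sigma2 * np.diag(xtx_inv))
        cf = coef[-k:]
        se = se_all[-k:]
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = cf / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
        return cf, se, p


def _with_intercept(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    w = np.asarray(covariates, dtype=float)
    if w.ndim == 1:
        w = w[:, None]
    const = np.any(np.all(w == w[0], axis=0) & (w[0] != 0))
    if not const:
        w = np.column_stack([np.ones(n), w])
    return w


def _drop_collinear(w: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Drop trailing columns that are linearly dependent on earlier ones."""
    q, r = np.linalg.qr(w)
    diag = np.abs(np.diag(r))
    keep = diag > tol * max(diag.max(), 1.0)
    if keep.all():
        return w
    import warnings

    warnings.warn(f"dropping {np.sum(~keep)} collinear covariate column(s)")
    return w[:, keep]
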