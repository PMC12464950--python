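"""Statistical stage: PCA on standardized spectra, OLS fits, correlations.

The workflow mirrors a conventional chemometrics/phenotyping analysis:
spectra are standardized per wavelength and decomposed by PCA; responses are
related to fruit fresh weight by ordinary least squares (with an optional
weight x cultivar interaction to test slope differences between cultivars);
band-ratio indices vs weight are fitted with a second-order polynomial whose
vertex locates the lens-saturation weight; and a pairwise Pearson
correlation matrix with two-sided p-values summarises all responses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .spectra import Spectrum, standardize

__all__ = [
    "PCAResult",
    "LinearFit",
    "QuadraticFit",
    "CorrelationMatrix",
    "pca_spectra",
    "fit_linear",
    "fit_interaction",
    "fit_poly2",
    "pearson_matrix",
    "significance_stars",
]


@dataclass
class PCAResult:
    """Scores (n x k), loadings (k x p) and percent variance per component.

    ``explained_pct`` covers all min(n-1, p) components and sums to 100;
    ``scores``/``loadings`` are truncated to the requested k.  Each loading
    vector is oriented so its largest-magnitude element is positive.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_pct: np.ndarray


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    interaction: float | None = None
    interaction_p: float | None = None


@dataclass
class QuadraticFit:
    a: float
    b: float
    c: float
    r_squared: float

    @property
    def vertex_x(self) -> float:
        return -self.b / (2.0 * self.a)

    @property
    def is_maximum(self) -> bool:
        return self.a < 0


def pca_spectra(spectra: Sequence[Spectrum] | np.ndarray,
                n_components: int | None = None) -> PCAResult:
    """PCA of per-wavelength standardized spectra.

    Eigen-decomposition of the sample covariance of the standardized data
    (equivalently, of the correlation matrix of the raw spectra), components
    ordered by decreasing variance.
    """
    from sklearn.decomposition import PCA

    z = standardize(spectra)
    n, p = z.shape
    k_full = min(n - 1, p)
    if n_components is None:
        n_components = k_full
    if n_components > k_full:
        raise ValueError(
            f"cannot extract {n_components} components from {n} spectra "
            f"({k_full} available)"
        )
    pca = PCA(n_components=k_full).fit(z)
    explained_pct = pca.explained_variance_ratio_ * 100.0
    scores = pca.transform(z)[:, :n_components]
    loadings = pca.components_[:n_components].copy()
    for j in range(loadings.shape[0]):
        if loadings[j, np.argmax(np.abs(loadings[j]))] < 0:
            loadings[j] *= -1.0
            scores[:, j] *= -1.0
    return PCAResult(scores=scores, loadings=loadings, explained_pct=explained_pct)


def _check_xy(x, y, min_n: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; cannot fit")
    return x, y


def fit_linear(x, y) -> LinearFit:
    """OLS of y on x with intercept; p-value is the slope's two-sided t-test."""
    import statsmodels.api as sm

    x, y = _check_xy(x, y, 3)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
    )


def fit_interaction(x, y, group) -> LinearFit:
    """OLS of y ~ x + group + x:group for a two-level group.

    The reported slope/intercept describe the reference (first sorted) group;
    ``interaction`` is the slope difference of the second group, and its
    t-test p-value tells whether the two groups' slopes differ.
    """
    import statsmodels.api as sm

    x, y = _check_xy(x, y, 4)
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(f"group must have exactly 2 levels, got {levels.size}")
    g = (group == levels[1]).astype(float)
    design = sm.add_constant(np.column_stack([x, g, x * g]))
    model = sm.OLS(y, design).fit()
    return LinearFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        interaction=float(model.params[3]),
        interaction_p=float(model.pvalues[3]),
    )


def fit_poly2(x, y) -> QuadraticFit:
    """Least-squares quadratic y = a*x^2 + b*x + c with vertex at -b/(2a)."""
    x, y = _check_xy(x, y, 4)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct x values for a quadratic fit")
    design = np.column_stack([x**2, x, np.ones_like(x)])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 3:
        raise ValueError("degenerate design matrix for quadratic fit")
    resid = y - design @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return QuadraticFit(a=float(coef[0]), b=float(coef[1]), c=float(coef[2]),
                        r_squared=r2)


def significance_stars(p: float) -> str:
    """Conventional significance stars: * <0.05, ** <0.01, *** <0.001."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson r, two-sided p-values and pair counts."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def stars(self) -> pd.DataFrame:
        return self.p.map(significance_stars)

    def annotated(self) -> pd.DataFrame:
        """r rounded to 3 decimals with significance stars appended."""
        out = self.r.round(3).astype(str) + self.stars()
        np.fill_diagonal(out.values, "1")
        return out


def pearson_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """Pearson correlation of every pair of columns, pairwise-complete.

    p-values come from the t transform with n - 2 degrees of freedom; pairs
    with fewer than 3 complete observations are flagged missing (NaN).
    """
    cols = list(table.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            xi = pd.to_numeric(table[cols[i]], errors="coerce")
            xj = pd.to_numeric(table[cols[j]], errors="coerce")
            ok = xi.notna() & xj.notna()
            n[i, j] = n[j, i] = int(ok.sum())
            if i == j:
                r[i, i], p[i, i] = 1.0, 0.0
                continue
            if n[i, j] < 3:
                continue
            res = sps.pearsonr(xi[ok], xj[ok])
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    idx = pd.Index(cols)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
    )
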