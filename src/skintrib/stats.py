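"""Statistical layer: PCA, concentration ellipsoids, Tukey-Kramer tests.

PCA here is the plain eigendecomposition of the sample covariance (or
correlation) matrix of an observations x variables table.  Covariance mode
on the raw 1-10 ratings is the default for sensory data — the scale is
shared across attributes and the component variances then carry rating
units.  Correlation mode standardizes each variable first and is the
default when mixing tribological variables of different units.

The Tukey-Kramer procedure compares all group-mean pairs with the
studentized-range distribution, using the unequal-sample-size standard
error ``sqrt((MSE/2)(1/n_i + 1/n_j))``; with equal group sizes it reduces
to the classical Tukey HSD.  Family-wise error is controlled within one
feature family at a time (one test per panel), with no further correction
across families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError, ValidationError

logger = logging.getLogger(__name__)

NEAR_ZERO_R = 0.2  # |r| below this is reported as "near-zero"


# ---------------------------------------------------------------------------
# Principal component analysis
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Eigendecomposition of a centered (optionally standardized) table.

    ``loadings`` columns are the orthonormal eigenvectors, sign-fixed so
    the largest-magnitude loading of each component is positive;
    ``scores = X_centered @ loadings``.
    """

    eigenvalues: np.ndarray
    variance_pct: np.ndarray
    cumulative_pct: np.ndarray
    loadings: pd.DataFrame          # variables x components
    scores: np.ndarray              # observations x components
    mode: str
    mean: np.ndarray
    scale: np.ndarray | None = None
    observation_index: pd.Index | None = None

    @property
    def variables(self) -> list:
        return list(self.loadings.index)

    def variance_table(self) -> pd.DataFrame:
        """Eigenvalue / variance% / cumulative% table, one row per component."""
        return pd.DataFrame(
            {
                "component": [f"PC{k + 1}" for k in range(len(self.eigenvalues))],
                "eigenvalue": self.eigenvalues,
                "variance_pct": self.variance_pct,
                "cumulative_pct": self.cumulative_pct,
            }
        )

    def reconstruct(self) -> np.ndarray:
        """Back-project scores to the original (unscaled) variable space."""
        X = self.scores @ self.loadings.to_numpy().T
        if self.scale is not None:
            X = X * self.scale
        return X + self.mean


def variance_percentages(eigenvalues) -> tuple[np.ndarray, np.ndarray]:
    """Variance contribution (%) and cumulative (%) from eigenvalues."""
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(ev < 0):
        raise ValidationError("eigenvalues must be >= 0")
    total = ev.sum()
    if total <= 0:
        raise ValidationError("eigenvalues sum to zero")
    pct = 100.0 * ev / total
    return pct, np.cumsum(pct)


def run_pca(matrix, mode: str = "covariance") -> PCAModel:
    """PCA of an observations x variables table.

    Parameters
    ----------
    matrix : DataFrame or array, shape (n_obs, n_vars)
        Complete data, at least 2 observations and 2 variables.
    mode : {"covariance", "correlation"}
        Whether to standardize variables before the eigendecomposition.
        Correlation mode raises, naming the variable, if any variable is
        constant.
    """
    if isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns)
        index = matrix.index
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        names = [f"var{j + 1}" for j in range(X.shape[1])] if X.ndim == 2 else None
        index = None
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("need at least 2 observations and 2 variables")
    if np.isnan(X).any():
        raise ValidationError("PCA input contains missing cells")
    if mode not in ("covariance", "correlation"):
        raise ParameterError(f"unknown mode {mode!r}")

    mean = X.mean(axis=0)
    Xc = X - mean
    scale = None
    if mode == "correlation":
        sd = Xc.std(axis=0, ddof=1)
        zero = np.nonzero(sd == 0)[0]
        if zero.size:
            raise ValidationError(
                f"constant variable(s) in correlation mode: "
                f"{[names[j] for j in zero]}"
            )
        scale = sd
        Xc = Xc / sd

    C = (Xc.T @ Xc) / (X.shape[0] - 1)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    for j in range(V.shape[1]):  # deterministic sign: top loading positive
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    pct, cum = variance_percentages(w)
    loadings = pd.DataFrame(
        V, index=names, columns=[f"PC{k + 1}" for k in range(V.shape[1])]
    )
    return PCAModel(
        eigenvalues=w, variance_pct=pct, cumulative_pct=cum,
        loadings=loadings, scores=Xc @ V, mode=mode, mean=mean, scale=scale,
        observation_index=index,
    )


# ---------------------------------------------------------------------------
# Concentration ellipsoids
# ---------------------------------------------------------------------------

@dataclass
class Ellipsoid:
    """A level-``level`` concentration (data) ellipsoid of group scores."""

    center: np.ndarray
    axes: np.ndarray        # columns: orthonormal principal directions
    radii: np.ndarray
    level: float
    n: int
    group: str | None = None
    degenerate: bool = False
    scaling: str = "chi2"

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which points fall inside the ellipsoid."""
        P = np.atleast_2d(points) - self.center
        with np.errstate(divide="ignore", invalid="ignore"):
            coords = (P @ self.axes) / self.radii
        return np.nansum(coords**2, axis=1) <= 1.0


def concentration_ellipsoid(
    scores: np.ndarray,
    level: float = 0.95,
    dims: int = 3,
    scaling: str = "chi2",
    group: str | None = None,
) -> Ellipsoid:
    """Concentration ellipsoid of one group's component scores.

    The default convention is the population data ellipse: the sample
    covariance of the first ``dims`` score columns scaled by the
    chi-square quantile at ``level`` — the region expected to contain that
    fraction of the group's distribution.  ``scaling="f"`` instead gives
    the confidence region for the group *mean*
    (``dims (n-1) / (n (n-dims)) * F`` scaling), a much smaller ellipsoid.

    Groups with fewer than ``dims + 1`` points, or with a singular
    covariance, are returned with the ``degenerate`` flag set.
    """
    P = np.atleast_2d(np.asarray(scores, dtype=float))[:, :dims]
    n = P.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 points for an ellipsoid")
    if not 0 < level < 1:
        raise ParameterError("level must be in (0, 1)")
    center = P.mean(axis=0)
    cov = np.cov(P, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, V = np.clip(w[order], 0.0, None), V[:, order]
    if scaling == "chi2":
        c = sps.chi2.ppf(level, dims)
    elif scaling == "f":
        if n <= dims:
            c = np.nan
        else:
            c = dims * (n - 1) / (n * (n - dims)) * sps.f.ppf(level, dims, n - dims)
    else:
        raise ParameterError(f"unknown scaling {scaling!r}")
    radii = np.sqrt(w * c)
    degenerate = (n < dims + 1) or bool(np.any(radii <= 0)) or not np.all(
        np.isfinite(radii)
    )
    return Ellipsoid(center=center, axes=V, radii=radii, level=level, n=n,
                     group=group, degenerate=degenerate, scaling=scaling)


# ---------------------------------------------------------------------------
# Tukey-Kramer all-pairs comparison
# ---------------------------------------------------------------------------

@dataclass
class TukeyTable:
    """All-pairs comparison result."""

    table: pd.DataFrame
    alpha: float
    k: int
    df: int
    mse: float

    def pair(self, a, b) -> pd.Series:
        t = self.table
        row = t[((t.group_i == a) & (t.group_j == b))
                | ((t.group_i == b) & (t.group_j == a))]
        if row.empty:
            raise ParameterError(f"no pair ({a}, {b}) in table")
        return row.iloc[0]

    @property
    def any_significant(self) -> bool:
        return bool(self.table["significant"].any())


def _pooled_mse(groups: dict) -> tuple[float, int]:
    N = sum(len(v) for v in groups.values())
    k = len(groups)
    df = N - k
    ss = sum((len(v) - 1) * np.var(v, ddof=1) for v in groups.values())
    return ss / df, df


def tukey_kramer(groups: dict, alpha: float = 0.05) -> TukeyTable:
    """Tukey-Kramer all-pairs mean comparison.

    Parameters
    ----------
    groups : mapping label -> 1-D array of values
        At least 2 groups of at least 2 values each.
    alpha : float
        Family-wise significance level (default 0.05).

    Notes
    -----
    For each pair, ``q = |m_i - m_j| / sqrt((MSE/2)(1/n_i + 1/n_j))`` with
    MSE the pooled within-group mean square; the p-value is the survival
    function of the studentized-range distribution with ``k`` groups and
    ``N - k`` degrees of freedom, evaluated by numerical integration.
    When every group has zero variance but means differ, p is reported at
    the numerical floor.
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    clean = {str(g): np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in clean.items():
        if len(v) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 values")
    mse, df = _pooled_mse(clean)
    k = len(clean)
    labels = list(clean)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = labels[i], labels[j]
            vi, vj = clean[gi], clean[gj]
            diff = float(vi.mean() - vj.mean())
            se = np.sqrt((mse / 2.0) * (1.0 / len(vi) + 1.0 / len(vj)))
            if se > 0:
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df))
                if not np.isfinite(p):
                    p = 0.0
                p = min(max(p, np.finfo(float).tiny), 1.0)
            else:  # zero within-group variance everywhere
                q = np.inf if diff != 0 else 0.0
                p = np.finfo(float).tiny if diff != 0 else 1.0
            rows.append(
                dict(group_i=gi, group_j=gj, mean_diff=diff, se=float(se),
                     q=float(q), p=p, significant=bool(p < alpha))
            )
    return TukeyTable(table=pd.DataFrame(rows), alpha=alpha, k=k, df=df, mse=mse)


def family_wise_error_rate(
    k: int = 6,
    n: int = 12,
    n_replicates: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo family-wise type-I error of the Tukey-Kramer test.

    Draws ``k`` groups of ``n`` standard-normal values per replicate and
    reports the fraction of replicates in which any pair is declared
    significant.  Significance is decided by comparing the pairwise ``q``
    statistics against the studentized-range critical value — the same
    decision rule as :func:`tukey_kramer`, precomputed once so the
    simulation stays fast.  The rate should sit near ``alpha``.
    """
    rng = np.random.default_rng(seed)
    df = k * n - k
    q_crit = sps.studentized_range.ppf(1.0 - alpha, k, df)
    hits = 0
    for _ in range(n_replicates):
        X = rng.standard_normal((k, n))
        means = X.mean(axis=1)
        mse = X.var(axis=1, ddof=1).mean()  # equal n: pooled = mean of variances
        q_max = (means.max() - means.min()) / np.sqrt(mse / n)
        if q_max > q_crit:
            hits += 1
    return hits / n_replicates


# ---------------------------------------------------------------------------
# Combined tribology-sensory PCA
# ---------------------------------------------------------------------------

TRIBOLOGY_VARIABLES = ("static_cof", "dynamic_cof", "static_rms", "dynamic_rms")


def combined_pca(
    tribology: pd.DataFrame,
    sensory_means: pd.DataFrame,
    mode: str = "correlation",
) -> tuple[PCAModel, pd.DataFrame]:
    """PCA of tribological features with sensory attributes overlaid.

    Parameters
    ----------
    tribology : DataFrame indexed by (material, participant)
        Mean static/dynamic COF and static/dynamic AE RMS per cell
        (columns :data:`TRIBOLOGY_VARIABLES`).
    sensory_means : DataFrame with the same index
        Mean rating per attribute per cell.
    mode : str
        Correlation mode by default: the four active variables carry
        different units.

    Returns
    -------
    model : PCAModel
        Fitted on the four tribology variables only.
    overlays : DataFrame, attributes x components
        Supplementary vectors: the correlation of each sensory attribute
        with each component's scores.  They describe, without influencing
        the decomposition, how perception aligns with the physical axes.
    """
    missing = [c for c in TRIBOLOGY_VARIABLES if c not in tribology.columns]
    if missing:
        raise ValidationError(f"tribology table missing column(s): {missing}")
    trib = tribology[list(TRIBOLOGY_VARIABLES)].sort_index()
    sens = sensory_means.sort_index()
    only_t = trib.index.difference(sens.index)
    only_s = sens.index.difference(trib.index)
    if len(only_t) or len(only_s):
        raise ValidationError(
            "key mismatch between tribology and sensory tables; "
            f"tribology-only: {list(only_t)}, sensory-only: {list(only_s)}"
        )
    model = run_pca(trib, mode=mode)
    overlays = pd.DataFrame(
        {
            pc: [
                _pearson(sens[attr].to_numpy(), model.scores[:, c])
                for attr in sens.columns
            ]
            for c, pc in enumerate(model.loadings.columns)
        },
        index=list(sens.columns),
    )
    return model, overlays


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def correlation_signs(
    data: pd.DataFrame,
    pairs: list[tuple[str, str]],
    threshold: float = NEAR_ZERO_R,
) -> pd.DataFrame:
    """Signed correlations for requested variable pairs.

    Labels each pair positive / negative / near-zero (``|r| < threshold``).
    Variables are columns of ``data``; unknown names raise.
    """
    rows = []
    for a, b in pairs:
        for name in (a, b):
            if name not in data.columns:
                raise ParameterError(f"unknown variable {name!r}")
        r = _pearson(data[a].to_numpy(dtype=float), data[b].to_numpy(dtype=float))
        if np.isnan(r):
            label = "undefined"
        elif abs(r) < threshold:
            label = "near-zero"
        else:
            label = "positive" if r > 0 else "negative"
        rows.append(dict(var_a=a, var_b=b, r=r, label=label))
    return pd.DataFrame(rows)
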