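"""Per-CpG linear models of methylation on telomere length.

Methylation enters as M-values (base-2 logit of the beta proportion, the
recommended response for array regression because it is unbounded and closer
to homoscedastic).  Each CpG is regressed on [intercept, T/S ratio,
covariates] by ordinary least squares; the t-statistic and two-sided p-value
of the T/S coefficient are the quantities consumed by promoter enrichment.

Optionally, residual variances are shrunk toward a pooled prior before the
t-statistic is formed: an inverse-gamma (scaled inverse chi-square) prior is
fitted to the per-CpG residual variances by method of moments on the log
scale, and the posterior variance (d0*s0^2 + d*s^2)/(d0 + d) is used with
d0 + d degrees of freedom.  This is the empirical-Bayes moderation familiar
from microarray linear modelling; with few samples it stabilises the
denominator of t without changing the rank ordering much.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

BETA_EPS = 1e-6  # clamp for beta values so the logit stays finite


@dataclass
class MethylationMatrix:
    """CpG x sample methylation values with CpG genomic coordinates.

    ``values``: DataFrame, rows = CpG ids, columns = sample ids.
    ``coords``: DataFrame indexed by CpG id with columns ``chrom``, ``pos``
    (0-based).  ``value_kind`` is ``"beta"`` or ``"M"``.
    """

    values: pd.DataFrame
    coords: pd.DataFrame
    value_kind: str = "M"

    def __post_init__(self) -> None:
        if self.value_kind not in ("beta", "M"):
            raise ValueError(f"value_kind must be 'beta' or 'M', got {self.value_kind!r}")
        if self.values.index.has_duplicates:
            raise ValueError("CpG ids are not unique")
        if self.values.isna().any().any():
            raise ValueError("methylation matrix contains missing values")
        if not self.values.index.equals(self.coords.index):
            self.coords = self.coords.loc[self.values.index]

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def to_m(self) -> "MethylationMatrix":
        """Return an M-value matrix (identity if already M-values)."""
        if self.value_kind == "M":
            return self
        return MethylationMatrix(
            values=pd.DataFrame(
                m_values(self.values.to_numpy()),
                index=self.values.index,
                columns=self.values.columns,
            ),
            coords=self.coords,
            value_kind="M",
        )


def beta_values(m_intensity, u_intensity, eps: float = BETA_EPS):
    """Methylation proportion beta = M/(M+U), clamped to [eps, 1-eps].

    Wells with M + U = 0 give NaN (missing), matching array practice where a
    probe with no signal on either channel is uninformative.
    """
    m = np.asarray(m_intensity, dtype=float)
    u = np.asarray(u_intensity, dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("intensities must be non-negative")
    total = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, m / np.where(total > 0, total, 1.0), np.nan)
    return np.clip(beta, eps, 1 - eps)  # NaN propagates through clip


def m_values(beta, eps: float = BETA_EPS):
    """Base-2 logit transform M = log2(beta / (1 - beta)), clamping first."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1 - eps)
    return np.log2(b / (1 - b))


def beta_from_m(m):
    """Inverse of :func:`m_values`: beta = 2^M / (2^M + 1)."""
    m = np.asarray(m, dtype=float)
    return 1.0 / (1.0 + 2.0 ** (-m))


# ---------------------------------------------------------------------------
# Variance moderation
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (used to fit the prior df)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    f = lambda x: special.polygamma(1, x) - y
    lo, hi = 1e-8, 1e8
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled inverse chi-square prior.

    Under the prior, log(s^2) - digamma(d/2) + log(d/2) has mean
    log(s0^2) - digamma(d0/2) + log(d0/2)... more usefully, its mean and
    variance identify (d0, s0^2): the excess variance of log s^2 over the
    sampling term trigamma(d/2) equals trigamma(d0/2).  Returns
    ``(d0, s0_squared)``; ``d0 = inf`` when the variances are consistent with
    a single common value.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        raise ValueError("need >=2 positive residual variances to fit a prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    evar = np.var(e, ddof=1) - float(special.polygamma(1, df / 2))
    if evar <= 0:
        return np.inf, float(np.exp(np.mean(e)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0_sq


def moderate_variances(
    s2: np.ndarray, df: float
) -> tuple[np.ndarray, float, float, float]:
    """Shrink residual variances toward the fitted prior.

    Returns ``(posterior variances, d0, s0_squared, augmented df)``.
    """
    d0, s0_sq = fit_variance_prior(s2, df)
    if np.isinf(d0):
        post = np.full_like(np.asarray(s2, dtype=float), s0_sq)
        return post, d0, s0_sq, np.inf
    post = (d0 * s0_sq + df * np.asarray(s2, dtype=float)) / (d0 + df)
    return post, d0, s0_sq, df + d0


# ---------------------------------------------------------------------------
# Per-CpG association fits
# ---------------------------------------------------------------------------


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    collinear = []
    for j in range(X.shape[1]):
        X_wo = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(X_wo) == rank:
            collinear.append(names[j])
    raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")


def fit_cpg_associations(
    matrix: MethylationMatrix,
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
    moderate_variance: bool = True,
) -> pd.DataFrame:
    """OLS of per-CpG M-values on telomere length with covariates.

    Parameters
    ----------
    matrix
        Methylation values; converted to M-values if supplied as betas.
    samples
        DataFrame indexed by sample id with a ``ts_ratio`` column and any
        covariate columns.  Sample ids must match the matrix columns
        one-to-one (order is taken from the matrix).
    covariates
        Covariate column names; ``None`` means every numeric column other
        than ``ts_ratio``.
    moderate_variance
        Shrink residual variances toward an inverse-gamma prior before
        forming t (see module docstring).  Off = textbook OLS.

    Returns a DataFrame indexed by CpG id with columns ``chrom``, ``pos``,
    ``slope``, ``se``, ``t``, ``p_value``, ``df_residual``.  CpGs with zero
    residual variance get NaN t and p (undefined; excluded from ranking).
    """
    matrix = matrix.to_m()
    if set(samples.index) != set(matrix.sample_ids):
        raise ValueError("sample table ids do not match matrix columns")
    samples = samples.loc[matrix.sample_ids]

    if covariates is None:
        covariates = [
            c
            for c in samples.columns
            if c != "ts_ratio" and pd.api.types.is_numeric_dtype(samples[c])
        ]
    names = ["intercept", "ts_ratio", *covariates]
    X = np.column_stack(
        [
            np.ones(len(samples)),
            samples["ts_ratio"].to_numpy(dtype=float),
            *[samples[c].to_numpy(dtype=float) for c in covariates],
        ]
    )
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n_samples > n_covariates + 2 ({n} samples, {p - 2} covariates)")
    _check_full_rank(X, names)

    Y = matrix.values.to_numpy(dtype=float)  # CpGs x samples
    XtX_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ XtX_inv.T  # CpGs x p
    resid = Y - B @ X.T
    df_resid = n - p
    rss = np.einsum("ij,ij->i", resid, resid)
    s2 = rss / df_resid
    c_ts = XtX_inv[1, 1]
    slope = B[:, 1]

    # a CpG whose residuals are numerically zero has an undefined t
    scale = np.maximum(np.einsum("ij,ij->i", Y, Y), 1.0)
    defined = s2 > 1e-24 * scale / df_resid

    if moderate_variance:
        post_s2, d0, s0_sq, df_total = moderate_variances(s2[defined], df_resid)
        var = np.full(len(s2), np.nan)
        var[defined] = post_s2
    else:
        df_total = float(df_resid)
        var = np.where(defined, s2, np.nan)

    se = np.sqrt(var * c_ts)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = slope / se
    if np.isinf(df_total):
        pvals = 2 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2 * stats.t.sf(np.abs(t), df_total)

    out = pd.DataFrame(
        {
            "chrom": matrix.coords["chrom"].to_numpy(),
            "pos": matrix.coords["pos"].to_numpy(),
            "slope": slope,
            "se": se,
            "t": t,
            "p_value": pvals,
            "df_residual": float(df_total),
        },
        index=matrix.cpg_ids.copy(),
    )
    out.index.name = "cpg_id"
    out.loc[~defined, ["t", "p_value"]] = np.nan
    return out
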