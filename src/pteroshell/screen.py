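"""Expression-versus-saturation-state biomarker screen.

Candidate molecular bioindicators are genes whose normalized (TMM)
expression tracks the aragonite saturation state of the water the animals
were held in, across all seasons and treatments. Each gene's log(x+1)
expression is Pearson-correlated with per-sample Omega; genes pass a
sensitivity filter at |R| > 0.5 and a stringency filter at R^2 > 0.4
(the latter implies |R| > 0.632, so its pass set is nested within the
former). Filters act on R directly, not on p-values, so no
multiple-testing correction is applied to the pass decision; a BH
q-value column is emitted for reference only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "OmegaCorrelationScreen",
    "log_transform",
    "correlate_with_omega",
    "count_passing",
]

R_THRESHOLD = 0.5
R2_THRESHOLD = 0.4


def log_transform(values, base: str = "e"):
    """log(1 + x) transform of non-negative expression values.

    ``base="e"`` (natural log, default) or ``base="10"``. Pearson
    correlations are invariant to the base, which only rescales the
    transformed values.
    """
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("expression values must be non-negative")
    out = np.log1p(arr)
    if base == "10":
        out = out / np.log(10.0)
    elif base != "e":
        raise ValueError(f"unknown log base {base!r}")
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


class OmegaCorrelationScreen(BaseEstimator, TransformerMixin):
    """Screen genes for correlation with aragonite saturation state.

    scikit-learn style: ``fit(X, y)`` takes ``X`` as samples x genes
    (DataFrame or array) and ``y`` as the per-sample saturation state;
    ``transform(X)`` keeps only the genes passing the |R| filter.

    Parameters
    ----------
    r_threshold : sensitivity filter on |Pearson R| (default 0.5).
    r2_threshold : stringency filter on R^2 (default 0.4).
    log_base : "e" or "10" for the log(x+1) transform.
    pre_transformed : set True if ``X`` is already log-transformed.

    Attributes
    ----------
    results_ : per-gene DataFrame (r, r2, passes_r, passes_r2,
        is_constant, q_value).
    n_pass_r_, n_pass_r2_ : pass counts under each filter; constant
        (zero-variance) genes have undefined r and count in neither.
    """

    def __init__(
        self,
        r_threshold: float = R_THRESHOLD,
        r2_threshold: float = R2_THRESHOLD,
        log_base: str = "e",
        pre_transformed: bool = False,
    ):
        self.r_threshold = r_threshold
        self.r2_threshold = r2_threshold
        self.log_base = log_base
        self.pre_transformed = pre_transformed

    def fit(self, X, y) -> "OmegaCorrelationScreen":
        if isinstance(X, pd.DataFrame):
            genes = X.columns.to_numpy()
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            genes = np.array([f"g{i}" for i in range(values.shape[1])])
        omega = np.asarray(y, dtype=float)
        if values.shape[0] != omega.size:
            raise ValueError("X rows (samples) must align with y (omega)")
        if np.unique(omega).size < 3:
            raise ValueError(
                "need >= 3 samples with distinct omega_ar to correlate"
            )
        if not self.pre_transformed:
            values = log_transform(values, base=self.log_base)

        xc = values - values.mean(axis=0)
        yc = omega - omega.mean()
        sx = np.sqrt((xc**2).sum(axis=0))
        sy = np.sqrt((yc**2).sum())
        constant = sx == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
        r[constant] = np.nan

        n = omega.size
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        finite = np.isfinite(p)
        q = np.full_like(r, np.nan)
        if finite.any():
            q[finite] = stats.false_discovery_control(p[finite])

        res = pd.DataFrame(
            {
                "gene": genes,
                "r": r,
                "r2": r**2,
                "is_constant": constant,
                "q_value": q,
            }
        ).set_index("gene")
        res["passes_r"] = (np.abs(res["r"]) > self.r_threshold) & ~res["is_constant"]
        res["passes_r2"] = (res["r2"] > self.r2_threshold) & ~res["is_constant"]
        self.results_ = res
        self.n_pass_r_ = int(res["passes_r"].sum())
        self.n_pass_r2_ = int(res["passes_r2"].sum())
        return self

    def transform(self, X):
        check_is_fitted(self, "results_")
        passing = self.results_.index[self.results_["passes_r"]]
        if isinstance(X, pd.DataFrame):
            return X.loc[:, passing]
        idx = self.results_["passes_r"].to_numpy()
        return np.asarray(X)[:, idx]


def correlate_with_omega(
    matrix: pd.DataFrame,
    omega_ar,
    log_base: str = "e",
    pre_transformed: bool = False,
) -> pd.DataFrame:
    """Per-gene Pearson correlation of a genes x samples matrix with Omega.

    ``matrix`` follows the on-disk convention (rows = genes, columns =
    samples); ``omega_ar`` aligns with the columns. Returns the per-gene
    results table of :class:`OmegaCorrelationScreen`.
    """
    screen = OmegaCorrelationScreen(log_base=log_base,
                                    pre_transformed=pre_transformed)
    screen.fit(matrix.T, omega_ar)
    return screen.results_


def count_passing(results: pd.DataFrame) -> tuple[int, int]:
    """(n genes with |R| > 0.5, n genes with R^2 > 0.4) from a results table."""
    return int(results["passes_r"].sum()), int(results["passes_r2"].sum())
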