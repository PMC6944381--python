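"""Fixed-effect IVW meta-analysis and the effective number of tests.

Cohort estimates are pooled with weights ``w_i = 1/se_i^2`` (fixed-effect
inverse-variance weighting); heterogeneity is summarized by Cochran's Q
and I^2, and a DerSimonian-Laird random-effects re-pooling is computed
as a diagnostic only — significance flags always come from the
fixed-effect model.

The multiple-testing threshold is the Bonferroni correction with the
number of tests replaced by the effective number of independent traits:
the smallest count of principal components of the trait correlation
matrix explaining a target share (99%) of variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class MetaEstimate:
    trait_id: str
    variant_id: str  # or adjustment-model name for the Cox stage
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    cochran_q: float
    df: int
    i2: float
    n_cohorts: int
    tau2_dl: float = 0.0      # DerSimonian-Laird between-study variance
    beta_re: float = float("nan")   # random-effects diagnostic
    se_re: float = float("nan")
    significant: bool = False


@dataclass(frozen=True)
class TestingThreshold:
    n_components: int
    variance_explained_target: float = 0.99
    alpha_raw: float = 0.05

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")

    @property
    def alpha(self) -> float:
        return self.alpha_raw / self.n_components


def ivw_fixed(
    betas,
    ses,
    *,
    trait_id: str = "",
    variant_id: str = "",
) -> MetaEstimate:
    """Inverse-variance weighted fixed-effect pooling.

    pooled beta = sum(w_i b_i)/sum(w_i) with w_i = 1/se_i^2;
    pooled se = sum(w_i)^{-1/2}; Q = sum(w_i (b_i - pooled)^2);
    I^2 = max(0, (Q - df)/Q).  DL random-effects re-pooling is attached
    as a diagnostic.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 1:
        raise ValueError("need at least one study")
    if np.any(s <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / s**2
    sw = float(w.sum())
    pooled = float((w * b).sum() / sw)
    se = sw**-0.5
    q = float((w * (b - pooled) ** 2).sum())
    df = b.size - 1
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    p = max(2.0 * stats.norm.sf(abs(pooled / se)), 1e-300)
    # DerSimonian-Laird diagnostic
    if df > 0:
        c = sw - float((w**2).sum()) / sw
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    else:
        tau2 = 0.0
    w_re = 1.0 / (s**2 + tau2)
    beta_re = float((w_re * b).sum() / w_re.sum())
    se_re = float(w_re.sum()) ** -0.5
    return MetaEstimate(
        trait_id=trait_id,
        variant_id=variant_id,
        beta=pooled,
        se=se,
        ci_low=pooled - 1.96 * se,
        ci_high=pooled + 1.96 * se,
        p=p,
        cochran_q=q,
        df=df,
        i2=i2,
        n_cohorts=b.size,
        tau2_dl=tau2,
        beta_re=beta_re,
        se_re=se_re,
    )


def effective_tests(
    trait_matrix: pd.DataFrame,
    *,
    variance_explained_target: float = 0.99,
    alpha_raw: float = 0.05,
    method: str = "complete",
) -> TestingThreshold:
    """Effective number of tests from the trait correlation spectrum.

    Eigendecomposes the trait correlation matrix and returns the smallest
    component count whose cumulative eigenvalue share reaches the target
    (default 99%); alpha = alpha_raw / k.  ``method='complete'`` uses
    complete cases; ``method='pairwise'`` uses pairwise-complete
    correlations and errors if the resulting matrix is not positive
    semidefinite.
    """
    X = trait_matrix
    if X.shape[1] < 2:
        raise ValueError("need at least 2 traits")
    if method == "complete":
        Xc = X.dropna()
        if len(Xc) < X.shape[1] + 1:
            raise ValueError(
                f"need at least {X.shape[1] + 1} complete rows, got {len(Xc)}"
            )
        corr = np.corrcoef(Xc.to_numpy(dtype=float), rowvar=False)
    elif method == "pairwise":
        corr = X.corr(min_periods=2).to_numpy()
        if np.isnan(corr).any():
            raise ValueError("pairwise correlation matrix has missing entries")
    else:
        raise ValueError(f"unknown method {method!r}")
    eig = np.linalg.eigvalsh(corr)[::-1]
    if eig[-1] < -1e-8:
        raise ValueError(
            "correlation matrix not positive semidefinite "
            "(pairwise-complete artefact); use complete-case mode"
        )
    eig = np.clip(eig, 0.0, None)
    share = np.cumsum(eig) / eig.sum()
    k = int(np.searchsorted(share, variance_explained_target - 1e-12) + 1)
    return TestingThreshold(
        n_components=k,
        variance_explained_target=variance_explained_target,
        alpha_raw=alpha_raw,
    )


def flag_significance(results: pd.DataFrame, threshold: TestingThreshold) -> pd.DataFrame:
    """Add a boolean ``significant`` column: p strictly below alpha."""
    out = results.copy()
    out["significant"] = out["p"] < threshold.alpha if len(out) else pd.Series(
        dtype=bool
    )
    return out
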