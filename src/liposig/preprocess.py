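"""Sample exclusions and conversion of raw traits to the analysis scale.

The association stage works on covariate-adjusted, rank-normalized traits:
each trait is first residualized on sex, age, genotyping batch and the
first 10 genetic principal components by ordinary least squares, and the
residuals are then mapped to normal quantiles by a rank-based inverse
normal transformation (Blom offset 3/8, average ranks for ties).

Exclusions mirror the epidemiological conventions for this kind of data:
individuals on lipid-lowering medication, pregnant women, samples with a
high proportion (strictly more than 30%) of lipid traits missing, and —
for the survival stage only — prevalent CHD cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CohortDataset


@dataclass(frozen=True)
class ExclusionRules:
    drop_lipid_medication: bool = True
    drop_pregnant: bool = True
    max_missing_fraction: float = 0.30
    drop_prevalent_chd: bool = False  # survival stage only

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must lie in [0,1]")


def apply_exclusions(
    cohort: CohortDataset,
    rules: ExclusionRules,
    trait_columns: list[str] | None = None,
) -> tuple[CohortDataset, dict]:
    """Drop rows failing any active rule; return the filtered cohort + log.

    Rules apply in a fixed order (medication -> pregnancy -> missingness ->
    prevalent CHD) and the log counts removals per rule in that order.
    Missingness is judged over ``trait_columns`` (default: all panel lipid
    columns actually present).  Raises if nothing survives.
    """
    samples = cohort.samples
    panel_df = cohort.panel.data
    if trait_columns is None:
        from .panel import lipid_columns

        trait_columns = [c for c in lipid_columns(cohort.panel.scheme)
                         if c in panel_df.columns]
    keep = pd.Series(True, index=samples.index)
    log: dict[str, int] = {}
    if rules.drop_lipid_medication:
        hit = keep & (samples["lipid_medication"] == 1)
        log["medication"] = int(hit.sum())
        keep &= ~hit
    if rules.drop_pregnant:
        hit = keep & (samples["pregnant"] == 1)
        log["pregnancy"] = int(hit.sum())
        keep &= ~hit
    if rules.max_missing_fraction < 1.0 and trait_columns:
        frac = panel_df[trait_columns].isna().mean(axis=1)
        hit = keep & (frac > rules.max_missing_fraction)  # strictly >
        log["missingness"] = int(hit.sum())
        keep &= ~hit
    if rules.drop_prevalent_chd:
        hit = keep & (samples["prevalent_chd"] == 1)
        log["prevalent_chd"] = int(hit.sum())
        keep &= ~hit
    if not keep.any():
        raise ValueError("exclusion rules removed every sample")
    from .panel import LipoproteinPanel

    filtered = CohortDataset(
        cohort_id=cohort.cohort_id,
        samples=samples[keep].copy(),
        dosages=cohort.dosages[keep].copy(),
        panel=LipoproteinPanel(panel_df[keep].copy(), scheme=cohort.panel.scheme),
    )
    log["n_before"] = len(samples)
    log["n_after"] = int(keep.sum())
    return filtered, log


def residualize(values, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of a trait on intercept + covariate columns.

    Constant covariate columns are dropped; remaining collinearity is an
    error naming the offending columns.  Missing trait values propagate
    as NaN in the output; missing covariates among rows with observed
    trait values are an error.
    """
    y = np.asarray(values, dtype=float)
    X = covariates.astype(float)
    keep_cols = [c for c in X.columns if X[c].nunique(dropna=False) > 1]
    X = X[keep_cols]
    obs = ~np.isnan(y)
    if X.loc[obs].isna().any().any():
        bad = X.columns[X.loc[obs].isna().any()].tolist()
        raise ValueError(f"missing covariate values in columns {bad}")
    M = np.column_stack([np.ones(int(obs.sum())), X.loc[obs].to_numpy()])
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # identify a minimal culprit set by greedy elimination
        cols = ["intercept"] + keep_cols
        raise ValueError(
            f"covariate matrix rank-deficient (rank {rank} < {M.shape[1]}); "
            f"check collinearity among {cols}"
        )
    beta, *_ = np.linalg.lstsq(M, y[obs], rcond=None)
    out = np.full_like(y, np.nan)
    out[obs] = y[obs] - M @ beta
    return out


def inverse_normal_transform(values, offset: float = 0.375) -> np.ndarray:
    """Rank-based inverse normal transformation.

    Non-missing values are replaced by ``Phi^-1((r - c) / (m - 2c + 1))``
    with ``r`` the 1-based rank among the ``m`` non-missing values (ties
    averaged) and ``c`` the Blom offset 3/8, for which the denominator is
    ``m + 1/4``.  Missing stays missing.  Requires at least two distinct
    non-missing values.
    """
    y = np.asarray(values, dtype=float)
    obs = ~np.isnan(y)
    m = int(obs.sum())
    if m < 2:
        raise ValueError("need at least 2 non-missing values")
    yo = y[obs]
    if np.nanmax(yo) == np.nanmin(yo):
        raise ValueError("all values identical; ranks undefined")
    ranks = stats.rankdata(yo, method="average")
    out = np.full_like(y, np.nan)
    out[obs] = stats.norm.ppf((ranks - offset) / (m - 2 * offset + 1))
    return out
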