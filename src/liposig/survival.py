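"""Observational stage: Cox associations of lipoprotein measures with CHD.

Per-cohort Cox proportional-hazards models relate subclass lipid
concentrations and compositions to incident CHD under nested covariate
("adjustment ladder") sets, then pool the per-SD log hazard ratios across
cohorts by fixed-effect IVW meta-analysis.  Metabolic measures are
log-transformed and scaled to SD within each cohort before model fitting;
follow-up is administratively censored at 8 years and prevalent CHD cases
are excluded.

Partial-likelihood fits use statsmodels' ``PHReg`` with Breslow tie
handling by default (Efron available behind a flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .meta import MetaEstimate, ivw_fixed
from .panel import analysis_traits, friedewald_ldl_c
from .simulate import CohortDataset

BASIC_COVARIATES = (
    "age",
    "sex",
    "mean_arterial_pressure",
    "smoking",
    "diabetes",
    "lipid_medication",
    "region_or_ethnicity",
)

#: Lipid covariates available to adjustment rungs; created (log-SD
#: transformed) by :func:`prepare_survival`.
LIPID_COVARIATES = ("total_cholesterol", "total_tg", "hdl_c", "apoB", "ldl_c")

_ALLOWED = set(BASIC_COVARIATES) | set(LIPID_COVARIATES)


@dataclass(frozen=True)
class AdjustmentSet:
    """A named covariate set for one rung of the adjustment ladder."""

    name: str
    covariates: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = [c for c in self.covariates if c not in _ALLOWED]
        if unknown:
            raise ValueError(f"unknown covariates {unknown} in rung {self.name!r}")


_BASIC = tuple(BASIC_COVARIATES)

#: The nested adjustment sets: basic risk factors first, then the three
#: fundamental lipid measures (total TG, HDL-C, apoB) singly and in
#: combination, the serum-lipids model (basic + TC + total TG), and an
#: LDL-C add-on rung.
DEFAULT_LADDER = (
    AdjustmentSet("basic", _BASIC),
    AdjustmentSet("basic+totalTG", _BASIC + ("total_tg",)),
    AdjustmentSet("basic+HDL-C", _BASIC + ("hdl_c",)),
    AdjustmentSet("basic+apoB", _BASIC + ("apoB",)),
    AdjustmentSet("basic+apoB+HDL-C", _BASIC + ("apoB", "hdl_c")),
    AdjustmentSet("basic+apoB+totalTG", _BASIC + ("apoB", "total_tg")),
    AdjustmentSet("basic+TC+totalTG", _BASIC + ("total_cholesterol", "total_tg")),
    AdjustmentSet(
        "basic+TC+totalTG+LDL-C",
        _BASIC + ("total_cholesterol", "total_tg", "ldl_c"),
    ),
)


@dataclass(frozen=True)
class HazardEstimate:
    trait_id: str
    cohort_id: str
    adjustment: str
    log_hr: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int
    separation: bool = False

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("need at least one event")
        if abs(self.hr - math.exp(self.log_hr)) > 1e-9 * max(1.0, self.hr):
            raise ValueError("hr inconsistent with log_hr")


def transform_trait(values, *, zero_offset: bool = False) -> np.ndarray:
    """Log-transform then scale to SD (within-cohort analysis scale).

    Natural log, then centre and divide by the sample SD (denominator
    m-1).  Missing values propagate.  Non-positive values are an error
    unless ``zero_offset`` is set, in which case half the smallest
    positive value is added to every observation first (zeros only occur
    in real data; the generator avoids them).
    """
    y = np.asarray(values, dtype=float).copy()
    obs = ~np.isnan(y)
    yo = y[obs]
    if zero_offset and (yo <= 0).any():
        pos = yo[yo > 0]
        if pos.size == 0:
            raise ValueError("no positive values to derive a zero offset from")
        yo = yo + pos.min() / 2.0
    if (yo <= 0).any():
        raise ValueError("non-positive trait values; log undefined "
                         "(enable zero_offset for zeros)")
    ly = np.log(yo)
    sd = ly.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        raise ValueError("trait constant after log transform")
    out = np.full_like(y, np.nan)
    out[obs] = (ly - ly.mean()) / sd
    return out


def prepare_survival(
    cohort: CohortDataset,
    censor_years: float = 8.0,
) -> tuple[pd.DataFrame, dict]:
    """Build the per-cohort survival analysis table.

    Drops prevalent CHD cases, truncates follow-up at ``censor_years``
    (later events become censored non-events; events at exactly the
    horizon are retained), attaches covariates, log-SD-transformed lipid
    covariates, and the raw derived trait columns.  Returns the table and
    an exclusion/bookkeeping log.  Errors if no events remain.
    """
    s = cohort.samples
    keep = s["prevalent_chd"] != 1
    log = {"prevalent_chd_removed": int((~keep).sum())}
    s = s[keep]
    panel_df = cohort.panel.data[keep.to_numpy()]
    from .panel import LipoproteinPanel

    panel = LipoproteinPanel(panel_df, scheme=cohort.panel.scheme)

    time = s["followup_years"].to_numpy(dtype=float)
    event = s["chd_event"].to_numpy(dtype=int)
    event = np.where(time > censor_years, 0, event)
    time = np.minimum(time, censor_years)
    if event.sum() < 1:
        raise ValueError("no events remain after censoring/exclusion")

    table = s[list(BASIC_COVARIATES)].copy().reset_index(drop=True)
    table.insert(0, "time", time)
    table.insert(1, "event", event)

    d = panel.data.reset_index(drop=True)
    table["total_cholesterol"] = transform_trait(d["TOTC"].to_numpy())
    table["total_tg"] = transform_trait(d["TOTTG"].to_numpy())
    table["hdl_c"] = transform_trait(d["HDLC"].to_numpy())
    table["apoB"] = transform_trait(d["APOB"].to_numpy())
    fr = friedewald_ldl_c(d["TOTC"].to_numpy(), d["HDLC"].to_numpy(),
                          d["TOTTG"].to_numpy())
    fr = np.where(np.asarray(fr) <= 0, np.nan, fr)
    table["ldl_c"] = transform_trait(fr)

    traits = analysis_traits(panel).reset_index(drop=True)
    # covariate columns win on a name clash (e.g. the transformed apoB)
    traits = traits[[c for c in traits.columns if c not in table.columns]]
    table = pd.concat([table, traits], axis=1)
    log["n"] = len(table)
    log["n_events"] = int(event.sum())
    return table, log


def _design(table: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Numeric design columns for an adjustment set (dummy-coded factors)."""
    parts = []
    for c in covariates:
        col = table[c]
        if col.dtype == object or str(col.dtype) == "category":
            parts.append(pd.get_dummies(col, prefix=c, drop_first=True, dtype=float))
        else:
            parts.append(col.astype(float).to_frame(c))
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=table.index)
    # constant columns (e.g. a risk factor emptied by upstream exclusions)
    # would make the information matrix singular
    keep = [c for c in X.columns if X[c].nunique(dropna=True) > 1]
    return X[keep]


def cox_assoc(
    table: pd.DataFrame,
    trait_col: str,
    adjustment: AdjustmentSet,
    *,
    cohort_id: str = "",
    ties: str = "breslow",
    transform: bool = True,
    zero_offset: bool = False,
    maxiter: int = 100,
) -> HazardEstimate:
    """Per-SD log hazard ratio of a trait from a Cox PH fit.

    The trait is log-SD standardized (unless ``transform=False``, for
    already-standardized inputs), entered alongside the adjustment
    covariates, and fitted by partial-likelihood maximization with
    Breslow tie handling (``ties='efron'`` behind the flag).  Wald test
    with model-based standard errors; |log HR| > 10 is flagged as likely
    separation.
    """
    z = (
        transform_trait(table[trait_col].to_numpy(dtype=float),
                        zero_offset=zero_offset)
        if transform
        else table[trait_col].to_numpy(dtype=float)
    )
    X = _design(table, adjustment.covariates)
    X.insert(0, trait_col, z)
    mask = ~(X.isna().any(axis=1) | table["time"].isna() | table["event"].isna())
    Xm = X[mask].to_numpy(dtype=float)
    tm = table.loc[mask, "time"].to_numpy(dtype=float)
    em = table.loc[mask, "event"].to_numpy(dtype=int)
    n, n_events = len(tm), int(em.sum())
    if n_events < 1:
        raise ValueError(f"no events among complete cases for {trait_col}")
    model = PHReg(tm, Xm, status=em, ties=ties)
    res = model.fit(maxiter=maxiter, disp=False)
    grad = model.score(res.params)
    gnorm = float(np.linalg.norm(grad))
    if not np.all(np.isfinite(res.params)) or gnorm > 1e-2 * max(1, n_events):
        raise RuntimeError(
            f"Cox fit did not converge for {trait_col} "
            f"({adjustment.name}): gradient norm {gnorm:.3g}"
        )
    log_hr = float(res.params[0])
    se = float(res.bse[0])
    p = max(float(2.0 * stats.norm.sf(abs(log_hr / se))), 1e-300)
    return HazardEstimate(
        trait_id=trait_col,
        cohort_id=cohort_id,
        adjustment=adjustment.name,
        log_hr=log_hr,
        se=se,
        hr=math.exp(log_hr),
        ci_low=math.exp(log_hr - 1.96 * se),
        ci_high=math.exp(log_hr + 1.96 * se),
        p=p,
        n=n,
        n_events=n_events,
        separation=abs(log_hr) > 10,
    )


def run_adjustment_ladder(
    tables: Mapping[str, pd.DataFrame],
    trait_cols: Sequence[str],
    ladder: Sequence[AdjustmentSet] = DEFAULT_LADDER,
    *,
    alpha: float = 0.002,
    ties: str = "breslow",
    zero_offset: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every trait under every rung in every cohort, then IVW-pool.

    Returns (per-cohort estimates, meta table).  Per-cell fit failures
    are recorded in an ``error`` column and excluded from pooling, never
    fatal to the run.  Meta log-HRs are pooled on the log scale and
    exponentiated for reporting; flags use strict ``p < alpha``.
    """
    if not ladder:
        raise ValueError("adjustment ladder must be non-empty")
    rows = []
    for rung in ladder:
        for trait in trait_cols:
            for cid, table in tables.items():
                try:
                    est = cox_assoc(table, trait, rung, cohort_id=cid,
                                    ties=ties, zero_offset=zero_offset)
                    rows.append({**est.__dict__, "error": ""})
                except Exception as exc:  # recorded per cell
                    rows.append({
                        "trait_id": trait, "cohort_id": cid,
                        "adjustment": rung.name, "log_hr": np.nan,
                        "se": np.nan, "hr": np.nan, "ci_low": np.nan,
                        "ci_high": np.nan, "p": np.nan, "n": 0,
                        "n_events": 0, "separation": False,
                        "error": f"{type(exc).__name__}: {exc}",
                    })
    estimates = pd.DataFrame(rows)

    meta_rows = []
    ok = estimates[estimates["error"] == ""]
    for (trait, rung_name), grp in ok.groupby(["trait_id", "adjustment"], sort=False):
        m = ivw_fixed(grp["log_hr"], grp["se"], trait_id=trait, variant_id=rung_name)
        meta_rows.append({
            "trait_id": trait,
            "adjustment": rung_name,
            "log_hr": m.beta,
            "se": m.se,
            "hr": math.exp(m.beta),
            "ci_low": math.exp(m.ci_low),
            "ci_high": math.exp(m.ci_high),
            "p": m.p,
            "cochran_q": m.cochran_q,
            "i2": m.i2,
            "n_cohorts": m.n_cohorts,
            "n_events": int(grp["n_events"].sum()),
            "significant": m.p < alpha,
        })
    meta = pd.DataFrame(meta_rows)
    return estimates, meta
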