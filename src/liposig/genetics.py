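"""Per-cohort allele-trait association and drug-target scaling.

Each trait (already residualized and rank-normalized) is regressed on
the genotype dosage under an additive model, separately per cohort.
Estimates are harmonized to the variant specification's effect allele and
then scaled so the variant's external CHD association equals a fixed
benefit of -0.105 log-odds (odds ratio 0.90, i.e. a 10% lower relative
risk), which makes signatures of different drug targets comparable.

The external CHD log-odds is treated as a fixed constant when scaling —
its standard error is carried in the variant spec but not propagated —
so scaling preserves |z| and p exactly.  A delta-method variant that does
propagate the outcome uncertainty is available behind a flag for
sensitivity analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .simulate import VariantSpec

Z95 = 1.96  # normal-approximation multiplier for 95% CIs


@dataclass(frozen=True)
class EffectEstimate:
    """A beta/SE/CI/p record flowing through association -> scaling -> meta."""

    trait_id: str
    variant_id: str
    cohort_id: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    scale_state: str = "per_allele"  # per_allele | scaled
    eaf: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            if self.se <= 0:
                raise ValueError("se must be positive")
            if not (self.ci_low <= self.beta <= self.ci_high):
                raise ValueError("CI must bracket beta")
            if not 0.0 < self.p <= 1.0:
                raise ValueError("p must lie in (0,1]")
        if self.scale_state not in ("per_allele", "scaled"):
            raise ValueError(f"unknown scale_state {self.scale_state!r}")


@dataclass(frozen=True)
class ScalingTarget:
    """Fixed CHD benefit all trait estimates are aligned to."""

    target_logor: float = -0.105
    equivalent_or: float = 0.90

    def __post_init__(self) -> None:
        if round(math.exp(self.target_logor), 2) != round(self.equivalent_or, 2):
            raise ValueError(
                f"exp({self.target_logor}) does not round to {self.equivalent_or}"
            )


DEFAULT_TARGET = ScalingTarget()


def additive_assoc(
    trait,
    dosages,
    *,
    trait_id: str = "",
    variant_id: str = "",
    cohort_id: str = "",
) -> EffectEstimate:
    """OLS slope of a (transformed) trait on dosage, with intercept.

    Two-sided p from the normal approximation; 95% CI = beta +/- 1.96*se.
    Requires at least 3 complete pairs and non-constant dosage.  A perfect
    fit (zero residual variance) is returned with ``degenerate=True``.
    """
    y = np.asarray(trait, dtype=float)
    d = np.asarray(dosages, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(d))
    y, d = y[ok], d[ok]
    n = len(y)
    if n < 3:
        raise ValueError(f"need >=3 complete pairs, got {n}")
    sxx = float(np.sum((d - d.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("dosage is constant; slope undefined")
    beta = float(np.sum((d - d.mean()) * (y - y.mean())) / sxx)
    resid = y - y.mean() - beta * (d - d.mean())
    sigma2 = float(np.sum(resid**2)) / (n - 2)
    se = math.sqrt(sigma2 / sxx)
    if se == 0.0:
        return EffectEstimate(trait_id, variant_id, cohort_id, beta, 0.0,
                              beta, beta, 1e-300, n, degenerate=True)
    z = beta / se
    p = max(2.0 * stats.norm.sf(abs(z)), 1e-300)
    return EffectEstimate(trait_id, variant_id, cohort_id, beta, se,
                          beta - Z95 * se, beta + Z95 * se, p, n)


def harmonize_alleles(
    estimate: EffectEstimate,
    observed_effect_allele: str,
    spec: VariantSpec,
) -> EffectEstimate:
    """Orient an estimate to the spec's effect allele.

    If the association was counted in copies of the spec's *other* allele,
    the beta and CI flip sign (endpoints swapped) and the effect-allele
    frequency becomes 1-f.  Alleles outside the spec are an error — no
    strand inference is attempted.
    """
    if observed_effect_allele == spec.effect_allele:
        return estimate
    if observed_effect_allele != spec.other_allele:
        raise ValueError(
            f"allele {observed_effect_allele!r} not in spec "
            f"{{{spec.effect_allele},{spec.other_allele}}} for {spec.variant_id}"
        )
    return replace(
        estimate,
        beta=-estimate.beta,
        ci_low=-estimate.ci_high,
        ci_high=-estimate.ci_low,
        eaf=None if estimate.eaf is None else 1.0 - estimate.eaf,
    )


def scale_to_chd(
    estimate: EffectEstimate,
    chd_logor_harmonized: float,
    target: ScalingTarget = DEFAULT_TARGET,
    *,
    chd_logor_se: float | None = None,
    delta_method: bool = False,
) -> EffectEstimate:
    """Rescale a per-allele estimate to the fixed CHD benefit.

    factor = target_logor / chd_logor; beta' = beta*factor,
    se' = se*|factor|, CI' = beta' +/- 1.96*se', p unchanged.  The CHD
    log-odds is a fixed constant by default; with ``delta_method=True``
    its uncertainty is propagated into se' (first-order ratio variance),
    and the p-value is recomputed from the inflated se.
    """
    if estimate.scale_state != "per_allele":
        raise ValueError("estimate already scaled")
    if chd_logor_harmonized == 0.0:
        raise ValueError("cannot scale with a zero CHD logOR")
    factor = target.target_logor / chd_logor_harmonized
    beta = estimate.beta * factor
    se = estimate.se * abs(factor)
    p = estimate.p
    if delta_method:
        if chd_logor_se is None or chd_logor_se <= 0:
            raise ValueError("delta_method requires a positive chd_logor_se")
        var = (factor * estimate.se) ** 2 + (
            estimate.beta * target.target_logor / chd_logor_harmonized**2
        ) ** 2 * chd_logor_se**2
        se = math.sqrt(var)
        p = max(2.0 * stats.norm.sf(abs(beta / se)), 1e-300) if se > 0 else p
    return replace(
        estimate,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        p=p,
        scale_state="scaled",
    )
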