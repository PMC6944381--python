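"""Configuration-driven orchestration of the genetic and survival stages.

``run_genetic`` takes cohorts (simulated or loaded from TSV), applies
exclusions, residualizes and rank-normalizes every derived trait,
estimates per-cohort additive allele-trait associations for each variant,
harmonizes and scales them to the fixed CHD benefit, and pools them by
IVW meta-analysis with effective-number-of-tests flagging.

``run_survival`` prepares the censored survival tables and runs the Cox
adjustment ladder with IVW pooling per trait x rung.

All tabular IO is TSV (tab-separated, UTF-8, "." decimal, empty cell =
missing); run logs are JSON with a config fingerprint and seed so every
output row is traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genetics import (
    DEFAULT_TARGET,
    EffectEstimate,
    ScalingTarget,
    additive_assoc,
    harmonize_alleles,
    scale_to_chd,
)
from .meta import TestingThreshold, effective_tests, flag_significance, ivw_fixed
from .panel import LipoproteinPanel, analysis_traits, lipid_columns
from .preprocess import ExclusionRules, apply_exclusions, inverse_normal_transform, residualize
from .simulate import (
    DEFAULT_PROFILES,
    DEFAULT_PROSPECTIVE,
    DEFAULT_VARIANTS,
    CohortConfig,
    CohortDataset,
    EffectProfile,
    VariantSpec,
    simulate_multicohort,
)
from .survival import DEFAULT_LADDER, prepare_survival, run_adjustment_ladder

GENETIC_COVARIATES = ["sex", "age", "batch"] + [f"PC{k}" for k in range(1, 11)]

#: Default genetic-stage cohort mix: five population cohorts in the
#: 2,000-40,000 size range (adult plus one adolescent-aged cohort).
DEFAULT_GENETIC_COHORTS = (
    CohortConfig("cohort-A", 4702, age_range=(31.0, 31.9)),
    CohortConfig("cohort-B", 3726, age_range=(16.0, 16.9)),
    CohortConfig("cohort-C", 1948, age_range=(24.0, 39.0)),
    CohortConfig("cohort-D", 6942, age_range=(24.0, 74.0)),
    CohortConfig("cohort-E", 4124, age_range=(24.0, 74.0)),
)


@dataclass
class RunConfig:
    """Everything one run needs; YAML-serializable."""

    seed: int = 1
    outdir: str = "results"
    simulate: bool = True
    genetic_cohorts: Sequence[CohortConfig] = field(
        default_factory=lambda: list(DEFAULT_GENETIC_COHORTS)
    )
    survival_cohorts: Sequence[CohortConfig] = field(
        default_factory=lambda: list(DEFAULT_PROSPECTIVE)
    )
    variants: Mapping[str, VariantSpec] = field(
        default_factory=lambda: dict(DEFAULT_VARIANTS)
    )
    profiles: Mapping[str, EffectProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    exclusions: ExclusionRules = field(default_factory=ExclusionRules)
    target: ScalingTarget = field(default_factory=lambda: DEFAULT_TARGET)
    alpha_mode: str = "recompute"  # recompute | pinned
    pinned_components: int = 28
    transform: str = "int"  # int | log (analysis scale for trait betas)
    censor_years: float = 8.0
    ladder_names: Sequence[str] | None = None  # None = full default ladder
    survival_traits: Sequence[str] | None = None

    def fingerprint(self) -> str:
        blob = json.dumps(_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        for key in ("seed", "outdir", "simulate", "alpha_mode",
                    "pinned_components", "transform", "censor_years",
                    "ladder_names", "survival_traits"):
            if key in raw:
                kw[key] = raw[key]
        if "exclusions" in raw:
            kw["exclusions"] = ExclusionRules(**raw["exclusions"])
        if "target" in raw:
            kw["target"] = ScalingTarget(**raw["target"])
        if "genetic_cohorts" in raw:
            kw["genetic_cohorts"] = [_cohort_cfg(c) for c in raw["genetic_cohorts"]]
        if "survival_cohorts" in raw:
            kw["survival_cohorts"] = [_cohort_cfg(c) for c in raw["survival_cohorts"]]
        if "variants" in raw:
            kw["variants"] = {
                v["variant_id"]: VariantSpec(
                    variant_id=v["variant_id"],
                    effect_allele=v["effect_allele"],
                    other_allele=v["other_allele"],
                    effect_allele_freq=float(v["eaf"]),
                    chd_logor_per_allele=float(v["chd_logor"]),
                    chd_logor_se=float(v["chd_logor_se"]),
                    gene=v.get("gene", ""),
                )
                for v in raw["variants"]
            }
        return cls(**kw)


def _cohort_cfg(c: Mapping) -> CohortConfig:
    return CohortConfig(
        cohort_id=c["cohort_id"],
        n=int(c["n"]),
        age_range=tuple(c.get("age_range", (30.0, 60.0))),
        female_frac=float(c.get("female_frac", 0.51)),
        target_event_fraction=float(c.get("target_event_fraction", 0.04)),
        admin_censor_years=float(c.get("admin_censor_years", 8.0)),
        loghr_map=dict(c.get("loghr_map", {})),
    )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# Variant-spec TSV dialect
# ---------------------------------------------------------------------------


def read_variant_specs(path) -> dict[str, VariantSpec]:
    df = pd.read_csv(path, sep="\t")
    return {
        r.variant_id: VariantSpec(
            variant_id=r.variant_id,
            effect_allele=r.effect_allele,
            other_allele=r.other_allele,
            effect_allele_freq=float(r.eaf),
            chd_logor_per_allele=float(r.chd_logor),
            chd_logor_se=float(r.chd_logor_se),
            gene=getattr(r, "gene", ""),
        )
        for r in df.itertuples()
    }


def write_variant_specs(specs: Mapping[str, VariantSpec], path) -> None:
    pd.DataFrame(
        [
            {
                "variant_id": s.variant_id,
                "effect_allele": s.effect_allele,
                "other_allele": s.other_allele,
                "eaf": s.effect_allele_freq,
                "chd_logor": s.chd_logor_per_allele,
                "chd_logor_se": s.chd_logor_se,
                "gene": s.gene,
            }
            for s in specs.values()
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genetic stage
# ---------------------------------------------------------------------------


def preprocess_traits(
    cohort: CohortDataset,
    *,
    transform: str = "int",
) -> pd.DataFrame:
    """Derived traits on the analysis scale for one (filtered) cohort.

    ``transform='int'``: residualize on sex/age/batch/10 PCs, then
    rank-based inverse normal transform (the headline analysis scale).
    ``transform='log'``: natural log only — the scale on which the
    generator's latent per-allele shifts equal the regression slopes,
    used by the parameter-recovery suites.
    """
    traits = analysis_traits(cohort.panel)
    cov = cohort.samples[GENETIC_COVARIATES].reset_index(drop=True)
    out = {}
    for col in traits.columns:
        vals = traits[col].to_numpy(dtype=float)
        if transform == "int":
            resid = residualize(vals, cov)
            out[col] = inverse_normal_transform(resid)
        elif transform == "log":
            with np.errstate(invalid="ignore"):
                out[col] = np.where(vals > 0, np.log(np.where(vals > 0, vals, 1.0)),
                                    np.nan)
        else:
            raise ValueError(f"unknown transform {transform!r}")
    return pd.DataFrame(out)


def run_genetic(config: RunConfig, cohorts: Sequence[CohortDataset] | None = None):
    """Full genetic stage; returns (estimates df, meta df, run log dict).

    Deterministic given the config seed.  The estimates table is long
    format: one row per cohort x variant x trait x scale_state; the meta
    table pools the scaled estimates per variant x trait and flags
    significance at the configured alpha.
    """
    if cohorts is None:
        if not config.simulate:
            raise ValueError("no cohorts given and simulate=False")
        cohorts = simulate_multicohort(
            config.genetic_cohorts, config.seed,
            variants=config.variants, profiles=config.profiles,
        )
    log: dict = {"stage": "genetic", "seed": config.seed,
                 "config_fingerprint": config.fingerprint(), "cohorts": {}}
    rows: list[dict] = []
    int_blocks = []
    for cohort in cohorts:
        filtered, exlog = apply_exclusions(cohort, config.exclusions)
        log["cohorts"][cohort.cohort_id] = exlog
        traits = preprocess_traits(filtered, transform=config.transform)
        if config.transform == "int":
            int_blocks.append(traits)
        for vid, spec in config.variants.items():
            dos = filtered.dosages[vid].to_numpy()
            for trait_id in traits.columns:
                try:
                    est = additive_assoc(
                        traits[trait_id], dos,
                        trait_id=trait_id, variant_id=vid,
                        cohort_id=cohort.cohort_id,
                    )
                except ValueError as exc:
                    log.setdefault("errors", []).append(
                        f"{cohort.cohort_id}/{vid}/{trait_id}: {exc}")
                    continue
                est = harmonize_alleles(est, spec.effect_allele, spec)
                scaled = scale_to_chd(est, spec.chd_logor_per_allele, config.target)
                rows.append(est.__dict__)
                rows.append(scaled.__dict__)
    estimates = pd.DataFrame(rows)

    scaled = estimates[estimates["scale_state"] == "scaled"]
    meta_rows = []
    for (vid, trait_id), grp in scaled.groupby(["variant_id", "trait_id"], sort=False):
        m = ivw_fixed(grp["beta"], grp["se"], trait_id=trait_id, variant_id=vid)
        row = m.__dict__.copy()
        row["n_total"] = int(grp["n"].sum())
        meta_rows.append(row)
    meta = pd.DataFrame(meta_rows)

    if config.alpha_mode == "pinned":
        threshold = TestingThreshold(n_components=config.pinned_components)
    else:
        pooled = pd.concat(int_blocks, ignore_index=True) if int_blocks else None
        if pooled is None:
            raise ValueError("alpha recompute requires transform='int'")
        threshold = effective_tests(pooled)
    meta = flag_significance(meta, threshold)
    log["n_components"] = threshold.n_components
    log["alpha"] = threshold.alpha
    log["n_estimates"] = len(estimates)
    return estimates, meta, log


# ---------------------------------------------------------------------------
# Survival stage
# ---------------------------------------------------------------------------


def run_survival(config: RunConfig, cohorts: Sequence[CohortDataset] | None = None):
    """Full observational stage; returns (estimates, meta, run log)."""
    if cohorts is None:
        if not config.simulate:
            raise ValueError("no cohorts given and simulate=False")
        cohorts = simulate_multicohort(
            config.survival_cohorts, config.seed,
            variants=config.variants, profiles=config.profiles,
        )
    log: dict = {"stage": "survival", "seed": config.seed,
                 "config_fingerprint": config.fingerprint(), "cohorts": {}}
    # medication users stay in the survival stage (medication is a Cox
    # covariate there); prevalent CHD is handled by prepare_survival
    surv_rules = dataclasses.replace(
        config.exclusions, drop_lipid_medication=False, drop_prevalent_chd=False
    )
    tables = {}
    for cohort in cohorts:
        filtered, exlog = apply_exclusions(cohort, surv_rules)
        table, slog = prepare_survival(filtered, censor_years=config.censor_years)
        log["cohorts"][cohort.cohort_id] = {**exlog, **slog}
        tables[cohort.cohort_id] = table

    if config.survival_traits is None:
        scheme = cohorts[0].panel.scheme
        trait_cols = [f"{s}-TG" for s in scheme.names] + [
            f"{s}-TG-pct" for s in scheme.names
        ]
    else:
        trait_cols = list(config.survival_traits)
    ladder = DEFAULT_LADDER
    if config.ladder_names is not None:
        ladder = tuple(r for r in DEFAULT_LADDER if r.name in set(config.ladder_names))
        if not ladder:
            raise ValueError(f"no ladder rungs match {config.ladder_names}")
    alpha = (
        0.05 / config.pinned_components
        if config.alpha_mode == "pinned"
        else 0.002
    )
    estimates, meta = run_adjustment_ladder(tables, trait_cols, ladder, alpha=alpha)
    log["n_estimates"] = len(estimates)
    log["n_events_total"] = int(
        sum(t.loc[t["event"] == 1, "event"].sum() for t in tables.values())
    )
    return estimates, meta, log


# ---------------------------------------------------------------------------
# Disk-level entry points (used by the CLI)
# ---------------------------------------------------------------------------


def _write(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="")


def simulate_to_dir(config: RunConfig, outdir) -> list[str]:
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohorts = simulate_multicohort(
        list(config.genetic_cohorts) + [
            c for c in config.survival_cohorts
            if c.cohort_id not in {g.cohort_id for g in config.genetic_cohorts}
        ],
        config.seed, variants=config.variants, profiles=config.profiles,
    )
    for c in cohorts:
        c.write_tsv(out)
    write_variant_specs(config.variants, out / "variants.tsv")
    return [c.cohort_id for c in cohorts]


def load_cohort_tsv(outdir, cohort_id) -> CohortDataset:
    p = pathlib.Path(outdir)
    pheno = pd.read_csv(p / f"{cohort_id}.pheno.tsv", sep="\t")
    dosage = pd.read_csv(p / f"{cohort_id}.dosage.tsv", sep="\t")
    lipcols = [c for c in pheno.columns if c in set(lipid_columns())] + [
        "TOTC", "TOTTG", "HDLC", "APOB", "APOA1"
    ]
    panel = LipoproteinPanel(pheno[lipcols].copy())
    samples = pheno.drop(columns=[c for c in lipcols if c in pheno.columns])
    return CohortDataset(cohort_id=cohort_id, samples=samples,
                         dosages=dosage, panel=panel)


def run_genetic_to_dir(config: RunConfig) -> dict:
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    estimates, meta, log = run_genetic(config)
    _write(estimates, out / "genetic_estimates.tsv")
    _write(meta, out / "genetic_meta.tsv")
    (out / "genetic_run.json").write_text(json.dumps(log, indent=2, default=str))
    return log


def run_survival_to_dir(config: RunConfig) -> dict:
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    estimates, meta, log = run_survival(config)
    _write(estimates, out / "hazard_estimates.tsv")
    _write(meta, out / "hazard_meta.tsv")
    (out / "survival_run.json").write_text(json.dumps(log, indent=2, default=str))
    return log


def report_tables(indir) -> dict[str, pd.DataFrame]:
    """Figure-style long tables from a finished run directory.

    The genetic table lists trait x variant scaled estimates with CIs and
    significance flags (forest-plot layout); the hazard tables list
    trait x adjustment-rung hazard ratios.
    """
    p = pathlib.Path(indir)
    out = {}
    gm = p / "genetic_meta.tsv"
    if gm.exists():
        meta = pd.read_csv(gm, sep="\t")
        out["genetic_signature"] = meta[
            ["trait_id", "variant_id", "beta", "ci_low", "ci_high", "p",
             "significant", "n_cohorts"]
        ].sort_values(["trait_id", "variant_id"], kind="stable")
    hm = p / "hazard_meta.tsv"
    if hm.exists():
        meta = pd.read_csv(hm, sep="\t")
        out["incident_risk"] = meta[
            ["trait_id", "adjustment", "hr", "ci_low", "ci_high", "p",
             "significant", "n_cohorts", "n_events"]
        ].sort_values(["trait_id", "adjustment"], kind="stable")
    for name, df in out.items():
        _write(df, p / f"report_{name}.tsv")
    return out
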