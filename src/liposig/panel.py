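"""Lipoprotein subclass scheme and derived lipid traits.

The NMR lipoprotein platform resolves 14 size-defined subclass particle
categories, from potential chylomicrons / extremely large VLDL (>=75 nm)
down to small HDL (8.7 nm).  Each subclass carries four lipid constituents:
triglycerides (TG), cholesteryl esters (CE), free cholesterol (FC) and
phospholipids (PL), all in mmol/L.  This module defines the scheme, the
in-memory panel container, and the derived measures the analysis uses:
per-subclass compositions (a constituent's share of all lipid molecules in
the particles), Friedewald-estimated LDL cholesterol, size-specific LDL
cholesterol (cholesterol summed over the three LDL subclasses only,
diameters 18-26 nm), and remnant cholesterol (VLDL + IDL cholesterol).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONSTITUENTS: tuple[str, ...] = ("TG", "CE", "FC", "PL")

#: Summary columns carried alongside the subclass lipid matrix.
SUMMARY_COLUMNS: tuple[str, ...] = ("TOTC", "TOTTG", "HDLC", "APOB", "APOA1")


@dataclass(frozen=True)
class Subclass:
    """One size-defined lipoprotein subclass."""

    name: str
    diameter_nm: float
    lipo_class: str  # VLDL / IDL / LDL / HDL
    apob_containing: bool


_DEFAULT_ROWS = [
    ("XXL-VLDL", 75.0, "VLDL", True),
    ("XL-VLDL", 64.0, "VLDL", True),
    ("L-VLDL", 53.6, "VLDL", True),
    ("M-VLDL", 44.5, "VLDL", True),
    ("S-VLDL", 36.8, "VLDL", True),
    ("XS-VLDL", 31.3, "VLDL", True),
    ("IDL", 28.6, "IDL", True),
    ("L-LDL", 25.5, "LDL", True),
    ("M-LDL", 23.0, "LDL", True),
    ("S-LDL", 18.7, "LDL", True),
    ("XL-HDL", 14.3, "HDL", False),
    ("L-HDL", 12.1, "HDL", False),
    ("M-HDL", 10.9, "HDL", False),
    ("S-HDL", 8.7, "HDL", False),
]


@dataclass(frozen=True)
class SubclassScheme:
    """Ordered collection of the 14 size-defined subclasses.

    Invariants enforced at construction: exactly 14 subclasses, particle
    diameters strictly decreasing in listed order, and LDL subclasses
    confined to the 18-26 nm band that defines size-specific LDL.
    """

    subclasses: tuple[Subclass, ...]

    def __post_init__(self) -> None:
        if len(self.subclasses) != 14:
            raise ValueError(
                f"scheme must have exactly 14 subclasses, got {len(self.subclasses)}"
            )
        diam = [s.diameter_nm for s in self.subclasses]
        if not all(a > b for a, b in zip(diam, diam[1:])):
            raise ValueError("subclass diameters must be strictly decreasing")
        for s in self.subclasses:
            if s.lipo_class == "LDL" and not (18.0 <= s.diameter_nm <= 26.0):
                raise ValueError(
                    f"LDL subclass {s.name} diameter {s.diameter_nm} outside 18-26 nm"
                )
            if s.lipo_class == "HDL" and s.apob_containing:
                raise ValueError(f"HDL subclass {s.name} cannot be apoB-containing")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.subclasses)

    def of_class(self, lipo_class: str) -> tuple[str, ...]:
        return tuple(s.name for s in self.subclasses if s.lipo_class == lipo_class)

    @property
    def apob_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.subclasses if s.apob_containing)

    def __iter__(self):
        return iter(self.subclasses)

    @classmethod
    def default(cls) -> "SubclassScheme":
        return cls(tuple(Subclass(*row) for row in _DEFAULT_ROWS))

    @classmethod
    def from_yaml(cls, path) -> "SubclassScheme":
        """Load an override scheme from a YAML list of mappings."""
        import yaml

        with open(path) as fh:
            rows = yaml.safe_load(fh)
        return cls(
            tuple(
                Subclass(
                    name=r["name"],
                    diameter_nm=float(r["diameter_nm"]),
                    lipo_class=r["class"],
                    apob_containing=bool(r["apob_containing"]),
                )
                for r in rows
            )
        )


DEFAULT_SCHEME = SubclassScheme.default()


def lipid_column(subclass: str, constituent: str) -> str:
    return f"{subclass}_{constituent}"


def lipid_columns(scheme: SubclassScheme = DEFAULT_SCHEME) -> list[str]:
    return [lipid_column(s, c) for s in scheme.names for c in CONSTITUENTS]


@dataclass
class LipoproteinPanel:
    """Per-sample subclass x constituent lipid concentration matrix (mmol/L).

    Wraps a DataFrame with one row per sample, columns
    ``<SUBCLASS>_<TG|CE|FC|PL>`` plus the summary columns
    ``TOTC, TOTTG, HDLC, APOB, APOA1``.  Missing values are NaN
    (empty cells in the TSV dialect).
    """

    data: pd.DataFrame
    scheme: SubclassScheme = field(default_factory=lambda: DEFAULT_SCHEME)

    def __post_init__(self) -> None:
        missing = [c for c in lipid_columns(self.scheme) if c not in self.data.columns]
        if missing:
            raise ValueError(f"panel missing lipid columns: {missing[:6]}...")
        vals = self.data[lipid_columns(self.scheme)].to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < -1e-12:
            raise ValueError("lipid concentrations must be non-negative")

    # -- accessors -----------------------------------------------------

    def constituent(self, subclass: str, constituent: str) -> pd.Series:
        return self.data[lipid_column(subclass, constituent)]

    def subclass_total(self, subclass: str) -> pd.Series:
        """Total lipids TG+CE+FC+PL in one subclass."""
        cols = [lipid_column(subclass, c) for c in CONSTITUENTS]
        return self.data[cols].sum(axis=1, skipna=False)

    def subclass_cholesterol(self, subclass: str) -> pd.Series:
        """Total cholesterol CE+FC in one subclass (the platform's "C")."""
        return self.constituent(subclass, "CE") + self.constituent(subclass, "FC")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    # -- IO ------------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, na_rep="")

    @classmethod
    def from_tsv(cls, path, scheme: SubclassScheme = DEFAULT_SCHEME) -> "LipoproteinPanel":
        return cls(pd.read_csv(path, sep="\t"), scheme=scheme)


# ---------------------------------------------------------------------------
# Derived measures
# ---------------------------------------------------------------------------


def derive_compositions(panel: LipoproteinPanel) -> pd.DataFrame:
    """Per-subclass lipid percentages (share of all lipid molecules).

    For each subclass and constituent,
    ``pct = 100 * constituent / (TG + CE + FC + PL)``.  Samples whose
    subclass total lipids are zero (or missing) get NaN for that
    subclass's four percentages — flagged missing, not an exception.

    Returns a DataFrame with columns ``<SUBCLASS>_<CONSTITUENT>_pct``.
    """
    out = {}
    for sub in panel.scheme.names:
        total = panel.subclass_total(sub)
        denom = total.where(total > 0)
        for c in CONSTITUENTS:
            out[f"{sub}_{c}_pct"] = 100.0 * panel.constituent(sub, c) / denom
    return pd.DataFrame(out, index=panel.data.index)


def friedewald_ldl_c(
    total_c,
    hdl_c,
    total_tg,
    *,
    tg_divisor: float = 2.2,
    tg_bound: float = 4.5,
):
    """Friedewald-estimated LDL cholesterol, TC − HDL-C − TG/2.2 (mmol/L).

    The estimate is a composite: besides cholesterol in size-specific LDL
    particles it absorbs IDL and VLDL cholesterol to varying degrees.
    Samples with total TG above ``tg_bound`` (default 4.5 mmol/L, the
    conventional validity limit) are returned as NaN.  Negative inputs
    raise ``ValueError``.
    """
    tc = np.asarray(total_c, dtype=float)
    hdl = np.asarray(hdl_c, dtype=float)
    tg = np.asarray(total_tg, dtype=float)
    for name, arr in (("total_c", tc), ("hdl_c", hdl), ("total_tg", tg)):
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValueError(f"negative {name} value")
    result = tc - hdl - tg / tg_divisor
    result = np.where(tg > tg_bound, np.nan, result)
    if np.ndim(total_c) == 0 and np.ndim(hdl_c) == 0 and np.ndim(total_tg) == 0:
        return float(result)
    return result


def size_specific_ldl_c(panel: LipoproteinPanel) -> pd.Series:
    """Cholesterol carried in LDL defined by particle size (18-26 nm).

    Sum of CE+FC over the L/M/S-LDL subclasses only; IDL is excluded.
    Missing constituents propagate to a missing result.
    """
    ldl = panel.scheme.of_class("LDL")
    parts = [panel.subclass_cholesterol(s) for s in ldl]
    return sum(parts[1:], parts[0])


def remnant_cholesterol(panel: LipoproteinPanel) -> pd.Series:
    """Cholesterol in VLDL and IDL particles (remnant-C)."""
    subs = panel.scheme.of_class("VLDL") + panel.scheme.of_class("IDL")
    parts = [panel.subclass_cholesterol(s) for s in subs]
    return sum(parts[1:], parts[0])


def class_cholesterol(panel: LipoproteinPanel, lipo_class: str) -> pd.Series:
    subs = panel.scheme.of_class(lipo_class)
    parts = [panel.subclass_cholesterol(s) for s in subs]
    return sum(parts[1:], parts[0])


def class_triglycerides(panel: LipoproteinPanel, lipo_class: str) -> pd.Series:
    subs = panel.scheme.of_class(lipo_class)
    parts = [panel.constituent(s, "TG") for s in subs]
    return sum(parts[1:], parts[0])


def analysis_traits(panel: LipoproteinPanel) -> pd.DataFrame:
    """Assemble the derived trait table driving the association stages.

    Per subclass: total cholesterol (``<SUB>-C``), triglyceride
    concentration (``<SUB>-TG``) and triglyceride composition
    (``<SUB>-TG-pct``).  Plus the composite/summary measures: class
    cholesterols, size-specific and Friedewald LDL-C, remnant-C, totals
    and the apolipoprotein proxies.
    """
    comps = derive_compositions(panel)
    out = {}
    for sub in panel.scheme.names:
        out[f"{sub}-C"] = panel.subclass_cholesterol(sub)
        out[f"{sub}-TG"] = panel.constituent(sub, "TG")
        out[f"{sub}-TG-pct"] = comps[f"{sub}_TG_pct"]
    out["VLDL-C"] = class_cholesterol(panel, "VLDL")
    out["IDL-C"] = class_cholesterol(panel, "IDL")
    out["HDL-C"] = class_cholesterol(panel, "HDL")
    out["HDL-TG"] = class_triglycerides(panel, "HDL")
    out["remnant-C"] = remnant_cholesterol(panel)
    out["LDL-C-size-specific"] = size_specific_ldl_c(panel)
    d = panel.data
    out["total-C"] = d["TOTC"]
    out["total-TG"] = d["TOTTG"]
    out["LDL-C-friedewald"] = friedewald_ldl_c(
        d["TOTC"].to_numpy(), d["HDLC"].to_numpy(), d["TOTTG"].to_numpy()
    )
    out["apoB"] = d["APOB"]
    out["apoA1"] = d["APOA1"]
    return pd.DataFrame(out, index=d.index)
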