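import numpy as np
import pandas as pd
import pytest

from liposig import CohortConfig, LipoproteinPanel, simulate_cohort
from liposig.panel import CONSTITUENTS, DEFAULT_SCHEME, lipid_column


@pytest.fixture(scope="session")
def small_cohort():
    """One 1,500-sample cohort with the default two-variant effect profiles."""
    return simulate_cohort(CohortConfig("fixture", 1500), seed=42)


@pytest.fixture(scope="session")
def survival_cohort():
    """A cohort with a real event rate and an injected trait hazard."""
    cfg = CohortConfig(
        "surv-fixture", 3000, target_event_fraction=0.08,
        loghr_map={"M-HDL-TG-pct": 0.3},
    )
    return simulate_cohort(cfg, seed=7)


def panel_from_rows(rows: dict[str, list[float]], n: int) -> LipoproteinPanel:
    """Build a tiny panel with given subclass constituent values.

    ``rows`` maps lipid columns to per-sample values; unspecified lipid
    columns default to 0.1 and summaries to plausible constants.
    """
    data = {}
    for sub in DEFAULT_SCHEME.names:
        for c in CONSTITUENTS:
            col = lipid_column(sub, c)
            data[col] = rows.get(col, [0.1] * n)
    for col, default in (("TOTC", 5.0), ("TOTTG", 1.2), ("HDLC", 1.5),
                         ("APOB", 1.0), ("APOA1", 1.4)):
        data[col] = rows.get(col, [default] * n)
    return LipoproteinPanel(pd.DataFrame(data))
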