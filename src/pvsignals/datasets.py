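"""Small reference datasets shipped with the package.

These are published summary tables from large-scale FAERS/JADER
pharmacovigilance analyses of immune checkpoint inhibitors (ICIs) and
neurological immune-mediated adverse events (NAEs).  They serve as inputs
for worked examples and internal-consistency checks — e.g. verifying that
the package's statistics reproduce the arithmetic relations the published
columns satisfy (IC = log₂ EBGM, mortality = deaths/reports).  They are
*inputs*, never outputs, of this package.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd


def _path(name: str) -> Path:
    return Path(str(resources.files("pvsignals").joinpath("data", name)))


def load_ici_aie_signal_table() -> pd.DataFrame:
    """Published AIE disproportionality statistics for the ICI drugs.

    Columns: database, drug, n (case count), ror/ror_lo/ror_hi, prr, chi2,
    ebgm, ebgm05, ic, ic025 — one row per (database, ICI).
    """
    return pd.read_csv(_path("reference_ici_aie_signals.tsv"), sep="\t")


def load_annual_nae_counts() -> pd.DataFrame:
    """Published annual NAE / other-AE report counts (2007–2024, FAERS)."""
    return pd.read_csv(_path("reference_annual_nae_counts.tsv"), sep="\t")


def load_nae_group_outcomes() -> pd.DataFrame:
    """Published per-event-group report and death counts (FAERS, ICI cohort)."""
    return pd.read_csv(_path("reference_nae_group_outcomes.tsv"), sep="\t")


def load_drug_nae_proportions() -> pd.DataFrame:
    """Published NAE-report and total-report counts for selected ICIs."""
    return pd.read_csv(_path("reference_drug_nae_proportions.tsv"), sep="\t")


def load_drug_nae_outcomes() -> pd.DataFrame:
    """Published per-ICI NAE case and death counts (FAERS cohort)."""
    return pd.read_csv(_path("reference_drug_nae_outcomes.tsv"), sep="\t")
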