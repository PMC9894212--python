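"""In-memory containers for cytokine assay data.

A :class:`CytokinePanel` is a visits x markers matrix of natural-log
concentrations (log pg/mL) with missing entries coded as NaN; the
observed/missing mask is derived from the values and kept congruent by
construction.  A :class:`DuplicatePanel` holds the two technical replicates
per entry on the raw concentration scale, before the replicate-quality
(coefficient of variation) filter collapses them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 24 circulating immune proteins of the assay panel.
MARKERS = [
    "TNF_a", "IFN_g", "IL-6", "IL-10", "MCP-1", "MCP-4", "IP-10",
    "eotaxin", "eotaxin-3", "VEGF", "VEGF-D", "VEGF-C", "PLGF", "bFGF",
    "Vcam-1", "Icam-1", "Flt-1", "TIE2", "hs-CRP", "SAA", "MIP-1a",
    "MIP-1b", "TARC", "MDC",
]

#: The 7 functional cortical networks whose gray-matter volumes are analyzed.
NETWORKS = [
    "visual", "somatomotor", "dorsal_attention", "ventral_attention",
    "limbic", "frontoparietal", "default_mode",
]


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel data."""


@dataclass
class CytokinePanel:
    """Visits x markers matrix of log concentrations with a missingness mask.

    Parameters
    ----------
    values
        DataFrame indexed by visit id, one column per marker.  NaN marks a
        missing entry; every observed entry must be finite.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise PanelError("marker names must be unique")
        obs = self.values.to_numpy(dtype=float)
        if np.isinf(obs).any():
            raise PanelError("observed values must be finite")

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the entry is observed."""
        return self.values.notna()

    @property
    def marker_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_visits(self) -> int:
        return len(self.values)

    def missing_fraction(self) -> pd.Series:
        """Per-marker fraction of missing entries."""
        return self.values.isna().mean(axis=0)

    def copy(self) -> "CytokinePanel":
        return CytokinePanel(self.values.copy())

    def is_complete(self) -> bool:
        return bool(self.values.notna().all().all())


@dataclass
class DuplicatePanel:
    """Two technical replicates per entry, raw concentration scale (pg/mL)."""

    rep1: pd.DataFrame
    rep2: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.rep1.columns.equals(self.rep2.columns) or not self.rep1.index.equals(self.rep2.index):
            raise PanelError("replicate tables must share index and columns")

    @property
    def marker_names(self) -> list[str]:
        return list(self.rep1.columns)
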