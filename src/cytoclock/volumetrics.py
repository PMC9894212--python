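"""TIV normalization and descriptive correlation structure of brain volumes.

Raw per-visit volumes (mL) are expressed as dimensionless fractions of the
total intracranial volume to remove head-size variability; the pairwise
Pearson correlation matrix among aging factors (age, CyClo, sex) and the
seven normalized network volumes is computed on pairwise-complete rows with
two-sided t-test p-values.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .panel import NETWORKS

log = logging.getLogger(__name__)

VOLUME_COLUMNS = ["GMV"] + NETWORKS


class VolumeError(ValueError):
    pass


def normalize_to_tiv(raw: pd.DataFrame) -> pd.DataFrame:
    """Append TIV-normalized fraction columns (``<name>_frac``) to a volume table.

    Every raw volume column is divided by the visit's TIV; raw columns are
    preserved.  Rejects nonpositive TIV (naming the visit) and input that
    already looks normalized (a second normalization would silently square
    away the units).
    """
    if "TIV" not in raw.columns:
        raise VolumeError("volume table must contain a TIV column")
    tiv = raw["TIV"]
    bad = tiv[~(tiv > 0)]
    if len(bad):
        raise VolumeError(f"nonpositive TIV at visit(s) {list(bad.index[:5])}")
    present = [c for c in VOLUME_COLUMNS if c in raw.columns]
    if any(f"{c}_frac" in raw.columns for c in present):
        raise VolumeError("table already carries normalized columns")
    if present and (raw[present].max().max() <= 1.0):
        raise VolumeError("volumes look already normalized (all <= 1)")
    out = raw.copy()
    for c in present:
        frac = raw[c] / tiv
        if ((frac <= 0) | (frac >= 1)).any():
            raise VolumeError(f"normalized {c} outside (0, 1)")
        out[f"{c}_frac"] = frac
    return out


def correlation_matrix(table: pd.DataFrame
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations with two-sided t-test p-values.

    Returns (r, p); the correlation matrix is symmetric with unit diagonal.
    A constant column yields undefined correlations, reported as NaN with a
    warning.
    """
    cols = list(table.columns)
    if len(table.dropna(how="any")) < 3:
        raise VolumeError("need at least 3 complete rows")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            pair = table[[a, b]].dropna()
            x, y = pair[a].to_numpy(float), pair[b].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(f"constant column in pair ({a}, {b}); "
                              "correlation undefined", stacklevel=2)
                rij, pij = np.nan, np.nan
            else:
                res = stats.pearsonr(x, y)
                rij, pij = float(res.statistic), float(res.pvalue)
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    return r, p
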