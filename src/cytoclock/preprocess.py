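"""Raw assay measurements -> cleaned, batch-corrected log-scale panel.

The preprocessing chain follows standard multiplex-immunoassay practice:
collapse duplicate wells under a coefficient-of-variation quality filter,
drop markers whose missingness makes them uninformative, natural-log
transform, regress out assay-batch offsets while protecting the age and sex
signal, and derive per-visit age-bin balancing weights (1 / bin count) that
equalize the influence of age groups in downstream weighted fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import CytokinePanel, DuplicatePanel, PanelError

log = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


@dataclass
class BalancingWeights:
    """Per-visit weights w_i = 1 / (count of visits in the age bin of i)."""

    w: pd.Series
    bin_edges: np.ndarray
    bin_counts: np.ndarray

    def __post_init__(self) -> None:
        if (self.w <= 0).any():
            raise PreprocessError("balancing weights must be positive")

    def normalized(self) -> pd.Series:
        """Weights rescaled to mean 1 (comparable penalty scales across cohorts)."""
        return self.w / self.w.mean()


def replicate_cv(dups: DuplicatePanel) -> pd.DataFrame:
    """Percent CV per entry: 100 * sample sd (divisor n-1) / mean of the pair."""
    r1 = dups.rep1.to_numpy(dtype=float)
    r2 = dups.rep2.to_numpy(dtype=float)
    mean = (r1 + r2) / 2.0
    sd = np.abs(r1 - r2) / np.sqrt(2.0)   # two-replicate sample sd
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / mean
    return pd.DataFrame(cv, index=dups.rep1.index, columns=dups.rep1.columns)


def collapse_duplicates_cv_filter(dups: DuplicatePanel,
                                  cv_threshold: float = 20.0) -> CytokinePanel:
    """Collapse replicate pairs to their mean, blanking unreliable entries.

    An entry is retained (as the replicate mean, still on the raw
    concentration scale) when its percent CV is at or below the threshold;
    the boundary value itself is retained.  Entries with a nonpositive
    replicate mean cannot be log-transformed downstream and are set missing.
    """
    if cv_threshold <= 0:
        raise PreprocessError("cv_threshold must be positive")
    cv = replicate_cv(dups).to_numpy()
    mean = (dups.rep1.to_numpy(dtype=float) + dups.rep2.to_numpy(dtype=float)) / 2.0
    bad_mean = ~(mean > 0)
    if bad_mean.any():
        log.warning("%d entries with nonpositive replicate mean set missing",
                    int(bad_mean.sum()))
    keep = (cv <= cv_threshold) & ~bad_mean
    out = np.where(keep, mean, np.nan)
    return CytokinePanel(pd.DataFrame(out, index=dups.rep1.index,
                                      columns=dups.rep1.columns))


def log_transform(panel: CytokinePanel) -> CytokinePanel:
    """Natural-log transform of every observed entry; mask unchanged."""
    vals = panel.values.to_numpy(dtype=float)
    obs = ~np.isnan(vals)
    if (vals[obs] <= 0).any():
        i, j = np.argwhere(obs & ~(vals > 0))[0]
        raise PreprocessError(
            f"nonpositive value at visit {panel.values.index[i]!r}, "
            f"marker {panel.values.columns[j]!r}")
    out = np.where(obs, np.log(np.where(obs, vals, 1.0)), np.nan)
    return CytokinePanel(pd.DataFrame(out, index=panel.values.index,
                                      columns=panel.values.columns))


def drop_high_missingness_markers(panel: CytokinePanel, threshold: float = 0.55
                                  ) -> tuple[CytokinePanel, list[str]]:
    """Remove markers whose missing fraction exceeds the threshold."""
    if not (0.0 < threshold < 1.0):
        raise PreprocessError("threshold must be in (0, 1)")
    frac = panel.missing_fraction()
    dropped = [m for m in panel.marker_names if frac[m] > threshold]
    if len(dropped) == len(panel.marker_names):
        raise PreprocessError("all markers exceed the missingness threshold")
    kept = [m for m in panel.marker_names if m not in dropped]
    return CytokinePanel(panel.values[kept].copy()), dropped


def remove_batch_effects(panel: CytokinePanel, batches: pd.Series,
                         covariates: pd.DataFrame) -> CytokinePanel:
    """Subtract least-squares batch offsets per marker, protecting covariates.

    Per marker, the observed entries are fit on
    ``[intercept | covariates | sum-to-zero batch indicators]`` and only the
    fitted batch component is subtracted, so variation attributable to the
    covariates (age, sex) is preserved.  The sum-to-zero coding makes the
    correction mean-neutral across batches.  With a single batch the panel
    is returned unchanged; a batch level entirely unobserved for a marker
    contributes a zero correction and is logged.
    """
    levels = sorted(pd.unique(batches))
    if len(levels) < 2:
        return panel.copy()
    batches = batches.loc[panel.values.index]
    covariates = covariates.loc[panel.values.index]
    # sum-to-zero contrasts: last level = -(sum of others)
    n = len(batches)
    B = np.zeros((n, len(levels) - 1))
    codes = pd.Categorical(batches, categories=levels).codes
    for k in range(len(levels) - 1):
        B[codes == k, k] = 1.0
    B[codes == len(levels) - 1, :] = -1.0
    C = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    X = np.column_stack([C, B])
    p_cov = C.shape[1]

    vals = panel.values.to_numpy(dtype=float).copy()
    for j, m in enumerate(panel.marker_names):
        obs = ~np.isnan(vals[:, j])
        present = set(codes[obs])
        if len(present) < len(levels):
            log.warning("marker %s: batch level(s) entirely missing; "
                        "their coefficients treated as zero", m)
        Xo = X[obs]
        beta, *_ = np.linalg.lstsq(Xo, vals[obs, j], rcond=None)
        batch_comp = X[:, p_cov:] @ beta[p_cov:]
        vals[obs, j] -= batch_comp[obs]
    return CytokinePanel(pd.DataFrame(vals, index=panel.values.index,
                                      columns=panel.values.columns))


def compute_balancing_weights(ages: pd.Series, bin_width: float = 5.0
                              ) -> BalancingWeights:
    """Age-bin balancing weights: w_i = 1 / (number of visits in i's bin).

    Fixed-width bins span [min age, max age]; visits in the same bin share a
    weight, so summing w_i over all visits equals the number of nonempty
    bins.
    """
    if len(ages) == 0:
        raise PreprocessError("ages must be nonempty")
    if bin_width <= 0:
        raise PreprocessError("bin_width must be positive")
    a = ages.to_numpy(dtype=float)
    lo, hi = a.min(), a.max()
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi)
    idx = np.clip(np.digitize(a, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    w = 1.0 / counts[idx]
    return BalancingWeights(w=pd.Series(w, index=ages.index, name="weight"),
                            bin_edges=edges, bin_counts=counts)
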