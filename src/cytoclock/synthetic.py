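"""Seeded simulator for longitudinal cytokine + brain-volume cohorts.

The generator emulates the statistical structure of an observational
brain-aging cohort: ~554 adults aged 47-102 (mean 69), roughly three yearly
visits each, a 24-protein plasma panel measured in duplicate across four
assay batches, and per-visit brain volumetrics (total intracranial volume,
total gray matter, and seven functional-network gray-matter volumes that are
highly inter-correlated and decline with age).

Nine of the 24 markers carry a genuine age signal ("inflammaging"); the
remainder are age-null.  A per-visit latent inflammation score -- the
noise-free signed combination of the true markers' residual deviations --
couples the cytokine panel to the brain volumes, so a clock built from the
panel carries information about the volumes beyond calendar age.  Every
random draw flows from a single seed through named substreams, so cohorts
are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import MARKERS, NETWORKS, CytokinePanel, DuplicatePanel, PanelError


class ConfigError(ValueError):
    """Raised when a simulation config is internally inconsistent."""


#: Markers with a genuine (positive) age slope, in log-units per year.
DEFAULT_AGE_SLOPES = {
    "TNF_a": 0.013,
    "IL-6": 0.016,
    "MCP-1": 0.012,
    "IP-10": 0.013,
    "eotaxin": 0.012,
    "VEGF": 0.015,
    "VEGF-D": 0.013,
    "PLGF": 0.014,
    "Vcam-1": 0.012,
}

#: Loading of each true marker on the per-visit latent inflammation score
#: (log-units per latent unit); the shared factor makes the panel mutually
#: correlated beyond age, as inflammatory markers are in vivo.
DEFAULT_LATENT_LOADINGS = {m: 0.1 for m in DEFAULT_AGE_SLOPES}

#: Markers with small sex differences (female minus male, log-units).
DEFAULT_SEX_EFFECTS = {
    "IL-6": -0.08,
    "hs-CRP": 0.15,
    "SAA": 0.10,
    "TARC": -0.05,
    "MDC": 0.06,
}

#: Markers assayed reliably (<5% missingness); the other 13 fall in the
#: 40-55% band.
DEFAULT_LOW_MISSING_MARKERS = [
    "IL-6", "IL-10", "MCP-1", "IP-10", "VEGF", "hs-CRP", "SAA",
    "Icam-1", "MIP-1b", "TARC", "MDC",
]

#: Network gray-matter fractions of TIV at the cohort mean age.
DEFAULT_NETWORK_BASES = {
    "visual": 0.055,
    "somatomotor": 0.065,
    "dorsal_attention": 0.040,
    "ventral_attention": 0.045,
    "limbic": 0.050,
    "frontoparietal": 0.060,
    "default_mode": 0.075,
}

#: Fraction-of-TIV change per year of age; somatomotor declines fastest.
DEFAULT_NETWORK_AGE_SLOPES = {
    "visual": -1.2e-4,
    "somatomotor": -3.0e-4,
    "dorsal_attention": -1.8e-4,
    "ventral_attention": -1.9e-4,
    "limbic": -1.0e-4,
    "frontoparietal": -2.0e-4,
    "default_mode": -2.2e-4,
}

#: Sex effect on the normalized fraction (female minus male); women carry a
#: higher gray-matter fraction, the visual network is nearly balanced.
DEFAULT_NETWORK_SEX_EFFECTS = {
    "visual": 0.00005,
    "somatomotor": 0.0006,
    "dorsal_attention": 0.0004,
    "ventral_attention": 0.0010,
    "limbic": 0.0004,
    "frontoparietal": 0.0012,
    "default_mode": 0.0005,
}

#: Loading of each network fraction on the latent inflammation score
#: (fraction per latent unit); default-mode/limbic/dorsal-attention are the
#: most inflammation-sensitive.
DEFAULT_NETWORK_CLOCK_LOADINGS = {
    "visual": -1.0e-4,
    "somatomotor": -1.5e-4,
    "dorsal_attention": -1.0e-3,
    "ventral_attention": -2.0e-4,
    "limbic": -1.2e-3,
    "frontoparietal": -2.5e-4,
    "default_mode": -1.5e-3,
}


@dataclass
class SimConfig:
    """All magnitudes of the cohort simulator, with documented defaults.

    Defaults mirror the emulated study: 554 subjects, truncated-normal ages
    (mean 69, sd 9) on [47, 102], ~3 visits at least a year apart, 24
    markers of which 9 are age-associated, 4 assay batches, 11 markers with
    ~3% missingness and 13 with ~45%, and 7 network volumes sharing a
    common factor so their pairwise correlations are high.
    """

    n_subjects: int = 554
    age_range: tuple[float, float] = (47.0, 102.0)
    age_mean: float = 69.0
    age_sd: float = 9.0
    female_frac: float = 308 / 554
    mean_visits: float = 3.0
    max_visits: int = 13
    visit_gap: float = 0.3          # mean of the Exponential part; gaps are 1 + Exp
    n_markers: int = 24
    marker_names: list[str] = field(default_factory=lambda: list(MARKERS))
    true_marker_names: list[str] = field(default_factory=lambda: list(DEFAULT_AGE_SLOPES))
    age_slopes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_SLOPES))
    sex_effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_EFFECTS))
    latent_loadings: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LATENT_LOADINGS))
    marker_baseline_low: float = 1.5    # log pg/mL intercepts span this range
    marker_baseline_step: float = 0.15
    marker_noise_sd: float = 0.33
    n_batches: int = 4
    batch_magnitudes: float = 0.2   # sd of per-(batch, marker) offsets, log-units
    missing_low_frac: float = 0.03
    missing_high_frac: float = 0.45
    n_low_missing_markers: int = 11
    n_high_missing_markers: int = 13
    low_missing_markers: list[str] = field(
        default_factory=lambda: list(DEFAULT_LOW_MISSING_MARKERS))
    mar_age_gain: float = 0.3       # age-dependence of the MAR mechanism
    duplicate_cv_sd: float = 0.08   # log-scale dispersion of technical replicates
    network_bases: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NETWORK_BASES))
    network_age_slopes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NETWORK_AGE_SLOPES))
    network_sex_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NETWORK_SEX_EFFECTS))
    network_clock_loadings: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NETWORK_CLOCK_LOADINGS))
    shared_factor_sd: float = 0.003     # per-visit factor common to all networks
    subject_factor_sd: float = 0.002    # per-subject factor common to all networks
    network_noise_sd: float = 0.0012
    nonnetwork_gray_frac: float = 0.05  # subcortical/cerebellar gray, part of GMV
    gmv_noise_sd: float = 0.0015
    tiv_mean: float = 1500.0        # mL, male mean
    tiv_sex_gap: float = 160.0      # mL, male minus female
    tiv_sd: float = 100.0
    physio_age_gain: float = 8.0    # years of physiological age per latent unit
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.age_range
        if not (40.0 <= lo < hi <= 110.0):
            raise ConfigError("age_range must lie within [40, 110]")
        for name in ("n_subjects", "n_markers", "n_batches", "max_visits"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("missing_low_frac", "missing_high_frac"):
            frac = getattr(self, name)
            if not (0.0 <= frac < 1.0):
                raise ConfigError(f"{name} must be in [0, 1)")
        if self.n_low_missing_markers + self.n_high_missing_markers > self.n_markers:
            raise ConfigError("n_low + n_high missing markers exceed n_markers")
        if len(self.marker_names) != self.n_markers:
            raise ConfigError("marker_names length must equal n_markers")
        unknown = set(self.true_marker_names) - set(self.marker_names)
        if unknown:
            raise ConfigError(f"true markers not in panel: {sorted(unknown)}")
        if set(self.age_slopes) != set(self.true_marker_names):
            raise ConfigError("age_slopes keys must equal true_marker_names")

    def baselines(self) -> dict[str, float]:
        """Deterministic log-scale intercept per marker."""
        return {m: self.marker_baseline_low + self.marker_baseline_step * i
                for i, m in enumerate(self.marker_names)}


@dataclass
class TruthRecord:
    """Ground truth stored before missingness injection, for recovery tests."""

    age_slopes: dict[str, float]
    support: list[str]                  # markers with nonzero age slope
    sex_effects: dict[str, float]
    batch_offsets: dict[str, dict[str, float]]   # batch label -> marker -> offset
    latent: pd.Series                   # per-visit latent inflammation score
    physio_age: pd.Series               # age + gain * latent, per visit
    network_age_slopes: dict[str, float]
    network_sex_effects: dict[str, float]
    network_clock_loadings: dict[str, float]
    noise_free_values: pd.DataFrame     # marker levels without the e_ij noise
    conditional_mean: pd.DataFrame      # full generative mean per entry

    def to_json(self) -> str:
        doc = {
            "age_slopes": self.age_slopes,
            "support": self.support,
            "sex_effects": self.sex_effects,
            "batch_offsets": self.batch_offsets,
            "network_age_slopes": self.network_age_slopes,
            "network_sex_effects": self.network_sex_effects,
            "network_clock_loadings": self.network_clock_loadings,
            "latent": self.latent.round(10).to_dict(),
            "physio_age": self.physio_age.round(10).to_dict(),
        }
        return json.dumps(doc, indent=1, sort_keys=True)


def _simulate_visits(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    base_age = stats.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                                   size=config.n_subjects, random_state=rng)
    n_visits = 1 + rng.poisson(max(config.mean_visits - 1.0, 0.0), size=config.n_subjects)
    n_visits = np.clip(n_visits, 1, config.max_visits)
    sex = (rng.random(config.n_subjects) < config.female_frac).astype(int)

    rows = []
    ids = []
    for s in range(config.n_subjects):
        sid = f"S{s:04d}"
        t = 0.0
        for v in range(n_visits[s]):
            if v > 0:
                t += 1.0 + rng.exponential(config.visit_gap)
            ids.append(f"{sid}_v{v}")
            rows.append({
                "subject_id": sid,
                "visit_time": round(t, 6),
                "age": round(base_age[s] + t, 6),
                "sex": int(sex[s]),
                "batch": f"B{rng.integers(config.n_batches)}",
            })
    return pd.DataFrame(rows, index=pd.Index(ids, name="visit_id"))


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, CytokinePanel, pd.DataFrame, TruthRecord]:
    """Simulate a complete cohort (no missingness injected yet).

    Returns
    -------
    visits
        One row per visit: subject_id, visit_time (years from first visit),
        age, sex (female = 1, male = 0), batch label.
    panel
        Complete log-scale cytokine panel, all entries observed.
    volumes
        Per-visit TIV, GMV and the 7 network volumes, in mL.
    truth
        Generative parameters and latent scores for recovery tests.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_visits, rng_markers, rng_vols = (np.random.default_rng(s) for s in ss.spawn(3))

    visits = _simulate_visits(config, rng_visits)
    n = len(visits)
    age = visits["age"].to_numpy()
    sex = visits["sex"].to_numpy()
    age_c = age - config.age_mean

    # --- cytokine panel: mu_j + gamma_j age + s_j sex + b_batch + e_ij
    baselines = config.baselines()
    batch_labels = [f"B{b}" for b in range(config.n_batches)]
    batch_offsets = {
        lab: {m: float(rng_markers.normal(0.0, config.batch_magnitudes))
              for m in config.marker_names}
        for lab in batch_labels
    }
    # per-visit latent inflammation score: the shared, noise-free component
    # of the true markers' deviations (unit variance, independent of age)
    latent = rng_markers.standard_normal(n)
    noise = rng_markers.normal(0.0, config.marker_noise_sd,
                               size=(n, config.n_markers))
    mean = np.empty((n, config.n_markers))
    for j, m in enumerate(config.marker_names):
        gamma = config.age_slopes.get(m, 0.0)
        s_eff = config.sex_effects.get(m, 0.0)
        phi = config.latent_loadings.get(m, 0.0)
        b_off = visits["batch"].map(lambda lab: batch_offsets[lab][m]).to_numpy()
        mean[:, j] = (baselines[m] + gamma * age_c + s_eff * sex + b_off
                      + phi * latent)
    values = mean + noise
    panel = CytokinePanel(pd.DataFrame(values, index=visits.index,
                                       columns=config.marker_names))

    # --- brain volumes: fractions of TIV with shared visit- and subject-level
    # factors driving high pairwise network correlations
    shared_visit = rng_vols.normal(0.0, config.shared_factor_sd, size=n)
    subj_ids = visits["subject_id"].to_numpy()
    uniq = pd.unique(subj_ids)
    subj_fac = dict(zip(uniq, rng_vols.normal(0.0, config.subject_factor_sd, size=len(uniq))))
    shared_subj = np.array([subj_fac[s] for s in subj_ids])

    fracs = {}
    for k in NETWORKS:
        eps = rng_vols.normal(0.0, config.network_noise_sd, size=n)
        fracs[k] = (config.network_bases[k]
                    + config.network_age_slopes[k] * age_c
                    + config.network_sex_effects[k] * sex
                    + config.network_clock_loadings[k] * latent
                    + shared_visit + shared_subj + eps)
    net_frac = pd.DataFrame(fracs, index=visits.index)
    gmv_frac = (net_frac.sum(axis=1) + config.nonnetwork_gray_frac
                + rng_vols.normal(0.0, config.gmv_noise_sd, size=n))

    tiv_subj = {s: float(np.clip(
        rng_vols.normal(config.tiv_mean, config.tiv_sd), 1100.0, None))
        for s in uniq}
    sex_by_subj = visits.groupby("subject_id")["sex"].first().to_dict()
    tiv = np.array([tiv_subj[s] - config.tiv_sex_gap * sex_by_subj[s] for s in subj_ids])

    volumes = pd.DataFrame({"TIV": tiv, "GMV": gmv_frac.to_numpy() * tiv},
                           index=visits.index)
    for k in NETWORKS:
        volumes[k] = net_frac[k].to_numpy() * tiv

    truth = TruthRecord(
        age_slopes={m: config.age_slopes.get(m, 0.0) for m in config.marker_names},
        support=list(config.true_marker_names),
        sex_effects={m: config.sex_effects.get(m, 0.0) for m in config.marker_names},
        batch_offsets=batch_offsets,
        latent=pd.Series(latent, index=visits.index, name="latent"),
        physio_age=pd.Series(age + config.physio_age_gain * latent,
                             index=visits.index, name="physio_age"),
        network_age_slopes=dict(config.network_age_slopes),
        network_sex_effects=dict(config.network_sex_effects),
        network_clock_loadings=dict(config.network_clock_loadings),
        noise_free_values=pd.DataFrame(mean, index=visits.index,
                                       columns=config.marker_names),
        conditional_mean=pd.DataFrame(mean, index=visits.index,
                                      columns=config.marker_names),
    )
    return visits, panel, volumes, truth


def marker_missing_fractions(config: SimConfig) -> dict[str, float]:
    """Target missingness fraction per marker (low band vs high band)."""
    low = set(config.low_missing_markers[: config.n_low_missing_markers])
    fracs = {}
    n_high = 0
    for m in config.marker_names:
        if m in low:
            fracs[m] = config.missing_low_frac
        elif n_high < config.n_high_missing_markers:
            fracs[m] = config.missing_high_frac
            n_high += 1
        else:
            fracs[m] = config.missing_low_frac
    return fracs


def inject_missingness(panel: CytokinePanel, config: SimConfig,
                       visits: pd.DataFrame | None = None,
                       rng: np.random.Generator | None = None) -> CytokinePanel:
    """Blank entries missing-at-random to reach the configured per-marker bands.

    The missingness probability depends only on observed covariates (age,
    via a logistic tilt of strength ``mar_age_gain``), never on the hidden
    value itself.  Entries already missing count toward the target, so the
    operation composes with upstream filters; observed values are never
    altered, only the mask.
    """
    for name in ("missing_low_frac", "missing_high_frac"):
        if getattr(config, name) >= 1.0:
            raise ConfigError(f"{name} must be < 1")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    values = panel.values.copy()
    n = len(values)
    if visits is not None and config.mar_age_gain != 0.0:
        age = visits.loc[values.index, "age"].to_numpy()
        tilt = 1.0 + config.mar_age_gain * np.tanh((age - config.age_mean) / 15.0)
    else:
        tilt = np.ones(n)
    targets = marker_missing_fractions(config)
    for m in values.columns:
        frac = targets.get(m, config.missing_low_frac)
        already = values[m].isna().to_numpy()
        extra = frac - already.mean()
        if extra <= 0.0:
            continue
        p = extra / (1.0 - already.mean()) * tilt / tilt[~already].mean()
        hit = (rng.random(n) < p) & ~already
        values.loc[hit, m] = np.nan
    return CytokinePanel(values)


def inject_duplicate_noise(panel: CytokinePanel, cv_sd: float,
                           rng: np.random.Generator | None = None,
                           seed: int = 0) -> DuplicatePanel:
    """Expand a complete log-scale panel into noisy raw-scale replicate pairs.

    Each entry's two replicates are ``exp(value) * exp(eps)`` with
    independent ``eps ~ N(0, cv_sd)``, emulating duplicate assay wells; a
    large dispersion produces entries whose coefficient of variation exceeds
    the downstream quality threshold.
    """
    if cv_sd < 0:
        raise ConfigError("cv_sd must be nonnegative")
    if not panel.is_complete():
        raise PanelError("duplicate noise requires a complete panel")
    if rng is None:
        rng = np.random.default_rng(seed)
    raw = np.exp(panel.values.to_numpy())
    e1 = rng.normal(0.0, cv_sd, size=raw.shape) if cv_sd else np.zeros_like(raw)
    e2 = rng.normal(0.0, cv_sd, size=raw.shape) if cv_sd else np.zeros_like(raw)
    rep1 = pd.DataFrame(raw * np.exp(e1), index=panel.values.index,
                        columns=panel.values.columns)
    rep2 = pd.DataFrame(raw * np.exp(e2), index=panel.values.index,
                        columns=panel.values.columns)
    return DuplicatePanel(rep1, rep2)
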