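"""Synthetic longitudinal cohort generator.

Emulates the data structure of a daily CT-guided chemoradiation study:
per-patient, per-fraction textured 3D volumes with a spherical ROI whose
texture disorder drifts monotonically across fractions (in opposite
directions for good vs bad responders), sparse lognormal CA19-9
trajectories with group-dependent weekly multiplicative trends, binary
pathological response labels, and progression-free survival tied to the
biomarker change with independent censoring.

The texture mechanism is a spatially correlated Gaussian random field
posterized to ``L_f`` equiprobable gray values inside the ROI; the drift
acts multiplicatively on ``L_f`` per fraction, which gives an analytic
handle on the direction of the GLCM-entropy trend (fewer effective levels
=> lower entropy).

Everything is driven by one master seed; each patient gets an independent
RNG stream derived from (seed, patient index), so cohorts are extendable
without reshuffling existing patients.

The module also provides light-weight trajectory-level generators
(:func:`simulate_lme_dataset`, :func:`simulate_weekly_biomarkers`) used for
statistical calibration studies where synthesizing images would only add
runtime, not information.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .textures import VolumeROI

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "ConfigError",
    "week_of_fraction",
    "generate_volume_series",
    "generate_ca199",
    "generate_survival",
    "generate_cohort",
    "simulate_lme_dataset",
    "simulate_weekly_biomarkers",
]

FRACTIONS_PER_WEEK = 5


class ConfigError(ValueError):
    """Invalid cohort configuration."""


def week_of_fraction(fraction, per_week: int = FRACTIONS_PER_WEEK):
    """Treatment week of a fraction index: ceil(f / 5); fraction 0 (the
    pre-treatment baseline sample) maps to week 0."""
    f = np.asarray(fraction)
    return np.ceil(f / per_week).astype(int)


@dataclass
class CohortConfig:
    """Generating parameters of a synthetic cohort.

    Defaults mirror the study design being emulated: 24 patients split
    evenly into good (G1/G2) and bad (G3) pathological responders, 28 daily
    fractions, texture disorder drifting down ~2.5%/fraction for good
    responders and up ~1.5%/fraction for bad ones (with per-patient
    heterogeneity so the groups overlap), CA19-9 declining ~10%/week for
    good and rising ~10%/week for bad responders from a lognormal baseline
    (median 100 U/mL) with 30% observation CV, sparse sampling (baseline,
    two mid-course draws, a final-week draw), and exponential
    progression-free survival whose hazard decreases with the
    (benefit-oriented) normalized CA19-9 change.
    """

    n_patients: int = 24
    n_fractions: int = 28
    group_split: float = 0.5
    volume_shape: tuple[int, int, int] = (20, 20, 20)
    roi_radius_voxels: float = 7.0
    base_levels: int = 16
    correlation_length_voxels: float = 1.5
    texture_drift_good: float = -0.025
    texture_drift_bad: float = 0.015
    texture_drift_sd: float = 0.025
    ca199_trend_log_sd: float = 0.2
    ca199_baseline_log_mean: float = math.log(100.0)
    ca199_baseline_log_sd: float = 1.0
    ca199_weekly_multiplier_good: float = 0.90
    ca199_weekly_multiplier_bad: float = 1.10
    ca199_noise_cv: float = 0.30
    ca199_schedule: tuple[int, ...] = (0, 9, 18, 28)
    survival_hr_per_unit: float = 0.7
    baseline_median_survival_months: float = 40.0
    censor_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.n_fractions < 2:
            raise ConfigError("n_fractions must be >= 2")
        if not 0.0 <= self.group_split <= 1.0:
            raise ConfigError("group_split must be in [0, 1]")
        if any(s <= 0 for s in self.volume_shape):
            raise ConfigError("volume_shape must be positive")
        if self.roi_radius_voxels <= 0:
            raise ConfigError("roi_radius_voxels must be positive")
        if 2 * self.roi_radius_voxels >= min(self.volume_shape):
            raise ConfigError("ROI radius exceeds the volume")
        if (
            self.ca199_weekly_multiplier_good <= 0
            or self.ca199_weekly_multiplier_bad <= 0
        ):
            raise ConfigError("CA19-9 multipliers must be positive")
        if not self.ca199_schedule:
            raise ConfigError("CA19-9 schedule is empty")
        if 0 not in self.ca199_schedule:
            raise ConfigError("CA19-9 schedule must contain the baseline sample (0)")
        last_week = week_of_fraction(self.n_fractions)
        if not any(
            f > 0 and week_of_fraction(f) == last_week for f in self.ca199_schedule
        ):
            raise ConfigError("CA19-9 schedule needs a sample in the final week")
        if any(f < 0 or f > self.n_fractions for f in self.ca199_schedule):
            raise ConfigError("CA19-9 schedule outside 0..n_fractions")
        if self.survival_hr_per_unit <= 0:
            raise ConfigError("survival_hr_per_unit must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigError("censor_rate must be in [0, 1)")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["volume_shape"] = list(self.volume_shape)
        d["ca199_schedule"] = list(self.ca199_schedule)
        return d


@dataclass
class SyntheticCohort:
    """A generated cohort plus the exact parameters that produced it."""

    volumes: dict[str, dict[int, VolumeROI]]
    ca199: pd.DataFrame
    labels: pd.DataFrame
    survival: pd.DataFrame
    truth: dict


def _patient_rng(config: CohortConfig, index: int, stream: int = 0):
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed) % 2**31, index, stream])
    )


def _sphere_mask(shape, radius) -> np.ndarray:
    center = [(n - 1) / 2.0 for n in shape]
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius ** 2


def generate_volume_series(
    group: str, config: CohortConfig, rng: np.random.Generator
) -> dict[int, VolumeROI]:
    """Per-fraction textured volumes for one patient.

    Each fraction's ROI is an independent correlated Gaussian random field
    posterized to ``L_f = base_levels * (1 + drift)^(f-1)`` equiprobable
    gray values (floored at 2); a negative drift (good responders) makes
    the texture progressively more ordered, i.e. GLCM entropy trends down.
    """
    config.validate()
    drift = (
        config.texture_drift_good if group == "good" else config.texture_drift_bad
    )
    # per-patient trend heterogeneity: response groups overlap, as in any
    # real cohort, instead of separating deterministically
    drift = drift + config.texture_drift_sd * rng.standard_normal()
    mask = _sphere_mask(config.volume_shape, config.roi_radius_voxels)
    series: dict[int, VolumeROI] = {}
    for frac in range(1, config.n_fractions + 1):
        levels_f = max(2, int(round(config.base_levels * (1.0 + drift) ** (frac - 1))))
        field_ = ndimage.gaussian_filter(
            rng.standard_normal(config.volume_shape),
            sigma=config.correlation_length_voxels,
            mode="wrap",
        )
        vol = np.full(config.volume_shape, -100.0)
        vals = field_[mask]
        # rank -> equiprobable level -> gray value in [0, 100] HU-like units
        ranks = np.argsort(np.argsort(vals))
        lv = np.minimum((ranks * levels_f) // len(vals), levels_f - 1)
        vol[mask] = lv * (100.0 / max(levels_f - 1, 1))
        vol += 0.01 * rng.standard_normal(config.volume_shape)
        series[frac] = VolumeROI(vol, mask, spacing=(0.98, 0.98, 3.0))
    return series


def generate_ca199(
    group: str, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Sparse CA19-9 records for one patient (columns fraction, value).

    baseline ~ lognormal(log_mean, log_sd) drawn at the pre-treatment
    sample (fraction 0); the value at fraction f is
    baseline * multiplier^week(f) * noise with a unit-mean lognormal noise
    of coefficient of variation ``ca199_noise_cv``.
    """
    config.validate()
    mult = (
        config.ca199_weekly_multiplier_good
        if group == "good"
        else config.ca199_weekly_multiplier_bad
    )
    baseline = float(
        rng.lognormal(config.ca199_baseline_log_mean, config.ca199_baseline_log_sd)
    )
    log_mult = math.log(mult) + config.ca199_trend_log_sd * rng.standard_normal()
    mult = math.exp(log_mult)
    if config.ca199_noise_cv > 0:
        sig = math.sqrt(math.log(1.0 + config.ca199_noise_cv ** 2))
    else:
        sig = 0.0
    rows = []
    for frac in sorted(set(config.ca199_schedule)):
        week = int(week_of_fraction(frac))
        noise = 1.0 if frac == 0 else float(rng.lognormal(-sig ** 2 / 2.0, sig))
        rows.append((frac, baseline * mult ** week * noise))
    return pd.DataFrame(rows, columns=["fraction", "value"])


def generate_survival(
    labels: pd.DataFrame,
    ca199_changes: pd.Series,
    config: CohortConfig,
    rng: np.random.Generator,
    extra_covariates: pd.DataFrame | None = None,
    extra_log_hrs: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Exponential survival with hazard proportional to the biomarker change.

    hazard_i = (ln 2 / median) * hr_per_unit ** x_i where x_i is patient
    i's summary normalized CA19-9 change (positive = decline = benefit,
    so hr_per_unit < 1 means decline is protective). Optional extra
    covariates contribute multiplicatively through their own log-HRs.
    Censoring times are an independent exponential whose rate yields the
    configured marginal censoring fraction in the covariate-free case.
    """
    config.validate()
    lam0 = math.log(2.0) / config.baseline_median_survival_months
    beta = math.log(config.survival_hr_per_unit)
    pids = list(labels["patient_id"])
    x = ca199_changes.reindex(pids).to_numpy(dtype=float)
    lp = beta * x
    if extra_covariates is not None:
        for name, b in (extra_log_hrs or {}).items():
            lp = lp + b * extra_covariates.loc[pids, name].to_numpy(dtype=float)
    lam = lam0 * np.exp(lp)
    t_event = rng.exponential(1.0 / lam)
    if config.censor_rate > 0:
        lam_c = lam0 * config.censor_rate / (1.0 - config.censor_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=len(pids))
    else:
        t_cens = np.full(len(pids), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {"patient_id": pids, "time_months": time, "event": event}
    )


def generate_cohort(config: CohortConfig, with_volumes: bool = True) -> SyntheticCohort:
    """Full synthetic cohort: volumes (optional), CA19-9, labels, survival."""
    config.validate()
    n_good = int(round(config.n_patients * config.group_split))
    labels = pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(config.n_patients)],
            "ryan_grade": ["G1" if i < n_good else "G3" for i in range(config.n_patients)],
            "group": ["good" if i < n_good else "bad" for i in range(config.n_patients)],
        }
    )

    volumes: dict[str, dict[int, VolumeROI]] = {}
    ca_rows = []
    for i, row in labels.iterrows():
        pid, group = row["patient_id"], row["group"]
        if with_volumes:
            volumes[pid] = generate_volume_series(
                group, config, _patient_rng(config, i, stream=0)
            )
        ca = generate_ca199(group, config, _patient_rng(config, i, stream=1))
        ca.insert(0, "patient_id", pid)
        ca_rows.append(ca)
    ca199 = pd.concat(ca_rows, ignore_index=True)

    # summary biomarker change driving survival: normalized change at the
    # last scheduled sample, (baseline - last) / baseline
    base = ca199[ca199["fraction"] == 0].set_index("patient_id")["value"]
    last_frac = ca199["fraction"].max()
    last = ca199[ca199["fraction"] == last_frac].set_index("patient_id")["value"]
    change = (base - last) / base
    survival = generate_survival(
        labels, change, config, _patient_rng(config, config.n_patients, stream=2)
    )

    return SyntheticCohort(
        volumes=volumes,
        ca199=ca199,
        labels=labels,
        survival=survival,
        truth=config.as_dict(),
    )


# ---------------------------------------------------------------------------
# trajectory-level generators for statistical calibration studies

def simulate_lme_dataset(
    n_per_group: int,
    n_fractions: int,
    effect: float,
    rng: np.random.Generator,
    sd_patient: float = 0.3,
    sd_fraction: float = 0.2,
    sd_resid: float = 1.0,
) -> pd.DataFrame:
    """Longitudinal records from the crossed random-intercept model
    y = effect * response + b_patient + c_fraction + e, the generating
    model assumed by the mixed-effects response test."""
    n_pat = 2 * n_per_group
    pat = np.repeat(np.arange(n_pat), n_fractions)
    frac = np.tile(np.arange(n_fractions), n_pat)
    resp = (pat < n_per_group).astype(float)
    y = (
        effect * resp
        + rng.normal(0.0, sd_patient, n_pat)[pat]
        + rng.normal(0.0, sd_fraction, n_fractions)[frac]
        + rng.normal(0.0, sd_resid, n_pat * n_fractions)
    )
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in pat],
            "fraction": frac + 2,  # delta records start at fraction 2
            "group": np.where(resp == 1, "good", "bad"),
            "value": y,
        }
    )


def simulate_weekly_biomarkers(
    n_per_group: int,
    n_weeks: int,
    onsets: dict[str, int],
    rng: np.random.Generator,
    effect_sd: float = 2.0,
    fractions_per_week: int = FRACTIONS_PER_WEEK,
    sparse: tuple[str, ...] = ("ca199",),
) -> pd.DataFrame:
    """Weekly biomarker-change records with group divergence starting at a
    per-biomarker onset week.

    For biomarker b with onset week w_b, good responders are shifted by
    +effect_sd/2 and bad responders by -effect_sd/2 (in units of the unit
    residual SD) for every week >= w_b. Biomarkers listed in ``sparse``
    get one record per patient per week (a blood draw); the others get one
    record per fraction of the week (daily imaging).

    Returns columns: patient_id, group, biomarker, week, fraction, value.
    """
    rows = []
    for g, sign in (("good", 0.5), ("bad", -0.5)):
        for i in range(n_per_group):
            pid = f"{g[0].upper()}{i:03d}"
            for name, onset in onsets.items():
                for w in range(1, n_weeks + 1):
                    shift = sign * effect_sd if w >= onset else 0.0
                    if name in sparse:
                        fr_list = [w * fractions_per_week]
                    else:
                        fr_list = list(
                            range((w - 1) * fractions_per_week + 1,
                                  w * fractions_per_week + 1)
                        )
                    for fr in fr_list:
                        rows.append(
                            (pid, g, name, w, fr, shift + rng.normal())
                        )
    return pd.DataFrame(
        rows, columns=["patient_id", "group", "biomarker", "week", "fraction", "value"]
    )
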