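"""Synthetic multilevel longitudinal physical-activity data.

Generates accelerometer-style outcome data (minutes of MVPA / sedentary
time) for pupils nested in schools nested in studies, with repeated
measurement waves.  The generating model is the one assumed by the
downstream estimators and sample-size calculators:

    y_ijkt = mu + yeargroup + gender + slope * (wear - wear_mean)
             + study_i + school_ij(t) + pupil_ijk(t) + e_ijkt

with independent Gaussian effects.  School and pupil effects are
exchangeable (compound symmetric) across waves with correlations ``cac``
and ``iac`` respectively, so a single parameter per level governs
persistence over time.  Every moment of the generated data is available
in closed form (:func:`theoretical_moments`,
:func:`wave_pair_correlations`), which makes the generator usable as an
oracle for the estimation modules.

Pupils advance one school year per elapsed year; pupils who cross the
Y6 -> Y7 primary/secondary transition are moved to a new (secondary)
school id, which is what makes the same-school rule of the cluster
autocorrelation estimator non-trivial.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "generate_population",
    "theoretical_moments",
    "wave_pair_correlations",
    "filter_valid",
    "read_observations",
    "write_observations",
    "OBSERVATION_COLUMNS",
    "YEAR_GROUPS",
]

#: Exact CSV column order for observation tables.
OBSERVATION_COLUMNS = [
    "study_id", "school_id", "school_phase", "pupil_id",
    "wave_index", "years_since_baseline", "year_group", "gender",
    "wear_min", "valid_days",
    "mvpa_weekday", "mvpa_week", "sed_weekday", "sed_week",
]

OUTCOME_COLUMNS = ["mvpa_weekday", "mvpa_week", "sed_weekday", "sed_week"]

#: England school-year bands, primary (Y1-Y6) then secondary (Y7-Y11).
YEAR_GROUPS = ["Y1&4", "Y5", "Y6", "Y7", "Y8&9", "Y10&11"]


def year_to_band(year: int) -> str:
    """Map an England school year (1-11) to its analysis band."""
    year = int(min(year, 11))
    if year <= 4:
        return "Y1&4"
    if year == 5:
        return "Y5"
    if year == 6:
        return "Y6"
    if year == 7:
        return "Y7"
    if year <= 9:
        return "Y8&9"
    return "Y10&11"


# Outcome calibration: mean minutes and the ratio of each outcome's
# total SD to the weekday-MVPA total SD (sedentary time is negatively
# related to MVPA, hence the negative ratios).  Values follow pooled
# summaries of English accelerometer studies.
_OUTCOME_CALIBRATION = {
    "primary": {
        "mvpa_week": (54.3, 24.0 / 24.8),
        "sed_weekday": (418.3, -117.6 / 24.8),
        "sed_week": (406.4, -116.0 / 24.8),
    },
    "secondary": {
        "mvpa_week": (50.9, 26.1 / 28.1),
        "sed_weekday": (425.0, -96.0 / 28.1),
        "sed_week": (412.3, -91.0 / 28.1),
    },
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the multilevel generating model.

    Variance components are in minutes^2; ``cac`` and ``iac`` are the
    exchangeable correlations of the school and pupil effects across
    waves.  The within-study intra-cluster correlation implied by the
    config is ``var_school / (var_school + var_pupil + var_resid)``.
    """

    n_studies: int = 5
    schools_per_study: int = 40
    pupils_per_school: int = 25
    waves: tuple[float, ...] = (0.0,)
    phase: str = "primary"
    grand_mean: float = 55.8
    year_group_effects: Mapping[str, float] = field(
        default_factory=lambda: {"Y1&4": -2.0, "Y5": 0.5, "Y6": 1.5}
    )
    gender_effect: float = 9.0  # boys minus girls, minutes
    wear_time_mean: float = 760.0
    wear_time_sd: float = 60.0
    wear_time_slope: float = 0.0
    var_study: float = 54.5
    var_school: float = 43.06
    var_pupil: float = 277.2
    var_resid: float = 217.98
    cac: float = 0.6
    # chosen so the observable pupil wave-pair correlation (school and
    # gender persistence included) is 0.46 under the other defaults
    iac: float = 0.7605
    missing_rate: float = 0.08
    min_valid_days_distribution: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.05, 2: 0.10, 3: 0.15, 4: 0.30, 5: 0.40}
    )
    baseline_year_probs: Mapping[int, float] | None = None
    seed: int = 0

    # -- validation -------------------------------------------------
    def __post_init__(self):
        for name in ("n_studies", "schools_per_study", "pupils_per_school"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        for name in ("var_study", "var_school", "var_pupil", "var_resid"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("cac", "iac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        waves = tuple(float(w) for w in self.waves)
        if not waves or waves[0] != 0.0:
            raise ConfigurationError("waves must start at 0")
        if any(b <= a for a, b in zip(waves, waves[1:])):
            raise ConfigurationError("waves must be strictly increasing")
        object.__setattr__(self, "waves", waves)
        if self.phase not in ("primary", "secondary"):
            raise ConfigurationError("phase must be 'primary' or 'secondary'")
        probs = self.min_valid_days_distribution
        if abs(sum(probs.values()) - 1.0) > 1e-8 or any(p < 0 for p in probs.values()):
            raise ConfigurationError(
                "min_valid_days_distribution must be a probability distribution"
            )
        if self.wear_time_sd < 0:
            raise ConfigurationError("wear_time_sd must be >= 0")
        byp = self.baseline_year_probs
        if byp is not None:
            if abs(sum(byp.values()) - 1.0) > 1e-8 or any(p < 0 for p in byp.values()):
                raise ConfigurationError(
                    "baseline_year_probs must be a probability distribution"
                )

    # -- convenience constructors -----------------------------------
    @classmethod
    def primary_default(cls, **overrides) -> "SimulationConfig":
        """Calibration for English primary schools (weekday MVPA
        mean 55.8, marginal SD ~24.8, within-study SD 23.2, ICC 0.08,
        observable CAC 0.6 / pupil wave-pair correlation 0.46)."""
        return cls(**overrides)

    @classmethod
    def secondary_default(cls, **overrides) -> "SimulationConfig":
        """Calibration for English secondary schools (weekday MVPA
        mean 54.7, marginal SD ~28.1, within-study SD 27.5, ICC 0.05)."""
        params = dict(
            phase="secondary",
            grand_mean=54.7,
            year_group_effects={"Y7": -1.0, "Y8&9": 0.0, "Y10&11": 1.0},
            var_study=12.4,
            var_school=37.81,
            var_pupil=406.5,
            var_resid=311.94,
            iac=0.7731,
            pupils_per_school=50,
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from a YAML/JSON key-value file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
        raw = dict(raw)
        for key in ("min_valid_days_distribution", "baseline_year_probs"):
            if raw.get(key) is not None:
                raw[key] = {int(k): float(v) for k, v in raw[key].items()}
        if "waves" in raw:
            raw["waves"] = tuple(raw["waves"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["waves"] = list(self.waves)
        d["year_group_effects"] = dict(self.year_group_effects)
        d["min_valid_days_distribution"] = dict(self.min_valid_days_distribution)
        if self.baseline_year_probs is not None:
            d["baseline_year_probs"] = dict(self.baseline_year_probs)
        return d

    @property
    def total_variance(self) -> float:
        """Within-study total variance: school + pupil + residual."""
        return self.var_school + self.var_pupil + self.var_resid

    def _baseline_year_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        probs = self.baseline_year_probs
        if probs is None:
            probs = (
                {4: 0.4, 5: 0.35, 6: 0.25}
                if self.phase == "primary"
                else {7: 0.4, 8: 0.3, 9: 0.3}
            )
        years = np.array(sorted(probs), dtype=int)
        p = np.array([probs[y] for y in years], dtype=float)
        return years, p / p.sum()


# ---------------------------------------------------------------------
# closed-form moments (test oracles)
# ---------------------------------------------------------------------

def theoretical_moments(config: SimulationConfig) -> dict:
    """Closed-form moments of the generating model.

    Returns the within-study ICC, total (within-study) SD, and the
    configured school/pupil effect correlations.  Raises if all
    variance components are zero (the ICC is then undefined).
    """
    denom = config.total_variance
    if denom <= 0:
        raise ConfigurationError(
            "undefined ICC: var_school, var_pupil and var_resid are all zero"
        )
    return {
        "icc": config.var_school / denom,
        "total_sd": float(np.sqrt(denom)),
        "cac": config.cac,
        "iac": config.iac,
    }


def wave_pair_correlations(config: SimulationConfig, m: int | None = None) -> dict:
    """Closed-form between-wave Pearson correlations implied by the config.

    ``pupil``: correlation of one pupil's outcomes at two waves (school
    and gender persistence included), the estimand of the empirical IAC.
    ``school_mean``: correlation of observed school means of ``m``
    pupils at two waves — the CAC estimand, attenuated below ``cac`` by
    within-school sampling error when ``m`` is finite.

    The gender effect is a pupil-constant fixed effect (+/- half the
    effect), contributing persistent between-pupil variance
    ``gender_effect^2 / 4``.  The formulas assume complete data (the
    same pupils observed at both waves) and a common year-group
    trajectory; pass an effective ``m`` to approximate missingness.
    """
    c = config
    total = c.total_variance
    if total <= 0:
        raise ConfigurationError("undefined correlations: zero total variance")
    v_gender = c.gender_effect**2 / 4.0
    pupil = (c.cac * c.var_school + c.iac * c.var_pupil + v_gender) / (
        total + v_gender
    )
    if m is None:
        m = c.pupils_per_school
    school_num = c.cac * c.var_school + (c.iac * c.var_pupil + v_gender) / m
    school_den = c.var_school + (c.var_pupil + c.var_resid + v_gender) / m
    return {"pupil": pupil, "school_mean": school_num / school_den}


# ---------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------

def _exchangeable_effects(
    rng: np.random.Generator, n: int, n_waves: int, var: float, corr: float
) -> np.ndarray:
    """Draw (n, n_waves) effects, compound-symmetric across waves."""
    if var == 0:
        return np.zeros((n, n_waves))
    shared = rng.standard_normal((n, 1))
    unique = rng.standard_normal((n, n_waves))
    z = np.sqrt(corr) * shared + np.sqrt(1.0 - corr) * unique
    return np.sqrt(var) * z


def generate_population(config: SimulationConfig) -> pd.DataFrame:
    """Simulate one pooled multi-study observation table.

    Deterministic for a fixed config (seed included); identical configs
    yield bit-identical tables.  Missingness is applied completely at
    random per outcome cell at ``missing_rate``.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    n_waves = len(c.waves)
    n_sch = c.n_studies * c.schools_per_study
    n_pup = n_sch * c.pupils_per_school

    # unit-level structure
    study_of_school = np.repeat(np.arange(c.n_studies), c.schools_per_study)
    school_of_pupil = np.repeat(np.arange(n_sch), c.pupils_per_school)
    study_of_pupil = study_of_school[school_of_pupil]

    years, probs = c._baseline_year_distribution()
    baseline_year = rng.choice(years, size=n_pup, p=probs)
    gender = np.where(rng.random(n_pup) < 0.5, "F", "M")

    # secondary destination pool (only used by pupils crossing Y6->Y7)
    n_dest = max(1, c.schools_per_study // 2)
    dest_of_pupil = rng.integers(0, n_dest, size=n_pup)

    # random effects
    study_eff = rng.normal(0.0, np.sqrt(c.var_study), c.n_studies)
    school_eff = _exchangeable_effects(rng, n_sch, n_waves, c.var_school, c.cac)
    dest_eff = _exchangeable_effects(
        rng, c.n_studies * n_dest, n_waves, c.var_school, c.cac
    )
    pupil_eff = _exchangeable_effects(rng, n_pup, n_waves, c.var_pupil, c.iac)

    yg_effect = {g: float(c.year_group_effects.get(g, 0.0)) for g in YEAR_GROUPS}
    cal = _OUTCOME_CALIBRATION[c.phase]

    frames = []
    for w, offset in enumerate(c.waves):
        current_year = np.minimum(baseline_year + int(np.floor(offset)), 11)
        band = np.array([year_to_band(y) for y in current_year])
        in_secondary = current_year >= 7
        crossed = in_secondary & (baseline_year <= 6)

        sch_eff_w = np.where(
            crossed,
            dest_eff[study_of_pupil * n_dest + dest_of_pupil, w],
            school_eff[school_of_pupil, w],
        )
        wear = np.clip(
            rng.normal(c.wear_time_mean, c.wear_time_sd, n_pup), 0.0, None
        )
        resid = rng.normal(0.0, np.sqrt(c.var_resid), n_pup)

        fixed = (
            c.grand_mean
            + np.vectorize(yg_effect.get)(band).astype(float)
            + np.where(gender == "M", 0.5, -0.5) * c.gender_effect
            + c.wear_time_slope * (wear - c.wear_time_mean)
        )
        dev = study_eff[study_of_pupil] + sch_eff_w + pupil_eff[:, w] + resid
        mvpa_weekday = np.clip(fixed + dev, 0.0, None)

        school_id = np.array(
            [
                f"s{s}_sec{d}" if x else f"s{s}_sch{k}"
                for s, k, d, x in zip(
                    study_of_pupil, school_of_pupil, dest_of_pupil, crossed
                )
            ]
        )

        frame = pd.DataFrame(
            {
                "study_id": [f"s{s}" for s in study_of_pupil],
                "school_id": school_id,
                "school_phase": np.where(in_secondary, "secondary", "primary"),
                "pupil_id": [
                    f"s{s}_sch{k}_p{p}"
                    for s, k, p in zip(study_of_pupil, school_of_pupil, range(n_pup))
                ],
                "wave_index": w,
                "years_since_baseline": float(offset),
                "year_group": band,
                "gender": gender,
                "wear_min": wear,
                "valid_days": rng.choice(
                    sorted(c.min_valid_days_distribution),
                    size=n_pup,
                    p=np.array(
                        [
                            c.min_valid_days_distribution[k]
                            for k in sorted(c.min_valid_days_distribution)
                        ]
                    ),
                ),
                "mvpa_weekday": mvpa_weekday,
            }
        )
        # secondary outcomes: affine transforms of the weekday-MVPA
        # deviation from its phase mean (sedentary negatively signed)
        deviation = frame["mvpa_weekday"] - c.grand_mean
        for name, (mean_o, ratio) in cal.items():
            frame[name] = np.clip(mean_o + ratio * deviation, 0.0, None)
        frames.append(frame)

    data = pd.concat(frames, ignore_index=True)
    # MCAR missingness, independently per outcome cell
    if c.missing_rate > 0:
        mask = rng.random((len(data), len(OUTCOME_COLUMNS))) < c.missing_rate
        for j, name in enumerate(OUTCOME_COLUMNS):
            data.loc[mask[:, j], name] = np.nan
    return data[OBSERVATION_COLUMNS]


# ---------------------------------------------------------------------
# inclusion filter and IO
# ---------------------------------------------------------------------

def filter_valid(
    data: pd.DataFrame, min_valid_days: int = 2
) -> tuple[pd.DataFrame, int]:
    """Keep rows with at least ``min_valid_days`` valid wear days.

    Returns the filtered table (row order preserved) and the number of
    rows removed, for logging.
    """
    if "valid_days" not in data.columns:
        raise ConfigurationError("filter_valid requires a valid_days column")
    keep = data["valid_days"] >= min_valid_days
    return data.loc[keep].copy(), int((~keep).sum())


def write_observations(data: pd.DataFrame, path: str | Path) -> None:
    """Write the observation CSV dialect (missing cells empty)."""
    data[OBSERVATION_COLUMNS].to_csv(path, index=False)


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read an observation CSV written by :func:`write_observations`."""
    data = pd.read_csv(
        path,
        dtype={
            "study_id": str,
            "school_id": str,
            "school_phase": str,
            "pupil_id": str,
            "year_group": str,
            "gender": str,
        },
    )
    missing = set(OBSERVATION_COLUMNS) - set(data.columns)
    if missing:
        raise ConfigurationError(f"observation CSV missing column(s): {sorted(missing)}")
    return data[OBSERVATION_COLUMNS]
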