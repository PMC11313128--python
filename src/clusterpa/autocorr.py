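"""Cluster and individual autocorrelations with meta-analytic pooling.

The cluster autocorrelation (CAC) is the Pearson correlation of school
mean outcomes between two measurement waves, computed within each
study and restricted to schools whose identity is unchanged (pupils who
move across the primary/secondary transition carry their data to a new
school id and therefore drop out of the CAC pairs).  The individual
autocorrelation (IAC) is the Pearson correlation of pupils' outcomes
between two waves, school changes allowed.

Per-study, per-wave-pair correlations are Fisher z-transformed
(variance 1/(n-3)), pooled by inverse-variance meta-analysis
(DerSimonian-Laird random effects by default, fixed effect available)
within follow-up-length bins, and back-transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import InsufficientDataError

__all__ = [
    "CorrelationRecord",
    "PooledCorrelation",
    "school_period_means",
    "empirical_cac",
    "empirical_iac",
    "correlation_records",
    "fisher_z",
    "fisher_z_inverse",
    "pool_correlations",
    "pooled_table",
]

MIN_UNITS = 4  # Fisher variance 1/(n-3) needs n >= 4


@dataclass(frozen=True)
class CorrelationRecord:
    """One empirical correlation for a study / wave-pair combination."""

    study_id: str
    level: str  # "school" or "pupil"
    follow_up: float  # years between the two waves
    r: float
    n_units: int

    def __post_init__(self):
        if self.n_units < MIN_UNITS:
            raise InsufficientDataError(
                f"n_units={self.n_units} < {MIN_UNITS}: Fisher variance undefined"
            )
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("correlation outside [-1, 1]")


@dataclass(frozen=True)
class PooledCorrelation:
    """Meta-analytically pooled correlation for one follow-up bin."""

    level: str
    follow_up_bin: str
    r: float
    ci_low: float
    ci_high: float
    k_records: int
    tau2: float  # between-record heterogeneity on the z scale
    q_stat: float


def fisher_z(r):
    """Fisher transformation arctanh(r); domain |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("Fisher transformation requires |r| < 1")
    return np.arctanh(r)


def fisher_z_inverse(z):
    """Back-transform tanh(z)."""
    return np.tanh(np.asarray(z, dtype=float))


def school_period_means(
    data: pd.DataFrame,
    wave_pair: tuple[int, int],
    outcome: str = "mvpa_weekday",
    min_pupils: int = 5,
) -> tuple[pd.DataFrame, int]:
    """Per-school outcome-mean pairs for two waves.

    A school contributes only if at least ``min_pupils`` pupils have a
    non-missing outcome at *each* of the two waves and the school id is
    present at both (same-school rule).  Returns the pairs and the
    number of schools dropped by the pupil-count filter.
    """
    w0, w1 = wave_pair
    d = data.dropna(subset=[outcome])
    d = d[d["wave_index"].isin([w0, w1])]
    g = d.groupby(["school_id", "wave_index"])[outcome].agg(["mean", "size"])
    wide = g.unstack("wave_index")
    if ("mean", w0) not in wide.columns or ("mean", w1) not in wide.columns:
        return pd.DataFrame(columns=["school_id", "mean_0", "mean_1"]), 0
    present = wide[("size", w0)].notna() & wide[("size", w1)].notna()
    enough = (
        (wide[("size", w0)].fillna(0) >= min_pupils)
        & (wide[("size", w1)].fillna(0) >= min_pupils)
    )
    n_dropped = int((present & ~enough).sum())
    kept = wide[present & enough]
    pairs = pd.DataFrame(
        {
            "school_id": kept.index,
            "mean_0": kept[("mean", w0)].to_numpy(),
            "mean_1": kept[("mean", w1)].to_numpy(),
            "n_0": kept[("size", w0)].to_numpy(int),
            "n_1": kept[("size", w1)].to_numpy(int),
        }
    ).reset_index(drop=True)
    return pairs, n_dropped


def _follow_up_years(data: pd.DataFrame, wave_pair) -> float:
    by_wave = data.groupby("wave_index")["years_since_baseline"].first()
    return float(by_wave[wave_pair[1]] - by_wave[wave_pair[0]])


def empirical_cac(
    data: pd.DataFrame,
    study: str,
    wave_pair: tuple[int, int],
    outcome: str = "mvpa_weekday",
    min_pupils: int = 5,
) -> CorrelationRecord:
    """Cluster autocorrelation: correlation of same-school mean pairs."""
    d = data[data["study_id"] == study]
    pairs, _ = school_period_means(d, wave_pair, outcome, min_pupils)
    if len(pairs) < MIN_UNITS:
        raise InsufficientDataError(
            f"study {study!r}, waves {wave_pair}: only {len(pairs)} qualifying "
            f"schools (>= {MIN_UNITS} required)"
        )
    r, _ = stats.pearsonr(pairs["mean_0"], pairs["mean_1"])
    return CorrelationRecord(
        study_id=study,
        level="school",
        follow_up=_follow_up_years(d, wave_pair),
        r=float(r),
        n_units=len(pairs),
    )


def empirical_iac(
    data: pd.DataFrame,
    study: str,
    wave_pair: tuple[int, int],
    outcome: str = "mvpa_weekday",
) -> CorrelationRecord:
    """Individual autocorrelation: correlation over pupils of their two
    outcome values; pupils who changed school are retained."""
    w0, w1 = wave_pair
    d = data[data["study_id"] == study].dropna(subset=[outcome])
    wide = (
        d[d["wave_index"].isin([w0, w1])]
        .pivot_table(index="pupil_id", columns="wave_index", values=outcome)
        .dropna()
    )
    if len(wide) < MIN_UNITS or w0 not in wide.columns or w1 not in wide.columns:
        raise InsufficientDataError(
            f"study {study!r}, waves {wave_pair}: fewer than {MIN_UNITS} pupils "
            "with both measurements"
        )
    r, _ = stats.pearsonr(wide[w0], wide[w1])
    return CorrelationRecord(
        study_id=study,
        level="pupil",
        follow_up=_follow_up_years(d, wave_pair),
        r=float(r),
        n_units=len(wide),
    )


def correlation_records(
    data: pd.DataFrame,
    outcome: str = "mvpa_weekday",
    min_pupils: int = 5,
) -> list[CorrelationRecord]:
    """All school- and pupil-level correlation records over every wave
    pair within every study (one record per study/follow-up
    combination); combinations with too little data are skipped."""
    records: list[CorrelationRecord] = []
    for study, d in data.groupby("study_id"):
        waves = sorted(d["wave_index"].unique())
        for i, w0 in enumerate(waves):
            for w1 in waves[i + 1 :]:
                try:
                    records.append(
                        empirical_cac(d, study, (w0, w1), outcome, min_pupils)
                    )
                except InsufficientDataError:
                    pass
                try:
                    records.append(empirical_iac(d, study, (w0, w1), outcome))
                except InsufficientDataError:
                    pass
    return records


def _pool_z(
    z: np.ndarray, var: np.ndarray, method: str
) -> tuple[float, float, float, float]:
    """Inverse-variance pooling on the z scale.

    DerSimonian-Laird: Q = sum w (z - zbar_fe)^2 with fixed-effect
    weights w = 1/var; tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)),
    then re-weight by 1/(var + tau^2).
    """
    w = 1.0 / var
    sw = w.sum()
    zbar_fe = float(w @ z / sw)
    q_stat = float(w @ (z - zbar_fe) ** 2)
    k = len(z)
    if method == "fixed" or k == 1:
        return zbar_fe, float(np.sqrt(1.0 / sw)), 0.0, (q_stat if k > 1 else 0.0)
    denom = sw - float(w @ w) / sw
    tau2 = max(0.0, (q_stat - (k - 1)) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (var + tau2)
    mean_z = float(w_re @ z / w_re.sum())
    return mean_z, float(np.sqrt(1.0 / w_re.sum())), tau2, q_stat


def _bin_label(follow_up: float) -> str:
    if follow_up < 1.0:
        return "<1"
    return str(int(round(follow_up)))


def pool_correlations(
    records: list[CorrelationRecord],
    bin_by_followup: bool = False,
    method: str = "dl",
    level: float = 0.95,
) -> list[PooledCorrelation]:
    """Pool correlation records on the Fisher z scale.

    Inverse-variance weights with variance 1/(n-3); ``method="dl"``
    gives DerSimonian-Laird random-effects pooling (tau^2 floored at 0),
    ``method="fixed"`` fixed-effect pooling.  When ``bin_by_followup``,
    records are pooled within integer-year bins, with follow-ups under
    one year kept in a separate "<1" bin; otherwise all records of a
    level are pooled together ("all" bin).
    """
    if method not in ("dl", "fixed"):
        raise ValueError("method must be 'dl' or 'fixed'")
    out: list[PooledCorrelation] = []
    z_crit = stats.norm.ppf(0.5 + level / 2.0)
    groups: dict[tuple[str, str], list[CorrelationRecord]] = {}
    for rec in records:
        key = (rec.level, _bin_label(rec.follow_up) if bin_by_followup else "all")
        groups.setdefault(key, []).append(rec)
    for (lvl, label), recs in sorted(groups.items()):
        z = fisher_z([r.r for r in recs])
        var = 1.0 / (np.array([r.n_units for r in recs]) - 3.0)
        mean_z, se_z, tau2, q_stat = _pool_z(z, var, method)
        out.append(
            PooledCorrelation(
                level=lvl,
                follow_up_bin=label,
                r=float(fisher_z_inverse(mean_z)),
                ci_low=float(fisher_z_inverse(mean_z - z_crit * se_z)),
                ci_high=float(fisher_z_inverse(mean_z + z_crit * se_z)),
                k_records=len(recs),
                tau2=tau2,
                q_stat=q_stat,
            )
        )
        if not recs:
            warnings.warn(f"empty bin {label!r} omitted", stacklevel=2)
    return out


def pooled_table(pooled: list[PooledCorrelation]) -> pd.DataFrame:
    """Tabulate pooled correlations (CSV layout: one row per bin)."""
    return pd.DataFrame(
        [
            {
                "level": p.level,
                "follow_up_bin": p.follow_up_bin,
                "r": p.r,
                "ci_low": p.ci_low,
                "ci_high": p.ci_high,
                "k_records": p.k_records,
                "tau2": p.tau2,
                "Q": p.q_stat,
            }
            for p in pooled
        ]
    )
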