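"""School-level intra-cluster correlation coefficients.

Estimates variance components from a three-level mixed model
(study / school / pupil, with residual within-pupil variation) and
converts them to per-year-group ICCs with delta-method confidence
intervals on the logit scale.

The ICC reported is the *within-study* school proportion,

    rho_g = var_school_g / (var_school_g + var_pupil + var_resid),

i.e. the study-level variance is excluded from the denominator, because
a trial is run within a single study context; pass
``include_study=True`` to include it.  School variances may be modelled
separately per school year group (independent random coefficients).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from ._errors import (
    BoundaryICCError,
    EstimationError,
    UndefinedICCError,
)
from .reml import RemlResult, fit_reml

__all__ = [
    "VarianceComponents",
    "ICCEstimate",
    "fit_variance_components",
    "icc_from_components",
    "logit_delta_ci",
    "estimate_iccs",
    "baseline_adjusted_icc",
    "icc_table",
]

POOLED_KEY = "all"


@dataclass
class VarianceComponents:
    """REML variance components of the three-level model (minutes^2)."""

    var_study: float
    var_school_by_yeargroup: dict[str, float]
    var_pupil: float
    var_resid: float
    vcov: pd.DataFrame  # named covariance of the variance estimates
    n_schools: int
    n_pupils: int
    n_obs: int
    converged: bool
    reml: RemlResult | None = field(default=None, repr=False)

    @property
    def total_within_study(self) -> dict[str, float]:
        """School + pupil + residual variance, per year group."""
        base = self.var_pupil + self.var_resid
        return {g: v + base for g, v in self.var_school_by_yeargroup.items()}


@dataclass
class ICCEstimate:
    """One ICC with its delta-method logit-scale confidence interval."""

    year_group: str
    stratum: str
    outcome: str
    icc: float
    se_icc: float
    ci_low: float
    ci_high: float
    adjusted_for_baseline: bool = False
    sd_total: float | None = None
    n_schools: int | None = None


def _build_design(
    data: pd.DataFrame, fixed: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(data))]
    names = ["intercept"]
    if "year_group" in fixed:
        levels = sorted(data["year_group"].dropna().unique())
        for lev in levels[1:]:
            cols.append((data["year_group"] == lev).to_numpy(float))
            names.append(f"year_group[{lev}]")
    if "wear_min" in fixed:
        wear = data["wear_min"].to_numpy(float)
        cols.append(wear - np.nanmean(wear))  # centred at sample mean
        names.append("wear_min_centred")
    for name in fixed:
        if name in ("year_group", "wear_min"):
            continue
        x = data[name].to_numpy(float)
        cols.append(x - np.nanmean(x))
        names.append(name)
    return np.column_stack(cols), names


def fit_variance_components(
    data: pd.DataFrame,
    outcome: str = "mvpa_weekday",
    fixed: tuple[str, ...] = ("year_group", "wear_min"),
    by_yeargroup: bool = False,
    compute_vcov: bool = True,
) -> VarianceComponents:
    """REML fit of the three-level variance-component model.

    Random intercepts: study (when more than one study is present),
    school (one variance per year group when ``by_yeargroup``), and
    pupil (when any pupil contributes repeated rows).  Fixed effects
    default to year-group (age) and centred accelerometer wear time.
    """
    d = data.dropna(subset=[outcome] + [c for c in fixed if c != "year_group"])
    d = d.reset_index(drop=True)
    if len(d) < 10:
        raise EstimationError(f"fewer than 10 non-missing rows for {outcome!r}")
    n_schools = d["school_id"].nunique()
    if n_schools < 2:
        raise EstimationError("at least 2 schools are required")

    components: dict[str, np.ndarray] = {}
    n_studies = d["study_id"].nunique()
    if n_studies > 1:
        components["study"] = pd.factorize(d["study_id"])[0]
    else:
        warnings.warn(
            "single study: study-level variance not estimable, reported as 0",
            stacklevel=2,
        )
    school_codes = pd.factorize(d["school_id"])[0]
    year_groups = sorted(d["year_group"].dropna().unique())
    if by_yeargroup and len(year_groups) > 1:
        for g in year_groups:
            codes = np.where(d["year_group"] == g, school_codes, -1)
            components[f"school[{g}]"] = codes
    else:
        components["school"] = school_codes
    pupil_codes = pd.factorize(d["pupil_id"])[0]
    has_repeats = np.bincount(pupil_codes).max() > 1
    if has_repeats:
        components["pupil"] = pupil_codes

    X, fixed_names = _build_design(d, fixed)
    y = d[outcome].to_numpy(float)
    res = fit_reml(y, X, components, fixed_names, compute_vcov=compute_vcov)

    by_yg = {}
    for name, v in zip(res.component_names, res.variances):
        if name.startswith("school[") and name.endswith("]"):
            by_yg[name[len("school["):-1]] = float(v)
        elif name == "school":
            by_yg[POOLED_KEY] = float(v)
    if res.vcov is not None:
        vcov = pd.DataFrame(
            res.vcov, index=res.component_names, columns=res.component_names
        )
    else:
        k = len(res.component_names)
        vcov = pd.DataFrame(
            np.full((k, k), np.nan),
            index=res.component_names,
            columns=res.component_names,
        )
    return VarianceComponents(
        var_study=res.variance("study") if "study" in res.component_names else 0.0,
        var_school_by_yeargroup=by_yg,
        var_pupil=res.variance("pupil") if "pupil" in res.component_names else 0.0,
        var_resid=res.variance("resid"),
        vcov=vcov,
        n_schools=int(n_schools),
        n_pupils=int(d["pupil_id"].nunique()),
        n_obs=len(d),
        converged=res.converged,
        reml=res,
    )


def logit_delta_ci(
    icc: float, se_icc: float, level: float = 0.95
) -> tuple[float, float]:
    """Delta-method confidence interval for an ICC on the logit scale.

    The standard error is mapped to the logit scale as
    ``se_icc / (icc * (1 - icc))``, a symmetric normal interval is
    formed there and back-transformed, guaranteeing endpoints in (0, 1).
    A zero standard error collapses the interval to the point estimate.
    """
    if se_icc < 0:
        raise ValueError("se_icc must be >= 0")
    if se_icc == 0:
        return (icc, icc)
    if not 0.0 < icc < 1.0:
        raise BoundaryICCError(
            "ICC on the boundary of [0, 1]: a two-sided logit interval is "
            "undefined; use a one-sided bound instead"
        )
    z = stats.norm.ppf(0.5 + level / 2.0)
    se_logit = se_icc / (icc * (1.0 - icc))
    lo = float(expit(logit(icc) - z * se_logit))
    hi = float(expit(logit(icc) + z * se_logit))
    return lo, hi


def _one_sided_band(icc: float, se_icc: float, level: float) -> tuple[float, float]:
    """Interval for a boundary (0 or 1) ICC estimate."""
    z1 = stats.norm.ppf(level)
    half = z1 * se_icc
    if icc <= 0.0:
        return 0.0, float(min(1.0, half))
    return float(max(0.0, 1.0 - half)), 1.0


def icc_from_components(
    vc: VarianceComponents,
    year_group: str | None = None,
    outcome: str = "mvpa_weekday",
    stratum: str = "all",
    include_study: bool = False,
    level: float = 0.95,
) -> ICCEstimate:
    """ICC (with CI) for one year group from fitted variance components.

    ``include_study=False`` (default) uses the within-study denominator
    school + pupil + residual.
    """
    by_yg = vc.var_school_by_yeargroup
    if year_group is None:
        if len(by_yg) != 1:
            raise EstimationError(
                "year_group must be given when school variances are "
                "year-group specific"
            )
        year_group = next(iter(by_yg))
    if year_group not in by_yg:
        raise EstimationError(f"no school variance for year group {year_group!r}")
    s = by_yg[year_group]
    comp_name = (
        "school" if year_group == POOLED_KEY else f"school[{year_group}]"
    )

    den_parts = {comp_name: s, "pupil": vc.var_pupil, "resid": vc.var_resid}
    if include_study:
        den_parts["study"] = vc.var_study
    den = sum(den_parts.values())
    if den <= 0:
        raise UndefinedICCError("undefined ICC: zero total variance")
    icc = s / den

    # delta method on the ratio of components
    names = [n for n in den_parts if n in vc.vcov.index]
    grad = np.array(
        [((den - s) if n == comp_name else -s) / den**2 for n in names]
    )
    sub = vc.vcov.loc[names, names].to_numpy()
    var_icc = float(grad @ sub @ grad) if np.all(np.isfinite(sub)) else np.nan
    se = float(np.sqrt(max(var_icc, 0.0))) if np.isfinite(var_icc) else np.nan

    if 0.0 < icc < 1.0 and se > 0:
        lo, hi = logit_delta_ci(icc, se, level)
    elif se >= 0:
        lo, hi = _one_sided_band(icc, se, level)
    else:  # se unavailable
        lo = hi = icc
    return ICCEstimate(
        year_group=year_group,
        stratum=stratum,
        outcome=outcome,
        icc=float(icc),
        se_icc=se,
        ci_low=lo,
        ci_high=hi,
        sd_total=float(np.sqrt(s + vc.var_pupil + vc.var_resid)),
        n_schools=vc.n_schools,
    )


def estimate_iccs(
    data: pd.DataFrame,
    outcome: str = "mvpa_weekday",
    stratify_by_gender: bool = False,
    fixed: tuple[str, ...] = ("year_group", "wear_min"),
    include_study: bool = False,
    by_yeargroup: bool = True,
) -> list[ICCEstimate]:
    """Per-year-group ICCs, optionally stratified by gender.

    Strata with fewer than two schools are skipped with a warning.
    """
    strata = (
        [("girls", data[data["gender"] == "F"]), ("boys", data[data["gender"] == "M"])]
        if stratify_by_gender
        else [("all", data)]
    )
    out: list[ICCEstimate] = []
    for label, d in strata:
        if d["school_id"].nunique() < 2:
            warnings.warn(f"stratum {label!r} has < 2 schools; skipped", stacklevel=2)
            continue
        vc = fit_variance_components(
            d, outcome=outcome, fixed=fixed, by_yeargroup=by_yeargroup
        )
        for g in sorted(vc.var_school_by_yeargroup):
            out.append(
                icc_from_components(
                    vc, g, outcome=outcome, stratum=label, include_study=include_study
                )
            )
    return out


def baseline_adjusted_icc(
    data: pd.DataFrame,
    outcome: str = "mvpa_weekday",
    fixed: tuple[str, ...] = ("year_group", "wear_min"),
    include_study: bool = False,
) -> ICCEstimate:
    """ICC adjusted for the pupil's previous measurement.

    Refits the model on follow-up observations only, adding each
    pupil's most recent previous outcome value as a fixed covariate.
    The returned estimate carries the baseline-adjusted total SD in
    ``sd_total`` (needed for baseline-adjusted trial sizing).
    """
    d = data.dropna(subset=[outcome]).sort_values(["pupil_id", "wave_index"])
    prev = d.groupby("pupil_id")[outcome].shift(1)
    d = d.assign(baseline=prev).dropna(subset=["baseline"])
    if len(d) < 10:
        raise EstimationError(
            "baseline adjustment needs repeated measures on the same pupils"
        )
    vc = fit_variance_components(
        d,
        outcome=outcome,
        fixed=tuple(fixed) + ("baseline",),
        by_yeargroup=False,
    )
    est = icc_from_components(vc, outcome=outcome, include_study=include_study)
    est.adjusted_for_baseline = True
    return est


def icc_table(estimates: list[ICCEstimate]) -> pd.DataFrame:
    """Tabulate ICC estimates (one row per year group x stratum x outcome)."""
    return pd.DataFrame(
        [
            {
                "year_group": e.year_group,
                "stratum": e.stratum,
                "outcome": e.outcome,
                "adjusted_for_baseline": e.adjusted_for_baseline,
                "icc": e.icc,
                "se_icc": e.se_icc,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "sd_total": e.sd_total,
                "n_schools": e.n_schools,
            }
            for e in estimates
        ]
    )
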