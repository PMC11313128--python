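"""Sample size and power for school-based cluster trial designs.

Implements six designs on a common cluster-period variance
decomposition governed by the intra-cluster correlation rho (ICC), the
cluster autocorrelation pi (CAC) and the individual autocorrelation
tau (IAC):

* two-arm parallel cluster RCT (``crct``);
* cluster RCT analysed with baseline adjustment / ANCOVA
  (``crct_baseline_adjusted``) — same algorithm on baseline-adjusted
  sigma and rho supplied by the caller;
* cross-sectional and closed-cohort stepped wedge designs
  (``sw_cross_sectional``, ``sw_cohort``) with S steps, T = S + 1
  periods, an all-control first period and equal sequence allocation.

The parallel designs use the iterative t-correction (critical values
from the t distribution with 2(k-1) degrees of freedom, where the df
depend on the cluster count being solved for); the stepped wedge uses
the closed-form generalized-least-squares treatment variance of the
exchangeable cluster-period-mean model with normal critical values.
Both follow the behaviour of standard cluster-power software.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import AllocationError, InfeasibleDesignError

__all__ = [
    "DesignSpec",
    "SampleSizeResult",
    "design_effect_crct",
    "required_schools_crct",
    "required_schools_ancova",
    "cluster_period_variances",
    "hh_treatment_variance",
    "required_schools_sw",
    "required_schools",
    "achieved_power",
    "planning_table",
    "default_planning_grid",
]

DESIGNS = ("crct", "crct_baseline_adjusted", "sw_cross_sectional", "sw_cohort")
_MAX_CLUSTERS = 100_000


@dataclass(frozen=True)
class DesignSpec:
    """Inputs of one sample-size calculation.

    delta: target difference in mean minutes; sd_total: total SD of the
    outcome (within-study); m: pupils per school per period.  ``cac``
    and ``iac`` are only used by the stepped wedge designs (``iac``
    only when the cohort is closed).
    """

    design: str
    delta: float
    sd_total: float
    icc: float
    m: int
    cac: float = 1.0
    iac: float = 0.0
    steps: int = 2
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self):
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}")
        if self.delta < 0:
            raise ValueError("delta must be >= 0 (0 only for power evaluation)")
        if self.sd_total <= 0:
            raise ValueError("sd_total must be > 0")
        if not 0.0 <= self.icc < 1.0:
            raise ValueError("icc must lie in [0, 1)")
        if not 0.0 <= self.cac <= 1.0:
            raise ValueError("cac must lie in [0, 1]")
        if not 0.0 <= self.iac <= 1.0:
            raise ValueError("iac must lie in [0, 1]")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.steps < 2:
            raise ValueError("steps must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must lie in (0, 1)")


@dataclass(frozen=True)
class SampleSizeResult:
    """Smallest admissible school count reaching the target power."""

    total_schools: int
    allocation: tuple[int, ...]  # schools per arm / per sequence
    achieved_power: float
    design_effect: float | None = None  # parallel designs
    treatment_variance: float | None = None  # stepped wedge


# ---------------------------------------------------------------------
# parallel-arm cluster RCT
# ---------------------------------------------------------------------

def design_effect_crct(m: int, icc: float) -> float:
    """Classical design effect 1 + (m - 1) * rho for equal clusters."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 <= icc < 1.0:
        raise ValueError("icc must lie in [0, 1)")
    return 1.0 + (m - 1) * icc


def _crct_power(
    delta: float, sd_total: float, icc: float, m: int, k_per_arm: int, alpha: float
) -> float:
    """Two-sided power of the cluster-level t test with k clusters per
    arm (df = 2(k-1)); the negligible wrong-tail mass is ignored."""
    de = design_effect_crct(m, icc)
    se = np.sqrt(2.0 * sd_total**2 * de / (k_per_arm * m))
    df = 2 * (k_per_arm - 1)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - stats.nct.cdf(t_crit, df, delta / se))


def required_schools_crct(spec: DesignSpec) -> SampleSizeResult:
    """Two-arm cluster RCT sizing with the iterative t-correction.

    Finds the smallest per-arm cluster count k such that the t test
    with 2(k-1) degrees of freedom reaches the target power; the df
    depend on k, hence the iteration.
    """
    if spec.design not in ("crct", "crct_baseline_adjusted"):
        raise ValueError("spec.design must be a parallel cluster RCT")
    if spec.delta == 0:
        raise InfeasibleDesignError("delta = 0: no finite size reaches the power")
    k = 2
    while True:
        power = _crct_power(
            spec.delta, spec.sd_total, spec.icc, spec.m, k, spec.alpha
        )
        if power >= spec.power:
            break
        k += 1
        if 2 * k > _MAX_CLUSTERS:
            raise InfeasibleDesignError("no feasible cluster RCT size found")
    return SampleSizeResult(
        total_schools=2 * k,
        allocation=(k, k),
        achieved_power=power,
        design_effect=design_effect_crct(spec.m, spec.icc),
    )


def required_schools_ancova(spec: DesignSpec) -> SampleSizeResult:
    """Baseline-adjusted cluster RCT sizing.

    Identical algorithm to :func:`required_schools_crct`; the caller
    supplies the *baseline-adjusted* total SD and ICC (for instance
    from :func:`clusterpa.icc.baseline_adjusted_icc`), which is what
    makes the adjusted design cheaper.
    """
    if spec.design != "crct_baseline_adjusted":
        raise ValueError("spec.design must be 'crct_baseline_adjusted'")
    return required_schools_crct(spec)


# ---------------------------------------------------------------------
# stepped wedge
# ---------------------------------------------------------------------

def cluster_period_variances(
    sd_total: float,
    icc: float,
    cac: float,
    iac: float,
    m: int,
    cohort: bool,
) -> tuple[float, float]:
    """Decompose the cluster-period mean variance into a component
    shared across all periods and an independent per-period component.

    With sigma^2 = sd_total^2, a school's period mean of m pupils has
    variance rho sigma^2 + (1-rho) sigma^2 / m.  The school-effect part
    splits by the CAC into a persistent share pi rho sigma^2 and a
    period-specific share (1-pi) rho sigma^2; in a closed cohort the
    pupil part additionally persists with the IAC.  Setting pi = 1
    (cross-sectional) recovers the classical exchangeable model.
    """
    s2 = sd_total**2
    v_between = cac * icc * s2
    v_within = (1.0 - cac) * icc * s2
    pupil = (1.0 - icc) * s2 / m
    if cohort:
        v_between += iac * pupil
        v_within += (1.0 - iac) * pupil
    else:
        v_within += pupil
    return v_between, v_within


def _sw_design_matrix(n_schools: int, steps: int) -> np.ndarray:
    """Treatment indicators X (I x T) of the complete stepped wedge:
    T = steps + 1 periods, all-control first period, sequence s crosses
    over at period s."""
    if n_schools % steps != 0:
        raise AllocationError(
            f"{n_schools} schools not divisible by {steps} sequences"
        )
    per_seq = n_schools // steps
    T = steps + 1
    X = np.zeros((n_schools, T))
    for s in range(steps):
        X[s * per_seq : (s + 1) * per_seq, s + 1 :] = 1.0
    return X


def hh_treatment_variance(
    n_schools: int, steps: int, v_between: float, v_within_period: float
) -> float:
    """Closed-form GLS variance of the treatment effect for the
    complete stepped wedge under the exchangeable cluster-period-mean
    model (period fixed effects included).

    With I schools, T periods, indicator sums U = sum X,
    W = sum_t (sum_i X_it)^2 and V = sum_i (sum_t X_it)^2:

        var = I v_w (v_w + T v_b) /
              [ (I U - W) v_w + (U^2 + I T U - T W - I V) v_b ]
    """
    X = _sw_design_matrix(n_schools, steps)
    I, T = X.shape
    vb, vw = v_between, v_within_period
    U = X.sum()
    W = (X.sum(axis=0) ** 2).sum()
    V = (X.sum(axis=1) ** 2).sum()
    denom = (I * U - W) * vw + (U**2 + I * T * U - T * W - I * V) * vb
    if denom <= 0:
        raise InfeasibleDesignError(
            "degenerate stepped wedge: treatment effect not identifiable"
        )
    return float(I * vw * (vw + T * vb) / denom)


def _sw_power(spec: DesignSpec, n_schools: int) -> float:
    cohort = spec.design == "sw_cohort"
    vb, vw = cluster_period_variances(
        spec.sd_total, spec.icc, spec.cac, spec.iac, spec.m, cohort
    )
    var = hh_treatment_variance(n_schools, spec.steps, vb, vw)
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.cdf(spec.delta / np.sqrt(var) - z_crit))


def required_schools_sw(spec: DesignSpec) -> SampleSizeResult:
    """Smallest school total (multiple of the number of steps) whose
    normal-approximation stepped wedge power reaches the target.

    The acceptance rule is non-strict (power >= target), which decides
    near-ties at cell boundaries.
    """
    if spec.design not in ("sw_cross_sectional", "sw_cohort"):
        raise ValueError("spec.design must be a stepped wedge design")
    if spec.delta == 0:
        raise InfeasibleDesignError("delta = 0: no finite size reaches the power")
    n = spec.steps
    while True:
        power = _sw_power(spec, n)
        if power >= spec.power:
            break
        n += spec.steps
        if n > _MAX_CLUSTERS:
            raise InfeasibleDesignError("no feasible stepped wedge size found")
    cohort = spec.design == "sw_cohort"
    vb, vw = cluster_period_variances(
        spec.sd_total, spec.icc, spec.cac, spec.iac, spec.m, cohort
    )
    return SampleSizeResult(
        total_schools=n,
        allocation=(n // spec.steps,) * spec.steps,
        achieved_power=power,
        treatment_variance=hh_treatment_variance(n, spec.steps, vb, vw),
    )


# ---------------------------------------------------------------------
# dispatch, power evaluation, planning grids
# ---------------------------------------------------------------------

def required_schools(spec: DesignSpec) -> SampleSizeResult:
    """Dispatch to the calculator for ``spec.design``."""
    if spec.design in ("crct", "crct_baseline_adjusted"):
        return required_schools_crct(spec)
    return required_schools_sw(spec)


def achieved_power(
    spec: DesignSpec, total_schools: int, true_icc: float | None = None
) -> float:
    """Power of a design with a given school total, optionally under a
    true ICC different from the one used for planning (mis-specified
    sizing).  Parallel designs use the t test with df = 2(k-1); the
    stepped wedge uses the normal approximation.  delta = 0 returns
    alpha (the two-sided type I error)."""
    eval_spec = spec if true_icc is None else replace(spec, icc=true_icc)
    if eval_spec.design in ("crct", "crct_baseline_adjusted"):
        if total_schools % 2 != 0 or total_schools < 4:
            raise AllocationError("parallel design needs an even total >= 4")
        k = total_schools // 2
        if eval_spec.delta == 0:
            return eval_spec.alpha
        return _crct_power(
            eval_spec.delta,
            eval_spec.sd_total,
            eval_spec.icc,
            eval_spec.m,
            k,
            eval_spec.alpha,
        )
    if eval_spec.delta == 0:
        return eval_spec.alpha
    return _sw_power(eval_spec, total_schools)


def planning_table(
    designs: list[DesignSpec] | None = None,
    scenarios: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """School counts over a grid of designs x planning scenarios.

    ``scenarios`` maps a column label to keyword overrides applied to
    every design spec (e.g. phase-specific sd_total / m / icc).  Rows
    are the designs, columns the scenarios.
    """
    if designs is None or scenarios is None:
        designs, scenarios = default_planning_grid()
    rows = {}
    for spec in designs:
        label = spec.design + (
            f"_{spec.steps}step" if spec.design.startswith("sw") else ""
        )
        rows.setdefault(label, {})
        for col, overrides in scenarios.items():
            cell_spec = replace(spec, **overrides)
            rows[label][col] = required_schools(cell_spec).total_schools
    return pd.DataFrame(rows).T


def default_planning_grid() -> tuple[list[DesignSpec], dict[str, dict]]:
    """The package's reference planning grid for English school trials:
    a 5-minute weekday-MVPA effect at 80% power / 5% alpha, primary
    (SD 23.2, 25 pupils, ICC 0.08 with upper bound 0.10) and secondary
    (SD 27.5, 50 pupils, ICC 0.05 upper 0.08) scenarios, CAC 0.6 and
    IAC 0.5 for the stepped wedge cells."""
    base = dict(delta=5.0, sd_total=23.2, icc=0.08, m=25, cac=0.6, iac=0.5)
    designs = [DesignSpec(design="crct", **base)]
    for steps in (2, 3):
        for d in ("sw_cross_sectional", "sw_cohort"):
            designs.append(DesignSpec(design=d, steps=steps, **base))
    scenarios = {
        "primary_point": dict(sd_total=23.2, m=25, icc=0.08),
        "primary_upper": dict(sd_total=23.2, m=25, icc=0.10),
        "secondary_point": dict(sd_total=27.5, m=50, icc=0.05),
        "secondary_upper": dict(sd_total=27.5, m=50, icc=0.08),
    }
    return designs, scenarios
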