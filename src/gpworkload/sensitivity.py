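"""One-way and two-way parameter sweeps, tornado analysis, break-even solving.

The sweeps reproduce, as data, the kind of figure the workload model is
used for: percent change in GP workload on the y-axis against one varied
parameter, optionally stratified by a second (legend) parameter.  The
break-even solver finds the parameter value at which the digital-first
arrangement costs exactly as many GP minutes as conventional care.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DomainError, Scenario, ValidationError, workload_change
from .scenarios import PathwayKind, base_case, load_catalog, variables_for, with_param

__all__ = [
    "SweepSpec",
    "SweepTable",
    "TornadoEntry",
    "BreakEvenResult",
    "default_grid",
    "one_way_sweep",
    "two_way_grid",
    "break_even",
    "tornado",
]


@dataclass(frozen=True)
class SweepSpec:
    """One varied parameter and its (strictly monotone, non-empty) grid."""

    variable: str
    grid: tuple[float, ...]

    def __init__(self, variable: str, grid) -> None:
        object.__setattr__(self, "variable", variable)
        object.__setattr__(self, "grid", tuple(float(v) for v in grid))
        if not self.grid:
            raise ValidationError(f"{variable}: sweep grid must be non-empty")
        diffs = np.diff(self.grid)
        if len(self.grid) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValidationError(f"{variable}: sweep grid must be strictly monotone")


@dataclass(frozen=True)
class SweepTable:
    """Tidy sweep results: one row per grid point, ``percent_change`` last.

    Cells whose parameters leave the model's domain (unbounded induced
    demand) are kept as missing values rather than aborting the sweep; they
    serialize to empty CSV fields.
    """

    data: pd.DataFrame
    variables: tuple[str, ...]

    def to_csv(self, path_or_buf=None):
        return self.data.to_csv(path_or_buf, index=False, na_rep="")


@dataclass(frozen=True)
class TornadoEntry:
    """Percent change at one variable's lower/upper bound, others at base."""

    variable: str
    change_at_lower: float
    change_at_upper: float
    base_change: float


@dataclass(frozen=True)
class BreakEvenResult:
    """A solved break-even value with solver metadata."""

    variable: str
    value: float
    percent_change: float
    iterations: int
    warnings: tuple[str, ...] = field(default=())

    def __float__(self) -> float:
        return self.value


#: Default grids mirroring the published sensitivity figures.
_DEFAULT_GRIDS = {
    "completion_rate": tuple(np.round(np.arange(0.0, 1.0001, 0.05), 10)),
    "access_rate": tuple(np.round(np.arange(0.0, 1.0001, 0.05), 10)),
    "phone_followup_fraction": tuple(np.round(np.arange(0.0, 1.0001, 0.05), 10)),
    "digital_duration": (4.0, 5.0, 6.0),
    "demand_fraction": tuple(np.round(np.arange(-0.10, 0.3001, 0.02), 10)),
}


def default_grid(variable: str) -> SweepSpec:
    """The default sweep grid for a variable (rates 0-100% step 5,
    durations {4,5,6} min, demand -10%..30% step 2)."""
    try:
        return SweepSpec(variable, _DEFAULT_GRIDS[variable])
    except KeyError:
        raise ValidationError(f"no default grid for variable {variable!r}") from None


def _evaluate(scenario: Scenario, variable: str, value: float) -> float:
    """Percent change with one parameter perturbed; NaN when d*a >= 1."""
    try:
        perturbed = with_param(scenario, variable, value)
    except ValidationError as exc:
        raise ValidationError(f"invalid grid point {variable}={value}: {exc}") from exc
    try:
        return workload_change(perturbed).percent_change
    except DomainError:
        return float("nan")


def one_way_sweep(scenario: Scenario, spec: SweepSpec) -> SweepTable:
    """Percent change at each grid point, all other parameters at scenario
    values."""
    rows = [(v, _evaluate(scenario, spec.variable, v)) for v in spec.grid]
    frame = pd.DataFrame(rows, columns=[spec.variable, "percent_change"])
    return SweepTable(data=frame, variables=(spec.variable,))


def two_way_grid(
    scenario: Scenario, spec_x: SweepSpec, spec_legend: SweepSpec
) -> SweepTable:
    """Cartesian-product sweep over two distinct parameters.

    Row order is legend-major, x-minor: each legend value forms one series
    over the full x grid, matching how the results are plotted.
    """
    if spec_x.variable == spec_legend.variable:
        raise ValidationError(
            f"two-way grid needs distinct variables, got {spec_x.variable!r} twice"
        )
    rows = []
    for legend_value in spec_legend.grid:
        base = with_param(scenario, spec_legend.variable, legend_value)
        for x_value in spec_x.grid:
            rows.append(
                (legend_value, x_value, _evaluate(base, spec_x.variable, x_value))
            )
    frame = pd.DataFrame(
        rows, columns=[spec_legend.variable, spec_x.variable, "percent_change"]
    )
    return SweepTable(data=frame, variables=(spec_legend.variable, spec_x.variable))


def break_even(
    scenario: Scenario,
    variable: str,
    lo: float,
    hi: float,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> BreakEvenResult:
    """Solve for the parameter value giving zero percent change, by bisection.

    Requires opposite signs of the percent change at ``lo`` and ``hi``.
    Bisection (rather than the closed form, which exists for each variable
    separately) keeps the solver generic across variables; ``tol`` bounds
    ``|percent_change|`` at the returned value.  Non-monotone behaviour on
    the bracket — more than one sign change on a coarse scan — is reported
    as a warning in the result metadata, not an error.
    """
    f = lambda v: _evaluate(scenario, variable, v)  # noqa: E731
    f_lo, f_hi = f(lo), f(hi)
    if np.isnan(f_lo) or np.isnan(f_hi):
        raise DomainError("break_even bracket endpoint leaves the model domain")
    if abs(f_lo) < tol:
        return BreakEvenResult(variable, lo, f_lo, 0)
    if abs(f_hi) < tol:
        return BreakEvenResult(variable, hi, f_hi, 0)
    if np.sign(f_lo) == np.sign(f_hi):
        raise DomainError(
            f"no sign change of percent_change on [{lo}, {hi}] for {variable} "
            f"({f_lo:+.4f}% .. {f_hi:+.4f}%)"
        )

    warnings: list[str] = []
    scan = [f(v) for v in np.linspace(lo, hi, 17)]
    signs = np.sign([s for s in scan if not np.isnan(s) and s != 0.0])
    if (signs[:-1] != signs[1:]).sum() > 1:
        warnings.append(
            f"percent_change is non-monotone in {variable} on [{lo}, {hi}]; "
            "bisection returns one root of possibly several"
        )

    a, b, f_a = lo, hi, f_lo
    value, f_mid, it = a, f_lo, 0
    for it in range(1, max_iter + 1):
        value = 0.5 * (a + b)
        f_mid = f(value)
        if abs(f_mid) < tol:
            break
        if np.sign(f_mid) == np.sign(f_a):
            a, f_a = value, f_mid
        else:
            b = value
    if abs(f_mid) >= tol:
        warnings.append(
            f"bisection stopped after {max_iter} iterations with "
            f"|percent_change| = {abs(f_mid):.3g} >= tol"
        )
    return BreakEvenResult(variable, value, f_mid, it, tuple(warnings))


def tornado(kind: PathwayKind | str) -> list[TornadoEntry]:
    """One-way excursions to every catalog bound, for a tornado diagram.

    Each entry evaluates the workload change with one variable at its
    lower and upper bound and everything else at base; ``base_change`` is
    the same base-case value for every entry.
    """
    kind = PathwayKind(kind)
    scenario = base_case(kind)
    base_pct = workload_change(scenario).percent_change
    bounds = load_catalog().bounds[kind]
    entries = []
    for var in variables_for(kind):
        entries.append(
            TornadoEntry(
                variable=var,
                change_at_lower=_evaluate(scenario, var, bounds[var].lower),
                change_at_upper=_evaluate(scenario, var, bounds[var].upper),
                base_change=base_pct,
            )
        )
    return entries


def tornado_table(kind: PathwayKind | str) -> pd.DataFrame:
    """Tornado entries as a DataFrame, sorted by total swing (largest first)."""
    entries = tornado(kind)
    frame = pd.DataFrame(
        [
            (e.variable, e.change_at_lower, e.change_at_upper, e.base_change)
            for e in entries
        ],
        columns=["variable", "change_at_lower", "change_at_upper", "base_change"],
    )
    swing = (frame["change_at_upper"] - frame["change_at_lower"]).abs()
    return frame.loc[swing.sort_values(ascending=False).index].reset_index(drop=True)
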