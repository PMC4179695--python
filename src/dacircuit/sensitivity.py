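"""One-parameter-at-a-time individual-differences sensitivity analysis.

A cohort of simulated individuals is created by replacing a single model
parameter with a random normal variable (or a uniformly spaced grid), holding
every other parameter at its population mean -- a noise-free, one-at-a-time
sensitivity design.  Each individual runs the full task session; the cohort
then yields the parameter-output Pearson correlation and the output spread,
from which each parameter is scored against two psychometric plausibility
criteria:

* **VSR** (very strong relationship): the parameter must correlate almost
  perfectly with the simulated endophenotype output across individuals, with
  no disqualifying non-linearity;
* **MV** (maximal variance): the parameter must create substantial variance
  in the output, or its contribution would be swamped by the other sources of
  endophenotype variance.

A parameter is a plausible source of trait-endophenotype covariance only if it
passes both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .analysis import s1_output, s2_output
from .circuit import ModelParameters, run_session
from .task import TimingConfig, TrialSchedule

__all__ = [
    "ParameterSpec",
    "SensitivityResult",
    "TABLE_SPECS",
    "default_specs",
    "draw_parameter_values",
    "run_cohort",
    "sensitivity_stats",
    "classify_plausibility",
    "full_report",
    "expected_correlation",
]


@dataclass(frozen=True)
class ParameterSpec:
    """Population distribution of one perturbed parameter."""

    name: str                            # ModelParameters field name
    population_mean: float
    population_sd: float = 0.0
    mode: str = "normal"                 # "normal" or "grid"
    grid_range: tuple[float, float] | None = None
    figure_location: int | None = None   # numbered circuit location, 1-7
    pathway: str = "excitatory"          # excitatory | inhibitory | learning
    label: str | None = None             # display label for report rows

    def __post_init__(self) -> None:
        if self.name not in ModelParameters.field_names():
            raise ValueError(
                f"unknown parameter {self.name!r}; valid names: "
                f"{', '.join(ModelParameters.field_names())}"
            )
        if self.mode not in ("normal", "grid"):
            raise ValueError("mode must be 'normal' or 'grid'")
        if self.mode == "normal" and self.population_sd <= 0:
            raise ValueError("normal mode requires population_sd > 0")
        if self.mode == "grid":
            if self.grid_range is None or not self.grid_range[0] < self.grid_range[1]:
                raise ValueError("grid mode requires grid_range with low < high")
        if self.pathway not in ("excitatory", "inhibitory", "learning"):
            raise ValueError("invalid pathway")

    @property
    def display(self) -> str:
        return self.label or self.name


def _spec(name, mean, sd=0.0, mode="normal", grid=None, loc=None,
          pathway="excitatory", label=None, n=None):
    s = ParameterSpec(name=name, population_mean=mean, population_sd=sd,
                      mode=mode, grid_range=grid, figure_location=loc,
                      pathway=pathway, label=label)
    return (s, n)


#: Default sweep plan: one row per studied configuration, grouped by the
#: pathway the parameter sits on.  Normal rows use 50 individuals; grid rows
#: use the spacing implied by their printed range and mean.
TABLE_SPECS: tuple[tuple[ParameterSpec, int | None], ...] = (
    _spec("w_pd", 5.0, 1.0, loc=1, label="w_PD"),
    _spec("w_sp", 2.0, 0.5, loc=5, label="w_SP"),
    _spec("w_sp", 2.125, mode="grid", grid=(0.25, 4.0), loc=5,
          label="w_SP (grid)", n=16),
    _spec("w_rp", 0.8, 0.2, loc=6, label="w_RP"),
    _spec("w_rp", 2.05, mode="grid", grid=(0.1, 4.0), loc=6,
          label="w_RP (grid)", n=40),
    _spec("w_rs", 1.5, 0.35, loc=7, label="w_RS"),
    _spec("w_rs", 1.05, mode="grid", grid=(0.1, 2.0), loc=7,
          label="w_RS (grid)", n=20),
    _spec("w_max_s", 1.0, 0.25, loc=4, label="w_max_S"),
    _spec("tau_ws", 1.0, 0.25, loc=4, pathway="learning", label="tau_WS"),
    _spec("tau_ws", 20.0, 5.0, loc=4, pathway="learning",
          label="tau_WS (large mean)"),
    _spec("beta_ws", 0.5, 0.125, loc=4, pathway="learning", label="beta_WS"),
    _spec("h_d", 6.0, 1.0, loc=2, pathway="inhibitory", label="h_D"),
    _spec("gamma_s", 100.0, 20.0, loc=3, pathway="inhibitory",
          label="gamma_S"),
    _spec("alpha_z", 0.05, 0.0125, loc=3, pathway="inhibitory",
          label="alpha_Z"),
)


def default_specs() -> list[ParameterSpec]:
    return [spec for spec, _ in TABLE_SPECS]


def draw_parameter_values(spec: ParameterSpec, n: int = 50,
                          seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw one parameter value per simulated individual.

    Normal mode draws from Normal(mean, sd), redrawing any value <= 0 so the
    nominal mean is preserved better than by clipping; grid mode returns n
    uniformly spaced values covering the range inclusively.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if spec.mode == "grid":
        lo, hi = spec.grid_range
        return np.linspace(lo, hi, n)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    values = np.empty(n)
    for i in range(n):
        v = rng.normal(spec.population_mean, spec.population_sd)
        while v <= 0:
            v = rng.normal(spec.population_mean, spec.population_sd)
        values[i] = v
    return values


def run_cohort(spec: ParameterSpec, values: np.ndarray,
               base_params: ModelParameters, schedule: TrialSchedule,
               timing: TimingConfig) -> pd.DataFrame:
    """Run one session per individual, varying only ``spec.name``.

    Every other parameter is bit-identical across individuals.  Returns one
    row per individual with the parameter value and both scalar outputs.
    """
    rows = []
    for i, value in enumerate(values):
        params = base_params.with_value(spec.name, float(value))
        try:
            session = run_session(params, schedule, timing)
        except Exception as err:
            raise RuntimeError(
                f"individual {i} ({spec.name} = {value:g}) failed: {err}"
            ) from err
        rows.append(
            {
                "individual_id": i,
                "parameter_value": float(value),
                "s2_output": s2_output(session),
                "s1_output": s1_output(session),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SensitivityResult:
    """Cohort statistics and plausibility verdict for one parameter."""

    spec: ParameterSpec
    n: int
    parameter_mean: float
    parameter_sd: float
    output_mean: float
    output_sd: float
    pearson_r: float                 # NaN when undefined
    s1_output_mean: float
    s1_output_sd: float
    s1_pearson_r: float
    nonlinearity_flag: bool
    breakpoint: float | None
    vsr_pass: bool | None = None
    mv_pass: bool | None = None
    verdict: str = "unclassified"

    def to_row(self) -> dict:
        return {
            "parameter": self.spec.display,
            "name": self.spec.name,
            "location": self.spec.figure_location,
            "pathway": self.spec.pathway,
            "mode": self.spec.mode,
            "n": self.n,
            "population_mean": self.spec.population_mean,
            "population_sd": (self.spec.population_sd
                              if self.spec.mode == "normal" else np.nan),
            "parameter_mean": self.parameter_mean,
            "parameter_sd": self.parameter_sd,
            "output_mean": self.output_mean,
            "output_sd": self.output_sd,
            "pearson_r": self.pearson_r,
            "s1_output_mean": self.s1_output_mean,
            "s1_output_sd": self.s1_output_sd,
            "s1_pearson_r": self.s1_pearson_r,
            "nonlinearity_flag": self.nonlinearity_flag,
            "breakpoint": self.breakpoint,
            "vsr_pass": self.vsr_pass,
            "mv_pass": self.mv_pass,
            "verdict": self.verdict,
        }


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; NaN when either margin has zero variance."""
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _two_segment_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Best two-segment linear fit; returns (RSS, breakpoint).

    Segments are fitted independently on each side of every candidate split
    of the parameter-sorted data (at least 3 points per side); the breakpoint
    is the midpoint between the straddling parameter values.
    """
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    n = xs.shape[0]
    best_rss, best_break = math.inf, math.nan
    for k in range(3, n - 2):
        rss = _line_rss(xs[:k], ys[:k]) + _line_rss(xs[k:], ys[k:])
        if rss < best_rss:
            best_rss = rss
            best_break = 0.5 * (xs[k - 1] + xs[k])
    return best_rss, best_break


def _line_rss(x: np.ndarray, y: np.ndarray) -> float:
    A = np.column_stack([x, np.ones_like(x)])
    _, res, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if res.size:
        return float(res[0])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    return float(((A @ coef - y) ** 2).sum())


def sensitivity_stats(spec: ParameterSpec, samples: pd.DataFrame,
                      nonlinearity_ratio: float = 4.0,
                      linear_r2: float = 0.95) -> SensitivityResult:
    """Summarise a cohort: sample moments, Pearson r, non-linearity screen.

    Sample SDs use the n-1 denominator.  A parameter-output relationship is
    flagged non-linear when (a) a single straight line explains less than
    ``linear_r2`` of the output variance -- in a noise-free model any smooth
    monotone curve is fit almost perfectly by a line, so only genuine
    departures such as a step fail this -- and (b) a two-segment linear fit
    reduces the line's residual sum of squares by at least
    ``nonlinearity_ratio``.  The estimated breakpoint (midpoint between the
    straddling parameter values of the best split) is reported alongside.
    """
    n = len(samples)
    if n < 3:
        raise ValueError("need at least 3 individuals for cohort statistics")
    x = samples["parameter_value"].to_numpy(dtype=float)
    y = samples["s2_output"].to_numpy(dtype=float)
    y1 = samples["s1_output"].to_numpy(dtype=float)
    nonlinearity_flag = False
    breakpoint: float | None = None
    one_rss = _line_rss(x, y)
    tss = float(((y - y.mean()) ** 2).sum())
    if (n >= 8 and x.std(ddof=1) > 0 and one_rss > 0 and tss > 0
            and 1.0 - one_rss / tss < linear_r2):
        two_rss, candidate = _two_segment_fit(x, y)
        if two_rss <= one_rss / nonlinearity_ratio:
            nonlinearity_flag = True
            breakpoint = candidate
    return SensitivityResult(
        spec=spec,
        n=n,
        parameter_mean=float(x.mean()),
        parameter_sd=float(x.std(ddof=1)),
        output_mean=float(y.mean()),
        output_sd=float(y.std(ddof=1)),
        pearson_r=_pearson(x, y),
        s1_output_mean=float(y1.mean()),
        s1_output_sd=float(y1.std(ddof=1)),
        s1_pearson_r=_pearson(x, y1),
        nonlinearity_flag=nonlinearity_flag,
        breakpoint=breakpoint,
    )


def classify_plausibility(result: SensitivityResult, vsr_min: float = 0.90,
                          mv_min_sd: float = 0.03) -> SensitivityResult:
    """Score a cohort result against the VSR and MV criteria.

    VSR passes when |r| >= ``vsr_min`` and no disqualifying non-linearity was
    flagged; MV passes when the output SD reaches ``mv_min_sd`` spikes/bin.
    The verdict is "plausible" only when both pass, and "indeterminate" when
    r is undefined (zero variance in a margin).
    """
    if math.isnan(result.pearson_r):
        return replace(result, vsr_pass=None, mv_pass=None,
                       verdict="indeterminate")
    vsr = abs(result.pearson_r) >= vsr_min and not result.nonlinearity_flag
    mv = result.output_sd >= mv_min_sd
    verdict = "plausible" if (vsr and mv) else "implausible"
    return replace(result, vsr_pass=vsr, mv_pass=mv, verdict=verdict)


def full_report(specs: list[tuple[ParameterSpec, int | None]] | None = None,
                base_params: ModelParameters | None = None,
                schedule: TrialSchedule | None = None,
                timing: TimingConfig | None = None,
                n: int = 50, seed: int = 0,
                vsr_min: float = 0.90, mv_min_sd: float = 0.03,
                ) -> pd.DataFrame:
    """Run the whole sweep plan and assemble the per-parameter report table.

    Each row is seeded independently (spawned from ``seed``) and the whole
    report is reproducible for a given (specs, n, seed).  Per-row failures
    are annotated in the ``error`` column; remaining rows still complete.
    """
    from .task import build_schedule  # local import to avoid cycle at startup

    if specs is None:
        specs = list(TABLE_SPECS)
    if base_params is None:
        base_params = ModelParameters()
    if schedule is None:
        schedule = build_schedule(seed=seed)
    if timing is None:
        timing = TimingConfig()
    rows = []
    children = np.random.SeedSequence(seed).spawn(len(specs))
    for (spec, row_n), child in zip(specs, children):
        cohort_n = row_n if row_n is not None else n
        try:
            rng = np.random.default_rng(child)
            values = draw_parameter_values(spec, n=cohort_n, seed=rng)
            samples = run_cohort(spec, values, base_params, schedule, timing)
            result = classify_plausibility(
                sensitivity_stats(spec, samples),
                vsr_min=vsr_min, mv_min_sd=mv_min_sd,
            )
            row = result.to_row()
            row["error"] = ""
        except Exception as err:  # annotate and continue with other rows
            row = {"parameter": spec.display, "name": spec.name,
                   "error": str(err)}
        rows.append(row)
    return pd.DataFrame(rows)


def expected_correlation(m: int, p: int, reliability_trait: float,
                         reliability_endo: float, r_xy: float) -> float:
    """Expected trait-endophenotype correlation from shared-cause psychometrics.

    With ``m`` equal, independent causes of the trait and ``p`` of the
    endophenotype, one shared cause X whose relationship with the simulated
    endophenotypic process Y has correlation ``r_xy``, and the given
    measurement reliabilities, the observable correlation is the geometric
    mean of the two variance ratios::

        A = reliability_trait / m
        B = (reliability_endo / p) * r_xy**2
        r = sqrt(A * B)

    With m=8, reliabilities 0.8/0.9, p=1 and a perfect parameter-process
    relationship this gives 0.3, dropping to 0.15 at r_xy = 0.5.
    """
    if m < 1 or p < 1:
        raise ValueError("m and p must be >= 1")
    for name, rel in (("reliability_trait", reliability_trait),
                      ("reliability_endo", reliability_endo)):
        if not 0 < rel <= 1:
            raise ValueError(f"{name} must lie in (0, 1]")
    if abs(r_xy) > 1:
        raise ValueError("|r_xy| must be <= 1")
    a = reliability_trait / m
    b = (reliability_endo / p) * r_xy**2
    return math.sqrt(a * b)
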