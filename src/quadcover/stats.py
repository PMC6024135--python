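"""Agreement and treatment-effect inference for paired cover surveys.

Three layers of comparison between automated cover estimates and field
(ecologist) estimates:

1. **Pearson correlation** between the two raters' covers across quadrats.

2. **Directional-change Cohen's kappa**: for each plot and each pair of
   consecutive survey years, the year-to-year change in cover is binarized
   to *increase* / *decrease* for both raters; transitions where either
   rater's change is exactly zero are dropped (and counted).  Kappa is the
   chance-corrected agreement (p_o - p_e) / (1 - p_e) on the pooled 2x2
   table, with the conventional interpretation bands (<= 0 none,
   0.01-0.20 slight, 0.21-0.40 fair, 0.41-0.60 moderate, 0.61-0.80
   substantial, 0.81-1.00 almost perfect).

3. **Treatment-effect linear mixed model**: for each coverage variable,

       Coverage ~ Treatment + (1 | Year) + (1 | Year:Plot)

   with Control as the reference level, fitted by REML.  Effects get Wald
   95% intervals (estimate +/- 1.96 SE); a treatment's change is declared
   *significant* iff its interval excludes zero.  Two fits (automated vs
   field) *agree* on a treatment when they reach the same conclusion; the
   agreement count over the nine non-control treatments summarizes whether
   the automated system supports the same inferences as the field survey.

The random-effect structure "plots nested in years" is under-determined;
the default encodes a year intercept plus a (year, plot) intercept, and
``nesting="year_plot"`` gives the (year, plot)-only variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

#: The ten experimental treatment levels of the nutrient-addition design.
TREATMENTS = (
    "Control", "Fence", "K", "N", "NK", "NP", "NPK", "NPK+Fence", "P", "PK",
)

#: z quantile for the Wald 95% interval.
_Z95 = 1.959963984540054

#: Conventional kappa interpretation bands (upper edge inclusive).
KAPPA_BANDS = (
    (0.0, "no agreement"),
    (0.20, "none to slight agreement"),
    (0.40, "fair agreement"),
    (0.60, "moderate agreement"),
    (0.80, "substantial agreement"),
    (1.0, "almost perfect agreement"),
)


def interpret_kappa(kappa: float) -> str:
    if np.isnan(kappa):
        return "undefined"
    for upper, band in KAPPA_BANDS:
        if kappa <= upper:
            return band
    return KAPPA_BANDS[-1][1]


def pearson(auto, truth) -> float:
    """Pearson product-moment correlation between two cover vectors."""
    auto = np.asarray(auto, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if auto.shape != truth.shape or auto.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if auto.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(auto) == 0 or np.ptp(truth) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    return float(sps.pearsonr(auto, truth).statistic)


@dataclass
class ChangeSeries:
    """Ordered paired (automated, truth) cover values for one plot."""

    plot: str
    years: list
    auto: list[float]
    truth: list[float]

    def __post_init__(self):
        if not (len(self.years) == len(self.auto) == len(self.truth)):
            raise ValueError("years, auto and truth must have equal length")
        if len(self.years) < 2:
            raise ValueError("need at least 2 years to define a change")


@dataclass
class KappaResult:
    kappa: float
    table: np.ndarray  # rows: truth (increase, decrease); cols: automated
    n_transitions: int
    n_dropped_ties: int
    p_observed: float
    p_expected: float
    interpretation: str


def kappa_from_table(table) -> KappaResult:
    """Cohen's kappa from a 2x2 agreement table (closed form).

    ``table[i][j]`` counts transitions where truth direction is i and the
    automated direction is j (0 = increase, 1 = decrease).  Degenerate
    marginals with chance agreement p_e = 1 make kappa undefined (NaN).
    """
    table = np.asarray(table, dtype=np.float64)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("expected a non-negative 2x2 table")
    n = table.sum()
    if n == 0:
        raise ValueError("empty agreement table")
    p_o = np.trace(table) / n
    p_e = float(np.dot(table.sum(axis=1), table.sum(axis=0))) / n**2
    kappa = np.nan if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return KappaResult(
        kappa=float(kappa),
        table=table.astype(np.int64) if np.allclose(table, np.round(table)) else table,
        n_transitions=int(n),
        n_dropped_ties=0,
        p_observed=float(p_o),
        p_expected=float(p_e),
        interpretation=interpret_kappa(kappa),
    )


def directional_kappa(series: list[ChangeSeries]) -> KappaResult:
    """Agreement on the *direction* of year-to-year cover change.

    Pools all consecutive-year transitions over plots into one 2x2 table
    (increase/decrease by each rater) and returns Cohen's kappa on it.
    Transitions where either rater's change is exactly zero carry no
    direction and are dropped; their count is reported.
    """
    table = np.zeros((2, 2), dtype=np.int64)
    dropped = 0
    for s in series:
        for i in range(len(s.years) - 1):
            d_auto = s.auto[i + 1] - s.auto[i]
            d_truth = s.truth[i + 1] - s.truth[i]
            if d_auto == 0 or d_truth == 0:
                dropped += 1
                continue
            table[int(d_truth < 0), int(d_auto < 0)] += 1
    if table.sum() == 0:
        raise ValueError("no transitions with a nonzero change in both raters")
    result = kappa_from_table(table)
    result.n_dropped_ties = dropped
    return result


@dataclass
class TreatmentEffectFit:
    """Fixed treatment effects (relative to Control) with Wald 95% CIs."""

    variable: str
    intercept: float  # Control mean, beta_0
    effects: pd.DataFrame = field(repr=False)  # index: treatment; estimate, se, ci_low, ci_high, significant
    random_effects_var: dict = field(default_factory=dict)
    residual_var: float = float("nan")
    converged: bool = True
    singular: bool = False
    nesting: str = "year_plus_year_plot"

    @property
    def conclusions(self) -> pd.Series:
        """'significant' / 'not significant' per non-control treatment."""
        return self.effects["significant"].map(
            {True: "significant", False: "not significant"}
        )


def fit_treatment_lmem(
    covers: pd.DataFrame,
    value_col: str,
    *,
    treatments: tuple = TREATMENTS,
    nesting: str = "year_plus_year_plot",
) -> TreatmentEffectFit:
    """Fit the treatment-effect linear mixed model for one coverage variable.

    ``covers`` needs columns ``value_col``, ``treatment``, ``year``,
    ``plot``.  All treatment levels must be present and at least 2 years.
    REML estimation; coverage is modelled on the fraction scale
    untransformed.  A singular fit (a variance component at the boundary,
    or no convergence) is flagged, not hidden.
    """
    df = covers[[value_col, "treatment", "year", "plot"]].dropna().copy()
    present = set(df["treatment"].unique())
    missing = set(treatments) - present
    if missing:
        raise ValueError(f"missing treatment level(s): {sorted(missing)}")
    if df["year"].nunique() < 2:
        raise ValueError("need at least 2 years")
    df["treatment"] = pd.Categorical(df["treatment"], categories=list(treatments))
    df["year"] = df["year"].astype(str)
    df["plot"] = df["plot"].astype(str)
    df = df.rename(columns={value_col: "_cover"})

    if nesting == "year_plus_year_plot":
        # random intercept per year (re_formula) + per (year, plot) pair
        # (variance component evaluated within the year groups)
        model = sm.MixedLM.from_formula(
            "_cover ~ C(treatment)",
            groups="year",
            re_formula="1",
            vc_formula={"plot": "0 + C(plot)"},
            data=df,
        )
    elif nesting == "year_plot":
        df["_yearplot"] = df["year"] + ":" + df["plot"]
        model = sm.MixedLM.from_formula(
            "_cover ~ C(treatment)", groups="_yearplot", re_formula="1", data=df
        )
    else:
        raise ValueError(f"unknown nesting {nesting!r}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        res = model.fit(reml=True)

    fe = res.fe_params
    bse = res.bse_fe
    rows = []
    for trt in treatments[1:]:
        name = f"C(treatment)[T.{trt}]"
        est, se = float(fe[name]), float(bse[name])
        lo, hi = est - _Z95 * se, est + _Z95 * se
        rows.append(
            {"treatment": trt, "estimate": est, "se": se,
             "ci_low": lo, "ci_high": hi, "significant": bool(lo > 0 or hi < 0)}
        )
    effects = pd.DataFrame(rows).set_index("treatment")

    re_var = {}
    if nesting == "year_plus_year_plot":
        re_var["year"] = float(np.asarray(res.cov_re).ravel()[0])
        re_var["year:plot"] = float(res.vcomp[0]) if len(res.vcomp) else float("nan")
    else:
        re_var["year:plot"] = float(np.asarray(res.cov_re).ravel()[0])
    residual = float(res.scale)
    singular = (not res.converged) or any(v <= 1e-10 for v in re_var.values())

    return TreatmentEffectFit(
        variable=value_col,
        intercept=float(fe["Intercept"]),
        effects=effects,
        random_effects_var=re_var,
        residual_var=residual,
        converged=bool(res.converged),
        singular=bool(singular),
        nesting=nesting,
    )


def conclusion_agreement(fit_auto: TreatmentEffectFit, fit_truth: TreatmentEffectFit) -> int:
    """Number of non-control treatments on which two fits reach the same
    significant / not-significant conclusion (0..9 for the full design)."""
    if list(fit_auto.effects.index) != list(fit_truth.effects.index):
        raise ValueError("fits cover different treatment sets")
    return int(
        (fit_auto.effects["significant"] == fit_truth.effects["significant"]).sum()
    )


def change_series_from_tables(
    auto: pd.DataFrame, truth: pd.DataFrame, auto_col: str, truth_col: str
) -> list[ChangeSeries]:
    """Join automated and truth tables on (site, plot, year) into ChangeSeries."""
    merged = auto.merge(truth, on=["site", "plot", "year"], suffixes=("", "_truth"))
    out = []
    for (site, plot), grp in merged.groupby(["site", "plot"], sort=True):
        grp = grp.sort_values("year")
        if len(grp) < 2:
            continue
        out.append(
            ChangeSeries(
                plot=f"{site}:{plot}",
                years=list(grp["year"]),
                auto=[float(v) for v in grp[auto_col]],
                truth=[float(v) for v in grp[truth_col]],
            )
        )
    return out
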