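"""Statistical layer: replicate/donor aggregation, t-test, ANOVA, Dunnett.

Observations arrive as tidy DataFrames ("grouped values") with a ``value``
column and grouping columns (``group``, ``donor``, ``replicate``, optional
second factor).  Technical replicates are averaged within donor before
between-group testing; the donor is the experimental unit (n = donors).

Two reporting modes are provided for the screen's many-to-one comparisons:

* ``"donor-means"`` (default): run one test on the per-donor means — the
  statistically conventional choice, used by the eligibility gate.
* ``"per-donor-mean-p"``: run the test within each donor (technical
  replicates as observations) and average the p-values across donors —
  mirrors reporting significance as "the mean calculated p value of the
  donors".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, InsufficientReplicatesError

__all__ = [
    "TestResult",
    "aggregate_replicates",
    "unpaired_t",
    "anova",
    "dunnett",
    "dunnett_raw",
    "star_map",
]


@dataclass(frozen=True)
class TestResult:
    """A single hypothesis-test outcome with its significance label."""

    comparison: str
    statistic: float
    df: float
    p: float
    p_adjusted: float | None = None
    mode: str = ""

    @property
    def stars(self) -> str:
        return star_map(self.p_adjusted if self.p_adjusted is not None else self.p)


def star_map(p: float) -> str:
    """Significance label: ns / * / ** / *** / **** (strict thresholds)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p!r}")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def aggregate_replicates(
    values: pd.DataFrame,
    value: str = "value",
    donor: str = "donor",
) -> tuple[pd.Series, float, float]:
    """Average technical replicates within donor; summarize across donors.

    Returns ``(donor_means, grand_mean, sd)`` with the SD computed across
    donor means (ddof=1; NaN for a single donor — flagged, not an error).
    """
    if values.empty:
        raise InsufficientReplicatesError("no observations to aggregate")
    donor_means = values.groupby(donor, observed=True)[value].mean()
    grand = float(donor_means.mean())
    sd = float(donor_means.std(ddof=1)) if len(donor_means) > 1 else float("nan")
    return donor_means, grand, sd


def unpaired_t(
    a: Sequence[float],
    b: Sequence[float],
    equal_var: bool = True,
    comparison: str = "a vs b",
) -> TestResult:
    """Two-sided unpaired t-test (pooled variance by default; Welch optional).

    Two groups with zero variance and equal means return p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicatesError("each group needs >= 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult(comparison, 0.0, a.size + b.size - 2, 1.0)
        return TestResult(comparison, float("inf"), a.size + b.size - 2, 0.0)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = float(res.df) if hasattr(res, "df") else a.size + b.size - 2
    return TestResult(comparison, float(res.statistic), df, float(res.pvalue))


def anova(
    values: pd.DataFrame,
    value: str = "value",
    factors: Sequence[str] = ("group",),
    interaction: bool = True,
) -> list[TestResult]:
    """One-way or two-way ANOVA; type-II sums of squares for two-way layouts.

    Returns one :class:`TestResult` per factor (and the interaction when
    estimable in a two-way design).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    factors = list(factors)
    if not 1 <= len(factors) <= 2:
        raise ConfigurationError("anova supports one or two factors")
    for f in factors:
        if values[f].nunique() < 2:
            raise ConfigurationError(f"factor {f!r} needs >= 2 levels")
    data = values.rename(columns={value: "_y"})
    terms = [f"C(Q('{f}'))" for f in factors]
    if len(factors) == 2 and interaction:
        # the interaction is only estimable with >1 observation per cell
        cell_sizes = data.groupby(factors, observed=True).size()
        if (cell_sizes > 1).any():
            terms.append(f"C(Q('{factors[0]}')):C(Q('{factors[1]}'))")
    model = smf.ols("_y ~ " + " + ".join(terms), data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    results = []
    pretty = {f"C(Q('{f}'))": f for f in factors}
    pretty[f"C(Q('{factors[0]}')):C(Q('{factors[-1]}'))"] = ":".join(factors)
    for term, row in table.iterrows():
        if term == "Residual":
            continue
        results.append(
            TestResult(
                comparison=pretty.get(term, term),
                statistic=float(row["F"]),
                df=float(row["df"]),
                p=float(row["PR(>F)"]),
                mode="one-way" if len(factors) == 1 else "two-way/typeII",
            )
        )
    return results


def dunnett_raw(groups: Sequence[np.ndarray], control: np.ndarray) -> np.ndarray:
    """Adjusted p-values for many-to-one comparisons against ``control``.

    Two-sided Dunnett test; the familywise adjustment integrates the
    multivariate-t dependence of the contrasts.  Returns one adjusted p per
    group, in order.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    control = np.asarray(control, dtype=float)
    if control.size < 2 or any(g.size < 2 for g in groups):
        raise InsufficientReplicatesError("each group needs >= 2 observations")
    # the multivariate-t tail probability is evaluated by Monte Carlo inside
    # scipy; a fixed generator keeps results reproducible across calls
    res = sps.dunnett(*groups, control=control, random_state=np.random.default_rng(0))
    return np.asarray(res.pvalue, dtype=float)


def dunnett(
    values: pd.DataFrame,
    control: str,
    value: str = "value",
    group: str = "group",
    donor: str = "donor",
    mode: str = "donor-means",
) -> list[TestResult]:
    """Dunnett many-to-one comparisons of every group against ``control``.

    ``mode="donor-means"`` tests per-donor means (one observation per donor);
    ``mode="per-donor-mean-p"`` runs the family within each donor on the
    technical replicates and reports the across-donor mean of the adjusted
    p-values.  A family of size one reduces to the unpaired t-test.
    """
    if control not in set(values[group]):
        raise ConfigurationError(f"control group {control!r} not present")
    labels = [g for g in values[group].unique() if g != control]
    if not labels:
        raise ConfigurationError("no non-control groups to compare")

    def family_p(frame: pd.DataFrame) -> np.ndarray:
        ctrl = frame.loc[frame[group] == control, value].to_numpy()
        samples = [frame.loc[frame[group] == g, value].to_numpy() for g in labels]
        return dunnett_raw(samples, ctrl)

    if mode == "donor-means":
        if donor in values.columns:
            data = (
                values.groupby([group, donor], observed=True)[value]
                .mean()
                .reset_index()
            )
        else:
            data = values
        p_adj = family_p(data)
        used = data
    elif mode == "per-donor-mean-p":
        if donor not in values.columns:
            raise ConfigurationError("per-donor-mean-p mode requires a donor column")
        per_donor = [family_p(frame) for _, frame in values.groupby(donor, observed=True)]
        p_adj = np.mean(per_donor, axis=0)
        used = values
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")

    results = []
    n_total = len(used)
    df = n_total - (len(labels) + 1)
    ctrl_mean = used.loc[used[group] == control, value].mean()
    for g, p in zip(labels, p_adj):
        diff = used.loc[used[group] == g, value].mean() - ctrl_mean
        results.append(
            TestResult(
                comparison=f"{g} vs {control}",
                statistic=float(diff),
                df=float(df),
                p=float(p),
                p_adjusted=float(p),
                mode=mode,
            )
        )
    return results
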