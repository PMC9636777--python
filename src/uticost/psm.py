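"""Propensity estimation, 1:1 greedy matching, balance, gamma cost models.

Matching is greedy nearest-neighbor without replacement on the logit of the
propensity score, with a caliper expressed in SDs of the logit score
(default 0.2) and a seed-controlled processing order.  Cost models are
gamma-family log-link GLMs; adjusted dollar differences come from recycled
predictions (predict every analysis patient under each exposure level,
average, subtract).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit as _logit

from . import config as cfgmod


class PerfectSeparationError(RuntimeError):
    """The propensity model separated the groups perfectly."""


@dataclass
class PsModel:
    covariates: list[str]
    params: pd.Series
    scores: pd.Series  # indexed like the input frame, values in (0, 1)
    dropped_covariates: list[str] = field(default_factory=list)


@dataclass
class MatchedCohort:
    pairs: list[tuple]  # (treated_label, control_label, |logit distance|)
    caliper: float
    unmatched_treated: list
    unmatched_controls: list

    @property
    def treated_ids(self):
        return [t for t, _, _ in self.pairs]

    @property
    def control_ids(self):
        return [c for _, c, _ in self.pairs]

    @property
    def matched_ids(self):
        return self.treated_ids + self.control_ids

    def validate(self) -> None:
        ids = self.matched_ids
        if len(ids) != len(set(ids)):
            raise ValueError("an id appears in more than one pair")
        if any(d > self.caliper + 1e-12 for _, _, d in self.pairs):
            raise ValueError("pair exceeds caliper")


@dataclass
class CostModelResult:
    contrast: str
    family: str
    link: str
    reference: str
    n: int
    converged: bool
    coefficients: pd.DataFrame  # coef, se, pvalue per term
    adjusted_means: dict  # exposure level -> recycled-prediction mean
    differences: dict  # level -> adjusted dollar difference vs reference
    pvalues: dict  # level -> Wald p-value of the level's coefficient


def estimate_propensity(
    df: pd.DataFrame, group_col: str, covariates: list[str]
) -> PsModel:
    """Logistic model of group membership; returns per-patient scores.

    Zero-variance covariates are dropped (with a record) rather than left to
    produce a singular design; perfect separation raises instead of being
    absorbed silently.
    """
    y = df[group_col].astype(int)
    if y.nunique() < 2:
        raise ValueError("group column must contain both classes")
    X = df[list(covariates)].astype(float)
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    X = X.drop(columns=dropped)
    design = sm.add_constant(X, has_constant="add")
    try:
        # IRLS with pinv is robust to the near-singular designs that sparse
        # count covariates produce in small samples
        res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=200)
    except Exception as exc:  # statsmodels raises several separation types
        raise PerfectSeparationError(str(exc)) from exc
    if not getattr(res, "converged", True) or np.abs(res.params.to_numpy()).max() > 25:
        raise PerfectSeparationError("propensity model did not converge (separation?)")
    scores = res.predict(design).clip(1e-12, 1 - 1e-12)
    return PsModel(
        covariates=list(X.columns),
        params=res.params,
        scores=pd.Series(scores, index=df.index),
        dropped_covariates=dropped,
    )


def match_1to1(
    scores: pd.Series,
    treated: pd.Series,
    caliper: float = 0.2,
    caliper_scale: str = "sd",
    seed: int = 0,
) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    Distances are absolute differences of logit scores.  ``caliper`` is in
    SDs of the logit score when ``caliper_scale == "sd"``, else absolute.
    Treated units are processed in a seed-determined random order; a unit
    with no available control within the caliper stays unmatched.
    """
    treated = treated.astype(bool)
    if treated.all() or (~treated).all():
        raise ValueError("both groups must be non-empty")
    lg = pd.Series(_logit(scores.clip(1e-12, 1 - 1e-12)), index=scores.index)
    if caliper_scale == "sd":
        sd = float(lg.std(ddof=1))
        caliper_value = caliper * (sd if np.isfinite(sd) and sd > 0 else 1.0)
    else:
        caliper_value = float(caliper)

    rng = np.random.default_rng(seed)
    treated_labels = np.array(lg.index[treated], dtype=object)
    order = rng.permutation(len(treated_labels))

    control_labels = np.array(lg.index[~treated], dtype=object)
    c_order = np.argsort(lg.loc[control_labels].to_numpy(), kind="mergesort")
    c_labels = control_labels[c_order]
    c_scores = lg.loc[control_labels].to_numpy()[c_order]
    used = np.zeros(len(c_labels), dtype=bool)

    pairs: list[tuple] = []
    unmatched: list = []
    for pos in order:
        t_label = treated_labels[pos]
        t_score = lg.loc[t_label]
        j = np.searchsorted(c_scores, t_score)
        best, best_d = -1, np.inf
        # distances grow monotonically moving away from j in either
        # direction, so stop at the first unused candidate on each side
        lo = j - 1
        while lo >= 0:
            d = t_score - c_scores[lo]
            if d > best_d:
                break
            if not used[lo]:
                best, best_d = lo, d
                break
            lo -= 1
        hi = j
        while hi < len(c_scores):
            d = c_scores[hi] - t_score
            if d >= best_d:  # ties resolve to the left neighbor
                break
            if not used[hi]:
                best, best_d = hi, d
                break
            hi += 1
        if best >= 0 and best_d <= caliper_value:
            used[best] = True
            pairs.append((t_label, c_labels[best], float(best_d)))
        else:
            unmatched.append(t_label)

    result = MatchedCohort(
        pairs=pairs,
        caliper=caliper_value,
        unmatched_treated=unmatched,
        unmatched_controls=[lab for lab, u in zip(c_labels, used) if not u],
    )
    result.validate()
    return result


def standardized_mean_difference(a, b, binary: bool | None = None) -> float:
    """|mean_a - mean_b| / sqrt((var_a + var_b)/2).

    For binary covariates the variances are p(1-p).  Returns 0 when the
    pooled variance is 0 and the means agree, ``inf`` when they differ.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if binary is None:
        binary = set(np.unique(np.concatenate([a, b]))) <= {0.0, 1.0}
    ma, mb = a.mean(), b.mean()
    if binary:
        va, vb = ma * (1 - ma), mb * (1 - mb)
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("continuous SMD needs >= 2 observations per group")
        va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = (va + vb) / 2.0
    if pooled <= 0:
        return 0.0 if np.isclose(ma, mb) else float("inf")
    return float(abs(ma - mb) / np.sqrt(pooled))


def balance_table(
    df: pd.DataFrame,
    covariates: list[str],
    group_col: str,
    matched: MatchedCohort | None = None,
) -> pd.DataFrame:
    """Pre- (and optionally post-) match SMD per covariate."""
    g = df[group_col].astype(bool)
    rows = []
    matched_idx = None
    if matched is not None:
        matched_idx = df.index.isin(matched.matched_ids)
    for cov in covariates:
        x = df[cov].astype(float)
        row = {
            "covariate": cov,
            "smd_unmatched": standardized_mean_difference(x[g], x[~g]),
        }
        if matched_idx is not None:
            row["smd_matched"] = standardized_mean_difference(
                x[g & matched_idx], x[~g & matched_idx]
            )
        rows.append(row)
    return pd.DataFrame(rows)


def fit_cost_model(
    df: pd.DataFrame,
    outcome: str,
    exposure: str,
    adjusters: list[str] = (),
    reference: str | None = None,
    zero_offset: float = 0.01,
    drop_zeros: bool = False,
    contrast_name: str | None = None,
) -> CostModelResult:
    """Gamma log-link GLM of ``outcome`` on exposure + adjusters.

    Zero/negative outcomes are floored at ``zero_offset`` (or dropped).
    Adjusted differences use recycled predictions over the analysis sample.
    """
    data = df.copy()
    y = data[outcome].astype(float)
    if drop_zeros:
        data, y = data.loc[y > 0], y[y > 0]
    else:
        y = y.clip(lower=zero_offset)

    levels = [str(v) for v in pd.unique(data[exposure].astype(str))]
    levels.sort()
    if reference is None:
        reference = "S_app" if "S_app" in levels else levels[0]
    elif reference not in levels:
        raise ValueError(f"reference level {reference!r} absent")
    non_ref = [lv for lv in levels if lv != reference]

    X = pd.DataFrame(index=data.index)
    exp_str = data[exposure].astype(str)
    for lv in non_ref:
        X[f"exposure[{lv}]"] = (exp_str == lv).astype(float)
    for adj in adjusters:
        X[adj] = data[adj].astype(float)
    design = sm.add_constant(X, has_constant="add")

    if y.nunique() == 1:
        # degenerate zero-dispersion outcome: the gamma likelihood is on its
        # boundary; return the exact limiting answer instead of crashing
        mu = float(y.iloc[0])
        coef = pd.DataFrame(
            {"coef": 0.0, "se": np.nan, "pvalue": 1.0}, index=design.columns
        )
        coef.loc["const", "coef"] = np.log(mu)
        levels_means = {lv: mu for lv in levels}
        return CostModelResult(
            contrast=contrast_name or exposure,
            family="gamma",
            link="log",
            reference=reference,
            n=len(data),
            converged=True,
            coefficients=coef,
            adjusted_means=levels_means,
            differences={lv: 0.0 for lv in non_ref},
            pvalues={lv: 1.0 for lv in non_ref},
        )

    model = sm.GLM(y, design, family=sm.families.Gamma(link=sm.families.links.Log()))
    res = model.fit(maxiter=300)
    converged = bool(getattr(res, "converged", True))

    coef = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "pvalue": res.pvalues}
    )

    adjusted_means, differences, pvalues = {}, {}, {}
    for lv in levels:
        cf = design.copy()
        for other in non_ref:
            cf[f"exposure[{other}]"] = 1.0 if other == lv else 0.0
        adjusted_means[lv] = float(res.predict(cf).mean())
    for lv in non_ref:
        differences[lv] = adjusted_means[lv] - adjusted_means[reference]
        pvalues[lv] = float(res.pvalues[f"exposure[{lv}]"])

    return CostModelResult(
        contrast=contrast_name or exposure,
        family="gamma",
        link="log",
        reference=reference,
        n=len(data),
        converged=converged,
        coefficients=coef,
        adjusted_means=adjusted_means,
        differences=differences,
        pvalues=pvalues,
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def stratified_cost_report(
    df: pd.DataFrame,
    outcomes: list[str],
    exposure: str = "exposure_group",
    adjusters: list[str] = (),
    reference: str = "S_app",
    zero_offset: float = 0.01,
) -> pd.DataFrame:
    """Four-group adjusted cost table versus the reference group.

    One row per exposure group per outcome, with the adjusted mean, the
    difference versus reference, the p-value and significance markers at
    0.05 / 0.01 / 0.001.  Groups absent from the data are flagged missing.
    """
    present = set(df[exposure].astype(str))
    if reference not in present:
        raise ValueError(f"reference group {reference!r} is empty")
    rows = []
    results = {
        outcome: fit_cost_model(
            df, outcome, exposure, adjusters, reference=reference, zero_offset=zero_offset
        )
        for outcome in outcomes
    }
    from .synthetic_ehr import EXPOSURE_GROUPS

    for outcome in outcomes:
        result = results[outcome]
        for grp in EXPOSURE_GROUPS:
            if grp not in present:
                rows.append(
                    {"outcome": outcome, "group": grp, "n": 0, "missing": True}
                )
                continue
            n = int((df[exposure].astype(str) == grp).sum())
            row = {
                "outcome": outcome,
                "group": grp,
                "n": n,
                "missing": False,
                "adjusted_cost": result.adjusted_means[grp],
            }
            if grp != result.reference:
                p = result.pvalues[grp]
                row.update(
                    difference_vs_reference=result.differences[grp],
                    pvalue=p,
                    significance=_stars(p),
                )
            else:
                row.update(difference_vs_reference=0.0, pvalue=np.nan, significance="")
            rows.append(row)
    return pd.DataFrame(rows)
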