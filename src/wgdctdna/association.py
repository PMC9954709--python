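"""Association statistics for binary cohort outcomes.

Implements the analyses a clinical-cohort study of ctDNA detection runs:
2x2 odds ratios with Wald (or profile-likelihood) confidence intervals and
two-sided Wald p-values, stratified association tables, Cohen's kappa for
inter-method agreement, and multivariable logistic regression with Wald
inference per term.

Point estimates are always the 2x2 cross-product (a*d)/(b*c); with a zero
cell the Haldane-Anscombe 0.5 correction is applied and the result flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TwoByTwo",
    "AssociationResult",
    "KappaResult",
    "LogisticFit",
    "DegenerateRatersError",
    "SeparationError",
    "odds_ratio",
    "stratified_association",
    "cohens_kappa",
    "fit_logistic",
    "multivariable_model",
    "association_report",
    "expand_two_by_two",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile
_CHI2_95 = 3.841458820694124


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-by-outcome counts: a/c exposed with/without the outcome,
    b/d unexposed with/without the outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str  # "wald" or "profile"
    corrected: bool = False  # Haldane-Anscombe 0.5 applied
    table: TwoByTwo | None = None


@dataclass(frozen=True)
class KappaResult:
    percent_agreement: float
    kappa: float
    n: int


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression fit with per-term Wald inference."""

    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    converged: bool
    n_used: int
    deviance: float

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    @property
    def conf_int(self) -> np.ndarray:
        lo = np.exp(self.coefficients - Z95 * self.standard_errors)
        hi = np.exp(self.coefficients + Z95 * self.standard_errors)
        return np.column_stack([lo, hi])

    @property
    def p_values(self) -> np.ndarray:
        z = self.coefficients / self.standard_errors
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.standard_errors,
                "odds_ratio": self.odds_ratios,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p_value": self.p_values,
            },
            index=self.terms,
        )


class DegenerateRatersError(ValueError):
    """Both raters are constant: chance agreement is 1 and kappa is undefined."""

    def __init__(self, percent_agreement: float):
        self.percent_agreement = percent_agreement
        super().__init__(
            "kappa undefined: both raters constant "
            f"(percent agreement {percent_agreement:.3f})"
        )


class SeparationError(RuntimeError):
    """Perfect separation: a coefficient diverges during the logistic fit."""


def _profile_ci(a: float, b: float, c: float, d: float, level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood CI for the log odds ratio of a 2x2 table.

    For fixed log-OR psi the intercept of the one-covariate logistic model is
    profiled out numerically; the interval is where the likelihood-ratio
    statistic stays under the chi-square(1) quantile.
    """

    def negll(beta0: float, psi: float) -> float:
        # exposed: logit p = beta0 + psi; unexposed: logit p = beta0
        ll = 0.0
        for succ, fail, eta_shift in ((a, c, psi), (b, d, 0.0)):
            eta = beta0 + eta_shift
            # log(1+e^eta) computed stably
            log1pexp = np.logaddexp(0.0, eta)
            ll += succ * (eta - log1pexp) + fail * (-log1pexp)
        return -ll

    def profile_negll(psi: float) -> float:
        res = optimize.minimize_scalar(negll, args=(psi,), bounds=(-30, 30), method="bounded")
        return res.fun

    psi_hat = math.log((a * d) / (b * c))
    ll_max = -profile_negll(psi_hat)
    crit = stats.chi2.ppf(level, df=1) / 2.0

    def boundary(psi: float) -> float:
        return (ll_max + profile_negll(psi)) - crit

    lo = optimize.brentq(boundary, psi_hat - 20.0, psi_hat)
    hi = optimize.brentq(boundary, psi_hat, psi_hat + 20.0)
    return math.exp(lo), math.exp(hi)


def odds_ratio(table: TwoByTwo, ci_method: str = "wald", level: float = 0.95) -> AssociationResult:
    """Odds ratio with confidence interval and two-sided Wald p-value.

    Zero cells get the Haldane-Anscombe 0.5 correction (flagged in the
    result); two zero cells in the same row or column leave the odds ratio
    undefined and raise.
    """
    if ci_method not in ("wald", "profile"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    zero_pairs = [(a, b), (c, d), (a, c), (b, d)]
    if any(x == 0 and y == 0 for x, y in zero_pairs):
        raise ValueError("odds ratio undefined: two zero cells share a row or column")
    corrected = 0 in (a, b, c, d)
    if corrected:
        af, bf, cf, df_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        work = TwoByTwo(a, b, c, d)  # keep raw counts on the result
    else:
        af, bf, cf, df_ = float(a), float(b), float(c), float(d)
        work = table
    or_hat = (af * df_) / (bf * cf)
    log_or = math.log(or_hat)
    se = math.sqrt(1.0 / af + 1.0 / bf + 1.0 / cf + 1.0 / df_)
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = 2.0 * stats.norm.sf(abs(log_or) / se)
    if ci_method == "wald":
        ci_low, ci_high = math.exp(log_or - z * se), math.exp(log_or + z * se)
    else:
        ci_low, ci_high = _profile_ci(af, bf, cf, df_, level)
    return AssociationResult(
        odds_ratio=or_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        method=ci_method,
        corrected=corrected,
        table=work,
    )


def cohens_kappa(calls_a: Sequence, calls_b: Sequence) -> KappaResult:
    """Percent agreement and chance-corrected agreement for two binary raters.

    Expected agreement uses the marginal product; when both raters are
    constant the chance agreement is 1 and kappa is undefined
    (:class:`DegenerateRatersError`, which still carries the agreement).
    """
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("calls must be equal-length non-empty vectors")
    n = len(a)
    po = float(np.mean(a == b))
    levels = sorted(set(a.tolist()) | set(b.tolist()))
    pe = 0.0
    for lev in levels:
        pe += float(np.mean(a == lev)) * float(np.mean(b == lev))
    if pe >= 1.0 - 1e-15:
        raise DegenerateRatersError(po)
    kappa = (po - pe) / (1.0 - pe)
    return KappaResult(percent_agreement=po, kappa=kappa, n=n)


def fit_logistic(
    design: pd.DataFrame,
    outcome: Sequence,
    add_intercept: bool = True,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS.

    Rows with any missing covariate or outcome are dropped (complete-case).
    Perfect separation is reported as an error naming the diverging term
    (|coefficient| > 15 on the log-odds scale).
    """
    import statsmodels.api as sm

    X = pd.DataFrame(design).apply(pd.to_numeric)
    y = pd.Series(np.asarray(outcome, dtype=float), index=X.index, name="outcome")
    keep = X.notna().all(axis=1) & y.notna()
    X, y = X.loc[keep], y.loc[keep]
    if len(X) <= X.shape[1] + int(add_intercept):
        raise ValueError("not enough complete cases to fit the model")
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=max_iter, tol=tol)
        except Exception as exc:  # pragma: no cover - statsmodels failure path
            raise SeparationError(f"logistic fit failed: {exc}") from exc
    coefs = np.asarray(res.params)
    diverged = np.abs(coefs) > 15.0
    if diverged.any():
        bad = [t for t, flag in zip(X.columns, diverged) if flag]
        raise SeparationError(f"perfect separation suspected for term(s): {bad}")
    if not res.converged:
        raise SeparationError("logistic fit did not converge")
    return LogisticFit(
        terms=list(X.columns),
        coefficients=coefs,
        standard_errors=np.asarray(res.bse),
        converged=bool(res.converged),
        n_used=len(X),
        deviance=float(res.deviance),
    )


# ---------------------------------------------------------------------------
# cohort-table analyses
# ---------------------------------------------------------------------------

def _as_binary(series: pd.Series, positive=None) -> pd.Series:
    vals = series.dropna().unique()
    if positive is None:
        if set(vals) <= {0, 1} or set(vals) <= {False, True}:
            return series.astype(float)
        raise ValueError(
            f"column {series.name!r} is not binary; pass its positive level explicitly"
        )
    return (series == positive).astype(float).where(series.notna())


def two_by_two_from_cohort(
    cohort: pd.DataFrame, exposure: str, outcome: str,
    exposure_positive=None, outcome_positive=None,
) -> TwoByTwo:
    sub = cohort[[exposure, outcome]].dropna()
    e = _as_binary(sub[exposure], exposure_positive)
    o = _as_binary(sub[outcome], outcome_positive)
    return TwoByTwo(
        a=int(((e == 1) & (o == 1)).sum()),
        b=int(((e == 0) & (o == 1)).sum()),
        c=int(((e == 1) & (o == 0)).sum()),
        d=int(((e == 0) & (o == 0)).sum()),
    )


def stratified_association(
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str,
    strata: str | None = None,
    exposure_positive=None,
    outcome_positive=None,
    ci_method: str = "wald",
) -> pd.DataFrame:
    """Odds ratios for exposure vs outcome, overall and within each stratum.

    Returns one row per stratum (stratum ``"overall"`` first) with the 2x2
    counts, OR, CI and Wald p-value.  Strata where the exposure or outcome is
    constant are flagged with NaN estimates and a warning.
    """
    groups: list[tuple[str, pd.DataFrame]] = [("overall", cohort)]
    if strata is not None:
        for level, sub in cohort.groupby(strata, observed=True, sort=True):
            groups.append((str(level), sub))
    rows = []
    for name, sub in groups:
        if len(sub) == 0:
            warnings.warn(f"stratum {name!r} is empty; skipped")
            continue
        tab = two_by_two_from_cohort(sub, exposure, outcome, exposure_positive, outcome_positive)
        try:
            res = odds_ratio(tab, ci_method=ci_method)
            rows.append(
                dict(stratum=name, a=tab.a, b=tab.b, c=tab.c, d=tab.d,
                     odds_ratio=res.odds_ratio, ci_low=res.ci_low,
                     ci_high=res.ci_high, p_value=res.p_value,
                     corrected=res.corrected)
            )
        except ValueError:
            warnings.warn(f"odds ratio undefined in stratum {name!r} (constant margin)")
            rows.append(
                dict(stratum=name, a=tab.a, b=tab.b, c=tab.c, d=tab.d,
                     odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                     p_value=np.nan, corrected=False)
            )
    return pd.DataFrame(rows).set_index("stratum")


#: categorical covariates of the multivariable ctDNA-detection model and
#: their reference levels; tumor size enters as continuous mm.
MULTIVARIABLE_TERMS: Mapping[str, object] = {
    "wgd": (False, True),
    "uicc_stage": ("I", ("II", "III")),
    "location": ("right colon", ("left colon", "rectum")),
    "histology": ("adenocarcinoma", ("other",)),
    "venous_invasion": (False, True),
    "mmr": ("proficient", ("deficient",)),
}


def build_design(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Dummy-coded design matrix for the multivariable detection model."""
    needed = list(MULTIVARIABLE_TERMS) + ["size_mm", "ctdna_detected"]
    missing = [c for c in needed if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table is missing columns: {missing}")
    cols: dict[str, pd.Series] = {}
    for name, spec in MULTIVARIABLE_TERMS.items():
        ref, non_ref = spec
        if isinstance(non_ref, tuple):
            for level in non_ref:
                cols[f"{name}[{level}]"] = (cohort[name] == level).astype(float).where(
                    cohort[name].notna()
                )
        else:  # binary with boolean positive level
            cols[name] = (cohort[name] == non_ref).astype(float).where(cohort[name].notna())
    cols["size_mm"] = pd.to_numeric(cohort["size_mm"], errors="coerce")
    X = pd.DataFrame(cols, index=cohort.index)
    y = cohort["ctdna_detected"].astype(float)
    return X, y


def multivariable_model(cohort: pd.DataFrame) -> LogisticFit:
    """Multivariable logistic model of ctDNA detection on WGD, stage, type,
    venous invasion, size (per mm), location and MMR status."""
    X, y = build_design(cohort)
    return fit_logistic(X, y)


def two_by_two_from_reference(
    counts: pd.DataFrame, characteristic: str, level: str, stratum: str = "overall"
) -> TwoByTwo:
    """Build the 2x2 table for one characteristic level vs its reference from
    a stratum-level count table (columns: stratum, characteristic, level,
    is_reference, ctdna_pos, ctdna_neg)."""
    block = counts[(counts["stratum"] == stratum) & (counts["characteristic"] == characteristic)]
    exposed = block[block["level"] == level]
    ref = block[block["is_reference"] == 1]
    if len(exposed) != 1 or len(ref) != 1:
        raise KeyError(
            f"no unique counts for {characteristic}={level!r} (stratum {stratum!r})"
        )
    return TwoByTwo(
        a=int(exposed["ctdna_pos"].iloc[0]),
        b=int(ref["ctdna_pos"].iloc[0]),
        c=int(exposed["ctdna_neg"].iloc[0]),
        d=int(ref["ctdna_neg"].iloc[0]),
    )


def expand_two_by_two(
    table: TwoByTwo, exposure: str = "exposure", outcome: str = "outcome"
) -> pd.DataFrame:
    """Patient-level table reconstructed from 2x2 counts (for exact
    reproduction of count-derived statistics through model-based code paths)."""
    rows = (
        [(1, 1)] * table.a + [(0, 1)] * table.b + [(1, 0)] * table.c + [(0, 0)] * table.d
    )
    return pd.DataFrame(rows, columns=[exposure, outcome])


# ---------------------------------------------------------------------------
# stratified report
# ---------------------------------------------------------------------------

REPORT_CHARACTERISTICS = {
    "uicc_stage": ("I", ["II", "III"]),
    "location": ("right colon", ["left colon", "rectum"]),
    "histology": ("adenocarcinoma", ["other"]),
    "venous_invasion": (False, [True]),
    "mmr": ("proficient", ["deficient"]),
    "wgd": (False, [True]),
}


def association_report(
    cohort: pd.DataFrame,
    outcome: str = "ctdna_detected",
    strata: str = "uicc_stage",
    ci_method: str = "wald",
) -> pd.DataFrame:
    """Characteristic-by-stratum association table.

    For every characteristic level (vs its reference) and every stratum
    (plus "overall"), reports the 2x2 counts, odds ratio, CI and Wald
    p-value; tumor size is summarised as median (range) with a per-mm OR
    from a single-covariate logistic model.  A ``ci_covers_1`` column flags
    cells whose interval includes the null.
    """
    required = set(REPORT_CHARACTERISTICS) | {outcome, "size_mm"}
    missing = sorted(required - set(cohort.columns))
    if missing:
        raise KeyError(f"cohort table is missing columns: {missing}")
    columns = [
        "characteristic", "level", "stratum", "n_pos", "n_neg",
        "odds_ratio", "ci_low", "ci_high", "p_value", "ci_covers_1", "note",
    ]
    if len(cohort) == 0:
        return pd.DataFrame(columns=columns)

    strata_levels = ["overall"] + sorted(cohort[strata].dropna().unique().tolist())
    rows = []

    def subset(stratum):
        return cohort if stratum == "overall" else cohort[cohort[strata] == stratum]

    for char, (ref, levels) in REPORT_CHARACTERISTICS.items():
        for level in levels:
            for stratum in strata_levels:
                if char == strata and stratum != "overall":
                    continue
                sub = subset(stratum)
                sub = sub[sub[char].isin([ref, level])]
                tab = two_by_two_from_cohort(sub, char, outcome, exposure_positive=level)
                entry = dict(
                    characteristic=char, level=str(level), stratum=str(stratum),
                    n_pos=tab.a + tab.b, n_neg=tab.c + tab.d,
                    odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                    p_value=np.nan, ci_covers_1=np.nan, note="",
                )
                try:
                    res = odds_ratio(tab, ci_method=ci_method)
                    entry.update(
                        odds_ratio=res.odds_ratio, ci_low=res.ci_low,
                        ci_high=res.ci_high, p_value=res.p_value,
                        ci_covers_1=bool(res.ci_low <= 1.0 <= res.ci_high),
                        note="corrected" if res.corrected else "",
                    )
                except ValueError:
                    entry["note"] = "undefined"
                rows.append(entry)

    # continuous tumor size: median (range) and per-mm OR
    for stratum in strata_levels:
        sub = subset(stratum)[["size_mm", outcome]].dropna()
        entry = dict(
            characteristic="size_mm", level="per mm", stratum=str(stratum),
            n_pos=int(sub[outcome].sum()), n_neg=int((1 - sub[outcome]).sum()),
            odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
            p_value=np.nan, ci_covers_1=np.nan, note="",
        )
        if len(sub) > 2 and sub[outcome].nunique() == 2:
            try:
                fit = fit_logistic(sub[["size_mm"]], sub[outcome])
                frame = fit.summary_frame().loc["size_mm"]
                entry.update(
                    odds_ratio=frame["odds_ratio"], ci_low=frame["ci_low"],
                    ci_high=frame["ci_high"], p_value=frame["p_value"],
                    ci_covers_1=bool(frame["ci_low"] <= 1.0 <= frame["ci_high"]),
                    note=f"median {sub['size_mm'].median():g} "
                         f"({sub['size_mm'].min():g}, {sub['size_mm'].max():g})",
                )
            except (SeparationError, ValueError) as exc:
                entry["note"] = f"unfit: {exc}"
        rows.append(entry)
    return pd.DataFrame(rows, columns=columns)


def render_report(report: pd.DataFrame) -> str:
    """Aligned plain-text rendering of :func:`association_report` output."""
    if len(report) == 0:
        return "(empty cohort)"
    shown = report.copy()
    for col in ("odds_ratio", "ci_low", "ci_high"):
        shown[col] = shown[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    shown["p_value"] = shown["p_value"].map(lambda v: "" if pd.isna(v) else f"{v:.3g}")
    return shown.to_string(index=False)
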