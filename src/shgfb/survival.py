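"""Prognostic analysis of ln F/B (or ln R) against survival endpoints.

Endpoints are metastasis-free survival (MFS), overall survival (OS) and
progression-free survival under tamoxifen (PFS), all in months with 0/1
event flags.  The marker is analysed two ways, mirroring common biomarker
practice:

* stratified into quartiles (Q1 lowest ... Q4 highest ln F/B) with
  Kaplan-Meier curves and a 1-df log-rank test for trend across the ordered
  groups (default scores 1..4);
* as a continuous covariate in Cox proportional-hazards regression,
  univariately and adjusted for age band, menopausal status, tumor size,
  tumor grade, PgR and HER2 status (ER enters through subsetting, not as a
  covariate).  Ties use the Breslow approximation by default (Efron
  available).  HR = exp(coef) with Wald 95% CIs.

Records with missing covariates are dropped from multivariate fits
(complete-case) and the dropped count is reported; nothing is imputed.
No multiple-testing correction is applied: each endpoint/subset is tested
at two-sided 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .image_io import (
    AGE_BANDS, GRADES, MENOPAUSAL, POS_NEG, SIZE_BANDS,
    PatientRecord, records_to_frame,
)

logger = logging.getLogger(__name__)

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")

ENDPOINTS = {
    "MFS": ("mfs_time", "mfs_event"),
    "OS": ("os_time", "os_event"),
    "PFS": ("pfs_time", "pfs_event"),
}

#: adjustment set of the multivariate Cox model (ER handled by subsetting)
MULTIVARIATE_COVARIATES = ("age_band", "menopausal", "size_band", "grade", "pgr", "her2")

#: reference level of each categorical covariate (first = reference)
CATEGORY_LEVELS = {
    "age_band": AGE_BANDS,        # reference <=40
    "menopausal": MENOPAUSAL,     # reference pre
    "size_band": SIZE_BANDS,      # reference pT1 (<=2 cm)
    "grade": GRADES,              # reference I
    "er": POS_NEG[::-1],          # reference neg
    "pgr": POS_NEG[::-1],
    "her2": POS_NEG[::-1],
}


class CoxConvergenceError(RuntimeError):
    """Partial-likelihood maximisation failed or the fit is degenerate."""


@dataclass
class QuartileAssignment:
    patient_id: str
    quartile: str
    cutpoints: tuple[float, float, float]


@dataclass
class KMCurve:
    """Product-limit estimate for one group."""

    label: str
    times: np.ndarray           # event/censoring time grid (ascending)
    survival: np.ndarray        # S(t) just after each time
    at_risk_grid: np.ndarray    # time points at which at-risk counts are reported
    at_risk: np.ndarray         # number at risk at each grid point
    censor_times: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class TrendTestResult:
    chi_square: float
    p_value: float
    scores: tuple[float, ...]
    df: int = 1


@dataclass
class CoxFit:
    """Hazard ratios with Wald 95% CIs and p-values, one row per term."""

    summary: pd.DataFrame  # index: term; columns: coef, hr, ci_low, ci_high, p
    model: str             # "univariate" | "multivariate"
    endpoint: str
    n_used: int
    n_events: int
    n_dropped_missing: int
    tie_method: str

    def hr(self, term: str) -> float:
        return float(self.summary.loc[term, "hr"])

    def p(self, term: str) -> float:
        return float(self.summary.loc[term, "p"])

    def coef(self, term: str) -> float:
        return float(self.summary.loc[term, "coef"])


# ---------------------------------------------------------------------------
# quartiles

def quartile_cutpoints(values: np.ndarray) -> tuple[float, float, float]:
    """Empirical 25/50/75 percentiles, linear interpolation between order
    statistics."""
    q = np.percentile(np.asarray(values, dtype=float), [25, 50, 75], method="linear")
    return (float(q[0]), float(q[1]), float(q[2]))


def assign_quartiles(values: Sequence[tuple[str, float]]) -> list[QuartileAssignment]:
    """Split patients into four groups at the marker's quartile cutpoints.

    Assignment: value <= 25th percentile -> Q1, <= median -> Q2,
    <= 75th percentile -> Q3, else Q4.  Tied values land in the same
    quartile; if every value is identical all patients are Q1 (degenerate
    but well-defined).
    """
    vals = np.array([v for _, v in values], dtype=float)
    if np.isnan(vals).any():
        raise ValueError("missing marker values must be excluded before quartile assignment")
    if len(vals) < 4:
        raise ValueError(f"need at least 4 marker values for quartiles, got {len(vals)}")
    cuts = quartile_cutpoints(vals)
    out = []
    for (pid, v) in values:
        if v <= cuts[0]:
            q = "Q1"
        elif v <= cuts[1]:
            q = "Q2"
        elif v <= cuts[2]:
            q = "Q3"
        else:
            q = "Q4"
        out.append(QuartileAssignment(patient_id=pid, quartile=q, cutpoints=cuts))
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier

def km_estimate(
    times: Sequence[float],
    events: Sequence[int],
    group_labels: Optional[Sequence[str]] = None,
    at_risk_grid: Optional[Sequence[float]] = None,
) -> list[KMCurve]:
    """Product-limit survival estimate per group.

    at_risk_grid defaults to 6 evenly spaced points from 0 to the last
    observed time (the "patients at risk" row under a KM plot).  Empty
    groups are dropped with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if (times <= 0).any():
        raise ValueError("all times must be > 0")
    if group_labels is None:
        group_labels = np.array(["all"] * len(times))
    else:
        group_labels = np.asarray(group_labels)
    if at_risk_grid is None:
        at_risk_grid = np.linspace(0, times.max(), 6)
    at_risk_grid = np.asarray(at_risk_grid, dtype=float)

    curves = []
    for label in pd.unique(group_labels):
        sel = group_labels == label
        if not sel.any():
            logger.warning("group %s empty: dropped from KM estimate", label)
            continue
        t, e = times[sel], events[sel]
        kmf = KaplanMeierFitter()
        kmf.fit(t, e, label=str(label))
        timeline = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        # drop the t=0 anchor lifelines prepends; S before first time is 1
        if timeline[0] == 0 and 0 not in t:
            timeline, surv = timeline[1:], surv[1:]
        at_risk = np.array([(t >= g).sum() for g in at_risk_grid])
        curves.append(KMCurve(
            label=str(label), times=timeline, survival=surv,
            at_risk_grid=at_risk_grid, at_risk=at_risk,
            censor_times=np.sort(t[e == 0]), n=int(sel.sum()),
        ))
    return curves


# ---------------------------------------------------------------------------
# log-rank test for trend

def logrank_trend(
    times: Sequence[float],
    events: Sequence[int],
    group_labels: Sequence[str],
    ordered_groups: Sequence[str],
    scores: Optional[Sequence[float]] = None,
) -> TrendTestResult:
    """1-df chi-square log-rank test for a monotone trend across ordered
    survival groups.

    At each event time the observed-minus-expected event count of each group
    is weighted by its score (default equally spaced 1..k); the squared
    weighted sum over event times, divided by its hypergeometric variance,
    is chi-square(1) under the null.  With two groups and scores {0, 1} this
    reduces exactly to the ordinary log-rank statistic.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group_labels = np.asarray(group_labels)
    k = len(ordered_groups)
    if k < 2:
        raise ValueError("need at least 2 ordered groups")
    if scores is None:
        scores = np.arange(1, k + 1, dtype=float)
    else:
        scores = np.asarray(scores, dtype=float)
        if len(scores) != k:
            raise ValueError("one score per group required")
    gidx = {g: i for i, g in enumerate(ordered_groups)}
    unknown = set(group_labels) - set(ordered_groups)
    if unknown:
        raise ValueError(f"labels {unknown} not in ordered_groups")
    g = np.array([gidx[lab] for lab in group_labels])

    U = 0.0
    V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        if n == 0:
            continue
        d_g = np.bincount(g[(times == t) & (events == 1)], minlength=k).astype(float)
        n_g = np.bincount(g[at_risk], minlength=k).astype(float)
        d = d_g.sum()
        p_g = n_g / n
        U += float(scores @ (d_g - d * p_g))
        if n > 1:
            mult = d * (n - d) / (n - 1)
            V += mult * float(p_g @ scores**2 - (p_g @ scores) ** 2)
    if V <= 0:
        raise ValueError(
            "trend test undefined: no between-group variance in the risk sets "
            "(e.g. all events confined to a single populated group)"
        )
    chi2 = U * U / V
    return TrendTestResult(chi_square=float(chi2),
                           p_value=float(stats.chi2.sf(chi2, df=1)),
                           scores=tuple(scores))


# ---------------------------------------------------------------------------
# Cox regression

def _design_matrix(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Design matrix with dummy coding against the reference levels
    (age <=40, premenopausal, pT1, grade I, receptor negative)."""
    cols = {}
    for cov in covariates:
        if cov in CATEGORY_LEVELS:
            levels = CATEGORY_LEVELS[cov]
            for level in levels[1:]:
                cols[f"{cov}[{level}]"] = (df[cov] == level).astype(float)
        else:
            cols[cov] = pd.to_numeric(df[cov], errors="raise").astype(float)
    return pd.DataFrame(cols, index=df.index)


def cox_fit(
    records: Sequence[PatientRecord] | pd.DataFrame,
    endpoint: str,
    covariates: Sequence[str],
    model: str = "univariate",
    tie_method: str = "breslow",
    alpha: float = 0.05,
) -> CoxFit:
    """Cox proportional-hazards fit for one endpoint.

    covariates are column names; categorical ones are dummy-coded against
    the reference levels in CATEGORY_LEVELS, numeric ones (ln_fb, ln_r)
    enter as continuous.  Complete-case: rows missing any covariate or the
    endpoint are dropped and counted in n_dropped_missing.
    """
    from statsmodels.duration.hazard_regression import PHReg

    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {tuple(ENDPOINTS)}")
    if tie_method not in ("breslow", "efron"):
        raise ValueError("tie_method must be 'breslow' or 'efron'")
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(list(records))
    tcol, ecol = ENDPOINTS[endpoint]
    needed = [tcol, ecol, *covariates]
    full = df[needed]
    complete = full.dropna()
    n_dropped = len(full) - len(complete)
    if n_dropped:
        logger.info("%s %s Cox fit: %d record(s) dropped for missing values",
                    endpoint, model, n_dropped)
    if len(complete) < 2:
        raise ValueError("fewer than 2 complete records")
    X = _design_matrix(complete, covariates)
    keep = [c for c in X.columns if X[c].nunique() > 1]
    X = X[keep]
    if X.shape[1] == 0:
        raise ValueError("no covariate with variation after complete-case deletion")
    times = complete[tcol].to_numpy(dtype=float)
    status = complete[ecol].to_numpy(dtype=int)

    mod = PHReg(times, X.to_numpy(), status=status, ties=tie_method)
    import warnings as _warnings
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # separation diagnosed below, not by the optimizer
            res = mod.fit(maxiter=200, disp=False)
    except Exception as exc:  # singular information, failed line search, ...
        raise CoxConvergenceError(f"{endpoint} {model} Cox fit failed: {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not (np.isfinite(params).all() and np.isfinite(bse).all()) or (np.abs(params) > 25).any():
        raise CoxConvergenceError(
            f"{endpoint} {model} Cox fit degenerate (possible complete separation): "
            f"coef={params}, se={bse}"
        )
    # a category level with no events gives a monotone likelihood for its
    # dummy: finite software output, unbounded Wald CI.  Flag, don't fail.
    quasi = [c for c, s in zip(X.columns, bse) if s > 1e3]
    if quasi:
        logger.warning("%s %s Cox fit: unbounded Wald interval for %s "
                       "(level with no observed events)", endpoint, model, quasi)
    z = stats.norm.ppf(1 - alpha / 2)
    with np.errstate(over="ignore"):
        summary = pd.DataFrame({
            "coef": params,
            "se": bse,
            "hr": np.exp(params),
            "ci_low": np.exp(params - z * bse),
            "ci_high": np.exp(params + z * bse),
            "p": 2 * stats.norm.sf(np.abs(params) / bse),
        }, index=list(X.columns))
    return CoxFit(summary=summary, model=model, endpoint=endpoint,
                  n_used=len(complete), n_events=int(status.sum()),
                  n_dropped_missing=n_dropped, tie_method=tie_method)


# ---------------------------------------------------------------------------
# group association summaries

def group_summary_tests(
    records: Sequence[PatientRecord] | pd.DataFrame,
    grouping: str,
    value: str = "ln_fb",
) -> tuple[pd.DataFrame, float, str]:
    """Association of the marker with a clinical covariate.

    Returns (table, p, test_name): per-group n, percentage, median and
    interquartile range of the marker; Kruskal-Wallis p for >=3 groups,
    two-sided Wilcoxon rank-sum (Mann-Whitney) p for 2 groups.  Empty
    groups are dropped.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(list(records))
    sub = df[[grouping, value]].dropna()
    levels = [g for g in CATEGORY_LEVELS.get(grouping, sorted(sub[grouping].unique()))
              if (sub[grouping] == g).any()]
    if len(levels) < 2:
        raise ValueError("need at least 2 non-empty groups")
    samples = [sub.loc[sub[grouping] == g, value].to_numpy(dtype=float) for g in levels]
    n_total = sum(len(s) for s in samples)
    rows = []
    for g, s in zip(levels, samples):
        q25, q75 = np.percentile(s, [25, 75], method="linear")
        rows.append({
            "group": g, "n": len(s), "pct": 100.0 * len(s) / n_total,
            "median": float(np.median(s)), "iqr": float(q75 - q25),
        })
    if len(levels) == 2:
        test_name = "wilcoxon_rank_sum"
        p = float(stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided").pvalue)
    else:
        test_name = "kruskal_wallis"
        p = float(stats.kruskal(*samples).pvalue)
    return pd.DataFrame(rows), p, test_name


# ---------------------------------------------------------------------------
# full prognostic report

@dataclass
class PrognosticReport:
    """Everything the quartile + Cox analysis produces for one subset."""

    marker: str
    subset: Optional[str]
    n: int
    quartiles: list[QuartileAssignment]
    cutpoints: tuple[float, float, float]
    km_curves: dict[str, list[KMCurve]] = field(default_factory=dict)
    trend_tests: dict[str, TrendTestResult] = field(default_factory=dict)
    cox_univariate: dict[str, CoxFit] = field(default_factory=dict)
    cox_multivariate: dict[str, CoxFit] = field(default_factory=dict)

    def write(self, out_dir) -> None:
        """Emit km_curves.csv, trend_tests.csv, cox_univariate.csv,
        cox_multivariate.csv under out_dir."""
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        km_rows = []
        for ep, curves in self.km_curves.items():
            for c in curves:
                for t, s in zip(c.times, c.survival):
                    km_rows.append({"endpoint": ep, "group": c.label,
                                    "time": t, "survival": s})
        pd.DataFrame(km_rows).to_csv(out / "km_curves.csv", index=False)
        pd.DataFrame([
            {"endpoint": ep, "chi_square": t.chi_square, "df": t.df, "p": t.p_value}
            for ep, t in self.trend_tests.items()
        ]).to_csv(out / "trend_tests.csv", index=False)
        for name, fits in (("cox_univariate", self.cox_univariate),
                           ("cox_multivariate", self.cox_multivariate)):
            rows = []
            for ep, fit in fits.items():
                s = fit.summary.reset_index(names="term")
                s.insert(0, "endpoint", ep)
                s["n_used"] = fit.n_used
                rows.append(s)
            if rows:
                pd.concat(rows).to_csv(out / f"{name}.csv", index=False)


def run_prognostic_analysis(
    records: Sequence[PatientRecord] | pd.DataFrame,
    marker: str = "ln_fb",
    subset: Optional[str] = None,
    endpoints: Sequence[str] = ("MFS", "OS", "PFS"),
    multivariate: bool = True,
    tie_method: str = "breslow",
) -> PrognosticReport:
    """Quartile KM curves, trend tests and Cox models for one cohort subset.

    subset is a pandas query string over the cohort columns (e.g.
    ``"er == 'pos'"``).  Patients with a missing marker are excluded;
    subsets smaller than 8 are refused.  Endpoints without any usable
    (time, event) pair are skipped.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(list(records))
    if subset:
        df = df.query(subset)
    df = df[df[marker].notna()].reset_index(drop=True)
    if len(df) < 8:
        raise ValueError(
            f"subset too small for prognostic analysis: {len(df)} patients (< 8)"
        )
    qs = assign_quartiles(list(zip(df["patient_id"], df[marker].astype(float))))
    qmap = {q.patient_id: q.quartile for q in qs}
    df = df.assign(quartile=[qmap[p] for p in df["patient_id"]])
    report = PrognosticReport(marker=marker, subset=subset, n=len(df),
                              quartiles=qs, cutpoints=qs[0].cutpoints)
    for ep in endpoints:
        tcol, ecol = ENDPOINTS[ep]
        if tcol not in df or df[tcol].isna().all():
            continue
        epdf = df[df[tcol].notna() & df[ecol].notna()]
        report.km_curves[ep] = km_estimate(
            epdf[tcol], epdf[ecol].astype(int), epdf["quartile"])
        try:
            report.trend_tests[ep] = logrank_trend(
                epdf[tcol], epdf[ecol].astype(int), epdf["quartile"], QUARTILE_LABELS)
        except ValueError as exc:
            logger.warning("%s trend test skipped: %s", ep, exc)
        report.cox_univariate[ep] = cox_fit(
            epdf, ep, [marker], model="univariate", tie_method=tie_method)
        if multivariate:
            try:
                report.cox_multivariate[ep] = cox_fit(
                    epdf, ep, [marker, *MULTIVARIATE_COVARIATES],
                    model="multivariate", tie_method=tie_method)
            except (CoxConvergenceError, ValueError) as exc:
                logger.warning("%s multivariate Cox skipped: %s", ep, exc)
    return report
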