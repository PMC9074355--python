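"""Cohort-level comparison statistics for Ki-67 scoring methods.

Covers the analysis set used to compare visual and digital Ki-67
assessment: Pearson chi-squared association tables, Bland-Altman
agreement, competing-risks cumulative incidence of breast-cancer death
(Aalen-Johansen, other-cause death as the competing event), Gray's
K-sample test, cause-specific Cox proportional hazards and Harrell's
concordance.

Implementation notes: the Aalen-Johansen point estimate and its
delta-method variance are computed here directly (they must reduce
exactly to 1 - Kaplan-Meier without competing events); Gray's test is
delegated to R's ``cmprsk`` package through an Rscript subprocess, the
field-standard implementation; Cox models use statsmodels' PHReg
(Efron tie handling by default, Breslow switchable); Harrell's C uses
lifelines.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CIFCurve",
    "BAResult",
    "pearson_chi2",
    "bland_altman",
    "cumulative_incidence",
    "gray_test",
    "cox_ph",
    "harrell_c",
    "build_table1",
    "cohort_to_dataframe",
    "mitoses_quartile_bins",
]

EVENT_OF_INTEREST = "bc_death"
COMPETING_EVENT = "other_death"


def cohort_to_dataframe(records) -> pd.DataFrame:
    """Flatten CohortRecord objects into an analysis DataFrame."""
    return pd.DataFrame([vars(r) for r in records])


# ---------------------------------------------------------------------------
# Pearson chi-squared


def pearson_chi2(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on an r x c count table."""
    t = np.asarray(table, dtype=float)
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero row or column marginal")
    stat, p, df, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


# ---------------------------------------------------------------------------
# Bland-Altman


@dataclass
class BAResult:
    """Bland-Altman agreement between a comparator and a reference."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    differences: np.ndarray
    slope_diff_on_mean: float


def bland_altman(reference, comparator) -> BAResult:
    """Differences (comparator - reference) against pair means.

    Limits of agreement are bias +/- 1.96 sd (n-1 denominator); the
    slope of differences on means quantifies proportional bias.
    """
    ref = np.asarray(reference, dtype=float)
    comp = np.asarray(comparator, dtype=float)
    if ref.shape != comp.shape:
        raise ValueError("paired series must have equal length")
    if ref.size < 2:
        raise ValueError("need at least 2 pairs")
    diffs = comp - ref
    means = (comp + ref) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if np.ptp(means) > 0:
        slope = float(np.polyfit(means, diffs, 1)[0])
    else:
        slope = 0.0
    return BAResult(bias=bias, sd_diff=sd, loa_low=bias - 1.96 * sd,
                    loa_high=bias + 1.96 * sd, means=means,
                    differences=diffs, slope_diff_on_mean=slope)


# ---------------------------------------------------------------------------
# Aalen-Johansen cumulative incidence


@dataclass
class CIFCurve:
    """Step cumulative-incidence function for one group and event type."""

    group: object
    event_type: str
    times: np.ndarray       # event times (any cause), ascending
    cif: np.ndarray         # CIF right after each time
    variance: np.ndarray
    n_at_risk: np.ndarray

    def at(self, t: float) -> float:
        """CIF evaluated at time t (right-continuous step function)."""
        i = np.searchsorted(self.times, t, side="right") - 1
        return float(self.cif[i]) if i >= 0 else 0.0

    def variance_at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return float(self.variance[i]) if i >= 0 else 0.0

    def ci_at(self, t: float, alpha: float = 0.05):
        """Pointwise log(-log) confidence interval at time t."""
        f = self.at(t)
        v = self.variance_at(t)
        if f <= 0.0 or f >= 1.0 or v <= 0:
            return (f, f)
        z = sps.norm.ppf(1 - alpha / 2)
        theta = z * np.sqrt(v) / (f * np.log(f))
        lo, hi = sorted((f ** np.exp(theta), f ** np.exp(-theta)))
        return (float(lo), float(hi))


def _aalen_johansen(time, status) -> tuple[np.ndarray, ...]:
    """AJ estimator for cause 1; status: 0 censored, 1 cause, 2 competing.

    Returns (event_times, cif, variance, n_at_risk).  Variance is the
    delta-method (Marubini-Valsecchi) estimator.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    order = np.argsort(time, kind="stable")
    time, status = time[order], status[order]
    n = len(time)
    uniq = np.unique(time[status > 0])

    s_prev = 1.0
    cif = []
    svals = []   # S(t_{j-1})
    d1s, ds, ns = [], [], []
    f = 0.0
    for t in uniq:
        at_risk = int((time >= t).sum())
        d1 = int(((time == t) & (status == 1)).sum())
        d_all = int(((time == t) & (status > 0)).sum())
        f += s_prev * d1 / at_risk
        cif.append(f)
        svals.append(s_prev)
        d1s.append(d1)
        ds.append(d_all)
        ns.append(at_risk)
        s_prev *= 1.0 - d_all / at_risk

    cif = np.asarray(cif)
    svals = np.asarray(svals)
    d1s = np.asarray(d1s, dtype=float)
    ds = np.asarray(ds, dtype=float)
    ns = np.asarray(ns, dtype=float)

    var = np.zeros_like(cif)
    for i in range(len(uniq)):
        ft = cif[i]
        gap = ft - cif[: i + 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            term1 = np.where(ns[: i + 1] > ds[: i + 1],
                             gap**2 * ds[: i + 1]
                             / (ns[: i + 1] * (ns[: i + 1] - ds[: i + 1])),
                             0.0)
        term2 = (svals[: i + 1] ** 2 * (ns[: i + 1] - d1s[: i + 1])
                 / ns[: i + 1] * d1s[: i + 1] / ns[: i + 1] ** 2)
        term3 = gap * svals[: i + 1] * d1s[: i + 1] / ns[: i + 1] ** 2
        var[i] = term1.sum() + term2.sum() - 2 * term3.sum()
    return uniq, cif, np.clip(var, 0.0, None), np.array(
        [(time >= t).sum() for t in uniq], dtype=float)


def _status_codes(df: pd.DataFrame, event_of_interest: str) -> np.ndarray:
    ev = df["event"].to_numpy()
    status = np.zeros(len(df), dtype=int)
    status[ev == event_of_interest] = 1
    status[(ev != event_of_interest) & (ev != "censored")] = 2
    return status


def cumulative_incidence(df: pd.DataFrame, group_col: str | None = None,
                         event_of_interest: str = EVENT_OF_INTEREST
                         ) -> dict[object, CIFCurve]:
    """Aalen-Johansen CIF of the event of interest per group.

    ``df`` needs ``time_years`` and ``event`` (bc_death / other_death /
    censored) columns.  Competing causes stay in the risk set through
    the all-cause Kaplan-Meier factor, so without competing events the
    estimate reduces exactly to 1 - KM.
    """
    groups = ([(None, df)] if group_col is None
              else list(df.groupby(group_col, observed=True)))
    out = {}
    for g, sub in groups:
        if len(sub) == 0:
            raise ValueError(f"empty group {g!r}")
        status = _status_codes(sub, event_of_interest)
        times, cif, var, n_risk = _aalen_johansen(
            sub["time_years"].to_numpy(), status)
        out[g] = CIFCurve(group=g, event_type=event_of_interest,
                          times=times, cif=cif, variance=var,
                          n_at_risk=n_risk)
    return out


# ---------------------------------------------------------------------------
# Gray's test (R cmprsk bridge)

_R_SCRIPT = """
suppressMessages(library(cmprsk))
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1])
res <- cuminc(d$time, d$status, d$group, rho = as.numeric(args[3]),
              cencode = 0)
tests <- res$Tests
row <- tests[rownames(tests) == "1", , drop = FALSE]
out <- list(stat = unname(row[1, "stat"]), pv = unname(row[1, "pv"]),
            df = unname(row[1, "df"]))
writeLines(sprintf('{"stat": %.12g, "pv": %.12g, "df": %d}',
                   out$stat, out$pv, as.integer(out$df)), args[2])
"""


def gray_test(df: pd.DataFrame, group_col: str,
              event_of_interest: str = EVENT_OF_INTEREST,
              rho: float = 0.0) -> tuple[float, int, float]:
    """Gray's K-sample test for equality of cumulative incidence curves.

    Runs R's ``cmprsk::cuminc`` (the reference implementation) in a
    subprocess.  Returns (statistic, df, p).
    """
    if shutil.which("Rscript") is None:
        raise RuntimeError("Rscript not found; Gray's test requires R with "
                           "the cmprsk package")
    status = _status_codes(df, event_of_interest)
    groups = df[group_col].astype(str).to_numpy()
    for g in np.unique(groups):
        if not (status[groups == g] > 0).any() and len(np.unique(groups)) < 2:
            raise ValueError(f"group {g!r} has no events")
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 groups")
    with tempfile.TemporaryDirectory() as tmp:
        data_path = Path(tmp) / "data.csv"
        out_path = Path(tmp) / "out.json"
        script_path = Path(tmp) / "gray.R"
        pd.DataFrame({"time": df["time_years"].to_numpy(),
                      "status": status,
                      "group": groups}).to_csv(data_path, index=False)
        script_path.write_text(_R_SCRIPT)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script_path), str(data_path),
             str(out_path), str(rho)],
            capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"cmprsk::cuminc failed: {proc.stderr}")
        res = json.loads(out_path.read_text())
    return float(res["stat"]), int(res["df"]), float(res["pv"])


# ---------------------------------------------------------------------------
# Cox proportional hazards (cause-specific)


def cox_ph(df: pd.DataFrame, covariates: list[str],
           event_of_interest: str = EVENT_OF_INTEREST,
           ties: str = "efron", alpha: float = 0.05) -> pd.DataFrame:
    """Cause-specific Cox model: competing events censored at their time.

    Returns a table with log-HR, HR, Wald CI and p per covariate.
    Raises on non-convergence or an event-free dataset.
    """
    import statsmodels.api as sm

    status = _status_codes(df, event_of_interest) == 1
    if not status.any():
        raise ValueError("no events of interest")
    X = df[covariates].astype(float)
    if np.linalg.matrix_rank(np.asarray(X)) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    model = sm.PHReg(df["time_years"].to_numpy(), X,
                     status=status.astype(int), ties=ties)
    res = model.fit()
    if not np.isfinite(res.params).all():
        raise RuntimeError("Cox partial-likelihood maximization failed")
    z = sps.norm.ppf(1 - alpha / 2)
    coef = np.asarray(res.params)
    se = np.asarray(res.bse)
    table = pd.DataFrame({
        "coef": coef,
        "hr": np.exp(coef),
        "hr_ci_low": np.exp(coef - z * se),
        "hr_ci_high": np.exp(coef + z * se),
        "se": se,
        "p": 2 * sps.norm.sf(np.abs(coef / se)),
    }, index=covariates)
    return table


def harrell_c(df: pd.DataFrame, risk_scores,
              event_of_interest: str = EVENT_OF_INTEREST,
              all_cause: bool = False) -> float:
    """Harrell's concordance between risk ordering and survival.

    Cause-specific by default (competing events censored); ``all_cause``
    counts any death as the event.  Ties in risk count one half.
    """
    from lifelines.utils import concordance_index

    scores = np.asarray(risk_scores, dtype=float)
    if len(scores) != len(df):
        raise ValueError("risk scores must align with records")
    if all_cause:
        events = (df["event"] != "censored").to_numpy()
    else:
        events = _status_codes(df, event_of_interest) == 1
    if not events.any():
        raise ValueError("no usable pairs: no events")
    try:
        return float(concordance_index(df["time_years"].to_numpy(),
                                       -scores, events))
    except ZeroDivisionError as exc:
        raise ValueError("no usable pairs under censoring") from exc


# ---------------------------------------------------------------------------
# Stratified characteristic tables


def mitoses_quartile_bins(mitoses: pd.Series) -> pd.Series:
    """Quartile bins (<=p25, >p25-<=p50, >p50-<=p75, >p75) of the cohort."""
    q = mitoses.quantile([0.25, 0.5, 0.75]).to_numpy()
    labels = [f"<= {q[0]:g}", f"> {q[0]:g}-<= {q[1]:g}",
              f"> {q[1]:g}-<= {q[2]:g}", f"> {q[2]:g}"]
    bins = [-np.inf, q[0], q[1], q[2], np.inf]
    return pd.cut(mitoses, bins=bins, labels=labels)


def build_table1(df: pd.DataFrame, category_col: str,
                 characteristics: list[str]):
    """Counts and within-category percentages per characteristic.

    Returns ``(tables, chi2_p)``: per characteristic a DataFrame of
    counts with percentages of the category column total, and the
    Pearson chi-squared p-value for the association.
    """
    tables = {}
    pvals = {}
    for char in characteristics:
        counts = pd.crosstab(df[char], df[category_col], dropna=False)
        col_tot = counts.sum(axis=0)
        pct = 100.0 * counts / col_tot.replace(0, np.nan)
        cells = counts.astype(str) + " (" + pct.round(1).astype(str) + ")"
        tables[char] = cells
        nz = counts.loc[counts.sum(axis=1) > 0, counts.sum(axis=0) > 0]
        if nz.shape[0] > 1 and nz.shape[1] > 1:
            stat, dfree, p = pearson_chi2(nz.to_numpy())
            pvals[char] = p
        else:
            pvals[char] = np.nan
    return tables, pvals
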