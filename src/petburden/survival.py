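"""Biomarker-evaluation statistics for right-censored overall survival.

Implements the analysis battery used to evaluate skeletal tumor-burden
indices as prognostic biomarkers: administrative censoring at a follow-up
horizon, median split into high/low groups, Kaplan-Meier estimation with
"not reached" median semantics, the log-rank test, univariate Cox
regression (per-unit hazard ratio), Harrell's concordance index with a
bootstrap confidence interval and a paired comparison of two biomarkers'
C-indices, and Bland-Altman agreement between two indices.

Cohorts are plain pandas DataFrames with columns ``patient_id``,
``time_years`` (> 0), ``event`` (1 = death, 0 = censored) and one column
per biomarker (non-negative, NaN = missing).

Orientation convention: a HIGHER biomarker value predicts SHORTER survival
(hazard ratio > 1), so a comparable patient pair is concordant when the
patient who dies first has the higher value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .imaging import PetburdenError

#: sentinel for a Kaplan-Meier median that is never reached
NOT_REACHED = float("inf")

#: default bootstrap resamples for C-index confidence intervals
DEFAULT_BOOTSTRAP = 2000

#: default administrative censoring horizon (years)
DEFAULT_HORIZON_YEARS = 5.0

REQUIRED_COLUMNS = ("patient_id", "time_years", "event")


# --------------------------------------------------------------------------
# cohort table validation
# --------------------------------------------------------------------------

def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table; returns the input on success.

    Checks required columns, unique patient ids, strictly positive times
    and a binary event indicator, and reports offending rows by position.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise PetburdenError(f"cohort table missing columns: {missing}")
    if cohort["patient_id"].duplicated().any():
        dupes = cohort.loc[cohort["patient_id"].duplicated(), "patient_id"].tolist()
        raise PetburdenError(f"duplicate patient ids: {dupes}")
    bad_time = cohort.index[~(cohort["time_years"] > 0)].tolist()
    if bad_time:
        raise PetburdenError(f"non-positive time_years in rows {bad_time}")
    bad_event = cohort.index[~cohort["event"].isin([0, 1])].tolist()
    if bad_event:
        raise PetburdenError(f"event must be 0 or 1; bad rows {bad_event}")
    return cohort


def _biomarker_values(cohort: pd.DataFrame, biomarker: str) -> pd.DataFrame:
    if biomarker not in cohort.columns:
        raise PetburdenError(f"biomarker column {biomarker!r} not in cohort table")
    return cohort.dropna(subset=[biomarker])


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class MedianSplitResult:
    high: pd.DataFrame
    low: pd.DataFrame
    median_value: float
    n_missing: int


@dataclass
class KMEstimate:
    """Product-limit survival estimate at the observed event times."""

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    median_survival_years: float  # NOT_REACHED when survival never drops to 0.5

    @property
    def median_reached(self) -> bool:
        return math.isfinite(self.median_survival_years)


@dataclass
class CoxResult:
    beta: float
    hr: float
    ci95_low: float
    ci95_high: float
    p_value: float
    log_likelihood: float
    n: int
    n_events: int
    se_beta: float
    score_chi2: float
    score_p: float
    separation_suspected: bool = False


@dataclass
class CIndexResult:
    c_index: float
    ci95_low: float
    ci95_high: float
    n_comparable_pairs: int
    n_concordant: int
    n_tied: int


@dataclass
class CIndexComparison:
    delta: float          # c_A - c_B
    p_value: float        # paired t on per-patient concordance contributions
    c_a: float
    c_b: float
    n_patients: int
    p_value_bootstrap: float | None = None


@dataclass
class BlandAltmanResult:
    bias: float           # mean of x - y
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    means: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    diffs: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def censor_at_horizon(
    cohort: pd.DataFrame, horizon_years: float = DEFAULT_HORIZON_YEARS
) -> pd.DataFrame:
    """Administratively censor follow-up beyond a horizon.

    Rows with ``time_years > horizon`` become (horizon, censored); a time
    exactly equal to the horizon keeps its recorded event status.
    """
    if horizon_years <= 0:
        raise PetburdenError(f"horizon must be > 0, got {horizon_years}")
    out = cohort.copy()
    over = out["time_years"] > horizon_years
    out.loc[over, "time_years"] = float(horizon_years)
    out.loc[over, "event"] = 0
    return out


def median_split(cohort: pd.DataFrame, biomarker: str) -> MedianSplitResult:
    """Split a cohort at the biomarker median (midpoint convention).

    High = values strictly above the median, low = values at or below it;
    rows with a missing biomarker are excluded and counted.
    """
    present = _biomarker_values(cohort, biomarker)
    n_missing = len(cohort) - len(present)
    if len(present) < 2:
        raise PetburdenError("median split needs at least 2 non-missing values")
    median = float(np.median(present[biomarker].to_numpy(dtype=float)))
    high = present[present[biomarker] > median]
    low = present[present[biomarker] <= median]
    if high.empty:
        warnings.warn(
            f"no values above the median of {biomarker!r}; high group is empty",
            stacklevel=2,
        )
    return MedianSplitResult(high=high, low=low, median_value=median, n_missing=n_missing)


def km_estimate(times: np.ndarray, events: np.ndarray) -> KMEstimate:
    """Kaplan-Meier product-limit estimator.

    Events precede censorings tied at the same time (the standard
    convention); the median is the earliest time at which the survival
    estimate drops to <= 0.5, ``NOT_REACHED`` if it never does.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise PetburdenError("km_estimate needs at least one observation")
    if np.any(times <= 0):
        raise PetburdenError("survival times must be positive")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    ev_rows = table[table["observed"] > 0]
    ev_times = ev_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(ev_rows.index).to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)  # inf when never reaching 0.5
    return KMEstimate(
        event_times=ev_times,
        survival_prob=surv,
        at_risk=ev_rows["at_risk"].to_numpy(dtype=int),
        events=ev_rows["observed"].to_numpy(dtype=int),
        median_survival_years=median if math.isfinite(median) else NOT_REACHED,
    )


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df."""
    if group_a.empty or group_b.empty:
        raise PetburdenError("both groups must be non-empty")
    if group_a["event"].sum() == 0 and group_b["event"].sum() == 0:
        warnings.warn("no events in either group; log-rank p set to 1", stacklevel=2)
        return 0.0, 1.0
    res = _ll_logrank(
        group_a["time_years"], group_b["time_years"],
        event_observed_A=group_a["event"], event_observed_B=group_b["event"],
    )
    return float(res.test_statistic), float(res.p_value)


def _cox_score_test(time: np.ndarray, event: np.ndarray, x: np.ndarray) -> float:
    """Cox partial-likelihood score chi-square at beta = 0 (Efron ties)."""
    order = np.argsort(time, kind="stable")
    time, event, x = time[order], event[order], x[order]
    n = time.size
    score = 0.0
    info = 0.0
    i = 0
    while i < n:
        t = time[i]
        j = i
        while j < n and time[j] == t:
            j += 1
        deaths = x[i:j][event[i:j] == 1]
        d = deaths.size
        if d:
            risk = x[i:]
            n_risk = risk.size
            s1r, s2r = risk.sum(), (risk**2).sum()
            s1d, s2d = deaths.sum(), (deaths**2).sum()
            score += s1d
            for k in range(d):
                f = k / d
                denom = n_risk - k
                m1 = (s1r - f * s1d) / denom
                m2 = (s2r - f * s2d) / denom
                score -= m1
                info += m2 - m1**2
        i = j
    if info <= 0:
        return 0.0
    return score**2 / info


def cox_univariate(cohort: pd.DataFrame, biomarker: str) -> CoxResult:
    """Univariate Cox proportional-hazards regression for one biomarker.

    Partial-likelihood maximization with the Efron tie correction; Wald
    95% CI on the log-hazard scale, exponentiated to the HR scale.  Rows
    with a missing biomarker are dropped.  Also reports the score test at
    beta = 0 (for a binary group covariate without tied event times this
    equals the log-rank chi-square).
    """
    df = _biomarker_values(cohort, biomarker)
    n_events = int(df["event"].sum())
    if n_events < 1:
        raise PetburdenError("Cox regression needs at least one event")
    x = df[biomarker].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise PetburdenError(f"biomarker {biomarker!r} is constant")

    fitter = CoxPHFitter()
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fitter.fit(
                df[[biomarker, "time_years", "event"]],
                duration_col="time_years",
                event_col="event",
            )
        except ConvergenceError as err:
            raise PetburdenError(f"Cox fit did not converge: {err}") from err
        for w in caught:
            if "convergence" in str(w.message).lower() or "separation" in str(w.message).lower():
                separation = True

    summary = fitter.summary.loc[biomarker]
    score_chi2 = _cox_score_test(
        df["time_years"].to_numpy(dtype=float),
        df["event"].to_numpy(dtype=int),
        x,
    )
    return CoxResult(
        beta=float(summary["coef"]),
        hr=float(summary["exp(coef)"]),
        ci95_low=float(summary["exp(coef) lower 95%"]),
        ci95_high=float(summary["exp(coef) upper 95%"]),
        p_value=float(summary["p"]),
        log_likelihood=float(fitter.log_likelihood_),
        n=int(len(df)),
        n_events=n_events,
        se_beta=float(summary["se(coef)"]),
        score_chi2=float(score_chi2),
        score_p=float(stats.chi2.sf(score_chi2, df=1)),
        separation_suspected=separation,
    )


# --------------------------------------------------------------------------
# concordance
# --------------------------------------------------------------------------

def _pair_matrices(
    time: np.ndarray, event: np.ndarray, marker: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Comparable-pair indicator and per-pair concordance score.

    ``comp[i, j]`` is 1 when patient i is observed to die strictly before
    patient j's observed time (pairs with tied observed times are not
    comparable).  ``score[i, j]`` is 1 when the earlier death has the
    higher marker, 0.5 on marker ties, 0 otherwise.
    """
    t_i, t_j = time[:, None], time[None, :]
    comp = (t_i < t_j) & (event[:, None] == 1)
    m_i, m_j = marker[:, None], marker[None, :]
    score = np.where(m_i > m_j, 1.0, np.where(m_i == m_j, 0.5, 0.0))
    return comp, score


def _cindex_counts(
    time: np.ndarray, event: np.ndarray, marker: np.ndarray
) -> tuple[int, int, int]:
    comp, score = _pair_matrices(time, event, marker)
    n_pairs = int(comp.sum())
    n_conc = int((comp & (score == 1.0)).sum())
    n_tied = int((comp & (score == 0.5)).sum())
    return n_pairs, n_conc, n_tied


def harrell_cindex(
    cohort: pd.DataFrame,
    biomarker: str,
    *,
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
    higher_is_worse: bool = True,
) -> CIndexResult:
    """Harrell's concordance index with a percentile bootstrap CI.

    A pair is comparable when the shorter observed time is an event (and
    the times differ); it is concordant when the shorter-lived patient has
    the higher biomarker (``higher_is_worse=True``, matching the HR > 1
    orientation).  Biomarker ties count 0.5.  The CI resamples patients
    with replacement (seeded percentile interval).
    """
    df = _biomarker_values(validate_cohort(cohort), biomarker)
    time = df["time_years"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    marker = df[biomarker].to_numpy(dtype=float)
    if not higher_is_worse:
        marker = -marker

    n_pairs, n_conc, n_tied = _cindex_counts(time, event, marker)
    if n_pairs == 0:
        raise PetburdenError("no comparable pairs; C-index undefined")
    c = (n_conc + 0.5 * n_tied) / n_pairs

    rng = np.random.default_rng(seed)
    n = time.size
    boot = np.empty(n_bootstrap)
    boot[:] = np.nan
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        p, cc, tt = _cindex_counts(time[idx], event[idx], marker[idx])
        if p > 0:
            boot[b] = (cc + 0.5 * tt) / p
    boot = boot[np.isfinite(boot)]
    if boot.size:
        lo, hi = np.percentile(boot, [2.5, 97.5])
    else:  # pathological: no resample had comparable pairs
        lo = hi = c
    return CIndexResult(
        c_index=float(c),
        ci95_low=float(lo),
        ci95_high=float(hi),
        n_comparable_pairs=n_pairs,
        n_concordant=n_conc,
        n_tied=n_tied,
    )


def compare_cindex(
    cohort: pd.DataFrame,
    biomarker_a: str,
    biomarker_b: str,
    *,
    bootstrap_p: bool = False,
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
) -> CIndexComparison:
    """Paired comparison of two biomarkers' C-indices on the same patients.

    Comparable pairs depend only on the survival outcome, so both
    biomarkers share the same pair set and the C-index difference is a
    paired contrast.  The test references ``delta = c_A - c_B`` against a
    leave-one-patient-out jackknife standard error of the paired
    difference (both C-indices recomputed without each patient, which
    respects the sharing of pairs between patients) with a t(m-1)
    distribution.  A naive t-test that treats per-patient concordance
    fractions as independent observations is badly anti-conservative and
    is deliberately not used.  A seeded paired-bootstrap p is available
    as a cross-check.
    """
    df = validate_cohort(cohort).dropna(subset=[biomarker_a, biomarker_b])
    time = df["time_years"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    ma = df[biomarker_a].to_numpy(dtype=float)
    mb = df[biomarker_b].to_numpy(dtype=float)

    comp, score_a_mat = _pair_matrices(time, event, ma)
    _, score_b_mat = _pair_matrices(time, event, mb)
    a_mat = comp * score_a_mat
    b_mat = comp * score_b_mat
    total_pairs = int(comp.sum())
    if total_pairs == 0:
        raise PetburdenError("no comparable pairs; comparison undefined")
    c_a = float(a_mat.sum() / total_pairs)
    c_b = float(b_mat.sum() / total_pairs)
    delta = c_a - c_b

    # per-patient pair involvement (each comparable pair touches 2 patients)
    pairs_i = comp.sum(axis=1) + comp.sum(axis=0)
    score_a_i = a_mat.sum(axis=1) + a_mat.sum(axis=0)
    score_b_i = b_mat.sum(axis=1) + b_mat.sum(axis=0)

    m = int((pairs_i > 0).sum())
    if m < 3:
        raise PetburdenError("fewer than 3 patients with comparable pairs")

    # leave-one-out deltas; patients whose removal kills all pairs are skipped
    remaining = total_pairs - pairs_i
    ok = remaining > 0
    d_loo = (
        (a_mat.sum() - score_a_i[ok]) - (b_mat.sum() - score_b_i[ok])
    ) / remaining[ok]
    k = int(ok.sum())
    se = math.sqrt((k - 1) / k * float(((d_loo - d_loo.mean()) ** 2).sum()))
    if se == 0:
        p = 1.0 if delta == 0 else 0.0
    else:
        t_stat = delta / se
        p = float(2 * stats.t.sf(abs(t_stat), df=k - 1))

    p_boot: float | None = None
    if bootstrap_p:
        rng = np.random.default_rng(seed)
        n = time.size
        deltas = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            pa, ca_c, ta = _cindex_counts(time[idx], event[idx], ma[idx])
            pb, cb_c, tb = _cindex_counts(time[idx], event[idx], mb[idx])
            if pa > 0 and pb > 0:
                deltas.append((ca_c + 0.5 * ta) / pa - (cb_c + 0.5 * tb) / pb)
        deltas = np.asarray(deltas)
        if deltas.size:
            frac = float(np.mean(deltas <= 0))
            p_boot = float(min(1.0, 2 * min(frac, 1 - frac)))

    return CIndexComparison(
        delta=float(delta),
        p_value=p,
        c_a=c_a,
        c_b=c_b,
        n_patients=m,
        p_value_bootstrap=p_boot,
    )


def bland_altman(x: np.ndarray, y: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman agreement between two paired measurements.

    Differences are taken as x - y; limits of agreement are
    bias +/- 1.96 * sd (sd with ddof = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PetburdenError("x and y must be equal-length 1D arrays")
    if x.size < 2:
        raise PetburdenError("Bland-Altman needs at least 2 pairs")
    diffs = x - y
    means = (x + y) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=int(x.size),
        means=means,
        diffs=diffs,
    )


def format_p(p: float, threshold: float = 0.001) -> str:
    """Human-readable p-value: below the threshold renders as '<0.001'."""
    return f"<{threshold:g}" if p < threshold else f"{p:.3g}"


def format_median(median_years: float) -> str:
    return "not reached" if not math.isfinite(median_years) else f"{median_years:.2f}"
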