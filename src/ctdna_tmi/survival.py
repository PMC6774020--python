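"""Survival machinery shared by every analysis stage.

Kaplan–Meier estimation, two-sample survival tests (log-rank and the
Gehan–Breslow generalised Wilcoxon), Benjamini–Hochberg adjustment, ROC/AUC
with confidence interval and null test, the minimum-p cutoff scan used to
dichotomise continuous predictors, and per-subgroup predictor evaluation.

The two-sample tests are computed from the counting-process representation
(observed minus expected events at each distinct event time, hypergeometric
variance), vectorised so that thousands of single-mutation screens run as a
single matrix computation; :func:`batch_two_sample_test` exposes that path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

WEIGHTINGS = ("logrank", "gehan_wilcoxon", "peto_peto")

#: Returned by :func:`median_survival` when the curve never reaches 0.5.
NOT_REACHED = math.inf


class CutoffError(ValueError):
    """No admissible cutoff candidate for the scan."""


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate: S(t) evaluated at the distinct event times."""

    event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """S(t); 1.0 before the first event (right-continuous step)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_probs[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.event_times, "survival": self.survival_probs,
             "at_risk": self.at_risk}
        )


@dataclass(frozen=True)
class TwoSampleTestResult:
    statistic: float
    p_value: float
    test_name: str
    group_medians: tuple[float, float]
    n_per_group: tuple[int, int]


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    null_p: float
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    p_profile: tuple[tuple[float, float], ...]
    chosen_p: float
    test_name: str


@dataclass(frozen=True)
class SubgroupResult:
    """Predictor performance inside one demographic subgroup."""

    subgroup: str
    status: str  # "ok" or "not_evaluable"
    n: int = 0
    n_responder: int = 0
    km_pfs_p: float = math.nan
    km_os_p: float = math.nan
    auc_pfs: float = math.nan
    null_p_pfs: float = math.nan
    auc_os: float = math.nan
    null_p_os: float = math.nan


def _as_time_event(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("time and event must be 1-d arrays of equal length")
    if t.size == 0:
        raise ValueError("empty survival sample")
    if np.any(t <= 0):
        raise ValueError("survival times must be > 0")
    return t, e


def km_estimate(time, event) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate.

    A censored-only input gives a flat curve at 1.0 (no event times).
    """
    t, e = _as_time_event(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    mask = table["observed"] > 0
    ev_times = table.index.to_numpy(dtype=float)[mask]
    surv = kmf.survival_function_at_times(ev_times).to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=float)[mask]
    return SurvivalCurve(ev_times, surv, at_risk.astype(int), n=t.size)


def median_survival(curve: SurvivalCurve) -> float:
    """Smallest event time with S(t) <= 0.5; ``NOT_REACHED`` (inf) if none."""
    hit = np.nonzero(curve.survival_probs <= 0.5)[0]
    return NOT_REACHED if hit.size == 0 else float(curve.event_times[hit[0]])


def _km_median(time, event) -> float:
    return median_survival(km_estimate(time, event))


def batch_two_sample_test(
    time, event, group_masks, weighting: str = "logrank"
) -> tuple[np.ndarray, np.ndarray]:
    """Two-group survival chi-square for many groupings of one cohort.

    ``group_masks`` is an (m, n) boolean matrix; row k defines membership of
    "group 1" for the k-th comparison (the complement is group 2). Returns
    (statistics, p_values), each of length m. Weighting ``logrank`` uses
    w_j = 1; ``gehan_wilcoxon`` uses the at-risk count n_j (Gehan–Breslow);
    ``peto_peto`` uses the left-continuous pooled KM estimate.

    A comparison with no usable event information (zero variance, e.g. one
    empty group) gets statistic 0 and p 1.
    """
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    t, e = _as_time_event(time, event)
    M = np.atleast_2d(np.asarray(group_masks, dtype=bool))
    if M.shape[1] != t.size:
        raise ValueError("group_masks width must equal the number of samples")

    order = np.argsort(t, kind="mergesort")
    t, e, M = t[order], e[order], M[:, order]
    n = t.size
    ev_times = np.unique(t[e])
    if ev_times.size == 0:
        m = M.shape[0]
        return np.zeros(m), np.ones(m)

    start = np.searchsorted(t, ev_times, side="left")
    n_risk = (n - start).astype(float)
    # suffix counts of group-1 membership give group-1 at-risk numbers
    suffix = np.cumsum(M[:, ::-1].astype(np.float64), axis=1)[:, ::-1]
    suffix = np.concatenate([suffix, np.zeros((M.shape[0], 1))], axis=1)
    n1_risk = suffix[:, start]  # (m, k)

    is_event_at = (t[None, :] == ev_times[:, None]) & e[None, :]  # (k, n)
    d_total = is_event_at.sum(axis=1).astype(float)
    d1 = M.astype(np.float64) @ is_event_at.T.astype(np.float64)  # (m, k)

    if weighting == "logrank":
        w = np.ones_like(ev_times)
    elif weighting == "gehan_wilcoxon":
        w = n_risk
    else:  # peto_peto: left-continuous pooled survival estimate
        s = np.cumprod(1.0 - d_total / n_risk)
        w = np.concatenate([[1.0], s[:-1]])

    frac = n1_risk / n_risk[None, :]
    observed_minus_expected = (w[None, :] * (d1 - d_total[None, :] * frac)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_terms = (
            d_total * frac * (1.0 - frac) * (n_risk - d_total) / (n_risk - 1.0)
        )
    var_terms = np.where(n_risk > 1.0, var_terms, 0.0)
    variance = (w[None, :] ** 2 * var_terms).sum(axis=1)

    stat = np.zeros(M.shape[0])
    ok = variance > 0
    stat[ok] = observed_minus_expected[ok] ** 2 / variance[ok]
    p = np.where(ok, stats.chi2.sf(stat, df=1), 1.0)
    return stat, p


def _two_sample(
    time_a, event_a, time_b, event_b, weighting: str, test_name: str
) -> TwoSampleTestResult:
    ta, ea = _as_time_event(time_a, event_a)
    tb, eb = _as_time_event(time_b, event_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    mask = np.zeros(t.size, dtype=bool)
    mask[: ta.size] = True
    stat, p = batch_two_sample_test(t, e, mask[None, :], weighting=weighting)
    medians = (_km_median(ta, ea), _km_median(tb, eb))
    return TwoSampleTestResult(float(stat[0]), float(p[0]), test_name, medians,
                               (ta.size, tb.size))


def logrank_test(time_a, event_a, time_b, event_b) -> TwoSampleTestResult:
    """Standard (unweighted) log-rank test; chi-square with 1 df."""
    return _two_sample(time_a, event_a, time_b, event_b, "logrank", "logrank")


def gehan_wilcoxon_test(
    time_a, event_a, time_b, event_b, variant: str = "gehan"
) -> TwoSampleTestResult:
    """Generalised Wilcoxon test for survival curves.

    Default is the Gehan–Breslow form (weights = pooled at-risk count),
    which emphasises early differences; ``variant="peto"`` selects the
    Peto–Peto weighting instead.
    """
    weighting = "gehan_wilcoxon" if variant == "gehan" else "peto_peto"
    return _two_sample(time_a, event_a, time_b, event_b, weighting, "gehan_wilcoxon")


def two_sample_test(time_a, event_a, time_b, event_b, test: str) -> TwoSampleTestResult:
    if test == "logrank":
        return logrank_test(time_a, event_a, time_b, event_b)
    if test in ("gehan", "gehan_wilcoxon", "wilcoxon"):
        return gehan_wilcoxon_test(time_a, event_a, time_b, event_b)
    raise ValueError(f"unknown test {test!r}")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def _delong_se(scores: np.ndarray, positive: np.ndarray) -> float:
    xs = scores[positive]
    ys = scores[~positive]
    m, n = xs.size, ys.size
    v10 = np.array([(np.sum(x > ys) + 0.5 * np.sum(x == ys)) / n for x in xs])
    v01 = np.array([(np.sum(xs > y) + 0.5 * np.sum(xs == y)) / m for y in ys])
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    return math.sqrt(max(var, 0.0))


def roc_auc(scores, benefit_labels, ci_method: str = "hanley") -> ROCResult:
    """AUC for discriminating non-benefit from benefit patients.

    Orientation is fixed: the "positive" class is non-benefit, so an AUC
    above 0.5 means higher risk scores go with worse outcome. The AUC equals
    pairwise concordance with half credit for ties. The 95% CI uses the
    Hanley–McNeil standard error by default (``ci_method="delong"`` for the
    DeLong covariance estimate); the null test is a two-sided z-test of
    AUC = 0.5 using the null-hypothesis standard error.
    """
    s = np.asarray(scores, dtype=float)
    benefit = np.asarray(benefit_labels, dtype=bool)
    if s.shape != benefit.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    positive = ~benefit  # non-benefit is the event the score should rank high
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both benefit classes must be present")
    auc = float(roc_auc_score(positive, s))
    if ci_method == "hanley":
        se = _hanley_mcneil_se(auc, n_pos, n_neg)
    elif ci_method == "delong":
        se = _delong_se(s, positive)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    z975 = stats.norm.ppf(0.975)
    ci_low = max(0.0, auc - z975 * se)
    ci_high = min(1.0, auc + z975 * se)
    se0 = _hanley_mcneil_se(0.5, n_pos, n_neg)
    z = (auc - 0.5) / se0 if se0 > 0 else 0.0
    null_p = float(2.0 * stats.norm.sf(abs(z)))
    return ROCResult(auc, ci_low, ci_high, null_p, n_pos, n_neg)


def ward_cutoff_scan(
    predictor_values,
    time,
    event,
    min_group: int = 3,
    test: str = "gehan",
) -> CutoffResult:
    """Minimum-p cutoff scan over a continuous predictor.

    Candidate cutoffs are the midpoints between consecutive distinct sorted
    predictor values whose induced low/high split leaves at least
    ``min_group`` patients on each side. Each candidate is scored by the
    chosen two-sample survival test on the split; the candidate with the
    smallest p-value wins (ties broken toward the smallest candidate). The
    reported p-values are not adjusted for the multiplicity of the scan.
    """
    v = np.asarray(predictor_values, dtype=float)
    t, e = _as_time_event(time, event)
    if v.shape != t.shape:
        raise ValueError("predictor and survival arrays must align")
    if v.size < 2 * min_group:
        raise CutoffError(f"need at least {2 * min_group} patients")
    distinct = np.unique(v)
    if distinct.size < 2:
        raise CutoffError("predictor values are all equal")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    masks = v[None, :] < candidates[:, None]
    sizes = masks.sum(axis=1)
    admissible = (sizes >= min_group) & (v.size - sizes >= min_group)
    if not np.any(admissible):
        raise CutoffError("no split leaves min_group patients on both sides")
    candidates = candidates[admissible]
    masks = masks[admissible]
    weighting = "gehan_wilcoxon" if test in ("gehan", "gehan_wilcoxon", "wilcoxon") \
        else "logrank"
    _, pvals = batch_two_sample_test(t, e, masks, weighting=weighting)
    best = int(np.argmin(pvals))  # argmin takes the first (smallest candidate) on ties
    return CutoffResult(
        cutoff=float(candidates[best]),
        p_profile=tuple(zip(candidates.tolist(), pvals.tolist())),
        chosen_p=float(pvals[best]),
        test_name=weighting,
    )


# ---------------------------------------------------------------------------
# Subgroup evaluation
# ---------------------------------------------------------------------------

#: The ten demographic subgroups used for composition and subgroup scoring.
SUBGROUP_PREDICATES = {
    "male": lambda c: c["gender"] == "M",
    "female": lambda c: c["gender"] == "F",
    "smoking": lambda c: c["smoking"],
    "non_smoking": lambda c: ~c["smoking"],
    "LUAD": lambda c: c["pathology"] == "LUAD",
    "LUSC": lambda c: c["pathology"] == "LUSC",
    "driver_positive": lambda c: c["driver_positive"],
    "driver_negative": lambda c: ~c["driver_positive"],
    "metastases_gt3": lambda c: c["metastases"] > 3,
    "metastases_le3": lambda c: c["metastases"] <= 3,
}


def patient_subgroups(row) -> list[str]:
    """The five subgroups one patient belongs to (one per dichotomy)."""
    return [
        "male" if row["gender"] == "M" else "female",
        "smoking" if row["smoking"] else "non_smoking",
        "LUAD" if row["pathology"] == "LUAD" else "LUSC",
        "driver_positive" if row["driver_positive"] else "driver_negative",
        "metastases_gt3" if row["metastases"] > 3 else "metastases_le3",
    ]


def subgroup_evaluation(
    clinical: pd.DataFrame,
    responder: pd.Series,
    scores: pd.Series,
    pfs_benefit: pd.Series,
    os_benefit: pd.Series,
    min_group: int = 3,
    test: str = "gehan",
    subgroups: dict | None = None,
) -> dict[str, SubgroupResult]:
    """Evaluate one predictor inside each demographic subgroup.

    Within each subgroup the responder and non-responder arms are compared
    on PFS and OS with the configured two-sample test, and the continuous
    predictor score is scored by ROC/AUC against the PFS-benefit and
    OS-benefit labels (boolean Series; NA = indeterminate, dropped). A
    subgroup whose arms fall below ``min_group``, or with a single benefit
    class, is returned with status ``not_evaluable``.
    """
    if subgroups is None:
        subgroups = SUBGROUP_PREDICATES
    out: dict[str, SubgroupResult] = {}
    for name, pred in subgroups.items():
        member = pred(clinical).astype(bool)
        sub = clinical[member]
        resp = responder[member].astype(bool)
        if len(sub) == 0 or resp.sum() < min_group or (~resp).sum() < min_group:
            out[name] = SubgroupResult(name, "not_evaluable", n=len(sub),
                                       n_responder=int(resp.sum()))
            continue
        km_pfs = two_sample_test(
            sub.loc[resp, "pfs_days"], sub.loc[resp, "pfs_event"],
            sub.loc[~resp, "pfs_days"], sub.loc[~resp, "pfs_event"], test)
        km_os = two_sample_test(
            sub.loc[resp, "os_days"], sub.loc[resp, "os_event"],
            sub.loc[~resp, "os_days"], sub.loc[~resp, "os_event"], test)

        rocs = {}
        for label_name, labels in (("pfs", pfs_benefit), ("os", os_benefit)):
            lab = labels[member]
            usable = lab.notna()
            lab_bool = lab[usable].astype(bool)
            if usable.sum() == 0 or lab_bool.nunique() < 2:
                rocs[label_name] = None
                continue
            rocs[label_name] = roc_auc(scores[member][usable].to_numpy(),
                                       lab_bool.to_numpy())
        if rocs["pfs"] is None or rocs["os"] is None:
            out[name] = SubgroupResult(
                name, "not_evaluable", n=len(sub), n_responder=int(resp.sum()),
                km_pfs_p=km_pfs.p_value, km_os_p=km_os.p_value)
            continue
        out[name] = SubgroupResult(
            name, "ok", n=len(sub), n_responder=int(resp.sum()),
            km_pfs_p=km_pfs.p_value, km_os_p=km_os.p_value,
            auc_pfs=rocs["pfs"].auc, null_p_pfs=rocs["pfs"].null_p,
            auc_os=rocs["os"].auc, null_p_os=rocs["os"].null_p)
    return out
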