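"""Multi-reader multi-case (MRMC) statistics for aided-vs-unaided reading.

* :func:`assign_conditions` builds the two-session crossover design (half
  the cases aided in session 1, the complement in session 2, stratified).
* :func:`dbm_analysis` is the Dorfman-Berbaum-Metz method: case-jackknife
  pseudovalues of each reader's micro-averaged AUC enter a three-way
  mixed-effects ANOVA (condition fixed; readers and cases random), yielding
  least-squares mean AUCs per condition, their difference with a 95% CI, and
  a quasi-F test. Denominator degrees of freedom follow Hillis's adjustment
  by default; the classic Satterthwaite df is available by flag.
* :func:`delong_test` compares two correlated AUCs on the same cases via
  placement values (the caller applies any Bonferroni adjustment).
* :func:`miss_rate_reduction` and :func:`readtime_test` are the secondary
  endpoints: relative reduction in miss rate (1 - sensitivity) and a paired
  t-test on per-reader mean log read times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "assign_conditions",
    "jackknife_auc",
    "DbmResult",
    "dbm_analysis",
    "delong_test",
    "miss_rate_reduction",
    "ReadTimeResult",
    "readtime_test",
    "mrmc_report",
]


# ---------------------------------------------------------------------------
# crossover design
# ---------------------------------------------------------------------------

def assign_conditions(case_ids: Sequence, reader_ids: Sequence, seed: int,
                      strata: Mapping | None = None) -> pd.DataFrame:
    """Randomized stratified crossover assignment.

    For each reader, cases are split within each stratum into a near-half
    session-1 aided set (odd strata split +-1); session 2 reads every case in
    the opposite condition. Deterministic for a fixed seed. Returns a table
    (reader_id, case_id, session, condition).
    """
    case_ids = list(case_ids)
    if len(case_ids) < 2:
        raise ValueError("need at least two cases")
    if len(reader_ids) == 0:
        raise ValueError("need at least one reader")
    strata = strata or {c: 0 for c in case_ids}
    by_stratum: dict = {}
    for c in case_ids:
        by_stratum.setdefault(strata[c], []).append(c)
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    rows = []
    for reader in reader_ids:
        aided_first: set = set()
        for members in by_stratum.values():
            perm = rng.permutation(len(members))
            n_aided = len(members) // 2
            if len(members) % 2 and rng.random() < 0.5:
                n_aided += 1
            aided_first.update(members[i] for i in perm[:n_aided])
        for c in case_ids:
            first = "aided" if c in aided_first else "unaided"
            second = "unaided" if first == "aided" else "aided"
            rows.append((reader, c, 1, first))
            rows.append((reader, c, 2, second))
    return pd.DataFrame(rows, columns=["reader_id", "case_id", "session",
                                       "condition"])


# ---------------------------------------------------------------------------
# jackknife AUC machinery
# ---------------------------------------------------------------------------

def jackknife_auc(scores: np.ndarray, labels: np.ndarray,
                  groups: np.ndarray) -> tuple[float, np.ndarray]:
    """Full-data AUC and leave-one-group-out AUCs in O(n log n + G * d^2).

    ``groups`` maps each (score, label) pair to its case; deleting a case
    removes all of its pairs. Uses the incremental Mann-Whitney identity:
    removing points subtracts their placement sums and adds back the
    deleted-pair cross terms. Degenerate replicates (a deletion leaving one
    class empty) fall back to the full-data AUC with a warning.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    groups = np.asarray(groups)
    if labels.min() == labels.max():
        raise ValueError("AUC is undefined when only one class is present")
    pos = labels == 1
    xs, ys = scores[pos], scores[~pos]
    p_n, n_n = xs.size, ys.size
    ys_sorted = np.sort(ys)
    xs_sorted = np.sort(xs)
    # per-point win counts against the opposite class (ties count half)
    w_pos = (np.searchsorted(ys_sorted, xs, side="left")
             + np.searchsorted(ys_sorted, xs, side="right")) / 2.0
    w_neg = p_n - (np.searchsorted(xs_sorted, ys, side="left")
                   + np.searchsorted(xs_sorted, ys, side="right")) / 2.0
    total = float(w_pos.sum())
    auc = total / (p_n * n_n)

    uniq, inv = np.unique(groups, return_inverse=True)
    g_count_pos = np.bincount(inv[pos], minlength=uniq.size)
    g_count_neg = np.bincount(inv[~pos], minlength=uniq.size)
    g_wsum_pos = np.bincount(inv[pos], weights=w_pos, minlength=uniq.size)
    g_wsum_neg = np.bincount(inv[~pos], weights=w_neg, minlength=uniq.size)

    # cross terms: wins between deleted positives and deleted negatives
    cross = np.zeros(uniq.size)
    mixed = np.flatnonzero((g_count_pos > 0) & (g_count_neg > 0))
    if mixed.size:
        gp = inv[pos]
        gn = inv[~pos]
        for g in mixed:
            dx = xs[gp == g][:, None]
            dy = ys[gn == g][None, :]
            cross[g] = ((dx > dy).sum() + 0.5 * (dx == dy).sum())

    rem_p = p_n - g_count_pos
    rem_n = n_n - g_count_neg
    degenerate = (rem_p == 0) | (rem_n == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        loo = (total - g_wsum_pos - g_wsum_neg + cross) / (rem_p * rem_n)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} jackknife replicate(s) left "
                      "a single class; using the full-data AUC there")
        loo[degenerate] = auc
    return auc, loo


# ---------------------------------------------------------------------------
# DBM analysis
# ---------------------------------------------------------------------------

@dataclass
class DbmResult:
    """DBM MRMC result: LS mean AUCs, their aided-unaided difference with a
    95% CI, and the quasi-F test on the condition effect."""

    ls_mean_auc_unaided: float
    ls_mean_auc_aided: float
    difference: float
    ci_low: float
    ci_high: float
    f_statistic: float
    p_value: float
    ddf: float
    anova: dict = field(default_factory=dict)


def _reader_pseudovalues(sub: pd.DataFrame, case_codes: np.ndarray,
                         n_cases: int) -> np.ndarray:
    auc, loo = jackknife_auc(sub["confidence"].to_numpy(),
                             sub["reference"].to_numpy(), case_codes)
    return n_cases * auc - (n_cases - 1) * loo


def dbm_analysis(table: pd.DataFrame, hillis: bool = True) -> DbmResult:
    """DBM analysis of aided-vs-unaided reader AUC on a long-format table.

    Each reader's AUC per condition is micro-averaged over the table's
    categories; pseudovalues come from deleting one case at a time (all its
    category pairs together). Requires >= 2 readers, >= 2 cases and both
    conditions.
    """
    readers = np.sort(table["reader_id"].unique())
    cases = np.sort(table["case_id"].unique())
    conditions = ("unaided", "aided")
    if readers.size < 2 or cases.size < 2:
        raise ValueError("DBM needs at least two readers and two cases")
    if set(table["condition"].unique()) != set(conditions):
        raise ValueError("table must contain both conditions")
    case_pos = {c: i for i, c in enumerate(cases)}
    n_r, n_c, n_t = readers.size, cases.size, 2

    y = np.empty((n_t, n_r, n_c))
    for ti, cond in enumerate(conditions):
        for ri, reader in enumerate(readers):
            sub = table[(table["reader_id"] == reader)
                        & (table["condition"] == cond)]
            codes = sub["case_id"].map(case_pos).to_numpy()
            y[ti, ri] = _reader_pseudovalues(sub, codes, n_c)

    m = y.mean()
    m_t = y.mean(axis=(1, 2))
    m_r = y.mean(axis=(0, 2))
    m_c = y.mean(axis=(0, 1))
    m_tr = y.mean(axis=2)
    m_tc = y.mean(axis=1)
    m_rc = y.mean(axis=0)

    ss_t = n_r * n_c * np.sum((m_t - m) ** 2)
    ss_tr = n_c * np.sum((m_tr - m_t[:, None] - m_r[None, :] + m) ** 2)
    ss_tc = n_r * np.sum((m_tc - m_t[:, None] - m_c[None, :] + m) ** 2)
    resid = (y - m_tr[:, :, None] - m_tc[:, None, :] - m_rc[None, :, :]
             + m_t[:, None, None] + m_r[None, :, None] + m_c[None, None, :]
             - m)
    ss_trc = np.sum(resid ** 2)

    df_t = n_t - 1
    df_tr = (n_t - 1) * (n_r - 1)
    df_tc = (n_t - 1) * (n_c - 1)
    df_trc = (n_t - 1) * (n_r - 1) * (n_c - 1)
    ms_t = ss_t / df_t
    ms_tr = ss_tr / df_tr
    ms_tc = ss_tc / df_tc
    ms_trc = ss_trc / df_trc

    if hillis:
        denom = ms_tr + max(ms_tc - ms_trc, 0.0)
        ddf = (denom ** 2 / (ms_tr ** 2 / df_tr)) if ms_tr > 0 else df_tr
    else:
        denom = ms_tr + ms_tc - ms_trc
        num = denom ** 2
        den = (ms_tr ** 2 / df_tr + ms_tc ** 2 / df_tc
               + ms_trc ** 2 / df_trc)
        ddf = num / den if den > 0 else df_tr
    if denom <= 0:
        f_stat, p = (0.0, 1.0) if ms_t == 0 else (np.inf, 0.0)
    else:
        f_stat = float(ms_t / denom)
        p = float(stats.f.sf(f_stat, df_t, ddf))

    ls_unaided, ls_aided = float(m_t[0]), float(m_t[1])
    diff = ls_aided - ls_unaided
    se = float(np.sqrt(max(2.0 * denom / (n_r * n_c), 0.0)))
    tcrit = float(stats.t.ppf(0.975, ddf)) if ddf > 0 else np.nan
    anova = {"MS_T": float(ms_t), "MS_TR": float(ms_tr),
             "MS_TC": float(ms_tc), "MS_TRC": float(ms_trc),
             "df": {"T": df_t, "TR": df_tr, "TC": df_tc, "TRC": df_trc},
             "n_readers": int(n_r), "n_cases": int(n_c)}
    return DbmResult(ls_mean_auc_unaided=ls_unaided,
                     ls_mean_auc_aided=ls_aided, difference=float(diff),
                     ci_low=float(diff - tcrit * se),
                     ci_high=float(diff + tcrit * se),
                     f_statistic=float(f_stat), p_value=float(p),
                     ddf=float(ddf), anova=anova)


# ---------------------------------------------------------------------------
# DeLong test for two correlated AUCs
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, pos: np.ndarray):
    xs, ys = scores[pos], scores[~pos]
    ys_sorted, xs_sorted = np.sort(ys), np.sort(xs)
    v10 = (np.searchsorted(ys_sorted, xs, "left")
           + np.searchsorted(ys_sorted, xs, "right")) / (2.0 * ys.size)
    v01 = 1.0 - (np.searchsorted(xs_sorted, ys, "left")
                 + np.searchsorted(xs_sorted, ys, "right")) / (2.0 * xs.size)
    return v10, v01


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float,
                                                     float]:
    """DeLong comparison of two correlated AUCs on the same labeled cases.

    Returns ``(auc_a, auc_b, z, p)`` with a two-sided normal p-value; any
    multiplicity adjustment (e.g. Bonferroni) is the caller's concern.
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels).astype(int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired score vectors must align with labels")
    if labels.min() == labels.max():
        raise ValueError("AUC is undefined when only one class is present")
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    v10_a, v01_a = _placements(scores_a, pos)
    v10_b, v01_b = _placements(scores_b, pos)
    auc_a, auc_b = float(v10_a.mean()), float(v10_b.mean())
    if m > 1 and n > 1:
        s10 = np.cov(np.stack([v10_a, v10_b]))
        s01 = np.cov(np.stack([v01_a, v01_b]))
        var = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
               + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n)
    else:
        var = 0.0
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        z = diff / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if diff == 0:
        z, p = 0.0, 1.0
    return auc_a, auc_b, float(z), p


# ---------------------------------------------------------------------------
# secondary endpoints
# ---------------------------------------------------------------------------

def miss_rate_reduction(sens_unaided: float, sens_aided: float) -> float:
    """Relative reduction (%) in miss rate: 100 * ((1-s_u)-(1-s_a))/(1-s_u)."""
    if not (0 <= sens_unaided <= 1 and 0 <= sens_aided <= 1):
        raise ValueError("sensitivities must lie in [0, 1]")
    if sens_unaided >= 1.0:
        raise ValueError("miss-rate reduction undefined at zero unaided "
                         "miss rate")
    miss_u = 1.0 - sens_unaided
    miss_a = 1.0 - sens_aided
    return 100.0 * (miss_u - miss_a) / miss_u


class ReadTimeResult(NamedTuple):
    t: float
    df: int
    p: float
    median_unaided: float
    median_aided: float
    relative_median_change_pct: float


def readtime_test(times_unaided, times_aided, readers_unaided=None,
                  readers_aided=None) -> ReadTimeResult:
    """Paired t-test on log read times, paired at the reader level.

    When reader ids are given, each reader contributes one mean log read
    time per condition (df = n_readers - 1); otherwise the two time arrays
    are assumed already paired. Medians are reported on the raw times, with
    the relative median change 100 * (median_u - median_a) / median_u.
    """
    times_unaided = np.asarray(times_unaided, float)
    times_aided = np.asarray(times_aided, float)
    if np.any(times_unaided <= 0) or np.any(times_aided <= 0):
        raise ValueError("read times must be strictly positive")
    if readers_unaided is not None:
        su = pd.Series(np.log(times_unaided)).groupby(
            np.asarray(readers_unaided)).mean()
        sa = pd.Series(np.log(times_aided)).groupby(
            np.asarray(readers_aided)).mean()
        su, sa = su.align(sa, join="inner")
        lu, la = su.to_numpy(), sa.to_numpy()
    else:
        lu, la = np.log(times_unaided), np.log(times_aided)
    diffs = lu - la
    if np.allclose(diffs, 0.0):
        t_stat, p = 0.0, 1.0
    elif np.allclose(diffs, diffs[0]):
        # zero-variance paired differences: infinitely strong evidence
        t_stat, p = float(np.sign(diffs[0]) * np.inf), 0.0
    else:
        t_stat, p = stats.ttest_rel(lu, la)
    med_u = float(np.median(times_unaided))
    med_a = float(np.median(times_aided))
    return ReadTimeResult(t=float(t_stat), df=int(lu.size - 1), p=float(p),
                          median_unaided=med_u, median_aided=med_a,
                          relative_median_change_pct=100.0 * (med_u - med_a)
                          / med_u)


# ---------------------------------------------------------------------------
# report layer
# ---------------------------------------------------------------------------

def _group_sensitivity(sub: pd.DataFrame, threshold: float = 50.0) -> float:
    pos = sub[sub["reference"] == 1]
    return float((pos["confidence"] >= threshold).mean())


def mrmc_report(table: pd.DataFrame, bonferroni_alpha: float = 0.025) -> dict:
    """Full MRMC report: overall DBM result, per-specialty AUCs, DeLong
    comparison of radiologists vs non-radiologists (Bonferroni-adjusted
    alpha applied here, not inside the test), miss-rate reductions and
    read-time tests per group."""
    report: dict = {"dbm": dbm_analysis(table).__dict__}

    specialty_rows = []
    for (spec, cond), sub in table.groupby(["specialty", "condition"]):
        aucs = [jackknife_auc(g["confidence"].to_numpy(),
                              g["reference"].to_numpy(),
                              g["case_id"].to_numpy())[0]
                for _, g in sub.groupby("reader_id")]
        specialty_rows.append({"specialty": spec, "condition": cond,
                               "mean_reader_auc": float(np.mean(aucs)),
                               "n_readers": len(aucs)})
    report["per_specialty_auc"] = specialty_rows

    is_rad = table["specialty"] == "radiology"
    groups = {"radiologists": table[is_rad],
              "non_radiologists": table[~is_rad]}
    delong = {}
    for cond in ("unaided", "aided"):
        paired = {}
        for name, sub in groups.items():
            s = sub[sub["condition"] == cond].groupby(
                ["case_id", "category"])[["confidence", "reference"]].mean()
            paired[name] = s
        a, b = paired["radiologists"].align(paired["non_radiologists"],
                                            join="inner")
        auc_r, auc_n, z, p = delong_test(a["confidence"].to_numpy(),
                                         b["confidence"].to_numpy(),
                                         a["reference"].to_numpy().round())
        delong[cond] = {"auc_radiologists": auc_r,
                        "auc_non_radiologists": auc_n, "z": z, "p": p,
                        "significant": p < bonferroni_alpha,
                        "alpha": bonferroni_alpha}
    report["delong_rad_vs_nonrad"] = delong

    endpoints = {}
    for name, sub in groups.items():
        if len(sub) == 0:
            continue
        sens = {cond: _group_sensitivity(sub[sub["condition"] == cond])
                for cond in ("unaided", "aided")}
        entry = {"sensitivity_unaided": sens["unaided"],
                 "sensitivity_aided": sens["aided"]}
        if sens["unaided"] < 1.0:
            entry["miss_rate_reduction_pct"] = miss_rate_reduction(
                sens["unaided"], sens["aided"])
        times = sub.drop_duplicates(["reader_id", "case_id", "condition"])
        tu = times[times["condition"] == "unaided"]
        ta = times[times["condition"] == "aided"]
        entry["read_time"] = readtime_test(
            tu["read_time_s"].to_numpy(), ta["read_time_s"].to_numpy(),
            tu["reader_id"].to_numpy(), ta["reader_id"].to_numpy())._asdict()
        endpoints[name] = entry
    report["secondary_endpoints"] = endpoints
    return report
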