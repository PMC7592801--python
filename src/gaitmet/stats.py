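"""Comparison statistics for metabolic-rate estimates.

Condition effects are expressed in percent of each participant's baseline
(level grade, level shoes) stride average; associations are quantified with
the repeated-measures correlation — an ANCOVA with subject intercepts and a
common slope — and multiple conditions are Bonferroni-adjusted.  A slope
above one for estimation-versus-calorimetry percent changes means the
estimator under-responds to (underestimates) the measured change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .metabolics_muscle import MetabolicProfile
from .signals import PhaseBounds, remove_outliers

PHASES = ("ds1", "ss", "ds2", "swing")
ALPHA = 0.05


@dataclass(frozen=True)
class RmcorrResult:
    """Repeated-measures correlation: coefficient, p-value, common slope, df."""

    r: float
    p: float
    slope: float
    df: int


@dataclass
class ConditionSummary:
    """One participant-condition-method cell of the comparison design."""

    participant: str
    condition: object            # ConditionSpec
    method: str                  # musculoskeletal | jointspace | calorimetry
    stride_average: float        # W/kg
    phase_averages: dict = field(default_factory=dict)  # phase -> W/kg


def percent_change(values, baseline):
    """Change in percent of baseline: 100 (v - b) / b."""
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    return 100.0 * (np.asarray(values, dtype=float) - baseline) / baseline


def percent_of(values, baseline):
    """Level in percent of baseline: 100 v / b."""
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    return 100.0 * np.asarray(values, dtype=float) / baseline


def phase_average(profile: MetabolicProfile, phases: PhaseBounds):
    """Per-phase time averages of a profile plus shares of the stride total.

    Returns (means dict in profile units, shares dict in percent of the
    stride total; shares sum to 100).
    """
    f = profile.stride_grid / 100.0
    bounds = phases.as_dict()
    means, integrals = {}, {}
    for name, (lo, hi) in bounds.items():
        mask = (f >= lo) & (f < hi)
        if name == "swing":
            mask |= f >= bounds["swing"][1] - 1e-12  # the 100% sample
        if not mask.any():
            raise ValueError(f"phase {name} contains no grid samples")
        means[name] = float(profile.total[mask].mean())
        integrals[name] = float(profile.total[mask].sum())
    total = sum(integrals.values())
    if total == 0:
        shares = {name: 0.0 for name in bounds}
    else:
        shares = {name: 100.0 * v / total for name, v in integrals.items()}
    return means, shares


def rmcorr(x, y, subject) -> RmcorrResult:
    """Repeated-measures correlation via within-subject centering (ANCOVA).

    Fits a common slope with per-subject intercepts;
    r = sign(slope) sqrt(SS_x / (SS_x + SS_error)), tested with an F statistic
    on (1, df) where df = N - n_subjects - 1.  With a single subject this
    reduces to the Pearson correlation of that subject's data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subject = np.asarray(subject)
    if not (x.size == y.size == subject.size):
        raise ValueError("x, y and subject must be aligned")
    labels, inverse = np.unique(subject, return_inverse=True)
    counts = np.bincount(inverse)
    if labels.size > 1 and counts.min() < 2:
        raise ValueError("every subject needs at least 2 observations")
    df = x.size - labels.size - 1
    if df < 1:
        raise ValueError("insufficient observations for the repeated-measures correlation")
    x_mean = np.bincount(inverse, weights=x) / counts
    y_mean = np.bincount(inverse, weights=y) / counts
    xc = x - x_mean[inverse]
    yc = y - y_mean[inverse]
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    if sxx == 0.0:
        raise ValueError("x has no within-subject variation")
    slope = sxy / sxx
    if syy == 0.0:
        return RmcorrResult(r=0.0, p=1.0, slope=slope, df=df)
    r = sxy / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        f_stat = r**2 * df / (1.0 - r**2)
        p = float(sstats.f.sf(f_stat, 1, df))
    return RmcorrResult(r=r, p=p, slope=slope, df=df)


def bonferroni(p_values, m=None):
    """Bonferroni adjustment: min(1, p * m)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size if m is None else int(m)
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(p * m, 1.0)


def _summaries_frame(summaries):
    rows = []
    for s in summaries:
        row = {
            "participant": s.participant,
            "grade_deg": s.condition.grade_deg,
            "shoe_deg": s.condition.shoe_inclination_deg,
            "condition": s.condition.label(),
            "method": s.method,
            "stride_average": s.stride_average,
        }
        for ph in PHASES:
            row[ph] = s.phase_averages.get(ph, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def _percent_changes(df, method, family):
    """Percent change vs the participant's baseline for one method/family."""
    sub = df[df.method == method]
    base = sub[(sub.grade_deg == 0) & (sub.shoe_deg == 0)].set_index("participant")
    if family == "grade":
        fam = sub[sub.shoe_deg == 0]
    else:
        fam = sub[sub.grade_deg == 0]
    missing = sorted(set(fam.participant) - set(base.index))
    if missing:
        raise ValueError(f"missing baseline cells for {method}: {missing}")
    out = fam.copy()
    out["pct_change"] = [
        float(percent_change(v, base.loc[p, "stride_average"]))
        for p, v in zip(fam.participant, fam.stride_average)
    ]
    return out


def compare_methods(summaries, alpha: float = ALPHA, n_phase_conditions=None):
    """Run the full method-comparison analysis.

    (a) Repeated-measures correlation of each estimator's stride-average
    percent change against calorimetry, separately for the grade family and
    the shoe-inclination family (stride-average outliers beyond
    median +/- 3 IQR are removed per method first).
    (b) Per-condition repeated-measures correlation between the two
    estimators' four phase averages, Bonferroni-adjusted over conditions.

    Returns a nested dict report.
    """
    df = _summaries_frame(_as_summaries(summaries))
    methods = set(df.method)
    needed = {"musculoskeletal", "jointspace", "calorimetry"}
    if not needed <= methods:
        raise ValueError(f"missing methods: {sorted(needed - methods)}")
    cells = df.groupby(["participant", "condition"]).method.nunique()
    unmatched = cells[cells < 3]
    if len(unmatched):
        raise ValueError(
            "unmatched participant/condition cells: "
            + ", ".join(f"{p}/{c}" for p, c in unmatched.index))

    report = {"alpha": alpha, "stride_average": {}, "phase_profiles": {}}
    for family in ("grade", "shoe"):
        cal = _percent_changes(df, "calorimetry", family)
        fam_report = {}
        for method in ("musculoskeletal", "jointspace"):
            est = _percent_changes(df, method, family)
            merged = est.merge(cal, on=["participant", "condition"],
                               suffixes=("_est", "_cal"))
            _, keep_e = remove_outliers(merged.pct_change_est.to_numpy())
            _, keep_c = remove_outliers(merged.pct_change_cal.to_numpy())
            kept = merged[keep_e & keep_c]
            res = rmcorr(kept.pct_change_est, kept.pct_change_cal, kept.participant)
            fam_report[method] = {"rmcorr": res, "significant": res.p <= alpha,
                                  "n": int(len(kept))}
        report["stride_average"][family] = fam_report

    conditions = sorted(set(df.condition))
    raw_p, cond_results = [], {}
    for cond in conditions:
        sub = df[df.condition == cond]
        musc = sub[sub.method == "musculoskeletal"].set_index("participant")
        js = sub[sub.method == "jointspace"].set_index("participant")
        common = sorted(set(musc.index) & set(js.index))
        x = np.concatenate([musc.loc[p, list(PHASES)].to_numpy(dtype=float) for p in common])
        y = np.concatenate([js.loc[p, list(PHASES)].to_numpy(dtype=float) for p in common])
        subj = np.repeat(common, len(PHASES))
        res = rmcorr(x, y, subj)
        cond_results[cond] = res
        raw_p.append(res.p)
    m = len(conditions) if n_phase_conditions is None else n_phase_conditions
    adj = bonferroni(raw_p, m)
    for cond, p_adj in zip(conditions, adj):
        res = cond_results[cond]
        report["phase_profiles"][cond] = {
            "rmcorr": res, "p_adjusted": float(p_adj),
            "significant": p_adj <= alpha}
    return report


def _as_summaries(summaries):
    out = list(summaries)
    for s in out:
        if not isinstance(s, ConditionSummary):
            raise TypeError("summaries must be ConditionSummary instances")
    return out
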