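"""miRNA-stratified survival analysis.

Tumor samples are split by the expression of a chosen miRNA (median split
by default; tertile extremes and a log-rank-maximizing "optimal" cut with
a permutation p are available), and the resulting groups are compared with
Kaplan-Meier curves and the log-rank test. Control samples and samples
with missing time/event are excluded, with an exclusion count reported.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .diffexpr import NormalizationResult
from .simulate import CountMatrix


class DegenerateStratificationWarning(UserWarning):
    pass


@dataclass
class SurvivalResult:
    mirna: str | None
    rule: str
    curves: dict  # group label -> DataFrame(time, n_risk, n_events, survival)
    group_sizes: dict
    chi_square: float
    p: float
    df: int = 1
    excluded: int = 0  # samples dropped for missing time/event


def km_estimate(times, events, labels=None) -> dict:
    """Product-limit survival curves, one per group label.

    Returns {label: DataFrame(time, n_risk, n_events, survival)} where
    times are the observed event/censoring times. Censored observations
    decrement the risk set without dropping the curve.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels) if labels is not None else np.array(["all"] * len(times))
    out = {}
    for lab in pd.unique(labels):
        sel = labels == lab
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        table = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"]
        out[lab] = pd.DataFrame(
            {
                "time": table.index.to_numpy(),
                "n_risk": table["at_risk"].to_numpy(),
                "n_events": table["observed"].to_numpy(),
                "survival": surv.reindex(table.index).to_numpy(),
            }
        )
    return out


def logrank_test(times, events, labels) -> SurvivalResult:
    """Two-group log-rank test plus per-group Kaplan-Meier curves."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(groups)}")
    if events.sum() < 1:
        raise ValueError("no events observed")
    a = labels == groups[0]
    res = _ll_logrank(times[a], times[~a], events[a], events[~a])
    return SurvivalResult(
        mirna=None,
        rule="",
        curves=km_estimate(times, events, labels),
        group_sizes={str(g): int((labels == g).sum()) for g in groups},
        chi_square=float(res.test_statistic),
        p=float(res.p_value),
    )


def stratify_by_mirna(
    mirna: str,
    cm: CountMatrix,
    norm: NormalizationResult,
    rule: str = "median",
    seed: int = 0,
) -> pd.Series | None:
    """Group labels ("low"/"high") for tumor samples by miRNA expression.

    median: split at the median normalized expression, ties to "low".
    tertile: lowest vs highest tertile (middle third excluded).
    optimal: the cut among interior unique values maximizing the log-rank
    statistic (its p must then be calibrated by permutation; see
    ``test_mirna_survival``). Returns None (with a warning) when every
    sample lands in one group.
    """
    tumors = cm.tumor_ids()
    expr = norm.normalized.loc[mirna, tumors]
    if rule == "median":
        med = expr.median()
        labels = pd.Series(np.where(expr <= med, "low", "high"), index=expr.index)
    elif rule == "tertile":
        lo, hi = expr.quantile([1 / 3, 2 / 3])
        labels = pd.Series(pd.NA, index=expr.index, dtype=object)
        labels[expr <= lo] = "low"
        labels[expr > hi] = "high"
        labels = labels.dropna()
    elif rule == "optimal":
        labels = _optimal_cut_labels(expr, cm)
    else:
        raise ValueError(f"unknown stratification rule {rule!r}")
    if labels is None or labels.nunique() < 2:
        warnings.warn(
            f"constant expression for {mirna}; stratification degenerate",
            DegenerateStratificationWarning,
        )
        return None
    return labels


def _optimal_cut_labels(expr: pd.Series, cm: CountMatrix) -> pd.Series | None:
    meta = cm.samples.loc[expr.index]
    ok = meta["time"].notna() & meta["event"].notna()
    expr = expr[ok]
    if expr.nunique() < 2:
        return None
    t = meta.loc[expr.index, "time"].to_numpy(float)
    e = meta.loc[expr.index, "event"].to_numpy(int)
    cuts = np.unique(expr)[:-1]  # interior cuts: low group = expr <= cut
    best, best_stat = None, -np.inf
    for cut in cuts:
        low = expr <= cut
        if low.sum() < 2 or (~low).sum() < 2:
            continue
        res = _ll_logrank(t[low], t[~low], e[low], e[~low])
        if res.test_statistic > best_stat:
            best_stat, best = float(res.test_statistic), cut
    if best is None:
        return None
    return pd.Series(np.where(expr <= best, "low", "high"), index=expr.index)


def test_mirna_survival(
    mirna: str,
    cm: CountMatrix,
    norm: NormalizationResult,
    rule: str = "median",
    n_permutations: int = 1000,
    seed: int = 0,
) -> SurvivalResult | None:
    """Stratify tumor samples by one miRNA and run the log-rank test.

    Samples missing time or event are excluded and counted. For the
    "optimal" rule the reported p is a permutation p (labels re-derived on
    permuted expression), since the maximized statistic is not chi-square
    distributed.
    """
    labels = stratify_by_mirna(mirna, cm, norm, rule=rule, seed=seed)
    if labels is None:
        return None
    meta = cm.samples.loc[labels.index]
    ok = meta["time"].notna() & meta["event"].notna()
    excluded = int((~ok).sum())
    labels = labels[ok]
    if labels.nunique() < 2:
        return None
    times = meta.loc[labels.index, "time"].to_numpy(float)
    events = meta.loc[labels.index, "event"].to_numpy(int)
    result = logrank_test(times, events, labels.to_numpy())
    result.mirna = mirna
    result.rule = rule
    result.excluded = excluded
    if rule == "optimal" and n_permutations > 0:
        rng = np.random.default_rng(seed)
        expr = norm.normalized.loc[mirna, labels.index]
        observed = result.chi_square
        hits = 0
        for _ in range(n_permutations):
            perm = pd.Series(rng.permutation(expr.to_numpy()), index=expr.index)
            plabels = _optimal_cut_labels(perm, cm)
            if plabels is None or plabels.nunique() < 2:
                continue
            pl = plabels == "low"
            stat = _ll_logrank(
                times[pl.to_numpy()], times[~pl.to_numpy()],
                events[pl.to_numpy()], events[~pl.to_numpy()],
            ).test_statistic
            if stat >= observed:
                hits += 1
        result.p = (1 + hits) / (n_permutations + 1)
    return result
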