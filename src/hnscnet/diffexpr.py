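"""Differential expression of genes and miRNAs.

Median-of-ratios size factors, a negative-binomial Wald test for
tumor-vs-control contrasts (method-of-moments dispersion, delta-method
standard error), one-way ANOVA across disease stages on log-normalized
counts, and threshold-based selection of DEG / DE-miRNA sets.

The Wald test here is a deliberately simple NB contrast: per-feature
dispersion is estimated by method of moments with no shrinkage across
features and no GLM covariates. It is calibrated on synthetic data
(type-I error, FDR, planted-effect recovery) rather than matched to any
particular reference implementation; see docs/methods.md.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DEThresholds
from .simulate import CountMatrix

PSEUDOCOUNT = 0.5  # on group means, for log2FC stability at zero means


class NormalizationError(ValueError):
    """No feature has a positive geometric mean across all samples."""


@dataclass
class NormalizationResult:
    size_factors: pd.Series  # per sample, positive
    normalized: pd.DataFrame  # counts / size factor


def median_of_ratios(counts: pd.DataFrame) -> NormalizationResult:
    """Median-of-ratios size factors.

    s_j = median over features f of counts[f, j] / geomean_f, where the
    median runs over features whose geometric mean across samples is
    positive (i.e. features with no zero count).
    """
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no feature with a positive geometric mean; cannot compute size factors"
        )
    logx = np.log(x[positive])
    log_geomean = logx.mean(axis=1)
    ratios = np.exp(logx - log_geomean[:, None])
    s = np.median(ratios, axis=0)
    size_factors = pd.Series(s, index=counts.columns, name="size_factor")
    normalized = counts / size_factors
    return NormalizationResult(size_factors=size_factors, normalized=normalized)


def _mom_dispersion(norm_group: np.ndarray) -> np.ndarray:
    """Per-feature NB dispersion alpha from Var = mu + alpha*mu^2,
    method of moments within one group (rows features, cols samples)."""
    n = norm_group.shape[1]
    mu = norm_group.mean(axis=1)
    if n < 2:
        return np.zeros(norm_group.shape[0])
    var = norm_group.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mu > 0, (var - mu) / mu**2, 0.0)
    return alpha


def nb_wald_test(
    cm: CountMatrix,
    norm: NormalizationResult,
    group_a,
    group_b,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-feature NB Wald contrast of group_a vs group_b.

    log2FC = log2((mean_a + pc) / (mean_b + pc)) on normalized counts;
    SE from the delta method under NB variance mu + alpha*mu^2 with a
    pooled method-of-moments dispersion (floored at 1e-8); two-sided p
    from the standard normal; Benjamini-Hochberg adjustment over all
    tested features. Returns a frame indexed by feature with columns
    log2fc, fc, se, stat, pvalue, padj, mean_a, mean_b.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    low_power = len(group_a) == 1 or len(group_b) == 1

    xa = norm.normalized[group_a].to_numpy(dtype=float)
    xb = norm.normalized[group_b].to_numpy(dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    mu_a, mu_b = xa.mean(axis=1), xb.mean(axis=1)

    # pooled dispersion, weighted by residual degrees of freedom
    wa, wb = max(na - 1, 0), max(nb - 1, 0)
    if wa + wb == 0:
        alpha = np.zeros(xa.shape[0])
    else:
        alpha = (wa * _mom_dispersion(xa) + wb * _mom_dispersion(xb)) / (wa + wb)
    alpha = np.maximum(alpha, 1e-8)

    log2fc = np.log2((mu_a + pseudocount) / (mu_b + pseudocount))
    var_mean_a = (mu_a + alpha * mu_a**2) / max(na, 1)
    var_mean_b = (mu_b + alpha * mu_b**2) / max(nb, 1)
    ln2sq = np.log(2.0) ** 2
    se2 = (
        var_mean_a / (mu_a + pseudocount) ** 2 + var_mean_b / (mu_b + pseudocount) ** 2
    ) / ln2sq
    se = np.sqrt(se2)

    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, log2fc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    pvalue = np.where(se > 0, pvalue, 1.0)  # zero variance -> uninformative
    pvalue = np.clip(pvalue, 0.0, 1.0)
    padj = multipletests(pvalue, method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fc": signed_fold_change(log2fc),
            "se": se,
            "stat": stat,
            "pvalue": pvalue,
            "padj": padj,
            "mean_a": mu_a,
            "mean_b": mu_b,
        },
        index=norm.normalized.index,
    )
    out.attrs["low_power"] = low_power
    return out


def signed_fold_change(log2fc) -> np.ndarray:
    """Signed FC convention: 2**log2fc for up, -2**|log2fc| for down,
    so thresholds like |FC| >= 1.5 read naturally in both directions."""
    log2fc = np.asarray(log2fc, dtype=float)
    return np.where(log2fc >= 0, np.exp2(log2fc), -np.exp2(-log2fc))


def stage_anova(
    cm: CountMatrix,
    norm: NormalizationResult,
    stage_min_n: int = 15,
) -> tuple[pd.Series, list]:
    """One-way ANOVA across tumor stages on log2(normalized + 1).

    Stage groups with fewer than ``stage_min_n`` tumor samples are dropped
    from the design (the cohort this emulates excluded its smallest stage
    on the same grounds). Returns (per-feature p, retained stages).
    """
    tumors = cm.samples[cm.samples["condition"] == "tumor"]
    groups = {}
    for stage, sub in tumors.groupby("stage", observed=True):
        if len(sub) >= stage_min_n:
            groups[stage] = list(sub.index)
    retained = sorted(groups)
    if len(retained) < 2:
        raise ValueError(
            f"need >= 2 stage groups with n >= {stage_min_n}; have {retained}"
        )
    logx = [np.log2(norm.normalized[groups[s]].to_numpy() + 1.0) for s in retained]
    stat, p = stats.f_oneway(*logx, axis=1)
    p = np.where(np.isnan(p), 1.0, p)  # zero within/between variance
    return pd.Series(p, index=norm.normalized.index, name="anova_p"), retained


def de_table(
    cm: CountMatrix,
    norm: NormalizationResult,
    thresholds: DEThresholds | None = None,
) -> pd.DataFrame:
    """Full differential-expression table: tumor-vs-control Wald contrast,
    per-stage (vs control) contrasts for stages passing the group-size
    rule, and the stage ANOVA (raw and BH-adjusted p)."""
    thresholds = thresholds or DEThresholds()
    tumors, controls = cm.tumor_ids(), cm.control_ids()
    table = nb_wald_test(cm, norm, tumors, controls)

    tumor_meta = cm.samples[cm.samples["condition"] == "tumor"]
    for stage, sub in tumor_meta.groupby("stage", observed=True):
        if len(sub) < thresholds.stage_min_n:
            continue
        res = nb_wald_test(cm, norm, list(sub.index), controls)
        table[f"log2fc_stage_{stage}"] = res["log2fc"]
        table[f"pvalue_stage_{stage}"] = res["pvalue"]
        table[f"padj_stage_{stage}"] = res["padj"]
    try:
        anova_p, _ = stage_anova(cm, norm, thresholds.stage_min_n)
        table["anova_p"] = anova_p
        table["anova_padj"] = multipletests(anova_p.to_numpy(), method="fdr_bh")[1]
    except ValueError:
        pass  # too few stage groups; stage analysis skipped
    return table


def apply_thresholds(
    records: pd.DataFrame, thresholds: DEThresholds, mode: str
) -> pd.DataFrame:
    """Select significant features under one of three rule sets.

    mode="gene_list": adjP <= adjp_max and |FC| >= min_abs_fc_list.
    mode="gene_network": adjP <= adjp_max and |FC| >= min_abs_fc_network.
    mode="mirna": |FC| >= mirna_volcano_fc and (raw or adjusted)
    p <= mirna_volcano_p.

    Returns the selected rows with a ``direction`` column ("up"/"down").
    """
    if records.empty:
        out = records.copy()
        out["direction"] = pd.Series(dtype=object)
        return out
    absfc = records["fc"].abs()
    if mode == "gene_list":
        keep = (records["padj"] <= thresholds.adjp_max) & (absfc >= thresholds.min_abs_fc_list)
    elif mode == "gene_network":
        keep = (records["padj"] <= thresholds.adjp_max) & (
            absfc >= thresholds.min_abs_fc_network
        )
    elif mode == "mirna":
        pcol = "padj" if thresholds.mirna_use_adjusted_p else "pvalue"
        keep = (records[pcol] <= thresholds.mirna_volcano_p) & (
            absfc >= thresholds.mirna_volcano_fc
        )
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    out = records.loc[keep].copy()
    out["direction"] = np.where(out["fc"] > 0, "up", "down")
    return out


def volcano_export(records: pd.DataFrame, thresholds: DEThresholds, mode: str) -> pd.DataFrame:
    """Volcano-plot-ready frame: log2FC, -log10 p, significance class."""
    selected = apply_thresholds(records, thresholds, mode)
    pcol = (
        "padj"
        if (mode != "mirna" or thresholds.mirna_use_adjusted_p)
        else "pvalue"
    )
    with np.errstate(divide="ignore"):
        neglogp = -np.log10(records[pcol].to_numpy())
    klass = pd.Series("ns", index=records.index, dtype=object)
    klass[selected.index] = selected["direction"]
    return pd.DataFrame(
        {"log2fc": records["log2fc"], "neg_log10_p": neglogp, "class": klass}
    )
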