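"""Normalization, NB Wald contrast, stage ANOVA and threshold selection."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

import hnscnet.diffexpr as de
import hnscnet.simulate as sim
from hnscnet.config import DEThresholds, SimConfig
from oracles import bh_adjust_brute


# -- median of ratios ---------------------------------------------------------

def test_identical_columns_give_unit_size_factors():
    counts = pd.DataFrame({"s1": [2, 8, 5], "s2": [2, 8, 5], "s3": [2, 8, 5]})
    res = de.median_of_ratios(counts)
    assert np.allclose(res.size_factors, 1.0)


def test_scaled_column_scale_equivariance():
    base = np.array([3, 7, 20, 1])
    counts = pd.DataFrame({"a": base, "b": 2 * base})
    res = de.median_of_ratios(counts)
    assert res.size_factors["b"] / res.size_factors["a"] == pytest.approx(2.0)


def test_hand_computed_example():
    # geomeans (2.83, 11.31); per-column ratios constant -> s = (0.707, 1.414)
    counts = pd.DataFrame([[2, 4], [8, 16]], columns=["a", "b"])
    res = de.median_of_ratios(counts)
    assert res.size_factors["a"] == pytest.approx(1 / np.sqrt(2), abs=1e-12)
    assert res.size_factors["b"] == pytest.approx(np.sqrt(2), abs=1e-12)


def test_per_feature_scaling_invariance(rng):
    counts = pd.DataFrame(rng.integers(1, 100, size=(30, 6)))
    scale = rng.integers(1, 5, size=30)
    scaled = counts.mul(scale, axis=0)
    a = de.median_of_ratios(counts).size_factors
    b = de.median_of_ratios(scaled).size_factors
    assert np.allclose(a, b)


def test_all_zero_features_error():
    counts = pd.DataFrame([[0, 1], [1, 0]])
    with pytest.raises(de.NormalizationError):
        de.median_of_ratios(counts)


# -- NB Wald ------------------------------------------------------------------

def _cm(counts: np.ndarray, n_a: int, n_b: int) -> sim.CountMatrix:
    cols = [f"t{i}" for i in range(n_a)] + [f"c{i}" for i in range(n_b)]
    samples = pd.DataFrame(
        {
            "condition": ["tumor"] * n_a + ["control"] * n_b,
            "stage": ["II"] * n_a + [pd.NA] * n_b,
            "time": np.nan,
            "event": np.nan,
        },
        index=pd.Index(cols, name="sample_id"),
    )
    return sim.CountMatrix(
        counts=pd.DataFrame(counts, columns=cols), samples=samples
    ).validate()


def test_null_feature_has_zero_lfc_and_p_one():
    counts = np.tile([10, 10, 10, 10], (3, 1))
    cm = _cm(counts, 2, 2)
    norm = de.median_of_ratios(cm.counts)
    res = de.nb_wald_test(cm, norm, cm.tumor_ids(), cm.control_ids())
    assert np.allclose(res["log2fc"], 0.0)
    assert np.allclose(res["pvalue"], 1.0)


def test_wald_flags_low_power_single_sample_group():
    counts = np.abs(np.random.default_rng(0).integers(5, 50, size=(10, 4)))
    cm = _cm(counts, 1, 3)
    norm = de.median_of_ratios(cm.counts)
    res = de.nb_wald_test(cm, norm, cm.tumor_ids(), cm.control_ids())
    assert res.attrs["low_power"] is True


def test_groups_must_be_disjoint_and_nonempty():
    counts = np.ones((3, 4), dtype=int)
    cm = _cm(counts, 2, 2)
    norm = de.median_of_ratios(cm.counts)
    with pytest.raises(ValueError):
        de.nb_wald_test(cm, norm, [], cm.control_ids())
    with pytest.raises(ValueError):
        de.nb_wald_test(cm, norm, ["t0"], ["t0", "c0"])


def test_planted_effect_recovery_small():
    cfg = SimConfig(n_genes=500, n_tumor=40, n_control=40, frac_de_genes=0.1,
                    planted_log2fc=2.0, nb_dispersion=0.2, seed=4)
    cm, truth = sim.simulate_counts(cfg, "gene")
    norm = de.median_of_ratios(cm.counts)
    res = de.nb_wald_test(cm, norm, cm.tumor_ids(), cm.control_ids())
    sel = res[(res["padj"] <= 0.01) & (res["fc"].abs() >= 1.5)]
    true = set(truth.de_genes)
    recall = len(set(sel.index) & true) / len(true)
    assert recall >= 0.9


# -- BH adjustment property -----------------------------------------------------

@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
             min_size=1, max_size=100)
)
def test_bh_matches_brute_force_stepup(pvals):
    p = np.array(pvals)
    ours = multipletests(p, method="fdr_bh")[1]
    brute = bh_adjust_brute(p)
    assert np.allclose(ours, brute, atol=1e-12)
    assert (ours >= p - 1e-12).all()  # adjusted p >= raw p


# -- stage ANOVA ----------------------------------------------------------------

def test_two_group_anova_equals_t_test():
    rng = np.random.default_rng(1)
    counts = rng.integers(5, 200, size=(50, 40))
    cols = [f"s{i}" for i in range(40)]
    stages = ["II"] * 20 + ["III"] * 20
    samples = pd.DataFrame(
        {"condition": "tumor", "stage": stages, "time": np.nan, "event": np.nan},
        index=pd.Index(cols, name="sample_id"),
    )
    cm = sim.CountMatrix(pd.DataFrame(counts, columns=cols), samples).validate()
    norm = de.median_of_ratios(cm.counts)
    anova_p, retained = de.stage_anova(cm, norm, stage_min_n=15)
    assert retained == ["II", "III"]
    from scipy import stats

    logx = np.log2(norm.normalized.to_numpy() + 1.0)
    t_p = stats.ttest_ind(logx[:, :20], logx[:, 20:], axis=1).pvalue
    assert np.allclose(anova_p, t_p, atol=1e-10)  # F = t^2 identity


def test_small_stage_group_excluded():
    """A stage with fewer samples than the minimum is dropped from the design."""
    rng = np.random.default_rng(2)
    n = {"I": 20, "II": 25, "IVb": 10}
    cols, stages = [], []
    for s, k in n.items():
        cols += [f"{s}_{i}" for i in range(k)]
        stages += [s] * k
    counts = rng.integers(5, 100, size=(20, len(cols)))
    samples = pd.DataFrame(
        {"condition": "tumor", "stage": stages, "time": np.nan, "event": np.nan},
        index=pd.Index(cols, name="sample_id"),
    )
    cm = sim.CountMatrix(pd.DataFrame(counts, columns=cols), samples).validate()
    norm = de.median_of_ratios(cm.counts)
    _, retained = de.stage_anova(cm, norm, stage_min_n=15)
    assert retained == ["I", "II"]  # IVb (n=10) excluded


# -- threshold selection ---------------------------------------------------------

def _records(rows):
    df = pd.DataFrame(rows, columns=["log2fc", "pvalue", "padj"])
    df.index = [f"f{i}" for i in range(len(df))]
    df["fc"] = de.signed_fold_change(df["log2fc"])
    return df


def test_threshold_fixture_exact_membership():
    th = DEThresholds()
    # straddle every cut: adjp 0.01, |FC| 1.5 / 2, mirna p 1e-5
    rows = [
        (1.0, 1e-7, 0.005),   # f0 FC=2: all gene modes; mirna (p<=1e-5, FC>=2)
        (0.7, 1e-7, 0.005),   # f1 FC=1.62: gene_list only
        (1.0, 1e-7, 0.011),   # f2 adjP just over -> no gene mode; mirna ok (raw p)
        (-1.2, 1e-3, 0.009),  # f3 FC=-2.3: gene modes down; mirna fails p
        (0.5, 1e-7, 0.002),   # f4 FC=1.41: below every FC cut
        (-0.59, 1e-9, 0.001), # f5 FC=-1.5004: gene_list only
    ]
    rec = _records(rows)
    got_list = set(de.apply_thresholds(rec, th, "gene_list").index)
    got_net = set(de.apply_thresholds(rec, th, "gene_network").index)
    got_mirna = set(de.apply_thresholds(rec, th, "mirna").index)
    assert got_list == {"f0", "f1", "f3", "f5"}
    assert got_net == {"f0", "f3"}
    assert got_mirna == {"f0", "f2"}
    sel = de.apply_thresholds(rec, th, "gene_list")
    assert sel.loc["f3", "direction"] == "down"
    assert sel.loc["f0", "direction"] == "up"


def test_adjp_boundary_is_strict_le():
    th = DEThresholds()
    rec = _records([(2.0, 1e-9, 0.011), (2.0, 1e-9, 0.01)])
    got = set(de.apply_thresholds(rec, th, "gene_list").index)
    assert got == {"f1"}  # 0.011 excluded, 0.01 kept


def test_empty_records_empty_selection():
    th = DEThresholds()
    rec = _records([])
    assert de.apply_thresholds(rec, th, "gene_list").empty


def test_signed_fold_change_convention():
    assert de.signed_fold_change([1.0]) == pytest.approx([2.0])
    assert de.signed_fold_change([-1.0]) == pytest.approx([-2.0])
    assert de.signed_fold_change([0.0]) == pytest.approx([1.0])
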