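"""Tests for the normality gate, paired/group tests, ANCOVA slope
comparison and the three selection criteria."""

import numpy as np
import pytest

from equitherm import (
    compare_slopes,
    criterion1_select,
    criterion2_select,
    criterion3_select,
    group_comparison,
    normality_gate,
    paired_prepost_test,
)
from equitherm.errors import ConfigurationError, DimensionError

from conftest import simulate_measure_table
import oracles


# ---------------------------------------------------------------------------
# normality gate


def test_gate_accepts_normal_draws():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        if normality_gate(rng.standard_normal(24)) == "gaussian":
            hits += 1
    assert hits >= 90


def test_gate_flags_heavy_tailed_mixture():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        scale = np.where(rng.random(24) < 0.1, 10.0, 1.0)
        if normality_gate(scale * rng.standard_normal(24)) == "non_gaussian":
            hits += 1
    assert hits > 50


def test_gate_degenerates():
    assert normality_gate([3.0] * 10) == "non_gaussian"
    with pytest.raises(DimensionError):
        normality_gate([1.0, 2.0])


# ---------------------------------------------------------------------------
# paired pre/post test


def test_paired_no_effect_reports_one():
    with pytest.warns(RuntimeWarning):
        p, name = paired_prepost_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == 1.0


def test_paired_t_small_example():
    """Differences (2,1,2,2): t = 1.75 / (0.5/2) = 7.0 on 3 df,
    two-sided p = 0.005986."""
    p, name = paired_prepost_test([1.0, 2.0, 3.0, 4.0], [3.0, 3.0, 5.0, 6.0])
    assert name == "paired_t"
    assert p == pytest.approx(0.005986, abs=1e-4)


def test_paired_power_large_shift():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        pre = rng.standard_normal(24)
        post = pre + 3.0 + rng.standard_normal(24) * 0.5
        p, _ = paired_prepost_test(pre, post)
        hits += p < 0.05
    assert hits >= 99


# ---------------------------------------------------------------------------
# group comparison


def test_identical_groups_not_significant():
    g = [1.0, 2.0, 3.0, 4.0]
    res = group_comparison(g, g, g)
    assert res.omnibus_p > 0.05


def test_anova_toy_f_statistic():
    """One-way ANOVA on {1,2,3},{2,3,4},{7,8,9}: SSB = 62, SSW = 6,
    F = 31 on (2, 6) df."""
    from scipy.stats import f as fdist

    res = group_comparison([1, 2, 3], [2, 3, 4], [7, 8, 9])
    assert res.test == "anova_tukey"
    assert res.omnibus_p == pytest.approx(float(fdist.sf(31.0, 2, 6)), rel=1e-10)


def test_group_separation_power():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        res = group_comparison(
            rng.standard_normal(24),
            1.5 + rng.standard_normal(24),
            3.0 + rng.standard_normal(24),
        )
        hits += res.pairwise["L-H"] < 0.05
    assert hits >= 95


def test_group_too_small():
    with pytest.raises(DimensionError):
        group_comparison([1.0], [1.0, 2.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# slope comparison


def test_parallel_lines_share_slope_not_intercept():
    x = np.arange(10.0)
    y = 2.0 * x + 1.0
    comp = compare_slopes(x, y, y + 5.0)
    assert comp.p_slopes > 0.05
    assert comp.pooled_slope == pytest.approx(2.0)
    assert comp.p_intercepts < 0.05
    assert comp.pooled_intercept is None


def test_different_slopes_detected():
    x = np.arange(10.0)
    y = 1.0 * x
    comp = compare_slopes(x, y, 2.0 * y)
    assert comp.p_slopes < 0.05
    assert comp.pooled_slope is None


@pytest.mark.parametrize("seed", range(5))
def test_slope_f_matches_statsmodels_ancova(seed):
    rng = np.random.default_rng(seed)
    x = rng.uniform(10, 18, 24)
    y1 = 0.3 * x + rng.standard_normal(24)
    y2 = 0.32 * x + 1.0 + rng.standard_normal(24)
    comp = compare_slopes(x, y1, y2)
    f_bf, p_bf = oracles.ancova_slope_f_bf(x, y1, y2)
    assert comp.F_slopes == pytest.approx(f_bf, abs=1e-10)
    assert comp.p_slopes == pytest.approx(p_bf, abs=1e-12)


def test_degenerate_regressor():
    from equitherm.errors import ParameterError

    with pytest.raises(ParameterError):
        compare_slopes(np.ones(5), np.arange(5.0), np.arange(5.0))


# ---------------------------------------------------------------------------
# criteria on measure tables


def test_criterion1_recovers_planted_red_effect():
    """With a shift planted only in red-channel combinations, exactly the
    red combinations pass the simultaneous three-group test."""
    affected = {(m, "red") for m in ("SampEn", "FuzzEn", "PermEn", "DispEn", "DistEn")}
    tab = simulate_measure_table(seed=0, affected=affected, prepost_shift=1.5)
    ledger = criterion1_select(tab)
    passed = ledger.combos[ledger.combos.crit1_pass]
    assert set(passed.component) == {"red"}
    assert len(passed) == 10  # 5 measures x 2 ROIs


def test_criterion1_null_passes_nothing():
    tab = simulate_measure_table(seed=1)
    pre = tab[tab.session == "pre"].copy()
    post = pre.copy()
    post["session"] = "post"
    import pandas as pd

    with pytest.warns(RuntimeWarning):
        ledger = criterion1_select(pd.concat([pre, post], ignore_index=True))
    assert ledger.combos.crit1_pass.sum() == 0


def test_forty_combinations_enumerated():
    tab = simulate_measure_table(seed=2)
    ledger = criterion1_select(tab)
    assert len(ledger.combos) == 40


def test_criterion2_requires_group_dependence():
    """A pre/post shift identical across groups passes criterion 1 but not
    criterion 2; adding a group slope passes both."""
    flat = {("DispEn", "red")}
    tab = simulate_measure_table(seed=3, affected=flat, prepost_shift=2.0, group_slope=0.0)
    ledger = criterion2_select(tab, criterion1_select(tab))
    red = ledger.combos[(ledger.combos.measure == "DispEn") & (ledger.combos.component == "red")]
    assert red.crit1_pass.all()
    assert not red.crit2_pass.any()

    tab2 = simulate_measure_table(seed=3, affected=flat, prepost_shift=2.0, group_slope=1.5)
    ledger2 = criterion2_select(tab2, criterion1_select(tab2))
    red2 = ledger2.combos[(ledger2.combos.measure == "DispEn") & (ledger2.combos.component == "red")]
    assert red2.crit2_pass.all()


def _mini_ledger():
    import pandas as pd

    combos = pd.DataFrame(
        [
            {"measure": "DispEn", "component": "red", "roi": "ROI1_withers",
             "crit1_pass": True, "crit2_pass": True},
            {"measure": "DistEn", "component": "red", "roi": "ROI1_withers",
             "crit1_pass": True, "crit2_pass": True},
        ]
    )
    from equitherm.selection import SelectionLedger

    return SelectionLedger(combos=combos)


def test_criterion3_drops_shallow_feature_and_selects_tracking_measure():
    """A GLCM feature whose slope is below half the entropy slopes is
    dropped; an entropy measure tracking the remaining features is kept,
    one deviating from all of them is not."""
    rng = np.random.default_rng(4)
    x = np.repeat([11.2, 14.2, 16.9], 8) + rng.normal(0, 0.1, 24)
    track = 0.30 * x + rng.normal(0, 0.3, 24)
    deviant = 0.90 * x + rng.normal(0, 0.3, 24)  # much steeper than every feature
    entropy_series = {
        ("DispEn", "red", "ROI1_withers"): (x, track),
        ("DistEn", "red", "ROI1_withers"): (x, deviant),
    }
    glcm_series = {
        "SumEntrp/red/ROI1_withers": (x, 0.28 * x + rng.normal(0, 0.3, 24)),
        "Entropy/red/ROI1_withers": (x, 0.33 * x + rng.normal(0, 0.3, 24)),
        "DifEntrp/red/ROI1_withers": (x, 0.01 * x + rng.normal(0, 0.05, 24)),
    }
    ledger = criterion3_select(_mini_ledger(), entropy_series, glcm_series, standardize=False)
    feats = ledger.features.set_index("feature")
    assert not feats.loc["DifEntrp/red/ROI1_withers", "retained"]
    assert feats.loc["SumEntrp/red/ROI1_withers", "retained"]
    combos = ledger.combos.set_index("measure")
    assert combos.loc["DispEn", "crit3_pass"]
    assert not combos.loc["DistEn", "crit3_pass"]


def test_criterion3_needs_two_features():
    with pytest.raises(ConfigurationError):
        criterion3_select(_mini_ledger(), {}, {"only": (np.arange(5.0), np.arange(5.0))})


def test_criterion2_null_false_positive_rate():
    """Omnibus-level false positives stay near the nominal 5% level."""
    hits = 0
    n_rep = 200
    for seed in range(n_rep):
        rng = np.random.default_rng(seed)
        res = group_comparison(
            rng.standard_normal(24), rng.standard_normal(24), rng.standard_normal(24)
        )
        hits += res.omnibus_p < 0.05
    assert hits / n_rep <= 0.07
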