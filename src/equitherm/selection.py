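"""Three-criterion selection of informative texture measures.

A (measure, color component, ROI) combination survives:

1. **Exercise dependence** — pre- vs post-exercise values differ
   (paired t-test for Gaussian series, Wilcoxon signed-rank otherwise)
   in all three rider groups L, M and H simultaneously.
2. **Rider-group dependence** — post-exercise values differ between
   rider groups (one-way ANOVA + Tukey for Gaussian series,
   Kruskal-Wallis + Dunn with Bonferroni adjustment otherwise).
3. **Slope similarity** — the combination's regression slope against the
   rider:horse bodyweight ratio is statistically indistinguishable
   (ANCOVA slope-equality F-test, p > alpha) from at least two retained
   entropy-related GLCM texture features.  A GLCM feature is dropped
   beforehand when its slope falls below half the entropy-measure slope
   for the majority of compared pairs.

The Shapiro-Wilk test gates every parametric/non-parametric branch; the
parametric branch is used only when every series entering a test is
Gaussian.  Because the measures carry different units, criterion-3
regressions are computed on z-scored responses so slopes are comparable
across measures (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DimensionError, ParameterError

__all__ = [
    "normality_gate",
    "paired_prepost_test",
    "group_comparison",
    "GroupComparison",
    "compare_slopes",
    "RegressionComparison",
    "criterion1_select",
    "criterion2_select",
    "criterion3_select",
    "SelectionLedger",
]

PAIR_KEYS = ("L-M", "L-H", "M-H")
_COMBO_COLS = ["measure", "component", "roi"]


# ---------------------------------------------------------------------------
# elementary tests


def normality_gate(series, alpha: float = 0.05) -> str:
    """Classify a series as ``"gaussian"`` or ``"non_gaussian"``.

    Shapiro-Wilk at the given alpha; a zero-variance series is treated
    as non-Gaussian by documented rule (the test statistic is undefined).
    """
    v = np.asarray(series, dtype=float)
    if v.size < 3:
        raise DimensionError(f"normality test needs n >= 3, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise ParameterError("series contains non-finite values")
    if np.ptp(v) == 0:
        return "non_gaussian"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.shapiro(v).pvalue
    return "gaussian" if p >= alpha else "non_gaussian"


def paired_prepost_test(pre, post, alpha: float = 0.05) -> tuple[float, str]:
    """Two-sided paired comparison of pre- vs post-exercise values.

    Paired t-test when both series pass the normality gate, otherwise
    the Wilcoxon matched-pairs signed-rank test.  When every difference
    is zero the Wilcoxon statistic is undefined; p = 1 is reported with
    a warning (no evidence of any effect).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise DimensionError("pre and post series must be paired (equal length)")
    diffs = post - pre
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; reporting p = 1", RuntimeWarning,
                      stacklevel=2)
        return 1.0, "degenerate"
    if normality_gate(pre, alpha) == "gaussian" and normality_gate(post, alpha) == "gaussian":
        res = stats.ttest_rel(post, pre)
        return float(res.pvalue), "paired_t"
    res = stats.wilcoxon(post, pre)
    return float(res.pvalue), "wilcoxon"


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> dict[str, float]:
    """Dunn's post-hoc z-tests on pooled ranks, Bonferroni-adjusted.

    Uses the tie-corrected variance N(N+1)/12 - sum(t^3 - t)/(12(N-1)).
    """
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g in labels:
        n_g = groups[g].size
        mean_ranks[g] = ranks[start : start + n_g].mean()
        start += n_g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(labels) * (len(labels) - 1) // 2
    out = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            se = np.sqrt(var_base * (1.0 / groups[a].size + 1.0 / groups[b].size))
            if se == 0:
                p = 1.0
            else:
                z = (mean_ranks[a] - mean_ranks[b]) / se
                p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * n_pairs)
            out[f"{a}-{b}"] = float(p)
    return out


def _tukey_pairwise(groups: dict[str, np.ndarray]) -> dict[str, float]:
    labels = list(groups)
    res = stats.tukey_hsd(*(groups[g] for g in labels))
    out = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if j > i:
                out[f"{a}-{b}"] = float(res.pvalue[i, j])
    return out


@dataclass
class GroupComparison:
    """Omnibus and pairwise comparison of the three rider groups."""

    omnibus_p: float
    test: str
    pairwise: dict[str, float]


def group_comparison(L, M, H, alpha: float = 0.05) -> GroupComparison:
    """Compare rider-group series: ANOVA + Tukey or Kruskal-Wallis + Dunn.

    The parametric branch is used only when all three series pass the
    normality gate.
    """
    groups = {"L": np.asarray(L, float), "M": np.asarray(M, float), "H": np.asarray(H, float)}
    for g, v in groups.items():
        if v.size < 2:
            raise DimensionError(f"group {g} needs at least 2 values, got {v.size}")
    all_gaussian = all(normality_gate(v, alpha) == "gaussian" for v in groups.values())
    if all_gaussian:
        omnibus = stats.f_oneway(*groups.values())
        return GroupComparison(
            omnibus_p=float(omnibus.pvalue), test="anova_tukey", pairwise=_tukey_pairwise(groups)
        )
    try:
        omnibus_p = float(stats.kruskal(*groups.values()).pvalue)
    except ValueError:  # all values identical across groups
        omnibus_p = 1.0
    return GroupComparison(
        omnibus_p=omnibus_p, test="kruskal_dunn", pairwise=_dunn_pairwise(groups)
    )


# ---------------------------------------------------------------------------
# slope comparison (ANCOVA form)


@dataclass
class RegressionComparison:
    """Least-squares slope comparison of two series on a common regressor.

    ``p_slopes`` is the ANCOVA F-test of pooled-vs-separate slopes;
    ``pooled_slope`` is set only when the slopes do not differ
    (p > alpha), and ``pooled_intercept`` only when additionally the
    intercepts do not differ.
    """

    slope_1: float
    slope_2: float
    intercept_1: float
    intercept_2: float
    F_slopes: float
    p_slopes: float
    pooled_slope: float | None = None
    F_intercepts: float | None = None
    p_intercepts: float | None = None
    pooled_intercept: float | None = None


def _line_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """slope, intercept, rss, Sxx, Sxy for a simple least-squares line."""
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ParameterError("regressor has zero variance")
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    rss = syy - slope * sxy
    return slope, intercept, rss, sxx, sxy


def compare_slopes(x, y_1, y_2, alpha: float = 0.05) -> RegressionComparison:
    """ANCOVA comparison of two regression lines sharing the regressor x.

    Tests equality of slopes by comparing the residual sum of squares of
    the common-slope model against separate fits; on slope equality the
    pooled slope is computed and the intercepts compared the same way.
    """
    x = np.asarray(x, dtype=float)
    y_1 = np.asarray(y_1, dtype=float)
    y_2 = np.asarray(y_2, dtype=float)
    if y_1.shape != x.shape or y_2.shape != x.shape:
        raise DimensionError("both responses must match the regressor length")
    n = x.size
    if n < 3:
        raise DimensionError("need at least 3 observations per series")
    b1, a1, rss1, sxx1, sxy1 = _line_fit(x, y_1)
    b2, a2, rss2, sxx2, sxy2 = _line_fit(x, y_2)
    rss_sep = rss1 + rss2
    df_sep = 2 * n - 4
    # common slope, separate intercepts
    bc = (sxy1 + sxy2) / (sxx1 + sxx2)
    yc1 = y_1 - y_1.mean()
    yc2 = y_2 - y_2.mean()
    rss_common = float(yc1 @ yc1 + yc2 @ yc2) - bc * (sxy1 + sxy2)
    if rss_sep <= 0:  # exact fits: slopes differ iff they are unequal numbers
        f_slopes = np.inf if not np.isclose(b1, b2) else 0.0
        p_slopes = 0.0 if not np.isclose(b1, b2) else 1.0
    else:
        f_slopes = max(0.0, (rss_common - rss_sep)) / (rss_sep / df_sep)
        p_slopes = float(stats.f.sf(f_slopes, 1, df_sep))
    comp = RegressionComparison(
        slope_1=b1, slope_2=b2, intercept_1=a1, intercept_2=a2,
        F_slopes=float(f_slopes), p_slopes=p_slopes,
    )
    if p_slopes > alpha:
        comp.pooled_slope = float(bc)
        # single line over the stacked data (common slope and intercept)
        xs = np.concatenate([x, x])
        ys = np.concatenate([y_1, y_2])
        _, _, rss_single, _, _ = _line_fit(xs, ys)
        df_common = 2 * n - 3
        if rss_common <= 0:
            f_int = np.inf if rss_single > 1e-12 else 0.0
            p_int = 0.0 if rss_single > 1e-12 else 1.0
        else:
            f_int = max(0.0, (rss_single - rss_common)) / (rss_common / df_common)
            p_int = float(stats.f.sf(f_int, 1, df_common))
        comp.F_intercepts = float(f_int)
        comp.p_intercepts = p_int
        if p_int > alpha:
            ac = float(ys.mean() - bc * xs.mean())
            comp.pooled_intercept = ac
    return comp


# ---------------------------------------------------------------------------
# criteria over the tidy measure table


@dataclass
class SelectionLedger:
    """Per-combination provenance of the three selection criteria.

    ``combos`` has one row per (measure, component, roi) with the
    p-values, test names and pass flags of each criterion; ``features``
    (filled by criterion 3) has one row per GLCM feature with its slope
    and retained flag.
    """

    combos: pd.DataFrame
    features: pd.DataFrame | None = None
    alpha: float = 0.05
    meta: dict = field(default_factory=dict)

    def selected(self, criterion: int = 3) -> pd.DataFrame:
        col = f"crit{criterion}_pass"
        if col not in self.combos.columns:
            raise ConfigurationError(f"criterion {criterion} has not been evaluated")
        return self.combos[self.combos[col].fillna(False)]


def _check_table(measures: pd.DataFrame) -> None:
    needed = {"horse", "rider", "group", "session", "roi", "component", "measure", "value"}
    missing = needed - set(measures.columns)
    if missing:
        raise ConfigurationError(f"measure table lacks columns: {sorted(missing)}")


def _paired_series(sub: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    piv = sub.pivot_table(index=["horse", "rider"], columns="session", values="value")
    if "pre" not in piv.columns or "post" not in piv.columns:
        # all values of one session were dropped (e.g. undefined entropy)
        return np.array([]), np.array([])
    piv = piv.dropna(subset=["pre", "post"])
    return piv["pre"].to_numpy(), piv["post"].to_numpy()


def _norm_series(series) -> pd.DataFrame:
    """Normalize an (x, y) or (labels, x, y) series to a labeled frame."""
    if len(series) == 2:
        x, y = series
        labels = np.arange(len(x))
    else:
        labels, x, y = series
    frame = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float)},
                         index=list(labels))
    return frame.dropna()


def criterion1_select(measures: pd.DataFrame, alpha: float = 0.05) -> SelectionLedger:
    """Criterion 1: exercise dependence in all three rider groups at once.

    For each (measure, component, roi) combination, the pre/post paired
    test is run per rider group; the combination passes only when
    p < alpha in L and M and H simultaneously.
    """
    _check_table(measures)
    sessions = set(measures.session.unique())
    if not {"pre", "post"} <= sessions:
        raise ConfigurationError(f"both sessions required, table has {sorted(sessions)}")
    rows = []
    for (meas, comp, roi), combo in measures.groupby(_COMBO_COLS, sort=True):
        rec = {"measure": meas, "component": comp, "roi": roi}
        passed = True
        for g in ("L", "M", "H"):
            sub = combo[combo.group == g]
            if sub.empty:
                raise ConfigurationError(f"group {g} missing for combination {(meas, comp, roi)}")
            pre, post = _paired_series(sub)
            if pre.size < 3:
                # too few complete pairs (e.g. undefined sample entropy on
                # small patches): the combination cannot demonstrate an effect
                warnings.warn(
                    f"{(meas, comp, roi)}, group {g}: only {pre.size} complete "
                    "pairs; combination fails criterion 1",
                    RuntimeWarning, stacklevel=2,
                )
                rec[f"crit1_p_{g}"] = float("nan")
                rec[f"crit1_test_{g}"] = "insufficient_pairs"
                passed = False
                continue
            p, test = paired_prepost_test(pre, post, alpha)
            rec[f"crit1_p_{g}"] = p
            rec[f"crit1_test_{g}"] = test
            passed = passed and (p < alpha)
        rec["crit1_pass"] = passed
        rows.append(rec)
    return SelectionLedger(combos=pd.DataFrame(rows), alpha=alpha)


def criterion2_select(
    measures: pd.DataFrame, ledger: SelectionLedger, alpha: float = 0.05
) -> SelectionLedger:
    """Criterion 2: rider-group dependence of post-exercise values.

    Run only for combinations that passed criterion 1.  A combination
    passes when the omnibus test rejects (p < alpha) and at least one
    pairwise comparison rejects after adjustment.
    """
    _check_table(measures)
    combos = ledger.combos.copy()
    for col in ("crit2_omnibus_p", "crit2_test", "crit2_pass"):
        combos[col] = None
    for key in PAIR_KEYS:
        combos[f"crit2_p_{key}"] = None
    post = measures[measures.session == "post"]
    for idx, rec in combos.iterrows():
        if not rec["crit1_pass"]:
            combos.loc[idx, "crit2_pass"] = False
            continue
        sub = post[
            (post.measure == rec["measure"])
            & (post.component == rec["component"])
            & (post.roi == rec["roi"])
        ]
        series = {g: sub[sub.group == g].value.dropna().to_numpy() for g in ("L", "M", "H")}
        gc = group_comparison(series["L"], series["M"], series["H"], alpha)
        combos.loc[idx, "crit2_omnibus_p"] = gc.omnibus_p
        combos.loc[idx, "crit2_test"] = gc.test
        for key in PAIR_KEYS:
            combos.loc[idx, f"crit2_p_{key}"] = gc.pairwise[key]
        any_pair = min(gc.pairwise.values()) < alpha
        combos.loc[idx, "crit2_pass"] = bool(gc.omnibus_p < alpha and any_pair)
    combos["crit2_pass"] = combos["crit2_pass"].astype(bool)
    return SelectionLedger(combos=combos, features=ledger.features, alpha=alpha, meta=ledger.meta)


def _zscore(y: np.ndarray) -> np.ndarray:
    sd = y.std(ddof=1)
    if sd == 0:
        raise ParameterError("cannot standardize a constant series")
    return (y - y.mean()) / sd


def criterion3_select(
    ledger: SelectionLedger,
    entropy_series: dict[tuple, tuple[np.ndarray, np.ndarray]],
    glcm_series: dict[str, tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.05,
    half_slope_frac: float = 0.5,
    standardize: bool = True,
) -> SelectionLedger:
    """Criterion 3: slope similarity with retained GLCM entropy features.

    ``entropy_series`` maps (measure, component, roi) keys of the
    criterion-2 survivors to (x, y) or (labels, x, y) series, where x is
    the rider:horse bodyweight ratio of each post-exercise observation;
    ``glcm_series`` maps the GLCM feature names to series on the same
    kind of regressor.  Each comparison is made on the observations the
    two series share (labels align them; missing values are dropped).
    Responses are z-scored by default so slopes are unit-free.

    A GLCM feature is dropped when its slope is below ``half_slope_frac``
    of the entropy-measure slope for more than half of the compared
    survivor combinations.  A surviving combination passes when its slope
    is statistically equal (ANCOVA p > alpha) to at least two retained
    features.
    """
    if len(glcm_series) < 2:
        raise ConfigurationError("criterion 3 needs at least 2 GLCM features")
    combos = ledger.combos.copy()
    survivors = [
        key for key in entropy_series
        if not combos[
            (combos.measure == key[0]) & (combos.component == key[1]) & (combos.roi == key[2])
        ].empty
    ]
    prep = {}
    for key in survivors:
        frame = _norm_series(entropy_series[key])
        if standardize:
            frame = frame.assign(y=_zscore(frame.y.to_numpy()))
        prep[key] = frame
    feat_prep = {}
    for name, series in glcm_series.items():
        frame = _norm_series(series)
        if standardize:
            frame = frame.assign(y=_zscore(frame.y.to_numpy()))
        feat_prep[name] = frame

    comparisons: dict[tuple, dict[str, RegressionComparison]] = {}
    for key, ef in prep.items():
        comparisons[key] = {}
        for name, ff in feat_prep.items():
            joined = ef.join(ff, how="inner", lsuffix="_e", rsuffix="_f")
            if len(joined) < 3:
                raise ConfigurationError(
                    f"{key} and {name} share too few observations for regression"
                )
            if not np.allclose(joined.x_e, joined.x_f):
                raise ConfigurationError(
                    "entropy and GLCM series disagree on the shared regressor values"
                )
            comparisons[key][name] = compare_slopes(
                joined.x_e.to_numpy(), joined.y_e.to_numpy(), joined.y_f.to_numpy(), alpha
            )

    # half-slope exclusion of GLCM features
    feat_rows = []
    retained = []
    for name, ff in feat_prep.items():
        slope_f = _line_fit(ff.x.to_numpy(), ff.y.to_numpy())[0]
        low_count = 0
        for key in prep:
            slope_e = comparisons[key][name].slope_1
            if slope_f < half_slope_frac * slope_e:
                low_count += 1
        drop = len(prep) > 0 and low_count > 0.5 * len(prep)
        feat_rows.append(
            {"feature": name, "slope": slope_f, "n_low_slope": low_count,
             "n_compared": len(prep), "retained": not drop}
        )
        if not drop:
            retained.append(name)

    for col in ("crit3_n_equal", "crit3_pass"):
        combos[col] = None
    for name in glcm_series:
        combos[f"crit3_p_slope_{name}"] = None
        combos[f"crit3_pooled_slope_{name}"] = None
    for idx, rec in combos.iterrows():
        key = (rec["measure"], rec["component"], rec["roi"])
        if key not in prep:
            combos.loc[idx, "crit3_pass"] = False
            continue
        n_equal = 0
        for name, comp in comparisons[key].items():
            combos.loc[idx, f"crit3_p_slope_{name}"] = comp.p_slopes
            combos.loc[idx, f"crit3_pooled_slope_{name}"] = comp.pooled_slope
            if name in retained and comp.p_slopes > alpha:
                n_equal += 1
        combos.loc[idx, "crit3_n_equal"] = n_equal
        combos.loc[idx, "crit3_pass"] = bool(n_equal >= 2)
    combos["crit3_pass"] = combos["crit3_pass"].astype(bool)
    features = pd.DataFrame(feat_rows)
    return SelectionLedger(combos=combos, features=features, alpha=alpha, meta=ledger.meta)
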