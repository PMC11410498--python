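"""Outlier filter, binomial/Gaussian mixed models, and the recovery harness."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from herdrhythm import (
    fit_dfc_model,
    fit_di_model,
    remove_outliers_iqr,
    simulate_dfc_frame,
    simulate_di_frame,
)


# ------------------------------------------------------------------ IQR filter


def iqr_oracle(values, k=1.5):
    v = np.sort(np.asarray(values, float))
    n = len(v)

    def quartile(q):  # linear interpolation (R type 7)
        pos = q * (n - 1)
        lo = int(np.floor(pos))
        frac = pos - lo
        return v[lo] if lo + 1 >= n else v[lo] * (1 - frac) + v[lo + 1] * frac

    q1, q3 = quartile(0.25), quartile(0.75)
    iqr = q3 - q1
    return np.asarray(values)[
        (np.asarray(values) >= q1 - k * iqr) & (np.asarray(values) <= q3 + k * iqr)
    ]


def test_iqr_removes_gross_outlier():
    kept, mask = remove_outliers_iqr([0.1, 0.1, 0.1, 0.1, 5.0])
    assert kept.tolist() == [0.1] * 4
    assert mask.tolist() == [True] * 4 + [False]


def test_iqr_keeps_constant_values():
    kept, _ = remove_outliers_iqr([0.3] * 6)
    assert len(kept) == 6


def test_iqr_noop_below_four_values():
    kept, mask = remove_outliers_iqr([0.0, 100.0, -50.0])
    assert len(kept) == 3 and mask.all()


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=4, max_size=40))
def test_iqr_matches_quartile_arithmetic_oracle(values):
    kept, _ = remove_outliers_iqr(values)
    np.testing.assert_allclose(np.sort(kept), np.sort(iqr_oracle(values)))


# ------------------------------------------------------------------ DFC model


def test_all_ones_outcome_refused():
    frame = simulate_dfc_frame(seed=1)
    frame["dfc_binary"] = 1
    with pytest.raises(ValueError, match="no variation"):
        fit_dfc_model(frame)


def test_novar_clusters_excluded_and_logged():
    frame = simulate_dfc_frame(seed=2, n_per_group={"NOC": 8, "DTC": 8, "WDC": 8},
                               n_days=10, cluster_sd=3.0)
    res = fit_dfc_model(frame, exclude_novar=True)
    nun = frame.groupby("cluster")["dfc_binary"].nunique()
    assert res.n_clusters == int((nun > 1).sum())


def test_dfc_model_reference_levels_and_or():
    frame = simulate_dfc_frame(seed=3, n_per_group={"NOC": 10, "DTC": 10, "WDC": 10},
                               n_days=12, cluster_sd=0.8)
    res = fit_dfc_model(frame, exclude_novar=False)
    tab = res.table.set_index("term")
    assert set(tab.index) == {"intercept", "DTC", "WDC", "estrus", "milk_dev_evening"}
    np.testing.assert_allclose(
        tab["odds_ratio"], np.exp(tab["estimate"]), rtol=1e-12
    )
    assert (tab["ci_low"] <= tab["ci_high"]).all()


def test_dfc_estimates_invariant_to_row_order():
    frame = simulate_dfc_frame(seed=4, n_per_group={"NOC": 8, "DTC": 8, "WDC": 8},
                               n_days=10, cluster_sd=0.8)
    res1 = fit_dfc_model(frame, exclude_novar=False)
    shuffled = frame.sample(frac=1.0, random_state=0).reset_index(drop=True)
    res2 = fit_dfc_model(shuffled, exclude_novar=False)
    np.testing.assert_allclose(
        res1.table["estimate"], res2.table["estimate"], atol=1e-5
    )


def test_dfc_model_agrees_with_glmmtmb_oracle(tmp_path):
    """Cross-check the adaptive-GHQ logistic fit against R glmmTMB (Laplace)
    on one simulated frame."""
    frame = simulate_dfc_frame(seed=5, n_per_group={"NOC": 15, "DTC": 15, "WDC": 15},
                               n_days=15, cluster_sd=1.2)
    res = fit_dfc_model(frame, exclude_novar=False)
    csv = tmp_path / "frame.csv"
    frame.to_csv(csv, index=False)
    rscript = textwrap.dedent(f"""
        suppressMessages(library(glmmTMB))
        d <- read.csv("{csv}")
        d$treatment <- relevel(factor(d$treatment), ref = "NOC")
        m <- glmmTMB(dfc_binary ~ treatment + estrus + milk_dev_evening + (1 | cluster),
                     family = binomial, data = d)
        co <- fixef(m)$cond
        cat(paste(co, collapse = ","), "\\n")
        cat(sqrt(VarCorr(m)$cond$cluster[1]), "\\n")
    """)
    out = subprocess.run(["Rscript", "-e", rscript], capture_output=True, text=True,
                         timeout=300)
    assert out.returncode == 0, out.stderr
    lines = [l for l in out.stdout.strip().splitlines() if l.strip()]
    r_coefs = np.array([float(x) for x in lines[0].split(",")])
    r_sd = float(lines[1])
    mine = res.table.set_index("term").loc[
        ["intercept", "DTC", "WDC", "estrus", "milk_dev_evening"], "estimate"
    ].to_numpy()
    np.testing.assert_allclose(mine, r_coefs, atol=0.05)
    assert res.variance_components["cluster_sd"] == pytest.approx(r_sd, abs=0.1)


# ------------------------------------------------------------------- DI model


def test_intercept_only_di_model_recovers_sample_mean():
    rng = np.random.default_rng(6)
    n_cows, n_days = 12, 10
    rows = []
    for c in range(n_cows):
        for d in range(n_days):
            rows.append(dict(cluster=f"c{c}", treatment="NOC", estrus=0,
                             parity="primiparous", di=rng.normal(0.2, 0.1)))
    frame = pd.DataFrame(rows)
    res = fit_di_model(frame, filter_outliers=False)
    # balanced design: the fitted intercept is the grand mean
    assert res.coef("intercept") == pytest.approx(frame["di"].mean(), abs=1e-6)


def test_emmeans_equal_group_means_balanced_design():
    rng = np.random.default_rng(7)
    rows = []
    means = {"NOC": 0.10, "DTC": 0.15, "WDC": 0.05}
    for g, mu in means.items():
        for c in range(10):
            for d in range(8):
                rows.append(dict(cluster=f"{g}{c}", treatment=g, estrus=0,
                                 parity="primiparous", di=mu + rng.normal(0, 0.05)))
    frame = pd.DataFrame(rows)
    res = fit_di_model(frame, filter_outliers=False)
    emm = res.emmeans.set_index("treatment")["emmean"]
    group_means = frame.groupby("treatment")["di"].mean()
    for g in means:
        assert emm[g] == pytest.approx(group_means[g], abs=1e-6)


def test_di_outlier_filter_applied():
    frame = simulate_di_frame(seed=8, n_per_group={"NOC": 10}, n_days=10,
                              resid_sd=0.05)
    frame.loc[frame.index[:2], "di"] = 25.0  # impossible DI values
    res = fit_di_model(frame, filter_outliers=True)
    # both planted impossible values (and possibly a few genuine tail values)
    # are gone from the fit
    assert res.n_obs <= len(frame) - 2
    assert any("outlier" in n for n in res.notes)
    _, keep = remove_outliers_iqr(frame["di"].to_numpy())
    assert not keep[:2].any()


# ------------------------------------------------------------------- recovery


def test_dfc_null_estrus_effect_covered():
    """With a zero generating estrus effect, the estrus CI should cover OR=1
    in most replicates (quick 20-replicate check)."""
    effects = dict(intercept=0.5, DTC=0.0, WDC=0.0, estrus=0.0,
                   milk_dev_evening=0.0)
    covered = 0
    for rep in range(20):
        frame = simulate_dfc_frame(seed=100 + rep, effects=effects,
                                   cluster_sd=1.0,
                                   n_per_group={"NOC": 12, "DTC": 12, "WDC": 12},
                                   n_days=12)
        res = fit_dfc_model(frame, exclude_novar=False)
        lo, hi = res.ci("estrus")
        covered += int(lo <= 0.0 <= hi)
    assert covered >= 18


def test_di_null_effects_covered():
    effects = dict(intercept=0.1, DTC=0.0, WDC=0.0, estrus=0.0, multiparous=0.0)
    covered = []
    for rep in range(20):
        frame = simulate_di_frame(seed=200 + rep, effects=effects)
        res = fit_di_model(frame, filter_outliers=False)
        for term in ("DTC", "WDC", "estrus", "multiparous"):
            lo, hi = res.ci(term)
            covered.append(lo <= 0.0 <= hi)
    assert np.mean(covered) >= 0.9
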