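"""Degree of functional coupling: window ratio, sliding windows, median
split, and the harmonic-period catalog."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from herdrhythm import (
    dfc_window,
    harmonic_mask,
    harmonic_periods,
    harmonic_summary,
    inject_estrus,
    median_split,
    sliding_dfc,
)
from herdrhythm.spectral import Periodogram, fourier_grid

from conftest import cosine_series


def constructed_periodogram(sig_powers: dict[float, float], alpha=0.05):
    """Periodogram with given significant {period_h: power}; everything else
    has negligible power and FAP 1."""
    grid = fourier_grid()
    power = np.full(len(grid), 1e-6)
    fap = np.ones(len(grid))
    for period, p in sig_powers.items():
        i = int(np.argmin(np.abs(grid - 1.0 / period)))
        power[i] = p
        fap[i] = alpha / 2
    return Periodogram(freqs=grid, power=power, fap=fap, n_samples=672)


# ------------------------------------------------------------------ harmonics


@pytest.mark.parametrize("n,expected", [(2, 12.0), (5, 4.8), (7, 3.4)])
def test_harmonic_period_lengths_one_decimal(n, expected):
    periods = harmonic_periods(n)
    assert round(float(periods[-1]), 1) == expected


def test_harmonics_truncated_at_nyquist():
    periods = harmonic_periods(100)
    assert periods[-1] >= 0.5
    assert len(periods) == 48


def test_harmonic_mask_exact_on_fourier_grid():
    grid = fourier_grid()
    mask = harmonic_mask(grid)
    # harmonic n <-> grid index k = 7 n (period 24/n h on a 168-h window)
    expected = np.zeros(len(grid), bool)
    expected[np.arange(7, 337, 7) - 1] = True
    assert (mask == expected).all()


# ------------------------------------------------------------------ DFC ratio


def test_dfc_hand_computed_ratio():
    pg = constructed_periodogram({12.0: 3.0, 5.0: 1.0})
    rec = dfc_window(pg)
    assert rec.dfc == pytest.approx(0.75, abs=1e-12)
    assert rec.n_sig == 2 and rec.n_sig_harmonic == 1 and not rec.degenerate


def test_dfc_all_harmonic_is_one():
    rec = dfc_window(constructed_periodogram({24.0: 2.0, 12.0: 1.0, 8.0: 0.5}))
    assert rec.dfc == 1.0


def test_dfc_degenerate_no_significant():
    rec = dfc_window(constructed_periodogram({}))
    assert rec.dfc == 0.0 and rec.degenerate


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    harm=st.dictionaries(st.sampled_from([24.0, 12.0, 8.0, 6.0, 4.8]),
                         st.floats(0.01, 5.0), max_size=5),
    nonharm=st.dictionaries(st.sampled_from([5.0, 7.0, 9.6, 13.0]),
                            st.floats(0.01, 5.0), max_size=4),
)
def test_dfc_equals_hand_summed_power_ratio(harm, nonharm):
    pg = constructed_periodogram({**harm, **nonharm})
    rec = dfc_window(pg)
    num = sum(harm.values())
    den = num + sum(nonharm.values())
    if den == 0:
        assert rec.degenerate and rec.dfc == 0.0
    else:
        assert rec.dfc == pytest.approx(num / den, abs=1e-12)


def test_dfc_monotone_under_frequency_removal():
    base = {24.0: 2.0, 12.0: 1.5, 5.0: 1.0, 7.0: 0.5}
    dfc0 = dfc_window(constructed_periodogram(base)).dfc
    no_nonharm = dict(base)
    del no_nonharm[5.0]
    assert dfc_window(constructed_periodogram(no_nonharm)).dfc >= dfc0
    no_harm = dict(base)
    del no_harm[12.0]
    assert dfc_window(constructed_periodogram(no_harm)).dfc <= dfc0


# -------------------------------------------------------------- sliding window


def test_sliding_window_count():
    s = cosine_series(days=25, noise_sd=1.0)
    rec, _ = sliding_dfc(s)
    assert len(rec) == 25 - 7 + 1


def test_noiseless_24h_cosine_gives_dfc_one_everywhere():
    s = cosine_series(days=10)
    rec, _ = sliding_dfc(s)
    assert (rec["dfc"] == 1.0).all()


def test_dfc_scale_invariance():
    s = cosine_series(days=9, noise_sd=2.0, seed=7)
    rec1, _ = sliding_dfc(s)
    s2 = s.__class__(cow_id=s.cow_id,
                     data=s.data.assign(motion_index=s.data["motion_index"] * 3.7),
                     bin_width=s.bin_width)
    rec2, _ = sliding_dfc(s2)
    np.testing.assert_allclose(rec1["dfc"], rec2["dfc"], atol=1e-12)


def test_short_series_yields_empty_output():
    s = cosine_series(days=3)
    rec, sig = sliding_dfc(s)
    assert len(rec) == 0 and len(sig) == 0


def test_estrus_attenuation_does_not_increase_dfc():
    s = cosine_series(days=9, noise_sd=1.0, seed=12)
    day = s.data.index.normalize().unique()[4]
    attenuated = inject_estrus(s, [day], multiplier=0.2)
    rec0, _ = sliding_dfc(s)
    rec1, _ = sliding_dfc(attenuated)
    merged = rec0.merge(rec1, on="window_end_day", suffixes=("_0", "_1"))
    touched = merged[
        (merged["window_end_day"] >= day)
        & (merged["window_end_day"] <= day + pd.Timedelta(days=6))
    ]
    assert (touched["dfc_1"] <= touched["dfc_0"] + 1e-12).all()


# --------------------------------------------------------------- median split


def test_median_split_rule():
    rec = pd.DataFrame({"dfc": [1.0, 0.97, 1.0, 0.0, 1.0 - 1e-12]})
    out, med = median_split(rec)
    assert out["dfc_binary"].tolist() == [1, 0, 1, 0, 1]
    assert med == pytest.approx(1.0, abs=1e-9)


def test_median_split_warns_when_median_not_one(caplog):
    rec = pd.DataFrame({"dfc": [0.0, 0.0, 0.0]})
    with caplog.at_level("WARNING"):
        out, med = median_split(rec)
    assert (out["dfc_binary"] == 0).all() and med == 0.0
    assert any("median" in r.message for r in caplog.records)


def test_median_split_empty_errors():
    with pytest.raises(ValueError):
        median_split(pd.DataFrame({"dfc": []}))


# ------------------------------------------------------------ harmonic catalog


def test_harmonic_summary_constructed_counts():
    rows = []
    for w in range(10):
        for period in (24.0, 12.0):
            rows.append(dict(cow_id="cowA", window_end_day=w, freq=1 / period,
                             period_h=period, power=1.0, fap=0.01,
                             is_harmonic=True))
    sig = pd.DataFrame(rows)
    cat = harmonic_summary(sig, {"cowA": "NOC"})
    assert cat.counts["count"].sum() == 20
    props = cat.proportions.set_index("period_h")["proportion"]
    assert props[24.0] == 0.5 and props[12.0] == 0.5
    assert cat.per_cow["NOC"] == 20.0


def test_harmonic_summary_unknown_cow_errors():
    sig = pd.DataFrame(
        [dict(cow_id="ghost", window_end_day=0, freq=1 / 24, period_h=24.0,
              power=1.0, fap=0.01, is_harmonic=True)]
    )
    with pytest.raises(ValueError, match="ghost"):
        harmonic_summary(sig, {"cowA": "NOC"})


def test_dominant_ultradian_period_is_3_4h():
    # herd whose strongest component is the 24/7-h harmonic: the modal
    # significant harmonic period length is 3.4 h at one-decimal reporting
    from herdrhythm import HerdScenario, simulate_herd, convert_to_gmt
    from herdrhythm import exclude_invalid_days, resample_15min

    sc = HerdScenario(
        n_cows_per_group={"NOC": 2}, days=10, seed=21,
        harmonic_amplitudes={24.0: 2.0, 24.0 / 7.0: 9.0},
        estrus_probability=0.0, dropout_prob_per_day=0.0,
    )
    series, sched, metas, _ = simulate_herd(sc)
    sigs = []
    for s in series:
        s_utc, _ = convert_to_gmt(s, sched)
        s_cl, _ = exclude_invalid_days(s_utc)
        _, sig = sliding_dfc(resample_15min(s_cl))
        sigs.append(sig)
    sig = pd.concat(sigs, ignore_index=True)
    cat = harmonic_summary(sig, {s.cow_id: "NOC" for s in series})
    modal = cat.counts.loc[cat.counts["count"].idxmax(), "period_h"]
    assert modal == 3.4
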