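"""Lomb-Scargle spectral estimation with Baluev false-alarm probabilities.

A 7-day window of 15-min activity bins may have whole days missing after
cleaning, so the spectrum is estimated by least squares (Lomb-Scargle) rather
than an FFT.  Power uses the *standard* normalization

    z(f) = 1 - SSR(f) / SS0,

the fractional reduction in residual variance when a sinusoid at frequency f
is fitted to the mean-subtracted window; z lies in [0, 1].

Significance per frequency is the Baluev (2008) aliasing-free upper bound on
the false-alarm probability of observing a peak at least this high anywhere
on the searched range:

    FAP(z) <= 1 - (1 - FAP_single(z)) * exp(-tau(z)),
    FAP_single(z) = (1 - z)^((N-3)/2),
    tau(z) = gamma * W * (1 - z)^((N-4)/2) * sqrt(N_H * z / 2),

with N_H = N - 1, W = f_max * sqrt(4 pi var(t)) the effective bandwidth, and
gamma = sqrt(2/N_H) * Gamma(N_H/2) / Gamma((N_H-1)/2).  Being a bound, it is
conservative: under white noise the fraction of windows called significant at
alpha never exceeds alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lombscargle
from scipy.special import gammaln

__all__ = [
    "Periodogram",
    "fourier_grid",
    "lomb_scargle",
    "baluev_fap",
    "significant_frequencies",
    "periodogram_frame",
]

#: minimum number of samples for a spectral estimate
MIN_SAMPLES = 8


@dataclass
class Periodogram:
    """Normalized Lomb-Scargle power and per-frequency FAP on a fixed grid."""

    freqs: np.ndarray  # cycles/hour, strictly increasing
    power: np.ndarray  # standard-normalized, in [0, 1]
    fap: np.ndarray  # Baluev upper bound, in [0, 1]
    window_start: pd.Timestamp | None = None
    window_end: pd.Timestamp | None = None
    n_samples: int = 0
    valid: bool = True
    note: str = ""

    def peak(self) -> tuple[float, float]:
        """(frequency, power) of the global maximum."""
        i = int(np.argmax(self.power))
        return float(self.freqs[i]), float(self.power[i])


def fourier_grid(
    window_hours: float = 168.0, bin_minutes: float = 15.0, oversample: int = 1
) -> np.ndarray:
    """Fourier-style frequency grid k / window_hours, k = 1 .. N/2 (cycles/hour).

    For a complete 7-d window of 15-min bins this gives 336 frequencies and
    places every harmonic of the 24-h day (period 24/n h, n <= 48) exactly on
    the grid.  ``oversample`` > 1 refines the grid by that factor.
    """
    n = int(round(window_hours * 60.0 / bin_minutes))
    k = np.arange(1, (n // 2) * oversample + 1, dtype=float)
    return k / (window_hours * oversample)


def lomb_scargle(
    window,
    grid: np.ndarray | None = None,
    *,
    window_hours: float = 168.0,
) -> Periodogram:
    """Standard-normalized Lomb-Scargle periodogram of one activity window.

    ``window`` is either an :class:`~herdrhythm.activity_io.ActivitySeries`
    (its ``motion_index`` channel is analyzed) or a ``(t_hours, y)`` pair.
    The input is mean-subtracted; gaps (missing bins) are allowed.  Windows
    with fewer than 8 samples or zero variance are flagged invalid ("no
    rhythm evaluable"), which downstream feeds the DFC = 0 rule.
    """
    ws = we = None
    if hasattr(window, "data"):
        idx = window.data.index
        ws, we = idx[0], idx[-1]
        t = (idx - idx[0]).total_seconds().to_numpy() / 3600.0
        y = window.data["motion_index"].to_numpy(float)
        bin_minutes = window.bin_width
    else:
        t, y = window
        t = np.asarray(t, float)
        y = np.asarray(y, float)
        bin_minutes = np.median(np.diff(t)) * 60.0 if len(t) > 1 else 15.0
    if grid is None:
        grid = fourier_grid(window_hours, bin_minutes)
    grid = np.asarray(grid, float)

    n = len(t)
    if n < MIN_SAMPLES or np.ptp(y) == 0:
        return Periodogram(
            freqs=grid,
            power=np.zeros_like(grid),
            fap=np.ones_like(grid),
            window_start=ws,
            window_end=we,
            n_samples=n,
            valid=False,
            note="no rhythm evaluable",
        )

    yc = y - y.mean()
    power = lombscargle(t, yc, 2.0 * np.pi * grid, normalize=True)
    power = np.clip(power, 0.0, 1.0)
    fap = baluev_fap(power, n, fmax=float(grid[-1]), time_variance=float(np.var(t)))
    return Periodogram(
        freqs=grid,
        power=power,
        fap=fap,
        window_start=ws,
        window_end=we,
        n_samples=n,
    )


def baluev_fap(
    power,
    n_samples: int,
    fmax: float,
    time_variance: float,
):
    """Baluev upper bound on the false-alarm probability of a peak.

    ``power`` is standard-normalized spectral power in [0, 1] (scalar or
    array); ``n_samples`` the number of points in the window; ``fmax`` the
    highest searched frequency (cycles/hour); ``time_variance`` the variance
    of the sample times (hours^2).  Returns the FAP on the same shape.
    """
    z = np.asarray(power, dtype=float)
    if np.any(z < -1e-12) or np.any(z > 1.0 + 1e-12):
        raise ValueError("normalized power must lie in [0, 1]")
    z = np.clip(z, 0.0, 1.0)
    if n_samples <= 4:
        raise ValueError("Baluev bound needs more than 4 samples")

    nh = n_samples - 1.0
    nk = n_samples - 3.0
    fap_single = (1.0 - z) ** (0.5 * nk)
    g = np.sqrt(2.0 / nh) * np.exp(gammaln(0.5 * nh) - gammaln(0.5 * (nh - 1.0)))
    w_eff = fmax * np.sqrt(4.0 * np.pi * time_variance)
    tau = g * w_eff * (1.0 - z) ** (0.5 * (nk - 1.0)) * np.sqrt(0.5 * nh * z)
    fap = 1.0 - (1.0 - fap_single) * np.exp(-tau)
    return np.clip(fap, 0.0, 1.0) if fap.ndim else float(np.clip(fap, 0.0, 1.0))


def significant_frequencies(pg: Periodogram, alpha: float = 0.05) -> pd.DataFrame:
    """Frequencies with FAP <= ``alpha``, with periods and powers (tidy frame)."""
    mask = pg.fap <= alpha
    return pd.DataFrame(
        {
            "freq": pg.freqs[mask],
            "period_h": 1.0 / pg.freqs[mask],
            "power": pg.power[mask],
            "fap": pg.fap[mask],
        }
    )


def periodogram_frame(pg: Periodogram) -> pd.DataFrame:
    """Tidy CSV-ready export of a periodogram."""
    return pd.DataFrame(
        {
            "window_start": pg.window_start,
            "freq": pg.freqs,
            "period_h": 1.0 / pg.freqs,
            "power": pg.power,
            "fap": pg.fap,
        }
    )
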