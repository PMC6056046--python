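"""Mono-exponential relaxometry: synthetic decay series and fitting.

Mirrors the study's mapping protocols — saturation-recovery T1 (variable-TR
spin echo), multi-echo T2 and multi-echo gradient-echo T2* — as
ROI-mean-level curve fits.  The T1 model is the two-parameter saturation
recovery ``A·(1 − exp(−TR/T1))`` (the readout's constant TE factor is
absorbed into the amplitude A); a three-parameter variant with a free
inversion/saturation efficiency ``A·(1 − b·exp(−TR/T1))`` is available via a
flag.  Decays are ``A·exp(−TE/T)``.  Fixture noise is additive Gaussian:
ROI-mean signals aggregate many voxels, so the Rician floor of single-voxel
magnitude data averages out.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DecaySeries",
    "FitResult",
    "simulate_series",
    "fit_series",
    "summarize",
    "read_series_csv",
    "write_series_csv",
]

KINDS = ("t1_recovery", "t2_decay", "t2star_decay")


@dataclass(frozen=True)
class DecaySeries:
    """One measured or simulated relaxation series.

    ``abscissa_ms`` holds TR values (recovery) or TE values (decay),
    strictly increasing, length >= 3; ``signal`` is in arbitrary units.
    ``truth`` optionally records the generating ``(time_ms, amplitude)``.
    """

    kind: str
    abscissa_ms: tuple[float, ...]
    signal: tuple[float, ...]
    truth: tuple[float, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        x = np.asarray(self.abscissa_ms, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if x.size < 3 or x.size != y.size:
            raise ValueError("need >= 3 points with matching abscissa/signal lengths")
        if not np.all(np.diff(x) > 0):
            raise ValueError("abscissa_ms must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("signal values must be finite")
        object.__setattr__(self, "abscissa_ms", tuple(float(v) for v in x))
        object.__setattr__(self, "signal", tuple(float(v) for v in y))


@dataclass(frozen=True)
class FitResult:
    """Relaxation-time estimate with amplitude, residual norm and status."""

    estimate_ms: float
    amplitude: float
    rss: float
    converged: bool
    efficiency: float | None = None  # b of the 3-parameter recovery model
    message: str = ""


def _model(kind: str, three_param: bool = False):
    if kind == "t1_recovery":
        if three_param:
            return lambda x, a, t, b: a * (1.0 - b * np.exp(-x / t))
        return lambda x, a, t: a * (1.0 - np.exp(-x / t))
    return lambda x, a, t: a * np.exp(-x / t)


def simulate_series(
    kind: str,
    time_ms: float,
    amplitude: float,
    abscissa_ms: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> DecaySeries:
    """Generate a model series with seeded additive Gaussian noise.

    ``time_ms`` is the generating T1 (recovery) or T2/T2* (decay) and must be
    positive, as must ``amplitude``; ``noise_sd`` >= 0 is in signal units.
    """
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")
    if time_ms <= 0 or amplitude <= 0:
        raise ValueError("time_ms and amplitude must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    x = np.asarray(abscissa_ms, dtype=float)
    y = _model(kind)(x, amplitude, time_ms)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=x.shape)
    return DecaySeries(kind, tuple(x), tuple(y), truth=(time_ms, amplitude), seed=seed)


def fit_series(series: DecaySeries, three_param: bool = False) -> FitResult:
    """Nonlinear least-squares fit of the matching mono-exponential model.

    Initialization: amplitude = max signal; relaxation time = abscissa span/3
    for decays, abscissa median for recovery.  Non-convergence returns
    ``converged=False`` with the solver's message rather than raising.
    """
    x = np.asarray(series.abscissa_ms)
    y = np.asarray(series.signal)
    a0 = float(np.max(y))
    if a0 <= 0:
        a0 = 1.0
    if series.kind == "t1_recovery":
        t0 = float(np.median(x))
    else:
        t0 = float((x[-1] - x[0]) / 3.0)
    model = _model(series.kind, three_param and series.kind == "t1_recovery")
    p0 = [a0, t0]
    bounds_lo, bounds_hi = [0.0, 0.0], [np.inf, np.inf]
    if three_param and series.kind == "t1_recovery":
        p0.append(1.0)
        bounds_lo.append(0.0)
        bounds_hi.append(2.0)
    try:
        popt, _ = curve_fit(
            model, x, y, p0=p0, bounds=(bounds_lo, bounds_hi), maxfev=5000
        )
    except RuntimeError as exc:
        return FitResult(np.nan, np.nan, np.nan, False, message=str(exc))
    resid = y - model(x, *popt)
    eff = float(popt[2]) if len(popt) == 3 else None
    return FitResult(
        estimate_ms=float(popt[1]),
        amplitude=float(popt[0]),
        rss=float(np.sum(resid**2)),
        converged=True,
        efficiency=eff,
    )


def summarize(values: Sequence[float]) -> tuple[float, float, float]:
    """Sample mean, sample SD (n−1 denominator) and CV as a percentage."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    if mean == 0.0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return mean, sd, 100.0 * sd / abs(mean)


def write_series_csv(path: str | Path, series: DecaySeries) -> None:
    """Long-format CSV: columns kind, abscissa_ms, signal."""
    pd.DataFrame(
        {
            "kind": series.kind,
            "abscissa_ms": series.abscissa_ms,
            "signal": series.signal,
        }
    ).to_csv(path, index=False)


def read_series_csv(path: str | Path) -> DecaySeries:
    df = pd.read_csv(path)
    required = {"kind", "abscissa_ms", "signal"}
    if not required.issubset(df.columns):
        raise ValueError(f"series CSV needs columns {sorted(required)}, got {list(df.columns)}")
    kinds = df["kind"].unique()
    if len(kinds) != 1:
        raise ValueError(f"series CSV must hold a single kind, got {list(kinds)}")
    df = df.sort_values("abscissa_ms")
    return DecaySeries(str(kinds[0]), tuple(df["abscissa_ms"]), tuple(df["signal"]))
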