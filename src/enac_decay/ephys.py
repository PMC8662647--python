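"""Whole-cell and single-channel ENaC statistics from voltage-clamp data.

Operations mirror the standard analysis of two-electrode voltage-clamp
(TEVC) recordings of *Xenopus* oocytes expressing ENaC, clamped at
-60 mV with inward currents negative:

* ``measure_delta_ami`` — the amiloride-sensitive current fraction
  (dI_ami), the operational measure of ENaC activity;
* ``fit_ic50`` — Hill/Michaelian fit of the amiloride dose-response;
* ``ssi_magnitude`` — sodium self-inhibition, the percent decline of the
  peak response within 3 min of a low-to-high Na switch;
* ``fit_na_activation`` — Michaelis-Menten fit of current vs [Na+]
  (V_max, K_M);
* ``protease_fold_change`` — dI_ami ratio after/before chymotrypsin;
* ``compare_ssi_slopes`` — per-isoform SSI-vs-log[Na+] regression slopes
  with an ANCOVA interaction F-test;
* ``slope_conductance`` — single-channel slope conductance from unitary
  current-voltage points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    DivisionByZero,
    EpochMissing,
    FitDiagnosticWarning,
    FitError,
    InsufficientData,
    WindowTooShort,
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Epoch:
    """One perfusion condition: solution [Na+] and drug, in seconds."""

    start: float
    end: float
    na_mM: float
    drug: str = "none"          # none | amiloride | chymotrypsin
    conc: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("epoch end must exceed start")


@dataclass
class TevcTrace:
    """A TEVC current recording: time (s), membrane current I_M (µA)."""

    time: np.ndarray
    current: np.ndarray
    epochs: list[Epoch]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.shape != self.current.shape:
            raise ValueError("time and current must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def window(self, start: float, end: float) -> np.ndarray:
        return (self.time >= start) & (self.time < end)


@dataclass(frozen=True)
class SsiResult:
    delta_peak: float       # µA, signed peak response to the Na switch
    delta_3min: float       # µA, signed response 3 min after the switch
    ssi: float              # percent decline of the peak response


@dataclass(frozen=True)
class NaActivationFit:
    v_max: float            # µA, signed maximal current
    k_m: float              # mM, half-saturating [Na+]
    residual_norm: float

    def predict(self, na: float | np.ndarray) -> float | np.ndarray:
        na = np.asarray(na, dtype=float)
        return self.v_max * na / (self.k_m + na)


@dataclass(frozen=True)
class Ic50Fit:
    ic50: float             # µM
    hill: float
    baseline: float         # response at zero drug
    span: float             # full response amplitude

    def predict(self, conc: float | np.ndarray) -> float | np.ndarray:
        c = np.asarray(conc, dtype=float)
        ch = c ** self.hill
        return self.baseline + self.span * ch / (ch + self.ic50 ** self.hill)


@dataclass(frozen=True)
class ConductanceFit:
    g_slope: float          # pS
    reversal_mV: float      # extrapolated zero-current potential


@dataclass(frozen=True)
class SlopeComparison:
    slopes: dict            # group -> (slope, standard error)
    f_stat: float
    df: tuple[int, int]
    p_value: float


# ---------------------------------------------------------------------------
# trace statistics
# ---------------------------------------------------------------------------

def _plateau(trace: TevcTrace, epoch: Epoch, window: float) -> float:
    m = trace.window(max(epoch.start, epoch.end - window), epoch.end)
    if not np.any(m):
        raise WindowTooShort(f"no samples in the last {window} s of epoch")
    return float(np.mean(trace.current[m]))


def measure_delta_ami(trace: TevcTrace, *, plateau_window: float = 10.0) -> float:
    """Amiloride-sensitive current: drug-free minus amiloride plateau (µA).

    Uses the first amiloride epoch and the adjacent drug-free epoch in the
    same solution (the preceding one when available).  Plateaus are means
    over the trailing ``plateau_window`` seconds of each epoch.
    """
    epochs = trace.epochs
    idx = next(
        (i for i, e in enumerate(epochs) if e.drug == "amiloride"), None
    )
    if idx is None:
        raise EpochMissing("trace has no amiloride epoch")
    ami = epochs[idx]
    free = None
    for j in (idx - 1, idx + 1):
        if 0 <= j < len(epochs) and epochs[j].drug == "none" \
                and epochs[j].na_mM == ami.na_mM:
            free = epochs[j]
            break
    if free is None:
        raise EpochMissing("no adjacent drug-free epoch in the same solution")
    return _plateau(trace, free, plateau_window) - _plateau(trace, ami, plateau_window)


def _smooth(y: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average; edges use the available samples only."""
    if n <= 1:
        return y
    kernel = np.ones(n)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def ssi_magnitude(
    trace: TevcTrace,
    low: float = 1.0,
    high: float = 90.0,
    *,
    peak_window: float = 30.0,
    t3: float = 180.0,
    baseline_window: float = 10.0,
    smooth: float = 1.0,
) -> SsiResult:
    """Sodium self-inhibition from a low-to-high [Na+] switch.

    ``SSI = (|dI_peak| - |dI_3min|) / |dI_peak| * 100`` where dI_peak is
    the extremal response within ``peak_window`` seconds of the switch
    and dI_3min the response at the sample nearest ``t3`` seconds after
    it, both relative to the low-Na plateau.  The peak search runs on a
    lightly smoothed trace (``smooth`` seconds, set 0 to disable) so
    single noisy samples do not inflate the peak.
    """
    pair = None
    for a, b in zip(trace.epochs, trace.epochs[1:]):
        if (a.na_mM == low and b.na_mM == high
                and a.drug == "none" and b.drug == "none"):
            pair = (a, b)
            break
    if pair is None:
        raise EpochMissing(
            f"no consecutive {low} -> {high} mM drug-free epochs"
        )
    low_epoch, high_epoch = pair
    if high_epoch.end - high_epoch.start < t3:
        raise WindowTooShort(
            f"high-Na epoch shorter than {t3} s after the switch"
        )
    baseline = _plateau(trace, low_epoch, baseline_window)

    m_high = trace.window(high_epoch.start, high_epoch.end)
    t_high = trace.time[m_high]
    i_high = trace.current[m_high]
    if smooth > 0 and len(t_high) > 2:
        dt = np.median(np.diff(t_high))
        i_search = _smooth(i_high, max(int(round(smooth / dt)), 1))
    else:
        i_search = i_high
    m_peak = t_high < high_epoch.start + peak_window
    rel = i_search[m_peak] - baseline
    k = int(np.argmax(np.abs(rel)))
    delta_peak = float(rel[k])

    k3 = int(np.argmin(np.abs(t_high - (high_epoch.start + t3))))
    delta_3 = float(i_high[k3] - baseline)

    if delta_peak == 0.0:
        raise FitError("flat response: peak current equals the low-Na baseline")
    ssi = (abs(delta_peak) - abs(delta_3)) / abs(delta_peak) * 100.0
    return SsiResult(delta_peak=delta_peak, delta_3min=delta_3, ssi=float(ssi))


def protease_fold_change(delta_ami_before: float, delta_ami_after: float) -> float:
    """dI_ami ratio after/before protease exposure (signed ratio)."""
    if delta_ami_before == 0:
        raise DivisionByZero("dI_ami before protease is zero")
    return delta_ami_after / delta_ami_before


# ---------------------------------------------------------------------------
# dose-response and kinetic fits
# ---------------------------------------------------------------------------

def fit_ic50(
    conc_uM: Sequence[float],
    response: Sequence[float],
    *,
    hill: Optional[float] = 1.0,
) -> Ic50Fit:
    """Least-squares IC50 from an amiloride concentration-response series.

    ``response`` is the measured inhibition (any monotone measure: blocked
    current magnitude or fractional inhibition).  The model is
    ``baseline + span * c^h / (c^h + IC50^h)`` with the Hill coefficient
    fixed to 1 by default (pass ``hill=None`` to fit it).
    """
    c = np.asarray(conc_uM, dtype=float)
    y = np.asarray(response, dtype=float)
    if len(c) < 4:
        raise InsufficientData("need >= 4 concentrations spanning the transition")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")

    order = np.argsort(c)
    span0 = y[order[-1]] - y[order[0]]
    if span0 != 0:
        backsteps = np.diff(y[order]) * np.sign(span0)
        if np.any(backsteps < -0.25 * abs(span0)):
            warnings.warn(
                "dose-response series is non-monotonic beyond tolerance",
                FitDiagnosticWarning,
                stacklevel=2,
            )

    pos = c[c > 0]
    ic50_0 = float(np.exp(np.mean(np.log(pos)))) if len(pos) else 1.0

    def model_fixed(cc, log_ic50, base, span):
        ic50 = np.exp(log_ic50)
        h = hill
        ch = np.power(cc, h, where=cc > 0, out=np.zeros_like(cc))
        return base + span * ch / (ch + ic50 ** h)

    def model_free(cc, log_ic50, log_h, base, span):
        ic50, h = np.exp(log_ic50), np.exp(log_h)
        ch = np.power(cc, h, where=cc > 0, out=np.zeros_like(cc))
        return base + span * ch / (ch + ic50 ** h)

    try:
        if hill is not None:
            p0 = [np.log(ic50_0), float(y[order[0]]), float(span0) or 1.0]
            popt, _ = optimize.curve_fit(model_fixed, c, y, p0=p0, maxfev=20000)
            log_ic50, base, span = popt
            h = float(hill)
        else:
            p0 = [np.log(ic50_0), 0.0, float(y[order[0]]), float(span0) or 1.0]
            popt, _ = optimize.curve_fit(model_free, c, y, p0=p0, maxfev=20000)
            log_ic50, log_h, base, span = popt
            h = float(np.exp(log_h))
    except RuntimeError as err:
        raise FitError(f"IC50 fit did not converge: {err}") from err
    return Ic50Fit(ic50=float(np.exp(log_ic50)), hill=h,
                   baseline=float(base), span=float(span))


def fit_na_activation(
    na_mM: Sequence[float],
    current_uA: Sequence[float],
) -> NaActivationFit:
    """Michaelis-Menten fit of signed current vs extracellular [Na+]."""
    x = np.asarray(na_mM, dtype=float)
    y = np.asarray(current_uA, dtype=float)
    if len(x) < 4:
        raise InsufficientData("need >= 4 sodium concentrations")
    if np.any(x <= 0):
        raise ValueError("[Na+] must be positive")
    if np.allclose(y, 0.0):
        raise FitError("all currents are zero")

    def model(c, v_max, log_km):
        km = np.exp(log_km)
        return v_max * c / (km + c)

    p0 = [float(y[np.argmax(x)]) * 1.2, np.log(np.median(x))]
    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise FitError(f"Na-activation fit did not converge: {err}") from err
    v_max, log_km = popt
    resid = y - model(x, *popt)
    return NaActivationFit(
        v_max=float(v_max),
        k_m=float(np.exp(log_km)),
        residual_norm=float(np.linalg.norm(resid)),
    )


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, slope SE and residual sum of squares of y ~ x."""
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sse = float(resid @ resid)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise InsufficientData("all x values identical")
    se = np.sqrt(sse / max(n - 2, 1) / sxx)
    return float(coef[1]), float(se), sse


def compare_ssi_slopes(
    groups: Mapping[str, tuple[Sequence[float], Sequence[float]]],
) -> SlopeComparison:
    """Per-group SSI-vs-log10[Na+] slopes with an ANCOVA slope test.

    The ANCOVA is realized as the F-test on the group x log[Na+]
    interaction in the pooled linear model — identical slopes is the null
    hypothesis.
    """
    if len(groups) < 2:
        raise InsufficientData("need >= 2 groups")
    names = list(groups)
    slopes: dict[str, tuple[float, float]] = {}
    xs, ys, gs = [], [], []
    for gi, name in enumerate(names):
        x, y = groups[name]
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(np.unique(x)) < 3:
            raise InsufficientData(
                f"group {name!r} needs >= 3 distinct concentrations"
            )
        slope, se, _ = _ols(x, y)
        slopes[name] = (slope, se)
        xs.append(x)
        ys.append(y)
        gs.append(np.full(len(x), gi))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    g = np.concatenate(gs)
    n, k = len(x), len(names)

    dummies = np.column_stack([(g == i).astype(float) for i in range(1, k)])
    X_red = np.column_stack([np.ones(n), x, dummies])
    X_full = np.column_stack([X_red, dummies * x[:, None]])

    def _sse(X):
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r)

    sse_red = _sse(X_red)
    sse_full = _sse(X_full)
    df1 = k - 1
    df2 = n - X_full.shape[1]
    if df2 <= 0:
        raise InsufficientData("not enough points for the interaction test")
    delta = max(sse_red - sse_full, 0.0)
    scale = max(sse_red, 1.0)
    if delta <= 1e-12 * scale:
        f_stat, p = 0.0, 1.0
    elif sse_full <= 1e-12 * scale:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (delta / df1) / (sse_full / df2)
        p = float(stats.f.sf(f_stat, df1, df2))
    return SlopeComparison(slopes=slopes, f_stat=float(f_stat),
                           df=(df1, df2), p_value=p)


def slope_conductance(
    holding_mV: Sequence[float],
    unitary_pA: Sequence[float],
    *,
    v_range: tuple[float, float] = (-100.0, -20.0),
) -> ConductanceFit:
    """Single-channel slope conductance (pS) from unitary i-V points.

    Points outside ``v_range`` are dropped with a warning; the slope of
    the ordinary least-squares line i(pA) ~ V(mV) converts to pS as
    slope x 1000.
    """
    v = np.asarray(holding_mV, dtype=float)
    i = np.asarray(unitary_pA, dtype=float)
    m = (v >= v_range[0]) & (v <= v_range[1])
    if not np.all(m):
        warnings.warn(
            f"{int(np.sum(~m))} point(s) outside {v_range} mV were excluded",
            UserWarning,
            stacklevel=2,
        )
    v, i = v[m], i[m]
    if len(v) < 3 or len(np.unique(v)) < 2:
        raise InsufficientData("need >= 3 points within the voltage range")
    n = len(v)
    X = np.column_stack([np.ones(n), v])
    coef, *_ = np.linalg.lstsq(X, i, rcond=None)
    intercept, slope = coef
    reversal = float(-intercept / slope) if slope != 0 else float("nan")
    return ConductanceFit(g_slope=float(slope * 1000.0), reversal_mV=reversal)
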