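"""Current-voltage analysis for whole-cell voltage-clamp families.

Peak inward currents per holding step are fit with a Boltzmann-gated
ohmic driving force,

    I(V) = g_max * (V - V_rev) / (1 + exp[(V - V_1/2) / k]),

whose extrapolated zero-crossing V_rev is the reversal potential fed to
the permeability equations.  The module also carries the standard
corrections applied before fitting or comparing currents: P/4 leak and
capacitance subtraction, liquid-junction-potential correction, linear
rundown extrapolation and percent block of the sodium current.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "IVDataset",
    "BoltzmannFit",
    "RundownModel",
    "BlockResult",
    "FitError",
    "boltzmann_iv",
    "fit_boltzmann_iv",
    "subtract_leak_p4",
    "correct_junction",
    "fit_rundown",
    "percent_block",
    "peak_current",
    "read_iv_csv",
]


class FitError(RuntimeError):
    """Raised when the Boltzmann I-V fit fails to converge.

    Carries the attempted starting points and their outcomes in
    ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass
class IVDataset:
    """Peak-current family for one extracellular condition.

    ``sweeps`` rows are (holding voltage mV, peak current pA, time since
    seal s).
    """

    condition: str
    voltages: np.ndarray  # mV
    currents: np.ndarray  # pA
    times: np.ndarray | None = None  # s
    cell_capacitance: float | None = None  # pF

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
        if self.voltages.shape != self.currents.shape:
            raise ValueError("voltages and currents must have equal length")
        if not np.all(np.isfinite(self.voltages)):
            raise ValueError("voltages must be finite")
        if np.unique(self.voltages).size < 4:
            raise ValueError("need >= 4 distinct voltages for fitting")


@dataclass(frozen=True)
class BoltzmannFit:
    v_rev: float  # mV
    v_half: float  # mV
    slope_k: float  # mV
    g_max: float  # pA/mV
    residual: float  # root-mean-square, pA

    def __call__(self, v: np.ndarray) -> np.ndarray:
        return boltzmann_iv(np.asarray(v, dtype=float),
                            self.v_rev, self.v_half, self.slope_k, self.g_max)


@dataclass(frozen=True)
class RundownModel:
    """Linear fit of control-period current decay; callable at any t."""

    slope: float  # pA/s
    intercept: float  # pA
    window: tuple[float, float]  # s

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(t, dtype=float)


@dataclass(frozen=True)
class BlockResult:
    percent_block: float
    i_control: float  # pA, rundown-extrapolated
    i_metal: float  # pA


# --------------------------------------------------------------------------
# Boltzmann I-V fit
# --------------------------------------------------------------------------

def boltzmann_iv(v, v_rev, v_half, k, g_max):
    """Model current (pA): Boltzmann-gated linear driving force."""
    v = np.asarray(v, dtype=float)
    # clip the gate argument to keep exp() finite during optimisation
    arg = np.clip((v - v_half) / k, -500.0, 500.0)
    return g_max * (v - v_rev) / (1.0 + np.exp(arg))


def _initial_guesses(v: np.ndarray, i: np.ndarray) -> tuple[float, float, float, float]:
    order = np.argsort(v)
    v, i = v[order], i[order]
    j_peak = int(np.argmin(i))  # largest inward current anchors the open limb

    # v_rev: interpolated zero crossing nearest the peak on the depolarised
    # side (the physiological case); fall back to the hyperpolarised side,
    # then to a linear extrapolation of the whole family.
    v_rev0 = None
    crossing_above = True
    for j in range(j_peak, v.size - 1):
        if np.sign(i[j]) != np.sign(i[j + 1]) and i[j] != 0:
            denom = i[j + 1] - i[j]
            v_rev0 = v[j] - i[j] * (v[j + 1] - v[j]) / denom
            break
    if v_rev0 is None and i[j_peak] < 0 and j_peak < v.size - 2:
        # no crossing recorded: extrapolate the open limb above the peak
        res = stats.linregress(v[j_peak:], i[j_peak:])
        if res.slope > 0:
            v_rev0 = -res.intercept / res.slope
    if v_rev0 is None:
        for j in range(j_peak - 1, -1, -1):
            if np.sign(i[j]) != np.sign(i[j + 1]) and i[j + 1] != 0:
                denom = i[j + 1] - i[j]
                v_rev0 = v[j] - i[j] * (v[j + 1] - v[j]) / denom
                crossing_above = False
                break
    if v_rev0 is None:
        res = stats.linregress(v, i)
        v_rev0 = (-res.intercept / res.slope if res.slope != 0
                  else float(v[np.argmin(np.abs(i))]))

    # a crossing above the peak means the gate opens with depolarisation
    # (negative k in this parameterisation)
    k0 = -8.0 if crossing_above else 8.0

    # v_half: half-maximal inward current on the closed-gate side of the peak
    i_min = i[j_peak]
    if i_min < 0:
        limb = slice(0, j_peak + 1) if k0 < 0 else slice(j_peak, v.size)
        vl, il = v[limb], i[limb]
        v_half0 = float(vl[np.argmin(np.abs(il - 0.5 * i_min))])
    else:
        v_half0 = float(np.median(v))

    # g_max from the open-gate limb between the peak and the reversal
    mask = (v >= v[j_peak]) if k0 < 0 else (v <= v[j_peak])
    if mask.sum() >= 2 and np.unique(v[mask]).size >= 2:
        g0 = stats.linregress(v[mask], i[mask]).slope
    else:
        g0 = (i[-1] - i[0]) / (v[-1] - v[0])
    if g0 == 0:
        g0 = 1.0
    return float(v_rev0), float(v_half0), k0, float(g0)


def fit_boltzmann_iv(
    data: IVDataset,
    init: tuple[float, float, float, float] | None = None,
    max_restarts: int = 8,
) -> BoltzmannFit:
    """Least-squares fit of the Boltzmann-gated I-V model.

    Initialisation: V_rev from the interpolated zero crossing, V_1/2
    from the half-maximal inward current, k = 8 mV, g_max from the slope
    of the open-gate limb.  On non-convergence the fit restarts with
    jittered / sign-flipped k; failure after the restart schedule raises
    :class:`FitError` with per-attempt diagnostics.
    """
    v, i = data.voltages, data.currents
    p0 = init if init is not None else _initial_guesses(v, i)
    attempts = [p0]
    rng = np.random.default_rng(0)  # deterministic restart jitter
    for r in range(max_restarts):
        k_try = p0[2] * (-1 if r % 2 else 1) * (1 + 0.5 * r) + rng.normal(0, 1)
        attempts.append((p0[0], p0[1], k_try if k_try != 0 else 4.0, p0[3]))

    diagnostics = []
    best: BoltzmannFit | None = None
    for p in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    boltzmann_iv, v, i, p0=p, maxfev=20000)
        except (RuntimeError, optimize.OptimizeWarning) as exc:
            diagnostics.append((p, str(exc)))
            continue
        if not np.all(np.isfinite(popt)) or popt[2] == 0:
            diagnostics.append((p, "non-finite or degenerate parameters"))
            continue
        resid = i - boltzmann_iv(v, *popt)
        rms = float(np.sqrt(np.mean(resid**2)))
        fit = BoltzmannFit(v_rev=float(popt[0]), v_half=float(popt[1]),
                           slope_k=float(popt[2]), g_max=float(popt[3]),
                           residual=rms)
        if best is None or rms < best.residual:
            best = fit
        diagnostics.append((p, f"rms={rms:.3g}"))
    if best is None:
        raise FitError("Boltzmann I-V fit did not converge", diagnostics)
    return best


# --------------------------------------------------------------------------
# Corrections
# --------------------------------------------------------------------------

def subtract_leak_p4(
    test_voltages: Sequence[float],
    test_currents: Sequence[float],
    sub_currents: np.ndarray,
    condition: str = "",
    times: Sequence[float] | None = None,
) -> IVDataset:
    """P/4 leak and capacitance subtraction.

    Each test step at V is accompanied by four sub-sweeps at V/4;
    ``sub_currents`` has shape (n_steps, 4).  The corrected current is
    the test current minus the summed (equivalently 4x averaged)
    sub-sweep responses, which cancels any strictly linear component.
    """
    v = np.asarray(test_voltages, dtype=float)
    i = np.asarray(test_currents, dtype=float)
    sub = np.asarray(sub_currents, dtype=float)
    if sub.ndim != 2 or sub.shape != (v.size, 4):
        raise ValueError(
            f"expected {v.size} x 4 sub-sweep currents, got shape {sub.shape}")
    corrected = i - 4.0 * sub.mean(axis=1)
    return IVDataset(condition=condition, voltages=v, currents=corrected,
                     times=None if times is None else np.asarray(times, float))


def correct_junction(erev: float, jp: float,
                     plausible: tuple[float, float] = (-15.0, 15.0)) -> float:
    """Liquid-junction-potential correction.

    Convention: corrected E_rev = measured E_rev - JP.  A JP outside the
    plausibility window triggers a warning, not an error.
    """
    if not plausible[0] <= jp <= plausible[1]:
        warnings.warn(
            f"junction potential {jp} mV outside plausible window {plausible}",
            stacklevel=2)
    return erev - jp


def fit_rundown(times: Sequence[float], currents: Sequence[float]) -> RundownModel:
    """Ordinary least-squares line through the control-period decay.

    Needs >= 3 control points with non-degenerate timestamps.  The
    returned model extrapolates to any time.
    """
    t = np.asarray(times, dtype=float)
    i = np.asarray(currents, dtype=float)
    if t.size < 3:
        raise ValueError("need >= 3 control points for the rundown fit")
    if np.unique(t).size < 2:
        raise ValueError("degenerate design: all control timestamps identical")
    res = stats.linregress(t, i)
    return RundownModel(slope=float(res.slope), intercept=float(res.intercept),
                        window=(float(t.min()), float(t.max())))


def percent_block(i_metal: float, rundown: RundownModel,
                  t_measure: float) -> BlockResult:
    """Percent block relative to the rundown-extrapolated control current.

    percent = (I_metal - I_control) / I_control * 100 with
    I_control = rundown(t_measure).  Invariant under common rescaling of
    both currents.
    """
    i_control = float(rundown(t_measure))
    if i_control == 0:
        raise ValueError("extrapolated control current is zero at t_measure")
    pct = (i_metal - i_control) / i_control * 100.0
    return BlockResult(percent_block=pct, i_control=i_control, i_metal=i_metal)


def peak_current(trace_t: Sequence[float], trace_i: Sequence[float],
                 window_s: float = 0.1) -> float:
    """Peak (largest-magnitude) current within the first ``window_s`` of a step."""
    t = np.asarray(trace_t, dtype=float)
    i = np.asarray(trace_i, dtype=float)
    mask = t < t[0] + window_s
    seg = i[mask]
    return float(seg[np.argmax(np.abs(seg))])


def plot_iv_fit(data: IVDataset, fit: BoltzmannFit, path) -> None:
    """Save a quick-look figure of the peak I-V points and fitted curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.axhline(0.0, color="0.8", lw=0.8)
    ax.plot(data.voltages, data.currents, "o", ms=4, label=data.condition)
    vv = np.linspace(data.voltages.min(), data.voltages.max(), 400)
    ax.plot(vv, fit(vv), "-", lw=1.2,
            label=f"fit: $V_{{rev}}$={fit.v_rev:.1f} mV")
    ax.axvline(fit.v_rev, color="0.6", ls=":", lw=0.8)
    ax.set_xlabel("voltage (mV)")
    ax.set_ylabel("peak current (pA)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def read_iv_csv(path, condition: str | None = None) -> list[IVDataset]:
    """Read peak I-V sweeps from CSV.

    Long format columns: ``condition``, ``voltage_mV``, ``current_pA``,
    optional ``t_s``; or a bare two-column (voltage_mV, current_pA) file
    for a single condition.
    """
    df = pd.read_csv(path)
    if "condition" not in df.columns:
        df["condition"] = condition or "default"
    out = []
    for cond, grp in df.groupby("condition", sort=False):
        if condition is not None and cond != condition:
            continue
        out.append(IVDataset(
            condition=str(cond),
            voltages=grp["voltage_mV"].to_numpy(),
            currents=grp["current_pA"].to_numpy(),
            times=grp["t_s"].to_numpy() if "t_s" in grp.columns else None,
        ))
    if not out:
        raise ValueError(f"no sweeps found for condition {condition!r}")
    return out
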