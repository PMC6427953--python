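"""Van 't Hoff fits of one- and two-transition thermal denaturation curves.

Circular-dichroism ellipticity monitored at a fixed wavelength as the
sample is heated is modelled as a population-weighted sum of linear state
baselines,

    theta(T) = sum_s p_s(T) * (b_s + m_s * T),

with populations from two-state (N <-> D) or sequential three-state
(N <-> I <-> D) Boltzmann expressions.  Each transition i carries a
melting temperature Tm_i and a van 't Hoff enthalpy dH_i through the
Gibbs-Helmholtz free energy with dCp = 0:

    dG_i(T) = dH_i * (1 - T / Tm_i)        (temperatures in kelvin)
    K_i(T)  = exp(-dG_i(T) / (R * T))

so that at T = Tm_i the two states flanking transition i are equally
populated.  All public interfaces use degrees Celsius; kelvin appears only
inside the model.  Parameters are estimated by nonlinear least squares with
automatic initialization (transition guesses from extrema of the smoothed
derivative, baselines from linear fits to the curve ends); standard errors
are fit-covariance estimates and are labelled as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter

logger = logging.getLogger(__name__)

R_KJ = 8.31446261815324e-3   # gas constant, kJ/(mol K)
_T0 = 273.15


class DegenerateBaselineError(ValueError):
    """Native and denatured baselines coincide somewhere in the data range."""


@dataclass(frozen=True)
class MeltCurve:
    """A melting curve: temperatures (Celsius, strictly increasing) and
    ellipticity values in arbitrary units (e.g. mdeg at 222 nm)."""

    temperature: np.ndarray
    ellipticity: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.temperature, dtype=float)
        y = np.asarray(self.ellipticity, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("temperature and ellipticity must be equal-length 1D")
        if t.size < 10:
            raise ValueError("need at least 10 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in curve")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "ellipticity", y)

    def __len__(self):
        return self.temperature.size


def _populations(t_celsius: np.ndarray, tms, dhs) -> np.ndarray:
    """State populations (n_states x n_points) for sequential transitions."""
    tk = np.asarray(t_celsius, dtype=float) + _T0
    ks = []
    for tm, dh in zip(tms, dhs):
        dg = dh * (1.0 - tk / (tm + _T0))
        ks.append(np.exp(np.clip(-dg / (R_KJ * tk), -500, 500)))
    if len(ks) == 1:
        z = 1.0 + ks[0]
        return np.vstack([1.0 / z, ks[0] / z])
    k1, k2 = ks
    z = 1.0 + k1 + k1 * k2
    return np.vstack([1.0 / z, k1 / z, k1 * k2 / z])


def melt_model(t_celsius: np.ndarray, n_transitions: int,
               params: np.ndarray) -> np.ndarray:
    """Model ellipticity.

    ``params`` is ``[b_N, m_N, (b_I, m_I,) b_D, m_D, Tm_1, dH_1 (, Tm_2,
    dH_2)]`` -- one (intercept, slope) baseline per state in order
    native (, intermediate), denatured, then (Tm, dH) per transition with
    Tm in Celsius and dH in kJ/mol.
    """
    p = np.asarray(params, dtype=float)
    n_states = n_transitions + 1
    baselines = p[:2 * n_states].reshape(n_states, 2)
    tms = p[2 * n_states::2]
    dhs = p[2 * n_states + 1::2]
    pops = _populations(t_celsius, tms, dhs)
    t = np.asarray(t_celsius, dtype=float)
    theta = np.zeros_like(t)
    for s in range(n_states):
        theta += pops[s] * (baselines[s, 0] + baselines[s, 1] * t)
    return theta


@dataclass(frozen=True)
class MeltFit:
    """Result of fitting a melting curve.

    ``tm``/``dh`` are per-transition midpoints (Celsius) and van 't Hoff
    enthalpies (kJ/mol), ordered so Tm increases; ``tm_stderr``/``dh_stderr``
    are fit-covariance standard errors (not replicate spreads).
    ``fraction_denatured`` is the model-based baseline-normalized fraction;
    ``flags`` collects diagnostics such as overlapping transitions.
    """

    n_transitions: int
    tm: tuple
    dh: tuple
    tm_stderr: tuple
    dh_stderr: tuple
    baseline_native: tuple        # (intercept, slope)
    baseline_denatured: tuple
    baseline_intermediate: tuple | None
    fraction_denatured: np.ndarray
    residual_norm: float
    converged: bool
    flags: tuple = ()
    message: str = ""
    params: np.ndarray = field(default=None, repr=False)

    def predict(self, t_celsius) -> np.ndarray:
        """Model ellipticity at the given temperatures."""
        return melt_model(np.asarray(t_celsius, dtype=float),
                          self.n_transitions, self.params)

    def baseline_values(self, t_celsius):
        """(theta_N, theta_D) baseline values at the given temperatures."""
        t = np.asarray(t_celsius, dtype=float)
        bn, mn = self.baseline_native
        bd, md = self.baseline_denatured
        return bn + mn * t, bd + md * t

    def as_dict(self) -> dict:
        return {
            "n_transitions": self.n_transitions,
            "tm_celsius": list(self.tm),
            "dh_vant_hoff_kj_mol": list(self.dh),
            "tm_stderr": list(self.tm_stderr),
            "dh_stderr": list(self.dh_stderr),
            "baseline_native": list(self.baseline_native),
            "baseline_denatured": list(self.baseline_denatured),
            "baseline_intermediate": (list(self.baseline_intermediate)
                                      if self.baseline_intermediate else None),
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "flags": list(self.flags),
            "message": self.message,
        }


def _initial_guess(curve: MeltCurve, n_transitions: int) -> np.ndarray:
    t, y = curve.temperature, curve.ellipticity
    n = len(t)
    k = max(3, int(round(0.15 * n)))
    b_n = np.polyfit(t[:k], y[:k], 1)        # [slope, intercept]
    b_d = np.polyfit(t[-k:], y[-k:], 1)

    win = min(n if n % 2 == 1 else n - 1, max(5, (n // 10) * 2 + 1))
    smooth = savgol_filter(y, win, 3) if n >= 7 else y
    dy = np.abs(np.gradient(smooth, t))
    peaks, props = find_peaks(dy, distance=max(1, n // 10))
    order = peaks[np.argsort(dy[peaks])[::-1]] if peaks.size else np.array([], int)
    guesses = sorted(t[order[:n_transitions]]) if order.size else []
    span = t[-1] - t[0]
    fallback = [t[0] + 0.4 * span, t[0] + 0.7 * span]
    while len(guesses) < n_transitions:
        guesses.append(fallback[len(guesses)])
    guesses = sorted(guesses)

    params = [b_n[1], b_n[0]]
    if n_transitions == 2:
        mid = (y[np.searchsorted(t, guesses[0]):
                 np.searchsorted(t, guesses[1])])
        b_i = float(np.median(mid)) if mid.size else (b_n[1] + b_d[1]) / 2
        params += [b_i, 0.0]
    params += [b_d[1], b_d[0]]
    for g in guesses:
        params += [float(g), 300.0]
    return np.array(params)


def fit_melt(curve: MeltCurve, n_transitions: int = 1) -> MeltFit:
    """Fit a one- or two-transition van 't Hoff model to a melting curve.

    Non-convergence is reported through ``converged=False`` and ``message``
    rather than an exception; a two-transition fit whose midpoints come out
    closer than 5 Celsius is flagged ``overlapping-transitions``.
    """
    if n_transitions not in (1, 2):
        raise ValueError("n_transitions must be 1 or 2")
    t, y = curve.temperature, curve.ellipticity
    p0 = _initial_guess(curve, n_transitions)
    n_states = n_transitions + 1
    lo = [-np.inf] * (2 * n_states) + [t[0], 5.0] * n_transitions
    hi = [np.inf] * (2 * n_states) + [t[-1], 5000.0] * n_transitions
    p0[2 * n_states::2] = np.clip(p0[2 * n_states::2], t[0], t[-1])

    def f(tt, *p):
        return melt_model(tt, n_transitions, np.array(p))

    converged, message = True, ""
    try:
        popt, pcov = curve_fit(f, t, y, p0=p0, bounds=(lo, hi),
                               maxfev=20000)
        perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    except (RuntimeError, ValueError) as exc:
        converged, message = False, str(exc)
        popt, perr = p0, np.full(p0.shape, np.nan)

    tms = list(popt[2 * n_states::2])
    dhs = list(popt[2 * n_states + 1::2])
    tm_err = list(perr[2 * n_states::2])
    dh_err = list(perr[2 * n_states + 1::2])
    flags = []
    if n_transitions == 2:
        if tms[0] > tms[1]:
            tms[0], tms[1] = tms[1], tms[0]
            dhs[0], dhs[1] = dhs[1], dhs[0]
            tm_err[0], tm_err[1] = tm_err[1], tm_err[0]
            dh_err[0], dh_err[1] = dh_err[1], dh_err[0]
            popt = np.array(list(popt[:2 * n_states])
                            + [tms[0], dhs[0], tms[1], dhs[1]])
            flags.append("transitions-reordered")
        # a transition's temperature width is ~4RTm^2/dH; midpoints closer
        # than the mean width cannot be resolved as two separate steps
        widths = [4.0 * R_KJ * (tm + _T0) ** 2 / dh
                  for tm, dh in zip(tms, dhs)]
        if abs(tms[1] - tms[0]) < 0.5 * (widths[0] + widths[1]):
            flags.append("overlapping-transitions")

    baselines = popt[:2 * n_states].reshape(n_states, 2)
    b_nat = (float(baselines[0, 0]), float(baselines[0, 1]))
    b_den = (float(baselines[-1, 0]), float(baselines[-1, 1]))
    b_int = ((float(baselines[1, 0]), float(baselines[1, 1]))
             if n_transitions == 2 else None)

    theta_fit = melt_model(t, n_transitions, popt)
    resid = float(np.linalg.norm(y - theta_fit))
    theta_n = b_nat[0] + b_nat[1] * t
    theta_d = b_den[0] + b_den[1] * t
    den = theta_d - theta_n
    with np.errstate(divide="ignore", invalid="ignore"):
        f_d = np.clip((theta_fit - theta_n) / den, 0.0, 1.0)
    f_d = np.where(np.isfinite(f_d), f_d, 0.0)

    return MeltFit(
        n_transitions=n_transitions, tm=tuple(tms), dh=tuple(dhs),
        tm_stderr=tuple(tm_err), dh_stderr=tuple(dh_err),
        baseline_native=b_nat, baseline_denatured=b_den,
        baseline_intermediate=b_int, fraction_denatured=f_d,
        residual_norm=resid, converged=converged, flags=tuple(flags),
        message=message, params=np.asarray(popt, dtype=float))


def fraction_denatured(curve: MeltCurve, fit: MeltFit) -> np.ndarray:
    """Baseline-corrected, normalized fraction denatured of the *observed* data.

    f_D(T) = (theta(T) - theta_N(T)) / (theta_D(T) - theta_N(T)), clipped to
    [0, 1].  Raises :class:`DegenerateBaselineError` (naming the first
    offending temperature) if the two baselines approach each other within
    the data range.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; fraction undefined")
    t, y = curve.temperature, curve.ellipticity
    theta_n, theta_d = fit.baseline_values(t)
    den = theta_d - theta_n
    eps = 1e-9 + 1e-3 * float(np.std(y))
    bad = np.abs(den) < eps
    if np.any(bad):
        t_bad = float(t[np.argmax(bad)])
        raise DegenerateBaselineError(
            f"native and denatured baselines coincide near T = {t_bad:.1f} C")
    return np.clip((y - theta_n) / den, 0.0, 1.0)


def select_n_transitions(curve: MeltCurve, penalty: float = 2.0) -> int:
    """Simple model-selection helper: prefer 2 transitions only when the
    residual improves by more than ``penalty`` x the parameter-count cost
    (BIC-style)."""
    n = len(curve)
    fits = {k: fit_melt(curve, k) for k in (1, 2)}
    bic = {}
    for k, ft in fits.items():
        rss = max(ft.residual_norm ** 2, 1e-300)
        n_par = 2 * (k + 1) + 2 * k
        bic[k] = n * np.log(rss / n) + penalty * n_par * np.log(n)
    if not fits[2].converged or "overlapping-transitions" in fits[2].flags:
        return 1
    return 2 if bic[2] < bic[1] else 1
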