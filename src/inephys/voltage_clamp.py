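"""Voltage-clamp analysis: I–V extraction, conductance transform, Boltzmann
fits and availability-window analytics.

Peak transient inward (Na⁺-like) current is the minimum in the first 10 ms
of each step after 0.3 ms of capacitive-transient blanking; sustained
outward (K⁺-like) current is the mean of the last 20% of the step.
Conductance is current divided by driving force, G = I/(Vc − Erev), with
Erev = +66.7 mV for the inward branch by default.  Normalized conductance
is fitted with the Boltzmann equation

    G/Gmax = 1 / (1 + exp((V50 − Vc)/h))          (activation)
    G/Gmax = 1 / (1 + exp((Vc − V50)/h))          (inactivation)

with the slope factor h reported positive for both branches and the
direction carried by ``curve_type``.  The availability window is the
product of the steady-state activation and availability curves; its
maximum bounds the sustained (window) current a cell can pass, and the
crossing voltage is where the two curves intersect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .errors import FitError, ParameterError, ProtocolError
from .io import SweepSet

__all__ = [
    "IVPoint",
    "BoltzmannFit",
    "AvailabilityWindow",
    "extract_peak_currents",
    "extract_inactivation_peaks",
    "conductance_transform",
    "fit_boltzmann",
    "availability_window",
    "DEFAULT_E_REV_NA",
]

#: Na⁺ reversal potential (mV) used as the default driving-force reference
DEFAULT_E_REV_NA = 66.7


@dataclass(frozen=True)
class IVPoint:
    """Peak currents at one command potential (pA; densities in pA/pF)."""

    vc: float
    peak_inward: float
    peak_outward: float
    inward_density: Optional[float] = None
    outward_density: Optional[float] = None

    def __post_init__(self):
        if self.peak_inward > 0 or self.peak_outward < 0:
            raise ParameterError(
                "sign convention: peak_inward <= 0 <= peak_outward "
                f"(got {self.peak_inward}, {self.peak_outward})"
            )


@dataclass(frozen=True)
class BoltzmannFit:
    """Fitted Boltzmann parameters of one gating branch.

    ``gmax`` is the extrapolated maximum conductance (nS), ``v50`` the
    half-maximum voltage (mV), ``h`` the slope factor (mV, positive;
    direction given by ``curve_type``), ``rss`` the residual sum of
    squares in squared-conductance units.
    """

    gmax: float
    v50: float
    h: float
    rss: float
    n_points: int
    curve_type: str

    def __post_init__(self):
        if self.curve_type not in ("activation", "inactivation"):
            raise ParameterError(f"curve_type must be activation|inactivation, got {self.curve_type!r}")
        if not (self.gmax > 0):
            raise ParameterError(f"fitted gmax must be > 0, got {self.gmax}")
        if not (self.h > 0):
            raise ParameterError(f"slope factor must be reported positive, got {self.h}")

    def fraction(self, v) -> np.ndarray:
        """Normalized curve G/Gmax evaluated at voltage(s) ``v``."""
        v = np.asarray(v, dtype=float)
        sign = 1.0 if self.curve_type == "activation" else -1.0
        z = np.clip(sign * (self.v50 - v) / self.h, -500, 500)
        return 1.0 / (1.0 + np.exp(z))

    def __call__(self, v) -> np.ndarray:
        return self.gmax * self.fraction(v)


@dataclass
class AvailabilityWindow:
    """Overlap of steady-state activation and availability curves."""

    voltage_grid: np.ndarray
    window_curve: np.ndarray
    window_max: float
    v_at_max: float
    crossing_v: Optional[float]
    va50_minus_vi50: float


# ---------------------------------------------------------------------------
# peak extraction


def extract_peak_currents(
    rec: SweepSet,
    inward_window_s: float = 10e-3,
    blank_s: float = 0.3e-3,
    with_density: Optional[bool] = None,
) -> list[IVPoint]:
    """Peak inward / sustained outward current per activation step.

    ``with_density`` defaults to True when the recording has a known
    capacitance; requesting densities without one raises ParameterError.
    """
    if rec.mode != "voltage_clamp":
        raise ProtocolError(f"peak extraction needs voltage_clamp mode, got {rec.mode!r}")
    if with_density is None:
        with_density = rec.capacitance is not None
    if with_density and rec.capacitance is None:
        raise ParameterError("current density requested but capacitance is unknown")
    stepped = rec.stepped_sweeps()
    if not stepped:
        raise ProtocolError("no stepped sweeps present")

    points = []
    for tr, st in stepped:
        fs = tr.sampling_rate
        i = tr.values
        on = int(round(st.onset_time * fs))
        off = min(i.size, int(round(st.offset_time * fs)))
        w0 = on + max(1, int(round(blank_s * fs)))
        w1 = min(off, on + int(round(inward_window_s * fs)))
        if w1 <= w0:
            raise ProtocolError("step too short for the inward peak window")
        peak_in = min(0.0, float(np.min(i[w0:w1])))
        tail0 = off - max(1, (off - on) // 5)
        peak_out = max(0.0, float(np.mean(i[tail0:off])))
        points.append(
            IVPoint(
                vc=st.level,
                peak_inward=peak_in,
                peak_outward=peak_out,
                inward_density=peak_in / rec.capacitance if with_density else None,
                outward_density=peak_out / rec.capacitance if with_density else None,
            )
        )
    points.sort(key=lambda p: p.vc)
    return points


def extract_inactivation_peaks(
    rec: SweepSet,
    blank_s: float = 0.3e-3,
    inward_window_s: float = 10e-3,
) -> list[tuple[float, float]]:
    """(pre-pulse voltage, peak inward test current in pA) per sweep of an
    inactivation-protocol recording; the test-step window is read from the
    recording's metadata."""
    if rec.mode != "voltage_clamp":
        raise ProtocolError(f"expected voltage_clamp mode, got {rec.mode!r}")
    meta = rec.metadata
    if "test_onset_s" not in meta:
        raise ProtocolError("recording metadata lacks the inactivation test-step window")
    t_on = float(meta["test_onset_s"])
    out = []
    for tr, st in rec.stepped_sweeps():
        fs = tr.sampling_rate
        i = tr.values
        w0 = int(round(t_on * fs)) + max(1, int(round(blank_s * fs)))
        w1 = min(i.size, int(round(t_on * fs)) + int(round(inward_window_s * fs)))
        out.append((st.level, min(0.0, float(np.min(i[w0:w1])))))
    out.sort(key=lambda p: p[0])
    return out


# ---------------------------------------------------------------------------
# conductance transform


def conductance_transform(
    points: Sequence,
    e_rev: float = DEFAULT_E_REV_NA,
    branch: str = "inward",
    driving_potential: Optional[float] = None,
    restrict_below_e_rev: bool = True,
) -> list[tuple[float, float]]:
    """Convert peak currents to conductances, G = I/(V − Erev) in nS.

    ``points`` may be :class:`IVPoint` objects (the current of ``branch``
    is used) or plain ``(vc, current_pA)`` pairs.  The driving force is
    evaluated at the command potential, or at ``driving_potential`` when
    the current was measured at a fixed test step (inactivation protocol).
    Points whose driving force is exactly zero are excluded with a
    warning.  For the inward branch, steps at or beyond the reversal
    potential are excluded by default (the branch is ill-defined there).
    """
    if branch not in ("inward", "outward"):
        raise ParameterError(f"branch must be inward|outward, got {branch!r}")
    out = []
    for p in points:
        if isinstance(p, IVPoint):
            vc = p.vc
            i = p.peak_inward if branch == "inward" else p.peak_outward
        else:
            vc, i = p
        v_drive = vc if driving_potential is None else driving_potential
        df = v_drive - e_rev
        if df == 0:
            warnings.warn(
                f"command potential {vc:g} mV equals the reversal potential; point excluded"
            )
            continue
        if (
            branch == "inward"
            and restrict_below_e_rev
            and driving_potential is None
            and vc >= e_rev
        ):
            continue
        out.append((float(vc), float(i / df)))
    return out


# ---------------------------------------------------------------------------
# Boltzmann fitting


def _boltzmann_model(v: np.ndarray, gmax: float, v50: float, h: float, sign: float) -> np.ndarray:
    z = np.clip(sign * (v50 - v) / h, -500, 500)
    return gmax / (1.0 + np.exp(z))


def fit_boltzmann(
    gv: Sequence[tuple[float, float]],
    curve_type: str = "activation",
    max_iter: int = 500,
) -> BoltzmannFit:
    """Nonlinear least-squares Boltzmann fit of conductance–voltage data.

    Initial values: Gmax = max observed G, V50 = the voltage nearest
    G = Gmax/2, h = 7 mV.  Convergence when the relative parameter change
    falls below 1e-8, up to ``max_iter`` residual evaluations.
    """
    if curve_type not in ("activation", "inactivation"):
        raise ParameterError(f"curve_type must be activation|inactivation, got {curve_type!r}")
    v = np.asarray([p[0] for p in gv], dtype=float)
    g = np.asarray([p[1] for p in gv], dtype=float)
    if v.size < 5:
        raise FitError(f"need >= 5 conductance points, got {v.size}")
    gmax0 = float(np.max(g))
    if gmax0 <= 0 or np.ptp(g) == 0:
        raise FitError("degenerate conductance data (no dynamic range)")
    half = gmax0 / 2.0
    v50_0 = float(v[np.argmin(np.abs(g - half))])
    span = (np.min(g) <= 0.45 * gmax0) and (np.max(g) >= 0.55 * gmax0)
    if not span:
        warnings.warn("conductance data do not clearly bracket the half-maximum; fit may be weak")
    sign = 1.0 if curve_type == "activation" else -1.0
    x0 = np.array([gmax0, v50_0, 7.0])

    def residuals(p):
        return _boltzmann_model(v, p[0], p[1], p[2], sign) - g

    sol = least_squares(
        residuals,
        x0,
        bounds=([1e-12, -500.0, 1e-3], [np.inf, 500.0, 200.0]),
        xtol=1e-8,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=max_iter,
    )
    if not sol.success:
        raise FitError(f"Boltzmann fit did not converge: {sol.message}", last_params=sol.x)
    gmax, v50, h = (float(x) for x in sol.x)
    rss = float(np.sum(sol.fun**2))
    return BoltzmannFit(
        gmax=gmax, v50=v50, h=h, rss=rss, n_points=int(v.size), curve_type=curve_type
    )


# ---------------------------------------------------------------------------
# availability window


def availability_window(
    act: BoltzmannFit,
    inact: BoltzmannFit,
    grid_step: float = 0.5,
    v_min: float = -120.0,
    v_max: float = 80.0,
) -> AvailabilityWindow:
    """Product of the normalized activation and availability curves.

    The window maximum bounds the steady-state (window) current fraction;
    the crossing voltage (where the two curves are equal) is solved by
    bisection to 1e-6 mV.  Curves that never cross on the grid yield
    ``crossing_v = None`` with a warning.
    """
    if act.curve_type != "activation" or inact.curve_type != "inactivation":
        raise ParameterError("availability_window needs one activation and one inactivation fit")
    grid = np.arange(v_min, v_max + grid_step / 2.0, grid_step)
    a = act.fraction(grid)
    i = inact.fraction(grid)
    curve = a * i
    j = int(np.argmax(curve))
    diff = a - i
    crossing: Optional[float] = None
    sign_change = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    if sign_change.size:
        k = int(sign_change[0])
        f = lambda v: float(act.fraction(v) - inact.fraction(v))
        crossing = float(brentq(f, grid[k], grid[k + 1], xtol=1e-6))
    else:
        warnings.warn("activation and availability curves do not cross on the voltage grid")
    return AvailabilityWindow(
        voltage_grid=grid,
        window_curve=curve,
        window_max=float(curve[j]),
        v_at_max=float(grid[j]),
        crossing_v=crossing,
        va50_minus_vi50=float(act.v50 - inact.v50),
    )
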