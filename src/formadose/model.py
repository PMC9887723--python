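"""The nine-state mucosal dosimetry ODE system and its integration services.

State variables (all pmol/mm^3; 1 pmol/mm^3 = 1 uM):

=============  =============================================================
``endoF``      free formaldehyde of endogenous (1-carbon metabolism) origin
``exogF``      free formaldehyde of exogenous (inhaled) origin
``GSH``        free glutathione
``endoF_GSH``  S-hydroxymethylglutathione complex of endogenous origin
``exogF_GSH``  same complex, exogenous origin
``endoDG``     N2-hydroxymethyl-dG monoadducts, endogenous
``exogDG``     same monoadducts, exogenous
``endoDPX``    DNA-protein crosslinks, endogenous
``exogDPX``    DNA-protein crosslinks, exogenous
=============  =============================================================

Endogenous and exogenous formaldehyde obey identical kinetics except for the
source term: a zero-order intracellular production ``kp`` for the endogenous
pool versus the flux-derived volumetric uptake for the inhaled pool. Both
complexes compete for a single formaldehyde-dehydrogenase pool (shared
Michaelis-Menten denominator), and oxidation regenerates free GSH, so the
glutathione moiety ``GSH + endoF_GSH + exogF_GSH`` is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .exposure import ExposureSchedule, ppm_at
from .parameters import InvalidParameterError, KineticParameters, SiteFlux

SPECIES = (
    "endoF", "exogF", "GSH", "endoF_GSH", "exogF_GSH",
    "endoDG", "exogDG", "endoDPX", "exogDPX",
)
_IDX = {name: i for i, name in enumerate(SPECIES)}

#: exogenous state variables (zero whenever there is no exposure history)
EXOG_SPECIES = ("exogF", "exogF_GSH", "exogDG", "exogDPX")


class DomainError(ValueError):
    """A state vector violates the model's physical domain."""


class IntegrationError(RuntimeError):
    """The ODE solver failed or produced an unphysical trajectory."""


@dataclass(frozen=True)
class MucosalState:
    """One snapshot of the nine mucosal concentrations (pmol/mm^3)."""

    endoF: float
    exogF: float
    GSH: float
    endoF_GSH: float
    exogF_GSH: float
    endoDG: float
    exogDG: float
    endoDPX: float
    exogDPX: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "MucosalState":
        return cls(*(float(v) for v in y))

    @property
    def glutathione_total(self) -> float:
        return self.GSH + self.endoF_GSH + self.exogF_GSH


def initial_state_published(params: KineticParameters) -> MucosalState:
    """The strict "as-published initialization": the approximate tabulated
    initial concentrations, exogenous pools at zero."""
    return MucosalState(
        endoF=params.endoF_init,
        exogF=0.0,
        GSH=params.GSH_init,
        endoF_GSH=params.endoF_GSH_init,
        exogF_GSH=0.0,
        endoDG=params.endoDG_init,
        exogDG=0.0,
        endoDPX=params.endoDPX_init,
        exogDPX=0.0,
    )


def uptake_rate(site: SiteFlux, thick: float, ppm: float) -> float:
    """Volumetric uptake (pmol/mm^3/h) of inhaled formaldehyde at a site.

    Wall flux is the CFD-predicted value at 1 ppm scaled linearly with the
    inhaled concentration and distributed over the mucosal thickness:
    ``uptake = flux_per_ppm * ppm / thick``.
    """
    if thick <= 0:
        raise InvalidParameterError("mucosal thickness must be strictly positive")
    if ppm < 0:
        raise ValueError("ppm must be non-negative")
    return site.flux_per_ppm * ppm / thick


def _extracellular_clearance(exogF: float, p: KineticParameters) -> float:
    if p.ec_mode == "off":
        return 0.0
    if p.ec_mode == "zero_order":
        # clipped near zero so the clearance cannot drive exogF negative
        if exogF <= 0.0:
            return 0.0
        ramp = 1e-6  # pmol/mm^3; linear taper below this concentration
        return p.ec_rate if exogF >= ramp else p.ec_rate * exogF / ramp
    return p.ec_Vmax * exogF / (p.ec_Km + exogF)


def _rhs(y: Sequence[float], p: KineticParameters, uptake_now: float) -> list[float]:
    """Scalar-math right-hand side (hot path: called by the solvers)."""
    endoF, exogF, GSH, cen, cex, endoDG, exogDG, endoDPX, exogDPX = y
    assoc_en = p.k23 * endoF * GSH
    assoc_ex = p.k23 * exogF * GSH
    denom = p.Km + cen + cex  # shared-enzyme competition of the two complexes
    ox_en = p.Vmax * cen / denom
    ox_ex = p.Vmax * cex / denom
    k_dna = p.kDNA_DG + p.kDNA_DPX
    d_endoF = p.kp - p.k21 * endoF - assoc_en + p.k32 * cen - k_dna * endoF
    d_exogF = (
        uptake_now
        - _extracellular_clearance(exogF, p)
        - p.k21 * exogF
        - assoc_ex
        + p.k32 * cex
        - k_dna * exogF
    )
    d_cen = assoc_en - p.k32 * cen - ox_en
    d_cex = assoc_ex - p.k32 * cex - ox_ex
    d_GSH = -(assoc_en + assoc_ex) + p.k32 * (cen + cex) + ox_en + ox_ex
    return [
        d_endoF,
        d_exogF,
        d_GSH,
        d_cen,
        d_cex,
        p.kDNA_DG * endoF - p.krep_DG * endoDG,
        p.kDNA_DG * exogF - p.krep_DG * exogDG,
        p.kDNA_DPX * endoF - p.krep_DPX * endoDPX,
        p.kDNA_DPX * exogF - p.krep_DPX * exogDPX,
    ]


def derivatives(
    state: MucosalState, params: KineticParameters, uptake_now: float
) -> MucosalState:
    """Instantaneous rates of change (pmol/mm^3/h) at a given state.

    Raises :class:`DomainError` naming the offending field if any state
    component is negative.
    """
    for name in SPECIES:
        if getattr(state, name) < 0:
            raise DomainError(f"state field {name} is negative")
    if uptake_now < 0:
        raise DomainError("uptake must be non-negative")
    return MucosalState.from_array(_rhs(state.as_array(), params, uptake_now))


@dataclass(frozen=True)
class Trajectory:
    """States sampled at an ordered set of times, with run provenance."""

    times: np.ndarray  # (n,) hours, strictly increasing
    states: np.ndarray  # (n, 9) pmol/mm^3, columns in SPECIES order
    params_hash: str = ""
    schedule_label: str = ""
    site_label: str = ""

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("state count must equal time count")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def species(self, name: str) -> np.ndarray:
        return self.states[:, _IDX[name]]

    def state_at(self, t: float) -> MucosalState:
        i = int(np.searchsorted(self.times, t))
        if i >= len(self.times) or not np.isclose(self.times[i], t, rtol=0, atol=1e-9):
            raise KeyError(f"time {t} not among the sampled times")
        return MucosalState.from_array(self.states[i])

    def value_at(self, t: float, species: str) -> float:
        return getattr(self.state_at(t), species)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: time_h, species, value_pmol_mm3, site, schedule."""
        n = len(self.times)
        return pd.DataFrame(
            {
                "time_h": np.repeat(self.times, len(SPECIES)),
                "species": np.tile(SPECIES, n),
                "value_pmol_mm3": self.states.reshape(-1),
                "site": self.site_label,
                "schedule": self.schedule_label,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-12
_NEG_TOL = 1e-9  # pmol/mm^3; solver noise below this is clipped to zero


def integrate(
    params: KineticParameters,
    site: SiteFlux,
    schedule: ExposureSchedule,
    initial: MucosalState,
    output_times: Sequence[float],
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the model over an exposure schedule.

    The exposure square wave is piecewise constant, so integration restarts at
    every episode on/off edge and the stiff-capable LSODA solver runs on each
    constant-uptake segment with the requested output times interleaved.
    """
    out = np.asarray(sorted(output_times), dtype=float)
    if out.size == 0:
        raise ValueError("output_times must be non-empty")
    if out[0] < 0 or out[-1] > schedule.horizon_h:
        raise ValueError("output_times must lie within the schedule horizon")
    if np.any(np.diff(out) <= 0):
        raise ValueError("output_times must be strictly increasing")

    edges = sorted(set(schedule.breakpoints()) | {float(out[-1])})
    edges = [t for t in edges if t <= out[-1] + 1e-12]
    if edges[-1] < out[-1]:
        edges.append(float(out[-1]))

    y = initial.as_array().copy()
    results: dict[float, np.ndarray] = {}
    if out[0] == 0.0:
        results[0.0] = y.copy()

    for t0, t1 in zip(edges[:-1], edges[1:]):
        if t1 <= t0:
            continue
        ppm = ppm_at(schedule, 0.5 * (t0 + t1))
        uptake = uptake_rate(site, params.thick, ppm)
        seg_out = [t for t in out if t0 < t <= t1]
        t_eval = sorted(set(seg_out) | {t1})
        sol = solve_ivp(
            lambda t, yy: _rhs(yy, params, uptake),
            (t0, t1),
            y,
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed on [{t0}, {t1}] h at {ppm} ppm: {sol.message}"
            )
        if np.min(sol.y) < -_NEG_TOL:
            worst = SPECIES[int(np.argmin(np.min(sol.y, axis=1)))]
            raise IntegrationError(
                f"negative concentration in {worst} beyond tolerance on [{t0}, {t1}] h"
            )
        ys = np.clip(sol.y.T, 0.0, None)
        for t, row in zip(sol.t, ys):
            if t in seg_out:
                results[float(t)] = row.copy()
        y = ys[-1].copy()

    states = np.vstack([results[float(t)] for t in out])
    return Trajectory(
        times=out,
        states=states,
        params_hash=params.hash(),
        schedule_label=schedule.label,
        site_label=site.site_label,
    )


def integrate_rk4(
    params: KineticParameters,
    site: SiteFlux,
    schedule: ExposureSchedule,
    initial: MucosalState,
    output_times: Sequence[float],
    step_h: float = 1e-4,
) -> Trajectory:
    """Fixed-step classical 4th-order Runge-Kutta integration.

    A brute-force cross-check for the adaptive solver; episode edges are
    honoured by stepping each constant-uptake segment separately. Slow —
    intended for validation runs only.
    """
    out = np.asarray(sorted(output_times), dtype=float)
    edges = sorted(set(schedule.breakpoints()) | set(out.tolist()))
    edges = [t for t in edges if t <= out[-1] + 1e-12]
    y = initial.as_array().astype(float)
    results: dict[float, np.ndarray] = {}
    if out[0] == 0.0:
        results[0.0] = y.copy()
    out_set = set(out.tolist())
    for t0, t1 in zip(edges[:-1], edges[1:]):
        if t1 <= t0:
            continue
        uptake = uptake_rate(site, params.thick, ppm_at(schedule, 0.5 * (t0 + t1)))
        n_steps = max(1, int(round((t1 - t0) / step_h)))
        h = (t1 - t0) / n_steps
        yl = list(y)
        for _ in range(n_steps):
            k1 = _rhs(yl, params, uptake)
            k2 = _rhs([a + 0.5 * h * b for a, b in zip(yl, k1)], params, uptake)
            k3 = _rhs([a + 0.5 * h * b for a, b in zip(yl, k2)], params, uptake)
            k4 = _rhs([a + h * b for a, b in zip(yl, k3)], params, uptake)
            yl = [
                a + h / 6.0 * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
                for a, b1, b2, b3, b4 in zip(yl, k1, k2, k3, k4)
            ]
        y = np.array(yl)
        if t1 in out_set:
            results[float(t1)] = y.copy()
    states = np.vstack([results[float(t)] for t in out])
    return Trajectory(
        times=out,
        states=states,
        params_hash=params.hash(),
        schedule_label=schedule.label + "_rk4",
        site_label=site.site_label,
    )


def endogenous_steady_state(
    params: KineticParameters, tol: float = 1e-10
) -> MucosalState:
    """The zero-exposure fixed point of the model.

    With no exposure the exogenous pools vanish and the glutathione moiety is
    conserved at its initial total ``G_tot = GSH_init + endoF_GSH_init``, so the
    fixed point reduces to one equation in free formaldehyde F: summing the F
    and complex balances gives ``Vmax*C/(Km+C) = kp - (k21+kDNA_DG+kDNA_DPX)*F``
    (oxidation carries whatever production first-order loss does not), which
    fixes the complex C, and the complex balance
    ``k23*F*(G_tot-C) = k32*C + Vmax*C/(Km+C)`` then closes the root problem.
    Solved by bracketing bisection (brentq); the result is independent of the
    starting adduct concentrations, whose fixed points follow algebraically.
    """
    p = params
    g_tot = p.total_glutathione
    k_loss = p.k21 + p.kDNA_DG + p.kDNA_DPX

    def complex_for(F: float) -> float:
        r = p.kp - k_loss * F  # oxidation flux required at steady state
        if r <= 0:
            return 0.0
        if r >= p.Vmax:
            return float("inf")
        return p.Km * r / (p.Vmax - r)

    def residual(F: float) -> float:
        C = complex_for(F)
        if not np.isfinite(C) or C >= g_tot:
            # demanded oxidation exceeds what the glutathione pool can carry
            return -1e30
        return p.k23 * F * (g_tot - C) - p.k32 * C - (p.kp - k_loss * F)

    f_hi = p.kp / k_loss  # F if nothing were oxidized — residual > 0 there
    f_lo = f_hi * 1e-12
    if residual(f_lo) >= 0 or residual(f_hi) <= 0:
        return _steady_state_by_burn_in(params, tol)
    F = brentq(residual, f_lo, f_hi, xtol=1e-14, rtol=8.9e-16)
    C = complex_for(F)
    state = MucosalState(
        endoF=F,
        exogF=0.0,
        GSH=g_tot - C,
        endoF_GSH=C,
        exogF_GSH=0.0,
        endoDG=p.kDNA_DG * F / p.krep_DG,
        exogDG=0.0,
        endoDPX=p.kDNA_DPX * F / p.krep_DPX,
        exogDPX=0.0,
    )
    rates = derivatives(state, params, 0.0).as_array()
    if np.max(np.abs(rates)) > 1e-6 * p.kp:
        raise IntegrationError("steady-state residual rates exceed tolerance")
    return state


def _steady_state_by_burn_in(
    params: KineticParameters, tol: float, burn_in_h: float = 4000.0
) -> MucosalState:
    """Fallback: relax the zero-exposure model from the published initial values."""
    from .exposure import ExposureSchedule as _ES  # zero-exposure schedule

    schedule = _ES("burn_in", (), burn_in_h, (burn_in_h,))
    from .parameters import DG_SITE

    traj = integrate(
        params, DG_SITE, schedule, initial_state_published(params), [burn_in_h]
    )
    state = MucosalState.from_array(traj.states[-1])
    rates = derivatives(state, params, 0.0).as_array()
    if np.max(np.abs(rates)) > 1e-6 * params.kp:
        raise IntegrationError("burn-in did not reach the endogenous fixed point")
    return state


def simulate_protocol(
    params: KineticParameters,
    site: SiteFlux,
    schedule: ExposureSchedule,
    output_times: Sequence[float] | None = None,
    burn_in: bool = True,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Convenience wrapper: start from the endogenous steady state (or the
    as-published initial values if ``burn_in=False``) and integrate the
    schedule, returning states at ``output_times`` (default: the schedule's
    sampling times)."""
    initial = (
        endogenous_steady_state(params) if burn_in else initial_state_published(params)
    )
    times = tuple(output_times) if output_times is not None else schedule.sampling_times
    return integrate(params, site, schedule, initial, times, rtol=rtol, atol=atol)
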