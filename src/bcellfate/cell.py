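"""Single virtual B-cell: coupled receptor -> NF-kB -> fate dynamics.

The signaling subsystem (receptor layer + NF-kB module + apoptosis branch,
33 states) is integrated as one ODE system per cell.  The cell-cycle branch
is driven by the stored NF-kB readouts and does not feed back into
signaling, so it is integrated separately along the lineage: daughters
inherit the mother's sampled parameters and signaling/apoptosis state
unchanged and only the cell-cycle phase variables (CycB, Cdh1, mass) are
reset at division.  A lineage therefore shares one signaling trajectory and
one (shared) death time, and the division chain is computed once with the
generation count tracking multiplicity 2^g.

Simulation runs in two phases: a ligand-free pre-equilibration (capped at
800 h) to the cell's resting state, then the stimulated time course with
ligand doses applied at protocol onsets.  The basal culture-stress caspase
processing is active only in the second phase (culture onset).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import receptor as rc
from . import nfkb as nf
from . import fate as ft
from .stimulus import StimulationProtocol

__all__ = ["CellParams", "SignalingTrajectory", "LineageResult",
           "simulate_cell_signaling", "simulate_lineage", "find_cell_rest"]

N_SIG = rc.N_SPECIES + nf.N_NFKB + ft.N_APOP  # 33
_R0, _R1 = 0, rc.N_SPECIES
_N0, _N1 = _R1, _R1 + nf.N_NFKB
_A0, _A1 = _N1, _N1 + ft.N_APOP

_I_ABCR = rc.SPECIES.index("ABCR")
_I_IKK2 = rc.SPECIES.index("IKK2")
_I_IKK3 = rc.SPECIES.index("IKK3")
_I_NIK = rc.SPECIES.index("NIK")
_I_AN = _N0 + nf.NFKB_SPECIES.index("RelA_p50_nuc")
_I_CN = _N0 + nf.NFKB_SPECIES.index("cRel_p50_nuc")
_I_ZN = _N0 + nf.NFKB_SPECIES.index("cRel_p52_nuc")
_I_BAX = _A0 + ft.APOP_SPECIES.index("BaxA")
_I_CPARP = _A0 + ft.APOP_SPECIES.index("cParp")
_I_BCLXL = _A0 + ft.APOP_SPECIES.index("BclxL")
_I_C8 = _A0 + ft.APOP_SPECIES.index("C8")


@dataclass
class CellParams:
    """Full parameter set of one virtual cell."""

    receptor: rc.ReceptorParams = field(default_factory=rc.ReceptorParams)
    nfkb: nf.NfkbParams = field(default_factory=nf.NfkbParams)
    apoptosis: ft.ApoptosisParams = field(default_factory=ft.ApoptosisParams)
    cellcycle: ft.CellCycleParams = field(default_factory=ft.CellCycleParams)

    def copy(self) -> "CellParams":
        return CellParams(self.receptor.copy(), self.nfkb.copy(),
                          self.apoptosis.copy(), self.cellcycle.copy())


def _signaling_rhs(t: float, y: np.ndarray, params: CellParams,
                   rest_nuc: tuple[float, float],
                   momp: bool, culture: bool, aicd: bool) -> np.ndarray:
    """Combined 33-state right-hand side."""
    yr = y[_R0:_R1]
    yn = y[_N0:_N1]
    ya = y[_A0:_A1]
    k2 = max(yr[_I_IKK2] + yr[_I_IKK3], 0.0) / params.nfkb.ikk_ref
    nik = max(yr[_I_NIK], 0.0) / params.nfkb.nik_ref

    an0, cn0, zn0 = rest_nuc
    rela_fold = max(yn[1], 0.0) / an0
    crel_fold = (max(yn[3], 0.0) + max(yn[5], 0.0)) / cn0
    p52_fold = max(yn[5], 0.0) / zn0
    ap = params.apoptosis
    # weights are normalized so the resting drive is exactly 1; the weights
    # set the dimer mix only, the induction scale lives in bclxl_nfkb
    wsum = ap.w_rela + ap.w_crel + ap.w_p52
    bclxl_drive = (ap.w_rela * rela_fold + ap.w_crel * crel_fold
                   + ap.w_p52 * p52_fold) / wsum

    out = np.empty(N_SIG)
    out[_R0:_R1] = rc.receptor_rhs(yr, params.receptor)
    out[_N0:_N1] = nf.nfkb_rhs(yn, k2, nik, params.nfkb)
    out[_A0:_A1] = ft.apoptosis_rhs(ya, max(yr[_I_ABCR], 0.0), bclxl_drive,
                                    ap, momp, aicd_enabled=aicd, culture=culture)
    return out


def _rest_rhs(t: float, y: np.ndarray, params: CellParams) -> np.ndarray:
    # during pre-equilibration the fold drives are pinned to 1 (self-consistent
    # resting definition) and culture stress is off
    yr = y[_R0:_R1]
    yn = y[_N0:_N1]
    ya = y[_A0:_A1]
    k2 = max(yr[_I_IKK2] + yr[_I_IKK3], 0.0) / params.nfkb.ikk_ref
    nik = max(yr[_I_NIK], 0.0) / params.nfkb.nik_ref
    ap = params.apoptosis
    out = np.empty(N_SIG)
    out[_R0:_R1] = rc.receptor_rhs(yr, params.receptor)
    out[_N0:_N1] = nf.nfkb_rhs(yn, k2, nik, params.nfkb)
    out[_A0:_A1] = ft.apoptosis_rhs(ya, 0.0, 1.0, ap, momp=False,
                                    aicd_enabled=False, culture=False)
    return out


def find_cell_rest(params: CellParams,
                   initial: np.ndarray | None = None,
                   max_time: float = 800.0,
                   deriv_tol: float = 1e-7,
                   atol: float = 1e-5, rtol: float = 1e-3) -> tuple[np.ndarray, bool]:
    """Ligand-free resting state of the full signaling subsystem."""
    if initial is None:
        y = np.zeros(N_SIG)
        y[_R0:_R1] = rc.default_initial_array(params.receptor)
        y[_N0:_N1] = nf.resting_state(params.nfkb)
        ap = params.apoptosis
        y[_A0 + 0] = ap.pc8_syn / max(ap.pc8_deg, 1e-12)
        y[_A0 + 2] = ap.bclxl_syn0 / max(ap.bclxl_deg, 1e-12)
    else:
        y = initial.copy()
    t_now, converged = 0.0, False
    while t_now < max_time:
        t_next = min(t_now + 50.0, max_time)
        sol = solve_ivp(_rest_rhs, (t_now, t_next), y, args=(params,),
                        method="LSODA", atol=atol, rtol=rtol)
        if not sol.success:  # fall back to BDF on the rare LSODA stall
            sol = solve_ivp(_rest_rhs, (t_now, t_next), y, args=(params,),
                            method="BDF", atol=atol, rtol=rtol)
        if not sol.success:
            raise RuntimeError(f"pre-equilibration failed: {sol.message}")
        y = sol.y[:, -1]
        t_now = t_next
        dy = _rest_rhs(t_now, y, params)
        if np.max(np.abs(dy) / (np.abs(y) + 1.0)) < deriv_tol:
            converged = True
            break
    return np.maximum(y, 0.0), converged


@dataclass
class SignalingTrajectory:
    """Dense signaling solution of one cell over the stimulated phase."""

    times: np.ndarray
    values: np.ndarray           # (n_times, N_SIG)
    rest: np.ndarray             # resting state used at t=0 (pre-ligand)
    momp_time: float | None
    death_time: float | None

    @property
    def rela_fold(self) -> np.ndarray:
        return self.values[:, _I_AN] / self.rest[_I_AN]

    @property
    def crel_fold(self) -> np.ndarray:
        base = self.rest[_I_CN] + self.rest[_I_ZN]
        return (self.values[:, _I_CN] + self.values[:, _I_ZN]) / base

    @property
    def bclxl(self) -> np.ndarray:
        return self.values[:, _I_BCLXL]

    @property
    def caspase8(self) -> np.ndarray:
        return self.values[:, _I_C8]

    @property
    def cparp(self) -> np.ndarray:
        return self.values[:, _I_CPARP]

    def species(self, name: str) -> np.ndarray:
        if name in rc.SPECIES:
            return self.values[:, _R0 + rc.SPECIES.index(name)]
        if name in nf.NFKB_SPECIES:
            return self.values[:, _N0 + nf.NFKB_SPECIES.index(name)]
        if name in ft.APOP_SPECIES:
            return self.values[:, _A0 + ft.APOP_SPECIES.index(name)]
        raise KeyError(name)

    def nfkb_drive(self) -> np.ndarray:
        """Mean nuclear fold-change above baseline, the cell-cycle drive."""
        return np.maximum(0.5 * (self.rela_fold + self.crel_fold) - 1.0, 0.0)


def simulate_cell_signaling(params: CellParams,
                            protocol: StimulationProtocol,
                            horizon: float = 96.0,
                            rest: np.ndarray | None = None,
                            dt_out: float = 0.25,
                            atol: float = 1e-5, rtol: float = 1e-3) -> SignalingTrajectory:
    """Integrate the signaling subsystem of one cell under a protocol.

    Integration is split at ligand events and (once) at MOMP so that the
    latched MOMP flag and post-MOMP cParp accumulation are exact.
    """
    protocol.validate()
    if rest is None:
        rest, _ = find_cell_rest(params)
    aicd = protocol.toggles.aicd
    apop_on = protocol.toggles.apoptosis

    an0 = max(rest[_I_AN], 1e-12)
    cn0 = max(rest[_I_CN] + rest[_I_ZN], 1e-12)
    zn0 = max(rest[_I_ZN], 1e-12)
    rest_nuc = (an0, cn0, zn0)
    ap = params.apoptosis

    events = protocol.ligand_events(horizon)
    breakpoints = sorted({0.0, horizon} | {t for t, _ in events})
    actions_at = dict(events)

    t_grid = np.arange(0.0, horizon + dt_out / 2, dt_out)
    out_t: list[np.ndarray] = [np.array([0.0])]
    out_y: list[np.ndarray] = []
    y = rest.copy()
    for t0b, acts in sorted(actions_at.items()):
        if t0b == 0.0:
            for species, mode, value in acts:
                i = rc.SPECIES.index(species)
                y[i] = y[i] + value if mode == "add" else 0.0
    out_y.append(y[None, :].copy())

    momp = bool(y[_I_BAX] >= ap.momp_threshold) and apop_on
    momp_time: float | None = 0.0 if momp else None

    def momp_event(t, yy, *args):
        return yy[_I_BAX] - ap.momp_threshold

    momp_event.terminal = True
    momp_event.direction = 1.0

    seg_bounds = [b for b in breakpoints if 0.0 <= b <= horizon]
    for t0, t1 in zip(seg_bounds[:-1], seg_bounds[1:]):
        t_start = t0
        while t_start < t1 - 1e-12:
            te = t_grid[(t_grid > t_start + 1e-12) & (t_grid <= t1 + 1e-12)]
            ev = [momp_event] if (apop_on and not momp) else []
            sol = solve_ivp(_signaling_rhs, (t_start, t1), y,
                            args=(params, rest_nuc, momp, True, aicd),
                            method="LSODA", t_eval=te if len(te) else None,
                            events=ev, atol=atol, rtol=rtol)
            if not sol.success:
                raise RuntimeError(f"signaling integration failed at "
                                   f"t={sol.t[-1] if len(sol.t) else t_start:g} h: {sol.message}")
            n_out = len(sol.t)
            if n_out:
                out_t.append(np.asarray(sol.t, dtype=float))
                out_y.append(np.asarray(sol.y).T)
            if ev and sol.t_events[0].size:
                momp = True
                momp_time = float(sol.t_events[0][0])
                y = sol.y_events[0][0].copy()
                t_start = momp_time
            else:
                y = np.asarray(sol.y)[:, -1].copy() if n_out else y
                # make sure we land exactly on t1
                if not n_out or sol.t[-1] < t1 - 1e-12:
                    solf = solve_ivp(_signaling_rhs,
                                     (t_start if not n_out else float(sol.t[-1]), t1),
                                     y, args=(params, rest_nuc, momp, True, aicd),
                                     method="LSODA", atol=atol, rtol=rtol)
                    y = solf.y[:, -1].copy()
                t_start = t1
        # apply ligand actions scheduled at t1
        for species, mode, value in actions_at.get(t1, []):
            if t1 == 0.0:
                continue
            i = rc.SPECIES.index(species)
            y[i] = y[i] + value if mode == "add" else 0.0

    times = np.concatenate(out_t)
    values = np.vstack(out_y)
    times, idx = np.unique(times, return_index=True)
    values = values[idx]

    death = None
    if apop_on:
        death = ft.death_event(times, values[:, _I_CPARP],
                               ap.cparp_death_threshold)
    return SignalingTrajectory(times=times, values=values, rest=rest,
                               momp_time=momp_time, death_time=death)


@dataclass
class LineageResult:
    """Division chain of one founder lineage (daughters are identical)."""

    division_times: list[float]
    death_time: float | None
    horizon: float
    max_generation_reached: bool = False

    def generation_at(self, t: float) -> int | None:
        """Generation of the lineage's live cells at time t (None if dead)."""
        if self.death_time is not None and t >= self.death_time:
            return None
        return int(np.searchsorted(np.asarray(self.division_times), t, side="right"))

    def live_multiplicity(self, t: float) -> int:
        g = self.generation_at(t)
        return 0 if g is None else 2 ** g


def simulate_lineage(traj: SignalingTrajectory,
                     cc_params: ft.CellCycleParams,
                     horizon: float = 96.0,
                     enabled: bool = True,
                     max_divisions: int = 9,
                     atol: float = 1e-8, rtol: float = 1e-6) -> LineageResult:
    """Integrate the cell-cycle branch along a founder lineage.

    Driven by the lineage's stored NF-kB fold-change trajectory.  Division
    resets cyclin B and Cdh1 (and halves mass); commitment and Rb carry over,
    so post-first-division cycles run at the oscillator period.
    """
    death = traj.death_time
    t_stop = min(horizon, death) if death is not None else horizon
    if not enabled or t_stop <= 0:
        return LineageResult([], death, horizon)

    drive_t = traj.times
    drive_v = traj.nfkb_drive()
    p = cc_params
    thr = p.cdh1_division_threshold

    def rhs(t, y):
        d = float(np.interp(t, drive_t, drive_v))
        return ft.cellcycle_rhs(y, d, p)

    def div_event(t, y):
        return y[3] - thr

    div_event.terminal = True
    div_event.direction = -1.0

    y = ft.initial_cellcycle_array(p)
    t_now = 0.0
    divisions: list[float] = []
    capped = False
    while t_now < t_stop - 1e-9:
        sol = solve_ivp(rhs, (t_now, t_stop), y, method="LSODA",
                        events=[div_event], atol=atol, rtol=rtol)
        if not sol.success:
            raise RuntimeError(f"cell-cycle integration failed: {sol.message}")
        if sol.t_events[0].size:
            t_div = float(sol.t_events[0][0])
            y = sol.y_events[0][0].copy()
            y[2] = p.cycb_reset   # cyclin B degraded at mitotic exit
            y[3] = 1.0            # Cdh1 reactivated
            if y[4] >= p.division_mass_min:
                # executed division: daughters inherit half the mass
                divisions.append(t_div)
                y[4] = max(y[4] / 2.0, 1e-6)
            # else: abortive mitotic entry -- insufficient growth, the cell
            # resets the oscillator and keeps growing (division destiny)
            t_now = t_div
            if len(divisions) >= max_divisions:
                capped = True
                break
        else:
            break
    return LineageResult(divisions, death, horizon, capped)
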