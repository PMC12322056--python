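"""BCR and CD40 receptor-proximal signaling layer.

A 37-reaction mass-action ODE model of the receptor module that converts
extracellular ligand concentrations (ANTIGEN engaging the BCR, CD40L engaging
CD40) into the kinase activities that drive downstream NF-kB signaling:

* canonical arm -- CBM-complex (BCR) and TRAF6 (CD40) activation of TAK1,
  which drives the IKK activation cycle (IKK_off -> IKK2 -> IKK3 -> IIKK);
* non-canonical arm -- CD40-engagement-dependent depletion of TRAF3, which
  constitutively targets NIK for degradation through a Hill-type term.

Species are concentrations in nM; time is in hours.  Ligand <-> receptor
binding couples the extracellular medium to the cell surface; bimolecular
terms facing the medium carry the medium-to-cell volume scaling factor
``c_c2m`` (default 0.01).

Four species pools are closed under the model reactions and serve as
conservation laws (checked in the test-suite): the CBM cycle
(CBM + ACBM + ICBM), the TAK1 cycle (TAK1 + ATAK1), the TRAF6 switch
(TRAF6_off + TRAF6) and the IKK cycle (IKK_off + IKK2 + IKK3 + IIKK).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .stimulus import StimulationProtocol

__all__ = [
    "SPECIES",
    "ReceptorParams",
    "ReceptorState",
    "ReceptorTrajectory",
    "InvalidStateError",
    "ConfigurationError",
    "receptor_derivatives",
    "receptor_rhs",
    "simulate_receptor",
    "find_steady_state",
    "default_initial_array",
    "conservation_totals",
    "REACTIONS",
    "PHI_CATEGORY",
]

#: Species order used by every array-facing function in this module.
SPECIES: tuple[str, ...] = (
    "ANTIGEN", "BCR", "ABCR",
    "CBM", "ACBM", "ICBM",
    "CD40L", "CD40R", "CD40LR",
    "TRAF6_off", "TRAF6",
    "TRAF3",
    "TAK1", "ATAK1",
    "IKK_off", "IKK2", "IKK3", "IIKK",
    "NIK",
)

_IDX = {name: i for i, name in enumerate(SPECIES)}

N_SPECIES = len(SPECIES)

#: Default rate constants, indexed 1..37 (index 0 unused).
#: Units: zeroth-order nM/h, first-order 1/h, second-order 1/(nM h).
PHI_DEFAULTS: tuple[float, ...] = (
    float("nan"),
    0.05,     # 1  ANTIGEN ->            (free-antibody decay)
    4.93,     # 2  -> BCR
    1.43,     # 3  BCR ->
    66.0,     # 4  ANTIGEN + BCR -> ABCR
    1.26,     # 5  ABCR -> ANTIGEN + BCR
    0.35,     # 6  ABCR ->
    6.6,      # 7  CBM + ABCR -> ACBM + ABCR
    0.126,    # 8  ACBM -> CBM
    0.181,    # 9  ACBM + IKK -> ICBM + IKK
    0.068,    # 10 ICBM -> CBM
    0.05,     # 11 CD40L ->
    7.672,    # 12 -> CD40R
    0.05,     # 13 CD40R ->
    0.04,     # 14 CD40L + CD40R -> CD40LR
    11.3,     # 15 CD40LR -> CD40L + CD40R
    0.17,     # 16 CD40LR ->
    0.1,      # 17 CD40LR + TRAF6_off -> CD40LR + TRAF6
    7.5,      # 18 TRAF6 -> TRAF6_off
    10.0,     # 19 -> TRAF3
    0.5,      # 20 TRAF3 ->
    10.0,     # 21 CD40LR + TRAF3 -> CD40LR
    1050.0,   # 22 ACBM + TAK1 -> ACBM + ATAK1
    60.0,     # 23 TRAF6 + TAK1 -> TRAF6 + ATAK1
    401.14,   # 24 IKK2 + TAK1 -> IKK2 + ATAK1
    1182.86,  # 25 IKK3 + TAK1 -> IKK3 + ATAK1
    249.0,    # 26 TAK1 -> ATAK1
    258600.0, # 27 ATAK1 -> TAK1
    80.72,    # 28 ATAK1 + IKK_off -> ATAK1 + IKK2
    2175.6,   # 29 IKK2 -> IKK_off
    0.009,    # 30 IKK2 -> IKK3
    2094.0,   # 31 IKK3 + IKK2 -> IKK3 + IKK3
    53844.0,  # 32 IKK3 -> IKK2
    2528.4,   # 33 IKK3 -> IIKK
    957.6,    # 34 IIKK -> IKK_off
    12.0,     # 35 -> NIK
    0.231,    # 36 NIK ->
    2.0,      # 37 TRAF3 + NIK -> TRAF3   (Hill-gated NIK degradation)
)

#: Kinetic category of each rate constant; "synthesis", "degradation",
#: "association" and "dissociation" rates are distributed across virtual
#: cells, catalytic/conversion rates are not.
PHI_CATEGORY: dict[int, str] = {
    1: "degradation", 2: "synthesis", 3: "degradation",
    4: "association", 5: "dissociation", 6: "degradation",
    7: "catalysis", 8: "conversion", 9: "catalysis", 10: "conversion",
    11: "degradation", 12: "synthesis", 13: "degradation",
    14: "association", 15: "dissociation", 16: "degradation",
    17: "catalysis", 18: "conversion",
    19: "synthesis", 20: "degradation", 21: "catalysis",
    22: "catalysis", 23: "catalysis", 24: "catalysis", 25: "catalysis",
    26: "conversion", 27: "conversion",
    28: "catalysis", 29: "conversion", 30: "conversion", 31: "catalysis",
    32: "conversion", 33: "conversion", 34: "conversion",
    35: "synthesis", 36: "degradation", 37: "catalysis",
}

#: Machine-readable reaction registry mirroring the kinetic scheme.
#: Each entry: (index, reaction string, flux species, stoichiometry).
#: ``flux`` lists the species whose product with the rate constant gives the
#: reaction flux (catalysts appear in ``flux`` but not in ``stoich``).
#: ``stoich`` values may carry the medium-scaling factor symbolically via the
#: string "c_c2m" (resolved at evaluation time).
REACTIONS: tuple[dict, ...] = (
    {"i": 1, "eq": "ANTIGEN ->", "flux": ("ANTIGEN",), "stoich": {"ANTIGEN": -1}},
    {"i": 2, "eq": "-> BCR", "flux": (), "stoich": {"BCR": +1}},
    {"i": 3, "eq": "BCR ->", "flux": ("BCR",), "stoich": {"BCR": -1}},
    {"i": 4, "eq": "ANTIGEN + BCR -> ABCR", "flux": ("ANTIGEN", "BCR"),
     "stoich": {"ANTIGEN": "-c_c2m", "BCR": -1, "ABCR": +1}},
    {"i": 5, "eq": "ABCR -> ANTIGEN + BCR", "flux": ("ABCR",),
     "stoich": {"ABCR": -1, "ANTIGEN": "+c_c2m", "BCR": +1}},
    {"i": 6, "eq": "ABCR ->", "flux": ("ABCR",), "stoich": {"ABCR": -1}},
    {"i": 7, "eq": "CBM + ABCR -> ACBM + ABCR", "flux": ("CBM", "ABCR"),
     "stoich": {"CBM": -1, "ACBM": +1}},
    {"i": 8, "eq": "ACBM -> CBM", "flux": ("ACBM",), "stoich": {"ACBM": -1, "CBM": +1}},
    {"i": 9, "eq": "ACBM + IKK -> ICBM + IKK", "flux": ("ACBM", "IKK2"),
     "stoich": {"ACBM": -1, "ICBM": +1}},
    {"i": 10, "eq": "ICBM -> CBM", "flux": ("ICBM",), "stoich": {"ICBM": -1, "CBM": +1}},
    {"i": 11, "eq": "CD40L ->", "flux": ("CD40L",), "stoich": {"CD40L": -1}},
    {"i": 12, "eq": "-> CD40R", "flux": (), "stoich": {"CD40R": +1}},
    {"i": 13, "eq": "CD40R ->", "flux": ("CD40R",), "stoich": {"CD40R": -1}},
    {"i": 14, "eq": "CD40L + CD40R -> CD40LR", "flux": ("CD40L", "CD40R"),
     "stoich": {"CD40L": "-c_c2m", "CD40R": -1, "CD40LR": +1}},
    {"i": 15, "eq": "CD40LR -> CD40L + CD40R", "flux": ("CD40LR",),
     "stoich": {"CD40LR": -1, "CD40L": "+c_c2m", "CD40R": +1}},
    {"i": 16, "eq": "CD40LR ->", "flux": ("CD40LR",), "stoich": {"CD40LR": -1}},
    {"i": 17, "eq": "CD40LR + TRAF6_off -> CD40LR + TRAF6",
     "flux": ("CD40LR", "TRAF6_off"), "stoich": {"TRAF6_off": -1, "TRAF6": +1}},
    {"i": 18, "eq": "TRAF6 -> TRAF6_off", "flux": ("TRAF6",),
     "stoich": {"TRAF6": -1, "TRAF6_off": +1}},
    {"i": 19, "eq": "-> TRAF3", "flux": (), "stoich": {"TRAF3": +1}},
    {"i": 20, "eq": "TRAF3 ->", "flux": ("TRAF3",), "stoich": {"TRAF3": -1}},
    {"i": 21, "eq": "CD40LR + TRAF3 -> CD40LR", "flux": ("CD40LR", "TRAF3"),
     "stoich": {"TRAF3": -1}},
    {"i": 22, "eq": "ACBM + TAK1 -> ACBM + ATAK1", "flux": ("ACBM", "TAK1"),
     "stoich": {"TAK1": -1, "ATAK1": +1}},
    {"i": 23, "eq": "TRAF6 + TAK1 -> TRAF6 + ATAK1", "flux": ("TRAF6", "TAK1"),
     "stoich": {"TAK1": -1, "ATAK1": +1}},
    {"i": 24, "eq": "IKK2 + TAK1 -> IKK2 + ATAK1", "flux": ("IKK2", "TAK1"),
     "stoich": {"TAK1": -1, "ATAK1": +1}},
    {"i": 25, "eq": "IKK3 + TAK1 -> IKK3 + ATAK1", "flux": ("IKK3", "TAK1"),
     "stoich": {"TAK1": -1, "ATAK1": +1}},
    {"i": 26, "eq": "TAK1 -> ATAK1", "flux": ("TAK1",),
     "stoich": {"TAK1": -1, "ATAK1": +1}},
    {"i": 27, "eq": "ATAK1 -> TAK1", "flux": ("ATAK1",),
     "stoich": {"ATAK1": -1, "TAK1": +1}},
    {"i": 28, "eq": "ATAK1 + IKK_off -> ATAK1 + IKK2", "flux": ("ATAK1", "IKK_off"),
     "stoich": {"IKK_off": -1, "IKK2": +1}},
    {"i": 29, "eq": "IKK2 -> IKK_off", "flux": ("IKK2",),
     "stoich": {"IKK2": -1, "IKK_off": +1}},
    {"i": 30, "eq": "IKK2 -> IKK3", "flux": ("IKK2",),
     "stoich": {"IKK2": -1, "IKK3": +1}},
    {"i": 31, "eq": "IKK3 + IKK2 -> IKK3 + IKK3", "flux": ("IKK3", "IKK2"),
     "stoich": {"IKK2": -1, "IKK3": +1}},
    {"i": 32, "eq": "IKK3 -> IKK2", "flux": ("IKK3",),
     "stoich": {"IKK3": -1, "IKK2": +1}},
    {"i": 33, "eq": "IKK3 -> IIKK", "flux": ("IKK3",),
     "stoich": {"IKK3": -1, "IIKK": +1}},
    {"i": 34, "eq": "IIKK -> IKK_off", "flux": ("IIKK",),
     "stoich": {"IIKK": -1, "IKK_off": +1}},
    {"i": 35, "eq": "-> NIK", "flux": (), "stoich": {"NIK": +1}},
    {"i": 36, "eq": "NIK ->", "flux": ("NIK",), "stoich": {"NIK": -1}},
    # 37 is Hill-gated and handled specially: flux = phi37 * NIK * hill(TRAF3)
    {"i": 37, "eq": "TRAF3 + NIK -> TRAF3", "flux": ("NIK", "hill:TRAF3"),
     "stoich": {"NIK": -1}},
)


class InvalidStateError(ValueError):
    """A species concentration is negative beyond numerical tolerance."""


class ConfigurationError(ValueError):
    """Unknown species or malformed parameter configuration."""


@dataclass
class ReceptorParams:
    """Rate constants and structural parameters of the receptor layer.

    ``phi`` holds rate constants indexed 1..37 (entry 0 is unused NaN).
    ``c_c2m`` is the dimensionless medium-to-cell volume scaling applied to
    ligand-facing bimolecular terms.  ``k_traf3_half``/``n_traf3_hill``
    parameterize the Hill gate of TRAF3-mediated NIK degradation.  The pool
    totals set the initial sizes of the conserved cycles; they are free
    configuration because absolute pool concentrations are not identifiable
    from the calibration data.
    """

    phi: np.ndarray = field(default_factory=lambda: np.array(PHI_DEFAULTS))
    c_c2m: float = 0.01
    k_traf3_half: float = 0.5
    n_traf3_hill: float = 2.0
    cbm_total: float = 1.0
    tak1_total: float = 1.0
    traf6_total: float = 100.0
    ikk_total: float = 1.0

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != (38,):
            raise ConfigurationError("phi must have 38 entries (index 0 unused)")
        if np.any(self.phi[1:] < 0):
            raise ConfigurationError("rate constants must be non-negative")

    def copy(self) -> "ReceptorParams":
        return dataclasses.replace(self, phi=self.phi.copy())


@dataclass
class ReceptorState:
    """Concentrations (nM) of the 19 receptor-layer species."""

    values: np.ndarray

    @classmethod
    def from_dict(cls, conc: dict[str, float]) -> "ReceptorState":
        y = np.zeros(N_SPECIES)
        for name, v in conc.items():
            if name not in _IDX:
                raise ConfigurationError(f"unknown species {name!r}")
            y[_IDX[name]] = v
        return cls(y)

    def __getitem__(self, name: str) -> float:
        if name not in _IDX:
            raise ConfigurationError(f"unknown species {name!r}")
        return float(self.values[_IDX[name]])

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def default_initial_array(params: ReceptorParams) -> np.ndarray:
    """Pre-equilibration initial condition: everything zero except the
    conserved pools, which start fully in their inactive form."""
    y = np.zeros(N_SPECIES)
    y[_IDX["CBM"]] = params.cbm_total
    y[_IDX["TAK1"]] = params.tak1_total
    y[_IDX["TRAF6_off"]] = params.traf6_total
    y[_IDX["IKK_off"]] = params.ikk_total
    return y


def receptor_rhs(y: Sequence[float], params: ReceptorParams) -> np.ndarray:
    """Right-hand side of the 19 receptor ODEs (nM/h), array in / array out.

    Hand-assembled from the per-reaction kinetic scheme; the test-suite
    checks it against a brute-force stoichiometric evaluation of
    :data:`REACTIONS`.
    """
    p = params.phi
    c = params.c_c2m
    (ant, bcr, abcr, cbm, acbm, icbm, l40, r40, lr40,
     t6off, t6, t3, tak1, atak1, ikkoff, ikk2, ikk3, iikk, nik) = y

    dy = np.empty(N_SPECIES)

    bind_b = p[4] * ant * bcr
    bind_c = p[14] * l40 * r40

    dy[0] = -p[1] * ant - bind_b * c + p[5] * abcr * c            # ANTIGEN
    dy[1] = p[2] - p[3] * bcr - bind_b + p[5] * abcr              # BCR
    dy[2] = bind_b - p[5] * abcr - p[6] * abcr                    # ABCR

    f7 = p[7] * cbm * abcr
    f9 = p[9] * acbm * ikk2
    dy[3] = -f7 + p[8] * acbm + p[10] * icbm                      # CBM
    dy[4] = f7 - p[8] * acbm - f9                                 # ACBM
    dy[5] = f9 - p[10] * icbm                                     # ICBM

    dy[6] = -p[11] * l40 - bind_c * c + p[15] * lr40 * c          # CD40L
    dy[7] = p[12] - p[13] * r40 - bind_c + p[15] * lr40           # CD40R
    dy[8] = bind_c - p[15] * lr40 - p[16] * lr40                  # CD40LR

    f17 = p[17] * lr40 * t6off
    dy[9] = -f17 + p[18] * t6                                     # TRAF6_off
    dy[10] = f17 - p[18] * t6                                     # TRAF6

    dy[11] = p[19] - p[20] * t3 - p[21] * lr40 * t3               # TRAF3

    act_tak = (p[22] * acbm + p[23] * t6 + p[24] * ikk2
               + p[25] * ikk3 + p[26]) * tak1
    dy[12] = -act_tak + p[27] * atak1                             # TAK1
    dy[13] = act_tak - p[27] * atak1                              # ATAK1

    f28 = p[28] * atak1 * ikkoff
    f31 = p[31] * ikk3 * ikk2
    dy[14] = -f28 + p[29] * ikk2 + p[34] * iikk                   # IKK_off
    dy[15] = f28 - (p[29] + p[30]) * ikk2 - f31 + p[32] * ikk3    # IKK2
    dy[16] = p[30] * ikk2 + f31 - (p[32] + p[33]) * ikk3          # IKK3
    dy[17] = p[33] * ikk3 - p[34] * iikk                          # IIKK

    hn = params.n_traf3_hill
    t3n = t3 ** hn
    hill = t3n / (t3n + params.k_traf3_half ** hn) if t3 > 0 else 0.0
    dy[18] = p[35] - p[36] * nik - p[37] * nik * hill             # NIK

    return dy


def receptor_derivatives(state: ReceptorState | np.ndarray,
                         params: ReceptorParams,
                         t: float = 0.0) -> ReceptorState:
    """Time derivative of every receptor species (nM/h) at ``state``.

    Raises :class:`InvalidStateError` if any concentration is below -1e-9.
    """
    y = state.as_array() if isinstance(state, ReceptorState) else np.asarray(state, float)
    if y.shape != (N_SPECIES,):
        raise ConfigurationError(f"state must have {N_SPECIES} species")
    if np.any(y < -1e-9):
        bad = SPECIES[int(np.argmin(y))]
        raise InvalidStateError(f"negative concentration for {bad}: {y.min():g}")
    return ReceptorState(receptor_rhs(y, params))


@dataclass
class ReceptorTrajectory:
    """Receptor-layer solution on a time grid (times in h, nM concentrations)."""

    times: np.ndarray
    values: np.ndarray  # shape (len(times), N_SPECIES)

    def species(self, name: str) -> np.ndarray:
        if name not in _IDX:
            raise ConfigurationError(f"unknown species {name!r}")
        return self.values[:, _IDX[name]]

    def final_state(self) -> ReceptorState:
        return ReceptorState(self.values[-1].copy())

    def to_frame(self, cell_id: str | int = 0):
        """Tidy table (time_h, species, concentration_nM, cell_id)."""
        import pandas as pd

        n_t = len(self.times)
        return pd.DataFrame({
            "time_h": np.repeat(self.times, N_SPECIES),
            "species": np.tile(np.array(SPECIES), n_t),
            "concentration_nM": self.values.ravel(),
            "cell_id": cell_id,
        })


def _integrate_segment(y0: np.ndarray, t0: float, t1: float,
                       params: ReceptorParams,
                       t_eval: np.ndarray | None,
                       atol: float, rtol: float) -> tuple[np.ndarray, np.ndarray]:
    """Integrate one protocol segment.  LSODA handles the stiffness of the
    fast kinase cycles (rates up to ~2.6e5 / h) that an explicit solver
    cannot step over at a 96 h horizon."""
    fun = lambda t, y: receptor_rhs(y, params)
    sol = solve_ivp(fun, (t0, t1), y0, method="LSODA",
                    t_eval=t_eval, atol=atol, rtol=rtol)
    if not sol.success:
        raise RuntimeError(f"receptor integration failed at t={sol.t[-1] if len(sol.t) else t0:g} h: "
                           f"{sol.message}")
    return sol.t, sol.y.T


def simulate_receptor(protocol: StimulationProtocol,
                      params: ReceptorParams | None = None,
                      t_grid: Sequence[float] | None = None,
                      initial_state: ReceptorState | np.ndarray | None = None,
                      atol: float = 1e-5,
                      rtol: float = 1e-3) -> ReceptorTrajectory:
    """Integrate the receptor layer under a ligand stimulation protocol.

    Ligand additions are applied as instantaneous concentration jumps of the
    free-ligand species at the protocol onsets; washout sets the free ligand
    to zero at the offset (modeling an experimental wash).  If no initial
    state is given the ligand-free steady state is used.
    """
    params = params or ReceptorParams()
    protocol.validate()
    if initial_state is None:
        state, _ = find_steady_state(params)
        y = state.as_array().copy()
    else:
        y = (initial_state.as_array() if isinstance(initial_state, ReceptorState)
             else np.asarray(initial_state, float)).copy()

    if t_grid is None:
        t_grid = np.linspace(0.0, protocol.horizon(default=96.0), 385)
    t_grid = np.asarray(t_grid, dtype=float)
    t_end = float(t_grid[-1])

    lig_idx = {"ANTIGEN": _IDX["ANTIGEN"], "CD40L": _IDX["CD40L"]}
    events = protocol.ligand_events(t_end)

    out_t: list[np.ndarray] = []
    out_y: list[np.ndarray] = []
    t_now = float(t_grid[0])
    for ev_time, actions in events + [(t_end, [])]:
        if ev_time > t_now:
            mask = (t_grid >= t_now) & (t_grid <= ev_time)
            te = t_grid[mask]
            # ensure segment endpoints are integrated even if not requested
            seg_eval = np.unique(np.concatenate([[t_now], te, [ev_time]]))
            ts, ys = _integrate_segment(y, t_now, ev_time, params, seg_eval, atol, rtol)
            keep = np.isin(ts, te)
            out_t.append(ts[keep])
            out_y.append(ys[keep])
            y = ys[-1].copy()
            t_now = ev_time
        for species, mode, value in actions:
            i = lig_idx[species]
            if mode == "add":
                y[i] += value
            else:  # washout
                y[i] = 0.0

    times = np.concatenate(out_t) if out_t else t_grid[:1]
    values = np.vstack(out_y) if out_y else y[None, :]
    # de-duplicate grid points that straddle event boundaries
    times, unique_idx = np.unique(times, return_index=True)
    return ReceptorTrajectory(times=times, values=values[unique_idx])


def find_steady_state(params: ReceptorParams | None = None,
                      initial: np.ndarray | None = None,
                      max_time: float = 800.0,
                      deriv_tol: float = 1e-7,
                      atol: float = 1e-5,
                      rtol: float = 1e-3) -> tuple[ReceptorState, bool]:
    """Ligand-free resting state of the receptor layer.

    Integrates from the documented default initial condition until the
    largest relative derivative falls below ``deriv_tol`` per hour, capped at
    ``max_time`` (800 h).  Returns the state and a convergence flag; a
    non-converged run returns the best state found with ``converged=False``.
    """
    params = params or ReceptorParams()
    y = default_initial_array(params) if initial is None else np.asarray(initial, float).copy()
    t_now, converged = 0.0, False
    while t_now < max_time:
        t_next = min(t_now + 200.0, max_time)
        _, ys = _integrate_segment(y, t_now, t_next, params, np.array([t_now, t_next]),
                                   atol, rtol)
        y = ys[-1]
        t_now = t_next
        dy = receptor_rhs(y, params)
        if np.max(np.abs(dy) / (np.abs(y) + 1.0)) < deriv_tol:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn("receptor steady state not converged within "
                      f"{max_time:g} h", stacklevel=2)
    return ReceptorState(np.maximum(y, 0.0)), converged


def write_rate_table(path) -> None:
    """Write the kinetic scheme as a tabular CSV (module, index, reaction,
    rate, units, source, category) -- the package's parameter-exchange
    format."""
    import importlib.resources as res
    import shutil

    src = res.files("bcellfate") / "data" / "receptor_rates.csv"
    with open(path, "w") as fh:
        fh.write(src.read_text())


def load_rate_table(path, validate: bool = True) -> ReceptorParams:
    """Load rate constants from the tabular CSV dialect.

    With ``validate`` (default), indices must cover 1..37 and categories
    must match the built-in registry; rates themselves may differ (that is
    the point of the file).
    """
    import csv

    phi = np.array(PHI_DEFAULTS)
    seen = set()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            i = int(row["index"])
            if not 1 <= i <= 37:
                raise ConfigurationError(f"rate index {i} out of range")
            phi[i] = float(row["rate"])
            seen.add(i)
            if validate and row.get("category") and \
                    row["category"] != PHI_CATEGORY[i]:
                raise ConfigurationError(
                    f"category mismatch for rate {i}: {row['category']!r}")
    if validate and seen != set(range(1, 38)):
        missing = sorted(set(range(1, 38)) - seen)
        raise ConfigurationError(f"missing rate indices: {missing}")
    return ReceptorParams(phi=phi)


def conservation_totals(y: np.ndarray) -> dict[str, float]:
    """The four conserved pool totals at a state (used by invariant checks)."""
    g = lambda n: y[_IDX[n]]
    return {
        "CBM": g("CBM") + g("ACBM") + g("ICBM"),
        "TAK1": g("TAK1") + g("ATAK1"),
        "TRAF6": g("TRAF6_off") + g("TRAF6"),
        "IKK": g("IKK_off") + g("IKK2") + g("IKK3") + g("IIKK"),
    }
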