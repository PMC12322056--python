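"""Cell-fate decision layer: reduced apoptosis and cell-cycle modules.

Apoptosis branch
----------------
A compact caspase cascade carrying the BCR-engagement-driven caspase-8
processing term exactly as specified (flux = phi_c8_aicd * [PC8] * [ABCR],
moved from pre-caspase-8 to caspase-8 on top of the baseline turnover) plus
the Bcl-xL protection logic: caspase-8 activates Bax, NF-kB-induced Bcl-xL
neutralizes activated Bax, and mitochondrial outer-membrane
permeabilization (MOMP) fires when activated Bax exceeds a threshold.  MOMP
is latched; thereafter cleaved PARP (cParp) accumulates, and its crossing
of ``cparp_death_threshold`` defines virtual cell death.

The baseline PC8/C8 dynamics are first-order synthesis/turnover with a
basal processing term that is switched on at culture onset (t = 0): it
stands in for the survival-factor withdrawal that makes unstimulated
primary B cells die in culture, and gives NF-kB-induced Bcl-xL something to
rescue cells from.

Cell-cycle branch
-----------------
A reduced growth/commitment cascade: a cMyc-like commitment integrator
driven by saturating nuclear NF-kB activity gates retinoblastoma (Rb)
inactivation; once Rb falls below its restriction threshold, cyclin B
accumulates and flips the Cdh1 switch off.  Each downward crossing of Cdh1
through ``cdh1_division_threshold`` emits a division; the caller resets
CycB/Cdh1/mass afterwards.  The CD40 re-tuning of this branch multiplies
the Rb decay rate by 0.1 and the CycB synthesis rate by 1.8.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ApoptosisParams",
    "ApoptosisState",
    "CellCycleParams",
    "CellCycleState",
    "aicd_caspase8_flux",
    "apoptosis_rhs",
    "cellcycle_rhs",
    "death_event",
    "division_event",
    "apply_cd40_tuning",
    "first_downward_crossing",
]

APOP_SPECIES: tuple[str, ...] = ("PC8", "C8", "BclxL", "BaxA", "cParp")
N_APOP = len(APOP_SPECIES)

CC_SPECIES: tuple[str, ...] = ("commit", "Rb", "CycB", "Cdh1", "mass")
N_CC = len(CC_SPECIES)


@dataclass
class ApoptosisParams:
    """Apoptosis-branch rates (nM, per hour)."""

    phi_c8_aicd: float = 0.00021  # 1/(nM h), BCR-engagement-driven C8 processing
    pc8_syn: float = 190.0         # nM/h pre-caspase-8 synthesis
    pc8_deg: float = 0.01         # 1/h pre-caspase-8 turnover
    c8_basal: float = 2.65e-5        # 1/h basal PC8->C8 processing (culture stress)
    c8_deg: float = 0.08          # 1/h caspase-8 decay
    bclxl_syn0: float = 0.04      # nM/h basal Bcl-xL synthesis
    bclxl_nfkb: float = 0.45       # nM/h Bcl-xL induction per unit NF-kB drive
    w_rela: float = 0.3           # RelA weight in the Bcl-xL induction drive
    w_crel: float = 0.45           # canonical-cRel weight in the Bcl-xL drive
    w_p52: float = 2.8            # cRel:p52 weight in the Bcl-xL drive (the
                                  # non-canonical arm discriminates CD40 help
                                  # from BCR-only signaling)
    bclxl_deg: float = 0.09       # 1/h Bcl-xL turnover
    bax_act: float = 0.215         # 1/h Bax activation per nM caspase-8
    bax_sat: float = 15.5         # nM caspase-8 soft saturation of Bax activation
    bax_deg: float = 0.02         # 1/h activated-Bax decay
    neutralize: float = 1.0       # 1/(nM h) Bcl-xL sequestration of BaxA
    momp_threshold: float = 4.0   # nM activated Bax triggering MOMP
    parp_cleave: float = 2.0      # nM/h cParp accumulation after MOMP
    cparp_death_threshold: float = 1.0  # nM cParp defining virtual death

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")

    def copy(self) -> "ApoptosisParams":
        return dataclasses.replace(self)


APOP_CATEGORY: dict[str, str] = {
    "pc8_syn": "synthesis", "pc8_deg": "degradation",
    "c8_deg": "degradation",
    "bclxl_syn0": "synthesis", "bclxl_nfkb": "synthesis",
    "bclxl_deg": "degradation", "bax_deg": "degradation",
}


@dataclass
class ApoptosisState:
    """Apoptosis-branch concentrations plus the latched MOMP flag."""

    values: np.ndarray
    momp: bool = False

    def __getitem__(self, name: str) -> float:
        return float(self.values[APOP_SPECIES.index(name)])

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass
class CellCycleParams:
    """Cell-cycle-branch rates (dimensionless activity units, per hour)."""

    myc_gain: float = 0.0895      # commitment accumulation gain (cMyc proxy)
    myc_half: float = 0.025        # NF-kB drive at half-maximal accumulation
    myc_decay: float = 0.12       # 1/h commitment decay
    commit_threshold: float = 1.0  # commitment level gating Rb inactivation
    commit_sharpness: float = 8.0  # Hill exponent of the commitment gate
    commit_feedback: float = 1.0   # autocatalytic commitment gain (latch)
    rb_decay: float = 1.65        # 1/h committed Rb inactivation rate
    rb_drive_half: float = 0.8    # NF-kB drive at half-maximal Rb inactivation
    rb_initial: float = 1.0       # resting Rb level
    rb_threshold: float = 0.03    # restriction point: CycB allowed below this
    cycb_synth: float = 0.105     # 1/h cyclin B synthesis when cycling
    cycb_drive_half: float = 0.0  # optional drive gate on cycle re-entry (off)
    cycb_decay: float = 0.02      # 1/h cyclin B decay
    cdh1_on: float = 1.2          # 1/h Cdh1 re-activation rate
    cdh1_off: float = 10.0         # 1/(CycB h) CycB-driven Cdh1 inactivation
    cdh1_division_threshold: float = 0.2
    growth_gain: float = 0.04     # 1/h maximal mass growth rate
    growth_half: float = 0.25      # NF-kB drive at half-maximal growth
    division_mass_min: float = 0.8  # mass required to execute a division
    cycb_reset: float = 0.0       # post-division cyclin B
    tuned: bool = False           # guard against double application of tuning

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name == "tuned":
                continue
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")

    def copy(self) -> "CellCycleParams":
        return dataclasses.replace(self)


CC_CATEGORY: dict[str, str] = {
    "myc_gain": "synthesis", "myc_decay": "degradation",
    "rb_decay": "degradation",
    "cycb_synth": "synthesis", "cycb_decay": "degradation",
}

#: Parameters included in the local sensitivity scan.
CC_SCAN_PARAMETERS: tuple[str, ...] = (
    "myc_gain", "myc_half", "myc_decay", "rb_decay", "rb_threshold",
    "cycb_synth", "cycb_decay", "cdh1_on", "cdh1_off", "growth_gain",
)


@dataclass
class CellCycleState:
    values: np.ndarray

    def __getitem__(self, name: str) -> float:
        return float(self.values[CC_SPECIES.index(name)])

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def initial_cellcycle_array(params: CellCycleParams) -> np.ndarray:
    """Resting state: uncommitted, Rb at its full level, Cdh1 on, unit mass."""
    return np.array([0.0, params.rb_initial, 0.0, 1.0, 1.0])


def aicd_caspase8_flux(pc8: float, abcr: float, params: ApoptosisParams) -> float:
    """BCR-engagement-driven caspase-8 processing flux (nM/h).

    Applied as ``-flux`` to d[PC8]/dt and ``+flux`` to d[C8]/dt, so the
    PC8 + C8 bookkeeping is unchanged by the term.
    """
    if pc8 < 0 or abcr < 0:
        raise ValueError("concentrations must be non-negative")
    return params.phi_c8_aicd * pc8 * abcr


def apoptosis_rhs(y: Sequence[float], abcr: float, nfkb_drive: float,
                  params: ApoptosisParams, momp: bool,
                  aicd_enabled: bool = True,
                  culture: bool = True) -> np.ndarray:
    """Apoptosis-branch derivative.

    ``nfkb_drive`` is the weighted nuclear NF-kB activity
    (w_rela * RelA fold + w_crel * cRel fold, pre-weighted by the caller or
    passed raw via :func:`bclxl_drive`).  ``culture=False`` disables the
    basal stress processing (used during pre-equilibration).
    """
    p = params
    pc8, c8, bclxl, bax, _cparp = y
    aicd = p.phi_c8_aicd * pc8 * abcr if aicd_enabled else 0.0
    basal = p.c8_basal * pc8 if culture else 0.0
    dy = np.empty(N_APOP)
    dy[0] = p.pc8_syn - p.pc8_deg * pc8 - aicd - basal
    dy[1] = aicd + basal - p.c8_deg * c8
    dy[2] = (p.bclxl_syn0 + p.bclxl_nfkb * nfkb_drive
             - p.bclxl_deg * bclxl - p.neutralize * bclxl * bax)
    # effector activation saturates softly at high caspase-8 (finite
    # effector pool), so a large AICD burst cannot outrun protection
    # indefinitely
    bax_flux = p.bax_act * c8 / (1.0 + c8 / p.bax_sat)
    dy[3] = bax_flux - p.bax_deg * bax - p.neutralize * bclxl * bax
    dy[4] = p.parp_cleave * (c8 / (c8 + 1.0)) if momp else 0.0
    return dy


def cellcycle_rhs(y: Sequence[float], nfkb_drive: float,
                  params: CellCycleParams) -> np.ndarray:
    """Cell-cycle-branch derivative, driven by nuclear NF-kB activity."""
    p = params
    commit, rb, cycb, cdh1, mass = y
    sat = nfkb_drive / (p.myc_half + nfkb_drive) if nfkb_drive > 0 else 0.0
    cn = max(commit, 0.0) ** p.commit_sharpness
    gate = cn / (cn + p.commit_threshold ** p.commit_sharpness)
    cycling = p.rb_threshold ** 2 / (p.rb_threshold ** 2 + rb * rb)
    # cycle re-entry needs sustained mitogenic signal: when the NF-kB drive
    # decays, cyclin B synthesis stalls and the lineage stops dividing
    if p.cycb_drive_half > 0:
        d3 = nfkb_drive ** 3
        cycling *= d3 / (d3 + p.cycb_drive_half ** 3) if nfkb_drive > 0 else 0.0
    dy = np.empty(N_CC)
    # autocatalytic term latches commitment once the gate opens
    dy[0] = p.myc_gain * sat * (1.0 + p.commit_feedback * gate) - p.myc_decay * commit
    # Rb inactivation speed stays graded in the sustained drive (it does not
    # saturate with dose), which carries the dose dependence of the time to
    # first division
    w_rb = nfkb_drive / (p.rb_drive_half + nfkb_drive) if p.rb_drive_half > 0 else 1.0
    dy[1] = -p.rb_decay * gate * w_rb * rb
    dy[2] = p.cycb_synth * cycling - p.cycb_decay * cycb
    dy[3] = p.cdh1_on * (1.0 - cdh1) - p.cdh1_off * cycb * cdh1
    g = nfkb_drive / (p.growth_half + nfkb_drive) if nfkb_drive > 0 else 0.0
    dy[4] = p.growth_gain * g * mass
    return dy


def apply_cd40_tuning(base: CellCycleParams) -> CellCycleParams:
    """CD40-activated cell-fate tuning: Rb decay x0.1, CycB synthesis x1.8.

    Idempotent: a ``tuned`` flag guards against double application.
    """
    if base.tuned:
        return base.copy()
    out = base.copy()
    out.rb_decay = base.rb_decay * 0.1
    out.cycb_synth = base.cycb_synth * 1.8
    out.tuned = True
    return out


def _validate_grid(times: np.ndarray) -> None:
    if np.any(np.diff(times) <= 0):
        raise ValueError("time grid must be strictly increasing")


def death_event(times: Sequence[float], cparp: Sequence[float],
                threshold: float) -> float | None:
    """First time cParp crosses ``threshold`` (linear interpolation), or None."""
    times = np.asarray(times, dtype=float)
    cparp = np.asarray(cparp, dtype=float)
    _validate_grid(times)
    above = cparp >= threshold
    if not above.any():
        return None
    k = int(np.argmax(above))
    if k == 0:
        return float(times[0])
    t0, t1 = times[k - 1], times[k]
    v0, v1 = cparp[k - 1], cparp[k]
    if v1 == v0:
        return float(t1)
    return float(t0 + (threshold - v0) / (v1 - v0) * (t1 - t0))


def first_downward_crossing(times: np.ndarray, values: np.ndarray,
                            threshold: float) -> float | None:
    """First downward crossing of ``values`` through ``threshold``."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    _validate_grid(times)
    for k in range(1, len(times)):
        if values[k - 1] > threshold >= values[k]:
            v0, v1 = values[k - 1], values[k]
            t0, t1 = times[k - 1], times[k]
            return float(t0 + (v0 - threshold) / (v0 - v1) * (t1 - t0))
    return None


def division_event(times: Sequence[float], cdh1: Sequence[float],
                   threshold: float) -> list[float]:
    """All downward crossings of Cdh1 through ``threshold`` (division times)."""
    times = np.asarray(times, dtype=float)
    cdh1 = np.asarray(cdh1, dtype=float)
    _validate_grid(times)
    out: list[float] = []
    for k in range(1, len(times)):
        if cdh1[k - 1] > threshold >= cdh1[k]:
            v0, v1 = cdh1[k - 1], cdh1[k]
            t0, t1 = times[k - 1], times[k]
            out.append(float(t0 + (v0 - threshold) / (v0 - v1) * (t1 - t0)))
    return out
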