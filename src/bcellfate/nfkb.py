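"""Reduced multi-dimer NF-kB module.

Converts receptor-layer kinase activities (IKK2/IKK3 canonical, NIK
non-canonical) into nuclear RelA:p50, cRel:p50 and cRel:p52 trajectories.
This is a deliberately compact surrogate for the full published NF-kB
network: it keeps only the species and couplings needed to reproduce the
calibrated fold-change readouts and their qualitative dose structure:

* canonical arm -- IKK activity degrades IkBa, releasing RelA:p50 and
  cRel:p50 into the nucleus; NF-kB-inducible IkBa resynthesis provides the
  adaptive (transient) response;
* non-canonical arm -- NIK processes p100 into p52 (read out as nuclear
  cRel:p52, which keeps rising with dose while the canonical dimers
  saturate) and degrades the IkBd (p100-multimer) brake on the canonical
  dimers;
* cRel autoinduction -- total cRel synthesis is boosted by nuclear NF-kB,
  amplifying cRel under sustained stimulation.

Kinase drives enter as fold over a reference basal activity so that the
module is insensitive to the absolute scale of the receptor-layer pools.
Dimer abundances are normalized to a resting total of ~1; all readouts
consumed downstream are fold-changes over the cell's own resting state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "NFKB_SPECIES",
    "NfkbParams",
    "NfkbState",
    "nfkb_derivatives",
    "nfkb_rhs",
    "fold_change",
    "calibrate_surrogate",
    "CalibrationAnchor",
    "CalibrationResult",
]

#: State vector order.
NFKB_SPECIES: tuple[str, ...] = (
    "RelA_p50_cyt", "RelA_p50_nuc",
    "cRel_p50_cyt", "cRel_p50_nuc",
    "cRel_p52_cyt", "cRel_p52_nuc",
    "IkBa", "IkBd", "p100",
)
N_NFKB = len(NFKB_SPECIES)
_IDX = {n: i for i, n in enumerate(NFKB_SPECIES)}


@dataclass
class NfkbParams:
    """Rates of the reduced NF-kB module (per hour; abundances normalized).

    Defaults are the calibrated release fitted to population-mean nuclear
    RelA/cRel fold-change anchors under low and high CD40 stimulation
    (see :func:`calibrate_surrogate`).
    """

    # reference basal kinase activities used to express drives as folds
    ikk_ref: float = 3.57e-5     # nM, resting IKK2+IKK3
    nik_ref: float = 5.38        # nM, resting NIK

    # RelA:p50
    rela_syn: float = 0.02       # synthesis into cytoplasm
    rela_deg: float = 0.02       # first-order turnover
    rela_imp: float = 50.70        # max IKK-gated nuclear import
    rela_k: float = 2.612          # IKK fold at half-maximal import
    rela_h: float = 5.495          # import Hill coefficient
    rela_exp: float = 0.55       # basal nuclear export
    rela_exp_ikba: float = 1.45   # IkBa-enhanced export gain
    rela_brake: float = 1.2      # IkBd import brake coefficient

    # cRel:p50
    crel_syn: float = 0.015
    crel_deg: float = 0.015
    crel_aut: float = 0.6386        # autoinduction gain on synthesis
    crel_imp: float = 2.99
    crel_k: float = 2.093
    crel_h: float = 5.431
    crel_exp: float = 0.6
    crel_exp_ikba: float = 4.4
    crel_brake: float = 1.6

    # p100 / cRel:p52 (non-canonical)
    p100_syn: float = 0.05
    p100_ind: float = 0.5        # NF-kB-inducible p100 synthesis gain
    p100_deg: float = 0.05
    p100_proc: float = 0.00086     # NIK-driven processing rate (per NIK fold)
    p52_imp: float = 0.8
    p52_deg_cyt: float = 0.02
    p52_deg_nuc: float = 0.12

    # IkBa feedback
    ikba_syn0: float = 0.05
    ikba_syn_ind: float = 1.39    # NF-kB-inducible synthesis gain
    ikba_deg0: float = 0.25
    ikba_deg_ikk: float = 0.06   # IKK-driven degradation (per IKK fold)

    # IkBd brake
    ikbd_form: float = 0.1       # assembly from p100
    ikbd_deg0: float = 0.05
    ikbd_deg_nik: float = 0.05   # NIK-driven release (per NIK fold)

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")

    def copy(self) -> "NfkbParams":
        return dataclasses.replace(self)


#: Kinetic category per parameter, for heterogeneous-cell sampling.
NFKB_CATEGORY: dict[str, str] = {
    "rela_syn": "synthesis", "rela_deg": "degradation",
    "crel_syn": "synthesis", "crel_deg": "degradation",
    "p100_syn": "synthesis", "p100_deg": "degradation",
    "ikba_syn0": "synthesis", "ikba_deg0": "degradation",
    "p52_deg_cyt": "degradation", "p52_deg_nuc": "degradation",
    "ikbd_deg0": "degradation",
    # gated imports/exports, Hill constants and feedback gains are treated
    # as catalytic couplings and left undistributed
}


@dataclass
class NfkbState:
    values: np.ndarray

    def __getitem__(self, name: str) -> float:
        return float(self.values[_IDX[name]])

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @property
    def nuclear_rela(self) -> float:
        """Nuclear RelA readout group (RelA:p50; RelA:p52 is folded in)."""
        return float(self.values[_IDX["RelA_p50_nuc"]])

    @property
    def nuclear_crel(self) -> float:
        """Nuclear cRel readout group (cRel:p50 + cRel:p52)."""
        return float(self.values[_IDX["cRel_p50_nuc"]] + self.values[_IDX["cRel_p52_nuc"]])


def resting_state(params: NfkbParams) -> np.ndarray:
    """Crude pre-equilibration starting point (refined by the steady-state
    phase of a simulation)."""
    y = np.zeros(N_NFKB)
    y[_IDX["RelA_p50_cyt"]] = 1.0
    y[_IDX["cRel_p50_cyt"]] = 1.0
    y[_IDX["p100"]] = params.p100_syn / max(params.p100_deg, 1e-12)
    y[_IDX["IkBa"]] = params.ikba_syn0 / max(params.ikba_deg0, 1e-12)
    y[_IDX["IkBd"]] = 1.0
    return y


def nfkb_rhs(y: Sequence[float], k2_fold: float, nik_fold: float,
             params: NfkbParams) -> np.ndarray:
    """Right-hand side of the 9 NF-kB ODEs.

    ``k2_fold``/``nik_fold`` are canonical (IKK2+IKK3) and non-canonical
    (NIK) activities expressed as fold over the resting reference.
    """
    p = params
    (ac, an, cc, cn, zc, zn, ikba, ikbd, p100) = y

    nuc = an + cn  # nuclear NF-kB activity sensed by feedback promoters

    # canonical import gates (saturating in kinase fold)
    ga = k2_fold ** p.rela_h
    gate_a = ga / (ga + p.rela_k ** p.rela_h)
    gc = k2_fold ** p.crel_h
    gate_c = gc / (gc + p.crel_k ** p.crel_h)

    imp_a = p.rela_imp * gate_a / (1.0 + p.rela_brake * ikbd)
    exp_a = p.rela_exp * (1.0 + p.rela_exp_ikba * ikba)
    imp_c = p.crel_imp * gate_c / (1.0 + p.crel_brake * ikbd)
    exp_c = p.crel_exp * (1.0 + p.crel_exp_ikba * ikba)

    proc = p.p100_proc * nik_fold * p100  # NIK-driven p100 -> p52 processing

    dy = np.empty(N_NFKB)
    dy[0] = p.rela_syn - p.rela_deg * ac - imp_a * ac + exp_a * an
    dy[1] = imp_a * ac - exp_a * an - p.rela_deg * an
    csyn = p.crel_syn * (1.0 + p.crel_aut * nuc)
    dy[2] = csyn - p.crel_deg * cc - imp_c * cc + exp_c * cn
    dy[3] = imp_c * cc - exp_c * cn - p.crel_deg * cn
    dy[4] = proc - (p.p52_imp + p.p52_deg_cyt) * zc
    dy[5] = p.p52_imp * zc - p.p52_deg_nuc * zn
    dy[6] = (p.ikba_syn0 + p.ikba_syn_ind * nuc
             - ikba * (p.ikba_deg0 + p.ikba_deg_ikk * k2_fold))
    dy[7] = p.ikbd_form * p100 - ikbd * (p.ikbd_deg0 + p.ikbd_deg_nik * nik_fold)
    dy[8] = (p.p100_syn * (1.0 + p.p100_ind * nuc)
             - p.p100_deg * p100 - proc)
    return dy


def nfkb_derivatives(state: NfkbState | np.ndarray,
                     drive: Mapping[str, float],
                     params: NfkbParams) -> NfkbState:
    """Module derivative given raw kinase activities.

    ``drive`` maps ``IKK2``/``IKK3``/``NIK`` to activities in receptor-layer
    units (nM); they are normalized internally by the reference basals.
    """
    y = state.as_array() if isinstance(state, NfkbState) else np.asarray(state, float)
    for k, v in drive.items():
        if v < 0:
            raise ValueError(f"negative drive {k}={v!r}")
    k2 = (drive.get("IKK2", 0.0) + drive.get("IKK3", 0.0)) / params.ikk_ref
    nik = drive.get("NIK", 0.0) / params.nik_ref
    return NfkbState(nfkb_rhs(y, k2, nik, params))


def fold_change(times: np.ndarray, nuclear: np.ndarray,
                baseline: float | None = None) -> np.ndarray:
    """Fold-change time series of a nuclear readout relative to its t=0 value.

    ``nuclear`` is the summed nuclear dimer group (RelA group =
    RelA:p50 + RelA:p52; cRel group = cRel:p50 + cRel:p52).
    """
    nuclear = np.asarray(nuclear, dtype=float)
    if baseline is None:
        baseline = float(nuclear[0])
    if baseline <= 0:
        raise ValueError("fold-change baseline must be positive")
    return nuclear / baseline


@dataclass(frozen=True)
class CalibrationAnchor:
    """One fold-change calibration target.

    ``cd40_nM``/``bcr_nM`` define the stimulation condition, ``time_h`` the
    readout time, ``readout`` is ``"RelA"`` or ``"cRel"``, and ``fold`` the
    target population-mean nuclear fold-change.
    """

    cd40_nM: float
    time_h: float
    readout: str
    fold: float
    bcr_nM: float = 0.0


#: Anchor set used for the shipped parameter release: nuclear RelA rises
#: 10-fold (high CD40) and 5-fold (low CD40) at 7 h, nuclear cRel 13- and
#: 4-fold.
DEFAULT_ANCHORS: tuple[CalibrationAnchor, ...] = (
    CalibrationAnchor(30.0, 7.0, "RelA", 10.0),
    CalibrationAnchor(6.0, 7.0, "RelA", 5.0),
    CalibrationAnchor(30.0, 7.0, "cRel", 13.0),
    CalibrationAnchor(6.0, 7.0, "cRel", 4.0),
)

#: Parameters released to the optimizer during calibration (log-space).
CALIBRATION_FREE: tuple[str, ...] = (
    "rela_imp", "rela_k", "crel_imp", "crel_k", "p100_proc", "crel_aut",
)


@dataclass
class CalibrationResult:
    params: NfkbParams
    residuals: np.ndarray       # per-anchor log-fold errors
    achieved: np.ndarray        # per-anchor achieved folds
    converged: bool
    message: str = ""


def calibrate_surrogate(anchors: Sequence[CalibrationAnchor],
                        params0: NfkbParams | None = None,
                        free: Sequence[str] = CALIBRATION_FREE,
                        n_cells: int = 100,
                        seed: int = 20240101,
                        cv: float = 0.112,
                        max_nfev: int = 40,
                        rtol_skip: float = 0.02) -> CalibrationResult:
    """Fit the surrogate's free parameters to fold-change anchors.

    Minimizes squared log-fold errors of population-mean nuclear readouts
    over ``n_cells`` heterogeneous virtual cells (common random numbers
    across optimizer iterations), using bounded least squares in log
    parameter space.  If ``params0`` already satisfies every anchor within
    ``rtol_skip`` (log-fold), it is returned unchanged.
    """
    from scipy.optimize import least_squares

    if not anchors:
        raise ValueError("anchor list must be non-empty")
    params0 = params0 or NfkbParams()

    def residual_fn(pars: NfkbParams) -> tuple[np.ndarray, np.ndarray]:
        folds = _population_anchor_folds(anchors, pars, n_cells, seed, cv)
        res = np.log(folds / np.array([a.fold for a in anchors]))
        return res, folds

    res0, folds0 = residual_fn(params0)
    if np.all(np.abs(res0) <= rtol_skip):
        return CalibrationResult(params0, res0, folds0, True,
                                 "anchors already satisfied")

    x0 = np.log([getattr(params0, k) for k in free])

    def fun(x: np.ndarray) -> np.ndarray:
        pars = params0.copy()
        for k, v in zip(free, np.exp(x)):
            setattr(pars, k, float(v))
        return residual_fn(pars)[0]

    opt = least_squares(fun, x0, bounds=(x0 - 3.0, x0 + 3.0),
                        diff_step=0.05, max_nfev=max_nfev, xtol=1e-3, ftol=1e-4)
    fitted = params0.copy()
    for k, v in zip(free, np.exp(opt.x)):
        setattr(fitted, k, float(v))
    res, folds = residual_fn(fitted)
    return CalibrationResult(fitted, res, folds, bool(opt.success), opt.status and str(opt.message))


def _population_anchor_folds(anchors: Sequence[CalibrationAnchor],
                             params: NfkbParams,
                             n_cells: int, seed: int, cv: float) -> np.ndarray:
    """Population-mean nuclear fold-changes at every anchor.

    Implemented via the population simulator (signaling-only mode) to keep
    calibration consistent with how the model is used downstream.
    """
    from .population import population_fold_changes

    conditions = sorted({(a.cd40_nM, a.bcr_nM) for a in anchors})
    t_max = max(a.time_h for a in anchors) + 0.5
    out = np.empty(len(anchors))
    for cond in conditions:
        cd40, bcr = cond
        times = sorted({a.time_h for a in anchors if (a.cd40_nM, a.bcr_nM) == cond})
        folds = population_fold_changes(cd40_nM=cd40, bcr_nM=bcr, times=times,
                                        nfkb_params=params, n_cells=n_cells,
                                        seed=seed, cv=cv, horizon=t_max)
        for i, a in enumerate(anchors):
            if (a.cd40_nM, a.bcr_nM) == cond:
                out[i] = folds[a.readout][times.index(a.time_h)]
    return out
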