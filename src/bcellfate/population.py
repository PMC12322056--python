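"""Agent-based population simulator for heterogeneous virtual B-cells.

Samples per-cell parameter vectors (synthesis/degradation/association/
dissociation rates drawn from a truncated normal with CV 11.2% around the
standard parameter set), pre-equilibrates each cell to its ligand-free
resting state, runs the coupled receptor -> NF-kB -> fate system under a
stimulation protocol, branches lineages on Cdh1-triggered divisions and
censors lineages on cParp-triggered death, and reports generation-resolved
live-cell counts on the experimental time grid {0, 24, 36, 48, 72, 96} h.

Daughters inherit the mother's sampled parameters and signaling state, so a
founder lineage is simulated as one signaling trajectory plus a division
chain with multiplicity 2^generation (see :mod:`bcellfate.cell`).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import fate as ft
from . import nfkb as nf
from . import receptor as rc
from .cell import (CellParams, LineageResult, SignalingTrajectory,
                   find_cell_rest, simulate_cell_signaling, simulate_lineage)
from .stimulus import StimulationProtocol, constant_stimulation

__all__ = [
    "HeterogeneityConfig",
    "VirtualCell",
    "PopulationTrace",
    "sample_parameters",
    "dose_to_nM",
    "simulate_population",
    "population_nfkb_summary",
    "population_fold_changes",
    "EXPERIMENTAL_TIMEPOINTS",
]

#: The experimental observation grid (h).
EXPERIMENTAL_TIMEPOINTS: tuple[float, ...] = (0.0, 24.0, 36.0, 48.0, 72.0, 96.0)

#: Rate categories that are heterogeneous across cells.
DISTRIBUTED_CATEGORIES: frozenset[str] = frozenset(
    {"synthesis", "degradation", "association", "dissociation"})


@dataclass
class HeterogeneityConfig:
    """Cell-to-cell parameter variability.

    Rates in the distributed kinetic categories are drawn per cell from a
    normal distribution with the standard value as mean and ``cv`` times
    the mean as standard deviation, truncated at zero; catalytic rates are
    shared by all cells.
    """

    cv: float = 0.112
    distributed_categories: frozenset[str] = DISTRIBUTED_CATEGORIES

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


@dataclass
class VirtualCell:
    cell_id: str
    parent_id: str | None
    generation: int
    params: CellParams
    birth_time: float = 0.0


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0 or mean == 0:
        return mean
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v >= 0:
            return float(v)
    return 0.0


def sample_parameters(base: CellParams, config: HeterogeneityConfig,
                      rng: np.random.Generator) -> CellParams:
    """One heterogeneous parameter vector around the standard set."""
    out = base.copy()
    cv = config.cv
    cats = config.distributed_categories
    if cv == 0:
        return out
    # receptor rate constants
    for i, cat in sorted(rc.PHI_CATEGORY.items()):
        if cat in cats:
            out.receptor.phi[i] = _truncated_normal(rng, base.receptor.phi[i],
                                                    cv * base.receptor.phi[i])
    # downstream module rates (field order is deterministic)
    for params, registry in ((out.nfkb, nf.NFKB_CATEGORY),
                             (out.apoptosis, ft.APOP_CATEGORY),
                             (out.cellcycle, ft.CC_CATEGORY)):
        for name in sorted(registry):
            if registry[name] in cats:
                mean = getattr(params, name)
                setattr(params, name, _truncated_normal(rng, mean, cv * mean))
    return out


#: Canonical antibody-dose (ug/mL) to model-ligand (nM) mappings.
_DOSE_TABLES = {
    "anti-CD40": ((0.0, 0.0), (1.0, 6.0), (3.3, 12.0), (10.0, 30.0)),
    "anti-BCR": ((0.0, 0.0), (1.0, 0.005), (10.0, 0.25)),
}


def dose_to_nM(ligand: str, dose_ug_per_mL: float) -> float:
    """Map an experimental antibody dose to the model ligand concentration.

    Exact table points: anti-CD40 {0: 0, 1: 6, 3.3: 12, 10: 30} and
    anti-BCR {0: 0, 1: 0.005, 10: 0.25}; other doses are linearly
    interpolated (with a warning) and doses above the table are linearly
    extrapolated from the last segment.
    """
    if ligand not in _DOSE_TABLES:
        raise ValueError(f"unknown ligand {ligand!r}")
    if dose_ug_per_mL < 0:
        raise ValueError("dose must be non-negative")
    table = _DOSE_TABLES[ligand]
    for x, y in table:
        if dose_ug_per_mL == x:
            return y
    xs = np.array([x for x, _ in table])
    ys = np.array([y for _, y in table])
    warnings.warn(f"dose {dose_ug_per_mL} ug/mL for {ligand} is not a tabulated "
                  "point; interpolating linearly", stacklevel=2)
    if dose_ug_per_mL > xs[-1]:
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        return float(ys[-1] + slope * (dose_ug_per_mL - xs[-1]))
    return float(np.interp(dose_ug_per_mL, xs, ys))


@dataclass
class PopulationTrace:
    """Generation-resolved population dynamics of one simulated condition."""

    times: np.ndarray                     # output grid (h)
    counts: np.ndarray                    # (n_times, max_gen+1) live counts
    n_founders: int
    lineages: list[LineageResult]
    trajectories: list[SignalingTrajectory] | None = None
    n_failed: int = 0
    seed: int | None = None

    @property
    def total(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def live_total(self, t: float) -> float:
        return float(sum(lin.live_multiplicity(t) for lin in self.lineages))

    def to_generation_table(self, cap: int = 6, label: str = ""):
        """Bin generations above ``cap`` into the top bin ('cap+')."""
        from .rmsd import GenerationTable

        n = np.zeros((len(self.times), cap + 1))
        n[:, :cap] = self.counts[:, :cap]
        n[:, cap] = self.counts[:, cap:].sum(axis=1)
        return GenerationTable(timepoints=np.asarray(self.times, float),
                               counts=n, label=label)

    def event_log(self) -> pd.DataFrame:
        """Tidy fate-event log, one row per cell event.

        Columns: cell_id, parent_id, generation, event (division / death /
        censored), time_h.  Cells of a lineage share the founder's
        trajectory; ids are synthesized as ``f<founder>_g<generation>_<k>``.
        """
        rows = []
        horizon = float(self.times[-1])
        for i, lin in enumerate(self.lineages):
            death = lin.death_time if (lin.death_time is not None
                                       and lin.death_time <= horizon) else None
            for g, t_div in enumerate(lin.division_times):
                if death is not None and t_div >= death:
                    break
                for k in range(2 ** g):
                    rows.append((f"f{i}_g{g}_{k}",
                                 f"f{i}_g{g - 1}_{k // 2}" if g else None,
                                 g, "division", t_div))
            g_final = lin.generation_at(horizon)
            if g_final is None:
                g_dead = int(np.searchsorted(np.asarray(lin.division_times),
                                             death, side="right"))
                for k in range(2 ** g_dead):
                    rows.append((f"f{i}_g{g_dead}_{k}",
                                 f"f{i}_g{g_dead - 1}_{k // 2}" if g_dead else None,
                                 g_dead, "death", death))
            else:
                for k in range(2 ** g_final):
                    rows.append((f"f{i}_g{g_final}_{k}",
                                 f"f{i}_g{g_final - 1}_{k // 2}" if g_final else None,
                                 g_final, "censored", horizon))
        return pd.DataFrame(rows, columns=["cell_id", "parent_id", "generation",
                                           "event", "time_h"])

    def divider_fraction(self, by_time: float | None = None,
                         of_survivors: bool = False) -> float:
        """Fraction of founders with at least one division (by ``by_time``)."""
        t = by_time if by_time is not None else float(self.times[-1])
        lins = self.lineages
        if of_survivors:
            lins = [l for l in lins if l.generation_at(t) is not None]
        if not lins:
            return float("nan")
        n_div = sum(1 for l in lins
                    if l.division_times and l.division_times[0] <= t)
        return n_div / len(lins)

    def survival_fraction(self, t: float) -> float:
        alive = sum(1 for l in self.lineages if l.generation_at(t) is not None)
        return alive / max(len(self.lineages), 1)

    def first_division_times(self) -> np.ndarray:
        """Tdiv0 values: birth-to-first-division of generation-0 dividers."""
        return np.array([l.division_times[0] for l in self.lineages
                         if l.division_times])

    def later_division_intervals(self) -> np.ndarray:
        """Tdiv1+ values: inter-division intervals of generation >= 1 cells."""
        out = []
        for l in self.lineages:
            out.extend(np.diff(l.division_times))
        return np.asarray(out, dtype=float)


def simulate_population(n_founders: int,
                        protocol: StimulationProtocol,
                        base_params: CellParams | None = None,
                        heterogeneity: HeterogeneityConfig | None = None,
                        seed: int = 0,
                        horizon: float = 96.0,
                        output_times: Sequence[float] | None = None,
                        store_trajectories: bool = True,
                        max_divisions: int = 8,
                        max_failure_fraction: float = 0.1) -> PopulationTrace:
    """Simulate a heterogeneous founder cohort under a stimulation protocol.

    Fully reproducible given ``seed``: founder parameter draws use
    independent child streams of a single seed sequence, so founder ``i``
    receives the same parameter vector in any two runs with the same seed
    and base parameters, regardless of the protocol.
    """
    if n_founders < 1:
        raise ValueError("n_founders must be >= 1")
    base_params = base_params or CellParams()
    heterogeneity = heterogeneity or HeterogeneityConfig()
    if output_times is None:
        output_times = [t for t in EXPERIMENTAL_TIMEPOINTS if t <= horizon]
        if horizon not in output_times:
            output_times = list(output_times) + [horizon]
    output_times = np.asarray(sorted(output_times), dtype=float)

    streams = np.random.SeedSequence(seed).spawn(n_founders)
    base_rest, _ = find_cell_rest(base_params)

    lineages: list[LineageResult] = []
    trajs: list[SignalingTrajectory] = []
    n_failed = 0
    for i in range(n_founders):
        rng = np.random.default_rng(streams[i])
        params = sample_parameters(base_params, heterogeneity, rng)
        try:
            rest, _ = find_cell_rest(params, initial=base_rest.copy(),
                                     max_time=400.0)
            traj = simulate_cell_signaling(params, protocol, horizon=horizon,
                                           rest=rest)
            lin = simulate_lineage(traj, params.cellcycle, horizon=horizon,
                                   enabled=protocol.toggles.cellcycle,
                                   max_divisions=max_divisions)
        except RuntimeError as err:
            n_failed += 1
            warnings.warn(f"founder {i} excluded (solver failure: {err})",
                          stacklevel=2)
            continue
        lineages.append(lin)
        if store_trajectories:
            trajs.append(traj)

    if n_failed > max_failure_fraction * n_founders:
        raise RuntimeError(f"{n_failed}/{n_founders} founders failed to integrate")

    max_gen = max_divisions
    counts = np.zeros((len(output_times), max_gen + 1))
    for lin in lineages:
        for j, t in enumerate(output_times):
            g = lin.generation_at(t)
            if g is not None:
                counts[j, min(g, max_gen)] += 2 ** g
    return PopulationTrace(times=output_times, counts=counts,
                           n_founders=n_founders, lineages=lineages,
                           trajectories=trajs if store_trajectories else None,
                           n_failed=n_failed, seed=seed)


_READOUTS = {
    "RelA": lambda tr: tr.rela_fold,
    "cRel": lambda tr: tr.crel_fold,
    "BclxL": lambda tr: tr.bclxl,
    "C8": lambda tr: tr.caspase8,
}


def population_nfkb_summary(trace: PopulationTrace, readout: str,
                            times: Sequence[float],
                            live_only: bool = False) -> pd.DataFrame:
    """Cross-cell mean and sample SD of a signaling readout.

    With ``live_only`` a lineage stops contributing after its death time;
    otherwise every founder trajectory contributes at all times.  Lineages
    contribute with weight 1 (per founder).  Times with an empty live set
    yield NaN.
    """
    if trace.trajectories is None:
        raise ValueError("trace was run without stored trajectories")
    if readout not in _READOUTS:
        raise ValueError(f"unknown readout {readout!r}")
    times = np.asarray(times, dtype=float)
    rows = []
    for t in times:
        vals = []
        for traj, lin in zip(trace.trajectories, trace.lineages):
            if live_only and lin.death_time is not None and t >= lin.death_time:
                continue
            v = np.interp(t, traj.times, _READOUTS[readout](traj))
            vals.append(v)
        if vals:
            arr = np.asarray(vals)
            sd = arr.std(ddof=1) if len(arr) > 1 else 0.0
            rows.append((t, arr.mean(), sd, len(arr)))
        else:
            rows.append((t, np.nan, np.nan, 0))
    return pd.DataFrame(rows, columns=["time_h", "mean", "sd", "n"])


def population_fold_changes(cd40_nM: float, bcr_nM: float,
                            times: Sequence[float],
                            nfkb_params: nf.NfkbParams | None = None,
                            base_params: CellParams | None = None,
                            n_cells: int = 100, seed: int = 0,
                            cv: float = 0.112,
                            horizon: float | None = None) -> dict[str, np.ndarray]:
    """Population-mean nuclear RelA/cRel fold-changes (signaling-only runs).

    Each cell's fold-change is relative to its own resting nuclear level.
    """
    base = (base_params or CellParams()).copy()
    if nfkb_params is not None:
        base.nfkb = nfkb_params.copy()
    proto = constant_stimulation(bcr_nM=bcr_nM, cd40_nM=cd40_nM)
    proto.toggles.apoptosis = False
    proto.toggles.cellcycle = False
    times = np.asarray(times, dtype=float)
    h = horizon if horizon is not None else max(float(times.max()), 1.0)
    trace = simulate_population(n_cells, proto, base_params=base,
                                heterogeneity=HeterogeneityConfig(cv=cv),
                                seed=seed, horizon=h,
                                output_times=[0.0, h])
    rela = population_nfkb_summary(trace, "RelA", times)["mean"].to_numpy()
    crel = population_nfkb_summary(trace, "cRel", times)["mean"].to_numpy()
    return {"RelA": rela, "cRel": crel}
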