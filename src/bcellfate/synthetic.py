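"""Synthetic experiment-shaped datasets with known ground truth.

Generates the two data shapes the evaluation and calibration stages
consume, without requiring any real measurements:

* dye-dilution generation tables -- live-cell counts per timepoint and
  generation, produced by a Cyton-style stochastic division/death race:
  a fraction ``f0`` of founders divide, with the time to first division
  and subsequent inter-division times drawn from truncated normals, all
  cells subject to an exponential death hazard (first event wins);
* immunoblot-style fold-change series -- log-normal multiplicative noise
  around anchor means at the experimental timepoints {0, 7, 24, 48} h.

Presets for the six stimulation conditions ship with the measured
proliferation statistics (Tdiv0, Tdiv1+, F0) as generator parameters where
those were quantified; dispersions and death hazards are generator choices
documented in the preset registry.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .rmsd import DEFAULT_TIMEPOINTS, GenerationTable

__all__ = [
    "CytonParams",
    "simulate_cyton_events",
    "tabulate_events",
    "generate_dye_dilution",
    "generate_foldchange_series",
    "CYTON_PRESETS",
]


@dataclass
class CytonParams:
    """Division/death program of a simulated dye-dilution experiment.

    Times are hours since stimulation onset; ``f0`` is the fraction of
    founders that respond by dividing; ``death_hazard`` is the exponential
    death rate applied to every cell.
    """

    tdiv0_mean: float = 68.5
    tdiv0_sd: float = 10.0
    tdiv1_mean: float = 6.1
    tdiv1_sd: float = 1.0
    f0: float = 0.468
    death_hazard: float = 0.01
    generation_cap: int = 6
    n_founders: int = 1000
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS

    def __post_init__(self) -> None:
        if not 0.0 <= self.f0 <= 1.0:
            raise ValueError("f0 must lie in [0, 1]")
        for name in ("tdiv0_mean", "tdiv0_sd", "tdiv1_mean", "tdiv1_sd",
                     "death_hazard"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _load_preset_registry() -> dict[str, CytonParams]:
    """Load the versioned preset registry shipped with the package."""
    import importlib.resources as res

    import yaml

    text = (res.files("bcellfate") / "data" / "cyton_presets.yaml").read_text()
    reg = yaml.safe_load(text)
    out = {}
    for name, d in reg["presets"].items():
        d = dict(d)
        d["timepoints"] = tuple(d["timepoints"])
        out[name] = CytonParams(**d)
    return out


#: Generator presets for the experimental conditions, loaded from the
#: versioned registry (data/cyton_presets.yaml).  Tdiv0/Tdiv1+/F0 are the
#: dye-dilution-derived estimates per stimulation condition; dispersions
#: and death hazards are generator defaults chosen for realistic count
#: scales.
CYTON_PRESETS: dict[str, CytonParams] = _load_preset_registry()


def _truncated_positive_normal(rng: np.random.Generator, mean: float,
                               sd: float) -> float:
    if sd == 0:
        return max(mean, 0.0)
    while True:
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)


def simulate_cyton_events(params: CytonParams, seed: int = 0) -> list[tuple]:
    """Seeded event stream of the division/death race.

    Returns one row per cell: (founder, generation, birth_h, end_h, fate)
    with fate in {"division", "death", "censored"}; a "division" row ends
    at the moment the cell splits into two generation+1 cells.
    """
    rng = np.random.default_rng(seed)
    tp = np.asarray(params.timepoints, dtype=float)
    horizon = float(tp.max())
    cap = params.generation_cap
    rows: list[tuple] = []
    for f in range(params.n_founders):
        divides = rng.random() < params.f0
        # the lineage division schedule: generation g is born at birth[g]
        birth = [0.0]
        if divides:
            t = _truncated_positive_normal(rng, params.tdiv0_mean,
                                           params.tdiv0_sd)
            while t <= horizon and len(birth) <= cap:
                birth.append(t)
                t += _truncated_positive_normal(rng, params.tdiv1_mean,
                                                params.tdiv1_sd)
        n_alive = 1
        for g, b in enumerate(birth):
            end = birth[g + 1] if g + 1 < len(birth) else None
            survivors = 0
            for _cell in range(n_alive):
                t_death = (b + rng.exponential(1.0 / params.death_hazard)
                           if params.death_hazard > 0 else np.inf)
                if end is not None and t_death > end:
                    rows.append((f, g, b, end, "division"))
                    survivors += 1
                elif t_death <= horizon and (end is None or t_death <= end):
                    rows.append((f, g, b, float(t_death), "death"))
                else:
                    rows.append((f, g, b, horizon, "censored"))
            n_alive = survivors * 2
            if n_alive == 0:
                break
    return rows


def tabulate_events(rows: Sequence[tuple], params: CytonParams,
                    label: str = "") -> GenerationTable:
    """Bin an event stream into a timepoint x generation count table.

    A cell is counted at timepoint t if birth <= t < end, or t == end for
    a censored cell (alive through the horizon).
    """
    tp = np.asarray(params.timepoints, dtype=float)
    cap = params.generation_cap
    counts = np.zeros((len(tp), cap + 1))
    for _f, g, b, end, fate in rows:
        sel = (tp >= b) & ((tp < end) | ((tp == end) & (fate == "censored")))
        counts[sel, min(g, cap)] += 1
    return GenerationTable(tp, counts, label=label)


def generate_dye_dilution(params: CytonParams, seed: int = 0,
                          label: str = "") -> GenerationTable:
    """Simulate one dye-dilution experiment and tabulate live counts.

    Per founder: with probability ``f0`` the cell schedules its first
    division at Tdiv0 ~ N+(tdiv0_mean, tdiv0_sd) and subsequent divisions
    at N+(tdiv1_mean, tdiv1_sd) intervals up to the generation cap; every
    cell independently draws an exponential death time (first event wins).
    """
    return tabulate_events(simulate_cyton_events(params, seed), params,
                           label=label)


def generate_foldchange_series(anchors: Sequence[tuple[float, float]],
                               noise_cv: float = 0.2,
                               n_replicates: int = 3,
                               seed: int = 0) -> "np.ndarray":
    """Replicate-resolved fold-change series around anchor means.

    ``anchors`` is a list of (time_h, mean_fold) pairs and must include
    t = 0 with fold 1 (the normalization point).  Noise is multiplicative
    log-normal with coefficient of variation ``noise_cv``; the t = 0 point
    is exactly 1 in every replicate by construction.

    Returns a structured array-like pandas DataFrame
    (time_h, replicate, fold).
    """
    import pandas as pd

    anchors = sorted(anchors)
    if not anchors or anchors[0][0] != 0 or anchors[0][1] != 1.0:
        raise ValueError("anchors must include (0, 1.0)")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    rows = []
    for rep in range(n_replicates):
        for t, mean in anchors:
            if t == 0:
                fold = 1.0
            else:
                # median-preserving log-normal noise around the anchor
                fold = mean * rng.lognormal(-sigma ** 2 / 2, sigma)
            rows.append((t, rep, fold))
    return pd.DataFrame(rows, columns=["time_h", "replicate", "fold"])
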