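"""Goodness-of-fit metrics between generation-resolved cell-count datasets.

Two scores compare a pair of timepoint x generation live-cell count tables
(the common currency of dye-dilution experiments and model simulations) on
the standard grid {0, 24, 36, 48, 72, 96} h, generations 0..6 ("6+" top
bin):

* :func:`rmsd_generation` -- root of the summed squared differences of the
  generation-composition fractions n_ij / N_i over the five post-onset
  timepoints (root-sum-square, no division by the number of terms);
* :func:`rmsd_population` -- population-expansion score composed of two
  root terms over expansion-ratio deviations, one normalized to the 0 h
  population and one to the 24 h population (robust to early mechanical
  cell loss), each divided inside the root by (number of timepoints x the
  maximum expansion ratio).

Both metrics are invariant to uniform scaling of either table's counts.
The ``total`` score is their sum.

The normalization of the expansion score follows the expansion-ratio
reading of the max term (the default): dividing by a maximum raw cell
count would make the score collapse toward zero for experiment-sized
populations (N ~ 1e4), incompatible with the 0.3-1.6 score range this
metric is designed to resolve.  The raw-count reading remains available
via ``max_mode="count"``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GenerationTable",
    "rmsd_generation",
    "rmsd_population",
    "rmsd_total",
    "rmsd_matrix",
]

DEFAULT_TIMEPOINTS: tuple[float, ...] = (0.0, 24.0, 36.0, 48.0, 72.0, 96.0)


@dataclass
class GenerationTable:
    """Timepoint x generation live-cell counts.

    ``counts[i, j]`` is the number of live cells in generation ``j`` at
    ``timepoints[i]``; the last generation column is the open top bin
    (generation cap and above, conventionally "6+").
    """

    timepoints: np.ndarray
    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != len(self.timepoints):
            raise ValueError("counts must be (n_timepoints, n_generations)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n_generations(self) -> int:
        return self.counts.shape[1]

    def fractions(self) -> np.ndarray:
        tot = self.totals
        if np.any(tot <= 0):
            raise ValueError("zero total live count at an evaluated timepoint")
        return self.counts / tot[:, None]

    def total_at(self, t: float) -> float:
        idx = np.nonzero(np.isclose(self.timepoints, t))[0]
        if idx.size == 0:
            raise ValueError(f"timepoint {t} h not present")
        return float(self.totals[idx[0]])

    # -- CSV dialect: header `time_h,gen0,...,genG`, one row per timepoint --

    def to_csv(self, path_or_buf) -> None:
        gen_cols = ",".join(f"gen{j}" for j in range(self.n_generations))
        lines = [f"time_h,{gen_cols}"]
        for t, row in zip(self.timepoints, self.counts):
            lines.append(f"{t:g}," + ",".join(f"{v:.10g}" for v in row))
        text = "\n".join(lines) + "\n"
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_csv(cls, path_or_buf, label: str = "") -> "GenerationTable":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        header = lines[0].split(",")
        if header[0] != "time_h" or not all(h.startswith("gen") for h in header[1:]):
            raise ValueError("expected header 'time_h,gen0,gen1,...'")
        rows = [ln.split(",") for ln in lines[1:]]
        times = [float(r[0]) for r in rows]
        counts = [[float(v) for v in r[1:]] for r in rows]
        return cls(np.array(times), np.array(counts), label=label)


def _check_axes(exp: GenerationTable, sim: GenerationTable) -> None:
    if exp.counts.shape != sim.counts.shape or not np.allclose(
            exp.timepoints, sim.timepoints):
        raise ValueError("tables must share timepoint and generation axes")


def _post_onset(table: GenerationTable) -> np.ndarray:
    """Indices of the evaluated timepoints (everything after t = 0)."""
    idx = np.nonzero(table.timepoints > 0)[0]
    if idx.size == 0:
        raise ValueError("no post-onset timepoints to evaluate")
    return idx


def rmsd_generation(exp: GenerationTable, sim: GenerationTable) -> float:
    """Generation-composition deviation score.

    sqrt( sum_i sum_j (n_ij/N_i - m_ij/M_i)^2 ) over post-onset timepoints
    i and all generation bins j.
    """
    _check_axes(exp, sim)
    idx = _post_onset(exp)
    fe = exp.fractions()[idx]
    fs = sim.fractions()[idx]
    return float(np.sqrt(np.sum((fe - fs) ** 2)))


def rmsd_population(exp: GenerationTable, sim: GenerationTable,
                    max_mode: str = "ratio") -> float:
    """Population-expansion deviation score (two-baseline form).

    Term A compares expansion ratios N_t/N_0 over the post-onset
    timepoints; term B compares N_t/N_24 over the timepoints after 24 h.
    Each term is sqrt( sum (r - r_hat)^2 / (n_timepoints * max r) ), with
    ``max r`` the maximum experimental expansion ratio of that term
    (``max_mode="count"`` selects the raw-count maximum instead).
    """
    _check_axes(exp, sim)
    if max_mode not in ("ratio", "count"):
        raise ValueError("max_mode must be 'ratio' or 'count'")
    te = exp.timepoints

    def term(baseline_t: float, idx: np.ndarray) -> float:
        n0e = exp.total_at(baseline_t)
        n0s = sim.total_at(baseline_t)
        if n0e <= 0 or n0s <= 0:
            raise ValueError("zero population at the normalization timepoint")
        re = exp.totals[idx] / n0e
        rs = sim.totals[idx] / n0s
        denom_max = re.max() if max_mode == "ratio" else exp.totals[idx].max()
        return float(np.sqrt(np.sum((re - rs) ** 2) / (len(idx) * denom_max)))

    idx_a = _post_onset(exp)
    idx_b = np.nonzero(te > 24.0)[0]
    if not np.any(np.isclose(te, 24.0)):
        raise ValueError("the 24 h timepoint is required for the second term")
    if idx_b.size == 0:
        raise ValueError("no timepoints after 24 h")
    return term(0.0, idx_a) + term(24.0, idx_b)


def rmsd_total(exp: GenerationTable, sim: GenerationTable,
               max_mode: str = "ratio") -> float:
    """Total score: generation composition + population expansion."""
    return rmsd_generation(exp, sim) + rmsd_population(exp, sim, max_mode=max_mode)


def rmsd_matrix(datasets_exp: Sequence[GenerationTable],
                datasets_sim: Sequence[GenerationTable],
                max_mode: str = "ratio") -> np.ndarray:
    """Full cross matrix of total RMSD scores.

    Entry (i, j) compares experimental dataset i against simulated dataset
    j; the diagonal holds the condition-matched pairs.
    """
    if not datasets_exp or not datasets_sim:
        raise ValueError("dataset lists must be non-empty")
    out = np.empty((len(datasets_exp), len(datasets_sim)))
    for i, e in enumerate(datasets_exp):
        for j, s in enumerate(datasets_sim):
            out[i, j] = rmsd_total(e, s, max_mode=max_mode)
    return out
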