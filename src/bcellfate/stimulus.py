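"""Stimulation protocols: piecewise-constant ligand schedules.

A protocol is a list of ligand pulses -- (dose in nM, onset in h, optional
offset in h) -- for the two model inputs, ANTIGEN (the alpha-BCR stimulus)
and CD40L (the alpha-CD40 stimulus), plus toggles that enable or disable
model modules for a run (NF-kB layer, apoptosis, cell cycle, and the
BCR-engagement-driven caspase-8 term).

At a pulse onset the dose is added to the free-ligand species; at the
offset the free ligand is set to zero, modeling an experimental washout
rather than passive decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ProtocolError(ValueError):
    """Invalid dose or timing in a stimulation protocol."""


@dataclass(frozen=True)
class LigandPulse:
    dose_nM: float
    onset_h: float
    offset_h: float | None = None  # None = open-ended


@dataclass
class ModuleToggles:
    nfkb: bool = True
    apoptosis: bool = True
    cellcycle: bool = True
    aicd: bool = True


@dataclass
class StimulationProtocol:
    """Ligand schedules for ANTIGEN (alpha-BCR) and CD40L (alpha-CD40)."""

    antigen: list[LigandPulse] = field(default_factory=list)
    cd40l: list[LigandPulse] = field(default_factory=list)
    toggles: ModuleToggles = field(default_factory=ModuleToggles)

    def validate(self) -> None:
        for name, pulses in (("ANTIGEN", self.antigen), ("CD40L", self.cd40l)):
            for p in pulses:
                if p.dose_nM < 0:
                    raise ProtocolError(f"negative {name} dose {p.dose_nM!r}")
                if p.onset_h < 0:
                    raise ProtocolError(f"negative onset {p.onset_h!r}")
                if p.offset_h is not None and p.offset_h <= p.onset_h:
                    raise ProtocolError("offset must be after onset")

    def is_empty(self) -> bool:
        return not any(p.dose_nM > 0 for p in self.antigen + self.cd40l)

    def horizon(self, default: float = 96.0) -> float:
        """Latest protocol event time, or ``default`` if larger."""
        t = [default]
        for p in self.antigen + self.cd40l:
            t.append(p.onset_h)
            if p.offset_h is not None:
                t.append(p.offset_h)
        return max(t)

    def ligand_events(self, t_end: float) -> list[tuple[float, list[tuple[str, str, float]]]]:
        """Time-sorted ligand actions within [0, t_end].

        Returns ``[(time, [(species, 'add'|'wash', dose), ...]), ...]``.
        """
        raw: list[tuple[float, str, str, float]] = []
        for species, pulses in (("ANTIGEN", self.antigen), ("CD40L", self.cd40l)):
            for p in pulses:
                if p.onset_h <= t_end:
                    raw.append((p.onset_h, species, "add", p.dose_nM))
                if p.offset_h is not None and p.offset_h <= t_end:
                    raw.append((p.offset_h, species, "wash", 0.0))
        raw.sort(key=lambda r: r[0])
        grouped: list[tuple[float, list[tuple[str, str, float]]]] = []
        for t, species, mode, dose in raw:
            if grouped and grouped[-1][0] == t:
                grouped[-1][1].append((species, mode, dose))
            else:
                grouped.append((t, [(species, mode, dose)]))
        return grouped


def constant_stimulation(bcr_nM: float = 0.0, cd40_nM: float = 0.0,
                         onset_h: float = 0.0) -> StimulationProtocol:
    """Open-ended co-addition of both ligands at ``onset_h``."""
    proto = StimulationProtocol()
    if bcr_nM > 0:
        proto.antigen.append(LigandPulse(bcr_nM, onset_h))
    if cd40_nM > 0:
        proto.cd40l.append(LigandPulse(cd40_nM, onset_h))
    proto.validate()
    return proto
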