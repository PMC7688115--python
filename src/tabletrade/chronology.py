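"""Dated schedule of tableware availability on the eastern Mediterranean market.

The five wares under study (ESA, ESB, ESC, ESD, ITS) each have a dated window
of market availability, conventionally expressed as a sequence of phases
partitioning 200 BC -- AD 300.  Calendar years use astronomical numbering:
200 BC is encoded as -200 and no special role is given to a year zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

WARES: tuple[str, ...] = ("ESA", "ESB", "ESC", "ESD", "ITS")

STUDY_START = -200
STUDY_END = 300


@dataclass(frozen=True)
class Phase:
    """A contiguous span of calendar years with a fixed set of marketed wares."""

    year_from: int
    year_to: int
    wares: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.year_from > self.year_to:
            raise ValueError(f"phase runs backwards: {self.year_from}..{self.year_to}")
        unknown = set(self.wares) - set(WARES)
        if unknown:
            raise ValueError(f"unknown wares in phase: {sorted(unknown)}")


@dataclass(frozen=True)
class Chronology:
    """An ordered sequence of phases partitioning the study period.

    Phases must tile ``[STUDY_START, STUDY_END]`` inclusively without gaps or
    overlaps; consecutive phases meet at ``year_to + 1 == year_from``.
    """

    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("chronology needs at least one phase")
        if self.phases[0].year_from != STUDY_START:
            raise ValueError("chronology must start at %d" % STUDY_START)
        if self.phases[-1].year_to != STUDY_END:
            raise ValueError("chronology must end at %d" % STUDY_END)
        for a, b in zip(self.phases, self.phases[1:]):
            if b.year_from != a.year_to + 1:
                raise ValueError(
                    f"phases not contiguous: ..{a.year_to} then {b.year_from}.."
                )

    def wares_at(self, year: float) -> tuple[str, ...]:
        """Active wares for a (possibly fractional) calendar year.

        Fractional years fall in the phase whose inclusive integer range
        contains ``floor(year)``; the final year of the study belongs to the
        last phase.
        """
        for ph in self.phases:
            if ph.year_from <= year < ph.year_to + 1:
                return ph.wares
        if year >= self.phases[-1].year_to + 1 - 1e-9:
            return self.phases[-1].wares
        raise ValueError(f"year {year} outside the chronology")

    @property
    def all_wares(self) -> tuple[str, ...]:
        present = {w for ph in self.phases for w in ph.wares}
        return tuple(w for w in WARES if w in present)

    def ware_window(self, ware: str) -> tuple[int, int]:
        """Overall availability window (first and last year) of one ware."""
        spans = [(p.year_from, p.year_to) for p in self.phases if ware in p.wares]
        if not spans:
            raise ValueError(f"{ware!r} never active in this chronology")
        return min(s[0] for s in spans), max(s[1] for s in spans)


#: The six conventional phases of ware availability, 200 BC -- AD 300.
DEFAULT_PHASES: tuple[Phase, ...] = (
    Phase(-200, -101, ("ESA", "ESC")),
    Phase(-100, -41, ("ESA", "ESC", "ESD")),
    Phase(-40, -28, ("ESA", "ESC", "ESD", "ITS")),
    Phase(-27, 149, ("ESA", "ESB", "ESC", "ESD", "ITS")),
    Phase(150, 199, ("ESA", "ESC", "ESD")),
    Phase(200, 300, ("ESC", "ESD")),
)


def default_chronology(include_its: bool = True) -> Chronology:
    """The conventional availability schedule; optionally with ITS removed.

    ``include_its=False`` supports the sensitivity run that asks whether the
    western import drives the inference; phases that become identical to their
    neighbour after dropping ITS are merged.
    """
    if include_its:
        return Chronology(DEFAULT_PHASES)
    phases: list[Phase] = []
    for ph in DEFAULT_PHASES:
        wares = tuple(w for w in ph.wares if w != "ITS")
        if phases and phases[-1].wares == wares:
            prev = phases.pop()
            phases.append(Phase(prev.year_from, ph.year_to, wares))
        else:
            phases.append(Phase(ph.year_from, ph.year_to, wares))
    return Chronology(tuple(phases))


def phase_boundaries(chronology: Chronology) -> list[int]:
    """Start years of each phase, ascending (useful for searchsorted)."""
    return [p.year_from for p in chronology.phases]


def windows(chronology: Chronology, wares: Iterable[str] | None = None) -> dict[str, tuple[int, int]]:
    """Availability windows for each ware in the chronology."""
    wares = tuple(wares) if wares is not None else chronology.all_wares
    return {w: chronology.ware_window(w) for w in wares}
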