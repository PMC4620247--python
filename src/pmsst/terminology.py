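"""Fixture-scale terminology server.

Concept lookup, case-insensitive type-ahead (prefix) search on displays, and
symmetric cross-code-system concept mapping.  The shipped fixtures hold a
small MedDRA preferred-term subset (the adverse-event codes the use-case
schema binds), a matching toy ICD-9-CM subset (the warehouse coding of the
same conditions), a local observation-code list and sex codes.  Mapping is
deliberately single-hop: multi-hop terminology chaining silently broadens
clinical meaning, whereas a direct MedDRA↔ICD-9-CM crosswalk keeps the
value-matching semantics auditable.  One-to-many maps are allowed and every
mapped target counts as a match.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

from .errors import NotFoundError


@dataclass(frozen=True)
class Concept:
    code: str
    display: str


@dataclass
class CodeSystem:
    id: str
    concepts: dict[str, Concept] = field(default_factory=dict)


class TerminologyServer:
    """In-memory concept store plus concept map."""

    def __init__(self) -> None:
        self.systems: dict[str, CodeSystem] = {}
        # canonicalized (system_a, code_a, system_b, code_b) with a <= b
        self._pairs: set[tuple[str, str, str, str]] = set()

    # -- loading ---------------------------------------------------------

    def add_system(self, system_id: str) -> CodeSystem:
        return self.systems.setdefault(system_id, CodeSystem(id=system_id))

    def add_concept(self, system_id: str, code: str, display: str) -> None:
        if not code:
            raise ValueError("concept code must be nonempty")
        system = self.add_system(system_id)
        if code in system.concepts:
            raise ValueError(f"duplicate code {code!r} in {system_id}")
        system.concepts[code] = Concept(code=code, display=display)

    def add_mapping(
        self, system_a: str, code_a: str, system_b: str, code_b: str
    ) -> None:
        key = tuple(sorted([(system_a, code_a), (system_b, code_b)]))
        self._pairs.add((key[0][0], key[0][1], key[1][0], key[1][1]))

    def load_concepts_csv(self, source: str | Path | IO[str]) -> None:
        """Rows ``system,code,display`` (header optional)."""
        for row in _read_csv(source, 3, header=("system", "code", "display")):
            self.add_concept(*row)

    def load_map_csv(self, source: str | Path | IO[str]) -> None:
        """Rows ``system_a,code_a,system_b,code_b`` (header optional)."""
        for row in _read_csv(
            source, 4, header=("system_a", "code_a", "system_b", "code_b")
        ):
            self.add_mapping(*row)

    # -- queries ---------------------------------------------------------

    def _system(self, system_id: str) -> CodeSystem:
        try:
            return self.systems[system_id]
        except KeyError:
            raise NotFoundError(f"unknown code system: {system_id}") from None

    def lookup(self, system_id: str, code: str) -> Concept:
        system = self._system(system_id)
        try:
            return system.concepts[code]
        except KeyError:
            raise NotFoundError(
                f"unknown code {code!r} in system {system_id}"
            ) from None

    def search(self, prefix: str, system_id: str) -> list[Concept]:
        """Type-ahead: case-insensitive prefix match on concept displays,
        alphabetical by display (then code, for stability)."""
        needle = prefix.lower()
        hits = [
            c
            for c in self._system(system_id).concepts.values()
            if c.display.lower().startswith(needle)
        ]
        return sorted(hits, key=lambda c: (c.display, c.code))

    def map_code(
        self, code: str, from_system: str, to_system: str
    ) -> list[str]:
        """All codes in ``to_system`` mapped to ``(from_system, code)``;
        symmetric by construction."""
        out = set()
        for sa, ca, sb, cb in self._pairs:
            if (sa, ca) == (from_system, code) and sb == to_system:
                out.add(cb)
            if (sb, cb) == (from_system, code) and sa == to_system:
                out.add(ca)
        return sorted(out)

    def codes_match(
        self, code_a: str, system_a: str, code_b: str, system_b: str
    ) -> bool:
        """True iff the codes are identical within one system, or a concept-
        map pair links them directly (single hop)."""
        if system_a == system_b and code_a == code_b:
            return True
        return code_b in self.map_code(code_a, system_a, system_b)


def _read_csv(source, width: int, header: tuple[str, ...]):
    if isinstance(source, (str, Path)):
        fh: IO[str] = open(source, newline="", encoding="utf-8")
        close = True
    else:
        fh, close = source, False
    try:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            if tuple(c.strip().lower() for c in row) == header:
                continue
            if len(row) != width:
                raise ValueError(f"expected {width} columns, got {row!r}")
            yield tuple(c.strip() for c in row)
    finally:
        if close:
            fh.close()


def load_terminology(
    concepts_csv: str | Path, map_csv: str | Path, extra_systems: tuple[str, ...] = ("NCI",)
) -> TerminologyServer:
    """Build a server from the two fixture CSVs.  ``extra_systems`` registers
    code systems that exist but ship no concepts (NCI by default)."""
    server = TerminologyServer()
    for system_id in extra_systems:
        server.add_system(system_id)
    server.load_concepts_csv(concepts_csv)
    server.load_map_csv(map_csv)
    return server
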