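"""Plain-text CRS format: read/write catalytic reaction systems.

The format is line oriented and round-trippable::

    # optional comments
    food: 1,2,3
    r1: 1+1 -> 4 [cats: 5]
    r2: 4 -> 5 [cats:]

One header line names the food species (which must be 1..M0), then one
line per reaction: id, ``+``-joined reactants (repeats allowed), single
product, and a possibly empty catalyst list.  Blank lines and ``#``
comments are ignored.  The writer emits reactions in id order with
reactants and catalysts sorted, so write -> read -> write is
byte-identical.
"""

from __future__ import annotations

import re
from os import PathLike
from typing import IO, Iterable, Union

from .crs import CatalyticReactionSystem, CRSError, Reaction

__all__ = ["read_crs", "write_crs", "parse_crs", "format_crs"]

_FOOD_RE = re.compile(r"^food:\s*(?P<ids>\d+(?:\s*,\s*\d+)*)\s*$")
_REACTION_RE = re.compile(
    r"^r(?P<id>\d+):\s*"
    r"(?P<reactants>\d+(?:\s*\+\s*\d+)*)\s*->\s*(?P<product>\d+)\s*"
    r"\[cats:\s*(?P<cats>\d+(?:\s*,\s*\d+)*)?\]\s*$"
)


class CRSParseError(CRSError):
    """Malformed CRS text; the message names the offending line."""


def parse_crs(text: str) -> CatalyticReactionSystem:
    """Parse CRS text into a validated system."""
    food: frozenset[int] | None = None
    reactions: list[Reaction] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("food:"):
            if food is not None:
                raise CRSParseError(f"line {lineno}: duplicate food header")
            m = _FOOD_RE.match(line)
            if m is None:
                raise CRSParseError(f"line {lineno}: malformed food header: {line!r}")
            food = frozenset(int(s) for s in m.group("ids").split(","))
            continue
        m = _REACTION_RE.match(line)
        if m is None:
            raise CRSParseError(f"line {lineno}: malformed reaction line: {line!r}")
        if food is None:
            raise CRSParseError(f"line {lineno}: reaction before food header")
        cats = m.group("cats")
        reactions.append(
            Reaction(
                id=int(m.group("id")),
                reactants=tuple(
                    sorted(int(s) for s in re.split(r"\s*\+\s*", m.group("reactants")))
                ),
                product=int(m.group("product")),
                catalysts=frozenset(
                    int(s) for s in re.split(r"\s*,\s*", cats)
                )
                if cats
                else frozenset(),
            )
        )
    if food is None:
        raise CRSParseError("no food header found")
    return CatalyticReactionSystem(food=food, reactions=tuple(reactions))


def format_crs(system: CatalyticReactionSystem) -> str:
    """Render a system in canonical CRS text (reactions in id order)."""
    lines = ["food: " + ",".join(str(s) for s in sorted(system.food))]
    for r in system.reactions:
        reactants = "+".join(str(s) for s in sorted(r.reactants))
        cats = ",".join(str(s) for s in sorted(r.catalysts))
        cats_field = f"[cats: {cats}]" if cats else "[cats:]"
        lines.append(f"r{r.id}: {reactants} -> {r.product} {cats_field}")
    return "\n".join(lines) + "\n"


def read_crs(path_or_file: Union[str, PathLike, IO[str]]) -> CatalyticReactionSystem:
    if hasattr(path_or_file, "read"):
        return parse_crs(path_or_file.read())
    with open(path_or_file, "r", encoding="utf-8") as fh:
        return parse_crs(fh.read())


def write_crs(
    system: CatalyticReactionSystem, path_or_file: Union[str, PathLike, IO[str]]
) -> None:
    text = format_crs(system)
    if hasattr(path_or_file, "write"):
        path_or_file.write(text)
        return
    with open(path_or_file, "w", encoding="utf-8") as fh:
        fh.write(text)
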