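"""Gene sets, gene-set collections and GMT serialisation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers with an explicit universe tag."""

    name: str
    members: frozenset[str]
    universe_tag: str = "measured"
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))

    def intersect(self, universe: Iterable[str]) -> frozenset[str]:
        return self.members & frozenset(universe)


@dataclass
class GeneSetCollection:
    """An ordered collection of named gene sets (e.g. one GMT file)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def read_gmt(path: str | Path, universe_tag: str = "measured") -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB gene...) into a collection."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            sets.append(GeneSet(name, frozenset(genes), universe_tag, desc))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection | Iterable[GeneSet], path: str | Path) -> None:
    sets = collection.sets if isinstance(collection, GeneSetCollection) else list(collection)
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description or s.universe_tag, *sorted(s.members)]) + "\n")
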