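"""Geographic hierarchy: global → income group → continent → region → country.

Every country sits at the bottom of a five-level tree with exactly one
ancestor at each higher level.  Hierarchical parameter priors are composed
along this ancestor path (see :mod:`maternalsim.priors`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

LEVELS = ("global", "income_group", "continent", "region", "country")
LEVEL_INDEX = {name: i for i, name in enumerate(LEVELS)}


class HierarchyError(ValueError):
    """Raised when a node reference or tree structure is invalid."""


@dataclass(frozen=True)
class GeoNode:
    id: str
    level: str
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise HierarchyError(f"unknown level {self.level!r}")
        if self.level == "global" and self.parent is not None:
            raise HierarchyError("global node cannot have a parent")
        if self.level != "global" and self.parent is None:
            raise HierarchyError(f"node {self.id!r} at level {self.level} needs a parent")


@dataclass
class Hierarchy:
    """A validated five-level geography tree."""

    nodes: dict[str, GeoNode] = field(default_factory=dict)

    def add(self, node: GeoNode) -> None:
        if node.id in self.nodes:
            raise HierarchyError(f"duplicate node id {node.id!r}")
        if node.parent is not None:
            parent = self.nodes.get(node.parent)
            if parent is None:
                raise HierarchyError(f"parent {node.parent!r} of {node.id!r} not found")
            if LEVEL_INDEX[parent.level] != LEVEL_INDEX[node.level] - 1:
                raise HierarchyError(
                    f"{node.id!r} ({node.level}) cannot attach to {parent.id!r} ({parent.level})"
                )
        elif node.level != "global":
            raise HierarchyError("only the global node may be a root")
        else:
            if any(n.level == "global" for n in self.nodes.values()):
                raise HierarchyError("hierarchy already has a global root")
        self.nodes[node.id] = node

    def ancestor_path(self, country_id: str) -> list[str]:
        """Node ids from the global root down to ``country_id`` (5 entries)."""
        node = self.nodes.get(country_id)
        if node is None or node.level != "country":
            raise HierarchyError(f"{country_id!r} is not a country in this hierarchy")
        path = [node.id]
        while node.parent is not None:
            node = self.nodes[node.parent]
            path.append(node.id)
        if len(path) != len(LEVELS):
            raise HierarchyError(f"broken ancestor chain for {country_id!r}")
        return list(reversed(path))

    @property
    def countries(self) -> list[str]:
        return sorted(n.id for n in self.nodes.values() if n.level == "country")

    def to_dict(self) -> list[dict]:
        return [
            {"id": n.id, "level": n.level, "parent": n.parent}
            for n in sorted(self.nodes.values(), key=lambda n: (LEVEL_INDEX[n.level], n.id))
        ]

    @classmethod
    def from_dict(cls, records: list[dict]) -> "Hierarchy":
        h = cls()
        for rec in records:
            h.add(GeoNode(rec["id"], rec["level"], rec.get("parent")))
        return h


def linear_hierarchy(country_ids: list[str], prefix: str = "syn") -> Hierarchy:
    """Build a minimal valid tree: one branch per country under shared uppers."""
    h = Hierarchy()
    h.add(GeoNode("GLOBAL", "global"))
    h.add(GeoNode(f"{prefix}-income", "income_group", "GLOBAL"))
    h.add(GeoNode(f"{prefix}-continent", "continent", f"{prefix}-income"))
    h.add(GeoNode(f"{prefix}-region", "region", f"{prefix}-continent"))
    for cid in country_ids:
        h.add(GeoNode(cid, "country", f"{prefix}-region"))
    return h
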