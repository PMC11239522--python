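"""Hierarchical brain-region ontology (structure graph) and atlas volume.

Mirrors the Allen CCF structure-graph conventions: every region has an
integer id (> 0; 0 is reserved for "outside atlas / unassigned"), an
acronym, a parent, a structure level (1..11, root = 1) and an RGB color.
White-matter (fiber-tract) and ventricle membership are explicit flags that
propagate to descendants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MAX_LEVELS = 11


@dataclass
class RegionNode:
    id: int
    acronym: str
    name: str
    parent_id: int | None
    level: int
    color: tuple[int, int, int]
    is_fiber_tract: bool = False
    is_ventricle: bool = False

    def __post_init__(self):
        if self.id <= 0:
            raise ValueError("region ids must be positive (0 is reserved)")
        if not 1 <= self.level <= MAX_LEVELS:
            raise ValueError(f"level must be in 1..{MAX_LEVELS}")


@dataclass
class Ontology:
    nodes: list[RegionNode]
    root_id: int = field(init=False)

    def __post_init__(self):
        self._by_id = {n.id: n for n in self.nodes}
        if len(self._by_id) != len(self.nodes):
            raise ValueError("duplicate region ids")
        roots = [n for n in self.nodes if n.parent_id is None]
        if len(roots) != 1:
            raise ValueError("ontology must have exactly one root")
        self.root_id = roots[0].id
        self._children: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id is not None:
                if n.parent_id not in self._by_id:
                    raise ValueError(f"dangling parent {n.parent_id}")
                self._children[n.parent_id].append(n.id)
        self._check_tree()
        # propagate flags down the tree
        for nid in self.preorder():
            n = self._by_id[nid]
            if n.parent_id is not None:
                p = self._by_id[n.parent_id]
                n.is_fiber_tract = n.is_fiber_tract or p.is_fiber_tract
                n.is_ventricle = n.is_ventricle or p.is_ventricle

    def _check_tree(self) -> None:
        seen = set()
        for nid in self.preorder():
            if nid in seen:
                raise ValueError("parent links do not form a tree")
            seen.add(nid)
            n = self._by_id[nid]
            if n.parent_id is not None:
                if n.level != self._by_id[n.parent_id].level + 1:
                    raise ValueError(
                        f"region {nid}: level must be parent level + 1"
                    )
            elif n.level != 1:
                raise ValueError("root must be level 1")
        if len(seen) != len(self.nodes):
            raise ValueError("ontology contains unreachable nodes")

    # ------------------------------------------------------------- traversal
    def __getitem__(self, nid: int) -> RegionNode:
        return self._by_id[nid]

    def __contains__(self, nid: int) -> bool:
        return nid in self._by_id

    def children(self, nid: int) -> list[int]:
        return list(self._children[nid])

    def preorder(self) -> list[int]:
        out, stack = [], [self.root_id]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(reversed(self._children[nid]))
        return out

    def leaves(self) -> list[int]:
        return [nid for nid in self.preorder() if not self._children[nid]]

    @property
    def max_level(self) -> int:
        return max(n.level for n in self.nodes)

    def ancestor_at_level(self, nid: int, level: int) -> int:
        """The unique ancestor of ``nid`` at ``level`` (or ``nid`` itself if
        its level is <= the requested level)."""
        n = self._by_id[nid]
        while n.level > level and n.parent_id is not None:
            n = self._by_id[n.parent_id]
        return n.id

    # --------------------------------------------------------------------- IO
    def to_json(self, path) -> None:
        recs = []
        for n in self.nodes:
            recs.append({
                "id": n.id,
                "acronym": n.acronym,
                "name": n.name,
                "parent_structure_id": n.parent_id,
                "st_level": n.level,
                "color_hex_triplet": "{:02X}{:02X}{:02X}".format(*n.color),
                "is_fiber_tract": n.is_fiber_tract,
                "is_ventricle": n.is_ventricle,
            })
        Path(path).write_text(json.dumps({"msg": recs}, indent=1))

    @classmethod
    def from_json(cls, path) -> "Ontology":
        data = json.loads(Path(path).read_text())
        recs = data["msg"] if isinstance(data, dict) else data
        nodes = []
        for r in recs:
            hexc = r["color_hex_triplet"]
            color = tuple(int(hexc[i:i + 2], 16) for i in (0, 2, 4))
            nodes.append(RegionNode(
                id=int(r["id"]),
                acronym=r["acronym"],
                name=r.get("name", r["acronym"]),
                parent_id=None if r["parent_structure_id"] is None
                else int(r["parent_structure_id"]),
                level=int(r["st_level"]),
                color=color,
                is_fiber_tract=bool(r.get("is_fiber_tract", False)),
                is_ventricle=bool(r.get("is_ventricle", False)),
            ))
        return cls(nodes)


@dataclass
class AtlasVolume:
    """Isotropic region-label grid plus its ontology.

    Every nonzero voxel carries a *leaf* region id; 0 is outside the atlas.
    """

    labels: np.ndarray  # (D, H, W) int32
    spacing_um: float
    ontology: Ontology

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int32)
        self.spacing_um = float(self.spacing_um)
        if self.spacing_um <= 0:
            raise ValueError("spacing must be positive")
        present = set(np.unique(self.labels)) - {0}
        leaves = set(self.ontology.leaves())
        if not present <= leaves:
            raise ValueError(f"non-leaf labels present: {sorted(present - leaves)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def region_volume_mm3(self, nid: int) -> float:
        """Physical volume of a region (leaf voxel count, descendants included)."""
        leaves = [l for l in self.ontology.leaves()
                  if self.ontology.ancestor_at_level(l, self.ontology[nid].level) == nid
                  or l == nid]
        count = int(np.isin(self.labels, leaves).sum())
        return count * (self.spacing_um * 1e-3) ** 3

    def leaf_voxel_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts) if i != 0}
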