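"""Region-of-interest atlas defining node identity and matrix order.

Every connectivity matrix in this package is indexed by an :class:`ROIAtlas`:
row/column *k* of a subject's matrix is node *k* of the atlas, and all
subjects in a cohort share the same atlas.  The default atlas is the 19-node
salience-network parcellation used throughout: 7 anterior nodes (dorsal
anterior cingulate, bilateral anterior insula, middle-frontal nodes) and 12
posterior nodes (supramarginal, posterior insula, precuneus, middle
cingulate, thalamus, cerebellar lobule VI).  MNI coordinates are carried for
the 17 nodes with published peak locations; the remaining two template nodes
have no coordinate and are flagged as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple

ANTERIOR = "anterior"
POSTERIOR = "posterior"


@dataclass(frozen=True)
class ROINode:
    """A single atlas node."""

    node_id: int
    label: str
    subnetwork: str  # "anterior" | "posterior"
    mni_xyz: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.subnetwork not in (ANTERIOR, POSTERIOR):
            raise ValueError(
                f"subnetwork must be '{ANTERIOR}' or '{POSTERIOR}', "
                f"got {self.subnetwork!r}"
            )
        if self.mni_xyz is not None:
            if len(self.mni_xyz) != 3 or not all(
                math.isfinite(v) for v in self.mni_xyz
            ):
                raise ValueError(f"mni_xyz must be a finite (x, y, z) triple")


@dataclass
class ROIAtlas:
    """Ordered node set shared by all matrices of an analysis.

    Node order is significant: it fixes matrix row/column order and the
    lexicographic (i, j) ordering used for edge tables.
    """

    nodes: Sequence[ROINode] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [n.label for n in self.nodes]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate node labels: {dupes}")
        for k, node in enumerate(self.nodes):
            if node.node_id != k:
                raise ValueError(
                    f"node_id {node.node_id} at position {k}: ids must be "
                    "0..n-1 in order"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def labels(self) -> list[str]:
        return [n.label for n in self.nodes]

    def index(self, label: str) -> int:
        for node in self.nodes:
            if node.label == label:
                return node.node_id
        raise KeyError(f"no node labelled {label!r}")

    def edge_label(self, i: int, j: int) -> str:
        i, j = min(i, j), max(i, j)
        return f"{self.nodes[i].label}--{self.nodes[j].label}"

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node_id\tlabel\tsubnetwork\tx\ty\tz\n")
            for n in self.nodes:
                if n.mni_xyz is None:
                    x = y = z = "NA"
                else:
                    x, y, z = (f"{v:g}" for v in n.mni_xyz)
                fh.write(f"{n.node_id}\t{n.label}\t{n.subnetwork}\t{x}\t{y}\t{z}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ROIAtlas":
        nodes = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["node_id", "label", "subnetwork", "x", "y", "z"]
            if header != expected:
                raise ValueError(f"atlas header {header} != {expected}")
            for line in fh:
                if not line.strip():
                    continue
                nid, label, sub, x, y, z = line.rstrip("\n").split("\t")
                xyz = None if x == "NA" else (float(x), float(y), float(z))
                nodes.append(ROINode(int(nid), label, sub, xyz))
        return cls(nodes)


def _n(label: str, sub: str, xyz=None) -> dict:
    return {"label": label, "subnetwork": sub, "mni_xyz": xyz}


# 19-node salience-network parcellation (anterior + posterior subdivisions).
# Coordinates are peak MNI mm for the 17 nodes with published locations; the
# medial-frontal and second right-cerebellar template nodes carry none.
_DEFAULT_NODES = [
    _n("Medial_frontal", ANTERIOR),
    _n("Frontal_mid_L", ANTERIOR, (-32.0, 46.0, 22.0)),
    _n("Frontal_mid_L2", ANTERIOR, (-40.0, 36.0, 32.0)),
    _n("Frontal_mid_R", ANTERIOR, (28.0, 46.0, 26.0)),
    _n("dACC", ANTERIOR, (0.0, 16.0, 46.0)),
    _n("Anterior_insula_L", ANTERIOR, (-40.0, 14.0, -4.0)),
    _n("Anterior_insula_R", ANTERIOR, (42.0, 14.0, -2.0)),
    _n("Supramarginal_L", POSTERIOR, (-58.0, -38.0, 36.0)),
    _n("Supramarginal_R", POSTERIOR, (62.0, -32.0, 42.0)),
    _n("Posterior_insula_L", POSTERIOR, (-36.0, -14.0, -6.0)),
    _n("Posterior_insula_R", POSTERIOR, (40.0, -6.0, -8.0)),
    _n("Precuneus_L", POSTERIOR, (-8.0, -52.0, 60.0)),
    _n("Cingulum_mid_R", POSTERIOR, (12.0, -28.0, 44.0)),
    _n("Thalamus_L", POSTERIOR, (-12.0, -22.0, 6.0)),
    _n("Thalamus_R", POSTERIOR, (12.0, -14.0, 10.0)),
    _n("Cerebellum_6_L", POSTERIOR, (-34.0, -56.0, -32.0)),
    _n("Cerebellum_6_R", POSTERIOR, (36.0, -42.0, -40.0)),
    _n("Cerebellum_6_L2", POSTERIOR, (-34.0, -42.0, -38.0)),
    _n("Cerebellum_6_R2", POSTERIOR),
]


def default_sn_atlas() -> ROIAtlas:
    """The default 19-node salience-network atlas (7 anterior, 12 posterior)."""
    return ROIAtlas(
        [ROINode(node_id=k, **spec) for k, spec in enumerate(_DEFAULT_NODES)]
    )
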