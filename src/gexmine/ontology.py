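"""Disease Ontology subtree membership (cancer filter).

The relevance filter for tumor-vs-normal expression databases keeps only
records whose disease lies in the cancer subtree of the Disease Ontology,
rooted at DOID:162. A synthetic miniature ontology slice ships with the
package so the filter is testable offline; point ``DOSubtree.from_obo`` at a
full DO release for production use.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import networkx as nx
import obonet

from .records import ExpressionRecord

CANCER_ROOT = "DOID:162"


class DOSubtree:
    """Transitive-closure membership test for an is_a subtree of the DO."""

    def __init__(self, graph: nx.MultiDiGraph, root: str = CANCER_ROOT):
        if root not in graph:
            raise ValueError(f"root {root} not present in ontology")
        # obonet edges point child -> parent, so subtree members are the
        # nodes from which the root is reachable
        self.root = root
        self.members: frozenset[str] = frozenset(nx.ancestors(graph, root)) | {root}

    @classmethod
    def from_obo(cls, path: str | Path | None = None, root: str = CANCER_ROOT) -> "DOSubtree":
        if path is None:
            path = Path(str(resources.files("gexmine").joinpath("data", "do_slim.synthetic.obo")))
        try:
            graph = obonet.read_obo(str(path))
        except FileNotFoundError:
            raise
        except Exception as exc:
            raise ValueError(f"cannot read ontology file {path}: {exc}") from exc
        return cls(graph, root=root)

    def __contains__(self, doid: str | None) -> bool:
        return doid is not None and doid in self.members


def bioxpress_filter(records: list[ExpressionRecord], subtree: DOSubtree) -> list[ExpressionRecord]:
    """Keep records suitable for a tumor-vs-normal expression database:
    the disease must be cancer (per the ontology subtree) and the comparison
    baseline must be an explicit or implicit control."""
    return [
        r
        for r in records
        if r.doid in subtree and r.frame_of_reference in ("Control", "Control_Implicit")
    ]
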