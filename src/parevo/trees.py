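"""Fixed species trees with named internal nodes.

The default study system is the great-ape phylogeny over human (H),
chimpanzee (C), gorilla (G) and orangutan (O), rooted with the macaque (M)
outgroup, with internal nodes HC, HCG and HCGO.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy


@dataclass
class SpeciesTree:
    """A rooted tree given as a child -> parent map, plus optional branch ages.

    `ages` maps a child node label to the duration (in years) of the branch
    leading to it — the denominator used to turn a per-site divergence into a
    per-site-and-year rate.
    """

    parent: dict[str, str]
    root: str
    lengths: dict[str, float] = field(default_factory=dict)
    ages: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        labels = set(self.parent) | set(self.parent.values())
        if self.root not in labels:
            raise ValueError(f"root {self.root!r} not among node labels")
        if self.root in self.parent:
            raise ValueError("root must not have a parent")
        for child, age in self.ages.items():
            if age <= 0:
                raise ValueError(f"branch age for {child!r} must be positive")
        # every non-root node must reach the root
        for node in labels - {self.root}:
            seen = set()
            cur = node
            while cur != self.root:
                if cur in seen or cur not in self.parent:
                    raise ValueError(f"node {node!r} does not reach the root")
                seen.add(cur)
                cur = self.parent[cur]

    @property
    def nodes(self) -> set[str]:
        return set(self.parent) | {self.root}

    @property
    def leaves(self) -> set[str]:
        return self.nodes - set(self.parent.values())

    def branches(self) -> list[tuple[str, str]]:
        """(child, parent) pairs, sorted by child label."""
        return sorted(self.parent.items())

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        """Parse a newick string (or file path) with labelled internal nodes."""
        if "(" not in newick:
            with open(newick) as fh:
                newick = fh.read()
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=False)
        parent: dict[str, str] = {}
        lengths: dict[str, float] = {}

        def label(node) -> str:
            if node.taxon is not None and node.taxon.label:
                return node.taxon.label
            return node.label or "root"

        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                parent[label(node)] = label(node.parent_node)
                if node.edge.length is not None:
                    lengths[label(node)] = float(node.edge.length)
        return cls(parent=parent, root=label(tree.seed_node), lengths=lengths)

    def to_newick(self) -> str:
        children: dict[str, list[str]] = {}
        for c, p in self.parent.items():
            children.setdefault(p, []).append(c)

        def render(node: str) -> str:
            kids = sorted(children.get(node, []))
            blen = f":{self.lengths[node]}" if node in self.lengths else ""
            if not kids:
                return f"{node}{blen}"
            return f"({','.join(render(k) for k in kids)}){node}{blen}"

        return render(self.root) + ";"


#: Great-ape species tree with branch lengths equal to per-site PAR1
#: divergences of each branch since the great-ape ancestor, and an outgroup
#: branch to the macaque. Used as the default simulation scaffold.
GREAT_APE_NEWICK = (
    "((((H:0.0105,C:0.0120)HC:0.0036,G:0.0143)HCG:0.0166,O:0.0279)HCGO:0.013,"
    "M:0.045)root;"
)


def great_ape_tree() -> SpeciesTree:
    tree = SpeciesTree.from_newick(GREAT_APE_NEWICK)
    # branch durations in years implied by per-site and per-year divergence
    # rates of the region (duration = divergence / rate)
    tree.ages = {
        "H": 0.0105 / 0.9652e-9,
        "C": 0.0120 / 1.1023e-9,
        "HC": 0.0036 / 1.7496e-9,
        "G": 0.0143 / 1.1007e-9,
        "HCG": 0.0166 / 1.5248e-9,
        "O": 0.0279 / 1.1696e-9,
    }
    return tree
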