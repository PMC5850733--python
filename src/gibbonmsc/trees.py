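"""Rooted-tree data model for multispecies-coalescent analyses.

Topologies are immutable, canonical (child order sorted by smallest tip
label) and hashable, so they can be enumerated, counted and used as
dictionary keys for exact frequency tallies.  Species trees carry node
ages ``tau`` and population-size parameters ``theta``, both measured in
expected substitutions per site, following the convention in which the
coalescent rate for one pair of lineages within a population is
``2/theta`` and an internal branch measures ``t = 2*dtau/theta``
coalescent units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, inf, isfinite
from typing import Iterator, Mapping

__all__ = [
    "Topology",
    "SpeciesTreeModel",
    "CoalUnitTree",
    "NewickError",
    "enumerate_rooted_topologies",
    "topology_id",
    "topology_from_id",
    "TABLE1_TOPOLOGIES",
    "TABLE1_FREQUENCIES",
    "labeled_histories",
    "to_coalescent_units",
    "read_newick",
    "write_newick",
]


# A tree node is either a tip label (str) or a 2-tuple of nodes.
Node = object


def _min_tip(node: Node) -> str:
    while not isinstance(node, str):
        node = node[0] if _min_tip(node[0]) <= _min_tip(node[1]) else node[1]
    return node


def _canon(node: Node) -> Node:
    if isinstance(node, str):
        return node
    a, b = (_canon(c) for c in node)
    return (a, b) if _min_tip(a) <= _min_tip(b) else (b, a)


def _tips(node: Node) -> Iterator[str]:
    if isinstance(node, str):
        yield node
    else:
        yield from _tips(node[0])
        yield from _tips(node[1])


@dataclass(frozen=True)
class Topology:
    """A rooted binary tree over labelled tips, without branch lengths.

    The internal representation is a nested tuple in canonical form:
    equal topologies compare and hash equal regardless of the child
    order used to build them.
    """

    root: Node

    def __post_init__(self) -> None:
        object.__setattr__(self, "root", _canon(self.root))
        tips = list(_tips(self.root))
        if len(set(tips)) != len(tips):
            raise ValueError(f"duplicate tip labels: {sorted(tips)}")

    @property
    def tips(self) -> frozenset[str]:
        return frozenset(_tips(self.root))

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def clades(self) -> set[frozenset[str]]:
        """All clades (tip sets below each node), tips included."""
        out: set[frozenset[str]] = set()

        def rec(node: Node) -> frozenset[str]:
            c = frozenset([node]) if isinstance(node, str) else rec(node[0]) | rec(node[1])
            out.add(c)
            return c

        rec(self.root)
        return out

    def internal_clades(self) -> set[frozenset[str]]:
        return {c for c in self.clades() if len(c) > 1}

    def has_clade(self, clade) -> bool:
        return frozenset(clade) in self.clades()

    def newick(self) -> str:
        return write_newick(self)

    def relabel(self, mapping: Mapping[str, str]) -> "Topology":
        def rec(node: Node) -> Node:
            if isinstance(node, str):
                return mapping.get(node, node)
            return (rec(node[0]), rec(node[1]))

        return Topology(rec(self.root))

    def unrooted_splits(self) -> set[frozenset[frozenset[str]]]:
        """Nontrivial bipartitions of the tip set induced by internal edges
        of the unrooted version of this tree."""
        tips = self.tips
        out = set()
        for c in self.internal_clades():
            if 1 < len(c) < len(tips) - 1:
                out.add(frozenset([c, tips - c]))
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Topology({self.newick()!r})"


# ---------------------------------------------------------------------------
# species trees with tau / theta


@dataclass(frozen=True)
class SpeciesTreeModel:
    """Species tree with divergence times and population sizes.

    Parameters
    ----------
    topology
        Rooted species-tree shape.
    tau
        Age of each internal node, keyed by its clade (frozenset of tip
        labels), in expected substitutions/site.  Tips have age 0.
    theta
        Population-size parameter ``theta = 4*N*mu`` for each
        branch/population, keyed by the clade of the node *below* the
        branch.  The root population is keyed by the full tip set.
        Tip populations may be omitted when a single lineage is sampled.
    """

    topology: Topology
    tau: Mapping[frozenset, float]
    theta: Mapping[frozenset, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tau", {frozenset(k): float(v) for k, v in self.tau.items()})
        object.__setattr__(self, "theta", {frozenset(k): float(v) for k, v in self.theta.items()})
        for c in self.topology.internal_clades():
            if c not in self.tau:
                raise ValueError(f"missing tau for clade {sorted(c)}")
            if self.tau[c] < 0:
                raise ValueError("tau must be >= 0")
        for c, th in self.theta.items():
            if th <= 0:
                raise ValueError(f"theta must be > 0 (clade {sorted(c)})")
        # ages strictly decrease root -> tips
        for c in self.topology.internal_clades():
            for d in self.topology.internal_clades():
                if d < c and not self.tau[d] < self.tau[c]:
                    raise ValueError("tau must strictly decrease from root to tips")

    def node_age(self, clade: frozenset) -> float:
        return 0.0 if len(clade) == 1 else self.tau[clade]

    def parent_clade(self, clade: frozenset) -> frozenset | None:
        best = None
        for c in self.topology.internal_clades():
            if clade < c and (best is None or c < best):
                best = c
        return best

    @property
    def root_clade(self) -> frozenset:
        return self.topology.tips


@dataclass(frozen=True)
class CoalUnitTree:
    """Species-tree shape with internal branch lengths in coalescent units.

    ``lengths`` maps the clade of each non-root internal node to the
    length ``t = 2*dtau/theta`` of the branch above it.  ``stem`` is the
    length of the branch above the root before a final panmictic epoch
    (infinite by default); a finite stem models e.g. an in-group crown
    whose residual lineages coalesce with an outgroup far in the past.
    """

    topology: Topology
    lengths: Mapping[frozenset, float]
    stem: float = inf

    def __post_init__(self) -> None:
        object.__setattr__(self, "lengths", {frozenset(k): float(v) for k, v in self.lengths.items()})
        for c, t in self.lengths.items():
            if t < 0:
                raise ValueError(f"coalescent-unit length must be >= 0 (clade {sorted(c)})")
        if self.stem < 0:
            raise ValueError("stem length must be >= 0")
        expected = {
            c
            for c in self.topology.internal_clades()
            if c != self.topology.tips
        }
        if set(self.lengths) != expected:
            raise ValueError("lengths must cover exactly the non-root internal clades")


def to_coalescent_units(m: SpeciesTreeModel) -> CoalUnitTree:
    """Convert a ``SpeciesTreeModel`` to coalescent-unit branch lengths,
    ``t = 2 * (tau_parent - tau_node) / theta_branch`` exactly."""
    lengths = {}
    for c in m.topology.internal_clades():
        p = m.parent_clade(c)
        if p is None:
            continue
        if c not in m.theta:
            raise ValueError(f"missing theta for internal branch {sorted(c)}")
        lengths[c] = 2.0 * (m.tau[p] - m.tau[c]) / m.theta[c]
    return CoalUnitTree(m.topology, lengths)


# ---------------------------------------------------------------------------
# enumeration and the genus-level catalogue


def enumerate_rooted_topologies(labels) -> list[Topology]:
    """All distinct rooted binary topologies over ``labels``.

    Generated by stepwise addition: the n-th tip can be attached to any
    of the ``2n-3`` branches (including the root branch), giving the
    double-factorial count ``(2n-3)!!``.  Deterministic order: labels
    are sorted, and attachment points are visited in a fixed traversal.
    """
    labels = sorted(labels)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate labels")
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")

    trees: list[Node] = [(labels[0], labels[1])]
    for lab in labels[2:]:
        new: list[Node] = []
        for t in trees:
            new.append((t, lab))  # attach on the root branch

            def attach(node: Node) -> list[Node]:
                """All trees from attaching ``lab`` on a branch within node."""
                out = []
                if not isinstance(node, str):
                    a, b = node
                    out.extend(((x, b) for x in [(a, lab)] + attach(a)))
                    out.extend(((a, x) for x in [(b, lab)] + attach(b)))
                return out

            new.extend(attach(t))
        trees = new
    return sorted((Topology(t) for t in trees), key=lambda t: t.newick())


def _table1() -> list[Topology]:
    specs = [
        ((("S", "B"), "N"), "H"),
        ((("S", "B"), "H"), "N"),
        ((("N", "B"), "S"), "H"),
        ((("N", "S"), "B"), "H"),
        ((("N", "B"), "H"), "S"),
        ((("H", "B"), "S"), "N"),
        (("H", "N"), ("S", "B")),
        ((("H", "B"), "N"), "S"),
        ((("H", "S"), "B"), "N"),
        ((("N", "S"), "H"), "B"),
        ((("H", "N"), "B"), "S"),
        ((("H", "S"), "N"), "B"),
        ((("H", "N"), "S"), "B"),
        (("H", "S"), ("N", "B")),
        (("H", "B"), ("N", "S")),
    ]
    return [Topology(s) for s in specs]


#: Genus-level species trees numbered by the frequency of sliding-window
#: UPGMA trees in the source genomic study (most common first).
TABLE1_TOPOLOGIES: dict[int, Topology] = {i + 1: t for i, t in enumerate(_table1())}

#: Sliding-window frequencies associated with the numbering above.
TABLE1_FREQUENCIES: dict[int, float] = {
    1: 0.154, 2: 0.132, 3: 0.109, 4: 0.079, 5: 0.072, 6: 0.067, 7: 0.056,
    8: 0.052, 9: 0.051, 10: 0.047, 11: 0.041, 12: 0.038, 13: 0.037,
    14: 0.035, 15: 0.028,
}

_GENUS_LABELS = frozenset({"H", "N", "B", "S"})
_ID_BY_TOPOLOGY = {t: i for i, t in TABLE1_TOPOLOGIES.items()}


def topology_id(top: Topology, outgroup: str = "O") -> int | None:
    """Catalogue number (1..15) of a genus-level gibbon topology.

    Accepts trees over {H, N, B, S}, or over {Hm, Hp, N, B, S} in which
    case the (Hm, Hp) clade is collapsed to H; returns ``None`` when Hm
    and Hp are not monophyletic.  An outgroup tip (default "O") is
    pruned first if present.
    """
    node = top.root
    if outgroup in top.tips:
        node = _prune(node, outgroup)
    tips = set(_tips(node))
    if tips == {"Hm", "Hp", "N", "B", "S"}:
        collapsed = _collapse(node, frozenset({"Hm", "Hp"}), "H")
        if collapsed is None:
            return None
        node = collapsed
        tips = set(_tips(node))
    if tips != set(_GENUS_LABELS):
        raise ValueError(f"unexpected tip labels: {sorted(tips)}")
    return _ID_BY_TOPOLOGY.get(Topology(node))


def topology_from_id(i: int) -> Topology:
    return TABLE1_TOPOLOGIES[i]


def _prune(node: Node, label: str) -> Node:
    if isinstance(node, str):
        if node == label:
            raise ValueError("cannot prune to an empty tree")
        return node
    a, b = node
    if a == label:
        return b
    if b == label:
        return a
    atips, btips = set(_tips(a)), set(_tips(b))
    if label in atips:
        return (_prune(a, label), b)
    if label in btips:
        return (a, _prune(b, label))
    return node


def _collapse(node: Node, clade: frozenset, new_label: str) -> Node | None:
    """Replace the subtree spanning exactly ``clade`` by ``new_label``;
    None when the clade is not monophyletic."""
    if isinstance(node, str):
        return node
    if set(_tips(node)) == clade:
        return new_label
    a, b = node
    atips = set(_tips(a))
    if clade <= atips:
        sub = _collapse(a, clade, new_label)
        return None if sub is None else (sub, b)
    if clade <= set(_tips(b)):
        sub = _collapse(b, clade, new_label)
        return None if sub is None else (a, sub)
    return None  # clade straddles both children


# ---------------------------------------------------------------------------
# labeled histories


def labeled_histories(top: Topology) -> int:
    """Number of labeled histories (temporal orderings of the internal
    nodes) compatible with a rooted topology.

    Computed by the interleaving recursion: for a node with subtrees L
    and R having ``l`` and ``r`` internal nodes, the orderings multiply
    and interleave as ``C(l + r, l)``.
    """

    def rec(node: Node) -> tuple[int, int]:  # (histories, internal nodes)
        if isinstance(node, str):
            return 1, 0
        hl, nl = rec(node[0])
        hr, nr = rec(node[1])
        return hl * hr * comb(nl + nr, nl), nl + nr + 1

    return rec(top.root)[0]


# ---------------------------------------------------------------------------
# Newick I/O


class NewickError(ValueError):
    """Malformed Newick input; ``pos`` is the character offset."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


def read_newick(text: str, with_lengths: bool = False):
    """Parse a Newick string into a :class:`Topology`.

    With ``with_lengths=True``, returns ``(Topology, lengths)`` where
    ``lengths`` maps each clade to the branch length above it (missing
    lengths omitted).  Only binary trees are accepted.
    """
    s = text.strip()
    pos = 0
    lengths: dict[frozenset, float] = {}

    def error(msg: str):
        raise NewickError(msg, pos)

    def parse_clade() -> tuple[Node, frozenset]:
        nonlocal pos
        if pos >= len(s):
            error("unexpected end of input")
        if s[pos] == "(":
            pos += 1
            children = []
            while True:
                node, clade = parse_clade()
                length = parse_length()
                if length is not None:
                    lengths[clade] = length
                children.append((node, clade))
                if pos >= len(s):
                    error("unclosed '('")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                error(f"unexpected character {s[pos]!r}")
            if len(children) != 2:
                error(f"non-binary node with {len(children)} children")
            (a, ca), (b, cb) = children
            # ignore any internal node label
            while pos < len(s) and s[pos] not in ":,();":
                pos += 1
            return (a, b), ca | cb
        label = ""
        while pos < len(s) and s[pos] not in ":,();":
            label += s[pos]
            pos += 1
        label = label.strip()
        if not label:
            error("empty tip label")
        return label, frozenset([label])

    def parse_length() -> float | None:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",();":
                pos += 1
            try:
                return float(s[start:pos])
            except ValueError:
                error(f"bad branch length {s[start:pos]!r}")
        return None

    root, clade = parse_clade()
    length = parse_length()
    if length is not None:
        lengths[clade] = length
    if pos >= len(s) or s[pos] != ";":
        error("expected ';'")
    if s[pos + 1:].strip():
        error("trailing characters after ';'")
    top = Topology(root)
    return (top, lengths) if with_lengths else top


def write_newick(tree, lengths: Mapping[frozenset, float] | None = None,
                 precision: int = 17) -> str:
    """Serialize a :class:`Topology` (canonical child order), optionally
    annotating branch lengths keyed by clade."""
    top = tree if isinstance(tree, Topology) else Topology(tree)

    def fmt(clade: frozenset) -> str:
        if lengths is not None and clade in lengths:
            v = lengths[clade]
            return f":{v:.{precision}g}" if isfinite(v) else ""
        return ""

    def rec(node: Node) -> tuple[str, frozenset]:
        if isinstance(node, str):
            return node + fmt(frozenset([node])), frozenset([node])
        sa, ca = rec(node[0])
        sb, cb = rec(node[1])
        clade = ca | cb
        return f"({sa},{sb})" + (fmt(clade) if clade != top.tips else ""), clade

    return rec(top.root)[0] + ";"
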