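"""Gibbon-radiation presets: species tree 1 with realistic parameters.

The five-species tree is (((B, S), N), (Hm, Hp)) — Hoolock (B),
Symphalangus (S), Nomascus (N) and the two Hylobates species — with a
human outgroup (O).  Divergence times and population sizes are
calibrated so the internal branches measure, in coalescent units
(2*dtau/theta), the values estimated from the genomic data:

==========  =========  =======
branch      noncoding  coding
==========  =========  =======
SB          0.065      0.071
SBN         0.078      0.074
H (Hm-Hp)   2.330      2.050
gibbon stem 9.083      7.336
==========  =========  =======

The stem follows from the printed posterior means (noncoding: root age
0.0154, gibbon crown age 0.0045, stem theta 0.0024; coding: 0.0115,
0.0031, 0.00229).  Quantities not printed as text (tip and short
ancestral thetas, the Hm-Hp divergence time) are filled in from the
within-species diversity table and the triplet analysis, and the
remaining taus are solved so the coalescent-unit lengths above hold
exactly.  The trees are therefore approximate reconstructions on the
mutation-time scale but exact on the coalescent-unit scale.
"""

from __future__ import annotations

from .trees import (CoalUnitTree, SpeciesTreeModel, Topology,
                    TABLE1_TOPOLOGIES)

__all__ = [
    "GIBBON_TIPS",
    "SPECIES_TREE_1",
    "SPECIES_TREE_1_WITH_OUTGROUP",
    "truth_coal_unit_tree",
    "species_tree_model",
    "candidate_trees",
    "GENE_TREE_1",
    "GENE_TREE_7",
]

GIBBON_TIPS = ("B", "S", "N", "Hm", "Hp")

#: Species tree 1 at the species level (H clade resolved into Hm, Hp).
SPECIES_TREE_1 = Topology(((("B", "S"), "N"), ("Hm", "Hp")))
SPECIES_TREE_1_WITH_OUTGROUP = Topology((SPECIES_TREE_1.root, "O"))

#: The gene tree matching the species tree, and the anomalous balanced tree.
GENE_TREE_1 = SPECIES_TREE_1
GENE_TREE_7 = Topology((("B", "S"), (("Hm", "Hp"), "N")))

_SB = frozenset({"B", "S"})
_SBN = frozenset({"B", "S", "N"})
_H = frozenset({"Hm", "Hp"})
_GIB = frozenset(GIBBON_TIPS)

# coalescent-unit internal branch lengths ("Truth" rows) and the stem
_CU = {
    "noncoding": {"SB": 0.065, "SBN": 0.078, "H": 2.330,
                  "tau_root": 0.0154, "tau_gib": 0.0045, "theta_stem": 0.0024},
    "coding": {"SB": 0.071, "SBN": 0.074, "H": 2.050,
               "tau_root": 0.0115, "tau_gib": 0.0031, "theta_stem": 0.00229},
}

# per-regime reconstruction of the mutation-scale parameters
_FILL = {
    "noncoding": {
        "tip_theta": {"B": 0.0009, "S": 0.0012, "N": 0.0018, "Hm": 0.0014, "Hp": 0.0006},
        "theta_SB": 0.004, "theta_SBN": 0.004, "tau_H": 0.0014, "theta_root": 0.0055,
    },
    "coding": {
        "tip_theta": {"B": 0.0006, "S": 0.0008, "N": 0.0012, "Hm": 0.0010, "Hp": 0.0004},
        "theta_SB": 0.0025, "theta_SBN": 0.0025, "tau_H": 0.00094, "theta_root": 0.0078,
    },
}


def truth_coal_unit_tree(regime: str = "noncoding") -> CoalUnitTree:
    """Coalescent-unit species tree used for gene-tree-distribution and
    anomaly-zone reconstructions (one lineage per species; the human
    outgroup enters only through the finite stem + panmictic root)."""
    c = _CU[regime]
    stem = 2.0 * (c["tau_root"] - c["tau_gib"]) / c["theta_stem"]
    return CoalUnitTree(
        SPECIES_TREE_1,
        {_SB: c["SB"], _SBN: c["SBN"], _H: c["H"]},
        stem=stem,
    )


def species_tree_model(regime: str = "noncoding", outgroup: bool = False) -> SpeciesTreeModel:
    """Gibbon-like :class:`SpeciesTreeModel` on the mutation-time scale.

    The coalescent-unit lengths of SB, SBN and H reproduce the "Truth"
    values exactly; see the module docstring for provenance of the
    filled-in quantities.
    """
    c, f = _CU[regime], _FILL[regime]
    tau_gib = c["tau_gib"]
    theta_SBN, theta_SB = f["theta_SBN"], f["theta_SB"]
    tau_SBN = tau_gib - c["SBN"] * theta_SBN / 2.0
    tau_SB = tau_SBN - c["SB"] * theta_SB / 2.0
    tau_H = f["tau_H"]
    theta_H = 2.0 * (tau_gib - tau_H) / c["H"]

    tau = {_SB: tau_SB, _SBN: tau_SBN, _H: tau_H, _GIB: tau_gib}
    theta = {frozenset([k]): v for k, v in f["tip_theta"].items()}
    theta.update({_SB: theta_SB, _SBN: theta_SBN, _H: theta_H, _GIB: c["theta_stem"]})

    if not outgroup:
        # the gibbon crown is the root: its population is the stem
        return SpeciesTreeModel(SPECIES_TREE_1, tau, theta)

    tau = dict(tau)
    theta = dict(theta)
    root = _GIB | {"O"}
    tau[root] = c["tau_root"]
    theta[root] = f["theta_root"]
    return SpeciesTreeModel(SPECIES_TREE_1_WITH_OUTGROUP, tau, theta)


def candidate_trees(outgroup: bool = False,
                    split_h: bool = True) -> dict[int, Topology]:
    """The 15 genus-level candidate species trees, optionally with the
    H tip expanded into the fixed (Hm, Hp) clade and an outgroup O
    attached at the root.  The Hm-Hp grouping is never in doubt, so
    only these 15 candidates need be entertained."""

    def expand(node):
        if node == "H":
            return ("Hm", "Hp")
        if isinstance(node, str):
            return node
        return (expand(node[0]), expand(node[1]))

    out = {}
    for i, t in TABLE1_TOPOLOGIES.items():
        root = expand(t.root) if split_h else t.root
        if outgroup:
            root = (root, "O")
        out[i] = Topology(root)
    return out


def omega_from_slope(slope: float, synonymous_fraction: float = 0.25) -> float:
    """Genome-wide dN/dS implied by the coding/noncoding divergence slope.

    If a fraction p of coding sites is synonymous (and evolves
    neutrally, like the noncoding loci), the coding/noncoding rate
    ratio is p + (1 - p) * omega; inverting the observed slope 0.73
    with p = 1/4 gives omega = 0.64.
    """
    p = synonymous_fraction
    return (slope - p) / (1.0 - p)
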