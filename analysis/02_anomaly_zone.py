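"""Is the gibbon species tree in the anomaly zone?  Yes.

Checks the zero-branch-length limit (matching caterpillar 1/18,
balanced mismatch 2/18 — the labeled-history argument), then asks
whether the most probable gene tree differs from the species tree
under both parameterisations, which makes majority vote (and, in
practice, concatenation) inconsistent.
"""

import sys
from fractions import Fraction
from pathlib import Path

import pandas as pd

from gibbonmsc.genedist import find_anomalous_gene_trees, gene_tree_distribution
from gibbonmsc.gibbon import truth_coal_unit_tree
from gibbonmsc.trees import CoalUnitTree, Topology, labeled_histories

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    # the labeled-history limit: both internal branches -> 0
    cat = Topology(((("B", "S"), "N"), "H"))
    bal = Topology((("B", "S"), ("H", "N")))
    star = CoalUnitTree(cat, {frozenset({"B", "S"}): 0.0,
                              frozenset({"B", "S", "N"}): 0.0})
    dist = gene_tree_distribution(star)
    print(f"zero-length limit: P(matching caterpillar) = {dist.prob(cat):.6f}"
          f" (= {Fraction(1, 18)}), labeled histories {labeled_histories(cat)}")
    print(f"                   P(balanced mismatch)   = {dist.prob(bal):.6f}"
          f" (= {Fraction(2, 18)}), labeled histories {labeled_histories(bal)}")

    rows = []
    for regime in ("noncoding", "coding"):
        rep = find_anomalous_gene_trees(truth_coal_unit_tree(regime))
        print(f"{regime}: {rep.summary()}")
        rows.append({"regime": regime,
                     "most_probable": rep.most_probable_gene_tree.newick(),
                     "p_most_probable": round(rep.p_most_probable, 4),
                     "p_matching": round(rep.p_matching, 4),
                     "anomalous": rep.is_anomalous})
    pd.DataFrame(rows).to_csv(OUT / "anomaly_zone.tsv", sep="\t", index=False)


if __name__ == "__main__":
    sys.exit(main())
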