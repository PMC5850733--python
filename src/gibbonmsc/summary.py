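"""Summary species-tree estimators: majority vote, quartet scoring,
rooted-triple pseudo-likelihood, and SVD flattenings.

All estimators score a fixed candidate set (for the gibbon problem,
the 15 genus-level trees with the Hm-Hp clade held fixed) rather than
searching tree space — exhaustive scoring is both exact and cheap for
five species.

Gene trees may be fully resolved :class:`~gibbonmsc.trees.Topology`
objects, estimated :class:`~gibbonmsc.likelihood.MLTree` objects, or
raw split/clade sets; polytomies simply contribute no count for the
quartets or triples they leave unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import log
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .likelihood import (MLTree, SitePatternCounts, concat_ml,
                         rooted_clades_from_splits)
from .trees import Topology

__all__ = [
    "QuartetTally",
    "FlatteningMatrix",
    "majority_vote",
    "astral_score",
    "astral_search",
    "AstralBranch",
    "quartet_length",
    "mpest_pseudolik",
    "mpest_search",
    "svd_split_score",
    "flattening_matrix",
    "svd_quartets_search",
    "pooled_patterns",
    "subsample_one_per_species",
    "run_all_summary",
]


# ---------------------------------------------------------------------------
# uniform access to splits / clades


def unrooted_splits_of(tree) -> tuple[frozenset, frozenset[frozenset]]:
    """(tips, nontrivial splits) of a gene tree in any accepted form."""
    if isinstance(tree, MLTree):
        return tree.tips, tree.splits
    if isinstance(tree, Topology):
        return tree.tips, frozenset(min(s, key=sorted) for s in tree.unrooted_splits())
    raise TypeError(f"unsupported gene-tree type {type(tree)!r}")


def _quartet_split(tips, splits, quartet: frozenset) -> frozenset | None:
    """Induced quartet topology as a frozenset pair {xy, zw}; None when
    unresolved."""
    for s in splits:
        inside = quartet & s
        if len(inside) == 2:
            return frozenset([inside, quartet - inside])
        outside = quartet - (quartet & s)
        if len(outside) == 2:
            return frozenset([outside, quartet - outside])
    return None


def _triple_topology(clades: Iterable[frozenset], triple: frozenset) -> frozenset | None:
    """Induced rooted triple as the cherry pair frozenset; None when
    unresolved."""
    best = None
    for c in clades:
        inside = triple & c
        if len(inside) == 2 and not triple <= c:
            best = frozenset(inside)
            break
    return best


# ---------------------------------------------------------------------------
# majority vote


def majority_vote(gene_topologies: Sequence[Topology]) -> Topology:
    """Most frequent rooted topology; ties broken by canonical Newick."""
    if not gene_topologies:
        raise ValueError("no gene trees")
    counts: dict[Topology, int] = {}
    for t in gene_topologies:
        counts[t] = counts.get(t, 0) + 1
    best = max(counts.values())
    winners = sorted((t for t, c in counts.items() if c == best), key=lambda t: t.newick())
    return winners[0]


# ---------------------------------------------------------------------------
# quartet (astral-style) scoring


@dataclass(frozen=True)
class QuartetTally:
    """Per-quartet counts of the three unrooted topologies over a set of
    gene trees; unresolved quartets are skipped."""

    counts: Mapping[frozenset, Mapping[frozenset, int]]  # quartet -> split -> n
    n_trees: int

    @classmethod
    def from_gene_trees(cls, gene_trees, tips: Iterable[str] | None = None) -> "QuartetTally":
        if not gene_trees:
            raise ValueError("no gene trees")
        parsed = [unrooted_splits_of(t) for t in gene_trees]
        tipset = frozenset(tips) if tips is not None else frozenset.intersection(
            *(t for t, _ in parsed))
        counts: dict[frozenset, dict[frozenset, int]] = {
            frozenset(q): {} for q in combinations(sorted(tipset), 4)}
        for gtips, splits in parsed:
            for q, sub in counts.items():
                if not q <= gtips:
                    continue
                key = _quartet_split(gtips, splits, q)
                if key is not None:
                    sub[key] = sub.get(key, 0) + 1
        return cls(counts=counts, n_trees=len(parsed))

    def support(self, quartet: frozenset, split: frozenset) -> tuple[int, int]:
        """(agreeing count, resolved total) for one quartet topology."""
        sub = self.counts[frozenset(quartet)]
        return sub.get(frozenset(split), 0), sum(sub.values())


def _candidate_quartet_splits(candidate: Topology) -> dict[frozenset, frozenset]:
    tips, splits = candidate.tips, candidate.unrooted_splits()
    smalls = frozenset(min(s, key=sorted) for s in splits)
    out = {}
    for q in combinations(sorted(tips), 4):
        q = frozenset(q)
        key = _quartet_split(tips, smalls, q)
        if key is not None:
            out[q] = key
    return out


def astral_score(gene_trees_or_tally, candidate: Topology) -> int:
    """Total number of gene-tree quartets agreeing with the candidate."""
    tally = (gene_trees_or_tally if isinstance(gene_trees_or_tally, QuartetTally)
             else QuartetTally.from_gene_trees(gene_trees_or_tally, candidate.tips))
    score = 0
    for q, split in _candidate_quartet_splits(candidate).items():
        agree, _ = tally.support(q, split)
        score += agree
    return score


@dataclass(frozen=True)
class AstralBranch:
    """Quartet support around one internal branch of the best tree."""

    clade: frozenset
    q_hat: float
    length: float  # coalescent units


def quartet_length(q_hat: float) -> float:
    """Invert P(quartet match) = 1 - (2/3) e^(-t): t = -ln(1.5 (1-q));
    clamped to 0 at or below the star-tree value q = 1/3."""
    if q_hat <= 1.0 / 3.0:
        return 0.0
    if q_hat >= 1.0:
        return float("inf")
    return -log(1.5 * (1.0 - q_hat))


def _branch_quartets(candidate: Topology, clade: frozenset):
    """Quartets with one tip in each of the four subtrees around the
    internal edge above ``clade`` (the astral branch-support set)."""
    node = _find_node(candidate.root, clade)
    side1 = frozenset(_tips(node[0]))
    side2 = clade - side1
    rest = candidate.tips - clade
    # partition `rest` by the first split encountered outside the clade
    parts = _outside_partition(candidate, clade)
    out = []
    for a in side1:
        for b in side2:
            for c in parts[0]:
                for d in parts[1]:
                    out.append((frozenset([a, b, c, d]), frozenset([frozenset([a, b]), frozenset([c, d])])))
    return out


def _find_node(node, clade):
    if isinstance(node, str):
        return None
    if frozenset(_tips(node)) == clade:
        return node
    return _find_node(node[0], clade) or _find_node(node[1], clade)


def _tips(node):
    if isinstance(node, str):
        yield node
    else:
        yield from _tips(node[0])
        yield from _tips(node[1])


def _outside_partition(candidate: Topology, clade: frozenset) -> tuple[frozenset, frozenset]:
    """Split the tips outside ``clade`` into the two subtrees adjacent to
    the branch above ``clade`` in the unrooted candidate."""
    def rec(node, parent_rest):
        if isinstance(node, str):
            return None
        c0, c1 = (frozenset(_tips(ch)) for ch in node)
        if c0 == clade:
            return (c1, parent_rest)
        if c1 == clade:
            return (c0, parent_rest)
        r = rec(node[0], parent_rest | c1)
        if r is not None:
            return r
        return rec(node[1], parent_rest | c0)

    parts = rec(candidate.root, frozenset())
    assert parts is not None and all(parts)
    return parts


def astral_search(gene_trees, candidates: Mapping[int, Topology] | Sequence[Topology]):
    """Best candidate by total quartet score, with per-internal-branch
    support q-hat and coalescent-unit length t-hat = -ln(1.5(1-q))."""
    cands = dict(candidates) if isinstance(candidates, Mapping) else dict(enumerate(candidates))
    first = next(iter(cands.values()))
    tally = QuartetTally.from_gene_trees(gene_trees, first.tips)
    scores = {k: astral_score(tally, c) for k, c in cands.items()}
    best_key = max(scores, key=lambda k: (scores[k], cands[k].newick()))
    best = cands[best_key]
    branches = []
    for clade in sorted(best.internal_clades(), key=sorted):
        if clade == best.tips:
            continue
        if len(best.tips - clade) < 2:
            continue
        agree = total = 0
        for q, split in _branch_quartets(best, clade):
            a, t = tally.support(q, split)
            agree += a
            total += t
        q_hat = agree / total if total else 1.0 / 3.0
        branches.append(AstralBranch(clade=clade, q_hat=q_hat, length=quartet_length(q_hat)))
    return best_key, best, scores, branches


# ---------------------------------------------------------------------------
# rooted-triple pseudo-likelihood (mp-est style)


def _triple_counts(rooted_trees, tips: frozenset) -> dict[frozenset, dict[frozenset, int]]:
    counts: dict[frozenset, dict[frozenset, int]] = {
        frozenset(t): {} for t in combinations(sorted(tips), 3)}
    for tr in rooted_trees:
        if isinstance(tr, Topology):
            clades = tr.clades()
        elif isinstance(tr, (set, frozenset)):
            clades = tr
        else:
            raise TypeError("rooted gene trees must be Topology or clade sets; "
                            "root unrooted trees on the outgroup first")
        for t, sub in counts.items():
            pair = _triple_topology(clades, t)
            if pair is not None:
                sub[pair] = sub.get(pair, 0) + 1
    return counts


def _triple_branch_map(candidate: Topology) -> dict[frozenset, list[frozenset]]:
    """For each triple, the candidate internal branches whose lengths sum
    to the triple's internal branch (clades C with pair <= C, z not in C)."""
    internal = [c for c in candidate.internal_clades() if c != candidate.tips]
    out = {}
    for t in combinations(sorted(candidate.tips), 3):
        t = frozenset(t)
        pair = _triple_topology(candidate.clades(), t)
        (z,) = t - pair
        out[t] = (pair, [c for c in internal if pair <= c and z not in c])
    return out


def mpest_pseudolik(rooted_trees, candidate: Topology,
                    branch_lengths: Mapping[frozenset, float]) -> float:
    """Trinomial pseudo-log-likelihood of rooted triples.

    For a triple with internal length t: P(match) = 1 - (2/3)e^(-t),
    each mismatch (1/3)e^(-t); contributions sum over triples.
    """
    counts = _triple_counts(rooted_trees, candidate.tips)
    return _mpest_ll(counts, candidate, np.array(
        [branch_lengths[c] for c in _mpest_branches(candidate)]))


def _mpest_branches(candidate: Topology) -> list[frozenset]:
    return sorted((c for c in candidate.internal_clades() if c != candidate.tips),
                  key=sorted)


def _mpest_ll(counts, candidate, tvec) -> float:
    branches = _mpest_branches(candidate)
    tmap = {c: tvec[i] for i, c in enumerate(branches)}
    bmap = _triple_branch_map(candidate)
    ll = 0.0
    for trip, sub in counts.items():
        pair, path = bmap[trip]
        t = sum(tmap[c] for c in path)
        e = np.exp(-t)
        p_match = max(1.0 - 2.0 * e / 3.0, 1e-300)
        p_mis = max(e / 3.0, 1e-300)
        for obs_pair, n in sub.items():
            ll += n * log(p_match if obs_pair == pair else p_mis)
    return float(ll)


_T_CAP = 12.0  # pseudo-likelihood is flat beyond ~e^-12


def mpest_search(rooted_trees, candidates: Mapping[int, Topology] | Sequence[Topology]):
    """Maximise the triple pseudo-likelihood over branch lengths for each
    candidate; return (best key, best topology, per-candidate table)."""
    cands = dict(candidates) if isinstance(candidates, Mapping) else dict(enumerate(candidates))
    first = next(iter(cands.values()))
    counts = _triple_counts(rooted_trees, first.tips)
    results = {}
    for k, cand in cands.items():
        branches = _mpest_branches(cand)
        x0 = np.full(len(branches), 0.5)
        res = minimize(lambda x: -_mpest_ll(counts, cand, x), x0,
                       method="L-BFGS-B", bounds=[(0.0, _T_CAP)] * len(branches))
        results[k] = (float(-res.fun), dict(zip(branches, res.x)))
    best_key = max(results, key=lambda k: (results[k][0], cands[k].newick()))
    return best_key, cands[best_key], results


# ---------------------------------------------------------------------------
# SVD flattening


@dataclass(frozen=True)
class FlatteningMatrix:
    """16x16 site-pattern count matrix for a 2|2 split of four sequences.

    Rows index the joint states of the first pair, columns the second;
    the expected version under the MSC has rank <= 10 when the split
    matches the species tree.
    """

    pair_rows: tuple[str, str]
    pair_cols: tuple[str, str]
    matrix: np.ndarray

    def score(self) -> float:
        return svd_split_score(self.matrix)


def flattening_matrix(spc: SitePatternCounts, rows: Sequence[str],
                      cols: Sequence[str]) -> FlatteningMatrix:
    """Build the flattening for split {rows} | {cols} from (pooled) site
    patterns; columns with ambiguity in any of the four sequences are
    skipped."""
    idx = [spc.names.index(n) for n in [*rows, *cols]]
    pat = spc.patterns[idx]
    ok = (pat != 4).all(axis=0)
    pat = pat[:, ok]
    cnt = spc.counts[ok]
    f = np.zeros((16, 16))
    r = pat[0] * 4 + pat[1]
    c = pat[2] * 4 + pat[3]
    np.add.at(f, (r, c), cnt)
    return FlatteningMatrix(tuple(rows), tuple(cols), f)


def svd_split_score(f: np.ndarray) -> float:
    """Normalised tail-singular-value mass: sqrt(sum of sigma_11..16^2)
    divided by the Frobenius norm.  Zero (to numerical tolerance) when
    the expected flattening has rank <= 10."""
    f = np.asarray(f, dtype=float)
    if f.shape != (16, 16):
        raise ValueError("flattening must be 16x16")
    norm = np.linalg.norm(f)
    if norm == 0:
        raise ValueError("empty flattening")
    sv = np.linalg.svd(f, compute_uv=False)
    return float(np.sqrt((sv[10:] ** 2).sum()) / norm)


def pooled_patterns(loci, names: Sequence[str]) -> SitePatternCounts:
    """Merge all sites across loci (the SVD construction) for ``names``."""
    if not loci:
        raise ValueError("no loci")
    alns = [l.alignment if hasattr(l, "alignment") else l for l in loci]
    merged = {n: "".join(a[n] for a in alns) for n in names}
    return SitePatternCounts.from_alignment(merged, names)


def svd_quartets_search(loci_or_patterns, candidates: Mapping[int, Topology] | Sequence[Topology]):
    """Best candidate by summed flattening scores of its induced splits.

    For every 4-subset of the candidate tip set the candidate's 2|2
    split is scored on the pooled flattening; lower total is better.
    """
    cands = dict(candidates) if isinstance(candidates, Mapping) else dict(enumerate(candidates))
    first = next(iter(cands.values()))
    tips = sorted(first.tips)
    if len(tips) < 4:
        raise ValueError("need at least 4 species")
    spc = (loci_or_patterns if isinstance(loci_or_patterns, SitePatternCounts)
           else pooled_patterns(loci_or_patterns, tips))
    # score each possible split of each quartet once
    split_scores: dict[tuple[frozenset, frozenset], float] = {}
    for q in combinations(tips, 4):
        for pair in combinations(q, 2):
            rest = tuple(x for x in q if x not in pair)
            key = (frozenset(q), frozenset(pair))
            if frozenset(rest) < frozenset(pair):
                continue
            fm = flattening_matrix(spc, pair, rest)
            s = fm.score()
            split_scores[(frozenset(q), frozenset(pair))] = s
            split_scores[(frozenset(q), frozenset(rest))] = s
    totals = {}
    for k, cand in cands.items():
        smalls = frozenset(min(s, key=sorted) for s in cand.unrooted_splits())
        tot = 0.0
        for q in combinations(tips, 4):
            qf = frozenset(q)
            key = _quartet_split(cand.tips, smalls, qf)
            if key is None:
                continue
            pair = min(key, key=sorted)
            tot += split_scores[(qf, frozenset(pair))]
        totals[k] = tot
    best_key = min(totals, key=lambda k: (totals[k], cands[k].newick()))
    return best_key, cands[best_key], totals


# ---------------------------------------------------------------------------
# driver


def subsample_one_per_species(alignment: Mapping[str, str], species: Sequence[str],
                              rng: np.random.Generator) -> dict[str, str]:
    """Pick one haplotype per species (uniform, seeded) and rename the
    sequences by their species."""
    out = {}
    for sp in species:
        names = [n for n in alignment if n == sp or n.startswith(sp + "_")]
        if not names:
            raise ValueError(f"no sequences for species {sp!r}")
        out[sp] = alignment[names[int(rng.integers(len(names)))]]
    return out


def run_all_summary(candidates: Mapping[int, Topology], *, gene_trees=None,
                    rooted_gene_trees=None, loci=None, outgroup: str | None = "O",
                    methods: Sequence[str] = ("majority", "astral", "mpest", "svd"),
                    concat_candidates: Mapping[int, Topology] | None = None,
                    lm=None) -> dict[str, tuple[int | None, Topology]]:
    """Run the requested estimators and report each method's call.

    ``gene_trees`` feed the quartet methods (unrooted use);
    ``rooted_gene_trees`` (or gene trees that are Topologies) feed
    majority vote and the triple pseudo-likelihood; ``loci`` feed SVD
    and concatenation.  Returns method -> (candidate key, topology).
    """
    if gene_trees is None and loci is None:
        raise ValueError("need gene trees or loci")
    out: dict[str, tuple[int | None, Topology]] = {}
    if rooted_gene_trees is None and gene_trees is not None:
        rooted_gene_trees = [t for t in gene_trees if isinstance(t, Topology)]
    for method in methods:
        if method == "majority":
            tops = [t if isinstance(t, Topology) else None for t in rooted_gene_trees]
            if any(t is None for t in tops):
                raise ValueError("majority vote needs fully resolved rooted trees")
            win = majority_vote(tops)
            key = next((k for k, c in candidates.items() if c == win), None)
            out[method] = (key, win)
        elif method == "astral":
            key, top, _, _ = astral_search(gene_trees, candidates)
            out[method] = (key, top)
        elif method == "mpest":
            key, top, _ = mpest_search(rooted_gene_trees, candidates)
            out[method] = (key, top)
        elif method == "svd":
            key, top, _ = svd_quartets_search(loci, candidates)
            out[method] = (key, top)
        elif method == "concat":
            cc = concat_candidates if concat_candidates is not None else candidates
            ranked = concat_ml(loci, list(cc.values()), lm)
            win = ranked[0][0]
            key = next((k for k, c in cc.items() if c == win), None)
            out[method] = (key, win)
        else:
            raise ValueError(f"unknown method {method!r}")
    return out
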