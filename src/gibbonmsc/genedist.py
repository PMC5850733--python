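"""Gene-tree topology distributions under the multispecies coalescent.

Two routes to the same object:

* :func:`gene_tree_distribution` — exact probabilities for one sampled
  lineage per species, by dynamic programming over the species tree.
  Within each species-tree branch the lineages-in/lineages-out law is
  the Kingman death chain, and every particular ordered sequence of
  merges is equally likely; summing linear-extension counts over the
  partial forests realisable in a branch gives closed-form topology
  probabilities.  This doubles as the brute-force oracle for the
  simulator.
* :func:`sample_topology_counts` — fast Monte-Carlo tally of rooted
  topologies on a coalescent-unit species tree, used for the large
  (10^6-draw) frequency reconstructions.

Also: labeled-history-aware anomaly detection (is the most probable
gene tree different from the species tree?).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import comb, inf, isinf
from typing import Mapping

import numpy as np
from scipy.linalg import expm

from .trees import CoalUnitTree, Topology

__all__ = [
    "TopologyDistribution",
    "gene_tree_distribution",
    "clade_probability",
    "find_anomalous_gene_trees",
    "AnomalyReport",
    "sample_topology_counts",
    "simulate_topology_frequencies",
]

_MAX_TIPS = 7


@dataclass(frozen=True)
class TopologyDistribution:
    """Probability distribution over rooted gene-tree topologies."""

    probs: Mapping[Topology, float]
    provenance: str = "analytic"  # "analytic" or "simulated"
    n_draws: int | None = None

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if any(p < 0 for p in self.probs.values()):
            raise ValueError("negative probability")
        tol = 1e-12 if self.provenance == "analytic" else 1e-9
        if abs(total - 1.0) > max(tol, 1e-9 * len(self.probs)):
            raise ValueError(f"probabilities sum to {total!r}, not 1")

    def prob(self, top: Topology) -> float:
        return self.probs.get(top, 0.0)

    def most_probable(self) -> Topology:
        # deterministic tie-break on the canonical Newick string
        return max(self.probs, key=lambda t: (self.probs[t], t.newick()))

    def clade_probability(self, clade) -> float:
        return clade_probability(self, clade)

    def to_table(self):
        """(newick, probability) rows, most probable first."""
        import pandas as pd

        rows = sorted(self.probs.items(), key=lambda kv: -kv[1])
        return pd.DataFrame(
            {"topology": [t.newick() for t, _ in rows],
             "probability": [p for _, p in rows]}
        )


def clade_probability(dist: TopologyDistribution, clade) -> float:
    """Probability that ``clade`` is monophyletic in the gene tree."""
    clade = frozenset(clade)
    return sum(p for t, p in dist.probs.items() if t.has_clade(clade))


# ---------------------------------------------------------------------------
# exact distribution


@lru_cache(maxsize=None)
def _death_chain_probs(m: int, t: float) -> tuple[float, ...]:
    """P(m lineages reduce to k in time t), k = 1..m, coalescent units.

    Computed as the matrix exponential of the pure-death generator with
    rates C(k,2); numerically exact for the small m needed here.
    """
    if isinf(t):
        return tuple(1.0 if k == 1 else 0.0 for k in range(1, m + 1))
    q = np.zeros((m, m))
    for k in range(2, m + 1):
        rate = comb(k, 2)
        q[k - 1, k - 1] = -rate
        q[k - 1, k - 2] = rate
    p = expm(q * t)[m - 1]
    return tuple(max(float(x), 0.0) for x in p)


def _forest_internals(tree) -> int:
    """Internal-node count of a coarse tree (tokens as tips)."""
    return 0 if not isinstance(tree, tuple) else 1 + _forest_internals(tree[0]) + _forest_internals(tree[1])


def _coarse_histories(tree) -> int:
    """Linear extensions of the internal nodes of a coarse tree."""
    if not isinstance(tree, tuple):
        return 1
    hl, hr = _coarse_histories(tree[0]), _coarse_histories(tree[1])
    nl, nr = _forest_internals(tree[0]), _forest_internals(tree[1])
    return hl * hr * comb(nl + nr, nl)


@lru_cache(maxsize=None)
def _binary_forests(m: int) -> tuple[tuple[tuple, int, int], ...]:
    """All binary forests on m distinguishable tokens 0..m-1.

    Returns (forest, n_merges, n_orderings) triples, where ``forest``
    is a frozenset-free canonical tuple of coarse trees and
    ``n_orderings`` counts the distinct merge orders producing it.
    """
    def canon(tree):
        if not isinstance(tree, tuple):
            return tree
        a, b = canon(tree[0]), canon(tree[1])
        return (a, b) if _mintok(a) <= _mintok(b) else (b, a)

    def _mintok(tree):
        return tree if not isinstance(tree, tuple) else min(_mintok(tree[0]), _mintok(tree[1]))

    seen: dict[tuple, int] = {}
    start = tuple(range(m))

    def explore(forest: tuple) -> None:
        key = tuple(sorted(forest, key=str))
        if key in seen:
            return
        seen[key] = 1
        for i, j in combinations(range(len(forest)), 2):
            merged = canon((forest[i], forest[j]))
            rest = tuple(x for k, x in enumerate(forest) if k not in (i, j))
            explore(rest + (merged,))

    explore(start)
    out = []
    for forest in seen:
        trees = list(forest)
        js = [_forest_internals(tr) for tr in trees]
        total_j = sum(js)
        # interleave the per-tree linear extensions
        orderings = 1
        remaining = total_j
        for tr, j in zip(trees, js):
            orderings *= _coarse_histories(tr) * comb(remaining, j) // 1
            remaining -= j
        # comb-based interleaving: multiply by multinomial of js
        # (comb(remaining, j) above accumulates exactly that)
        out.append((forest, total_j, orderings))
    return tuple(out)


def _substitute(coarse, lineages):
    """Expand a coarse tree over token indices into a real gene subtree."""
    if not isinstance(coarse, tuple):
        return lineages[coarse]
    return (_substitute(coarse[0], lineages), _substitute(coarse[1], lineages))


def _evolve(state_probs: dict, t: float) -> dict:
    """Evolve a distribution over lineage sets through one branch.

    ``state_probs`` maps a tuple of gene subtrees (the lineages entering
    the branch) to a probability; the result maps surviving lineage
    sets at the top of the branch to probabilities.
    """
    out: dict = {}
    for lineages, p in state_probs.items():
        m = len(lineages)
        if m == 1:
            out[lineages] = out.get(lineages, 0.0) + p
            continue
        gk = _death_chain_probs(m, t)
        # probability of one *specific ordered* sequence of j merges
        denom = [1.0]
        for i in range(m - 1):
            denom.append(denom[-1] * comb(m - i, 2))
        for forest, j, orderings in _binary_forests(m):
            w = p * gk[m - j - 1] * orderings / denom[j]
            if w <= 0.0:
                continue
            survivors = tuple(sorted((_substitute(tr, lineages) for tr in forest), key=str))
            out[survivors] = out.get(survivors, 0.0) + w
    return out


def gene_tree_distribution(cu: CoalUnitTree) -> TopologyDistribution:
    """Exact rooted gene-tree topology distribution, one lineage per tip.

    Works branch by branch up the species tree; the final (root or
    post-stem) epoch is panmictic and infinite, so all surviving
    lineages coalesce there under the uniform-labeled-history law.
    """
    top = cu.topology
    if top.n_tips > _MAX_TIPS:
        raise ValueError(
            f"exact enumeration supports <= {_MAX_TIPS} tips; "
            "use sample_topology_counts for larger trees"
        )

    def state_at_top(node) -> dict:
        """Distribution over lineage sets at the *top* of the branch above
        ``node`` (for the root: at the end of the stem)."""
        if isinstance(node, str):
            return {(node,): 1.0}
        left = state_at_top(node[0])
        right = state_at_top(node[1])
        combined: dict = {}
        for ll, pl in left.items():
            for lr, pr in right.items():
                lineages = tuple(sorted(ll + lr, key=str))
                combined[lineages] = combined.get(lineages, 0.0) + pl * pr
        clade = frozenset(t for lin in combined for t in _tips_of(lin))
        if clade == top.tips:
            t = cu.stem
        else:
            t = cu.lengths[clade]
        return _evolve(combined, t)

    def _tips_of(lineages):
        for lin in lineages:
            yield from _leaves(lin)

    def _leaves(tree):
        if isinstance(tree, str):
            yield tree
        else:
            yield from _leaves(tree[0])
            yield from _leaves(tree[1])

    state = state_at_top(top.root)
    # final panmictic epoch: everything left coalesces
    final = _evolve(state, inf)
    probs: dict[Topology, float] = {}
    for lineages, p in final.items():
        assert len(lineages) == 1
        gt = Topology(lineages[0])
        probs[gt] = probs.get(gt, 0.0) + p
    return TopologyDistribution(probs, provenance="analytic")


# ---------------------------------------------------------------------------
# anomaly detection


@dataclass(frozen=True)
class AnomalyReport:
    species_topology: Topology
    most_probable_gene_tree: Topology
    p_most_probable: float
    p_matching: float
    is_anomalous: bool
    majority_vote_consistent: bool

    def summary(self) -> str:
        verdict = "IS" if self.is_anomalous else "is NOT"
        return (
            f"species tree {self.species_topology.newick()} {verdict} in the "
            f"anomaly zone: most probable gene tree "
            f"{self.most_probable_gene_tree.newick()} "
            f"(p={self.p_most_probable:.4f} vs matching p={self.p_matching:.4f}); "
            f"majority vote is {'consistent' if self.majority_vote_consistent else 'inconsistent'}"
        )


def find_anomalous_gene_trees(cu: CoalUnitTree) -> AnomalyReport:
    """Identify the most probable gene tree and flag anomaly when it
    differs from the species-tree topology (one lineage per tip)."""
    dist = gene_tree_distribution(cu)
    best = dist.most_probable()
    anomalous = best != cu.topology
    return AnomalyReport(
        species_topology=cu.topology,
        most_probable_gene_tree=best,
        p_most_probable=dist.prob(best),
        p_matching=dist.prob(cu.topology),
        is_anomalous=anomalous,
        majority_vote_consistent=not anomalous,
    )


# ---------------------------------------------------------------------------
# bulk Monte-Carlo topology sampler


def sample_topology_counts(cu: CoalUnitTree, n: int, rng: np.random.Generator,
                           chunk: int = 100_000,
                           outgroup: str | None = None) -> dict[Topology, int]:
    """Tally rooted gene-tree topologies from ``n`` MSC draws.

    One lineage per tip; only the topology is recorded, which allows an
    interned-merge representation and block-generated random numbers —
    roughly two orders of magnitude faster than building full
    genealogies.  ``outgroup`` adds one extra lineage that enters in
    the final panmictic epoch (after a finite stem), which is where an
    outgroup that diverged far before the in-group crown coalesces.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    top = cu.topology
    if outgroup is not None and outgroup in top.tips:
        raise ValueError("outgroup label collides with a tip")

    # Post-order schedule: (duration, source indices); sources < 0 encode
    # leaf tokens, sources >= 0 index earlier schedule entries.
    schedule: list[tuple[float, tuple[int, ...]]] = []
    leaf_tokens: dict[str, int] = {}

    def build(node) -> int:
        if isinstance(node, str):
            tok = leaf_tokens.setdefault(node, len(leaf_tokens))
            return -(tok + 1)
        srcs = tuple(build(c) for c in node)
        clade = frozenset(_leaf_set(node))
        dur = cu.stem if clade == top.tips else cu.lengths[clade]
        schedule.append((dur, srcs))
        return len(schedule) - 1

    def _leaf_set(node):
        if isinstance(node, str):
            yield node
        else:
            yield from _leaf_set(node[0])
            yield from _leaf_set(node[1])

    root_idx = build(top.root)
    if outgroup is not None:
        leaf_tokens[outgroup] = len(leaf_tokens)
    n_leaves = len(leaf_tokens)
    extra = [] if outgroup is None else [leaf_tokens[outgroup]]

    # interned merges: node ids 0..n_leaves-1 are leaves
    merge_ids: dict[tuple[int, int], int] = {}
    id_children: list[tuple[int, int] | None] = [None] * n_leaves

    counts: dict[int, int] = {}
    done = 0
    # generous per-replicate random budget (refilled when exhausted)
    exp_need = 4 * n_leaves
    uni_need = 3 * n_leaves
    while done < n:
        b = min(chunk, n - done)
        exps = rng.exponential(size=b * exp_need)
        unis = rng.random(size=b * uni_need)
        ei = ui = 0
        for _ in range(b):
            if ei + exp_need > exps.size:
                exps = rng.exponential(size=b * exp_need)
                ei = 0
            if ui + uni_need > unis.size:
                unis = rng.random(size=b * uni_need)
                ui = 0
            survivors: list[list[int]] = [None] * len(schedule)  # type: ignore
            for si, (dur, srcs) in enumerate(schedule):
                lineages: list[int] = []
                for s in srcs:
                    if s < 0:
                        lineages.append(-s - 1)
                    else:
                        lineages.extend(survivors[s])
                k = len(lineages)
                elapsed = 0.0
                while k >= 2:
                    npairs = k * (k - 1) // 2
                    elapsed += exps[ei] / npairs
                    ei += 1
                    if elapsed > dur:
                        break
                    r = int(unis[ui] * npairs)
                    ui += 1
                    # map r -> pair (i, j), i < j
                    i = 0
                    while r >= k - 1 - i:
                        r -= k - 1 - i
                        i += 1
                    j = i + 1 + r
                    a, c = lineages[i], lineages[j]
                    key = (a, c) if a <= c else (c, a)
                    mid = merge_ids.get(key)
                    if mid is None:
                        mid = len(id_children)
                        merge_ids[key] = mid
                        id_children.append(key)
                    lineages[j] = lineages[-1]
                    lineages.pop()
                    lineages[i] = mid
                    k -= 1
                survivors[si] = lineages
            rem = survivors[root_idx] + extra
            k = len(rem)
            while k >= 2:  # final panmictic epoch
                npairs = k * (k - 1) // 2
                r = int(unis[ui] * npairs)
                ui += 1
                i = 0
                while r >= k - 1 - i:
                    r -= k - 1 - i
                    i += 1
                j = i + 1 + r
                a, c = rem[i], rem[j]
                key = (a, c) if a <= c else (c, a)
                mid = merge_ids.get(key)
                if mid is None:
                    mid = len(id_children)
                    merge_ids[key] = mid
                    id_children.append(key)
                rem[j] = rem[-1]
                rem.pop()
                rem[i] = mid
                k -= 1
            rid = rem[0]
            counts[rid] = counts.get(rid, 0) + 1
        done += b

    label_by_token = {v: k for k, v in leaf_tokens.items()}

    def decode(i: int):
        if i < n_leaves:
            return label_by_token[i]
        a, b2 = id_children[i]
        return (decode(a), decode(b2))

    return {Topology(decode(i)): c for i, c in counts.items()}


def simulate_topology_frequencies(cu: CoalUnitTree, n: int,
                                  rng: np.random.Generator) -> TopologyDistribution:
    """Monte-Carlo version of :func:`gene_tree_distribution`."""
    counts = sample_topology_counts(cu, n, rng)
    return TopologyDistribution(
        {t: c / n for t, c in counts.items()}, provenance="simulated", n_draws=n
    )


# ---------------------------------------------------------------------------
# exact expected site-pattern probabilities (MSC + JC)


def _set_partitions(items: tuple):
    """All partitions of ``items`` (Bell-number many)."""
    if not items:
        yield frozenset()
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        blocks = sorted(part, key=sorted)
        for i, b in enumerate(blocks):
            yield frozenset([b | {first}]) | frozenset(blocks[:i] + blocks[i + 1:])
        yield part | frozenset([frozenset([first])])


def expected_pattern_probabilities(m, names=None):
    """Exact expected site-pattern probabilities under the MSC with JC
    mutation, one sequence per species.

    Tracks the conditional-likelihood tensor of the ancestral-lineage
    process: the state space is (set partition of the samples into
    surviving lineages) x (nucleotide per lineage); backward mutation
    acts as a Kronecker sum of JC generators and each co-located lineage
    pair coalesces at rate 2/theta, merging tensor factors.  Epoch by
    epoch the functional is propagated by matrix exponentials; the root
    epoch uses the absorbing-limit linear solve.  The result is the full
    4^n joint distribution (rows sum to one), the oracle behind the
    flattening-rank property used by the SVD estimator.

    Returns (names, probs) with ``probs`` of shape (4,)*n in the
    (T, C, A, G) order.
    """
    names = sorted(m.topology.tips) if names is None else list(names)
    n = len(names)
    if n > 5:
        raise ValueError("exact pattern expectation supports <= 5 samples")

    parts = sorted(set(_set_partitions(tuple(range(n)))),
                   key=lambda p: (-len(p), sorted(map(sorted, p))))
    offsets = {}
    dim = 0
    for p in parts:
        offsets[p] = dim
        dim += 4 ** len(p)

    q_jc = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(q_jc, -1.0)

    def block_species(block) -> frozenset:
        return frozenset(names[i] for i in block)

    pops = [frozenset([t]) for t in sorted(m.topology.tips)] + \
        sorted(m.topology.internal_clades(), key=lambda c: (len(c), sorted(c)))

    def pop_of(species: frozenset, t0: float) -> frozenset:
        best = None
        for p in pops:
            if species <= p and (best is None or p < best):
                best = p
        while True:
            parent = _pop_parent(best)
            if parent is None or m.tau[parent] > t0 + 1e-300:
                return best
            best = parent

    def _pop_parent(p):
        best = None
        for q in m.topology.internal_clades():
            if p < q and (best is None or q < best):
                best = q
        return best

    def build_generator(t0: float) -> np.ndarray:
        g = np.zeros((dim, dim))
        for p in parts:
            blocks = sorted(p, key=sorted)
            k = len(blocks)
            off = offsets[p]
            # mutation: Kronecker sum of JC generators
            for bi in range(k):
                eye_l = 4 ** bi
                eye_r = 4 ** (k - bi - 1)
                kron = np.kron(np.kron(np.eye(eye_l), q_jc), np.eye(eye_r))
                g[off:off + 4 ** k, off:off + 4 ** k] += kron
            # coalescence between co-located blocks
            locs = [pop_of(block_species(b), t0) for b in blocks]
            for i in range(k):
                for j in range(i + 1, k):
                    if locs[i] != locs[j]:
                        continue
                    theta = m.theta.get(locs[i])
                    if theta is None:
                        raise ValueError(f"missing theta for population {sorted(locs[i])}")
                    lam = 2.0 / theta
                    merged = blocks[i] | blocks[j]
                    p2 = frozenset(b for a, b in enumerate(blocks) if a not in (i, j)) \
                        | frozenset([merged])
                    blocks2 = sorted(p2, key=sorted)
                    off2 = offsets[p2]
                    pos2 = blocks2.index(merged)
                    keep = [a for a in range(k) if a not in (i, j)]
                    for src in range(4 ** k):
                        digits = [(src // 4 ** (k - 1 - a)) % 4 for a in range(k)]
                        g[off + src, off + src] -= lam
                        if digits[i] != digits[j]:
                            continue
                        # target digits: kept blocks in blocks2 order
                        tgt_digits = []
                        for b2 in blocks2:
                            if b2 == merged:
                                tgt_digits.append(digits[i])
                            else:
                                tgt_digits.append(digits[blocks.index(b2)])
                        tgt = 0
                        for d in tgt_digits:
                            tgt = tgt * 4 + d
                        g[off2 + tgt, off + src] += lam
        return g

    # epochs from the species-tree node ages
    taus = sorted({0.0} | {m.tau[c] for c in m.topology.internal_clades()})
    root_t0 = taus[-1]

    # root epoch: phi^T = limit of pi-functional under exp(G t)
    g_root = build_generator(root_t0)
    single = next(p for p in parts if len(p) == 1)
    off1 = offsets[single]
    phi = np.zeros(dim)
    phi[off1:off1 + 4] = 0.25
    trans_idx = np.array([i for i in range(dim) if not (off1 <= i < off1 + 4)])
    g_tt = g_root[np.ix_(trans_idx, trans_idx)]
    g_st = g_root[np.ix_(np.arange(off1, off1 + 4), trans_idx)]
    # phi_trans = phi_single . G[single, trans] . (-G_trans)^{-1}
    rhs = phi[off1:off1 + 4] @ g_st
    phi_trans = np.linalg.solve(-g_tt.T, rhs)
    phi[trans_idx] = phi_trans

    # propagate down through the finite epochs
    for lo, hi_t in zip(taus[:-1][::-1], taus[1:][::-1]):
        g = build_generator(lo)
        phi = expm(g.T * (hi_t - lo)) @ phi

    singles = next(p for p in parts if len(p) == n)
    offn = offsets[singles]
    blocksn = sorted(singles, key=sorted)
    probs = phi[offn:offn + 4 ** n].reshape((4,) * n)
    # axes follow sorted singleton blocks = sorted sample indices = names order
    order = [blocksn.index(frozenset([i])) for i in range(n)]
    probs = np.transpose(probs, order)
    return names, probs
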