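"""Phylogenetic likelihood: JC/GTR+Gamma pruning, distances, ML trees.

The engine is deliberately small: site patterns are compressed once,
conditional likelihoods flow tip-to-root (Felsenstein pruning), and
among-site rate variation uses the mean-per-category discretisation of
the Gamma with 4 categories by default.  Trees are optimised by
coordinate-wise branch-length sweeps (Brent per branch, using cached
directional partials) until the log-likelihood improves by less than a
relative tolerance.

Maximum-likelihood gene trees are found exhaustively for small tip
counts and by NNI hill-climbing from a UPGMA start otherwise; branches
estimated below a collapse threshold (default 1e-6) are removed from
the reported split set, yielding polytomies.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import inf, log
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import average as _upgma_linkage
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import squareform
from scipy.stats import gamma as _gamma_dist

from .simulate import GeneTree, LocusModel, NUCLEOTIDES
from .trees import Topology, enumerate_rooted_topologies

__all__ = [
    "SitePatternCounts",
    "jc_distance",
    "jc_distance_matrix",
    "discrete_gamma_rates",
    "log_likelihood",
    "MLTree",
    "ml_gene_tree",
    "upgma_topology",
    "concat_ml",
    "concatenate",
    "rooted_clades_from_splits",
]

_CODE = {c: i for i, c in enumerate(NUCLEOTIDES)}
_AMBIG = 4  # anything not TCAG: gap or ambiguity -> full uncertainty


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, _AMBIG) for c in seq.upper()], dtype=np.int8)


@dataclass(frozen=True)
class SitePatternCounts:
    """Compressed alignment: unique site patterns with multiplicities.

    Collapsing identical columns is lossless for likelihoods that treat
    sites as i.i.d. given the tree.
    """

    names: tuple[str, ...]
    patterns: np.ndarray  # (n_tips, n_patterns) int8, 4 = ambiguous
    counts: np.ndarray  # (n_patterns,)

    @classmethod
    def from_alignment(cls, alignment: Mapping[str, str],
                       names: Sequence[str] | None = None) -> "SitePatternCounts":
        names = tuple(names if names is not None else sorted(alignment))
        mat = np.stack([_encode(alignment[n]) for n in names])
        patterns, counts = np.unique(mat, axis=1, return_counts=True)
        return cls(names=names, patterns=patterns, counts=counts.astype(float))

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    def restrict(self, names: Sequence[str]) -> "SitePatternCounts":
        idx = [self.names.index(n) for n in names]
        patterns, inv = np.unique(self.patterns[idx], axis=1, return_inverse=True)
        counts = np.zeros(patterns.shape[1])
        np.add.at(counts, inv, self.counts)
        return SitePatternCounts(tuple(names), patterns, counts)


# ---------------------------------------------------------------------------
# distances


def jc_distance(seq1: str, seq2: str) -> float:
    """JC69 distance d = -(3/4) ln(1 - 4p/3); sites with a gap or
    ambiguity in either sequence are skipped pairwise."""
    a, b = _encode(seq1), _encode(seq2)
    if a.size != b.size:
        raise ValueError("sequences must have equal length")
    ok = (a != _AMBIG) & (b != _AMBIG)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable sites")
    p = float((a[ok] != b[ok]).mean())
    if p >= 0.75:
        raise ValueError(f"saturated: mismatch proportion {p:.3f} >= 0.75")
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def jc_distance_matrix(alignment: Mapping[str, str],
                       names: Sequence[str] | None = None,
                       saturated: str = "raise") -> tuple[list[str], np.ndarray]:
    """Pairwise JC distances; ``saturated="cap"`` replaces saturated
    pairs (p >= 0.75) by a large finite distance instead of raising."""
    names = list(names if names is not None else sorted(alignment))
    n = len(names)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        try:
            dij = jc_distance(alignment[names[i]], alignment[names[j]])
        except ValueError:
            if saturated != "cap":
                raise
            dij = 10.0
        d[i, j] = d[j, i] = dij
    return names, d


# ---------------------------------------------------------------------------
# rates and transition probabilities


def discrete_gamma_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Mean-per-category discretisation of Gamma(alpha, alpha) into
    ``ncat`` equal-probability rate classes (overall mean 1)."""
    if not np.isfinite(alpha):
        return np.ones(1)
    edges = _gamma_dist.ppf(np.linspace(0, 1, ncat + 1), alpha, scale=1.0 / alpha)
    upper = _gamma_dist.cdf(edges, alpha + 1, scale=1.0 / alpha)
    means = (upper[1:] - upper[:-1]) * ncat
    return means


class _Engine:
    """Pruning-likelihood evaluator over an unrooted edge-labelled tree."""

    def __init__(self, spc: SitePatternCounts, lm: LocusModel, ncat: int = 4):
        self.spc = spc
        self.lm = lm
        self.pi = np.asarray(lm.pi)
        self.rates = discrete_gamma_rates(lm.alpha, ncat)
        lam, u, uinv = lm.eigensystem()
        self.lam, self.u, self.uinv = lam, u, uinv
        # tip partials: (tip, pattern, state)
        n, P = spc.patterns.shape
        tp = np.zeros((n, P, 4))
        for i in range(n):
            codes = spc.patterns[i]
            tp[i][codes == _AMBIG] = 1.0
            known = codes != _AMBIG
            tp[i, np.arange(P)[known], codes[known]] = 1.0
        self.tip_partials = tp

    def pmat(self, t: float) -> np.ndarray:
        """(ncat, 4, 4) transition matrices for branch length t."""
        if t <= 0:  # exact identity so impossible patterns get P = 0 exactly
            return np.broadcast_to(np.eye(4), (self.rates.size, 4, 4))
        e = np.exp(self.lam[None, :] * (t * self.rates)[:, None])  # (K,4)
        p = np.einsum("ik,ck,kj->cij", self.u, e, self.uinv)
        return np.clip(p, 0.0, None)

    def loglik_rooted(self, root, lengths: Mapping[frozenset, float]) -> float:
        """Pruning over a rooted nested-tuple tree; ``lengths`` keyed by
        the clade below each branch."""
        K = self.rates.size
        name_idx = {n: i for i, n in enumerate(self.spc.names)}

        def rec(node) -> tuple[np.ndarray, frozenset]:
            if isinstance(node, str):
                part = np.broadcast_to(self.tip_partials[name_idx[node]],
                                       (K,) + self.tip_partials[name_idx[node]].shape)
                return part, frozenset([node])
            pa, ca = rec(node[0])
            pb, cb = rec(node[1])
            pma = self.pmat(lengths[ca])
            pmb = self.pmat(lengths[cb])
            out = np.einsum("cij,cpj->cpi", pma, pa) * np.einsum("cij,cpj->cpi", pmb, pb)
            return out, ca | cb

        part, _ = rec(root)
        site = np.einsum("cpi,i->pc", part, self.pi).mean(axis=1)
        if np.any(site <= 0):
            return -inf
        return float(self.spc.counts @ np.log(site))


def log_likelihood(tree, lengths, alignment, lm: LocusModel | None = None,
                   ncat: int = 4) -> float:
    """Log-likelihood of an alignment on a tree with branch lengths.

    ``tree`` may be a :class:`Topology` plus a clade-keyed ``lengths``
    mapping, or a :class:`GeneTree` (``lengths=None``).  ``lm`` defaults
    to JC.  Returns -inf for zero-probability configurations.
    """
    if isinstance(tree, GeneTree):
        if lengths is not None:
            raise ValueError("lengths are implied by a GeneTree")
        lengths = tree.branch_lengths()
        tree = tree.topology
    lm = lm if lm is not None else LocusModel.jc()
    spc = alignment if isinstance(alignment, SitePatternCounts) else SitePatternCounts.from_alignment(alignment)
    missing = tree.tips - set(spc.names)
    if missing:
        raise ValueError(f"alignment lacks sequences for {sorted(missing)}")
    if set(spc.names) != tree.tips:
        spc = spc.restrict(sorted(tree.tips))
    eng = _Engine(spc, lm, ncat)
    return eng.loglik_rooted(tree.root, dict(lengths))


# ---------------------------------------------------------------------------
# unrooted ML trees


class _UnrootedTree:
    """Unrooted binary tree as adjacency over node ids with edge lengths."""

    def __init__(self, rooted: Topology, lengths: Mapping[frozenset, float] | None = None):
        self.tips: list[str] = sorted(rooted.tips)
        self.adj: dict[int, dict[int, float]] = {}
        self._tip_id = {n: i for i, n in enumerate(self.tips)}
        self._next = len(self.tips)
        root_children: list[tuple[int, float]] = []

        default = 0.05

        def add_edge(a, b, t):
            self.adj.setdefault(a, {})[b] = t
            self.adj.setdefault(b, {})[a] = t

        def rec(node) -> tuple[int, float]:
            if isinstance(node, str):
                clade = frozenset([node])
                t = lengths.get(clade, default) if lengths else default
                return self._tip_id[node], t
            clade = frozenset(node_tips(node))
            t = lengths.get(clade, default) if lengths else default
            me = self._next
            self._next += 1
            self.adj[me] = {}
            for ch in node:
                cid, ct = rec(ch)
                add_edge(me, cid, ct)
            return me, t

        def node_tips(node):
            if isinstance(node, str):
                yield node
            else:
                yield from node_tips(node[0])
                yield from node_tips(node[1])

        root = rooted.root
        a, ta = rec(root[0])
        b, tb = rec(root[1])
        add_edge(a, b, ta + tb)  # suppress the root

    def edges(self) -> list[tuple[int, int]]:
        return sorted({tuple(sorted((u, v))) for u in self.adj for v in self.adj[u]})

    def split_of(self, u: int, v: int) -> frozenset:
        """Tips on u's side of edge (u, v)."""
        seen = set()

        def rec(x, avoid):
            seen.add(x)
            for y in self.adj[x]:
                if y != avoid and y not in seen:
                    rec(y, x)

        rec(u, v)
        return frozenset(self.tips[i] for i in seen if i < len(self.tips))

    def splits_and_lengths(self) -> dict[frozenset, float]:
        out = {}
        for u, v in self.edges():
            s = self.split_of(u, v)
            s = min(s, frozenset(self.tips) - s, key=lambda x: (len(x), sorted(x)))
            out[s] = self.adj[u][v]
        return out

    def rooted_at_tip(self, tip: str | None = None) -> tuple[object, dict[frozenset, float]]:
        """Re-root on the branch incident to ``tip`` (default: first tip),
        returning (nested tuple, clade-keyed lengths)."""
        tip = tip if tip is not None else self.tips[0]
        tid = self._tip_id[tip]
        (nb, t0), = [(v, t) for v, t in self.adj[tid].items()]
        lengths: dict[frozenset, float] = {}

        def rec(x, avoid):
            if x < len(self.tips):
                return self.tips[x]
            children = []
            for y, t in self.adj[x].items():
                if y == avoid:
                    continue
                sub = rec(y, x)
                clade = frozenset(_nested_tips(sub))
                lengths[clade] = t
                children.append(sub)
            assert len(children) == 2
            return tuple(children)

        sub = rec(nb, tid)
        clade = frozenset(_nested_tips(sub))
        lengths[clade] = t0 / 2.0
        lengths[frozenset([tip])] = t0 / 2.0
        return (sub, tip), lengths

    def nni_neighbours(self) -> list["_UnrootedTree"]:
        """All trees one NNI away (2 per internal edge)."""
        out = []
        ntips = len(self.tips)
        for u, v in self.edges():
            if u < ntips or v < ntips:
                continue
            un = [x for x in self.adj[u] if x != v]
            vn = [x for x in self.adj[v] if x != u]
            for swap in (0, 1):
                t = self._copy()
                a, b = un[0], vn[swap]
                ta, tb = t.adj[u].pop(a), t.adj[v].pop(b)
                t.adj[a].pop(u), t.adj[b].pop(v)
                t.adj[u][b] = tb
                t.adj[b][u] = tb
                t.adj[v][a] = ta
                t.adj[a][v] = ta
                out.append(t)
        return out

    def _copy(self) -> "_UnrootedTree":
        t = object.__new__(_UnrootedTree)
        t.tips = self.tips
        t._tip_id = self._tip_id
        t._next = self._next
        t.adj = {u: dict(d) for u, d in self.adj.items()}
        return t


def _nested_tips(node):
    if isinstance(node, str):
        yield node
    else:
        yield from _nested_tips(node[0])
        yield from _nested_tips(node[1])


_MIN_BL, _MAX_BL = 1e-9, 8.0


def _optimise_branches(ut: _UnrootedTree, eng: _Engine, sweeps: int = 3,
                       rtol: float = 1e-8, max_extra: int = 12) -> float:
    """Coordinate-wise Brent over every branch, cached directional
    partials recomputed per edge; extra sweeps until relative
    improvement < ``rtol``."""
    name_idx = {n: i for i, n in enumerate(eng.spc.names)}
    K = eng.rates.size
    ntips = len(ut.tips)

    def message(src, dst, cache):
        """Partial likelihood of the subtree behind src, as seen by dst,
        *after* transporting across the (src, dst) edge is NOT applied;
        i.e. conditional on the state at src."""
        key = (src, dst)
        if key in cache:
            return cache[key]
        if src < ntips:
            tp = eng.tip_partials[name_idx[ut.tips[src]]]
            val = np.broadcast_to(tp, (K,) + tp.shape)
        else:
            val = None
            for nb, t in ut.adj[src].items():
                if nb == dst:
                    continue
                sub = message(nb, src, cache)
                pm = eng.pmat(t)
                piece = np.einsum("cij,cpj->cpi", pm, sub)
                val = piece if val is None else val * piece
        cache[key] = val
        return val

    def loglik_edge(u, v, t, cache):
        du = message(u, v, cache)
        dv = message(v, u, cache)
        pm = eng.pmat(t)
        site = np.einsum("i,cpi,cij,cpj->pc", eng.pi, du, pm, dv).mean(axis=1)
        with np.errstate(divide="ignore"):
            return float(eng.spc.counts @ np.log(np.clip(site, 1e-300, None)))

    prev = -inf
    for sweep in range(sweeps + max_extra):
        cache: dict = {}
        for u, v in ut.edges():
            t0 = ut.adj[u][v]
            res = minimize_scalar(
                lambda t: -loglik_edge(u, v, t, cache),
                bounds=(_MIN_BL, _MAX_BL), method="bounded",
                options={"xatol": 1e-10})
            if -res.fun >= loglik_edge(u, v, t0, cache):
                ut.adj[u][v] = ut.adj[v][u] = float(res.x)
                cache = {}  # directional partials through this edge are stale
        e0 = ut.edges()[0]
        cur = loglik_edge(e0[0], e0[1], ut.adj[e0[0]][e0[1]], {})
        if sweep >= sweeps - 1 and cur - prev <= rtol * max(1.0, abs(cur)):
            prev = cur
            break
        prev = cur
    return prev


@dataclass(frozen=True)
class MLTree:
    """Maximum-likelihood unrooted gene tree.

    ``splits`` is the post-collapse set of nontrivial bipartitions
    (each given as the smaller side); branches shorter than the
    collapse threshold are absent, so the tree may be polytomous.
    """

    tips: frozenset[str]
    splits: frozenset[frozenset[str]]
    lengths: Mapping[frozenset, float]
    loglik: float
    topology: Topology  # fully-resolved pre-collapse shape (arbitrary rooting)

    def rooted_clades(self, outgroup: str) -> frozenset[frozenset[str]]:
        return rooted_clades_from_splits(self.tips, self.splits, outgroup)


def rooted_clades_from_splits(tips: frozenset, splits: Iterable[frozenset],
                              outgroup: str) -> frozenset[frozenset[str]]:
    """Root an unrooted split system on the edge to ``outgroup``; return
    the clades of the ingroup rooted tree (tips included, root included)."""
    if outgroup not in tips:
        raise ValueError(f"outgroup {outgroup!r} not among tips")
    ingroup = frozenset(tips) - {outgroup}
    clades = {frozenset([t]) for t in ingroup} | {ingroup}
    for s in splits:
        side = s if outgroup not in s else frozenset(tips) - s
        if side != ingroup:
            clades.add(side)
    return frozenset(clades)


def upgma_topology(alignment: Mapping[str, str],
                   names: Sequence[str] | None = None) -> Topology:
    """Rooted UPGMA tree from JC distances (average-linkage clustering);
    clock-like data make this a cheap, sensible ML starting point."""
    names, d = jc_distance_matrix(alignment, names, saturated="cap")
    z = _upgma_linkage(squareform(d, checks=False))
    nodes: list[object] = list(names)
    for a, b, *_ in z:
        nodes.append((nodes[int(a)], nodes[int(b)]))
    return Topology(nodes[-1])


def ml_gene_tree(alignment: Mapping[str, str], lm: LocusModel | None = None,
                 search: str = "auto", ncat: int = 4,
                 collapse: float = 1e-6) -> MLTree:
    """ML unrooted gene tree with optimised branch lengths.

    ``search``: "exhaustive" scores every unrooted topology (feasible
    for <= 6 tips); "nni" hill-climbs from the UPGMA tree; "auto" picks
    exhaustive up to 5 tips.  Branches below ``collapse`` are removed
    from the reported splits (polytomies).
    """
    lm = lm if lm is not None else LocusModel.jc()
    names = sorted(alignment)
    if len(names) < 3:
        raise ValueError("need >= 3 sequences")
    spc = SitePatternCounts.from_alignment(alignment, names)
    eng = _Engine(spc, lm, ncat)
    if search == "auto":
        search = "exhaustive" if len(names) <= 5 else "nni"

    def finish(ut: _UnrootedTree, ll: float) -> MLTree:
        sl = ut.splits_and_lengths()
        splits = frozenset(s for s, t in sl.items()
                           if 1 < len(s) < len(names) - 1 and t >= collapse)
        root, lengths = ut.rooted_at_tip()
        return MLTree(tips=frozenset(names), splits=splits, lengths=sl,
                      loglik=ll, topology=Topology(root))

    if search == "exhaustive":
        # unrooted topologies over n tips = rooted topologies over n-1
        # tips with the first tip attached at the suppressed root
        first, rest = names[0], names[1:]
        best = None
        if len(rest) == 2:
            cands = [Topology(((rest[0], rest[1]), first))]
        else:
            cands = [Topology((t.root, first)) for t in enumerate_rooted_topologies(rest)]
        for cand in cands:
            ut = _UnrootedTree(cand)
            ll = _optimise_branches(ut, eng)
            if best is None or ll > best[1]:
                best = (ut, ll)
        return finish(*best)

    if search != "nni":
        raise ValueError("search must be 'auto', 'exhaustive' or 'nni'")
    start = upgma_topology(alignment, names)
    ut = _UnrootedTree(start)
    ll = _optimise_branches(ut, eng)
    improved = True
    while improved:
        improved = False
        for nb in ut.nni_neighbours():
            ll2 = _optimise_branches(nb, eng, sweeps=2)
            if ll2 > ll + 1e-9:
                ut, ll = nb, ll2
                improved = True
                break
    return finish(ut, ll)


# ---------------------------------------------------------------------------
# concatenation


def concatenate(loci) -> dict[str, str]:
    """Merge per-name sequences across loci into one supermatrix."""
    if not loci:
        raise ValueError("no loci")
    alns = [l.alignment if hasattr(l, "alignment") else l for l in loci]
    names = set(alns[0])
    for a in alns:
        if set(a) != names:
            raise ValueError("inconsistent sequence names across loci")
    return {n: "".join(a[n] for a in alns) for n in sorted(names)}


def concat_ml(loci, candidates: Sequence[Topology],
              lm: LocusModel | None = None, ncat: int = 4) -> list[tuple[Topology, float]]:
    """Rank candidate species topologies by concatenated ML.

    Candidates must be rooted trees over exactly the alignment names;
    each is evaluated unrooted with free branch lengths and the list is
    returned best first.
    """
    lm = lm if lm is not None else LocusModel.jc()
    sup = concatenate(loci)
    spc = SitePatternCounts.from_alignment(sup)
    eng = _Engine(spc, lm, ncat)
    scored = []
    for cand in candidates:
        if cand.tips != set(spc.names):
            raise ValueError("candidate tips must match alignment names")
        ut = _UnrootedTree(cand)
        ll = _optimise_branches(ut, eng)
        scored.append((cand, ll))
    scored.sort(key=lambda x: (-x[1], x[0].newick()))
    return scored
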