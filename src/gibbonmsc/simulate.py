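"""Synthetic multilocus data under the multispecies coalescent.

Gene trees are drawn by the standard structured-coalescent recursion:
within a population with k lineages the next coalescence is
Exponential with rate k(k-1)/theta (time in expected substitutions per
site, pair rate 2/theta), the coalescing pair is uniform, and
uncoalesced lineages propagate to the parent population.  Sequences
then evolve down the genealogy under JC or a per-locus GTR+Gamma model
whose parameters are drawn from the study's locus-heterogeneity
regimes:

* ``noncoding`` — base frequencies ~ Dirichlet(44.8, 30.5, 44.8, 30.6),
  exchangeabilities ~ Dirichlet(10, 5, 5, 5, 5, 10) (transition /
  transversion ratio kappa ~= 2), site-rate shape alpha ~ Gamma(100, 20)
  (mean 5); locus length 1,000 bp.
* ``coding`` — Dirichlet(11.7, 11.4, 11.7, 11.3), same exchangeabilities,
  alpha ~ Gamma(100, 50) (mean 2); locus length 200 bp.

An isolation-with-migration variant for three species allows gene flow
between the two ingroup species back to their divergence time, with
``M_ij = N_j * m_ij`` immigrants per generation translating to a
per-lineage backward migration rate ``4*M_ij/theta_j`` per unit
mutation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf, isinf
from typing import Iterable, Mapping

import numpy as np

from .trees import SpeciesTreeModel, Topology, write_newick

__all__ = [
    "NUCLEOTIDES",
    "SampleConfig",
    "LocusModel",
    "SimulationRegime",
    "NONCODING_REGIME",
    "CODING_REGIME",
    "GeneTree",
    "Locus",
    "IMTripletParams",
    "simulate_gene_tree",
    "draw_locus_model",
    "simulate_alignment",
    "simulate_dataset",
    "simulate_im_gene_tree",
    "write_phylip",
    "write_fasta",
    "write_gene_trees",
]

#: State order follows the (T, C, A, G) convention of the GTR
#: parameterisation in which exchangeabilities a..f are
#: TC, TA, TG, CA, CG, AG (a and f are the transitions).
NUCLEOTIDES = "TCAG"


@dataclass(frozen=True)
class SampleConfig:
    """How many sequences are sampled per species, and the locus shape.

    The genomic design this emulates used two diploid individuals
    (four phased haplotypes) for B, S and N, one individual each for
    Hm and Hp, and a single outgroup sequence — 17 sequences per locus
    across 12,413 noncoding loci of 1,000 bp or 11,323 coding loci of
    200 bp.  Desk-scale runs use fewer sequences and loci.
    """

    samples: Mapping[str, int]
    n_loci: int = 100
    sites: int = 1000

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", dict(self.samples))
        if any(v < 1 for v in self.samples.values()):
            raise ValueError("sample counts must be >= 1")
        if self.n_loci < 0 or self.sites < 1:
            raise ValueError("invalid locus count or length")

    def sequence_names(self, species: str) -> list[str]:
        k = self.samples[species]
        return [species] if k == 1 else [f"{species}_{i+1}" for i in range(k)]


@dataclass(frozen=True)
class LocusModel:
    """Per-locus substitution model: GTR exchangeabilities + Gamma rates.

    ``pi`` orders base frequencies as (T, C, A, G); ``exch`` orders the
    six exchangeabilities as (TC, TA, TG, CA, CG, AG).  ``alpha`` is
    the shape of the among-site rate Gamma (mean 1); ``inf`` means
    rate-homogeneous.  The rate matrix is normalised to mean rate 1.
    """

    pi: tuple[float, float, float, float]
    exch: tuple[float, float, float, float, float, float]
    alpha: float = inf

    def __post_init__(self) -> None:
        pi = tuple(float(x) for x in self.pi)
        if len(pi) != 4 or any(x <= 0 for x in pi) or abs(sum(pi) - 1) > 1e-9:
            raise ValueError("pi must be 4 positive frequencies summing to 1")
        if any(x < 0 for x in self.exch):
            raise ValueError("exchangeabilities must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "exch", tuple(float(x) for x in self.exch))

    @classmethod
    def jc(cls) -> "LocusModel":
        return cls(pi=(0.25,) * 4, exch=(1.0,) * 6, alpha=inf)

    @property
    def is_jc(self) -> bool:
        return (
            max(self.pi) - min(self.pi) < 1e-12
            and max(self.exch) - min(self.exch) < 1e-12
            and isinf(self.alpha)
        )

    def rate_matrix(self) -> np.ndarray:
        """GTR generator Q with stationary distribution pi, mean rate 1."""
        a, b, c, d, e, f = self.exch
        s = np.array(
            [[0, a, b, c],
             [a, 0, d, e],
             [b, d, 0, f],
             [c, e, f, 0]], dtype=float)
        pi = np.asarray(self.pi)
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(eigenvalues, U, U^-1) of Q via the symmetrised form, so that
        P(t) = U diag(exp(lambda t)) U^-1 row-stochastically."""
        q = self.rate_matrix()
        pi = np.asarray(self.pi)
        sq = np.sqrt(pi)
        sym = q * sq[:, None] / sq[None, :]
        lam, w = np.linalg.eigh((sym + sym.T) / 2.0)
        u = w / sq[:, None]
        uinv = w.T * sq[None, :]
        return lam, u, uinv

    def kappa(self) -> float:
        """Transition/transversion exchangeability ratio: the mean of the
        two transition exchangeabilities (TC, AG) over the mean of the
        four transversion exchangeabilities."""
        a, b, c, d, e, f = self.exch
        return float(((a + f) / 2.0) / ((b + c + d + e) / 4.0))


@dataclass(frozen=True)
class SimulationRegime:
    """Hyperparameters for among-locus substitution heterogeneity."""

    name: str
    pi_concentration: tuple[float, float, float, float]
    exch_concentration: tuple[float, float, float, float, float, float]
    alpha_shape: float
    alpha_rate: float
    sites: int = 1000

    def mean_alpha(self) -> float:
        return self.alpha_shape / self.alpha_rate


NONCODING_REGIME = SimulationRegime(
    "noncoding", (44.8, 30.5, 44.8, 30.6), (10, 5, 5, 5, 5, 10), 100.0, 20.0, sites=1000
)
CODING_REGIME = SimulationRegime(
    "coding", (11.7, 11.4, 11.7, 11.3), (10, 5, 5, 5, 5, 10), 100.0, 50.0, sites=200
)


def draw_locus_model(reg: SimulationRegime, rng: np.random.Generator) -> LocusModel:
    """Independent draw of (pi, exchangeabilities, alpha) for one locus."""
    pi = rng.dirichlet(reg.pi_concentration)
    exch = rng.dirichlet(reg.exch_concentration)
    alpha = rng.gamma(reg.alpha_shape, 1.0 / reg.alpha_rate)
    return LocusModel(pi=tuple(pi), exch=tuple(exch), alpha=float(alpha))


# ---------------------------------------------------------------------------
# gene trees


@dataclass(frozen=True)
class GeneTree:
    """Rooted coalescent genealogy with node ages (substitutions/site)
    and, for each coalescence, the species-tree population it occurred
    in (keyed by the clade of sequence names below the node)."""

    topology: Topology
    ages: Mapping[frozenset, float]
    populations: Mapping[frozenset, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ages", {frozenset(k): float(v) for k, v in self.ages.items()})
        object.__setattr__(self, "populations", dict(self.populations))
        for c in self.topology.internal_clades():
            if c not in self.ages:
                raise ValueError(f"missing age for clade {sorted(c)}")

    def age(self, clade: frozenset) -> float:
        return 0.0 if len(clade) == 1 else self.ages[clade]

    def branch_lengths(self) -> dict[frozenset, float]:
        """Length of the branch above each non-root node."""
        out: dict[frozenset, float] = {}

        def rec(node, parent_age: float | None):
            clade = frozenset([node]) if isinstance(node, str) else frozenset(_leaves(node))
            age = self.age(clade)
            if parent_age is not None:
                out[clade] = parent_age - age
            if not isinstance(node, str):
                rec(node[0], age)
                rec(node[1], age)

        rec(self.topology.root, None)
        return out

    def newick(self, precision: int = 10) -> str:
        return write_newick(self.topology, self.branch_lengths(), precision=precision)

    def validate(self, model: SpeciesTreeModel | None = None) -> None:
        """Assert rootward-increasing ages and, when a species tree is
        given, that every coalescence is in an ancestral population
        containing its age."""
        for c in self.topology.internal_clades():
            for d in self.topology.internal_clades():
                if d < c and not self.ages[d] < self.ages[c]:
                    raise AssertionError("node ages must increase rootward")
        if model is None:
            return
        for c in self.topology.internal_clades():
            pop = self.populations.get(c)
            if pop is None:
                continue
            sp = {name.split("_")[0] for name in c}
            if not sp <= set(pop):
                raise AssertionError("coalescence population must contain both children")
            lo = model.node_age(pop)
            parent = model.parent_clade(pop)
            hi = model.tau[parent] if parent is not None else inf
            if not (lo <= self.ages[c] <= hi):
                raise AssertionError("coalescence age outside its population's span")


def simulate_gene_tree(m: SpeciesTreeModel, s: SampleConfig,
                       rng: np.random.Generator) -> GeneTree:
    """One genealogy under the MSC on ``m`` with ``s`` samples per species."""
    top = m.topology
    ages: dict[frozenset, float] = {}
    pops: dict[frozenset, frozenset] = {}

    def coalesce(lineages: list, t0: float, t1: float, theta: float, pop: frozenset):
        t = t0
        while len(lineages) >= 2:
            k = len(lineages)
            t += rng.exponential(theta / (k * (k - 1)))
            if t > t1:
                return
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[i], lineages[j]
            merged = (a, b)
            clade = frozenset(_leaves(merged))
            ages[clade] = t
            pops[clade] = pop
            lineages[:] = [x for idx, x in enumerate(lineages) if idx not in (i, j)]
            lineages.append(merged)

    def rec(node) -> list:
        """Lineages surviving to the top of the branch above ``node``."""
        if isinstance(node, str):
            lineages = list(s.sequence_names(node))
            clade = frozenset([node])
        else:
            lineages = rec(node[0]) + rec(node[1])
            clade = frozenset(_leaves(node))
        t0 = m.node_age(clade)
        parent = m.parent_clade(clade)
        t1 = m.tau[parent] if parent is not None else inf
        if len(lineages) >= 2:
            theta = m.theta.get(clade)
            if theta is None:
                raise ValueError(f"theta needed for population {sorted(clade)}")
            coalesce(lineages, t0, t1, theta, clade)
        return lineages

    survivors = rec(top.root)
    assert len(survivors) == 1
    return GeneTree(Topology(survivors[0]), ages, pops)


def _leaves(node):
    if isinstance(node, str):
        yield node
    else:
        yield from _leaves(node[0])
        yield from _leaves(node[1])


# ---------------------------------------------------------------------------
# sequence evolution


def simulate_alignment(g: GeneTree, lm: LocusModel, length: int,
                       rng: np.random.Generator) -> dict[str, str]:
    """Evolve ``length`` i.i.d. sites down the gene tree.

    Each site gets a Gamma(alpha, 1/alpha) rate multiplier (continuous
    gamma; alpha = inf means constant rate).  The root state is drawn
    from the stationary distribution and the chain is applied branch by
    branch via the eigendecomposition of Q.
    """
    pi = np.asarray(lm.pi)
    lam, u, uinv = lm.eigensystem()
    rates = (np.ones(length) if isinf(lm.alpha)
             else rng.gamma(lm.alpha, 1.0 / lm.alpha, size=length))

    seqs: dict[str, str] = {}
    root_states = rng.choice(4, size=length, p=pi)
    lut = np.array(list(NUCLEOTIDES))

    def evolve(states: np.ndarray, t: float) -> np.ndarray:
        if t <= 0:
            return states.copy()
        # per-site transition probabilities P(t * r)[parent_state, :]
        e = np.exp(np.outer(lam, t * rates))  # (4, L)
        w = uinv[:, states] * e  # (4, L)
        probs = u @ w  # (4, L): P(x -> y) for y rows
        probs = np.clip(probs, 0.0, None)
        probs /= probs.sum(axis=0, keepdims=True)
        cum = np.cumsum(probs, axis=0)
        r = rng.random(length)
        return (r[None, :] > cum[:-1]).sum(axis=0)

    def rec(node, states: np.ndarray) -> None:
        if isinstance(node, str):
            seqs[node] = "".join(lut[states])
            return
        clade = frozenset(_leaves(node))
        age = g.age(clade)
        for child in node:
            cclade = frozenset([child]) if isinstance(child, str) else frozenset(_leaves(child))
            t = age - g.age(cclade)
            rec(child, evolve(states, t))

    rec(g.topology.root, root_states)
    return seqs


@dataclass(frozen=True)
class Locus:
    alignment: Mapping[str, str]
    gene_tree: GeneTree
    model: LocusModel


def simulate_dataset(m: SpeciesTreeModel, s: SampleConfig,
                     reg: SimulationRegime | None, n_loci: int,
                     rng: np.random.Generator,
                     sites: int | None = None) -> list[Locus]:
    """Independent loci: gene tree + alignment (+ the locus model used).

    ``reg=None`` simulates every locus under JC (the study's "JC data"
    design); otherwise per-locus GTR+Gamma parameters are drawn from
    the regime.  True gene trees are retained for oracle tests.
    """
    sites = sites if sites is not None else (reg.sites if reg is not None else s.sites)
    out = []
    for _ in range(n_loci):
        lm = LocusModel.jc() if reg is None else draw_locus_model(reg, rng)
        gt = simulate_gene_tree(m, s, rng)
        aln = simulate_alignment(gt, lm, sites, rng)
        out.append(Locus(alignment=aln, gene_tree=gt, model=lm))
    return out


# ---------------------------------------------------------------------------
# isolation with migration (three species)


@dataclass(frozen=True)
class IMTripletParams:
    """Three-species isolation-with-migration block for ((A, B), C).

    Times and thetas in substitutions/site; ``m_ab`` is the expected
    number of immigrants per generation into B from A (``M_AB = N_B *
    m``), and symmetrically for ``m_ba``.  ``m_ab = m_ba = 0`` is the
    pure-isolation model M0; the two extra rates give model M2.
    """

    tau_abc: float
    tau_ab: float
    theta_abc: float
    theta_ab: float
    theta_a: float
    theta_b: float
    m_ab: float = 0.0
    m_ba: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.tau_ab < self.tau_abc:
            raise ValueError("need 0 < tau_AB < tau_ABC")
        if min(self.theta_abc, self.theta_ab, self.theta_a, self.theta_b) <= 0:
            raise ValueError("thetas must be > 0")
        if self.m_ab < 0 or self.m_ba < 0:
            raise ValueError("migration rates must be >= 0")

    @property
    def is_m0(self) -> bool:
        return self.m_ab == 0.0 and self.m_ba == 0.0

    def with_migration(self, m_ab: float, m_ba: float) -> "IMTripletParams":
        return IMTripletParams(self.tau_abc, self.tau_ab, self.theta_abc,
                               self.theta_ab, self.theta_a, self.theta_b, m_ab, m_ba)


_CONFIG_SAMPLES = {"ABC": ("a", "b", "c"), "AAC": ("a1", "a2", "c"), "BBC": ("b1", "b2", "c")}


def simulate_im_gene_tree(p: IMTripletParams, config: str,
                          rng: np.random.Generator) -> GeneTree:
    """Structured-coalescent draw with migration between A and B.

    Backward in time a lineage in population j jumps to i at rate
    ``4*M_ij/theta_j``; co-located pairs coalesce at rate ``2/theta``.
    Migration operates between the present and tau_AB only.
    """
    if config not in _CONFIG_SAMPLES:
        raise ValueError(f"config must be one of {sorted(_CONFIG_SAMPLES)}")
    names = _CONFIG_SAMPLES[config]
    ages: dict[frozenset, float] = {}
    pops: dict[frozenset, frozenset] = {}
    popkey = {"A": frozenset("a"), "B": frozenset("b"),
              "AB": frozenset("ab"), "ABC": frozenset("abc")}

    # epoch 1: populations A and B with migration, from 0 back to tau_AB
    loc: dict[object, str] = {}
    for nm in names[:2]:
        loc[nm] = "A" if nm.startswith("a") else "B"
    rate_a_to_b = 4.0 * p.m_ba / p.theta_a  # lineage in A jumps to B
    rate_b_to_a = 4.0 * p.m_ab / p.theta_b
    t = 0.0
    while len(loc) > 1:
        in_a = [x for x, l in loc.items() if l == "A"]
        in_b = [x for x, l in loc.items() if l == "B"]
        ca = len(in_a) * (len(in_a) - 1) / p.theta_a
        cb = len(in_b) * (len(in_b) - 1) / p.theta_b
        mig = len(in_a) * rate_a_to_b + len(in_b) * rate_b_to_a
        total = ca + cb + mig
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= p.tau_ab:
            break
        u = rng.random() * total
        if u < ca:
            pair = rng.choice(len(in_a), size=2, replace=False)
            a, b = in_a[pair[0]], in_a[pair[1]]
            merged = (a, b)
            clade = frozenset(_leaves(merged))
            ages[clade], pops[clade] = t, popkey["A"]
            del loc[a], loc[b]
            loc[merged] = "A"
        elif u < ca + cb:
            pair = rng.choice(len(in_b), size=2, replace=False)
            a, b = in_b[pair[0]], in_b[pair[1]]
            merged = (a, b)
            clade = frozenset(_leaves(merged))
            ages[clade], pops[clade] = t, popkey["B"]
            del loc[a], loc[b]
            loc[merged] = "B"
        else:
            u -= ca + cb
            if u < len(in_a) * rate_a_to_b:
                x = in_a[int(u / rate_a_to_b)] if rate_a_to_b > 0 else in_a[0]
                loc[x] = "B"
            else:
                u -= len(in_a) * rate_a_to_b
                x = in_b[int(u / rate_b_to_a)] if rate_b_to_a > 0 else in_b[0]
                loc[x] = "A"

    # epoch 2: ancestral AB population, tau_AB .. tau_ABC
    lineages = list(loc.keys())
    t = p.tau_ab
    while len(lineages) >= 2:
        k = len(lineages)
        t += rng.exponential(p.theta_ab / (k * (k - 1)))
        if t >= p.tau_abc:
            break
        i, j = rng.choice(k, size=2, replace=False)
        merged = (lineages[i], lineages[j])
        clade = frozenset(_leaves(merged))
        ages[clade], pops[clade] = t, popkey["AB"]
        lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)] + [merged]

    # epoch 3: root population with the outgroup lineage, tau_ABC .. inf
    lineages.append(names[2])
    t = p.tau_abc
    while len(lineages) >= 2:
        k = len(lineages)
        t += rng.exponential(p.theta_abc / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        merged = (lineages[i], lineages[j])
        clade = frozenset(_leaves(merged))
        ages[clade], pops[clade] = t, popkey["ABC"]
        lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)] + [merged]

    return GeneTree(Topology(lineages[0]), ages, pops)


# ---------------------------------------------------------------------------
# writers


def write_phylip(alignment: Mapping[str, str]) -> str:
    """Sequential PHYLIP with padded names."""
    names = list(alignment)
    L = len(next(iter(alignment.values())))
    width = max(10, max(len(n) for n in names) + 2)
    lines = [f" {len(names)} {L}"]
    lines += [f"{n:<{width}}{alignment[n]}" for n in names]
    return "\n".join(lines) + "\n"


def write_fasta(alignment: Mapping[str, str]) -> str:
    return "".join(f">{n}\n{s}\n" for n, s in alignment.items())


def write_gene_trees(trees: Iterable[GeneTree]) -> str:
    """One Newick per line."""
    return "".join(t.newick() + "\n" for t in trees)
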