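"""Bayesian MSC inference on a fixed species tree, bpp-A00 style.

The state is (tau, theta, per-locus gene trees); the target is

    p(theta) p(tau) p(G | tau, theta) L(D | G)^beta

with gamma priors on every theta and on the root age tau0, the other
node ages uniform on the admissible region given tau0, the MSC density
for the gene trees, and a JC sequence likelihood (beta < 1 gives the
power posteriors used for path-sampling marginal likelihoods; beta = 0
or ``no_data=True`` leaves the prior, which is how the sampler itself
is validated).

Proposals, cycled every iteration and auto-tuned during burn-in to
~30% acceptance:

* per-locus gene-tree node-age slides (uniform window, reflected);
* per-locus subtree exchanges (swap two non-nested subtrees whose
  parents are old enough), which traverse gene-tree topology space;
* multiplicative random walks on each theta;
* joint theta-and-event-ages scaling per population (mixes theta
  through regimes where pinned coalescences would otherwise trap it);
* tau updates with the rubber-band remap of gene-tree node ages in the
  affected interval (piecewise-linear, Jacobian included), with an
  extra bold root-age multiplier;
* a whole-state rescaling ("mixing") move.

Everything is desk-scale: a few hundred loci with <= 8 sequences each
run in minutes, which is the regime the package's simulation studies
use.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from math import exp, inf, lgamma, log
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._kernels import coal_logdensity_kernel, jc_loglik_kernel
from .likelihood import SitePatternCounts
from .simulate import SampleConfig, simulate_gene_tree
from .trees import SpeciesTreeModel, Topology

__all__ = [
    "PriorSpec",
    "MCMCSettings",
    "PowerSchedule",
    "PosteriorSample",
    "a00_mcmc",
    "summarize_posterior",
    "power_posterior_logml",
    "rank_candidate_trees",
]


@dataclass(frozen=True)
class PriorSpec:
    """Gamma priors: theta ~ G(shape, rate) for every population and
    tau0 ~ G(shape, rate) for the root age; non-root ages uniform given
    tau0."""

    theta_shape: float = 2.0
    theta_rate: float = 1000.0
    tau_shape: float = 1.6
    tau_rate: float = 100.0

    @classmethod
    def noncoding(cls) -> "PriorSpec":
        return cls(2.0, 1000.0, 1.6, 100.0)

    @classmethod
    def coding(cls) -> "PriorSpec":
        return cls(2.0, 2000.0, 2.0, 200.0)

    def log_theta(self, x: float) -> float:
        a, b = self.theta_shape, self.theta_rate
        return a * log(b) - lgamma(a) + (a - 1) * log(x) - b * x

    def log_tau0(self, x: float) -> float:
        a, b = self.tau_shape, self.tau_rate
        return a * log(b) - lgamma(a) + (a - 1) * log(x) - b * x


@dataclass(frozen=True)
class MCMCSettings:
    """Chain lengths follow the source study's defaults scaled to desk
    size; the full-scale run used burn-in 1e5 and 2e4 samples at
    frequency 10."""

    burnin: int = 2000
    samples: int = 2000
    sample_freq: int = 2
    seed: int = 0
    tune_interval: int = 100
    n_exchange: int = 2  # subtree-exchange attempts per locus per iteration


@dataclass(frozen=True)
class PowerSchedule:
    """Beta ladder for power posteriors with quadrature weights.

    The default is the power-spaced midpoint rule beta_k =
    ((k - 1/2) / K)^(1/a) with a = 0.3, which concentrates points near
    beta = 0 where the integrand moves fastest under diffuse priors;
    the marginal-likelihood integral over beta then uses the matching
    d(beta)/dz weights.
    """

    betas: tuple[float, ...]
    weights: tuple[float, ...]

    @classmethod
    def power_midpoint(cls, k: int = 16, a: float = 0.3) -> "PowerSchedule":
        z = (np.arange(1, k + 1) - 0.5) / k
        betas = z ** (1.0 / a)
        weights = (1.0 / k) * (1.0 / a) * z ** (1.0 / a - 1.0)
        return cls(tuple(betas), tuple(weights))

    def integrate(self, mean_logliks: Sequence[float]) -> float:
        if len(mean_logliks) != len(self.betas):
            raise ValueError("one mean log-likelihood per beta required")
        return float(np.dot(self.weights, mean_logliks))


# ---------------------------------------------------------------------------
# species-tree bookkeeping


class _SpeciesFrame:
    """Immutable shape information for the fixed species topology."""

    def __init__(self, topology: Topology):
        self.topology = topology
        self.tips = sorted(topology.tips)
        self.internals = sorted(topology.internal_clades(), key=lambda c: (len(c), sorted(c)))
        self.root = topology.tips
        self.pops = [frozenset([t]) for t in self.tips] + list(self.internals)
        self.parent: dict[frozenset, frozenset | None] = {}
        for p in self.pops:
            best = None
            for q in self.internals:
                if p < q and (best is None or q < best):
                    best = q
            self.parent[p] = best
        self.children: dict[frozenset, list[frozenset]] = {p: [] for p in self.pops}
        for p in self.pops:
            if self.parent[p] is not None:
                self.children[self.parent[p]].append(p)
        # integer encoding for the density kernel (children precede parents)
        self.pop_index = {p: i for i, p in enumerate(self.pops)}
        self.pop_parent_idx = np.array(
            [self.pop_index[self.parent[p]] if self.parent[p] is not None else -1
             for p in self.pops], dtype=np.int64)
        self.pop_order_idx = np.arange(len(self.pops), dtype=np.int64)

    def tau_arrays(self, tau) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([0.0 if len(p) == 1 else tau[p] for p in self.pops])
        hi = np.array([lo[self.pop_parent_idx[i]] if self.pop_parent_idx[i] >= 0 else np.inf
                       for i in range(len(self.pops))])
        return lo, hi

    def theta_array(self, theta) -> np.ndarray:
        return np.array([theta.get(p, -1.0) for p in self.pops])

    def mrca_pop(self, species: frozenset) -> frozenset:
        best = None
        for p in self.pops:
            if species <= p and (best is None or p < best):
                best = p
        return best


# ---------------------------------------------------------------------------
# per-locus gene-tree state


class _LocusState:
    """Mutable array-backed gene tree + cached JC pruning."""

    def __init__(self, names: Sequence[str], species: Sequence[str],
                 spc: SitePatternCounts | None):
        n = len(names)
        self.n = n
        self.names = list(names)
        self.species = list(species)
        total = 2 * n - 1
        self.parent = np.full(total, -1, dtype=int)
        self.left = np.full(total, -1, dtype=int)
        self.right = np.full(total, -1, dtype=int)
        self.age = np.zeros(total)
        self.root = total - 1
        self.spc = spc
        if spc is not None:
            self.tipcode = np.stack(
                [spc.patterns[spc.names.index(nm)] for nm in names]).astype(np.int8)
            self.counts = spc.counts.astype(np.float64)

    _sets_cache: list | None = None
    _mrca_cache: dict | None = None
    _postorder_cache: list | None = None

    def invalidate_topology(self) -> None:
        self._sets_cache = None
        self._mrca_cache = None
        self._postorder_cache = None
        self._post_int = None
        self._node_pop0 = None

    def set_from_genetree(self, gt) -> None:
        self.invalidate_topology()
        idx = {frozenset([nm]): i for i, nm in enumerate(self.names)}
        cursor = self.n

        def rec(node) -> int:
            nonlocal cursor
            if isinstance(node, str):
                return idx[frozenset([node])]
            a = rec(node[0])
            b = rec(node[1])
            me = cursor
            cursor += 1
            self.left[me], self.right[me] = a, b
            self.parent[a] = self.parent[b] = me
            clade = frozenset(self._tipnames(a)) | frozenset(self._tipnames(b))
            self.age[me] = gt.ages[clade]
            return me

        root = rec(gt.topology.root)
        self.parent[root] = -1
        self.root = root

    def _tipnames(self, i: int):
        if i < self.n:
            yield self.names[i]
        else:
            yield from self._tipnames(self.left[i])
            yield from self._tipnames(self.right[i])

    def internal_nodes(self) -> np.ndarray:
        return np.arange(self.n, 2 * self.n - 1)

    def species_sets(self) -> list[frozenset]:
        """Species set below each node (index-aligned; cached until the
        topology changes)."""
        if self._sets_cache is not None:
            return self._sets_cache
        out: list[frozenset | None] = [None] * (2 * self.n - 1)
        for i in range(self.n):
            out[i] = frozenset([self.species[i]])

        def rec(i):
            if out[i] is None:
                out[i] = rec(self.left[i]) | rec(self.right[i])
            return out[i]

        rec(self.root)
        self._sets_cache = out  # type: ignore
        return out  # type: ignore

    def mrca_pops(self, frame) -> dict[int, frozenset]:
        """Species-MRCA population of each internal gene node (cached)."""
        if self._mrca_cache is None:
            sets = self.species_sets()
            self._mrca_cache = {int(i): frame.mrca_pop(sets[i])
                                for i in self.internal_nodes()}
        return self._mrca_cache

    def postorder(self) -> list[int]:
        if self._postorder_cache is None:
            order: list[int] = []

            def rec(i):
                if i >= self.n:
                    rec(self.left[i])
                    rec(self.right[i])
                order.append(i)

            rec(self.root)
            self._postorder_cache = order
        return self._postorder_cache

    def is_ancestor(self, a: int, b: int) -> bool:
        while b != -1:
            if b == a:
                return True
            b = self.parent[b]
        return False

    # JC pruning (numba kernel) -------------------------------------------
    def loglik(self) -> float:
        if self.spc is None:
            return 0.0
        post = self._post_internal()
        return float(jc_loglik_kernel(post, self.left, self.right, self.age,
                                      self.tipcode, self.counts, self.n))

    def _post_internal(self) -> np.ndarray:
        if getattr(self, "_post_int", None) is None:
            self._post_int = np.array([i for i in self.postorder() if i >= self.n],
                                      dtype=np.int64)
        return self._post_int

    def node_pop0(self, frame) -> np.ndarray:
        """Species-MRCA population index for internal nodes n..2n-2."""
        if getattr(self, "_node_pop0", None) is None:
            mrca = self.mrca_pops(frame)
            self._node_pop0 = np.array(
                [frame.pop_index[mrca[i]] for i in range(self.n, 2 * self.n - 1)],
                dtype=np.int64)
        return self._node_pop0


# ---------------------------------------------------------------------------
# MSC coalescent density


def _coal_logdensity(loc: _LocusState, frame: _SpeciesFrame,
                     tau: Mapping[frozenset, float],
                     theta: Mapping[frozenset, float],
                     arrays=None) -> float:
    """MSC log-density of the locus gene tree given (tau, theta); -inf
    for incompatible states.  ``arrays`` may carry precomputed
    (lo, hi, theta_vec) to amortise over loci."""
    if arrays is None:
        lo, hi = frame.tau_arrays(tau)
        th = frame.theta_array(theta)
    else:
        lo, hi, th = arrays
    if getattr(loc, "_k_base", None) is None:
        k = np.zeros(len(frame.pops), dtype=np.int64)
        for sp in loc.species:
            k[frame.pop_index[frozenset([sp])]] += 1
        loc._k_base = k
    ages = loc.age[loc.n:]
    return float(coal_logdensity_kernel(ages, loc.node_pop0(frame),
                                        frame.pop_parent_idx, frame.pop_order_idx,
                                        lo, hi, th, loc._k_base))


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorSample:
    """Thinned MCMC sample: one row per retained iteration."""

    frame_topology: Topology
    table: pd.DataFrame  # columns tau:<clade>, theta:<clade>, loglik, logprior
    acceptance: Mapping[str, float]
    settings: MCMCSettings

    def column(self, kind: str, clade) -> np.ndarray:
        return self.table[f"{kind}:{','.join(sorted(clade))}"].to_numpy()


def _ckey(kind: str, clade: frozenset) -> str:
    return f"{kind}:{','.join(sorted(clade))}"


# ---------------------------------------------------------------------------
# the sampler


def a00_mcmc(loci, topology: Topology, priors: PriorSpec,
             settings: MCMCSettings, *, species_map: Callable[[str], str] | None = None,
             beta: float = 1.0, no_data: bool = False,
             theta_pops: Sequence[frozenset] | None = None) -> PosteriorSample:
    """Sample (tau, theta, gene trees) on a fixed species topology.

    ``loci`` is a sequence of alignments (mappings name -> sequence) or
    objects with an ``alignment`` attribute.  Sequence names map to
    species by ``species_map`` (default: strip a trailing "_k").
    ``no_data`` forces the likelihood to 1, turning the sampler into a
    prior sampler (the standard MCMC validation); ``beta`` powers the
    likelihood for path sampling.
    """
    rng = np.random.default_rng(settings.seed)
    frame = _SpeciesFrame(topology)
    smap = species_map if species_map is not None else (lambda n: n.split("_")[0])

    alns = [l.alignment if hasattr(l, "alignment") else l for l in loci]
    if not alns:
        raise ValueError("no loci")
    states: list[_LocusState] = []
    for aln in alns:
        names = sorted(aln)
        species = [smap(n) for n in names]
        bad = set(species) - set(frame.tips)
        if bad:
            raise ValueError(f"species {sorted(bad)} not in the species tree")
        spc = None if no_data else SitePatternCounts.from_alignment(aln, names)
        states.append(_LocusState(names, species, spc))

    # population set that needs a theta: any pop that can hold >= 2 lineages
    if theta_pops is None:
        need = set(frame.internals)
        for st in states:
            cnt = Counter(st.species)
            for sp, k in cnt.items():
                if k >= 2:
                    need.add(frozenset([sp]))
        theta_pops = sorted(need, key=lambda c: (len(c), sorted(c)))

    # initial parameters: prior means, taus staggered by clade size
    theta = {p: priors.theta_shape / priors.theta_rate for p in theta_pops}
    tau0 = priors.tau_shape / priors.tau_rate
    tau: dict[frozenset, float] = {}
    s = len(frame.tips)
    for c in frame.internals:
        tau[c] = tau0 * (0.3 + 0.7 * (len(c) - 1) / (s - 1))
    tau[frame.root] = tau0

    # initial gene trees simulated from the MSC at the initial parameters
    full_theta = dict(theta)
    for p in frame.pops:
        full_theta.setdefault(p, priors.theta_shape / priors.theta_rate)
    init_model = SpeciesTreeModel(topology, tau, full_theta)
    for st in states:
        cnt = Counter(st.species)
        cfg = SampleConfig({sp: k for sp, k in cnt.items()}, n_loci=1, sites=1)
        gt = simulate_gene_tree(init_model, cfg, rng)
        # simulate_gene_tree names tips "sp" or "sp_i"; remap to actual names
        by_species: dict[str, list[str]] = {}
        for nm, sp in zip(st.names, st.species):
            by_species.setdefault(sp, []).append(nm)
        counters = {sp: 0 for sp in by_species}
        mapping = {}
        for nm in gt.topology.tips:
            sp = nm.split("_")[0]
            mapping[nm] = by_species[sp][counters[sp]]
            counters[sp] += 1
        gt2 = type(gt)(gt.topology.relabel(mapping),
                       {frozenset(mapping[n] for n in k): v for k, v in gt.ages.items()})
        st.set_from_genetree(gt2)

    coal = [_coal_logdensity(st, frame, tau, theta) for st in states]
    lik = [0.0 if no_data else st.loglik() for st in states]
    if any(c == -inf for c in coal):
        raise RuntimeError("invalid initial state")

    def log_tau_prior() -> float:
        lp = priors.log_tau0(tau[frame.root])
        for c in frame.internals:
            if c == frame.root:
                continue
            par = frame.parent[c]
            if not tau[c] < tau[par]:
                return -inf
        # uniform on ratios given tau0: density ~ (s-2)!/tau0^(s-2)
        n_free = len(frame.internals) - 1
        return lp - n_free * log(tau[frame.root]) + lgamma(n_free + 1)

    def log_theta_prior() -> float:
        return sum(priors.log_theta(v) for v in theta.values())

    # tunable step sizes
    steps = {"age": tau0 * 0.2, "theta": 0.5, "tau": tau0 * 0.05,
             "root": 0.3, "mix": 0.2, "thscale": 0.8}
    acc = {k: [0, 0] for k in [*steps, "root_bold"]}

    def tune() -> None:
        for k, (a, n) in acc.items():
            if k not in steps or n < 20:
                continue
            rate = a / n
            steps[k] *= exp(1.5 * (rate - 0.3))
            acc[k] = [0, 0]

    lam = beta if not no_data else 0.0

    def mh(delta_logpost: float) -> bool:
        return delta_logpost >= 0 or rng.random() < exp(max(delta_logpost, -700))

    def locus_update(li: int, arrays) -> None:
        st = states[li]
        # node-age slides
        for node in st.internal_nodes():
            lo_children = max(st.age[st.left[node]], st.age[st.right[node]])
            if node == st.root:
                gap = st.age[node] - lo_children
                c = exp(0.7 * (rng.random() - 0.5))
                new = lo_children + gap * c
                log_hastings = log(c)
            else:
                hi_node = st.age[st.parent[node]]
                w = steps["age"]
                new = st.age[node] + w * (rng.random() - 0.5)
                # reflect into (lo_children, hi_node)
                span = hi_node - lo_children
                if span <= 0:
                    continue
                y = (new - lo_children) % (2 * span)
                new = lo_children + (y if y <= span else 2 * span - y)
                log_hastings = 0.0
            old = st.age[node]
            st.age[node] = new
            c2 = _coal_logdensity(st, frame, tau, theta, arrays)
            l2 = 0.0 if no_data else st.loglik()
            d = (c2 - coal[li]) + lam * (l2 - lik[li]) + log_hastings
            acc["age"][1] += 1
            if c2 > -inf and mh(d):
                coal[li], lik[li] = c2, l2
                acc["age"][0] += 1
            else:
                st.age[node] = old

        # subtree exchanges
        for _ in range(settings.n_exchange):
            nodes = [i for i in range(2 * st.n - 1) if i != st.root]
            a, b = rng.choice(len(nodes), size=2, replace=False)
            a, b = nodes[a], nodes[b]
            if st.is_ancestor(a, b) or st.is_ancestor(b, a):
                continue
            pa, pb = st.parent[a], st.parent[b]
            if pa == pb:
                continue
            if st.age[pa] <= st.age[b] or st.age[pb] <= st.age[a]:
                continue
            # swap attachments (symmetric given the uniform pair choice)
            for p, old_c, new_c in ((pa, a, b), (pb, b, a)):
                if st.left[p] == old_c:
                    st.left[p] = new_c
                else:
                    st.right[p] = new_c
            st.parent[a], st.parent[b] = pb, pa
            st.invalidate_topology()
            c2 = _coal_logdensity(st, frame, tau, theta, arrays)
            l2 = 0.0 if no_data else st.loglik()
            d = (c2 - coal[li]) + lam * (l2 - lik[li])
            if c2 > -inf and mh(d):
                coal[li], lik[li] = c2, l2
            else:  # revert
                for p, old_c, new_c in ((pa, b, a), (pb, a, b)):
                    if st.left[p] == old_c:
                        st.left[p] = new_c
                    else:
                        st.right[p] = new_c
                st.parent[a], st.parent[b] = pa, pb
                st.invalidate_topology()

    def theta_update() -> None:
        nonlocal coal
        lo, hi = frame.tau_arrays(tau)
        for p in theta_pops:
            old = theta[p]
            c = exp(steps["theta"] * (rng.random() - 0.5))
            theta[p] = old * c
            arrays = (lo, hi, frame.theta_array(theta))
            c2 = [_coal_logdensity(st, frame, tau, theta, arrays) for st in states]
            d = (sum(c2) - sum(coal)
                 + priors.log_theta(theta[p]) - priors.log_theta(old) + log(c))
            acc["theta"][1] += 1
            if all(x > -inf for x in c2) and mh(d):
                coal = c2
                acc["theta"][0] += 1
            else:
                theta[p] = old

    def theta_scale_update() -> None:
        """Joint move: scale theta_p and the ages of the coalescent events
        inside population p by a common factor.  The coalescent density
        is nearly invariant along this ridge, so the move mixes theta
        through regimes where events pin it (e.g. unidentifiable short
        branches)."""
        nonlocal coal, lik
        lo_arr, hi_arr = frame.tau_arrays(tau)
        for p in theta_pops:
            pidx = frame.pop_index[p]
            lo_p, hi_p = lo_arr[pidx], hi_arr[pidx]
            c = exp(steps["thscale"] * (rng.random() - 0.5))
            moved = []
            ok = True
            for li2, st in enumerate(states):
                npop0 = st.node_pop0(frame)
                for k, i in enumerate(range(st.n, 2 * st.n - 1)):
                    pop = npop0[k]
                    a = st.age[i]
                    while hi_arr[pop] <= a:
                        pop = frame.pop_parent_idx[pop]
                    if pop != pidx:
                        continue
                    new_age = lo_p + (a - lo_p) * c
                    if new_age >= hi_p:
                        ok = False
                        break
                    moved.append((li2, st, i, a, new_age))
                if not ok:
                    break
            if not ok:
                continue
            old_theta = theta[p]
            theta[p] = old_theta * c
            touched = set()
            for li2, st, i, _, new_age in moved:
                st.age[i] = new_age
                touched.add(li2)
            arrays = (lo_arr, hi_arr, frame.theta_array(theta))
            c2 = [_coal_logdensity(st, frame, tau, theta, arrays) for st in states]
            l2 = (lik if no_data else
                  [st.loglik() if li2 in touched else lik[li2]
                   for li2, st in enumerate(states)])
            d = (sum(c2) - sum(coal) + lam * (sum(l2) - sum(lik))
                 + priors.log_theta(theta[p]) - priors.log_theta(old_theta)
                 + (len(moved) + 1) * log(c))
            acc["thscale"][1] += 1
            if all(x > -inf for x in c2) and mh(d):
                coal, lik = c2, l2
                acc["thscale"][0] += 1
            else:
                theta[p] = old_theta
                for li2, st, i, a, _ in moved:
                    st.age[i] = a

    def rubber_band(v: frozenset, new_tau: float) -> tuple[float, list]:
        """Remap gene node ages for the tau_v change; returns (log-Jacobian,
        undo list)."""
        t_l = max((tau[c] for c in frame.children[v] if len(c) > 1), default=0.0)
        par = frame.parent[v]
        t_u = tau[par] if par is not None else inf
        old_tau = tau[v]
        undo = []
        logj = 0.0
        for li, st in enumerate(states):
            sets = st.species_sets()
            for i in st.internal_nodes():
                if not sets[i] <= v:
                    continue
                y = st.age[i]
                if y <= t_l or y >= t_u:
                    continue
                if y < old_tau:
                    scale = (new_tau - t_l) / (old_tau - t_l)
                    ynew = t_l + (y - t_l) * scale
                elif t_u == inf:
                    # above the root age: rigid shift keeps the map an
                    # involution-consistent bijection of (t_l, inf)
                    scale = 1.0
                    ynew = y + (new_tau - old_tau)
                else:
                    scale = (t_u - new_tau) / (t_u - old_tau)
                    ynew = t_u - (t_u - y) * scale
                undo.append((st, i, y))
                st.age[i] = ynew
                logj += log(scale)
        return logj, undo

    def tau_update(bold_root: bool = False) -> None:
        nonlocal coal, lik
        for v in frame.internals:
            if bold_root and frame.parent[v] is not None:
                continue  # bold pass touches only the root age
            t_l = max((tau[c] for c in frame.children[v] if len(c) > 1), default=0.0)
            par = frame.parent[v]
            old = tau[v]
            if par is None:
                gap = old - t_l
                width = 2.5 if bold_root else steps["root"]
                c = exp(width * (rng.random() - 0.5))
                new = t_l + gap * c
                log_hastings = log(c)
                key = "root_bold" if bold_root else "root"
            else:
                t_u = tau[par]
                span = t_u - t_l
                if span <= 0:
                    continue
                w = min(steps["tau"], span)
                new = old + w * (rng.random() - 0.5)
                y = (new - t_l) % (2 * span)
                new = t_l + (y if y <= span else 2 * span - y)
                log_hastings = 0.0
                key = "tau"
            logj, undo = rubber_band(v, new)
            tau[v] = new
            arrays = (*frame.tau_arrays(tau), frame.theta_array(theta))
            c2 = [_coal_logdensity(st, frame, tau, theta, arrays) for st in states]
            # likelihoods change only where the rubber band moved an age
            touched = {id(st) for st, _, _ in undo}
            l2 = (lik if no_data else
                  [st.loglik() if id(st) in touched else lik[li2]
                   for li2, st in enumerate(states)])
            lp_new = log_tau_prior()
            tau[v] = old
            lp_old = log_tau_prior()
            tau[v] = new
            d = (sum(c2) - sum(coal) + lam * (sum(l2) - sum(lik))
                 + lp_new - lp_old + log_hastings + logj)
            acc[key][1] += 1
            if all(x > -inf for x in c2) and lp_new > -inf and mh(d):
                coal, lik = c2, l2
                acc[key][0] += 1
            else:
                tau[v] = old
                for st, i, y in undo:
                    st.age[i] = y

    def mixing_update() -> None:
        nonlocal coal, lik, tau0
        c = exp(steps["mix"] * (rng.random() - 0.5))
        n_scaled = len(frame.internals)
        old_tau = dict(tau)
        for v in tau:
            tau[v] *= c
        old_ages = []
        for st in states:
            ages = st.age[st.internal_nodes()].copy()
            old_ages.append(ages)
            st.age[st.internal_nodes()] = ages * c
            n_scaled += st.n - 1
        arrays = (*frame.tau_arrays(tau), frame.theta_array(theta))
        c2 = [_coal_logdensity(st, frame, tau, theta, arrays) for st in states]
        l2 = lik if no_data else [st.loglik() for st in states]
        lp_new = log_tau_prior()
        tau_backup = dict(tau)
        tau.clear()
        tau.update(old_tau)
        lp_old = log_tau_prior()
        tau.clear()
        tau.update(tau_backup)
        d = (sum(c2) - sum(coal) + lam * (sum(l2) - sum(lik))
             + lp_new - lp_old + n_scaled * log(c))
        acc["mix"][1] += 1
        if all(x > -inf for x in c2) and mh(d):
            coal, lik = c2, l2
            acc["mix"][0] += 1
        else:
            tau.clear()
            tau.update(old_tau)
            for st, ages in zip(states, old_ages):
                st.age[st.internal_nodes()] = ages

    # main loop
    rows = []
    total_iters = settings.burnin + settings.samples * settings.sample_freq
    for it in range(total_iters):
        iter_arrays = (*frame.tau_arrays(tau), frame.theta_array(theta))
        for li in range(len(states)):
            locus_update(li, iter_arrays)
        theta_update()
        theta_scale_update()
        tau_update()
        tau_update(bold_root=True)
        mixing_update()
        in_burnin = it < settings.burnin
        if in_burnin and (it + 1) % settings.tune_interval == 0:
            tune()
        if not in_burnin and (it - settings.burnin + 1) % settings.sample_freq == 0:
            row = {_ckey("tau", c): tau[c] for c in frame.internals}
            row.update({_ckey("theta", p): theta[p] for p in theta_pops})
            row["loglik"] = sum(lik)
            row["logprior"] = log_tau_prior() + log_theta_prior() + sum(coal)
            rows.append(row)

    rates = {k: (a / n if n else 0.0) for k, (a, n) in acc.items()}
    return PosteriorSample(frame_topology=topology, table=pd.DataFrame(rows),
                           acceptance=rates, settings=settings)


# ---------------------------------------------------------------------------
# summaries


def summarize_posterior(sample: PosteriorSample,
                        ci: float = 0.95) -> pd.DataFrame:
    """Posterior means and equal-tail CIs for every parameter, plus the
    coalescent-unit length 2*dtau/theta of each internal branch, both
    transform-then-average and the plug-in of posterior means."""
    if sample.table.empty:
        raise ValueError("empty sample")
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    rows = []
    tbl = sample.table
    for col in tbl.columns:
        if col in ("loglik", "logprior"):
            continue
        x = tbl[col].to_numpy()
        rows.append({"parameter": col, "mean": x.mean(),
                     f"q{lo_q:.3f}": np.quantile(x, lo_q),
                     f"q{hi_q:.3f}": np.quantile(x, hi_q)})
    top = sample.frame_topology
    frame = _SpeciesFrame(top)
    for c in frame.internals:
        if c == frame.root:
            continue
        par = frame.parent[c]
        tkey, pkey, thkey = _ckey("tau", c), _ckey("tau", par), _ckey("theta", c)
        if thkey not in tbl.columns:
            continue
        t = 2.0 * (tbl[pkey].to_numpy() - tbl[tkey].to_numpy()) / tbl[thkey].to_numpy()
        plug = 2.0 * (tbl[pkey].mean() - tbl[tkey].mean()) / tbl[thkey].mean()
        rows.append({"parameter": f"coalunits:{','.join(sorted(c))}",
                     "mean": t.mean(),
                     f"q{lo_q:.3f}": np.quantile(t, lo_q),
                     f"q{hi_q:.3f}": np.quantile(t, hi_q),
                     "plug_in": plug})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# marginal likelihood by path sampling


def power_posterior_logml(loci, topology: Topology, priors: PriorSpec,
                          schedule: PowerSchedule, settings: MCMCSettings,
                          **kwargs) -> tuple[float, pd.DataFrame]:
    """Thermodynamic-integration log marginal likelihood.

    Runs one chain per beta targeting prior x likelihood^beta, records
    the mean log-likelihood per beta and integrates over the schedule.
    Returns (log-ML, per-beta table with Monte-Carlo standard errors).
    """
    means, ses = [], []
    for i, b in enumerate(schedule.betas):
        s = replace(settings, seed=settings.seed + 1000 * i + 1)
        post = a00_mcmc(loci, topology, priors, s, beta=float(b), **kwargs)
        x = post.table["loglik"].to_numpy()
        means.append(float(x.mean()))
        # crude batch-means standard error
        nb = max(len(x) // 20, 1)
        bm = np.array_split(x, nb)
        ses.append(float(np.std([np.mean(c) for c in bm], ddof=1) / np.sqrt(nb))
                   if nb > 1 else float("nan"))
    logml = schedule.integrate(means)
    table = pd.DataFrame({"beta": schedule.betas, "weight": schedule.weights,
                          "mean_loglik": means, "mc_se": ses})
    return logml, table


def rank_candidate_trees(loci, candidates: Mapping[int, Topology],
                         priors: PriorSpec, schedule: PowerSchedule,
                         settings: MCMCSettings, **kwargs) -> pd.DataFrame:
    """Log marginal likelihood per candidate topology; posterior
    probabilities assume a uniform prior over the candidates."""
    rows = []
    for key, top in candidates.items():
        logml, _ = power_posterior_logml(loci, top, priors, schedule, settings, **kwargs)
        rows.append({"candidate": key, "topology": top.newick(), "log_ml": logml})
    df = pd.DataFrame(rows).sort_values("log_ml", ascending=False).reset_index(drop=True)
    rel = df["log_ml"] - df["log_ml"].max()
    w = np.exp(rel)
    df["posterior"] = w / w.sum()
    return df
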