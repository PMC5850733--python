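"""Three-species MSC likelihood with and without gene flow, and the LRT.

The model follows the species tree ((A, B), C): divergence times
``tau_AB < tau_ABC`` and population sizes ``theta`` for A, B, AB and
ABC, all in expected substitutions/site.  Model M0 has no migration;
M2 adds rates ``M_AB`` and ``M_BA`` (expected immigrants per
generation, ``M_ij = N_j m_ij``) acting between the present and
``tau_AB``.

Each locus has three sequences in configuration ABC, AAC or BBC.  The
likelihood sums over the three rooted gene-tree topologies and
integrates the two coalescent ages (cherry age t1, root age t0)
against their density.  The density factorises by epoch, so the double
integral splits into products of one-dimensional pieces handled by
Gauss-Legendre quadrature (32 points per dimension by default) after
mapping each piece to [0, 1] through the relevant CDF.  Under M2 the
pre-divergence epoch is a lineage-location Markov chain (states: both
lineages in A, one in each, both in B, plus absorption by coalescence)
whose transition probabilities come from 3x3 matrix exponentials.

Sequence likelihoods are JC with a molecular clock: for three
sequences only five site-pattern classes matter, with closed-form
probabilities in (t1, t0).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import chi2

from .simulate import IMTripletParams

__all__ = [
    "IMTripletParams",
    "TripletLocus",
    "TripletDataset",
    "LRTResult",
    "pattern_class_counts",
    "m0_loglik",
    "m2_loglik",
    "fit",
    "lrt_migration",
    "build_triplet_dataset",
]

_N_GL = 32

# site-pattern classes for sequences (s1, s2, s3):
# 0 xxx, 1 xxy (s1=s2), 2 xyx (s1=s3), 3 yxx (s2=s3), 4 xyz
_CLASS_NAMES = ("xxx", "xxy", "xyx", "yxx", "xyz")


def pattern_class_counts(seqs: Sequence[str]) -> np.ndarray:
    """Counts of the five 3-sequence site-pattern classes; sites with a
    non-ACGT character in any sequence are skipped."""
    if len(seqs) != 3:
        raise ValueError("need exactly 3 sequences")
    a, b, c = (np.frombuffer(s.upper().encode(), dtype="S1") for s in seqs)
    acgt = np.frombuffer(b"ACGT", dtype="S1")
    valid = np.isin(a, acgt) & np.isin(b, acgt) & np.isin(c, acgt)
    a, b, c = a[valid], b[valid], c[valid]
    ab, ac, bc = a == b, a == c, b == c
    counts = np.array([
        (ab & ac).sum(),
        (ab & ~ac).sum(),
        (ac & ~ab).sum(),
        (bc & ~ab).sum(),
        (~ab & ~ac & ~bc).sum(),
    ], dtype=float)
    return counts


@dataclass(frozen=True)
class TripletLocus:
    config: str  # ABC | AAC | BBC
    counts: np.ndarray  # 5 pattern-class counts

    def __post_init__(self) -> None:
        if self.config not in ("ABC", "AAC", "BBC"):
            raise ValueError("config must be ABC, AAC or BBC")
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))


@dataclass(frozen=True)
class TripletDataset:
    """Per-locus pattern-class counts with configuration labels.

    The study design draws three sequences per locus with half the
    loci in configuration ABC, a quarter AAC and a quarter BBC.
    """

    loci: tuple[TripletLocus, ...]

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("empty dataset")

    @classmethod
    def from_alignments(cls, items: Iterable[tuple[str, Sequence[str]]]) -> "TripletDataset":
        return cls(tuple(TripletLocus(cfg, pattern_class_counts(seqs))
                         for cfg, seqs in items))

    def stacked(self) -> dict[str, np.ndarray]:
        """Config -> (n_loci, 5) count matrix."""
        out = {}
        for cfg in ("ABC", "AAC", "BBC"):
            rows = [l.counts for l in self.loci if l.config == cfg]
            if rows:
                out[cfg] = np.stack(rows)
        return out


# ---------------------------------------------------------------------------
# JC pattern-class probabilities for a clock triple


def _jc_log_class_probs(t1: np.ndarray, t0: np.ndarray) -> np.ndarray:
    """log probabilities of the five representative site patterns for a
    gene tree with cherry (s1, s2) at age t1 and root at age t0.

    Returned per *representative pattern* (so a class with multiplicity
    m has total probability m * exp(value)); shape (..., 5).
    """
    t1 = np.asarray(t1, dtype=float)
    t0 = np.asarray(t0, dtype=float)

    def peq(t):
        return 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)

    # transition probability between specific states x -> y
    def pmat(t):
        e = peq(t)
        return e, (1.0 - e) / 3.0  # (equal, different)

    eq_c, df_c = pmat(t1)        # cherry tip branches, length t1
    eq_i, df_i = pmat(t0 - t1)   # internal branch
    eq_w, df_w = pmat(t0)        # outsider branch

    reps = [(0, 0, 0), (0, 0, 1), (0, 1, 0), (1, 0, 0), (0, 1, 2)]
    out = np.empty(t1.shape + (5,))
    for pi, (i, j, k) in enumerate(reps):
        tot = 0.0
        for r in range(4):
            pk = eq_w if r == k else df_w
            for a in range(4):
                pa = eq_i if r == a else df_i
                pi_ = eq_c if a == i else df_c
                pj_ = eq_c if a == j else df_c
                tot = tot + 0.25 * pa * pi_ * pj_ * pk
        out[..., pi] = np.log(tot)
    return out


# role maps: observed class counts (xxx, s1s2, s1s3, s2s3, xyz) reordered so
# that index 1 is "cherry pair equal" for each gene-tree topology
_ROLE = {
    (0, 1): (0, 1, 2, 3, 4),  # cherry (s1, s2)
    (0, 2): (0, 2, 1, 3, 4),  # cherry (s1, s3)
    (1, 2): (0, 3, 2, 1, 4),  # cherry (s2, s3) [slots 1<->3; slot 2 symmetric]
}


def _log_pattern_matrix(counts: np.ndarray, cherry: tuple[int, int],
                        logp: np.ndarray) -> np.ndarray:
    """(n_loci, n_nodes) log P(data | t1, t0) for a given cherry."""
    perm = _ROLE[cherry]
    return counts[:, list(perm)] @ logp.reshape(-1, 5).T


# ---------------------------------------------------------------------------
# quadrature pieces


@lru_cache(maxsize=16)
def _gl_unit(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


@lru_cache(maxsize=16)
def _laguerre(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.laguerre.laggauss(n)


def _exp_nodes(rate: float, lo: float, hi: float, n: int):
    """Nodes/log-weights for integrating h(t) against the exponential
    density rate*exp(-rate(t-lo)) over (lo, hi).

    Infinite upper limit: Gauss-Laguerre in x = rate*(t-lo), whose
    weight is exactly the density — geometric convergence for
    exponentially-decaying h.  Finite interval: CDF-substituted
    Gauss-Legendre (the integrand is then smooth on a closed interval).
    Weights sum to the interval's probability mass.
    """
    if np.isinf(hi):
        x, w = _laguerre(n)
        return lo + x / rate, np.log(w)
    z, w = _gl_unit(n)
    mass = -np.expm1(-rate * (hi - lo))
    if mass <= 0:
        return np.full(n, lo), np.full(n, -np.inf)
    t = lo - np.log1p(-z * mass) / rate
    return t, np.log(w * mass)


# ---------------------------------------------------------------------------
# epoch-1 models (present back to tau_AB)


def _epoch1_m0(p: IMTripletParams, config: str, n: int):
    """(t1 nodes, log|weights|, signs, log-survival) for coalescence
    before tau_AB without migration."""
    if config == "ABC":
        return np.empty(0), np.empty(0), np.empty(0), 0.0
    theta = p.theta_a if config == "AAC" else p.theta_b
    rate = 2.0 / theta
    t, logw = _exp_nodes(rate, 0.0, p.tau_ab, n)
    log_surv = -rate * p.tau_ab
    return t, logw, np.ones_like(logw), log_surv


def _epoch1_m2(p: IMTripletParams, config: str, n: int):
    """Same contract as :func:`_epoch1_m0` but lineage locations follow
    the backward migration chain.

    The coalescence-time density is a three-term exponential mixture
    (the chain generator is tridiagonal, hence real eigenvalues); each
    term gets its own CDF-matched Gauss-Legendre rule, which keeps the
    quadrature exact-in-the-density whatever the rate magnitudes.  Mixture
    coefficients can be negative, so weights carry signs.
    """
    ra = 4.0 * p.m_ba / p.theta_a  # lineage in A jumps to B (backward)
    rb = 4.0 * p.m_ab / p.theta_b
    ca, cb = 2.0 / p.theta_a, 2.0 / p.theta_b
    # transient states: (2,0), (1,1), (0,2)
    q = np.array([
        [-(2 * ra + ca), 2 * ra, 0.0],
        [rb, -(ra + rb), ra],
        [0.0, 2 * rb, -(2 * rb + cb)],
    ])
    iinit = {"ABC": 1, "AAC": 0, "BBC": 2}[config]
    init = np.zeros(3)
    init[iinit] = 1.0
    cvec = np.array([ca, 0.0, cb])
    lam, v = np.linalg.eig(q)
    lam = np.real(lam)
    v = np.real(v)
    coef = (init @ v) * (np.linalg.solve(v, cvec))  # density = sum c_k e^{lam_k t}
    surv = float((init @ expm(q * p.tau_ab)).sum())

    ts_all, logw_all, sign_all = [], [], []
    z, w = _gl_unit(n)
    for b_k, lam_k in zip(coef, lam):
        mu = max(-lam_k, 1e-12)
        if abs(b_k) < 1e-300:
            continue
        t, logw = _exp_nodes(mu, 0.0, p.tau_ab, n)
        ts_all.append(t)
        logw_all.append(logw + np.log(abs(b_k) / mu))
        sign_all.append(np.full(n, np.sign(b_k)))
    log_surv = np.log(max(surv, 1e-300))
    if not ts_all:
        return np.empty(0), np.empty(0), np.empty(0), log_surv
    return (np.concatenate(ts_all), np.concatenate(logw_all),
            np.concatenate(sign_all), log_surv)


# ---------------------------------------------------------------------------
# full likelihood


def _config_loglik(counts: np.ndarray, p: IMTripletParams, config: str,
                   n_gl: int, epoch1) -> np.ndarray:
    """Per-locus log-likelihood for loci sharing one configuration.

    ``counts`` is (n_loci, 5); the cherry formed by any pre-root
    coalescence is always (s1, s2) for ABC/AAC/BBC sampling order.
    """
    tau1, tau0 = p.tau_ab, p.tau_abc
    r_ab = 2.0 / p.theta_ab
    r_root2 = 2.0 / p.theta_abc
    r_root3 = 6.0 / p.theta_abc

    pieces = []  # [(mat (n_loci, nodes), signs (nodes,))]

    # t0 nodes shared by every pre-root-coalescence branch
    t0_nodes, t0_logw = _exp_nodes(r_root2, tau0, np.inf, n_gl)

    def cherry12_piece(t1_nodes, t1_logw, t1_signs):
        if t1_nodes.size == 0:
            return
        tt1 = np.repeat(t1_nodes, n_gl)
        tt0 = np.tile(t0_nodes, t1_nodes.size)
        logw = (np.repeat(t1_logw, n_gl) + np.tile(t0_logw, t1_nodes.size))
        signs = np.repeat(t1_signs, n_gl)
        logp = _jc_log_class_probs(tt1, tt0)
        mat = _log_pattern_matrix(counts, (0, 1), logp)
        pieces.append((mat + logw[None, :], signs))

    # epoch 1 (AAC/BBC always; ABC only with migration)
    t1e, logwe, signse, log_surv1 = epoch1(p, config, n_gl)
    cherry12_piece(t1e, logwe, signse)

    # epoch 2: coalescence in AB between tau1 and tau0
    t1m, logwm = _exp_nodes(r_ab, tau1, tau0, n_gl)
    cherry12_piece(t1m, logwm + log_surv1, np.ones_like(logwm))

    # epoch 3: all three lineages in the root population
    log_surv2 = log_surv1 - r_ab * (tau0 - tau1)
    x_nodes, x_logw = _exp_nodes(r_root3, tau0, np.inf, n_gl)
    y_nodes, y_logw = _exp_nodes(r_root2, 0.0, np.inf, n_gl)
    tt1 = np.repeat(x_nodes, n_gl)
    tt0 = tt1 + np.tile(y_nodes, n_gl)
    logw = (np.repeat(x_logw, n_gl) + np.tile(y_logw, n_gl)
            + log_surv2 - np.log(3.0))
    logp = _jc_log_class_probs(tt1, tt0)
    for cherry in ((0, 1), (0, 2), (1, 2)):
        pieces.append((_log_pattern_matrix(counts, cherry, logp) + logw[None, :],
                       np.ones(logw.size)))

    allp = np.concatenate([m for m, _ in pieces], axis=1)
    allsign = np.concatenate([s for _, s in pieces])
    # manual signed log-sum-exp (hot path)
    mx = allp.max(axis=1, keepdims=True)
    total = (np.exp(allp - mx) * allsign[None, :]).sum(axis=1)
    if np.any(total <= 0):  # numerically impossible for a true likelihood
        raise FloatingPointError("signed quadrature lost positivity")
    return mx[:, 0] + np.log(total)


def _total_loglik(data: TripletDataset, p: IMTripletParams, n_gl: int, epoch1) -> float:
    total = 0.0
    for cfg, counts in data.stacked().items():
        total += float(_config_loglik(counts, p, cfg, n_gl, epoch1).sum())
    return total


def m0_loglik(data: TripletDataset, p: IMTripletParams, n_gl: int = _N_GL) -> float:
    """Log-likelihood under the no-gene-flow model M0 (closed-form
    exponential epoch densities)."""
    if not p.is_m0:
        raise ValueError("M0 requires M_AB = M_BA = 0; use m2_loglik")
    return _total_loglik(data, p, n_gl, _epoch1_m0)


def m2_loglik(data: TripletDataset, p: IMTripletParams, n_gl: int = _N_GL) -> float:
    """Log-likelihood under the gene-flow model M2 (migration-coalescence
    Markov chain before tau_AB); reduces to M0 at M = 0."""
    return _total_loglik(data, p, n_gl, _epoch1_m2)


# ---------------------------------------------------------------------------
# fitting and the LRT


@dataclass(frozen=True)
class FitResult:
    params: IMTripletParams
    loglik: float
    converged: bool
    n_starts: int


@dataclass(frozen=True)
class LRTResult:
    """2*delta-loglik referred to chi-squared with df = 2 (the boundary
    at M = 0 makes the test conservative under this convention)."""

    l0: float
    l2: float
    fit0: FitResult
    fit2: FitResult
    statistic: float
    df: int
    p_value: float

    def significant(self, level: float = 0.01) -> bool:
        return self.p_value < level


_BOUNDS_TAU0 = (1e-5, 0.2)
_BOUNDS_FRAC = (1e-3, 0.995)
_BOUNDS_THETA = (1e-5, 0.2)
_BOUNDS_M = (0.0, 20.0)


def _vec_to_params(x: np.ndarray, model: str) -> IMTripletParams:
    tau0, frac, th_abc, th_ab, th_a, th_b = x[:6]
    m_ab, m_ba = (x[6], x[7]) if model == "M2" else (0.0, 0.0)
    return IMTripletParams(tau_abc=tau0, tau_ab=tau0 * frac,
                           theta_abc=th_abc, theta_ab=th_ab,
                           theta_a=th_a, theta_b=th_b,
                           m_ab=m_ab, m_ba=m_ba)


def fit(data: TripletDataset, model: str = "M0", n_gl: int = _N_GL,
        n_starts: int = 3, seed: int = 0,
        x0: Sequence[float] | None = None) -> FitResult:
    """Maximum-likelihood fit of M0 or M2 by bounded quasi-Newton from
    multiple seeded starts."""
    if model not in ("M0", "M2"):
        raise ValueError("model must be 'M0' or 'M2'")
    lik = m0_loglik if model == "M0" else m2_loglik

    def nll(x):
        try:
            return -lik(data, _vec_to_params(x, model), n_gl)
        except (ValueError, FloatingPointError):
            return 1e12

    bounds = [_BOUNDS_TAU0, _BOUNDS_FRAC, _BOUNDS_THETA, _BOUNDS_THETA,
              _BOUNDS_THETA, _BOUNDS_THETA]
    if model == "M2":
        bounds += [_BOUNDS_M, _BOUNDS_M]
    rng = np.random.default_rng(seed)
    base = np.array([0.01, 0.3, 0.005, 0.003, 0.002, 0.002])
    starts = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    while len(starts) < n_starts:
        jitter = base * np.exp(rng.normal(0.0, 0.5, size=6))
        s = jitter if model == "M0" else np.concatenate([jitter, rng.uniform(0, 0.05, 2)])
        starts.append(np.clip(s, [b[0] for b in bounds], [b[1] for b in bounds]))
    best = None
    ok = False
    for s in starts:
        res = minimize(nll, s, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
            ok = bool(res.success)
    return FitResult(params=_vec_to_params(best.x, model),
                     loglik=float(-best.fun), converged=ok, n_starts=len(starts))


def lrt_migration(data: TripletDataset, n_gl: int = _N_GL, seed: int = 0,
                  n_starts: int = 3) -> LRTResult:
    """Likelihood ratio test of gene flow: M0 vs M2, chi-squared df = 2
    (1%/5% critical values 9.21/5.99)."""
    f0 = fit(data, "M0", n_gl=n_gl, n_starts=n_starts, seed=seed)
    x0 = np.array([f0.params.tau_abc, f0.params.tau_ab / f0.params.tau_abc,
                   f0.params.theta_abc, f0.params.theta_ab,
                   f0.params.theta_a, f0.params.theta_b, 0.0, 0.0])
    f2 = fit(data, "M2", n_gl=n_gl, n_starts=n_starts, seed=seed, x0=x0)
    stat = max(2.0 * (f2.loglik - f0.loglik), 0.0)
    return LRTResult(l0=f0.loglik, l2=f2.loglik, fit0=f0, fit2=f2,
                     statistic=stat, df=2, p_value=float(chi2.sf(stat, 2)))


# ---------------------------------------------------------------------------
# building triplet data


def build_triplet_dataset(loci, a: str, b: str, c: str,
                          rng: np.random.Generator) -> TripletDataset:
    """Subsample three sequences per locus from multilocus alignments.

    Half the loci get configuration ABC (one sequence from each
    species), a quarter AAC, a quarter BBC (seeded uniform draws of
    haplotypes within species).
    """
    def pick(aln, sp, k, exclude=()):
        names = [n for n in aln if (n == sp or n.startswith(sp + "_")) and n not in exclude]
        if len(names) < k:
            raise ValueError(f"species {sp!r} has fewer than {k} sequences")
        idx = rng.choice(len(names), size=k, replace=False)
        return [names[i] for i in idx]

    items = []
    for i, locus in enumerate(loci):
        aln = locus.alignment if hasattr(locus, "alignment") else locus
        u = rng.random()
        if u < 0.5:
            cfg = "ABC"
            n1, n2 = pick(aln, a, 1)[0], pick(aln, b, 1)[0]
        elif u < 0.75:
            cfg = "AAC"
            n1, n2 = pick(aln, a, 2)
        else:
            cfg = "BBC"
            n1, n2 = pick(aln, b, 2)
        n3 = pick(aln, c, 1)[0]
        items.append((cfg, (aln[n1], aln[n2], aln[n3])))
    return TripletDataset.from_alignments(items)
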