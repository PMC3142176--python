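"""Maximum-likelihood codon substitution models and selection tests.

Implements Goldman–Yang-style (GY94) codon models with site-class mixtures:

* M0       — single dN/dS ratio omega.
* M3(K)    — K discrete omega classes (default K = 3).
* M7       — omega ~ Beta(p, q) on (0, 1), discretized.
* M8       — Beta plus one extra class with omega_s >= 1 (positive selection).
* Dual3x3  — synonymous rate alpha and nonsynonymous rate beta each drawn
  from independent 3-category general discrete distributions (9 joint
  classes); reports coefficients of variation CV_S and CV_N.
* ZetaNull / ZetaAlt — combined coding + noncoding model: coding sites under
  M0, noncoding sites under HKY at rate zeta times the average synonymous
  rate, with two noncoding classes (zeta0 < 1 constrained; zeta1 = 1 fixed
  under the null, zeta1 >= 1 free under the alternative).

Likelihoods are computed by Felsenstein pruning with eigendecomposition of
the reversible generator; nested models are compared by chi-square LRTs and
sites are assigned to classes by naive empirical Bayes.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
from scipy import optimize, stats
from skbio import TreeNode

from .locus import STOP_CODONS, AlignedLocus, translate_codon

logger = logging.getLogger("popgenkit")

NUCS = "TCAG"
CODONS = [
    a + b + c
    for a in NUCS
    for b in NUCS
    for c in NUCS
    if a + b + c not in STOP_CODONS
]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
NCODON = len(CODONS)  # 61
AMINO = [translate_codon(c) for c in CODONS]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _build_pair_tables():
    """Index arrays of single-nucleotide codon neighbors."""
    pi_idx, pj_idx, is_ts, is_syn, nuc_target, nuc_pos = [], [], [], [], [], []
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            pi_idx.append(i)
            pj_idx.append(j)
            is_ts.append((ci[k], cj[k]) in _TRANSITIONS)
            is_syn.append(AMINO[i] == AMINO[j])
            nuc_target.append(cj[k])
            nuc_pos.append(k)
    return (
        np.array(pi_idx), np.array(pj_idx),
        np.array(is_ts), np.array(is_syn),
        nuc_target, np.array(nuc_pos),
    )


PAIR_I, PAIR_J, PAIR_TS, PAIR_SYN, PAIR_TARGET, PAIR_POS = _build_pair_tables()


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

class CodonDataError(ValueError):
    pass


@dataclass
class CodonAlignment:
    """In-frame stop-free codon matrix (codon indices; -1 = missing)."""

    taxa: list[str]
    codons: np.ndarray                 # (n_taxa, n_sites) int
    site_coords: list[tuple] = field(default_factory=list)  # original coords

    def __post_init__(self):
        self.codons = np.asarray(self.codons, dtype=int)
        if self.codons.ndim != 2 or len(self.taxa) != self.codons.shape[0]:
            raise CodonDataError("taxa/codon matrix mismatch")

    @property
    def n_sites(self) -> int:
        return self.codons.shape[1]

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(",".join(self.taxa).encode())
        h.update(self.codons.tobytes())
        return h.hexdigest()[:16]

    def f3x4(self) -> np.ndarray:
        """Codon frequencies from position-specific nucleotide frequencies."""
        counts = np.zeros((3, 4))
        nuc_idx = {n: k for k, n in enumerate("ACGT")}
        for row in self.codons:
            for c in row:
                if c < 0:
                    continue
                codon = CODONS[c]
                for pos in range(3):
                    counts[pos, nuc_idx[codon[pos]]] += 1
        counts += 0.5  # pseudocount guards empty positions
        freqs = counts / counts.sum(axis=1, keepdims=True)
        pi = np.array(
            [
                freqs[0, nuc_idx[c[0]]]
                * freqs[1, nuc_idx[c[1]]]
                * freqs[2, nuc_idx[c[2]]]
                for c in CODONS
            ]
        )
        return pi / pi.sum()

    def f61(self) -> np.ndarray:
        counts = np.full(NCODON, 0.5)
        for row in self.codons:
            for c in row:
                if c >= 0:
                    counts[c] += 1
        return counts / counts.sum()


@dataclass
class NucAlignment:
    """Nucleotide matrix for the noncoding partition (indices; -1 missing)."""

    taxa: list[str]
    sites: np.ndarray  # (n_taxa, n_sites) int over ACGT; -1 missing

    @property
    def n_sites(self) -> int:
        return self.sites.shape[1]

    def base_freqs(self) -> np.ndarray:
        counts = np.full(4, 0.5)
        for b in range(4):
            counts[b] += np.sum(self.sites == b)
        return counts / counts.sum()


class PhyloTree:
    """Rooted tree with branch lengths; binary roots are collapsed.

    Built from a newick string or a skbio TreeNode.  Node 0..n_tips-1 are the
    tips in ``taxa`` order; internal nodes follow; the root is last in
    ``postorder``.
    """

    def __init__(self, newick: str | None = None, sk_tree: TreeNode | None = None):
        if sk_tree is None:
            sk_tree = TreeNode.read(StringIO(newick))
        sk_tree = sk_tree.copy()
        root = sk_tree
        children = root.children
        if len(children) == 2:  # unroot: collapse binary root
            c1, c2 = children
            if not c2.is_tip():
                c1, c2 = c2, c1
            if not c1.is_tip():
                extra = (c1.length or 0.0) + (c2.length or 0.0)
                root.remove(c1)
                for gc in list(c1.children):
                    c1.remove(gc)
                    root.append(gc)
                c2.length = extra
        tips = list(sk_tree.tips())
        self.taxa = [t.name for t in tips]
        n_tips = len(tips)
        node_ids = {}
        for k, t in enumerate(tips):
            node_ids[id(t)] = k
        next_id = n_tips
        post = []
        for node in sk_tree.postorder():
            if node.is_tip():
                post.append(node_ids[id(node)])
            else:
                node_ids[id(node)] = next_id
                post.append(next_id)
                next_id += 1
        self.n_nodes = next_id
        self.n_tips = n_tips
        self.postorder = post
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.branch_lengths = np.zeros(self.n_nodes)
        for node in sk_tree.postorder():
            nid = node_ids[id(node)]
            self.branch_lengths[nid] = node.length or 0.1
            if node.parent is not None:
                pid = node_ids[id(node.parent)]
                self.parent[nid] = pid
                self.children[pid].append(nid)
        self.root = post[-1]

    @property
    def branch_nodes(self) -> list[int]:
        """Nodes that own a branch (everything but the root)."""
        return [v for v in self.postorder if v != self.root]

    def with_branch_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        import copy

        t = copy.copy(self)
        t.branch_lengths = self.branch_lengths.copy()
        for k, v in enumerate(self.branch_nodes):
            t.branch_lengths[v] = lengths[k]
        return t

    def total_length(self) -> float:
        return float(
            sum(self.branch_lengths[v] for v in self.branch_nodes)
        )

    def newick(self) -> str:
        def rec(v):
            if v < self.n_tips:
                return f"{self.taxa[v]}:{self.branch_lengths[v]:.6f}"
            inner = ",".join(rec(c) for c in self.children[v])
            if v == self.root:
                return f"({inner});"
            return f"({inner}):{self.branch_lengths[v]:.6f}"

        return rec(self.root)


@dataclass
class ModelFit:
    model: str
    log_likelihood: float
    params: dict
    class_rates: list          # per class: dict with rates and proportion
    tree: PhyloTree
    site_class_likelihoods: np.ndarray | None  # (n_sites, K)
    class_proportions: np.ndarray | None
    converged: bool
    n_restarts: int
    data_fingerprint: str
    flags: list = field(default_factory=list)

    def posteriors(self) -> np.ndarray:
        """Naive empirical Bayes posterior class probabilities per site."""
        if self.site_class_likelihoods is None or self.class_proportions is None:
            raise ValueError("fit has no site-class decomposition")
        w = self.site_class_likelihoods * self.class_proportions[None, :]
        return w / w.sum(axis=1, keepdims=True)


@dataclass
class LRTResult:
    null_model: str
    alt_model: str
    statistic: float
    df: int
    p_value: float
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Rate matrices and transition probabilities
# ---------------------------------------------------------------------------

def codon_rate_matrix(
    pi: np.ndarray, kappa: float, syn_rate: float, nonsyn_rate: float
) -> np.ndarray:
    """Unscaled GY94-style generator; syn/nonsyn single-step rates."""
    Q = np.zeros((NCODON, NCODON))
    rates = np.where(PAIR_TS, kappa, 1.0) * np.where(
        PAIR_SYN, syn_rate, nonsyn_rate
    )
    Q[PAIR_I, PAIR_J] = rates * pi[PAIR_J]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def synonymous_flux(Q: np.ndarray, pi: np.ndarray) -> float:
    """Expected synonymous substitutions per codon per unit time under Q."""
    return float(np.sum(pi[PAIR_I[PAIR_SYN]] * Q[PAIR_I[PAIR_SYN],
                                                 PAIR_J[PAIR_SYN]]))


def nonsynonymous_flux(Q: np.ndarray, pi: np.ndarray) -> float:
    ns = ~PAIR_SYN
    return float(np.sum(pi[PAIR_I[ns]] * Q[PAIR_I[ns], PAIR_J[ns]]))


class _Eigens:
    """Spectral decomposition of a reversible generator for fast P(t)."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(np.maximum(pi, 1e-12))
        B = (Q * d[:, None]) / d[None, :]
        B = 0.5 * (B + B.T)  # enforce symmetry against round-off
        lam, V = np.linalg.eigh(B)
        self.lam = lam
        self.left = V.T * d[None, :]      # V^T D^{1/2}
        self.right = (V.T / d[None, :]).T  # D^{-1/2} V

    def transition(self, t: float) -> np.ndarray:
        P = (self.right * np.exp(self.lam * t)[None, :]) @ self.left
        np.maximum(P, 0.0, out=P)
        return P


def hky_rate_matrix(pi: np.ndarray, kappa: float) -> np.ndarray:
    """HKY85 generator scaled to one expected substitution per unit time."""
    Q = np.zeros((4, 4))
    nucs = "ACGT"
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            ts = (nucs[i], nucs[j]) in _TRANSITIONS
            Q[i, j] = (kappa if ts else 1.0) * pi[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -np.sum(pi * np.diag(Q))
    return Q / rate


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

def _compress_patterns(matrix: np.ndarray):
    patterns, inverse, counts = np.unique(
        matrix.T, axis=0, return_inverse=True, return_counts=True
    )
    return patterns, inverse.ravel(), counts


def _pattern_likelihoods(
    tree: PhyloTree,
    patterns: np.ndarray,  # (npat, n_tips) state indices, -1 missing
    Ps: dict,              # node -> P matrix for its branch
    pi: np.ndarray,
) -> np.ndarray:
    npat = patterns.shape[0]
    nstate = len(pi)
    partials = {}
    log_scale = np.zeros(npat)
    for v in tree.postorder:
        if v < tree.n_tips:
            continue
        part = np.ones((npat, nstate))
        for c in tree.children[v]:
            P = Ps[c]
            if c < tree.n_tips:
                states = patterns[:, c]
                contrib = np.ones((npat, nstate))
                known = states >= 0
                contrib[known] = P[:, states[known]].T
            else:
                contrib = partials.pop(c) @ P.T
            part *= contrib
        scale = part.max(axis=1)
        scale[scale == 0] = 1.0
        part /= scale[:, None]
        log_scale += np.log(scale)
        partials[v] = part
    root_part = partials[tree.root]
    return (root_part @ pi) * np.exp(log_scale), (root_part @ pi), log_scale


def _mixture_loglik(class_pattern_liks, proportions, counts):
    """Stable mixture log-likelihood from per-class (lik, logscale) pairs."""
    K = len(class_pattern_liks)
    npat = len(counts)
    logs = np.empty((npat, K))
    for k, (lik, ls) in enumerate(class_pattern_liks):
        logs[:, k] = np.log(np.maximum(lik, 1e-300)) + ls
    logp = np.log(np.maximum(proportions, 1e-300))
    m = logs + logp[None, :]
    mmax = m.max(axis=1)
    site_ll = mmax + np.log(np.exp(m - mmax[:, None]).sum(axis=1))
    return float(np.sum(counts * site_ll)), logs


# ---------------------------------------------------------------------------
# Model definitions: parameter packing and class construction
# ---------------------------------------------------------------------------

def _beta_discretized(p: float, q: float, ncat: int) -> np.ndarray:
    """Median-of-decile discretization of Beta(p, q)."""
    probs = (np.arange(ncat) + 0.5) / ncat
    return stats.beta.ppf(probs, p, q)


def _stick(q1: float, q2: float) -> np.ndarray:
    p1 = q1
    p2 = (1 - q1) * q2
    return np.array([p1, p2, 1 - p1 - p2])


class _ModelSpec:
    """Free parameters, bounds and class construction for one site model."""

    def __init__(self, model: str, options: dict):
        self.model = model
        self.options = options
        K3 = options.get("m3_classes", 3)
        ncat = options.get("beta_categories", 10)
        self.ncat = ncat
        self.K3 = K3
        if model == "M0":
            self.names = ["kappa", "omega"]
            self.bounds = [(0.05, 99.0), (1e-6, 50.0)]
            self.init = [2.0, 0.4]
        elif model == "M3":
            self.names = (
                ["kappa"]
                + [f"omega{k}" for k in range(K3)]
                + [f"q{k}" for k in range(K3 - 1)]
            )
            self.bounds = (
                [(0.05, 99.0)]
                + [(1e-6, 50.0)] * K3
                + [(1e-4, 1 - 1e-4)] * (K3 - 1)
            )
            self.init = [2.0] + list(np.linspace(0.05, 1.0, K3)) + [0.4] * (K3 - 1)
        elif model == "M7":
            self.names = ["kappa", "p", "q"]
            self.bounds = [(0.05, 99.0), (0.005, 99.0), (0.005, 99.0)]
            self.init = [2.0, 0.5, 1.5]
        elif model == "M8":
            self.names = ["kappa", "p", "q", "p0", "omega_s"]
            self.bounds = [
                (0.05, 99.0), (0.005, 99.0), (0.005, 99.0),
                (1e-4, 1 - 1e-4), (1.0, 99.0),
            ]
            self.init = [2.0, 0.5, 1.5, 0.9, 2.0]
        elif model == "Dual3x3":
            self.names = [
                "kappa",
                "alpha0", "alpha1", "alpha2", "qa0", "qa1",
                "beta0", "beta1", "beta2", "qb0", "qb1",
            ]
            self.bounds = (
                [(0.05, 99.0)]
                + [(1e-4, 99.0)] * 3 + [(1e-4, 1 - 1e-4)] * 2
                + [(1e-6, 99.0)] * 3 + [(1e-4, 1 - 1e-4)] * 2
            )
            self.init = [2.0, 0.5, 1.0, 2.0, 0.3, 0.5,
                         0.05, 0.3, 1.0, 0.3, 0.5]
        else:
            raise ValueError(f"unknown model {model!r}")

    def classes(self, x: np.ndarray):
        """-> (list of (syn_rate, nonsyn_rate), proportions array, params)."""
        d = dict(zip(self.names, x))
        if self.model == "M0":
            return [(1.0, d["omega"])], np.array([1.0]), d
        if self.model == "M3":
            K = self.K3
            omegas = [d[f"omega{k}"] for k in range(K)]
            if K == 1:
                props = np.array([1.0])
            else:
                props = np.array([1.0])
                rem = 1.0
                out = []
                for k in range(K - 1):
                    out.append(rem * d[f"q{k}"])
                    rem -= out[-1]
                props = np.array(out + [rem])
            return [(1.0, w) for w in omegas], props, d
        if self.model == "M7":
            om = _beta_discretized(d["p"], d["q"], self.ncat)
            props = np.full(self.ncat, 1.0 / self.ncat)
            return [(1.0, w) for w in om], props, d
        if self.model == "M8":
            om = _beta_discretized(d["p"], d["q"], self.ncat)
            p0 = d["p0"]
            props = np.concatenate(
                [np.full(self.ncat, p0 / self.ncat), [1 - p0]]
            )
            rates = [(1.0, w) for w in om] + [(1.0, d["omega_s"])]
            return rates, props, d
        if self.model == "Dual3x3":
            alphas = np.array([d["alpha0"], d["alpha1"], d["alpha2"]])
            pa = _stick(d["qa0"], d["qa1"])
            betas = np.array([d["beta0"], d["beta1"], d["beta2"]])
            pb = _stick(d["qb0"], d["qb1"])
            alphas = alphas / np.sum(pa * alphas)  # mean syn rate fixed at 1
            rates = []
            props = []
            for (a, wa) in zip(alphas, pa):
                for (b, wb) in zip(betas, pb):
                    rates.append((a, b))
                    props.append(wa * wb)
            d["alphas"] = alphas.tolist()
            d["alpha_props"] = pa.tolist()
            d["betas"] = betas.tolist()
            d["beta_props"] = pb.tolist()
            return rates, np.array(props), d
        raise AssertionError


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _codon_class_matrices(pi, kappa, class_rates, proportions):
    """Scaled per-class generators (shared normalization over the mixture)."""
    Qs = [codon_rate_matrix(pi, kappa, a, b) for a, b in class_rates]
    rates = np.array([-np.sum(pi * np.diag(Q)) for Q in Qs])
    mean_rate = float(np.sum(proportions * rates))
    if mean_rate <= 0:
        mean_rate = 1e-12
    return [Q / mean_rate for Q in Qs], mean_rate


def _loglik_codon(
    x, spec, tree, patterns, counts, pi, n_branch, want_details=False
):
    bl = x[:n_branch]
    class_rates, props, params = spec.classes(x[n_branch:])
    Qs, _ = _codon_class_matrices(pi, params["kappa"], class_rates, props)
    class_liks = []
    branch_nodes = tree.branch_nodes
    for Q in Qs:
        eig = _Eigens(Q, pi)
        Ps = {v: eig.transition(bl[k]) for k, v in enumerate(branch_nodes)}
        _, lik, ls = _pattern_likelihoods(tree, patterns, Ps, pi)
        class_liks.append((lik, ls))
    ll, logs = _mixture_loglik(class_liks, props, counts)
    if want_details:
        return ll, logs, props, params, class_rates
    return ll


def fit_model(
    data: CodonAlignment,
    tree: PhyloTree | str,
    model: str = "M0",
    noncoding: NucAlignment | None = None,
    frequencies: str = "f3x4",
    restarts: int = 3,
    seed: int = 0,
    tol: float = 1e-6,
    maxiter: int = 500,
    options: dict | None = None,
) -> ModelFit:
    """Fit a codon (or combined coding+noncoding zeta) model by ML.

    Branch lengths and all model parameters are optimized jointly with
    bounded quasi-Newton (L-BFGS-B) from ``restarts`` seeded start points.
    ``frequencies`` is "f3x4" (default) or "f61".
    """
    options = options or {}
    if isinstance(tree, str):
        tree = PhyloTree(newick=tree)
    if set(tree.taxa) != set(data.taxa):
        raise CodonDataError("tree taxa do not match alignment taxa")
    if model in ("ZetaNull", "ZetaAlt"):
        return _fit_zeta(
            data, tree, model, noncoding, frequencies, restarts, seed, tol,
            maxiter, options,
        )
    spec = _ModelSpec(model, options)
    pi = data.f3x4() if frequencies == "f3x4" else data.f61()
    # reorder alignment rows to tree tip order
    order = [data.taxa.index(t) for t in tree.taxa]
    patterns, _, counts = _compress_patterns(data.codons[order])
    n_branch = len(tree.branch_nodes)
    bl_bounds = [(1e-7, 20.0)] * n_branch
    bounds = bl_bounds + spec.bounds
    rng = np.random.default_rng(seed)
    best = None
    init_bl = np.clip(
        np.array([tree.branch_lengths[v] for v in tree.branch_nodes]),
        1e-6, 10.0,
    )

    def negll(x):
        return -_loglik_codon(x, spec, tree, patterns, counts, pi, n_branch)

    for r in range(max(1, restarts)):
        if r == 0:
            x0 = np.concatenate([init_bl, spec.init])
        else:
            jb = init_bl * np.exp(rng.normal(0, 0.5, n_branch))
            jp = np.array(
                [
                    np.clip(v * np.exp(rng.normal(0, 0.4)), lo, hi)
                    for v, (lo, hi) in zip(spec.init, spec.bounds)
                ]
            )
            x0 = np.concatenate([np.clip(jb, 1e-6, 10.0), jp])
        res = optimize.minimize(
            negll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": tol, "maxfun": 20000},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    converged = bool(best.success or best.fun < np.inf)
    flags = [] if best.success else ["optimizer did not report convergence"]

    ll, logs, props, params, class_rates = _loglik_codon(
        best.x, spec, tree, patterns, counts, pi, n_branch, want_details=True
    )
    fitted_tree = tree.with_branch_lengths(best.x[:n_branch])
    t = fitted_tree.total_length()
    if t < 1e-4:
        flags.append("tree length ~0: parameters unidentifiable")

    # Tree-length decomposition into synonymous/nonsynonymous parts.
    Qs, _ = _codon_class_matrices(pi, params["kappa"], class_rates, props)
    syn_part = float(
        np.sum([p * synonymous_flux(Q, pi) for p, Q in zip(props, Qs)])
    )
    nonsyn_part = float(
        np.sum([p * nonsynonymous_flux(Q, pi) for p, Q in zip(props, Qs)])
    )
    params = dict(params)
    params["t"] = t
    params["dS_tree"] = t * syn_part
    params["dN_tree"] = t * nonsyn_part
    if model == "Dual3x3":
        alphas = np.array(params["alphas"])
        pa = np.array(params["alpha_props"])
        betas = np.array(params["betas"])
        pb = np.array(params["beta_props"])
        ma = float(np.sum(pa * alphas))
        mb = float(np.sum(pb * betas))
        params["CVS"] = float(
            np.sqrt(np.sum(pa * (alphas - ma) ** 2)) / ma if ma > 0 else 0.0
        )
        params["CVN"] = float(
            np.sqrt(np.sum(pb * (betas - mb) ** 2)) / mb if mb > 0 else 0.0
        )

    # Expand pattern-level class logs back to sites.
    _, inverse, _ = _compress_patterns(data.codons[order])
    site_logs = logs[inverse]
    site_liks = np.exp(site_logs - site_logs.max(axis=1, keepdims=True))
    return ModelFit(
        model=model,
        log_likelihood=ll,
        params=params,
        class_rates=[
            {"syn": a, "omega_or_beta": b, "proportion": float(p)}
            for (a, b), p in zip(class_rates, props)
        ],
        tree=fitted_tree,
        site_class_likelihoods=site_liks,
        class_proportions=props,
        converged=converged,
        n_restarts=max(1, restarts),
        data_fingerprint=data.fingerprint(),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Zeta (coding + noncoding) models
# ---------------------------------------------------------------------------

def _loglik_zeta(
    x, tree, cod_patterns, cod_counts, nc_patterns, nc_counts,
    pi_codon, pi_nuc, n_branch, alt: bool, want_details=False,
):
    bl = x[:n_branch]
    kappa, omega, zeta0, p0 = x[n_branch : n_branch + 4]
    zeta1 = x[n_branch + 4] if alt else 1.0
    Q = codon_rate_matrix(pi_codon, kappa, 1.0, omega)
    rate = -np.sum(pi_codon * np.diag(Q))
    Q = Q / rate
    eig = _Eigens(Q, pi_codon)
    branch_nodes = tree.branch_nodes
    Ps = {v: eig.transition(bl[k]) for k, v in enumerate(branch_nodes)}
    _, clik, cls = _pattern_likelihoods(tree, cod_patterns, Ps, pi_codon)
    cod_ll = float(
        np.sum(cod_counts * (np.log(np.maximum(clik, 1e-300)) + cls))
    )
    # noncoding: HKY at zeta * (mean synonymous rate per nucleotide site)
    syn_site_rate = synonymous_flux(Q, pi_codon) / 3.0
    Qn = hky_rate_matrix(pi_nuc, kappa)
    eign = _Eigens(Qn, pi_nuc)
    class_liks = []
    for z in (zeta0, zeta1):
        Pns = {
            v: eign.transition(bl[k] * syn_site_rate * z)
            for k, v in enumerate(branch_nodes)
        }
        _, nlik, nls = _pattern_likelihoods(tree, nc_patterns, Pns, pi_nuc)
        class_liks.append((nlik, nls))
    props = np.array([p0, 1 - p0])
    nc_ll, nc_logs = _mixture_loglik(class_liks, props, nc_counts)
    ll = cod_ll + nc_ll
    if want_details:
        return ll, nc_logs, props, {
            "kappa": kappa, "omega": omega, "zeta0": zeta0, "zeta1": zeta1,
            "p0": p0, "p1": 1 - p0, "syn_site_rate": syn_site_rate,
        }
    return ll


def _fit_zeta(
    data, tree, model, noncoding, frequencies, restarts, seed, tol, maxiter,
    options,
):
    if noncoding is None:
        raise CodonDataError("zeta models require a noncoding alignment")
    if set(noncoding.taxa) != set(data.taxa):
        raise CodonDataError("noncoding taxa do not match codon taxa")
    alt = model == "ZetaAlt"
    pi_codon = data.f3x4() if frequencies == "f3x4" else data.f61()
    pi_nuc = noncoding.base_freqs()
    order = [data.taxa.index(t) for t in tree.taxa]
    nc_order = [noncoding.taxa.index(t) for t in tree.taxa]
    cod_patterns, _, cod_counts = _compress_patterns(data.codons[order])
    nc_patterns, nc_inverse, nc_counts = _compress_patterns(
        noncoding.sites[nc_order]
    )
    n_branch = len(tree.branch_nodes)
    bounds = [(1e-7, 20.0)] * n_branch + [
        (0.05, 99.0),          # kappa
        (1e-6, 50.0),          # omega
        (1e-4, 1.0 - 1e-6),    # zeta0 < 1
        (1e-4, 1 - 1e-4),      # p0
    ]
    init = [2.0, 0.3, 0.3, 0.8]
    if alt:
        bounds.append((1.0, 99.0))
        init.append(1.5)
    rng = np.random.default_rng(seed)
    init_bl = np.clip(
        np.array([tree.branch_lengths[v] for v in tree.branch_nodes]),
        1e-6, 10.0,
    )

    def negll(x):
        return -_loglik_zeta(
            x, tree, cod_patterns, cod_counts, nc_patterns, nc_counts,
            pi_codon, pi_nuc, n_branch, alt,
        )

    best = None
    for r in range(max(1, restarts)):
        if r == 0:
            x0 = np.concatenate([init_bl, init])
        else:
            jb = init_bl * np.exp(rng.normal(0, 0.5, n_branch))
            jp = np.array(
                [
                    np.clip(v * np.exp(rng.normal(0, 0.4)), lo, hi)
                    for v, (lo, hi) in zip(init, bounds[n_branch:])
                ]
            )
            x0 = np.concatenate([np.clip(jb, 1e-6, 10.0), jp])
        res = optimize.minimize(
            negll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": tol, "maxfun": 20000},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    ll, nc_logs, props, params = _loglik_zeta(
        best.x, tree, cod_patterns, cod_counts, nc_patterns, nc_counts,
        pi_codon, pi_nuc, n_branch, alt, want_details=True,
    )
    fitted_tree = tree.with_branch_lengths(best.x[:n_branch])
    params["t"] = fitted_tree.total_length()
    site_logs = nc_logs[nc_inverse]
    site_liks = np.exp(site_logs - site_logs.max(axis=1, keepdims=True))
    return ModelFit(
        model=model,
        log_likelihood=ll,
        params=params,
        class_rates=[
            {"zeta": params["zeta0"], "proportion": float(props[0])},
            {"zeta": params["zeta1"], "proportion": float(props[1])},
        ],
        tree=fitted_tree,
        site_class_likelihoods=site_liks,
        class_proportions=props,
        converged=bool(best.success),
        n_restarts=max(1, restarts),
        data_fingerprint=data.fingerprint(),
        flags=[] if best.success else ["optimizer did not report convergence"],
    )


# ---------------------------------------------------------------------------
# LRT and posteriors
# ---------------------------------------------------------------------------

def lrt(null: ModelFit, alt: ModelFit, df: int) -> LRTResult:
    """Chi-square likelihood ratio test of nested model fits."""
    if null.data_fingerprint != alt.data_fingerprint:
        raise ValueError("fits were made on different data")
    stat = 2.0 * (alt.log_likelihood - null.log_likelihood)
    flags = []
    if stat < 0:
        if stat > -1e-3:
            flags.append("negative statistic within tolerance clamped to 0")
            stat = 0.0
        else:
            flags.append(
                "alternative fit worse than null beyond tolerance: "
                "optimizer failure suspected"
            )
            stat = 0.0
    p = float(stats.chi2.sf(stat, df))
    return LRTResult(
        null_model=null.model, alt_model=alt.model,
        statistic=float(stat), df=df, p_value=p, flags=flags,
    )


def site_posteriors(
    fit: ModelFit, positive_threshold: float = 0.95
) -> dict:
    """NEB posterior class probabilities and the flagged positive-selection sites.

    The "positive" class is the extra omega_s class for M8, classes with
    omega > 1 for M3, the zeta1 class for zeta models.  Sites are reported
    1-based.
    """
    post = fit.posteriors()
    K = post.shape[1]
    if K < 2:
        return {"posteriors": post, "positive_sites": []}
    if fit.model == "M8":
        pos_cols = [K - 1]
    elif fit.model in ("ZetaNull", "ZetaAlt"):
        pos_cols = [1] if fit.params.get("zeta1", 1.0) > 1.0 else []
    elif fit.model in ("M3", "M7"):
        pos_cols = [
            k
            for k, cr in enumerate(fit.class_rates)
            if cr.get("omega_or_beta", 0.0) > 1.0
        ]
    elif fit.model == "Dual3x3":
        pos_cols = []
    else:
        pos_cols = []
    pos_prob = post[:, pos_cols].sum(axis=1) if pos_cols else np.zeros(len(post))
    positive = [
        {"site": int(i + 1), "posterior": float(p)}
        for i, p in enumerate(pos_prob)
        if p > positive_threshold
    ]
    return {"posteriors": post, "positive_sites": positive,
            "positive_class_columns": pos_cols}


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

def build_codon_data(
    locus: AlignedLocus,
    taxa: list[str] | None = None,
) -> tuple[CodonAlignment, NucAlignment]:
    """Extract paired coding (codon) and noncoding matrices for chosen taxa.

    Codon columns containing any gap or N in any selected taxon are removed
    whole (logged); internal stop codons raise an error naming the taxon and
    position.  Noncoding columns (intron + flank) with any gap are dropped;
    N is kept as missing.
    """
    if locus.annotation is None:
        raise CodonDataError("build_codon_data requires a region annotation")
    if taxa is None:
        taxa = list(locus.ids)
    rows = np.array([locus.ids.index(t) for t in taxa])
    sub = locus.matrix[rows]

    codon_cols = []
    coords = []
    dropped = 0
    for _, positions in locus.annotation.codon_map(locus.L):
        cols = [p - 1 for p in positions]
        block = sub[:, cols]
        if ((block == "-") | (block == "N")).any():
            dropped += 1
            continue
        col_idx = []
        for i, t in enumerate(taxa):
            codon = "".join(block[i])
            if codon in STOP_CODONS:
                raise CodonDataError(
                    f"internal stop codon {codon} in taxon {t} at "
                    f"alignment positions {positions}"
                )
            col_idx.append(CODON_INDEX[codon])
        codon_cols.append(col_idx)
        coords.append(positions)
    if dropped:
        logger.info("dropped %d codon columns containing gaps or N", dropped)
    if not codon_cols:
        raise CodonDataError("no usable codon columns")
    codons = np.array(codon_cols).T  # (n_taxa, n_sites)

    nuc_idx = {n: k for k, n in enumerate("ACGT")}
    nc_mask = locus.annotation.positions_of_class(("intron", "flank"), locus.L)
    nc_cols = []
    for col in np.flatnonzero(nc_mask):
        column = sub[:, col]
        if (column == "-").any():
            continue
        nc_cols.append([nuc_idx.get(str(b), -1) for b in column])
    nc = (
        np.array(nc_cols).T
        if nc_cols
        else np.zeros((len(taxa), 0), dtype=int)
    )
    return (
        CodonAlignment(taxa=list(taxa), codons=codons, site_coords=coords),
        NucAlignment(taxa=list(taxa), sites=nc),
    )


def degenerate_loglik(data: CodonAlignment, pi: np.ndarray) -> float:
    """Log-likelihood at t = 0 for identical sequences: sum log pi[codon]."""
    first = data.codons[0]
    return float(np.sum(np.log(pi[first])))
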