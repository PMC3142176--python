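"""Linkage disequilibrium, minimum recombination events, and rho estimation.

* ``ld_pairwise`` — D, D', r^2 and Fisher exact association for every pair of
  biallelic segregating sites (singletons excluded by default).
* ``hudson_kaplan_rm`` — the four-gamete test on every site pair followed by
  the Hudson–Kaplan interval reduction, giving Rm, the minimum number of
  recombination events in the sample history.
* ``estimate_rho`` — a moment estimator of the per-site population
  recombination rate rho = 4*N0*r that matches the observed variance of
  pairwise difference counts to its coalescent expectation (computed by
  seeded simulation at the observed theta), in the spirit of Hudson (1987).
* ``ld_decay_test`` — permutation test for decay of r^2 with distance.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import coalescent
from .locus import AlignedLocus, SiteTable
from .neutrality import biallelic_matrix

logger = logging.getLogger("popgenkit")


@dataclass
class LDPair:
    pos_i: int
    pos_j: int
    distance: int
    D: float
    D_prime: float
    r2: float
    fisher_p: float


@dataclass
class LDMatrix:
    pairs: list[LDPair]

    def __len__(self):
        return len(self.pairs)

    def arrays(self):
        r2 = np.array([p.r2 for p in self.pairs])
        dist = np.array([p.distance for p in self.pairs], dtype=float)
        return r2, dist


@dataclass
class RecombinationReport:
    rm: int | None = None
    incompatible_intervals: list | None = None
    rho_per_site: float | None = None
    rho_over_theta: float | None = None
    estimator: str | None = None
    decay_correlation: float | None = None
    decay_p: float | None = None
    details: dict = field(default_factory=dict)


def ld_pairwise(
    locus: AlignedLocus,
    sites: SiteTable | None = None,
    mask: str = "all",
    rows: np.ndarray | None = None,
    exclude_singletons: bool = True,
) -> LDMatrix:
    """All pairwise LD measures on 2x2 haplotype counts."""
    matrix, positions = biallelic_matrix(
        locus, sites, mask, rows, exclude_singletons=exclude_singletons
    )
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 biallelic sites for LD")
    pairs = []
    for i, j in itertools.combinations(range(matrix.shape[1]), 2):
        x, y = matrix[:, i], matrix[:, j]
        both = (x >= 0) & (y >= 0)
        x, y = x[both], y[both]
        p1, p2 = x.mean(), y.mean()
        if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
            logger.info(
                "site pair (%d, %d) monomorphic after missing-data "
                "restriction; skipped", positions[i], positions[j],
            )
            continue
        p11 = float(np.mean((x == 1) & (y == 1)))
        D = p11 - p1 * p2
        if D >= 0:
            dmax = min(p1 * (1 - p2), (1 - p1) * p2)
        else:
            dmax = min(p1 * p2, (1 - p1) * (1 - p2))
        d_prime = D / dmax if dmax > 0 else 0.0
        r2 = D * D / (p1 * (1 - p1) * p2 * (1 - p2))
        counts = np.array(
            [
                [np.sum((x == 0) & (y == 0)), np.sum((x == 0) & (y == 1))],
                [np.sum((x == 1) & (y == 0)), np.sum((x == 1) & (y == 1))],
            ]
        )
        _, fp = stats.fisher_exact(counts, alternative="two-sided")
        pairs.append(
            LDPair(
                pos_i=int(positions[i]), pos_j=int(positions[j]),
                distance=int(positions[j] - positions[i]),
                D=float(D), D_prime=float(d_prime), r2=float(r2),
                fisher_p=float(fp),
            )
        )
    return LDMatrix(pairs)


# ---------------------------------------------------------------------------
# Hudson–Kaplan Rm
# ---------------------------------------------------------------------------

def four_gamete_violation(x: np.ndarray, y: np.ndarray) -> bool:
    """True when all four gametes occur among pairwise-complete sequences."""
    both = (x >= 0) & (y >= 0)
    g = set(zip(x[both].tolist(), y[both].tolist()))
    return len(g) == 4


def _interval_reduction(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Hudson–Kaplan reduction: maximal set of disjoint incompatible intervals.

    Intervals are open (between site indices).  Greedy by leftmost right
    endpoint; deterministic.  Returns the retained disjoint intervals whose
    count is Rm.
    """
    if not intervals:
        return []
    chosen = []
    last_right = -math.inf
    for left, right in sorted(intervals, key=lambda iv: (iv[1], iv[0])):
        if left >= last_right:
            chosen.append((left, right))
            last_right = right
    return chosen


def hudson_kaplan_rm(
    locus_or_matrix,
    sites: SiteTable | None = None,
    mask: str = "all",
    rows: np.ndarray | None = None,
) -> RecombinationReport:
    """Minimum number of recombination events (Hudson & Kaplan 1985).

    Accepts an :class:`AlignedLocus` (with optional mask) or a 0/1 haplotype
    matrix plus implicit unit-spaced positions.
    """
    if isinstance(locus_or_matrix, AlignedLocus):
        matrix, positions = biallelic_matrix(locus_or_matrix, sites, mask, rows)
    else:
        matrix = np.asarray(locus_or_matrix)
        positions = np.arange(1, matrix.shape[1] + 1)
    S = matrix.shape[1]
    incompatible = []
    for i, j in itertools.combinations(range(S), 2):
        if four_gamete_violation(matrix[:, i], matrix[:, j]):
            incompatible.append((int(positions[i]), int(positions[j])))
    chosen = _interval_reduction(incompatible)
    return RecombinationReport(
        rm=len(chosen),
        incompatible_intervals=chosen,
        details={"n_incompatible_pairs": len(incompatible)},
    )


# ---------------------------------------------------------------------------
# rho estimation
# ---------------------------------------------------------------------------

def variance_pairwise_differences(matrix: np.ndarray) -> tuple[float, float]:
    """(mean, variance) of pairwise difference counts over all pairs."""
    n = matrix.shape[0]
    valid = matrix >= 0
    ks = []
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        diff = (matrix[i] != matrix[i + 1 :]) & both
        ks.extend(diff.sum(axis=1).tolist())
    ks = np.array(ks, dtype=float)
    return float(ks.mean()), float(ks.var())


def _expected_variance(
    n: int, L: int, theta_site: float, rho_site: float,
    reps: int, rng: np.random.Generator,
) -> float:
    vals = []
    seed = int(rng.integers(1, 2**31 - 1))
    for rep in coalescent.simulate_sample(
        n, L, "theta", theta_site, rho_site, reps, seed
    ):
        vals.append(variance_pairwise_differences(rep.matrix)[1])
    return float(np.mean(vals))


def estimate_rho(
    locus_or_matrix,
    sites: SiteTable | None = None,
    mask: str = "all",
    rows: np.ndarray | None = None,
    L: int | None = None,
    reps_per_point: int = 120,
    seed: int = 0,
) -> RecombinationReport:
    """Moment estimate of rho per site from the variance of pairwise differences.

    The observed variance of pairwise difference counts shrinks as
    recombination decouples genealogies along the locus.  Its coalescent
    expectation (at the sample's theta, estimated from mean pairwise
    differences) is computed by seeded simulation on a log-spaced rho grid
    and inverted by monotone interpolation — a simulation-matched version of
    Hudson's (1987) moment estimator.
    """
    if isinstance(locus_or_matrix, AlignedLocus):
        matrix, _ = biallelic_matrix(locus_or_matrix, sites, mask, rows)
        if L is None:
            L = locus_or_matrix.L
    else:
        matrix = np.asarray(locus_or_matrix)
        if L is None:
            raise ValueError("L required when passing a raw matrix")
    n, S = matrix.shape
    if S < 5:
        logger.warning("estimate_rho: fewer than 5 segregating sites")
    kbar, obs_var = variance_pairwise_differences(matrix)
    theta_site = kbar / L  # per-site theta from mean pairwise differences
    if theta_site <= 0 or obs_var <= 0:
        return RecombinationReport(estimator="pairwise-variance moment",
                                   details={"flag": "no estimate"})
    rng = np.random.default_rng(seed)
    # grid top of 0.2/site is ~10x the largest plausible per-site rho in
    # nuclear loci; estimates above it are capped and logged
    grid = np.concatenate([[0.0], np.logspace(-4, -0.7, 8)])  # rho per site
    expected = np.array(
        [
            _expected_variance(n, L, theta_site, r, reps_per_point, rng)
            for r in grid
        ]
    )
    # enforce monotone decrease (smooth out MC noise)
    expected = np.minimum.accumulate(expected)
    theta_w_site = S / (
        float(np.sum(1.0 / np.arange(1, n))) * L
    )
    if obs_var >= expected[0]:
        rho_hat = 0.0
    elif obs_var <= expected[-1]:
        rho_hat = float(grid[-1])
        logger.warning("estimate_rho: observed variance below grid; "
                       "estimate capped at %.3g per site", rho_hat)
    else:
        # interpolate on log-rho for the interior grid
        interior = grid[1:]
        exp_int = expected[1:]
        if obs_var >= exp_int[0]:
            # between rho=0 and first grid point: linear in rho
            frac = (expected[0] - obs_var) / (expected[0] - exp_int[0])
            rho_hat = float(interior[0] * frac)
        else:
            logr = np.log10(interior)
            rho_hat = float(
                10 ** np.interp(-obs_var, -exp_int, logr)
            )
    return RecombinationReport(
        rho_per_site=rho_hat,
        rho_over_theta=rho_hat / theta_w_site if theta_w_site > 0 else None,
        estimator="pairwise-variance moment (simulation-matched)",
        details={
            "observed_variance": obs_var, "theta_site_pi": theta_site,
            "theta_site_watterson": theta_w_site, "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# LD decay permutation test
# ---------------------------------------------------------------------------

def ld_decay_test(
    ldmatrix: LDMatrix,
    permutations: int = 10_000,
    seed: int | None = None,
) -> RecombinationReport:
    """Permutation test for negative correlation of r^2 with distance.

    Site labels (positions) are permuted among the sites, pair distances
    recomputed, and p is the fraction of permutations with correlation <=
    observed.  When the number of sites is small enough that all orderings
    fit in the permutation budget, the test enumerates them exhaustively.
    """
    if len(ldmatrix) < 10:
        raise ValueError("need at least 10 site pairs for the decay test")
    site_positions = sorted(
        {p.pos_i for p in ldmatrix.pairs} | {p.pos_j for p in ldmatrix.pairs}
    )
    S = len(site_positions)
    pos_index = {p: k for k, p in enumerate(site_positions)}
    pair_idx = np.array(
        [(pos_index[p.pos_i], pos_index[p.pos_j]) for p in ldmatrix.pairs]
    )
    r2 = np.array([p.r2 for p in ldmatrix.pairs])
    pos_arr = np.array(site_positions, dtype=float)
    if np.std(r2) == 0:
        raise FloatingPointError("r^2 constant across pairs; no decay signal")

    def corr_for(assignment: np.ndarray) -> float:
        d = np.abs(assignment[pair_idx[:, 0]] - assignment[pair_idx[:, 1]])
        if np.std(d) == 0:
            return 0.0
        return float(np.corrcoef(r2, d)[0, 1])

    observed = corr_for(pos_arr)
    exhaustive = math.factorial(S) <= permutations
    if exhaustive:
        count = 0
        total = 0
        for perm in itertools.permutations(pos_arr):
            total += 1
            if corr_for(np.array(perm)) <= observed + 1e-12:
                count += 1
        p = count / total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(permutations):
            if corr_for(rng.permutation(pos_arr)) <= observed + 1e-12:
                count += 1
        p = (count + 1) / (permutations + 1)
    return RecombinationReport(
        decay_correlation=observed,
        decay_p=p,
        details={"exhaustive": exhaustive, "permutations": permutations,
                 "seed": seed, "n_sites": S},
    )
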