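"""Neutrality tests: frequency-spectrum and LD-based statistics with simulated
nulls, plus the HKA and McDonald–Kreitman tests and Hudson's haplotype test.

All sample statistics have a core implementation on a 0/1 haplotype matrix
(rows = sequences, columns = biallelic segregating sites, -1 = missing) so
that the same code path evaluates observed data and coalescent replicates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from . import coalescent
from .diversity import harmonic_number, resolve_mask
from .locus import AlignedLocus, SiteTable, _pathway_changes

UNDEFINED = float("nan")


@dataclass
class NeutralityResult:
    statistic: str
    value: float
    p_value: float | None = None
    tail: str | None = None
    null_quantiles: dict = field(default_factory=dict)
    conditioning: dict = field(default_factory=dict)
    details: dict = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return not np.isnan(self.value)


# ---------------------------------------------------------------------------
# Binary haplotype matrix extraction
# ---------------------------------------------------------------------------

def biallelic_matrix(
    locus: AlignedLocus,
    sites: SiteTable | None = None,
    mask: str = "all",
    rows: np.ndarray | None = None,
    exclude_singletons: bool = False,
):
    """(matrix, positions): biallelic segregating sites coded 0/1, -1 missing.

    0 is the major allele.  Sites with more than two alleles are dropped.
    """
    if rows is None:
        rows = locus.ingroup_indices()
    col_mask = resolve_mask(locus, sites, mask, rows)
    sub = locus.matrix[rows]
    cols = []
    codes = []
    for col in np.flatnonzero(col_mask):
        column = sub[:, col]
        missing = column == "N"
        residues = column[~missing]
        alleles, counts = np.unique(residues, return_counts=True)
        if len(alleles) != 2:
            continue
        if exclude_singletons and counts.min() == 1:
            continue
        major = alleles[np.argmax(counts)]
        code = np.where(missing, -1, np.where(column == major, 0, 1))
        cols.append(col + 1)
        codes.append(code.astype(np.int8))
    if not codes:
        return np.zeros((len(rows), 0), dtype=np.int8), np.array([], dtype=int)
    return np.column_stack(codes), np.array(cols)


# ---------------------------------------------------------------------------
# Core statistics on 0/1 matrices
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict:
    """Tajima (1989) normalization constants."""
    a1 = harmonic_number(n)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d_matrix(matrix: np.ndarray) -> float:
    """Tajima's D from a 0/1 matrix (missing = -1 handled pairwise)."""
    n, S = matrix.shape
    if S == 0 or n < 2:
        return UNDEFINED
    valid = matrix >= 0
    # Mean pairwise differences (per locus).
    total = 0.0
    npairs = 0
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        diff = (matrix[i] != matrix[i + 1 :]) & both
        total += diff.sum()
        npairs += matrix.shape[0] - i - 1
    pi_total = total / npairs
    c = tajima_constants(n)
    theta_total = S / c["a1"]
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:
        return UNDEFINED
    return float((pi_total - theta_total) / np.sqrt(var))


def r_squared_pair(x: np.ndarray, y: np.ndarray) -> float:
    """r^2 between two 0/1 site columns on pairwise-complete sequences."""
    both = (x >= 0) & (y >= 0)
    x, y = x[both], y[both]
    p1, p2 = x.mean(), y.mean()
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        return UNDEFINED
    p11 = float(np.mean((x == 1) & (y == 1)))
    D = p11 - p1 * p2
    return float(D * D / (p1 * (1 - p1) * p2 * (1 - p2)))


def kelly_zns_matrix(matrix: np.ndarray) -> float:
    """Kelly's ZnS: mean r^2 over all pairs of biallelic segregating sites."""
    S = matrix.shape[1]
    if S < 2:
        return UNDEFINED
    vals = []
    for i, j in itertools.combinations(range(S), 2):
        r2 = r_squared_pair(matrix[:, i], matrix[:, j])
        if not np.isnan(r2):
            vals.append(r2)
    if not vals:
        return UNDEFINED
    return float(np.mean(vals))


def _site_partition(col: np.ndarray) -> frozenset | None:
    """Canonical bipartition induced by a site (indices of one side).

    Uses only non-missing entries; canonicalized so that complementary
    labelings are identified.  Returns None for monomorphic restrictions.
    """
    idx = np.flatnonzero(col >= 0)
    ones = frozenset(int(i) for i in idx[col[idx] == 1])
    zeros = frozenset(int(i) for i in idx[col[idx] == 0])
    if not ones or not zeros:
        return None
    return min(ones, zeros, key=lambda s: (len(s), sorted(s)))


def wall_b_q_matrix(matrix: np.ndarray):
    """Wall (1999) B and Q from a 0/1 matrix; returns (B, Q, B_prime, A).

    A pair of adjacent segregating sites is congruent when both induce the
    same sample bipartition.  B = B'/(S-1); Q = (B' + A)/S with A the number
    of distinct bipartitions among congruent adjacent pairs.
    """
    S = matrix.shape[1]
    if S < 2:
        return UNDEFINED, UNDEFINED, 0, 0
    partitions = [_site_partition(matrix[:, j]) for j in range(S)]
    b_prime = 0
    congruent_partitions = set()
    for j in range(S - 1):
        p1, p2 = partitions[j], partitions[j + 1]
        if p1 is not None and p1 == p2:
            b_prime += 1
            congruent_partitions.add(p1)
    A = len(congruent_partitions)
    return b_prime / (S - 1), (b_prime + A) / S, b_prime, A


# ---------------------------------------------------------------------------
# Locus-level wrappers with simulated nulls
# ---------------------------------------------------------------------------

def _simulated_p(
    stat_func, observed, n, S, rho_per_site, L, reps, seed, tail,
    statistic_name,
):
    null = coalescent.null_distribution(
        lambda rep: stat_func(rep.matrix),
        n=n, S=S, rho_per_site=rho_per_site, L=L, reps=reps, seed=seed,
        statistic_name=statistic_name,
    )
    p = null.empirical_p(observed, tail=tail)
    qlev = null.quantile_levels
    return p, dict(zip(qlev, null.quantiles)), null.params


def tajima_d(
    locus: AlignedLocus,
    sites: SiteTable | None = None,
    mask: str = "all",
    rows: np.ndarray | None = None,
    rho_per_site: float = 0.0,
    reps: int = 0,
    seed: int | None = None,
) -> NeutralityResult:
    """Tajima's D with an optional simulated two-tailed p-value."""
    matrix, _ = biallelic_matrix(locus, sites, mask, rows)
    value = tajima_d_matrix(matrix)
    result = NeutralityResult("TajimaD", value, tail="two-sided")
    if reps and result.defined:
        p, q, cond = _simulated_p(
            tajima_d_matrix, value, matrix.shape[0], matrix.shape[1],
            rho_per_site, locus.L, reps, seed, "two-sided", "TajimaD",
        )
        result.p_value, result.null_quantiles, result.conditioning = p, q, cond
    return result


def kelly_zns(
    locus: AlignedLocus,
    sites: SiteTable | None = None,
    mask: str = "all",
    rows: np.ndarray | None = None,
    rho_per_site: float = 0.0,
    reps: int = 0,
    seed: int | None = None,
) -> NeutralityResult:
    """Kelly's ZnS with an optional simulated upper-tail p-value."""
    matrix, _ = biallelic_matrix(locus, sites, mask, rows)
    value = kelly_zns_matrix(matrix)
    result = NeutralityResult("ZnS", value, tail="upper")
    if reps and result.defined:
        p, q, cond = _simulated_p(
            kelly_zns_matrix, value, matrix.shape[0], matrix.shape[1],
            rho_per_site, locus.L, reps, seed, "upper", "ZnS",
        )
        result.p_value, result.null_quantiles, result.conditioning = p, q, cond
    return result


def wall_b_q(
    locus: AlignedLocus,
    sites: SiteTable | None = None,
    mask: str = "all",
    rows: np.ndarray | None = None,
    rho_per_site: float = 0.0,
    reps: int = 0,
    seed: int | None = None,
) -> tuple[NeutralityResult, NeutralityResult]:
    """Wall's B and Q with optional simulated upper-tail p-values."""
    matrix, _ = biallelic_matrix(locus, sites, mask, rows)
    B, Q, b_prime, A = wall_b_q_matrix(matrix)
    res_b = NeutralityResult("WallB", B, tail="upper",
                             details={"b_prime": b_prime})
    res_q = NeutralityResult("WallQ", Q, tail="upper", details={"A": A})
    if reps and res_b.defined:
        n, S = matrix.shape
        pB, qB, cond = _simulated_p(
            lambda m: wall_b_q_matrix(m)[0], B, n, S,
            rho_per_site, locus.L, reps, seed, "upper", "WallB",
        )
        res_b.p_value, res_b.null_quantiles, res_b.conditioning = pB, qB, cond
        pQ, qQ, cond = _simulated_p(
            lambda m: wall_b_q_matrix(m)[1], Q, n, S,
            rho_per_site, locus.L, reps, seed, "upper", "WallQ",
        )
        res_q.p_value, res_q.null_quantiles, res_q.conditioning = pQ, qQ, cond
    return res_b, res_q


# ---------------------------------------------------------------------------
# McDonald–Kreitman
# ---------------------------------------------------------------------------

def mk_test(
    locus: AlignedLocus,
    sites: SiteTable,
    outgroup_id: str,
) -> NeutralityResult:
    """McDonald–Kreitman 2x2 test of coding polymorphism vs fixation.

    The table is [[Ps, Pn], [Ds, Dn]] (rows: polymorphic, fixed; columns:
    synonymous, nonsynonymous).  Fixed differences are positions where the
    ingroup is monomorphic and differs from the outgroup; their syn/nonsyn
    attribution follows minimal mutational pathways between the ingroup and
    outgroup codons (fractions assigned to the majority interpretation).
    """
    if outgroup_id not in locus.ids:
        raise ValueError(f"outgroup {outgroup_id!r} not in alignment")
    ingroup = locus.ingroup_indices()
    out_idx = locus.ids.index(outgroup_id)

    Ps = len(sites.positions(classes=("synonymous",)))
    Pn = len(sites.positions(classes=("nonsynonymous",)))

    all_rows = np.append(ingroup, out_idx)
    gap_free = locus.gap_free_mask(all_rows)
    Ds = 0.0
    Dn = 0.0
    seg_positions = {s.position for s in sites.sites}
    for _, positions in locus.annotation.codon_map(locus.L):
        cols = [p - 1 for p in positions]
        if not all(gap_free[c] for c in cols):
            continue
        ing_block = locus.matrix[np.ix_(ingroup, cols)]
        out_codon = "".join(locus.matrix[out_idx, cols])
        if "N" in out_codon:
            continue
        # ingroup consensus codon, only at ingroup-monomorphic positions
        fixed_pos = []
        consensus = []
        for k, c in enumerate(cols):
            column = ing_block[:, k]
            residues = column[column != "N"]
            alleles = np.unique(residues)
            if len(alleles) == 0:
                consensus = None
                break
            consensus.append(str(alleles[0]) if len(alleles) == 1
                             else str(out_codon[k]))
            if len(alleles) == 1 and alleles[0] != out_codon[k] \
                    and (c + 1) not in seg_positions:
                fixed_pos.append(k)
        if consensus is None or not fixed_pos:
            continue
        ing_codon = "".join(consensus)
        attribution = _pathway_changes(ing_codon, out_codon)
        for k in fixed_pos:
            if k in attribution:
                s, ns = attribution[k]
                if s >= ns:
                    Ds += 1
                else:
                    Dn += 1

    table = np.array([[Ps, Pn], [int(Ds), int(Dn)]])
    details = {"table": table.tolist()}
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return NeutralityResult(
            "MK", UNDEFINED, details={**details, "flag": "zero margin"}
        )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    ni = UNDEFINED
    if Ps > 0 and Dn > 0:
        ni = (Pn / Ps) / (Dn / Ds) if Ds > 0 else UNDEFINED
    return NeutralityResult(
        "MK", float(odds), p_value=float(p), tail="two-sided",
        details={**details, "neutrality_index": ni},
    )


# ---------------------------------------------------------------------------
# HKA
# ---------------------------------------------------------------------------

def hka_test(loci: list[dict]) -> NeutralityResult:
    """Hudson–Kaplan–Aguadé (1987) multilocus polymorphism/divergence test.

    Each locus is a dict with keys ``S`` (segregating sites in the sample),
    ``K`` (per-site divergence to the other species), ``N`` (sites) and ``n``
    (sample size).  Divergence counts D = K*N.  Expectations under equal
    population sizes: E[S_i] = theta_i*a1(n_i), E[D_i] = theta_i*(T+1);
    variances E[S_i] + theta_i^2*a2(n_i) and E[D_i] + theta_i^2.  Parameters
    solve the method-of-moments system; the goodness-of-fit sum is compared
    to chi^2 with (loci - 1) d.f. (an approximation, flagged as such).
    """
    if len(loci) < 2:
        raise ValueError("HKA needs at least 2 loci")
    S = np.array([float(x["S"]) for x in loci])
    D = np.array([float(x["K"]) * float(x["N"]) for x in loci])
    n = np.array([int(x["n"]) for x in loci])
    a1 = np.array([harmonic_number(k) for k in n])
    a2 = np.array([float(np.sum(1.0 / np.arange(1, k) ** 2)) for k in n])

    def theta_hat(T):
        return (S + D) / (a1 + T + 1.0)

    def moment_gap(T):
        th = theta_hat(T)
        return float(np.sum(th * a1) - S.sum())

    lo, hi = 1e-9, 1e9
    glo, ghi = moment_gap(lo), moment_gap(hi)
    if glo * ghi > 0:
        raise FloatingPointError(
            "HKA moment system has no root: "
            f"gap({lo})={glo:.3g}, gap({hi})={ghi:.3g}; check inputs"
        )
    T = float(optimize.brentq(moment_gap, lo, hi, xtol=1e-12))
    th = theta_hat(T)
    ES = th * a1
    ED = th * (T + 1.0)
    varS = ES + th**2 * a2
    varD = ED + th**2
    x2 = float(np.sum((S - ES) ** 2 / varS) + np.sum((D - ED) ** 2 / varD))
    df = len(loci) - 1
    p = float(stats.chi2.sf(x2, df))
    return NeutralityResult(
        "HKA", x2, p_value=p, tail="upper",
        details={
            "theta_hat": th.tolist(), "T_hat": T, "df": df,
            "approximation": "chi-square",
        },
    )


# ---------------------------------------------------------------------------
# Hudson's haplotype test
# ---------------------------------------------------------------------------

def _subset_exists(matrix: np.ndarray, i: int, j: int) -> bool:
    """Exact test: is there a subset of >= i rows with <= j segregating sites?

    Branch-and-bound over distinct haplotypes.  A qualifying subset's members
    all lie within Hamming distance j of each member, and its segregating
    columns are the union of difference columns to any fixed anchor member.
    """
    n, S = matrix.shape
    if i <= 1 or (i <= n and j >= S):
        return True
    haplos, counts = np.unique(matrix, axis=0, return_counts=True)
    if counts.max() >= i:
        return True
    H = len(haplos)
    # pairwise difference-column sets between distinct haplotypes
    diff = haplos[:, None, :] != haplos[None, :, :]
    hamming = diff.sum(axis=2)
    for a in range(H):
        near = np.flatnonzero(hamming[a] <= j)
        if counts[near].sum() < i:
            continue
        # candidates excluding anchor, sorted by count descending
        cands = [h for h in near if h != a]
        cands.sort(key=lambda h: -counts[h])
        diffcols = {h: frozenset(np.flatnonzero(diff[a, h])) for h in cands}
        target = i - counts[a]
        if target <= 0:
            return True
        # DFS: pick candidates, track union of difference columns
        suffix_counts = np.cumsum([counts[h] for h in cands][::-1])[::-1]

        def dfs(idx: int, got: int, union: frozenset) -> bool:
            if got >= target:
                return True
            if idx >= len(cands):
                return False
            if got + suffix_counts[idx] < target:
                return False
            h = cands[idx]
            new_union = union | diffcols[h]
            if len(new_union) <= j and dfs(idx + 1, got + counts[h], new_union):
                return True
            return dfs(idx + 1, got, union)

        if dfs(0, 0, frozenset()):
            return True
    return False


def _subset_greedy(matrix: np.ndarray, i: int, j: int) -> bool:
    """Greedy lower-bound fallback: may miss subsets (conservative direction
    for an upper-tail probability of 'few-polymorphism subsets exist')."""
    haplos, counts = np.unique(matrix, axis=0, return_counts=True)
    diff = haplos[:, None, :] != haplos[None, :, :]
    for a in range(len(haplos)):
        union: frozenset = frozenset()
        got = counts[a]
        order = np.argsort(diff[a].sum(axis=1))
        for h in order:
            if h == a:
                continue
            cand = union | frozenset(np.flatnonzero(diff[a, h]))
            if len(cand) <= j:
                union = cand
                got += counts[h]
        if got >= i:
            return True
    return False


def haplotype_test(
    n: int,
    S: int,
    rho_per_site: float,
    i: int,
    j: int,
    L: int = 1000,
    reps: int = 10_000,
    seed: int | None = None,
    exact: bool = True,
    max_exact_n: int = 80,
) -> NeutralityResult:
    """Hudson's haplotype test.

    p = fraction of fixed-S coalescent replicates (conditional on n, S, L and
    rho) containing at least ``i`` sequences whose restriction segregates at
    no more than ``j`` sites.  Subset existence is decided exactly by
    branch-and-bound unless n exceeds ``max_exact_n``, in which case a greedy
    lower-bound search is used (warned; biases p downward conservatively for
    detecting an excess of near-identical haplotype subsets, i.e. the
    reported p is if anything an underestimate of the true simulated p).
    """
    if i > n or j > S:
        raise ValueError("need i <= n and j <= S")
    if reps < 1000:
        raise ValueError("reps must be >= 1000 for a stable p")
    use_exact = exact and n <= max_exact_n
    if not use_exact:
        import warnings

        warnings.warn("falling back to greedy subset search (n too large)")
    hits = 0
    for rep in coalescent.simulate_sample(
        n, L, "fixed_s", S, rho_per_site, reps, seed
    ):
        found = (
            _subset_exists(rep.matrix, i, j)
            if use_exact
            else _subset_greedy(rep.matrix, i, j)
        )
        hits += int(found)
    p = hits / reps
    return NeutralityResult(
        "HaplotypeTest", p, p_value=p, tail="lower",
        conditioning={
            "n": n, "S": S, "rho_per_site": rho_per_site, "i": i, "j": j,
            "L": L, "reps": reps, "seed": seed, "exact": use_exact,
        },
    )
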