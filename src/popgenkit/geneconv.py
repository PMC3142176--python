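"""Statistical scan for intragenic gene-conversion tracts.

The alignment is condensed to its silent polymorphic sites.  For every pair
of sequences the maximal uninterrupted runs of identity ("fragments") are
identified; unusually long fragments betray gene-conversion tracts copied
between diverged haplotypes.  Significance comes from permuting the order of
the condensed site columns, which destroys physical clustering of identity
while preserving every pair's match/mismatch composition (Sawyer 1989).

Statistics:
* SSCF — sum over all pairs of squared condensed fragment lengths; its
  global permutation p-value tests for clustering of identity overall.
* SSUF — the same sum with physical (uninterrupted) fragment lengths,
  reported descriptively.
* per-fragment significance — each fragment is compared with the permutation
  distribution of *its own pair's* maximum condensed run length.  Comparing
  against the pair's own null is essential: a pair differing at only one or
  two sites has long identity runs under any column order, and a global
  maximum-run null would be dominated by such near-identical pairs.
  Fragments touching the alignment ends are flagged "outer" and excluded
  from the mean tract length, following Sawyer's convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .locus import AlignedLocus, SiteTable
from .neutrality import biallelic_matrix


@dataclass
class Fragment:
    seq_i: str
    seq_j: str
    start: int            # physical 1-based bound (exclusive mismatch + 1)
    end: int
    condensed_length: int
    physical_length: int
    outer: bool
    p_value: float | None = None
    significant: bool = False


@dataclass
class ConversionScan:
    n_condensed_sites: int
    positions: np.ndarray
    fragments: list[Fragment]
    sscf: float
    ssuf: float
    sscf_p: float
    pair_thresholds: dict = field(default_factory=dict)
    significant_fragments: list[Fragment] = field(default_factory=list)
    mean_significant_physical_length: float | None = None
    details: dict = field(default_factory=dict)


def _pair_runs(eq: np.ndarray):
    """Maximal runs of True in a boolean identity vector.

    Returns list of (start_idx, end_idx) inclusive condensed indices.
    """
    runs = []
    i = 0
    m = len(eq)
    while i < m:
        if eq[i]:
            j = i
            while j + 1 < m and eq[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def _informative_pairs(matrix: np.ndarray, ids):
    """(pair id list, match matrix, mismatch matrix) over informative pairs.

    A pair identical at every comparable condensed site carries no
    information about clustering and is dropped.  Missing entries are neither
    match nor mismatch: runs continue across them, mirroring the condensed
    per-pair site sequence with missing sites skipped.
    """
    n, S = matrix.shape
    pair_ids = []
    match_rows = []
    mismatch_rows = []
    for a, b in itertools.combinations(range(n), 2):
        x, y = matrix[a], matrix[b]
        usable = (x >= 0) & (y >= 0)
        if not usable.any():
            continue
        eq = (x == y) & usable
        ne = (x != y) & usable
        if not ne.any():
            continue  # identical pair: uninformative
        pair_ids.append((ids[a], ids[b]))
        match_rows.append(eq)
        mismatch_rows.append(ne)
    if not pair_ids:
        return [], np.zeros((0, S), bool), np.zeros((0, S), bool)
    return pair_ids, np.array(match_rows), np.array(mismatch_rows)


def _pair_stats_for_order(match: np.ndarray, mismatch: np.ndarray, order):
    """Per-pair (SSCF contribution, max run) for one column order, vectorized.

    ``match``/``mismatch`` are (pairs, S) booleans; missing entries (neither)
    extend the current run without adding to its length.
    """
    P = match.shape[0]
    acc = np.zeros(P, dtype=np.int64)
    sscf = np.zeros(P, dtype=np.int64)
    max_run = np.zeros(P, dtype=np.int64)
    for j in order:
        m = match[:, j]
        x = mismatch[:, j]
        acc = np.where(m, acc + 1, acc)
        closing = x & (acc > 0)
        sscf += np.where(closing, acc * acc, 0)
        np.maximum(max_run, np.where(closing, acc, 0), out=max_run)
        acc = np.where(x, 0, acc)
    sscf += acc * acc
    np.maximum(max_run, acc, out=max_run)
    return sscf, max_run


def _fragments_for_matrix(matrix: np.ndarray, positions: np.ndarray, ids, L: int):
    """All per-pair fragments plus SSCF/SSUF totals."""
    n, S = matrix.shape
    fragments = []
    sscf = 0.0
    ssuf = 0.0
    for a, b in itertools.combinations(range(n), 2):
        x, y = matrix[a], matrix[b]
        usable = (x >= 0) & (y >= 0)
        idx = np.flatnonzero(usable)
        if len(idx) == 0:
            continue
        eq = x[idx] == y[idx]
        if eq.all():
            # pair identical over all condensed sites: uninformative
            continue
        for s, e in _pair_runs(eq):
            cond_len = e - s + 1
            outer = s == 0 or e == len(idx) - 1
            # physical bounds: between flanking mismatches, exclusive
            left = int(positions[idx[s - 1]]) + 1 if s > 0 else 1
            right = int(positions[idx[e + 1]]) - 1 if e < len(idx) - 1 else L
            phys_len = right - left + 1
            fragments.append(
                Fragment(
                    seq_i=ids[a], seq_j=ids[b],
                    start=left, end=right,
                    condensed_length=cond_len,
                    physical_length=phys_len,
                    outer=outer,
                )
            )
            sscf += cond_len**2
            ssuf += phys_len**2
    return fragments, sscf, ssuf


def sawyer_scan(
    locus: AlignedLocus,
    sites: SiteTable | None = None,
    mask: str = "silent",
    rows: np.ndarray | None = None,
    permutations: int = 10_000,
    seed: int | None = None,
) -> ConversionScan:
    """Gene-conversion scan with column-permutation significance.

    When the number of condensed sites is small enough for the permutation
    budget, all column orders are enumerated exactly and p-values are plain
    fractions; otherwise random permutations are used with the (b+1)/(B+1)
    convention.
    """
    if rows is None:
        rows = locus.ingroup_indices()
    matrix, positions = biallelic_matrix(locus, sites, mask, rows)
    ids = [locus.ids[i] for i in rows]
    if matrix.shape[1] < 2:
        return ConversionScan(
            n_condensed_sites=matrix.shape[1], positions=positions,
            fragments=[], sscf=0.0, ssuf=0.0, sscf_p=float("nan"),
            details={"flag": "fewer than 2 silent polymorphic sites"},
        )
    fragments, sscf_obs, ssuf_obs = _fragments_for_matrix(
        matrix, positions, ids, locus.L
    )
    pair_ids, match, mismatch = _informative_pairs(matrix, ids)
    S = matrix.shape[1]

    exhaustive = math.factorial(S) <= permutations
    if exhaustive:
        orders = [list(p) for p in itertools.permutations(range(S))]
    else:
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(S) for _ in range(permutations)]
    B = len(orders)
    null_sscf = np.empty(B)
    null_pair_max = np.empty((B, len(pair_ids)), dtype=np.int64)
    for k, order in enumerate(orders):
        per_pair_sscf, per_pair_max = _pair_stats_for_order(
            match, mismatch, order
        )
        null_sscf[k] = per_pair_sscf.sum()
        null_pair_max[k] = per_pair_max

    if exhaustive:
        sscf_p = float(np.mean(null_sscf >= sscf_obs - 1e-9))
    else:
        sscf_p = float(
            (np.sum(null_sscf >= sscf_obs - 1e-9) + 1) / (B + 1)
        )

    pair_index = {pid: k for k, pid in enumerate(pair_ids)}
    pair_thresholds = {
        pid: float(np.quantile(null_pair_max[:, k], 0.95))
        for pid, k in pair_index.items()
    }
    significant = []
    for frag in fragments:
        k = pair_index.get((frag.seq_i, frag.seq_j))
        if k is None:
            continue
        exceed = int(np.sum(null_pair_max[:, k] >= frag.condensed_length))
        frag.p_value = (
            exceed / B if exhaustive else (exceed + 1) / (B + 1)
        )
        if frag.condensed_length > pair_thresholds[(frag.seq_i, frag.seq_j)]:
            frag.significant = True
            significant.append(frag)
    inner_sig = [f for f in significant if not f.outer]
    mean_len = (
        float(np.mean([f.physical_length for f in inner_sig]))
        if inner_sig
        else None
    )
    return ConversionScan(
        n_condensed_sites=S,
        positions=positions,
        fragments=fragments,
        sscf=sscf_obs,
        ssuf=ssuf_obs,
        sscf_p=sscf_p,
        pair_thresholds=pair_thresholds,
        significant_fragments=significant,
        mean_significant_physical_length=mean_len,
        details={
            "exhaustive": exhaustive, "permutations": permutations,
            "seed": seed, "n_informative_pairs": len(pair_ids),
        },
    )
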