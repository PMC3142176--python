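"""Nucleotide diversity, divergence, GC content, and sliding-window series.

Definitions follow the classical sample estimators:

* pi — average number of pairwise nucleotide differences per site among all
  pairs of sequences (Nei 1987 eq. 10.5 style, with per-pair complete sites).
* theta (Watterson) — S / (a1 * N) with a1 = sum_{i=1}^{n-1} 1/i, where N is
  the number of analyzed sites with indel-containing columns excluded.
* K — mean over ingroup sequences of the per-site difference to a named
  outgroup sequence, optionally Jukes–Cantor corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .locus import AlignedLocus, SiteTable

MISSING = float("nan")


class UndefinedStatisticError(ValueError):
    """Raised when a statistic has no defined value on the given mask."""


def harmonic_number(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))  # a1 = sum_{i=1}^{n-1} 1/i


def resolve_mask(
    locus: AlignedLocus,
    sites: SiteTable | None,
    mask: str,
    rows: np.ndarray,
) -> np.ndarray:
    """Boolean column mask (0-based) for a named site-class selector.

    ``mask`` is one of: all, silent, synonymous, nonsynonymous, noncoding,
    coding, intron, flank.  Gap-containing columns (among the selected rows)
    are always excluded.  For class selectors that need per-site codon
    classification (synonymous / nonsynonymous / silent), segregating exon
    columns use the SiteTable classes; invariant exon columns count as
    potentially synonymous only for "coding"/"all" masks — the class masks
    select columns by annotation for noncoding and by SiteTable for exon
    columns, plus all annotated-class invariant columns for region masks.
    """
    L = locus.L
    gap_free = locus.gap_free_mask(rows)
    ann = locus.annotation
    if mask == "all":
        base = np.ones(L, dtype=bool)
    elif mask in ("noncoding", "ncod"):
        base = ann.positions_of_class(("intron", "flank"), L)
    elif mask == "intron":
        base = ann.positions_of_class(("intron",), L)
    elif mask == "flank":
        base = ann.positions_of_class(("flank",), L)
    elif mask == "coding":
        base = ann.positions_of_class(("exon",), L)
    elif mask in ("synonymous", "nonsynonymous"):
        base = np.zeros(L, dtype=bool)
        if sites is None:
            raise ValueError(f"mask {mask!r} requires a SiteTable")
        want = mask
        exon = ann.positions_of_class(("exon",), L)
        seg_positions = {s.position: s.cls for s in sites.sites}
        for col in range(L):
            if not exon[col]:
                continue
            cls = seg_positions.get(col + 1)
            if cls is None or cls == want:
                # invariant exon columns belong to both potential classes;
                # they are included so per-site rates use a site denominator
                base[col] = True
    elif mask == "silent":
        # synonymous segregating + all noncoding + exon columns that are not
        # nonsynonymous/ambiguous segregating
        base = ann.positions_of_class(("intron", "flank"), L).copy()
        exon = ann.positions_of_class(("exon",), L)
        bad = set()
        if sites is not None:
            bad = {
                s.position
                for s in sites.sites
                if s.cls in ("nonsynonymous", "ambiguous")
            }
        for col in range(L):
            if exon[col] and (col + 1) not in bad:
                base[col] = True
    else:
        raise ValueError(f"unknown mask {mask!r}")
    return base & gap_free


@dataclass
class DiversityReport:
    mask: str
    n: int
    N: int  # analyzed sites (indel columns excluded)
    S: int
    singletons: int
    pi: float
    theta: float
    mean_pairwise: float  # per-locus mean pairwise differences


@dataclass
class DivergenceReport:
    outgroup_id: str
    mask: str
    N: int
    K_raw: float
    K_jc: float


@dataclass
class WindowSeries:
    statistic: str
    window: int
    step: int
    midpoints: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    valid_sites: np.ndarray


def _pairwise_difference_stats(sub: np.ndarray, cols: np.ndarray):
    """Mean per-pair difference count and per-pair valid-site count.

    Missing data (N) handled pairwise: a site enters a pair's comparison only
    if both sequences have a residue there.
    """
    block = sub[:, cols]
    n = block.shape[0]
    valid = (block != "N") & (block != "-")
    total_diff = 0.0
    total_pairs = 0
    per_site_sum = 0.0
    for i in range(n - 1):
        vi = valid[i]
        bi = block[i]
        both = vi & valid[i + 1 :]
        diff = (bi != block[i + 1 :]) & both
        nsites = both.sum(axis=1)
        ndiff = diff.sum(axis=1)
        ok = nsites > 0
        per_site_sum += float((ndiff[ok] / nsites[ok]).sum())
        total_diff += float(ndiff.sum())
        total_pairs += int(ok.sum())
    return total_diff, per_site_sum, total_pairs


def diversity_stats(
    locus: AlignedLocus,
    sites: SiteTable | None = None,
    mask: str = "all",
    rows: np.ndarray | None = None,
) -> DiversityReport:
    """Compute pi, Watterson's theta, S and singleton counts on a mask."""
    if rows is None:
        rows = locus.ingroup_indices()
    n = len(rows)
    if n < 2:
        raise ValueError("diversity requires at least 2 sequences")
    cols = np.flatnonzero(resolve_mask(locus, sites, mask, rows))
    N = len(cols)
    if N == 0:
        raise UndefinedStatisticError(f"no analyzable sites under mask {mask!r}")
    sub = locus.matrix[rows]
    block = sub[:, cols]

    # Segregating sites among non-missing residues.
    S = 0
    singletons = 0
    for j in range(block.shape[1]):
        column = block[:, j]
        residues = column[column != "N"]
        alleles, counts = np.unique(residues, return_counts=True)
        if len(alleles) >= 2:
            S += 1
            if len(alleles) == 2 and counts.min() == 1:
                singletons += 1

    total_diff, per_site_sum, total_pairs = _pairwise_difference_stats(sub, cols)
    pi = per_site_sum / total_pairs
    mean_pairwise = total_diff / total_pairs
    theta = S / (harmonic_number(n) * N)
    return DiversityReport(
        mask=mask, n=n, N=N, S=S, singletons=singletons,
        pi=pi, theta=theta, mean_pairwise=mean_pairwise,
    )


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor distance for raw proportion p (inf when saturated)."""
    if p >= 0.75:
        return float("inf")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def divergence_k(
    locus: AlignedLocus,
    outgroup_id: str,
    sites: SiteTable | None = None,
    mask: str = "all",
    rows: np.ndarray | None = None,
) -> DivergenceReport:
    """Mean per-site divergence of the ingroup sample to one outgroup."""
    if outgroup_id not in locus.ids:
        raise ValueError(f"outgroup {outgroup_id!r} not in alignment")
    if rows is None:
        rows = locus.ingroup_indices()
    out_idx = locus.ids.index(outgroup_id)
    all_rows = np.append(rows, out_idx)
    cols = np.flatnonzero(resolve_mask(locus, sites, mask, all_rows))
    if len(cols) == 0:
        raise UndefinedStatisticError(f"no analyzable sites under mask {mask!r}")
    out_seq = locus.matrix[out_idx][cols]
    out_valid = out_seq != "N"
    ps = []
    for i in rows:
        seq = locus.matrix[i][cols]
        both = out_valid & (seq != "N")
        nsites = int(both.sum())
        if nsites == 0:
            continue
        ps.append(float(((seq != out_seq) & both).sum()) / nsites)
    K_raw = float(np.mean(ps))
    return DivergenceReport(
        outgroup_id=outgroup_id, mask=mask, N=len(cols),
        K_raw=K_raw, K_jc=jukes_cantor(K_raw),
    )


def gc_fraction(
    locus: AlignedLocus,
    sites: SiteTable | None = None,
    mask: str = "all",
    rows: np.ndarray | None = None,
) -> float:
    """(G+C)/(A+C+G+T) over all selected sequences and masked columns."""
    if rows is None:
        rows = np.arange(locus.n)
    cols = np.flatnonzero(resolve_mask(locus, sites, mask, rows))
    if len(cols) == 0:
        raise UndefinedStatisticError("all-gap mask for gc_fraction")
    block = locus.matrix[np.ix_(rows, cols)]
    gc = np.isin(block, ["G", "C"]).sum()
    acgt = np.isin(block, ["A", "C", "G", "T"]).sum()
    if acgt == 0:
        raise UndefinedStatisticError("no residues under mask")
    return float(gc) / float(acgt)


# Named window statistics -----------------------------------------------------

def _window_pi(locus, rows, cols):
    if len(cols) == 0:
        return MISSING
    _, per_site_sum, total_pairs = _pairwise_difference_stats(
        locus.matrix[rows], cols
    )
    if total_pairs == 0:
        return MISSING
    return per_site_sum / total_pairs


def _window_theta(locus, rows, cols):
    if len(cols) == 0:
        return MISSING
    block = locus.matrix[np.ix_(rows, cols)]
    S = 0
    for j in range(block.shape[1]):
        column = block[:, j]
        residues = column[column != "N"]
        if len(np.unique(residues)) >= 2:
            S += 1
    return S / (harmonic_number(len(rows)) * len(cols))


WINDOW_STATISTICS = {"pi": _window_pi, "theta": _window_theta}


def sliding_window(
    locus: AlignedLocus,
    statistic: str = "pi",
    window: int = 100,
    step: int = 1,
    sites: SiteTable | None = None,
    mask: str = "silent",
    min_valid_sites: int = 10,
    rows: np.ndarray | None = None,
) -> WindowSeries:
    """Evaluate a named statistic in sliding windows along the alignment.

    Windows with fewer than ``min_valid_sites`` analyzable columns yield NaN
    (a missing-value marker, not zero).  Missing/excluded sites reduce the
    window's denominator; window bounds are fixed on alignment coordinates.
    """
    if statistic not in WINDOW_STATISTICS:
        raise ValueError(
            f"unknown statistic {statistic!r}; known: {sorted(WINDOW_STATISTICS)}"
        )
    if window > locus.L:
        raise ValueError("window exceeds alignment length")
    if step < 1:
        raise ValueError("step must be >= 1")
    if rows is None:
        rows = locus.ingroup_indices()
    func = WINDOW_STATISTICS[statistic]
    col_mask = resolve_mask(locus, sites, mask, rows)
    starts = np.arange(0, locus.L - window + 1, step)
    values = np.empty(len(starts))
    valid_counts = np.empty(len(starts), dtype=int)
    for k, s in enumerate(starts):
        cols = np.flatnonzero(col_mask[s : s + window]) + s
        valid_counts[k] = len(cols)
        if len(cols) < min_valid_sites:
            values[k] = MISSING
        else:
            values[k] = func(locus, rows, cols)
    return WindowSeries(
        statistic=statistic,
        window=window,
        step=step,
        midpoints=starts + (window + 1) / 2.0,
        starts=starts + 1,
        ends=starts + window,
        values=values,
        valid_sites=valid_counts,
    )
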