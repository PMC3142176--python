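"""Haplotype-group structure: distance trees, differentiation, ΔG comparison.

* ``k2p_nj_tree`` — neighbor-joining on Kimura 2-parameter distances with
  site-bootstrap support values.
* ``group_differentiation`` — Kst (Hudson–Boos–Kaplan) and Fst with label
  permutation p-values, plus Dxy and per-group pi.
* ``group_contrast`` — fixed differences, shared and private polymorphisms.
* ``deltaG_group_test`` — Mann–Whitney comparison of per-sequence mRNA
  folding free energies between haplotype groups (ΔG values are inputs from
  any folding engine; this package does not fold RNA).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .locus import AlignedLocus

logger = logging.getLogger("popgenkit")

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class SaturatedDistanceError(FloatingPointError):
    pass


def k2p_distance(x: np.ndarray, y: np.ndarray, on_saturation: str = "error"):
    """Kimura 2-parameter distance between two aligned sequences.

    Gap and N positions are excluded pairwise.  ``on_saturation`` is "error"
    or "inf" for pairs where a logarithm argument is non-positive.
    """
    ok = np.isin(x, list("ACGT")) & np.isin(y, list("ACGT"))
    xs, ys = x[ok], y[ok]
    m = len(xs)
    if m == 0:
        raise ValueError("no comparable sites between sequences")
    diff = xs != ys
    ts = sum(
        1 for a, b in zip(xs[diff], ys[diff]) if (str(a), str(b)) in TRANSITIONS
    )
    P = ts / m
    Q = (int(diff.sum()) - ts) / m
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        if on_saturation == "inf":
            return float("inf")
        raise SaturatedDistanceError(
            f"saturated pair (P={P:.3f}, Q={Q:.3f})"
        )
    return float(-0.5 * np.log(arg1) - 0.25 * np.log(arg2))


def _k2p_matrix(matrix: np.ndarray, ids, on_saturation="error") -> DistanceMatrix:
    n = matrix.shape[0]
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = k2p_distance(
            matrix[i], matrix[j], on_saturation=on_saturation
        )
    return DistanceMatrix(d, ids)


def _bipartitions(tree: TreeNode, taxa: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions (canonical smaller side) of an NJ tree."""
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = taxa - side
        if 1 < len(side) < len(taxa) - 1:
            parts.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return parts


@dataclass
class TreeWithSupport:
    tree: TreeNode
    support: dict  # bipartition (frozenset of tip names) -> percent support
    bootstrap_replicates: int

    def newick(self) -> str:
        """Newick string with bootstrap percentages as internal node names."""
        taxa = frozenset(t.name for t in self.tree.tips())
        for node in self.tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            key = min(side, taxa - side, key=lambda s: (len(s), sorted(s)))
            if key in self.support:
                node.name = f"{self.support[key]:.0f}"
        return str(self.tree)


def k2p_nj_tree(
    locus: AlignedLocus,
    rows: np.ndarray | None = None,
    bootstrap: int = 1000,
    seed: int | None = None,
    on_saturation: str = "error",
) -> TreeWithSupport:
    """Neighbor-joining tree on K2P distances with site-bootstrap support."""
    if rows is None:
        rows = np.arange(locus.n)
    if len(rows) < 3:
        raise ValueError("NJ needs at least 3 sequences")
    ids = [locus.ids[i] for i in rows]
    sub = locus.matrix[rows]
    dm = _k2p_matrix(sub, ids, on_saturation)
    tree = nj(dm)
    taxa = frozenset(ids)
    target_parts = _bipartitions(tree, taxa)
    counts = {p: 0 for p in target_parts}
    rng = np.random.default_rng(seed)
    for _ in range(bootstrap):
        cols = rng.integers(0, sub.shape[1], size=sub.shape[1])
        try:
            bdm = _k2p_matrix(sub[:, cols], ids, on_saturation="inf")
        except ValueError:
            continue
        bparts = _bipartitions(nj(bdm), taxa)
        for p in target_parts:
            if p in bparts:
                counts[p] += 1
    support = {
        p: 100.0 * c / bootstrap for p, c in counts.items()
    } if bootstrap else {}
    return TreeWithSupport(tree=tree, support=support,
                           bootstrap_replicates=bootstrap)


# ---------------------------------------------------------------------------
# Group differentiation
# ---------------------------------------------------------------------------

def _pairwise_per_site(matrix: np.ndarray, idx_a, idx_b=None):
    """Mean per-site difference over pairs (within idx_a, or between sets)."""
    vals = []
    if idx_b is None:
        pairs = itertools.combinations(idx_a, 2)
    else:
        pairs = itertools.product(idx_a, idx_b)
    for i, j in pairs:
        x, y = matrix[i], matrix[j]
        ok = np.isin(x, list("ACGT")) & np.isin(y, list("ACGT"))
        m = int(ok.sum())
        if m:
            vals.append(float(((x != y) & ok).sum()) / m)
    return float(np.mean(vals)) if vals else float("nan")


def _kst_fst(matrix: np.ndarray, labels: np.ndarray, fst_variant: str):
    groups = [np.flatnonzero(labels == g) for g in np.unique(labels)]
    sizes = np.array([len(g) for g in groups])
    n = sizes.sum()
    within = np.array([_pairwise_per_site(matrix, g) for g in groups])
    kt = _pairwise_per_site(matrix, np.arange(n))
    ks = float(np.sum(sizes / n * within))
    kst = 1.0 - ks / kt if kt > 0 else float("nan")
    if fst_variant == "pi-ratio":
        fst = kst  # same form: 1 - (size-weighted within pi)/(total pi)
    elif fst_variant == "hsm":
        between = [
            _pairwise_per_site(matrix, a, b)
            for a, b in itertools.combinations(groups, 2)
        ]
        hw = float(np.sum(sizes / n * within))
        hb = float(np.mean(between))
        fst = 1.0 - hw / hb if hb > 0 else float("nan")
    else:
        raise ValueError(f"unknown Fst variant {fst_variant!r}")
    return kst, fst, within, kt


@dataclass
class GroupDifferentiation:
    group_labels: list[str]
    group_sizes: list[int]
    kst: float
    fst: float
    fst_variant: str
    p_value: float | None
    dxy: float | None = None
    within_pi: dict = field(default_factory=dict)
    fixed_differences: int | None = None
    shared_polymorphisms: int | None = None
    private_polymorphisms: dict = field(default_factory=dict)
    details: dict = field(default_factory=dict)


def group_differentiation(
    locus: AlignedLocus,
    groups: list[str] | None = None,
    rows: np.ndarray | None = None,
    permutations: int = 1000,
    seed: int | None = None,
    fst_variant: str = "hsm",
) -> GroupDifferentiation:
    """Kst/Fst between haplotype groups with a label-permutation p-value.

    ``fst_variant``: "hsm" (Hudson–Slatkin–Maddison, 1 - Hw/Hb) or
    "pi-ratio" (1 - size-weighted within-group pi / total pi).  Kst always
    follows Hudson–Boos–Kaplan (1 - Ks/Kt, size-weighted Ks).
    Groups with fewer than 2 members are excluded with a warning.
    """
    if rows is None:
        rows = locus.ingroup_indices()
    if groups is None:
        if locus.groups is None:
            raise ValueError("no group labels available")
        groups = [locus.groups[i] for i in rows]
    labels = np.asarray(groups)
    keep = np.ones(len(rows), dtype=bool)
    for g, c in zip(*np.unique(labels, return_counts=True)):
        if c < 2:
            logger.warning("group %r has <2 members; excluded", g)
            keep &= labels != g
    rows = np.asarray(rows)[keep]
    labels = labels[keep]
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups with >= 2 members")
    matrix = locus.matrix[rows]

    kst_obs, fst_obs, within, kt = _kst_fst(matrix, labels, fst_variant)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        perm = rng.permutation(labels)
        kst_p, _, _, _ = _kst_fst(matrix, perm, "pi-ratio")
        if kst_p >= kst_obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (permutations + 1)

    group_idx = [np.flatnonzero(labels == g) for g in uniq]
    dxy = (
        _pairwise_per_site(matrix, group_idx[0], group_idx[1])
        if len(uniq) == 2
        else None
    )
    return GroupDifferentiation(
        group_labels=list(uniq),
        group_sizes=[int(len(g)) for g in group_idx],
        kst=kst_obs,
        fst=fst_obs,
        fst_variant=fst_variant,
        p_value=p,
        dxy=dxy,
        within_pi={str(g): float(w) for g, w in zip(uniq, within)},
        details={"kt": kt, "permutations": permutations, "seed": seed},
    )


def group_contrast(
    locus: AlignedLocus,
    groups: list[str] | None = None,
    rows: np.ndarray | None = None,
) -> GroupDifferentiation:
    """Fixed differences, shared and private polymorphisms between two groups."""
    if rows is None:
        rows = locus.ingroup_indices()
    if groups is None:
        if locus.groups is None:
            raise ValueError("no group labels available")
        groups = [locus.groups[i] for i in rows]
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("group_contrast requires exactly 2 groups")
    rows = np.asarray(rows)
    matrix = locus.matrix[rows]
    idx = {g: np.flatnonzero(labels == g) for g in uniq}
    gap_free = ~(matrix == "-").any(axis=0)

    fixed = 0
    shared = 0
    private = {str(g): 0 for g in uniq}
    for col in np.flatnonzero(gap_free):
        column = matrix[:, col]
        alleles = {}
        for g in uniq:
            vals = column[idx[g]]
            vals = vals[vals != "N"]
            alleles[g] = set(vals.tolist())
        a, b = alleles[uniq[0]], alleles[uniq[1]]
        if not a or not b:
            continue
        if len(a) == 1 and len(b) == 1 and a != b:
            fixed += 1
        elif len(a) > 1 and len(b) > 1 and len(a & b) >= 2:
            shared += 1
        elif len(a) > 1 and len(b) == 1:
            private[str(uniq[0])] += 1
        elif len(b) > 1 and len(a) == 1:
            private[str(uniq[1])] += 1

    within = {
        str(g): _pairwise_per_site(matrix, idx[g]) for g in uniq
    }
    dxy = _pairwise_per_site(matrix, idx[uniq[0]], idx[uniq[1]])
    return GroupDifferentiation(
        group_labels=[str(g) for g in uniq],
        group_sizes=[int(len(idx[g])) for g in uniq],
        kst=float("nan"), fst=float("nan"), fst_variant="n/a", p_value=None,
        dxy=dxy,
        within_pi=within,
        fixed_differences=fixed,
        shared_polymorphisms=shared,
        private_polymorphisms=private,
    )


# ---------------------------------------------------------------------------
# ΔG haplogroup comparison
# ---------------------------------------------------------------------------

@dataclass
class DeltaGTable:
    values: dict[str, float]         # sequence id -> ΔG (kcal/mol)
    groups: dict[str, str]           # sequence id -> group label
    engine: str = "external"

    def __post_init__(self):
        for sid, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite ΔG for {sid}")
            if v > 0:
                logger.warning("positive ΔG for %s (%.3f kcal/mol)", sid, v)


def read_deltag_table(path: str, engine: str = "external") -> DeltaGTable:
    """Parse a tab-separated ΔG table: id, deltaG, group."""
    values, groups = {}, {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in ("id", "sequence"):
                continue
            values[parts[0]] = float(parts[1])
            groups[parts[0]] = parts[2]
    return DeltaGTable(values, groups, engine)


@dataclass
class DeltaGGroupTest:
    group_labels: list[str]
    group_means: dict
    group_sds: dict
    group_ns: dict
    u_statistic: float
    p_value: float
    method: str


def deltaG_group_test(table: DeltaGTable) -> DeltaGGroupTest:
    """Mann–Whitney comparison of folding free energies between two groups.

    Exact for combined n <= 20 (no ties); normal approximation with tie
    correction otherwise.  Two-sided.
    """
    labels = sorted(set(table.groups.values()))
    if len(labels) != 2:
        raise ValueError("deltaG_group_test requires exactly 2 groups")
    samples = {
        g: np.array(
            [v for sid, v in table.values.items() if table.groups[sid] == g]
        )
        for g in labels
    }
    for g, arr in samples.items():
        if len(arr) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 ΔG values")
    x, y = samples[labels[0]], samples[labels[1]]
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return DeltaGGroupTest(
        group_labels=labels,
        group_means={g: float(np.mean(s)) for g, s in samples.items()},
        group_sds={g: float(np.std(s, ddof=1)) for g, s in samples.items()},
        group_ns={g: int(len(s)) for g, s in samples.items()},
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=method,
    )
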