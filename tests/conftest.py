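import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from popgenkit.locus import AlignedLocus, RegionAnnotation, Segment

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_locus(rows: list[str], annotation=None, ids=None, groups=None,
               species=None):
    n = len(rows)
    ids = ids or [f"s{i+1}" for i in range(n)]
    return AlignedLocus(
        ids=ids,
        matrix=np.array([list(r) for r in rows], dtype="<U1"),
        populations=["pop"] * n,
        species=species or ["ingroup"] * n,
        annotation=annotation,
        groups=groups,
    )


@pytest.fixture
def tiny_annotation():
    return RegionAnnotation(
        [
            Segment("flank5", 1, 3, "flank"),
            Segment("exonI", 4, 9, "exon", 0),
            Segment("intronI", 10, 12, "intron"),
        ]
    )


@pytest.fixture
def tiny_locus(tiny_annotation):
    # Segregating sites: pos 3 flanking (G/T), pos 4 nonsynonymous
    # (ATG->CTG, M->L), pos 9 synonymous (AAA->AAG, K), pos 12 intronic
    # (T/C).  All singletons.
    rows = [
        "ACGATGAAATTT",
        "ACTATGAAGTTT",
        "ACGATGAAATTC",
        "ACGCTGAAATTT",
    ]
    return make_locus(rows, annotation=tiny_annotation)


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the package implementations)
# ---------------------------------------------------------------------------

def oracle_pi(matrix: np.ndarray) -> float:
    """Mean per-site pairwise difference over fully ACGT-comparable sites."""
    n = matrix.shape[0]
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = np.isin(matrix[i], list("ACGT")) & np.isin(
                matrix[j], list("ACGT")
            )
            vals.append(((matrix[i] != matrix[j]) & ok).sum() / ok.sum())
    return float(np.mean(vals))


def oracle_tajima_d(matrix01: np.ndarray) -> float:
    """Tajima's D on a complete 0/1 matrix, written out from the 1989 paper."""
    n, S = matrix01.shape
    k = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            k += (matrix01[i] != matrix01[j]).sum()
    k /= n * (n - 1) / 2
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def oracle_zns(matrix01: np.ndarray) -> float:
    """Mean squared Pearson correlation over all site pairs (complete data)."""
    S = matrix01.shape[1]
    vals = []
    for i in range(S):
        for j in range(i + 1, S):
            r = np.corrcoef(matrix01[:, i], matrix01[:, j])[0, 1]
            vals.append(r * r)
    return float(np.mean(vals))


def oracle_wall_b_q(matrix01: np.ndarray):
    """Wall's B and Q by explicit bipartition comparison."""
    n, S = matrix01.shape

    def part(j):
        ones = frozenset(np.flatnonzero(matrix01[:, j] == 1).tolist())
        zeros = frozenset(np.flatnonzero(matrix01[:, j] == 0).tolist())
        return min(ones, zeros, key=lambda s: (len(s), sorted(s)))

    bp = 0
    parts = set()
    for j in range(S - 1):
        if part(j) == part(j + 1):
            bp += 1
            parts.add(part(j))
    return bp / (S - 1), (bp + len(parts)) / S


def oracle_rm(matrix01: np.ndarray) -> int:
    """Max number of disjoint incompatible intervals, by exhaustive search."""
    from itertools import combinations

    S = matrix01.shape[1]
    intervals = []
    for i, j in combinations(range(S), 2):
        g = set(zip(matrix01[:, i].tolist(), matrix01[:, j].tolist()))
        if len(g) == 4:
            intervals.append((i, j))
    best = 0
    for r in range(1, len(intervals) + 1):
        found = False
        for combo in combinations(intervals, r):
            ok = all(
                a[1] <= b[0] or b[1] <= a[0]
                for a, b in combinations(combo, 2)
            )
            if ok:
                best = r
                found = True
                break
        if not found:
            break
    return best
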