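"""Seeded synthetic data generators with ground truth.

Three generators cover the package's analysis surfaces:

* :func:`gen_neutral` — a neutral-equilibrium population sample of an
  annotated locus (flank/exon/intron structure) built from a coalescent
  genealogy, for calibrating diversity and neutrality statistics.
* :func:`gen_dimorphic` — a sample split into two diverged haplotype groups
  with a known number of planted fixed differences, optional gene-conversion
  tracts copied between groups, and optional group-associated indels.
* :func:`gen_codon` — a codon alignment evolved down a phylogeny under a
  site-class mixture of dN/dS ratios, with the per-site class assignment
  recorded as truth.

Every generator is deterministic given its seed and returns ``(data, truth)``
where ``truth`` is a JSON-serializable dict of the planted quantities.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import coalescent
from .codon import (
    CODON_INDEX,
    CODONS,
    NCODON,
    CodonAlignment,
    PhyloTree,
    _codon_class_matrices,
    _Eigens,
)
from .locus import (
    STOP_CODONS,
    AlignedLocus,
    RegionAnnotation,
    Segment,
    extract_indels,
)

logger = logging.getLogger("popgenkit")

_NUCS = np.array(list("ACGT"))


def default_annotation(L: int) -> RegionAnnotation:
    """Flank / exon / intron / exon / flank layout scaled to length L.

    Exon lengths are trimmed to multiples of three so the coding sequence is
    in frame end to end.
    """
    if L < 60:
        raise ValueError("locus too short to annotate (need L >= 60)")
    f1 = max(10, L // 10)
    e1 = max(30, (3 * L // 10) // 3 * 3)
    i1 = max(10, L // 5)
    e2_start = f1 + e1 + i1 + 1
    f2 = max(10, L // 10)
    e2 = (L - f2 - e2_start + 1) // 3 * 3
    if e2 < 30:
        raise ValueError("locus too short for the default layout")
    segs = [
        Segment("flank5", 1, f1, "flank"),
        Segment("exonI", f1 + 1, f1 + e1, "exon", 0),
        Segment("intronI", f1 + e1 + 1, f1 + e1 + i1, "intron"),
        Segment("exonII", e2_start, e2_start + e2 - 1, "exon", 0),
        Segment("flank3", e2_start + e2, L, "flank"),
    ]
    return RegionAnnotation(segs)


def _random_reference(
    L: int, annotation: RegionAnnotation, rng: np.random.Generator,
    gc: float = 0.55,
) -> np.ndarray:
    """Random reference sequence with no in-frame stop codons."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    ref = _NUCS[rng.choice(4, size=L, p=p)]
    for _, positions in annotation.codon_map(L):
        cols = [q - 1 for q in positions]
        while "".join(ref[cols]) in STOP_CODONS:
            ref[cols] = _NUCS[rng.choice(4, size=3, p=p)]
    return ref


def _codon_context(annotation: RegionAnnotation, L: int) -> dict[int, tuple]:
    """Map 0-based column -> (codon column triple) for in-frame exon sites."""
    ctx = {}
    for _, positions in annotation.codon_map(L):
        cols = tuple(q - 1 for q in positions)
        for c in cols:
            ctx[c] = cols
    return ctx


def _safe_derived(
    ref: np.ndarray, col: int, ctx: dict, rng: np.random.Generator
) -> str:
    """A derived allele at ``col`` that creates no stop codon on the
    reference background.  Falls back to any non-reference base when all
    three alternatives would create a stop (logged); this slightly biases
    coding-site mutations away from stop-adjacent codons, which matches how
    functional sequences behave.
    """
    anc = ref[col]
    choices = [b for b in "ACGT" if b != anc]
    rng.shuffle(choices)
    cols = ctx.get(col)
    for b in choices:
        if cols is None:
            return b
        codon = [ref[c] for c in cols]
        codon[cols.index(col)] = b
        if "".join(codon) not in STOP_CODONS:
            return b
    logger.info("all derived alleles at column %d create stops; allowing one", col)
    return choices[0]


def gen_neutral(
    n: int = 28,
    L: int = 2000,
    theta_per_site: float = 0.005,
    rho_per_site: float = 0.006,
    seed: int = 0,
    gc: float = 0.55,
) -> tuple[AlignedLocus, dict]:
    """Neutral-equilibrium sample of an annotated locus.

    A single coalescent genealogy with recombination generates the haplotype
    configuration; derived alleles are placed on a random reference so that
    no in-frame stop codons arise.
    """
    rng = np.random.default_rng(seed)
    annotation = default_annotation(L)
    ref = _random_reference(L, annotation, rng, gc)
    ctx = _codon_context(annotation, L)
    rep = next(
        coalescent.simulate_sample(
            n, L, "theta", theta_per_site, rho_per_site, 1,
            int(rng.integers(1, 2**31 - 1)),
        )
    )
    matrix = np.tile(ref, (n, 1))
    derived_alleles = {}
    for k, coord in enumerate(rep.site_coords):
        col = int(coord) - 1
        b = _safe_derived(ref, col, ctx, rng)
        derived_alleles[int(coord)] = b
        matrix[rep.matrix[:, k] == 1, col] = b
    ids = [f"sim{idx:02d}" for idx in range(1, n + 1)]
    locus = AlignedLocus(
        ids=ids,
        matrix=matrix,
        populations=["sample"] * n,
        species=["ingroup"] * n,
        annotation=annotation,
    )
    truth = {
        "generator": "gen_neutral",
        "n": n, "L": L,
        "theta_per_site": theta_per_site, "rho_per_site": rho_per_site,
        "seed": seed,
        "segregating_sites": int(rep.S),
        "site_coords": [int(c) for c in rep.site_coords],
        "derived_alleles": {str(k): v for k, v in derived_alleles.items()},
        "num_marginal_trees": int(rep.num_trees),
    }
    return locus, truth


def gen_dimorphic(
    n1: int = 14,
    n2: int = 14,
    L: int = 2000,
    n_fixed: int = 19,
    theta1_per_site: float = 0.0002,
    theta2_per_site: float = 0.0011,
    conversion_tract: dict | None = None,
    indel_spec: list[dict] | None = None,
    seed: int = 0,
    gc: float = 0.55,
) -> tuple[AlignedLocus, dict]:
    """Two diverged haplotype groups with planted fixed differences.

    ``conversion_tract`` (optional): ``{"start": int, "end": int,
    "recipients": int}`` — the first ``recipients`` sequences of group B have
    group A's alleles copied over the tract, mimicking gene conversion
    between haplogroups.  ``indel_spec`` (optional): list of
    ``{"start": int, "end": int, "group": "A"|"B"}`` gap spans carried by all
    members of one group.
    """
    rng = np.random.default_rng(seed)
    annotation = default_annotation(L)
    ref = _random_reference(L, annotation, rng, gc)
    ctx = _codon_context(annotation, L)

    n = n1 + n2
    matrix = np.tile(ref, (n, 1))
    rows_a = np.arange(n1)
    rows_b = np.arange(n1, n)

    # planted fixed differences: group B carries the derived allele
    fixed_cols = rng.choice(L, size=n_fixed, replace=False)
    fixed_positions = []
    for col in sorted(int(c) for c in fixed_cols):
        b = _safe_derived(ref, col, ctx, rng)
        matrix[rows_b, col] = b
        fixed_positions.append(col + 1)

    # within-group variation from independent genealogies
    within_truth = {}
    for label, rows, theta in (
        ("A", rows_a, theta1_per_site),
        ("B", rows_b, theta2_per_site),
    ):
        rep = next(
            coalescent.simulate_sample(
                len(rows), L, "theta", theta, 0.0, 1,
                int(rng.integers(1, 2**31 - 1)),
            )
        )
        placed = []
        for k, coord in enumerate(rep.site_coords):
            col = int(coord) - 1
            if col + 1 in fixed_positions:
                continue  # keep planted fixed differences fixed
            b = _safe_derived(ref, col, ctx, rng)
            if np.all(matrix[rows, col] == b):
                continue
            matrix[rows[rep.matrix[:, k] == 1], col] = b
            placed.append(col + 1)
        within_truth[label] = placed

    tract_truth = None
    if conversion_tract is not None:
        start = int(conversion_tract["start"])
        end = int(conversion_tract["end"])
        recipients = int(conversion_tract.get("recipients", 1))
        if not (1 <= start <= end <= L):
            raise ValueError("conversion tract outside the locus")
        donor = matrix[rows_a[0]].copy()
        rec_rows = rows_b[:recipients]
        matrix[rec_rows, start - 1 : end] = donor[start - 1 : end]
        tract_truth = {
            "start": start, "end": end,
            "recipients": [f"B{r - n1 + 1:02d}" for r in rec_rows],
            "donor": "A01",
        }

    indel_truth = []
    if indel_spec:
        for spec in indel_spec:
            start, end = int(spec["start"]), int(spec["end"])
            rows = rows_a if spec["group"] == "A" else rows_b
            matrix[rows, start - 1 : end] = "-"
            indel_truth.append(
                {"start": start, "end": end, "group": spec["group"]}
            )

    ids = [f"A{k:02d}" for k in range(1, n1 + 1)] + [
        f"B{k:02d}" for k in range(1, n2 + 1)
    ]
    groups = ["A"] * n1 + ["B"] * n2
    locus = AlignedLocus(
        ids=ids,
        matrix=matrix,
        populations=["sample"] * n,
        species=["ingroup"] * n,
        annotation=annotation,
        groups=groups,
    )
    locus.indels = extract_indels(ids, matrix)
    truth = {
        "generator": "gen_dimorphic",
        "n1": n1, "n2": n2, "L": L, "seed": seed,
        "n_fixed": n_fixed,
        "fixed_positions": fixed_positions,
        "theta1_per_site": theta1_per_site,
        "theta2_per_site": theta2_per_site,
        "within_group_sites": within_truth,
        "conversion_tract": tract_truth,
        "indels": indel_truth,
    }
    return locus, truth


# ---------------------------------------------------------------------------
# Codon alignments under site-class mixtures
# ---------------------------------------------------------------------------

_DEFAULT_TREE = (
    "((t1:0.05,t2:0.05):0.05,(t3:0.05,t4:0.05):0.05,(t5:0.05,t6:0.1):0.02);"
)


def gen_codon(
    tree: PhyloTree | str = _DEFAULT_TREE,
    n_sites: int = 143,
    kappa: float = 3.7,
    site_classes: list[tuple[float, float]] | None = None,
    pi: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[CodonAlignment, dict]:
    """Codon alignment evolved down a tree under a dN/dS site mixture.

    ``site_classes`` is a list of ``(omega, proportion)``; the default is a
    single class with omega = 0.22.  Each site draws a class, the root codon
    is drawn from ``pi`` (default uniform over sense codons), and states are
    propagated by endpoint sampling from the per-branch transition matrices
    of the normalized mixture generator.  Truth records the class of every
    site.
    """
    if isinstance(tree, str):
        tree = PhyloTree(newick=tree)
    if site_classes is None:
        site_classes = [(0.22, 1.0)]
    props = np.array([p for _, p in site_classes], dtype=float)
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("site-class proportions must sum to 1")
    omegas = [w for w, _ in site_classes]
    if pi is None:
        pi = np.full(NCODON, 1.0 / NCODON)
    pi = np.asarray(pi, dtype=float)
    pi = pi / pi.sum()

    rng = np.random.default_rng(seed)
    rates = [(1.0, w) for w in omegas]
    Qs, _ = _codon_class_matrices(pi, kappa, rates, props)
    eigs = [_Eigens(Q, pi) for Q in Qs]

    site_class = rng.choice(len(omegas), size=n_sites, p=props)
    n_tips = tree.n_tips
    states = np.empty((tree.n_nodes, n_sites), dtype=int)
    states[tree.root] = rng.choice(NCODON, size=n_sites, p=pi)
    preorder = list(reversed(tree.postorder))
    Ps = {}
    for v in preorder:
        if v == tree.root:
            continue
        t = tree.branch_lengths[v]
        for k, eig in enumerate(eigs):
            key = (v, k)
            if key not in Ps:
                Ps[key] = np.maximum(eig.transition(t), 0.0)
        parent_states = states[tree.parent[v]]
        for s in range(n_sites):
            row = Ps[(v, site_class[s])][parent_states[s]]
            row = row / row.sum()
            states[v, s] = rng.choice(NCODON, p=row)

    data = CodonAlignment(
        taxa=list(tree.taxa),
        codons=states[:n_tips],
        site_coords=[(3 * k + 1, 3 * k + 2, 3 * k + 3) for k in range(n_sites)],
    )
    truth = {
        "generator": "gen_codon",
        "n_sites": n_sites, "kappa": kappa, "seed": seed,
        "tree": tree.newick(),
        "site_classes": [
            {"omega": float(w), "proportion": float(p)}
            for w, p in site_classes
        ],
        "site_class_index": site_class.tolist(),
    }
    return data, truth


# ---------------------------------------------------------------------------
# Serialization helpers
# ---------------------------------------------------------------------------

def write_locus_bundle(
    locus: AlignedLocus, truth: dict, outdir: str | Path, stem: str = "synthetic"
) -> dict[str, str]:
    """Write FASTA + regions TSV + labels TSV + truth JSON; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{stem}.fasta"
    with open(fasta, "w") as fh:
        for i, sid in enumerate(locus.ids):
            fh.write(f">{sid}\n{''.join(locus.matrix[i])}\n")
    regions = outdir / f"{stem}.regions.tsv"
    with open(regions, "w") as fh:
        fh.write("name\tstart\tend\tclass\tphase\n")
        for seg in locus.annotation.segments:
            fh.write(
                f"{seg.name}\t{seg.start}\t{seg.end}\t{seg.cls}\t{seg.phase}\n"
            )
    labels = outdir / f"{stem}.labels.tsv"
    with open(labels, "w") as fh:
        fh.write("id\tpopulation\tspecies\tgroup\n")
        for i, sid in enumerate(locus.ids):
            grp = locus.groups[i] if locus.groups else ""
            fh.write(
                f"{sid}\t{locus.populations[i]}\t{locus.species[i]}\t{grp}\n"
            )
    truth_path = outdir / f"{stem}.truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return {
        "fasta": str(fasta), "regions": str(regions),
        "labels": str(labels), "truth": str(truth_path),
    }
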