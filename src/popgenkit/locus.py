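"""Aligned-locus containers, region annotation, and per-site classification.

The central object is :class:`AlignedLocus`: a gap-aware multiple sequence
alignment of a population sample (optionally with outgroup species), carrying
per-sequence population/species/group labels and a functional-region
annotation (intron / exon / flank with codon phase).  ``classify_sites``
produces a :class:`SiteTable` of segregating sites classified as synonymous,
nonsynonymous, intronic, flanking or ambiguous, using Nei–Gojobori pathway
counting for codons that differ at more than one position.

Conventions
-----------
* Coordinates are 1-based inclusive throughout.
* Any alignment column containing a gap in any analyzed sequence is excluded
  from site counts ("indels excluded"); indels are recorded separately in the
  :class:`IndelRegistry`.
* ``N`` is treated as sequence-specific missing data; the column is kept.
"""

from __future__ import annotations

import itertools
import logging
import sys
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger("popgenkit")

VALID_SYMBOLS = frozenset("ACGTN-")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)


def translate_codon(codon: str) -> str:
    """Translate a codon with the standard genetic code; '*' for stops."""
    if codon in STOP_CODONS:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


class AlignmentFormatError(ValueError):
    pass


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class Segment:
    """One annotated functional region (1-based inclusive coordinates)."""

    name: str
    start: int
    end: int
    cls: str  # "intron" | "exon" | "flank"
    phase: int = 0  # codon phase of the first exon column; 0 for non-exons

    def __post_init__(self):
        if self.cls not in ("intron", "exon", "flank"):
            raise AnnotationError(f"unknown region class {self.cls!r}")
        if not (1 <= self.start <= self.end):
            raise AnnotationError(f"bad segment bounds {self.start}-{self.end}")
        if self.cls == "exon" and self.phase not in (0, 1, 2):
            raise AnnotationError(f"bad exon phase {self.phase}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegionAnnotation:
    """Ordered, non-overlapping functional segments covering (part of) a locus.

    Overlapping consecutive segments sharing a single boundary coordinate are
    normalized by advancing the later segment's start, and the adjustment is
    logged (some published coordinate tables print closed intervals that touch).
    """

    segments: list[Segment]

    def __post_init__(self):
        segs = sorted(self.segments, key=lambda s: s.start)
        fixed = []
        prev_end = 0
        for seg in segs:
            if seg.start <= prev_end:
                new_start = prev_end + 1
                if new_start > seg.end:
                    raise AnnotationError(
                        f"segment {seg.name} fully overlaps its predecessor"
                    )
                logger.warning(
                    "normalizing segment %s start %d -> %d (overlap with predecessor)",
                    seg.name, seg.start, new_start,
                )
                shift = new_start - seg.start
                phase = (seg.phase + shift) % 3 if seg.cls == "exon" else 0
                seg = Segment(seg.name, new_start, seg.end, seg.cls, phase)
            fixed.append(seg)
            prev_end = seg.end
        self.segments = fixed

    def check_bounds(self, L: int) -> None:
        for seg in self.segments:
            if seg.end > L:
                raise AnnotationError(
                    f"segment {seg.name} end {seg.end} exceeds alignment length {L}"
                )

    def class_of(self, pos: int) -> str | None:
        """Region class at 1-based position ``pos`` (None if unannotated)."""
        for seg in self.segments:
            if seg.start <= pos <= seg.end:
                return seg.cls
        return None

    def exon_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.cls == "exon"]

    def positions_of_class(self, classes, L: int) -> np.ndarray:
        """Boolean mask (length L, 0-based index) of columns in the classes."""
        mask = np.zeros(L, dtype=bool)
        for seg in self.segments:
            if seg.cls in classes:
                mask[seg.start - 1 : seg.end] = True
        return mask

    def codon_map(self, L: int):
        """Yield (codon_index, (p1, p2, p3)) for every complete in-frame codon.

        Positions are 1-based alignment coordinates.  Partial codons at exon
        boundaries (nonzero phase leading bases, trailing remainder) are
        skipped.  Codons are allowed to be split across exon segments: bases
        are taken in exon order, concatenated over segments.
        """
        coding_positions: list[int] = []
        for seg in self.exon_segments():
            usable = list(range(seg.start, seg.end + 1))
            if seg.phase:
                usable = usable[(3 - seg.phase) % 3 :]
            coding_positions.extend(usable)
        idx = 0
        for i in range(0, len(coding_positions) - 2, 3):
            yield idx, tuple(coding_positions[i : i + 3])
            idx += 1


@dataclass(frozen=True)
class IndelEvent:
    start: int
    end: int
    kind: str  # "insertion" | "deletion"
    carriers: frozenset[str]


@dataclass
class IndelRegistry:
    """Distinct gap-run events: one event per maximal identical-span gap run."""

    events: list[IndelEvent] = field(default_factory=list)

    def __len__(self):
        return len(self.events)


@dataclass
class AlignedLocus:
    """Aligned sample of sequences with labels and functional annotation."""

    ids: list[str]
    matrix: np.ndarray  # (n, L) array of single characters
    populations: list[str]
    species: list[str]
    annotation: RegionAnnotation | None = None
    indels: IndelRegistry = field(default_factory=IndelRegistry)
    groups: list[str] | None = None  # optional haplotype-group labels

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise AlignmentFormatError("matrix must be 2-dimensional")
        n, L = self.matrix.shape
        if n < 2:
            raise AlignmentFormatError("alignment needs at least 2 sequences")
        if len(self.ids) != n:
            raise AlignmentFormatError("ids/matrix row mismatch")
        if len(set(self.ids)) != n:
            raise AlignmentFormatError("duplicate sequence identifiers")
        if len(self.populations) != n or len(self.species) != n:
            raise AlignmentFormatError("label/matrix row mismatch")
        bad = set(np.unique(self.matrix)) - VALID_SYMBOLS
        if bad:
            raise AlignmentFormatError(f"invalid symbols in alignment: {sorted(bad)}")
        if self.annotation is not None:
            self.annotation.check_bounds(L)
        if self.groups is not None and len(self.groups) != n:
            raise AlignmentFormatError("group labels/matrix row mismatch")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    def row(self, seq_id: str) -> np.ndarray:
        return self.matrix[self.ids.index(seq_id)]

    def subset(self, ids: list[str]) -> "AlignedLocus":
        idx = [self.ids.index(i) for i in ids]
        return AlignedLocus(
            ids=[self.ids[i] for i in idx],
            matrix=self.matrix[idx],
            populations=[self.populations[i] for i in idx],
            species=[self.species[i] for i in idx],
            annotation=self.annotation,
            indels=self.indels,
            groups=None if self.groups is None else [self.groups[i] for i in idx],
        )

    def ingroup_indices(self, species: str | None = None) -> np.ndarray:
        """Row indices of the focal species (default: the most common one)."""
        if species is None:
            vals, counts = np.unique(self.species, return_counts=True)
            species = vals[np.argmax(counts)]
        return np.flatnonzero(np.asarray(self.species) == species)

    def gap_free_mask(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Columns without any gap among the selected rows (indels excluded)."""
        sub = self.matrix if rows is None else self.matrix[rows]
        return ~(sub == "-").any(axis=0)


@dataclass(frozen=True)
class SiteRecord:
    position: int  # 1-based alignment coordinate
    major_allele: str
    minor_allele: str
    counts: dict  # allele -> count among non-missing residues
    cls: str  # synonymous | nonsynonymous | intronic | flanking | ambiguous
    singleton: bool
    excluded: bool  # True if the column contains a gap (dropped from N)


@dataclass
class SiteTable:
    sites: list[SiteRecord]

    def __len__(self):
        return len(self.sites)

    def positions(self, classes=None, include_excluded=False) -> list[int]:
        return [
            s.position
            for s in self.sites
            if (classes is None or s.cls in classes)
            and (include_excluded or not s.excluded)
        ]

    def singleton_count(self, classes=None) -> int:
        return sum(
            1
            for s in self.sites
            if s.singleton
            and not s.excluded
            and (classes is None or s.cls in classes)
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_regions_table(path: str) -> RegionAnnotation:
    """Parse a tab-separated region table: name, start, end, class[, phase]."""
    segments = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in ("name", "region"):
                continue
            name, start, end, cls = parts[:4]
            phase = int(parts[4]) if len(parts) > 4 and parts[4] else 0
            segments.append(Segment(name, int(start), int(end), cls, phase))
    if not segments:
        raise AnnotationError(f"no segments parsed from {path}")
    return RegionAnnotation(segments)


def read_labels_table(path: str) -> dict[str, dict]:
    """Parse a tab-separated label table: id, population, species[, group]."""
    labels = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in ("id", "sequence"):
                continue
            entry = {"population": parts[1], "species": parts[2]}
            if len(parts) > 3 and parts[3]:
                entry["group"] = parts[3]
            labels[parts[0]] = entry
    return labels


def extract_indels(ids: list[str], matrix: np.ndarray) -> IndelRegistry:
    """Register one event per distinct maximal gap-run span.

    Carriers of a span are the sequences whose maximal gap run equals that
    span exactly.  A span whose gap carriers are a minority is a deletion in
    the carriers; if most sequences are gapped there, it is an insertion
    carried by the ungapped sequences.
    """
    n, L = matrix.shape
    span_carriers: dict[tuple[int, int], set[str]] = {}
    is_gap = matrix == "-"
    for i in range(n):
        j = 0
        while j < L:
            if is_gap[i, j]:
                k = j
                while k + 1 < L and is_gap[i, k + 1]:
                    k += 1
                span_carriers.setdefault((j + 1, k + 1), set()).add(ids[i])
                j = k + 1
            else:
                j += 1
    events = []
    all_ids = set(ids)
    for (start, end), gap_ids in sorted(span_carriers.items()):
        if len(gap_ids) <= n / 2:
            events.append(IndelEvent(start, end, "deletion", frozenset(gap_ids)))
        else:
            events.append(
                IndelEvent(start, end, "insertion", frozenset(all_ids - gap_ids))
            )
    return IndelRegistry(events)


def read_alignment(
    fasta_path: str,
    regions_path: str | None = None,
    labels_path: str | None = None,
    default_population: str = "sample",
    default_species: str = "ingroup",
) -> AlignedLocus:
    """Read an aligned FASTA plus optional region and label tables."""
    ids, rows = [], []
    for rec in SeqIO.parse(fasta_path, "fasta"):
        if rec.id in ids:
            raise AlignmentFormatError(f"duplicate id {rec.id} in {fasta_path}")
        ids.append(rec.id)
        rows.append(list(str(rec.seq).upper()))
    if not rows:
        raise AlignmentFormatError(f"no records in {fasta_path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise AlignmentFormatError(
            f"records of unequal length in {fasta_path}: {sorted(lengths)}"
        )
    matrix = np.array(rows, dtype="<U1")

    annotation = read_regions_table(regions_path) if regions_path else None
    labels = read_labels_table(labels_path) if labels_path else {}
    populations = [labels.get(i, {}).get("population", default_population) for i in ids]
    species = [labels.get(i, {}).get("species", default_species) for i in ids]
    groups = None
    if any("group" in labels.get(i, {}) for i in ids):
        groups = [labels.get(i, {}).get("group", "") for i in ids]

    locus = AlignedLocus(
        ids=ids,
        matrix=matrix,
        populations=populations,
        species=species,
        annotation=annotation,
        groups=groups,
    )
    locus.indels = extract_indels(ids, matrix)
    return locus


# ---------------------------------------------------------------------------
# Codon pathway classification (Nei & Gojobori 1986 style)
# ---------------------------------------------------------------------------

def _pathway_changes(c1: str, c2: str):
    """Average syn/nonsyn change attribution per differing position.

    Considers every minimal mutational pathway between the codons (skipping
    pathways through stop codons when any stop-free pathway exists) and
    averages the per-position attribution.  Returns {position(0-2): (syn,
    nonsyn)} with syn + nonsyn = 1 for each differing position.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return {}
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []  # (position, from_codon, to_codon)
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != c2:
                ok = False
                break
            steps.append((pos, cur, nxt))
            cur = nxt
        if ok:
            paths.append(steps)
    if not paths:  # all intermediates are stops; fall back to all orders
        for order in itertools.permutations(diff):
            cur = c1
            steps = []
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                steps.append((pos, cur, nxt))
                cur = nxt
            paths.append(steps)
    attribution = {pos: [0.0, 0.0] for pos in diff}
    for steps in paths:
        for pos, frm, to in steps:
            if translate_codon(frm) == translate_codon(to):
                attribution[pos][0] += 1.0
            else:
                attribution[pos][1] += 1.0
    npaths = len(paths)
    return {pos: (s / npaths, n / npaths) for pos, (s, n) in attribution.items()}


def nei_gojobori_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) effective site counts for one codon.

    Each position contributes the fraction of its possible single-base
    changes that are synonymous; changes to stop codons are excluded from the
    denominator (standard convention), so each position contributes one site.
    """
    if codon in STOP_CODONS or any(b not in "ACGT" for b in codon):
        return 0.0, 0.0
    aa = translate_codon(codon)
    syn = 0.0
    nonsyn = 0.0
    for pos in range(3):
        psyn = 0
        pnon = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            if translate_codon(mut) == aa:
                psyn += 1
            else:
                pnon += 1
        denom = psyn + pnon
        if denom:
            syn += psyn / denom
            nonsyn += pnon / denom
    return syn, nonsyn


def classify_sites(locus: AlignedLocus, ingroup_only: bool = True) -> SiteTable:
    """Classify every segregating alignment column.

    Columns with any gap among the analyzed sequences are recorded with
    ``excluded=True`` and do not enter site counts.  Exon columns are
    classified from all observed codon pairs with pathway attribution; a
    column supporting both synonymous and nonsynonymous interpretations
    (or involving an N at the polymorphic position) is ``ambiguous``.
    """
    if locus.annotation is None:
        raise AnnotationError("classify_sites requires a region annotation")
    rows = locus.ingroup_indices() if ingroup_only else np.arange(locus.n)
    sub = locus.matrix[rows]
    L = locus.L

    # Precompute codon classification for exon columns.
    exon_class: dict[int, str] = {}
    for _, positions in locus.annotation.codon_map(L):
        cols = [p - 1 for p in positions]
        codon_block = sub[:, cols]
        usable = ~((codon_block == "-") | (codon_block == "N")).any(axis=1)
        codons = {"".join(codon_block[i]) for i in np.flatnonzero(usable)}
        codons = {c for c in codons if c not in STOP_CODONS}
        per_pos_syn = {0: set(), 1: set(), 2: set()}
        for c1, c2 in itertools.combinations(sorted(codons), 2):
            for pos, (s, n) in _pathway_changes(c1, c2).items():
                if s > 0:
                    per_pos_syn[pos].add("syn")
                if n > 0:
                    per_pos_syn[pos].add("nonsyn")
        has_missing = ((codon_block == "N")).any(axis=0)
        for k, p in enumerate(positions):
            tags = per_pos_syn[k]
            if not tags:
                continue
            if len(tags) == 2:
                exon_class[p] = "ambiguous"
            elif has_missing[k]:
                # N at a polymorphic codon position: interpretation uncertain
                exon_class[p] = "ambiguous"
            else:
                exon_class[p] = "synonymous" if "syn" in tags else "nonsynonymous"

    records = []
    n_nonmissing_total = 0
    for col in range(L):
        column = sub[:, col]
        has_gap = (column == "-").any()
        residues = column[(column != "-") & (column != "N")]
        alleles, counts = np.unique(residues, return_counts=True)
        if len(alleles) < 2:
            continue
        order = np.argsort(-counts)
        alleles, counts = alleles[order], counts[order]
        pos = col + 1
        region = locus.annotation.class_of(pos)
        if region == "exon":
            cls = exon_class.get(pos, "ambiguous")
        elif region == "intron":
            cls = "intronic"
        elif region == "flank":
            cls = "flanking"
        else:
            cls = "flanking"  # unannotated columns treated as flanking
        records.append(
            SiteRecord(
                position=pos,
                major_allele=str(alleles[0]),
                minor_allele=str(alleles[-1]),
                counts={str(a): int(c) for a, c in zip(alleles, counts)},
                cls=cls,
                singleton=bool(counts[-1] == 1 and len(alleles) == 2),
                excluded=bool(has_gap),
            )
        )
        n_nonmissing_total += len(residues)
    if any(r.cls == "ambiguous" for r in records):
        logger.info(
            "%d sites with ambiguous synonymous/nonsynonymous interpretation",
            sum(1 for r in records if r.cls == "ambiguous"),
        )
    return SiteTable(records)


def effective_coding_sites(locus: AlignedLocus, ingroup_only: bool = True):
    """Nei–Gojobori effective (synonymous, nonsynonymous) site counts.

    Counted over the sample consensus codons, using only codons whose three
    columns are all gap-free among the analyzed sequences.
    """
    if locus.annotation is None:
        raise AnnotationError("effective_coding_sites requires an annotation")
    rows = locus.ingroup_indices() if ingroup_only else np.arange(locus.n)
    sub = locus.matrix[rows]
    gap_free = locus.gap_free_mask(rows)
    syn = 0.0
    nonsyn = 0.0
    for _, positions in locus.annotation.codon_map(locus.L):
        cols = [p - 1 for p in positions]
        if not all(gap_free[c] for c in cols):
            continue
        consensus = []
        for c in cols:
            column = sub[:, c]
            residues = column[(column != "-") & (column != "N")]
            if len(residues) == 0:
                consensus = None
                break
            alleles, counts = np.unique(residues, return_counts=True)
            consensus.append(str(alleles[np.argmax(counts)]))
        if consensus is None:
            continue
        s, ns = nei_gojobori_sites("".join(consensus))
        syn += s
        nonsyn += ns
    return syn, nonsyn


def configure_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.WARNING)
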