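"""cox1 intron position classes (Pcls) on a reference coordinate system.

Group I introns interrupt the cox1 coding sequence at characteristic sites.
Expressing each insertion site as a nucleotide coordinate in one reference
cox1 CDS makes introns comparable across species: introns sharing a position
class are treated as homologous. The mapping runs at the protein level --
each species' cox1 protein is globally aligned to the reference protein, the
codon containing the insertion is located in the alignment, and the position
is back-converted to reference CDS nucleotides, preserving the codon phase
arithmetically.

A class label is rendered ``P<ref nt position>``; a ``+1`` / ``+2`` suffix
marks insertions inside a codon (between nt 1 and 2, or nt 2 and 3). A class
is *common* when present in strictly more than one fifth of the species
surveyed, *rare* otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from .mito_io import (
    GeneFeature,
    MitogenomeAnnotation,
    extract_cds,
    translate_code4,
)

__all__ = [
    "PclName",
    "PclMatrix",
    "IntronCountRecord",
    "ProteinAlignment",
    "align_protein_global",
    "intron_insertion_points",
    "project_to_reference",
    "build_pcl_matrix",
    "pearson_size_intron",
]

_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class PclName:
    """An intron position class: reference-CDS nt coordinate + codon phase."""

    ref_nt_position: int
    phase: int  # 0 (codon boundary), 1, or 2
    exact: bool = True  # False when the site fell in a reference-gap column

    def __post_init__(self) -> None:
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0, 1 or 2: {self.phase}")
        if self.ref_nt_position < 1:
            raise ValueError("reference position must be >= 1")
        if self.phase != self.ref_nt_position % 3:
            raise ValueError(
                f"phase {self.phase} inconsistent with position "
                f"{self.ref_nt_position} (mod 3 = {self.ref_nt_position % 3})"
            )

    @property
    def label(self) -> str:
        """Bare label, e.g. ``P383``."""
        return f"P{self.ref_nt_position}"

    @property
    def label_with_phase(self) -> str:
        """Label with in-codon suffix, e.g. ``P383+2``."""
        suffix = f"+{self.phase}" if self.phase else ""
        return f"P{self.ref_nt_position}{suffix}"


@dataclass(frozen=True)
class IntronCountRecord:
    species: str
    mitogenome_size: int
    intron_count: int

    def __post_init__(self) -> None:
        if self.mitogenome_size <= 0:
            raise ValueError("mitogenome size must be positive")
        if self.intron_count < 0:
            raise ValueError("intron count must be >= 0")


@dataclass(frozen=True)
class ProteinAlignment:
    """A global pairwise protein alignment as two gapped strings."""

    query: str  # gapped
    reference: str  # gapped
    score: float

    def __post_init__(self) -> None:
        if len(self.query) != len(self.reference):
            raise ValueError("gapped rows differ in length")


def _make_aligner(open_penalty: float, extend_penalty: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # first gap position costs `open_penalty`, each further one `extend_penalty`
    aligner.open_gap_score = -open_penalty
    aligner.extend_gap_score = -extend_penalty
    return aligner


def align_protein_global(
    query: str,
    reference: str,
    open_penalty: float = 10.0,
    extend_penalty: float = 1.0,
) -> ProteinAlignment:
    """Global protein alignment, BLOSUM62, affine gaps (default 10/1).

    Tie-breaking is deterministic: the first optimal alignment in the
    aligner's fixed enumeration order is returned.
    """
    for name, seq in (("query", query), ("reference", reference)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
        bad = sorted(set(seq) - _AA)
        if bad:
            raise ValueError(f"{name} contains non-amino-acid characters: {bad}")
    aligner = _make_aligner(open_penalty, extend_penalty)
    alignment = next(iter(aligner.align(query, reference)))
    q_gapped, r_gapped = _gapped_rows(alignment, query, reference)
    return ProteinAlignment(query=q_gapped, reference=r_gapped,
                            score=float(alignment.score))


def _gapped_rows(alignment, query: str, reference: str) -> tuple[str, str]:
    qa, ra = [], []
    q_aln, r_aln = alignment.aligned  # paired blocks (query uses .aligned[0])
    qpos = rpos = 0
    for (qs, qe), (rs, re_) in zip(q_aln, r_aln):
        # unaligned stretch before this block = gaps
        if qs > qpos and rs > rpos:
            # both advance without being aligned (shouldn't happen in global
            # pairwise, but handle by stacking)
            qa.append(query[qpos:qs])
            ra.append("-" * (qs - qpos))
            qa.append("-" * (rs - rpos))
            ra.append(reference[rpos:rs])
        elif qs > qpos:
            qa.append(query[qpos:qs])
            ra.append("-" * (qs - qpos))
        elif rs > rpos:
            qa.append("-" * (rs - rpos))
            ra.append(reference[rpos:rs])
        qa.append(query[qs:qe])
        ra.append(reference[rs:re_])
        qpos, rpos = qe, re_
    if qpos < len(query):
        qa.append(query[qpos:])
        ra.append("-" * (len(query) - qpos))
    if rpos < len(reference):
        qa.append("-" * (len(reference) - rpos))
        ra.append(reference[rpos:])
    return "".join(qa), "".join(ra)


# ---------------------------------------------------------------------------
# insertion points


def intron_insertion_points(
    cox1: GeneFeature, annotation: MitogenomeAnnotation
) -> list[tuple[int, int]]:
    """Per intron of the host gene: (ordinal, coding-nt offset before the site).

    The offset counts coding nucleotides preceding the insertion in the
    exon-concatenated, strand-corrected CDS. An intron that does not lie
    between two consecutive exons of the host raises an annotation error.
    """
    from .mito_io import AnnotationError

    L = annotation.genome.length
    exons = cox1.exons
    out: list[tuple[int, int]] = []
    for intr in annotation.introns_of(cox1.name):
        loc = intr.location
        offset = None
        for k in range(len(exons) - 1):
            a, b = exons[k], exons[k + 1]
            if cox1.strand == "+":
                gap_start, gap_end = a.end + 1, b.start - 1
            else:
                gap_start, gap_end = b.end + 1, a.start - 1
            if gap_start <= gap_end and loc.start >= gap_start and loc.end <= gap_end:
                offset = sum(e.length(L) for e in exons[: k + 1])
                break
        if offset is None:
            raise AnnotationError(
                f"intron {intr.ordinal} of {cox1.name} does not lie between "
                f"consecutive exons"
            )
        out.append((intr.ordinal, offset))
    out.sort(key=lambda t: t[0])
    return out


def project_to_reference(
    cds_nt_offset: int,
    query_protein: str,
    reference_protein: str,
    alignment: ProteinAlignment,
) -> PclName:
    """Map a query-CDS insertion offset onto reference-CDS nt coordinates.

    The codon containing (or ending at) the offset is located in the
    alignment and the aligned reference residue gives the reference codon;
    the phase carries over arithmetically. When the query codon aligns to a
    reference gap the nearest reference residue to the LEFT anchors the
    label, flagged inexact.
    """
    if cds_nt_offset <= 0:
        raise ValueError("offset must be positive (site after >=1 coding nt)")
    if cds_nt_offset >= 3 * len(query_protein) + 3:
        raise ValueError("offset beyond query CDS")
    phase = cds_nt_offset % 3
    query_codon = math.ceil(cds_nt_offset / 3)  # 1-based codon index

    # locate the alignment column of that query residue
    qpos = 0
    col_of_codon = None
    for col, ch in enumerate(alignment.query):
        if ch != "-":
            qpos += 1
            if qpos == query_codon:
                col_of_codon = col
                break
    if col_of_codon is None:
        raise ValueError(
            f"query codon {query_codon} beyond aligned query "
            f"({qpos} residues)"
        )

    # reference residue index at (or left of) that column
    ref_index = 0
    exact = True
    for col in range(col_of_codon + 1):
        if alignment.reference[col] != "-":
            ref_index += 1
    if alignment.reference[col_of_codon] == "-":
        exact = False  # anchored to nearest reference residue on the left
    if ref_index == 0:
        # site precedes the first aligned reference residue; anchor at codon 1
        ref_index, exact = 1, False

    ref_nt = 3 * (ref_index - 1) + (phase if phase > 0 else 3)
    return PclName(ref_nt_position=ref_nt, phase=phase, exact=exact)


# ---------------------------------------------------------------------------
# matrix


@dataclass(frozen=True)
class PclMatrix:
    """Species x Pcl presence matrix with prevalence and common/rare calls."""

    presence: pd.DataFrame  # bool, index species, columns bare labels
    details: pd.DataFrame  # per-intron report rows

    @property
    def species(self) -> list[str]:
        return list(self.presence.index)

    @property
    def labels(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def prevalence(self) -> pd.Series:
        return self.presence.sum(axis=0).astype(int)

    def classification(self, threshold_fraction: float = 1 / 5) -> pd.Series:
        """'common' when prevalence strictly exceeds n_species * fraction."""
        cut = len(self.presence.index) * threshold_fraction
        return self.prevalence.map(lambda p: "common" if p > cut else "rare")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# species x Pcl presence (1 = intron present)\n")
            self.presence.astype(int).to_csv(fh, sep="\t")


def build_pcl_matrix(
    annotations: list[MitogenomeAnnotation],
    reference_cds: str,
    host_gene: str = "cox1",
) -> PclMatrix:
    """Map every cox1 intron of every species to a Pcl and build the matrix.

    Identical labels across species are merged (homologous introns). Species
    lacking the host gene contribute an all-absent row with a warning.
    """
    reference_protein = translate_code4(reference_cds)
    rows: dict[str, set[str]] = {}
    detail_rows: list[dict] = []
    order: list[tuple[int, str]] = []
    for ann in annotations:
        name = ann.species or ann.genome.id
        rows[name] = set()
        if not ann.has_gene(host_gene):
            warnings.warn(f"{name}: no {host_gene} gene; zero-intron row",
                          stacklevel=2)
            continue
        gene = ann.gene(host_gene)
        cds = extract_cds(ann, host_gene)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            query_protein = translate_code4(cds[: len(cds) - len(cds) % 3])
        query_protein = query_protein.replace("*", "X")
        aln = align_protein_global(query_protein, reference_protein)
        for ordinal, offset in intron_insertion_points(gene, ann):
            pcl = project_to_reference(offset, query_protein,
                                       reference_protein, aln)
            rows[name].add(pcl.label)
            order.append((pcl.ref_nt_position, pcl.label))
            detail_rows.append(
                {
                    "species": name,
                    "intron_ordinal": ordinal,
                    "query_offset": offset,
                    "label": pcl.label,
                    "label_with_phase": pcl.label_with_phase,
                    "phase": pcl.phase,
                    "exact": pcl.exact,
                }
            )
    labels = [lbl for _, lbl in sorted(set(order))]
    presence = pd.DataFrame(
        [[lbl in rows[sp] for lbl in labels] for sp in rows],
        index=list(rows), columns=labels, dtype=bool,
    )
    details = pd.DataFrame(
        detail_rows,
        columns=["species", "intron_ordinal", "query_offset", "label",
                 "label_with_phase", "phase", "exact"],
    )
    return PclMatrix(presence=presence, details=details)


def pearson_size_intron(records: list[IntronCountRecord]) -> float:
    """Pearson r between mitogenome size and intron count."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    sizes = np.array([r.mitogenome_size for r in records], dtype=float)
    counts = np.array([r.intron_count for r in records], dtype=float)
    if np.allclose(sizes.var(), 0) or np.allclose(counts.var(), 0):
        raise ValueError("zero variance: correlation undefined")
    r, _ = stats.pearsonr(sizes, counts)
    return float(r)
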