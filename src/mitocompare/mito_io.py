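"""Annotation model and flat-file I/O for circular mitochondrial genomes.

The central container is :class:`MitogenomeAnnotation`: a genome sequence
plus typed features (protein-coding genes with exon intervals, introns with
their encoded ORFs, tRNA and rRNA genes) in a single 1-based inclusive
coordinate frame, the convention of the GenBank flat files the package
consumes and writes.

Circularity is first-class: a feature spanning the origin of a circular
molecule is stored as a single :class:`Interval` with ``start > end`` and is
re-emitted as an origin-spanning ``join()`` on output.

Translation uses NCBI genetic code 4 (the mold/protozoan/coelenterate
mitochondrial code, in which TGA encodes tryptophan), the code under which
fungal mitochondrial genes are annotated.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CORE_PCGS",
    "RRNA_GENES",
    "COMPARISON_GENES",
    "Interval",
    "GenomeSequence",
    "GeneFeature",
    "IntronFeature",
    "MitogenomeAnnotation",
    "GenBankFormatError",
    "AnnotationError",
    "normalize_gene_name",
    "reverse_complement",
    "complement",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "write_feature_table",
    "extract_cds",
    "extract_gene_sequence",
    "translate_code4",
]

#: The 15 protein-coding genes conserved across Basidiomycota mitogenomes.
CORE_PCGS = (
    "atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "rps3",
)
RRNA_GENES = ("rnl", "rns")
#: 17-gene set used for gene-order comparison and the combined gene set.
COMPARISON_GENES = CORE_PCGS + RRNA_GENES

_CORE_SET = frozenset(CORE_PCGS)
_RRNA_SET = frozenset(RRNA_GENES)

# Synonym table for cross-record comparability; keys lower-case.
_GENE_SYNONYMS = {
    "cytb": "cob", "cob1": "cob", "cyt-b": "cob",
    "rrnl": "rnl", "rnl": "rnl", "lsu": "rnl", "rrn26": "rnl", "21s_rrna": "rnl",
    "rrns": "rns", "rns": "rns", "ssu": "rns", "rrn16": "rns", "15s_rrna": "rns",
    "nad4l": "nad4L", "nd4l": "nad4L",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd5": "nad5", "nd6": "nad6",
    "atpase6": "atp6", "atpase8": "atp8", "atpase9": "atp9",
    "var1": "rps3", "rps3": "rps3",
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class GenBankFormatError(ValueError):
    """Raised when a record cannot be parsed as a GenBank flat file."""


class AnnotationError(ValueError):
    """Raised when feature coordinates or structure are inconsistent."""


def normalize_gene_name(name: str) -> str:
    """Map gene-name synonyms (cytb, rrnL, nd4L ...) to canonical symbols."""
    key = name.strip().lower()
    if key in _GENE_SYNONYMS:
        return _GENE_SYNONYMS[key]
    if key in _CORE_SET or key in {c.lower() for c in _CORE_SET}:
        # restore canonical capitalisation (nad4L)
        for canon in CORE_PCGS:
            if canon.lower() == key:
                return canon
    return name.strip()


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Interval:
    """1-based inclusive genomic interval.

    On circular genomes ``start > end`` encodes an origin-spanning interval
    (``start..L`` followed by ``1..end``).
    """

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise AnnotationError(f"interval coordinates must be >= 1: {self}")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"strand must be '+' or '-': {self.strand!r}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, genome_length: int | None = None) -> int:
        if not self.wraps:
            return self.end - self.start + 1
        if genome_length is None:
            raise AnnotationError("origin-spanning interval needs genome length")
        return (genome_length - self.start + 1) + self.end

    def positions(self, genome_length: int) -> Iterator[int]:
        """Yield covered 1-based positions in ascending wrap order."""
        if not self.wraps:
            yield from range(self.start, self.end + 1)
        else:
            yield from range(self.start, genome_length + 1)
            yield from range(1, self.end + 1)

    def slices(self, genome_length: int) -> list[tuple[int, int]]:
        """0-based half-open slices covering the interval, in wrap order."""
        if not self.wraps:
            return [(self.start - 1, self.end)]
        return [(self.start - 1, genome_length), (0, self.end)]

    def overlaps(self, other: "Interval", genome_length: int) -> bool:
        mine = set(self.positions(genome_length))
        return any(p in mine for p in other.positions(genome_length))


@dataclass(frozen=True)
class GenomeSequence:
    """A genome sequence; residues over {A,C,G,T,N}, uppercase."""

    id: str
    residues: str
    circular: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise AnnotationError("empty genome sequence")
        if not re.fullmatch(r"[ACGTN]+", self.residues):
            bad = sorted(set(self.residues) - set("ACGTN"))
            raise AnnotationError(f"non-ACGTN residues in genome: {bad}")

    @property
    def length(self) -> int:
        return len(self.residues)

    def slice(self, interval: Interval) -> str:
        """Residues covered by ``interval`` on the forward strand, wrap-aware."""
        parts = interval.slices(self.length)
        return "".join(self.residues[a:b] for a, b in parts)


@dataclass(frozen=True)
class GeneFeature:
    """A gene with one or more exons, all on one strand.

    ``exons`` are ordered in transcription direction: ascending genomic
    coordinates for '+' genes, descending for '-' genes.
    """

    name: str
    feature_class: str  # core_pcg | free_orf | intronic_orf | trna | rrna
    exons: tuple[Interval, ...]
    product: str = ""
    host_intron: tuple[str, int] | None = None  # (host gene, intron ordinal)

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"gene {self.name}: no exons")
        strands = {e.strand for e in self.exons}
        if len(strands) != 1:
            raise AnnotationError(f"gene {self.name}: exons on mixed strands")
        if self.feature_class not in (
            "core_pcg", "free_orf", "intronic_orf", "trna", "rrna"
        ):
            raise AnnotationError(
                f"gene {self.name}: unknown feature class {self.feature_class!r}"
            )

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    def span_length(self, genome_length: int) -> int:
        return sum(e.length(genome_length) for e in self.exons)


@dataclass(frozen=True)
class IntronFeature:
    """An intron of a host gene, 1-based ordinal in transcription order."""

    host_gene: str
    ordinal: int
    location: Interval
    group: str = "I"  # I | II | unknown
    orfs: tuple[GeneFeature, ...] = ()

    def __post_init__(self) -> None:
        if self.ordinal < 1:
            raise AnnotationError(
                f"intron of {self.host_gene}: ordinal must be >= 1"
            )
        if self.group not in ("I", "II", "unknown"):
            raise AnnotationError(f"unknown intron group {self.group!r}")


@dataclass(frozen=True)
class MitogenomeAnnotation:
    """A genome plus its typed features in one coordinate frame."""

    genome: GenomeSequence
    genes: tuple[GeneFeature, ...] = ()
    introns: tuple[IntronFeature, ...] = ()
    species: str = ""
    taxon_labels: str = ""

    def __post_init__(self) -> None:
        L = self.genome.length
        for g in self.genes:
            for e in g.exons:
                if e.start > L or e.end > L:
                    raise AnnotationError(
                        f"gene {g.name}: exon {e.start}..{e.end} outside "
                        f"1..{L}"
                    )
                if e.wraps and not self.genome.circular:
                    raise AnnotationError(
                        f"gene {g.name}: origin-spanning exon on linear genome"
                    )
        for i in self.introns:
            if i.location.start > L or i.location.end > L:
                raise AnnotationError(
                    f"intron {i.host_gene}/{i.ordinal}: location outside genome"
                )
            if i.host_gene not in {g.name for g in self.genes}:
                raise AnnotationError(
                    f"intron {i.host_gene}/{i.ordinal}: host gene not annotated"
                )

    def gene(self, name: str) -> GeneFeature:
        canon = normalize_gene_name(name)
        for g in self.genes:
            if g.name == canon:
                return g
        raise KeyError(f"gene {name!r} not found in {self.species or self.genome.id}")

    def has_gene(self, name: str) -> bool:
        canon = normalize_gene_name(name)
        return any(g.name == canon for g in self.genes)

    def genes_of_class(self, *classes: str) -> tuple[GeneFeature, ...]:
        return tuple(g for g in self.genes if g.feature_class in classes)

    def introns_of(self, host: str) -> tuple[IntronFeature, ...]:
        canon = normalize_gene_name(host)
        found = [i for i in self.introns if i.host_gene == canon]
        return tuple(sorted(found, key=lambda i: i.ordinal))

    def canonical(self) -> "MitogenomeAnnotation":
        """Deterministically ordered copy (genes by coordinate then name).

        ``read_genbank`` returns canonical annotations; comparing two
        annotations for semantic equality should go through this form.
        """
        genes = tuple(
            sorted(self.genes, key=lambda g: (g.exons[0].start, g.name))
        )
        introns = tuple(
            sorted(self.introns, key=lambda i: (i.host_gene, i.ordinal))
        )
        return replace(self, genes=genes, introns=introns)


# ---------------------------------------------------------------------------
# sequence extraction and translation


def extract_gene_sequence(annotation: MitogenomeAnnotation, gene: str) -> str:
    """Concatenated exon sequence of any gene, in transcription direction.

    '-' strand exons are reverse-complemented individually and joined in the
    stored (transcription) order.
    """
    g = annotation.gene(gene)
    parts = []
    for exon in g.exons:
        raw = annotation.genome.slice(exon)
        parts.append(reverse_complement(raw) if g.strand == "-" else raw)
    return "".join(parts)


def extract_cds(annotation: MitogenomeAnnotation, gene: str) -> str:
    """Coding sequence of a protein-coding gene (exons joined, strand-corrected).

    Warns when the result is not a whole number of codons.
    """
    g = annotation.gene(gene)
    if g.feature_class not in ("core_pcg", "free_orf", "intronic_orf"):
        raise KeyError(f"gene {gene!r} is {g.feature_class}, not protein-coding")
    cds = extract_gene_sequence(annotation, gene)
    if len(cds) % 3 != 0:
        warnings.warn(
            f"CDS of {g.name} in {annotation.species or annotation.genome.id} "
            f"has length {len(cds)}, not divisible by 3",
            stacklevel=2,
        )
    return cds


class FrameError(ValueError):
    """CDS length not divisible by 3."""


def translate_code4(cds: str) -> str:
    """Translate a CDS under NCBI genetic code 4 (TGA = Trp).

    A terminal stop codon is stripped; internal stops are kept as ``*`` with
    a warning so frame problems surface rather than vanish.
    """
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} not divisible by 3")
    if not cds:
        return ""
    protein = str(Seq(cds).translate(table=4))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        warnings.warn(
            f"internal stop codon(s) at protein position(s) "
            f"{[i + 1 for i, a in enumerate(protein) if a == '*']}",
            stacklevel=2,
        )
    return protein


# ---------------------------------------------------------------------------
# GenBank reading


def _merge_wrap_parts(parts: list[Interval], genome_length: int) -> list[Interval]:
    """Merge an exon pair (x..L)+(1..y) into a single origin-spanning interval."""
    merged: list[Interval] = []
    i = 0
    while i < len(parts):
        cur = parts[i]
        if (
            i + 1 < len(parts)
            and cur.end == genome_length
            and parts[i + 1].start == 1
            and cur.strand == parts[i + 1].strand
            and not cur.wraps
            and not parts[i + 1].wraps
        ):
            merged.append(Interval(cur.start, parts[i + 1].end, cur.strand))
            i += 2
        else:
            merged.append(cur)
            i += 1
    return merged


def _feature_intervals(feat: SeqFeature, genome_length: int) -> list[Interval]:
    """Feature location parts as 1-based intervals in transcription order."""
    strand = "-" if feat.location.strand == -1 else "+"
    parts = []
    for part in feat.location.parts:
        s = int(part.start) + 1
        e = int(part.end)
        if e > genome_length or s > genome_length:
            raise AnnotationError(
                f"feature {feat.type} at {feat.location}: coordinate outside "
                f"sequence of length {genome_length}"
            )
        parts.append(Interval(s, e, strand))
    if strand == "-":
        # complement(join(...)) lists segments in ascending genome order;
        # transcription runs right to left.
        parts_sorted = sorted(parts, key=lambda p: p.start)
        parts_sorted = _merge_wrap_parts(parts_sorted, genome_length)
        return list(reversed(parts_sorted))
    parts = _merge_wrap_parts(parts, genome_length)
    return parts


def _qualifier(feat: SeqFeature, key: str) -> str | None:
    vals = feat.qualifiers.get(key)
    return vals[0] if vals else None


def _contained_in(inner: list[Interval], outer: Interval, L: int) -> bool:
    outer_pos = set(outer.positions(L))
    return all(
        p in outer_pos for iv in inner for p in iv.positions(L)
    )


def _cds_offset_of_intron(
    gene: GeneFeature, intron_loc: Interval, L: int
) -> int | None:
    """Coding nucleotides preceding an intron that sits between two
    consecutive exons of ``gene``; None when the intron does not bracket."""
    exons = gene.exons
    for k in range(len(exons) - 1):
        a, b = exons[k], exons[k + 1]
        if gene.strand == "+":
            gap_start, gap_end = a.end + 1, b.start - 1
        else:
            gap_start, gap_end = b.end + 1, a.start - 1
        if gap_start > gap_end:  # wrap-adjacent exons; compare positionally
            continue
        if intron_loc.start >= gap_start and intron_loc.end <= gap_end:
            return sum(e.length(L) for e in exons[: k + 1])
    return None


def read_genbank(path: str | Path) -> MitogenomeAnnotation:
    """Parse a GenBank flat file into the annotation model.

    Feature classes are assigned from the core-PCG name table, with CDSs
    contained in annotated introns classed ``intronic_orf`` and the rest
    ``free_orf``. Unparseable qualifiers are logged, never fatal.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad files
        raise GenBankFormatError(f"{path}: not a readable GenBank record: {exc}")
    try:
        seq = str(record.seq)
    except Exception:
        raise GenBankFormatError(f"{path}: record has no ORIGIN sequence")
    if not seq:
        raise GenBankFormatError(f"{path}: record has no ORIGIN sequence")
    try:
        genome = GenomeSequence(
            id=record.id or record.name,
            residues=seq,
            circular=record.annotations.get("topology", "linear") == "circular",
        )
    except AnnotationError as exc:
        raise GenBankFormatError(f"{path}: {exc}")
    L = genome.length
    species = record.annotations.get("organism", "")
    if not species:
        for feat in record.features:
            if feat.type == "source" and _qualifier(feat, "organism"):
                species = _qualifier(feat, "organism")
                break
    if not species:
        species = record.description.rstrip(".")

    raw_introns: list[tuple[Interval, dict]] = []
    raw_cds: list[tuple[str, list[Interval], str]] = []
    raw_rna: list[tuple[str, list[Interval], str, str]] = []

    for feat in record.features:
        if feat.type not in ("CDS", "tRNA", "rRNA", "intron"):
            continue
        intervals = _feature_intervals(feat, L)
        name = (
            _qualifier(feat, "gene")
            or _qualifier(feat, "locus_tag")
            or _qualifier(feat, "product")
            or f"{feat.type}_{intervals[0].start}"
        )
        name = normalize_gene_name(name)
        product = _qualifier(feat, "product") or ""
        if feat.type == "intron":
            if len(intervals) != 1:
                logger.warning("%s: multi-part intron location, using span", path)
            raw_introns.append((intervals[0], dict(feat.qualifiers)))
        elif feat.type == "CDS":
            raw_cds.append((name, intervals, product))
        else:
            raw_rna.append((name, intervals, product, feat.type))

    genes: list[GeneFeature] = []
    for name, intervals, product, ftype in raw_rna:
        genes.append(
            GeneFeature(
                name=name,
                feature_class="trna" if ftype == "tRNA" else "rrna",
                exons=tuple(intervals),
                product=product,
            )
        )

    # first pass: classify CDSs without intron containment resolved
    pending: list[tuple[str, list[Interval], str]] = []
    for name, intervals, product in raw_cds:
        if name in _CORE_SET:
            genes.append(
                GeneFeature(name, "core_pcg", tuple(intervals), product)
            )
        else:
            pending.append((name, intervals, product))

    # resolve intron host genes and ordinals
    intron_feats: list[IntronFeature] = []
    host_order: dict[str, list[tuple[int, Interval, dict]]] = {}
    coding_genes = [g for g in genes if g.feature_class == "core_pcg"]
    for loc, quals in raw_introns:
        host = quals.get("gene", [None])[0]
        host = normalize_gene_name(host) if host else None
        offset = None
        if host is None:
            for g in coding_genes:
                offset = _cds_offset_of_intron(g, loc, L)
                if offset is not None:
                    host = g.name
                    break
        else:
            for g in genes:
                if g.name == host:
                    offset = _cds_offset_of_intron(g, loc, L)
                    break
        if host is None:
            logger.warning(
                "%s: intron at %s..%s has no bracketing gene; skipped",
                path, loc.start, loc.end,
            )
            continue
        host_order.setdefault(host, []).append(
            (offset if offset is not None else loc.start, loc, quals)
        )

    for host, entries in host_order.items():
        entries.sort(key=lambda t: t[0])
        for ordinal, (_, loc, quals) in enumerate(entries, start=1):
            note = " ".join(quals.get("note", []))
            group = "unknown"
            m = re.search(r"group[ _]?(I{1,2})\b", note, flags=re.IGNORECASE)
            if m:
                group = m.group(1).upper()
            num = quals.get("number", [None])[0]
            if num is not None:
                try:
                    ordinal = int(num)
                except ValueError:
                    logger.warning("unparseable intron /number=%r", num)
            intron_feats.append(
                IntronFeature(host_gene=host, ordinal=ordinal, location=loc,
                              group=group)
            )

    # second pass: non-core CDSs are intronic ORFs when contained in an intron
    final_introns: dict[tuple[str, int], IntronFeature] = {
        (i.host_gene, i.ordinal): i for i in intron_feats
    }
    for name, intervals, product in pending:
        host_key = None
        for key, intr in final_introns.items():
            if _contained_in(intervals, intr.location, L):
                host_key = key
                break
        if host_key is not None:
            gf = GeneFeature(name, "intronic_orf", tuple(intervals), product,
                             host_intron=host_key)
            genes.append(gf)
            intr = final_introns[host_key]
            final_introns[host_key] = replace(intr, orfs=intr.orfs + (gf,))
        else:
            genes.append(GeneFeature(name, "free_orf", tuple(intervals), product))

    return MitogenomeAnnotation(
        genome=genome,
        genes=tuple(genes),
        introns=tuple(final_introns.values()),
        species=species,
    ).canonical()


# ---------------------------------------------------------------------------
# GenBank writing


def _location_from_exons(
    exons: Sequence[Interval], genome_length: int
) -> SimpleLocation | CompoundLocation:
    strand = 1 if exons[0].strand == "+" else -1
    ordered = exons if strand == 1 else list(reversed(exons))
    parts: list[SimpleLocation] = []
    for e in ordered:
        if e.wraps:
            parts.append(SimpleLocation(e.start - 1, genome_length, strand))
            parts.append(SimpleLocation(0, e.end, strand))
        else:
            parts.append(SimpleLocation(e.start - 1, e.end, strand))
    if len(parts) == 1:
        return parts[0]
    return CompoundLocation(parts)


def _locus_name(annotation: MitogenomeAnnotation) -> str:
    base = annotation.genome.id or annotation.species or "mitogenome"
    return re.sub(r"[^A-Za-z0-9_]", "_", base)[:16] or "mitogenome"


def write_genbank(annotation: MitogenomeAnnotation, path: str | Path) -> Path:
    """Write the annotation as a GenBank flat file re-readable losslessly.

    ORIGIN lines follow the standard 60 nt / 6 x 10 layout (Biopython's
    writer). The date field is fixed so identical annotations produce
    byte-identical files.
    """
    path = Path(path)
    genome = annotation.genome
    record = SeqRecord(
        Seq(genome.residues),
        id=genome.id,
        name=_locus_name(annotation),
        description=f"{annotation.species} mitochondrion".strip(),
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
            "organism": annotation.species or genome.id,
            "date": "01-JAN-2024",
            "data_file_division": "PLN",
        },
    )
    record.features.append(
        SeqFeature(
            SimpleLocation(0, genome.length, 1),
            type="source",
            qualifiers={"organism": [annotation.species or genome.id]},
        )
    )
    type_for_class = {
        "core_pcg": "CDS", "free_orf": "CDS", "intronic_orf": "CDS",
        "trna": "tRNA", "rrna": "rRNA",
    }
    for g in annotation.genes:
        quals: dict[str, list[str]] = {"gene": [g.name]}
        if g.product:
            quals["product"] = [g.product]
        if g.feature_class == "intronic_orf" and g.host_intron:
            quals["note"] = [
                f"intronic ORF within intron {g.host_intron[1]} of "
                f"{g.host_intron[0]}"
            ]
        record.features.append(
            SeqFeature(
                _location_from_exons(g.exons, genome.length),
                type=type_for_class[g.feature_class],
                qualifiers=quals,
            )
        )
    for intr in annotation.introns:
        loc = Interval(intr.location.start, intr.location.end, intr.location.strand)
        record.features.append(
            SeqFeature(
                _location_from_exons([loc], genome.length),
                type="intron",
                qualifiers={
                    "gene": [intr.host_gene],
                    "number": [str(intr.ordinal)],
                    "note": [f"group {intr.group}" if intr.group != "unknown"
                             else "group unknown"],
                },
            )
        )
    # stable feature order: by type then coordinate, source first
    record.features[1:] = sorted(
        record.features[1:],
        key=lambda f: (int(f.location.start), f.type, str(f.location)),
    )
    SeqIO.write(record, str(path), "genbank")
    return path


# ---------------------------------------------------------------------------
# FASTA and tabular output


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return path


def write_feature_table(annotation: MitogenomeAnnotation, path: str | Path) -> Path:
    """Feature table TSV: species, gene, class, strand, exon coords, length.

    Coordinates are 1-based inclusive.
    """
    path = Path(path)
    L = annotation.genome.length
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        fh.write("species\tgene\tclass\tstrand\texon_coords\tlength\n")
        for g in annotation.genes:
            coords = ",".join(f"{e.start}..{e.end}" for e in g.exons)
            fh.write(
                f"{annotation.species}\t{g.name}\t{g.feature_class}\t"
                f"{g.strand}\t{coords}\t{g.span_length(L)}\n"
            )
        for i in annotation.introns:
            fh.write(
                f"{annotation.species}\t{i.host_gene}_intron{i.ordinal}\t"
                f"intron\t{i.location.strand}\t"
                f"{i.location.start}..{i.location.end}\t"
                f"{i.location.length(L)}\n"
            )
    return path
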