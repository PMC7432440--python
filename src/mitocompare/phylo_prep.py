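"""Combined mitochondrial gene set: per-gene alignment, supermatrix, NJ tree.

The phylogenetic data product is a concatenated alignment of the 15 core
protein-coding genes (as genetic-code-4 translations by default) and the two
rRNA genes (as nucleotide), with a partition table declaring each gene's
column block. Tree inference proper is left to external ML/BI software; a
neighbor-joining tree on p-distances is provided as a fast sanity check of
the matrix.

Per-gene alignment can be delegated to an external aligner (e.g. ``mafft``)
through a command template, or run through the built-in deterministic
progressive aligner (center-star on the package's own global pairwise
aligner), which needs no subprocess and gives reproducible columns.
"""

from __future__ import annotations

import io
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .intron_pcl import align_protein_global
from .mito_io import (
    COMPARISON_GENES,
    CORE_PCGS,
    MitogenomeAnnotation,
    RRNA_GENES,
    extract_cds,
    extract_gene_sequence,
    translate_code4,
    write_fasta,
)

__all__ = [
    "GeneSet",
    "Supermatrix",
    "DistanceMatrix",
    "extract_gene_set",
    "align_gene",
    "align_with_mafft",
    "star_align",
    "concatenate",
    "p_distance_matrix",
    "nj_tree",
    "write_phylip",
    "read_phylip",
    "write_nexus",
    "write_partitions",
]


@dataclass(frozen=True)
class GeneSet:
    """Per-gene unaligned sequences across taxa."""

    sequences: dict[str, dict[str, str]]  # gene -> taxon -> sequence
    types: dict[str, str]  # gene -> 'protein' | 'rna'
    missing: dict[str, tuple[str, ...]]  # gene -> taxa lacking it


@dataclass(frozen=True)
class Supermatrix:
    taxa: tuple[str, ...]
    rows: dict[str, str]  # taxon -> concatenated characters
    partitions: tuple[tuple[str, int, int, str], ...]  # (gene, start, end, type)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def gap_fraction(self, taxon: str) -> float:
        row = self.rows[taxon]
        return row.count("-") / len(row) if row else 0.0


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric, zero diagonal")


def extract_gene_set(
    annotations: list[MitogenomeAnnotation],
    protein: bool = True,
) -> GeneSet:
    """Collect the 17 comparison genes across species.

    Core PCGs are exported as code-4 translations (``protein=False`` keeps
    nucleotide CDS); rRNAs are always nucleotide. Absent genes are recorded
    rather than failing.
    """
    if len(annotations) < 2:
        raise ValueError("need at least 2 annotations")
    sequences: dict[str, dict[str, str]] = {g: {} for g in COMPARISON_GENES}
    missing: dict[str, list[str]] = {g: [] for g in COMPARISON_GENES}
    for ann in annotations:
        taxon = ann.species or ann.genome.id
        for gene in CORE_PCGS:
            if ann.has_gene(gene):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cds = extract_cds(ann, gene)
                    if protein:
                        trimmed = cds[: len(cds) - len(cds) % 3]
                        seq = translate_code4(trimmed).replace("*", "X")
                    else:
                        seq = cds
                sequences[gene][taxon] = seq
            else:
                missing[gene].append(taxon)
        for gene in RRNA_GENES:
            if ann.has_gene(gene):
                sequences[gene][taxon] = extract_gene_sequence(ann, gene)
            else:
                missing[gene].append(taxon)
    types = {g: ("protein" if g in CORE_PCGS else "rna") for g in COMPARISON_GENES}
    return GeneSet(
        sequences=sequences,
        types=types,
        missing={g: tuple(m) for g, m in missing.items()},
    )


# ---------------------------------------------------------------------------
# alignment


def _pairwise_dna(a: str, b: str) -> tuple[str, str]:
    """Global nucleotide alignment (match 2 / mismatch -1, gaps 5/1)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    aln = next(iter(aligner.align(a, b)))
    from .intron_pcl import _gapped_rows

    return _gapped_rows(aln, a, b)


def _pairwise(a: str, b: str, seq_type: str) -> tuple[str, str]:
    if seq_type == "protein":
        aln = align_protein_global(a, b)
        return aln.query, aln.reference
    return _pairwise_dna(a, b)


def star_align(sequences: dict[str, str], seq_type: str) -> dict[str, str]:
    """Deterministic center-star multiple alignment.

    The longest sequence (ties by taxon label) is the center; every other
    sequence is aligned to it pairwise and gaps are merged into a common
    center coordinate system ("once a gap, always a gap").
    """
    if not sequences:
        return {}
    taxa = sorted(sequences)
    if len(taxa) == 1:
        return dict(sequences)
    center = max(taxa, key=lambda t: (len(sequences[t]), t))
    center_seq = sequences[center]
    pairs: dict[str, tuple[str, str]] = {}
    for t in taxa:
        if t == center:
            continue
        other_g, center_g = _pairwise(sequences[t], center_seq, seq_type)
        pairs[t] = (other_g, center_g)

    # merged gap profile for the center: max insertions before each center
    # position (index 0..len(center)), per pairwise alignment
    n = len(center_seq)
    ins_before = np.zeros(n + 1, dtype=int)
    for other_g, center_g in pairs.values():
        cpos = 0
        run = 0
        for ch in center_g:
            if ch == "-":
                run += 1
            else:
                ins_before[cpos] = max(ins_before[cpos], run)
                run = 0
                cpos += 1
        ins_before[n] = max(ins_before[n], run)

    def expand(other_g: str, center_g: str) -> str:
        out = []
        cpos = 0
        run_chars: list[str] = []
        for oc, cc in zip(other_g, center_g):
            if cc == "-":
                run_chars.append(oc)
            else:
                pad = ins_before[cpos] - len(run_chars)
                out.append("".join(run_chars) + "-" * pad)
                out.append(oc)
                run_chars = []
                cpos += 1
        pad = ins_before[n] - len(run_chars)
        out.append("".join(run_chars) + "-" * pad)
        return "".join(out)

    aligned: dict[str, str] = {}
    center_g_full = expand(center_seq, center_seq)
    aligned[center] = center_g_full
    for t, (other_g, center_g) in pairs.items():
        aligned[t] = expand(other_g, center_g)
    width = {len(s) for s in aligned.values()}
    assert len(width) == 1, "center-star merge produced ragged rows"
    return {t: aligned[t] for t in taxa}


def align_with_mafft(
    sequences: dict[str, str], mafft_cmd: str = "mafft --auto --quiet {input}"
) -> dict[str, str]:
    """Align through an external aligner command template.

    ``{input}`` in the template is replaced by a FASTA path; the aligner must
    print aligned FASTA on stdout (the mafft convention).
    """
    exe = mafft_cmd.split()[0]
    if shutil.which(exe) is None:
        raise RuntimeError(f"external aligner {exe!r} not on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fasta"
        write_fasta(sequences, fasta)
        cmd = mafft_cmd.format(input=str(fasta)).split()
        res = subprocess.run(cmd, capture_output=True, text=True, check=True)
    out: dict[str, str] = {}
    name = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            out[name] = ""
        elif name:
            out[name] += line.strip().upper()
    return out


def align_gene(
    sequences: dict[str, str],
    seq_type: str,
    method: str = "builtin",
    mafft_cmd: str = "mafft --auto --quiet {input}",
) -> dict[str, str]:
    if method == "builtin":
        return star_align(sequences, seq_type)
    if method == "mafft":
        return align_with_mafft(sequences, mafft_cmd)
    raise ValueError(f"unknown alignment method {method!r}")


# ---------------------------------------------------------------------------
# concatenation


def concatenate(aligned_genes: dict[str, dict[str, str]],
                types: dict[str, str] | None = None) -> Supermatrix:
    """Concatenate per-gene alignments in alphabetical gene order.

    Taxa absent from a gene are gap-filled across that partition. Partition
    coordinates are 1-based inclusive.
    """
    genes = sorted(aligned_genes)
    taxa = sorted({t for g in genes for t in aligned_genes[g]})
    if len(taxa) != len(set(taxa)):
        raise ValueError("duplicate taxon labels")
    rows = {t: [] for t in taxa}
    partitions: list[tuple[str, int, int, str]] = []
    col = 0
    for gene in genes:
        block = aligned_genes[gene]
        if not block:
            continue
        widths = {len(s) for s in block.values()}
        if len(widths) != 1:
            raise ValueError(f"{gene}: unequal aligned lengths {sorted(widths)}")
        width = widths.pop()
        for t in taxa:
            rows[t].append(block.get(t, "-" * width))
        gtype = (types or {}).get(gene, "protein")
        partitions.append((gene, col + 1, col + width, gtype))
        col += width
    return Supermatrix(
        taxa=tuple(taxa),
        rows={t: "".join(parts) for t, parts in rows.items()},
        partitions=tuple(partitions),
    )


# ---------------------------------------------------------------------------
# distances and NJ


def p_distance_matrix(matrix: Supermatrix) -> DistanceMatrix:
    """Pairwise p-distances over shared non-gap columns."""
    taxa = matrix.taxa
    n = len(taxa)
    arrs = {
        t: np.frombuffer(matrix.rows[t].encode(), dtype=np.uint8) for t in taxa
    }
    gap = ord("-")
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[taxa[i]], arrs[taxa[j]]
            ok = (a != gap) & (b != gap)
            shared = int(ok.sum())
            d = float((a[ok] != b[ok]).sum() / shared) if shared else 0.0
            values[i, j] = values[j, i] = d
    return DistanceMatrix(taxa=taxa, values=values)


def nj_tree(matrix: DistanceMatrix) -> str:
    """Neighbor-joining tree (newick, unrooted) from a distance matrix.

    Taxa are fed to the NJ implementation in label-sorted order so ties
    break identically across runs.
    """
    if len(matrix.taxa) < 4:
        raise ValueError("need at least 4 taxa")
    if not np.all(np.isfinite(matrix.values)):
        raise ValueError("non-finite distances")
    order = sorted(range(len(matrix.taxa)), key=lambda i: matrix.taxa[i])
    taxa = [matrix.taxa[i] for i in order]
    sub = matrix.values[np.ix_(order, order)]
    csv_buf = io.StringIO()
    csv_buf.write("," + ",".join(taxa) + "\n")
    for i, t in enumerate(taxa):
        csv_buf.write(t + "," + ",".join(f"{x:.10f}" for x in sub[i]) + "\n")
    csv_buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        csv_buf, delimiter=","
    )
    tree = pdm.nj_tree()
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# writers


def write_phylip(matrix: Supermatrix, path) -> Path:
    """Relaxed PHYLIP: name, two spaces, full row."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.taxa)} {matrix.n_columns}\n")
        for t in matrix.taxa:
            fh.write(f"{t.replace(' ', '_')}  {matrix.rows[t]}\n")
    return path


def read_phylip(path) -> Supermatrix:
    with open(path) as fh:
        header = fh.readline().split()
        ntax, ncol = int(header[0]), int(header[1])
        rows: dict[str, str] = {}
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            rows[name] = seq.strip()
    if len(rows) != ntax or any(len(s) != ncol for s in rows.values()):
        raise ValueError(f"{path}: malformed relaxed PHYLIP")
    return Supermatrix(taxa=tuple(sorted(rows)), rows=rows, partitions=())


def write_nexus(matrix: Supermatrix, path, datatype: str = "protein") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(matrix.taxa)} "
                 f"NCHAR={matrix.n_columns};\n")
        fh.write(f"  FORMAT DATATYPE={datatype} GAP=- MISSING=?;\n  MATRIX\n")
        for t in matrix.taxa:
            fh.write(f"    {t.replace(' ', '_')}  {matrix.rows[t]}\n")
        fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
        for gene, start, end, _ in matrix.partitions:
            fh.write(f"  CHARSET {gene} = {start}-{end};\n")
        fh.write("END;\n")
    return path


def write_partitions(
    matrix: Supermatrix, path,
    protein_model: str = "WAG", rna_model: str = "GTR",
) -> Path:
    """RAxML-style partition file: ``MODEL, gene = start-end`` per gene."""
    path = Path(path)
    with open(path, "w") as fh:
        for gene, start, end, gtype in matrix.partitions:
            model = protein_model if gtype == "protein" else rna_model
            fh.write(f"{model}, {gene} = {start}-{end}\n")
    return path
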