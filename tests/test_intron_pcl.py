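"""Protein alignment, insertion-point mapping, Pcl matrix and correlation."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from mitocompare.intron_pcl import (
    IntronCountRecord,
    PclName,
    align_protein_global,
    build_pcl_matrix,
    intron_insertion_points,
    pearson_size_intron,
    project_to_reference,
    ProteinAlignment,
)
from mitocompare.mito_io import (
    GeneFeature,
    Interval,
    IntronFeature,
    translate_code4,
)
from mitocompare.synthetic_data import (
    IntronPlan,
    SyntheticSpec,
    back_translate,
    generate_clade,
    generate_mitogenome,
    mutate_protein,
    reference_cox1_cds,
)
from conftest import make_annotation
from oracles import gotoh_score


# ---------------------------------------------------------------------------
# alignment


def test_identical_sequences_align_gapless():
    aln = align_protein_global("MKVLWA", "MKVLWA")
    assert aln.query == aln.reference == "MKVLWA"
    blosum = substitution_matrices.load("BLOSUM62")
    assert aln.score == sum(blosum[a, a] for a in "MKVLWA")


def test_single_deletion_column():
    aln = align_protein_global("MKV", "MV")
    assert aln.query == "MKV"
    assert aln.reference in ("M-V", "MV-")
    assert aln.reference.count("-") == 1


def test_alignment_score_matches_independent_dp(rng):
    """PairwiseAligner scores equal a hand-rolled Gotoh DP on random pairs."""
    blosum = substitution_matrices.load("BLOSUM62")
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(8):
        n, m = int(rng.integers(30, 100)), int(rng.integers(30, 100))
        a = "".join(alphabet[i] for i in rng.integers(0, 20, n))
        b = "".join(alphabet[i] for i in rng.integers(0, 20, m))
        aln = align_protein_global(a, b)
        assert aln.score == pytest.approx(gotoh_score(a, b, blosum, 10.0, 1.0))


def test_alignment_rejects_bad_characters():
    with pytest.raises(ValueError, match="non-amino-acid"):
        align_protein_global("MK*V", "MKV")
    with pytest.raises(ValueError):
        align_protein_global("", "MKV")


# ---------------------------------------------------------------------------
# insertion points


def _two_exon_gene(exon1, intron, exon2, strand="+"):
    """Build a plus-strand layout [exon1][intron][exon2] starting at 101."""
    a1 = 101
    e1 = Interval(a1, a1 + exon1 - 1, strand)
    iv = Interval(a1 + exon1, a1 + exon1 + intron - 1, strand)
    e2 = Interval(a1 + exon1 + intron, a1 + exon1 + intron + exon2 - 1, strand)
    return e1, iv, e2


def test_insertion_point_simple():
    e1, iv, e2 = _two_exon_gene(120, 500, 300)
    gene = GeneFeature("cox1", "core_pcg", (e1, e2))
    ann = make_annotation(
        "A" * 2000, [gene], [IntronFeature("cox1", 1, iv)]
    )
    assert intron_insertion_points(gene, ann) == [(1, 120)]


def test_insertion_points_strictly_increasing():
    base = 101
    exons, introns = [], []
    pos = base
    for k, (elen, ilen) in enumerate([(90, 200), (60, 150), (120, 0)]):
        exons.append(Interval(pos, pos + elen - 1, "+"))
        pos += elen
        if ilen:
            introns.append(
                IntronFeature("cox1", k + 1, Interval(pos, pos + ilen - 1, "+"))
            )
            pos += ilen
    gene = GeneFeature("cox1", "core_pcg", tuple(exons))
    ann = make_annotation("A" * 2000, [gene], introns)
    points = intron_insertion_points(gene, ann)
    offsets = [off for _, off in points]
    assert offsets == [90, 150]
    assert offsets == sorted(offsets)


def test_insertion_point_minus_strand_matches_hand_computation():
    """'-' strand gene: transcription runs right to left, so the first exon
    is the rightmost; offsets counted on the reverse complement."""
    # genome layout: [exon2 201..320][intron 321..720][exon1 721..840]
    e2 = Interval(201, 320, "-")
    iv = Interval(321, 720, "-")
    e1 = Interval(721, 840, "-")
    gene = GeneFeature("cox1", "core_pcg", (e1, e2))  # transcription order
    ann = make_annotation("A" * 1000, [gene], [IntronFeature("cox1", 1, iv)])
    assert intron_insertion_points(gene, ann) == [(1, 120)]


def test_insertion_point_rejects_non_bracketed_intron():
    from mitocompare.mito_io import AnnotationError

    e1, iv, e2 = _two_exon_gene(120, 500, 300)
    gene = GeneFeature("cox1", "core_pcg", (e1, e2))
    bad = IntronFeature("cox1", 1, Interval(1500, 1600, "+"))
    ann = make_annotation("A" * 2000, [gene], [bad])
    with pytest.raises(AnnotationError):
        intron_insertion_points(gene, ann)


# ---------------------------------------------------------------------------
# projection onto the reference


@pytest.fixture(scope="module")
def reference_protein():
    return translate_code4(reference_cox1_cds())


def _identity_alignment(protein):
    return ProteinAlignment(query=protein, reference=protein, score=0.0)


@pytest.mark.parametrize(
    "offset,label,phase",
    [(383, "P383", 2), (1107, "P1107", 0), (1281, "P1281", 0)],
)
def test_projection_identity(reference_protein, offset, label, phase):
    """When query equals reference the label is the raw offset."""
    pcl = project_to_reference(offset, reference_protein, reference_protein,
                               _identity_alignment(reference_protein))
    assert pcl.label == label
    assert pcl.phase == phase
    assert pcl.exact


def test_projection_label_with_phase(reference_protein):
    pcl = project_to_reference(383, reference_protein, reference_protein,
                               _identity_alignment(reference_protein))
    assert pcl.label_with_phase == "P383+2"
    pcl0 = project_to_reference(1107, reference_protein, reference_protein,
                                _identity_alignment(reference_protein))
    assert pcl0.label_with_phase == "P1107"


def test_projection_with_nterminal_extension(reference_protein):
    """A 10-aa N-terminal extension shifts query coordinates but not the
    reference label."""
    query = "M" + "A" * 9 + reference_protein
    aln = align_protein_global(query, reference_protein)
    pcl = project_to_reference(30 + 383, query, reference_protein, aln)
    assert pcl.label == "P383"
    assert pcl.phase == 2


def test_projection_in_reference_gap_anchors_left():
    """An insertion inside a query-only segment is flagged inexact and
    anchored to the nearest reference residue on the left."""
    reference = "MKVAAAWLE"
    query = "MKVDDDAAAWLE"  # 3-aa insertion after position 3
    aln = align_protein_global(query, reference)
    # site inside the inserted DDD block: query codon 5, phase 0 -> offset 15
    pcl = project_to_reference(15, query, reference, aln)
    assert not pcl.exact
    assert pcl.ref_nt_position == 9  # after reference codon 3 (V)


def test_pclname_validates_phase_consistency():
    with pytest.raises(ValueError):
        PclName(ref_nt_position=383, phase=1)
    assert PclName(ref_nt_position=383, phase=2).label == "P383"


# ---------------------------------------------------------------------------
# matrix logic


def test_pcl_matrix_planted_prevalences():
    """P383 planted in 7/10 species and P1107 in 2/10: prevalences exact,
    common/rare split by the strict >n/5 rule."""
    base = SyntheticSpec(seed=13, genome_length=32_000)
    clade = generate_clade(
        10, base,
        pcl_memberships={383: tuple(range(7)), 1107: (7, 8)},
    )
    anns = [a for a, _ in clade]
    matrix = build_pcl_matrix(anns, reference_cox1_cds())
    assert matrix.labels == ["P383", "P1107"]
    assert matrix.prevalence["P383"] == 7
    assert matrix.prevalence["P1107"] == 2
    cls = matrix.classification()
    assert cls["P383"] == "common"  # 7 > 10/5
    assert cls["P1107"] == "rare"  # 2 == 10/5, not strictly greater
    assert (matrix.prevalence == matrix.presence.sum(axis=0)).all()


def test_pcl_matrix_single_species_all_rare():
    spec = SyntheticSpec(seed=5, genome_length=32_000,
                         intron_plan=(IntronPlan("cox1", 383, 800),))
    ann, _ = generate_mitogenome(spec)
    others = [
        generate_mitogenome(
            SyntheticSpec(seed=s, genome_length=32_000,
                          species=f"Other_{s}")
        )[0]
        for s in (101, 102, 103, 104, 105)
    ]
    matrix = build_pcl_matrix([ann] + others, reference_cox1_cds())
    assert (matrix.classification() == "rare").all()


def test_pcl_matrix_zero_intron_species_row():
    spec = SyntheticSpec(seed=5, genome_length=32_000)
    ann, _ = generate_mitogenome(spec)
    spec2 = SyntheticSpec(seed=6, genome_length=32_000, species="No introns",
                          intron_plan=(IntronPlan("cox1", 383, 800),))
    ann2, _ = generate_mitogenome(spec2)
    matrix = build_pcl_matrix([ann2, ann], reference_cox1_cds())
    assert matrix.presence.loc["Synthetica mitogenomica"].sum() == 0
    assert matrix.presence.loc["No introns", "P383"]


def test_pcl_recovery_under_divergence(rng):
    """Planted labels survive 20% protein divergence plus indels away from
    the insertion site in >= 95% of cases."""
    ref_cds = reference_cox1_cds()
    ref_protein = translate_code4(ref_cds)
    n_ok = 0
    n_introns = 60
    positions = [383, 1107, 1281] * (n_introns // 3)
    for pos in positions:
        prot = mutate_protein(rng, ref_protein,
                              int(0.2 * len(ref_protein)))
        # indel away from the site: delete 2 aa at least 5 codons away
        site_codon = -(-pos // 3)
        while True:
            del_at = int(rng.integers(1, len(prot) - 2))
            if abs(del_at - site_codon) > 5:
                break
        prot = prot[: del_at - 1] + prot[del_at + 1 :]
        cds = back_translate(rng, prot, 0.3)
        query_protein = translate_code4(cds)
        offset = pos if del_at > site_codon else pos - 6
        aln = align_protein_global(query_protein, ref_protein)
        pcl = project_to_reference(offset, query_protein, ref_protein, aln)
        if pcl.label == f"P{pos}":
            n_ok += 1
    assert n_ok / n_introns >= 0.95


# ---------------------------------------------------------------------------
# correlation


def test_pearson_exact_linear():
    records = [
        IntronCountRecord(f"s{i}", 20_000 + 5_000 * i, i) for i in range(10)
    ]
    assert pearson_size_intron(records) == pytest.approx(1.0)


def test_pearson_undefined_on_constant_counts():
    records = [IntronCountRecord(f"s{i}", 20_000 + i * 100, 3)
               for i in range(5)]
    with pytest.raises(ValueError, match="zero variance"):
        pearson_size_intron(records)


def test_pearson_needs_three_records():
    with pytest.raises(ValueError):
        pearson_size_intron(
            [IntronCountRecord("a", 1000, 1), IntronCountRecord("b", 2000, 2)]
        )
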