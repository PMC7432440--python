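"""Repeat detectors against brute-force oracles and planted truth."""

import numpy as np
import pytest

from mitocompare.mito_io import GenomeSequence
from mitocompare.repeats import (
    ScoringScheme,
    find_exact_repeats,
    find_interspersed_repeats,
    find_tandem_repeats,
    find_transfer_fragments,
    repeat_coverage,
    RepeatHit,
)
from mitocompare.mito_io import Interval
from mitocompare.synthetic_data import (
    RepeatPlan,
    SyntheticSpec,
    TandemPlan,
    TransferPlan,
    generate_mitogenome,
    generate_nuclear_with_transfer,
    mutate_sequence,
    random_dna,
)
from oracles import brute_force_exact_repeats


def _as_key_set(hits):
    return {
        (
            (h.interval_a.start - 1, h.interval_a.end),
            (h.interval_b.start - 1, h.interval_b.end),
            h.orientation,
            h.length,
        )
        for h in hits
    }


# ---------------------------------------------------------------------------
# exact repeats


def test_exact_forward_pair_example():
    hits = find_exact_repeats("AATTCCCCAATT", min_len=4, kinds=("forward",))
    assert [(h.interval_a.start, h.interval_a.end,
             h.interval_b.start, h.interval_b.end) for h in hits] == [
        (1, 4, 9, 12)
    ]
    assert hits[0].identity == 100.0


def test_exact_repeats_match_brute_force_oracle(rng):
    """Maximal exact pairs equal a full diagonal-scan enumeration on random
    sequences up to 300 bp, all four orientation classes."""
    for k in range(12):
        n = int(rng.integers(50, 301))
        s = random_dna(rng, n, 0.35)
        min_len = int(rng.integers(5, 9))
        got = _as_key_set(find_exact_repeats(s, min_len=min_len))
        expected = brute_force_exact_repeats(s, min_len)
        assert got == expected


def test_homopolymer_suppressed_by_low_complexity_filter():
    s = "A" * 60
    assert find_exact_repeats(s, min_len=8, kinds=("forward",),
                              low_complexity_filter=True) == []
    assert len(find_exact_repeats(s, min_len=8, kinds=("forward",))) > 0


def test_exact_repeats_shorter_than_min_len():
    assert find_exact_repeats("ACGTACG", min_len=8) == []


# ---------------------------------------------------------------------------
# interspersed repeats


def test_planted_exact_duplication_recovered(rng):
    spec = SyntheticSpec(seed=123, genome_length=30_000,
                         repeat_plan=(RepeatPlan("forward", 80),))
    ann, truth = generate_mitogenome(spec)
    hits = find_interspersed_repeats(ann.genome)
    assert len(hits) == 1
    h = hits[0]
    rec = truth.repeat_records[0]
    got = {(h.interval_a.start, h.interval_a.end),
           (h.interval_b.start, h.interval_b.end)}
    assert got == {tuple(rec["interval_a"]), tuple(rec["interval_b"])}
    assert h.identity == 100.0
    assert h.evalue < 1e-10


def test_planted_mutated_duplication_identity_band():
    spec = SyntheticSpec(seed=77, genome_length=30_000,
                         repeat_plan=(RepeatPlan("forward", 200, identity=90),))
    ann, _ = generate_mitogenome(spec)
    hits = find_interspersed_repeats(ann.genome)
    assert hits, "mutated duplication not recovered"
    assert 88.0 <= hits[0].identity <= 92.0


def test_random_sequence_yields_no_hits_at_strict_threshold(rng):
    misses = 0
    for _ in range(20):
        s = random_dna(rng, 1000, 0.27)
        if find_interspersed_repeats(s, evalue_max=1e-10):
            misses += 1
    assert misses == 0


def test_word_size_validated():
    with pytest.raises(ValueError):
        find_interspersed_repeats("ACGT" * 100, word=4)


def test_origin_spanning_repeat_found_once():
    """A duplication whose second copy spans the circular origin is seeded
    through the wrap-around extension and reported once."""
    rng = np.random.default_rng(5)
    unit = random_dna(rng, 60, 0.35)
    middle = random_dna(rng, 400, 0.35)
    tail = random_dna(rng, 300, 0.35)
    # genome = [last 30 of unit] + middle + unit + tail + [first 30 of unit]
    residues = unit[30:] + middle + unit + tail + unit[:30]
    genome = GenomeSequence(id="w", residues=residues, circular=True)
    hits = find_interspersed_repeats(genome, word=11, evalue_max=1e-3)
    spans = [
        {(h.interval_a.start, h.interval_a.end),
         (h.interval_b.start, h.interval_b.end)}
        for h in hits
    ]
    L = len(residues)
    wrapped = (L - 30 + 1, 30)  # start > end encodes the origin-spanning copy
    inner = (431, 490)
    assert {wrapped, inner} in spans


def test_null_calibration_of_evalues(rng):
    """Monte-Carlo false-positive counts track the Karlin-Altschul E-value.

    At a threshold whose score cutoff exceeds the seed word length the mean
    number of hits per random sequence should approximate the threshold
    (within a factor of 3)."""
    e = 0.02
    reps = 400
    total = 0
    for _ in range(reps):
        s = random_dna(rng, 500, 0.5)
        total += len(find_interspersed_repeats(s, word=8, evalue_max=e,
                                               dust=False))
    mean = total / reps
    assert e / 3 <= mean <= 3 * e


# ---------------------------------------------------------------------------
# tandem repeats


def test_tandem_simple_array():
    hits = find_tandem_repeats("ACACACACACAC")
    assert len(hits) == 1
    t = hits[0]
    assert (t.period, t.copies, t.total_length) == (2, 6.0, 12)
    assert t.consensus == "AC"


def test_tandem_below_threshold_not_reported():
    assert find_tandem_repeats("ACGACGACG") == []


def test_tandem_planted_arrays_recovered(rng):
    for k in range(5):
        spec = SyntheticSpec(
            seed=int(rng.integers(2**31)), genome_length=25_000,
            tandem_plan=(TandemPlan(7, 5), TandemPlan(4, 4)),
        )
        ann, truth = generate_mitogenome(spec)
        found = find_tandem_repeats(ann.genome)
        for rec in truth.tandem_records:
            a, b = rec["interval"]
            match = [
                t for t in found
                if t.interval.start == a and t.interval.end == b
            ]
            assert match, f"planted array {rec} not recovered"
            assert match[0].period == rec["period"]
            assert match[0].copies == pytest.approx(rec["copies"], abs=0.05)


def test_tandem_overlap_reduced_to_single_period():
    # a period-3 array is also periodic at 6; only one call survives
    hits = find_tandem_repeats("TAGTAGTAGTAGTAGTAG")
    assert len(hits) == 1
    assert hits[0].period == 3


# ---------------------------------------------------------------------------
# transfer fragments


def test_identical_sequences_full_length_fragment():
    s = random_dna(np.random.default_rng(9), 500, 0.4)
    frags = find_transfer_fragments(s, s, evalue_max=1e-3)
    assert frags[0].length == 500
    assert frags[0].identity == 100.0


def test_unrelated_sequences_no_fragments(rng):
    a = random_dna(rng, 2000, 0.3)
    b = random_dna(rng, 2000, 0.5)
    assert find_transfer_fragments(a, b, evalue_max=1e-10) == []


def test_planted_transfer_fragments_recovered():
    spec = SyntheticSpec(
        seed=21, genome_length=30_000,
        transfer_plan=TransferPlan(n_fragments=3, length_range=(300, 500),
                                   identity=95.0, nuclear_length=40_000),
    )
    ann, _ = generate_mitogenome(spec)
    nuc, truth = generate_nuclear_with_transfer(ann, spec)
    frags = find_transfer_fragments(ann.genome, nuc, evalue_max=1e-10,
                                    annotation=ann)
    planted = {tuple(r["nuclear_interval"]) for r in truth.transfer_records}
    # every planted fragment is hit by a detection covering >= 80% of it
    for (a, b) in planted:
        cover = [
            f for f in frags
            if f.nuclear_interval.start <= b and f.nuclear_interval.end >= a
            and min(b, f.nuclear_interval.end) - max(a, f.nuclear_interval.start)
            >= 0.8 * (b - a)
        ]
        assert cover, f"planted fragment {(a, b)} not recovered"
        assert 90.0 <= cover[0].identity <= 99.0


def test_transfer_fragment_reports_overlapped_features():
    spec = SyntheticSpec(
        seed=33, genome_length=30_000,
        transfer_plan=TransferPlan(n_fragments=0),
    )
    ann, _ = generate_mitogenome(spec)
    # build a nuclear sequence containing an exact copy of the cox1 start
    cox1 = ann.gene("cox1")
    exon = cox1.exons[0]
    rng = np.random.default_rng(4)
    segment = ann.genome.slice(Interval(exon.start, exon.start + 299, "+"))
    nuclear = random_dna(rng, 5000, 0.5) + segment + random_dna(rng, 5000, 0.5)
    frags = find_transfer_fragments(ann.genome, nuclear, annotation=ann)
    assert any("cox1" in f.overlapped_mito_features for f in frags)


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        find_transfer_fragments("", "ACGT")


# ---------------------------------------------------------------------------
# coverage


def _hit(a0, a1, b0, b1):
    return RepeatHit(Interval(a0, a1), Interval(b0, b1), "forward",
                     a1 - a0 + 1, 100.0, float(a1 - a0 + 1), 0.0)


def test_coverage_disjoint_pairs():
    hits = [_hit(1, 100, 1001, 1100), _hit(2001, 2100, 3001, 3100)]
    bp, pct = repeat_coverage(hits, 10_000)
    assert (bp, pct) == (400, pytest.approx(4.00))


def test_coverage_union_no_double_counting(rng):
    """Coverage equals an independent position-set union for random hits."""
    L = 5000
    hits = []
    truth = set()
    for _ in range(30):
        a = int(rng.integers(1, L - 200))
        b = int(rng.integers(1, L - 200))
        length = int(rng.integers(20, 200))
        hits.append(_hit(a, a + length - 1, b, b + length - 1))
        truth |= set(range(a, a + length)) | set(range(b, b + length))
    bp, pct = repeat_coverage(hits, L)
    assert bp == len(truth)
    assert bp <= L
    assert pct == pytest.approx(100.0 * len(truth) / L)
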