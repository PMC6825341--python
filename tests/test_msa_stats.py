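import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contactfold.msa_stats import (AlignedSequenceSet, AlignmentParseError,
                                   EmptyAlignmentError, RaggedAlignmentError,
                                   effective_count, filter_gap_rows,
                                   filter_redundancy, identity_matrix,
                                   mean_sequences_per_run, nff,
                                   pairwise_identity, read_alignment,
                                   triage_family, write_fasta)

from conftest import random_msa


def nf_bruteforce(msa, threshold=0.8):
    """Independent double-loop evaluation of the effective count."""
    seqs = msa.sequences()
    total = 0.0
    for i in range(len(seqs)):
        neighbours = sum(
            1 for j in range(len(seqs))
            if j != i and pairwise_identity(seqs[i], seqs[j]) >= threshold)
        total += 1.0 / (1.0 + neighbours)
    return total / math.sqrt(msa.L)


# -- reading --------------------------------------------------------------


def test_read_fasta(tmp_path):
    p = tmp_path / "aln.fasta"
    p.write_text(">a\nACDEFGHIKL\n>b\nACDEFGHIK-\n>c\nAC-EFGHIKL\n")
    msa = read_alignment(p, "fasta")
    assert msa.n_seq == 3
    assert msa.L == 10
    assert msa.query_id == "a"


def test_read_a3m_drops_insertions(tmp_path):
    p = tmp_path / "aln.a3m"
    p.write_text(">q\nACDFG\n>h\nACDeFG\n")
    msa = read_alignment(p, "a3m")
    assert dict(msa.rows)["h"] == "ACDFG"


def test_read_stockholm(tmp_path):
    p = tmp_path / "aln.sto"
    p.write_text(
        "# STOCKHOLM 1.0\n"
        "seqA ACDEF\n"
        "seqB AC.EF\n"
        "//\n")
    msa = read_alignment(p, "stockholm")
    assert msa.n_seq == 2
    assert dict(msa.rows)["seqB"] == "AC-EF"


def test_read_ragged_raises(tmp_path):
    p = tmp_path / "bad.fasta"
    p.write_text(">a\nACDEFGHIKL\n>b\nACDEFGHIK\n")
    with pytest.raises(RaggedAlignmentError):
        read_alignment(p, "fasta")


def test_read_empty_raises(tmp_path):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    with pytest.raises(AlignmentParseError):
        read_alignment(p, "fasta")


def test_read_missing_file_raises(tmp_path):
    with pytest.raises(AlignmentParseError):
        read_alignment(tmp_path / "nope.fasta", "fasta")


def test_write_fasta_roundtrip(tmp_path, rng):
    msa = random_msa(rng, 5, 30)
    p = tmp_path / "out.fasta"
    write_fasta(msa, p)
    again = read_alignment(p, "fasta")
    assert again.rows == msa.rows


# -- pairwise identity ----------------------------------------------------


def test_identity_exact():
    assert pairwise_identity("ACDE", "ACDE") == 1.0


def test_identity_gap_columns_excluded():
    assert pairwise_identity("AC-E", "ACDE") == 1.0


def test_identity_hand_count():
    assert pairwise_identity("ACDE", "ACDF") == 0.75


def test_identity_no_overlap_is_zero():
    assert pairwise_identity("A--", "-CC") == 0.0


def test_identity_length_mismatch():
    with pytest.raises(ValueError):
        pairwise_identity("ACD", "AC")


def test_identity_matrix_matches_scalar(rng):
    msa = random_msa(rng, 8, 40)
    S = identity_matrix(msa).S
    seqs = msa.sequences()
    for i in range(8):
        for j in range(8):
            expected = 1.0 if i == j else pairwise_identity(seqs[i], seqs[j])
            assert S[i, j] == pytest.approx(expected, abs=1e-12)


# -- effective count ------------------------------------------------------


def test_nf_identical_sequences():
    rows = tuple((f"s{k}", "A" * 100) for k in range(4))
    msa = AlignedSequenceSet("s0", rows)
    assert effective_count(msa).nf == pytest.approx(0.1)


def test_nf_all_dissimilar():
    seqs = ["ACDEFGHIKLMNPQRSTVWYACDEF",
            "CDEFGHIKLMNPQRSTVWYACDEFA",
            "DEFGHIKLMNPQRSTVWYACDEFAC",
            "EFGHIKLMNPQRSTVWYACDEFACD",
            "FGHIKLMNPQRSTVWYACDEFACDE"]
    msa = AlignedSequenceSet(
        "s0", tuple((f"s{k}", s) for k, s in enumerate(seqs)))
    assert effective_count(msa).nf == pytest.approx(1.0)


def test_nf_matches_bruteforce(rng):
    for _ in range(5):
        msa = random_msa(rng, 20, 60)
        assert effective_count(msa).nf == pytest.approx(
            nf_bruteforce(msa), abs=1e-9)


def test_nf_identical_copies_floor():
    for n in (1, 3, 9):
        rows = tuple((f"s{k}", "ACDEFGHIKLMNPQRS") for k in range(n))
        msa = AlignedSequenceSet("s0", rows)
        assert effective_count(msa).nf == pytest.approx(1 / math.sqrt(16))


@settings(max_examples=20, deadline=None)
@given(st.randoms(use_true_random=False))
def test_nf_row_permutation_invariant(pyrandom):
    rng = np.random.default_rng(pyrandom.randrange(2 ** 31))
    msa = random_msa(rng, 10, 30)
    nf0 = effective_count(msa).nf
    order = list(range(10))
    pyrandom.shuffle(order)
    rows = tuple(msa.rows[k] for k in order)
    query = msa.rows[0][0]
    permuted = AlignedSequenceSet(query, rows)
    assert effective_count(permuted).nf == pytest.approx(nf0, abs=1e-12)


def test_nf_invariant_under_renaming(rng):
    msa = random_msa(rng, 6, 25)
    renamed = AlignedSequenceSet(
        "x0", tuple((f"x{k}", seq) for k, (_, seq) in enumerate(msa.rows)))
    assert effective_count(renamed).nf == pytest.approx(
        effective_count(msa).nf)


# -- Nff and triage -------------------------------------------------------


def test_nff_examples():
    assert nff(100, 40).nff == pytest.approx(0.6)
    assert nff(64, 64).nff == 0.0
    assert nff(158, 30).nff == pytest.approx(0.8101, abs=5e-5)


def test_nff_rejects_nonpositive_combined():
    with pytest.raises(ValueError):
        nff(0.0, 1.0)


def test_triage_examples():
    assert triage_family(158, 30) == "modelable_metagenome_driven"
    assert triage_family(100, 90) == "modelable_base_driven"
    assert triage_family(50, 10) == "not_modelable"


def test_triage_boundary_is_strict():
    assert triage_family(64, 0) == "not_modelable"


def test_triage_monotone_in_combined_depth(rng):
    for _ in range(50):
        base = float(rng.uniform(0, 100))
        lo = float(rng.uniform(base, 200))
        hi = lo + float(rng.uniform(0, 100))
        order = {"not_modelable": 0, "modelable_base_driven": 1,
                 "modelable_metagenome_driven": 1}
        assert order[triage_family(hi, base)] >= order[
            triage_family(lo, base)]


# -- filters --------------------------------------------------------------


def _msa(rows):
    return AlignedSequenceSet(rows[0][0], tuple(rows))


def test_filter_gap_rows_examples():
    msa = _msa([("q", "ACDEFGHIKL"),
                ("g8", "AC--------"),
                ("g7", "ACD-------")])
    out = filter_gap_rows(msa)
    names = [n for n, _ in out.rows]
    assert "g8" not in names       # 8/10 gaps >= 0.75
    assert "g7" in names           # 7/10 gaps < 0.75


def test_filter_gap_rows_keeps_query():
    msa = _msa([("q", "ACDEFGHIKL"), ("g", "-" * 10)])
    out = filter_gap_rows(msa, max_gap_fraction=0.5)
    assert [n for n, _ in out.rows] == ["q"]


def test_filter_redundancy_drops_duplicates():
    msa = _msa([("q", "ACDEFGHIKL"),
                ("a", "ACDEFGHWYM"),
                ("b", "ACDEFGHWYM")])
    out = filter_redundancy(msa)
    assert [n for n, _ in out.rows] == ["q", "a"]


def test_filter_redundancy_coverage():
    msa = _msa([("q", "ACDEFGHIKL"),
                ("half", "ACDEF-----")])
    out = filter_redundancy(msa, min_coverage=0.75)
    assert [n for n, _ in out.rows] == ["q"]


def _redundancy_oracle(msa, max_identity=0.90, min_coverage=0.75):
    """Independent quadratic scan with the same greedy contract."""
    from contactfold.msa_stats import row_coverage
    qidx = next(k for k, (n, _) in enumerate(msa.rows)
                if n == msa.query_id)
    kept = [qidx]
    for k, (name, seq) in enumerate(msa.rows):
        if k == qidx:
            continue
        if row_coverage(msa, seq) < min_coverage:
            continue
        ok = True
        for j in kept:
            if pairwise_identity(seq, msa.rows[j][1]) >= max_identity:
                ok = False
                break
        if ok:
            kept.append(k)
    return [msa.rows[k] for k in sorted(kept)]


def test_filter_redundancy_matches_oracle(rng):
    for _ in range(10):
        # low-diversity alphabet makes redundant rows likely
        rows = []
        for k in range(10):
            rows.append((f"s{k}", "".join(
                "-" if rng.random() < 0.1 else "AC"[rng.integers(2)]
                for _ in range(20))))
        rows[0] = ("s0", "A" * 20)
        msa = _msa(rows)
        out = filter_redundancy(msa)
        assert list(out.rows) == _redundancy_oracle(msa)


def test_filters_idempotent(rng):
    msa = random_msa(rng, 12, 30, gap_prob=0.4)
    once = filter_gap_rows(msa)
    assert filter_gap_rows(once).rows == once.rows
    once = filter_redundancy(msa)
    assert filter_redundancy(once).rows == once.rows


# -- misc -----------------------------------------------------------------


def test_mean_sequences_per_run():
    assert mean_sequences_per_run(1000, 10) == 100
    assert mean_sequences_per_run(5, 2) == 2  # round(2.5) banker's -> 2
    with pytest.raises(ValueError):
        mean_sequences_per_run(10, 0)


def test_invalid_alignment_set():
    with pytest.raises(EmptyAlignmentError):
        AlignedSequenceSet("q", ())
    with pytest.raises(RaggedAlignmentError):
        AlignedSequenceSet("q", (("q", "ACD"), ("b", "AC")))
    with pytest.raises(AlignmentParseError):
        AlignedSequenceSet("missing", (("q", "ACD"),))
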