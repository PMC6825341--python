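"""Multiple sequence alignment parsing, filtering, and depth statistics.

Implements the effective sequence count

    Nf = (1/sqrt(L)) * sum_i 1 / [1 + sum_{j != i} I(S_ij >= 0.8)]

where ``L`` is the query length in match columns, ``S_ij`` the pairwise
sequence identity computed over columns where both rows are non-gap, and
``I`` the Iverson bracket. Also provides the augmentation fraction
``Nff = (Nf_combined - Nf_base) / Nf_combined`` and the family triage rule
(modelable when Nf exceeds a depth cutoff, metagenome-driven when more than
half of the effective depth comes from the augmenting database).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import AlignIO

GAP_CHARS = frozenset("-.")

DEFAULT_IDENTITY_THRESHOLD = 0.8
DEFAULT_NF_CUTOFF = 64.0
DEFAULT_NFF_CUTOFF = 0.5
DEFAULT_MAX_GAP_FRACTION = 0.75
DEFAULT_MAX_IDENTITY = 0.90
DEFAULT_MIN_COVERAGE = 0.75

TriageLabel = Literal[
    "modelable_metagenome_driven", "modelable_base_driven", "not_modelable"]


class AlignmentParseError(ValueError):
    """Base class for alignment reading failures."""


class RaggedAlignmentError(AlignmentParseError):
    """Rows of the alignment have unequal lengths."""


class EmptyAlignmentError(AlignmentParseError):
    """The alignment contains no sequences."""


@dataclass(frozen=True)
class AlignedSequenceSet:
    """An MSA with a designated query row.

    ``rows`` are ``(identifier, aligned string)`` pairs over the amino-acid
    alphabet plus ``-`` gaps; all strings share one length. ``L`` is the
    query length counted in match (non-gap) columns.
    """

    query_id: str
    rows: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not self.rows:
            raise EmptyAlignmentError("alignment has no rows")
        width = len(self.rows[0][1])
        for name, seq in self.rows:
            if len(seq) != width:
                raise RaggedAlignmentError(
                    f"row {name!r} has length {len(seq)}, expected {width}")
        if self.query_id not in {name for name, _ in self.rows}:
            raise AlignmentParseError(
                f"query {self.query_id!r} not present in alignment")
        if self.L < 1:
            raise AlignmentParseError("query has no match columns")

    @property
    def n_seq(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def query(self) -> str:
        for name, seq in self.rows:
            if name == self.query_id:
                return seq
        raise AssertionError("unreachable: query checked in __post_init__")

    @property
    def L(self) -> int:
        return sum(1 for c in self.query if c not in GAP_CHARS)

    def sequences(self) -> list[str]:
        return [seq for _, seq in self.rows]

    def replace_rows(self, rows: Iterable[tuple[str, str]]) -> "AlignedSequenceSet":
        return AlignedSequenceSet(self.query_id, tuple(rows))


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric pairwise identity matrix with unit diagonal."""

    S: np.ndarray

    def __post_init__(self):
        S = self.S
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("identity matrix must be square")
        if not np.allclose(S, S.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(S), 1.0):
            raise ValueError("identity matrix diagonal must be 1")
        if S.min() < -1e-12 or S.max() > 1 + 1e-12:
            raise ValueError("identities must lie in [0, 1]")


@dataclass(frozen=True)
class EffectiveCount:
    nf: float
    identity_threshold: float
    n_seq: int
    L: int

    def __post_init__(self):
        lo = 1.0 / np.sqrt(self.L) - 1e-9
        hi = self.n_seq / np.sqrt(self.L) + 1e-9
        if not (lo <= self.nf <= hi):
            raise ValueError(
                f"nf={self.nf} outside [1/sqrt(L), n_seq/sqrt(L)]")


@dataclass(frozen=True)
class NfFraction:
    nf_combined: float
    nf_base: float
    nff: float


def _normalize(seq: str) -> str:
    return "".join("-" if c in GAP_CHARS else c.upper() for c in seq)


def _read_a3m(path: Path) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                continue
            if line.startswith(">"):
                if name is not None:
                    rows.append((name, "".join(chunks)))
                name = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            elif line.strip():
                if name is None:
                    raise AlignmentParseError(
                        "a3m sequence data before first header")
                # lowercase letters are insertion states relative to the
                # query; drop them to recover the match-column alignment
                chunks.append("".join(
                    c for c in line.strip() if not c.islower()))
    if name is not None:
        rows.append((name, "".join(chunks)))
    return rows


def read_alignment(path, fmt: str = "fasta",
                   query_id: str | None = None) -> AlignedSequenceSet:
    """Read an MSA in FASTA, Stockholm, or A3M format.

    The query defaults to the first row. A3M lowercase insertion states are
    removed so every row spans the query match columns.
    """
    path = Path(path)
    if not path.exists():
        raise AlignmentParseError(f"no such file: {path}")
    if fmt not in {"fasta", "stockholm", "a3m"}:
        raise ValueError(f"unknown alignment format {fmt!r}")
    if fmt == "a3m":
        raw = _read_a3m(path)
    else:
        try:
            aln = AlignIO.read(str(path), fmt)
            raw = [(rec.id, str(rec.seq)) for rec in aln]
        except ValueError as exc:
            msg = str(exc).lower()
            if "same length" in msg or "length" in msg and "differ" in msg:
                raise RaggedAlignmentError(str(exc)) from exc
            if "no records" in msg or "empty" in msg:
                raise EmptyAlignmentError(str(exc)) from exc
            raise AlignmentParseError(str(exc)) from exc
    if not raw:
        raise EmptyAlignmentError(f"{path} contains no sequences")
    rows = tuple((name, _normalize(seq)) for name, seq in raw)
    widths = {len(seq) for _, seq in rows}
    if len(widths) > 1:
        raise RaggedAlignmentError(
            f"{path}: rows have differing lengths {sorted(widths)}")
    return AlignedSequenceSet(query_id or rows[0][0], rows)


def write_fasta(msa: AlignedSequenceSet, path) -> None:
    with open(path, "w") as fh:
        for name, seq in msa.rows:
            fh.write(f">{name}\n{seq}\n")


def pairwise_identity(a: str, b: str) -> float:
    """Sequence identity over columns where both rows are non-gap.

    Returns 0 when the two rows share no co-aligned column.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned length mismatch: {len(a)} vs {len(b)}")
    matches = 0
    co_aligned = 0
    for x, y in zip(a, b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        co_aligned += 1
        if x == y:
            matches += 1
    return matches / co_aligned if co_aligned else 0.0


def _char_matrix(msa: AlignedSequenceSet) -> np.ndarray:
    return np.array([list(seq) for seq in msa.sequences()], dtype="U1")


def identity_matrix(msa: AlignedSequenceSet) -> IdentityMatrix:
    """Vectorised all-against-all identity with the same column convention
    as :func:`pairwise_identity`."""
    arr = _char_matrix(msa)
    non_gap = arr != "-"
    both = non_gap[:, None, :] & non_gap[None, :, :]
    eq = arr[:, None, :] == arr[None, :, :]
    matches = (eq & both).sum(axis=-1)
    co = both.sum(axis=-1)
    with np.errstate(invalid="ignore"):
        S = np.where(co > 0, matches / np.maximum(co, 1), 0.0)
    np.fill_diagonal(S, 1.0)
    return IdentityMatrix(S)


def effective_count(msa: AlignedSequenceSet,
                    threshold: float = DEFAULT_IDENTITY_THRESHOLD
                    ) -> EffectiveCount:
    """Number of effective sequences of the alignment.

    Each row is down-weighted by one plus its number of neighbours at
    identity >= ``threshold``; the weighted sum is scaled by 1/sqrt(L).
    """
    if not (0 < threshold <= 1):
        raise ValueError("identity threshold must be in (0, 1]")
    S = identity_matrix(msa).S
    neighbours = (S >= threshold).sum(axis=1) - 1  # diagonal is always 1
    weights = 1.0 / (1.0 + neighbours)
    nf = float(weights.sum() / np.sqrt(msa.L))
    return EffectiveCount(nf=nf, identity_threshold=threshold,
                          n_seq=msa.n_seq, L=msa.L)


def nff(nf_combined: float, nf_base: float) -> NfFraction:
    """Fraction of the combined effective depth contributed by augmentation."""
    if nf_combined <= 0:
        raise ValueError("nf_combined must be positive")
    if nf_base < 0:
        raise ValueError("nf_base must be non-negative")
    return NfFraction(nf_combined=nf_combined, nf_base=nf_base,
                      nff=(nf_combined - nf_base) / nf_combined)


def gap_fraction(seq: str) -> float:
    return sum(1 for c in seq if c in GAP_CHARS) / len(seq)


def filter_gap_rows(msa: AlignedSequenceSet,
                    max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION
                    ) -> AlignedSequenceSet:
    """Drop rows whose gap fraction reaches the cutoff; the query is kept."""
    kept = [(name, seq) for name, seq in msa.rows
            if name == msa.query_id or gap_fraction(seq) < max_gap_fraction]
    return msa.replace_rows(kept)


def row_coverage(msa: AlignedSequenceSet, seq: str) -> float:
    """Fraction of query match columns at which the row is non-gap."""
    query = msa.query
    covered = 0
    total = 0
    for qc, rc in zip(query, seq):
        if qc in GAP_CHARS:
            continue
        total += 1
        if rc not in GAP_CHARS:
            covered += 1
    return covered / total if total else 0.0


def filter_redundancy(msa: AlignedSequenceSet,
                      max_identity: float = DEFAULT_MAX_IDENTITY,
                      min_coverage: float = DEFAULT_MIN_COVERAGE
                      ) -> AlignedSequenceSet:
    """Coverage filter followed by greedy identity-based deduplication.

    Rows covering fewer than ``min_coverage`` of the query match columns are
    dropped. Remaining rows are scanned in input order (query first); a row
    is rejected when its identity to any already-kept row reaches
    ``max_identity``.
    """
    query_idx = next(k for k, (name, _) in enumerate(msa.rows)
                     if name == msa.query_id)
    kept_idx: list[int] = [query_idx]
    for k, (name, seq) in enumerate(msa.rows):
        if k == query_idx:
            continue
        if row_coverage(msa, seq) < min_coverage:
            continue
        if all(pairwise_identity(seq, msa.rows[j][1]) < max_identity
               for j in kept_idx):
            kept_idx.append(k)
    rows = [msa.rows[k] for k in sorted(kept_idx)]
    return msa.replace_rows(rows)


def triage_family(nf_combined: float, nf_base: float,
                  nf_cutoff: float = DEFAULT_NF_CUTOFF,
                  nff_cutoff: float = DEFAULT_NFF_CUTOFF) -> TriageLabel:
    """Classify a family by alignment depth and augmentation contribution."""
    if nf_combined < 0 or nf_base < 0:
        raise ValueError("effective counts must be non-negative")
    if nf_combined <= nf_cutoff:
        return "not_modelable"
    fraction = nff(nf_combined, nf_base).nff
    if fraction > nff_cutoff:
        return "modelable_metagenome_driven"
    return "modelable_base_driven"


def mean_sequences_per_run(total_sequences: int, n_runs: int) -> int:
    """Mean number of family-assigned sequences per sequencing run,
    rounded to the nearest integer."""
    if n_runs <= 0:
        raise ValueError("n_runs must be positive")
    if total_sequences < 0:
        raise ValueError("total_sequences must be non-negative")
    return int(round(total_sequences / n_runs))
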