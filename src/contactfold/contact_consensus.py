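"""Ranked contact-prediction parsing and consensus selection.

Predictors are grouped into four accuracy tiers; the consensus contact set
unions the top L, L/2, L/4.5, and L/7.5 pairs of the very-high, high,
medium, and low tiers respectively. The per-pair restraint weight U_ij is
the mean confidence over the truncated lists that report the pair.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

Category = Literal["very_high", "high", "medium", "low"]
SeparationClass = Literal["short", "medium", "long"]

CATEGORIES: tuple[Category, ...] = ("very_high", "high", "medium", "low")

#: divisor of L applied to each tier's ranked list
DEFAULT_CATEGORY_DIVISORS: dict[str, float] = {
    "very_high": 1.0,
    "high": 2.0,
    "medium": 4.5,
    "low": 7.5,
}

#: default tier membership of the supported external predictors
DEFAULT_PREDICTOR_CATEGORIES: dict[str, Category] = {
    "nebcon": "very_high",
    "respre": "very_high",
    "deepplm": "very_high",
    "deepcov": "high",
    "deepcontact": "high",
    "dncon2": "high",
    "metapsicov2": "medium",
    "gremlin": "low",
    "ccmpred": "low",
    "freecontact": "low",
}

#: residue-separation class boundaries; long-range is fixed at > 24
SHORT_MAX_SEPARATION = 11
MEDIUM_MAX_SEPARATION = 24


class ContactParseError(ValueError):
    """A contact list file could not be parsed."""


@dataclass(frozen=True)
class Contact:
    i: int
    j: int
    u: float
    separation_class: SeparationClass

    @property
    def separation(self) -> int:
        return self.j - self.i


@dataclass(frozen=True)
class PredictorOutput:
    """Ranked (i, j, confidence) pairs from one predictor."""

    predictor_name: str
    category: Category
    pairs: tuple[tuple[int, int, float], ...]

    def __post_init__(self):
        prev = math.inf
        for i, j, conf in self.pairs:
            if not (1 <= i < j):
                raise ValueError(f"pair ({i}, {j}) not normalized to 1 <= i < j")
            if conf > prev + 1e-12:
                raise ValueError("confidences must be non-increasing")
            prev = conf

    def truncated(self, n: int) -> "PredictorOutput":
        return replace(self, pairs=self.pairs[:n])


@dataclass(frozen=True)
class CategoryScheme:
    """Tier truncation rules, with independent branches on alignment depth.

    Both branches default to the same divisor list; they are exposed
    separately so an asymmetric scheme can be configured.
    """

    low_nf_divisors: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_DIVISORS))
    high_nf_divisors: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_DIVISORS))
    nf_switch: float = 50.0

    def __post_init__(self):
        for divisors in (self.low_nf_divisors, self.high_nf_divisors):
            for cat, div in divisors.items():
                if div <= 0:
                    raise ValueError(f"divisor for {cat!r} must be positive")

    def divisors_for(self, nf: float) -> dict[str, float]:
        return (self.low_nf_divisors if nf < self.nf_switch
                else self.high_nf_divisors)


@dataclass(frozen=True)
class ConsensusContactSet:
    """Unique residue pairs with positive restraint weights."""

    contacts: tuple[Contact, ...]
    L: int

    def __post_init__(self):
        seen = set()
        for c in self.contacts:
            if not (1 <= c.i < c.j <= self.L):
                raise ValueError(f"bad contact indices ({c.i}, {c.j})")
            if c.u <= 0:
                raise ValueError("restraint weights must be positive")
            if (c.i, c.j) in seen:
                raise ValueError(f"duplicate contact ({c.i}, {c.j})")
            seen.add((c.i, c.j))

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self):
        return iter(self.contacts)


def separation_class(i: int, j: int) -> SeparationClass:
    sep = abs(j - i)
    if sep <= SHORT_MAX_SEPARATION:
        return "short"
    if sep <= MEDIUM_MAX_SEPARATION:
        return "medium"
    return "long"


_RR_HEADER_TOKENS = {"PFRMAT", "TARGET", "AUTHOR", "METHOD", "MODEL",
                     "REMARK", "END"}


def read_rr(path, L: int, predictor_name: str | None = None,
            category: Category | None = None) -> PredictorOutput:
    """Read a CASP-RR-style contact list: lines of ``i j d1 d2 confidence``
    (a bare ``i j confidence`` is also accepted).

    Pairs are normalized to i < j and sorted by confidence descending with
    ties broken by (i, j) ascending. Duplicate pairs keep their highest
    confidence.
    """
    path = Path(path)
    if not path.exists():
        raise ContactParseError(f"no such file: {path}")
    name = predictor_name or path.stem
    if category is None:
        category = DEFAULT_PREDICTOR_CATEGORIES.get(name.lower())
        if category is None:
            raise ContactParseError(
                f"unknown predictor {name!r}: an explicit category is required")
    best: dict[tuple[int, int], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens:
                continue
            if tokens[0].upper() in _RR_HEADER_TOKENS:
                continue
            if len(tokens) == 1 and tokens[0].isalpha():
                continue  # sequence line of the RR dialect
            if len(tokens) not in (3, 5):
                raise ContactParseError(
                    f"{path}:{lineno}: expected 'i j [d1 d2] conf', "
                    f"got {line.strip()!r}")
            try:
                i, j = int(tokens[0]), int(tokens[1])
                conf = float(tokens[-1])
            except ValueError as exc:
                raise ContactParseError(
                    f"{path}:{lineno}: malformed contact line "
                    f"{line.strip()!r}") from exc
            if i > j:
                i, j = j, i
            if not (1 <= i <= L and 1 <= j <= L):
                raise ContactParseError(
                    f"{path}:{lineno}: residue index out of range "
                    f"for L={L}: ({i}, {j})")
            if i == j:
                raise ContactParseError(
                    f"{path}:{lineno}: self-contact ({i}, {j})")
            key = (i, j)
            if key not in best or conf > best[key]:
                best[key] = conf
    ranked = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
    pairs = tuple((i, j, conf) for (i, j), conf in ranked)
    return PredictorOutput(name, category, pairs)


def write_rr(cs: ConsensusContactSet, path, sequence: str | None = None) -> None:
    """Write contacts as RR lines with U_ij in the confidence column."""
    with open(path, "w") as fh:
        fh.write("PFRMAT RR\n")
        if sequence:
            fh.write(sequence + "\n")
        for c in cs.contacts:
            fh.write(f"{c.i} {c.j} 0 8 {c.u:.6f}\n")
        fh.write("END\n")


def top_count(category: Category, L: int,
              divisors: dict[str, float] | None = None) -> int:
    """Tier-dependent truncation length: round-half-up of L / divisor,
    floored at 1."""
    if L < 1:
        raise ValueError("L must be positive")
    divisors = divisors or DEFAULT_CATEGORY_DIVISORS
    if category not in divisors:
        raise ValueError(f"unknown category {category!r}")
    return max(1, math.floor(L / divisors[category] + 0.5))


def build_consensus(outputs: Sequence[PredictorOutput], L: int, nf: float,
                    scheme: CategoryScheme | None = None
                    ) -> ConsensusContactSet:
    """Union of tier-truncated predictor lists with mean-confidence weights.

    Output is ordered by U_ij descending, ties by (i, j) ascending.
    """
    if not outputs:
        raise ValueError("at least one predictor output is required")
    scheme = scheme or CategoryScheme()
    divisors = scheme.divisors_for(nf)
    confidences: dict[tuple[int, int], list[float]] = {}
    for out in outputs:
        n = top_count(out.category, L, divisors)
        for i, j, conf in out.pairs[:n]:
            if j > L:
                raise ValueError(
                    f"contact ({i}, {j}) exceeds sequence length {L}")
            confidences.setdefault((i, j), []).append(conf)
    contacts = [
        Contact(i=i, j=j, u=sum(confs) / len(confs),
                separation_class=separation_class(i, j))
        for (i, j), confs in confidences.items()
    ]
    contacts.sort(key=lambda c: (-c.u, c.i, c.j))
    return ConsensusContactSet(tuple(contacts), L)


def long_range_subset(cs: ConsensusContactSet, top: int,
                      min_separation: int = MEDIUM_MAX_SEPARATION
                      ) -> ConsensusContactSet:
    """Contacts with |i - j| > ``min_separation`` truncated to ``top`` by
    descending weight."""
    if top < 0:
        raise ValueError("top must be non-negative")
    lr = [c for c in cs.contacts if c.separation > min_separation]
    lr.sort(key=lambda c: (-c.u, c.i, c.j))
    return ConsensusContactSet(tuple(lr[:top]), cs.L)


def read_consensus_rr(path, L: int) -> ConsensusContactSet:
    """Read an RR file written by :func:`write_rr` back as a consensus set."""
    out = read_rr(path, L, predictor_name="consensus", category="very_high")
    contacts = tuple(
        Contact(i=i, j=j, u=conf, separation_class=separation_class(i, j))
        for i, j, conf in out.pairs)
    return ConsensusContactSet(contacts, L)
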