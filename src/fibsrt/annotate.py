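"""Hierarchical point classification and string-level structure of Fib strings.

Two independent routes identify the structurally salient *k-points* of a
Fibonacci-grammar string:

* **hierarchical** (:func:`classify_points`): a k-point is a 1 immediately
  dominated by a 0 in the derivation tree and immediately dominating the
  constituent [0 1]; an n-point is a 1 whose parent is a k-point; an s-point
  is a 1 whose parent is an n- or s-point.
* **string-level** (:func:`k_positions_by_segmentation`): greedily chunk the
  string left-to-right into [01] bigrams; the stranded 1s that cannot start
  a chunk are the k-points.

On Fibonacci strings the two definitions coincide position-for-position.  On
Skip strings the hierarchical route returns nothing (a 1 there dominates the
five-symbol block 01101, never [01]) while segmentation still strands 1s —
the structural dissociation the experiment is built on.

The surface side is captured by the Three Laws (0 is always followed by 1;
11 is always followed by 0; a single 1 is ambiguous), the {3, 5} metric over
consecutive k-points with its succession rules, and an effective procedure
that reconstructs a full string from its k-skeleton alone.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .grammar import Derivation, AlphabetError

__all__ = [
    "PointClass",
    "PointAnnotation",
    "KSkeleton",
    "LawReport",
    "LawViolationError",
    "InvalidSkeletonError",
    "AmbiguousSuffixError",
    "classify_points",
    "k_positions_by_segmentation",
    "skeleton_of",
    "k_gap_sequence",
    "validate_gap_succession",
    "validate_three_laws",
    "reconstruct_from_skeleton",
    "format_skeleton",
    "parse_skeleton",
]


class PointClass(str, enum.Enum):
    K = "k"
    N = "n"
    S = "s"
    PLAIN_ONE = "plain_one"
    ZERO = "zero"


@dataclass(frozen=True)
class PointAnnotation:
    """Structural class of one symbol occurrence."""

    gen: int
    pos: int  # 1-based
    symbol: str
    point_class: PointClass


@dataclass(frozen=True)
class KSkeleton:
    """A string abstracted to its length and its 1-based k-point positions."""

    length: int
    k_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("length must be >= 0")
        ks = tuple(self.k_positions)
        object.__setattr__(self, "k_positions", ks)
        if any(not 1 <= p <= self.length for p in ks):
            raise ValueError(f"k positions {ks} outside [1, {self.length}]")
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("k positions must be strictly ascending")


@dataclass
class LawReport:
    """Result of checking a symbol string against the Three Laws.

    ``position_labels[i]`` (0-based list, one per symbol) says how much the
    left context determines the symbol at 1-based position ``i+1``:
    ``forced_one`` after a 0 (First Law), ``forced_zero`` after 11 (Second
    Law), ``ambiguous`` after a single 1 (Third Law), ``undefined`` with no
    left context.
    """

    first_law_violations: list[int] = field(default_factory=list)
    second_law_violations: list[int] = field(default_factory=list)
    position_labels: list[str] = field(default_factory=list)

    @property
    def grammatical(self) -> bool:
        return not self.first_law_violations and not self.second_law_violations


class LawViolationError(ValueError):
    """A string required to be grammatical violates the Three Laws."""

    def __init__(self, report: LawReport):
        self.report = report
        super().__init__(
            f"ungrammatical string: '00' at {report.first_law_violations}, "
            f"'111' at {report.second_law_violations}"
        )


class InvalidSkeletonError(ValueError):
    """Skeleton geometry incompatible with the Fibonacci k-point metric."""


class AmbiguousSuffixError(ValueError):
    """Trailing slots of a skeleton are not forced by any k-point."""


def classify_points(derivation: Derivation, gen: int) -> list[PointAnnotation]:
    """Classify every symbol of one generation as k / n / s / plain_one / zero.

    Classification is hierarchical, so parent classes are propagated from
    generation 1 upward.  Children of a symbol are its rule image (for the
    final generation this amounts to a one-step lookahead rewrite); the
    downward clause "immediately dominates [0 1]" is checked explicitly even
    though it is vacuous in Fib — it is precisely what empties the k-set in
    Skip.
    """
    derivation._check_gen(gen)
    if gen < 1:
        raise ValueError("classification needs parent links; use gen >= 1")
    rules = derivation.grammar.rules
    dominates_01 = rules.get("1") == "01"

    # classes for the axiom: no parents, so no 1 can be a k/n/s point
    prev = [
        PointClass.ZERO if ch == "0" else PointClass.PLAIN_ONE
        for ch in derivation.generations[0]
    ]
    for m in range(1, gen + 1):
        s = derivation.generations[m]
        parents = derivation.parent_links[m]
        parent_str = derivation.generations[m - 1]
        cur: list[PointClass] = []
        for j, ch in enumerate(s):
            if ch == "0":
                cur.append(PointClass.ZERO)
                continue
            p = parents[j]  # type: ignore[index]
            if parent_str[p] == "0" and dominates_01:
                cur.append(PointClass.K)
            elif prev[p] is PointClass.K:
                cur.append(PointClass.N)
            elif prev[p] in (PointClass.N, PointClass.S):
                cur.append(PointClass.S)
            else:
                cur.append(PointClass.PLAIN_ONE)
        prev = cur
    return [
        PointAnnotation(gen=gen, pos=j + 1, symbol=ch, point_class=cls)
        for j, (ch, cls) in enumerate(zip(derivation.generations[gen], prev))
    ]


def k_positions_by_segmentation(s: str) -> list[int]:
    """Stranded 1s under greedy left-to-right [01] chunking (1-based).

    Requires a grammatical string (no 00, no 111).  Equivalently: the second
    1 of every 11 bigram, plus position 1 when the string starts with 1.
    """
    report = validate_three_laws(s)
    if not report.grammatical:
        raise LawViolationError(report)
    stranded: list[int] = []
    i = 0
    while i < len(s):
        if s[i] == "0":
            # First Law guarantees a following 1 except at string end
            i += 2 if i + 1 < len(s) else 1
        else:
            stranded.append(i + 1)
            i += 1
    return stranded


def skeleton_of(s: str) -> KSkeleton:
    """The k-skeleton of a grammatical string."""
    return KSkeleton(length=len(s), k_positions=tuple(k_positions_by_segmentation(s)))


def k_gap_sequence(sk: KSkeleton) -> list[int]:
    """Successive position differences between consecutive k-points."""
    ks = sk.k_positions
    return [b - a for a, b in zip(ks, ks[1:])]


def validate_gap_succession(gaps: list[int]) -> list[int]:
    """Check the k-gap succession rules; return 1-based indices of offenders.

    Rules: a 3-gap is followed by a 5-gap; a 5-gap may be followed by either;
    two 5-gaps are followed by a 3-gap.  A gap at index i is flagged when it
    is a 3 right after a 3, or a 5 right after two 5s.
    """
    violations: list[int] = []
    for i in range(1, len(gaps)):
        if gaps[i - 1] == 3 and gaps[i] == 3:
            violations.append(i + 1)
        elif i >= 2 and gaps[i - 2] == 5 and gaps[i - 1] == 5 and gaps[i] == 5:
            violations.append(i + 1)
    return violations


def validate_three_laws(s: str) -> LawReport:
    """Scan a {0,1} string for 00 / 111 violations and label each position."""
    for i, ch in enumerate(s):
        if ch not in "01":
            raise AlphabetError(
                f"symbol {ch!r} at position {i + 1} is not in the alphabet {{0, 1}}"
            )
    report = LawReport()
    for i in range(len(s) - 1):
        if s[i] == "0" and s[i + 1] == "0":
            report.first_law_violations.append(i + 1)
    for i in range(len(s) - 2):
        if s[i : i + 3] == "111":
            report.second_law_violations.append(i + 1)
    labels: list[str] = []
    for i in range(len(s)):
        if i == 0:
            labels.append("undefined")
        elif s[i - 1] == "0":
            labels.append("forced_one")
        elif i >= 2 and s[i - 2] == "1":  # predecessor pair is 11
            labels.append("forced_zero")
        else:  # single 1: preceded by 0 or string start
            labels.append("ambiguous")
    report.position_labels = labels
    return report


def reconstruct_from_skeleton(sk: KSkeleton) -> str:
    """Rebuild a full string from k-point positions and inter-k distances.

    Effective procedure: each k-point is a 1 and forces 0, 1 into the two
    slots that follow it (a k is the mother of [0 1], and the First Law);
    when the next k is 5 away, the remaining two slots before it are forced
    to 0, 1 as well; a 2-slot prefix before the first k is forced to 0, 1
    by the same logic.  Any slot the procedure cannot force makes the
    skeleton invalid (gaps outside {3, 5}, a prefix other than 0 or 2
    symbols, or a suffix longer than 2 after the last k).
    """
    ks = sk.k_positions
    if sk.length == 0 and not ks:
        return ""
    if not ks:
        raise InvalidSkeletonError(
            "a non-empty skeleton without k-points is under-determined"
        )
    gaps = [b - a for a, b in zip(ks, ks[1:])]
    bad = [g for g in gaps if g not in (3, 5)]
    if bad:
        raise InvalidSkeletonError(
            f"k-gaps must be 3 or 5 symbols, got {bad} in gaps {gaps}"
        )
    prefix = ks[0] - 1
    if prefix not in (0, 2):
        raise InvalidSkeletonError(
            f"prefix before the first k must be 0 or 2 slots, got {prefix}"
        )
    suffix = sk.length - ks[-1]
    if suffix > 2:
        raise AmbiguousSuffixError(
            f"{suffix} trailing slots after the last k-point are not forced"
        )

    out = ["?"] * sk.length
    if prefix == 2:
        out[0], out[1] = "0", "1"
    for p in ks:
        out[p - 1] = "1"
        if p < sk.length:
            out[p] = "0"
        if p + 1 < sk.length:
            out[p + 1] = "1"
    for p, g in zip(ks, gaps):
        if g == 5:
            out[p + 2], out[p + 3] = "0", "1"
    assert "?" not in out
    return "".join(out)


def format_skeleton(sk: KSkeleton) -> str:
    """Render a skeleton as underscores with 1s at k-positions, e.g. ``1__1``."""
    chars = ["_"] * sk.length
    for p in sk.k_positions:
        chars[p - 1] = "1"
    return "".join(chars)


def parse_skeleton(text: str) -> KSkeleton:
    """Inverse of :func:`format_skeleton` (whitespace is ignored)."""
    compact = "".join(text.split())
    ks = tuple(i + 1 for i, ch in enumerate(compact) if ch == "1")
    bad = set(compact) - {"_", "1"}
    if bad:
        raise ValueError(f"skeleton text may contain only '_' and '1', got {bad}")
    return KSkeleton(length=len(compact), k_positions=ks)
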