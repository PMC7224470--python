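"""Deterministic context-free Lindenmayer systems with parent-link tracking.

An L-system rewrites *every* symbol of a string simultaneously at each
derivational step; there is no terminal/non-terminal split.  The two systems
of interest here are the Fibonacci grammar (0→1, 1→01), whose generation
lengths follow the Fibonacci numbers, and the Skip grammar (0→01, 1→01101),
obtained by rewriting each symbol as a non-subsequent Fibonacci generation.
Both share the same surface transition laws but differ in constituent
structure, which is what the rest of the package probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from typing import Mapping, Sequence

import yaml

__all__ = [
    "LSystemGrammar",
    "Derivation",
    "AlphabetError",
    "FIB",
    "SKIP",
    "BUILTIN_GRAMMARS",
    "rewrite_generation",
    "derive",
    "symbol_counts",
    "load_grammar",
]

#: hard cap on requested generation count; Fib g30 is ~1.3M symbols
MAX_GENERATION = 30


class AlphabetError(ValueError):
    """A symbol outside the grammar's alphabet was encountered."""


@dataclass(frozen=True)
class LSystemGrammar:
    """A deterministic context-free L-system (Σ, δ).

    Parameters
    ----------
    name : short label, e.g. ``"fib"``.
    alphabet : ordered tuple of single-character symbols.
    rules : total map symbol → non-empty replacement string.  Every alphabet
        symbol must have exactly one rule and every right-hand-side symbol
        must be in the alphabet.
    """

    name: str
    alphabet: tuple[str, ...]
    rules: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.alphabet:
            raise ValueError("alphabet must be non-empty")
        for sym in self.alphabet:
            if len(sym) != 1:
                raise ValueError(f"symbols must be single characters, got {sym!r}")
        if set(self.rules) != set(self.alphabet):
            raise ValueError(
                "rules must cover the alphabet exactly: "
                f"alphabet={set(self.alphabet)}, rules for={set(self.rules)}"
            )
        for lhs, rhs in self.rules.items():
            if not rhs:
                raise ValueError(f"empty right-hand side for {lhs!r}")
            for ch in rhs:
                if ch not in self.alphabet:
                    raise ValueError(
                        f"rule {lhs!r} -> {rhs!r} uses symbol {ch!r} "
                        "outside the alphabet"
                    )
        # freeze the mapping so the dataclass is safely hashable in spirit
        object.__setattr__(self, "rules", dict(self.rules))

    def validate_string(self, seq: str) -> None:
        """Raise :class:`AlphabetError` naming the first bad position (1-based)."""
        for i, ch in enumerate(seq):
            if ch not in self.rules:
                raise AlphabetError(
                    f"symbol {ch!r} at position {i + 1} is not in the alphabet "
                    f"of grammar {self.name!r}"
                )


FIB = LSystemGrammar("fib", ("0", "1"), {"0": "1", "1": "01"})
SKIP = LSystemGrammar("skip", ("0", "1"), {"0": "01", "1": "01101"})

BUILTIN_GRAMMARS: dict[str, LSystemGrammar] = {"fib": FIB, "skip": SKIP}


def rewrite_generation(
    grammar: LSystemGrammar, seq: str
) -> tuple[str, list[tuple[int, int]]]:
    """Apply one parallel derivational step.

    Every symbol of ``seq`` is replaced by its rule image simultaneously and
    the images are concatenated in order.

    Returns
    -------
    out : the next generation.
    spans : list of ``(start, stop)`` half-open 0-based index ranges into
        ``out``, one per input position, partitioning ``out`` in order.
    """
    grammar.validate_string(seq)
    parts: list[str] = []
    spans: list[tuple[int, int]] = []
    cursor = 0
    for ch in seq:
        image = grammar.rules[ch]
        parts.append(image)
        spans.append((cursor, cursor + len(image)))
        cursor += len(image)
    return "".join(parts), spans


@dataclass
class Derivation:
    """An eager derivation: generations ``g_0 .. g_n`` plus parent links.

    ``generations[0]`` is the axiom.  ``parent_links[m][j]`` (for m ≥ 1) is
    the 0-based position in generation ``m-1`` whose rule image produced the
    symbol at 0-based position ``j`` of generation ``m``; ``parent_links[0]``
    is ``None``.
    """

    grammar: LSystemGrammar
    generations: list[str]
    parent_links: list[list[int] | None] = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.generations) - 1

    def generation(self, gen: int) -> str:
        self._check_gen(gen)
        return self.generations[gen]

    def parent_of(self, gen: int, pos: int) -> int:
        """1-based parent position in generation ``gen - 1`` of 1-based ``pos``."""
        self._check_gen(gen)
        if gen == 0:
            raise ValueError("generation 0 (the axiom) has no parents")
        links = self.parent_links[gen]
        assert links is not None
        if not 1 <= pos <= len(links):
            raise IndexError(f"position {pos} out of range for generation {gen}")
        return links[pos - 1] + 1

    def _check_gen(self, gen: int) -> None:
        if not 0 <= gen <= self.n:
            raise IndexError(
                f"generation index {gen} out of range [0, {self.n}]"
            )


def derive(grammar: LSystemGrammar, axiom: str, n: int) -> Derivation:
    """Derive ``n`` generations from ``axiom`` (which counts as generation 0)."""
    if n < 0:
        raise ValueError(f"generation count must be >= 0, got {n}")
    if n > MAX_GENERATION:
        raise ValueError(
            f"generation count {n} exceeds the cap of {MAX_GENERATION}"
        )
    if not axiom:
        raise ValueError("axiom must be non-empty")
    grammar.validate_string(axiom)

    generations = [axiom]
    parent_links: list[list[int] | None] = [None]
    for _ in range(n):
        nxt, spans = rewrite_generation(grammar, generations[-1])
        links = [0] * len(nxt)
        for src, (start, stop) in enumerate(spans):
            for j in range(start, stop):
                links[j] = src
        generations.append(nxt)
        parent_links.append(links)
    return Derivation(grammar=grammar, generations=generations, parent_links=parent_links)


def symbol_counts(derivation: Derivation, gen: int) -> dict[str, int]:
    """Count each alphabet symbol in one generation (absent symbols count 0)."""
    s = derivation.generation(gen)
    counts = Counter(s)
    return {sym: counts.get(sym, 0) for sym in derivation.grammar.alphabet}


def load_grammar(source: str | dict) -> LSystemGrammar:
    """Load a grammar from a YAML file path, YAML text, or a parsed mapping.

    Expected keys: ``name``, ``alphabet`` (string or list of symbols) and
    ``rules`` (mapping lhs → rhs string).  A bare built-in name ("fib",
    "skip") is also accepted.
    """
    if isinstance(source, str):
        if source in BUILTIN_GRAMMARS:
            return BUILTIN_GRAMMARS[source]
        try:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        except (OSError, FileNotFoundError):
            data = yaml.safe_load(source)
    else:
        data = source
    if not isinstance(data, dict):
        raise ValueError(f"cannot interpret grammar definition from {source!r}")
    alphabet = data["alphabet"]
    if isinstance(alphabet, str):
        alphabet = tuple(alphabet)
    else:
        alphabet = tuple(str(a) for a in alphabet)
    rules = {str(k): str(v) for k, v in data["rules"].items()}
    return LSystemGrammar(str(data.get("name", "custom")), alphabet, rules)
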