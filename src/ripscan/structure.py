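"""RNA secondary structure by base-pair maximization.

Folding here is the classic Nussinov dynamic program over the canonical
pair set (Watson-Crick plus GU wobble) with a minimum hairpin-loop size.
For the short windows scanned by :mod:`ripscan.mimic` (15 nt by default)
the pairing pattern -- not a free-energy model -- is what the downstream
stem-loop calls depend on, and pair maximization admits an exhaustive
enumeration oracle (:func:`enumerate_structures`) against which the DP is
tested exactly.

The traceback is canonical and fully deterministic: at subproblem
``(i, j)`` the algorithm prefers leaving ``j`` unpaired whenever that is
optimal, and otherwise pairs ``j`` with the smallest admissible partner
``k``.  Two implementations of the same scoring therefore produce the
same dot-bracket string.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SecondaryStructure",
    "CANONICAL_PAIRS",
    "to_rna",
    "fold_window",
    "enumerate_structures",
    "find_hairpin_loops",
    "closing_stem",
]

#: Allowed base pairs: Watson-Crick and GU wobble.
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

_RNA_ALPHABET = set("ACGU")


def to_rna(seq: str) -> str:
    """Uppercase and transcribe a DNA/RNA string to the RNA alphabet.

    Raises ``ValueError`` on characters outside ``ACGUT``.
    """
    rna = seq.upper().replace("T", "U")
    bad = set(rna) - _RNA_ALPHABET
    if bad:
        raise ValueError(
            f"illegal characters in sequence: {sorted(bad)} (expected ACGU/T)"
        )
    return rna


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in CANONICAL_PAIRS


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure of a short RNA.

    Attributes
    ----------
    sequence:
        The folded sequence, RNA alphabet.
    pairs:
        Base pairs as 1-based ``(i, j)`` tuples with ``i < j``, sorted by
        ``i``.  Pairs are non-crossing and drawn from the canonical set.
    dot_bracket:
        Dot-bracket string consistent with ``pairs``.
    """

    sequence: str
    pairs: tuple[tuple[int, int], ...]
    dot_bracket: str = field(default="", compare=False)

    def __post_init__(self):
        n = len(self.sequence)
        db = ["."] * n
        for i, j in self.pairs:
            if not (1 <= i < j <= n):
                raise ValueError(f"pair ({i},{j}) out of range for length {n}")
            db[i - 1] = "("
            db[j - 1] = ")"
        object.__setattr__(self, "dot_bracket", "".join(db))

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def is_valid(self, min_loop: int = 3) -> bool:
        """Check canonical pairing, loop size, and non-crossing nesting."""
        seq = self.sequence
        seen: set[int] = set()
        for i, j in self.pairs:
            if j - i < min_loop + 1:
                return False
            if not _can_pair(seq[i - 1], seq[j - 1]):
                return False
            if i in seen or j in seen:
                return False
            seen.update((i, j))
        for (i, j) in self.pairs:
            for (k, l) in self.pairs:
                if i < k < j < l:  # crossing
                    return False
        return True


def fold_window(seq: str, min_loop: int = 3) -> SecondaryStructure:
    """Fold a sequence to a maximum-pair structure (Nussinov DP).

    Parameters
    ----------
    seq:
        RNA or DNA string (T is transcribed to U).
    min_loop:
        Minimum number of unpaired bases enclosed by any pair; pairs
        ``(i, j)`` require ``j - i >= min_loop + 1``.

    Returns
    -------
    SecondaryStructure
        The canonical optimal structure (see module docstring for the
        traceback convention).
    """
    rna = to_rna(seq)
    n = len(rna)
    if n == 0:
        raise ValueError("empty sequence")
    # N[i][j]: max pairs on rna[i..j], 0-based inclusive.
    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i][j - 1]  # j unpaired
            for k in range(i, j - min_loop):
                if _can_pair(rna[k], rna[j]):
                    left = N[i][k - 1] if k > i else 0
                    inner = N[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    best = max(best, left + inner + 1)
            N[i][j] = best

    pairs: list[tuple[int, int]] = []

    def traceback(i: int, j: int) -> None:
        while j > i:
            if N[i][j] == (N[i][j - 1] if j - 1 >= i else 0):
                j -= 1
                continue
            for k in range(i, j - min_loop):
                if _can_pair(rna[k], rna[j]):
                    left = N[i][k - 1] if k > i else 0
                    inner = N[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    if left + inner + 1 == N[i][j]:
                        pairs.append((k + 1, j + 1))
                        if k + 1 <= j - 1:
                            traceback(k + 1, j - 1)
                        j = k - 1
                        break
            else:  # pragma: no cover - DP consistency guard
                raise AssertionError("traceback failed")

    traceback(0, n - 1)
    return SecondaryStructure(rna, tuple(sorted(pairs)))


_MAX_ENUM_LEN = 22


def enumerate_structures(seq: str, min_loop: int = 3) -> list[SecondaryStructure]:
    """Exhaustively enumerate all valid structures of a short sequence.

    Serves as the independent oracle for :func:`fold_window`: the list is
    duplicate-free and complete over non-crossing canonical-pair
    structures respecting ``min_loop``.  Guarded to ``len(seq) <= 22``.
    """
    rna = to_rna(seq)
    n = len(rna)
    if n > _MAX_ENUM_LEN:
        raise ValueError(
            f"sequence length {n} exceeds enumeration guard ({_MAX_ENUM_LEN})"
        )

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def enum(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        # All pair sets on rna[i..j] (0-based inclusive); () when empty.
        if j - i < min_loop + 1:
            return ((),)
        out: list[tuple[tuple[int, int], ...]] = []
        # Case: j unpaired.  Each structure on [i, j-1] appears exactly once
        # here; pairing j (below) yields structures disjoint from these, so
        # the union is duplicate-free.
        out.extend(enum(i, j - 1))
        for k in range(i, j - min_loop):
            if _can_pair(rna[k], rna[j]):
                lefts = enum(i, k - 1) if k > i else ((),)
                inners = enum(k + 1, j - 1) if k + 1 <= j - 1 else ((),)
                for left in lefts:
                    for inner in inners:
                        out.append(left + inner + ((k + 1, j + 1),))
        return tuple(out)

    return [
        SecondaryStructure(rna, tuple(sorted(p))) for p in enum(0, n - 1)
    ]


def find_hairpin_loops(structure: SecondaryStructure) -> list[tuple[int, int]]:
    """Return hairpin-loop intervals of a structure.

    A hairpin loop is a maximal unpaired run ``(a, b)`` (1-based,
    inclusive) directly closed by a pair ``(a-1, b+1)`` that encloses no
    other pair.
    """
    loops = []
    paired = {i for p in structure.pairs for i in p}
    for i, j in structure.pairs:
        inner = range(i + 1, j)
        if inner and not any(k in paired for k in inner):
            loops.append((i + 1, j - 1))
    return sorted(loops)


def closing_stem(
    structure: SecondaryStructure, loop: tuple[int, int]
) -> list[tuple[int, int]]:
    """The contiguous stack of pairs directly closing a hairpin loop.

    Returns pairs ``(i, j)`` ordered from innermost (adjacent to the
    loop) outward; the walk stops at the first interruption of the
    stack (bulge or unpaired base on either strand).
    """
    a, b = loop
    pair_set = set(structure.pairs)
    stem = []
    i, j = a - 1, b + 1
    while (i, j) in pair_set:
        stem.append((i, j))
        i, j = i - 1, j + 1
    return stem
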