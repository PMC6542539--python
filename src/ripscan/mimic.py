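"""Anticodon-mimic detection and mutation-effect classification.

An aminoacyl-tRNA synthetase reads its cognate tRNA largely through the
anticodon loop.  An mRNA can present the same triplet in the loop of a
stem-loop ("anticodon mimic") and thereby engage the synthetase's
anticodon-binding domain.  This module scans a coding sequence with a
sliding window, folds each window by base-pair maximization
(:mod:`ripscan.structure`), and reports windows where the query triplet
sits entirely inside a hairpin loop closed by a stem.

It also applies point mutations given in the compact ``T1101A`` notation
(1-based CDS coordinates on the coding strand, position 1 = the A of the
start codon), checks their synonymy under the standard genetic code, and
classifies a mutation set against a wild-type stem-loop window as
``anticodon_lost``, ``stem_disrupted`` or ``stem_preserved``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq

from .structure import (
    SecondaryStructure,
    closing_stem,
    find_hairpin_loops,
    fold_window,
    to_rna,
)

__all__ = [
    "MimicHit",
    "MutationSpec",
    "VariantClass",
    "scan_mimic",
    "apply_mutations",
    "is_synonymous",
    "classify_variant",
]


@dataclass(frozen=True)
class MimicHit:
    """A triplet-in-hairpin-loop call from a window scan.

    Coordinates are 1-based on the coding strand from the start codon.
    ``triplet_offset`` is the triplet's 1-based offset within the window;
    ``triplet_pos`` its absolute CDS position.  ``loop`` is the hairpin
    loop interval in window coordinates.
    """

    window_start: int
    window_len: int
    triplet_offset: int
    triplet_pos: int
    structure: SecondaryStructure
    stem_len: int
    loop: tuple[int, int]


_MUTATION_RE = re.compile(r"^([ACGTUacgtu])(\d+)([ACGTUacgtu])$")


@dataclass(frozen=True)
class MutationSpec:
    """A point substitution, e.g. ``T1101A``: ref base, 1-based CDS position, alt."""

    position: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        ref, alt = self.ref.upper(), self.alt.upper()
        if ref not in "ACGTU" or alt not in "ACGTU":
            raise ValueError(f"bases must be in ACGT/U: {self.ref}>{self.alt}")
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)
        if to_rna(self.ref) == to_rna(self.alt):
            raise ValueError(f"ref equals alt at position {self.position}")

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        m = _MUTATION_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse mutation spec {text!r} (expected e.g. T1101A)")
        ref, pos, alt = m.groups()
        return cls(position=int(pos), ref=ref, alt=alt)


@dataclass(frozen=True)
class VariantClass:
    """Outcome of :func:`classify_variant` with diagnostics.

    ``label`` is one of ``anticodon_lost`` / ``stem_disrupted`` /
    ``stem_preserved``; ``pairs_retained`` is the fraction of wild-type
    closing-stem pairs present in the mutant fold, ``triplet_intact``
    whether the triplet sequence is unchanged, ``triplet_in_loop``
    whether the mutant fold still holds the triplet in a hairpin loop.
    """

    label: str
    pairs_retained: float
    triplet_intact: bool
    triplet_in_loop: bool


def _window_hits(
    window: str,
    window_start: int,
    triplet: str,
    min_loop: int,
    min_stem: int,
) -> list[MimicHit]:
    structure = fold_window(window, min_loop=min_loop)
    loops = find_hairpin_loops(structure)
    hits = []
    for offset0 in _find_all(structure.sequence, triplet):
        t0, t1 = offset0 + 1, offset0 + 3  # 1-based window coords
        for loop in loops:
            if loop[0] <= t0 and t1 <= loop[1]:
                stem = closing_stem(structure, loop)
                if len(stem) >= min_stem:
                    hits.append(
                        MimicHit(
                            window_start=window_start,
                            window_len=len(window),
                            triplet_offset=t0,
                            triplet_pos=window_start + offset0,
                            structure=structure,
                            stem_len=len(stem),
                            loop=loop,
                        )
                    )
                break  # loops are disjoint; the triplet sits in at most one
    return hits


def _find_all(seq: str, sub: str) -> list[int]:
    out, i = [], seq.find(sub)
    while i != -1:
        out.append(i)
        i = seq.find(sub, i + 1)
    return out


def scan_mimic(
    cds: str,
    triplet: str,
    window_len: int = 15,
    step: int = 1,
    min_loop: int = 3,
    min_stem: int = 2,
) -> list[MimicHit]:
    """Scan a CDS for the triplet presented in a hairpin loop.

    Every window of ``window_len`` (advanced by ``step``) is folded; a
    raw hit requires all three triplet bases inside one hairpin loop
    whose closing stem stacks at least ``min_stem`` pairs.  Raw hits at
    overlapping windows that present the same triplet occurrence are
    merged into a single hit keeping the longest stem (ties resolved
    toward the smallest window start).  Hits are returned sorted by
    triplet position.
    """
    rna = to_rna(cds)
    trip = to_rna(triplet)
    if len(trip) != 3:
        raise ValueError(f"triplet must be 3 nt, got {triplet!r}")
    if len(rna) < window_len:
        raise ValueError(
            f"CDS length {len(rna)} shorter than window {window_len}"
        )
    raw: list[MimicHit] = []
    for start0 in range(0, len(rna) - window_len + 1, step):
        window = rna[start0 : start0 + window_len]
        raw.extend(
            _window_hits(window, start0 + 1, trip, min_loop, min_stem)
        )
    # Merge by triplet occurrence: same absolute position = same element.
    best: dict[int, MimicHit] = {}
    for hit in raw:
        cur = best.get(hit.triplet_pos)
        if (
            cur is None
            or hit.stem_len > cur.stem_len
            or (hit.stem_len == cur.stem_len and hit.window_start < cur.window_start)
        ):
            best[hit.triplet_pos] = hit
    return [best[k] for k in sorted(best)]


def apply_mutations(cds: str, mutations: list[MutationSpec]) -> str:
    """Apply point substitutions to a CDS; order-independent for distinct sites.

    Reference bases are checked against the CDS with U/T equivalence;
    the returned sequence keeps the input alphabet convention (DNA in,
    DNA out).
    """
    is_dna = "T" in cds.upper() or "U" not in cds.upper()
    seq = list(cds.upper())
    for m in mutations:
        if not (1 <= m.position <= len(seq)):
            raise ValueError(
                f"mutation position {m.position} outside CDS of length {len(seq)}"
            )
        found = seq[m.position - 1]
        if to_rna(found) != to_rna(m.ref):
            raise ValueError(
                f"reference mismatch at position {m.position}: "
                f"expected {m.ref}, found {found}"
            )
        alt = m.alt
        seq[m.position - 1] = alt.replace("U", "T") if is_dna else to_rna(alt)
    return "".join(seq)


def is_synonymous(cds: str, mutation: MutationSpec) -> bool:
    """Whether a substitution is silent under the standard genetic code."""
    seq = cds.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    if not (1 <= mutation.position <= len(seq)):
        raise ValueError(
            f"mutation position {mutation.position} outside CDS of length {len(seq)}"
        )
    mutated = apply_mutations(seq, [mutation])
    codon_i = (mutation.position - 1) // 3
    before = seq[codon_i * 3 : codon_i * 3 + 3].replace("U", "T")
    after = mutated[codon_i * 3 : codon_i * 3 + 3].replace("U", "T")
    return str(Seq(before).translate()) == str(Seq(after).translate())


def classify_variant(
    wt_window: str,
    mutations: list[MutationSpec],
    triplet: str,
    min_loop: int = 3,
    window_start: int = 1,
    stem_retention: float = 0.5,
) -> VariantClass:
    """Classify the structural effect of mutations on a mimic window.

    Mutation positions are absolute CDS coordinates interpreted relative
    to ``window_start`` (default 1: positions are window-relative).  The
    wild-type window must contain the triplet inside a hairpin loop of
    its maximum-pair fold; classification then proceeds:

    * ``anticodon_lost`` -- any mutation changes a base of the triplet
      occurrence in the loop (sequence-level; independent of folding);
    * ``stem_disrupted`` -- the stem closing the triplet's loop in the
      mutant fold retains fewer than ``stem_retention`` of the wild-type
      closing-stem pairs, or the mutant fold no longer holds the triplet
      in a hairpin loop;
    * ``stem_preserved`` -- otherwise.

    Retention is measured on the mutant loop's closing stack, not on the
    whole structure: distal pairs that survive a mutation do not rescue
    a mimic whose own stem has come apart.
    """
    wt = to_rna(wt_window)
    trip = to_rna(triplet)
    rel = []
    for m in mutations:
        off = m.position - window_start + 1
        if not (1 <= off <= len(wt)):
            raise ValueError(
                f"mutation at CDS position {m.position} falls outside the "
                f"window [{window_start}, {window_start + len(wt) - 1}]"
            )
        rel.append(MutationSpec(position=off, ref=m.ref, alt=m.alt))

    wt_structure = fold_window(wt, min_loop=min_loop)
    wt_loop = None
    for loop in find_hairpin_loops(wt_structure):
        for off0 in _find_all(wt, trip):
            if loop[0] <= off0 + 1 and off0 + 3 <= loop[1]:
                wt_loop = loop
                wt_trip0 = off0
                break
        if wt_loop:
            break
    if wt_loop is None:
        raise ValueError(
            "wild-type window does not present the triplet in a hairpin loop"
        )
    wt_stem = set(closing_stem(wt_structure, wt_loop))

    triplet_sites = {wt_trip0 + 1, wt_trip0 + 2, wt_trip0 + 3}
    triplet_intact = not any(m.position in triplet_sites for m in rel)

    mut = to_rna(apply_mutations(wt, rel)) if rel else wt
    mut_structure = fold_window(mut, min_loop=min_loop)
    mut_stem: set[tuple[int, int]] = set()
    triplet_in_loop = False
    for loop in find_hairpin_loops(mut_structure):
        for off0 in _find_all(mut, trip):
            if loop[0] <= off0 + 1 and off0 + 3 <= loop[1]:
                triplet_in_loop = True
                mut_stem |= set(closing_stem(mut_structure, loop))
    pairs_retained = (
        len(wt_stem & mut_stem) / len(wt_stem) if wt_stem else 1.0
    )

    if not triplet_intact:
        label = "anticodon_lost"
    elif pairs_retained < stem_retention or not triplet_in_loop:
        label = "stem_disrupted"
    else:
        label = "stem_preserved"
    return VariantClass(
        label=label,
        pairs_retained=pairs_retained,
        triplet_intact=triplet_intact,
        triplet_in_loop=triplet_in_loop,
    )
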