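"""RNA secondary-structure representation, motif decomposition, and base-pair matrices.

Structures are pseudoknot-free (nested) sets of base pairs in 0-based
coordinates.  Each position carries exactly one motif tag; paired positions
are tagged ``helix`` and unpaired positions are classified by the loop that
contains them (hairpin loop, interior loop, bulge, x-way junction, dangle,
or single strand between helices in the exterior loop).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = [
    "PairedStructure",
    "Helix",
    "StructureParseError",
    "parse_dot_bracket",
    "annotate_motifs",
    "weighted_bp_matrix",
    "bp_set_distance",
]

#: motif tags used by the collapse map.  Junctions are parameterized by the
#: number of branching helices: ``junction(3)`` is a three-way junction.
HELIX = "helix"
HAIRPIN_LOOP = "hairpin_loop"
INTERIOR_LOOP = "interior_loop"
BULGE = "bulge"
DANGLE = "dangle"
SS_BETWEEN_HELICES = "ss_between_helices"


def junction(x: int) -> str:
    return f"junction({x})"


class StructureParseError(ValueError):
    """Raised for malformed dot-bracket strings; carries the offending index."""

    def __init__(self, message: str, index: int):
        super().__init__(f"{message} (index {index})")
        self.index = index


@dataclass(frozen=True)
class Helix:
    """A maximal stack of consecutive base pairs (i,j),(i+1,j-1),...

    A bulge or loop of any size breaks a helix; 1-bp helices are valid
    objects but are excluded from benchmark scoring (which requires >=3 bp).
    """

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        ps = self.pairs
        for (a, b), (c, d) in zip(ps, ps[1:]):
            if (c, d) != (a + 1, b - 1):
                raise ValueError(f"pairs {ps} are not a consecutive stack")

    @property
    def length(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return pair in self.pairs


@dataclass(frozen=True)
class PairedStructure:
    """One nested secondary structure over a sequence of given length."""

    sequence_length: int
    pairs: frozenset[tuple[int, int]]
    motif_labels: tuple[str, ...] | None = field(default=None, compare=False)

    def __post_init__(self):
        n = self.sequence_length
        seen: dict[int, tuple[int, int]] = {}
        for i, j in self.pairs:
            if not (0 <= i < j < n):
                raise ValueError(f"pair ({i},{j}) out of range for length {n}")
            for k in (i, j):
                if k in seen:
                    raise ValueError(f"position {k} appears in two pairs")
                seen[k] = (i, j)
        sorted_pairs = sorted(self.pairs)
        for a, b in sorted_pairs:
            for c, d in sorted_pairs:
                if a < c < b < d:
                    raise ValueError(
                        f"crossing pairs ({a},{b}) and ({c},{d}): pseudoknots unsupported"
                    )

    @cached_property
    def partner(self) -> np.ndarray:
        """partner[i] = j if (i,j) or (j,i) paired, else -1."""
        p = np.full(self.sequence_length, -1, dtype=int)
        for i, j in self.pairs:
            p[i], p[j] = j, i
        return p

    @property
    def dot_bracket(self) -> str:
        chars = ["."] * self.sequence_length
        for i, j in self.pairs:
            chars[i], chars[j] = "(", ")"
        return "".join(chars)

    @cached_property
    def helices(self) -> tuple[Helix, ...]:
        """Maximal stacks; every pair belongs to exactly one helix."""
        pairs = sorted(self.pairs)
        pair_set = set(pairs)
        out = []
        for i, j in pairs:
            if (i - 1, j + 1) in pair_set:
                continue  # not the outermost pair of its stack
            run = [(i, j)]
            while (run[-1][0] + 1, run[-1][1] - 1) in pair_set:
                run.append((run[-1][0] + 1, run[-1][1] - 1))
            out.append(Helix(tuple(run)))
        return tuple(out)


def parse_dot_bracket(text: str) -> PairedStructure:
    """Parse a dot-bracket string into a PairedStructure by stack matching.

    Only the nested alphabet ``(``, ``)``, ``.`` is accepted; pseudoknot
    brackets (``[``, ``]``) are rejected.
    """
    text = text.strip()
    stack: list[int] = []
    pairs = set()
    for idx, ch in enumerate(text):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise StructureParseError("unmatched ')'", idx)
            pairs.add((stack.pop(), idx))
        elif ch == ".":
            continue
        elif ch in "[]{}<>":
            raise StructureParseError("pseudoknot brackets unsupported", idx)
        else:
            raise StructureParseError(f"invalid character {ch!r}", idx)
    if stack:
        raise StructureParseError("unmatched '('", stack[0])
    return PairedStructure(sequence_length=len(text), pairs=frozenset(pairs))


def _classify_loop(
    s: PairedStructure, labels: list[str], lo: int, hi: int, exterior: bool
) -> None:
    """Label the unpaired positions of the loop spanning [lo, hi] (closed by
    the pair (lo-1, hi+1) unless exterior), then recurse into branch helices.
    """
    partner = s.partner
    branches: list[tuple[int, int]] = []
    runs: list[list[int]] = [[]]  # unpaired runs separated by branches
    k = lo
    while k <= hi:
        j = partner[k]
        if j > k:
            branches.append((k, j))
            runs.append([])
            k = j + 1
        else:
            runs[-1].append(k)
            k += 1

    nb = len(branches)
    if exterior:
        for ridx, run in enumerate(runs):
            if not run:
                continue
            if nb == 0:
                tag = DANGLE  # fully single-stranded strand
            elif ridx == 0 or ridx == nb:
                tag = DANGLE
            else:
                tag = SS_BETWEEN_HELICES
            for p in run:
                labels[p] = tag
    else:
        unpaired = [p for run in runs for p in run]
        if nb == 0:
            tag = HAIRPIN_LOOP
        elif nb == 1:
            two_sided = bool(runs[0]) and bool(runs[1])
            tag = INTERIOR_LOOP if two_sided else BULGE
        else:
            tag = junction(nb + 1)
        for p in unpaired:
            labels[p] = tag

    for i, j in branches:
        # descend through the helix stack to its innermost pair, then recurse
        while partner[i + 1] == j - 1:
            i, j = i + 1, j - 1
        if i + 1 <= j - 1:
            _classify_loop(s, labels, i + 1, j - 1, exterior=False)


def annotate_motifs(s: PairedStructure) -> PairedStructure:
    """Return a copy of ``s`` with every position carrying one motif tag.

    Paired positions are ``helix``; unpaired positions are classified by loop
    decomposition.  Exterior unpaired runs flanking the outermost helices are
    ``dangle``; runs between two exterior helices are ``ss_between_helices``.
    """
    n = s.sequence_length
    labels = [HELIX] * n
    if n > 0:
        _classify_loop(s, labels, 0, n - 1, exterior=True)
        for i, j in s.pairs:
            labels[i] = labels[j] = HELIX
    return PairedStructure(
        sequence_length=n, pairs=s.pairs, motif_labels=tuple(labels)
    )


def weighted_bp_matrix(
    structures: list[PairedStructure], weights: np.ndarray
) -> np.ndarray:
    """Population-weighted base-pair probability matrix.

    Entry (i,j) = sum over structures of weight_s * [ (i,j) paired in s ].
    Weights must be a simplex vector matching ``structures``.
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(structures):
        raise ValueError(
            f"{len(weights)} weights for {len(structures)} structures"
        )
    if len(structures) == 0:
        raise ValueError("no structures")
    if np.any(weights < -1e-9) or abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError("weights must be nonnegative and sum to 1")
    n = structures[0].sequence_length
    mat = np.zeros((n, n))
    for w, s in zip(weights, structures):
        for i, j in s.pairs:
            mat[i, j] += w
            mat[j, i] += w
    return np.clip(mat, 0.0, 1.0)


def bp_set_distance(a: PairedStructure, b: PairedStructure) -> int:
    """Symmetric-difference distance between two structures' base-pair sets."""
    return len(a.pairs ^ b.pairs)
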