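"""Pluggable folding backends supplying suboptimal structures and energies.

Three interchangeable implementations:

* :class:`ViennaBackend` — ViennaRNA python bindings (``RNA`` module); the
  nearest-neighbor backend used for real data.
* :class:`ToyBackend` — exhaustive enumeration of nested structures built
  from maximal complementary runs (>=3 bp) with a simple stacking score.
  Deterministic, dependency-free, suitable for sequences up to ~40 nt; used
  by the test suite and the in-silico benchmark.
* :class:`ExternalBackend` — shells out to AllSub/efn2-compatible
  executables when they are installed and configured.

A backend must implement ``subopt(seq, max_structures, energy_window)``
returning ``[(dot_bracket, energy_kcal)]`` within ``energy_window`` percent
of the minimum free energy, and ``energy(seq, structure)`` scoring an
arbitrary structure on an arbitrary sequence.  Pairs rendered non-canonical
by a mutation are dropped before scoring: the model's local-perturbation
variables, not the energy function, absorb the disruption.
"""

from __future__ import annotations

import itertools
import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structures import PairedStructure, parse_dot_bracket

__all__ = [
    "FoldingBackend",
    "ToyBackend",
    "ViennaBackend",
    "ExternalBackend",
    "FileBackend",
    "get_backend",
    "CANONICAL_PAIRS",
]

CANONICAL_PAIRS = {
    ("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G"),
}


def canonical(a: str, b: str) -> bool:
    return (a.upper(), b.upper()) in CANONICAL_PAIRS


def drop_noncanonical(seq: str, structure: PairedStructure) -> PairedStructure:
    """Remove pairs a mutation has rendered non-canonical."""
    keep = frozenset(
        (i, j) for i, j in structure.pairs if canonical(seq[i], seq[j])
    )
    if keep == structure.pairs:
        return structure
    return PairedStructure(structure.sequence_length, keep)


class FoldingBackend:
    """Interface; see module docstring."""

    def subopt(
        self, seq: str, max_structures: int = 200, energy_window: float = 5.0
    ) -> list[tuple[str, float]]:
        raise NotImplementedError

    def energy(self, seq: str, structure: PairedStructure) -> float:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# Toy backend: exhaustive helix-subset enumeration with a stacking score.

#: kcal/mol-like pair strengths for the toy score; a stack of pairs p,q
#: contributes -(strength(p)+strength(q))/2, and each helix pays a +3
#: initiation penalty, loosely mirroring loop-closure cost.
_PAIR_STRENGTH = {frozenset("GC"): 3.0, frozenset("AU"): 2.0, frozenset("GU"): 1.0}
_HELIX_INIT = 3.0


def _pair_strength(a: str, b: str) -> float:
    return _PAIR_STRENGTH.get(frozenset((a.upper(), b.upper())), 0.0)


@dataclass
class ToyBackend(FoldingBackend):
    """Exhaustive enumerator over compatible sets of maximal helices.

    Candidate helices are maximal runs of >=``min_helix`` consecutive
    canonical pairs with a hairpin loop of >=``min_loop`` nucleotides;
    structures are all mutually compatible (non-overlapping, non-crossing)
    subsets of candidates, including the open chain at 0 kcal/mol.
    """

    min_helix: int = 3
    min_loop: int = 3
    max_candidates: int = 24
    max_enumerate: int = 20000

    def _candidates(self, seq: str) -> list[tuple[tuple[int, int], ...]]:
        n = len(seq)
        runs = []
        for i in range(n):
            for j in range(n - 1, i + self.min_loop, -1):
                if not canonical(seq[i], seq[j]):
                    continue
                # skip if extendable outward (we want maximal runs only)
                if i > 0 and j < n - 1 and canonical(seq[i - 1], seq[j + 1]):
                    continue
                a, b, run = i, j, []
                while a < b - self.min_loop and canonical(seq[a], seq[b]):
                    run.append((a, b))
                    a, b = a + 1, b - 1
                if len(run) >= self.min_helix:
                    runs.append(tuple(run))
        runs = sorted(set(runs), key=lambda r: (self._helix_energy(seq, r), r))
        return runs[: self.max_candidates]

    def _helix_energy(self, seq: str, run: tuple[tuple[int, int], ...]) -> float:
        e = _HELIX_INIT
        for (a, b), (c, d) in zip(run, run[1:]):
            e -= (_pair_strength(seq[a], seq[b]) + _pair_strength(seq[c], seq[d])) / 2.0
        return e

    @staticmethod
    def _compatible(r1, r2) -> bool:
        (i1, j1), (k1, l1) = r1[0], r1[-1]
        (i2, j2), (k2, l2) = r2[0], r2[-1]
        span1 = set(range(i1, k1 + 1)) | set(range(l1, j1 + 1))
        span2 = set(range(i2, k2 + 1)) | set(range(l2, j2 + 1))
        if span1 & span2:
            return False
        for a, b in (r1[0],):
            for c, d in (r2[0],):
                if a < c < b < d or c < a < d < b:
                    return False
        return True

    def enumerate(self, seq: str) -> list[tuple[PairedStructure, float]]:
        cands = self._candidates(seq)
        energies = [self._helix_energy(seq, r) for r in cands]
        out: list[tuple[PairedStructure, float]] = []
        n = len(seq)

        def rec(start: int, chosen: list[int]):
            if len(out) >= self.max_enumerate:
                return
            pairs = frozenset(p for k in chosen for p in cands[k])
            out.append(
                (PairedStructure(n, pairs), sum(energies[k] for k in chosen))
            )
            for k in range(start, len(cands)):
                if all(self._compatible(cands[k], cands[c]) for c in chosen):
                    rec(k + 1, chosen + [k])

        rec(0, [])
        return out

    def subopt(self, seq, max_structures=200, energy_window=5.0):
        structs = self.enumerate(seq)
        structs.sort(key=lambda se: se[1])
        emin = structs[0][1]
        window = abs(emin) * energy_window / 100.0
        kept = [
            (s.dot_bracket, e) for s, e in structs if e <= emin + window
        ][:max_structures]
        return kept

    def energy(self, seq, structure):
        s = drop_noncanonical(seq, structure)
        return sum(self._helix_energy(seq, h.pairs) for h in s.helices)


# ---------------------------------------------------------------------------
# ViennaRNA backend.


@dataclass
class ViennaBackend(FoldingBackend):
    """Suboptimal structures and energies via the ViennaRNA python bindings."""

    def _rna(self):
        try:
            import RNA
        except ImportError as e:  # pragma: no cover
            raise RuntimeError(
                "ViennaRNA python bindings not available; use the toy or "
                "external backend"
            ) from e
        return RNA

    def subopt(self, seq, max_structures=200, energy_window=5.0):
        RNA = self._rna()
        fc = RNA.fold_compound(seq)
        _, mfe = fc.mfe()
        delta_kcal = max(abs(mfe) * energy_window / 100.0, 0.01)
        sols = fc.subopt(int(round(delta_kcal * 100)))
        pairs = sorted(
            ((s.structure, float(s.energy)) for s in sols), key=lambda x: x[1]
        )
        return pairs[:max_structures]

    def energy(self, seq, structure):
        RNA = self._rna()
        s = drop_noncanonical(seq, structure)
        fc = RNA.fold_compound(seq)
        return float(fc.eval_structure(s.dot_bracket))


# ---------------------------------------------------------------------------
# External AllSub/efn2-style adapter and a precomputed-file backend.


@dataclass
class ExternalBackend(FoldingBackend):
    """Adapter shelling out to AllSub/efn2-compatible executables.

    ``subopt_cmd`` and ``energy_cmd`` are command templates with ``{seq}``,
    ``{ct}`` placeholders; output parsing expects one dot-bracket + energy
    per line for subopt and a single energy for scoring.
    """

    subopt_cmd: str = "AllSub {seq}"
    energy_cmd: str = "efn2 {seq} {db}"

    def _run(self, template: str, **kw) -> str:
        cmd = [a.format(**kw) for a in shlex.split(template)]
        res = subprocess.run(cmd, capture_output=True, text=True)
        if res.returncode != 0:
            raise RuntimeError(f"backend command {cmd} failed: {res.stderr}")
        return res.stdout

    def subopt(self, seq, max_structures=200, energy_window=5.0):
        out = self._run(self.subopt_cmd, seq=seq)
        pairs = []
        for line in out.splitlines():
            parts = line.split()
            if len(parts) >= 2 and set(parts[0]) <= set("()."):
                pairs.append((parts[0], float(parts[1])))
        pairs.sort(key=lambda x: x[1])
        return pairs[:max_structures]

    def energy(self, seq, structure):
        s = drop_noncanonical(seq, structure)
        out = self._run(self.energy_cmd, seq=seq, db=s.dot_bracket)
        return float(out.split()[-1])


@dataclass
class FileBackend(FoldingBackend):
    """Structures supplied in a dot-bracket file (one per line, optional
    trailing energy column); energies scored by a delegate backend when a
    line has no energy."""

    path: str
    scorer: FoldingBackend | None = None
    _cache: list[tuple[str, float | None]] = field(default_factory=list, repr=False)

    def __post_init__(self):
        for line in Path(self.path).read_text().splitlines():
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            db = parts[0]
            e = float(parts[1]) if len(parts) > 1 else None
            self._cache.append((db, e))
        if not self._cache:
            raise ValueError(f"{self.path}: no structures")

    def subopt(self, seq, max_structures=200, energy_window=5.0):
        out = []
        for db, e in self._cache[:max_structures]:
            if e is None:
                if self.scorer is None:
                    raise RuntimeError(
                        f"{self.path}: structure without energy and no scoring backend"
                    )
                e = self.scorer.energy(seq, parse_dot_bracket(db))
            out.append((db, e))
        return out

    def energy(self, seq, structure):
        if self.scorer is None:
            raise RuntimeError("file backend has no scoring delegate")
        return self.scorer.energy(seq, structure)


def get_backend(name: str, **kw) -> FoldingBackend:
    name = name.lower()
    if name == "toy":
        return ToyBackend(**kw)
    if name == "vienna":
        return ViennaBackend(**kw)
    if name == "external":
        return ExternalBackend(**kw)
    if name == "file":
        return FileBackend(**kw)
    raise ValueError(f"unknown folding backend {name!r}")
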