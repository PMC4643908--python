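"""Candidate-ensemble assembly: per-variant suboptimal structures, free
energies and Boltzmann initial weights, motif-collapse map, and
mutation-perturbation masks.

The candidate set is the union of every variant's suboptimal structures,
deduplicated by base-pair set, and each retained structure is scored on
every variant's sequence (filling the m x r energy table ΔG_js).  Hidden
reactivity variables of structures that place a position in the same motif
class are collapsed into one variable per (position, motif) — the assumption
that identical motifs react identically regardless of context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fold import FoldingBackend
from .rdat import ReactivityDataset, Variant
from .structures import PairedStructure, annotate_motifs, parse_dot_bracket

__all__ = [
    "EnergyTable",
    "CollapseMap",
    "Ensemble",
    "sample_ensemble",
    "assemble_ensemble",
    "boltzmann_weights",
    "build_collapse_map",
    "build_perturbation_mask",
    "DEFAULT_KT",
]

#: kcal/mol at 37 C, the reference temperature of nearest-neighbor models.
DEFAULT_KT = 0.6156


@dataclass
class EnergyTable:
    """Free energies ΔG_js (kcal/mol) of each structure s on each variant j."""

    dG: np.ndarray  # (m, r)
    kT: float = DEFAULT_KT

    def __post_init__(self):
        self.dG = np.atleast_2d(np.asarray(self.dG, dtype=float))
        if self.kT <= 0:
            raise ValueError("kT must be positive")


def boltzmann_weights(energies: EnergyTable) -> np.ndarray:
    """Row-wise Boltzmann weights W0[j,s] = exp(-ΔG_js/kT) / Σ_s' exp(-ΔG_js'/kT),
    computed with a max-shift for overflow safety."""
    x = -energies.dG / energies.kT
    finite_rows = np.isfinite(x).any(axis=1)
    if not finite_rows.all():
        raise ValueError("energy table row with no finite entry")
    x = x - x.max(axis=1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class CollapseMap:
    """Partition of (structure, position) pairs into collapsed variables.

    ``var_index[s, i]`` is the global variable id for structure s at
    position i; structures sharing a motif tag at i share the id.
    ``var_paired[v]`` is True when variable v is a helix (paired) variable,
    selecting the paired exponential prior rate; ``var_position[v]`` is the
    sequence position the variable lives at.
    """

    var_index: np.ndarray  # (r, n) int
    var_paired: np.ndarray  # (n_vars,) bool
    var_position: np.ndarray  # (n_vars,) int
    tags: list[list[str]]  # per position, tag per variable (diagnostics)

    @property
    def n_variables(self) -> int:
        return len(self.var_paired)

    def expand(self, values: np.ndarray) -> np.ndarray:
        """Map per-variable values back to a dense (r, n) matrix."""
        return values[self.var_index]


def build_collapse_map(
    structures: list[PairedStructure], sequence_length: int
) -> CollapseMap:
    r = len(structures)
    annotated = [annotate_motifs(s) if s.motif_labels is None else s for s in structures]
    var_index = np.zeros((r, sequence_length), dtype=int)
    var_paired: list[bool] = []
    var_position: list[int] = []
    tags: list[list[str]] = []
    for i in range(sequence_length):
        local: dict[str, int] = {}
        tags.append([])
        for s_idx, s in enumerate(annotated):
            tag = s.motif_labels[i]
            if tag not in local:
                local[tag] = len(var_paired)
                var_paired.append(tag == "helix")
                var_position.append(i)
                tags[-1].append(tag)
            var_index[s_idx, i] = local[tag]
    return CollapseMap(
        var_index=var_index,
        var_paired=np.array(var_paired, dtype=bool),
        var_position=np.array(var_position, dtype=int),
        tags=tags,
    )


def build_perturbation_mask(
    structures: list[PairedStructure],
    variants: list[Variant],
    sequence_length: int,
) -> np.ndarray:
    """Boolean (r, m, n) tensor marking perturbed(s, j) positions.

    For variant j mutating position p, the mask for structure s covers
    p-1..p+1 and, when s pairs p with q, q-1..q+1 (the pair the mutation
    disrupts), clipped to sequence bounds.  The wild-type row is empty.
    Multi-mutants take the union of per-mutation masks.
    """
    r, m, n = len(structures), len(variants), sequence_length
    mask = np.zeros((r, m, n), dtype=bool)
    partners = [s.partner for s in structures]
    for j, var in enumerate(variants):
        for pos, _wt, _mut in var.mutations:
            lo, hi = max(0, pos - 1), min(n, pos + 2)
            mask[:, j, lo:hi] = True
            for s_idx in range(r):
                q = partners[s_idx][pos]
                if q >= 0:
                    qlo, qhi = max(0, q - 1), min(n, q + 2)
                    mask[s_idx, j, qlo:qhi] = True
    return mask


@dataclass
class Ensemble:
    """The candidate structure set with its energy table and model maps."""

    structures: list[PairedStructure]
    energies: EnergyTable
    collapse: CollapseMap
    mask: np.ndarray  # (r, m, n)

    @property
    def n_structures(self) -> int:
        return len(self.structures)

    def initial_weights(self) -> np.ndarray:
        return boltzmann_weights(self.energies)


def assemble_ensemble(
    structures: list[PairedStructure],
    variants: list[Variant],
    sequence_length: int,
    dG: np.ndarray,
    kT: float = DEFAULT_KT,
) -> Ensemble:
    """Build an Ensemble from an explicit structure list and energy table
    (no folding backend involved)."""
    structures = [annotate_motifs(s) for s in structures]
    dG = np.atleast_2d(np.asarray(dG, dtype=float))
    if dG.shape != (len(variants), len(structures)):
        raise ValueError(
            f"energy table {dG.shape} does not match "
            f"{len(variants)} variants x {len(structures)} structures"
        )
    return Ensemble(
        structures=structures,
        energies=EnergyTable(dG=dG, kT=kT),
        collapse=build_collapse_map(structures, sequence_length),
        mask=build_perturbation_mask(structures, variants, sequence_length),
    )


def sample_ensemble(
    dataset: ReactivityDataset,
    backend: FoldingBackend,
    max_structures: int = 200,
    energy_window: float = 5.0,
    structures: list[PairedStructure] | None = None,
    kT: float = DEFAULT_KT,
) -> Ensemble:
    """Assemble the candidate ensemble for an M2 dataset.

    Samples up to ``max_structures`` suboptimal structures within
    ``energy_window`` percent of the MFE for each variant's sequence, takes
    the union deduplicated by base-pair set, and scores every retained
    structure on every variant.  When ``structures`` is given the sampling
    step is skipped and the backend only scores energies.
    """
    seqs = dataset.variant_sequences()
    n = len(dataset.sequence)

    if structures is None:
        if backend is None:
            raise ValueError("no folding backend and no structure list supplied")
        seen: dict[frozenset, PairedStructure] = {}
        order: list[frozenset] = []
        for seq in seqs:
            for db, _e in backend.subopt(seq, max_structures, energy_window):
                s = parse_dot_bracket(db)
                if s.sequence_length != n:
                    raise ValueError(
                        f"backend structure length {s.sequence_length} != {n}"
                    )
                if s.pairs not in seen:
                    seen[s.pairs] = s
                    order.append(s.pairs)
        structures = [seen[k] for k in order]
    else:
        for s in structures:
            if s.sequence_length != n:
                raise ValueError("structure length does not match sequence")

    structures = [annotate_motifs(s) for s in structures]
    m, r = len(seqs), len(structures)
    dG = np.empty((m, r))
    for j, seq in enumerate(seqs):
        for s_idx, s in enumerate(structures):
            dG[j, s_idx] = backend.energy(seq, s)

    collapse = build_collapse_map(structures, n)
    mask = build_perturbation_mask(structures, dataset.variants, n)
    return Ensemble(
        structures=structures,
        energies=EnergyTable(dG=dG, kT=kT),
        collapse=collapse,
        mask=mask,
    )
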