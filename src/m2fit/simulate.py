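"""Synthetic mutate-and-map data with known ground-truth landscapes.

The generator emulates the in-silico benchmark protocol: for the wild type
and every single-nucleotide complement mutant, take the folding backend's
suboptimal ensemble, perturb each structure's free energy with Gaussian
noise (mean 0, sd 1 kcal/mol by default — mimicking inaccuracies of
nearest-neighbor energy models), and Boltzmann-reweight to obtain the true
per-variant populations.  Hidden reactivity profiles are determined once
per dataset from exponential draws — rate ``lambda_P`` = 0.5 for paired
positions (mean 2.0) and ``lambda_U`` = 0.2 for unpaired positions (mean
5.0), the literal rate convention of the calibrated priors; both rates are
configurable.  Rows are the weight mixtures of these profiles plus Gaussian
measurement noise, clamped at zero.

Two draw schemes are available.  The default, ``positional``, draws one
paired and one unpaired value per sequence position and shares them across
structures — consistent with the model's premise that identical motifs
react identically regardless of context.  ``structural`` draws every
structure's profile independently, which deliberately violates that
premise and probes the method's robustness to per-structure reactivity
idiosyncrasy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import DEFAULT_KT, Ensemble, sample_ensemble
from .fold import FoldingBackend
from .rdat import ReactivityDataset, Variant, single_complement_mutants
from .structures import PairedStructure

__all__ = ["SimulationSpec", "GroundTruth", "simulate_dataset", "bistable_sequence"]


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions of one simulated M2 experiment."""

    sequence: str
    max_structures: int = 200
    energy_window: float = 5.0           # percent above MFE for subopt sampling
    energy_noise_sd: float = 1.0         # kcal/mol, mean 0
    measurement_noise_sd: float = 0.1    # reactivity units
    lambda_P: float = 0.5                # paired-reactivity rate (mean 2.0)
    lambda_U: float = 0.2                # unpaired-reactivity rate (mean 5.0)
    kT: float = DEFAULT_KT
    profile_draws: str = "positional"    # or "structural"
    seed: int | None = None

    def __post_init__(self):
        if self.energy_noise_sd < 0 or self.measurement_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if self.profile_draws not in ("positional", "structural"):
            raise ValueError("profile_draws must be 'positional' or 'structural'")


@dataclass
class GroundTruth:
    """The landscape a simulated dataset was generated from."""

    weights: np.ndarray                  # (m, r) true per-variant populations
    profiles: np.ndarray                 # (r, n) true per-structure reactivities
    structures: list[PairedStructure]
    spec: SimulationSpec = field(repr=False, default=None)


def simulate_dataset(
    spec: SimulationSpec,
    backend: FoldingBackend,
    structures: list[PairedStructure] | None = None,
) -> tuple[ReactivityDataset, GroundTruth, Ensemble]:
    """Generate one synthetic M2 dataset plus its ground truth.

    Returns the dataset, the ground truth, and the (noise-free) candidate
    ensemble whose energy table holds the backend energies before the
    Gaussian reweighting — the quantity a fit would start from.
    Identical seeds give bit-identical datasets.
    """
    rng = np.random.default_rng(spec.seed)
    seq = spec.sequence.upper().replace("T", "U")
    variants = [Variant()] + single_complement_mutants(seq)

    placeholder = ReactivityDataset(
        sequence=seq,
        reactivities=np.zeros((len(variants), len(seq))),
        variants=variants,
    )
    ensemble = sample_ensemble(
        placeholder,
        backend,
        max_structures=spec.max_structures,
        energy_window=spec.energy_window,
        structures=structures,
        kT=spec.kT,
    )
    structures = ensemble.structures
    r, n, m = len(structures), len(seq), len(variants)

    # true weights: Boltzmann reweighting of noise-perturbed energies
    dG = ensemble.energies.dG + rng.normal(0.0, spec.energy_noise_sd, size=(m, r))
    x = -dG / spec.kT
    x -= x.max(axis=1, keepdims=True)
    true_W = np.exp(x)
    true_W /= true_W.sum(axis=1, keepdims=True)

    # hidden profiles: determined once per dataset
    if spec.profile_draws == "positional":
        paired_vals = rng.exponential(1.0 / spec.lambda_P, n)
        unpaired_vals = rng.exponential(1.0 / spec.lambda_U, n)
        profiles = np.array(
            [np.where(s.partner >= 0, paired_vals, unpaired_vals) for s in structures]
        )
    else:  # independent per-structure draws
        profiles = np.empty((r, n))
        for s_idx, s in enumerate(structures):
            paired = s.partner >= 0
            profiles[s_idx, paired] = rng.exponential(1.0 / spec.lambda_P, paired.sum())
            profiles[s_idx, ~paired] = rng.exponential(1.0 / spec.lambda_U, (~paired).sum())

    data = true_W @ profiles
    if spec.measurement_noise_sd > 0:
        data = data + rng.normal(0.0, spec.measurement_noise_sd, size=data.shape)
    data = np.clip(data, 0.0, None)

    dataset = ReactivityDataset(
        sequence=seq,
        reactivities=data,
        variants=variants,
        modifier="1M7-simulated",
        name="synthetic-m2",
    )
    truth = GroundTruth(
        weights=true_W, profiles=profiles, structures=structures, spec=spec
    )
    return dataset, truth, ensemble


def bistable_sequence(stem: str = "GGCAGCUC", loop: str = "UUCG") -> str:
    """A sequence that can fold the central segment against either flank.

    Layout is ``stem + loop + revcomp(stem) + loop + stem``: the middle
    segment pairs with the 5' copy (hairpin A) or the 3' copy (hairpin B),
    the classic bistable-switch architecture used for two-state fixtures.
    """
    comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
    rc = "".join(comp[b] for b in reversed(stem.upper()))
    return stem.upper() + loop.upper() + rc + loop.upper() + stem.upper()
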