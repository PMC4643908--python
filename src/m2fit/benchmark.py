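"""Helix-level scoring against ground truth and cross-validated selection
of the regularization strengths.

A *true* helix in a variant has ground-truth population >= 25% and at least
3 base pairs; a *detection* is a fitted helix meeting the same population
threshold whose population also exceeds its bootstrap error (SNR > 1).
True/false positives are counted per variant;
sensitivity, false negative rate (FNR = 1 - sensitivity) and false
discovery rate (FDR) are aggregated over the pooled counts.  The no-data
baseline scores the Boltzmann ensemble the same way, with detection by the
population threshold alone (no bootstrap error exists without data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .em import Hyperparameters, build_model, e_step, fit
from .ensemble import Ensemble, boltzmann_weights, EnergyTable
from .landscape import HelixCall, helix_membership, helix_universe
from .simulate import GroundTruth

__all__ = [
    "BenchmarkScore",
    "score_landscape",
    "no_data_baseline",
    "crossval_select_lambdas",
]

MIN_HELIX_LENGTH = 3
MIN_POPULATION = 0.25


@dataclass
class BenchmarkScore:
    """Per-variant TP/FP helix counts and pooled error rates."""

    tp: np.ndarray            # (m,) true positives per variant
    fp: np.ndarray            # (m,) false positives per variant
    n_true: np.ndarray        # (m,) true helices per variant
    n_detected: np.ndarray    # (m,) detections per variant
    criteria: dict = field(default_factory=dict)

    @property
    def sensitivity(self) -> float:
        total = self.n_true.sum()
        return float(self.tp.sum() / total) if total > 0 else float("nan")

    @property
    def fnr(self) -> float:
        s = self.sensitivity
        return float("nan") if np.isnan(s) else 1.0 - s

    @property
    def fdr(self) -> float:
        det = self.n_detected.sum()
        return float(self.fp.sum() / det) if det > 0 else float("nan")

    @property
    def mean_tp(self) -> float:
        return float(self.tp.mean())

    @property
    def mean_fp(self) -> float:
        return float(self.fp.mean())


def _score_matrices(
    detected: np.ndarray, true_present: np.ndarray, criteria: dict
) -> BenchmarkScore:
    tp = (detected & true_present).sum(axis=1).astype(float)
    fp = (detected & ~true_present).sum(axis=1).astype(float)
    return BenchmarkScore(
        tp=tp,
        fp=fp,
        n_true=true_present.sum(axis=1).astype(float),
        n_detected=detected.sum(axis=1).astype(float),
        criteria=criteria,
    )


def score_landscape(
    fit_calls: list[list[HelixCall]],
    truth: GroundTruth,
    min_length: int = MIN_HELIX_LENGTH,
    min_population: float = MIN_POPULATION,
) -> BenchmarkScore:
    """Score fitted helix calls against a known landscape.

    ``fit_calls`` is the per-variant output of ``helix_populations`` (one
    list per variant, all over the same helix universe).  Ground-truth helix
    populations are computed with the same containment rule, on the truth's
    structure set and weights.  Helices shorter than ``min_length`` are
    excluded from scoring entirely (the model retains them; the benchmark
    does not count them).
    """
    helices = [c.helix for c in fit_calls[0]]
    keep = np.array([h.length >= min_length for h in helices])
    M = helix_membership(helices, truth.structures)  # (H, r)
    truth_pops = truth.weights @ M.T                 # (m, H)
    m = truth.weights.shape[0]
    if len(fit_calls) != m:
        raise ValueError(
            f"{len(fit_calls)} variants in calls, {m} in ground truth"
        )
    detected = np.array(
        [[c.detected and c.population >= min_population for c in row]
         for row in fit_calls],
        dtype=bool,
    )
    true_present = truth_pops >= min_population
    detected &= keep
    true_present &= keep
    return _score_matrices(
        detected,
        true_present,
        criteria={
            "min_helix_length": min_length,
            "min_population": min_population,
            "detection": "population >= threshold and > bootstrap sd (SNR > 1)",
            "helix_merging": "a bulge breaks a helix (no merging across bulges)",
        },
    )


def no_data_baseline(
    ensemble: Ensemble,
    truth: GroundTruth,
    min_length: int = MIN_HELIX_LENGTH,
    min_population: float = MIN_POPULATION,
) -> BenchmarkScore:
    """Score the data-free Boltzmann ensemble against the ground truth.

    The baseline 'detects' a helix when its Boltzmann population reaches the
    same threshold that defines true helices (no bootstrap error is
    available without data).  Deterministic given the energy table.
    """
    W0 = boltzmann_weights(ensemble.energies)
    helices = helix_universe(ensemble.structures)
    keep = np.array([h.length >= min_length for h in helices])
    M = helix_membership(helices, ensemble.structures)
    base_pops = W0 @ M.T
    truth_M = helix_membership(helices, truth.structures)
    truth_pops = truth.weights @ truth_M.T
    detected = (base_pops >= min_population) & keep
    true_present = (truth_pops >= min_population) & keep
    return _score_matrices(
        detected,
        true_present,
        criteria={
            "min_helix_length": min_length,
            "min_population": min_population,
            "detection": f"Boltzmann population >= {min_population}",
        },
    )


def strided_folds(n: int, k: int) -> list[np.ndarray]:
    """The i-th test fold is the position sequence {i, i+k, i+2k, ...} — the
    structured-data splitting used for spline-type smoothers.  Folds
    partition 0..n-1 exactly."""
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} positions")
    return [np.arange(i, n, k) for i in range(k)]


def crossval_select_lambdas(
    datasets: list,
    grid_delta: np.ndarray,
    grid_R: np.ndarray,
    k: int = 10,
    hyper: Hyperparameters | None = None,
) -> tuple[tuple[float, float], np.ndarray]:
    """Choose (lambda_Delta, lambda_R) by structured k-fold cross-validation.

    ``datasets`` is a list of (ReactivityDataset, Ensemble) pairs.  For each
    grid point and fold, weights are fitted on the training columns; the
    held-out columns are then predicted by re-running the E-step on them
    with the fitted weights fixed, and scored by mean squared error.
    Returns the grid point minimizing the mean CV error and the full error
    surface (len(grid_delta) x len(grid_R)).
    """
    base = hyper or Hyperparameters()
    if len(grid_delta) == 0 or len(grid_R) == 0:
        raise ValueError("empty hyperparameter grid")
    surface = np.zeros((len(grid_delta), len(grid_R)))
    for (a, ld), (b, lr) in product(enumerate(grid_delta), enumerate(grid_R)):
        from dataclasses import replace

        h = replace(base, lambda_Delta=float(ld), lambda_R=float(lr))
        errs = []
        for dataset, ensemble in datasets:
            n = dataset.matrix.shape[1]
            for test in strided_folds(n, k):
                train = np.setdiff1d(np.arange(n), test)
                _, res = fit(dataset, ensemble, h, col_idx=train)
                model, Y_test = build_model(
                    dataset, ensemble, h, initial_W=res.W, col_idx=test
                )
                d, C, _ = e_step(model, Y_test)
                model.d_vars, model.C = d, C
                pred = model.predicted()
                errs.append(float(((pred - Y_test) ** 2).mean()))
        surface[a, b] = float(np.mean(errs))
    best = np.unravel_index(np.argmin(surface), surface.shape)
    return (float(grid_delta[best[0]]), float(grid_R[best[1]])), surface
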