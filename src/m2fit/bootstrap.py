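"""Column-resampling bootstrap for weight uncertainties.

Sequence positions (columns of the reactivity matrix) are resampled with
replacement; variant rows are never resampled.  Each replicate refits the
full model warm-started from the full-data fit, and the final weight
estimate is the replicate average with bootstrap standard deviations as
uncertainties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .em import EnsembleModel, FitResult, Hyperparameters, fit
from .ensemble import Ensemble
from .rdat import ReactivityDataset

__all__ = ["BootstrapResult", "bootstrap_fit"]


@dataclass
class BootstrapResult:
    """Replicate weight matrices with their mean and standard deviation."""

    replicates: np.ndarray  # (B, m, r)
    mean_W: np.ndarray      # (m, r)
    sd_W: np.ndarray        # (m, r)
    n_failed: int = 0

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def snr(self) -> np.ndarray:
        """Signal-to-noise ratio of each weight (mean over sd)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.sd_W > 0, self.mean_W / self.sd_W, np.inf)


def bootstrap_fit(
    dataset: ReactivityDataset,
    ensemble: Ensemble,
    hyper: Hyperparameters | None = None,
    n_replicates: int = 100,
    seed: int | None = None,
    warm_start: EnsembleModel | FitResult | np.ndarray | None = None,
    max_failure_fraction: float = 0.2,
) -> BootstrapResult:
    """Refit the model on ``n_replicates`` column-resampled datasets.

    ``warm_start`` (a fitted model, fit result, or weight matrix) seeds each
    replicate's weights; when omitted a full-data fit is run first.  Each
    replicate draws its resampling indices from an independent child stream
    of ``seed``, so results do not depend on execution order.  Replicates
    that fail to converge are excluded and counted; more than
    ``max_failure_fraction`` failures is an error.
    """
    hyper = hyper or Hyperparameters()
    if warm_start is None:
        _, warm = fit(dataset, ensemble, hyper)
        W_init = warm.W
    elif isinstance(warm_start, (EnsembleModel, FitResult)):
        W_init = warm_start.W
    else:
        W_init = np.asarray(warm_start, dtype=float)

    # resampled-column problems can hover near the tolerance longer than the
    # full-data fit; give replicates twice the iteration budget
    from dataclasses import replace as _replace

    rep_hyper = _replace(
        hyper, max_em_iterations=max(2 * hyper.max_em_iterations, 100)
    )
    n = dataset.matrix.shape[1]
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    kept: list[np.ndarray] = []
    n_failed = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        cols = rng.integers(0, n, size=n)
        try:
            _, res = fit(dataset, ensemble, rep_hyper, initial_W=W_init, col_idx=cols)
        except FloatingPointError:
            n_failed += 1
            continue
        if not res.converged:
            n_failed += 1
            continue
        kept.append(res.W)
    if n_failed > max_failure_fraction * n_replicates:
        raise RuntimeError(
            f"{n_failed}/{n_replicates} bootstrap replicates failed to converge"
        )
    reps = np.stack(kept)
    return BootstrapResult(
        replicates=reps,
        mean_W=reps.mean(axis=0),
        sd_W=reps.std(axis=0),
        n_failed=n_failed,
    )
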