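"""Constrained factor-analysis model of M2 data and its hard-EM MAP fit.

The observed reactivity matrix is modeled as a weight mixture of hidden
per-structure reactivity profiles plus mutation-local perturbations and
position-wise Gaussian noise:

    D_obs[j,i] = sum_s W[j,s] * (D[s,i] + C[s,j,i]) + eps_i,
    eps_i ~ N(0, Psi_i)

with each weight row on the simplex, exponential priors on the hidden
reactivities (rate lambda_P for paired, lambda_U for unpaired positions,
one rate per collapsed motif variable), Gaussian N(0, 1/lambda_perturbed)
priors on the perturbations, a ridge N(0, 1/lambda_R) prior on weights, and
a Gaussian anchor tying wild-type/mutant weight differences to the folding
model's Boltzmann differences with precision lambda_Delta.

The fit alternates a hard E-step (per-position linear systems for D and C,
with D clamped to its nonnegative support) and an M-step (one
simplex-constrained quadratic program per measurement row for W, wild type
first, then a closed-form noise update), until the population-weighted
base-pair probability matrices of consecutive iterations agree within a
tolerance.

Throughout, all Gaussian prior lambdas are precisions (variance = 1/lambda).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import DEFAULT_KT, Ensemble, boltzmann_weights, EnergyTable
from .rdat import ReactivityDataset
from .structures import PairedStructure

__all__ = [
    "Hyperparameters",
    "EnsembleModel",
    "FitResult",
    "build_model",
    "log_posterior",
    "e_step",
    "m_step_weights",
    "update_noise",
    "fit",
    "solve_simplex_qp",
]

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class Hyperparameters:
    """Model hyperparameters; defaults are the calibrated values.

    lambda_P / lambda_U: exponential prior rates for paired / unpaired
    reactivities (means 1/0.5 = 2.0 and 1/0.2 = 5.0 reactivity units).
    lambda_perturbed: precision of the perturbation prior.
    lambda_R: ridge precision on weights; lambda_Delta: precision of the
    wild-type/mutant weight-difference anchor (both cross-validated).
    kT in kcal/mol converts free energies to Boltzmann weights.
    """

    lambda_P: float = 0.5
    lambda_U: float = 0.2
    lambda_perturbed: float = 2.0
    lambda_R: float = 0.26
    lambda_Delta: float = 5.0
    kT: float = DEFAULT_KT
    max_em_iterations: int = 50
    bp_matrix_tolerance: float = 0.01
    psi_floor: float = 1e-6

    def __post_init__(self):
        for name in ("lambda_P", "lambda_U", "lambda_perturbed", "lambda_R",
                     "lambda_Delta", "kT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.bp_matrix_tolerance < 1.0):
            raise ValueError("bp_matrix_tolerance must be in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperparameters":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class EnsembleModel:
    """Fitted state of the factor-analysis model over working columns.

    ``d_vars`` holds one value per collapsed hidden-reactivity variable;
    ``var_index[s, c]`` maps (structure, working column) to that variable and
    ``var_rate`` carries the variable's exponential prior rate.  ``C`` is
    zero off the perturbation mask.  Working columns may repeat sequence
    positions (bootstrap resampling); ``column_positions`` records the
    mapping back to 0-based sequence positions.
    """

    W: np.ndarray             # (m, r) simplex rows
    d_vars: np.ndarray        # (n_vars,)
    C: np.ndarray             # (r, m, n_cols)
    Psi: np.ndarray           # (n_cols,)
    var_index: np.ndarray     # (r, n_cols) int
    var_rate: np.ndarray      # (n_vars,)
    mask: np.ndarray          # (r, m, n_cols) bool
    W0: np.ndarray            # (m, r) Boltzmann initial weights
    wt_row: int
    hyper: Hyperparameters
    column_positions: np.ndarray  # (n_cols,) 0-based sequence positions
    structures: list[PairedStructure] = field(default_factory=list)
    #: upper bound for hidden reactivities (1.5x the data maximum).  The
    #: exponential prior is linear, so variables carried by ~zero weight
    #: would otherwise be unbounded above; the cap binds only such
    #: unidentifiable variables.
    d_cap: float = np.inf

    @property
    def shape(self) -> tuple[int, int, int]:
        m, r = self.W.shape
        return m, r, self.C.shape[2]

    def d_matrix(self) -> np.ndarray:
        """Hidden reactivities expanded to (r, n_cols)."""
        return self.d_vars[self.var_index]

    def profiles(self) -> np.ndarray:
        """Per-(structure, measurement, column) profile D + C."""
        return self.d_matrix()[:, None, :] + self.C

    def predicted(self) -> np.ndarray:
        """Model reconstruction W (D + C), shape (m, n_cols)."""
        return np.einsum("js,sjc->jc", self.W, self.profiles())

    def anchor_targets(self) -> np.ndarray:
        """|W0_WT - W0_j| per (measurement, structure)."""
        return np.abs(self.W0[self.wt_row] - self.W0)


def build_model(
    dataset: ReactivityDataset,
    ensemble: Ensemble,
    hyper: Hyperparameters | None = None,
    initial_W: np.ndarray | None = None,
    col_idx: np.ndarray | None = None,
) -> tuple[EnsembleModel, np.ndarray]:
    """Assemble the initial model state and the working data matrix.

    Rows flagged low-quality are excluded; ``col_idx`` selects (possibly
    repeated) dataset columns, the mechanism used by bootstrap resampling
    and cross-validation.  Initial weights default to the Boltzmann weights
    of the energy table; initial noise variances are the empirical
    per-column variances across measurements.
    """
    hyper = hyper or Hyperparameters()
    good = dataset.good_rows
    Y_all = dataset.matrix
    n_cols_total = Y_all.shape[1]
    if col_idx is None:
        col_idx = np.arange(n_cols_total)
    col_idx = np.asarray(col_idx, dtype=int)
    Y = Y_all[:, col_idx]
    positions = dataset.column_index()[col_idx]

    r = ensemble.n_structures
    m = len(good)
    n_cols = len(col_idx)

    # re-index collapsed variables per working column so duplicated columns
    # get independent hidden variables (bootstrap-with-replacement semantics)
    var_index = np.zeros((r, n_cols), dtype=int)
    rates: list[float] = []
    cm = ensemble.collapse
    for c, p in enumerate(positions):
        col = cm.var_index[:, p]
        uniq, inv = np.unique(col, return_inverse=True)
        var_index[:, c] = inv + len(rates)
        for v in uniq:
            rates.append(hyper.lambda_P if cm.var_paired[v] else hyper.lambda_U)
    var_rate = np.array(rates)

    mask = ensemble.mask[:, good, :][:, :, positions]
    dG = EnergyTable(ensemble.energies.dG[good], kT=hyper.kT)
    W0 = boltzmann_weights(dG)
    W = W0.copy() if initial_W is None else np.array(initial_W, dtype=float)
    if W.shape != (m, r):
        raise ValueError(f"initial weights shape {W.shape}, expected {(m, r)}")

    wt_row = dataset.wildtype_row()
    Psi = np.maximum(Y.var(axis=0), hyper.psi_floor)

    # E-step solution provides initial hidden reactivities
    d_vars = np.zeros(len(var_rate))
    C = np.zeros((r, m, n_cols))
    model = EnsembleModel(
        W=W, d_vars=d_vars, C=C, Psi=Psi, var_index=var_index,
        var_rate=var_rate, mask=mask, W0=W0, wt_row=wt_row, hyper=hyper,
        column_positions=positions, structures=ensemble.structures,
        d_cap=1.5 * float(Y.max()) if Y.max() > 0 else 1.0,
    )
    return model, Y


def log_posterior(model: EnsembleModel, Y: np.ndarray) -> float:
    """Joint log-posterior of weights, hidden profiles, perturbations and
    noise variances given the data (normalizing constant omitted)."""
    if np.any(model.Psi <= 0):
        raise ValueError("noise variances must be positive")
    m, r, n = model.shape
    h = model.hyper
    resid = Y - model.predicted()
    ll = (
        -0.5 * m * n * LOG2PI
        - 0.5 * m * np.log(model.Psi).sum()
        - 0.5 * (resid**2 / model.Psi).sum()
    )
    d_prior = float(np.sum(np.log(model.var_rate) - model.var_rate * model.d_vars))
    n_masked = int(model.mask.sum())
    c_prior = (
        0.5 * n_masked * (np.log(h.lambda_perturbed) - LOG2PI)
        - 0.5 * h.lambda_perturbed * float((model.C[model.mask] ** 2).sum())
    )
    w_prior = (
        0.5 * m * r * (np.log(h.lambda_R) - LOG2PI)
        - 0.5 * h.lambda_R * float((model.W**2).sum())
    )
    mut = [j for j in range(m) if j != model.wt_row]
    anchor = 0.0
    if mut:
        diff = np.abs(model.W[model.wt_row] - model.W[mut])
        t = model.anchor_targets()[mut]
        anchor = (
            0.5 * len(mut) * r * (np.log(h.lambda_Delta) - LOG2PI)
            - 0.5 * h.lambda_Delta * float(((diff - t) ** 2).sum())
        )
    total = ll + d_prior + c_prior + w_prior + anchor
    if not np.isfinite(total):
        raise FloatingPointError("non-finite log posterior")
    return float(total)


def e_step(
    model: EnsembleModel, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """MAP values of the hidden reactivities and perturbations.

    For each working column the stationarity conditions of the log-posterior
    in (D, C) form one linear system: one equation per collapsed variable
    active at the column plus one per masked (structure, measurement).
    Solutions are projected onto the exponential prior's support (D >= 0);
    the number of clamped variables is returned for diagnostics.
    """
    m, r, n = model.shape
    W = model.W
    lam_c = model.hyper.lambda_perturbed
    d_new = model.d_vars.copy()
    C_new = np.zeros_like(model.C)
    clamped = 0

    for c in range(n):
        col_vars = model.var_index[:, c]
        uniq = np.unique(col_vars)
        mask_c = model.mask[:, :, c]  # (r, m)
        A_full = np.zeros((m, len(uniq)))
        for k, v in enumerate(uniq):
            A_full[:, k] = W[:, col_vars == v].sum(axis=1)
        # variables carried by ~zero total weight are unidentifiable at this
        # column: skip them (their values persist), solve the rest
        active = (A_full**2).sum(axis=0) > 1e-8
        uniq = uniq[active]
        A = A_full[:, active]
        y = Y[:, c]
        psi = model.Psi[c]

        # The per-row perturbation block is rank one: eliminating the masked
        # C_(s,j) analytically shrinks row j's residual by
        # gamma_j = psi*lam_c / (psi*lam_c + sum_s W[j,s]^2), leaving a small
        # system in the collapsed variables alone (exact block elimination).
        u_sq = np.where(mask_c.T, W, 0.0) ** 2  # (m, r)
        unorm = u_sq.sum(axis=1)
        gamma = (psi * lam_c) / (psi * lam_c + unorm)
        H = (A * gamma[:, None]).T @ A
        rhs = A.T @ (gamma * y) - psi * model.var_rate[uniq]
        x, n_clamped = solve_box_qp(H, rhs, hi=model.d_cap)
        clamped += n_clamped
        d_new[uniq] = x

        # back-substitute for the perturbations given the clamped d
        resid = y - A_full @ d_new[np.unique(col_vars)]
        scale = resid / (psi * lam_c + unorm)  # (m,)
        Wm = np.where(mask_c, W.T, 0.0)  # (r, m)
        C_new[:, :, c] = Wm * scale[None, :]
    return d_new, C_new, clamped


def solve_box_qp(
    H: np.ndarray,
    rhs: np.ndarray,
    hi: float = np.inf,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> tuple[np.ndarray, int]:
    """Minimize (1/2) x'Hx - rhs'x subject to 0 <= x <= hi.

    Iterated active-set: solve the free subsystem (minimum-norm on singular
    blocks), project onto the box, and repeat until the active set is
    stable and KKT conditions hold.  Returns the solution and the number of
    coordinates pinned at a bound.  H must be symmetric PSD.
    """
    k = len(rhs)
    if k == 0:
        return np.zeros(0), 0
    x = np.zeros(k)
    free = np.zeros(k, dtype=bool)
    capped = np.zeros(k, dtype=bool)
    for _ in range(max_iter * max(k, 1)):
        grad = rhs - H @ x  # negative objective gradient
        cand = ~free & ~capped & (grad > tol)
        if not cand.any():
            # release capped coordinates whose gradient points inward
            rel = capped & (grad < -tol)
            if not rel.any():
                break
            capped[np.argmax(np.where(rel, -grad, -np.inf))] = False
            free[np.argmax(np.where(rel, -grad, -np.inf))] = True
            continue
        free[np.argmax(np.where(cand, grad, -np.inf))] = True
        # inner loop: restore feasibility of the free subproblem
        for _ in range(max_iter):
            idx = np.flatnonzero(free)
            b = rhs[idx] - H[np.ix_(idx, np.flatnonzero(capped))] @ \
                np.full(int(capped.sum()), hi)
            z, *_ = np.linalg.lstsq(H[np.ix_(idx, idx)], b, rcond=None)
            if np.all(z >= -tol) and np.all(z <= hi + tol):
                x[:] = 0.0
                x[capped] = hi
                x[idx] = np.clip(z, 0.0, hi)
                break
            # step toward z until the first coordinate hits a bound
            xf = x[idx]
            dz = z - xf
            with np.errstate(divide="ignore", invalid="ignore"):
                a_lo = np.where(dz < -tol, -xf / dz, np.inf)
                a_hi = np.where(dz > tol, (hi - xf) / dz, np.inf)
            alpha = min(1.0, float(np.minimum(a_lo, a_hi).min()))
            xf = np.clip(xf + alpha * dz, 0.0, hi)
            x[idx] = xf
            hit_lo = xf <= tol
            hit_hi = np.isfinite(hi) & (xf >= hi - tol)
            free[idx[hit_lo]] = False
            capped[idx[hit_hi]] = True
            free[idx[hit_hi]] = False
            if not free.any():
                break
    return np.clip(x, 0.0, hi), int(k - free.sum())


def _sign_pattern(model: EnsembleModel) -> np.ndarray:
    """Sign of (W_WT - W_j) from the current iterate; zeros treated as +1.
    Fixing the pattern makes the non-smooth anchor term quadratic within
    each measurement's program."""
    sigma = np.sign(model.W[model.wt_row][None, :] - model.W)
    sigma[sigma == 0] = 1.0
    return sigma


def m_step_weights(model: EnsembleModel, Y: np.ndarray) -> np.ndarray:
    """Simplex-constrained quadratic program per measurement row.

    The wild-type row is solved first (its anchor term couples it to every
    mutant's current weights); mutant rows follow with the wild type fixed.
    """
    m, r, n = model.shape
    h = model.hyper
    P = model.profiles()  # (r, m, n)
    t = model.anchor_targets()
    W_new = model.W.copy()
    mut = [j for j in range(m) if j != model.wt_row]

    def likelihood_terms(j: int) -> tuple[np.ndarray, np.ndarray]:
        Pj = P[:, j, :]  # (r, n)
        Qj = (Pj / model.Psi) @ Pj.T
        bj = Pj @ (Y[j] / model.Psi)
        return Qj, bj

    def wt_row_true_obj(w):
        Q, b = likelihood_terms(model.wt_row)
        val = 0.5 * w @ Q @ w - b @ w + 0.5 * h.lambda_R * (w**2).sum()
        for j in mut:
            val += 0.5 * h.lambda_Delta * ((np.abs(w - W_new[j]) - t[j]) ** 2).sum()
        return val

    def mut_row_true_obj(j, w, w_wt):
        Q, b = likelihood_terms(j)
        return (
            0.5 * w @ Q @ w - b @ w + 0.5 * h.lambda_R * (w**2).sum()
            + 0.5 * h.lambda_Delta * ((np.abs(w_wt - w) - t[j]) ** 2).sum()
        )

    def solve_wt(sigma_block):
        # sigma_block: (n_mut, r) signs for (w_s - W_js)
        Q, b = likelihood_terms(model.wt_row)
        Q = Q + h.lambda_R * np.eye(r)
        if mut:
            Q = Q + h.lambda_Delta * len(mut) * np.eye(r)
            centers = W_new[mut] + sigma_block * t[mut]
            b = b + h.lambda_Delta * centers.sum(axis=0)
        return solve_simplex_qp(Q, b, x0=W_new[model.wt_row])

    def solve_mut(j, sigma_row, w_wt):
        Q, b = likelihood_terms(j)
        Q = Q + (h.lambda_R + h.lambda_Delta) * np.eye(r)
        b = b + h.lambda_Delta * (w_wt - sigma_row * t[j])
        return solve_simplex_qp(Q, b, x0=W_new[j])

    # |W_WT - W_j| makes each row's program piecewise quadratic in the sign
    # pattern of the differences.  For small pattern spaces the regions are
    # enumerated exactly; otherwise the pattern is re-derived from each
    # pass's solution until self-consistent (regional ascent).
    from itertools import product as _product

    sigma = _sign_pattern(model)
    n_mut = len(mut)

    if mut and n_mut * r <= 10:
        best = None
        for bits in _product((-1.0, 1.0), repeat=n_mut * r):
            sig = np.array(bits).reshape(n_mut, r)
            w = solve_wt(sig)
            val = wt_row_true_obj(w)
            if best is None or val < best[1]:
                best = (w, val)
        W_new[model.wt_row] = best[0]
        w_wt = W_new[model.wt_row]
        for j in mut:
            bestj = None
            for bits in _product((-1.0, 1.0), repeat=r):
                w = solve_mut(j, np.array(bits), w_wt)
                val = mut_row_true_obj(j, w, w_wt)
                if bestj is None or val < bestj[1]:
                    bestj = (w, val)
            W_new[j] = bestj[0]
        return W_new

    for _ in range(4):
        W_new[model.wt_row] = solve_wt(sigma[mut]) if mut else solve_wt(None)
        w_wt = W_new[model.wt_row]
        for j in mut:
            W_new[j] = solve_mut(j, sigma[j], w_wt)
        sigma_new = np.sign(W_new[model.wt_row][None, :] - W_new)
        sigma_new[sigma_new == 0] = 1.0
        if (sigma_new == sigma).all():
            break
        sigma = sigma_new
    return W_new


def update_noise(model: EnsembleModel, Y: np.ndarray) -> np.ndarray:
    """Closed-form per-column noise variances: mean squared residual,
    floored at a small positive constant."""
    resid = Y - model.predicted()
    return np.maximum((resid**2).mean(axis=0), model.hyper.psi_floor)


def solve_simplex_qp(
    Q: np.ndarray,
    b: np.ndarray,
    x0: np.ndarray | None = None,
    tol: float = 1e-10,
) -> np.ndarray:
    """Minimize (1/2) x'Qx - b'x subject to sum(x) = 1, x >= 0.

    Primal active-set method with closed forms for one- and two-dimensional
    problems; falls back to SLSQP if the active-set iteration stalls.
    ``Q`` must be symmetric positive (semi)definite.
    """
    r = len(b)
    if r == 1:
        return np.ones(1)
    if r == 2:
        a = Q[0, 0] - 2.0 * Q[0, 1] + Q[1, 1]
        lin = b[0] - b[1] + Q[1, 1] - Q[0, 1]

        def f(w):
            x = np.array([w, 1.0 - w])
            return 0.5 * x @ Q @ x - b @ x

        if a > tol:
            w = min(1.0, max(0.0, lin / a))
        else:
            w = 0.0 if f(0.0) <= f(1.0) else 1.0
        return np.array([w, 1.0 - w])

    x = np.full(r, 1.0 / r) if x0 is None else np.clip(np.asarray(x0, float), 0, None)
    s = x.sum()
    x = x / s if s > 0 else np.full(r, 1.0 / r)
    active = x <= tol
    x[active] = 0.0
    if active.any():
        x /= x.sum()

    ones = np.ones(r)
    for _ in range(50 * r):
        free = ~active
        nf = int(free.sum())
        K = np.zeros((nf + 1, nf + 1))
        K[:nf, :nf] = Q[np.ix_(free, free)]
        K[:nf, nf] = 1.0
        K[nf, :nf] = 1.0
        rhs = np.append(b[free], 1.0)
        try:
            sol = np.linalg.solve(K, rhs)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
        z, nu = sol[:nf], sol[nf]
        if np.all(z >= -tol):
            x_new = np.zeros(r)
            x_new[free] = np.maximum(z, 0.0)
            x_new /= x_new.sum()
            grad = Q @ x_new - b + nu
            mu = grad[active]
            if mu.size == 0 or mu.min() >= -1e-8:
                return x_new
            release = np.flatnonzero(active)[int(np.argmin(mu))]
            active[release] = False
            x = x_new
        else:
            xf = x[free]
            dz = z - xf
            bad = dz < -tol
            with np.errstate(divide="ignore", invalid="ignore"):
                alphas = np.where(bad, -xf / dz, np.inf)
            k = int(np.argmin(alphas))
            alpha = min(1.0, float(alphas[k]))
            xf = xf + alpha * dz
            x[free] = np.maximum(xf, 0.0)
            block = np.flatnonzero(free)[k]
            x[block] = 0.0
            active[block] = True
            if active.sum() >= r:  # pathological; keep one coordinate free
                active[np.argmax(x)] = False

    from scipy.optimize import minimize  # fallback, rarely reached

    res = minimize(
        lambda v: 0.5 * v @ Q @ v - b @ v,
        x0=np.full(r, 1.0 / r),
        jac=lambda v: Q @ v - b,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * r,
        constraints=[{"type": "eq", "fun": lambda v: v.sum() - 1.0,
                      "jac": lambda v: ones}],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    v = np.clip(res.x, 0.0, None)
    return v / v.sum()


@dataclass
class FitResult:
    """Outcome of an EM fit (optionally aggregated over bootstrap)."""

    W: np.ndarray                       # (m, r) weights (mean over replicates
                                        # when bootstrapped)
    predicted: np.ndarray               # (m, n_cols) reconstructed reactivities
    structure_profiles: np.ndarray      # (r, n_cols) hidden profiles D
    log_posterior_trace: list[float]
    n_iterations: int
    converged: bool
    W_sd: np.ndarray | None = None      # bootstrap standard deviations
    clamped_fraction: float = 0.0       # share of E-step solves hitting D>=0


def _bp_values(W: np.ndarray, structures: list[PairedStructure]) -> np.ndarray:
    """Per-variant probabilities of every base pair in the ensemble union;
    the flattened representation of all weighted base-pair matrices."""
    all_pairs = sorted({p for s in structures for p in s.pairs})
    if not all_pairs:
        return np.zeros((W.shape[0], 0))
    ind = np.zeros((W.shape[1], len(all_pairs)))
    index = {p: k for k, p in enumerate(all_pairs)}
    for s_idx, s in enumerate(structures):
        for p in s.pairs:
            ind[s_idx, index[p]] = 1.0
    return W @ ind


def fit(
    dataset: ReactivityDataset,
    ensemble: Ensemble,
    hyper: Hyperparameters | None = None,
    initial_W: np.ndarray | None = None,
    col_idx: np.ndarray | None = None,
) -> tuple[EnsembleModel, FitResult]:
    """Hard-EM MAP fit of the full model.

    Alternates the E-step, the weight M-step and the noise update until the
    maximum absolute change in every variant's weighted base-pair
    probability matrix falls below ``hyper.bp_matrix_tolerance`` (default
    1%) or the iteration cap is reached.
    """
    hyper = hyper or Hyperparameters()
    model, Y = build_model(dataset, ensemble, hyper, initial_W, col_idx)
    trace: list[float] = []
    total_solves = 0
    total_clamped = 0
    converged = False
    n_iter = 0

    bp_prev = _bp_values(model.W, model.structures)
    for n_iter in range(1, hyper.max_em_iterations + 1):
        d_new, C_new, clamped = e_step(model, Y)
        model.d_vars, model.C = d_new, C_new
        total_clamped += clamped
        total_solves += len(model.d_vars)
        model.W = m_step_weights(model, Y)
        model.Psi = update_noise(model, Y)
        trace.append(log_posterior(model, Y))
        bp_now = _bp_values(model.W, model.structures)
        delta = np.abs(bp_now - bp_prev).max() if bp_now.size else 0.0
        bp_prev = bp_now
        if delta < hyper.bp_matrix_tolerance:
            converged = True
            break

    result = FitResult(
        W=model.W.copy(),
        predicted=model.predicted(),
        structure_profiles=model.d_matrix(),
        log_posterior_trace=trace,
        n_iterations=n_iter,
        converged=converged,
        clamped_fraction=total_clamped / max(total_solves, 1),
    )
    return model, result
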