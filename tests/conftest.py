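"""Shared fixtures: all synthetic, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import m2fit as mf
from m2fit.structures import parse_dot_bracket

#: the two degenerate registers of the 30-nt bistable fixture sequence
BISTABLE_SEQ = mf.bistable_sequence("GGCAGCUC", "UUC")
REGISTER_A = "((((((((...))))))))..........."
REGISTER_B = "...........((((((((...))))))))"


@pytest.fixture(scope="session")
def toy_backend():
    return mf.ToyBackend()


@pytest.fixture(scope="session")
def two_state(toy_backend):
    """Two-state dataset: truth restricted to the two bistable registers."""
    A, B = parse_dot_bracket(REGISTER_A), parse_dot_bracket(REGISTER_B)
    spec = mf.SimulationSpec(
        sequence=BISTABLE_SEQ, seed=11, measurement_noise_sd=0.05
    )
    ds, truth, ens = mf.simulate_dataset(spec, toy_backend, structures=[A, B])
    return ds, truth, ens


@pytest.fixture(scope="session")
def bistable_full(toy_backend):
    """Full toy-ensemble dataset on the bistable sequence."""
    spec = mf.SimulationSpec(sequence=BISTABLE_SEQ, seed=7)
    ds, truth, ens = mf.simulate_dataset(spec, toy_backend)
    return ds, truth, ens


@pytest.fixture(scope="session")
def two_state_fit(two_state):
    ds, truth, ens = two_state
    model, res = mf.fit(ds, ens)
    return model, res


def make_tiny_instance(rng: np.random.Generator, n_structures: int = 2,
                       n_rows: int = 3):
    """A tiny random model state for step-wise oracle comparisons.

    5 positions, 2-3 structures, wild type plus 2-3 single mutants; random
    simplex weights, random noise variances, uncapped hidden reactivities.
    """
    from m2fit.em import build_model
    from m2fit.ensemble import assemble_ensemble
    from m2fit.rdat import ReactivityDataset, Variant

    n = 5
    seq = "GCGCG"
    comp = {"C": "G", "G": "C"}
    dbs = ["(...)", ".....", "((.))"][:n_structures]
    structs = [parse_dot_bracket(db) for db in dbs]
    variants = [mf.Variant()] + [
        Variant(((1 + k % 3, seq[1 + k % 3], comp[seq[1 + k % 3]]),))
        for k in range(n_rows - 1)
    ]
    ds = ReactivityDataset(
        sequence=seq,
        reactivities=rng.exponential(3.0, (n_rows, n)),
        variants=variants,
    )
    ens = assemble_ensemble(structs, variants, n, rng.normal(0, 1, (n_rows, len(structs))))
    model, Y = build_model(ds, ens)
    model.W = rng.dirichlet(np.ones(len(structs)) * 2, size=n_rows)
    model.Psi = rng.uniform(0.5, 2.0, n)
    model.d_cap = np.inf
    return model, Y


def random_nested_structure(rng: np.random.Generator, n: int):
    """Random pseudoknot-free structure via random balanced insertion."""
    chars = ["."] * n
    for _ in range(rng.integers(0, n // 3 + 1)):
        # pick a random span and pair its ends if free and wide enough
        i, j = sorted(rng.integers(0, n, 2))
        if j - i >= 4 and chars[i] == "." and chars[j] == ".":
            enclosed = chars[i + 1 : j]
            if enclosed.count("(") == enclosed.count(")"):
                chars[i], chars[j] = "(", ")"
    return parse_dot_bracket("".join(chars))
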