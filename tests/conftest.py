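"""Shared fixtures: small simulated libraries and genomes with known truth.

Expensive end-to-end artefacts are session-scoped so the acceptance tests and
the analytic-identity tests reuse one simulation.
"""

from __future__ import annotations

import numpy as np
import pytest

from selexdimer.motifs import iupac_to_ppm
from selexdimer.synthetic import (
    BindingMode,
    BindingModel,
    make_er1a_like_model,
    simulate_selex,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_reads(n: int, length: int, seed: int) -> list[str]:
    g = np.random.default_rng(seed)
    lut = np.array(list("ACGT"))
    return ["".join(lut[g.integers(0, 4, length)]) for _ in range(n)]


@pytest.fixture(scope="session")
def monomer_only_library():
    """Small SELEX simulation with a single planted monomer mode."""
    motif = iupac_to_ppm("ACCTAAT", name="planted")
    mode = BindingMode(motif=motif, activity=float(np.log(2)), name="planted")
    model = BindingModel(modes=[mode])
    lib, truth = simulate_selex(model, n_ligands=20_000, cycles=3, seed=7)
    return lib, truth, motif


@pytest.fixture(scope="session")
def er1a_recovery():
    """Full planted-specificity-change recovery at the documented scale."""
    from selexdimer.pipeline import recover_er1a

    return recover_er1a(seed=1)


@pytest.fixture(scope="session")
def genome_eval():
    from selexdimer.pipeline import genome_evaluation

    return genome_evaluation(seed=2)


@pytest.fixture(scope="session")
def promoter_eval():
    from selexdimer.pipeline import promoter_evaluation

    return promoter_evaluation(seed=4)
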