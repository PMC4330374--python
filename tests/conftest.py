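import math

import numpy as np
import pytest

from ribobench import EnergyModel, RnaSequence
from ribobench.fold import structure_energy, enumerate_structures


@pytest.fixture(scope="session")
def default_model() -> EnergyModel:
    return EnergyModel()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_sequence(rng: np.random.Generator, n: int) -> RnaSequence:
    return RnaSequence("rand", "".join(rng.choice(list("ACGU"), size=n)))


def random_model(rng: np.random.Generator, with_stacks: bool = False) -> EnergyModel:
    pair_types = ["AU", "UA", "GC", "CG", "GU", "UG"]
    stacks = None
    if with_stacks:
        stacks = {
            f"{a}/{b}": float(-rng.uniform(0, 2))
            for a in pair_types
            for b in pair_types
        }
    return EnergyModel(
        pair_energies={p: float(-rng.uniform(0.5, 4)) for p in pair_types},
        stack_energies=stacks,
        min_hairpin_loop=int(rng.integers(0, 4)),
        temperature_kT=float(rng.uniform(0.3, 1.0)),
    )


def brute_force_ensemble(seq: RnaSequence, model: EnergyModel):
    """Independent reference: Z, pair probabilities and MFE by enumeration."""
    structs = enumerate_structures(seq, model)
    kt = model.temperature_kT
    weights = [math.exp(-s.energy / kt) for s in structs]
    Z = sum(weights)
    probs = {}
    for s, w in zip(structs, weights):
        for pr in s.pairs:
            probs[pr] = probs.get(pr, 0.0) + w / Z
    emin = min(s.energy for s in structs)
    return Z, probs, emin
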