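import dataclasses

import numpy as np
import pytest

from satarscan.io import RunConfig
from satarscan.pipeline import run_pipeline
from satarscan.simulate import SimulationSpec, simulate

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def brute_force_ssrs(seq, thresholds):
    """Independent SSR oracle: for every start position and motif
    length, extend a perfect repeat maximally and apply thresholds.
    Mirrors the contract of find_ssrs but shares no code with it."""
    from satarscan.ssr import canonical_motif

    seq = seq.upper()
    n = len(seq)
    found = set()
    for m, min_units in thresholds.min_units_by_motif_length.items():
        for i in range(n - m + 1):
            unit = seq[i:i + m]
            if any(c not in "ACGT" for c in unit):
                continue
            # shortest-motif rule: skip internally periodic units
            if any(unit == unit[:p] * (m // p)
                   for p in range(1, m) if m % p == 0):
                continue
            # left-maximality at base resolution
            if i > 0 and seq[i - 1] in "ACGT" and seq[i - 1] == seq[i + m - 1]:
                continue
            j = i + m
            while j < n and seq[j] in "ACGT" and seq[j] == seq[j - m]:
                j += 1
            units = (j - i) // m
            if units >= min_units:
                found.add((i, i + units * m, canonical_motif(unit), units))
    return sorted(found)


# --- shared simulation/pipeline runs (expensive; session-scoped) -----

_CACHE = {}


def run_default_recovery(seed: int):
    """Default synthetic assembly (10 x 500 kb scaffolds, 3 families)
    pushed through the full pipeline."""
    key = ("recovery", seed)
    if key not in _CACHE:
        sim = simulate(SimulationSpec(seed=seed))
        config = RunConfig(out_dir="")
        result = run_pipeline(config, assembly_a=sim.assembly_a,
                              write_outputs=False)
        _CACHE[key] = (sim, result)
    return _CACHE[key]


def run_nested(seed: int, n_nested: int):
    key = ("nested", seed, n_nested)
    if key not in _CACHE:
        sim = simulate(SimulationSpec(n_scaffolds=4, scaffold_length=300_000,
                                      n_nested=n_nested, n_arrays=3,
                                      n_fusions=1, seed=seed))
        config = RunConfig(out_dir="")
        config = dataclasses.replace(
            config, probing=dataclasses.replace(config.probing,
                                                keep_partial=True))
        result = run_pipeline(config, assembly_a=sim.assembly_a,
                              write_outputs=False)
        _CACHE[key] = (sim, result)
    return _CACHE[key]


def run_comparative(seed: int):
    key = ("comparative", seed)
    if key not in _CACHE:
        sim = simulate(SimulationSpec(seed=seed, make_b=True))
        config = RunConfig(out_dir="")
        result = run_pipeline(config, assembly_a=sim.assembly_a,
                              assembly_b=sim.assembly_b, write_outputs=False)
        _CACHE[key] = (sim, result)
    return _CACHE[key]
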