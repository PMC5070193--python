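"""Shared fixtures: tiny hand-built models and a scaled-down synthetic
dataset (12 eukaryotes + 4 archaea) reused across module tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from tandemaaa.seqio import MultipleAlignment
from tandemaaa.profile_hmm import ProfileHMM
from tandemaaa import synthgen as sg

warnings.filterwarnings("ignore", message=".*uncommon residue.*")


def single_path_model(p_match_a: float = 1.0) -> ProfileHMM:
    """L=1 model emitting A with probability ``p_match_a`` (rest uniform),
    forced B->M->E transitions, uniform background."""
    em = np.full((1, 20), (1.0 - p_match_a) / 19.0)
    em[0, 0] = p_match_a
    ins = np.full((2, 20), 1.0 / 20.0)
    t = {k: np.array([v]) for k, v in
         [("mm", 1.0), ("mi", 0.0), ("md", 0.0), ("im", 0.5), ("ii", 0.5),
          ("dm", 1.0), ("dd", 0.0)]}
    return ProfileHMM("single", em, ins, t,
                      background=np.full(20, 1.0 / 20.0))


def random_model(rng: np.random.Generator, L: int) -> ProfileHMM:
    """A small random (but valid) profile HMM for property tests."""
    em = rng.dirichlet(np.ones(20) * 0.5, size=L)
    ins = np.tile(np.full(20, 0.05), (L + 1, 1))
    mm = rng.uniform(0.6, 0.95, L)
    mi = (1 - mm) * rng.uniform(0.2, 0.8, L)
    md = 1 - mm - mi
    md[0] = 1 - mm[0]   # begin state has no insert branch
    im = rng.uniform(0.3, 0.7, L)
    dm = rng.uniform(0.3, 0.9, L)
    t = {"mm": mm, "mi": mi, "md": md, "im": im, "ii": 1 - im,
         "dm": dm, "dd": 1 - dm}
    t["mi"][0] = 0.0
    return ProfileHMM(f"rand{L}", em, ins, t,
                      background=np.full(20, 0.05))


@pytest.fixture(scope="session")
def small_config() -> sg.SynthConfig:
    cfg = sg.default_config()
    cfg.n_euk_species = 12
    cfg.n_arch_species = 4
    return cfg


@pytest.fixture(scope="session")
def small_dataset(small_config) -> sg.Dataset:
    return sg.generate(small_config, seed=11)


@pytest.fixture(scope="session")
def small_library(small_dataset):
    """Calibrated model library (D1/D2 + N + tail helix) for the small
    dataset, built from truth-derived seed alignments."""
    from tandemaaa import pipeline as pl
    from tandemaaa.profile_hmm import build_hmm, calibrate, filter_alignment
    seeds = pl.seed_truth_alignments(small_dataset, include_accessory=True)
    library = {}
    for name, aln in seeds.items():
        filtered, _ = filter_alignment(aln)
        h = build_hmm(filtered, name)
        calibrate(h, n_random=1000, length_law=("fixed", 300),
                  seed=np.random.default_rng([3, len(name)]))
        library[name] = h
    return library


@pytest.fixture(scope="session")
def small_state(small_dataset):
    """Converged iterative classification of the small dataset."""
    from tandemaaa import pipeline as pl
    from tandemaaa.classify import ClassifyConfig
    return pl.run_iterative_classification(
        small_dataset, ClassifyConfig(seed=11, calibration_n=1000))


@pytest.fixture()
def toy_alignment() -> MultipleAlignment:
    return MultipleAlignment({
        "a": "MKV-LT",
        "b": "MKVALT",
        "c": "MRV-LT",
        "d": "M-VAL-",
    })
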