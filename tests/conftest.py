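"""Shared fixtures: the standard synthetic two-layer fixture and the full
module-construction chain run on it (computed once per session)."""

from __future__ import annotations

import collections

import numpy as np
import pytest

from modmix import (
    SimConfig,
    eigenfeatures_for_all,
    generate_multiomics,
    integrate_all,
    modules_from_matrix,
)
from modmix.io import AbundanceMatrix
from modmix.preprocess import standardize


@pytest.fixture(scope="session")
def standard_fixture():
    """The standard planted fixture: 2 layers, 6 modules of 30 features,
    within-module correlation 0.6, two cross-layer links of strength 0.9,
    100 samples, seed 42."""
    return generate_multiomics(SimConfig())


@pytest.fixture(scope="session")
def standard_run(standard_fixture):
    """Full chain (standardize -> GGM -> TOM -> hybrid cut -> eigenfeatures
    -> integration) on the standard fixture."""
    matrices, meta, truth = standard_fixture
    out = {"truth": truth, "meta": meta, "matrices": {}, "assignments": {},
           "eigensets": {}, "rhos": {}}
    eigensets = []
    for m in matrices:
        mp = standardize(m)
        assign, dend, tom, rho = modules_from_matrix(mp)
        es = eigenfeatures_for_all(mp, assign)
        out["matrices"][m.omics_name] = mp
        out["assignments"][m.omics_name] = assign
        out["eigensets"][m.omics_name] = es
        out["rhos"][m.omics_name] = rho
        eigensets.append(es)
    out["edges"] = integrate_all(eigensets)
    return out


def label_to_true_module(assign, truth, dataset):
    """Map each detected module label to the majority planted module."""
    tm = truth.true_modules[dataset]
    mapping = {}
    for label in assign.module_sizes:
        counts = collections.Counter(tm[f] for f in assign.members(label))
        mapping[label] = counts.most_common(1)[0][0]
    return mapping


def make_matrix(values, name="test") -> AbundanceMatrix:
    values = np.asarray(values, dtype=float)
    return AbundanceMatrix(
        [f"f{i+1}" for i in range(values.shape[0])],
        [f"s{j+1}" for j in range(values.shape[1])],
        values,
        name,
    )
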