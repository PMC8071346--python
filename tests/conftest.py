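"""Shared fixtures: a toy genome cohort and a trained reference model.

Everything is generated at run time by the synthetic-data module on a
~60 Mb five-chromosome toy genome, keeping the whole suite desk-scale.
"""

from __future__ import annotations

import warnings

import pytest

from cnvscreen.binning import scale_compartments
from cnvscreen.normalize import (
    NormalizationConfig,
    loess_gc_correct,
    train_reference_model,
)
from cnvscreen.synthetic import SyntheticPanelSpec, make_panel, make_reference_genome


TOY_PANEL_SIZE = 40  # enough for a stable PCA basis; keeps fixtures fast


@pytest.fixture(scope="session")
def toy_spec() -> SyntheticPanelSpec:
    return SyntheticPanelSpec(n_samples=TOY_PANEL_SIZE, seed=7)


@pytest.fixture(scope="session")
def toy_genome(toy_spec):
    return make_reference_genome(toy_spec)


@pytest.fixture(scope="session")
def toy_grid(toy_genome):
    return toy_genome[0]


@pytest.fixture(scope="session")
def toy_gc(toy_genome):
    return toy_genome[1]


@pytest.fixture(scope="session")
def toy_panel(toy_spec, toy_genome):
    grid, gc, truth = toy_genome
    return make_panel(toy_spec, grid, gc, truth)


@pytest.fixture(scope="session")
def toy_corrected(toy_panel, toy_genome):
    grid, gc, _ = toy_genome
    return [
        loess_gc_correct(scale_compartments(s, grid), gc, grid)
        for s in toy_panel[0]
    ]


@pytest.fixture(scope="session")
def toy_model(toy_corrected, toy_genome):
    grid, gc, _ = toy_genome
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # panel smaller than the recommended 100
        return train_reference_model(toy_corrected, gc, grid, NormalizationConfig())
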