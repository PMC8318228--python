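"""Shared fixtures: small geometric fixtures plus the (expensive) scenario
runs, computed once per session and reused by scenario, metric and
acceptance tests."""

import numpy as np
import pytest

import blastomech as bm
from blastomech import embryo_scenarios as es
from blastomech.neighborhoods import Population


@pytest.fixture(scope="session")
def params():
    return bm.SimParams()


@pytest.fixture()
def single_cell_pop():
    def make(spec=None, center=(0.0, 0.0, 0.0), polarity=(0.0, 0.0, 1.0),
             cell_type="EPI"):
        pop = Population()
        mesh = bm.build_epithelial_cell(spec or bm.CellShapeSpec(),
                                        center=center, polarity=polarity)
        pop.add_cell(mesh, cell_type, (0, 0, 0))
        pop.rebuild_cell_pairs()
        return pop
    return make


@pytest.fixture()
def two_cell_pop():
    """Two abutting columnar cells on neighbouring lattice sites."""
    def make(cell_types=("EPI", "EPI"), separation=1.0):
        pop = Population()
        spec = bm.CellShapeSpec()
        for k, ct in enumerate(cell_types):
            mesh = bm.build_epithelial_cell(spec,
                                            center=(k * separation, 0.0, 0.0))
            pop.add_cell(mesh, ct, (k, 0, 0))
        pop.rebuild_cell_pairs()
        return pop
    return make


def _embryo(params, lumen, detach):
    pop = es.build_rosette_epiblast(params=params)
    es.build_te_monolayer(on_top_of=pop, params=params)
    sc = es.default_implantation_scenario(lumen=lumen, detach=detach)
    series = es.run_scenario(sc, pop, params)
    return pop, series.to_frame()


@pytest.fixture(scope="session")
def implantation_detach(params):
    """Full implantation with lumenogenesis and TE/EPI detachment (t=9000)."""
    return _embryo(params, lumen=True, detach=True)


@pytest.fixture(scope="session")
def implantation_push(params):
    """Pushing-distance experiment (no detachment, t=6000), with lumen."""
    return _embryo(params, lumen=True, detach=False)


@pytest.fixture(scope="session")
def implantation_push_nolumen(params):
    """Pushing-distance control without lumenogenesis (t=6000)."""
    return _embryo(params, lumen=False, detach=False)


@pytest.fixture(scope="session")
def lumenogenesis_run(params):
    """Epiblast alone: lumen opened at t=0, 2000 steps."""
    pop = es.build_rosette_epiblast(params=params)
    sc = es.Scenario(n_steps=2000, sample_interval=50, snapshot_times=())
    sc.add(0, "open_lumen", r_lum=0.25)
    series = es.run_scenario(sc, pop, params)
    return pop, series.to_frame()


def smooth(x, window=5):
    """Centered moving average used by the trend assertions."""
    x = np.asarray(x, dtype=float)
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="valid")
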