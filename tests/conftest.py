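"""Shared fixtures.

The canonical scenario trio is expensive (about two minutes), so it runs at
most once per session and is shared by the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from ocuflow.geometry import GeometryParams, build_outflow_domain


@pytest.fixture(scope="session")
def small_geometry() -> GeometryParams:
    """A reduced outflow domain for fast pipeline tests."""
    return GeometryParams(tm_depth=30.0, channel_length=8.0,
                          channel_height=4.0, tissue_band=4.0)


@pytest.fixture(scope="session")
def small_mesh(small_geometry):
    return build_outflow_domain(small_geometry, resolution=1.0)


@pytest.fixture(scope="session")
def default_mesh():
    return build_outflow_domain(GeometryParams(), resolution=0.5)


@pytest.fixture(scope="session")
def canonical_results(default_mesh):
    """The three canonical scenario bundles on one shared mesh."""
    from ocuflow.pipeline import canonical_scenarios, run_scenario

    bundles = {}
    for cfg in canonical_scenarios():
        bundles[cfg.name] = run_scenario(cfg, mesh=default_mesh)
    return bundles


@pytest.fixture(scope="session")
def zero_charge_bundle(default_mesh):
    """EFSI at 15 mmHg with the zeta potential set to zero."""
    from dataclasses import replace

    from ocuflow.electrostatics import ElectroProperties
    from ocuflow.pipeline import canonical_scenarios, run_scenario

    cfg = canonical_scenarios()[2]
    electro = replace(cfg.params.electro, zeta_potential=0.0)
    cfg = replace(cfg, name="EFSI_15_zeta0",
                  params=replace(cfg.params, electro=electro))
    return run_scenario(cfg, mesh=default_mesh)
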