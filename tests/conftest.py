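"""Shared fixtures: synthetic meshes reused across the suite.

Heavy products (the fine LV for fibre-angle measurement, the contraction
trace) are session-scoped so each is computed once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from cardioem.eikonal_ep import StimulusProtocol, build_conduction, solve_eikonal
from cardioem.fibres_uvc import assign_fibres, measure_fibre_angles
from cardioem.mechanics import (
    ContractionSchedule,
    MaterialConfig,
    default_lv_bcs,
    run_contraction,
)
from cardioem.synthetic_anatomy import (
    EllipsoidSpec,
    SlabSpec,
    generate_lv_ellipsoid,
    generate_slab,
    place_electrode,
)


@pytest.fixture(scope="session")
def slab_cv():
    """60×20×20 mm slab at 1 mm with fibres along x (CV verification fixture)."""
    return generate_slab(SlabSpec(extents=(60.0, 20.0, 20.0), edge_length=1.0))


@pytest.fixture(scope="session")
def slab_small():
    """Small slab (≤ 5000 tets) for oracle comparisons."""
    return generate_slab(SlabSpec(extents=(24.0, 9.0, 9.0), edge_length=1.5))


@pytest.fixture(scope="session")
def lv_coarse():
    """Mid-size idealised LV (a=b=20, c=60, 8 mm wall) at 2.5 mm."""
    spec = EllipsoidSpec(a_endo=20, b_endo=20, c_endo=60, wall_thickness=8, edge_length=2.5)
    mesh, surfaces = generate_lv_ellipsoid(spec)
    return spec, mesh, surfaces


@pytest.fixture(scope="session")
def lv_fine_fibres():
    """Default (heart-failure-scale) LV at 1.5 mm with rule-based fibres and
    the measured helix/sheet angles."""
    spec = EllipsoidSpec()  # edge_length 1.5 mm
    mesh, surfaces = generate_lv_ellipsoid(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assign_fibres(mesh, surfaces)
        angles = measure_fibre_angles(mesh, surfaces)
    return spec, mesh, surfaces, angles


@pytest.fixture(scope="session")
def lv_mech():
    """Desk-scale LV (~14k tets) with fibres and an apical-stimulus activation map."""
    spec = EllipsoidSpec(edge_length=6.0, min_transmural_layers=3)
    mesh, surfaces = generate_lv_ellipsoid(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assign_fibres(mesh, surfaces)
    cond = build_conduction(mesh, surfaces)
    endo = surfaces.nodes_of("lv_endo")
    apex_pt = mesh.nodes[surfaces.node_sets["apex"][0]]
    d = np.linalg.norm(mesh.nodes[endo] - apex_pt, axis=1)
    place_electrode(mesh, surfaces, mesh.nodes[endo[np.argmin(d)]], radius=5.0, surface="lv_endo")
    amap = solve_eikonal(mesh, cond, StimulusProtocol.from_label(mesh))
    return spec, mesh, surfaces, amap


@pytest.fixture(scope="session")
def lv_contraction(lv_mech):
    """Free-contraction trace of one beat on the desk-scale LV.

    Schedule: 10 ms quasi-static steps to 500 ms, which covers the rise and
    the volume minimum of the default twitch.
    """
    spec, mesh, surfaces, amap = lv_mech
    trace = run_contraction(
        mesh,
        surfaces,
        MaterialConfig.lv_defaults(),
        default_lv_bcs(mesh, surfaces),
        amap,
        ContractionSchedule(dt=10.0, t_end=500.0),
    )
    return spec, mesh, surfaces, amap, trace
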