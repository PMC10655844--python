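"""Shared fixtures: synthetic heads, a flat grid mesh, and one mid-scale
end-to-end build reused by the optimizer and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

import seegrs as sg
from seegrs import trajectories as tj


@pytest.fixture(scope="session")
def head3():
    """Folded synthetic head at subdivision 3 (1280 cortex faces)."""
    return sg.make_synthetic_head(sg.SyntheticHeadSpec())


@pytest.fixture(scope="session")
def sphere3():
    """Unfolded (spherical-cortex) head at subdivision 3."""
    return sg.make_synthetic_head(sg.SyntheticHeadSpec(fold_amplitude=0.0))


@pytest.fixture(scope="session")
def flat_grid():
    """Planar unit-grid mesh, 60 x 60 mm, 1 mm cells (7200 triangles)."""
    n = 61
    xs = np.arange(n, dtype=float)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + n, a + 1])
            faces.append([a + 1, a + n, a + n + 1])
    return sg.SurfaceMesh(verts, np.array(faces))


@pytest.fixture(scope="session")
def midscale(head3):
    """One seeded mid-scale planning problem shared across tests:
    candidate trajectories on the folded head, their collision matrix,
    the analytic lead field at the stacked contacts, the default-source
    patch lead field, and a 45-degree-cap ROI."""
    head = head3
    sulci = sg.derive_sulci_surface(head.cortex)
    entries, normals = tj.sample_entries(head.scalp, (0, 0, 1), 60.0,
                                         n=40, seed=7)
    cands, line = [], 0
    for e, nrm in zip(entries, normals):
        for d in tj.sample_directions(nrm, 10.0, 6, seed=7):
            cands.extend(tj.discretize_depths(e, d, line))
            line += 1
    tset = tj.filter_valid(cands, sulci, head.skull, (0, 0, 0), (1, 0, 0))
    tset = tj.downsample_lines(tset, 600, seed=7)
    coll = tj.collision_matrix(tset.trajectories)
    contacts = np.concatenate([t.contact_points for t in tset.trajectories])
    lf = sg.build_lead_field(sg.sources_from_cortex(head.cortex), contacts,
                             sg.ConductivityModel())
    patches = sg.grow_patches(head.cortex, sg.DEFAULT_AREA_CM2)
    plf = sg.build_patch_lead_field(lf, patches, sg.DEFAULT_DENSITY,
                                    head.cortex)
    c = head.cortex.centroids
    cos = (c @ np.array([0, 0, 1.0])) / np.linalg.norm(c, axis=1)
    roi = sg.ROI.from_ids(np.flatnonzero(cos >= np.cos(np.radians(45.0))),
                          "dorsal-cap")
    return {
        "head": head, "sulci": sulci, "tset": tset, "collision": coll,
        "lead_field": lf, "patches": patches, "patch_lf": plf, "roi": roi,
        "electrodes": sg.contact_rows_for(len(tset)),
    }
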