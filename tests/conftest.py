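"""Shared fixtures: one small synthetic aneurysm with fields and renders.

Expensive objects are session-scoped; tests treat them as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

from multiview_wss.mesh import TriMesh, mean_curvature
from multiview_wss.render import ColorMapCodec, render_views
from multiview_wss.synthetic import AortaParams, generate_aorta, pseudo_cfd_wss, tawss


def make_tube(radius: float, length: float, n_axial: int = 40,
              n_circ: int = 48, closed: bool = False) -> TriMesh:
    """Open (or capped) cylinder with outward-wound faces, axis +z."""
    t = np.linspace(0.0, length, n_axial)
    th = np.linspace(0, 2 * np.pi, n_circ, endpoint=False)
    verts = np.array([[radius * np.cos(c), radius * np.sin(c), z]
                      for z in t for c in th])
    faces = []
    for a in range(n_axial - 1):
        for c in range(n_circ):
            c2 = (c + 1) % n_circ
            i00, i01 = a * n_circ + c, a * n_circ + c2
            i10, i11 = (a + 1) * n_circ + c, (a + 1) * n_circ + c2
            faces.append([i00, i11, i10])
            faces.append([i00, i01, i11])
    verts = np.asarray(verts)
    if closed:
        v0, v1 = len(verts), len(verts) + 1
        verts = np.vstack([verts, [0, 0, 0], [0, 0, length]])
        for c in range(n_circ):
            c2 = (c + 1) % n_circ
            faces.append([v0, c2, c])
            faces.append([v1, (n_axial - 1) * n_circ + c,
                          (n_axial - 1) * n_circ + c2])
    return TriMesh(verts, np.asarray(faces))


@pytest.fixture(scope="session")
def aorta_params() -> AortaParams:
    return AortaParams(axial_resolution=48, circumferential_resolution=20, seed=3)


@pytest.fixture(scope="session")
def aorta_mesh(aorta_params):
    mesh = generate_aorta(aorta_params)
    series = pseudo_cfd_wss(mesh, aorta_params)
    mesh.attach(tawss(series, cycle_index=3))
    mesh.attach(mean_curvature(mesh))
    mesh.metadata["id"] = "fixture-aorta"
    return mesh


@pytest.fixture(scope="session")
def tawss_codec(aorta_mesh) -> ColorMapCodec:
    return ColorMapCodec.rainbow(value_range=aorta_mesh.fields["tawss"].range)


@pytest.fixture(scope="session")
def view_ring(aorta_mesh, tawss_codec):
    """12 stress-map views at 30° steps, 64 px."""
    return render_views(aorta_mesh, "field", tawss_codec, "tawss", "z", 30, 64)


@pytest.fixture(scope="session")
def curvature_view(aorta_mesh):
    return render_views(aorta_mesh, "field", None, "curvature", "z", 360, 64)[0]
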