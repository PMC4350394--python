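"""Small helpers shared between test modules."""

import numpy as np

from sdsim.surfaces import TriSurface


def quadratic_patch(a, b, c, n_ring=8, radius=0.3):
    """Fan mesh sampling z = a x^2 + b x y + c y^2 around the origin.

    The ring is symmetric under point reflection, so the averaged vertex
    normal at the centre is exactly +z and the paraboloid fit there must
    recover (a, b, c) exactly.
    """
    ang = 2 * np.pi * np.arange(n_ring) / n_ring
    x, y = radius * np.cos(ang), radius * np.sin(ang)
    z = a * x * x + b * x * y + c * y * y
    verts = np.vstack([[0, 0, 0], np.column_stack([x, y, z])])
    faces = np.array([[0, 1 + i, 1 + (i + 1) % n_ring] for i in range(n_ring)])
    return TriSurface(verts, faces)
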