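"""Deterministic test geometries.

All fixtures derive from real cage embeddings so their incidence structure
is genuine; the distortions are controlled and seeded.
"""

from __future__ import annotations

import numpy as np

from .geometry import PCageGeometry, embed_labeling
from .labelings import labeling_from_name


def make_fixture(kind, params=None, seed=0):
    """Named deterministic fixtures.

    * ``regular``           -- exactly embedded regular cage (default the
      icosahedral P10 cage); param ``name``.
    * ``noisy``             -- regular cage plus Gaussian node noise of
      standard deviation ``sigma`` (default 1e-3).
    * ``pinched``           -- cage with two non-adjacent boundary nodes of
      one hole moved onto each other.
    * ``self-intersecting`` -- cage with one face reflected through the
      cage centre so it pierces the opposite side.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    name = params.pop("name", "Pic_P10_1_1_1_1_1")
    geo = embed_labeling(labeling_from_name(name))
    if kind == "regular":
        return geo
    if kind == "noisy":
        sigma = float(params.pop("sigma", 1e-3))
        out = geo.copy()
        out.nodes = out.nodes + rng.normal(scale=sigma, size=out.nodes.shape)
        return out
    if kind == "pinched":
        out = geo.copy()
        hole = max(out.topology.holes, key=len)   # needs >= 4 boundary nodes
        i, j = 0, len(hole) // 2
        out.nodes[hole[i]] = out.nodes[hole[j]]
        return out
    if kind == "self-intersecting":
        out = geo.copy()
        face = out.topology.faces[0]
        centre = out.nodes.mean(axis=0)
        for node in face:
            out.nodes[node] = 2.0 * centre - out.nodes[node]
        return out
    raise ValueError(f"unknown fixture kind: {kind!r}")
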