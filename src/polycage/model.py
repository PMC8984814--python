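"""Model/Results front end for single-cage studies.

``PCageModel`` wraps one cage candidate -- a connectivity-invariant
hole-edge distribution on a uniform solid -- the way statistical modelling
packages wrap a model specification: construct it from a catalogue name (or
a labeling), inspect its combinatorial structure, then ``fit()`` to run the
geometric realization and obtain a ``PCageResults`` with the deformation
metrics, the quality breakdown and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import replace

from .constraints import DEFAULT_KAPPA, prune_configuration
from .geometry import initial_embedding
from .labelings import CornerLabeling, labeling_from_name
from .meshio import export_geometry
from .optimize import OptimizationConfig, optimize_cage
from .topology import build_topology, hole_size_census


class PCageModel:
    """A p-cage candidate ready for geometric realization.

    Parameters
    ----------
    labeling : CornerLabeling
        Connectivity-invariant hole-edge distribution.
    config : OptimizationConfig, optional
        Realization settings (seed, weight sweep, thresholds).
    """

    def __init__(self, labeling, config=None):
        if not isinstance(labeling, CornerLabeling):
            raise TypeError("labeling must be a CornerLabeling; "
                            "use PCageModel.from_name for catalogue names")
        self.labeling = labeling
        self.config = config or OptimizationConfig()
        self.topology = build_topology(labeling)

    @classmethod
    def from_name(cls, name, config=None):
        """Build from a catalogue name such as ``"Asc_P11_2_1_1_1_1"``."""
        return cls(labeling_from_name(name), config=config)

    # ------------------------------------------------------------------
    @property
    def name(self):
        return self.labeling.name

    @property
    def n_faces(self):
        return self.topology.N

    @property
    def n_nodes(self):
        return self.topology.NN

    @property
    def n_holes(self):
        return self.topology.n_holes

    def hole_census(self):
        return hole_size_census(self.topology)

    def prune_report(self, kappa_t=DEFAULT_KAPPA, use_angle=True):
        return prune_configuration(self.labeling, kappa_t, use_angle=use_angle)

    def initial_geometry(self):
        return initial_embedding(self.topology)

    def fit(self, **overrides):
        """Run the full realization pipeline; returns :class:`PCageResults`.

        Keyword overrides are applied to the model's OptimizationConfig,
        e.g. ``fit(seed=3, sweep_points=25)``.
        """
        cfg = replace(self.config, **overrides) if overrides else self.config
        cage = optimize_cage(self.labeling, cfg)
        return PCageResults(self, cage, cfg)


class PCageResults:
    """Realized cage with deformation metrics and classification."""

    def __init__(self, model, cage, config):
        self.model = model
        self.cage = cage
        self.config = config

    # main read-outs ----------------------------------------------------
    @property
    def delta_l(self):
        return self.cage.report.delta_l

    @property
    def delta_a(self):
        return self.cage.report.delta_a

    @property
    def max_deformation(self):
        return self.cage.report.max_deformation

    @property
    def omega_l(self):
        return self.cage.report.omega_l

    @property
    def omega_a(self):
        return self.cage.report.omega_a

    @property
    def classification(self):
        return self.cage.classification

    @property
    def geometry(self):
        return self.cage.geometry

    def export(self, path):
        export_geometry(self.cage.geometry, path)

    def summary(self):
        m = self.model
        qb = self.cage.breakdown
        census = ", ".join(f"{n}x{k}-gon" for k, n in sorted(m.hole_census().items()))
        lines = [
            "P-cage realization results",
            "=" * 54,
            f"cage                 {m.name}",
            f"faces (N x P-gon)    {m.n_faces} x {m.topology.P}-gon",
            f"nodes (NN)           {m.n_nodes}",
            f"holes                {m.n_holes} ({census})",
            "-" * 54,
            f"delta_l (max edge)   {self.delta_l:.3e}",
            f"delta_a (max angle)  {self.delta_a:.3e}",
            f"max deformation      {self.max_deformation * 100:.4f} %",
            f"omega_l / omega_a    {self.omega_l:.3e} / {self.omega_a:.3e}",
            f"best (c_l, c_a)      ({self.cage.best_weights[0]:.4f}, "
            f"{self.cage.best_weights[1]:.4f})",
            f"Q breakdown          length {qb.q_length:.3e}  angle {qb.q_angle:.3e}",
            f"                     planar {qb.q_planar:.3e}  convex "
            f"{qb.q_conv_face:.0f}/{qb.q_conv_cage:.0f}",
            f"self-intersecting    {self.cage.self_intersects}",
            f"pinched holes        {self.cage.pinched_holes or 'none'}",
            f"classification       {self.classification}",
            f"seed                 {self.config.seed}",
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (f"<PCageResults {self.model.name}: {self.classification}, "
                f"max deformation {self.max_deformation:.3e}>")
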