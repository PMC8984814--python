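# polycage

Enumeration and geometric realization of **near-miss connectivity-invariant
polyhedral cages** (p-cages): assemblies of N planar, nearly regular P-gonal
faces separated by holes, the geometry underlying engineered protein
nano-cages such as the TRAP-cage (24 hendecagonal protein rings, five
neighbours each, 38 holes).

A p-cage is *homogeneous* when every face has P edges, and
*connectivity-invariant* when a graph automorphism maps any face onto any
other while preserving shared and hole edges (reflections excluded).  The
dual of such a cage — the **hole-polyhedron**, whose vertices, edges and
faces correspond to the cage's faces, shared edges and holes — must then be
a vertex-transitive convex polyhedron: a Platonic or Archimedean solid, a
uniform prism or an antiprism.  Around every hole-polyhedron vertex of
degree E_h, the face's edges split into E_h shared edges and hole
contributions a_i ≥ 1 with

    P = E_h + Σ_{i=1..E_h} a_i ,

and the assignment must be preserved by a vertex-transitive subgroup of the
solid's rotation group.  The pipeline:

1. **enumerate** all such corner labelings for every supported solid and
   P = 6..17 (a labeling is connectivity-invariant iff it is constant on
   the corner orbits of a vertex-transitive subgroup);
2. **prune** with two geometric necessary conditions at threshold
   deformation κ_t = 0.1: the projected angle-sum bound
   `P ≤ 2Σ(q_i+1)/(Q−2) · (1 + κ_t (P−2)/2)` and a polygon inequality on
   the hole chords subtended by each face's run of hole edges;
3. **realize** each surviving candidate: assemble rigid regular faces on the
   solid's vertices, then minimize the deformation functional

       Q = c_l Q_length + c_a Q_angle + c_p Q_planar + c_cf Q_ConvFace + c_cp Q_ConvPol

   over all node positions (defaults c_l = c_a = 1, c_p = 1000,
   c_cf = c_cp = 100), sweep the c_l/c_a ratio over log-spaced values with
   c_l + c_a = 2, and refine by bisection;
4. **classify** by the maximum deformations Δl = max|l − 1| and
   Δa = max|α − α₀|/α₀: *regular* (≤ 1e−5), *near-miss* (≤ 0.1),
   *rejected*, or overriding *degenerate* (pinched holes) /
   *self-intersecting* (Möller triangle–triangle tests on the facelets).

## Worked example

```python
from polycage import PCageModel

model = PCageModel.from_name("Asc_P11_2_1_1_1_1")   # TRAP-cage geometry
print(model.n_faces, model.n_holes, model.hole_census())
res = model.fit(seed=1, sweep_points=9, compute_similarity=True)
print(res.summary())
```

```
24 38 {3: 32, 8: 6}
P-cage realization results
======================================================
cage                 Asc_P11_2_1_1_1_1
faces (N x P-gon)    24 x 11-gon
nodes (NN)           144
holes                38 (32x3-gon, 6x8-gon)
------------------------------------------------------
delta_l (max edge)   4.956e-03
delta_a (max angle)  2.721e-03
max deformation      0.4956 %
omega_l / omega_a    1.935e-03 / 1.652e-03
best (c_l, c_a)      (0.9968, 1.0032)
Q breakdown          length 3.717e-03  angle 5.307e-03
                     planar 6.269e-09  convex 0/0
self-intersecting    False
pinched holes        none
classification       near-miss
seed                 1
```

The snub-cube cage with hendecagonal faces (two edges to each square hole,
one to each triangular hole) realizes with at most 0.50% edge and angle
deformation — regular-looking to the naked eye, mathematically a near-miss.
Ω_l/Ω_a show the 24 faces end up deformed slightly differently, so face
congruence is not imposed and indeed does not hold exactly.

The same pipeline is scriptable from the shell:

```bash
polycage enumerate Asc 11           # connectivity-invariant distributions
polycage optimize Asc_P11_2_1_1_1_1 --seed 1 --off trap.off
polycage catalog --symbols tp,Pdo --pmin 6 --pmax 9 --out catalog.csv
```

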