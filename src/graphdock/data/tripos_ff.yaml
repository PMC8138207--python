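# Molecular-mechanics parameter table (Tripos 5.2-style functional forms).
# Units: energies kcal/mol, lengths Å, angles degrees.
#   bonds:    E = k (r - r0)^2            k in kcal/mol/Å^2
#   angles:   E = k (θ - θ0)^2            k in kcal/mol/deg^2, keyed by centre type
#   torsions: E = V/2 (1 + s cos(n φ))    keyed by the central bond's types
#   oop:      E = k d^2                   d = out-of-plane distance of an sp2 centre, Å
#   vdw:      E = ε [ (R/r)^12 − 2 (R/r)^6 ],  R = Ri + Rj, ε = sqrt(εi εj)
# Edit freely; missing bonded parameters fall back to the `defaults` entries
# (with a logged warning); a missing vdW entry is an error.

vdw:
  C.3:  {radius: 1.70, eps: 0.107}
  C.2:  {radius: 1.70, eps: 0.107}
  C.1:  {radius: 1.70, eps: 0.107}
  # aromatic-carbon radius calibrated so the plane-summed stacking optimum
  # of benzene over a graphene patch reproduces the graphitic interlayer
  # spacing (~3.35 Å); a lattice sum puts the minimum well below the
  # pairwise R*, so the pairwise 1.70 Å radius would stack at ~3.0 Å
  C.ar: {radius: 1.90, eps: 0.107}
  H:    {radius: 1.50, eps: 0.042}
  O.3:  {radius: 1.52, eps: 0.116}
  O.2:  {radius: 1.52, eps: 0.116}
  O.co2: {radius: 1.52, eps: 0.116}
  N.3:  {radius: 1.55, eps: 0.095}
  N.2:  {radius: 1.55, eps: 0.095}
  N.1:  {radius: 1.55, eps: 0.095}
  N.ar: {radius: 1.55, eps: 0.095}
  N.am: {radius: 1.55, eps: 0.095}
  N.pl3: {radius: 1.55, eps: 0.095}
  N.4:  {radius: 1.55, eps: 0.095}
  S.3:  {radius: 1.80, eps: 0.314}
  S.2:  {radius: 1.80, eps: 0.314}
  P.3:  {radius: 1.80, eps: 0.314}
  F:    {radius: 1.47, eps: 0.109}
  Cl:   {radius: 1.75, eps: 0.314}
  Br:   {radius: 1.85, eps: 0.434}
  I:    {radius: 1.98, eps: 0.600}

bonds:
  - {types: [C.3, C.3],  k: 633.6,  r0: 1.540}
  - {types: [C.3, C.ar], k: 640.0,  r0: 1.510}
  - {types: [C.3, C.2],  k: 639.0,  r0: 1.501}
  - {types: [C.3, H],    k: 662.4,  r0: 1.090}
  - {types: [C.ar, C.ar], k: 1400.0, r0: 1.395}
  - {types: [C.ar, H],   k: 692.0,  r0: 1.084}
  - {types: [C.ar, C.2], k: 700.0,  r0: 1.470}
  - {types: [C.ar, O.3], k: 700.0,  r0: 1.360}
  - {types: [C.3, O.3],  k: 618.9,  r0: 1.430}
  - {types: [C.2, O.2],  k: 1555.2, r0: 1.220}
  - {types: [C.2, O.3],  k: 700.0,  r0: 1.360}
  - {types: [C.2, H],    k: 662.4,  r0: 1.089}
  - {types: [C.2, C.2],  k: 1340.0, r0: 1.335}
  - {types: [O.3, H],    k: 1007.5, r0: 0.950}
  - {types: [C.3, N.3],  k: 760.2,  r0: 1.470}
  - {types: [N.3, H],    k: 692.0,  r0: 1.020}
  - {types: [C.ar, N.ar], k: 1305.9, r0: 1.346}

# harmonic angle bend, keyed by the centre atom's type; per-triple overrides
# may be added under `angle_overrides` with key "TYPE1 TYPE2 TYPE3"
angles:
  C.3:  {k: 0.024, theta0: 109.5}
  C.2:  {k: 0.024, theta0: 120.0}
  C.ar: {k: 0.024, theta0: 120.0}
  C.1:  {k: 0.024, theta0: 180.0}
  O.3:  {k: 0.020, theta0: 106.8}
  N.3:  {k: 0.020, theta0: 109.5}
  N.ar: {k: 0.024, theta0: 120.0}
  N.am: {k: 0.024, theta0: 120.0}
angle_overrides: {}

# periodic torsion, keyed by the central bond's two types
torsions:
  - {types: [C.3, C.3],  v: 0.20, n: 3, s: 1}
  - {types: [C.3, C.2],  v: 0.12, n: 3, s: 1}
  - {types: [C.3, C.ar], v: 0.12, n: 3, s: 1}
  - {types: [C.3, O.3],  v: 0.20, n: 3, s: 1}
  - {types: [C.ar, C.ar], v: 2.35, n: 2, s: -1}
  - {types: [C.ar, C.2], v: 1.00, n: 2, s: -1}
  - {types: [C.ar, O.3], v: 1.00, n: 2, s: -1}
  - {types: [C.2, O.3],  v: 1.00, n: 2, s: -1}
  - {types: [C.2, C.2],  v: 12.5, n: 2, s: -1}

# out-of-plane restraint for trigonal centres
oop:
  C.2:  {k: 40.0}
  C.ar: {k: 40.0}
  N.pl3: {k: 40.0}
  N.am: {k: 40.0}

defaults:
  bond: {k: 600.0}          # r0 falls back to the covalent-radius sum
  angle: {k: 0.020, theta0: 109.5}
  torsion: {v: 0.0, n: 3, s: 1}

covalent_radii: {H: 0.37, C: 0.77, N: 0.75, O: 0.73, S: 1.02, P: 1.06, F: 0.71, Cl: 0.99, Br: 1.14, I: 1.33}

electrostatics:
  coulomb_constant: 332.0637   # kcal·Å/(mol·e²)
  dielectric_scale: 4.0        # ε(r) = scale · r (distance-dependent)
  scale_14: 0.5                # 1-4 nonbonded scaling (vdW and Coulomb)
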