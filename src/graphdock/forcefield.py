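"""Internal molecular-mechanics energy engine and Powell minimization.

Functional forms follow the published Tripos 5.2 force field: harmonic
bond stretch and angle bend, periodic cosine torsions, a quadratic
out-of-plane restraint on trigonal centres, 6-12 van der Waals over pairs
separated by more than two bonds, and Coulomb electrostatics with a
distance-dependent dielectric ε(r) = 4r (1-4 pairs scaled by 0.5).  A
minimal embedded parameter table (``data/tripos_ff.yaml``) covers the atom
types emitted by the carrier builder and the fixture catalogue; missing
bonded parameters fall back to documented defaults with a logged warning,
while a missing van der Waals entry is an error.

For a carrier/ligand complex the binding energy is

    E_Delta = E_GDDS − E_G − E_lig

with E_GDDS the total potential energy of the complex and E_G, E_lig the
fragment energies at the same geometry; with rigid fragments E_Delta
reduces exactly to the intermolecular nonbonded sum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .structures import AROMATIC, Atom, ComplexPose, MolecularStructure, total_formal_charge

__all__ = [
    "EnergyReport",
    "ForceFieldParameters",
    "TriposForceField",
    "assign_atom_types",
    "assign_partial_charges",
    "potential_energy",
    "minimize_powell",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# report


@dataclass
class EnergyReport:
    """Decomposed potential energies in kcal/mol.

    ``e_g``/``e_lig``/``e_delta`` are populated only for complexes;
    ``e_delta = e_gdds − e_g − e_lig`` holds exactly whenever they are set.
    """

    e_gdds: float
    e_g: float | None = None
    e_lig: float | None = None
    e_delta: float | None = None
    terms: dict = field(default_factory=dict)
    trace: list = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        out = {"E_GDDS": self.e_gdds}
        if self.e_g is not None:
            out["E_G"] = self.e_g
        if self.e_lig is not None:
            out["E_lig"] = self.e_lig
        if self.e_delta is not None:
            out["E_Delta"] = self.e_delta
        return out


# ---------------------------------------------------------------------------
# atom typing


def assign_atom_types(structure: MolecularStructure) -> MolecularStructure:
    """Assign SYBYL-style atom types from element, bond orders and
    aromaticity.  Returns a typed copy; raises on an untypeable atom."""
    s = structure.copy()
    adj = s.neighbours()
    orders = {}
    for b in s.bonds:
        orders.setdefault(b.i, []).append(b.order)
        orders.setdefault(b.j, []).append(b.order)

    def bond_orders(i: int) -> list:
        return orders.get(i, [])

    for i, a in enumerate(s.atoms):
        el = a.element.capitalize()
        bo = bond_orders(i)
        if el == "H":
            t = "H"
        elif el == "C":
            if AROMATIC in bo:
                t = "C.ar"
            elif 3 in bo:
                t = "C.1"
            elif 2 in bo:
                t = "C.2"
            else:
                t = "C.3"
        elif el == "O":
            if a.formal_charge == -1:
                t = "O.co2"
            elif 2 in bo or AROMATIC in bo:
                t = "O.2"
            else:
                t = "O.3"
        elif el == "N":
            if AROMATIC in bo:
                t = "N.ar"
            elif 3 in bo:
                t = "N.1"
            elif 2 in bo:
                t = "N.2"
            elif any(
                s.atoms[j].element == "C" and 2 in bond_orders(j)
                and any(s.atoms[k].element == "O" for k in adj[j])
                for j in adj[i]
            ):
                t = "N.am"
            elif len(adj[i]) == 4:
                t = "N.4"
            else:
                t = "N.3"
        elif el == "S":
            t = "S.2" if 2 in bo else "S.3"
        elif el == "P":
            t = "P.3"
        elif el in ("F", "Cl", "Br", "I"):
            t = el
        else:
            raise ValueError(f"cannot assign an atom type to atom {i} ({a.element})")
        a.atom_type = t
    return s


def assign_partial_charges(structure: MolecularStructure, n_iter: int = 24) -> MolecularStructure:
    """Gasteiger (iterative electronegativity-equalization) partial charges.

    Computed on the molecular graph via RDKit; any numerical residual is
    spread uniformly so the charges sum to the total formal charge within
    1e-6 e.  Raises if the computation yields non-finite charges.
    """
    from rdkit.Chem import rdPartialCharges

    from .structures import to_rdkit

    s = structure.copy()
    mol = to_rdkit(s, sanitize="partial")
    rdPartialCharges.ComputeGasteigerCharges(mol, nIter=n_iter, throwOnParamFailure=False)
    charges = np.array([float(at.GetProp("_GasteigerCharge")) for at in mol.GetAtoms()])
    if not np.all(np.isfinite(charges)):
        raise ValueError("Gasteiger charge computation did not converge (non-finite charges)")
    residual = total_formal_charge(s) - charges.sum()
    charges += residual / len(charges)
    for a, q in zip(s.atoms, charges):
        a.partial_charge = float(q)
    return s


# ---------------------------------------------------------------------------
# parameters


class ForceFieldParameters:
    """Lookup tables loaded from the embedded YAML (or a user file)."""

    def __init__(self, source: str | Path | dict | None = None) -> None:
        if isinstance(source, dict):
            raw = source
        else:
            if source is None:
                with resources.files("graphdock.data").joinpath("tripos_ff.yaml").open() as fh:
                    raw = yaml.safe_load(fh)
            else:
                raw = yaml.safe_load(Path(source).read_text())
        self.vdw = {t: (v["radius"], v["eps"]) for t, v in raw["vdw"].items()}
        self.bonds = {tuple(sorted(e["types"])): (e["k"], e["r0"]) for e in raw["bonds"]}
        self.angles = raw["angles"]
        self.angle_overrides = {
            tuple(k.split()): v for k, v in (raw.get("angle_overrides") or {}).items()
        }
        self.torsions = {tuple(sorted(e["types"])): (e["v"], e["n"], e["s"]) for e in raw["torsions"]}
        self.oop = {t: v["k"] for t, v in raw["oop"].items()}
        self.defaults = raw["defaults"]
        self.covalent_radii = raw["covalent_radii"]
        es = raw["electrostatics"]
        self.coulomb_constant = es["coulomb_constant"]
        self.dielectric_scale = es["dielectric_scale"]
        self.scale_14 = es["scale_14"]

    def vdw_params(self, atom_type: str) -> tuple[float, float]:
        try:
            return self.vdw[atom_type]
        except KeyError:
            raise KeyError(f"no van der Waals parameters for atom type {atom_type!r}") from None

    def bond_params(self, ti: str, tj: str, elements: tuple[str, str]) -> tuple[float, float]:
        key = tuple(sorted((ti, tj)))
        if key in self.bonds:
            return self.bonds[key]
        r0 = self.covalent_radii.get(elements[0], 0.77) + self.covalent_radii.get(elements[1], 0.77)
        log.warning("no bond parameters for %s-%s; using defaults (k=%s, r0=%.2f)",
                    ti, tj, self.defaults["bond"]["k"], r0)
        return (self.defaults["bond"]["k"], r0)

    def angle_params(self, ti: str, tj: str, tk: str) -> tuple[float, float]:
        for key in ((ti, tj, tk), (tk, tj, ti)):
            if key in self.angle_overrides:
                v = self.angle_overrides[key]
                return (v["k"], v["theta0"])
        if tj in self.angles:
            v = self.angles[tj]
            return (v["k"], v["theta0"])
        log.warning("no angle parameters for centre type %s; using defaults", tj)
        d = self.defaults["angle"]
        return (d["k"], d["theta0"])

    def torsion_params(self, tj: str, tk: str) -> tuple[float, int, int]:
        key = tuple(sorted((tj, tk)))
        if key in self.torsions:
            return self.torsions[key]
        d = self.defaults["torsion"]
        if d["v"]:
            log.warning("no torsion parameters for central bond %s-%s; using defaults", tj, tk)
        return (d["v"], d["n"], d["s"])


# ---------------------------------------------------------------------------
# topology + energy


class _Topology:
    """Precomputed index arrays and parameters for one structure."""

    def __init__(self, structure: MolecularStructure, params: ForceFieldParameters) -> None:
        n = structure.n_atoms
        adj = structure.neighbours()
        types = [a.atom_type for a in structure.atoms]
        elements = [a.element for a in structure.atoms]

        bidx, bk, br0 = [], [], []
        for b in structure.bonds:
            k, r0 = params.bond_params(types[b.i], types[b.j], (elements[b.i], elements[b.j]))
            bidx.append((b.i, b.j))
            bk.append(k)
            br0.append(r0)
        self.bond_idx = np.array(bidx, int).reshape(-1, 2)
        self.bond_k = np.array(bk)
        self.bond_r0 = np.array(br0)

        aidx, ak, ath0 = [], [], []
        for j in range(n):
            nb = sorted(adj[j])
            for x in range(len(nb)):
                for y in range(x + 1, len(nb)):
                    i, k_ = nb[x], nb[y]
                    kk, th0 = params.angle_params(types[i], types[j], types[k_])
                    aidx.append((i, j, k_))
                    ak.append(kk)
                    ath0.append(th0)
        self.angle_idx = np.array(aidx, int).reshape(-1, 3)
        self.angle_k = np.array(ak)
        self.angle_th0 = np.array(ath0)

        tidx, tv, tn, ts = [], [], [], []
        for b in structure.bonds:
            j, k_ = b.i, b.j
            v, nper, sgn = params.torsion_params(types[j], types[k_])
            if v == 0.0:
                continue
            for i in adj[j]:
                if i == k_:
                    continue
                for l in adj[k_]:
                    if l == j or l == i:
                        continue
                    tidx.append((i, j, k_, l))
                    tv.append(v)
                    tn.append(nper)
                    ts.append(sgn)
        self.tors_idx = np.array(tidx, int).reshape(-1, 4)
        self.tors_v = np.array(tv)
        self.tors_n = np.array(tn)
        self.tors_s = np.array(ts)

        oidx, ok = [], []
        for j in range(n):
            if len(adj[j]) == 3 and types[j] in params.oop:
                i, k_, l = adj[j]
                oidx.append((j, i, k_, l))
                ok.append(params.oop[types[j]])
        self.oop_idx = np.array(oidx, int).reshape(-1, 4)
        self.oop_k = np.array(ok)

        # nonbonded: pairs at graph distance ≥ 3 (1-4 pairs scaled)
        dist = _bond_distance_upto(adj, n, cap=3)
        pairs, scale = [], []
        for i in range(n):
            for j in range(i + 1, n):
                d = dist.get((i, j), 4)
                if d >= 3:
                    pairs.append((i, j))
                    scale.append(params.scale_14 if d == 3 else 1.0)
        self.nb_idx = np.array(pairs, int).reshape(-1, 2)
        self.nb_scale = np.array(scale)

        radii = np.array([params.vdw_params(t)[0] for t in types])
        eps = np.array([params.vdw_params(t)[1] for t in types])
        if len(self.nb_idx):
            i, j = self.nb_idx[:, 0], self.nb_idx[:, 1]
            self.nb_rstar = radii[i] + radii[j]
            self.nb_eps = np.sqrt(eps[i] * eps[j])
        else:
            self.nb_rstar = np.zeros(0)
            self.nb_eps = np.zeros(0)
        self.charges = np.array([a.partial_charge for a in structure.atoms])
        self.radii = radii
        self.eps = eps
        self.params = params


def _bond_distance_upto(adj: list[list[int]], n: int, cap: int) -> dict[tuple[int, int], int]:
    """Graph distances ≤ cap as {(i<j): d} via truncated BFS from each atom."""
    out: dict[tuple[int, int], int] = {}
    for src in range(n):
        seen = {src: 0}
        frontier = [src]
        for d in range(1, cap + 1):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen[v] = d
                        nxt.append(v)
            frontier = nxt
        for v, d in seen.items():
            if src < v:
                key = (src, v)
                if key not in out or d < out[key]:
                    out[key] = d
    return out


def _dihedral(p0, p1, p2, p3):
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.arctan2(y, x)


class TriposForceField:
    """Vectorized evaluator over a prepared topology."""

    def __init__(self, params: ForceFieldParameters | None = None) -> None:
        self.params = params or ForceFieldParameters()
        self._topo_cache: dict[int, _Topology] = {}

    def topology(self, structure: MolecularStructure) -> _Topology:
        key = id(structure)
        topo = self._topo_cache.get(key)
        if topo is None:
            topo = _Topology(structure, self.params)
            self._topo_cache[key] = topo
        return topo

    # -- single-structure terms ------------------------------------------
    def energy_terms(self, structure: MolecularStructure, xyz: np.ndarray | None = None) -> dict:
        t = self.topology(structure)
        xyz = structure.coords if xyz is None else xyz
        terms = {}

        if len(t.bond_idx):
            d = np.linalg.norm(xyz[t.bond_idx[:, 0]] - xyz[t.bond_idx[:, 1]], axis=1)
            terms["bond"] = float(np.sum(t.bond_k * (d - t.bond_r0) ** 2))
        else:
            terms["bond"] = 0.0

        if len(t.angle_idx):
            v1 = xyz[t.angle_idx[:, 0]] - xyz[t.angle_idx[:, 1]]
            v2 = xyz[t.angle_idx[:, 2]] - xyz[t.angle_idx[:, 1]]
            cosang = np.sum(v1 * v2, axis=1) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
            )
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            terms["angle"] = float(np.sum(t.angle_k * (ang - t.angle_th0) ** 2))
        else:
            terms["angle"] = 0.0

        if len(t.tors_idx):
            phi = _dihedral(
                xyz[t.tors_idx[:, 0]], xyz[t.tors_idx[:, 1]],
                xyz[t.tors_idx[:, 2]], xyz[t.tors_idx[:, 3]],
            )
            terms["torsion"] = float(np.sum(0.5 * t.tors_v * (1.0 + t.tors_s * np.cos(t.tors_n * phi))))
        else:
            terms["torsion"] = 0.0

        if len(t.oop_idx):
            c = xyz[t.oop_idx[:, 0]]
            p1 = xyz[t.oop_idx[:, 1]]
            p2 = xyz[t.oop_idx[:, 2]]
            p3 = xyz[t.oop_idx[:, 3]]
            nrm = np.cross(p2 - p1, p3 - p1)
            nn = np.linalg.norm(nrm, axis=1)
            good = nn > 1e-12
            dist = np.zeros(len(c))
            dist[good] = np.abs(np.sum((c - p1)[good] * nrm[good], axis=1)) / nn[good]
            terms["oop"] = float(np.sum(t.oop_k * dist**2))
        else:
            terms["oop"] = 0.0

        if len(t.nb_idx):
            i, j = t.nb_idx[:, 0], t.nb_idx[:, 1]
            r = np.linalg.norm(xyz[i] - xyz[j], axis=1)
            x6 = (t.nb_rstar / r) ** 6
            terms["vdw"] = float(np.sum(t.nb_scale * t.nb_eps * (x6**2 - 2.0 * x6)))
            p = self.params
            terms["electrostatic"] = float(
                np.sum(
                    t.nb_scale
                    * p.coulomb_constant
                    * t.charges[i]
                    * t.charges[j]
                    / (p.dielectric_scale * r**2)
                )
            )
        else:
            terms["vdw"] = 0.0
            terms["electrostatic"] = 0.0
        return terms

    def structure_energy(self, structure: MolecularStructure, xyz: np.ndarray | None = None) -> float:
        return float(sum(self.energy_terms(structure, xyz).values()))

    # -- intermolecular ---------------------------------------------------
    def intermolecular_energy(
        self,
        a: MolecularStructure,
        b: MolecularStructure,
        xyz_a: np.ndarray | None = None,
        xyz_b: np.ndarray | None = None,
    ) -> dict:
        ta, tb = self.topology(a), self.topology(b)
        pa = a.coords if xyz_a is None else xyz_a
        pb = b.coords if xyz_b is None else xyz_b
        diff = pa[:, None, :] - pb[None, :, :]
        r = np.sqrt(np.sum(diff * diff, axis=-1))
        rstar = ta.radii[:, None] + tb.radii[None, :]
        eps = np.sqrt(ta.eps[:, None] * tb.eps[None, :])
        x6 = (rstar / r) ** 6
        vdw = float(np.sum(eps * (x6**2 - 2.0 * x6)))
        p = self.params
        elec = float(
            np.sum(p.coulomb_constant * ta.charges[:, None] * tb.charges[None, :] / (p.dielectric_scale * r**2))
        )
        return {"inter_vdw": vdw, "inter_electrostatic": elec}

    # -- public evaluation -----------------------------------------------
    def evaluate(self, obj: MolecularStructure | ComplexPose) -> EnergyReport:
        if isinstance(obj, ComplexPose):
            e_g = self.structure_energy(obj.carrier)
            e_lig_terms = self.energy_terms(obj.ligand)
            e_lig = float(sum(e_lig_terms.values()))
            inter = self.intermolecular_energy(obj.carrier, obj.ligand)
            e_inter = inter["inter_vdw"] + inter["inter_electrostatic"]
            e_gdds = e_g + e_lig + e_inter
            terms = dict(e_lig_terms)
            terms.update(inter)
            terms["intermolecular"] = e_inter
            return EnergyReport(
                e_gdds=e_gdds, e_g=e_g, e_lig=e_lig, e_delta=e_gdds - e_g - e_lig, terms=terms
            )
        terms = self.energy_terms(obj)
        return EnergyReport(e_gdds=float(sum(terms.values())), terms=terms)


def potential_energy(
    obj: MolecularStructure | ComplexPose, forcefield: TriposForceField | None = None
) -> EnergyReport:
    """Total potential energy (kcal/mol); for a complex the report also
    carries the fragment energies and the binding energy E_Delta."""
    ff = forcefield or TriposForceField()
    return ff.evaluate(obj)


# ---------------------------------------------------------------------------
# Powell minimization


def minimize_powell(
    structure: MolecularStructure,
    tol: float = 1e-4,
    max_iter: int = 2000,
    forcefield: TriposForceField | None = None,
) -> tuple[MolecularStructure, EnergyReport]:
    """Derivative-free Powell direction-set minimization over Cartesian
    coordinates.  The returned report's ``trace`` holds the per-iteration
    energies (non-increasing); final energy never exceeds the initial one.
    """
    from scipy.optimize import minimize

    ff = forcefield or TriposForceField()
    topo = ff.topology(structure)  # built once; reused through the closure
    n = structure.n_atoms
    x0 = structure.coords.ravel()

    def objective(x: np.ndarray) -> float:
        return ff.structure_energy(structure, x.reshape(n, 3))

    e0 = objective(x0)
    trace = [e0]

    def callback(xk: np.ndarray) -> None:
        trace.append(objective(xk))

    res = minimize(
        objective,
        x0,
        method="Powell",
        callback=callback,
        options={"maxiter": max_iter, "ftol": tol, "xtol": 1e-6, "disp": False},
    )
    xbest, ebest = (res.x, float(res.fun)) if res.fun <= e0 else (x0, e0)
    out = structure.copy()
    out.set_coords(xbest.reshape(n, 3))
    report = ff.evaluate(out)
    report.trace = trace
    return out, report
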