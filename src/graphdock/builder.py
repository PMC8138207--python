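"""Graphene and graphene-oxide carrier generation.

Pristine sheets are cut from an ideal honeycomb lattice (C–C 1.42 Å) laid in
the z = 0 plane with a hexagon centre at the origin and the central
hexagon's vertices at 30° + 60°k.  Under this convention the circular cut of
diameter 21.760 Å contains 138 ring carbons and 30 edge hydrogens — 168
atoms.  Sheets are functionalized into GO ensembles with hydroxyl, epoxy
(basal plane) and carboxyl (edge) groups; every emitted model's aromatic
system is inspected for π connectivity and the 4n+2 electron count, and
ensembles are deduplicated by a 2048-bit radius-5 circular fingerprint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, product

import networkx as nx
import numpy as np

from .structures import AROMATIC, Atom, Bond, MolecularStructure

__all__ = [
    "CC_BOND",
    "CH_BOND",
    "FunctionalizationSpec",
    "AromaticityReport",
    "build_circular_graphene",
    "build_rectangular_graphene",
    "functionalize_graphene",
    "check_hueckel",
    "circular_fingerprint",
    "deduplicate_models",
]

CC_BOND = 1.42  # Å, aromatic C–C
CH_BOND = 1.08  # Å, aromatic C–H
_HEX_WIDTH = math.sqrt(3.0) * CC_BOND  # one hexagon across flats, ≈2.46 Å


# ---------------------------------------------------------------------------
# lattice generation


def _honeycomb_carbons(xmax: float, ymax: float) -> np.ndarray:
    """All carbon sites of the ideal lattice with |x|≤xmax, |y|≤ymax.

    Hexagon centres form a triangular lattice of spacing √3·a₀ with one
    centre at the origin; each centre contributes its six vertices at
    angles 30°+60°k.  Shared vertices are merged on a rounded-coordinate
    key (distinct sites are ≥1.42 Å apart, so 1e-6 rounding is safe).
    """
    s = _HEX_WIDTH
    v1 = np.array([s, 0.0])
    v2 = np.array([s / 2.0, s * math.sqrt(3.0) / 2.0])
    reach = max(xmax, ymax) + 3 * CC_BOND
    n = int(reach / s) + 3
    seen: dict[tuple[int, int], np.ndarray] = {}
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            c = i * v1 + j * v2
            if abs(c[0]) > reach or abs(c[1]) > reach:
                continue
            for k in range(6):
                ang = math.pi / 6 + k * math.pi / 3
                p = c + CC_BOND * np.array([math.cos(ang), math.sin(ang)])
                if abs(p[0]) <= xmax and abs(p[1]) <= ymax:
                    key = (round(p[0] * 1e6), round(p[1] * 1e6))
                    seen.setdefault(key, p)
    return np.array(list(seen.values())) if seen else np.zeros((0, 2))


def _carbon_adjacency(xy: np.ndarray) -> list[list[int]]:
    from scipy.spatial import cKDTree

    adj: list[list[int]] = [[] for _ in range(len(xy))]
    if len(xy) >= 2:
        tree = cKDTree(xy)
        for i, j in tree.query_pairs(CC_BOND * 1.1):
            adj[i].append(j)
            adj[j].append(i)
    return adj


def _assemble_sheet(xy: np.ndarray, name: str, annotations: dict) -> MolecularStructure:
    """Drop dangling carbons, bond the rest aromatically, H-terminate edges."""
    xy = np.asarray(xy)
    keep = np.ones(len(xy), dtype=bool)
    while True:
        pts = xy[keep]
        adj = _carbon_adjacency(pts)
        degs = np.array([len(a) for a in adj]) if len(pts) else np.zeros(0, int)
        drop_local = np.where(degs < 2)[0]
        if len(drop_local) == 0:
            break
        global_idx = np.where(keep)[0]
        keep[global_idx[drop_local]] = False
    pts = xy[keep]
    if len(pts) < 6:
        raise ValueError("requested size is too small to contain one aromatic ring")
    adj = _carbon_adjacency(pts)

    atoms = [Atom("C", "C.ar", np.array([p[0], p[1], 0.0])) for p in pts]
    bonds: list[Bond] = []
    for i, nbrs in enumerate(adj):
        for j in nbrs:
            if i < j:
                bonds.append(Bond(i, j, AROMATIC))
    # one in-plane H on each 2-coordinate edge carbon, pointing away
    for i, nbrs in enumerate(adj):
        if len(nbrs) == 2:
            direction = pts[i] - 0.5 * (pts[nbrs[0]] + pts[nbrs[1]])
            direction = direction / np.linalg.norm(direction)
            hp = pts[i] + CH_BOND * direction
            atoms.append(Atom("H", "H", np.array([hp[0], hp[1], 0.0])))
            bonds.append(Bond(i, len(atoms) - 1, 1))
    return MolecularStructure(atoms, bonds, name=name, annotations=annotations)


def build_circular_graphene(diameter: float) -> MolecularStructure:
    """Circular pristine sheet: carbons kept iff their distance from the
    central hexagon centre is ≤ diameter/2."""
    if diameter < _HEX_WIDTH:
        raise ValueError(f"diameter {diameter} Å cannot contain one hexagon (~{_HEX_WIDTH:.2f} Å)")
    r = diameter / 2.0
    xy = _honeycomb_carbons(r, r)
    xy = xy[np.linalg.norm(xy, axis=1) <= r + 1e-9]
    return _assemble_sheet(
        xy,
        name=f"graphene_circ_{diameter:g}",
        annotations={"shape": "circular", "diameter": float(diameter)},
    )


def build_rectangular_graphene(width: float, height: float) -> MolecularStructure:
    """Axis-aligned rectangular cut |x| ≤ width/2, |y| ≤ height/2."""
    if width < _HEX_WIDTH or height < _HEX_WIDTH:
        raise ValueError("both dimensions must fit at least one hexagon (~2.46 Å)")
    xy = _honeycomb_carbons(width / 2.0, height / 2.0)
    return _assemble_sheet(
        xy,
        name=f"graphene_rect_{width:g}x{height:g}",
        annotations={"shape": "rectangular", "width": float(width), "height": float(height)},
    )


# ---------------------------------------------------------------------------
# aromaticity inspection


@dataclass
class AromaticityReport:
    pi_electron_count: int
    hueckel_ok: bool
    pi_connected: bool


def check_hueckel(structure: MolecularStructure) -> AromaticityReport:
    """π bookkeeping: one electron per conjugated aromatic carbon; the 4n+2
    rule holds iff the count ≡ 2 (mod 4); connectivity is judged on the
    graph induced by aromatic bonds."""
    aromatic_atoms = {
        i for i, a in enumerate(structure.atoms) if a.atom_type == "C.ar" or a.atom_type.endswith(".ar")
    }
    g = nx.Graph()
    g.add_nodes_from(aromatic_atoms)
    for b in structure.bonds:
        if b.order == AROMATIC and b.i in aromatic_atoms and b.j in aromatic_atoms:
            g.add_edge(b.i, b.j)
    count = len(aromatic_atoms)
    connected = count > 0 and nx.number_connected_components(g) == 1
    return AromaticityReport(
        pi_electron_count=count,
        hueckel_ok=count % 4 == 2,
        pi_connected=connected,
    )


# ---------------------------------------------------------------------------
# fingerprints / dedup


def circular_fingerprint(structure: MolecularStructure, n_bits: int = 2048, radius: int = 5):
    """Extended-connectivity fingerprint of diameter 2·radius folded to
    ``n_bits`` — computed on the molecular graph, 3D coordinates ignored."""
    from rdkit.Chem import rdFingerprintGenerator

    from .structures import to_rdkit

    mol = to_rdkit(structure, sanitize="partial")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprint(mol)


def _fp_key(structure: MolecularStructure) -> bytes:
    return circular_fingerprint(structure).ToBitString().encode()


def deduplicate_models(models: list[MolecularStructure]) -> list[MolecularStructure]:
    """Keep the first model of each distinct fingerprint, preserving order."""
    seen: set[bytes] = set()
    out: list[MolecularStructure] = []
    for m in models:
        key = _fp_key(m)
        if key not in seen:
            seen.add(key)
            out.append(m)
    return out


# ---------------------------------------------------------------------------
# functionalization


@dataclass
class FunctionalizationSpec:
    """How to decorate a pristine sheet into GO models.

    Hydroxyl and epoxy go on basal-plane carbons (epoxy bridges a bonded
    pair), carboxyl replaces an edge hydrogen.  ``surface_mode`` picks the
    z-side for basal groups; ``manner`` picks random sampling (seeded) or
    systematic lexicographic enumeration of placements.  Emitted models are
    fingerprint-unique and must keep a connected π system; demanding the
    4n+2 count as well (``require_hueckel``) is optional because fixed group
    counts fix the π-electron parity.
    """

    n_hydroxyl: int = 0
    n_epoxy: int = 0
    n_carboxyl: int = 0
    surface_mode: str = "upper"  # upper | lower | dual
    manner: str = "random"  # random | systematic
    max_models: int = 1
    seed: int = 0
    require_hueckel: bool = False
    max_attempts_per_model: int = 200

    def __post_init__(self) -> None:
        if self.max_models < 1:
            raise ValueError("max_models must be ≥ 1")
        if min(self.n_hydroxyl, self.n_epoxy, self.n_carboxyl) < 0:
            raise ValueError("group counts must be non-negative")
        if self.n_hydroxyl + self.n_epoxy + self.n_carboxyl == 0:
            raise ValueError("functionalization requested with all group counts zero")
        if self.surface_mode not in ("upper", "lower", "dual"):
            raise ValueError(f"unknown surface_mode {self.surface_mode!r}")
        if self.manner not in ("random", "systematic"):
            raise ValueError(f"unknown manner {self.manner!r}")


def _site_lists(base: MolecularStructure) -> tuple[list[int], list[tuple[int, int]], list[int]]:
    """(basal carbons, basal C–C bonds, edge carbons bearing an H)."""
    adj = base.neighbours()
    is_c = [a.element == "C" for a in base.atoms]
    has_h = [any(base.atoms[j].element == "H" for j in adj[i]) for i in range(base.n_atoms)]
    basal = [i for i in range(base.n_atoms) if is_c[i] and not has_h[i]]
    basal_set = set(basal)
    basal_bonds = [
        (b.i, b.j)
        for b in base.bonds
        if b.order == AROMATIC and b.i in basal_set and b.j in basal_set
    ]
    edge = [i for i in range(base.n_atoms) if is_c[i] and has_h[i]]
    return basal, basal_bonds, edge


def _surface_sign(spec: FunctionalizationSpec, rng: np.random.Generator, k: int) -> float:
    if spec.surface_mode == "upper":
        return 1.0
    if spec.surface_mode == "lower":
        return -1.0
    if spec.manner == "systematic":
        return 1.0 if k % 2 == 0 else -1.0
    return 1.0 if rng.random() < 0.5 else -1.0


def _apply_placement(
    base: MolecularStructure,
    oh_sites: list[int],
    ep_bonds: list[tuple[int, int]],
    cooh_sites: list[int],
    signs: list[float],
) -> MolecularStructure:
    """Graft the groups; modified basal carbons are re-typed sp3 and their
    ring bonds demoted to single, removing them from the π system."""
    m = base.copy()
    sp3: set[int] = set()
    sign_iter = iter(signs)

    def add_atom(element: str, atype: str, pos: np.ndarray) -> int:
        m.atoms.append(Atom(element, atype, pos))
        return len(m.atoms) - 1

    for c in oh_sites:
        s = next(sign_iter)
        cpos = m.atoms[c].position
        o = add_atom("O", "O.3", cpos + np.array([0.0, 0.0, s * 1.43]))
        h = add_atom("H", "H", cpos + np.array([0.31, 0.0, s * (1.43 + 0.90)]))
        m.bonds.append(Bond(c, o, 1))
        m.bonds.append(Bond(o, h, 1))
        sp3.add(c)

    for (ci, cj) in ep_bonds:
        s = next(sign_iter)
        mid = 0.5 * (m.atoms[ci].position + m.atoms[cj].position)
        o = add_atom("O", "O.3", mid + np.array([0.0, 0.0, s * 1.25]))
        m.bonds.append(Bond(ci, o, 1))
        m.bonds.append(Bond(cj, o, 1))
        sp3.update((ci, cj))

    adj = base.neighbours()
    for c in cooh_sites:
        # replace this edge carbon's hydrogen with -C(=O)OH, in plane
        h_idx = next(j for j in adj[c] if base.atoms[j].element == "H")
        cpos = m.atoms[c].position
        direction = m.atoms[h_idx].position - cpos
        direction = direction / np.linalg.norm(direction)
        perp = np.cross(np.array([0.0, 0.0, 1.0]), direction)
        cc = cpos + 1.50 * direction
        o2 = cc + 1.21 * (0.5 * direction + 0.866 * perp)
        o3 = cc + 1.36 * (0.5 * direction - 0.866 * perp)
        hpos = o3 + 0.96 * direction
        m.atoms[h_idx].element = "C"
        m.atoms[h_idx].atom_type = "C.2"
        m.atoms[h_idx].position = cc
        io2 = add_atom("O", "O.2", o2)
        io3 = add_atom("O", "O.3", o3)
        ih = add_atom("H", "H", hpos)
        m.bonds = [b if b.key() != Bond(c, h_idx).key() else Bond(c, h_idx, 1) for b in m.bonds]
        m.bonds.append(Bond(h_idx, io2, 2))
        m.bonds.append(Bond(h_idx, io3, 1))
        m.bonds.append(Bond(io3, ih, 1))

    for c in sp3:
        m.atoms[c].atom_type = "C.3"
    m.bonds = [
        Bond(b.i, b.j, 1) if (b.order == AROMATIC and (b.i in sp3 or b.j in sp3)) else b
        for b in m.bonds
    ]
    m.validate()
    return m


def _random_placements(
    spec: FunctionalizationSpec,
    basal: list[int],
    basal_bonds: list[tuple[int, int]],
    edge: list[int],
    rng: np.random.Generator,
):
    while True:
        used: set[int] = set()
        try:
            oh = list(rng.choice(len(basal), size=spec.n_hydroxyl, replace=False))
            oh_sites = [basal[i] for i in oh]
            used.update(oh_sites)
            free_bonds = [bp for bp in basal_bonds if bp[0] not in used and bp[1] not in used]
            ep: list[tuple[int, int]] = []
            for _ in range(spec.n_epoxy):
                if not free_bonds:
                    raise ValueError("no free basal bond for epoxy")
                bp = free_bonds[int(rng.integers(len(free_bonds)))]
                ep.append(bp)
                used.update(bp)
                free_bonds = [q for q in free_bonds if q[0] not in used and q[1] not in used]
            co = list(rng.choice(len(edge), size=spec.n_carboxyl, replace=False))
            cooh_sites = [edge[i] for i in co]
        except ValueError:
            yield None
            continue
        yield (oh_sites, ep, cooh_sites)


def _systematic_placements(
    spec: FunctionalizationSpec,
    basal: list[int],
    basal_bonds: list[tuple[int, int]],
    edge: list[int],
):
    for oh_sites in combinations(basal, spec.n_hydroxyl):
        used = set(oh_sites)
        free_bonds = [bp for bp in basal_bonds if bp[0] not in used and bp[1] not in used]
        for ep in combinations(free_bonds, spec.n_epoxy):
            flat = [a for bp in ep for a in bp]
            if len(set(flat)) != len(flat):
                continue
            for cooh_sites in combinations(edge, spec.n_carboxyl):
                yield (list(oh_sites), list(ep), list(cooh_sites))


def functionalize_graphene(
    base: MolecularStructure, spec: FunctionalizationSpec
) -> list[MolecularStructure]:
    """Emit up to ``spec.max_models`` fingerprint-unique GO models, each with
    exactly the requested group counts and a fully connected π system.

    Candidates failing the aromaticity check (or duplicating an earlier
    fingerprint) are rejected and regenerated, up to a bounded number of
    attempts per emitted model.
    """
    basal, basal_bonds, edge = _site_lists(base)
    if spec.n_hydroxyl + 2 * spec.n_epoxy > len(basal):
        raise ValueError("not enough basal-plane carbons for the requested hydroxyl/epoxy count")
    if spec.n_carboxyl > len(edge):
        raise ValueError("not enough hydrogen-terminated edge carbons for the requested carboxyl count")

    rng = np.random.default_rng(spec.seed)
    if spec.manner == "random":
        gen = _random_placements(spec, basal, basal_bonds, edge, rng)
    else:
        gen = _systematic_placements(spec, basal, basal_bonds, edge)

    n_basal_groups = spec.n_hydroxyl + spec.n_epoxy
    out: list[MolecularStructure] = []
    seen: set[bytes] = set()
    attempts = 0
    budget = spec.max_attempts_per_model * spec.max_models
    last_reason = "placement enumeration exhausted"
    for placement in gen:
        if len(out) >= spec.max_models:
            break
        attempts += 1
        if spec.manner == "random" and attempts > budget:
            raise ValueError(
                f"could not assemble {spec.max_models} valid GO models in {budget} attempts; "
                f"last failing constraint: {last_reason}"
            )
        if placement is None:
            last_reason = "site collision while sampling placements"
            continue
        oh_sites, ep, cooh_sites = placement
        signs = [_surface_sign(spec, rng, k) for k in range(n_basal_groups)]
        model = _apply_placement(base, oh_sites, ep, cooh_sites, signs)
        report = check_hueckel(model)
        if not report.pi_connected:
            last_reason = "π system disconnected"
            continue
        if spec.require_hueckel and not report.hueckel_ok:
            last_reason = f"4n+2 violated (π count {report.pi_electron_count})"
            continue
        key = _fp_key(model)
        if key in seen:
            last_reason = "duplicate fingerprint"
            continue
        seen.add(key)
        model.name = f"{base.name}_GO{len(out):03d}"
        model.annotations.update(
            n_hydroxyl=spec.n_hydroxyl,
            n_epoxy=spec.n_epoxy,
            n_carboxyl=spec.n_carboxyl,
            pi_electron_count=report.pi_electron_count,
            hueckel_ok=report.hueckel_ok,
        )
        out.append(model)
    if len(out) < spec.max_models and spec.manner == "systematic":
        # systematic enumeration may legitimately run out of combinations
        if not out:
            raise ValueError("no valid placement exists for the requested specification")
    elif len(out) < spec.max_models:
        raise ValueError(
            f"only {len(out)} of {spec.max_models} models assembled; last failing constraint: {last_reason}"
        )
    return out
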