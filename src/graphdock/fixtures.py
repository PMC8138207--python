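"""Deterministic catalogue of small test molecules and mini-carriers.

Everything here is generated from internal templates (seeded 3D embedding
for the organic molecules, the lattice builder for the carbon patches), so
the full test suite runs with no downloads.  Repeated calls return
identical structures.
"""

from __future__ import annotations

from functools import lru_cache

from .builder import FunctionalizationSpec, build_circular_graphene, functionalize_graphene
from .forcefield import assign_atom_types, assign_partial_charges
from .structures import MolecularStructure, read_smiles

__all__ = ["FIXTURE_NAMES", "make_fixture"]

_SMILES = {
    "benzene": "c1ccccc1",
    "n_butane": "CCCC",
    "biphenyl": "c1ccc(-c2ccccc2)cc1",
    "methanol": "CO",
    "methane": "C",
    "naphthalene": "c1ccc2ccccc2c1",
}

# diameter chosen so the circular cut is the 7-ring (coronene-like) patch
_CORONENE_DIAMETER = 7.6

FIXTURE_NAMES = tuple(sorted(_SMILES)) + ("coronene_patch", "go_patch")


@lru_cache(maxsize=None)
def _build(name: str) -> MolecularStructure:
    if name in _SMILES:
        s = read_smiles(_SMILES[name], name=name, seed=20210507)
        s = assign_atom_types(s)
        return assign_partial_charges(s)
    if name == "coronene_patch":
        s = build_circular_graphene(_CORONENE_DIAMETER)
        s.name = "coronene_patch"
        return assign_partial_charges(s)
    if name == "go_patch":
        base = _build("coronene_patch")
        model = functionalize_graphene(
            base, FunctionalizationSpec(n_hydroxyl=1, max_models=1, seed=1)
        )[0]
        model.name = "go_patch"
        return assign_partial_charges(model)
    raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")


def make_fixture(name: str) -> MolecularStructure:
    """Return a canonical typed-and-charged structure by name."""
    return _build(name.replace("-", "_")).copy()
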