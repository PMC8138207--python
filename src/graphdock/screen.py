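"""Batch screening of a ligand library against one carrier.

Ligands are pre-filtered on hydrophobicity (computed logP above a
threshold — highly hydrophobic molecules are the ones that adsorb well on
a graphitic surface) and on size (the longest intramolecular distance must
not exceed the carrier diameter, so edge effects stay moderate).  Each
surviving ligand is docked by repeated cascade runs; records are ranked by
the average binding energy over the repeats, most negative first.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .cascade import CascadeConfig, run_cascade
from .structures import MolecularStructure, longest_intramolecular_distance

__all__ = ["ScreenRecord", "filter_library", "screen_library", "crippen_logp", "write_screen_tsv"]

log = logging.getLogger(__name__)


def crippen_logp(ligand: MolecularStructure) -> float:
    """Atomic-contribution (Crippen) logP estimate of a ligand."""
    from rdkit.Chem import Crippen

    from .structures import to_rdkit

    return float(Crippen.MolLogP(to_rdkit(ligand, sanitize="full")))


def carrier_size_limit(carrier: MolecularStructure) -> float:
    """Diameter of a circular carrier, the smaller side of a rectangular
    one, or the longest intramolecular distance as a fallback."""
    ann = carrier.annotations
    if ann.get("shape") == "circular":
        return float(ann["diameter"])
    if ann.get("shape") == "rectangular":
        return float(min(ann["width"], ann["height"]))
    return longest_intramolecular_distance(carrier)


def filter_library(
    ligands: list[MolecularStructure],
    carrier: MolecularStructure,
    logp_threshold: float = 5.0,
) -> list[MolecularStructure]:
    """Keep ligands with logP > threshold whose longest intramolecular
    distance does not exceed the carrier diameter; log both filter counts."""
    limit = carrier_size_limit(carrier)
    kept: list[MolecularStructure] = []
    n_logp = 0
    n_size = 0
    for lig in ligands:
        if crippen_logp(lig) <= logp_threshold:
            n_logp += 1
            continue
        if longest_intramolecular_distance(lig) > limit:
            n_size += 1
            continue
        kept.append(lig)
    log.info(
        "filter_library: %d in, %d rejected on logP<=%.2f, %d rejected on size>%.2f Å, %d kept",
        len(ligands), n_logp, logp_threshold, n_size, limit, len(kept),
    )
    return kept


@dataclass
class ScreenRecord:
    ligand_id: str
    repeat_energies: list[float] = field(default_factory=list)
    average_energy: float | None = None
    rank: int | None = None
    failed: bool = False
    error: str = ""


def screen_library(
    ligands: list[MolecularStructure],
    carrier: MolecularStructure,
    cascade: CascadeConfig,
    repeats: int = 3,
    seeds: list[int] | None = None,
) -> list[ScreenRecord]:
    """Dock every ligand ``repeats`` times with the cascade protocol and
    rank by the average best-pose binding energy (ascending: most negative
    first; ties broken by ligand id).  A per-ligand failure flags the
    record but never drops it."""
    if repeats < 1:
        raise ValueError("repeats must be ≥ 1")
    base = cascade.layers[0][1].seed
    if seeds is None:
        seeds = [base + r for r in range(repeats)]
    if len(seeds) != repeats:
        raise ValueError("one seed per repeat required")

    records: list[ScreenRecord] = []
    for lig in ligands:
        rec = ScreenRecord(ligand_id=lig.name)
        try:
            for seed in seeds:
                layers = [
                    (espec, dataclasses.replace(qcfg, seed=seed + 1000 * li))
                    for li, (espec, qcfg) in enumerate(cascade.layers)
                ]
                cfg = dataclasses.replace(cascade, layers=layers)
                result = run_cascade(carrier, lig, cfg)
                if result.best_report is None or result.best_report.e_delta is None:
                    raise RuntimeError("cascade returned no binding energy")
                rec.repeat_energies.append(float(result.best_report.e_delta))
            rec.average_energy = sum(rec.repeat_energies) / len(rec.repeat_energies)
        except Exception as exc:  # per-ligand failure: flag and continue
            rec.failed = True
            rec.error = str(exc)
            log.warning("screen: ligand %s failed: %s", lig.name, exc)
        records.append(rec)

    ok = sorted(
        (r for r in records if not r.failed), key=lambda r: (r.average_energy, r.ligand_id)
    )
    for i, r in enumerate(ok, start=1):
        r.rank = i
    failed = sorted((r for r in records if r.failed), key=lambda r: r.ligand_id)
    for i, r in enumerate(failed, start=len(ok) + 1):
        r.rank = i
    return sorted(records, key=lambda r: r.rank)


def write_screen_tsv(records: list[ScreenRecord], path: str | Path) -> None:
    import pandas as pd

    rows = [
        {
            "rank": r.rank,
            "ligand_id": r.ligand_id,
            "repeat_energies_kcal_mol": ";".join(f"{e:.4f}" for e in r.repeat_energies),
            "average_binding_energy_kcal_mol": (
                f"{r.average_energy:.4f}" if r.average_energy is not None else ""
            ),
            "failed": int(r.failed),
            "error": r.error,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
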