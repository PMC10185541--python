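"""Structure readers and writers: multi-record XYZ and SDF."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .compare import AtomSet
from .errors import MetallobuildError

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_sdf",
    "read_structure",
    "conformers_to_xyz",
    "write_build_report",
]


def write_xyz(path, frames: Sequence[tuple]) -> None:
    """Write a multi-record XYZ file.

    ``frames`` is a sequence of (elements, coordinates, comment) triples.
    """
    lines = []
    for elements, coords, comment in frames:
        coords = np.asarray(coords, dtype=float)
        lines.append(str(len(elements)))
        lines.append(str(comment).replace("\n", " "))
        for el, (x, y, z) in zip(elements, coords):
            lines.append(f"{el:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_xyz(path) -> list[AtomSet]:
    """Read every record of a (multi-)XYZ file into AtomSets (no graph)."""
    text = Path(path).read_text(encoding="utf-8").splitlines()
    out: list[AtomSet] = []
    i = 0
    while i < len(text):
        line = text[i].strip()
        if not line:
            i += 1
            continue
        n = int(line)
        body = text[i + 2 : i + 2 + n]
        elements, coords = [], []
        for row in body:
            parts = row.split()
            elements.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        out.append(AtomSet(elements=elements, coordinates=np.array(coords)))
        i += 2 + n
    if not out:
        raise MetallobuildError(f"no XYZ records found in {path}")
    return out


def conformers_to_xyz(conformers: Sequence, path) -> None:
    """One XYZ record per conformer; energy and provenance in the comment."""
    frames = []
    for k, c in enumerate(conformers):
        prov = c.provenance
        comment = (
            f"rank={k} energy={c.energy:.6f} calculator={c.calculator} "
            f"core={prov.get('core')} charge={c.total_charge} "
            f"multiplicity={c.spin_multiplicity}"
        )
        frames.append((c.elements, c.coordinates, comment))
    write_xyz(path, frames)


_BOND_TYPES = {
    1.0: Chem.BondType.SINGLE,
    1.5: Chem.BondType.AROMATIC,
    2.0: Chem.BondType.DOUBLE,
    3.0: Chem.BondType.TRIPLE,
}


def write_sdf(conformers: Sequence, path) -> None:
    """Write conformers (elements/coordinates/graph) to an SDF file."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for c in conformers:
            mol = Chem.RWMol()
            for el in c.elements:
                atom = Chem.Atom(el)
                atom.SetNoImplicit(True)
                mol.AddAtom(atom)
            for i, j, order in c.graph:
                mol.AddBond(int(i), int(j), _BOND_TYPES.get(float(order),
                                                            Chem.BondType.SINGLE))
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i, pos in enumerate(np.asarray(c.coordinates)):
                conf.SetAtomPosition(i, pos.tolist())
            mol.AddConformer(conf)
            m = mol.GetMol()
            m.UpdatePropertyCache(strict=False)
            m.SetDoubleProp("energy", float(c.energy))
            writer.write(m)
    finally:
        writer.close()


def read_structure(path, metal_index: Optional[int] = None) -> AtomSet:
    """Read the first record of an XYZ or SDF file into an AtomSet."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xyz":
        atoms = read_xyz(path)[0]
    elif suffix in (".sdf", ".mol"):
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
        mol = next((m for m in supplier if m is not None), None)
        if mol is None:
            raise MetallobuildError(f"no readable molecule in {path}")
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
        graph = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
        ]
        atoms = AtomSet(elements=elements, coordinates=coords, graph=graph)
    else:
        raise MetallobuildError(f"unsupported structure format {suffix!r}")
    atoms.metal_index = metal_index
    return atoms


def write_build_report(report, path) -> None:
    payload = {
        "parameters": report.parameters,
        "counts": report.counts,
        "failure_reasons": report.failure_reasons,
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")
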