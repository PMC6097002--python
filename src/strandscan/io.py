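"""Structure and trajectory input: one backbone grain per residue.

PDB structures are coarse-grained on read: each residue becomes a single
grain placed at the centre of mass of its backbone heavy atoms (N, CA, C,
O — the conventional CG backbone-bead placement) or, as a fallback for
CA-only depositions, at the CA position.  Coarse-grained trajectories
(GRO/XTC/TRR) are read through MDAnalysis by selecting the backbone beads
by name (default ``BB``); coordinates are Angstrom internally everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from os import PathLike
from typing import Iterator, Literal

import numpy as np

from .topology import BackboneFrame

__all__ = [
    "PdbBackbone",
    "load_pdb_backbone",
    "load_cg_trajectory",
    "write_gro",
]

# standard atomic masses for the backbone heavy atoms
_MASSES = {"N": 14.007, "CA": 12.011, "C": 12.011, "O": 15.999}
_BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class PdbBackbone:
    """CG-mapped PDB structure: coordinates plus chain bookkeeping.

    ``chain_breaks`` lists the grain indices ending a chain segment
    (chain changes and gaps in residue numbering both break the chain, so
    a strand can never be built across missing residues).
    """

    frame: BackboneFrame
    chain_breaks: tuple[int, ...]
    residue_labels: tuple[str, ...]

    @property
    def n_grains(self) -> int:
        return self.frame.n_grains


def load_pdb_backbone(
    path: str | PathLike,
    mapping: Literal["backbone_com", "ca_only"] = "backbone_com",
    model: int = 0,
) -> PdbBackbone:
    """Read a PDB file and map each residue to one backbone grain.

    Parameters
    ----------
    path:
        PDB file.
    mapping:
        ``backbone_com`` — mass-weighted centre of the N, CA, C, O atoms
        (default); ``ca_only`` — the CA position.
    model:
        Model index for multi-model (NMR) entries; the first model by
        default.

    Raises
    ------
    ValueError
        If a residue lacks the required backbone atoms (named by chain and
        residue), or the file contains no residues.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no models found")
    try:
        mdl = models[model]
    except IndexError:
        raise ValueError(
            f"{path}: model {model} requested but only {len(models)} present"
        ) from None

    needed = _BACKBONE_ATOMS if mapping == "backbone_com" else ("CA",)
    coords: list[np.ndarray] = []
    labels: list[str] = []
    breaks: list[int] = []
    for chain in mdl:
        prev_resseq: int | None = None
        chain_started_at = len(coords)
        for residue in chain:
            het, resseq, icode = residue.id
            if het.strip():
                continue  # water / ligands are not peptide residues
            missing = [a for a in needed if a not in residue]
            if missing:
                raise ValueError(
                    f"{path}: chain {chain.id} residue {resseq}{icode.strip()} "
                    f"({residue.resname}) lacks backbone atom(s) "
                    f"{', '.join(missing)}"
                )
            if (
                prev_resseq is not None
                and resseq != prev_resseq + 1
                and coords
            ):
                breaks.append(len(coords) - 1)  # numbering gap = chain break
            prev_resseq = resseq
            if mapping == "ca_only":
                coords.append(np.asarray(residue["CA"].coord, dtype=float))
            else:
                pos = np.array([residue[a].coord for a in needed], dtype=float)
                m = np.array([_MASSES[a] for a in needed])
                coords.append((pos * m[:, None]).sum(axis=0) / m.sum())
            labels.append(f"{chain.id}:{residue.resname}{resseq}")
        if len(coords) > chain_started_at:
            breaks.append(len(coords) - 1)  # end of chain
    if not coords:
        raise ValueError(f"{path}: no standard residues found")
    frame = BackboneFrame(np.asarray(coords))
    return PdbBackbone(frame, tuple(sorted(set(breaks))), tuple(labels))


def load_cg_trajectory(
    topology_path: str | PathLike,
    trajectory_path: str | PathLike | None = None,
    backbone_name: str = "BB",
) -> Iterator[BackboneFrame]:
    """Iterate backbone-bead frames of a CG trajectory.

    ``topology_path`` is a GRO (or other MDAnalysis-readable) file naming
    the beads; ``trajectory_path`` an optional XTC/TRR/GRO trajectory.
    Yields one :class:`BackboneFrame` per frame in file order, with
    coordinates in Angstrom, per-frame box lengths, and time in ns.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # mass guessing on CG bead names
        if trajectory_path is None:
            universe = mda.Universe(str(topology_path))
        else:
            universe = mda.Universe(str(topology_path), str(trajectory_path))
    beads = universe.select_atoms(f"name {backbone_name}")
    if beads.n_atoms == 0:
        raise ValueError(
            f"{topology_path}: no beads named {backbone_name!r} found"
        )
    for ts in universe.trajectory:
        box = None
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            box = np.array(ts.dimensions[:3], dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # readers without dt information
            time_ns = float(ts.time) / 1000.0 if ts.time is not None else None
        yield BackboneFrame(
            beads.positions.astype(float), box=box, time=time_ns
        )


def write_gro(
    frame: BackboneFrame,
    path: str | PathLike,
    backbone_name: str = "BB",
    resname: str = "PEP",
) -> None:
    """Write a frame as a GRO file with one ``BB`` bead per grain.

    Frames without a box get a bounding box padded by 20 A, since the GRO
    format always carries box vectors.
    """
    import MDAnalysis as mda

    n = frame.n_grains
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe.empty(
            n, n_residues=n, atom_resindex=np.arange(n), trajectory=True
        )
        universe.add_TopologyAttr("names", [backbone_name] * n)
        universe.add_TopologyAttr("resnames", [resname] * n)
        universe.add_TopologyAttr("resids", np.arange(1, n + 1))
        universe.atoms.positions = frame.coordinates
        if frame.box is not None:
            box = frame.box
        else:
            span = frame.coordinates.max(axis=0) - frame.coordinates.min(axis=0)
            box = span + 20.0
        universe.dimensions = [*box, 90.0, 90.0, 90.0]
        universe.atoms.write(str(path))
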