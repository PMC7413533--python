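"""Structure/trajectory data model, PDB/DCD input-output and atom selection.

Coordinates are stored in Angstrom, energies in kcal/mol and temperatures in
Kelvin throughout the package.  Residue identifiers are the author numbers
from the input file (1-based, inclusive ranges); nothing is ever renumbered,
so a residue referred to in the literature as e.g. A71 keeps ``residue_id``
71 here.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import yaml

#: Boltzmann constant in kcal mol^-1 K^-1.
KB = 0.0019872041

# 3-letter codes of the standard amino acids.
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# Residue names used for DNA/RNA nucleotides in PDB files.
NUCLEOTIDES = {"DA", "DT", "DG", "DC", "DU", "A", "T", "G", "C", "U"}


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


@dataclass(frozen=True)
class Atom:
    """One atom record.

    ``coordinates`` is a length-3 float array in Angstrom; ``residue_id`` is
    the author residue number of the source file.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    coordinates: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(
                f"atom {self.serial} ({self.name}): coordinates must be a "
                f"finite 3-vector, got {self.coordinates!r}"
            )
        object.__setattr__(self, "coordinates", coords)


@dataclass
class Structure:
    """An ordered collection of atoms, e.g. one MODEL of a PDB file."""

    atoms: list[Atom]
    metadata: str = ""

    def __post_init__(self):
        keys = [(a.chain_id, a.residue_id, a.name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(
                f"duplicate atom (chain, residue, name) triple: {dup}"
            )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    @property
    def coordinates(self) -> np.ndarray:
        """All coordinates as an (N, 3) array (a copy)."""
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    def with_coordinates(self, coords: np.ndarray) -> "Structure":
        """A new Structure with identical atom metadata but new coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"expected coordinates of shape {(len(self.atoms), 3)}, "
                f"got {coords.shape}"
            )
        atoms = [replace(a, coordinates=c) for a, c in zip(self.atoms, coords)]
        return Structure(atoms=atoms, metadata=self.metadata)

    def protein_chains(self) -> list[str]:
        """Chain ids containing standard amino acids, in order of appearance."""
        out: list[str] = []
        for a in self.atoms:
            if a.residue_name in AMINO_ACIDS and a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def nucleic_chains(self) -> list[str]:
        """Chain ids containing nucleotides, in order of appearance."""
        out: list[str] = []
        for a in self.atoms:
            if a.residue_name in NUCLEOTIDES and a.chain_id not in out:
                out.append(a.chain_id)
        return out


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology.

    ``frames`` has shape (F, N, 3) in Angstrom with N equal to the number of
    atoms of the topology.
    """

    topology: Structure
    frames: np.ndarray
    frame_spacing: float | None = None  # ps between stored frames

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (F, N, 3) array with F >= 1")
        if self.frames.shape[1:] != (len(self.topology), 3):
            raise ValueError(
                f"frame atom count mismatch: expected "
                f"{len(self.topology)} atoms, got {self.frames.shape[1]}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> Structure:
        """Topology with the coordinates of frame ``i``."""
        return self.topology.with_coordinates(self.frames[i])


@dataclass(frozen=True)
class Selection:
    """Ordered atom indices into a Structure."""

    indices: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("indices must be one-dimensional")
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("indices must be strictly increasing")
        if idx.size and idx[0] < 0:
            raise ValueError("indices must be non-negative")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return self.indices.size


def select(
    structure: Structure,
    chain: str | None = None,
    residue_range: tuple[int, int] | None = None,
    atom_names: Iterable[str] | None = None,
) -> Selection:
    """Indices of atoms matching every given criterion, in structure order.

    An empty result is valid; downstream operations that require atoms
    reject empty selections themselves.
    """
    if not structure.atoms:
        raise ValueError("cannot select from an empty structure")
    names = set(atom_names) if atom_names is not None else None
    idx = []
    for i, a in enumerate(structure.atoms):
        if chain is not None and a.chain_id != chain:
            continue
        if residue_range is not None and not (
            residue_range[0] <= a.residue_id <= residue_range[1]
        ):
            continue
        if names is not None and a.name not in names:
            continue
        idx.append(i)
    return Selection(indices=np.array(idx, dtype=int))


@dataclass
class RegionConfig:
    """Secondary-structure layout and analysis anchors of a homodimer.

    ``elements`` maps element names (``alpha1`` ... ``alpha6``, ``beta1``,
    ``beta2``, ``loop1``) to inclusive author-residue ranges, applied
    identically to both protein chains.  ``dna_binding_domain`` spans the
    winged helix-turn-helix region (start of the second helix through the
    end of the second beta strand).  ``probe_residue`` is the residue whose
    two C-alpha atoms (one per chain) define the recognition-helix
    separation; 71 corresponds to A71/A71' of ZitR.
    """

    protein_chains: tuple[str, str]
    dna_binding_domain: tuple[int, int]
    elements: dict[str, tuple[int, int]] = field(default_factory=dict)
    probe_residue: int = 71
    temperature: float = 300.0
    dna_chains: tuple[str, ...] = ()

    def __post_init__(self):
        self.protein_chains = tuple(self.protein_chains)
        self.dna_chains = tuple(self.dna_chains)
        self.dna_binding_domain = tuple(int(v) for v in self.dna_binding_domain)
        self.elements = {
            str(k): (int(v[0]), int(v[1])) for k, v in self.elements.items()
        }
        if len(self.protein_chains) != 2:
            raise ValueError("exactly two protein chains are required")
        for name, (lo, hi) in self.elements.items():
            if lo > hi:
                raise ValueError(f"element {name}: range {lo}..{hi} is empty")
        ranges = sorted(self.elements.values())
        for (lo1, hi1), (lo2, hi2) in zip(ranges, ranges[1:]):
            if lo2 <= hi1:
                raise ValueError(
                    f"overlapping element ranges {lo1}..{hi1} and {lo2}..{hi2}"
                )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RegionConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise ParseError(f"{path}: expected a mapping at top level")
        return cls(
            protein_chains=tuple(raw["protein_chains"]),
            dna_binding_domain=tuple(raw["dna_binding_domain"]),
            elements={k: tuple(v) for k, v in raw.get("elements", {}).items()},
            probe_residue=int(raw.get("probe_residue", 71)),
            temperature=float(raw.get("temperature", 300.0)),
            dna_chains=tuple(raw.get("dna_chains", ())),
        )

    def to_yaml(self, path: str | os.PathLike) -> None:
        data = {
            "protein_chains": list(self.protein_chains),
            "dna_binding_domain": list(self.dna_binding_domain),
            "elements": {k: list(v) for k, v in self.elements.items()},
            "probe_residue": self.probe_residue,
            "temperature": self.temperature,
            "dna_chains": list(self.dna_chains),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# File I/O.  PDB reading/writing is backed by biotite, DCD by mdtraj's
# low-level reader (which keeps the file's native Angstrom units).
# ---------------------------------------------------------------------------


def _scan_pdb_lines(path: str | os.PathLike) -> None:
    """Raise ParseError naming the first malformed ATOM/HETATM line."""
    with open(path) as fh:
        n_records = 0
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            n_records += 1
            if len(line.rstrip("\n")) < 54:
                raise ParseError(
                    f"{path}: line {lineno}: truncated ATOM/HETATM record"
                )
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: unparsable coordinates "
                    f"{line[30:54]!r}"
                ) from None
    if n_records == 0:
        raise ParseError(f"{path}: no ATOM/HETATM records found")


def _atoms_from_atom_array(arr, metadata: str) -> Structure:
    serials = (
        arr.get_annotation("atom_id")
        if "atom_id" in arr.get_annotation_categories()
        else np.arange(1, arr.array_length() + 1)
    )
    atoms = [
        Atom(
            serial=int(serials[i]),
            name=str(arr.atom_name[i]),
            element=str(arr.element[i]),
            residue_name=str(arr.res_name[i]),
            residue_id=int(arr.res_id[i]),
            chain_id=str(arr.chain_id[i]),
            coordinates=arr.coord[i],
        )
        for i in range(arr.array_length())
    ]
    return Structure(atoms=atoms, metadata=metadata)


def read_structure(path: str | os.PathLike, format: str = "pdb") -> Structure:
    """Read the first model of a PDB file as a Structure.

    All ATOM and HETATM records are kept; alternate locations are resolved
    by highest occupancy (ties toward altloc 'A').  Chain ids and author
    residue numbers are preserved.
    """
    if format != "pdb":
        raise ValueError(f"unsupported structure format: {format}")
    if os.path.getsize(path) == 0:
        raise ParseError(f"{path}: file is empty")
    _scan_pdb_lines(path)
    import biotite.structure.io.pdb as pdbio

    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        arr = pdb_file.get_structure(
            model=1, altloc="occupancy", extra_fields=["atom_id"]
        )
    except Exception as exc:  # biotite raises several exception types
        raise ParseError(f"{path}: failed to parse PDB: {exc}") from exc
    return _atoms_from_atom_array(arr, metadata=os.fspath(path))


def write_structure(structure: Structure, path: str | os.PathLike) -> None:
    """Write a Structure as a single-model PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    arr = struc.AtomArray(len(structure))
    arr.coord = structure.coordinates
    arr.chain_id = np.array([a.chain_id for a in structure.atoms])
    arr.res_id = np.array([a.residue_id for a in structure.atoms])
    arr.res_name = np.array([a.residue_name for a in structure.atoms])
    arr.atom_name = np.array([a.name for a in structure.atoms])
    arr.element = np.array([a.element for a in structure.atoms])
    arr.set_annotation(
        "atom_id", np.array([a.serial for a in structure.atoms], dtype=int)
    )
    hetero = np.array(
        [
            a.residue_name not in AMINO_ACIDS and a.residue_name not in NUCLEOTIDES
            for a in structure.atoms
        ]
    )
    arr.hetero = hetero
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def _infer_traj_format(path: str | os.PathLike) -> str:
    suffix = os.path.splitext(os.fspath(path))[1].lower()
    if suffix == ".dcd":
        return "dcd"
    return "pdb"


def read_trajectory(
    path: str | os.PathLike,
    topology: Structure,
    format: str | None = None,
) -> Trajectory:
    """Read a multi-model PDB or DCD file as a Trajectory over ``topology``."""
    fmt = format or _infer_traj_format(path)
    if fmt == "pdb":
        import biotite.structure.io.pdb as pdbio

        _scan_pdb_lines(path)
        pdb_file = pdbio.PDBFile.read(str(path))
        stack = pdb_file.get_structure(altloc="occupancy")
        frames = np.asarray(stack.coord, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
    elif fmt == "dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(path)) as fh:
            xyz, _cell_len, _cell_ang = fh.read()
        frames = np.asarray(xyz, dtype=float)
    else:
        raise ValueError(f"unsupported trajectory format: {fmt}")
    if frames.shape[1] != len(topology):
        raise ValueError(
            f"trajectory atom count mismatch: expected {len(topology)}, "
            f"got {frames.shape[1]}"
        )
    return Trajectory(topology=topology, frames=frames)


def write_trajectory(
    traj: Trajectory, path: str | os.PathLike, format: str | None = None
) -> None:
    """Write trajectory frames as DCD (default) or multi-model PDB."""
    fmt = format or _infer_traj_format(path)
    if fmt == "dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(path), "w") as fh:
            fh.write(np.asarray(traj.frames, dtype=np.float32))
        _fix_dcd_title(path)
    elif fmt == "pdb":
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdbio

        template = traj.topology
        arrays = []
        for f in range(traj.n_frames):
            s = template.with_coordinates(traj.frames[f])
            arr = struc.AtomArray(len(s))
            arr.coord = s.coordinates
            arr.chain_id = np.array([a.chain_id for a in s.atoms])
            arr.res_id = np.array([a.residue_id for a in s.atoms])
            arr.res_name = np.array([a.residue_name for a in s.atoms])
            arr.atom_name = np.array([a.name for a in s.atoms])
            arr.element = np.array([a.element for a in s.atoms])
            arrays.append(arr)
        stack = struc.stack(arrays)
        pdb_file = pdbio.PDBFile()
        pdb_file.set_structure(stack)
        pdb_file.write(str(path))
    else:
        raise ValueError(f"unsupported trajectory format: {fmt}")


def _fix_dcd_title(path: str | os.PathLike) -> None:
    """Replace the writer's timestamped DCD title line with a fixed string.

    The title is free-form text; pinning it makes repeated writes of the
    same trajectory byte-identical.
    """
    with open(path, "r+b") as fh:
        head = fh.read(4096)
        idx = head.find(b"REMARKS Created")
        if idx >= 0:
            fixed = b"REMARKS Written by allodyn".ljust(80, b"\x00")
            fh.seek(idx)
            fh.write(fixed)


def fetch_pdb(accession: str, out_dir: str | os.PathLike = ".") -> str:
    """Download a PDB entry from RCSB (optional helper; needs network access).

    Returns the path of the downloaded file.
    """
    import urllib.request

    accession = accession.upper()
    url = f"https://files.rcsb.org/download/{accession}.pdb"
    out_path = os.path.join(os.fspath(out_dir), f"{accession}.pdb")
    with urllib.request.urlopen(url, timeout=30) as resp:
        data = resp.read()
    with open(out_path, "wb") as fh:
        fh.write(data)
    return out_path


def sha256_of(path: str | os.PathLike) -> str:
    """Checksum helper used for provenance manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
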