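"""Protein-DNA interaction census: hydrogen bonds, ionic, hydrophobic.

Counts the intermolecular contacts that anchor a protein-DNA complex, in
the three categories typically reported for repressor-operator
interfaces: hydrogen bonds (donor/acceptor heavy-atom pairs, mostly to
the phosphate-deoxyribose backbone), ionic interactions (side-chain
cationic nitrogens of Lys/Arg/His to phosphate oxygens) and hydrophobic
contacts (apolar side-chain carbons to deoxyribose/base carbons).

The geometric criteria are package defaults (3.5 A and, when hydrogens
are present, a D-H...A angle of at least 120 degrees for hydrogen bonds;
4.0 A ionic; 4.5 A hydrophobic), configurable per call; every report
embeds the criteria used, since absolute counts depend on them.
Hydrogen-free structures (typical of crystal models) fall back to
distance-only hydrogen-bond detection.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import AMINO_ACIDS, NUCLEOTIDES, Structure, Trajectory

# --- donor/acceptor/apolar atom tables --------------------------------------

# Protein heavy-atom hydrogen-bond donors (backbone N plus side chains).
_PROTEIN_DONORS: dict[str, set[str]] = {aa: {"N"} for aa in AMINO_ACIDS}
_PROTEIN_DONORS["PRO"] = set()  # proline backbone N carries no hydrogen
for aa, names in {
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"},
}.items():
    _PROTEIN_DONORS[aa] = _PROTEIN_DONORS[aa] | names

# Protein heavy-atom hydrogen-bond acceptors.
_PROTEIN_ACCEPTORS: dict[str, set[str]] = {aa: {"O", "OXT"} for aa in AMINO_ACIDS}
for aa, names in {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
}.items():
    _PROTEIN_ACCEPTORS[aa] = _PROTEIN_ACCEPTORS[aa] | names

# DNA backbone oxygens plus base acceptors/donors (heavy atoms).
_DNA_BACKBONE_O = {"OP1", "OP2", "O3'", "O5'", "O4'"}
_DNA_ACCEPTORS: dict[str, set[str]] = {
    "DA": _DNA_BACKBONE_O | {"N1", "N3", "N7"},
    "DG": _DNA_BACKBONE_O | {"N3", "N7", "O6"},
    "DC": _DNA_BACKBONE_O | {"O2", "N3"},
    "DT": _DNA_BACKBONE_O | {"O2", "O4"},
}
_DNA_DONORS: dict[str, set[str]] = {
    "DA": {"N6"},
    "DG": {"N1", "N2"},
    "DC": {"N4"},
    "DT": {"N3"},
}
for alias, canon in (("A", "DA"), ("G", "DG"), ("C", "DC"), ("T", "DT")):
    _DNA_ACCEPTORS[alias] = _DNA_ACCEPTORS[canon]
    _DNA_DONORS[alias] = _DNA_DONORS[canon]

# Side-chain cationic nitrogens for ionic interactions.
_CATIONIC_N = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
}
_DNA_PHOSPHATE_O = {"OP1", "OP2", "O3'", "O5'"}

# Apolar side-chain carbons of the hydrophobic residues (+ Thr CG2).
_PROTEIN_APOLAR_C: dict[str, set[str]] = {
    "ALA": {"CB"},
    "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "MET": {"CB", "CG", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "PRO": {"CB", "CG", "CD"},
    "TRP": {"CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "THR": {"CG2"},
}
# Deoxyribose and base carbons (C7/C5M: thymine methyl naming variants).
_DNA_CARBONS = {
    "C1'", "C2'", "C3'", "C4'", "C5'",
    "C2", "C4", "C5", "C6", "C8", "C7", "C5M",
}


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric cutoffs, Angstrom (angle in degrees)."""

    hbond_distance: float = 3.5
    hbond_angle_min: float = 120.0  # applied only when hydrogens are present
    ionic_distance: float = 4.0
    hydrophobic_distance: float = 4.5

    def __post_init__(self):
        for name in ("hbond_distance", "ionic_distance", "hydrophobic_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class InteractionRecord:
    """One intermolecular contact between a protein and a DNA partner."""

    kind: str  # hbond | ionic | hydrophobic
    protein: tuple[str, int, str, str]  # chain, residue_id, residue_name, atom
    dna: tuple[str, int, str, str]  # chain, nucleotide_id, base, atom
    distance: float
    angle: float | None = None  # D-H...A, hydrogen bonds only


def _partition(structure: Structure):
    protein, dna = [], []
    for i, a in enumerate(structure.atoms):
        if a.residue_name in AMINO_ACIDS:
            protein.append(i)
        elif a.residue_name in NUCLEOTIDES:
            dna.append(i)
    if not dna:
        raise ValueError("no nucleic chain found")
    if not protein:
        raise ValueError("no protein chain found")
    return protein, dna


def _has_hydrogens(structure: Structure) -> bool:
    return any(a.element == "H" for a in structure.atoms)


def _cross_pairs(structure, prot_idx, dna_idx, cutoff):
    """(protein atom index, dna atom index, distance) within cutoff."""
    coords = structure.coordinates
    if not prot_idx or not dna_idx:
        return []
    tp = cKDTree(coords[prot_idx])
    td = cKDTree(coords[dna_idx])
    out = []
    for ip, neighbors in enumerate(tp.query_ball_tree(td, cutoff)):
        for jd in neighbors:
            i, j = prot_idx[ip], dna_idx[jd]
            d = float(np.linalg.norm(coords[i] - coords[j]))
            out.append((i, j, d))
    return out


def _bound_hydrogens(structure: Structure, heavy_index: int) -> list[int]:
    heavy = structure.atoms[heavy_index]
    out = []
    for i, a in enumerate(structure.atoms):
        if (
            a.element == "H"
            and a.chain_id == heavy.chain_id
            and a.residue_id == heavy.residue_id
            and np.linalg.norm(a.coordinates - heavy.coordinates) <= 1.25
        ):
            out.append(i)
    return out


def _dha_angle(d, h, a) -> float:
    v1 = d - h
    v2 = a - h
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def hydrogen_bonds(
    structure: Structure, criteria: InteractionCriteria | None = None
) -> list[InteractionRecord]:
    """Donor-acceptor pairs across the protein/DNA interface.

    Both directions are considered (protein donor to DNA acceptor and DNA
    donor to protein acceptor).  When the structure carries hydrogens, a
    donor qualifies only if some bound hydrogen makes a D-H...A angle of
    at least ``hbond_angle_min``; otherwise detection is distance-only.
    """
    crit = criteria or InteractionCriteria()
    prot_idx, dna_idx = _partition(structure)
    with_h = _has_hydrogens(structure)
    coords = structure.coordinates
    records = []
    seen: set[tuple[int, int]] = set()
    for i, j, d in _cross_pairs(structure, prot_idx, dna_idx, crit.hbond_distance):
        ap, ad = structure.atoms[i], structure.atoms[j]
        p_donates = ap.name in _PROTEIN_DONORS.get(ap.residue_name, set()) and (
            ad.name in _DNA_ACCEPTORS.get(ad.residue_name, set())
        )
        d_donates = ad.name in _DNA_DONORS.get(ad.residue_name, set()) and (
            ap.name in _PROTEIN_ACCEPTORS.get(ap.residue_name, set())
        )
        if not (p_donates or d_donates):
            continue
        angle = None
        if with_h:
            ok = False
            donors = []
            if p_donates:
                donors.append((i, j))
            if d_donates:
                donors.append((j, i))
            for donor_i, acceptor_i in donors:
                for h in _bound_hydrogens(structure, donor_i):
                    ang = _dha_angle(
                        coords[donor_i], coords[h], coords[acceptor_i]
                    )
                    if ang >= crit.hbond_angle_min:
                        ok = True
                        angle = ang
                        break
                if ok:
                    break
            if not ok:
                continue
        key = (i, j)
        if key in seen:
            continue
        seen.add(key)
        records.append(
            InteractionRecord(
                kind="hbond",
                protein=(ap.chain_id, ap.residue_id, ap.residue_name, ap.name),
                dna=(ad.chain_id, ad.residue_id, ad.residue_name, ad.name),
                distance=d,
                angle=angle,
            )
        )
    return records


def ionic_interactions(
    structure: Structure, criteria: InteractionCriteria | None = None
) -> list[InteractionRecord]:
    """Side-chain cationic N (Lys/Arg/His) to DNA phosphate oxygens."""
    crit = criteria or InteractionCriteria()
    prot_idx, dna_idx = _partition(structure)
    records = []
    for i, j, d in _cross_pairs(structure, prot_idx, dna_idx, crit.ionic_distance):
        ap, ad = structure.atoms[i], structure.atoms[j]
        if ap.name not in _CATIONIC_N.get(ap.residue_name, set()):
            continue
        if ad.name not in _DNA_PHOSPHATE_O:
            continue
        records.append(
            InteractionRecord(
                kind="ionic",
                protein=(ap.chain_id, ap.residue_id, ap.residue_name, ap.name),
                dna=(ad.chain_id, ad.residue_id, ad.residue_name, ad.name),
                distance=d,
            )
        )
    return records


def hydrophobic_contacts(
    structure: Structure, criteria: InteractionCriteria | None = None
) -> list[InteractionRecord]:
    """Apolar carbon pairs, one record per (protein residue, nucleotide).

    All apolar-carbon pairs within the cutoff are aggregated to a single
    record per residue pair carrying the minimum distance (and the atom
    names realizing it).
    """
    crit = criteria or InteractionCriteria()
    prot_idx, dna_idx = _partition(structure)
    best: dict[tuple, InteractionRecord] = {}
    for i, j, d in _cross_pairs(
        structure, prot_idx, dna_idx, crit.hydrophobic_distance
    ):
        ap, ad = structure.atoms[i], structure.atoms[j]
        if ap.name not in _PROTEIN_APOLAR_C.get(ap.residue_name, set()):
            continue
        if ad.residue_name not in NUCLEOTIDES or ad.name not in _DNA_CARBONS:
            continue
        key = (ap.chain_id, ap.residue_id, ad.chain_id, ad.residue_id)
        rec = InteractionRecord(
            kind="hydrophobic",
            protein=(ap.chain_id, ap.residue_id, ap.residue_name, ap.name),
            dna=(ad.chain_id, ad.residue_id, ad.residue_name, ad.name),
            distance=d,
        )
        if key not in best or d < best[key].distance:
            best[key] = rec
    return [best[k] for k in sorted(best)]


def interaction_summary(
    structure: Structure, criteria: InteractionCriteria | None = None
) -> dict[str, int]:
    """Counts of each interaction kind for one structure."""
    crit = criteria or InteractionCriteria()
    return {
        "hbond": len(hydrogen_bonds(structure, crit)),
        "ionic": len(ionic_interactions(structure, crit)),
        "hydrophobic": len(hydrophobic_contacts(structure, crit)),
    }


def interaction_timeseries(
    traj: Trajectory, criteria: InteractionCriteria | None = None
):
    """Per-frame interaction counts by kind, as a pandas DataFrame."""
    import pandas as pd

    crit = criteria or InteractionCriteria()
    rows = []
    for f in range(traj.n_frames):
        counts = interaction_summary(traj.frame_structure(f), crit)
        counts["frame"] = f
        rows.append(counts)
    df = pd.DataFrame(rows, columns=["frame", "hbond", "ionic", "hydrophobic"])
    return df


def criteria_as_dict(criteria: InteractionCriteria) -> dict:
    """Criteria in serializable form, embedded in every report."""
    return asdict(criteria)
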