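"""Interface geometry between a peptide and adjacent filament protomers.

Implements the interface criteria used to describe the peptide-recombinase
complexes: polar (hydrogen-bond-like) contacts at donor-acceptor distance
< 4 Å with a 110-180 degree angle at the donor, hydrophobic contacts between
apolar carbons within 4.5 Å, and buried surface area (BSA) between two
structural units computed as ``SASA(A) + SASA(B) - SASA(A u B)`` with a
Shrake-Rupley solvent-accessible surface area at probe radius 1.4 Å.

The angle criterion is evaluated without hydrogens, as CryoEM models carry
none: the angle is measured at the donor heavy atom between its bonded
antecedent atom and the acceptor, an approximation of hydrogen-placement
tools.  The van der Waals radii are a fixed Bondi-style table pinned here so
SASA values are reproducible bit-for-bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

# pinned Bondi-style van der Waals radii (Angstrom)
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
DEFAULT_VDW_RADIUS = 1.70
PROBE_RADIUS = 1.40
SASA_POINTS = 960

# donor/acceptor templates for the 20 standard residues:
# atom -> (is_donor, is_acceptor, antecedent bonded heavy atom)
_BACKBONE = {
    "N": (True, False, "CA"),
    "O": (False, True, "C"),
    "OXT": (False, True, "C"),
}
_SIDECHAIN = {
    "SER": {"OG": (True, True, "CB")},
    "THR": {"OG1": (True, True, "CB")},
    "TYR": {"OH": (True, True, "CZ")},
    "CYS": {"SG": (True, True, "CB")},
    "LYS": {"NZ": (True, False, "CE")},
    "ARG": {
        "NE": (True, False, "CD"),
        "NH1": (True, False, "CZ"),
        "NH2": (True, False, "CZ"),
    },
    "HIS": {"ND1": (True, True, "CG"), "NE2": (True, True, "CD2")},
    "ASN": {"OD1": (False, True, "CG"), "ND2": (True, False, "CG")},
    "GLN": {"OE1": (False, True, "CD"), "NE2": (True, False, "CD")},
    "ASP": {"OD1": (False, True, "CG"), "OD2": (False, True, "CG")},
    "GLU": {"OE1": (False, True, "CD"), "OE2": (False, True, "CD")},
    "TRP": {"NE1": (True, False, "CE2")},
    "MET": {"SD": (False, True, "CG")},
}
_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# apolar carbons (not bonded to N/O) per residue, for hydrophobic contacts
_APOLAR_CARBONS = {
    "ALA": {"CB"},
    "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "MET": {"CB", "CG", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
    "PRO": {"CB", "CG"},
    "ARG": {"CB", "CG"},
    "LYS": {"CB", "CG", "CD"},
    "GLU": {"CB", "CG"},
    "GLN": {"CB", "CG"},
    "ASP": {"CB"},
    "ASN": {"CB"},
    "HIS": {"CB"},
    "THR": {"CG2"},
    "CYS": {"CB"},
}


@dataclass
class StructureUnit:
    """One structural unit: a set of atoms grouped by residue and chain."""

    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray  # (n, 3) Angstrom
    res_names: list[str]
    res_ids: list[int]
    chains: list[str]
    occupancies: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        n = len(self.coords)
        for attr in ("atom_names", "elements", "res_names", "res_ids", "chains"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"{attr} length mismatch")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        if self.occupancies is None:
            self.occupancies = np.ones(n)
        self.elements = [e.upper() for e in self.elements]

    def __len__(self) -> int:
        return len(self.coords)

    def __add__(self, other: "StructureUnit") -> "StructureUnit":
        return StructureUnit(
            atom_names=self.atom_names + other.atom_names,
            elements=self.elements + other.elements,
            coords=np.vstack([self.coords, other.coords]),
            res_names=self.res_names + other.res_names,
            res_ids=self.res_ids + other.res_ids,
            chains=self.chains + other.chains,
            occupancies=np.concatenate([self.occupancies, other.occupancies]),
            label=f"{self.label}+{other.label}",
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureUnit":
        """Rigid-body copy: ``x -> R x + t``."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        return replace(self, coords=self.coords @ rotation.T + translation)

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def radii(self) -> np.ndarray:
        return np.array([VDW_RADII.get(e, DEFAULT_VDW_RADIUS) for e in self.elements])

    def atom_label(self, i: int) -> str:
        return f"{self.chains[i]}/{self.res_names[i]}{self.res_ids[i]}/{self.atom_names[i]}"

    @classmethod
    def from_file(
        cls,
        path,
        chains: Sequence[str] | None = None,
        residue_range: tuple[int, int] | None = None,
        label: str = "",
        model: int = 0,
    ) -> "StructureUnit":
        """Read atoms from mmCIF or PDB, optionally selecting chains/residues."""
        import gemmi

        st = gemmi.read_structure(str(path))
        st.setup_entities()
        names, elements, coords, res_names, res_ids, chain_ids, occ = [], [], [], [], [], [], []
        for chain in st[model]:
            if chains is not None and chain.name not in chains:
                continue
            for residue in chain:
                if residue_range is not None and not (
                    residue_range[0] <= residue.seqid.num <= residue_range[1]
                ):
                    continue
                for atom in residue:
                    if atom.is_hydrogen():
                        continue
                    names.append(atom.name)
                    elements.append(atom.element.name.upper())
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    res_names.append(residue.name)
                    res_ids.append(residue.seqid.num)
                    chain_ids.append(chain.name)
                    occ.append(atom.occ)
        if not names:
            raise ValueError(f"no atoms selected from {path}")
        return cls(
            atom_names=names,
            elements=elements,
            coords=np.array(coords),
            res_names=res_names,
            res_ids=res_ids,
            chains=chain_ids,
            occupancies=np.array(occ),
            label=label or str(path),
        )


@dataclass(frozen=True)
class ContactRecord:
    """One interfacial atom-pair contact."""

    donor: str
    acceptor: str
    distance: float
    angle: float | None
    klass: str  # "polar" or "hydrophobic"
    donor_residue: tuple[str, str, int]
    acceptor_residue: tuple[str, str, int]
    protomer: str | None = None


def _residue_atom_index(unit: StructureUnit) -> dict[tuple[str, int], dict[str, int]]:
    out: dict[tuple[str, int], dict[str, int]] = {}
    for i in range(len(unit)):
        out.setdefault((unit.chains[i], unit.res_ids[i]), {})[unit.atom_names[i]] = i
    return out


def _nearest_in_residue(unit: StructureUnit, i: int, atom_map: dict[str, int]) -> int | None:
    """Nearest bonded-distance heavy atom within the same residue."""
    best, best_d = None, 2.0
    for j in atom_map.values():
        if j == i:
            continue
        d = float(np.linalg.norm(unit.coords[i] - unit.coords[j]))
        if d < best_d:
            best, best_d = j, d
    return best


def _polar_atoms(unit: StructureUnit) -> tuple[list[tuple[int, int]], list[int]]:
    """(donor atom idx, antecedent idx) pairs and acceptor atom indices."""
    res_atoms = _residue_atom_index(unit)
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    warned: set[str] = set()
    for i in range(len(unit)):
        res_name = unit.res_names[i]
        atom = unit.atom_names[i]
        atom_map = res_atoms[(unit.chains[i], unit.res_ids[i])]
        if res_name in _STANDARD_RESIDUES:
            template = dict(_BACKBONE)
            if res_name == "PRO":
                del template["N"]  # proline backbone N has no H to donate
            template.update(_SIDECHAIN.get(res_name, {}))
            if atom not in template:
                continue
            is_donor, is_acceptor, antecedent = template[atom]
            if is_acceptor:
                acceptors.append(i)
            if is_donor:
                j = atom_map.get(antecedent)
                if j is None:
                    j = _nearest_in_residue(unit, i, atom_map)
                if j is not None:
                    donors.append((i, j))
        else:
            if res_name not in warned:
                warned.add(res_name)
                warnings.warn(
                    f"residue {res_name!r} has no donor/acceptor template; "
                    "typing its N/O/S atoms by element"
                )
            if unit.elements[i] in ("N", "O", "S"):
                acceptors.append(i)
                j = _nearest_in_residue(unit, i, atom_map)
                if j is not None:
                    donors.append((i, j))
    return donors, acceptors


def donor_angle(donor: np.ndarray, antecedent: np.ndarray, acceptor: np.ndarray) -> float:
    """Angle (degrees) at the donor between its antecedent and the acceptor."""
    v1 = antecedent - donor
    v2 = acceptor - donor
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def find_polar_contacts(
    unit_a: StructureUnit,
    unit_b: StructureUnit,
    dmax: float = 4.0,
    angle_range: tuple[float, float] = (110.0, 180.0),
) -> list[ContactRecord]:
    """All inter-unit donor-acceptor pairs with distance < dmax and an
    antecedent-donor-acceptor angle inside ``angle_range``."""
    records: list[ContactRecord] = []
    for dunit, aunit in ((unit_a, unit_b), (unit_b, unit_a)):
        donors, _ = _polar_atoms(dunit)
        _, acceptors = _polar_atoms(aunit)
        if not donors or not acceptors:
            continue
        acc_coords = aunit.coords[acceptors]
        tree = cKDTree(acc_coords)
        for di, anti in donors:
            for k in tree.query_ball_point(dunit.coords[di], dmax):
                ai = acceptors[k]
                dist = float(np.linalg.norm(dunit.coords[di] - aunit.coords[ai]))
                if dist >= dmax:
                    continue
                ang = donor_angle(dunit.coords[di], dunit.coords[anti], aunit.coords[ai])
                if angle_range[0] <= ang <= angle_range[1]:
                    records.append(
                        ContactRecord(
                            donor=dunit.atom_label(di),
                            acceptor=aunit.atom_label(ai),
                            distance=dist,
                            angle=ang,
                            klass="polar",
                            donor_residue=(dunit.chains[di], dunit.res_names[di], dunit.res_ids[di]),
                            acceptor_residue=(aunit.chains[ai], aunit.res_names[ai], aunit.res_ids[ai]),
                        )
                    )
    records.sort(key=lambda r: (r.donor, r.acceptor))
    return records


def _apolar_carbons(unit: StructureUnit) -> list[int]:
    res_atoms = _residue_atom_index(unit)
    out = []
    for i in range(len(unit)):
        if unit.elements[i] != "C":
            continue
        res_name = unit.res_names[i]
        if res_name in _STANDARD_RESIDUES:
            if unit.atom_names[i] in _APOLAR_CARBONS.get(res_name, set()):
                out.append(i)
        else:
            # unknown residue: carbon is apolar if no N/O within bonding distance
            atom_map = res_atoms[(unit.chains[i], unit.res_ids[i])]
            polar_neighbor = False
            for j in atom_map.values():
                if unit.elements[j] in ("N", "O") and np.linalg.norm(
                    unit.coords[i] - unit.coords[j]
                ) < 1.8:
                    polar_neighbor = True
                    break
            if not polar_neighbor:
                out.append(i)
    return out


def find_hydrophobic_contacts(
    unit_a: StructureUnit, unit_b: StructureUnit, dmax: float = 4.5
) -> list[ContactRecord]:
    """Apolar carbon-carbon pairs across the interface within ``dmax``."""
    ca = _apolar_carbons(unit_a)
    cb = _apolar_carbons(unit_b)
    records: list[ContactRecord] = []
    if not ca or not cb:
        return records
    tree = cKDTree(unit_b.coords[cb])
    for i in ca:
        for k in tree.query_ball_point(unit_a.coords[i], dmax):
            j = cb[k]
            dist = float(np.linalg.norm(unit_a.coords[i] - unit_b.coords[j]))
            if dist > dmax:
                continue
            records.append(
                ContactRecord(
                    donor=unit_a.atom_label(i),
                    acceptor=unit_b.atom_label(j),
                    distance=dist,
                    angle=None,
                    klass="hydrophobic",
                    donor_residue=(unit_a.chains[i], unit_a.res_names[i], unit_a.res_ids[i]),
                    acceptor_residue=(unit_b.chains[j], unit_b.res_names[j], unit_b.res_ids[j]),
                )
            )
    records.sort(key=lambda r: (r.donor, r.acceptor))
    return records


def residue_contact_table(records: Iterable[ContactRecord]):
    """Deduplicate atom-level contacts to one row per residue pair."""
    import pandas as pd

    grouped: dict[tuple, dict] = {}
    for r in records:
        key = (r.donor_residue, r.acceptor_residue, r.klass)
        g = grouped.setdefault(key, {"n_atom_pairs": 0, "min_distance": float("inf")})
        g["n_atom_pairs"] += 1
        g["min_distance"] = min(g["min_distance"], r.distance)
    rows = [
        {
            "residue_a": f"{k[0][0]}/{k[0][1]}{k[0][2]}",
            "residue_b": f"{k[1][0]}/{k[1][1]}{k[1][2]}",
            "class": k[2],
            "n_atom_pairs": v["n_atom_pairs"],
            "min_distance": v["min_distance"],
        }
        for k, v in sorted(grouped.items())
    ]
    return pd.DataFrame(rows, columns=["residue_a", "residue_b", "class", "n_atom_pairs", "min_distance"])


def sphere_points(n: int = SASA_POINTS) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    unit: StructureUnit, probe: float = PROBE_RADIUS, n_points: int = SASA_POINTS
) -> float:
    """Solvent-accessible surface area (Angstrom^2), Shrake-Rupley sampling.

    Each atom's expanded sphere (vdW radius + probe) is sampled with a fixed
    deterministic point set; a point is accessible when it lies outside every
    other atom's expanded sphere.  Deterministic for a fixed point count.
    """
    if len(unit) == 0:
        raise ValueError("empty structural unit")
    if n_points < SASA_POINTS:
        raise ValueError(f"n_points must be >= {SASA_POINTS}")
    radii = unit.radii() + probe
    coords = unit.coords
    pts = sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    total = 0.0
    for i in range(len(unit)):
        shell = coords[i] + radii[i] * pts
        accessible = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], radii[i] + max_r):
            if j == i:
                continue
            d2 = np.sum((shell - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
            if not accessible.any():
                break
        total += 4.0 * math.pi * radii[i] ** 2 * accessible.sum() / n_points
    return total


def buried_surface_area(
    unit_a: StructureUnit,
    unit_b: StructureUnit,
    probe: float = PROBE_RADIUS,
    n_points: int = SASA_POINTS,
) -> float:
    """Interface size: ``SASA(A) + SASA(B) - SASA(A u B)`` in Angstrom^2.

    Symmetric in its arguments and invariant under rigid-body motion of the
    whole complex; zero for units too far apart to occlude each other.
    """
    if len(unit_a) == 0 or len(unit_b) == 0:
        raise ValueError("both structural units must contain atoms")
    return (
        shrake_rupley_sasa(unit_a, probe, n_points)
        + shrake_rupley_sasa(unit_b, probe, n_points)
        - shrake_rupley_sasa(unit_a + unit_b, probe, n_points)
    )


def assign_protomer_roles(
    protomers: Sequence[StructureUnit],
    dna: StructureUnit | None,
    dna_runs_5_to_3: bool = True,
) -> list[dict[str, str]]:
    """Label adjacent protomer pairs by which ssDNA end they face.

    The filament axis is taken from the bound DNA: the vector from the
    centroid of its first residue to its last (residue order along the strand;
    ``dna_runs_5_to_3=False`` if the ordering runs 3'->5').  Protomers are
    sorted by their centroid projection on that axis and each adjacent pair is
    labelled with the protomer nearer the 5' end as ``5prime_facing`` and the
    one nearer the 3' end as ``3prime_facing``.  Projections are relative, so
    labels are invariant under rigid-body motion of the whole complex.
    """
    if dna is None or len(set(zip(dna.chains, dna.res_ids))) < 2:
        warnings.warn("ssDNA polarity undeterminable; protomer roles left unlabeled")
        return [
            {"5prime_facing": None, "3prime_facing": None}
            for _ in range(max(len(protomers) - 1, 0))
        ]
    order = sorted(set(zip(dna.chains, dna.res_ids)), key=lambda cr: cr[1])
    first = np.mean(
        [dna.coords[i] for i in range(len(dna)) if (dna.chains[i], dna.res_ids[i]) == order[0]],
        axis=0,
    )
    last = np.mean(
        [dna.coords[i] for i in range(len(dna)) if (dna.chains[i], dna.res_ids[i]) == order[-1]],
        axis=0,
    )
    axis = last - first
    if not dna_runs_5_to_3:
        axis = -axis
    norm = np.linalg.norm(axis)
    if norm == 0:
        warnings.warn("degenerate DNA axis; protomer roles left unlabeled")
        return [
            {"5prime_facing": None, "3prime_facing": None}
            for _ in range(max(len(protomers) - 1, 0))
        ]
    axis = axis / norm
    names = [p.label or p.chains[0] for p in protomers]
    proj = [float(np.dot(p.centroid() - first, axis)) for p in protomers]
    ranked = sorted(zip(proj, names))
    return [
        {"5prime_facing": ranked[k][1], "3prime_facing": ranked[k + 1][1]}
        for k in range(len(ranked) - 1)
    ]
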