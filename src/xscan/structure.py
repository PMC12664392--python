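"""Structural footprint analysis of binder / HLA-peptide complexes.

Given a two-group partition of a complex (group A: the binder; group B: the
MHC heavy chain, β2-microglobulin and peptide), this module computes

* solvent-accessible surface area (SASA) by Shrake–Rupley quadrature,
* the buried interface area, ``½ (SASA_A + SASA_B − SASA_AB)`` —
  the convention PISA reports,
* per-residue and per-atom buried areas (the footprint),
* typed contacts across the interface (distance-based hydrogen bonds
  between donor/acceptor N/O heavy atoms, and apolar carbon–carbon
  hydrophobic contacts),
* the backbone share of each side's buried area,
* optimal least-squares superposition (Kabsch) and RMSD.

Coordinates are in Å, areas in Å².  The radius table follows the
NACCESS-like convention (C 1.70, N 1.55, O 1.52, S 1.80 Å) with a 1.4 Å
water probe.
"""

from __future__ import annotations

import math
import re
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

DEFAULT_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
    "SE": 1.90,
}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

# Heavy-atom hydrogen-bond chemistry per residue: which N/O atoms can donate
# and/or accept.  Backbone N donates, backbone O (and OXT) accepts, for every
# residue; the table below adds the side-chain atoms.
_SIDECHAIN_DONORS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "ASN": frozenset({"ND2"}),
    "GLN": frozenset({"NE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "LYS": frozenset({"NZ"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TRP": frozenset({"NE1"}),
    "TYR": frozenset({"OH"}),
}
_SIDECHAIN_ACCEPTORS: dict[str, frozenset[str]] = {
    "ASN": frozenset({"OD1"}),
    "ASP": frozenset({"OD1", "OD2"}),
    "GLN": frozenset({"OE1"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "MET": frozenset(),
}

# Carbon atoms regarded as polar (carbonyl / carboxylate / guanidinium /
# amide carbons and the TYR ring carbon bearing the hydroxyl); all other
# carbons count as apolar for hydrophobic-contact detection.
_POLAR_CARBONS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"CG"}),
    "GLU": frozenset({"CD"}),
    "ASN": frozenset({"CG"}),
    "GLN": frozenset({"CD"}),
    "ARG": frozenset({"CZ"}),
    "TYR": frozenset({"CZ"}),
}

_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name}: coordinates must be finite 3-vectors")
        self.element = self.element.upper()


@dataclass
class Residue:
    name: str
    seq_id: int
    atoms: list[Atom] = field(default_factory=list)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Structure:
    """Chains → residues (author numbering) → atoms."""

    chains: list[Chain] = field(default_factory=list)
    id: str = ""

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for chain in self.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    yield chain, res, atom

    def chain(self, chain_id: str) -> Chain:
        for chain in self.chains:
            if chain.id == chain_id:
                return chain
        raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")

    def atom_table(self) -> pd.DataFrame:
        rows = [
            {
                "chain": c.id,
                "seq_id": r.seq_id,
                "res_name": r.name,
                "atom": a.name,
                "element": a.element,
                "x": a.pos[0],
                "y": a.pos[1],
                "z": a.pos[2],
            }
            for c, r, a in self.iter_atoms()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SasaConfig:
    """Shrake–Rupley parameters: water probe, quadrature density, radii."""

    probe_radius: float = 1.4
    n_points: int = 960
    radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    fallback_radius: float | None = None

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")
        if self.n_points < 92:
            raise ValueError("at least 92 quadrature points are required")

    def radius_of(self, element: str) -> float:
        r = self.radii.get(element.upper(), self.fallback_radius)
        if r is None:
            raise ValueError(f"no radius for element {element!r} and no fallback set")
        return r


def read_structure(path, fmt: str | None = None, keep_hetero: bool = False) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    The first model is used; waters and (by default) other hetero residues
    are excluded; for alternate locations the highest-occupancy atom is
    retained.  ``fmt`` is inferred from the file extension when omitted.
    """
    import gemmi

    path = Path(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if not len(st):
        raise ValueError(f"{path}: no models found")
    model = st[0]
    out = Structure(id=st.name or path.stem)
    for ch in model:
        chain = Chain(id=ch.name)
        for res in ch:
            if res.is_water():
                continue
            if not keep_hetero and res.name not in _AA3:
                continue
            residue = Residue(name=res.name, seq_id=res.seqid.num)
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                if atom.element.name.upper() == "H":
                    continue
                residue.atoms.append(
                    Atom(
                        name=atom.name,
                        element=atom.element.name,
                        pos=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=atom.occ,
                        altloc=atom.altloc or "",
                    )
                )
            if residue.atoms:
                chain.residues.append(residue)
        if chain.residues:
            out.chains.append(chain)
    if not out.chains:
        raise ValueError(f"{path}: no polymer atoms read")
    return out


def fetch_structure(pdb_id: str, cache_dir, fmt: str = "mmcif") -> Path:
    """Download a PDB entry from RCSB into ``cache_dir`` (network required)."""
    pdb_id = pdb_id.lower()
    suffix = ".cif" if fmt == "mmcif" else ".pdb"
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    dest = cache_dir / f"{pdb_id}{suffix}"
    if not dest.exists():
        url = f"https://files.rcsb.org/download/{pdb_id.upper()}{suffix}"
        with urllib.request.urlopen(url, timeout=60) as resp:
            dest.write_bytes(resp.read())
    return dest


_SEL_RE = re.compile(r"^(?P<chain>[^:]+)(?::(?P<start>-?\d+)-(?P<end>-?\d+))?$")


def parse_selection(spec: str) -> list[tuple[str, int | None, int | None]]:
    """Parse ``chain[:resStart-resEnd]`` selections, comma-separated."""
    out = []
    for part in spec.split(","):
        m = _SEL_RE.match(part.strip())
        if m is None:
            raise ValueError(f"malformed selection {part!r}")
        start = int(m["start"]) if m["start"] is not None else None
        end = int(m["end"]) if m["end"] is not None else None
        out.append((m["chain"], start, end))
    return out


@dataclass(frozen=True)
class GroupPartition:
    """Two disjoint named selections, e.g. binder vs HLA+β2m+peptide."""

    group_a: str
    group_b: str
    name_a: str = "A"
    name_b: str = "B"

    def __post_init__(self) -> None:
        sel_a = {c for c, _, _ in parse_selection(self.group_a)}
        sel_b = {c for c, _, _ in parse_selection(self.group_b)}
        if sel_a & sel_b:
            raise ValueError(f"partition groups overlap on chains {sorted(sel_a & sel_b)}")


def _select(structure: Structure, spec: str) -> Structure:
    wanted = parse_selection(spec)
    out = Structure(id=structure.id)
    for chain_id, start, end in wanted:
        chain = structure.chain(chain_id)
        residues = [
            r
            for r in chain.residues
            if (start is None or start <= r.seq_id) and (end is None or r.seq_id <= end)
        ]
        if not residues:
            raise ValueError(f"selection {spec!r}: no residues in chain {chain_id}")
        out.chains.append(Chain(id=chain.id, residues=residues))
    return out


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere quadrature (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_arrays(structure: Structure, config: SasaConfig):
    coords, radii, meta = [], [], []
    for c, r, a in structure.iter_atoms():
        coords.append(a.pos)
        radii.append(config.radius_of(a.element))
        meta.append((c.id, r.seq_id, r.name, a.name, a.element))
    if not coords:
        raise ValueError("structure contains no atoms")
    meta_df = pd.DataFrame(
        meta, columns=["chain", "seq_id", "res_name", "atom", "element"]
    )
    return np.asarray(coords), np.asarray(radii), meta_df


def sasa(structure: Structure, config: SasaConfig | None = None) -> pd.DataFrame:
    """Per-atom solvent-accessible surface area (Shrake–Rupley).

    For every atom, quadrature points are placed on its probe-inflated
    sphere; the accessible fraction is the share of points lying outside all
    other inflated spheres, times the sphere area.  Returns the atom table
    with an ``area`` column (Å²).
    """
    config = config or SasaConfig()
    coords, radii, meta = _atom_arrays(structure, config)
    areas = _sasa_arrays(coords, radii + config.probe_radius, config.n_points)
    meta["area"] = areas
    return meta


def _sasa_arrays(coords: np.ndarray, inflated: np.ndarray, n_points: int) -> np.ndarray:
    unit = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    r_max = inflated.max()
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        r_i = inflated[i]
        neighbors = tree.query_ball_point(coords[i], r_i + r_max)
        neighbors = [j for j in neighbors if j != i]
        pts = coords[i] + r_i * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > inflated[j] ** 2
        areas[i] = 4.0 * math.pi * r_i**2 * accessible.mean()
    return areas


@dataclass
class Contact:
    """One interface contact between an atom of side A and an atom of side B."""

    kind: str  # "hydrogen_bond" | "hydrophobic"
    chain_a: str
    res_a: str
    seq_a: int
    atom_a: str
    chain_b: str
    res_b: str
    seq_b: int
    atom_b: str
    distance: float


@dataclass
class InterfaceReport:
    """Buried-area totals, per-residue/per-atom footprints, typed contacts."""

    interface_area: float
    per_atom: pd.DataFrame  # side, chain, seq_id, res_name, atom, buried (Å²)
    contacts: list[Contact] = field(default_factory=list)

    @property
    def per_residue(self) -> pd.DataFrame:
        """Buried area per residue, both sides (Å²)."""
        return (
            self.per_atom.groupby(["side", "chain", "seq_id", "res_name"], as_index=False)[
                "buried"
            ]
            .sum()
            .sort_values(["side", "chain", "seq_id"])
            .reset_index(drop=True)
        )

    def backbone_fraction(self) -> dict[str, float]:
        """Share of each side's buried area on backbone atoms (N, CA, C, O)."""
        out = {}
        for side, grp in self.per_atom.groupby("side"):
            total = grp["buried"].sum()
            bb = grp.loc[grp["atom"].isin(BACKBONE_ATOMS), "buried"].sum()
            out[side] = float(bb / total) if total > 0 else 0.0
        return out

    def contact_residues(self, side: str = "A") -> set[str]:
        """Residue labels (one-letter + author number, e.g. ``K89``) on a side."""
        labels = set()
        for c in self.contacts:
            if side == "A":
                labels.add(_residue_label(c.res_a, c.seq_a))
            else:
                labels.add(_residue_label(c.res_b, c.seq_b))
        return labels


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M", "SEC": "U",
}


def _residue_label(res_name: str, seq_id: int) -> str:
    return f"{_THREE_TO_ONE.get(res_name, 'X')}{seq_id}"


def interface_area(
    structure: Structure,
    partition: GroupPartition,
    config: SasaConfig | None = None,
    with_contacts: bool = True,
) -> InterfaceReport:
    """Buried interface area and per-atom footprint for a two-group split.

    ``interface area = ½ (SASA(A alone) + SASA(B alone) − SASA(A∪B))``.
    Per-atom buried area is the atom's SASA in isolation of its own group
    minus its SASA in the complex, clipped at 0 (quadrature noise can
    produce tiny negative differences).
    """
    config = config or SasaConfig()
    part_a = _select(structure, partition.group_a)
    part_b = _select(structure, partition.group_b)
    sasa_a = sasa(part_a, config)
    sasa_b = sasa(part_b, config)

    combined = Structure(id=structure.id, chains=part_a.chains + part_b.chains)
    sasa_ab = sasa(combined, config)

    total_a, total_b = sasa_a["area"].sum(), sasa_b["area"].sum()
    total_ab = sasa_ab["area"].sum()
    area = 0.5 * (total_a + total_b - total_ab)

    n_a = len(sasa_a)
    alone = pd.concat([sasa_a, sasa_b], ignore_index=True)
    buried = np.clip(alone["area"].to_numpy() - sasa_ab["area"].to_numpy(), 0.0, None)
    per_atom = alone.drop(columns="area").copy()
    per_atom["side"] = ["A"] * n_a + ["B"] * len(sasa_b)
    per_atom["buried"] = buried

    contacts = (
        detect_contacts(part_a, part_b) if with_contacts else []
    )
    return InterfaceReport(interface_area=float(area), per_atom=per_atom, contacts=contacts)


def _hbond_roles(res_name: str, atom_name: str) -> tuple[bool, bool]:
    """(is_donor, is_acceptor) for a heavy atom, distance-only chemistry."""
    donor = acceptor = False
    if atom_name == "N" and res_name != "PRO":
        donor = True
    if atom_name in ("O", "OXT"):
        acceptor = True
    donor = donor or atom_name in _SIDECHAIN_DONORS.get(res_name, frozenset())
    acceptor = acceptor or atom_name in _SIDECHAIN_ACCEPTORS.get(res_name, frozenset())
    return donor, acceptor


def _is_apolar_carbon(res_name: str, atom_name: str, element: str) -> bool:
    if element != "C":
        return False
    if atom_name == "C":  # backbone carbonyl
        return False
    return atom_name not in _POLAR_CARBONS.get(res_name, frozenset())


def detect_contacts(
    side_a: Structure,
    side_b: Structure,
    hbond_cutoff: float = 3.5,
    hydrophobic_cutoff: float = 4.5,
) -> list[Contact]:
    """Distance-typed contacts across a two-group partition.

    Hydrogen bonds: donor/acceptor-typed N or O heavy-atom pairs (one atom
    per side, complementary roles) within ``hbond_cutoff`` Å.  Hydrophobic
    contacts: apolar carbon pairs within ``hydrophobic_cutoff`` Å.  Each
    qualifying atom pair is reported once, with its distance; a pair that
    qualifies as a hydrogen bond is not additionally counted as hydrophobic.
    """
    atoms_a = [(c, r, a) for c, r, a in side_a.iter_atoms()]
    atoms_b = [(c, r, a) for c, r, a in side_b.iter_atoms()]
    if not atoms_a or not atoms_b:
        return []
    coords_a = np.array([a.pos for _, _, a in atoms_a])
    coords_b = np.array([a.pos for _, _, a in atoms_b])
    tree_b = cKDTree(coords_b)
    cutoff = max(hbond_cutoff, hydrophobic_cutoff)
    contacts: list[Contact] = []
    for i, (ca, ra, aa) in enumerate(atoms_a):
        for j in tree_b.query_ball_point(coords_a[i], cutoff):
            cb, rb, ab = atoms_b[j]
            d = float(np.linalg.norm(coords_a[i] - coords_b[j]))
            kind = None
            if d <= hbond_cutoff and aa.element in ("N", "O") and ab.element in ("N", "O"):
                don_a, acc_a = _hbond_roles(ra.name, aa.name)
                don_b, acc_b = _hbond_roles(rb.name, ab.name)
                if (don_a and acc_b) or (don_b and acc_a):
                    kind = "hydrogen_bond"
            if (
                kind is None
                and d <= hydrophobic_cutoff
                and _is_apolar_carbon(ra.name, aa.name, aa.element)
                and _is_apolar_carbon(rb.name, ab.name, ab.element)
            ):
                kind = "hydrophobic"
            if kind is not None:
                contacts.append(
                    Contact(
                        kind=kind,
                        chain_a=ca.id, res_a=ra.name, seq_a=ra.seq_id, atom_a=aa.name,
                        chain_b=cb.id, res_b=rb.name, seq_b=rb.seq_id, atom_b=ab.name,
                        distance=d,
                    )
                )
    return contacts


def contacts_table(contacts: Sequence[Contact]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in contacts])


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rotation/translation superposing P onto Q; returns (R, t, rmsd).

    Proper rotation is enforced: when the best orthogonal transform is a
    reflection, the smallest singular direction is flipped.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate arrays required")
    if len(P) < 3:
        raise ValueError("at least 3 paired atoms are required")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P0 @ R.T) - Q0
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return R, t, rmsd


def paired_coordinates(
    a: Structure,
    b: Structure,
    chain_map: dict[str, str] | None = None,
    atoms: str = "CA",
) -> tuple[np.ndarray, np.ndarray]:
    """Pair atoms of two structures by chain and author residue number.

    ``atoms="CA"`` pairs Cα atoms only (the default); ``atoms="all"`` pairs
    every atom name shared by corresponding residues.  Residues missing from
    either side (unmodeled) are dropped.
    """
    if chain_map is None:
        if len(a.chains) == 1 and len(b.chains) == 1:
            chain_map = {a.chains[0].id: b.chains[0].id}
        else:
            chain_map = {c.id: c.id for c in a.chains}
    pa, pb = [], []
    for ca_id, cb_id in chain_map.items():
        chain_a = a.chain(ca_id)
        chain_b = b.chain(cb_id)
        res_b = {r.seq_id: r for r in chain_b.residues}
        for ra in chain_a.residues:
            rb = res_b.get(ra.seq_id)
            if rb is None:
                continue
            atoms_b = {at.name: at for at in rb.atoms}
            for at in ra.atoms:
                if atoms != "all" and at.name != atoms:
                    continue
                other = atoms_b.get(at.name)
                if other is not None:
                    pa.append(at.pos)
                    pb.append(other.pos)
    if len(pa) < 3:
        raise ValueError("fewer than 3 paired atoms; check chain map and numbering")
    return np.asarray(pa), np.asarray(pb)


def superpose_rmsd(
    a: Structure,
    b: Structure,
    chain_map: dict[str, str] | None = None,
    atoms: str = "CA",
) -> float:
    """Kabsch-superposed RMSD (Å) over paired atoms of two structures."""
    P, Q = paired_coordinates(a, b, chain_map=chain_map, atoms=atoms)
    _, _, rmsd = kabsch(P, Q)
    return rmsd
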