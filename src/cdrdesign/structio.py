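"""Structure parsing, atom typing, solvent accessibility and interface classes.

Coordinates come in as PDB text (parsed with gemmi) and are held in a plain
:class:`Structure` of typed heavy atoms.  On top of that this module provides

* a residue/atom-name -> physicochemical atom-type scheme (amide vs aromatic
  nitrogen, carbonyl vs hydroxyl vs carboxylate oxygen, aliphatic vs aromatic
  carbon, sulfur, water oxygen),
* Shrake-Rupley solvent-accessible surface areas on a deterministic
  golden-spiral quadrature,
* core / rim / non-interface classification of a two-sided complex from the
  change in relative SASA on complexation (Levy-style thresholds), and
* boolean van-der-Waals occupancy masks on regular grids.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .grids import GridSpec

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Structure",
    "InterfaceClassification",
    "read_structure",
    "default_typing_scheme",
    "assign_atom_types",
    "compute_sasa",
    "residue_sasa",
    "classify_interface",
    "volume_mask",
    "BONDI_RADII",
    "MAX_SASA",
    "WATER_O",
    "OTHER_TYPE",
]

# Bondi (1964) van der Waals radii, Å.
BONDI_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}
DEFAULT_RADIUS = 1.70

# Theoretical maximum residue SASA (Tien et al. 2013), Å²; used for
# relative-accessibility normalisation.
MAX_SASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}
WATER_O = "O_WATER"
OTHER_TYPE = "OTHER"


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str = ""
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    vdw_radius: float = DEFAULT_RADIUS
    atom_type: str | None = None

    @property
    def residue_label(self) -> str:
        """Author residue number with insertion-code suffix, e.g. '100A'."""
        return f"{self.residue_number}{self.insertion_code}"

    @property
    def residue_key(self) -> tuple[str, str]:
        return (self.chain_id, self.residue_label)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial} {self.name}: non-finite position")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial} {self.name}: vdw radius must be > 0")


class Structure:
    """An ordered collection of heavy atoms from one model."""

    def __init__(self, atoms: list[AtomRecord], source: str = ""):
        if not atoms:
            raise ValueError("a Structure needs at least one atom")
        self.atoms = list(atoms)
        self.source = source

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def select(self, pred) -> "Structure":
        sel = [a for a in self.atoms if pred(a)]
        if not sel:
            raise ValueError("selection is empty")
        return Structure(sel, source=self.source)

    def chains(self, chain_ids) -> "Structure":
        wanted = set(chain_ids)
        return self.select(lambda a: a.chain_id in wanted)

    def without_waters(self) -> "Structure":
        return self.select(lambda a: a.residue_name not in WATER_RESNAMES)

    def residues(self):
        """Iterate (chain_id, residue_label, residue_name, [AtomRecord]) in
        file order."""
        order: list[tuple[str, str]] = []
        groups: dict[tuple[str, str], list[AtomRecord]] = {}
        for a in self.atoms:
            key = a.residue_key
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(a)
        for key in order:
            atoms = groups[key]
            yield key[0], key[1], atoms[0].residue_name, atoms

    def residue(self, chain_id: str, residue_label: str) -> list[AtomRecord]:
        res = [a for a in self.atoms if a.residue_key == (chain_id, str(residue_label))]
        if not res:
            raise KeyError(f"residue {residue_label} in chain {chain_id} not found")
        return res

    def copy(self) -> "Structure":
        return Structure([replace(a, position=a.position.copy()) for a in self.atoms],
                         source=self.source)


def _vdw(element: str, radii: dict[str, float]) -> float:
    return radii.get(element.upper(), DEFAULT_RADIUS)


def read_structure(
    pdb_text: str,
    model_index: int = 0,
    keep_waters: bool = False,
    radii: dict[str, float] | None = None,
    source: str = "",
) -> Structure:
    """Parse PDB text into a :class:`Structure` of heavy atoms.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties keep the first).  Hydrogens and deuteriums are dropped; waters are
    kept only under ``keep_waters``.
    """
    radii = radii or BONDI_RADII
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"PDB parse error: {exc}") from exc
    if len(st) == 0:
        raise ValueError("PDB text contains no model")
    if not 0 <= model_index < len(st):
        raise IndexError(f"model_index {model_index} out of range (0..{len(st) - 1})")
    model = st[model_index]

    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            if res.name in WATER_RESNAMES and not keep_waters:
                continue
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                el = at.element.name.upper()
                if el in ("H", "D"):
                    continue
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            seqid = res.seqid
            for at in best.values():
                atoms.append(
                    AtomRecord(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name,
                        residue_name=res.name,
                        chain_id=chain.name,
                        residue_number=seqid.num,
                        insertion_code=(seqid.icode or "").strip(),
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        vdw_radius=_vdw(at.element.name, radii),
                    )
                )
    if not atoms:
        raise ValueError("no heavy atoms in the selected model")
    return Structure(atoms, source=source or st.name)


def write_pdb(s: Structure) -> str:
    """Minimal PDB text (ATOM records) for a Structure."""
    lines = []
    for i, a in enumerate(s.atoms, start=1):
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {i:5d} {name:<4s} {a.residue_name:>3s} {a.chain_id[:1]}"
            f"{a.residue_number:4d}{(a.insertion_code or ' ')[:1]}   "
            f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {a.element.upper():>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# atom typing
# ---------------------------------------------------------------------------

_BACKBONE_TYPES = {"N": "N_AMIDE", "CA": "C_ALIPHATIC", "C": "C_CARBONYL",
                   "O": "O_CARBONYL", "OXT": "O_CARBOXYL"}

_SIDECHAIN_TYPES: dict[str, dict[str, str]] = {
    "ALA": {"CB": "C_ALIPHATIC"},
    "ARG": {"CB": "C_ALIPHATIC", "CG": "C_ALIPHATIC", "CD": "C_ALIPHATIC",
            "NE": "N_POSITIVE", "CZ": "C_CARBONYL", "NH1": "N_POSITIVE",
            "NH2": "N_POSITIVE"},
    "ASN": {"CB": "C_ALIPHATIC", "CG": "C_CARBONYL", "OD1": "O_CARBONYL",
            "ND2": "N_AMIDE"},
    "ASP": {"CB": "C_ALIPHATIC", "CG": "C_CARBONYL", "OD1": "O_CARBOXYL",
            "OD2": "O_CARBOXYL"},
    "CYS": {"CB": "C_ALIPHATIC", "SG": "S_SULFUR"},
    "GLN": {"CB": "C_ALIPHATIC", "CG": "C_ALIPHATIC", "CD": "C_CARBONYL",
            "OE1": "O_CARBONYL", "NE2": "N_AMIDE"},
    "GLU": {"CB": "C_ALIPHATIC", "CG": "C_ALIPHATIC", "CD": "C_CARBONYL",
            "OE1": "O_CARBOXYL", "OE2": "O_CARBOXYL"},
    "GLY": {},
    "HIS": {"CB": "C_ALIPHATIC", "CG": "C_AROMATIC", "ND1": "N_AROMATIC",
            "CD2": "C_AROMATIC", "CE1": "C_AROMATIC", "NE2": "N_AROMATIC"},
    "ILE": {"CB": "C_ALIPHATIC", "CG1": "C_ALIPHATIC", "CG2": "C_ALIPHATIC",
            "CD1": "C_ALIPHATIC"},
    "LEU": {"CB": "C_ALIPHATIC", "CG": "C_ALIPHATIC", "CD1": "C_ALIPHATIC",
            "CD2": "C_ALIPHATIC"},
    "LYS": {"CB": "C_ALIPHATIC", "CG": "C_ALIPHATIC", "CD": "C_ALIPHATIC",
            "CE": "C_ALIPHATIC", "NZ": "N_POSITIVE"},
    "MET": {"CB": "C_ALIPHATIC", "CG": "C_ALIPHATIC", "SD": "S_SULFUR",
            "CE": "C_ALIPHATIC"},
    "PHE": {"CB": "C_ALIPHATIC", "CG": "C_AROMATIC", "CD1": "C_AROMATIC",
            "CD2": "C_AROMATIC", "CE1": "C_AROMATIC", "CE2": "C_AROMATIC",
            "CZ": "C_AROMATIC"},
    "PRO": {"CB": "C_ALIPHATIC", "CG": "C_ALIPHATIC", "CD": "C_ALIPHATIC"},
    "SER": {"CB": "C_ALIPHATIC", "OG": "O_HYDROXYL"},
    "THR": {"CB": "C_ALIPHATIC", "OG1": "O_HYDROXYL", "CG2": "C_ALIPHATIC"},
    "TRP": {"CB": "C_ALIPHATIC", "CG": "C_AROMATIC", "CD1": "C_AROMATIC",
            "CD2": "C_AROMATIC", "NE1": "N_AROMATIC", "CE2": "C_AROMATIC",
            "CE3": "C_AROMATIC", "CZ2": "C_AROMATIC", "CZ3": "C_AROMATIC",
            "CH2": "C_AROMATIC"},
    "TYR": {"CB": "C_ALIPHATIC", "CG": "C_AROMATIC", "CD1": "C_AROMATIC",
            "CD2": "C_AROMATIC", "CE1": "C_AROMATIC", "CE2": "C_AROMATIC",
            "CZ": "C_AROMATIC", "OH": "O_HYDROXYL"},
    "VAL": {"CB": "C_ALIPHATIC", "CG1": "C_ALIPHATIC", "CG2": "C_ALIPHATIC"},
}

#: All atom-type codes used by the default scheme, in a fixed order.
ATOM_TYPES = ["C_ALIPHATIC", "C_AROMATIC", "C_CARBONYL", "N_AMIDE",
              "N_AROMATIC", "N_POSITIVE", "O_CARBONYL", "O_CARBOXYL",
              "O_HYDROXYL", "S_SULFUR", WATER_O, OTHER_TYPE]


def default_typing_scheme() -> dict[tuple[str, str], str]:
    """(residue_name, atom_name) -> atom-type code for the 20 standard
    residues plus water oxygen."""
    scheme: dict[tuple[str, str], str] = {}
    for res, side in _SIDECHAIN_TYPES.items():
        for at, t in _BACKBONE_TYPES.items():
            scheme[(res, at)] = t
        for at, t in side.items():
            scheme[(res, at)] = t
    for wres in WATER_RESNAMES:
        scheme[(wres, "O")] = WATER_O
        scheme[(wres, "OW")] = WATER_O
    return scheme


def assign_atom_types(
    s: Structure, scheme: dict[tuple[str, str], str] | None = None
) -> Structure:
    """Return a copy of ``s`` with ``atom_type`` filled in.

    Pairs absent from the scheme get the reserved ``OTHER`` code; the number
    of such fallbacks is logged.
    """
    if scheme is not None and len(scheme) == 0:
        raise ValueError("empty typing scheme")
    scheme = scheme or default_typing_scheme()
    out = s.copy()
    n_other = 0
    for a in out.atoms:
        t = scheme.get((a.residue_name, a.name))
        if t is None:
            t = OTHER_TYPE
            n_other += 1
        a.atom_type = t
    if n_other:
        logger.warning("%d atoms fell back to the %r atom type", n_other, OTHER_TYPE)
    return out


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral quadrature points on the unit sphere."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def compute_sasa(
    s: Structure, probe_radius: float = 1.4, n_points: int = 960
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake-Rupley.

    Deterministic for a fixed ``n_points`` (the quadrature is a fixed golden
    spiral, not random).
    """
    if len(s) == 0:
        raise ValueError("empty structure")
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable quadrature")
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    coords = s.coords
    radii = s.radii + probe_radius
    pts = _sphere_points(n_points)
    tree = cKDTree(coords)
    cutoff = 2.0 * radii.max()
    out = np.empty(len(s))
    pairs = tree.query_ball_point(coords, r=cutoff)
    for idx in range(len(s)):
        r = radii[idx]
        surface = coords[idx] + r * pts
        accessible = np.ones(n_points, dtype=bool)
        for j in pairs[idx]:
            if j == idx:
                continue
            d2 = np.sum((surface - coords[j]) ** 2, axis=1)
            # tolerance-band tie-break: a point exactly on a neighbour sphere
            # is owned by the lower-index atom, so duplicated atoms count
            # their shared surface exactly once
            eps = 1e-9 * radii[j] ** 2
            limit = radii[j] ** 2 + (eps if j < idx else -eps)
            accessible &= d2 >= limit
        out[idx] = accessible.mean() * 4.0 * np.pi * r * r
    return out


def residue_sasa(
    s: Structure, probe_radius: float = 1.4, n_points: int = 960
) -> dict[tuple[str, str], float]:
    """Per-residue SASA: sum of the per-atom values."""
    per_atom = compute_sasa(s, probe_radius, n_points)
    out: dict[tuple[str, str], float] = {}
    for a, v in zip(s.atoms, per_atom):
        out[a.residue_key] = out.get(a.residue_key, 0.0) + float(v)
    return out


# ---------------------------------------------------------------------------
# interface classification
# ---------------------------------------------------------------------------

@dataclass
class InterfaceClassification:
    """Levy-style interface classes plus CDR contact flags.

    ``residue_class`` maps (chain, residue_label) to one of ``core``, ``rim``
    or ``non_interface``; ``delta_fraction`` is the fractional SASA loss on
    complexation (buried / free); ``contact_positions`` flags each supplied
    CDR position.
    """

    residue_class: dict[tuple[str, str], str]
    delta_fraction: dict[tuple[str, str], float]
    sasa_free: dict[tuple[str, str], float]
    sasa_complex: dict[tuple[str, str], float]
    contact_positions: dict[tuple[str, str], bool]

    def to_rows(self, structure: Structure) -> list[dict]:
        rows = []
        for chain, label, resname, _ in structure.residues():
            key = (chain, label)
            if key not in self.residue_class:
                continue
            rows.append({
                "chain": chain,
                "resnum": label,
                "resname": resname,
                "sasa_free": round(self.sasa_free[key], 3),
                "sasa_complex": round(self.sasa_complex[key], 3),
                "delta_fraction": round(self.delta_fraction[key], 4),
                "class": self.residue_class[key],
            })
        return rows


def classify_interface(
    complex_structure: Structure,
    side_a_chains,
    side_b_chains,
    cdr_positions=None,
    contact_flags: dict[tuple[str, str], bool] | None = None,
    core_rel_threshold: float = 0.25,
    contact_distance: float = 6.0,
    sidechain_reach: float = 7.0,
    probe_radius: float = 1.4,
    n_points: int = 960,
    burial_tol: float = 0.5,
) -> InterfaceClassification:
    """Classify residues of a two-sided complex as core / rim / non-interface.

    A residue is *interface* if it loses SASA on complexation (more than
    ``burial_tol`` Å²); it is *core* if its relative SASA (against the
    free-amino-acid maximum) is >= ``core_rel_threshold`` in the free protomer
    and drops below that threshold in the complex, and *rim* otherwise.

    CDR contact flags: explicit ``contact_flags`` win (the rotamer-based rule
    lives in :mod:`cdrdesign.confrot`); otherwise a geometric fallback marks a
    position as contact when its backbone/CB atoms come within
    ``contact_distance + sidechain_reach`` of the other side.
    """
    side_a = set(side_a_chains)
    side_b = set(side_b_chains)
    if side_a & side_b:
        raise ValueError(f"chains on both sides: {sorted(side_a & side_b)}")
    prot = complex_structure.without_waters()
    known = set(prot.chain_ids)
    missing = (side_a | side_b) - known
    if missing:
        raise ValueError(f"chains not in structure: {sorted(missing)}")

    sasa_cplx = residue_sasa(prot, probe_radius, n_points)
    sasa_free: dict[tuple[str, str], float] = {}
    for side in (side_a, side_b):
        part = prot.chains(side)
        sasa_free.update(residue_sasa(part, probe_radius, n_points))

    res_class: dict[tuple[str, str], str] = {}
    delta_frac: dict[tuple[str, str], float] = {}
    for chain, label, resname, atoms in prot.residues():
        key = (chain, label)
        free = sasa_free.get(key, 0.0)
        cplx = sasa_cplx.get(key, 0.0)
        buried = max(free - cplx, 0.0)
        delta_frac[key] = min(buried / free, 1.0) if free > 0 else 0.0
        max_area = MAX_SASA.get(resname, 200.0)
        if buried <= burial_tol:
            res_class[key] = "non_interface"
        else:
            rel_free = free / max_area
            rel_cplx = cplx / max_area
            if rel_free >= core_rel_threshold and rel_cplx < core_rel_threshold:
                res_class[key] = "core"
            else:
                res_class[key] = "rim"

    contact: dict[tuple[str, str], bool] = {}
    if cdr_positions:
        other = prot.chains(side_b)
        tree = cKDTree(other.coords)
        reach = contact_distance + sidechain_reach
        for pos in cdr_positions:
            key = (pos[0], str(pos[1]))
            if contact_flags is not None and key in contact_flags:
                contact[key] = bool(contact_flags[key])
                continue
            try:
                atoms = prot.residue(*key)
            except KeyError:
                raise ValueError(f"CDR position {key} not found on side A") from None
            anchor = np.array([a.position for a in atoms
                               if a.name in ("N", "CA", "C", "O", "CB")])
            dmin = tree.query(anchor)[0].min()
            contact[key] = bool(dmin <= reach)

    return InterfaceClassification(
        residue_class=res_class,
        delta_fraction=delta_frac,
        sasa_free=sasa_free,
        sasa_complex={k: sasa_cplx.get(k, 0.0) for k in res_class},
        contact_positions=contact,
    )


# ---------------------------------------------------------------------------
# volume masks
# ---------------------------------------------------------------------------

def volume_mask(s: Structure, grid: GridSpec) -> np.ndarray:
    """Boolean grid, true where the cell center lies inside the van der Waals
    volume of any atom."""
    centers = grid.cell_centers()
    tree = cKDTree(centers)
    mask = np.zeros(grid.n_cells, dtype=bool)
    for a in s.atoms:
        idx = tree.query_ball_point(a.position, r=a.vdw_radius)
        mask[idx] = True
    return mask.reshape(grid.shape)
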