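"""Conformation classes, rotamer placement and steric clash filtering.

Side chains are built on a fixed backbone by superimposing ideal residue
geometry (Chemical Component Dictionary coordinates via biotite) onto the
scaffold N/CA/C frame and then driving the chi torsions to rotamer-library
values.  No local minimization is applied afterwards; a van-der-Waals overlap
filter removes placements that clash with the rest of the complex.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from biotite.structure.info import residue as ccd_residue
from scipy.spatial import cKDTree

from .aminoacids import BACKBONE_ATOMS, CHI_ATOMS, ONE_TO_THREE, THREE_TO_ONE
from .structio import AtomRecord, BONDI_RADII, Structure, _vdw

logger = logging.getLogger(__name__)

__all__ = [
    "ConformationClass",
    "RotamerLibrary",
    "RotamerPlacement",
    "load_rotamer_library",
    "default_rotamer_library",
    "build_alanine_scaffold",
    "enumerate_placements",
    "classify_conformation",
    "residue_conformation",
    "contact_flags_by_rotamers",
    "dihedral",
    "UNCLASSIFIED",
]

UNCLASSIFIED = "unclassified"


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees, in (-180, 180]) for four points."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    x, y, z = axis
    return np.array([
        [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
        [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
        [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
    ])


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t with R @ mobile + t ~ target."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, tc - r @ mc


def ideal_cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral C-beta from backbone N, CA, C coordinates."""
    b = ca - n
    cvec = c - ca
    a = np.cross(b, cvec)
    direction = -0.58273431 * a + 0.56802827 * b - 0.54067466 * cvec
    return ca + 1.526 * direction / np.linalg.norm(direction)


# ---------------------------------------------------------------------------
# ideal residue templates
# ---------------------------------------------------------------------------

_TEMPLATE_CACHE: dict[str, tuple[list[str], np.ndarray, list[tuple[int, int]]]] = {}


def _ideal_template(resname: str):
    """Heavy-atom names, ideal coordinates and bond list for a residue type."""
    if resname not in _TEMPLATE_CACHE:
        arr = ccd_residue(resname)
        keep = [i for i in range(arr.array_length())
                if arr.element[i] not in ("H", "D") and arr.atom_name[i] != "OXT"]
        names = [arr.atom_name[i] for i in keep]
        coords = np.array([arr.coord[i] for i in keep], dtype=float)
        remap = {old: new for new, old in enumerate(keep)}
        bonds = []
        for a, b, _order in arr.bonds.as_array():
            if a in remap and b in remap:
                bonds.append((remap[a], remap[b]))
        _TEMPLATE_CACHE[resname] = (names, coords, bonds)
    return _TEMPLATE_CACHE[resname]


def _downstream_atoms(n_atoms: int, bonds, cut: tuple[int, int]) -> set[int]:
    """Atoms on the far side of the directed bond ``cut`` = (b, c)."""
    adj: dict[int, set[int]] = {i: set() for i in range(n_atoms)}
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    b_idx, c_idx = cut
    seen = {b_idx, c_idx}
    stack = [c_idx]
    out = {c_idx}
    while stack:
        cur = stack.pop()
        for nxt in adj[cur]:
            if nxt not in seen:
                seen.add(nxt)
                out.add(nxt)
                stack.append(nxt)
    out.discard(c_idx)
    return out | {c_idx}


# ---------------------------------------------------------------------------
# rotamer library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rotamer:
    restype: str
    chis: tuple[float, ...]
    frequency: float = 1.0


class RotamerLibrary:
    def __init__(self, rotamers: dict[str, list[Rotamer]]):
        self._rot = rotamers

    def rotamers(self, restype: str) -> list[Rotamer]:
        resname = ONE_TO_THREE.get(restype, restype).upper()
        if resname not in self._rot:
            raise KeyError(f"no rotamers for residue type {restype!r}")
        return self._rot[resname]

    def types(self) -> list[str]:
        return sorted(self._rot)


def load_rotamer_library(table_text: str) -> RotamerLibrary:
    """Parse a rotamer table (TSV: restype, chi1..chi4, frequency; '.' for an
    unused torsion).  Ala/Gly/Pro rows carry no chi angles and yield single
    conformers; rows for unknown residue types are skipped with a warning."""
    rot: dict[str, list[Rotamer]] = {}
    lines = [ln for ln in table_text.splitlines() if ln.strip()]
    for ln in lines:
        parts = ln.split("\t")
        if parts[0].strip().lower() == "restype":
            continue
        resname = parts[0].strip().upper()
        if resname not in THREE_TO_ONE:
            logger.warning("skipping rotamer row for unknown residue %r", resname)
            continue
        n_chi = len(CHI_ATOMS[resname])
        chis = []
        for v in parts[1:1 + n_chi]:
            v = v.strip()
            if v and v != ".":
                chis.append(float(v))
        freq = 1.0
        if len(parts) >= 6 and parts[5].strip() not in ("", "."):
            freq = float(parts[5])
        rot.setdefault(resname, []).append(Rotamer(resname, tuple(chis), freq))
    for resname in ("ALA", "GLY", "PRO"):
        rot.setdefault(resname, [Rotamer(resname, ())])
    # collapse duplicate chi-free rows
    for resname in rot:
        if not CHI_ATOMS[resname]:
            rot[resname] = rot[resname][:1]
    return RotamerLibrary(rot)


def default_rotamer_library() -> RotamerLibrary:
    text = (importlib.resources.files("cdrdesign") / "data" / "rotamers.tsv").read_text()
    return load_rotamer_library(text)


# ---------------------------------------------------------------------------
# alanine scaffold
# ---------------------------------------------------------------------------

def build_alanine_scaffold(s: Structure, positions) -> Structure:
    """Reduce the listed (chain, residue-label) positions to alanine.

    Keeps N, CA, C, O, CB; builds an ideal CB when the residue lacks one
    (glycine).  All other residues are untouched.
    """
    wanted = {(p[0], str(p[1])) for p in positions}
    found: set[tuple[str, str]] = set()
    out_atoms: list[AtomRecord] = []
    for a in s.atoms:
        key = a.residue_key
        if key not in wanted:
            out_atoms.append(replace(a, position=a.position.copy()))
            continue
        found.add(key)
        if a.name in ("N", "CA", "C", "O", "CB"):
            out_atoms.append(replace(a, residue_name="ALA", position=a.position.copy()))
    missing = wanted - found
    if missing:
        raise KeyError(f"positions not found in structure: {sorted(missing)}")
    # build CB for positions that lost it (Gly) and check backbone completeness
    result = Structure(out_atoms, source=s.source)
    final_atoms = list(result.atoms)
    for key in sorted(found):
        res = [a for a in final_atoms if a.residue_key == key]
        names = {a.name for a in res}
        lacking = {"N", "CA", "C"} - names
        if lacking:
            raise ValueError(f"residue {key}: missing backbone atoms {sorted(lacking)}")
        if "CB" not in names:
            by = {a.name: a for a in res}
            cb_pos = ideal_cb_position(by["N"].position, by["CA"].position,
                                       by["C"].position)
            anchor = by["CA"]
            idx = final_atoms.index(anchor)
            final_atoms.insert(idx + 1, AtomRecord(
                serial=anchor.serial, name="CB", element="C",
                residue_name="ALA", chain_id=anchor.chain_id,
                residue_number=anchor.residue_number,
                insertion_code=anchor.insertion_code,
                position=cb_pos, vdw_radius=_vdw("C", BONDI_RADII),
            ))
    return Structure(final_atoms, source=s.source)


# ---------------------------------------------------------------------------
# rotamer placement
# ---------------------------------------------------------------------------

@dataclass
class RotamerPlacement:
    position_j: tuple[str, str]
    aa_type_i: str          # 1-letter code
    rotamer_k: int
    atoms: list[AtomRecord]  # full residue: scaffold backbone + placed side chain
    sidechain_atoms: list[AtomRecord]
    clash_free: bool

    @property
    def heavy_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])


def _place_rotamer(backbone: dict[str, AtomRecord], resname: str,
                   chis: tuple[float, ...]) -> list[AtomRecord]:
    """Ideal residue superimposed on the scaffold N/CA/C with chi torsions set."""
    names, coords, bonds = _ideal_template(resname)
    coords = coords.copy()
    idx = {n: i for i, n in enumerate(names)}
    for bb in ("N", "CA", "C"):
        if bb not in idx:
            raise ValueError(f"{resname}: ideal template lacks backbone atom {bb}")
    mobile = np.array([coords[idx[bb]] for bb in ("N", "CA", "C")])
    target = np.array([backbone[bb].position for bb in ("N", "CA", "C")])
    r, t = _kabsch(mobile, target)
    coords = coords @ r.T + t

    chi_defs = CHI_ATOMS[resname]
    for k, target_chi in enumerate(chis):
        if k >= len(chi_defs):
            break
        a, b, c, d = (idx[nm] for nm in chi_defs[k])
        current = dihedral(coords[a], coords[b], coords[c], coords[d])
        rot = _rotation_about_axis(coords[c] - coords[b], target_chi - current)
        moving = sorted(_downstream_atoms(len(names), bonds, (b, c)))
        pivot = coords[b]
        coords[moving] = (coords[moving] - pivot) @ rot.T + pivot
    anchor = backbone["CA"]
    out = []
    for n, xyz in zip(names, coords):
        if n in BACKBONE_ATOMS:
            continue
        el = "".join(ch for ch in n if ch.isalpha())[0]
        if n.startswith("O"):
            el = "O"
        elif n.startswith("N"):
            el = "N"
        elif n.startswith("S"):
            el = "S"
        else:
            el = "C"
        out.append(AtomRecord(
            serial=anchor.serial, name=n, element=el, residue_name=resname,
            chain_id=anchor.chain_id, residue_number=anchor.residue_number,
            insertion_code=anchor.insertion_code, position=xyz,
            vdw_radius=_vdw(el, BONDI_RADII),
        ))
    return out


def enumerate_placements(
    scaffold: Structure,
    position_j,
    aa_type_i: str,
    library: RotamerLibrary,
    clash_tolerance: float = 0.6,
    keep_clashing: bool = False,
) -> list[RotamerPlacement]:
    """All rotamers of ``aa_type_i`` at ``position_j`` on a fixed scaffold.

    Placements whose side-chain heavy atoms overlap any other atom of the
    complex closer than (r1 + r2 - clash_tolerance) are removed.  Backbone
    atoms of the two chain neighbours of the position are exempt (covalent
    1-3/1-4 proximity, not a steric clash).
    """
    key = (position_j[0], str(position_j[1]))
    res_atoms = scaffold.residue(*key)
    backbone = {a.name: a for a in res_atoms if a.name in ("N", "CA", "C", "O")}
    if not {"N", "CA", "C"} <= set(backbone):
        raise ValueError(f"position {key}: incomplete backbone")
    resname = ONE_TO_THREE.get(aa_type_i, aa_type_i).upper()

    # clash environment: everything except this residue and neighbouring
    # backbone atoms
    def _exempt(a: AtomRecord) -> bool:
        if a.residue_key == key:
            return True
        if (a.chain_id == key[0]
                and a.name in ("N", "CA", "C", "O", "CB")
                and abs(a.residue_number - res_atoms[0].residue_number) == 1
                and not a.insertion_code
                and not res_atoms[0].insertion_code):
            return True
        return False

    env = [a for a in scaffold.atoms if not _exempt(a)]
    env_coords = np.array([a.position for a in env]) if env else np.empty((0, 3))
    env_radii = np.array([a.vdw_radius for a in env]) if env else np.empty(0)
    tree = cKDTree(env_coords) if len(env) else None

    placements: list[RotamerPlacement] = []
    for k, rotamer in enumerate(library.rotamers(aa_type_i)):
        if resname == "GLY":
            side: list[AtomRecord] = []
        else:
            side = _place_rotamer(backbone, resname, rotamer.chis)
        clash = False
        if tree is not None and side:
            for a in side:
                near = tree.query_ball_point(a.position, r=a.vdw_radius
                                             + env_radii.max())
                for j in near:
                    lim = a.vdw_radius + env_radii[j] - clash_tolerance
                    if np.linalg.norm(a.position - env_coords[j]) < lim:
                        clash = True
                        break
                if clash:
                    break
        if clash and not keep_clashing:
            continue
        full = [replace(a, residue_name=resname) for a in res_atoms
                if a.name in ("N", "CA", "C", "O")] + side
        placements.append(RotamerPlacement(
            position_j=key, aa_type_i=THREE_TO_ONE[resname], rotamer_k=k,
            atoms=full, sidechain_atoms=side, clash_free=not clash,
        ))
    return placements


# ---------------------------------------------------------------------------
# conformation classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConformationClass:
    class_id: str
    backbone_bin: str
    chi1_bin: str | None = None


# Half-open phi/psi rectangles, checked in order; first match wins.  Angles
# exactly on a shared edge therefore fall into the earlier (lower) bin.
_BACKBONE_BINS = [
    ("helix", -120.0, -30.0, -80.0, 0.0),
    ("sheet", -180.0, -100.0, 100.0, 180.0),
    ("ppii", -100.0, -40.0, 100.0, 180.0),
    ("left", 30.0, 100.0, -20.0, 90.0),
    ("bridge", -180.0, -20.0, 0.0, 100.0),
]


def _chi1_bin(chi1: float) -> str:
    c = ((chi1 + 180.0) % 360.0) - 180.0
    if -120.0 <= c < 0.0:
        return "gm"
    if 0.0 <= c < 120.0:
        return "gp"
    return "t"


def classify_conformation(
    phi: float | None, psi: float | None, chi1: float | None = None
) -> ConformationClass:
    """Backbone phi/psi rectangle x chi1 staggered-well bin.

    Terminal residues (phi or psi unavailable) get the ``unclassified``
    sentinel.
    """
    if phi is None or psi is None:
        return ConformationClass(UNCLASSIFIED, UNCLASSIFIED)
    bb = "other"
    for name, plo, phi_hi, qlo, qhi in _BACKBONE_BINS:
        if plo <= phi < phi_hi and qlo <= psi < qhi:
            bb = name
            break
    if chi1 is None:
        return ConformationClass(bb, bb)
    cb = _chi1_bin(chi1)
    return ConformationClass(f"{bb}/{cb}", bb, cb)


def residue_conformation(s: Structure, chain_id: str, residue_label: str) -> ConformationClass:
    """Classify a residue of a structure from its coordinates."""
    res = s.residue(chain_id, str(residue_label))
    by = {a.name: a for a in res}
    num = res[0].residue_number
    prev_c = next_n = None
    for a in s.atoms:
        if a.chain_id != chain_id or a.insertion_code:
            continue
        if a.residue_number == num - 1 and a.name == "C":
            prev_c = a.position
        if a.residue_number == num + 1 and a.name == "N":
            next_n = a.position
    phi = psi = chi1 = None
    if prev_c is not None and all(n in by for n in ("N", "CA", "C")):
        phi = dihedral(prev_c, by["N"].position, by["CA"].position, by["C"].position)
    if next_n is not None and all(n in by for n in ("N", "CA", "C")):
        psi = dihedral(by["N"].position, by["CA"].position, by["C"].position, next_n)
    chi_defs = CHI_ATOMS.get(res[0].residue_name, [])
    if chi_defs:
        names = chi_defs[0]
        if all(n in by for n in names):
            chi1 = dihedral(*(by[n].position for n in names))
    return classify_conformation(phi, psi, chi1)


# ---------------------------------------------------------------------------
# CDR contact flags (rotamer-based rule)
# ---------------------------------------------------------------------------

def contact_flags_by_rotamers(
    scaffold: Structure,
    positions,
    antigen: Structure,
    library: RotamerLibrary | None = None,
    contact_distance: float = 6.0,
    clash_tolerance: float = 0.6,
    aa_types: str = "ACDEFGHIKLMNPQRSTVWY",
) -> dict[tuple[str, str], bool]:
    """A position is *contact* when any heavy atom of any clash-free rotamer
    of any amino-acid type comes within ``contact_distance`` of an antigen
    atom."""
    library = library or default_rotamer_library()
    tree = cKDTree(antigen.coords)
    flags: dict[tuple[str, str], bool] = {}
    for pos in positions:
        key = (pos[0], str(pos[1]))
        hit = False
        for aa in aa_types:
            for pl in enumerate_placements(scaffold, key, aa, library,
                                           clash_tolerance=clash_tolerance):
                d = tree.query(pl.heavy_coords)[0]
                if np.min(d) <= contact_distance:
                    hit = True
                    break
            if hit:
                break
        flags[key] = hit
    return flags
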