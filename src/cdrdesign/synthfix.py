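"""Synthetic fixtures: toy complexes, statistics libraries, simulated
selections and planted model tables.

Every generator is deterministic per seed and returns a manifest carrying the
generator parameters and ground-truth tallies, so every expected value in a
test can be recomputed from the manifest alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aminoacids import AA1, ONE_TO_THREE
from .confrot import ideal_cb_position
from .pdm import _residue_frame
from .phageprof import SelectionDataset, nnk_background
from .structio import AtomRecord, BONDI_RADII, Structure, assign_atom_types

__all__ = [
    "FixtureManifest",
    "make_toy_complex",
    "make_structure_library",
    "simulate_selection",
    "make_planted_model_tables",
]


@dataclass
class FixtureManifest:
    seed: int
    generator: str
    params: dict = field(default_factory=dict)
    tallies: dict = field(default_factory=dict)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"generator\t{self.generator}\n")
            fh.write(f"seed\t{self.seed}\n")
            for section, d in (("param", self.params), ("tally", self.tallies)):
                for k in sorted(d):
                    fh.write(f"{section}.{k}\t{d[k]}\n")


_BB_OFFSETS = {  # toy extended-strand template, relative to CA, z = 0
    "N": np.array([-1.20, 0.80, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.20, 0.80, 0.0]),
    "O": np.array([1.40, 2.00, 0.0]),
}


def _strand(chain_id: str, n_residues: int, resname: str, jitter: np.ndarray | None,
            serial0: int) -> list[AtomRecord]:
    atoms: list[AtomRecord] = []
    serial = serial0
    j_idx = 0
    for i in range(n_residues):
        ca = np.array([3.8 * i, 0.0, 0.0])
        pos = {}
        for name in ("N", "CA", "C", "O"):
            p = ca + _BB_OFFSETS[name]
            if jitter is not None:
                p = p + jitter[j_idx]
                j_idx += 1
            pos[name] = p
        if resname != "GLY":
            pos["CB"] = ideal_cb_position(pos["N"], pos["CA"], pos["C"])
        for name in ("N", "CA", "C", "O", "CB"):
            if name not in pos:
                continue
            el = name[0]
            atoms.append(AtomRecord(
                serial=serial, name=name, element=el, residue_name=resname,
                chain_id=chain_id, residue_number=i + 1, position=pos[name],
                vdw_radius=BONDI_RADII.get(el, 1.7),
            ))
            serial += 1
    return atoms


def make_toy_complex(
    seed: int,
    n_residues_a: int = 6,
    n_residues_b: int = 6,
    interface_gap: float = 4.0,
    resname: str = "ALA",
    jitter_sd: float = 0.0,
) -> tuple[Structure, FixtureManifest]:
    """Two ideal-geometry peptide strands facing each other across a gap.

    ``interface_gap`` is the exact minimum heavy-atom distance between the
    chains.  ``jitter_sd`` adds seeded Gaussian coordinate noise (Å).
    """
    if n_residues_a < 1 or n_residues_b < 1:
        raise ValueError("chains need at least one residue")
    rng = np.random.default_rng(seed)
    jit_a = rng.normal(0, jitter_sd, (4 * n_residues_a, 3)) if jitter_sd > 0 else None
    jit_b = rng.normal(0, jitter_sd, (4 * n_residues_b, 3)) if jitter_sd > 0 else None
    chain_a = _strand("A", n_residues_a, resname, jit_a, serial0=1)
    chain_b = _strand("B", n_residues_b, resname, jit_b,
                      serial0=len(chain_a) + 1)
    # flip chain B upside-down so the two strands face each other, then set
    # the exact gap along z
    for a in chain_b:
        a.position = a.position * np.array([1.0, -1.0, -1.0])
    coords_a = np.array([a.position for a in chain_a])
    coords_b = np.array([a.position for a in chain_b])
    # translate along z so the minimum inter-chain distance equals the gap
    dz = coords_b[:, 2][None, :] - coords_a[:, 2][:, None]
    dxy2 = ((coords_a[:, None, :2] - coords_b[None, :, :2]) ** 2).sum(axis=2)

    def _min_dist(shift: float) -> float:
        return float(np.sqrt(dxy2 + (dz + shift) ** 2).min())

    lo, hi = 0.0, interface_gap + 100.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _min_dist(mid) < interface_gap:
            lo = mid
        else:
            hi = mid
    shift = hi
    for a in chain_b:
        a.position = a.position + np.array([0.0, 0.0, shift])
    structure = Structure(chain_a + chain_b, source=f"toy-complex-seed{seed}")
    coords_b2 = np.array([a.position for a in chain_b])
    gap = float(np.min(np.linalg.norm(coords_a[:, None] - coords_b2[None, :], axis=2)))
    manifest = FixtureManifest(
        seed=seed, generator="make_toy_complex",
        params={"n_residues_a": n_residues_a, "n_residues_b": n_residues_b,
                "interface_gap": interface_gap, "resname": resname,
                "jitter_sd": jitter_sd},
        tallies={"n_atoms": len(structure),
                 "n_atoms_a": len(chain_a), "n_atoms_b": len(chain_b),
                 "achieved_gap": round(gap, 6)},
    )
    return structure, manifest


def make_structure_library(
    seed: int,
    n_structures: int = 4,
    planted_contact: tuple[str, str, tuple[float, float, float]] = (
        "ALA", "O_CARBONYL", (3.0, 0.0, 0.0)),
    n_decoys: int = 3,
    decoy_distance: float = 30.0,
) -> tuple[list[Structure], FixtureManifest]:
    """Structures each containing one source residue with a neighbour atom
    planted at a fixed offset in the residue's local N-CA-C frame, plus
    far-away decoy atoms that fall outside any harvest shell."""
    source_resname, target_type, offset = planted_contact
    source_resname = ONE_TO_THREE.get(source_resname, source_resname).upper()
    offset = np.asarray(offset, dtype=float)
    rng = np.random.default_rng(seed)
    structures: list[Structure] = []
    for s_idx in range(n_structures):
        atoms = _strand("A", 3, source_resname, None, serial0=1)
        typed = assign_atom_types(Structure(atoms))
        atoms = typed.atoms
        mid = [a for a in atoms if a.residue_number == 2]
        frame = _residue_frame({a.name: a for a in mid})
        origin, axes = frame
        target_pos = origin + axes @ offset
        el = target_type.split("_")[0][:1] or "C"
        atoms.append(AtomRecord(
            serial=len(atoms) + 1, name="PLT", element=el, residue_name="LIG",
            chain_id="X", residue_number=900, position=target_pos,
            vdw_radius=BONDI_RADII.get(el, 1.7), atom_type=target_type,
        ))
        for d in range(n_decoys):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            atoms.append(AtomRecord(
                serial=len(atoms) + 1, name="DCY", element="C",
                residue_name="LIG", chain_id="X", residue_number=901 + d,
                position=origin + decoy_distance * direction,
                vdw_radius=BONDI_RADII["C"], atom_type="C_ALIPHATIC",
            ))
        structures.append(Structure(atoms, source=f"lib-{seed}-{s_idx}"))
    manifest = FixtureManifest(
        seed=seed, generator="make_structure_library",
        params={"n_structures": n_structures, "source_resname": source_resname,
                "target_type": target_type, "offset": tuple(offset),
                "n_decoys": n_decoys, "decoy_distance": decoy_distance},
        tallies={"planted_per_structure": 1,
                 "expected_planted_total": n_structures},
    )
    return structures, manifest


def simulate_selection(
    seed: int,
    window_positions,
    true_enrichment: dict | None = None,
    m_sequences: int = 200,
    stop_policy: str = "amber_to_Gln",
    library_id: str = "SIM",
) -> tuple[SelectionDataset, FixtureManifest]:
    """Simulated selected binders: sequences drawn position-independently
    with probability proportional to p_i * enrichment_ji over the NNK
    background p."""
    if m_sequences < 1:
        raise ValueError("m_sequences must be >= 1")
    positions = [str(p) for p in window_positions]
    enrich = true_enrichment or {}
    for (pos, aa), e in enrich.items():
        if e <= 0:
            raise ValueError(f"enrichment for ({pos}, {aa}) must be > 0")
    rng = np.random.default_rng(seed)
    p = nnk_background(stop_policy).reindex(list(AA1)).to_numpy()
    columns = []
    tallies: dict[str, int] = {}
    for pos in positions:
        weights = p * np.array([enrich.get((pos, aa), 1.0) for aa in AA1])
        weights = weights / weights.sum()
        draws = rng.choice(len(AA1), size=m_sequences, p=weights)
        columns.append([AA1[d] for d in draws])
        for aa_idx in draws:
            key = f"{pos}.{AA1[aa_idx]}"
            tallies[key] = tallies.get(key, 0) + 1
    sequences = ["".join(col[r] for col in columns) for r in range(m_sequences)]
    dataset = SelectionDataset(library_id=library_id, positions=positions,
                               sequences=sequences)
    manifest = FixtureManifest(
        seed=seed, generator="simulate_selection",
        params={"positions": ",".join(positions), "M": m_sequences,
                "stop_policy": stop_policy,
                "enrichment": {f"{k[0]}.{k[1]}": v for k, v in enrich.items()}},
        tallies=tallies,
    )
    return dataset, manifest


def make_planted_model_tables(
    seed: int,
    n_positions: int = 24,
    weights: tuple[float, float, float, float] = (1.5, -1.0, 0.8, 0.0),
    noise_sd: float = 0.0,
    margin: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, FixtureManifest]:
    """Score and preference tables with planted logistic structure.

    X, Y, Z are standard normal per (position, type); the binary label is the
    sign of the noisy linear predictor.  W is set to the predictor itself so
    sign(W) matches deltaW.  Feature draws whose noiseless predictor falls
    inside ``margin`` of the decision boundary are redrawn, so that at
    noise_sd = 0 the labels are a consistently learnable function of the
    features (boundary points carry no recoverable label information).
    """
    if n_positions < 3:
        raise ValueError("need at least 3 positions for leave-one-out work")
    wx, wy, wz, a0 = weights
    rng = np.random.default_rng(seed)
    positions = [f"{i + 1:02d}" for i in range(n_positions)]
    score_rows = []
    pref_rows = []
    n_pos_labels = 0
    w_norm = float(np.linalg.norm([wx, wy, wz])) or 1.0
    for pos in positions:
        for aa in AA1:
            while True:
                x, y, z = rng.normal(size=3)
                latent = wx * x + wy * y + wz * z + a0
                if abs(latent) >= margin * w_norm:
                    break
            if noise_sd > 0:
                latent += rng.normal(0, noise_sd)
            dw = int(latent > 0)
            n_pos_labels += dw
            score_rows.append({"position": pos, "aa": aa, "X": x, "Y": y, "Z": z})
            pref_rows.append({"position": pos, "aa": aa, "W": latent,
                              "deltaW": dw})
    manifest = FixtureManifest(
        seed=seed, generator="make_planted_model_tables",
        params={"n_positions": n_positions, "weights": weights,
                "noise_sd": noise_sd, "margin": margin},
        tallies={"n_rows": n_positions * len(AA1),
                 "n_positive_labels": n_pos_labels},
    )
    return pd.DataFrame(score_rows), pd.DataFrame(pref_rows), manifest
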