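"""Per-position, per-amino-acid interface scores.

Three log-odds terms are computed for amino-acid type i placed at interface
position j:

* ``X`` - atomistic contact score: for each heavy atom of the placed residue,
  the PDM of that atom's type around the antigen is averaged over the atom's
  van der Waals sphere (AVE) and log10(AVE / p_ref) summed over atoms, with
  AVE floored at p_ref.  The per-position value is the maximum over the
  clash-free rotamers (most favourable contact geometry).
* ``Y`` - hydration / desolvation balance: two negative desolvation sums
  (water density of one side inside the molecular volume of the other) plus
  two positive water-mediated terms on the overlap of the two hydration
  shells.  The per-position value is the minimum over rotamers.
* ``Z`` - structural propensity from a structure-based sequence profile,
  a Bayesian pseudo-counted log-odds in half-bit units.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .aminoacids import AA1
from .confrot import RotamerLibrary, RotamerPlacement, enumerate_placements
from .grids import GridSpec
from .pdm import (
    DEFAULT_P_REF,
    ProbabilityDensityMap,
    average_pdm_over_atom,
    build_water_pdm,
)
from .structio import Structure, assign_atom_types, volume_mask

logger = logging.getLogger(__name__)

__all__ = [
    "log_ratio",
    "contact_score",
    "hydration_score",
    "structural_propensity",
    "score_positions",
    "antigen_contact_map",
    "correlate_preferences",
]


def log_ratio(values, p_ref: float = DEFAULT_P_REF) -> np.ndarray:
    """log10(max(value, p_ref) / p_ref) - the singularity-guarded log-odds
    against the far-field reference probability."""
    v = np.maximum(np.asarray(values, dtype=float), p_ref)
    return np.log10(v / p_ref)


def contact_score(
    placement: RotamerPlacement,
    antigen_maps: dict[str, ProbabilityDensityMap],
    p_ref: float = DEFAULT_P_REF,
) -> float:
    """X for one rotamer: sum over the residue's heavy atoms of
    log10(max(AVE, p_ref) / p_ref)."""
    x = 0.0
    for atom in placement.atoms:
        t = atom.atom_type
        if t is None:
            raise ValueError(f"atom {atom.name} has no atom type assigned")
        if t not in antigen_maps:
            raise KeyError(f"no antigen PDM for atom type {t!r}")
        ave = average_pdm_over_atom(antigen_maps[t], atom)
        x += float(log_ratio(ave, p_ref))
    return x


def hydration_score(
    water_map_ab: np.ndarray | ProbabilityDensityMap,
    water_map_ag: np.ndarray | ProbabilityDensityMap,
    mask_ab: np.ndarray,
    mask_ag: np.ndarray,
    p_ref: float = DEFAULT_P_REF,
) -> float:
    """Y for one rotamer from two water maps and two molecular-volume masks
    sharing one grid.

    Y = - sum_{cells in antigen volume} L(ab)
        - sum_{cells in antibody volume} L(ag)
        + sum_{cells in the hydration overlap} [L(ab) + L(ag)]

    with L(map, cell) = log10(max(value, p_ref)/p_ref) and the overlap being
    cells where both water maps exceed p_ref outside both molecular volumes.
    """
    ab = water_map_ab.values if isinstance(water_map_ab, ProbabilityDensityMap) else water_map_ab
    ag = water_map_ag.values if isinstance(water_map_ag, ProbabilityDensityMap) else water_map_ag
    ab = np.asarray(ab, dtype=float)
    ag = np.asarray(ag, dtype=float)
    if not (ab.shape == ag.shape == np.shape(mask_ab) == np.shape(mask_ag)):
        raise ValueError("water maps and masks must share one grid")
    l_ab = log_ratio(ab, p_ref)
    l_ag = log_ratio(ag, p_ref)
    overlap = (ab > p_ref) & (ag > p_ref) & ~mask_ab & ~mask_ag
    y = (-l_ab[mask_ag].sum() - l_ag[mask_ab].sum()
         + l_ab[overlap].sum() + l_ag[overlap].sum())
    return float(y)


def structural_propensity(
    counts: np.ndarray, m_rows: int, background: np.ndarray, b: float | None = None
) -> np.ndarray:
    """Half-bit structural propensity from a (possibly gapped) count profile.

    For a position with per-type counts C_i, profile depth M (rows, gaps
    included), pseudo-count base B (default sqrt(M)) and background p_i:

        M' = sum_i C_i            (effective, gap-free count)
        B' = B + M - M'           (Bayesian prediction pseudo-count)
        Z_i = 2 * log2( ((C_i + B' * p_i) / (M' + B')) / p_i )
    """
    counts = np.asarray(counts, dtype=float)
    p = np.asarray(background, dtype=float)
    if counts.shape[-1] != p.shape[-1]:
        raise ValueError("counts and background must cover the same types")
    if np.any((p <= 0) & (counts > 0)):
        raise ValueError("zero background probability with non-zero count")
    m_eff = counts.sum(axis=-1, keepdims=True)
    if np.any(m_eff > m_rows):
        raise ValueError("column counts exceed the number of profile rows")
    if b is None:
        b = float(np.sqrt(m_rows))
    b_eff = b + m_rows - m_eff
    q = (counts + b_eff * p) / (m_eff + b_eff)
    with np.errstate(divide="ignore"):
        z = 2.0 * np.log2(np.where(p > 0, q / np.where(p > 0, p, 1.0), 1.0))
    return z


def score_positions(
    scaffold: Structure,
    antigen: Structure,
    positions,
    antigen_maps: dict[str, ProbabilityDensityMap],
    library: RotamerLibrary,
    types: str = AA1,
    water_stats=None,
    water_map_ag: ProbabilityDensityMap | None = None,
    grid: GridSpec | None = None,
    p_ref: float = DEFAULT_P_REF,
    clash_tolerance: float = 0.6,
    scheme=None,
) -> pd.DataFrame:
    """Score every (position, amino-acid type) on an alanine-reduced scaffold.

    Returns a tidy frame with one row per (position, type): the max-over-
    rotamers X, the min-over-rotamers Y (zero unless water statistics are
    supplied), the clash-free rotamer count and a ``sterically_excluded``
    flag for types with no clash-free rotamer.  Per-rotamer values are kept
    in the ``rotamer_X``/``rotamer_Y`` list columns.
    """
    compute_y = water_stats is not None
    mask_ag = mask_ab_base = None
    if compute_y:
        if grid is None:
            both = np.vstack([scaffold.coords, antigen.coords])
            grid = GridSpec.around(both, spacing=water_stats.spacing, margin=8.0)
        if water_map_ag is None:
            water_map_ag = build_water_pdm(antigen, water_stats, grid=grid, p_ref=p_ref)
        mask_ag = volume_mask(antigen, grid)
        mask_ab_base = volume_mask(scaffold, grid)

    rows = []
    for pos in positions:
        key = (pos[0], str(pos[1]))
        for aa in types:
            placements = enumerate_placements(scaffold, key, aa, library,
                                              clash_tolerance=clash_tolerance)
            rot_x: list[float] = []
            rot_y: list[float] = []
            for pl in placements:
                pl.atoms = assign_atom_types(Structure(pl.atoms), scheme).atoms
                rot_x.append(contact_score(pl, antigen_maps, p_ref))
                if compute_y:
                    res_struct = Structure([a for a in pl.atoms])
                    map_ab = build_water_pdm(res_struct, water_stats, grid=grid,
                                             p_ref=p_ref, surface_cutoff=0.0)
                    mask_ab = mask_ab_base | volume_mask(res_struct, grid)
                    rot_y.append(hydration_score(map_ab, water_map_ag,
                                                 mask_ab, mask_ag, p_ref))
            excluded = len(placements) == 0
            rows.append({
                "chain": key[0],
                "position": key[1],
                "aa": aa,
                "X": max(rot_x) if rot_x else 0.0,
                "Y": min(rot_y) if rot_y else 0.0,
                "Z": 0.0,
                "n_rotamers": len(placements),
                "sterically_excluded": excluded,
                "rotamer_X": rot_x,
                "rotamer_Y": rot_y,
            })
    return pd.DataFrame(rows)


def antigen_contact_map(
    antigen: Structure,
    model_placements,
    antigen_maps: dict[str, ProbabilityDensityMap],
    p_ref: float = DEFAULT_P_REF,
    assign_radius: float = 6.0,
) -> np.ndarray:
    """Per-antigen-atom interaction strength averaged over binder models.

    Each placed CDR atom contributes its X-type log-odds L = log10(max(AVE,
    p_ref)/p_ref); the contribution is attributed to the nearest antigen atom
    within ``assign_radius``.  The map is the mean over models of the summed
    attributions.
    """
    model_placements = list(model_placements)
    if not model_placements:
        raise ValueError("at least one binder model is required")
    tree = cKDTree(antigen.coords)
    strength = np.zeros(len(antigen.atoms))
    for model in model_placements:
        contrib = np.zeros(len(antigen.atoms))
        for pl in model:
            for atom in pl.atoms:
                t = atom.atom_type
                if t is None or t not in antigen_maps:
                    continue
                l_val = float(log_ratio(
                    average_pdm_over_atom(antigen_maps[t], atom), p_ref))
                if l_val <= 0.0:
                    continue
                d, idx = tree.query(atom.position)
                if d <= assign_radius:
                    contrib[idx] += l_val
        strength += contrib
    return strength / len(model_placements)


def correlate_preferences(
    score_table: pd.DataFrame, preference_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-position Pearson correlation of the experimental preference W with
    each of X, Y and Z over the 20 amino-acid types.

    Positions where either vector has zero variance get NaN for that term.
    Both frames must be tidy with ``position``, ``aa`` and the respective
    value columns.
    """
    merged = score_table.merge(preference_table[["position", "aa", "W"]],
                               on=["position", "aa"], how="inner")
    rows = []
    for pos, grp in merged.groupby("position", sort=False):
        if len(grp) < 3:
            raise ValueError(f"position {pos}: fewer than 3 types in common")
        row = {"position": pos}
        for term in ("X", "Y", "Z"):
            w = grp["W"].to_numpy(float)
            v = grp[term].to_numpy(float)
            if np.std(w) == 0 or np.std(v) == 0:
                row[f"cc_W{term}"] = np.nan
            else:
                row[f"cc_W{term}"] = float(pearsonr(w, v)[0])
        rows.append(row)
    return pd.DataFrame(rows)
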