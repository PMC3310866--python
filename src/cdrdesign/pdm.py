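"""Knowledge-based probability density maps (PDMs) of interacting atoms.

The statistics behind a PDM are harvested from a library of protein
structures: around every buried (interior) residue, the positions of
neighbouring atoms are recorded in the residue's local N-CA-C frame, binned
into a 3-D histogram keyed by (source residue type, backbone/chi1
conformation class, neighbour atom type).  Crystallographic waters harvested
around *surface* residues give the water-oxygen statistics used for hydration
pattern prediction.

Projecting those class-conditioned histograms back out of every surface
residue of a query structure and normalising yields a discrete probability
map of where an atom of a given type (or a water oxygen) is expected around
the query.  A pairwise interaction-preference filter (log-odds of observed
pair frequencies against marginal expectation) suppresses deposits for atom
type pairs that do not interact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .confrot import residue_conformation
from .grids import GridSpec, write_dx
from .structio import (
    MAX_SASA,
    OTHER_TYPE,
    Structure,
    WATER_O,
    assign_atom_types,
    residue_sasa,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ContactStatistics",
    "InteractionPreferenceFilter",
    "ProbabilityDensityMap",
    "collect_interior_contacts",
    "build_interaction_filter",
    "build_pdm",
    "build_water_pdm",
    "average_pdm_over_atom",
    "hydration_pattern_score",
    "DEFAULT_P_REF",
]

DEFAULT_P_REF = 1e-10


def _residue_frame(by_name: dict) -> tuple[np.ndarray, np.ndarray] | None:
    """Orthonormal local frame (origin CA) from backbone N, CA, C."""
    if not all(n in by_name for n in ("N", "CA", "C")):
        return None
    n = by_name["N"].position
    ca = by_name["CA"].position
    c = by_name["C"].position
    e1 = c - n
    nrm = np.linalg.norm(e1)
    if nrm < 1e-9:
        return None
    e1 = e1 / nrm
    normal = np.cross(n - ca, c - ca)
    nn = np.linalg.norm(normal)
    if nn < 1e-9:
        return None
    e3 = normal / nn
    e2 = np.cross(e3, e1)
    return ca, np.column_stack([e1, e2, e3])  # columns are frame axes


@dataclass
class ContactStatistics:
    """3-D neighbour histograms in residue local frames plus atom-type pair
    counts.

    ``histograms`` maps (residue_name, conformation class id, target atom
    type) to an integer count grid of shape (nb, nb, nb) spanning
    [-extent, extent) at ``spacing`` Å per cell.
    """

    extent: float
    spacing: float
    shell: tuple[float, float]
    histograms: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)
    pair_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    n_contacts: int = 0

    @property
    def n_bins(self) -> int:
        return int(round(2.0 * self.extent / self.spacing))

    def _bin(self, offset: np.ndarray) -> tuple[int, int, int] | None:
        idx = np.floor((offset + self.extent) / self.spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= self.n_bins):
            return None
        return tuple(idx)

    def add(self, key: tuple[str, str, str], offset: np.ndarray) -> bool:
        b = self._bin(offset)
        if b is None:
            return False
        if key not in self.histograms:
            nb = self.n_bins
            self.histograms[key] = np.zeros((nb, nb, nb), dtype=np.int64)
        self.histograms[key][b] += 1
        self.n_contacts += 1
        return True

    def add_pair(self, type_a: str, type_b: str) -> None:
        key = tuple(sorted((type_a, type_b)))
        self.pair_counts[key] = self.pair_counts.get(key, 0) + 1

    def bin_centers(self) -> np.ndarray:
        """(nb, ) cell-center coordinates along one axis, local frame."""
        nb = self.n_bins
        return -self.extent + self.spacing * (np.arange(nb) + 0.5)

    def target_types(self) -> set[str]:
        return {k[2] for k in self.histograms}


def collect_interior_contacts(
    structures,
    scheme=None,
    shell: tuple[float, float] = (0.0, 6.0),
    extent: float = 8.0,
    spacing: float = 1.0,
    burial_cutoff: float = 0.05,
    source_selection: str = "buried",
    pair_contact_distance: float = 4.5,
    sasa_points: int = 240,
) -> ContactStatistics:
    """Harvest neighbour-atom statistics from a structure library.

    ``source_selection`` chooses the source residues: ``buried`` (relative
    SASA below ``burial_cutoff`` - protein-interior statistics), ``surface``
    (above the cutoff - used for water harvesting) or ``all``.
    Neighbour atoms whose distance to the nearest source-residue heavy atom
    lies inside ``shell`` are recorded; atoms of the source residue itself
    and the flanking backbone are not.
    """
    structures = list(structures)
    if not structures:
        raise ValueError("empty structure library")
    if source_selection not in ("buried", "surface", "all"):
        raise ValueError(f"unknown source_selection {source_selection!r}")
    stats = ContactStatistics(extent=extent, spacing=spacing, shell=shell)
    for s in structures:
        typed = s if all(a.atom_type for a in s.atoms) else assign_atom_types(s, scheme)
        protein = typed.without_waters()
        rsasa = residue_sasa(protein, n_points=sasa_points)
        all_atoms = typed.atoms
        all_coords = typed.coords
        tree = cKDTree(all_coords)
        for chain, label, resname, res_atoms in protein.residues():
            if resname not in MAX_SASA:
                continue
            rel = rsasa.get((chain, label), 0.0) / MAX_SASA[resname]
            if source_selection == "buried" and rel >= burial_cutoff:
                continue
            if source_selection == "surface" and rel < burial_cutoff:
                continue
            by = {a.name: a for a in res_atoms}
            frame = _residue_frame(by)
            if frame is None:
                continue
            origin, axes = frame
            conf = residue_conformation(protein, chain, label)
            key_class = conf.class_id
            res_coords = np.array([a.position for a in res_atoms])
            res_tree = cKDTree(res_coords)
            near = set()
            for i in tree.query_ball_point(origin, r=extent * (3.0 ** 0.5)):
                near.add(i)
            for i in sorted(near):
                a = all_atoms[i]
                if a.residue_key == (chain, label):
                    continue
                if (a.chain_id == chain and a.name in ("N", "CA", "C", "O")
                        and abs(a.residue_number - res_atoms[0].residue_number) == 1):
                    continue
                d = res_tree.query(a.position)[0]
                if not (shell[0] <= d <= shell[1]):
                    continue
                offset = axes.T @ (a.position - origin)
                stats.add((resname, key_class, a.atom_type or OTHER_TYPE), offset)
                if d <= pair_contact_distance:
                    src = res_tree.query(a.position)[1]
                    src_type = res_atoms[src].atom_type or OTHER_TYPE
                    stats.add_pair(src_type, a.atom_type or OTHER_TYPE)
    return stats


@dataclass
class InteractionPreferenceFilter:
    """Pairwise atom-type interaction preferences (log10 odds of the observed
    pair frequency against the product of marginals); pairs below the
    threshold are treated as non-interacting."""

    preferences: dict[tuple[str, str], float]
    threshold: float

    def preference(self, a: str, b: str) -> float | None:
        return self.preferences.get(tuple(sorted((a, b))))

    def interacting(self, a: str, b: str) -> bool:
        p = self.preference(a, b)
        return p is not None and p >= self.threshold


def build_interaction_filter(
    stats: ContactStatistics, threshold: float = -1.0
) -> InteractionPreferenceFilter:
    """Log-odds preferences from the harvested pair counts.

    preference(a, b) = log10( f_ab / (f_a * f_b * g) ), where f are observed
    pair and marginal frequencies and g = 2 for a != b (two ordered ways to
    draw an unordered heterotypic pair).  Unobserved pairs are
    non-interacting.
    """
    total = sum(stats.pair_counts.values())
    prefs: dict[tuple[str, str], float] = {}
    if total > 0:
        marg: dict[str, float] = {}
        for (a, b), n in stats.pair_counts.items():
            marg[a] = marg.get(a, 0.0) + n
            marg[b] = marg.get(b, 0.0) + n
        denom = 2.0 * total
        for (a, b), n in stats.pair_counts.items():
            fa = marg[a] / denom
            fb = marg[b] / denom
            expected = (2.0 if a != b else 1.0) * fa * fb
            prefs[(a, b)] = float(np.log10((n / total) / expected))
    return InteractionPreferenceFilter(preferences=prefs, threshold=threshold)


def _splat_trilinear(deposit: np.ndarray, grid: GridSpec, points: np.ndarray,
                     weights: np.ndarray) -> None:
    """Cloud-in-cell deposit: each weight is shared among the 8 cells
    surrounding its point, which keeps the accumulated field insensitive to
    sub-cell grid alignment."""
    if len(points) == 0:
        return
    rel = (np.asarray(points) - np.asarray(grid.origin)) / grid.spacing
    base = np.floor(rel).astype(int)
    frac = rel - base
    shape = np.asarray(grid.shape)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                idx = base + np.array([dx, dy, dz])
                inside = np.all((idx >= 0) & (idx < shape), axis=1)
                if not np.any(inside):
                    continue
                fx = frac[:, 0] if dx else 1.0 - frac[:, 0]
                fy = frac[:, 1] if dy else 1.0 - frac[:, 1]
                fz = frac[:, 2] if dz else 1.0 - frac[:, 2]
                w = weights * fx * fy * fz
                flat = np.ravel_multi_index(tuple(idx[inside].T), grid.shape)
                np.add.at(deposit, flat, w[inside])


@dataclass
class ProbabilityDensityMap:
    """Discrete probability map (sums to 1 over the grid) for one atom type
    around a fixed query structure; values below p_ref are stored as zero."""

    atom_type: str
    grid: GridSpec
    values: np.ndarray
    p_ref: float = DEFAULT_P_REF
    query_structure_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(self.grid.shape)
        if np.any(self.values < 0):
            raise ValueError("PDM values must be non-negative")
        if not 0 < self.p_ref < 1:
            raise ValueError("p_ref must lie in (0, 1)")

    def write(self, path: str) -> None:
        write_dx(path, self.grid, self.values,
                 comment=f"PDM {self.atom_type} query={self.query_structure_id}")


def build_pdm(
    query: Structure,
    target_atom_type: str,
    stats: ContactStatistics,
    preference_filter: InteractionPreferenceFilter | None = None,
    grid: GridSpec | None = None,
    p_ref: float = DEFAULT_P_REF,
    surface_cutoff: float = 0.05,
    sasa_points: int = 240,
    smoothing_sigma: float = 0.75,
) -> ProbabilityDensityMap:
    """Project class-conditioned histograms out of every surface residue of
    the query and normalise to a probability over the grid.

    Each covered residue deposits its histogram normalised to unit weight
    (so the map is invariant to the absolute size of the statistics
    library).  Deposits are blurred with an isotropic Gaussian kernel of
    ``smoothing_sigma`` Å (0 disables smoothing) so the binned statistics
    behave as a density rather than a point set.  Residue types/classes
    absent from the statistics contribute nothing; a query with no covered
    residue yields the uniform map.
    """
    protein = (query if all(a.atom_type for a in query.atoms)
               else assign_atom_types(query)).without_waters()
    if grid is None:
        grid = GridSpec.around(protein.coords, spacing=stats.spacing, margin=8.0)
    lo = protein.coords.min(axis=0)
    hi = protein.coords.max(axis=0)
    g_lo = np.asarray(grid.origin)
    g_hi = g_lo + grid.spacing * (np.asarray(grid.shape) - 1)
    if np.any(g_lo > lo) or np.any(g_hi < hi):
        raise ValueError("grid does not cover the query structure")

    rsasa = residue_sasa(protein, n_points=sasa_points)
    centers = stats.bin_centers()
    cx, cy, cz = np.meshgrid(centers, centers, centers, indexing="ij")
    local_cells = np.column_stack([cx.ravel(), cy.ravel(), cz.ravel()])
    deposit = np.zeros(grid.n_cells)
    covered = 0
    for chain, label, resname, res_atoms in protein.residues():
        if resname not in MAX_SASA:
            continue
        rel = rsasa.get((chain, label), 0.0) / MAX_SASA[resname]
        if rel < surface_cutoff:
            continue
        by = {a.name: a for a in res_atoms}
        frame = _residue_frame(by)
        if frame is None:
            continue
        conf = residue_conformation(protein, chain, label)
        hist = stats.histograms.get((resname, conf.class_id, target_atom_type))
        if hist is None or hist.sum() == 0:
            continue
        if preference_filter is not None:
            res_types = {a.atom_type for a in res_atoms if a.atom_type}
            if not any(preference_filter.interacting(t, target_atom_type)
                       for t in res_types):
                continue
        origin, axes = frame
        weights = hist.ravel().astype(float)
        nz = weights > 0
        world = local_cells[nz] @ axes.T + origin
        w = weights[nz] / weights.sum()
        _splat_trilinear(deposit, grid, world, w)
        covered += 1

    if smoothing_sigma > 0:
        deposit = gaussian_filter(deposit.reshape(grid.shape),
                                  sigma=smoothing_sigma / grid.spacing,
                                  mode="constant").ravel()
    total = deposit.sum()
    if total <= 0:
        if covered == 0:
            logger.warning("no query residue covered by the statistics; "
                           "returning the uniform map")
        values = np.full(grid.n_cells, 1.0 / grid.n_cells)
    else:
        values = deposit / total
        values[values < p_ref] = 0.0
        values = values / values.sum()
    return ProbabilityDensityMap(
        atom_type=target_atom_type, grid=grid, values=values.reshape(grid.shape),
        p_ref=p_ref, query_structure_id=protein.source,
    )


def build_water_pdm(
    query: Structure,
    stats: ContactStatistics,
    grid: GridSpec | None = None,
    p_ref: float = DEFAULT_P_REF,
    surface_cutoff: float = 0.05,
    sasa_points: int = 240,
) -> ProbabilityDensityMap:
    """Water-oxygen PDM around the query surface (hydration pattern)."""
    if WATER_O not in stats.target_types():
        logger.warning("statistics library carries no water contacts; the "
                       "hydration map will be uniform")
    return build_pdm(query, WATER_O, stats, preference_filter=None, grid=grid,
                     p_ref=p_ref, surface_cutoff=surface_cutoff,
                     sasa_points=sasa_points)


def average_pdm_over_atom(pdm: ProbabilityDensityMap, atom) -> float:
    """Mean map value over cells whose centers fall inside the atom's van der
    Waals sphere (AVE); zero when no cell center is enclosed."""
    grid = pdm.grid
    r = atom.vdw_radius
    pos = np.asarray(atom.position, dtype=float)
    lo = np.floor((pos - r - np.asarray(grid.origin)) / grid.spacing).astype(int)
    hi = np.ceil((pos + r - np.asarray(grid.origin)) / grid.spacing).astype(int)
    lo_c = np.maximum(lo, 0)
    hi_c = np.minimum(hi, np.asarray(grid.shape) - 1)
    if np.any(lo_c > hi_c):
        logger.warning("atom %s lies outside the PDM grid; AVE = 0", atom.name)
        return 0.0
    ax = [grid.origin[d] + grid.spacing * np.arange(lo_c[d], hi_c[d] + 1)
          for d in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = np.sum((pts - pos) ** 2, axis=1) <= r * r
    if not np.any(inside):
        return 0.0
    sub = pdm.values[lo_c[0]:hi_c[0] + 1, lo_c[1]:hi_c[1] + 1, lo_c[2]:hi_c[2] + 1]
    return float(sub.ravel()[inside].mean())


def hydration_pattern_score(
    s: Structure, water_map: ProbabilityDensityMap, shell: float = 4.0
) -> np.ndarray:
    """Per-atom hydration score: sum of water-map values within ``shell`` Å
    of the atom center."""
    centers = water_map.grid.cell_centers()
    vals = water_map.values.ravel()
    tree = cKDTree(centers)
    out = np.zeros(len(s))
    for i, a in enumerate(s.atoms):
        idx = tree.query_ball_point(a.position, r=shell)
        if idx:
            out[i] = vals[idx].sum()
    return out
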