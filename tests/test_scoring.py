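import numpy as np
import pandas as pd
import pytest

from cdrdesign import scoring
from cdrdesign.grids import GridSpec
from cdrdesign.pdm import ProbabilityDensityMap
from cdrdesign.phageprof import experimental_preference
from cdrdesign.scoring import (
    antigen_contact_map,
    contact_score,
    correlate_preferences,
    hydration_score,
    log_ratio,
    score_positions,
    structural_propensity,
)
from cdrdesign.structio import ATOM_TYPES, Structure, assign_atom_types
from cdrdesign.synthfix import make_toy_complex

P_REF = 1e-10


def _const_map(atom_type: str, value: float, n: int = 21) -> ProbabilityDensityMap:
    g = GridSpec(origin=(-10.0, -10.0, -10.0), spacing=1.0, shape=(n, n, n))
    return ProbabilityDensityMap(atom_type=atom_type, grid=g,
                                 values=np.full(g.shape, value))


class _FakePlacement:
    """Minimal placement stand-in: three typed atoms."""

    def __init__(self, types, positions=None):
        from cdrdesign.structio import AtomRecord
        positions = positions or [(0, 0, 0)] * len(types)
        self.atoms = [
            AtomRecord(serial=i + 1, name=f"C{i}", element="C",
                       residue_name="LIG", chain_id="A", residue_number=1,
                       position=np.asarray(p, dtype=float), vdw_radius=1.7,
                       atom_type=t)
            for i, (t, p) in enumerate(zip(types, positions))
        ]
        self.sidechain_atoms = self.atoms


class TestContactScore:
    def test_reference_level_scores_zero(self):
        maps = {"T1": _const_map("T1", P_REF)}
        pl = _FakePlacement(["T1", "T1"])
        assert contact_score(pl, maps, P_REF) == pytest.approx(0.0)

    def test_floored_zero_map_scores_zero(self):
        maps = {"T1": _const_map("T1", 0.0)}
        pl = _FakePlacement(["T1", "T1", "T1"])
        assert contact_score(pl, maps, P_REF) == pytest.approx(0.0)

    def test_hand_computed_three_atom_score(self):
        maps = {"A1": _const_map("A1", 1e-5), "A2": _const_map("A2", 1e-7),
                "A3": _const_map("A3", 0.0)}
        pl = _FakePlacement(["A1", "A2", "A3"])
        # log10(1e-5/1e-10) + log10(1e-7/1e-10) + 0 = 5 + 3 + 0
        assert contact_score(pl, maps, P_REF) == pytest.approx(8.0)

    def test_missing_map_raises_with_type_name(self):
        pl = _FakePlacement(["UNSEEN"])
        with pytest.raises(KeyError, match="UNSEEN"):
            contact_score(pl, {}, P_REF)

    def test_monotone_in_ave(self):
        lo = contact_score(_FakePlacement(["T1"]),
                           {"T1": _const_map("T1", 1e-6)}, P_REF)
        hi = contact_score(_FakePlacement(["T1"]),
                           {"T1": _const_map("T1", 1e-4)}, P_REF)
        assert hi > lo

    def test_ranking_invariant_to_p_ref(self):
        # same AVE profile, two reference probabilities: ordering across
        # amino-acid candidates must not change
        aves = {"a": [1e-4, 1e-6], "b": [1e-5, 1e-5], "c": [0.0, 1e-3]}
        for p_ref in (1e-10, 1e-12):
            scores = {}
            for name, vals in aves.items():
                scores[name] = sum(float(log_ratio(v, p_ref)) for v in vals)
            order = sorted(scores, key=scores.get)
            # difference of sums of log10(AVE) is p_ref independent for
            # non-floored values; the floored atom only adds a constant
            assert order == sorted(
                aves, key=lambda k: sum(np.log10(max(v, p_ref)) for v in aves[k]))


class TestHydrationScore:
    def _grids(self, n=5):
        shape = (n, n, n)
        return (np.zeros(shape), np.zeros(shape),
                np.zeros(shape, dtype=bool), np.zeros(shape, dtype=bool))

    def test_zero_maps_score_zero(self):
        ab, ag, mab, mag = self._grids()
        assert hydration_score(ab, ag, mab, mag, P_REF) == 0.0

    def test_mirror_symmetric_desolvation_terms_balance(self):
        ab, ag, mab, mag = self._grids()
        ab[0, 0, 0] = 1e-4
        ag[4, 4, 4] = 1e-4
        mab[4, 4, 4] = True   # antibody volume holds the antigen's water peak
        mag[0, 0, 0] = True
        y = hydration_score(ab, ag, mab, mag, P_REF)
        # both desolvation sums equal log10(1e-4/1e-10) = 6, no overlap
        assert y == pytest.approx(-12.0)

    def test_matches_brute_force_four_sum(self, rng):
        shape = (5, 5, 5)
        ab = rng.random(shape) * 1e-4
        ag = rng.random(shape) * 1e-4
        ab[ab < 3e-5] = 0.0
        ag[ag < 3e-5] = 0.0
        mab = rng.random(shape) < 0.2
        mag = rng.random(shape) < 0.2
        got = hydration_score(ab, ag, mab, mag, P_REF)
        lab = np.log10(np.maximum(ab, P_REF) / P_REF)
        lag = np.log10(np.maximum(ag, P_REF) / P_REF)
        expected = 0.0
        for idx in np.ndindex(shape):
            if mag[idx]:
                expected -= lab[idx]
            if mab[idx]:
                expected -= lag[idx]
            if ab[idx] > P_REF and ag[idx] > P_REF and not mab[idx] and not mag[idx]:
                expected += lab[idx] + lag[idx]
        assert got == pytest.approx(expected)

    def test_grid_mismatch_rejected(self):
        ab, ag, mab, mag = self._grids()
        with pytest.raises(ValueError):
            hydration_score(ab[:3], ag, mab, mag, P_REF)


class TestStructuralPropensity:
    def test_background_frequency_scores_zero(self):
        p = np.full(20, 0.05)
        counts = 100 * p
        z = structural_propensity(counts, 100, p)
        assert np.allclose(z, 0.0, atol=1e-12)

    def test_absent_type_scores_negative(self):
        p = np.full(20, 0.05)
        counts = np.full(20, 5.0)
        counts[0] = 0.0
        counts[1] = 10.0
        z = structural_propensity(counts, 100, p)
        assert z[0] < 0 < z[1]

    def test_hand_computed_value_with_gaps(self):
        # M = 16 rows, B = 4, one type observed 8 times, others absent,
        # 4 gap rows: M' = 12, B' = 4 + 16 - 12 = 8
        p = np.full(20, 0.05)
        counts = np.zeros(20)
        counts[3] = 8.0
        counts[5] = 4.0
        z = structural_propensity(counts, 16, p, b=4.0)
        expected = 2 * np.log2(((8 + 8 * 0.05) / (12 + 8)) / 0.05)
        assert z[3] == pytest.approx(expected)

    def test_reduces_to_experimental_preference_without_gaps(self, rng):
        # no gaps and B = sqrt(M): the propensity equals the half-bit
        # experimental preference form
        p = rng.dirichlet(np.ones(20))
        m = 36
        counts = rng.multinomial(m, p)
        z = structural_propensity(counts, m, p)
        w, _ = experimental_preference(counts, m, p)
        assert np.allclose(z, w, atol=1e-12)

    def test_zero_background_with_count_rejected(self):
        p = np.full(20, 0.05)
        p[0] = 0.0
        counts = np.zeros(20)
        counts[0] = 1.0
        with pytest.raises(ValueError):
            structural_propensity(counts, 10, p)


@pytest.fixture(scope="module")
def scored_toy():
    cplx, _ = make_toy_complex(seed=41, n_residues_a=4, n_residues_b=4,
                               interface_gap=4.0)
    from cdrdesign.confrot import build_alanine_scaffold, default_rotamer_library
    from cdrdesign.pdm import build_pdm, collect_interior_contacts
    from cdrdesign.synthfix import make_structure_library

    lib, _ = make_structure_library(seed=42, n_structures=3)
    stats = collect_interior_contacts(lib, burial_cutoff=2.0)
    antigen = assign_atom_types(cplx.chains(["B"]))
    grid = GridSpec.around(cplx.coords, spacing=1.0, margin=8.0)
    maps = {t: build_pdm(antigen, t, stats, grid=grid, surface_cutoff=0.0)
            for t in ATOM_TYPES}
    scaffold = build_alanine_scaffold(cplx.chains(["A"]), [("A", "2")])
    rot = default_rotamer_library()
    table = score_positions(scaffold, antigen, [("A", "2")], maps, rot,
                            types="AGSLW")
    return cplx, scaffold, antigen, maps, rot, table


class TestScorePositions:
    def test_single_rotamer_type_equals_its_rotamer_score(self, scored_toy):
        _, _, _, _, _, table = scored_toy
        row = table[table["aa"] == "A"].iloc[0]
        assert row["n_rotamers"] == 1
        assert row["X"] == pytest.approx(row["rotamer_X"][0])

    def test_aggregation_is_max_over_rotamers(self, scored_toy):
        _, _, _, _, _, table = scored_toy
        for _, row in table.iterrows():
            if row["rotamer_X"]:
                assert row["X"] == pytest.approx(max(row["rotamer_X"]))

    def test_matches_independent_per_rotamer_recomputation(self, scored_toy):
        cplx, scaffold, antigen, maps, rot, table = scored_toy
        from cdrdesign.confrot import enumerate_placements
        for _, row in table.iterrows():
            pls = enumerate_placements(scaffold, ("A", "2"), row["aa"], rot)
            xs = []
            for pl in pls:
                pl.atoms = assign_atom_types(Structure(pl.atoms)).atoms
                xs.append(contact_score(pl, maps, P_REF))
            assert row["X"] == pytest.approx(max(xs) if xs else 0.0)

    def test_removed_antigen_zeroes_x(self, scored_toy):
        cplx, scaffold, antigen, _, rot, _ = scored_toy
        zero_maps = {t: _const_map(t, 0.0, n=41) for t in ATOM_TYPES}
        table = score_positions(scaffold, antigen, [("A", "2")], zero_maps,
                                rot, types="ASL")
        assert np.allclose(table["X"], 0.0)


class TestAntigenContactMap:
    def test_zero_maps_give_zero_strength(self, scored_toy):
        cplx, scaffold, antigen, _, rot, _ = scored_toy
        from cdrdesign.confrot import enumerate_placements
        pls = enumerate_placements(scaffold, ("A", "2"), "S", rot)
        for pl in pls:
            pl.atoms = assign_atom_types(Structure(pl.atoms)).atoms
        zero_maps = {t: _const_map(t, 0.0, n=41) for t in ATOM_TYPES}
        strengths = antigen_contact_map(antigen, [pls], zero_maps)
        assert np.allclose(strengths, 0.0)

    def test_identical_models_average_to_single_model(self, scored_toy):
        cplx, scaffold, antigen, maps, rot, _ = scored_toy
        from cdrdesign.confrot import enumerate_placements
        pls = enumerate_placements(scaffold, ("A", "2"), "S", rot)
        for pl in pls:
            pl.atoms = assign_atom_types(Structure(pl.atoms)).atoms
        one = antigen_contact_map(antigen, [pls], maps)
        two = antigen_contact_map(antigen, [pls, pls], maps)
        assert np.allclose(one, two)

    def test_requires_at_least_one_model(self, scored_toy):
        _, _, antigen, maps, _, _ = scored_toy
        with pytest.raises(ValueError):
            antigen_contact_map(antigen, [], maps)


class TestCorrelations:
    def _tables(self, rng):
        rows = []
        for pos in ("10", "11"):
            for aa in "ACDEFGHIKLMNPQRSTVWY":
                rows.append({"position": pos, "aa": aa,
                             "X": rng.normal(), "Y": rng.normal(),
                             "Z": rng.normal()})
        score = pd.DataFrame(rows)
        pref = score[["position", "aa"]].copy()
        return score, pref

    def test_perfectly_correlated_terms(self, rng):
        score, pref = self._tables(rng)
        pref["W"] = score["X"]
        cc = correlate_preferences(score, pref)
        assert np.allclose(cc["cc_WX"], 1.0)
        score2 = score.copy()
        pref2 = pref.copy()
        pref2["W"] = -score2["Y"]
        cc2 = correlate_preferences(score2, pref2)
        assert np.allclose(cc2["cc_WY"], -1.0)

    def test_zero_variance_reported_missing(self, rng):
        score, pref = self._tables(rng)
        score["Z"] = 1.0
        pref["W"] = score["X"]
        cc = correlate_preferences(score, pref)
        assert cc["cc_WZ"].isna().all()

    def test_too_few_common_types_rejected(self, rng):
        score, pref = self._tables(rng)
        pref = pref.iloc[:2].copy()
        pref["W"] = 1.0
        with pytest.raises(ValueError):
            correlate_preferences(score, pref)
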