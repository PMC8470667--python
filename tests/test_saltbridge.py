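"""Salt-bridge detection, lifetimes, categories and densities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cypflex as cf
from cypflex.errors import ConfigError
from cypflex.saltbridge import (
    ACIDIC_MEMBER_ATOMS,
    BASIC_MEMBER_ATOMS,
    density_distinct,
)


def brute_force_bridges(coords, groups, cutoff):
    """Independent oracle: double loop over every O--N atom cross pair."""
    pairs = set()
    for ga in groups:
        if ga.sign != "acidic":
            continue
        for gb in groups:
            if gb.sign != "basic":
                continue
            for i in ga.member_atoms:
                for j in gb.member_atoms:
                    if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                        pairs.add((ga.residue, gb.residue))
    return pairs


def random_group_fixture(rng, n_groups=50, box=30.0):
    """Random charged groups scattered in a box, as a bare coordinate set."""
    names = ["ASP", "GLU", "LYS", "ARG", "HIS"]
    coords = []
    groups = []
    for k in range(n_groups):
        res = names[rng.integers(len(names))]
        if res in ACIDIC_MEMBER_ATOMS:
            atom_names, sign = ACIDIC_MEMBER_ATOMS[res], "acidic"
        else:
            atom_names, sign = BASIC_MEMBER_ATOMS[res], "basic"
        center = rng.uniform(0, box, 3)
        members = []
        for _ in atom_names:
            members.append(len(coords))
            coords.append(center + rng.normal(0, 1.0, 3))
        groups.append(
            cf.ChargedGroup(("A", k + 1, ""), res, sign, tuple(members))
        )
    return np.asarray(coords), groups


class TestEnumerateChargedGroups:
    def test_toy_chain_groups(self):
        structure = cf.make_toy_structure(
            cf.ToyProteinSpec(n_residues=3, placements=((1, "ASP"), (3, "LYS")))
        )
        groups = cf.enumerate_charged_groups(structure)
        signs = sorted(g.sign for g in groups)
        assert signs == ["acidic", "basic"]
        acid = next(g for g in groups if g.sign == "acidic")
        assert {structure.atom_name[i] for i in acid.member_atoms} == {"OD1", "OD2"}

    def test_his_excluded_on_request(self):
        structure = cf.make_toy_structure(
            cf.ToyProteinSpec(n_residues=4, placements=((1, "ASP"), (4, "HIS")))
        )
        with_his = cf.enumerate_charged_groups(structure, include_his=True)
        without = cf.enumerate_charged_groups(structure, include_his=False)
        assert len(with_his) == 2 and len(without) == 1

    def test_residue_missing_member_atoms_skipped(self, caplog):
        structure = cf.make_toy_structure(
            cf.ToyProteinSpec(n_residues=3, placements=((1, "ASP"), (3, "LYS")))
        )
        # drop the carboxylate oxygens
        keep = [i for i in range(structure.n_atoms)
                if structure.atom_name[i] not in ("OD1", "OD2")]
        pruned = structure.subset(np.array(keep))
        with caplog.at_level("WARNING"):
            groups = cf.enumerate_charged_groups(pruned)
        assert [g.sign for g in groups] == ["basic"]
        assert "skipped" in caplog.text


class TestDetectBridgesFrame:
    def _two_residue_fixture(self, separation):
        coords = np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]])
        groups = [
            cf.ChargedGroup(("A", 1, ""), "ASP", "acidic", (0,)),
            cf.ChargedGroup(("A", 2, ""), "LYS", "basic", (1,)),
        ]
        return coords, groups

    def test_contact_within_cutoff(self):
        coords, groups = self._two_residue_fixture(3.0)
        assert cf.detect_bridges_frame(coords, groups) == {
            (("A", 1, ""), ("A", 2, ""))
        }

    def test_beyond_cutoff_excluded(self):
        coords, groups = self._two_residue_fixture(3.30)
        assert cf.detect_bridges_frame(coords, groups) == set()

    def test_cutoff_boundary_inclusive(self):
        coords, groups = self._two_residue_fixture(3.2)
        assert len(cf.detect_bridges_frame(coords, groups)) == 1

    def test_empty_groups(self):
        assert cf.detect_bridges_frame(np.zeros((1, 3)), []) == set()

    def test_matches_brute_force_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            coords, groups = random_group_fixture(rng)
            got = cf.detect_bridges_frame(coords, groups, cutoff=3.2)
            want = brute_force_bridges(coords, groups, 3.2)
            assert got == want


class TestComputeRecords:
    def _bridged(self, occupancy, n_frames, seed=0, n_residues=12):
        spec = cf.ToyProteinSpec(
            n_residues=n_residues,
            placements=((1, "ASP"), (2, "LYS")),
            bridges=(cf.BridgeSpec(1, 2, occupancy),),
            seed=seed,
        )
        structure, traj, realized = cf.make_toy_trajectory(spec, n_frames)
        return traj, realized[(1, 2)]

    def test_lifetime_fraction_arithmetic(self):
        traj, realized = self._bridged(0.6, 5, seed=7)
        summary = cf.compute_records(traj)
        assert len(summary.records) == (1 if realized.any() else 0)
        if summary.records:
            rec = summary.records[0]
            assert rec.lifetime == pytest.approx(realized.mean())
            assert rec.lifetime_ns == pytest.approx(
                rec.lifetime * traj.total_time_ns
            )

    def test_never_formed_pair_absent(self):
        traj, _ = self._bridged(0.0, 50)
        assert cf.compute_records(traj).records == []

    @pytest.mark.parametrize(
        "occupancy,category", [(0.01, "short"), (0.10, "medium"), (0.50, "long")]
    )
    def test_programmed_occupancy_in_binomial_ci(self, occupancy, category):
        from scipy import stats

        n = 10_000
        traj, realized = self._bridged(occupancy, n, seed=int(occupancy * 1000))
        rec = cf.compute_records(traj).records[0]
        lo, hi = stats.binom.interval(0.99, n, occupancy)
        assert lo / n <= rec.lifetime <= hi / n
        assert rec.category() == category
        assert rec.lifetime == pytest.approx(realized.mean())

    def test_category_boundaries_inclusive_medium(self):
        formed = np.zeros(100, bool)
        formed[:2] = True  # exactly 2%
        rec = cf.SaltBridgeRecord(("A", 1, ""), ("A", 2, ""), "ASP", "LYS",
                                  formed, 1.0)
        assert rec.category() == "medium"
        formed20 = np.zeros(100, bool)
        formed20[:20] = True  # exactly 20%
        rec20 = cf.SaltBridgeRecord(("A", 1, ""), ("A", 2, ""), "ASP", "LYS",
                                    formed20, 1.0)
        assert rec20.category() == "medium"

    def test_lifetime_invariant_to_frame_permutation(self):
        traj, _ = self._bridged(0.4, 200, seed=3)
        perm = np.random.default_rng(0).permutation(traj.n_frames)
        shuffled = cf.Trajectory(topology=traj.topology,
                                 frames=traj.frames[perm], dt=traj.dt)
        a = cf.compute_records(traj)
        b = cf.compute_records(shuffled)
        assert a.records[0].lifetime == b.records[0].lifetime
        np.testing.assert_array_equal(
            np.sort(a.density_series), np.sort(b.density_series)
        )
        np.testing.assert_array_equal(a.density_series[perm], b.density_series)

    def test_frame_doubling_preserves_lifetimes(self):
        traj, _ = self._bridged(0.3, 150, seed=5)
        doubled = cf.Trajectory(
            topology=traj.topology,
            frames=np.repeat(traj.frames, 2, axis=0),
            dt=traj.dt,
        )
        a = cf.compute_records(traj).records[0]
        b = cf.compute_records(doubled).records[0]
        assert a.lifetime == pytest.approx(b.lifetime)

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(11)
        structure = cf.make_toy_structure(
            cf.ToyProteinSpec(
                n_residues=16,
                placements=((1, "ASP"), (4, "LYS"), (8, "GLU"), (12, "ARG")),
            )
        )
        traj = cf.make_gaussian_trajectory(structure, 1.2, 100, seed=13)
        small = cf.compute_records(traj, cutoff=3.2)
        large = cf.compute_records(traj, cutoff=4.5)
        small_pairs = {(r.acidic, r.basic): r.lifetime for r in small.records}
        large_pairs = {(r.acidic, r.basic): r.lifetime for r in large.records}
        assert set(small_pairs) <= set(large_pairs)
        for pair, lt in small_pairs.items():
            assert large_pairs[pair] >= lt

    def test_category_counts_sum_to_distinct(self):
        traj, _ = self._bridged(0.5, 300, seed=9)
        summary = cf.compute_records(traj)
        assert sum(summary.counts_by_category.values()) == summary.n_distinct

    def test_density_series_bounded_by_distinct(self):
        traj, _ = self._bridged(0.7, 300, seed=2)
        summary = cf.compute_records(traj)
        assert np.all(summary.density_series <= summary.density_distinct + 1e-12)


class TestDensity:
    def test_per_hundred_arithmetic(self):
        assert density_distinct(10, 200) == 5.0

    def test_zero_pairs(self):
        assert density_distinct(0, 200) == 0.0

    def test_rounding_to_one_decimal(self):
        # 100 * 30 / 405 = 7.407... -> 7.4
        assert density_distinct(30, 405) == 7.4

    def test_zero_residues_error(self):
        with pytest.raises(ValueError):
            density_distinct(5, 0)


class TestFilterRegion:
    def _summary(self):
        spec = cf.ToyProteinSpec(
            n_residues=40,
            placements=((5, "ASP"), (6, "LYS"), (25, "GLU"), (26, "ARG")),
            bridges=(cf.BridgeSpec(5, 6, 1.0), cf.BridgeSpec(25, 26, 1.0)),
        )
        _, traj, _ = cf.make_toy_trajectory(spec, 10)
        return cf.compute_records(traj)

    def test_keeps_pairs_touching_region(self):
        summary = self._summary()
        filtered = cf.filter_region(summary, [(1, 10)])
        assert [r.acidic[1] for r in filtered.records] == [5]
        assert filtered.n_residues == summary.n_residues  # denominator unchanged

    def test_empty_region_list(self):
        assert cf.filter_region(self._summary(), []).records == []

    def test_full_cover_is_identity_on_records(self):
        summary = self._summary()
        filtered = cf.filter_region(summary, [(1, 40)])
        assert len(filtered.records) == len(summary.records)

    def test_malformed_range(self):
        with pytest.raises(ConfigError):
            cf.filter_region(self._summary(), [(10, 5)])


@given(n_pairs=st.integers(0, 60), n_residues=st.integers(1, 600))
@settings(deadline=None, max_examples=50)
def test_density_formula_property(n_pairs, n_residues):
    value = density_distinct(n_pairs, n_residues)
    assert value == pytest.approx(100.0 * n_pairs / n_residues, abs=0.0501)
    assert value >= 0
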