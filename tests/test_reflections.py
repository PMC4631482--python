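import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meshmx.reflections import (
    ReflectionFileError,
    ReflectionSet,
    SymmetrySetting,
    WedgeParams,
    generate_ground_truth,
    preset_setting,
    read_reflections,
    reduce_array_to_asu,
    reduce_to_asu,
    simulate_partial_dataset,
    write_reflections,
)

PRESETS = ["P1", "P2", "P4", "H3", "P6"]


class TestSymmetrySetting:
    @pytest.mark.parametrize("name", PRESETS)
    def test_presets_are_closed_groups(self, name):
        preset_setting(name)  # constructor runs the closure check

    def test_open_operator_list_rejected(self):
        r4 = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]])
        with pytest.raises(ValueError, match="closed"):
            SymmetrySetting(name="bad", cell=(10, 10, 10, 90, 90, 90),
                            operators=(np.eye(3, dtype=int), r4))

    def test_missing_identity_rejected(self):
        neg = -np.eye(3, dtype=int)
        with pytest.raises(ValueError, match="identity"):
            SymmetrySetting(name="bad", cell=(10, 10, 10, 90, 90, 90),
                            operators=(neg,))

    def test_d_spacing_matches_gemmi(self):
        import gemmi

        cell = (23.0, 31.0, 47.0, 85.0, 95.0, 103.0)
        setting = preset_setting("P1", cell=cell)
        gcell = gemmi.UnitCell(*cell)
        for hkl in [(1, 0, 0), (0, 2, 0), (3, -1, 2), (-2, 5, -4)]:
            assert setting.d_spacing(hkl) == pytest.approx(
                gcell.calculate_d(hkl), rel=1e-9
            )


class TestAsuReduction:
    def test_p1_without_friedel_is_identity(self):
        setting = preset_setting("P1", friedel=False)
        assert reduce_to_asu((2, -3, 5), setting) == (2, -3, 5)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        name=st.sampled_from(PRESETS),
        hkl=st.tuples(*[st.integers(-6, 6)] * 3),
        op_i=st.integers(0, 11),
    )
    def test_orbit_invariance_and_idempotence(self, name, hkl, op_i):
        setting = preset_setting(name)
        ops = setting.operators
        g = ops[op_i % len(ops)]
        image = tuple(np.asarray(g, int) @ np.asarray(hkl))
        assert reduce_to_asu(image, setting) == reduce_to_asu(hkl, setting)
        rep = reduce_to_asu(hkl, setting)
        assert reduce_to_asu(rep, setting) == rep

    @pytest.mark.parametrize("name", PRESETS)
    def test_friedel_mates_reduce_identically(self, name):
        setting = preset_setting(name, friedel=True)
        rng = np.random.default_rng(0)
        hkl = rng.integers(-5, 6, (50, 3))
        assert np.array_equal(
            reduce_array_to_asu(hkl, setting), reduce_array_to_asu(-hkl, setting)
        )

    def test_orbit_sizes_match_brute_force(self):
        setting = preset_setting("P4", friedel=True)
        block = np.array(
            [(h, k, l) for h in range(-2, 3) for k in range(-2, 3) for l in range(-2, 3)]
        )
        # brute-force orbit enumeration
        orbits = {}
        for hkl in map(tuple, block):
            members = set()
            for op in setting.operators:
                im = tuple(np.asarray(op, int) @ hkl)
                members.add(im)
                members.add(tuple(-np.asarray(im)))
            orbits[frozenset(members)] = members
        reps = {tuple(r) for r in reduce_array_to_asu(block, setting)}
        assert len(reps) == len(orbits)
        for members in orbits.values():
            in_block = [m for m in members if m in set(map(tuple, block))]
            assert len({reduce_to_asu(m, setting) for m in in_block}) == 1


class TestGroundTruth:
    def test_unique_count_matches_brute_force(self):
        setting = preset_setting("P2", cell=(12.0, 13.0, 14.0, 90.0, 100.0, 90.0))
        truth = generate_ground_truth(setting, 3.0, seed=0)
        lim = 6
        brute = set()
        for h in range(-lim, lim + 1):
            for k in range(-lim, lim + 1):
                for l in range(-lim, lim + 1):
                    if (h, k, l) == (0, 0, 0):
                        continue
                    if setting.d_spacing((h, k, l)) >= 3.0:
                        brute.add(reduce_to_asu((h, k, l), setting))
        assert {tuple(r) for r in truth.hkl} == brute

    def test_loosening_dmin_gives_superset(self):
        setting = preset_setting("P4")
        tight = generate_ground_truth(setting, 3.5, seed=1)
        loose = generate_ground_truth(setting, 3.0, seed=1)
        assert {tuple(r) for r in tight.hkl} <= {tuple(r) for r in loose.hkl}

    def test_seeded_reproducibility(self):
        setting = preset_setting("P4")
        a = generate_ground_truth(setting, 3.0, seed=5)
        b = generate_ground_truth(setting, 3.0, seed=5)
        assert np.array_equal(a.hkl, b.hkl)
        assert np.array_equal(a.intensity, b.intensity)


@pytest.fixture(scope="module")
def truth():
    return generate_ground_truth(preset_setting("P4"), 3.0, seed=2)


class TestPartialSimulation:

    def test_identity_limit_reproduces_truth(self, truth):
        rset = simulate_partial_dataset(
            truth, WedgeParams(fraction=1.0, noise_frac=0.0, seed=0)
        )
        assert np.array_equal(np.sort(rset.hkl, axis=0), np.sort(truth.hkl, axis=0))
        lookup = truth.as_dict()
        for hkl, i_obs in zip(rset.hkl, rset.intensity):
            assert i_obs == pytest.approx(lookup[tuple(hkl)], rel=1e-12)

    def test_same_class_cc_approaches_one_as_noise_vanishes(self, truth):
        from meshmx.clustering import pairwise_cc

        ccs = []
        for noise in (0.3, 0.01):
            sets = [
                simulate_partial_dataset(
                    truth, WedgeParams(fraction=0.6, noise_frac=noise, seed=s)
                )
                for s in (1, 2)
            ]
            ccs.append(pairwise_cc(sets).cc[0, 1])
        assert ccs[1] > ccs[0]
        assert ccs[1] > 0.999

    def test_reindex_round_trip(self, truth):
        op = truth.setting.ambiguity_ops[0]
        flipped = simulate_partial_dataset(
            truth, WedgeParams(fraction=0.5, noise_frac=0.0, reindex_op=op, seed=3)
        )
        # the swap operator is its own inverse; mapping back restores indices
        back = reduce_array_to_asu(flipped.hkl @ np.asarray(op).T, truth.setting)
        plain = simulate_partial_dataset(
            truth, WedgeParams(fraction=0.5, noise_frac=0.0, seed=3)
        )
        assert np.array_equal(np.sort(back, axis=0), np.sort(plain.hkl, axis=0))

    def test_mean_model_within_standard_errors(self, truth):
        # mean(I_obs)/I_true at fixed hkl ≈ scale_k · exp(-2 b_rel s²)
        params = dict(fraction=1.0, scale_k=1.7, b_rel=3.0, noise_frac=0.2)
        n_rep = 60
        acc = {}
        for s in range(n_rep):
            rset = simulate_partial_dataset(truth, WedgeParams(**params, seed=s))
            for hkl, i_obs in zip(map(tuple, rset.hkl), rset.intensity):
                acc.setdefault(hkl, []).append(i_obs)
        lookup = truth.as_dict()
        rng = np.random.default_rng(0)
        keys = list(acc)
        for hkl in [keys[i] for i in rng.choice(len(keys), 5, replace=False)]:
            i_true = lookup[hkl]
            d = truth.setting.d_spacing(np.array(hkl))
            expect = 1.7 * np.exp(-2 * 3.0 * (0.5 / d) ** 2) * i_true
            se = 0.2 * i_true / np.sqrt(n_rep)
            assert np.mean(acc[hkl]) == pytest.approx(expect, abs=3 * se)

    def test_sigma_floor_positive_even_without_noise(self, truth):
        rset = simulate_partial_dataset(
            truth, WedgeParams(fraction=0.3, noise_frac=0.0, seed=4)
        )
        assert np.all(rset.sigma > 0)


class TestReflectionIO:
    @pytest.fixture()
    def rset(self):
        truth = generate_ground_truth(preset_setting("H3"), 3.5, seed=9)
        return simulate_partial_dataset(
            truth, WedgeParams(fraction=0.5, noise_frac=0.1, seed=9), label="wedge_a"
        )

    def test_round_trip(self, rset, tmp_path):
        path = tmp_path / "a.hkl"
        write_reflections(rset, path)
        back = read_reflections(path)
        assert back.label == "wedge_a"
        assert back.setting.sg_number == rset.setting.sg_number
        assert back.setting.cell == pytest.approx(rset.setting.cell, abs=1e-3)
        assert np.array_equal(back.hkl, rset.hkl)
        assert np.allclose(back.intensity, rset.intensity, rtol=1e-5)
        assert np.allclose(back.sigma, rset.sigma, rtol=1e-5)

    def test_nonpositive_sigma_rejected_with_line_number(self, rset, tmp_path):
        path = tmp_path / "bad.hkl"
        write_reflections(rset, path)
        lines = path.read_text().splitlines()
        first_data = next(i for i, ln in enumerate(lines) if not ln.startswith("!"))
        parts = lines[first_data].split()
        parts[4] = "0.0"
        lines[first_data] = " ".join(parts)
        path.write_text("\n".join(lines))
        with pytest.raises(ReflectionFileError, match=f":{first_data + 1}:"):
            read_reflections(path)

    def test_malformed_row_reports_line(self, rset, tmp_path):
        path = tmp_path / "bad2.hkl"
        write_reflections(rset, path)
        lines = path.read_text().splitlines()
        first_data = next(i for i, ln in enumerate(lines) if not ln.startswith("!"))
        lines[first_data] = "1 2 three 4 5"
        path.write_text("\n".join(lines))
        with pytest.raises(ReflectionFileError, match=f":{first_data + 1}:"):
            read_reflections(path)

    def test_duplicate_free_after_asu_reduction(self, rset):
        asu = reduce_array_to_asu(rset.hkl, rset.setting)
        assert len(np.unique(asu, axis=0)) == len(asu)

    def test_direct_sigma_validation(self):
        with pytest.raises(ValueError):
            ReflectionSet(
                hkl=[[1, 0, 0]], intensity=[1.0], sigma=[0.0],
                setting=preset_setting("P1"),
            )
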