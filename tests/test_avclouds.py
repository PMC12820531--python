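"""Accessible-volume dye clouds: geometry oracles, Rmp, and predicted <E>."""

import numpy as np
import pytest

from repstates.avclouds import (AVCloud, DyeParams, Structure,
                                av_fret_efficiency, compute_av,
                                read_structure, rmp, state_agreement)


def toy_structure(coords, elements=None):
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    return Structure(
        coords=coords,
        elements=np.array(elements if elements else ["C"] * n),
        chain_ids=np.array(["A"] * n),
        res_ids=np.arange(1, n + 1),
        atom_names=np.array(["CA"] * n),
    )


SMALL_DYE = DyeParams(linker_length=10.0, linker_width=1.0,
                      dye_radii=(0.5, 0.5, 0.5), r0=50.0, grid_spacing=1.0)


class TestReadStructure:
    PDB_TEXT = (
        "ATOM      1  CA  ALA A  97      10.000  10.000  10.000  1.00  0.00           C\n"
        "ATOM      2  CB  ALA A  97      11.500  10.000  10.000  1.00  0.00           C\n"
        "ATOM      3  CA  GLY A  98      13.000  11.000  10.000  1.00  0.00           C\n"
        "END\n"
    )

    def test_three_atom_round_trip(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(self.PDB_TEXT)
        s = read_structure(str(p))
        assert s.coords.shape == (3, 3)
        assert np.allclose(s.coords[0], [10.0, 10.0, 10.0])
        assert s.atom_index("A", 97, "CB") == 1

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        text = (
            "ATOM      1  CA AALA A   1      10.000  10.000  10.000  0.30  0.00           C\n"
            "ATOM      2  CA BALA A   1      20.000  10.000  10.000  0.70  0.00           C\n"
            "END\n"
        )
        p = tmp_path / "alt.pdb"
        p.write_text(text)
        s = read_structure(str(p))
        assert s.coords.shape == (1, 3)
        assert s.coords[0, 0] == pytest.approx(20.0)

    def test_missing_attachment_named_in_error(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(self.PDB_TEXT)
        s = read_structure(str(p))
        with pytest.raises(KeyError, match="473"):
            s.atom_index("A", 473, "CB")


class TestComputeAV:
    def test_isolated_attachment_fills_ball(self):
        s = toy_structure([[0.0, 0.0, 0.0]])
        cloud = compute_av(s, 0, SMALL_DYE)
        # symmetric free cloud: mean position on the attachment atom
        assert np.linalg.norm(cloud.mean_position - 0.0) < SMALL_DYE.grid_spacing
        # all positions within the linker length (grid metric overhead ~ 8%)
        d = np.linalg.norm(cloud.positions, axis=1)
        assert d.max() <= SMALL_DYE.linker_length + 1e-9

    def test_half_ball_centroid_offset(self):
        # Dense wall at z = -1.7 (atom radius 1.2, clearance 0.5): the free
        # half-space is z >= 0 and the half-ball centroid sits at 3R/8.
        g = np.arange(-14, 15, 1.0)
        wall = [[x, y, -1.7] for x in g for y in g]
        s = toy_structure([[0.0, 0.0, 0.0]] + wall)
        cloud = compute_av(s, 0, SMALL_DYE)
        assert cloud.mean_position[2] == pytest.approx(3 * 10.0 / 8, abs=0.75)
        assert abs(cloud.mean_position[0]) < 0.3
        assert np.all(cloud.positions[:, 2] >= -1e-9)

    def test_against_brute_force_clash_check(self):
        rng = np.random.default_rng(5)
        atoms = rng.uniform(-6, 6, size=(10, 3))
        s = toy_structure(np.vstack([[0.0, 0.0, 0.0], atoms]))
        cloud = compute_av(s, 0, SMALL_DYE)
        radii = s.radii[1:]
        # every reported position must be clash-free for the dye radius
        for p in cloud.positions:
            clear = np.min(np.linalg.norm(atoms - p, axis=1) - radii)
            assert clear >= 0.5 - 1e-9
        # every clash-free grid point well inside the linker range (with
        # clearance for the path) must be in the cloud
        pos_set = {tuple(np.round(p, 6)) for p in cloud.positions}

        def line_clear(p, margin):
            # straight-path clearance from the attachment to p
            ts = np.linspace(0, 1, int(np.linalg.norm(p) * 4) + 2)
            for t in ts:
                q = t * p
                if np.min(np.linalg.norm(atoms - q, axis=1) - radii) < margin:
                    return False
            return True

        g = np.arange(-10, 11, 1.0)
        missed = 0
        checked = 0
        for x in g:
            for y in g:
                for z in g:
                    p = np.array([x, y, z])
                    # inside the linker range even with ~8% grid-metric
                    # overhead, and reachable along the straight line
                    if np.linalg.norm(p) > 0.9 * SMALL_DYE.linker_length:
                        continue
                    if np.min(np.linalg.norm(atoms - p, axis=1) - radii) < 0.5:
                        continue
                    if not line_clear(p, 1.0):
                        continue
                    checked += 1
                    missed += tuple(np.round(p, 6)) not in pos_set
        assert checked > 100
        assert missed == 0

    def test_buried_attachment_raises(self):
        g = np.arange(-4, 5, 1.0)
        cage = [[x, y, z] for x in g for y in g for z in g
                if max(abs(x), abs(y), abs(z)) >= 2]
        s = toy_structure([[0.0, 0.0, 0.0]] + cage)
        dye = DyeParams(linker_length=8.0, linker_width=3.0,
                        dye_radii=(2.0, 2.0, 2.0), r0=50.0, grid_spacing=1.0)
        with pytest.raises(ValueError, match="empty accessible volume"):
            compute_av(s, 0, dye)

    def test_cloud_shrinks_with_added_obstacles(self):
        s0 = toy_structure([[0.0, 0.0, 0.0]])
        c0 = compute_av(s0, 0, SMALL_DYE)
        s1 = toy_structure([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0], [0.0, 4.0, 0.0]])
        c1 = compute_av(s1, 0, SMALL_DYE)
        assert c1.positions.shape[0] < c0.positions.shape[0]


class TestRmpAndE:
    def _free_cloud(self, center):
        s = toy_structure([center])
        return compute_av(s, 0, SMALL_DYE)

    def test_identical_clouds_zero_rmp(self):
        c = self._free_cloud([0.0, 0.0, 0.0])
        assert rmp(c, c) == 0.0

    def test_translation_gives_distance(self):
        c = self._free_cloud([0.0, 0.0, 0.0])
        assert rmp(c, c.translated([30.0, 0.0, 0.0])) == pytest.approx(30.0)

    def test_rmp_invariant_under_rigid_motion(self):
        coords = [[0.0, 0.0, 0.0], [3.0, 2.0, 1.0], [40.0, 5.0, 0.0]]
        s = toy_structure(coords)
        a = compute_av(s, 0, SMALL_DYE)
        b = compute_av(s, 2, SMALL_DYE)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        s2 = s.transformed(rotation=R, translation=[5.0, -3.0, 11.0])
        a2 = compute_av(s2, 0, SMALL_DYE)
        b2 = compute_av(s2, 2, SMALL_DYE)
        assert rmp(a2, b2) == pytest.approx(rmp(a, b), abs=0.3)

    def test_e_at_forster_radius_is_half(self):
        pos = np.array([[0.0, 0.0, 0.0]])
        a = AVCloud(pos[0], pos, np.array([1.0]), 1.0)
        b = AVCloud(pos[0] + [50.0, 0, 0], pos + [50.0, 0, 0], np.array([1.0]), 1.0)
        assert av_fret_efficiency(a, b, r0=50.0, n_samples=100) == pytest.approx(0.5)

    def test_e_limits_and_monotonicity(self):
        c = self._free_cloud([0.0, 0.0, 0.0])
        es = [av_fret_efficiency(c, c.translated([d, 0, 0]), r0=50.0,
                                 n_samples=20_000, seed=1)
              for d in (0.0, 30.0, 60.0, 120.0, 400.0)]
        assert es[0] > 0.97
        assert es[-1] < 0.01
        assert all(a > b for a, b in zip(es[:-1], es[1:]))

    def test_deterministic_given_seed(self):
        c = self._free_cloud([0.0, 0.0, 0.0])
        d = c.translated([40.0, 0, 0])
        e1 = av_fret_efficiency(c, d, 50.0, n_samples=5000, seed=7)
        e2 = av_fret_efficiency(c, d, 50.0, n_samples=5000, seed=7)
        assert e1 == e2


class TestStateAgreement:
    class _Mix:
        means = np.array([0.21, 0.54, 0.82, 0.98])
        sigmas = np.array([0.10, 0.10, 0.07, 0.02])

    def test_predictions_at_means_all_agree(self):
        assert state_agreement(self._Mix.means.copy(), self._Mix()) == 1.0

    def test_predictions_beyond_sigma_fail(self):
        preds = self._Mix.means + 1.5 * self._Mix.sigmas
        # 0.82 + 1.5*0.07 = 0.925 is still >1 sigma from both 0.82 and 0.98
        assert state_agreement(preds, self._Mix()) == 0.0

    def test_gaussian_draws_agree_at_one_sigma_rate(self):
        rng = np.random.default_rng(3)
        m = self._Mix()
        comp = rng.choice(4, size=2000)
        preds = rng.normal(m.means[comp], m.sigmas[comp])
        frac = state_agreement(preds, m)
        # by construction ~erf(1/sqrt(2)) ~ 0.683 (slightly higher: nearest-
        # state assignment can rescue far draws)
        assert 0.64 <= frac <= 0.78
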