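"""Hydrogen-bond detection, density, autocorrelation, decay fit, lifetime."""

import numpy as np
import pytest

from polytherm import hbonds as hb
from polytherm import synth
from polytherm.core.geometry import min_image_displacement
from polytherm.core.types import AtomSet, Box, PolythermError, Trajectory
from polytherm.hbonds import Autocorrelation, BondOccupancy


def make_role_frame(pos_d, pos_h, pos_a, box, species=None, n_frames=1, jitter=None, rng=None):
    """Trajectory with explicit donor/hydrogen/acceptor blocks, in that order."""
    pos = np.vstack([pos_d, pos_h, pos_a])
    nd, nh, na = len(pos_d), len(pos_h), len(pos_a)
    n = nd + nh + na
    roles = dict(
        is_donor=np.r_[np.ones(nd, bool), np.zeros(nh + na, bool)],
        is_hydrogen=np.r_[np.zeros(nd, bool), np.ones(nh, bool), np.zeros(na, bool)],
        is_acceptor=np.r_[np.zeros(nd + nh, bool), np.ones(na, bool)],
    )
    atoms = AtomSet(
        positions=pos,
        elements=np.array(["O"] * nd + ["H"] * nh + ["O"] * na, dtype=object),
        vdw_radii=np.full(n, 0.15),
        molecule_ids=np.arange(n),
        species=None if species is None else np.asarray(species, dtype=object),
        **roles,
    )
    coords = np.repeat(pos[None], n_frames, axis=0)
    if jitter is not None:
        coords = coords + rng.normal(0, jitter, coords.shape)
        coords[0] = pos
    return Trajectory(np.arange(n_frames, dtype=float), coords, [box] * n_frames, atoms)


def brute_force_detect(traj, d_max=0.35, angle_max=30.0):
    """All-triples oracle: loops over every (donor, hydrogen, acceptor)."""
    atoms = traj.atoms
    n = atoms.n_atoms
    donors = [i for i in range(n) if atoms.is_donor[i]]
    out = {}
    for f in range(traj.n_frames):
        pos = traj.coordinates[f]
        box = traj.boxes[f]
        pos0 = traj.coordinates[0]
        for h in range(n):
            if not atoms.is_hydrogen[h]:
                continue
            # attachment from frame 0, nearest donor within 0.12 nm
            dists = [
                np.linalg.norm(min_image_displacement(pos0[h] - pos0[d], traj.boxes[0]))
                for d in donors
            ]
            if not dists or min(dists) > 0.12:
                continue
            d = donors[int(np.argmin(dists))]
            for a in range(n):
                if not atoms.is_acceptor[a] or a == d:
                    continue
                da = min_image_displacement(pos[a] - pos[d], box)
                r_da = np.linalg.norm(da)
                if r_da >= d_max:
                    continue
                dh = min_image_displacement(pos[h] - pos[d], box)
                cos = da @ dh / (r_da * np.linalg.norm(dh))
                if np.degrees(np.arccos(np.clip(cos, -1, 1))) < angle_max:
                    out.setdefault((d, h, a), set()).add(f)
    return out


class TestDetect:
    def test_geometry_inside_criteria_is_a_bond(self):
        box = Box(3, 3, 3)
        traj = make_role_frame([[1.0, 1.0, 1.0]], [[1.1, 1.0, 1.0]], [[1.3, 1.0, 1.05]], box)
        occ = hb.detect_hbonds(traj)  # d = 0.304 nm, angle ~ 9.6 deg
        assert occ.n_bonds == 1 and occ.matrix[0, 0] == 1

    def test_distance_violation_is_not_a_bond(self):
        box = Box(3, 3, 3)
        traj = make_role_frame([[1.0, 1.0, 1.0]], [[1.1, 1.0, 1.0]], [[1.36, 1.0, 1.0]], box)
        assert hb.detect_hbonds(traj).n_bonds == 0

    def test_angle_violation_is_not_a_bond(self):
        box = Box(3, 3, 3)
        traj = make_role_frame([[1.0, 1.0, 1.0]], [[1.1, 1.0, 1.0]], [[1.0, 1.0, 1.3]], box)
        assert hb.detect_hbonds(traj).n_bonds == 0  # 90 deg

    def test_minimum_image_bond_across_boundary(self):
        box = Box(3, 3, 3)
        traj = make_role_frame([[0.05, 1.0, 1.0]], [[2.95, 1.0, 1.0]], [[2.80, 1.0, 1.0]], box)
        occ = hb.detect_hbonds(traj)
        assert occ.n_bonds == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_triples_oracle_on_random_frames(self, seed):
        rng = np.random.default_rng(seed)
        box = Box(2.0, 2.0, 2.0)
        nd, na = 10, 15
        pos_d = rng.uniform(0, 2, (nd, 3))
        pos_h = pos_d + rng.normal(0, 0.03, (nd, 3))  # hydrogens near their donors
        pos_a = rng.uniform(0, 2, (na, 3))
        traj = make_role_frame(pos_d, pos_h, pos_a, box, n_frames=3, jitter=0.02, rng=rng)
        occ = hb.detect_hbonds(traj)
        oracle = brute_force_detect(traj)
        assert set(occ.triples) == set(oracle)
        for i, triple in enumerate(occ.triples):
            assert set(np.flatnonzero(occ.matrix[i])) == oracle[triple]

    def test_missing_roles_rejected(self, random_frame):
        with pytest.raises(PolythermError, match="role flags"):
            hb.detect_hbonds(random_frame)

    def test_species_pair_tags(self):
        box = Box(3, 3, 3)
        traj = make_role_frame(
            [[1.0, 1.0, 1.0]],
            [[1.1, 1.0, 1.0]],
            [[1.3, 1.0, 1.0]],
            box,
            species=["polymer", "polymer", "water"],
        )
        occ = hb.detect_hbonds(traj)
        assert list(occ.pair_tags) == ["PW"]
        assert occ.select("PW").n_bonds == 1 and occ.select("PP").n_bonds == 0


class TestDensity:
    def test_reference_scale(self):
        matrix = np.ones((114, 10), dtype=np.uint8)
        occ = BondOccupancy(matrix, [(3 * i, 3 * i + 1, 3 * i + 2) for i in range(114)], np.arange(10.0))
        assert hb.hbond_density(occ, np.full(10, 10.0)) == pytest.approx(11.4)

    def test_empty_occupancy_is_zero(self):
        occ = BondOccupancy(np.zeros((0, 5), dtype=np.uint8), [], np.arange(5.0))
        assert hb.hbond_density(occ, np.full(5, 10.0)) == 0.0

    def test_matches_per_frame_ratio_oracle(self, rng):
        matrix = (rng.random((50, 20)) < 0.4).astype(np.uint8)
        occ = BondOccupancy(matrix, [(3 * i, 3 * i + 1, 3 * i + 2) for i in range(50)], np.arange(20.0))
        volumes = rng.uniform(8, 12, 20)
        expected = np.mean([matrix[:, f].sum() / volumes[f] for f in range(20)])
        assert hb.hbond_density(occ, volumes) == pytest.approx(expected)

    def test_misaligned_volumes_rejected(self):
        occ = synth.gen_bond_telegraph(5, 50.0, 0.0, 1.0, 10, seed=0)
        with pytest.raises(PolythermError, match="frames"):
            hb.hbond_density(occ, np.full(7, 10.0))


class TestAutocorrelation:
    def test_permanent_bonds_stay_fully_correlated(self):
        occ = synth.gen_bond_telegraph(20, 100.0, 1.0, 1.0, 50, seed=0)
        corr = hb.hbond_autocorrelation(occ)
        np.testing.assert_allclose(corr.values, 1.0)

    def test_hand_enumerated_four_frames(self):
        # one bond on for the first two of four frames
        occ = BondOccupancy(np.array([[1, 1, 0, 0]], dtype=np.uint8), [(0, 1, 2)], np.arange(4.0))
        corr = hb.hbond_autocorrelation(occ)
        # S(tau)=sum_t h(t)h(t+tau): S=[2,1,0,0]; origins=[4,3,2,1]
        # C = (S/origins)/(S0/origins0) = [0.5, 1/3, 0, 0]/0.5
        np.testing.assert_allclose(corr.values, [1.0, 2 / 3, 0.0, 0.0], atol=1e-12)

    def test_telegraph_decay_matches_exponential(self):
        occ = synth.gen_bond_telegraph(20000, 100.0, 0.0, 1.0, 1500, seed=9)
        corr = hb.hbond_autocorrelation(occ, max_lag_ps=300.0)
        expected = np.exp(-corr.lags / 100.0)
        # finite-window origin averaging inflates long lags slightly
        assert np.max(np.abs(corr.values - expected)) < 0.05

    def test_all_zero_occupancy_rejected(self):
        occ = BondOccupancy(np.zeros((3, 5), dtype=np.uint8), [(0, 1, 2), (3, 4, 5), (6, 7, 8)], np.arange(5.0))
        with pytest.raises(PolythermError, match="no bonds"):
            hb.hbond_autocorrelation(occ)


class TestDecayFit:
    def test_single_exponential_recovered(self):
        t = np.linspace(0, 500, 400)
        fit = hb.fit_decay(Autocorrelation(t, np.exp(-t / 50.0)), n_terms=1)
        assert fit.weights[0] == pytest.approx(1.0)
        assert fit.taus[0] == pytest.approx(50.0, rel=1e-6)

    def test_two_term_mixture_recovered_within_five_percent(self):
        t = np.geomspace(1, 2000, 300)
        t = np.concatenate([[0.0], t])
        c = 0.7 * np.exp(-t / 10.0) + 0.3 * np.exp(-t / 200.0)
        fit = hb.fit_decay(Autocorrelation(t, c), n_terms=2)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert sorted(fit.taus) == pytest.approx([10.0, 200.0], rel=0.05)
        assert sorted(fit.weights) == pytest.approx([0.3, 0.7], rel=0.05)

    def test_constant_correlation_hits_upper_bound(self):
        t = np.linspace(0, 100, 50)
        fit = hb.fit_decay(Autocorrelation(t, np.ones(50)), n_terms=1)
        assert fit.flags and "upper bound" in fit.flags[0]
        assert fit.taus[0] == pytest.approx(100.0 * 100.0)


class TestLifetime:
    def test_known_integral_of_pure_exponential(self):
        tau = 40.0
        t = np.linspace(0, 10 * tau, 8000)
        life = hb.hbond_lifetime(Autocorrelation(t, np.exp(-t / tau)), fit=None, horizon_ps=t[-1])
        assert life.lifetime_ps == pytest.approx(tau * (1 - np.exp(-10)), rel=1e-3)
        assert not life.lower_bound

    def test_permanent_population_lifetime_is_horizon(self):
        t = np.linspace(0, 1.0e4, 100)  # 10 ns window
        life = hb.hbond_lifetime(Autocorrelation(t, np.ones(100)), fit=None, horizon_ps=1.0e4)
        assert life.lifetime_ps == pytest.approx(1.0e4)
        assert life.lower_bound

    def test_tail_extension_equals_analytic_formula(self):
        t = np.linspace(0, 500, 600)
        c = 0.6 * np.exp(-t / 30.0) + 0.4 * np.exp(-t / 300.0)
        fit = hb.fit_decay(Autocorrelation(t, c), n_terms=2)
        horizon = 1.0e5
        life = hb.hbond_lifetime(Autocorrelation(t, c), fit, horizon_ps=horizon)
        tail = np.sum(fit.weights * fit.taus * (np.exp(-500.0 / fit.taus) - np.exp(-horizon / fit.taus)))
        assert life.tail_integral_ps == pytest.approx(tail, rel=1e-9)
        assert life.lifetime_ps == pytest.approx(np.trapezoid(c, t) + tail, rel=1e-9)

    def test_horizon_shorter_than_window_rejected(self):
        t = np.linspace(0, 100, 50)
        with pytest.raises(ValueError, match="horizon"):
            hb.hbond_lifetime(Autocorrelation(t, np.exp(-t / 10)), fit=None, horizon_ps=50.0)


def test_autocorrelation_non_increasing_in_expectation():
    """Averaged over seeds, the telegraph C_HB decays monotonically."""
    acc = []
    for seed in range(15):
        occ = synth.gen_bond_telegraph(400, 50.0, 0.0, 1.0, 300, seed=seed)
        acc.append(hb.hbond_autocorrelation(occ, max_lag_ps=150.0).values)
    mean_c = np.mean(acc, axis=0)
    assert np.all(np.diff(mean_c) < 0.01)
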