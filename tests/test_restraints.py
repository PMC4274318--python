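"""Ensemble-averaged distances, square-well energetics, superposition and
NCS restraints."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from spindock.restraints import (
    DistanceRestraint,
    NCSGroup,
    RestraintParams,
    effective_distance,
    effective_distance_gradient,
    kabsch_superpose,
    ncs_energy,
    ncs_energy_gradient,
    noe_summary,
    read_restraint_table,
    square_well_energy,
    well_energy_and_slope,
    write_restraint_table,
)

DEFAULTS = RestraintParams()


def _restraint(target, minus, plus):
    return DistanceRestraint("all", "all", target, minus, plus)


class TestEffectiveDistance:
    def test_singletons_reduce_to_plain_distance(self):
        a, b = [[0.0, 0.0, 0.0]], [[10.0, 0.0, 0.0]]
        for mode in ("R-3", "R-6", "center"):
            assert effective_distance(a, b, mode) == pytest.approx(10.0)

    def test_two_point_r3_average_matches_formula(self):
        a = [[0.0, 0.0, 0.0]]
        b = [[10.0, 0.0, 0.0], [20.0, 0.0, 0.0]]
        expected = ((10.0**-3 + 20.0**-3) / 2.0) ** (-1.0 / 3.0)
        assert effective_distance(a, b) == pytest.approx(expected)
        assert effective_distance(a, b) == pytest.approx(12.114, abs=5e-4)

    def test_symmetric_in_arguments(self, rng):
        a, b = rng.normal(size=(4, 3)) * 5, rng.normal(size=(6, 3)) * 5 + 20
        assert effective_distance(a, b) == pytest.approx(effective_distance(b, a))

    def test_bounded_by_extreme_pair_distances(self, rng):
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(7, 3)) + 15
        r = np.linalg.norm(a[:, None] - b[None], axis=-1)
        assert r.min() <= effective_distance(a, b) <= r.max()

    def test_r3_le_centroid_when_short_pairs_exist(self):
        a = [[0.0, 0.0, 0.0]]
        b = [[5.0, 0.0, 0.0], [30.0, 0.0, 0.0]]
        assert effective_distance(a, b, "R-3") < effective_distance(a, b, "center")

    def test_coincident_atoms_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            effective_distance([[0, 0, 0]], [[0, 0, 0]])


class TestSquareWell:
    def test_overlong_distance_worked_example(self):
        row = square_well_energy(37.937, _restraint(33, 2, 2), DEFAULTS)
        assert row.delta == pytest.approx(-2.937)
        assert row.energy == pytest.approx(86.2597, abs=1e-3)

    def test_inside_well_zero(self):
        row = square_well_energy(34.0, _restraint(33, 2, 2), DEFAULTS)
        assert row.delta == 0.0
        assert row.energy == 0.0

    def test_short_side_positive_delta(self):
        row = square_well_energy(29.0, _restraint(33, 2, 2), DEFAULTS)
        assert row.delta == pytest.approx(2.0)
        assert row.energy == pytest.approx(40.0)

    def test_ceiling_caps_unscaled_term(self):
        row = square_well_energy(1000.0, _restraint(33, 2, 2), DEFAULTS)
        assert row.energy == pytest.approx(
            DEFAULTS.scale * DEFAULTS.ceiling
        ) == pytest.approx(500.0)

    def test_energy_continuous_and_monotone(self):
        r = _restraint(33, 2, 2)
        grid = np.linspace(20.0, 60.0, 4001)
        e = np.array([square_well_energy(x, r, DEFAULTS).energy for x in grid])
        # continuity: steps bounded by (max slope ~ 2*scale*v_c) * grid spacing
        assert np.max(np.abs(np.diff(e))) < 2.5
        above = grid >= 35.0
        assert np.all(np.diff(e[above]) >= -1e-12)
        assert np.all(e <= 500.0 + 1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RestraintParams(ceiling=-1)
        with pytest.raises(ValueError):
            RestraintParams(sqexponent=0.5)
        with pytest.raises(ValueError):
            DistanceRestraint("all", "all", 30, -1, 1)


class TestObjectiveSlope:
    def test_matches_reported_energy_below_cap(self):
        r = _restraint(33, 2, 2)
        for x in (30.0, 34.0, 37.5, 40.0):
            e, _ = well_energy_and_slope(x, r, DEFAULTS)
            assert e == pytest.approx(square_well_energy(x, r, DEFAULTS).energy)

    def test_linear_continuation_keeps_pulling_beyond_cap(self):
        r = _restraint(33, 2, 2)
        e1, s1 = well_energy_and_slope(80.0, r, DEFAULTS)
        e2, s2 = well_energy_and_slope(90.0, r, DEFAULTS)
        assert e2 > e1 > 500.0
        assert s1 == pytest.approx(s2)  # constant slope in the far field
        assert s1 > 0

    def test_slope_matches_finite_difference(self):
        r = _restraint(33, 2, 2)
        for x in (29.5, 36.0, 41.9, 43.0, 60.0):
            _, s = well_energy_and_slope(x, r, DEFAULTS)
            h = 1e-6
            fd = (
                well_energy_and_slope(x + h, r, DEFAULTS)[0]
                - well_energy_and_slope(x - h, r, DEFAULTS)[0]
            ) / (2 * h)
            assert s == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestNoeSummary:
    def test_three_row_published_breakdown(self):
        rows = [
            square_well_energy(37.937, _restraint(33, 2, 2), DEFAULTS),
            square_well_energy(37.937, _restraint(33, 2, 2), DEFAULTS),
            square_well_energy(80.584, _restraint(78, 0.1, 0.1), DEFAULTS),
        ]
        s = noe_summary(rows)
        assert s.rms == pytest.approx(2.794, abs=2e-3)
        assert s.n_violated == 3
        assert s.n_total == 3

    def test_all_satisfied(self):
        rows = [square_well_energy(33.0, _restraint(33, 2, 2), DEFAULTS)] * 3
        s = noe_summary(rows)
        assert s.total_energy == 0.0
        assert s.rms == 0.0
        assert s.n_violated == 0

    def test_single_row_rms_is_abs_delta(self):
        row = square_well_energy(28.0, _restraint(33, 2, 2), DEFAULTS)
        assert noe_summary([row]).rms == pytest.approx(3.0)


class TestGradients:
    @pytest.mark.parametrize("averaging", ["R-3", "center"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_effective_distance_gradient_matches_fd(self, averaging, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(4, 3)) * 3
        b = rng.normal(size=(5, 3)) * 3 + np.array([12.0, 0, 0])
        r0, ga, gb = effective_distance_gradient(a, b, averaging)
        h = 1e-6
        for arr, g in ((a, ga), (b, gb)):
            for i in range(arr.shape[0]):
                for k in range(3):
                    arr[i, k] += h
                    rp = effective_distance(a, b, averaging)
                    arr[i, k] -= 2 * h
                    rm = effective_distance(a, b, averaging)
                    arr[i, k] += h
                    fd = (rp - rm) / (2 * h)
                    assert g[i, k] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestKabsch:
    def test_self_superposition_zero_rmsd(self, rng):
        x = rng.normal(size=(6, 3))
        R, t, rmsd = kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-7)
        assert np.allclose(R, np.eye(3), atol=1e-7)

    def test_pure_translation_removed(self, rng):
        x = rng.normal(size=(5, 3))
        R, t, rmsd = kabsch_superpose(x, x + np.array([5.0, 0.0, 0.0]))
        assert rmsd == pytest.approx(0.0, abs=1e-7)

    def test_proper_rotation_only(self, rng):
        x = rng.normal(size=(8, 3))
        y = x @ np.diag([1.0, 1.0, -1.0])  # mirrored set
        R, _, _ = kabsch_superpose(x, y)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_displaced_vertex_matches_brute_force(self):
        """Right triangle with one vertex displaced 1 Å: the analytic
        superposition matches a direct numerical minimisation over
        rotations + translations."""
        x = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1.0, 0]])
        y = x.copy()
        y[2, 2] += 1.0
        _, _, rmsd = kabsch_superpose(x, y)

        def objective(p):
            R = Rotation.from_rotvec(p[:3]).as_matrix()
            d = y @ R.T + p[3:] - x
            return float(np.sum(d * d))

        best = min(
            minimize(objective, np.concatenate([v, np.zeros(3)]),
                     method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-14,
                              "maxiter": 20000}).fun
            for v in (np.zeros(3), np.array([0.5, 0, 0]),
                      np.array([0, 0.5, 0.5]))
        )
        assert rmsd == pytest.approx(np.sqrt(best / 3.0), abs=1e-6)

    def test_collinear_sets_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line)


def _two_copy_structure(rng, n=8, perturb=0.0):
    from spindock.pdb_model import Structure

    base = rng.normal(size=(n, 3)) * 4
    copy2 = base.copy()
    copy2[0] += perturb
    R = Rotation.random(rng=rng).as_matrix()
    copy2 = copy2 @ R.T + rng.normal(size=3) * 10
    coords = np.vstack([base, copy2])
    return Structure(
        names=["CA"] * (2 * n),
        resnames=["ALA"] * (2 * n),
        chains=["A"] * n + ["B"] * n,
        resids=list(range(1, n + 1)) * 2,
        coords=coords,
        segids=["A"] * n + ["B"] * n,
    )


class TestNCS:
    def test_rigidly_related_copies_cost_nothing(self, rng):
        s = _two_copy_structure(rng)
        g = NCSGroup(copies=["segid A", "segid B"])
        assert ncs_energy([g], s) == pytest.approx(0.0, abs=1e-16)

    def test_displaced_atom_matches_closed_form(self, rng):
        """For two copies the fixed-point energy equals
        w/2 * (misfit after optimal superposition)^2 summed over atoms."""
        s = _two_copy_structure(rng, n=10, perturb=np.array([0.8, -0.3, 0.5]))
        g = NCSGroup(copies=["segid A", "segid B"], weight_ncs=1.0)
        e = ncs_energy([g], s)
        from spindock.pdb_model import select_atoms

        x = s.coords[select_atoms(s, "segid A")]
        y = s.coords[select_atoms(s, "segid B")]
        _, _, rmsd = kabsch_superpose(x, y)
        expected = 0.5 * rmsd**2 * len(x)
        assert e == pytest.approx(expected, abs=1e-8)

    def test_energy_linear_in_weight(self, rng):
        s = _two_copy_structure(rng, perturb=np.array([1.0, 0, 0]))
        e1 = ncs_energy([NCSGroup(copies=["segid A", "segid B"],
                                  weight_ncs=1.0)], s)
        e2 = ncs_energy([NCSGroup(copies=["segid A", "segid B"],
                                  weight_ncs=2.0)], s)
        assert e2 == pytest.approx(2.0 * e1)

    def test_invariant_under_rigid_motion_of_one_copy(self, rng):
        from spindock.pdb_model import apply_transform

        s = _two_copy_structure(rng, perturb=np.array([0.5, 0.5, 0]))
        g = NCSGroup(copies=["segid A", "segid B"])
        e0 = ncs_energy([g], s)
        moved = apply_transform(
            s, "segid B", Rotation.random(rng=rng).as_matrix(),
            rng.normal(size=3) * 50,
        )
        assert abs(ncs_energy([g], moved) - e0) < 1e-8

    def test_cardinality_mismatch_names_group(self, rng):
        s = _two_copy_structure(rng)
        g = NCSGroup(copies=["segid A", "segid B and resid 1:4"], name="bad")
        with pytest.raises(ValueError, match="bad"):
            g.resolve(s)

    def test_gradient_matches_finite_differences(self, rng):
        s = _two_copy_structure(rng, perturb=np.array([0.7, 0.2, -0.4]))
        g = NCSGroup(copies=["segid A", "segid B"])
        resolved = [(g.resolve(s), g.weight_ncs)]
        e0, grad = ncs_energy_gradient(s.coords, resolved)
        h = 1e-5
        idx = [(0, 0), (3, 1), (9, 2), (12, 0), (15, 2)]
        for i, k in idx:
            c = s.coords.copy()
            c[i, k] += h
            ep, _ = ncs_energy_gradient(c, resolved)
            c[i, k] -= 2 * h
            em, _ = ncs_energy_gradient(c, resolved)
            fd = (ep - em) / (2 * h)
            assert grad[i, k] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestRestraintTable:
    def test_round_trip(self, tmp_path):
        rs = [
            DistanceRestraint("segid S and resid 1 and name N*",
                              "segid T and resid 2 and name N*",
                              33.0, 2.0, 2.0, "E56R1 AC"),
            DistanceRestraint("segid S and resid 3 and name N*",
                              "segid T and resid 3 and name N*",
                              78.0, 0.1, 0.1, "Y35Rx2"),
        ]
        path = tmp_path / "rest.tbl"
        write_restraint_table(rs, path)
        back = read_restraint_table(path)
        assert len(back) == 2
        assert back[0].d_target == 33.0
        assert back[1].d_minus == 0.1
        assert back[0].label == "E56R1 AC"
        assert back[0].sel_a.expression == "segid S and resid 1 and name N*"

    def test_malformed_line_reports_location(self, tmp_path):
        path = tmp_path / "bad.tbl"
        path.write_text("only | three | fields\n")
        with pytest.raises(ValueError, match="bad.tbl:1"):
            read_restraint_table(path)
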