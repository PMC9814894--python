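"""Constrained RESP fitting: exactness, constraints, restraint behaviour.

The independent oracle for the unrestrained constrained fit is a
nullspace-parameterized linear least-squares solve (scipy), kept apart
from the package's KKT iteration.
"""

import numpy as np
import pytest
from scipy.linalg import null_space

from cagekit import (ChargeConstraint, EspGrid, MethylGroup, RestraintParams,
                     extract_block_charges, resp_fit, synth_esp_grid,
                     two_stage_fit)
from cagekit.elements import ANGSTROM_TO_BOHR
from cagekit.resp import ChargeFitError


def oracle_constrained_lstsq(grids, b_rows, d):
    """min ||A q - v|| s.t. B q = d via nullspace parameterization."""
    a = np.vstack([np.sqrt(g.weight) * g.design_matrix() for g in grids])
    v = np.concatenate([np.sqrt(g.weight) * g.potentials for g in grids])
    b = np.asarray(b_rows, float)
    d = np.asarray(d, float)
    q0 = np.linalg.lstsq(b, d, rcond=None)[0]
    ns = null_space(b)
    y = np.linalg.lstsq(a @ ns, v - a @ q0, rcond=None)[0]
    return q0 + ns @ y


def diatomic_grid(q=(0.4, -0.4), sep=1.2):
    coords = np.array([[0.0, 0.0, 0.0], [sep, 0.0, 0.0]])
    return synth_esp_grid(coords, q, ["C", "O"])


def methanol_like():
    """5 heavy+H toy: one methyl carbon with 3 H, plus O and H(O)."""
    coords = np.array([
        [0.0, 0.0, 0.0],     # C
        [0.63, 0.63, 0.63],  # H
        [-0.63, -0.63, 0.63],  # H
        [-0.63, 0.63, -0.63],  # H
        [1.0, -1.0, -1.0],   # O
        [1.6, -1.6, -1.6],   # H(O)
    ])
    elements = ["C", "H", "H", "H", "O", "H"]
    q_true = np.array([0.15, 0.05, 0.04, 0.06, -0.6, 0.3])
    return coords, elements, q_true


class TestRespFit:
    def test_recovers_ground_truth_unrestrained(self):
        g = diatomic_grid()
        res = resp_fit([g], [ChargeConstraint("total_charge", value=0.0)],
                       RestraintParams(a=0.0))
        assert np.allclose(res.charges, [0.4, -0.4], atol=1e-8)
        assert res.rrms < 1e-8

    def test_matches_nullspace_oracle(self):
        coords, elements, q_true = methanol_like()
        g = synth_esp_grid(coords, q_true, elements)
        n = len(q_true)
        total = float(q_true.sum())
        res = resp_fit([g], [ChargeConstraint("total_charge", value=total)],
                       RestraintParams(a=0.0))
        oracle = oracle_constrained_lstsq([g], [np.ones(n)], [total])
        assert np.sqrt(np.mean((res.charges - oracle) ** 2)) < 1e-6

    def test_total_charge_constraint_exact(self):
        g = diatomic_grid(q=(-1.3, -0.7))
        res = resp_fit([g], [ChargeConstraint("total_charge", value=-2.0)])
        assert abs(res.total_charge - (-2.0)) < 1e-10
        assert all(r < 1e-10 for r in res.constraint_residuals)

    def test_equivalence_across_conformers_bitwise(self):
        coords, elements, q_true = methanol_like()
        g1 = synth_esp_grid(coords, q_true, elements, conformer_id="a")
        rot = coords @ np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0],
                                 [0.0, 0.0, 1.0]]).T
        g2 = synth_esp_grid(rot, q_true, elements, conformer_id="b")
        res = resp_fit([g1, g2], [
            ChargeConstraint("total_charge", value=float(q_true.sum())),
            ChargeConstraint("equivalence", (1, 5)),
        ])
        assert res.charges[1] == res.charges[5]  # shared unknown: bitwise

    def test_grid_order_invariance(self):
        coords, elements, q_true = methanol_like()
        g1 = synth_esp_grid(coords, q_true, elements, conformer_id="a")
        g2 = synth_esp_grid(coords * 1.02, q_true, elements, conformer_id="b")
        cons = [ChargeConstraint("total_charge", value=float(q_true.sum()))]
        q_ab = resp_fit([g1, g2], cons).charges
        q_ba = resp_fit([g2, g1], cons).charges
        assert np.max(np.abs(q_ab - q_ba)) < 1e-12

    def test_restraint_shrinks_charges_monotonically(self):
        coords, elements, q_true = methanol_like()
        # all-carbon labels so every atom is restrained
        g = synth_esp_grid(coords, q_true, ["C"] * 6)
        cons = [ChargeConstraint("total_charge", value=float(q_true.sum()))]
        mean_abs = [np.mean(np.abs(resp_fit([g], cons,
                                            RestraintParams(a=a)).charges))
                    for a in (0.0, 5e-4, 1e-2)]
        assert mean_abs[0] > mean_abs[1] > mean_abs[2]

    def test_underdetermined_grid_rejected(self):
        coords = np.array([[0.0, 0.0, 0.0], [1.2, 0.0, 0.0]])
        with pytest.raises(ChargeFitError, match="under-determined"):
            EspGrid("x", coords, coords[:1] + 5.0, np.array([0.1]))

    def test_contradictory_constraints_raise(self):
        g = diatomic_grid()
        with pytest.raises(ChargeFitError, match="singular"):
            resp_fit([g], [ChargeConstraint("total_charge", value=0.0),
                           ChargeConstraint("total_charge", value=1.0)],
                     RestraintParams(a=0.0))


class TestTwoStage:
    def test_methyl_hydrogens_identical_after_stage2(self):
        coords, elements, q_true = methanol_like()
        g = synth_esp_grid(coords, q_true, elements)
        cons = [ChargeConstraint("total_charge", value=float(q_true.sum()))]
        res = two_stage_fit([g], cons,
                            groups=[MethylGroup(0, (1, 2, 3))])
        assert res.charges[1] == res.charges[2] == res.charges[3]
        assert abs(res.total_charge - q_true.sum()) < 1e-10

    def test_no_groups_equals_stage1(self):
        g = diatomic_grid()
        cons = [ChargeConstraint("total_charge", value=0.0)]
        s1 = RestraintParams(a=0.0005)
        assert np.array_equal(two_stage_fit([g], cons, stage1=s1).charges,
                              resp_fit([g], cons, s1).charges)

    def test_non_group_charges_frozen(self):
        coords, elements, q_true = methanol_like()
        g = synth_esp_grid(coords, q_true, elements)
        cons = [ChargeConstraint("total_charge", value=float(q_true.sum()))]
        s1 = resp_fit([g], cons, RestraintParams(a=0.0005))
        s2 = two_stage_fit([g], cons, groups=[MethylGroup(0, (1, 2, 3))],
                           stage1=RestraintParams(a=0.0005))
        for i in (4, 5):  # O and hydroxyl H are outside the methyl group
            assert abs(s2.charges[i] - s1.charges[i]) < 1e-10

    def test_non_carbon_center_rejected(self):
        coords, elements, q_true = methanol_like()
        g = synth_esp_grid(coords, q_true, elements)
        with pytest.raises(ChargeFitError, match="expected a carbon"):
            two_stage_fit([g], [], groups=[MethylGroup(4, (5,))])


class TestExtractBlockCharges:
    def test_blocked_fragment_sums(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(scale=2.0, size=(8, 3))
        elements = ["C"] * 8
        blocking = [5, 6, 7]
        q_true = rng.normal(scale=0.3, size=8)
        q_true[blocking] -= q_true[blocking].mean()  # blocking sums to 0
        q_true[:5] += (-2.0 - q_true.sum()) / 5     # total is -2
        g = synth_esp_grid(coords, q_true, elements)
        res = resp_fit([g], [
            ChargeConstraint("total_charge", value=-2.0),
            ChargeConstraint("group_sum", tuple(blocking), 0.0),
        ], RestraintParams(a=0.0))
        residue = extract_block_charges(res, blocking)
        assert len(residue) == 5
        assert abs(residue.sum() - (-2.0)) < 1e-8

    def test_identity_when_nothing_blocked(self):
        g = diatomic_grid()
        res = resp_fit([g], [ChargeConstraint("total_charge", value=0.0)])
        assert np.array_equal(extract_block_charges(res, []), res.charges)

    def test_missing_group_constraint_detected(self):
        g = diatomic_grid(q=(0.5, -0.3))
        res = resp_fit([g], [ChargeConstraint("total_charge", value=0.2)],
                       RestraintParams(a=0.0))
        with pytest.raises(ChargeFitError, match="group-sum"):
            extract_block_charges(res, [0])


class TestSynthGrid:
    def test_neutral_charges_give_zero_potential(self):
        coords = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]])
        g = synth_esp_grid(coords, [0.0, 0.0], ["C", "C"])
        assert np.max(np.abs(g.potentials)) == 0.0

    def test_coulomb_identity_one_bohr(self):
        # V = q/r in au: a +1 charge seen from 1 Bohr away gives 1.0
        from cagekit.elements import BOHR_TO_ANGSTROM
        coords = np.zeros((1, 3))
        grid = np.array([[BOHR_TO_ANGSTROM, 0.0, 0.0]])
        g = EspGrid("c", coords, grid, np.array([0.0]))
        v = g.design_matrix() @ np.array([1.0])
        assert abs(v[0] - 1.0) < 1e-12

    def test_points_respect_exclusion_shells(self):
        coords = np.array([[0.0, 0.0, 0.0], [1.2, 0.0, 0.0]])
        g = synth_esp_grid(coords, [0.1, -0.1], ["C", "O"],
                           shells=(1.4,), density=0.5)
        from cagekit.elements import vdw_radius
        d = np.linalg.norm(g.grid_points[:, None, :] - coords[None], axis=2)
        limits = 1.4 * np.array([vdw_radius("C"), vdw_radius("O")])
        assert np.all(d >= limits[None, :] - 1e-6)

    def test_round_trip_through_fit(self):
        coords, elements, q_true = methanol_like()
        g = synth_esp_grid(coords, q_true, elements)
        res = resp_fit([g], [ChargeConstraint("total_charge",
                                              value=float(q_true.sum()))],
                       RestraintParams(a=0.0))
        assert np.allclose(res.charges, q_true, atol=1e-8)
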