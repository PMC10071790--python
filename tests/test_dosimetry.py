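"""Residence times, interspecies scaling, S-matrix doses, effective dose."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from immunopet.core import ZR89, Radionuclide
from immunopet.dosimetry import (
    ICRP103_WEIGHTS,
    DoseReport,
    OrganBiokinetics,
    PhantomMasses,
    ResidenceTimeTable,
    SMatrix,
    administered_dose,
    effective_dose,
    organ_doses,
    remainder_and_total,
    residence_time,
    scale_rabbit_to_human,
)

TOTAL_BOUND_H = ZR89.half_life_h / math.log(2)  # 114.26 h


def physical_decay_bio(u=1.0, n=20001, t_max=2000.0):
    t = np.linspace(0.0, t_max, n)
    return OrganBiokinetics("body", t, u * np.exp2(-t / ZR89.half_life_h))


class TestResidenceTime:
    def test_pure_physical_decay_gives_half_life_over_ln2(self):
        tau = residence_time(physical_decay_bio(), ZR89)
        assert tau == pytest.approx(TOTAL_BOUND_H, rel=1e-6)

    def test_zero_fraction_gives_zero(self):
        bio = OrganBiokinetics("o", np.array([0.0, 24.0, 48.0]), np.zeros(3))
        assert residence_time(bio, ZR89) == 0.0

    def test_linearity_in_fractions(self):
        bio = physical_decay_bio(u=0.5)
        assert residence_time(bio, ZR89) == pytest.approx(TOTAL_BOUND_H / 2, rel=1e-6)

    def test_decay_corrected_series_rejected(self):
        bio = OrganBiokinetics("o", np.array([0.0, 24.0]), np.array([0.5, 0.5]),
                               decay_corrected=True)
        with pytest.raises(ValueError, match="decay-corrected"):
            residence_time(bio, ZR89)

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            OrganBiokinetics("o", np.array([0.0, 1.0]), np.array([0.1, -0.1]))


class TestRabbitToHumanScaling:
    def _masses(self, liver_rel_r, liver_rel_h):
        r = PhantomMasses("rabbit", {"liver": liver_rel_r * 3.0}, 3.0)
        h = PhantomMasses("human", {"liver": liver_rel_h * 70.0}, 70.0)
        return r, h

    def test_equal_relative_masses_identity(self):
        bio = {"liver": OrganBiokinetics("liver", np.array([0.0, 24.0]), np.array([0.3, 0.2]))}
        r, h = self._masses(0.03, 0.03)
        out = scale_rabbit_to_human(bio, r, h)
        assert np.allclose(out["liver"].fraction_of_injected, [0.3, 0.2])

    def test_relative_mass_ratio_two_doubles_fractions(self):
        bio = {"liver": OrganBiokinetics("liver", np.array([0.0, 24.0]), np.array([0.3, 0.2]))}
        r, h = self._masses(0.02, 0.04)
        out = scale_rabbit_to_human(bio, r, h)
        assert np.allclose(out["liver"].fraction_of_injected, [0.6, 0.4])

    def test_oversubscribed_sum_renormalized_preserving_ratios(self):
        t = np.array([0.0, 24.0])
        bio = {
            "liver": OrganBiokinetics("liver", t, np.array([0.4, 0.1])),
            "spleen": OrganBiokinetics("spleen", t, np.array([0.2, 0.05])),
        }
        r = PhantomMasses("rabbit", {"liver": 0.06, "spleen": 0.03}, 3.0)
        h = PhantomMasses("human", {"liver": 2.8, "spleen": 1.4}, 70.0)  # 2x relative
        with pytest.warns(UserWarning, match="renormalized"):
            out = scale_rabbit_to_human(bio, r, h)
        total0 = out["liver"].fraction_of_injected[0] + out["spleen"].fraction_of_injected[0]
        assert total0 == pytest.approx(1.0, rel=1e-12)  # 1.2 renormalized to 1
        ratio = out["liver"].fraction_of_injected[0] / out["spleen"].fraction_of_injected[0]
        assert ratio == pytest.approx(2.0, rel=1e-12)
        # second time point (sum 0.3) untouched
        assert out["liver"].fraction_of_injected[1] == pytest.approx(0.2)

    def test_missing_organ_mass_rejected(self):
        bio = {"liver": OrganBiokinetics("liver", np.array([0.0, 1.0]), np.array([0.1, 0.1]))}
        r = PhantomMasses("rabbit", {}, 3.0)
        h = PhantomMasses("human", {"liver": 1.8}, 70.0)
        with pytest.raises(KeyError):
            scale_rabbit_to_human(bio, r, h)


class TestRemainderAndTotal:
    def test_no_source_organs(self):
        table = remainder_and_total({}, ZR89)
        assert table.remainder_h == pytest.approx(TOTAL_BOUND_H, rel=1e-12)
        assert table.total_h == table.remainder_h

    def test_full_absorption_leaves_zero_remainder(self):
        table = remainder_and_total({"body": TOTAL_BOUND_H}, ZR89)
        assert table.remainder_h == pytest.approx(0.0, abs=1e-9)

    def test_two_organ_subtraction(self):
        table = remainder_and_total({"a": 30.0, "b": 40.0}, ZR89)
        assert table.remainder_h == pytest.approx(TOTAL_BOUND_H - 70.0, rel=1e-9)

    def test_oversubscribed_rejected(self):
        with pytest.raises(ValueError, match="exceeds|>"):
            remainder_and_total({"a": 200.0}, ZR89)

    @given(
        taus=st.lists(st.floats(min_value=0.0, max_value=30.0), min_size=1, max_size=5)
    )
    def test_conservation_budget(self, taus):
        table = remainder_and_total({f"o{i}": v for i, v in enumerate(taus)}, ZR89)
        assert sum(table.organ_tau_h.values()) + table.remainder_h == pytest.approx(
            TOTAL_BOUND_H, rel=1e-12
        )


class TestOrganDoses:
    def test_single_source_diagonal(self):
        s = SMatrix({("liver", "liver"): 0.5, ("liver", "remainder"): 0.0,
                     ("remainder", "remainder"): 0.0})
        table = ResidenceTimeTable({"liver": 10.0}, TOTAL_BOUND_H - 10.0, TOTAL_BOUND_H)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = organ_doses(table, s)
        assert d["liver"] == pytest.approx(5.0)

    def test_zero_residence_times_zero_doses(self):
        s = SMatrix({("a", "a"): 1.0, ("a", "remainder"): 0.1})
        table = ResidenceTimeTable({"a": 0.0}, 0.0, 0.0)
        assert organ_doses(table, s)["a"] == 0.0

    def test_matches_matrix_vector_product(self):
        organs = ["liver", "spleen", "kidneys"]
        rng = np.random.default_rng(3)
        S = rng.uniform(0.01, 0.5, size=(3, 4))  # targets x (organs + remainder)
        entries = {}
        for i, tgt in enumerate(organs):
            for j, src in enumerate(organs + ["remainder"]):
                entries[(tgt, src)] = S[i, j]
        taus = {"liver": 20.0, "spleen": 5.0, "kidneys": 8.0}
        table = remainder_and_total(taus, ZR89)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = organ_doses(table, SMatrix(entries))
        tau_vec = np.array([20.0, 5.0, 8.0, table.remainder_h])
        expected = S @ tau_vec
        assert [d[o] for o in organs] == pytest.approx(expected.tolist(), rel=1e-12)

    def test_missing_source_row_reported(self):
        s = SMatrix({("liver", "liver"): 0.5})
        table = ResidenceTimeTable({"liver": 10.0}, TOTAL_BOUND_H - 10.0, TOTAL_BOUND_H)
        with pytest.raises(KeyError, match="remainder"):
            organ_doses(table, s)

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    def test_linearity_in_residence_times(self, scale):
        s = SMatrix({("liver", "liver"): 0.08, ("liver", "remainder"): 0.003,
                     ("spleen", "liver"): 0.004, ("spleen", "remainder"): 0.003})
        t1 = ResidenceTimeTable({"liver": 10.0}, 20.0, 30.0)
        t2 = ResidenceTimeTable({"liver": 10.0 * scale}, 20.0 * scale, 30.0 * scale)
        d1 = organ_doses(t1, s)
        d2 = organ_doses(t2, s)
        for k in d1:
            assert d2[k] == pytest.approx(scale * d1[k], rel=1e-12)


class TestEffectiveDose:
    def test_weights_sum_to_one(self):
        assert sum(ICRP103_WEIGHTS.values()) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_unit_dose_gives_unit_effective_dose(self):
        doses = {organ: 1.0 for organ in
                 ["liver", "lung", "stomach", "colon", "red_marrow", "breast",
                  "gonads", "bladder", "oesophagus", "thyroid", "bone_surface",
                  "brain", "salivary_glands", "skin", "spleen", "kidneys"]}
        assert effective_dose(doses) == pytest.approx(1.0, rel=1e-12)

    def test_doubling_doses_doubles_effective_dose(self):
        doses = {"liver": 2.0, "lung": 1.0, "kidneys": 0.5}
        assert effective_dose({k: 2 * v for k, v in doses.items()}) == pytest.approx(
            2 * effective_dose(doses), rel=1e-12
        )

    def test_bad_weight_table_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            effective_dose({"liver": 1.0}, weights={"liver": 0.5})


class TestAdministeredDose:
    @pytest.mark.parametrize(
        "coeff, activity, expected",
        [(0.702, 37.0, 26.0), (1.0, 1.0, 1.0), (0.702, 74.0, 52.0)],
    )
    def test_examples(self, coeff, activity, expected):
        assert administered_dose(coeff, activity) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            administered_dose(0.0, 37.0)


class TestEndToEndClosedForm:
    def test_liver_only_instant_uptake_pipeline(self):
        """Liver with instant uptake u and physical decay only: human tau equals
        u * (relative-mass ratio) * T_half/ln2."""
        u = 0.3
        t = np.linspace(0.0, 2000.0, 20001)
        bios = {"liver": OrganBiokinetics("liver", t, u * np.exp2(-t / ZR89.half_life_h))}
        r = PhantomMasses("rabbit", {"liver": 0.09}, 3.0)  # 3.0% of body
        h = PhantomMasses("human", {"liver": 1.8}, 70.0)  # ~2.57% of body
        scaled = scale_rabbit_to_human(bios, r, h)
        tau = residence_time(scaled["liver"], ZR89)
        mass_ratio = (1.8 / 70.0) / (0.09 / 3.0)
        assert tau == pytest.approx(u * mass_ratio * TOTAL_BOUND_H, rel=1e-6)

    def test_self_dose_monotone_in_uptake(self):
        s = SMatrix({("liver", "liver"): 0.08, ("liver", "remainder"): 0.003,
                     ("remainder", "remainder"): 0.01})
        doses = []
        for u in (0.1, 0.2, 0.4):
            bio = physical_decay_bio(u=u)
            tau = residence_time(bio, ZR89)
            table = remainder_and_total({"liver": tau}, ZR89)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                doses.append(organ_doses(table, s)["liver"])
        assert doses[0] < doses[1] < doses[2]
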