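"""Generator correctness: pedigree structure, map calibration, meiosis model,
distortion, rearrangement injection, and determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cervmap import pedio, simdata


class TestSimulatePedigree:
    def test_minimal_case_two_subpedigrees(self):
        ped = simdata.simulate_pedigree(1, 1, 1, seed=1)
        subs = pedio.build_subpedigrees(ped, set(ped["id"]))
        fids = {s.fid for s in subs}
        assert len(subs) == 2 and fids == {"M1", "F1"}

    def test_counts_and_sexes(self):
        ped = simdata.simulate_pedigree(5, 5, 2, seed=7)
        subs = pedio.build_subpedigrees(ped, set(ped["id"]))
        assert len(subs) == 20
        assert all(s.fid_sex in ("male", "female") for s in subs)
        sx = ped.set_index("id")["sex"]
        assert all(sx[s.fid_sire] == "male" and sx[s.fid_dam] == "female" for s in subs)

    def test_study_scale_config(self):
        # emulates many offspring from fewer unique males than females
        ped = simdata.simulate_pedigree(83, 259, (1, 8), seed=3)
        subs = pedio.build_subpedigrees(ped, set(ped["id"]))
        males = {s.fid for s in subs if s.fid_sex == "male"}
        females = {s.fid for s in subs if s.fid_sex == "female"}
        assert len(males) == 83 and len(females) == 259

    def test_deterministic_given_seed(self):
        a = simdata.simulate_pedigree(5, 5, (1, 3), seed=7)
        b = simdata.simulate_pedigree(5, 5, (1, 3), seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            simdata.simulate_pedigree(0, 1, 1, seed=1)
        with pytest.raises(ValueError):
            simdata.simulate_pedigree(1, 1, 0, seed=1)


class TestSimulateTrueMap:
    def test_null_landscape_sexes_identical(self):
        tm = simdata.simulate_true_map(2, 50, 60.0, female_ratio=1.0,
                                       pericentromeric_multiplier=1.0, seed=1)
        for g in tm.groups.values():
            np.testing.assert_allclose(g.marker_cm("male"), g.marker_cm("female"))

    def test_pericentromeric_intensity_ratio_by_integration(self):
        tm = simdata.simulate_true_map(1, 50, 100.0, female_ratio=1.21,
                                       pericentromeric_multiplier=4.0,
                                       pericentromeric_fraction=0.2, seed=2)
        g = tm.groups["G1"]
        # numerically integrate the generated female intensity on both sides
        bp = np.linspace(0, g.length_bp, 100001)
        cm = g.cm_at(bp, "female")
        dens = np.diff(cm) / np.diff(bp)
        inside = dens[bp[:-1] < 0.2 * g.length_bp].mean()
        outside = dens[bp[:-1] >= 0.2 * g.length_bp].mean()
        assert inside / outside == pytest.approx(4.0, rel=1e-6)

    def test_total_ratio_calibration(self):
        tm = simdata.simulate_true_map(5, 50, 80.0, female_ratio=1.21,
                                       pericentromeric_multiplier=4.0, seed=3)
        assert tm.total_length("female") / tm.total_length("male") == pytest.approx(1.21, abs=0.02)

    def test_invariants(self):
        tm = simdata.simulate_true_map(3, 40, 70.0, seed=4)
        for g in tm.groups.values():
            assert np.all(np.diff(g.bp) > 0)
            for sex in ("male", "female"):
                assert np.all(np.diff(g.marker_cm(sex)) >= 0)

    def test_history_length_mismatch(self):
        with pytest.raises(ValueError):
            simdata.simulate_true_map(3, 10, 50.0, histories=["unchanged"], seed=0)


class TestGametesAndGenotypes:
    def test_poisson_crossover_expectation(self):
        # 100 cM chromosome: 1 crossover per meiosis on average
        tm = simdata.simulate_true_map(1, 50, 100.0, female_ratio=1.0,
                                       pericentromeric_multiplier=1.0, seed=5)
        gam = simdata.simulate_true_gametes(tm, 500, 500, seed=6)
        O, _ = gam["G1"]
        flips = (O[:, 1:] != O[:, :-1]).sum(axis=1)
        # observable flips undercount slightly (breakpoints outside the marker
        # span); compare to truth via the generator's own breakpoint draw
        mean, se = flips.mean(), flips.std() / np.sqrt(len(flips))
        assert abs(mean - 1.0) < 3 * se + 0.05

    def test_mendelian_consistency_without_error(self, small_sim):
        _, _, rep = pedio.mendelian_check(small_sim["subpeds"], small_sim["genotypes"])
        total = rep.loc[rep["item"] == "total_incompatibilities", "value"].iloc[0]
        assert total == 0

    def test_errors_create_incompatibilities(self, small_sim):
        gm2, _ = simdata.simulate_gametes_and_genotypes(
            small_sim["pedigree"], small_sim["truemap"], error_rate=0.02, seed=14)
        _, _, rep = pedio.mendelian_check(small_sim["subpeds"], gm2)
        total = rep.loc[rep["item"] == "total_incompatibilities", "value"].iloc[0]
        assert total > 0

    def test_deterministic_given_seed(self, small_sim):
        gm2, _ = simdata.simulate_gametes_and_genotypes(
            small_sim["pedigree"], small_sim["truemap"], seed=13)
        pd.testing.assert_frame_equal(small_sim["genotypes"].calls, gm2.calls)

    def test_null_distortion_balanced(self):
        tm = simdata.simulate_true_map(1, 20, 50.0, seed=7)
        ped = simdata.simulate_pedigree(5, 200, 2, seed=8)
        locus = tm.groups["G1"].markers[10]
        gm, _ = simdata.simulate_gametes_and_genotypes(
            ped, tm, distortion_loci=[simdata.DistortionLocus(locus, 0.5)], seed=9)
        subs = pedio.build_subpedigrees(ped, set(gm.calls.index))
        from cervmap import distortion
        rec = distortion.transmission_counts(subs, gm)
        row = rec[(rec.marker == locus) & (rec.fid_sex == "female")].iloc[0]
        n = row.count_a + row.count_b
        p, _ = distortion.binomial_exact_test(row.count_a, row.count_b)
        assert p > 0.001  # no significant deviation from 0.5

    def test_planted_distortion_recovered(self):
        tm = simdata.simulate_true_map(1, 20, 50.0, seed=17)
        ped = simdata.simulate_pedigree(5, 400, 2, seed=18)
        locus = tm.groups["G1"].markers[10]
        gm, _ = simdata.simulate_gametes_and_genotypes(
            ped, tm, distortion_loci=[simdata.DistortionLocus(locus, 0.7, sex="female")], seed=19)
        subs = pedio.build_subpedigrees(ped, set(gm.calls.index))
        from cervmap import distortion
        rec = distortion.transmission_counts(subs, gm)
        row = rec[(rec.marker == locus) & (rec.fid_sex == "female")].iloc[0]
        n = row.count_a + row.count_b
        assert n > 100
        assert row.count_a / n == pytest.approx(0.7, abs=0.05)

    def test_unknown_distortion_locus_rejected(self, small_sim):
        with pytest.raises(ValueError):
            simdata.simulate_gametes_and_genotypes(
                small_sim["pedigree"], small_sim["truemap"],
                distortion_loci=[simdata.DistortionLocus("nope", 0.7)], seed=1)

    def test_founder_pool_creates_ld(self):
        tm = simdata.simulate_true_map(1, 40, 40.0, seed=20)
        ped = simdata.simulate_pedigree(30, 30, 2, seed=21)
        gm_le, _ = simdata.simulate_gametes_and_genotypes(ped, tm, seed=22)
        gm_ld, _ = simdata.simulate_gametes_and_genotypes(ped, tm, founder_pool=6, seed=22)
        from cervmap import mapbuild
        ms = tm.groups["G1"].markers[:10]  # tightly spaced block
        r2_le = np.nanmedian(mapbuild.ld_r2(gm_le, ms).to_numpy()[np.triu_indices(10, 1)])
        r2_ld = np.nanmedian(mapbuild.ld_r2(gm_ld, ms).to_numpy()[np.triu_indices(10, 1)])
        assert r2_ld > 5 * max(r2_le, 1e-4)


class TestInjectRearrangements:
    ORDER = {"A": [f"a{i}" for i in range(50)], "B": [f"b{i}" for i in range(50)]}

    def test_empty_spec_identity(self):
        out, entries = simdata.inject_rearrangements(self.ORDER, [], seed=0)
        assert out == self.ORDER and entries == []

    def test_inversion_reverses_span_only(self):
        spec = [simdata.Rearrangement("inversion", "A", 10, 25)]
        out, _ = simdata.inject_rearrangements(self.ORDER, spec, seed=0)
        assert out["A"][10:35] == self.ORDER["A"][10:35][::-1]
        assert out["A"][:10] == self.ORDER["A"][:10]
        assert out["A"][35:] == self.ORDER["A"][35:]
        assert out["B"] == self.ORDER["B"]

    def test_displacement_set_consistency(self):
        spec = [simdata.Rearrangement("chunk_displacement", "A", 5, 30,
                                      dest_group="B", dest_index=7)]
        out, entries = simdata.inject_rearrangements(self.ORDER, spec, seed=0)
        moved = set(self.ORDER["A"][5:35])
        assert set(out["A"]) == set(self.ORDER["A"]) - moved
        assert set(out["B"]) == set(self.ORDER["B"]) | moved
        assert set(entries[0]["markers"]) == moved

    def test_fission_partitions_group(self):
        spec = [simdata.Rearrangement("fission", "A", 20, 30, new_group="A2")]
        out, _ = simdata.inject_rearrangements(self.ORDER, spec, seed=0)
        assert out["A"] + out["A2"] == self.ORDER["A"]

    def test_overlapping_spans_rejected(self):
        spec = [simdata.Rearrangement("inversion", "A", 0, 10),
                simdata.Rearrangement("inversion", "A", 5, 10)]
        with pytest.raises(ValueError):
            simdata.inject_rearrangements(self.ORDER, spec, seed=0)


def test_writers_round_trip(tmp_path):
    tm = simdata.simulate_true_map(1, 5, 10.0, seed=1)
    simdata.write_true_map(tm, tmp_path / "map.tsv")
    assert (tmp_path / "map.tsv").read_text().startswith("marker\tgroup")
    cfg = {"n_groups": 1, "female_ratio": 1.21}
    simdata.write_config(cfg, tmp_path / "cfg.yaml")
    assert simdata.read_config(tmp_path / "cfg.yaml") == cfg


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_true_gametes_symbols_valid(seed):
    tm = simdata.simulate_true_map(1, 10, 30.0, seed=1)
    gam = simdata.simulate_true_gametes(tm, 3, 3, seed=seed)
    O, sx = gam["G1"]
    assert set(np.unique(O)) <= {-1, 1}
    assert O.shape == (6, 10)
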