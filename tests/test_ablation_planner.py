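"""Planner tests: scripted oracles, worked patient cases, brute-force verifier."""

import numpy as np
import pytest

from atrialdt import ablation_planner as ap
from atrialdt import synthetic_substrate as synth


class TestLesionGeometry:
    def test_disc_default_diameter(self):
        lesion = ap.Lesion(shape="disc", center=(15.0, 15.0))
        mask = lesion.to_mask((100, 100), 0.3)
        area_mm2 = mask.sum() * 0.09
        assert area_mm2 == pytest.approx(np.pi * 36.0, rel=0.05)

    def test_ellipse_for_wide_meander(self):
        from atrialdt.rotor_analysis import RotorEvent

        ev = RotorEvent(
            trajectory=np.array([[0.0, 0.0], [15.0, 0.0]]),
            times_ms=np.array([0.0, 6000.0]),
            chirality=1,
            birth_s=0.0,
            death_s=6.0,
            centroid=(7.5, 0.0),
            meander_extent_mm=15.0,
            principal_axis_rad=0.0,
            wide_meander=True,
        )
        lesion = ap.lesion_for_rotor(ev)
        assert lesion.shape == "ellipse"
        assert lesion.axes == (21.0, 12.0)

    def test_edge_lesion_clipped(self):
        lesion = ap.Lesion(shape="disc", center=(0.0, 0.0))
        mask = lesion.to_mask((50, 50), 0.3)
        assert mask.any()
        assert mask.sum() * 0.09 < np.pi * 36.0  # clipped to the sheet

    def test_band_width(self):
        band = ap.Lesion(shape="band", endpoints=((0.0, 5.0), (30.0, 5.0)), width=7.5)
        mask = band.to_mask((100, 100), 0.3)
        rows = np.nonzero(mask[:, 50])[0]
        assert (rows.max() - rows.min()) * 0.3 == pytest.approx(7.5, abs=0.7)


class TestScriptOracleClassification:
    def test_patient1_classification(self):
        oracle = ap.script_oracle(synth.builtin_patient_fixture(1))
        cls, emergent = ap.classify_rotors(oracle)
        assert cls == {"A": "LIR", "B": "LCR", "C": "LIR"}
        assert emergent == {}

    def test_patient2_classification_with_emergent(self):
        oracle = ap.script_oracle(synth.builtin_patient_fixture(2))
        cls, emergent = ap.classify_rotors(oracle)
        assert cls == {"A": "LIR", "B": "LCR", "C": "LIR"}
        assert "D" in emergent

    def test_patient3_all_contingent(self):
        oracle = ap.script_oracle(synth.builtin_patient_fixture(3))
        cls, _ = ap.classify_rotors(oracle)
        assert cls == {"A": "LCR", "B": "LCR"}


class TestGuidedSearch:
    @pytest.mark.parametrize(
        "pid,expected_lesions,expected_all_at_once",
        [(1, {"A", "C"}, 3), (2, {"A", "C"}, 4), (3, None, 2)],
    )
    def test_worked_patient_cases(self, pid, expected_lesions, expected_all_at_once):
        plan = ap.guided_search(ap.script_oracle(synth.builtin_patient_fixture(pid)))
        assert not plan.final_inducible
        if expected_lesions is not None:
            assert set(plan.lesion_ids) == expected_lesions
        else:  # patient 3: exactly one of the two mutually contingent sites
            assert len(plan.lesion_ids) == 1
            assert plan.lesion_ids[0] in {"A", "B"}
        aao = ap.all_at_once(ap.script_oracle(synth.builtin_patient_fixture(pid)))
        assert not aao.final_inducible
        assert aao.n_lesions == expected_all_at_once

    def test_patient1_iat_annotations(self):
        plan = ap.guided_search(ap.script_oracle(synth.builtin_patient_fixture(1)))
        assert plan.iat_annotations["A"] == "barrier-contact"
        assert plan.iat_annotations["C"] == "iat"

    def test_lcr_tiebreak_prefers_high_fd(self):
        plan = ap.guided_search(ap.script_oracle(synth.builtin_patient_fixture(3)))
        # patient 3 FDs: A=62 > B=58
        assert plan.lesion_ids == ["A"]

    def test_single_rotor_script(self):
        s = synth.generate_random_dependency(1, p_contingent=0.0, p_emergent=0.0, seed=0)
        plan = ap.guided_search(ap.script_oracle(s))
        assert plan.n_lesions == 1
        assert not plan.final_inducible

    def test_plan_json_roundtrip(self, tmp_path):
        plan = ap.guided_search(ap.script_oracle(synth.builtin_patient_fixture(2)))
        plan.to_json(tmp_path / "plan.json")
        import json

        obj = json.loads((tmp_path / "plan.json").read_text())
        assert obj["strategy"] == "lesion-minimizing"
        assert set(obj["lesion_ids"]) == {"A", "C"}
        assert obj["classification"]["D"].startswith("emergent")


class TestExhaustiveVerifier:
    def test_patient1_minimal_sets(self):
        ess, minimal = ap.exhaustive_minimal_sets(synth.builtin_patient_fixture(1))
        assert ess == {"A", "C"}
        assert minimal == [frozenset({"A", "C"})]

    def test_patient3_minimal_sets(self):
        ess, minimal = ap.exhaustive_minimal_sets(synth.builtin_patient_fixture(3))
        assert ess == set()
        assert sorted(minimal, key=sorted) == [frozenset({"A"}), frozenset({"B"})]

    def test_all_essential_without_contingency(self):
        s = synth.generate_random_dependency(4, p_contingent=0.0, p_emergent=0.0, seed=3)
        ess, minimal = ap.exhaustive_minimal_sets(s)
        assert ess == set(s.rotor_ids)
        assert minimal == [frozenset(s.rotor_ids)]


class TestPlannerProperties:
    """Guided search vs brute force across random dependency scripts."""

    N_SCRIPTS = 200

    def test_random_scripts_guided_vs_exhaustive(self):
        rng = np.random.default_rng(123)
        optimal_hits = 0
        for i in range(self.N_SCRIPTS):
            n = int(rng.integers(2, 7))
            script = synth.generate_random_dependency(
                n,
                p_contingent=float(rng.uniform(0.0, 0.8)),
                p_emergent=float(rng.uniform(0.0, 0.5)),
                seed=int(rng.integers(2**31)),
            )
            oracle = ap.script_oracle(script)
            plan = ap.guided_search(oracle)
            assert not plan.final_inducible
            aao = ap.all_at_once(ap.script_oracle(script))
            assert plan.n_lesions <= aao.n_lesions
            essential, minimal = ap.exhaustive_minimal_sets(script)
            assert essential <= set(plan.lesion_ids)
            # probe budget: memoized query count stays within n^2 + 3n
            n_ids = len(script.rotor_ids)
            assert oracle.n_queries <= n_ids**2 + 3 * n_ids
            if minimal:
                best = min(len(m) for m in minimal)
                native_lesions = [
                    r for r in plan.lesion_ids if not script.rotors[r].emergent
                ]
                if len(native_lesions) <= best:
                    optimal_hits += 1
        # logged, not asserted: how often the greedy plan is optimal
        print(f"guided plan optimal in {optimal_hits}/{self.N_SCRIPTS} scripts")

    def test_inconsistent_oracle_detected(self):
        s = synth.builtin_patient_fixture(1)
        # corrupt: suppressed rotor B reappears in a superset
        table = dict(s.induce_table)
        table[frozenset({"A", "C"})] = frozenset({"B"})
        bad = synth.DependencyScript(rotors=s.rotors, induce_table=table)
        with pytest.raises((ap.OracleConsistencyError, ValueError)):
            ap.guided_search(ap.script_oracle(bad))


class TestConnectingLine:
    def _tissue_with_barrier(self):
        from atrialdt import ep_simulator as ep

        fmap = synth.FibrosisMap(np.zeros((167, 167), dtype=np.uint8))
        barriers = np.zeros((167, 167), dtype=bool)
        barriers[:, :4] = True  # barrier along x=0 edge
        with pytest.warns(UserWarning):
            return ep.build_tissue(fmap, barriers=barriers)

    def test_distance_geometry(self):
        tissue = self._tissue_with_barrier()
        lesion = ap.Lesion(shape="disc", center=(30.0, 25.0), diameter=12.0)
        line, dist = ap.connecting_line(lesion, tissue)
        # barrier ends at x~0.9 mm, lesion boundary at x=24 -> ~23 mm
        assert dist == pytest.approx(30.0 - 6.0 - 0.9, abs=1.0)
        assert line.shape == "line"

    def test_touching_barrier_zero_length(self):
        tissue = self._tissue_with_barrier()
        lesion = ap.Lesion(shape="disc", center=(6.0, 25.0), diameter=12.0)
        _, dist = ap.connecting_line(lesion, tissue)
        assert dist <= 0.5

    def test_no_barrier_error(self):
        from atrialdt import ep_simulator as ep

        fmap = synth.FibrosisMap(np.zeros((50, 50), dtype=np.uint8))
        with pytest.warns(UserWarning):
            tissue = ep.build_tissue(fmap)
        with pytest.raises(ValueError):
            ap.connecting_line(ap.Lesion(shape="disc", center=(5.0, 5.0)), tissue)
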