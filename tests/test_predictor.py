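"""Shift database, cascading prediction and tolerance formulas."""
import numpy as np
import pytest

import shiftlearn as sl
from shiftlearn import predictor
from shiftlearn.predictor import ShiftEntry


@pytest.fixture
def ethanol_db(ethanol):
    db = sl.ShiftDatabase()
    ch3 = sl.proton_classes(ethanol)[0]
    sl.add_observation(db, ethanol, ch3.representative, 1.2, iteration=0)
    return db


class TestDatabase:
    def test_one_observation_creates_one_entry_per_radius(self, ethanol_db):
        assert len(ethanol_db) == 3  # radii 2, 3, 4

    def test_duplicate_observation_is_a_noop(self, ethanol, ethanol_db):
        ch3 = sl.proton_classes(ethanol)[0]
        added = sl.add_observation(ethanol_db, ethanol, ch3.representative, 1.2, iteration=4)
        assert added == 0 and len(ethanol_db) == 3

    def test_equivalent_protons_with_equal_shift_deduplicate(self, ethanol):
        db = sl.ShiftDatabase()
        ch3 = sl.proton_classes(ethanol)[0]
        for h in ch3.members[:2]:
            sl.add_observation(db, ethanol, h, 1.2, iteration=0)
        assert len(db) == 3

    def test_same_code_from_distinct_molecules_kept(self, ethanol):
        db = sl.ShiftDatabase()
        other = sl.Molecule.from_smiles("CCO", "ethanol-run2")
        for mol in (ethanol, other):
            ch3 = sl.proton_classes(mol)[0]
            sl.add_observation(db, mol, ch3.representative, 1.2, iteration=0)
        assert len(db) == 6

    def test_sqlite_round_trip(self, ethanol_db, tmp_path):
        path = tmp_path / "shifts.db"
        ethanol_db.save(path)
        loaded = sl.ShiftDatabase.load(path)
        assert loaded.all_entries() == ethanol_db.all_entries()

    def test_tsv_round_trip(self, ethanol_db, tmp_path):
        path = tmp_path / "shifts.tsv"
        ethanol_db.to_tsv(path)
        loaded = sl.ShiftDatabase.from_tsv(path)
        assert loaded.all_entries() == ethanol_db.all_entries()

    def test_non_finite_shift_rejected(self, ethanol):
        db = sl.ShiftDatabase()
        h = ethanol.hydrogen_indices[0]
        with pytest.raises(ValueError):
            sl.add_observation(db, ethanol, h, float("nan"), iteration=0)


class TestPredict:
    def test_empty_database_fails(self, ethanol):
        pred = sl.predict(sl.ShiftDatabase(), ethanol, ethanol.hydrogen_indices[0])
        assert pred.status == "failed" and not pred.ok

    def test_single_match_returns_its_shift(self, ethanol, ethanol_db):
        ch3 = sl.proton_classes(ethanol)[0]
        pred = sl.predict(ethanol_db, ethanol, ch3.representative)
        assert pred.ok
        assert pred.delta_hat == pytest.approx(1.2)
        assert pred.m == 1 and pred.radius_used == 4 and pred.epsilon is None

    def test_single_entry_at_large_radius(self, ethanol):
        # a lone radius-4 observation of 7.394 ppm is returned verbatim
        db = sl.ShiftDatabase()
        code = sl.encode(ethanol, ethanol.hydrogen_indices[0], 4)
        db.add(ShiftEntry(code.code, 4, 7.394, "ref", 0))
        pred = sl.predict(db, ethanol, ethanol.hydrogen_indices[0])
        assert (pred.delta_hat, pred.m, pred.radius_used) == (7.394, 1, 4)

    def test_median_and_std_of_radius_two_matches(self, ethanol):
        db = sl.ShiftDatabase()
        h = sl.proton_classes(ethanol)[0].representative
        code2 = sl.encode(ethanol, h, 2)
        for i, delta in enumerate((7.0, 7.2, 7.6)):
            db.add(ShiftEntry(code2.code, 2, delta, f"m{i}", 0))
        pred = sl.predict(db, ethanol, h)
        assert pred.radius_used == 2 and pred.m == 3
        assert pred.delta_hat == pytest.approx(7.2)
        assert pred.epsilon == pytest.approx(np.std([7.0, 7.2, 7.6], ddof=1))

    def test_cascade_never_consults_smaller_radii_after_a_match(self, ethanol, monkeypatch):
        db = sl.ShiftDatabase()
        h = sl.proton_classes(ethanol)[0].representative
        for r in (2, 4):
            db.add(ShiftEntry(sl.encode(ethanol, h, r).code, r, 1.0 + r, "m", 0))
        consulted = []
        original = sl.ShiftDatabase.lookup

        def spy(self, code, radius):
            consulted.append(radius)
            return original(self, code, radius)

        monkeypatch.setattr(sl.ShiftDatabase, "lookup", spy)
        pred = sl.predict(db, ethanol, h)
        assert consulted == [4]
        assert pred.radius_used == 4 and pred.delta_hat == pytest.approx(5.0)

    def test_repeat_calls_identical(self, ethanol, ethanol_db):
        h = sl.proton_classes(ethanol)[0].representative
        assert sl.predict(ethanol_db, ethanol, h) == sl.predict(ethanol_db, ethanol, h)

    @pytest.mark.parametrize("n", [1, 2, 5, 20, 100])
    def test_median_std_match_brute_force_oracle(self, ethanol, n):
        rng = np.random.default_rng(n)
        deltas = rng.uniform(0, 10, size=n).round(3)
        db = sl.ShiftDatabase()
        h = sl.proton_classes(ethanol)[0].representative
        code = sl.encode(ethanol, h, 4)
        for i, d in enumerate(deltas):
            db.add(ShiftEntry(code.code, 4, float(d), f"m{i}", 0))
        pred = sl.predict(db, ethanol, h)
        assert pred.delta_hat == pytest.approx(np.median(deltas))
        if n >= 2:
            assert pred.epsilon == pytest.approx(np.std(deltas, ddof=1))
        else:
            assert pred.epsilon is None


class TestUncertaintyAndTolerance:
    def test_printed_formula_value(self):
        assert sl.scaled_uncertainty(0.1, 4, 2) == pytest.approx(0.125)

    def test_single_match_rejected(self):
        with pytest.raises(ValueError):
            sl.scaled_uncertainty(0.1, 1, 2)

    def test_strictly_decreasing_towards_epsilon(self):
        values = [sl.scaled_uncertainty(0.1, 4, i) for i in range(0, 12)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(0.1, abs=1e-3)

    def test_low_match_gets_twenty_ppm(self):
        pred = sl.Prediction("ok", delta_hat=1.0, epsilon=None, m=1, radius_used=4)
        for iteration in (0, 3, 9):
            assert sl.assignment_tolerance(pred, iteration) == 20.0

    def test_three_sigma_window(self):
        pred = sl.Prediction("ok", delta_hat=1.0, epsilon=0.1, m=4, radius_used=3)
        assert sl.assignment_tolerance(pred, 2) == pytest.approx(0.375)

    def test_zero_epsilon_hits_the_floor(self):
        pred = sl.Prediction("ok", delta_hat=1.0, epsilon=0.0, m=2, radius_used=2)
        assert sl.assignment_tolerance(pred, 1) == pytest.approx(0.02)
        bare = sl.LearnerConfig(tolerance_floor=0.0)
        assert sl.assignment_tolerance(pred, 1, bare) == 0.0

    def test_configurable_low_match_threshold(self):
        pred = sl.Prediction("ok", delta_hat=1.0, epsilon=0.05, m=2, radius_used=2)
        strict = sl.LearnerConfig(low_match_threshold=3)
        assert sl.assignment_tolerance(pred, 1, strict) == 20.0
        assert sl.assignment_tolerance(pred, 1) < 1.0

    def test_failed_prediction_rejected(self):
        with pytest.raises(ValueError):
            sl.assignment_tolerance(sl.Prediction("failed"), 0)

    def test_tolerance_non_increasing_in_iteration_and_matches(self):
        for m in (2, 4, 9):
            tols = [
                sl.assignment_tolerance(
                    sl.Prediction("ok", 1.0, 0.2, m, 2), i)
                for i in range(8)
            ]
            assert all(a >= b for a, b in zip(tols, tols[1:]))
        for i in (0, 2, 5):
            tols = [
                sl.assignment_tolerance(sl.Prediction("ok", 1.0, 0.2, m, 2), i)
                for m in (2, 3, 5, 9)
            ]
            assert all(a >= b for a, b in zip(tols, tols[1:]))
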