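"""Preprocessing of raw diet records: LW fits, digestion handling, imputation."""

import copy

import numpy as np
import pytest

from ppmr.diet_ingest import (
    DropLog,
    IngestConfig,
    build_mean_mass_table,
    estimate_predator_mass,
    filter_digestion,
    fit_length_weight,
    impute_prey_mass,
    lookup_mean_mass,
    preprocess,
    reconstruct_digested_mass,
)
from ppmr.errors import InsufficientLWDataError, InvalidMeasurementError
from ppmr.records import LengthWeightModel

from conftest import make_predator, make_prey


class TestFitLengthWeight:
    def test_two_points_determine_the_line_exactly(self):
        lw = fit_length_weight([(10, 10), (100, 10000)], min_n=2)
        assert lw.exponent_b == pytest.approx(3.0, abs=1e-12)
        assert lw.coef_a == pytest.approx(0.01, rel=1e-10)
        assert lw.n_fit == 2

    def test_noiseless_cubic_recovered(self):
        pairs = [(L, 0.01 * L ** 3) for L in range(10, 101, 10)]
        lw = fit_length_weight(pairs)
        assert lw.exponent_b == pytest.approx(3.0, abs=1e-9)

    def test_noisy_recovery_within_ols_sampling_error(self, rng):
        L = rng.uniform(10, 200, 500)
        mass = 0.01 * L ** 3.1 * 10 ** rng.normal(0, 0.05, 500)
        lw = fit_length_weight(list(zip(L, mass)))
        assert 3.05 <= lw.exponent_b <= 3.15

    def test_errors(self):
        with pytest.raises(InsufficientLWDataError):
            fit_length_weight([(10, 10)] * 5, min_n=10)
        with pytest.raises(InvalidMeasurementError):
            fit_length_weight([(10, -1)] * 12, min_n=10)


class TestReconstructDigestedMass:
    lw = LengthWeightModel("t", "adult", coef_a=1e-5, exponent_b=3, n_fit=20)

    def test_masses_from_lengths(self):
        prey = make_prey(masses=[], lengths=[50, 60, 70], pct=30, group="fish")
        out = reconstruct_digested_mass(prey, self.lw)
        assert out.individual_masses == pytest.approx([1.25, 2.16, 3.43])
        assert "mass_reconstructed" in out.flags

    def test_not_applied_above_threshold(self):
        prey = make_prey(masses=[], lengths=[100], pct=80, group="fish")
        out = reconstruct_digested_mass(prey, self.lw)
        assert out.individual_masses == []
        assert "mass_reconstructed" not in out.flags

    def test_no_length_flags_for_exclusion(self):
        prey = make_prey(masses=[], pct=30, group="crab")
        out = reconstruct_digested_mass(prey, self.lw)
        assert "no-length-for-reconstruction" in out.flags

    def test_idempotent(self):
        prey = make_prey(masses=[], lengths=[100], pct=30, group="fish")
        once = reconstruct_digested_mass(prey, self.lw)
        masses = list(once.individual_masses)
        twice = reconstruct_digested_mass(once, self.lw)
        assert twice.individual_masses == masses


class TestFilterDigestion:
    def test_boundary_at_threshold(self):
        pred = make_predator(prey=[
            make_prey(taxon="a", pct=74.9),
            make_prey(taxon="b", pct=75.0),
        ])
        kept, log = filter_digestion([pred])
        assert [p.prey_taxon for p in kept[0].prey] == ["b"]
        assert [e.reason for e in log.entries] == ["digested"]

    def test_emptied_predator_removed_and_logged(self):
        pred = make_predator(prey=[make_prey(pct=10)])
        kept, log = filter_digestion([pred])
        assert kept == []
        reasons = {e.reason for e in log.entries}
        assert "no-prey-after-digestion-filter" in reasons

    def test_reconstructed_prey_survive(self):
        prey = make_prey(masses=[2.0], pct=30)
        prey.flags.add("mass_reconstructed")
        kept, _ = filter_digestion([make_predator(prey=[prey])])
        assert len(kept[0].prey) == 1


class TestImputePreyMass:
    def test_count_and_total_divides(self):
        prey = make_prey(masses=[], count=50, total=5.0)
        out = impute_prey_mass(prey)
        assert len(out.individual_masses) == 50
        assert sum(out.individual_masses) == pytest.approx(5.0, rel=1e-9)
        assert out.individual_masses[0] == pytest.approx(0.1)

    def test_total_only_imputes_count_and_preserves_biomass(self):
        prey = make_prey(masses=[], total=1.0)
        out = impute_prey_mass(prey, mean_mass=0.12)
        assert out.count == 8                      # round(1.0 / 0.12)
        assert out.individual_masses == pytest.approx([0.125] * 8)
        assert sum(out.individual_masses) == pytest.approx(1.0)
        assert "count_imputed" in out.flags

    def test_degenerate_single_individual_keeps_recorded_total(self):
        prey = make_prey(masses=[], total=0.05)
        out = impute_prey_mass(prey, mean_mass=0.12)
        assert out.count == 1
        assert out.individual_masses == [0.05]

    def test_unresolvable_without_table_entry(self):
        prey = make_prey(masses=[], total=1.0)
        out = impute_prey_mass(prey, mean_mass=None)
        assert "unresolvable" in out.flags


class TestMeanMassTable:
    def test_regional_then_global_fallback(self):
        p1 = make_predator(region="regA", prey=[
            make_prey(taxon="cope", count=10, total=1.0, masses=[]),
        ])
        p2 = make_predator(pid="p2", region="regB", prey=[
            make_prey(taxon="cope", count=10, total=3.0, masses=[]),
        ])
        table = build_mean_mass_table([p1, p2])
        assert lookup_mean_mass(table, "cope", "adult", "regA") == pytest.approx(0.1)
        # unseen region falls back to the pooled mean (4 g / 20)
        assert lookup_mean_mass(table, "cope", "adult", "regZ") == pytest.approx(0.2)
        assert lookup_mean_mass(table, "nope", "adult", "regA") is None


class TestEstimatePredatorMass:
    lw = LengthWeightModel("sp1", coef_a=0.01, exponent_b=3, n_fit=30)

    def test_cubic_backcalculation(self):
        pred = make_predator(mass=None, length=40.0)
        out = estimate_predator_mass(pred, self.lw)
        assert out.body_mass == pytest.approx(640.0)
        assert "mass_estimated" in out.flags

    def test_existing_mass_untouched(self):
        pred = make_predator(mass=123.0, length=40.0)
        assert estimate_predator_mass(pred, self.lw).body_mass == 123.0

    def test_zero_length_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            estimate_predator_mass(make_predator(mass=None, length=0.0), self.lw)


class TestPreprocess:
    def _sample(self):
        preds = []
        # enough intact fish with both length and mass for an LW fit
        for i in range(12):
            L = 50 + 10 * i
            preds.append(make_predator(
                pid=f"f{i}", mass=500.0,
                prey=[make_prey(taxon="smelt", masses=[1e-5 * L ** 3],
                                lengths=[L], pct=90, group="fish")],
            ))
        # a digested fish with length only: reconstructable
        preds.append(make_predator(pid="dig", mass=800.0, prey=[
            make_prey(taxon="smelt", masses=[], lengths=[100], pct=40, group="fish"),
        ]))
        # a digested invert without length: dropped
        preds.append(make_predator(pid="gone", mass=800.0, prey=[
            make_prey(taxon="cope", masses=[], pct=40, group="other_invert"),
        ]))
        # aggregated invert record (count+total) and a total-only one
        preds.append(make_predator(pid="agg", mass=300.0, prey=[
            make_prey(taxon="cope", masses=[], count=20, total=2.0,
                      group="other_invert"),
            make_prey(taxon="cope", stage="adult", masses=[], total=0.5,
                      group="other_invert"),
        ]))
        # predator with length only; species shared with the 12 above
        preds.append(make_predator(pid="lenonly", mass=None, length=30.0, prey=[
            make_prey(taxon="smelt", masses=[2.0], lengths=[58], pct=95,
                      group="fish"),
        ]))
        for i in range(12):  # length-weight pairs for the predator species
            preds.append(make_predator(
                pid=f"plw{i}", mass=0.01 * (20 + i) ** 3, length=float(20 + i),
                prey=[make_prey(taxon="smelt", masses=[1.0], pct=90, group="fish")],
            ))
        return preds

    def test_chain_resolves_and_logs(self):
        clean, log = preprocess(self._sample())
        ids = {p.predator_id for p in clean}
        assert "dig" in ids          # reconstructed from length
        assert "gone" not in ids     # digested, no length
        assert "lenonly" in ids
        lenonly = next(p for p in clean if p.predator_id == "lenonly")
        assert lenonly.body_mass == pytest.approx(0.01 * 30 ** 3, rel=0.05)
        agg = next(p for p in clean if p.predator_id == "agg")
        assert all(p.individual_masses for p in agg.prey)
        reasons = [e.reason for e in log.entries]
        assert "digested" in reasons

    def test_idempotent_and_monotone(self):
        preds = self._sample()
        once, log1 = preprocess(preds)
        twice, log2 = preprocess(once)
        assert len(once) <= len(preds)
        assert len(twice) == len(once)
        assert len(log2) == 0
        for a, b in zip(once, twice):
            assert a.body_mass == pytest.approx(b.body_mass)
            for pa, pb in zip(a.prey, b.prey):
                assert pa.individual_masses == pytest.approx(pb.individual_masses)

    def test_input_not_mutated(self):
        preds = self._sample()
        snapshot = copy.deepcopy(preds)
        preprocess(preds)
        assert all(
            [q.individual_masses for q in p.prey]
            == [q.individual_masses for q in s.prey]
            for p, s in zip(preds, snapshot)
        )

    def test_every_drop_logged_once(self):
        _, log = preprocess(self._sample())
        keys = [(e.record_id, e.reason) for e in log.entries]
        assert len(keys) == len(set(keys))
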