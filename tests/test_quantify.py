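"""Filtering, summary statistics and copy-number interpolation."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cosiquant as cq
from cosiquant.config import DEFAULT_R2_THRESHOLDS
from cosiquant.reference import CULTURE_VESICLE_COUNTS


def _record(r2_marker, r2_az, r2_poi, converged=True):
    cand = cq.SpotCandidate(10, 10, 1.0, "f", 0)
    fits = {}
    for role, r2 in zip(cq.SYNAPSE_ROLES, (r2_marker, r2_az, r2_poi)):
        fits[role] = cq.GaussianFit(
            x0_px=10.0, y0_px=10.0, sigma_major_px=2.0, sigma_minor_px=2.0,
            theta_rad=0.0, amplitude=10.0, offset=0.0,
            integrated_intensity=2 * math.pi * 40.0, r2=r2,
            converged=converged, channel_role=role,
        )
    return cq.SynapseRecord(cand, fits)


class TestFilterRecords:
    @pytest.mark.parametrize(
        "triple,expect,reason",
        [
            ((0.90, 0.75, 0.65), True, None),
            ((0.84, 0.99, 0.99), False, "marker"),
            ((0.85, 0.70, 0.60), True, None),  # thresholds are inclusive
            ((0.99, 0.69, 0.59), False, "active_zone,poi"),
        ],
    )
    def test_threshold_triples(self, config, triple, expect, reason):
        rec = cq.filter_records([_record(*triple)], config)[0]
        assert rec.accepted is expect
        assert rec.reject_reason == reason

    def test_nonconverged_fit_always_rejected(self, config):
        rec = cq.filter_records([_record(0.99, 0.99, 0.99, converged=False)], config)[0]
        assert rec.accepted is False

    @given(
        r2s=st.tuples(*([st.floats(0.0, 1.0)] * 3)),
    )
    @settings(derandomize=True, max_examples=200)
    def test_randomized_triples_match_predicate_oracle(self, r2s):
        config = cq.PipelineConfig()
        rec = cq.filter_records([_record(*r2s)], config)[0]
        oracle = (
            r2s[0] >= DEFAULT_R2_THRESHOLDS["marker"]
            and r2s[1] >= DEFAULT_R2_THRESHOLDS["active_zone"]
            and r2s[2] >= DEFAULT_R2_THRESHOLDS["poi"]
        )
        assert rec.accepted is oracle

    def test_tightening_thresholds_never_accepts_more(self, rng):
        records = [_record(*rng.uniform(0, 1, 3)) for _ in range(300)]
        base = cq.PipelineConfig()
        n_base = sum(r.accepted for r in cq.filter_records(records, base))
        for role in cq.SYNAPSE_ROLES:
            thr = dict(DEFAULT_R2_THRESHOLDS)
            thr[role] = min(1.0, thr[role] + 0.1)
            tight = dataclasses.replace(base, r2_thresholds=thr)
            assert sum(r.accepted for r in cq.filter_records(records, tight)) <= n_base


class TestMeanSem:
    def test_vesicle_counts_reproduce_published_summary(self):
        mean, sem = cq.mean_sem(CULTURE_VESICLE_COUNTS)
        assert round(mean) == 250
        assert round(sem) == 26

    def test_constant_sample_has_zero_sem(self):
        assert cq.mean_sem([5, 5, 5, 5]) == (5.0, 0.0)

    def test_hand_computed_example(self):
        mean, sem = cq.mean_sem([1, 2, 3])
        assert mean == pytest.approx(2.0)
        assert sem == pytest.approx(1.0 / math.sqrt(3), abs=1e-4)  # 0.5774

    def test_empty_list_raises(self):
        with pytest.raises(cq.DomainError):
            cq.mean_sem([])


class TestCopyNumbers:
    def test_identity_ratio_gives_reference_copies(self, rng):
        ints = rng.uniform(100, 1000, 50)
        est = cq.estimate_copy_numbers([ints.mean()], ints, 1000.0)
        assert est.mean_copies == pytest.approx(1000.0)

    def test_half_intensity_halves_reference(self):
        # a synapse at half the mean synaptosome intensity, against the
        # synapsin reference of 23422.77 copies per synaptosome
        est = cq.estimate_copy_numbers([50.0], [100.0], 23422.77, target="Synapsin1/2")
        assert est.per_synapse_copies == (pytest.approx(11711.385),)
        assert est.mean_copies == pytest.approx(11711.385)

    @given(scale=st.floats(1e-3, 1e3))
    @settings(derandomize=True, max_examples=50)
    def test_scale_equivariance(self, scale):
        syn = [120.0, 90.0, 150.0]
        ref = [200.0, 210.0, 190.0, 205.0]
        a = cq.estimate_copy_numbers(syn, ref, 500.0)
        b = cq.estimate_copy_numbers(
            [s * scale for s in syn], [r * scale for r in ref], 500.0
        )
        assert b.mean_copies == pytest.approx(a.mean_copies, rel=1e-9)

    def test_nonpositive_reference_mean_raises(self):
        with pytest.raises(cq.DomainError):
            cq.estimate_copy_numbers([1.0], [0.0, 0.0], 100.0)
        with pytest.raises(cq.DomainError):
            cq.estimate_copy_numbers([1.0], [10.0], -5.0)

    def test_sem_matches_mean_sem_of_per_synapse_values(self, rng):
        syn = rng.uniform(50, 150, 40)
        est = cq.estimate_copy_numbers(syn, [100.0] * 10, 2000.0)
        mean, sem = cq.mean_sem(est.per_synapse_copies)
        assert est.mean_copies == pytest.approx(mean)
        assert est.sem_copies == pytest.approx(sem)


class TestAntibodiesPerStructure:
    def test_unit_and_threefold(self):
        out = cq.antibodies_per_structure([100.0, 300.0, 0.0], 100.0)
        np.testing.assert_allclose(out, [1.0, 3.0, 0.0])

    def test_nonpositive_calibration_raises(self):
        with pytest.raises(cq.DomainError):
            cq.antibodies_per_structure([1.0], 0.0)


class TestRegression:
    def test_identity_line(self):
        slope, r2 = cq.compare_measured_vs_estimated([1, 2, 3, 5.0], [1, 2, 3, 5.0])
        assert slope == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_exact_doubling(self):
        x = [1.0, 2, 3, 4, 5]
        slope, r2 = cq.compare_measured_vs_estimated([2 * v for v in x], x)
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_noisy_slope_recovered(self, rng):
        x = np.linspace(1, 10, 100)
        y = 1.3 * x + rng.normal(0, 0.05, 100)
        slope, r2 = cq.compare_measured_vs_estimated(y, x)
        assert slope == pytest.approx(1.3, abs=0.02)
        assert r2 > 0.99

    def test_length_mismatch(self):
        with pytest.raises(cq.DomainError):
            cq.compare_measured_vs_estimated([1.0, 2.0], [1.0])
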