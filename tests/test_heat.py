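import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermotee import heat
from thermotee.heat import (
    EmptyPartitionError,
    MaterialSpec,
    bare_skin_mask,
    correct_occluded,
    estimate_flux,
    kmeans_1d,
    partition_and_correct,
    thermal_resistance,
)
from thermotee.io import PATIENT, LabelMask, ThermalFrame
from thermotee.phantom import default_spec, generate_phantom

from _oracles import dec_radiative_power, dp_kmeans_1d_wcss


def _uniform_scene(patient_temp=36.0, shape=(12, 12)):
    temps = np.full(shape, 22.0)
    labels = np.zeros(shape, dtype=np.uint8)
    labels[3:9, 3:9] = PATIENT
    temps[3:9, 3:9] = patient_temp
    return ThermalFrame(temps=temps, ambient_c=22.0), LabelMask(labels=labels)


class TestKmeans1d:
    def test_separated_clusters_split_perfectly(self):
        vals = np.array([30.0, 30, 30, 36, 36, 36])
        labels, cents = kmeans_1d(vals, k=2, seed=0)
        np.testing.assert_allclose(cents, [36.0, 30.0])
        np.testing.assert_array_equal(labels, [1, 1, 1, 0, 0, 0])

    def test_k1_returns_mean(self):
        vals = np.array([1.0, 2.0, 6.0])
        _, cents = kmeans_1d(vals, k=1)
        assert cents[0] == pytest.approx(3.0)

    def test_matches_dp_optimum_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            n = int(rng.integers(5, 51))
            k = int(rng.integers(1, 5))
            vals = rng.normal(30, 4, size=n)
            labels, cents = kmeans_1d(vals, k=min(k, n), seed=int(rng.integers(1000)))
            wcss = sum(((vals[labels == c] - vals[labels == c].mean()) ** 2).sum()
                       for c in np.unique(labels))
            assert wcss == pytest.approx(dp_kmeans_1d_wcss(vals, min(k, n)), rel=1e-9, abs=1e-9)

    def test_fewer_distinct_values_reduces_k(self):
        with pytest.warns(UserWarning, match="distinct"):
            labels, cents = kmeans_1d(np.array([5.0, 5.0, 5.0, 7.0]), k=3)
        assert len(cents) == 2

    @given(
        st.lists(st.floats(min_value=-40, max_value=120, allow_nan=False),
                 min_size=3, max_size=40),
        st.integers(min_value=1, max_value=4),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_clusters_are_contiguous_intervals(self, vals, k):
        vals = np.asarray(vals)
        k = min(k, len(vals))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels, cents = kmeans_1d(vals, k)
        # in sorted order labels must be monotone (label 0 = warmest)
        lab_sorted = labels[np.argsort(vals, kind="stable")]
        assert (np.diff(lab_sorted) <= 0).all()
        assert list(cents) == sorted(cents, reverse=True)

    def test_centroids_descending_warmest_is_zero(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(25, 0.5, 30), rng.normal(36, 0.5, 30)])
        labels, cents = kmeans_1d(vals, k=2, seed=1)
        assert cents[0] > cents[1]
        assert vals[labels == 0].min() > vals[labels == 1].max()


class TestBareSkinMask:
    def test_uniform_patient_entirely_bare(self):
        frame, mask = _uniform_scene()
        with pytest.warns(UserWarning):
            part = bare_skin_mask(frame, mask, k=2)
        np.testing.assert_array_equal(part.bare_mask, mask.labels == PATIENT)
        assert not part.covered_mask.any()

    def test_noiseless_phantom_recovers_truth_bare_mask(self, noiseless_phantom):
        frame, truth = noiseless_phantom
        part = bare_skin_mask(frame, truth.mask, k=2)
        np.testing.assert_array_equal(part.bare_mask, truth.bare_mask)

    def test_three_pixel_patient(self):
        temps = np.full((8, 8), 20.0)
        labels = np.zeros((8, 8), dtype=np.uint8)
        for i, t in zip(range(3), (30.0, 30.5, 36.0)):
            labels[4, 2 + i] = PATIENT
            temps[4, 2 + i] = t
        part = bare_skin_mask(ThermalFrame(temps=temps), LabelMask(labels=labels), k=2)
        assert part.bare_mask.sum() + part.covered_mask.sum() == 3

    def test_no_patient_pixels_errors(self):
        frame, _ = _uniform_scene()
        with pytest.raises(EmptyPartitionError):
            bare_skin_mask(frame, LabelMask(np.zeros((12, 12), np.uint8)), k=2)

    def test_hot_spot_guard_merges_tiny_warm_cluster(self):
        frame, mask = _uniform_scene(patient_temp=33.0)
        t = frame.temps.copy()
        t[3, 3] = 41.0  # single artifact pixel, ~3% of the 36 patient pixels
        part = bare_skin_mask(ThermalFrame(temps=t, ambient_c=22.0), mask, k=2)
        assert "cluster-guard" in part.flags
        np.testing.assert_array_equal(part.bare_mask, mask.labels == PATIENT)

    def test_partition_permutation_invariant(self, noiseless_phantom):
        # clustering depends only on the multiset of temperatures, so the
        # partition must be identical for any pixel ordering; rerunning with
        # a different seed must give the same split on well-separated data
        frame, truth = noiseless_phantom
        p1 = bare_skin_mask(frame, truth.mask, k=2, seed=0)
        p2 = bare_skin_mask(frame, truth.mask, k=2, seed=123)
        np.testing.assert_array_equal(p1.bare_mask, p2.bare_mask)


class TestOcclusionCorrection:
    def test_zero_resistance_identity(self):
        assert correct_occluded(31.0, 50.0, MaterialSpec("x", 0.0)) == 31.0

    def test_known_arithmetic(self):
        assert correct_occluded(31.0, 50.0, MaterialSpec("x", 0.1)) == pytest.approx(36.0)

    def test_forward_inverse_consistency_machine_precision(self, material):
        spec = default_spec(noise_sd_c=0.0, seed=8, tube=None, screen=None)
        frame, truth = generate_phantom(spec)
        part = partition_and_correct(frame, truth.mask, material, k=2)
        covered = part.covered_mask
        assert covered.any()
        np.testing.assert_allclose(
            part.corrected_c[covered], truth.skin_field_c[covered], rtol=0, atol=1e-10
        )

    def test_negative_resistance_rejected(self):
        with pytest.raises(ValueError):
            MaterialSpec("bad", -0.1)


class TestFluxAndResistance:
    def test_flux_zero_when_bare_equals_ambient(self):
        frame, mask = _uniform_scene(patient_temp=22.0)
        part = heat.HeatPartition(
            bare_mask=mask.labels == PATIENT,
            covered_mask=np.zeros_like(mask.labels, dtype=bool), centroids=[22.0],
        )
        assert estimate_flux(frame, part, ambient_c=22.0) == pytest.approx(0.0)

    def test_flux_closed_form(self):
        frame, mask = _uniform_scene(patient_temp=36.5)
        part = heat.HeatPartition(
            bare_mask=mask.labels == PATIENT,
            covered_mask=np.zeros_like(mask.labels, dtype=bool), centroids=[36.5],
        )
        got = estimate_flux(frame, part, ambient_c=24.0)
        assert got == pytest.approx(float(dec_radiative_power(36.5, 24.0)), rel=1e-12)

    def test_flux_monotone_in_bare_mean(self):
        fluxes = []
        for t in (30.0, 33.0, 36.0):
            frame, mask = _uniform_scene(patient_temp=t)
            part = heat.HeatPartition(
                bare_mask=mask.labels == PATIENT,
                covered_mask=np.zeros_like(mask.labels, dtype=bool), centroids=[t],
            )
            fluxes.append(estimate_flux(frame, part, ambient_c=24.0))
        assert fluxes[0] < fluxes[1] < fluxes[2]

    def test_empty_bare_mask_errors(self):
        frame, _ = _uniform_scene()
        part = heat.HeatPartition(
            bare_mask=np.zeros(frame.shape, dtype=bool),
            covered_mask=np.zeros(frame.shape, dtype=bool), centroids=[],
        )
        with pytest.raises(EmptyPartitionError):
            estimate_flux(frame, part, ambient_c=22.0)

    def test_material_table_loads(self, tmp_path):
        p = tmp_path / "materials.csv"
        p.write_text("# name, r_t\nfleece-blanket,0.15\ngauze,0.02\n")
        table = heat.load_material_table(p)
        assert table["gauze"].r_t == 0.02 and table["fleece-blanket"].r_t == 0.15

    def test_resistance_arithmetic_and_scaling(self):
        assert thermal_resistance(5.0, 0.01, 0.5).r_t == pytest.approx(0.1)
        assert thermal_resistance(0.0, 0.01, 0.5).r_t == 0.0
        assert thermal_resistance(5.0, 0.01, 1.0).r_t == pytest.approx(
            thermal_resistance(5.0, 0.01, 0.5).r_t / 2
        )
        with pytest.raises(ValueError):
            thermal_resistance(5.0, 0.01, 0.0)
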