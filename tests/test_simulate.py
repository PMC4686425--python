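"""Ground-truth contracts of the synthetic-data generators."""

import numpy as np
import pytest

from kogbody import simulate as sim


class TestSimulateLane:
    def test_fully_phosphorylated_mass_at_top_band(self):
        spec = sim.LaneSimSpec(phospho_fraction=1.0, noise_sd=0.0)
        lane = sim.simulate_lane(spec)
        com = np.average(np.arange(spec.n_pixels), weights=lane.intensities)
        assert com == pytest.approx(spec.band_top_center, abs=1e-6)

    def test_unphosphorylated_mass_at_bottom_band(self):
        spec = sim.LaneSimSpec(phospho_fraction=0.0, noise_sd=0.0)
        lane = sim.simulate_lane(spec)
        com = np.average(np.arange(spec.n_pixels), weights=lane.intensities)
        assert com == pytest.approx(spec.band_bottom_center, abs=1e-6)

    def test_half_fraction_splits_mass_symmetrically(self):
        spec = sim.LaneSimSpec(phospho_fraction=0.5, noise_sd=0.0)
        lane = sim.simulate_lane(spec)
        mid = (spec.band_top_center + spec.band_bottom_center) / 2
        x = np.arange(spec.n_pixels)
        assert lane.intensities[x < mid].sum() == pytest.approx(
            lane.intensities[x > mid].sum(), rel=1e-9
        )

    @pytest.mark.parametrize("fraction", [0.0, 0.3, 1.0])
    def test_noiseless_integral_conservation(self, fraction):
        spec = sim.LaneSimSpec(phospho_fraction=fraction, noise_sd=0.0)
        assert sim.simulate_lane(spec).total == pytest.approx(
            spec.total_signal, rel=1e-6
        )

    def test_noise_never_produces_negative_intensity(self):
        lane = sim.simulate_lane(sim.LaneSimSpec(noise_sd=50.0, seed=3))
        assert np.all(lane.intensities >= 0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            sim.LaneSimSpec(band_top_center=70, band_bottom_center=30)
        with pytest.raises(ValueError):
            sim.LaneSimSpec(phospho_fraction=1.5)

    def test_reproducible_bitwise(self):
        a = sim.simulate_lane(sim.LaneSimSpec(noise_sd=5.0, seed=9))
        b = sim.simulate_lane(sim.LaneSimSpec(noise_sd=5.0, seed=9))
        assert np.array_equal(a.intensities, b.intensities)


class TestSimulateTimecourse:
    def test_flat_zero_baseline_all_counts_zero(self):
        ds = sim.simulate_timecourse(
            sim.TimecourseSimSpec(model="flat", A=0.0, c=0.0, seed=1)
        )
        assert all(p.n_with_bodies == 0 for rep in ds.replicates for p in rep)

    def test_formation_p_at_time_zero_is_baseline(self):
        spec = sim.TimecourseSimSpec(A=0.49, tau=11.0, c=0.08)
        assert spec.p([0.0])[0] == pytest.approx(0.08)

    def test_empirical_fractions_within_binomial_error(self, formation_truth):
        spec = sim.TimecourseSimSpec(
            n_cells_per_timepoint=10_000, n_replicates=1, seed=5, **formation_truth
        )
        ds = sim.simulate_timecourse(spec)
        p = spec.p(spec.timepoints)
        frac = np.array([pt.fraction for pt in ds.replicates[0]])
        tol = 3 * np.sqrt(p * (1 - p) / 10_000)
        assert np.all(np.abs(frac - p) <= tol)

    def test_probability_overflow_rejected(self):
        with pytest.raises(ValueError):
            sim.TimecourseSimSpec(A=0.8, c=0.3)

    def test_adding_replicates_preserves_earlier_streams(self):
        a = sim.simulate_timecourse(sim.TimecourseSimSpec(n_replicates=2, seed=4))
        b = sim.simulate_timecourse(sim.TimecourseSimSpec(n_replicates=3, seed=4))
        assert a.replicates == b.replicates[:2]

    def test_truth_recorded(self):
        spec = sim.TimecourseSimSpec(seed=2)
        assert sim.simulate_timecourse(spec).truth is spec


class TestSimulateSequence:
    def test_default_background_has_no_qn(self):
        out = sim.simulate_sequence(sim.SequenceSimSpec(length=50, seed=0))
        assert not set(out.sequence.residues) & {"Q", "N"}
        assert out.motifs == []

    def test_pure_qn_insertion(self):
        out = sim.simulate_sequence(
            sim.SequenceSimSpec(length=50, motif_insertions=((10, 20, 1.0),), seed=0)
        )
        assert set(out.sequence.residues[10:30]) <= {"Q", "N"}

    def test_planted_qn_count_follows_rounding_rule(self):
        out = sim.simulate_sequence(
            sim.SequenceSimSpec(length=100, motif_insertions=((20, 34, 0.5),), seed=1)
        )
        segment = out.sequence.residues[20:54]
        assert sum(r in "QN" for r in segment) == 17

    def test_overlapping_insertions_rejected(self):
        with pytest.raises(ValueError):
            sim.SequenceSimSpec(length=100, motif_insertions=((10, 20, 0.5), (25, 20, 0.5)))

    def test_reproducible_bitwise(self):
        spec = sim.SequenceSimSpec(length=80, motif_insertions=((10, 30, 0.7),), seed=6)
        assert (
            sim.simulate_sequence(spec).sequence.residues
            == sim.simulate_sequence(spec).sequence.residues
        )


class TestSimulateCellStack:
    def test_no_bodies_when_probability_zero(self):
        field = sim.simulate_cell_stack(
            sim.CellImageSimSpec(n_cells=9, body_probability=0.0, seed=0)
        )
        assert field.truth.empty
        assert field.n_body_positive == 0

    def test_exactly_one_focus_per_cell_at_probability_one(self):
        field = sim.simulate_cell_stack(
            sim.CellImageSimSpec(
                n_cells=16, body_probability=1.0,
                bodies_per_cell_weights=((1, 1.0),), seed=0,
            )
        )
        foci = field.truth[field.truth.channel == "foci"]
        assert len(foci) == 16
        assert sorted(foci.cell_id) == list(range(1, 17))

    def test_planted_positive_fraction_within_binomial_error(self):
        n, p = 500, 0.57
        field = sim.simulate_cell_stack(
            sim.CellImageSimSpec(n_cells=n, body_probability=p, background_sd=0.0, seed=7)
        )
        tol = 3 * np.sqrt(p * (1 - p) / n)
        assert abs(field.planted_fraction - p) <= tol

    def test_foci_lie_in_annulus_outside_membrane_ring(self):
        spec = sim.CellImageSimSpec(n_cells=25, body_probability=1.0, seed=2)
        field = sim.simulate_cell_stack(spec)
        pitch = spec.cell_pitch_px
        n_side = int(np.ceil(np.sqrt(spec.n_cells)))
        for row in field.truth[field.truth.channel == "foci"].itertuples():
            r, c = divmod(row.cell_id - 1, n_side)
            cy, cx = r * pitch + pitch / 2, c * pitch + pitch / 2
            dist = np.hypot(row.y - cy, row.x - cx)
            assert spec.membrane_ring_radius + 1.5 <= dist <= spec.membrane_ring_radius + 3.5

    def test_cell_map_labels_every_cell(self):
        field = sim.simulate_cell_stack(sim.CellImageSimSpec(n_cells=12, seed=1))
        labels = set(np.unique(field.cell_map)) - {0}
        assert labels == set(range(1, 13))

    def test_reproducible_bitwise(self):
        spec = sim.CellImageSimSpec(n_cells=9, seed=5)
        a = sim.simulate_cell_stack(spec)
        b = sim.simulate_cell_stack(spec)
        assert np.array_equal(a.stack.voxels, b.stack.voxels)
        assert a.truth.equals(b.truth)
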