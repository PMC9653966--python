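import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leda_ms import (
    MeasuredRatios,
    MRMTrace,
    RatioTable,
    TransitionDescriptor,
    assemble_leda_matrix,
    compute_characteristic_ratios,
    deconvolve,
    deconvolve_scanwise,
    integrate_peak,
    peak_purity,
)
from leda_ms.synth import SynthConfig, generate_mixture_sample, generate_pure_sample


def two_by_two_oracle(matrix, b):
    """Closed-form analytic inversion of a 2x2 linear system."""
    (a11, a12), (a21, a22) = matrix
    det = a11 * a22 - a12 * a21
    return np.array([(a22 * b[0] - a12 * b[1]) / det, (a11 * b[1] - a21 * b[0]) / det])


class TestAssembleMatrix:
    def test_printed_two_equation_matrix(self, fra_table):
        matrix = assemble_leda_matrix(fra_table, ["221/590", "195/590"])
        np.testing.assert_array_equal(matrix, [[1.30, 0.60], [0.09, 0.64]])

    def test_all_transitions_give_six_by_two(self, elf_table):
        assert assemble_leda_matrix(elf_table).shape == (6, 2)

    def test_identical_columns_raise_singularity_naming_pair(self):
        table = RatioTable(
            ["A", "B"], ["x", "y"], [[1.0, 1.0], [0.5, 0.5]], np.zeros((2, 2))
        )
        with pytest.raises(np.linalg.LinAlgError, match="'A' and 'B'"):
            assemble_leda_matrix(table)

    def test_underdetermined_rejected(self, fra_table):
        with pytest.raises(ValueError, match="under-determined"):
            assemble_leda_matrix(fra_table, ["221/590"])

    def test_unknown_transition_rejected(self, fra_table):
        with pytest.raises(KeyError):
            assemble_leda_matrix(fra_table, ["999/590", "195/590"])


class TestDeconvolve:
    def test_equal_mixture_recovered_exactly(self, fra_table):
        matrix = assemble_leda_matrix(fra_table, ["221/590", "195/590"])
        measured = MeasuredRatios(["221/590", "195/590"], matrix @ [0.5, 0.5])
        result = deconvolve(measured, matrix, fra_table.isomer_ids)
        assert result.fractions["FRA76"] == pytest.approx(0.5, abs=1e-12)
        assert result.fractions["GDE5"] == pytest.approx(0.5, abs=1e-12)
        assert result.residual_norm < 1e-12

    def test_pure_column_is_identity_case(self, elf_table):
        matrix = assemble_leda_matrix(elf_table)
        measured = MeasuredRatios(
            list(elf_table.transition_labels), elf_table.column("ELF94")
        )
        result = deconvolve(measured, matrix, elf_table.isomer_ids)
        assert result.fractions["ELF94"] == pytest.approx(1.0, abs=1e-12)
        assert result.fractions["ELF96"] == pytest.approx(0.0, abs=1e-12)

    def test_overdetermined_90_10(self, elf_table):
        matrix = assemble_leda_matrix(elf_table)
        measured = MeasuredRatios(
            list(elf_table.transition_labels), matrix @ [0.9, 0.1]
        )
        result = deconvolve(measured, matrix, elf_table.isomer_ids)
        assert result.fractions["ELF94"] == pytest.approx(0.9, abs=1e-12)
        assert result.residual_norm < 1e-12

    def test_negative_measured_rejected(self, fra_table):
        matrix = assemble_leda_matrix(fra_table, ["221/590", "195/590"])
        with pytest.raises(ValueError, match="non-negative"):
            deconvolve(
                MeasuredRatios(["221/590", "195/590"], [-0.1, 0.5]),
                matrix,
                fra_table.isomer_ids,
            )

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        entries=st.lists(
            st.floats(min_value=0.01, max_value=2.0), min_size=4, max_size=4
        ),
        w=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_2x2_agrees_with_analytic_inversion(self, entries, w):
        """Unconstrained solve matches closed-form 2x2 inversion to 1e-10."""
        matrix = np.array(entries).reshape(2, 2)
        if np.linalg.cond(matrix) > 1e6:
            return
        b = matrix @ [w, 1 - w]
        expected = two_by_two_oracle(matrix, b)
        result = deconvolve(
            MeasuredRatios(["p", "q"], b), matrix, ["A", "B"], nonneg=False
        )
        np.testing.assert_allclose(result.raw_solution, expected, atol=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        seed=st.integers(min_value=0, max_value=10_000),
        w=st.floats(min_value=0.0, max_value=1.0),
        rows=st.integers(min_value=2, max_value=8),
    )
    def test_exact_weight_recovery_on_random_tables(self, seed, w, rows):
        """Forward-constructed measurements invert to the generating weights."""
        rng = np.random.default_rng(seed)
        matrix = rng.uniform(0.01, 2.0, size=(rows, 2))
        if np.linalg.cond(matrix) > 1e6:
            return
        weights = np.array([w, 1 - w])
        b = matrix @ weights
        result = deconvolve(
            MeasuredRatios([f"r{i}" for i in range(rows)], b), matrix, ["A", "B"]
        )
        np.testing.assert_allclose(result.raw_solution, weights, atol=1e-9)
        assert result.residual_norm < 1e-9


class TestIntegratePeak:
    def _trace(self, times, intensities):
        desc = TransitionDescriptor("t", 604.0, 221.0, 25.0, "Pi")
        return MRMTrace(desc, times, intensities, "s")

    def test_rectangle(self):
        trace = self._trace([0.0, 0.5, 1.0], [10.0, 10.0, 10.0])
        assert integrate_peak(trace, (0.0, 1.0)) == pytest.approx(10.0)

    def test_gaussian_area_matches_closed_form(self):
        area, rt, sigma = 250.0, 1.8, 0.025
        t = np.arange(0.0, 3.6, 0.002)
        y = area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
        got = integrate_peak(self._trace(t, y), (0.0, 3.6))
        assert got == pytest.approx(area, rel=1e-6)

    def test_window_outside_domain_rejected(self):
        trace = self._trace([0.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="does not overlap"):
            integrate_peak(trace, (2.0, 3.0))

    def test_partial_window_continuous(self):
        trace = self._trace([0.0, 1.0], [10.0, 10.0])
        assert integrate_peak(trace, (0.25, 0.75)) == pytest.approx(5.0)


class TestCharacteristicRatios:
    def test_noise_free_pure_sample_reproduces_table_column(self, elf_table):
        config = SynthConfig(seed=1, noise_cv=0.0, ratio_table=elf_table)
        rec = generate_pure_sample(config, "ELF94", 100.0)
        column = compute_characteristic_ratios(rec, (0.0, 3.6), "ELF94")
        assert column.transition_labels == list(elf_table.transition_labels)
        np.testing.assert_allclose(
            column.ratios[:, 0], elf_table.column("ELF94"), rtol=1e-6
        )

    def test_printed_fra76_ratio_from_noisy_replicates(self, fra_table):
        config = SynthConfig(seed=21, noise_cv=0.02, ratio_table=fra_table)
        rng = config.rng()
        recs = [
            generate_pure_sample(config, "FRA76", 100.0, f"rep{i}", rng=rng)
            for i in range(6)
        ]
        column = compute_characteristic_ratios(recs, (0.0, 3.6), "FRA76")
        i221 = column.transition_labels.index("221/590")
        assert column.ratios[i221, 0] == pytest.approx(1.30, abs=0.10)
        assert column.ratio_sds[i221, 0] > 0

    def test_zero_ri_area_rejected(self, elf_table):
        config = SynthConfig(seed=1, noise_cv=0.0, ratio_table=elf_table)
        rec = generate_pure_sample(config, "ELF94", 0.0)
        with pytest.raises(ValueError, match="Ri peak area is zero"):
            compute_characteristic_ratios(rec, (0.0, 3.6), "ELF94")


class TestPeakPurity:
    WINDOW = (0.0, 3.6)

    def test_noise_free_25_75_mixture(self, clean_config, elf_table):
        rec = generate_mixture_sample(clean_config, {"ELF94": 0.25, "ELF96": 0.75})
        matrix = assemble_leda_matrix(elf_table)
        result = peak_purity(rec, matrix, elf_table, self.WINDOW)
        assert result.fractions["ELF94"] == pytest.approx(0.25, abs=1e-6)
        assert result.fractions["ELF96"] == pytest.approx(0.75, abs=1e-6)
        assert result.mode == "area"

    def test_spurious_signal_raises_residual(self, clean_config, elf_table):
        rec = generate_mixture_sample(clean_config, {"ELF94": 0.5, "ELF96": 0.5})
        clean = peak_purity(
            rec, assemble_leda_matrix(elf_table), elf_table, self.WINDOW
        )
        rec.traces["Pi_253"].intensities *= 3.0  # unknown co-eluting component
        perturbed = peak_purity(
            rec, assemble_leda_matrix(elf_table), elf_table, self.WINDOW
        )
        assert clean.residual_norm < 1e-9
        assert perturbed.residual_norm > 1e-3

    def test_noise_robustness_overdetermined(self, elf_table):
        """2% channel noise shifts recovered fractions by < 5 points."""
        config = SynthConfig(seed=1234, noise_cv=0.02, ratio_table=elf_table)
        rng = config.rng()
        matrix = assemble_leda_matrix(elf_table)
        for _ in range(10):
            rec = generate_mixture_sample(
                config, {"ELF94": 0.5, "ELF96": 0.5}, rng=rng
            )
            result = peak_purity(rec, matrix, elf_table, self.WINDOW, closure=True)
            assert abs(result.fractions["ELF94"] - 0.5) < 0.05


class TestScanwise:
    WINDOW = (0.0, 3.6)

    @pytest.fixture
    def aligned_config(self, elf_table):
        """Noise-free generator with all channels on one time grid.

        With interleaved (staggered) channel timestamps the scanwise solve
        carries a small linear-interpolation error in the peak tails; the
        aligned grid isolates the exact algebraic properties.
        """
        return SynthConfig(
            seed=0, noise_cv=0.0, ratio_table=elf_table, dwell_offset=0.0
        )

    def test_equal_mixture_partitions_ri_in_half(self, clean_config, elf_table):
        """Interleaved timestamps: interpolation keeps errors ~1% in-peak."""
        rec = generate_mixture_sample(clean_config, {"ELF94": 0.5, "ELF96": 0.5})
        matrix = assemble_leda_matrix(elf_table, ["221/604", "195/604"])
        profiles = deconvolve_scanwise(
            rec, matrix, elf_table, self.WINDOW, ["221/604", "195/604"]
        )
        active = profiles.measured_ri > 0.10 * profiles.measured_ri.max()
        for iso in ("ELF94", "ELF96"):
            np.testing.assert_allclose(
                profiles.per_isomer_ri[iso][active],
                0.5 * profiles.measured_ri[active],
                rtol=1e-2,
            )

    def test_pure_sample_assigns_everything_to_one_isomer(
        self, aligned_config, elf_table
    ):
        rec = generate_mixture_sample(aligned_config, {"ELF94": 1.0, "ELF96": 0.0})
        matrix = assemble_leda_matrix(elf_table)
        profiles = deconvolve_scanwise(rec, matrix, elf_table, self.WINDOW)
        fractions = profiles.area_fractions()
        assert fractions["ELF94"] == pytest.approx(1.0, abs=1e-6)
        assert fractions["ELF96"] == pytest.approx(0.0, abs=1e-6)

    def test_closure_partitions_ri_pointwise(self, clean_config, elf_table):
        rec = generate_mixture_sample(clean_config, {"ELF94": 0.3, "ELF96": 0.7})
        matrix = assemble_leda_matrix(elf_table)
        profiles = deconvolve_scanwise(rec, matrix, elf_table, self.WINDOW)
        total = sum(profiles.per_isomer_ri.values())
        active = profiles.measured_ri > 0.01 * profiles.measured_ri.max()
        np.testing.assert_allclose(
            total[active], profiles.measured_ri[active], rtol=1e-9
        )
        assert np.all(total[~active] == 0.0)

    def test_area_mode_matches_ri_weighted_scan_mean(self, aligned_config, elf_table):
        rec = generate_mixture_sample(aligned_config, {"ELF94": 0.25, "ELF96": 0.75})
        matrix = assemble_leda_matrix(elf_table)
        area_result = peak_purity(
            rec, matrix, elf_table, self.WINDOW, closure=True
        )
        profiles = deconvolve_scanwise(rec, matrix, elf_table, self.WINDOW)
        active = profiles.measured_ri > 0.01 * profiles.measured_ri.max()
        weights = profiles.measured_ri[active]
        for iso in elf_table.isomer_ids:
            scan_mean = np.average(
                profiles.fractions_by_scan[iso][active], weights=weights
            )
            assert area_result.fractions[iso] == pytest.approx(scan_mean, abs=1e-6)

    def test_empty_overlap_rejected(self, clean_config, elf_table):
        rec = generate_mixture_sample(clean_config, {"ELF94": 0.5, "ELF96": 0.5})
        matrix = assemble_leda_matrix(elf_table)
        with pytest.raises(ValueError):
            deconvolve_scanwise(rec, matrix, elf_table, (10.0, 11.0))
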