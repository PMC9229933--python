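"""Synthetic-cohort generator: signature library contents, design shape,
determinism, zero-noise exactness, interference placement and threshold
structure."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from nmrbin.binning import bin_cohort, make_bins
from nmrbin.filtering import WATER_REGION, default_water_exclusion
from nmrbin.simulate import (
    DEFAULT_PLANTED_RATIOS,
    CohortDesign,
    MetaboliteSignature,
    default_signature_library,
    null_cohort,
    simulate_cohort,
)
from nmrbin.stats import group_ratio
from nmrbin.types import ConfigurationError, ValidationError


class TestSignatureLibrary:
    def test_contains_the_eight_metabolites(self, library):
        names = {s.name for s in library}
        assert names == {
            "Xanthine",
            "Butyrate",
            "Propionate",
            "UDP-glucose",
            "Valerate",
            "Uridine derivates",
            "Bile acids",
            "Kynurenic acid",
        }

    def test_xanthine_peak_centre_in_its_bin(self, library):
        xan = next(s for s in library if s.name == "Xanthine")
        (centre, _, _) = xan.peaks[0]
        assert 7.93 <= centre < 7.94

    def test_kynurenic_acid_has_four_peaks(self, library):
        kyn = next(s for s in library if s.name == "Kynurenic acid")
        assert len(kyn.peaks) == 4
        bins = sorted(f"{np.floor(c * 100) / 100:.2f}" for c, _, _ in kyn.peaks)
        assert bins == ["6.65", "7.49", "7.68", "7.82"]

    def test_relative_areas_sum_to_one(self, library):
        for sig in library:
            assert sum(a for _, a, _ in sig.peaks) == pytest.approx(1.0, abs=1e-9)

    def test_peak_centres_inside_default_window(self, library):
        for sig in library:
            for c, _, _ in sig.peaks:
                assert 0.0 <= c < 10.0

    def test_signature_validation(self):
        with pytest.raises(ValidationError):
            MetaboliteSignature("bad", ((1.0, -0.5, 0.005),), "diet")
        with pytest.raises(ValidationError):
            MetaboliteSignature("bad", ((1.0, 1.0, 0.0),), "diet")


class TestCohortShape:
    def test_design_gives_24_samples(self, fast_cohort):
        spectra, meta, truth = fast_cohort
        assert len(spectra) == 24
        assert len(meta) == 24
        cells = {(m.treatment, m.week) for m in meta}
        assert cells == {("HSC", 14), ("HSC", 22), ("LSC", 14), ("LSC", 22)}
        for cell in cells:
            assert sum((m.treatment, m.week) == cell for m in meta) == 6

    def test_animals_sampled_at_both_weeks(self, fast_cohort):
        _, meta, _ = fast_cohort
        animals = {m.animal_id for m in meta}
        assert len(animals) == 12
        for a in animals:
            assert {m.week for m in meta if m.animal_id == a} == {14, 22}

    def test_truth_table_covers_planted_keys(self, fast_cohort):
        _, _, truth = fast_cohort
        keys = set(zip(truth["metabolite"], truth["week"]))
        assert keys == set(DEFAULT_PLANTED_RATIOS)
        xan = truth.query("metabolite == 'Xanthine' and week == 22").iloc[0]
        assert xan["true_ratio"] == 1.41
        assert xan["affected_bins"] == "7.93"

    def test_n_per_cell_one_rejected(self):
        with pytest.raises(ConfigurationError, match="n_per_cell"):
            CohortDesign(n_per_cell=1)

    def test_interference_region_must_span_20_bins(self):
        with pytest.raises(ConfigurationError, match="20 bins"):
            CohortDesign(interference_region=(4.70, 4.85))

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ConfigurationError, match="positive"):
            CohortDesign(planted_ratio={("Xanthine", 14): 0.0})


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        d = CohortDesign(points_per_bin=4, seed=77)
        s1, m1, t1 = simulate_cohort(d)
        s2, m2, t2 = simulate_cohort(d)
        assert m1 == m2
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.intensity, b.intensity)
        assert t1.equals(t2)

    def test_different_seed_differs(self):
        s1, _, _ = simulate_cohort(CohortDesign(points_per_bin=4, seed=77))
        s2, _, _ = simulate_cohort(CohortDesign(points_per_bin=4, seed=78))
        assert not np.array_equal(s1[0].intensity, s2[0].intensity)


class TestZeroNoiseLimit:
    def _noise_free(self, ratio, week=14):
        lib = [MetaboliteSignature("Xanthine", ((7.935, 1.0, 0.005),), "diet")]
        design = CohortDesign(
            planted_ratio={("Xanthine", week): ratio},
            animal_cv=0.0,
            noise_sd=0.0,
            baseline_amplitude=0.0,
            points_per_bin=8,
            seed=1,
        )
        spectra, meta, _ = simulate_cohort(design, lib)
        return bin_cohort(spectra, design.bin_spec()), meta

    def test_planted_ratio_recovered_exactly(self):
        matrix, meta = self._noise_free(0.5)
        r = group_ratio(matrix, meta, 14)
        assert r["7.93"] == pytest.approx(0.5, rel=1e-12)

    def test_unplanted_week_ratio_is_one(self):
        matrix, meta = self._noise_free(0.5, week=14)
        r = group_ratio(matrix, meta, 22)
        assert r["7.93"] == pytest.approx(1.0, rel=1e-12)

    def test_null_cohort_zero_noise_ratio_exactly_one(self):
        design = CohortDesign(
            animal_cv=0.0, noise_sd=0.0, baseline_amplitude=0.0, points_per_bin=8, seed=2
        )
        spectra, meta, truth = null_cohort(design)
        assert set(truth["true_ratio"]) == {1.0}
        matrix = bin_cohort(spectra, design.bin_spec())
        for week in (14, 22):
            r = group_ratio(matrix, meta, week)
            assert r["7.93"] == 1.0
            assert r["1.06"] == 1.0


class TestSpectralStructure:
    def test_interference_bins_are_top_20(self, fast_binned):
        matrix, _, _ = fast_binned
        mean_per_bin = matrix.data.mean(axis=0)
        top20 = set(mean_per_bin.nlargest(20).index)
        assert top20 == set(default_water_exclusion())
        lo, hi = WATER_REGION
        assert all(lo <= float(l) < hi for l in top20)

    def test_bins_straddle_the_intensity_threshold(self, fast_binned):
        matrix, _, _ = fast_binned
        col_max = matrix.data.max(axis=0)
        assert (col_max >= 100_000).sum() > 0
        assert (col_max < 100_000).sum() > 0

    def test_metabolite_bins_carry_signal(self, fast_binned, library):
        matrix, _, truth = fast_binned
        labels = set(matrix.bin_labels)
        for bins in truth["affected_bins"]:
            for b in bins.split(";"):
                assert b in labels
                # peak bins visibly exceed the baseline-only background
                assert matrix.data[b].min() > 1_000

    def test_spectra_cover_grid(self, fast_cohort, fast_design):
        spectra, _, _ = fast_cohort
        n_bins = fast_design.bin_spec().n_bins
        assert len(spectra[0]) == n_bins * fast_design.points_per_bin
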