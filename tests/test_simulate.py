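import numpy as np
import pytest

from dermalight.msp import ChromatophoreMSP, average_by_type, read_scan_directory, transmittance
from dermalight.simulate import (
    DEFAULT_FIXTURE_SUBSTITUTIONS,
    GeneratorConfig,
    default_pigment_models,
    generate_fixture_sequences,
    generate_scans,
    lamp_counts,
    write_scan_directory,
)
from dermalight.tuning import SubstitutionRecord, compare_tuning_sites, map_to_bovine


class TestScanGeneration:
    def test_same_seed_is_bit_identical(self):
        cfg = GeneratorConfig(seed=11, n_fish=1, cells_per_fish_per_type=2)
        a = generate_scans(cfg)
        b = generate_scans(cfg)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.sample.values, sb.sample.values)
            np.testing.assert_array_equal(sa.reference.values, sb.reference.values)

    def test_default_replication_is_60_cells_per_type(self):
        scans = generate_scans(GeneratorConfig())
        assert len(scans) == 180
        per_type = {}
        for s in scans:
            per_type[s.chromatophore_type] = per_type.get(s.chromatophore_type, 0) + 1
        assert per_type == {"melanophore": 60, "erythrophore": 60, "xanthophore": 60}

    def test_noiseless_scans_recover_the_pigment_curve_exactly(self):
        cfg = GeneratorConfig(noise_cv=0.0, jitter_sigma=0.0,
                              n_fish=1, cells_per_fish_per_type=1)
        models = default_pigment_models()
        for scan in generate_scans(cfg):
            expected = models[scan.chromatophore_type].transmittance_percent(cfg.grid)
            T = transmittance(scan, cfg.grid)
            np.testing.assert_allclose(T.values, expected, rtol=1e-12, atol=1e-12)

    def test_cell_streams_are_independent_of_replication_size(self):
        # per-cell seeding: the first cells of a small run match a large run
        small = generate_scans(GeneratorConfig(seed=3, cells_per_fish_per_type=2))
        large = generate_scans(GeneratorConfig(seed=3, cells_per_fish_per_type=5))
        small_by_id = {s.cell_id: s for s in small}
        matched = 0
        for s in large:
            if s.cell_id in small_by_id:
                np.testing.assert_array_equal(
                    s.sample.values, small_by_id[s.cell_id].sample.values
                )
                matched += 1
        assert matched == len(small)

    def test_poisson_mode_produces_integer_counts(self):
        cfg = GeneratorConfig(noise_model="poisson", n_fish=1,
                              cells_per_fish_per_type=1)
        scan = generate_scans(cfg)[0]
        assert np.all(scan.reference.values == np.round(scan.reference.values))

    def test_lamp_is_positive_and_scaled(self):
        cfg = GeneratorConfig()
        lamp = lamp_counts(cfg)
        assert np.all(lamp > 0)
        assert lamp.mean() == pytest.approx(cfg.reference_mean_counts)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_fish=0)
        with pytest.raises(ValueError):
            GeneratorConfig(noise_cv=-0.1)
        with pytest.raises(ValueError):
            GeneratorConfig(noise_model="uniform")


def test_scan_directory_roundtrip(tmp_path):
    cfg = GeneratorConfig(seed=5, n_fish=1, cells_per_fish_per_type=1)
    scans = generate_scans(cfg)
    write_scan_directory(scans, tmp_path / "scans")
    back = read_scan_directory(tmp_path / "scans")
    assert len(back) == len(scans)
    by_id = {s.cell_id: s for s in back}
    for scan in scans:
        np.testing.assert_allclose(
            by_id[scan.cell_id].sample.values, scan.sample.values, rtol=1e-6
        )
        assert by_id[scan.cell_id].chromatophore_type == scan.chromatophore_type


def test_sem_scales_as_inverse_sqrt_n():
    # quadrupling the number of cells should halve the s.e.m. (within 20%)
    models = {"erythrophore": default_pigment_models()["erythrophore"]}
    sems = {}
    for n_cells in (10, 40):
        cfg = GeneratorConfig(seed=21, n_fish=1, cells_per_fish_per_type=n_cells)
        scans = generate_scans(cfg, models)
        summary = average_by_type(scans, cfg.grid, "erythrophore")
        sems[n_cells] = summary.sem_T.values.mean()
    ratio = sems[10] / sems[40]
    assert ratio == pytest.approx(2.0, rel=0.2)


def test_transition_estimator_recovers_generator_intercepts(noisy_transition_samples):
    # under the generator's own noise the estimator is unbiased: the mean
    # estimate over 50 seeds sits within 2 nm of the closed-form intercept
    models = default_pigment_models()
    for ctype, samples in noisy_transition_samples.items():
        expected = models[ctype].tangent_intercept_nm
        assert np.mean(samples) == pytest.approx(expected, abs=2.0)


class TestFixtureSequences:
    def test_empty_spec_gives_identical_pair(self):
        (_, a), (_, b) = generate_fixture_sequences([])
        assert a == b

    def test_default_spec_round_trips_through_substitution_calling(self):
        pair = generate_fixture_sequences()
        anchor, query = (map_to_bovine(seq, seq_id=sid) for sid, seq in pair)
        comparison = compare_tuning_sites(anchor, query)
        assert {r.notation for r in comparison.substitutions} == {
            r.notation for r in DEFAULT_FIXTURE_SUBSTITUTIONS
        }

    def test_non_tuning_site_substitution_invisible_to_site_calling(self):
        (_, anchor_seq), _ = generate_fixture_sequences([])
        ref_residue = anchor_seq[200 - 1]  # 200 is not a tuning site
        alt = "A" if ref_residue != "A" else "G"
        pair = generate_fixture_sequences(
            [SubstitutionRecord(200, ref_residue, alt)]
        )
        (_, a), (_, b) = pair
        assert a != b  # visible to a full-sequence diff
        anchor, query = (map_to_bovine(seq, seq_id=sid) for sid, seq in pair)
        assert compare_tuning_sites(anchor, query).substitutions == ()

    def test_out_of_range_site_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            generate_fixture_sequences([SubstitutionRecord(400, "A", "S")])

    def test_mismatched_reference_residue_rejected(self):
        with pytest.raises(ValueError, match="cannot apply"):
            generate_fixture_sequences([SubstitutionRecord(97, "A", "C")])
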