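"""The cohort generator: class structure, planting, dropout, round-trip."""

import numpy as np
import pytest

from neoprog import (CharacteristicDescriptor, ClassDistribution, CohortSpec,
                     RATIO_MEASURES, all_characteristics,
                     compute_ld, generate_cohort, read_cohort, write_cohort)
from conftest import brute_force_ld


def test_descriptor_roundtrip_and_validation():
    c = CharacteristicDescriptor("NAA/Cho", "CWMR")
    assert c.column == "NAA_Cho.CWMR"
    assert CharacteristicDescriptor.from_column("FA.FWMR").measure == "FA"
    with pytest.raises(ValueError, match="region"):
        CharacteristicDescriptor("FA", "XXXX")
    with pytest.raises(ValueError, match="measure"):
        CharacteristicDescriptor("NAA/Glx", "FWMR")
    assert len(all_characteristics()) == 42


def test_packaged_defaults_cover_panel(motor_dist, cognitive_dist):
    for dist in (motor_dist, cognitive_dist):
        assert len(dist.delayed) == 42 and len(dist.normal) == 42
        for table in (dist.delayed, dist.normal):
            for char, (mean, sd) in table.items():
                assert sd > 0
                if char.measure == "FA":
                    assert 0 < mean < 1  # the transcription corrected FA>1
                if char.measure == "MD":
                    assert mean > 0


def test_expected_delayed_count(motor_dist):
    spec = CohortSpec(n_subjects=103, prevalence=0.126, seed=7)
    counts = [generate_cohort(CohortSpec(103, 0.126, seed=s),
                              motor_dist).n_delayed for s in range(40)]
    # expected 13 delayed of 103; 40-seed mean within 4 SE of 13
    se = np.sqrt(103 * 0.126 * 0.874 / 40)
    assert abs(np.mean(counts) - 103 * 0.126) < 4 * se
    assert generate_cohort(spec, motor_dist).n_delayed > 0


def test_no_dropout_table_is_complete(study_cohort):
    assert np.isfinite(
        study_cohort.df.drop(columns=["subject_id"]).to_numpy(float)).all()


def test_physical_ranges(study_cohort):
    for char in study_cohort.characteristics:
        vals = study_cohort.values(char)
        if char.measure == "FA":
            assert ((vals >= 0) & (vals <= 1)).all()
        if char.measure == "MD":
            assert (vals > 0).all()


def test_planted_characteristic_has_floor_ld(planted_cohort):
    table, char = planted_cohort
    vals = table.values(char)
    delayed = vals[table.labels == 1]
    profile = compute_ld(vals, delayed, char)
    assert profile.ld == 0.125
    assert brute_force_ld(list(vals), list(delayed)) == 0.125


@pytest.mark.parametrize("octile", [1, 3, 8])
def test_planting_works_in_any_octile(motor_dist, octile):
    char = CharacteristicDescriptor("NAA/Cr", "PWML")
    spec = CohortSpec(n_subjects=103, prevalence=0.126,
                      planted_localised=((char, octile),), seed=5)
    table = generate_cohort(spec, motor_dist)
    vals = table.values(char)
    assert brute_force_ld(list(vals), list(vals[table.labels == 1])) == 0.125


def test_class_means_converge(motor_dist):
    spec = CohortSpec(n_subjects=4000, prevalence=0.5, seed=2)
    table = generate_cohort(spec, motor_dist)
    labels = table.labels
    for char in table.characteristics[::5]:
        vals = table.values(char)
        for cls, params in ((1, motor_dist.delayed), (0, motor_dist.normal)):
            mean, sd = params[char]
            sub = vals[labels == cls]
            assert abs(sub.mean() - mean) < 3 * sd / np.sqrt(len(sub))


def test_dropout_rate_and_scope(motor_dist):
    spec = CohortSpec(n_subjects=1000, prevalence=0.126, dropout_rate=0.05,
                      seed=9)
    table = generate_cohort(spec, motor_dist)
    ratio_cols = [c for c in table.characteristics
                  if c.measure in RATIO_MEASURES]
    dti_cols = [c for c in table.characteristics
                if c.measure not in RATIO_MEASURES]
    n_cells = 1000 * len(ratio_cols)
    n_missing = sum(np.isnan(table.values(c)).sum() for c in ratio_cols)
    # binomial 4-sigma band around the nominal per-value rate
    se = np.sqrt(0.05 * 0.95 / n_cells)
    assert abs(n_missing / n_cells - 0.05) < 4 * se
    assert all(np.isfinite(table.values(c)).all() for c in dti_cols)


def test_equicorrelation_within_region(motor_dist):
    dist = ClassDistribution(delayed=dict(motor_dist.delayed),
                             normal=dict(motor_dist.normal), rho=0.6)
    table = generate_cohort(CohortSpec(n_subjects=3000, prevalence=0.5,
                                       seed=4), dist)
    a = table.values(CharacteristicDescriptor("NAA/Cho", "CWMR"))
    b = table.values(CharacteristicDescriptor("NAA/Cr", "CWMR"))
    c = table.values(CharacteristicDescriptor("NAA/Cho", "PWML"))
    same_region = np.corrcoef(a, b)[0, 1]
    other_region = np.corrcoef(a, c)[0, 1]
    assert same_region > 0.4
    assert abs(other_region) < 0.1


def test_seed_determinism_byte_identical_csv(tmp_path, motor_dist):
    spec = CohortSpec(n_subjects=60, prevalence=0.2, dropout_rate=0.02,
                      severe_injury_rate=0.1, seed=13)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cohort(generate_cohort(spec, motor_dist), p1)
    write_cohort(generate_cohort(spec, motor_dist), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_csv_roundtrip_value_exact(tmp_path, motor_dist):
    spec = CohortSpec(n_subjects=50, prevalence=0.2, dropout_rate=0.03, seed=3)
    table = generate_cohort(spec, motor_dist)
    path = tmp_path / "cohort.csv"
    write_cohort(table, path)
    back = read_cohort(path)
    assert table.equals(back)


def test_read_rejects_bad_region(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("subject_id,label,severe_injury,FA.XXXX\nS1,0,0,0.2\n")
    with pytest.raises(ValueError, match="XXXX"):
        read_cohort(path)


def test_read_rejects_bad_label(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("subject_id,label,severe_injury,FA.FWMR\nS1,2,0,0.2\n")
    with pytest.raises(ValueError, match="label"):
        read_cohort(path)


def test_read_rejects_non_numeric_cell(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("subject_id,label,severe_injury,FA.FWMR\nS1,0,0,oops\n")
    with pytest.raises(ValueError, match="row 0.*FA.FWMR"):
        read_cohort(path)


def test_spec_validation():
    with pytest.raises(ValueError, match="below 1"):
        CohortSpec(n_subjects=5, prevalence=0.1)
    with pytest.raises(ValueError, match="octile"):
        CohortSpec(n_subjects=100, prevalence=0.2, planted_localised=(
            (CharacteristicDescriptor("FA", "FWMR"), 9),))
    with pytest.raises(ValueError, match="missing"):
        generate_cohort(
            CohortSpec(n_subjects=100, prevalence=0.2, planted_localised=(
                (CharacteristicDescriptor("FA", "FWMR"), 2),)),
            ClassDistribution(
                delayed={CharacteristicDescriptor("MD", "FWMR"): (1.3, 0.1)},
                normal={CharacteristicDescriptor("MD", "FWMR"): (1.4, 0.1)}))
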