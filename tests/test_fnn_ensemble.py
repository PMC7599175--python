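"""The voting ensemble: architecture contracts, vote algebra, recovery."""

import itertools

import numpy as np
import pytest

from neoprog import (DELAYED, EXCLUDED, NORMAL, CharacteristicDescriptor,
                     CohortSpec, FnnSpec, RelaxedZoneSet, ensemble_from_dict,
                     ensemble_to_dict, generate_cohort, out_of_fold_votes,
                     predict, predict_two_step, select_characteristics,
                     tally_votes, train_ensemble)
from conftest import shifted_distribution

INNER = [CharacteristicDescriptor("NAA/Cho", "CWMR"),
         CharacteristicDescriptor("NAA/mI", "CWMR"),
         CharacteristicDescriptor("mI/Cr", "CWMR"),
         CharacteristicDescriptor("mI/Cr", "CWML"),
         CharacteristicDescriptor("NAA/Cho", "PWMR")]


@pytest.fixture(scope="module")
def separable_members(motor_dist):
    """A member-like table with a strong (4 class-SD) delayed shift on
    five characteristics — separable classes."""
    dist = shifted_distribution(motor_dist, INNER, 4.0)
    table = generate_cohort(CohortSpec(n_subjects=64, prevalence=0.3, seed=17),
                            dist)
    sel = select_characteristics(table, ld_threshold=1.0, inner_size=5)
    # force the shifted characteristics as ensemble inputs
    from neoprog.ld_selection import SelectionResult
    sel = SelectionResult(all_profiles=sel.all_profiles,
                          selected=sel.selected, ld_threshold=1.0,
                          inner_subset=tuple(INNER))
    return table, sel


@pytest.fixture(scope="module")
def trained(separable_members):
    table, sel = separable_members
    spec = FnnSpec(max_epochs=150)
    return table, sel, train_ensemble(table, sel, spec, seed=11)


def test_ensemble_shape(trained):
    _, _, ens = trained
    assert len(ens.types) == 4
    assert all(t.n_nets == 100 for t in ens.types)
    assert sum(t.n_nets for t in ens.types) == 400


def test_probabilities_normalised(trained):
    table, _, ens = trained
    X = np.column_stack([table.values(c) for c in ens.inner_subset])
    for t in ens.types:
        P = t.probabilities(X)
        assert np.allclose(P.sum(axis=-1), 1.0, atol=1e-9)
        assert (P >= 0).all()


def test_determinism_identical_votes(separable_members):
    table, sel = separable_members
    spec = FnnSpec(max_epochs=60)
    e1 = train_ensemble(table, sel, spec, seed=5)
    e2 = train_ensemble(table, sel, spec, seed=5)
    for i in range(0, len(table), 9):
        sv = table.subject_values(i)
        assert predict(sv, e1) == predict(sv, e2)


def test_separable_classes_out_of_fold_perfect(trained):
    """With a margin between the classes, every type classifies its held-out
    fold correctly."""
    table, sel, ens = trained
    # margin oracle: nearest-centroid gap on standardised inputs is wide
    X = np.column_stack([table.values(c) for c in sel.inner_subset])
    Xs = (X - X.mean(0)) / X.std(0)
    y = table.labels
    d0 = np.linalg.norm(Xs - Xs[y == 0].mean(0), axis=1)
    d1 = np.linalg.norm(Xs - Xs[y == 1].mean(0), axis=1)
    assert (((d1 < d0).astype(int) == y).mean()) > 0.95
    votes = out_of_fold_votes(table, ens)
    correct = [votes[sid] == bool(lab) for sid, lab in
               zip(table.df["subject_id"], y)]
    assert np.mean(correct) == 1.0


def test_vote_thresholds():
    rec = tally_votes([51, 49, 50, 10], n_nets=100)
    assert rec.type_votes == (True, False, True, False)
    assert rec.final_delayed  # two-vote aggregation threshold reached
    assert not tally_votes([100, 0, 0, 0], 100).final_delayed
    assert not tally_votes([0, 0, 0, 0], 100).final_delayed
    assert tally_votes([100, 100, 100, 100], 100).final_delayed


def test_final_vote_permutation_invariant():
    for counts in itertools.permutations([51, 49, 50, 10]):
        assert tally_votes(list(counts), 100).final_delayed


def test_two_step_routing(trained):
    table, sel, ens = trained
    zones = RelaxedZoneSet(zones={c: (-1e9, 1e9) for c in sel.inner_subset},
                           relaxation=0.0)
    narrow = RelaxedZoneSet(zones={c: (1e8, 1e9) for c in sel.inner_subset},
                            relaxation=0.0)
    sv = table.subject_values(0)
    in_zone = predict_two_step(sv, zones, ens)
    assert in_zone in (DELAYED, NORMAL)
    # non-member is called normal without consulting the ensemble
    assert predict_two_step(sv, narrow, ens) == NORMAL
    # a missing zone value excludes the subject
    sv_missing = dict(sv); sv_missing[sel.inner_subset[0]] = np.nan
    assert predict_two_step(sv_missing, zones, ens) == EXCLUDED


def test_predict_missing_input_raises(trained):
    table, sel, ens = trained
    sv = dict(table.subject_values(0))
    del sv[ens.inner_subset[0]]
    with pytest.raises(ValueError, match="missing input"):
        predict(sv, ens)


def test_too_few_members_raises(motor_dist):
    table = generate_cohort(CohortSpec(n_subjects=6, prevalence=0.4, seed=2),
                            motor_dist)
    sel = select_characteristics(table, ld_threshold=1.0, inner_size=3,
                                 min_delayed=1)
    with pytest.raises(ValueError, match="folds or more data"):
        train_ensemble(table, sel, FnnSpec(max_epochs=5), seed=0)


def test_serialisation_roundtrip(trained):
    table, _, ens = trained
    back = ensemble_from_dict(ensemble_to_dict(ens))
    for i in range(0, len(table), 11):
        sv = table.subject_values(i)
        assert predict(sv, back) == predict(sv, ens)


def test_matches_reference_mlp_on_separable_data(separable_members):
    """Independent cross-check: a scikit-learn MLP of the same architecture
    also classifies the near-separable member table, so the signal the
    ensemble learns is in the data, not an artefact of our trainer."""
    from sklearn.neural_network import MLPClassifier
    table, sel = separable_members
    X = np.column_stack([table.values(c) for c in sel.inner_subset])
    X = (X - X.mean(0)) / X.std(0)
    y = table.labels
    clf = MLPClassifier(hidden_layer_sizes=(6,), activation="logistic",
                        solver="lbfgs", max_iter=2000, random_state=0)
    clf.fit(X, y)
    assert clf.score(X, y) >= 0.95
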