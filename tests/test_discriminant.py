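"""Two-group CVA, phi statistic, nulls, and classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snoutshape.discriminant import (
    GroupedScores, assign, classify, cva_fit, jackknife, null_bootstrap,
    null_montecarlo,
)


def gaussian_groups(rng, n1=20, n2=20, k=2, gap=5.0):
    x1 = rng.normal(size=(n1, k))
    x2 = rng.normal(size=(n2, k)) + gap / np.sqrt(k)
    scores = np.vstack([x1, x2])
    labels = np.array(["browser"] * n1 + ["grazer"] * n2)
    return GroupedScores(ids=None, scores=scores, labels=labels)


def test_coincident_centroids_give_phi_near_zero(rng):
    x = rng.normal(size=(40, 3))
    data = GroupedScores(None, np.vstack([x, x]),
                         np.array(["browser"] * 40 + ["grazer"] * 40))
    model = cva_fit(data)
    assert model.wilks_lambda == pytest.approx(1.0, abs=1e-10)
    assert model.phi == pytest.approx(0.0, abs=1e-8)


def test_direction_matches_closed_form_fisher_oracle(rng):
    data = gaussian_groups(rng, gap=5.0, k=2)
    model = cva_fit(data)
    g0, g1 = model.groups
    mu0 = data.scores[data.labels == g0].mean(axis=0)
    mu1 = data.scores[data.labels == g1].mean(axis=0)
    w = np.zeros((2, 2))
    for g in model.groups:
        dev = data.scores[data.labels == g] - data.scores[data.labels == g].mean(axis=0)
        w += dev.T @ dev
    fisher = np.linalg.solve(w, mu0 - mu1)
    cosine = model.discriminant_vector @ fisher / (
        np.linalg.norm(model.discriminant_vector) * np.linalg.norm(fisher)
    )
    assert abs(cosine) > 0.999


def test_unit_pooled_within_variance(rng):
    data = gaussian_groups(rng, k=3)
    model = cva_fit(data)
    pooled = 0.0
    for g in model.groups:
        cv = model.cv_scores[data.labels == g]
        pooled += np.sum((cv - cv.mean()) ** 2)
    assert pooled / (data.scores.shape[0] - 2) == pytest.approx(1.0, abs=1e-8)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_phi_invariant_to_affine_recoding(seed):
    rng = np.random.default_rng(seed)
    data = gaussian_groups(rng, n1=12, n2=14, k=3, gap=2.0)
    base = cva_fit(data).phi
    a = rng.normal(size=(3, 3)) + 3 * np.eye(3)
    b = rng.normal(size=3)
    recoded = GroupedScores(None, data.scores @ a + b, data.labels)
    assert cva_fit(recoded).phi == pytest.approx(base, abs=1e-6)


def test_point_at_centroid_assigned_to_that_group(rng):
    data = gaussian_groups(rng)
    model = cva_fit(data)
    g0 = model.groups[0]
    assigned, dists, ties = assign(model, np.array([model.centroids[g0]]))
    assert assigned[0] == g0
    assert dists[0, 0] == pytest.approx(0.0, abs=1e-12)


def test_perfectly_separated_groups_classify_fully(rng):
    data = gaussian_groups(rng, gap=50.0)
    model = cva_fit(data)
    _, cm = classify(model, data.scores, data.labels)
    assert cm.percent_correct == 100.0
    assert jackknife(data).percent_correct == 100.0


def test_jackknife_equals_naive_reloop(rng):
    data = gaussian_groups(rng, n1=10, n2=12, k=2, gap=1.5)
    cm = jackknife(data)
    # independent naive re-loop
    n = data.scores.shape[0]
    counts = np.zeros((2, 2), dtype=int)
    groups = data.groups
    for hold in range(n):
        keep = [i for i in range(n) if i != hold]
        sub = GroupedScores(None, data.scores[keep], data.labels[keep])
        m = cva_fit(sub)
        cv = m.transform(data.scores[hold][None, :])[0]
        dists = {g: abs(cv - m.centroids[g]) for g in groups}
        hat = min(groups, key=lambda g: (dists[g], g))
        counts[groups.index(data.labels[hold]), groups.index(hat)] += 1
    np.testing.assert_array_equal(cm.counts, counts)


def test_resubstitution_beats_jackknife_on_average():
    diffs = []
    for seed in range(100):
        rng = np.random.default_rng(1000 + seed)
        data = gaussian_groups(rng, n1=12, n2=12, k=2, gap=1.0)
        model = cva_fit(data)
        _, cm = classify(model, data.scores, data.labels)
        diffs.append(cm.percent_correct - jackknife(data).percent_correct)
    assert np.mean(diffs) >= 0.0


def test_chi2_and_montecarlo_agree_on_rejection():
    agree = 0
    trials = 200
    for seed in range(trials):
        rng = np.random.default_rng(33_000 + seed)
        gap = rng.uniform(0.0, 1.4)  # spans phi near and far from critical
        data = gaussian_groups(rng, n1=15, n2=15, k=2, gap=gap)
        model = cva_fit(data)
        mc = null_montecarlo(data, R=199, seed=rng)
        if (model.p_chi2 < 0.05) == (mc.p_value < 0.05):
            agree += 1
    assert agree / trials >= 0.90


def test_montecarlo_degenerate_replicate_count(rng):
    data = gaussian_groups(rng)
    nd = null_montecarlo(data, R=1, seed=0)
    assert nd.p_value in (0.0, 1.0)


def test_separated_groups_reject_under_both_nulls(rng):
    data = gaussian_groups(rng, gap=8.0)
    mc = null_montecarlo(data, R=1000, seed=1)
    boot = null_bootstrap(data, R=1000, seed=2)
    assert mc.p_value == 0.0
    assert boot.p_value == 0.0
    assert np.all(boot.phi_values < boot.phi_observed)


def test_bootstrap_destroys_label_structure(rng):
    pooled = rng.normal(size=(40, 2))
    labels_sep = np.array(["browser"] * 20 + ["grazer"] * 20)
    # same pooled rows, once sorted to fake separation, once as-is
    order = np.argsort(pooled[:, 0])
    sep = GroupedScores(None, pooled[order], labels_sep)
    unsep = GroupedScores(None, pooled, labels_sep)
    mean_sep = np.mean(null_bootstrap(sep, R=500, seed=3).phi_values)
    mean_unsep = np.mean(null_bootstrap(unsep, R=500, seed=4).phi_values)
    assert mean_sep == pytest.approx(mean_unsep, rel=0.15)


def test_single_group_rejected(rng):
    with pytest.raises(ValueError, match="2 groups"):
        cva_fit(GroupedScores(None, rng.normal(size=(10, 2)), np.array(["b"] * 10)))
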