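"""Constraint handling, EM contracts, and the 3-class decision rules."""

import dataclasses
import math
import warnings

import numpy as np
import pytest

from cogmix import distributions as d
from cogmix import mixture as mx
from cogmix import synthetic_data as sd


def toy_model(k=2, lam=(3.0, 9.0), weights=None):
    """Small mixture over the animals metric only (Poisson clusters)."""
    structure = mx.THREE_CLUSTER_STRUCTURE if k == 3 else mx.ClusterStructure(
        names=("CU", "Dem"), groups={"CU": ("CU",), "MCI": (), "Dem": ("Dem",)}
    )
    comps = tuple({"animals": d.CMPoissonParams(lam=l, nu=1.0)} for l in lam[:k])
    w = np.full(k, 1.0 / k) if weights is None else np.asarray(weights)
    return mx.MixtureModel(weights=w, components=comps, structure=structure)


# ---------------------------------------------------------------------------
# records and constraints
# ---------------------------------------------------------------------------


def test_assessment_record_invariants():
    with pytest.raises(ValueError):
        mx.AssessmentRecord("a", bdst=16, animals=5, recall=3, recognition=(6, 0, 0))
    with pytest.raises(ValueError):
        mx.AssessmentRecord("a", bdst=5, animals=5, recall=3, recognition=(4, 1, 0))
    with pytest.raises(ValueError):
        mx.AssessmentRecord("a", bdst=5, animals=-1, recall=3, recognition=(6, 0, 0))


def test_build_constraints_rows():
    s = mx.DEFAULT_STRUCTURE
    C = mx.build_constraints(["unlabeled", "CU", "MCI", "Dem", "aMCI"], s)
    np.testing.assert_array_equal(C[0], [1, 1, 1, 1, 1, 1])
    np.testing.assert_array_equal(C[1], [1, 0, 0, 0, 0, 0])
    np.testing.assert_array_equal(C[2], [0, 1, 1, 1, 0, 0])
    np.testing.assert_array_equal(C[3], [0, 0, 0, 0, 1, 1])
    np.testing.assert_array_equal(C[4], [0, 0, 0, 1, 0, 0])
    assert np.all(C.sum(axis=1) >= 1)


def test_build_constraints_unknown_label_errors():
    with pytest.raises(ValueError, match="unknown label"):
        mx.build_constraints(["possible-MCI"], mx.DEFAULT_STRUCTURE)


def test_records_csv_round_trip(tmp_path):
    recs = [
        mx.AssessmentRecord("s1", 10, 18, 4, (6, 0, 0), "CU", {"age": 70.5}),
        mx.AssessmentRecord("s2", 5, 7, 1, (3, 2, 1), "unlabeled", {"age": 81.0}),
    ]
    path = tmp_path / "r.csv"
    mx.write_records_csv(recs, path)
    back = mx.read_records_csv(path)
    assert back == recs


def test_records_csv_reports_bad_lines(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "subject_id,bdst_serial,animals,recall_correct,"
        "recog_correct,recog_prototypical,recog_generic,label\n"
        "s1,10,18,4,6,0,0,CU\n"
        "s2,99,18,4,6,0,0,\n"
    )
    with pytest.raises(ValueError, match="line 3"):
        mx.read_records_csv(path)


# ---------------------------------------------------------------------------
# densities / E-step / M-step
# ---------------------------------------------------------------------------


def test_record_log_density_is_sum_of_metric_pmfs(true_model):
    rec = mx.AssessmentRecord("x", 11, 20, 4, (5, 1, 0))
    comp = true_model.components[0]
    expect = (
        d.cm_binomial_log_pmf(11, comp["bdst"])
        + d.cm_poisson_log_pmf(20, comp["animals"])
        + d.cm_binomial_log_pmf(4, comp["recall"])
        + d.cm_multinomial_log_pmf([5, 1, 0], comp["recognition"])
    )
    assert mx.record_log_density(rec, comp) == pytest.approx(expect, abs=1e-12)


def test_e_step_single_permitted_cluster_is_one_hot():
    model = toy_model()
    data = {"animals": np.array([4, 9])}
    C = np.array([[1, 0], [0, 1]])
    gamma = mx.e_step(model, data, C)
    np.testing.assert_array_equal(gamma, C)


def test_e_step_symmetric_clusters_split_evenly():
    model = toy_model(lam=(5.0, 5.0))
    gamma = mx.e_step(model, {"animals": np.array([3, 8])}, np.ones((2, 2), int))
    np.testing.assert_allclose(gamma, 0.5)


def test_e_step_bayes_arithmetic():
    # per-cluster likelihoods 0.8 / 0.2 at k=0 (Poisson pmf(0)=e^-lam) with
    # equal weights -> gamma = (0.8, 0.2) by Bayes' rule
    comps = (
        {"animals": d.CMPoissonParams(lam=math.log(1 / 0.8), nu=1.0)},
        {"animals": d.CMPoissonParams(lam=math.log(1 / 0.2), nu=1.0)},
    )
    model = mx.MixtureModel(
        weights=np.array([0.5, 0.5]),
        components=comps,
        structure=mx.ClusterStructure(
            names=("CU", "Dem"), groups={"CU": ("CU",), "MCI": (), "Dem": ("Dem",)}
        ),
    )
    gamma = mx.e_step(model, {"animals": np.array([0])}, np.ones((1, 2), int))
    np.testing.assert_allclose(gamma[0], [0.8, 0.2], atol=1e-12)


def test_e_step_impossible_record_names_position():
    model = toy_model()
    # recognition impossible under a point-mass-free cluster cannot happen with
    # Poisson; use a constraint excluding everything instead via pi0=1 clusters
    comps = (
        {"animals": d.CMPoissonParams(lam=5.0, nu=1.0, pi0=1.0)},
        {"animals": d.CMPoissonParams(lam=5.0, nu=1.0, pi0=1.0)},
    )
    model = dataclasses.replace(model, components=comps)
    with pytest.raises(mx.ImpossibleRecordError) as exc:
        mx.e_step(model, {"animals": np.array([0, 3])}, np.ones((2, 2), int))
    assert exc.value.indices == [1]


def test_m_step_hard_assignments_give_closed_form():
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.poisson(3.0, 40), rng.poisson(9.0, 60)])
    gamma = np.zeros((100, 2))
    gamma[:40, 0] = 1.0
    gamma[40:, 1] = 1.0
    structure = mx.ClusterStructure(
        names=("CU", "Dem"), groups={"CU": ("CU",), "MCI": (), "Dem": ("Dem",)}
    )
    metrics = {"animals": {"family": "cm_poisson",
                           "fixed": {"nu": 1.0, "pi": 0.0}}}
    model = mx.m_step({"animals": x}, gamma, structure, metrics)
    np.testing.assert_allclose(model.weights, [0.4, 0.6], atol=1e-12)
    # Poisson MLE is the group mean
    assert model.components[0]["animals"].lam == pytest.approx(x[:40].mean(), rel=1e-3)
    assert model.components[1]["animals"].lam == pytest.approx(x[40:].mean(), rel=1e-3)


def test_m_step_uniform_gamma_gives_uniform_weights():
    x = np.arange(1, 13)
    gamma = np.full((12, 2), 0.5)
    structure = mx.ClusterStructure(
        names=("CU", "Dem"), groups={"CU": ("CU",), "MCI": (), "Dem": ("Dem",)}
    )
    metrics = {"animals": {"family": "cm_poisson", "fixed": {"nu": 1.0, "pi": 0.0}}}
    model = mx.m_step({"animals": x}, gamma, structure, metrics)
    np.testing.assert_allclose(model.weights, 0.5)


def test_log_likelihood_matches_brute_force(true_model, small_data):
    sub = {k: v[:25] for k, v in small_data.items()}
    C = mx.build_constraints(list(sub["label"]), true_model.structure)
    got = mx.log_likelihood(true_model, sub, C)
    expect = 0.0
    for i in range(25):
        rec = {
            "bdst": sub["bdst"][i], "animals": sub["animals"][i],
            "recall": sub["recall"][i], "recognition": sub["recognition"][i],
        }
        tot = 0.0
        for c, comp in enumerate(true_model.components):
            if C[i, c]:
                tot += true_model.weights[c] * math.exp(mx.record_log_density(rec, comp))
        expect += math.log(tot)
    assert got == pytest.approx(expect, abs=1e-8)


def test_log_likelihood_all_ones_equals_unconstrained(true_model, small_data):
    sub = {k: v[:40] for k, v in small_data.items()}
    C = np.ones((40, 6), dtype=int)
    assert mx.log_likelihood(true_model, sub, C) == pytest.approx(
        mx.log_likelihood(true_model, sub), abs=1e-10
    )


# ---------------------------------------------------------------------------
# EM behavior
# ---------------------------------------------------------------------------


def test_fit_em_monotone_and_constraint_honoring(fitted_small, small_data):
    tr = fitted_small.log_likelihood_trace
    assert np.all(np.diff(tr) >= -1e-8 * np.abs(tr[:-1]))
    C = mx.build_constraints(list(small_data["label"]), mx.DEFAULT_STRUCTURE)
    gamma = mx.e_step(fitted_small.model, small_data, C)
    assert np.all(gamma[C == 0] == 0.0)
    np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-12)


def test_fit_em_deterministic_given_seed(small_data):
    sub = {k: v[:150] for k, v in small_data.items()}
    kw = dict(seed=3, tol=1e-6, max_iter=40)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        a = mx.fit_em(sub, **kw)
        b = mx.fit_em(sub, **kw)
    assert a.model.to_json() == b.model.to_json()
    np.testing.assert_array_equal(a.log_likelihood_trace, b.log_likelihood_trace)


def test_fit_em_fully_labeled_equals_per_group_mle():
    """With one cluster per group and every record labeled, the
    semi-supervised fit reduces to independent per-group fits."""
    ds = sd.generate(N=300, seed=21)
    recs = [dataclasses.replace(r, label=g) for r, g in
            zip(ds.records, ds.true_labels)]
    data = mx.records_to_arrays(recs)
    metrics = {"recall": mx.DAC_METRICS["recall"]}
    fr = mx.fit_em(data, structure=mx.THREE_CLUSTER_STRUCTURE, metrics=metrics,
                   seed=0, max_iter=50, tol=1e-10)
    lab = np.array([r.label for r in recs])
    for c, g in enumerate(("CU", "MCI", "Dem")):
        mask = lab == g
        direct = d.fit_weighted(
            data["recall"][mask], np.ones(mask.sum()), "cm_binomial",
            n=6, inflation="zero", seed=0,
        )
        got = fr.model.components[c]["recall"]
        w = np.ones(mask.sum())
        ll_direct = float(w @ d.cm_binomial_log_pmf(data["recall"][mask], direct))
        ll_em = float(w @ d.cm_binomial_log_pmf(data["recall"][mask], got))
        assert ll_em == pytest.approx(ll_direct, abs=1e-4)
        assert fr.model.weights[c] == pytest.approx(mask.mean(), abs=1e-9)


def test_canonicalization_invariant_to_init_seed(small_data):
    sub = {k: v[:250] for k, v in small_data.items()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        a = mx.fit_em(sub, seed=5, tol=1e-6, max_iter=150).model.canonicalized()
        b = mx.fit_em(sub, seed=104, tol=1e-6, max_iter=150).model.canonicalized()
    # same local structure up to modest numerical differences after reordering
    np.testing.assert_allclose(
        a.cluster_means("recall"), b.cluster_means("recall"), atol=0.35
    )


def test_model_json_round_trip(fitted_small, tmp_path):
    path = tmp_path / "model.json"
    fitted_small.model.save(path)
    back = mx.MixtureModel.load(path)
    assert back.to_json() == fitted_small.model.to_json()


# ---------------------------------------------------------------------------
# posterior collapse and decision rules
# ---------------------------------------------------------------------------


def test_collapse_posteriors_stated_sums():
    gamma = np.array([[0.1, 0.2, 0.3, 0.1, 0.2, 0.1]])
    p3 = mx.collapse_posteriors(gamma, mx.DEFAULT_STRUCTURE)
    np.testing.assert_allclose(p3, [[0.1, 0.6, 0.3]], atol=1e-12)


def test_collapse_one_hot_dem():
    gamma = np.zeros((1, 6))
    gamma[0, 5] = 1.0  # saDem
    np.testing.assert_allclose(
        mx.collapse_posteriors(gamma, mx.DEFAULT_STRUCTURE), [[0, 0, 1]]
    )


def test_collapse_conserves_row_sums():
    rng = np.random.default_rng(8)
    gamma = rng.dirichlet(np.ones(6), size=30)
    p3 = mx.collapse_posteriors(gamma, mx.DEFAULT_STRUCTURE)
    np.testing.assert_allclose(p3.sum(axis=1), 1.0, atol=1e-12)


def test_classify_argmax_and_threshold_rules_differ():
    row = np.array([0.45, 0.35, 0.20])
    assert mx.classify(row)[0] == "CU"
    assert mx.classify(row, "impairment")[0]  # 0.55 > 0.45 -> positive
    assert mx.classify([0.1, 0.6, 0.3])[0] == "MCI"
    assert mx.classify([0.3, 0.4, 0.3], "cu_vs_mci")[0]  # 0.4/0.7 > 0.5


def test_classify_tie_prefers_less_impaired():
    assert mx.classify([0.4, 0.4, 0.2])[0] == "CU"
    assert not mx.classify([0.5, 0.3, 0.2], "impairment")[0]  # exact tie -> negative


def test_predict_posteriors_matches_hand_bayes():
    model = toy_model(lam=(3.0, 9.0), weights=[0.3, 0.7])
    gamma = mx.predict_posteriors(model, {"animals": np.array([5])})
    l1 = 0.3 * math.exp(d.cm_poisson_log_pmf(5, model.components[0]["animals"]))
    l2 = 0.7 * math.exp(d.cm_poisson_log_pmf(5, model.components[1]["animals"]))
    np.testing.assert_allclose(gamma[0], [l1 / (l1 + l2), l2 / (l1 + l2)], atol=1e-12)
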