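"""AUC scoring, repeated-CV evaluation and greedy network-constrained selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pathpin as pp
from pathpin import io as pio
from pathpin.pin import EdgeEvidence, PathwayNetwork


def brute_force_auc(scores, y):
    """Exhaustive pairwise positive-vs-negative comparison, ties one half."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def make_activity(rows, samples):
    scores = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    scores.columns = samples
    return pp.ActivityMatrix(scores=scores, loadings={})


def balanced_labels(samples):
    half = len(samples) // 2
    return pp.SampleLabels(
        assignments={s: ("disease" if i < half else "control") for i, s in enumerate(samples)}
    )


def trivial_pin(nodes, edges):
    ev = {PathwayNetwork.canonical(a, b): EdgeEvidence(shared_de_genes=frozenset({"x"})) for a, b in edges}
    return PathwayNetwork(nodes=list(nodes), edges=ev, params={"alpha": 0.05, "rho_min": 0.8})


# ---------------------------------------------------------------------------
# auc_score


def test_auc_perfect_and_ties():
    assert pp.auc_score(np.array([1, 2, 3, 4]), np.array([0, 0, 1, 1])) == 1.0
    assert pp.auc_score(np.ones(6), np.array([0, 1, 0, 1, 0, 1])) == 0.5


def test_auc_single_class_raises():
    with pytest.raises(pio.InputError):
        pp.auc_score(np.array([1.0, 2.0]), np.array([1, 1]))


def test_auc_matches_brute_force_and_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    for _ in range(30):
        n = int(rng.integers(4, 50))
        scores = rng.choice(np.round(rng.standard_normal(8), 2), size=n)  # forced ties
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            continue
        ours = pp.auc_score(scores, y)
        assert ours == pytest.approx(brute_force_auc(scores, y), abs=1e-12)
        assert ours == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(-5, 5), min_size=4, max_size=20))
def test_auc_complement_symmetry(vals):
    """Flipping all labels mirrors the AUC around one half."""
    scores = np.array(vals, dtype=float)
    y = (np.arange(len(vals)) % 2).astype(int)
    assert pp.auc_score(scores, y) + pp.auc_score(scores, 1 - y) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# evaluate_feature_set


def test_separable_activity_scores_auc_one():
    samples = [f"s{i}" for i in range(30)]
    act = make_activity({"P": [5.0 + 0.01 * i if i < 15 else -5.0 + 0.01 * i for i in range(30)]}, samples)
    labels = balanced_labels(samples)
    cfg = pp.EvaluationConfig(seed=3)
    res = pp.evaluate_feature_set(act, ["P"], labels, cfg, n_repeats=5)
    assert res["mean_auc"] == pytest.approx(1.0)


def test_noise_activity_scores_near_half(rng):
    # per-dataset CV-AUC fluctuates around 0.5 under the null; average over
    # independent noise datasets to estimate the centre
    samples = [f"s{i}" for i in range(60)]
    labels = balanced_labels(samples)
    cfg = pp.EvaluationConfig(seed=7)
    means = []
    for _ in range(8):
        act = make_activity({"P": rng.standard_normal(60)}, samples)
        means.append(pp.evaluate_feature_set(act, ["P"], labels, cfg, n_repeats=10)["mean_auc"])
    assert abs(np.mean(means) - 0.5) < 0.1


def test_duplicated_feature_changes_little(rng):
    samples = [f"s{i}" for i in range(50)]
    signal = np.r_[rng.standard_normal(25) + 1.2, rng.standard_normal(25)]
    act = make_activity({"P": signal, "Pdup": signal.copy()}, samples)
    labels = balanced_labels(samples)
    cfg = pp.EvaluationConfig(seed=11)
    single = pp.evaluate_feature_set(act, ["P"], labels, cfg, n_repeats=20)
    doubled = pp.evaluate_feature_set(act, ["P", "Pdup"], labels, cfg, n_repeats=20)
    assert abs(single["mean_auc"] - doubled["mean_auc"]) <= 0.02


def test_too_few_samples_per_class_rejected(rng):
    samples = [f"s{i}" for i in range(8)]
    act = make_activity({"P": rng.standard_normal(8)}, samples)
    labels = balanced_labels(samples)
    cfg = pp.EvaluationConfig(n_folds=5)
    with pytest.raises(pio.InputError):
        pp.evaluate_feature_set(act, ["P"], labels, cfg, n_repeats=2)


def test_evaluation_deterministic(rng):
    samples = [f"s{i}" for i in range(40)]
    act = make_activity({"P": rng.standard_normal(40), "Q": rng.standard_normal(40)}, samples)
    labels = balanced_labels(samples)
    cfg = pp.EvaluationConfig(seed=5)
    r1 = pp.evaluate_feature_set(act, ["P", "Q"], labels, cfg, n_repeats=4)
    r2 = pp.evaluate_feature_set(act, ["P", "Q"], labels, cfg, n_repeats=4)
    assert r1 == r2


# ---------------------------------------------------------------------------
# greedy_select


def test_isolated_informative_pathway_selected_alone(rng):
    samples = [f"s{i}" for i in range(30)]
    rows = {"INF": np.r_[np.full(15, 4.0), np.full(15, -4.0)] + 0.01 * rng.standard_normal(30)}
    noise_nodes = [f"N{i}" for i in range(9)]
    for n in noise_nodes:
        rows[n] = rng.standard_normal(30)
    act = make_activity(rows, samples)
    labels = balanced_labels(samples)
    # INF is isolated; noise pathways form their own chain
    pin = trivial_pin(["INF", *noise_nodes], [(noise_nodes[i], noise_nodes[i + 1]) for i in range(8)])
    cfg = pp.EvaluationConfig(seed=2, search_repeats=5, n_repeats=5)
    trace = pp.greedy_select(act, pin, labels, cfg)
    assert trace.final_set == ["INF"]
    assert trace.steps[0].mean_auc == pytest.approx(1.0)


def test_complementary_pair_selected_in_order(rng):
    # two orthogonal half-strength signals; jointly nearly separable
    samples = [f"s{i}" for i in range(80)]
    y = np.r_[np.ones(40), np.zeros(40)]
    s1 = rng.standard_normal(80) + 1.0 * y
    s2 = rng.standard_normal(80) + 0.9 * y
    rows = {"P1": s1, "P2": s2, "N1": rng.standard_normal(80), "N2": rng.standard_normal(80)}
    act = make_activity(rows, samples)
    labels = balanced_labels(samples)
    pin = trivial_pin(["P1", "P2", "N1", "N2"], [("P1", "P2"), ("P2", "N1"), ("N1", "N2")])
    cfg = pp.EvaluationConfig(seed=13, search_repeats=10, n_repeats=10)
    trace = pp.greedy_select(act, pin, labels, cfg)
    assert set(trace.final_set[:2]) == {"P1", "P2"}
    # exhaustive 1-subset oracle at the same seeds: the first selected pathway
    # is the one with the best individual AUC (lexicographic on exact ties)
    best_name, best_auc = None, -1.0
    for n in sorted(pin.nodes):
        auc = pp.evaluate_feature_set(act, [n], labels, cfg, cfg.search_repeats)["mean_auc"]
        if auc > best_auc:
            best_name, best_auc = n, auc
    assert trace.steps[0].pathway == best_name
    # the complementary pair beats either single signal
    joint = pp.evaluate_feature_set(act, ["P1", "P2"], labels, cfg, cfg.search_repeats)
    assert joint["mean_auc"] > best_auc


def test_step_one_equals_brute_force_scan(rng):
    data = pp.simulate_dataset(pp.SimulationDesign(n_genes=150, n_samples_per_class=25, n_pathways=10, seed=42))
    expr = pp.standardize(data.expression)
    mapped = pp.map_genes_to_pathways(expr, data.gene_sets)
    act = pp.compute_activity(expr, mapped)
    pin = pp.build_pin(mapped, data.ppi, expr, data.labels)
    cfg = pp.EvaluationConfig(seed=9, search_repeats=5, n_repeats=5)
    trace = pp.greedy_select(act, pin, data.labels, cfg)
    best_name, best_auc = None, -1.0
    for n in sorted(pin.nodes):
        auc = pp.evaluate_feature_set(act, [n], data.labels, cfg, cfg.search_repeats)["mean_auc"]
        if auc > best_auc:
            best_name, best_auc = n, auc
    assert trace.steps[0].pathway == best_name
    assert trace.steps[0].mean_auc == pytest.approx(best_auc)


def test_trace_invariants_and_determinism(rng):
    data = pp.simulate_dataset(pp.SimulationDesign(n_genes=150, n_samples_per_class=25, n_pathways=10, seed=7))
    expr = pp.standardize(data.expression)
    mapped = pp.map_genes_to_pathways(expr, data.gene_sets)
    act = pp.compute_activity(expr, mapped)
    pin = pp.build_pin(mapped, data.ppi, expr, data.labels)
    cfg = pp.EvaluationConfig(seed=21, search_repeats=5, n_repeats=5)
    t1 = pp.greedy_select(act, pin, data.labels, cfg)
    t2 = pp.greedy_select(act, pin, data.labels, cfg)
    assert t1.to_dict() == t2.to_dict()
    aucs = [s.mean_auc for s in t1.steps]
    for prev, nxt in zip(aucs, aucs[1:]):
        assert nxt > prev + cfg.improvement_tol
    for i, step in enumerate(t1.steps[1:], start=1):
        earlier = {s.pathway for s in t1.steps[:i]}
        assert pin.neighbors(step.pathway) & earlier


def test_first_only_frontier_restricts_candidates(rng):
    samples = [f"s{i}" for i in range(60)]
    y = np.r_[np.ones(30), np.zeros(30)]
    rows = {
        "A": 0.3 * rng.standard_normal(60) + 3.0 * y,
        "B": rng.standard_normal(60) + 0.8 * y,
        "C": rng.standard_normal(60) + 0.8 * y,
    }
    act = make_activity(rows, samples)
    labels = balanced_labels(samples)
    # chain A - B - C: under first-only, C is never reachable
    pin = trivial_pin(["A", "B", "C"], [("A", "B"), ("B", "C")])
    cfg = pp.EvaluationConfig(seed=4, search_repeats=5, n_repeats=5, frontier="first-only")
    trace = pp.greedy_select(act, pin, labels, cfg)
    assert trace.steps[0].pathway == "A"
    assert "C" not in trace.final_set


def test_empty_pin_raises(rng):
    act = make_activity({"P": rng.standard_normal(20)}, [f"s{i}" for i in range(20)])
    labels = balanced_labels(act.sample_ids)
    pin = PathwayNetwork(nodes=[], edges={}, params={})
    with pytest.raises(pio.InputError):
        pp.greedy_select(act, pin, labels, pp.EvaluationConfig())
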