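import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from parklens import cluster as cl
from parklens.exceptions import ValidationError
from parklens.synth import generate_keyword_photos

from conftest import brute_jaccard


# --- binary matrix -------------------------------------------------------

def test_binary_matrix_example(photo_frame):
    bm = cl.build_binary_matrix(photo_frame([{"a", "b"}, {"b", "c"}]))
    assert bm.vocabulary == ["a", "b", "c"]
    assert bm.bits.tolist() == [[True, True, False], [False, True, True]]


def test_binary_matrix_single_photo_and_duplicates(photo_frame):
    df = photo_frame([{"a"}])
    df.at[0, "keywords"] = ["a", "a"]  # duplicates count once
    bm = cl.build_binary_matrix(df)
    assert bm.bits.shape == (1, 1) and bm.bits[0, 0]


def test_binary_matrix_rejects_empty_keyword_sets(photo_frame):
    df = photo_frame([{"a"}, set()])
    with pytest.raises(ValidationError, match="p1"):
        cl.build_binary_matrix(df)


# --- Jaccard distances ---------------------------------------------------

def test_jaccard_examples(photo_frame):
    dm = cl.jaccard_distances(cl.build_binary_matrix(photo_frame(
        [{"a", "b", "c"}, {"b", "c", "d"}, {"a", "b", "c"}, {"x", "y"}])))
    assert dm.d[0, 1] == pytest.approx(0.5)   # 1 - 2/4
    assert dm.d[0, 2] == 0.0                  # identical sets
    assert dm.d[0, 3] == 1.0                  # disjoint sets
    assert np.allclose(dm.d, dm.d.T) and np.all(np.diag(dm.d) == 0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.sets(st.sampled_from("abcdefghij"), min_size=1, max_size=8),
                min_size=2, max_size=20))
def test_jaccard_matches_brute_force_set_arithmetic(sets):
    df = pd.DataFrame({"photo_id": [f"p{i}" for i in range(len(sets))],
                       "keywords": [sorted(s) for s in sets]})
    dm = cl.jaccard_distances(cl.build_binary_matrix(df))
    for i in range(len(sets)):
        for j in range(len(sets)):
            assert dm.d[i, j] == pytest.approx(
                brute_jaccard(sets[i], sets[j]), abs=1e-12)


# --- Ward clustering -----------------------------------------------------

def test_ward_first_merge_is_the_identical_pair():
    d = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
    dend = cl.ward_cluster(cl.DistanceMatrix(["a", "b", "c"], d))
    assert set(dend.linkage[0, :2].astype(int)) == {0, 1}
    assert dend.linkage[0, 2] == pytest.approx(0.0)


def test_ward_heights_nondecreasing_and_cuts_give_k_clusters():
    photos, _ = generate_keyword_photos(60, seed=11)
    dm = cl.jaccard_distances(cl.build_binary_matrix(photos))
    dend = cl.ward_cluster(dm)
    heights = dend.linkage[:, 2]
    assert np.all(np.diff(heights) >= -1e-12)
    for k in (2, 5, 17, 60):
        model = cl.cut_and_label(dend, k, photos)
        assert model.assignments.nunique() == k


def test_ward_recovers_separated_blocks_exactly():
    # 4 blocks of 10 photos; zero within-block, large between-block distance
    sets = []
    for b in range(4):
        sets += [{f"b{b}x", f"b{b}y", f"b{b}z"}] * 10
    df = pd.DataFrame({"photo_id": [f"p{i}" for i in range(40)],
                       "keywords": [sorted(s) for s in sets]})
    dend = cl.ward_cluster(cl.jaccard_distances(cl.build_binary_matrix(df)))
    labels = cl.cut_and_label(dend, 4, df).assignments
    truth = np.repeat(np.arange(4), 10)
    assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0


# --- evaluation graph ----------------------------------------------------

def _block_fixture(sizes):
    sets = []
    for b, s in enumerate(sizes):
        sets += [{f"b{b}"}] * s
    return pd.DataFrame({"photo_id": [f"p{i}" for i in range(sum(sizes))],
                         "keywords": [sorted(s) for s in sets]})


def test_evaluation_graph_on_three_pure_blocks():
    # 9 points in 3 blocks: within distance 0, between distance 1.
    # k=2: one cluster holds two blocks -> within mean 9/18, between mean 1
    #      -> eval = 0.5
    # k=3 (pure blocks): within 0, between 1 -> eval = 1 (the maximum).
    # k=4 splits a block, moving 2 zero-distance pairs across clusters:
    #      between mean 27/29, eval < 1.
    df = _block_fixture([3, 3, 3])
    dm = cl.jaccard_distances(cl.build_binary_matrix(df))
    dend = cl.ward_cluster(dm)
    g = cl.evaluation_graph(dend, dm, k_max=5, sample_fraction=1.0)
    assert g.eval[0] == pytest.approx(1.0 - 9.0 / 18.0)
    assert g.eval[1] == pytest.approx(1.0)
    assert g.eval[2] == pytest.approx(27.0 / 29.0)
    assert g.eval.argmax() == 1  # peak at the true block count


def test_evaluation_graph_identical_points_is_zero():
    df = _block_fixture([8])
    dm = cl.jaccard_distances(cl.build_binary_matrix(df))
    dend = cl.ward_cluster(dm)
    g = cl.evaluation_graph(dend, dm, k_max=4, sample_fraction=1.0)
    assert np.allclose(g.eval, 0.0)


def test_evaluation_graph_sampling_degenerate_fractions_match():
    photos, _ = generate_keyword_photos(100, seed=5)
    dm = cl.jaccard_distances(cl.build_binary_matrix(photos))
    dend = cl.ward_cluster(dm)
    g1 = cl.evaluation_graph(dend, dm, 10, sample_fraction=1.0, seed=3)
    g2 = cl.evaluation_graph(dend, dm, 10, sample_fraction=0.999, seed=3,
                             min_sample=200)  # floor pulls sample to n
    assert np.allclose(g1.eval, g2.eval)


def test_evaluation_graph_rejects_bad_k_max():
    photos, _ = generate_keyword_photos(10, seed=5)
    dm = cl.jaccard_distances(cl.build_binary_matrix(photos))
    dend = cl.ward_cluster(dm)
    with pytest.raises(ValidationError):
        cl.evaluation_graph(dend, dm, k_max=10)


# --- L-method ------------------------------------------------------------

def _piecewise(ks, break_k, s1=0.30, s2=0.01):
    ks = np.asarray(ks, dtype=float)
    y = np.where(ks <= break_k, s1 * (ks - 2),
                 s1 * (break_k - 2) + s2 * (ks - break_k))
    return cl.EvaluationGraph(ks.astype(int), y)


@pytest.mark.parametrize("break_k", range(3, 20))
def test_lmethod_finds_exact_piecewise_linear_breaks(break_k):
    g = _piecewise(np.arange(2, 22), break_k)
    assert cl.lmethod_knee(g, initial_cutoff=20) == break_k


def test_lmethod_collinear_graph_warns_and_returns_smallest_candidate():
    g = cl.EvaluationGraph(np.arange(2, 12), 0.1 * np.arange(2, 12))
    with pytest.warns(UserWarning, match="collinear"):
        assert cl.lmethod_knee(g) == 3


def test_lmethod_rejects_nonfinite_values():
    g = cl.EvaluationGraph(np.arange(2, 12), np.full(10, np.nan))
    with pytest.raises(ValidationError):
        cl.lmethod_knee(g)


def brute_force_knee(ks, ys):
    """Independent exhaustive two-line search (size-weighted RMSE)."""
    ks, ys = np.asarray(ks, float), np.asarray(ys, float)
    b = len(ks)
    best, best_c = np.inf, None
    for c in range(2, b - 1):
        r = 0.0
        for xs, yy in ((ks[:c], ys[:c]), (ks[c:], ys[c:])):
            coef = np.polyfit(xs, yy, 1)
            r += len(xs) * np.sqrt(np.mean((yy - np.polyval(coef, xs)) ** 2))
        if r / b < best:
            best, best_c = r / b, c
    return int(ks[best_c - 1])


def test_lmethod_matches_brute_force_on_smooth_curve():
    ks = np.arange(2, 31)
    ys = 1.0 - 0.9 ** ks
    g = cl.EvaluationGraph(ks, ys)
    knee = cl.lmethod_knee(g, initial_cutoff=20)
    # compare against the oracle run on the same final window
    assert knee == brute_force_knee(ks[:20], ys[:20])


# --- cut_and_label / aggregation -----------------------------------------

def test_cut_and_label_top_keywords_and_boundaries(photo_frame):
    df = photo_frame([{"bird", "tree"}, {"bird", "sky"}, {"car", "road"},
                      {"car", "night"}])
    dend = cl.ward_cluster(cl.jaccard_distances(cl.build_binary_matrix(df)))
    model = cl.cut_and_label(dend, 2, df, top_n=3)
    bird_cat = model.assignments["p0"]
    assert "bird" in model.labels[bird_cat]["top_keywords"]
    every_own = cl.cut_and_label(dend, 4, df)
    assert every_own.assignments.nunique() == 4


def test_synthetic_category_recovery_ari():
    photos, truth = generate_keyword_photos(600, seed=21)
    dm = cl.jaccard_distances(cl.build_binary_matrix(photos))
    dend = cl.ward_cluster(dm)
    model = cl.cut_and_label(dend, 10, photos)
    ari = adjusted_rand_score(truth.to_numpy(),
                              model.assignments.reindex(truth.index).to_numpy())
    assert ari >= 0.8


def test_aggregate_identity_and_coarsening(photo_frame):
    photos, _ = generate_keyword_photos(120, n_categories=10, seed=4)
    dend = cl.ward_cluster(cl.jaccard_distances(cl.build_binary_matrix(photos)))
    model = cl.cut_and_label(dend, 10, photos)
    same = cl.aggregate_categories(model, {})
    assert same.aggregated_assignments().equals(model.assignments)
    merged = cl.aggregate_categories(
        model, {c: c - (c % 2) for c in range(10)})  # 10 -> 5
    assert merged.aggregated_assignments().nunique() == 5
    with pytest.raises(ValidationError):
        cl.aggregate_categories(model, {99: 0})


def test_aggregating_truth_aligned_groups_never_lowers_accuracy():
    photos, truth = generate_keyword_photos(500, seed=8)
    dend = cl.ward_cluster(cl.jaccard_distances(cl.build_binary_matrix(photos)))
    model = cl.cut_and_label(dend, 10, photos)
    assign = model.assignments.reindex(truth.index)
    # align cluster ids to truth by majority vote
    align = (pd.DataFrame({"a": assign, "t": truth})
             .groupby("a")["t"].agg(lambda s: s.value_counts().idxmax()))
    acc_before = (assign.map(align) == truth).mean()
    merge = {c: min(c, 3) for c in range(4)}  # pool the first four categories
    coarse = cl.aggregate_categories(model, merge)
    assign_c = coarse.aggregated_assignments().reindex(truth.index)
    truth_c = truth.map(lambda t: min(t, 3) if t < 4 else t)
    align_c = (pd.DataFrame({"a": assign_c, "t": truth_c})
               .groupby("a")["t"].agg(lambda s: s.value_counts().idxmax()))
    acc_after = (assign_c.map(align_c) == truth_c).mean()
    assert acc_after >= acc_before
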