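import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import special_ortho_group

from microshift import (DissimilarityMatrix, OrdinationResult, SampleMetadata,
                        anosim, bray_curtis, gm_offset, gm_offset_test,
                        group_centroids, pcoa, to_relative)
from microshift.errors import ParameterError, ValidationError

from conftest import null_two_group_design
from microshift.synthetic_data import simulate_counts


def _ord(coords, ids=None):
    coords = np.asarray(coords, float)
    ids = ids or [f"s{i}" for i in range(len(coords))]
    k = coords.shape[1]
    return OrdinationResult(sample_ids=ids, coordinates=coords,
                            eigenvalues=np.ones(k),
                            proportion_explained=np.full(k, 1 / k))


def _meta(labels, ids=None):
    ids = ids or [f"s{i}" for i in range(len(labels))]
    return SampleMetadata(pd.DataFrame(
        [{"sample_id": s, "mouse_id": s, "group": g, "week": 10}
         for s, g in zip(ids, labels)]))


def _dm(points):
    return DissimilarityMatrix([f"s{i}" for i in range(len(points))],
                               squareform(pdist(points)))


def test_centroids_worked_examples():
    o = _ord([[1, 2], [3, 4], [7, 7]])
    cents = {c.group: c for c in group_centroids(o, _meta(["G", "G", "H"]))}
    np.testing.assert_allclose(cents["G"].means, [2, 3])
    np.testing.assert_allclose(cents["H"].means, [7, 7])  # singleton
    assert cents["G"].n_samples == 2
    # order invariance
    o2 = _ord([[3, 4], [7, 7], [1, 2]], ids=["s1", "s2", "s0"])
    cents2 = {c.group: c for c in group_centroids(
        o2, _meta(["G", "H", "G"], ids=["s1", "s2", "s0"]))}
    np.testing.assert_allclose(cents2["G"].means, [2, 3])


def test_gm_offset_three_four_five():
    o = _ord([[0, 0], [3, 4]])
    assert gm_offset(o, _meta(["A", "B"]), "A", "B") == pytest.approx(5.0)


def test_gm_offset_same_group_zero_with_warning():
    o = _ord([[0, 0], [3, 4]])
    with pytest.warns(UserWarning, match="itself"):
        assert gm_offset(o, _meta(["A", "A"]), "A", "A") == 0.0


def test_gm_offset_symmetric_in_groups():
    o = _ord(np.random.default_rng(0).normal(size=(8, 2)))
    m = _meta(["A"] * 4 + ["B"] * 4)
    assert gm_offset(o, m, "A", "B") == pytest.approx(
        gm_offset(o, m, "B", "A"), abs=1e-14)


@pytest.mark.parametrize("seed", range(5))
def test_gm_offset_invariant_under_orthogonal_transforms(seed):
    rng = np.random.default_rng(seed)
    coords = rng.normal(size=(10, 2))
    m = _meta(["A"] * 5 + ["B"] * 5)
    base = gm_offset(_ord(coords), m, "A", "B")
    # sign flips of either axis
    for flip in ([-1, 1], [1, -1], [-1, -1]):
        assert gm_offset(_ord(coords * flip), m, "A", "B") == pytest.approx(
            base, abs=1e-10)
    # random in-plane rotations
    for _ in range(3):
        Q = special_ortho_group.rvs(2, random_state=rng)
        assert gm_offset(_ord(coords @ Q), m, "A", "B") == pytest.approx(
            base, abs=1e-10)


def test_gm_offset_brute_force_oracle_small_n():
    # ≤6 samples: compare against hand-coded centroid arithmetic
    rng = np.random.default_rng(1)
    coords = rng.normal(size=(6, 3))
    labels = ["A", "B", "A", "B", "B", "A"]
    m = _meta(labels)
    got = gm_offset(_ord(coords), m, "A", "B", n_axes=3)
    ca = np.mean([coords[i] for i, l in enumerate(labels) if l == "A"], axis=0)
    cb = np.mean([coords[i] for i, l in enumerate(labels) if l == "B"], axis=0)
    expected = float(np.sqrt(((ca - cb) ** 2).sum()))
    assert got == pytest.approx(expected, abs=1e-12)


def test_gm_offset_monotone_in_retained_axes(default_study):
    _, counts, meta, _ = default_study
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        o = pcoa(bray_curtis(to_relative(counts)))
    end = SampleMetadata(meta.df[meta.df.week == 10].copy())
    full = o.coordinates.shape[1]
    off2 = gm_offset(o, end, "CD+SPSS", "HFD+SPSS", n_axes=2)
    off_all = gm_offset(o, end, "CD+SPSS", "HFD+SPSS", n_axes=full)
    assert off_all >= off2 - 1e-12


def test_gm_offset_test_separated_clouds_attain_min_p():
    rng = np.random.default_rng(0)
    a = rng.normal(size=(6, 2)) * 0.01
    b = rng.normal(size=(6, 2)) * 0.01 + 100.0
    D = _dm(np.vstack([a, b]))
    m = _meta(["A"] * 6 + ["B"] * 6)
    res = gm_offset_test(D, m, "A", "B", n_permutations=999, seed=5)
    assert res.permutation_p == pytest.approx(1 / 1000)
    assert res.bootstrap_ci[0] <= res.gm_offset <= res.bootstrap_ci[1] * 1.001


def test_gm_offset_test_deterministic_under_seed():
    d = null_two_group_design(seed=9)
    t, meta, _ = simulate_counts(d)
    D = bray_curtis(to_relative(t))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = gm_offset_test(D, meta, "A", "B", n_permutations=199, seed=3)
        r2 = gm_offset_test(D, meta, "A", "B", n_permutations=199, seed=3)
    assert r1 == r2


def test_gm_offset_test_small_groups_rejected():
    D = _dm(np.random.default_rng(0).normal(size=(3, 2)))
    m = _meta(["A", "A", "B"])
    with pytest.raises(ValidationError, match="< 4"):
        gm_offset_test(D, m, "A", "B")
    with pytest.raises(ParameterError, match="99"):
        gm_offset_test(_dm(np.random.default_rng(0).normal(size=(6, 2))),
                       _meta(["A"] * 3 + ["B"] * 3), "A", "B", n_permutations=10)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def test_anosim_perfect_separation_gives_r_one():
    rng = np.random.default_rng(2)
    a = rng.normal(size=(5, 2)) * 0.1
    b = rng.normal(size=(5, 2)) * 0.1 + 50.0
    res = anosim(_dm(np.vstack([a, b])), _meta(["A"] * 5 + ["B"] * 5),
                 n_permutations=99, seed=0)
    assert res.R == pytest.approx(1.0)
    assert res.permutation_p <= 0.05


def test_anosim_null_mean_r_near_zero():
    # fixed exchangeable cloud, labels re-assigned at random each rep
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(12, 3))
    D = _dm(pts)
    rs = []
    for rep in range(1000):
        labels = rng.permutation(["A"] * 6 + ["B"] * 6)
        res = anosim(D, _meta(list(labels)), n_permutations=99, seed=rep)
        rs.append(res.R)
    assert abs(np.mean(rs)) < 0.02


def test_anosim_matches_skbio(default_study):
    skbio = pytest.importorskip("skbio")
    _, counts, meta, _ = default_study
    end = SampleMetadata(meta.df[meta.df.week == 10].copy())
    rel = to_relative(counts).subset(end.sample_ids)
    D = bray_curtis(rel)
    ours = anosim(D, end, n_permutations=999, seed=0)
    ref = skbio.stats.distance.anosim(
        skbio.DistanceMatrix(D.values, ids=D.sample_ids),
        grouping=[end.group_of()[s] for s in D.sample_ids],
        permutations=999)
    assert ours.R == pytest.approx(ref["test statistic"], abs=1e-12)


def test_anosim_determinism_and_size_guard():
    d = null_two_group_design(seed=1)
    t, meta, _ = simulate_counts(d)
    D = bray_curtis(to_relative(t))
    assert anosim(D, meta, 199, seed=4) == anosim(D, meta, 199, seed=4)
    with pytest.raises(ValidationError, match="size 1"):
        anosim(_dm(np.random.default_rng(0).normal(size=(3, 2))),
               _meta(["A", "A", "B"]))
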