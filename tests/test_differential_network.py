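import dataclasses

import numpy as np
import pandas as pd
import pytest

from microshift import (RelativeAbundanceTable, SampleMetadata,
                        abundance_ratio, core_specific, correlation_network,
                        differential_genera, key_microbes)
from microshift.differential_network import DifferentialRecord, edges_to_frame
from microshift.errors import JoinError, ParameterError, ValidationError
from microshift.synthetic_data import SimDesign, simulate_counts
from microshift import to_relative


def _rel_and_meta(col_a, col_b, n_extra_mass=True):
    """Two-condition rel table whose first genus carries the given values."""
    vals = np.concatenate([col_a, col_b])
    rows = []
    for v in vals:
        rows.append([v, (1 - v) / 2, (1 - v) / 2])
    ids = [f"s{i}" for i in range(len(vals))]
    rel = RelativeAbundanceTable(ids, ["g0", "g1", "g2"], np.array(rows))
    meta = SampleMetadata(pd.DataFrame(
        [{"sample_id": s, "mouse_id": s,
          "group": "A" if i < len(col_a) else "B", "week": 4}
         for i, s in enumerate(ids)]))
    return rel, meta


def _welch_p(a, b):
    # independent hand-coded Welch oracle
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    from scipy.stats import t as tdist
    return 2 * tdist.sf(abs(t), df)


def test_differential_identical_values_not_significant():
    rel, meta = _rel_and_meta([0.2] * 3, [0.2] * 3)
    recs = differential_genera(rel, meta, "A", "B")
    g0 = next(r for r in recs if r.genus == "g0")
    assert g0.p_value == 1.0 and not g0.significant and g0.log2_ratio == 0.0


def test_differential_welch_worked_example():
    a = [0.10, 0.11, 0.09, 0.10, 0.10]
    b = [0.20, 0.21, 0.19, 0.20, 0.20]
    rel, meta = _rel_and_meta(a, b)
    recs = differential_genera(rel, meta, "A", "B")
    g0 = next(r for r in recs if r.genus == "g0")
    assert g0.significant
    assert g0.log2_ratio == pytest.approx(np.log2(0.10 / 0.20), abs=1e-9)
    assert g0.p_value == pytest.approx(_welch_p(a, b), rel=1e-9)
    # records sorted by p ascending
    assert [r.p_value for r in recs] == sorted(r.p_value for r in recs)


def test_differential_requires_two_samples_per_condition():
    rel, meta = _rel_and_meta([0.2], [0.2, 0.3])
    with pytest.raises(ValidationError, match="2 samples"):
        differential_genera(rel, meta, "A", "B")


def test_differential_min_prevalence_excludes_and_warns():
    rel, meta = _rel_and_meta([0.0] * 4, [0.0] * 4)  # g0 absent everywhere
    with pytest.warns(UserWarning, match="prevalence"):
        recs = differential_genera(rel, meta, "A", "B", min_prevalence=0.5)
    assert all(r.genus != "g0" for r in recs)


def _recs(genera):
    return [DifferentialRecord(g, 0.1, 0.2, -1.0, 0.01, True) for g in genera]


def test_key_microbes_intersection_rules():
    assert key_microbes(_recs("ABC"), _recs("BCD")) == {"B", "C"}
    assert key_microbes(_recs("AB"), _recs("CD")) == set()
    assert key_microbes(_recs("AB"), _recs("AB")) == {"A", "B"}
    # commutative and idempotent
    assert key_microbes(_recs("ABC"), _recs("BCD")) == key_microbes(
        _recs("BCD"), _recs("ABC"))
    assert key_microbes(_recs("AB"), _recs("AB")) == {"A", "B"}


def _group_rel(rows_by_group, genera):
    ids, labels, mat = [], [], []
    for g, rows in rows_by_group.items():
        for i, r in enumerate(rows):
            ids.append(f"{g}{i}")
            labels.append(g)
            mat.append(r)
    rel = RelativeAbundanceTable(ids, genera, np.array(mat, float))
    meta = SampleMetadata(pd.DataFrame(
        [{"sample_id": s, "mouse_id": s, "group": g, "week": 10}
         for s, g in zip(ids, labels)]))
    return rel, meta


def test_core_specific_partitions():
    genera = ["u", "v", "w"]
    rel, meta = _group_rel({
        "A": [[0.5, 0.5, 0.0]],
        "B": [[0.4, 0.6, 0.0]],
    }, genera)
    part = core_specific(rel, meta)
    assert part.core == {"u", "v"}
    assert part.specific == {"A": set(), "B": set()}
    # one genus present in exactly one group → that group's specific set
    rel2, meta2 = _group_rel({
        "A": [[0.5, 0.3, 0.2]],
        "B": [[0.4, 0.6, 0.0]],
    }, genera)
    part2 = core_specific(rel2, meta2)
    assert "w" in part2.specific["A"] and part2.core == {"u", "v"}


def test_core_count_matches_constructed_venn():
    # 4 groups sharing exactly 23 genera; each group has 2 private genera
    rng = np.random.default_rng(0)
    n_core, n_priv, groups = 23, 2, ["G1", "G2", "G3", "G4"]
    genera = [f"core{i}" for i in range(n_core)] + [
        f"{g}_priv{i}" for g in groups for i in range(n_priv)]
    rows_by_group = {}
    for gi, g in enumerate(groups):
        vec = np.zeros(len(genera))
        vec[:n_core] = rng.random(n_core) + 0.1
        start = n_core + gi * n_priv
        vec[start:start + n_priv] = 0.05
        vec /= vec.sum()
        rows_by_group[g] = [vec, vec]
    rel, meta = _group_rel(rows_by_group, genera)
    part = core_specific(rel, meta)
    assert len(part.core) == 23
    assert all(len(part.specific[g]) == n_priv for g in groups)


def test_abundance_ratio_values():
    rel, meta = _rel_and_meta([0.2, 0.2], [0.1, 0.1])
    out = abundance_ratio(rel, meta, "A", "B", pseudocount=0.0).set_index("genus")
    assert out.loc["g0", "ratio"] == pytest.approx(2.0)
    same = abundance_ratio(rel, meta, "A", "A", pseudocount=0.0).set_index("genus")
    assert same.loc["g0", "ratio"] == pytest.approx(1.0)
    with pytest.raises(ParameterError, match="pseudocount"):
        abundance_ratio(rel, meta, "A", "B", pseudocount=-1e-6)


def test_abundance_ratio_pseudocount_arithmetic():
    rel, meta = _rel_and_meta([1e-3, 1e-3], [0.0, 0.0])
    out = abundance_ratio(rel, meta, "A", "B", pseudocount=1e-6).set_index("genus")
    assert out.loc["g0", "ratio"] == pytest.approx((1e-3 + 1e-6) / 1e-6)


def _network_inputs(n_mice=10, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"m{i}" for i in range(n_mice)]
    meta = SampleMetadata(pd.DataFrame(
        [{"sample_id": s, "mouse_id": s, "group": "A", "week": 10} for s in ids]))
    fr = rng.dirichlet(np.full(5, 30.0), size=n_mice)
    rel = RelativeAbundanceTable(ids, [f"g{j}" for j in range(5)], fr)
    return rel, meta, ids


def test_network_perfect_correlation_edge_retained():
    rel, meta, ids = _network_inputs(4)
    feat = pd.DataFrame({"mouse_id": ids,
                         "bw": 2.0 * rel.fractions[:, 0]})  # exactly linear
    edges = correlation_network(rel, feat, meta)
    hit = [e for e in edges if {e.node_a, e.node_b} == {"g0", "bw"}]
    assert len(hit) == 1 and hit[0].r == pytest.approx(1.0)


def test_network_no_self_edges_unique_pairs():
    rel, meta, ids = _network_inputs(12, seed=1)
    feat = pd.DataFrame({"mouse_id": ids,
                         "bw": np.random.default_rng(1).normal(size=12)})
    edges = correlation_network(rel, feat, meta, alpha=1.0)
    pairs = [frozenset((e.node_a, e.node_b)) for e in edges]
    assert all(len(p) == 2 for p in pairs)
    assert len(pairs) == len(set(pairs))


def test_network_bh_subset_of_unadjusted():
    rel, meta, ids = _network_inputs(15, seed=2)
    rng = np.random.default_rng(3)
    feat = pd.DataFrame({"mouse_id": ids,
                         **{f"f{j}": rng.normal(size=15) for j in range(4)}})
    raw = correlation_network(rel, feat, meta, alpha=0.05, adjust="none")
    bh = correlation_network(rel, feat, meta, alpha=0.05, adjust="bh")
    raw_pairs = {frozenset((e.node_a, e.node_b)) for e in raw}
    bh_pairs = {frozenset((e.node_a, e.node_b)) for e in bh}
    assert bh_pairs <= raw_pairs


def test_network_unjoinable_and_constant_columns():
    rel, meta, ids = _network_inputs(5, seed=4)
    feat = pd.DataFrame({"mouse_id": ids[:-1],
                         "bw": np.arange(4.0)})
    with pytest.raises(JoinError, match="m4"):
        correlation_network(rel, feat, meta)
    feat2 = pd.DataFrame({"mouse_id": ids, "bw": np.ones(5)})
    with pytest.warns(UserWarning, match="constant"):
        correlation_network(rel, feat2, meta)


def test_sensitivity_and_bh_false_discoveries_on_planted_effects():
    # δ=1 planted shifts at n=20/group: recover ≥80% of shifted genera, and
    # BH keeps false discoveries among null genera ≤10% of calls
    d = SimDesign(groups=("CD+SPSS", "HFD+SPSS"), n_mice_per_group=20, seed=12)
    tab, meta, truth = simulate_counts(d)
    rel = to_relative(tab)
    recs = differential_genera(rel, meta, ("HFD+SPSS", 10), ("CD+SPSS", 10))
    sig = {r.genus for r in recs if r.significant}
    shifted = truth.genera_truly_shifted
    assert len(sig & shifted) / len(shifted) >= 0.8
    # BH on the p-values: discoveries outside the truly shifted set are rare
    from scipy.stats import false_discovery_control
    ps = np.array([r.p_value for r in recs])
    q = false_discovery_control(ps)
    disc = {r.genus for r, qq in zip(recs, q) if qq < 0.05}
    if disc:
        assert len(disc - shifted) / len(disc) <= 0.10


def test_edges_to_frame_columns():
    rel, meta, ids = _network_inputs(6, seed=5)
    feat = pd.DataFrame({"mouse_id": ids, "bw": np.arange(6.0)})
    df = edges_to_frame(correlation_network(rel, feat, meta, alpha=1.0))
    assert list(df.columns) == ["source", "target", "method", "r", "p", "q"]
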