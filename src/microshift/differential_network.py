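"""Differential genera, key-microbe intersection, core/specific partition,
abundance ratios, and genus–phenotype correlation networks.

The differential rule follows the study design it serves: a per-genus
two-sample t-test on relative abundances with raw p < α retention (Welch's
unequal-variance form by default; Student's and Kruskal–Wallis available).
Benjamini–Hochberg adjustment is optional — off by default for fidelity,
recommended in practice.

A "condition" below is either a group label (all weeks) or a
``(group, week)`` pair, so the same machinery expresses both between-group
contrasts (e.g. treated vs untreated at the endpoint) and within-group
pre/post contrasts (week 4 vs week 10 under one treatment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import RelativeAbundanceTable
from .errors import JoinError, ParameterError, ValidationError
from .tables_io import SampleMetadata

Condition = "str | tuple[str, int]"


@dataclass
class DifferentialRecord:
    genus: str
    mean_a: float
    mean_b: float
    log2_ratio: float
    p_value: float
    significant: bool


@dataclass
class NetworkEdge:
    node_a: str
    node_b: str
    type_a: str  # "genus" | "body_feature"
    type_b: str
    method: str
    r: float
    p_value: float
    q_value: float | None = None


@dataclass
class CoreGenusPartition:
    group_sets: dict[str, set[str]]
    core: set[str]
    specific: dict[str, set[str]]


def _select_samples(meta: SampleMetadata, cond) -> list[str]:
    if isinstance(cond, tuple):
        group, week = cond
        sids = meta.samples_in(group, week)
    else:
        sids = meta.samples_in(cond)
    if not sids:
        raise ValidationError(f"condition {cond!r} selects no samples")
    return sids


def differential_genera(rel: RelativeAbundanceTable, meta: SampleMetadata,
                        cond_a, cond_b, alpha: float = 0.05,
                        min_prevalence: float = 0.0, test: str = "welch",
                        pseudocount: float = 0.0,
                        ) -> list[DifferentialRecord]:
    """Per-genus two-sample test of relative abundance between conditions.

    Genera present (nonzero) in fewer than ``min_prevalence`` of the
    combined samples are excluded (reported via a warning). Records are
    sorted by p-value ascending. ``log2_ratio`` is
    log2((mean_a + ε)/(mean_b + ε)) with ε = ``pseudocount``; means equal
    on both sides give exactly 0.
    """
    if test not in ("welch", "student", "kruskal"):
        raise ParameterError("test must be 'welch', 'student' or 'kruskal'")
    if pseudocount < 0:
        raise ParameterError("pseudocount must be non-negative")
    sids_a = _select_samples(meta, cond_a)
    sids_b = _select_samples(meta, cond_b)
    if len(sids_a) < 2 or len(sids_b) < 2:
        raise ValidationError("both conditions need ≥ 2 samples")
    A = rel.subset(sids_a).fractions
    B = rel.subset(sids_b).fractions

    both = np.vstack([A, B])
    prevalence = (both > 0).mean(axis=0)
    keep = prevalence >= min_prevalence
    dropped = [g for g, k in zip(rel.genus_ids, keep) if not k]
    if dropped:
        warnings.warn(f"{len(dropped)} genera below prevalence "
                      f"{min_prevalence}: {dropped[:5]}", stacklevel=2)

    records = []
    for j, genus in enumerate(rel.genus_ids):
        if not keep[j]:
            continue
        a, b = A[:, j], B[:, j]
        ma, mb = float(a.mean()), float(b.mean())
        if np.ptp(a) == 0 and np.ptp(b) == 0 and ma == mb:
            p = 1.0
        elif test == "kruskal":
            p = float(stats.kruskal(a, b).pvalue)
        else:
            p = float(stats.ttest_ind(a, b, equal_var=(test == "student")).pvalue)
            if np.isnan(p):
                p = 1.0
        if ma == mb:
            lr = 0.0
        else:
            num, den = ma + pseudocount, mb + pseudocount
            lr = float(np.log2(num / den)) if den > 0 and num > 0 else float("inf") * np.sign(ma - mb)
        records.append(DifferentialRecord(genus=genus, mean_a=ma, mean_b=mb,
                                          log2_ratio=lr, p_value=p,
                                          significant=p < alpha))
    records.sort(key=lambda r: (r.p_value, r.genus))
    return records


def key_microbes(diff_a: list[DifferentialRecord],
                 diff_b: list[DifferentialRecord]) -> set[str]:
    """Genera significant in BOTH contrasts (set intersection)."""
    sa = {r.genus for r in diff_a if r.significant}
    sb = {r.genus for r in diff_b if r.significant}
    return sa & sb


def core_specific(rel: RelativeAbundanceTable, meta: SampleMetadata,
                  presence_threshold: float = 0.0) -> CoreGenusPartition:
    """Partition genera into core (present in every group) and specific
    (present in exactly one group). "Present" means group-mean relative
    abundance strictly above ``presence_threshold``."""
    groups = meta.groups
    if len(groups) < 2:
        raise ValidationError("core/specific partition needs ≥ 2 groups")
    group_sets: dict[str, set[str]] = {}
    for grp in groups:
        sub = rel.subset(meta.samples_in(grp))
        means = sub.fractions.mean(axis=0)
        group_sets[grp] = {g for g, m in zip(rel.genus_ids, means)
                           if m > presence_threshold}
    core = set.intersection(*group_sets.values())
    specific = {}
    for grp in groups:
        others = set.union(*(group_sets[o] for o in groups if o != grp)) if len(groups) > 1 else set()
        specific[grp] = group_sets[grp] - others
    return CoreGenusPartition(group_sets=group_sets, core=core, specific=specific)


def abundance_ratio(rel: RelativeAbundanceTable, meta: SampleMetadata,
                    cond_post, cond_pre, pseudocount: float = 1e-6
                    ) -> pd.DataFrame:
    """(mean_post + ε)/(mean_pre + ε) per genus."""
    if pseudocount < 0:
        raise ParameterError("pseudocount must be non-negative")
    post = rel.subset(_select_samples(meta, cond_post)).fractions.mean(axis=0)
    pre = rel.subset(_select_samples(meta, cond_pre)).fractions.mean(axis=0)
    ratio = (post + pseudocount) / (pre + pseudocount)
    return pd.DataFrame({"genus": rel.genus_ids, "mean_post": post,
                         "mean_pre": pre, "ratio": ratio})


def correlation_network(rel: RelativeAbundanceTable, features: pd.DataFrame,
                        meta: SampleMetadata, method: str = "pearson",
                        alpha: float = 0.05, adjust: str = "none",
                        ) -> list[NetworkEdge]:
    """All genus–genus and genus–feature pairwise correlations, retained at
    p < α (or BH-adjusted q < α).

    ``features`` holds one row per mouse (column ``mouse_id`` plus numeric
    body-measurement columns); each sample is joined to its mouse's
    features. Constant columns are skipped with a warning. The edge list is
    symmetric by construction: each unordered pair appears once.
    """
    if method not in ("pearson", "spearman"):
        raise ParameterError("method must be 'pearson' or 'spearman'")
    if adjust not in ("none", "bh"):
        raise ParameterError("adjust must be 'none' or 'bh'")
    if "mouse_id" not in features.columns:
        raise JoinError("features table needs a mouse_id column")
    mouse_of = meta.mouse_of()
    feat = features.set_index("mouse_id")
    missing = sorted({mouse_of[s] for s in rel.sample_ids
                      if mouse_of.get(s) not in feat.index})
    if missing or any(s not in mouse_of for s in rel.sample_ids):
        unjoined = [s for s in rel.sample_ids
                    if mouse_of.get(s) not in feat.index]
        raise JoinError(f"samples not joinable to features: {unjoined}")

    feat_cols = [c for c in feat.columns]
    F = feat.loc[[mouse_of[s] for s in rel.sample_ids], feat_cols].to_numpy(float)
    X = np.hstack([rel.fractions, F])
    names = list(rel.genus_ids) + feat_cols
    types = ["genus"] * len(rel.genus_ids) + ["body_feature"] * len(feat_cols)
    n = X.shape[0]
    if n < 3:
        raise ValidationError("need ≥ 3 joint observations")

    const = np.ptp(X, axis=0) == 0
    if const.any():
        warnings.warn(f"constant columns skipped: "
                      f"{[names[i] for i in np.where(const)[0]]}", stacklevel=2)
    keep = ~const
    X, names = X[:, keep], [nm for nm, k in zip(names, keep) if k]
    types = [t for t, k in zip(types, keep) if k]

    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 0, X)
    R = np.corrcoef(X, rowvar=False)
    R = np.clip(R, -1.0, 1.0)
    iu, ju = np.triu_indices(len(names), k=1)
    r = R[iu, ju]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    q = stats.false_discovery_control(p) if adjust == "bh" else None

    edges = []
    crit = q if adjust == "bh" else p
    for k in range(len(r)):
        if crit[k] < alpha:
            i, j = iu[k], ju[k]
            edges.append(NetworkEdge(
                node_a=names[i], node_b=names[j], type_a=types[i],
                type_b=types[j], method=method, r=float(r[k]),
                p_value=float(p[k]),
                q_value=float(q[k]) if q is not None else None))
    return edges


def edges_to_frame(edges: list[NetworkEdge]) -> pd.DataFrame:
    """Cytoscape-importable edge table (source, target, method, r, p, q)."""
    return pd.DataFrame(
        [{"source": e.node_a, "target": e.node_b, "method": e.method,
          "r": e.r, "p": e.p_value, "q": e.q_value} for e in edges],
        columns=["source", "target", "method", "r", "p", "q"])
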