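"""The GM_offset centroid-distance statistic and its inference machinery.

GM_offset(g1, g2) is the Euclidean distance between the two groups' mean
coordinates on the first ordination axes (two by default: PCo1 and PCo2) —
a scalar effect size for "how far did the community move". It is invariant
to axis sign flips, to any rotation of the retained subspace, and to
swapping the two groups.

Because the statistic comes with no analytic null, significance is assessed
by permuting group labels among the two groups' samples on the *fixed*
ordination (the ordination depends only on the distance matrix, never on
labels, so recomputing it per permutation would change nothing), and
uncertainty by bootstrap resampling of mice within groups. ANOSIM is
provided as the standard rank-based companion test of group separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .beta_ordination import DissimilarityMatrix, OrdinationResult, pcoa
from .errors import ParameterError, ValidationError
from .tables_io import SampleMetadata


@dataclass
class GroupCentroid:
    group: str
    means: np.ndarray  # one mean per retained axis; means[0] is PCo1
    n_samples: int

    @property
    def pco1_mean(self) -> float:
        return float(self.means[0])

    @property
    def pco2_mean(self) -> float:
        return float(self.means[1]) if self.means.size > 1 else 0.0


@dataclass
class OffsetResult:
    group_a: str
    group_b: str
    gm_offset: float
    n_axes_used: int
    permutation_p: float
    n_permutations: int
    bootstrap_ci: tuple[float, float]
    seed: int


@dataclass
class AnosimResult:
    R: float
    permutation_p: float
    n_permutations: int
    seed: int


def _coords_for(ord_res: OrdinationResult, sample_ids: list[str],
                n_axes: int) -> np.ndarray:
    if n_axes < 1:
        raise ParameterError("n_axes must be ≥ 1")
    avail = ord_res.coordinates.shape[1]
    if n_axes > avail:
        raise ParameterError(f"n_axes={n_axes} exceeds available axes ({avail})")
    pos = {s: i for i, s in enumerate(ord_res.sample_ids)}
    try:
        idx = [pos[s] for s in sample_ids]
    except KeyError as e:
        raise ValidationError(f"sample {e.args[0]!r} not in ordination") from None
    return ord_res.coordinates[idx, :n_axes]


def group_centroids(ord_res: OrdinationResult, meta: SampleMetadata,
                    n_axes: int = 2) -> list[GroupCentroid]:
    """Arithmetic mean of each retained axis per group."""
    out = []
    for grp in meta.groups:
        sids = meta.samples_in(grp)
        if not sids:
            raise ValidationError(f"group {grp!r} has no samples")
        C = _coords_for(ord_res, sids, n_axes)
        out.append(GroupCentroid(grp, C.mean(axis=0), len(sids)))
    return out


def _centroid(ord_res: OrdinationResult, meta: SampleMetadata, group: str,
              n_axes: int) -> np.ndarray:
    sids = meta.samples_in(group)
    if not sids:
        raise ValidationError(f"group {group!r} has no samples")
    return _coords_for(ord_res, sids, n_axes).mean(axis=0)


def gm_offset(ord_res: OrdinationResult, meta: SampleMetadata,
              group_a: str, group_b: str, n_axes: int = 2) -> float:
    """Euclidean distance between the two group centroids on the first
    ``n_axes`` ordination axes."""
    if group_a == group_b:
        warnings.warn(f"gm_offset of a group with itself ({group_a!r}) is 0",
                      stacklevel=2)
        _centroid(ord_res, meta, group_a, n_axes)  # still validates
        return 0.0
    ca = _centroid(ord_res, meta, group_a, n_axes)
    cb = _centroid(ord_res, meta, group_b, n_axes)
    return float(np.linalg.norm(ca - cb))


def gm_offset_test(D: DissimilarityMatrix, meta: SampleMetadata,
                   group_a: str, group_b: str, n_axes: int = 2,
                   n_permutations: int = 999, seed: int = 0,
                   n_bootstrap: int = 999, correction: str = "none",
                   ord_res: OrdinationResult | None = None) -> OffsetResult:
    """Permutation p-value and bootstrap CI for the observed GM_offset.

    The null permutes group labels among the two groups' samples on the
    fixed ordination; p uses the add-one estimator
    (1 + #{null ≥ observed}) / (1 + B), so p ≥ 1/(B+1) and never 0. The CI
    resamples mice (not samples) within each group, respecting the repeated-
    measures design.
    """
    if n_permutations < 99:
        raise ParameterError("n_permutations must be ≥ 99")
    sids_a, sids_b = meta.samples_in(group_a), meta.samples_in(group_b)
    if not sids_a or not sids_b:
        raise ValidationError(f"empty group among {group_a!r}, {group_b!r}")
    if len(sids_a) + len(sids_b) < 4:
        raise ValidationError("combined group size < 4: permutation null degenerate")
    if ord_res is None:
        ord_res = pcoa(D, correction=correction)
    n_axes_eff = min(n_axes, ord_res.coordinates.shape[1])
    observed = gm_offset(ord_res, meta, group_a, group_b, n_axes_eff)

    rng = np.random.default_rng(seed)
    A = _coords_for(ord_res, sids_a, n_axes_eff)
    B_ = _coords_for(ord_res, sids_b, n_axes_eff)
    pool = np.vstack([A, B_])
    na, m = len(sids_a), len(sids_a) + len(sids_b)
    # vectorized label permutations: rows of random keys → argsort = shuffle
    perm = np.argsort(rng.random((n_permutations, m)), axis=1)
    pooled = pool[perm]                        # (B, m, k)
    null_a = pooled[:, :na, :].mean(axis=1)
    null_b = pooled[:, na:, :].mean(axis=1)
    null = np.linalg.norm(null_a - null_b, axis=1)
    p = (1.0 + np.sum(null >= observed - 1e-12)) / (1.0 + n_permutations)

    # bootstrap over mice within groups
    mouse_of = meta.mouse_of()
    by_mouse_a: dict[str, list[int]] = {}
    for i, s in enumerate(sids_a):
        by_mouse_a.setdefault(mouse_of[s], []).append(i)
    by_mouse_b: dict[str, list[int]] = {}
    for i, s in enumerate(sids_b):
        by_mouse_b.setdefault(mouse_of[s], []).append(i)
    mice_a, mice_b = list(by_mouse_a), list(by_mouse_b)
    boots = np.empty(n_bootstrap)
    for t in range(n_bootstrap):
        ia = np.concatenate([by_mouse_a[m_] for m_ in
                             rng.choice(mice_a, size=len(mice_a), replace=True)])
        ib = np.concatenate([by_mouse_b[m_] for m_ in
                             rng.choice(mice_b, size=len(mice_b), replace=True)])
        boots[t] = np.linalg.norm(A[ia].mean(axis=0) - B_[ib].mean(axis=0))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return OffsetResult(group_a=group_a, group_b=group_b, gm_offset=observed,
                        n_axes_used=n_axes_eff, permutation_p=float(p),
                        n_permutations=n_permutations,
                        bootstrap_ci=(float(lo), float(hi)), seed=seed)


def anosim(D: DissimilarityMatrix, meta: SampleMetadata,
           n_permutations: int = 999, seed: int = 0) -> AnosimResult:
    """Clarke's analysis of similarities on ranked dissimilarities.

    R = (mean between-group rank − mean within-group rank) / (n(n−1)/4),
    bounded in [−1, 1]; R = 1 iff every between-group dissimilarity exceeds
    every within-group one. p by label permutation (add-one estimator).
    """
    sids = meta.sample_ids
    if set(sids) != set(D.sample_ids):
        raise ValidationError("metadata and dissimilarity matrix sample sets differ")
    groups = meta.groups
    if len(groups) < 2:
        raise ValidationError("ANOSIM needs ≥ 2 groups")
    sizes = {g: len(meta.samples_in(g)) for g in groups}
    small = [g for g, n in sizes.items() if n < 2]
    if small:
        raise ValidationError(f"ANOSIM groups of size 1: {small}")

    pos = {s: i for i, s in enumerate(D.sample_ids)}
    idx = np.array([pos[s] for s in sids])
    Dm = D.values[np.ix_(idx, idx)]
    n = len(sids)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(Dm[iu])  # average ranks for ties
    labels = meta.df["group"].to_numpy()
    denom = n * (n - 1) / 4.0

    def _r(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return float((ranks[~within].mean() - ranks[within].mean()) / denom)

    observed = _r(labels)
    rng = np.random.default_rng(seed)
    count = 0
    lab = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(lab)
        if _r(lab) >= observed - 1e-12:
            count += 1
    p = (1.0 + count) / (1.0 + n_permutations)
    return AnosimResult(R=observed, permutation_p=float(p),
                        n_permutations=n_permutations, seed=seed)
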