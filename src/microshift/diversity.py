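"""Alpha diversity, relative-abundance normalization and the F/B ratio.

Shannon entropy uses natural log (nats) by default; "Simpson" is the
Gini–Simpson form 1 − Σp² throughout (the index the usual richness-
estimation toolchains report under that name — documented here because the
bare name is ambiguous between 1 − Σp², Σp² and 1/Σp²).

Indices are computed on proportions of raw counts without rarefaction by
default; an optional rarefaction depth is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables_io import GenusCountTable, SampleMetadata

SIMPLEX_TOL = 1e-9


@dataclass
class RelativeAbundanceTable:
    """Samples × genera fractions; every row sums to 1."""

    sample_ids: list[str]
    genus_ids: list[str]
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 2:
            raise ValidationError("fractions must be 2-D")
        if np.any(self.fractions < 0) or np.any(self.fractions > 1):
            raise ValidationError("fractions must lie in [0, 1]")
        sums = self.fractions.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-6)[0]
        if bad.size:
            raise ValidationError(
                f"rows do not sum to 1: {[self.sample_ids[i] for i in bad[:5]]}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.fractions,
                            index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.genus_ids)

    def subset(self, sample_ids: list[str]) -> "RelativeAbundanceTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return RelativeAbundanceTable(list(sample_ids), list(self.genus_ids),
                                      self.fractions[idx])


def to_relative(counts: GenusCountTable) -> RelativeAbundanceTable:
    """Row-normalize counts to fractions. Zero-sum samples are an error."""
    totals = counts.counts.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if zero.size:
        raise ValidationError(
            f"zero-count samples cannot be normalized: "
            f"{[counts.sample_ids[i] for i in zero]}")
    fr = counts.counts / totals[:, None]
    return RelativeAbundanceTable(list(counts.sample_ids), list(counts.genus_ids), fr)


def rarefy(counts: GenusCountTable, depth: int, seed: int) -> GenusCountTable:
    """Subsample every sample to ``depth`` reads without replacement."""
    totals = counts.counts.sum(axis=1)
    if np.any(totals < depth):
        low = [counts.sample_ids[i] for i in np.where(totals < depth)[0]]
        raise ValidationError(f"samples below rarefaction depth {depth}: {low}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts.counts)
    for i, row in enumerate(counts.counts):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return GenusCountTable(list(counts.sample_ids), list(counts.genus_ids),
                           out, dict(counts.taxonomy))


def _check_simplex(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or np.any(p < 0) or abs(p.sum() - 1.0) > SIMPLEX_TOL * p.size + 1e-9:
        raise ValidationError("input is not a probability vector")
    return p


def shannon(p: np.ndarray, base: float | None = None) -> float:
    """Shannon entropy −Σ p·ln p over p > 0, in nats (or the given base)."""
    p = _check_simplex(p)
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def simpson(p: np.ndarray) -> float:
    """Gini–Simpson index 1 − Σ p²."""
    p = _check_simplex(p)
    return float(1.0 - (p ** 2).sum())


def alpha_diversity(rel: RelativeAbundanceTable, base: float | None = None) -> pd.DataFrame:
    """Per-sample Shannon and Simpson indices."""
    rows = [{"sample_id": sid,
             "shannon": shannon(rel.fractions[i], base=base),
             "simpson": simpson(rel.fractions[i])}
            for i, sid in enumerate(rel.sample_ids)]
    return pd.DataFrame(rows, columns=["sample_id", "shannon", "simpson"])


def fb_ratio(rel: RelativeAbundanceTable, taxonomy: dict[str, str],
             level: str = "per_sample", metadata: SampleMetadata | None = None,
             firmicutes: str = "Firmicutes", bacteroidota: str = "Bacteroidota",
             ) -> pd.DataFrame:
    """Firmicutes/Bacteroidota ratio per sample or per group.

    ``per_group`` aggregates group-mean fractions before taking the ratio.
    A zero Bacteroidota total yields NaN with ``undefined=True`` rather than
    an exception.
    """
    f_idx = [j for j, g in enumerate(rel.genus_ids) if taxonomy.get(g) == firmicutes]
    b_idx = [j for j, g in enumerate(rel.genus_ids) if taxonomy.get(g) == bacteroidota]
    if not f_idx or not b_idx:
        raise ValidationError(
            f"taxonomy must map at least one genus to each of "
            f"{firmicutes!r} and {bacteroidota!r}")
    f_tot = rel.fractions[:, f_idx].sum(axis=1)
    b_tot = rel.fractions[:, b_idx].sum(axis=1)

    def _ratio(f: float, b: float) -> tuple[float, bool]:
        return (np.nan, True) if b == 0 else (f / b, False)

    if level == "per_sample":
        rows = []
        for sid, f, b in zip(rel.sample_ids, f_tot, b_tot):
            r, und = _ratio(f, b)
            rows.append({"sample_id": sid, "firmicutes": f, "bacteroidota": b,
                         "fb_ratio": r, "undefined": und})
        return pd.DataFrame(rows)
    if level == "per_group":
        if metadata is None:
            raise ValidationError("per_group F/B ratio requires metadata")
        pos = {s: i for i, s in enumerate(rel.sample_ids)}
        rows = []
        for grp in metadata.groups:
            idx = [pos[s] for s in metadata.samples_in(grp)]
            f, b = float(f_tot[idx].mean()), float(b_tot[idx].mean())
            r, und = _ratio(f, b)
            rows.append({"group": grp, "firmicutes": f, "bacteroidota": b,
                         "fb_ratio": r, "undefined": und})
        return pd.DataFrame(rows)
    raise ValidationError(f"unknown level {level!r}; use per_sample or per_group")
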