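"""Dirichlet-multinomial simulator for the 4-group × 5-mouse × 2-week design.

The generator emulates a genus-level gut community of a mouse diet-
intervention study: a chow control (CD+SPSS), an untreated high-fat-diet
group (HFD+SPSS), and two treated HFD groups (HFD+PA, HFD+Rutin), each with
five mice sampled at a reference week (model construction, week 4) and an
endpoint week (end of intervention, week 10).

Community model: each (group, week) cell has an expected composition
``softmax(base + effect)`` on a latent log scale; a sample's composition is
drawn from ``Dirichlet(θ · expectation)`` (θ = overdispersion concentration)
and counts multinomially at a log-normal library size. Effects are additive
on the log scale, so shifting a "key taxa" subset automatically renormalizes
the rest — the compositional trade-off (e.g. a Firmicutes/Bacteroidota
seesaw) seen in real HFD data.

Phenotypes: per-mouse body weight and fasting glucose follow
``baseline + slope·(week − w0) + κ·shift·(week − w0)/(w_end − w0) + noise``
where ``shift`` is the mouse's realized composition displacement between the
two sampled weeks, so κ > 0 couples community change to phenotype change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .tables_io import GenusCountTable, PhenotypeTable, SampleMetadata

import pandas as pd

DEFAULT_GROUPS = ("CD+SPSS", "HFD+SPSS", "HFD+PA", "HFD+Rutin")

# phylum composition of the default 66-genus community; Firmicutes and
# Bacteroidota dominate, as in mouse gut amplicon surveys
DEFAULT_PHYLUM_COUNTS = {
    "Firmicutes": 30,
    "Bacteroidota": 15,
    "Proteobacteria": 6,
    "Actinobacteriota": 4,
    "Desulfobacterota": 3,
    "Verrucomicrobiota": 2,
    "Deferribacterota": 2,
    "Campilobacterota": 2,
    "Patescibacteria": 2,
}

# group-mean body weight (g) at the reference week and weekly slopes chosen
# so the expected 6-week group deltas equal the study-scale values
# (ΔBW: CD +3.35, HFD +5.52, PA −3.116, Rutin −0.594 g)
DEFAULT_BW_BASELINE = {"CD+SPSS": 22.65, "HFD+SPSS": 29.68,
                       "HFD+PA": 26.12, "HFD+Rutin": 25.39}
DEFAULT_BW_BASELINE_SD = {"CD+SPSS": 0.95, "HFD+SPSS": 2.40,
                          "HFD+PA": 2.26, "HFD+Rutin": 1.98}
DEFAULT_BW_SLOPES = {"CD+SPSS": 3.35 / 6, "HFD+SPSS": 5.52 / 6,
                     "HFD+PA": -3.116 / 6, "HFD+Rutin": -0.594 / 6}

# fasting glucose (mmol/L): HFD-type groups above the 9.5 mmol/L diabetic-
# model threshold at the reference week; slopes give deltas
# CD +0.66, HFD −0.2, PA −4.54, Rutin −4.56 over 6 weeks
DEFAULT_FBG_BASELINE = {"CD+SPSS": 7.0, "HFD+SPSS": 11.0,
                        "HFD+PA": 11.0, "HFD+Rutin": 11.0}
DEFAULT_FBG_BASELINE_SD = {g: 0.8 for g in DEFAULT_GROUPS}
DEFAULT_FBG_SLOPES = {"CD+SPSS": 0.66 / 6, "HFD+SPSS": -0.2 / 6,
                      "HFD+PA": -4.54 / 6, "HFD+Rutin": -4.56 / 6}

FBG_FLOOR = 0.1  # mmol/L; keeps simulated glucose physical


def default_phylum_assignment(n_genera: int = 66,
                              phylum_counts: dict[str, int] | None = None
                              ) -> tuple[list[str], dict[str, str]]:
    """Deterministic genus names and genus→phylum map.

    Phyla are interleaved across abundance ranks (not blocked), so both
    dominant phyla span common and rare genera.
    """
    counts = dict(phylum_counts or DEFAULT_PHYLUM_COUNTS)
    total = sum(counts.values())
    if total != n_genera:
        # rescale proportionally, give remainder to the largest phylum
        scaled = {p: max(1, round(c * n_genera / total)) for p, c in counts.items()}
        drift = n_genera - sum(scaled.values())
        largest = max(scaled, key=scaled.get)
        scaled[largest] += drift
        counts = scaled
    keys, positions = [], []
    for p, c in counts.items():
        keys.extend([p] * c)
        positions.extend(((np.arange(c) + 0.5) / c).tolist())
    order = np.argsort(np.asarray(positions), kind="stable")
    phyla_by_rank = [keys[i] for i in order]
    genus_ids = [f"Genus{i + 1:02d}" for i in range(n_genera)]
    return genus_ids, dict(zip(genus_ids, phyla_by_rank))


def default_base_log_abundance(n_genera: int = 66, span: float = 4.0) -> np.ndarray:
    """Geometric-decay rank-abundance curve on the log scale."""
    return -np.linspace(0.0, span, n_genera)


def default_key_taxa(phylum_assignment: dict[str, str],
                     n_up: int = 5, n_down: int = 5,
                     max_rank: int = 26) -> tuple[list[str], list[str]]:
    """Key taxa for the default HFD effect: mid-to-high-rank genera.

    Returns (Firmicutes genera raised under HFD, Bacteroidota genera
    depressed under HFD) — the seesaw the F/B ratio tracks.
    """
    genera = list(phylum_assignment)
    up = [g for g in genera[1:max_rank] if phylum_assignment[g] == "Firmicutes"][:n_up]
    down = [g for g in genera[1:max_rank] if phylum_assignment[g] == "Bacteroidota"][:n_down]
    return up, down


@dataclass
class SimDesign:
    """Full parameterization of a synthetic study (defaults mirror the
    4 × 5 × 2 design; see module docstring)."""

    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_mice_per_group: int = 5
    weeks: tuple[int, ...] = (4, 10)
    n_genera: int = 66
    n_phyla: int = 9
    genus_ids: list[str] = field(default_factory=list)
    phylum_assignment: dict[str, str] = field(default_factory=dict)
    base_log_abundance: np.ndarray | None = None
    theta: float = 50.0  # Dirichlet concentration (overdispersion knob)
    effect_table: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    library_size_log_mean: float = 10.8  # ln scale; e^10.8 ≈ 49k reads
    library_size_log_sd: float = 0.3
    bw_baseline_mean: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BW_BASELINE))
    bw_baseline_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BW_BASELINE_SD))
    bw_group_slopes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BW_SLOPES))
    bw_noise_sd: float = 0.5
    fbg_baseline_mean: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FBG_BASELINE))
    fbg_baseline_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FBG_BASELINE_SD))
    fbg_group_slopes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FBG_SLOPES))
    fbg_noise_sd: float = 0.3
    coupling: float = 0.0  # κ: community shift → phenotype delta
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ParameterError("theta must be strictly positive")
        for name in ("library_size_log_sd", "bw_noise_sd", "fbg_noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.library_size_log_mean <= 0:
            raise ParameterError("library_size_log_mean must be positive")
        if self.n_mice_per_group < 1:
            raise ParameterError("need at least one mouse per group")
        if len(self.weeks) < 1:
            raise ParameterError("need at least one sampling week")
        if not self.genus_ids or not self.phylum_assignment:
            self.genus_ids, self.phylum_assignment = default_phylum_assignment(self.n_genera)
        if len(self.genus_ids) != self.n_genera:
            raise ParameterError("genus_ids length must equal n_genera")
        if self.base_log_abundance is None:
            self.base_log_abundance = default_base_log_abundance(self.n_genera)
        self.base_log_abundance = np.asarray(self.base_log_abundance, dtype=float)
        if self.base_log_abundance.shape != (self.n_genera,):
            raise ParameterError("base_log_abundance must have length n_genera")
        for sd in list(self.bw_baseline_sd.values()) + list(self.fbg_baseline_sd.values()):
            if sd < 0:
                raise ParameterError("baseline sd must be non-negative")
        if not self.effect_table:
            self.effect_table = default_effect_table(
                self.groups, self.weeks, self.genus_ids, self.phylum_assignment)
        cells = {(g, w) for g in self.groups for w in self.weeks}
        for key, vec in self.effect_table.items():
            if key not in cells:
                raise ParameterError(
                    f"effect_table key {key} references an undeclared group/week")
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.n_genera,):
                raise ParameterError(f"effect vector for {key} has wrong length")
            self.effect_table[key] = vec

    def effect(self, group: str, week: int) -> np.ndarray:
        return self.effect_table.get((group, week), np.zeros(self.n_genera))

    def cell_composition(self, group: str, week: int) -> np.ndarray:
        """Expected relative abundance (softmax of base + effect)."""
        z = self.base_log_abundance + self.effect(group, week)
        z = z - z.max()
        e = np.exp(z)
        return e / e.sum()


def default_effect_table(groups, weeks, genus_ids, phylum_assignment,
                         delta_hfd: float = 1.0,
                         pa_retention: float = 0.6, pa_signature: float = 0.5,
                         rutin_retention: float = 0.2, rutin_signature: float = 1.0,
                         ) -> dict[tuple[str, int], np.ndarray]:
    """HFD raises 5 Firmicutes key taxa and depresses 5 Bacteroidota key taxa
    (log-fold δ = 1). Treatments partially revert that at the endpoint week
    and add their own small signatures; rutin reverts more than PA, so the
    rutin endpoint sits further from the untreated HFD community.
    """
    n = len(genus_ids)
    idx = {g: i for i, g in enumerate(genus_ids)}
    up, down = default_key_taxa(phylum_assignment)
    e_hfd = np.zeros(n)
    for g in up:
        e_hfd[idx[g]] = delta_hfd
    for g in down:
        e_hfd[idx[g]] = -delta_hfd
    # distinct signature taxa for each treatment (mid-rank, non-key)
    key = set(up) | set(down)
    spare = [g for g in genus_ids[5:40] if g not in key]
    s_pa, s_rutin = np.zeros(n), np.zeros(n)
    for g in spare[:3]:
        s_pa[idx[g]] = 1.0
    for g in spare[3:6]:
        s_rutin[idx[g]] = 1.0
    w_ref, w_end = weeks[0], weeks[-1]
    table: dict[tuple[str, int], np.ndarray] = {}
    for grp in groups:
        if not grp.startswith("HFD"):
            continue
        table[(grp, w_ref)] = e_hfd.copy()
        if "PA" in grp:
            table[(grp, w_end)] = pa_retention * e_hfd + pa_signature * s_pa
        elif "Rutin" in grp:
            table[(grp, w_end)] = rutin_retention * e_hfd + rutin_signature * s_rutin
        else:
            table[(grp, w_end)] = e_hfd.copy()
    return table


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests.

    ``true_centroid_displacement`` is the Euclidean distance between
    centered latent log-composition (effect) vectors of two design cells —
    zero exactly when the cells share an effect vector.
    ``mouse_shift`` is each mouse's realized Bray–Curtis displacement
    between its first- and last-week compositions (0 with a single week).
    """

    expected_relative_abundance: dict[tuple[str, int], np.ndarray]
    true_centroid_displacement: dict[tuple[tuple[str, int], tuple[str, int]], float]
    genera_truly_shifted: set[str]
    mouse_shift: dict[str, float] = field(default_factory=dict)


def _centered(v: np.ndarray) -> np.ndarray:
    return v - v.mean()


def simulate_counts(design: SimDesign
                    ) -> tuple[GenusCountTable, SampleMetadata, GroundTruth]:
    """Draw one sample per (mouse, week) from the Dirichlet-multinomial model.

    Identical design (including seed) ⇒ byte-identical outputs.
    """
    rng = np.random.default_rng([design.seed, 0])
    n = design.n_genera
    sample_ids, meta_rows, count_rows = [], [], []
    per_mouse_fracs: dict[str, dict[int, np.ndarray]] = {}
    for grp in design.groups:
        for m in range(design.n_mice_per_group):
            mouse_id = f"{grp}_m{m + 1}"
            per_mouse_fracs[mouse_id] = {}
            for w in design.weeks:
                sid = f"{mouse_id}_w{w}"
                p = design.cell_composition(grp, w)
                comp = rng.dirichlet(design.theta * p)
                lib = int(np.round(rng.lognormal(design.library_size_log_mean,
                                                 design.library_size_log_sd)))
                lib = max(lib, 1)
                counts = rng.multinomial(lib, comp)
                sample_ids.append(sid)
                meta_rows.append({"sample_id": sid, "mouse_id": mouse_id,
                                  "group": grp, "week": w})
                count_rows.append(counts)
                per_mouse_fracs[mouse_id][w] = counts / counts.sum()
    table = GenusCountTable(sample_ids=sample_ids, genus_ids=list(design.genus_ids),
                            counts=np.vstack(count_rows),
                            taxonomy=dict(design.phylum_assignment))
    meta = SampleMetadata(pd.DataFrame(meta_rows))

    cells = [(g, w) for g in design.groups for w in design.weeks]
    expected = {c: design.cell_composition(*c) for c in cells}
    displacement = {}
    for i, a in enumerate(cells):
        for b in cells[i + 1:]:
            da = _centered(design.effect(*a))
            db = _centered(design.effect(*b))
            displacement[(a, b)] = float(np.linalg.norm(da - db))
    shifted = {design.genus_ids[j] for vec in design.effect_table.values()
               for j in np.nonzero(np.asarray(vec))[0]}
    w_ref, w_end = design.weeks[0], design.weeks[-1]
    mouse_shift = {}
    for mouse_id, by_week in per_mouse_fracs.items():
        if w_ref == w_end or w_end not in by_week:
            mouse_shift[mouse_id] = 0.0
        else:
            # Bray–Curtis between the two weekly compositions (both simplex,
            # so Σ|a−b|/Σ(a+b) reduces to half the L1 distance)
            mouse_shift[mouse_id] = float(
                0.5 * np.abs(by_week[w_end] - by_week[w_ref]).sum())
    truth = GroundTruth(expected_relative_abundance=expected,
                        true_centroid_displacement=displacement,
                        genera_truly_shifted=shifted,
                        mouse_shift=mouse_shift)
    return table, meta, truth


def simulate_phenotypes(design: SimDesign, ground_truth: GroundTruth | None = None
                        ) -> PhenotypeTable:
    """Weekly body-weight and fasting-glucose series for every mouse.

    The weekly grid spans the design's first to last sampling week. With
    coupling κ > 0 a mouse whose community moved more (per
    ``ground_truth.mouse_shift``) gains a proportionally larger phenotype
    delta by the endpoint week.
    """
    rng = np.random.default_rng([design.seed, 1])
    w0, w_end = design.weeks[0], design.weeks[-1]
    week_grid = list(range(w0, w_end + 1))
    span = max(w_end - w0, 1)
    shifts = ground_truth.mouse_shift if ground_truth is not None else {}
    rows = []
    for grp in design.groups:
        bw0 = design.bw_baseline_mean.get(grp, 25.0)
        bw0_sd = design.bw_baseline_sd.get(grp, 1.0)
        bws = design.bw_group_slopes.get(grp, 0.0)
        fb0 = design.fbg_baseline_mean.get(grp, 8.0)
        fb0_sd = design.fbg_baseline_sd.get(grp, 0.5)
        fbs = design.fbg_group_slopes.get(grp, 0.0)
        for m in range(design.n_mice_per_group):
            mouse_id = f"{grp}_m{m + 1}"
            base_bw = rng.normal(bw0, bw0_sd)
            base_fb = rng.normal(fb0, fb0_sd)
            shift = shifts.get(mouse_id, 0.0)
            for w in week_grid:
                frac = (w - w0) / span
                coupled = design.coupling * shift * frac
                bw = (base_bw + bws * (w - w0) + coupled
                      + rng.normal(0.0, design.bw_noise_sd))
                fb = (base_fb + fbs * (w - w0) + coupled
                      + rng.normal(0.0, design.fbg_noise_sd))
                rows.append({"mouse_id": mouse_id, "week": w,
                             "bw": max(bw, 1.0), "fbg": max(fb, FBG_FLOOR)})
    return PhenotypeTable(pd.DataFrame(rows))


def effect_grid(design: SimDesign, deltas: list[float]) -> list[SimDesign]:
    """Copies of ``design`` with the key-taxa effect magnitude rescaled to
    each value in ``deltas`` (non-negative, sorted ascending)."""
    deltas = list(deltas)
    if any(d < 0 for d in deltas):
        raise ParameterError("deltas must be non-negative")
    if deltas != sorted(deltas):
        raise ParameterError("deltas must be sorted ascending")
    max_abs = max((float(np.max(np.abs(v))) for v in design.effect_table.values()),
                  default=0.0)
    out = []
    for d in deltas:
        if d == 0:
            table = {k: np.zeros_like(v) for k, v in design.effect_table.items()}
        elif max_abs == 0:
            raise ParameterError(
                "cannot scale a zero effect table to a nonzero magnitude")
        else:
            table = {k: v * (d / max_abs) for k, v in design.effect_table.items()}
        out.append(replace(design, effect_table=table))
    return out
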