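"""End-to-end orchestration: simulate/load → diversity → ordination →
offsets → phenotype → differential/network, with one report.

A single top-level seed deterministically derives per-stage seeds by
hashing the stage name, so any stage re-run in isolation reproduces its
part of a full run. Everything written to ``report.json`` is a pure
function of (inputs, config, seed); only ``run.log`` carries timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import tables_io
from .beta_ordination import bray_curtis, pca_relabund, pcoa
from .differential_network import (core_specific, correlation_network,
                                   differential_genera, edges_to_frame,
                                   key_microbes)
from .diversity import alpha_diversity, fb_ratio, to_relative
from .errors import ConfigError
from .offset_inference import anosim, gm_offset, gm_offset_test
from .phenotype_metrics import (delta_contrast, group_delta,
                                offset_phenotype_correlation)
from .synthetic_data import SimDesign, simulate_counts, simulate_phenotypes
from .tables_io import SampleMetadata


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


_KNOWN_KEYS = {
    "seed", "out_dir", "design", "inputs", "groups", "week_ref", "week_end",
    "n_axes", "n_permutations", "alpha", "adjust", "correction", "ordination",
    "presence_threshold", "min_prevalence", "test",
}
_DESIGN_KEYS = {f.name for f in dataclasses.fields(SimDesign)}


@dataclass
class RunConfig:
    seed: int
    out_dir: str = "microshift_out"
    design: SimDesign | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    groups: list[str] | None = None
    week_ref: int = 4
    week_end: int = 10
    n_axes: int = 2
    n_permutations: int = 999
    alpha: float = 0.05
    adjust: str = "none"
    correction: str = "none"
    ordination: str = "pcoa"
    presence_threshold: float = 0.0
    min_prevalence: float = 0.0
    test: str = "welch"

    def __post_init__(self) -> None:
        if self.design is None and not self.inputs:
            self.design = SimDesign(seed=derive_seed(self.seed, "simulate"))
        if self.ordination not in ("pcoa", "pca"):
            raise ConfigError("ordination must be 'pcoa' or 'pca'")


def validate_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config; unknown keys and a missing seed are errors."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    if "seed" not in raw:
        raise ConfigError("seed is mandatory (permutation/bootstrap/"
                          "simulation stages are stochastic)")
    design = None
    if "design" in raw and raw["design"] is not None:
        dk = raw["design"]
        if not isinstance(dk, dict):
            raise ConfigError("design must be a mapping of SimDesign fields")
        bad = sorted(set(dk) - _DESIGN_KEYS)
        if bad:
            raise ConfigError(f"unknown design keys: {bad}")
        if "groups" in dk:
            dk = {**dk, "groups": tuple(dk["groups"])}
        if "weeks" in dk:
            dk = {**dk, "weeks": tuple(dk["weeks"])}
        dk.setdefault("seed", derive_seed(int(raw["seed"]), "simulate"))
        design = SimDesign(**dk)
    kwargs = {k: v for k, v in raw.items() if k != "design"}
    return RunConfig(design=design, **kwargs)


def _cell_meta(meta: SampleMetadata, cells: list[tuple[str, int, str]]
               ) -> SampleMetadata:
    """Metadata restricted to (group, week) cells, relabeled per cell.

    Lets the same centroid machinery express pre/post contrasts (the two
    cells are the same mice at different weeks)."""
    frames = []
    for group, week, label in cells:
        sub = meta.df[(meta.df["group"] == group) & (meta.df["week"] == week)].copy()
        sub["group"] = label
        frames.append(sub)
    return SampleMetadata(pd.concat(frames, ignore_index=True))


def run_all(config: RunConfig) -> dict:
    """Execute every stage; write artifacts, run.log and report.json.

    Returns the report dict. Any stage error aborts with the stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    log_lines: list[str] = []
    report: dict = {"seed": config.seed}
    bundle: dict[str, object] = {}

    def _log(stage: str, **info) -> None:
        line = json.dumps({"stage": stage, "time": time.time(), **info})
        log_lines.append(line)

    def _stage(name: str):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                self_inner.cm = warnings.catch_warnings(record=True)
                self_inner.caught = self_inner.cm.__enter__()
                warnings.simplefilter("always")
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                self_inner.cm.__exit__(None, None, None)
                msgs = [str(w.message) for w in self_inner.caught]
                if exc is not None:
                    _log(name, status="error", error=str(exc))
                    log_path.write_text("\n".join(log_lines) + "\n")
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                _log(name, status="ok",
                     elapsed_s=round(time.perf_counter() - self_inner.t0, 3),
                     warnings=msgs)
                return False
        return _Ctx()

    # ---- inputs ----------------------------------------------------------
    with _stage("inputs"):
        if config.design is not None:
            counts, meta, truth = simulate_counts(config.design)
            pheno = simulate_phenotypes(config.design, truth)
        else:
            paths = config.inputs
            counts = tables_io.read_count_table(paths["counts"], paths.get("taxonomy"))
            meta = tables_io.read_metadata(paths["metadata"])
            pheno = tables_io.read_phenotype(paths["phenotype"])
            truth = None
        meta.validate_against(counts)
        groups = config.groups or meta.groups
        absent = sorted(set(groups) - set(meta.groups))
        if absent:
            raise ConfigError(f"configured groups absent from metadata: {absent}")
        w_ref, w_end = config.week_ref, config.week_end
        if w_ref not in meta.weeks or w_end not in meta.weeks:
            raise ConfigError(
                f"weeks {w_ref}/{w_end} not both present in metadata "
                f"(available: {meta.weeks})")
        bundle["counts"] = counts.to_dataframe().reset_index()
        bundle["metadata"] = meta.df

    # ---- diversity -------------------------------------------------------
    with _stage("diversity"):
        rel = to_relative(counts)
        adiv = alpha_diversity(rel)
        adiv_g = (adiv.merge(meta.df, on="sample_id")
                  .groupby(["group", "week"])[["shannon", "simpson"]]
                  .mean().reset_index())
        fb = fb_ratio(rel, counts.taxonomy, level="per_group", metadata=meta)
        bundle["diversity"] = adiv
        report["alpha_diversity_group_means"] = {
            f"{r.group}@w{r.week}": {"shannon": round(r.shannon, 6),
                                     "simpson": round(r.simpson, 6)}
            for r in adiv_g.itertuples()}
        report["fb_ratio_per_group"] = {
            r.group: (None if r.undefined else round(r.fb_ratio, 6))
            for r in fb.itertuples()}
        bundle["fb_ratio"] = fb

    # ---- ordination ------------------------------------------------------
    with _stage("ordination"):
        D = bray_curtis(rel)
        if config.ordination == "pcoa":
            ordn = pcoa(D, correction=config.correction)
        else:
            ordn = pca_relabund(rel)
        k = min(config.n_axes, ordn.coordinates.shape[1])
        ord_df = pd.DataFrame(
            ordn.coordinates[:, :k],
            columns=[f"PCo{i + 1}" for i in range(k)])
        ord_df.insert(0, "sample_id", ordn.sample_ids)
        bundle["ordination"] = ord_df
        bundle["distance"] = pd.DataFrame(
            D.values, columns=D.sample_ids).assign(sample_id=D.sample_ids)
        report["ordination"] = {
            "method": ordn.method,
            "n_negative_eigenvalues": ordn.n_negative_eigenvalues,
            "negative_eigenvalue_mass": round(ordn.negative_eigenvalue_mass, 6),
            "proportion_explained_first_axes":
                [round(float(p), 6) for p in ordn.proportion_explained[:k]],
        }

    # ---- offsets + anosim ------------------------------------------------
    with _stage("offsets"):
        seed_off = derive_seed(config.seed, "offsets")
        end_cells = [(g, w_end, g) for g in groups]
        meta_end = _cell_meta(meta, end_cells)
        D_end, ord_end = _subset_ordination(rel, meta_end, config)
        pairwise: dict[str, dict[str, float]] = {g: {} for g in groups}
        offset_tests = {}
        for i, ga in enumerate(groups):
            for gb in groups:
                if ga == gb:
                    pairwise[ga][gb] = 0.0
            for gb in groups[i + 1:]:
                res = gm_offset_test(D_end, meta_end, ga, gb,
                                     n_axes=config.n_axes,
                                     n_permutations=config.n_permutations,
                                     seed=seed_off, ord_res=ord_end)
                pairwise[ga][gb] = pairwise[gb][ga] = round(res.gm_offset, 6)
                offset_tests[f"{ga} vs {gb}"] = _offset_dict(res)
        prepost = {}
        for g in groups:
            m2 = _cell_meta(meta, [(g, w_ref, f"{g}@w{w_ref}"),
                                   (g, w_end, f"{g}@w{w_end}")])
            D2, ord2 = _subset_ordination(rel, m2, config)
            res = gm_offset_test(D2, m2, f"{g}@w{w_ref}", f"{g}@w{w_end}",
                                 n_axes=config.n_axes,
                                 n_permutations=config.n_permutations,
                                 seed=seed_off, ord_res=ord2)
            prepost[g] = _offset_dict(res)
        report["gm_offset_pairwise_week_end"] = pairwise
        report["gm_offset_tests_week_end"] = offset_tests
        report["gm_offset_prepost"] = prepost
        ano = anosim(D_end, meta_end,
                     n_permutations=config.n_permutations,
                     seed=derive_seed(config.seed, "anosim"))
        report["anosim_week_end"] = {"R": round(ano.R, 6),
                                     "p": round(ano.permutation_p, 6),
                                     "n_permutations": ano.n_permutations}
        bundle["offsets"] = {"pairwise_week_end": pairwise, "prepost": prepost}

    # ---- phenotype -------------------------------------------------------
    with _stage("phenotype"):
        deltas = {g: group_delta(pheno, meta, g, w_ref, w_end) for g in groups}
        report["deltas"] = {
            g: {"delta_bw": round(d.delta_bw, 6),
                "delta_fbg": round(d.delta_fbg, 6),
                "bw_mean_ref": round(d.bw_mean_ref, 6),
                "bw_mean_end": round(d.bw_mean_end, 6),
                "fbg_mean_ref": round(d.fbg_mean_ref, 6),
                "fbg_mean_end": round(d.fbg_mean_end, 6),
                "n_mice": d.n_mice}
            for g, d in deltas.items()}
        if "HFD+SPSS" in deltas and "CD+SPSS" in deltas:
            c = delta_contrast(deltas["HFD+SPSS"], deltas["CD+SPSS"], "bw")
            report["bw_contrast_hfd_vs_cd"] = {
                "absolute_excess_g": round(c.absolute_excess, 6),
                "percent_excess": (None if c.undefined
                                   else round(c.percent_excess, 6))}
        # per-mouse coupling: ordination displacement vs ΔFBG within group
        coupling = {}
        mouse_of = meta.mouse_of()
        coord_of = dict(zip(ordn.sample_ids, ordn.coordinates[:, :k]))
        for g in groups:
            pts = []
            for m in meta.mice_in(g):
                s_ref = [s for s in meta.samples_in(g, w_ref) if mouse_of[s] == m]
                s_end = [s for s in meta.samples_in(g, w_end) if mouse_of[s] == m]
                if not s_ref or not s_end:
                    continue
                disp = float(np.linalg.norm(coord_of[s_end[0]] - coord_of[s_ref[0]]))
                dfbg = pheno.at(m, w_end, "fbg") - pheno.at(m, w_ref, "fbg")
                pts.append((disp, dfbg))
            if len(pts) >= 3:
                cres = offset_phenotype_correlation(pts)
                coupling[g] = {"r": None if cres.undefined else round(cres.r, 6),
                               "p": None if cres.undefined else round(cres.p, 6),
                               "n": cres.n}
        report["offset_fbg_coupling_per_group"] = coupling
        bundle["phenotype"] = pheno.df
        bundle["deltas"] = pd.DataFrame(
            [dataclasses.asdict(d) for d in deltas.values()])

    # ---- differential + network -----------------------------------------
    with _stage("differential"):
        contrasts = {}
        for g in groups:
            if g in ("CD+SPSS",) or not meta.samples_in(g, w_ref):
                continue
            contrasts[g] = differential_genera(
                rel, meta, (g, w_end), (g, w_ref), alpha=config.alpha,
                min_prevalence=config.min_prevalence, test=config.test)
        report["differential_significant_counts"] = {
            g: sum(r.significant for r in recs) for g, recs in contrasts.items()}
        treated = [g for g in contrasts if g not in ("HFD+SPSS",)]
        if len(treated) >= 2:
            km = key_microbes(contrasts[treated[0]], contrasts[treated[1]])
            report["key_microbes"] = sorted(km)
        part = core_specific(rel, _cell_meta(meta, end_cells),
                             presence_threshold=config.presence_threshold)
        report["core_genera_count"] = len(part.core)
        report["specific_genera_counts"] = {g: len(s)
                                            for g, s in part.specific.items()}
        bundle["core_partition"] = {
            "core": sorted(part.core),
            "specific": {g: sorted(s) for g, s in part.specific.items()}}
        feats = []
        for m in sorted({*pheno.df["mouse_id"]}):
            try:
                feats.append({"mouse_id": m, "bw": pheno.at(m, w_end, "bw"),
                              "fbg": pheno.at(m, w_end, "fbg")})
            except Exception:
                continue
        rel_end = rel.subset(meta_end.sample_ids)
        edges = correlation_network(rel_end, pd.DataFrame(feats), meta_end,
                                    alpha=config.alpha, adjust=config.adjust)
        report["network_edge_count"] = len(edges)
        report["network_genus_feature_edges"] = sum(
            1 for e in edges if {e.type_a, e.type_b} == {"genus", "body_feature"})
        bundle["edges"] = edges_to_frame(edges)

    # ---- write -----------------------------------------------------------
    with _stage("write"):
        bundle["report"] = report
        manifest = tables_io.write_outputs(bundle, out)
        report["manifest_files"] = sorted(manifest)
    log_path.write_text("\n".join(log_lines) + "\n")
    return report


def _offset_dict(res) -> dict:
    return {"gm_offset": round(res.gm_offset, 6),
            "p": round(res.permutation_p, 6),
            "ci": [round(res.bootstrap_ci[0], 6), round(res.bootstrap_ci[1], 6)],
            "n_permutations": res.n_permutations,
            "n_axes": res.n_axes_used}


def _subset_ordination(rel, meta_sub: SampleMetadata, config: RunConfig):
    """Distance matrix + ordination recomputed on a sample subset."""
    sub = rel.subset(meta_sub.sample_ids)
    D = bray_curtis(sub)
    if config.ordination == "pcoa":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ordn = pcoa(D, correction=config.correction)
    else:
        ordn = pca_relabund(sub)
    return D, ordn
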