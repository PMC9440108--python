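"""End-to-end orchestration: configuration, stages, manifests.

A pipeline run is a sequence of stages over one output directory::

    simulate -> ordinate -> calibrate -> reconstruct -> assess -> attribute

Each stage reads CSVs (either user-supplied paths or earlier stages'
outputs), writes its result tables into the output directory, and drops a
JSON manifest recording the stage seed, the configuration hash and the
SHA-256 checksums of its inputs, so deterministic stages rerun
bit-identically under an identical configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assessment, attribution, calibration, community, ordination, synthetic
from .attribution import SEASONS

__all__ = ["PipelineConfig", "run_stage", "run_all", "STAGES"]

log = logging.getLogger("paleoseason")

STAGES = ("simulate", "ordinate", "calibrate", "reconstruct", "assess",
          "attribute")

TARGETS = tuple(SEASONS) + ("MAT",)


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    outdir: str = "out"
    seed: int = 0
    # input paths; when absent the simulate stage must provide them
    modern_taxa: str | None = None
    modern_env: str | None = None
    fossil_taxa: str | None = None
    # stage knobs
    simulate: dict = field(default_factory=dict)      # SimConfig overrides
    ordinate: dict = field(default_factory=lambda: {
        "metric": "bray_curtis", "n_perm": 199, "vif_threshold": 20.0,
        "alpha": 0.05, "nmds_starts": 8})
    calibrate: dict = field(default_factory=lambda: {
        "methods": ["WAPLS", "LW-WA", "LW-WAPLS"], "n_components": 2,
        "n_boot": 100, "metric": "squared_chord", "deshrinking": "inverse"})
    reconstruct: dict = field(default_factory=lambda: {
        "method": "LW-WAPLS", "with_errors": True, "n_boot": 100})
    assess: dict = field(default_factory=lambda: {
        "n_random": 199, "metric": "squared_chord"})
    attribute: dict = field(default_factory=lambda: {
        "dt": 100.0, "window": 1000.0, "step": 100.0,
        "lowess_span": 0.3, "bin_width": 10.0})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown configuration key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(val, dict):
                getattr(cfg, key).update(val)
            else:
                setattr(cfg, key, val)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        # deterministic per-stage child seeds below 2**31
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, cfg: PipelineConfig,
                    inputs: list[Path], outputs: list[Path], seconds: float) -> None:
    manifest = {
        "stage": stage,
        "seed": cfg.stage_seed(stage),
        "config_hash": cfg.config_hash(),
        "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
        "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
        "elapsed_s": round(seconds, 3),
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _resolve(cfg: PipelineConfig, key: str, outdir: Path, default_name: str) -> Path:
    configured = getattr(cfg, key)
    path = Path(configured) if configured else outdir / default_name
    if not path.exists():
        raise FileNotFoundError(
            f"stage input {path} not found; set '{key}' in the configuration "
            "or run the simulate stage first")
    return path


def _load_modern(cfg: PipelineConfig, outdir: Path) -> tuple:
    taxa_p = _resolve(cfg, "modern_taxa", outdir, "modern_taxa.csv")
    env_p = _resolve(cfg, "modern_env", outdir, "modern_env.csv")
    taxa = community.read_taxon_csv(taxa_p)
    env = community.read_env_csv(env_p)
    env.check_aligned(taxa)
    return taxa, env, [taxa_p, env_p]


def _load_fossil(cfg: PipelineConfig, outdir: Path) -> tuple:
    p = _resolve(cfg, "fossil_taxa", outdir, "fossil_taxa.csv")
    return community.read_taxon_csv(p), [p]


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    seed = cfg.stage_seed("simulate")
    sim = synthetic.SimConfig(**{k: v for k, v in cfg.simulate.items()
                                 if k not in ("history", "count_depth_fossil")})
    responses = synthetic.make_species_responses(sim, seed=seed)
    taxa, env = synthetic.simulate_training_set(sim, responses, seed=seed)
    history = synthetic.simulate_temperature_history(seed=seed)
    fossil, truth = synthetic.simulate_fossil_sequence(
        history, responses, resolution=sim.fossil_resolution,
        count_depth=sim.count_depth, seed=seed)
    community.write_taxon_csv(taxa, outdir / "modern_taxa.csv")
    community.write_env_csv(env, outdir / "modern_env.csv")
    community.write_taxon_csv(fossil, outdir / "fossil_taxa.csv")
    truth_df = pd.DataFrame({"age_calBP": fossil.ages,
                             **{k: truth[k] for k in TARGETS}})
    truth_df.to_csv(outdir / "fossil_truth.csv", index=False)
    with open(outdir / "simulation_params.json", "w") as fh:
        json.dump({"seed": seed, "sim": asdict(sim),
                   "history": asdict(history.params)}, fh, indent=2, default=list)
    return [outdir / n for n in ("modern_taxa.csv", "modern_env.csv",
                                 "fossil_taxa.csv", "fossil_truth.csv",
                                 "simulation_params.json")]


def _stage_ordinate(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    knobs = cfg.ordinate
    seed = cfg.stage_seed("ordinate")
    taxa, env, _ = _load_modern(cfg, outdir)
    pct = community.to_percentages(taxa)
    sq = community.sqrt_transform(pct)

    gl = ordination.dca_gradient_length(sq)
    d = community.pairwise_dissimilarity(pct, knobs.get("metric", "bray_curtis"))
    pco = ordination.pcoa(d, n_axes=2)
    kept = ordination.vif_filter(env, list(env.variables),
                                 threshold=knobs.get("vif_threshold", 20.0))
    cca_res = ordination.cca(sq, env, kept)
    single = [ordination.permutation_test(sq, env, v,
                                          n_perm=knobs.get("n_perm", 199),
                                          seed=seed)
              for v in kept]
    fwd = ordination.forward_select(sq, env, kept,
                                    alpha=knobs.get("alpha", 0.05),
                                    n_perm=knobs.get("n_perm", 199), seed=seed)
    summary = pd.DataFrame({
        "variable": [t.variable for t in single],
        "constrained_inertia": [t.statistic for t in single],
        "p_value": [t.p_value for t in single],
        "forward_selected": [v in [f[0] for f in fwd] for v in kept],
    })
    summary.to_csv(outdir / "ordination_tests.csv", index=False)
    pd.DataFrame(pco.site_scores, index=list(taxa.site_ids),
                 columns=["PCoA1", "PCoA2"]).to_csv(outdir / "pcoa_scores.csv")
    pd.DataFrame(cca_res.site_scores[:, :2], index=list(taxa.site_ids),
                 columns=["CCA1", "CCA2"]).to_csv(outdir / "cca_scores.csv")

    # fossil-modern overlap: NMDS of the modern cloud, fossil samples
    # projected passively so they never shape the modern configuration
    nmds_res = ordination.nmds(d, k=2, n_starts=knobs.get("nmds_starts", 8),
                               seed=seed)
    scores = pd.DataFrame(nmds_res.site_scores, index=list(taxa.site_ids),
                          columns=["NMDS1", "NMDS2"])
    scores["group"] = "modern"
    fossil_path = Path(cfg.fossil_taxa) if cfg.fossil_taxa else outdir / "fossil_taxa.csv"
    if fossil_path.exists():
        fossil = community.read_taxon_csv(fossil_path)
        aligned, _ = fossil.align_taxa(pct.taxon_ids)
        tots = aligned.values.sum(axis=1)
        keep = tots > 0
        fo = aligned.select_sites(np.where(keep)[0])
        fo_pct = community.to_percentages(fo)
        cross = community.cross_dissimilarity(
            fo_pct, pct, metric=knobs.get("metric", "bray_curtis"))
        proj = ordination.nmds_project(nmds_res, cross)
        fdf = pd.DataFrame(proj, index=list(fo.site_ids),
                           columns=["NMDS1", "NMDS2"])
        fdf["group"] = "fossil"
        scores = pd.concat([scores, fdf])
    scores.to_csv(outdir / "nmds_scores.csv")
    report = {
        "dca_gradient_length_sd": gl,
        "unimodal_methods_appropriate": gl > 2.0,
        "nmds_stress": nmds_res.stress,
        "vif_selected_variables": kept,
        "cca_explained_fraction": cca_res.explained_fraction,
        "forward_selection": [{"variable": v, "added_inertia": g, "p": p}
                              for v, g, p in fwd],
    }
    with open(outdir / "ordination_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return [outdir / n for n in ("ordination_tests.csv", "pcoa_scores.csv",
                                 "cca_scores.csv", "nmds_scores.csv",
                                 "ordination_report.json")]


def _method_spec(name: str, knobs: dict) -> calibration.MethodSpec:
    return calibration.MethodSpec(
        method=name,
        n_components=int(knobs.get("n_components", 2)),
        deshrinking=knobs.get("deshrinking", "inverse"),
        k=int(knobs.get("k", 10)),
        m_local=knobs.get("m_local"),
        metric=knobs.get("metric", "squared_chord"),
        sqrt_abundance=bool(knobs.get("sqrt_abundance", False)))


def _stage_calibrate(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    knobs = cfg.calibrate
    seed = cfg.stage_seed("calibrate")
    taxa, env, _ = _load_modern(cfg, outdir)
    pct = community.to_percentages(taxa)
    rows = []
    for method in knobs.get("methods", ["WAPLS", "LW-WA", "LW-WAPLS"]):
        spec = _method_spec(method, knobs)
        for target in TARGETS:
            if target not in env.variables:
                continue
            stats, _ = calibration.bootstrap_validate(
                spec, pct, env[target], n_boot=int(knobs.get("n_boot", 100)),
                seed=seed, target=target)
            rows.append(stats.as_dict())
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "model_comparison.csv", index=False)
    return [outdir / "model_comparison.csv"]


def _stage_reconstruct(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    knobs = cfg.reconstruct
    seed = cfg.stage_seed("reconstruct")
    taxa, env, _ = _load_modern(cfg, outdir)
    fossil, _ = _load_fossil(cfg, outdir)
    pct = community.to_percentages(taxa)
    spec = _method_spec(knobs.get("method", "LW-WAPLS"), knobs)
    env_values = {t: env[t] for t in TARGETS if t in env.variables}
    series = calibration.reconstruct(
        spec, pct, env_values, fossil,
        with_errors=bool(knobs.get("with_errors", True)),
        n_boot=int(knobs.get("n_boot", 100)), seed=seed)
    df = series.to_frame()
    # MAT both ways: direct transfer-function reconstruction plus the
    # arithmetic mean of the four reconstructed seasons
    if all(s in df.columns for s in SEASONS):
        df["MAT_from_seasons"] = df[list(SEASONS)].mean(axis=1)
    df.to_csv(outdir / "reconstruction.csv", index=False)
    card = {"method": spec.method, "n_components": spec.n_components,
            "deshrinking": spec.deshrinking, "metric": spec.metric,
            "m_local": spec.m_local, "seed": seed,
            "targets": list(env_values)}
    with open(outdir / "reconstruction_card.json", "w") as fh:
        json.dump(card, fh, indent=2)
    return [outdir / "reconstruction.csv", outdir / "reconstruction_card.json"]


def _stage_assess(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    knobs = cfg.assess
    seed = cfg.stage_seed("assess")
    taxa, env, _ = _load_modern(cfg, outdir)
    fossil, _ = _load_fossil(cfg, outdir)
    cls = assessment.classify_analogues(fossil, taxa,
                                        metric=knobs.get("metric", "squared_chord"))
    cls.to_frame().to_csv(outdir / "analogue_classes.csv", index=False)
    spec = _method_spec(cfg.reconstruct.get("method", "LW-WAPLS"),
                        cfg.reconstruct)
    pct = community.to_percentages(taxa)
    rows = []
    for i, target in enumerate(t for t in TARGETS if t in env.variables):
        res = assessment.significance_test(
            pct, env[target], fossil, spec,
            n_random=int(knobs.get("n_random", 199)), seed=seed + i,
            target=target)
        rows.append(res.as_dict())
    pd.DataFrame(rows).to_csv(outdir / "significance_tests.csv", index=False)
    summary = {"fraction_good_or_fair": cls.fraction_good_or_fair(),
               "counts": cls.counts(), "q5": cls.q5, "q10": cls.q10}
    with open(outdir / "assessment_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return [outdir / n for n in ("analogue_classes.csv",
                                 "significance_tests.csv",
                                 "assessment_summary.json")]


def _stage_attribute(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    knobs = cfg.attribute
    rec_p = outdir / "reconstruction.csv"
    if not rec_p.exists():
        raise FileNotFoundError(f"stage input {rec_p} not found; run the "
                                "reconstruct stage first")
    df = pd.read_csv(rec_p)
    series = attribution.SeasonalSeries(
        df["age_calBP"].to_numpy(float),
        {s: df[s].to_numpy(float) for s in SEASONS})
    grid = attribution.interpolate_uniform(series, dt=knobs.get("dt", 100.0))
    grid = attribution.with_mat(grid)
    grid.to_frame().to_csv(outdir / "gridded_series.csv", index=False)
    records = attribution.sliding_contributions(
        grid, step=knobs.get("step", 100.0), window=knobs.get("window", 1000.0))
    contrib = attribution.contributions_frame(records)
    span = knobs.get("lowess_span", 0.3)
    for s in SEASONS:
        mask = contrib[s].notna()
        if mask.sum() >= 4:
            contrib.loc[mask, f"{s}_lowess"] = attribution.lowess_smooth(
                contrib.loc[mask, "age_calBP"].to_numpy(),
                contrib.loc[mask, s].to_numpy(), span=span)
    contrib.to_csv(outdir / "contributions.csv", index=False)
    hist = attribution.contribution_histogram(records,
                                              bin_width=knobs.get("bin_width", 10.0))
    hist.to_csv(outdir / "contribution_histogram.csv", index=False)
    return [outdir / n for n in ("gridded_series.csv", "contributions.csv",
                                 "contribution_histogram.csv")]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "ordinate": _stage_ordinate,
    "calibrate": _stage_calibrate,
    "reconstruct": _stage_reconstruct,
    "assess": _stage_assess,
    "attribute": _stage_attribute,
}


def run_stage(stage: str, cfg: PipelineConfig) -> list[Path]:
    """Run one stage; outputs land in ``cfg.outdir`` with a manifest."""
    if stage not in _STAGE_FN:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = []
    for key, name in (("modern_taxa", "modern_taxa.csv"),
                      ("modern_env", "modern_env.csv"),
                      ("fossil_taxa", "fossil_taxa.csv")):
        configured = getattr(cfg, key)
        p = Path(configured) if configured else outdir / name
        if p.exists():
            inputs.append(p)
    t0 = time.monotonic()
    log.info("stage %s starting", stage)
    outputs = _STAGE_FN[stage](cfg, outdir)
    dt = time.monotonic() - t0
    log.info("stage %s finished in %.2fs", stage, dt)
    _write_manifest(outdir, stage, cfg, inputs, outputs, dt)
    return outputs


def run_all(cfg: PipelineConfig, skip_simulate: bool | None = None) -> dict[str, list[Path]]:
    """Run the full chain; simulation is skipped when input paths are given."""
    if skip_simulate is None:
        skip_simulate = cfg.modern_taxa is not None
    out: dict[str, list[Path]] = {}
    for stage in STAGES:
        if stage == "simulate" and skip_simulate:
            continue
        out[stage] = run_stage(stage, cfg)
    return out
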