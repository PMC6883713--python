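"""End-to-end orchestration of the analysis stages.

Each stage reads the plain-text bundle written by :mod:`splicegc.simulate`
(or equivalently formatted real annotations), writes its results as TSV
into the output directory, and is idempotent for fixed inputs and seed.
A run manifest records the package version, seed, configuration hash, and
the files each stage produced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as sio
from .classify import (ClassThresholds, LABEL_AT, LABEL_GC, U1_FACTOR_GROUP,
                       U2_FACTOR_GROUP, assemble_class_exons,
                       build_activated_sets, build_control_set, classify_factor)
from .composition import base_set_fraction, junction_profile
from .coverage import CoverageTrack
from .domains import (assign_domains, compute_domain_gc, domain_exon_counts,
                      class_proportion_in_kind, domain_summary_frame,
                      exon_domain_gc_correlation)
from .intervals import extract_sequence
from .metaplot import (MetaplotSpec, binned_profile, clip_positional_proportion,
                       gc_at_ratio, mean_coverage)
from .records import smallest_flanking_intron
from .signals import FeatureWindows, exon_signal_features
from .simulate import SimulationConfig, simulate, write_bundle
from .vvalue import v_value_table

log = logging.getLogger("splicegc")


@dataclass
class PipelineConfig:
    """Paths, thresholds, and window geometry for a full run.

    Every analysis constant is a named key with its standard default, so
    a YAML config can audit or override any of them.
    """

    bundle_dir: str = "bundle"
    out_dir: str = "results"
    seed: int = 1
    simulate: bool = True
    gc_threshold: float = 49.3
    intron_threshold: float = 691.0
    base_set: str = "GC"
    n_iter: int = 10_000
    bp_min_count: int = 2
    metaplot_bins: int = 1000
    metaplot_drop_first: int = 199
    exon_center_flank: int = 100
    windows: FeatureWindows = field(default_factory=FeatureWindows)
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        windows = FeatureWindows(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("windows", {}).items()
        })
        sim = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("sim", {}).items()
        })
        return cls(windows=windows, sim=sim, **raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _load_inputs(cfg: PipelineConfig, need=("genome", "exons")):
    bundle = Path(cfg.bundle_dir)
    paths = {k: bundle / name for k, name in
             [("genome", "genome.fa"), ("genes", "genes.tsv"),
              ("exons", "exons.tsv"), ("regulation", "regulation.tsv"),
              ("spliceosome_regulation", "spliceosome_regulation.tsv"),
              ("peaks", "peaks.bed"), ("coverage", "coverage.bedgraph"),
              ("domains", "domains.tsv"), ("truth", "truth.tsv")]}
    for key in need:
        if not paths[key].exists():
            raise PipelineError("load", f"missing input {paths[key]}")
    return paths


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s started", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                log.info("stage %s finished in %.2fs", stage, dt)
            else:
                log.error("stage %s failed after %.2fs: %s", stage, dt, exc)
            return False

    return _Timer()


def _out(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _header(cfg: PipelineConfig) -> str:
    return f"# splicegc {__version__} seed={cfg.seed} config={cfg.digest()}\n"


def _write_tsv(cfg: PipelineConfig, df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=False)


def stage_simulate(cfg: PipelineConfig) -> dict:
    with _timed("simulate"):
        sim_cfg = cfg.sim if cfg.sim.seed == cfg.seed else \
            type(cfg.sim)(**{**asdict(cfg.sim), "seed": cfg.seed})
        bundle = simulate(sim_cfg)
        paths = write_bundle(bundle, cfg.bundle_dir)
    return {"files": [str(p) for p in paths.values()], "n_genes": len(bundle.genes)}


def stage_classify(cfg: PipelineConfig) -> dict:
    with _timed("classify"):
        paths = _load_inputs(cfg, need=("genome", "genes", "exons", "regulation"))
        genome = sio.read_fasta(paths["genome"], as_dict=True)
        genes = sio.read_genes(paths["genes"], paths["exons"])
        exons = {e.exon_id: e for g in genes for e in g.exons}
        records = sio.read_regulation(paths["regulation"])
        sets = build_activated_sets(records)
        thresholds = ClassThresholds(gc_threshold=cfg.gc_threshold,
                                     intron_threshold=cfg.intron_threshold,
                                     base_set=cfg.base_set)
        rows = []
        classes = {}
        for factor, fs in sorted(sets.items()):
            fs.compute_medians(exons, genome, base_set=thresholds.base_set)
            classes[factor] = classify_factor(fs, thresholds)
            rows.append({"factor": factor, "n_exons": len(fs.exon_ids),
                         "median_gc": fs.median_gc,
                         "median_min_intron": fs.median_min_intron,
                         "class": classes[factor]})
        labels = assemble_class_exons(classes, sets, universe=exons.keys())
        control = build_control_set(exons.values(), sets)
        out = _out(cfg)
        _write_tsv(cfg, pd.DataFrame(rows), out / "factor_classes.tsv")
        label_df = pd.DataFrame(sorted(labels.items()), columns=["exon_id", "label"])
        _write_tsv(cfg, label_df, out / "exon_labels.tsv")
        control_df = pd.DataFrame({"exon_id": sorted(e.exon_id for e in control)})
        _write_tsv(cfg, control_df, out / "control_exons.tsv")
    return {"n_factors": len(classes),
            "n_gc": sum(v == LABEL_GC for v in labels.values()),
            "n_at": sum(v == LABEL_AT for v in labels.values())}


def _read_labels(cfg: PipelineConfig) -> dict[str, str]:
    path = Path(cfg.out_dir) / "exon_labels.tsv"
    if not path.exists():
        raise PipelineError("features", f"run classify first: missing {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["exon_id"].astype(str), df["label"]))


def stage_features(cfg: PipelineConfig) -> dict:
    with _timed("features"):
        paths = _load_inputs(cfg, need=("genome", "genes", "exons"))
        genome = sio.read_fasta(paths["genome"], as_dict=True)
        genes = sio.read_genes(paths["genes"], paths["exons"])
        labels = _read_labels(cfg)
        exons = [e for g in genes for e in g.exons]
        table = exon_signal_features(exons, genome, windows=cfg.windows,
                                     labels=labels, bp_min_count=cfg.bp_min_count)
        out = _out(cfg)
        _write_tsv(cfg, table, out / "signal_features.tsv")
        # junction composition profiles for the two classes
        profiles = []
        for label in (LABEL_GC, LABEL_AT):
            subset = [e for e in exons if labels.get(e.exon_id) == label]
            if not subset:
                continue
            for anchor in ("5ss", "3ss"):
                prof = junction_profile(subset, genome, anchor, base_set="GC")
                df = prof.to_frame()
                df.insert(0, "anchor", anchor)
                df.insert(0, "class", label)
                profiles.append(df)
        if profiles:
            _write_tsv(cfg, pd.concat(profiles), out / "junction_profiles.tsv")
    return {"n_exons": len(table)}


def stage_vvalue(cfg: PipelineConfig) -> dict:
    with _timed("vvalue"):
        paths = _load_inputs(cfg, need=("spliceosome_regulation",))
        labels = _read_labels(cfg)
        gc_exons = {e for e, lab in labels.items() if lab == LABEL_GC}
        at_exons = {e for e, lab in labels.items() if lab == LABEL_AT}
        records = sio.read_regulation(paths["spliceosome_regulation"])
        sets = build_activated_sets(records)
        factor_sets = {f: set(fs.exon_ids) for f, fs in sets.items()}
        table = v_value_table(factor_sets, gc_exons, at_exons,
                              n_iter=cfg.n_iter, seed=cfg.seed)
        _write_tsv(cfg, table, _out(cfg) / "v_values.tsv")
    return {"n_factors": len(table)}


def stage_metaplot(cfg: PipelineConfig) -> dict:
    with _timed("metaplot"):
        paths = _load_inputs(cfg, need=("genome", "genes", "exons",
                                        "coverage", "peaks"))
        genes = sio.read_genes(paths["genes"], paths["exons"])
        genome = sio.read_fasta(paths["genome"], as_dict=True)
        sizes = {c: len(s) for c, s in genome.items()}
        coverage = CoverageTrack.from_bedgraph(paths["coverage"], chrom_sizes=sizes)
        peaks = sio.read_peaks_bed(paths["peaks"])
        labels = _read_labels(cfg)
        exons = {e.exon_id: e for g in genes for e in g.exons}
        by_class = {
            lab: [exons[e] for e, l in labels.items() if l == lab and e in exons]
            for lab in (LABEL_GC, LABEL_AT)
        }
        out = _out(cfg)
        frames = []
        for kind in ("whole_gene", "internal_exons", "introns"):
            spec = MetaplotSpec(region_kind=kind, n_bins=cfg.metaplot_bins,
                                drop_first=cfg.metaplot_drop_first)
            prof = binned_profile(genes, coverage, spec)
            df = prof.to_frame()
            df.insert(0, "region", kind)
            frames.append(df)
        _write_tsv(cfg, pd.concat(frames), out / "metaplots.tsv")
        stats_rows = []
        group_means = {}
        for lab, group in by_class.items():
            if not group:
                continue
            _, grp_mean = mean_coverage(group, coverage, flank=cfg.exon_center_flank)
            group_means[lab] = grp_mean
            stats_rows.append({"class": lab, "n": len(group),
                               "mean_coverage": grp_mean})
        stats = pd.DataFrame(stats_rows)
        if LABEL_GC in group_means and LABEL_AT in group_means:
            ratio = gc_at_ratio(group_means[LABEL_GC], group_means[LABEL_AT])
            stats["gc_at_ratio"] = ratio
        _write_tsv(cfg, stats, out / "coverage_stats.tsv")
        clip_frames = []
        for lab, group in by_class.items():
            if not group:
                continue
            prop = clip_positional_proportion(group, peaks, cfg.windows, anchor="3ss")
            prop.insert(0, "class", lab)
            clip_frames.append(prop)
        if clip_frames:
            _write_tsv(cfg, pd.concat(clip_frames), out / "clip_proportions.tsv")
    return {"regions": 3}


def stage_domains(cfg: PipelineConfig) -> dict:
    with _timed("domains"):
        paths = _load_inputs(cfg, need=("genome", "genes", "exons", "domains"))
        genome = sio.read_fasta(paths["genome"], as_dict=True)
        genes = sio.read_genes(paths["genes"], paths["exons"])
        domains = sio.read_domains(paths["domains"])
        compute_domain_gc(domains, genome)
        labels = _read_labels(cfg)
        exons = {e.exon_id: e for g in genes for e in g.exons}
        out = _out(cfg)
        summaries = []
        prop_rows = []
        corr_rows = []
        for kind in ("isochore", "TAD", "LAD"):
            doms = [d for d in domains if d.kind == kind]
            if not doms:
                continue
            assignments = assign_domains(exons.values(), doms)
            summaries += domain_exon_counts(labels, assignments, doms)
            props = class_proportion_in_kind(labels, assignments)
            for lab, pct in props.items():
                prop_rows.append({"kind": kind, "class": lab, "pct_inside": pct})
            dom_gc = {d.domain_id: d.gc_percent for d in doms}
            xs, ys = [], []
            for eid, did in assignments.items():
                if did in dom_gc and labels.get(eid) in (LABEL_GC, LABEL_AT):
                    xs.append(base_set_fraction(
                        extract_sequence(exons[eid].interval, genome), "GC"))
                    ys.append(dom_gc[did])
            if len(xs) >= 3 and np.std(xs) > 0 and np.std(ys) > 0:
                corr_rows.append({"kind": kind, "n": len(xs),
                                  "pearson_r": exon_domain_gc_correlation(xs, ys)})
        _write_tsv(cfg, domain_summary_frame(summaries), out / "domain_summaries.tsv")
        _write_tsv(cfg, pd.DataFrame(prop_rows), out / "domain_proportions.tsv")
        _write_tsv(cfg, pd.DataFrame(corr_rows), out / "domain_correlations.tsv")
    return {"n_domains": len(summaries)}


STAGES = {
    "simulate": stage_simulate,
    "classify": stage_classify,
    "features": stage_features,
    "vvalue": stage_vvalue,
    "metaplot": stage_metaplot,
    "domains": stage_domains,
}


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage in order and write a manifest; any stage failure
    aborts with a stage-tagged error and marks the manifest incomplete."""
    manifest = {"version": __version__, "seed": cfg.seed,
                "config_hash": cfg.digest(), "stages": {}, "complete": False}
    order = (["simulate"] if cfg.simulate else []) + \
        ["classify", "features", "vvalue", "metaplot", "domains"]
    out = _out(cfg)
    try:
        for name in order:
            try:
                manifest["stages"][name] = STAGES[name](cfg)
            except PipelineError:
                raise
            except Exception as exc:  # tag the failing stage
                raise PipelineError(name, str(exc)) from exc
        manifest["complete"] = True
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
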