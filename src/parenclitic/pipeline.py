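"""Linear end-to-end pipeline driven by a single YAML config.

Stages: simulate (or load) -> qc -> select-panel -> fit-baseline ->
build-networks -> features -> train -> evaluate -> candidates. Each stage
writes its artifacts plus a manifest (input/output digests, settings,
seed); rerunning with an identical config reproduces byte-identical
artifacts because every writer is deterministic and all randomness flows
from the single master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from . import io_qc
from .classify import candidate_loci, evaluate, split_cohorts, train
from .exceptions import ConfigError, PipelineError
from .gmm import GMMSettings
from .baseline import fit_baseline
from .networks import build_networks, write_network
from .panel import top_variant_loci, write_panel
from .synthetic import SyntheticConfig, generate_annotation, generate_dataset
from .topology import feature_matrix
from .utils import sha256_file

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "QCConfig", "ClassifierConfig", "validate_config", "run_all"]


@dataclass
class QCConfig:
    enabled: bool = True
    alpha: float = 0.05
    max_fail_fraction_per_probe: float = 0.0
    max_failed_sample_fraction: float = 0.10
    masks: tuple = ("snp", "non_cpg", "sex_chromosomes")


@dataclass
class ClassifierConfig:
    C: float = 1.0
    standardize: bool = False


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 0
    beta: str | None = None
    detection: str | None = None
    phenotype: str | None = None
    annotation: str | None = None
    simulate: SyntheticConfig | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    panel_k: int = 1000
    variance_cohort: str = "discovery"
    n_modeling: int | None = None
    gmm: GMMSettings = field(default_factory=GMMSettings)
    feature: str = "degree"
    top_fraction: float = 0.05
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    write_networks: bool = True
    network_format: str = "edgelist"


def _build(dc_type, data: dict, section: str):
    known = {f.name for f in fields(dc_type)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown key {sorted(unknown)[0]!r} in section {section!r}")
    return dc_type(**data)


def validate_config(source) -> RunConfig:
    """Parse and validate a YAML config (path, text, or dict)."""
    if isinstance(source, dict):
        data = dict(source)
    else:
        text = str(source)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("config must be a mapping")
    for section, dc in (("simulate", SyntheticConfig), ("qc", QCConfig),
                        ("gmm", GMMSettings), ("classifier", ClassifierConfig)):
        if isinstance(data.get(section), dict):
            data[section] = _build(dc, data[section], section)
    if isinstance(data.get("qc"), QCConfig) and isinstance(data["qc"].masks, list):
        data["qc"].masks = tuple(data["qc"].masks)
    cfg = _build(RunConfig, data, "top level")

    if cfg.simulate is None:
        for name in ("beta", "phenotype"):
            if getattr(cfg, name) is None:
                raise ConfigError(
                    f"config requires either a simulate block or a {name!r} path")
            if not Path(getattr(cfg, name)).exists():
                raise ConfigError(f"{name} path does not exist: {getattr(cfg, name)}")
    else:
        cfg.simulate.validate()
        if cfg.panel_k > cfg.simulate.n_loci:
            raise ConfigError(
                f"panel_k ({cfg.panel_k}) exceeds simulated n_loci "
                f"({cfg.simulate.n_loci})")
    if cfg.feature not in ("degree", "degree_centrality", "eigenvector",
                           "betweenness", "second_order", "eccentricity"):
        raise ConfigError(f"unknown feature {cfg.feature!r}")
    return cfg


def _normalised(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if d.get("qc"):
        d["qc"]["masks"] = list(d["qc"]["masks"])
    return d


class _Manifests:
    def __init__(self, outdir: Path):
        self.dir = outdir / "manifests"
        self.dir.mkdir(parents=True, exist_ok=True)
        self.completed: list[str] = []

    def record(self, stage: str, inputs: dict, outputs: dict, settings: dict, seed: int):
        doc = {
            "stage": stage,
            "inputs": {str(k): sha256_file(v) for k, v in inputs.items()},
            "outputs": {str(k): sha256_file(v) for k, v in outputs.items()},
            "settings": settings,
            "seed": seed,
        }
        (self.dir / f"{stage}.json").write_text(
            json.dumps(doc, sort_keys=True, indent=1) + "\n")
        self.completed.append(stage)


@contextmanager
def _stage(name: str, manifests: _Manifests):
    log.info("stage %s: start", name)
    t0 = time.perf_counter()
    try:
        yield
    except Exception as exc:
        raise PipelineError(
            f"stage {name!r} failed after completed stages "
            f"{manifests.completed}: {exc}") from exc
    log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)


def run_all(config: RunConfig | dict | str) -> Path:
    """Execute the whole pipeline; returns the run directory."""
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(_normalised(cfg), sort_keys=True))
    manifests = _Manifests(outdir)
    seed = cfg.seed

    with _stage("simulate" if cfg.simulate else "load", manifests):
        if cfg.simulate is not None:
            sim = dataclasses.replace(cfg.simulate, seed=seed)
            beta, det, phen, truth = generate_dataset(sim)
            annotation = generate_annotation(
                beta.probe_ids, seed=seed, exclude_from_masks=truth.planted_loci)
            beta.write(outdir / "beta.tsv")
            det.write(outdir / "detection.tsv")
            io_qc.write_phenotype_table(phen, outdir / "phenotypes.tsv")
            io_qc.write_annotation(annotation, outdir / "annotation.tsv")
            (outdir / "truth.json").write_text(truth.to_json() + "\n")
            outputs = {p.name: p for p in (
                outdir / "beta.tsv", outdir / "detection.tsv",
                outdir / "phenotypes.tsv", outdir / "annotation.tsv",
                outdir / "truth.json")}
            manifests.record("simulate", {}, outputs,
                             dataclasses.asdict(sim), seed)
        else:
            beta = io_qc.BetaMatrix.read(cfg.beta)
            det = io_qc.DetectionMatrix.read(cfg.detection) if cfg.detection else None
            phen = io_qc.read_phenotype_table(cfg.phenotype)
            annotation = io_qc.read_annotation(cfg.annotation) if cfg.annotation else None
            inputs = {k: v for k, v in (("beta", cfg.beta), ("detection", cfg.detection),
                                        ("phenotype", cfg.phenotype),
                                        ("annotation", cfg.annotation)) if v}
            manifests.record("load", inputs, {}, {}, seed)

    with _stage("qc", manifests):
        if cfg.qc.enabled:
            if det is not None:
                beta_probes = io_qc.filter_probes_by_detection(
                    beta, det, alpha=cfg.qc.alpha,
                    max_fail_fraction_per_probe=cfg.qc.max_fail_fraction_per_probe)
                det_probes = det.select_probes(beta_probes.probe_ids)
                beta = io_qc.filter_failed_samples(
                    beta_probes, det_probes, alpha=cfg.qc.alpha,
                    max_failed_fraction=cfg.qc.max_failed_sample_fraction)
            if annotation is not None and cfg.qc.masks:
                beta = io_qc.mask_probes(beta, annotation, masks=cfg.qc.masks)
            phen = phen.loc[[s for s in phen.index if s in set(beta.sample_ids)]]
        beta.write(outdir / "beta_qc.tsv")
        manifests.record("qc", {}, {"beta_qc.tsv": outdir / "beta_qc.tsv"},
                         dataclasses.asdict(cfg.qc), seed)

    with _stage("split", manifests):
        if "cohort" not in phen.columns or (phen["cohort"] == "").any():
            if cfg.n_modeling is None:
                raise ConfigError(
                    "phenotypes lack cohort roles; set n_modeling in the config")
            phen = split_cohorts(phen, cfg.n_modeling, seed=seed)
        io_qc.write_phenotype_table(phen, outdir / "cohorts.tsv")
        manifests.record("split", {}, {"cohorts.tsv": outdir / "cohorts.tsv"}, {}, seed)

    modeling = phen.index[phen["cohort"] == "modeling"].tolist()
    training = phen.index[phen["cohort"] == "training"].tolist()
    evaluation = phen.index[phen["cohort"] == "evaluation"].tolist()

    with _stage("select-panel", manifests):
        if cfg.variance_cohort == "all":
            var_samples = phen.index.tolist()
        elif cfg.variance_cohort == "modeling":
            var_samples = modeling
        else:
            var_samples = modeling + training
        panel = top_variant_loci(beta, min(cfg.panel_k, beta.shape[0]),
                                 samples=var_samples)
        write_panel(panel, outdir / "panel.txt")
        manifests.record("select-panel", {"beta_qc.tsv": outdir / "beta_qc.tsv"},
                         {"panel.txt": outdir / "panel.txt"},
                         {"k": len(panel), "variance_cohort": cfg.variance_cohort}, seed)

    with _stage("fit-baseline", manifests):
        baseline = fit_baseline(beta.select_samples(modeling), panel,
                                settings=cfg.gmm, master_seed=seed)
        baseline.save(outdir / "baseline.bin")
        manifests.record("fit-baseline", {"panel.txt": outdir / "panel.txt"},
                         {"baseline.bin": outdir / "baseline.bin"},
                         dataclasses.asdict(cfg.gmm), seed)

    with _stage("build-networks", manifests):
        nets = build_networks(beta, baseline, sample_ids=training + evaluation)
        outputs = {}
        if cfg.write_networks:
            netdir = outdir / "networks"
            netdir.mkdir(exist_ok=True)
            for net in nets:
                ext = "graphml" if cfg.network_format == "graphml" else "tsv"
                path = netdir / f"{net.sample_id}.{ext}"
                write_network(net, path, format=cfg.network_format)
                outputs[f"networks/{path.name}"] = path
        manifests.record("build-networks", {"baseline.bin": outdir / "baseline.bin"},
                         outputs, {"format": cfg.network_format}, seed)

    with _stage("features", manifests):
        fm = feature_matrix(nets, cfg.feature)
        fm.write(outdir / "features.tsv")
        manifests.record("features", {}, {"features.tsv": outdir / "features.tsv"},
                         {"feature": cfg.feature}, seed)

    with _stage("train", manifests):
        clf = train(type(fm)(name=fm.name, frame=fm.frame.loc[training],
                             params=fm.params),
                    phen.loc[training, "label"], C=cfg.classifier.C,
                    standardize=cfg.classifier.standardize, seed=seed)
        (outdir / "classifier.json").write_text(clf.to_json() + "\n")
        manifests.record("train", {"features.tsv": outdir / "features.tsv"},
                         {"classifier.json": outdir / "classifier.json"},
                         dataclasses.asdict(cfg.classifier), seed)

    with _stage("evaluate", manifests):
        if evaluation:
            report = evaluate(clf, fm.frame.loc[evaluation],
                              phen.loc[evaluation, "label"])
            (outdir / "evaluation.json").write_text(report.to_json() + "\n")
            (outdir / "evaluation.txt").write_text(str(report))
            report.roc_points.to_csv(outdir / "roc.tsv", sep="\t", index=False,
                                     float_format="%.10g")
            manifests.record("evaluate",
                             {"classifier.json": outdir / "classifier.json"},
                             {"evaluation.json": outdir / "evaluation.json",
                              "roc.tsv": outdir / "roc.tsv"}, {}, seed)

    with _stage("candidates", manifests):
        table = candidate_loci(clf, annotation, top_fraction=cfg.top_fraction)
        table.to_csv(outdir / "candidates.tsv", sep="\t", float_format="%.10g")
        manifests.record("candidates", {"classifier.json": outdir / "classifier.json"},
                         {"candidates.tsv": outdir / "candidates.tsv"},
                         {"top_fraction": cfg.top_fraction}, seed)

    return outdir
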