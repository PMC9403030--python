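"""End-to-end orchestration: config validation, staged runs, run manifest.

A run is driven by a flat, typed key-value config (YAML).  Stages execute in
dependency order — contacts -> specificity -> associations / metagene /
fitness — each writing TSV reports; a JSON manifest records the config
snapshot, software version, seeds and per-output SHA-256 checksums so that a
re-run with identical inputs is verifiably identical for deterministic
stages (and for stochastic stages given the same seeds).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .fitness import ElongationParams, FitnessParams, delta_v, fitness_effect, selection_regime
from .io import (
    bin_contact_map,
    build_contact_map,
    filter_genes_by_read_count,
    group_records_by_gene,
    read_anchor_table,
    read_coverage_bedgraph,
    read_gene_models_gff3,
)
from .metagene import metagene_profile, normalize_density, select_focal_site
from .simulate import SimConfig, emit_dataset, simulate_cohort
from .specificity import gene_specificity, site_specificity_track
from .stats import binned_trend, bootstrap_se, spearman

__all__ = ["RunConfig", "RunManifest", "ConfigViolation", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

_DEFAULTS: dict[str, Any] = {
    # inputs (None -> stage skipped or simulated)
    "anchors": None,
    "genes": None,
    "ribo": None,
    "expression": None,
    "out_dir": "foldspec_out",
    "simulate": False,
    "n_genes": 200,
    # thresholds
    "min_reads": 5,
    "halfwidth": 10,
    "min_offset": 200,
    "n_bins": 20,
    "bootstrap": 1000,
    "downsample_k": 5,
    "downsample_reps": 1000,
    "circ_fraction": 0.05,
    "mode": "binned",
    # fitness defaults
    "fitness_p": 1.0,
    "fitness_q": 1.2,
    "fitness_L": 400.0,
    "fitness_v": 20.0,
    "fitness_expression": 5000.0,
    "seed": 0,
}

_POSITIVE_KEYS = (
    "min_reads", "halfwidth", "min_offset", "n_bins", "bootstrap",
    "downsample_k", "downsample_reps", "circ_fraction", "n_genes",
)


@dataclass(frozen=True)
class ConfigViolation:
    key: str
    message: str
    remedy: str


@dataclass
class RunConfig:
    """Flat run configuration; unknown keys are rejected at load time."""

    values: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(_DEFAULTS)
        if unknown:
            raise KeyError(f"unknown config key(s): {sorted(unknown)}")
        merged = dict(_DEFAULTS)
        merged.update(self.values)
        self.values = merged

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise KeyError(f"{path}: config must be a key-value document")
        return cls(data)


@dataclass
class RunManifest:
    config: dict[str, Any]
    version: str
    seed: int
    started: float
    finished: float = 0.0
    outputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    stages: dict[str, str] = field(default_factory=dict)    # stage -> status/reason

    def write(self, path: str | Path) -> None:
        """Atomic write: temp file in the target directory, then rename."""
        path = Path(path)
        payload = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
        try:
            with os.fdopen(fd, "w") as fh:
                fh.write(payload)
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise


def validate_config(config: RunConfig | Mapping[str, Any]) -> list[ConfigViolation]:
    """List every violated invariant; an empty list means the config is valid."""
    if not isinstance(config, RunConfig):
        try:
            config = RunConfig(dict(config))
        except KeyError as exc:
            return [ConfigViolation("", str(exc), "remove or rename the unknown key")]
    v: list[ConfigViolation] = []
    for key in _POSITIVE_KEYS:
        if not config[key] or config[key] <= 0:
            v.append(ConfigViolation(key, f"{key} must be positive (got {config[key]})",
                                     f"set {key} to a positive value"))
    if config["mode"] not in ("binned", "raw"):
        v.append(ConfigViolation("mode", f"mode must be binned or raw (got {config['mode']})",
                                 "use 'binned' or 'raw'"))
    if not config["simulate"]:
        for key in ("anchors", "genes"):
            p = config[key]
            if p is None:
                v.append(ConfigViolation(key, f"{key} path is required unless simulate=true",
                                         f"provide {key} or set simulate: true"))
            elif not Path(p).exists():
                v.append(ConfigViolation(key, f"{key} path {p!r} does not exist",
                                         "fix the path"))
        for key in ("ribo", "expression"):
            p = config[key]
            if p is not None and not Path(p).exists():
                v.append(ConfigViolation(key, f"{key} path {p!r} does not exist",
                                         "fix the path or drop the key"))
    return v


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig | Mapping[str, Any]) -> RunManifest:
    """Execute all runnable stages and write the manifest.

    Raises on an invalid config before any stage runs.  Missing optional
    inputs skip only their dependent stages, with the reason logged and
    recorded in the manifest.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig(dict(config))
    problems = validate_config(config)
    if problems:
        raise ValueError(
            "invalid configuration: "
            + "; ".join(f"{p.key}: {p.message}" for p in problems)
        )
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest = RunManifest(dict(config.values), __version__, seed, time.time())

    # --- inputs -----------------------------------------------------------
    ribo_tracks = None
    expression = None
    if config["simulate"]:
        sim = simulate_cohort(SimConfig(n_genes=int(config["n_genes"]), seed=seed))
        paths = emit_dataset(sim, out_dir / "simdata")
        records = sim.records
        models = sim.models
        expression = sim.expression
        manifest.stages["simulate"] = "ok"
        for p in paths.values():
            manifest.outputs[str(p)] = _sha256(p)
    else:
        records = read_anchor_table(config["anchors"])
        models = read_gene_models_gff3(config["genes"])
        if config["expression"] is not None:
            import pandas as pd

            df = pd.read_csv(config["expression"], sep="\t")
            expression = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))
        if config["ribo"] is not None:
            ribo_tracks = read_coverage_bedgraph(
                config["ribo"], {g: m.length for g, m in models.items()}
            )

    # --- contacts + specificity ------------------------------------------
    keep = filter_genes_by_read_count(records, config["min_reads"])
    by_gene = {g: rs for g, rs in group_records_by_gene(records).items() if g in keep}
    mode = config["mode"]
    h = int(config["halfwidth"])
    gene_rows = []
    site_tracks = {}
    maps = {}
    for gid in sorted(by_gene):
        cmap = build_contact_map(by_gene[gid], models[gid])
        cmap = bin_contact_map(cmap, h)
        maps[gid] = cmap
        res = gene_specificity(cmap, mode=mode)
        if res is None:
            continue
        gene_rows.append((gid, len(by_gene[gid]), res.n, res.s_obs, res.s_max, res.s))
        site_tracks[gid] = site_specificity_track(cmap, mode=mode)
    s_path = out_dir / "gene_specificity.tsv"
    with open(s_path, "w") as fh:
        fh.write("gene_id\tn_reads\tn_pairs\tS_obs\tS_max\tS\n")
        for row in gene_rows:
            fh.write("{}\t{}\t{}\t{:.6g}\t{:.6g}\t{:.6g}\n".format(*row))
    manifest.outputs[str(s_path)] = _sha256(s_path)
    site_path = out_dir / "site_specificity.tsv"
    with open(site_path, "w") as fh:
        fh.write("gene_id\tpos\tS\tsupport\n")
        for gid, tr in site_tracks.items():
            for pos in np.flatnonzero(tr.defined()):
                fh.write(f"{gid}\t{pos}\t{tr.s[pos]:.6g}\t{tr.support[pos]}\n")
    manifest.outputs[str(site_path)] = _sha256(site_path)
    manifest.stages["specificity"] = "ok"

    gene_s = {row[0]: row[5] for row in gene_rows}

    # --- associations -----------------------------------------------------
    if expression is not None and len(gene_s) >= int(config["n_bins"]):
        common = sorted(set(gene_s) & set(expression))
        x = np.array([expression[g] for g in common])
        y = np.array([gene_s[g] for g in common])
        trend = binned_trend(x, y, n_bins=int(config["n_bins"]))
        se = bootstrap_se(y, n_boot=int(config["bootstrap"]), seed=seed)
        a_path = out_dir / "association_expression.tsv"
        with open(a_path, "w") as fh:
            fh.write("statistic\tvalue\n")
            fh.write(f"spearman_rho\t{trend.rho:.6g}\n")
            fh.write(f"spearman_p\t{trend.p:.6g}\n")
            fh.write(f"pearson_r\t{trend.pearson_r:.6g}\n")
            fh.write(f"mean_S\t{y.mean():.6g}\n")
            fh.write(f"bootstrap_se_mean_S\t{se:.6g}\n")
            fh.write(f"n_genes\t{len(common)}\n")
            fh.write(f"seed\t{seed}\n")
        manifest.outputs[str(a_path)] = _sha256(a_path)
        manifest.stages["associations"] = "ok"
    else:
        manifest.stages["associations"] = "skipped: no expression table"
        logger.info("associations skipped: no expression input")

    # --- metagene ---------------------------------------------------------
    if config["simulate"] and ribo_tracks is None:
        # generate matching ribosome coverage with the configured stall
        from .simulate import simulate_ribo_coverage

        ribo_tracks = {}
        focal = {}
        for gi, gid in enumerate(sorted(site_tracks)):
            site = select_focal_site(site_tracks[gid], min_offset=int(config["min_offset"]))
            if site is None:
                continue
            focal[gid] = site
            ribo_tracks[gid] = simulate_ribo_coverage(
                models[gid], site.position, seed=[seed, 2, gi]
            )
    elif ribo_tracks is not None:
        focal = {}
        for gid in sorted(site_tracks):
            if gid not in ribo_tracks:
                continue
            site = select_focal_site(site_tracks[gid], min_offset=int(config["min_offset"]))
            if site is not None:
                focal[gid] = site
    else:
        focal = {}
    if focal:
        norm = {}
        for gid in focal:
            try:
                norm[gid] = normalize_density(ribo_tracks[gid])
            except ValueError:
                logger.info("metagene: %s has zero-mean coverage, excluded", gid)
        focal = {g: f for g, f in focal.items() if g in norm}
        profile = metagene_profile(norm, focal)
        m_path = out_dir / "metagene_profile.tsv"
        with open(m_path, "w") as fh:
            fh.write("offset\tmean\tse\tn\n")
            for o, m, s_, n_ in zip(profile.offsets, profile.mean, profile.se, profile.n_genes):
                fh.write(f"{o}\t{m:.6g}\t{s_:.6g}\t{n_}\n")
        manifest.outputs[str(m_path)] = _sha256(m_path)
        manifest.stages["metagene"] = "ok"
    else:
        manifest.stages["metagene"] = "skipped: no ribosome coverage track"
        logger.info("metagene skipped: no ribosome coverage input")

    # --- fitness ----------------------------------------------------------
    ep = ElongationParams(
        p=float(config["fitness_p"]), q=float(config["fitness_q"]),
        length=float(config["fitness_L"]), v=float(config["fitness_v"]),
    )
    dv = delta_v(ep, form="approximate")
    fp = FitnessParams.from_yaml(None, expression=float(config["fitness_expression"]))
    s_coef = fitness_effect(dv, fp, length_codons=ep.length, baseline_speed=ep.v)
    f_path = out_dir / "fitness.tsv"
    with open(f_path, "w") as fh:
        fh.write("quantity\tvalue\n")
        fh.write(f"delta_v_codons_per_s\t{dv:.6g}\n")
        fh.write(f"selection_coefficient\t{s_coef:.6g}\n")
        fh.write(f"regime\t{selection_regime(s_coef, fp.ne)}\n")
    manifest.outputs[str(f_path)] = _sha256(f_path)
    manifest.stages["fitness"] = "ok"

    manifest.finished = time.time()
    manifest.write(out_dir / "manifest.json")
    return manifest
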