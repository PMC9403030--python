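"""Synthetic transcriptomes with known folding-specificity ground truth.

Every pipeline stage is testable without downloads: genes carry a small set
of latent duplexes, chimeric reads pick a duplex by a Dirichlet-multinomial
allocation whose concentration parameter tunes folding specificity, and
anchors scatter around the duplex arm centres with bounded uniform jitter
(mimicking the minor offsets of real proximity-ligation reads).  Read depth
is coupled linearly to a log-normal expression level; per-site conservation
(and melting temperature) can be statistically coupled to the realized
per-site specificity; ribosome coverage is Poisson with a multiplicative
stall factor injected a fixed distance upstream of chosen focal sites.

Generation contract (everything a test can hold on to):

* each read is promiscuous (background) with probability
  ``background_fraction``, pairing two random distant nucleotides — the
  scattered single-read pairs seen in real data, against which specific
  clusters stand out;
* otherwise the read picks a duplex by a Dirichlet(alpha_g/K, ...,
  alpha_g/K)-multinomial allocation, so the specific component diversifies —
  and measured S falls — as alpha grows;
* ``alpha_g = alpha * (expr_g / median_expr)^(-coupling)`` couples expression
  to specificity (coupling = 0 gives the null);
* every duplex-derived anchor lies within ``jitter`` nt of a true arm
  centre (exact with ``background_fraction = 0``);
* conservation_i = beta * z(S_i) + Normal(0, sigma) on defined sites, so the
  within-gene correlation approaches beta/sqrt(beta^2 + sigma^2);
* normalized ribosome density at the stalled nucleotide has expectation
  q L / (L - 1 + q) ~ q, and ~ 1 elsewhere.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import (
    AnchorRecord,
    CoverageTrack,
    GeneModel,
    write_anchor_table,
    write_coverage_bedgraph,
    write_gene_models_gff3,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimData",
    "simulate_transcriptome",
    "simulate_reads",
    "simulate_covariates",
    "simulate_ribo_coverage",
    "simulate_cohort",
    "emit_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic cohort (defaults are the baseline)."""

    n_genes: int = 500
    length_min: int = 500          # nt
    length_max: int = 1500
    duplexes_per_gene: int = 3     # K latent duplexes
    alpha: float = 1.0             # Dirichlet concentration (diversity knob)
    background_fraction: float = 0.5  # promiscuous (non-duplex) read probability
    jitter: int = 5                # anchor jitter half-width, nt
    arm_min_separation: int = 30   # nt between any two duplex arm centres
    expr_log_mean: float = 3.0     # log-normal expression, ln-scale
    expr_log_sd: float = 1.0
    depth_per_expression: float = 1.0   # reads per expression unit (linear)
    min_depth: int = 5
    max_depth: int = 40            # library-size saturation
    expression_alpha_coupling: float = 1.0  # 0 = expression-independent S
    conservation_beta: float = 1.0
    conservation_sigma: float = 1.0
    stall_factor: float = 1.2      # q
    stall_offset: int = 42         # nt upstream of the focal site
    ribo_lambda: float = 30.0      # baseline Ribo-Seq coverage per nt
    utr5_fraction: float = 0.10
    utr3_fraction: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must be in [0, 1)")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        if self.duplexes_per_gene < 1:
            raise ValueError("need at least one duplex per gene")
        if self.arm_min_separation <= 2 * self.jitter:
            raise ValueError("arm separation must exceed 2*jitter")
        if not 0 < self.length_min <= self.length_max:
            raise ValueError("invalid length bounds")
        if not 0 < self.min_depth <= self.max_depth:
            raise ValueError("invalid depth bounds")
        if self.stall_factor <= 0 or self.ribo_lambda <= 0:
            raise ValueError("stall factor and coverage rate must be positive")
        if not (0 <= self.utr5_fraction and 0 <= self.utr3_fraction
                and self.utr5_fraction + self.utr3_fraction < 1):
            raise ValueError("UTR fractions must be non-negative and sum below 1")
        m = 2 * self.duplexes_per_gene
        avail = (self.length_min - 2 * self.jitter) - (m - 1) * self.arm_min_separation
        if avail < m:
            raise ValueError(
                f"{self.duplexes_per_gene} duplexes do not fit in a "
                f"{self.length_min}-nt gene at separation {self.arm_min_separation}"
            )


@dataclass
class GroundTruth:
    """Per-gene latent duplexes, usage probabilities and stall positions."""

    duplexes: dict[str, list[tuple[int, int]]]
    usage: dict[str, np.ndarray]
    alpha: dict[str, float]
    stall_sites: dict[str, int] = field(default_factory=dict)

    def intended_specificity_rank(self) -> dict[str, int]:
        """Rank genes by intended specificity (1 = most specific = lowest alpha)."""
        order = sorted(self.alpha, key=lambda g: (self.alpha[g], g))
        return {g: i + 1 for i, g in enumerate(order)}


@dataclass
class SimData:
    """A full synthetic cohort: inputs plus ground truth."""

    config: SimConfig
    models: dict[str, GeneModel]
    truth: GroundTruth
    expression: dict[str, float]
    depth: dict[str, int]
    records_by_gene: dict[str, list[AnchorRecord]]

    @property
    def records(self) -> list[AnchorRecord]:
        return [r for recs in self.records_by_gene.values() for r in recs]


def _rng(seed: int | Sequence[int] | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_transcriptome(
    config: SimConfig,
) -> tuple[dict[str, GeneModel], GroundTruth, dict[str, float]]:
    """Draw gene models, latent duplexes, usage probabilities and expression."""
    config.validate()
    rng = _rng([config.seed, 0])
    K = config.duplexes_per_gene
    m = 2 * K
    sep = config.arm_min_separation
    j = config.jitter
    models: dict[str, GeneModel] = {}
    duplexes: dict[str, list[tuple[int, int]]] = {}
    usage: dict[str, np.ndarray] = {}
    alphas: dict[str, float] = {}
    expression: dict[str, float] = {}
    median_expr = math.exp(config.expr_log_mean)
    for gi in range(config.n_genes):
        gid = f"g{gi:05d}"
        L = int(rng.integers(config.length_min, config.length_max + 1))
        # sorted arm centres with pairwise separation >= sep, >= jitter from ends
        avail = (L - 2 * j) - (m - 1) * sep
        offs = np.sort(rng.choice(avail, size=m, replace=False))
        arms = j + offs + np.arange(m) * sep
        pairing = rng.permutation(m)
        dups = []
        for k in range(K):
            a, b = arms[pairing[2 * k]], arms[pairing[2 * k + 1]]
            dups.append((int(min(a, b)), int(max(a, b))))
        expr = float(rng.lognormal(config.expr_log_mean, config.expr_log_sd))
        alpha_g = config.alpha * (expr / median_expr) ** (-config.expression_alpha_coupling)
        alpha_g = float(np.clip(alpha_g, 1e-3, 1e3))
        usage[gid] = rng.dirichlet(np.full(K, alpha_g / K))
        alphas[gid] = alpha_g
        duplexes[gid] = dups
        expression[gid] = expr
        u5 = int(config.utr5_fraction * L)
        u3 = int(config.utr3_fraction * L)
        models[gid] = GeneModel(
            gid, L,
            cds=((u5, L - u3),),
            utr5=((0, u5),) if u5 else (),
            utr3=((L - u3, L),) if u3 else (),
        )
    return models, GroundTruth(duplexes, usage, alphas), expression


def simulate_reads(
    model: GeneModel,
    truth: GroundTruth,
    depth: int,
    jitter: int = 3,
    background_fraction: float = 0.0,
    seed: int | Sequence[int] | np.random.Generator = 0,
) -> list[AnchorRecord]:
    """Draw ``depth`` chimeric reads for one gene.

    Each read is promiscuous with probability ``background_fraction``
    (anchors at two random nucleotides at least 10 nt apart); otherwise it
    picks a latent duplex by the gene's usage probabilities and places its
    anchors at the duplex arm centres plus independent uniform jitter in
    [-jitter, +jitter].
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = _rng(seed)
    dups = truth.duplexes[model.gene_id]
    n_bg = int(rng.binomial(depth, background_fraction)) if background_fraction else 0
    counts = rng.multinomial(depth - n_bg, truth.usage[model.gene_id]) \
        if depth - n_bg > 0 else np.zeros(len(dups), dtype=int)
    records: list[AnchorRecord] = []
    for (a5, a3), cnt in zip(dups, counts):
        if cnt == 0:
            continue
        j5 = rng.integers(-jitter, jitter + 1, size=cnt)
        j3 = rng.integers(-jitter, jitter + 1, size=cnt)
        for d5, d3 in zip(j5, j3):
            records.append(AnchorRecord(model.gene_id, int(a5 + d5), int(a3 + d3)))
    min_gap = 10
    for _ in range(n_bg):
        i = int(rng.integers(0, model.length - min_gap))
        j = int(rng.integers(i + min_gap, model.length))
        records.append(AnchorRecord(model.gene_id, i, j))
    return records


def simulate_covariates(
    site_tracks: Mapping[str, "np.ndarray | object"],
    beta: float = 1.0,
    sigma: float = 1.0,
    seed: int | Sequence[int] | np.random.Generator = 0,
    gene_s: Mapping[str, float] | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict[str, float]]:
    """Per-site conservation and Tm coupled to specificity, plus gene importance.

    ``site_tracks`` maps gene -> per-site S (array with NaN at undefined
    sites, or a SiteSpecificityTrack).  On defined sites,
    ``conservation = beta * z(S) + eps`` and ``tm = -beta * z(S) + eps'`` with
    eps ~ Normal(0, sigma); undefined sites stay NaN.  Gene importance is
    ``beta * z(gene S) + eps`` across genes when ``gene_s`` is given.
    """
    if not (math.isfinite(beta) and math.isfinite(sigma)) or sigma < 0:
        raise ValueError("beta and sigma must be finite, sigma >= 0")
    rng = _rng(seed)
    conservation: dict[str, np.ndarray] = {}
    tm: dict[str, np.ndarray] = {}
    for gid, track in site_tracks.items():
        s = getattr(track, "s", track)
        s = np.asarray(s, float)
        cons = np.full_like(s, np.nan)
        tmv = np.full_like(s, np.nan)
        ok = np.isfinite(s)
        if ok.any():
            sv = s[ok]
            sd = sv.std()
            z = (sv - sv.mean()) / sd if sd > 0 else np.zeros_like(sv)
            cons[ok] = beta * z + rng.normal(0.0, sigma, size=z.size)
            tmv[ok] = -beta * z + rng.normal(0.0, sigma, size=z.size)
        conservation[gid] = cons
        tm[gid] = tmv
    importance: dict[str, float] = {}
    if gene_s:
        gids = sorted(gene_s)
        vals = np.array([gene_s[g] for g in gids], float)
        sd = vals.std()
        z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
        noise = rng.normal(0.0, sigma, size=len(gids))
        importance = {g: float(beta * zi + ni) for g, zi, ni in zip(gids, z, noise)}
    return conservation, tm, importance


def simulate_ribo_coverage(
    model: GeneModel,
    focal_position: int | None,
    q: float = 1.2,
    offset: int = 42,
    lam: float = 30.0,
    noise: bool = True,
    seed: int | Sequence[int] | np.random.Generator = 0,
) -> CoverageTrack:
    """Poisson ribosome coverage with a q-fold stall one nucleotide upstream.

    The stalled nucleotide sits at ``focal_position - offset`` (skipped when
    that falls outside the gene or ``focal_position`` is None).  With
    ``noise=False`` the track is the deterministic expectation (lam per nt,
    q*lam at the stall), for closed-form checks.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    rng = _rng(seed)
    lam_track = np.full(model.length, float(lam))
    if focal_position is not None:
        stall = focal_position - offset
        if 0 <= stall < model.length:
            lam_track[stall] *= q
    values = rng.poisson(lam_track).astype(float) if noise else lam_track
    return CoverageTrack(model.gene_id, values)


def simulate_cohort(config: SimConfig) -> SimData:
    """Full cohort: transcriptome, expression-coupled depths and reads."""
    models, truth, expression = simulate_transcriptome(config)
    depth: dict[str, int] = {}
    records_by_gene: dict[str, list[AnchorRecord]] = {}
    for gi, gid in enumerate(sorted(models)):
        d = min(
            config.max_depth,
            max(config.min_depth,
                int(round(config.depth_per_expression * expression[gid]))),
        )
        depth[gid] = d
        records_by_gene[gid] = simulate_reads(
            models[gid], truth, d, jitter=config.jitter,
            background_fraction=config.background_fraction,
            seed=[config.seed, 1, gi],
        )
    return SimData(config, models, truth, expression, depth, records_by_gene)


def emit_dataset(sim: SimData, out_dir: str | Path,
                 ribo: Mapping[str, CoverageTrack] | None = None) -> dict[str, Path]:
    """Write the cohort in the same text formats the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "anchors": out / "anchors.tsv",
        "genes": out / "genes.gff3",
        "expression": out / "expression.tsv",
    }
    write_anchor_table(sim.records, paths["anchors"])
    write_gene_models_gff3(sim.models, paths["genes"])
    with open(paths["expression"], "w") as fh:
        fh.write("gene_id\texpression\n")
        for gid in sorted(sim.expression):
            fh.write(f"{gid}\t{sim.expression[gid]:.6g}\n")
    if ribo is not None:
        paths["ribo"] = out / "ribo.bedgraph"
        write_coverage_bedgraph(ribo, paths["ribo"])
    return paths
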