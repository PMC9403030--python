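"""Ribosome-density normalization, focal/control sites and meta-gene profiles.

Ribosome stalling leaves a footprint as locally elevated Ribo-Seq coverage.
To compare stalling across genes the coverage at each nucleotide is divided
by the transcript mean (normalized ribosome density; transcript mean exactly
1, values > 1 suggest stalling).  Per gene, a focal site is the 5'-most
nucleotide of maximal folding specificity at least ``min_offset`` nt into the
transcript (default 200, excluding the 5' elongation ramp); control sites are
random zero-specificity sites, optionally matched on proximity-ligation
coverage.  Aligning genes on their focal sites (x = 0) and averaging the
normalized density per offset yields a meta-gene stalling profile.  The same
machinery, anchored on the start codon, produces positional specificity
profiles over the first nucleotides of the CDS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import CoverageTrack, GeneModel
from .specificity import SiteSpecificityTrack
from .stats import sign_binomial_test

__all__ = [
    "MetaGeneProfile",
    "FocalSite",
    "normalize_density",
    "select_focal_site",
    "select_control_site",
    "metagene_profile",
    "positional_profile",
    "cds_utr_contrast",
    "cds_utr_sign_test",
]

logger = logging.getLogger(__name__)

S_ZERO_TOL = 1e-12  # numerical tolerance for "S = 0" site classification


@dataclass
class MetaGeneProfile:
    """Mean +/- SE of a per-nucleotide signal over focal-aligned offsets."""

    offsets: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_genes: np.ndarray


@dataclass(frozen=True)
class FocalSite:
    """An aligned x = 0 position for one gene in a meta-gene analysis."""

    gene_id: str
    position: int
    s: float
    rpl_coverage: float
    kind: str = "specific"


def normalize_density(riboseq: CoverageTrack, gene: GeneModel | None = None) -> CoverageTrack:
    """Divide per-nucleotide coverage by the transcript mean coverage.

    The output transcript mean is exactly 1; a zero-mean transcript raises
    (callers exclude such genes with a log entry).
    """
    mean = riboseq.values.mean()
    if mean <= 0:
        raise ValueError(f"{riboseq.gene_id}: zero-mean transcript, cannot normalize")
    return CoverageTrack(riboseq.gene_id, riboseq.values / mean)


def select_focal_site(
    track: SiteSpecificityTrack,
    rpl_coverage: CoverageTrack | None = None,
    min_offset: int = 200,
    require_positive: bool = True,
) -> FocalSite | None:
    """5'-most maximal-specificity site at position >= ``min_offset``.

    Among qualifying sites the maximal S wins; ties go to the smallest
    position (closest to the 5' end).  By default the gene must show specific
    folding at all (max S > 0): a zero-specificity "focal" site would be
    indistinguishable from the S = 0 control class.  Returns None when no
    defined site qualifies (the gene is excluded with a log entry).
    """
    s = track.s
    qual = np.isfinite(s)
    if require_positive:
        qual &= s > S_ZERO_TOL
    qual[:min_offset] = False
    if not qual.any():
        logger.info("focal site: %s has no defined site >= %d nt, excluded",
                    track.gene_id, min_offset)
        return None
    idx = np.flatnonzero(qual)
    best = idx[np.argmax(s[idx])]  # argmax returns the first (5'-most) maximum
    cov = float(rpl_coverage.values[best]) if rpl_coverage is not None else float("nan")
    return FocalSite(track.gene_id, int(best), float(s[best]), cov, "specific")


def select_control_site(
    track: SiteSpecificityTrack,
    rpl_coverage: CoverageTrack,
    scheme: str = "random_zero_S",
    reference: FocalSite | None = None,
    min_offset: int = 200,
    seed: int | np.random.Generator = 0,
) -> FocalSite | None:
    """Random zero-specificity control site for a meta-gene profile.

    ``random_zero_S``: uniform over sites with S = 0 and nonzero
    proximity-ligation coverage.  ``coverage_matched_zero_S``: additionally
    requires the same coverage as the reference focal site; if no exact match
    exists, the nearest coverage is used with a log entry (the matching rule
    has no published fallback).  Deterministic under a fixed seed.  Returns
    None when no site qualifies.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = track.s
    cov = rpl_coverage.values
    qual = np.isfinite(s) & (np.abs(s) <= S_ZERO_TOL) & (cov > 0)
    qual[:min_offset] = False
    if not qual.any():
        logger.info("control site: %s has no qualifying S=0 site, excluded", track.gene_id)
        return None
    idx = np.flatnonzero(qual)
    if scheme == "coverage_matched_zero_S":
        if reference is None:
            raise ValueError("coverage-matched scheme requires a reference site")
        exact = idx[cov[idx] == reference.rpl_coverage]
        if len(exact) > 0:
            idx = exact
        else:
            gap = np.abs(cov[idx] - reference.rpl_coverage)
            idx = idx[gap == gap.min()]
            logger.info(
                "control site: %s has no exact coverage match for %g, "
                "using nearest (|gap| = %g)",
                track.gene_id, reference.rpl_coverage, float(np.min(gap)),
            )
    elif scheme != "random_zero_S":
        raise ValueError(f"unknown control scheme {scheme!r}")
    pick = int(idx[rng.integers(len(idx))]) if len(idx) > 1 else int(idx[0])
    kind = "matched_control" if scheme == "coverage_matched_zero_S" else "random_control"
    return FocalSite(track.gene_id, pick, float(s[pick]), float(cov[pick]), kind)


def metagene_profile(
    tracks: Mapping[str, np.ndarray | CoverageTrack | SiteSpecificityTrack],
    focal: Mapping[str, FocalSite] | Sequence[FocalSite],
    window: tuple[int, int] = (-100, 50),
) -> MetaGeneProfile:
    """Average a per-nucleotide signal across genes aligned on focal sites.

    ``window=(lo, hi)`` spans offsets lo..hi inclusive relative to x = 0.
    Each gene contributes only offsets that fall inside the gene and carry a
    defined (non-NaN) value; per-offset SE is across contributing genes.
    """
    if not isinstance(focal, Mapping):
        focal = {f.gene_id: f for f in focal}
    if not focal:
        raise ValueError("empty focal-site set")
    lo, hi = window
    if hi < lo:
        raise ValueError("window upper bound below lower bound")
    offsets = np.arange(lo, hi + 1)
    n = np.zeros(len(offsets), dtype=np.int64)
    tot = np.zeros(len(offsets))
    tot2 = np.zeros(len(offsets))
    for gid, site in focal.items():
        track = tracks[gid]
        if isinstance(track, CoverageTrack):
            values = track.values
        elif isinstance(track, SiteSpecificityTrack):
            values = track.s
        else:
            values = np.asarray(track, float)
        pos = site.position + offsets
        ok = (pos >= 0) & (pos < len(values))
        vals = values[pos[ok]]
        fin = np.isfinite(vals)
        sel = np.flatnonzero(ok)[fin]
        v = vals[fin]
        n[sel] += 1
        tot[sel] += v
        tot2[sel] += v * v
    mean = np.full(len(offsets), np.nan)
    se = np.full(len(offsets), np.nan)
    has = n >= 1
    mean[has] = tot[has] / n[has]
    two = n >= 2
    var = np.maximum(tot2[two] / n[two] - mean[two] ** 2, 0.0) * n[two] / (n[two] - 1)
    se[two] = np.sqrt(var / n[two])
    return MetaGeneProfile(offsets, mean, se, n)


def positional_profile(
    tracks: Mapping[str, SiteSpecificityTrack],
    models: Mapping[str, GeneModel] | None = None,
    window: tuple[int, int] = (0, 149),
) -> MetaGeneProfile:
    """Start-anchored per-nucleotide specificity profile (focal = CDS start).

    With gene models, x = 0 is the first CDS nucleotide; otherwise the
    transcript start.  The default window covers the first 150 nt after the
    start codon, where translation-regulatory hairpins (e.g. Dhh1 targets,
    around nucleotide 70) show elevated specificity.
    """
    focal = {}
    for gid, track in tracks.items():
        start = 0
        if models is not None and gid in models and models[gid].cds:
            start = min(s for s, _e in models[gid].cds)
        focal[gid] = FocalSite(gid, start, float("nan"), float("nan"), "start_anchor")
    return metagene_profile(tracks, focal, window=window)


def cds_utr_contrast(
    track: SiteSpecificityTrack, model: GeneModel
) -> tuple[float, float, str] | None:
    """Mean per-site S of the CDS vs the UTRs of one gene.

    Returns ``(mean_cds, mean_utr, label)`` with label 'CDS>UTR', 'UTR>CDS'
    or 'tie'; None when either region has no defined site (gene excluded).
    """
    defined = track.defined()
    cds_mask = model.region_mask("cds") & defined
    utr_mask = model.region_mask("utr") & defined
    if not cds_mask.any() or not utr_mask.any():
        logger.info("CDS/UTR contrast: %s lacks defined sites in one region", track.gene_id)
        return None
    mean_cds = float(track.s[cds_mask].mean())
    mean_utr = float(track.s[utr_mask].mean())
    if mean_cds > mean_utr:
        label = "CDS>UTR"
    elif mean_utr > mean_cds:
        label = "UTR>CDS"
    else:
        label = "tie"
    return mean_cds, mean_utr, label


def cds_utr_sign_test(
    tracks: Mapping[str, SiteSpecificityTrack], models: Mapping[str, GeneModel]
) -> tuple[int, int, float]:
    """Cohort CDS-vs-UTR sign test: (n_cds_higher, n_utr_higher, binomial p).

    Ties and genes lacking defined sites in either region are excluded.
    """
    n_cds = n_utr = 0
    for gid, track in tracks.items():
        if gid not in models:
            continue
        res = cds_utr_contrast(track, models[gid])
        if res is None:
            continue
        if res[2] == "CDS>UTR":
            n_cds += 1
        elif res[2] == "UTR>CDS":
            n_utr += 1
    total = n_cds + n_utr
    p = sign_binomial_test(n_cds, total) if total else float("nan")
    return n_cds, n_utr, p
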