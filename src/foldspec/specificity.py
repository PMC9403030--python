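"""Entropy-based RNA folding specificity at gene, region and site resolution.

The folding specificity of a gene (or region, or single nucleotide) measures
how reproducibly its chimeric reads pick the same folding partner.  Given the
weights ``w_k`` of the ``n`` observed anchor pairs (raw counts ``M`` or binned
scores ``M*``), with ``p_k = w_k / sum(w)``:

    S_obs = -sum_k p_k ln p_k         (Shannon entropy of partner choice)
    S_max = ln n                      (entropy if every pair were equal)
    S     = S_max - S_obs             (folding specificity, in nats)

``S`` is zero when all observed pairs are equally supported (maximally diverse
folding) and grows as support concentrates on few pairs.  It is mathematically
the Theil T inequality index of the weight vector, and subtracting ``S_max``
controls for sequencing depth and the number of supported sites.

Circularization scores (anchor distance normalized to gene length) support
subsetting reads into distal/proximal folding before recomputing ``S``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import (
    AnchorRecord,
    ContactMap,
    GeneModel,
    bin_contact_map,
    build_contact_map,
)

__all__ = [
    "SpecificityResult",
    "SiteSpecificityTrack",
    "CircScore",
    "entropy_specificity",
    "gene_specificity",
    "region_specificity",
    "site_specificity",
    "site_specificity_track",
    "circularization_score",
    "specificity_by_circularization",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpecificityResult:
    """Observed entropy, maximal entropy and specificity (all in nats)."""

    s_obs: float
    s_max: float
    s: float
    n: int
    scope: str = "gene"


@dataclass
class SiteSpecificityTrack:
    """Per-nucleotide folding specificity of one gene.

    ``s[i]`` is NaN where nucleotide i occurs in no observed pair; NaN is an
    explicit missing marker, distinct from S = 0 (observed, perfectly diverse
    partner choice).  ``support[i]`` counts the observed pairs involving i.
    """

    gene_id: str
    s: np.ndarray
    support: np.ndarray

    def defined(self) -> np.ndarray:
        return self.support > 0


@dataclass(frozen=True)
class CircScore:
    """Circularization score of one chimeric read: anchor distance / length."""

    record: AnchorRecord
    score: float


def entropy_specificity(
    weights: Iterable[float], scope: str = "gene"
) -> SpecificityResult:
    """Specificity of a positive weight multiset: ``S = ln n - S_obs``."""
    w = np.asarray(list(weights) if not isinstance(weights, np.ndarray) else weights,
                   dtype=float)
    if w.size == 0:
        raise ValueError("empty weight set")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    p = w / w.sum()
    s_obs = float(-(p * np.log(p)).sum())
    s_max = math.log(w.size)
    return SpecificityResult(s_obs, s_max, s_max - s_obs, int(w.size), scope)


def _map_weights(cmap: ContactMap, mode: str) -> np.ndarray:
    if mode == "binned":
        if cmap.mstar is None:
            raise ValueError("contact map is not binned; call bin_contact_map first")
        return cmap.mstar
    if mode == "raw":
        return cmap.counts
    raise ValueError(f"mode must be 'binned' or 'raw', got {mode!r}")


def gene_specificity(cmap: ContactMap, mode: str = "binned") -> SpecificityResult | None:
    """Gene-level folding specificity over the observed-pair support.

    Returns ``None`` (undefined) for an empty map.  The default uses the
    binned scores ``M*``; ``mode='raw'`` uses raw pair counts, in which nearby
    anchor offsets do not reinforce each other.
    """
    if cmap.is_empty():
        return None
    return entropy_specificity(_map_weights(cmap, mode), scope="gene")


def region_specificity(
    cmap: ContactMap,
    region: str | Sequence[tuple[int, int]],
    model: GeneModel | None = None,
    mode: str = "binned",
    membership: str = "both",
) -> SpecificityResult | None:
    """Specificity over the observed pairs lying inside ``region``.

    A pair belongs to the region iff both anchors are inside it (a duplex is a
    property of both partners); ``membership='single'`` relaxes this to either
    anchor.  ``region`` may be explicit intervals or a named region of
    ``model`` ('cds', 'utr5', 'utr3', 'utr').  Returns ``None`` when the
    region contains no observed pair.
    """
    if cmap.is_empty():
        return None
    if isinstance(region, str):
        if model is None:
            raise ValueError("named region requires a GeneModel")
        mask = model.region_mask(region)
    else:
        mask = np.zeros(cmap.length, dtype=bool)
        for s, e in region:
            mask[max(0, s) : min(cmap.length, e)] = True
    in_i = mask[cmap.pair_i]
    in_j = mask[cmap.pair_j]
    if membership == "both":
        keep = in_i & in_j
    elif membership == "single":
        keep = in_i | in_j
    else:
        raise ValueError(f"membership must be 'both' or 'single', got {membership!r}")
    if not keep.any():
        return None
    return entropy_specificity(_map_weights(cmap, mode)[keep], scope="region")


def site_specificity(cmap: ContactMap, site: int, mode: str = "binned") -> float:
    """Folding specificity of one nucleotide over the pairs involving it.

    NaN (missing) when the site occurs in no observed pair.
    """
    if not 0 <= site < cmap.length:
        raise IndexError(f"site {site} outside [0,{cmap.length})")
    keep = (cmap.pair_i == site) | (cmap.pair_j == site)
    if not keep.any():
        return float("nan")
    return entropy_specificity(_map_weights(cmap, mode)[keep], scope="site").s


def site_specificity_track(cmap: ContactMap, mode: str = "binned") -> SiteSpecificityTrack:
    """Per-nucleotide specificity for every site of the gene at once.

    Equivalent to calling :func:`site_specificity` at each site, vectorized:
    each observed pair contributes its weight to both of its anchors, and the
    per-site entropy is computed from grouped sums of ``w`` and ``w ln w``.
    """
    w = _map_weights(cmap, mode)
    L = cmap.length
    s = np.full(L, np.nan)
    support = np.zeros(L, dtype=np.int64)
    if cmap.n_pairs == 0:
        return SiteSpecificityTrack(cmap.gene_id, s, support)
    sites = np.concatenate([cmap.pair_i, cmap.pair_j])
    ww = np.concatenate([w, w])
    np.add.at(support, sites, 1)
    wsum = np.zeros(L)
    wlogsum = np.zeros(L)
    np.add.at(wsum, sites, ww)
    np.add.at(wlogsum, sites, ww * np.log(ww))
    defined = support > 0
    # S = ln n - (ln W - sum(w ln w)/W)  with W = sum of the site's weights
    s[defined] = (
        np.log(support[defined])
        - np.log(wsum[defined])
        + wlogsum[defined] / wsum[defined]
    )
    # guard tiny negative rounding
    s[defined] = np.maximum(s[defined], 0.0)
    return SiteSpecificityTrack(cmap.gene_id, s, support)


# ---------------------------------------------------------------------------
# circularization

def circularization_score(record: AnchorRecord, model: GeneModel) -> CircScore:
    """Anchor-centre distance normalized to gene length, in [0, 1)."""
    if model.length <= 0:
        raise ValueError(f"{model.gene_id}: zero-length gene")
    if max(record.pos5, record.pos3) >= model.length:
        raise ValueError(f"{model.gene_id}: anchor outside gene")
    return CircScore(record, abs(record.pos3 - record.pos5) / model.length)


def specificity_by_circularization(
    records_by_gene: Mapping[str, Sequence[AnchorRecord]],
    models: Mapping[str, GeneModel],
    fraction: float = 0.05,
    side: str = "distal",
    mode: str = "binned",
    halfwidth: int = 10,
) -> dict[str, SpecificityResult]:
    """Recompute per-gene S from the most distal or proximal folding reads.

    Per gene, reads are ranked by circularization score and the top
    (``side='distal'``) or bottom (``side='proximal'``) ``ceil(fraction * n)``
    reads are kept; ties at the boundary break deterministically by
    (score, pos5, pos3).  Genes left with no reads are dropped with a log entry.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if side not in ("distal", "proximal"):
        raise ValueError(f"side must be 'distal' or 'proximal', got {side!r}")
    out: dict[str, SpecificityResult] = {}
    for gid, records in records_by_gene.items():
        model = models[gid]
        if not records:
            logger.info("circularization subset: %s has no reads, dropped", gid)
            continue
        keyed = sorted(
            records,
            key=lambda r: (abs(r.pos3 - r.pos5) / model.length, r.pos5, r.pos3),
            reverse=(side == "distal"),
        )
        k = math.ceil(fraction * len(keyed))
        subset = keyed[:k]
        cmap = build_contact_map(subset, model)
        if mode == "binned":
            cmap = bin_contact_map(cmap, halfwidth)
        res = gene_specificity(cmap, mode=mode)
        if res is not None:
            out[gid] = res
    return out
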