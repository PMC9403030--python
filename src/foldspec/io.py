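"""I/O and contact-map construction for intramolecular chimeric-read data.

Proximity-ligation assays (RPL, PARIS and relatives) produce chimeric reads
whose two mapped anchors evidence an intramolecular RNA duplex.  This module
reads/writes the anchor tables, transcript-space gene models and per-nucleotide
coverage tracks used throughout the package, and builds per-gene contact maps:

* ``M``        raw pair counts over unordered anchor pairs (i < j);
* ``c``        pooled per-base anchor coverage (both read sides);
* ``Mnorm``    coverage-normalized scores ``M_ij / (c_i * c_j)``;
* ``Mstar``    window-binned scores: the sum of ``Mnorm`` over the
  ``(2h+1) x (2h+1)`` window centred on (i, j), evaluated on the observed-pair
  support only.  Binning pools chimeric reads that support the same duplex
  with minor anchor offsets.

Coordinates are 0-based half-open internally; text formats default to 1-based
inclusive (typical of public deposits) with a flag to control conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnchorRecord",
    "GeneModel",
    "CoverageTrack",
    "ContactMap",
    "AnchorTableError",
    "read_anchor_table",
    "write_anchor_table",
    "read_gene_models_gff3",
    "write_gene_models_gff3",
    "read_gene_models_bed12",
    "read_coverage_bedgraph",
    "write_coverage_bedgraph",
    "read_coverage_tsv",
    "group_records_by_gene",
    "build_contact_map",
    "bin_contact_map",
    "filter_genes_by_read_count",
]


class AnchorTableError(ValueError):
    """Malformed anchor table input."""


@dataclass(frozen=True)
class AnchorRecord:
    """One chimeric read: two intramolecular anchor coordinates on a gene.

    Positions are 0-based transcript coordinates.  ``pos5``/``pos3`` name the
    5'- and 3'-side anchors as deposited; duplexes are physically symmetric, so
    contact maps canonicalize pairs to i < j.
    """

    gene_id: str
    pos5: int
    pos3: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.pos5 == self.pos3:
            raise ValueError(
                f"{self.gene_id}: anchors must differ (got pos5 == pos3 == {self.pos5})"
            )
        if self.pos5 < 0 or self.pos3 < 0:
            raise ValueError(f"{self.gene_id}: negative anchor coordinate")
        if self.weight <= 0:
            raise ValueError(f"{self.gene_id}: read weight must be positive")


@dataclass(frozen=True)
class GeneModel:
    """A gene represented by its longest transcript, in transcript coordinates.

    ``cds``, ``utr5`` and ``utr3`` are sequences of 0-based half-open
    intervals within ``[0, length)``.
    """

    gene_id: str
    length: int
    cds: tuple[tuple[int, int], ...] = ()
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()
    biotype: str = "mRNA"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.gene_id}: non-positive length")
        for name in ("cds", "utr5", "utr3"):
            ivals = tuple(tuple(iv) for iv in getattr(self, name))
            object.__setattr__(self, name, ivals)
            for s, e in ivals:
                if not (0 <= s < e <= self.length):
                    raise ValueError(
                        f"{self.gene_id}: {name} interval ({s},{e}) outside [0,{self.length})"
                    )

    def region_mask(self, region: str | Sequence[tuple[int, int]]) -> np.ndarray:
        """Boolean per-nucleotide mask for 'cds'/'utr5'/'utr3'/'utr' or explicit intervals."""
        if isinstance(region, str):
            key = region.lower()
            if key == "utr":
                ivals = self.utr5 + self.utr3
            elif key in ("cds", "utr5", "utr3"):
                ivals = getattr(self, key)
            else:
                raise KeyError(f"unknown region name {region!r}")
        else:
            ivals = region
        mask = np.zeros(self.length, dtype=bool)
        for s, e in ivals:
            mask[max(0, s) : min(self.length, e)] = True
        return mask


@dataclass
class CoverageTrack:
    """Per-nucleotide non-negative coverage for one transcript."""

    gene_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("coverage must be 1-dimensional")
        if np.any(self.values < 0):
            raise ValueError(f"{self.gene_id}: negative coverage")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ContactMap:
    """Per-gene sparse pair-count matrix with normalized and binned scores.

    Pairs are unordered, stored with ``pair_i < pair_j`` on the observed-pair
    support only.  ``coverage[i]`` is the total anchor weight at base i, both
    read sides pooled, so ``coverage.sum() == 2 * total read weight``.
    ``mstar`` is ``None`` until :func:`bin_contact_map` is applied.
    """

    gene_id: str
    length: int
    pair_i: np.ndarray
    pair_j: np.ndarray
    counts: np.ndarray
    coverage: np.ndarray
    mnorm: np.ndarray
    halfwidth: int | None = None
    mstar: np.ndarray | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pair_i)

    @property
    def total_weight(self) -> float:
        return float(self.counts.sum())

    def is_empty(self) -> bool:
        return self.n_pairs == 0


# ---------------------------------------------------------------------------
# anchor tables

def read_anchor_table(path: str | Path, one_based: bool = True) -> list[AnchorRecord]:
    """Read a tab-separated anchor table (gene_id, pos5, pos3[, weight]).

    Lines starting with ``#`` and blank lines are skipped.  Records with equal
    anchors are rejected; their count is reported as a single warning.
    Malformed lines raise :class:`AnchorTableError` naming the line number.
    """
    records: list[AnchorRecord] = []
    rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AnchorTableError(f"{path}: line {lineno}: expected >=3 columns")
            try:
                gene_id = fields[0]
                pos5 = int(fields[1])
                pos3 = int(fields[2])
                weight = float(fields[3]) if len(fields) > 3 else 1.0
            except ValueError as exc:
                raise AnchorTableError(f"{path}: line {lineno}: {exc}") from None
            if one_based:
                pos5 -= 1
                pos3 -= 1
            if pos5 == pos3:
                rejected += 1
                continue
            try:
                records.append(AnchorRecord(gene_id, pos5, pos3, weight))
            except ValueError as exc:
                raise AnchorTableError(f"{path}: line {lineno}: {exc}") from None
    if rejected:
        warnings.warn(
            f"{path}: rejected {rejected} record(s) with identical anchors",
            stacklevel=2,
        )
    return records


def write_anchor_table(
    records: Iterable[AnchorRecord], path: str | Path, one_based: bool = True
) -> None:
    shift = 1 if one_based else 0
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.gene_id}\t{r.pos5 + shift}\t{r.pos3 + shift}\t{r.weight:g}\n")


# ---------------------------------------------------------------------------
# gene models

_GFF_UTR5 = {"five_prime_utr", "five_prime_UTR", "5UTR"}
_GFF_UTR3 = {"three_prime_utr", "three_prime_UTR", "3UTR"}


def read_gene_models_gff3(path: str | Path) -> dict[str, GeneModel]:
    """Read transcript-space gene models from GFF3.

    The dialect (as emitted by :func:`write_gene_models_gff3` and the
    simulator) uses one seqid per transcript, a ``gene`` (or ``mRNA``) feature
    spanning the transcript, and ``CDS``/``five_prime_UTR``/``three_prime_UTR``
    children.  GFF3 coordinates are 1-based inclusive.
    """
    lengths: dict[str, int] = {}
    biotypes: dict[str, str] = {}
    parts: dict[str, dict[str, list[tuple[int, int]]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8:
                raise AnchorTableError(f"{path}: malformed GFF3 line: {line!r}")
            seqid, _src, ftype, start, end = cols[0], cols[1], cols[2], cols[3], cols[4]
            s, e = int(start) - 1, int(end)  # to 0-based half-open
            slot = parts.setdefault(seqid, {"cds": [], "utr5": [], "utr3": []})
            if ftype in ("gene", "mRNA", "transcript", "ncRNA"):
                lengths[seqid] = max(lengths.get(seqid, 0), e)
                if len(cols) > 8:
                    for kv in cols[8].split(";"):
                        if kv.startswith("biotype="):
                            biotypes[seqid] = kv.split("=", 1)[1]
            elif ftype == "CDS":
                slot["cds"].append((s, e))
            elif ftype in _GFF_UTR5:
                slot["utr5"].append((s, e))
            elif ftype in _GFF_UTR3:
                slot["utr3"].append((s, e))
    models = {}
    for gid, slot in parts.items():
        length = lengths.get(gid)
        if length is None:
            length = max(e for ivals in slot.values() for _s, e in ivals)
        models[gid] = GeneModel(
            gid,
            length,
            cds=tuple(sorted(slot["cds"])),
            utr5=tuple(sorted(slot["utr5"])),
            utr3=tuple(sorted(slot["utr3"])),
            biotype=biotypes.get(gid, "mRNA"),
        )
    return models


def write_gene_models_gff3(models: Mapping[str, GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(models):
            m = models[gid]
            fh.write(
                f"{gid}\tfoldspec\tgene\t1\t{m.length}\t.\t+\t.\t"
                f"ID={gid};biotype={m.biotype}\n"
            )
            for ftype, ivals in (
                ("five_prime_UTR", m.utr5),
                ("CDS", m.cds),
                ("three_prime_UTR", m.utr3),
            ):
                for s, e in ivals:
                    fh.write(
                        f"{gid}\tfoldspec\t{ftype}\t{s + 1}\t{e}\t.\t+\t.\tParent={gid}\n"
                    )


def read_gene_models_bed12(path: str | Path) -> dict[str, GeneModel]:
    """Read gene models from BED12 where each line is one transcript in its
    own coordinate system (chromStart 0, chromEnd = length, thick = CDS)."""
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "thick_start", "thick_end", "rgb", "block_count", "block_sizes", "block_starts",
    ]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    models = {}
    for row in df.itertuples(index=False):
        gid = str(row.name) if str(row.name) != "." else str(row.chrom)
        length = int(row.end) - int(row.start)
        ts, te = int(row.thick_start), int(row.thick_end)
        cds = ((ts, te),) if te > ts else ()
        utr5 = ((0, ts),) if ts > 0 else ()
        utr3 = ((te, length),) if te < length and te > ts else ()
        models[gid] = GeneModel(gid, length, cds=cds, utr5=utr5, utr3=utr3)
    return models


# ---------------------------------------------------------------------------
# coverage tracks

def read_coverage_bedgraph(
    path: str | Path, lengths: Mapping[str, int]
) -> dict[str, CoverageTrack]:
    """Read per-transcript coverage from bedGraph (0-based half-open intervals)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["gene_id", "start", "end", "value"],
    )
    tracks = {}
    for gid, sub in df.groupby("gene_id", sort=False):
        gid = str(gid)
        if gid not in lengths:
            raise KeyError(f"{path}: unknown transcript {gid!r}")
        values = np.zeros(lengths[gid], dtype=float)
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            values[int(s) : int(e)] = v
        tracks[gid] = CoverageTrack(gid, values)
    return tracks


def write_coverage_bedgraph(
    tracks: Mapping[str, CoverageTrack], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for gid in sorted(tracks):
            v = tracks[gid].values
            # run-length encode constant stretches
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(v)]))
            for s, e in zip(starts, ends):
                fh.write(f"{gid}\t{s}\t{e}\t{v[s]:g}\n")


def read_coverage_tsv(
    path: str | Path, gene_id: str, length: int, one_based: bool = True
) -> CoverageTrack:
    """Read a 2-column (pos, value) per-transcript coverage TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["pos", "value"])
    values = np.zeros(length, dtype=float)
    pos = df["pos"].to_numpy(dtype=int) - (1 if one_based else 0)
    if np.any((pos < 0) | (pos >= length)):
        raise ValueError(f"{path}: position outside [0,{length})")
    values[pos] = df["value"].to_numpy(dtype=float)
    return CoverageTrack(gene_id, values)


# ---------------------------------------------------------------------------
# contact maps

def group_records_by_gene(
    records: Iterable[AnchorRecord],
) -> dict[str, list[AnchorRecord]]:
    out: dict[str, list[AnchorRecord]] = {}
    for r in records:
        out.setdefault(r.gene_id, []).append(r)
    return out


def build_contact_map(records: Sequence[AnchorRecord], model: GeneModel) -> ContactMap:
    """Build the normalized contact map of one gene.

    ``M`` counts read weight per unordered anchor pair; ``c`` pools anchor
    occurrences of both read sides; ``Mnorm_ij = M_ij / (c_i c_j)``.
    An empty record set yields a valid empty map.
    """
    coverage = np.zeros(model.length, dtype=float)
    if not records:
        return ContactMap(
            model.gene_id, model.length,
            np.empty(0, int), np.empty(0, int),
            np.empty(0, float), coverage, np.empty(0, float),
        )
    gids = {r.gene_id for r in records}
    if gids != {model.gene_id}:
        raise ValueError(f"records for {gids} do not match gene {model.gene_id!r}")
    p5 = np.array([r.pos5 for r in records], dtype=np.int64)
    p3 = np.array([r.pos3 for r in records], dtype=np.int64)
    w = np.array([r.weight for r in records], dtype=float)
    if np.any((p5 >= model.length) | (p3 >= model.length)):
        raise ValueError(f"{model.gene_id}: anchor coordinate beyond gene length")
    lo = np.minimum(p5, p3)
    hi = np.maximum(p5, p3)
    np.add.at(coverage, lo, w)
    np.add.at(coverage, hi, w)
    key = lo * model.length + hi
    uniq, inv = np.unique(key, return_inverse=True)
    counts = np.zeros(len(uniq), dtype=float)
    np.add.at(counts, inv, w)
    pair_i = (uniq // model.length).astype(np.int64)
    pair_j = (uniq % model.length).astype(np.int64)
    mnorm = counts / (coverage[pair_i] * coverage[pair_j])
    return ContactMap(model.gene_id, model.length, pair_i, pair_j, counts, coverage, mnorm)


def bin_contact_map(cmap: ContactMap, halfwidth: int = 10) -> ContactMap:
    """Fill ``Mstar`` by window-summing ``Mnorm`` around every observed pair.

    ``Mstar_ij`` sums ``Mnorm`` over all observed unordered pairs falling in
    the ``(i±h) x (j±h)`` window in either orientation (each pair counted
    once); windows truncate at the gene ends, which is automatic on the
    observed-pair support.  Returns a new map; the input is unmodified.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    n = cmap.n_pairs
    if n == 0:
        mstar = np.empty(0, dtype=float)
    else:
        i = cmap.pair_i[:, None]
        j = cmap.pair_j[:, None]
        a = cmap.pair_i[None, :]
        b = cmap.pair_j[None, :]
        h = halfwidth
        hit = ((np.abs(a - i) <= h) & (np.abs(b - j) <= h)) | (
            (np.abs(b - i) <= h) & (np.abs(a - j) <= h)
        )
        mstar = hit @ cmap.mnorm
    return ContactMap(
        cmap.gene_id, cmap.length, cmap.pair_i, cmap.pair_j, cmap.counts,
        cmap.coverage, cmap.mnorm, halfwidth=halfwidth, mstar=mstar,
    )


def filter_genes_by_read_count(
    records: Iterable[AnchorRecord], min_reads: float = 5
) -> set[str]:
    """Genes whose total intramolecular read weight reaches ``min_reads``."""
    totals: dict[str, float] = {}
    for r in records:
        totals[r.gene_id] = totals.get(r.gene_id, 0.0) + r.weight
    return {g for g, t in totals.items() if t >= min_reads}
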