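"""Genomic interval I/O and bead-chain annotation.

Maps BED-format annotation tracks (protein-binding sites from accessibility
peaks, open-chromatin intervals from H3K27ac, oriented CTCF/cohesin loop
anchors with occupancy weights) onto a discretized polymer chain at a fixed
number of base pairs per bead (default 1 kbp), and concatemerizes several
locus copies onto one long fiber separated by unmarked spacer chromatin.

Coordinates are 0-based half-open throughout, as in BED.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "BeadAnnotation",
    "CopySpan",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "build_bead_annotation",
    "annotation_flag_to_intervals",
    "concatemerize",
    "CTCF_NONE",
    "CTCF_FORWARD",
    "CTCF_REVERSE",
    "CTCF_BOTH",
]

# CTCF orientation codes (per-bead int8 vector)
CTCF_NONE, CTCF_FORWARD, CTCF_REVERSE, CTCF_BOTH = 0, 1, 2, 3

#: track-name aliases recognized by build_bead_annotation
_TRACK_ALIASES = {
    "binding": "binding",
    "binding_sites": "binding",
    "atac": "binding",
    "open": "open",
    "h3k27ac": "open",
    "ctcf": "ctcf",
    "anchors": "ctcf",
}


class BedParseError(ValueError):
    """Malformed BED input; message carries the offending line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand and score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    name: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.score is not None and self.score < 0:
            raise ValueError("score must be nonnegative")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class CopySpan:
    """Placement record of one locus copy on a concatemerized chain."""

    copy_id: int          # 1-based; 0 denotes spacer beads
    source_index: int     # index into the source-annotation list
    start_bead: int
    n_beads: int

    @property
    def stop_bead(self) -> int:
        return self.start_bead + self.n_beads


@dataclass
class BeadAnnotation:
    """Per-bead classification of the polymer chain.

    Boolean flags mark protein-binding-site beads and open-chromatin beads;
    ``ctcf`` holds orientation codes (0 none / 1 forward / 2 reverse / 3 both)
    with ``stall_weight`` in [0, 1]; ``copy_id`` labels which locus copy each
    bead belongs to (0 = spacer chromatin).
    """

    bead_bp: int
    region: GenomicInterval
    is_binding_site: np.ndarray
    is_open: np.ndarray
    ctcf: np.ndarray
    stall_weight: np.ndarray
    copy_id: np.ndarray
    copies: list[CopySpan] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.is_binding_site = np.asarray(self.is_binding_site, dtype=bool)
        self.is_open = np.asarray(self.is_open, dtype=bool)
        self.ctcf = np.asarray(self.ctcf, dtype=np.int8)
        self.stall_weight = np.asarray(self.stall_weight, dtype=float)
        self.copy_id = np.asarray(self.copy_id, dtype=np.int32)
        n = self.n_beads
        for name in ("is_open", "ctcf", "stall_weight", "copy_id"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"flag vector {name} has wrong length")
        if np.any(self.stall_weight[self.ctcf == CTCF_NONE] != 0.0):
            raise ValueError("stall_weight must be 0 where ctcf is none")
        if np.any((self.stall_weight < 0) | (self.stall_weight > 1)):
            raise ValueError("stall_weight must lie in [0, 1]")
        if not self.copies:
            self.copies = [CopySpan(1, 0, 0, n)]

    @property
    def n_beads(self) -> int:
        return len(self.is_binding_site)

    @classmethod
    def empty(cls, n_beads: int, bead_bp: int = 1000,
              region: GenomicInterval | None = None) -> "BeadAnnotation":
        """All-compact, unmarked chain of ``n_beads`` beads."""
        if region is None:
            region = GenomicInterval("chrU", 0, n_beads * bead_bp)
        return cls(
            bead_bp=bead_bp,
            region=region,
            is_binding_site=np.zeros(n_beads, dtype=bool),
            is_open=np.zeros(n_beads, dtype=bool),
            ctcf=np.zeros(n_beads, dtype=np.int8),
            stall_weight=np.zeros(n_beads, dtype=float),
            copy_id=np.ones(n_beads, dtype=np.int32),
        )

    def copy(self) -> "BeadAnnotation":
        out = BeadAnnotation(
            bead_bp=self.bead_bp,
            region=self.region,
            is_binding_site=self.is_binding_site.copy(),
            is_open=self.is_open.copy(),
            ctcf=self.ctcf.copy(),
            stall_weight=self.stall_weight.copy(),
            copy_id=self.copy_id.copy(),
            copies=[replace(c) for c in self.copies],
        )
        if hasattr(self, "source_regions"):
            out.source_regions = list(self.source_regions)
        return out

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for a in (self.is_binding_site, self.is_open, self.ctcf,
                  self.stall_weight, self.copy_id):
            h.update(np.ascontiguousarray(a).tobytes())
        h.update(f"{self.bead_bp}|{self.region.chrom}:{self.region.start}-"
                 f"{self.region.end}".encode())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# BED / bedGraph I/O
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path, scored: bool = False) -> list[GenomicInterval]:
    """Read a 3–6 column BED file into :class:`GenomicInterval` records.

    Comment, ``track`` and ``browser`` lines are tolerated.  Intervals are
    returned in file order with coordinates preserved 0-based half-open.
    With ``scored=True``, a missing/"." score column is an error.

    Raises
    ------
    BedParseError
        On non-integer coordinates, ``start >= end``, or too few columns;
        the message names the 1-based line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"line {lineno}: non-integer coordinates "
                    f"{fields[1]!r}, {fields[2]!r}") from None
            if start < 0 or start >= end:
                raise BedParseError(
                    f"line {lineno}: invalid interval {chrom}:{start}-{end}")
            name = fields[3] if len(fields) > 3 else "."
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise BedParseError(
                        f"line {lineno}: non-numeric score {fields[4]!r}") from None
                if score < 0:
                    raise BedParseError(f"line {lineno}: negative score {score}")
            elif scored:
                raise BedParseError(f"line {lineno}: score column required")
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in ("+", "-", "."):
                raise BedParseError(f"line {lineno}: invalid strand {strand!r}")
            out.append(GenomicInterval(chrom, start, end, strand, score, name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path,
              track_name: str | None = None,
              source_region: GenomicInterval | None = None) -> None:
    """Write BED6; track line and source-region comment included when given."""
    with open(path, "w") as fh:
        if source_region is not None:
            fh.write(f"# source_region={source_region.chrom}:"
                     f"{source_region.start}-{source_region.end}\n")
        if track_name is not None:
            fh.write(f'track name="{track_name}"\n')
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                     f"{score}\t{iv.strand}\n")


def write_bedgraph(values, region: GenomicInterval, bead_bp: int, path,
                   track_name: str = "observable") -> None:
    """Write a per-bead profile as bedGraph in source-region coordinates.

    NaN beads are skipped.  Runs of equal values are merged into one line.
    """
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"# source_region={region.chrom}:{region.start}-{region.end}\n")
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        i = 0
        n = len(values)
        while i < n:
            if np.isnan(values[i]):
                i += 1
                continue
            j = i + 1
            while j < n and values[j] == values[i]:
                j += 1
            start = region.start + i * bead_bp
            end = min(region.start + j * bead_bp, region.end)
            fh.write(f"{region.chrom}\t{start}\t{end}\t{values[i]:.8g}\n")
            i = j


def read_bedgraph(path) -> tuple[list[GenomicInterval], np.ndarray]:
    """Read a bedGraph file -> (intervals, values array in file order)."""
    intervals: list[GenomicInterval] = []
    vals: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise BedParseError(f"line {lineno}: bedGraph needs 4 columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise BedParseError(f"line {lineno}: malformed bedGraph fields") from None
            if start >= end:
                raise BedParseError(f"line {lineno}: invalid interval")
            intervals.append(GenomicInterval(fields[0], start, end))
            vals.append(value)
    return intervals, np.asarray(vals, dtype=float)


# ---------------------------------------------------------------------------
# bead annotation construction
# ---------------------------------------------------------------------------

def _beads_overlapped(iv: GenomicInterval, region: GenomicInterval,
                      bead_bp: int, n_beads: int) -> tuple[int, int]:
    """Half-open bead-index range overlapped (>= 1 bp) by ``iv``."""
    lo = max(iv.start, region.start)
    hi = min(iv.end, region.start + n_beads * bead_bp)
    if lo >= hi:
        return 0, 0
    first = (lo - region.start) // bead_bp
    last = (hi - 1 - region.start) // bead_bp
    return int(first), int(last) + 1


def build_bead_annotation(region: GenomicInterval,
                          tracks: Mapping[str, Sequence[GenomicInterval]],
                          bead_bp: int = 1000) -> BeadAnnotation:
    """Discretize annotation tracks onto a bead chain.

    A bead is flagged by a track iff the track overlaps the bead's genomic
    interval by at least 1 bp.  Track names are matched case-insensitively
    against the aliases ``atac``/``binding`` (protein-binding sites),
    ``h3k27ac``/``open`` (open chromatin) and ``ctcf``/``anchors`` (loop
    anchors; strand gives orientation, score the occupancy weight normalized
    to [0, 1] by the track maximum, missing scores -> 1.0).

    A trailing partial bead (when ``bead_bp`` does not divide the region
    length) is dropped with a logged warning.
    """
    n_beads = (region.end - region.start) // bead_bp
    if n_beads <= 0:
        raise ValueError("region shorter than one bead")
    if (region.end - region.start) % bead_bp:
        logger.warning(
            "region length %d not a multiple of bead_bp=%d; dropping the "
            "final partial bead", region.end - region.start, bead_bp)

    ann = BeadAnnotation.empty(n_beads, bead_bp=bead_bp, region=region)

    for raw_name, intervals in tracks.items():
        key = _TRACK_ALIASES.get(raw_name.lower())
        if key is None:
            raise ValueError(
                f"unrecognized track name {raw_name!r}; expected an alias of "
                "binding/open/ctcf")
        for iv in intervals:
            if iv.chrom != region.chrom:
                raise ValueError(
                    f"track {raw_name!r} interval on {iv.chrom} does not "
                    f"match region chromosome {region.chrom}")
        if key == "binding":
            for iv in intervals:
                a, b = _beads_overlapped(iv, region, bead_bp, n_beads)
                ann.is_binding_site[a:b] = True
        elif key == "open":
            for iv in intervals:
                a, b = _beads_overlapped(iv, region, bead_bp, n_beads)
                ann.is_open[a:b] = True
        else:  # ctcf
            scores = [iv.score for iv in intervals if iv.score is not None]
            max_score = max(scores) if scores else None
            for iv in intervals:
                a, b = _beads_overlapped(iv, region, bead_bp, n_beads)
                if a == b:
                    continue
                if iv.score is None or not max_score:
                    weight = 1.0
                else:
                    weight = iv.score / max_score
                orient = {"+": CTCF_FORWARD, "-": CTCF_REVERSE,
                          ".": CTCF_BOTH}[iv.strand]
                for i in range(a, b):
                    prev = ann.ctcf[i]
                    if prev == CTCF_NONE or prev == orient:
                        ann.ctcf[i] = orient
                    else:
                        # opposite-strand evidence on one bead -> blocks both ways
                        ann.ctcf[i] = CTCF_BOTH
                    ann.stall_weight[i] = max(ann.stall_weight[i], weight)
    return ann


def annotation_flag_to_intervals(ann: BeadAnnotation, flag: str) -> list[GenomicInterval]:
    """Export one boolean flag as BED intervals (one per maximal run).

    ``flag`` is ``"is_binding_site"``, ``"is_open"`` or ``"ctcf"``; for CTCF
    each maximal run of a single orientation becomes one stranded interval
    carrying the run-maximum stall weight as score.
    """
    region, bp = ann.region, ann.bead_bp
    out: list[GenomicInterval] = []
    if flag in ("is_binding_site", "is_open"):
        vec = getattr(ann, flag)
        i = 0
        while i < ann.n_beads:
            if vec[i]:
                j = i
                while j < ann.n_beads and vec[j]:
                    j += 1
                out.append(GenomicInterval(region.chrom,
                                           region.start + i * bp,
                                           region.start + j * bp))
                i = j
            else:
                i += 1
    elif flag == "ctcf":
        strand_of = {CTCF_FORWARD: "+", CTCF_REVERSE: "-", CTCF_BOTH: "."}
        i = 0
        while i < ann.n_beads:
            code = ann.ctcf[i]
            if code != CTCF_NONE:
                j = i
                while j < ann.n_beads and ann.ctcf[j] == code:
                    j += 1
                out.append(GenomicInterval(
                    region.chrom, region.start + i * bp, region.start + j * bp,
                    strand=strand_of[int(code)],
                    score=float(ann.stall_weight[i:j].max())))
                i = j
            else:
                i += 1
    else:
        raise ValueError(f"unknown flag {flag!r}")
    return out


# ---------------------------------------------------------------------------
# concatemerization
# ---------------------------------------------------------------------------

def concatemerize(annotations: Sequence[BeadAnnotation],
                  n_copies_each: Sequence[int],
                  spacer_beads: int = 1000,
                  order_seed: int = 0) -> BeadAnnotation:
    """Place locus copies along one long fiber, spacers after each copy.

    ``n_copies_each[i]`` copies of ``annotations[i]`` are laid out in a
    seeded random order (so repeat simulations embed each variant in varied
    surrounding context), each followed by ``spacer_beads`` of unmarked
    compact chromatin.  ``copy_id`` numbers the copies 1..n in placement
    order; spacer beads carry ``copy_id`` 0.
    """
    if len(annotations) != len(n_copies_each):
        raise ValueError("annotations and n_copies_each length mismatch")
    if any(c < 0 for c in n_copies_each):
        raise ValueError("copy counts must be nonnegative")
    bead_bp = annotations[0].bead_bp
    for a in annotations:
        if a.bead_bp != bead_bp:
            raise ValueError("all annotations must share bead_bp")

    order = [i for i, c in enumerate(n_copies_each) for _ in range(c)]
    rng = np.random.default_rng(order_seed)
    order = [order[k] for k in rng.permutation(len(order))]

    total = sum(annotations[i].n_beads for i in order) + spacer_beads * len(order)
    region = GenomicInterval("concatemer", 0, total * bead_bp)
    out = BeadAnnotation.empty(total, bead_bp=bead_bp, region=region)
    out.copy_id[:] = 0
    copies: list[CopySpan] = []
    pos = 0
    for copy_id, src in enumerate(order, start=1):
        a = annotations[src]
        n = a.n_beads
        sl = slice(pos, pos + n)
        out.is_binding_site[sl] = a.is_binding_site
        out.is_open[sl] = a.is_open
        out.ctcf[sl] = a.ctcf
        out.stall_weight[sl] = a.stall_weight
        out.copy_id[sl] = copy_id
        copies.append(CopySpan(copy_id, src, pos, n))
        pos += n + spacer_beads
    out.copies = copies
    out.source_regions = [a.region for a in annotations]
    return out
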