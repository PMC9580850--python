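"""Readers for the standard-format reference inputs.

Everything downstream works in 0-based half-open coordinates (the BED
convention).  This module is the only place where other coordinate
conventions (1-based circRNA lists, GTF) are converted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pyfaidx
from Bio import SeqIO
from intervaltree import IntervalTree

from .seq import encode

__all__ = [
    "GenomeReference",
    "CircCoordinate",
    "TranscriptModel",
    "SnpTrack",
    "Transcriptome",
    "load_genome",
    "parse_circ_list",
    "parse_exon_annotation",
    "load_snp_track",
    "load_transcriptome",
]


class GenomeReference:
    """Random-access view of an indexed genome FASTA.

    Wraps :class:`pyfaidx.Fasta`; all returned slices are uppercase and
    bounds-checked against the chromosome length.
    """

    def __init__(self, fasta: pyfaidx.Fasta):
        self._fasta = fasta

    @property
    def chromosomes(self) -> list[str]:
        return list(self._fasta.keys())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta

    def length(self, chrom: str) -> int:
        if chrom not in self._fasta:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return genome[start:end) on *chrom*, uppercase.

        Raises on negative coordinates or ``end`` beyond the chromosome.
        An empty half-open interval returns the empty string.
        """
        n = self.length(chrom)
        if start < 0 or end < start:
            raise ValueError(f"invalid interval [{start}, {end})")
        if end > n:
            raise ValueError(
                f"interval [{start}, {end}) exceeds length {n} of {chrom!r}"
            )
        if start == end:
            return ""
        return str(self._fasta[chrom][start:end])


def load_genome(path: str | Path) -> GenomeReference:
    """Open a genome FASTA with random access (builds/reuses a .fai index)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        fasta = pyfaidx.Fasta(str(path), sequence_always_upper=True)
    except (pyfaidx.FastaIndexingError, ValueError) as exc:
        raise ValueError(f"cannot index FASTA {path}: {exc}") from exc
    if len(fasta.keys()) == 0:
        raise ValueError(f"no sequences found in {path}")
    return GenomeReference(fasta)


@dataclass(frozen=True)
class CircCoordinate:
    """One circRNA back-splice junction, 0-based half-open.

    ``start`` is the acceptor (circle 5' end on the + strand) and
    ``end - 1`` the donor base.  The BSJ joins position ``end - 1``
    back to ``start``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"
    id: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"{self.id or self.chrom}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start


_REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def _parse_region_string(s: str, coordinate_base: int) -> tuple[str, int, int]:
    m = _REGION_RE.match(s.strip())
    if not m:
        raise ValueError(f"cannot parse region string {s!r}")
    start = int(m.group("start")) - (1 if coordinate_base == 1 else 0)
    return m.group("chrom"), start, int(m.group("end"))


def parse_circ_list(
    source: str | Path | Iterable[str],
    coordinate_base: int = 0,
    min_size: int = 30,
) -> list[CircCoordinate]:
    """Parse circRNA coordinates from a BED/TSV file or region strings.

    Accepts a path to a whitespace-delimited file with columns
    ``chrom start end [name] [score] [strand]``, or an iterable of
    ``chr:start-end`` strings.  ``coordinate_base=1`` treats the input
    start as 1-based inclusive (converted by ``start - 1``); the end is
    interpreted identically under both conventions.  Missing ids become
    ``circ_<n>``.
    """
    if coordinate_base not in (0, 1):
        raise ValueError("coordinate_base must be 0 or 1")

    rows: list[tuple[str, int, int, str, str]] = []
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        lines = Path(source).read_text().splitlines()
    elif isinstance(source, (str, Path)):
        raise FileNotFoundError(source)
    else:
        lines = list(source)

    for n, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        if ":" in line and "\t" not in line and " " not in line:
            chrom, start, end = _parse_region_string(line, coordinate_base)
            rows.append((chrom, start, end, "", "+"))
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ValueError(f"line {n}: need at least chrom/start/end: {line!r}")
        try:
            start = int(fields[1]) - (1 if coordinate_base == 1 else 0)
            end = int(fields[2])
        except ValueError as exc:
            raise ValueError(f"line {n}: non-integer coordinates: {line!r}") from exc
        name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "+"
        rows.append((fields[0], start, end, name, strand))

    circs = []
    for i, (chrom, start, end, name, strand) in enumerate(rows, start=1):
        if start >= end:
            raise ValueError(f"circ {name or i}: empty interval [{start}, {end})")
        if end - start < min_size:
            raise ValueError(
                f"circ {name or i}: size {end - start} below minimum {min_size}"
            )
        circs.append(
            CircCoordinate(chrom, start, end, strand, name or f"circ_{i}")
        )
    return circs


@dataclass(frozen=True)
class TranscriptModel:
    """Exon chain of one transcript (0-based half-open, sorted)."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty exon [{s}, {e})")
            if s < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def contains_exonic(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def exonic_positions(self, start: int, end: int) -> list[int]:
        """Genomic positions inside this transcript's exons, restricted
        to [start, end), ascending."""
        out: list[int] = []
        for s, e in self.exons:
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                out.extend(range(lo, hi))
        return out


def parse_exon_annotation(
    path: str | Path,
    allowlist: Optional[Iterable[str]] = None,
) -> list[TranscriptModel]:
    """Parse exon features from a GTF into ranked transcript models.

    Ranking (used later for spliced-template transcript selection):
    allowlisted transcripts first, then longest total exonic length,
    then lexicographic transcript id.
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tids = feat.attributes.get("transcript_id")
        if not tids:
            raise ValueError(f"exon at {feat.seqid}:{feat.start} lacks transcript_id")
        tid = tids[0]
        gid = (feat.attributes.get("gene_id") or [tid])[0]
        rec = grouped.setdefault(
            tid, {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand, "exons": []}
        )
        # GTF is 1-based inclusive; convert to 0-based half-open
        rec["exons"].append((feat.start - 1, feat.end))

    models = []
    for tid, rec in grouped.items():
        exons = tuple(sorted(rec["exons"]))
        models.append(
            TranscriptModel(tid, rec["gene_id"], rec["chrom"],
                            rec["strand"] or "+", exons)
        )

    allowed = set(allowlist) if allowlist is not None else set()
    models.sort(
        key=lambda t: (t.transcript_id not in allowed, -t.exonic_length, t.transcript_id)
    )
    return models


def read_allowlist(path: str | Path) -> set[str]:
    """One transcript id per line; blank lines and # comments ignored."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.add(line.split()[0])
    return ids


class SnpTrack:
    """Positional membership of common-variant intervals (per chromosome)."""

    def __init__(self, entries: Iterable[tuple[str, int, int]] = ()):
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for chrom, start, end in entries:
            if start >= end:
                raise ValueError(f"empty SNP interval {chrom}:{start}-{end}")
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)
            self._n += 1

    def __len__(self) -> int:
        return self._n

    def overlaps(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree.overlaps_point(pos)) if tree is not None else False

    def __contains__(self, key: tuple[str, int]) -> bool:
        return self.overlaps(*key)


def load_snp_track(path: str | Path) -> SnpTrack:
    """Load a BED3+ file of common-variant intervals."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries = []
    for n, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ValueError(f"{path}:{n}: malformed BED row: {line!r}")
        try:
            entries.append((fields[0], int(fields[1]), int(fields[2])))
        except ValueError as exc:
            raise ValueError(f"{path}:{n}: non-integer coordinates") from exc
    return SnpTrack(entries)


class Transcriptome:
    """In-memory transcript sequences — the off-target search space."""

    def __init__(self, records: dict[str, str]):
        self.records = {tid: seq.upper() for tid, seq in records.items()}
        self._encoded: dict[str, np.ndarray] = {}

    @property
    def ids(self) -> list[str]:
        return sorted(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, tid: str) -> str:
        return self.records[tid]

    def encoded(self, tid: str) -> np.ndarray:
        arr = self._encoded.get(tid)
        if arr is None:
            arr = encode(self.records[tid])
            self._encoded[tid] = arr
        return arr


def load_transcriptome(path: str | Path) -> Transcriptome:
    """Load a transcript FASTA; ids are the first header token."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        tid = rec.id
        if tid in records:
            raise ValueError(f"duplicate transcript id {tid!r} in {path}")
        records[tid] = str(rec.seq).upper()
    return Transcriptome(records)
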