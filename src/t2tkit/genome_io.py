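"""Assembly containers, standard-format I/O, gap detection, and read/contig filters.

All coordinates throughout the toolkit are 0-based half-open; interval length
is always ``end - start``. FASTA input is uppercased on read and soft-masking
is ignored. The only permitted sequence alphabet is {A, C, G, T, N}.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_ALPHABET = frozenset("ACGTN")

_INVALID_RE = re.compile(r"[^ACGTN]")


class InvalidAlphabetError(ValueError):
    """A sequence contains a character outside {A, C, G, T, N}."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named chromosome or contig sequence over {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be nonempty")
        m = _INVALID_RE.search(self.seq)
        if m:
            raise InvalidAlphabetError(
                f"record {self.id!r}: invalid character {m.group()!r} "
                f"at position {m.start()}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class GenomeAssembly:
    """An ordered collection of sequence records; order defines report order."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in assembly")
        self._by_id = {r.id: r for r in self.records}

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __getitem__(self, record_id: str) -> SequenceRecord:
        return self._by_id[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id

    def __len__(self) -> int:
        return len(self.records)

    def replace(self, record_id: str, new_seq: str) -> "GenomeAssembly":
        """Return a new assembly with one record's sequence replaced."""
        if record_id not in self._by_id:
            raise KeyError(record_id)
        return GenomeAssembly(
            [
                SequenceRecord(r.id, new_seq) if r.id == record_id else r
                for r in self.records
            ]
        )


@dataclass(frozen=True)
class Feature:
    """A genomic interval (gene, exon, repeat ...) in 0-based half-open coords."""

    chrom: str
    start: int
    end: int
    kind: str = "other"
    strand: str = "."
    attributes: dict = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid feature interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GapRecord:
    """A maximal run of N characters within one record."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReadMeta:
    """Per-read metadata used by the sequencing-platform filter rules.

    Optional fields that are absent make the corresponding filter
    inapplicable: the filter raises rather than silently passing the read.
    """

    id: str
    length: int
    mean_q: float | None = None
    passes: int | None = None
    snr: float | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"read {self.id!r}: length must be positive")


# ---------------------------------------------------------------------------
# Gap detection and assembly statistics
# ---------------------------------------------------------------------------

def find_gaps(assembly: GenomeAssembly, min_len: int = 1) -> list[GapRecord]:
    """Locate every maximal N-run of length >= ``min_len``.

    Returns gaps sorted by (record order, start). Alphabet validity is
    guaranteed by SequenceRecord construction.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    gaps: list[GapRecord] = []
    for rec in assembly.records:
        arr = np.frombuffer(rec.seq.encode("ascii"), dtype=np.uint8)
        is_n = arr == ord("N")
        if not is_n.any():
            continue
        # boundaries of True runs via padded diff
        padded = np.concatenate(([False], is_n, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_len:
                gaps.append(GapRecord(rec.id, int(s), int(e)))
    return gaps


def assembly_stats(assembly: GenomeAssembly, gap_min_len: int = 1) -> dict:
    """Basic contiguity statistics: total length, N50/L50, gap count/bases."""
    if not assembly.records:
        raise ValueError("assembly has no records")
    lengths = sorted((r.length for r in assembly.records), reverse=True)
    total = sum(lengths)
    cum = 0
    n50 = lengths[0]
    l50 = len(lengths)
    for i, ln in enumerate(lengths, start=1):
        cum += ln
        if cum * 2 >= total:
            n50, l50 = ln, i
            break
    gaps = find_gaps(assembly, min_len=gap_min_len)
    return {
        "total_length": total,
        "n_records": len(lengths),
        "N50": n50,
        "L50": l50,
        "gap_count": len(gaps),
        "gap_bases": sum(g.length for g in gaps),
    }


# ---------------------------------------------------------------------------
# Read and contig filters
# ---------------------------------------------------------------------------

def filter_ont_reads(
    reads: Sequence[ReadMeta],
    min_len: int = 30_000,
    min_q: float = 9.0,
    pre_min_len: int = 10_000,
    pre_min_q: float = 7.0,
) -> list[ReadMeta]:
    """Ultra-long read filter: keep reads at least ``min_len`` long with mean
    Q-score strictly above ``min_q``.

    A configurable pre-filter stage (adapter-trimmed length >= ``pre_min_len``
    and mean Q >= ``pre_min_q``) runs first; at the defaults it is subsumed by
    the main thresholds but both stages are independently tunable.
    """
    for r in reads:
        if r.mean_q is None:
            raise ValueError(f"read {r.id!r}: mean_q missing; ONT filter inapplicable")
    staged = [r for r in reads if r.length >= pre_min_len and r.mean_q >= pre_min_q]
    return [r for r in staged if r.length >= min_len and r.mean_q > min_q]


def filter_hifi_reads(
    reads: Sequence[ReadMeta], min_passes: int = 3, min_snr: float = 2.5
) -> list[ReadMeta]:
    """HiFi read filter: keep reads with >= ``min_passes`` subread passes and
    signal-to-noise ratio >= ``min_snr``."""
    for r in reads:
        if r.passes is None or r.snr is None:
            raise ValueError(
                f"read {r.id!r}: passes/snr missing; HiFi filter inapplicable"
            )
    return [r for r in reads if r.passes >= min_passes and r.snr >= min_snr]


def filter_contaminant_contigs(
    contigs: GenomeAssembly,
    organelle_alignments: Iterable,
    frac: float = 0.5,
) -> tuple[GenomeAssembly, GenomeAssembly]:
    """Partition contigs into (kept, excluded) by organelle alignment coverage.

    A contig is excluded iff the union of its aligned intervals against
    organelle references covers strictly more than ``frac`` of its length.
    Overlapping alignments are unioned, never summed. Alignments are any
    objects carrying ``ref_chrom`` (the contig id), ``ref_start``, ``ref_end``.
    """
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for aln in organelle_alignments:
        cid = aln.ref_chrom
        if cid not in contigs:
            raise ValueError(f"alignment references unknown contig {cid!r}")
        clen = contigs[cid].length
        if not (0 <= aln.ref_start < aln.ref_end <= clen):
            raise ValueError(
                f"alignment interval [{aln.ref_start}, {aln.ref_end}) outside "
                f"contig {cid!r} of length {clen}"
            )
        by_contig.setdefault(cid, []).append((aln.ref_start, aln.ref_end))
    kept, excluded = [], []
    for rec in contigs.records:
        covered = union_length(by_contig.get(rec.id, []))
        (excluded if covered > frac * rec.length else kept).append(rec)
    return GenomeAssembly(kept), GenomeAssembly(excluded)


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total bases covered by the union of half-open intervals."""
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted, disjoint list."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


# ---------------------------------------------------------------------------
# Format I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeAssembly:
    """Read a (multi-)FASTA into an assembly, uppercasing sequence."""
    records = [
        SequenceRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeAssembly(records)


def write_fasta(assembly: GenomeAssembly, path: str | Path, width: int = 60) -> None:
    """Write an assembly as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in assembly.records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq_reads(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ sequences as (id, uppercased sequence) pairs."""
    fmt = "fastq" if str(path).endswith((".fastq", ".fq")) else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


def read_bed(path: str | Path, kind: str = "other") -> list[Feature]:
    """Read BED (0-based half-open). Column 4 (name), if present, becomes the
    feature kind; column 6 the strand."""
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            k = parts[3] if len(parts) > 3 and parts[3] != "." else kind
            strand = parts[5] if len(parts) > 5 else "."
            feats.append(Feature(chrom, start, end, kind=k, strand=strand))
    return feats


def write_bed(features: Sequence[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.kind}\t.\t{f.strand}\n")


def read_gff3(path: str | Path) -> list[Feature]:
    """Read GFF3 features; 1-based inclusive coordinates are converted to
    0-based half-open. ``Parent``/``ID`` attributes are preserved."""
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                continue
            chrom, _src, kind, start, end, _score, strand, _phase = parts[:8]
            attrs = {}
            if len(parts) > 8:
                for kv in parts[8].split(";"):
                    if "=" in kv:
                        k, v = kv.split("=", 1)
                        attrs[k.strip()] = v.strip()
            feats.append(
                Feature(
                    chrom,
                    int(start) - 1,
                    int(end),
                    kind=kind,
                    strand=strand if strand in "+-" else ".",
                    attributes=attrs,
                )
            )
    return feats


def write_gff3(features: Sequence[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write(
                f"{f.chrom}\tt2tkit\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def write_gap_report(gaps: Sequence[GapRecord], path: str | Path) -> None:
    """TSV gap report with columns chrom, start, end, length."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tlength\n")
        for g in gaps:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.length}\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
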