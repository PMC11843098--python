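"""k-mer consensus quality (QV) and the consolidated T2T completeness report.

The QV follows the standard k-mer-spectrum definition: with b the fraction
of assembly k-mers (counted per position, N-containing windows excluded)
that are unsupported by the read k-mer set, the per-base error rate is
``1 - (1 - b)**(1/k)`` and QV is its Phred transform ``-10*log10(e)``,
capped when no k-mer is missing. Canonical k-mers make read strand
irrelevant; a minimum read-k-mer count filter absorbs read errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._kmers import encode_kmers
from .genome_io import GapRecord, GenomeAssembly, assembly_stats


@dataclass(frozen=True)
class QVResult:
    scope: str  # "genome" or a chromosome id
    k: int
    assembly_kmers: int
    missing_kmers: int

    @property
    def b(self) -> float:
        return self.missing_kmers / self.assembly_kmers if self.assembly_kmers else 0.0

    @property
    def error_rate(self) -> float:
        return 1.0 - (1.0 - self.b) ** (1.0 / self.k)

    def qv(self, cap: float = 99.0) -> float:
        if self.missing_kmers == 0:
            return cap
        return min(cap, -10.0 * math.log10(self.error_rate))


@dataclass(frozen=True)
class T2TReport:
    n_chromosomes: int
    telomere_count: int
    centromere_count: int
    gap_count: int
    N50: int
    total_length: int
    telomere_matrix: tuple = ()  # (chrom, upstream_count, downstream_count) rows

    def __post_init__(self) -> None:
        if self.telomere_count > 2 * self.n_chromosomes:
            raise ValueError("more telomeres than chromosome ends")


def read_kmer_set(
    reads: Iterable[str] | Iterable[tuple[str, str]], k: int, min_count: int = 1
) -> np.ndarray:
    """Sorted canonical k-mer codes present (>= min_count times) in reads."""
    chunks = []
    for r in reads:
        seq = r[1] if isinstance(r, tuple) else getattr(r, "seq", r)
        codes, _, valid = encode_kmers(seq, k)
        chunks.append(codes[valid])
    if not chunks:
        raise ValueError("no reads supplied")
    allc = np.concatenate(chunks)
    if min_count <= 1:
        return np.unique(allc)
    uniq, counts = np.unique(allc, return_counts=True)
    return uniq[counts >= min_count]


def kmer_qv(
    assembly: GenomeAssembly,
    reads: Iterable,
    k: int = 21,
    qv_cap: float = 99.0,
    min_count: int = 1,
) -> tuple[QVResult, list[QVResult]]:
    """Genome-wide and per-chromosome QV from a read k-mer spectrum.

    Assembly k-mers are a per-position multiset; reads contribute a presence
    set. Returns (genome result, per-chromosome results); Phred values come
    from ``QVResult.qv(qv_cap)``.
    """
    if k % 2 == 0 or not (11 <= k <= 31):
        raise ValueError("k must be odd and within 11..31")
    for rec in assembly.records:
        if rec.length < k:
            raise ValueError(f"record {rec.id!r} shorter than k={k}")
    read_set = read_kmer_set(reads, k, min_count=min_count)
    per_chrom = []
    total = missing_total = 0
    for rec in assembly.records:
        codes, _, valid = encode_kmers(rec.seq, k)
        codes = codes[valid]
        present = np.zeros(len(codes), dtype=bool)
        if len(read_set):
            idx = np.searchsorted(read_set, codes)
            idx[idx == len(read_set)] = len(read_set) - 1
            present = read_set[idx] == codes
        missing = int(len(codes) - present.sum())
        per_chrom.append(QVResult(rec.id, k, len(codes), missing))
        total += len(codes)
        missing_total += missing
    genome = QVResult("genome", k, total, missing_total)
    return genome, per_chrom


def t2t_report(
    assembly: GenomeAssembly,
    telomere_calls: Sequence,
    centromere_candidates: Sequence,
    gap_records: Sequence[GapRecord],
) -> T2TReport:
    """Aggregate telomere, centromere and gap evidence into one report."""
    if not assembly.records:
        raise ValueError("empty assembly")
    for c in telomere_calls:
        if c.chrom not in assembly:
            raise ValueError(f"telomere call on unknown chromosome {c.chrom!r}")
    for c in centromere_candidates:
        if c is not None and c.chrom not in assembly:
            raise ValueError(f"centromere candidate on unknown chromosome {c.chrom!r}")
    for g in gap_records:
        if g.chrom not in assembly:
            raise ValueError(f"gap on unknown chromosome {g.chrom!r}")
    stats = assembly_stats(assembly)
    by_chrom: dict[str, dict[str, int]] = {}
    for c in telomere_calls:
        by_chrom.setdefault(c.chrom, {})[c.end] = c.repeat_count if c.present else 0
    matrix = tuple(
        (rec.id,
         by_chrom.get(rec.id, {}).get("5prime", 0),
         by_chrom.get(rec.id, {}).get("3prime", 0))
        for rec in assembly.records
    )
    return T2TReport(
        n_chromosomes=len(assembly.records),
        telomere_count=sum(1 for c in telomere_calls if c.present),
        centromere_count=sum(1 for c in centromere_candidates if c is not None),
        gap_count=len(gap_records),
        N50=stats["N50"],
        total_length=stats["total_length"],
        telomere_matrix=matrix,
    )


def percent(numerator: float, denominator: float, digits: int = 2) -> float:
    """Percentage helper used in completeness/annotation summaries."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round(100.0 * numerator / denominator, digits)


def tally(counts: dict[str, int] | Sequence[int]) -> int:
    """Sum of class counts (e.g. ncRNA classes into their total)."""
    values = counts.values() if isinstance(counts, dict) else counts
    return sum(values)


def write_qv_tsv(genome: QVResult, per_chrom: Sequence[QVResult], path,
                 qv_cap: float = 99.0) -> None:
    with open(path, "w") as fh:
        fh.write("scope\tassembly_kmers\tmissing_kmers\tqv\n")
        for r in [genome, *per_chrom]:
            fh.write(
                f"{r.scope}\t{r.assembly_kmers}\t{r.missing_kmers}\t"
                f"{r.qv(qv_cap):.2f}\n"
            )
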