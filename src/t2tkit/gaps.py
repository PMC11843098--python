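"""Gap catalog and priority-ranked gap filling.

Gaps are maximal N-runs (see :func:`t2tkit.genome_io.find_gaps`). Candidate
fill sequences are ranked by source hierarchy — error-corrected genome
version first, then HiFi reads, then ONT ultra-long reads — and among equal
sources by the longest aligned span and then identity. A candidate fills a
gap only when it spans it, i.e. aligns across both flank anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from typing import Sequence

from .genome_io import GapRecord, GenomeAssembly, find_gaps

SOURCE_PRIORITY = {"corrected_genome": 0, "hifi": 1, "ont": 2}


@dataclass(frozen=True)
class FillCandidate:
    """A sequence competing to fill one gap.

    ``fill_start``/``fill_end`` are coordinates on the candidate sequence
    delimiting the segment that replaces the N-run (set by
    :func:`anchor_candidate`); they bound the left-flank-anchor end and the
    right-flank-anchor start.
    """

    id: str
    source: str
    seq: str
    spans_gap: bool = False
    aligned_length: int = 0
    identity: float = 1.0
    fill_start: int | None = None
    fill_end: int | None = None

    def __post_init__(self) -> None:
        if self.source not in SOURCE_PRIORITY:
            raise ValueError(
                f"unknown source {self.source!r}; expected one of "
                f"{sorted(SOURCE_PRIORITY)}"
            )
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must lie in [0, 1]")


@dataclass(frozen=True)
class FillResult:
    gap: GapRecord
    chosen: str | None
    filled_length: int
    remaining_N: int
    length_delta: int = 0  # filled_length - gap.length when the estimate differed


def rank_fill_candidates(
    candidates: Sequence[FillCandidate], min_identity: float = 0.0
) -> list[FillCandidate]:
    """Order spanning candidates by (source priority, aligned length desc,
    identity desc, id asc). Non-spanning candidates are dropped; an optional
    identity floor can exclude poor alignments."""
    spanning = [
        c for c in candidates if c.spans_gap and c.identity >= min_identity
    ]
    return sorted(
        spanning,
        key=lambda c: (
            SOURCE_PRIORITY[c.source],
            -c.aligned_length,
            -c.identity,
            c.id,
        ),
    )


def anchor_candidate(
    assembly: GenomeAssembly,
    gap: GapRecord,
    candidate: FillCandidate,
    flank: int = 1_000,
) -> FillCandidate:
    """Locate a candidate's fill segment by exact flank-anchor matching.

    The ``flank`` bases immediately left and right of the N-run must occur,
    in order, within the candidate sequence; the segment between the anchor
    matches becomes the fill. Returns an updated candidate with
    ``spans_gap``, ``aligned_length`` and fill coordinates set.
    """
    chrom = assembly[gap.chrom]
    left = chrom.seq[max(0, gap.start - flank) : gap.start]
    right = chrom.seq[gap.end : gap.end + flank]
    if not left or not right:
        return _dc_replace(candidate, spans_gap=False)
    li = candidate.seq.find(left)
    if li < 0:
        return _dc_replace(candidate, spans_gap=False)
    ri = candidate.seq.find(right, li + len(left))
    if ri < 0:
        return _dc_replace(candidate, spans_gap=False)
    return _dc_replace(
        candidate,
        spans_gap=True,
        aligned_length=(ri + len(right)) - li,
        fill_start=li + len(left),
        fill_end=ri,
    )


def fill_gap(
    assembly: GenomeAssembly,
    gap: GapRecord,
    candidate: FillCandidate | None,
) -> tuple[GenomeAssembly, FillResult]:
    """Replace one N-run with a candidate's fill segment.

    With no candidate the assembly is returned unchanged and the gap remains
    entirely N. When the candidate's implied fill length differs from the
    N-run length, the candidate wins (gap sizes are estimates) and the delta
    is recorded.
    """
    if candidate is None:
        return assembly, FillResult(gap, None, 0, gap.length)
    if not candidate.spans_gap or candidate.fill_start is None:
        raise ValueError(f"candidate {candidate.id!r} does not span the gap")
    fill_seq = candidate.seq[candidate.fill_start : candidate.fill_end]
    chrom = assembly[gap.chrom]
    new_seq = chrom.seq[: gap.start] + fill_seq + chrom.seq[gap.end :]
    result = FillResult(
        gap,
        candidate.id,
        len(fill_seq),
        fill_seq.count("N"),  # a candidate may itself carry unresolved bases
        length_delta=len(fill_seq) - gap.length,
    )
    return assembly.replace(gap.chrom, new_seq), result


def fill_all_gaps(
    assembly: GenomeAssembly,
    candidates_by_gap: dict[tuple[str, int, int], list[FillCandidate]],
    min_len: int = 1,
    flank: int = 1_000,
    min_identity: float = 0.0,
) -> tuple[GenomeAssembly, list[FillResult]]:
    """Catalog gaps and fill each with its best-ranked anchored candidate.

    Gaps are processed per chromosome right-to-left so earlier fills do not
    shift later gap coordinates. ``candidates_by_gap`` maps
    (chrom, start, end) of the original gap catalog to candidate lists.
    """
    results: list[FillResult] = []
    gaps = find_gaps(assembly, min_len=min_len)
    for gap in sorted(gaps, key=lambda g: (g.chrom, -g.start)):
        cands = [
            anchor_candidate(assembly, gap, c, flank=flank)
            for c in candidates_by_gap.get((gap.chrom, gap.start, gap.end), [])
        ]
        ranked = rank_fill_candidates(cands, min_identity=min_identity)
        assembly, res = fill_gap(assembly, gap, ranked[0] if ranked else None)
        results.append(res)
    results.sort(key=lambda r: (r.gap.chrom, r.gap.start))
    return assembly, results


def scaffold_join(
    contigs: Sequence, spacer_n: int = 100, record_id: str = "scaffold"
):
    """Concatenate contigs into one record with ``spacer_n`` Ns between
    neighbours (the standard placeholder for unsized joins)."""
    from .genome_io import SequenceRecord

    seqs = [c.seq if hasattr(c, "seq") else c for c in contigs]
    if not seqs:
        raise ValueError("no contigs to join")
    return SequenceRecord(record_id, ("N" * spacer_n).join(seqs))


def split_on_gaps(record, min_len: int = 1) -> list[str]:
    """Inverse of scaffold_join: contig sequences between maximal N-runs."""
    asm = GenomeAssembly([record])
    gaps = find_gaps(asm, min_len=min_len)
    pieces, pos = [], 0
    for g in gaps:
        if g.start > pos:
            pieces.append(record.seq[pos : g.start])
        pos = g.end
    if pos < record.length:
        pieces.append(record.seq[pos:])
    return pieces


def write_fill_results(results: Sequence[FillResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tgap_length\tchosen\tfilled_length\tremaining_N\tlength_delta\n")
        for r in results:
            fh.write(
                f"{r.gap.chrom}\t{r.gap.start}\t{r.gap.end}\t{r.gap.length}\t"
                f"{r.chosen or '.'}\t{r.filled_length}\t{r.remaining_N}\t{r.length_delta}\n"
            )
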