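"""Two-assembly comparison: syntenic blocks, small variants, SVs and PAVs.

The desk-scale aligner chains unique exact 21-mer anchors into colinear
blocks per (ref chromosome, qry chromosome, strand), bridges same-diagonal
neighbouring blocks across anchor deserts (satellite arrays, telomere
arrays, N-runs) after verifying the intervening sequence identity, and
computes base-level alignments within blocks on demand with edlib.

Variant classes follow the usual assembly-comparison taxonomy:

* SNP — single-base substitution inside a block.
* INS/DEL — insertions/deletions; the 2–50 bp class is the reported indel
  range, 1-bp events are tallied separately, and longer events surface as
  uncovered regions (PAV) or rearranged blocks (SV).
* INV — a reverse-strand block embedded in a forward context.
* TRANS — a block breaking reference colinearity or changing chromosome.
* DUP — a reference region aligning to two or more disjoint query loci.
* PAV — maximal regions of either assembly uncovered by any block
  (presence: query-only; absence: reference-only), N-runs excluded.

Genic context (exon > intron > upstream2k > downstream2k > intergenic) is
assigned at each record's reference midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from typing import Iterable, Sequence

import edlib
import numpy as np
from intervaltree import IntervalTree

from ._kmers import CodeIndex, encode_kmers, match_sorted
from .genome_io import (
    Feature,
    GenomeAssembly,
    find_gaps,
    merge_intervals,
    reverse_complement,
    union_length,
)


@dataclass
class AlignmentBlock:
    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    strand: str  # + or -
    identity: float = 1.0
    unique: bool = True
    n_anchors: int = 0
    # anchor positions retained for chunked base-level alignment
    anchors: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end or self.qry_start >= self.qry_end:
            raise ValueError("alignment block intervals must be nonempty")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def ref_length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class VariantRecord:
    kind: str  # SNP | INS | DEL
    ref_chrom: str
    ref_pos: int
    length: int
    ref_allele: str
    alt_allele: str
    context: str | None = None


@dataclass(frozen=True)
class SVRecord:
    kind: str  # INV | TRANS | DUP
    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    context: str | None = None

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def length_bin(self) -> str:
        return sv_length_bin(self.length)


@dataclass(frozen=True)
class PAVRecord:
    kind: str  # presence | absence
    chrom: str  # on the carrying assembly (qry for presence, ref for absence)
    start: int
    end: int
    context: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Anchor-based whole-genome alignment (desk scale)
# ---------------------------------------------------------------------------

def _genome_kmers(assembly: GenomeAssembly, k: int):
    codes, fwd, valid, chrom_ids, offsets = [], [], [], [], {}
    gpos0 = 0
    for ci, rec in enumerate(assembly.records):
        c, f, v = encode_kmers(rec.seq, k)
        codes.append(c)
        fwd.append(f)
        valid.append(v)
        chrom_ids.append(np.full(len(c), ci, dtype=np.int32))
        offsets[ci] = gpos0
        gpos0 += len(c)
    return (
        np.concatenate(codes) if codes else np.zeros(0, np.int64),
        np.concatenate(fwd) if fwd else np.zeros(0, bool),
        np.concatenate(valid) if valid else np.zeros(0, bool),
        np.concatenate(chrom_ids) if chrom_ids else np.zeros(0, np.int32),
        offsets,
    )


def _chains_to_blocks(
    ref_chrom: str,
    qry_chrom: str,
    strand: str,
    rpos: np.ndarray,
    qpos: np.ndarray,
    k: int,
    max_anchor_gap: int,
    diag_tol: int,
    min_anchors: int,
    unique: bool,
    sort_by_diag: bool,
) -> list[AlignmentBlock]:
    if len(rpos) == 0:
        return []
    diag = qpos - rpos if strand == "+" else qpos + rpos
    if sort_by_diag:
        order = np.lexsort((rpos, diag))
    else:
        order = np.argsort(rpos, kind="stable")
    rpos, qpos, diag = rpos[order], qpos[order], diag[order]
    dr = np.diff(rpos)
    dq = np.diff(qpos)
    dd = np.abs(np.diff(diag))
    colinear = dq > 0 if strand == "+" else dq < 0
    split = (np.abs(dr) > max_anchor_gap) | (dd > diag_tol) | ~colinear
    chain_id = np.concatenate(([0], np.cumsum(split)))
    blocks = []
    boundaries = np.concatenate(
        ([0], np.flatnonzero(np.diff(chain_id)) + 1, [len(rpos)])
    )
    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        if b1 - b0 < min_anchors:
            continue
        r = rpos[b0:b1]
        q = qpos[b0:b1]
        rs, re = int(r.min()), int(r.max()) + k
        qs, qe = int(q.min()), int(q.max()) + k
        blocks.append(
            AlignmentBlock(
                ref_chrom, rs, re, qry_chrom, qs, qe, strand,
                unique=unique,
                n_anchors=int(b1 - b0),
                anchors=np.column_stack([r, q]),
            )
        )
    return blocks


def _seg_identity(a: str, b: str) -> float:
    if not a and not b:
        return 1.0
    res = edlib.align(a, b, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def _bridge_blocks(
    blocks: list[AlignmentBlock],
    ref: GenomeAssembly,
    qry: GenomeAssembly,
    bridge_min_identity: float,
    k: int,
) -> list[AlignmentBlock]:
    """Merge consecutive same-diagonal forward blocks across anchor deserts,
    and extend the outermost blocks to the chromosome termini when the
    overhanging tails correspond."""
    out: list[AlignmentBlock] = []
    by_pair: dict[tuple[str, str], list[AlignmentBlock]] = {}
    for b in blocks:
        if b.unique and b.strand == "+":
            by_pair.setdefault((b.ref_chrom, b.qry_chrom), []).append(b)
        else:
            out.append(b)
    for (rc, qc), group in by_pair.items():
        group.sort(key=lambda b: b.ref_start)
        merged = [group[0]]
        for nxt in group[1:]:
            prev = merged[-1]
            gr = nxt.ref_start - prev.ref_end
            gq = nxt.qry_start - prev.qry_end
            slack = max(100, int(0.02 * max(abs(gr), abs(gq))))
            ok = -k <= gr and -k <= gq and abs(gr - gq) <= slack
            if ok and gr > 0 and gq > 0:
                rseg = ref[rc].seq[prev.ref_end : nxt.ref_start]
                qseg = qry[qc].seq[prev.qry_end : nxt.qry_start]
                ok = _seg_identity(qseg, rseg) >= bridge_min_identity
            if ok:
                merged[-1] = AlignmentBlock(
                    rc, prev.ref_start, nxt.ref_end, qc, prev.qry_start,
                    nxt.qry_end, "+",
                    unique=True,
                    n_anchors=prev.n_anchors + nxt.n_anchors,
                    anchors=np.concatenate([prev.anchors, nxt.anchors])
                    if prev.anchors is not None and nxt.anchors is not None
                    else None,
                )
            else:
                merged.append(nxt)
        # terminal extension: only the outermost block on each side
        first = min(merged, key=lambda b: b.ref_start)
        if first.ref_start > 0 or first.qry_start > 0:
            hr, hq = first.ref_start, first.qry_start
            slack = max(100, int(0.02 * max(hr, hq)))
            if abs(hr - hq) <= slack and _seg_identity(
                qry[qc].seq[:hq], ref[rc].seq[:hr]
            ) >= bridge_min_identity:
                i = merged.index(first)
                merged[i] = _dc_replace(first, ref_start=0, qry_start=0)
        last = max(merged, key=lambda b: b.ref_end)
        rlen, qlen = ref[rc].length, qry[qc].length
        tr, tq = rlen - last.ref_end, qlen - last.qry_end
        if tr > 0 or tq > 0:
            slack = max(100, int(0.02 * max(tr, tq)))
            if abs(tr - tq) <= slack and _seg_identity(
                qry[qc].seq[last.qry_end :], ref[rc].seq[last.ref_end :]
            ) >= bridge_min_identity:
                i = merged.index(last)
                merged[i] = _dc_replace(last, ref_end=rlen, qry_end=qlen)
        out.extend(merged)
    return out


def align_small_genomes(
    ref: GenomeAssembly,
    qry: GenomeAssembly,
    anchor_k: int = 21,
    max_anchor_gap: int = 1_000,
    diag_tol: int = 100,
    min_anchors: int = 3,
    dup_max_copies: int = 4,
    bridge_min_identity: float = 0.8,
    compute_identity: bool = True,
    anchor_stride: int = 8,
) -> list[AlignmentBlock]:
    """Chain unique exact k-mer anchors into colinear alignment blocks.

    A primary pass uses k-mers unique in both assemblies (``unique=True``
    blocks). A secondary pass uses k-mers unique in the reference but with
    2..``dup_max_copies`` occurrences in the query (and vice versa), so that
    duplicated sequence — invisible to mutually-unique anchoring — still
    produces (non-unique) blocks for duplication calling and PAV masking.
    """
    k = anchor_k
    r_codes, r_fwd, r_valid, r_chrom, r_off = _genome_kmers(ref, k)
    q_codes, q_fwd, q_valid, q_chrom, q_off = _genome_kmers(qry, k)

    r_index = CodeIndex(r_codes, r_valid)
    q_index = CodeIndex(q_codes, q_valid)
    ru_codes, ru_gpos = r_index.select(1, 1)
    qu_codes, qu_gpos = q_index.select(1, 1)

    blocks: list[AlignmentBlock] = []

    def _emit(anchor_r, anchor_q, unique, sort_by_diag, dtol):
        """Group anchors by (ref chrom, qry chrom, strand) and chain them."""
        if len(anchor_r) == 0:
            return
        strands = np.where(r_fwd[anchor_r] == q_fwd[anchor_q], 0, 1)
        rc_ids = r_chrom[anchor_r]
        qc_ids = q_chrom[anchor_q]
        key = np.lexsort((anchor_r, strands, qc_ids, rc_ids))
        ar, aq, st = anchor_r[key], anchor_q[key], strands[key]
        rc, qc = rc_ids[key], qc_ids[key]
        group_break = np.concatenate(
            ([True], (np.diff(rc) != 0) | (np.diff(qc) != 0) | (np.diff(st) != 0))
        )
        bounds = np.concatenate(
            (np.flatnonzero(group_break), [len(ar)])
        )
        for g0, g1 in zip(bounds[:-1], bounds[1:]):
            rci, qci, sti = int(rc[g0]), int(qc[g0]), int(st[g0])
            rpos = (ar[g0:g1] - r_off[rci]).astype(np.int64)
            qpos = (aq[g0:g1] - q_off[qci]).astype(np.int64)
            blocks.extend(
                _chains_to_blocks(
                    ref.records[rci].id,
                    qry.records[qci].id,
                    "+" if sti == 0 else "-",
                    rpos,
                    qpos,
                    k,
                    max_anchor_gap,
                    dtol,
                    min_anchors,
                    unique,
                    sort_by_diag,
                )
            )

    # primary: mutually unique anchors (thinned when dense; chains keep the
    # same breakpoints because planted-feature anchor deserts are far wider
    # than the thinned spacing)
    ri, qi = match_sorted(ru_codes, qu_codes)
    if anchor_stride > 1 and len(ri) > 500_000:
        ri, qi = ri[::anchor_stride], qi[::anchor_stride]
    _emit(ru_gpos[ri], qu_gpos[qi], True, False, diag_tol)

    # secondary: ref-unique k-mers with 2..cap query copies (duplications in
    # the query), and the symmetric direction
    if dup_max_copies >= 2:
        qm_codes, qm_gpos = q_index.select(2, dup_max_copies)
        ai, bi = match_sorted(qm_codes, ru_codes)
        if len(ai):
            _emit(ru_gpos[bi], qm_gpos[ai], False, True, 5)
        rm_codes, rm_gpos = r_index.select(2, dup_max_copies)
        ai, bi = match_sorted(rm_codes, qu_codes)
        if len(ai):
            _emit(rm_gpos[ai], qu_gpos[bi], False, True, 5)

    blocks = _bridge_blocks(blocks, ref, qry, bridge_min_identity, k)
    if compute_identity:
        for i, b in enumerate(blocks):
            qseg = qry[b.qry_chrom].seq[b.qry_start : b.qry_end]
            if b.strand == "-":
                qseg = reverse_complement(qseg)
            blocks[i] = _dc_replace(
                b,
                identity=_seg_identity(
                    qseg, ref[b.ref_chrom].seq[b.ref_start : b.ref_end]
                ),
            )
    blocks.sort(key=lambda b: (b.ref_chrom, b.ref_start, b.qry_chrom, b.qry_start))
    return blocks


# ---------------------------------------------------------------------------
# Small-variant calling within blocks
# ---------------------------------------------------------------------------

def normalize_indel(ref_seq: str, kind: str, pos: int, allele: str) -> tuple[int, str]:
    """Left-align an indel against the reference sequence.

    For DEL, ``allele`` is the deleted reference segment starting at ``pos``;
    for INS, the inserted segment placed before ``pos``. Returns the
    canonical leftmost (pos, allele)."""
    L = len(allele)
    if kind == "DEL":
        while pos > 0 and ref_seq[pos - 1] == ref_seq[pos + L - 1]:
            pos -= 1
        return pos, ref_seq[pos : pos + L]
    if kind == "INS":
        while pos > 0 and ref_seq[pos - 1] == allele[-1]:
            allele = ref_seq[pos - 1] + allele[:-1]
            pos -= 1
        return pos, allele
    raise ValueError(f"not an indel kind: {kind}")


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


_REFINE_SEP = 30  # events closer than this (ref bp) are realigned together
_REFINE_PAD = 30  # matching context kept on each side of a realigned window


def _affine_aligner():
    from Bio import Align

    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -2
    a.open_gap_score = -4
    a.extend_gap_score = -0.5
    return a


_AFFINE = _affine_aligner()


def _affine_events(t_win: str, q_win: str) -> list[tuple[str, int, int, int]]:
    """(op, t_off, q_off, n) events from an affine-gap global alignment.

    Edit-distance (unit-cost) alignments may split one indel into equal-cost
    pieces separated by chance single-base matches; a gap-open penalty makes
    the contiguous representation strictly preferred, which is what variant
    comparison needs.
    """
    aln = _AFFINE.align(t_win, q_win)[0]
    coords = aln.coordinates
    events: list[tuple[str, int, int, int]] = []
    for i in range(coords.shape[1] - 1):
        t0, t1 = int(coords[0, i]), int(coords[0, i + 1])
        q0, q1 = int(coords[1, i]), int(coords[1, i + 1])
        if t1 > t0 and q1 > q0:  # aligned run: scan for mismatch runs
            j = 0
            while j < t1 - t0:
                if t_win[t0 + j] != q_win[q0 + j]:
                    j0 = j
                    while j < t1 - t0 and t_win[t0 + j] != q_win[q0 + j]:
                        j += 1
                    events.append(("X", t0 + j0, q0 + j0, j - j0))
                else:
                    j += 1
        elif t1 > t0:
            events.append(("D", t0, q0, t1 - t0))
        elif q1 > q0:
            events.append(("I", t0, q0, q1 - q0))
    return events


def _event_t_end(ev: tuple[str, int, int, int]) -> int:
    op, t_off, _q, n = ev
    return t_off + (n if op in "XD" else 0)


def _event_q_end(ev: tuple[str, int, int, int]) -> int:
    op, _t, q_off, n = ev
    return q_off + (n if op in "XI" else 0)


def refined_edit_events(
    t_seg: str, q_seg: str
) -> list[tuple[str, int, int, int]]:
    """Edit events (op, t_off, q_off, n) between two near-identical segments.

    edlib provides the fast global alignment; clusters of nearby events are
    then locally realigned with affine gap scoring, so each indel comes out
    as one contiguous event and substitutions are never represented as
    equal-cost insertion/deletion pairs.
    """
    res = edlib.align(q_seg, t_seg, mode="NW", task="path")
    raw: list[tuple[str, int, int, int]] = []  # (op, t_off, q_off, n)
    rpos = qpos = 0
    for n, op in _cigar_ops(res["cigar"]):
        if op == "=":
            rpos += n
            qpos += n
        elif op == "X":
            raw.append(("X", rpos, qpos, n))
            rpos += n
            qpos += n
        elif op == "I":
            raw.append(("I", rpos, qpos, n))
            qpos += n
        elif op == "D":
            raw.append(("D", rpos, qpos, n))
            rpos += n

    clusters: list[list[tuple[str, int, int, int]]] = []
    for ev in raw:
        if clusters and ev[1] - _event_t_end(clusters[-1][-1]) <= _REFINE_SEP:
            clusters[-1].append(ev)
        else:
            clusters.append([ev])

    out: list[tuple[str, int, int, int]] = []
    for cluster in clusters:
        if len(cluster) > 1:
            pad_l = min(_REFINE_PAD, cluster[0][1], cluster[0][2])
            t0 = cluster[0][1] - pad_l
            q0 = cluster[0][2] - pad_l
            t_end = _event_t_end(cluster[-1])
            q_end = _event_q_end(cluster[-1])
            pad_r = min(_REFINE_PAD, len(t_seg) - t_end, len(q_seg) - q_end)
            out.extend(
                (op, t0 + dt, q0 + dq, n)
                for op, dt, dq, n in _affine_events(
                    t_seg[t0 : t_end + pad_r], q_seg[q0 : q_end + pad_r]
                )
            )
        else:
            out.extend(cluster)
    return out


def _variants_from_alignment(
    ref_chrom: str, ref_seq: str, rs: int, t_seg: str, q_seg: str
) -> list[VariantRecord]:
    """Align q_seg to t_seg (= ref_seq[rs:...]) and emit variant records in
    reference coordinates, indels left-normalized."""
    out: list[VariantRecord] = []
    for op, t_off, q_off, n in refined_edit_events(t_seg, q_seg):
        if op == "X":
            for i in range(n):
                out.append(
                    VariantRecord(
                        "SNP", ref_chrom, rs + t_off + i, 1,
                        ref_seq[rs + t_off + i], q_seg[q_off + i],
                    )
                )
        elif op == "I":
            pos, allele = normalize_indel(
                ref_seq, "INS", rs + t_off, q_seg[q_off : q_off + n]
            )
            out.append(VariantRecord("INS", ref_chrom, pos, n, "", allele))
        elif op == "D":
            pos, allele = normalize_indel(
                ref_seq, "DEL", rs + t_off, ref_seq[rs + t_off : rs + t_off + n]
            )
            out.append(VariantRecord("DEL", ref_chrom, pos, n, allele, ""))
    return out


def call_small_variants(
    blocks: Sequence[AlignmentBlock],
    ref: GenomeAssembly,
    qry: GenomeAssembly,
    indel_min: int = 2,
    indel_max: int = 50,
    chunk: int = 500_000,
) -> list[VariantRecord]:
    """Base-level variant calls within unique alignment blocks.

    All SNPs and indels are returned; callers and summaries report the
    ``indel_min``..``indel_max`` class, 1-bp events separately, and treat
    longer events as structural. Large forward blocks are aligned in chunks
    cut at anchor positions (exact-match cut points), which bounds edlib
    memory without changing the result.
    """
    variants: list[VariantRecord] = []
    for b in blocks:
        if not b.unique:
            continue
        if b.ref_chrom not in ref or b.qry_chrom not in qry:
            raise ValueError(
                f"block references missing sequence {b.ref_chrom}/{b.qry_chrom}"
            )
        ref_seq = ref[b.ref_chrom].seq
        qry_seq = qry[b.qry_chrom].seq
        if b.strand == "-":
            q_seg = reverse_complement(qry_seq[b.qry_start : b.qry_end])
            variants.extend(
                _variants_from_alignment(
                    b.ref_chrom, ref_seq, b.ref_start,
                    ref_seq[b.ref_start : b.ref_end], q_seg,
                )
            )
            continue
        # forward blocks: cut at anchors nearest chunk boundaries
        cuts = [(b.ref_start, b.qry_start)]
        if b.ref_length > chunk and b.anchors is not None and len(b.anchors):
            anchors = b.anchors[np.argsort(b.anchors[:, 0])]
            target = b.ref_start + chunk
            for r_a, q_a in anchors:
                if r_a >= target and r_a > cuts[-1][0] and q_a > cuts[-1][1]:
                    cuts.append((int(r_a), int(q_a)))
                    target = r_a + chunk
        cuts.append((b.ref_end, b.qry_end))
        for (r0, q0), (r1, q1) in zip(cuts[:-1], cuts[1:]):
            variants.extend(
                _variants_from_alignment(
                    b.ref_chrom, ref_seq, r0, ref_seq[r0:r1], qry_seq[q0:q1]
                )
            )
    variants.sort(key=lambda v: (v.ref_chrom, v.ref_pos, v.kind))
    return variants


# ---------------------------------------------------------------------------
# Structural variants, PAV
# ---------------------------------------------------------------------------

def _weighted_lis(values: list[int], weights: list[int]) -> set[int]:
    """Indices forming the maximum-weight strictly increasing subsequence."""
    n = len(values)
    best = list(weights)
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if values[j] < values[i] and best[j] + weights[i] > best[i]:
                best[i] = best[j] + weights[i]
                prev[i] = j
    if not n:
        return set()
    i = max(range(n), key=lambda x: best[x])
    keep = set()
    while i != -1:
        keep.add(i)
        i = prev[i]
    return keep


def detect_svs(
    blocks: Sequence[AlignmentBlock], sv_min: int = 50
) -> list[SVRecord]:
    """Classify rearranged blocks as inversions, translocations, duplications.

    Per reference chromosome the dominant query partner and a maximum-weight
    colinear backbone (weighted longest increasing subsequence over query
    position) are established from unique forward blocks. Reverse-strand
    unique blocks on the dominant partner are inversions; unique blocks off
    the backbone or on another partner are translocations. Reference regions
    covered by two or more non-unique blocks with disjoint query partner
    loci are duplications.
    """
    svs: list[SVRecord] = []
    by_ref: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_ref.setdefault(b.ref_chrom, []).append(b)
    for rc, group in by_ref.items():
        uniq = [b for b in group if b.unique]
        fwd = [b for b in uniq if b.strand == "+"]
        partner_bases: dict[str, int] = {}
        for b in fwd:
            partner_bases[b.qry_chrom] = partner_bases.get(b.qry_chrom, 0) + b.ref_length
        primary = max(partner_bases, key=partner_bases.get) if partner_bases else None

        backbone_pool = sorted(
            (b for b in fwd if b.qry_chrom == primary), key=lambda b: b.ref_start
        )
        keep = _weighted_lis(
            [b.qry_start for b in backbone_pool],
            [b.ref_length for b in backbone_pool],
        )
        for i, b in enumerate(backbone_pool):
            if i not in keep and b.ref_length >= sv_min:
                svs.append(
                    SVRecord("TRANS", rc, b.ref_start, b.ref_end,
                             b.qry_chrom, b.qry_start, b.qry_end)
                )
        for b in fwd:
            if b.qry_chrom != primary and b.ref_length >= sv_min:
                svs.append(
                    SVRecord("TRANS", rc, b.ref_start, b.ref_end,
                             b.qry_chrom, b.qry_start, b.qry_end)
                )
        for b in uniq:
            if b.strand == "-" and b.ref_length >= sv_min:
                svs.append(
                    SVRecord("INV", rc, b.ref_start, b.ref_end,
                             b.qry_chrom, b.qry_start, b.qry_end)
                )

        # duplications from non-unique blocks: cluster on ref overlap
        dup_blocks = sorted(
            (b for b in group if not b.unique), key=lambda b: b.ref_start
        )
        cluster: list[AlignmentBlock] = []

        def _flush(cluster):
            if not cluster:
                return
            loci: list[tuple[str, int, int]] = []
            for b in sorted(cluster, key=lambda b: (b.qry_chrom, b.qry_start)):
                redundant = False
                for qc, qs, qe in loci:
                    if qc == b.qry_chrom:
                        ov = min(qe, b.qry_end) - max(qs, b.qry_start)
                        if ov > 0.5 * min(qe - qs, b.qry_end - b.qry_start):
                            redundant = True
                            break
                if not redundant:
                    loci.append((b.qry_chrom, b.qry_start, b.qry_end))
            rs = min(b.ref_start for b in cluster)
            re_ = max(b.ref_end for b in cluster)
            if len(loci) >= 2 and re_ - rs >= sv_min:
                qc, qs, qe = loci[0]
                svs.append(SVRecord("DUP", rc, rs, re_, qc, qs, qe))

        cur_end = -1
        for b in dup_blocks:
            if cluster and b.ref_start >= cur_end:
                _flush(cluster)
                cluster = []
                cur_end = -1
            cluster.append(b)
            cur_end = max(cur_end, b.ref_end)
        _flush(cluster)
    svs.sort(key=lambda s: (s.ref_chrom, s.ref_start))
    return svs


def _uncovered(
    assembly: GenomeAssembly, covered: dict[str, list[tuple[int, int]]],
    pav_min: int,
) -> list[tuple[str, int, int]]:
    out = []
    gaps = find_gaps(assembly, min_len=1)
    gap_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in gaps:
        gap_by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    for rec in assembly.records:
        mask = merge_intervals(
            covered.get(rec.id, []) + gap_by_chrom.get(rec.id, [])
        )
        pos = 0
        for s, e in mask:
            if s - pos >= pav_min:
                out.append((rec.id, pos, s))
            pos = max(pos, e)
        if rec.length - pos >= pav_min:
            out.append((rec.id, pos, rec.length))
    return out


def detect_pav(
    blocks: Sequence[AlignmentBlock],
    ref: GenomeAssembly,
    qry: GenomeAssembly,
    pav_min: int = 50,
) -> list[PAVRecord]:
    """Presence/absence variation from alignment coverage.

    Maximal reference regions uncovered by any block (and not N) of length
    >= ``pav_min`` are absence variants (sequence absent from the query);
    uncovered query regions are presence variants (query-only sequence).
    """
    ref_cov: dict[str, list[tuple[int, int]]] = {}
    qry_cov: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        ref_cov.setdefault(b.ref_chrom, []).append((b.ref_start, b.ref_end))
        qry_cov.setdefault(b.qry_chrom, []).append((b.qry_start, b.qry_end))
    pavs = [
        PAVRecord("absence", c, s, e)
        for c, s, e in _uncovered(ref, ref_cov, pav_min)
    ]
    pavs += [
        PAVRecord("presence", c, s, e)
        for c, s, e in _uncovered(qry, qry_cov, pav_min)
    ]
    return pavs


# ---------------------------------------------------------------------------
# Genic context, bins, summary
# ---------------------------------------------------------------------------

CONTEXT_PRECEDENCE = ("exon", "intron", "upstream2k", "downstream2k", "intergenic")


def build_context_index(
    genes: Sequence[Feature], flank: int = 2_000
) -> dict[str, dict[str, IntervalTree]]:
    """Interval trees per chromosome for exon/intron/upstream/downstream.

    ``genes`` is a flat feature list: kind 'gene' features (with strand and
    an ``ID`` attribute) and kind 'exon' children carrying ``Parent``. An
    exon outside its parent gene raises."""
    gene_by_id = {
        f.attributes.get("ID", f"{f.chrom}:{f.start}"): f
        for f in genes
        if f.kind == "gene"
    }
    idx: dict[str, dict[str, IntervalTree]] = {}

    def tree(chrom, cat):
        return idx.setdefault(chrom, {}).setdefault(cat, IntervalTree())

    for f in genes:
        if f.kind != "exon":
            continue
        parent = f.attributes.get("Parent")
        g = gene_by_id.get(parent)
        if g is None or f.start < g.start or f.end > g.end or f.chrom != g.chrom:
            raise ValueError(
                f"exon [{f.start},{f.end}) outside its gene ({parent})"
            )
        tree(f.chrom, "exon")[f.start : f.end] = True
    for g in gene_by_id.values():
        tree(g.chrom, "intron")[g.start : g.end] = True  # minus exon via precedence
        if g.strand == "-":
            up = (g.end, g.end + flank)
            down = (max(0, g.start - flank), g.start)
        else:
            up = (max(0, g.start - flank), g.start)
            down = (g.end, g.end + flank)
        if up[0] < up[1]:
            tree(g.chrom, "upstream2k")[up[0] : up[1]] = True
        if down[0] < down[1]:
            tree(g.chrom, "downstream2k")[down[0] : down[1]] = True
    return idx


def context_label(
    index: dict[str, dict[str, IntervalTree]], chrom: str, point: int
) -> str:
    cats = index.get(chrom, {})
    for cat in ("exon", "intron", "upstream2k", "downstream2k"):
        t = cats.get(cat)
        if t is not None and t.overlaps(point):
            return cat
    return "intergenic"


def assign_context(records: Sequence, genes: Sequence[Feature], flank: int = 2_000):
    """Return records with their genic context label set.

    The label is evaluated at each record's reference midpoint with
    precedence exon > intron > upstream2k > downstream2k > intergenic.
    Records are any of the variant/SV/PAV dataclasses; presence PAVs (which
    live on the query assembly) are labelled against the same coordinate
    system only if the caller passes query-side genes.
    """
    index = build_context_index(genes, flank=flank)
    out = []
    for r in records:
        if isinstance(r, VariantRecord):
            chrom, mid = r.ref_chrom, r.ref_pos + max(r.length, 1) // 2
        elif isinstance(r, SVRecord):
            chrom, mid = r.ref_chrom, (r.ref_start + r.ref_end) // 2
        else:
            chrom, mid = r.chrom, (r.start + r.end) // 2
        out.append(_dc_replace(r, context=context_label(index, chrom, mid)))
    return out


SV_BIN_EDGES = [50, 1000] + list(range(2000, 9001, 1000))


def sv_length_bin(length: int) -> str:
    """Histogram bin label for an SV length: 50-1000, 1001-2000, ...,
    8001-9000, >9000."""
    if length < 50:
        raise ValueError(f"SV length {length} below the 50-bp minimum")
    if length <= 1000:
        return "50-1000"
    for hi in range(2000, 9001, 1000):
        if length <= hi:
            return f"{hi - 999}-{hi}"
    return ">9000"


def bin_sv_lengths(svs: Sequence[SVRecord]) -> dict[str, int]:
    """SV length histogram over the standard bins (every SV in exactly one)."""
    labels = (
        ["50-1000"]
        + [f"{hi - 999}-{hi}" for hi in range(2000, 9001, 1000)]
        + [">9000"]
    )
    hist = {lab: 0 for lab in labels}
    for sv in svs:
        hist[sv_length_bin(sv.length)] += 1
    return hist


def summarize_comparison(
    variants: Sequence[VariantRecord],
    svs: Sequence[SVRecord],
    pavs: Sequence[PAVRecord],
    blocks: Sequence[AlignmentBlock],
    indel_min: int = 2,
    indel_max: int = 50,
) -> dict:
    """Per-class totals and syntenic-base tallies.

    SNP gene/intergenic follows the two-way convention: exon or intron
    context counts as gene region, everything else as intergenic.
    """
    n_snp = sum(1 for v in variants if v.kind == "SNP")
    snp_gene = sum(
        1 for v in variants if v.kind == "SNP" and v.context in ("exon", "intron")
    )
    n_ins = sum(
        1
        for v in variants
        if v.kind == "INS" and indel_min <= v.length <= indel_max
    )
    n_del = sum(
        1
        for v in variants
        if v.kind == "DEL" and indel_min <= v.length <= indel_max
    )
    n_1bp = sum(1 for v in variants if v.kind in ("INS", "DEL") and v.length < indel_min)
    n_large = sum(1 for v in variants if v.kind in ("INS", "DEL") and v.length > indel_max)
    n_inv = sum(1 for s in svs if s.kind == "INV")
    n_trans = sum(1 for s in svs if s.kind == "TRANS")
    n_dup = sum(1 for s in svs if s.kind == "DUP")
    ref_iv: dict[str, list[tuple[int, int]]] = {}
    qry_iv: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        ref_iv.setdefault(b.ref_chrom, []).append((b.ref_start, b.ref_end))
        qry_iv.setdefault(b.qry_chrom, []).append((b.qry_start, b.qry_end))
    return {
        "n_snp": n_snp,
        "snp_gene": snp_gene,
        "snp_intergenic": n_snp - snp_gene,
        "n_ins": n_ins,
        "n_del": n_del,
        "indel_total": n_ins + n_del,
        "indel_1bp": n_1bp,
        "indel_gt_max": n_large,
        "n_inv": n_inv,
        "n_trans": n_trans,
        "n_dup": n_dup,
        "sv_total": n_inv + n_trans + n_dup,
        "n_presence": sum(1 for p in pavs if p.kind == "presence"),
        "n_absence": sum(1 for p in pavs if p.kind == "absence"),
        "pav_total": len(pavs),
        "syntenic_ref_bases": sum(union_length(v) for v in ref_iv.values()),
        "syntenic_qry_bases": sum(union_length(v) for v in qry_iv.values()),
    }


# ---------------------------------------------------------------------------
# Block / variant I/O
# ---------------------------------------------------------------------------

def write_blocks_tsv(blocks: Sequence[AlignmentBlock], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "ref_chrom\tref_start\tref_end\tqry_chrom\tqry_start\tqry_end\t"
            "strand\tidentity\tunique\n"
        )
        for b in blocks:
            fh.write(
                f"{b.ref_chrom}\t{b.ref_start}\t{b.ref_end}\t{b.qry_chrom}\t"
                f"{b.qry_start}\t{b.qry_end}\t{b.strand}\t{b.identity:.6f}\t"
                f"{int(b.unique)}\n"
            )


def read_blocks_tsv(path) -> list[AlignmentBlock]:
    blocks = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            p = line.rstrip("\n").split("\t")
            blocks.append(
                AlignmentBlock(
                    p[0], int(p[1]), int(p[2]), p[3], int(p[4]), int(p[5]),
                    p[6], float(p[7]), bool(int(p[8])),
                )
            )
    return blocks


def read_paf(path) -> list[AlignmentBlock]:
    """Minimal PAF reader: target columns become the reference side; a
    ``tp:A:P`` tag (or its absence) marks the block unique/primary."""
    blocks = []
    with open(path) as fh:
        for line in fh:
            p = line.rstrip("\n").split("\t")
            if len(p) < 12:
                continue
            unique = True
            for tag in p[12:]:
                if tag.startswith("tp:A:"):
                    unique = tag[5] == "P"
            nmatch, alnlen = int(p[9]), int(p[10])
            blocks.append(
                AlignmentBlock(
                    ref_chrom=p[5], ref_start=int(p[7]), ref_end=int(p[8]),
                    qry_chrom=p[0], qry_start=int(p[2]), qry_end=int(p[3]),
                    strand=p[4],
                    identity=nmatch / alnlen if alnlen else 0.0,
                    unique=unique,
                )
            )
    return blocks


def write_vcf(
    variants: Sequence[VariantRecord], ref: GenomeAssembly, path
) -> None:
    """Minimal VCF 4.2 for SNPs and indels (anchor-base representation)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for rec in ref.records:
            fh.write(f"##contig=<ID={rec.id},length={rec.length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            seq = ref[v.ref_chrom].seq
            if v.kind == "SNP":
                pos, r, a = v.ref_pos + 1, v.ref_allele, v.alt_allele
            elif v.kind == "DEL":
                p = v.ref_pos
                anchor = seq[p - 1] if p > 0 else seq[p + v.length]
                if p > 0:
                    pos, r, a = p, anchor + v.ref_allele, anchor
                else:
                    pos, r, a = 1, v.ref_allele + anchor, anchor
            else:  # INS
                p = v.ref_pos
                anchor = seq[p - 1] if p > 0 else (seq[0] if seq else "N")
                if p > 0:
                    pos, r, a = p, anchor, anchor + v.alt_allele
                else:
                    pos, r, a = 1, anchor, v.alt_allele + anchor
            info = f"TYPE={v.kind};LEN={v.length}"
            if v.context:
                info += f";CONTEXT={v.context}"
            fh.write(f"{v.ref_chrom}\t{pos}\t.\t{r}\t{a}\t.\tPASS\t{info}\n")


def write_sv_tsv(svs: Sequence[SVRecord], pavs: Sequence[PAVRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tchrom\tstart\tend\tlength\tcontext\tbin\n")
        for s in svs:
            fh.write(
                f"{s.kind}\t{s.ref_chrom}\t{s.ref_start}\t{s.ref_end}\t"
                f"{s.length}\t{s.context or '.'}\t{s.length_bin}\n"
            )
        for p in pavs:
            fh.write(
                f"{p.kind}\t{p.chrom}\t{p.start}\t{p.end}\t{p.length}\t"
                f"{p.context or '.'}\t.\n"
            )
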