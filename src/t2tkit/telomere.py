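"""Telomere identification and terminal-patch decisions.

Plant telomeres are tandem arrays of a 7-bp minisatellite, TTTAGGG on the
G-rich (3') strand and its reverse complement CCCTAAA on the C-rich (5')
strand. The toolkit counts motif copies in chromosome-terminal windows to
call telomeres, selects a reference read among terminal-anchored long reads,
builds a simple majority-vote consensus, and decides whether a consensus
sequence may replace a chromosome terminus (identity >= 80% and alignment
within 20 kb of the end).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib

from .genome_io import GenomeAssembly, SequenceRecord, reverse_complement

FIVE_PRIME = "5prime"
THREE_PRIME = "3prime"


@dataclass(frozen=True)
class TelomereMotif:
    """The telomeric repeat unit pair. ``forward`` is the G-rich strand motif
    expected at the 3' end; ``reverse`` (its reverse complement) at the 5' end."""

    forward: str = "TTTAGGG"
    reverse: str = "CCCTAAA"

    def __post_init__(self) -> None:
        if not self.forward:
            raise ValueError("motif must be nonempty")
        if reverse_complement(self.forward) != self.reverse:
            raise ValueError(
                f"reverse motif {self.reverse!r} is not the reverse complement "
                f"of {self.forward!r}"
            )

    @property
    def period(self) -> int:
        return len(self.forward)


@dataclass(frozen=True)
class TelomereCall:
    """Motif-repeat evidence at one chromosome end."""

    chrom: str
    end: str  # FIVE_PRIME or THREE_PRIME
    repeat_count: int
    present: bool
    array_interval: tuple[int, int] | None = None


@dataclass(frozen=True)
class PatchDecision:
    accept: bool
    identity: float | None
    distance_to_end: int | None
    reason: str  # ok | low_identity | too_far | no_alignment


def count_motif_repeats(seq: str, motif: str) -> int:
    """Non-overlapping, greedy left-to-right count of exact motif copies.

    Only the supplied orientation is counted; callers pass the forward or the
    reverse motif as appropriate. N never matches any motif position (exact
    matching guarantees this).
    """
    if not motif:
        raise ValueError("motif must be nonempty")
    return seq.count(motif)


def count_motif_both(seq: str, motif: TelomereMotif) -> int:
    """Motif copies in both orientations summed (read-orientation agnostic)."""
    return count_motif_repeats(seq, motif.forward) + count_motif_repeats(
        seq, motif.reverse
    )


def motif_array_interval(seq: str, motif: str) -> tuple[int, int] | None:
    """Span from the first to the last motif occurrence, or None."""
    first = seq.find(motif)
    if first < 0:
        return None
    last = seq.rfind(motif)
    return first, last + len(motif)


def call_chromosome_telomeres(
    assembly: GenomeAssembly,
    motif: TelomereMotif = TelomereMotif(),
    terminal_window: int = 20_000,
    min_repeats: int = 10,
) -> list[TelomereCall]:
    """Scan both termini of every chromosome for telomeric repeat arrays.

    The first ``terminal_window`` bases are scanned with the reverse (C-rich)
    motif and the last ``terminal_window`` with the forward motif. A call is
    marked present when at least ``min_repeats`` copies are found. Exactly two
    calls are emitted per chromosome.
    """
    shortest = min(r.length for r in assembly.records)
    if terminal_window > shortest:
        raise ValueError(
            f"terminal_window {terminal_window} exceeds shortest chromosome "
            f"({shortest} bp)"
        )
    calls = []
    for rec in assembly.records:
        head = rec.seq[:terminal_window]
        tail = rec.seq[-terminal_window:]
        n5 = count_motif_repeats(head, motif.reverse)
        n3 = count_motif_repeats(tail, motif.forward)
        iv5 = motif_array_interval(head, motif.reverse)
        iv3 = motif_array_interval(tail, motif.forward)
        if iv3 is not None:
            off = rec.length - terminal_window
            iv3 = (iv3[0] + off, iv3[1] + off)
        calls.append(
            TelomereCall(rec.id, FIVE_PRIME, n5, n5 >= min_repeats, iv5)
        )
        calls.append(
            TelomereCall(rec.id, THREE_PRIME, n3, n3 >= min_repeats, iv3)
        )
    return calls


def telomere_count(calls: Iterable[TelomereCall]) -> int:
    """Number of chromosome ends with a present telomere call."""
    return sum(1 for c in calls if c.present)


def collect_terminal_reads(
    read_alignments: Iterable,
    assembly: GenomeAssembly,
    screen_window: int = 50,
    unique_only: bool = True,
) -> dict[tuple[str, str], list[str]]:
    """Collect read ids anchored at chromosome termini.

    ``read_alignments`` are objects with ``read_id``, ``chrom``, ``start``,
    ``end``, ``n_alignments``. A read is collected for the 5' end of a
    chromosome when its alignment start lies within ``screen_window`` bases of
    position 0, and for the 3' end when its alignment end lies within
    ``screen_window`` of the chromosome length. With ``unique_only`` a read
    must align to exactly one location.
    """
    out: dict[tuple[str, str], list[str]] = {
        (rec.id, end): [] for rec in assembly.records for end in (FIVE_PRIME, THREE_PRIME)
    }
    for aln in read_alignments:
        if aln.chrom not in assembly:
            continue
        if unique_only and getattr(aln, "n_alignments", 1) != 1:
            continue
        clen = assembly[aln.chrom].length
        if aln.start <= screen_window:
            out[(aln.chrom, FIVE_PRIME)].append(aln.read_id)
        if clen - aln.end <= screen_window:
            out[(aln.chrom, THREE_PRIME)].append(aln.read_id)
    return out


def select_reference_read(
    reads: Sequence[tuple[str, str]], motif: TelomereMotif = TelomereMotif()
) -> tuple[str, list[str]]:
    """Pick the read with the most telomere motif copies (both orientations).

    Ties break to the longer read, then the lexicographically smaller id.
    Returns (reference id, query ids in input order).
    """
    if not reads:
        raise ValueError("no reads supplied")
    best_id, best_seq = reads[0]
    best_key = (count_motif_both(best_seq, motif), len(best_seq))
    for rid, seq in reads[1:]:
        key = (count_motif_both(seq, motif), len(seq))
        if key > best_key or (key == best_key and rid < best_id):
            best_id, best_key = rid, key
    return best_id, [rid for rid, _ in reads if rid != best_id]


def decide_terminal_patch(
    consensus_alignment: dict | None,
    chrom_length: int,
    end: str,
    identity_threshold: float = 0.80,
    max_dist: int = 20_000,
) -> PatchDecision:
    """Decide whether a consensus sequence may replace a chromosome terminus.

    ``consensus_alignment`` carries ``identity`` (fraction) and
    ``aligned_ref_interval`` (0-based half-open on the chromosome). The patch
    is accepted only when identity >= ``identity_threshold`` and the
    alignment's near-terminus boundary lies within ``max_dist`` bases of the
    relevant chromosome end.
    """
    if consensus_alignment is None:
        return PatchDecision(False, None, None, "no_alignment")
    identity = consensus_alignment["identity"]
    s, e = consensus_alignment["aligned_ref_interval"]
    if not (0 <= s < e <= chrom_length):
        raise ValueError("aligned interval outside chromosome")
    dist = s if end == FIVE_PRIME else chrom_length - e
    if identity < identity_threshold:
        return PatchDecision(False, identity, dist, "low_identity")
    if dist > max_dist:
        return PatchDecision(False, identity, dist, "too_far")
    return PatchDecision(True, identity, dist, "ok")


def apply_terminal_patch(
    assembly: GenomeAssembly,
    chrom: str,
    end: str,
    consensus_seq: str,
    consensus_alignment: dict,
    decision: PatchDecision,
) -> GenomeAssembly:
    """Replace a chromosome terminus with the consensus-derived sequence.

    For the 5' end, the chromosome prefix up to the alignment's inner ref
    boundary is replaced by the consensus prefix up to the corresponding
    consensus coordinate; symmetric for the 3' end. All other records are
    untouched.
    """
    if not decision.accept:
        raise ValueError("cannot apply a rejected patch decision")
    rs, re_ = consensus_alignment["aligned_ref_interval"]
    qs, qe = consensus_alignment["aligned_qry_interval"]
    old = assembly[chrom].seq
    if end == FIVE_PRIME:
        new = consensus_seq[:qe] + old[re_:]
    elif end == THREE_PRIME:
        new = old[:rs] + consensus_seq[qs:]
    else:
        raise ValueError(f"unknown end {end!r}")
    return assembly.replace(chrom, new)


def align_consensus_to_terminus(
    consensus_seq: str,
    chrom_seq: str,
    end: str,
    probe_len: int = 2_000,
    max_scan: int = 40_000,
) -> dict | None:
    """Locate a consensus sequence against one chromosome terminus.

    The consensus usually extends past the assembled end, so this is an
    overlap problem: terminal probes of the chromosome (length ``probe_len``,
    at offsets 0, probe_len, 2*probe_len ... up to ``max_scan``) are
    infix-aligned within the consensus, and the best-identity hit is
    returned as ``identity``, ``aligned_ref_interval`` (chromosome coords)
    and ``aligned_qry_interval`` (consensus coords). None if no probe aligns
    at all. The ref interval's distance from the terminus feeds the patch
    decision rule.
    """
    L = len(chrom_seq)
    probe_len = min(probe_len, L)
    best = None
    for off in range(0, min(max_scan, L - probe_len + 1), probe_len):
        if end == FIVE_PRIME:
            probe = chrom_seq[off : off + probe_len]
            ref_iv = (off, off + probe_len)
        else:
            probe = chrom_seq[L - off - probe_len : L - off]
            ref_iv = (L - off - probe_len, L - off)
        res = edlib.align(probe, consensus_seq, mode="HW", task="locations")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        qs, qe = res["locations"][0]
        identity = 1.0 - res["editDistance"] / probe_len
        if best is None or identity > best["identity"]:
            best = {
                "identity": identity,
                "aligned_ref_interval": ref_iv,
                "aligned_qry_interval": (qs, qe + 1),
            }
        if best["identity"] >= 0.99:
            break
    return best


def naive_consensus(queries: Sequence[str], ref: str) -> str:
    """Per-position majority-vote consensus of query reads against a reference.

    Each query is infix-located on the reference with edlib, then the
    covered window is realigned with the toolkit's refined event model
    (affine-gap local realignment, so substitutions are never expressed as
    indel pairs). Aligned query bases vote at their reference position;
    deletions abstain and insertions are ignored. Positions with no query
    coverage, and ties, keep the reference base. Deterministic.
    """
    from .compare import refined_edit_events

    if not ref:
        raise ValueError("reference must be nonempty")
    import numpy as np

    agree = np.zeros(len(ref), dtype=np.int32)  # votes matching the ref base
    alt_votes: dict[int, dict[str, int]] = {}
    for q in queries:
        res = edlib.align(q, ref, mode="HW", task="locations")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        w0, w1 = res["locations"][0]
        w1 += 1
        agree[w0:w1] += 1
        for op, t_off, q_off, n in refined_edit_events(ref[w0:w1], q):
            if op == "X":
                for i in range(n):
                    p = w0 + t_off + i
                    agree[p] -= 1
                    d = alt_votes.setdefault(p, {})
                    b = q[q_off + i]
                    d[b] = d.get(b, 0) + 1
            elif op == "D":  # ref bases unmatched by this query: abstain
                agree[w0 + t_off : w0 + t_off + n] -= 1
    out = list(ref)
    for p, d in alt_votes.items():
        best_b, best_n = out[p], int(agree[p])
        for b in sorted(d):
            if d[b] > best_n:
                best_b, best_n = b, d[b]
        out[p] = best_b
    return "".join(out)


def write_telomere_table(
    calls: Sequence[TelomereCall], path, chrom_order: Sequence[str] | None = None
) -> None:
    """TSV with one row per chromosome: upstream (5') and downstream (3')
    motif-repeat counts; zero where no telomere was called."""
    by = {}
    for c in calls:
        by.setdefault(c.chrom, {})[c.end] = c
    order = chrom_order or list(by)
    with open(path, "w") as fh:
        fh.write("chrom\tupstream_count\tdownstream_count\n")
        for chrom in order:
            d = by.get(chrom, {})
            up = d.get(FIVE_PRIME)
            dn = d.get(THREE_PRIME)
            fh.write(
                f"{chrom}\t{up.repeat_count if up and up.present else 0}"
                f"\t{dn.repeat_count if dn and dn.present else 0}\n"
            )
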