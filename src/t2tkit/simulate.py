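"""Deterministic synthetic genome, derived assembly, and read simulation.

The generator emulates the architecture of a small plant genome at desk
scale: each chromosome carries a 5' telomere array (CCCTAAA copies), a gene-
and LTR-bearing arm, a centromeric satellite array (171-bp monomer tandem
repeat with mild divergence, Gypsy-enriched), a second arm, and a 3'
telomere array (TTTAGGG copies). N-run gaps can be planted, and a derived
("previous version") assembly can be produced by applying SNPs, 2-50 bp
indels, inversions, translocations, tandem duplications and
presence/absence segments at recorded coordinates. Everything planted is
returned as an exact truth set so every detection module can be scored.

Each operation draws from its own pseudo-random stream keyed by
(seed, operation), so adding one stage never perturbs another's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from typing import Sequence

import numpy as np

from .compare import VariantRecord, normalize_indel
from .genome_io import Feature, GapRecord, GenomeAssembly, SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# per-operation RNG stream keys
_STREAM_GENOME = 101
_STREAM_MUTATE = 102
_STREAM_READS = 103


@dataclass(frozen=True)
class SimConfig:
    n_chromosomes: int = 4
    chrom_length: int = 2_000_000
    # telomeres: per-end copy counts drawn from copy_range; listed ends dropped
    telomere_copy_range: tuple[int, int] = (158, 612)
    dropped_ends: tuple[tuple[int, str], ...] = ()  # (chrom index, "5prime"/"3prime")
    telomere_forward: str = "TTTAGGG"
    telomere_reverse: str = "CCCTAAA"
    # centromere satellite
    monomer_length: int = 171
    array_length: int = 200_000
    position_fraction: float = 0.45
    monomer_divergence: float = 0.01
    # annotation layers
    gene_density: float = 100.0  # genes per Mb, arms only
    gene_length_range: tuple[int, int] = (1_000, 6_000)
    exons_per_gene: int = 5
    ltr_gypsy_inside: float = 0.30  # target coverage fraction inside centromere
    ltr_gypsy_outside: float = 0.03
    ltr_copia: float = 0.03
    # N-run gaps: (chrom index, position fraction, length)
    gap_spec: tuple[tuple[int, float, int], ...] = ()
    # derived-assembly variant spec
    snp_rate: float = 6e-5
    indel_rate: float = 2.5e-5
    indel_length_range: tuple[int, int] = (2, 50)
    sv_list: tuple[tuple[str, int], ...] = (
        ("INV", 5_000),
        ("INV", 3_000),
        ("TRANS", 20_000),
        ("DUP", 3_000),
        ("DUP", 1_500),
    )
    pav_list: tuple[tuple[str, int], ...] = (
        ("presence", 2_000),
        ("absence", 1_500),
        ("presence", 800),
        ("absence", 3_000),
    )
    seed: int = 0


@dataclass(frozen=True)
class TruthSV:
    kind: str  # INV | TRANS | DUP
    ref_chrom: str
    ref_start: int
    ref_end: int

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class TruthPAV:
    kind: str  # presence | absence
    chrom: str  # ref chromosome for absence, qry chromosome for presence
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthSet:
    telomeres: dict = field(default_factory=dict)  # (chrom, end) -> copy count
    centromeres: dict = field(default_factory=dict)  # chrom -> (start, end)
    features: list = field(default_factory=list)  # genes/exons/LTRs/TRF
    gaps: list = field(default_factory=list)  # GapRecord
    ungapped: GenomeAssembly | None = None  # genome before N-masking
    variants: list = field(default_factory=list)  # VariantRecord (SNP/INS/DEL)
    svs: list = field(default_factory=list)  # TruthSV
    pavs: list = field(default_factory=list)  # TruthPAV


@dataclass(frozen=True)
class SimRead:
    id: str
    seq: str
    chrom: str
    start: int
    end: int
    strand: str


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _substitute(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode("ascii")


class _ZoneAllocator:
    """Non-overlapping placement of intervals within allowed zones."""

    def __init__(self, rng: np.random.Generator, zones: list[tuple[int, int]]):
        self.rng = rng
        self.free = sorted(zones)

    def take(self, length: int, buffer: int = 150) -> int | None:
        """Reserve a ``length`` interval plus buffer; returns its start."""
        need = length + 2 * buffer
        candidates = [i for i, (s, e) in enumerate(self.free) if e - s >= need]
        if not candidates:
            return None
        weights = np.array(
            [self.free[i][1] - self.free[i][0] - need + 1 for i in candidates],
            dtype=float,
        )
        pick = candidates[
            int(self.rng.choice(len(candidates), p=weights / weights.sum()))
        ]
        s, e = self.free[pick]
        start = int(self.rng.integers(s + buffer, e - length - buffer + 1))
        self.free[pick : pick + 1] = [
            iv
            for iv in [(s, start - buffer), (start + length + buffer, e)]
            if iv[1] - iv[0] > 0
        ]
        self.free.sort()
        return start


def simulate_genome(config: SimConfig) -> tuple[GenomeAssembly, TruthSet]:
    """Build the reference-role genome and its truth set."""
    rng = np.random.default_rng([config.seed, _STREAM_GENOME])
    truth = TruthSet()
    records = []
    tel_f, tel_r = config.telomere_forward, config.telomere_reverse
    for ci in range(config.n_chromosomes):
        chrom = f"Chr{ci + 1}"
        lo, hi = config.telomere_copy_range
        c5 = 0 if (ci, "5prime") in config.dropped_ends else int(
            rng.integers(lo, hi + 1)
        )
        c3 = 0 if (ci, "3prime") in config.dropped_ends else int(
            rng.integers(lo, hi + 1)
        )
        tel5 = tel_r * c5
        tel3 = tel_f * c3
        cen_start = int(config.position_fraction * config.chrom_length)
        cen_end = cen_start + config.array_length
        arm1_len = cen_start - len(tel5)
        arm2_len = config.chrom_length - cen_end - len(tel3)
        if arm1_len <= 0 or arm2_len <= 0:
            raise ValueError(
                f"{chrom}: telomere/centromere layout exceeds chromosome length"
            )
        monomer = _random_dna(rng, config.monomer_length)
        n_copies = -(-config.array_length // config.monomer_length)
        satellite = (monomer * n_copies)[: config.array_length]
        satellite = _substitute(rng, satellite, config.monomer_divergence)
        arm1 = _random_dna(rng, arm1_len)
        arm2 = _random_dna(rng, arm2_len)
        seq = tel5 + arm1 + satellite + arm2 + tel3
        assert len(seq) == config.chrom_length
        records.append(SequenceRecord(chrom, seq))
        truth.telomeres[(chrom, "5prime")] = c5
        truth.telomeres[(chrom, "3prime")] = c3
        truth.centromeres[chrom] = (cen_start, cen_end)
        truth.features.append(Feature(chrom, cen_start, cen_end, kind="TRF"))
        arm_zones = [
            (len(tel5), cen_start),
            (cen_end, config.chrom_length - len(tel3)),
        ]
        _plant_genes(rng, config, chrom, arm_zones, truth)
        _plant_ltrs(rng, config, chrom, (cen_start, cen_end), arm_zones, truth)

    assembly = GenomeAssembly(records)
    truth.ungapped = assembly

    # N-run gaps, kept clear of telomere and satellite intervals
    if config.gap_spec:
        new_records = list(assembly.records)
        for ci, frac, length in config.gap_spec:
            chrom = f"Chr{ci + 1}"
            rec = new_records[ci]
            start = int(frac * rec.length)
            end = start + length
            cen = truth.centromeres[chrom]
            tel5_len = truth.telomeres[(chrom, "5prime")] * len(tel_r)
            tel3_len = truth.telomeres[(chrom, "3prime")] * len(tel_f)
            if (
                end > rec.length - tel3_len
                or start < tel5_len
                or (start < cen[1] and end > cen[0])
            ):
                raise ValueError(
                    f"gap [{start},{end}) on {chrom} collides with telomere "
                    "or satellite array"
                )
            new_records[ci] = SequenceRecord(
                chrom, rec.seq[:start] + "N" * length + rec.seq[end:]
            )
            truth.gaps.append(GapRecord(chrom, start, end))
        assembly = GenomeAssembly(new_records)
    return assembly, truth


def _plant_genes(rng, config: SimConfig, chrom, arm_zones, truth) -> None:
    alloc = _ZoneAllocator(rng, arm_zones)
    gi = 0
    for zs, ze in arm_zones:
        n = int(round(config.gene_density * (ze - zs) / 1e6))
        for _ in range(n):
            glen = int(rng.integers(*config.gene_length_range))
            start = alloc.take(glen, buffer=100)
            if start is None:
                continue
            gi += 1
            gid = f"{chrom}.g{gi}"
            strand = "+" if rng.random() < 0.5 else "-"
            truth.features.append(
                Feature(chrom, start, start + glen, kind="gene", strand=strand,
                        attributes={"ID": gid})
            )
            n_ex = config.exons_per_gene
            exon_len = max(50, glen // (2 * n_ex))
            step = (glen - exon_len) // max(1, n_ex - 1) if n_ex > 1 else 0
            for ei in range(n_ex):
                es = start + ei * step
                truth.features.append(
                    Feature(chrom, es, min(es + exon_len, start + glen),
                            kind="exon", strand=strand,
                            attributes={"ID": f"{gid}.e{ei + 1}",
                                        "Parent": gid})
                )


def _plant_ltrs(rng, config: SimConfig, chrom, cen, arm_zones, truth) -> None:
    def scatter(zone, target_frac, kind):
        zs, ze = zone
        span = ze - zs
        covered = 0
        while covered < target_frac * span:
            ln = int(rng.integers(500, 3_001))
            s = int(rng.integers(zs, max(zs + 1, ze - ln)))
            truth.features.append(Feature(chrom, s, min(s + ln, ze), kind=kind))
            covered += ln

    scatter(cen, config.ltr_gypsy_inside, "LTR_Gypsy")
    for zone in arm_zones:
        scatter(zone, config.ltr_gypsy_outside, "LTR_Gypsy")
        scatter(zone, config.ltr_copia, "LTR_Copia")
    scatter((0, config.chrom_length), config.ltr_copia, "LTR_Copia")


# ---------------------------------------------------------------------------
# Derived-assembly mutation
# ---------------------------------------------------------------------------

# buffer (bp) kept clear around each planted edit so anchor recovery and
# alignment representations stay unambiguous
_SMALL_BUFFER = 150
_LARGE_BUFFER = 400
_TERMINAL_KEEPOUT = 5_000


def _safe_zones(config: SimConfig, truth: TruthSet, chrom: str) -> list[tuple[int, int]]:
    tel5 = truth.telomeres[(chrom, "5prime")] * len(config.telomere_reverse)
    tel3 = truth.telomeres[(chrom, "3prime")] * len(config.telomere_forward)
    cs, ce = truth.centromeres[chrom]
    L = config.chrom_length
    zones = [
        (max(tel5, _TERMINAL_KEEPOUT), cs - 1_000),
        (ce + 1_000, L - max(tel3, _TERMINAL_KEEPOUT)),
    ]
    out = []
    gap_ivs = [(g.start - 1_000, g.end + 1_000) for g in truth.gaps if g.chrom == chrom]
    for zs, ze in zones:
        pieces = [(zs, ze)]
        for gs, ge in gap_ivs:
            nxt = []
            for s, e in pieces:
                if ge <= s or gs >= e:
                    nxt.append((s, e))
                else:
                    if gs - s > 0:
                        nxt.append((s, gs))
                    if e - ge > 0:
                        nxt.append((ge, e))
            pieces = nxt
        out.extend(p for p in pieces if p[1] - p[0] > 0)
    return out


def mutate_assembly(
    genome: GenomeAssembly, truth: TruthSet, config: SimConfig
) -> tuple[GenomeAssembly, TruthSet]:
    """Apply the configured variant spec, returning the derived assembly and
    a truth set extended with the exact variant coordinates and alleles.

    Edits never overlap one another (a spacing buffer is enforced at
    placement; an explicit overlap in a hand-built spec raises) and avoid
    telomere arrays, the satellite array, N-runs and chromosome termini so
    that every planted event is recoverable by unique-anchor alignment.
    """
    rng = np.random.default_rng([config.seed, _STREAM_MUTATE])
    truth = _dc_replace_truth(truth)
    chroms = [r.id for r in genome.records]
    alloc = {
        c: _ZoneAllocator(rng, _safe_zones(config, truth, c)) for c in chroms
    }
    edits: dict[str, list[tuple]] = {c: [] for c in chroms}

    def place(kind_label, length, buffer) -> tuple[str, int] | None:
        order = rng.permutation(len(chroms))
        for ci in order:
            start = alloc[chroms[ci]].take(length, buffer=buffer)
            if start is not None:
                return chroms[ci], start
        raise ValueError(
            f"cannot place {kind_label} of length {length}: no free zone left"
        )

    # structural variants first (largest constraints)
    for kind, length in config.sv_list:
        if kind == "INV":
            chrom, s = place("INV", length, _LARGE_BUFFER)
            edits[chrom].append(("INV", s, s + length))
            truth.svs.append(TruthSV("INV", chrom, s, s + length))
        elif kind == "DUP":
            chrom, s = place("DUP", length, _LARGE_BUFFER)
            edits[chrom].append(("DUP", s, s + length))
            truth.svs.append(TruthSV("DUP", chrom, s, s + length))
        elif kind == "TRANS":
            chrom, s = place("TRANS", length, _LARGE_BUFFER)
            others = [c for c in chroms if c != chrom] or [chrom]
            dest = others[int(rng.integers(0, len(others)))]
            dpos = alloc[dest].take(0, buffer=_LARGE_BUFFER)
            if dpos is None:
                raise ValueError("cannot place translocation destination")
            edits[chrom].append(("TRANS_SRC", s, s + length))
            edits[dest].append(("TRANS_DST", dpos, chrom, s, s + length))
            truth.svs.append(TruthSV("TRANS", chrom, s, s + length))
        else:
            raise ValueError(f"unknown SV kind {kind!r}")

    for kind, length in config.pav_list:
        if kind == "absence":
            chrom, s = place("absence", length, _LARGE_BUFFER)
            edits[chrom].append(("ABS", s, s + length))
            truth.pavs.append(TruthPAV("absence", chrom, s, s + length))
        elif kind == "presence":
            chrom, s = place("presence", 0, _LARGE_BUFFER)
            novel = _random_dna(rng, length)
            edits[chrom].append(("PRES", s, novel))
            # query coordinates recorded during application
        else:
            raise ValueError(f"unknown PAV kind {kind!r}")

    total = sum(r.length for r in genome.records)
    n_indel = int(round(config.indel_rate * total))
    ilo, ihi = config.indel_length_range
    for _ in range(n_indel):
        ln = int(rng.integers(ilo, ihi + 1))
        if rng.random() < 0.5:
            chrom, s = place("DEL", ln, _SMALL_BUFFER)
            pos, allele = normalize_indel(genome[chrom].seq, "DEL", s, genome[chrom].seq[s : s + ln])
            edits[chrom].append(("DEL", s, s + ln))
            truth.variants.append(VariantRecord("DEL", chrom, pos, ln, allele, ""))
        else:
            chrom, s = place("INS", 0, _SMALL_BUFFER)
            ins = _random_dna(rng, ln)
            pos, allele = normalize_indel(genome[chrom].seq, "INS", s, ins)
            edits[chrom].append(("INS", s, ins))
            truth.variants.append(VariantRecord("INS", chrom, pos, ln, "", allele))

    n_snp = int(round(config.snp_rate * total))
    for _ in range(n_snp):
        chrom, s = place("SNP", 1, _SMALL_BUFFER)
        ref_base = genome[chrom].seq[s]
        choices = [b for b in "ACGT" if b != ref_base]
        alt = choices[int(rng.integers(0, 3))]
        edits[chrom].append(("SNP", s, alt))
        truth.variants.append(VariantRecord("SNP", chrom, s, 1, ref_base, alt))

    derived = _apply_edits(genome, edits, truth)
    truth.variants.sort(key=lambda v: (v.ref_chrom, v.ref_pos))
    truth.svs.sort(key=lambda s: (s.ref_chrom, s.ref_start))
    return derived, truth


def _dc_replace_truth(truth: TruthSet) -> TruthSet:
    return TruthSet(
        telomeres=dict(truth.telomeres),
        centromeres=dict(truth.centromeres),
        features=list(truth.features),
        gaps=list(truth.gaps),
        ungapped=truth.ungapped,
        variants=list(truth.variants),
        svs=list(truth.svs),
        pavs=list(truth.pavs),
    )


def _edit_span(e: tuple) -> tuple[int, int]:
    kind = e[0]
    if kind in ("SNP",):
        return e[1], e[1] + 1
    if kind in ("INS", "PRES"):
        return e[1], e[1]
    if kind == "TRANS_DST":
        return e[1], e[1]
    return e[1], e[2]


def _apply_edits(
    genome: GenomeAssembly, edits: dict[str, list[tuple]], truth: TruthSet
) -> GenomeAssembly:
    records = []
    for rec in genome.records:
        evs = sorted(edits.get(rec.id, []), key=_edit_span)
        for a, b in zip(evs, evs[1:]):
            if _edit_span(a)[1] > _edit_span(b)[0]:
                raise ValueError(
                    f"overlapping edits on {rec.id}: {a[:3]} vs {b[:3]}"
                )
        seq = rec.seq
        pieces: list[str] = []
        pos = 0
        qpos = 0  # running length of the derived sequence

        def emit(s: str):
            nonlocal qpos
            pieces.append(s)
            qpos += len(s)

        for e in evs:
            s0 = _edit_span(e)[0]
            emit(seq[pos:s0])
            kind = e[0]
            if kind == "SNP":
                emit(e[2])
                pos = s0 + 1
            elif kind == "INS":
                emit(e[2])
                pos = s0
            elif kind == "DEL" or kind == "ABS" or kind == "TRANS_SRC":
                pos = e[2]
            elif kind == "INV":
                from .genome_io import reverse_complement

                emit(reverse_complement(seq[e[1] : e[2]]))
                pos = e[2]
            elif kind == "DUP":
                emit(seq[e[1] : e[2]])
                emit(seq[e[1] : e[2]])
                pos = e[2]
            elif kind == "PRES":
                q0 = qpos
                emit(e[2])
                truth.pavs.append(TruthPAV("presence", rec.id, q0, qpos))
                pos = s0
            elif kind == "TRANS_DST":
                _, _, src_chrom, ss, se = e
                emit(genome[src_chrom].seq[ss:se])
                pos = s0
            else:
                raise ValueError(f"unknown edit {kind!r}")
        emit(seq[pos:])
        records.append(SequenceRecord(rec.id, "".join(pieces)))
    return GenomeAssembly(records)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    genome: GenomeAssembly,
    read_length: int = 20_000,
    depth: float = 5.0,
    error_rate: float = 0.0,
    seed: int = 0,
    tiling: bool = False,
    tile_overlap: int = 1_000,
) -> list[SimRead]:
    """Sample reads with recorded provenance (chrom, start, strand).

    ``tiling=True`` emits a deterministic full tiling of every chromosome
    (adjacent reads overlapping by ``tile_overlap``) instead of random
    sampling; substitution errors are applied at ``error_rate`` either way.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng([seed, _STREAM_READS])
    reads: list[SimRead] = []
    ri = 0
    for rec in genome.records:
        L = rec.length
        if read_length > L:
            raise ValueError(
                f"read length {read_length} exceeds chromosome {rec.id} ({L})"
            )
        if tiling:
            step = max(1, read_length - tile_overlap)
            starts = list(range(0, L - read_length + 1, step))
            if starts[-1] + read_length < L:
                starts.append(L - read_length)
        else:
            n = int(np.ceil(depth * L / read_length))
            starts = sorted(int(x) for x in rng.integers(0, L - read_length + 1, n))
        for s in starts:
            ri += 1
            sub = rec.seq[s : s + read_length]
            strand = "+"
            if not tiling and rng.random() < 0.5:
                from .genome_io import reverse_complement

                sub = reverse_complement(sub)
                strand = "-"
            sub = _substitute(rng, sub, error_rate)
            reads.append(
                SimRead(f"read{ri}", sub, rec.id, s, s + read_length, strand)
            )
    return reads
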