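"""Centromere candidate prediction from windowed density tracks.

Centromeres are predicted from two complementary signals: high tandem-repeat
(satellite) coverage and low gene coverage. Both are summarized as windowed
covered-fraction tracks (default window 10 kb); windows passing both
thresholds are merged into runs and the longest surviving run per chromosome
becomes the candidate. LTR retrotransposon (Gypsy/Copia) density inside vs
outside the candidate is reported descriptively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_io import Feature, merge_intervals


@dataclass
class DensityTrack:
    """Covered fraction per fixed-size window along one chromosome."""

    chrom: str
    window: int
    chrom_length: int
    values: np.ndarray

    def __post_init__(self) -> None:
        expected = math.ceil(self.chrom_length / self.window)
        if len(self.values) != expected:
            raise ValueError(
                f"{self.chrom}: expected {expected} windows, got {len(self.values)}"
            )
        if len(self.values) and (self.values.min() < 0 or self.values.max() > 1 + 1e-9):
            raise ValueError("track values must lie in [0, 1]")

    @property
    def n_windows(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CentromereCandidate:
    chrom: str
    start: int
    end: int
    mean_trf: float
    mean_gene: float

    @property
    def length(self) -> int:
        return self.end - self.start


def coverage_track(
    features: Sequence[Feature], chrom: str, chrom_length: int, window: int = 10_000
) -> DensityTrack:
    """Fraction of bases covered by the union of features, per window.

    The final partial window is normalized by its actual width. Features on
    other chromosomes are ignored; out-of-bounds features raise.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n_win = math.ceil(chrom_length / window)
    covered = np.zeros(n_win, dtype=float)
    ivs = []
    for f in features:
        if f.chrom != chrom:
            continue
        if f.start < 0 or f.end > chrom_length:
            raise ValueError(
                f"feature [{f.start}, {f.end}) outside {chrom} of length {chrom_length}"
            )
        ivs.append((f.start, f.end))
    for s, e in merge_intervals(ivs):
        w0, w1 = s // window, (e - 1) // window
        for w in range(w0, w1 + 1):
            ws, we = w * window, min((w + 1) * window, chrom_length)
            covered[w] += max(0, min(e, we) - max(s, ws))
    widths = np.minimum(
        (np.arange(n_win) + 1) * window, chrom_length
    ) - np.arange(n_win) * window
    return DensityTrack(chrom, window, chrom_length, covered / widths)


def find_tandem_arrays(
    seq: str,
    chrom: str = "seq",
    min_period: int = 2,
    max_period: int = 500,
    min_array: int = 1_000,
    max_mismatch_frac: float = 0.0,
    smooth_window: int = 100,
) -> list[Feature]:
    """Detect intervals of short-period tandem repetition.

    A position i is p-periodic when seq[i] == seq[i+p]; maximal runs of
    periodicity of total length >= ``min_array`` (for any period in range)
    are reported, merged across periods, as TRF features. With
    ``max_mismatch_frac`` > 0, the per-position match indicator is smoothed
    over ``smooth_window`` and positions with local match fraction
    >= 1 - max_mismatch_frac count as periodic, tolerating diverged
    monomers. N positions never count as matches.
    """
    if min_period < 2:
        raise ValueError("min_period must be >= 2")
    n = len(seq)
    if n < min_period + 1:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = arr != ord("N")
    intervals: list[tuple[int, int]] = []
    for p in range(min_period, min(max_period, n - 1) + 1):
        eq = (arr[:-p] == arr[p:]) & valid[:-p] & valid[p:]
        if max_mismatch_frac > 0:
            w = min(smooth_window, len(eq))
            if w < 1:
                continue
            # sliding mean of eq over windows [i, i+w) via cumulative sum
            cs = np.concatenate(([0], np.cumsum(eq, dtype=np.int64)))
            frac = (cs[w:] - cs[:-w]) / w
            good = frac >= 1.0 - max_mismatch_frac
            tail = w - 1  # a good start i certifies eq through i + w - 1
        else:
            good = eq
            tail = 0
        if not good.any():
            continue
        padded = np.concatenate(([False], good, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        # run of match positions [s, e) implies repeated interval [s, e + tail + p)
        keep = (ends - starts + tail + p) >= min_array
        for s, e in zip(starts[keep], ends[keep]):
            intervals.append((int(s), int(e) + tail + p))
    return [
        Feature(chrom, s, e, kind="TRF") for s, e in merge_intervals(intervals)
    ]


def call_centromere(
    trf_track: DensityTrack,
    gene_track: DensityTrack,
    trf_min: float = 0.5,
    gene_max: float = 0.05,
    merge_gap: int = 5,
    min_length: int = 100_000,
) -> CentromereCandidate | None:
    """Call at most one centromere candidate from TRF and gene density tracks.

    Windows with TRF coverage >= ``trf_min`` and gene coverage <=
    ``gene_max`` are selected; runs separated by <= ``merge_gap`` windows are
    merged; runs shorter than ``min_length`` bases are discarded; the longest
    survivor is returned with its mean densities.
    """
    if (
        trf_track.chrom != gene_track.chrom
        or trf_track.window != gene_track.window
        or trf_track.n_windows != gene_track.n_windows
    ):
        raise ValueError("TRF and gene tracks do not align")
    sel = (trf_track.values >= trf_min) & (gene_track.values <= gene_max)
    runs: list[list[int]] = []  # [first_window, last_window] inclusive
    for w in np.flatnonzero(sel):
        if runs and w - runs[-1][1] <= merge_gap + 1:
            runs[-1][1] = int(w)
        else:
            runs.append([int(w), int(w)])
    window = trf_track.window
    best = None
    for w0, w1 in runs:
        start = w0 * window
        end = min((w1 + 1) * window, trf_track.chrom_length)
        if end - start < min_length:
            continue
        if best is None or end - start > best[1] - best[0]:
            best = (start, end, w0, w1)
    if best is None:
        return None
    start, end, w0, w1 = best
    return CentromereCandidate(
        trf_track.chrom,
        start,
        end,
        mean_trf=float(trf_track.values[w0 : w1 + 1].mean()),
        mean_gene=float(gene_track.values[w0 : w1 + 1].mean()),
    )


def ltr_density_report(
    gypsy_track: DensityTrack,
    copia_track: DensityTrack,
    candidate: CentromereCandidate | None,
) -> dict:
    """Mean Gypsy/Copia coverage inside vs outside the candidate interval.

    Descriptive only; not used for calling. With no candidate, genome-wide
    means are reported under 'outside' and inside-means are None.
    """
    out = {}
    for name, track in (("gypsy", gypsy_track), ("copia", copia_track)):
        if candidate is None:
            out[f"{name}_inside"] = None
            out[f"{name}_outside"] = float(track.values.mean()) if track.n_windows else 0.0
            continue
        if track.chrom != candidate.chrom:
            raise ValueError("track chromosome does not match candidate")
        w0 = candidate.start // track.window
        w1 = math.ceil(candidate.end / track.window)
        inside = track.values[w0:w1]
        outside = np.concatenate([track.values[:w0], track.values[w1:]])
        out[f"{name}_inside"] = float(inside.mean()) if len(inside) else 0.0
        out[f"{name}_outside"] = float(outside.mean()) if len(outside) else 0.0
    return out


def write_candidates_tsv(
    candidates: Sequence[CentromereCandidate | None], path, chrom_order=None
) -> None:
    """TSV of centromere candidates: chrom, start, end, length."""
    rows = [c for c in candidates if c is not None]
    if chrom_order:
        order = {c: i for i, c in enumerate(chrom_order)}
        rows.sort(key=lambda c: order.get(c.chrom, len(order)))
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tlength\n")
        for c in rows:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.length}\n")


def write_bedgraph(track: DensityTrack, path) -> None:
    with open(path, "w") as fh:
        for w, v in enumerate(track.values):
            s = w * track.window
            e = min(s + track.window, track.chrom_length)
            fh.write(f"{track.chrom}\t{s}\t{e}\t{v:.6g}\n")
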