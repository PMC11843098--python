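# t2tkit

A toolkit for finishing and evaluating telomere-to-telomere (T2T) genome
assemblies, aimed at small plant genomes assembled from long reads. It
implements the computations that turn a chromosome-scale draft into a
validated gap-free assembly and quantify how complete and accurate it is:

* **Telomere identification and terminal patching.** Plant telomeres are
  tandem arrays of the 7-bp minisatellite TTTAGGG (C-rich strand CCCTAAA).
  The toolkit counts motif copies in chromosome-terminal windows, screens
  long reads anchored within 50 bp of each chromosome end, selects the read
  with the most telomeric repeats as the consensus reference, and decides
  whether a consensus may replace a terminus — accepted only when alignment
  identity ≥ 80 % and the alignment lies within 20 kb of the end.
* **Centromere prediction.** Windowed covered-fraction tracks (default
  10 kb windows) of tandem-repeat (TRF) and gene intervals; windows with
  TRF coverage ≥ 0.5 and gene coverage ≤ 0.05 are merged into runs and the
  longest run ≥ 100 kb per chromosome is the centromere candidate. A
  built-in periodicity scanner detects satellite arrays directly from
  sequence when no external TRF track is supplied; LTR Gypsy/Copia density
  inside vs outside the candidate is reported descriptively.
* **Gap cataloging and filling.** Gaps are maximal N-runs. Fill candidates
  are ranked by source (error-corrected genome > HiFi > ONT ultra-long),
  then by aligned span and identity; only candidates spanning both 1-kb
  flank anchors may fill a gap.
* **k-mer consensus quality (QV).** With *b* the fraction of assembly
  k-mers unsupported by the read k-mer set (canonical k-mers, default
  k = 21), the per-base error rate is *e* = 1 − (1 − *b*)^(1/k) and
  QV = −10·log₁₀ *e*.
* **Two-assembly comparison.** A desk-scale aligner chains unique exact
  21-mer anchors into colinear blocks, then classifies differences: SNPs
  and 2–50 bp indels inside blocks (affine-gap local realignment keeps
  every indel contiguous), inversions (reverse-strand blocks),
  translocations (order- or chromosome-breaking blocks), duplications
  (reference regions with ≥ 2 disjoint query partner loci), and
  presence/absence variants (regions uncovered by any block). Records carry
  genic context (exon > intron > 2-kb upstream > 2-kb downstream >
  intergenic) and SV length bins (50–1000, 1001–2000, …, > 9000 bp).
* **Read/contig filters.** ONT ultra-long reads: length ≥ 30 kb and mean
  Q-score > 9 (with a configurable 10 kb / Q ≥ 7 pre-stage); HiFi reads:
  ≥ 3 subread passes and SNR ≥ 2.5; contigs with > 50 % of their bases
  aligning to organelle references (alignment union, not sum) are excluded.
* **Synthetic genomes with planted truth.** A deterministic simulator
  builds chromosomes with telomere arrays, a diverged 171-bp satellite
  centromere, genes, LTRs and N-gaps, and derives a mutated assembly with
  known SNPs, indels, inversions, translocations, duplications and
  presence/absence segments — so every detector above can be scored against
  exact ground truth.

All coordinates are 0-based half-open; interval length is always
`end − start`.

## Worked example

Simulate a 4-chromosome genome (400 kb each, 120-kb satellite arrays, one
planted 500-bp gap, no telomere at the Chr2 5′ end), then run the
consolidated T2T report:

```sh
t2tkit sim --seed 5 --out-dir sim --n-chromosomes 4 --chrom-length 400000 \
       --array-length 120000 --drop-end 2:5prime --gap 1:0.2:500
t2tkit report --fasta sim/genome.fasta --features sim/features.gff3 --out-dir rep
cat rep/report.json
```

```json
{
  "N50": 400000,
  "centromere_count": 4,
  "gap_count": 1,
  "n_chromosomes": 4,
  "telomere_count": 7,
  "telomere_matrix": [["Chr1", 285, 534], ["Chr2", 0, 480],
                      ["Chr3", 399, 467], ["Chr4", 509, 429]],
  "total_length": 1600000
}
```

Seven of the eight chromosome ends carry a telomere (the dropped Chr2 5′
end reads 0, exactly as planted); the matrix gives the motif copy count per
end. All four planted satellite arrays are recovered as centromere
candidates (`rep/centromeres.tsv`):

```text
chrom   start   end     length
Chr1    180000  300000  120000
...
```

and the planted N-run appears in `rep/gaps.tsv` as `Chr1 80000 80500 500`.
Other subcommands follow the same pattern: `telo`, `cent`, `gaps`, `fill`,
`compare` (two FASTAs → blocks, VCF, SV/PAV tables, summary JSON), and
`qv` (assembly + reads → QV table). Every subcommand takes `--config`
(YAML mirroring its flags) and is byte-deterministic for a fixed `--seed`.

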