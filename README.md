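# ervfossil

Endogenous retroviruses (ERVs) are retroviruses fossilised in host
germlines: each integration leaves a provirus (5' LTR — *gag/pol/env* —
3' LTR, flanked by a 4-bp target-site duplication) that then evolves at
the host's neutral rate. Read correctly, these fossils date past
infections, expose cross-species transmissions, and reveal whether a
family amplified by reinfection or by intracellular retrotransposition.
`ervfossil` is a toolkit for exactly that reading, aimed at people
mining repeat-annotated genome assemblies:

* **annotate** — classify LTR hits (RepeatMasker `.out` dialect) into
  putative full-length proviruses (two same-orientation LTRs separated
  by 3–10 kb) and complete solo LTRs (missing <150 bp at the consensus
  5' end, <10 bp at the 3' end), with copy-number tables, the 80%/80%
  cross-species hit filter and the 80%-identity family-membership rule;
* **dating** — insertion ages from LTR–LTR divergence: CpG-masked
  Kimura 2-parameter distance d = −½·ln[(1−2P−Q)√(1−2Q)] and the
  two-LTR clock t = d / (2r); sliding-window identity profiles
  (300-bp windows, 50-bp step);
* **orthology** — presence/absence of each insertion at the orthologous
  position in a second species, via 200+200 bp junction probes, flank
  pairing, and empty-site detection with TSD recovery;
* **conversion** — inter-LTR gene conversion through the 4-LTR quartet
  test (four-point condition on K2P distances, column-bootstrap
  support);
* **selection / integrity** — per-domain dN/dS (ω) by Nei–Gojobori
  counting with a codon-bootstrap test of ω = 1, stop/frameshift
  frequencies per codon with exact Poisson 95% intervals, and shared
  deletion-breakpoint clustering;
* **simulate** — a two-species genome generator with fully known ground
  truth (ages, orthology, solo status, conversion history, envelope
  deletions, planted ORF disruptions) so every stage above is testable
  without any downloads.

See `docs/methods.md` for the models, parameter choices and
limitations.

## Worked example

Dating and conversion on simulated proviruses
(`examples/04_gene_conversion.py`; every capability has a script under
`examples/`):

```text
no conversion                  topology=by_ltr_position support=1.00  LTR-clock age=13.4 MY
converted (90% tract, 5 MYA)   topology=by_provirus     support=0.97  LTR-clock age=6.9 MY
```

Both proviruses inserted 16 MY ago in the common ancestor of two
species that split 10 MY ago. The unconverted quartet groups by LTR
position — the speciation signal — and its LTR clock reads ~13 MY
(conversion-free, mildly dispersed around truth). In the converted
provirus, a 90% conversion tract at 5 MYA homogenised each lineage's
LTR pair: the quartet flips to grouping by provirus (support 0.97),
and the LTR clock collapses to ~7 MY — the mechanism that makes
LTR-based ages underestimates relative to orthology-based ones.

Orthology calls on the same kind of data
(`examples/03_orthologous_loci.py`):

```text
L0001 (ancestral provirus) -> present_provirus
L0006 (A         solo_ltr) -> absent_empty tsd=TGCA
```

Ancestral insertions are found at the orthologous position in the
second genome; post-split insertions hit an empty pre-integration site
with the single 4-bp target-site copy recovered.

## Command line

A thin CLI wraps the library for batch use:

```sh
ervfossil annotate --rm-out hits.out --ltr-family ERV1-LTR \
    --out loci.bed --summary counts.tsv
ervfossil date --loci loci.bed --genome g.fa --ltr-len 600 \
    --rate 2.7e-9 --out ages.tsv
ervfossil orthology --loci loci.bed --donor a.fa --target b.fa \
    --ltr-len 600 --out calls.tsv
ervfossil simulate --config sim.yaml --outdir sim/
```

The `simulate` YAML mirrors `ervfossil.simulate.SimConfig`: scalar
fields (`seed`, `genome_len`, `split_time_years`, `gc_content`,
`ltr_len`, `internal_len`, `tsd_len`, `rate_per_year`, `ti_tv_ratio`,
`cpg_multiplier`, `solo_fraction`) plus `insertion_events` (list of
`{time_years, mode, lineage, kind}`), `conversion_events` (list of
`{locus_index, lineage, time_years, tract_fraction}`) and an optional
`env_deletion` (`{start, end, affected_loci}`).

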