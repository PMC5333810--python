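# lophopax

Identification and classification of **Pax transcription-factor family**
proteins in Lophotrochozoa (molluscs, annelids, platyhelminths, nemerteans,
brachiopods).  Public databases routinely mis-annotate lophotrochozoan Pax
sequences (Pax6 entries that are actually *eyegone*, Paxβ entries annotated
as mucins, and so on); this package mechanizes the evidence used to correct
them, for curators and molecular evolution researchers who need reproducible
subfamily calls rather than one-off visual inspection.

## What it does

Pax proteins are defined by the **paired domain (PRD)**, a 128-aa DNA-binding
domain composed of the N-terminal PAI and C-terminal RED subdomains.
Downstream of the PRD a sequence may carry an **octapeptide motif (OM)** and
a ~60-aa paired-type **homeodomain (HD)**.  The six lophotrochozoan
subfamilies are separated by domain composition and short diagnostic motifs:

| family   | architecture | diagnostics |
|----------|--------------|-------------|
| Pax1/9   | PRD + OM, no HD | octapeptide `H[ST]V[ST][DN][IL]LG` |
| Pax2/5/8 | PRD + OM, no HD | octapeptide `Y[TS]IX2ILG` + quadribasic/diacid signal |
| Pax3/7   | PRD + HD, OM optional | — |
| Pax4/6   | PRD + HD, no OM | `MDKL` linker between PRD and HD |
| Paxβ     | PRD + long variable region | ≥2 of three conserved motifs (`YDY[NS]LPDRGL`, `PLDLS`, a 31-column consensus) |
| PoxNeuro | PRD only | tribasic helix-1 signal, `KPKQVAT` PAI/RED junction insertion, post-PRD `[VI]PGLSYP[KR][IL]V` |

plus the divergent/duplicated-PRD *eyegone* configuration, which is only
ever flagged `eyg?` for manual review.

The pipeline stages, each usable as a library module:

* `seqio` — FASTA/alignment I/O and the bundled 56-row reclassification
  table of previously non- or mis-identified lophotrochozoan Pax sequences;
* `motifs` — a bracket-notation consensus pattern language
  (literals, residue classes, counted wildcards `X2`) with a mismatch-counting
  scanner and basic-signal detector;
* `domains` — ungapped position-profile detection of PRD (as PAI+RED with a
  junction-insert allowance), HD, octapeptide, and PRD percent identity;
* `classifier` — required/forbidden-evidence family assignment with
  fragment `(f)`, indeterminate `Pax`, `Paxβlike` and `eyg?` outcomes;
* `blocks` — conserved-block alignment curation (minimum block length 10,
  no gap columns, non-conserved runs >8 rejected, 85% flank agreement);
* `trees` — gamma/p distances, deterministic neighbor joining, bootstrap
  supports (branches <50% collapsed into polytomies), family monophyly report;
* `synthetic` — a seeded generator of Pax-like proteins with planted
  architectures, used as the offline benchmark for every stage.

## Worked example

Generate a noise-free labeled dataset and classify it:

```
$ lophopax simulate --out demo --n-per-family 2 --seed 4
$ lophopax classify --in demo/synthetic.fasta --out demo
$ cat demo/reclassification.tsv
Accession	Submitted name	Proposed name	Species	Classification
pax19_000		Pax1/9
pax19_001		Pax1/9
pax258_000		Pax2/5/8
pax258_001		Pax2/5/8
pax37_000		Pax3/7
pax37_001		Pax3/7
pax46_000		Pax4/6
pax46_001		Pax4/6
paxb_000		Paxβ
paxb_001		Paxβ
poxn_000		PoxNeuro
poxn_001		PoxNeuro
```

Every record is recovered as its planted family (at mutation rate 0 this is
exact by construction; the accompanying `annotation.tsv` lists each PRD/OM/HD
hit with coordinates and scores).  `lophopax tree --in <aligned.fasta> --out
<dir>` curates an alignment and writes `curated.fasta`, `distances.phylip`,
a support-annotated `tree.nwk` and, given `--calls`, `monophyly.tsv`;
`lophopax all` chains the stages.

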