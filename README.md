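# phagekit

A tested, reusable re-implementation of a single-phage-genome
characterization pipeline:

* **ORF/CDS calling** (bacterial translation table 11, alternative
  initiators GTG/TTG, stop codon counted inside the CDS interval) with a
  minimum-product-mass filter, plus genome-packing statistics
  (orientation counts, intergenic gaps/overlaps, largest gap).
* **IUPAC-degenerate restriction screening** — distinct-site counting that
  understands IUPAC-palindromic recognition sequences, with a built-in
  pattern registry.
* **Bipartite promoter search** — sigma-70-style `TTGACA (N15-18) TATAAT`
  consensus with a shared mismatch budget across both boxes,
  deduplicated per −10 box.
* **Intrinsic (rho-independent) terminator detection** — maximal
  inverted-repeat hairpins (optional G·T weak pairs, bounded stem
  mismatches), a stem-only nearest-neighbor free-energy estimate, and a
  downstream T-tract score.
* **Composition profiling** — global GC, sliding-window GC and GC-skew
  `(G−C)/(G+C)`, and extreme-region calls.
* **Protein properties** — average molecular mass and theoretical pI
  (Henderson–Hasselbalch charge balance, bisection, Bjellqvist pKa set).
* **Synthetic-genome generator** — seeded phage-like genomes with a
  planted-feature ledger (CDSs, promoters with known mismatch counts,
  terminators, restriction sites) so every stage is testable offline; the
  background is scrubbed of accidental features so recovery is exact.

All coordinates are 1-based and inclusive at both ends, everywhere.

## Test

```sh
python -m pytest -q tests/
```

Note on expected failures: the acceptance tests in
`tests/test_acceptance.py::TestReferenceGenome` validate published numbers
for the deposited reference genome (GenBank KY565347.1). That sequence is
not redistributable inside this repository, so those tests fail with an
explanatory message unless you provide the FASTA at
`data/KY565347.1.fasta` (or point `PHAGEKIT_TP84_FASTA` at it). Everything
else — unit tests, property tests, brute-force-oracle equivalence, and the
50-seed planted-recovery sweep — runs fully offline.

## CLI

```sh
phagekit run genome.fasta --out outdir/            # full pipeline
phagekit annotate genome.fasta --min-mass 4.0      # CDS calls + table
phagekit scan genome.fasta                         # restriction screen
phagekit promoters genome.fasta                    # bipartite search
phagekit terminators genome.fasta                  # hairpin + T-tract
phagekit composition genome.fasta --plot gc.png    # GC / skew profile
phagekit protein-table genome.fasta cds.tsv        # mass/pI per CDS
phagekit simulate --length 20000 --n-cds 8 --seed 1 \
    --fasta syn.fasta --ledger truth.json          # synthetic genome
phagekit validate genome.fasta                     # concordance vs the
                                                   # bundled reference table
```

`phagekit run` emits `genome.gff3`, `cds_table.tsv`,
`restriction_counts.tsv`, `promoters.tsv`, `terminators.tsv`,
`composition.tsv` and `summary.json`, all deterministic for a given genome
and config (YAML config via `--config`; every output embeds the config
hash and tool version).

## Data

`src/phagekit/data/tp84_cds_table.tsv` is an 81-row CDS table (label,
printed nt length, coordinates, strand, product length, mass, pI)
transcribed from the published per-gene annotation table of the reference
genome; it drives the concordance checks and the `validate` subcommand.
One row (`TP84_43`) carries a printed length that disagrees with its
printed coordinate span by 1 nt — the importer preserves the printed
values and exposes the discrepancy via
`phagekit.orfs.coordinate_inconsistencies`.
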