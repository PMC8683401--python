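# famscreen

A gene-family mining toolkit built around PROSITE-dialect consensus motif
keys, written for the genome-wide identification and characterization of the
cyclic nucleotide-gated channel (CNGC) family in *Brassica rapa* L. (field
mustard), and reusable for any protein family screened the same way.

Plant CNGCs are ligand-gated cation channels with an N-terminal ion-transport
(IT) domain and a C-terminal cyclic-nucleotide-binding domain (CNBD) that
contains the phosphate-binding cassette (PBC) and hinge region. The modern
membership criterion for the family combines three tests: a full-length
protein (> 500 aa), the presence of both the cNMP-binding and IT domains, and
a match to a family-specific consensus motif key induced from the PBC + hinge
alignment at > 90 % conservation. `famscreen` implements that whole workflow:

- **pattern_engine** — parse and scan PROSITE-dialect patterns
  (`[ST]-X(2)-[DE]`, classes, exclusions `{P}`, bounded wildcards
  `X(7,14)`, anchors), including the 22-element family consensus key and a
  bundled set of PROSITE PTM site patterns (CK2, PKC, N-glycosylation, …).
- **key_induction** — derive a consensus key from a multiple sequence
  alignment at a conservation threshold. A column with top-residue fraction
  ≥ *t* (over non-gap rows) becomes a fixed token; runs of other columns
  become `X(min,max)` wildcards. In *cover* mode the induced key provably
  matches 100 % of its training sequences.
- **family_screen** — accept/reject candidates with enumerated reasons.
- **physchem** — ProtParam-style property vectors: MW, theoretical pI (by
  bisection of the Henderson–Hasselbalch charge curve with Bjellqvist pKa
  values), instability index (Guruprasad dipeptide weights), aliphatic
  index, GRAVY (Kyte–Doolittle), charge, residue and atomic composition.
- **gene_structure** — GFF3 gene models, exon counts, intron phases
  (phase = cumulative coding length upstream of the intron mod 3).
- **duplication** — tandem-pair detection (same chromosome and group,
  gap ≤ 50 kb, ≤ 1 intervening family gene) plus heuristic
  candidate-segmental labels.
- **expression** — FPKM matrices: expressed-gene calling (FPKM > 1),
  log2 fold change vs paired controls, up/down/unchanged/not-expressed.
- **fixtures** — the packaged family tables (30 candidate records, 29
  member property rows) and seeded generators for synthetic families with
  planted motifs, GFF3 with known intron phases, and expression matrices
  with planted effects — each with a machine-readable truth object.

## Worked example

Screen the packaged candidate table (the 29 family members plus one
truncated accession lacking the CNBD):

```
$ famscreen screen --candidates candidates.tsv
accession	accepted	reasons
Bra034281	True
...
Bra022235	False	short-sequence;missing-domain:cNMP
famscreen INFO: accepted 29 / rejected 1
```

Find tandem duplicates with the default thresholds — the three group IV-b
pairs sit 1.7–7.3 kb apart on chromosomes A01, A03 and A05:

```
$ famscreen tandem --coords candidates.tsv
gene_a	gene_b	chromosome	gap_bp	group
BrCNGC25	BrCNGC28	A01	2257	IV-b
BrCNGC22	BrCNGC27	A03	7275	IV-b
BrCNGC26	BrCNGC29	A05	1763	IV-b
```

Scan a protein for PTM sites (1-based coordinates):

```
$ famscreen scan --ptm --fasta p.fasta
seq_id	pattern	start	end	matched_text
p1	N-glycosylation	11	14	NGSA
p1	casein-kinase-II	1	4	STTE
...
```

Simulate a family with a planted motif and re-derive its key (the planted
fixed positions come back exactly; flanks collapse to bounded wildcards):

```
$ famscreen --seed 7 simulate family --n 8 --out-prefix fam
$ famscreen induce --msa fam.aln.fasta --threshold 0.9 --mode cover
X(11,59)-L-X(2)-G-X(3)-G-L-L-X-W-X(22,51)
```

The library surface mirrors the CLI; e.g.

```python
from famscreen import fixtures, family_screen, duplication
records = fixtures.load_table1()
decisions = family_screen.screen(records)          # 29 accepted, 1 rejected
members = [r for r in records if r.chromosome]
pairs = duplication.find_tandem_pairs(members)     # the three IV-b pairs
```

Note: protein sequences of the 29 members are not bundled; sequence-level
checks (key coverage of the real family, per-protein property rows) need a
one-time download from the BRAD *Brassica* database —
`python scripts/fetch_brad.py` lists the accessions.

## CLI conventions

All outputs are TSV/FASTA/GFF3; existing files are only overwritten with
`--force`; `--config <yaml>` supplies per-subcommand option defaults that
explicit flags override. Exit codes follow click's convention (2 for usage
errors, 1 for data errors reported by the tool).
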