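# Methods

This note records the models, conventions and numerical choices behind
`famscreen`, in the order a user meets them.

## Pattern dialect and matching semantics

Patterns are ordered lists of elements, each a residue matcher (fixed
residue, residue class `[..]`, excluded class `{..}`, or wildcard `X`) with
a bounded repeat count. Separators may be `-`, en/em dashes or whitespace,
because printed keys mix all three; a trailing PROSITE `.` is ignored. A
count list such as `X(0,1,2)` is read as min..max of the listed values and
must be non-decreasing. A fully-enclosing outer bracket pair is stripped
only when its interior contains further brackets, braces or repeat groups,
so a bare class token `[ST]` is untouched while a printed key wrapped as
`[[L]-X(2)-...-L]` parses to its 22 inner tokens. `[L]` and `L` are matched
identically: no published definition distinguishes them, so both forms are
accepted and the canonical serialization emits the plain letter.

Scanning tests **every start position** independently, so overlapping
matches at distinct starts are all reported and the match count equals the
number of matching start positions. At a given start, variable-length
elements take the **shortest** satisfying expansion (depth-first, smallest
repeat first), which makes coordinates deterministic and coincides with
classic ScanProsite behaviour for fixed-length patterns. For variable-length
patterns, site-count conventions of external servers may differ; this one is
documented and reproducible. Ambiguity codes in sequences (X, B, Z, U)
satisfy wildcards only — never fixed residues, classes, or excluded classes
(an excluded class is still a class: it admits exactly the standard residues
outside its set). Sequence case is normalized to upper.

The scanner's correctness is checked against an independent enumeration
oracle (a reachable-position-set expansion over all repeat choices) on
randomized pattern/sequence instances, both in the test suite and in the
acceptance script.

## Key induction

Column conservation is computed over non-gap rows; ties break
alphabetically. The threshold comparison defaults to `>=` with a
`strict_greater` switch, since a "> 90 %" criterion is ambiguous at the
boundary. Columns are demoted to wildcard runs when (a) more than half their
rows are gaps (no consensus signal), or (b) — in cover mode — they contain
any gap at all, because a fixed token cannot absorb a gap and the cover-mode
contract is that the induced key matches every training row. A wildcard run
spanning columns *C* becomes `X(min,max)` where min/max are the fewest/most
non-gap residues any single row contributes across *C*; an all-gap run is
dropped. In cover mode, a conserved but non-unanimous column widens to the
class of all residues observed there. With these rules the cover-mode
guarantee is constructive: every row is the concatenation of its per-column
residues, each fixed/class token accepts that row's residue, and each run
accepts that row's residue count. Strict mode instead emits the top residue
and reports the realized coverage.

Adjacent identical fixed tokens are not merged into repeats (consensus keys
are conventionally written with explicit `L-L`). Raising the threshold can
only demote columns, so the fixed-token count is monotone non-increasing in
the threshold (property-tested). The PBC/hinge region is supplied as an
explicit column interval; the toolkit does not auto-detect domain
boundaries.

## Physicochemical properties

Molecular weight, GRAVY and residue composition delegate to Biopython's
`ProteinAnalysis` (average isotopic masses, one water of 18.0153 Da per
chain). The instability index is the Guruprasad statistic
`(10/L)·Σ DIWV(x_i, x_{i+1})`, with the 400-entry DIWV table imported from
`Bio.SeqUtils.ProtParamData`; sequences shorter than two residues have no
dipeptides and the index is defined as 0. The aliphatic index is Ikai's
`100·(fA + 2.9·fV + 3.9·(fI + fL))`. Net charge is a Henderson–Hasselbalch
sum over D, E, C, Y, H, K, R and both termini using the Bjellqvist pKa set
(with residue-specific terminal overrides) as shipped with Biopython — the
same constants the ProtParam web service uses — so swapping pKa sets means
swapping those dictionaries. The theoretical pI is found by bisection of the
charge curve on [0, 14] to a pH tolerance of 1e-3; the charge is strictly
decreasing in pH, so the root is unique. Tests cross-check charge, pI and
instability against Biopython's independent implementations and a fine-grid
scan oracle (agreement within 2e-3 pH units). Note that Biopython's own
`pi()` clamps its search to [4.05, 12] by default and converges on |charge|
rather than pH width, hence the looser tolerance in that particular
cross-check.

Atomic composition uses the standard residue formulas (free amino acid minus
water) plus one closing water. The ambiguity policy defaults to `strict`
(raise on non-standard letters), because reproducing published property
tables requires clean sequences; `lenient` gives unknowns a mean residue
mass of 110 g/mol, zero hydropathy, neutral dipeptide weights, and excludes
them from composition fractions.

The published "Charge" column's pH convention is unstated upstream (values
like 38 suggest a non-neutral convention); reports therefore carry the pH at
which charge was computed (default 7.0) and treat the published column as
annotation, not a target.

## Screening

Acceptance requires length **strictly** greater than `min_length`
(default 500; configurable to `>=` — the family's observed minimum of 556 aa
is consistent with either reading), all required domains present (default
{cNMP, IT}; domain calls are inputs from external domain services, never
computed here), and — when both a key and a sequence are available — at
least one key match. Rejection reasons are enumerated
(`short-sequence`, `missing-domain:<name>`, `key-mismatch`), so a decision
is accepted exactly when its reason list is empty. Decisions are per-record
and therefore order-independent and idempotent; tightening `min_length`
can only shrink the accepted set.

## Gene structures

Coordinates are converted to 0-based half-open at the GFF3 boundary and kept
that way internally. Exon/CDS lists are stored in transcription order. When
a gene has several transcripts, the one with the longest total CDS
represents the gene. Intron phase is `cumulative upstream CDS length mod 3`,
computed in transcription order; introns outside the CDS span are labelled
`-`. A CDS total that is not a multiple of three triggers a warning but
phases are still reported. The family-wide phase histogram always totals
`Σ(exon_count − 1)`.

## Tandem duplication

A tandem pair shares chromosome and group, has an intergenic gap
(downstream start − upstream stop, clamped at 0 for overlapping loci) of at
most 50 kb, and at most one other family gene between the two loci. The
defaults are generous on purpose: the three known pairs in the packaged
family sit 1.7–7.3 kb apart, so the result is stable across a wide threshold
range (property-tested: shrinking the gap never adds pairs). The
`candidate-segmental` label — same group, different chromosome — is an
explicitly heuristic flag for follow-up synteny analysis, which is out of
scope here, and is not expected to reproduce any particular published count.

## Expression

A gene is "expressed" in a condition when FPKM > 1 (strict). Fold change is
`log2((t + 1)/(c + 1))` with a configurable pseudo-count of 1 (zero FPKM is
common and the upstream convention for zeros is unstated). The calls are
`up` (fc > 0), `down` (fc < 0), `unchanged` (fc = 0 — resolving the
up/down threshold ambiguity at 0 to a distinct class), and `not-expressed`
when both members of the pair sit at or below the expressed threshold.
Fold change is antisymmetric under swapping treatment and control
(property-tested). Both log2 and linear ratios are reported, since published
fold-change prose rarely states the scale.

## Synthetic-data generators

All generators take an explicit seed (NumPy `default_rng`) and are
byte-reproducible; each emits a truth object consumed by downstream tests.

*Family generator*: 29 members by default (the size of the family that
motivated the toolkit), with a fixed-length planted motif (default
`L-X(2)-G-X(3)-G-L-L-X-W`, a compact stand-in with the consensus key's
token variety), flanks of 10–60 uniform-random residues, and conservation
0.90. Conservation is enforced deterministically: for each fixed motif
column, exactly `floor((1 − c)·n)` members receive a substitute residue, so
the realized column conservation never falls below the requested level (for
c > 0.5 the consensus always remains the top residue). The alignment pads
flanks with edge gaps; it therefore models length variation but not
internal indels, substitution matrices or phylogenetic correlation — passing
the recovery tests shows the induction machinery is correct, not that real
alignments are this clean.

*GFF generator*: fully coding genes (CDS = exons), 1–11 exons of 30–300 bp
with 60–500 bp introns, last exon padded so the coding length is a codon
multiple; truth phases are fixed at construction from cumulative sums, and
GFF3 CDS phase fields are written as `(3 − cum mod 3) mod 3`. UTR structure
is not simulated.

*Expression generator*: planted classes up/down (treatment = control ×/÷
effect, default 4), unchanged (identical values), and not-expressed (both
below threshold); effect genes get a control floor of 5 FPKM above a
lognormal baseline so planted classes are exactly recoverable. Real FPKM
noise, replicates and dispersion are deliberately absent — the generator
validates the classification logic, not a statistical test.

## Problem sizes

The acceptance script runs the packaged 30-record family end-to-end, 1000
random pattern/sequence oracle instances, five 29-member synthetic families,
25 synthetic gene models and a 50-gene × 3-pair expression design; the whole
run takes on the order of a second, and the full test suite a few seconds.

## Known limitations

- No profile/HMM matching, mismatch tolerance, or nucleotide patterns.
- Induction does not build alignments and does not promise string-identity
  with any hand-derived key — only coverage and planted-motif recovery.
- Domain calls, phylogenetic groups and subcellular localization are inputs.
- Segmental-duplication labelling is a heuristic adjacency-free flag.
- Sequence-level family checks require the external BRAD download
  (`scripts/fetch_brad.py`).
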