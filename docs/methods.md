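# Methods

## Data model

A *member* is a subject named by a (pedigree, person) pair, with optional
father/mother references (by person name within the same pedigree) and a sex
code; parentage must be acyclic and parents must exist, which is enforced at
load time over the union of the incoming file and the store. *Samples* tie
lab identifiers to members; a member with several samples may mark one as
preferred, in which case the others are ignored during merging. *Markers*
have canonical names plus aliases (for rsID merges and renames), and map
positions (chromosome, bp, optional sex-specific and average cM) per named
*build*, so several builds can coexist. *Traits* are typed qualitative or
quantitative and validated accordingly.

A genotype is an unordered pair of single-character allele codes drawn from
{0, 1–9, A, C, G, T}, stored sorted by code point; `0/0` is the missing
genotype, used both for untyped cells and for masked conflicts. A pair with
exactly one `0` is rejected as malformed rather than silently half-imputed —
no upstream format in use emits half-missing calls, so one is always a
parsing or plumbing error.

## Storage

The backend is sqlite3 (stdlib): a single-file, embedded, fully
transactional engine; all SQL is constructed in Python with no stored
procedures, so the schema ports to any ANSI-ish engine. All write paths run
inside savepoint-scoped transactions, which nest, so a multi-table import is
a single atomic unit.

Targeted experiments store one row per (member, marker, experiment,
technology) call. Genome-wide experiments use a block representation: each
record packs up to B consecutive genotypes for one sample on one chromosome
(2 bytes per genotype — the two allele characters — so a block is a 2B-byte
blob), and a `snpblocks` index maps marker → (chromosome, block, offset).
The chromosome recorded in the index is the chromosome *at load time*: if a
later build moves the marker, selection uses the new build's coordinates
while retrieval still addresses the original slot. The index is keyed by a
named *layout* (one per mapping-file load, defaulting to the mapping file's
stem), so experiments genotyped on the same chip share it.

B defaults to 500 genotypes per block. Block count per chromosome is
⌈m_c/B⌉; trailing slots of the final block are padded with `0/0` and never
surface as data. Unlike the row store (which skips missing genotypes),
blocks are layout-complete: an all-missing sample still occupies the full
block set. The 2-characters-per-genotype encoding was chosen over 2-bit
SNP packing because it represents the full allele alphabet (microsatellite-
style numeric labels included) and keeps the codec trivially invertible; a
bit-packed variant would be a pure optimization behind the same interface.

## Load protocol

Every loader follows the same flag protocol. Without `commit` it parses and
validates only (a dry run never touches the store). `commit` inserts records
whose natural key is absent and *warns* about records that differ from the
store without modifying them; `replace` deletes-then-reinserts changed
records, while `update` modifies them in place (for rows whose ids other
tables reference); `compare` reports differences only; `delete` removes the
listed records. Any error in a committing run — parse failure, integrity
violation, injected fault — rolls back every change of the run, verified in
tests by store checksums. Committing the same file twice is a no-op, and a
run that only produces changed-row warnings still exits 0 (warnings are
advisory; the new rows did load).

Targeted genotype import requires every marker name to be registered
already (internal-consistency check); unknown markers or persons abort the
run. A second measurement for the same (member, marker) within one
experiment that *differs* from the stored call is warned about and kept as a
within-experiment duplicate, so it participates in conflict resolution and
the agreement report rather than being silently dropped.

## Merging

At extraction, each (member, marker) cell is resolved from all of its
measurements: allele maps are applied first (per experiment and marker,
required injective, `0` never remapped; maps are applied at read time so the
vault retains all original data); inactive rows are skipped; non-preferred
samples are dropped when a preferred one exists; missing calls are
discarded; then only calls at the maximal trust level survive. Trust is an
integer per experiment (default 0), overridable per (experiment, marker) —
the override wins, and may be negative to demote a marker inside an
otherwise trusted experiment. If the survivors agree, that value is output;
otherwise the cell is masked to `0/0` and the conflict logged with all
contributing calls. Ties in trust among discordant calls therefore resolve
to missing — the system never guesses between equally trusted measurements,
and never outputs a genotype that none of the inputs contained.

Agreement matrices count joint genotypes for each experiment pair at each
marker over the union of members measured by either experiment (explicitly
stored `0/0` counts as an assayed-missing measurement, so "typed in one
experiment only" mass lands in the `0/0` row/column). Rows are labeled by
the first experiment, and the genotype alphabet is ordered `0/0` first, then
lexicographically.

## Selection

Member filters: include/exclude sets of pedigrees and persons (exclusion
wins on overlap), then trait-value predicates (conjunctive), then optional
pedigree completion, which closes the pool over pedigree co-membership.
Completion may reinstate relatives removed by earlier filters — by design,
since its purpose is structural integrity; the invariant is that every
output member's parents are output members or absent from the store. Trait
filters run before completion, so "affecteds plus their families" is the
natural reading of an affection filter with completion on.

Marker filters: explicit name lists (resolved through aliases; a requested
marker with no map info under the chosen build is an error naming it),
whole chromosomes, and inclusive position ranges in bp or cM — always
against the chosen build. Markers lacking a genetic position are excluded
from cM ranges with that semantics made explicit in tests. Exclusion ranges
mask cells to missing before merging, optionally only for listed members,
and `drop_untyped_markers` removes columns with no observation among the
selected subjects. Output order is (chromosome, bp, name): total and
deterministic.

## Export

Members are ordered by (pedigree, person), markers in map order. Dialects:
delimited columnar text; PLINK ped/map; PLINK bed/bim/fam (binary v1,
SNP-major, magic `6c 1b 01`; A1 is the minor allele by count with ties
broken by code point, `0` when unknown; a marker with more than two alleles
after merging is an error naming it); and a Mega2-style annotated trio
(pedigree/names/map with a version header) documented in the writer since
that dialect has no single canonical spec. Missing is `0` in text formats
and the `01` code in bed. A streaming mode formats one person at a time and
gathers no statistics (for runs where statistics bookkeeping would dominate
memory); its output is byte-identical to the buffered path. The frequency
report counts alleles and genotypes per marker directly over the exported
matrix, so it is consistent with the files by construction.

## Synthetic data

The fixture generator emulates the input side of a study: pedigree files
(two founders plus children; parent links but *no* Mendelian transmission —
inheritance checking is out of scope), samples, one qualitative trait, a
marker map, and the same genotype matrix written in every import dialect.
Genotypes are independent biallelic draws with per-marker allele frequencies
uniform on (0.1, 0.9) and i.i.d. missingness (default 5% for the small
study, 2% for the chip-scale study); there is no LD, population structure,
batch effect or genotyping-error model. Passing tests therefore demonstrate
correctness of storage, reconciliation and format round-trips — not
robustness to realistic error processes. A single integer seed drives all
randomness; equal seeds yield byte-identical files.

Two exact-realization builders support diagnostics: one turns a requested
joint genotype count table into two per-member call maps whose recomputed
agreement matrix equals the request cell for cell (counts, not rates), and
one builds a marker map realizing a requested per-chromosome block
occupancy — each chromosome with k blocks holds between (k−1)·B+1 and k·B
markers, with the requested total distributed deterministically smallest
chromosome first. The chip-scale defaults (25,143 markers across 25
chromosomes occupying 63 blocks per sample at B = 500; 1,058 samples) are
the package's reference operating point for block-arithmetic checks; the
acceptance script runs them at full size, which completes in about a minute
on one CPU.

## Numerical and degenerate-input choices

Allele codes sort by byte value, so digit labels precede letters and
comparisons are deterministic. Ranges are inclusive on both ends with
1-based bp coordinates. An empty selector match (e.g. `set_active` on
nothing) is a count of zero, not an error; an empty marker selection is an
error for fixed-width dialects but allowed for columnar output. Re-running a
block import skips samples that already have blocks for the (experiment,
layout) pair, making commits idempotent at sample granularity. `resolve` is
a total function: no measurements at all yields (`0/0`, no conflict).

## Known limitations

No Mendelian-inheritance checking, genotype phasing, or sex-chromosome
dosage handling. No VCF import/export, transposed-PLINK or dosage formats.
No concurrent writers or user/privilege administration. Uncalled imputed
genotypes (posterior-probability triples) and intensity data are not
stored. Within-experiment duplicates are resolved with the same trust
machinery as cross-experiment ones; there is no probabilistic consensus or
quality-score weighting.
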