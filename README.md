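# genovault

A transactional warehouse for pedigree, phenotype and genotype data from
multiple, overlapping genotyping experiments.

Genetic studies of complex traits typically accumulate several rounds of
genotyping: a genome-wide chip first, then targeted follow-up panels on
subsets of the same samples, often produced by different labs with different
sample identifiers, marker names and allele labels. genovault stores all of
that data as originally delivered, indexes it for retrieval by person and
marker, and produces one *coherent, consistent* subset on the way out —
reconciling duplicate measurements instead of hiding them.

## What it does

* **Two genotype representations.** Targeted panels are stored one genotype
  per row. Genome-wide experiments are packed into fixed-capacity blocks —
  one record per (sample, experiment, chromosome, block) holding up to
  *B* = 500 consecutive genotypes — with a `snpblocks` index mapping each
  marker to its (chromosome, block, offset) slot. For a map with
  m<sub>c</sub> markers on chromosome c, each sample occupies
  Σ<sub>c</sub> ⌈m<sub>c</sub>/B⌉ block records; reads of a chromosome or
  position range touch only the blocks that cover it.
* **Aliases and relabelings.** Members and markers may carry alternate
  names; per-(experiment, marker) allele maps translate label schemes
  (e.g. 1/2 → A/C) at extraction time, never rewriting stored data.
* **Conflict resolution.** When a person/marker has multiple measurements,
  missing calls (0/0) are discarded, only calls at the maximal *trust*
  level survive, and discordant survivors are masked to 0/0 and logged.
  Agreement matrices (joint genotype counts per experiment pair) audit the
  overlap.
* **Transactional loading.** Every loader validates first and writes only
  under `--commit`; a plain commit adds *only new* records (changed rows
  warn and stay untouched; `--replace`/`--update` opt in to modification),
  and any error rolls the whole run back.
* **Flexible extraction.** Filter by pedigree/person (with optional
  pedigree completion so family structures stay intact), trait values,
  marker lists, chromosomes and bp/cM ranges, experiments/technologies;
  export as delimited text, PLINK ped/map, PLINK bed/bim/fam or a
  Mega2-style trio, with allele/genotype frequency statistics.

## Worked example

```python
from genovault import Database, SelectionSpec, PositionRange
from genovault.export import extract
from genovault.fixtures import load_marker_lookup_example

db = Database()                      # in-memory store
info = load_marker_lookup_example(db)  # one member, two experiments

# markers on chr1 between 10 Mb and 20 Mb (current build)
res = extract(db, SelectionSpec(build="current",
                                ranges=[PositionRange(1, 10_000_000, 20_000_000)]))
print([m[1] for m in res.markers])
# ['rs123451', 'rs123452']

# a marker renamed to rs34567 and remapped from chr2 to chr3: selectable by
# either name or by chr3, although its blocks were stored under chr2
res = extract(db, SelectionSpec(build="current", chromosomes={3}))
print(res.markers[0][1], res.call(0, 0))
# rs456784 G/T

# merging the doubly-genotyped member across both experiments
res = extract(db, SelectionSpec(build="current",
                                marker_names={"rs123401", "rs123451", "rs123452"}))
print([str(res.call(j, 0)) for j in range(3)], len(res.conflicts))
# ['A/C', '0/0', 'A/C'] 1
```

The first marker is missing in one experiment, so the measured A/C wins; the
second is 1/2 in one experiment and G/T in the other at equal trust, so it is
masked to 0/0 and logged as a conflict; the third agrees.

The same flows run from the shell via the `genovault` command
(`createdb`, `member`, `sample`, `marker_info`, `geno`, `genoi`, `genoa`,
`genok`, `genout`, ...), each driven by an INI config file, writing a
timestamped log, and mutating nothing without `--commit`.

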