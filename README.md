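# probegrid

Degenerate oligonucleotide probe design for SSU rRNA phylogenetic
microarrays (POAs), with curated group databases, explorative probes, and
load-balanced parallel specificity screening.

## The problem

Phylogenetic oligonucleotide arrays profile microbial communities by
hybridizing small-subunit rRNA genes (16S for prokaryotes, 18S for fungi)
against probes that are specific to taxonomic groups — typically genera.
Designing such probes at scale requires:

1. a **curated group database**: full-length, high-quality, correctly
   oriented, non-redundant, taxonomically homogeneous sequence sets per
   group;
2. **degenerate consensus probes**: each group's alignment is condensed
   into one IUPAC consensus, and every gap-free window of length *l* with
   degeneracy ≤ MaxDeg is a candidate probe. Its expansions split into
   *known* probes (observed verbatim in a group member) and *explorative*
   probes — unobserved recombinations of observed variation that can
   detect relatives not yet deposited in public databases;
3. **specificity screening**: a candidate is rejected when its expansions
   accumulate more than MaxXH cross-hybridizations, i.e. ungapped matches
   at similarity ≥ *S* to non-target sequences on either strand;
4. **load balancing**: screening cost is proportional to probe degeneracy,
   so candidate probes are distributed over *N* jobs by sorting descending
   by weight (= degeneracy) and assigning each probe worst-fit to the job
   with the most remaining capacity. Job loads then differ by at most one
   probe's weight, in contrast to splitting the consensus into *N* equal
   parts, which leaves the per-job degeneracy wildly uneven.

Default parameters: *l* = 25, MaxDeg = 2000, *S* = 0.88 (inclusive),
MaxXH = 100.

The toolkit runs entirely locally: jobs execute on a process pool with
bounded retries, and the merged result file is canonically ordered, hence
byte-identical for any job count. A synthetic fixture generator emulates
genus-like groups (shared template, controlled divergence, planted
duplicates, reversed entries, short fragments, and outliers) so that
every stage is testable without downloads.

## Worked example

```python
from probegrid import DesignParameters, load_stats
from probegrid.curation import CurationCriteria
from probegrid.fixtures import FixtureSpec, generate_fixture
from probegrid.pipeline import run_design

fix = generate_fixture(FixtureSpec(n_groups=3, sequences_per_group=6,
                                   template_length=600, seed=1))
crit = CurationCriteria(min_length=400, max_length_prokaryote=800,
                        max_length_fungi=900)          # scaled with the fixture
result = run_design(fix.records, fix.reference,
                    DesignParameters(job_count=4), crit, seed=1)

print("groups kept:", [(g.taxon, len(g)) for g in result.groups])
print("candidate probes:", len(result.probes))
print("job loads:", result.partition.loads,
      "std: %.2f" % load_stats(result.partition.loads).sample_std)
```

prints

```
groups kept: [('genus00', 7), ('genus01', 7), ('genus02', 7)]
candidate probes: 1728
job loads: [8378.0, 8378.0, 8378.0, 8378.0] std: 0.00
```

Each fixture group enters curation with 10 records; the short fragment is
rejected, the duplicate and the divergent outlier are removed, and the
reverse-complemented entry is flipped back, leaving 7 members. The 1,728
gap-free consensus windows are spread over 4 jobs whose total degeneracy
loads are exactly equal here (worst-fit guarantees they differ by at most
one probe's degeneracy). `result.results` is the merged per-expansion
table (probe position, degenerate sequence, expansion, known/explorative
label, acceptance status, cross-hybridization count), and `result.hits`
lists each individual cross-hybridization with strand, subject position,
similarity, and 1-based mismatch positions.

The same run is available from the shell:

```bash
probegrid fixture --out fx --groups 3 --seqs 6 --template-length 600 --seed 1
probegrid pipeline --config run.cfg          # key = value file, see docs
```

plus stage-wise subcommands (`curate`, `align`, `design`, `partition`,
`run`, `merge`) operating on FASTA/TSV intermediates.

## Layout

- `probegrid.seq_core` — IUPAC algebra, records, FASTA/taxonomy I/O
- `probegrid.curation` — filtering, orientation, dereplication, homogeneity
- `probegrid.alignment` — pairwise/progressive alignment, subgroup
  clustering, profile merging (alignment-of-alignments)
- `probegrid.consensus_design` — IUPAC consensus, probe enumeration,
  known/explorative classification
- `probegrid.specificity` — seed-and-extend cross-hybridization screening
- `probegrid.partition_exec` — worst-fit partitioning, load statistics,
  local executor with retries
- `probegrid.fixtures`, `probegrid.config`, `probegrid.pipeline`,
  `probegrid.cli` — synthetic data, configuration, orchestration

See `docs/methods.md` for the model, parameter, and design details.
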