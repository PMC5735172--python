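# Methods

## Library model

The simulator and the pipeline share one model of a 3′RACE-seq amplicon
library. A molecule is an RNA fragment that starts at the amplicon anchor
(the first base matching the gene-specific forward primer), ends at a true
3′ extremity drawn from a discrete end distribution, and optionally carries
a non-templated 3′ tail. The ligated adapter contributes, in read-2
coordinates, 15 randomized nucleotides (cycles 1–15), a 5-nt delimiter
(cycles 16–20) and then the reverse complement of [templated insert +
tail]. Read 1 is the first 41 nt of the sense amplicon. When the insert is
shorter than the 81 insert-side cycles of read 2, the read runs through the
reverse complement of the forward primer and into upstream sequence; a
fixed 25-nt outer handle stands in for the non-genomic context beyond the
simulated reference.

Tunable parameters, with defaults chosen as a realistic study condition:

| parameter | default | meaning |
|---|---|---|
| `end_distribution` | ¼ each at 161/168/176/186 | true 3′-end mixture (reported coordinates); the four major 5′ ETS P-P1 intermediates |
| `tail_probability` | 0.3 | per-molecule probability of a non-templated tail (up to ~35% of intermediates are tailed in vivo) |
| `tail_length_distribution` | geometric, decay 0.65, truncated at 30 nt | ~35% single-nucleotide tails, none longer than the 30-nt trimming ceiling |
| `tail_composition` | A 0.85, C/G/T 0.05 | A-rich tails (74–94% A observed for 2–30 nt tails) |
| `duplication_mean` | 1.5 | mean PCR copies per molecule, drawn as 1 + Poisson(mean − 1) |
| `error_rate` | 0 | per-base substitution probability (no indels; the pipeline has no indel handling) |
| `read1_length`, `read2_length` | 41, 101 | MiSeq cycle setting |

Base qualities are written as a constant 'I' — the pipeline never reads
them. All randomness flows from a single integer seed; identical seeds give
byte-identical FASTQ output.

## What the truth table asserts, and what it cannot

Minimal-depth trim-and-map has an inherent identifiability limit: a true
tail whose first k bases equal the next k reference bases is absorbed into
the templated sequence, so the call reports a deeper end and a shorter
tail. This is a property of the method, not of any implementation. The
truth table therefore records, per molecule, the *expected* observable call
(`expected_end`, `expected_tail`) derived analytically from the absorption
rule, plus an `expected_fate`:

* `retained` — expected call equals the simulated truth;
* `shifted` — retained, but absorption moves the end/tail;
* `second_nt_match`, `stretch_filter`, `upstream_of_primer`,
  `unmapped_after_30`, `too_short` — expected discards;
* `umi_collision` — a later molecule sharing (read 1, randomized tag) with
  an earlier one; lost to deduplication (~1 per 50,000 molecules over 4¹⁵
  tags).

Expected fates are exact at `error_rate = 0` and `duplication` handled by
first-occurrence deduplication; with sequencing errors they are
approximate and the round-trip guarantees are not asserted.

`generate_reference` fixes the two reference bases immediately downstream
of each canonical peak to C and G. Real intermediates likewise sit in a
fixed reference context; pinning a non-A context keeps absorption of the
A-rich tails rare (~5% of tailed molecules) so that parameter recovery at
the canonical peaks is meaningful. This choice is part of the generator's
design, made once; the residual, method-inherent bias is visible in the
recovered tailing fraction (≈ 28.5% for a simulated 30%).

What passing tests do **not** show about real data: ligation bias, reverse
transcription drop-off, indels, quality-dependent errors and genomic
polymorphism are not modelled, so recovery rates here are upper bounds on
real-library behaviour.

## Pipeline rules and numerical choices

* **Deduplication** keeps the first occurrence per key; qualities are
  unused so any representative is equivalent, and first is deterministic.
* **Target search** is Hamming with one allowed mismatch; N counts as a
  mismatch. A read matching two targets raises an error rather than being
  silently resolved (impossible with the shipped panel).
* **Delimiter check** is positional (cycles 16–20, exact) by default; the
  adapter architecture fixes its location. `delimiter_mode="search"`
  restores a literal substring test.
* **Primer run-in removal** requires an exact match of the forward search
  sequence in the sense insert; a mismatched primer copy leaves the read
  unstripped, which then typically fails exact mapping. The insert begins
  at the first templated base after the primer; consequently, amplicons
  whose templated extent past the primer is shorter than the 20-nt length
  floor are unobservable under this dialect, and short-extension 5.8S
  species must be simulated with ends ≥ primer 3′ end + 20.
* **Mapping** is exact (no mismatches) within an amplicon window from the
  anchor to 600 nt downstream (amplicons are short; the window suppresses
  spurious matches). Multiple exact placements are surfaced as no-match
  ("ambiguous") rather than resolved arbitrarily. Minimal trim depth wins,
  so the trim depth always equals the tail length.
* **Second-nucleotide rule**: a candidate tail of ≥ 2 nt whose second base
  equals the reference base two positions past the mapped end is discarded
  as a probable terminal mismatch followed by templated sequence.
  Single-base tails have no second base and are exempt. When the mapped end
  is so close to the window edge that the comparison base does not exist,
  the rule cannot apply and the tail is kept.
* **Stretch filter**: tails of length ≥ 7 / ≥ 11 / ≥ 16 need ≥ 1 / 2 / 3
  stretches of AAA or TTT ("longer than 6, 10, 15" read strictly).
  Stretches are counted greedily left-to-right, non-overlapping, over the
  union pattern set, which attains the maximum non-overlapping count for
  3-mers; `stretch_mode="overlapping"` switches the dialect.
* **Coordinates** are 1-based, fully closed, on the sense strand; raw
  position 1 is the anchor base, and a per-amplicon offset maps raw ends to
  reporting coordinates (5′ ETS: length from the P site; 5.8S precursors:
  position 1 = first base after the mature 3′ end).
* **Densities** are normalized by all retained calls for the
  library/target, so ends outside a plotted range still count in the
  denominator. Quartiles use linear interpolation between order statistics
  (the common statistical-software default); whiskers follow Tukey's
  1.5 × IQR rule. Profiles are strictly per replicate; only tail-length box
  statistics pool replicates, and only when the caller concatenates them
  explicitly.
* **Peak detection** (`min_density 0.02`, `min_separation 2`) labels local
  maxima `P<position>`; the defaults separate intermediates 7 nt apart
  while ignoring shot noise. Peak calling is a convenience for synthetic
  data; on real libraries the major intermediates are usually identified by
  inspection.

## Conservation module

The residue panel is defined on Arabidopsis RRP41 numbering: the
phosphate-coordination pentapeptide DGGTR at 127–131 (with per-position
conservative substitutions: D→E, T→S/V, R→K/H; glycines strict), the
non-critical S132, and the critical Mg²⁺-coordinating aspartate D174
(D→E conservative). The RNA-binding position set defaults to empty and is
user-editable: its exact membership is not pinned down by the source
material, so the default panel encodes only positions with explicit
support. Verdicts: `active` = all critical positions exact; `partial` = no
critical deviation beyond a listed conservative substitution; `inactive`
otherwise. With this panel the three characterized motifs behave as
expected: DGGTR → active, DGGVK → partial, the R131Y/S132A/D174A context
(mimicking the degenerate GGTYAA of human RRP41) → inactive.

For unaligned sequences the panel is anchored on the best DGGTR-like window
(≥ 3/5 class-compatible positions required) and other positions are read at
fixed offsets from it — adequate for scanning, but indels between the motif
and D174 are not modelled; `classify_alignment` transfers positions through
a user-supplied alignment instead and should be preferred when one exists.

Logo columns score log₂(20) − H, gaps excluded from the frequencies
(columns with > 50% gaps are flagged); the WebLogo-style small-sample
correction is available behind a flag but off by default.

`synthetic_orthologue_set` builds a synthetic cohort (scaffold with the
wild-type panel residues, 5% background divergence outside panel positions,
plus DGGVK/inactive variants as requested). It exists to exercise the
classifier and group tallies at realistic cohort sizes — it is a labelled
stand-in, not the real orthologue sets.

## Problem sizes

The shipped validation runs use 50,000 simulated molecules (≈ 75,000 read
pairs at 1.5× duplication) for the 5′ ETS library, 20,000 for the mature
5.8S library, 1,000 random instances for trim-oracle equivalence, and
exhaustive enumeration of all ≤ 8-nt tails (87,380 cases) for the filter
truth tables. These sizes give binomial standard errors well inside the
asserted tolerances (e.g. ± 0.002 on a 0.3 fraction at n = 50,000).

## Known limitations

* Exact matching only: a single internal sequencing error discards a read
  (or, near the 3′ end, converts it into a candidate tail that the
  second-nucleotide rule must catch).
* The primer-stripping dialect makes short after-primer extensions
  unobservable (see above).
* One library per invocation; no demultiplexing, no quality trimming, no
  differential testing between genotypes.
* The conservation calls are only as good as the panel; for taxa with
  insertions near the motif, alignment-based transfer is required.
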