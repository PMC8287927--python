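# Methods

## Model and scope

`busscan` treats the basal unwinding system (BUS) as a linear sequence
module on one strand of a replication origin: a reference DnaA-box,
optionally a second (tandem) box, a spacer, and a maximal run of N-A-N
DnaA-trios. The scanner consumes *predicted* origin sequences — it does not
locate origins in whole genomes — and makes at most one call per input
record (one record = one origin; multi-chromosome genomes and plasmid
origins are out of scope). Matching is purely positional: Hamming distance
for boxes, exact N-A-N pattern for trios, no indels anywhere.

Conventions:

* **Strands.** Both strands are scanned by default (`both_strands=False`
  restricts to plus). Strand "−" means the scan ran over the reverse
  complement; internal coordinates are 0-based half-open on the scanned
  strand, all emitted coordinates are 1-based inclusive on the forward
  strand of the input, with sequence columns holding forward-strand slices.
  The motif-strand trios (box-proximal first) are carried separately in the
  `trios` column because the cohort statistics need them.
* **Ambiguity.** An N in a *sequence* never matches any motif position —
  ambiguity in data must not create hits. An IUPAC code in a user-supplied
  *motif* is a wildcard over its expansion. Trios tolerate no N at all.
* **Trio orientation.** The trio consensus is conventionally written
  3'-GAT-5'; on the scanned strand written 5'→3' this is TAG. All internal
  matching uses 5'→3' strings; this conversion is made once, here.

## Search parameters

| Parameter | Default | Meaning |
|---|---|---|
| `max_mm_sole_9` | 2 | mismatch cap, sole 9 bp box |
| `max_mm_primary_tandem_9` | 2 | cap for the more conserved box of a 9 bp pair |
| `max_mm_secondary` | 4 | cap for the less conserved box of a pair |
| `max_mm_long_motif` | 3 | sole/primary cap when the standard motif is > 9 bp |
| `max_spacer` | 16 bp | box-to-trios distance for the first-located box |
| `min_trios` | 3 | minimum N-A-N repeats in a qualifying run |
| `preferred_spacer` | 13 bp | spacer preference applied by screening filter 3 |
| `max_interbox_gap` | 3 bp | gap allowed between tandem boxes (upstream window) |
| `trio_scoring` | consensus-weighted | see below |

The 16 bp spacer cap is the sum of its anatomical parts: up to 3 bp between
tandem boxes + a 9 bp secondary box + a ~4 bp second gap. When an upstream
second box is strictly better conserved than the first-located box it
becomes the reference and the spacer is recounted from it, which is the one
case a reported spacer exceeds 16 bp.

## Trio scoring

No closed-form definition of the trio score accompanies the rule set, so
the score is pluggable. The default, **consensus-weighted count**, rewards
the two properties screening needs — run length and consensus content:
each trio contributes `w_full` (3.0) if it equals TAG, else `w_partial`
(1.0). Two alternatives are selectable in config: **count** (score = number
of trios) and **matrix** (user-supplied per-position base weights, summed
over trios). All screening tests and planted-fixture guarantees hold for
the default scheme; the matrix scheme is for users who have trained
position weights of their own.

## The screening cascade

Filters apply in a fixed order — highest trio score, fewest mismatches in
the sole/more-conserved box, spacer closest to `preferred_spacer` — and
each can only shrink the candidate set. Score comparison uses a 1e-9
absolute tolerance (scores are small sums of user weights); mismatch and
spacer comparisons are exact integers. Survivors of filter 3 are counted in
`tie_count` and the retained call is the first survivor in a documented
total order: plus strand before minus, then smaller reference-box offset,
then smaller trio offset. Equal-mismatch tandem pairs are genuinely
ambiguous about which box anchors; enumeration keeps both readings and the
spacer filter (then the positional tie-break) decides.

Candidate enumeration deduplicates by (strand, reference box, secondary
box, trio run), so the same physical module reached from either box of a
tandem pair is counted once; `candidates_considered` reports the deduplicated
count.

## Synthetic origins

The generator (`busscan.simulate`) emulates DoriC-style inputs: one planted
module per origin on a random background of controlled length (default
~module + 40–120 bp) and GC content (0.35–0.65 in the sampler), on either
strand. It emulates *module geometry*, not real genomic base composition:
backgrounds are i.i.d., carry no AT-skew, no DnaA-box clusters and no
regulatory context, so passing recovery tests demonstrates the rule cascade
is implemented exactly — not that real origins are this clean. On real data
multiple same-origin candidates and residual ties are expected and are
surfaced via `candidates_considered` and `tie_count` rather than hidden.

Plant recipes (`PlantSpec`) control box mismatch counts, arrangement (sole,
tandem with downstream second box, tandem with upstream takeover), gaps,
spacer, trio count and composition. Three design rules keep the recorded
ground truth the *unique* correct answer:

* **Strict conservation order in tandem plants.** The anchoring box must
  have strictly fewer mismatches than its partner; with equal mismatches
  both anchoring readings are legitimate and screening, not the plant,
  would pick one.
* **Run-edge hygiene.** The two bases before the trio run, the first base
  of trio 1, the third base of the last trio and the two bases after the
  run are kept away from A, so no same-phase extension or phase-shifted run
  can reach the planted run's length or score. Gap lengths that would place
  a motif adenine (e.g. the terminal A of TTATCCACA) in the run's extension
  frame are rejected as ill-posed at validation time — for the default
  motif this excludes a 1 bp spacer in sole plants and 0–1 bp trio gaps in
  tandem plants.
* **Background repair.** "Clean background" is enforced by bounded
  repair-resampling: the assembled sequence is scanned for spurious box
  hits (within the first-located cap anywhere on either strand; within the
  secondary cap inside the module's secondary-search windows) and for
  qualifying trio runs outside the planted locus, and offending positions
  outside the plant are redrawn from {C, G}; the scan-repair loop iterates
  (≤ 120 rounds, ≤ 40 fresh attempts) until clean. Whole-sequence rejection
  sampling would essentially never terminate — a random 300 bp background
  carries several qualifying N-A-N runs in expectation. Box-like windows
  confined to the trio block itself (some trio compositions spell a near
  reverse complement of the motif) are left in place: they cannot be
  repaired without touching planted bases and any candidate they seed
  scores strictly below the plant.

Every generated origin is finally **verified by the scanner itself**: an
in-range plant must be recovered exactly (strand, reference box, spacer,
trio count), an out-of-range one must produce no call; generation raises
with the seed rather than emit a fixture whose truth the search could
legitimately contradict. Generation is deterministic per spec and seed.

Negative controls (`generate_negative`) apply the same repair with no
plant: no box within the first-located cap and no qualifying run on either
strand, re-verified by a scan.

## Numerical and degenerate-input choices

* Sequences shorter than `len(motif) + 3·min_trios` are flagged
  unsearchable and produce a found=false row, not an error; records with
  non-ACGTN characters are rejected with a logged reason and the run
  continues.
* A motif longer than the sequence yields no hits; empty inputs yield
  empty outputs plus a warning.
* With several admissible secondary boxes, the fewest mismatches wins,
  preferring the downstream (in-module) placement, then proximity to the
  first box. A downstream secondary never becomes the reference.
* Prevalence over zero origins is reported as 0 with
  `prevalence_defined=false`.
* Per-phylum summaries group by the first lineage rank ("unclassified"
  when absent) and are reported only for phyla with ≥ 1 found origin and
  ≥ `min_genomes` (default 15) sampled origins.
* The tandem fraction is computed over all found origins of a group.

## Problem sizes used by the test suite

Scanner-versus-brute-force equivalence runs on 1000 random sequences of up
to 300 bp (2% N); planted-module recovery on 500 sampled recipes spanning
the legal rule ranges plus 200 background-only negatives; boundary sweeps
construct one probe origin per parameter value on a GC-only inert
background. These sizes exercise every rule boundary and both strands while
keeping the default suite fast; they are not calibrated to any external
dataset.

## Known limitations

* The trio score is a package definition (see above), not a community
  standard; cohort statistics that depend on score ties may differ under
  other schemes.
* Maximal trio runs are always used; a module whose box adenine extends the
  run in frame is reported with the extended run's geometry (or not at all
  if the spacer becomes negative), which is why such layouts are excluded
  from plants.
* Species-specific divergent box motifs are accepted as IUPAC strings per
  record; nothing is inferred about which species need them.
* No statistical enrichment testing, tree building or figure rendering:
  the cohort module emits the data tracks (trio score, spacer, box
  conservation, tandem flag) for external annotation tools.
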