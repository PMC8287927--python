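# busscan

Rule-based detection of the **basal unwinding system (BUS)** in bacterial
replication origins.

Bacterial DNA replication starts at *oriC*, where the initiator protein DnaA
opens the duplex. The sequence module that directs this unwinding — the BUS —
consists of one or two **DnaA-boxes** (9 bp double-strand binding sites,
highest-affinity consensus 5'-TTATCCACA-3'), a short **spacer**, and a run of
at least three **DnaA-trios** (single-strand binding trinucleotides matching
N-A-N, consensus 3'-GAT-5', i.e. TAG read 5'→3' on the scanned strand). DnaA
binds the boxes, then oligomerizes along the trios to stretch and separate
the strands.

`busscan` scans predicted origin sequences (e.g. DoriC-style dumps) for this
module and is aimed at people doing comparative genomics of replication
initiation: given a FASTA or table of origins it emits at most one BUS call
per origin plus cohort-level survey statistics.

## The search in brief

For each origin and each strand:

1. **Candidate enumeration.** Every maximal N-A-N run with ≥ 3 trios is
   paired with every upstream DnaA-box match whose Hamming distance to the
   standard motif is ≤ 2 (≤ 3 for motifs longer than 9 bp) and whose spacer
   (bases between the box 3' end and the first trio) is 0–16 bp. For each
   pair a second box (≤ 4 mismatches) is sought inside the spacer or
   immediately upstream (gap ≤ 3 bp); a strictly better-conserved upstream
   second box becomes the reference box and the spacer is recounted from it
   (the only way a reported spacer exceeds 16 bp). Indels are never
   considered; N in a sequence matches nothing, while IUPAC codes in a
   user-supplied motif act as wildcards.
2. **Screening cascade.** Three filters in fixed order reduce the candidates
   to one call: highest trio score (default: 3 per consensus TAG trio, 1 per
   other N-A-N trio), then fewest mismatches in the sole/more-conserved box,
   then spacer closest to 13 bp. Residual ties are broken deterministically
   (plus strand first, then leftmost reference box) and reported via
   `tie_count`.

The rule thresholds (2/4/3 mismatches, 16 bp spacer, ≥ 3 trios, 13 bp
preference) are all adjustable through `SearchParams` / a YAML config.

## Worked example

```python
from busscan import OriginRecord, search_origin
from busscan.io import results_to_table
from busscan.simulate import inert_background

seq = (inert_background(40) + "TTATCCACA" + inert_background(13, 3)
       + "TAG" * 5 + inert_background(40, 7))
origin = OriginRecord(id="demo_oriC", sequence=seq)
row = results_to_table([search_origin(origin)]).iloc[0]
```

Running `python examples/01_scan_one_origin.py` (the same construction)
prints:

```
found=True strand=+ tie_count=1
box: 41-49 TTATCCACA (0 mismatches)
spacer: 13 bp
trios: 63-77 x5 score=15.0
```

One unambiguous call: the box occupies forward-strand positions 41–49
(1-based, inclusive), a perfect match to the consensus; 13 bp separate it
from a run of five consensus trios scoring 5 × 3.0 = 15.0. The other
examples plant modules with known ground truth and recover them
(`examples/02_simulate_and_recover.py`, 50/50 exact), and survey a synthetic
cohort (`examples/03_cohort_survey.py`: prevalence, tandem fraction, spacer
histogram, per-position trio base frequencies).

## Command line

```bash
busscan simulate --n 100 --seed 7 --out-fasta syn.fasta --out-truth truth.tsv
busscan search --fasta syn.fasta --out results.tsv        # or --doric table.tsv
busscan summarize results.tsv --out-prefix cohort
```

`search` accepts `--params params.yaml` (keys mirror `SearchParams`),
`--motif` for a different default box, and `--strands plus` to restrict
scanning. Coordinates in all outputs are 1-based inclusive on the forward
strand of the input; sequence columns are forward-strand slices.

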