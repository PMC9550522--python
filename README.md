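# polyxy

Detection, classification and analysis of **polyXY regions** — protein
segments composed of exactly two amino-acid types — the natural next step
up in complexity from homorepeats (polyX).

Low-complexity regions (LCRs) are frequent in proteins, often outside
globular domains, and are linked to disorder, aggregation and phase
separation.  The simplest LCRs are homorepeats; regions built from two
residue types (e.g. the RS domains of SR splicing factors, RG-rich
segments of RNA-binding proteins, or polyQ followed by polyP) form the
next family of candidate sequence motifs.  `polyxy` finds them and
characterizes their internal order.

## Method

A window of length *w* (default 6 residues, which is also the minimum
reportable region length) slides along each sequence.  A window is
**positive** when it contains exactly two distinct standard amino acids,
each occurring at least twice.  Overlapping positive windows of the same
unordered pair {X, Y} are unioned into maximal regions; regions of
different pairs may overlap.  Each region is then assigned to exactly one
category:

- **direpeat** — a perfect tandem repeat of the unit `XY` (equivalently
  `YX`), allowing at most one lone X or Y at a terminus or between units,
  e.g. `SRSRSR`, `GLGLGLG`.  The number of complete units is reported
  (`⌊length/2⌋`; at *w* = 6 the smallest direpeat has 3 units).
- **joined** — a run of X immediately followed by a run of Y (both runs
  ≥ 2), e.g. `VVVGGG`.  The order X→Y is biologically meaningful and is
  recorded.
- **shuffled** — everything else, e.g. `SSGGSGG`; shuffled regions can
  optionally be searched for embedded joined/direpeat sub-spans.

Downstream statistics: dataset totals and ratios, category proportions,
per-amino-acid usage versus proteome background, relative positions
(region midpoint / protein length), direpeat unit-count distributions,
joined-order asymmetry (two-sided Mann–Whitney U on position samples),
and containment of regions within domain or predicted-disorder intervals
compared with equally long segments placed uniformly at random in the
same proteins.

## Worked example

```sh
$ polyxy scan --in demo.fasta --out regions.tsv
2 proteins scanned: 3 polyXY regions (1 direpeats, 1 joined, 1 shuffled)

$ cat regions.tsv
protein_id	start	end	pair	sequence	category	n_units	joined_order
sp|Q16637|SMN_HUMAN	4	10	GS	SSGGSGG	shuffled
demo2	3	11	GL	LGLGLGLGL	direpeat	4
demo2	14	19	GV	VVVGGG	joined		VG
```

Coordinates are 1-based and inclusive.  The first row is the N-terminal
polySG of the human SMN protein at positions 4–10: its serines and
glycines are interleaved, so it is *shuffled*.  The second is a
glycine–leucine *direpeat* with 4 complete `GL` units plus one lone
leucine.  The third is a *joined* region — three valines followed by
three glycines — whose recorded order `VG` distinguishes it from the
reverse arrangement `GV`.

Other subcommands: `polyxy summarize` (dataset summary, composition
usage, unit distribution, joined orders), `polyxy overlap` (containment
in domain/disorder annotations vs the random baseline) and
`polyxy simulate` (synthetic proteomes with an oracle-defined truth
table).  The same functionality is available as a library:

```python
import polyxy
proteins = polyxy.read_fasta("demo.fasta")
regions = polyxy.scan_proteins(proteins)
summary = polyxy.summarize_dataset(proteins, regions)
```

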