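# rnaed

Design and analysis of mRNA secondary-structure **ensemble diversity** under
synonymous-codon constraints.

Because the genetic code is degenerate, a 200-residue protein can be encoded
by roughly 10^86 distinct mRNA sequences. These synonymous sequences fold
into very different *ensembles* of secondary structures, and the breadth of
that ensemble — not any single structure — shapes how an mRNA behaves in
RNA–protein assemblies and biomolecular condensates. `rnaed` is for
computational RNA biologists who want to isolate this property: it designs
synonymous variants of a transcript whose ensemble diversity is pushed as
high or as low as the codon space allows, and provides the ensemble
statistics used to validate and interpret such designs.

## The quantities at the core

For a sequence of length *n* with base-pair probabilities *p<sub>ij</sub>*
(from a McCaskill-style partition function over nested structures),

- **Ensemble diversity**: ED = Σ<sub>i&lt;j</sub> 2 p<sub>ij</sub>(1 −
  p<sub>ij</sub>), the expected base-pair distance (symmetric-difference
  size) between two independent Boltzmann draws; **NED** = ED / n.
- **MFE structure**: argmin of the energy; **centroid**: the structure
  containing exactly the pairs with p<sub>ij</sub> &gt; ½, which minimizes
  the expected distance to the ensemble.
- **Dimer ΔG and ΔED**: for a homodimer, ΔG = G<sub>dimer</sub> −
  2 G<sub>monomer</sub> (and analogously for ED), from a two-strand
  cofolding partition function.
- **Variance identity**: with per-nucleotide pairedness q<sub>i</sub> =
  Σ<sub>j</sub> p<sub>ij</sub> and m = mean(q), it holds exactly that
  Var(q) = m(1 − m) − (1/n) Σ q<sub>i</sub>(1 − q<sub>i</sub>) — the term
  subtracted approximates ED/n, giving an inverse linear ED–variance
  relation.

The folding engine uses a deliberately simple energy model (per-pair-type
energies GC/AU/GU, optional uniform stacking bonus, minimum hairpin size 3,
25 °C) so that every quantity is verifiable against exhaustive enumeration;
see `docs/methods.md`.

The **design algorithm** is an elitist genetic algorithm over synonymous
codon moves (substitutions and same-amino-acid codon exchanges) that only
accepts candidates keeping transcript length, UTRs, encoded protein and
motif sites identical, nucleotide composition within 1 %, and per-codon
usage within 10 % of the reference. The **probing simulator** emulates
adenosine-specific single-molecule chemical probing: each read's molecule is
an independent Boltzmann draw, modified at single-stranded adenosines with a
high rate and at paired ones with a low rate, read out on variable-span long
reads; overlap-normalized pairwise distances among the longest reads, and
Jensen–Shannon distances between their distributions, recover the designed
ensemble differences.

## Worked example

```bash
python examples/02_design_ed_variants.py
```

```
reference ED: 108.79
maximize: final ED  113.14  constraints pass: True  protein unchanged: True
minimize: final ED   87.73  constraints pass: True  protein unchanged: True
```

The reference is a 195-nt synthetic transcript (40-codon CDS, three embedded
UGCAU motifs). Ten GA generations push its ensemble diversity up by ~4 base
pairs or down by ~21 while the encoded protein, UTRs, composition, codon
usage and motif sites stay fixed — the two designs differ from the reference
only by synonymous mutations, yet sample visibly broader or narrower
structural ensembles. The other scripts in `examples/` walk through folding
summaries, probing-distance recovery, dimer trends, and the codon-space /
enrichment statistics.

A command-line interface mirrors the library:

```bash
rnaed fixture --seed 5 --out fx
rnaed design --fasta fx/fixture.fa --cds 60:360 --objective max \
      --generations 50 --children 20 --seed 7 --out designs/
rnaed probe-sim --fasta designs/designs.fa --n-reads 1000 --seed 9 --out reads/
```

Every command writes a provenance JSON (seeds, model parameters, config) next
to its outputs.

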