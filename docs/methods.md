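# Methods

## Scope and model

`rnaed` treats an mRNA as a sequence over {A,C,G,U} with a codon-aligned CDS
flanked by frozen UTRs, and its structure as the Boltzmann ensemble of
nested (pseudoknot-free) sets of base pairs. The package's claims are about
ensemble-level quantities — ensemble diversity (ED), pair probabilities,
free energies, dimerization changes, probing-distance statistics — not
about the accuracy of any single predicted structure.

### Energy model

The folding engine uses a simplified pairwise model rather than the full
nearest-neighbour parameter set:

| parameter | default | meaning |
|---|---|---|
| e(GC), e(AU), e(GU) | −3.0, −2.0, −1.0 kcal/mol | energy per base pair, by type |
| stacking_bonus | 0.0 kcal/mol | added per pair whose inner neighbour is also paired; must be ≤ 0 |
| min_hairpin | 3 nt | minimum unpaired length closed by a hairpin pair |
| temperature | 298.15 K | Boltzmann temperature (25 °C) |
| salt_mM | 150 | provenance metadata only; no energetic effect |

This choice trades thermodynamic realism for exact testability: every
engine output (partition function Z, pair probabilities p_ij, ED, MFE) is
verified against exhaustive enumeration of all structures on short
sequences, to 1e−9 relative error, in the test suite. Absolute ED and G
values therefore differ from what a full Turner-parameter engine would
give; all downstream analyses are designed around identities, orderings and
sign patterns, which are insensitive to this. The engine interface
(`FoldTables`) is narrow, so a full-thermodynamics backend can replace it
without touching the design or probing code.

### Algorithms and numerics

*Inside/outside.* Z and p_ij come from McCaskill-style inside and outside
recursions over nested structures, vectorized per column / per span so each
pass is O(n³) with O(n²) numpy work at the Python level. The stacking term
is handled by splitting the paired-interval recursion into
adjacent/non-adjacent branches (exact only for stacking_bonus ≤ 0, which is
enforced).

*Rescaling.* Boltzmann weights are rescaled per nucleotide (the Vienna
strategy): the scale is initialized from the MFE energy
(ln s = 1.02·β|E_mfe|/n + 0.4, the constant absorbing the conformational
entropy of this permissive pair model) and adjusted by bisection whenever
the tables overflow double range or the total underflows. This keeps
sequences of thousands of nucleotides stable without log-domain arithmetic.

*MFE tie-break.* Among co-optimal structures the traceback is
deterministic: an interval whose optimum is 0 returns the open chain;
otherwise the leftmost position is paired to its smallest co-optimal
partner, recursively. (A globally lexicographic-minimal pair set is not
well defined by local choices — an extra early pair can be
lexicographically smaller — so this simpler deterministic rule is used.)

*Sampling.* Structures are drawn by stochastic traceback of the inside
tables; a chi-squared test against enumerated Boltzmann weights validates
the sampler.

*Cofolding.* A dimer is the concatenation A·B with a strand break: pairs
whose span contains the break are exempt from the hairpin rule, and the
ensemble includes fully disconnected configurations. ΔG = G_dimer − (G_A +
G_B) is therefore ≤ 0 by construction (the two-strand ensemble contains the
product of the monomer ensembles), matching the definition that subtracts
monomer free energies rather than conditioning on binding.

*Centroid.* The structure containing exactly the pairs with p_ij > ½; such
pairs can neither clash nor cross (two conflicting pairs cannot both exceed
probability ½), so the result is always valid, and it minimizes the
expected base-pair distance to the ensemble.

## Design algorithm

The GA is (1 + M) elitist by default: each generation draws M
constraint-satisfying children (each child = 1–3 random synonymous moves
from the parent; rejected proposals are resampled up to 100 times), selects
the child with the extreme ED, and keeps the parent if no child improves.
Elitism makes the best-ED series monotone; a (1, M) "best child always
becomes parent" mode is available via `elitist=False`, in which case only
the best-so-far envelope is monotone. The stopping rule is a fixed number
of generations. ED is recomputed from a fresh pair-probability matrix for
every candidate (no incremental updates), which costs O(n³) per evaluation
but removes a whole class of cache-consistency bugs; the feasible scale is
n up to ~2000.

Move kinds: `substitute` replaces one codon by a different synonym (stop
codons excluded unless explicitly allowed); `exchange` swaps the codons of
two positions encoding the same amino acid, preserving codon usage exactly;
`mixed` (default) picks either. Both readings of "swapping codons" are thus
available.

Constraints, checked against the reference on every candidate: transcript
length unchanged; UTRs byte-identical; per-nucleotide composition fractions
within 1 % (absolute, over the full transcript); per-codon counts within
ceil(10 % of the reference count), with codons unused in the reference
remaining unused (the strict count reading of "within 10 % of codon usage";
a frequency reading is a one-line change in `check_constraints`); encoded
protein identical; motif occurrences at identical positions (a count-only
mode is available, but position preservation guarantees that no site is
created or destroyed under any reading).

Panel designs derive per-run seeds from (master seed, design index) via
`numpy.random.SeedSequence`, recorded in provenance, so panels are
reproducible and individually re-runnable.

## Probing simulator and statistics

The simulator emulates adenosine-specific single-molecule chemical probing
read out on long reads. Per read: one structure is drawn from the Boltzmann
ensemble (the modeling assumption that makes read-pair distance a proxy for
ED); a span is drawn (uniform start; lognormal length, default median
0.7 n, truncated to [min_length, n]); each covered adenosine is called
modified with probability 0.25 if unpaired in that draw, 0.02 if paired.
The unprobed control uses 0.02 everywhere, erasing the structural signal
while keeping the read-sampling machinery identical.

The pairwise distance between two reads is the fraction of *shared
adenosine positions* with differing calls (the probe only reports
adenosines); pairs sharing fewer than `min_overlap` adenosines (default 50)
are undefined and counted, not raised. Distances are computed among the
`top_k` longest reads (default 1000; ties by earlier start, then input
order). Jensen–Shannon distances between distance distributions use 50
equal bins on [0,1], base-2 logarithms, and the square root of the
divergence, so values live in [0,1].

What the simulator does not model: base-caller errors correlated along a
read, coverage biases, carry-over of reactivity into refolding
(reactivity-guided structure prediction is out of scope), or any
non-adenosine chemistry. A consequence of drawing reads independently is
that the *expected* pairwise distance at one position depends only on the
marginal call rate; ensemble diversity enters through the pairedness
profile and the across-position covariance within reads. Passing tests
therefore show that the pipeline recovers designed ensemble differences
under these idealized conditions, not that it would quantify ED from any
particular real dataset.

## Statistics

- Enrichment of synonymous substitutions: one-sided binomial tail
  P(X ≥ n_syn) with the null fraction equal to the proportion of all
  single-nucleotide changes to the reference CDS that are synonymous; no
  multiple-testing correction (a single comparison).
- Codon-space size: exact in log10 (sum of per-residue degeneracy logs;
  +log10(3) for the stop codon); for a uniform-composition 200-mer this is
  ~85.8, i.e. ~10^86 sequences.
- ED–variance: the identity Var(q) = m(1−m) − (1/n)Σq(1−q) is algebraic and
  asserted to 1e−12 on every pair matrix; the regression of Var(q) on ED/n
  across an equal-length design panel exposes the inverse linear relation
  (slope ≈ −1 when each nucleotide has a single dominant partner; shallower
  slopes when pairing is spread).
- Correlations are standard Pearson r with two-sided p-values
  (`scipy.stats.pearsonr`).

## Problem sizes in tests and the acceptance script

The shipped analyses are scaled-down analogs chosen so the full pipeline
runs on a laptop core in minutes: oracle panels use sequences of length
≤ 12 (≤ 14 for two strands, where enumeration is exact and fast); the ED
semantics checks use 10-nt sequences and 10⁴ sampled structure pairs; the
GA optimality check uses an 8-codon CDS whose feasible synonymous space is
enumerable; the high/low design panel uses a 300-nt fixture (64-codon CDS,
54-nt UTRs, five motifs) with 40 GA generations of 10 children; probing
uses 1000 reads per design with near-full-length spans (lognormal around
0.9 n) and a 50-adenosine overlap floor; the ED–variance panel uses 20
designs on a 90-nt fixture; the dimer panel uses 46 designs on a 150-nt
fixture. The fixture transcripts are synthetic stand-ins generated by
`rnaed.fileio.make_fixture` (the study organism's transcript sequence is
not part of the package); their sizes are one among several reasonable
choices and the qualitative results (separation, orderings, sign patterns)
do not depend on them.

## Known limitations

- No pseudoknots, no suboptimal-structure enumeration, no 3-D observables
  (radius of gyration, solvent accessibility).
- Under the default (stacking-free) energy model the homodimer ΔG spread
  across same-composition designs is small (~1–2 kcal/mol), so the sign of
  the ED–ΔG correlation depends on the reference sequence; the ED–ΔED
  correlation, by contrast, is robustly negative across references. A
  backend with stacking cooperativity would make inter-strand duplex
  formation more decisive, and the `stacking_bonus` parameter exists for
  that exploration.
- The simplified energy model makes absolute ED/G values model-specific;
  only ensemble identities and cross-design comparisons are meaningful.
- The GA optimizes a single objective with no crossover; it is a local
  stochastic search, and global optimality is only guaranteed (and tested)
  on enumerable toys.
- Reads are positionally exact (no alignment step); transcript coordinates
  are assumed known.
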