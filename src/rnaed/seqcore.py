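"""Sequence, codon and constraint logic for synonymous mRNA design.

The design algorithm mutates only the coding sequence (CDS) of a transcript,
never changing the encoded protein, the UTRs, the transcript length, the
nucleotide composition (beyond a small tolerance), per-codon usage (beyond a
small tolerance) or the occurrences of a protein-binding motif.  This module
provides the :class:`Transcript` container, the codon table, the synonymous
move proposers used by the genetic algorithm, the constraint checker, and two
desk statistics: the synonymous-substitution enrichment test and the
(logarithmic) size of the synonymous coding space.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from Bio.Data import CodonTable as _BioCodonTable
from scipy import stats as _stats

RNA_ALPHABET = frozenset("ACGU")

__all__ = [
    "RNA_ALPHABET",
    "CodonTable",
    "STANDARD_TABLE",
    "Transcript",
    "ConstraintSpec",
    "ConstraintReport",
    "ConstraintResult",
    "SubstitutionReport",
    "NoSynonymousMoveError",
    "translate",
    "propose_synonymous_move",
    "check_constraints",
    "scan_motif",
    "classify_substitutions",
    "synonymous_space_size",
]

STOP_SYMBOL = "*"


def _normalize_rna(seq: str) -> str:
    """Uppercase and transcribe T->U; raise on anything outside {A,C,G,U}."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid characters in RNA sequence: {sorted(bad)}")
    return s


class CodonTable:
    """Mapping of all 64 RNA codons to amino-acid symbols (stops to ``*``).

    Wraps a Biopython NCBI table.  Degeneracy counts and synonym lists are
    precomputed; they drive both the move proposers and the codon-space
    combinatorics.
    """

    def __init__(self, ncbi_id: int = 1):
        bio = _BioCodonTable.unambiguous_rna_by_id[ncbi_id]
        fwd = dict(bio.forward_table)
        for stop in bio.stop_codons:
            fwd[stop] = STOP_SYMBOL
        if len(fwd) != 64:
            raise ValueError("codon table must cover all 64 codons")
        self.codon_to_aa: dict[str, str] = fwd
        self.aa_to_codons: dict[str, tuple[str, ...]] = {}
        for codon, aa in sorted(fwd.items()):
            self.aa_to_codons.setdefault(aa, ())
            self.aa_to_codons[aa] = self.aa_to_codons[aa] + (codon,)
        self.degeneracy: dict[str, int] = {
            aa: len(cods) for aa, cods in self.aa_to_codons.items()
        }
        self.start_codons: frozenset[str] = frozenset(bio.start_codons)
        self.stop_codons: frozenset[str] = frozenset(bio.stop_codons)

    def synonyms(self, codon: str) -> tuple[str, ...]:
        return self.aa_to_codons[self.codon_to_aa[codon]]


STANDARD_TABLE = CodonTable(1)


def translate(
    cds: str, table: CodonTable = STANDARD_TABLE, warn_internal_stop: bool = True
) -> str:
    """Translate a codon-aligned RNA string, one symbol per codon.

    Internal stop codons are reported through the warning channel (they are
    legal in designed fixtures only as the terminal codon).
    """
    s = _normalize_rna(cds)
    if len(s) % 3:
        raise ValueError(f"CDS length {len(s)} is not a multiple of 3")
    protein = "".join(table.codon_to_aa[s[i : i + 3]] for i in range(0, len(s), 3))
    if warn_internal_stop and STOP_SYMBOL in protein[:-1]:
        warnings.warn(
            f"internal stop codon at codon {protein.index(STOP_SYMBOL)}",
            stacklevel=2,
        )
    return protein


@dataclass(frozen=True)
class Transcript:
    """An mRNA with CDS bounds (0-based half-open) and a binding-site motif."""

    seq: str
    cds_start: int
    cds_end: int
    motif: str = "UGCAU"
    name: str = "transcript"

    def __post_init__(self):
        object.__setattr__(self, "seq", _normalize_rna(self.seq))
        object.__setattr__(self, "motif", _normalize_rna(self.motif))
        if not (0 <= self.cds_start < self.cds_end <= len(self.seq)):
            raise ValueError(
                f"CDS bounds [{self.cds_start}, {self.cds_end}) out of range "
                f"for length {len(self.seq)}"
            )
        if (self.cds_end - self.cds_start) % 3:
            raise ValueError("CDS length must be a multiple of 3")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def cds(self) -> str:
        return self.seq[self.cds_start : self.cds_end]

    @property
    def utr5(self) -> str:
        return self.seq[: self.cds_start]

    @property
    def utr3(self) -> str:
        return self.seq[self.cds_end :]

    @property
    def codons(self) -> list[str]:
        c = self.cds
        return [c[i : i + 3] for i in range(0, len(c), 3)]

    def with_cds(self, new_cds: str, name: str | None = None) -> "Transcript":
        if len(new_cds) != self.cds_end - self.cds_start:
            raise ValueError("replacement CDS must keep the transcript length")
        return replace(
            self,
            seq=self.utr5 + new_cds + self.utr3,
            name=self.name if name is None else name,
        )

    def validate_orf(self, table: CodonTable = STANDARD_TABLE) -> list[str]:
        """Warn-level ORF checks: start codon first, stop codon last."""
        issues = []
        cods = self.codons
        if cods and cods[0] not in table.start_codons:
            issues.append(f"CDS does not begin with a start codon ({cods[0]})")
        if cods and cods[-1] not in table.stop_codons:
            issues.append(f"CDS does not end with a stop codon ({cods[-1]})")
        return issues


class NoSynonymousMoveError(Exception):
    """Raised when the CDS admits no synonymous move of the requested kind."""


MoveKind = Literal["substitute", "exchange", "mixed"]


def propose_synonymous_move(
    t: Transcript,
    rng: np.random.Generator,
    kind: MoveKind = "mixed",
    table: CodonTable = STANDARD_TABLE,
    allow_stop_swap: bool = False,
    _max_tries: int = 200,
) -> Transcript:
    """Propose one random synonymous change to the CDS.

    ``substitute`` replaces a single codon by a different synonym;
    ``exchange`` swaps the codons of two positions encoding the same amino
    acid (preserving codon usage exactly); ``mixed`` picks either uniformly,
    falling back to the other when one kind is impossible.  Stop codons are
    excluded from substitution unless ``allow_stop_swap``.
    """
    cods = t.codons
    protein = [table.codon_to_aa[c] for c in cods]

    def movable(i: int) -> bool:
        if protein[i] == STOP_SYMBOL and not allow_stop_swap:
            return False
        return table.degeneracy[protein[i]] > 1

    sub_sites = [i for i in range(len(cods)) if movable(i)]

    exch_pairs: dict[str, list[int]] = {}
    for i, aa in enumerate(protein):
        exch_pairs.setdefault(aa, []).append(i)
    # an exchange only changes the sequence if the two codons differ
    exch_aas = [
        aa
        for aa, sites in exch_pairs.items()
        if len({cods[i] for i in sites}) > 1
    ]

    if kind == "mixed":
        options = []
        if sub_sites:
            options.append("substitute")
        if exch_aas:
            options.append("exchange")
        if not options:
            raise NoSynonymousMoveError("CDS admits no synonymous move")
        kind = options[int(rng.integers(len(options)))]

    if kind == "substitute":
        if not sub_sites:
            raise NoSynonymousMoveError("no codon admits a synonymous substitution")
        i = int(rng.choice(sub_sites))
        alts = [c for c in table.synonyms(cods[i]) if c != cods[i]]
        cods[i] = alts[int(rng.integers(len(alts)))]
    elif kind == "exchange":
        if not exch_aas:
            raise NoSynonymousMoveError("no amino acid has two distinct codons to swap")
        aa = exch_aas[int(rng.integers(len(exch_aas)))]
        sites = exch_pairs[aa]
        for _ in range(_max_tries):
            i, j = rng.choice(sites, size=2, replace=False)
            if cods[i] != cods[j]:
                cods[int(i)], cods[int(j)] = cods[int(j)], cods[int(i)]
                break
        else:  # pragma: no cover - sites guaranteed heterogeneous above
            raise NoSynonymousMoveError("exchange sampling exhausted")
    else:
        raise ValueError(f"unknown move kind {kind!r}")

    return t.with_cds("".join(cods))


@dataclass(frozen=True)
class ConstraintSpec:
    """Tolerances for accepting a designed variant against its reference."""

    composition_tol: float = 0.01
    codon_usage_tol: float = 0.10
    preserve_motif: Literal["positions", "count"] = "positions"
    utr_frozen: bool = True

    def __post_init__(self):
        if not (0 <= self.composition_tol <= 1 and 0 <= self.codon_usage_tol <= 1):
            raise ValueError("tolerances must lie in [0, 1]")


@dataclass(frozen=True)
class ConstraintResult:
    name: str
    passed: bool
    deviation: float
    detail: str = ""


@dataclass(frozen=True)
class ConstraintReport:
    results: tuple[ConstraintResult, ...]

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.results)

    def __getitem__(self, name: str) -> ConstraintResult:
        for r in self.results:
            if r.name == name:
                return r
        raise KeyError(name)

    def failures(self) -> list[ConstraintResult]:
        return [r for r in self.results if not r.passed]


def check_constraints(
    candidate: Transcript,
    reference: Transcript,
    spec: ConstraintSpec = ConstraintSpec(),
    table: CodonTable = STANDARD_TABLE,
) -> ConstraintReport:
    """Evaluate every design constraint of ``candidate`` against ``reference``.

    Violations are results, not errors: the report lists each constraint with
    a boolean and the measured deviation.
    """
    results: list[ConstraintResult] = []

    dev = abs(len(candidate) - len(reference))
    results.append(ConstraintResult("length", dev == 0, float(dev)))

    utr_ok = (
        candidate.utr5 == reference.utr5 and candidate.utr3 == reference.utr3
    ) or not spec.utr_frozen
    n_diff = sum(a != b for a, b in zip(candidate.utr5, reference.utr5)) + sum(
        a != b for a, b in zip(candidate.utr3, reference.utr3)
    )
    results.append(ConstraintResult("utr_identity", utr_ok, float(n_diff)))

    # composition: per-nucleotide absolute fraction difference over the full
    # transcript
    n_c, n_r = len(candidate), len(reference)
    max_frac_dev = 0.0
    if n_c and n_r:
        cc, cr = Counter(candidate.seq), Counter(reference.seq)
        max_frac_dev = max(
            abs(cc.get(nt, 0) / n_c - cr.get(nt, 0) / n_r) for nt in "ACGU"
        )
    comp_ok = max_frac_dev <= spec.composition_tol + 1e-12
    results.append(ConstraintResult("composition", comp_ok, max_frac_dev))

    # codon usage: per-codon count deviation <= ceil(tol * reference count);
    # codons unused in the reference must remain unused
    uc, ur = Counter(candidate.codons), Counter(reference.codons)
    worst = 0.0
    usage_ok = True
    offender = ""
    for codon in set(uc) | set(ur):
        c_ref = ur.get(codon, 0)
        c_mut = uc.get(codon, 0)
        allowed = math.ceil(spec.codon_usage_tol * c_ref)
        excess = abs(c_mut - c_ref) - allowed
        if excess > worst:
            worst, offender = float(excess), codon
        if c_ref == 0 and c_mut > 0:
            usage_ok = False
            offender = codon
        elif excess > 0:
            usage_ok = False
    results.append(
        ConstraintResult("codon_usage", usage_ok, worst, detail=offender)
    )

    same_protein = (
        len(candidate.cds) == len(reference.cds)
        and translate(candidate.cds, table, warn_internal_stop=False)
        == translate(reference.cds, table, warn_internal_stop=False)
    )
    results.append(ConstraintResult("protein_identity", same_protein, 0.0 if same_protein else 1.0))

    ref_sites = scan_motif(reference.seq, reference.motif)
    cand_sites = scan_motif(candidate.seq, reference.motif)
    if spec.preserve_motif == "positions":
        motif_ok = ref_sites == cand_sites
        dev = float(len(set(ref_sites) ^ set(cand_sites)))
    else:
        motif_ok = len(ref_sites) == len(cand_sites)
        dev = float(abs(len(ref_sites) - len(cand_sites)))
    results.append(ConstraintResult("motif", motif_ok, dev))

    return ConstraintReport(tuple(results))


def scan_motif(seq: str, motif: str) -> list[int]:
    """All 0-based start offsets of ``motif`` in ``seq``, overlaps included."""
    if not motif:
        raise ValueError("motif must be non-empty")
    seq = _normalize_rna(seq)
    motif = _normalize_rna(motif)
    hits: list[int] = []
    i = seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return hits


@dataclass(frozen=True)
class SubstitutionReport:
    n_synonymous: int
    n_nonsynonymous: int
    expected_syn_fraction: float
    p_value: float


def _expected_syn_fraction(ref_cds: str, table: CodonTable) -> float:
    """Fraction of all single-nucleotide changes to ``ref_cds`` that are synonymous."""
    syn = total = 0
    for i in range(0, len(ref_cds), 3):
        codon = ref_cds[i : i + 3]
        aa = table.codon_to_aa[codon]
        for pos in range(3):
            for nt in "ACGU":
                if nt == codon[pos]:
                    continue
                mut = codon[:pos] + nt + codon[pos + 1 :]
                total += 1
                syn += table.codon_to_aa[mut] == aa
    return syn / total if total else 0.0


def classify_substitutions(
    ref_cds: str, alt_cds: str, table: CodonTable = STANDARD_TABLE
) -> SubstitutionReport:
    """Classify codon differences as synonymous / nonsynonymous and test enrichment.

    Differing codons are classified by their translated symbol.  The null
    expectation is the fraction of all possible single-nucleotide changes to
    the reference CDS that are synonymous; the p-value is the one-sided
    binomial tail P(X >= n_synonymous) for the observed number of changed
    codons (an enrichment test, no multiple-testing correction).
    """
    ref = _normalize_rna(ref_cds)
    alt = _normalize_rna(alt_cds)
    if len(ref) != len(alt):
        raise ValueError("reference and alternate CDS must have equal length")
    if len(ref) % 3:
        raise ValueError("CDS length must be a multiple of 3")

    n_syn = n_non = 0
    for i in range(0, len(ref), 3):
        a, b = ref[i : i + 3], alt[i : i + 3]
        if a == b:
            continue
        if table.codon_to_aa[a] == table.codon_to_aa[b]:
            n_syn += 1
        else:
            n_non += 1

    p0 = _expected_syn_fraction(ref, table)
    n_total = n_syn + n_non
    if n_total == 0:
        p_value = 1.0
    else:
        p_value = float(_stats.binom.sf(n_syn - 1, n_total, p0))
    return SubstitutionReport(n_syn, n_non, p0, p_value)


def synonymous_space_size(
    protein: str,
    table: CodonTable = STANDARD_TABLE,
    include_stop: bool = False,
) -> float:
    """log10 of the number of distinct coding sequences for ``protein``.

    Exact in log space: the count is the product of per-residue codon
    degeneracies (times 3 for the stop codon when ``include_stop``).
    """
    total = 0.0
    for aa in protein:
        if aa not in table.degeneracy or aa == STOP_SYMBOL:
            raise ValueError(f"unknown amino-acid symbol {aa!r}")
        total += math.log10(table.degeneracy[aa])
    if include_stop:
        total += math.log10(len(table.stop_codons))
    return total


def expected_space_size_uniform(
    n_residues: int, table: CodonTable = STANDARD_TABLE, include_stop: bool = True
) -> float:
    """Expected log10 coding-space size for a uniform-composition protein.

    Averages log10 degeneracy over the 20 standard amino acids and scales by
    the protein length; a 200-residue protein gives the familiar ~1e86
    combinatorial explosion of the synonymous sequence space.
    """
    aas = [aa for aa in table.degeneracy if aa != STOP_SYMBOL]
    mean_log_deg = sum(math.log10(table.degeneracy[aa]) for aa in aas) / len(aas)
    total = n_residues * mean_log_deg
    if include_stop:
        total += math.log10(len(table.stop_codons))
    return total
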