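"""Exhaustive enumeration of nested secondary structures.

Brute-force generation of every valid structure on a short sequence (or
two-strand concatenation), with energies.  This is the independent oracle
against which the dynamic-programming engine is verified; it deliberately
shares no recursion with :mod:`rnaed.thermo.fold`.  Guard-railed to short
inputs because the structure count grows exponentially.
"""

from __future__ import annotations

import numpy as np

from .model import EnergyModel, SecondaryStructure

__all__ = ["enumerate_structures", "count_structures", "boltzmann_weights"]

MAX_ENUM_LENGTH = 20


def _pair_ok(seq: str, i: int, j: int, model: EnergyModel, nick: int | None) -> bool:
    if model.pair_energy(seq[i], seq[j]) is None:
        return False
    if nick is not None and i < nick <= j:
        return True  # loop spans the strand break: hairpin rule waived
    return j - i > model.min_hairpin


def enumerate_structures(
    seq: str,
    model: EnergyModel,
    nick: int | None = None,
    max_length: int = MAX_ENUM_LENGTH,
) -> list[tuple[SecondaryStructure, float]]:
    """All valid nested structures with their energies.

    ``nick`` marks a strand break after position ``nick - 1`` (two-strand
    enumeration); pairs whose span contains the break are exempt from the
    minimum-hairpin rule.
    """
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    if n > max_length:
        raise ValueError(
            f"enumeration limited to length {max_length} (got {n}); "
            "this is a test oracle, use the DP engine for real sequences"
        )

    def rec(i: int, j: int) -> list[frozenset]:
        """All structures on the closed interval [i, j]."""
        if i >= j:
            return [frozenset()]
        out = []
        # position i unpaired
        out.extend(rec(i + 1, j))
        # position i paired to k
        for k in range(i + 1, j + 1):
            if _pair_ok(seq, i, k, model, nick):
                inner = rec(i + 1, k - 1)
                outer = rec(k + 1, j)
                base = frozenset({(i, k)})
                for s1 in inner:
                    for s2 in outer:
                        out.append(base | s1 | s2)
        return out

    results = []
    for pairset in rec(0, n - 1):
        s = SecondaryStructure(pairset, n, nick=nick)
        results.append((s, s.energy(seq, model)))
    return results


def count_structures(seq: str, model: EnergyModel, nick: int | None = None) -> int:
    """Structure count by the standard nested recursion.

    N(i, j) = N(i, j-1) + sum_k N(i, k-1) * N(k+1, j-1) over allowed pairs
    (k, j) — a decomposition on the last position, independent of the
    first-position decomposition used by :func:`enumerate_structures`.
    """
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    N = np.ones((n + 2, n + 2), dtype=object)  # big ints; empty intervals = 1

    def get(i, j):
        return 1 if i > j else N[i, j]

    for span in range(1, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            total = get(i, j - 1)
            for k in range(i, j):
                if _pair_ok(seq, k, j, model, nick):
                    total += get(i, k - 1) * get(k + 1, j - 1)
            N[i, j] = total
    return int(get(0, n - 1))


def boltzmann_weights(
    structures: list[tuple[SecondaryStructure, float]], model: EnergyModel
) -> np.ndarray:
    """Normalized Boltzmann probabilities for an enumerated ensemble."""
    e = np.array([en for _, en in structures])
    w = np.exp(-e / model.RT)
    return w / w.sum()
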