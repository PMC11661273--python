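"""Energy model and secondary-structure containers.

The energy model is deliberately simple — per-pair-type energies (GC, AU, GU),
an optional uniform stacking bonus for adjacent pairs, and a minimum hairpin
size — so that every downstream quantity (partition function, pair
probabilities, ensemble diversity, MFE, centroid, samples) can be verified
exactly against exhaustive enumeration.  A full nearest-neighbour backend can
be slotted in behind the same interface without changing any caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

GAS_CONSTANT = 0.0019872  # kcal / (mol K)

__all__ = ["GAS_CONSTANT", "EnergyModel", "SecondaryStructure"]

_COMPLEMENT_PAIRS = {
    ("G", "C"): "GC",
    ("C", "G"): "GC",
    ("A", "U"): "AU",
    ("U", "A"): "AU",
    ("G", "U"): "GU",
    ("U", "G"): "GU",
}


@dataclass(frozen=True)
class EnergyModel:
    """Pairwise RNA folding energies with Boltzmann temperature.

    Parameters
    ----------
    pair_energies:
        kcal/mol per pair type; keys "GC", "AU", "GU" (symmetric).
    stacking_bonus:
        kcal/mol added for each pair (i, j) whose neighbour (i+1, j-1) is also
        paired.  Must be <= 0 (a bonus); default 0 (no stacking term).
    min_hairpin:
        minimum number of unpaired nucleotides closed by a hairpin pair; a
        pair (i, j) on a single strand requires j - i > min_hairpin.
    temperature:
        kelvin; default 298.15 K (25 C).
    salt_mM:
        recorded in provenance only; the model has no salt dependence.
    """

    pair_energies: dict = field(
        default_factory=lambda: {"GC": -3.0, "AU": -2.0, "GU": -1.0}
    )
    stacking_bonus: float = 0.0
    min_hairpin: int = 3
    temperature: float = 298.15
    salt_mM: float = 150.0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.min_hairpin < 1:
            raise ValueError("min_hairpin must be >= 1")
        if self.stacking_bonus > 0:
            raise ValueError("stacking_bonus must be <= 0 (it is a bonus)")
        for k, v in self.pair_energies.items():
            if not math.isfinite(v):
                raise ValueError(f"pair energy {k} must be finite")

    @property
    def RT(self) -> float:
        return GAS_CONSTANT * self.temperature

    def pair_energy(self, a: str, b: str) -> float | None:
        """Energy of pairing nucleotides ``a``/``b``; None if not pairable."""
        kind = _COMPLEMENT_PAIRS.get((a, b))
        if kind is None:
            return None
        return self.pair_energies.get(kind)

    def pair_energy_matrix(self, seq: str) -> np.ndarray:
        """n x n energies with +inf at unpairable (by type) positions."""
        order = "ACGU"
        lut = np.full((4, 4), np.inf)
        for (a, b), kind in _COMPLEMENT_PAIRS.items():
            if kind in self.pair_energies:
                lut[order.index(a), order.index(b)] = self.pair_energies[kind]
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        idx = np.zeros(len(seq), dtype=np.intp)
        for k, ch in enumerate(order):
            idx[codes == ord(ch)] = k
        return lut[idx[:, None], idx[None, :]]

    def provenance(self) -> dict:
        return {
            "pair_energies": dict(self.pair_energies),
            "stacking_bonus": self.stacking_bonus,
            "min_hairpin": self.min_hairpin,
            "temperature_K": self.temperature,
            "salt_mM": self.salt_mM,
            "gas_constant": GAS_CONSTANT,
        }


class SecondaryStructure:
    """A nested set of base pairs over one or two strands.

    Pairs are stored as 0-based (i, j) tuples with i < j over the
    concatenated sequence; for two-strand structures ``nick`` is the length
    of the first strand and the dot-bracket rendering joins the strands with
    ``&`` (Vienna cofold dialect).
    """

    __slots__ = ("pairs", "n", "nick")

    def __init__(self, pairs, n: int, nick: int | None = None):
        self.pairs: frozenset[tuple[int, int]] = frozenset(
            (int(i), int(j)) if i < j else (int(j), int(i)) for i, j in pairs
        )
        self.n = int(n)
        self.nick = nick
        self._validate()

    def _validate(self):
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.n):
                raise ValueError(f"pair ({i}, {j}) out of range for n={self.n}")
            if i in seen or j in seen:
                raise ValueError("a position participates in more than one pair")
            seen.add(i)
            seen.add(j)
        ordered = sorted(self.pairs)
        for a in range(len(ordered)):
            i1, j1 = ordered[a]
            for b in range(a + 1, len(ordered)):
                i2, j2 = ordered[b]
                if i2 > j1:
                    break
                if not (i1 < i2 and j2 < j1):
                    raise ValueError(
                        f"pairs ({i1},{j1}) and ({i2},{j2}) cross (pseudoknot)"
                    )

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SecondaryStructure)
            and self.pairs == other.pairs
            and self.n == other.n
        )

    def __hash__(self) -> int:
        return hash((self.pairs, self.n))

    def __repr__(self) -> str:
        return f"SecondaryStructure({self.dot_bracket()!r})"

    def partner(self) -> np.ndarray:
        """Partner index per position, -1 if unpaired."""
        p = np.full(self.n, -1, dtype=int)
        for i, j in self.pairs:
            p[i], p[j] = j, i
        return p

    def paired_mask(self) -> np.ndarray:
        m = np.zeros(self.n, dtype=bool)
        for i, j in self.pairs:
            m[i] = m[j] = True
        return m

    def dot_bracket(self) -> str:
        chars = ["."] * self.n
        for i, j in self.pairs:
            chars[i], chars[j] = "(", ")"
        s = "".join(chars)
        if self.nick is not None:
            s = s[: self.nick] + "&" + s[self.nick :]
        return s

    @classmethod
    def from_dot_bracket(cls, db: str) -> "SecondaryStructure":
        nick = None
        if "&" in db:
            nick = db.index("&")
            db = db.replace("&", "")
        stack: list[int] = []
        pairs: list[tuple[int, int]] = []
        for k, c in enumerate(db):
            if c == "(":
                stack.append(k)
            elif c == ")":
                if not stack:
                    raise ValueError(f"unbalanced ')' at position {k}")
                pairs.append((stack.pop(), k))
            elif c != ".":
                raise ValueError(f"invalid dot-bracket character {c!r}")
        if stack:
            raise ValueError("unbalanced '(' in dot-bracket string")
        return cls(pairs, len(db), nick=nick)

    def basepair_distance(self, other: "SecondaryStructure") -> int:
        """Symmetric-difference distance: pairs present in exactly one structure."""
        if self.n != other.n:
            raise ValueError("structures must share the sequence length")
        return len(self.pairs ^ other.pairs)

    def energy(self, seq: str, model: EnergyModel) -> float:
        """Total energy: sum of pair energies plus stacking bonuses."""
        e = 0.0
        for i, j in self.pairs:
            v = model.pair_energy(seq[i], seq[j])
            if v is None:
                raise ValueError(f"pair ({i},{j}) {seq[i]}-{seq[j]} not pairable")
            e += v
            if (i + 1, j - 1) in self.pairs:
                e += model.stacking_bonus
        return e
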