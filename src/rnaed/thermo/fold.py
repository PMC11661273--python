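"""Dynamic-programming engine for the secondary-structure ensemble.

Inside (McCaskill-style) and outside recursions over nested structures under
the simplified pair-energy model, giving the partition function, base-pair
probability matrix, ensemble diversity (ED), MFE and centroid structures,
stochastic Boltzmann sampling, and two-strand cofolding for dimer dG / dED.

Numerics: Boltzmann weights are rescaled per nucleotide (Vienna-style) so the
tables stay inside double range; the scale is estimated from the MFE and
adjusted automatically (bisection) on over-/underflow, keeping long sequences
stable without log-domain arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import EnergyModel, SecondaryStructure

__all__ = [
    "PairProbMatrix",
    "EnsembleSummary",
    "DimerResult",
    "FoldTables",
    "partition_function",
    "basepair_probabilities",
    "ensemble_diversity",
    "ned",
    "mfe_structure",
    "centroid_structure",
    "sample_structures",
    "cofold",
    "ensemble_summary",
]

_TOL = 1e-9
_MAX_SAFE = 1e140
_MIN_TOTAL = 1e-200


@dataclass(frozen=True)
class PairProbMatrix:
    """Symmetric base-pair probability matrix with per-nucleotide pairedness."""

    p: np.ndarray  # n x n, symmetric, zero diagonal

    @property
    def n(self) -> int:
        return self.p.shape[0]

    @property
    def q(self) -> np.ndarray:
        """q_i = sum_j p_ij, the probability that nucleotide i is paired."""
        return self.p.sum(axis=1)

    def to_tsv(self, path, threshold: float = 0.0) -> None:
        """Write nonzero entries as 3 columns (i, j, p), 1-based, i < j."""
        iu, ju = np.triu_indices(self.n, k=1)
        mask = self.p[iu, ju] > threshold
        with open(path, "w") as fh:
            fh.write("# i\tj\tprob (1-based)\n")
            for i, j, v in zip(iu[mask] + 1, ju[mask] + 1, self.p[iu, ju][mask]):
                fh.write(f"{i}\t{j}\t{v:.10g}\n")


@dataclass(frozen=True)
class EnsembleSummary:
    """Headline ensemble statistics for one sequence."""

    name: str
    n: int
    log_Z: float
    G: float  # ensemble free energy, kcal/mol
    ED: float  # ensemble diversity, base pairs
    NED: float  # ED / n
    mfe_energy: float
    mfe: SecondaryStructure
    centroid: SecondaryStructure

    @property
    def Z(self) -> float:
        try:
            return math.exp(self.log_Z)
        except OverflowError:
            return math.inf

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n": self.n,
            "log_Z": self.log_Z,
            "G_kcal_mol": self.G,
            "ED": self.ED,
            "NED": self.NED,
            "mfe_energy_kcal_mol": self.mfe_energy,
            "mfe_dot_bracket": self.mfe.dot_bracket(),
            "centroid_dot_bracket": self.centroid.dot_bracket(),
        }


@dataclass(frozen=True)
class DimerResult:
    """Two-strand ensemble statistics relative to non-interacting monomers."""

    G_dimer: float
    ED_dimer: float
    G_monomers: float  # sum of the two monomer free energies
    ED_monomers: float
    delta_G: float
    delta_ED: float


def _normalize(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"invalid characters in RNA sequence: {sorted(bad)}")
    if not s:
        raise ValueError("empty sequence")
    return s


class FoldTables:
    """Inside/outside tables for one sequence (optionally with a strand break).

    Computes lazily: MFE tables on demand, then the scaled inside tables,
    then the outside/pair-probability pass.  All public entry points below
    are thin wrappers over this class.
    """

    def __init__(self, seq: str, model: EnergyModel, nick: int | None = None):
        self.seq = _normalize(seq)
        self.model = model
        self.nick = nick
        n = self.n = len(self.seq)
        if nick is not None and not (0 < nick < n):
            raise ValueError("nick must split the sequence into two non-empty strands")

        idx = np.arange(n)
        e = model.pair_energy_matrix(self.seq)
        span_ok = (idx[None, :] - idx[:, None]) > model.min_hairpin
        if nick is not None:
            crosses = (idx[:, None] < nick) & (idx[None, :] >= nick)
            span_ok = span_ok | crosses
        self.allowed = np.isfinite(e) & span_ok & (idx[:, None] < idx[None, :])
        self.e = np.where(self.allowed, e, np.inf)

        self._mfe_tables = None
        self._inside = None
        self._pmat: PairProbMatrix | None = None

    # ---------------- MFE (min-plus) ----------------

    def _mfe(self):
        if self._mfe_tables is not None:
            return self._mfe_tables
        n, stack = self.n, self.model.stacking_bonus
        F = np.full((n + 1, n + 1), np.inf)
        np.fill_diagonal(F, 0.0)  # F[i, k] = min energy on [i, k-1]; empty = 0
        Eb = np.full((n, n), np.inf)  # min energy on [i, j] given pair (i, j)
        with np.errstate(invalid="ignore"):
            for j in range(n):
                if j >= 1:
                    interior = F[1 : j + 1, j]
                    adj = Eb[1 : j + 1, j - 1] + stack
                    cand = self.e[0:j, j] + np.minimum(interior, adj)
                    Eb[0:j, j] = np.where(self.allowed[0:j, j], cand, np.inf)
                best_pair = np.min(
                    F[0 : j + 1, 0 : j + 1] + Eb[0 : j + 1, j][None, :], axis=1
                )
                F[0 : j + 1, j + 1] = np.minimum(F[0 : j + 1, j], best_pair)
        self._mfe_tables = (F, Eb)
        return self._mfe_tables

    @property
    def mfe_energy(self) -> float:
        F, _ = self._mfe()
        return float(F[0, self.n])

    def mfe_structure(self) -> SecondaryStructure:
        """Deterministic traceback.

        Tie-break: the open chain whenever energy 0 is co-optimal on an
        interval; otherwise the leftmost position pairs with its smallest
        co-optimal partner (the stacking branch, when present and co-optimal,
        is preferred since it pairs the leftmost interior position).
        """
        F, Eb = self._mfe()
        stack_b = self.model.stacking_bonus
        pairs: list[tuple[int, int]] = []
        # entries: ("int", i, j) free interval; ("bp", i, j) interior of a
        # placed pair (i, j), where the stacking branch must be resolved
        todo: list[tuple[str, int, int]] = [("int", 0, self.n - 1)]

        def M(i, j):
            return 0.0 if i > j else F[i, j + 1]

        def place(i, k):
            pairs.append((i, k))
            ii, jj = i + 1, k - 1
            if (
                stack_b != 0.0
                and ii < jj
                and self.allowed[ii, jj]
                and Eb[ii, jj] + stack_b <= Eb[i, k] - self.e[i, k] + _TOL
            ):
                place(ii, jj)
            else:
                todo.append(("int", ii, jj))

        while todo:
            tag, i, j = todo.pop()
            if i >= j:
                continue
            target = M(i, j)
            if target >= -_TOL:
                continue  # open chain co-optimal: take it
            placed = False
            for k in range(i + 1, j + 1):
                if self.allowed[i, k] and Eb[i, k] + M(k + 1, j) <= target + _TOL:
                    place(i, k)
                    todo.append(("int", k + 1, j))
                    placed = True
                    break
            if not placed:
                todo.append(("int", i + 1, j))
        return SecondaryStructure(pairs, self.n, nick=self.nick)

    # ---------------- inside (partition function) ----------------

    def _run_inside(self, ln_s: float):
        n = self.n
        model = self.model
        sigma = math.exp(-model.stacking_bonus / model.RT)
        u = math.exp(-ln_s)
        with np.errstate(over="ignore", under="ignore", invalid="ignore"):
            w = np.where(
                self.allowed, np.exp(-self.e / model.RT - 2.0 * ln_s), 0.0
            )
            E = np.zeros((n + 1, n + 1))
            np.fill_diagonal(E, 1.0)
            Zb = np.zeros((n, n))
            for j in range(n):
                if j >= 1:
                    interior = E[1 : j + 1, j]
                    adj = Zb[1 : j + 1, j - 1]
                    Zb[0:j, j] = w[0:j, j] * (interior + (sigma - 1.0) * adj)
                contrib = E[0 : j + 1, 0 : j + 1] @ Zb[0 : j + 1, j]
                E[0 : j + 1, j + 1] = u * E[0 : j + 1, j] + contrib
        return w, E, Zb, sigma, u

    def _ensure_inside(self):
        if self._inside is not None:
            return self._inside
        n = self.n
        beta_mfe = -self.mfe_energy / self.model.RT  # >= 0
        ln_s = 1.02 * beta_mfe / n + 0.4
        lo = hi = None  # ln_s known too small / too large
        step = 1.0
        for _ in range(200):
            w, E, Zb, sigma, u = self._run_inside(ln_s)
            total = E[0, n]
            finite = np.isfinite(E).all() and np.isfinite(Zb).all()
            too_big = (not finite) or max(E.max(), Zb.max(initial=0.0)) > _MAX_SAFE
            too_small = finite and total < _MIN_TOTAL
            if too_big:
                lo = ln_s
                ln_s = (lo + hi) / 2 if hi is not None else ln_s + step
                step *= 2
            elif too_small:
                hi = ln_s
                ln_s = (lo + hi) / 2 if lo is not None else ln_s - step
                step *= 2
            else:
                self._inside = (w, E, Zb, sigma, u, ln_s)
                return self._inside
        raise ArithmeticError("partition-function rescaling failed to converge")

    @property
    def log_Z(self) -> float:
        w, E, Zb, sigma, u, ln_s = self._ensure_inside()
        return math.log(E[0, self.n]) + self.n * ln_s

    @property
    def G(self) -> float:
        return -self.model.RT * self.log_Z

    # ---------------- outside (pair probabilities) ----------------

    def pair_probabilities(self) -> PairProbMatrix:
        if self._pmat is not None:
            return self._pmat
        w, E, Zb, sigma, u, ln_s = self._ensure_inside()
        n = self.n
        total = E[0, n]
        Zout = np.zeros((n, n))
        B = np.zeros((n, n))  # B[k, j] = sum_l w[k,l] Zout[k,l] * Zhat(j+1, l-1)
        with np.errstate(over="ignore", under="ignore", invalid="ignore"):
            for d in range(n, 0, -1):
                # fold A-entries of span d+2 into B
                if d + 2 <= n:
                    ks = np.arange(0, n - d - 1)  # l = k + d + 1 <= n-1
                    a = w[ks, ks + d + 1] * Zout[ks, ks + d + 1]
                    # B[k, j] += a[k] * Zhat(j+1, l-1) = a[k] * E[j+1, l]
                    Esub = E[1 : n + 1, d + 1 : n]  # [j, k] -> E[j+1, k+d+1]
                    B[: n - d - 1, :] += (Esub * a[None, :]).T
                # outside values for span-d entries (i, j = i+d-1)
                m = n - d + 1
                i_idx = np.arange(m)
                j_idx = i_idx + d - 1
                ext = E[0, 0:m] * E[d : n + 1, n]
                mid = (B[0:n, d - 1 : n] * E[1 : n + 1, 0:m]).sum(axis=0)
                vals = ext + mid
                if sigma != 1.0:
                    ok = (i_idx >= 1) & (j_idx + 1 <= n - 1)
                    ii = np.where(ok, i_idx - 1, 0)
                    jj = np.where(ok, j_idx + 1, 0)
                    corr = (sigma - 1.0) * w[ii, jj] * Zout[ii, jj]
                    vals = vals + np.where(ok, corr, 0.0)
                Zout[i_idx, j_idx] = vals
            p = Zb * Zout / total
        p = np.clip(np.where(np.isfinite(p), p, 0.0), 0.0, 1.0)
        p = np.triu(p, k=1)
        self._pmat = PairProbMatrix(p + p.T)
        return self._pmat

    # ---------------- stochastic traceback ----------------

    def sample(self, k: int, seed) -> list[SecondaryStructure]:
        """k i.i.d. Boltzmann draws via stochastic traceback."""
        if k < 0:
            raise ValueError("k must be >= 0")
        w, E, Zb, sigma, u, ln_s = self._ensure_inside()
        rng = np.random.default_rng(seed)
        n = self.n
        out = []
        for _ in range(k):
            pairs: list[tuple[int, int]] = []
            # stack entries: ("int", i, j) interval; ("bp", i, j) interior of pair
            todo: list[tuple[str, int, int]] = [("int", 0, n - 1)]
            while todo:
                tag, i, j = todo.pop()
                if tag == "bp":
                    ii, jj = i + 1, j - 1
                    if sigma == 1.0 or not (ii < jj and self.allowed[ii, jj]):
                        todo.append(("int", ii, jj))
                        continue
                    w_adj = sigma * Zb[ii, jj]
                    w_rest = E[ii, jj + 1] - Zb[ii, jj]
                    if rng.random() * (w_adj + w_rest) < w_adj:
                        pairs.append((ii, jj))
                        todo.append(("bp", ii, jj))
                    else:
                        todo.append(("nopair_ends", ii, jj))
                    continue
                if i >= j:
                    continue
                exclude_ends = tag == "nopair_ends"
                # decompose on the last position j
                opts = E[i, i : j] * Zb[i:j, j]
                if exclude_ends:
                    opts = opts.copy()
                    opts[0] = 0.0  # forbid the (i, j) pair itself
                w_unp = u * E[i, j]
                r = rng.random() * (w_unp + opts.sum())
                if r < w_unp:
                    todo.append((tag, i, j - 1) if exclude_ends else ("int", i, j - 1))
                    continue
                c = np.cumsum(opts)
                kk = i + int(np.searchsorted(c, r - w_unp, side="right"))
                pairs.append((kk, j))
                todo.append(("int", i, kk - 1))
                todo.append(("bp", kk, j))
            out.append(SecondaryStructure(pairs, n, nick=self.nick))
        return out


# ---------------- public functional API ----------------


def partition_function(seq: str, model: EnergyModel) -> tuple[float, float]:
    """(Z, G): Boltzmann sum over all valid structures and -RT ln Z."""
    t = FoldTables(seq, model)
    log_Z = t.log_Z
    try:
        Z = math.exp(log_Z)
    except OverflowError:
        Z = math.inf
    return Z, -model.RT * log_Z


def basepair_probabilities(seq: str, model: EnergyModel) -> PairProbMatrix:
    return FoldTables(seq, model).pair_probabilities()


def ensemble_diversity(P: PairProbMatrix | np.ndarray) -> float:
    """ED = sum_{i<j} 2 p_ij (1 - p_ij).

    Equals the expected base-pair (symmetric-difference) distance between two
    independent draws from the Boltzmann ensemble.
    """
    p = P.p if isinstance(P, PairProbMatrix) else np.asarray(P)
    iu = np.triu_indices(p.shape[0], k=1)
    v = p[iu]
    return float(np.sum(2.0 * v * (1.0 - v)))


def ned(ed: float, n: int) -> float:
    """Length-normalized ensemble diversity."""
    return ed / n


def mfe_structure(seq: str, model: EnergyModel) -> tuple[SecondaryStructure, float]:
    t = FoldTables(seq, model)
    return t.mfe_structure(), t.mfe_energy


def centroid_structure(P: PairProbMatrix, nick: int | None = None) -> SecondaryStructure:
    """Structure containing exactly the pairs with p_ij > 1/2.

    This minimizes the expected base-pair distance to the ensemble; pairs
    with probability > 1/2 can neither clash nor cross, so the result is
    always a valid structure.
    """
    p = P.p
    iu, ju = np.where(np.triu(p, k=1) > 0.5)
    return SecondaryStructure(list(zip(iu, ju)), P.n, nick=nick)


def sample_structures(
    seq: str, model: EnergyModel, k: int, seed
) -> list[SecondaryStructure]:
    return FoldTables(seq, model).sample(k, seed)


def ensemble_summary(
    seq: str, model: EnergyModel, name: str = "sequence"
) -> EnsembleSummary:
    t = FoldTables(seq, model)
    P = t.pair_probabilities()
    ed = ensemble_diversity(P)
    mfe = t.mfe_structure()
    return EnsembleSummary(
        name=name,
        n=t.n,
        log_Z=t.log_Z,
        G=t.G,
        ED=ed,
        NED=ed / t.n,
        mfe_energy=t.mfe_energy,
        mfe=mfe,
        centroid=centroid_structure(P),
    )


def cofold(seqA: str, seqB: str, model: EnergyModel) -> DimerResult:
    """Two-strand ensemble for the concatenation A&B.

    The dimer ensemble contains every nested structure on the concatenation,
    including fully disconnected ones (no inter-strand pair); the minimum
    hairpin rule is waived for pairs whose loop spans the strand break.
    dG = G_dimer - (G_A + G_B) is therefore always <= 0.
    """
    a, b = _normalize(seqA), _normalize(seqB)
    t = FoldTables(a + b, model, nick=len(a))
    ed_dimer = ensemble_diversity(t.pair_probabilities())
    g_dimer = t.G
    ta, tb = FoldTables(a, model), FoldTables(b, model)
    g_mono = ta.G + tb.G
    ed_mono = ensemble_diversity(ta.pair_probabilities()) + ensemble_diversity(
        tb.pair_probabilities()
    )
    return DimerResult(
        G_dimer=g_dimer,
        ED_dimer=ed_dimer,
        G_monomers=g_mono,
        ED_monomers=ed_mono,
        delta_G=g_dimer - g_mono,
        delta_ED=ed_dimer - ed_mono,
    )
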