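"""Synthetic single-molecule structure probing and its ensemble statistics.

The simulator emulates adenosine-specific chemical probing read out on long
single-molecule reads: each read's molecule adopts one conformation drawn
independently from the Boltzmann ensemble, every covered adenosine is called
"modified" with a high rate when single-stranded and a low rate when paired,
and read spans vary (uniform start, truncated-lognormal length).  Because
each read reflects one ensemble draw, the overlap-normalized pairwise
distance between reads is an experimental proxy for ensemble diversity;
the analysis functions below (top-k longest reads, pairwise distance
distributions, Jensen-Shannon distances between them, the ED-variance
identity, NED correlation) mirror how such probing data is interpreted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy import stats as _stats

from .thermo.fold import FoldTables, PairProbMatrix
from .thermo.model import EnergyModel

__all__ = [
    "ReadSimConfig",
    "ProbingRead",
    "DistanceDistribution",
    "simulate_reads",
    "read_distance",
    "distance_distribution",
    "jsd",
    "group_jsd",
    "state_variance",
    "ned_correlation",
]

DEFAULT_BINS = 50


@dataclass(frozen=True)
class ReadSimConfig:
    """Read-span and modification-rate model for the simulator.

    ``mod_rate_ss`` / ``mod_rate_ds`` are the per-adenosine modification-call
    probabilities for single-stranded vs paired positions; ``probed=False``
    gives the unprobed control in which both rates equal ``mod_rate_ds`` so
    reads carry no structural signal.  Read length is lognormal
    (``length_log_mean``, ``length_log_sd``) truncated to [L_min, n]; a
    ``length_log_mean`` of None defaults to ln(0.7 n).
    """

    n_reads: int = 1000
    mod_rate_ss: float = 0.25
    mod_rate_ds: float = 0.02
    probed: bool = True
    length_log_mean: float | None = None
    length_log_sd: float = 0.3
    min_length: int = 50
    seed: int = 0

    def __post_init__(self):
        for r in (self.mod_rate_ss, self.mod_rate_ds):
            if not 0 <= r <= 1:
                raise ValueError("modification rates must lie in [0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass(frozen=True)
class ProbingRead:
    """A covered interval [start, end) with binary calls at its adenosines."""

    read_id: str
    start: int
    end: int
    a_positions: tuple[int, ...]  # adenosine positions within [start, end)
    calls: tuple[int, ...]  # 1 = modified

    def __post_init__(self):
        if len(self.a_positions) != len(self.calls):
            raise ValueError("one call per adenosine position")
        for p in self.a_positions:
            if not (self.start <= p < self.end):
                raise ValueError("adenosine position outside the read interval")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def modified_positions(self) -> tuple[int, ...]:
        return tuple(p for p, c in zip(self.a_positions, self.calls) if c)


def simulate_reads(
    seq: str, model: EnergyModel, cfg: ReadSimConfig
) -> list[ProbingRead]:
    """Simulate probing reads from the sequence's Boltzmann ensemble.

    One independent structure draw per read; each covered adenosine is called
    modified with probability ``mod_rate_ss`` if unpaired in that draw, else
    ``mod_rate_ds`` (both ``mod_rate_ds`` for the unprobed control).
    """
    tables = FoldTables(seq, model)
    n = tables.n
    if n < cfg.min_length:
        raise ValueError(f"sequence length {n} below min_length {cfg.min_length}")
    rng = np.random.default_rng(cfg.seed)
    structures = tables.sample(cfg.n_reads, rng.integers(2**31))
    a_all = np.array([i for i, c in enumerate(tables.seq) if c == "A"], dtype=int)

    mu = cfg.length_log_mean if cfg.length_log_mean is not None else math.log(0.7 * n)
    rate_ss = cfg.mod_rate_ss if cfg.probed else cfg.mod_rate_ds
    rate_ds = cfg.mod_rate_ds

    reads = []
    for k, s in enumerate(structures):
        L = int(round(rng.lognormal(mu, cfg.length_log_sd)))
        L = max(cfg.min_length, min(n, L))
        start = int(rng.integers(0, n - L + 1))
        end = start + L
        a_pos = a_all[(a_all >= start) & (a_all < end)]
        paired = s.paired_mask()[a_pos]
        rates = np.where(paired, rate_ds, rate_ss)
        calls = (rng.random(len(a_pos)) < rates).astype(int)
        reads.append(
            ProbingRead(
                read_id=f"read{k:06d}",
                start=start,
                end=end,
                a_positions=tuple(int(p) for p in a_pos),
                calls=tuple(int(c) for c in calls),
            )
        )
    return reads


def read_distance(
    a: ProbingRead, b: ProbingRead, min_overlap: int = 50
) -> float | None:
    """Overlap-normalized distance between two reads, or None.

    The distance is the fraction of adenosine positions covered by both
    reads at which the modification calls differ; it is undefined (None)
    when fewer than ``min_overlap`` adenosines are shared.
    """
    map_a = dict(zip(a.a_positions, a.calls))
    shared = [p for p in b.a_positions if p in map_a]
    if len(shared) < min_overlap:
        return None
    map_b = dict(zip(b.a_positions, b.calls))
    diff = sum(map_a[p] != map_b[p] for p in shared)
    return diff / len(shared)


@dataclass(frozen=True)
class DistanceDistribution:
    """Normalized pairwise distances with a fixed-bin histogram."""

    values: np.ndarray
    n_undefined: int = 0
    bins: int = DEFAULT_BINS
    label: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("distances must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def histogram(self) -> np.ndarray:
        """Probability mass over ``bins`` equal bins on [0, 1]."""
        if self.values.size == 0:
            raise ValueError("empty distance distribution has no histogram")
        h, _ = np.histogram(self.values, bins=self.bins, range=(0.0, 1.0))
        return h / h.sum()

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values.size else math.nan

    @property
    def median(self) -> float:
        return float(np.median(self.values)) if self.values.size else math.nan


def _pairwise_distances_vectorized(
    reads: list[ProbingRead], all_a: np.ndarray, min_overlap: int
) -> tuple[np.ndarray, int]:
    """All defined pairwise distances via boolean matrix algebra."""
    pos_index = {int(p): k for k, p in enumerate(all_a)}
    m, nA = len(reads), len(all_a)
    cov = np.zeros((m, nA), dtype=np.float32)
    mod = np.zeros((m, nA), dtype=np.float32)
    for r, read in enumerate(reads):
        idx = [pos_index[p] for p in read.a_positions]
        cov[r, idx] = 1.0
        mod[r, idx] = read.calls
    unmod = cov - mod
    shared = cov @ cov.T
    differing = mod @ unmod.T + unmod @ mod.T
    iu = np.triu_indices(m, k=1)
    sh = shared[iu]
    ok = sh >= min_overlap
    with np.errstate(invalid="ignore", divide="ignore"):
        d = differing[iu][ok] / sh[ok]
    return d.astype(float), int((~ok).sum())


def distance_distribution(
    reads: list[ProbingRead],
    top_k: int = 1000,
    min_overlap: int = 50,
    bins: int = DEFAULT_BINS,
    label: str = "",
) -> DistanceDistribution:
    """Pairwise distances among the ``top_k`` longest reads.

    Length ties are broken by earlier start, then input order.  Pairs with
    insufficient overlap are counted in ``n_undefined`` rather than raised.
    """
    if len(reads) < 2:
        raise ValueError("need at least 2 reads")
    order = sorted(
        range(len(reads)), key=lambda i: (-len(reads[i]), reads[i].start, i)
    )
    chosen = [reads[i] for i in order[:top_k]]
    all_a = np.unique(
        np.concatenate([np.asarray(r.a_positions, dtype=int) for r in chosen])
    ) if chosen else np.array([], dtype=int)
    values, n_undef = _pairwise_distances_vectorized(chosen, all_a, min_overlap)
    return DistanceDistribution(values, n_undefined=n_undef, bins=bins, label=label)


def jsd(P: DistanceDistribution, Q: DistanceDistribution) -> float:
    """Jensen-Shannon distance (base-2 root divergence) between histograms.

    Symmetric, 0 iff the binned histograms coincide, 1 for disjoint support.
    """
    if P.bins != Q.bins:
        raise ValueError("distributions must share the binning")
    v = float(jensenshannon(P.histogram(), Q.histogram(), base=2))
    return 0.0 if math.isnan(v) else v


def group_jsd(groups: dict[str, list[DistanceDistribution]]) -> pd.DataFrame:
    """Mean pairwise JSD within each group and between each group pair.

    Returns a symmetric DataFrame (groups x groups); a diagonal entry is NaN
    when the group has fewer than two distributions.
    """
    names = list(groups)
    for g, ds in groups.items():
        if len(ds) < 1:
            raise ValueError(f"group {g!r} is empty")
    out = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for a in range(len(names)):
        for b in range(a, len(names)):
            da, db = groups[names[a]], groups[names[b]]
            if a == b:
                vals = [
                    jsd(da[i], da[j])
                    for i in range(len(da))
                    for j in range(i + 1, len(da))
                ]
            else:
                vals = [jsd(x, y) for x in da for y in db]
            v = float(np.mean(vals)) if vals else math.nan
            out.iloc[a, b] = out.iloc[b, a] = v
    return out


@dataclass(frozen=True)
class StateVarianceResult:
    variance: float  # Var_i(q_i)
    mean_pairedness: float  # m
    identity_residual: float  # Var - (m(1-m) - mean q(1-q)); algebraically 0
    ed_hat: float  # sum q_i (1 - q_i), the single-partner approximation to ED


def state_variance(P: PairProbMatrix) -> StateVarianceResult:
    """Variance of per-nucleotide pairedness and its exact relation to ED.

    Var_i(q_i) = m(1-m) - (1/n) sum_i q_i(1-q_i) holds for any pairedness
    profile (pure algebra).  When each paired nucleotide has one dominant
    partner, sum q_i(1-q_i) approximates ED, giving the inverse linear
    relation Var ~ m(1-m) - ED/n.
    """
    q = P.q
    n = q.size
    m = float(q.mean())
    var = float(q.var())
    s = float(np.sum(q * (1.0 - q)))
    residual = var - (m * (1.0 - m) - s / n)
    return StateVarianceResult(var, m, residual, s)


def ned_correlation(
    pairs: list[tuple[float, DistanceDistribution]]
) -> tuple[float, float]:
    """Pearson r (and p-value) between NED and mean pairwise read distance."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 sequences")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1].mean for p in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input to the correlation")
    r = _stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)
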