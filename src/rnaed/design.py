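"""Genetic algorithm over the synonymous codon space.

Each generation proposes ``children_per_gen`` constraint-satisfying synonymous
variants of the current parent (1-3 random codon substitutions/exchanges per
child, resampling rejected proposals), evaluates the ensemble diversity (ED)
of each full transcript, and selects the child with the extreme ED — keeping
the parent when elitist and no child improves.  ED is recomputed from the
pair-probability matrix for every candidate, never cached across mutations;
the O(n^3) evaluation dominates the run time.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .seqcore import (
    ConstraintSpec,
    NoSynonymousMoveError,
    Transcript,
    check_constraints,
    propose_synonymous_move,
)
from .thermo.fold import FoldTables, ensemble_diversity
from .thermo.model import EnergyModel

__all__ = ["GAConfig", "GenerationRecord", "DesignTrajectory", "evolve", "design_panel"]


@dataclass(frozen=True)
class GAConfig:
    objective: Literal["maximize", "minimize"] = "maximize"
    generations: int = 50
    children_per_gen: int = 20
    moves_min: int = 1
    moves_max: int = 3
    move_kind: Literal["substitute", "exchange", "mixed"] = "mixed"
    seed: int = 0
    elitist: bool = True
    max_resample: int = 100

    def __post_init__(self):
        if self.generations < 0 or self.children_per_gen < 1:
            raise ValueError("generations must be >= 0 and children_per_gen >= 1")
        if not (1 <= self.moves_min <= self.moves_max):
            raise ValueError("need 1 <= moves_min <= moves_max")

    def to_dict(self) -> dict:
        return {
            "objective": self.objective,
            "generations": self.generations,
            "children_per_gen": self.children_per_gen,
            "moves_min": self.moves_min,
            "moves_max": self.moves_max,
            "move_kind": self.move_kind,
            "seed": self.seed,
            "elitist": self.elitist,
            "max_resample": self.max_resample,
        }


@dataclass(frozen=True)
class GenerationRecord:
    generation: int
    best_ed: float
    best_ned: float
    accepted_child: bool
    seq_digest: str
    n_rejected: int  # constraint-rejected proposals during this generation


@dataclass
class DesignTrajectory:
    reference: Transcript
    final: Transcript
    final_ed: float
    records: list[GenerationRecord]
    config: GAConfig
    model: EnergyModel
    warnings: list[str] = field(default_factory=list)

    @property
    def best_ed_series(self) -> np.ndarray:
        return np.array([r.best_ed for r in self.records])

    def provenance(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "model": self.model.provenance(),
            "reference_name": self.reference.name,
            "final_digest": _digest(self.final.seq),
            "final_ed": self.final_ed,
        }


def _digest(seq: str) -> str:
    return hashlib.sha1(seq.encode()).hexdigest()[:12]


def transcript_ed(t: Transcript, model: EnergyModel) -> float:
    """ED of the full transcript (UTRs fold together with the CDS)."""
    return ensemble_diversity(FoldTables(t.seq, model).pair_probabilities())


def evolve(
    reference: Transcript,
    model: EnergyModel,
    spec: ConstraintSpec,
    cfg: GAConfig,
) -> DesignTrajectory:
    """Run the in-silico evolution and return the full trajectory.

    Every accepted candidate passes :func:`check_constraints` against the
    reference; identical seed + config reproduce the trajectory exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    better = (lambda a, b: a > b) if cfg.objective == "maximize" else (lambda a, b: a < b)

    parent = reference
    parent_ed = transcript_ed(parent, model)
    records: list[GenerationRecord] = []
    warns: list[str] = []

    # a CDS with no synonymous move at all ends the run before it starts
    try:
        propose_synonymous_move(parent, np.random.default_rng(cfg.seed), cfg.move_kind)
    except NoSynonymousMoveError:
        msg = "reference CDS admits no synonymous move; returning it unchanged"
        warnings.warn(msg, stacklevel=2)
        return DesignTrajectory(
            reference, parent, parent_ed, [], cfg, model, warnings=[msg]
        )

    for gen in range(cfg.generations):
        best_child = None
        best_child_ed = None
        n_rejected = 0
        for _ in range(cfg.children_per_gen):
            child = None
            for _attempt in range(cfg.max_resample):
                cand = parent
                n_moves = int(rng.integers(cfg.moves_min, cfg.moves_max + 1))
                try:
                    for _m in range(n_moves):
                        cand = propose_synonymous_move(cand, rng, cfg.move_kind)
                except NoSynonymousMoveError:
                    n_rejected += 1
                    continue
                if check_constraints(cand, reference, spec).passed:
                    child = cand
                    break
                n_rejected += 1
            if child is None:
                warns.append(
                    f"generation {gen}: child skipped after "
                    f"{cfg.max_resample} rejected proposals"
                )
                continue
            ed = transcript_ed(child, model)
            if best_child_ed is None or better(ed, best_child_ed):
                best_child, best_child_ed = child, ed

        accepted = False
        if best_child is not None:
            if not cfg.elitist or better(best_child_ed, parent_ed):
                parent, parent_ed = best_child, best_child_ed
                accepted = True
        records.append(
            GenerationRecord(
                generation=gen,
                best_ed=parent_ed,
                best_ned=parent_ed / len(parent),
                accepted_child=accepted,
                seq_digest=_digest(parent.seq),
                n_rejected=n_rejected,
            )
        )

    return DesignTrajectory(reference, parent, parent_ed, records, cfg, model, warns)


def derive_seed(master_seed: int, index: int) -> int:
    """Stable per-design seed below 2^31, derived from (master seed, index)."""
    return int(
        np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0]
        % (2**31)
    )


def design_panel(
    reference: Transcript,
    model: EnergyModel,
    spec: ConstraintSpec,
    n_designs: int,
    objective_mix: list[str] | None = None,
    seed: int = 0,
    cfg: GAConfig | None = None,
) -> list[DesignTrajectory]:
    """Run ``n_designs`` independent GA runs with distinct derived seeds.

    ``objective_mix`` gives the per-design objective (cycled); default is an
    alternating maximize/minimize panel.  The base ``cfg`` supplies all other
    GA settings; its objective and seed fields are overridden per design.
    """
    if n_designs < 1:
        raise ValueError("n_designs must be >= 1")
    if objective_mix is None:
        objective_mix = ["maximize", "minimize"]
    base = cfg if cfg is not None else GAConfig()
    out = []
    for i in range(n_designs):
        obj = objective_mix[i % len(objective_mix)]
        run_cfg = GAConfig(
            objective=obj,  # type: ignore[arg-type]
            generations=base.generations,
            children_per_gen=base.children_per_gen,
            moves_min=base.moves_min,
            moves_max=base.moves_max,
            move_kind=base.move_kind,
            seed=derive_seed(seed, i),
            elitist=base.elitist,
            max_resample=base.max_resample,
        )
        traj = evolve(reference, model, spec, run_cfg)
        traj.final = Transcript(
            traj.final.seq,
            traj.final.cds_start,
            traj.final.cds_end,
            motif=traj.final.motif,
            name=f"{reference.name}_design{i}_{obj[:3]}",
        )
        out.append(traj)
    return out
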