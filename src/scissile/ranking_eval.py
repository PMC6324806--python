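"""Normalized rank-recovery evaluation of cleavage-site predictions.

The model's job on an unseen peptide is to put the truly cleaved bonds at
the top of the predicted-probability ordering.  Each known cleavage site
therefore gets a *rank* (1 = highest probability, ties resolved to the
mid-rank) which is normalized by the peptide's number of possible cleavage
sites, making peptides of different lengths comparable.  Accumulating the
normalized ranks of all known sites gives a cumulative recovery curve:
the percentage of known sites recovered at or below each normalized
position.  Two reference curves frame a model:

* the *best* baseline assigns the known sites of each peptide ranks
  1, 2, 3, ... — the upper bound any predictor could reach;
* the *random* baseline scores every bond with a uniform random number and
  averages the resulting curves over repetitions — in expectation the
  diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .peptide_core import CleavageEvent, Peptide

__all__ = [
    "RankRecord",
    "RecoveryCurve",
    "rank_bonds",
    "evaluate_ranking",
    "recovery_curve",
    "best_baseline",
    "random_baseline",
    "recovered_at",
]

GRID_STEP = 0.01


@dataclass(frozen=True)
class RankRecord:
    """Rank of one known cleavage site within its peptide's bond ordering."""

    peptide_id: str
    bond_index: int
    rank: float
    n_bonds: int

    @property
    def normalized_rank(self) -> float:
        return self.rank / self.n_bonds


@dataclass(frozen=True)
class RecoveryCurve:
    """Cumulative % of known sites recovered at each normalized-rank position."""

    grid: np.ndarray
    cumulative: np.ndarray
    label: str = ""

    def at(self, x: float) -> float:
        """Cumulative recovery (%) at normalized position x."""
        i = int(np.searchsorted(self.grid, x, side="right")) - 1
        return float(self.cumulative[max(i, 0)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.grid, "cumulative_percent": self.cumulative,
             "series": self.label}
        )


def rank_bonds(probabilities) -> np.ndarray:
    """Descending-probability ranks; tied values share their mid-rank."""
    p = np.asarray(probabilities, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one bond")
    if not np.all(np.isfinite(p)):
        raise ValueError("probabilities must be finite")
    return rankdata(-p, method="average")


def evaluate_ranking(
    peptides: list[Peptide],
    events: list[CleavageEvent],
    probabilities: dict[str, np.ndarray],
) -> list[RankRecord]:
    """One RankRecord per known cleavage site, from per-bond probabilities.

    ``probabilities`` maps peptide id to a per-bond probability array (length
    = number of bonds of that peptide); every event of a listed peptide is
    scored exactly once.
    """
    by_id = {p.id: p for p in peptides}
    records = []
    for ev in events:
        p = by_id.get(ev.peptide_id)
        if p is None:
            continue
        probs = probabilities[p.id]
        if len(probs) != p.n_bonds:
            raise ValueError(
                f"peptide {p.id!r}: expected {p.n_bonds} probabilities, "
                f"got {len(probs)}"
            )
        ranks = rank_bonds(probs)
        records.append(
            RankRecord(p.id, ev.bond_index, float(ranks[ev.bond_index]), p.n_bonds)
        )
    return records


def recovery_curve(records: list[RankRecord], label: str = "") -> RecoveryCurve:
    """Cumulative recovery on a uniform grid 0..1 with step 0.01."""
    if not records:
        raise ValueError("no rank records")
    nr = np.array([r.normalized_rank for r in records])
    grid = np.round(np.arange(0.0, 1.0 + GRID_STEP / 2, GRID_STEP), 10)
    cumulative = np.array([100.0 * np.mean(nr <= x + 1e-12) for x in grid])
    return RecoveryCurve(grid=grid, cumulative=cumulative, label=label)


def best_baseline(
    peptides: list[Peptide], events: list[CleavageEvent], label: str = "best"
) -> RecoveryCurve:
    """Optimal curve: known sites of each peptide take ranks 1, 2, 3, ..."""
    by_id = {p.id: p for p in peptides}
    per_pep: dict[str, list[CleavageEvent]] = {}
    for ev in events:
        if ev.peptide_id in by_id:
            per_pep.setdefault(ev.peptide_id, []).append(ev)
    records = []
    for pid, evs in per_pep.items():
        n = by_id[pid].n_bonds
        for i, ev in enumerate(sorted(evs, key=lambda e: e.bond_index), start=1):
            records.append(RankRecord(pid, ev.bond_index, float(i), n))
    return recovery_curve(records, label=label)


def random_baseline(
    peptides: list[Peptide],
    events: list[CleavageEvent],
    seed: int = 0,
    reps: int = 100,
    label: str = "random",
) -> RecoveryCurve:
    """Null curve: uniform-random per-bond scores, averaged over ``reps`` runs."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(reps):
        probs = {p.id: rng.uniform(size=p.n_bonds) for p in peptides}
        records = evaluate_ranking(peptides, events, probs)
        curves.append(recovery_curve(records).cumulative)
    grid = np.round(np.arange(0.0, 1.0 + GRID_STEP / 2, GRID_STEP), 10)
    return RecoveryCurve(grid=grid, cumulative=np.mean(curves, axis=0), label=label)


def recovered_at(curve: RecoveryCurve, x: float) -> float:
    """Convenience accessor: % of known sites recovered by position x."""
    return curve.at(x)
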