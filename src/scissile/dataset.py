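"""Labeled training data: train/external split, balancing and oversampling.

Cleavage-site prediction is a heavily imbalanced binary problem: in a
typical substrate set the non-cleaved windows outnumber the cleaved ones by
one to two orders of magnitude.  The training scheme here keeps every
negative while balancing each base classifier's view of the data:

1. Substrates are split whole into a train and an external set, targeting a
   fraction (default 80%) of cleavage *events* in train.
2. Window patterns are deduplicated; each unique pattern carries its
   occurrence count M.  A pattern is positive when any of its occurrences
   is a cleavage site.
3. The unique negatives are partitioned into X groups the size of the
   positive pool, so X = ceil(#negatives / #positives); each partition plus
   the full positive pool forms one balanced training subset.
4. Within each subset, every pattern is replicated N = max(1,
   round(11 M / (100 + M))) times — *directed oversampling*, which up-weights
   frequently met motifs while saturating at 11 copies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .descriptors import DescriptorTable, pattern_features
from .peptide_core import CleavageEvent, Peptide, enumerate_windows

__all__ = [
    "LabeledPattern",
    "TrainingSubset",
    "SplitSpec",
    "split_train_external",
    "extract_patterns",
    "oversampling_repeats",
    "partition_negatives",
    "assemble_subsets",
    "build_training_subsets",
    "patterns_to_frame",
    "frame_to_patterns",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabeledPattern:
    """A unique window pattern with its label and occurrence count.

    ``M`` is how many times the pattern occurs among all windows of the
    dataset (its ``found`` count); ``cleaved`` is True when at least one
    occurrence coincides with an observed cleavage event.
    """

    pattern: tuple[str, ...]
    cleaved: bool
    M: int

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")


@dataclass
class TrainingSubset:
    """One balanced, oversampled subset: features + labels for one base model."""

    index: int
    X: np.ndarray
    y: np.ndarray
    patterns: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def n_pos(self) -> int:
        return int(self.y.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.y) - self.y.sum())


@dataclass(frozen=True)
class SplitSpec:
    """Train/external split parameters."""

    fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("fraction must lie strictly between 0 and 1")


def split_train_external(
    peptides: list[Peptide],
    events: list[CleavageEvent],
    spec: SplitSpec = SplitSpec(),
) -> tuple[tuple[list[Peptide], list[CleavageEvent]],
           tuple[list[Peptide], list[CleavageEvent]]]:
    """Split substrates whole into train and external sets.

    Substrates are visited in a seed-shuffled order and greedily assigned to
    train while that moves the train-side cleavage-event count closer to the
    target fraction; a deterministic repair pass then flips single
    substrates while a flip reduces the deviation from the target, which
    brings the train event share within one substrate's event count of the
    target.  No peptide appears on both sides, so no window pattern leaks
    from train to external via a shared substrate.  Both sides are
    guaranteed non-empty.
    """
    if len(peptides) < 2:
        raise ValueError("need at least 2 substrates to split")
    if not events:
        raise ValueError("need at least one cleavage event to split")
    ev_count = {p.id: 0 for p in peptides}
    for ev in events:
        if ev.peptide_id not in ev_count:
            raise ValueError(f"event references unknown peptide {ev.peptide_id!r}")
        ev_count[ev.peptide_id] += 1

    rng = np.random.default_rng(spec.seed)
    order = list(peptides)
    rng.shuffle(order)

    target = spec.fraction * sum(ev_count.values())
    train_ids: set[str] = set()
    acc = 0
    for p in order:
        e = ev_count[p.id]
        if abs(acc + e - target) <= abs(acc - target):
            train_ids.add(p.id)
            acc += e
    # repair: flip whichever single substrate best reduces the deviation
    while True:
        best_gain, best_pid, best_delta = 0.0, None, 0
        for p in order:
            delta = -ev_count[p.id] if p.id in train_ids else ev_count[p.id]
            gain = abs(acc - target) - abs(acc + delta - target)
            if gain > best_gain:
                best_gain, best_pid, best_delta = gain, p.id, delta
        if best_pid is None:
            break
        train_ids.symmetric_difference_update({best_pid})
        acc += best_delta
    # degenerate greedy outcomes: keep both sides non-empty
    if len(train_ids) == len(peptides):
        train_ids.discard(min(train_ids, key=lambda i: ev_count[i]))
    if not train_ids:
        train_ids.add(max(ev_count, key=lambda i: ev_count[i]))

    train_p = [p for p in peptides if p.id in train_ids]
    ext_p = [p for p in peptides if p.id not in train_ids]
    train_e = [e for e in events if e.peptide_id in train_ids]
    ext_e = [e for e in events if e.peptide_id not in train_ids]
    return (train_p, train_e), (ext_p, ext_e)


def extract_patterns(
    peptides: list[Peptide],
    events: list[CleavageEvent],
    k: int,
    protease_id: str | None = None,
) -> list[LabeledPattern]:
    """Deduplicate all k-windows into labeled patterns with occurrence counts.

    Cleavage sites whose bond has no full window (near a terminus, k > 1)
    cannot be represented and are skipped with a logged count.
    """
    cleaved_bonds: dict[str, set[int]] = {}
    for ev in events:
        if protease_id is not None and ev.protease_id != protease_id:
            continue
        cleaved_bonds.setdefault(ev.peptide_id, set()).add(ev.bond_index)

    found: dict[tuple[str, ...], int] = {}
    is_pos: dict[tuple[str, ...], bool] = {}
    covered: dict[str, set[int]] = {}
    for p in peptides:
        bonds = cleaved_bonds.get(p.id, set())
        for w in enumerate_windows(p, k):
            found[w.pattern] = found.get(w.pattern, 0) + 1
            if w.bond_index in bonds:
                is_pos[w.pattern] = True
                covered.setdefault(p.id, set()).add(w.bond_index)

    lost = sum(
        len(bonds - covered.get(pid, set())) for pid, bonds in cleaved_bonds.items()
    )
    if lost:
        log.info(
            "extract_patterns: %d cleavage site(s) have no full k=%d window "
            "and are not represented as positives", lost, k,
        )
    return [
        LabeledPattern(pattern=pat, cleaved=is_pos.get(pat, False), M=m)
        for pat, m in found.items()
    ]


def oversampling_repeats(M: int) -> int:
    """Directed-oversampling replication count N = max(1, round(11M/(100+M))).

    Integer arithmetic, round half up; monotone non-decreasing in M and
    capped at 11 (the asymptote of 11M/(100+M)).  A pattern met once still
    yields one copy, so no motif is dropped.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    # round-half-up of 11M / (100 + M) without floating point
    n = (2 * 11 * M + (100 + M)) // (2 * (100 + M))
    return max(1, n)


def partition_negatives(
    negatives: list[LabeledPattern],
    n_pos: int,
    seed: int = 0,
) -> list[list[LabeledPattern]]:
    """Partition unique negative patterns into groups of size ``n_pos``.

    Produces X = ceil(#negatives / n_pos) partitions after a seeded shuffle.
    The first X-1 have exactly ``n_pos`` members; the last is padded back up
    to ``n_pos`` by sampling without replacement from the negatives outside
    it (left short only when there are fewer than ``n_pos`` negatives in
    total).  Every negative appears in at least one partition.
    """
    if n_pos < 1:
        raise ValueError("n_pos must be >= 1")
    if not negatives:
        raise ValueError("no negative patterns to partition")
    rng = np.random.default_rng(seed)
    pool = list(negatives)
    rng.shuffle(pool)
    parts = [pool[i : i + n_pos] for i in range(0, len(pool), n_pos)]
    last = parts[-1]
    deficit = n_pos - len(last)
    if deficit > 0 and len(pool) > len(last):
        others = pool[: len(pool) - len(last)]
        take = min(deficit, len(others))
        idx = rng.choice(len(others), size=take, replace=False)
        parts[-1] = last + [others[i] for i in idx]
        log.info("partition_negatives: padded last partition with %d resampled "
                 "negative(s)", take)
    return parts


def assemble_subsets(
    positives: list[LabeledPattern],
    partitions: list[list[LabeledPattern]],
    table: DescriptorTable,
) -> list[TrainingSubset]:
    """Combine the positive pool with each negative partition into subsets.

    Each subset replicates every pattern (positive and negative) by its
    directed-oversampling count N(M), then featurizes through the
    descriptor table.  All subsets share the identical positive pool.
    """
    if not positives:
        raise ValueError("cannot assemble subsets without positive patterns")
    feat = {p.pattern: pattern_features(p.pattern, table)
            for part in [positives, *partitions] for p in part}

    subsets = []
    for i, part in enumerate(partitions):
        rows, labels, pats = [], [], []
        for lp in [*positives, *part]:
            n = oversampling_repeats(lp.M)
            rows.extend([feat[lp.pattern]] * n)
            labels.extend([1 if lp.cleaved else 0] * n)
            pats.extend([lp.pattern] * n)
        subsets.append(
            TrainingSubset(
                index=i,
                X=np.vstack(rows),
                y=np.asarray(labels, dtype=int),
                patterns=pats,
            )
        )
    return subsets


def patterns_to_frame(patterns: list[LabeledPattern], table: DescriptorTable):
    """Export labeled patterns as a DataFrame: pattern, label, M, features.

    The feature columns are ``<position-index>_<descriptor-name>`` in window
    order, so the CSV written from this frame re-imports losslessly via
    :func:`frame_to_patterns` (features are recomputed from the table).
    """
    import pandas as pd

    if not patterns:
        raise ValueError("no patterns to export")
    k2 = len(patterns[0].pattern)
    cols = [f"{i}_{name}" for i in range(k2) for name in table.names]
    X = np.vstack([pattern_features(p.pattern, table) for p in patterns])
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "M", [p.M for p in patterns])
    df.insert(0, "label", ["cleaved" if p.cleaved else "non-cleaved"
                           for p in patterns])
    df.insert(0, "pattern", ["-".join(p.pattern) for p in patterns])
    return df


def frame_to_patterns(df) -> list[LabeledPattern]:
    """Rebuild labeled patterns from an exported frame (or read-back CSV)."""
    return [
        LabeledPattern(
            pattern=tuple(str(r.pattern).split("-")),
            cleaved=(r.label == "cleaved"),
            M=int(r.M),
        )
        for r in df.itertuples()
    ]


def build_training_subsets(
    peptides: list[Peptide],
    events: list[CleavageEvent],
    table: DescriptorTable,
    k: int = 4,
    protease_id: str | None = None,
    seed: int = 0,
) -> list[TrainingSubset]:
    """End-to-end: windows -> unique patterns -> partitions -> balanced subsets."""
    patterns = extract_patterns(peptides, events, k, protease_id)
    positives = [p for p in patterns if p.cleaved]
    negatives = [p for p in patterns if not p.cleaved]
    if not positives:
        raise ValueError("no cleaved patterns: cannot build a training set")
    if not negatives:
        raise ValueError("no non-cleaved patterns: cannot build a training set")
    partitions = partition_negatives(negatives, len(positives), seed=seed)
    return assemble_subsets(positives, partitions, table)
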