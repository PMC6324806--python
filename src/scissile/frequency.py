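"""Frequency analysis of potential vs actual cleavage sites.

For a given protease, every window of half-width ``k`` in every substrate is
a *potential* site of cleavage (pSoC); the ones coinciding with an observed
cleavage event are *actual* sites (aSoC).  Simple frequency analysis (sFA)
counts, per distinct block pattern, how often the pattern was found and how
often it was cleaved; the similarity variant (SFA) matches patterns by
descriptor similarity instead of exact identity.  The position-occurrence
matrix underlying specificity heat maps gives, for each block and window
position, the percentage of actual cleavage windows carrying that block
there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptors import DescriptorTable, similarity_matrix
from .peptide_core import (
    CleavageEvent,
    Peptide,
    Window,
    enumerate_windows,
    position_labels,
    window_at,
)

__all__ = [
    "FrequencyRecord",
    "ConsistencyError",
    "simple_frequency_analysis",
    "frequency_tables",
    "position_occurrence_matrix",
    "similarity_search",
    "write_fa_excel",
    "plot_occurrence_heatmap",
]

log = logging.getLogger(__name__)


class ConsistencyError(ValueError):
    """An event references a peptide or bond that the input set cannot resolve."""


@dataclass
class FrequencyRecord:
    """Counts for one distinct window pattern.

    ``found`` counts occurrences of the pattern among all windows of all
    substrates; ``cleaved`` counts the occurrences that are actual cleavage
    sites.  ``once``/``twice``/``more`` classify, per substrate carrying at
    least one cleavage of this pattern, whether it was cleaved once, twice
    or more than twice in that substrate.
    """

    pattern: tuple[str, ...]
    found: int = 0
    cleaved: int = 0
    once: int = 0
    twice: int = 0
    more: int = 0


def _index_events(
    peptides: list[Peptide], events: list[CleavageEvent], protease_id: str | None
) -> dict[str, set[int]]:
    """Map peptide id -> set of cleaved bond indices, validating references."""
    by_id = {p.id: p for p in peptides}
    cleaved: dict[str, set[int]] = {}
    for ev in events:
        if protease_id is not None and ev.protease_id != protease_id:
            continue
        p = by_id.get(ev.peptide_id)
        if p is None:
            raise ConsistencyError(f"event references unknown peptide {ev.peptide_id!r}")
        if not 0 <= ev.bond_index < p.n_bonds:
            raise ConsistencyError(
                f"event references bond {ev.bond_index} of peptide {ev.peptide_id!r} "
                f"which has only {p.n_bonds} bonds"
            )
        cleaved.setdefault(ev.peptide_id, set()).add(ev.bond_index)
    return cleaved


def simple_frequency_analysis(
    peptides: list[Peptide],
    events: list[CleavageEvent],
    protease_id: str | None = None,
    k: int = 1,
) -> list[FrequencyRecord]:
    """Exact-match frequency analysis (sFA) for one protease.

    Returns one :class:`FrequencyRecord` per distinct pattern, covering both
    count tables.  Every cleavage event with a full window contributes
    exactly one ``cleaved`` count; events whose bond lies too close to a
    terminus for a full window (possible only for k > 1) are skipped with a
    logged count.
    """
    cleaved_bonds = _index_events(peptides, events, protease_id)
    records: dict[tuple[str, ...], FrequencyRecord] = {}
    skipped = 0

    for p in peptides:
        bonds = cleaved_bonds.get(p.id, set())
        per_substrate: dict[tuple[str, ...], int] = {}
        seen_bonds = set()
        for w in enumerate_windows(p, k):
            rec = records.setdefault(w.pattern, FrequencyRecord(w.pattern))
            rec.found += 1
            seen_bonds.add(w.bond_index)
            if w.bond_index in bonds:
                rec.cleaved += 1
                per_substrate[w.pattern] = per_substrate.get(w.pattern, 0) + 1
        skipped += len(bonds - seen_bonds)
        for pattern, c in per_substrate.items():
            rec = records[pattern]
            if c == 1:
                rec.once += 1
            elif c == 2:
                rec.twice += 1
            else:
                rec.more += 1

    if skipped:
        log.info("sFA: %d cleavage event(s) had no full k=%d window and were skipped",
                 skipped, k)
    return sorted(records.values(), key=lambda r: (-r.cleaved, -r.found, r.pattern))


def frequency_tables(
    records: list[FrequencyRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two sFA output tables: (pattern, found, cleaved) and multiplicity."""
    pat = ["-".join(r.pattern) for r in records]
    counts = pd.DataFrame(
        {"pattern": pat,
         "found": [r.found for r in records],
         "cleaved": [r.cleaved for r in records]}
    )
    multiplicity = pd.DataFrame(
        {"pattern": pat,
         "found": [r.found for r in records],
         "once": [r.once for r in records],
         "twice": [r.twice for r in records],
         "more_than_twice": [r.more for r in records]}
    )
    return counts, multiplicity


def position_occurrence_matrix(
    events: list[CleavageEvent],
    peptides: list[Peptide],
    k: int = 4,
    protease_id: str | None = None,
) -> pd.DataFrame:
    """Block-by-position occurrence percentages over actual cleavage windows.

    Cell (b, pos) is ``100 * #{aSoC windows with block b at pos} / #{aSoC
    windows}``, so each column sums to 100 (up to rounding).  Events without
    a full window are skipped with a logged count; zero usable events is an
    error.
    """
    by_id = {p.id: p for p in peptides}
    cleaved = _index_events(peptides, events, protease_id)
    cols = position_labels(k)
    windows: list[Window] = []
    skipped = 0
    for pid, bonds in cleaved.items():
        for b in sorted(bonds):
            w = window_at(by_id[pid], b, k)
            if w is None:
                skipped += 1
            else:
                windows.append(w)
    if skipped:
        log.info("occurrence matrix: %d event(s) lacked a full window and were skipped",
                 skipped)
    if not windows:
        raise ConsistencyError("no cleavage event has a full window; matrix is empty")

    blocks = sorted({b for w in windows for b in w.blocks})
    M = pd.DataFrame(0.0, index=blocks, columns=list(cols))
    for w in windows:
        for pos, b in zip(cols, w.blocks):
            M.loc[b, pos] += 1.0
    return M * (100.0 / len(windows))


def similarity_search(
    query: Window,
    records: list[FrequencyRecord],
    t: DescriptorTable,
    threshold: float,
    metric: str = "cosine",
) -> list[tuple[float, FrequencyRecord]]:
    """Similarity frequency analysis: match records by descriptor similarity.

    A record matches when the mean per-position block similarity between its
    pattern and the query reaches ``threshold``.  Matches are returned as
    (similarity, record) sorted by descending similarity.  Aggregation
    across positions is the mean (see methods note).
    """
    sim = similarity_matrix(t, metric=metric)
    for b in query.blocks:
        if b not in sim.index:
            raise ValueError(f"query block {b!r} missing from descriptor table")
    out = []
    for rec in records:
        if len(rec.pattern) != len(query.blocks):
            continue
        if any(b not in sim.index for b in rec.pattern):
            continue
        vals = [sim.loc[q, r] for q, r in zip(query.blocks, rec.pattern)]
        if metric == "euclidean":
            # distances: smaller is more similar; threshold is an upper bound
            score = float(np.mean(vals))
            if score <= threshold:
                out.append((score, rec))
        else:
            score = float(np.mean(vals))
            if score >= threshold:
                out.append((score, rec))
    reverse = metric != "euclidean"
    out.sort(key=lambda t: t[0], reverse=reverse)
    return out


def write_fa_excel(
    records: list[FrequencyRecord],
    directory,
    deterministic_name: bool = False,
    seed: int | None = None,
) -> str:
    """Write both FA tables to one ``soc<number>.xls``-style workbook.

    Mirrors the temporary-file convention of interactive FA tools: the file
    is named ``soc`` plus a random number (``.xlsx``); pass
    ``deterministic_name=True`` (optionally with ``seed``) for a
    reproducible name.  Returns the path written.
    """
    from pathlib import Path

    if deterministic_name:
        number = seed if seed is not None else 0
    else:
        number = int(np.random.default_rng(seed).integers(0, 2**63))
    path = Path(directory) / f"soc{number}.xlsx"
    counts, multiplicity = frequency_tables(records)
    with pd.ExcelWriter(path) as xls:
        counts.to_excel(xls, sheet_name="found_cleaved", index=False)
        multiplicity.to_excel(xls, sheet_name="multiplicity", index=False)
    return str(path)


def plot_occurrence_heatmap(matrix: pd.DataFrame, ax=None, title: str = ""):
    """Render an occurrence matrix as the conventional specificity heat map."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns)
    ax.set_yticks(range(matrix.shape[0]), matrix.index)
    ax.set_xlabel("window position")
    ax.set_ylabel("structural block")
    if title:
        ax.set_title(title)
    ax.figure.colorbar(im, ax=ax, label="% of cleavage windows")
    return ax
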