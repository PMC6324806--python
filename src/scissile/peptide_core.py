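"""Peptides as sequences of structural blocks, and cleavage windows.

A *structural block* (SB) generalizes "amino acid residue": it is the
structural fragment between two consecutive amide bonds, so a peptide is an
ordered chain of blocks joined by amide bonds.  Cleavage happens at one of
those bonds (the scissile bond); the residues flanking it are labelled with
Schechter-Berger positions ``... P4 P3 P2 P1 | P1' P2' P3' P4' ...``, the
scissile bond lying between P1 and P1'.

Bond indexing is 0-based throughout: bond ``i`` joins blocks ``i`` and
``i + 1``.  A linear peptide of ``L`` blocks has ``L - 1`` bonds; a cyclic
one has ``L`` (the extra bond joins the last block back to the first).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "AMINO_ACIDS",
    "StructuralBlock",
    "BlockRegistry",
    "Peptide",
    "CleavageEvent",
    "Window",
    "UnresolvedBlockError",
    "default_registry",
    "parse_sequence",
    "enumerate_windows",
    "window_at",
    "position_labels",
]

#: One-letter codes of the 20 canonical amino acids.
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


class UnresolvedBlockError(KeyError):
    """A sequence token or window block is not present in the registry/table."""


@dataclass(frozen=True)
class StructuralBlock:
    """A structural fragment between amide bonds.

    Parameters
    ----------
    name:
        Short identifier.  One-letter code for the natural amino acids; any
        other block is addressed in sequences by a bracketed token such as
        ``[Aib]``.
    structure:
        Optional opaque structure payload (SMILES or mol text).  Never
        interpreted by this package.
    natural:
        True for the 20 canonical amino acids.
    """

    name: str
    structure: Optional[str] = None
    natural: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("block name must be non-empty")
        if self.natural and self.name not in AMINO_ACIDS:
            raise ValueError(
                f"natural block name must be a canonical one-letter code, got {self.name!r}"
            )

    @property
    def token(self) -> str:
        """Sequence token: bare letter for naturals, bracketed otherwise."""
        return self.name if self.natural else f"[{self.name}]"


class BlockRegistry:
    """Mapping of block names to :class:`StructuralBlock` definitions."""

    def __init__(self, blocks: Optional[list[StructuralBlock]] = None):
        self._blocks: dict[str, StructuralBlock] = {}
        for b in blocks or []:
            self.add(b)

    def add(self, block: StructuralBlock) -> None:
        if block.name in self._blocks:
            raise ValueError(f"duplicate block name {block.name!r}")
        self._blocks[block.name] = block

    def __getitem__(self, name: str) -> StructuralBlock:
        try:
            return self._blocks[name]
        except KeyError:
            raise UnresolvedBlockError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self._blocks

    def __iter__(self) -> Iterator[StructuralBlock]:
        return iter(self._blocks.values())

    def __len__(self) -> int:
        return len(self._blocks)

    def names(self) -> list[str]:
        return list(self._blocks)


def default_registry() -> BlockRegistry:
    """Registry holding the 20 natural amino acids."""
    return BlockRegistry([StructuralBlock(a, natural=True) for a in AMINO_ACIDS])


@dataclass(frozen=True)
class Peptide:
    """An ordered chain of structural blocks.

    ``blocks`` stores block *names*; resolve them through a registry when the
    block definition (structure, descriptors) is needed.  ``topology`` is
    ``"linear"`` (default) or ``"cyclic"``; cyclic peptides close the chain
    with one extra amide bond.
    """

    id: str
    blocks: tuple[str, ...]
    topology: str = "linear"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.blocks) < 2:
            raise ValueError(f"peptide {self.id!r}: need at least 2 blocks")
        if self.topology not in ("linear", "cyclic"):
            raise ValueError(f"unknown topology {self.topology!r}")
        object.__setattr__(self, "blocks", tuple(self.blocks))

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def n_bonds(self) -> int:
        """Number of amide bonds (possible cleavage sites)."""
        return len(self.blocks) - 1 if self.topology == "linear" else len(self.blocks)

    def to_tokens(self, registry: BlockRegistry) -> str:
        """Re-emit the sequence token stream (inverse of :func:`parse_sequence`)."""
        return "".join(registry[b].token for b in self.blocks)


@dataclass(frozen=True)
class CleavageEvent:
    """One observed cleavage: a protease hydrolyzing one bond of one peptide.

    ``count`` is the number of independent observations backing the event
    (evidence weight), not a multiplicity of distinct sites.
    """

    peptide_id: str
    bond_index: int
    protease_id: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.bond_index < 0:
            raise ValueError("bond_index must be >= 0")
        if self.count < 1:
            raise ValueError("count must be >= 1")


# position labels for a window of half-width k: P_k..P1, P1'..P_k'
def position_labels(k: int) -> tuple[str, ...]:
    return tuple(f"P{i}" for i in range(k, 0, -1)) + tuple(f"P{i}'" for i in range(1, k + 1))


@dataclass(frozen=True)
class Window:
    """A cleavage window of ``2k`` blocks centred on one bond.

    ``blocks[k-1]`` is the P1 block and ``blocks[k]`` the P1' block; the
    scissile bond lies between them.
    """

    blocks: tuple[str, ...]
    bond_index: int
    k: int

    def __post_init__(self) -> None:
        if len(self.blocks) != 2 * self.k:
            raise ValueError(f"window must have exactly {2 * self.k} blocks")

    @property
    def positions(self) -> tuple[str, ...]:
        return position_labels(self.k)

    @property
    def pattern(self) -> tuple[str, ...]:
        """The ordered block-name tuple (the window's identity for counting)."""
        return self.blocks


_TOKEN_RE = re.compile(r"\[([^\[\]]+)\]|(.)", re.DOTALL)


def tokenize(seq: str) -> list[tuple[str, int]]:
    """Split a sequence string into (token, offset) pairs.

    Bare characters are single-letter tokens; ``[...]`` groups are one token
    (brackets stripped).  Offsets are character offsets into ``seq``.
    """
    out = []
    for m in _TOKEN_RE.finditer(seq):
        tok = m.group(1) if m.group(1) is not None else m.group(2)
        out.append((tok, m.start()))
    return out


def parse_sequence(
    seq: str,
    registry: BlockRegistry,
    *,
    id: str = "",
    topology: str = "linear",
) -> Peptide:
    """Parse a block sequence like ``"GDEVDGK"`` or ``"A[Aib]K"`` into a Peptide.

    Raises
    ------
    UnresolvedBlockError
        If a token is not in the registry; the message names the token and
        its character offset.
    """
    names = []
    for tok, off in tokenize(seq):
        if tok not in registry:
            raise UnresolvedBlockError(f"unresolved block {tok!r} at offset {off}")
        names.append(tok)
    return Peptide(id=id, blocks=tuple(names), topology=topology)


def window_at(p: Peptide, bond_index: int, k: int) -> Optional[Window]:
    """Full 2k-block window centred on ``bond_index``, or None near a terminus.

    For a linear peptide the window needs ``k`` blocks on each side of the
    bond, so bonds within ``k - 1`` blocks of either end have no full window.
    Cyclic peptides wrap around and every bond has a window.
    """
    if not 0 <= bond_index < p.n_bonds:
        raise IndexError(
            f"bond index {bond_index} out of range for peptide {p.id!r} "
            f"with {p.n_bonds} bonds"
        )
    L = len(p.blocks)
    if p.topology == "cyclic":
        idx = [(bond_index - k + 1 + j) % L for j in range(2 * k)]
        return Window(tuple(p.blocks[i] for i in idx), bond_index, k)
    start = bond_index - k + 1
    if start < 0 or start + 2 * k > L:
        return None
    return Window(tuple(p.blocks[start : start + 2 * k]), bond_index, k)


def enumerate_windows(p: Peptide, k: int) -> list[Window]:
    """All full windows of half-width ``k``.

    A linear peptide of ``L`` blocks yields ``max(0, L - 2k + 1)`` windows
    (a 100-mer gives 93 windows at k=4 and 99 at k=1); a cyclic one yields
    exactly ``L``.
    """
    out = []
    for b in range(p.n_bonds):
        w = window_at(p, b, k)
        if w is not None:
            out.append(w)
    return out
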