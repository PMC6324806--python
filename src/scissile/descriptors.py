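"""Per-block physicochemical descriptor tables and window featurization.

The prediction pipeline never computes molecular descriptors itself: it
consumes a *descriptor table* mapping each structural-block name to a fixed
length real vector.  Any CSV in the documented layout is accepted, so
proprietary descriptor sets (e.g. molecular-interaction-field summaries for
non-natural blocks) plug in as data.  A built-in open table for the 20
natural amino acids is shipped as the default; it covers the same property
axes such descriptors summarize — size, hydrophobicity, polarity, charge,
aromaticity — using published experimental scales.

A cleavage window of 2k blocks is featurized by concatenating the k
unprimed- and k primed-position block vectors in window order, giving a
``2k * d`` feature vector.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peptide_core import Window, UnresolvedBlockError

__all__ = [
    "DescriptorTable",
    "FeatureVector",
    "DescriptorFormatError",
    "load_descriptor_table",
    "builtin_table",
    "featurize_window",
    "featurize_windows",
    "similarity_matrix",
]


class DescriptorFormatError(ValueError):
    """A descriptor CSV violates the expected layout."""


@dataclass(frozen=True)
class DescriptorTable:
    """Block name -> real descriptor vector, all vectors of equal length."""

    names: tuple[str, ...]
    rows: dict[str, np.ndarray]
    provenance: str = ""

    def __post_init__(self) -> None:
        d = len(self.names)
        if d < 1:
            raise DescriptorFormatError("need at least one descriptor column")
        for block, vec in self.rows.items():
            v = np.asarray(vec, dtype=float)
            if v.shape != (d,):
                raise DescriptorFormatError(
                    f"row {block!r} has length {v.shape}, expected ({d},)"
                )
            if not np.all(np.isfinite(v)):
                raise DescriptorFormatError(f"row {block!r} contains non-finite values")
            self.rows[block] = v

    @property
    def d(self) -> int:
        return len(self.names)

    @property
    def blocks(self) -> list[str]:
        return list(self.rows)

    def __contains__(self, block: str) -> bool:
        return block in self.rows

    def __getitem__(self, block: str) -> np.ndarray:
        try:
            return self.rows[block]
        except KeyError:
            raise UnresolvedBlockError(
                f"block {block!r} has no descriptor row"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {b: v for b, v in self.rows.items()}, index=list(self.names)
        ).T.rename_axis("block")

    def zscaled(self) -> "DescriptorTable":
        """Per-column z-scored copy (zero-variance columns are left centred).

        Off by default; scale-sensitive classifier backends (linear models,
        RBF kernels) may benefit.
        """
        frame = self.to_frame()
        sd = frame.std(ddof=0).replace(0.0, 1.0)
        scaled = (frame - frame.mean()) / sd
        return DescriptorTable(
            names=self.names,
            rows={b: scaled.loc[b].to_numpy() for b in scaled.index},
            provenance=self.provenance + " (z-scaled)",
        )

    def fingerprint(self) -> str:
        """Content hash used to verify model/table pairing at predict time."""
        h = hashlib.sha256()
        h.update(",".join(self.names).encode())
        for b in sorted(self.rows):
            h.update(b.encode())
            h.update(np.ascontiguousarray(self.rows[b]).tobytes())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class FeatureVector:
    """Featurized window: concatenated per-block descriptors, window order."""

    values: np.ndarray
    window_key: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def load_descriptor_table(path, provenance: str | None = None) -> DescriptorTable:
    """Load a descriptor CSV: header ``block,<name1>,...,<named>``, one row per block.

    Raises :class:`DescriptorFormatError` on ragged rows, duplicate block
    names, non-numeric cells or an empty file, naming the offending row.
    """
    try:
        frame = pd.read_csv(path, index_col=0, dtype=str)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as e:
        raise DescriptorFormatError(f"unreadable descriptor CSV: {e}") from e
    if frame.empty or frame.shape[1] == 0:
        raise DescriptorFormatError("descriptor CSV has no data rows or columns")
    dup = frame.index[frame.index.duplicated()]
    if len(dup):
        raise DescriptorFormatError(f"duplicate block name(s): {sorted(set(dup))}")
    rows = {}
    for block, row in frame.iterrows():
        if row.isna().any():
            raise DescriptorFormatError(f"row {block!r}: missing cell(s)")
        try:
            rows[str(block)] = row.astype(float).to_numpy()
        except ValueError as e:
            raise DescriptorFormatError(f"row {block!r}: non-numeric cell ({e})") from e
    return DescriptorTable(
        names=tuple(frame.columns),
        rows=rows,
        provenance=provenance or str(path),
    )


# Built-in open descriptor set for the 20 natural amino acids.
#   volume       — residue volume, A^3 (Zamyatnin 1972)
#   hydropathy   — Kyte-Doolittle hydropathy index (1982)
#   polarity     — Grantham polarity (1974)
#   isoelectric  — isoelectric point of the free amino acid
#   charge       — net side-chain charge at pH 7 (His partially protonated)
#   aromatic     — aromatic side chain indicator
_BUILTIN_CSV = """\
block,volume,hydropathy,polarity,isoelectric,charge,aromatic
A,88.6,1.8,8.1,6.00,0,0
C,108.5,2.5,5.5,5.07,0,0
D,111.1,-3.5,13.0,2.77,-1,0
E,138.4,-3.5,12.3,3.22,-1,0
F,189.9,2.8,5.2,5.48,0,1
G,60.1,-0.4,9.0,5.97,0,0
H,153.2,-3.2,10.4,7.59,0.1,1
I,166.7,4.5,5.2,6.02,0,0
K,168.6,-3.9,11.3,9.74,1,0
L,166.7,3.8,4.9,5.98,0,0
M,162.9,1.9,5.7,5.74,0,0
N,114.1,-3.5,11.6,5.41,0,0
P,112.7,-1.6,8.0,6.30,0,0
Q,143.8,-3.5,10.5,5.65,0,0
R,173.4,-4.5,10.5,10.76,1,0
S,89.0,-0.8,9.2,5.68,0,0
T,116.1,-0.7,8.6,5.60,0,0
V,140.0,4.2,5.9,5.96,0,0
W,227.8,-0.9,5.4,5.89,0,1
Y,193.6,-1.3,6.2,5.66,0,1
"""


def builtin_table() -> DescriptorTable:
    """The shipped open table: 20 natural amino acids, 6 descriptors."""
    return load_descriptor_table(
        io.StringIO(_BUILTIN_CSV),
        provenance="builtin: volume/hydropathy/polarity/pI/charge/aromatic scales",
    )


def featurize_window(w: Window, t: DescriptorTable) -> FeatureVector:
    """Concatenate the descriptor vectors of a window's blocks, window order.

    Position P_k comes first and P_k' last, each block's ``d`` descriptors
    contiguous, so the result has length ``2k * d``.  Missing blocks raise
    :class:`~scissile.peptide_core.UnresolvedBlockError`; no imputation.
    """
    vecs = [t[b] for b in w.blocks]
    return FeatureVector(values=np.concatenate(vecs), window_key=w.blocks)


def featurize_windows(windows, t: DescriptorTable) -> np.ndarray:
    """Feature matrix (n_windows, 2k*d) for a list of windows."""
    if not windows:
        return np.empty((0, 0))
    return np.vstack([featurize_window(w, t).values for w in windows])


def pattern_features(pattern: tuple[str, ...], t: DescriptorTable) -> np.ndarray:
    """Feature vector for a bare block-name tuple (no Window object needed)."""
    return np.concatenate([t[b] for b in pattern])


def similarity_matrix(t: DescriptorTable, metric: str = "cosine") -> pd.DataFrame:
    """Pairwise block similarity (cosine) or distance (euclidean) matrix.

    Cosine entries lie in [-1, 1] with unit diagonal; a zero-norm descriptor
    row makes cosine undefined and raises ``ValueError``.
    """
    blocks = t.blocks
    X = np.vstack([t[b] for b in blocks])
    if metric == "cosine":
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            bad = [b for b, n in zip(blocks, norms) if n == 0]
            raise ValueError(f"zero-norm descriptor row(s) {bad}: cosine undefined")
        M = (X @ X.T) / np.outer(norms, norms)
        np.clip(M, -1.0, 1.0, out=M)
        np.fill_diagonal(M, 1.0)
    elif metric == "euclidean":
        diff = X[:, None, :] - X[None, :, :]
        M = np.sqrt((diff**2).sum(axis=2))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    # enforce exact symmetry against floating-point noise
    M = (M + M.T) / 2.0
    return pd.DataFrame(M, index=blocks, columns=blocks)
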