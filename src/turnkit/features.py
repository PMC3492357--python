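"""Per-residue feature assembly and context expansion.

Each residue is described by 43 real-valued features: the 20 squashed
PSSM columns, the 3-column secondary-structure profile, a one-hot of the
predicted 3-state secondary structure, the 8-column shape-string profile,
a one-hot of the predicted shape string, and a constant bias column.  A
context window of offsets (−2, −1, 0, +1, +2) concatenates neighbouring
rows into the 215-column observation the sequence model consumes;
out-of-range offsets contribute all-zero padding rows, so the bias column
doubles as a "real residue" indicator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TextIO

import numpy as np
import pandas as pd

from .profiles import AA_ALPHABET, ProfileMatrix

PSS_ALPHABET = "HEC"
#: 8-state shape-string alphabet (Ramachandran-space conformation codes).
SHAPE_ALPHABET = "SRUVKATG"

DEFAULT_OFFSETS = (-2, -1, 0, 1, 2)

FEATURE_COLUMNS: tuple[str, ...] = (
    tuple(f"pssm_{a}" for a in AA_ALPHABET)
    + tuple(f"spssm_{s}" for s in PSS_ALPHABET)
    + tuple(f"pss_{s}" for s in PSS_ALPHABET)
    + tuple(f"ssprof_{s}" for s in SHAPE_ALPHABET)
    + tuple(f"sspred_{s}" for s in SHAPE_ALPHABET)
    + ("bias",)
)
FEATURE_WIDTH = len(FEATURE_COLUMNS)
assert FEATURE_WIDTH == 43


@dataclass
class FeatureTable:
    """L×43 per-residue observation matrix with stable column names."""

    values: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError("values shape does not match columns")
        if len(self.columns) != FEATURE_WIDTH:
            raise ValueError(
                f"feature table must have exactly {FEATURE_WIDTH} columns, "
                f"got {len(self.columns)}"
            )

    @property
    def length(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns)


def _one_hot(symbols: str, alphabet: str, what: str) -> np.ndarray:
    out = np.zeros((len(symbols), len(alphabet)))
    for i, ch in enumerate(symbols):
        k = alphabet.find(ch)
        if k < 0:
            raise ValueError(f"invalid {what} symbol {ch!r} at position {i}")
        out[i, k] = 1.0
    return out


def assemble_features(pssm: ProfileMatrix, spssm: ProfileMatrix, pss: str,
                      ssprofile: ProfileMatrix, sspred: str) -> FeatureTable:
    """Concatenate the five per-residue feature families plus bias:
    20 PSSM + 3 SPSSM + 3 one-hot(PSS) + 8 SSProfile + 8 one-hot(SSPred)
    + 1 bias = 43 columns."""
    L = pssm.length
    for name, length in (("spssm", spssm.length), ("pss", len(pss)),
                         ("ssprofile", ssprofile.length),
                         ("sspred", len(sspred))):
        if length != L:
            raise ValueError(
                f"length mismatch: {name} has {length} rows, pssm has {L}"
            )
    if pssm.values.shape[1] != 20:
        raise ValueError("pssm must have 20 columns")
    if spssm.values.shape[1] != 3:
        raise ValueError("spssm must have 3 columns")
    if ssprofile.values.shape[1] != 8:
        raise ValueError("ssprofile must have 8 columns")
    blocks = [
        pssm.values,
        spssm.values,
        _one_hot(pss, PSS_ALPHABET, "secondary-structure"),
        ssprofile.values,
        _one_hot(sspred, SHAPE_ALPHABET, "shape-string"),
        np.ones((L, 1)),
    ]
    return FeatureTable(values=np.hstack(blocks), columns=list(FEATURE_COLUMNS))


def expand_context(table: FeatureTable,
                   offsets: Sequence[int] = DEFAULT_OFFSETS) -> np.ndarray:
    """Concatenate the feature rows at each offset around every position.

    Out-of-range neighbours contribute all-zero rows (their zero bias
    marks them as padding).  With the default five offsets the output has
    5 × 43 = 215 columns.
    """
    L = table.length
    if L == 0:
        raise ValueError("cannot expand an empty feature table")
    D = table.values.shape[1]
    out = np.zeros((L, D * len(offsets)))
    for b, off in enumerate(offsets):
        src_lo = max(0, -off)
        src_hi = min(L, L - off)
        if src_lo < src_hi:
            out[src_lo:src_hi, b * D:(b + 1) * D] = \
                table.values[src_lo + off:src_hi + off]
    return out


def expanded_column_names(columns: Sequence[str],
                          offsets: Sequence[int] = DEFAULT_OFFSETS
                          ) -> list[str]:
    return [f"{name}@{off:+d}" for off in offsets for name in columns]


def write_features_tsv(table: FeatureTable, sink: TextIO | str) -> None:
    """TSV with a 1-based position column and all 43 named columns."""
    if isinstance(sink, str):
        with open(sink, "w") as fh:
            write_features_tsv(table, fh)
            return
    sink.write("pos\t" + "\t".join(table.columns) + "\n")
    for i, row in enumerate(table.values, start=1):
        sink.write(str(i) + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")


def read_features_tsv(source: TextIO | str) -> FeatureTable:
    if isinstance(source, str):
        with open(source) as fh:
            return read_features_tsv(fh)
    header = source.readline().rstrip("\n").split("\t")
    if header[0] != "pos":
        raise ValueError("feature TSV must start with a 'pos' column")
    columns = header[1:]
    rows = [
        [float(x) for x in line.rstrip("\n").split("\t")[1:]]
        for line in source if line.strip()
    ]
    return FeatureTable(values=np.array(rows), columns=columns)
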