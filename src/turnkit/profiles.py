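"""Evolution profiles from alignment hit sets and PSI-BLAST PSSMs.

A profile row is the normalized frequency of structural elements observed
among aligned homologs at one query position: 20 columns for the
sequence profile (PSSM, squashed log-odds), 3 for the secondary-structure
profile and 8 for the shape-string profile.  Positions covered by no
non-gap hit element yield all-zero rows, signalling absence rather than a
flat prior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, TextIO

import numpy as np

GAP = "-"

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"  # PSI-BLAST column order


@dataclass
class AlignmentHit:
    evalue: float
    elements: str          # aligned structural elements, gap = '-'

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


@dataclass
class AlignmentHitSet:
    query_length: int
    hits: list[AlignmentHit]

    def __post_init__(self) -> None:
        for h in self.hits:
            if len(h.elements) != self.query_length:
                raise ValueError(
                    f"hit element string length {len(h.elements)} != "
                    f"query length {self.query_length}"
                )


@dataclass
class ProfileConfig:
    """Hit filtering: keep the top `max_hits` hits with E-value strictly
    below `evalue_max` (defaults: 50 and 1e-6)."""

    max_hits: int = 50
    evalue_max: float = 1e-6

    def __post_init__(self) -> None:
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")


@dataclass
class ProfileMatrix:
    """L×K matrix of per-position frequencies over a structural alphabet.

    Invariant: each row sums to 1 (covered) or is all-zero (uncovered).
    """

    alphabet: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.alphabet):
            raise ValueError("values must be L x len(alphabet)")

    @property
    def length(self) -> int:
        return self.values.shape[0]


def filter_hits(hitset: AlignmentHitSet, cfg: ProfileConfig | None = None
                ) -> AlignmentHitSet:
    """Retain hits with E-value < `evalue_max`, sorted ascending by
    E-value (stable for ties), truncated to the top `max_hits`."""
    cfg = cfg or ProfileConfig()
    kept = [h for h in hitset.hits if h.evalue < cfg.evalue_max]
    kept.sort(key=lambda h: h.evalue)  # stable: ties keep input order
    return AlignmentHitSet(hitset.query_length, kept[: cfg.max_hits])


def build_structural_profile(hitset: AlignmentHitSet, alphabet: Iterable[str]
                             ) -> ProfileMatrix:
    """Per-position normalized frequency of each alphabet symbol among the
    non-gap hit elements; all-gap positions yield zero rows."""
    alphabet = list(alphabet)
    index = {ch: k for k, ch in enumerate(alphabet)}
    L = hitset.query_length
    counts = np.zeros((L, len(alphabet)))
    for h in hitset.hits:
        for j, ch in enumerate(h.elements):
            if ch == GAP:
                continue
            try:
                counts[j, index[ch]] += 1
            except KeyError:
                raise ValueError(
                    f"element {ch!r} at position {j} outside alphabet "
                    f"{''.join(alphabet)!r}"
                ) from None
    coverage = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(coverage > 0, counts / coverage, 0.0)
    return ProfileMatrix(alphabet=alphabet, values=values)


class PSSMParseError(ValueError):
    pass


def read_psiblast_pssm(source: TextIO | str) -> ProfileMatrix:
    """Parse a PSI-BLAST ASCII PSSM and squash the 20 log-odds columns
    through the logistic function ``1/(1+exp(-x))``.

    Accepts a text stream or a path.  Rows must carry a position index,
    the query residue and at least 20 integer log-odds columns (the
    trailing weighted-frequency and information columns are ignored).
    """
    if isinstance(source, str):
        with open(source) as fh:
            return read_psiblast_pssm(fh)
    rows: list[list[float]] = []
    expected_idx = 1
    for lineno, line in enumerate(source, start=1):
        parts = line.split()
        if len(parts) < 22:
            continue
        if not (parts[0].isdigit() and len(parts[1]) == 1 and parts[1].isalpha()):
            continue
        idx = int(parts[0])
        if idx != expected_idx:
            raise PSSMParseError(
                f"line {lineno}: residue index {idx}, expected {expected_idx}"
            )
        try:
            scores = [float(x) for x in parts[2:22]]
        except ValueError as exc:
            raise PSSMParseError(f"line {lineno}: non-numeric cell ({exc})") from None
        rows.append(scores)
        expected_idx += 1
    if not rows:
        raise PSSMParseError("no PSSM rows found")
    raw = np.array(rows)
    return ProfileMatrix(alphabet=list(AA_ALPHABET),
                         values=1.0 / (1.0 + np.exp(-raw)))


def write_profile_tsv(profile: ProfileMatrix, sink: TextIO | str) -> None:
    """TSV: position (1-based) followed by one column per alphabet symbol."""
    if isinstance(sink, str):
        with open(sink, "w") as fh:
            write_profile_tsv(profile, fh)
            return
    sink.write("pos\t" + "\t".join(profile.alphabet) + "\n")
    for i, row in enumerate(profile.values, start=1):
        sink.write(str(i) + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")


def read_profile_tsv(source: TextIO | str) -> ProfileMatrix:
    if isinstance(source, str):
        with open(source) as fh:
            return read_profile_tsv(fh)
    header = source.readline().rstrip("\n").split("\t")
    if header[0] != "pos":
        raise ValueError("profile TSV must start with a 'pos' column")
    alphabet = header[1:]
    rows = []
    for line in source:
        parts = line.rstrip("\n").split("\t")
        if not parts or parts == [""]:
            continue
        rows.append([float(x) for x in parts[1:]])
    return ProfileMatrix(alphabet=alphabet, values=np.array(rows))


def read_hits_tsv(source: TextIO | str, query_length: int) -> AlignmentHitSet:
    """TSV columns: hit_id, evalue, aligned element string."""
    if isinstance(source, str):
        with open(source) as fh:
            return read_hits_tsv(fh, query_length)
    hits = []
    for line in source:
        line = line.rstrip("\n")
        if not line or line.startswith("#") or line.startswith("hit_id\t"):
            continue
        _, evalue, elements = line.split("\t")
        hits.append(AlignmentHit(evalue=float(evalue), elements=elements))
    return AlignmentHitSet(query_length=query_length, hits=hits)


def write_hits_tsv(hitset: AlignmentHitSet, sink: TextIO | str) -> None:
    if isinstance(sink, str):
        with open(sink, "w") as fh:
            write_hits_tsv(hitset, fh)
            return
    sink.write("hit_id\tevalue\telements\n")
    for i, h in enumerate(hitset.hits):
        sink.write(f"h{i}\t{h.evalue:.6g}\t{h.elements}\n")
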