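"""Ground-truth turn annotation from backbone geometry.

A *tight turn* is a site where the chain reverses direction: either the
first and last residue of the span are hydrogen bonded, or their Cα atoms
lie closer than 7 Å.  γ-, β-, α- and π-turns span 3, 4, 5 and 6 residues
respectively.  The unified ground truth labels a residue as "turn" when it
is covered by any detected span of any type, or when it lies in a run of
three or more consecutive DSSP 'T' states.  α- and π-spans buried inside
regular helices are excluded, as are β-spans whose two central residues
are helical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from . import geometry
from .geometry import hbond_energy, synthesize_amide_h

SS8_ALPHABET = "HGIEBTS-"
SS3_ALPHABET = "HEC"
#: DSSP 8→3 reduction: H/G/I → helix, E → sheet, everything else → coil.
SS8_TO_SS3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E",
    "B": "C", "T": "C", "S": "C", "-": "C",
}

TURN_SPANS = {"gamma": 3, "beta": 4, "alpha": 5, "pi": 6}


@dataclass
class Residue:
    """One residue's backbone record; O may be absent (flagged None)."""

    res_seq_label: str
    aa: str
    N: Optional[np.ndarray] = None
    CA: Optional[np.ndarray] = None
    C: Optional[np.ndarray] = None
    O: Optional[np.ndarray] = None


@dataclass
class BackboneChain:
    """One protein chain: ordered backbone residues plus optional 8-state
    secondary structure string of the same length."""

    chain_id: str
    residues: list[Residue]
    ss8: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("BackboneChain requires at least one residue")
        if self.ss8 is not None and len(self.ss8) != len(self.residues):
            raise ValueError(
                f"ss8 length {len(self.ss8)} != chain length {len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


@dataclass
class TurnConfig:
    """Detection thresholds for the unified turn definition."""

    ca_dist_max: float = 7.0          # Å, strict upper bound on endpoint Cα-Cα
    hbond_energy_cut: float = geometry.DEFAULT_HBOND_CUTOFF  # kcal/mol
    t_run_min: int = 3                # minimal consecutive-'T' run
    turn_spans: dict = field(default_factory=lambda: dict(TURN_SPANS))

    def __post_init__(self) -> None:
        if self.ca_dist_max <= 0:
            raise ValueError("ca_dist_max must be positive")
        if self.t_run_min < 1:
            raise ValueError("t_run_min must be >= 1")


@dataclass
class TurnSegment:
    start: int            # 0-based inclusive
    end_exclusive: int
    types: set[str]


@dataclass
class TurnLabels:
    labels: np.ndarray                 # uint8, 1 = turn residue
    segments: list[TurnSegment]


class InvalidSecondaryStructureError(ValueError):
    pass


def _check_ss8(ss8: str) -> None:
    for i, ch in enumerate(ss8):
        if ch not in SS8_ALPHABET:
            raise InvalidSecondaryStructureError(
                f"invalid 8-state symbol {ch!r} at position {i}"
            )


def map_ss8_to_ss3(ss8: str) -> str:
    """Reduce a DSSP 8-state string to 3 states: H/G/I→H, E→E, else C."""
    _check_ss8(ss8)
    return "".join(SS8_TO_SS3[ch] for ch in ss8)


def trun_labels(ss8: str, t_run_min: int = 3) -> np.ndarray:
    """Binary labels marking residues inside runs of >= `t_run_min`
    consecutive DSSP 'T' states."""
    _check_ss8(ss8)
    out = np.zeros(len(ss8), dtype=np.uint8)
    i = 0
    while i < len(ss8):
        if ss8[i] == "T":
            j = i
            while j < len(ss8) and ss8[j] == "T":
                j += 1
            if j - i >= t_run_min:
                out[i:j] = 1
            i = j
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# Hydrogen-bond bookkeeping


def _amide_h(chain: BackboneChain, i: int) -> Optional[np.ndarray]:
    """Synthesized amide H of residue i, or None (first residue / missing
    atoms / proline has no donor but we do not track residue identity of
    side chains here, so proline is treated like any donor)."""
    if i == 0:
        return None
    prev = chain.residues[i - 1]
    cur = chain.residues[i]
    if prev.C is None or cur.N is None or cur.CA is None:
        return None
    return synthesize_amide_h(prev.C, cur.N, cur.CA)


def backbone_hbond_energy(chain: BackboneChain, i: int, j: int) -> Optional[float]:
    """Energy of the putative hydrogen bond CO(i) → NH(j); None when the
    needed atoms are absent (including j = 0, which has no amide H)."""
    acc = chain.residues[i]
    don = chain.residues[j]
    if acc.C is None or acc.O is None or don.N is None:
        return None
    h = _amide_h(chain, j)
    if h is None:
        return None
    try:
        return hbond_energy(don.N, h, acc.O, acc.C)
    except geometry.DegenerateGeometryError:
        return None


def hbond_matrix(chain: BackboneChain, cutoff: float) -> np.ndarray:
    """Boolean matrix: entry (i, j) is True when CO(i)→NH(j) is a hydrogen
    bond.  Covalently adjacent pairs (j in {i, i+1}) are skipped."""
    L = len(chain)
    bonded = np.zeros((L, L), dtype=bool)
    for i in range(L):
        res_i = chain.residues[i]
        if res_i.C is None or res_i.O is None:
            continue
        for j in range(L):
            if j in (i, i + 1):
                continue
            don = chain.residues[j]
            # cheap distance prefilter on Cα (9 Å, generous)
            if res_i.CA is not None and don.CA is not None:
                if np.linalg.norm(res_i.CA - don.CA) > 9.0:
                    continue
            e = backbone_hbond_energy(chain, i, j)
            if e is not None and e < cutoff:
                bonded[i, j] = True
    return bonded


# ---------------------------------------------------------------------------
# Reduced DSSP-style 8-state assignment


def assign_ss8(chain: BackboneChain,
               cutoff: float = geometry.DEFAULT_HBOND_CUTOFF) -> str:
    """Reduced 8-state secondary-structure assignment from backbone
    hydrogen-bond patterns (Kabsch–Sander energies).

    Covers H/G/I (runs of two consecutive n-turns, n = 4/3/5), E (bridge
    partners), T (residues inside isolated n-turns) and '-'.  Bends (S)
    and the single-bridge distinction (B) are not reproduced; callers
    needing exact DSSP parity should supply a DSSP file instead.
    """
    L = len(chain)
    if L < 3:
        return "-" * L
    bonded = hbond_matrix(chain, cutoff)

    def nturn_starts(n: int) -> np.ndarray:
        starts = np.zeros(L, dtype=bool)
        for i in range(L - n):
            if bonded[i, i + n]:
                starts[i] = True
        return starts

    t3 = nturn_starts(3)
    t4 = nturn_starts(4)
    t5 = nturn_starts(5)

    ss = ["-"] * L

    def mark_helix(starts: np.ndarray, n: int, symbol: str) -> None:
        for i in range(1, L):
            if starts[i] and starts[i - 1]:
                for p in range(i, min(i + n, L)):
                    if ss[p] == "-":
                        ss[p] = symbol

    mark_helix(t4, 4, "H")
    mark_helix(t3, 3, "G")
    mark_helix(t5, 5, "I")

    # β-bridges: parallel / antiparallel Kabsch–Sander patterns.
    for i in range(1, L - 1):
        for j in range(i + 3, L - 1):
            para = (bonded[i - 1, j] and bonded[j, i + 1]) or \
                   (bonded[j - 1, i] and bonded[i, j + 1])
            anti = (bonded[i, j] and bonded[j, i]) or \
                   (bonded[i - 1, j + 1] and bonded[j - 1, i + 1])
            if para or anti:
                for p in (i, j):
                    if ss[p] == "-":
                        ss[p] = "E"

    # isolated n-turn interiors → T
    for starts, n in ((t3, 3), (t4, 4), (t5, 5)):
        for i in range(L):
            if starts[i]:
                for p in range(i + 1, min(i + n, L)):
                    if ss[p] == "-":
                        ss[p] = "T"
    return "".join(ss)


# ---------------------------------------------------------------------------
# Span detectors


def _helix_mask(ss8: str) -> np.ndarray:
    return np.frombuffer(ss8.encode(), dtype="S1") == b"H"


def _regular_helix_regions(ss8: str, min_len: int = 4) -> list[tuple[int, int]]:
    """Maximal runs of >= `min_len` consecutive H states, each extended by
    one residue on both sides (clamped to the chain).  The extension covers
    the hydrogen-bonded helix termini, which 8-state assignment marks as
    turn ('T') rather than 'H' although they belong to the regular helix.
    """
    regions = []
    L = len(ss8)
    i = 0
    while i < L:
        if ss8[i] == "H":
            j = i
            while j < L and ss8[j] == "H":
                j += 1
            if j - i >= min_len:
                regions.append((max(0, i - 1), min(L, j + 1)))
            i = j
        else:
            i += 1
    return regions


def _need_ss8(chain: BackboneChain, cfg: TurnConfig) -> str:
    if chain.ss8 is not None:
        _check_ss8(chain.ss8)
        return chain.ss8
    return assign_ss8(chain, cfg.hbond_energy_cut)


def detect_beta_turns(chain: BackboneChain, cfg: TurnConfig | None = None
                      ) -> list[tuple[int, int]]:
    """4-residue spans (i, i+4 exclusive) with Cα(i)–Cα(i+3) strictly below
    the 7 Å cutoff and non-helical central residues i+1, i+2."""
    cfg = cfg or TurnConfig()
    L = len(chain)
    if L < 4:
        return []
    ss8 = _need_ss8(chain, cfg)
    helix = _helix_mask(ss8)
    spans = []
    for i in range(L - 3):
        ca_i = chain.residues[i].CA
        ca_j = chain.residues[i + 3].CA
        if ca_i is None or ca_j is None:
            warnings.warn(f"missing CA at span ({i},{i + 3}); skipped")
            continue
        if np.linalg.norm(ca_i - ca_j) >= cfg.ca_dist_max:
            continue
        if helix[i + 1] or helix[i + 2]:
            continue
        spans.append((i, i + 4))
    return spans


def detect_gamma_turns(chain: BackboneChain, cfg: TurnConfig | None = None
                       ) -> list[tuple[int, int]]:
    """3-residue spans (i, i+3 exclusive) with a CO(i)→NH(i+2) hydrogen
    bond below the energy cutoff."""
    cfg = cfg or TurnConfig()
    L = len(chain)
    spans = []
    for i in range(L - 2):
        res = chain.residues[i]
        don = chain.residues[i + 2]
        if res.O is None or res.C is None or don.N is None:
            warnings.warn(f"missing backbone atoms for γ span at {i}; skipped")
            continue
        e = backbone_hbond_energy(chain, i, i + 2)
        if e is not None and e < cfg.hbond_energy_cut:
            spans.append((i, i + 3))
    return spans


def detect_alpha_pi_turns(chain: BackboneChain, cfg: TurnConfig | None = None
                          ) -> list[tuple[int, int]]:
    """5-residue (α) and 6-residue (π) spans closed by an endpoint hydrogen
    bond or an endpoint Cα distance below the cutoff, excluding spans lying
    inside regular helix regions."""
    cfg = cfg or TurnConfig()
    L = len(chain)
    ss8 = _need_ss8(chain, cfg)
    regions = _regular_helix_regions(ss8)

    def in_regular_helix(a: int, b: int) -> bool:
        return any(a >= s and b <= e for s, e in regions)

    spans = []
    for n in (5, 6):
        for i in range(L - n + 1):
            j = i + n - 1
            first, last = chain.residues[i], chain.residues[j]
            closed = False
            e = backbone_hbond_energy(chain, i, j)
            if e is not None and e < cfg.hbond_energy_cut:
                closed = True
            elif first.CA is not None and last.CA is not None:
                closed = np.linalg.norm(first.CA - last.CA) < cfg.ca_dist_max
            if closed and not in_regular_helix(i, j + 1):
                spans.append((i, i + n))
    return spans


# ---------------------------------------------------------------------------
# Unified annotation


def _span_type_iter(chain: BackboneChain, cfg: TurnConfig
                    ) -> Iterator[tuple[tuple[int, int], str]]:
    for s in detect_beta_turns(chain, cfg):
        yield s, "beta"
    for s in detect_gamma_turns(chain, cfg):
        yield s, "gamma"
    for s in detect_alpha_pi_turns(chain, cfg):
        yield s, "alpha" if s[1] - s[0] == 5 else "pi"


def segments_from_labels(labels: Sequence[int],
                         types_per_pos: list[set[str]] | None = None
                         ) -> list[TurnSegment]:
    """Maximal contiguous runs of label 1, each carrying the union of the
    contributing type tags of its positions."""
    segs = []
    L = len(labels)
    i = 0
    while i < L:
        if labels[i]:
            j = i
            types: set[str] = set()
            while j < L and labels[j]:
                if types_per_pos is not None:
                    types |= types_per_pos[j]
                j += 1
            segs.append(TurnSegment(i, j, types))
            i = j
        else:
            i += 1
    return segs


def annotate_turns(chain: BackboneChain, cfg: TurnConfig | None = None
                   ) -> TurnLabels:
    """Unified ground-truth turn labels: the union of all β/γ/α/π span
    detections and of runs of >= 3 consecutive 'T' states."""
    cfg = cfg or TurnConfig()
    L = len(chain)
    if L == 0:
        raise ValueError("empty chain")
    ss8 = _need_ss8(chain, cfg)

    labels = np.zeros(L, dtype=np.uint8)
    types_per_pos: list[set[str]] = [set() for _ in range(L)]
    for (a, b), kind in _span_type_iter(
        BackboneChain(chain.chain_id, chain.residues, ss8), cfg
    ):
        labels[a:b] = 1
        for p in range(a, b):
            types_per_pos[p].add(kind)
    trun = trun_labels(ss8, cfg.t_run_min)
    for p in np.flatnonzero(trun):
        labels[p] = 1
        types_per_pos[p].add("trun")

    return TurnLabels(labels, segments_from_labels(labels, types_per_pos))
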