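"""Synthetic inputs for the whole pipeline.

Three generators:

* :func:`build_backbone` — exact internal-to-Cartesian chain construction
  from per-residue φ/ψ/ω, with carbonyl oxygens in the peptide plane;
* :func:`make_turn_peptide` / :func:`make_multi_turn_chain` — peptides with
  planted turns between extended flanks, whose planted spans are verified
  against the detectors at generation time (fail loud, never shift);
* :func:`sample_hits` and :func:`sample_crf_corpus` — alignment hit sets
  with known generating frequencies and labelled feature corpora drawn
  from a sticky two-state chain with class-conditional emissions.

Every generator is a pure function of its seed and spec.  The peptides are
geometric fixtures: ideal covalent geometry, no side chains, no clash
checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import geometry
from .annotate import (
    BackboneChain,
    Residue,
    TurnConfig,
    TurnLabels,
    detect_beta_turns,
    detect_gamma_turns,
    segments_from_labels,
)
from .features import FEATURE_WIDTH, FeatureTable
from .profiles import AlignmentHit, AlignmentHitSet, GAP, ProfileMatrix

# Canonical turn dihedrals (Venkatachalam values from the turn literature;
# fixture parameters, not fitted quantities).
TURN_DIHEDRALS = {
    "beta_I": [(-60.0, -30.0), (-90.0, 0.0)],
    "beta_II": [(-60.0, 120.0), (80.0, 0.0)],
    "gamma": [(75.0, -65.0)],
}
#: φ/ψ of the span anchor residues (first and last residue of the planted
#: span).  Chosen so that the peptide's *unified* annotation is exactly
#: the planted span: the anchors open the enclosing 5/6-residue windows
#: beyond the 7 Å endpoint criterion, so no incidental α/π span wraps the
#: planted turn.
TURN_ANCHORS = {
    "beta_I": ((-100.0, 130.0), (-75.0, 145.0)),
    "beta_II": ((-100.0, 130.0), (-75.0, 145.0)),
    "gamma": ((-150.0, 160.0), (-75.0, 145.0)),
}
# Flank conformation for planted-turn peptides: polyproline-II-like
# extended backbone.  Chosen so flanks are cleanly non-turn under every
# detector (γ-bond energies ≈ −0.15 kcal/mol, far from the −0.5 cutoff;
# Cα(i)–Cα(i+3..5) distances > 9 Å).
EXTENDED_PHI_PSI = (-75.0, 145.0)
HELIX_PHI_PSI = (-57.0, -47.0)


@dataclass
class DihedralSpec:
    """Per-residue backbone torsions plus ideal covalent geometry."""

    phi: np.ndarray      # degrees; phi[0] unused
    psi: np.ndarray      # degrees
    omega: Optional[np.ndarray] = None  # degrees, default all 180
    sequence: Optional[str] = None       # default poly-alanine

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.phi.shape != self.psi.shape or self.phi.ndim != 1:
            raise ValueError("phi and psi must be 1-D arrays of equal length")
        if len(self.phi) < 1:
            raise ValueError("at least one residue required")
        if self.omega is None:
            self.omega = np.full(len(self.phi), 180.0)
        else:
            self.omega = np.asarray(self.omega, dtype=float)
            if self.omega.shape != self.phi.shape:
                raise ValueError("omega length mismatch")
        for name, arr in (("phi", self.phi), ("psi", self.psi),
                          ("omega", self.omega)):
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite {name}")
            if (arr <= -180.0).any() or (arr > 180.0).any():
                raise ValueError(f"{name} must lie in (-180, 180]")
        if self.sequence is None:
            self.sequence = "A" * len(self.phi)
        if len(self.sequence) != len(self.phi):
            raise ValueError("sequence length mismatch")

    def __len__(self) -> int:
        return len(self.phi)


def build_backbone(spec: DihedralSpec, chain_id: str = "A") -> BackboneChain:
    """Sequentially place N/CA/C/O from internal coordinates (NeRF).

    Round-trip exact: dihedrals measured on the output match the spec to
    well below 1e-6 degrees.
    """
    L = len(spec)
    g = geometry
    coords: list[dict[str, np.ndarray]] = []

    n0 = np.zeros(3)
    ca0 = np.array([g.BOND_N_CA, 0.0, 0.0])
    ang = np.radians(g.ANGLE_N_CA_C)
    c0 = ca0 + g.BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})

    for i in range(1, L):
        prev = coords[-1]
        n = g.place_atom(prev["N"], prev["CA"], prev["C"],
                         g.BOND_C_N, g.ANGLE_CA_C_N, spec.psi[i - 1])
        ca = g.place_atom(prev["CA"], prev["C"], n,
                          g.BOND_N_CA, g.ANGLE_C_N_CA, spec.omega[i - 1])
        c = g.place_atom(prev["C"], n, ca,
                         g.BOND_CA_C, g.ANGLE_N_CA_C, spec.phi[i])
        coords.append({"N": n, "CA": ca, "C": c})

    # carbonyl O in the peptide plane: dihedral N-CA-C-O = psi - 180
    for i, at in enumerate(coords):
        o_tor = spec.psi[i] - 180.0
        at["O"] = g.place_atom(at["N"], at["CA"], at["C"],
                               g.BOND_C_O, g.ANGLE_CA_C_O, o_tor)

    residues = [
        Residue(res_seq_label=str(i + 1), aa=spec.sequence[i], **coords[i])
        for i in range(L)
    ]
    return BackboneChain(chain_id, residues)


def measure_dihedrals(chain: BackboneChain) -> tuple[np.ndarray, np.ndarray]:
    """(phi, psi) measured from coordinates; phi[0] and psi[-1] are NaN
    only when undefined — here psi[-1] is recovered from the carbonyl O."""
    L = len(chain)
    phi = np.full(L, np.nan)
    psi = np.full(L, np.nan)
    r = chain.residues
    for i in range(L):
        if i > 0:
            phi[i] = geometry.dihedral(r[i - 1].C, r[i].N, r[i].CA, r[i].C)
        if i < L - 1:
            psi[i] = geometry.dihedral(r[i].N, r[i].CA, r[i].C, r[i + 1].N)
        elif r[i].O is not None:
            o_tor = geometry.dihedral(r[i].N, r[i].CA, r[i].C, r[i].O)
            psi[i] = ((o_tor + 180.0) + 180.0) % 360.0 - 180.0
    return phi, psi


class FixtureGenerationError(RuntimeError):
    """A planted fixture failed its own detection criterion."""


def _phi_psi_with_turn(kind: str, flank_length: int
                       ) -> tuple[np.ndarray, np.ndarray, int, int]:
    if kind not in TURN_DIHEDRALS:
        raise ValueError(f"unknown turn kind {kind!r}")
    if flank_length < 2:
        raise ValueError("flank_length must be >= 2")
    inner = TURN_DIHEDRALS[kind]
    entry, exit_ = TURN_ANCHORS[kind]
    span_len = len(inner) + 2          # turn span includes both anchors
    L = span_len + 2 * flank_length
    phi = np.full(L, EXTENDED_PHI_PSI[0])
    psi = np.full(L, EXTENDED_PHI_PSI[1])
    start = flank_length               # first residue of the planted span
    phi[start], psi[start] = entry
    for k, (ph, ps) in enumerate(inner):
        phi[start + 1 + k] = ph
        psi[start + 1 + k] = ps
    phi[start + span_len - 1], psi[start + span_len - 1] = exit_
    return phi, psi, start, span_len


def make_turn_peptide(kind: str, flank_length: int = 4,
                      cfg: TurnConfig | None = None
                      ) -> tuple[BackboneChain, TurnLabels]:
    """Peptide with extended flanks and one planted turn of `kind`
    (beta_I, beta_II or gamma).  The planted span is re-detected at
    generation time; any mismatch raises :class:`FixtureGenerationError`.
    """
    cfg = cfg or TurnConfig()
    phi, psi, start, span_len = _phi_psi_with_turn(kind, flank_length)
    chain = build_backbone(DihedralSpec(phi=phi, psi=psi))

    detector = detect_gamma_turns if kind == "gamma" else detect_beta_turns
    found = detector(chain, cfg)
    expected = [(start, start + span_len)]
    if found != expected:
        raise FixtureGenerationError(
            f"planted {kind} turn at {expected} but detector returned {found}"
        )
    L = len(chain)
    labels = np.zeros(L, dtype=np.uint8)
    labels[start:start + span_len] = 1
    from .annotate import annotate_turns  # local import avoids cycle

    union = annotate_turns(chain, cfg).labels
    if not np.array_equal(union, labels):
        raise FixtureGenerationError(
            f"unified annotation {union.tolist()} differs from planted "
            f"{labels.tolist()} for kind {kind}"
        )
    kind_tag = "gamma" if kind == "gamma" else "beta"
    segs = segments_from_labels(labels, [({kind_tag} if labels[p] else set())
                                         for p in range(L)])
    return chain, TurnLabels(labels, segs)


def make_helix_chain(length: int) -> BackboneChain:
    """Ideal α-helix (φ=−57°, ψ=−47°): the canonical negative fixture."""
    phi = np.full(length, HELIX_PHI_PSI[0])
    psi = np.full(length, HELIX_PHI_PSI[1])
    return build_backbone(DihedralSpec(phi=phi, psi=psi))


def make_multi_turn_chain(n_residues: int = 91, n_turns: int = 10,
                          seed: int = 0, cfg: TurnConfig | None = None
                          ) -> tuple[BackboneChain, TurnLabels]:
    """SYNTHETIC stand-in chain: `n_turns` planted β-turns separated by
    extended flanks, padded to exactly `n_residues`.

    This is a geometric fixture built from ideal internal coordinates —
    not a real protein structure.  The unified annotation of the returned
    chain is verified at generation time to contain exactly `n_turns`
    maximal turn segments.
    """
    cfg = cfg or TurnConfig()
    rng = np.random.default_rng(seed)
    span = 4
    n_flanks = n_turns + 1
    spare = n_residues - n_turns * span - n_flanks * 4
    if spare < 0:
        raise ValueError("n_residues too small for the requested turns")
    flanks = np.full(n_flanks, 4)
    for _ in range(spare):
        flanks[rng.integers(0, n_flanks)] += 1

    kinds = [("beta_I" if rng.random() < 0.5 else "beta_II")
             for _ in range(n_turns)]
    phi = []
    psi = []
    truth = []
    for t in range(n_turns):
        phi += [EXTENDED_PHI_PSI[0]] * flanks[t]
        psi += [EXTENDED_PHI_PSI[1]] * flanks[t]
        truth += [0] * flanks[t]
        inner = TURN_DIHEDRALS[kinds[t]]
        entry, exit_ = TURN_ANCHORS[kinds[t]]
        phi += [entry[0]] + [d[0] for d in inner] + [exit_[0]]
        psi += [entry[1]] + [d[1] for d in inner] + [exit_[1]]
        truth += [1] * span
    phi += [EXTENDED_PHI_PSI[0]] * flanks[-1]
    psi += [EXTENDED_PHI_PSI[1]] * flanks[-1]
    truth += [0] * flanks[-1]

    chain = build_backbone(DihedralSpec(phi=np.array(phi), psi=np.array(psi)))
    from .annotate import annotate_turns  # local import avoids cycle at module load

    ann = annotate_turns(chain, cfg)
    if len(ann.segments) != n_turns:
        raise FixtureGenerationError(
            f"planted {n_turns} turns but annotation found {len(ann.segments)}"
        )
    truth_arr = np.array(truth, dtype=np.uint8)
    if not np.array_equal(ann.labels, truth_arr):
        raise FixtureGenerationError("annotated labels differ from planted truth")
    return chain, ann


# ---------------------------------------------------------------------------
# Alignment-hit sampling


def sample_hits(true_profile: ProfileMatrix, n_hits: int = 50,
                gap_rate: float = 0.0, seed: int = 0) -> AlignmentHitSet:
    """Draw alignment hits whose per-position elements follow the rows of
    `true_profile`; elements are replaced by gaps at `gap_rate`.  E-values
    are drawn below 1e-6 so that the default filter keeps every hit."""
    if not (0.0 <= gap_rate < 1.0):
        raise ValueError("gap_rate must lie in [0, 1)")
    vals = true_profile.values
    row_sums = vals.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-9):
        raise ValueError("true_profile rows must be stochastic")
    rng = np.random.default_rng(seed)
    L, K = vals.shape
    alphabet = true_profile.alphabet
    hits = []
    for _ in range(n_hits):
        chars = []
        for j in range(L):
            if gap_rate > 0 and rng.random() < gap_rate:
                chars.append(GAP)
            else:
                chars.append(alphabet[rng.choice(K, p=vals[j])])
        evalue = float(10.0 ** rng.uniform(-12.0, -6.5))
        hits.append(AlignmentHit(evalue=evalue, elements="".join(chars)))
    return AlignmentHitSet(query_length=L, hits=hits)


# ---------------------------------------------------------------------------
# CRF corpus sampling


@dataclass
class EmissionModel:
    """Class-conditional emission parameters for the 43 feature columns.

    Profile-style blocks (3-state and 8-state) are drawn from Dirichlet
    distributions whose means differ by class; the 20 PSSM columns are
    logistic squashes of Gaussians with class-shifted means; the two
    one-hot blocks are categorical draws; the bias column is 1.

    Defaults emulate informative-but-imperfect upstream predictors (real
    3-state secondary-structure prediction plateaus near Q3 ≈ 80%), so
    class posteriors are graded rather than saturated and the decision
    threshold genuinely trades sensitivity against specificity.
    """

    pssm_shift: float = 0.15     # +/- mean shift of pre-squash Gaussians
    pssm_sigma: float = 1.0
    dirichlet_conc: float = 4.0
    # categorical probabilities over PSS (H, E, C) per class
    pss_probs_turn: np.ndarray = field(
        default_factory=lambda: np.array([0.20, 0.15, 0.65]))
    pss_probs_nonturn: np.ndarray = field(
        default_factory=lambda: np.array([0.35, 0.30, 0.35]))
    # categorical probabilities over the 8 shape symbols per class
    shape_probs_turn: np.ndarray = field(
        default_factory=lambda: np.array(
            [0.10, 0.08, 0.10, 0.12, 0.08, 0.07, 0.30, 0.15]))
    shape_probs_nonturn: np.ndarray = field(
        default_factory=lambda: np.array(
            [0.25, 0.18, 0.08, 0.08, 0.08, 0.18, 0.08, 0.07]))


@dataclass
class SyntheticCorpusSpec:
    """Generating process for a labelled corpus standing in for a real
    training set: sticky two-state label chain at the empirical turn
    fraction of globular proteins (~24.5%), strong class-conditional
    emissions over the 43 feature columns."""

    n_sequences: int = 200
    length_low: int = 50
    length_high: int = 70           # inclusive
    turn_fraction: float = 0.245    # stationary probability of the turn state
    turn_stay: float = 0.8          # P(turn -> turn); mean segment 5 residues
    emission: EmissionModel = field(default_factory=EmissionModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.turn_fraction < 1.0):
            raise ValueError("turn_fraction must lie in (0, 1)")
        if not (0.0 <= self.turn_stay < 1.0):
            raise ValueError("turn_stay must lie in [0, 1)")
        if self.n_sequences < 1 or self.length_low < 1 \
                or self.length_high < self.length_low:
            raise ValueError("invalid corpus dimensions")

    @property
    def transition_matrix(self) -> np.ndarray:
        """Rows: from-state (nonturn, turn); stationary turn probability
        equals `turn_fraction`."""
        p_tn = 1.0 - self.turn_stay                      # turn -> nonturn
        p_nt = p_tn * self.turn_fraction / (1.0 - self.turn_fraction)
        if p_nt >= 1.0:
            raise ValueError("inconsistent turn_fraction / turn_stay")
        return np.array([[1.0 - p_nt, p_nt], [p_tn, self.turn_stay]])


def _sample_emissions(rng: np.random.Generator, labels: np.ndarray,
                      em: EmissionModel) -> np.ndarray:
    L = len(labels)
    X = np.empty((L, FEATURE_WIDTH))
    turn = labels.astype(bool)
    # PSSM block: first 10 columns shift up for turns, last 10 down.
    mu = np.where(turn[:, None], em.pssm_shift, -em.pssm_shift) \
        * np.concatenate([np.ones(10), -np.ones(10)])
    raw = rng.normal(mu, em.pssm_sigma)
    X[:, 0:20] = 1.0 / (1.0 + np.exp(-raw))
    # SPSSM block (3): Dirichlet with class-dependent mean
    for i in range(L):
        p = em.pss_probs_turn if turn[i] else em.pss_probs_nonturn
        X[i, 20:23] = rng.dirichlet(p * em.dirichlet_conc)
    # PSS one-hot (3)
    X[:, 23:26] = 0.0
    for i in range(L):
        p = em.pss_probs_turn if turn[i] else em.pss_probs_nonturn
        X[i, 23 + rng.choice(3, p=p)] = 1.0
    # shape profile (8): Dirichlet
    for i in range(L):
        p = em.shape_probs_turn if turn[i] else em.shape_probs_nonturn
        X[i, 26:34] = rng.dirichlet(p * em.dirichlet_conc)
    # predicted shape one-hot (8)
    X[:, 34:42] = 0.0
    for i in range(L):
        p = em.shape_probs_turn if turn[i] else em.shape_probs_nonturn
        X[i, 34 + rng.choice(8, p=p)] = 1.0
    X[:, 42] = 1.0  # bias
    return X


def _feature_table_from_matrix(X: np.ndarray) -> FeatureTable:
    # route through the assembler's column layout without re-deriving one-hots
    from .features import FEATURE_COLUMNS

    return FeatureTable(values=X, columns=list(FEATURE_COLUMNS))


def sample_crf_corpus(spec: SyntheticCorpusSpec
                      ) -> list[tuple[FeatureTable, np.ndarray]]:
    """Labelled corpus: labels from the sticky two-state chain, features
    from the class-conditional emission model, in the exact 43-column
    layout of :func:`turnkit.features.assemble_features`."""
    rng = np.random.default_rng(spec.seed)
    T = spec.transition_matrix
    init = np.array([1.0 - spec.turn_fraction, spec.turn_fraction])
    corpus = []
    for _ in range(spec.n_sequences):
        L = int(rng.integers(spec.length_low, spec.length_high + 1))
        y = np.empty(L, dtype=np.uint8)
        y[0] = rng.choice(2, p=init)
        for t in range(1, L):
            y[t] = rng.choice(2, p=T[y[t - 1]])
        X = _sample_emissions(rng, y, spec.emission)
        corpus.append((_feature_table_from_matrix(X), y))
    return corpus


def profile_from_probs(probs: np.ndarray, alphabet: str) -> ProfileMatrix:
    """Convenience: wrap an L×K stochastic matrix as a ProfileMatrix."""
    return ProfileMatrix(alphabet=list(alphabet),
                         values=np.asarray(probs, dtype=float))
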