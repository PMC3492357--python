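"""Readers and writers for the standard formats around the pipeline:
PDB backbones, DSSP files, annotation TSV/BED, and the 9-line prediction
report with its machine-readable TSV twin."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, TextIO

import numpy as np

from .annotate import BackboneChain, Residue, TurnLabels

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",   # selenomethionine, deposited as HETATM
}


class ChainNotFoundError(KeyError):
    pass


def read_pdb_backbone(source: TextIO | str, chain_id: str) -> BackboneChain:
    """Read the backbone (N, CA, C, O) of one chain from PDB-format text.

    First model only; altloc blank or 'A'; insertion codes preserved in
    the residue label; HETATM ignored except selenomethionine (MSE → M).
    Residues without a CA atom are dropped with a warning.
    """
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(source)
    atoms = pdb_file.get_structure(model=1, altloc="first")
    chains = sorted(set(atoms.chain_id))
    if chain_id not in chains:
        raise ChainNotFoundError(
            f"chain {chain_id!r} not found; available chains: "
            + ", ".join(chains)
        )
    sel = atoms[atoms.chain_id == chain_id]
    keep = ~sel.hetero | np.isin(sel.res_name, ["MSE"])
    sel = sel[keep]

    residues: list[Residue] = []
    seen: dict[tuple, int] = {}
    order: list[tuple] = []
    per_res: dict[tuple, dict] = {}
    for i in range(sel.array_length()):
        ins = sel.ins_code[i] if hasattr(sel, "ins_code") else ""
        key = (int(sel.res_id[i]), str(ins))
        if key not in per_res:
            per_res[key] = {"res_name": str(sel.res_name[i])}
            order.append(key)
        atom_name = str(sel.atom_name[i])
        if atom_name in ("N", "CA", "C", "O") and atom_name not in per_res[key]:
            per_res[key][atom_name] = np.array(sel.coord[i], dtype=float)

    for key in order:
        rec = per_res[key]
        if "CA" not in rec:
            warnings.warn(f"residue {key[0]}{key[1]} lacks CA; dropped")
            continue
        aa = _THREE_TO_ONE.get(rec["res_name"], "X")
        label = f"{key[0]}{key[1]}".strip()
        residues.append(Residue(res_seq_label=label, aa=aa,
                                N=rec.get("N"), CA=rec.get("CA"),
                                C=rec.get("C"), O=rec.get("O")))
    if not residues:
        raise ValueError(f"chain {chain_id!r} has no usable residues")
    return BackboneChain(chain_id, residues)


def write_pdb_backbone(chain: BackboneChain, sink: TextIO | str) -> None:
    """Minimal PDB writer for backbone fixtures (ATOM records only)."""
    if isinstance(sink, str):
        with open(sink, "w") as fh:
            write_pdb_backbone(chain, fh)
            return
    one_to_three = {v: k for k, v in _THREE_TO_ONE.items() if k != "MSE"}
    serial = 1
    for i, res in enumerate(chain.residues, start=1):
        res3 = one_to_three.get(res.aa, "UNK")
        for name in ("N", "CA", "C", "O"):
            xyz = getattr(res, name)
            if xyz is None:
                continue
            sink.write(
                f"ATOM  {serial:5d}  {name:<4s}{res3:>3s} {chain.chain_id}"
                f"{i:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {name[0]:>2s}\n"
            )
            serial += 1
    sink.write("END\n")


def read_dssp_ss8(path: str, chain_id: str) -> tuple[str, str]:
    """Extract (sequence, 8-state string) for one chain from a DSSP
    output file; blank structure states become '-'."""
    from Bio.PDB.DSSP import make_dssp_dict

    dssp_dict, keys = make_dssp_dict(path)
    seq = []
    ss8 = []
    for key in keys:
        if key[0] != chain_id:
            continue
        aa, ss = dssp_dict[key][0], dssp_dict[key][1]
        seq.append(aa)
        ss8.append(ss if ss.strip() else "-")
    if not seq:
        raise ChainNotFoundError(f"chain {chain_id!r} not in DSSP file")
    return "".join(seq), "".join(ss8)


def read_fasta(source: TextIO | str) -> list[tuple[str, str]]:
    from Bio import SeqIO

    if isinstance(source, str):
        with open(source) as fh:
            return read_fasta(fh)
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(source, "fasta")]


# ---------------------------------------------------------------------------
# Annotation output


def write_annotation_tsv(chain: BackboneChain, ann: TurnLabels, ss8: str,
                         sink: TextIO | str) -> None:
    """Per-residue TSV: 1-based position, residue, 8-state SS, turn label,
    segment id (or '.'), contributing turn types."""
    if isinstance(sink, str):
        with open(sink, "w") as fh:
            write_annotation_tsv(chain, ann, ss8, fh)
            return
    seg_of_pos: dict[int, int] = {}
    for s_id, seg in enumerate(ann.segments):
        for p in range(seg.start, seg.end_exclusive):
            seg_of_pos[p] = s_id
    sink.write("pos\taa\tss8\tlabel\tsegment_id\ttypes\n")
    for i, res in enumerate(chain.residues):
        if i in seg_of_pos:
            seg = ann.segments[seg_of_pos[i]]
            seg_id = str(seg_of_pos[i])
            types = ",".join(sorted(seg.types)) or "."
        else:
            seg_id, types = ".", "."
        sink.write(f"{i + 1}\t{res.aa}\t{ss8[i]}\t{int(ann.labels[i])}"
                   f"\t{seg_id}\t{types}\n")


def write_segments_bed(chain: BackboneChain, ann: TurnLabels,
                       sink: TextIO | str) -> None:
    """BED-like 0-based half-open turn segments: chain, start, end, types."""
    if isinstance(sink, str):
        with open(sink, "w") as fh:
            write_segments_bed(chain, ann, fh)
            return
    for seg in ann.segments:
        types = ",".join(sorted(seg.types)) or "."
        sink.write(f"{chain.chain_id}\t{seg.start}\t{seg.end_exclusive}"
                   f"\t{types}\n")


# ---------------------------------------------------------------------------
# Prediction report (9 lines per query + TSV twin)

DIAGRAM_ALPHABET = "-+=*"


def render_diagram(turn_labels, ss3: str) -> str:
    """Structure diagram: '+' turn, '=' sheet, '*' helix, '-' band (coil).
    A residue that is both turn and helix/sheet renders as turn."""
    turn_labels = np.asarray(turn_labels).ravel()
    if len(turn_labels) != len(ss3):
        raise ValueError("turn labels and ss3 must have equal length")
    out = []
    for t, s in zip(turn_labels, ss3):
        if t:
            out.append("+")
        elif s == "E":
            out.append("=")
        elif s == "H":
            out.append("*")
        else:
            out.append("-")
    return "".join(out)


@dataclass
class QueryResult:
    """One query's prediction bundle for the report writer."""

    query_id: str
    sequence: str
    turn_labels: np.ndarray
    turn_probability: np.ndarray
    pss: str                      # predicted 3-state secondary structure
    sspred: str                   # predicted shape string
    pss_confidence: Optional[np.ndarray] = None
    sspred_confidence: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        L = len(self.sequence)
        for name, val in (("turn_labels", self.turn_labels),
                          ("turn_probability", self.turn_probability)):
            if len(val) != L:
                raise ValueError(f"{name} length != sequence length")
        for name, s in (("pss", self.pss), ("sspred", self.sspred)):
            if len(s) != L:
                raise ValueError(f"{name} length != sequence length")


def _ruler(length: int, start: int) -> str:
    """Position marks every 10 residues, right-aligned under the mark."""
    chars = [" "] * length
    for pos in range(start, start + length):
        if (pos + 1) % 10 == 0:
            label = str(pos + 1)
            end = pos - start
            begin = end - len(label) + 1
            if begin >= 0:
                chars[begin:end + 1] = list(label)
    return "".join(chars)


def _digits(values: Optional[np.ndarray], length: int) -> str:
    if values is None:
        return "." * length
    return "".join(str(min(int(v * 10), 9)) for v in values)


def write_report(results: list[QueryResult], sink: TextIO | str,
                 width: int = 60) -> None:
    """Human-readable report: 9 lines per query — sequence, position
    ruler, predicted turn and its probability digits, predicted 3-state
    secondary structure and confidence, predicted shape string and
    confidence, and the structure diagram — wrapped at `width` columns.
    Probability digits are floor(10·p); the TSV twin carries 2-decimal
    probabilities."""
    if isinstance(sink, str):
        with open(sink, "w") as fh:
            write_report(results, fh, width=width)
            return
    for res in results:
        L = len(res.sequence)
        turn_str = "".join("T" if t else "-" for t in res.turn_labels)
        ss3 = res.pss
        diagram = render_diagram(res.turn_labels, ss3)
        sink.write(f"> {res.query_id}\n")
        for off in range(0, L, width):
            hi = min(off + width, L)
            lines = [
                ("SEQ   ", res.sequence[off:hi]),
                ("POS   ", _ruler(hi - off, off)),
                ("TURN  ", turn_str[off:hi]),
                ("TPROB ", _digits(res.turn_probability, L)[off:hi]),
                ("SS3   ", ss3[off:hi]),
                ("SPROB ", _digits(res.pss_confidence, L)[off:hi]),
                ("SHAPE ", res.sspred[off:hi]),
                ("HPROB ", _digits(res.sspred_confidence, L)[off:hi]),
                ("DIAG  ", diagram[off:hi]),
            ]
            for tag, body in lines:
                sink.write(tag + body + "\n")
            sink.write("\n")


def write_report_tsv(results: list[QueryResult], sink: TextIO | str) -> None:
    """Machine-readable twin of the report (normative format)."""
    if isinstance(sink, str):
        with open(sink, "w") as fh:
            write_report_tsv(results, fh)
            return
    sink.write("query\tpos\taa\tturn\tturn_prob\tss3\tshape\tdiagram\n")
    for res in results:
        diagram = render_diagram(res.turn_labels, res.pss)
        for i in range(len(res.sequence)):
            sink.write(
                f"{res.query_id}\t{i + 1}\t{res.sequence[i]}"
                f"\t{int(res.turn_labels[i])}\t{res.turn_probability[i]:.2f}"
                f"\t{res.pss[i]}\t{res.sspred[i]}\t{diagram[i]}\n"
            )


def read_report_tsv(source: TextIO | str) -> list[QueryResult]:
    if isinstance(source, str):
        with open(source) as fh:
            return read_report_tsv(fh)
    header = source.readline().rstrip("\n").split("\t")
    if header[:2] != ["query", "pos"]:
        raise ValueError("not a turnkit report TSV")
    per_query: dict[str, list[list[str]]] = {}
    order = []
    for line in source:
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 8:
            continue
        if parts[0] not in per_query:
            per_query[parts[0]] = []
            order.append(parts[0])
        per_query[parts[0]].append(parts)
    out = []
    for qid in order:
        rows = per_query[qid]
        out.append(QueryResult(
            query_id=qid,
            sequence="".join(r[2] for r in rows),
            turn_labels=np.array([int(r[3]) for r in rows], dtype=np.uint8),
            turn_probability=np.array([float(r[4]) for r in rows]),
            pss="".join(r[5] for r in rows),
            sspred="".join(r[6] for r in rows),
        ))
    return out


def read_plain_string(source: TextIO | str) -> str:
    """Single PSS/shape string from a plain-text (optionally FASTA-headed)
    file: concatenates all non-header, non-blank lines."""
    if isinstance(source, str):
        with open(source) as fh:
            return read_plain_string(fh)
    parts = [line.strip() for line in source
             if line.strip() and not line.startswith(">")]
    return "".join(parts)
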