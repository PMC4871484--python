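"""Sequence-level proteorhodopsin analyses.

Pairwise global protein alignment (BLOSUM62, affine gaps) drives three
operations: percent identity between homologs, green/blue spectral-tuning
classification from the single switch residue (leucine -> green-absorbing,
~525 nm; glutamine -> blue-absorbing, ~490 nm, read at the position
homologous to 106 in blue-PR numbering), and transfer of annotated key
functional residues (Schiff-base lysine, proton acceptor/donor, the histidine
interacting with the acceptor) from an annotated reference onto a query.
Positions are 1-based throughout, matching the field's residue numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "SequenceRecord",
    "PairwiseIdentity",
    "MappedResidue",
    "ResidueMap",
    "read_fasta",
    "write_fasta",
    "pairwise_identity",
    "classify_spectral_tuning",
    "map_key_residues",
    "coding_length_nt",
    "KEY_RESIDUE_CLASSES",
]

_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: Expected one-letter residue class at each annotated key position.
KEY_RESIDUE_CLASSES = {
    "acceptor": "D",
    "donor": "K",
    "his_partner": "H",
    "schiff_lysine": "K",
    "tuning_switch": "LQ",  # either family's switch residue
}


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty sequence")
        bad = set(self.residues.upper()) - _ALPHABET
        if bad:
            raise ValueError(f"invalid residue letters: {sorted(bad)}")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PairwiseIdentity:
    percent: float  # one decimal
    rounded: int
    aligned_query: str
    aligned_target: str
    n_identical: int
    n_columns: int


@dataclass
class MappedResidue:
    position: int  # 1-based in the query
    residue: str
    expected_class: str
    matches_expectation: bool


@dataclass
class ResidueMap:
    """Key functional residues transferred onto a query sequence.

    Fields are ``None`` where the reference position falls in a query gap."""

    acceptor: MappedResidue | None = None
    donor: MappedResidue | None = None
    his_partner: MappedResidue | None = None
    schiff_lysine: MappedResidue | None = None
    tuning_switch: MappedResidue | None = None
    extra: dict = field(default_factory=dict)

    def __getitem__(self, name: str):
        if name in ("acceptor", "donor", "his_partner", "schiff_lysine", "tuning_switch"):
            return getattr(self, name)
        return self.extra[name]


def read_fasta(path) -> list[SequenceRecord]:
    return [SequenceRecord(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.residues), 60):
                fh.write(r.residues[i : i + 60] + "\n")


def _aligner(end_gap_free: bool = False) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    if end_gap_free:
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def _align(a: SequenceRecord, b: SequenceRecord, end_gap_free: bool = False):
    alignment = _aligner(end_gap_free).align(a.residues, b.residues)[0]
    return alignment[0], alignment[1]  # gapped strings, equal length


def pairwise_identity(
    a: SequenceRecord, b: SequenceRecord, end_gap_free: bool = False
) -> PairwiseIdentity:
    """Percent identity over a global alignment.

    Identity = identical aligned pairs / columns holding at least one residue
    (dual-gap columns cannot occur in a pairwise alignment), x 100, reported
    to one decimal plus the conventional rounded integer.
    """
    ga, gb = _align(a, b, end_gap_free)
    n_id = sum(x == y and x != "-" for x, y in zip(ga, gb))
    n_cols = sum(not (x == "-" and y == "-") for x, y in zip(ga, gb))
    pct = 100.0 * n_id / n_cols
    return PairwiseIdentity(
        percent=round(pct, 1),
        rounded=int(round(pct)),
        aligned_query=ga,
        aligned_target=gb,
        n_identical=n_id,
        n_columns=n_cols,
    )


def _map_position(
    ref_gapped: str, query_gapped: str, ref_position: int
) -> tuple[int | None, str | None]:
    """Query 1-based position aligned to a reference 1-based position."""
    seen = 0
    for col, (r, q) in enumerate(zip(ref_gapped, query_gapped)):
        if r != "-":
            seen += 1
            if seen == ref_position:
                if q == "-":
                    return None, None
                qpos = sum(c != "-" for c in query_gapped[: col + 1])
                return qpos, q
    return None, None  # reference shorter than the annotated position


def classify_spectral_tuning(
    query: SequenceRecord,
    ref: SequenceRecord,
    tuning_position: int = 106,
    min_identity: float = 30.0,
) -> dict:
    """Green/blue classification from the spectral-tuning switch residue.

    Aligns the query to a blue-PR-numbered reference and reads the residue
    homologous to ``tuning_position`` (106 in BPR numbering): L -> "green",
    Q -> "blue", anything else -> "unassigned" with the residue reported.
    Raises when the alignment identity falls below ``min_identity`` percent.
    """
    ident = pairwise_identity(ref, query)
    if ident.percent < min_identity:
        raise ValueError(
            f"query/reference identity {ident.percent:.1f}% below the "
            f"{min_identity:.0f}% floor: unalignable"
        )
    qpos, residue = _map_position(ident.aligned_query, ident.aligned_target, tuning_position)
    if qpos is None:
        return {"classification": "unassigned", "residue": None,
                "query_position": None, "identity": ident.percent}
    call = {"L": "green", "Q": "blue"}.get(residue, "unassigned")
    return {"classification": call, "residue": residue,
            "query_position": qpos, "identity": ident.percent}


def map_key_residues(
    query: SequenceRecord,
    ref: SequenceRecord,
    annotations: dict,
    min_identity: float = 30.0,
) -> ResidueMap:
    """Transfer annotated reference positions onto a query via the alignment.

    ``annotations`` maps names (e.g. "acceptor", "schiff_lysine") to 1-based
    reference positions.  Each transferred position is checked against the
    expected residue class (:data:`KEY_RESIDUE_CLASSES`); positions falling in
    a query gap come back as ``None`` (unmapped).
    """
    for name, pos in annotations.items():
        if not 1 <= pos <= len(ref):
            raise ValueError(f"annotation {name!r} at {pos} outside the reference")
    ident = pairwise_identity(ref, query)
    if ident.percent < min_identity:
        raise ValueError(
            f"query/reference identity {ident.percent:.1f}% below the "
            f"{min_identity:.0f}% floor: unalignable"
        )
    result = ResidueMap()
    for name, pos in annotations.items():
        qpos, residue = _map_position(ident.aligned_query, ident.aligned_target, pos)
        if qpos is None:
            mapped = None
        else:
            expected = KEY_RESIDUE_CLASSES.get(name, "")
            mapped = MappedResidue(
                position=qpos,
                residue=residue,
                expected_class=expected,
                matches_expectation=(residue in expected) if expected else True,
            )
        if name in ("acceptor", "donor", "his_partner", "schiff_lysine", "tuning_switch"):
            setattr(result, name, mapped)
        else:
            result.extra[name] = mapped
    return result


def coding_length_nt(n_residues: int, include_stop: bool = False) -> int:
    """Coding-sequence length in nucleotides for a protein of given length
    (3 nt per residue; 248 residues <-> 744 bp)."""
    if n_residues <= 0:
        raise ValueError("n_residues must be positive")
    return 3 * (n_residues + (1 if include_stop else 0))
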