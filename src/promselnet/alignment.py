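"""Three-species (human/chimp/macaque) alignment container and FASTA I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval

__all__ = [
    "TripletAlignment",
    "read_triplet_fasta",
    "write_triplet_fasta",
    "extract_analysis_segment",
]

ALPHABET = set("ACGT-N")

# integer encoding used throughout the likelihood machinery
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
GAP = 5
N_CODE = 4

_SPECIES_TAGS = {
    "human": ("human", "homo", "hsap", "hg18", "hg19", "hg38"),
    "chimp": ("chimp", "pan_troglodytes", "pantro", "ptro"),
    "macaque": ("macaque", "macaca", "rhesus", "macrhe", "mmul"),
}


@dataclass(frozen=True)
class TripletAlignment:
    """Aligned human/chimp/macaque sequences of equal length over {A,C,G,T,-,N}.

    Row order is fixed: (human, chimp, macaque).
    """

    ids: tuple[str, str, str]
    seqs: tuple[str, str, str]
    role: str = "promoter"

    def __post_init__(self) -> None:
        if len(self.ids) != 3 or len(self.seqs) != 3:
            raise ValueError("a triplet alignment needs exactly three rows")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError(f"unequal row lengths: {[len(s) for s in self.seqs]}")
        for sid, s in zip(self.ids, self.seqs):
            bad = set(s) - ALPHABET
            if bad:
                raise ValueError(f"{sid}: illegal characters {sorted(bad)}")
        if self.role not in ("promoter", "intron"):
            raise ValueError(f"role must be 'promoter' or 'intron', got {self.role!r}")

    def __len__(self) -> int:
        return len(self.seqs[0])

    @property
    def human(self) -> str:
        return self.seqs[0]

    @property
    def chimp(self) -> str:
        return self.seqs[1]

    @property
    def macaque(self) -> str:
        return self.seqs[2]

    def codes(self) -> np.ndarray:
        """(3, L) int8 matrix: A=0 C=1 G=2 T=3 N=4 gap=5."""
        table = np.full(128, -1, dtype=np.int8)
        for ch, code in BASE_CODES.items():
            table[ord(ch)] = code
        return np.vstack(
            [table[np.frombuffer(s.encode(), dtype=np.uint8)] for s in self.seqs]
        )


def _order_by_species_tag(records: list[SeqRecord]) -> list[SeqRecord] | None:
    """Reorder records as (human, chimp, macaque) if headers carry species tags."""
    picked: dict[str, SeqRecord] = {}
    for rec in records:
        text = (rec.id + " " + (rec.description or "")).lower()
        for species, tags in _SPECIES_TAGS.items():
            if any(tag in text for tag in tags):
                if species in picked:
                    return None  # ambiguous tagging, keep file order
                picked[species] = rec
                break
    if len(picked) == 3:
        return [picked["human"], picked["chimp"], picked["macaque"]]
    return None


def read_triplet_fasta(path: str | Path, role: str = "promoter") -> TripletAlignment:
    """Read a 3-record aligned FASTA as (human, chimp, macaque).

    Records are taken in file order unless all three headers carry
    recognizable species tags, in which case tags win.  Sequences are
    upper-cased; anything outside {A,C,G,T,-,N} is rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 3:
        raise ValueError(f"{path}: expected 3 FASTA records, found {len(records)}")
    ordered = _order_by_species_tag(records) or records
    ids = tuple(rec.id for rec in ordered)
    seqs = tuple(str(rec.seq).upper() for rec in ordered)
    return TripletAlignment(ids=ids, seqs=seqs, role=role)


def write_triplet_fasta(aln: TripletAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def extract_analysis_segment(
    aln: TripletAlignment,
    human_window: GenomicInterval,
    human_anchor: int,
) -> TripletAlignment:
    """Slice the alignment columns covering a human coordinate window.

    ``human_anchor`` is the absolute human coordinate of the first ungapped
    human base of the alignment; ungapped human positions are laid off from
    it.  Columns whose human residue falls in [window.start, window.end) are
    kept; human-gap columns strictly inside the already-started window are
    retained (so the returned segment can be longer than the window when the
    human row carries gaps).
    """
    start, end = human_window.start, human_window.end
    human = aln.human
    ungapped = sum(1 for ch in human if ch != "-")
    if start < human_anchor or end > human_anchor + ungapped:
        raise ValueError(
            f"window [{start},{end}) outside aligned human span "
            f"[{human_anchor},{human_anchor + ungapped})"
        )
    keep: list[int] = []
    pos = human_anchor
    for col, ch in enumerate(human):
        if ch == "-":
            if start < pos < end:
                keep.append(col)
        else:
            if start <= pos < end:
                keep.append(col)
            pos += 1
    if not keep:
        raise ValueError("window selects no alignment columns")
    seqs = tuple("".join(s[c] for c in keep) for s in aln.seqs)
    return TripletAlignment(ids=aln.ids, seqs=seqs, role=aln.role)
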