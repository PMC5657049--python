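"""Six-frame translation of nucleotide read ends for protein-space search.

Frames +1..+3 read the sequence at offsets 0..2; frames -1..-3 read the
reverse complement at the same offsets.  The standard genetic code
(NCBI table 1) is used throughout.  Stop codons become ``'*'`` and are
kept in the peptide: the aligner assigns them zero emission
probability, which truncates any alignment at the stop.  Codons with
ambiguity codes translate to the unique residue when every resolution
agrees, else to ``'X'`` (emitted at background probability downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(slots=True, frozen=True)
class FramedPeptide:
    """One reading frame of one read end.

    ``nt_offset`` is the 0-based offset of the frame start on the read
    (for minus frames, on its reverse complement).
    """

    read_id: str
    end: int
    frame: int
    peptide: str
    nt_offset: int


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_frame(seq: str, frame: int) -> str:
    """Translate one frame; the trailing partial codon is dropped."""
    s = seq if frame > 0 else reverse_complement(seq)
    off = abs(frame) - 1
    usable = (len(s) - off) // 3 * 3
    if usable <= 0:
        return ""
    return str(Seq(s[off:off + usable]).translate())


def six_frame_translate(seq: str, read_id: str = "", end: int = 1) -> list[FramedPeptide]:
    """All six reading frames of ``seq`` as :class:`FramedPeptide` objects."""
    if len(seq) < 3:
        raise ValueError(f"sequence of length {len(seq)} has no complete codon")
    return [
        FramedPeptide(read_id, end, f, translate_frame(seq, f), abs(f) - 1)
        for f in FRAMES
    ]
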