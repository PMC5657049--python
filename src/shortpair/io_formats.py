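"""Readers and writers for the standard formats the tool touches.

FASTA/FASTQ parsing goes through Biopython; Stockholm reading uses
``Bio.AlignIO`` (which copes with interleaved and wrapped files) while
writing uses a minimal single-block Pfam-style emitter so that files
round-trip byte-identically.  Profile HMMs are exchanged in HMMER3/f
ASCII; per-domain hits in HMMER's ``--domtblout`` table.

No science lives here: every function maps bytes to domain types and
back.  All coordinates in files produced by this module are 1-based
inclusive, matching HMMER conventions.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import AlignIO, SeqIO

AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ALPHABET)}
GAP_CHARS = frozenset("-.")

_IUPAC_NT = frozenset("ACGTUNRYSWKMBDHV" "acgtunryswkmbdhv")

# Casava 1.8 style: "read1 1:N:0:ACGT" -> mate tag is first field of the
# description after the id.
_CASAVA_RE = re.compile(r"^([12]):[YN]:\d+:")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# paired reads
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class ReadPair:
    """A paired-end nucleotide read: two mates sharing one identifier."""

    id: str
    end1: str
    end2: str
    qual1: str | None = None
    qual2: str | None = None

    def __post_init__(self) -> None:
        if not self.end1 or not self.end2:
            raise ValueError(f"read pair {self.id!r}: empty end sequence")
        for end in (self.end1, self.end2):
            bad = set(end) - _IUPAC_NT
            if bad:
                raise ValueError(
                    f"read pair {self.id!r}: non-IUPAC nucleotide codes {sorted(bad)}"
                )


def _strip_mate_tag(record_id: str, description: str) -> tuple[str, int | None]:
    """Return (pair id, mate number) for one FASTA/FASTQ record.

    Supports the ``/1``-``/2`` suffix dialect and the Casava-style
    space-delimited ``1:N:0:...`` tag; returns mate ``None`` when the
    record carries no recognisable tag.
    """
    if record_id.endswith("/1") or record_id.endswith("/2"):
        return record_id[:-2], int(record_id[-1])
    # description includes the id itself; look at the remainder
    rest = description[len(record_id):].strip() if description.startswith(record_id) else description
    m = _CASAVA_RE.match(rest)
    if m:
        return record_id, int(m.group(1))
    return record_id, None


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line[0]
                break
        else:
            raise FormatError(f"{path}: empty file")
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise FormatError(f"{path}: neither FASTA nor FASTQ (first char {first!r})")


def _read_records(path: Path) -> tuple[str, list[tuple[str, int | None, str, str | None]]]:
    fmt = _sniff_format(path)
    out = []
    for rec in SeqIO.parse(str(path), fmt):
        pid, mate = _strip_mate_tag(rec.id, rec.description)
        qual = None
        if fmt == "fastq":
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((pid, mate, str(rec.seq), qual))
    if not out:
        raise FormatError(f"{path}: no records")
    return fmt, out


def read_paired_reads(path1: str | Path, path2: str | Path | None = None) -> list[ReadPair]:
    """Read paired-end reads from two files, or one interleaved file.

    Mates are paired by identifier after stripping ``/1``, ``/2`` or
    Casava-style mate tags; the output preserves the order of the first
    file.  Raises :class:`FormatError` naming the orphan when an id
    appears on only one side.
    """
    fmt1, recs1 = _read_records(Path(path1))
    if path2 is not None:
        fmt2, recs2 = _read_records(Path(path2))
        if fmt2 != fmt1:
            raise FormatError(
                f"mixed formats: {path1} is {fmt1.upper()}, {path2} is {fmt2.upper()}")
    else:
        # interleaved convention: records alternate /1, /2
        if len(recs1) % 2:
            raise FormatError(f"{path1}: odd record count in interleaved file")
        recs1, recs2 = recs1[0::2], recs1[1::2]

    by_id2 = {}
    for pid, mate, seq, qual in recs2:
        if pid in by_id2:
            raise FormatError(f"duplicate identifier {pid!r} in mate-2 records")
        by_id2[pid] = (seq, qual)

    pairs: list[ReadPair] = []
    seen = set()
    for pid, mate, seq, qual in recs1:
        if pid not in by_id2:
            raise FormatError(f"unpaired identifier {pid!r}: no mate-2 record")
        seq2, qual2 = by_id2[pid]
        pairs.append(ReadPair(pid, seq, seq2, qual, qual2))
        seen.add(pid)
    orphans = [pid for pid, *_ in recs2 if pid not in seen]
    if orphans:
        raise FormatError(f"unpaired identifier(s) in mate-2 file: {orphans}")
    return pairs


def write_paired_fastq(pairs: Sequence[ReadPair], path1: str | Path, path2: str | Path,
                       default_qual: str = "I") -> None:
    """Write mates to two FASTQ files with ``/1`` and ``/2`` suffixes."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            q1 = p.qual1 or default_qual * len(p.end1)
            q2 = p.qual2 or default_qual * len(p.end2)
            f1.write(f"@{p.id}/1\n{p.end1}\n+\n{q1}\n")
            f2.write(f"@{p.id}/2\n{p.end2}\n+\n{q2}\n")


# ---------------------------------------------------------------------------
# seed alignments (Stockholm / aligned FASTA)
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class SeedAlignment:
    """A family's seed multiple sequence alignment.

    ``rf`` holds the ``#=GC RF`` reference-annotation line when the file
    provides one; gap characters in rows are ``-`` or ``.`` and are
    treated identically.
    """

    family_id: str
    rows: list[tuple[str, str]]
    n_columns: int
    rf: str | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"alignment {self.family_id!r}: no rows")
        for sid, aligned in self.rows:
            if len(aligned) != self.n_columns:
                raise ValueError(
                    f"alignment {self.family_id!r}: row {sid!r} has length "
                    f"{len(aligned)}, expected {self.n_columns}"
                )
        if self.rf is not None and len(self.rf) != self.n_columns:
            raise ValueError(f"alignment {self.family_id!r}: RF length mismatch")


def read_stockholm(path: str | Path) -> SeedAlignment:
    """Read a single-alignment Stockholm 1.0 file (aligned FASTA fallback)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    fmt = "stockholm" if first.startswith("# STOCKHOLM") else "fasta"
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if len(aln) == 0:
        raise FormatError(f"{path}: empty alignment")
    rf = aln.column_annotations.get("reference_annotation")
    family_id = _stockholm_family_id(path) or path.stem
    return SeedAlignment(
        family_id=family_id,
        rows=[(rec.id, str(rec.seq)) for rec in aln],
        n_columns=aln.get_alignment_length(),
        rf=rf,
    )


def _stockholm_family_id(path: Path) -> str | None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#=GF ID"):
                return line.split(None, 2)[2].strip()
            if line.startswith("//"):
                break
    return None


def write_stockholm(msa: SeedAlignment, path: str | Path) -> None:
    """Write a single-block Pfam-style Stockholm file.

    The emitted layout (``#=GF ID``, padded names, optional ``#=GC RF``)
    is stable: reading the file back and writing it again reproduces the
    bytes exactly.
    """
    width = max(len(sid) for sid, _ in msa.rows)
    width = max(width, len("#=GC RF"))
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        fh.write(f"#=GF ID {msa.family_id}\n")
        for sid, aligned in msa.rows:
            # '.' and '-' are equivalent; emit the canonical '-' so the
            # file is stable under a read/write cycle
            fh.write(f"{sid:<{width}} {aligned.replace('.', '-')}\n")
        if msa.rf is not None:
            fh.write(f"{'#=GC RF':<{width}} {msa.rf}\n")
        fh.write("//\n")


# ---------------------------------------------------------------------------
# profile HMM exchange (HMMER3/f ASCII)
# ---------------------------------------------------------------------------

# transition column order in HMMER3 files and in ProfileHMM.transitions
TRANS_ORDER = ("MM", "MI", "MD", "IM", "II", "DM", "DD")


def _score(p: float) -> str:
    """Probability -> negative-natural-log field (HMMER convention)."""
    if p <= 0.0:
        return "*"
    return f"{-math.log(p):.10f}"


def _prob(tok: str) -> float:
    if tok == "*":
        return 0.0
    v = float(tok)
    p = math.exp(-v)
    if math.isnan(p) or p < 0.0:
        raise FormatError(f"invalid score field {tok!r}")
    return p


def write_hmmer3_hmm(hmm, path: str | Path) -> None:
    """Write a ProfileHMM as HMMER3/f ASCII.

    Fields are emitted with 10 decimal places (more than hmmbuild's 5)
    so probabilities survive a write/read cycle to better than 1e-9.
    """
    L = hmm.L
    with open(path, "w") as fh:
        fh.write("HMMER3/f [shortpair]\n")
        fh.write(f"NAME  {hmm.family_id}\n")
        fh.write(f"LENG  {L}\n")
        fh.write("ALPH  amino\n")
        fh.write("RF    no\nMM    no\nCONS  no\nCS    no\nMAP   yes\n")
        if hmm.gumbel_mu is not None and hmm.gumbel_lambda is not None:
            fh.write(f"STATS LOCAL VITERBI {hmm.gumbel_mu:.5f} {hmm.gumbel_lambda:.5f}\n")
        fh.write("HMM          " + "        ".join(AMINO_ALPHABET) + "\n")
        fh.write("            m->m     m->i     m->d     i->m     i->i     d->m     d->d\n")
        if hmm.background is not None:
            fh.write("  COMPO   " + " ".join(_score(p) for p in hmm.background) + "\n")
        # node 0: insert-0 emissions and begin transitions (uniform entry is
        # modelled separately; the file records a conventional B->M1 line)
        fh.write("          " + " ".join(_score(p) for p in hmm.background) + "\n")
        fh.write("          " + " ".join([_score(1.0), _score(0.0), _score(0.0),
                                          _score(1.0), _score(0.0), _score(1.0), "*"]) + "\n")
        for k in range(L):
            fh.write(f"{k + 1:7d}   " + " ".join(_score(p) for p in hmm.match_emissions[k])
                     + f" {hmm.map_to_column[k]:6d} - - - -\n")
            fh.write("          " + " ".join(_score(p) for p in hmm.insert_emissions[k]) + "\n")
            fh.write("          " + " ".join(_score(p) for p in hmm.transitions[k]) + "\n")
        fh.write("//\n")


def read_hmmer3_hmm(path: str | Path):
    """Parse an HMMER3/f ASCII profile into a :class:`ProfileHMM`.

    Scores are converted from the file's negative-natural-log convention
    to probabilities.  The MAP annotation and the ``STATS LOCAL VITERBI``
    line are captured when present; a missing COMPO line falls back to a
    uniform background and is recorded on the returned object.
    """
    from .profile_hmm import ProfileHMM  # deferred: avoids import cycle

    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("HMMER3/"):
        raise FormatError(f"{path}: not an HMMER3 ASCII file")
    if not lines[0].startswith("HMMER3/f"):
        raise FormatError(f"{path}: unsupported format version {lines[0].split()[0]!r}")

    name = path.stem
    L = None
    mu = lam = None
    i = 1
    while i < len(lines) and not lines[i].startswith("HMM "):
        tok = lines[i].split()
        if tok and tok[0] == "NAME":
            name = tok[1]
        elif tok and tok[0] == "LENG":
            L = int(tok[1])
        elif tok and tok[0] == "ALPH" and tok[1].lower() != "amino":
            raise FormatError(f"{path}: alphabet {tok[1]!r} not supported")
        elif tok and tok[0] == "STATS" and tok[1] == "LOCAL" and tok[2] == "VITERBI":
            mu, lam = float(tok[3]), float(tok[4])
        i += 1
    if L is None or i >= len(lines):
        raise FormatError(f"{path}: missing LENG or HMM section")
    i += 2  # skip the two column-header lines

    background = None
    background_from_compo = False
    tok = lines[i].split()
    if tok and tok[0] == "COMPO":
        background = np.array([_prob(t) for t in tok[1:21]])
        background_from_compo = True
        i += 1
    i += 2  # node-0 insert emissions + transitions (fixed by convention)
    if background is None:
        background = np.full(20, 1.0 / 20.0)

    match = np.zeros((L, 20))
    insert = np.zeros((L, 20))
    trans = np.zeros((L, 7))
    map_to_column = np.zeros(L, dtype=np.int64)
    have_map = True
    for k in range(L):
        mt = lines[i].split()
        if int(mt[0]) != k + 1:
            raise FormatError(f"{path}: expected node {k + 1}, got {mt[0]!r}")
        match[k] = [_prob(t) for t in mt[1:21]]
        map_tok = mt[21] if len(mt) > 21 else "-"
        if map_tok == "-":
            have_map = False
        else:
            map_to_column[k] = int(map_tok)
        insert[k] = [_prob(t) for t in lines[i + 1].split()[:20]]
        trans[k] = [_prob(t) for t in lines[i + 2].split()[:7]]
        i += 3
    if not have_map:
        map_to_column = np.arange(1, L + 1, dtype=np.int64)

    # files carry limited decimal precision; restore exact normalisation
    match /= match.sum(axis=1, keepdims=True)
    insert /= insert.sum(axis=1, keepdims=True)
    for sl in (slice(0, 3), slice(3, 5), slice(5, 7)):
        block = trans[:, sl]
        sums = block.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise FormatError(f"{path}: empty transition bundle")
        trans[:, sl] = block / sums
    background = background / background.sum()

    return ProfileHMM(
        family_id=name,
        L=L,
        match_emissions=match,
        insert_emissions=insert,
        transitions=trans,
        background=background,
        map_to_column=map_to_column,
        gumbel_mu=mu,
        gumbel_lambda=lam,
        background_from_compo=background_from_compo,
    )


# ---------------------------------------------------------------------------
# domtblout
# ---------------------------------------------------------------------------

def parse_domtblout(path: str | Path):
    """Parse an HMMER3 ``--domtblout`` table into DomainHits.

    Model coordinates come from the ``hmm coord`` from/to columns
    (fields 16-17, 1-based), envelope coordinates from fields 20-21, the
    per-domain bit score from field 14 and the i-E-value from field 13.
    The query name is split back into (read id, end, frame) when it uses
    this tool's ``<id>/<end>:<frame>`` convention.
    """
    from .profile_hmm import DomainHit  # deferred: avoids import cycle

    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 23:
                raise FormatError(f"{path}:{lineno}: short domtblout line ({len(f)} fields)")
            query = f[3]
            read_id, end, frame = _split_query_name(query)
            hits.append(DomainHit(
                read_id=read_id, end=end, frame=frame,
                family_id=f[0],
                model_start=int(f[15]), model_end=int(f[16]),
                seq_start=int(f[19]), seq_end=int(f[20]),
                score=float(f[13]), evalue=float(f[12]),
            ))
    return hits


_QUERY_RE = re.compile(r"^(.*)/([12]):([+-][123])$")


def _split_query_name(query: str) -> tuple[str, int, int]:
    m = _QUERY_RE.match(query)
    if m:
        return m.group(1), int(m.group(2)), int(m.group(3))
    rid, mate = query, 1
    if query.endswith("/1") or query.endswith("/2"):
        rid, mate = query[:-2], int(query[-1])
    return rid, mate, 1


def format_query_name(read_id: str, end: int, frame: int) -> str:
    return f"{read_id}/{end}:{frame:+d}"


# ---------------------------------------------------------------------------
# fragment-length distribution TSV
# ---------------------------------------------------------------------------

def write_fragdist_tsv(dist, path: str | Path) -> None:
    """Serialize a fragment-length distribution as (length_aa, probability)."""
    with open(path, "w") as fh:
        fh.write("length_aa\tprobability\n")
        for length in range(dist.support_min, dist.support_max + 1):
            fh.write(f"{length}\t{dist.prob(length):.10g}\n")


def read_fragdist_tsv(path: str | Path):
    from .fragment_model import FragmentLengthDistribution

    probs: dict[int, float] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("length_aa"):
            raise FormatError(f"{path}: missing fragdist header")
        for line in fh:
            if not line.strip():
                continue
            length, p = line.split("\t")
            probs[int(length)] = float(p)
    if not probs:
        raise FormatError(f"{path}: empty distribution")
    return FragmentLengthDistribution.from_probs(probs)
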