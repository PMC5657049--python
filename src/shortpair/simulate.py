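"""Synthetic families, genes and paired-end reads with known truth.

The generator emulates the data regime the method targets: protein
domain families given as seed alignments, a held-out member gene that
is *not* in the training set, DNA fragments drawn from a truncated
normal length distribution, and fixed-length inward-facing (FR) read
pairs sequenced from the two fragment ends with substitution errors.

The substitution model is deliberately analytic rather than
biological: a residue mutates to one of the 19 alternatives uniformly,
so pairwise identity has a closed form and tests can assert against
it.  Back-translation picks synonymous codons uniformly.  Optionally a
chosen fraction of pairs carries a "diverged mate": extra substitutions
applied to the gene region under end 2 only, emulating read pairs whose
second end has drifted too far from the family for a default scan to
find while the first end still anchors the pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .io_formats import AMINO_ALPHABET, ReadPair, SeedAlignment, write_paired_fastq, write_stockholm
from .translate import reverse_complement

# inverse standard genetic code (NCBI table 1), sense codons only
_BACK_TABLE: dict[str, list[str]] = {}
for codon, aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _BACK_TABLE.setdefault(aa, []).append(codon)
for codons in _BACK_TABLE.values():
    codons.sort()

_AA = np.array(list(AMINO_ALPHABET))
_NT = np.array(list("ACGT"))


@dataclass(slots=True)
class SimScenario:
    """Parameters of one synthetic study condition.

    Defaults follow an Illumina-style paired-end protein-domain
    screen: 76-bp reads, fragments of 198-801 bp (66-267 amino acids)
    centred near 450 bp, and seed families of ten members at moderate
    divergence from their common ancestor.
    """

    n_families: int = 5
    seeds_per_family: int = 10
    family_length: int = 300          # amino acids
    divergence: float = 0.3           # per-site seed substitution probability
    indel_rate: float = 0.02          # per-site seed indel probability
    member_divergence: float = 0.1    # divergence of the held-out gene
    fragment_mean: float = 150.0      # amino acids
    fragment_sd: float = 15.0
    fragment_min: int = 66            # 198 bp / 3
    fragment_max: int = 267           # 801 bp / 3
    read_length_nt: int = 76
    n_pairs: int = 1000
    error_rate: float = 0.005         # per-base sequencing substitution
    diverged_mate_fraction: float = 0.0
    diverged_mate_divergence: float = 0.4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("divergence", "indel_rate", "member_divergence", "error_rate",
                     "diverged_mate_fraction", "diverged_mate_divergence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.fragment_min * 3 < self.read_length_nt:
            raise ValueError("minimum fragment must cover one read length")
        if self.family_length < self.fragment_max:
            raise ValueError("family must be at least as long as the longest fragment")


@dataclass(slots=True)
class PairTruth:
    read_id: str
    family_id: str
    fragment_length_aa: int
    gene_start_nt: int  # 0-based fragment start on the gene
    diverged_mate: bool


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each residue with probability ``rate``, uniformly over
    the 19 alternatives."""
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    for i in np.nonzero(hit)[0]:
        choices = [a for a in AMINO_ALPHABET if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return out


def back_translate(peptide: str, rng: np.random.Generator) -> str:
    """Nucleotide sequence for a peptide, synonymous codons uniform."""
    return "".join(
        _BACK_TABLE[aa][rng.integers(len(_BACK_TABLE[aa]))] for aa in peptide
    )


def simulate_family(scenario: SimScenario, family_id: str, rng: np.random.Generator
                    ) -> tuple[SeedAlignment, str, str]:
    """One family: a seed alignment plus a held-out member gene.

    Returns ``(alignment, member_aa, member_nt)``.  Seeds and the
    member derive independently from a background-sampled ancestor by
    i.i.d. substitutions; seed indels appear as delete gaps in match
    columns and single-residue insert columns (marked '.' in the RF
    line).  The member carries no indels and never appears among the
    seeds.
    """
    n = scenario.family_length
    ancestor = _AA[rng.integers(20, size=n)]

    seeds = []
    inserts_after: dict[int, dict[int, str]] = {}  # position -> {seed: residue}
    for s in range(scenario.seeds_per_family):
        row = _mutate(ancestor, scenario.divergence, rng)
        chars = list(row)
        # deletions: gap out a match position
        for i in np.nonzero(rng.random(n) < scenario.indel_rate / 2.0)[0]:
            chars[int(i)] = "-"
        seeds.append(chars)
        # insertions: one residue after a position, private to this seed
        for i in np.nonzero(rng.random(n) < scenario.indel_rate / 2.0)[0]:
            inserts_after.setdefault(int(i), {})[s] = str(_AA[rng.integers(20)])

    columns: list[list[str]] = []
    rf = []
    for i in range(n):
        columns.append([seeds[s][i] for s in range(len(seeds))])
        rf.append("x")
        if i in inserts_after:
            ins = inserts_after[i]
            columns.append([ins.get(s, ".") for s in range(len(seeds))])
            rf.append(".")
    rows = [
        (f"{family_id}_seed{s + 1}", "".join(col[s] for col in columns))
        for s in range(len(seeds))
    ]
    msa = SeedAlignment(family_id, rows, n_columns=len(columns), rf="".join(rf))

    member = _mutate(ancestor, scenario.member_divergence, rng)
    member_aa = "".join(member)
    member_nt = back_translate(member_aa, rng)
    return msa, member_aa, member_nt


def _truncated_normal_int(mean: float, sd: float, lo: int, hi: int,
                          rng: np.random.Generator) -> int:
    """Rejection-sampled integer from a truncated normal."""
    while True:
        x = int(round(rng.normal(mean, sd)))
        if lo <= x <= hi:
            return x


def _sequencing_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return read
    chars = list(read)
    for i in np.nonzero(rng.random(len(chars)) < rate)[0]:
        alts = [b for b in "ACGT" if b != chars[i]]
        chars[int(i)] = alts[rng.integers(3)]
    return "".join(chars)


def simulate_pairs(scenario: SimScenario, gene_nt: str, family_id: str,
                   rng: np.random.Generator, n_pairs: int,
                   id_offset: int = 0) -> tuple[list[ReadPair], list[PairTruth]]:
    """Sequence ``n_pairs`` FR-oriented read pairs from one gene.

    Fragment lengths are drawn in amino acids from the scenario's
    truncated normal and converted to nucleotides (x3); fragments are
    placed uniformly (any offset, not codon-aligned).  End 1 is the
    first ``read_length_nt`` bases of the fragment, end 2 the reverse
    complement of the last.  For a ``diverged_mate_fraction`` of pairs,
    the codons under end 2 are additionally substituted at
    ``diverged_mate_divergence`` before sequencing.
    """
    rl = scenario.read_length_nt
    max_frag_nt = scenario.fragment_max * 3
    if len(gene_nt) < max_frag_nt:
        raise ValueError("gene shorter than the maximum fragment")
    pairs, truths = [], []
    for j in range(n_pairs):
        f_aa = _truncated_normal_int(scenario.fragment_mean, scenario.fragment_sd,
                                     scenario.fragment_min, scenario.fragment_max, rng)
        f_nt = 3 * f_aa
        start = int(rng.integers(0, len(gene_nt) - f_nt + 1))
        fragment = gene_nt[start:start + f_nt]
        diverged = bool(rng.random() < scenario.diverged_mate_fraction)
        if diverged:
            fragment = _diverge_tail_codons(
                fragment, rl, scenario.diverged_mate_divergence, rng)
        end1 = _sequencing_errors(fragment[:rl], scenario.error_rate, rng)
        end2 = _sequencing_errors(reverse_complement(fragment[-rl:]),
                                  scenario.error_rate, rng)
        rid = f"sim{id_offset + j:06d}"
        pairs.append(ReadPair(rid, end1, end2))
        truths.append(PairTruth(rid, family_id, f_aa, start, diverged))
    return pairs, truths


def _diverge_tail_codons(fragment: str, read_len: int, rate: float,
                         rng: np.random.Generator) -> str:
    """Substitute amino acids encoded in the fragment's 3' tail (the
    region end 2 is sequenced from) and re-back-translate them."""
    tail_start = len(fragment) - read_len
    first_codon = -(-tail_start // 3)  # first codon fully inside the tail
    n_codons = len(fragment) // 3
    chars = list(fragment)
    for c in range(first_codon, n_codons):
        if rng.random() < rate:
            codon = fragment[3 * c: 3 * c + 3]
            table = CodonTable.unambiguous_dna_by_id[1].forward_table
            aa = table.get(codon)
            if aa is None:
                continue
            alt = [a for a in AMINO_ALPHABET if a != aa]
            new_aa = alt[rng.integers(len(alt))]
            new_codon = _BACK_TABLE[new_aa][rng.integers(len(_BACK_TABLE[new_aa]))]
            chars[3 * c: 3 * c + 3] = list(new_codon)
    return "".join(chars)


@dataclass(slots=True)
class SimulatedDataset:
    scenario: SimScenario
    families: dict[str, SeedAlignment]
    members_aa: dict[str, str]
    members_nt: dict[str, str]
    pairs: list[ReadPair]
    truth: list[PairTruth]

    def truth_by_read(self) -> dict[str, PairTruth]:
        return {t.read_id: t for t in self.truth}


def simulate_dataset(scenario: SimScenario) -> SimulatedDataset:
    """Families plus reads: pairs are assigned to source families by
    uniform choice; fully deterministic under ``scenario.rng_seed``."""
    rng = np.random.default_rng(scenario.rng_seed)
    families, members_aa, members_nt = {}, {}, {}
    fam_ids = [f"FAM{i + 1}" for i in range(scenario.n_families)]
    for fid in fam_ids:
        msa, aa, nt = simulate_family(scenario, fid, rng)
        families[fid] = msa
        members_aa[fid] = aa
        members_nt[fid] = nt
    source = rng.integers(scenario.n_families, size=scenario.n_pairs)
    pairs, truth = [], []
    for j, fi in enumerate(source):
        fid = fam_ids[int(fi)]
        p, t = simulate_pairs(scenario, members_nt[fid], fid, rng, 1, id_offset=j)
        pairs.extend(p)
        truth.extend(t)
    return SimulatedDataset(scenario, families, members_aa, members_nt, pairs, truth)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Write reads_1/2.fastq, families/*.sto, truth.tsv and the scenario echo."""
    outdir = Path(outdir)
    (outdir / "families").mkdir(parents=True, exist_ok=True)
    write_paired_fastq(ds.pairs, outdir / "reads_1.fastq", outdir / "reads_2.fastq")
    for fid, msa in ds.families.items():
        write_stockholm(msa, outdir / "families" / f"{fid}.sto")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("read_id\tfamily_ids\tfragment_length_aa\tdiverged_mate\n")
        for t in ds.truth:
            fh.write(f"{t.read_id}\t{t.family_id}\t{t.fragment_length_aa}\t"
                     f"{int(t.diverged_mate)}\n")
    with open(outdir / "scenario.json", "w") as fh:
        json.dump(asdict(ds.scenario), fh, indent=2, sort_keys=True)
        fh.write("\n")
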