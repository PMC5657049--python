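# Methods

This note records the models, estimators and numerical choices behind
`shortpair`, and what the synthetic study conditions do and do not
establish about behaviour on real data.

## The aligner

`profile_hmm` implements a compact Plan7-like profile HMM rather than
wrapping an external search engine, so the whole method is testable
hermetically; externally computed scans can still be substituted at
file level (`--models` for HMMER3 `.hmm` profiles, `--domtblout` for
per-end hits).

Model structure and scoring:

* One match/insert/delete node per consensus column.  Match columns
  are those flagged by `#=GC RF` when the seed alignment provides it,
  otherwise columns with gap fraction strictly below 0.5.
* Emissions are residue counts plus one unit of pseudocount mass
  distributed as the background (uniform 1/20 unless a `.hmm` COMPO
  line supplies one); transitions are state-path counts plus
  pseudocount 1 per transition type, normalised per bundle.
  Insert states emit the background, so insertions cost only their
  transitions.  Sequence weighting and Dirichlet mixture priors are
  deliberately out of scope; with the clean, moderately diverged seed
  alignments this package targets, plus-one smoothing is adequate and
  exactly checkable against a counting oracle.
* Alignment is local in the Smith–Waterman sense: uniform entry
  probability $1/L$ into any match state, free exit from any match
  state, score = log2 likelihood ratio of the Viterbi path against an
  i.i.d. background null.  A peptide whose best score is not positive
  yields no hit.  Stop codons (`*`) have zero emission probability
  everywhere, which truncates alignments at stops — a read crossing a
  UTR or intergenic boundary cannot align through it.  Ambiguity codes
  translate to `X` and emit the background (log-odds 0).
* Scores are Viterbi bits throughout, including inside the posterior.
  Forward scores would be a defensible alternative for the posterior's
  $s_a$; Viterbi was chosen because the rescue stage is defined by the
  full Viterbi pass and using one score type keeps the two stages'
  scores directly comparable.
* Per read end only the best-scoring frame per family is kept: the six
  frames are mutually exclusive hypotheses about one molecule.
* The DP kernel is a numba-compiled triple loop with strict
  left-to-right accumulation.  The exhaustive path-enumeration oracle
  in the test suite adds terms in the same order, so their agreement
  is float-exact, not approximate.

E-values use a Gumbel null, $E = N e^{-\lambda (s - \mu)}$ clipped to
$[0, N]$, with $N$ the number of framed peptides scanned.  Profiles
built from seed alignments have no precomputed statistics, so
$(\mu, \lambda)$ are fitted by maximum likelihood (scipy's
`gumbel_r.fit`) to the Viterbi scores of 500 background-sampled
peptides of the typical read-peptide length; the fit is deterministic
given the run seed.  `STATS LOCAL VITERBI` lines in loaded `.hmm`
files are honoured instead when present.

## Fragment-length estimation without a reference

For each read pair uniquely aligned to one family (each end hits
exactly one family and it is the same one), both mates' match-state
spans are converted through the seed alignment: a model position maps
to its MSA column, and a column maps to the count of non-gap
characters in a seed row up to and including it (1-based).  A span
whose two terminal columns are both gaps in a row is undefined for
that row.  The fragment length is the mean over seed rows of the
**outer** span — from the smaller converted start to the larger
converted end, inclusive — because the fragment physically covers both
read footprints and everything between them; the inner gap between the
two alignments would be an equally self-consistent but different
convention and must not be mixed with this one.  Which seed is closest
to the unobserved source gene is unknown, hence the average.

Per-pair means are rounded half up to integers.  Pooled lengths build
a 1-aa-resolution histogram over the observed range; one unit of
pseudocount mass is spread uniformly over the support so no observable
length has probability zero (the same floor value is returned for
lengths outside the support).  Lengths outside a user-supplied clip
range (nucleotide bounds divided by 3) are dropped as estimation
outliers before histogramming.  The distribution is global, not
per-family, and is built from step-1 unique pairs only — rescued
alignments do not feed back into it (a single pass, no iterative
refinement).

Under the 10,000-pair single-family condition (truncated-Normal
fragments, mean 150 aa, sd 15 aa, no indels, no sequencing error) the
estimated distribution stays within 0.004 of the sampling truth at
every length and within 0.7 aa in the mean; the acceptance bound is
0.02 / 1 aa.  The residual error comes from fragments not being
codon-aligned, which shifts individual estimates by up to one amino
acid.

## Posterior and retention

Candidate weights $e^{s_1/T} e^{s_2/T} \Pr(f)$ are accumulated in log
space and normalised with log-sum-exp over **all** of a read pair's
candidate families, so posteriors are comparable across families and
immune to overflow.  $T = 1/\ln 2$ by default, making $e^{s/T} = 2^s$
the model-vs-null odds of a bit score; $T$ is configurable.  The
retention rule keeps candidates with posterior $\ge p_{\max}\tau$
(non-strict, so ties at the threshold are stable), $\tau = 0.40$ by
default.  Pairs with one aligned end even after rescue get no
posterior — the model is defined only for pairs — and are reported as
case 1 with E-value-ranked single-end hits.  When one end hits the
same family in several ways, the best-scoring hit represents the
family, avoiding double counting in the normalisation.

## Pipeline order and determinism

Scan → unique-pair collection → distribution building → rescue →
ranking.  Rescue admits any positive-bit-score alignment with no
E-value gate: the scan stage is responsible for anchoring, the
posterior stage for specificity, so the rescue stage is free to
maximise sensitivity.  Rescue only ever adds hits, so the case-2 share
is non-decreasing from the step-1 tally to the final one.  Per-pair
work is independent; results are emitted in input order, output floats
at fixed precision, so identical inputs and seed reproduce output
tables byte for byte.

## The synthetic study conditions

The generator emulates the data regime the method targets: families of
10 seeds at 0.3 divergence from a background-sampled ancestor
(substitutions uniform over the 19 alternative residues — chosen for
closed-form pairwise-identity expectations, not biological realism),
single-residue indels at rate 0.02, a held-out member gene at 0.1
divergence that never enters training, fragments of 66–267 aa
(truncated Normal, mean 150 aa, sd 15 aa — the 198–801 bp range of a
typical Illumina library, centred near 450 bp), 76-bp inward-facing
read pairs cut from uniformly placed fragments (not codon-aligned),
and per-base substitution errors at 0.005.  Optionally a fraction of
pairs carries a "diverged mate": codons under the second read
substituted at rate 0.4, emulating pairs whose far end has drifted
beyond the reach of the permissive first scan while the near end still
anchors the family.

What the generator does **not** emulate: realistic amino-acid
substitution matrices and codon usage, site-rate heterogeneity,
domain architecture (one domain per gene), related/clan families with
shared sub-motifs, indel sequencing errors, and quality-score
structure.  Passing tests therefore demonstrate the estimators'
internal correctness and the method's behaviour under its stated
assumptions; they do not quantify performance against Pfam-scale
family collections, where inter-family similarity makes ranking
genuinely harder.

Problem sizes used in the test suite and acceptance script — 1000
pairs for the end-to-end conditions, 500 for the rescue condition,
10,000 for fragment-length recovery — were chosen so each statistic's
sampling noise is well inside its acceptance margin.

## Known limitations

* No Forward/posterior-decoding scores and no multi-hit architecture;
  at read length a peptide contains at most one domain fragment.
* No glocal mode and no gathering-threshold curation.
* One global fragment-length distribution; libraries with mixed insert
  sizes would need per-library runs.
* The rescue stage trusts step-1 anchors; a wrong anchor can recruit a
  wrong mate alignment, which the posterior can demote but not remove
  when it is the only candidate.
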