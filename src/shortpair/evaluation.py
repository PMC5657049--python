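"""Per-read-pair accuracy metrics and domain-abundance comparison.

For one read pair with true family set TP, predicted set C, and family
universe U (so TN = U - TP):

    sensitivity = |TP n C| / |TP|
    FP rate     = |C - TP| / |TN|
    PPV         = |TP n C| / |C|
    F-score     = 2 * sensitivity * PPV / (sensitivity + PPV)

Dataset-level values are unweighted means over pairs; ROC-style sweeps
re-evaluate predictions across a grid of retention thresholds (tau for
posterior-ranked output, E-value for a single-threshold baseline).
Abundance distance is the per-family absolute difference between
predicted and true read-pair counts, families missing on one side
counting as zero.
"""

from __future__ import annotations

from dataclasses import dataclass


def pair_sensitivity(tp: set[str], c: set[str]) -> float:
    if not tp:
        raise ValueError("sensitivity undefined for empty true set")
    return len(tp & c) / len(tp)


def pair_fp_rate(tp: set[str], c: set[str], universe: set[str]) -> float:
    tn = len(universe - tp)
    if tn == 0:
        raise ValueError("FP rate undefined when the universe equals the true set")
    return len(c - tp) / tn


def f_score_ppv(tp: set[str], c: set[str]) -> tuple[float, float]:
    """(F-score, PPV); F is reported as 0 when sensitivity + PPV = 0.
    PPV of an empty prediction set is 0 by convention here (the pair
    predicted nothing)."""
    ppv = len(tp & c) / len(c) if c else 0.0
    sens = len(tp & c) / len(tp) if tp else 0.0
    f = 2 * sens * ppv / (sens + ppv) if (sens + ppv) > 0 else 0.0
    return f, ppv


@dataclass(slots=True)
class DatasetMetrics:
    sensitivity: float
    fp_rate: float
    f_score: float
    ppv: float
    n_pairs: int
    n_skipped_empty_truth: int


def dataset_metrics(truth: dict[str, set[str]], predictions: dict[str, set[str]],
                    universe: set[str]) -> DatasetMetrics:
    """Unweighted means over evaluable pairs.

    Pairs whose true set is empty are excluded from the averages (their
    sensitivity is undefined) and counted separately.
    """
    sens = fpr = f = ppv = 0.0
    n = skipped = 0
    for rid, tp in truth.items():
        if not tp:
            skipped += 1
            continue
        c = predictions.get(rid, set())
        sens += pair_sensitivity(tp, c)
        fpr += pair_fp_rate(tp, c, universe)
        fi, pi = f_score_ppv(tp, c)
        f += fi
        ppv += pi
        n += 1
    if n == 0:
        raise ValueError("no evaluable pairs (all true sets empty)")
    return DatasetMetrics(sens / n, fpr / n, f / n, ppv / n, n, skipped)


def roc_sweep_tau(scored: dict[str, list[tuple[str, float]]],
                  truth: dict[str, set[str]], universe: set[str],
                  taus=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)
                  ) -> list[tuple[float, DatasetMetrics]]:
    """Re-apply the p_max*tau retention rule over a tau grid.

    ``scored`` maps read id -> [(family id, posterior), ...] before any
    filtering, so each grid point recomputes the retained set.
    """
    from .posterior import CandidatePair  # noqa: F401  (documentation link)

    out = []
    for tau in taus:
        preds = {}
        for rid, cands in scored.items():
            if not cands:
                preds[rid] = set()
                continue
            p_max = max(p for _, p in cands)
            preds[rid] = {fid for fid, p in cands if p >= p_max * tau}
        out.append((tau, dataset_metrics(truth, preds, universe)))
    return out


def roc_sweep_evalue(hits: dict[str, list[tuple[str, float]]],
                     truth: dict[str, set[str]], universe: set[str],
                     evalues=(1000.0, 100.0, 10.0, 1.0, 0.1, 1e-2, 1e-3, 1e-4, 1e-5)
                     ) -> list[tuple[float, DatasetMetrics]]:
    """Baseline sweep: predicted set = families of hits with E <= cutoff.

    Loosening the cutoff never shrinks any pair's predicted set.
    """
    out = []
    for ev in evalues:
        preds = {rid: {fid for fid, e in hs if e <= ev} for rid, hs in hits.items()}
        out.append((ev, dataset_metrics(truth, preds, universe)))
    return out


def abundance_distance(predicted: dict[str, int], truth: dict[str, int]
                       ) -> tuple[dict[str, int], float]:
    """Per-family |predicted - true| read-pair counts and their mean.

    Families present on only one side count as zero on the other.
    """
    fams = sorted(set(predicted) | set(truth))
    per_family = {f: abs(predicted.get(f, 0) - truth.get(f, 0)) for f in fams}
    mean = sum(per_family.values()) / len(per_family) if per_family else 0.0
    return per_family, mean


def read_truth_tsv(path) -> dict[str, set[str]]:
    """Parse ``read_id TAB comma-separated family ids`` (header optional)."""
    truth: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("read_id"):
                continue
            fields = line.split("\t")
            fams = fields[1]
            truth[fields[0]] = set(fams.split(",")) if fams else set()
    return truth
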