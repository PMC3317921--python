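"""Resampling designs, success rates, Wilson intervals, overall success.

Identification performance is measured by resampling: either
leave-one-out (each replicate removes one specimen and classifies it
against the rest) or a random reference:query split (9:1 or 1:1).
Successes are Bernoulli trials, so the success rate N_hit/N_query gets a
Wilson score confidence interval. Because a barcode can only identify a
specimen that sequenced, the overall success rate multiplies the
assignment rate by the fraction of specimens successfully sequenced for
every locus of the barcode.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .classifiers import (
    Assignment,
    ReferenceLibrary,
    TIE_EPS,
    assign_bp,
    bcm_threshold,
    train_bp,
)
from .distances import distance_matrix
from .io import LocusAlignment, MultiLocusDataset, concatenate, sequencing_success

logger = logging.getLogger(__name__)

METHODS = ("md", "bcm", "bp")


@dataclass
class SimulationResult:
    """Outcome of one resampling simulation for one method and barcode."""

    method: str
    loci: list[str]
    design: str  # leave_one_out | split
    n_queries: int
    n_hits: int
    assignments: list[Assignment] = field(repr=False)
    seed: int = 0
    ratio: str | None = None
    #: hits if ambiguous assignments with the correct species among the
    #: tied set were counted as successes (reported, not the headline)
    n_hits_lenient: int = 0

    @property
    def success_rate(self) -> float:
        return success_rate(self.n_hits, self.n_queries)


@dataclass
class SuccessReport:
    """Success rate with CI and the sequencing-corrected overall rate."""

    method: str
    loci: list[str]
    p_hat: float
    ci_low: float
    ci_high: float
    level: float
    seq_success: float
    overall: float
    n_queries: int
    n_hits: int


def success_rate(n_hits: int, n_total: int) -> float:
    """Fraction of queries assigned to their correct species."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_hits <= n_total:
        raise ValueError("n_hits must be in [0, n_total]")
    return n_hits / n_total


def wilson_ci(p_hat: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a Bernoulli proportion.

    center = (p + z^2/2n) / (1 + z^2/n), half-width =
    z * sqrt(p(1-p)/n + z^2/4n^2) / (1 + z^2/n), clipped to [0, 1].
    Takes the proportion (not counts) so that intervals can be computed
    from rounded published rates as well as exact fractions.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= p_hat <= 1:
        raise ValueError("p_hat must be in [0, 1]")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = norm.ppf(0.5 + level / 2)
    z2 = z * z
    denom = 1 + z2 / n
    center = (p_hat + z2 / (2 * n)) / denom
    half = z * math.sqrt(p_hat * (1 - p_hat) / n + z2 / (4 * n * n)) / denom
    return max(0.0, center - half), min(1.0, center + half)


def overall_success(
    p_hat: float,
    seq_counts: tuple[int, int],
    mode: str = "joint_counts",
    per_locus_rates=None,
) -> float:
    """Sequencing-corrected overall identification success.

    ``joint_counts`` (default): p_hat * n_success / n_submitted, where
    n_success counts specimens with ALL loci of the barcode sequenced.
    ``independence_product``: p_hat * product of per-locus sequencing
    rates, the approximation implied when joint counts are unavailable.
    """
    n_success, n_submitted = seq_counts
    if n_submitted <= 0:
        raise ValueError("n_submitted must be positive")
    if mode == "joint_counts":
        return p_hat * n_success / n_submitted
    if mode == "independence_product":
        if per_locus_rates is None:
            raise ValueError("independence_product needs per_locus_rates")
        out = p_hat
        for r in per_locus_rates:
            out *= r
        return out
    raise ValueError(f"unknown mode {mode!r}")


def _species_labels(dataset: MultiLocusDataset, alignment: LocusAlignment) -> list[str]:
    return dataset.labels_for(alignment.specimen_ids)


def _loo_distance_hit(values, labels, q: int, threshold=None):
    """Classify row q against all other rows of a precomputed matrix.

    Returns (predicted, status, best_distance) with the same tie and
    threshold semantics as the per-query classifiers.
    """
    d = values[q].copy()
    d[q] = np.nan
    if np.all(np.isnan(d)):
        return None, "unidentified", None
    best = float(np.nanmin(d))
    if threshold is not None and best > threshold:
        return None, "unidentified", best
    tied = {labels[i] for i in np.where(d <= best + TIE_EPS)[0]}
    if len(tied) > 1:
        return None, "ambiguous", best, tied
    return tied.pop(), "assigned", best, tied


def _loo_threshold_excluding(values, labels, q: int, quantile: float = 0.95):
    """BCM threshold from intraspecific pairs not involving specimen q."""
    n = len(labels)
    intra = []
    for i in range(n):
        if i == q:
            continue
        for j in range(i + 1, n):
            if j == q or labels[i] != labels[j]:
                continue
            v = values[i, j]
            if not math.isnan(v):
                intra.append(v)
    if not intra:
        return None
    return float(np.quantile(intra, quantile, method="linear"))


def run_leave_one_out(
    dataset: MultiLocusDataset,
    loci,
    method: str = "md",
    n_reps: int = 500,
    seed: int = 0,
    bcm_quantile: float = 0.95,
) -> SimulationResult:
    """Leave-one-out resampling: each replicate draws one specimen
    uniformly at random (with replacement across replicates) and
    classifies it against all remaining specimens.

    Only the distance methods support this design (the BP method uses
    reference:query splits because retraining per replicate is
    impractical). Species singletons are logged: their queries can never
    hit. For BCM the threshold is recomputed per replicate from
    intraspecific pairs not involving the query.
    """
    if method not in ("md", "bcm"):
        raise ValueError("leave-one-out supports methods 'md' and 'bcm'")
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    alignment = concatenate(dataset, list(loci))
    labels = _species_labels(dataset, alignment)
    if len(labels) < 2:
        raise ValueError("need >= 2 specimens after locus intersection")
    singletons = {s for s in set(labels) if labels.count(s) == 1}
    if singletons:
        logger.warning("species with a single specimen (cannot hit): %s", sorted(singletons))

    m = distance_matrix(alignment)
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(labels), size=n_reps)
    hits = lenient = 0
    assignments = []
    thr_cache: dict[int, float | None] = {}
    for q in picks:
        q = int(q)
        if method == "bcm":
            if q not in thr_cache:
                thr_cache[q] = _loo_threshold_excluding(m.values, labels, q, bcm_quantile)
            thr = thr_cache[q]
            if thr is None:
                assignments.append(Assignment(m.ids[q], None, "unidentified"))
                continue
        else:
            thr = None
        res = _loo_distance_hit(m.values, labels, q, thr)
        pred, status, best = res[0], res[1], res[2]
        tied = res[3] if len(res) > 3 else set()
        assignments.append(Assignment(m.ids[q], pred, status, best_distance=best))
        if status == "assigned" and pred == labels[q]:
            hits += 1
            lenient += 1
        elif status == "ambiguous" and labels[q] in tied:
            lenient += 1
    return SimulationResult(
        method=method, loci=list(loci), design="leave_one_out",
        n_queries=n_reps, n_hits=hits, assignments=assignments, seed=seed,
        n_hits_lenient=lenient,
    )


def split_counts(n: int, ratio: str) -> tuple[int, int]:
    """Reference/query sizes for a ratio 'r:1': queries = round(n/(r+1))."""
    r = ratio.split(":")
    if len(r) != 2 or r[1] != "1":
        raise ValueError("ratio must look like '9:1' or '1:1'")
    rr = int(r[0])
    n_query = round(n / (rr + 1))
    n_query = min(max(n_query, 1), n - 1)
    return n - n_query, n_query


def run_split(
    dataset: MultiLocusDataset,
    loci,
    method: str = "bp",
    ratio: str = "1:1",
    seed: int = 0,
    bcm_quantile: float = 0.95,
    max_retries: int = 100,
    **bp_kwargs,
) -> SimulationResult:
    """Random reference:query split evaluation.

    Specimens are partitioned at the stated ratio; the classifier is
    trained/indexed on the reference partition and every query is
    classified. The partition is redrawn (up to ``max_retries`` times,
    logged) until every species has at least one reference sequence.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    alignment = concatenate(dataset, list(loci))
    ids = alignment.specimen_ids
    labels = _species_labels(dataset, alignment)
    n = len(ids)
    n_ref, n_query = split_counts(n, ratio)
    rng = np.random.default_rng(seed)
    all_species = set(labels)
    for attempt in range(max_retries):
        perm = rng.permutation(n)
        ref_idx, qry_idx = perm[:n_ref], perm[n_ref:]
        if {labels[i] for i in ref_idx} == all_species:
            break
        logger.info("split retry %d: species missing from reference", attempt + 1)
    else:
        raise ValueError("could not draw a split covering every species")

    ref_rows = [alignment.rows[i] for i in ref_idx]
    ref_labels = [labels[i] for i in ref_idx]
    lib = ReferenceLibrary(
        LocusAlignment(alignment.locus_name, ref_rows), ref_labels
    )
    if method == "bp":
        bp_seed = int(rng.integers(0, 2**31 - 1))
        model = train_bp(lib, seed=bp_kwargs.pop("bp_seed", bp_seed), **bp_kwargs)
    elif method == "bcm":
        threshold = bcm_threshold(lib, bcm_quantile)

    from .classifiers import assign_bcm, assign_md

    hits = lenient = 0
    assignments = []
    for i in qry_idx:
        qid, qseq = alignment.rows[i]
        if method == "md":
            a = assign_md(qseq, lib, query_id=qid)
        elif method == "bcm":
            a = assign_bcm(qseq, lib, threshold, query_id=qid)
        else:
            a = assign_bp(model, qseq, query_id=qid)
        assignments.append(a)
        if a.status == "assigned" and a.predicted_species == labels[i]:
            hits += 1
            lenient += 1
    return SimulationResult(
        method=method, loci=list(loci), design="split",
        n_queries=len(qry_idx), n_hits=hits, assignments=assignments,
        seed=seed, ratio=ratio, n_hits_lenient=lenient,
    )


def evaluate_barcode(
    dataset: MultiLocusDataset,
    loci,
    method: str = "md",
    design: str = "loo",
    ratio: str = "1:1",
    n_reps: int = 500,
    seed: int = 0,
    level: float = 0.95,
    overall_mode: str = "joint_counts",
) -> SuccessReport:
    """Run one simulation and summarise it as a :class:`SuccessReport`.

    Combines the resampling design, the Wilson interval at ``level`` and
    the sequencing-corrected overall rate for the chosen barcode.
    """
    if design in ("loo", "leave_one_out"):
        sim = run_leave_one_out(dataset, loci, method=method, n_reps=n_reps, seed=seed)
    elif design == "split":
        sim = run_split(dataset, loci, method=method, ratio=ratio, seed=seed)
    else:
        raise ValueError(f"unknown design {design!r}")
    p_hat = sim.success_rate
    lo, hi = wilson_ci(p_hat, sim.n_queries, level)
    rate, n_success, n_submitted = sequencing_success(dataset, list(loci))
    if overall_mode == "independence_product":
        per = [sequencing_success(dataset, [l])[0] for l in loci]
        overall = overall_success(p_hat, (n_success, n_submitted), overall_mode, per)
    else:
        overall = overall_success(p_hat, (n_success, n_submitted), overall_mode)
    return SuccessReport(
        method=method, loci=list(loci), p_hat=p_hat, ci_low=lo, ci_high=hi,
        level=level, seq_success=rate, overall=overall,
        n_queries=sim.n_queries, n_hits=sim.n_hits,
    )
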