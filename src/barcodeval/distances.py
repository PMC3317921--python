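"""Kimura two-parameter distances and barcoding-gap summaries.

The K2P model distinguishes transitions (purine<->purine, A<->G, or
pyrimidine<->pyrimidine, C<->T) from transversions. With P and Q the
proportions of sites showing a transition and a transversion difference,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Sites where either sequence has a gap or N are excluded pairwise
("pairwise deletion"); if the log arguments fall to zero or below the
distance is saturated and reported as undefined (NaN) rather than
clamped, with a count kept by callers that summarise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

# A=0, C=1, G=2, T=3 -- purines even, pyrimidines odd, so two distinct
# valid bases are a transition iff they share parity. Gap/N -> 255.
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i
MISSING = 255


class UndefinedDistanceError(ValueError):
    """No comparable sites between two sequences."""


def seq_to_ints(seq: str) -> np.ndarray:
    """Encode a sequence over {A,C,G,T,-,N} as uint8 (ACGT -> 0..3, else 255)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _pq(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    ok = (a != MISSING) & (b != MISSING)
    n = int(ok.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable sites under pairwise deletion")
    av, bv = a[ok], b[ok]
    diff = av != bv
    ts = int((diff & ((av & 1) == (bv & 1))).sum())
    tv = int(diff.sum()) - ts
    return ts / n, tv / n, n


def k2p(seq_a, seq_b) -> float:
    """K2P distance between two equal-length aligned sequences.

    Accepts strings or pre-encoded uint8 arrays. Returns NaN on
    saturation (log argument <= 0); raises
    :class:`UndefinedDistanceError` if no site is comparable.
    """
    a = seq_to_ints(seq_a) if isinstance(seq_a, str) else np.asarray(seq_a)
    b = seq_to_ints(seq_b) if isinstance(seq_b, str) else np.asarray(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal aligned length")
    p, q, _ = _pq(a, b)
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P distances for one (possibly concatenated) locus.

    ``values[i, j]`` is in substitutions/site; NaN marks a saturated or
    undefined pair. Gap handling is pairwise deletion.
    """

    ids: list[str]
    values: np.ndarray
    gap_mode: str = "pairwise_deletion"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        self.values = v

    @property
    def n_flagged(self) -> int:
        """Number of unordered pairs with undefined (saturated) distance."""
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def submatrix(self, keep_ids) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in keep_ids]
        return DistanceMatrix(list(keep_ids), self.values[np.ix_(idx, idx)], self.gap_mode)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def distance_matrix(alignment) -> DistanceMatrix:
    """All-pairs K2P matrix for a :class:`~barcodeval.io.LocusAlignment`.

    Saturated pairs propagate as NaN entries; pairs with zero comparable
    sites are likewise flagged NaN (and logged) rather than raising, so a
    matrix is always returned for >= 2 rows.
    """
    ids = alignment.specimen_ids
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    enc = np.vstack([seq_to_ints(seq) for _, seq in alignment.rows])
    valid = enc != MISSING
    vals = np.zeros((n, n))
    n_undef = 0
    for i in range(n):
        ai, vi = enc[i], valid[i]
        for j in range(i + 1, n):
            ok = vi & valid[j]
            m = int(ok.sum())
            if m == 0:
                d = math.nan
                n_undef += 1
            else:
                av, bv = ai[ok], enc[j][ok]
                diff = av != bv
                ts = int((diff & ((av & 1) == (bv & 1))).sum())
                tv = int(diff.sum()) - ts
                p, q = ts / m, tv / m
                w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
                if w1 <= 0.0 or w2 <= 0.0:
                    d = math.nan
                    n_undef += 1
                else:
                    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
            vals[i, j] = vals[j, i] = d
    if n_undef:
        logger.warning("%d pairwise distances undefined/saturated", n_undef)
    return DistanceMatrix(ids=list(ids), values=vals)


def partition_distances(matrix: DistanceMatrix, labels) -> tuple[list[float], list[float]]:
    """Split unordered pairwise distances into intra- and inter-specific sets.

    ``labels`` maps specimen_id -> species (a dict or a sequence aligned
    with ``matrix.ids``). Flagged (NaN) pairs are excluded from both sets.
    """
    if isinstance(labels, dict):
        try:
            lab = [labels[i] for i in matrix.ids]
        except KeyError as e:
            raise ValueError(f"unlabeled specimen {e.args[0]!r}") from e
    else:
        lab = list(labels)
        if len(lab) != len(matrix.ids):
            raise ValueError("label list length does not match matrix")
    intra, inter = [], []
    n = len(matrix.ids)
    for i in range(n):
        for j in range(i + 1, n):
            d = matrix.values[i, j]
            if math.isnan(d):
                continue
            (intra if lab[i] == lab[j] else inter).append(float(d))
    return intra, inter


@dataclass
class GapReport:
    """Barcoding-gap summary for one barcode.

    The gap for a species is (minimum inter-specific distance involving
    it) minus (maximum intra-specific distance within it); the barcode
    shows a positive gap only if every species does. Global means pool
    all pairs; per-species means are also reported.
    """

    per_species: dict[str, dict[str, float]]
    mean_intra: float
    mean_inter: float
    ratio: float
    global_gap: float
    mean_intra_by_species: float
    mean_inter_by_species: float
    bins: np.ndarray = field(repr=False)
    intra_hist: np.ndarray = field(repr=False)
    inter_hist: np.ndarray = field(repr=False)

    @property
    def positive_gap(self) -> bool:
        return self.global_gap > 0


def barcoding_gap(
    matrix: DistanceMatrix, labels, bins: int = 50
) -> GapReport:
    """Barcoding-gap analysis from a distance matrix and species labels.

    Pooled mean intra- and inter-specific distances, their ratio, shared
    axis histograms (``bins`` equal-width bins over the pooled range), and
    per-species max-intra / min-inter / gap. Species with < 2 members get
    no intra statistics but still a min-inter.
    """
    if isinstance(labels, dict):
        lab = [labels[i] for i in matrix.ids]
    else:
        lab = list(labels)
    intra, inter = partition_distances(matrix, lab)
    if not inter:
        raise ValueError("barcoding gap needs at least two species")
    species = sorted(set(lab))
    per_species: dict[str, dict[str, float]] = {}
    n = len(matrix.ids)
    per_intra: dict[str, list[float]] = {s: [] for s in species}
    per_inter: dict[str, list[float]] = {s: [] for s in species}
    for i in range(n):
        for j in range(i + 1, n):
            d = matrix.values[i, j]
            if math.isnan(d):
                continue
            if lab[i] == lab[j]:
                per_intra[lab[i]].append(d)
            else:
                per_inter[lab[i]].append(d)
                per_inter[lab[j]].append(d)
    gaps = []
    for s in species:
        entry: dict[str, float] = {}
        if per_intra[s]:
            entry["max_intra"] = max(per_intra[s])
            entry["mean_intra"] = float(np.mean(per_intra[s]))
        if per_inter[s]:
            entry["min_inter"] = min(per_inter[s])
            entry["mean_inter"] = float(np.mean(per_inter[s]))
        if "max_intra" in entry and "min_inter" in entry:
            entry["gap"] = entry["min_inter"] - entry["max_intra"]
            gaps.append(entry["gap"])
        per_species[s] = entry

    mean_intra = float(np.mean(intra)) if intra else math.nan
    mean_inter = float(np.mean(inter))
    ratio = mean_inter / mean_intra if intra and mean_intra > 0 else math.nan
    sp_intra = [np.mean(v) for v in per_intra.values() if v]
    sp_inter = [np.mean(v) for v in per_inter.values() if v]

    pooled = np.array(intra + inter)
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, bins + 1)
    intra_hist, _ = np.histogram(intra, bins=edges)
    inter_hist, _ = np.histogram(inter, bins=edges)

    return GapReport(
        per_species=per_species,
        mean_intra=mean_intra,
        mean_inter=mean_inter,
        ratio=ratio,
        global_gap=min(gaps) if gaps else math.nan,
        mean_intra_by_species=float(np.mean(sp_intra)) if sp_intra else math.nan,
        mean_inter_by_species=float(np.mean(sp_inter)) if sp_inter else math.nan,
        bins=edges,
        intra_hist=intra_hist,
        inter_hist=inter_hist,
    )
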