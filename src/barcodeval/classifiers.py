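"""Species-assignment methods: minimum distance, best close match, BP network.

Minimum distance (MD) assigns a query to the species of its nearest
reference under K2P. Best close match (BCM) does the same, but only when
the best match falls within a threshold set at the 95th percentile of all
intraspecific reference distances; otherwise the query is left
unidentified. The BP method trains a single-hidden-layer feed-forward
network by backpropagation (batch gradient descent with momentum) on
one-hot encoded alignment columns, one output unit per species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .distances import MISSING, DistanceMatrix, distance_matrix, seq_to_ints

#: Distances closer than this are considered tied (ambiguous assignment).
TIE_EPS = 1e-12
#: BP output activations closer than this are considered tied.
BP_TIE_EPS = 1e-6


@dataclass
class ReferenceLibrary:
    """Reference alignment with a species label per row."""

    alignment: "LocusAlignment"
    labels: list[str]
    matrix: DistanceMatrix | None = None
    _encoded: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.alignment.rows):
            raise ValueError("one label per alignment row required")
        if len(set(self.labels)) < 2:
            raise ValueError("reference library needs >= 2 species")

    @property
    def species(self) -> list[str]:
        return sorted(set(self.labels))

    @property
    def encoded(self) -> np.ndarray:
        if self._encoded is None:
            self._encoded = np.vstack(
                [seq_to_ints(seq) for _, seq in self.alignment.rows]
            )
        return self._encoded

    def distances(self) -> DistanceMatrix:
        if self.matrix is None:
            self.matrix = distance_matrix(self.alignment)
        return self.matrix


@dataclass
class Assignment:
    """One query's predicted species and assignment status.

    ``predicted_species`` is set iff ``status == "assigned"``;
    ``best_distance`` is filled by the distance methods, ``score_vector``
    (per-species activations) by the BP method.
    """

    query_id: str
    predicted_species: str | None
    status: str  # assigned | ambiguous | unidentified
    best_distance: float | None = None
    score_vector: dict[str, float] | None = None


def _query_distances(query, library: ReferenceLibrary) -> np.ndarray:
    """Vectorised K2P distances from one query to every reference row."""
    q = seq_to_ints(query) if isinstance(query, str) else np.asarray(query)
    refs = library.encoded
    if q.shape[0] != refs.shape[1]:
        raise ValueError("query length does not match library alignment")
    ok = (q != MISSING)[None, :] & (refs != MISSING)
    n = ok.sum(axis=1).astype(float)
    diff = ok & (q[None, :] != refs)
    ts = (diff & (((q & 1)[None, :]) == (refs & 1))).sum(axis=1)
    tv = diff.sum(axis=1) - ts
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, ts / n, np.nan)
        qv = np.where(n > 0, tv / n, np.nan)
        w1 = 1.0 - 2.0 * p - qv
        w2 = 1.0 - 2.0 * qv
        d = np.where(
            (w1 > 0) & (w2 > 0), -0.5 * np.log(w1) - 0.25 * np.log(w2), np.nan
        )
    return d


def _nearest(query_id, query, library) -> Assignment:
    d = _query_distances(query, library)
    if np.all(np.isnan(d)):
        return Assignment(query_id, None, "unidentified")
    best = float(np.nanmin(d))
    tied = {library.labels[i] for i in np.where(d <= best + TIE_EPS)[0]}
    if len(tied) > 1:
        return Assignment(query_id, None, "ambiguous", best_distance=best)
    return Assignment(query_id, tied.pop(), "assigned", best_distance=best)


def assign_md(query, library: ReferenceLibrary, query_id: str = "query") -> Assignment:
    """Minimum-distance assignment: species of the nearest reference.

    Ambiguous if references of more than one species tie at the minimum
    distance (within ``TIE_EPS``); unidentified if no reference shares a
    comparable site with the query.
    """
    return _nearest(query_id, query, library)


def bcm_threshold(library: ReferenceLibrary, quantile: float = 0.95) -> float:
    """Distance below which 95% of intraspecific reference distances fall.

    Linear-interpolation quantile of all defined intraspecific pairwise
    K2P distances in the library. The quantile level is configurable; the
    convention of the original best-close-match protocol is 0.95.
    """
    m = library.distances()
    labels = library.labels
    intra = []
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == labels[j] and not math.isnan(m.values[i, j]):
                intra.append(m.values[i, j])
    if not intra:
        raise ValueError("no intraspecific pairs in library: threshold undefined")
    return float(np.quantile(intra, quantile, method="linear"))


def assign_bcm(
    query, library: ReferenceLibrary, threshold: float, query_id: str = "query"
) -> Assignment:
    """Best-close-match assignment: nearest reference, gated by ``threshold``.

    A query whose best match is farther than the threshold is left
    unidentified; ties across species at the best distance are ambiguous.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    a = _nearest(query_id, query, library)
    if a.best_distance is not None and a.best_distance > threshold:
        return Assignment(query_id, None, "unidentified", best_distance=a.best_distance)
    return a


def encode_onehot(rows) -> np.ndarray:
    """One-hot encode aligned sequences: each site contributes 4 features.

    ``rows`` is an iterable of sequences (strings or uint8-encoded); A, C,
    G, T map to indicator columns and gap/N to all-zeros at that site.
    Output shape is (n, 4L).
    """
    enc = [seq_to_ints(r) if isinstance(r, str) else np.asarray(r) for r in rows]
    mat = np.vstack(enc)
    n, L = mat.shape
    out = np.zeros((n, 4 * L), dtype=float)
    for base in range(4):
        out[:, base::4] = mat == base
    return out


@dataclass
class BPModel:
    """Trained single-hidden-layer backpropagation network.

    Sigmoid activations throughout, one output unit per species, trained
    with full-batch gradient descent plus momentum against a mean squared
    error goal. Deterministic for fixed data, hyperparameters and seed.
    """

    species: list[str]
    w_hidden: np.ndarray
    b_hidden: np.ndarray
    w_out: np.ndarray
    b_out: np.ndarray
    final_error: float
    epochs: int
    converged: bool
    seed: int

    @property
    def input_width(self) -> int:
        return self.w_hidden.shape[0]

    @property
    def hidden_width(self) -> int:
        return self.w_hidden.shape[1]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = _sigmoid(x @ self.w_hidden + self.b_hidden)
        return _sigmoid(h @ self.w_out + self.b_out)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def train_bp(
    library: ReferenceLibrary,
    hidden_width: int | None = None,
    learning_rate: float = 0.2,
    momentum: float = 0.5,
    goal: float = 1e-5,
    max_epochs: int = 5000,
    seed: int = 0,
) -> BPModel:
    """Train the BP network on a reference library.

    Defaults follow the published protocol: learning rate 0.2, momentum
    0.5, training goal (mean squared error) 1e-5. ``hidden_width``
    defaults to 4x the number of species. Training stops when the MSE
    drops to the goal or at ``max_epochs`` (the model is then returned
    with ``converged=False``).
    """
    species = library.species
    x = encode_onehot(seq for _, seq in library.alignment.rows)
    sp_index = {s: k for k, s in enumerate(species)}
    t = np.zeros((x.shape[0], len(species)))
    for i, lab in enumerate(library.labels):
        t[i, sp_index[lab]] = 1.0

    n_in = x.shape[1]
    n_hid = hidden_width if hidden_width is not None else 4 * len(species)
    n_out = len(species)
    rng = np.random.default_rng(seed)
    lim1 = math.sqrt(6.0 / (n_in + n_hid))
    lim2 = math.sqrt(6.0 / (n_hid + n_out))
    w1 = rng.uniform(-lim1, lim1, (n_in, n_hid))
    b1 = np.zeros(n_hid)
    w2 = rng.uniform(-lim2, lim2, (n_hid, n_out))
    b2 = np.zeros(n_out)
    vw1 = np.zeros_like(w1); vb1 = np.zeros_like(b1)
    vw2 = np.zeros_like(w2); vb2 = np.zeros_like(b2)

    n = x.shape[0]
    mse = math.inf
    epoch = 0
    for epoch in range(max_epochs):
        h = _sigmoid(x @ w1 + b1)
        o = _sigmoid(h @ w2 + b2)
        err = o - t
        mse = float(np.mean(err**2))
        if mse <= goal:
            break
        # backprop with sigmoid derivatives, gradients averaged over batch
        do = err * o * (1 - o)
        dh = (do @ w2.T) * h * (1 - h)
        gw2 = h.T @ do / n
        gb2 = do.mean(axis=0)
        gw1 = x.T @ dh / n
        gb1 = dh.mean(axis=0)
        vw2 = momentum * vw2 - learning_rate * gw2
        vb2 = momentum * vb2 - learning_rate * gb2
        vw1 = momentum * vw1 - learning_rate * gw1
        vb1 = momentum * vb1 - learning_rate * gb1
        w2 += vw2; b2 += vb2; w1 += vw1; b1 += vb1
    else:
        epoch = max_epochs

    return BPModel(
        species=species,
        w_hidden=w1, b_hidden=b1, w_out=w2, b_out=b2,
        final_error=mse, epochs=epoch, converged=mse <= goal, seed=seed,
    )


def assign_bp(model: BPModel, query, query_id: str = "query") -> Assignment:
    """Classify a query with a trained BP model (argmax of output units).

    Ambiguous if the top two activations differ by less than
    ``BP_TIE_EPS`` (e.g. for an all-missing query the outputs are nearly
    uniform).
    """
    x = encode_onehot([query])
    if x.shape[1] != model.input_width:
        raise ValueError("query length does not match model input width")
    scores = model.forward(x)[0]
    order = np.argsort(scores)[::-1]
    best, second = scores[order[0]], scores[order[1]]
    vec = {s: float(v) for s, v in zip(model.species, scores)}
    if best - second < BP_TIE_EPS:
        return Assignment(query_id, None, "ambiguous", score_vector=vec)
    return Assignment(query_id, model.species[order[0]], "assigned", score_vector=vec)
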