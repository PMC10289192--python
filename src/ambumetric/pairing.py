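"""Within-participant similar/dissimilar training pairs.

Pairs are formed strictly within participant: every unordered pair of a
participant's labeled samples becomes one training pair, flagged similar
when the raw labels differ by at most ``threshold``. Class-imbalance
weights are inverse-frequency, normalized to mean 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocessing import LabelNormalizer
from .schema_io import ID_COL, Dataset

__all__ = ["SamplePair", "PairSet", "form_pairs", "compute_pair_weights"]


@dataclass(frozen=True)
class SamplePair:
    participant_id: str
    features_a: np.ndarray
    features_b: np.ndarray
    y_a: float
    y_b: float
    yhat_a: float
    yhat_b: float
    similar: bool
    weight: float


@dataclass
class PairSet:
    """Sample matrix plus index pairs (compact pair storage).

    ``X``/``y``/``yhat``/``pids`` describe the pooled labeled samples;
    ``idx_a``/``idx_b`` index rows of ``X`` forming each unordered pair.
    """

    X: np.ndarray
    y: np.ndarray
    yhat: np.ndarray
    pids: np.ndarray
    idx_a: np.ndarray
    idx_b: np.ndarray
    similar: np.ndarray
    threshold: int
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = np.ones(len(self.idx_a))
        if np.any(self.idx_a == self.idx_b):
            raise ValueError("a pair must join two distinct samples")
        if np.any(self.pids[self.idx_a] != self.pids[self.idx_b]):
            raise ValueError("pairs must be within-participant")

    def __len__(self) -> int:
        return len(self.idx_a)

    @property
    def n_similar(self) -> int:
        return int(self.similar.sum())

    @property
    def n_dissimilar(self) -> int:
        return int(len(self) - self.n_similar)

    def __getitem__(self, i: int) -> SamplePair:
        a, b = self.idx_a[i], self.idx_b[i]
        return SamplePair(
            participant_id=str(self.pids[a]),
            features_a=self.X[a], features_b=self.X[b],
            y_a=float(self.y[a]), y_b=float(self.y[b]),
            yhat_a=float(self.yhat[a]), yhat_b=float(self.yhat[b]),
            similar=bool(self.similar[i]),
            weight=float(self.weights[i]),
        )

    def subsample(self, max_pairs: int, seed: int = 0) -> "PairSet":
        """Random pair cap for large cohorts (weights recomputed)."""
        if len(self) <= max_pairs:
            return self
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(self), size=max_pairs, replace=False)
        sub = PairSet(X=self.X, y=self.y, yhat=self.yhat, pids=self.pids,
                      idx_a=self.idx_a[keep], idx_b=self.idx_b[keep],
                      similar=self.similar[keep], threshold=self.threshold)
        return compute_pair_weights(sub)


def form_pairs(dataset: Dataset, construct: str,
               threshold: int = 1,
               normalizer: LabelNormalizer | None = None,
               feature_columns: list[str] | None = None) -> PairSet:
    """Enumerate all unordered within-participant pairs of labeled samples.

    Participants with fewer than two labeled samples contribute no pairs.
    ``normalizer`` supplies per-participant label norms; when omitted it is
    fitted on this dataset's own labels.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    from .preprocessing import fit_label_normalizers
    if normalizer is None:
        normalizer = fit_label_normalizers(dataset, construct)
    cols = feature_columns or dataset.feature_schema.names

    frame = dataset.frame.dropna(subset=[construct]).reset_index(drop=True)
    X = frame[cols].to_numpy(float)
    y = frame[construct].to_numpy(float)
    pids = frame[ID_COL].to_numpy(str)
    yhat = np.empty_like(y)
    for pid in np.unique(pids):
        sel = pids == pid
        yhat[sel] = normalizer(pid, y[sel])

    idx_a_parts, idx_b_parts = [], []
    for pid in np.unique(pids):
        rows = np.flatnonzero(pids == pid)
        if len(rows) < 2:
            continue
        ia, ib = np.triu_indices(len(rows), k=1)
        idx_a_parts.append(rows[ia])
        idx_b_parts.append(rows[ib])
    if not idx_a_parts:
        raise ValueError("no participant has >= 2 labeled samples")
    idx_a = np.concatenate(idx_a_parts)
    idx_b = np.concatenate(idx_b_parts)
    similar = np.abs(y[idx_a] - y[idx_b]) <= threshold

    pairs = PairSet(X=X, y=y, yhat=yhat, pids=pids,
                    idx_a=idx_a, idx_b=idx_b, similar=similar,
                    threshold=threshold)
    return compute_pair_weights(pairs)


def compute_pair_weights(pairs: PairSet) -> PairSet:
    """Inverse-frequency class weights, normalized so the mean weight is 1.

    The similar-class weight times the similar count equals the
    dissimilar-class weight times the dissimilar count; with one class
    empty all weights are 1 (with a warning).
    """
    n_sim, n_dis = pairs.n_similar, pairs.n_dissimilar
    n = len(pairs)
    if n_sim == 0 or n_dis == 0:
        warnings.warn("only one pair class present; uniform weights",
                      stacklevel=2)
        pairs.weights = np.ones(n)
        return pairs
    w_sim = n / (2.0 * n_sim)
    w_dis = n / (2.0 * n_dis)
    pairs.weights = np.where(pairs.similar, w_sim, w_dis)
    return pairs
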