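"""Trait-based personalization: feature augmentation and cluster models.

Two mechanisms on top of the base metric-learning regressor:

* trait augmentation — each daily record's feature vector is extended by
  the participant's (constant) trait vector, with the trait
  positive/negative-affect entries dropped when the target construct is
  positive or negative affect (leakage rule);
* cluster-specific models — participants are clustered by K-means on the
  first three principal components of their min-max-scaled trait vectors
  (fitted on training participants only), and one trait-augmented model is
  trained per cluster, with held-out participants routed by
  nearest-centroid assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .metric_model import ModelConfig, TrainedModel, build_model, train
from .pairing import form_pairs
from .schema_io import FeatureSchema, Dataset, ID_COL

__all__ = ["DEFAULT_N_CLUSTERS", "ClusterModel", "ElbowReport",
           "ClusterEnsemble", "augment_with_traits", "fit_trait_clusters",
           "select_k_elbow", "assign_clusters", "cluster_trait_means",
           "train_cluster_models", "predict_cluster_ensemble"]

DEFAULT_N_CLUSTERS = 4
N_PCA_COMPONENTS = 3


def augment_with_traits(dataset: Dataset, construct: str) -> Dataset:
    """Append each participant's trait vector to every daily record.

    The returned dataset's feature schema gains a ``traits`` group, so all
    downstream feature handling picks up the widened vectors transparently.
    Trait affect entries are dropped first for the affect constructs.
    """
    trait_names = dataset.trait_schema.names_for_construct(construct)
    missing = dataset.frame[trait_names].isna()
    if missing.any().any():
        row = dataset.frame.loc[missing.any(axis=1)].iloc[0]
        raise ValueError(
            f"participant {row[ID_COL]!r} has missing trait values")
    groups = dict(dataset.feature_schema.groups)
    groups["traits"] = tuple(trait_names)
    return Dataset(dataset.frame, FeatureSchema(groups=groups),
                   dataset.trait_schema, dataset.label_schemas)


@dataclass
class ClusterModel:
    """Fitted trait-space clustering: min-max scaling -> 3-d PCA -> K-means."""

    trait_names: list[str]
    trait_min: pd.Series
    trait_max: pd.Series
    pca: PCA
    kmeans: KMeans
    n_clusters: int
    assignments: dict[str, int]  # training participants only

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_

    def transform(self, traits: pd.DataFrame) -> np.ndarray:
        if list(traits.columns) != self.trait_names:
            traits = traits[self.trait_names]
        span = (self.trait_max - self.trait_min).replace(0.0, np.nan)
        scaled = ((traits - self.trait_min) / span).fillna(0.0)
        return self.pca.transform(scaled.to_numpy(float))


@dataclass
class ElbowReport:
    ks: list[int]
    distortion: list[float]
    inertia: list[float]
    chosen_k: int
    clear_elbow: bool


def _scaled_traits(trait_table: pd.DataFrame
                   ) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    tmin, tmax = trait_table.min(), trait_table.max()
    span = (tmax - tmin).replace(0.0, np.nan)
    return ((trait_table - tmin) / span).fillna(0.0), tmin, tmax


def fit_trait_clusters(trait_table: pd.DataFrame,
                       n_clusters: int = DEFAULT_N_CLUSTERS,
                       seed: int = 0) -> ClusterModel:
    """Cluster training participants in trait space.

    ``trait_table`` holds one row per training participant (index =
    participant id). Scaling, PCA, and K-means are all fitted here and
    reused verbatim for held-out assignment.
    """
    if n_clusters > len(trait_table):
        raise ValueError("more clusters than training participants")
    scaled, tmin, tmax = _scaled_traits(trait_table)
    n_comp = min(N_PCA_COMPONENTS, scaled.shape[1], len(scaled))
    pca = PCA(n_components=n_comp, random_state=seed)
    projected = pca.fit_transform(scaled.to_numpy(float))
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(projected)
    assignments = {str(pid): int(c)
                   for pid, c in zip(trait_table.index, labels)}
    return ClusterModel(trait_names=list(trait_table.columns),
                        trait_min=tmin, trait_max=tmax, pca=pca, kmeans=km,
                        n_clusters=n_clusters, assignments=assignments)


def select_k_elbow(trait_table: pd.DataFrame,
                   k_range: list[int] | range = range(1, 9),
                   seed: int = 0,
                   default_k: int = DEFAULT_N_CLUSTERS) -> ElbowReport:
    """Distortion/inertia elbow scan with a second-difference elbow rule.

    When no clear elbow exists the configured default K is returned with
    ``clear_elbow=False``.
    """
    ks = sorted(int(k) for k in k_range)
    if ks[0] < 1 or ks[-1] > len(trait_table):
        raise ValueError("k_range must lie within [1, n_participants]")
    scaled, _, _ = _scaled_traits(trait_table)
    n_comp = min(N_PCA_COMPONENTS, scaled.shape[1], len(scaled))
    projected = PCA(n_components=n_comp, random_state=seed).fit_transform(
        scaled.to_numpy(float))
    inertia, distortion = [], []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        km.fit(projected)
        inertia.append(float(km.inertia_))
        distortion.append(float(km.inertia_) / len(projected))
    chosen, clear = default_k, False
    if len(ks) >= 3:
        curv = [inertia[i - 1] - 2 * inertia[i] + inertia[i + 1]
                for i in range(1, len(ks) - 1)]
        total_drop = inertia[0] - inertia[-1]
        if total_drop > 0 and max(curv) > 0.1 * total_drop:
            chosen = ks[1 + int(np.argmax(curv))]
            clear = True
    return ElbowReport(ks=ks, distortion=distortion, inertia=inertia,
                       chosen_k=chosen, clear_elbow=clear)


def assign_clusters(cm: ClusterModel, dataset: Dataset) -> pd.Series:
    """Nearest-centroid cluster per participant, in the fitted PCA space."""
    traits = dataset.trait_table()[cm.trait_names]
    projected = cm.transform(traits)
    labels = cm.kmeans.predict(projected)
    return pd.Series(labels, index=traits.index, name="cluster")


def cluster_trait_means(cm: ClusterModel,
                        trait_table: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster mean of min-max-normalized traits (profile table)."""
    scaled = trait_table[cm.trait_names].copy()
    span = (cm.trait_max - cm.trait_min).replace(0.0, np.nan)
    scaled = ((scaled - cm.trait_min) / span).fillna(0.0)
    labels = cm.kmeans.predict(cm.pca.transform(scaled.to_numpy(float)))
    scaled["cluster"] = labels
    return scaled.groupby("cluster").mean()


@dataclass
class ClusterEnsemble:
    cluster_model: ClusterModel
    models: dict[int, TrainedModel]
    feature_columns: list[str]
    construct: str


def train_cluster_models(train_data: Dataset, val_data: Dataset,
                         cm: ClusterModel, construct: str,
                         cfg: ModelConfig,
                         pair_threshold: int = 1,
                         max_pairs: Optional[int] = None) -> ClusterEnsemble:
    """Train one trait-augmented metric model per trait cluster.

    ``train_data``/``val_data`` must already be preprocessed and
    trait-augmented. A cluster with no trainable participants gets no
    model; its held-out samples are routed to the nearest trained cluster.
    """
    feature_columns = train_data.feature_schema.names
    train_assign = assign_clusters(cm, train_data)
    val_assign = assign_clusters(cm, val_data)
    models: dict[int, TrainedModel] = {}
    for c in range(cm.n_clusters):
        pids = list(train_assign.index[train_assign == c])
        if not pids:
            warnings.warn(f"cluster {c} has no training participants",
                          stacklevel=2)
            continue
        subset = train_data.subset(pids)
        try:
            pairs = form_pairs(subset, construct, threshold=pair_threshold,
                               feature_columns=feature_columns)
        except ValueError:
            warnings.warn(f"cluster {c} has no trainable pairs",
                          stacklevel=2)
            continue
        if max_pairs is not None:
            pairs = pairs.subsample(max_pairs, seed=cfg.seed or 0)
        val_pids = list(val_assign.index[val_assign == c])
        val_subset = val_data.subset(val_pids) if val_pids else val_data
        val_frame = val_subset.frame.dropna(subset=[construct])
        if val_frame.empty:
            val_frame = val_data.frame.dropna(subset=[construct])
        model = build_model(cfg, input_dim=len(feature_columns))
        models[c] = train(model, pairs,
                          val_frame[feature_columns].to_numpy(float),
                          val_frame[construct].to_numpy(float), cfg)
    if not models:
        raise ValueError("no cluster produced a trainable model")
    return ClusterEnsemble(cluster_model=cm, models=models,
                           feature_columns=feature_columns,
                           construct=construct)


def predict_cluster_ensemble(ensemble: ClusterEnsemble,
                             dataset: Dataset) -> np.ndarray:
    """Route each record to its participant's cluster model and predict."""
    from .metric_model import predict
    cm = ensemble.cluster_model
    assign = assign_clusters(cm, dataset)
    trained_clusters = sorted(ensemble.models)
    centroids = cm.kmeans.cluster_centers_

    def route(c: int) -> int:
        if c in ensemble.models:
            return c
        dists = [np.linalg.norm(centroids[c] - centroids[t])
                 for t in trained_clusters]
        return trained_clusters[int(np.argmin(dists))]

    X = dataset.frame[ensemble.feature_columns].to_numpy(float)
    out = np.empty(len(X))
    pid_cluster = {pid: route(int(c)) for pid, c in assign.items()}
    row_pids = dataset.frame[ID_COL].to_numpy(str)
    for c in set(pid_cluster.values()):
        rows = np.array([pid_cluster[p] == c for p in row_pids])
        if rows.any():
            out[rows] = predict(ensemble.models[c], X[rows])
    return out
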