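"""Participant-independent evaluation protocol.

Stratified participant folds (10 by default), per-fold fine-tuning
splits, restart loops with fresh models, Pearson scoring, one-tailed
paired t-tests, Gaussian-process hyperparameter search, and the
person-identification probe that measures how much participant identity a
representation retains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .baselines import SmidaConfig, fit_smida, smida_predict, \
    train_fnn_baseline
from .metric_model import ModelConfig, build_model, fine_tune_split, \
    predict, train
from .pairing import form_pairs
from .personalization import DEFAULT_N_CLUSTERS, augment_with_traits, \
    fit_trait_clusters, predict_cluster_ensemble, train_cluster_models
from .preprocessing import apply_minmax, fit_minmax, interpolate_dataset
from .schema_io import DAY_COL, ID_COL, Dataset

__all__ = ["FoldPlan", "EvalReport", "LeakageError", "VARIANTS",
           "make_folds", "pearson_r", "paired_ttest", "person_id_probe",
           "tune_hyperparameters", "run_experiment"]

VARIANTS = ("ml-a", "ml-at", "ml-c", "fnn", "smida")
DEFAULT_N_FOLDS = 10


class LeakageError(RuntimeError):
    """Raised when train and test data share samples or participants."""


@dataclass(frozen=True)
class FoldPlan:
    """Partition of participants into test folds with rotating validation.

    For test fold ``f`` the validation fold is ``(f+1) mod n_folds`` and
    the remaining folds train.
    """

    folds: tuple[tuple[str, ...], ...]
    construct: str
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def test_participants(self, f: int) -> list[str]:
        return list(self.folds[f])

    def val_participants(self, f: int) -> list[str]:
        return list(self.folds[(f + 1) % self.n_folds])

    def train_participants(self, f: int) -> list[str]:
        skip = {f, (f + 1) % self.n_folds}
        return [p for i, fold in enumerate(self.folds) if i not in skip
                for p in fold]

    def audit(self) -> None:
        all_p = [p for fold in self.folds for p in fold]
        if len(set(all_p)) != len(all_p):
            raise LeakageError("participant appears in more than one fold")
        for f in range(self.n_folds):
            tr = set(self.train_participants(f))
            va = set(self.val_participants(f))
            te = set(self.test_participants(f))
            if tr & va or tr & te or va & te:
                raise LeakageError(f"fold {f}: train/val/test sets overlap")


def make_folds(dataset: Dataset, construct: str,
               n_folds: int = DEFAULT_N_FOLDS, seed: int = 0) -> FoldPlan:
    """Stratified participant folds.

    Participants are ordered by their mean construct label (seeded random
    tie-breaking) and dealt round-robin, so every fold sees a comparable
    label distribution.
    """
    pids = dataset.participants
    if len(pids) < n_folds:
        raise ValueError(
            f"need at least {n_folds} participants, have {len(pids)}")
    rng = np.random.default_rng(seed)
    means = (dataset.frame[[ID_COL, construct]]
             .dropna(subset=[construct])
             .groupby(ID_COL, sort=False)[construct].mean())
    shuffled = list(rng.permutation(pids))
    shuffled.sort(key=lambda p: means.get(p, np.inf))
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for i, pid in enumerate(shuffled):
        folds[i % n_folds].append(pid)
    plan = FoldPlan(folds=tuple(tuple(f) for f in folds),
                    construct=construct, seed=seed)
    plan.audit()
    return plan


def pearson_r(pred: np.ndarray, true: np.ndarray) -> float:
    """Sample Pearson correlation; NaN for constant inputs."""
    pred = np.asarray(pred, float)
    true = np.asarray(true, float)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if len(pred) < 2:
        raise ValueError("need at least two samples")
    pc = pred - pred.mean()
    tc = true - true.mean()
    denom = math.sqrt((pc ** 2).sum() * (tc ** 2).sum())
    if denom == 0.0:
        return float("nan")
    return float(np.clip((pc * tc).sum() / denom, -1.0, 1.0))


def paired_ttest(scores_a: Sequence[float], scores_b: Sequence[float],
                 alternative: str = "greater"
                 ) -> tuple[float, int, float]:
    """One-tailed paired t-test of mean(scores_a - scores_b).

    Returns (t, df, p). Zero-variance zero-mean differences are degenerate
    and reported as (0, df, 0.5).
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired score vectors of equal length >= 2 needed")
    df = len(a) - 1
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        warnings.warn("zero-variance differences in paired t-test",
                      stacklevel=2)
        if np.allclose(diff.mean(), 0.0):
            return 0.0, df, 0.5
        t = math.inf if diff.mean() > 0 else -math.inf
        p = 0.0 if (t > 0) == (alternative == "greater") else 1.0
        return t, df, p
    res = stats.ttest_rel(a, b, alternative=alternative)
    return float(res.statistic), df, float(res.pvalue)


@dataclass
class EvalReport:
    """Per-(variant, fold, restart, fraction) scores plus aggregates."""

    scores: pd.DataFrame
    construct: str
    metadata: dict = field(default_factory=dict)
    probe: dict = field(default_factory=dict)

    SCORE_COLUMNS = ("variant", "construct", "fold", "restart",
                     "fraction", "pearson_r")

    def aggregates(self) -> pd.DataFrame:
        """Mean/SD Pearson per (variant, fraction), NaN scores excluded."""
        def _agg(g: pd.Series) -> pd.Series:
            finite = g.dropna()
            return pd.Series({"mean_r": finite.mean(),
                              "sd_r": finite.std(ddof=1),
                              "n_scores": len(finite),
                              "n_missing": g.isna().sum()})
        return (self.scores.groupby(["variant", "fraction"])["pearson_r"]
                .apply(_agg).unstack().reset_index())

    def restart_means(self, variant: str, fraction: float) -> np.ndarray:
        """Per-restart mean r over folds (pairing unit for t-tests)."""
        sel = self.scores[(self.scores["variant"] == variant)
                          & (self.scores["fraction"] == fraction)]
        return (sel.groupby("restart")["pearson_r"].mean()
                .sort_index().to_numpy())

    def compare(self, variant_a: str, variant_b: str,
                fraction: float) -> tuple[float, int, float]:
        return paired_ttest(self.restart_means(variant_a, fraction),
                            self.restart_means(variant_b, fraction))

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "construct": self.construct,
            "metadata": self.metadata,
            "probe": self.probe,
            "scores": self.scores.where(pd.notna(self.scores), None)
                                 .to_dict(orient="records"),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "EvalReport":
        scores = pd.DataFrame(payload["scores"],
                              columns=list(cls.SCORE_COLUMNS))
        if len(scores):
            scores["pearson_r"] = pd.to_numeric(scores["pearson_r"])
        return cls(scores=scores, construct=payload["construct"],
                   metadata=payload.get("metadata", {}),
                   probe=payload.get("probe", {}))

    @classmethod
    def empty(cls, construct: str) -> "EvalReport":
        return cls(scores=pd.DataFrame(columns=list(cls.SCORE_COLUMNS)),
                   construct=construct)


# -- Gaussian-process hyperparameter search -------------------------------

@dataclass(frozen=True)
class SearchDimension:
    name: str
    choices: Optional[tuple] = None          # categorical / discrete
    low: Optional[float] = None              # continuous
    high: Optional[float] = None
    log: bool = False

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.random())

    def decode(self, u: float):
        if self.choices is not None:
            i = min(int(u * len(self.choices)), len(self.choices) - 1)
            return self.choices[i]
        lo, hi = float(self.low), float(self.high)
        if self.log:
            return float(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))))
        return lo + u * (hi - lo)


def tune_hyperparameters(space: dict,
                         objective: Callable[[dict], float],
                         n_calls: int = 200,
                         n_initial: int = 10,
                         seed: int = 42) -> tuple[dict, list]:
    """Sequential GP minimization with an expected-improvement acquisition.

    ``space`` maps parameter names to either a list/tuple of choices or a
    (low, high) bound pair (optionally (low, high, "log")). ``objective``
    receives a parameter dict and returns the value to minimize (use the
    negative validation Pearson). Returns (best_params, evaluation_log).
    Deterministic given ``seed`` and a deterministic objective; objective
    failures are penalized and the search continues.
    """
    dims = []
    for name, spec in space.items():
        spec = tuple(spec)
        is_bounds = (len(spec) == 2 and all(isinstance(v, float)
                                            for v in spec)) \
            or (len(spec) == 3 and spec[2] == "log")
        if is_bounds:
            dims.append(SearchDimension(
                name, low=float(spec[0]), high=float(spec[1]),
                log=len(spec) == 3))
        else:
            dims.append(SearchDimension(name, choices=spec))
    rng = np.random.default_rng(seed)
    evaluated: dict[tuple, float] = {}
    log_entries: list[tuple[dict, float]] = []

    def decode(u: np.ndarray) -> dict:
        return {d.name: d.decode(u[i]) for i, d in enumerate(dims)}

    def run(u: np.ndarray) -> float:
        params = decode(u)
        key = tuple(params.values())
        if key in evaluated:
            return evaluated[key]
        try:
            val = float(objective(params))
            if not np.isfinite(val):
                raise ValueError("non-finite objective")
        except Exception as exc:  # penalize and continue
            warnings.warn(f"objective failed ({exc}); penalizing",
                          stacklevel=2)
            val = 1e6
        evaluated[key] = val
        log_entries.append((params, val))
        return val

    U = rng.random((max(2, min(n_initial, n_calls)), len(dims)))
    vals = [run(u) for u in U]
    while len(log_entries) < n_calls:
        if len(evaluated) >= _space_cardinality(dims):
            break  # exhausted a fully discrete space
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5), normalize_y=True, alpha=1e-6,
            random_state=seed)
        gp.fit(U, np.asarray(vals))
        cand = rng.random((256, len(dims)))
        mu, sigma = gp.predict(cand, return_std=True)
        best = min(vals)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (best - mu) / sigma
            ei = (best - mu) * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)
        ei[sigma < 1e-12] = 0.0
        u = cand[int(np.argmax(ei))]
        v = run(u)
        U = np.vstack([U, u])
        vals.append(v)
    best_params, _ = min(log_entries, key=lambda e: e[1])
    return best_params, log_entries


def _space_cardinality(dims: list[SearchDimension]) -> float:
    total = 1.0
    for d in dims:
        if d.choices is None:
            return math.inf
        total *= len(d.choices)
    return total


# -- person-identification probe -----------------------------------------

def person_id_probe(X: np.ndarray, participant_ids: np.ndarray,
                    restarts: int = 20, seed: int = 0) -> float:
    """Mean accuracy of a logistic-regression participant classifier.

    70/30 stratified sample-level split per restart; higher accuracy means
    the representation retains more person-specific information.
    """
    X = np.asarray(X, float)
    pids = np.asarray(participant_ids)
    if len(np.unique(pids)) < 2:
        raise ValueError("probe needs at least two participants")
    accs = []
    rng = np.random.default_rng(seed)
    for _ in range(restarts):
        rs = int(rng.integers(0, 2 ** 31 - 1))
        Xtr, Xte, ytr, yte = train_test_split(
            X, pids, test_size=0.3, stratify=pids, random_state=rs)
        clf = LogisticRegression(max_iter=500, random_state=rs)
        clf.fit(Xtr, ytr)
        accs.append(float((clf.predict(Xte) == yte).mean()))
    return float(np.mean(accs))


# -- experiment runner ----------------------------------------------------

def _check_no_sample_overlap(train_frame: pd.DataFrame,
                             test_frame: pd.DataFrame) -> None:
    keys_tr = set(zip(train_frame[ID_COL], train_frame[DAY_COL]))
    keys_te = set(zip(test_frame[ID_COL], test_frame[DAY_COL]))
    shared = keys_tr & keys_te
    if shared:
        raise LeakageError(
            f"{len(shared)} samples appear in both train and test, e.g. "
            f"{sorted(shared)[:3]}")


def run_experiment(variant: str, dataset: Dataset, plan: FoldPlan,
                   construct: str,
                   fractions: Sequence[float] = (0.0,),
                   restarts: int = 20,
                   model_config: ModelConfig | None = None,
                   smida_config: SmidaConfig | None = None,
                   n_clusters: int = DEFAULT_N_CLUSTERS,
                   pair_threshold: int = 1,
                   max_pairs: Optional[int] = None,
                   folds: Optional[Sequence[int]] = None,
                   seed: int = 0) -> EvalReport:
    """Cross-validated evaluation of one model variant.

    For every fold x fraction x restart a fresh model is trained on the
    training folds plus the fine-tuning portion of the target
    participants' data, and scored (Pearson r) on the reduced test fold.
    Normalization statistics are refit on the training pool each time; no
    state crosses folds. A sample-overlap audit guards against leakage.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; one of {VARIANTS}")
    plan.audit()
    model_config = model_config or ModelConfig()
    smida_config = smida_config or SmidaConfig()
    dataset = interpolate_dataset(dataset)
    fold_ids = list(folds) if folds is not None else list(
        range(plan.n_folds))

    rows = []
    for f in fold_ids:
        train_p = plan.train_participants(f)
        val_p = plan.val_participants(f)
        test_p = plan.test_participants(f)
        base_train = dataset.subset(train_p)
        val_data = dataset.subset(val_p)
        test_data = dataset.subset(test_p)
        for fraction in fractions:
            ft_data, reduced_test = fine_tune_split(
                test_data, fraction, seed=seed + 1000 * f)
            train_pool = base_train.replace_frame(
                pd.concat([base_train.frame, ft_data.frame],
                          ignore_index=True))
            _check_no_sample_overlap(train_pool.frame, reduced_test.frame)

            stats_ = fit_minmax(train_pool)
            tr = apply_minmax(train_pool, stats_)
            va = apply_minmax(val_data, stats_)
            te = apply_minmax(reduced_test, stats_)
            if variant in ("ml-at", "ml-c"):
                tr, va, te = _scale_traits(tr, va, te)
                tr = augment_with_traits(tr, construct)
                va = augment_with_traits(va, construct)
                te = augment_with_traits(te, construct)
            feature_cols = tr.feature_schema.names
            va_frame = va.frame.dropna(subset=[construct])
            te_frame = te.frame.dropna(subset=[construct])
            if len(te_frame) < 2:
                warnings.warn(f"fold {f}: test fold too small to score",
                              stacklevel=2)
                continue
            te_X = te_frame[feature_cols].to_numpy(float)
            te_y = te_frame[construct].to_numpy(float)

            for restart in range(restarts):
                rseed = seed + 100_000 * f + 10_000 * restart \
                    + int(fraction * 1000)
                cfg = replace(model_config, seed=rseed)
                pred = _fit_predict(
                    variant, tr, va_frame, te_X, te_y, te_frame,
                    construct, feature_cols, cfg, smida_config,
                    n_clusters, pair_threshold, max_pairs, rseed)
                rows.append({"variant": variant, "construct": construct,
                             "fold": f, "restart": restart,
                             "fraction": fraction,
                             "pearson_r": pearson_r(pred, te_y)})
    report = EvalReport(scores=pd.DataFrame(
        rows, columns=list(EvalReport.SCORE_COLUMNS)), construct=construct)
    report.metadata = {"variant": variant, "restarts": restarts,
                       "fractions": list(fractions), "seed": seed,
                       "n_folds_run": len(fold_ids),
                       "multiple_comparison_correction": "none"}
    return report


def _fit_predict(variant, tr, va_frame, te_X, te_y, te_frame, construct,
                 feature_cols, cfg, smida_cfg, n_clusters, pair_threshold,
                 max_pairs, rseed) -> np.ndarray:
    va_X = va_frame[feature_cols].to_numpy(float)
    va_y = va_frame[construct].to_numpy(float)
    tr_frame = tr.frame.dropna(subset=[construct])
    tr_X = tr_frame[feature_cols].to_numpy(float)
    tr_y = tr_frame[construct].to_numpy(float)

    if variant in ("ml-a", "ml-at"):
        pairs = form_pairs(tr, construct, threshold=pair_threshold,
                           feature_columns=feature_cols)
        if max_pairs is not None:
            pairs = pairs.subsample(max_pairs, seed=rseed)
        model = build_model(cfg, input_dim=len(feature_cols))
        trained = train(model, pairs, va_X, va_y, cfg)
        return predict(trained, te_X)
    if variant == "ml-c":
        cm = fit_trait_clusters(tr.trait_table(),
                                n_clusters=min(n_clusters,
                                               len(tr.participants)),
                                seed=rseed)
        ensemble = train_cluster_models(
            tr, _as_dataset(tr, va_frame), cm, construct, cfg,
            pair_threshold=pair_threshold, max_pairs=max_pairs)
        return predict_cluster_ensemble(ensemble, _as_dataset(tr, te_frame))
    if variant == "fnn":
        trained = train_fnn_baseline(tr_X, tr_y, va_X, va_y, cfg)
        return predict(trained, te_X)
    if variant == "smida":
        X_all = np.vstack([tr_X, te_X])
        domains = np.concatenate([tr_frame[ID_COL].to_numpy(str),
                                  te_frame[ID_COL].to_numpy(str)])
        y_masked = np.concatenate([tr_y, np.full(len(te_y), np.nan)])
        scfg = replace(smida_cfg,
                       subspace_dim=min(smida_cfg.subspace_dim,
                                        X_all.shape[1]))
        proj = fit_smida(X_all, domains, y_masked, scfg)
        return smida_predict(proj, tr_X, tr_y, te_X)
    raise AssertionError(variant)


def _scale_traits(tr: Dataset, va: Dataset, te: Dataset
                  ) -> tuple[Dataset, Dataset, Dataset]:
    """Min-max scale trait columns with training-pool extremes, clipped
    to [0, 1] (same convention as the ambulatory features)."""
    cols = tr.trait_schema.names
    tmin = tr.frame[cols].min()
    span = (tr.frame[cols].max() - tmin).replace(0.0, np.nan)

    def scale(ds: Dataset) -> Dataset:
        frame = ds.frame.copy()
        frame[cols] = ((frame[cols] - tmin) / span).fillna(0.0) \
            .clip(0.0, 1.0)
        return ds.replace_frame(frame)

    return scale(tr), scale(va), scale(te)


def _as_dataset(template: Dataset, frame: pd.DataFrame) -> Dataset:
    return Dataset(frame.reset_index(drop=True), template.feature_schema,
                   template.trait_schema, template.label_schemas)
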