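"""Nested cross-validation benchmark of AD definitions.

The workflow: an outer K-fold loop assesses performance; for each outer
training set, an inner K-fold loop tunes hyperparameters - the regression
(QRPR) model by minimizing cross-validated RMSE, the AD definitions by
maximizing the OIR or OD metric on the inner-loop predictions.  Tuned
models are refitted on the full outer training set, applied to the outer
test fold, and the per-reaction predictions and in/out decisions of all
folds are merged before the AD metrics are computed.  Composite methods
(written with a trailing ``*``, e.g. ``RFR_VAR*/OIR``) AND their decision
with Reaction Type Control at radius 1 (RTC1).

Method names follow the ``BASE[*][/OBJECTIVE]`` convention:

==============  =============================================  ==========
base            definition                                     tuned by
==============  =============================================  ==========
OZ, PZ          all-inlier / all-outlier zero models           -
Perfect         X-inlier iff |error| <= 3x RMSE (oracle)       -
BB, FC          bounding box, fragment control                 -
Leverage        h <= 3(M+1)/N                                  -
Z-1NN           1-NN distance <= 0.5*sigma + <d>               -
RTC1            reaction type control, radius 1                -
Lev_cv          leverage with tuned h*                         OIR or OD
Z-1NN_cv        1-NN with tuned distance threshold             OIR or OD
1-SVM           one-class SVM (nu, gamma)                      OIR or OD
2CC             Y-inlier classifier (max_features, p*)         OIR or OD
RTC_cv          reaction type control (radius)                 OIR or OD
RFR_VAR         per-tree variance of the QRPR forest (sigma*)  OIR or OD
GPR-AD          GPR posterior variance (alpha, gamma, sigma*)  OIR or OD
==============  =============================================  ==========

Everything is a pure function of (dataset, configuration, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from . import metrics as M
from .ad_methods import (
    ADInputs,
    BoundingBox,
    FragmentControl,
    GaussianProcessAD,
    Leverage,
    OneClassSVMAD,
    RandomForestVarianceAD,
    ReactionTypeControl,
    TwoClassClassifierAD,
    ZOneNN,
    forest_variance,
    twoclass_label,
)
from .descriptors import ReactionFeaturizer
from .io import ReactionDataset

__all__ = [
    "CVPlan",
    "BenchmarkConfig",
    "MethodSpec",
    "BenchmarkReport",
    "RankingRule",
    "DEFAULT_METHODS",
    "cross_validated_predictions",
    "tune_qrpr",
    "tune_ad",
    "run_benchmark",
    "apply_methods",
    "detect_nonnative",
    "rank_methods",
    "external_validate",
]


@dataclass(frozen=True)
class CVPlan:
    """Seeded fold assignments for the nested cross-validation."""

    n_outer: int = 5
    n_inner: int = 5
    seed: int = 0

    def outer_folds(self, n: int) -> list[np.ndarray]:
        perm = np.random.default_rng(self.seed).permutation(n)
        return [np.sort(f) for f in np.array_split(perm, self.n_outer)]

    def inner_folds(self, n: int, outer_index: int) -> list[np.ndarray]:
        perm = np.random.default_rng((self.seed, outer_index + 1)).permutation(n)
        return [np.sort(f) for f in np.array_split(perm, self.n_inner)]


def _log_grid(lo: float, hi: float, num: int) -> tuple[float, ...]:
    return tuple(float(v) for v in np.geomspace(lo, hi, num))


@dataclass(frozen=True)
class BenchmarkConfig:
    """All tunable knobs of the workflow; defaults are the studied conditions."""

    n_trees: int = 500
    qrpr_max_features_grid: tuple = (0.3, 0.6, 1.0)
    svm_nu_grid: tuple = (0.01, 0.05, 0.1, 0.2, 0.35, 0.5)
    svm_gamma_grid: tuple = _log_grid(1e-4, 1.0, 7)
    gpr_alpha_grid: tuple = _log_grid(1e-3, 10.0, 5)
    gpr_gamma_grid: tuple = _log_grid(1e-4, 1.0, 7)
    twocc_max_features_grid: tuple = (0.1, 0.3, 0.5, 0.7, 1.0)
    n_threshold_quantiles: int = 20
    rtc_radius_grid: tuple = (0, 1, 2, 3)
    rtc_radius: int = 1
    fragment_min_atoms: int = 2
    fragment_max_atoms: int = 4

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MethodSpec:
    """Parsed method name: base definition, composite flag, tuning objective."""

    base: str
    composite: bool
    objective: str | None

    TUNABLE = {"Lev_cv", "Z-1NN_cv", "1-SVM", "2CC", "RTC_cv", "RFR_VAR", "GPR-AD"}
    KNOWN = TUNABLE | {"OZ", "PZ", "Perfect", "BB", "FC", "Leverage", "Z-1NN", "RTC1"}

    @classmethod
    def parse(cls, name: str) -> "MethodSpec":
        objective = None
        if "/" in name:
            name, objective = name.split("/", 1)
            if objective not in ("OIR", "OD"):
                raise ValueError(f"unknown tuning objective {objective!r}")
        composite = name.endswith("*")
        base = name[:-1] if composite else name
        if base not in cls.KNOWN:
            raise ValueError(f"unknown AD method {base!r}")
        if base in cls.TUNABLE and objective is None:
            raise ValueError(f"{base} needs a tuning objective, e.g. {base}/OIR")
        if base not in cls.TUNABLE and objective is not None:
            raise ValueError(f"{base} has no hyperparameters to tune by {objective}")
        return cls(base=base, composite=composite, objective=objective)

    @property
    def name(self) -> str:
        out = self.base + ("*" if self.composite else "")
        return out + (f"/{self.objective}" if self.objective else "")

    @property
    def uses_gpr(self) -> bool:
        return self.base == "GPR-AD"


#: the benchmarked composite methods plus baselines, as in the study design
DEFAULT_METHODS = [
    "OZ", "PZ", "Perfect", "RTC1", "BB*", "FC*", "Leverage*", "Z-1NN*",
    "Lev_cv*/OIR", "Z-1NN_cv*/OIR", "1-SVM*/OIR", "2CC*/OIR", "RFR_VAR*/OIR", "GPR-AD*/OIR",
    "Lev_cv*/OD", "Z-1NN_cv*/OD", "1-SVM*/OD", "2CC*/OD", "RFR_VAR*/OD", "GPR-AD*/OD",
]


# ---------------------------------------------------------------------------
# inner-loop artifact computation


@dataclass
class _InnerArtifacts:
    """Merged inner-CV views over one outer training set."""

    best_max_features: float
    cv_pred: np.ndarray            # forest predictions, aligned to the outer-train rows
    cv_abs_errors: np.ndarray
    cv_rmse: float
    variance: np.ndarray           # per-tree variance of the same forests
    leverage: np.ndarray | None = None
    nn_distance: np.ndarray | None = None
    svm_decisions: dict | None = None        # (nu, gamma) -> bool array
    twocc_proba: dict | None = None          # max_features -> proba array
    rtc_decisions: dict | None = None        # radius -> bool array
    gpr_params: tuple | None = None          # (alpha, gamma)
    gpr_pred: np.ndarray | None = None
    gpr_abs_errors: np.ndarray | None = None
    gpr_rmse: float | None = None
    gpr_variance: np.ndarray | None = None


def _forest(config: BenchmarkConfig, max_features: float, seed: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=config.n_trees, max_features=max_features, random_state=seed
    )


def _inner_pass(train: ReactionDataset, plan: CVPlan, config: BenchmarkConfig,
                outer_index: int, need: set[str]) -> _InnerArtifacts:
    """One sweep of the inner CV loop computing everything tuning will need."""
    n = len(train)
    y = train.y
    folds = plan.inner_folds(n, outer_index)
    splits = []
    for test_idx in folds:
        mask = np.zeros(n, dtype=bool)
        mask[test_idx] = True
        tr, te = train.subset(np.where(~mask)[0]), train.subset(test_idx)
        feat = ReactionFeaturizer(config.fragment_min_atoms, config.fragment_max_atoms,
                                  train.solvent_table)
        feat.fit(tr.cgrs, tr.conditions)
        Xtr = feat.transform_standardized(tr.cgrs, tr.conditions)[0]
        Xte, unseen_te = feat.transform_standardized(te.cgrs, te.conditions)
        splits.append((test_idx, tr, te, Xtr, Xte, unseen_te))

    # QRPR tuning: forest max_features minimizing inner-CV RMSE
    preds = {}
    variances = {}
    for mf in config.qrpr_max_features_grid:
        p = np.empty(n)
        v = np.empty(n)
        for k, (test_idx, tr, te, Xtr, Xte, _) in enumerate(splits):
            forest = _forest(config, mf, seed=_derive_seed(plan.seed, outer_index, k))
            forest.fit(Xtr, tr.y)
            p[test_idx] = forest.predict(Xte)
            v[test_idx] = forest_variance(forest, Xte)
        preds[mf], variances[mf] = p, v
    rmses = {mf: M.rmse(y - preds[mf]) for mf in preds}
    best_mf = min(config.qrpr_max_features_grid, key=lambda mf: rmses[mf])

    art = _InnerArtifacts(
        best_max_features=best_mf,
        cv_pred=preds[best_mf],
        cv_abs_errors=np.abs(y - preds[best_mf]),
        cv_rmse=M.rmse(y - preds[best_mf]),
        variance=variances[best_mf],
    )

    if "leverage" in need:
        art.leverage = np.empty(n)
        for test_idx, tr, te, Xtr, Xte, _ in splits:
            lev = Leverage().fit(ADInputs(X=Xtr))
            art.leverage[test_idx] = lev.score(ADInputs(X=Xte))
    if "nn" in need:
        art.nn_distance = np.empty(n)
        for test_idx, tr, te, Xtr, Xte, _ in splits:
            knn = ZOneNN().fit(ADInputs(X=Xtr))
            art.nn_distance[test_idx] = knn.score(ADInputs(X=Xte))
    if "svm" in need:
        art.svm_decisions = {}
        for nu in config.svm_nu_grid:
            for gamma in config.svm_gamma_grid:
                d = np.empty(n, dtype=bool)
                for test_idx, tr, te, Xtr, Xte, _ in splits:
                    svm = OneClassSVMAD(nu=nu, gamma=gamma).fit(ADInputs(X=Xtr))
                    d[test_idx] = svm.decide(ADInputs(X=Xte))
                art.svm_decisions[(nu, gamma)] = d
    if "rtc" in need:
        art.rtc_decisions = {}
        for radius in config.rtc_radius_grid:
            d = np.empty(n, dtype=bool)
            for test_idx, tr, te, Xtr, Xte, _ in splits:
                rtc = ReactionTypeControl(radius=radius).fit(ADInputs(cgrs=tr.cgrs))
                d[test_idx] = rtc.decide(ADInputs(cgrs=te.cgrs))
            art.rtc_decisions[radius] = d
    if "2cc" in need:
        art.twocc_proba = {}
        for mf in config.twocc_max_features_grid:
            p = np.empty(n)
            for k, (test_idx, tr, te, Xtr, Xte, _) in enumerate(splits):
                import warnings as _w

                clf = TwoClassClassifierAD(
                    max_features=mf, n_trees=config.n_trees,
                    random_state=_derive_seed(plan.seed, outer_index, k),
                )
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    clf.fit(ADInputs(X=Xtr,
                                     cv_abs_errors=art.cv_abs_errors[~np.isin(np.arange(n), test_idx)],
                                     cv_rmse=art.cv_rmse))
                p[test_idx] = clf.score(ADInputs(X=Xte))
            art.twocc_proba[mf] = p
    if "gpr" in need:
        best = None
        for alpha in config.gpr_alpha_grid:
            for gamma in config.gpr_gamma_grid:
                p = np.empty(n)
                for test_idx, tr, te, Xtr, Xte, _ in splits:
                    gpr = GaussianProcessAD(alpha=alpha, gamma=gamma)
                    gpr.fit(ADInputs(X=Xtr, y=tr.y))
                    p[test_idx] = gpr.predict(Xte)
                r = M.rmse(y - p)
                if best is None or r < best[0]:
                    best = (r, alpha, gamma, p)
        _, alpha, gamma, p = best
        v = np.empty(n)
        for test_idx, tr, te, Xtr, Xte, _ in splits:
            gpr = GaussianProcessAD(alpha=alpha, gamma=gamma)
            gpr.fit(ADInputs(X=Xtr, y=tr.y))
            v[test_idx] = gpr.score(ADInputs(X=Xte))
        art.gpr_params = (alpha, gamma)
        art.gpr_pred = p
        art.gpr_abs_errors = np.abs(y - p)
        art.gpr_rmse = M.rmse(y - p)
        art.gpr_variance = v
    return art


def _derive_seed(seed: int, *parts: int) -> int:
    out = seed & 0x7FFFFFFF
    for p in parts:
        out = (out * 1_000_003 + p + 1) % (2**31 - 1)
    return out


# ---------------------------------------------------------------------------
# objective evaluation and candidate selection


def _objective_value(objective: str, errors: np.ndarray, decisions: np.ndarray,
                     flags: np.ndarray) -> float:
    if objective == "OIR":
        return M.oir(errors, decisions)
    if objective == "OD":
        return M.od(M.quadrant_counts(flags, decisions))
    raise ValueError(f"unknown objective {objective!r}")


def _select(candidates: list, decisions_per_candidate: list[np.ndarray],
            objective: str, errors: np.ndarray, flags: np.ndarray):
    """Best candidate by objective; ties to larger coverage, then grid order."""
    best_idx = None
    best_key = None
    for i, dec in enumerate(decisions_per_candidate):
        key = (_objective_value(objective, errors, dec, flags), float(np.mean(dec)))
        if best_key is None or key > best_key:
            best_key, best_idx = key, i
    return candidates[best_idx], best_key[0]


def _threshold_candidates(scores: np.ndarray, n_quantiles: int) -> np.ndarray:
    qs = np.linspace(0.0, 1.0, n_quantiles)
    return np.unique(np.quantile(np.asarray(scores, dtype=float), qs))


# ---------------------------------------------------------------------------
# per-fold fitting and application


@dataclass
class _FoldModels:
    featurizer: ReactionFeaturizer
    forest: RandomForestRegressor
    artifacts: _InnerArtifacts
    ad_models: dict            # method name -> fitted ADModel (base, non-composite)
    rtc1: ReactionTypeControl | None
    gpr: GaussianProcessAD | None
    chosen: dict               # method name -> hyperparameter record


def _needed_artifacts(specs: list[MethodSpec]) -> set[str]:
    need = set()
    for s in specs:
        if s.base == "Lev_cv":
            need.add("leverage")
        elif s.base == "Z-1NN_cv":
            need.add("nn")
        elif s.base == "1-SVM":
            need.add("svm")
        elif s.base == "2CC":
            need.add("2cc")
        elif s.base == "RTC_cv":
            need.add("rtc")
        elif s.base == "GPR-AD":
            need.add("gpr")
    return need


def _fit_fold(train: ReactionDataset, specs: list[MethodSpec], plan: CVPlan,
              config: BenchmarkConfig, outer_index: int) -> _FoldModels:
    import warnings as _w

    art = _inner_pass(train, plan, config, outer_index, _needed_artifacts(specs))
    feat = ReactionFeaturizer(config.fragment_min_atoms, config.fragment_max_atoms,
                              train.solvent_table)
    feat.fit(train.cgrs, train.conditions)
    X = feat.transform_standardized(train.cgrs, train.conditions)[0]
    y = train.y
    forest = _forest(config, art.best_max_features,
                     seed=_derive_seed(plan.seed, outer_index, 99))
    forest.fit(X, y)

    flags = M.y_outlier_flags(art.cv_abs_errors, art.cv_rmse)
    errors = art.cv_abs_errors
    gpr_flags = (M.y_outlier_flags(art.gpr_abs_errors, art.gpr_rmse)
                 if art.gpr_abs_errors is not None else None)

    gpr_model: GaussianProcessAD | None = None
    rtc1 = None
    if any(s.composite for s in specs) or any(s.base == "RTC1" for s in specs):
        rtc1 = ReactionTypeControl(radius=config.rtc_radius).fit(ADInputs(cgrs=train.cgrs))

    ad_models: dict = {}
    chosen: dict = {}
    train_inputs = ADInputs(X=X, y=y, cgrs=train.cgrs,
                            cv_abs_errors=errors, cv_rmse=art.cv_rmse)
    for s in specs:
        base, obj = s.base, s.objective
        if base in ("OZ", "PZ", "Perfect", "RTC1"):
            continue  # no fitting needed / handled at merge time or via rtc1
        if base == "BB":
            ad_models[s.name] = BoundingBox().fit(train_inputs)
        elif base == "FC":
            ad_models[s.name] = FragmentControl().fit(train_inputs)
        elif base == "Leverage":
            ad_models[s.name] = Leverage().fit(train_inputs)
        elif base == "Z-1NN":
            ad_models[s.name] = ZOneNN(z=0.5).fit(train_inputs)
        elif base == "Lev_cv":
            cands = list(_threshold_candidates(art.leverage, config.n_threshold_quantiles))
            decs = [art.leverage <= t for t in cands]
            h_star, _ = _select(cands, decs, obj, errors, flags)
            ad_models[s.name] = Leverage(h_star=h_star).fit(train_inputs)
            chosen[s.name] = {"h_star": h_star}
        elif base == "Z-1NN_cv":
            cands = list(_threshold_candidates(art.nn_distance, config.n_threshold_quantiles))
            decs = [art.nn_distance <= t for t in cands]
            dc, _ = _select(cands, decs, obj, errors, flags)
            ad_models[s.name] = ZOneNN(dc=dc).fit(train_inputs)
            chosen[s.name] = {"dc": dc}
        elif base == "1-SVM":
            cands = list(art.svm_decisions)
            decs = [art.svm_decisions[c] for c in cands]
            (nu, gamma), _ = _select(cands, decs, obj, errors, flags)
            ad_models[s.name] = OneClassSVMAD(nu=nu, gamma=gamma).fit(train_inputs)
            chosen[s.name] = {"nu": nu, "gamma": gamma}
        elif base == "2CC":
            cands, decs = [], []
            for mf, proba in art.twocc_proba.items():
                for p_star in _threshold_candidates(proba, config.n_threshold_quantiles):
                    cands.append((mf, float(p_star)))
                    decs.append(proba > p_star)
            (mf, p_star), _ = _select(cands, decs, obj, errors, flags)
            model = TwoClassClassifierAD(
                max_features=mf, p_star=p_star, n_trees=config.n_trees,
                random_state=_derive_seed(plan.seed, outer_index, 7))
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                ad_models[s.name] = model.fit(train_inputs)
            chosen[s.name] = {"max_features": mf, "p_star": p_star,
                              "degenerate": model.degenerate_}
        elif base == "RTC_cv":
            cands = list(art.rtc_decisions)
            decs = [art.rtc_decisions[c] for c in cands]
            radius, _ = _select(cands, decs, obj, errors, flags)
            ad_models[s.name] = ReactionTypeControl(radius=radius).fit(train_inputs)
            chosen[s.name] = {"radius": radius}
        elif base == "RFR_VAR":
            cands = list(_threshold_candidates(art.variance, config.n_threshold_quantiles))
            decs = [art.variance <= t for t in cands]
            sigma_star, _ = _select(cands, decs, obj, errors, flags)
            ad_models[s.name] = RandomForestVarianceAD(
                sigma_star=sigma_star, forest=forest).fit(train_inputs)
            chosen[s.name] = {"sigma_star": sigma_star,
                              "max_features": art.best_max_features}
        elif base == "GPR-AD":
            alpha, gamma = art.gpr_params
            if gpr_model is None:
                gpr_model = GaussianProcessAD(alpha=alpha, gamma=gamma)
                gpr_model.fit(ADInputs(X=X, y=y))
            cands = list(_threshold_candidates(art.gpr_variance, config.n_threshold_quantiles))
            decs = [art.gpr_variance <= t for t in cands]
            sigma_star, _ = _select(cands, decs, obj, art.gpr_abs_errors, gpr_flags)
            model = GaussianProcessAD(alpha=alpha, gamma=gamma, sigma_star=sigma_star)
            model.gpr_ = gpr_model.gpr_
            model.y_mean_, model.y_sd_ = gpr_model.y_mean_, gpr_model.y_sd_
            model.fitted_ = True
            ad_models[s.name] = model
            chosen[s.name] = {"alpha": alpha, "gamma": gamma, "sigma_star": sigma_star}
    return _FoldModels(featurizer=feat, forest=forest, artifacts=art,
                       ad_models=ad_models, rtc1=rtc1, gpr=gpr_model, chosen=chosen)


def _apply_fold(models: _FoldModels, test: ReactionDataset, specs: list[MethodSpec]
                ) -> tuple[np.ndarray, np.ndarray | None, dict]:
    """Predictions and per-method base decisions on one outer test fold."""
    X, unseen = models.featurizer.transform_standardized(test.cgrs, test.conditions)
    inputs = ADInputs(X=X, cgrs=test.cgrs, unseen_fragments=unseen)
    pred_rfr = models.forest.predict(X)
    pred_gpr = models.gpr.predict(X) if models.gpr is not None else None
    decisions: dict[str, np.ndarray] = {}
    rtc1_dec = models.rtc1.decide(inputs) if models.rtc1 is not None else None
    for s in specs:
        if s.base in ("OZ", "PZ", "Perfect"):
            continue  # merge-time decisions
        if s.base == "RTC1":
            decisions[s.name] = rtc1_dec
            continue
        dec = models.ad_models[s.name].decide(inputs)
        if s.composite:
            dec = dec & rtc1_dec
        decisions[s.name] = dec
    return pred_rfr, pred_gpr, decisions


# ---------------------------------------------------------------------------
# reports


@dataclass
class BenchmarkReport:
    """Merged outer-fold metrics, predictions and tuning records."""

    metrics: pd.DataFrame
    predictions: pd.DataFrame
    chosen: dict
    seed: int
    config: dict

    def summary(self, digits: int = 2) -> str:
        cols = ["coverage", "oir", "delta_r2_ad", "od", "auc_ad"]
        table = self.metrics[cols].round(digits)
        lines = ["AD definition benchmark (merged outer folds)",
                 f"seed = {self.seed}, n = {len(self.predictions)}", ""]
        lines.append(table.to_string())
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "config": self.config,
            "metrics": {
                name: {k: (None if isinstance(v, float) and math.isnan(v) else v)
                       for k, v in row.items()}
                for name, row in self.metrics.round(12).to_dict("index").items()
            },
            "chosen": self.chosen,
            "predictions": json.loads(self.predictions.round(9).to_json(orient="split")),
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def run_benchmark(dataset: ReactionDataset, methods: list[str] | None = None,
                  plan: CVPlan | None = None,
                  config: BenchmarkConfig | None = None) -> BenchmarkReport:
    """Nested-CV benchmark of the requested AD methods on one dataset."""
    methods = methods or DEFAULT_METHODS
    plan = plan or CVPlan()
    config = config or BenchmarkConfig()
    specs = [MethodSpec.parse(m) for m in methods]
    if plan.n_outer < 2:
        raise ValueError("need at least two outer folds")

    n = len(dataset)
    y = dataset.y
    pred_rfr = np.empty(n)
    pred_gpr = np.full(n, np.nan) if any(s.uses_gpr for s in specs) else None
    decisions: dict[str, np.ndarray] = {
        s.name: np.zeros(n, dtype=bool) for s in specs
        if s.base not in ("OZ", "PZ", "Perfect")
    }
    chosen: dict = {}
    failures: dict = {}
    for fold_index, test_idx in enumerate(plan.outer_folds(n)):
        mask = np.zeros(n, dtype=bool)
        mask[test_idx] = True
        train = dataset.subset(np.where(~mask)[0])
        test = dataset.subset(test_idx)
        try:
            models = _fit_fold(train, specs, plan, config, fold_index)
        except Exception as exc:
            failures[f"fold{fold_index}"] = repr(exc)
            raise
        p_rfr, p_gpr, fold_dec = _apply_fold(models, test, specs)
        pred_rfr[test_idx] = p_rfr
        if pred_gpr is not None and p_gpr is not None:
            pred_gpr[test_idx] = p_gpr
        for name, dec in fold_dec.items():
            decisions[name][test_idx] = dec
        chosen[f"fold{fold_index}"] = models.chosen

    # merge-time baselines: zero models and the error-defined perfect model
    errors_rfr = np.abs(y - pred_rfr)
    rmse_rfr = M.rmse(errors_rfr)
    for s in specs:
        if s.base == "OZ":
            decisions[s.name] = np.ones(n, dtype=bool)
        elif s.base == "PZ":
            decisions[s.name] = np.zeros(n, dtype=bool)
        elif s.base == "Perfect":
            decisions[s.name] = ~M.y_outlier_flags(errors_rfr, rmse_rfr)

    rows = {}
    for s in specs:
        y_pred = pred_gpr if s.uses_gpr else pred_rfr
        rows[s.name] = M.compute_report(y, y_pred, decisions[s.name]).to_dict()
    metrics = pd.DataFrame.from_dict(rows, orient="index")
    metrics.index.name = "method"

    pred_table = pd.DataFrame({"row": np.arange(n), "y_true": y, "y_pred_rfr": pred_rfr})
    if pred_gpr is not None:
        pred_table["y_pred_gpr"] = pred_gpr
    for s in specs:
        pred_table[f"in_ad[{s.name}]"] = decisions[s.name]
    return BenchmarkReport(metrics=metrics, predictions=pred_table, chosen=chosen,
                           seed=plan.seed, config=config.to_dict())


# ---------------------------------------------------------------------------
# spec-level convenience operations


def cross_validated_predictions(dataset: ReactionDataset, plan: CVPlan | None = None,
                                config: BenchmarkConfig | None = None
                                ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Cross-validated forest predictions and per-tree variances.

    Runs the inner CV loop once (tuning max_features by RMSE) and returns
    the merged out-of-fold predictions, the matching ensemble variances and
    an info record (chosen max_features, cross-validated RMSE).  This is
    the evaluation that defines Y-outliers (|error| > 3x RMSE).
    """
    plan = plan or CVPlan()
    config = config or BenchmarkConfig()
    art = _inner_pass(dataset, plan, config, outer_index=0, need=set())
    info = {"max_features": art.best_max_features, "cv_rmse": art.cv_rmse}
    return art.cv_pred, art.variance, info


def tune_qrpr(train: ReactionDataset, plan: CVPlan | None = None,
              config: BenchmarkConfig | None = None
              ) -> tuple[RandomForestRegressor, dict]:
    """Grid-tuned forest refitted on the full training set."""
    plan = plan or CVPlan()
    config = config or BenchmarkConfig()
    art = _inner_pass(train, plan, config, outer_index=0, need=set())
    feat = ReactionFeaturizer(config.fragment_min_atoms, config.fragment_max_atoms,
                              train.solvent_table)
    feat.fit(train.cgrs, train.conditions)
    X = feat.transform_standardized(train.cgrs, train.conditions)[0]
    forest = _forest(config, art.best_max_features, seed=_derive_seed(plan.seed, 0, 99))
    forest.fit(X, train.y)
    return forest, {"max_features": art.best_max_features, "cv_rmse": art.cv_rmse}


def tune_ad(train: ReactionDataset, method: str, plan: CVPlan | None = None,
            config: BenchmarkConfig | None = None):
    """Tune and fit one AD method on a training set (pass-through when untunable)."""
    plan = plan or CVPlan()
    config = config or BenchmarkConfig()
    spec = MethodSpec.parse(method)
    models = _fit_fold(train, [spec], plan, config, outer_index=0)
    if spec.base == "RTC1":
        return models.rtc1, {}
    return models.ad_models[spec.name], models.chosen.get(spec.name, {})


def detect_nonnative(train: ReactionDataset, foreign: ReactionDataset,
                     method: str = "RTC1",
                     config: BenchmarkConfig | None = None) -> float:
    """Fraction of a foreign dataset's reactions decided X-outliers.

    The method is fitted on the full training set with default settings
    (no cross-validated threshold tuning), mirroring the cross-application
    of structure-based AD filters between reaction types.
    """
    config = config or BenchmarkConfig()
    spec = MethodSpec.parse(method)
    feat = ReactionFeaturizer(config.fragment_min_atoms, config.fragment_max_atoms,
                              train.solvent_table)
    feat.fit(train.cgrs, train.conditions)
    X = feat.transform_standardized(train.cgrs, train.conditions)[0]
    train_inputs = ADInputs(X=X, y=train.y, cgrs=train.cgrs)
    builders = {
        "RTC1": lambda: ReactionTypeControl(radius=config.rtc_radius),
        "FC": lambda: FragmentControl(),
        "BB": lambda: BoundingBox(),
        "Leverage": lambda: Leverage(),
        "Z-1NN": lambda: ZOneNN(),
    }
    if spec.base not in builders:
        raise ValueError(f"detect_nonnative supports {sorted(builders)}, not {spec.base!r}")
    model = builders[spec.base]().fit(train_inputs)
    Xf, unseen = feat.transform_standardized(foreign.cgrs, foreign.conditions)
    dec = model.decide(ADInputs(X=Xf, cgrs=foreign.cgrs, unseen_fragments=unseen))
    if spec.composite:
        rtc1 = ReactionTypeControl(radius=config.rtc_radius).fit(train_inputs)
        dec = dec & rtc1.decide(ADInputs(cgrs=foreign.cgrs))
    return float(np.mean(~dec))


@dataclass(frozen=True)
class RankingRule:
    """Penalty scheme: 0 when a method is in the top half for a characteristic."""

    performance_metric: str = "delta_r2_ad"   # the "improvement" characteristic
    include_nonnative: bool = True


def rank_methods(reports: dict[str, BenchmarkReport],
                 nonnative_accepted: dict[str, dict[str, bool]] | None = None,
                 rule: RankingRule | None = None) -> pd.DataFrame:
    """Penalty ranking across datasets.

    For coverage, the performance-improvement metric and OD, a method in
    the top 50% for a dataset gets no penalty (strictly above the median;
    the median and below are penalized).  NaN metric values are always
    penalized.  A method accepting at least one non-native reaction gets
    one penalty per dataset where that happened.  Methods are ordered by
    ascending penalty sum, ties broken alphabetically.
    """
    rule = rule or RankingRule()
    method_sets = [set(r.metrics.index) for r in reports.values()]
    methods = sorted(set.intersection(*method_sets)) if method_sets else []
    if len(methods) < 2:
        raise ValueError("ranking needs at least two methods common to all reports")
    penalties = pd.DataFrame(0, index=methods, columns=[], dtype=int)
    for ds_name, report in reports.items():
        for characteristic in ("coverage", rule.performance_metric, "od"):
            values = report.metrics.loc[methods, characteristic]
            median = values.median(skipna=True)
            col = f"{ds_name}:{characteristic}"
            penalties[col] = [
                0 if (not pd.isna(v) and v > median) else 1 for v in values
            ]
        if rule.include_nonnative and nonnative_accepted and ds_name in nonnative_accepted:
            col = f"{ds_name}:nonnative"
            accepted = nonnative_accepted[ds_name]
            penalties[col] = [1 if accepted.get(m, False) else 0 for m in methods]
    out = penalties.copy()
    out["penalty_sum"] = penalties.sum(axis=1)
    out = out.sort_index().sort_values("penalty_sum", kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def apply_methods(train: ReactionDataset, test: ReactionDataset,
                  methods: list[str], plan: CVPlan | None = None,
                  config: BenchmarkConfig | None = None
                  ) -> tuple[np.ndarray, np.ndarray | None, dict[str, np.ndarray]]:
    """Tune + fit methods on a training set and apply them to an external set.

    Returns (forest predictions, GPR predictions or None, decisions per
    method name).  Zero/perfect baselines are decided from the external
    errors, as in the merged-fold evaluation.
    """
    plan = plan or CVPlan()
    config = config or BenchmarkConfig()
    specs = [MethodSpec.parse(m) for m in methods]
    models = _fit_fold(train, specs, plan, config, outer_index=0)
    pred_rfr, pred_gpr, decisions = _apply_fold(models, test, specs)
    y = test.y
    errors_rfr = np.abs(y - pred_rfr)
    rmse_rfr = M.rmse(errors_rfr)
    for s in specs:
        if s.base == "OZ":
            decisions[s.name] = np.ones(len(test), dtype=bool)
        elif s.base == "PZ":
            decisions[s.name] = np.zeros(len(test), dtype=bool)
        elif s.base == "Perfect":
            decisions[s.name] = ~M.y_outlier_flags(errors_rfr, rmse_rfr)
    return pred_rfr, pred_gpr, decisions


def external_validate(train: ReactionDataset, test: ReactionDataset,
                      methods: list[str] | None = None, plan: CVPlan | None = None,
                      config: BenchmarkConfig | None = None) -> pd.DataFrame:
    """Train on one dataset, apply to an external set; metrics on X-inliers only."""
    methods = methods or DEFAULT_METHODS
    specs = [MethodSpec.parse(m) for m in methods]
    pred_rfr, pred_gpr, decisions = apply_methods(train, test, methods, plan, config)
    y = test.y
    rows = {}
    for s in specs:
        y_pred = pred_gpr if s.uses_gpr else pred_rfr
        dec = decisions[s.name]
        if dec.sum() >= 2 and not np.all(y[dec] == y[dec][0]):
            r2 = M.r_squared(y[dec], y_pred[dec])
            rm = M.rmse(y[dec] - y_pred[dec])
        else:
            r2, rm = float("nan"), float("nan")
        rows[s.name] = {"r2": r2, "rmse": rm, "coverage": float(dec.mean())}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "method"
    return frame
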