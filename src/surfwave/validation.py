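"""Cross-validated diagnostic performance and adjusted misclassification.

The full training procedure - per-coefficient selection at the chosen
p-threshold, hierarchical clustering of the selected coefficients, and
majority-rule labeling of the two resulting groups - is re-run inside
every cross-validation fold, so no information from a held-out subject
(including which coefficients are selected) leaks into the model that
classifies it.

Three misclassification estimates are combined per class:

1. leave-one-out over the entire cohort,
2. ten stratified split-half replications (train on one half, classify the
   other), and
3. leave-one-out within each of the twenty half-cohorts from (2).

The adjusted rate is (1) + [mean(2) - mean(3)], clipped into [0, 1]; the
patient-class and comparison-class adjusted rates give sensitivity and
specificity, and the positive predictive value follows from the class
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .cluster import classify, cut_two_groups, hierarchical_cluster, majority_label
from .features import FeatureMatrix, select_features

__all__ = ["ClassifierConfig", "EmptySelectionError", "fit_group_model",
           "loo", "split_half", "adjusted_rates", "sens_spec_ppv",
           "iterative_three_way", "ValidationReport", "validate_cohort",
           "round_half_up"]


class EmptySelectionError(RuntimeError):
    """No feature survived the p-threshold in a training set."""


def round_half_up(x: float, decimals: int = 3) -> float:
    """Decimal round-half-up (0.0685 -> 0.069), matching how printed rates
    are conventionally rounded."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClassifierConfig:
    """Configuration of the train-and-classify procedure inside each fold."""

    alpha: float = 1e-7
    metric: str = "euclidean"
    linkage: str = "ward"
    test: str = "welch"
    residualize: bool = False
    fallback_all_when_empty: bool = False

    def replace(self, **kw) -> "ClassifierConfig":
        return dc_replace(self, **kw)


@dataclass(frozen=True)
class FoldModel:
    """Everything fitted on one training fold: the optional nuisance
    regression, the selected feature indices and the labeled group model."""

    model: object
    selected: np.ndarray
    residualizer: object = None

    def predict(self, fm_test: FeatureMatrix) -> pd.Series:
        if self.residualizer is not None:
            fm_test = self.residualizer.transform(fm_test)
        preds = {}
        for sid in fm_test.X.index:
            label, _d, _tie = classify(fm_test.X.loc[sid].iloc[self.selected],
                                       self.model)
            preds[sid] = label
        return pd.Series(preds)


def fit_group_model(fm: FeatureMatrix, labels: pd.Series,
                    cfg: ClassifierConfig) -> FoldModel:
    """Residualize (optionally), select features, cluster, cut into two
    groups and majority-label - all on the given (training) cohort only.

    Raises :class:`EmptySelectionError` when nothing passes the threshold
    and no fallback is configured.
    """
    residualizer = None
    if cfg.residualize:
        from .features import fit_residualizer
        residualizer = fit_residualizer(fm)
        fm = residualizer.transform(fm)
    if cfg.alpha >= 1.0:
        sel = np.arange(fm.n_features)
    else:
        res = select_features(fm, labels, alpha=cfg.alpha, test=cfg.test)
        sel = res.selected
        if len(sel) == 0:
            if not cfg.fallback_all_when_empty:
                raise EmptySelectionError(
                    f"no feature with p < {cfg.alpha:g} in training set")
            sel = np.arange(fm.n_features)
    x = fm.X.iloc[:, sel]
    dend = hierarchical_cluster(x, metric=cfg.metric, linkage=cfg.linkage)
    groups = cut_two_groups(dend)
    model = majority_label(groups, labels.loc[x.index], x, metric=cfg.metric)
    return FoldModel(model, np.asarray(sel), residualizer)


@dataclass(frozen=True)
class RateResult:
    per_class: dict          # class -> misclassification rate
    overall: float
    predictions: pd.Series


def _rates(labels: pd.Series, preds: pd.Series) -> RateResult:
    per_class = {}
    for cls in sorted(labels.dropna().unique()):
        ids = labels.index[labels == cls]
        per_class[cls] = float((preds.loc[ids] != cls).mean())
    overall = float((preds.loc[labels.index] != labels).mean())
    return RateResult(per_class, overall, preds)


def loo(fm: FeatureMatrix, labels=None, cfg: ClassifierConfig | None = None) -> RateResult:
    """Leave-one-out: the full selection + clustering + labeling pipeline
    is retrained on the n-1 remaining subjects for every fold."""
    cfg = cfg or ClassifierConfig()
    labels = fm.labels if labels is None else pd.Series(labels, index=fm.X.index)
    counts = labels.value_counts()
    if (counts < 3).any():
        raise ValueError(f"need >= 3 subjects per class, have {dict(counts)}")
    preds = {}
    for sid in fm.X.index:
        rest = [i for i in fm.X.index if i != sid]
        fold = fit_group_model(fm.subset(rest), labels.loc[rest], cfg)
        preds[sid] = fold.predict(fm.subset([sid])).loc[sid]
    return _rates(labels, pd.Series(preds))


def _stratified_halves(labels: pd.Series, rng) -> tuple:
    train, test = [], []
    for cls in sorted(labels.dropna().unique()):
        ids = list(labels.index[labels == cls])
        perm = list(rng.permutation(ids))
        half = (len(perm) + 1) // 2
        train += perm[:half]
        test += perm[half:]
    return sorted(train), sorted(test)


@dataclass(frozen=True)
class SplitHalfResult:
    split_mean: dict         # class -> mean test-half rate over splits
    split_sd: dict
    loo_split_mean: dict     # class -> mean LOO rate over the 2*n half-cohorts
    loo_split_sd: dict
    n_splits: int


def split_half(fm: FeatureMatrix, labels=None, cfg: ClassifierConfig | None = None,
               n_splits: int = 10, seed: int = 0) -> SplitHalfResult:
    """Stratified split-half replications plus LOO on every half-cohort."""
    cfg = cfg or ClassifierConfig()
    labels = fm.labels if labels is None else pd.Series(labels, index=fm.X.index)
    counts = labels.value_counts()
    if (counts < 4).any():
        raise ValueError("split-half needs >= 4 subjects per class")
    rng = np.random.default_rng(seed)
    classes = sorted(labels.dropna().unique())
    split_rates = {c: [] for c in classes}
    loo_rates = {c: [] for c in classes}
    for _ in range(n_splits):
        train_ids, test_ids = _stratified_halves(labels, rng)
        fold = fit_group_model(fm.subset(train_ids), labels.loc[train_ids], cfg)
        preds = fold.predict(fm.subset(test_ids))
        res = _rates(labels.loc[test_ids], preds)
        for c in classes:
            split_rates[c].append(res.per_class[c])
        for half in (train_ids, test_ids):
            res_half = loo(fm.subset(half), labels.loc[half], cfg)
            for c in classes:
                loo_rates[c].append(res_half.per_class[c])
    return SplitHalfResult(
        {c: float(np.mean(split_rates[c])) for c in classes},
        {c: float(np.std(split_rates[c], ddof=1)) for c in classes},
        {c: float(np.mean(loo_rates[c])) for c in classes},
        {c: float(np.std(loo_rates[c], ddof=1)) for c in classes},
        n_splits)


def adjusted_rates(loo_entire: float, split_half_mean: float,
                   loo_split_mean: float):
    """Adjusted misclassification rate, clipped into [0, 1].

    adjusted = LOO(entire cohort) + [mean split-half - mean LOO-on-split];
    returns ``(rate, clipped_flag)``.
    """
    for v in (loo_entire, split_half_mean, loo_split_mean):
        if not 0.0 <= v <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    raw = loo_entire + (split_half_mean - loo_split_mean)
    clipped = not 0.0 <= raw <= 1.0
    return float(min(max(raw, 0.0), 1.0)), clipped


def sens_spec_ppv(adjusted_patient: float, adjusted_comparison: float,
                  n_patient: int, n_comparison: int) -> dict:
    """Sensitivity, specificity and PPV from per-class adjusted rates.

    sensitivity = 1 - adjusted rate of the patient class; specificity =
    1 - adjusted rate of the comparison class; PPV = TP / (TP + FP) with
    TP = sensitivity * n_patient and FP = (1 - specificity) * n_comparison.
    """
    sens = 1.0 - adjusted_patient
    spec = 1.0 - adjusted_comparison
    tp = sens * n_patient
    fp = (1.0 - spec) * n_comparison
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    return {"sensitivity": sens, "specificity": spec, "ppv": ppv,
            "ppv_defined": (tp + fp) > 0}


@dataclass(frozen=True)
class ValidationReport:
    """Per-class cross-validated performance of one two-way comparison."""

    classes: tuple
    patient_class: str
    loo_entire: dict
    split_mean: dict
    split_sd: dict
    loo_split_mean: dict
    loo_split_sd: dict
    adjusted: dict
    sensitivity: float
    specificity: float
    ppv: float
    n_selected_full: int
    config: ClassifierConfig
    seed: int

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("classes", "patient_class", "loo_entire", "split_mean",
              "split_sd", "loo_split_mean", "loo_split_sd", "adjusted",
              "sensitivity", "specificity", "ppv", "n_selected_full", "seed")}
        d["classes"] = list(self.classes)
        d["config"] = self.config.__dict__
        return d


def validate_cohort(fm: FeatureMatrix, labels=None, patient_class: str | None = None,
                    cfg: ClassifierConfig | None = None, n_splits: int = 10,
                    seed: int = 0) -> ValidationReport:
    """Full two-way validation: LOO, split-half, adjusted rates and
    sensitivity/specificity/PPV for the designated patient class."""
    cfg = cfg or ClassifierConfig()
    labels = fm.labels if labels is None else pd.Series(labels, index=fm.X.index)
    classes = sorted(labels.dropna().unique())
    if len(classes) != 2:
        raise ValueError("two-way validation needs exactly two classes")
    patient = patient_class or classes[0]
    comparison = [c for c in classes if c != patient][0]
    res_loo = loo(fm, labels, cfg)
    res_sh = split_half(fm, labels, cfg, n_splits=n_splits, seed=seed)
    adjusted = {}
    for c in classes:
        adjusted[c], _ = adjusted_rates(res_loo.per_class[c],
                                        res_sh.split_mean[c],
                                        res_sh.loo_split_mean[c])
    counts = labels.value_counts()
    metrics = sens_spec_ppv(adjusted[patient], adjusted[comparison],
                            int(counts[patient]), int(counts[comparison]))
    try:
        n_sel = len(select_features(fm, labels, alpha=cfg.alpha,
                                    test=cfg.test).selected) \
            if cfg.alpha < 1.0 else fm.n_features
    except ValueError:
        n_sel = 0
    return ValidationReport(tuple(classes), patient, res_loo.per_class,
                            res_sh.split_mean, res_sh.split_sd,
                            res_sh.loo_split_mean, res_sh.loo_split_sd,
                            adjusted, metrics["sensitivity"],
                            metrics["specificity"], metrics["ppv"],
                            n_sel, cfg, seed)


def iterative_three_way(fm: FeatureMatrix, labels=None, merge_pair: tuple = None,
                        cfg: ClassifierConfig | None = None) -> dict:
    """Iterative two-way strategy for three classes.

    Stage 1 discriminates the two ``merge_pair`` classes (pooled) from the
    third; stage 2 separates the pair with an independently selected
    feature set.  LOO is run through both stages per subject; returns
    per-class composite misclassification rates and the stage feature
    sets selected on the full cohort.
    """
    cfg = cfg or ClassifierConfig()
    labels = fm.labels if labels is None else pd.Series(labels, index=fm.X.index)
    classes = sorted(labels.dropna().unique())
    if len(classes) != 3:
        raise ValueError("need exactly three classes")
    if merge_pair is None or len(merge_pair) != 2 \
            or not set(merge_pair) <= set(classes):
        raise ValueError("merge_pair must name two of the three classes")
    pair = sorted(merge_pair)
    third = [c for c in classes if c not in pair][0]
    merged_name = "+".join(pair)

    stage1_labels = labels.map(lambda c: merged_name if c in pair else c)
    pair_ids = list(labels.index[labels.isin(pair)])

    preds = {}
    for sid in fm.X.index:
        rest = [i for i in fm.X.index if i != sid]
        fold1 = fit_group_model(fm.subset(rest), stage1_labels.loc[rest], cfg)
        p1 = fold1.predict(fm.subset([sid])).loc[sid]
        if p1 == third:
            preds[sid] = third
            continue
        rest_pair = [i for i in pair_ids if i != sid]
        fold2 = fit_group_model(fm.subset(rest_pair),
                                labels.loc[rest_pair], cfg)
        preds[sid] = fold2.predict(fm.subset([sid])).loc[sid]
    res = _rates(labels, pd.Series(preds))

    # stage feature sets on the full cohort (for reporting/independence)
    try:
        sel1_full = fit_group_model(fm, stage1_labels, cfg).selected
    except EmptySelectionError:
        sel1_full = np.array([], dtype=int)
    try:
        sel2_full = fit_group_model(fm.subset(pair_ids),
                                    labels.loc[pair_ids], cfg).selected
    except EmptySelectionError:
        sel2_full = np.array([], dtype=int)
    return {"per_class": res.per_class, "overall": res.overall,
            "stage1_features": np.asarray(sel1_full),
            "stage2_features": np.asarray(sel2_full),
            "merged": tuple(pair), "third": third}
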