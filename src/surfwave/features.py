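"""Feature assembly, nuisance-covariate control and univariate selection.

A subject's feature vector is the concatenation, in fixed region order, of
the wavelet scaling coefficients of its surface fields at a chosen
resolution level (level 2, 162 coefficients per region, by default).
Features may be residualized on age and sex by ordinary least squares
before a per-coefficient two-sample test selects the coefficients that
separate two diagnostic groups at a stringent threshold (p < 1e-7 by
default; with thresholds this extreme no further multiple-testing
correction is applied).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from .icosphere import vertex_count
from .wavelet import forward, scaling_at

log = logging.getLogger(__name__)

__all__ = ["SubjectRecord", "FeatureMatrix", "SelectionResult",
           "build_features", "residualize", "fit_residualizer",
           "FittedResidualizer", "select_features", "threshold_sweep"]

TESTS = ("welch", "student", "mannwhitney")


@dataclass
class SubjectRecord:
    """One subject: identifier, optional diagnosis, demographics and
    per-region surface data (icosphere fields or precomputed pyramids)."""

    id: str
    label: str | None = None
    age: float = 30.0
    sex: str = "M"
    fields: dict = dc_field(default_factory=dict)     # region -> field values
    pyramids: dict = dc_field(default_factory=dict)   # region -> WaveletPyramid

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError(f"subject {self.id}: age must be positive")


@dataclass(frozen=True)
class FeatureMatrix:
    """Subjects x features with provenance and covariates.

    ``X`` rows are subjects (indexed by id); ``provenance`` has one row per
    feature with (region, level, vertex); ``covariates`` holds age and sex;
    ``labels`` the known diagnoses (may contain None for unlabeled
    subjects).
    """

    X: pd.DataFrame
    provenance: pd.DataFrame
    covariates: pd.DataFrame
    labels: pd.Series

    def __post_init__(self):
        if len(self.provenance) != self.X.shape[1]:
            raise ValueError("provenance length must equal feature count")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_subjects(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, ids) -> "FeatureMatrix":
        """Row subset by subject ids (used by the cross-validation loops)."""
        return FeatureMatrix(self.X.loc[ids], self.provenance,
                             self.covariates.loc[ids], self.labels.loc[ids])


def build_features(cohort: list, regions: list, level: int = 2,
                   scheme: str = "linear_lifted") -> FeatureMatrix:
    """Concatenate per-region scaling coefficients into feature vectors.

    Every subject must provide every requested region either as a
    precomputed pyramid or as a field on an icosphere (transformed here).
    """
    n_per_region = vertex_count(level)
    rows, ids, ages, sexes, labels = [], [], [], [], []
    for rec in cohort:
        vec = []
        for region in regions:
            if region in rec.pyramids:
                pyr = rec.pyramids[region]
            elif region in rec.fields:
                pyr = forward(rec.fields[region], scheme=scheme)
            else:
                raise KeyError(
                    f"subject {rec.id!r} is missing region {region!r}")
            if pyr.finest_level < level:
                raise ValueError(
                    f"subject {rec.id!r}, region {region!r}: pyramid finest "
                    f"level {pyr.finest_level} < requested level {level}")
            vec.append(scaling_at(pyr, level))
        rows.append(np.concatenate(vec))
        ids.append(rec.id)
        ages.append(rec.age)
        sexes.append(rec.sex)
        labels.append(rec.label)
    prov = pd.DataFrame(
        [(r, level, v) for r in regions for v in range(n_per_region)],
        columns=["region", "level", "vertex"])
    x = pd.DataFrame(np.asarray(rows), index=pd.Index(ids, name="id"))
    cov = pd.DataFrame({"age": ages, "sex": sexes}, index=x.index)
    return FeatureMatrix(x, prov, cov, pd.Series(labels, index=x.index,
                                                 name="label"))


def _design_matrix(covariates: pd.DataFrame, use: tuple) -> np.ndarray:
    age = covariates["age"].to_numpy(dtype=float)
    sex = (covariates["sex"].astype(str) == "F").to_numpy(dtype=float)
    cols = [np.ones(len(covariates))]
    if "age" in use:
        cols.append(age)
    if "sex" in use:
        cols.append(sex)
    return np.column_stack(cols)


@dataclass(frozen=True)
class FittedResidualizer:
    """OLS fit of features on [1, age, sex], reusable on held-out subjects
    so cross-validation folds never refit nuisance effects on test data."""

    beta: np.ndarray
    used: tuple

    def transform(self, fm: FeatureMatrix) -> FeatureMatrix:
        design = _design_matrix(fm.covariates, self.used)
        resid = fm.X.to_numpy(dtype=float) - design @ self.beta
        return FeatureMatrix(pd.DataFrame(resid, index=fm.X.index,
                                          columns=fm.X.columns),
                             fm.provenance, fm.covariates, fm.labels)


def fit_residualizer(fm: FeatureMatrix) -> FittedResidualizer:
    """Fit the nuisance regression on a (training) cohort.

    Age enters linearly only; sex is coded M=0, F=1.  Covariates that make
    the design rank-deficient (e.g. sex in a single-sex cohort) are dropped
    with a logged warning.
    """
    if fm.n_subjects < 3:
        raise ValueError("residualization needs at least 3 subjects")
    use = []
    for name in ("age", "sex"):
        cand = _design_matrix(fm.covariates, tuple(use) + (name,))
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            use.append(name)
        else:
            log.warning("residualize: dropping rank-deficient covariate %r", name)
    design = _design_matrix(fm.covariates, tuple(use))
    beta, *_ = np.linalg.lstsq(design, fm.X.to_numpy(dtype=float), rcond=None)
    return FittedResidualizer(beta, tuple(use))


def residualize(fm: FeatureMatrix) -> FeatureMatrix:
    """Replace every feature by its OLS residual on [1, age, sex].

    Features orthogonal to the covariates are simply centered; constant
    features become all-zero.
    """
    return fit_residualizer(fm).transform(fm)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of per-feature two-group testing."""

    selected: np.ndarray     # feature indices with p < alpha, ascending
    pvalues: np.ndarray
    alpha: float
    groups: tuple            # the two label values tested

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def _two_sample_pvalues(a: np.ndarray, b: np.ndarray, test: str) -> np.ndarray:
    """Per-column p-values; zero-variance columns get the documented
    convention (p=1 if both groups constant and equal, p=0 if constant but
    different)."""
    with np.errstate(all="ignore"):
        if test == "welch":
            p = stats.ttest_ind(a, b, equal_var=False, axis=0).pvalue
        elif test == "student":
            p = stats.ttest_ind(a, b, equal_var=True, axis=0).pvalue
        elif test == "mannwhitney":
            p = stats.mannwhitneyu(a, b, axis=0).pvalue
        else:
            raise ValueError(f"unknown test {test!r} (use one of {TESTS})")
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        same = np.isclose(a[:, degenerate].mean(axis=0),
                          b[:, degenerate].mean(axis=0))
        p[degenerate] = np.where(same, 1.0, 0.0)
    return p


def select_features(fm: FeatureMatrix, labels=None, alpha: float = 1e-7,
                    test: str = "welch") -> SelectionResult:
    """Keep the features whose two-group test gives p < alpha."""
    labels = fm.labels if labels is None else pd.Series(labels, index=fm.X.index)
    values = labels.dropna()
    groups = sorted(values.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    x = fm.X.to_numpy(dtype=float)
    mask_a = (labels == groups[0]).to_numpy()
    mask_b = (labels == groups[1]).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    p = _two_sample_pvalues(x[mask_a], x[mask_b], test)
    selected = np.flatnonzero(p < alpha)
    return SelectionResult(selected, p, alpha, tuple(groups))


def threshold_sweep(fm: FeatureMatrix, labels=None, alphas=None,
                    config=None) -> pd.DataFrame:
    """LOO sensitivity/specificity and selection size per p-threshold.

    ``alphas`` must be sorted descending.  Thresholds at which some LOO
    training fold selects no feature get NaN sensitivity/specificity rather
    than raising.  Columns: alpha, n_selected, sensitivity, specificity.
    """
    from .validation import ClassifierConfig, EmptySelectionError, loo

    if alphas is None:
        alphas = [1e-2, 1e-4, 1e-7]
    alphas = list(alphas)
    if any(a1 < a2 for a1, a2 in zip(alphas, alphas[1:])):
        raise ValueError("alphas must be sorted descending")
    base = config or ClassifierConfig()
    labels = fm.labels if labels is None else pd.Series(labels, index=fm.X.index)
    groups = sorted(labels.dropna().unique())
    rows = []
    for alpha in alphas:
        n_sel = select_features(fm, labels, alpha=alpha, test=base.test).n_selected
        cfg = base.replace(alpha=alpha)
        try:
            res = loo(fm, labels, cfg)
            sens = 1.0 - res.per_class[groups[0]]
            spec = 1.0 - res.per_class[groups[1]]
        except EmptySelectionError:
            sens = spec = float("nan")
        rows.append({"alpha": alpha, "n_selected": n_sel,
                     "sensitivity": sens, "specificity": spec})
    return pd.DataFrame(rows)
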