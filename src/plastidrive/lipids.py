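"""Prediction of plastid inheritance strength from lipid levels.

A lipidomics experiment measured in several independent series is first
made comparable across series: within each series every lipid's levels
are log-transformed and centered on the median over the genotypes of
inheritance-strength class 1 (the common reference class present in all
series).  Series are then merged on the lipids measured in every series.

Inheritance strength (the ordinal class 1-5, treated as a Gaussian
response) is regressed on the merged lipid levels with LASSO (pure L1
penalty).  Generalisation is assessed by repeated leave-two-genotypes-out
cross-validation: in each of the repeated runs all replicate samples of
two randomly chosen genotypes are held out, the penalty is chosen on the
training genotypes by inner k-fold CV at the 1-SE rule, and cvR — the
Pearson correlation between actual and predicted strengths over the
pooled held-out samples — is recorded.  Lipids are ranked by avgW, the
mean absolute coefficient across runs; lipids with avgW above one
standard deviation of all avgW values are called predictive, and lipid
classes are tested for enrichment among predictive lipids with Fisher's
exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

__all__ = [
    "LipidMatrix",
    "SeriesNormalizer",
    "normalize_series",
    "merge_series",
    "LipidLassoPredictor",
    "LassoRunResult",
    "lasso_cv_run",
    "run_repeated",
    "select_predictive",
    "class_enrichment",
]


@dataclass
class LipidMatrix:
    """Samples x lipids level matrix with sample and lipid metadata.

    ``levels``: DataFrame, rows = samples (index = sample ids), columns =
    lipid ids; NaN marks a lipid not measured for that sample's series.
    ``samples``: DataFrame indexed like ``levels`` with columns
    ``genotype``, ``series``, ``replicate``, ``inheritance_class``.
    ``lipid_classes``: Series lipid id -> class label (MGDG, DGDG, ...).
    """

    levels: pd.DataFrame
    samples: pd.DataFrame
    lipid_classes: pd.Series
    normalized: bool = False
    dropped_lipids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.levels.index.equals(self.samples.index):
            raise ValueError("levels and samples indexes differ")
        required = {"genotype", "series", "replicate", "inheritance_class"}
        if required - set(self.samples.columns):
            raise ValueError(f"sample metadata missing {sorted(required - set(self.samples.columns))}")
        unknown = set(self.levels.columns) - set(self.lipid_classes.index)
        if unknown:
            raise ValueError(f"lipids without a class label: {sorted(unknown)[:5]} ...")

    @property
    def lipids(self) -> list[str]:
        return list(self.levels.columns)

    @classmethod
    def from_long_csv(cls, path) -> "LipidMatrix":
        """Long format: sample_id, genotype, series, replicate,
        inheritance_class, lipid_id, lipid_class, level."""
        df = pd.read_csv(path)
        levels = df.pivot_table(index="sample_id", columns="lipid_id", values="level")
        meta = (
            df[["sample_id", "genotype", "series", "replicate", "inheritance_class"]]
            .drop_duplicates("sample_id")
            .set_index("sample_id")
            .loc[levels.index]
        )
        classes = df[["lipid_id", "lipid_class"]].drop_duplicates("lipid_id").set_index("lipid_id")["lipid_class"]
        return cls(levels=levels, samples=meta, lipid_classes=classes)

    def to_long_frame(self) -> pd.DataFrame:
        long = (
            self.levels.stack()
            .rename("level")
            .rename_axis(["sample_id", "lipid_id"])
            .reset_index()
        )
        long = long.merge(self.samples, left_on="sample_id", right_index=True)
        long["lipid_class"] = long["lipid_id"].map(self.lipid_classes)
        return long


class SeriesNormalizer(BaseEstimator):
    """Per-series log transform and class-1 median centering.

    For every experimental series and every lipid, levels are
    log-transformed and the median over that series' class-1 samples is
    subtracted, making class 1 the common zero point across series.
    Stateless across calls (the centering medians are per-input by
    construction), so ``transform`` accepts an unnormalized
    :class:`LipidMatrix` directly.
    """

    def __init__(self, reference_class: int = 1):
        self.reference_class = reference_class

    def fit(self, matrix: LipidMatrix, y=None):
        return self

    def transform(self, matrix: LipidMatrix) -> LipidMatrix:
        if matrix.normalized:
            raise ValueError("matrix is already normalized")
        levels = matrix.levels.copy()
        bad = levels <= 0
        if bad.any().any():
            s = levels.stack()[lambda v: v <= 0]
            sample, lipid = s.index[0]
            raise ValueError(
                f"nonpositive level for sample {sample!r}, lipid {lipid!r}: cannot log"
            )
        logged = np.log(levels)
        out = logged.copy()
        for series, idx in matrix.samples.groupby("series").groups.items():
            sub = matrix.samples.loc[idx]
            ref_idx = sub.index[sub["inheritance_class"] == self.reference_class]
            if len(ref_idx) == 0:
                raise ValueError(
                    f"series {series!r} has no inheritance-class-"
                    f"{self.reference_class} genotype to center on"
                )
            medians = logged.loc[ref_idx].median(axis=0, skipna=True)
            out.loc[idx] = logged.loc[idx].sub(medians, axis=1)
        return replace(matrix, levels=out, normalized=True)

    def fit_transform(self, matrix: LipidMatrix, y=None) -> LipidMatrix:
        return self.fit(matrix).transform(matrix)


def normalize_series(matrix: LipidMatrix, reference_class: int = 1) -> LipidMatrix:
    """Functional wrapper over :class:`SeriesNormalizer`."""
    return SeriesNormalizer(reference_class=reference_class).fit_transform(matrix)


def merge_series(matrices) -> LipidMatrix:
    """Merge normalized series on the lipids present in all of them.

    ``matrices`` is a list of per-series :class:`LipidMatrix` objects (or
    a single multi-series matrix with NaN for unmeasured lipids).  Lipids
    lacking complete data in any series are dropped and recorded in
    ``dropped_lipids``.
    """
    if isinstance(matrices, LipidMatrix):
        matrices = [matrices]
    if not matrices:
        raise ValueError("no matrices to merge")
    if any(not m.normalized for m in matrices):
        raise ValueError("all series must be normalized before merging")
    levels = pd.concat([m.levels for m in matrices], axis=0)
    samples = pd.concat([m.samples for m in matrices], axis=0)
    if levels.index.duplicated().any():
        raise ValueError("duplicate sample ids across series")
    keep = []
    for lipid in levels.columns:
        complete = levels[lipid].notna().groupby(samples["series"]).all()
        if complete.all() and len(complete) > 0:
            keep.append(lipid)
    dropped = [c for c in levels.columns if c not in keep]
    if not keep:
        raise ValueError("no lipid measured in every series")
    classes = pd.concat([m.lipid_classes for m in matrices]).groupby(level=0).first()
    return LipidMatrix(
        levels=levels[keep],
        samples=samples,
        lipid_classes=classes.loc[keep],
        normalized=True,
        dropped_lipids=dropped,
    )


@dataclass
class LassoRunResult:
    """One leave-two-genotypes-out LASSO cross-validation run."""

    run_index: int
    holdout_genotypes: tuple
    alpha: float
    coef: np.ndarray
    intercept: float
    y_true: np.ndarray
    y_pred: np.ndarray
    cv_r: float  # NaN when held-out actuals are constant


def _alpha_1se(alphas: np.ndarray, mse_path: np.ndarray) -> float:
    """Largest penalty whose mean CV error is within one standard error
    of the minimum (the 1-SE rule)."""
    mean = mse_path.mean(axis=1)
    se = mse_path.std(axis=1, ddof=1) / np.sqrt(mse_path.shape[1])
    i_min = int(np.argmin(mean))
    ok = mean <= mean[i_min] + se[i_min]
    return float(alphas[ok].max())


def _single_run(
    X: np.ndarray,
    y: np.ndarray,
    genotypes: np.ndarray,
    run_index: int,
    rng: np.random.Generator,
    n_holdout: int,
    inner_cv: int,
    n_alphas: int,
    standardize: bool,
    alpha: float | None = None,
) -> LassoRunResult:
    uniq = np.unique(genotypes)
    held = tuple(rng.choice(uniq, size=n_holdout, replace=False))
    test = np.isin(genotypes, held)
    Xtr, ytr = X[~test], y[~test]
    Xte, yte = X[test], y[test]
    if standardize:
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
    else:
        mu = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
    Xtr_s = (Xtr - mu) / sd
    if alpha is None:
        folds = KFold(n_splits=inner_cv, shuffle=True,
                      random_state=int(rng.integers(0, 2**31 - 1)))
        cv_model = LassoCV(alphas=n_alphas, cv=folds, max_iter=50_000).fit(Xtr_s, ytr)
        alpha = _alpha_1se(cv_model.alphas_, cv_model.mse_path_)
    model = Lasso(alpha=alpha, max_iter=50_000).fit(Xtr_s, ytr)
    coef = model.coef_ / sd  # back to the original level scale
    intercept = float(model.intercept_ - (mu * coef).sum())
    y_pred = Xte @ coef + intercept
    if len(yte) >= 2 and np.var(yte) > 0 and np.var(y_pred) > 0:
        cv_r = float(stats.pearsonr(yte, y_pred)[0])
    else:
        cv_r = float("nan")
    return LassoRunResult(
        run_index=run_index,
        holdout_genotypes=held,
        alpha=alpha,
        coef=coef,
        intercept=intercept,
        y_true=yte,
        y_pred=y_pred,
        cv_r=cv_r,
    )


class LipidLassoPredictor(BaseEstimator, RegressorMixin):
    """Repeated leave-two-genotypes-out LASSO prediction of inheritance
    strength from lipid levels.

    Each of ``n_runs`` runs holds out all replicate samples of two
    randomly drawn genotypes, selects the L1 penalty on the remaining
    genotypes by inner ``inner_cv``-fold cross-validation at the 1-SE
    rule (Gaussian response), refits at that penalty, and predicts the
    held-out samples.  cvR is the Pearson correlation of actual versus
    predicted strengths over the pooled held-out replicates.

    Parameters
    ----------
    n_runs : number of cross-validation runs (default 100).
    n_holdout_genotypes : genotypes held out per run (default 2).
    inner_cv : inner CV folds for the penalty path (default 10).
    n_alphas : penalty-path resolution.
    standardize : z-score lipids on the training split before the L1 fit
        (coefficients are reported on the input scale).
    avg_weight : {"mean_abs", "abs_mean"} — avgW as mean of absolute
        per-run coefficients (default) or absolute value of the mean.
    sd_ddof : delta degrees of freedom for the avgW standard-deviation
        threshold (default 1, sample SD).
    random_state : seed for genotype draws and inner folds.

    Attributes
    ----------
    results_ : list of :class:`LassoRunResult`.
    coef_matrix_ : (n_runs, n_lipids) per-run coefficients.
    cv_r_ : (n_runs,) per-run cvR (NaN where undefined).
    avg_weights_ : avgW per lipid.
    weight_threshold_ : 1 SD of the avgW vector.
    predictive_mask_ : bool per lipid, avgW strictly above the threshold.
    mean_coef_ : signed mean coefficient per lipid (direction of the
        lipid's association with strength).
    """

    def __init__(
        self,
        n_runs: int = 100,
        n_holdout_genotypes: int = 2,
        inner_cv: int = 10,
        n_alphas: int = 100,
        standardize: bool = True,
        avg_weight: str = "mean_abs",
        sd_ddof: int = 1,
        random_state=None,
    ):
        self.n_runs = n_runs
        self.n_holdout_genotypes = n_holdout_genotypes
        self.inner_cv = inner_cv
        self.n_alphas = n_alphas
        self.standardize = standardize
        self.avg_weight = avg_weight
        self.sd_ddof = sd_ddof
        self.random_state = random_state

    def fit(self, X, y, genotypes=None):
        if genotypes is None:
            raise ValueError("genotypes labels are required (leave-genotypes-out CV)")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        genotypes = np.asarray(genotypes)
        if len(np.unique(genotypes)) < self.n_holdout_genotypes + 2:
            raise ValueError("too few genotypes for leave-two-out cross-validation")
        if self.avg_weight not in ("mean_abs", "abs_mean"):
            raise ValueError(f"unknown avg_weight {self.avg_weight!r}")
        rng = np.random.default_rng(self.random_state)
        self.results_ = [
            _single_run(
                X, y, genotypes, r, rng,
                self.n_holdout_genotypes, self.inner_cv, self.n_alphas,
                self.standardize,
            )
            for r in range(self.n_runs)
        ]
        self.coef_matrix_ = np.vstack([r.coef for r in self.results_])
        self.cv_r_ = np.array([r.cv_r for r in self.results_])
        if self.avg_weight == "mean_abs":
            self.avg_weights_ = np.abs(self.coef_matrix_).mean(axis=0)
        else:
            self.avg_weights_ = np.abs(self.coef_matrix_.mean(axis=0))
        self.mean_coef_ = self.coef_matrix_.mean(axis=0)
        self.weight_threshold_ = float(np.std(self.avg_weights_, ddof=self.sd_ddof))
        self.predictive_mask_ = self.avg_weights_ > self.weight_threshold_
        self.intercept_ = float(np.mean([r.intercept for r in self.results_]))
        return self

    def predict(self, X):
        """Predict with the run-averaged linear model."""
        X = np.asarray(X, dtype=float)
        return X @ self.mean_coef_ + self.intercept_


def lasso_cv_run(
    matrix: LipidMatrix,
    run_index: int = 0,
    n_holdout_genotypes: int = 2,
    inner_cv: int = 10,
    n_alphas: int = 100,
    standardize: bool = True,
    random_state=None,
    alpha: float | None = None,
) -> LassoRunResult:
    """One leave-two-genotypes-out run on a normalized, merged matrix.

    ``alpha`` forces a fixed penalty and skips the inner CV (an
    arbitrarily large value gives the all-zero null model)."""
    if not matrix.normalized:
        raise ValueError("matrix must be normalized and merged first")
    rng = np.random.default_rng(random_state)
    return _single_run(
        matrix.levels.to_numpy(),
        matrix.samples["inheritance_class"].to_numpy(dtype=float),
        matrix.samples["genotype"].to_numpy(),
        run_index, rng, n_holdout_genotypes, inner_cv, n_alphas, standardize,
        alpha=alpha,
    )


def run_repeated(
    matrix: LipidMatrix, n_runs: int = 100, random_state=None, **kwargs
) -> tuple[LipidLassoPredictor, pd.DataFrame]:
    """Fit the repeated-CV predictor and summarise the cvR distribution.

    Returns the fitted :class:`LipidLassoPredictor` and a histogram table
    of cvR counts in bins of width 0.1 over [-1, 1].
    """
    if not matrix.normalized:
        raise ValueError("matrix must be normalized and merged first")
    model = LipidLassoPredictor(n_runs=n_runs, random_state=random_state, **kwargs).fit(
        matrix.levels.to_numpy(),
        matrix.samples["inheritance_class"].to_numpy(dtype=float),
        genotypes=matrix.samples["genotype"].to_numpy(),
    )
    edges = np.round(np.arange(-1.0, 1.01, 0.1), 10)
    finite = model.cv_r_[np.isfinite(model.cv_r_)]
    counts, _ = np.histogram(finite, bins=edges)
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
    hist.attrs["n_undefined"] = int(np.isnan(model.cv_r_).sum())
    return model, hist


def select_predictive(model: LipidLassoPredictor, lipid_ids=None) -> pd.DataFrame:
    """Per-lipid report: avgW, signed mean coefficient, predictive flag.

    A lipid is predictive when its avgW exceeds one standard deviation of
    the avgW values of all lipids (strict inequality)."""
    n = len(model.avg_weights_)
    ids = list(lipid_ids) if lipid_ids is not None else [f"lipid{i}" for i in range(n)]
    report = pd.DataFrame(
        {
            "lipid_id": ids,
            "avgW": model.avg_weights_,
            "mean_coef": model.mean_coef_,
            "predictive": model.predictive_mask_,
        }
    )
    report.attrs["threshold"] = model.weight_threshold_
    return report


def class_enrichment(report: pd.DataFrame, lipid_classes: pd.Series) -> pd.DataFrame:
    """Fisher's exact enrichment of each lipid class among predictive
    lipids: 2x2 table (in class vs not) x (predictive vs not), two-sided
    p and sample odds ratio.  Classes absent from the report are skipped.
    """
    missing = [l for l in report["lipid_id"] if l not in lipid_classes.index]
    if missing:
        raise ValueError(f"lipids without class assignment: {missing[:5]}")
    classes = report["lipid_id"].map(lipid_classes)
    predictive = report["predictive"].to_numpy(dtype=bool)
    rows = []
    for cls in sorted(classes.unique()):
        in_class = (classes == cls).to_numpy()
        a = int(np.sum(in_class & predictive))
        b = int(np.sum(in_class & ~predictive))
        c = int(np.sum(~in_class & predictive))
        d = int(np.sum(~in_class & ~predictive))
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((cls, a + b, a, float(odds), float(p)))
    return pd.DataFrame(
        rows, columns=["lipid_class", "n_in_class", "n_predictive", "odds_ratio", "p"]
    )
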