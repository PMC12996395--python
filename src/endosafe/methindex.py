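"""Construction, selection and application of the methylation-based
endometrial-cancer index.

The recipe, applied to any case/control beta matrix:

1. stratified 70/30 train/test split (subject-grouped on request);
2. per-CpG linear models of beta on group, adjusted for age and total
   immune fraction (ic), with Benjamini-Hochberg FDR across tested CpGs;
3. group-wise regressions of beta on ic alone; the difference of the two
   intercepts estimates delta-beta at ic = 0, i.e. the methylation
   difference in a notional pure-epithelial tissue;
4. CpGs ranked by |delta-beta at ic = 0| (FDR-significant set by default);
5. a grid of penalised logistic classifiers over penalty mixing
   alpha in {0, 0.5, 1} (ridge / elastic net / lasso) and increasing
   feature counts, each evaluated on the held-out test set by AUC and
   calibration slope/intercept; the winner maximises AUC, then calibration
   closeness, then parsimony.

The resulting :class:`IndexModel` stores features, standardisation
parameters and coefficients, and scores new samples on the linear-predictor
(log-odds) scale; the same contract is reused by the expression index.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .io import BetaMatrix, CountMatrix, SampleSheet

logger = logging.getLogger("endosafe")

DEFAULT_ALPHAS = (0.0, 0.5, 1.0)
#: feature-count ladder: 100, 500, then 1000-step increments
DEFAULT_TOP_N = 30000
CV_PATH_LENGTH = 20
CV_FOLDS = 5

MODEL_SCHEMA_VERSION = 1
MIN_FEATURE_OVERLAP = 0.9

#: test-AUC differences below this are treated as ties during model
#: selection and resolved on calibration; one Hanley-McNeil standard error
#: of an AUC near 0.95-0.98 on a 30-versus-30 test set
AUC_TIE_TOLERANCE = 0.02


class IndexError_(ValueError):
    pass


def default_feature_counts(top_n: int = DEFAULT_TOP_N) -> tuple[int, ...]:
    """100, 500, 1000 and then every 1000 up to ``top_n``."""
    counts = [100, 500] + list(range(1000, top_n + 1, 1000))
    return tuple(c for c in counts if c <= top_n)


@dataclass
class ModelMetrics:
    auc: float
    calibration_slope: float
    calibration_intercept: float


@dataclass
class SplitAssignment:
    assignment: pd.Series  # sample_id -> "train" / "test"
    stratify_by: str = "group"
    group_by: str | None = None

    @property
    def train_ids(self) -> list[str]:
        return list(self.assignment.index[self.assignment == "train"])

    @property
    def test_ids(self) -> list[str]:
        return list(self.assignment.index[self.assignment == "test"])


@dataclass
class IndexModel:
    """A trained penalised-logistic cancer index."""

    feature_ids: list[str]
    means: np.ndarray
    sds: np.ndarray
    coefficients: np.ndarray
    intercept: float
    alpha: float
    penalty_strength: float
    n_features_requested: int
    train_metrics: ModelMetrics | None = None
    test_metrics: ModelMetrics | None = None
    positive_label: str = "case"

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        k = len(self.feature_ids)
        if not (len(self.means) == len(self.sds) == len(self.coefficients) == k):
            raise IndexError_("inconsistent model dimensions")
        if (self.sds <= 0).any():
            raise IndexError_("standardisation sds must be positive")
        if not 0 <= self.alpha <= 1:
            raise IndexError_("alpha must lie in [0, 1]")

    @property
    def nonzero_features(self) -> list[str]:
        return [f for f, w in zip(self.feature_ids, self.coefficients) if w != 0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "feature_ids": list(self.feature_ids),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "alpha": self.alpha,
            "penalty_strength": self.penalty_strength,
            "n_features_requested": self.n_features_requested,
            "positive_label": self.positive_label,
            "train_metrics": asdict(self.train_metrics) if self.train_metrics else None,
            "test_metrics": asdict(self.test_metrics) if self.test_metrics else None,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "IndexModel":
        raw = json.loads(Path(path).read_text())
        if raw.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise IndexError_("unknown model schema version")
        tm = raw.get("train_metrics")
        sm_ = raw.get("test_metrics")
        return cls(
            feature_ids=raw["feature_ids"], means=raw["means"], sds=raw["sds"],
            coefficients=raw["coefficients"], intercept=raw["intercept"],
            alpha=raw["alpha"], penalty_strength=raw["penalty_strength"],
            n_features_requested=raw["n_features_requested"],
            positive_label=raw.get("positive_label", "case"),
            train_metrics=ModelMetrics(**tm) if tm else None,
            test_metrics=ModelMetrics(**sm_) if sm_ else None,
        )


def split_cohort(sheet: SampleSheet, train_fraction: float = 0.7,
                 group_by_subject: bool = True, seed: int = 0
                 ) -> SplitAssignment:
    """Label-stratified train/test split, keeping subjects together.

    Within each class, subjects are shuffled and assigned to the training
    set until its share of the class reaches ``train_fraction``.
    """
    meta = sheet.data
    labels = meta["group"].to_numpy()
    for lab in np.unique(labels):
        if (labels == lab).sum() < 2:
            raise IndexError_(f"class {lab!r} has < 2 samples")
    rng = np.random.default_rng(seed)
    assign = pd.Series("test", index=meta["sample_id"].to_numpy(), dtype=object)
    for lab in np.unique(labels):
        sub = meta[meta["group"] == lab]
        if group_by_subject:
            units = [g["sample_id"].tolist()
                     for _, g in sub.groupby("subject_id", sort=True)]
        else:
            units = [[s] for s in sub["sample_id"]]
        order = rng.permutation(len(units))
        target = train_fraction * len(sub)
        placed = 0
        for ui in order:
            if placed >= target:
                break
            for sid in units[ui]:
                assign[sid] = "train"
            placed += len(units[ui])
    split = SplitAssignment(assignment=assign,
                            group_by="subject_id" if group_by_subject else None)
    for part in (split.train_ids, split.test_ids):
        part_labels = set(meta.set_index("sample_id").loc[part, "group"])
        if part_labels != set(np.unique(labels)):
            raise IndexError_("a class is absent from one side of the split")
    return split


def _design(sheet: SampleSheet, props, sample_ids: Sequence[str]
            ) -> tuple[np.ndarray, np.ndarray]:
    meta = sheet.aligned_to(sample_ids)
    if meta["age"].isna().any():
        raise IndexError_("age missing for some samples")
    group = (meta["group"].isin(["case", "mifepristone"])).to_numpy(dtype=float)
    age = meta["age"].to_numpy(dtype=float)
    ic = props.ic.loc[list(sample_ids)].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(sample_ids)), group, age, ic])
    return X, group


def fit_cpg_adjusted_models(betas: BetaMatrix, sheet: SampleSheet, props
                            ) -> pd.DataFrame:
    """Per-CpG OLS of beta on (group, age, ic); two-sided t-test on the
    group coefficient; BH q across all tested CpGs.

    Returns a DataFrame with columns cpg_id, group_coefficient, p_value,
    q_value, flagged (constant CpGs get p = 1 and a flag).
    """
    samples = betas.sample_ids
    X, _ = _design(sheet, props, samples)
    Y = betas.values.to_numpy(dtype=float).T  # n x G
    n, k = X.shape
    if n <= k:
        raise IndexError_("need more samples than regression parameters")
    XtX_inv = np.linalg.pinv(X.T @ X)  # tolerant of degenerate toy designs
    B = XtX_inv @ X.T @ Y  # k x G
    resid = Y - X @ B
    dof = n - k
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    coef = B[1]
    constant = Y.std(axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, coef / se, 0.0)
    from scipy import stats as sps
    p = 2 * sps.t.sf(np.abs(tval), dof)
    p[constant | (se == 0)] = 1.0
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({
        "cpg_id": betas.feature_ids,
        "group_coefficient": coef,
        "p_value": p,
        "q_value": q,
        "flagged": constant,
    })


def estimate_delta_beta_ic0(betas: BetaMatrix, sheet: SampleSheet, props
                            ) -> pd.DataFrame:
    """Delta-beta at ic = 0: per CpG, regress beta on ic within cases and
    within controls separately; report the intercept difference.

    This estimates the case/control methylation difference in an
    immune-free (epithelial-enriched) tissue.  Requires ic to vary within
    both groups.
    """
    samples = betas.sample_ids
    meta = sheet.aligned_to(samples)
    group = meta["group"].isin(["case", "mifepristone"]).to_numpy()
    ic = props.ic.loc[samples].to_numpy(dtype=float)
    Y = betas.values.to_numpy(dtype=float)  # G x n

    intercepts = {}
    for name, mask in (("case", group), ("control", ~group)):
        if mask.sum() < 3:
            raise IndexError_(f"group {name!r} has < 3 samples")
        x = ic[mask]
        if np.ptp(x) == 0:
            raise IndexError_(f"ic constant within group {name!r}; "
                              "intercept at ic = 0 undefined")
        y = Y[:, mask]
        xc = x - x.mean()
        slope = (y @ xc) / (xc @ xc)
        intercepts[name] = y.mean(axis=1) - slope * x.mean()
    delta = intercepts["case"] - intercepts["control"]
    return pd.DataFrame({"cpg_id": betas.feature_ids,
                         "delta_beta_ic0": delta})


def rank_and_select_cpgs(records: pd.DataFrame, top_n: int = DEFAULT_TOP_N,
                         require_fdr: bool = True, fdr_threshold: float = 0.05
                         ) -> list[str]:
    """Rank CpGs by |delta-beta at ic = 0| (descending, ties broken by id)
    and return the top ``top_n``, optionally restricted to FDR-significant
    CpGs first."""
    df = records.copy()
    if "flagged" in df.columns:
        df = df[~df["flagged"].astype(bool)]
    if require_fdr:
        if "q_value" not in df.columns:
            raise IndexError_("require_fdr needs a q_value column")
        df = df[df["q_value"] < fdr_threshold]
    df = df.dropna(subset=["delta_beta_ic0"])
    df = df.assign(_abs=df["delta_beta_ic0"].abs())
    df = df.sort_values(["_abs", "cpg_id"], ascending=[False, True],
                        kind="mergesort")
    if top_n > len(df):
        logger.warning("top_n=%d exceeds %d available CpGs; returning all",
                       top_n, len(df))
    return df["cpg_id"].head(top_n).tolist()


def train_penalized_classifier(X: pd.DataFrame, labels: Sequence[str],
                               alpha: float = 0.0, n_folds: int = CV_FOLDS,
                               seed: int = 0,
                               penalty_selection: str = "min",
                               positive_label: str = "case") -> IndexModel:
    """Penalised logistic regression (feature x sample input).

    Features are standardised internally; zero-variance features are dropped
    with a warning.  Penalty strength is chosen by ``n_folds``-fold
    stratified cross-validated deviance over a logarithmic path;
    ``penalty_selection='1se'`` (the glmnet reporting convention) takes the
    strongest penalty within one standard error of the best cross-validated
    deviance, ``'min'`` the best itself.
    """
    y = np.asarray([1 if l == positive_label else 0 for l in labels])
    if len(np.unique(y)) < 2 or y.sum() < 2 or (1 - y).sum() < 2:
        raise IndexError_("need >= 2 samples per class")
    M = X.to_numpy(dtype=float).T  # n x p
    feature_ids = list(X.index)
    sds = M.std(axis=0, ddof=0)
    keep = sds > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance features", int((~keep).sum()))
        M = M[:, keep]
        feature_ids = [f for f, k in zip(feature_ids, keep) if k]
        sds = sds[keep]
    means = M.mean(axis=0)
    Z = (M - means) / sds

    Cs = np.logspace(-3, 3, CV_PATH_LENGTH)
    cv = StratifiedKFold(n_splits=min(n_folds, int(y.sum()), int((1 - y).sum())),
                         shuffle=True, random_state=seed)
    clf = LogisticRegressionCV(
        Cs=Cs, cv=cv, penalty="elasticnet", solver="saga",
        l1_ratios=[alpha], scoring="neg_log_loss", max_iter=1000,
        tol=1e-3, random_state=seed, n_jobs=1,
    )
    clf.fit(Z, y)
    chosen_C = float(clf.C_[0])
    if penalty_selection == "1se":
        scores = clf.scores_[1][:, :, 0] if clf.scores_[1].ndim == 3 \
            else clf.scores_[1]  # folds x Cs, neg log loss
        mean = scores.mean(axis=0)
        se = scores.std(axis=0, ddof=1) / np.sqrt(scores.shape[0])
        best = int(np.argmax(mean))
        eligible = np.nonzero(mean >= mean[best] - se[best])[0]
        one_se_C = float(Cs[eligible.min()])  # smallest C = strongest penalty
        if one_se_C != chosen_C:
            chosen_C = one_se_C
            refit = LogisticRegression(
                C=chosen_C, penalty="elasticnet", solver="saga",
                l1_ratio=alpha, max_iter=5000, tol=1e-6, random_state=seed)
            refit.fit(Z, y)
            clf.coef_, clf.intercept_ = refit.coef_, refit.intercept_
    elif penalty_selection != "min":
        raise IndexError_("penalty_selection must be 'min' or '1se'")
    return IndexModel(
        feature_ids=feature_ids, means=means, sds=sds,
        coefficients=clf.coef_.ravel(), intercept=float(clf.intercept_[0]),
        alpha=alpha, penalty_strength=float(1.0 / chosen_C),
        n_features_requested=len(feature_ids), positive_label=positive_label,
    )


def compute_auc(scores: Sequence[float], labels: Sequence[str],
                positive_label: str = "case") -> float:
    """Mann-Whitney concordance; tied scores count 0.5."""
    from scipy.stats import rankdata

    y = np.asarray([1 if l == positive_label else 0 for l in labels])
    s = np.asarray(scores, dtype=float)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise IndexError_("AUC needs both classes present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def compute_calibration(predicted_probabilities: Sequence[float],
                        labels: Sequence[str],
                        positive_label: str = "case"
                        ) -> tuple[float, float]:
    """Calibration slope and intercept: ML logistic regression of outcomes
    on logit(p); (1, 0) is perfect calibration."""
    p = np.asarray(predicted_probabilities, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise IndexError_("probabilities must lie strictly in (0, 1)")
    y = np.asarray([1 if l == positive_label else 0 for l in labels])
    lp = logit(p)
    if np.ptp(lp) == 0:
        raise IndexError_("logit(p) constant across samples; "
                          "calibration slope undefined")
    X = sm.add_constant(lp)
    with np.errstate(all="ignore"):
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    intercept, slope = fit.params
    return float(slope), float(intercept)


def select_model_over_grid(X: pd.DataFrame, labels: pd.Series,
                           split: SplitAssignment,
                           ranked_features: Sequence[str],
                           alphas: Sequence[float] = DEFAULT_ALPHAS,
                           feature_counts: Sequence[int] | None = None,
                           seed: int = 0,
                           positive_label: str = "case") -> IndexModel:
    """Grid search over (penalty mixing, feature count).

    Each candidate is trained on the training split with the first ``count``
    ranked features and evaluated on the held-out test split.  Selection is
    by test AUC first, but AUC differences below ``AUC_TIE_TOLERANCE`` are
    treated as ties (a handful of discordant test pairs is not a meaningful
    difference); practical ties compete on calibration closeness
    |slope - 1| + |intercept|, then smaller feature count, then smaller
    alpha.  A divergent calibration fit (perfectly separated test scores)
    counts as infinitely far from calibrated.
    """
    if feature_counts is None:
        feature_counts = default_feature_counts()
    usable = [c for c in feature_counts if c <= len(ranked_features)]
    skipped = [c for c in feature_counts if c > len(ranked_features)]
    if skipped:
        logger.warning("skipping feature counts beyond %d ranked features: %s",
                       len(ranked_features), skipped)
    if not usable or not alphas:
        raise IndexError_("empty model grid")

    train_ids, test_ids = split.train_ids, split.test_ids
    y_train = labels.loc[train_ids]
    y_test = labels.loc[test_ids]

    candidates = []
    for count in sorted(usable):
        feats = list(ranked_features[:count])
        X_train = X.loc[feats, train_ids]
        for alpha in sorted(alphas):
            model = train_penalized_classifier(
                X_train, y_train.tolist(), alpha=alpha, seed=seed,
                positive_label=positive_label,
            )
            model.n_features_requested = count
            model.train_metrics = evaluate_index(model, X, y_train, train_ids,
                                                 positive_label)
            model.test_metrics = evaluate_index(model, X, y_test, test_ids,
                                                positive_label)
            candidates.append(model)
            m = model.test_metrics
            logger.debug("grid alpha=%.1f count=%d auc=%.4f slope=%.3f",
                         alpha, count, m.auc, m.calibration_slope)

    def calib_distance(m: ModelMetrics) -> float:
        d = abs(m.calibration_slope - 1) + abs(m.calibration_intercept)
        return d if np.isfinite(d) else np.inf

    best_auc = max(c.test_metrics.auc for c in candidates)
    finalists = [c for c in candidates
                 if c.test_metrics.auc >= best_auc - AUC_TIE_TOLERANCE]
    finalists.sort(key=lambda c: (calib_distance(c.test_metrics),
                                  c.n_features_requested, c.alpha))
    return finalists[0]


def build_methylation_index(betas: BetaMatrix, sheet: SampleSheet, props,
                            train_fraction: float = 0.7,
                            alphas: Sequence[float] = DEFAULT_ALPHAS,
                            feature_counts: Sequence[int] | None = None,
                            top_n: int = DEFAULT_TOP_N,
                            require_fdr: bool = True,
                            seed: int = 0) -> tuple[IndexModel, pd.DataFrame,
                                                    SplitAssignment]:
    """End-to-end index construction on a case/control cohort.

    Splits the cohort, fits the adjusted per-CpG models and the group-wise
    ic regressions on the training split only, ranks CpGs, and selects the
    final classifier over the (alpha, feature count) grid by held-out AUC
    and calibration.  Returns (model, per-CpG records, split).
    """
    split = split_cohort(sheet, train_fraction, group_by_subject=True,
                         seed=seed)
    train_betas = BetaMatrix(betas.values[split.train_ids])
    train_sheet = SampleSheet(
        sheet.data[sheet.data["sample_id"].isin(split.train_ids)].copy())
    dm = fit_cpg_adjusted_models(train_betas, train_sheet, props)
    db = estimate_delta_beta_ic0(train_betas, train_sheet, props)
    records = dm.merge(db, on="cpg_id")
    ranked = rank_and_select_cpgs(records, top_n=top_n,
                                  require_fdr=require_fdr)
    labels = sheet.indexed()["group"]
    model = select_model_over_grid(betas.values, labels, split, ranked,
                                   alphas=alphas,
                                   feature_counts=feature_counts, seed=seed)
    return model, records, split


def evaluate_index(model: IndexModel, X: pd.DataFrame, labels: pd.Series,
                   sample_ids: Sequence[str],
                   positive_label: str = "case") -> ModelMetrics:
    """AUC and calibration of a model on the given samples of X."""
    scores = _score_frame(model, X[list(sample_ids)])
    labs = labels.loc[list(sample_ids)].tolist()
    auc = compute_auc(scores.to_numpy(), labs, positive_label)
    prob = np.clip(expit(scores.to_numpy()), 1e-12, 1 - 1e-12)
    try:
        slope, intercept = compute_calibration(prob, labs, positive_label)
    except IndexError_:
        slope, intercept = np.nan, np.nan
    return ModelMetrics(auc=auc, calibration_slope=slope,
                        calibration_intercept=intercept)


def _score_frame(model: IndexModel, X: pd.DataFrame) -> pd.Series:
    present = [f for f in model.feature_ids if f in X.index]
    frac = len(present) / len(model.feature_ids)
    if frac < MIN_FEATURE_OVERLAP:
        raise IndexError_(
            f"only {frac:.0%} of model features present "
            f"(need >= {MIN_FEATURE_OVERLAP:.0%})"
        )
    if frac < 1.0:
        logger.warning("imputing %d missing model features at their stored "
                       "means", len(model.feature_ids) - len(present))
    idx = {f: i for i, f in enumerate(model.feature_ids)}
    Z = np.zeros((X.shape[1], len(model.feature_ids)))
    rows = [idx[f] for f in present]
    vals = X.loc[present].to_numpy(dtype=float).T  # n x present
    Z[:, rows] = (vals - model.means[rows]) / model.sds[rows]
    scores = model.intercept + Z @ model.coefficients
    return pd.Series(scores, index=list(X.columns), name="index_score")


def apply_index(model: IndexModel, matrix: BetaMatrix | CountMatrix | pd.DataFrame
                ) -> pd.Series:
    """Score samples on the linear-predictor (log-odds) scale.

    Missing model features (up to 10%) are imputed at their stored mean and
    therefore contribute zero after standardisation.
    """
    X = matrix if isinstance(matrix, pd.DataFrame) else matrix.values
    return _score_frame(model, X)
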