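"""RNA-seq endometrial-cancer index and the expression-level analyses
around it.

Counts are collapsed from transcripts to gene symbols, filtered on a
minimum-count rule, normalised with median-of-ratios size factors and
transformed to log2(n/s + 1).  Differential expression uses a
negative-binomial GLM per gene with a Wald test on the group coefficient —
a deliberately plain estimator (method-of-moments dispersion, no shrinkage
or independent filtering), since the index recipe, not the DE machinery, is
the point here.  Significant genes feed a single elastic-net logistic fit
whose nonzero-coefficient genes form the index; training and scoring reuse
the :class:`~endosafe.methindex.IndexModel` contract.

Also here: mean-z gene-set shift scores and the anchored correlation
signature rule (genes with Pearson r > threshold to any anchor gene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, SampleSheet
from .methindex import IndexModel, train_penalized_classifier

logger = logging.getLogger("endosafe")

DE_P_THRESHOLD = 0.01
DISPERSION_FLOOR = 1e-8
CORRELATION_R_THRESHOLD = 0.75
ELASTIC_NET_ALPHA = 0.5


class ExpressionError(ValueError):
    pass


@dataclass
class NormalizedExpression:
    """log2(count / size_factor + 1) values plus the size factors used."""

    values: pd.DataFrame  # gene x sample
    size_factors: pd.Series  # per sample, > 0

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ExpressionError("size factors must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def collapse_to_gene_symbols(counts: CountMatrix, mapping: pd.DataFrame
                             ) -> CountMatrix:
    """Sum transcript counts per gene symbol.

    ``mapping`` needs columns ``transcript_id`` and ``gene_id`` and must
    cover at least 90% of the matrix features; unmapped transcripts are
    dropped with a logged count.
    """
    if mapping.empty:
        raise ExpressionError("empty transcript-to-gene mapping")
    m = mapping.set_index("transcript_id")["gene_id"]
    present = counts.values.index.intersection(m.index)
    coverage = len(present) / counts.shape[0]
    if coverage < 0.9:
        raise ExpressionError(
            f"mapping covers only {coverage:.0%} of features (need >= 90%)"
        )
    dropped = counts.shape[0] - len(present)
    if dropped:
        logger.info("dropping %d unmapped transcripts", dropped)
    df = counts.values.loc[present]
    collapsed = df.groupby(m.loc[present].to_numpy()).sum()
    collapsed.index.name = counts.values.index.name
    return CountMatrix(collapsed.astype(np.int64))


def filter_low_counts(counts: CountMatrix, min_count: int = 10,
                      min_fraction: float = 0.8, strict: bool = True
                      ) -> CountMatrix:
    """Keep genes expressed (count >= min_count) in enough samples.

    ``strict=True`` requires the expressed fraction to exceed
    ``min_fraction`` (the tumour-cohort rule: at least 10 counts in more
    than 80% of samples); ``strict=False`` requires >=, matching the trial
    rule of at least one count in 80% or more of samples.
    """
    if not 0 < min_fraction <= 1:
        raise ExpressionError("min_fraction must lie in (0, 1]")
    frac = (counts.values >= min_count).mean(axis=1)
    keep = frac > min_fraction if strict else frac >= min_fraction
    if not keep.any():
        raise ExpressionError("count filter removed every gene")
    return CountMatrix(counts.values.loc[keep])


def median_of_ratios_size_factors(counts: CountMatrix) -> pd.Series:
    """Per-sample median ratio of counts to per-gene geometric means.

    Genes containing any zero are excluded from the reference set (their
    geometric mean would vanish)."""
    arr = counts.values.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=1)
    if not all_positive.any():
        raise ExpressionError("no gene has nonzero counts in every sample "
                              "(empty size-factor reference set)")
    ref = arr[all_positive]
    log_geo_mean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geo_mean[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.sample_ids, name="size_factor")


def normalize_log2(counts: CountMatrix, size_factors: pd.Series
                   ) -> NormalizedExpression:
    """x_gj = log2(count_gj / s_j + 1)."""
    sf = size_factors.loc[counts.sample_ids].to_numpy(dtype=float)
    vals = np.log2(counts.values.to_numpy(dtype=float) / sf[None, :] + 1.0)
    return NormalizedExpression(
        values=pd.DataFrame(vals, index=counts.feature_ids,
                            columns=counts.sample_ids),
        size_factors=size_factors.loc[counts.sample_ids],
    )


def _nb_irls(y: np.ndarray, group: np.ndarray, offset: np.ndarray,
             alpha: np.ndarray, n_iter: int = 25
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised IRLS for per-gene NB GLMs with design (1, group).

    y: genes x samples, alpha: per-gene dispersions.  Returns (b0, b1, se1).
    """
    G, n = y.shape
    X = np.column_stack([np.ones(n), group])  # shared design
    # init from group means of offset-corrected counts
    adj = y / np.exp(offset)[None, :]
    mean1 = adj[:, group == 1].mean(axis=1)
    mean0 = adj[:, group == 0].mean(axis=1)
    b0 = np.log(np.maximum(mean0, 1e-8))
    b1 = np.log(np.maximum(mean1, 1e-8)) - b0
    for _ in range(n_iter):
        eta = b0[:, None] + np.outer(b1, group) + offset[None, :]
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + alpha[:, None] * mu)  # NB working weights
        z = eta - offset[None, :] + (y - mu) / mu
        # per-gene 2x2 weighted normal equations, solved in closed form
        s00 = w.sum(axis=1)
        s01 = w @ group
        s11 = w @ (group ** 2)
        t0 = (w * z).sum(axis=1)
        t1 = (w * z) @ group
        det = s00 * s11 - s01 ** 2
        det = np.where(det <= 0, np.nan, det)
        new_b0 = (s11 * t0 - s01 * t1) / det
        new_b1 = (s00 * t1 - s01 * t0) / det
        move = np.nanmax(np.abs(new_b0 - b0) + np.abs(new_b1 - b1))
        b0 = np.where(np.isfinite(new_b0), new_b0, b0)
        b1 = np.where(np.isfinite(new_b1), new_b1, b1)
        if move < 1e-10:
            break
    eta = b0[:, None] + np.outer(b1, group) + offset[None, :]
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + alpha[:, None] * mu)
    s00 = w.sum(axis=1)
    s01 = w @ group
    s11 = w @ (group ** 2)
    det = s00 * s11 - s01 ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.sqrt(s00 / det)
    return b0, b1, se1


def nb_wald_de_test(counts: CountMatrix, sheet: SampleSheet,
                    min_count: int = 10, min_fraction: float = 0.8,
                    strict: bool = True, p_threshold: float = DE_P_THRESHOLD
                    ) -> pd.DataFrame:
    """Negative-binomial Wald differential expression, case versus control.

    Per gene: NB GLM with log link and log-size-factor offsets; gene-wise
    dispersion by method of moments on normalized counts (floored at 1e-8);
    Wald test on the group coefficient; BH q across tested genes.
    ``significant`` marks genes at raw p below ``p_threshold``.
    """
    meta = sheet.aligned_to(counts.sample_ids)
    group = meta["group"].isin(["case", "mifepristone"]).to_numpy(dtype=float)
    if group.sum() < 3 or (1 - group).sum() < 3:
        raise ExpressionError("need >= 3 samples per group")

    filtered = filter_low_counts(counts, min_count, min_fraction, strict)
    sf = median_of_ratios_size_factors(filtered)
    s = sf.to_numpy(dtype=float)
    y = filtered.values.to_numpy(dtype=float)
    norm = y / s[None, :]

    # method-of-moments dispersion, pooled over the two groups
    disp_terms = []
    for g in (0.0, 1.0):
        m = norm[:, group == g]
        mean = m.mean(axis=1)
        var = m.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            disp_terms.append((var - mean) / np.maximum(mean, 1e-12) ** 2)
    alpha = np.nanmean(np.vstack(disp_terms), axis=0)
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    b0, b1, se1 = _nb_irls(y, group, np.log(s), alpha)
    log2fc = b1 / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se1 > 0, b1 / se1, 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    # constant genes: no information on the group effect
    constant = (y == y[:, [0]]).all(axis=1)
    p = np.where(constant | ~np.isfinite(p), 1.0, p)
    log2fc = np.where(constant, 0.0, log2fc)
    from statsmodels.stats.multitest import multipletests
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({
        "gene_id": filtered.feature_ids,
        "base_mean": norm.mean(axis=1),
        "log2_fold_change": log2fc,
        "standard_error": se1 / np.log(2.0),
        "p_value": p,
        "q_value": q,
        "significant": p < p_threshold,
    })


def train_expression_index(normalized: NormalizedExpression,
                           labels: pd.Series, significant_genes: list[str],
                           alpha: float = ELASTIC_NET_ALPHA, seed: int = 0,
                           positive_label: str = "case") -> IndexModel:
    """Single elastic-net logistic fit on the significant genes (no grid).

    The retained genes of the index are the nonzero-coefficient features;
    the model is scored through the shared IndexModel contract.
    """
    genes = [g for g in significant_genes if g in normalized.values.index]
    if not genes:
        raise ExpressionError("no significant genes present in the matrix")
    X = normalized.values.loc[genes]
    model = train_penalized_classifier(X, labels.loc[list(X.columns)].tolist(),
                                       alpha=alpha, seed=seed,
                                       positive_label=positive_label)
    logger.info("expression index retains %d of %d genes",
                len(model.nonzero_features), len(genes))
    return model


def geneset_score(normalized: NormalizedExpression,
                  gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Mean per-gene z-score within each set, per sample.

    Genes are z-scored across samples; a sample's set score is the mean z
    over member genes.  Zero-variance genes are excluded with a warning;
    a set matching no genes is an error.
    """
    if normalized.values.shape[1] < 2:
        raise ExpressionError("gene-set scores need >= 2 samples")
    vals = normalized.values
    sds = vals.std(axis=1, ddof=0)
    zero_var = sds == 0
    if zero_var.any():
        logger.warning("excluding %d zero-variance genes from gene-set "
                       "scores", int(zero_var.sum()))
    z = vals.loc[~zero_var].sub(vals.loc[~zero_var].mean(axis=1), axis=0) \
            .div(sds[~zero_var], axis=0)
    rows = []
    for name, members in gene_sets.items():
        matched = [g for g in members if g in z.index]
        missing = len(members) - len(matched)
        if not matched:
            raise ExpressionError(f"gene set {name!r} matches no genes")
        if missing:
            logger.warning("gene set %r: %d member genes absent", name, missing)
        score = z.loc[matched].mean(axis=0)
        for sid, val in score.items():
            rows.append({"sample_id": sid, "set_name": name,
                         "score": float(val)})
    return pd.DataFrame(rows)


def correlation_signature(expression: NormalizedExpression,
                          anchor_genes: list[str],
                          r_threshold: float = CORRELATION_R_THRESHOLD
                          ) -> list[str]:
    """Genes whose maximum Pearson r with any anchor gene strictly exceeds
    ``r_threshold``; anchors themselves are excluded from the output."""
    vals = expression.values
    missing = [a for a in anchor_genes if a not in vals.index]
    if missing:
        raise ExpressionError(f"anchor genes absent: {missing}")
    others = vals.index.difference(anchor_genes)
    A = vals.loc[anchor_genes].to_numpy(dtype=float)
    B = vals.loc[others].to_numpy(dtype=float)

    def _std_rows(M):
        c = M - M.mean(axis=1, keepdims=True)
        s = np.sqrt((c ** 2).sum(axis=1))
        s[s == 0] = np.inf  # zero-variance rows correlate with nothing
        return c / s[:, None]

    r = np.clip(_std_rows(B) @ _std_rows(A).T, -1.0, 1.0)  # others x anchors
    rmax = r.max(axis=1)
    return sorted(others[rmax > r_threshold])
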