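"""Paired pre/post and between-arm statistics for the two-arm biopsy trial.

The workhorse tests are the Wilcoxon signed-rank test (within-arm, baseline
versus end of treatment) and the Mann-Whitney rank-sum test (between arms,
on the within-subject change from baseline).  Both carry exact branches:
with no ties and small n the full null distribution is computed by dynamic
programming over integer ranks, so small-sample p-values — e.g. the minimal
two-sided paired p of 2/2^8 = 0.0078125 at eight pairs — are exact rather
than normal approximations.

Also here: covariate residualisation of index scores (age and fibroblast
fraction confound both methylation and expression indices), the SNP-probe
sample identity check, and the end-to-end trial analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix, CountMatrix, SampleSheet

logger = logging.getLogger("endosafe")

EXACT_PAIRED_MAX_N = 25
EXACT_UNPAIRED_MAX_PRODUCT = 400

SNP_HOMOZYGOUS_LOW = 0.25
SNP_HOMOZYGOUS_HIGH = 0.75
SNP_PASS_THRESHOLD = 0.9


class TrialAnalysisError(ValueError):
    pass


@dataclass
class TestResult:
    statistic: float  # W+ (paired) or U (unpaired)
    n_effective: int
    p_value: float
    method: Literal["exact", "normal-approx"]


@dataclass
class AdjustedScores:
    """Index scores residualised on covariates (OLS with intercept)."""

    scores: pd.Series  # adjusted (residual) score per sample
    raw: pd.Series
    covariates: list[str]


def _signed_rank_distribution(ranks: np.ndarray) -> np.ndarray:
    """Counts of sign patterns by W+ value for integer ranks 1..n (no ties)."""
    total = int(ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    return counts


def paired_wilcoxon(pre: Sequence[float], post: Sequence[float],
                    zero_method: Literal["wilcox", "pratt"] = "wilcox"
                    ) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on post - pre differences.

    Zero differences are discarded before ranking (classical convention);
    ``zero_method='pratt'`` instead ranks them and drops their ranks.  Exact
    two-sided p = min(1, 2 * min(P(W+ <= w), P(W+ >= w))) from the full sign
    distribution when n_effective <= 25 and ranks are untied, otherwise a
    tie- and continuity-corrected normal approximation.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise TrialAnalysisError("pre and post must have equal length")
    d = post - pre
    nonzero = d != 0
    if not nonzero.any():
        raise TrialAnalysisError(
            "all paired differences are zero; with zeros discarded before "
            "ranking the signed-rank statistic is undefined"
        )
    if zero_method == "wilcox":
        d_used = d[nonzero]
        ranks = stats.rankdata(np.abs(d_used))
    else:  # pratt: rank |d| including zeros, then drop the zero ranks
        ranks_all = stats.rankdata(np.abs(d))
        d_used = d[nonzero]
        ranks = ranks_all[nonzero]
    n = len(d_used)
    w_plus = float(ranks[d_used > 0].sum())

    has_ties = len(np.unique(ranks)) != n
    if n <= EXACT_PAIRED_MAX_N and not has_ties and zero_method == "wilcox":
        counts = _signed_rank_distribution(ranks)
        total = counts.sum()
        w = int(round(w_plus))
        p_le = counts[:w + 1].sum() / total
        p_ge = counts[w:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(w_plus, n, float(p), "exact")

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
    if var <= 0:
        return TestResult(w_plus, n, 1.0, "normal-approx")
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return TestResult(w_plus, n, float(p), "normal-approx")


def _rank_sum_distribution(n_x: int, n_total: int) -> np.ndarray:
    """Counts of rank subsets of size n_x by rank-sum, ranks 1..n_total."""
    max_sum = n_x * n_total
    # dp[k][s] = number of size-k subsets of ranks seen so far with sum s
    dp = np.zeros((n_x + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in range(1, n_total + 1):
        for k in range(min(n_x, r), 0, -1):
            dp[k, r:] += dp[k - 1, :max_sum + 1 - r]
    return dp[n_x]


def unpaired_wilcoxon(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney rank-sum test with midranks.

    Exact when n_x * n_y <= 400 and there are no ties (full rank-subset
    enumeration by dynamic programming); otherwise tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise TrialAnalysisError("both groups must be nonempty")
    n_x, n_y = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:n_x].sum() - n_x * (n_x + 1) / 2.0)

    has_ties = len(np.unique(pooled)) != len(pooled)
    if n_x * n_y <= EXACT_UNPAIRED_MAX_PRODUCT and not has_ties:
        counts = _rank_sum_distribution(n_x, n_x + n_y)
        total = counts.sum()
        offset = n_x * (n_x + 1) // 2
        u_int = int(round(u))
        p_le = counts[:offset + u_int + 1].sum() / total
        p_ge = counts[offset + u_int:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(u, n_x + n_y, float(p), "exact")

    mean = n_x * n_y / 2.0
    n = n_x + n_y
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
    var = n_x * n_y / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return TestResult(u, n, 1.0, "normal-approx")
    z = (u - mean - 0.5 * np.sign(u - mean)) / np.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return TestResult(u, n, float(p), "normal-approx")


def adjust_index_for_covariates(scores: pd.Series, sheet: SampleSheet,
                                props=None,
                                covariates: Sequence[str] = ("age", "fibroblast")
                                ) -> AdjustedScores:
    """Residualise an index on covariates by OLS across all analysis samples.

    Covariates are looked up in the sample sheet first, then among the
    deconvolved cell fractions.  Residuals are exactly orthogonal to every
    covariate (normal equations), and the operation is idempotent.
    """
    samples = list(scores.index)
    cols = []
    meta = sheet.aligned_to(samples)
    for cov in covariates:
        if cov in meta.columns and not meta[cov].isna().any():
            cols.append(pd.to_numeric(meta[cov]).to_numpy(dtype=float))
        elif props is not None and cov in props.as_frame().columns:
            cols.append(props.as_frame().loc[samples, cov].to_numpy(dtype=float))
        else:
            raise TrialAnalysisError(f"covariate {cov!r} unavailable")
    X = np.column_stack([np.ones(len(samples))] + cols)
    # collinearity gate: name the offending covariate pair
    for i in range(len(covariates)):
        for j in range(i + 1, len(covariates)):
            c = np.corrcoef(cols[i], cols[j])[0, 1]
            if abs(c) > 1 - 1e-12:
                raise TrialAnalysisError(
                    f"collinear covariates: {covariates[i]!r} and "
                    f"{covariates[j]!r}"
                )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise TrialAnalysisError("covariate design is rank-deficient")
    y = scores.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return AdjustedScores(scores=pd.Series(resid, index=scores.index,
                                           name=f"{scores.name}_adjusted"),
                          raw=scores, covariates=list(covariates))


def snp_concordance_check(betas_pre: pd.Series, betas_post: pd.Series,
                          snp_probe_ids: Sequence[str]) -> dict:
    """Genotype-call concordance between a subject's pre and post samples.

    Beta < 0.25 -> AA, 0.25-0.75 -> AB, > 0.75 -> BB; a pair passes when at
    least 90% of calls agree.
    """
    shared = [p for p in snp_probe_ids
              if p in betas_pre.index and p in betas_post.index]
    if len(shared) < 10:
        raise TrialAnalysisError(
            f"need >= 10 shared SNP probes, got {len(shared)}"
        )

    def call(v: np.ndarray) -> np.ndarray:
        return np.where(v < SNP_HOMOZYGOUS_LOW, 0,
                        np.where(v > SNP_HOMOZYGOUS_HIGH, 2, 1))

    a = call(betas_pre.loc[shared].to_numpy(dtype=float))
    b = call(betas_post.loc[shared].to_numpy(dtype=float))
    concordance = float(np.mean(a == b))
    return {"concordance": concordance, "n_probes": len(shared),
            "pass": concordance >= SNP_PASS_THRESHOLD}


def _paired_frames(sheet: SampleSheet) -> pd.DataFrame:
    """subject_id-indexed frame with pre/post sample ids, arm and age."""
    meta = sheet.data
    wide = meta.pivot(index="subject_id", columns="timepoint",
                      values="sample_id")
    for tp in ("pre", "post"):
        if tp not in wide.columns:
            raise TrialAnalysisError(f"no samples at timepoint {tp!r}")
    wide = wide[["pre", "post"]].dropna()
    info = meta.drop_duplicates("subject_id").set_index("subject_id")
    wide["group"] = info.loc[wide.index, "group"]
    wide["age"] = info.loc[wide.index, "age"]
    return wide


def _comparison_rows(values: pd.Series, pairs: pd.DataFrame, variable: str
                     ) -> list[dict]:
    rows = []
    arms = sorted(pairs["group"].unique())
    deltas = {}
    for arm in arms:
        sub = pairs[pairs["group"] == arm]
        x_pre = values.loc[sub["pre"]].to_numpy(dtype=float)
        x_post = values.loc[sub["post"]].to_numpy(dtype=float)
        res = paired_wilcoxon(x_pre, x_post)
        deltas[arm] = x_post - x_pre
        rows.append({
            "variable": variable, "arm": arm, "comparison": "paired_pre_post",
            "n": len(sub), "statistic": res.statistic, "p_value": res.p_value,
            "method": res.method,
            "median_pre": float(np.median(x_pre)),
            "q1_pre": float(np.percentile(x_pre, 25)),
            "q3_pre": float(np.percentile(x_pre, 75)),
            "median_post": float(np.median(x_post)),
            "q1_post": float(np.percentile(x_post, 25)),
            "q3_post": float(np.percentile(x_post, 75)),
        })
    if len(arms) == 2:
        res = unpaired_wilcoxon(deltas[arms[0]], deltas[arms[1]])
        rows.append({
            "variable": variable, "arm": f"{arms[0]} vs {arms[1]}",
            "comparison": "delta_between_arms",
            "n": int(sum(len(d) for d in deltas.values())),
            "statistic": res.statistic, "p_value": res.p_value,
            "method": res.method,
            "median_pre": np.nan, "q1_pre": np.nan, "q3_pre": np.nan,
            "median_post": np.nan, "q1_post": np.nan, "q3_post": np.nan,
        })
    return rows


def run_trial_analysis(betas: BetaMatrix, counts: CountMatrix | None,
                       sheet: SampleSheet, props, meth_model=None,
                       expr_model=None, gene_sets: dict | None = None,
                       snp_probe_ids: Sequence[str] | None = None,
                       seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """End-to-end trial comparison table.

    Subjects failing the SNP identity check are excluded first.  Every
    per-sample quantity (cell fractions, methylation/expression index,
    gene-set scores) is compared raw and, for the indices and gene-set
    scores, after residualisation on age and fibroblast fraction.  Returns
    the tidy comparison table and a run manifest.
    """
    from .methindex import apply_index
    from .exprindex import (median_of_ratios_size_factors, normalize_log2,
                            geneset_score)

    pairs = _paired_frames(sheet)

    excluded: list[str] = []
    if snp_probe_ids is not None:
        for subj, row in pairs.iterrows():
            chk = snp_concordance_check(betas.values[row["pre"]],
                                        betas.values[row["post"]],
                                        snp_probe_ids)
            if not chk["pass"]:
                excluded.append(str(subj))
        if excluded:
            logger.warning("excluding subjects with SNP mismatch: %s", excluded)
            pairs = pairs.drop(index=excluded)
    kept_samples = list(pairs["pre"]) + list(pairs["post"])
    props_frame = props.as_frame().loc[kept_samples]
    fibro = props_frame["fibroblast"]

    rows: list[dict] = []

    # cell composition (undetected types excluded)
    for ct in props.detected_cell_types():
        rows.extend(_comparison_rows(props_frame[ct], pairs, ct))

    def add_index(scores: pd.Series, name: str) -> None:
        rows.extend(_comparison_rows(scores, pairs, name))
        sheet_aug = SampleSheet(sheet.data[sheet.data["sample_id"]
                                           .isin(kept_samples)].copy())
        adj = adjust_index_for_covariates(scores, sheet_aug, props,
                                          covariates=("age", "fibroblast"))
        rows.extend(_comparison_rows(adj.scores, pairs, f"{name}_adjusted"))

    if meth_model is not None:
        meth_scores = apply_index(meth_model, betas).loc[kept_samples]
        meth_scores.name = "meth_index"
        add_index(meth_scores, "meth_index")

    norm = None
    if counts is not None and (expr_model is not None or gene_sets):
        sub = CountMatrix(counts.values[kept_samples])
        sf = median_of_ratios_size_factors(sub)
        norm = normalize_log2(sub, sf)

    if expr_model is not None and norm is not None:
        expr_scores = apply_index(expr_model, norm.values).loc[kept_samples]
        expr_scores.name = "expr_index"
        add_index(expr_scores, "expr_index")

    if gene_sets and norm is not None:
        gs = geneset_score(norm, gene_sets)
        for set_name, per_sample in gs.groupby("set_name"):
            s = per_sample.set_index("sample_id")["score"].loc[kept_samples]
            s.name = set_name
            add_index(s, f"geneset:{set_name}")

    table = pd.DataFrame(rows)
    manifest = {
        "n_pairs_analyzed": int(len(pairs)),
        "arms": {a: int((pairs["group"] == a).sum())
                 for a in sorted(pairs["group"].unique())},
        "excluded_subjects": excluded,
        "snp_check_run": snp_probe_ids is not None,
        "variables": sorted(table["variable"].unique().tolist()),
        "seed": int(seed),
    }
    return table, manifest
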