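"""Reference-based cell-type deconvolution of methylation beta values.

Each sample's marker-CpG vector is modelled as a convex combination of the
reference cell-type profiles; proportions are the constrained least-squares
solution

    pi_hat = argmin || beta_markers - P pi ||^2   s.t.  pi >= 0, sum(pi) = 1.

The solver enumerates support sets and solves the equality-constrained
normal equations on each, which is exact for this small, strictly convex
problem (at most a few cell types) and fully deterministic.

Hierarchical (two-level) inference first resolves the major compartments
(epithelial, fibroblast, immune), then splits the immune compartment into
subtypes using immune-specific markers, rescaling subtype fractions by the
total immune fraction ic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io import BetaMatrix, ReferenceProfiles, SampleSheet

logger = logging.getLogger("endosafe")

#: a cell type with estimated fraction below this in every sample is
#: reported as undetected (below the solver noise floor on null data)
UNDETECTED_THRESHOLD = 1e-3

MIN_MARKER_OVERLAP = 0.5


class DeconvolutionError(ValueError):
    pass


@dataclass
class CellProportions:
    """Two-level per-sample cell composition.

    ``level1`` rows lie on the simplex; ``level2`` rows (if present) sum to
    the sample's total immune fraction ``ic``.
    """

    level1: pd.DataFrame  # samples x (epithelial, fibroblast, immune)
    level2: pd.DataFrame | None = None  # samples x immune subtypes
    undetected: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        s = self.level1.to_numpy().sum(axis=1)
        if not np.allclose(s, 1.0, atol=1e-6):
            raise DeconvolutionError("level-1 proportions must sum to 1")
        if (self.level1.to_numpy() < -1e-9).any():
            raise DeconvolutionError("negative level-1 proportion")
        if self.level2 is not None:
            s2 = self.level2.to_numpy().sum(axis=1)
            if not np.allclose(s2, self.ic.to_numpy(), atol=1e-6):
                raise DeconvolutionError("level-2 proportions must sum to ic")

    @property
    def ic(self) -> pd.Series:
        """Total immune fraction per sample."""
        return self.level1["immune"]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.level1.index)

    def detected_cell_types(self) -> list[str]:
        cols = list(self.level1.columns)
        if self.level2 is not None:
            cols += list(self.level2.columns)
        return [c for c in cols if c not in self.undetected]

    def as_frame(self) -> pd.DataFrame:
        """Tidy samples x cell-type table with an ``ic`` column appended."""
        out = self.level1.copy()
        if self.level2 is not None:
            out = pd.concat([out, self.level2], axis=1)
        out["ic"] = self.ic
        return out


def simplex_lsq(P: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact least squares of b on columns of P over the probability simplex.

    Enumerates candidate supports; on each support solves the
    sum-to-one-constrained normal equations via the KKT system and keeps the
    feasible candidate with the smallest residual.
    """
    m, k = P.shape
    PtP = P.T @ P
    Ptb = P.T @ b
    best, best_obj = None, np.inf
    for size in range(1, k + 1):
        for support in combinations(range(k), size):
            idx = list(support)
            A = np.zeros((size + 1, size + 1))
            A[:size, :size] = PtP[np.ix_(idx, idx)]
            A[:size, size] = 0.5
            A[size, :size] = 1.0
            rhs = np.append(Ptb[idx], 1.0)
            try:
                sol = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            x = sol[:size]
            if (x < -1e-10).any():
                continue
            pi = np.zeros(k)
            pi[idx] = np.clip(x, 0.0, None)
            pi /= pi.sum()
            obj = float(np.sum((b - P @ pi) ** 2))
            if obj < best_obj - 1e-15:
                best, best_obj = pi, obj
    if best is None:  # cannot happen for k >= 1, kept as a guard
        raise DeconvolutionError("no feasible simplex solution found")
    return best


def _align_markers(betas: BetaMatrix, profiles: ReferenceProfiles
                   ) -> tuple[np.ndarray, np.ndarray]:
    markers = [m for m in profiles.marker_ids if m in betas.values.index]
    frac = len(markers) / len(profiles.marker_ids)
    if frac < MIN_MARKER_OVERLAP:
        raise DeconvolutionError(
            f"only {frac:.0%} of reference markers present in the beta matrix "
            f"(need >= {MIN_MARKER_OVERLAP:.0%})"
        )
    if frac < 1.0:
        logger.warning("dropping %d reference markers absent from input",
                       len(profiles.marker_ids) - len(markers))
    P = profiles.values.loc[markers].to_numpy(dtype=float)
    if np.linalg.matrix_rank(P) < P.shape[1]:
        raise DeconvolutionError("reference profile matrix is rank-deficient")
    B = betas.values.loc[markers].to_numpy(dtype=float)
    return P, B


def estimate_proportions(betas: BetaMatrix, profiles: ReferenceProfiles
                         ) -> CellProportions:
    """Level-1 compartment proportions for every sample."""
    P, B = _align_markers(betas, profiles)
    pis = np.vstack([simplex_lsq(P, B[:, j]) for j in range(B.shape[1])])
    level1 = pd.DataFrame(pis, index=betas.sample_ids,
                          columns=profiles.cell_types)
    return CellProportions(level1=level1)


def estimate_proportions_hierarchical(betas: BetaMatrix,
                                      profiles_l1: ReferenceProfiles,
                                      profiles_l2: ReferenceProfiles,
                                      undetected_threshold: float =
                                      UNDETECTED_THRESHOLD
                                      ) -> CellProportions:
    """Two-stage composition: compartments, then immune subtypes scaled by ic.

    Subtypes whose fraction stays below the detection threshold in every
    sample are flagged undetected (e.g. CD8T in the trial data this design
    emulates) and excluded from downstream comparisons.
    """
    l1 = estimate_proportions(betas, profiles_l1)
    P2, B2 = _align_markers(betas, profiles_l2)
    sub = np.vstack([simplex_lsq(P2, B2[:, j]) for j in range(B2.shape[1])])
    ic = l1.ic.to_numpy()
    level2 = pd.DataFrame(sub * ic[:, None], index=betas.sample_ids,
                          columns=profiles_l2.cell_types)
    undetected = [ct for ct in profiles_l2.cell_types
                  if (level2[ct] < undetected_threshold).all()]
    if undetected:
        logger.info("undetected immune subtypes: %s", undetected)
    return CellProportions(level1=l1.level1, level2=level2,
                           undetected=undetected)


def compare_composition(props_pre: CellProportions, props_post: CellProportions,
                        sheet: SampleSheet) -> pd.DataFrame:
    """Per-cell-type paired (pre vs post, within arm) and between-arm
    (unpaired, on post - pre) rank tests; undetected cell types excluded."""
    from .trial import paired_wilcoxon, unpaired_wilcoxon

    pre = props_pre.as_frame().drop(columns="ic")
    post = props_post.as_frame().drop(columns="ic")
    meta = sheet.indexed()
    pre_subj = meta.loc[pre.index, "subject_id"]
    post_subj = meta.loc[post.index, "subject_id"]
    if set(pre_subj) != set(post_subj):
        raise DeconvolutionError("unpaired subject encountered")
    pre = pre.set_index(pre_subj)
    arm = meta.loc[props_pre.sample_ids, ["subject_id", "group"]] \
              .set_index("subject_id")["group"]
    post = post.set_index(post_subj).loc[pre.index]

    undetected = set(props_pre.undetected) | set(props_post.undetected)
    rows = []
    cell_types = [c for c in pre.columns if c not in undetected]
    arms = sorted(arm.unique())
    for ct in cell_types:
        delta_by_arm = {}
        for a in arms:
            subj = arm.index[arm == a]
            x_pre = pre.loc[subj, ct].to_numpy(dtype=float)
            x_post = post.loc[subj, ct].to_numpy(dtype=float)
            res = paired_wilcoxon(x_pre, x_post)
            delta_by_arm[a] = x_post - x_pre
            rows.append({
                "variable": ct, "arm": a, "comparison": "paired_pre_post",
                "n": len(subj), "statistic": res.statistic,
                "p_value": res.p_value, "method": res.method,
                "median_pre": float(np.median(x_pre)),
                "median_post": float(np.median(x_post)),
            })
        if len(arms) == 2:
            res = unpaired_wilcoxon(delta_by_arm[arms[0]], delta_by_arm[arms[1]])
            rows.append({
                "variable": ct, "arm": f"{arms[0]} vs {arms[1]}",
                "comparison": "delta_between_arms",
                "n": sum(len(d) for d in delta_by_arm.values()),
                "statistic": res.statistic, "p_value": res.p_value,
                "method": res.method,
                "median_pre": np.nan, "median_post": np.nan,
            })
    return pd.DataFrame(rows)
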