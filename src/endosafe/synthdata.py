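"""Synthetic cohorts and trials with the statistical structure the analysis
assumes.

The methylation model is a convex cell-type mixture: each sample's expected
beta at CpG g is sum_k pi_k * m_{g,k}, where pi lies on the simplex over
(epithelial, fibroblast, immune) and m_{g,k} is the cell-type-specific
baseline.  Disease signal is injected only into the epithelial component of
case samples, which is exactly the compartment the delta-beta-at-ic=0
statistic targets; age adds a small linear drift at a subset of CpGs.
Measurement noise is Beta-distributed around the expectation so values
respect the [0, 1] support.

The RNA-seq model draws negative-binomial counts with per-sample depth
factors and a fixed set of differentially expressed genes.

The trial generator emulates a paired two-arm design (default 8 treated and
6 comparator pairs, matching the molecular cohort of the trial this package
analyses), with a configurable post-treatment fibroblast shift and a
configurable (default zero) shift along the stored case-signal axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import BetaMatrix, CountMatrix, ReferenceProfiles, SampleSheet

LEVEL1_CELL_TYPES = ("epithelial", "fibroblast", "immune")
LEVEL2_CELL_TYPES = ("B", "NK", "CD4T", "CD8T", "monocyte", "neutrophil")

#: number of genotype-like identity probes emulating the EPIC SNP probe set
N_SNP_PROBES = 59


class SimulationError(ValueError):
    """Raised when a simulation request is infeasible."""


@dataclass
class CohortSimConfig:
    """Case/control methylation cohort parameters.

    Defaults emulate a tumour-versus-normal tissue cohort at desk scale:
    cases are enriched for epithelium (tumours are epithelial), about 5% of
    CpGs carry a case-specific epithelial methylation difference of 0.1-0.4
    (typical array-scale cancer effect sizes), and measurement noise has
    Beta concentration 50 (sd ~ 0.07 at beta = 0.5, i.e. tissue-level
    biological plus technical variability).
    """

    n_cases: int = 100
    n_controls: int = 100
    n_cpgs: int = 5000
    n_differential: int = 250
    delta_range: tuple[float, float] = (0.1, 0.4)
    age_range: tuple[float, float] = (30.0, 80.0)
    n_age_cpgs: int = 100
    age_slope: float = 0.002
    noise_concentration: float = 50.0
    # tumour/normal bulk tissue modelled as epithelium plus infiltrating
    # immune cells with a minor stromal share: the two-compartment regime in
    # which an ic-only adjustment (and the intercept at ic = 0) is exact
    proportion_alpha_cases: tuple[float, float, float] = (12.0, 0.3, 3.7)
    proportion_alpha_controls: tuple[float, float, float] = (10.0, 0.3, 5.7)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_differential > self.n_cpgs:
            raise SimulationError("n_differential cannot exceed n_cpgs")
        lo, hi = self.delta_range
        if not (-1 < lo <= hi < 1):
            raise SimulationError("delta_range must lie within (-1, 1)")
        if self.noise_concentration <= 0:
            raise SimulationError("noise_concentration must be positive")


@dataclass
class TrialSimConfig:
    """Paired two-arm trial parameters.

    ``fibroblast_shift`` is the additive change in the treated arm's true
    fibroblast fraction after treatment (before simplex renormalisation);
    the default +0.05 mirrors the compositional change the analysis is built
    to detect.  ``index_effect`` shifts treated post-treatment samples along
    the stored case-signal axis (0 = no oncogenic change).
    """

    n_treated_pairs: int = 8
    n_control_pairs: int = 6
    fibroblast_shift: float = 0.05
    index_effect: float = 0.0
    seed: int = 0
    cohort: CohortSimConfig = field(default_factory=lambda: CohortSimConfig(
        n_cpgs=2000, n_differential=100, n_age_cpgs=50,
        # healthy endometrium: roughly 55% epithelial, 31% fibroblast,
        # 14% immune at baseline
        proportion_alpha_controls=(11.0, 6.2, 2.8),
        proportion_alpha_cases=(11.0, 6.2, 2.8),
    ))

    def __post_init__(self) -> None:
        if abs(self.fibroblast_shift) >= 1:
            raise SimulationError("fibroblast_shift must keep fractions in [0,1]")


@dataclass
class SimTruth:
    """Ground truth emitted alongside every simulated dataset."""

    proportions: pd.DataFrame  # sample x cell type, true mixing fractions
    differential: pd.DataFrame  # feature_id, true effect (delta-beta or log2FC)
    index_axis: pd.Series  # per-sample coordinate along the case-signal axis
    extras: dict = field(default_factory=dict)


def make_reference_profiles(n_markers: int, level: int, seed: int = 0
                            ) -> ReferenceProfiles:
    """Block-structured reference: each cell type owns a marker block where
    it is nearly fully methylated (0.8-0.95) and all others nearly
    unmethylated (0.05-0.2)."""
    cell_types = LEVEL1_CELL_TYPES if level == 1 else LEVEL2_CELL_TYPES
    k = len(cell_types)
    if n_markers < 10 * k:
        raise SimulationError(
            f"need at least {10 * k} markers for {k} cell types, got {n_markers}"
        )
    rng = np.random.default_rng(seed)
    vals = rng.uniform(0.05, 0.2, size=(n_markers, k))
    owner = np.arange(n_markers) % k  # interleaved blocks, balanced sizes
    vals[np.arange(n_markers), owner] = rng.uniform(0.8, 0.95, size=n_markers)
    ids = [f"cg_l{level}_{i:05d}" for i in range(n_markers)]
    df = pd.DataFrame(vals, index=ids, columns=list(cell_types))
    return ReferenceProfiles(level=level, values=df)


def _beta_noise(rng: np.random.Generator, mean: np.ndarray,
                concentration: float) -> np.ndarray:
    """Beta-distributed observation around ``mean`` with given precision."""
    if np.isinf(concentration):
        return mean.copy()
    m = np.clip(mean, 1e-6, 1 - 1e-6)
    a = m * concentration
    b = (1 - m) * concentration
    return np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)


def _celltype_baselines(rng: np.random.Generator, cpg_ids: Sequence[str],
                        profiles: ReferenceProfiles) -> pd.DataFrame:
    """Per-cell-type baseline betas over the full CpG panel.

    Marker CpGs from the reference keep their profile values; all remaining
    CpGs get a shared baseline (identical across cell types) drawn from a
    mid-range uniform, so they carry no compositional information.
    """
    k = len(profiles.cell_types)
    base = np.repeat(rng.uniform(0.1, 0.9, size=(len(cpg_ids), 1)), k, axis=1)
    df = pd.DataFrame(base, index=list(cpg_ids), columns=profiles.cell_types)
    shared = [c for c in profiles.marker_ids if c in df.index]
    df.loc[shared] = profiles.values.loc[shared].to_numpy()
    return df


def simulate_cohort(config: CohortSimConfig, profiles: ReferenceProfiles
                    ) -> tuple[BetaMatrix, SampleSheet, SimTruth]:
    """Simulate a case/control methylation cohort.

    The CpG panel is the union of the reference markers and enough
    background CpGs to reach ``n_cpgs``; differential and age CpGs are drawn
    from the background so deconvolution markers stay clean.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    groups = np.array(["case"] * config.n_cases + ["control"] * config.n_controls)
    sample_ids = [f"S{i:04d}" for i in range(n)]

    markers = profiles.marker_ids
    n_background = config.n_cpgs - len(markers)
    if n_background < config.n_differential + config.n_age_cpgs:
        raise SimulationError(
            "n_cpgs too small for the requested markers + differential + age CpGs"
        )
    cpg_ids = markers + [f"cg_bg_{i:06d}" for i in range(n_background)]
    baselines = _celltype_baselines(rng, cpg_ids, profiles)

    # true mixing proportions and ages
    alpha = np.where(groups[:, None] == "case",
                     np.asarray(config.proportion_alpha_cases),
                     np.asarray(config.proportion_alpha_controls))
    pi = np.vstack([rng.dirichlet(a) for a in alpha])
    ages = rng.uniform(*config.age_range, size=n)

    # case-specific epithelial effects on background CpGs
    bg_ids = np.array(cpg_ids[len(markers):])
    chosen = rng.choice(len(bg_ids), size=config.n_differential + config.n_age_cpgs,
                        replace=False)
    diff_ids = bg_ids[chosen[:config.n_differential]]
    age_ids = bg_ids[chosen[config.n_differential:]]
    magnitude = rng.uniform(*config.delta_range, size=config.n_differential)
    sign = rng.choice([-1.0, 1.0], size=config.n_differential)
    deltas = magnitude * sign
    # keep epithelial case betas inside (0, 1): flip infeasible signs once
    epi_base = baselines.loc[diff_ids, "epithelial"].to_numpy()
    flip = ((epi_base + deltas < 0.01) | (epi_base + deltas > 0.99))
    deltas[flip] *= -1
    still_bad = ((epi_base + deltas < 0) | (epi_base + deltas > 1))
    if still_bad.any():
        raise SimulationError(
            f"infeasible epithelial delta at CpGs {list(diff_ids[still_bad][:5])}"
        )

    axis = (groups == "case").astype(float)  # case-signal coordinate
    expected = _expected_betas(baselines, pi, axis, diff_ids, deltas,
                               age_ids, ages, config)
    observed = _beta_noise(rng, expected, config.noise_concentration)

    betas = BetaMatrix(pd.DataFrame(observed, index=cpg_ids, columns=sample_ids))
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": sample_ids,
        "subject_id": sample_ids,
        "group": groups,
        "timepoint": "NA",
        "age": np.round(ages, 1),
        "menstrual_phase": "NA",
    }))
    truth = SimTruth(
        proportions=pd.DataFrame(pi, index=sample_ids,
                                 columns=list(LEVEL1_CELL_TYPES)),
        differential=pd.DataFrame({"feature_id": diff_ids, "effect": deltas}),
        index_axis=pd.Series(axis, index=sample_ids, name="index_axis"),
        extras={"age_cpgs": list(age_ids), "ages": dict(zip(sample_ids, ages)),
                "expected": pd.DataFrame(expected, index=cpg_ids,
                                         columns=sample_ids)},
    )
    return betas, sheet, truth


def _expected_betas(baselines: pd.DataFrame, pi: np.ndarray, axis: np.ndarray,
                    diff_ids, deltas, age_ids, ages, config: CohortSimConfig
                    ) -> np.ndarray:
    """Expected beta matrix (CpG x sample) from the mixture model."""
    cpg_ids = baselines.index
    base = baselines.to_numpy()  # G x K
    expected = base @ pi.T  # G x n
    # epithelial-only case effect, scaled by each sample's epithelial fraction
    gi = cpg_ids.get_indexer(diff_ids)
    expected[gi, :] += np.outer(deltas, axis * pi[:, 0])
    # linear age drift around the age-range midpoint, both groups alike
    ai = cpg_ids.get_indexer(age_ids)
    mid = 0.5 * (config.age_range[0] + config.age_range[1])
    expected[ai, :] += config.age_slope * (ages - mid)[None, :]
    return np.clip(expected, 0.001, 0.999)


def simulate_counts_cohort(n_cases: int = 100, n_controls: int = 100,
                           n_genes: int = 5000, n_de: int = 500,
                           lfc_range: tuple[float, float] = (0.5, 2.0),
                           dispersion: float = 0.1,
                           depth_range: tuple[float, float] = (0.5, 2.0),
                           seed: int = 0
                           ) -> tuple[CountMatrix, SampleSheet, SimTruth]:
    """Simulate an RNA-seq case/control cohort.

    counts_gj ~ NB(mean = depth_j * q_g * FC_g^{case_j}, dispersion), with
    gene baselines q_g log-normal and ``n_de`` genes carrying log2
    fold-changes drawn from +/- ``lfc_range``.
    """
    if min(n_cases, n_controls, n_genes) <= 0 or n_de < 0 or dispersion < 0:
        raise SimulationError("parameters must be positive (n_de >= 0)")
    if n_de > n_genes:
        raise SimulationError("n_de cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    groups = np.array(["case"] * n_cases + ["control"] * n_controls)
    sample_ids = [f"R{i:04d}" for i in range(n)]
    gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]

    q = np.exp(rng.normal(np.log(50.0), 1.2, size=n_genes))  # baseline means
    depth = rng.uniform(*depth_range, size=n)
    lfc = np.zeros(n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    lfc[de_idx] = (rng.uniform(*lfc_range, size=n_de)
                   * rng.choice([-1.0, 1.0], size=n_de))

    case = (groups == "case").astype(float)
    mu = depth[None, :] * q[:, None] * np.power(2.0, np.outer(lfc, case))
    if dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / dispersion
        counts = rng.negative_binomial(size, size / (size + mu))

    cm = CountMatrix(pd.DataFrame(counts.astype(np.int64), index=gene_ids,
                                  columns=sample_ids))
    ages = rng.uniform(30, 80, size=n)
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": sample_ids,
        "subject_id": sample_ids,
        "group": groups,
        "timepoint": "NA",
        "age": np.round(ages, 1),
        "menstrual_phase": "NA",
    }))
    truth = SimTruth(
        proportions=pd.DataFrame(index=sample_ids),
        differential=pd.DataFrame({"feature_id": np.array(gene_ids)[de_idx],
                                   "effect": lfc[de_idx]}),
        index_axis=pd.Series(case, index=sample_ids, name="index_axis"),
        extras={"depth": dict(zip(sample_ids, depth)), "dispersion": dispersion},
    )
    return cm, sheet, truth


def _draw_snp_genotypes(rng: np.random.Generator, n_subjects: int
                        ) -> np.ndarray:
    """Genotype-like beta centres for identity probes: {0.05, 0.5, 0.95}."""
    return rng.choice([0.05, 0.5, 0.95], size=(N_SNP_PROBES, n_subjects))


def _immune_subtype_block(rng: np.random.Generator,
                          profiles_l2: ReferenceProfiles,
                          n_units: int) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-unit immune-subtype shares and the resulting subtype-marker betas.

    CD8T is held at exactly zero (the absent-subtype scenario); the other
    subtypes share the immune compartment via a Dirichlet draw.  At these
    markers the synthetic non-immune compartment mirrors the immune-average
    methylation, so the bulk beta equals the within-immune mixture profile —
    the regime in which two-stage deconvolution factorises exactly.
    """
    subtypes = profiles_l2.cell_types
    k = len(subtypes)
    alpha = np.full(k, 2.0)
    shares = np.zeros((n_units, k))
    active = [i for i, s in enumerate(subtypes) if s != "CD8T"]
    draws = np.vstack([rng.dirichlet(alpha[active]) for _ in range(n_units)])
    shares[:, active] = draws
    marker_betas = profiles_l2.values.to_numpy() @ shares.T  # markers x units
    df = pd.DataFrame(shares, columns=subtypes)
    return marker_betas, df


def simulate_trial(config: TrialSimConfig, profiles: ReferenceProfiles,
                   profiles_l2: ReferenceProfiles | None = None
                   ) -> tuple[BetaMatrix, CountMatrix, SampleSheet, SimTruth]:
    """Simulate the paired two-arm trial (pre/post biopsies per subject).

    Treated subjects' post-treatment fibroblast fraction is shifted by
    ``fibroblast_shift`` and renormalised on the simplex; ``index_effect``
    moves treated post samples along the case-signal axis.  A block of
    genotype-like SNP probes, constant within subject, supports the sample
    identity check.  When ``profiles_l2`` is given, its immune-subtype
    markers are appended (CD8T truly absent) so hierarchical deconvolution
    can be exercised end to end.
    """
    cc = config.cohort
    rng = np.random.default_rng(config.seed)
    subjects = ([f"T{i:02d}" for i in range(config.n_treated_pairs)]
                + [f"C{i:02d}" for i in range(config.n_control_pairs)])
    arms = (["mifepristone"] * config.n_treated_pairs
            + ["comparator"] * config.n_control_pairs)

    markers = profiles.marker_ids
    n_background = cc.n_cpgs - len(markers)
    if n_background < cc.n_differential + cc.n_age_cpgs:
        raise SimulationError("n_cpgs too small for markers + signal CpGs")
    cpg_ids = markers + [f"cg_bg_{i:06d}" for i in range(n_background)]
    baselines = _celltype_baselines(rng, cpg_ids, profiles)
    bg_ids = np.array(cpg_ids[len(markers):])
    chosen = rng.choice(len(bg_ids), size=cc.n_differential + cc.n_age_cpgs,
                        replace=False)
    diff_ids = bg_ids[chosen[:cc.n_differential]]
    age_ids = bg_ids[chosen[cc.n_differential:]]
    magnitude = rng.uniform(*cc.delta_range, size=cc.n_differential)
    deltas = magnitude * rng.choice([-1.0, 1.0], size=cc.n_differential)
    epi_base = baselines.loc[diff_ids, "epithelial"].to_numpy()
    flip = ((epi_base + deltas < 0.01) | (epi_base + deltas > 0.99))
    deltas[flip] *= -1

    # per-subject biology: proportions (healthy endometrium), age, genotypes
    n_subj = len(subjects)
    ages = rng.uniform(*cc.age_range, size=n_subj)
    genotypes = _draw_snp_genotypes(rng, n_subj)

    pre_pi = np.zeros((n_subj, 3))
    post_pi = np.zeros((n_subj, 3))
    for i, arm in enumerate(arms):
        for attempt in range(100):
            p = rng.dirichlet(np.asarray(cc.proportion_alpha_controls))
            if arm == "mifepristone":
                q = p.copy()
                q[1] += config.fibroblast_shift
                if q[1] < 0 or q[1] > 1:
                    continue
                q = np.clip(q, 0, None)
                q /= q.sum()
            else:
                q = p.copy()
            pre_pi[i], post_pi[i] = p, q
            break
        else:
            raise SimulationError(
                f"could not draw feasible proportions for subject {subjects[i]}"
            )

    sample_rows = []
    pi_rows, axis_vals, sample_ids = [], [], []
    for i, (subj, arm) in enumerate(zip(subjects, arms)):
        for tp in ("pre", "post"):
            sid = f"{subj}_{tp}"
            sample_ids.append(sid)
            pi_rows.append(pre_pi[i] if tp == "pre" else post_pi[i])
            treated_post = (arm == "mifepristone" and tp == "post")
            axis_vals.append(config.index_effect if treated_post else 0.0)
            if tp == "pre":
                phase = "luteal"
            else:
                phase = "no_menstruation" if arm == "mifepristone" else "luteal"
            sample_rows.append({
                "sample_id": sid, "subject_id": subj, "group": arm,
                "timepoint": tp, "age": round(ages[i], 1),
                "menstrual_phase": phase,
            })
    pi = np.vstack(pi_rows)
    axis = np.asarray(axis_vals)
    ages_per_sample = np.repeat(ages, 2)

    expected = _expected_betas(baselines, pi, axis, diff_ids, deltas,
                               age_ids, ages_per_sample, cc)
    observed = _beta_noise(rng, expected, cc.noise_concentration)

    # SNP identity block: constant genotype within subject, small jitter
    snp_ids = [f"rs_{i:03d}" for i in range(N_SNP_PROBES)]
    snp_centres = np.repeat(genotypes, 2, axis=1)  # probes x samples
    snp_obs = np.clip(snp_centres + rng.normal(0, 0.01,
                                               size=snp_centres.shape),
                      1e-6, 1 - 1e-6)

    blocks = [observed, snp_obs]
    block_ids = cpg_ids + snp_ids
    subtype_shares = None
    if profiles_l2 is not None:
        l2_expected, subtype_shares = _immune_subtype_block(
            rng, profiles_l2, n_subj)
        l2_expected = np.repeat(l2_expected, 2, axis=1)  # constant in subject
        l2_obs = _beta_noise(rng, l2_expected, cc.noise_concentration)
        blocks.append(l2_obs)
        block_ids = block_ids + profiles_l2.marker_ids
        subtype_shares.index = subjects

    beta_df = pd.DataFrame(np.vstack(blocks), index=block_ids,
                           columns=sample_ids)
    betas = BetaMatrix(beta_df)

    # matched RNA-seq: gene panel with its own DE axis, shared coordinate
    n_genes, n_de = 2000, 200
    gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    q = np.exp(rng.normal(np.log(50.0), 1.2, size=n_genes))
    lfc = np.zeros(n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    lfc[de_idx] = rng.uniform(0.5, 2.0, size=n_de) * rng.choice([-1.0, 1.0],
                                                                size=n_de)
    depth = rng.uniform(0.5, 2.0, size=len(sample_ids))
    mu = depth[None, :] * q[:, None] * np.power(2.0, np.outer(lfc, axis))
    size = 1.0 / 0.1
    counts = rng.negative_binomial(size, size / (size + mu))
    cm = CountMatrix(pd.DataFrame(counts.astype(np.int64), index=gene_ids,
                                  columns=sample_ids))

    sheet = SampleSheet(pd.DataFrame(sample_rows))
    truth = SimTruth(
        proportions=pd.DataFrame(pi, index=sample_ids,
                                 columns=list(LEVEL1_CELL_TYPES)),
        differential=pd.DataFrame({"feature_id": diff_ids, "effect": deltas}),
        index_axis=pd.Series(axis, index=sample_ids, name="index_axis"),
        extras={
            "snp_probe_ids": snp_ids,
            "immune_subtype_shares": subtype_shares,
            "de_genes": pd.DataFrame({"feature_id": np.array(gene_ids)[de_idx],
                                      "effect": lfc[de_idx]}),
            "config": {"n_treated_pairs": config.n_treated_pairs,
                       "n_control_pairs": config.n_control_pairs,
                       "fibroblast_shift": config.fibroblast_shift,
                       "index_effect": config.index_effect,
                       "seed": config.seed},
        },
    )
    return betas, cm, sheet, truth
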