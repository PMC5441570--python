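"""Mass-univariate two-sample testing with multiplicity control and feature QC.

Each feature is tested for a patient-vs-control mean difference with a
pooled-variance (Student) two-sample t-test; the resulting p-value vector is
corrected by Bonferroni and Benjamini-Hochberg FDR at a common alpha. The
"stable Bonferroni" set intersects the Bonferroni survivors over
leave-one-subject-out folds. The samples are runs, not subjects; runs of one
subject are not independent, which is why fold-based stability is assessed
downstream rather than trusting single-dataset significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import FeatureMatrix

__all__ = [
    "UnivariateResult",
    "GroupDifference",
    "two_sample_ttest",
    "bonferroni",
    "bh_fdr",
    "stable_bonferroni",
    "residualize_features",
    "feature_qc",
]


@dataclass
class UnivariateResult:
    """Per-feature test statistics with correction masks.

    Sign convention: positive t means the patient mean exceeds the control
    mean. ``degenerate`` flags features with zero pooled variance.
    """

    tstat: np.ndarray
    pvalue: np.ndarray
    mean_patient: np.ndarray
    mean_control: np.ndarray
    sd_patient: np.ndarray
    sd_control: np.ndarray
    degenerate: np.ndarray
    alpha: float = 0.05
    bonferroni_survivors: np.ndarray = field(default=None)
    fdr_survivors: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.bonferroni_survivors is None:
            self.bonferroni_survivors = bonferroni(self.pvalue, self.alpha)
        if self.fdr_survivors is None:
            self.fdr_survivors = bh_fdr(self.pvalue, self.alpha)

    @property
    def m(self) -> int:
        return len(self.pvalue)

    def frame(self, descriptors=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "tstat": self.tstat,
                "pvalue": self.pvalue,
                "mean_patient": self.mean_patient,
                "mean_control": self.mean_control,
                "sd_patient": self.sd_patient,
                "sd_control": self.sd_control,
                "bonferroni": self.bonferroni_survivors,
                "fdr": self.fdr_survivors,
            }
        )
        if descriptors is not None:
            df.insert(0, "descriptor", [str(d) for d in descriptors])
        return df


def two_sample_ttest(
    values: np.ndarray | FeatureMatrix, is_patient: np.ndarray | None = None, alpha: float = 0.05
) -> UnivariateResult:
    """Pooled-variance two-sample t-test per feature (patients minus controls).

    Two-sided p-values from the t distribution with n1 + n2 - 2 df. Features
    with zero pooled variance get p = 1 when the group means agree and p = 0
    otherwise, flagged as degenerate.
    """
    if isinstance(values, FeatureMatrix):
        if is_patient is None:
            is_patient = values.is_patient
        values = values.values
    values = np.asarray(values, dtype=float)
    is_patient = np.asarray(is_patient, dtype=bool)
    xp = values[is_patient]
    xc = values[~is_patient]
    n1, n2 = xp.shape[0], xc.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 samples")
    mp, mc = xp.mean(axis=0), xc.mean(axis=0)
    vp, vc = xp.var(axis=0, ddof=1), xc.var(axis=0, ddof=1)
    pooled = ((n1 - 1) * vp + (n2 - 1) * vc) / (n1 + n2 - 2)
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mp - mc) / se
    df = n1 + n2 - 2
    p = 2.0 * stats.t.sf(np.abs(t), df)
    equal_means = mp == mc
    with np.errstate(invalid="ignore"):
        t[degenerate] = np.where(
            equal_means[degenerate], 0.0, np.inf * np.sign((mp - mc)[degenerate])
        )
    p[degenerate] = np.where(equal_means[degenerate], 1.0, 0.0)
    return UnivariateResult(
        tstat=t,
        pvalue=p,
        mean_patient=mp,
        mean_control=mc,
        sd_patient=np.sqrt(vp),
        sd_control=np.sqrt(vc),
        degenerate=degenerate,
        alpha=alpha,
    )


def bonferroni(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Single-step correction: survivor iff p < alpha / m."""
    p = np.asarray(p, dtype=float)
    return p < alpha / len(p)


def bh_fdr(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level alpha."""
    p = np.asarray(p, dtype=float)
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def stable_bonferroni(per_fold_results: list[UnivariateResult]) -> np.ndarray:
    """Indices surviving Bonferroni in every fold (sorted)."""
    if not per_fold_results:
        raise ValueError("need at least one fold")
    m = per_fold_results[0].m
    mask = np.ones(m, dtype=bool)
    for res in per_fold_results:
        if res.m != m:
            raise ValueError("folds tested different feature sets")
        mask &= res.bonferroni_survivors
    return np.flatnonzero(mask)


def residualize_features(fm: FeatureMatrix, covariates: np.ndarray) -> FeatureMatrix:
    """Replace each feature by its residual after regressing on [1, covariates].

    Used e.g. to regress nuisance motion summaries out of the features.
    Rank-deficient designs fall back to the minimum-norm solution with a
    warning (redundant columns carry no extra information).
    """
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != fm.n_samples:
        cov = cov.T
    if cov.shape[0] != fm.n_samples:
        raise ValueError("covariates must be row-aligned with the samples")
    design = np.column_stack([np.ones(fm.n_samples), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("rank-deficient covariate design; redundant columns ignored")
    beta, *_ = np.linalg.lstsq(design, fm.values, rcond=None)
    resid = fm.values - design @ beta
    return FeatureMatrix(
        values=resid,
        feature_type=fm.feature_type,
        descriptors=fm.descriptors,
        samples=fm.samples,
        constant_flags=fm.constant_flags,
    )


def feature_qc(fm: FeatureMatrix, is_patient: np.ndarray | None = None):
    """Per-feature normality check and group variance summary.

    Per (feature, group): one-sample Kolmogorov-Smirnov p against a normal with
    the group's estimated mean and SD (estimating the parameters makes the test
    conservative, in the Lilliefors sense). Also returns the sigma-bar summary:
    mean +/- SD of the per-feature sample SDs within each group.
    """
    if is_patient is None:
        is_patient = fm.is_patient
    is_patient = np.asarray(is_patient, dtype=bool)
    out = {}
    summary = {}
    for label, rows in (("patient", is_patient), ("control", ~is_patient)):
        block = fm.values[rows]
        if block.shape[0] < 5:
            raise ValueError("need >= 5 samples per group for QC")
        sds = block.std(axis=0, ddof=1)
        pvals = np.empty(fm.n_features)
        for j in range(fm.n_features):
            x = block[:, j]
            s = sds[j]
            if s == 0:
                pvals[j] = 0.0
                continue
            pvals[j] = stats.kstest(x, "norm", args=(x.mean(), s)).pvalue
        out[f"ks_p_{label}"] = pvals
        summary[label] = {"sigma_bar": float(sds.mean()), "sigma_sd": float(sds.std(ddof=1) if len(sds) > 1 else 0.0)}
    table = pd.DataFrame(out)
    return table, summary


class GroupDifference:
    """Mass-univariate group-difference model over a feature matrix.

    statsmodels-style: construct from data, call :meth:`fit` to obtain a
    results object.
    """

    def __init__(self, fm: FeatureMatrix, is_patient: np.ndarray | None = None):
        self.fm = fm
        self.is_patient = fm.is_patient if is_patient is None else np.asarray(is_patient, bool)

    def fit(self, alpha: float = 0.05) -> "GroupDifferenceResults":
        res = two_sample_ttest(self.fm.values, self.is_patient, alpha=alpha)
        return GroupDifferenceResults(self, res, alpha)


class GroupDifferenceResults:
    def __init__(self, model: GroupDifference, result: UnivariateResult, alpha: float):
        self.model = model
        self.result = result
        self.alpha = alpha

    @property
    def pvalues(self) -> np.ndarray:
        return self.result.pvalue

    @property
    def tvalues(self) -> np.ndarray:
        return self.result.tstat

    @property
    def bonferroni_survivors(self) -> np.ndarray:
        return self.result.bonferroni_survivors

    @property
    def fdr_survivors(self) -> np.ndarray:
        return self.result.fdr_survivors

    def frame(self) -> pd.DataFrame:
        return self.result.frame(self.model.fm.descriptors)

    def summary(self) -> str:
        r = self.result
        lines = [
            "Mass-univariate group difference (pooled-variance two-sample t)",
            f"  feature type: {self.model.fm.feature_type}",
            f"  features tested (m): {r.m}",
            f"  samples: {self.model.fm.n_samples} "
            f"({int(self.model.is_patient.sum())} patient / "
            f"{int((~self.model.is_patient).sum())} control runs)",
            f"  alpha: {self.alpha}",
            f"  Bonferroni survivors: {int(r.bonferroni_survivors.sum())}",
            f"  FDR (BH) survivors:   {int(r.fdr_survivors.sum())}",
            f"  min p-value: {r.pvalue.min():.3g}",
        ]
        return "\n".join(lines)
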