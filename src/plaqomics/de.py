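"""Two-group differential expression for count and LFQ-intensity matrices.

Covers median-of-ratios normalization, FPKM, a negative-binomial Wald test
for RNA count layers, a Welch test on log2 LFQ intensities for the protein
layer, and the qPCR 2^(-ddCt) relative-quantification calculator.

A feature is called differentially expressed when |log2FoldChange| > 1.0
and raw p < 0.05 (strict inequalities).  Benjamini-Hochberg q-values are
reported alongside for transparency but do not enter the call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: default DE criterion
LFC_THRESHOLD = 1.0
P_THRESHOLD = 0.05

GROUP_STABLE = "stable"
GROUP_UNSTABLE = "unstable"


@dataclass
class OmicsMatrix:
    """Feature-by-sample numeric matrix with two-group sample labels.

    ``values`` holds raw counts (RNA layers) or LFQ intensities (protein
    layer); ``groups`` maps each sample id (column) to its group label.
    """

    values: pd.DataFrame
    groups: pd.Series
    layer: str = "mrna"

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples missing group labels: {missing}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative values in omics matrix")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in(self, group: str) -> list:
        return list(self.groups.index[self.groups == group])

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.samples_in(group)]

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_tsv(
        cls, matrix_path: str | Path, samples_path: str | Path, layer: str = "mrna"
    ) -> "OmicsMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        sheet = pd.read_csv(samples_path, sep="\t")
        groups = pd.Series(
            sheet["group"].to_numpy(), index=sheet["sample_id"].astype(str)
        )
        return cls(values=values, groups=groups, layer=layer)

    def to_tsv(self, matrix_path: str | Path, samples_path: Optional[str | Path] = None) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="feature_id")
        if samples_path is not None:
            pd.DataFrame(
                {"sample_id": self.groups.index, "group": self.groups.to_numpy()}
            ).to_csv(samples_path, sep="\t", index=False)


# ----------------------------------------------------------- normalization

def size_factors(counts: OmicsMatrix) -> pd.Series:
    """Median-of-ratios per-sample size factors, rescaled to geometric mean 1.

    Each sample's factor is the median, over features with all-positive
    counts, of that sample's count divided by the feature's geometric mean
    across samples.  If no feature is positive in every sample, falls back
    to library-size ratios with a warning.
    """
    x = counts.values.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if all_pos.any():
        logx = np.log(x[all_pos])
        log_gm = logx.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logx - log_gm, axis=0))
    else:
        warnings.warn(
            "no feature with positive counts in all samples; "
            "falling back to library-size ratios",
            RuntimeWarning,
        )
        lib = x.sum(axis=0)
        if lib.sum() == 0:
            factors = np.ones(x.shape[1])
        else:
            factors = lib / np.exp(np.mean(np.log(np.where(lib > 0, lib, 1.0))))
    # rescale to geometric mean 1
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def fpkm(counts: OmicsMatrix, lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase of feature per million library reads.

    fpkm_ij = count_ij * 1e9 / (length_i * library_size_j); columns with a
    zero library size come back all zero.
    """
    lengths = lengths.reindex(counts.feature_ids)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("feature lengths must be positive for all features")
    lib = counts.values.sum(axis=0).to_numpy(dtype=float)
    denom = np.outer(lengths.to_numpy(dtype=float), lib)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = counts.values.to_numpy(dtype=float) * 1e9 / denom
    out[:, lib == 0] = 0.0
    return pd.DataFrame(out, index=counts.feature_ids, columns=counts.sample_ids)


# ------------------------------------------------------------------ NB test

def _pooled_dispersion(
    g1: np.ndarray, g2: np.ndarray, floor: float
) -> np.ndarray:
    """Method-of-moments NB dispersion pooled across both groups.

    Per group, alpha = (s^2 - m) / m^2 from the NB variance m + alpha m^2;
    the two estimates are averaged weighted by residual degrees of freedom
    and floored.
    """
    alphas, weights = [], []
    for g in (g1, g2):
        m = g.mean(axis=1)
        s2 = g.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (s2 - m) / np.square(m)
        a = np.where(np.isfinite(a), a, 0.0)
        alphas.append(a)
        weights.append(g.shape[1] - 1)
    pooled = (alphas[0] * weights[0] + alphas[1] * weights[1]) / sum(weights)
    return np.maximum(pooled, floor)


def nb_test(
    counts: OmicsMatrix,
    pseudocount: float = 0.5,
    dispersion_floor: float = 1e-8,
    lfc_threshold: float = LFC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    group_a: str = GROUP_STABLE,
    group_b: str = GROUP_UNSTABLE,
) -> pd.DataFrame:
    """Negative-binomial Wald test per feature, group_b vs group_a.

    Counts are normalized by median-of-ratios size factors; the log fold
    change is computed on pseudocounted group means; the Wald statistic for
    the difference of log group means uses the delta-method variance
    (1/mu + alpha)/n under the NB variance model with a pooled
    method-of-moments dispersion, and is referred to a t distribution with
    n_a + n_b - 2 degrees of freedom to account for the dispersion being
    estimated from few samples.

    Returns a data frame indexed by feature with columns baseMean,
    log2FoldChange, pvalue, qvalue, is_de.
    """
    a_samples = counts.samples_in(group_a)
    b_samples = counts.samples_in(group_b)
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError("each group needs at least 2 samples")
    sf = size_factors(counts)
    norm = counts.values / sf
    g1 = norm[a_samples].to_numpy(dtype=float)
    g2 = norm[b_samples].to_numpy(dtype=float)
    n1, n2 = g1.shape[1], g2.shape[1]
    m1 = g1.mean(axis=1)
    m2 = g2.mean(axis=1)
    base_mean = norm.mean(axis=1).to_numpy()

    alpha = _pooled_dispersion(g1, g2, dispersion_floor)
    pc = pseudocount
    lfc = np.log2((m2 + pc) / (m1 + pc))
    # delta-method variance of the log of a mean of n NB draws
    var_log = (1.0 / (m1 + pc) + alpha) / n1 + (1.0 / (m2 + pc) + alpha) / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.log(m2 + pc) - np.log(m1 + pc)) / np.sqrt(var_log)
    df = n1 + n2 - 2
    pvalue = 2.0 * stats.t.sf(np.abs(z), df)

    all_zero = (m1 == 0) & (m2 == 0)
    pvalue = np.where(all_zero, 1.0, pvalue)
    lfc = np.where(all_zero, 0.0, lfc)

    qvalue = multipletests(pvalue, method="fdr_bh")[1]
    is_de = (np.abs(lfc) > lfc_threshold) & (pvalue < p_threshold)
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": lfc,
            "pvalue": pvalue,
            "qvalue": qvalue,
            "is_de": is_de,
        },
        index=counts.feature_ids.rename("feature_id"),
    )


# -------------------------------------------------------------- LFQ test

def protein_test(
    lfq: OmicsMatrix,
    lfc_threshold: float = LFC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    group_a: str = GROUP_STABLE,
    group_b: str = GROUP_UNSTABLE,
) -> pd.DataFrame:
    """Welch two-sample test on log2 LFQ intensities, group_b vs group_a.

    Zero intensities are treated as missing (not imputed).  Proteins with
    fewer than 2 observed values in either group get p = 1, a ``low_n``
    flag, and are excluded from the BH q computation.
    """
    x = lfq.values.to_numpy(dtype=float)
    logx = np.where(x > 0, np.log2(np.where(x > 0, x, 1.0)), np.nan)
    logdf = pd.DataFrame(logx, index=lfq.feature_ids, columns=lfq.sample_ids)
    g1 = logdf[lfq.samples_in(group_a)].to_numpy()
    g2 = logdf[lfq.samples_in(group_b)].to_numpy()
    n1 = np.sum(~np.isnan(g1), axis=1)
    n2 = np.sum(~np.isnan(g2), axis=1)
    low_n = (n1 < 2) | (n2 < 2)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(g1, axis=1)
        m2 = np.nanmean(g2, axis=1)
        v1 = np.nanvar(g1, axis=1, ddof=1)
        v2 = np.nanvar(g2, axis=1, ddof=1)
    lfc = m2 - m1
    lfc = np.where(np.isnan(lfc), 0.0, lfc)

    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = v1 / n1 + v2 / n2
        tstat = (m2 - m1) / np.sqrt(se2)
        # Welch-Satterthwaite degrees of freedom
        dof = se2**2 / (
            (v1 / n1) ** 2 / np.maximum(n1 - 1, 1)
            + (v2 / n2) ** 2 / np.maximum(n2 - 1, 1)
        )
    pvalue = 2.0 * stats.t.sf(np.abs(tstat), dof)
    # identical groups (zero variance, zero difference) -> no evidence
    pvalue = np.where(np.isnan(pvalue), 1.0, pvalue)
    pvalue = np.where(low_n, 1.0, pvalue)
    lfc = np.where(low_n, 0.0, lfc)

    qvalue = np.full_like(pvalue, np.nan)
    tested = ~low_n
    if tested.any():
        qvalue[tested] = multipletests(pvalue[tested], method="fdr_bh")[1]
    is_de = (np.abs(lfc) > lfc_threshold) & (pvalue < p_threshold) & ~low_n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        base = np.nanmean(np.concatenate([g1, g2], axis=1), axis=1)
    return pd.DataFrame(
        {
            "baseMean": np.where(np.isnan(base), 0.0, base),
            "log2FoldChange": lfc,
            "pvalue": pvalue,
            "qvalue": qvalue,
            "is_de": is_de,
            "low_n": low_n,
        },
        index=lfq.feature_ids.rename("feature_id"),
    )


# ------------------------------------------------------------------- qPCR

def ddct(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    control_group: str = GROUP_STABLE,
) -> pd.DataFrame:
    """Relative expression by the 2^(-ddCt) method.

    ``ct`` needs columns ``sample``, ``group``, ``gene``, ``ct``.  Per
    sample, dCt = Ct(target) - Ct(reference); per group, ddCt is the mean
    dCt minus the control group's mean dCt, and fold = 2^(-ddCt), so the
    control group is 1 by construction.  Samples missing the reference (or
    target) Ct are dropped with a warning.
    """
    required = {"sample", "group", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"ct table needs columns {sorted(required)}")
    wide = ct[ct["gene"].isin([target, reference])].pivot_table(
        index=["sample", "group"], columns="gene", values="ct"
    )
    for gene in (target, reference):
        if gene not in wide.columns:
            wide[gene] = np.nan
    incomplete = wide[target].isna() | wide[reference].isna()
    if incomplete.any():
        dropped = [s for s, _ in wide.index[incomplete]]
        warnings.warn(
            f"dropping samples missing target/reference Ct: {dropped}",
            RuntimeWarning,
        )
        wide = wide[~incomplete]
    if wide.empty:
        raise ValueError("no sample has both target and reference Ct")
    dct = (wide[target] - wide[reference]).rename("dct").reset_index()
    group_dct = dct.groupby("group")["dct"].mean()
    if control_group not in group_dct.index:
        raise ValueError(f"control group {control_group!r} absent from ct table")
    ddct_vals = group_dct - group_dct[control_group]
    return pd.DataFrame(
        {
            "group": ddct_vals.index,
            "ddct": ddct_vals.to_numpy(),
            "fold_change": np.power(2.0, -ddct_vals.to_numpy()),
        }
    ).reset_index(drop=True)
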