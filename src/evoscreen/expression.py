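"""Expression screens: venom-gland gene filtering, concentration statistics,
a negative-binomial Wald differential-expression test, and fold-change/q
classifiers for diet- and sex-biased genes.

The differential test is a transparent stand-in for a full shrinkage-based
NB GLM framework: library sizes are normalised by the median-of-ratios rule,
per-gene dispersions are estimated by the method of moments (floored at a
small positive value), and the Wald statistic on the log2 fold change is
referred to a t distribution with ``n_a + n_b - 2`` degrees of freedom to
keep type-I error calibrated at typical 3-vs-3 replication.  The venom-gland
filter also accepts any precomputed differential-expression table, so a
different tester can be plugged in.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import ValidationError

__all__ = [
    "ExpressionMatrix",
    "bh_adjust",
    "NegativeBinomialWaldTest",
    "nb_de_test",
    "VenomGlandFilter",
    "identify_vggs",
    "cumulative_concentration",
    "classify_biased",
]

_LN2 = math.log(2.0)


class ExpressionMatrix:
    """A genes x samples abundance table with its sample design.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative abundances, index = gene ids (unique), columns = sample
        ids.
    design : pandas.DataFrame
        Columns ``sample_id``, ``group``, ``replicate`` (1-based int);
        (group, replicate) pairs unique; every value column must map to
        exactly one design row.
    unit : {"counts", "FPKM"}
    """

    def __init__(self, values: pd.DataFrame, design: pd.DataFrame, unit: str):
        if unit not in ("counts", "FPKM"):
            raise ValidationError(f"unit must be 'counts' or 'FPKM', got {unit!r}")
        required = {"sample_id", "group", "replicate"}
        missing = required - set(design.columns)
        if missing:
            raise ValidationError(f"design missing columns: {sorted(missing)}")
        if design["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in design")
        if design.duplicated(subset=["group", "replicate"]).any():
            raise ValidationError("duplicate (group, replicate) pairs in design")
        if (design["replicate"] < 1).any():
            raise ValidationError("replicate numbers must be >= 1")
        if values.index.duplicated().any():
            raise ValidationError("duplicate gene ids")
        unmapped = set(values.columns) - set(design["sample_id"])
        if unmapped:
            raise ValidationError(f"columns not in design: {sorted(unmapped)}")
        if (values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")
        self.values = values
        self.design = design.reset_index(drop=True)
        self.unit = unit

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.design["group"]))

    def samples_in_group(self, group: str) -> list[str]:
        ids = self.design.loc[self.design["group"] == group, "sample_id"]
        ids = [s for s in ids if s in self.values.columns]
        if not ids:
            raise ValidationError(f"group {group!r} not present in the design")
        return ids

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.samples_in_group(group)]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Negative-binomial Wald test
# ---------------------------------------------------------------------------

class NegativeBinomialWaldTest(BaseEstimator):
    """Two-group NB Wald test on count data.

    Parameters
    ----------
    group_a, group_b : str
        Design groups to contrast; log2 fold change is A over B.
    dispersion_floor : float, default 1e-8
        Lower bound for the method-of-moments dispersion estimate.
    pseudocount : float, default 0.5
        Added (in normalised-count units) to group means when forming the
        fold change and its standard error, keeping both finite when one
        group is unobserved.

    Attributes
    ----------
    results_ : pandas.DataFrame
        gene_id, base_mean, log2_fold_change, p_value, q_value.
    excluded_ : list of str
        Genes with all-zero counts in both groups, excluded from testing.
    size_factors_ : pandas.Series
        Median-of-ratios library size factors.
    """

    def __init__(
        self,
        group_a: str,
        group_b: str,
        dispersion_floor: float = 1e-8,
        pseudocount: float = 0.5,
    ):
        self.group_a = group_a
        self.group_b = group_b
        self.dispersion_floor = dispersion_floor
        self.pseudocount = pseudocount

    def fit(self, X: ExpressionMatrix, y: None = None) -> "NegativeBinomialWaldTest":
        if X.unit != "counts":
            raise ValidationError("the NB test requires raw counts, not FPKM")
        cols_a = X.samples_in_group(self.group_a)
        cols_b = X.samples_in_group(self.group_b)
        if len(cols_a) < 2 or len(cols_b) < 2:
            raise ValidationError("each group needs at least 2 replicates")

        K = X.values[cols_a + cols_b].to_numpy(dtype=float)
        gene_ids = np.asarray(X.gene_ids)
        keep = K.sum(axis=1) > 0
        self.excluded_ = list(gene_ids[~keep])
        K = K[keep]
        gene_ids = gene_ids[keep]

        s = _median_of_ratios(K)
        self.size_factors_ = pd.Series(s, index=cols_a + cols_b)
        ycounts = K / s

        na, nb = len(cols_a), len(cols_b)
        ya, yb = ycounts[:, :na], ycounts[:, na:]
        ma, mb = ya.mean(axis=1), yb.mean(axis=1)
        va, vb = ya.var(axis=1, ddof=1), yb.var(axis=1, ddof=1)

        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_a = np.where(ma > 0, (va - ma) / ma**2, np.nan)
            alpha_b = np.where(mb > 0, (vb - mb) / mb**2, np.nan)
        wa = np.where(np.isnan(alpha_a), 0.0, na - 1)
        wb = np.where(np.isnan(alpha_b), 0.0, nb - 1)
        num = np.nan_to_num(alpha_a) * wa + np.nan_to_num(alpha_b) * wb
        den = wa + wb
        alpha = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        alpha = np.maximum(alpha, self.dispersion_floor)

        eps = self.pseudocount
        mta, mtb = ma + eps, mb + eps
        log2fc = np.log2(mta / mtb)
        # Delta-method variance of log2 group means under var(y) = m + a m^2.
        var_a = (mta + alpha * mta**2) / (na * mta**2 * _LN2**2)
        var_b = (mtb + alpha * mtb**2) / (nb * mtb**2 * _LN2**2)
        se = np.sqrt(var_a + var_b)
        tstat = np.where(se > 0, log2fc / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(tstat), df=na + nb - 2)
        p = np.clip(p, 0.0, 1.0)
        q = bh_adjust(p)

        self.results_ = pd.DataFrame(
            {
                "gene_id": gene_ids,
                "base_mean": ycounts.mean(axis=1),
                "log2_fold_change": log2fc,
                "p_value": p,
                "q_value": q,
            }
        )
        return self


def _median_of_ratios(K: np.ndarray) -> np.ndarray:
    """DESeq-style library size factors; total-count fallback if no gene is
    positive in every sample."""
    with np.errstate(divide="ignore"):
        logK = np.log(K)
    all_pos = np.all(K > 0, axis=1)
    if all_pos.any():
        log_gm = logK[all_pos].mean(axis=1)
        s = np.exp(np.median(logK[all_pos] - log_gm[:, None], axis=0))
    else:
        tot = K.sum(axis=0)
        s = tot / tot.mean() if tot.mean() > 0 else np.ones(K.shape[1])
    return s / np.exp(np.mean(np.log(s)))


def nb_de_test(
    counts: ExpressionMatrix, group_a: str, group_b: str
) -> pd.DataFrame:
    """Run the NB Wald test and return its per-gene result table."""
    return NegativeBinomialWaldTest(group_a, group_b).fit(counts).results_


# ---------------------------------------------------------------------------
# Venom-gland-associated gene filter
# ---------------------------------------------------------------------------

class VenomGlandFilter(BaseEstimator):
    """Three-criterion tissue-restricted expression filter.

    A gene is venom-gland associated iff it is
    (a) among the ``n_top`` most expressed genes in the venom gland, ranked
    by median FPKM across venom-gland replicates (descending);
    (b) significantly higher in the venom gland than the carcass
    (q < ``q_max`` and log2 fold change > 0, venom gland over carcass); and
    (c) lowly expressed in the carcass (median FPKM strictly below
    ``carcass_fpkm_max``).

    Attributes
    ----------
    records_ : pandas.DataFrame
        One row per gene in the top-``n_top`` set, flagged genes first:
        gene_id, vg_median_fpkm, carcass_median_fpkm, vg_rank, q_value,
        log2_fold_change, passes_a, passes_b, passes_c, is_vgg
        (plus has_signal_peptide when annotations are supplied).
    vggs_ : frozenset of str
    """

    def __init__(
        self,
        n_top: int = 500,
        q_max: float = 0.05,
        carcass_fpkm_max: float = 50.0,
        venom_group: str = "venom_gland",
        carcass_group: str = "carcass",
    ):
        self.n_top = n_top
        self.q_max = q_max
        self.carcass_fpkm_max = carcass_fpkm_max
        self.venom_group = venom_group
        self.carcass_group = carcass_group

    def fit(
        self,
        X: ExpressionMatrix,
        de: pd.DataFrame,
        signal_peptides: pd.DataFrame | None = None,
    ) -> "VenomGlandFilter":
        if X.unit != "FPKM":
            raise ValidationError("the VGG filter requires FPKM values")
        required = {"gene_id", "log2_fold_change", "q_value"}
        missing = required - set(de.columns)
        if missing:
            raise ValidationError(f"DE table missing columns: {sorted(missing)}")

        vg_med = X.group_values(self.venom_group).median(axis=1)
        cc_med = X.group_values(self.carcass_group).median(axis=1)
        df = pd.DataFrame(
            {
                "gene_id": X.gene_ids,
                "vg_median_fpkm": vg_med.to_numpy(),
                "carcass_median_fpkm": cc_med.to_numpy(),
            }
        )
        order = df.sort_values(
            ["vg_median_fpkm", "gene_id"], ascending=[False, True], kind="mergesort"
        ).index
        df["vg_rank"] = 0
        df.loc[order, "vg_rank"] = np.arange(1, len(df) + 1)

        df = df.merge(
            de[["gene_id", "log2_fold_change", "q_value"]], on="gene_id", how="left"
        )
        df["passes_a"] = df["vg_rank"] <= self.n_top
        df["passes_b"] = (df["q_value"] < self.q_max) & (df["log2_fold_change"] > 0)
        df["passes_b"] = df["passes_b"].fillna(False)
        df["passes_c"] = df["carcass_median_fpkm"] < self.carcass_fpkm_max
        df["is_vgg"] = df["passes_a"] & df["passes_b"] & df["passes_c"]

        if signal_peptides is not None:
            sp = signal_peptides[["gene_id", "has_signal_peptide"]]
            df = df.merge(sp, on="gene_id", how="left")

        top = df[df["passes_a"]].sort_values(
            ["is_vgg", "vg_rank"], ascending=[False, True], kind="mergesort"
        )
        self.records_ = top.reset_index(drop=True)
        self.vggs_ = frozenset(top.loc[top["is_vgg"], "gene_id"])
        return self


def identify_vggs(
    fpkm: ExpressionMatrix,
    de: pd.DataFrame,
    n_top: int = 500,
    q_max: float = 0.05,
    carcass_fpkm_max: float = 50.0,
    venom_group: str = "venom_gland",
    carcass_group: str = "carcass",
    signal_peptides: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply the venom-gland filter and return its record table."""
    f = VenomGlandFilter(
        n_top=n_top,
        q_max=q_max,
        carcass_fpkm_max=carcass_fpkm_max,
        venom_group=venom_group,
        carcass_group=carcass_group,
    )
    return f.fit(fpkm, de, signal_peptides=signal_peptides).records_


# ---------------------------------------------------------------------------
# Expression concentration and biased-gene classification
# ---------------------------------------------------------------------------

def cumulative_concentration(
    expression: Sequence[float], fraction: float
) -> int:
    """Minimal number of genes whose summed expression reaches ``fraction``
    of the total (largest values first)."""
    v = np.asarray(expression, dtype=float)
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    if v.size == 0 or (v < 0).any():
        raise ValidationError("expression must be a non-empty non-negative vector")
    total = v.sum()
    if total <= 0:
        raise ValidationError("expression vector is all zero")
    csum = np.cumsum(np.sort(v)[::-1])
    target = fraction * total - 1e-9 * total  # guard float round-off at ties
    return int(np.searchsorted(csum, target) + 1)


def classify_biased(
    de: pd.DataFrame,
    min_fold: float,
    q_max: float = 0.05,
    direction: str = "both",
) -> pd.DataFrame:
    """Genes passing fold change strictly above ``min_fold`` at q strictly
    below ``q_max``, optionally restricted by sign of the log2 fold change.

    ``direction``: "up" (A over B), "down", or "both".
    """
    if not min_fold > 1:
        raise ValidationError("min_fold must be > 1")
    if direction not in ("up", "down", "both"):
        raise ValidationError("direction must be 'up', 'down' or 'both'")
    l2 = de["log2_fold_change"].to_numpy(dtype=float)
    q = de["q_value"].to_numpy(dtype=float)
    fold = 2.0 ** np.abs(l2)
    passing = (fold > min_fold) & (q < q_max)
    if direction == "up":
        passing &= l2 > 0
    elif direction == "down":
        passing &= l2 < 0
    out = de.loc[passing].copy()
    out["fold_change"] = fold[passing]
    return out.reset_index(drop=True)
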