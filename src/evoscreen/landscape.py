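"""Transposable-element divergence landscapes and genome-composition
arithmetic.

Observed mismatch proportions between a TE copy and its family consensus
underestimate the true number of substitutions; the Jukes-Cantor correction
d = -(3/4) ln(1 - (4/3) p) accounts for multiple hits and is defined for
p < 0.75.  Corrected distances (in percent) are pooled into bins of unit
width per TE class, weighting each copy by its genomic span, which
recapitulates the proliferation history of each class.

Genome-composition arithmetic (component percentages, average chromosome
length, assembly size ratios) rounds half-up to one decimal, at the
reporting layer only.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import ValidationError

__all__ = [
    "jc_correct",
    "LandscapeBins",
    "bin_landscape",
    "TELandscape",
    "genome_stats",
    "round_half_up",
]

JC_DOMAIN_MAX = 0.75


def jc_correct(p):
    """Jukes-Cantor distance d = -(3/4) ln(1 - (4/3) p) for proportion p.

    Accepts a scalar or array; requires 0 <= p < 0.75.  d >= p with equality
    only at p = 0.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("divergence proportion must be >= 0")
    if np.any(arr >= JC_DOMAIN_MAX):
        raise ValidationError(
            f"divergence proportion must be < {JC_DOMAIN_MAX} (Jukes-Cantor domain)"
        )
    d = -0.75 * np.log1p(-(4.0 / 3.0) * arr)
    return float(d) if np.isscalar(p) else d


@dataclass
class LandscapeBins:
    """Per-class genomic bp pooled into divergence bins.

    ``table`` is long-format: te_class, bin_left, bin_right (percent units,
    left-closed right-open), bp.  Total bp per class equals the summed spans
    of that class's records.
    """

    bin_width: float
    corrected: bool
    table: pd.DataFrame

    def pivot(self) -> pd.DataFrame:
        """bins x classes wide table of bp, indexed by bin left edge."""
        if self.table.empty:
            return pd.DataFrame()
        return (
            self.table.pivot_table(
                index="bin_left", columns="te_class", values="bp",
                aggfunc="sum", fill_value=0,
            )
            .sort_index()
        )

    def class_totals(self) -> pd.Series:
        return self.table.groupby("te_class")["bp"].sum()


def bin_landscape(
    records: pd.DataFrame, bin_width: float = 1.0, correct: bool = True
) -> LandscapeBins:
    """Pool TE spans into divergence bins per class.

    ``records`` needs columns element_id, te_class, divergence_p (proportion
    of mismatching sites, in [0, 0.75)), span_bp (positive int).  With
    ``correct`` the Jukes-Cantor distance is binned; otherwise the raw
    proportion.  Divergences are expressed in percent and assigned to
    [k*w, (k+1)*w) bins.
    """
    if not bin_width > 0:
        raise ValidationError("bin_width must be > 0")
    required = {"element_id", "te_class", "divergence_p", "span_bp"}
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"TE records missing columns: {sorted(missing)}")
    if records.empty:
        return LandscapeBins(bin_width, correct, pd.DataFrame(
            columns=["te_class", "bin_left", "bin_right", "bp"]))
    p = records["divergence_p"].to_numpy(dtype=float)
    span = records["span_bp"].to_numpy()
    if (span < 1).any():
        raise ValidationError("span_bp must be >= 1")
    if (p < 0).any() or (p >= JC_DOMAIN_MAX).any():
        raise ValidationError(
            "divergence_p outside [0, 0.75); express divergences as proportions"
        )
    d = jc_correct(p) if correct else p
    pct = 100.0 * np.asarray(d, dtype=float)
    k = np.floor(pct / bin_width).astype(int)
    df = pd.DataFrame(
        {
            "te_class": records["te_class"].to_numpy(),
            "bin_left": k * bin_width,
            "bin_right": (k + 1) * bin_width,
            "bp": span,
        }
    )
    table = (
        df.groupby(["te_class", "bin_left", "bin_right"], as_index=False)["bp"]
        .sum()
        .sort_values(["te_class", "bin_left"], kind="mergesort")
        .reset_index(drop=True)
    )
    return LandscapeBins(bin_width=bin_width, corrected=correct, table=table)


class TELandscape(BaseEstimator):
    """Estimator wrapper over :func:`bin_landscape`.

    Parameters: bin_width (percent units, default 1) and jc (apply the
    Jukes-Cantor correction, default True).  ``fit_transform`` returns the
    wide bins x classes bp table; the full result is kept in ``bins_``.
    """

    def __init__(self, bin_width: float = 1.0, jc: bool = True):
        self.bin_width = bin_width
        self.jc = jc

    def fit(self, X: pd.DataFrame, y: None = None) -> "TELandscape":
        self.bins_ = bin_landscape(X, bin_width=self.bin_width, correct=self.jc)
        return self

    def transform(self, X: pd.DataFrame | None = None) -> pd.DataFrame:
        return self.bins_.pivot()

    def fit_transform(self, X: pd.DataFrame, y: None = None) -> pd.DataFrame:
        return self.fit(X).transform()


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (5 rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def genome_stats(
    assembly_size: float,
    components: dict[str, float] | None = None,
    n_chromosomes: int = 1,
    other_assembly_size: float | None = None,
) -> dict:
    """Genome-composition summary with half-up rounding to one decimal.

    All sizes must share one unit (e.g. Mb).  Per component:
    percent = 100 * size / assembly_size.  Average chromosome length =
    assembly_size / n_chromosomes.  Size ratio = assembly_size /
    other_assembly_size when the comparison assembly is given.
    """
    if not assembly_size > 0:
        raise ValidationError("assembly size must be > 0")
    if n_chromosomes < 1:
        raise ValidationError("n_chromosomes must be >= 1")
    components = components or {}
    pct = {}
    for name, size in components.items():
        if size < 0 or size > assembly_size:
            raise ValidationError(
                f"component {name!r} size {size} outside [0, assembly size]"
            )
        pct[name] = round_half_up(100.0 * size / assembly_size, 1)
    out = {
        "assembly_size": assembly_size,
        "component_percent": pct,
        "average_chromosome_length": round_half_up(
            assembly_size / n_chromosomes, 1
        ),
    }
    if other_assembly_size is not None:
        if not other_assembly_size > 0:
            raise ValidationError("comparison assembly size must be > 0")
        out["size_ratio"] = round_half_up(assembly_size / other_assembly_size, 1)
    return out
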