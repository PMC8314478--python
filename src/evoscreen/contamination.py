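"""Windowed taxonomic contamination screen for genome assemblies.

Each contig is split into consecutive, non-overlapping 1000-bp units (the
final, shorter remainder unit is kept and counted like any other); units are
searched externally against a contaminant database and the resulting
12-column tabular hit file is consumed here.  A unit is "matched" if it has
at least one hit at or below the e-value cutoff, and a contig is flagged as
a likely contaminant when the fraction of matched units among all of its
units is strictly greater than the threshold (default 40%).
"""

from __future__ import annotations

import math
import re
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import FastaRecord, HitRecord, ValidationError

__all__ = [
    "UnitRecord",
    "split_into_units",
    "ContigContaminationScreen",
    "screen_contigs",
]

_UNIT_RE = re.compile(r"^(?P<contig>.+)_u(?P<k>\d+)$")


class UnitRecord(NamedTuple):
    """One window of a contig; coordinates are 0-based half-open."""

    id: str
    contig_id: str
    start: int
    end: int
    seq: str


def split_into_units(
    contig: FastaRecord | tuple, unit_size: int = 1000
) -> list[UnitRecord]:
    """Split a contig into consecutive windows of ``unit_size`` bp.

    Unit ids are ``{contig_id}_u{k}`` with k 1-based; the final remainder
    unit (shorter than ``unit_size``) is kept.
    """
    contig = FastaRecord(*contig)
    if unit_size < 1:
        raise ValidationError("unit_size must be >= 1")
    if not contig.seq:
        raise ValidationError(f"contig {contig.id!r} is empty")
    units = []
    for k, start in enumerate(range(0, len(contig.seq), unit_size), start=1):
        end = min(start + unit_size, len(contig.seq))
        units.append(
            UnitRecord(
                id=f"{contig.id}_u{k}",
                contig_id=contig.id,
                start=start,
                end=end,
                seq=contig.seq[start:end],
            )
        )
    return units


class ContigContaminationScreen(BaseEstimator):
    """Flag contigs whose matched-unit fraction exceeds a threshold.

    Parameters
    ----------
    unit_size : int, default 1000
        Window size in bp.
    fraction_threshold : float, default 0.40
        A contig is flagged iff matched_fraction is strictly greater.
    evalue_max : float, default 1e-5
        Hits with larger e-values do not count as matches.
    min_unit_length : int, default 1
        Remainder units shorter than this are dropped from both numerator
        and denominator (default keeps every unit).

    Attributes
    ----------
    calls_ : pandas.DataFrame
        contig_id, length_bp, n_units, n_matched_units, matched_fraction,
        flagged.
    clean_ : list of FastaRecord
        Contigs not flagged (the cleaned assembly).
    flagged_ : list of FastaRecord
        Contigs flagged as likely contaminants.
    """

    def __init__(
        self,
        unit_size: int = 1000,
        fraction_threshold: float = 0.40,
        evalue_max: float = 1e-5,
        min_unit_length: int = 1,
    ):
        self.unit_size = unit_size
        self.fraction_threshold = fraction_threshold
        self.evalue_max = evalue_max
        self.min_unit_length = min_unit_length

    def fit(
        self, X: Sequence[FastaRecord | tuple], hits: Sequence[HitRecord]
    ) -> "ContigContaminationScreen":
        if not 0 < self.fraction_threshold < 1:
            raise ValidationError("fraction_threshold must be in (0, 1)")
        if self.unit_size < 1:
            raise ValidationError("unit_size must be >= 1")
        contigs = [FastaRecord(*c) for c in X]
        unit_ids: set[str] = set()
        rows = []
        for c in contigs:
            units = [
                u
                for u in split_into_units(c, self.unit_size)
                if u.end - u.start >= self.min_unit_length
            ]
            unit_ids.update(u.id for u in units)
            rows.append((c.id, len(c.seq), len(units)))

        matched: set[str] = set()
        unknown: set[str] = set()
        for h in hits:
            if h.query_id not in unit_ids:
                unknown.add(h.query_id)
            elif h.evalue <= self.evalue_max:
                matched.add(h.query_id)
        if unknown:
            raise ValidationError(
                f"hits reference unknown unit ids: {sorted(unknown)[:10]}"
                + ("..." if len(unknown) > 10 else "")
            )

        matched_per_contig: dict[str, int] = {}
        for uid in matched:
            cid = _UNIT_RE.match(uid).group("contig")
            matched_per_contig[cid] = matched_per_contig.get(cid, 0) + 1

        calls = []
        for cid, length, n_units in rows:
            n_matched = matched_per_contig.get(cid, 0)
            frac = n_matched / n_units if n_units else 0.0
            calls.append(
                {
                    "contig_id": cid,
                    "length_bp": length,
                    "n_units": n_units,
                    "n_matched_units": n_matched,
                    "matched_fraction": frac,
                    "flagged": frac > self.fraction_threshold,
                }
            )
        self.calls_ = pd.DataFrame(calls)
        flagged_ids = set(self.calls_.loc[self.calls_["flagged"], "contig_id"])
        self.clean_ = [c for c in contigs if c.id not in flagged_ids]
        self.flagged_ = [c for c in contigs if c.id in flagged_ids]
        return self


def screen_contigs(
    contigs: Sequence[FastaRecord | tuple],
    hits: Sequence[HitRecord],
    unit_size: int = 1000,
    fraction_threshold: float = 0.40,
    evalue_max: float = 1e-5,
    min_unit_length: int = 1,
) -> tuple[pd.DataFrame, list[FastaRecord]]:
    """Run the contamination screen; return (per-contig calls, clean contigs)."""
    screen = ContigContaminationScreen(
        unit_size=unit_size,
        fraction_threshold=fraction_threshold,
        evalue_max=evalue_max,
        min_unit_length=min_unit_length,
    ).fit(contigs, hits)
    return screen.calls_, screen.clean_
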