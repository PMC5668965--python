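"""Correlation-loading extraction of differential metabolites.

After a pairwise OPLS-DA fit, every retained bucket is back-calculated to a
signed Pearson correlation coefficient r between its intensities and the
predictive score vector.  Buckets with |r| above an analytic cutoff -- the
critical value of the Pearson correlation test at a chosen significance
level and degrees of freedom, r_crit = t / sqrt(t^2 + df) -- are significant;
they are assigned to library metabolites by chemical-shift proximity and
aggregated into a per-metabolite coefficient table.  Positive r means a
higher level in the +1-coded (second-named) class of the comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .library import MetaboliteSignature
from .models import LatentModel

__all__ = [
    "CoefficientTable",
    "critical_r",
    "backcalc_bin_coefficients",
    "assign_bins",
    "metabolite_coefficients",
]

log = logging.getLogger(__name__)

_EPS = 1e-12


def critical_r(alpha: float = 0.05, df: int = 10) -> float:
    """Two-tailed critical value of the Pearson correlation coefficient.

    r_crit = t / sqrt(t^2 + df) with t the two-tailed Student-t critical
    value at significance ``alpha`` with ``df`` degrees of freedom.  The
    shipped defaults (alpha=0.05, df=10) give 0.576.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    t = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t / np.sqrt(t * t + df))


def backcalc_bin_coefficients(
    model: LatentModel,
    values: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bucket correlation (and covariance) with the predictive score.

    ``values`` is the matrix the model was fitted on (any column scaling --
    the Pearson correlation is scale-invariant, so the coefficients are on
    the back-calculated, unscaled footing).  Constant columns get r = 0 and
    are flagged via the returned covariance being 0 as well.

    Returns ``(r, covariance)``; the covariance-weighted loading is what a
    colour-coded coefficient plot draws on its y-axis.
    """
    if model.kind != "oplsda":
        raise ValueError("coefficients are defined for pairwise OPLS-DA models")
    x = np.asarray(values, dtype=float)
    t = model.scores[:, 0]
    if x.shape[0] != t.size:
        raise ValueError("matrix and model sample counts disagree")
    xc = x - x.mean(axis=0)
    tc = t - t.mean()
    n = x.shape[0]
    cov = xc.T @ tc / (n - 1)
    sx = np.sqrt((xc * xc).sum(axis=0))
    st = float(np.sqrt((tc * tc).sum()))
    denom = sx * st
    constant = denom <= _EPS
    r = np.zeros(x.shape[1])
    np.divide(xc.T @ tc, denom, out=r, where=~constant)
    cov[constant] = 0.0
    return r, cov


def assign_bins(
    bin_centers: np.ndarray,
    library: Sequence[MetaboliteSignature],
    tolerance: float = 0.01,
) -> list[list[str]]:
    """Candidate metabolites per bucket by chemical-shift proximity.

    A bucket centre matches every non-marker library peak within
    ``tolerance`` ppm; buckets matching nothing get an empty candidate list
    (reported downstream as unassigned).
    """
    centers = np.asarray(bin_centers, dtype=float)
    out: list[set[str]] = [set() for _ in centers]
    for sig in library:
        if sig.is_marker:
            continue
        for peak in sig.peaks:
            close = np.abs(centers - peak.shift_ppm) <= tolerance + 1e-12
            for i in np.flatnonzero(close):
                out[i].add(sig.abbreviation)
    return [sorted(s) for s in out]


@dataclass
class CoefficientTable:
    """Per-metabolite back-calculated coefficients for one pair comparison."""

    comparison: str            # e.g. "BxPC-3 vs SW1990"
    cutoff: float
    table: pd.DataFrame        # abbreviation, name, category, r, significant,
                               # ambiguous, support_ppm, n_bins

    def significant(self, include_ambiguous: bool = True) -> pd.DataFrame:
        sig = self.table[self.table["significant"]]
        if not include_ambiguous:
            sig = sig[~sig["ambiguous"]]
        return sig

    def significant_abbreviations(
        self, include_ambiguous: bool = True
    ) -> set[str]:
        return set(self.significant(include_ambiguous)["abbreviation"])

    def to_frame(self, masked: bool = True) -> pd.DataFrame:
        """Report-style frame; insignificant coefficients rendered as "-"."""
        df = self.table.copy()
        if masked:
            df["r"] = [
                f"{r:.3f}" if sig else "-"
                for r, sig in zip(df["r"], df["significant"])
            ]
        return df

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# comparison: {self.comparison}\n")
            fh.write(f"# cutoff |r| > {self.cutoff:.3f}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def metabolite_coefficients(
    bin_centers: np.ndarray,
    r: np.ndarray,
    assignments: Sequence[Sequence[str]],
    library: Sequence[MetaboliteSignature],
    cutoff: float,
    comparison: str = "",
) -> CoefficientTable:
    """Aggregate per-bucket coefficients into a per-metabolite table.

    Each metabolite takes the maximum-|r| bucket among all buckets assigned
    to it; a call whose best bucket is shared between several candidate
    metabolites is flagged ``ambiguous`` (it still contributes to every
    candidate).  ``significant`` is |r| > cutoff.  Metabolites with no
    assigned bucket are omitted with a log entry.
    """
    centers = np.asarray(bin_centers, dtype=float)
    r = np.asarray(r, dtype=float)
    per_metab: dict[str, list[int]] = {}
    for i, cands in enumerate(assignments):
        for abbr in cands:
            per_metab.setdefault(abbr, []).append(i)

    rows = []
    for sig in library:
        if sig.is_marker:
            continue
        bins = per_metab.get(sig.abbreviation)
        if not bins:
            log.info("%s: no bucket within tolerance; omitted",
                     sig.abbreviation)
            continue
        bins_arr = np.asarray(bins)
        best = bins_arr[int(np.argmax(np.abs(r[bins_arr])))]
        best_r = float(r[best])
        rows.append({
            "abbreviation": sig.abbreviation,
            "name": sig.name,
            "category": sig.category,
            "r": best_r,
            "significant": bool(abs(best_r) > cutoff),
            "ambiguous": len(assignments[best]) > 1,
            "support_ppm": float(centers[best]),
            "n_bins": int(bins_arr.size),
        })
    return CoefficientTable(
        comparison=comparison, cutoff=cutoff, table=pd.DataFrame(rows)
    )
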