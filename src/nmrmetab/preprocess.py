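"""Spectral preprocessing: lactate referencing, binning, normalization.

Frequency-domain serum spectra are referenced to the endogenous lactate
doublet at 1.33 ppm, integrated into 0.002-ppm buckets over 9.0-0.5 ppm with
the residual-water (6.40-5.50 ppm) and urea (5.19-4.36 ppm) windows removed,
and row-normalized to the total retained intensity.  Bucket value = sum of
the intensity samples falling in the half-open interval [left, right); with
a uniform acquisition grid the sum is proportional to the integral and the
proportionality constant cancels under total-sum normalization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "SpectrumRecord",
    "BinnedMatrix",
    "DEFAULT_REGION",
    "DEFAULT_BIN_WIDTH",
    "DEFAULT_EXCLUSIONS",
    "reference_to_lactate",
    "bin_spectrum",
    "build_matrix",
    "total_sum_normalize",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

log = logging.getLogger(__name__)

#: integration region as (high ppm, low ppm)
DEFAULT_REGION: tuple[float, float] = (9.0, 0.5)
DEFAULT_BIN_WIDTH: float = 0.002
#: excluded windows as (high ppm, low ppm): residual water, then urea
DEFAULT_EXCLUSIONS: tuple[tuple[float, float], ...] = ((6.40, 5.50), (5.19, 4.36))


@dataclass
class SpectrumRecord:
    """One sample's frequency-domain spectrum plus metadata."""

    sample_id: str
    group: str
    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must be equal-length 1-D arrays")
        if self.ppm.size < 2:
            raise ValueError("spectrum needs at least two points")
        d = np.diff(self.ppm)
        if np.all(d > 0):
            pass
        elif np.all(d < 0):  # store ascending internally
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        else:
            raise ValueError("ppm axis must be strictly monotone")


def read_spectrum_csv(path: str | Path, sample_id: str | None = None,
                      group: str = "") -> SpectrumRecord:
    df = pd.read_csv(path)
    return SpectrumRecord(
        sample_id=sample_id or Path(path).stem,
        group=group,
        ppm=df["ppm"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
    )


def write_spectrum_csv(spec: SpectrumRecord, path: str | Path) -> None:
    pd.DataFrame({"ppm": spec.ppm, "intensity": spec.intensity}).to_csv(
        path, index=False
    )


def reference_to_lactate(
    spec: SpectrumRecord,
    search_halfwidth: float = 0.05,
    target: float = 1.33,
) -> SpectrumRecord:
    """Shift the ppm axis so the lactate doublet midpoint lands on 1.33 ppm.

    The two tallest local maxima within ``target +- search_halfwidth`` are
    taken as the doublet lines; the axis is translated so their midpoint is
    at ``target``.  If fewer than two local maxima are found, the single
    tallest point in the window is used and a warning is logged.
    """
    lo, hi = target - search_halfwidth, target + search_halfwidth
    mask = (spec.ppm >= lo) & (spec.ppm <= hi)
    if not mask.any():
        raise ValueError(
            f"spectrum does not cover the lactate window [{lo}, {hi}] ppm"
        )
    win_ppm = spec.ppm[mask]
    win_int = spec.intensity[mask]
    peaks, _ = find_peaks(win_int)
    if peaks.size >= 2:
        top = peaks[np.argsort(win_int[peaks])[-2:]]
        midpoint = float(win_ppm[top].mean())
    else:
        log.warning(
            "%s: fewer than two local maxima in lactate window; "
            "falling back to the tallest point", spec.sample_id,
        )
        midpoint = float(win_ppm[np.argmax(win_int)])
    shift = target - midpoint
    return replace(spec, ppm=spec.ppm + shift, intensity=spec.intensity.copy())


def _bin_edges(
    region: tuple[float, float], width: float
) -> np.ndarray:
    hi, lo = max(region), min(region)
    n = (hi - lo) / width
    n_int = round(n)
    if abs(n - n_int) > 1e-9 or n_int < 1:
        raise ValueError(
            f"bin width {width} does not divide the region [{lo}, {hi}]"
        )
    return lo + width * np.arange(n_int + 1)


def _retained_mask(
    edges: np.ndarray,
    exclusions: Iterable[tuple[float, float]],
    width: float,
) -> np.ndarray:
    left, right = edges[:-1], edges[1:]
    keep = np.ones(left.size, dtype=bool)
    tol = 1e-9 * max(1.0, width)
    for win in exclusions:
        whi, wlo = max(win), min(win)
        keep &= ~((left >= wlo - tol) & (right <= whi + tol))
    return keep


def bin_spectrum(
    spec: SpectrumRecord,
    region: tuple[float, float] = DEFAULT_REGION,
    width: float = DEFAULT_BIN_WIDTH,
    exclusions: Sequence[tuple[float, float]] = DEFAULT_EXCLUSIONS,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Integrate a spectrum into fixed-width buckets, dropping excluded windows.

    Returns ``(values, (left_edges, right_edges))`` in descending-ppm report
    order.  Each bucket holds the sum of intensity samples with
    ``left <= ppm < right``; buckets wholly inside an excluded window are
    dropped.  Empty buckets (no data points) are filled by trapezoidal
    interpolation at the bucket centre and a warning is issued.
    """
    edges = _bin_edges(region, width)
    keep = _retained_mask(edges, exclusions, width)

    idx = np.searchsorted(edges, spec.ppm, side="right") - 1
    in_region = (idx >= 0) & (idx < edges.size - 1) & (spec.ppm < edges[-1])
    counts = np.bincount(idx[in_region], minlength=edges.size - 1)
    values = np.bincount(
        idx[in_region], weights=spec.intensity[in_region],
        minlength=edges.size - 1,
    )

    empty = (counts == 0) & keep
    if empty.any():
        warnings.warn(
            f"{spec.sample_id}: {int(empty.sum())} empty bucket(s) filled by "
            "interpolation", stacklevel=2,
        )
        centers = (edges[:-1] + edges[1:]) / 2.0
        spacing = float(np.median(np.diff(spec.ppm)))
        fill = np.interp(centers[empty], spec.ppm, spec.intensity)
        values[empty] = fill * (width / spacing)

    left = edges[:-1][keep][::-1]
    right = edges[1:][keep][::-1]
    return values[keep][::-1], (left, right)


@dataclass
class BinnedMatrix:
    """Samples x retained-buckets intensity matrix with bucket geometry."""

    sample_ids: list[str]
    groups: list[str]
    values: np.ndarray
    left_edges: np.ndarray
    right_edges: np.ndarray
    excluded_windows: tuple[tuple[float, float], ...] = DEFAULT_EXCLUSIONS
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), self.left_edges.size):
            raise ValueError("matrix shape disagrees with ids/edges")
        if len(self.groups) != len(self.sample_ids):
            raise ValueError("groups and sample_ids length mismatch")

    @property
    def centers(self) -> np.ndarray:
        return (self.left_edges + self.right_edges) / 2.0

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_bins(self) -> int:
        return self.left_edges.size

    def group_mask(self, *names: str) -> np.ndarray:
        wanted = set(names)
        return np.array([g in wanted for g in self.groups])

    def subset(self, mask_or_index: np.ndarray) -> "BinnedMatrix":
        arr = np.asarray(mask_or_index)
        idx = np.flatnonzero(arr) if arr.dtype == bool else arr
        return BinnedMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            groups=[self.groups[i] for i in idx],
            values=self.values[idx],
            left_edges=self.left_edges,
            right_edges=self.right_edges,
            excluded_windows=self.excluded_windows,
            normalized=self.normalized,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            columns=[f"{c:.4f}" for c in self.centers],
        )
        df.insert(0, "group", self.groups)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_matrix(
    spectra: Sequence[SpectrumRecord],
    manifest: pd.DataFrame | Mapping[str, str],
    region: tuple[float, float] = DEFAULT_REGION,
    width: float = DEFAULT_BIN_WIDTH,
    exclusions: Sequence[tuple[float, float]] = DEFAULT_EXCLUSIONS,
) -> BinnedMatrix:
    """Bin every spectrum and stack rows in manifest order.

    ``manifest`` maps sample id to group label (mapping, or a DataFrame with
    ``sample_id``/``group`` columns).  Spectra are expected to be referenced
    already.  A manifest entry without a matching spectrum raises an error
    naming the sample.
    """
    if isinstance(manifest, pd.DataFrame):
        order = list(manifest["sample_id"])
        group_of = dict(zip(manifest["sample_id"], manifest["group"]))
    else:
        group_of = dict(manifest)
        order = list(group_of)
    specs = {s.sample_id: s for s in spectra}
    missing = [sid for sid in specs if sid not in group_of]
    if missing:
        raise ValueError(f"spectra missing from manifest: {missing}")
    absent = [sid for sid in order if sid not in specs]
    if absent:
        raise ValueError(f"manifest samples without spectra: {absent}")

    rows = []
    edges: tuple[np.ndarray, np.ndarray] | None = None
    for sid in order:
        vals, e = bin_spectrum(specs[sid], region=region, width=width,
                               exclusions=exclusions)
        rows.append(vals)
        edges = e
    assert edges is not None
    return BinnedMatrix(
        sample_ids=order,
        groups=[group_of[sid] for sid in order],
        values=np.vstack(rows),
        left_edges=edges[0],
        right_edges=edges[1],
        excluded_windows=tuple((max(w), min(w)) for w in exclusions),
        normalized=False,
    )


def total_sum_normalize(m: BinnedMatrix) -> BinnedMatrix:
    """Divide each row by its own sum (probabilistic-quotient-free TSN)."""
    if m.normalized:
        raise ValueError("matrix is already normalized")
    sums = m.values.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        names = [m.sample_ids[i] for i in bad]
        raise ValueError(f"non-positive total intensity for sample(s) {names}")
    return BinnedMatrix(
        sample_ids=list(m.sample_ids),
        groups=list(m.groups),
        values=m.values / sums[:, None],
        left_edges=m.left_edges,
        right_edges=m.right_edges,
        excluded_windows=m.excluded_windows,
        normalized=True,
    )
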