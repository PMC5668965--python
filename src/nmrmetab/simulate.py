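"""Synthetic serum cohort generator with known ground truth.

Emulates already-processed (Fourier-transformed, phased, baseline-corrected)
500-MHz CPMG serum spectra for a three-group xenograft-style study design:
Panc-1 (n=12), BxPC-3 (n=13) and SW1990 (n=11).  Per-sample metabolite
concentrations are drawn log-normally around group means; each metabolite is
rendered as Lorentzian multiplets at its library chemical shifts with a
3.5-kHz-style J coupling (7 Hz at 500.13 MHz), small per-peak shift jitter,
a per-sample global referencing offset and additive Gaussian noise.  CPMG
attenuation of macromolecule signal is emulated by the broad (``br``)
linewidths of the lipoprotein/glycoprotein signatures rather than by
time-domain modelling.

The default group effect directions are derived from the bundled reference
coefficient table: metabolites of glycolysis/glutaminolysis and the amino
acids are elevated in the well-differentiated SW1990 group, choline species
in the poorly differentiated Panc-1 group.  Each non-zero direction is one
2-fold step; inconsistent three-way sign patterns are reconciled by least
squares, which yields intermediate effect sizes for a few metabolites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library import MetaboliteSignature, by_abbreviation, load_library
from .preprocess import SpectrumRecord

__all__ = [
    "CohortDesign",
    "GroundTruth",
    "default_design",
    "null_design",
    "default_axis",
    "sample_concentrations",
    "render_spectrum",
    "generate_cohort",
    "BASE_CONCENTRATIONS",
    "GROUPS",
    "COMPARISONS",
]

#: study groups in manifest order (poor -> moderate/well differentiated)
GROUPS: tuple[str, ...] = ("Panc-1", "BxPC-3", "SW1990")
#: pairwise comparisons as (first, second); positive effects favour `second`
COMPARISONS: tuple[tuple[str, str], ...] = (
    ("Panc-1", "SW1990"),
    ("BxPC-3", "SW1990"),
    ("Panc-1", "BxPC-3"),
)
_REFERENCE_COLUMNS = {
    ("BxPC-3", "SW1990"): "bxpc3_vs_sw1990",
    ("Panc-1", "SW1990"): "panc1_vs_sw1990",
    ("Panc-1", "BxPC-3"): "panc1_vs_bxpc3",
}

#: proton frequency (MHz) and J couplings expressed in ppm
PROTON_MHZ = 500.13
J_MAIN_PPM = 7.0 / PROTON_MHZ
J_SMALL_PPM = 3.0 / PROTON_MHZ

#: reference concentration of each signature (arbitrary integral units);
#: glucose and lipoproteins dominate, as in CPMG serum spectra
BASE_CONCENTRATIONS: dict[str, float] = {
    "α-Glc": 0.35, "β-Glc": 0.65, "Lac": 0.30,
    "L1": 0.10, "L2": 0.10, "L3": 0.06,
    "NAG": 0.12, "Gln": 0.10, "Glu": 0.08, "Ala": 0.08, "Lys": 0.07,
    "G": 0.06, "Cr": 0.06, "Gly": 0.06, "Leu": 0.06,
    "Val": 0.05, "Thr": 0.05, "3-HB": 0.05,
    "Ace": 0.04, "Cit": 0.04,
    "Eth": 0.03, "m-I": 0.03, "PC": 0.03, "Bet": 0.03, "Ile": 0.03,
    "Act": 0.02, "Py": 0.02, "Cho": 0.02, "GPC": 0.02, "Tyr": 0.02,
    "Phe": 0.02, "His": 0.02, "Met": 0.02, "1-MH": 0.02,
    "Trp": 0.015, "AA": 0.015,
    "Suc": 0.01, "Mol": 0.01, "TMA": 0.01, "MG": 0.01, "All": 0.01,
    "Mal": 0.01, "IB": 0.01, "For": 0.008, "Fum": 0.006,
    "HOD": 0.50, "Urea": 0.05,
}


@dataclass(frozen=True)
class CohortDesign:
    """Everything needed to draw one reproducible synthetic cohort."""

    group_names: tuple[str, ...] = GROUPS
    group_sizes: tuple[int, ...] = (12, 13, 11)
    #: abbreviation -> group -> log2 fold change vs the base concentration
    effect_map: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    base_concentrations: Mapping[str, float] = field(
        default_factory=lambda: dict(BASE_CONCENTRATIONS)
    )
    #: sd of per-sample log2 concentration (biological variation)
    conc_dispersion_log2: float = 0.2
    #: additive spectral noise sd (intensity units)
    noise_sd: float = 0.05
    #: per-peak chemical-shift jitter sd (ppm)
    shift_jitter_sd: float = 0.001
    #: per-sample global referencing offset sd (ppm), removed by referencing
    reference_offset_sd: float = 0.003
    #: Lorentzian FWHM (ppm); 0.004 ppm ~ 2 Hz at 500 MHz
    linewidth_ppm: float = 0.004
    baseline_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_names) != len(self.group_sizes):
            raise ValueError("group_names and group_sizes length mismatch")
        if any(n < 3 for n in self.group_sizes):
            raise ValueError("every group needs at least 3 samples")
        if not self.linewidth_ppm > 0:
            raise ValueError("linewidth_ppm must be positive")
        if self.conc_dispersion_log2 < 0 or self.noise_sd < 0:
            raise ValueError("dispersion and noise must be non-negative")
        unknown = set(self.effect_map) - set(self.base_concentrations)
        if unknown:
            raise ValueError(f"effect_map keys without base level: {unknown}")

    def validate_against(self, library: Sequence[MetaboliteSignature]) -> None:
        known = {s.abbreviation for s in library}
        unknown = set(self.effect_map) - known
        if unknown:
            raise ValueError(f"effect_map keys not in library: {unknown}")

    def group_mean(self, abbr: str, group: str) -> float:
        fc = self.effect_map.get(abbr, {}).get(group, 0.0)
        return self.base_concentrations[abbr] * 2.0 ** fc


def _load_reference_signs() -> pd.DataFrame:
    ref = resources.files("nmrmetab.data").joinpath("reference_coefficients.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def _levels_from_signs(
    signs: Mapping[tuple[str, str], float],
    groups: Sequence[str],
    step: float,
) -> dict[str, float]:
    """Per-group log2 levels reconciling a pairwise sign pattern.

    Each non-zero sign contributes the constraint L[b] - L[a] = step * sign;
    a zero sign constrains equality.  Solved by least squares with the group
    levels anchored to sum to zero, so inconsistent triangles (which occur in
    the reference table) are softened rather than rejected.
    """
    gi = {g: i for i, g in enumerate(groups)}
    rows, rhs = [], []
    for (a, b), s in signs.items():
        row = np.zeros(len(groups))
        row[gi[b]] = 1.0
        row[gi[a]] = -1.0
        rows.append(row)
        rhs.append(step * s)
    rows.append(np.ones(len(groups)))
    rhs.append(0.0)
    sol, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
    return {g: float(sol[gi[g]]) for g in groups}


def default_design(
    convention: str = "discussion",
    step_log2: float = 1.0,
    seed: int = 0,
    **overrides,
) -> CohortDesign:
    """The shipped three-group design with reference effect directions.

    ``convention`` resolves the reporting ambiguity for the direction of the
    glycolysis/amino-acid differences: ``"discussion"`` (default) takes a
    positive coefficient in comparison "A vs B" to mean a higher
    concentration in B (SW1990 elevated), ``"results"`` flips every
    direction.  ``step_log2`` is the fold-change step per sign unit
    (default one 2-fold step).
    """
    if convention not in ("discussion", "results"):
        raise ValueError("convention must be 'discussion' or 'results'")
    flip = -1.0 if convention == "results" else 1.0
    ref = _load_reference_signs()
    effect_map: dict[str, dict[str, float]] = {}
    for _, row in ref.iterrows():
        signs: dict[tuple[str, str], float] = {}
        for pair, col in _REFERENCE_COLUMNS.items():
            val = row[col]
            signs[pair] = flip * float(np.sign(val)) if pd.notna(val) else 0.0
        effect_map[row["abbreviation"]] = _levels_from_signs(
            signs, GROUPS, step_log2
        )
    return CohortDesign(effect_map=effect_map, seed=seed, **overrides)


def null_design(seed: int = 0, **overrides) -> CohortDesign:
    """Default design with every effect zeroed (no group differences)."""
    return CohortDesign(effect_map={}, seed=seed, **overrides)


def default_axis(n_points: int = 12288, lo: float = -0.5,
                 hi: float = 10.0) -> np.ndarray:
    """Default ppm grid: 12k points over -0.5..10 ppm (6-kHz-style window)."""
    return np.linspace(lo, hi, n_points)


@dataclass
class GroundTruth:
    """True per-sample concentrations and the designed differential sets."""

    concentrations: pd.DataFrame  # index sample_id, columns abbreviations
    group_means: pd.DataFrame     # index group
    manifest: pd.DataFrame        # sample_id, group
    design: CohortDesign
    marker_abbreviations: frozenset[str] = frozenset({"HOD", "Urea"})

    def log2_delta(self, first: str, second: str) -> pd.Series:
        """log2 group-mean difference (second minus first) per metabolite."""
        delta = np.log2(self.group_means.loc[second]) - np.log2(
            self.group_means.loc[first]
        )
        return delta.drop(labels=self.marker_abbreviations, errors="ignore")

    def differential(
        self, first: str, second: str, min_abs_log2: float = 1.0
    ) -> dict[str, int]:
        """Metabolites with at least ``min_abs_log2`` effect, with direction.

        The sign follows the coefficient convention: +1 means higher in
        ``second`` (the +1-coded class of the pairwise model).
        """
        delta = self.log2_delta(first, second)
        hits = delta[delta.abs() >= min_abs_log2 - 1e-9]
        return {a: int(np.sign(v)) for a, v in hits.items()}

    def null_metabolites(
        self, first: str, second: str, tol: float = 1e-9
    ) -> set[str]:
        delta = self.log2_delta(first, second)
        return set(delta[delta.abs() <= tol].index)


def sample_concentrations(
    design: CohortDesign, rng: np.random.Generator
) -> GroundTruth:
    """Draw per-sample concentrations log-normally around the group means."""
    abbrs = list(design.base_concentrations)
    sample_ids: list[str] = []
    groups: list[str] = []
    rows: list[np.ndarray] = []
    means = {
        g: np.array([design.group_mean(a, g) for a in abbrs])
        for g in design.group_names
    }
    for g, n in zip(design.group_names, design.group_sizes):
        noise = rng.normal(0.0, design.conc_dispersion_log2, size=(n, len(abbrs)))
        conc = means[g] * 2.0 ** noise
        for i in range(n):
            sample_ids.append(f"{g}_{i + 1:02d}")
            groups.append(g)
            rows.append(conc[i])
    manifest = pd.DataFrame({"sample_id": sample_ids, "group": groups})
    return GroundTruth(
        concentrations=pd.DataFrame(rows, index=sample_ids, columns=abbrs),
        group_means=pd.DataFrame(
            [means[g] for g in design.group_names],
            index=list(design.group_names), columns=abbrs,
        ),
        manifest=manifest,
        design=design,
    )


def _multiplet_lines(multiplicity: str) -> list[tuple[float, float, float]]:
    """(offset ppm, intensity fraction, linewidth factor) per resonance line.

    Adjacent lines of first-order multiplets are separated by J (7 Hz);
    ``dd`` adds a 3-Hz splitting; ``m``/``br`` collapse to one broadened line.
    """
    j, j2 = J_MAIN_PPM, J_SMALL_PPM
    if multiplicity == "s":
        return [(0.0, 1.0, 1.0)]
    if multiplicity == "d":
        return [(-j / 2, 0.5, 1.0), (j / 2, 0.5, 1.0)]
    if multiplicity == "t":
        return [(-j, 0.25, 1.0), (0.0, 0.5, 1.0), (j, 0.25, 1.0)]
    if multiplicity == "q":
        return [
            (-1.5 * j, 0.125, 1.0), (-0.5 * j, 0.375, 1.0),
            (0.5 * j, 0.375, 1.0), (1.5 * j, 0.125, 1.0),
        ]
    if multiplicity in ("dd", "ddb"):
        wf = 2.0 if multiplicity == "ddb" else 1.0
        return [
            ((sj * j + sj2 * j2) / 2, 0.25, wf)
            for sj in (-1, 1) for sj2 in (-1, 1)
        ]
    if multiplicity == "m":
        return [(0.0, 1.0, 2.5)]
    if multiplicity == "br":
        return [(0.0, 1.0, 6.0)]
    raise ValueError(f"unknown multiplicity {multiplicity!r}")


def render_spectrum(
    concentrations: Mapping[str, float],
    library: Sequence[MetaboliteSignature],
    axis: np.ndarray,
    design: CohortDesign,
    rng: np.random.Generator | None = None,
    sample_id: str = "sample",
    group: str = "",
    global_shift: float = 0.0,
) -> SpectrumRecord:
    """Render one spectrum: sum of unit-area Lorentzian multiplets plus noise.

    intensity(d) = sum_metab conc * sum_peaks weight * multiplet(d) with the
    multiplet centred at the library shift plus jitter and ``global_shift``.
    Each metabolite's total spectral area equals its concentration, so the
    rendering is exactly linear in the concentration vector.  Peaks whose
    centre falls outside the axis are clipped with a warning.
    """
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2 or not np.all(np.diff(axis) > 0):
        raise ValueError("axis must be a strictly increasing 1-D ppm grid")
    intensity = np.zeros_like(axis)
    for sig in library:
        conc = float(concentrations.get(sig.abbreviation, 0.0))
        if conc == 0.0:
            continue
        for peak in sig.peaks:
            jitter = (
                rng.normal(0.0, design.shift_jitter_sd)
                if rng is not None and design.shift_jitter_sd > 0
                else 0.0
            )
            center0 = peak.shift_ppm + jitter + global_shift
            if not axis[0] <= center0 <= axis[-1]:
                warnings.warn(
                    f"{sig.abbreviation} peak at {center0:.3f} ppm outside "
                    "axis; clipped", stacklevel=2,
                )
                continue
            for off, frac, wf in _multiplet_lines(peak.multiplicity):
                hw = design.linewidth_ppm * wf / 2.0
                area = conc * peak.weight * frac
                d = axis - (center0 + off)
                intensity += area * (hw / np.pi) / (d * d + hw * hw)
    if design.baseline_amplitude > 0 and rng is not None:
        x = np.linspace(-1.0, 1.0, axis.size)
        coeffs = rng.uniform(-1.0, 1.0, size=4) * design.baseline_amplitude
        intensity += np.clip(np.polyval(coeffs, x), 0.0, None)
    if design.noise_sd > 0 and rng is not None:
        intensity = intensity + rng.normal(0.0, design.noise_sd, size=axis.size)
    return SpectrumRecord(sample_id=sample_id, group=group,
                          ppm=axis.copy(), intensity=intensity)


def generate_cohort(
    design: CohortDesign,
    library: Sequence[MetaboliteSignature] | None = None,
    axis: np.ndarray | None = None,
) -> tuple[list[SpectrumRecord], GroundTruth, pd.DataFrame]:
    """Draw a full cohort: one spectrum per sample, fully seeded.

    Returns ``(spectra, ground_truth, manifest)``; identical seeds give
    byte-identical outputs.
    """
    if library is None:
        library = load_library()
    if axis is None:
        axis = default_axis()
    design.validate_against(library)
    sigs = by_abbreviation(library)
    missing = set(design.base_concentrations) - set(sigs)
    if missing:
        raise ValueError(f"base concentrations without signatures: {missing}")
    rng = np.random.default_rng(design.seed)
    truth = sample_concentrations(design, rng)
    spectra: list[SpectrumRecord] = []
    for sid, grp in zip(truth.manifest["sample_id"], truth.manifest["group"]):
        offset = (
            rng.normal(0.0, design.reference_offset_sd)
            if design.reference_offset_sd > 0 else 0.0
        )
        spectra.append(
            render_spectrum(
                truth.concentrations.loc[sid].to_dict(), library, axis,
                design, rng=rng, sample_id=sid, group=grp,
                global_shift=offset,
            )
        )
    return spectra, truth, truth.manifest.copy()
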