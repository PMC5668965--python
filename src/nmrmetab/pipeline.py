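"""End-to-end orchestration: simulate -> preprocess -> model -> diff -> enrich.

The tested surface is tabular: a normalized bucket matrix (TSV), overview
PCA/PLS-DA scores (TSV), per-comparison OPLS-DA diagnostics (JSON) with the
permutation summary (TSV), a combined per-metabolite coefficient table
mirroring the classic "one signed r column per pair comparison" layout, and
per-comparison enrichment tables.  A JSON run manifest echoes the full
configuration, seed and per-stage timings.  Everything is deterministic
given the seed; plots are optional renderings of the TSV artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import (
    CoefficientTable,
    assign_bins,
    backcalc_bin_coefficients,
    critical_r,
    metabolite_coefficients,
)
from .enrichment import enrich, results_to_frame
from .library import MetaboliteSignature, load_library, load_pathway_map
from .models import (
    CvAnovaResult,
    CvResult,
    LatentModel,
    ModelSpec,
    PermutationResult,
    cross_validated_q2,
    cv_anova,
    fit_pca,
    fit_plsda,
    permutation_test,
    scale_matrix,
)
from .preprocess import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_EXCLUSIONS,
    DEFAULT_REGION,
    BinnedMatrix,
    SpectrumRecord,
    build_matrix,
    read_spectrum_csv,
    reference_to_lactate,
    total_sum_normalize,
    write_spectrum_csv,
)
from .simulate import COMPARISONS, default_design, generate_cohort

__all__ = [
    "RunConfig",
    "ComparisonResult",
    "preprocess_spectra",
    "compare_groups",
    "run_all",
]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters; the defaults reproduce the reference method

    (0.002-ppm buckets over 9.0-0.5 ppm, water/urea exclusions, total-sum
    normalization, mean-centred PCA, Pareto-scaled PLS/OPLS, 10-fold CV,
    200 permutations, cutoff from alpha=0.05 at df=10, enrichment p<0.01).
    """

    output_dir: str = "nmrmetab_run"
    input_dir: str | None = None       # per-sample CSVs + manifest.csv
    simulate: bool = True              # generate the default cohort if no input
    seed: int = 0
    # preprocessing
    region: tuple[float, float] = DEFAULT_REGION
    bin_width: float = DEFAULT_BIN_WIDTH
    exclusions: tuple[tuple[float, float], ...] = DEFAULT_EXCLUSIONS
    reference_halfwidth: float = 0.05
    # models
    pca_components: int = 2
    pls_components: int = 2
    n_orth: int = 1
    cv_folds: int = 10
    n_permutations: int = 200
    scaling_pca: str = "mean_center"
    scaling_pls: str = "pareto"
    # differential cutoff
    alpha: float = 0.05
    df: int = 10
    assign_tolerance: float = 0.01
    # enrichment
    enrich_threshold: float = 0.01
    pathway_map_path: str | None = None
    library_path: str | None = None
    # ordered (first, second) pairs; None = the three default comparisons
    comparisons: tuple[tuple[str, str], ...] | None = None

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["region"] = list(self.region)
        d["exclusions"] = [list(w) for w in self.exclusions]
        if self.comparisons is not None:
            d["comparisons"] = [list(c) for c in self.comparisons]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "region" in d:
            d["region"] = tuple(d["region"])
        if "exclusions" in d:
            d["exclusions"] = tuple(tuple(w) for w in d["exclusions"])
        if d.get("comparisons") is not None:
            d["comparisons"] = tuple(tuple(c) for c in d["comparisons"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def preprocess_spectra(
    spectra: Sequence[SpectrumRecord],
    manifest: pd.DataFrame,
    config: RunConfig | None = None,
) -> BinnedMatrix:
    """Reference, bucket and total-sum normalize a set of spectra."""
    config = config or RunConfig()
    referenced = [
        reference_to_lactate(s, search_halfwidth=config.reference_halfwidth)
        for s in spectra
    ]
    matrix = build_matrix(
        referenced, manifest, region=config.region, width=config.bin_width,
        exclusions=config.exclusions,
    )
    return total_sum_normalize(matrix)


@dataclass
class ComparisonResult:
    """Everything the pipeline derives from one ordered pair of groups."""

    first: str
    second: str
    model: LatentModel
    cv: CvResult
    anova: CvAnovaResult
    permutation: PermutationResult | None
    bin_r: np.ndarray
    bin_cov: np.ndarray
    coefficients: CoefficientTable
    cutoff: float

    @property
    def label(self) -> str:
        return f"{self.first} vs {self.second}"

    def diagnostics(self) -> dict:
        d = {
            "comparison": self.label,
            "r2x": self.model.r2x,
            "r2y": self.model.r2y,
            "q2": self.cv.q2,
            "cutoff": self.cutoff,
            "cv_anova_F": self.anova.f_statistic,
            "cv_anova_p": self.anova.p_value,
            "n_orthogonal": self.model.n_orthogonal,
        }
        if self.permutation is not None:
            d.update({
                "p_q2": self.permutation.p_q2,
                "r2_intercept": self.permutation.r2_intercept,
                "q2_intercept": self.permutation.q2_intercept,
                "n_permutations": self.permutation.n_permutations,
            })
        return d


def compare_groups(
    matrix: BinnedMatrix,
    first: str,
    second: str,
    library: Sequence[MetaboliteSignature],
    config: RunConfig | None = None,
    run_permutation: bool = True,
) -> ComparisonResult:
    """Pairwise OPLS-DA with diagnostics and the coefficient table.

    Samples of ``first`` are coded -1 and ``second`` +1, so positive
    coefficients mean a higher level in ``second``.
    """
    config = config or RunConfig()
    pair = matrix.subset(matrix.group_mask(first, second))
    # enforce coding order (first -> -1, second -> +1) regardless of input order
    idx = np.argsort([0 if g == first else 1 for g in pair.groups],
                     kind="stable")
    pair = pair.subset(idx)
    groups = np.asarray(pair.groups)
    spec = ModelSpec(kind="oplsda", n_orth=config.n_orth,
                     scaling=config.scaling_pls)
    xs, scaling = scale_matrix(pair.values, spec.scaling)
    model = spec.fit(xs, groups, scaling=scaling)
    cv = cross_validated_q2(pair.values, groups, spec, k=config.cv_folds,
                            seed=config.seed)
    anova = cv_anova(cv)
    permutation = None
    if run_permutation:
        permutation = permutation_test(
            pair.values, groups, spec, n=config.n_permutations,
            k=config.cv_folds, seed=config.seed,
        )
    r, cov = backcalc_bin_coefficients(model, pair.values)
    cutoff = critical_r(config.alpha, config.df)
    assignments = assign_bins(pair.centers, library,
                              tolerance=config.assign_tolerance)
    coefficients = metabolite_coefficients(
        pair.centers, r, assignments, library, cutoff,
        comparison=f"{first} vs {second}",
    )
    return ComparisonResult(
        first=first, second=second, model=model, cv=cv, anova=anova,
        permutation=permutation, bin_r=r, bin_cov=cov,
        coefficients=coefficients, cutoff=cutoff,
    )


def _combined_coefficient_table(
    results: Sequence[ComparisonResult],
) -> pd.DataFrame:
    """One row per metabolite, one masked signed-r column per comparison."""
    base: pd.DataFrame | None = None
    for res in results:
        col = res.label
        df = res.coefficients.table[
            ["abbreviation", "name", "category", "r", "significant"]
        ].copy()
        df[col] = [
            f"{r:.3f}" if sig else "-"
            for r, sig in zip(df["r"], df["significant"])
        ]
        df = df[["abbreviation", "name", "category", col]]
        base = df if base is None else base.merge(
            df, on=["abbreviation", "name", "category"], how="outer"
        )
    return base if base is not None else pd.DataFrame()


def _slug(text: str) -> str:
    return text.replace(" ", "_").replace("/", "-")


def run_all(config: RunConfig) -> Path:
    """Run the full pipeline into ``config.output_dir``; returns that path.

    Stages: obtain spectra (simulated default cohort, or read from
    ``input_dir``), preprocess into the normalized bucket matrix, fit the
    PCA/PLS-DA overview, run every pairwise OPLS-DA with CV, CV-ANOVA and
    permutation diagnostics, extract the coefficient tables, and run pathway
    over-representation per comparison.  Output TSVs are byte-identical
    across runs with the same config and seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    library = load_library(config.library_path)
    pathway_map = load_pathway_map(config.pathway_map_path)

    t0 = time.perf_counter()
    if config.input_dir is not None:
        in_dir = Path(config.input_dir)
        manifest_path = in_dir / "manifest.csv"
        if not manifest_path.exists():
            raise FileNotFoundError(f"required file missing: {manifest_path}")
        manifest = pd.read_csv(manifest_path)
        spectra = []
        for sid, grp in zip(manifest["sample_id"], manifest["group"]):
            spath = in_dir / f"{sid}.csv"
            if not spath.exists():
                raise FileNotFoundError(f"required spectrum missing: {spath}")
            spectra.append(read_spectrum_csv(spath, sample_id=sid, group=grp))
    elif config.simulate:
        design = default_design(seed=config.seed)
        spectra, truth, manifest = generate_cohort(design, library=library)
        sim_dir = out / "simulated"
        sim_dir.mkdir(exist_ok=True)
        manifest.to_csv(sim_dir / "manifest.csv", index=False)
        truth.concentrations.rename_axis("sample_id").reset_index().melt(
            id_vars="sample_id", var_name="abbreviation",
            value_name="concentration",
        ).to_csv(sim_dir / "ground_truth.csv", index=False)
        for spec_rec in spectra:
            write_spectrum_csv(spec_rec, sim_dir / f"{spec_rec.sample_id}.csv")
    else:
        raise ValueError("no input_dir given and simulation disabled")
    timings["acquire_spectra"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    matrix = preprocess_spectra(spectra, manifest, config)
    matrix.to_tsv(out / "matrix.tsv")
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    xs_pca, _ = scale_matrix(matrix.values, config.scaling_pca)
    pca = fit_pca(xs_pca, n_components=config.pca_components)
    xs_pls, _ = scale_matrix(matrix.values, config.scaling_pls)
    plsda = fit_plsda(xs_pls, matrix.groups,
                      n_components=config.pls_components)
    for name, model in (("pca", pca), ("plsda", plsda)):
        sdf = pd.DataFrame(
            model.scores,
            columns=[f"t{i + 1}" for i in range(model.scores.shape[1])],
        )
        sdf.insert(0, "group", matrix.groups)
        sdf.insert(0, "sample_id", matrix.sample_ids)
        sdf.to_csv(out / f"{name}_scores.tsv", sep="\t", index=False)
    overview = {
        "pca": {"r2x": pca.r2x,
                "r2x_per_component": pca.r2x_per_component.tolist()},
        "plsda": {"r2x": plsda.r2x, "r2y": plsda.r2y},
    }
    (out / "overview.json").write_text(json.dumps(overview, indent=2))
    timings["overview_models"] = time.perf_counter() - t0

    comparisons = config.comparisons or COMPARISONS
    results: list[ComparisonResult] = []
    for first, second in comparisons:
        t0 = time.perf_counter()
        res = compare_groups(matrix, first, second, library, config)
        results.append(res)
        cdir = out / f"comparison_{_slug(first)}_vs_{_slug(second)}"
        cdir.mkdir(exist_ok=True)
        (cdir / "diagnostics.json").write_text(
            json.dumps(res.diagnostics(), indent=2)
        )
        pd.DataFrame({
            "ppm": matrix.centers,
            "r": res.bin_r,
            "covariance": res.bin_cov,
        }).to_csv(cdir / "bin_coefficients.tsv", sep="\t", index=False)
        res.coefficients.to_tsv(cdir / "coefficients.tsv")
        if res.permutation is not None:
            res.permutation.to_frame().to_csv(
                cdir / "permutation.tsv", sep="\t", index=False
            )
        query = res.coefficients.significant_abbreviations()
        annotated = query & pathway_map.universe
        enr = enrich(annotated, pathway_map,
                     threshold=config.enrich_threshold)
        results_to_frame(enr).to_csv(cdir / "enrichment.tsv", sep="\t",
                                     index=False)
        timings[f"compare_{_slug(first)}_vs_{_slug(second)}"] = (
            time.perf_counter() - t0
        )
        log.info("%s: R2Y=%.3f Q2=%.3f p_Q2=%s", res.label, res.model.r2y,
                 res.cv.q2,
                 None if res.permutation is None else res.permutation.p_q2)

    _combined_coefficient_table(results).to_csv(
        out / "coefficient_table.tsv", sep="\t", index=False
    )
    run_manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "cutoff": critical_r(config.alpha, config.df),
        "config": config.to_dict(),
        "timings_s": timings,
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2))
    return out
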