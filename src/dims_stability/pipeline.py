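"""End-to-end orchestration: config, validation, pipeline run, manifest.

A run either loads a library/design/peak-table triple from files or
generates a synthetic study from a generator block, then annotates, computes
sILC QC variability, classifies per-metabolite storage stability against the
analysis-variability band and runs the feature-wise statistics battery.
All interchange is headered CSV/TSV plus JSON; re-running the same config
and seed gives byte-identical outputs, and a run can be regenerated from its
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .adducts import SCAN_WINDOW
from .annotation import AnnotatedMatrix, match_peaks, summed_intensities
from .library import MetaboliteLibrary, generate_library
from .qc import silc_qc_table, variability_bands
from .stability import (
    compute_stability,
    count_affected,
    extreme_records,
    stability_plot_table,
)
from .stats import feature_tests, pca
from .synthetic import (
    DEFAULT_GRID,
    REFERENCE_SERIES,
    EffectSpec,
    StudyDesign,
    generate_design,
    read_peak_tables,
    simulate_peak_tables,
    write_peak_tables,
)

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Pipeline configuration.

    Either ``library_path``/``design_path``/``peaks_path`` are all set, or a
    ``generator`` block describes the synthetic study to create.
    """

    seed: int = 0
    out_dir: str = "results/run"
    tol_ppm: float = 2.0
    ci_method: str = "t"  # "t" | "minmax"
    replicate_agg: str = "mean"  # "mean" | "median"
    quantile_method: str = "linear"
    panel_only: bool = False
    library_path: str | None = None
    design_path: str | None = None
    peaks_path: str | None = None
    generator: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise ValueError("tolerance must be positive")
        paths = (self.library_path, self.design_path, self.peaks_path)
        if any(paths) and not all(paths):
            raise ValueError(
                "library_path, design_path and peaks_path must be given together"
            )
        if not any(paths) and not self.generator:
            raise ValueError("config needs either input paths or a generator block")

    @property
    def from_files(self) -> bool:
        return self.library_path is not None

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        return cls(**dict(d))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.from_dict(data)

    def sha256(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def validate_inputs(
    library: MetaboliteLibrary,
    design: StudyDesign,
    peaks: pd.DataFrame | None = None,
) -> list[dict[str, Any]]:
    """Machine-readable validation report; reports issues, never raises."""
    issues: list[dict[str, Any]] = []
    base = design.samples.drop_duplicates("sample_id")
    refs = base[base["series"] == REFERENCE_SERIES].groupby("pool").size()
    for pool in sorted(base["pool"].unique()):
        n = int(refs.get(pool, 0))
        if n != 1:
            issues.append({"code": "missing_reference", "pool": int(pool), "found": n})
    entries = library.entries
    for name, mass in entries[["name", "monoisotopic_mass"]].itertuples(index=False):
        if mass <= 0:
            issues.append({"code": "nonpositive_mass", "name": name})
    if entries["name"].duplicated().any():
        issues.append(
            {
                "code": "duplicate_names",
                "names": entries.loc[entries["name"].duplicated(), "name"].tolist(),
            }
        )
    unreachable = entries.loc[~entries["reachable"], "name"].tolist()
    if unreachable:
        issues.append({"code": "unreachable_entries", "names": unreachable})
    for (pool, series), grp in base[base["series"] != REFERENCE_SERIES].groupby(
        ["pool", "series"]
    ):
        levels = grp["level"].tolist()
        if len(set(levels)) != len(levels):
            issues.append(
                {"code": "duplicate_levels", "pool": int(pool), "series": series}
            )
    if peaks is not None:
        lo, hi = SCAN_WINDOW
        n_out = int(((peaks["mz"] < lo) | (peaks["mz"] > hi)).sum())
        if n_out:
            issues.append({"code": "peaks_outside_window", "count": n_out})
        if (peaks["intensity"] < 0).any():
            issues.append({"code": "negative_intensities"})
    return issues


def _build_effects(gen: Mapping[str, Any], seed: int) -> EffectSpec:
    return EffectSpec(
        drifts=gen.get("drifts", {}),
        pool_factors=gen.get("pool_factors"),
        noise_sigma=float(gen.get("noise_sigma", 0.0)),
        seed=seed,
        dropout_rate=float(gen.get("dropout_rate", 0.0)),
        mz_jitter_ppm=float(gen.get("mz_jitter_ppm", 0.0)),
        baseline_log10_range=tuple(gen.get("baseline_log10_range", (5.0, 7.0))),
    )


def load_or_generate(
    config: RunConfig,
) -> tuple[MetaboliteLibrary, StudyDesign, pd.DataFrame]:
    if config.from_files:
        library = MetaboliteLibrary.from_tsv(config.library_path)
        design = StudyDesign.from_tsv(config.design_path)
        peaks = read_peak_tables(config.peaks_path)
        return library, design, peaks
    gen = config.generator
    library = generate_library(
        int(gen.get("n_metabolites", 200)),
        tuple(gen.get("mass_range", (70.0, 600.0))),
        int(gen.get("n_silc", 17)),
        seed=config.seed,
    )
    grid = gen.get("grid") or DEFAULT_GRID
    design = generate_design(
        int(gen.get("pools", 3)), grid, int(gen.get("replicates", 3))
    )
    if gen.get("excluded_samples"):
        design = design.exclude(list(gen["excluded_samples"]))
    peaks = simulate_peak_tables(library, design, _build_effects(gen, config.seed))
    return library, design, peaks


@dataclass
class ReportBundle:
    out_dir: Path
    library: MetaboliteLibrary
    design: StudyDesign
    annotated: AnnotatedMatrix
    qc_table: pd.DataFrame
    bands: pd.DataFrame
    records: pd.DataFrame
    counts_all: pd.DataFrame
    counts_panel: pd.DataFrame | None
    tests: pd.DataFrame
    pca_scores: pd.DataFrame
    manifest: dict[str, Any]


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full pipeline and write the report bundle under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    library, design, peaks = load_or_generate(config)
    issues = validate_inputs(library, design, peaks)
    hard = [i for i in issues if i["code"] == "missing_reference"]
    if hard:
        raise ValueError(f"invalid inputs: {hard}")
    (out / "validation.json").write_text(json.dumps(issues, sort_keys=True, default=str))

    n_excluded = int(design.samples["excluded"].sum())
    if n_excluded:
        log.info("skipping %d excluded measurement rows", n_excluded)

    if not config.from_files:
        library.to_tsv(out / "library.tsv")
        design.to_tsv(out / "design.tsv")
        write_peak_tables(peaks, out / "peaks.csv")

    matches = match_peaks(peaks, library, config.tol_ppm)
    annotated = summed_intensities(matches, library, design, config.replicate_agg)
    annotated.to_csv(out / "annotated_matrix.csv")
    annotated.provenance_json(out / "provenance.json")

    qc = silc_qc_table(annotated, design, library, config.quantile_method)
    qc.to_csv(out / "qc_table.csv", float_format=_FLOAT_FMT)
    bands = variability_bands(qc)
    bands.to_csv(out / "variability_bands.csv", float_format=_FLOAT_FMT)
    (out / "qc_summary.json").write_text(
        json.dumps(
            {
                "median_cv": float(qc.loc["median", "cv"]),
                "bands": bands.to_dict(orient="index"),
            },
            sort_keys=True,
        )
    )

    mav_by_series = bands["mav"].to_dict()
    records = compute_stability(
        annotated, design, mav_by_series, config.ci_method, library=library
    )
    if config.panel_only:
        records = records[
            records["metabolite"].isin(set(library.panel_names))
        ].reset_index(drop=True)
    records.to_csv(out / "stability_records.csv", index=False, float_format=_FLOAT_FMT)
    ext = extreme_records(records, design)
    counts_all = count_affected(ext)
    counts_all.to_csv(out / "affected_counts.csv", float_format=_FLOAT_FMT)
    counts_panel = None
    if library.panel_names:
        counts_panel = count_affected(ext, set(library.panel_names))
        counts_panel.to_csv(out / "affected_counts_panel.csv", float_format=_FLOAT_FMT)
    for series in design.condition_series():
        tbl = stability_plot_table(records, design, library, series)
        tbl.to_csv(out / f"stability_{series}.csv", index=False, float_format=_FLOAT_FMT)
    log.info(
        "stability calls: %s",
        records["call"].value_counts().to_dict(),
    )

    tests = pd.concat(
        [
            feature_tests(annotated, design, series).assign(series=series)
            for series in design.condition_series()
        ],
        ignore_index=True,
    )
    tests.to_csv(out / "test_results.csv", index=False, float_format=_FLOAT_FMT)

    pca_res = pca(annotated)
    pca_res.scores.to_csv(out / "pca_scores.csv", float_format=_FLOAT_FMT)
    pca_res.loadings.to_csv(out / "pca_loadings.csv", float_format=_FLOAT_FMT)

    manifest = {
        "package": "dims-stability",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))

    return ReportBundle(
        out_dir=out,
        library=library,
        design=design,
        annotated=annotated,
        qc_table=qc,
        bands=bands,
        records=records,
        counts_all=counts_all,
        counts_panel=counts_panel,
        tests=tests,
        pca_scores=pca_res.scores,
        manifest=manifest,
    )


def regenerate_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> ReportBundle:
    """Re-run a pipeline from its manifest alone (into a new directory)."""
    manifest = json.loads(Path(manifest_path).read_text())
    cfg = RunConfig.from_dict({**manifest["config"], "out_dir": str(out_dir)})
    return run_pipeline(cfg)
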