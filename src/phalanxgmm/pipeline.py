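"""End-to-end study workflow: slide -> GPA -> PCA -> size tests -> MANOVA
-> CVA -> allometry, driven by a run configuration.

Fore- and hindlimb phalanges are always analysed separately (one run per
limb).  The ``caribou_only`` analysis family restricts the sample to the
one subspecies covering several habitats and mobility types before any
statistics are computed.  Interaction factors (e.g. ``subspecies*habitat``)
are tested as composite cross-classifications — the observed cells act as
the groups, so the hypothesis df is #cells - 1.

Specimens are sorted by id before analysis, making every output table
independent of input order; the seed and the PC count used are recorded in
every result.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allometry import AllometryResult, allometry_regression
from .cva import CvaReport, cva_crossvalidated
from .io import (
    Dataset,
    Subspecies,
    build_dataset,
    load_metadata,
    read_landmark_table,
    write_landmark_table,
)
from .procrustes import AlignedSample, gpa_align
from .shape_pca import ShapeSpace, pca_shape, select_pcs
from .simulate import generate_population, study_spec
from .sliding import slide_semilandmarks
from .stats import (
    ManovaTable,
    SizeTestResult,
    kruskal_wallis,
    manova_pillai,
    pairwise_manova,
    pairwise_wilcoxon_bh,
)
from .templates import Limb, template_for_limb
from .warp import tps_warp_mean, write_ply_points

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "export_warps"]

_ALL_FACTORS = (
    "subspecies",
    "habitat",
    "mobility",
    "subspecies*habitat",
    "subspecies*mobility",
    "mobility*habitat",
    "composite",
)
_CARIBOU_FACTORS = ("habitat", "mobility", "mobility*habitat", "composite")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (one limb)."""

    limb: str = "fore"
    landmarks: str | None = None  # canonical landmark CSV; None -> synthetic
    metadata: str | None = None
    analysis_family: str = "all_subspecies"  # or "caribou_only"
    factors: tuple[str, ...] = ()  # empty -> family default
    cva_factors: tuple[str, ...] = ("habitat", "mobility")
    slide: bool = True
    slide_n_iter: int = 3
    slide_tol: float = 1e-6
    slide_reference: str = "consensus"
    max_cum_pct: float = 95.0
    p_adjust: str = "bonferroni"
    n_permutations: int = 999
    warp_axes: tuple[int, ...] = (0, 1)
    warp_magnification: float = 0.1
    seed: int = 0
    output_dir: str = "results/run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        for attr in ("factors", "cva_factors", "warp_axes"):
            setattr(cfg, attr, tuple(getattr(cfg, attr)))
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def resolved_factors(self) -> tuple[str, ...]:
        if self.factors:
            return self.factors
        return (
            _CARIBOU_FACTORS
            if self.analysis_family == "caribou_only"
            else _ALL_FACTORS
        )


@dataclass
class RunReport:
    config: RunConfig
    n_specimens: int
    aligned: AlignedSample
    shape_space: ShapeSpace
    size_tests: dict[str, SizeTestResult] = field(default_factory=dict)
    manova: dict[str, ManovaTable] = field(default_factory=dict)
    manova_pairwise: dict[str, list[ManovaTable]] = field(default_factory=dict)
    cva: dict[str, CvaReport] = field(default_factory=dict)
    allometry: AllometryResult | None = None
    n_pcs: dict[str, int] = field(default_factory=dict)
    sliding_energy: list[tuple[float, float]] = field(default_factory=list)


def _load_or_simulate(config: RunConfig) -> Dataset:
    limb = Limb(config.limb)
    if config.landmarks is None:
        logger.info("no landmark file given: simulating the %s-limb design", limb.value)
        return generate_population(study_spec(limb, seed=config.seed))
    template = template_for_limb(limb)
    configs = read_landmark_table(config.landmarks, template)
    if config.metadata is None:
        raise ValueError("a metadata file is required with a landmark file")
    records = load_metadata(config.metadata)
    return build_dataset(configs, records, template)


def _group_sizes(labels: np.ndarray) -> list[int]:
    return [int(np.sum(labels == lv)) for lv in pd.unique(labels)]


def run_pipeline(config: RunConfig, write: bool = True) -> RunReport:
    """Execute the full workflow for one limb; optionally write all tables."""
    outdir = Path(config.output_dir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        dataset = _load_or_simulate(config)
        order = np.argsort(np.array(dataset.specimen_ids, dtype=object))
        dataset = Dataset(
            dataset.template,
            [dataset.configurations[i] for i in order],
            [dataset.records[i] for i in order],
        )
        if config.analysis_family == "caribou_only":
            mask = [r.subspecies is Subspecies.CARIBOU for r in dataset.records]
            dataset = dataset.subset(mask)
        elif config.analysis_family != "all_subspecies":
            raise ValueError(f"unknown analysis family {config.analysis_family!r}")
        logger.info("analysing %d specimens (%s)", len(dataset), config.analysis_family)

        report_sliding: list[tuple[float, float]] = []
        if config.slide:
            stage = "slide"
            dataset = slide_semilandmarks(
                dataset,
                n_iter=config.slide_n_iter,
                tol=config.slide_tol,
                reference=config.slide_reference,
            )
            hist = slide_semilandmarks.last_history
            report_sliding = list(zip(hist.energy_before, hist.energy_after))

        stage = "gpa"
        aligned = gpa_align(dataset.configurations)
        stage = "pca"
        space = pca_shape(aligned)

        report = RunReport(
            config=config,
            n_specimens=len(dataset),
            aligned=aligned,
            shape_space=space,
            sliding_energy=report_sliding,
        )

        log_cs = aligned.log_centroid_sizes
        factors = config.resolved_factors()
        for factor in factors:
            stage = f"size tests ({factor})"
            labels = dataset.labels(factor)
            if len(pd.unique(labels)) < 2:
                logger.warning("factor %s has a single level; skipped", factor)
                continue
            res = kruskal_wallis(log_cs, labels, factor)
            res.pairwise = pairwise_wilcoxon_bh(log_cs, labels)
            report.size_tests[factor] = res

            stage = f"manova ({factor})"
            npcs = select_pcs(space, _group_sizes(labels), config.max_cum_pct)
            # the error df must stay positive: p <= n - g
            npcs = min(npcs, len(dataset) - len(pd.unique(labels)))
            if npcs < 1:
                logger.warning("factor %s leaves no error df; MANOVA skipped", factor)
                continue
            report.n_pcs[factor] = npcs
            scores = space.scores[:, :npcs]
            report.manova[factor] = manova_pillai(scores, labels, factor)
            report.manova_pairwise[factor] = pairwise_manova(
                scores, labels, p_adjust=config.p_adjust
            )

        for factor in config.cva_factors:
            stage = f"cva ({factor})"
            labels = dataset.labels(factor)
            counts = _group_sizes(labels)
            if len(counts) < 2 or min(counts) < 2:
                logger.warning("factor %s unsuitable for CVA; skipped", factor)
                continue
            npcs = select_pcs(space, counts, config.max_cum_pct)
            npcs = min(npcs, len(dataset) - len(counts))
            report.cva[factor] = cva_crossvalidated(space.scores, labels, npcs)

        stage = "allometry"
        report.allometry = allometry_regression(
            aligned, n_permutations=config.n_permutations, seed=config.seed
        )

        if write:
            stage = "write"
            _write_report(report, dataset, outdir)
            export_warps(
                space,
                [a for a in config.warp_axes if a < space.n_components],
                config.warp_magnification,
                outdir,
            )
        return report
    except Exception as exc:
        if write:
            outdir.mkdir(parents=True, exist_ok=True)
            (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise


def _manova_frame(report: RunReport) -> pd.DataFrame:
    rows = []
    for factor, table in report.manova.items():
        row = table.as_row()
        row["n"] = report.n_specimens
        row["g"] = table.df + 1
        rows.append(row)
    return pd.DataFrame(rows)


def _write_report(report: RunReport, dataset: Dataset, outdir: Path) -> None:
    cfg = report.config
    provenance = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_digest": cfg.digest(),
        "config": asdict(cfg),
        "n_specimens": report.n_specimens,
        "n_pcs_by_factor": report.n_pcs,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))

    pd.DataFrame(
        {
            "specimen_id": report.aligned.specimen_ids,
            "centroid_size": report.aligned.centroid_sizes,
            "log_centroid_size": report.aligned.log_centroid_sizes,
            "group": dataset.labels("composite"),
        }
    ).to_csv(outdir / "sizes.csv", index=False)

    from .io import LandmarkConfiguration  # local import to avoid cycle noise

    aligned_cfgs = [
        LandmarkConfiguration(sid, dataset.template.limb, coords)
        for sid, coords in zip(report.aligned.specimen_ids, report.aligned.aligned)
    ]
    write_landmark_table(aligned_cfgs, outdir / "aligned_landmarks.csv")
    write_landmark_table(
        [LandmarkConfiguration("consensus", dataset.template.limb, report.aligned.mean_shape)],
        outdir / "consensus.csv",
    )

    pd.DataFrame(
        {
            "PC": np.arange(1, report.shape_space.n_components + 1),
            "eigenvalue": report.shape_space.eigenvalues,
            "pct_variance": report.shape_space.pct_variance,
        }
    ).to_csv(outdir / "pca_variance.csv", index=False)
    pd.DataFrame(
        report.shape_space.scores,
        index=pd.Index(report.aligned.specimen_ids, name="specimen_id"),
        columns=[f"PC{i+1}" for i in range(report.shape_space.n_components)],
    ).to_csv(outdir / "pc_scores.csv")

    kw_rows = []
    for factor, res in report.size_tests.items():
        kw_rows.append(
            {"factor": factor, "Df": res.df, "Chi-square": res.chi_square, "P value": res.p}
        )
        if res.pairwise is not None:
            res.pairwise.to_csv(outdir / f"wilcoxon_{_slug(factor)}.csv")
    pd.DataFrame(kw_rows).to_csv(outdir / "kruskal_wallis.csv", index=False)

    manova_df = _manova_frame(report)
    manova_df.to_csv(outdir / "manova.csv", index=False)
    manova_df.to_json(outdir / "manova.json", orient="records", indent=2)
    for factor, tables in report.manova_pairwise.items():
        rows = []
        for t in tables:
            row = t.as_row()
            row["n"] = report.n_specimens
            rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / f"manova_pairwise_{_slug(factor)}.csv", index=False)

    cva_rows = []
    for factor, rep in report.cva.items():
        row = {"factor": factor, **rep.as_row(), "n": report.n_specimens}
        cva_rows.append(row)
        rep.confusion.to_csv(outdir / f"cva_confusion_{_slug(factor)}.csv")
    pd.DataFrame(cva_rows).to_csv(outdir / "cva.csv", index=False)

    if report.allometry is not None:
        pd.DataFrame(
            [
                {
                    **report.allometry.as_row(),
                    "n": report.n_specimens,
                    "permutations": cfg.n_permutations,
                    "seed": cfg.seed,
                }
            ]
        ).to_csv(outdir / "allometry.csv", index=False)
        pd.DataFrame(
            {
                "specimen_id": report.aligned.specimen_ids,
                "log_centroid_size": report.aligned.log_centroid_sizes,
                "regression_score": report.allometry.regression_scores,
            }
        ).to_csv(outdir / "regression_scores.csv", index=False)


def _slug(factor: str) -> str:
    return factor.replace("*", "x").replace("+", "_")


def export_warps(
    space: ShapeSpace,
    axes,
    magnification: float = 0.1,
    outdir: str | Path = ".",
) -> list[Path]:
    """Write warped consensus point sets at the extremes of requested PC axes.

    For each axis the consensus is TPS-warped toward the shapes at the
    observed score minimum and maximum, magnified, and written as ASCII PLY.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for axis in axes:
        if not 0 <= axis < space.n_components:
            raise ValueError(f"axis {axis} outside the shape space dimensionality")
        lo = float(space.scores[:, axis].min())
        hi = float(space.scores[:, axis].max())
        for tag, score in (("min", lo), ("max", hi)):
            target = space.shape_at(axis, score)
            warped = tps_warp_mean(
                space.mean_shape, target, space.mean_shape, magnification
            )
            path = outdir / f"warp_PC{axis + 1}_{tag}.ply"
            write_ply_points(warped, path)
            written.append(path)
    return written
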