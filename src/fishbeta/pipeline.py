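"""End-to-end two-period analysis: from inputs (or a simulation) to report files.

``run_analysis`` consumes either a synthetic-generator config or real
checklist/attribute/driver files, then writes, per period: incidence
matrices, alpha/gamma richness, the per-area extirpation/introduction
report, ecotype-loss reports on the three ecological-type axes, the three
beta-dissimilarity matrices with area-focal and species-subset summaries,
principal-coordinate ordinations, a Mantel grid against the geographical
drivers, and a completeness report — plus a machine-readable manifest
recording seeds, settings and collected warnings.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .beta_partition import (
    DissimilarityMatrix,
    area_focal_summary,
    beta_matrices,
    origin_and_family_subsets,
    subset_summary,
    summary_frame,
)
from .diversity_summary import (
    alpha_richness,
    ecotype_loss,
    extirpation_table,
    gamma_richness,
    mean_extirpation_pct,
    redlist_tally,
)
from .mantel import driver_to_matrix, mantel_grid
from .occurrence_io import (
    ECOTYPE_AXES,
    IncidenceMatrix,
    SpeciesAttributes,
    build_incidence,
    normalize_names,
    read_checklist,
)
from .ordination import pcoa
from .richness import completeness_report
from .synthetic_data import SyntheticConfig, SyntheticTruth, generate_metacommunity

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to run the full analysis once, reproducibly."""

    outdir: str | Path = "fishbeta_out"
    synthetic: SyntheticConfig | None = None
    checklist_path: str | Path | None = None
    attributes_path: str | Path | None = None
    distance_path: str | Path | None = None
    scalars_path: str | Path | None = None
    areas: list[str] | None = None
    synonym_map: Mapping[str, str] | None = None
    mantel_permutations: int = 9999
    mantel_tail: str = "two_sided"
    mantel_method: str = "spearman"
    n_bootstrap: int = 100
    bootstrap_level: float = 0.95
    pcoa_axes: int = 2
    pcoa_correction: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.synthetic is None and self.checklist_path is None:
            raise ValueError("provide either a synthetic config or input paths")


def _load_inputs(cfg: RunConfig):
    if cfg.synthetic is not None:
        truth = generate_metacommunity(cfg.synthetic)
        return (
            truth.historical,
            truth.current,
            truth.attributes,
            truth.distance,
            truth.drainage_area,
            truth.annual_runoff,
        )
    records = normalize_names(read_checklist(cfg.checklist_path), cfg.synonym_map)
    areas = cfg.areas or sorted({r.area for r in records})
    hist = build_incidence(records, "historical", areas)
    curr = build_incidence(records, "current", areas)
    attrs = SpeciesAttributes.from_csv(cfg.attributes_path)
    distance = None
    if cfg.distance_path:
        df = pd.read_csv(cfg.distance_path, index_col=0).loc[areas, areas]
        distance = DissimilarityMatrix(areas, df.to_numpy(float), "waterway_distance")
    drainage = runoff = None
    if cfg.scalars_path:
        sc = pd.read_csv(cfg.scalars_path, index_col=0).loc[areas]
        drainage = sc["drainage_area"]
        runoff = sc["annual_runoff"]
    return hist, curr, attrs, distance, drainage, runoff


def run_analysis(cfg: RunConfig) -> dict:
    """Run every stage and write all report artifacts; returns the manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collected: list[str] = []
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "settings": {
            "mantel": {
                "method": cfg.mantel_method,
                "tail": cfg.mantel_tail,
                "permutations": cfg.mantel_permutations,
            },
            "pcoa": {"axes": cfg.pcoa_axes, "correction": cfg.pcoa_correction},
            "bootstrap": {"n": cfg.n_bootstrap, "level": cfg.bootstrap_level},
            "beta_sd": "sample SD (ddof=1)",
        },
        "artifacts": {},
    }
    if cfg.synthetic is not None:
        manifest["synthetic_config"] = cfg.synthetic.to_dict()

    def emit(name: str, path: Path) -> None:
        manifest["artifacts"][name] = str(path.relative_to(outdir))

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        stage = "load"
        try:
            hist, curr, attrs, distance, drainage, runoff = _load_inputs(cfg)

            stage = "incidence"
            for m, tag in ((hist, "historical"), (curr, "current")):
                p = outdir / f"incidence_{tag}.csv"
                m.to_csv(p)
                emit(f"incidence_{tag}", p)

            stage = "richness"
            rich = pd.DataFrame(
                {
                    "alpha_historical": alpha_richness(hist),
                    "alpha_current": alpha_richness(curr),
                }
            )
            rich.loc["(gamma)"] = [gamma_richness(hist), gamma_richness(curr)]
            p = outdir / "alpha_gamma.csv"
            rich.to_csv(p, index_label="area")
            emit("alpha_gamma", p)

            stage = "extirpation"
            ext = extirpation_table(hist, curr, attrs)
            p = outdir / "extirpation_by_area.csv"
            ext.to_csv(p, index=False)
            emit("extirpation_by_area", p)
            manifest["mean_extirpation_pct"] = mean_extirpation_pct(_rows_to_summaries(ext))

            stage = "ecotype_loss"
            losses = []
            for axis in ECOTYPE_AXES:
                try:
                    losses.append(ecotype_loss(hist, curr, attrs, axis))
                except ValueError as exc:
                    collected.append(f"ecotype axis {axis}: {exc}")
            if losses:
                p = outdir / "ecotype_loss.csv"
                pd.concat(losses, ignore_index=True).to_csv(p, index=False)
                emit("ecotype_loss", p)

            stage = "red_list"
            tally = redlist_tally(attrs, curr.species)
            p = outdir / "red_list_tally.json"
            p.write_text(json.dumps(tally, indent=1))
            emit("red_list_tally", p)

            stage = "beta"
            beta: dict[str, dict[str, DissimilarityMatrix]] = {}
            for m, tag in ((hist, "historical"), (curr, "current")):
                beta[tag] = beta_matrices(m)
                for idx, dm in beta[tag].items():
                    p = outdir / f"beta_{idx}_{tag}.csv"
                    dm.to_frame().to_csv(p, index_label="area")
                    emit(f"beta_{idx}_{tag}", p)
                p = outdir / f"beta_area_summary_{tag}.csv"
                summary_frame(area_focal_summary(beta[tag])).to_csv(p, index=False)
                emit(f"beta_area_summary_{tag}", p)
                p = outdir / f"beta_subset_summary_{tag}.csv"
                subs = subset_summary(m, origin_and_family_subsets(m, attrs))
                summary_frame(subs).to_csv(p, index=False)
                emit(f"beta_subset_summary_{tag}", p)

            stage = "pcoa"
            for tag in beta:
                for idx, dm in beta[tag].items():
                    res = pcoa(dm, correction=cfg.pcoa_correction, n_axes=cfg.pcoa_axes)
                    p = outdir / f"pcoa_{idx}_{tag}.csv"
                    frame = res.to_frame()
                    frame.to_csv(p, index_label="area")
                    emit(f"pcoa_{idx}_{tag}", p)
                    if res.negative_eigenvalue_share > 0:
                        collected.append(
                            f"pcoa {idx}/{tag}: negative eigenvalue share "
                            f"{res.negative_eigenvalue_share:.3f}"
                        )

            stage = "mantel"
            if distance is not None and drainage is not None:
                drivers = {
                    "geographical_distance": distance,
                    "annual_runoff": driver_to_matrix(runoff.to_dict()),
                    "drainage_area": driver_to_matrix(drainage.to_dict()),
                }
                grid = mantel_grid(
                    beta,
                    drivers,
                    method=cfg.mantel_method,
                    tail=cfg.mantel_tail,
                    n_permutations=cfg.mantel_permutations,
                    seed=cfg.seed,
                )
                p = outdir / "mantel_grid.csv"
                grid.to_csv(p, index=False)
                emit("mantel_grid", p)

            stage = "completeness"
            # areas act as the sampling units for basin-level completeness
            tables = {"historical": hist.data.to_numpy(), "current": curr.data.to_numpy()}
            comp = completeness_report(
                tables,
                n_bootstrap=cfg.n_bootstrap,
                level=cfg.bootstrap_level,
                seed=cfg.seed,
            )
            p = outdir / "completeness.csv"
            comp.to_csv(p, index=False)
            emit("completeness", p)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

        collected.extend(str(w.message) for w in caught)

    manifest["warnings"] = collected
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("analysis complete: %d artifacts in %s", len(manifest["artifacts"]), outdir)
    return manifest


def _rows_to_summaries(ext: pd.DataFrame):
    from .diversity_summary import ExtirpationSummary

    out = []
    for _, r in ext.iterrows():
        out.append(
            ExtirpationSummary(
                area=r["area"],
                n_hist_native=int(r["n_hist_native"]),
                n_curr_native=int(r["n_curr_native"]),
                n_extirpated=int(r["n_extirpated"]),
                pct_extirpated=None if pd.isna(r["pct_extirpated"]) else float(r["pct_extirpated"]),
                n_introduced=int(r["n_introduced"]),
                pct_introduced=None if pd.isna(r["pct_introduced"]) else float(r["pct_introduced"]),
            )
        )
    return out
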