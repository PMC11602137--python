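"""Top-level pipeline driver: simulate -> coverage -> matrices -> orientation ->
stratification -> statistics -> figures, with a digest manifest for reproducibility.

The driver is deliberately thin: every stage is a call into the library modules,
and all numeric outputs are plain-text tables (TSV/JSON) that downstream tests
can read back. Re-running with the same configuration and seed reproduces every
output byte-for-byte, which the manifest's content digests make checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coverage import FlankMatrix, cpm_coverage, compute_flank_matrix
from .io_formats import ValidationError, write_flank_matrix, write_intervals
from .orientation import orient
from .plotting import FigureSpec, render_figures
from .stats import log2_fold_change, metagene_profile, pca_samples, rank_sum_test, window_coverage
from .stratification import (
    classify_repair_pathway,
    classify_transcription_activity,
    new_site_table,
    rank_cleavage_efficiency,
)
from .synthetic_data import CONDITIONS, Annotation, SimulationConfig, generate_annotation, simulate_chrRNA, simulate_track

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("simulate", "coverage", "orientation", "stratification", "stats", "figures")

# Stage -> stages it cannot run without.
_STAGE_DEPS = {
    "coverage": ("simulate",),
    "orientation": ("coverage",),
    "stratification": ("simulate",),
    "stats": ("orientation",),
    "figures": ("stats", "stratification"),
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the offending input."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _check_stage_deps(stages: dict[str, bool]) -> None:
    for stage, deps in _STAGE_DEPS.items():
        if stages.get(stage, True):
            for dep in deps:
                if not stages.get(dep, True):
                    raise StageError(
                        f"stage '{stage}' requires stage '{dep}', which is disabled; "
                        f"enable '{dep}' or disable '{stage}'"
                    )


def run_pipeline(
    config: dict | None = None,
    outdir: str | Path = "dsbdart_out",
    seed: int = 0,
) -> dict:
    """Run the full synthetic-data analysis and return the manifest.

    ``config`` keys (all optional): ``simulate`` (overrides for
    :class:`SimulationConfig`), ``flank``, ``bin_size``, ``window_width``,
    ``window_offset``, ``pseudocount``, ``quantile``, ``pathway_k``,
    ``stages`` (mapping stage name -> bool). Outputs (BED/TSV/JSON/PNG) are
    written under ``outdir``; the manifest records parameters, versions, the
    seed, excluded sites, and a sha256 digest of every output file.
    """
    config = dict(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = {name: True for name in DEFAULT_STAGES}
    stages.update(config.get("stages", {}))
    _check_stage_deps(stages)

    flank = int(config.get("flank", 2500))
    bin_size = int(config.get("bin_size", 1))
    window_width = int(config.get("window_width", 500))
    window_offset = int(config.get("window_offset", 0))
    pseudocount = float(config.get("pseudocount", 0.01))
    quantile = float(config.get("quantile", 1 / 3))
    sim_config = SimulationConfig(**config.get("simulate", {}))

    manifest: dict = {
        "tool": "dsbdart",
        "version": __version__,
        "seed": seed,
        "parameters": {
            "flank": flank,
            "bin_size": bin_size,
            "window_width": window_width,
            "window_offset": window_offset,
            "pseudocount": pseudocount,
            "quantile": quantile,
            "stages": stages,
            "simulate": sim_config.to_dict(),
        },
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "warnings": [],
    }

    def _stage(name: str):
        if not stages.get(name, True):
            return False
        logger.info("pipeline stage: %s", name)
        return True

    # --- simulate ---------------------------------------------------------
    try:
        annotation = generate_annotation(sim_config, seed)
        annotation.write(outdir / "annotation")
        reads_by = {}
        for condition in CONDITIONS:
            for rep in range(1, sim_config.replicates + 1):
                reads, truth = simulate_chrRNA(annotation, condition, rep, seed)
                reads_by[(condition, rep)] = reads
                bed = outdir / "reads" / f"{condition}_rep{rep}.bed"
                bed.parent.mkdir(exist_ok=True)
                write_intervals(reads.reads, bed)
                with open(outdir / "reads" / f"{condition}_rep{rep}.truth.json", "w") as fh:
                    json.dump(truth, fh, indent=1, sort_keys=True)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'simulate' failed: {exc}") from exc

    # --- coverage + flank matrices ---------------------------------------
    try:
        cov_by = {key: cpm_coverage(rs, annotation.sizes) for key, rs in reads_by.items()}
        matrices: dict[tuple[str, str], FlankMatrix] = {}
        matdir = outdir / "matrices"
        matdir.mkdir(exist_ok=True)
        for condition in CONDITIONS:
            cov = cov_by[(condition, 1)]
            for track in ("plus", "minus"):
                m = compute_flank_matrix(cov, annotation.sites, flank, bin_size, track)
                matrices[(condition, track)] = m
                write_flank_matrix(m, matdir / f"{condition}_{track}.tsv")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'coverage' failed: {exc}") from exc

    # --- orientation ------------------------------------------------------
    oriented = {}
    excluded: list[str] = []
    if _stage("orientation"):
        try:
            for condition in CONDITIONS:
                res = orient(
                    matrices[(condition, "plus")], matrices[(condition, "minus")],
                    annotation.sites, annotation.genes,
                )
                oriented[condition] = res
                write_flank_matrix(res.sense_matrix, matdir / f"{condition}_sense.tsv")
                write_flank_matrix(res.antisense_matrix, matdir / f"{condition}_antisense.tsv")
                excluded = res.excluded_sites
            with open(outdir / "excluded_sites.txt", "w") as fh:
                fh.writelines(sid + "\n" for sid in excluded)
            for sid in excluded:
                logger.info("excluded site (no gene in flank): %s", sid)
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage 'orientation' failed: {exc}") from exc
    manifest["excluded_sites"] = excluded

    # --- stratification ---------------------------------------------------
    site_table = None
    if _stage("stratification"):
        try:
            bless, _ = simulate_track(annotation, "bless", seed)
            rad51, _ = simulate_track(annotation, "rad51", seed)
            xrcc4, _ = simulate_track(annotation, "xrcc4", seed)
            site_table = new_site_table(
                annotation.sites,
                cut_status=[annotation.site_info[s.name]["cut_status"] for s in annotation.sites],
            )
            site_table = rank_cleavage_efficiency(bless, annotation.sites, table=site_table)
            cut_ids = [sid for sid in site_table.index if site_table.at[sid, "cut_status"] == "cut"]
            k = int(config.get("pathway_k", min(30, len(cut_ids) // 2)))
            rad51_cov = cpm_coverage(rad51, annotation.sizes)
            xrcc4_cov = cpm_coverage(xrcc4, annotation.sizes)
            if k >= 1 and 2 * k <= len(site_table):
                site_table = classify_repair_pathway(rad51_cov, xrcc4_cov, site_table, k=k)
            if oriented:
                site_table = classify_transcription_activity(
                    oriented["no_damage"].sense_matrix, site_table, quantile=quantile
                )
            site_table.to_csv(outdir / "site_table.tsv", sep="\t")
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage 'stratification' failed: {exc}") from exc

    # --- statistics -------------------------------------------------------
    stats_out: dict = {}
    if _stage("stats"):
        try:
            ctrl, kd = oriented["damage_control"], oriented["damage_knockdown"]
            cut_kept = [
                sid for sid in ctrl.sense_matrix.site_ids
                if annotation.site_info[sid]["cut_status"] == "cut"
            ]
            uncut_kept = [
                sid for sid in ctrl.sense_matrix.site_ids
                if annotation.site_info[sid]["cut_status"] == "uncut"
            ]
            profiles = {}
            for condition in CONDITIONS:
                res = oriented[condition]
                profiles[condition] = (
                    metagene_profile(res.sense_matrix, cut_kept, f"{condition} sense"),
                    metagene_profile(res.antisense_matrix, cut_kept, f"{condition} antisense"),
                )
            prof_rows = []
            for condition, (ps, pa) in profiles.items():
                for prof in (ps, pa):
                    prof_rows.append(
                        pd.DataFrame({
                            "group": prof.label, "offset": prof.offsets,
                            "mean_cpm": prof.mean, "sem": prof.sem,
                        })
                    )
            pd.concat(prof_rows, ignore_index=True).to_csv(
                outdir / "metagene_profiles.tsv", sep="\t", index=False
            )

            fc = {}
            for orientation_name in ("sense", "antisense"):
                cond_m = getattr(kd, f"{orientation_name}_matrix")
                ctrl_m = getattr(ctrl, f"{orientation_name}_matrix")
                fc[orientation_name] = log2_fold_change(
                    cond_m, ctrl_m, window_offset, window_width, pseudocount
                )
                fc[orientation_name].to_csv(
                    outdir / f"log2fc_{orientation_name}.tsv", sep="\t"
                )

            def _fcs(table: pd.DataFrame, ids: list[str]) -> np.ndarray:
                sub = table.loc[[i for i in ids if i in table.index]]
                return sub.loc[~sub["excluded"], "log2fc"].to_numpy()

            sense_cut = _fcs(fc["sense"], cut_kept)
            anti_cut = _fcs(fc["antisense"], cut_kept)
            test = rank_sum_test(anti_cut, sense_cut)
            stats_out = {
                "median_log2fc_sense_cut": float(np.median(sense_cut)),
                "median_log2fc_antisense_cut": float(np.median(anti_cut)),
                "n_cut_sites_tested": len(cut_kept),
                "ranksum_antisense_vs_sense": {
                    "U": test.statistic, "pvalue": test.pvalue, "method": test.method,
                },
            }

            # replicate PCA over total coverage at cut sites (anchor +/- flank)
            pca_cols = {}
            for condition in ("damage_control", "damage_knockdown"):
                for rep in range(1, sim_config.replicates + 1):
                    cov = cov_by[(condition, rep)]
                    m = compute_flank_matrix(cov, annotation.sites, flank, bin_size, "unstranded")
                    pca_cols[f"{condition}_rep{rep}"] = window_coverage(m, 0, 2 * flank)
            pca_table = pd.DataFrame(pca_cols)
            pca_table = pca_table.loc[[s.name for s in annotation.sites
                                       if annotation.site_info[s.name]["cut_status"] == "cut"]]
            pca = pca_samples(pca_table)
            stats_out["pca"] = {
                "explained_variance_ratio": [float(v) for v in pca.explained_variance_ratio],
                "coordinates": {
                    str(k): [float(x) for x in row]
                    for k, row in pca.coordinates.iterrows()
                },
            }
            with open(outdir / "stats.json", "w") as fh:
                json.dump(stats_out, fh, indent=1, sort_keys=True)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage 'stats' failed: {exc}") from exc

    # --- figures ----------------------------------------------------------
    if _stage("figures"):
        try:
            figdir = outdir / "figures"
            figdir.mkdir(exist_ok=True)
            render_figures(
                FigureSpec("metagene", str(figdir / "metagene_cut.png"),
                           title="damage_knockdown, cut sites"),
                {"profiles": list(profiles["damage_knockdown"])},
            )
            render_figures(
                FigureSpec("heatmap", str(figdir / "heatmap_antisense.png"),
                           title="antisense coverage, damage_knockdown"),
                {"matrix": kd.antisense_matrix,
                 "efficiency_rank": site_table["efficiency_rank"]},
            )
            render_figures(
                FigureSpec("boxplot", str(figdir / "log2fc_boxplot.png"),
                           title="knockdown vs control, cut sites"),
                {"groups": {"sense": sense_cut, "antisense": anti_cut}},
            )
            render_figures(
                FigureSpec("fillplot", str(figdir / "fillplot.png")),
                {"matrix": kd.antisense_matrix, "site_id": kd.antisense_matrix.site_ids[0]},
            )
            render_figures(FigureSpec("pca_scatter", str(figdir / "pca.png")), {"pca": pca})
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage 'figures' failed: {exc}") from exc

    # --- manifest ---------------------------------------------------------
    outputs = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            outputs[str(path.relative_to(outdir))] = _sha256(path)
    manifest["outputs"] = outputs
    manifest["stats"] = stats_out
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
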