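"""End-to-end orchestration of the variant-landscape stages.

``run_all`` drives the full pipeline on synthetic inputs generated from one
seed: ortholog alignment -> species filter -> conservation profile;
multi-source variant tables -> harmonized catalog -> conserved/common filter
and zygosity summary; tool-score panel -> total scores -> pathogenic-range
threshold -> VUS shortlist; block-correlated trajectory -> superposition ->
DCC -> correlation summaries -> spatial clusters; eQTL table -> LD-block
report. Every stage writes a TSV into the output directory and logs record
counts; identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import catalog as cat
from . import dynamics as dyn
from . import eqtl, scoring, synthetic
from .conservation import conservation, filter_species
from .errors import StageError

log = logging.getLogger("f8landscape")


@dataclass
class RunConfig:
    """Thresholds, sizes and the seed for one pipeline run.

    Defaults are desk-scale: a 200-position reference with 100 species keeps
    the synthetic run under a second while leaving every statistic
    well-resolved.
    """

    outdir: str = "f8landscape_out"
    seed: int = 0
    # synthetic sizes
    n_species: int = 100
    ref_length: int = 200
    n_frames: int = 2000
    n_residues: int = 40
    n_variants: int | None = None  # default: ref_length // 2; 0 -> empty catalog
    eqtl_block_size: int = 12
    eqtl_background: int = 50
    # thresholds
    min_conservation: float = 0.7
    min_max_af: float = 0.001
    score_quantile: float = 0.05
    dcc_thresholds: tuple[float, ...] = (0.8, 0.85, 0.9)
    cluster_cutoff: float = 12.0
    max_gap_run: int = 10
    eqtl_p_tolerance: float = 0.1
    eqtl_effect_tolerance: float = 0.02

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "dcc_thresholds" in data:
            data["dcc_thresholds"] = tuple(data["dcc_thresholds"])
        return cls(**data)


def run_all(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every stage on synthetic inputs; returns the report tables.

    Writes each report to ``config.outdir`` and a run log of thresholds and
    record counts. Stage failures re-raise as :class:`StageError` naming the
    stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    reports: dict[str, pd.DataFrame] = {}

    def stage(name):
        log.info("stage %s", name)
        return name

    # --- conservation -----------------------------------------------------
    name = stage("conservation")
    try:
        targets = rng.uniform(0.5, 1.0, size=config.ref_length).round(2)
        aln, _truth = synthetic.make_msa(
            synthetic.MsaSpec(
                n_species=config.n_species, ref_length=config.ref_length,
                conservation_targets=targets, long_gap_species=3,
                gap_length=config.max_gap_run + 1, seed=int(rng.integers(2**31)),
            )
        )
        kept = filter_species(aln, max_gap_run=config.max_gap_run)
        profile = conservation(kept)
        reports["conservation"] = profile.to_frame()
    except Exception as e:  # noqa: BLE001
        raise StageError(name, str(e)) from e

    # --- catalog ----------------------------------------------------------
    name = stage("catalog")
    try:
        n_var = config.n_variants if config.n_variants is not None \
            else max(4, config.ref_length // 2)
        counts = {"UniProt": n_var // 10, "ClinVar_Path": n_var // 5,
                  "ClinVar_VUS": n_var // 4, "Geno2MP": n_var // 5,
                  "gnomAD": n_var - n_var // 10 - 2 * (n_var // 5) - n_var // 4}
        tables = synthetic.make_variant_tables(
            synthetic.VariantTableSpec(counts=counts, seed=int(rng.integers(2**31))),
            profile,
        )
        truth = tables.pop("truth")
        panel = tables.pop("panel")
        merged = cat.merge_sources(tables)
        merged = cat.annotate_conservation(merged, profile)
        filtered = cat.filter_conserved_common(
            merged, config.min_conservation, config.min_max_af
        )
        zyg = cat.zygosity_summary(merged, {"ClinVar_Path"})
        enrich = cat.population_enrichment(filtered, merged)
        reports["catalog"] = merged
        reports["catalog_filtered"] = filtered
        reports["zygosity"] = zyg
        reports["population_enrichment"] = enrich
        log.info("catalog: %d merged, %d pass conserved/common filter",
                 len(merged), len(filtered))
    except Exception as e:  # noqa: BLE001
        raise StageError(name, str(e)) from e

    # --- scoring ----------------------------------------------------------
    name = stage("scoring")
    try:
        cons_by_variant = merged.set_index("variant")["conservation"]
        totals = scoring.score_panel(panel, cons_by_variant)
        path_variants = merged[
            merged["source_groups"].str.contains("ClinVar_Path", na=False)
        ]["variant"]
        path_scores = totals.set_index("variant").loc[path_variants, "total"]
        if len(path_scores) >= 2:
            threshold = scoring.pathogenic_range_threshold(
                path_scores, config.score_quantile
            )
            shortlist = scoring.shortlist_vus(merged, totals, threshold)
        else:
            threshold, shortlist = float("nan"), totals.iloc[0:0]
        reports["totals"] = totals
        reports["shortlist"] = shortlist
        reports["truth"] = truth
        log.info("scoring: threshold %.3f, %d shortlisted", threshold, len(shortlist))
    except Exception as e:  # noqa: BLE001
        raise StageError(name, str(e)) from e

    # --- dynamics ---------------------------------------------------------
    name = stage("dynamics")
    try:
        n_res = config.n_residues
        block = list(range(0, max(3, n_res // 10)))
        traj = synthetic.make_trajectory(
            synthetic.TrajectorySpec(
                n_frames=config.n_frames, n_residues=n_res,
                correlation_blocks=[(block, 0.9)], seed=int(rng.integers(2**31)),
            )
        )
        sup = dyn.superpose(traj)
        matrix = dyn.dcc(sup)
        vus = [("A", block[0] + 1), ("A", n_res)]
        pathogenic = [("A", i + 1) for i in block[1:]]
        summaries = dyn.correlation_summary(
            matrix, vus, pathogenic, partner_chain=None,
            thresholds=config.dcc_thresholds,
        )
        ref_coords = sup.mean_structure()
        coords_by_res = {("A", i + 1): ref_coords[i] for i in range(n_res)}
        clusters = dyn.cluster_top_vus(coords_by_res, vus, config.cluster_cutoff)
        reports["rmsd"] = pd.DataFrame({"frame": np.arange(sup.n_frames),
                                        "rmsd": dyn.rmsd_series(sup)})
        reports["rmsf"] = pd.DataFrame({"resnum": np.arange(1, n_res + 1),
                                        "rmsf": dyn.rmsf_per_residue(sup)})
        reports["dcc_summary"] = dyn.summary_frame(summaries)
        reports["clusters"] = pd.DataFrame(
            [{"chain": c, "resnum": r, "cluster": cl} for (c, r), cl in clusters.items()]
        )
    except Exception as e:  # noqa: BLE001
        raise StageError(name, str(e)) from e

    # --- eQTL block -------------------------------------------------------
    name = stage("eqtl")
    try:
        table = synthetic.make_eqtl_table(
            block_size=config.eqtl_block_size, n_background=config.eqtl_background,
            seed=int(rng.integers(2**31)),
        )
        blocks = eqtl.detect_block(
            table, config.eqtl_p_tolerance, config.eqtl_effect_tolerance
        )
        reports["ld_blocks"] = eqtl.blocks_frame(blocks)
    except Exception as e:  # noqa: BLE001
        raise StageError(name, str(e)) from e

    # --- write ------------------------------------------------------------
    for key, df in reports.items():
        df.to_csv(out / f"{key}.tsv", sep="\t", index=False)
    run_log = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "counts": {k: int(len(v)) for k, v in reports.items()},
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    return reports
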