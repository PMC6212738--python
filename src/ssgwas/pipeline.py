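"""Stage orchestration: qc -> traits -> reml -> scan -> annotate, with a
hashed artifact manifest so a rerun with the same config and inputs is
verifiable bit-for-bit.  Analysis stages are deterministic by construction
(direct solvers, fixed iteration counts); the single global seed governs
only the simulator."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats as io
from .annotation import annotate_regions, region_report, summarize_candidates
from .config import PipelineConfig
from .mixed_model import (
    ModelSpec,
    VarianceComponents,
    build_design,
    em_reml,
    genetic_parameters,
)
from .qc import apply_qc
from .relationship import a_inverse
from .scan import region_snp_table, run_ssgwas, select_regions, manhattan_table
from .traits import SowRecordSet, derive_traits, summary_statistics

log = logging.getLogger("ssgwas")

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the artifact manifest.

    Any stage error aborts with the stage name attached to the exception.
    """
    config.validate()
    config.check_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    stage = "setup"
    try:
        stage = "read"
        ped = io.read_pedigree(config.pedigree)
        gm = io.read_genotypes(
            config.genotypes, "matrix-tsv", map_path=config.genotype_map
        )
        genes = io.read_gene_annotation(
            config.gene_annotation, config.gene_annotation_format
        )

        stage = "qc"
        log.info(
            "qc thresholds: snp call rate %.2f, sample call rate %.2f, maf %.2f",
            config.qc.min_snp_call_rate,
            config.qc.min_sample_call_rate,
            config.qc.min_maf,
        )
        qc_res = apply_qc(gm, config.qc, pedigree=ped)
        qc_report = pd.concat(
            [
                qc_res.removed_snps.rename(columns={"snp_id": "item"}).assign(
                    kind="snp"
                ),
                qc_res.removed_animals.rename(
                    columns={"animal_id": "item"}
                ).assign(kind="animal"),
            ],
            ignore_index=True,
        )
        qc_path = out / "qc_report.tsv"
        qc_report.to_csv(qc_path, sep="\t", index=False)
        outputs.append(qc_path)
        gm = qc_res.kept

        stage = "traits"
        if config.phenotypes:
            traits_table = io.read_trait_table(config.phenotypes)
        else:
            litters = pd.read_csv(config.sow_records, sep="\t")
            herd = pd.read_csv(config.herd_days, sep="\t", index_col=0).iloc[:, 0]
            herd.index = herd.index.astype(str)
            litters["sow"] = litters["sow"].astype(str)
            traits_table = derive_traits(SowRecordSet(litters, herd))
        traits_table = traits_table.loc[[a for a in traits_table.index if a in set(ped.ids)]]
        tt_path = out / "trait_table.tsv"
        io.write_trait_table(traits_table, tt_path)
        outputs.append(tt_path)
        stats_path = out / "trait_summary.tsv"
        summary_statistics(traits_table, columns=config.traits).to_csv(
            stats_path, sep="\t"
        )
        outputs.append(stats_path)

        stage = "reml"
        spec = ModelSpec(
            traits=tuple(config.traits), fixed_effects=tuple(config.fixed_effects)
        )
        ainv = a_inverse(ped)
        design = build_design(traits_table, spec, ped.ids)
        Y = traits_table[list(spec.traits)]
        sp = np.cov(Y.to_numpy(), rowvar=False)
        sp = np.atleast_2d(sp)
        start = VarianceComponents(
            traits=spec.traits, sigma_a=0.5 * sp, sigma_e=0.5 * sp
        )
        log.info("reml: EM on pedigree relationship, %d records", len(Y))
        reml = em_reml(
            design, ainv, Y, start, max_rounds=config.reml_max_rounds, tol=1e-6
        )
        params = genetic_parameters(reml.varcomp)
        vc_path = out / "variance_components.tsv"
        pd.DataFrame(
            {
                "sigma_a2": np.diag(reml.varcomp.sigma_a),
                "sigma_e2": np.diag(reml.varcomp.sigma_e),
                "sigma_p2": np.diag(reml.varcomp.sigma_p),
                "h2": params.h2,
            },
            index=list(spec.traits),
        ).to_csv(vc_path, sep="\t", index_label="trait")
        outputs.append(vc_path)
        rg_path = out / "genetic_correlations.tsv"
        params.r_g.to_csv(rg_path, sep="\t")
        outputs.append(rg_path)

        stage = "scan"
        log.info(
            "scan: %d weighting iterations, %d-SNP windows, %.1f%% rule",
            config.iterations,
            config.window_size,
            config.threshold_pct,
        )
        result = run_ssgwas(
            ped,
            gm,
            traits_table,
            spec,
            reml.varcomp,
            n_iterations=config.iterations,
            window_size=config.window_size,
            blend_tau=config.blend_tau,
            tune=config.tune_diagonal,
            denominator=config.denominator,
        )
        scan_path = out / "window_scan.tsv"
        io.write_window_scan(result.scan.windows, scan_path)
        outputs.append(scan_path)
        man_path = out / "manhattan.tsv"
        manhattan_table(result.scan).to_csv(man_path, sep="\t", index=False)
        outputs.append(man_path)

        stage = "annotate"
        regions = select_regions(result.scan, config.threshold_pct)
        snp_table = region_snp_table(regions, gm.markers)
        ann = annotate_regions(snp_table, genes, flank_bp=config.flank_bp)
        region_path = out / "candidate_regions.tsv"
        io.write_region_table(region_report(ann), region_path)
        outputs.append(region_path)
        summary_path = out / "candidate_summary.tsv"
        summarize_candidates(ann, trait_order=config.traits).to_csv(
            summary_path, sep="\t", index=False
        )
        outputs.append(summary_path)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
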