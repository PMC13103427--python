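"""End-to-end pipeline: simulate (optional) -> filter -> ancestry HMM ->
admixture summaries -> modality -> associations -> spatial statistics.

Driven by a plain dict (usually loaded from YAML).  Every stage writes its
report CSV into the output directory and the run ends with a manifest
recording the seed, stage outputs and their SHA-256 hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import admixture as adx
from . import association as assoc
from . import modality as modal
from . import spatial as spat
from .filters import FilterConfig, apply_filters
from .hmm import ReadCountMatrix, SnpPanelTable, fit_group
from .io import naive_genotypes, read_vcf, write_vcf
from .simulate import (SimConfig, simulate_panels, simulate_reads, simulate_zone,
                       records_to_frame, write_metadata_csv, write_truth_tsv)

log = logging.getLogger("contactzone")

__all__ = ["run_pipeline", "load_config"]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _subset(cfg_cls, d: dict):
    names = set(cfg_cls.__dataclass_fields__)
    return cfg_cls(**{k: v for k, v in (d or {}).items() if k in names})


def run_pipeline(config: dict, outdir) -> dict:
    """Run all stages; returns a manifest dict (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {"seed": seed, "stages": {}, "outputs": {}}

    def record(stage: str, path: Path):
        manifest["outputs"][path.name] = _sha256(path)
        manifest["stages"].setdefault(stage, []).append(path.name)

    stage = "input"
    try:
        if "simulate" in config:
            stage = "simulate"
            sim = _subset(SimConfig, {**config["simulate"], "seed": seed})
            panels = simulate_panels(sim)
            records, truth = simulate_zone(sim, panels)
            ids = [r.id for r in records]
            reads = simulate_reads(truth, panels, sim, ids=ids)
            vcf_path = outdir / "simulated.vcf"
            write_vcf(vcf_path, panels, reads, seed=seed)
            meta_path = outdir / "metadata.csv"
            write_metadata_csv(records, meta_path)
            truth_path = outdir / "truth.tsv"
            write_truth_tsv(truth, truth_path, ids=ids)
            panel_path = outdir / "panels.tsv"
            panels.to_tsv(panel_path)
            for p in (vcf_path, meta_path, truth_path, panel_path):
                record("simulate", p)
            meta = records_to_frame(records)
        else:
            inp = config["input"]
            vcf_path = Path(inp["vcf"])
            panels = SnpPanelTable.from_tsv(inp["panels"])
            meta = pd.read_csv(inp["metadata"])

        stage = "filter"
        vcf = read_vcf(vcf_path)
        fcfg = _subset(FilterConfig, config.get("filter", {}))
        selfer_ids = [s for s in vcf.samples
                      if s in set(meta.loc[meta.taxon == "selfer", "id"])]
        fres = apply_filters(vcf, fcfg, selfer_ids)
        pd.Series(fres.removed_by_rule).rename("removed").to_csv(outdir / "filter_log.csv")
        record("filter", outdir / "filter_log.csv")
        site_idx = fres.kept_sites
        samp_idx = fres.kept_samples
        kept_ids = [vcf.samples[i] for i in samp_idx]
        panels_f = SnpPanelTable(panels.df.iloc[site_idx].reset_index(drop=True))
        reads_f = ReadCountMatrix(
            ref=vcf.ref_depth[np.ix_(site_idx, samp_idx)].T,
            alt=vcf.alt_depth[np.ix_(site_idx, samp_idx)].T,
            ids=kept_ids,
        )
        meta = meta.set_index("id").loc[kept_ids].reset_index()

        stage = "hmm"
        hcfg = config.get("hmm", {})
        summaries = []
        posteriors_by_id = {}
        for (zone, taxon), sub in meta.groupby(["zone", "taxon"], sort=True):
            rows = [kept_ids.index(i) for i in sub["id"]]
            grp = ReadCountMatrix(ref=reads_f.ref[rows], alt=reads_f.alt[rows],
                                  ids=list(sub["id"]))
            fit = fit_group(grp, panels_f, conspecific=taxon,
                            error_rate=hcfg.get("error_rate", 0.01),
                            alpha_init=hcfg.get("alpha_init", 0.05),
                            tol=hcfg.get("tol", 0.001),
                            max_iter=hcfg.get("max_iter", 50))
            summ = adx.summarize_group(fit, taxon_label=taxon)
            summ["zone"] = zone
            fitsum = fit.summary().rename(columns={"alpha": "alpha_em"})
            summaries.append(summ.merge(fitsum, on="id"))
            posteriors_by_id.update(dict(zip(fit.ids, (f.posteriors for f in fit.fits))))
        summary = pd.concat(summaries, ignore_index=True)
        summary.to_csv(outdir / "admixture_summary.csv", index=False)
        record("admixture", outdir / "admixture_summary.csv")

        stage = "admixture"
        if "chloroplast" in meta.columns and meta["chloroplast"].notna().any():
            tally = adx.chloroplast_capture_tally(meta)
            tally.to_csv(outdir / "chloroplast_tally.csv", index=False)
            record("admixture", outdir / "chloroplast_tally.csv")
        else:
            warnings.warn("no chloroplast genotypes present; capture tally skipped")

        stage = "modality"
        gt = naive_genotypes(reads_f).astype(float)  # individuals x sites
        gt[gt < 0] = np.nan
        complete = ~np.isnan(gt).any(axis=0)
        results = {}
        if complete.sum() >= 2:
            results["genomic"] = modal.genomic_modality(
                gt[:, complete] / 2.0, seed=seed)
        for trait in ["petal_size", "herkogamy", "protandry", "flowering_time"]:
            if trait in meta.columns:
                vals = meta[trait].dropna().to_numpy()
                if len(vals) >= 9:
                    results[f"phenotype:{trait}"] = modal.fit_gmm_path(
                        vals, seed=seed, data_kind=f"phenotype:{trait}")
        modal.modality_report(results).to_csv(outdir / "modality_report.csv", index=False)
        record("modality", outdir / "modality_report.csv")

        stage = "association"
        merged = summary.merge(meta, on=["id", "taxon", "zone"])
        rows = []
        for (zone, taxon), sub in merged.groupby(["zone", "taxon"], sort=True):
            include_color = (taxon == "selfer"
                             and sub["flower_color"].nunique() > 1)
            if len(sub) <= 5 + (2 if include_color else 1):
                continue
            try:
                rep = assoc.zone_regression(
                    sub["alpha_all"].reset_index(drop=True),
                    sub.reset_index(drop=True),
                    include_color=include_color, zone=zone, taxon=taxon)
            except ValueError as exc:
                log.warning("association skipped for %s/%s: %s", zone, taxon, exc)
                continue
            tab = rep.table.assign(zone=zone, taxon=taxon, n=rep.n)
            rows.append(tab)
        if rows:
            pd.concat(rows, ignore_index=True).to_csv(
                outdir / "association_table.csv", index=False)
            record("association", outdir / "association_table.csv")

        stage = "spatial"
        srows = []
        planar = bool(config.get("planar_coordinates", "simulate" in config))
        for (zone, taxon), sub in merged.groupby(["zone", "taxon"], sort=True):
            other = merged[(merged.zone == zone) & (merged.taxon != taxon)]
            if len(sub) < 10 or len(other) < 3:
                continue
            zone_df = merged[merged.zone == zone].reset_index(drop=True)
            d3 = spat.dist_to_heterospecifics(zone_df, planar=planar)
            mask = zone_df["taxon"] == taxon
            try:
                rep = spat.admixture_vs_distance(
                    zone_df.loc[mask, "alpha_all"], d3[mask], quadratic=True)
            except ValueError as exc:
                log.warning("spatial model skipped for %s/%s: %s", zone, taxon, exc)
                continue
            srows.append({"zone": zone, "taxon": taxon, "slope": rep.slope,
                          "linear_F": rep.linear_F, "linear_p": rep.linear_p,
                          "quadratic_F": rep.quadratic_F, "quadratic_p": rep.quadratic_p,
                          "n": rep.n})
        if srows:
            pd.DataFrame(srows).to_csv(outdir / "spatial_table.csv", index=False)
            record("spatial", outdir / "spatial_table.csv")

    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
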