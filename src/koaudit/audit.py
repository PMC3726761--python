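"""End-to-end audit: DE -> signatures -> variant scan -> enrichment ->
methylation, driven by one declarative config, with a consolidated report.

The report is deterministic for a fixed config and seed: no timestamps,
sorted JSON keys, and provenance limited to the config hash, seed, and
package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import io as kio
from .core import validate_inputs
from .de import run_de
from .enrichment import region_enrichment_test, top_n_genes, chromosome_contribution
from .methylation import compare_methylation, comparison_to_frame, element_loads
from .regionscan import (
    RegionCall,
    ScanConfig,
    call_regions,
    label_strain,
    regions_to_bed,
    window_density,
    windows_to_bedgraph,
)
from .signatures import gene_family_shift, score_signatures, shifts_to_frame
from .simulate import scenario_config, simulate_all


class AuditError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _json_default(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _file_checksum(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_audit(config: dict | str | Path, log=print) -> dict:
    """Run every stage in dependency order and write the report.

    ``config`` is a dict or a YAML path; see the README for the schema.
    Returns the report dict (also written to ``<out>/report.json`` and a
    human-readable ``report.txt``).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(config.get("out", "audit_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report: dict = {
        "provenance": {
            "config_sha256": _config_hash(config),
            "seed": seed,
            "koaudit_version": __version__,
        }
    }

    # ------------------------------------------------------------- inputs
    stage = "inputs"
    try:
        if "simulate" in config:
            sim = dict(config["simulate"])
            scenario = sim.pop("scenario", "GC")
            inject = sim.pop("inject_demethylation", None)
            sim_config = scenario_config(scenario, seed=seed, **sim)
            paths = simulate_all(sim_config, out / "inputs",
                                 inject_demethylation=inject)
            log(f"[{stage}] simulated scenario {scenario!r} -> {out/'inputs'}")
        else:
            paths = dict(config["inputs"])
            missing = [p for p in paths.values()
                       if isinstance(p, str) and not Path(p).exists()]
            if missing:
                raise FileNotFoundError(f"missing input file(s): {missing}")
        counts = kio.read_counts_tsv(paths["counts_tsv"], paths["groups_tsv"])
        annotation = kio.read_annotation(
            paths["genes_bed"] if "genes_bed" in paths
            else Path(paths["counts_tsv"]).parent / "annotation" / "genes.bed",
            paths.get("chrom_sizes")
            or Path(paths["counts_tsv"]).parent / "annotation" / "chrom.sizes",
            elements_bed=paths.get("elements_bed")
            or Path(paths["counts_tsv"]).parent / "annotation" / "elements.bed",
        )
        check = validate_inputs(counts, annotation)
        report["inputs"] = {
            "n_genes": len(check.shared_genes),
            "n_samples": len(counts.samples),
            "discrepancies": check.discrepancies,
            "checksums": {
                k: _file_checksum(v)
                for k, v in sorted(paths.items())
                if isinstance(v, str) and Path(v).is_file()
            },
        }
        log(f"[{stage}] {len(check.shared_genes)} genes, "
            f"{len(counts.samples)} samples")
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise AuditError(f"stage {stage!r} failed: {exc}") from exc

    # ----------------------------------------------------------------- DE
    stage = "de"
    try:
        de_cfg = config.get("de", {})
        fdr = float(de_cfg.get("fdr", 0.01))
        de_table, significant = run_de(
            counts.subset_genes(check.shared_genes),
            fdr_cutoff=fdr,
            pseudocount=float(de_cfg.get("pseudocount", 0.5)),
            annotation=annotation,
        )
        de_path = out / "de.tsv"
        de_table.to_csv(de_path, sep="\t", index=False)
        sig_path = out / "significant_genes.tsv"
        de_table[de_table["gene"].isin(significant)].to_csv(
            sig_path, sep="\t", index=False
        )
        report["de"] = {
            "n_tested": len(de_table),
            "fdr_cutoff": fdr,
            "n_significant": len(significant),
        }
        log(f"[{stage}] {len(significant)} genes at FDR<{fdr}")
    except Exception as exc:
        raise AuditError(f"stage {stage!r} failed: {exc}") from exc

    # --------------------------------------------------------- signatures
    stage = "signatures"
    try:
        sig_cfg = config.get("signatures", {})
        sets_dir = sig_cfg.get("sets_dir") or paths.get("sets_dir")
        if sets_dir and Path(sets_dir).is_dir():
            gene_sets = kio.read_gene_sets_dir(sets_dir)
            shifts = score_signatures(de_table, gene_sets)
            family = sig_cfg.get("family_prefix", "Ighv")
            try:
                shifts.append(gene_family_shift(de_table, family))
            except Exception:
                pass  # no family genes present
            frame = shifts_to_frame(shifts)
            frame.to_csv(out / "signatures.tsv", sep="\t", index=False)
            report["signatures"] = [
                {k: (None if isinstance(v, float) and np.isnan(v) else v)
                 for k, v in row.items()}
                for row in frame.to_dict("records")
            ]
            log(f"[{stage}] scored {len(shifts)} sets")
        else:
            report["signatures"] = {"skipped": "no gene sets supplied"}
            log(f"[{stage}] skipped")
    except Exception as exc:
        raise AuditError(f"stage {stage!r} failed: {exc}") from exc

    # --------------------------------------------------------------- scan
    stage = "scan"
    regions: list[RegionCall] = []
    try:
        scan_cfg = dict(config.get("scan", {}))
        strain = scan_cfg.pop("strain", "auto")
        if "variants_vcf" in paths and "panel_vcf" in paths:
            variants = kio.read_vcf(paths["variants_vcf"])
            panel = kio.read_vcf(paths["panel_vcf"])
            labeled = label_strain(variants, panel)
            if strain == "auto":
                known = labeled.records.loc[
                    labeled.records["strain"] != "", "strain"
                ]
                strain = known.mode().iloc[0] if len(known) else None
            sconf = ScanConfig(**scan_cfg)
            density = window_density(
                labeled, annotation.chrom_sizes, sconf, strain=strain
            )
            regions = call_regions(density, sconf, variants=labeled)
            kio.write_bedgraph(
                windows_to_bedgraph(density), out / "windows.bedgraph"
            )
            regions_to_bed(regions).to_csv(
                out / "regions.bed", sep="\t", header=False, index=False
            )
            report["scan"] = {
                "strain": strain,
                "n_variants": len(labeled),
                "n_labeled": int((labeled.records["strain"] != "").sum()),
                "regions": [dataclasses.asdict(r) for r in regions],
            }
            log(f"[{stage}] {len(regions)} region(s) called")
        else:
            report["scan"] = {"skipped": "no variant/panel VCF supplied"}
            log(f"[{stage}] skipped")
    except Exception as exc:
        raise AuditError(f"stage {stage!r} failed: {exc}") from exc

    # ------------------------------------------------------------- enrich
    stage = "enrich"
    try:
        enr_cfg = config.get("enrich", {})
        n_top = int(enr_cfg.get("top_n", 100))
        if regions:
            region = max(regions, key=lambda r: r.n_variants)
            result = region_enrichment_test(
                de_table, region, annotation, n_top=n_top,
                membership=enr_cfg.get("membership", "overlap"),
            )
            contrib = chromosome_contribution(
                top_n_genes(de_table, n_top), annotation
            )
            contrib.to_csv(out / "chromosome_contribution.tsv", sep="\t")
            report["enrichment"] = {
                "region": dataclasses.asdict(region),
                "top_n": n_top,
                "table": result.table.tolist(),
                "chi2": result.chi2,
                "chi2_pvalue": result.chi2_pvalue,
                "fisher_pvalue": result.fisher_pvalue,
                "odds_ratio": result.odds_ratio,
                "degenerate_margin": result.degenerate_margin,
            }
            log(f"[{stage}] chi2 p={result.chi2_pvalue}")
        else:
            report["enrichment"] = {"skipped": "no region called"}
            log(f"[{stage}] skipped (no region)")
    except Exception as exc:
        raise AuditError(f"stage {stage!r} failed: {exc}") from exc

    # ------------------------------------------------------------- methyl
    stage = "methyl"
    try:
        met_cfg = config.get("methyl", {})
        if "coverage_a" in paths and "coverage_b" in paths:
            cov_a = kio.read_bedgraph(paths["coverage_a"])
            cov_b = kio.read_bedgraph(paths["coverage_b"])
            prof_a = element_loads(cov_a, annotation)
            prof_b = element_loads(cov_b, annotation)
            comparison = compare_methylation(
                prof_a, prof_b, test=met_cfg.get("test", "mannwhitney")
            )
            frame = comparison_to_frame(comparison)
            frame.to_csv(out / "methylation.tsv", sep="\t", index=False)
            report["methylation"] = {
                "classes": [
                    {k: (None if isinstance(v, float) and np.isnan(v) else v)
                     for k, v in row.items()}
                    for row in frame.to_dict("records")
                ],
                "pearson_r_tss": comparison.pearson_r,
            }
            log(f"[{stage}] r(TSS)={comparison.pearson_r}")
        else:
            report["methylation"] = {"skipped": "no coverage supplied"}
            log(f"[{stage}] skipped")
    except Exception as exc:
        raise AuditError(f"stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=1, default=_json_default)
        + "\n"
    )
    (out / "report.txt").write_text(_render_text(report))
    return report


def _render_text(report: dict) -> str:
    lines = ["koaudit report", "=" * 40]
    de = report.get("de", {})
    lines.append(
        f"DE: {de.get('n_significant')} of {de.get('n_tested')} genes at "
        f"FDR<{de.get('fdr_cutoff')}"
    )
    sig = report.get("signatures")
    if isinstance(sig, list):
        for row in sig:
            lines.append(
                f"signature {row['set']}: median log2FC="
                f"{row['median_log2FC']}, sign-test p={row['sign_test_p']}"
            )
    scan = report.get("scan", {})
    for r in scan.get("regions", []):
        lines.append(
            f"region {r['chrom']}:{r['start']}-{r['end']} "
            f"({r['n_variants']} variants, strain {r['strain'] or '?'})"
        )
    enr = report.get("enrichment", {})
    if "chi2_pvalue" in enr:
        lines.append(
            f"enrichment: chi2 p={enr['chi2_pvalue']}, "
            f"Fisher p={enr['fisher_pvalue']}, OR={enr['odds_ratio']}"
        )
    met = report.get("methylation", {})
    if "classes" in met:
        for row in met["classes"]:
            lines.append(
                f"methylation {row['element_class']}: p={row['pvalue']}"
            )
        lines.append(f"TSS Pearson r={met['pearson_r_tss']}")
    return "\n".join(lines) + "\n"
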