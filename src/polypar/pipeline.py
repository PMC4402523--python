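"""End-to-end orchestration: simulate -> phenotype -> scans -> enrichment.

``run_pipeline`` executes the stages named in a :class:`RunConfig` in
dependency order, writes plain-text TSV/JSON outputs, and returns a manifest
listing every file created with its sha256 checksum, so a rerun with the
same config and seed can be verified to reproduce the deterministic stages
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import poly_composition as pc
from . import structure_scan as sc
from . import enrichment as en
from . import synthetic_data as syn

log = logging.getLogger("polypar")

__all__ = ["RunConfig", "run_pipeline", "demo_config"]


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips through YAML unchanged."""

    out_dir: str = "polypar_run"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    phenotype: bool = True
    scan: bool = True
    enrich: bool = True
    # inputs when not simulating
    vcf: str | None = None
    groups_file: str | None = None
    genes_file: str | None = None
    terms_file: str | None = None
    repair_file: str | None = None
    # stage settings
    filters: dict = field(default_factory=dict)
    sim: dict = field(default_factory=dict)
    scan_model: str = "mixed"
    covar_pcs: tuple[int, int] = (2, 6)
    threshold_method: str = "bonferroni"
    alpha: float = 0.05
    window_sizes: tuple[int, ...] = (500_000, 1_000_000, 1_500_000, 2_000_000)
    representative_window: int = 1_500_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("covar_pcs", "window_sizes"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["covar_pcs"] = list(self.covar_pcs)
        data["window_sizes"] = list(self.window_sizes)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def demo_config(out_dir: str, seed: int = 0) -> RunConfig:
    """A small self-contained run exercising every pattern class."""
    return RunConfig(
        out_dir=out_dir,
        seed=seed,
        sim={"n_basal": 40, "n_derived": 80, "n_snps": 4000},
    )


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; return the manifest dict (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "files": {}}
    created: list[Path] = []

    def record(path: Path) -> None:
        created.append(path)

    # validate stage dependencies and inputs before any compute
    if config.scan and not config.phenotype:
        raise StageFailure("scan", ValueError("the scan stage requires the phenotype stage"))
    if config.enrich and not config.scan:
        raise StageFailure("enrich", ValueError("the enrichment stage requires the scan stage"))
    if not config.simulate:
        for stage, attr in (("phenotype", "vcf"), ("phenotype", "groups_file")):
            if getattr(config, stage) and getattr(config, attr) is None:
                raise StageFailure(stage, ValueError(f"{attr} is required when not simulating"))
            p = getattr(config, attr)
            if getattr(config, stage) and p and not Path(p).exists():
                raise StageFailure(stage, FileNotFoundError(p))

    variants = genotypes = groups = None
    genes = gene_terms = repair = None
    t_all = time.time()
    try:
        if config.simulate:
            t0 = time.time()
            sim_kwargs = dict(config.sim)
            mod = sim_kwargs.pop("modifier", None)
            if mod is not None:
                sim_kwargs["modifier"] = syn.ModifierConfig(**mod)
            sim_cfg = syn.PopSimConfig(seed=config.seed, **sim_kwargs)
            pop = syn.simulate_populations(sim_cfg)
            variants, genotypes, groups = pop.variants, pop.genotypes, pop.groups
            syn.write_vcf(variants, genotypes, out / "simulated.vcf",
                          contig_lengths={str(c + 1): sim_cfg.chrom_length
                                          for c in range(sim_cfg.n_chrom)})
            groups.to_csv(out / "groups.tsv", sep="\t", header=False)
            with open(out / "truth.json", "w") as fh:
                json.dump(pop.truth, fh, indent=2, default=str)
            for f in ("simulated.vcf", "groups.tsv", "truth.json"):
                record(out / f)
            # synthetic annotation for the enrichment stage
            if config.enrich and config.genes_file is None:
                rng = np.random.default_rng(np.random.SeedSequence([config.seed, 97]))
                genes, gene_terms, repair = syn.simulate_gene_annotation(
                    n_genes=800, n_chrom=sim_cfg.n_chrom,
                    chrom_length=sim_cfg.chrom_length, rng=rng,
                )
            manifest["stages"]["simulate"] = {"seconds": round(time.time() - t0, 2),
                                              "n_variants": int(len(variants))}
            log.info("simulate: %d variants, %d samples", len(variants), genotypes.n_samples)
    except StageFailure:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageFailure("simulate", e) from e

    try:
        if config.phenotype:
            t0 = time.time()
            if variants is None:
                filt = pc.FilterConfig(**config.filters)
                variants, genotypes, report = pc.load_variants(config.vcf, filt)
                groups = pc.read_groups(config.groups_file)
                report.as_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
                record(out / "filter_report.tsv")
            pheno = pc.base_phenotype(variants, genotypes)
            pc.write_phenotype(pheno, out / "phenotype.tsv", groups)
            record(out / "phenotype.tsv")
            sep = pc.group_separation(pheno, groups)
            with open(out / "group_separation.json", "w") as fh:
                json.dump({k: v for k, v in sep.items() if k != "summary"}, fh, indent=2)
            record(out / "group_separation.json")
            manifest["stages"]["phenotype"] = {"seconds": round(time.time() - t0, 2),
                                               "diff_frac_a": sep["diff_frac_a"]}
            log.info("phenotype: derived-basal frac_a diff %.5f", sep["diff_frac_a"])
    except StageFailure:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageFailure("phenotype", e) from e

    scan = None
    try:
        if config.scan:
            t0 = time.time()
            y = pheno["frac_a"].to_numpy()
            k_top = max(config.covar_pcs[1], 1)
            pcs = sc.pca(genotypes, k=min(k_top, genotypes.n_samples - 1))
            covs = pcs.scores[:, config.covar_pcs[0] - 1 : config.covar_pcs[1]]
            if config.scan_model == "mixed":
                K = sc.compute_kinship(genotypes)
                scan, vc = sc.mixed_scan(y, genotypes, K, covariates=covs, variants=variants)
                manifest["stages"]["scan_vc"] = vc
            elif config.scan_model == "linear":
                scan = sc.linear_scan(y, genotypes, covariates=None, variants=variants)
            else:
                raise ValueError(f"unknown scan model {config.scan_model!r}")
            if config.threshold_method == "bonferroni":
                thr_p, neglog = sc.bonferroni_threshold(len(scan), config.alpha)
                scan = sc.flag_tas(scan, thr_p, on="p")
                thr_info = {"method": "bonferroni", "p": thr_p, "neg_log10": neglog}
            elif config.threshold_method == "switch-sim":
                res = sc.allele_switch_threshold(y, groups.reindex(genotypes.samples))
                scan = sc.flag_tas(scan, res["threshold_F"], on="F")
                res["table"].to_csv(out / "switch_distributions.tsv", sep="\t", index=False)
                record(out / "switch_distributions.tsv")
                thr_info = {"method": "switch-sim", "F": res["threshold_F"],
                            "proportion": res["chosen_proportion"]}
            else:
                raise ValueError(f"unknown threshold method {config.threshold_method!r}")
            scan.to_csv(out / "scan.tsv", sep="\t", index=False)
            record(out / "scan.tsv")
            with open(out / "threshold.json", "w") as fh:
                json.dump(thr_info, fh, indent=2)
            record(out / "threshold.json")
            manifest["stages"]["scan"] = {"seconds": round(time.time() - t0, 2),
                                          "n_tas": int(scan["is_tas"].sum()),
                                          **thr_info}
            log.info("scan: %d TASs at %s threshold", int(scan["is_tas"].sum()),
                     config.threshold_method)
    except StageFailure:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageFailure("scan", e) from e

    try:
        if config.enrich:
            t0 = time.time()
            if genes is None:
                if config.genes_file is None:
                    raise ValueError("genes_file is required for the enrichment stage")
                genes = pd.read_csv(config.genes_file, sep="\t",
                                    dtype={"chrom": str})
                gene_terms = pd.read_csv(config.terms_file, sep="\t")
                repair = [l.strip() for l in open(config.repair_file) if l.strip()]
            tas = scan[scan["is_tas"]]
            regions = en.tabulate_tas_regions(tas)
            regions.to_csv(out / "tas_regions.bed", sep="\t", index=False, header=False)
            record(out / "tas_regions.bed")
            all_terms = []
            for size in config.window_sizes:
                wins = en.build_windows(tas, size)
                inw = en.genes_in_windows(genes, wins)
                terms = en.term_enrichment(genes, gene_terms, inw)
                terms.insert(0, "window_size", size)
                all_terms.append(terms)
                rep = en.repair_gene_enrichment(genes, repair, inw)
                rep["window_size"] = size
                all_terms[-1].attrs["repair"] = rep
            pd.concat(all_terms, ignore_index=True).to_csv(
                out / "term_enrichment.tsv", sep="\t", index=False)
            record(out / "term_enrichment.tsv")
            tags = en.gene_tagging(genes, tas, config.representative_window)
            tags.to_csv(out / "gene_tagging.tsv", sep="\t", index=False)
            record(out / "gene_tagging.tsv")
            repair_rows = [t.attrs["repair"] for t in all_terms]
            with open(out / "repair_enrichment.json", "w") as fh:
                json.dump(repair_rows, fh, indent=2)
            record(out / "repair_enrichment.json")
            manifest["stages"]["enrich"] = {"seconds": round(time.time() - t0, 2),
                                            "n_regions": int(len(regions))}
            log.info("enrich: %d TAS regions tabulated", len(regions))
    except StageFailure:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageFailure("enrich", e) from e

    manifest["seconds_total"] = round(time.time() - t_all, 2)
    manifest["files"] = {str(p.relative_to(out)): _sha256(p) for p in created}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
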