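"""File formats, run configuration and the end-to-end pipeline.

Genotypes travel as minimal VCF (8 mandatory columns + GT-only samples;
REF=A, ALT=B by convention for the synthetic biallelic panels) or as a
HapMap-like TSV (rs, chrom, cM, one dosage column per accession).  VCF
positions are base pairs by standard, so the genetic-map position (cM)
lives in a sidecar map file ``marker<TAB>chrom<TAB>cM`` that is written
alongside every VCF and read back with it.

All writers are deterministic for fixed inputs; timestamps appear only in
the run manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import gwas as _gwas
from . import irrigation as _irrigation
from . import phenostats as _phenostats
from . import popgen as _popgen
from . import synthetic as _synthetic
from .errors import ConfigError

log = logging.getLogger("seedgwas")

__all__ = [
    "write_panel_vcf",
    "write_panel_hapmap",
    "read_genotypes",
    "write_results",
    "RunConfig",
    "validate_config",
    "run_pipeline",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_panel_vcf(panel: _popgen.GenotypePanel, path: str | Path) -> Path:
    """Minimal VCF + sidecar cM map (``<path>.map``).

    POS is a pseudo base-pair coordinate (cM x 1e4, 1-based) kept only so
    the file is valid VCF; the sidecar carries the authoritative cM.
    """
    path = Path(path)
    samples = list(panel.accessions["id"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=seedgwas\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in panel.markers["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, row in panel.markers.iterrows():
            pos_bp = int(round(row["cm"] * 1e4)) + 1
            gts = "\t".join(_GT[int(d)] for d in panel.dosages[:, j])
            fh.write(f"{row['chrom']}\t{pos_bp}\t{row['id']}\tA\tB\t.\t.\t.\t"
                     f"GT\t{gts}\n")
    map_path = path.with_suffix(path.suffix + ".map")
    panel.markers[["id", "chrom", "cm"]].to_csv(
        map_path, sep="\t", index=False, header=False)
    return path


def write_panel_hapmap(panel: _popgen.GenotypePanel, path: str | Path) -> Path:
    """HapMap-like TSV: rs, chrom, cM, then one dosage column per accession."""
    path = Path(path)
    df = panel.markers[["id", "chrom", "cm"]].rename(columns={"id": "rs"})
    dos = pd.DataFrame(panel.dosages.T, columns=panel.accessions["id"])
    pd.concat([df.reset_index(drop=True), dos], axis=1).to_csv(
        path, sep="\t", index=False)
    return path


def _genome_of(chrom: str) -> str:
    return chrom[-1] if str(chrom)[-1:] in ("A", "B", "D") else "unknown"


def read_genotypes(path: str | Path, fmt: str = "vcf",
                   map_path: str | Path | None = None) -> _popgen.GenotypePanel:
    """Read a genotype panel from minimal VCF or HapMap-like TSV.

    For VCF, cM positions come from ``map_path`` (default:
    ``<path>.map``); markers absent from the map fall back to POS / 1e4.
    Missing genotype calls become dosage -1.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FileNotFoundError(f"missing or empty genotype file: {path}")
    if fmt == "vcf":
        from cyvcf2 import VCF

        cm_map = {}
        mp = Path(map_path) if map_path else path.with_suffix(path.suffix + ".map")
        if mp.exists():
            m = pd.read_csv(mp, sep="\t", header=None,
                            names=["id", "chrom", "cm"])
            cm_map = dict(zip(m["id"], m["cm"]))
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows, dosage_cols = [], []
        for i, var in enumerate(vcf):
            gts = var.genotypes
            d = np.array([a + b if a >= 0 and b >= 0 else -1
                          for a, b, *_ in gts], dtype=np.int8)
            mid = var.ID or f"{var.CHROM}_{var.POS}"
            rows.append({
                "id": mid,
                "chrom": var.CHROM,
                "genome": _genome_of(var.CHROM),
                "cm": float(cm_map.get(mid, var.POS / 1e4)),
            })
            dosage_cols.append(d)
        if not rows:
            raise ValueError(f"no variant records in {path}")
        markers = pd.DataFrame(rows)
        dosages = np.column_stack(dosage_cols)
    elif fmt == "hapmap":
        df = pd.read_csv(path, sep="\t")
        need = {"rs", "chrom", "cm"}
        if not need <= set(df.columns):
            raise ValueError(f"hapmap file lacks columns {need - set(df.columns)}")
        sample_cols = [c for c in df.columns if c not in need]
        if not sample_cols:
            raise ValueError("hapmap file has no accession columns")
        markers = pd.DataFrame({
            "id": df["rs"], "chrom": df["chrom"],
            "genome": df["chrom"].map(_genome_of), "cm": df["cm"],
        })
        dosages = df[sample_cols].to_numpy(dtype=np.int8).T
        samples = sample_cols
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    accessions = pd.DataFrame({"id": samples})
    markers = markers.reset_index(drop=True)
    return _popgen.GenotypePanel(dosages=dosages, markers=markers,
                                 accessions=accessions)


def write_results(objects: dict, out_dir: str | Path,
                  manifest: dict | None = None) -> list[Path]:
    """Write a name -> object mapping to disk deterministically.

    DataFrames become UTF-8 CSVs with their column order preserved;
    strings ending in ';' or named ``*_newick`` become ``.nwk`` files;
    other strings become ``.txt``.  A ``manifest.json`` echoes the config,
    seeds and a timestamp (the only non-deterministic output).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(objects):
        obj = objects[name]
        if isinstance(obj, pd.DataFrame):
            p = out / f"{name}.csv"
            obj.to_csv(p, index=False, float_format="%.10g")
        elif isinstance(obj, str):
            suffix = ".nwk" if (obj.rstrip().endswith(";")
                                or name.endswith("newick")) else ".txt"
            p = out / f"{name}{suffix}"
            p.write_text(obj if obj.endswith("\n") else obj + "\n")
        else:
            p = out / f"{name}.json"
            p.write_text(json.dumps(obj, indent=2, default=float) + "\n")
        written.append(p)
    if manifest is not None:
        p = out / "manifest.json"
        p.write_text(json.dumps({**manifest, "written_at": time.strftime(
            "%Y-%m-%dT%H:%M:%S")}, indent=2, default=str) + "\n")
        written.append(p)
    return written


@dataclass
class RunConfig:
    """Declarative configuration of the demo pipeline.

    With ``simulate=True`` the genotype/phenotype inputs are generated by
    the synthetic module (and ``genotype_path`` may be unset); otherwise
    the referenced files must exist.
    """

    out_dir: str = "seedgwas_out"
    simulate: bool = True
    genotype_path: str | None = None
    genotype_format: str = "vcf"
    phenotype_path: str | None = None
    images_dir: str | None = None
    scale_mm_per_px: float = 0.02
    threshold_method: str = "otsu"
    circ_variant: str = "table5"
    n_accessions: int = 50
    markers_per_chromosome: int = 24
    n_chromosomes: int = 21
    seeds_per_accession: int = 0
    ld_alpha: float = 0.001
    ld_near_cm: float = 10.0
    n_pcs: int = 3
    n_clusters: int = 3
    gwas_alpha: float = 0.05
    p3d: bool = True
    run_gwas: bool = True
    seed: int = 0


def validate_config(config: RunConfig) -> list[str]:
    """List every violation; never mutates state. Empty list = valid."""
    issues = []
    for name, a in (("ld_alpha", config.ld_alpha),
                    ("gwas_alpha", config.gwas_alpha)):
        if not 0 < a < 1:
            issues.append(f"{name} must be in (0, 1), got {a}")
    if config.scale_mm_per_px <= 0:
        issues.append(f"scale must be > 0, got {config.scale_mm_per_px}")
    if config.threshold_method not in ("otsu", "fixed"):
        issues.append(f"unknown threshold method {config.threshold_method!r}")
    if config.circ_variant not in ("table5", "scaled"):
        issues.append(f"unknown circ variant {config.circ_variant!r}")
    if not config.simulate:
        if config.genotype_path is None:
            issues.append("genotype_path required when simulate is off and "
                          "GWAS is enabled")
        elif not Path(config.genotype_path).exists():
            issues.append(f"genotype file not found: {config.genotype_path}")
        if config.phenotype_path and not Path(config.phenotype_path).exists():
            issues.append(f"phenotype file not found: {config.phenotype_path}")
    if config.images_dir and not Path(config.images_dir).exists():
        issues.append(f"image directory not found: {config.images_dir}")
    if config.n_clusters < 2:
        issues.append("n_clusters must be >= 2")
    return issues


def run_pipeline(config: RunConfig) -> dict:
    """(simulate | load) -> traits -> phenostats -> popgen -> gwas -> reports.

    Returns the in-memory artifacts; everything is also written under
    ``config.out_dir``. Deterministic end-to-end for a fixed seed.
    """
    issues = validate_config(config)
    if issues:
        raise ConfigError("; ".join(issues))
    rng_seed = config.seed
    artifacts: dict = {}

    log.info("stage: genotypes")
    if config.simulate:
        spec = _synthetic.PanelSpec(
            n_accessions=config.n_accessions,
            markers_per_chromosome=config.markers_per_chromosome,
            chromosomes=_synthetic.WHEAT_CHROMOSOMES[:config.n_chromosomes],
            seed=rng_seed,
        )
        panel = _synthetic.generate_genotype_panel(spec)
    else:
        panel = read_genotypes(config.genotype_path, config.genotype_format)

    log.info("stage: phenotypes")
    if config.simulate or config.phenotype_path is None:
        pheno_spec = _synthetic.PhenoSpec(
            qtns=[_synthetic.QTN(panel.markers["id"].iloc[panel.n_markers // 2],
                                 effect=1.0)])
        pheno, truth = _synthetic.simulate_phenotypes(panel, pheno_spec,
                                                      seed=rng_seed + 1)
        artifacts["phenotypes"] = pheno
        trait = pheno_spec.trait_name
    else:
        pheno = pd.read_csv(config.phenotype_path)
        artifacts["phenotypes"] = pheno
        trait = pheno["trait"].iloc[0]

    if config.seeds_per_accession > 0:
        log.info("stage: segmentation + traits (%d seeds/accession)",
                 config.seeds_per_accession)
        from . import morphometrics as _morph
        from . import segmentation as _seg

        rng = np.random.default_rng(rng_seed + 2)
        records = []
        for i, acc in enumerate(panel.accessions["id"]):
            for s in range(config.seeds_per_accession):
                p = _synthetic.ShapeParams(
                    a=float(rng.uniform(2.8, 3.8)),
                    b=float(rng.uniform(1.3, 1.9)),
                    n=float(rng.uniform(1.8, 3.0)),
                    rotation=float(rng.uniform(0, 180)))
                img, _ = _synthetic.generate_seed_image(
                    p, scale=config.scale_mm_per_px, seed=rng_seed + 3)
                geom = _seg.measure_image(img, config.threshold_method,
                                          fixed_threshold=100)
                rec = _morph.seed_traits(geom, circ_variant=config.circ_variant)
                rec.update(accession=acc, env="env1", rep=1, seed=s)
                records.append(rec)
        artifacts["trait_table"] = _morph.assemble_trait_table(records)

    log.info("stage: phenostats")
    anova = _phenostats.combined_anova(pheno, trait)
    vc = _phenostats.variance_components(anova)
    artifacts["anova"] = anova.table
    artifacts["heritability"] = {
        "trait": trait, "H2": _phenostats.heritability(vc),
        "sigma2_g": vc.sigma2_g, "sigma2_ge": vc.sigma2_ge,
        "sigma2_e": vc.sigma2_e}
    wide = pheno.pivot_table(index=["accession", "env", "rep"],
                             columns="trait", values="value").reset_index()
    artifacts["summary"] = _phenostats.summary_stats(
        wide.drop(columns=["accession", "env", "rep"]))
    corr, corr_p = _phenostats.correlation_matrix(
        wide.drop(columns=["accession", "env", "rep"]))
    artifacts["correlations"] = corr.reset_index(names="trait")
    artifacts["correlation_p"] = corr_p.reset_index(names="trait")

    log.info("stage: popgen")
    ld, _ = _popgen.pairwise_ld(panel, alpha=config.ld_alpha)
    artifacts["ld_records"] = ld
    artifacts["ld_summary"] = _popgen.ld_summary(
        ld, alpha=config.ld_alpha, near_threshold=config.ld_near_cm)
    curve, decay = _popgen.ld_decay_curve(ld)
    artifacts["ld_decay_curve"] = curve
    K = _popgen.kinship_vanraden(panel)
    artifacts["kinship"] = pd.DataFrame(K, columns=panel.accessions["id"])
    vals, scores, pct = _popgen.pca_genotypes(K)
    artifacts["pca"] = pd.DataFrame({
        "pc": np.arange(1, len(pct) + 1), "eigenvalue": vals,
        "pct_variance": pct})
    labels, _dists = _popgen.cluster_accessions(scores, config.n_clusters,
                                                seed=rng_seed)
    artifacts["clusters"] = pd.DataFrame({
        "accession": panel.accessions["id"], "cluster": labels})
    D = _popgen.kinship_distance(K)
    artifacts["nj_newick"] = _popgen.nj_tree(D, list(panel.accessions["id"]))

    if config.run_gwas:
        log.info("stage: gwas")
        yacc = (pheno[pheno["trait"] == trait]
                .groupby(["accession", "env"])["value"].mean().unstack())
        yacc = yacc.loc[panel.accessions["id"]]
        Q = scores[:, :config.n_pcs]
        y_mean = yacc.mean(axis=1).to_numpy()
        res = _gwas.mlm_scan(y_mean, Q, panel, K, p3d=config.p3d,
                             alpha=config.gwas_alpha)
        log.info("gwas: n=%d m=%d delta=%.4g", panel.n_accessions,
                 panel.n_markers, res.attrs["delta"])
        artifacts["association"] = res
        manh, qq = _gwas.manhattan_qq_export(res)
        artifacts["manhattan"] = manh
        artifacts["qq"] = qq
        env_cols = list(yacc.columns)
        if len(env_cols) >= 2:
            qei = _gwas.qei_scan(
                {c: yacc[c].to_numpy() for c in env_cols}, Q, panel, K,
                alpha=config.gwas_alpha)
            artifacts["qei"] = qei

    artifacts["irrigation"] = _irrigation.month_table()

    manifest = {"config": asdict(config), "seed": config.seed,
                "n_accessions": panel.n_accessions,
                "n_markers": panel.n_markers}
    write_results(artifacts, config.out_dir, manifest)
    return artifacts
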