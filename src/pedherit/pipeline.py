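"""Orchestration of the full family-study analysis.

Given a declarative YAML config, runs: synthetic-cohort simulation (optional),
metabolic-index computation (PMI, HOMA-IR, Matsuda ISI), per-trait
heritability (variance components), trait-pair correlation partitioning with
FDR correction, and carotenoid x PMI response surfaces on ISI. All outputs
are plain delimited text plus a machine-readable run manifest (config hash,
seed, package versions) for auditability.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bivariate import fit_bivariate
from .indices import homa_ir, matsuda_isi, pmi, unit_convert
from .pedigree import compute_kinship, read_pedigree, relative_pairs, write_pedigree
from .polygenic import fit_polygenic
from .simulate import (
    CohortSpec,
    CorrelationStructure,
    TraitGenSpec,
    simulate_cohort,
)
from .surface import fit_surface, summarize_surface
from .traits import TraitSpec, bh_fdr, prepare_trait

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Validated view of the YAML analysis config."""

    raw: dict
    path: Path | None = None
    outdir: Path = field(init=False)

    def __post_init__(self):
        self.outdir = Path(self.raw.get("outdir", "pedherit_out"))
        self.seed = int(self.raw.get("seed", 0))
        trait_names = {t["name"] for t in self.raw.get("traits", [])}
        for pair in self.raw.get("pairs", []):
            for name in pair:
                if trait_names and name not in trait_names:
                    raise ValueError(
                        f"trait pair references undeclared trait {name!r}"
                    )

    @property
    def trait_specs(self) -> list[TraitSpec]:
        return [
            TraitSpec(
                name=t["name"],
                transform=t.get("transform", "inverse_normal"),
                covariates=t.get(
                    "covariates", ["age", "sex", "age2", "age_x_sex"]
                ),
            )
            for t in self.raw.get("traits", [])
        ]

    def phenotype_path(self) -> Path:
        p = self.raw.get("phenotypes")
        if p is None:
            p = self.outdir / "phenotypes.tsv"
        return Path(p)

    def pedigree_path(self) -> Path:
        p = self.raw.get("pedigree")
        if p is None:
            p = self.outdir / "pedigree.fam"
        return Path(p)


def load_config(path) -> AnalysisConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return AnalysisConfig(raw=raw, path=path)


def _load_inputs(cfg: AnalysisConfig):
    ped_path, phe_path = cfg.pedigree_path(), cfg.phenotype_path()
    for p in (ped_path, phe_path):
        if not p.exists():
            raise FileNotFoundError(f"required input file does not exist: {p}")
    ped = read_pedigree(ped_path, dialect="plink_fam")
    pheno = pd.read_csv(phe_path, sep="\t", dtype={"id": str})
    return ped, pheno


def run_simulate(cfg: AnalysisConfig) -> dict:
    """Generate a synthetic cohort and write pedigree + phenotype tables."""
    sim = cfg.raw.get("simulate")
    if sim is None:
        raise ValueError("config has no 'simulate' section")
    spec = CohortSpec(
        n_nuclear_families=sim.get("n_nuclear_families", 401),
        extended_linking=sim.get("extended_linking", 0.3),
        girl_fraction=sim.get("girl_fraction", 0.493),
        seed=cfg.seed,
    )
    traits = [
        TraitGenSpec(
            name=t["name"], mean=t["mean"], sd=t["sd"], h2=t["h2"],
            transform=t.get("transform", "identity"),
            age_beta=t.get("age_beta", 0.0), sex_beta=t.get("sex_beta", 0.0),
        )
        for t in sim["traits"]
    ]
    names = [t.name for t in traits]
    corr_cfg = sim.get("correlations", {})
    corr = CorrelationStructure.from_pairs(
        names,
        {(a, b): r for a, b, r in corr_cfg.get("rho_g", [])},
        {(a, b): r for a, b, r in corr_cfg.get("rho_e", [])},
    )
    cohort = simulate_cohort(
        spec, traits, corr, seed=cfg.seed,
        ogtt=sim.get("ogtt", False),
        ir_source=sim.get("ir_source"),
        carotenoid_effects=sim.get("carotenoid_effects"),
    )
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    write_pedigree(cohort.pedigree, cfg.pedigree_path())
    cohort.phenotypes.to_csv(cfg.phenotype_path(), sep="\t", index=False)
    pairs = relative_pairs(
        cohort.pedigree, cohort.kinship, ids=cohort.pedigree.leaves()
    )
    pairs.to_csv(cfg.outdir / "relative_pairs.tsv", sep="\t", index=False)
    total = int(pairs.loc[pairs.pair_class == "total related", "count"].iloc[0])
    logger.info("simulated %d children, %d related pairs among children",
                len(cohort.pedigree.leaves()), total)
    return {"n_children": len(cohort.pedigree.leaves()), "related_pairs": total}


def run_indices(cfg: AnalysisConfig) -> pd.DataFrame:
    """Append PMI / HOMA-IR / Matsuda ISI columns to the phenotype table."""
    _, pheno = _load_inputs(cfg)
    idx_cfg = cfg.raw.get("indices", {})
    pmi_cfg = idx_cfg.get("pmi")
    if pmi_cfg is not None:
        wc = pheno[pmi_cfg.get("wc", "waist")].to_numpy(dtype=float)
        if pmi_cfg.get("wc_unit", "cm") == "mm":
            wc = unit_convert(wc, "wc")
        tg = pheno[pmi_cfg.get("tg", "tg")].to_numpy(dtype=float)
        if pmi_cfg.get("tg_unit", "mmol/L") == "mg/dl":
            tg = unit_convert(tg, "tg")
        hdl = pheno[pmi_cfg.get("hdl", "hdl")].to_numpy(dtype=float)
        if pmi_cfg.get("hdl_unit", "mmol/L") == "mg/dl":
            hdl = unit_convert(hdl, "hdl")
        pheno["pmi"] = pmi(
            pheno[pmi_cfg.get("bmi_z", "bmi_z")].to_numpy(dtype=float),
            wc, tg, hdl,
            pheno["age"].to_numpy(dtype=float),
            pheno["sex"].to_numpy(),
        )
    gcols = sorted(
        (c for c in pheno.columns if c.startswith("glucose_")),
        key=lambda c: int(c.split("_")[1]),
    )
    icols = [c.replace("glucose", "insulin") for c in gcols]
    if gcols and all(c in pheno.columns for c in icols):
        G = pheno[gcols].to_numpy(dtype=float)
        I = pheno[icols].to_numpy(dtype=float)
        pheno["homa_ir"] = homa_ir(G[:, 0], I[:, 0])
        pheno["isi"] = matsuda_isi(G, I)
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    out = cfg.outdir / "phenotypes_with_indices.tsv"
    pheno.to_csv(out, sep="\t", index=False)
    cfg.raw["phenotypes"] = str(out)  # downstream stages read the augmented table
    return pheno


def _prepared_traits(cfg: AnalysisConfig, pheno: pd.DataFrame) -> dict:
    prepared = {}
    for spec in cfg.trait_specs:
        try:
            prepared[spec.name] = prepare_trait(
                pheno, spec, screen=cfg.raw.get("screen_covariates", False)
            )
        except Exception as exc:  # per-trait failure: record, continue
            logger.error("preparing trait %s failed: %s", spec.name, exc)
    return prepared


def run_heritability(cfg: AnalysisConfig) -> pd.DataFrame:
    """Per-trait polygenic heritability table (trait, h2, SE, p, n)."""
    ped, pheno = _load_inputs(cfg)
    kin = compute_kinship(ped)
    prepared = _prepared_traits(cfg, pheno)
    rows = []
    for name, prep in prepared.items():
        try:
            fit = fit_polygenic(prep.values, kin)
            rows.append({"trait": name, **fit.as_row()})
            logger.info("heritability %s: h2=%.3f (SE %.3f), p=%.3g, n=%d",
                        name, fit.h2, fit.h2_se, fit.lrt_p, fit.n)
        except Exception as exc:
            logger.error("heritability fit for %s failed: %s", name, exc)
            rows.append({"trait": name, "h2": np.nan, "error": str(exc)})
    table = pd.DataFrame(rows)
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(cfg.outdir / "heritability.tsv", sep="\t", index=False)
    return table


def run_correlations(cfg: AnalysisConfig) -> pd.DataFrame:
    """Trait-pair correlation partitioning with BH-FDR adjusted p columns."""
    ped, pheno = _load_inputs(cfg)
    kin = compute_kinship(ped)
    prepared = _prepared_traits(cfg, pheno)
    rows = []
    for a, b in cfg.raw.get("pairs", []):
        if a not in prepared or b not in prepared:
            logger.error("pair (%s, %s): missing prepared trait", a, b)
            continue
        try:
            fit = fit_bivariate(
                prepared[a].values, prepared[b].values, kin, names=(a, b)
            )
            rows.append(fit.as_row())
        except Exception as exc:
            logger.error("bivariate fit (%s, %s) failed: %s", a, b, exc)
            rows.append({"trait1": a, "trait2": b, "error": str(exc)})
    table = pd.DataFrame(rows)
    if cfg.raw.get("fdr", True) and not table.empty:
        for col in ("p_rho_p", "p_rho_g", "p_rho_e"):
            if col in table:
                ok = table[col].notna()
                table.loc[ok, col + "_fdr"] = bh_fdr(table.loc[ok, col].to_numpy())
        logger.info(
            "FDR correction applied (Benjamini-Hochberg step-up) across %d pairs",
            len(table),
        )
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(cfg.outdir / "correlations.tsv", sep="\t", index=False)
    return table


def run_rsm(cfg: AnalysisConfig) -> dict:
    """Per-carotenoid response-surface grids of ISI over (carotenoid, PMI)."""
    _, pheno = _load_inputs(cfg)
    rsm = cfg.raw.get("rsm", {})
    pmi_col = rsm.get("pmi_col", "pmi")
    isi_col = rsm.get("isi_col", "isi")
    bands = [tuple(b) for b in rsm.get("pmi_bands", [[2.0, 4.0]])]
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    summaries = {}
    for name in rsm.get("carotenoids", []):
        fit = fit_surface(
            pheno[name], pheno[pmi_col], pheno[isi_col],
            bandwidth=rsm.get("bandwidth", 0.5),
            grid_size=rsm.get("grid_size", 50),
        )
        fit.to_long().to_csv(cfg.outdir / f"rsm_{name}.tsv", sep="\t", index=False)
        summaries[name] = []
        for band in bands:
            rep = summarize_surface(fit, band)
            rep.pop("profile")
            summaries[name].append(rep)
            logger.info("rsm %s band %s: %s", name, band, rep["trend"])
    with open(cfg.outdir / "rsm_summaries.json", "w") as fh:
        json.dump(summaries, fh, indent=2)
    return summaries


def write_manifest(cfg: AnalysisConfig) -> Path:
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    cfg_bytes = yaml.safe_dump(cfg.raw, sort_keys=True).encode()
    manifest = {
        "config_sha256": hashlib.sha256(cfg_bytes).hexdigest(),
        "seed": cfg.seed,
        "pedherit": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    path = cfg.outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def run_all(cfg: AnalysisConfig) -> None:
    if "simulate" in cfg.raw:
        run_simulate(cfg)
    run_indices(cfg)
    run_heritability(cfg)
    run_correlations(cfg)
    if cfg.raw.get("rsm"):
        run_rsm(cfg)
    write_manifest(cfg)


def default_config(outdir: str = "pedherit_out", seed: int = 1) -> dict:
    """A complete demo config: synthetic cohort with study-like parameters."""
    carotenoids = [
        # (name, mean umol/L, sd, h2)
        ("alpha_carotene", 0.60, 0.97, 0.81),
        ("beta_carotene", 0.48, 0.59, 0.90),
        ("beta_cryptoxanthin", 0.51, 0.42, 0.58),
        ("lycopene", 0.41, 0.58, 0.98),
    ]
    sim_traits = [
        {"name": n, "mean": m, "sd": s, "h2": h, "transform": "exp",
         "age_beta": 0.02, "sex_beta": 0.1}
        for n, m, s, h in carotenoids
    ]
    sim_traits += [
        {"name": "hdl", "mean": 45.8, "sd": 10.9, "h2": 0.64},
        {"name": "waist", "mean": 764.5, "sd": 179.7, "h2": 0.63,
         "age_beta": 0.15},
        {"name": "tg", "mean": 74.9, "sd": 39.8, "h2": 0.77, "transform": "exp"},
        {"name": "bmi_z", "mean": 1.0, "sd": 1.0, "h2": 0.75},
        {"name": "insulin", "mean": 13.6, "sd": 9.4, "h2": 0.55,
         "transform": "exp"},
    ]
    rho_g = [
        ["beta_cryptoxanthin", "hdl", 0.62],
        ["beta_cryptoxanthin", "waist", -0.34],
        ["beta_cryptoxanthin", "tg", -0.44],
        ["lycopene", "hdl", 0.24],
        ["lycopene", "waist", -0.06],
        ["beta_cryptoxanthin", "lycopene", 0.3],
        ["alpha_carotene", "beta_carotene", 0.5],
        ["hdl", "tg", -0.4],
        ["insulin", "waist", 0.4],
        ["insulin", "bmi_z", 0.35],
    ]
    rho_e = [
        ["beta_cryptoxanthin", "hdl", -0.19],
        ["beta_cryptoxanthin", "waist", -0.1],
        ["beta_cryptoxanthin", "tg", 0.36],
        ["lycopene", "hdl", -0.08],
        ["lycopene", "waist", -0.02],
        ["beta_cryptoxanthin", "lycopene", 0.2],
        ["alpha_carotene", "beta_carotene", 0.3],
        ["hdl", "tg", -0.2],
        ["insulin", "waist", 0.3],
        ["insulin", "bmi_z", 0.25],
    ]
    analysis_traits = [
        {"name": n, "transform": "inverse_normal",
         "covariates": ["age", "sex", "age2", "age_x_sex"]}
        for n in ("alpha_carotene", "beta_carotene", "beta_cryptoxanthin",
                  "lycopene", "hdl", "waist", "tg", "insulin")
    ]
    return {
        "seed": seed,
        "outdir": outdir,
        "simulate": {
            "n_nuclear_families": 401,
            "extended_linking": 0.3,
            "traits": sim_traits,
            "correlations": {"rho_g": rho_g, "rho_e": rho_e},
            "ogtt": True,
            "ir_source": "insulin",
            "carotenoid_effects": {"alpha_carotene": 0.35, "beta_carotene": 0.35},
        },
        "traits": analysis_traits,
        "pairs": [
            ["beta_cryptoxanthin", "hdl"],
            ["beta_cryptoxanthin", "waist"],
            ["beta_cryptoxanthin", "tg"],
            ["lycopene", "hdl"],
            ["lycopene", "waist"],
        ],
        "fdr": True,
        "indices": {
            "pmi": {"bmi_z": "bmi_z", "wc": "waist", "wc_unit": "mm",
                    "tg": "tg", "tg_unit": "mg/dl",
                    "hdl": "hdl", "hdl_unit": "mg/dl"},
        },
        "rsm": {
            "carotenoids": ["alpha_carotene", "beta_carotene",
                            "beta_cryptoxanthin", "lycopene"],
            "pmi_col": "pmi",
            "isi_col": "isi",
            "bandwidth": 0.5,
            "grid_size": 50,
            "pmi_bands": [[0, 2], [2, 4]],
        },
    }
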