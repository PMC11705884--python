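"""End-to-end orchestration: filter -> PCA/GWAS -> candidates -> effects ->
diversity -> morphology and climate trends, from one declarative YAML config.

Every stage is also callable on its own through the library modules; the
pipeline only sequences them, writes their tables, and records a manifest of
output files with content hashes so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, assoc, diversity, effects, glcore, phenoclim, simulate

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "demo"]

log = logging.getLogger("tempopgen.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    beagle: str
    samples: str
    output_dir: str
    gff: str | None = None
    climate: str | None = None
    seed: int = 0
    filters: dict = field(default_factory=dict)
    gwas: list = field(default_factory=lambda: [{"response": "bill", "sex": "M"}])
    effects: dict = field(default_factory=lambda: {"cross_sex": True})
    diversity: dict = field(default_factory=lambda: {"window": 10_000, "min_per_year": 5})
    morphology: dict = field(default_factory=lambda: {"traits": ["bill", "tarsus", "wing"]})
    climate_summary: dict = field(
        default_factory=lambda: {"variable": "tmin", "season": "breeding"}
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self):
        for name in ("beagle", "samples", "gff", "climate"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; return a manifest {filename: sha256}."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def emit(name: str):
        manifest[name] = _sha256(outdir / name)

    t0 = time.time()
    with _Stage("load"):
        gl = glcore.read_beagle(cfg.beagle)
        samples = pd.read_csv(cfg.samples, sep="\t")
        if len(samples) != gl.n_individuals:
            raise ValueError("sample table and BEAGLE file disagree on individuals")

    with _Stage("filter"):
        fcfg = glcore.FilterConfig(**cfg.filters)
        gl_f, drop_counts = glcore.apply_filters(gl, fcfg)
        _write(
            pd.DataFrame(
                {"filter": list(drop_counts), "dropped": list(drop_counts.values())}
            ),
            outdir / "filter_report.tsv",
        )
        glcore.write_beagle(gl_f, outdir / "filtered.beagle.gz")
        emit("filter_report.tsv")
        manifest["filtered.beagle.gz"] = _sha256(outdir / "filtered.beagle.gz")

    samples = phenoclim.relative_traits(samples)
    candidates_by_run: dict[tuple[str, str], pd.DataFrame] = {}
    with _Stage("gwas"):
        for run_cfg in cfg.gwas:
            acfg = assoc.AssocConfig(**run_cfg)
            res = assoc.run_gwas(gl_f, samples, acfg)
            name = f"gwas_{acfg.response}_{acfg.sex}.tsv"
            _write(res, outdir / name)
            emit(name)
            cands = res[res["p"] < acfg.candidate_cutoff]
            cands = cands.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
            cname = f"candidates_{acfg.response}_{acfg.sex}.tsv"
            _write(cands, outdir / cname)
            emit(cname)
            candidates_by_run[(acfg.response, acfg.sex)] = cands

    with _Stage("effects"):
        comparisons = {}
        for (response, sex), cands in candidates_by_run.items():
            if response == "year" or len(cands) < 4:
                continue
            bm = effects.beta_for_response(gl_f, samples, cands, response, sex)
            by = effects.beta_for_response(gl_f, samples, cands, "year", sex)
            comp = effects.compare_effects(
                bm[f"beta_{response}"].to_numpy(), by["beta_year"].to_numpy()
            )
            tab = bm[["chrom", "pos", "minor", f"beta_{response}"]].copy()
            tab["beta_year"] = by["beta_year"].to_numpy()
            name = f"effects_{response}_{sex}.tsv"
            _write(tab, outdir / name)
            emit(name)
            entry = {
                "rho": comp.rho,
                "p": comp.p,
                "n": comp.n,
                "method": comp.method,
            }
            if cfg.effects.get("cross_sex", True):
                other = "F" if sex == "M" else "M"
                try:
                    bx = effects.cross_sex_effects(
                        gl_f, samples, cands, response, sex, other
                    )
                    xcomp = effects.compare_effects(
                        bm[f"beta_{response}"].to_numpy(),
                        bx[f"beta_{response}"].to_numpy(),
                    )
                    entry["cross_sex_rho"] = xcomp.rho
                    entry["cross_sex_p"] = xcomp.p
                except ValueError as err:
                    entry["cross_sex_error"] = str(err)
            comparisons[f"{response}_{sex}"] = entry
        (outdir / "effect_comparisons.json").write_text(
            json.dumps(comparisons, indent=2, default=float)
        )
        emit("effect_comparisons.json")

    with _Stage("diversity"):
        dcfg = cfg.diversity
        wd = diversity.window_diversity(
            gl_f,
            samples,
            window=int(dcfg.get("window", 10_000)),
            min_per_year=int(dcfg.get("min_per_year", 5)),
            min_sites=int(dcfg.get("min_sites", diversity.MIN_SITES_PER_WINDOW)),
        )
        _write(wd, outdir / "window_diversity.tsv")
        emit("window_diversity.tsv")
        trends = {}
        for metric in ("thetaW", "pi"):
            try:
                fit, _ = phenoclim.diversity_trend(wd, metric)
                trends[metric] = {"slope": fit.slope, "p": fit.p, "n": fit.n}
            except ValueError as err:
                trends[metric] = {"error": str(err)}
        (outdir / "diversity_trends.json").write_text(json.dumps(trends, indent=2))
        emit("diversity_trends.json")

    with _Stage("morphology"):
        morph = {}
        for trait in cfg.morphology.get("traits", []):
            try:
                res = phenoclim.fit_trait_model(samples, trait)
                morph[trait] = {
                    "formula": res.formula,
                    "aic": res.aic,
                    "coefficients": res.coefficients.to_dict(orient="records"),
                    "n": res.n,
                }
            except ValueError as err:
                morph[trait] = {"error": str(err)}
        (outdir / "morphology_models.json").write_text(
            json.dumps(morph, indent=2, default=float)
        )
        emit("morphology_models.json")

    if cfg.climate is not None:
        with _Stage("climate"):
            daily = pd.read_csv(cfg.climate, sep="\t")
            ccfg = cfg.climate_summary
            summ = phenoclim.seasonal_summaries(
                daily, ccfg.get("variable", "tmin"), ccfg.get("season", "breeding")
            )
            trends = phenoclim.climate_trends(summ)
            _write(trends, outdir / "climate_trends.tsv")
            emit("climate_trends.tsv")
            frac = phenoclim.fraction_increasing(trends)
            (outdir / "climate_summary.json").write_text(
                json.dumps({"fraction_increasing_pct": frac, "n_points": len(trends)})
            )
            emit("climate_summary.json")

    if cfg.gff is not None:
        with _Stage("annotate"):
            genes = annotate.read_gff3(cfg.gff)
            for (response, sex), cands in candidates_by_run.items():
                if len(cands) == 0:
                    continue
                reports = annotate.ld_link_genes(cands, gl_f, genes)
                name = f"linked_genes_{response}_{sex}.tsv"
                _write(annotate.linkage_table(reports), outdir / name)
                emit(name)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline finished in %.1f s (%d outputs)", time.time() - t0, len(manifest))
    return manifest


class _Stage:
    """Context manager that tags any failure with the stage name."""

    def __init__(self, name: str):
        self.name = name
        self.t0 = time.time()
        log.info("stage %s start", name)

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise PipelineError(self.name, exc) from exc
        log.info("stage %s done (%.1f s)", self.name, time.time() - self.t0)
        return False


def _demo_gff(gl: glcore.GLMatrix, path: Path):
    """Synthetic three-gene annotation covering part of the simulated chromosome."""
    chrom = gl.sites["chrom"].iloc[0]
    lo = int(gl.sites["pos"].min())
    hi = int(gl.sites["pos"].max())
    third = max((hi - lo) // 3, 1)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i in range(3):
            a = lo + i * third
            b = min(a + third - 1, hi)
            fh.write(
                f"{chrom}\tsynthetic\tgene\t{a}\t{b}\t.\t+\t.\tID=gene{i + 1}\n"
            )


def demo(seed: int = 42, outdir: str | Path = "demo_out") -> dict:
    """Generate a small synthetic study and run the full pipeline on it.

    Uses a 200-site cohort with selection on bill length so the headline
    comparison (beta_bill vs beta_year) is exercised end to end.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate.SimConfig(
        n_sites=200,
        n_causal_per_trait=5,
        years=(1986, 2014),
        n_per_year=40,
        effect_sd=0.8,
        effect_dist="graded",
        trait_residual_sd=0.3,
        selection_gradient={"bill": -0.08, "tarsus": 0.0, "wing": 0.0},
        init_freq_range=(0.3, 0.7),
        seed=int(seed),
    )
    truth, samples, gl = simulate.simulate_full(sim)
    glcore.write_beagle(gl, outdir / "input.beagle.gz")
    samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    truth.z_genetic.to_csv(outdir / "truth_genetic_values.tsv", sep="\t", index=False)
    _demo_gff(gl, outdir / "genes.gff3")
    daily, _ = simulate.simulate_climate_grid(
        12, (2000, 2014), trend_mean=0.06, noise_sd=1.0, seed=int(seed), frac_positive=0.9
    )
    daily.to_csv(outdir / "climate.tsv", sep="\t", index=False)
    cfg = PipelineConfig(
        beagle=str(outdir / "input.beagle.gz"),
        samples=str(outdir / "samples.tsv"),
        gff=str(outdir / "genes.gff3"),
        climate=str(outdir / "climate.tsv"),
        output_dir=str(outdir / "results"),
        seed=int(seed),
        filters={"min_maf": 0.02, "min_individuals": 100},
        # demo-scale candidate cutoff: the 200-site cohort is far smaller than
        # a genome-wide screen, so the genome-wide 1e-5 threshold is relaxed
        gwas=[
            {"response": "bill", "sex": "M", "n_pcs": 4, "candidate_cutoff": 1e-3},
            {"response": "bill", "sex": "F", "n_pcs": 4, "candidate_cutoff": 1e-3},
        ],
        diversity={"window": 50_000, "min_per_year": 5, "min_sites": 20},
    )
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.__dict__, fh)
    return run_pipeline(cfg)
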