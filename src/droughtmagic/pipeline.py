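"""End-to-end orchestration: simulate (or ingest) -> tolerance indices ->
QC -> per-trait GWAS -> LD + association network -> genomic selection.

All randomness flows from a single root seed split per stage; the run
manifest records the seed, stage counts and output files, so a rerun
with the same configuration is byte-identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gselect, gwas, io, ld, qc, simulate, tolerance

GWAS_TRAITS = list(tolerance.TI_COLUMNS.values()) + ["habit_change"]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "droughtmagic_run"
    genotype_path: str | None = None  # ingest instead of simulating
    phenotype_path: str | None = None
    n_rils: int = 305
    n_chrom: int = 11
    snps_per_chrom: int = 182
    cm_length: float = 80.0
    selfing_generations: int = 7
    missing_rate: float = 0.02
    het_error_rate: float = 0.01
    max_missing: float = 0.10
    max_het: float = 0.10
    min_maf: float = 0.05
    ld_prune_r2: float = 0.7
    max_iterations: int = 10
    candidate_p_cap: float | None = None
    lod_threshold: float = 3.0
    fallback_top_n: int = 5
    r2_high: float = 0.8
    gs_k_values: list = field(default_factory=lambda: list(range(2, 9)))
    gs_reps: int = 100
    traits: list = field(default_factory=lambda: list(GWAS_TRAITS))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {
        name: int(rng.integers(2**31 - 1))
        for name in ("simulate", "gwas", "gs")
    }
    manifest = {"seed": config.seed, "stage_seeds": stage_seeds, "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                info = fn()
            except Exception as err:  # persist prior outputs, name the stage
                io.write_manifest(manifest, out / "manifest.json")
                raise StageError(name, err) from err
            manifest["stages"][name] = info
            return info

        return deco

    _state: dict = {}

    @stage("input")
    def _input():
        if config.genotype_path:
            geno = io.read_genotypes(config.genotype_path)
            pheno = io.read_phenotypes(config.phenotype_path)
        else:
            geno, pheno, truth = simulate.simulate_population(
                n_rils=config.n_rils,
                n_chrom=config.n_chrom,
                snps_per_chrom=config.snps_per_chrom,
                cm_lengths=config.cm_length,
                selfing_generations=config.selfing_generations,
                missing_rate=config.missing_rate,
                het_error_rate=config.het_error_rate,
                seed=stage_seeds["simulate"],
            )
            io.write_genotypes(geno, out / "genotypes.tsv")
            io.write_phenotypes(pheno, out / "phenotypes.tsv")
            io.write_truth(truth, geno, out / "truth.tsv")
        _state["geno"], _state["pheno"] = geno, pheno
        return {"n_samples": geno.n_samples, "n_snps": geno.n_snps}

    @stage("tolerance")
    def _tolerance():
        ti = tolerance.tolerance_table(_state["pheno"])
        ti.to_csv(out / "tolerance_index.tsv", sep="\t", index=False, na_rep="NA")
        screen = tolerance.habit_logistic_screen(ti)
        screen.to_csv(out / "habit_logistic.tsv", sep="\t", index=False, na_rep="NA")
        corr = tolerance.correlation_matrix(ti)
        corr.to_csv(out / "ti_correlations.tsv", sep="\t", na_rep="NA")
        _state["ti"] = ti
        return {"n_rils": len(ti), "n_habit_changed": int((ti["habit_change"] == 9).sum())}

    @stage("qc")
    def _qc():
        filt = qc.SnpQC(config.max_missing, config.max_het, config.min_maf).fit(
            _state["geno"]
        )
        geno_qc = filt.transform(_state["geno"])
        rep = filt.report_
        rep.per_snp.to_csv(out / "qc_report.tsv", sep="\t", index=False, na_rep="NA")
        io.write_genotypes(geno_qc, out / "genotypes.qc.tsv")
        _state["geno_qc"] = geno_qc
        return {
            "n_input": rep.n_input,
            "n_retained": rep.n_retained,
            "n_fail_missing": rep.n_fail_missing,
            "n_fail_het": rep.n_fail_het,
            "n_fail_maf": rep.n_fail_maf,
        }

    @stage("gwas")
    def _gwas():
        geno_qc = _state["geno_qc"]
        ti = _state["ti"].set_index("ril").loc[_state["geno"].samples]
        results = {}
        info = {}
        for trait in config.traits:
            y = ti[trait].to_numpy(dtype=float)
            keep = ~np.isnan(y)
            sub = simulate.GenotypeMatrix(
                calls=geno_qc.calls[keep],
                snp_id=geno_qc.snp_id,
                chrom=geno_qc.chrom,
                pos=geno_qc.pos,
                samples=[s for s, k in zip(geno_qc.samples, keep) if k],
            )
            res = gwas.blink(
                sub,
                y[keep],
                gwas.BlinkConfig(
                    ld_prune_r2=config.ld_prune_r2,
                    max_iterations=config.max_iterations,
                    candidate_p_cap=config.candidate_p_cap,
                    lod_threshold=config.lod_threshold,
                    fallback_top_n=config.fallback_top_n,
                    seed=stage_seeds["gwas"],
                ),
            )
            res.table.to_csv(out / f"gwas_{trait}.tsv", sep="\t", index=False, na_rep="NA")
            results[trait] = res
            info[trait] = {
                "n_significant": int(res.table["significant"].sum()),
                "fallback": res.fallback,
                "n_qtn": len(res.qtn_ids),
            }
        _state["gwas"] = results
        return info

    @stage("network")
    def _network():
        geno_qc = _state["geno_qc"]
        trait_results = {
            trait: res.significant[["snp_id", "lod"]]
            for trait, res in _state["gwas"].items()
        }
        all_snps = sorted(
            {s for df in trait_results.values() for s in df["snp_id"]}
        )
        ldm = ld.ld_matrix(geno_qc, snp_ids=all_snps) if all_snps else None
        if ldm is not None:
            ldm.to_csv(out / "ld_significant.tsv", sep="\t", na_rep="NA")
        net = ld.build_network(trait_results, ldm, r2_high=config.r2_high)
        ld.export_graph(net, str(out / "network"))
        comps = ld.subnetworks(net)
        return {
            "n_nodes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
            "n_subnetworks": len(comps),
        }

    @stage("gs")
    def _gs():
        geno_qc = _state["geno_qc"]
        ti = _state["ti"].set_index("ril").loc[_state["geno"].samples]
        all_records = []
        info = {}
        for trait in config.traits:
            y = ti[trait].to_numpy(dtype=float)
            if trait == "habit_change":
                y = tolerance.habit_change_binary(y)
            sub, yy, n_dropped = gselect.drop_missing_phenotypes(geno_qc, y)
            res = gselect.cross_validate(
                sub,
                yy,
                k_values=config.gs_k_values,
                reps=config.gs_reps,
                seed=stage_seeds["gs"],
            )
            rec = res.records.copy()
            rec.insert(0, "trait", trait)
            all_records.append(rec)
            info[trait] = {
                "n_used": len(yy),
                "n_dropped": n_dropped,
                "mean_accuracy": float(res.records["accuracy"].mean()),
            }
        pd.concat(all_records, ignore_index=True).to_csv(
            out / "gs_accuracy.tsv", sep="\t", index=False, na_rep="NA"
        )
        return info

    config.to_yaml(out / "config.yaml")
    io.write_manifest(manifest, out / "manifest.json")
    return manifest
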