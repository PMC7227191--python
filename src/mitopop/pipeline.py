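"""End-to-end analysis pipeline.

From a FASTA of equal-length same-locus sequences and a population map, runs:
complete-deletion filtering, haplotype collapsing, diversity indices per
analysis unit, neutrality tests, hierarchical and pairwise AMOVA with
permutation significance, gene-flow conversion, mismatch-distribution
demography, and median-joining network export. Every report value is
re-derivable from the underlying module calls with the logged parameters.

A stage failure aborts the run with the stage name and cause; outputs of the
stages already completed are retained and MANIFEST.json records per-stage
completeness.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import demography, differentiation, diversity, haplotypes, network, neutrality, seq_io

logger = logging.getLogger("mitopop")

ALL_STAGES = (
    "diversity",
    "neutrality",
    "amova",
    "fst",
    "mismatch",
    "network",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    fasta: str | Path
    popmap: str | Path
    outdir: str | Path
    seed: int
    units: tuple[str, ...] = ("population", "pooled")
    permutations: int = 10000
    neutrality_reps: int = 10000
    bootstrap_reps: int = 1000
    skip: tuple[str, ...] = ()
    ecological_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        bad = set(self.skip) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages to skip: {sorted(bad)}")


@dataclass
class PipelineResult:
    outdir: Path
    files: dict[str, Path] = dc_field(default_factory=dict)
    manifest: dict[str, str] = dc_field(default_factory=dict)


def _fmt(df: pd.DataFrame, decimals: dict[str, int]) -> pd.DataFrame:
    out = df.copy()
    for col, nd in decimals.items():
        if col in out:
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.{nd}f}"
            )
    return out


def run(config: PipelineConfig) -> PipelineResult:
    """Run the configured stages; returns output paths and a MANIFEST."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    full = outdir / "full_precision"
    full.mkdir(exist_ok=True)
    result = PipelineResult(outdir)
    manifest = result.manifest

    t0 = time.time()
    records = seq_io.read_fasta(config.fasta)
    popmap = seq_io.read_popmap(config.popmap, records)
    raw = seq_io.AlignmentMatrix.from_records(records)
    aln, kept = seq_io.complete_deletion(raw)
    logger.info(
        "input: n=%d, raw L=%d, post-deletion L=%d", aln.n, raw.L, aln.L
    )
    sites_path = outdir / "retained_sites.tsv"
    pd.DataFrame({"retained_position_1based": kept + 1}).to_csv(
        sites_path, sep="\t", index=False
    )
    result.files["retained_sites"] = sites_path

    table = haplotypes.collapse_haplotypes(aln, popmap)
    sharing = haplotypes.classify_sharing(table, popmap)
    hap_df = table.to_frame()
    hap_df["status"] = [sharing.status[l] for l in table.labels]
    hap_path = outdir / "haplotypes.tsv"
    hap_df.to_csv(hap_path, sep="\t")
    result.files["haplotypes"] = hap_path
    manifest["haplotypes"] = "complete"

    dist = diversity.pairwise_differences(aln)

    def units_of(kind: str) -> list[tuple[str, list[str]]]:
        if kind == "pooled":
            return [("pooled", list(aln.ids))]
        if kind == "population":
            return [(p, popmap.members(p)) for p in popmap.populations()]
        if kind == "subpopulation":
            return [(p, popmap.subpop_members(p)) for p in popmap.subpopulations()]
        raise ValueError(f"unknown unit kind {kind!r}")

    unit_list = [u for kind in config.units for u in units_of(kind)]

    def stage_diversity() -> None:
        rows = []
        for name, ids in unit_list:
            sub = aln.subset(ids)
            summ = diversity.summarize_diversity(sub, unit=name)
            rows.append(vars(summ))
        div_df = pd.DataFrame(rows)
        div_df.to_csv(full / "diversity.tsv", sep="\t", index=False)
        _fmt(div_df, {"K": 4, "pi": 4, "Hd": 4}).to_csv(
            outdir / "diversity.tsv", sep="\t", index=False
        )
        result.files["diversity"] = outdir / "diversity.tsv"

    def stage_neutrality() -> None:
        rows = []
        for i, (name, ids) in enumerate(unit_list):
            sub = aln.subset(ids)
            S, _ = haplotypes.segregating_sites(sub)
            K = dist.submatrix(ids).mean_pairwise()
            h = len(set(sub.sequences()))
            if sub.n < 4:
                logger.info(
                    "neutrality[%s]: n=%d too small, reporting NaN", name, sub.n
                )
                nan = float("nan")
                rows.append(
                    dict(unit=name, n=sub.n, S=S, K=K, D=nan, p_D=nan, Fs=nan,
                         S_prime=nan, p_Fs=nan, theta_hat=K,
                         reps=config.neutrality_reps, seed=None)
                )
                continue
            res = neutrality.neutrality_tests(
                name, sub.n, S, K, h,
                reps=config.neutrality_reps, seed=config.seed + 1000 + i,
            )
            rows.append(vars(res))
        neut_df = pd.DataFrame(rows)
        neut_df.to_csv(full / "neutrality.tsv", sep="\t", index=False)
        _fmt(neut_df, {"K": 4, "D": 5, "Fs": 5, "p_D": 4, "p_Fs": 4}).to_csv(
            outdir / "neutrality.tsv", sep="\t", index=False
        )
        result.files["neutrality"] = outdir / "neutrality.tsv"

    def stage_amova() -> None:
        frames = {}
        frames["region"] = differentiation.amova(
            dist, popmap, levels=3,
            permutations=config.permutations, seed=config.seed + 1,
        )
        if config.ecological_groups:
            eco = popmap.with_grouping(config.ecological_groups)
            frames["ecology"] = differentiation.amova(
                dist, eco, levels=3,
                permutations=config.permutations, seed=config.seed + 2,
            )
        parts = []
        for label, res in frames.items():
            t = res.table.copy()
            t.insert(0, "grouping", label)
            parts.append(t)
            logger.info(
                "amova[%s]: indices=%s p=%s", label, res.indices, res.p_values
            )
        amova_df = pd.concat(parts)
        amova_df.to_csv(full / "amova.tsv", sep="\t")
        amova_df.to_csv(outdir / "amova.tsv", sep="\t")
        with open(outdir / "amova_indices.json", "w") as fh:
            json.dump(
                {
                    label: {
                        "indices": {k: float(v) for k, v in res.indices.items()},
                        "p_values": res.p_values,
                    }
                    for label, res in frames.items()
                },
                fh,
                indent=2,
            )
        result.files["amova"] = outdir / "amova.tsv"

    def stage_fst() -> None:
        fst_m, p_m, pair_results = differentiation.pairwise_fst(
            dist, popmap,
            permutations=config.permutations, seed=config.seed + 3,
        )
        fst_m.to_csv(outdir / "fst_matrix.tsv", sep="\t")
        p_m.to_csv(outdir / "fst_pvalues.tsv", sep="\t")
        nm_rows = [
            {
                "pop_a": r.pair[0],
                "pop_b": r.pair[1],
                "fst": r.fst,
                "p": r.p_value,
                "Nm": r.nm,
            }
            for r in pair_results
        ]
        pd.DataFrame(nm_rows).to_csv(outdir / "nm.tsv", sep="\t", index=False)
        result.files["fst"] = outdir / "fst_matrix.tsv"

    def stage_mismatch() -> None:
        (outdir / "mismatch").mkdir(exist_ok=True)
        fit_rows = []
        for i, (name, ids) in enumerate(unit_list):
            sub_d = dist.submatrix(ids)
            spec = demography.mismatch_spectrum(sub_d)
            fit = demography.fit_sudden_expansion(spec, n=len(ids))
            p_ssd, p_r = demography.mismatch_pvalues(
                spec, fit, n=len(ids),
                reps=config.bootstrap_reps, seed=config.seed + 2000 + i,
            )
            support = np.arange(fit.support + 1)
            obs_ext = np.zeros(fit.support + 1)
            obs_ext[: len(spec.x)] = spec.x
            pd.DataFrame(
                {"class": support, "observed": obs_ext, "expected": fit.expected}
            ).to_csv(outdir / "mismatch" / f"{name}.csv", index=False)
            fit_rows.append(
                {
                    "unit": name, "tau": fit.tau, "theta0": fit.theta0,
                    "theta1": fit.theta1, "SSD": fit.ssd, "p_SSD": p_ssd,
                    "raggedness": fit.r, "p_raggedness": p_r,
                    "reps": config.bootstrap_reps, "seed": config.seed + 2000 + i,
                }
            )
        fit_df = pd.DataFrame(fit_rows)
        fit_df.to_csv(full / "fit.tsv", sep="\t", index=False)
        _fmt(fit_df, {"tau": 4, "theta0": 4, "theta1": 4, "SSD": 5,
                      "raggedness": 5, "p_SSD": 4, "p_raggedness": 4}).to_csv(
            outdir / "fit.tsv", sep="\t", index=False
        )
        result.files["mismatch"] = outdir / "fit.tsv"

    def stage_network() -> None:
        net = network.build_mjn(table)
        network.export_network(net, outdir / "network.graphml", fmt="graphml")
        network.export_network(net, outdir / "network.tsv", fmt="tsv")
        result.files["network"] = outdir / "network.graphml"

    stages: dict[str, Callable[[], None]] = {
        "diversity": stage_diversity,
        "neutrality": stage_neutrality,
        "amova": stage_amova,
        "fst": stage_fst,
        "mismatch": stage_mismatch,
        "network": stage_network,
    }

    def write_manifest() -> None:
        with open(outdir / "MANIFEST.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    for name in ALL_STAGES:
        if name in config.skip:
            manifest[name] = "skipped"
            continue
        t_stage = time.time()
        try:
            stages[name]()
        except Exception as exc:
            manifest[name] = f"failed: {exc}"
            write_manifest()
            raise StageError(name, exc) from exc
        manifest[name] = "complete"
        logger.info("stage %s: %.2f s", name, time.time() - t_stage)

    write_manifest()
    with open(outdir / "run_log.txt", "w") as fh:
        import mitopop

        fh.write(f"mitopop {mitopop.__version__}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"permutations: {config.permutations}\n")
        fh.write(f"neutrality_reps: {config.neutrality_reps}\n")
        fh.write(f"bootstrap_reps: {config.bootstrap_reps}\n")
        fh.write(f"units: {config.units}\n")
        fh.write(f"skip: {config.skip}\n")
        fh.write(f"elapsed_s: {time.time() - t0:.2f}\n")
    return result
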