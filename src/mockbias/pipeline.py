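"""End-to-end pipeline: estimate -> partition -> trajectories -> trait models -> RMSE.

Given a classified count table, sample metadata, the mock design and the
trait table, the pipeline

1. bootstrap-estimates the centered bias of every (stage, protocol,
   primer) group, pooling replicate runs, and of every per-run subgroup;
2. partitions each protocol's total bias into extraction, PCR and
   sequencing components (pooled over runs) and computes cumulative
   abundance trajectories;
3. fits trait models per protocol for the total bias and each partitioned
   component, stacking the per-run, per-primer estimates as observations,
   with bootstrap coefficient intervals;
4. reports raw and bias-corrected RMSE per group.

All bootstrap seeds are derived deterministically from the single
configured seed, so a rerun with the same configuration writes
byte-identical result files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bias import BiasEstimate, bootstrap_bias, observed_expected_pairs, select_samples
from .composition import rmse
from .io import FLOAT_FORMAT, read_count_table, read_design, read_meta, read_traits
from .partition import COMPONENTS, PartitionedBias, partition_bias, trajectory
from .traits import bootstrap_trait_cis, build_design_matrix

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

RESPONSES = ("total",) + COMPONENTS


class PipelineError(ValueError):
    """Raised when the configuration or input data cannot support a run."""


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    counts: Path
    meta: Path
    design: Path
    traits: Path
    out_dir: Path
    n_boot: int = 1000
    seed: int = 0
    zero_policy: str = "exclude"
    pseudocount: float = 0.5
    rmse_mode: str = "pooled"
    trait_encoding: str = "full_dummy"

    def validate(self) -> None:
        for name in ("counts", "meta", "design", "traits"):
            path = Path(getattr(self, name))
            if not path.is_file():
                raise PipelineError(f"{name} file does not exist: {path}")
        if self.n_boot < 1:
            raise PipelineError("n_boot must be >= 1")
        if self.zero_policy not in ("exclude", "pseudocount"):
            raise PipelineError(f"unknown zero_policy {self.zero_policy!r}")
        if self.pseudocount <= 0:
            raise PipelineError("pseudocount must be positive")
        if self.rmse_mode not in ("pooled", "per_sample"):
            raise PipelineError(f"unknown rmse_mode {self.rmse_mode!r}")
        if self.trait_encoding not in ("full_dummy", "reference"):
            raise PipelineError(f"unknown trait_encoding {self.trait_encoding!r}")


def _group_seed(base_seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence((base_seed, index))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write TSV/JSON results.

    Returns a bundle with the in-memory estimates, partitions, trait-model
    fits, the RMSE table and the output paths.
    """
    config.validate()
    counts = read_count_table(config.counts)
    meta = read_meta(config.meta)
    design = read_design(config.design)
    traits = read_traits(config.traits)

    stages_present = set(meta["stage"])
    missing_stages = {"insect", "dna", "pcr"} - stages_present
    if missing_stages:
        raise PipelineError(
            f"required stage groups absent from metadata: {sorted(missing_stages)}"
        )
    protocols = sorted(
        set(meta.loc[meta["stage"] == "insect", "extraction"]) - {"none"}
    )
    if not protocols:
        raise PipelineError("no extraction protocol found among insect-stage samples")
    primers = sorted(set(meta["primer"]))
    runs = sorted(set(meta["run"]))

    policy = dict(zero_policy=config.zero_policy, pseudocount=config.pseudocount)
    seed_counter = iter(range(10_000))

    def boot(group):
        samples = select_samples(meta, group)
        if not samples:
            raise PipelineError(f"no samples for required group {group!r}")
        return bootstrap_bias(
            counts,
            meta,
            design,
            group,
            n_boot=config.n_boot,
            seed=_group_seed(config.seed, next(seed_counter)),
            **policy,
        )

    # -- pooled-run estimates (one per stage x protocol x primer) ----------
    totals: dict[tuple[str, str], BiasEstimate] = {}
    dna_stage: dict[str, BiasEstimate] = {}
    pcr_stage: dict[str, BiasEstimate] = {}
    for prot in protocols:
        for pr in primers:
            totals[(prot, pr)] = boot(
                {"stage": "insect", "extraction": prot, "primer": pr}
            )
    for pr in primers:
        dna_stage[pr] = boot({"stage": "dna", "primer": pr})
        pcr_stage[pr] = boot({"stage": "pcr", "primer": pr})

    # -- per-run estimates (observations for the trait models) ------------
    totals_run: dict[tuple, BiasEstimate] = {}
    dna_run: dict[tuple, BiasEstimate] = {}
    pcr_run: dict[tuple, BiasEstimate] = {}
    for prot in protocols:
        for pr in primers:
            for run in runs:
                totals_run[(prot, pr, run)] = boot(
                    {"stage": "insect", "extraction": prot, "primer": pr, "run": run}
                )
    for pr in primers:
        for run in runs:
            dna_run[(pr, run)] = boot({"stage": "dna", "primer": pr, "run": run})
            pcr_run[(pr, run)] = boot({"stage": "pcr", "primer": pr, "run": run})

    # -- partitioning ------------------------------------------------------
    partitions: dict[tuple[str, str], PartitionedBias] = {}
    trajectories: dict[tuple[str, str], pd.DataFrame] = {}
    for prot in protocols:
        for pr in primers:
            part = partition_bias(
                totals[(prot, pr)], dna_stage[pr], pcr_stage[pr], protocol=prot, primer=pr
            )
            partitions[(prot, pr)] = part
            trajectories[(prot, pr)] = trajectory(part)
    partitions_run: dict[tuple, PartitionedBias] = {}
    for prot in protocols:
        for pr in primers:
            for run in runs:
                partitions_run[(prot, pr, run)] = partition_bias(
                    totals_run[(prot, pr, run)],
                    dna_run[(pr, run)],
                    pcr_run[(pr, run)],
                    protocol=prot,
                    primer=pr,
                )

    # -- trait models ------------------------------------------------------
    trait_fits = []
    for prot in protocols:
        for response in RESPONSES:
            ys, Xs, reps = [], [], []
            for pr in primers:
                for run in runs:
                    if response == "total":
                        est = totals_run[(prot, pr, run)]
                        eff, rep = est.efficiency, est.log_replicates
                    else:
                        part = partitions_run[(prot, pr, run)]
                        eff = part.components[response]
                        rep = (
                            part.log_replicates[response]
                            if part.log_replicates is not None
                            else None
                        )
                    taxa = list(eff.index)
                    X = build_design_matrix(
                        traits, taxa, pr, encoding=config.trait_encoding
                    )
                    idx = pd.MultiIndex.from_tuples(
                        [(t, pr, run) for t in taxa], names=["taxon", "primer", "run"]
                    )
                    X.index = idx
                    ys.append(pd.Series(np.log(eff.to_numpy()), index=idx))
                    Xs.append(X)
                    reps.append(rep)
            y = pd.concat(ys)
            X = pd.concat(Xs)
            R = np.hstack(reps)
            fit = bootstrap_trait_cis(y, X, R, response_label=response)
            frame = fit.to_frame().reset_index()
            frame.insert(0, "protocol", prot)
            frame["r2_adj"] = fit.r2_adj
            frame["f_stat"] = fit.f_stat
            frame["df_num"] = fit.df_num
            frame["df_den"] = fit.df_den
            frame["n_obs"] = fit.n_obs
            trait_fits.append((prot, response, fit, frame))

    # -- RMSE report -------------------------------------------------------
    rmse_rows = []
    group_specs = []
    for prot in protocols:
        for pr in primers:
            group_specs.append(
                ("insect", prot, pr, {"stage": "insect", "extraction": prot, "primer": pr},
                 totals[(prot, pr)])
            )
    for pr in primers:
        group_specs.append(("dna", "none", pr, {"stage": "dna", "primer": pr}, dna_stage[pr]))
        group_specs.append(("pcr", "none", pr, {"stage": "pcr", "primer": pr}, pcr_stage[pr]))
    for stage, prot, pr, group, est in group_specs:
        obs, exp = observed_expected_pairs(counts, meta, design, group)
        raw = rmse(obs, exp, mode=config.rmse_mode)
        obs_c, pred = observed_expected_pairs(
            counts, meta, design, group, bias=est.efficiency
        )
        corrected = rmse(obs_c, pred, mode=config.rmse_mode)
        rmse_rows.append(
            {
                "stage": stage,
                "protocol": prot,
                "primer": pr,
                "rmse_raw_pct": raw,
                "rmse_corrected_pct": corrected,
                "n_samples": est.n_samples,
            }
        )
    rmse_table = pd.DataFrame(rmse_rows)

    # -- outputs -----------------------------------------------------------
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    est_rows = []
    for stage, prot, pr, _, est in group_specs:
        frame = est.to_frame().reset_index()
        frame.insert(0, "primer", pr)
        frame.insert(0, "protocol", prot)
        frame.insert(0, "stage", stage)
        frame["n_samples"] = est.n_samples
        est_rows.append(frame)
    estimates_table = pd.concat(est_rows, ignore_index=True)
    estimates_table.to_csv(
        out_dir / "bias_estimates.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )

    partition_table = pd.concat(
        [partitions[key].to_frame() for key in sorted(partitions)], ignore_index=True
    )
    partition_table.to_csv(
        out_dir / "partition.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )

    traj_rows = []
    for (prot, pr), traj in sorted(trajectories.items()):
        frame = traj.reset_index()
        frame.insert(0, "primer", pr)
        frame.insert(0, "protocol", prot)
        traj_rows.append(frame)
    pd.concat(traj_rows, ignore_index=True).to_csv(
        out_dir / "trajectories.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )

    trait_table = pd.concat([f for *_, f in trait_fits], ignore_index=True)
    trait_table.to_csv(
        out_dir / "trait_models.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )

    rmse_table.to_csv(
        out_dir / "rmse.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )

    summary = {
        "seed": config.seed,
        "n_boot": config.n_boot,
        "protocols": protocols,
        "primers": primers,
        "runs": [int(r) for r in runs],
        "rmse": rmse_rows,
        "trait_models": [
            {
                "protocol": prot,
                "response": response,
                "r2_adj": fit.r2_adj,
                "f_stat": fit.f_stat,
                "df": [fit.df_num, fit.df_den],
                "n_obs": fit.n_obs,
            }
            for prot, response, fit, _ in trait_fits
        ],
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    log_lines = [
        f"mockbias {__version__}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
        "config: " + json.dumps({k: str(v) for k, v in asdict(config).items()}, sort_keys=True),
    ]
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")

    return {
        "totals": totals,
        "dna_stage": dna_stage,
        "pcr_stage": pcr_stage,
        "totals_run": totals_run,
        "partitions": partitions,
        "partitions_run": partitions_run,
        "trajectories": trajectories,
        "trait_fits": {(p, r): f for p, r, f, _ in trait_fits},
        "rmse": rmse_table,
        "out_dir": out_dir,
    }
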