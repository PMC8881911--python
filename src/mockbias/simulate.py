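"""Synthetic three-stage mock-community experiments with known truth.

The generator emulates the full factorial structure of the calibration
experiment: eight mock pools of counted insects, sequenced at three entry
points of the workflow (whole-insect pools, DNA pools, PCR pools), with
two non-destructive extraction protocols (each applied to four insect
pools), two degenerate COI primer sets, and replicate sequencing runs.

Ground-truth step biases are trait-driven: the log bias of each workflow
step is a linear combination of the packaged trait covariates plus
taxon-level lognormal noise, geometrically centered.  A sample entering
the workflow at stage *k* accumulates the biases of stages >= *k* only;
its read counts are a multinomial (optionally Dirichlet-multinomial
overdispersed) draw at a normally distributed depth, with optional
per-cell taxon dropout.  Every quantity is a pure function of the
parameter object, including its seed.

Default coefficient values encode the qualitative structure seen in real
insect mock communities: soft-bodied taxa extract more efficiently than
hard-bodied ones under non-destructive lysis, body volume helps at the
extraction step, and primer-template mismatch suppresses — while amplicon
GC content raises — amplification efficiency at the PCR step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import MockDesign, center, close
from .traits import MORPHOLOGY_COLUMNS, TraitTable, build_design_matrix

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "SimulatedExperiment",
    "simulate_bias_vectors",
    "simulate_counts",
    "simulate_experiment",
    "write_fixture",
]

STAGE_ORDER = ("insect", "dna", "pcr")


def _default_design() -> MockDesign:
    from .datasets import load_mock_design

    return load_mock_design()


def _default_traits() -> TraitTable:
    from .datasets import load_trait_table

    return load_trait_table()


def _default_extraction_coefs() -> dict[str, dict[str, float]]:
    return {
        "quickextract": {"soft": 1.2, "intermediate": 0.7, "hard": -0.6, "log_volume": 0.3},
        "dneasy": {"soft": 1.0, "intermediate": 0.8, "hard": -0.4, "log_volume": 0.35},
    }


def _default_pcr_coefs() -> dict[str, dict[str, float]]:
    return {
        "fwhF2-fwhR2n": {"log_volume": -0.15, "mismatch": -3.0, "gc": 3.0},
        "fwhF2-HexCOIR4": {"log_volume": -0.15, "mismatch": -3.2, "gc": 3.0},
    }


def _default_sequencing_coefs() -> dict[str, dict[str, float]]:
    return {
        "fwhF2-fwhR2n": {"mismatch": -0.5, "gc": 0.8},
        "fwhF2-HexCOIR4": {"mismatch": -0.5, "gc": 0.6},
    }


def _default_protocol_pools() -> dict[str, tuple]:
    return {"quickextract": (1, 2, 3, 4), "dneasy": (5, 6, 7, 8)}


@dataclass
class SimulationParams:
    """Complete description of one simulated experiment.

    Attributes
    ----------
    design, traits
        Mock-community design and trait tables (packaged tables by
        default).
    extraction_coefs
        Per-protocol log-scale coefficients over the morphological design
        columns (hardness indicators, log volume); extraction acts before
        amplification so it is primer-independent.
    pcr_coefs, sequencing_coefs
        Per-primer log-scale coefficients over the full trait design
        columns.
    protocol_pools
        Which insect pools each extraction protocol was applied to.
    step_noise_sd
        SD of the lognormal taxon-level noise added to each step's log
        bias (dimensionless, default 0.2).
    depth_mean, depth_sd
        Normal distribution of per-sample read depth; defaults mirror a
        MiSeq run delivering ~272,600 (+/- 3,762) reads per sample.
    overdispersion
        Dirichlet-multinomial precision (larger = closer to multinomial);
        ``None`` disables overdispersion.
    dropout_prob
        Probability that any taxon-sample cell is zeroed after the count
        draw, mimicking stochastic taxon dropout.
    runs_per_pool
        Replicate sequencing runs per pool (default 2).
    seed
        Master seed; the whole experiment is a pure function of it.
    """

    design: MockDesign = field(default_factory=_default_design)
    traits: TraitTable = field(default_factory=_default_traits)
    extraction_coefs: dict = field(default_factory=_default_extraction_coefs)
    pcr_coefs: dict = field(default_factory=_default_pcr_coefs)
    sequencing_coefs: dict = field(default_factory=_default_sequencing_coefs)
    protocol_pools: dict = field(default_factory=_default_protocol_pools)
    step_noise_sd: float = 0.2
    depth_mean: float = 272_600.0
    depth_sd: float = 3_762.0
    overdispersion: float | None = None
    dropout_prob: float = 0.0
    runs_per_pool: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.depth_sd < 0 or self.step_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.runs_per_pool < 1:
            raise ValueError("runs_per_pool must be >= 1")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive when set")
        all_pools = set(self.design.pools)
        for protocol, pools in self.protocol_pools.items():
            unknown = set(pools) - all_pools
            if unknown:
                raise ValueError(f"protocol {protocol!r}: unknown pools {sorted(unknown)}")

    @property
    def protocols(self) -> list[str]:
        return sorted(self.protocol_pools)

    @property
    def primers(self) -> list[str]:
        return sorted(self.pcr_coefs)


@dataclass
class GroundTruth:
    """Known centered step biases and per-sample true compositions."""

    extraction: dict[str, pd.Series]
    pcr: dict[str, pd.Series]
    sequencing: dict[str, pd.Series]
    sample_compositions: dict[str, pd.Series] = field(default_factory=dict)

    def component(self, name: str, protocol: str, primer: str) -> pd.Series:
        if name == "extraction":
            return self.extraction[protocol]
        if name == "pcr":
            return self.pcr[primer]
        if name == "sequencing":
            return self.sequencing[primer]
        raise KeyError(f"unknown component {name!r}")

    def total_bias(self, protocol: str, primer: str) -> pd.Series:
        """Centered product of the three step biases."""
        return center(self.extraction[protocol] * self.pcr[primer] * self.sequencing[primer])

    def to_dict(self) -> dict:
        return {
            "extraction": {k: v.to_dict() for k, v in self.extraction.items()},
            "pcr": {k: v.to_dict() for k, v in self.pcr.items()},
            "sequencing": {k: v.to_dict() for k, v in self.sequencing.items()},
            "sample_compositions": {
                k: v.to_dict() for k, v in self.sample_compositions.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            extraction={k: pd.Series(v) for k, v in d["extraction"].items()},
            pcr={k: pd.Series(v) for k, v in d["pcr"].items()},
            sequencing={k: pd.Series(v) for k, v in d["sequencing"].items()},
            sample_compositions={
                k: pd.Series(v) for k, v in d.get("sample_compositions", {}).items()
            },
        )


def _step_bias(X: pd.DataFrame, coefs: dict, noise_sd: float, rng) -> pd.Series:
    log_bias = np.zeros(X.shape[0])
    for col, beta in coefs.items():
        if col not in X.columns:
            raise KeyError(f"coefficient refers to unknown design column {col!r}")
        log_bias = log_bias + beta * X[col].to_numpy(dtype=float)
    log_bias = log_bias + rng.normal(0.0, noise_sd, size=X.shape[0])
    return center(pd.Series(np.exp(log_bias), index=X.index))


def simulate_bias_vectors(params: SimulationParams, rng=None) -> GroundTruth:
    """Draw the ground-truth centered bias vectors for every step.

    Stream order (fixed, documented): extraction biases for protocols in
    sorted order, then PCR biases for primers in sorted order, then
    sequencing biases for primers in sorted order.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((params.seed, 0)))
    taxa = list(params.design.taxa)
    X_by_primer = {
        p: build_design_matrix(params.traits, taxa, p) for p in params.primers
    }
    # morphology is primer-independent; use the first primer's matrix
    X_morph = X_by_primer[params.primers[0]][list(MORPHOLOGY_COLUMNS)]
    extraction = {
        prot: _step_bias(X_morph, params.extraction_coefs[prot], params.step_noise_sd, rng)
        for prot in params.protocols
    }
    pcr = {
        p: _step_bias(X_by_primer[p], params.pcr_coefs[p], params.step_noise_sd, rng)
        for p in params.primers
    }
    sequencing = {
        p: _step_bias(X_by_primer[p], params.sequencing_coefs[p], params.step_noise_sd, rng)
        for p in params.primers
    }
    return GroundTruth(extraction=extraction, pcr=pcr, sequencing=sequencing)


def _protocol_for_pool(params: SimulationParams, pool) -> str | None:
    for protocol, pools in params.protocol_pools.items():
        if pool in pools:
            return protocol
    return None


def _cumulative_bias(truth: GroundTruth, stage: str, protocol: str | None, primer: str) -> pd.Series:
    if stage == "insect":
        return center(truth.extraction[protocol] * truth.pcr[primer] * truth.sequencing[primer])
    if stage == "dna":
        return center(truth.pcr[primer] * truth.sequencing[primer])
    if stage == "pcr":
        return truth.sequencing[primer]
    raise KeyError(f"unknown stage {stage!r}")


def _sample_rng(params: SimulationParams, stage: str, pool_idx: int, primer_idx: int, run: int):
    # independent stream per sample, so that toggling a stage's coefficients
    # cannot perturb the draws of samples that never traverse that stage
    return np.random.default_rng(
        np.random.SeedSequence(
            (params.seed, 1, STAGE_ORDER.index(stage), pool_idx, primer_idx, run)
        )
    )


def simulate_counts(
    design: MockDesign,
    truth: GroundTruth,
    params: SimulationParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw read counts and metadata for every sample of the experiment.

    Samples are generated in a fixed order — stage (insect, dna, pcr),
    pool, primer (sorted), run — each with true proportions
    ``close(expected x cumulative bias through that stage)`` and counts
    drawn multinomially at a normal depth.  Each sample consumes its own
    seed stream derived from the master seed.  True per-sample
    compositions are recorded into ``truth.sample_compositions``.
    """
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    taxa = design.taxa
    for stage in STAGE_ORDER:
        for pool_idx, pool in enumerate(design.pools):
            protocol = _protocol_for_pool(params, pool)
            if stage == "insect" and protocol is None:
                continue  # pool not assigned to any extraction protocol
            extraction = protocol if stage == "insect" else "none"
            for primer_idx, primer in enumerate(params.primers):
                bias = _cumulative_bias(truth, stage, protocol, primer)
                expected = design.expected_composition(pool)
                props = close(expected * bias.reindex(expected.index))
                for run in range(1, params.runs_per_pool + 1):
                    rng = _sample_rng(params, stage, pool_idx, primer_idx, run)
                    sid = f"{stage}.{extraction}.{primer}.pool{pool}.run{run}"
                    depth = max(1, int(round(rng.normal(params.depth_mean, params.depth_sd))))
                    p = props.to_numpy()
                    if params.overdispersion is not None:
                        p = rng.dirichlet(p * params.overdispersion)
                    draw = rng.multinomial(depth, p)
                    if params.dropout_prob > 0:
                        draw = np.where(rng.random(draw.size) < params.dropout_prob, 0, draw)
                    col = pd.Series(0, index=taxa, dtype=np.int64)
                    col[props.index] = draw
                    columns[sid] = col.to_numpy()
                    meta_rows.append(
                        {
                            "sample": sid,
                            "pool": pool,
                            "stage": stage,
                            "extraction": extraction,
                            "primer": primer,
                            "run": run,
                        }
                    )
                    truth.sample_compositions[sid] = props
    counts = pd.DataFrame(columns, index=taxa)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return counts, meta


@dataclass
class SimulatedExperiment:
    """Bundle of one simulated experiment: counts, metadata, truth."""

    counts: pd.DataFrame
    meta: pd.DataFrame
    truth: GroundTruth
    params: SimulationParams


def simulate_experiment(params: SimulationParams) -> SimulatedExperiment:
    """Run the full generator from a single master seed."""
    truth = simulate_bias_vectors(params)
    counts, meta = simulate_counts(params.design, truth, params)
    return SimulatedExperiment(counts=counts, meta=meta, truth=truth, params=params)


def write_fixture(path, params: SimulationParams | None = None) -> dict[str, Path]:
    """Write a complete seeded experiment to ``path``.

    Produces ``design.tsv``, ``traits.tsv``, ``counts.tsv``, ``meta.tsv``
    and ``truth.json`` in the directory, and returns the file paths.
    """
    from .io import write_count_table, write_design, write_meta, write_traits

    params = params if params is not None else SimulationParams()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    exp = simulate_experiment(params)
    files = {
        "design": path / "design.tsv",
        "traits": path / "traits.tsv",
        "counts": path / "counts.tsv",
        "meta": path / "meta.tsv",
        "truth": path / "truth.json",
    }
    write_design(params.design, files["design"])
    write_traits(params.traits, files["traits"])
    write_count_table(exp.counts, files["counts"])
    write_meta(exp.meta, files["meta"])
    files["truth"].write_text(json.dumps(exp.truth.to_dict(), indent=1, sort_keys=True))
    return files
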