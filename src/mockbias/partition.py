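"""Multiplicative partitioning of total protocol bias into workflow steps.

Mock communities entering the workflow at successive stages isolate the
bias each stage contributes.  Whole-insect pools traverse DNA extraction,
PCR and sequencing/bioinformatics, so their bias is the product of all
three step biases; DNA pools (pooled genomic DNA) skip extraction; PCR
pools (pooled amplicons) skip extraction and PCR.  Dividing the stage
estimates therefore telescopes into per-step components:

* extraction = center(total / dna_stage)
* pcr        = center(dna_stage / pcr_stage)
* sequencing = pcr_stage (already centered)

and the re-centered product of the three reconstructs the centered total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bias import BiasEstimate, expanded_tail
from .composition import center

__all__ = ["PartitionedBias", "partition_bias", "trajectory"]

COMPONENTS = ("extraction", "pcr", "sequencing")


@dataclass
class PartitionedBias:
    """Per-step centered efficiency components for one (protocol, primer).

    ``components`` maps each of ``extraction``, ``pcr`` and ``sequencing``
    to its centered efficiency vector; ``se_log``, ``ci_lower`` and
    ``ci_upper`` carry bootstrap uncertainty propagated from the stage
    estimates, and ``total`` is the centered whole-protocol bias over the
    common taxon set.
    """

    protocol: str
    primer: str
    components: dict[str, pd.Series]
    total: pd.Series
    se_log: dict[str, pd.Series] | None = None
    ci_lower: dict[str, pd.Series] | None = None
    ci_upper: dict[str, pd.Series] | None = None
    n_boot: int = 0
    log_replicates: dict[str, np.ndarray] | None = field(default=None, repr=False)

    @property
    def taxa(self) -> pd.Index:
        return self.total.index

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per taxon x component."""
        rows = []
        for comp in COMPONENTS:
            eff = self.components[comp]
            frame = pd.DataFrame(
                {
                    "protocol": self.protocol,
                    "primer": self.primer,
                    "component": comp,
                    "taxon": eff.index,
                    "efficiency": eff.to_numpy(),
                }
            )
            frame["se_log"] = (
                self.se_log[comp].to_numpy() if self.se_log is not None else np.nan
            )
            frame["ci_lo"] = (
                self.ci_lower[comp].to_numpy() if self.ci_lower is not None else np.nan
            )
            frame["ci_hi"] = (
                self.ci_upper[comp].to_numpy() if self.ci_upper is not None else np.nan
            )
            rows.append(frame)
        return pd.concat(rows, ignore_index=True)


def _restrict(est: BiasEstimate, taxa: pd.Index) -> tuple[pd.Series, np.ndarray | None]:
    """Recenter an estimate over a taxon subset, subsetting replicates too."""
    eff = center(est.efficiency.reindex(taxa))
    reps = None
    if est.log_replicates is not None:
        cols = est.efficiency.index.get_indexer(taxa)
        reps = est.log_replicates[:, cols]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            reps = reps - np.nanmean(reps, axis=1, keepdims=True)
    return eff, reps


def partition_bias(
    total: BiasEstimate,
    dna_stage: BiasEstimate,
    pcr_stage: BiasEstimate,
    protocol: str = "",
    primer: str = "",
) -> PartitionedBias:
    """Split total protocol bias into extraction, PCR and sequencing parts.

    Parameters
    ----------
    total
        Bias estimated from whole-insect pools (one extraction protocol,
        one primer set).
    dna_stage
        Bias estimated from the DNA pools (same primer set).
    pcr_stage
        Bias estimated from the PCR pools (same primer set).

    Notes
    -----
    Taxa missing from any stage estimate are excluded from every component
    with a warning, and each stage vector is re-centered over the common
    taxon set first so that all components remain relative to the same
    "average" taxon.

    Standard errors are propagated on the log scale.  When all three
    estimates carry the same number of bootstrap replicates the components
    are recomputed per replicate pair (the stages come from independent
    sample groups, so pairing arbitrary replicate indices is valid) and
    percentile intervals are taken; otherwise log-variances are added and
    normal-theory intervals are reported.
    """
    common = total.taxa.intersection(dna_stage.taxa).intersection(pcr_stage.taxa)
    dropped = set(total.taxa) | set(dna_stage.taxa) | set(pcr_stage.taxa)
    dropped -= set(common)
    if dropped:
        warnings.warn(
            f"taxa missing from at least one stage, excluded from partition: "
            f"{sorted(dropped)}",
            stacklevel=2,
        )
    if len(common) == 0:
        raise ValueError("partition_bias: no taxa common to all three stages")

    tot, tot_r = _restrict(total, common)
    dna, dna_r = _restrict(dna_stage, common)
    pcr, pcr_r = _restrict(pcr_stage, common)

    components = {
        "extraction": center(tot / dna),
        "pcr": center(dna / pcr),
        "sequencing": pcr,
    }

    se_log = ci_lower = ci_upper = reps_out = None
    n_boot = 0
    paired = (
        tot_r is not None
        and dna_r is not None
        and pcr_r is not None
        and tot_r.shape[0] == dna_r.shape[0] == pcr_r.shape[0]
    )
    if paired:
        n_boot = tot_r.shape[0]
        comp_reps = {
            "extraction": tot_r - dna_r,
            "pcr": dna_r - pcr_r,
            "sequencing": pcr_r,
        }
        # expanded-percentile tail per component, using the smaller of the
        # contributing groups' sample counts (conservative)
        comp_n = {
            "extraction": min(total.n_samples, dna_stage.n_samples),
            "pcr": min(dna_stage.n_samples, pcr_stage.n_samples),
            "sequencing": pcr_stage.n_samples,
        }
        se_log, ci_lower, ci_upper, reps_out = {}, {}, {}, {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for comp, R in comp_reps.items():
                R = R - np.nanmean(R, axis=1, keepdims=True)
                reps_out[comp] = R
                se_log[comp] = pd.Series(np.nanstd(R, axis=0, ddof=1), index=common)
                tail = expanded_tail(comp_n[comp], 0.025)
                q = np.nanquantile(R, [tail, 1 - tail], axis=0)
                ci_lower[comp] = pd.Series(np.exp(q[0]), index=common)
                ci_upper[comp] = pd.Series(np.exp(q[1]), index=common)
    elif all(e.se_log is not None for e in (total, dna_stage, pcr_stage)):
        se_t = total.se_log.reindex(common)
        se_d = dna_stage.se_log.reindex(common)
        se_p = pcr_stage.se_log.reindex(common)
        se_log = {
            "extraction": np.sqrt(se_t**2 + se_d**2),
            "pcr": np.sqrt(se_d**2 + se_p**2),
            "sequencing": se_p,
        }
        ci_lower, ci_upper = {}, {}
        for comp in COMPONENTS:
            log_eff = np.log(components[comp])
            ci_lower[comp] = np.exp(log_eff - 1.96 * se_log[comp])
            ci_upper[comp] = np.exp(log_eff + 1.96 * se_log[comp])

    return PartitionedBias(
        protocol=protocol,
        primer=primer,
        components=components,
        total=center(tot),
        se_log=se_log,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        n_boot=n_boot,
        log_replicates=reps_out,
    )


def trajectory(p: PartitionedBias) -> pd.DataFrame:
    """Cumulative relative abundance of each taxon through the workflow.

    Starting from one, each taxon's abundance is multiplied by the
    partitioned bias of each successive step and re-centered to the
    geometric-mean taxon.  Columns: ``start``, ``extraction``, ``pcr``,
    ``sequencing``; the final column equals the centered total bias.
    """
    taxa = p.taxa
    out = pd.DataFrame(index=taxa)
    out.index.name = "taxon"
    out["start"] = 1.0
    cumulative = pd.Series(1.0, index=taxa)
    for comp in COMPONENTS:
        cumulative = center(cumulative * p.components[comp])
        out[comp] = cumulative
    return out
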