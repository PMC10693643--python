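"""Synthetic pseudo-observed datasets and reference tables.

The real cohorts behind this analysis are access-restricted, so every
downstream stage is exercised on synthetic data with the same statistical
structure: two populations simulated under the clean-split model, reduced
to phased biallelic SNP VCFs, with genotype errors injected at the study's
rate.  A truth sidecar written beside every synthetic VCF records the
parameters and seeds needed to regenerate the dataset bit-for-bit.

Per-row randomness in reference tables derives from
``SeedSequence((master_seed, row_index))`` so chunked and monolithic
generation produce identical rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import __version__
from .demography import (
    PARAM_NAMES,
    ModelConstants,
    PriorSpec,
    SplitModelParams,
    sample_prior,
)
from .errors import ErrorConfig, apply_genotype_error
from .inference import ReferenceTable
from .formats import write_vcf
from .simulate import GenomeConfig, RecombinationMap, panel_to_genotypes, simulate_panel
from .sumstats import StatRegistry, compute_summary_vector, registry_names

logger = logging.getLogger(__name__)

#: desk-scale defaults: small enough to iterate on one workstation while
#: preserving the study's structure (two pops, variable map optional,
#: genotype error 0.001)
DESK_GENOME = GenomeConfig(sequence_length=10e6, samples_per_pop=20)


@dataclass(frozen=True)
class TruthRecord:
    """Everything needed to regenerate a synthetic dataset bit-for-bit."""

    params: dict
    sequence_length: float
    samples_per_pop: int
    mutation_rate: float
    recombination: dict  # {"uniform": rate} or {"map": {positions, cum_cm}}
    error_rate: float
    seed: int
    package_version: str = __version__

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(**doc)

    def split_params(self) -> SplitModelParams:
        return SplitModelParams(**self.params)

    def genome(self) -> GenomeConfig:
        if "uniform" in self.recombination:
            recomb = self.recombination["uniform"]
        else:
            m = self.recombination["map"]
            recomb = RecombinationMap(np.array(m["positions"]), np.array(m["cum_cm"]))
        return GenomeConfig(
            sequence_length=self.sequence_length,
            recombination=recomb,
            mutation_rate=self.mutation_rate,
            samples_per_pop=self.samples_per_pop,
        )


def _recomb_doc(genome: GenomeConfig) -> dict:
    if isinstance(genome.recombination, RecombinationMap):
        return {
            "map": {
                "positions": genome.recombination.positions.tolist(),
                "cum_cm": genome.recombination.cum_cm.tolist(),
            }
        }
    return {"uniform": float(genome.recombination)}


def _sample_names(genome: GenomeConfig) -> list[str]:
    n = genome.samples_per_pop
    return [f"CAB{i:03d}" for i in range(n)] + [f"MOZ{i:03d}" for i in range(n)]


def _subseeds(master_seed: int, row: int, n: int = 3) -> list[int]:
    state = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, int(row)]).generate_state(
        n, dtype=np.uint32
    )
    return [int(s % (2**31 - 1)) + 1 for s in state]


def prior_draws_for_rows(prior: PriorSpec, master_seed: int, rows) -> list[SplitModelParams]:
    """The parameter draw assigned to each reference-table row.

    Row ``i`` always receives the same draw for a given master seed, whatever
    chunking is used to generate the table.
    """
    return [sample_prior(prior, 1, _subseeds(master_seed, r)[0])[0] for r in rows]


def generate_pseudo_observed(
    truth: SplitModelParams,
    genome: GenomeConfig | None = None,
    error: ErrorConfig | None = None,
    seed: int = 1,
    out_vcf=None,
    constants: ModelConstants | None = None,
):
    """Simulate one dataset at known parameters: panel -> genotypes -> error.

    Returns ``(panel, genotypes, altered_mask, truth_record)``; writes a
    phased VCF (error-hit genotypes unphased) plus a ``.truth.json`` sidecar
    when ``out_vcf`` is given.
    """
    genome = genome or DESK_GENOME
    error = error or ErrorConfig()
    sim_seed, err_seed, _ = _subseeds(seed, 0)
    panel = simulate_panel(truth, constants, genome, seed=sim_seed)
    genotypes = panel_to_genotypes(panel)
    noisy, altered = apply_genotype_error(
        genotypes, ErrorConfig(error.error_rate, seed=err_seed), return_altered=True
    )
    record = TruthRecord(
        params={k: getattr(truth, k) for k in PARAM_NAMES},
        sequence_length=genome.sequence_length,
        samples_per_pop=genome.samples_per_pop,
        mutation_rate=genome.mutation_rate,
        recombination=_recomb_doc(genome),
        error_rate=error.error_rate,
        seed=int(seed),
    )
    if out_vcf is not None:
        # altered entries are emitted unphased with the perturbed dosage:
        # patch the haplotype pair so its sum equals the noisy genotype
        haps = panel.haplotypes.copy()
        ind, site = np.where(altered)
        haps[2 * ind, site] = (noisy[altered] > 1).astype(np.int8)
        haps[2 * ind + 1, site] = (noisy[altered] > 0).astype(np.int8)
        write_vcf(
            out_vcf,
            panel.positions,
            _sample_names(genome),
            haplotypes=haps,
            altered=altered,
            sequence_length=genome.sequence_length,
        )
        record.to_json(str(out_vcf) + ".truth.json")
    return panel, noisy, altered, record


def regenerate(record: TruthRecord, out_vcf=None):
    """Re-run :func:`generate_pseudo_observed` from a truth sidecar."""
    return generate_pseudo_observed(
        record.split_params(),
        record.genome(),
        ErrorConfig(record.error_rate),
        seed=record.seed,
        out_vcf=out_vcf,
    )


def generate_reference(
    prior: PriorSpec | None = None,
    n_sim: int = 1000,
    genome: GenomeConfig | None = None,
    error: ErrorConfig | None = None,
    seed: int = 1,
    constants: ModelConstants | None = None,
    registry: StatRegistry | None = None,
    start_row: int = 0,
    progress: bool = False,
) -> ReferenceTable:
    """Simulate ``n_sim`` rows of (parameters, 46 statistics).

    Rows ``start_row .. start_row + n_sim`` of the master-seeded stream are
    produced, so a run chunked as (0..k) + (k..n) concatenates to the
    monolithic run.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    prior = prior or PriorSpec()
    genome = genome or DESK_GENOME
    error = error or ErrorConfig()
    constants = constants or ModelConstants()
    prior.validate_against(constants)
    registry = registry or StatRegistry()

    param_rows = []
    stat_rows = []
    for row in range(start_row, start_row + n_sim):
        _, sim_seed, err_seed = _subseeds(seed, row)
        params = prior_draws_for_rows(prior, seed, [row])[0]
        panel = simulate_panel(params, constants, genome, seed=sim_seed)
        genotypes = panel_to_genotypes(panel)
        noisy = apply_genotype_error(genotypes, ErrorConfig(error.error_rate, seed=err_seed))
        sv = compute_summary_vector(
            noisy, panel.positions, panel.genetic_pos_cm, panel.individual_labels, registry
        )
        param_rows.append(params.as_array())
        stat_rows.append(sv.values)
        if progress and (row - start_row + 1) % 100 == 0:
            logger.info("reference: %d / %d rows", row - start_row + 1, n_sim)

    params_df = pd.DataFrame(np.vstack(param_rows), columns=list(PARAM_NAMES))
    stats_df = pd.DataFrame(np.vstack(stat_rows), columns=list(registry_names(registry)))
    provenance = {
        "master_seed": int(seed),
        "start_row": int(start_row),
        "n_sim": int(n_sim),
        "sequence_length": genome.sequence_length,
        "samples_per_pop": genome.samples_per_pop,
        "error_rate": error.error_rate,
        "registry": registry.version,
        "package_version": __version__,
    }
    return ReferenceTable(params_df, stats_df, provenance)


def concat_references(tables: list[ReferenceTable]) -> ReferenceTable:
    """Concatenate chunked reference tables (in row order)."""
    return ReferenceTable(
        pd.concat([t.params for t in tables], ignore_index=True),
        pd.concat([t.stats for t in tables], ignore_index=True),
        {"chunks": [t.provenance for t in tables]},
    )
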