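"""Genotype error injection.

Emulates the genotyping error typical of low/intermediate-coverage
sequencing: each non-missing diploid genotype is independently perturbed
with a fixed probability; a perturbed homozygote becomes a heterozygote and
a perturbed heterozygote becomes one of the two homozygotes with equal
probability.  Errors are applied at the genotype level after simulation and
before any summary statistic, and perturbed genotypes lose their phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MISSING = -1  # missing genotype sentinel used package-wide


class InvalidGenotypeError(ValueError):
    """Genotype matrix contains values outside {0, 1, 2, missing}."""


@dataclass(frozen=True)
class ErrorConfig:
    """Per-genotype error probability and RNG seed."""

    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError(f"error_rate must be in [0, 1], got {self.error_rate}")


def apply_genotype_error(
    genotypes: np.ndarray, cfg: ErrorConfig, return_altered: bool = False
):
    """Return a copy of ``genotypes`` with errors injected.

    0 -> 1 and 2 -> 1 (homozygote to heterozygote); 1 -> 0 or 2 each with
    probability 1/2.  Missing genotypes are untouched.  With
    ``return_altered=True`` also returns the boolean mask of perturbed
    entries (used to emit those genotypes unphased in VCF output).
    """
    g = np.asarray(genotypes)
    valid = np.isin(g, (0, 1, 2, MISSING))
    if not valid.all():
        bad = np.unique(g[~valid])
        raise InvalidGenotypeError(f"genotypes contain invalid values {bad.tolist()}")

    out = g.copy()
    rng = np.random.default_rng(cfg.seed)
    hit = (rng.random(g.shape) < cfg.error_rate) & (g != MISSING)
    hom_hit = hit & ((g == 0) | (g == 2))
    het_hit = hit & (g == 1)
    out[hom_hit] = 1
    # heterozygote -> random homozygote; draw for every entry to keep the
    # stream layout independent of which entries were hit
    coin = rng.random(g.shape) < 0.5
    out[het_hit] = np.where(coin[het_hit], 0, 2)

    if return_altered:
        return out, hit
    return out
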