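"""File formats and run configuration.

Coordinates are 0-based half-open internally and converted to 1-based at
the VCF boundary.  Only the subset of VCF 4.2 the pipeline emits is
supported on the way back in: biallelic SNP records with GT fields.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import MISSING

logger = logging.getLogger(__name__)


class VCFFormatError(ValueError):
    """Malformed VCF content."""


class ConfigFileError(ValueError):
    """Malformed run-configuration document."""


@dataclass
class VCFData:
    """Genotype matrix view of a VCF: individuals x sites, dosage coding."""

    genotypes: np.ndarray  # (n_individuals, n_sites), {0,1,2,MISSING}
    positions: np.ndarray  # 0-based bp
    samples: list[str]
    phased: np.ndarray  # bool, (n_individuals, n_sites)
    contig: str = "1"
    n_skipped: int = 0  # multiallelic / non-SNP records dropped on read


def read_vcf(path) -> VCFData:
    """Read biallelic SNP GT records from a VCF file.

    Multiallelic or non-SNP records are skipped (count logged and recorded).
    ``./.`` becomes the missing sentinel.  VCF 1-based positions become
    0-based.
    """
    from cyvcf2 import VCF

    try:
        reader = VCF(str(path), gts012=False)
    except Exception as exc:
        raise VCFFormatError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(reader.samples)
    genotypes: list[np.ndarray] = []
    phased_rows: list[np.ndarray] = []
    positions: list[int] = []
    contig = "1"
    skipped = 0
    for variant in reader:
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            skipped += 1
            continue
        contig = variant.CHROM
        row = np.empty(len(samples), dtype=np.int8)
        prow = np.zeros(len(samples), dtype=bool)
        for i, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            prow[i] = bool(gt[2])
            row[i] = MISSING if (a < 0 or b < 0) else a + b
        genotypes.append(row)
        phased_rows.append(prow)
        positions.append(variant.POS - 1)
    reader.close()
    if skipped:
        logger.info("read_vcf(%s): skipped %d multiallelic/non-SNP records", path, skipped)
    if genotypes:
        G = np.stack(genotypes, axis=1)
        P = np.stack(phased_rows, axis=1)
        pos = np.array(positions)
    else:
        G = np.zeros((len(samples), 0), dtype=np.int8)
        P = np.zeros((len(samples), 0), dtype=bool)
        pos = np.zeros(0, dtype=int)
    return VCFData(G, pos, samples, P, contig=contig, n_skipped=skipped)


_GT_UNPHASED = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    path,
    positions,
    samples,
    genotypes=None,
    haplotypes=None,
    altered=None,
    contig: str = "1",
    sequence_length: float | None = None,
) -> None:
    """Write a minimal VCF 4.2 with GT-only records.

    Either ``haplotypes`` (2n x S phased 0/1, written as ``a|b``) or
    ``genotypes`` (n x S dosage, written unphased) must be given.  With
    haplotypes, ``altered`` (n x S bool) marks genotypes whose phase was
    invalidated (e.g. by error injection): those are written as unphased
    dosage calls.  Positions are 0-based internally and 1-based on disk.
    """
    positions = np.asarray(positions)
    if positions.size and np.any(np.diff(positions) <= 0):
        raise VCFFormatError("positions must be strictly increasing")
    if (genotypes is None) == (haplotypes is None):
        raise VCFFormatError("provide exactly one of genotypes/haplotypes")
    if haplotypes is not None:
        haplotypes = np.asarray(haplotypes)
        if haplotypes.shape[0] != 2 * len(samples):
            raise VCFFormatError("haplotype rows must equal 2 x samples")
        n_sites = haplotypes.shape[1]
        dosage = haplotypes[0::2] + haplotypes[1::2]
    else:
        genotypes = np.asarray(genotypes)
        if genotypes.shape[0] != len(samples):
            raise VCFFormatError("genotype rows must equal number of samples")
        n_sites = genotypes.shape[1]
        dosage = genotypes
    if positions.shape != (n_sites,):
        raise VCFFormatError("positions length must equal site count")
    if altered is not None:
        altered = np.asarray(altered, dtype=bool)

    length = int(sequence_length) if sequence_length else (int(positions[-1]) + 1 if n_sites else 1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in range(n_sites):
            fields = [contig, str(int(positions[j]) + 1), ".", "A", "G", ".", "PASS", ".", "GT"]
            if haplotypes is not None:
                for i in range(len(samples)):
                    if altered is not None and altered[i, j]:
                        fields.append(_GT_UNPHASED[int(dosage[i, j])])
                    else:
                        fields.append(f"{haplotypes[2 * i, j]}|{haplotypes[2 * i + 1, j]}")
            else:
                for i in range(len(samples)):
                    fields.append(_GT_UNPHASED[int(dosage[i, j])])
            fh.write("\t".join(fields) + "\n")


def read_bed_mask(path) -> list[tuple[int, int]]:
    """Read excluded-region intervals from a BED file (0-based half-open)."""
    intervals: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith(("#", "track", "browser")):
                continue
            if len(parts) < 3:
                raise ConfigFileError(f"{path}:{lineno}: BED needs >= 3 columns")
            start, end = int(parts[1]), int(parts[2])
            if end < start:
                raise ConfigFileError(f"{path}:{lineno}: end < start")
            intervals.append((start, end))
    return sorted(intervals)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_ALLOWED_TOP_KEYS = {"priors", "constants", "genome", "error", "abc", "registry", "reference"}


@dataclass
class RunConfig:
    """One structured document holding every stage's settings.

    Sections are optional; missing sections fall back to package defaults.
    Unknown top-level keys are rejected so that typos fail loudly.
    """

    doc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.doc) - _ALLOWED_TOP_KEYS
        if unknown:
            raise ConfigFileError(f"unknown config sections: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigFileError(f"{path}: config root must be a mapping")
        return cls(doc)

    def section(self, name: str) -> dict:
        value = self.doc.get(name, {})
        if not isinstance(value, dict):
            raise ConfigFileError(f"config section {name!r} must be a mapping")
        return value

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.doc, sort_keys=True, separators=(",", ":")).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def priors(self):
        from .demography import PriorSpec

        sec = self.section("priors")
        return PriorSpec.from_dict(sec) if sec else PriorSpec()

    def constants(self):
        from .demography import ModelConstants

        return ModelConstants(**self.section("constants"))

    def genome(self):
        from .simulate import GenomeConfig, read_recombination_map

        sec = dict(self.section("genome"))
        if "map_file" in sec:
            sec["recombination"] = read_recombination_map(sec.pop("map_file"))
        return GenomeConfig(**sec)

    def error(self):
        from .errors import ErrorConfig

        return ErrorConfig(**self.section("error"))

    def abc(self):
        from .inference import ABCConfig

        return ABCConfig(**self.section("abc"))
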