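"""Shared containers and errors for the cushaw pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1  # dosage code for a missing diploid genotype


class CushawError(Exception):
    """Base class for package errors."""


class ValidationError(CushawError):
    """Invalid parameter or malformed input."""


class StructuralModelError(CushawError):
    """Demographic model whose demes can never share a common ancestor."""


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix (samples x biallelic sites).

    ``dosages`` holds derived/ALT allele counts in {0, 1, 2} with -1 for
    missing.  ``pops`` labels each sample with its population; ``status``
    maps a population to wild / domesticated / feral / outgroup.
    Positions are 1-based and strictly increasing within a chromosome.
    """

    dosages: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    samples: list
    pops: np.ndarray
    status: dict = field(default_factory=dict)
    site_ids: np.ndarray | None = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.pops = np.asarray(self.pops)
        if self.site_ids is None:
            self.site_ids = np.array(
                [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)])
        if self.dosages.shape != (len(self.samples), len(self.pos)):
            raise ValidationError("dosage matrix shape does not match "
                                  "samples x sites")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValidationError(
                    f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def sample_mask(self, pops=None, statuses=None) -> np.ndarray:
        keep = np.ones(self.n_samples, dtype=bool)
        if pops is not None:
            keep &= np.isin(self.pops, list(pops))
        if statuses is not None:
            st = np.array([self.status.get(p, "") for p in self.pops])
            keep &= np.isin(st, list(statuses))
        return keep

    def allele_freq(self, sample_mask=None) -> np.ndarray:
        """Derived-allele frequency per site over non-missing genotypes."""
        d = self.dosages if sample_mask is None else self.dosages[sample_mask]
        ok = d >= 0
        alleles = 2 * ok.sum(axis=0)
        derived = np.where(ok, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(alleles > 0, derived / np.maximum(alleles, 1),
                            np.nan)

    def missing_site_fraction(self) -> np.ndarray:
        return (self.dosages < 0).mean(axis=0)

    def missing_sample_fraction(self) -> np.ndarray:
        return (self.dosages < 0).mean(axis=1)

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.dosages[:, idx], self.chrom[idx],
                              self.pos[idx], list(self.samples),
                              self.pops.copy(), dict(self.status),
                              self.site_ids[idx])

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(self.dosages[idx], self.chrom.copy(),
                              self.pos.copy(),
                              [self.samples[i] for i in idx],
                              self.pops[idx], dict(self.status),
                              self.site_ids.copy())

    def pop_names(self) -> list:
        seen = {}
        for p in self.pops:
            seen.setdefault(p, None)
        return list(seen)
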