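"""SNP genotype container and post-variant-calling quality control.

The filters mirror routine GBS practice for biparental RIL panels: drop
loci with excess missing calls, excess heterozygosity (unexpected in
near-inbred lines, so usually a paralog/alignment artifact), or a rare
minor allele; then restrict to loci where the two parents carry distinct
homozygous alleles, since only those are informative about parental
origin downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "FilterReport", "filter_variants", "informative_loci"]

# genotype call codes in GenotypeMatrix.calls
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1


@dataclass
class GenotypeMatrix:
    """Biallelic SNP calls for a set of samples.

    Attributes
    ----------
    loci : DataFrame with columns ``chrom``, ``pos`` (1-based), ``ref``,
        ``alt``; positions strictly increasing within each chromosome.
    samples : ordered sample ids (conventionally the two parents first).
    calls : int8 array of shape (n_loci, n_samples) coded
        0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing.
    """

    loci: pd.DataFrame
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        if len(self.samples) != len(set(self.samples)):
            raise ValueError("duplicate sample ids")
        if self.calls.shape != (len(self.loci), len(self.samples)):
            raise ValueError("calls shape does not match loci x samples")
        for _, grp in self.loci.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("positions must be strictly increasing per chromosome")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample!r}") from None

    def calls_for(self, sample_ids: list[str]) -> np.ndarray:
        idx = [self.sample_index(s) for s in sample_ids]
        return self.calls[:, idx]

    def subset_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            loci=self.loci.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            calls=self.calls[mask],
        )

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.loci["chrom"]))


@dataclass
class FilterReport:
    """Attrition bookkeeping for :func:`filter_variants`.

    Each removal is attributed to the first rule the locus violated, in the
    fixed order missingness -> heterozygosity -> MAF.
    """

    n_input: int
    removed_missing: int
    removed_het: int
    removed_maf: int
    removed_noninformative: int = 0
    retained_per_chrom: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.n_input - (
            self.removed_missing
            + self.removed_het
            + self.removed_maf
            + self.removed_noninformative
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input", self.n_input),
            ("removed_missing", self.removed_missing),
            ("removed_het", self.removed_het),
            ("removed_maf", self.removed_maf),
            ("removed_noninformative", self.removed_noninformative),
            ("retained", self.n_retained),
        ]
        return pd.DataFrame(rows, columns=["rule", "count"])


def _ril_columns(G: GenotypeMatrix, parents: tuple[str, str] | None) -> np.ndarray:
    """Calls restricted to RIL samples (all samples minus the parents)."""
    if parents is None:
        return G.calls
    keep = [s for s in G.samples if s not in parents]
    return G.calls_for(keep)


def filter_variants(
    G: GenotypeMatrix,
    max_missing: float = 0.10,
    max_het: float = 0.10,
    min_maf: float = 0.05,
    parents: tuple[str, str] | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Retain loci with missing-call fraction <= ``max_missing``, het-call
    fraction <= ``max_het`` and minor allele frequency >= ``min_maf``.

    Fractions and allele frequencies are computed over the RIL samples only
    (parents, when given, are excluded); missing calls are dropped from the
    allele-frequency denominator.  Locus order is preserved.
    """
    for name, v in (("max_missing", max_missing), ("max_het", max_het), ("min_maf", min_maf)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if G.n_loci == 0:
        raise ValueError("empty genotype matrix")

    calls = _ril_columns(G, parents)
    n = calls.shape[1]
    miss_frac = (calls == MISSING).sum(axis=1) / n
    het_frac = (calls == HET).sum(axis=1) / n
    n_called = (calls != MISSING).sum(axis=1)
    alt_dose = np.where(calls == MISSING, 0, calls).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(n_called > 0, alt_dose / (2.0 * n_called), np.nan)
    maf = np.fmin(alt_freq, 1.0 - alt_freq)

    fail_miss = miss_frac > max_missing
    fail_het = ~fail_miss & (het_frac > max_het)
    fail_maf = ~fail_miss & ~fail_het & (np.isnan(maf) | (maf < min_maf))
    keep = ~(fail_miss | fail_het | fail_maf)

    retained = G.subset_loci(keep)
    report = FilterReport(
        n_input=G.n_loci,
        removed_missing=int(fail_miss.sum()),
        removed_het=int(fail_het.sum()),
        removed_maf=int(fail_maf.sum()),
        retained_per_chrom=retained.loci.groupby("chrom", sort=False).size().to_dict(),
    )
    if report.n_retained == 0:
        warnings.warn("all loci removed by filtering", stacklevel=2)
    return retained, report


def informative_loci(G: GenotypeMatrix, parent_a: str, parent_b: str) -> np.ndarray:
    """Boolean mask of loci where both parents are non-missing, homozygous,
    and carry different alleles — the loci whose bulk allele frequencies are
    interpretable as parental-origin fractions."""
    a = G.calls[:, G.sample_index(parent_a)]
    b = G.calls[:, G.sample_index(parent_b)]
    hom = np.isin(a, (HOM_REF, HOM_ALT)) & np.isin(b, (HOM_REF, HOM_ALT))
    return hom & (a != b)
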