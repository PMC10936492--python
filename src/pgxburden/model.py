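"""Core data model: variants, genotype matrices, annotation records and errors.

All genomic coordinates are 1-based inclusive (VCF convention). Genotype
calls are stored as allele indices (0 = reference, 1 = effect/alternate,
-1 = missing) in a samples x variants x 2 integer array, with a per-call
phase flag. Missing calls are never imputed; every consumer states its own
missing-data rule.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

MISSING = -1

_ALLELE_RE = re.compile(r"^[ACGT]+$")

PHENOTYPE_VOCABULARY = (
    "increased response",
    "decreased response",
    "increased toxicity",
    "decreased toxicity",
    "other",
)

FUNCTION_ROLES = ("target", "enzyme", "transporter")

VERDICT_VALUES = ("deleterious", "tolerated", "missing")

INHIBITOR_STRENGTHS = ("strong", "moderate", "weak")


class PgxError(Exception):
    """Base class for all package errors."""


class FormatError(PgxError):
    """Malformed external file (VCF/TSV) content."""


class SchemaError(PgxError):
    """A table is missing required columns."""


class ParameterError(PgxError, ValueError):
    """An argument is outside its documented domain."""


class UndefinedFrequencyError(PgxError):
    """Frequency requested where every call is missing."""


class PhaseError(PgxError):
    """Haplotype-level operation attempted on unphased calls."""


class MonomorphicError(PgxError):
    """LD undefined because a variant has zero variance."""


class InsufficientDataError(PgxError):
    """Too few complete observations for the statistic."""


class IndeterminateError(PgxError):
    """A consensus verdict cannot be formed (all tools missing)."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of one biallelic variant.

    ``ref``/``alt`` are uppercase nucleotide strings (indels allowed as
    multi-base strings); symbolic alleles (``<DEL>``, ``*``, breakends)
    are rejected.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ParameterError(f"position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not _ALLELE_RE.match(allele):
                raise ParameterError(
                    f"{name} allele {allele!r} is not an uppercase A/C/G/T string"
                )
        if self.ref == self.alt:
            raise ParameterError(f"ref and alt are identical ({self.ref})")

    @property
    def vid(self) -> str:
        """Canonical string id, ``chrom:pos:ref:alt``."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def from_vid(cls, vid: str, rsid: Optional[str] = None) -> "VariantKey":
        parts = vid.split(":")
        if len(parts) != 4:
            raise ParameterError(f"variant id {vid!r} is not chrom:pos:ref:alt")
        chrom, pos, ref, alt = parts
        return cls(chrom, int(pos), ref.upper(), alt.upper(), rsid=rsid)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.vid if self.rsid is None else f"{self.vid}({self.rsid})"


class GenotypeMatrix:
    """Diploid genotype calls for ordered samples x ordered variants.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    populations
        Population label per sample (same order as ``samples``).
    variants
        Ordered :class:`VariantKey` panel.
    alleles
        ``(n_samples, n_variants, 2)`` int8 array of allele indices,
        ``0`` reference, ``1`` alternate, ``-1`` missing.
    phased
        ``(n_samples, n_variants)`` boolean array; haplotype extraction is
        only permitted where this flag is set.
    """

    def __init__(
        self,
        samples: Sequence[str],
        populations: Sequence[str],
        variants: Sequence[VariantKey],
        alleles: np.ndarray,
        phased: np.ndarray,
    ) -> None:
        self.samples = list(samples)
        self.populations = list(populations)
        self.variants = list(variants)
        alleles = np.asarray(alleles, dtype=np.int8)
        phased = np.asarray(phased, dtype=bool)
        n, m = len(self.samples), len(self.variants)
        if len(self.populations) != n:
            raise ParameterError("one population label per sample is required")
        if alleles.shape != (n, m, 2):
            raise ParameterError(
                f"alleles shape {alleles.shape} != ({n}, {m}, 2)"
            )
        if phased.shape != (n, m):
            raise ParameterError(f"phased shape {phased.shape} != ({n}, {m})")
        bad = ~np.isin(alleles, (MISSING, 0, 1))
        if bad.any():
            raise ParameterError("allele indices must be in {-1, 0, 1}")
        half_missing = (alleles == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise ParameterError("half-missing diploid calls are not supported")
        self.alleles = alleles
        self.phased = phased
        self._index = {v.vid: j for j, v in enumerate(self.variants)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, v: VariantKey) -> int:
        try:
            return self._index[v.vid]
        except KeyError:
            raise ParameterError(f"variant {v.vid} not in matrix") from None

    def population_mask(self, population: Optional[str]) -> np.ndarray:
        """Boolean sample mask for one population (``None`` = all samples)."""
        if population is None:
            return np.ones(self.n_samples, dtype=bool)
        mask = np.array([p == population for p in self.populations])
        if not mask.any():
            raise ParameterError(f"unknown population {population!r}")
        return mask

    def dosage(self, j: int, allele_index: int = 1) -> np.ndarray:
        """Per-sample count of ``allele_index`` (float; NaN where missing)."""
        calls = self.alleles[:, j, :]
        out = (calls == allele_index).sum(axis=1).astype(float)
        out[(calls == MISSING).any(axis=1)] = np.nan
        return out

    def missing_mask(self, j: int) -> np.ndarray:
        return (self.alleles[:, j, :] == MISSING).any(axis=1)

    def haplotypes(self, variant_indices: Sequence[int], sample_mask: Optional[np.ndarray] = None) -> np.ndarray:
        """Extract the ``(2n, k)`` haplotype matrix at ``variant_indices``.

        Requires every involved call to be phased and non-missing.
        """
        if sample_mask is None:
            sample_mask = np.ones(self.n_samples, dtype=bool)
        idx = list(variant_indices)
        sub_phased = self.phased[sample_mask][:, idx]
        if not sub_phased.all():
            samp = np.array(self.samples)[sample_mask]
            bad_sample = samp[np.where(~sub_phased.all(axis=1))[0][0]]
            raise PhaseError(
                f"unphased call at a defining site for sample {bad_sample}"
            )
        sub = self.alleles[sample_mask][:, idx, :]
        if (sub == MISSING).any():
            raise PhaseError("missing call inside a phased haplotype request")
        # interleave the two haplotypes of each individual
        return np.concatenate([sub[:, :, 0], sub[:, :, 1]], axis=0)

    def subset_variants(self, variant_indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(variant_indices)
        return GenotypeMatrix(
            self.samples,
            self.populations,
            [self.variants[j] for j in idx],
            self.alleles[:, idx, :],
            self.phased[:, idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.populations == other.populations
            and self.variants == other.variants
            and np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.phased, other.phased)
        )


@dataclass(frozen=True)
class ClinicalAnnotation:
    """One drug-variant clinical annotation (PharmGKB-style row)."""

    variant: object  # VariantKey or star-allele / rsid string
    effect_allele: str
    drugs: tuple
    drug_class: str
    phenotype_terms: tuple
    evidence_level: int
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.drugs:
            raise ParameterError("annotation requires at least one drug")
        if not self.phenotype_terms:
            raise ParameterError("annotation requires at least one phenotype term")
        if self.evidence_level not in (1, 2, 3, 4):
            raise ParameterError(
                f"evidence level {self.evidence_level!r} outside the 4-level scheme"
            )
        for t in self.phenotype_terms:
            if t not in PHENOTYPE_VOCABULARY:
                raise ParameterError(f"unnormalized phenotype term {t!r}")


class DrugGeneMap:
    """Drug -> {(gene, function role)} associations plus drug categories."""

    def __init__(
        self,
        entries: Iterable[tuple],
        categories: Mapping[str, str],
    ) -> None:
        self.entries: set = set()
        for drug, gene, role in entries:
            if role not in FUNCTION_ROLES:
                raise ParameterError(f"unknown function role {role!r}")
            self.entries.add((drug, gene, role))
        self.categories = dict(categories)
        for drug in self.drugs():
            if drug not in self.categories:
                raise ParameterError(f"drug {drug!r} has no category")

    def drugs(self) -> list:
        return sorted({d for d, _, _ in self.entries})

    def genes(self, drug: Optional[str] = None, role: Optional[str] = None) -> set:
        return {
            g
            for d, g, r in self.entries
            if (drug is None or d == drug) and (role is None or r == role)
        }

    def category_genes(self, category: str) -> set:
        return {
            g for d, g, _ in self.entries if self.categories.get(d) == category
        }

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class VerdictRow:
    variant: VariantKey
    verdicts: tuple  # aligned with tool names
    gene: Optional[str] = None


class VerdictTable:
    """Per-variant deleteriousness verdicts, one column per in-silico tool."""

    def __init__(self, tools: Sequence[str], rows: Sequence[VerdictRow]) -> None:
        if len(tools) < 1:
            raise SchemaError("verdict table requires at least one tool column")
        self.tools = list(tools)
        for row in rows:
            if len(row.verdicts) != len(self.tools):
                raise SchemaError(
                    f"row {row.variant.vid} has {len(row.verdicts)} verdicts "
                    f"for {len(self.tools)} tools"
                )
            for v in row.verdicts:
                if v not in VERDICT_VALUES:
                    raise SchemaError(f"verdict {v!r} outside {VERDICT_VALUES}")
        self.rows = list(rows)

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class InhibitionRecord:
    """A perpetrator drug inhibiting (or inducing) one enzyme."""

    drug: str
    enzyme: str
    strength: str
    action: str = "inhibit"  # "inhibit" or "induce"

    def __post_init__(self) -> None:
        if self.strength not in INHIBITOR_STRENGTHS:
            raise ParameterError(f"unknown inhibitor strength {self.strength!r}")
        if self.action not in ("inhibit", "induce"):
            raise ParameterError(f"unknown action {self.action!r}")


@dataclass(frozen=True)
class StarAlleleDefinition:
    """A named pharmacogene haplotype defined by required variant alleles."""

    gene: str
    star_name: str
    defining_alleles: tuple  # of (VariantKey, required allele string)

    def __post_init__(self) -> None:
        if not self.defining_alleles:
            raise ParameterError(
                f"star allele {self.star_name} has an empty defining set"
            )
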