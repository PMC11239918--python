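"""Somatic-variant filtering and per-gene mutation summaries.

The filters mirror a targeted FFPE panel's analytical validation: a
variant call needs at least 7 reads supporting the alternate allele, a
variant allele fraction (VAF) of at least 5% for SNVs or 10% for indels,
and must not be a frequent population polymorphism (gnomAD allele
frequency above 1e-4 removes the call; a missing population AF keeps
it).  All thresholds are inclusive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

VARIANT_CLASSES = ("SNV", "INDEL")


class VariantError(ValueError):
    pass


@dataclass(frozen=True)
class VariantRecord:
    sample_id: str
    gene: str
    chromosome: str
    position: int
    ref: str
    alt: str
    variant_class: str
    alt_reads: int
    depth: int
    vaf: float
    population_af: float | None = None

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise VariantError(
                f"unknown variant_class {self.variant_class!r}; "
                f"expected one of {VARIANT_CLASSES}"
            )
        if self.alt_reads > self.depth:
            raise VariantError(
                f"alt_reads ({self.alt_reads}) exceeds depth ({self.depth})"
            )
        if not (0.0 <= self.vaf <= 1.0):
            raise VariantError(f"vaf must be in [0, 1], got {self.vaf}")


@dataclass(frozen=True)
class FilterThresholds:
    min_alt_reads: int = 7
    min_vaf_snv: float = 0.05
    min_vaf_indel: float = 0.10
    max_pop_af: float = 1e-4
    apply_vaf_filter: bool = True


@dataclass(frozen=True)
class FilterReport:
    kept: tuple[VariantRecord, ...]
    drop_counts: Mapping[str, int]  # first failing rule attributed


def filter_variants(
    records: Iterable[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> FilterReport:
    """Apply the read-support, VAF and population-frequency filters.

    Rules are checked in order (alt_reads, vaf, population_af) and a
    dropped record is attributed to the first rule it fails.  Filtering
    is idempotent and monotone in every threshold.
    """
    kept: list[VariantRecord] = []
    drops: Counter[str] = Counter({"alt_reads": 0, "vaf": 0, "population_af": 0})
    for r in records:
        if r.alt_reads < thresholds.min_alt_reads:
            drops["alt_reads"] += 1
            continue
        if thresholds.apply_vaf_filter:
            min_vaf = (
                thresholds.min_vaf_snv
                if r.variant_class == "SNV"
                else thresholds.min_vaf_indel
            )
            if r.vaf < min_vaf:
                drops["vaf"] += 1
                continue
        if r.population_af is not None and r.population_af > thresholds.max_pop_af:
            drops["population_af"] += 1
            continue
        kept.append(r)
    return FilterReport(kept=tuple(kept), drop_counts=dict(drops))


def mutation_frequency(
    records: Iterable[VariantRecord], n_samples: int
) -> dict[str, tuple[int, float]]:
    """Per-gene (distinct mutated samples, fraction of cohort)."""
    if n_samples < 1:
        raise VariantError("n_samples must be >= 1")
    samples_by_gene: dict[str, set[str]] = {}
    for r in records:
        samples_by_gene.setdefault(r.gene, set()).add(r.sample_id)
    return {
        g: (len(s), len(s) / n_samples) for g, s in sorted(samples_by_gene.items())
    }


def mutation_status(
    records: Iterable[VariantRecord], gene: str, sample_ids: Sequence[str]
) -> dict[str, bool]:
    """Per-sample mutant/wild-type status for one gene over a fixed cohort."""
    mutated = {r.sample_id for r in records if r.gene == gene}
    return {s: s in mutated for s in sample_ids}


def gene_response_table(
    mutation_by_sample: Mapping[str, bool],
    responder_by_sample: Mapping[str, bool],
) -> list[list[int]]:
    """2x2 table [[mut_resp, mut_nonresp], [wt_resp, wt_nonresp]].

    Both mappings must cover exactly the same samples; the cell sum
    equals the cohort size.  A table with an empty mutant row is valid
    but degenerate (warned about downstream by the statistics layer).
    """
    if set(mutation_by_sample) != set(responder_by_sample):
        only = set(mutation_by_sample) ^ set(responder_by_sample)
        raise VariantError(
            f"mutation and response status cover different samples "
            f"(e.g. {sorted(only)[0]!r})"
        )
    table = [[0, 0], [0, 0]]
    for s, mut in mutation_by_sample.items():
        row = 0 if mut else 1
        col = 0 if responder_by_sample[s] else 1
        table[row][col] += 1
    return table


def relax_thresholds(
    thresholds: FilterThresholds, *, no_vaf_filter: bool = False
) -> FilterThresholds:
    """Convenience for the CLI's --no-vaf-filter flag."""
    return replace(thresholds, apply_vaf_filter=not no_vaf_filter)
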