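"""Dataset-construction pipeline for labeled variants.

Raw disease and neutral variant sets are turned into the analysis set by a
fixed stage order: class-overlap resolution, basic filters (synonymous,
exact duplicates, start-codon positions, non-standard letters),
multi-nucleotide substitutions, sequence fit, and duplicate sequence
windows.  A :class:`FilterReport` reconciles every removed record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genetic_code import AMINO_ACIDS, ReachabilityMatrix, standard_reachability
from .io import DISEASE, NEUTRAL, VariantRecord


@dataclass
class FilterReport:
    """Per-rule removal counts; ``input == output + sum(removed)`` always."""

    input: int = 0
    removed_overlap: int = 0
    removed_synonymous_or_duplicate: int = 0
    removed_multinucleotide: int = 0
    removed_no_sequence: int = 0
    removed_nonfitting: int = 0
    removed_duplicate_window: int = 0
    output_neutral: int = 0
    output_disease: int = 0

    @property
    def output(self) -> int:
        return self.output_neutral + self.output_disease

    @property
    def total_removed(self) -> int:
        return (
            self.removed_overlap
            + self.removed_synonymous_or_duplicate
            + self.removed_multinucleotide
            + self.removed_no_sequence
            + self.removed_nonfitting
            + self.removed_duplicate_window
        )

    def reconciles(self) -> bool:
        return self.input == self.output + self.total_removed

    def to_tsv(self) -> str:
        rows = [
            ("input", self.input),
            ("removed_overlap", self.removed_overlap),
            ("removed_synonymous_or_duplicate", self.removed_synonymous_or_duplicate),
            ("removed_multinucleotide", self.removed_multinucleotide),
            ("removed_no_sequence", self.removed_no_sequence),
            ("removed_nonfitting", self.removed_nonfitting),
            ("removed_duplicate_window", self.removed_duplicate_window),
            ("output_neutral", self.output_neutral),
            ("output_disease", self.output_disease),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def resolve_class_overlap(
    disease: list[VariantRecord], neutral: list[VariantRecord]
) -> tuple[list[VariantRecord], list[VariantRecord], int]:
    """Variants present in both classes keep the disease label and are
    removed from the neutral set."""
    disease_keys = {v.key for v in disease}
    kept = [v for v in neutral if v.key not in disease_keys]
    return disease, kept, len(neutral) - len(kept)


def basic_filters(variants: list[VariantRecord]) -> tuple[list[VariantRecord], int]:
    """Drop synonymous records, exact duplicates, start-codon variants
    (position 1) and substitutions involving non-standard letters."""
    seen: set[tuple] = set()
    kept: list[VariantRecord] = []
    for v in variants:
        if v.ref_aa == v.mut_aa:
            continue
        if v.position == 1:
            continue
        if v.ref_aa not in AMINO_ACIDS or v.mut_aa not in AMINO_ACIDS:
            continue
        if v.key in seen:
            continue
        seen.add(v.key)
        kept.append(v)
    return kept, len(variants) - len(kept)


def filter_multinucleotide(
    variants: list[VariantRecord], reach: ReachabilityMatrix | None = None
) -> tuple[list[VariantRecord], int]:
    """Drop substitutions that require more than one mutation in the codon."""
    reach = reach or standard_reachability()
    kept = [v for v in variants if reach[v.ref_aa, v.mut_aa]]
    return kept, len(variants) - len(kept)


def filter_sequence_fit(
    variants: list[VariantRecord], proteins: dict[str, str]
) -> tuple[list[VariantRecord], int, int]:
    """Drop variants without a known protein or whose reference amino acid
    does not match the sequence at the stated position.

    Returns ``(kept, n_no_sequence, n_nonfitting)``.
    """
    kept: list[VariantRecord] = []
    n_missing = n_mismatch = 0
    for v in variants:
        seq = proteins.get(v.protein_id)
        if seq is None:
            n_missing += 1
        elif v.position > len(seq) or seq[v.position - 1] != v.ref_aa:
            n_mismatch += 1
        else:
            kept.append(v)
    return kept, n_missing, n_mismatch


def sequence_window(seq: str, position: int, length: int = 19) -> str:
    """The subsequence of ``length`` residues centred on ``position``
    (1-based), truncated at the sequence ends."""
    half = length // 2
    return seq[max(0, position - 1 - half) : position + half]


def filter_duplicate_windows(
    variants: list[VariantRecord],
    proteins: dict[str, str],
    window: int = 19,
    keep_one: bool = True,
) -> tuple[list[VariantRecord], int]:
    """Collapse variants sharing an identical sequence window and substitution.

    Variants whose (window string, ref, mut) coincide are assumed to be the
    same underlying DNA mutation mapped to multiple proteins.  By default
    one canonical record survives per group (smallest protein id, then
    smallest position); with ``keep_one=False`` every member of a
    multi-record group is dropped (the stricter reading).
    """
    groups: dict[tuple[str, str, str], list[VariantRecord]] = {}
    for v in variants:
        win = sequence_window(proteins[v.protein_id], v.position, window)
        groups.setdefault((win, v.ref_aa, v.mut_aa), []).append(v)
    keep: set[tuple] = set()
    for members in groups.values():
        if len(members) == 1:
            keep.add(members[0].key)
        elif keep_one:
            canonical = min(members, key=lambda v: (v.protein_id, v.position))
            keep.add(canonical.key)
    kept = [v for v in variants if v.key in keep]
    return kept, len(variants) - len(kept)


@dataclass
class FilterResult:
    variants: list[VariantRecord]
    report: FilterReport = field(default_factory=FilterReport)


def apply_filters(
    disease: list[VariantRecord],
    neutral: list[VariantRecord],
    proteins: dict[str, str],
    reach: ReachabilityMatrix | None = None,
    window: int = 19,
    keep_one_window_dup: bool = True,
) -> FilterResult:
    """Run the full pipeline in its fixed stage order and reconcile counts."""
    report = FilterReport(input=len(disease) + len(neutral))
    disease, neutral, report.removed_overlap = resolve_class_overlap(disease, neutral)
    merged = [v.with_label(DISEASE) for v in disease] + [
        v.with_label(NEUTRAL) for v in neutral
    ]
    merged, report.removed_synonymous_or_duplicate = basic_filters(merged)
    merged, report.removed_multinucleotide = filter_multinucleotide(merged, reach)
    merged, report.removed_no_sequence, report.removed_nonfitting = filter_sequence_fit(
        merged, proteins
    )
    merged, report.removed_duplicate_window = filter_duplicate_windows(
        merged, proteins, window=window, keep_one=keep_one_window_dup
    )
    report.output_disease = sum(1 for v in merged if v.label == DISEASE)
    report.output_neutral = sum(1 for v in merged if v.label == NEUTRAL)
    assert report.reconciles(), "filter report does not reconcile"
    return FilterResult(variants=merged, report=report)
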