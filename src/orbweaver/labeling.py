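"""Accessibility labels: merged peaks -> seven-category training loci.

Open chromatin is measured in three cell types — iPSC, LCL and iPSC-CM — and
every locus accessible in at least one of them receives a categorical label
O in {1..7} encoding exactly which cell types it is open in:

    1  iPSC-CM alone            5  iPSC and iPSC-CM
    2  LCL alone                6  iPSC and LCL
    3  iPSC-CM and LCL          7  all three
    4  iPSC alone

A locus open in no cell type has no label (it is not part of the universe).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome import BedRecord, GenomeError, GenomicInterval, OneHotWindow, extract_window

log = logging.getLogger("orbweaver")

CELL_TYPES = ("iPSC", "LCL", "iPSC-CM")

# (iPSC, LCL, iPSC-CM) open flags -> category
_FLAGS_TO_CATEGORY = {
    (False, False, True): 1,
    (False, True, False): 2,
    (False, True, True): 3,
    (True, False, False): 4,
    (True, False, True): 5,
    (True, True, False): 6,
    (True, True, True): 7,
}
_CATEGORY_TO_FLAGS = {v: k for k, v in _FLAGS_TO_CATEGORY.items()}


class LabelError(ValueError):
    pass


def assign_category(flags: tuple[bool, bool, bool]) -> int:
    """Map (iPSC, LCL, iPSC-CM) open flags to the 7-way category."""
    flags = tuple(bool(f) for f in flags)
    if flags == (False, False, False):
        raise LabelError("locus accessible in no cell type")
    return _FLAGS_TO_CATEGORY[flags]


def flags_from_category(category: int) -> tuple[bool, bool, bool]:
    """Inverse of :func:`assign_category`."""
    try:
        return _CATEGORY_TO_FLAGS[int(category)]
    except KeyError:
        raise LabelError(f"category must be in 1..7, got {category}") from None


def categories_containing(cell_type: str) -> tuple[int, ...]:
    """Categories whose flag for ``cell_type`` is open."""
    t = CELL_TYPES.index(cell_type)
    return tuple(o for o in range(1, 8) if _CATEGORY_TO_FLAGS[o][t])


@dataclass
class AccessibilityLabel:
    open_flags: tuple[bool, bool, bool]  # (iPSC, LCL, iPSC-CM)
    category: int

    def __post_init__(self) -> None:
        if assign_category(self.open_flags) != self.category:
            raise LabelError(
                f"flags {self.open_flags} inconsistent with category {self.category}"
            )

    @classmethod
    def from_flags(cls, flags: tuple[bool, bool, bool]) -> "AccessibilityLabel":
        return cls(tuple(bool(f) for f in flags), assign_category(flags))


@dataclass
class LabeledLocus:
    interval: GenomicInterval
    label: AccessibilityLabel
    window: OneHotWindow


def _union_merge(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Coalesce overlapping or book-ended intervals per chromosome."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def merge_peaks(
    per_sample_peaks: list[list[BedRecord]], min_fold: float = 15.0
) -> list[GenomicInterval]:
    """Merge per-sample peak calls of one cell type.

    Peaks below ``min_fold`` fold-change enrichment over background are
    discarded; survivors are merged by interval union.  Idempotent.
    """
    kept: list[GenomicInterval] = []
    for peaks in per_sample_peaks:
        for rec in peaks:
            if rec.fold_enrichment is None:
                raise LabelError(
                    f"peak {rec.interval.chrom}:{rec.interval.start}-"
                    f"{rec.interval.end} lacks a fold-enrichment column"
                )
            if rec.fold_enrichment >= min_fold:
                kept.append(rec.interval)
    return _union_merge(kept)


def _overlap_len(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def build_dataset(
    merged_peaks_by_celltype: dict[str, list[GenomicInterval]],
    genome,
    width: int = 500,
    min_overlap_frac: float = 0.0,
) -> list[LabeledLocus]:
    """Candidate loci = union of the three cell types' merged peak sets.

    Each union locus is flagged open in cell type t iff it overlaps one of
    t's merged peaks (>= 1 bp by default; ``min_overlap_frac`` of the locus
    length if set), and a centered window is extracted.  Loci whose windows
    overhang chromosome ends are dropped with a logged count.
    """
    missing = [t for t in CELL_TYPES if t not in merged_peaks_by_celltype]
    if missing:
        raise LabelError(f"missing peak sets for cell types: {missing}")
    all_peaks = [iv for t in CELL_TYPES for iv in merged_peaks_by_celltype[t]]
    union = _union_merge(all_peaks)
    if not union:
        raise LabelError("empty peak union: no accessible loci")

    loci: list[LabeledLocus] = []
    dropped = 0
    for locus in union:
        flags = []
        for t in CELL_TYPES:
            ovl = max(
                (_overlap_len(locus, p) for p in merged_peaks_by_celltype[t]),
                default=0,
            )
            need = max(1, int(np.ceil(min_overlap_frac * len(locus))))
            flags.append(ovl >= need)
        label = AccessibilityLabel.from_flags(tuple(flags))
        try:
            window = extract_window(genome, locus, width)
        except GenomeError:
            dropped += 1
            continue
        loci.append(LabeledLocus(locus, label, window))
    if dropped:
        log.info("dropped %d loci with windows overhanging chromosome ends", dropped)
    if not loci:
        raise LabelError("all union loci dropped during window extraction")
    return loci


def split_dataset(
    loci: list[LabeledLocus], held_out_fraction: float, seed: int
) -> tuple[list[LabeledLocus], list[LabeledLocus]]:
    """Category-stratified reproducible train/held-out split."""
    from sklearn.model_selection import train_test_split

    if not (0.0 < held_out_fraction < 1.0):
        raise LabelError("held_out_fraction must be in (0, 1)")
    categories = [l.label.category for l in loci]
    counts = {o: categories.count(o) for o in set(categories)}
    thin = [o for o, c in counts.items() if c < 2]
    if thin:
        raise LabelError(
            f"categories {thin} have fewer than 2 loci; merge categories or "
            "simulate a larger dataset before splitting"
        )
    train, test = train_test_split(
        loci,
        test_size=held_out_fraction,
        random_state=seed,
        stratify=categories,
        shuffle=True,
    )
    return list(train), list(test)
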