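"""Sequence, interval and phased-genotype I/O.

Coordinates are BED-convention 0-based half-open throughout.  Sequences are
one-hot encoded as L x 4 binary matrices (columns A, C, G, T); ambiguous
bases become all-zero rows so the input stays strictly binary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger("orbweaver")

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")


class GenomeError(ValueError):
    pass


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def one_hot(seq: str) -> np.ndarray:
    """Encode a DNA string as an L x 4 binary matrix (non-ACGT -> zero row)."""
    arr = np.zeros((len(seq), 4), dtype=np.float32)
    for i, ch in enumerate(seq.upper()):
        j = _BASE_INDEX.get(ch)
        if j is not None:
            arr[i, j] = 1.0
    return arr


def decode_one_hot(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot`; all-zero rows decode to ``N``."""
    out = []
    for row in np.asarray(matrix):
        nz = np.nonzero(row)[0]
        out.append(BASES[nz[0]] if len(nz) == 1 else "N")
    return "".join(out)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class OneHotWindow:
    """A fixed-width locus-centered window with its one-hot encoding."""

    interval: GenomicInterval
    matrix: np.ndarray  # (width, 4)
    n_mask: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.interval), 4):
            raise GenomeError(
                f"window matrix {self.matrix.shape} does not match interval "
                f"length {len(self.interval)}"
            )

    @property
    def sequence(self) -> str:
        return decode_one_hot(self.matrix)


def extract_window(genome, locus: GenomicInterval, width: int = 500) -> OneHotWindow:
    """One-hot 500-bp (default) window centered at the locus midpoint.

    ``genome`` is a ``pyfaidx.Fasta`` (or any mapping chrom -> indexable
    sequence).  A window overhanging a chromosome end is an error, never
    silently clipped.
    """
    if width % 2:
        raise GenomeError("window width must be even")
    if locus.chrom not in genome:
        raise GenomeError(f"unknown chromosome {locus.chrom!r}")
    c = locus.center
    start, end = c - width // 2, c + width // 2
    chrom_len = len(genome[locus.chrom])
    if start < 0 or end > chrom_len:
        raise GenomeError(
            f"window [{start},{end}) around {locus.chrom}:{c} overhangs "
            f"chromosome of length {chrom_len}"
        )
    seq = str(genome[locus.chrom][start:end]).upper()
    matrix = one_hot(seq)
    n_mask = frozenset(int(i) for i in np.nonzero(matrix.sum(axis=1) == 0)[0])
    return OneHotWindow(GenomicInterval(locus.chrom, start, end), matrix, n_mask)


@dataclass
class BedRecord:
    interval: GenomicInterval
    name: str | None = None
    score: float | None = None
    fold_enrichment: float | None = None  # narrowPeak signalValue (column 7)


def read_bed(path: str) -> list[BedRecord]:
    """Read BED3/BED6/narrowPeak lines into 0-based half-open records."""
    records: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GenomeError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise GenomeError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise GenomeError(f"{path}:{lineno}: start >= end")
            rec = BedRecord(GenomicInterval(fields[0], start, end))
            if len(fields) >= 4:
                rec.name = fields[3]
            if len(fields) >= 5 and fields[4] != ".":
                rec.score = float(fields[4])
            if len(fields) >= 7:  # narrowPeak: signalValue = fold enrichment
                rec.fold_enrichment = float(fields[6])
            records.append(rec)
    return records


@dataclass(frozen=True)
class FocalSNP:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise GenomeError("focal SNP must be a biallelic SNV")


@dataclass
class Haplotype:
    sample_id: str
    haplotype_index: int  # 0 or 1
    sequence: str
    focal_allele: str


@dataclass
class HaplotypeSet:
    locus: GenomicInterval  # the window interval
    haplotypes: list[Haplotype]
    focal_snp: FocalSNP

    def allele_groups(self) -> tuple[list[Haplotype], list[Haplotype]]:
        """(ref-carrying, alt-carrying) haplotypes."""
        ref = [h for h in self.haplotypes if h.focal_allele == self.focal_snp.ref]
        alt = [h for h in self.haplotypes if h.focal_allele == self.focal_snp.alt]
        return ref, alt


def build_haplotypes(
    genome,
    locus: GenomicInterval,
    vcf_path: str,
    focal_snp: FocalSNP,
    width: int = 500,
    substitute_all: bool = True,
) -> HaplotypeSet:
    """Per-haplotype window sequences from phased genotypes.

    Every phased biallelic SNV inside the window is substituted into the
    carrying haplotype (``substitute_all=False`` restricts to the focal SNP).
    Indels and multiallelic records are skipped with a warning; an unphased
    genotype at any in-window variant is an error.
    """
    from cyvcf2 import VCF

    window = extract_window(genome, locus, width)
    ref_seq = window.sequence
    wstart, wend = window.interval.start, window.interval.end

    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    variants = []  # (pos0, ref, alt, genotypes)
    focal_found = False
    for v in vcf:
        if v.CHROM != locus.chrom or not (wstart <= v.start < wend):
            continue
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            log.warning(
                "skipping non-SNV/multiallelic record %s:%d in haplotype window",
                v.CHROM, v.POS,
            )
            continue
        is_focal = (
            v.start == focal_snp.pos
            and v.REF == focal_snp.ref
            and v.ALT[0] == focal_snp.alt
        )
        focal_found = focal_found or is_focal
        if not substitute_all and not is_focal:
            continue
        for s_i, gt in enumerate(v.genotypes):
            if len(gt) < 3 or not gt[2]:
                raise GenomeError(
                    f"unphased genotype for sample {samples[s_i]!r} at "
                    f"{v.CHROM}:{v.POS}"
                )
        variants.append((v.start, v.REF, v.ALT[0], [g[:2] for g in v.genotypes]))
    if not focal_found:
        raise GenomeError(
            f"focal SNP {focal_snp.chrom}:{focal_snp.pos} "
            f"{focal_snp.ref}>{focal_snp.alt} absent from VCF"
        )

    haplotypes: list[Haplotype] = []
    for s_i, sample in enumerate(samples):
        for hap in (0, 1):
            seq = list(ref_seq)
            focal_allele = focal_snp.ref
            for pos0, ref, alt, gts in variants:
                offset = pos0 - wstart
                if seq[offset] != ref and seq[offset] != "N":
                    raise GenomeError(
                        f"VCF REF {ref!r} at {locus.chrom}:{pos0 + 1} does not "
                        f"match reference sequence base {seq[offset]!r}"
                    )
                allele = alt if gts[s_i][hap] == 1 else ref
                seq[offset] = allele
                if pos0 == focal_snp.pos:
                    focal_allele = allele
            haplotypes.append(Haplotype(sample, hap, "".join(seq), focal_allele))
    return HaplotypeSet(window.interval, haplotypes, focal_snp)
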