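"""Synthetic benchmark generator: motif-planted windows, labels, phased
haplotype panels and simulated allelic imbalance.

The generator emulates the study design at desk scale: a small set of
cell-type-specific TF motifs (plus ubiquitously planted shared motifs)
defines which of the seven accessibility categories a window belongs to;
window sequences are i.i.d. background (human-like 41% GC by default) with
one sampled instance of each relevant motif planted at a random position and
strand.  caQTL panels add a focal SNP inside a planted motif whose
alternate allele changes the PWM log-odds of the site; the simulated
allelic imbalance is a binomial read split whose expected alternate-allele
fraction shifts in proportion to that log-odds change.

All outputs are deterministic functions of the seed; written FASTA/VCF/TSV
files are byte-identical across runs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .genome import (
    FocalSNP,
    GenomicInterval,
    Haplotype,
    HaplotypeSet,
    OneHotWindow,
    one_hot,
    reverse_complement,
)
from .labeling import (
    CELL_TYPES,
    AccessibilityLabel,
    LabeledLocus,
    flags_from_category,
)
from .pwm import BASES, PWM

SHARED = "shared"


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    ``planting_strength`` is the probability of the consensus base at every
    motif position (0.25 = uninformative, 1 = hard consensus).
    ``effect_size`` is the largest expected shift of the alternate-allele
    read fraction away from 0.5 for a maximally disruptive caQTL SNP.
    """

    motifs_per_celltype: int = 2
    n_shared_motifs: int = 1
    motif_width_range: tuple[int, int] = (8, 12)
    loci_per_category: int = 300
    window_width: int = 500
    gc_content: float = 0.41
    planting_strength: float = 0.9
    n_caqtl: int = 200
    n_decoys: int = 200
    n_individuals: int = 60
    n_background_snvs: int = 2
    effect_size: float = 0.35
    depth: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.25 <= self.planting_strength <= 1.0):
            # 0.25 is the no-information limit (uniform columns)
            raise SimulationError("planting_strength must be in [0.25, 1]")
        for name in (
            "motifs_per_celltype", "loci_per_category", "n_caqtl",
            "n_individuals", "depth",
        ):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if self.motif_width_range[0] < 4:
            raise SimulationError("motif width must be >= 4")
        if self.depth < 10:
            import logging

            logging.getLogger("orbweaver").warning(
                "read depth %d < 10: imbalance estimates will be unstable",
                self.depth,
            )

    @property
    def background(self) -> np.ndarray:
        gc = self.gc_content
        return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def simulate_pwms(config: SimulationConfig) -> list[PWM]:
    """Random sparse-consensus PWMs for each cell type plus shared motifs.

    tf_ids encode the assignment: ``TF_<cell type>_<k>`` and
    ``TF_shared_<k>``.  Every column puts ``planting_strength`` probability
    on a random consensus base and splits the rest evenly.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.motif_width_range
    if lo < 4:
        raise SimulationError("motif width must be >= 4")
    s = config.planting_strength
    pwms = []
    groups = [(t, config.motifs_per_celltype) for t in CELL_TYPES]
    groups.append((SHARED, config.n_shared_motifs))
    for group, count in groups:
        for k in range(count):
            w = int(rng.integers(lo, hi + 1))
            consensus = rng.integers(0, 4, size=w)
            matrix = np.full((w, 4), (1 - s) / 3)
            matrix[np.arange(w), consensus] = s
            pwms.append(
                PWM(
                    tf_id=f"TF_{group}_{k}",
                    tf_name=f"TF_{group}_{k}",
                    matrix=matrix,
                    source="simulated",
                )
            )
    return pwms


def celltype_motif_map(pwms: list[PWM]) -> dict[str, list[PWM]]:
    """Group generated PWMs by the cell type encoded in their tf_id."""
    out: dict[str, list[PWM]] = {t: [] for t in (*CELL_TYPES, SHARED)}
    for p in pwms:
        group = p.tf_id.split("_")[1]
        if group in out:
            out[group].append(p)
    return out


def _random_background(rng: np.random.Generator, length: int, bg: np.ndarray) -> list[str]:
    return [BASES[i] for i in rng.choice(4, size=length, p=bg)]


def _sample_motif_instance(rng: np.random.Generator, pwm: PWM) -> str:
    return "".join(
        BASES[rng.choice(4, p=pwm.matrix[w])] for w in range(pwm.width)
    )


def _plant(
    rng: np.random.Generator,
    seq: list[str],
    pwm: PWM,
    occupied: list[tuple[int, int]],
    max_start: int | None = None,
    max_tries: int = 200,
) -> tuple[int, str]:
    """Insert a sampled motif instance at a random free position/strand.

    ``max_start`` keeps plants inside the region a valid-convolution scan
    with the bank's widest filter can see (no edge-invisible motifs).
    """
    L, w = len(seq), pwm.width
    hi = (L - w if max_start is None else min(max_start, L - w)) + 1
    for _ in range(max_tries):
        pos = int(rng.integers(0, hi))
        if all(pos + w <= s or pos >= e for s, e in occupied):
            instance = _sample_motif_instance(rng, pwm)
            strand = "+" if rng.random() < 0.5 else "-"
            planted = instance if strand == "+" else reverse_complement(instance)
            seq[pos : pos + w] = list(planted)
            occupied.append((pos, pos + w))
            return pos, strand, planted
    raise SimulationError("could not place motif without overlap; window too crowded")


@dataclass
class PlantedMotif:
    tf_id: str
    position: int
    strand: str
    instance: str = ""  # window-frame subsequence actually written


@dataclass
class SimulatedDataset:
    loci: list[LabeledLocus]
    ground_truth: list[list[PlantedMotif]]
    config: SimulationConfig

    @property
    def X(self) -> np.ndarray:
        return np.stack([l.window.matrix for l in self.loci])

    @property
    def categories(self) -> np.ndarray:
        return np.array([l.label.category for l in self.loci])

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "windows.fa"), "w") as fa:
            for locus in self.loci:
                fa.write(f">{locus.interval.chrom}\n{locus.window.sequence}\n")
        with open(os.path.join(out_dir, "labels.tsv"), "w") as tsv:
            tsv.write("chrom\tstart\tend\tiPSC\tLCL\tiPSC-CM\tcategory\n")
            for locus in self.loci:
                f = locus.label.open_flags
                tsv.write(
                    f"{locus.interval.chrom}\t{locus.interval.start}\t"
                    f"{locus.interval.end}\t{int(f[0])}\t{int(f[1])}\t{int(f[2])}\t"
                    f"{locus.label.category}\n"
                )
        with open(os.path.join(out_dir, "ground_truth.tsv"), "w") as tsv:
            tsv.write("chrom\ttf_id\tposition\tstrand\n")
            for locus, planted in zip(self.loci, self.ground_truth):
                for pm in planted:
                    tsv.write(
                        f"{locus.interval.chrom}\t{pm.tf_id}\t{pm.position}\t{pm.strand}\n"
                    )
        with open(os.path.join(out_dir, "manifest.txt"), "w") as mf:
            mf.write(f"seed\t{self.config.seed}\n")
            mf.write(f"loci_per_category\t{self.config.loci_per_category}\n")


def simulate_dataset(
    config: SimulationConfig,
    pwms: list[PWM] | None = None,
    plant: bool = True,
) -> SimulatedDataset:
    """Motif-planted windows with deterministic seven-category labels.

    Each locus of category O carries one sampled instance of every motif of
    every cell type open in O, plus every shared motif; ``plant=False``
    produces pure background (labels then carry no sequence signal).
    """
    if pwms is None:
        pwms = simulate_pwms(config)
    by_group = celltype_motif_map(pwms)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    width = config.window_width
    for p in pwms:
        if p.width > width:
            raise SimulationError(f"motif {p.tf_id} longer than the window")

    loci: list[LabeledLocus] = []
    truth: list[list[PlantedMotif]] = []
    idx = 0
    for category in range(1, 8):
        flags = flags_from_category(category)
        motifs = [m for t, f in zip(CELL_TYPES, flags) if f for m in by_group[t]]
        motifs = motifs + by_group[SHARED]
        for _ in range(config.loci_per_category):
            seq = _random_background(rng, width, config.background)
            planted: list[PlantedMotif] = []
            if plant:
                occupied: list[tuple[int, int]] = []
                wmax = max(p.width for p in pwms)
                for m in motifs:
                    pos, strand, inst = _plant(rng, seq, m, occupied, width - wmax)
                    planted.append(PlantedMotif(m.tf_id, pos, strand, inst))
            chrom = f"locus_{idx:06d}"
            idx += 1
            interval = GenomicInterval(chrom, 0, width)
            window = OneHotWindow(interval, one_hot("".join(seq)))
            loci.append(
                LabeledLocus(interval, AccessibilityLabel.from_flags(flags), window)
            )
            truth.append(planted)
    return SimulatedDataset(loci=loci, ground_truth=truth, config=config)


@dataclass
class SimulatedCaqtl:
    chrom: str
    ref_seq: str
    snp: FocalSNP
    cell_type: str
    tf_id: str
    motif_position: int
    strand: str
    is_causal: bool
    pi_l: float
    pi_s: float
    effect: float  # expected alt-fraction shift, p_eff - 0.5 (0 for decoys)
    p_eff: float
    hap_alleles: np.ndarray  # (2N,) 0/1 at the focal SNP, haplotype-major
    background_snvs: list[tuple[int, str, str, np.ndarray]]  # pos, ref, alt, alleles
    alt_count: int
    ref_count: int


@dataclass
class CaqtlPanel:
    caqtls: list[SimulatedCaqtl]
    config: SimulationConfig
    samples: list[str]

    def haplotype_set(self, i: int) -> HaplotypeSet:
        """In-memory haplotype windows for caQTL i (all SNVs substituted)."""
        c = self.caqtls[i]
        width = self.config.window_width
        haplotypes = []
        variants = [(c.snp.pos, c.snp.ref, c.snp.alt, c.hap_alleles)] + [
            (pos, ref, alt, alleles) for pos, ref, alt, alleles in c.background_snvs
        ]
        for s_i, sample in enumerate(self.samples):
            for hap in (0, 1):
                h = 2 * s_i + hap
                seq = list(c.ref_seq)
                focal_allele = c.snp.ref
                for pos, ref, alt, alleles in variants:
                    allele = alt if alleles[h] else ref
                    seq[pos] = allele
                    if pos == c.snp.pos:
                        focal_allele = allele
                haplotypes.append(Haplotype(sample, hap, "".join(seq), focal_allele))
        return HaplotypeSet(
            GenomicInterval(c.chrom, 0, width), haplotypes, c.snp
        )

    def causal_records(self):
        from .variants import CausalLocus

        width = self.config.window_width
        return [
            CausalLocus(
                GenomicInterval(c.chrom, 0, width), c.snp, c.pi_l, c.pi_s
            )
            for c in self.caqtls
        ]

    def imbalance_records(self):
        from .variants import ImbalanceRecord

        return [
            ImbalanceRecord(c.chrom, c.ref_count, c.alt_count) for c in self.caqtls
        ]

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "reference.fa"), "w") as fa:
            for c in self.caqtls:
                fa.write(f">{c.chrom}\n{c.ref_seq}\n")
        with open(os.path.join(out_dir, "panel.vcf"), "w") as vcf:
            vcf.write("##fileformat=VCFv4.2\n")
            for c in self.caqtls:
                vcf.write(
                    f"##contig=<ID={c.chrom},length={self.config.window_width}>\n"
                )
            vcf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            vcf.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            for c in self.caqtls:
                records = [
                    (c.snp.pos, f"{c.chrom}_focal", c.snp.ref, c.snp.alt, c.hap_alleles)
                ] + [
                    (pos, f"{c.chrom}_bg{k}", ref, alt, alleles)
                    for k, (pos, ref, alt, alleles) in enumerate(c.background_snvs)
                ]
                for pos, vid, ref, alt, alleles in sorted(records):
                    gts = "\t".join(
                        f"{alleles[2 * s]}|{alleles[2 * s + 1]}"
                        for s in range(len(self.samples))
                    )
                    vcf.write(
                        f"{c.chrom}\t{pos + 1}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n"
                    )
        with open(os.path.join(out_dir, "causal.tsv"), "w") as tsv:
            tsv.write("chrom\tpos\tref\talt\tpi_l\tpi_s\n")
            for c in self.caqtls:
                tsv.write(
                    f"{c.chrom}\t{c.snp.pos + 1}\t{c.snp.ref}\t{c.snp.alt}\t"
                    f"{c.pi_l:.6f}\t{c.pi_s:.6f}\n"
                )
        with open(os.path.join(out_dir, "imbalance.tsv"), "w") as tsv:
            tsv.write("snp\tref_count\talt_count\n")
            for c in self.caqtls:
                tsv.write(f"{c.chrom}\t{c.ref_count}\t{c.alt_count}\n")
        with open(os.path.join(out_dir, "ground_truth.tsv"), "w") as tsv:
            tsv.write(
                "chrom\tcell_type\ttf_id\tis_causal\teffect\tp_eff\tdirection\n"
            )
            for c in self.caqtls:
                tsv.write(
                    f"{c.chrom}\t{c.cell_type}\t{c.tf_id}\t{int(c.is_causal)}\t"
                    f"{c.effect:.6f}\t{c.p_eff:.6f}\t{int(np.sign(c.effect))}\n"
                )


def max_disruption(strength: float) -> float:
    """Largest possible PWM log2-odds drop for a single-base change."""
    return float(np.log2(strength / ((1 - strength) / 3)))


def simulate_caqtl_panel(
    config: SimulationConfig, pwms: list[PWM] | None = None
) -> CaqtlPanel:
    """Synthetic caQTLs with motif-altering SNPs, a phased diploid panel and
    binomially sampled allelic imbalance.

    For each true caQTL a motif instance is planted and the focal SNP swaps
    one motif position to another base; the expected alternate-allele read
    fraction is 0.5 - effect_size * d / d_max, where d is the PWM log2-odds
    change of the site (ref vs alt) and d_max its largest possible value, so
    disrupting alleles (d > 0) reduce accessibility on the alt haplotype.
    Decoys place the SNP in background sequence (no effect, p_eff = 0.5)
    with pi_s < 0.5.  Observed counts are Binomial(depth, p_eff).
    """
    if pwms is None:
        pwms = simulate_pwms(config)
    by_group = celltype_motif_map(pwms)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    width = config.window_width
    n_hap = 2 * config.n_individuals
    samples = [f"NA{i:05d}" for i in range(config.n_individuals)]
    d_max = max_disruption(config.planting_strength)
    scale = config.effect_size / d_max

    caqtls: list[SimulatedCaqtl] = []
    total = config.n_caqtl + config.n_decoys
    for i in range(total):
        is_causal = i < config.n_caqtl
        cell_type = CELL_TYPES[i % len(CELL_TYPES)]
        candidates = by_group[cell_type]
        pwm = candidates[int(rng.integers(len(candidates)))]
        seq = _random_background(rng, width, config.background)
        occupied: list[tuple[int, int]] = []
        # keep the motif near the center so the SNP stays well inside the window
        lo = width // 2 - 50
        pos = lo + int(rng.integers(0, 100 - pwm.width + 1))
        instance = _sample_motif_instance(rng, pwm)
        strand = "+" if rng.random() < 0.5 else "-"
        planted = instance if strand == "+" else reverse_complement(instance)
        seq[pos : pos + pwm.width] = list(planted)
        occupied.append((pos, pos + pwm.width))

        if is_causal:
            col = int(rng.integers(pwm.width))
            q = pos + col if strand == "+" else pos + pwm.width - 1 - col
            ref_base = seq[q]
            alt_base = BASES[
                int(rng.choice([b for b in range(4) if BASES[b] != ref_base]))
            ]
            # PWM probabilities are evaluated in the motif frame
            if strand == "+":
                ref_m, alt_m = ref_base, alt_base
            else:
                ref_m = reverse_complement(ref_base)
                alt_m = reverse_complement(alt_base)
            p_ref = pwm.matrix[col, BASES.index(ref_m)]
            p_alt = pwm.matrix[col, BASES.index(alt_m)]
            d = float(np.log2(p_ref / p_alt))
            p_eff = float(np.clip(0.5 - scale * d, 0.05, 0.95))
            pi_l, pi_s = 1.0, 1.0
        else:
            free = [
                q for q in range(width) if all(q < s or q >= e for s, e in occupied)
            ]
            q = int(rng.choice(free))
            ref_base = seq[q]
            alt_base = BASES[
                int(rng.choice([b for b in range(4) if BASES[b] != ref_base]))
            ]
            p_eff = 0.5
            pi_l = float(rng.uniform(0.5, 1.0))
            pi_s = float(rng.uniform(0.0, 0.5))

        # phased panel at the focal SNP; both alleles forced present
        af = float(rng.uniform(0.1, 0.9))
        alleles = (rng.random(n_hap) < af).astype(int)
        if alleles.sum() == 0:
            alleles[int(rng.integers(n_hap))] = 1
        elif alleles.sum() == n_hap:
            alleles[int(rng.integers(n_hap))] = 0

        bg_snvs = []
        taken = {q}
        for _ in range(config.n_background_snvs):
            free = [
                p
                for p in range(width)
                if p not in taken and all(p < s or p >= e for s, e in occupied)
            ]
            bp = int(rng.choice(free))
            taken.add(bp)
            b_ref = seq[bp]
            b_alt = BASES[int(rng.choice([b for b in range(4) if BASES[b] != b_ref]))]
            b_af = float(rng.uniform(0.05, 0.95))
            b_alleles = (rng.random(n_hap) < b_af).astype(int)
            bg_snvs.append((bp, b_ref, b_alt, b_alleles))

        alt_count = int(rng.binomial(config.depth, p_eff))
        chrom = f"caqtl_{i:05d}"
        caqtls.append(
            SimulatedCaqtl(
                chrom=chrom,
                ref_seq="".join(seq),
                snp=FocalSNP(chrom, q, ref_base, alt_base),
                cell_type=cell_type,
                tf_id=pwm.tf_id,
                motif_position=pos,
                strand=strand,
                is_causal=is_causal,
                pi_l=pi_l,
                pi_s=pi_s,
                effect=p_eff - 0.5,
                p_eff=p_eff,
                hap_alleles=alleles,
                background_snvs=bg_snvs,
                alt_count=alt_count,
                ref_count=config.depth - alt_count,
            )
        )
    return CaqtlPanel(caqtls=caqtls, config=config, samples=samples)


def generative_correlation(
    panel: CaqtlPanel, n_draws: int = 10_000, seed: int = 1
) -> float:
    """Monte-Carlo correlation between planted effects and freshly sampled
    imbalance fractions for the causal caQTLs of a panel.

    Replicate binomial panels are drawn until ``n_draws`` total samples are
    spent; the mean Pearson r across replicates is returned.  This is the
    reference value the end-to-end pipeline's predicted-vs-observed
    correlation is compared against.
    """
    rng = np.random.default_rng(seed)
    causal = [c for c in panel.caqtls if c.is_causal]
    effects = np.array([c.effect for c in causal])
    depth = panel.config.depth
    n_reps = max(1, n_draws // len(causal))
    rs = []
    for _ in range(n_reps):
        fracs = rng.binomial(depth, [c.p_eff for c in causal]) / depth
        if fracs.std() == 0:
            continue
        rs.append(np.corrcoef(effects, fracs - 0.5)[0, 1])
    return float(np.mean(rs))
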