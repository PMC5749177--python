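"""Cell-type-specific caQTL effect prediction from haplotype scoring.

A caQTL (chromatin accessibility QTL) is a variant associated with the
accessibility of a nearby region.  Candidate loci arrive with posterior
probabilities pi_l (locus is a caQTL) and pi_s (the SNP is the causal
variant given the locus is a caQTL); loci passing pi_l > 0.99 and
pi_s > 0.99 (strict) are scored by predicting accessibility on every phased
haplotype of a panel and contrasting the two allele groups of the causal
SNP: the predicted effect is the difference in median open probability
between alternate- and reference-allele haplotypes, per cell type.

Predicted effects are compared with observed allelic imbalance — the
fraction of accessibility reads carrying the alternate allele at
heterozygous sites — via Pearson correlation of the effect against the
imbalance fraction centered at 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import FocalSNP, GenomicInterval, HaplotypeSet, one_hot
from .labeling import CELL_TYPES
from .model import OrbWeaverNet

log = logging.getLogger("orbweaver")


class VariantError(ValueError):
    pass


@dataclass
class CausalLocus:
    locus: GenomicInterval
    snp: FocalSNP
    pi_l: float  # P(locus is a caQTL)
    pi_s: float  # P(SNP is causal | locus is a caQTL)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi_l <= 1.0 and 0.0 <= self.pi_s <= 1.0):
            raise VariantError(
                f"posteriors must lie in [0, 1]: pi_l={self.pi_l}, pi_s={self.pi_s}"
            )


@dataclass
class VariantEffect:
    snp: FocalSNP
    delta_median: dict  # cell type -> median(alt preds) - median(ref preds)
    n_ref: int
    n_alt: int


@dataclass
class ImbalanceRecord:
    snp_id: str
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise VariantError("allele counts must be non-negative")
        if self.ref_count + self.alt_count == 0:
            raise VariantError(f"no reads at SNP {self.snp_id}")

    @property
    def fraction(self) -> float:
        """Fraction of accessibility signal from the alternate allele."""
        return self.alt_count / (self.ref_count + self.alt_count)


@dataclass
class CorrelationReport:
    r: float | None
    p_value: float | None
    n: int
    method: str
    table: pd.DataFrame


def read_causal_tsv(path: str) -> list[CausalLocus]:
    """Input TSV: chrom, pos (1-based), ref, alt, pi_l, pi_s."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "ref", "alt", "pi_l", "pi_s"}
    if not required <= set(df.columns):
        raise VariantError(f"causal TSV must have columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        pos0 = int(row.pos) - 1
        snp = FocalSNP(str(row.chrom), pos0, str(row.ref), str(row.alt))
        locus = GenomicInterval(snp.chrom, max(0, pos0 - 250), pos0 + 250)
        out.append(CausalLocus(locus, snp, float(row.pi_l), float(row.pi_s)))
    return out


def read_imbalance_tsv(path: str) -> list[ImbalanceRecord]:
    """Input TSV: snp, ref_count, alt_count."""
    df = pd.read_csv(path, sep="\t")
    return [
        ImbalanceRecord(str(r.snp), int(r.ref_count), int(r.alt_count))
        for r in df.itertuples(index=False)
    ]


def select_causal(
    candidates: list[CausalLocus], threshold: float = 0.99
) -> list[CausalLocus]:
    """Keep loci with pi_l > threshold AND pi_s > threshold (strict)."""
    kept = [c for c in candidates if c.pi_l > threshold and c.pi_s > threshold]
    dropped = len(candidates) - len(kept)
    if dropped:
        log.info("select_causal: dropped %d of %d candidates", dropped, len(candidates))
    if not kept:
        log.warning("select_causal: no candidates passed the %.2f threshold", threshold)
    return kept


def haplotype_effect(
    net: OrbWeaverNet,
    hapset: HaplotypeSet,
    cell_types: tuple[str, ...] = CELL_TYPES,
) -> VariantEffect:
    """Median allele-group difference of predicted open probability.

    For each requested cell type: median of the model's open probability
    over alternate-allele haplotypes minus the median over reference-allele
    haplotypes.  Identical haplotype sequences are scored once (the model is
    deterministic).  Antisymmetric under swapping the allele labels.
    """
    ref_haps, alt_haps = hapset.allele_groups()
    if not ref_haps or not alt_haps:
        raise VariantError(
            f"monomorphic focal SNP {hapset.focal_snp.chrom}:"
            f"{hapset.focal_snp.pos}: n_ref={len(ref_haps)}, n_alt={len(alt_haps)}"
        )
    unique_seqs = sorted({h.sequence for h in hapset.haplotypes})
    X = np.stack([one_hot(s) for s in unique_seqs])
    p = net.predict_open(X)  # (n_unique, 3)
    pred_by_seq = {s: p[i] for i, s in enumerate(unique_seqs)}

    delta = {}
    for t in cell_types:
        ti = CELL_TYPES.index(t)
        ref_p = np.array([pred_by_seq[h.sequence][ti] for h in ref_haps])
        alt_p = np.array([pred_by_seq[h.sequence][ti] for h in alt_haps])
        delta[t] = float(np.median(alt_p) - np.median(ref_p))
    return VariantEffect(
        snp=hapset.focal_snp,
        delta_median=delta,
        n_ref=len(ref_haps),
        n_alt=len(alt_haps),
    )


def compare_to_imbalance(
    effects: list[VariantEffect],
    effect_ids: list[str],
    observed: list[ImbalanceRecord],
    cell_type: str,
    method: str = "pearson",
    transform: str = "centered",
) -> CorrelationReport:
    """Correlate predicted allele effects with observed allelic imbalance.

    ``transform`` maps the observed alt-allele fraction q to the compared
    value: ``centered`` (q - 0.5, default), ``raw`` (q) or ``logit``.
    Unmatched SNPs are dropped with a logged count; fewer than 3 matches or
    zero variance makes the correlation undefined (r = None).
    """
    obs_by_id = {o.snp_id: o for o in observed}
    xs, ys, rows = [], [], []
    for eff, sid in zip(effects, effect_ids):
        rec = obs_by_id.get(sid)
        if rec is None:
            continue
        q = rec.fraction
        if transform == "centered":
            yv = q - 0.5
        elif transform == "raw":
            yv = q
        elif transform == "logit":
            q = min(max(q, 1e-6), 1 - 1e-6)
            yv = float(np.log(q / (1 - q)))
        else:
            raise VariantError(f"unknown transform {transform!r}")
        xs.append(eff.delta_median[cell_type])
        ys.append(yv)
        rows.append({"snp": sid, "delta_median": xs[-1], "observed": yv})
    dropped = len(effects) - len(xs)
    if dropped:
        log.info("compare_to_imbalance: %d effects without observed imbalance", dropped)
    table = pd.DataFrame(rows, columns=["snp", "delta_median", "observed"])
    if len(xs) < 3:
        raise VariantError(f"need >= 3 matched SNPs, got {len(xs)}")
    xs, ys = np.array(xs), np.array(ys)
    if xs.std() == 0 or ys.std() == 0:
        log.warning("zero variance; correlation undefined")
        return CorrelationReport(None, None, len(xs), method, table)
    if method == "pearson":
        r, p = stats.pearsonr(xs, ys)
    elif method == "spearman":
        r, p = stats.spearmanr(xs, ys)
    else:
        raise VariantError(f"unknown method {method!r}")
    return CorrelationReport(float(r), float(p), len(xs), method, table)
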