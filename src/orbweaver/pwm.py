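"""Transcription-factor PWMs and the fixed convolutional filter bank.

A position weight matrix (PWM) gives, for each position of a TF's binding
site, the probability of observing each base (columns ordered A, C, G, T).
PWMs enter the network as the *frozen* first convolutional layer: each matrix
is converted to log2-odds against a background base composition, zero-padded
to a common width, and optionally paired with its reverse complement so that
binding on either strand is scored.

Forward-strand filters are padded on the right and reverse-complement filters
on the left.  With that convention the set of valid scan offsets maps onto
itself under reverse-complementing the sequence (offset i <-> L - Wmax - i),
so the per-TF maximum over positions is exactly strand-symmetric even when
filter widths differ.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as bio_motifs

BASES = "ACGT"
UNIFORM_BACKGROUND = np.full(4, 0.25)

# complement under column order A,C,G,T is a reversal of the columns
_RC_COLS = np.array([3, 2, 1, 0])


class PWMError(ValueError):
    """Malformed or invalid PWM input."""


@dataclass
class PWM:
    """A TF binding model: a width-W x 4 matrix of base probabilities."""

    tf_id: str
    tf_name: str
    matrix: np.ndarray  # (W, 4), rows sum to 1
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise PWMError(
                f"PWM {self.tf_id!r}: matrix must be W x 4, got {self.matrix.shape}"
            )
        if self.width < 1:
            raise PWMError(f"PWM {self.tf_id!r}: empty matrix")
        if np.any(self.matrix < 0):
            raise PWMError(f"PWM {self.tf_id!r}: negative probabilities")
        rowsums = self.matrix.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-6):
            raise PWMError(
                f"PWM {self.tf_id!r}: rows must sum to 1 (got {rowsums})"
            )

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[b] for b in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            tf_id=self.tf_id,
            tf_name=self.tf_name,
            matrix=self.matrix[::-1, _RC_COLS],
            source=self.source,
        )


def _normalize_counts(counts: np.ndarray, tf_id: str, pseudocount: float) -> np.ndarray:
    counts = np.asarray(counts, dtype=float) + pseudocount
    rowsums = counts.sum(axis=1, keepdims=True)
    if np.any(rowsums <= 0):
        bad = int(np.nonzero(rowsums.ravel() <= 0)[0][0])
        raise PWMError(f"PWM {tf_id!r}: zero-sum count row at position {bad}")
    return counts / rowsums


def read_pwms(path: str, dialect: str, pseudocount: float = 0.0) -> list[PWM]:
    """Read PWMs from ``path`` in one of the supported motif dialects.

    Parameters
    ----------
    path:
        Motif file.
    dialect:
        ``"meme"`` (MEME minimal text), ``"jaspar"`` (raw count blocks /
        ``.pfm``), or ``"transfac"`` (count-matrix blocks).
    pseudocount:
        Added to every count before row-normalization (count dialects only;
        MEME records already carry probabilities).

    Count matrices are converted to probabilities as (c + pseudocount) /
    sum(c + pseudocount) per position.  tf_ids duplicated within a file are
    disambiguated by suffixing the dialect name and an ordinal.
    """
    dialect = dialect.lower()
    fmt = {"meme": "minimal", "jaspar": "jaspar", "transfac": "transfac"}.get(dialect)
    if fmt is None:
        raise PWMError(f"unsupported dialect {dialect!r}")
    with open(path) as handle:
        text = handle.read()
    try:
        records = list(bio_motifs.parse(io.StringIO(text), fmt))
    except Exception as exc:  # Bio.motifs raises bare ValueError/KeyError
        if dialect == "jaspar":
            # raw .pfm count block (4 unlabeled rows, no header)
            try:
                records = list(bio_motifs.parse(io.StringIO(text), "pfm"))
            except Exception:
                raise PWMError(
                    f"{path}: malformed jaspar/pfm motif file: {exc}"
                ) from exc
        else:
            raise PWMError(f"{path}: malformed {dialect} motif file: {exc}") from exc
    if not records:
        raise PWMError(f"{path}: no motifs found ({dialect})")
    if dialect == "meme":
        # Bio's minimal parser truncates at a malformed matrix row; compare
        # each motif's parsed width against its declared "w=" to catch that.
        import re

        declared = [int(m.group(1)) for m in re.finditer(r"\bw=\s*(\d+)", text)]
        widths = [m.length for m in records]
        for i, (d, w) in enumerate(zip(declared, widths)):
            if d != w:
                raise PWMError(
                    f"{path}: malformed matrix row in MOTIF #{i + 1} "
                    f"({records[i].name!r}): declared w={d}, parsed {w} rows"
                )

    pwms: list[PWM] = []
    seen: dict[str, int] = {}
    for i, mot in enumerate(records):
        if dialect == "transfac":
            tf_id = mot.get("ID") or mot.get("AC") or mot.name or f"motif_{i}"
        else:
            tf_id = getattr(mot, "matrix_id", None) or mot.name or f"motif_{i}"
        tf_name = mot.name or tf_id
        if tf_id in seen:
            seen[tf_id] += 1
            tf_id = f"{tf_id}_{dialect}{seen[tf_id]}"
        else:
            seen[tf_id] = 0
        raw = np.array([mot.counts[b] for b in BASES], dtype=float).T  # (W, 4)
        if dialect == "meme":
            # probabilities; renormalize to absorb printed rounding
            rowsums = raw.sum(axis=1, keepdims=True)
            if np.any(rowsums <= 0):
                raise PWMError(f"PWM {tf_id!r}: zero-sum probability row")
            matrix = raw / rowsums
        else:
            matrix = _normalize_counts(raw, tf_id, pseudocount)
        pwms.append(PWM(tf_id=tf_id, tf_name=tf_name, matrix=matrix, source=dialect))
    return pwms


def log_transform(
    pwm: PWM,
    background: np.ndarray | None = None,
    pseudocount: float = 1e-3,
) -> np.ndarray:
    """Log2-odds weights: entry (w, b) = log2((p_wb + pc) / (bg_b + pc)).

    The pseudocount keeps weights finite for zero probabilities.  With a
    uniform background and a uniform PWM the result is exactly zero.
    """
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if bg.shape != (4,) or np.any(bg <= 0):
        raise PWMError("background must be a positive 4-vector")
    if not np.isclose(bg.sum(), 1.0, atol=1e-6):
        raise PWMError(f"background must sum to 1 (got {bg.sum()})")
    if pseudocount <= 0:
        raise PWMError("pseudocount must be > 0")
    weights = np.log2((pwm.matrix + pseudocount) / (bg[None, :] + pseudocount))
    if not np.all(np.isfinite(weights)):
        raise PWMError(f"PWM {pwm.tf_id!r}: non-finite log weights")
    return weights


@dataclass
class FilterBank:
    """Log-transformed, width-padded PWM filters for the frozen conv layer.

    ``filters_fwd[f]`` is the (Wmax, 4) forward-strand filter of TF f,
    zero-padded on the right; ``filters_rc[f]`` (rc_max policy only) is the
    reverse complement, zero-padded on the left.  Scan scores take the
    positionwise max of the two strands.
    """

    filters_fwd: np.ndarray  # (F, Wmax, 4)
    filters_rc: np.ndarray | None  # (F, Wmax, 4) or None under forward_only
    tf_ids: list[str]
    widths: np.ndarray  # (F,) true motif widths
    strand_policy: str = "rc_max"
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudocount: float = 1e-3

    @property
    def n_filters(self) -> int:
        return self.filters_fwd.shape[0]

    @property
    def max_width(self) -> int:
        return self.filters_fwd.shape[1]

    @property
    def tf_index(self) -> dict[str, int]:
        return {tf: i for i, tf in enumerate(self.tf_ids)}

    def checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.filters_fwd).tobytes())
        if self.filters_rc is not None:
            h.update(np.ascontiguousarray(self.filters_rc).tobytes())
        return h.hexdigest()

    def scan(self, onehot: np.ndarray) -> np.ndarray:
        """Score a (L, 4) one-hot sequence: (L - Wmax + 1, F) strand-maxed."""
        return scan_batch(self, onehot[None])[0]


def scan_batch(bank: FilterBank, onehot: np.ndarray) -> np.ndarray:
    """Pre-activation scores of the frozen layer for (B, L, 4) inputs.

    Returns (B, P, F) with P = L - Wmax + 1; under rc_max the positionwise
    max of the forward and reverse-complement filter scores.
    """
    onehot = np.asarray(onehot, dtype=np.float64)
    B, L, _ = onehot.shape
    W = bank.max_width
    if L < W:
        raise PWMError(f"sequence length {L} shorter than filter width {W}")
    windows = np.lib.stride_tricks.sliding_window_view(onehot, (W, 4), axis=(1, 2))
    # windows: (B, P, 1, W, 4)
    windows = windows.reshape(B, L - W + 1, W * 4)
    flat_fwd = bank.filters_fwd.reshape(bank.n_filters, W * 4).T
    scores = windows @ flat_fwd
    if bank.strand_policy == "rc_max" and bank.filters_rc is not None:
        flat_rc = bank.filters_rc.reshape(bank.n_filters, W * 4).T
        np.maximum(scores, windows @ flat_rc, out=scores)
    return scores


def build_filter_bank(
    pwms: list[PWM],
    strand_policy: str = "rc_max",
    background: np.ndarray | None = None,
    pseudocount: float = 1e-3,
) -> FilterBank:
    """Log-transform and pad PWMs into the frozen first-layer filter tensor."""
    if not pwms:
        raise PWMError("cannot build a filter bank from an empty PWM list")
    if strand_policy not in ("rc_max", "forward_only"):
        raise PWMError(f"unknown strand_policy {strand_policy!r}")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)

    seen: dict[str, int] = {}
    tf_ids = []
    for p in pwms:
        tf_id = p.tf_id
        if tf_id in seen:
            seen[tf_id] += 1
            tf_id = f"{tf_id}_{p.source}{seen[p.tf_id]}"
        else:
            seen[tf_id] = 0
        tf_ids.append(tf_id)

    widths = np.array([p.width for p in pwms])
    wmax = int(widths.max())
    F = len(pwms)
    fwd = np.zeros((F, wmax, 4))
    rc = np.zeros((F, wmax, 4)) if strand_policy == "rc_max" else None
    for i, p in enumerate(pwms):
        w = log_transform(p, bg, pseudocount)
        fwd[i, : p.width] = w
        if rc is not None:
            # left-pad: keeps strand-max scan offsets mirror-symmetric
            rc[i, wmax - p.width :] = log_transform(p.reverse_complement(), bg, pseudocount)
    return FilterBank(
        filters_fwd=fwd,
        filters_rc=rc,
        tf_ids=tf_ids,
        widths=widths,
        strand_policy=strand_policy,
        background=bg,
        pseudocount=pseudocount,
    )


def pwm_scan(onehot: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Sliding-window dot product of one filter over a one-hot sequence.

    Plain-loop reference used as the oracle for conv-layer equivalence;
    returns scores at offsets 0 .. L - W.
    """
    onehot = np.asarray(onehot, dtype=float)
    filt = np.asarray(filt, dtype=float)
    L, W = onehot.shape[0], filt.shape[0]
    if L < W:
        raise PWMError(f"sequence length {L} < filter width {W}")
    return np.array([float(np.sum(onehot[i : i + W] * filt)) for i in range(L - W + 1)])
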