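"""Attribution: DeepLIFT scores over the frozen TF filters, key-TF calls,
and saturation in-silico mutagenesis.

DeepLIFT assigns each unit a contribution relative to its activation on a
*reference* input, such that contributions sum exactly to the difference in
the target output between the actual and reference inputs
(summation-to-delta).  Multipliers are propagated from the target output
down to the post-ReLU activations of the frozen PWM layer, giving a score
for every TF at every scan position of a locus:

* linear layers: the multiplier is carried through the transposed weights;
* ReLU / sigmoid: the Rescale rule, m = (f(x) - f(ref)) / (x - ref)
  (zero when the input delta is zero — the output delta is then zero too);
* max-pooling: the window's output delta is distributed over input deltas
  proportionally to delta_i^2, which preserves summation-to-delta exactly
  and stays bounded (a winner-takes-all rule loses completeness whenever the
  argmax differs between input and reference).

The default reference is a window of background base frequencies ("no
sequence information"); all-zero and shuffled-sequence references are
available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import OneHotWindow
from .labeling import CELL_TYPES, categories_containing
from .model import OrbWeaverNet, Prediction, _sigmoid

log = logging.getLogger("orbweaver")


class InterpretError(ValueError):
    pass


@dataclass
class ImportanceProfile:
    """Per-TF, per-scan-position contributions for one locus."""

    scores: np.ndarray  # (T, P) TF x scan position
    tf_ids: list[str]
    target: int | str  # category 1..7 or a cell-type name
    reference_spec: str
    delta_output: float  # f(x) - f(reference)


@dataclass
class KeyTFAssignment:
    tf_id: str | None  # None when no TF has positive aggregate score
    score: float


@dataclass
class MutagenesisMap:
    """Delta-prediction for every single-base substitution in a window."""

    delta: np.ndarray  # (width, 4)
    target: int | str
    base_value: float  # f of the unmutated window


def _target_output_indices(target: int | str) -> np.ndarray:
    """Output units summed to form the scalar attribution target."""
    if isinstance(target, str):
        if target not in CELL_TYPES:
            raise InterpretError(f"unknown cell type {target!r}")
        return np.array(categories_containing(target)) - 1
    if not 1 <= int(target) <= 7:
        raise InterpretError(f"category target must be in 1..7, got {target}")
    return np.array([int(target) - 1])


def _target_value(scores: np.ndarray, target: int | str) -> np.ndarray:
    """f(x): the targeted category score, or the summed open-category score
    for a cell type (the unnormalized open signal)."""
    idx = _target_output_indices(target)
    return np.atleast_2d(scores)[:, idx].sum(axis=1)


def make_reference(
    window: OneHotWindow | np.ndarray,
    spec: str = "background_freq",
    background: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    matrix = window.matrix if isinstance(window, OneHotWindow) else np.asarray(window)
    if spec == "background_freq":
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return np.tile(bg, (matrix.shape[0], 1)).astype(np.float32)
    if spec == "zeros":
        return np.zeros_like(matrix, dtype=np.float32)
    if spec == "shuffled":
        rng = np.random.default_rng(seed)
        return matrix[rng.permutation(matrix.shape[0])].astype(np.float32)
    raise InterpretError(f"unknown reference spec {spec!r}")


def _rescale(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Elementwise Rescale multiplier dy/dx with 0 where dx == 0."""
    out = np.zeros_like(dy)
    nz = dx != 0
    out[nz] = dy[nz] / dx[nz]
    return out


def _distribute_pool(m_out: np.ndarray, dy: np.ndarray, dx: np.ndarray) -> np.ndarray:
    """Multipliers for a max-pool window: share m_out * dy over input deltas
    in proportion to dx_i^2 (exact conservation: sum m_i dx_i = m_out dy).

    ``dx`` carries the pooled positions on its LAST axis; ``m_out`` and
    ``dy`` have that axis absent.  When all input deltas vanish the output
    delta vanishes too and the multipliers are zero.
    """
    denom = np.sum(dx * dx, axis=-1, keepdims=True)
    weight = np.divide(dx, denom, out=np.zeros_like(dx), where=denom > 0)
    return (m_out * dy)[..., None] * weight


def deeplift_scores(
    net: OrbWeaverNet,
    window: OneHotWindow | np.ndarray,
    target: int | str,
    reference_spec: str = "background_freq",
    reference: np.ndarray | None = None,
) -> ImportanceProfile:
    """Contributions of every (TF, scan position) to the targeted output.

    Satisfies summation-to-delta: ``profile.scores.sum()`` equals
    f(window) - f(reference) for the targeted output.
    """
    matrix = window.matrix if isinstance(window, OneHotWindow) else np.asarray(window)
    if reference is None:
        reference = make_reference(matrix, reference_spec, net.bank.background)
    X = np.stack([matrix, reference]).astype(np.float32)
    _, cache = net.forward_batch(X, return_cache=True)
    cfg = net.config

    def dpair(key):  # delta = actual - reference, keeping a batch axis of 1
        return (cache[key][0] - cache[key][1])[None]

    idx = _target_output_indices(target)
    f_x = float(_target_value(cache["s"][0], target)[0])
    f_ref = float(_target_value(cache["s"][1], target)[0])
    delta_out = f_x - f_ref

    # output head
    dz = dpair("z")
    if cfg.output_head == "sigmoid":
        m_z = np.zeros_like(dz)
        ds = dpair("s")
        m_z[:, idx] = _rescale(dz[:, idx], ds[:, idx])
    else:
        # softmax couples all logits; distribute the target-probability delta
        # over all logit deltas (conservative rescale across units)
        m_z = _distribute_pool(
            np.ones(1), np.array([delta_out]), dz
        )

    if delta_out == 0.0 and not np.any(dz):
        log.warning("dead attribution target: zero delta everywhere")

    # dense output layer (linear)
    m_h = m_z @ net.params["Wo"].T
    m_hpre = m_h * _rescale(dpair("hpre"), dpair("h"))
    # dense layer (linear)
    m_g = m_hpre @ net.params["Wd"].T  # (1, K)
    # global max-pool over conv2 positions (pooled axis moved last)
    m_a2 = _distribute_pool(
        m_g, dpair("g"), dpair("a2").swapaxes(1, 2)
    ).swapaxes(1, 2)  # (1, P3, K)
    m_z2 = m_a2 * _rescale(dpair("z2"), dpair("a2"))
    # learnable convolution (linear): transpose conv back to pooled features
    T = net.bank.n_filters
    W2 = net.params["W2"].reshape(cfg.conv2_width, T, -1)  # (w2, T, K)
    m_pooled = np.zeros((1, net.p2, T))
    for w in range(cfg.conv2_width):
        m_pooled[:, w : w + net.p3] += np.einsum("bpk,tk->bpt", m_z2, W2[w])
    # first max-pool over frozen-layer positions
    d_pooled = dpair("pooled")  # (1, p2, T)
    a1_d = dpair("a1_full")[0]  # (P1, T)
    used = net.p2 * cfg.pool1_width
    dx = a1_d[:used].reshape(net.p2, cfg.pool1_width, T)
    dx = np.transpose(dx, (0, 2, 1))[None]  # (1, p2, T, pool)
    m_win = _distribute_pool(m_pooled, d_pooled, dx)  # (1, p2, T, pool)
    m_a1 = np.zeros_like(a1_d)
    m_a1[:used] = np.transpose(m_win[0], (0, 2, 1)).reshape(used, T)

    contributions = (m_a1 * a1_d).T  # (T, P1)
    return ImportanceProfile(
        scores=contributions,
        tf_ids=list(net.bank.tf_ids),
        target=target,
        reference_spec="custom" if reference_spec is None else reference_spec,
        delta_output=delta_out,
    )


def key_tf(profile: ImportanceProfile, aggregate: str = "sum_positive") -> KeyTFAssignment:
    """The TF with the highest aggregate contribution for a locus.

    Default aggregation sums positive contributions over positions
    (``aggregate="max"`` takes the positionwise maximum instead).  Exact ties
    break lexicographically by tf_id; if no TF aggregates above zero a
    none-sentinel is returned.
    """
    if aggregate == "sum_positive":
        agg = np.where(profile.scores > 0, profile.scores, 0.0).sum(axis=1)
    elif aggregate == "max":
        agg = profile.scores.max(axis=1)
    else:
        raise InterpretError(f"unknown aggregation {aggregate!r}")
    if np.all(agg <= 0):
        log.warning("no TF with positive aggregate contribution")
        return KeyTFAssignment(tf_id=None, score=float(agg.max()))
    best = agg.max()
    tied = [profile.tf_ids[i] for i in np.nonzero(agg == best)[0]]
    if len(tied) > 1:
        log.info("key-TF tie between %s; keeping %s", tied, min(tied))
    return KeyTFAssignment(tf_id=min(tied), score=float(best))


def aggregate_key_tfs(
    categories_true: np.ndarray,
    predictions: list[Prediction] | np.ndarray,
    assignments: list[KeyTFAssignment],
) -> pd.DataFrame:
    """Fraction of each category's loci explained by each key TF.

    Only loci whose predicted category matches the true category enter the
    denominators; none-sentinel assignments are excluded from the numerators
    (so fractions per category sum to <= 1).
    """
    cats_true = np.asarray(categories_true, dtype=int)
    if isinstance(predictions, np.ndarray):
        cats_pred = np.asarray(predictions, dtype=int)
    else:
        cats_pred = np.array([p.category for p in predictions])
    if not (len(cats_true) == len(cats_pred) == len(assignments)):
        raise InterpretError("loci, predictions and assignments must align")

    rows = []
    for o in range(1, 8):
        correct = np.nonzero((cats_true == o) & (cats_pred == o))[0]
        if len(correct) == 0:
            if np.any(cats_true == o):
                log.warning("category %d: no correctly predicted loci; omitted", o)
            continue
        counts: dict[str, int] = {}
        for i in correct:
            tf = assignments[i].tf_id
            if tf is not None:
                counts[tf] = counts.get(tf, 0) + 1
        for tf, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append(
                {"category": o, "tf_id": tf, "n_loci": c,
                 "fraction": c / len(correct)}
            )
    return pd.DataFrame(rows, columns=["category", "tf_id", "n_loci", "fraction"])


def saturation_mutagenesis(
    net: OrbWeaverNet,
    window: OneHotWindow | np.ndarray,
    target: int | str,
    batch: int = 512,
) -> MutagenesisMap:
    """Delta-prediction of every single-base substitution in the window.

    delta[p, b] = f(window with position p set to base b) - f(window); the
    entry at the window's own base is exactly zero.  Masked (all-zero) rows
    are mutated against the zero row like any other.
    """
    matrix = window.matrix if isinstance(window, OneHotWindow) else np.asarray(window)
    width = matrix.shape[0]
    base = float(_target_value(net.forward_batch(matrix[None].astype(np.float32)), target)[0])

    muts = []
    coords = []
    eye = np.eye(4, dtype=np.float32)
    for p in range(width):
        for b in range(4):
            if matrix[p, b] == 1.0:
                continue  # identity mutation: delta is 0 by definition
            m = matrix.copy()
            m[p] = eye[b]
            muts.append(m)
            coords.append((p, b))
    delta = np.zeros((width, 4))
    muts = np.asarray(muts, dtype=np.float32)
    for i in range(0, len(muts), batch):
        vals = _target_value(net.forward_batch(muts[i : i + batch]), target)
        for (p, b), v in zip(coords[i : i + batch], vals):
            delta[p, b] = v - base
    return MutagenesisMap(delta=delta, target=target, base_value=base)


def mutagenesis_to_frame(locus_id: str, mmap: MutagenesisMap) -> pd.DataFrame:
    """Long-format (locus, pos, base, delta) table for one map."""
    width = mmap.delta.shape[0]
    return pd.DataFrame(
        {
            "locus": locus_id,
            "pos": np.repeat(np.arange(width), 4),
            "base": list("ACGT") * width,
            "delta": mmap.delta.ravel(),
        }
    )
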