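"""Inference of motif-motif interactions from self-attention maps.

Pipeline, per interpreted sequence: combine attention heads by an
elementwise maximum; keep position pairs whose attention exceeds the
per-sequence mean; translate attended positions into the convolutional
filters active there; pool the resulting filter-pair scores over sequences.
Foreground scores (correctly predicted positives) are compared with
background scores (correctly predicted negatives, or dinucleotide-shuffled
sequences for multi-label tasks) by a one-sided Mann-Whitney U test with
Benjamini-Hochberg correction, and significant filter pairs are mapped to
motif names via filter annotation.

Scores can be raw attention values or attention attributions — integrated
gradients of the classifier output with respect to the attention matrices
along a straight path from the zero matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .model import SequenceModel, encode_batch
from .motifs import FilterAnnotation, MotifLibrary, filter_to_pwm, match_pwms
from .nn import Tensor
from .simulate import LabeledSequenceSet

logger = logging.getLogger(__name__)

Pair = tuple[int, int]

#: fraction of a filter's maximum activation that counts as "active"
ACTIVATION_FRACTION = 0.65
#: fraction of the maximum PSSM score used with pre-loaded filters
PRELOADED_FRACTION = 0.5


# ---------------------------------------------------------------------------
# Attention-map plumbing
# ---------------------------------------------------------------------------

def combine_heads(maps: np.ndarray) -> np.ndarray:
    """Elementwise maximum across heads: (h, n, n) -> (n, n)."""
    maps = np.asarray(maps)
    if maps.ndim != 3:
        raise ValueError("expected (h, n, n) attention maps")
    return maps.max(axis=0)


def select_candidates(matrix: np.ndarray,
                      threshold_mode: str = "mean"
                      ) -> list[tuple[int, int, float]]:
    """Unordered off-diagonal position pairs scoring above the per-matrix
    mean.  The pair score is the larger of the two directions, and a pair is
    kept only when that larger value strictly exceeds the mean."""
    if threshold_mode != "mean":
        raise ValueError(f"unknown threshold mode {threshold_mode!r}")
    m = np.asarray(matrix)
    if not np.all(np.isfinite(m)):
        raise ValueError("attention matrix contains non-finite values")
    cutoff = m.mean()
    sym = np.maximum(m, m.T)
    iu, ju = np.triu_indices(m.shape[0], k=1)
    keep = sym[iu, ju] > cutoff
    return [(int(i), int(j), float(s))
            for i, j, s in zip(iu[keep], ju[keep], sym[iu, ju][keep])]


def positions_to_filters(candidates: list[tuple[int, int, float]],
                         conv_activations: np.ndarray,
                         filter_max: np.ndarray,
                         activation_fraction: float = ACTIVATION_FRACTION
                         ) -> dict[Pair, float]:
    """Translate attended position pairs into filter pairs.

    ``conv_activations`` is the (F, n) pooled activation matrix of one
    sequence; ``filter_max`` the per-filter reference maximum (dataset-wide
    maximum for trained filters, maximum possible PSSM score for pre-loaded
    ones).  A filter is active at a position when its activation is at least
    ``activation_fraction`` of its reference maximum.  Each candidate
    contributes all cross products of active filters at its two ends;
    self-pairs are dropped; per sequence, a filter pair keeps its best
    score.
    """
    thresh = activation_fraction * filter_max
    usable = filter_max > 0
    act = (conv_activations >= thresh[:, None]) & usable[:, None] \
        & (conv_activations > 0)
    pairs: dict[Pair, float] = {}
    for i, j, score in candidates:
        fi = np.flatnonzero(act[:, i])
        fj = np.flatnonzero(act[:, j])
        if fi.size == 0 or fj.size == 0:
            logger.debug("no active filter at positions (%d, %d)", i, j)
            continue
        for a in fi:
            for b in fj:
                if a == b:
                    continue
                key = (int(min(a, b)), int(max(a, b)))
                if score > pairs.get(key, -np.inf):
                    pairs[key] = score
    return pairs


# ---------------------------------------------------------------------------
# Attribution
# ---------------------------------------------------------------------------

def attention_attribution(model: SequenceModel, sequences: list[str],
                          m: int = 20, targets: np.ndarray | None = None,
                          batch_size: int = 64) -> np.ndarray:
    """Integrated-gradients attribution of attention maps, zero baseline.

    Attr(A^(k)) = (A^(k)/m) ⊙ Σ_{t=1..m} ∂F((t/m)·A)/∂A^(k), where F is the
    logit of the predicted class (binary) or of ``targets`` (per-sequence
    label indices for multi-label models).  Returns (B, h, n, n); the result
    is not row-stochastic.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    model.set_training(False)
    x_all = encode_batch(sequences) if not isinstance(sequences, np.ndarray) \
        else sequences
    out = model.forward(x_all)
    A = out.attention
    B = A.shape[0]
    if targets is None:
        if model.spec.n_outputs == 1:
            signs = np.where(out.predictions[:, 0] >= 0.5, 1.0, -1.0)
            sel = np.zeros(B, dtype=int)
        else:
            raise ValueError("targets required for multi-output models")
    else:
        targets = np.asarray(targets, dtype=int)
        signs = np.ones(B)
        sel = targets
    grad_sum = np.zeros_like(A)
    for lo in range(0, B, batch_size):
        hi = min(lo + batch_size, B)
        Ab = A[lo:hi]
        xb = x_all[lo:hi]
        for t in range(1, m + 1):
            leaf = Tensor((t / m) * Ab, requires_grad=True)
            logits, _, _ = model.forward_graph(xb, attn_override=leaf)
            picked = logits[np.arange(hi - lo), sel[lo:hi]]
            target = (picked * signs[lo:hi]).sum()
            target.backward()
            grad_sum[lo:hi] += leaf.grad
    return (A / m) * grad_sum


# ---------------------------------------------------------------------------
# Backgrounds
# ---------------------------------------------------------------------------

def dinuc_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Random shuffle preserving exact dinucleotide counts (random Eulerian
    walk on the de Bruijn multigraph of order 1)."""
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    if len(set(sequence)) == 1:
        return sequence
    edges: dict[str, list[str]] = {}
    for a, b in zip(sequence, sequence[1:]):
        edges.setdefault(a, []).append(b)
    start, end = sequence[0], sequence[-1]
    vertices = list(edges)
    for _ in range(1000):
        last = {}
        for v in vertices:
            if v == end and len(edges[v]) == 0:
                continue
            last[v] = edges[v][int(rng.integers(len(edges[v])))]
        # the chosen last edges must form a tree pointing toward `end`
        ok = True
        for v in vertices:
            if v == end:
                continue
            seen = {v}
            cur = v
            while cur != end:
                cur = last.get(cur)
                if cur is None or cur in seen or cur not in set(vertices) | {end}:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if not ok:
            continue
        # shuffle the remaining edges and append the designated last edge
        walk_edges: dict[str, list[str]] = {}
        for v in vertices:
            rest = list(edges[v])
            if v in last:
                rest.remove(last[v])
            order = rng.permutation(len(rest))
            walk_edges[v] = [rest[int(i)] for i in order]
            if v in last:
                walk_edges[v].append(last[v])
        out = [start]
        cur = start
        counters = {v: 0 for v in vertices}
        total = len(sequence) - 1
        for _ in range(total):
            nxt = walk_edges[cur][counters[cur]]
            counters[cur] += 1
            out.append(nxt)
            cur = nxt
        return "".join(out)
    raise RuntimeError("dinucleotide shuffle failed to converge")


# ---------------------------------------------------------------------------
# Scoring and testing
# ---------------------------------------------------------------------------

def collect_pair_scores(model: SequenceModel, sequences: list[str],
                        filter_max: np.ndarray, mode: str = "raw",
                        activation_fraction: float = ACTIVATION_FRACTION,
                        attribution_steps: int = 20,
                        batch_size: int = 256) -> dict[Pair, list[float]]:
    """Run the candidate pipeline (combine heads -> mean threshold -> map to
    filters) over a set of sequences and pool scores per filter pair."""
    if mode not in ("raw", "attribution"):
        raise ValueError(f"unknown mode {mode!r}")
    scores: dict[Pair, list[float]] = {}
    for lo in range(0, len(sequences), batch_size):
        chunk = sequences[lo:lo + batch_size]
        out = model.forward(chunk)
        if mode == "raw":
            maps = out.attention
        else:
            maps = attention_attribution(model, chunk,
                                         m=attribution_steps)
        for b in range(len(chunk)):
            combined = combine_heads(maps[b])
            cands = select_candidates(combined)
            pair_scores = positions_to_filters(
                cands, out.conv_activations[b], filter_max,
                activation_fraction)
            for pair, s in pair_scores.items():
                scores.setdefault(pair, []).append(s)
    return scores


def dataset_filter_max(model: SequenceModel, sequences: list[str],
                       batch_size: int = 256) -> np.ndarray:
    """Per-filter maximum pooled activation over a sequence set."""
    fmax = np.zeros(model.spec.n_filters)
    for lo in range(0, len(sequences), batch_size):
        out = model.forward(sequences[lo:lo + batch_size])
        fmax = np.maximum(fmax, out.conv_activations.max(axis=(0, 2)))
    return fmax


def preloaded_filter_max(model: SequenceModel) -> np.ndarray:
    """Maximum possible PSSM score per pre-loaded filter (best base at each
    kernel position)."""
    if model.spec.preloaded is None:
        raise ValueError("model has no pre-loaded filters")
    w = model.conv.w.data  # (F, 4, k) log-odds kernels, zero-padded
    return np.maximum(w.max(axis=1), 0).sum(axis=1)


def background_scores(model: SequenceModel,
                      background_set: list[str],
                      filter_max: np.ndarray, mode: str = "raw",
                      activation_fraction: float = ACTIVATION_FRACTION
                      ) -> dict[Pair, list[float]]:
    """Pair scores over a background sequence set (negative examples for
    binary tasks, dinucleotide-shuffled sequences for multi-label)."""
    if len(background_set) == 0:
        raise ValueError("empty background set")
    return collect_pair_scores(model, background_set, filter_max, mode,
                               activation_fraction)


def mann_whitney_p(fg, bg, exact_limit: int = 12) -> float:
    """One-sided Mann-Whitney U p-value for fg stochastically greater
    than bg.

    For small samples (n_fg + n_bg <= ``exact_limit``) the p-value is the
    exact permutation tail probability P(U >= U_obs) over all labelings of
    the pooled values (ties counted 1/2); larger samples use the
    tie-corrected normal approximation.
    """
    fg = np.asarray(fg, dtype=np.float64)
    bg = np.asarray(bg, dtype=np.float64)
    if fg.size == 0 or bg.size == 0:
        raise ValueError("both samples must be non-empty")
    n = fg.size + bg.size
    if np.ptp(np.concatenate([fg, bg])) == 0:
        return 1.0  # fully tied: no evidence of enrichment
    if n <= exact_limit:
        pooled = np.concatenate([fg, bg])
        u_obs = _u_stat(fg, bg)
        hits = total = 0
        for idx in combinations(range(n), fg.size):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            u = _u_stat(pooled[mask], pooled[~mask])
            hits += u >= u_obs - 1e-12
            total += 1
        assert total == comb(n, fg.size)
        return hits / total
    return float(mannwhitneyu(fg, bg, alternative="greater",
                              method="asymptotic").pvalue)


def _u_stat(a: np.ndarray, b: np.ndarray) -> float:
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def test_interactions(foreground: dict[Pair, list[float]],
                      background: dict[Pair, list[float]],
                      alpha: float = 0.05, min_support: int = 5,
                      keep_all: bool = False) -> pd.DataFrame:
    """Per-pair one-sided Mann-Whitney U tests with BH correction.

    Pairs with fewer than ``min_support`` foreground sequences are not
    tested.  A pair never seen in the background is compared against the
    pooled global background sample.  Returns rows with q <= ``alpha``
    unless ``keep_all``.
    """
    pooled_bg = np.sort(np.concatenate(
        [np.asarray(v) for v in background.values()])) \
        if background else np.array([])
    rows = []
    for pair in sorted(foreground):
        fg = np.asarray(foreground[pair])
        if fg.size < min_support:
            continue
        bg = np.asarray(background.get(pair, []))
        if bg.size == 0:
            if pooled_bg.size == 0:
                raise ValueError("empty background")
            bg = pooled_bg
        rows.append(dict(filter_a=pair[0], filter_b=pair[1],
                         n_support=int(fg.size),
                         median_fg_score=float(np.median(fg)),
                         p_value=mann_whitney_p(fg, bg)))
    table = pd.DataFrame(rows, columns=["filter_a", "filter_b", "n_support",
                                        "median_fg_score", "p_value"])
    if len(table):
        table["q_value"] = multipletests(table["p_value"],
                                         method="fdr_bh")[1]
    else:
        table["q_value"] = pd.Series(dtype=float)
    if not keep_all:
        table = table[table["q_value"] <= alpha].reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# Filter annotation
# ---------------------------------------------------------------------------

def annotate_filters(model: SequenceModel, sequences: list[str],
                     library: MotifLibrary,
                     activation_fraction: float = ACTIVATION_FRACTION,
                     min_sites: int = 10, max_sites: int = 1000,
                     match_threshold: float = 0.75,
                     batch_size: int = 256) -> list[FilterAnnotation]:
    """Map trained convolutional filters to library motifs.

    Scans the (pre-pool) convolution output over ``sequences``; substrings
    activating a filter above ``activation_fraction`` of its maximum build
    the filter's PWM, which is matched against the library.
    """
    if model.spec.preloaded is not None:
        return [FilterAnnotation(f, m.name, 1.0, 0)
                for f, m in enumerate(model.spec.preloaded)]
    from .nn import no_grad

    k = model.spec.filter_length
    left = (k - 1) // 2
    F = model.spec.n_filters
    acts = []
    for lo in range(0, len(sequences), batch_size):
        xb = encode_batch(sequences[lo:lo + batch_size])
        with no_grad():
            acts.append(model.conv(Tensor(xb)).relu().data)
    acts = np.concatenate(acts)  # (B, F, L)
    fmax = acts.max(axis=(0, 2))
    annotations = []
    for f in range(F):
        if fmax[f] <= 0:
            annotations.append(FilterAnnotation(f, None, 0.0, 0))
            continue
        b_idx, pos = np.nonzero(acts[:, f, :] >= activation_fraction * fmax[f])
        strength = acts[b_idx, f, pos]
        order = np.argsort(-strength)[:max_sites]
        sites = []
        for bi, p in zip(b_idx[order], pos[order]):
            start = p - left
            if start < 0 or start + k > len(sequences[bi]):
                continue
            sites.append(sequences[bi][start:start + k])
        pwm = filter_to_pwm(sites, name=f"filter{f}", min_sites=min_sites)
        if pwm is None:
            annotations.append(FilterAnnotation(f, None, 0.0, 0))
            continue
        annotations.append(match_pwms(pwm, library, threshold=match_threshold,
                                      filter_index=f))
    return annotations


# ---------------------------------------------------------------------------
# End-to-end inference
# ---------------------------------------------------------------------------

@dataclass
class InteractionResult:
    filter_table: pd.DataFrame
    motif_table: pd.DataFrame
    annotations: list[FilterAnnotation]
    n_foreground: int
    n_background: int

    @property
    def predicted_pairs(self) -> set[tuple[str, str]]:
        return {tuple(sorted((a, b)))
                for a, b in zip(self.motif_table["motif_a"],
                                self.motif_table["motif_b"])}


def infer_interactions(model: SequenceModel, test_set: LabeledSequenceSet,
                       library: MotifLibrary | None = None,
                       annotations: list[FilterAnnotation] | None = None,
                       mode: str = "raw",
                       background_policy: str = "negatives",
                       alpha: float = 0.05, min_support: int = 5,
                       activation_fraction: float | None = None,
                       attribution_steps: int = 20,
                       annotation_sequences: list[str] | None = None,
                       rng: np.random.Generator | int = 0
                       ) -> InteractionResult:
    """Full interaction-inference pipeline on a held-out set.

    Foreground = correctly predicted positive sequences; background =
    correctly predicted negatives (``background_policy="negatives"``) or
    dinucleotide-shuffled foreground sequences (``"shuffle"``, the
    multi-label setting).  Filter-level results are mapped to motif pairs
    via ``annotations`` (computed from ``library`` when absent),
    deduplicated per unordered motif pair keeping the smallest q.
    """
    if background_policy not in ("negatives", "shuffle"):
        raise ValueError(f"unknown background policy {background_policy!r}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    preloaded = model.spec.preloaded is not None
    if activation_fraction is None:
        activation_fraction = (PRELOADED_FRACTION if preloaded
                               else ACTIVATION_FRACTION)

    out = model.forward(test_set.sequences)
    if test_set.is_multilabel:
        foreground = list(test_set.sequences)
        background_policy = "shuffle"
    else:
        labels = np.asarray(test_set.labels).ravel()
        pred = (out.predictions[:, 0] >= 0.5).astype(int)
        # both sets are conditioned on correct prediction: a negative the
        # model scores as pair-containing is contaminated foreground from
        # the model's perspective and would bias the null upward exactly
        # for the true pairs
        fg_idx = np.flatnonzero((labels == 1) & (pred == 1))
        bg_idx = np.flatnonzero((labels == 0) & (pred == 0))
        if bg_idx.size == 0:
            logger.warning("no correctly predicted negatives; falling back "
                           "to all negatives as background")
            bg_idx = np.flatnonzero(labels == 0)
        foreground = [test_set.sequences[i] for i in fg_idx]
        if background_policy == "negatives":
            background = [test_set.sequences[i] for i in bg_idx]
    if background_policy == "shuffle":
        background = [dinuc_shuffle(s, rng) for s in foreground]
    if not foreground:
        raise ValueError("no correctly predicted positive sequences")

    if preloaded:
        fmax = preloaded_filter_max(model)
    else:
        fmax = dataset_filter_max(model, foreground + background)

    fg_scores = collect_pair_scores(model, foreground, fmax, mode,
                                    activation_fraction,
                                    attribution_steps=attribution_steps)
    bg_scores = background_scores(model, background, fmax, mode,
                                  activation_fraction)
    filter_table = test_interactions(fg_scores, bg_scores, alpha=alpha,
                                     min_support=min_support)

    if annotations is None:
        if library is None:
            raise ValueError("need a motif library or filter annotations")
        ann_seqs = annotation_sequences or foreground
        annotations = annotate_filters(model, ann_seqs, library,
                                       activation_fraction=ACTIVATION_FRACTION)
    by_index = {a.filter_index: a for a in annotations}

    motif_rows: dict[tuple[str, str], dict] = {}
    for row in filter_table.itertuples():
        na = by_index.get(row.filter_a)
        nb = by_index.get(row.filter_b)
        if na is None or nb is None or na.motif_name is None \
                or nb.motif_name is None:
            continue
        if na.motif_name == nb.motif_name:
            continue  # filter pair collapsing onto one motif
        key = tuple(sorted((na.motif_name, nb.motif_name)))
        rec = dict(motif_a=key[0], motif_b=key[1], filter_a=row.filter_a,
                   filter_b=row.filter_b, n_support=row.n_support,
                   median_fg_score=row.median_fg_score,
                   p_value=row.p_value, q_value=row.q_value)
        if key not in motif_rows or rec["q_value"] < motif_rows[key]["q_value"]:
            motif_rows[key] = rec
    motif_table = pd.DataFrame(
        list(motif_rows.values()),
        columns=["motif_a", "motif_b", "filter_a", "filter_b", "n_support",
                 "median_fg_score", "p_value", "q_value"])
    return InteractionResult(filter_table=filter_table,
                             motif_table=motif_table,
                             annotations=annotations,
                             n_foreground=len(foreground),
                             n_background=len(background))
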