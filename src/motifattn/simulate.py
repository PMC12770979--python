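"""Simulated regulatory sequences with implanted interacting motif pairs.

Positive sequences carry several motif *pairs* placed in close proximity
(each member sampled from its PWM at no less than half the maximum log-odds
score); negative sequences carry isolated motifs from the same pool, kept
far apart.  Class membership is therefore carried by motif *cooperation*,
not by motif presence — the property the attention-based interaction
inference is benchmarked against.  Every dataset ships with machine-readable
ground truth (the implanted pair list).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .motifs import MotifLibrary, PWM, reverse_complement, sample_site

logger = logging.getLogger(__name__)

#: approximate single-nucleotide frequencies of the human genome (A,C,G,T)
HUMAN_BACKGROUND = (0.295, 0.205, 0.205, 0.295)

ALPHABET = "ACGT"


class PlacementError(RuntimeError):
    """Raised internally when implants cannot be placed; the sequence is
    resampled."""


@dataclass
class SimulationConfig:
    n_sequences: int = 60_000
    seq_length: int = 300
    n_motifs: int = 25
    n_pairs: int = 60
    pairs_per_positive: tuple[int, int] = (3, 3)
    pair_gap: tuple[int, int] = (8, 15)
    neg_motifs_per_sequence: tuple[int, int] = (1, 3)
    neg_min_separation: int = 40
    background_freqs: tuple[float, float, float, float] = HUMAN_BACKGROUND
    site_min_fraction: float = 0.5
    random_strand: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.pair_gap[0] < 1:
            raise ValueError("pair_gap minimum must be >= 1")
        if self.neg_min_separation < self.pair_gap[1]:
            raise ValueError(
                "neg_min_separation must be >= the maximum pair gap, "
                "otherwise negatives can mimic positive pair spacing")
        if abs(sum(self.background_freqs) - 1.0) > 1e-6:
            raise ValueError("background_freqs must sum to 1")
        if self.n_sequences % 2:
            raise ValueError("n_sequences must be even (balanced classes)")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("pairs_per_positive", "pair_gap",
                    "neg_motifs_per_sequence", "background_freqs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


#: presets replicating the published simulation protocols.  The short
#: presets use 60 000 x 300 bp with exactly 3 implanted pairs per positive
#: and gaps of 8-15 bp; the long preset uses 1500 bp, 3-5 pairs per positive
#: and gaps of 8-80 bp with motifs drawn from distinct clusters.
_PRESETS: dict[str, dict] = {
    "data40": dict(n_motifs=20, n_pairs=40),
    "data60": dict(n_motifs=25, n_pairs=60),
    "data80": dict(n_motifs=30, n_pairs=80),
    "long": dict(n_motifs=40, n_pairs=80, seq_length=1500,
                 pairs_per_positive=(3, 5), pair_gap=(8, 80),
                 neg_min_separation=80),
}


def preset(name: str, **overrides) -> SimulationConfig:
    """Named simulation presets (``data40``, ``data60``, ``data80``,
    ``long``); keyword overrides allow scaled-down instances."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(_PRESETS)}")
    kwargs = dict(_PRESETS[name])
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@dataclass
class Implant:
    motif_name: str
    start: int  # 0-based
    strand: str
    site: str  # the text written into the sequence (already oriented)
    pair_id: int | None = None

    @property
    def end(self) -> int:  # half-open
        return self.start + len(self.site)


@dataclass
class GroundTruth:
    pairs: set[tuple[str, str]]  # unordered, stored name-sorted
    motif_pool: set[str]

    def __post_init__(self):
        self.pairs = {tuple(sorted(p)) for p in self.pairs}
        for a, b in self.pairs:
            if a not in self.motif_pool or b not in self.motif_pool:
                raise ValueError(f"pair ({a},{b}) outside the motif pool")

    def __contains__(self, pair) -> bool:
        return tuple(sorted(pair)) in self.pairs


@dataclass
class LabeledSequenceSet:
    ids: list[str]
    sequences: list[str]
    labels: np.ndarray  # (n,) for binary, (n, k) for multi-label
    implants: list[list[Implant]] = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("sequences must share a single length")
        if not self.implants:
            self.implants = [[] for _ in self.sequences]

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def seq_length(self) -> int:
        return len(self.sequences[0])

    @property
    def is_multilabel(self) -> bool:
        return self.labels.ndim == 2

    def subset(self, idx) -> "LabeledSequenceSet":
        idx = np.asarray(idx)
        return LabeledSequenceSet(
            [self.ids[i] for i in idx],
            [self.sequences[i] for i in idx],
            self.labels[idx],
            [self.implants[i] for i in idx])


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def select_interacting_pairs(lib: MotifLibrary, n_motifs: int, n_pairs: int,
                             rng: np.random.Generator) -> GroundTruth:
    """Pick ``n_motifs`` motifs uniformly without replacement, then
    ``n_pairs`` distinct unordered pairs among them.

    The pair set is resampled until every pool motif participates in at
    least one pair: the motif pool is defined as the set of *paired* TFs,
    so unpaired pool members would otherwise become pure negative-class
    markers and leak label information through single-motif occurrence.
    """
    if n_motifs > len(lib):
        raise ValueError(f"n_motifs {n_motifs} > library size {len(lib)}")
    max_pairs = n_motifs * (n_motifs - 1) // 2
    if n_pairs > max_pairs:
        raise ValueError(f"n_pairs {n_pairs} > C({n_motifs},2) = {max_pairs}")
    if 2 * n_pairs < n_motifs:
        raise ValueError(
            f"n_pairs {n_pairs} cannot cover {n_motifs} motifs")
    chosen = rng.choice(len(lib), size=n_motifs, replace=False)
    names = sorted(lib[int(i)].name for i in chosen)
    all_pairs = list(combinations(names, 2))
    for _ in range(10_000):
        picked = rng.choice(len(all_pairs), size=n_pairs, replace=False)
        pairs = {all_pairs[int(i)] for i in picked}
        if {m for p in pairs for m in p} == set(names):
            return GroundTruth(pairs, set(names))
    raise RuntimeError("could not sample a pair set covering the pool")


def generate_background(length: int, freqs, rng: np.random.Generator) -> str:
    freqs = np.asarray(freqs, dtype=np.float64)
    if abs(freqs.sum() - 1.0) > 1e-6:
        raise ValueError("background frequencies must sum to 1")
    idx = rng.choice(4, size=length, p=freqs / freqs.sum())
    return "".join(ALPHABET[i] for i in idx)


def _overlaps(a: tuple[int, int], intervals: list[tuple[int, int]],
              margin: int = 0) -> bool:
    return any(a[0] < hi + margin and lo < a[1] + margin
               for lo, hi in intervals)


def _make_site(pwm: PWM, cfg: SimulationConfig,
               rng: np.random.Generator) -> tuple[str, str]:
    site = sample_site(pwm, rng, min_fraction=cfg.site_min_fraction)
    if cfg.random_strand and rng.random() < 0.5:
        return reverse_complement(site), "-"
    return site, "+"


def generate_positive(cfg: SimulationConfig, truth: GroundTruth,
                      lib: MotifLibrary, rng: np.random.Generator,
                      max_restarts: int = 50
                      ) -> tuple[str, list[Implant]]:
    """A positive sequence: k interacting pairs (k drawn from the configured
    range, without replacement from the ground-truth pair set), each pair
    placed with an end-to-start gap drawn uniformly from ``pair_gap``."""
    pairs = sorted(truth.pairs)
    lo, hi = cfg.pairs_per_positive
    for _ in range(max_restarts):
        k = int(rng.integers(lo, hi + 1))
        if k > len(pairs):
            raise ValueError(
                f"pairs_per_positive {k} exceeds ground-truth pairs "
                f"{len(pairs)}")
        chosen = rng.choice(len(pairs), size=k, replace=False)
        try:
            implants = _place_pairs(
                [pairs[int(i)] for i in chosen], cfg, lib, rng)
        except PlacementError:
            logger.debug("positive placement failed; resampling sequence")
            continue
        seq = _write_implants(
            generate_background(cfg.seq_length, cfg.background_freqs, rng),
            implants)
        return seq, implants
    raise PlacementError(
        "could not place pairs; sequence too short for configuration")


def _place_pairs(chosen_pairs, cfg, lib, rng) -> list[Implant]:
    implants: list[Implant] = []
    occupied: list[tuple[int, int]] = []
    for pair_id, (name_a, name_b) in enumerate(chosen_pairs):
        site_a, strand_a = _make_site(lib[name_a], cfg, rng)
        site_b, strand_b = _make_site(lib[name_b], cfg, rng)
        first, second = ((name_a, site_a, strand_a),
                         (name_b, site_b, strand_b))
        if rng.random() < 0.5:
            first, second = second, first
        la, lb = len(first[1]), len(second[1])
        placed = False
        for _ in range(100):
            gap = int(rng.integers(cfg.pair_gap[0], cfg.pair_gap[1] + 1))
            block = la + gap + lb
            if block > cfg.seq_length:
                continue
            s = int(rng.integers(0, cfg.seq_length - block + 1))
            iv_a, iv_b = (s, s + la), (s + la + gap, s + la + gap + lb)
            if _overlaps(iv_a, occupied) or _overlaps(iv_b, occupied):
                continue
            occupied += [iv_a, iv_b]
            implants.append(Implant(first[0], iv_a[0], first[2], first[1],
                                    pair_id))
            implants.append(Implant(second[0], iv_b[0], second[2], second[1],
                                    pair_id))
            placed = True
            break
        if not placed:
            raise PlacementError("pair placement failed")
    return implants


def generate_negative(cfg: SimulationConfig, truth: GroundTruth,
                      lib: MotifLibrary, rng: np.random.Generator,
                      max_restarts: int = 50
                      ) -> tuple[str, list[Implant]]:
    """A negative sequence: 1-3 isolated motifs from the same pool, every
    two implants at least ``neg_min_separation`` bp apart edge-to-edge."""
    pool = sorted(truth.motif_pool)
    lo, hi = cfg.neg_motifs_per_sequence
    for _ in range(max_restarts):
        m = min(int(rng.integers(lo, hi + 1)), len(pool))
        names = [pool[int(i)]
                 for i in rng.choice(len(pool), size=m, replace=False)]
        implants: list[Implant] = []
        occupied: list[tuple[int, int]] = []
        ok = True
        for name in names:
            site, strand = _make_site(lib[name], cfg, rng)
            placed = False
            for _ in range(100):
                s = int(rng.integers(0, cfg.seq_length - len(site) + 1))
                iv = (s, s + len(site))
                if _overlaps(iv, occupied, margin=cfg.neg_min_separation):
                    continue
                occupied.append(iv)
                implants.append(Implant(name, s, strand, site, None))
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            seq = _write_implants(
                generate_background(cfg.seq_length, cfg.background_freqs,
                                    rng), implants)
            return seq, implants
    raise PlacementError("could not place separated negative motifs")


def _write_implants(background: str, implants: list[Implant]) -> str:
    seq = list(background)
    for imp in implants:
        seq[imp.start:imp.end] = imp.site
    return "".join(seq)


def generate_dataset(cfg: SimulationConfig, lib: MotifLibrary
                     ) -> tuple[LabeledSequenceSet, GroundTruth]:
    """Balanced dataset of ``cfg.n_sequences`` sequences (half positive,
    half negative, shuffled), deterministic for a fixed ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    truth = select_interacting_pairs(lib, cfg.n_motifs, cfg.n_pairs, rng)
    half = cfg.n_sequences // 2
    seqs: list[str] = []
    implants: list[list[Implant]] = []
    labels = np.concatenate([np.ones(half, dtype=np.int64),
                             np.zeros(half, dtype=np.int64)])
    for _ in range(half):
        s, imp = generate_positive(cfg, truth, lib, rng)
        seqs.append(s)
        implants.append(imp)
    for _ in range(half):
        s, imp = generate_negative(cfg, truth, lib, rng)
        seqs.append(s)
        implants.append(imp)
    order = rng.permutation(cfg.n_sequences)
    ids = [f"seq{i:06d}" for i in range(cfg.n_sequences)]
    ds = LabeledSequenceSet(
        ids, [seqs[i] for i in order], labels[order],
        [implants[i] for i in order])
    return ds, truth


def split_dataset(ds: LabeledSequenceSet,
                  ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  rng: np.random.Generator | int = 0
                  ) -> tuple[LabeledSequenceSet, LabeledSequenceSet,
                             LabeledSequenceSet]:
    """Stratified train/validation/test partition (binary labels stratify
    by class; multi-label splits are random)."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = len(ds)
    if ds.is_multilabel:
        strata = [np.arange(n)]
    else:
        strata = [np.flatnonzero(ds.labels == c)
                  for c in np.unique(ds.labels)]
    parts: list[list[int]] = [[], [], []]
    for stratum in strata:
        perm = stratum[rng.permutation(len(stratum))]
        c1 = int(round(ratios[0] * len(perm)))
        c2 = int(round((ratios[0] + ratios[1]) * len(perm)))
        parts[0] += list(perm[:c1])
        parts[1] += list(perm[c1:c2])
        parts[2] += list(perm[c2:])
    return tuple(ds.subset(sorted(p)) for p in parts)  # type: ignore


# ---------------------------------------------------------------------------
# On-disk representation (FASTA + TSV sidecars)
# ---------------------------------------------------------------------------

def write_dataset(ds: LabeledSequenceSet, outdir, truth: GroundTruth | None
                  = None, prefix: str = "dataset") -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    fasta = outdir / f"{prefix}.fasta"
    with open(fasta, "w") as fh:
        for sid, seq in zip(ds.ids, ds.sequences):
            fh.write(f">{sid}\n{seq}\n")
    paths["fasta"] = fasta

    if ds.is_multilabel:
        label_col = [",".join(map(str, row)) for row in ds.labels]
    else:
        label_col = list(ds.labels)
    labels = pd.DataFrame({"id": ds.ids, "label": label_col})
    paths["labels"] = outdir / f"{prefix}.labels.tsv"
    labels.to_csv(paths["labels"], sep="\t", index=False)

    rows = [
        dict(id=sid, motif_name=imp.motif_name, start=imp.start,
             end=imp.end, strand=imp.strand,
             pair_id="" if imp.pair_id is None else imp.pair_id)
        for sid, imps in zip(ds.ids, ds.implants) for imp in imps]
    paths["implants"] = outdir / f"{prefix}.implants.tsv"
    pd.DataFrame(rows, columns=["id", "motif_name", "start", "end",
                                "strand", "pair_id"]).to_csv(
        paths["implants"], sep="\t", index=False)

    if truth is not None:
        paths["ground_truth"] = outdir / f"{prefix}.ground_truth.tsv"
        pd.DataFrame(sorted(truth.pairs),
                     columns=["motif_a", "motif_b"]).to_csv(
            paths["ground_truth"], sep="\t", index=False)
    return paths


def read_dataset(outdir, prefix: str = "dataset"
                 ) -> tuple[LabeledSequenceSet, GroundTruth | None]:
    from Bio import SeqIO

    outdir = Path(outdir)
    ids, seqs = [], []
    for rec in SeqIO.parse(str(outdir / f"{prefix}.fasta"), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    labels_df = pd.read_csv(outdir / f"{prefix}.labels.tsv", sep="\t",
                            dtype={"id": str, "label": str})
    by_id = dict(zip(labels_df["id"], labels_df["label"]))
    first = by_id[ids[0]]
    if "," in first:
        labels = np.array([[int(v) for v in by_id[i].split(",")]
                           for i in ids])
    else:
        labels = np.array([int(by_id[i]) for i in ids])

    implants: list[list[Implant]] = [[] for _ in ids]
    imp_path = outdir / f"{prefix}.implants.tsv"
    if imp_path.exists():
        pos = {sid: k for k, sid in enumerate(ids)}
        df = pd.read_csv(imp_path, sep="\t", dtype={"id": str})
        for row in df.itertuples():
            pid = None if pd.isna(row.pair_id) or row.pair_id == "" \
                else int(row.pair_id)
            k = pos[row.id]
            site = seqs[k][row.start:row.end]
            implants[k].append(Implant(row.motif_name, int(row.start),
                                       row.strand, site, pid))
    ds = LabeledSequenceSet(ids, seqs, labels, implants)

    truth = None
    gt_path = outdir / f"{prefix}.ground_truth.tsv"
    if gt_path.exists():
        df = pd.read_csv(gt_path, sep="\t")
        pairs = {(a, b) for a, b in zip(df["motif_a"], df["motif_b"])}
        pool = {m for p in pairs for m in p}
        pool |= {imp.motif_name for imps in implants for imp in imps}
        truth = GroundTruth(pairs, pool)
    return ds, truth
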