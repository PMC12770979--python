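"""Position weight matrices: I/O, scoring, sampling, comparison, clustering.

A :class:`PWM` is an L×4 column-stochastic matrix over A,C,G,T plus a
background distribution.  Matrices come from MEME-minimal or JASPAR raw-count
files (parsed with ``Bio.motifs``), from convolutional-filter activation
sites, or from the synthetic library generator used by the sequence
simulator.  Filter-to-motif assignment uses an ungapped, reverse-complement
aware, per-column Pearson-correlation comparator.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import motifs as bio_motifs

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: probability floor applied before taking logs, so log-odds stay finite
PROB_FLOOR = 1e-3
#: per-cell pseudocount when converting JASPAR counts to probabilities
JASPAR_PSEUDOCOUNT = 0.25
#: total per-column pseudocount when estimating a PWM from filter sites
FILTER_PSEUDOCOUNT = 0.5

UNIFORM_BG = np.full(4, 0.25)


class MotifParseError(ValueError):
    """Raised when a motif file cannot be parsed."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """A named probability matrix (L columns × 4 bases, order A,C,G,T)."""

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"{self.name}: matrix must be L x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError(f"{self.name}: motif length must be >= 4")
        if np.any(self.matrix < 0):
            raise ValueError(f"{self.name}: negative probabilities")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{self.name}: columns must sum to 1")
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-6):
            raise ValueError(f"{self.name}: background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """log2 odds against the background, probability-floored."""
        p = np.maximum(self.matrix, PROB_FLOOR)
        bg = np.maximum(self.background, PROB_FLOOR)
        return np.log2(p / bg[None, :])

    @property
    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    @property
    def information_content(self) -> float:
        """Total IC in bits: sum over columns of 2 + Σ p log2 p."""
        p = self.matrix
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        return float((2.0 + plogp.sum(axis=1)).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.matrix[::-1, ::-1].copy(),
                   self.background[::-1].copy())


@dataclass
class MotifLibrary:
    motifs: list[PWM]
    source: str = ""

    def __post_init__(self):
        names = [m.name for m in self.motifs]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate motif names: {dup}")
        self._by_name = {m.name: m for m in self.motifs}

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def __getitem__(self, key) -> PWM:
        if isinstance(key, str):
            return self._by_name[key]
        return self.motifs[key]

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.motifs]


@dataclass
class FilterAnnotation:
    """Best library match for a convolutional filter (or None below cutoff)."""

    filter_index: int
    motif_name: str | None
    match_score: float
    match_offset: int
    orientation: str = "+"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_motifs(path, fmt: str | None = None) -> MotifLibrary:
    """Read a motif library from MEME minimal or JASPAR raw-count format.

    ``fmt`` is ``"meme"`` or ``"jaspar"``; if omitted it is sniffed from the
    file contents.  JASPAR counts c are converted to probabilities as
    (c + p) / (Σc + 4p) with per-cell pseudocount p = 0.25.
    """
    path = Path(path)
    text = path.read_text()
    if fmt is None:
        stripped = text.lstrip()
        fmt = "jaspar" if stripped.startswith(">") else "meme"
    if not text.strip():
        logger.warning("motif file %s is empty", path)
        return MotifLibrary([], source=str(path))
    try:
        if fmt == "meme":
            records = bio_motifs.parse(io.StringIO(text), "minimal")
            pwms = [_from_meme_record(r) for r in records]
        elif fmt == "jaspar":
            records = bio_motifs.parse(io.StringIO(text), "jaspar")
            pwms = [_from_jaspar_record(r) for r in records]
        else:
            raise ValueError(f"unknown motif format: {fmt!r}")
    except ValueError as exc:
        if isinstance(exc, MotifParseError):
            raise
        raise MotifParseError(
            f"{path}: could not parse as {fmt}: {exc}") from exc
    try:
        return MotifLibrary(pwms, source=str(path))
    except ValueError as exc:
        raise MotifParseError(f"{path}: {exc}") from exc


def _from_meme_record(rec) -> PWM:
    mat = np.array([[rec.pwm[b][i] for b in ALPHABET]
                    for i in range(rec.length)])
    mat = mat / mat.sum(axis=1, keepdims=True)  # force exact normalization
    bg = np.array([rec.background[b] for b in ALPHABET])
    bg = bg / bg.sum()
    name = rec.name or rec.base_id
    return PWM(name, mat, bg)


def _from_jaspar_record(rec) -> PWM:
    counts = np.array([[rec.counts[b][i] for b in ALPHABET]
                       for i in range(rec.length)])
    p = JASPAR_PSEUDOCOUNT
    mat = (counts + p) / (counts.sum(axis=1, keepdims=True) + 4 * p)
    name = rec.name or rec.matrix_id
    return PWM(name, mat)


def write_motifs(lib: MotifLibrary, path) -> None:
    """Write a library in MEME minimal format (round-trips to 1e-4)."""
    if len(lib) == 0:
        raise ValueError("refusing to write an empty motif library")
    bg = lib.motifs[0].background
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        "strands: + -", "",
        "Background letter frequencies",
        " ".join(f"{b} {bg[i]:.5f}" for i, b in enumerate(ALPHABET)),
        "",
    ]
    for m in lib:
        lines.append(f"MOTIF {m.name}")
        # nsites is large because some readers quantize probabilities to
        # multiples of 1/nsites when reconstructing counts
        lines.append(
            f"letter-probability matrix: alength= 4 w= {len(m)} "
            f"nsites= 1000000 E= 0")
        for row in m.matrix:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Scoring and sampling
# ---------------------------------------------------------------------------

def score_site(pwm: PWM, site: str) -> float:
    """log2-odds score of ``site`` under ``pwm`` against its background."""
    if len(site) != len(pwm):
        raise ValueError(
            f"site length {len(site)} != motif length {len(pwm)}")
    lo = pwm.log_odds()
    try:
        idx = [ALPHABET.index(b) for b in site]
    except ValueError:
        bad = sorted(set(site) - set(ALPHABET))
        raise ValueError(f"non-ACGT characters in site: {bad}") from None
    return float(lo[np.arange(len(site)), idx].sum())


def sample_site(pwm: PWM, rng: np.random.Generator,
                min_fraction: float = 0.5, max_tries: int = 100) -> str:
    """Draw a site column-wise from the PWM, rejecting draws that score
    below ``min_fraction`` of the maximum log-odds score.  Falls back to the
    consensus after ``max_tries`` rejections, so it always terminates."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    cutoff = min_fraction * pwm.max_score
    cum = pwm.matrix.cumsum(axis=1)
    for _ in range(max_tries):
        u = rng.random(len(pwm))
        idx = (u[:, None] < cum).argmax(axis=1)
        site = "".join(ALPHABET[i] for i in idx)
        if score_site(pwm, site) >= cutoff:
            return site
    return pwm.consensus


# ---------------------------------------------------------------------------
# Filter annotation
# ---------------------------------------------------------------------------

def filter_to_pwm(activating_sites: list[str], name: str = "filter",
                  min_sites: int = 10,
                  pseudocount: float = FILTER_PSEUDOCOUNT) -> PWM | None:
    """Estimate a PWM from the sub-sequences that strongly activate a filter.

    Returns None when fewer than ``min_sites`` sites are available — such a
    filter is left unannotated rather than annotated from noise.
    """
    if len(activating_sites) < min_sites:
        return None
    L = len(activating_sites[0])
    counts = np.zeros((L, 4))
    for s in activating_sites:
        for i, b in enumerate(s):
            j = ALPHABET.find(b)
            if j >= 0:  # N and other ambiguity codes contribute nothing
                counts[i, j] += 1
    counts += pseudocount / 4.0
    return PWM(name, counts / counts.sum(axis=1, keepdims=True))


def _column_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Mean per-column Pearson correlation of two aligned L×4 blocks."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac ** 2).sum(axis=1) * (bc ** 2).sum(axis=1))
    r = np.where(den > 1e-12, num / np.where(den > 1e-12, den, 1.0), 0.0)
    return float(r.mean())


def _best_alignment(q: np.ndarray, t: np.ndarray,
                    min_overlap: int) -> tuple[float, int, int]:
    """Best ungapped offset of q against t; ties in mean correlation are
    broken in favor of the longer overlap."""
    lq, lt = q.shape[0], t.shape[0]
    best, best_off, best_n = -np.inf, 0, 0
    for off in range(-(lq - min_overlap), lt - min_overlap + 1):
        qs, ts = max(0, -off), max(0, off)
        n = min(lq - qs, lt - ts)
        if n < min_overlap:
            continue
        r = _column_corr(q[qs:qs + n], t[ts:ts + n])
        if r > best + 1e-9 or (abs(r - best) <= 1e-9 and n > best_n):
            best, best_off, best_n = r, off, n
    return best, best_off, best_n


def match_pwms(query: PWM, lib: MotifLibrary, min_overlap: int = 4,
               threshold: float = 0.75,
               filter_index: int = -1) -> FilterAnnotation:
    """Best ungapped match of ``query`` against a library, both strands.

    Similarity is the mean per-column Pearson correlation over the aligned
    columns, maximized over all offsets with at least ``min_overlap``
    overlapping columns; ``motif_name`` is None when the best similarity is
    below ``threshold``.
    """
    if len(lib) == 0:
        raise ValueError("empty motif library")
    if len(query) < min_overlap:
        raise ValueError(
            f"query length {len(query)} < min_overlap {min_overlap}")
    q_fwd = query.matrix
    q_rev = query.matrix[::-1, ::-1]
    best = FilterAnnotation(filter_index, None, -np.inf, 0)
    best_n = 0
    for target in lib:
        for orient, q in (("+", q_fwd), ("-", q_rev)):
            score, off, n = _best_alignment(q, target.matrix, min_overlap)
            if score > best.match_score + 1e-9 or (
                    abs(score - best.match_score) <= 1e-9 and n > best_n):
                best = FilterAnnotation(filter_index, target.name, score,
                                        off, orient)
                best_n = n
    if best.match_score < threshold:
        best.motif_name = None
    return best


def pairwise_similarity(lib: MotifLibrary, min_overlap: int = 4) -> np.ndarray:
    n = len(lib)
    sim = np.eye(n)
    for i in range(n):
        qf = lib[i].matrix
        qr = qf[::-1, ::-1]
        for j in range(i + 1, n):
            s = max(_best_alignment(qf, lib[j].matrix, min_overlap)[0],
                    _best_alignment(qr, lib[j].matrix, min_overlap)[0])
            sim[i, j] = sim[j, i] = s
    return sim


def cluster_motifs(lib: MotifLibrary,
                   similarity_threshold: float = 0.8,
                   min_overlap: int = 4) -> MotifLibrary:
    """Greedy single-linkage clustering on the match similarity; each cluster
    is represented by its highest-information-content member."""
    if not 0 < similarity_threshold < 1:
        raise ValueError("similarity_threshold must be in (0, 1)")
    n = len(lib)
    if n == 0:
        return MotifLibrary([], source=lib.source)
    sim = pairwise_similarity(lib, min_overlap=min_overlap)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if sim[i, j] >= similarity_threshold:
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    reps = []
    for members in clusters.values():
        rep = max(members, key=lambda i: (lib[i].information_content, -i))
        reps.append(rep)
    reps.sort()
    return MotifLibrary([lib[i] for i in reps],
                        source=f"{lib.source}|clustered@{similarity_threshold}")


# ---------------------------------------------------------------------------
# Synthetic libraries
# ---------------------------------------------------------------------------

def random_library(n: int, rng: np.random.Generator,
                   length_range: tuple[int, int] = (8, 12),
                   dominance_range: tuple[float, float] = (0.70, 0.95),
                   max_similarity: float = 0.75,
                   prefix: str = "TF") -> MotifLibrary:
    """Generate ``n`` synthetic TF-like PWMs: each column has one dominant
    base (probability drawn from ``dominance_range``) with the remainder
    spread over the other bases.  Members are rejection-sampled to stay
    pairwise dissimilar under the match comparator, mimicking motifs chosen
    from distinct clusters of a real database."""
    motifs: list[PWM] = []
    attempts = 0
    while len(motifs) < n:
        attempts += 1
        if attempts > 100 * n:
            raise RuntimeError("could not generate a dissimilar library")
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        dom = rng.integers(0, 4, size=L)
        p = rng.uniform(*dominance_range, size=L)
        mat = ((1 - p) / 3)[:, None] * np.ones((L, 4))
        mat[np.arange(L), dom] = p
        cand = PWM(f"{prefix}{len(motifs):03d}", mat)
        ok = True
        cf, cr = cand.matrix, cand.matrix[::-1, ::-1]
        for m in motifs:
            s = max(_best_alignment(cf, m.matrix, 4)[0],
                    _best_alignment(cr, m.matrix, 4)[0])
            if s >= max_similarity:
                ok = False
                break
        if ok:
            motifs.append(cand)
    return MotifLibrary(motifs, source="synthetic")


# ---------------------------------------------------------------------------
# Optional external TomTom adapter
# ---------------------------------------------------------------------------

def tomtom_annotate(queries: MotifLibrary, target_meme_path,
                    tomtom_executable: str = "tomtom",
                    workdir=None) -> list[FilterAnnotation]:
    """Annotate query motifs with the external TomTom tool, if installed.

    Writes the queries to a MEME file, runs
    ``tomtom <queries> <targets>`` and keeps the top target (smallest
    q-value, then p-value) per query.  The built-in correlation comparator
    (:func:`match_pwms`) is the default annotator; this adapter exists for
    users who want TomTom's statistics instead.
    """
    import shutil
    import subprocess
    import tempfile

    import pandas as pd

    if shutil.which(tomtom_executable) is None:
        raise FileNotFoundError(
            f"{tomtom_executable!r} not found on PATH; use match_pwms for "
            "the built-in comparator")
    workdir = Path(workdir or tempfile.mkdtemp(prefix="tomtom_"))
    query_path = workdir / "queries.meme"
    write_motifs(queries, query_path)
    subprocess.run(
        [tomtom_executable, "-oc", str(workdir / "out"), "-text",
         str(query_path), str(target_meme_path)],
        check=True, capture_output=True)
    out_file = workdir / "out" / "tomtom.tsv"
    return parse_tomtom_output(out_file, queries)


def parse_tomtom_output(path, queries: MotifLibrary
                        ) -> list[FilterAnnotation]:
    """Parse TomTom tab-separated output into per-query annotations."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip() for c in df.columns]
    annotations = []
    for idx, query in enumerate(queries):
        rows = df[df["Query_ID"] == query.name]
        if not len(rows):
            annotations.append(FilterAnnotation(idx, None, 0.0, 0))
            continue
        best = rows.sort_values(["q-value", "p-value"]).iloc[0]
        annotations.append(FilterAnnotation(
            idx, str(best["Target_ID"]),
            float(-np.log10(max(best["p-value"], 1e-300))),
            int(best.get("Optimal_offset", 0)),
            str(best.get("Orientation", "+"))))
    return annotations
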