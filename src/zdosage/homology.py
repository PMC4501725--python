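"""Protein homology search and chromosome assignment.

Global (Needleman-Wunsch/Gotoh) and local (Smith-Waterman) affine-gap
alignment against BLOSUM62, Karlin-Altschul significance, and best-hit
assignment of six-frame-translated nucleotide contigs to the chromosome
of their closest reference gene model.

Gap convention: a gap of length k costs gap_open + k * gap_extend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .errors import InvalidInputError
from .simulate import ReferenceGeneModel

try:  # pragma: no cover - exercised implicitly
    from numba import njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


# ungapped Karlin-Altschul parameters for BLOSUM62
KA_LAMBDA = 0.3176
KA_K = 0.134

NEG_INF = -1e30

__all__ = [
    "Scoring",
    "AlignmentResult",
    "Hit",
    "global_align",
    "local_score",
    "local_search",
    "six_frame_peptides",
    "assign_chromosomes",
    "evalue",
]


@dataclass(frozen=True)
class Scoring:
    """Substitution matrix plus affine gap penalties (positive costs)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend < 0:
            raise InvalidInputError("gap penalties must be >= 0")

    @property
    def matrix(self) -> np.ndarray:
        return _load_matrix(self.matrix_name)[0]

    @property
    def alphabet(self) -> str:
        return _load_matrix(self.matrix_name)[1]

    def encode(self, seq: str) -> np.ndarray:
        """Residues to matrix indices; unknown characters map to 'X'."""
        lookup = _char_lookup(self.matrix_name)
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        return lookup[arr]


@lru_cache(maxsize=4)
def _load_matrix(name: str) -> tuple[np.ndarray, str]:
    m = substitution_matrices.load(name)
    alpha = str(m.alphabet)
    arr = np.array(m, dtype=np.float64)
    return arr, alpha


@lru_cache(maxsize=4)
def _char_lookup(name: str) -> np.ndarray:
    alpha = _load_matrix(name)[1]
    x_index = alpha.index("X") if "X" in alpha else 0
    lookup = np.full(128, x_index, dtype=np.int64)
    for i, ch in enumerate(alpha):
        lookup[ord(ch)] = i
    return lookup


@dataclass(frozen=True)
class AlignmentResult:
    aligned_query: str
    aligned_subject: str
    score: float
    identities: int
    aligned_columns: int
    evalue: float

    @property
    def percent_identity(self) -> float:
        if self.aligned_columns == 0:
            return 0.0
        return 100.0 * self.identities / self.aligned_columns


@dataclass(frozen=True, order=True)
class Hit:
    """One significant database hit, ordered for deterministic ranking."""

    evalue: float
    neg_score: float
    target_id: str

    @property
    def score(self) -> float:
        return -self.neg_score


def evalue(score: float, m: int, n: int,
           lam: float = KA_LAMBDA, k: float = KA_K) -> float:
    """Karlin-Altschul expected chance-hit count E = K m n exp(-lambda S)
    for a search of query length m against total database length n."""
    if m <= 0 or n <= 0:
        raise InvalidInputError("search space sizes must be positive")
    return float(k * m * n * np.exp(-lam * score))


# ---------------------------------------------------------------------------
# DP kernels (numba-accelerated when available)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _global_score_kernel(a, b, sub, gap_open, gap_ext):
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)  # gap in b (a consumed)
    Y = np.full((n + 1, m + 1), NEG_INF)  # gap in a (b consumed)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - gap_ext * i
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - gap_ext * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1],
                            Y[i - 1, j - 1])
            M[i, j] = best_prev + s
            X[i, j] = max(M[i - 1, j] - gap_open - gap_ext,
                          X[i - 1, j] - gap_ext,
                          Y[i - 1, j] - gap_open - gap_ext)
            Y[i, j] = max(M[i, j - 1] - gap_open - gap_ext,
                          Y[i, j - 1] - gap_ext,
                          X[i, j - 1] - gap_open - gap_ext)
    return max(M[n, m], X[n, m], Y[n, m])


@njit(cache=False)
def _local_score_kernel(a, b, sub, gap_open, gap_ext):
    n, m = len(a), len(b)
    prev_m = np.zeros(m + 1)
    prev_x = np.full(m + 1, NEG_INF)
    prev_y = np.full(m + 1, NEG_INF)
    best = 0.0
    for i in range(1, n + 1):
        cur_m = np.zeros(m + 1)
        cur_x = np.full(m + 1, NEG_INF)
        cur_y = np.full(m + 1, NEG_INF)
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            diag = max(prev_m[j - 1], prev_x[j - 1], prev_y[j - 1])
            cur_m[j] = max(0.0, diag + s)
            cur_x[j] = max(prev_m[j] - gap_open - gap_ext,
                           prev_x[j] - gap_ext,
                           prev_y[j] - gap_open - gap_ext)
            cur_y[j] = max(cur_m[j - 1] - gap_open - gap_ext,
                           cur_y[j - 1] - gap_ext,
                           cur_x[j - 1] - gap_open - gap_ext)
            cell = max(cur_m[j], cur_x[j], cur_y[j])
            if cell > best:
                best = cell
        prev_m, prev_x, prev_y = cur_m, cur_x, cur_y
    return best


def local_score(a: str, b: str, scoring: Scoring | None = None) -> float:
    """Optimal Smith-Waterman local alignment score (empty alignment = 0)."""
    scoring = scoring or Scoring()
    if not a or not b:
        raise InvalidInputError("sequences must be nonempty")
    return float(_local_score_kernel(
        scoring.encode(a), scoring.encode(b), scoring.matrix,
        float(scoring.gap_open), float(scoring.gap_extend)))


def global_align(a: str, b: str,
                 scoring: Scoring | None = None) -> AlignmentResult:
    """Optimal global alignment with affine gaps, including traceback.

    Percent identity is computed over columns where neither row carries
    a gap. The attached E-value applies the Karlin-Altschul formula to
    the global score (for cross-operation comparability only).
    """
    scoring = scoring or Scoring()
    if not a or not b:
        raise InvalidInputError("sequences must be nonempty")
    ea, eb = scoring.encode(a), scoring.encode(b)
    sub = scoring.matrix
    go, ge = float(scoring.gap_open), float(scoring.gap_extend)
    n, m = len(a), len(b)

    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -go - ge * i
    for j in range(1, m + 1):
        Y[0, j] = -go - ge * j

    for i in range(1, n + 1):
        si = ea[i - 1]
        for j in range(1, m + 1):
            s = sub[si, eb[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1],
                          Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - go - ge, X[i - 1, j] - ge,
                          Y[i - 1, j] - go - ge)
            Y[i, j] = max(M[i, j - 1] - go - ge, Y[i, j - 1] - ge,
                          X[i, j - 1] - go - ge)

    # traceback
    i, j = n, m
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    out_a: list[str] = []
    out_b: list[str] = []
    eps = 1e-9
    while i > 0 or j > 0:
        if i == 0:
            state = 2
        elif j == 0:
            state = 1
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            target = X[i, j]
            if abs(M[i - 1, j] - go - ge - target) < eps:
                state = 0
            elif abs(X[i - 1, j] - ge - target) < eps:
                state = 1
            else:
                state = 2
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            target = Y[i, j]
            if abs(M[i, j - 1] - go - ge - target) < eps:
                state = 0
            elif abs(Y[i, j - 1] - ge - target) < eps:
                state = 2
            else:
                state = 1
            j -= 1

    aq = "".join(reversed(out_a))
    asub = "".join(reversed(out_b))
    identities = sum(1 for x, y in zip(aq, asub)
                     if x != "-" and y != "-" and x == y)
    cols = sum(1 for x, y in zip(aq, asub) if x != "-" and y != "-")
    score = float(max(M[n, m], X[n, m], Y[n, m]))
    return AlignmentResult(aq, asub, score, identities, cols,
                           evalue(score, n, m))


# ---------------------------------------------------------------------------
# search and assignment
# ---------------------------------------------------------------------------

def local_search(query: str, targets: dict[str, str] | list[tuple[str, str]],
                 scoring: Scoring | None = None,
                 evalue_threshold: float = 1e-9) -> list[Hit]:
    """Rank database sequences by Smith-Waterman score against ``query``,
    keeping hits with E-value below the threshold. Sorted by ascending
    E-value, then descending score, then target id."""
    scoring = scoring or Scoring()
    if not query:
        raise InvalidInputError("empty query")
    items = list(targets.items()) if isinstance(targets, dict) else list(targets)
    if not items:
        raise InvalidInputError("empty target set")
    db_len = sum(len(s) for _, s in items)
    eq = scoring.encode(query)
    sub = scoring.matrix
    go, ge = float(scoring.gap_open), float(scoring.gap_extend)
    hits = []
    for tid, tseq in items:
        if not tseq:
            continue
        score = float(_local_score_kernel(eq, scoring.encode(tseq), sub,
                                          go, ge))
        e = evalue(score, len(query), db_len)
        if e < evalue_threshold:
            hits.append(Hit(evalue=e, neg_score=-score, target_id=tid))
    return sorted(hits)


_FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")


def six_frame_peptides(nt: str) -> list[tuple[str, str]]:
    """(frame label, peptide) for all six reading frames; each frame is
    truncated to its longest stop-free stretch. Frames shorter than one
    codon yield no peptide."""
    seq = Seq(nt.upper())
    out: list[tuple[str, str]] = []
    for strand, s in (("+", seq), ("-", seq.reverse_complement())):
        for off in range(3):
            frame = s[off:]
            frame = frame[:len(frame) - len(frame) % 3]
            if len(frame) < 3:
                continue
            pep = str(frame.translate(table=1))
            longest = max(pep.split("*"), key=len)
            if longest:
                out.append((f"{strand}{off + 1}", longest))
    return out


def assign_chromosomes(contigs: list[tuple[str, str]],
                       reference: list[ReferenceGeneModel],
                       scoring: Scoring | None = None,
                       evalue_threshold: float = 1e-9) -> pd.DataFrame:
    """Best-hit chromosome assignment of nucleotide contigs.

    Each contig is translated in six frames; the highest-significance hit
    of any frame against the reference proteins decides the chromosome.
    Contigs whose best hit misses the threshold (or that are shorter than
    one codon) get chromosome 'unassigned'. Ties on (evalue, score) break
    to the lexicographically smallest gene_id.

    Returns a DataFrame with columns contig_id, chromosome, gene_id,
    frame, score, evalue, indexed by contig_id.
    """
    scoring = scoring or Scoring()
    if not contigs:
        raise InvalidInputError("empty contig set")
    if not reference:
        raise InvalidInputError("empty reference set")
    targets = [(g.gene_id, g.protein) for g in reference]
    chrom_of = {g.gene_id: g.chromosome for g in reference}
    db_len = sum(len(p) for _, p in targets)
    sub = scoring.matrix
    go, ge = float(scoring.gap_open), float(scoring.gap_extend)
    encoded_targets = [(tid, scoring.encode(p), len(p)) for tid, p in targets]

    rows = []
    for cid, nt in contigs:
        if len(nt) < 3:
            warnings.warn(f"contig {cid} shorter than one codon; unassigned")
            rows.append(_unassigned_row(cid))
            continue
        best: tuple[float, float, str, str] | None = None  # e, -score, gid, frame
        for frame, pep in six_frame_peptides(nt):
            ep = scoring.encode(pep)
            for tid, et, _tlen in encoded_targets:
                score = float(_local_score_kernel(ep, et, sub, go, ge))
                e = evalue(score, len(pep), db_len)
                key = (e, -score, tid, frame)
                if best is None or key < best:
                    best = key
        if best is None or best[0] >= evalue_threshold:
            rows.append(_unassigned_row(cid))
        else:
            e, neg_score, gid, frame = best
            rows.append({"contig_id": cid, "chromosome": chrom_of[gid],
                         "gene_id": gid, "frame": frame,
                         "score": -neg_score, "evalue": e})
    df = pd.DataFrame(rows).set_index("contig_id", drop=False)
    return df


def _unassigned_row(cid: str) -> dict:
    return {"contig_id": cid, "chromosome": "unassigned", "gene_id": "",
            "frame": "", "score": np.nan, "evalue": np.nan}
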