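"""Expression-ratio analysis of infected vs uninfected pools.

Normalizes count matrices, computes per-contig log2 infected/uninfected
ratios (M) and mean log2 abundance (A), summarizes them per chromosome
(median and quartiles), and tests for a Z-specific upward shift with a
one-sided permutation test on the difference of medians.

``normalize`` offers two methods: plain counts-per-million ("cpm") and a
median-of-ratios scheme ("median") that anchors the bulk of contigs at a
ratio of 1 and is therefore robust to composition shifts when a large
fraction of the transcriptome (e.g. the Z chromosome) moves in one
direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSampleError,
    InsufficientDataError,
    InvalidDesignError,
    InvalidInputError,
    NotFoundError,
)

__all__ = [
    "CountTable",
    "ZShiftResult",
    "normalize",
    "compute_ratios",
    "summarize_by_chromosome",
    "z_shift_test",
    "timecourse_profile",
    "bh_adjust",
]


@dataclass
class CountTable:
    """Contig x sample matrix of non-negative integers plus per-sample
    metadata (hpo, infected)."""

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if self.counts.columns.duplicated().any():
            raise InvalidInputError("duplicate sample ids in count matrix")
        if not np.issubdtype(self.counts.to_numpy().dtype, np.number):
            raise InvalidInputError("non-numeric counts")
        if (self.counts.to_numpy() < 0).any():
            raise InvalidInputError("negative counts")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise InvalidInputError(
                f"samples missing metadata: {sorted(missing)}")
        for col in ("hpo", "infected"):
            if col not in self.samples.columns:
                raise InvalidInputError(f"sample sheet lacks column {col!r}")

    def sample_ids(self, infected: bool, hpo: float | None = None
                   ) -> list[str]:
        meta = self.samples.loc[list(self.counts.columns)]
        mask = meta["infected"].astype(bool) == infected
        if hpo is not None:
            mask &= meta["hpo"] == hpo
        return list(meta.index[mask])


def normalize(counts: pd.DataFrame | CountTable, method: str = "cpm",
              reference_contigs: list[str] | pd.Index | None = None,
              ) -> pd.DataFrame:
    """Per-sample scaled abundance.

    "cpm": each column scaled to sum to 1e6.
    "median": median-of-ratios size factors (geometric-mean reference over
    contigs nonzero in all samples), rescaled so the grand total matches
    CPM magnitudes; column sums are then NOT exactly 1e6 by design.

    ``reference_contigs`` restricts the size-factor estimation (method
    "median") to a subset of contigs — e.g. autosomal contigs, so that a
    genuine chromosome-wide Z shift cannot drag the scaling with it.
    """
    df = counts.counts if isinstance(counts, CountTable) else counts
    totals = df.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero) > 0:
        raise DegenerateSampleError(
            f"all-zero sample(s): {', '.join(map(str, zero.index))}")
    if method == "cpm":
        return df / totals * 1e6
    if method == "median":
        sub = df if reference_contigs is None \
            else df.loc[df.index.intersection(reference_contigs)]
        arr = sub.to_numpy(dtype=float)
        positive = (arr > 0).all(axis=1)
        if positive.sum() < 1:
            raise DegenerateSampleError(
                "no reference contig is nonzero in every sample")
        logratio = np.log(arr[positive])
        logratio = logratio - logratio.mean(axis=1, keepdims=True)
        size = np.exp(np.median(logratio, axis=0))
        scaled = df / size
        return scaled * 1e6 / (scaled.sum(axis=0).mean())
    raise InvalidInputError(f"unknown normalization method {method!r}")


def compute_ratios(normalized: pd.DataFrame, chromosomes: pd.Series,
                   infected_ids: list[str], uninfected_ids: list[str],
                   pseudocount: float = 0.5,
                   min_abundance: float = 1.0) -> pd.DataFrame:
    """Per-contig M (log2 infected/uninfected group-mean ratio) and A
    (mean log2 abundance), both pseudocounted.

    Contigs whose group means are below ``min_abundance`` in both groups
    are dropped; the number dropped is available as ``df.attrs['n_dropped']``.
    Returns a DataFrame (contig_id, chromosome, M, A) indexed by contig_id;
    contigs without a chromosome label get 'unassigned'.
    """
    if not infected_ids or not uninfected_ids:
        raise InvalidDesignError("both sample groups must be nonempty")
    if pseudocount <= 0:
        raise InvalidDesignError("pseudocount must be > 0")
    missing = (set(infected_ids) | set(uninfected_ids)) \
        - set(normalized.columns)
    if missing:
        raise InvalidInputError(f"unknown sample ids: {sorted(missing)}")
    mi = normalized[infected_ids].mean(axis=1)
    mu = normalized[uninfected_ids].mean(axis=1)
    keep = (mi >= min_abundance) | (mu >= min_abundance)
    n_dropped = int((~keep).sum())
    mi, mu = mi[keep], mu[keep]
    m = np.log2(mi + pseudocount) - np.log2(mu + pseudocount)
    a = 0.5 * (np.log2(mi + pseudocount) + np.log2(mu + pseudocount))
    chrom = chromosomes.reindex(m.index).fillna("unassigned")
    df = pd.DataFrame({
        "contig_id": m.index,
        "chromosome": chrom,
        "M": m,
        "A": a,
    })
    df.index.name = None
    df.attrs["n_dropped"] = n_dropped
    return df


def summarize_by_chromosome(ratios: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome n, median M and quartiles (linear-interpolation
    quantiles), ordered Z first then autosomes lexicographically.
    Unassigned contigs are excluded."""
    if "M" not in ratios or "chromosome" not in ratios:
        raise InvalidInputError("ratios table lacks M/chromosome columns")
    rows = []
    present = [c for c in ratios["chromosome"].unique()
               if c != "unassigned"]
    ordered = (["Z"] if "Z" in present else []) \
        + sorted(c for c in present if c != "Z")
    for chrom in ordered:
        m = ratios.loc[ratios["chromosome"] == chrom, "M"].to_numpy()
        rows.append({
            "chromosome": chrom,
            "n": len(m),
            "q25": float(np.quantile(m, 0.25)),
            "median": float(np.median(m)),
            "q75": float(np.quantile(m, 0.75)),
        })
    return pd.DataFrame(rows,
                        columns=["chromosome", "n", "q25", "median", "q75"])


@dataclass(frozen=True)
class ZShiftResult:
    observed_shift: float
    p_value: float
    n_z: int
    n_autosomal: int
    n_permutations: int


def z_shift_test(ratios: pd.DataFrame, n_permutations: int = 999,
                 seed: int | None = None, z_label: str = "Z",
                 ) -> ZShiftResult:
    """One-sided permutation test of median(M on Z) - median(M elsewhere).

    Chromosome labels are permuted over contigs;
    p = (1 + #{permuted shift >= observed}) / (1 + n_permutations).
    """
    if n_permutations < 100:
        raise InvalidDesignError("n_permutations must be >= 100")
    work = ratios[ratios["chromosome"] != "unassigned"]
    chroms = work["chromosome"].to_numpy()
    if len(set(chroms)) < 2:
        raise InsufficientDataError("need >= 2 chromosomes")
    is_z = chroms == z_label
    n_z = int(is_z.sum())
    if n_z < 5:
        raise InsufficientDataError(
            f"only {n_z} contigs on {z_label!r}; need >= 5")
    m = work["M"].to_numpy()
    observed = float(np.median(m[is_z]) - np.median(m[~is_z]))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(is_z)
        shift = np.median(m[perm]) - np.median(m[~perm])
        if shift >= observed:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return ZShiftResult(observed, float(p), n_z, int(len(m) - n_z),
                        n_permutations)


def timecourse_profile(table: CountTable, contig_id: str,
                       norm_method: str = "cpm") -> pd.DataFrame:
    """Normalized abundance of one contig over time, infected vs
    uninfected, with the infected/uninfected ratio per timepoint."""
    if contig_id not in table.counts.index:
        raise NotFoundError(f"contig {contig_id!r} not in count table")
    norm = normalize(table, method=norm_method)
    rows = []
    for hpo in sorted(table.samples["hpo"].unique()):
        inf_ids = table.sample_ids(True, hpo)
        ctl_ids = table.sample_ids(False, hpo)
        if not inf_ids or not ctl_ids:
            continue
        vi = float(norm.loc[contig_id, inf_ids].mean())
        vu = float(norm.loc[contig_id, ctl_ids].mean())
        rows.append({"hpo": hpo, "uninfected": vu, "infected": vi,
                     "ratio": vi / vu if vu > 0 else np.nan})
    return pd.DataFrame(rows, columns=["hpo", "uninfected", "infected",
                                       "ratio"])


def bh_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
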