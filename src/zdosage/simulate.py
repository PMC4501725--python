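"""Synthetic data generation for the whole pipeline.

Emulates pooled-RNA transcriptomes of mixed-sex embryo batches under a
WZ/ZZ gene-dose model: Z-linked genes carry copy number 2 in ZZ males and
1 in WZ females; an active dosage-compensation mechanism halves male Z
output (male dose 1), and a compensation-failure factor ``f`` restores it
toward the uncompensated level (male dose ``f``, up to 2). A single
Z-linked "masc-like" regulator follows a unimodal temporal profile peaking
at 6 hours post-oviposition and is knocked down by factor ``d`` in
infected pools. Counts are negative-binomial around the dose-model
expectation. The module also simulates qPCR Ct tables for molecular
sexing and protein alignments evolved along a known tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .errors import InvalidDesignError, InvalidInputError
from .phylo import MsaBlock, Tree

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

_STD = CodonTable.unambiguous_dna_by_id[1]
CODONS_BY_AA: dict[str, list[str]] = {
    aa: sorted(c for c, a in _STD.forward_table.items() if a == aa)
    for aa in AMINO_ACIDS
}
STOP_CODONS = sorted(_STD.stop_codons)

# qPCR sexing genes: two Z-linked targets and one autosomal normalizer
GENE_TPI = "Tpi"
GENE_KETTIN = "kettin"
GENE_EF1A = "EF1a"
Z_SEXING_GENES = (GENE_TPI, GENE_KETTIN)
SEXING_GENES = (GENE_TPI, GENE_KETTIN, GENE_EF1A)

# unimodal expression profile of the masc-like gene in uninfected pools:
# piecewise linear with its maximum at 6 hpo, flat beyond the last knot
MASC_PROFILE_KNOTS = ((0.0, 1.0), (6.0, 3.0), (12.0, 1.0), (18.0, 0.5))

__all__ = [
    "SimDesign",
    "ReferenceGeneModel",
    "ReferenceSet",
    "GroundTruth",
    "simulate_reference",
    "masc_profile",
    "simulate_pool_counts",
    "simulate_experiment",
    "simulate_qpcr",
    "simulate_sexing_cohort",
    "evolve_alignment",
]


@dataclass(frozen=True)
class SimDesign:
    """Parameters of one synthetic experiment.

    ``compensation_failure_factor`` (f) is the Z dose of an infected ZZ
    male relative to a compensated one: 1 means compensation is intact,
    2 means it failed completely (doubled output). ``masc_knockdown`` (d)
    multiplies the masc-like gene's expression in infected pools.
    """

    n_chromosomes: int = 2
    genes_per_chromosome: int = 50
    male_fraction: float = 0.5
    compensation_failure_factor: float = 2.0
    masc_knockdown: float = 0.2
    dispersion: float = 0.05
    library_size: float = 1e6
    timepoints: tuple[float, ...] = (0.0, 12.0, 24.0, 36.0, 48.0)
    seed: int = 0
    protein_length: int = 80
    mutation_rate: float = 0.0
    base_expression_sigma: float = 1.0
    # compensation failure can switch on mid-timecourse: before this hpo
    # infected males are still fully compensated (effective f = 1)
    failure_onset_hpo: float | None = None

    def __post_init__(self):
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise InvalidDesignError("dimensions must be positive")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise InvalidDesignError("male_fraction must lie in [0, 1]")
        if not 1.0 <= self.compensation_failure_factor <= 2.0:
            raise InvalidDesignError(
                "compensation_failure_factor must lie in [1, 2]")
        if not 0.0 < self.masc_knockdown <= 1.0:
            raise InvalidDesignError("masc_knockdown must lie in (0, 1]")
        if self.dispersion < 0 or not math.isfinite(self.dispersion):
            raise InvalidDesignError("dispersion must be finite and >= 0")
        if self.library_size <= 0 or not math.isfinite(self.library_size):
            raise InvalidDesignError("library_size must be finite and > 0")
        if not self.timepoints:
            raise InvalidDesignError("at least one timepoint required")
        if any(t < 0 for t in self.timepoints):
            raise InvalidDesignError("timepoints must be >= 0")
        if self.protein_length < 1:
            raise InvalidDesignError("protein_length must be positive")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise InvalidDesignError("mutation_rate must lie in [0, 1)")
        if self.failure_onset_hpo is not None and self.failure_onset_hpo < 0:
            raise InvalidDesignError("failure_onset_hpo must be >= 0")

    @property
    def chromosomes(self) -> list[str]:
        return ["Z"] + [f"A{i}" for i in range(1, self.n_chromosomes)]


@dataclass(frozen=True)
class ReferenceGeneModel:
    gene_id: str
    chromosome: str
    protein: str = ""
    cds: str = ""
    base_expression: float = 1.0
    is_masc_like: bool = False


@dataclass
class ReferenceSet:
    """Gene models plus the derived transcript contigs and their origin."""

    genes: list[ReferenceGeneModel]
    contigs: list[tuple[str, str]]          # (contig_id, nucleotide seq)
    contig_to_gene: dict[str, str]

    def gene_by_id(self, gene_id: str) -> ReferenceGeneModel:
        return self._index()[gene_id]

    def _index(self) -> dict[str, ReferenceGeneModel]:
        if not hasattr(self, "_idx"):
            self._idx = {g.gene_id: g for g in self.genes}
        return self._idx

    @property
    def masc_like_gene(self) -> ReferenceGeneModel:
        return next(g for g in self.genes if g.is_masc_like)

    def contig_chromosomes(self) -> pd.Series:
        idx = self._index()
        return pd.Series(
            {cid: idx[gid].chromosome
             for cid, gid in self.contig_to_gene.items()},
            name="chromosome",
        )


@dataclass(frozen=True)
class GroundTruth:
    """What was actually simulated for one pool sample."""

    male_fraction: float
    compensation_failure_factor: float
    masc_knockdown: float
    infected: bool
    timepoint: float


def simulate_reference(design: SimDesign) -> ReferenceSet:
    """Reference gene models with chromosome labels, plus contigs derived
    from their CDSs (optionally mutated so homology assignment is
    nontrivial). Exactly one Z-linked gene is flagged masc-like.

    Byte-reproducible for a fixed design (seeded).
    """
    rng = np.random.default_rng([design.seed, 101])
    genes: list[ReferenceGeneModel] = []
    aa = np.array(list(AMINO_ACIDS))
    masc_index = int(rng.integers(design.genes_per_chromosome))  # on Z
    for ci, chrom in enumerate(design.chromosomes):
        for gi in range(design.genes_per_chromosome):
            protein = "".join(
                rng.choice(aa, size=design.protein_length))
            cds = "".join(
                CODONS_BY_AA[res][rng.integers(len(CODONS_BY_AA[res]))]
                for res in protein)
            cds += STOP_CODONS[rng.integers(len(STOP_CODONS))]
            base = float(np.exp(
                rng.normal(0.0, design.base_expression_sigma)))
            genes.append(ReferenceGeneModel(
                gene_id=f"{chrom}_g{gi:04d}",
                chromosome=chrom,
                protein=protein,
                cds=cds,
                base_expression=base,
                is_masc_like=(ci == 0 and gi == masc_index),
            ))

    order = rng.permutation(len(genes))
    contigs: list[tuple[str, str]] = []
    contig_to_gene: dict[str, str] = {}
    for k, gidx in enumerate(order):
        gene = genes[int(gidx)]
        seq = _mutate_nt(gene.cds, design.mutation_rate, rng)
        cid = f"t{k:05d}"
        contigs.append((cid, seq))
        contig_to_gene[cid] = gene.gene_id
    return ReferenceSet(genes, contigs, contig_to_gene)


def _mutate_nt(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alternatives = [b for b in NUCLEOTIDES if b != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


def masc_profile(timepoint: float, infected: bool, d: float = 1.0) -> float:
    """Expression multiplier of the masc-like gene: unimodal in time with
    its maximum at 6 hpo; infected pools are scaled down by ``d``."""
    if d <= 0:
        raise InvalidDesignError("masc_knockdown d must be > 0")
    if timepoint < 0:
        raise InvalidDesignError("timepoint must be >= 0")
    xs = [k[0] for k in MASC_PROFILE_KNOTS]
    ys = [k[1] for k in MASC_PROFILE_KNOTS]
    value = float(np.interp(timepoint, xs, ys))
    return value * d if infected else value


def _expected_counts(design: SimDesign, ref: ReferenceSet, infected: bool,
                     timepoint: float) -> np.ndarray:
    """Dose-model expectations, ordered like ``ref.contigs``.

    Scaling anchors the uninfected pool at exactly ``library_size``
    expected total reads; an infected pool under failed compensation
    carries proportionally more Z-derived reads (its total exceeds the
    library size by the pooled dose excess), so per-gene infected/
    uninfected count ratios equal the dose-model ratios exactly.
    """
    mf = design.male_fraction
    f = design.compensation_failure_factor
    if design.failure_onset_hpo is not None and \
            timepoint < design.failure_onset_hpo:
        f = 1.0
    male_dose = f if infected else 1.0
    z_pool_dose = mf * male_dose + (1.0 - mf) * 1.0

    idx = {g.gene_id: g for g in ref.genes}
    mu = np.empty(len(ref.contigs))
    denom = 0.0
    for k, (cid, _) in enumerate(ref.contigs):
        gene = idx[ref.contig_to_gene[cid]]
        dose = z_pool_dose if gene.chromosome == "Z" else 1.0
        mult = 1.0
        base_mult = 1.0
        if gene.is_masc_like:
            mult = masc_profile(timepoint, infected, design.masc_knockdown)
            base_mult = masc_profile(timepoint, False)
        mu[k] = gene.base_expression * dose * mult
        denom += gene.base_expression * base_mult
    return design.library_size * mu / denom


def simulate_pool_counts(design: SimDesign, ref: ReferenceSet,
                         infected: bool, timepoint: float,
                         noise: bool = True,
                         ) -> tuple[pd.Series, GroundTruth]:
    """One pooled-RNA library (counts per contig) for a mixed-sex embryo
    pool at the given timepoint.

    Counts are negative-binomial with variance mu + dispersion * mu^2
    (Poisson when dispersion is 0); ``noise=False`` returns the rounded
    expectations instead, for closed-form checks.
    """
    if timepoint not in design.timepoints:
        raise InvalidDesignError(
            f"timepoint {timepoint} not in design.timepoints")
    if not ref.genes:
        raise InvalidDesignError("empty reference set")
    mean = _expected_counts(design, ref, infected, timepoint)
    t_index = design.timepoints.index(timepoint)
    rng = np.random.default_rng(
        [design.seed, 211, t_index, int(infected)])
    if not noise:
        counts = np.rint(mean).astype(np.int64)
    elif design.dispersion == 0.0:
        counts = rng.poisson(mean)
    else:
        size = 1.0 / design.dispersion
        p = size / (size + mean)
        counts = rng.negative_binomial(size, p)
    series = pd.Series(counts, index=[cid for cid, _ in ref.contigs],
                       dtype=np.int64)
    truth = GroundTruth(design.male_fraction,
                        design.compensation_failure_factor,
                        design.masc_knockdown, infected, timepoint)
    return series, truth


def simulate_experiment(design: SimDesign, ref: ReferenceSet | None = None,
                        noise: bool = True,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, ReferenceSet]:
    """Full design: one infected and one uninfected library per timepoint.

    Returns (counts, sample sheet, reference). Counts is a contig x sample
    integer DataFrame; the sample sheet has columns sample_id, hpo,
    infected, indexed by sample_id.
    """
    if ref is None:
        ref = simulate_reference(design)
    columns: dict[str, pd.Series] = {}
    meta: list[dict] = []
    for t in design.timepoints:
        for infected in (False, True):
            tag = "inf" if infected else "ctl"
            sid = f"{tag}_{t:g}hpo"
            counts, _ = simulate_pool_counts(design, ref, infected, t,
                                             noise=noise)
            columns[sid] = counts
            meta.append({"sample_id": sid, "hpo": t, "infected": infected})
    counts_df = pd.DataFrame(columns)
    samples = pd.DataFrame(meta).set_index("sample_id", drop=False)
    return counts_df, samples, ref


# ---------------------------------------------------------------------------
# qPCR sexing simulation
# ---------------------------------------------------------------------------

def simulate_qpcr(sex: str, efficiency: float = 1.0, noise_sd: float = 0.0,
                  seed: int | None = None, base_ct: float = 20.0,
                  ) -> dict[str, float]:
    """Ct values for the two Z-linked sexing genes and the autosomal
    normalizer for a single individual.

    Ct = base_ct - log(dose) / log(1 + efficiency) + N(0, noise_sd); the
    Z-gene dose is 2 for ZZ and 1 for WZ, the normalizer dose is 2 in
    both sexes. At efficiency 1 and zero noise a WZ individual's Z-gene
    Ct is exactly one cycle later than a ZZ individual's.
    """
    if not 0.0 < efficiency <= 1.0:
        raise InvalidDesignError("efficiency must lie in (0, 1]")
    if sex not in ("WZ", "ZZ"):
        raise InvalidInputError(f"sex must be 'WZ' or 'ZZ', got {sex!r}")
    if noise_sd < 0:
        raise InvalidDesignError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    log_base = math.log(1.0 + efficiency)
    out: dict[str, float] = {}
    for gene in SEXING_GENES:
        if gene in Z_SEXING_GENES:
            dose = 2.0 if sex == "ZZ" else 1.0
        else:
            dose = 2.0
        ct = base_ct - math.log(dose) / log_base
        if noise_sd > 0:
            ct += rng.normal(0.0, noise_sd)
        out[gene] = float(ct)
    return out


def simulate_sexing_cohort(n_individuals: int, male_fraction: float = 0.5,
                           efficiency: float = 1.0, noise_sd: float = 0.0,
                           seed: int | None = None, base_ct: float = 20.0,
                           ) -> tuple[pd.DataFrame, pd.Series]:
    """Ct table (individual_id, gene, ct, replicate) for a cohort with the
    given expected male fraction, plus the true karyotype per individual."""
    if n_individuals < 1:
        raise InvalidDesignError("n_individuals must be positive")
    if not 0.0 <= male_fraction <= 1.0:
        raise InvalidDesignError("male_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    truth = {}
    for i in range(n_individuals):
        iid = f"ind{i:04d}"
        sex = "ZZ" if rng.random() < male_fraction else "WZ"
        truth[iid] = sex
        cts = simulate_qpcr(sex, efficiency, noise_sd,
                            seed=rng.integers(2**63), base_ct=base_ct)
        for gene, ct in cts.items():
            rows.append({"individual_id": iid, "gene": gene,
                         "ct": ct, "replicate": 1})
    table = pd.DataFrame(rows)
    return table, pd.Series(truth, name="sex")


# ---------------------------------------------------------------------------
# alignment evolution along a known tree
# ---------------------------------------------------------------------------

def evolve_alignment(tree: Tree, seq_length: int,
                     seed: int | None = None) -> MsaBlock:
    """Evolve a gap-free protein alignment down ``tree``.

    Substitution events per branch are Poisson with mean
    branch_length * seq_length; each event replaces a uniformly chosen
    site with a uniformly chosen different residue (symmetric model,
    independent columns).
    """
    leaves = tree.leaves()
    if not leaves:
        raise InvalidInputError("tree has no leaves")
    if any(lf.name is None for lf in leaves):
        raise InvalidInputError("every leaf needs a name")
    if seq_length < 1:
        raise InvalidInputError("seq_length must be positive")
    for node in tree.root.walk():
        if node.length < 0:
            raise InvalidInputError("negative branch length")
    rng = np.random.default_rng(seed)
    n_aa = len(AMINO_ACIDS)
    root_seq = rng.integers(0, n_aa, size=seq_length)

    taxa: list[str] = []
    rows: list[str] = []

    def descend(node: Node, seq: np.ndarray):
        for child in node.children:
            child_seq = seq.copy()
            n_events = rng.poisson(child.length * seq_length)
            for _ in range(n_events):
                pos = int(rng.integers(seq_length))
                shift = 1 + int(rng.integers(n_aa - 1))
                child_seq[pos] = (child_seq[pos] + shift) % n_aa
            if child.is_leaf:
                taxa.append(child.name)
                rows.append("".join(AMINO_ACIDS[k] for k in child_seq))
            else:
                descend(child, child_seq)

    if tree.root.is_leaf:  # degenerate single-leaf tree
        taxa.append(tree.root.name)
        rows.append("".join(AMINO_ACIDS[k] for k in root_seq))
    else:
        descend(tree.root, root_seq)
    return MsaBlock(taxa, rows)
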