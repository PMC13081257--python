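"""Founder sampling, pedigree gene dropping, and pseudo-haploid observations.

A desk-scale observation model for low-coverage ancient-DNA relatedness
benchmarks.  Founder genotypes are drawn under Hardy-Weinberg equilibrium
from a per-site allele-frequency spectrum, descendants are generated by
Mendelian gene dropping with Haldane (no-interference) crossovers, and the
sequencing process is emulated at the called-site level: Poisson depth per
site, a single uniformly chosen read per covered site (pseudo-haploid calling
at minimum depth 1), optional contamination from a single contaminant
individual at a fixed rate, and a symmetric allele-flip error standing in for
residual damage and sequencing error.

Under this model a pair with relationship coefficient ``r`` has expected
pairwise mismatch rate ``(1 - r/2) * mean(2 p (1 - p))`` when error and
contamination are zero -- the identity the benchmark's calibration checks
rely on.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pedigree import Pedigree

__all__ = [
    "FrequencySpectrum",
    "GenotypeMatrix",
    "ObservationConfig",
    "ObservationMatrix",
    "sample_founders",
    "gene_drop",
    "simulate_observations",
    "expected_unrelated_pmr",
]

MISSING = -1  # observation sentinel: site not covered by any read


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class FrequencySpectrum:
    """Per-site alternate-allele frequencies ``p_s`` in [0, 1].

    ``labels`` optionally carries site identifiers (e.g. chrom:pos) for
    serialisation; it plays no role in the maths.
    """

    freqs: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        freqs = np.asarray(self.freqs, dtype=float)
        if freqs.ndim != 1 or freqs.size < 1:
            raise ValueError("frequency spectrum must be a non-empty 1-D array")
        if np.any((freqs < 0) | (freqs > 1)) or np.any(~np.isfinite(freqs)):
            raise ValueError("allele frequencies must lie in [0, 1]")
        object.__setattr__(self, "freqs", freqs)
        if self.labels is not None and len(self.labels) != freqs.size:
            raise ValueError("labels length must match site count")

    @property
    def n_sites(self) -> int:
        return int(self.freqs.size)

    @classmethod
    def uniform(cls, n_sites: int, low: float = 0.05, high: float = 0.95,
                seed=None) -> "FrequencySpectrum":
        """Frequencies drawn uniformly on [low, high]."""
        rng = _as_rng(seed)
        return cls(rng.uniform(low, high, size=n_sites))

    @classmethod
    def beta(cls, n_sites: int, a: float = 0.5, b: float = 0.5,
             low: float = 0.01, seed=None) -> "FrequencySpectrum":
        """Beta-distributed frequencies, clipped away from fixation.

        The default Beta(0.5, 0.5) is U-shaped, mimicking a neutral site
        frequency spectrum ascertained away from fixed sites.
        """
        rng = _as_rng(seed)
        p = np.clip(rng.beta(a, b, size=n_sites), low, 1.0 - low)
        return cls(p)

    @classmethod
    def from_table(cls, text: str) -> "FrequencySpectrum":
        """Parse a two-column text table: site-id, frequency."""
        labels, freqs = [], []
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"line {lineno}: expected 2 columns")
            labels.append(fields[0])
            freqs.append(float(fields[1]))
        if not freqs:
            raise ValueError("empty frequency table")
        return cls(np.asarray(freqs), tuple(labels))

    def to_table(self) -> str:
        labels = self.labels or tuple(
            f"site{i}" for i in range(self.n_sites)
        )
        buf = io.StringIO()
        for lab, p in zip(labels, self.freqs):
            buf.write(f"{lab}\t{p:.6g}\n")
        return buf.getvalue()


def expected_unrelated_pmr(freqs: FrequencySpectrum) -> float:
    """Expected pairwise mismatch rate between two unrelated individuals:
    the mean over sites of ``2 p (1 - p)``."""
    p = freqs.freqs
    return float(np.mean(2.0 * p * (1.0 - p)))


@dataclass
class GenotypeMatrix:
    """Diploid genotypes: ``alleles[individual, site, haplotype]`` in {0, 1}."""

    ids: tuple[str, ...]
    alleles: np.ndarray  # (n, L, 2) int8

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n, L, 2)")
        if len(self.ids) != self.alleles.shape[0]:
            raise ValueError("ids length must match allele rows")

    @property
    def n_sites(self) -> int:
        return int(self.alleles.shape[1])

    def row(self, iid: str) -> np.ndarray:
        return self.alleles[self.ids.index(iid)]

    def to_table(self) -> str:
        """Tab-separated layout: one row per individual, genotypes as
        ``a|b`` per site."""
        buf = io.StringIO()
        for k, iid in enumerate(self.ids):
            genos = "\t".join(
                f"{a}|{b}" for a, b in self.alleles[k]
            )
            buf.write(f"{iid}\t{genos}\n")
        return buf.getvalue()


@dataclass
class ObservationMatrix:
    """Pseudo-haploid calls: ``calls[individual, site]`` in {0, 1, -1};
    -1 marks a site with sampled depth zero."""

    ids: tuple[str, ...]
    calls: np.ndarray  # (n, L) int8

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must have shape (n, L)")
        if len(self.ids) != self.calls.shape[0]:
            raise ValueError("ids length must match call rows")

    @property
    def n_sites(self) -> int:
        return int(self.calls.shape[1])

    def row(self, iid: str) -> np.ndarray:
        return self.calls[self.ids.index(iid)]

    def to_table(self) -> str:
        buf = io.StringIO()
        for k, iid in enumerate(self.ids):
            row = "\t".join(
                "." if c == MISSING else str(int(c)) for c in self.calls[k]
            )
            buf.write(f"{iid}\t{row}\n")
        return buf.getvalue()


@dataclass
class ObservationConfig:
    """Sequencing-process parameters for :func:`simulate_observations`.

    coverage
        Mean read depth per site (Poisson rate); "0.1X" maps to 0.1.
    contamination
        Probability that any given read originates from the contaminant.
    error
        Symmetric allele-flip probability per sampled read, in [0, 0.5].
    contaminant
        Diploid genotype row of the single contaminating individual, shape
        (L, 2); required whenever ``contamination > 0``.
    seed
        Fixes all randomness (int, SeedSequence or Generator).
    """

    coverage: float
    contamination: float = 0.0
    error: float = 0.0
    contaminant: np.ndarray | None = None
    seed: object = None

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.contamination <= 1.0:
            raise ValueError("contamination rate must lie in [0, 1]")
        if not 0.0 <= self.error <= 0.5:
            raise ValueError("allele-flip error must lie in [0, 0.5]")
        if self.contamination > 0 and self.contaminant is None:
            raise ValueError(
                "a contaminant genotype row is required when contamination > 0"
            )


def sample_founders(
    freqs: FrequencySpectrum, n: int, seed=None
) -> GenotypeMatrix:
    """Draw ``n`` founder genotypes under Hardy-Weinberg equilibrium: each
    haplotype allele is an independent Bernoulli(p_s) draw."""
    if n < 1:
        raise ValueError("need at least one founder")
    rng = _as_rng(seed)
    p = freqs.freqs
    alleles = (rng.random((n, p.size, 2)) < p[None, :, None]).astype(np.int8)
    return GenotypeMatrix(tuple(f"founder{k}" for k in range(n)), alleles)


def _chromosome_slices(n_sites: int, n_chromosomes: int) -> list[slice]:
    bounds = np.linspace(0, n_sites, n_chromosomes + 1).astype(int)
    return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def _gamete(parent: np.ndarray, slices: list[slice], chrom_morgans: float,
            rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete under the Haldane model.

    Crossover counts are Poisson with mean equal to the chromosome's genetic
    length; breakpoints are uniform along the chromosome; sites are assumed
    evenly spaced in genetic distance.
    """
    L = parent.shape[0]
    gamete = np.empty(L, dtype=np.int8)
    for sl in slices:
        n_sites = sl.stop - sl.start
        start_hap = rng.integers(2)
        n_x = rng.poisson(chrom_morgans)
        if n_x == 0:
            hap_idx = np.full(n_sites, start_hap)
        else:
            breaks = np.sort(rng.random(n_x))
            pos = (np.arange(n_sites) + 0.5) / n_sites
            hap_idx = (start_hap + np.searchsorted(breaks, pos)) % 2
        gamete[sl.start:sl.stop] = parent[sl, :][np.arange(n_sites), hap_idx]
    return gamete


def gene_drop(
    ped: Pedigree,
    founders: GenotypeMatrix,
    map_length_morgans: float = 35.0,
    n_chromosomes: int = 22,
    seed=None,
) -> GenotypeMatrix:
    """Drop founder genotypes through the pedigree.

    Founder rows of ``founders`` are assigned to pedigree founders in
    topological order.  Each transmitted gamete is formed under the Haldane
    crossover model; sites are partitioned evenly across ``n_chromosomes``
    chromosomes sharing the total genetic map length equally.  Twin
    duplicates receive their source's genotypes verbatim.
    """
    rng = _as_rng(seed)
    founder_ids = ped.founders
    if founders.alleles.shape[0] < len(founder_ids):
        raise ValueError(
            f"need {len(founder_ids)} founder genotype rows, "
            f"got {founders.alleles.shape[0]}"
        )
    L = founders.n_sites
    slices = _chromosome_slices(L, n_chromosomes)
    chrom_morgans = map_length_morgans / len(slices)
    genomes: dict[str, np.ndarray] = {}
    founder_iter = iter(range(founders.alleles.shape[0]))
    for ind in ped.members:  # topological order: parents precede children
        iid = ind.id
        if iid in ped.twin_of:
            continue  # filled after the source below
        if ind.is_founder:
            genomes[iid] = founders.alleles[next(founder_iter)].copy()
        else:
            pat = _gamete(genomes[ind.father_id], slices, chrom_morgans, rng)
            mat = _gamete(genomes[ind.mother_id], slices, chrom_morgans, rng)
            genomes[iid] = np.stack([pat, mat], axis=1)
    for twin, src in ped.twin_of.items():
        genomes[twin] = genomes[ped._twin_source(twin)].copy()
    ids = ped.ids
    return GenotypeMatrix(ids, np.stack([genomes[i] for i in ids]))


def simulate_observations(
    genotypes: GenotypeMatrix, cfg: ObservationConfig
) -> ObservationMatrix:
    """Emulate pseudo-haploid variant calling at minimum depth 1.

    Per individual and site: depth ``d ~ Poisson(coverage)``; ``d = 0``
    yields a missing call; otherwise one read is chosen uniformly.  The
    chosen read's source genotype is the contaminant with probability
    ``contamination`` (else the endogenous genotype); the read carries one
    uniformly chosen allele of its source, flipped with probability
    ``error``.
    """
    rng = _as_rng(cfg.seed)
    geno = genotypes.alleles
    n, L, _ = geno.shape
    depth = rng.poisson(cfg.coverage, size=(n, L))
    covered = depth > 0
    hap = rng.integers(2, size=(n, L))
    calls = np.take_along_axis(geno, hap[:, :, None], axis=2)[:, :, 0]
    if cfg.contamination > 0:
        cont = np.asarray(cfg.contaminant, dtype=np.int8)
        if cont.shape != (L, 2):
            raise ValueError("contaminant genotype row must have shape (L, 2)")
        from_cont = rng.random((n, L)) < cfg.contamination
        cont_hap = rng.integers(2, size=(n, L))
        cont_calls = cont[np.arange(L)[None, :], cont_hap]
        calls = np.where(from_cont, cont_calls, calls)
    if cfg.error > 0:
        flip = rng.random((n, L)) < cfg.error
        calls = np.where(flip, 1 - calls, calls)
    calls = np.where(covered, calls, MISSING).astype(np.int8)
    return ObservationMatrix(genotypes.ids, calls)
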