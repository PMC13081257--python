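"""Pairwise mismatch rates, normalisation, and r-coefficient derivations.

The pairwise mismatch rate (PMR) between two pseudo-haploid call vectors is
the fraction of jointly covered sites at which the calls differ.  Its
expectation scales with the cohort's heterozygosity, so raw PMR values are
normalised either by the cohort median (the READ/READv2/KIN convention,
appropriate when most pairs are unrelated) or by a reference expectation of
the unrelated PMR (the GRUPS-rs convention).  From a normalised value
``P0`` the coefficient of relationship follows as ``r = 2 (1 - P0)``.

The module also evaluates the Queller & Goodnight single-locus estimator in
its pseudo-haploid adaptation (the TKGWV2 backend): ``r = 1`` when the two
sampled alleles are identical, and ``r = 1 - 1/(2p) - 1/(2(1-p))`` on a
mismatch at allele frequency ``p``; and it converts the native statistics of
six published tools (READ, READv2, KIN, GRUPS-rs, correctKin, TKGWV2) into r
coefficients through configurable column maps.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import DEFAULT_GRID, DegreeGrid
from .simulate import MISSING, FrequencySpectrum, ObservationMatrix

__all__ = [
    "PairwiseObservation",
    "NormalisationContext",
    "ToolOutputRecord",
    "PairEstimate",
    "ZeroOverlapError",
    "pairwise_mismatch",
    "all_pairwise_mismatches",
    "median_normalise",
    "r_from_p0",
    "r_from_grups",
    "r_from_kin",
    "r_from_phi",
    "qg_single_locus",
    "qg_aggregate",
    "parse_tool_output",
    "derive_r",
    "TOOLS",
    "DEFAULT_COLUMN_MAPS",
]


class ZeroOverlapError(ValueError):
    """Raised when a pair shares no jointly covered site."""


@dataclass(frozen=True)
class PairwiseObservation:
    """Overlap, mismatch count and PMR for one unordered pair."""

    pair: tuple[str, str]
    overlap: int
    mismatches: int

    @property
    def pmr(self) -> float:
        return self.mismatches / self.overlap


@dataclass(frozen=True)
class NormalisationContext:
    """How raw PMR values are scaled to normalised P0 estimates.

    mode
        ``cohort-median`` divides by the median PMR over all supplied pairs;
        ``fixed-value`` and ``reference-expectation`` divide by ``value``
        (the latter name documents that the constant is an expected
        unrelated PMR rather than an arbitrary number).
    """

    mode: str = "cohort-median"
    value: float | None = None

    def __post_init__(self):
        if self.mode not in ("cohort-median", "fixed-value", "reference-expectation"):
            raise ValueError(f"unknown normalisation mode: {self.mode!r}")
        if self.mode != "cohort-median":
            if self.value is None or not np.isfinite(self.value) or self.value <= 0:
                raise ValueError("normalisation value must be finite and positive")


@dataclass(frozen=True)
class ToolOutputRecord:
    """One pair's native statistics as reported by an external tool."""

    tool: str
    pair: tuple[str, str]
    stats: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PairEstimate:
    """Final per-pair estimate: r coefficient and ordinal degree class."""

    pair: tuple[str, str]
    r_hat: float
    predicted_class: str


def pairwise_mismatch(
    obs_i: np.ndarray, obs_j: np.ndarray, pair: tuple[str, str] = ("i", "j")
) -> PairwiseObservation:
    """Overlap and mismatch counts between two pseudo-haploid call rows."""
    a = np.asarray(obs_i)
    b = np.asarray(obs_j)
    if a.shape != b.shape:
        raise ValueError("call vectors must have equal site counts")
    both = (a != MISSING) & (b != MISSING)
    overlap = int(both.sum())
    if overlap == 0:
        raise ZeroOverlapError(f"pair {pair} shares no covered site")
    mism = int((a[both] != b[both]).sum())
    return PairwiseObservation(pair, overlap, mism)


def all_pairwise_mismatches(
    obs: ObservationMatrix, pairs=None
) -> list[PairwiseObservation]:
    """PMR for every requested pair (default: all unordered pairs)."""
    if pairs is None:
        n = len(obs.ids)
        pairs = [
            (obs.ids[i], obs.ids[j]) for i in range(n) for j in range(i + 1, n)
        ]
    return [
        pairwise_mismatch(obs.row(i), obs.row(j), (i, j)) for i, j in pairs
    ]


def median_normalise(
    pmrs: list[PairwiseObservation], ctx: NormalisationContext
) -> dict[tuple[str, str], float]:
    """Normalised P0 per pair under the given context.

    The median convention for even pair counts is the mean of the two
    central values (numpy's default).
    """
    if not pmrs:
        raise ValueError("no pairs to normalise")
    if ctx.mode == "cohort-median":
        if len(pmrs) < 3:
            warnings.warn(
                "cohort-median normalisation over fewer than 3 pairs is "
                "unlikely to be meaningful",
                stacklevel=2,
            )
        denom = float(np.median([p.pmr for p in pmrs]))
        if denom == 0:
            raise ValueError("cohort median PMR is zero")
    else:
        denom = float(ctx.value)
    return {p.pair: p.pmr / denom for p in pmrs}


# ----------------------------------------------------------- r-coefficients

def r_from_p0(p0_norm: float) -> float:
    """READ convention: r = 2 (1 - normalised P0)."""
    if p0_norm < 0:
        raise ValueError("normalised P0 must be non-negative")
    return 2.0 * (1.0 - p0_norm)


def r_from_grups(pwd_obs: float, pwd_unrel: float) -> float:
    """GRUPS-rs convention: r = 2 (1 - PWD_obs / PWD_unrelated)."""
    if pwd_unrel <= 0:
        raise ValueError("expected unrelated PWD must be positive")
    return 2.0 * (1.0 - pwd_obs / pwd_unrel)


def r_from_kin(k1: float, k2: float) -> float:
    """KIN convention from Cotterman coefficients: r = k1/2 + k2."""
    if not (0.0 <= k1 <= 1.0 and 0.0 <= k2 <= 1.0 and k1 + k2 <= 1.0 + 1e-12):
        raise ValueError("Cotterman coefficients must satisfy 0 <= k1, k2, k1+k2 <= 1")
    return k1 / 2.0 + k2


def r_from_phi(phi: float) -> float:
    """correctKin/TKGWV2 convention from a kinship coefficient: r = 2 phi."""
    if not np.isfinite(phi):
        raise ValueError("kinship coefficient must be finite")
    return 2.0 * phi


def qg_single_locus(a_i: int, a_j: int, p: float) -> float:
    """Queller & Goodnight single-locus estimate for pseudo-haploid alleles.

    Identical alleles give 1; a mismatch at allele frequency ``p`` gives
    ``1 - 1/(2p) - 1/(2(1-p))`` (symmetric in p <-> 1-p).  Fixed sites
    (p in {0, 1}) are undefined on a mismatch and must be excluded upstream.
    """
    if a_i == a_j:
        return 1.0
    if not 0.0 < p < 1.0:
        raise ValueError("fixed site (p in {0, 1}) is undefined on a mismatch")
    return 1.0 - 1.0 / (2.0 * p) - 1.0 / (2.0 * (1.0 - p))


def qg_aggregate(
    calls_i: np.ndarray, calls_j: np.ndarray, freqs: FrequencySpectrum
) -> float:
    """Unweighted mean of the single-locus estimator over overlapping,
    non-fixed sites."""
    a = np.asarray(calls_i)
    b = np.asarray(calls_j)
    p = freqs.freqs
    if a.shape != b.shape or a.shape != p.shape:
        raise ValueError("call vectors and frequencies must align")
    usable = (a != MISSING) & (b != MISSING) & (p > 0.0) & (p < 1.0)
    if not usable.any():
        raise ZeroOverlapError("no overlapping non-fixed site")
    pa, aa, bb = p[usable], a[usable], b[usable]
    values = np.where(
        aa == bb, 1.0, 1.0 - 1.0 / (2.0 * pa) - 1.0 / (2.0 * (1.0 - pa))
    )
    return float(values.mean())


# ------------------------------------------------------------- tool outputs

TOOLS = ("READ", "READv2", "KIN", "GRUPS-rs", "correctKin", "TKGWV2")

#: which native statistics each tool reports, and the default column names
#: used when parsing its output table.  Exact headers vary across tool
#: versions; callers override per file via ``column_map``.
DEFAULT_COLUMN_MAPS: dict[str, dict[str, str]] = {
    "READ": {"id1": "id1", "id2": "id2", "p0": "p0_norm"},
    "READv2": {"id1": "id1", "id2": "id2", "r": "r"},
    "KIN": {"id1": "id1", "id2": "id2", "k1": "k1", "k2": "k2"},
    "GRUPS-rs": {"id1": "id1", "id2": "id2", "pwd_obs": "pwd_obs",
                 "pwd_unrel": "pwd_unrel"},
    "correctKin": {"id1": "id1", "id2": "id2", "phi": "phi",
                   "status": "status"},
    "TKGWV2": {"id1": "id1", "id2": "id2", "phi": "phi"},
}

#: statistic fields (everything except the pair ids) required per tool
_REQUIRED_STATS = {
    "READ": ("p0",),
    "READv2": ("r",),
    "KIN": ("k1", "k2"),
    "GRUPS-rs": ("pwd_obs", "pwd_unrel"),
    "correctKin": ("phi",),
    "TKGWV2": ("phi",),
}

#: optional per-tool fields (parsed when mapped and present)
_OPTIONAL_STATS = {"correctKin": ("status",)}


def parse_tool_output(
    text: str, tool: str, column_map: dict[str, str] | None = None,
    sep: str = "\t",
) -> list[ToolOutputRecord]:
    """Parse a tool's delimited output table into per-pair records.

    ``column_map`` binds the required fields (pair ids plus the tool's
    native statistics) to column names of the file; defaults per tool are in
    :data:`DEFAULT_COLUMN_MAPS`.  correctKin semantics are honoured
    downstream: pairs absent from its output are unrelated, and rows whose
    mapped ``status`` column reads "uncertain" are reclassified unrelated.
    """
    if tool not in TOOLS:
        raise ValueError(f"unknown tool: {tool!r}")
    cmap = dict(DEFAULT_COLUMN_MAPS[tool])
    if column_map:
        cmap.update(column_map)
    frame = pd.read_csv(io.StringIO(text), sep=sep)
    required = ("id1", "id2") + _REQUIRED_STATS[tool]
    for fieldname in required:
        if cmap.get(fieldname) not in frame.columns:
            raise ValueError(
                f"column {cmap.get(fieldname)!r} (field {fieldname!r}) "
                f"missing from {tool} output"
            )
    optional = [
        f for f in _OPTIONAL_STATS.get(tool, ())
        if cmap.get(f) in frame.columns
    ]
    records = []
    for _, row in frame.iterrows():
        stats = {}
        for fieldname in _REQUIRED_STATS[tool]:
            value = row[cmap[fieldname]]
            try:
                stats[fieldname] = float(value)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric value {value!r} in column "
                    f"{cmap[fieldname]!r}"
                ) from None
        for fieldname in optional:
            stats[fieldname] = str(row[cmap[fieldname]])
        pair = (str(row[cmap["id1"]]), str(row[cmap["id2"]]))
        records.append(ToolOutputRecord(tool, pair, stats))
    return records


def derive_r(record: ToolOutputRecord) -> float:
    """Convert a tool's native statistics into an r coefficient."""
    stats = record.stats
    if record.tool == "READ":
        return r_from_p0(stats["p0"])
    if record.tool == "READv2":
        return float(stats["r"])
    if record.tool == "KIN":
        return r_from_kin(stats["k1"], stats["k2"])
    if record.tool == "GRUPS-rs":
        return r_from_grups(stats["pwd_obs"], stats["pwd_unrel"])
    if record.tool in ("correctKin", "TKGWV2"):
        if record.tool == "correctKin" and (
            stats.get("status", "").strip().lower() == "uncertain"
        ):
            return 0.0
        return r_from_phi(stats["phi"])
    raise ValueError(f"unknown tool: {record.tool!r}")


def classify_records(
    records: list[ToolOutputRecord], grid: DegreeGrid = DEFAULT_GRID
) -> list[PairEstimate]:
    """r derivation plus ordinal classification for a batch of records."""
    out = []
    for record in records:
        r = derive_r(record)
        out.append(PairEstimate(record.pair, r, grid.classify(r)))
    return out
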