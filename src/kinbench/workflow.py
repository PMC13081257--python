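"""Configuration-driven benchmark orchestration.

Runs replicate simulate -> observe -> estimate -> classify -> score loops on
synthetic data, or scores externally produced tool outputs against a truth
pedigree, and emits machine-readable report tables.  All randomness flows
from the single configured seed through per-condition/per-replicate derived
seeds, so a given configuration is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimators, fixtures, metrics
from .pedigree import DEFAULT_GRID, DegreeGrid, Pedigree
from .simulate import (
    FrequencySpectrum,
    ObservationConfig,
    expected_unrelated_pmr,
    gene_drop,
    sample_founders,
    simulate_observations,
)

__all__ = ["BenchmarkConfig", "BenchmarkReport", "run_benchmark",
           "evaluate_external"]

logger = logging.getLogger(__name__)


@dataclass
class BenchmarkConfig:
    """Parameters of one synthetic benchmark run.

    Coverage values are mean depths per site ("0.1X" -> 0.1); the
    contaminant is always a single additional unrelated individual drawn
    from the same frequency spectrum, mixed in at ``contamination`` per
    read across all samples.
    """

    pedigree: str = ""                      # trio-format text (inline)
    pedigree_file: str | None = None        # or a path to one
    twins: list[str] = field(default_factory=list)
    pairs: list[tuple[str, str]] | None = None  # default: all pairs
    n_sites: int = 20_000
    freq_low: float = 0.05
    freq_high: float = 0.95
    freq_file: str | None = None
    replicates: int = 10
    coverages: list[float] = field(default_factory=lambda: [0.1, 0.5])
    contamination: float = 0.0
    error: float = 0.0
    map_length_morgans: float = 35.0
    n_chromosomes: int = 22
    normalisation: str = "cohort-median"    # or "reference-expectation"
    seed: int = 0
    out_dir: str = "kinbench-report"

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if not self.coverages or any(c <= 0 for c in self.coverages):
            raise ValueError("coverage grid values must be positive")
        if self.normalisation not in ("cohort-median", "reference-expectation"):
            raise ValueError(f"unknown normalisation: {self.normalisation!r}")

    @classmethod
    def from_yaml(cls, path) -> "BenchmarkConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "pairs" in raw and raw["pairs"] is not None:
            raw["pairs"] = [tuple(p) for p in raw["pairs"]]
        return cls(**raw)

    def build_pedigree(self) -> Pedigree:
        if self.pedigree_file:
            ped = Pedigree.from_file(self.pedigree_file)
        elif self.pedigree:
            ped = Pedigree.from_text(self.pedigree)
        else:
            ped = Pedigree.from_text(fixtures.PEDIGREE_11)
        for iid in self.twins:
            ped = ped.duplicate_individual(iid)
        return ped


@dataclass
class BenchmarkReport:
    """Aggregated benchmark outputs, one row set per coverage condition."""

    uoc_table: pd.DataFrame          # coverage, mean UOC, CI bounds, n
    confusion: dict[float, metrics.ConfusionMatrix]
    deviation_table: pd.DataFrame    # per coverage x degree nRMSD/nMBE + CIs
    onevsall_table: pd.DataFrame
    auc: float | None

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.uoc_table.to_csv(out / "uoc.tsv", sep="\t", index=False)
        self.deviation_table.to_csv(out / "deviation.tsv", sep="\t", index=False)
        self.onevsall_table.to_csv(out / "onevsall.tsv", sep="\t")
        for coverage, cm in self.confusion.items():
            cm.to_frame().to_csv(
                out / f"confusion_{coverage:g}X.tsv", sep="\t"
            )
        summary = {
            "auc_one_minus_uoc": self.auc,
            "conditions": self.uoc_table.to_dict(orient="records"),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        return out


def _replicate_rng(seed: int, condition: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(condition, replicate))
    )


def _spectrum(cfg: BenchmarkConfig, rng) -> FrequencySpectrum:
    if cfg.freq_file:
        return FrequencySpectrum.from_table(Path(cfg.freq_file).read_text())
    return FrequencySpectrum.uniform(
        cfg.n_sites, cfg.freq_low, cfg.freq_high, seed=rng
    )


def simulate_replicate(
    cfg: BenchmarkConfig,
    ped: Pedigree,
    coverage: float,
    rng: np.random.Generator,
    grid: DegreeGrid = DEFAULT_GRID,
):
    """One replicate: genotypes -> observations -> per-pair r estimates.

    Returns ``(estimates, truths)`` where both are dicts keyed by pair.
    """
    freqs = _spectrum(cfg, rng)
    n_founders = len(ped.founders)
    extra = 1 if cfg.contamination > 0 else 0
    founders = sample_founders(freqs, n_founders + extra, seed=rng)
    genotypes = gene_drop(
        ped, founders, cfg.map_length_morgans, cfg.n_chromosomes, seed=rng
    )
    contaminant = founders.alleles[-1] if extra else None
    obs = simulate_observations(
        genotypes,
        ObservationConfig(
            coverage=coverage,
            contamination=cfg.contamination,
            error=cfg.error,
            contaminant=contaminant,
            seed=rng,
        ),
    )
    pmrs = estimators.all_pairwise_mismatches(obs)  # cohort = all pairs
    if cfg.normalisation == "cohort-median":
        ctx = estimators.NormalisationContext("cohort-median")
    else:
        ctx = estimators.NormalisationContext(
            "reference-expectation", expected_unrelated_pmr(freqs)
        )
    p0 = estimators.median_normalise(pmrs, ctx)
    eval_pairs = cfg.pairs or list(ped.pairs())
    ests, truths = {}, {}
    for pair in eval_pairs:
        i, j = pair
        key = (i, j) if (i, j) in p0 else (j, i)
        r_hat = estimators.r_from_p0(p0[key])
        ests[pair] = estimators.PairEstimate(pair, r_hat, grid.classify(r_hat))
        truths[pair] = grid.classify(ped.expected_r(i, j))
    return ests, truths


def run_benchmark(
    cfg: BenchmarkConfig, grid: DegreeGrid = DEFAULT_GRID
) -> BenchmarkReport:
    """Full replicate benchmark across the coverage grid."""
    ped = cfg.build_pedigree()
    uoc_rows, dev_rows = [], []
    confusion: dict[float, metrics.ConfusionMatrix] = {}
    onevsall_frames = []
    for cond_idx, coverage in enumerate(cfg.coverages):
        t0 = time.perf_counter()
        replicate_uocs = []
        truths_all, preds_all = [], []
        r_by_degree: dict[str, list[float]] = {c: [] for c in grid.classes}
        for rep in range(cfg.replicates):
            rng = _replicate_rng(cfg.seed, cond_idx, rep)
            try:
                ests, truths = simulate_replicate(cfg, ped, coverage, rng, grid)
            except Exception:
                logger.exception(
                    "replicate %d at %.3gX aborted", rep, coverage
                )
                raise
            t_seq = [truths[p] for p in ests]
            p_seq = [ests[p].predicted_class for p in ests]
            truths_all.extend(t_seq)
            preds_all.extend(p_seq)
            for pair, est in ests.items():
                r_by_degree[truths[pair]].append(est.r_hat)
            cm_rep = metrics.build_confusion(t_seq, p_seq, grid.classes)
            replicate_uocs.append(metrics.uoc(cm_rep).integrated)
        cm_total = metrics.build_confusion(truths_all, preds_all, grid.classes)
        confusion[coverage] = cm_total
        if cfg.replicates >= 2:
            mu, lo, hi = metrics.mean_uoc_ci(replicate_uocs)
        else:
            mu, lo, hi = replicate_uocs[0], float("nan"), float("nan")
        uoc_rows.append(
            dict(coverage=coverage, mean_uoc=mu, ci_low=lo, ci_high=hi,
                 n_replicates=cfg.replicates, n_predictions=cm_total.total)
        )
        for degree, values in r_by_degree.items():
            if not values:
                continue
            summary = metrics.nrmsd(values, degree, method="simulator",
                                    grid=grid)
            if len(values) >= 2:
                metrics.deviation_cis(summary)
            dev_rows.append(
                dict(coverage=coverage, degree=degree, n=summary.n,
                     denominator=summary.denominator, nrmsd=summary.nrmsd,
                     nmbe=summary.nmbe,
                     nrmsd_ci_low=(summary.nrmsd_ci or (np.nan, np.nan))[0],
                     nrmsd_ci_high=(summary.nrmsd_ci or (np.nan, np.nan))[1],
                     nmbe_ci_low=(summary.nmbe_ci or (np.nan, np.nan))[0],
                     nmbe_ci_high=(summary.nmbe_ci or (np.nan, np.nan))[1])
            )
        ova = metrics.onevsall_metrics(cm_total).reset_index()
        ova.insert(0, "coverage", coverage)
        onevsall_frames.append(ova)
        logger.info(
            "condition %.3gX done in %.1fs (mean UOC %.4f)",
            coverage, time.perf_counter() - t0, mu,
        )
    uoc_table = pd.DataFrame(uoc_rows)
    auc = None
    if len(cfg.coverages) >= 2:
        order = np.argsort(cfg.coverages)
        x = np.asarray(cfg.coverages, dtype=float)[order]
        y = 1.0 - uoc_table["mean_uoc"].to_numpy()[order]
        # normalised to the coverage span so a perfect method scores 1
        auc = metrics.auc_trapezoid(x, y) / (x[-1] - x[0])
    return BenchmarkReport(
        uoc_table=uoc_table,
        confusion=confusion,
        deviation_table=pd.DataFrame(dev_rows),
        onevsall_table=pd.concat(onevsall_frames, ignore_index=True),
        auc=auc,
    )


def evaluate_external(
    ped: Pedigree,
    tool_records: dict[str, list[estimators.ToolOutputRecord]],
    grid: DegreeGrid = DEFAULT_GRID,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Score externally produced tool outputs against a truth pedigree.

    Each tool's records are converted to r coefficients through its native
    convention and classified on the grid.  correctKin semantics: evaluated
    pairs absent from its output are scored Unrelated.  A reported pair
    whose members are unknown to the truth pedigree is an error.

    Returns a long table with per-tool UOC and per-class metrics.
    """
    eval_pairs = pairs or list(ped.pairs())
    truth = {
        frozenset(p): grid.classify(ped.expected_r(*p)) for p in eval_pairs
    }
    rows = []
    for tool, records in tool_records.items():
        preds: dict[frozenset, str] = {}
        for record in records:
            for iid in record.pair:
                if iid not in ped:
                    raise ValueError(
                        f"{tool} reports pair {record.pair} but "
                        f"{iid!r} is absent from the truth pedigree"
                    )
            key = frozenset(record.pair)
            if key not in truth:
                continue  # reported but not under evaluation
            r_hat = estimators.derive_r(record)
            preds[key] = grid.classify(r_hat)
        if tool == "correctKin":
            for key in truth:
                preds.setdefault(key, grid.classes[0])
        missing = set(truth) - set(preds)
        if missing:
            raise ValueError(
                f"{tool} output lacks {len(missing)} evaluated pair(s)"
            )
        t_seq = [truth[k] for k in truth]
        p_seq = [preds[k] for k in truth]
        cm = metrics.build_confusion(t_seq, p_seq, grid.classes)
        result = metrics.uoc(cm)
        ova = metrics.onevsall_metrics(cm)
        for label, row in ova.iterrows():
            rows.append(dict(tool=tool, uoc=result.integrated,
                             **{"class": label}, **row.to_dict()))
    return pd.DataFrame(rows)
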