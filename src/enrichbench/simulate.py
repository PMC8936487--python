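"""Synthetic study generator with known ground truth.

Emulates the statistical shape of a two-group bulk RNA-seq contrast as seen
through a gene-level count aggregator: a genome annotation of which only a
minority of genes (~38% by default) pass the 10-reads-per-sample detection
filter, negative-binomial counts with a planted fraction of differentially
expressed (DE) genes, a gene set library mixing planted enriched sets with
null sets, and survey records with known issue frequencies. Every generator
takes an explicit seed and is deterministic given it.

The point of the library design: planted sets draw their members from DE
(hence detected) genes, while null sets sample uniformly from the whole
annotation, most of which is undetected. An analyst who uses the whole
annotation as the ORA background therefore inflates the significance of
exactly the sets that are concentrated among detected genes — the distortion
this package exists to measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import bh_adjust, detection_filter
from .io import GeneSetLibrary
from .survey import SurveyRecord


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic study.

    Defaults mirror the shape of a typical human bulk RNA-seq contrast:
    3 vs 3 samples, ~39,000 annotated genes of which ~38% are detected at a
    mean of 10 reads per sample, with roughly a fifth of detected genes DE
    at an 8-fold change. ``mean_log_sd`` is the spread (natural-log scale)
    of the long-tailed log-normal distribution of true gene abundances;
    ``nb_dispersion`` is the negative-binomial dispersion alpha in
    ``var = mu + alpha * mu^2``.
    """

    seed: int = 0
    n_annotation_genes: int = 39_000
    detected_fraction: float = 0.38
    n_samples_per_group: int = 3
    nb_dispersion: float = 0.05
    mean_log_sd: float = 1.6
    detection_threshold: float = 10.0
    de_fraction: float = 0.2
    log2fc_magnitude: float = 3.0
    n_sets: int = 500
    set_size_range: tuple[int, int] = (10, 100)
    n_planted_sets: int = 50
    planted_de_overlap: float = 0.8
    null_set_detected_bias: float = 0.8

    def __post_init__(self):
        if not 0 < self.detected_fraction <= 1:
            raise ValueError("detected_fraction must be in (0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.n_planted_sets > self.n_sets:
            raise ValueError("n_planted_sets cannot exceed n_sets")
        if not 0 < self.planted_de_overlap <= 1:
            raise ValueError("planted_de_overlap must be in (0, 1]")
        if not 0 <= self.null_set_detected_bias <= 1:
            raise ValueError("null_set_detected_bias must be in [0, 1]")
        lo, hi = self.set_size_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid set_size_range")
        if self.n_samples_per_group < 2:
            raise ValueError("need at least 2 samples per group")


@dataclass
class GroundTruth:
    """What the generator actually planted, for parameter-recovery checks."""

    annotation: frozenset[str]
    true_de_up: frozenset[str]
    true_de_down: frozenset[str]
    detected: frozenset[str] = frozenset()
    #: set name -> planted direction ("up"/"down"); filled by simulate_library
    planted_sets: dict[str, str] = field(default_factory=dict)

    @property
    def true_de(self) -> frozenset[str]:
        return self.true_de_up | self.true_de_down


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_counts(spec: SimulationSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a genes x samples negative-binomial count matrix.

    True per-gene abundances are log-normal, rescaled so that exactly
    ``detected_fraction`` of genes have a true mean at or above the
    detection threshold (the realised detected fraction then matches in
    expectation). DE genes are drawn from the detectable pool and shifted
    by half the fold change in each direction (control down, case up, or
    vice versa), which keeps the overall mean — and hence detectability —
    roughly unchanged.
    """
    rng = np.random.default_rng([spec.seed, 0])
    G = spec.n_annotation_genes
    genes = _gene_ids(G)

    lam = rng.lognormal(mean=0.0, sigma=spec.mean_log_sd, size=G)
    # calibration: the (1 - detected_fraction) empirical quantile of the true
    # means lands exactly on the detection threshold
    cutoff = np.quantile(lam, 1.0 - spec.detected_fraction)
    if cutoff <= 0:
        raise ValueError("infeasible spec: cannot calibrate detection cutoff")
    mu = lam * (spec.detection_threshold / cutoff)

    detectable = np.flatnonzero(mu >= spec.detection_threshold)
    n_de = int(round(spec.de_fraction * detectable.size))
    de_idx = rng.choice(detectable, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    half = n_de // 2
    up_idx, down_idx = de_idx[:half], de_idx[half:]

    k = spec.n_samples_per_group
    shift = np.zeros(G)
    shift[up_idx] = spec.log2fc_magnitude / 2.0
    shift[down_idx] = -spec.log2fc_magnitude / 2.0
    mu_control = mu * 2.0 ** (-shift)
    mu_case = mu * 2.0**shift

    r = 1.0 / spec.nb_dispersion  # NB size parameter
    cols = {}
    for j in range(k):
        m = mu_control
        cols[f"ctrl_{j + 1}"] = rng.negative_binomial(r, r / (r + m))
    for j in range(k):
        m = mu_case
        cols[f"case_{j + 1}"] = rng.negative_binomial(r, r / (r + m))
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))

    gene_arr = np.array(genes)
    truth = GroundTruth(
        annotation=frozenset(genes),
        true_de_up=frozenset(gene_arr[up_idx]),
        true_de_down=frozenset(gene_arr[down_idx]),
        detected=detection_filter(counts, spec.detection_threshold),
    )
    return counts, truth


def simulate_de_table(
    counts: pd.DataFrame, truth: GroundTruth, spec: SimulationSpec
) -> pd.DataFrame:
    """Per-gene two-group comparison on the detection-filtered counts.

    A simple, fully transparent DE surrogate: a moderated pooled-variance
    t-test on log2(normalized count + 1), where counts are scaled to the
    mean library size and per-gene variances are shrunk toward the median
    gene variance (a fixed prior with 4 degrees of freedom, in the spirit
    of empirical-Bayes moderation). The shrinkage is what makes n = 3 + 3
    designs workable: an unmoderated t-test at 2-4 residual degrees of
    freedom cannot produce small p-values even for large fold changes. The
    log2 fold change is the difference of group means on the transformed
    scale; BH adjustment runs across genes. This stands in for a dedicated
    count-based DE tool only so the enrichment stages can be exercised end
    to end. Deterministic given the counts.
    """
    k = spec.n_samples_per_group
    if k < 2:
        raise ValueError("need at least 2 samples per group")
    detected = sorted(truth.detected) if truth.detected else sorted(
        detection_filter(counts, spec.detection_threshold)
    )
    sub = counts.loc[detected]
    libsize = counts.sum(axis=0)
    norm = sub / libsize * libsize.mean()
    logn = np.log2(norm + 1.0)
    ctrl = logn.iloc[:, :k].to_numpy()
    case = logn.iloc[:, k:].to_numpy()
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)

    df_resid = 2 * k - 2
    ss = ((ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (case - case.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid
    prior_df = 4.0
    s2_prior = float(np.median(s2))
    s2_mod = (prior_df * s2_prior + df_resid * s2) / (prior_df + df_resid)
    df_mod = prior_df + df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / np.sqrt(s2_mod * (2.0 / k))
    p = 2.0 * stats.t.sf(np.abs(t), df_mod)
    p = np.where(np.isnan(p), 1.0, p)  # zero variance everywhere
    de = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "fdr": bh_adjust(p)},
        index=pd.Index(detected, name="gene"),
    )
    return de


def simulate_library(spec: SimulationSpec, truth: GroundTruth) -> GeneSetLibrary:
    """Build a gene set library with planted enriched sets and null sets.

    Planted sets draw ``planted_de_overlap`` of their members from the true
    DE genes of one direction (so they are genuinely, directionally
    enriched among detected DE genes) and the remainder from detected
    non-DE genes. Null sets — not enriched for DE status — draw
    ``null_set_detected_bias`` of their members from detected genes and the
    rest from undetected annotation genes, emulating the bias of curated
    pathway databases toward expressed protein-coding genes. That bias is
    what makes a whole-annotation ORA background misleading: any set
    concentrated among detected genes looks over-represented when the query
    (which can only contain detected genes) is judged against a universe
    that is mostly undetected. Sets drawn uniformly from the annotation
    would instead match the detected/undetected mix of the whole-genome
    universe and leave the hypergeometric test calibrated under either
    background. Set names carry no hint of planted status;
    ``truth.planted_sets`` records it.
    """
    rng = np.random.default_rng([spec.seed, 1])
    lo, hi = spec.set_size_range
    detected_arr = np.array(sorted(truth.detected))
    undetected_arr = np.array(sorted(truth.annotation - truth.detected))
    de_pools = {
        "up": np.array(sorted(truth.true_de_up)),
        "down": np.array(sorted(truth.true_de_down)),
    }
    filler = np.array([g for g in detected_arr if g not in truth.true_de])

    if spec.n_planted_sets > 0:
        min_pool = min(len(de_pools["up"]), len(de_pools["down"]))
        if int(np.ceil(spec.planted_de_overlap * hi)) > min_pool and min_pool < lo:
            raise ValueError("infeasible spec: too few DE genes to plant enriched sets")

    width = len(str(spec.n_sets))
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    truth.planted_sets.clear()
    for i in range(spec.n_sets):
        name = f"GS{i + 1:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        if i < spec.n_planted_sets:
            direction = "up" if i % 2 == 0 else "down"
            pool = de_pools[direction]
            n_de = min(int(round(spec.planted_de_overlap * size)), len(pool))
            if n_de < 1:
                raise ValueError("infeasible spec: planted set would contain no DE genes")
            members = list(rng.choice(pool, size=n_de, replace=False))
            n_fill = min(size - n_de, len(filler))
            if n_fill > 0:
                members += list(rng.choice(filler, size=n_fill, replace=False))
            truth.planted_sets[name] = direction
            descriptions[name] = "synthetic planted set"
        else:
            n_det = min(int(round(spec.null_set_detected_bias * size)), len(detected_arr))
            n_undet = min(size - n_det, len(undetected_arr))
            members = list(rng.choice(detected_arr, size=n_det, replace=False))
            if n_undet > 0:
                members += list(rng.choice(undetected_arr, size=n_undet, replace=False))
            descriptions[name] = "synthetic null set"
        sets[name] = frozenset(members)
    return GeneSetLibrary(
        name="synthetic", source="enrichbench.simulate", version="", sets=sets,
        descriptions=descriptions,
    )


#: Default per-item rates for the survey generator. For deduction-side items
#: the value is the probability the *deficiency* occurs; for the award items
#: (code_available, data_provided) it is the probability the award applies;
#: ``is_ora`` is the probability an analysis uses an ORA method, and the two
#: background rates are conditional: not-defined among ORA analyses, and
#: inappropriate among ORA analyses that did define a background.
DEFAULT_ISSUE_RATES: dict[str, float] = {
    "is_ora": 0.84,
    "library_origin_stated": 0.06,
    "library_version_stated": 0.92,
    "test_stated": 0.65,
    "test_conducted": 0.06,
    "fdr_corrected": 0.46,
    "app_stated": 0.06,
    "app_version_stated": 0.71,
    "background_defined": 0.85,
    "background_appropriate": 0.73,
    "code_available": 0.013,
    "data_provided": 0.40,
}

_AWARD_KEYS = {"code_available", "data_provided"}


def simulate_survey(
    n: int,
    issue_rates: Mapping[str, float] | None = None,
    seed: int = 0,
    *,
    n_journals: int = 20,
) -> list[SurveyRecord]:
    """Generate survey records with known issue frequencies.

    Checklist fields are independent Bernoulli draws at the given rates
    (see :data:`DEFAULT_ISSUE_RATES` for the rate conventions), except the
    two background fields, which are drawn conditionally on the analysis
    being ORA. Journals are assigned round-robin-free at random from a small
    pool with log-normal SJR values, and citation counts are log-normal
    integers, so the bibliometric analyses have realistic inputs.
    """
    rates = dict(DEFAULT_ISSUE_RATES)
    if issue_rates:
        unknown = set(issue_rates) - set(rates)
        if unknown:
            raise ValueError(f"unknown issue-rate key(s): {sorted(unknown)}")
        rates.update(issue_rates)
    for key, value in rates.items():
        if not 0 <= value <= 1:
            raise ValueError(f"rate {key!r} = {value} outside [0, 1]")

    rng = np.random.default_rng([seed, 2])
    journals = [f"Journal_{j + 1:02d}" for j in range(n_journals)]
    sjr_by_journal = dict(zip(journals, np.round(rng.lognormal(0.2, 0.6, n_journals), 3)))

    def draw(field: str) -> str:
        p_yes = rates[field] if field in _AWARD_KEYS else 1.0 - rates[field]
        return "yes" if rng.random() < p_yes else "no"

    records = []
    for i in range(n):
        journal = journals[int(rng.integers(0, n_journals))]
        is_ora = "yes" if rng.random() < rates["is_ora"] else "no"
        if is_ora == "yes":
            bg_defined = "yes" if rng.random() < 1.0 - rates["background_defined"] else "no"
            if bg_defined == "yes":
                bg_appropriate = (
                    "yes" if rng.random() < 1.0 - rates["background_appropriate"] else "no"
                )
            else:
                bg_appropriate = "unknown"
        else:
            bg_defined = bg_appropriate = "yes"  # not applicable: no deduction
        records.append(
            SurveyRecord(
                analysis_id=f"A{i + 1:05d}",
                journal=journal,
                omics_type="RNA-seq",
                is_ora=is_ora,
                library_origin_stated=draw("library_origin_stated"),
                library_version_stated=draw("library_version_stated"),
                test_stated=draw("test_stated"),
                test_conducted=draw("test_conducted"),
                fdr_corrected=draw("fdr_corrected"),
                app_stated=draw("app_stated"),
                app_version_stated=draw("app_version_stated"),
                background_defined=bg_defined,
                background_appropriate=bg_appropriate,
                code_available=draw("code_available"),
                data_provided=draw("data_provided"),
                sjr=sjr_by_journal[journal],
                citations=float(int(rng.lognormal(1.5, 1.0))),
            )
        )
    return records
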