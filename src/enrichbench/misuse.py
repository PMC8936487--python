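"""Scenario engine: run an enrichment analysis several "wrong" ways and
quantify how far the results drift.

The canonical grid crosses two methods (rank-based FCS; hypergeometric ORA),
two ORA backgrounds (detected genes; the whole genome annotation, flagged
with a ``*``) and two significance rules (BH FDR < alpha; nominal p < alpha,
flagged with ``nom``). Divergence between the resulting collections of
significant (set, direction) pairs is measured with the Jaccard index and
with the fraction of nominal calls that evaporate under FDR control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations as _combinations
from typing import Iterable, Literal, Sequence

import pandas as pd

from .core import (
    DEFAULT_MAX_SET_SIZE,
    DEFAULT_MIN_SET_SIZE,
    BackgroundSpec,
    fcs_rank_test,
    ora_test,
    significant_sets,
)

#: Marker for an undefined statistic (e.g. Jaccard of two empty collections).
UNDEFINED = float("nan")


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the misuse grid.

    ``background_mode`` only applies to ORA; FCS consumes the DE table of
    detected genes and has no background concept, so an FCS scenario with a
    whole-annotation background is rejected at validation.
    """

    label: str
    method: Literal["ora", "fcs"]
    background_mode: Literal["detected", "whole_annotation"] = "detected"
    significance_mode: Literal["fdr", "nominal"] = "fdr"
    alpha: float = 0.05

    def __post_init__(self):
        if self.method not in ("ora", "fcs"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "fcs" and self.background_mode == "whole_annotation":
            raise ValueError(
                f"scenario {self.label!r}: FCS ranks the detected genes directly and "
                "has no background list; a whole-annotation background is meaningless "
                "for it"
            )


@dataclass(frozen=True)
class SignedResultSet:
    """The (set name, direction) pairs called significant under one scenario."""

    label: str
    members: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    @property
    def n_up(self) -> int:
        return sum(1 for _, d in self.members if d == "up")

    @property
    def n_down(self) -> int:
        return sum(1 for _, d in self.members if d == "down")

    def __len__(self) -> int:
        return len(self.members)

    def unsigned(self) -> frozenset[str]:
        """Pool directions: the set names alone."""
        return frozenset(s for s, _ in self.members)


def canonical_grid(alpha: float = 0.05) -> list[ScenarioConfig]:
    """The six-scenario grid: FCS, FCS_nom, ORA, ORA_nom, ORA*, ORA*nom.

    ``*`` marks a whole-genome-annotation background, ``nom`` a nominal
    (unadjusted) p < alpha significance rule.
    """
    return [
        ScenarioConfig("FCS", "fcs", "detected", "fdr", alpha),
        ScenarioConfig("FCS_nom", "fcs", "detected", "nominal", alpha),
        ScenarioConfig("ORA", "ora", "detected", "fdr", alpha),
        ScenarioConfig("ORA_nom", "ora", "detected", "nominal", alpha),
        ScenarioConfig("ORA*", "ora", "whole_annotation", "fdr", alpha),
        ScenarioConfig("ORA*nom", "ora", "whole_annotation", "nominal", alpha),
    ]


def deg_lists(de: pd.DataFrame, fdr_threshold: float = 0.05) -> tuple[frozenset[str], frozenset[str]]:
    """Up- and down-regulated DEG lists: DE-table FDR < threshold split by
    fold-change sign. No fold-change magnitude threshold is applied."""
    sig = de[de["fdr"] < fdr_threshold]
    up = frozenset(sig.index[sig["log2fc"] > 0])
    down = frozenset(sig.index[sig["log2fc"] < 0])
    return up, down


def run_scenarios(
    de: pd.DataFrame,
    detected: Iterable[str],
    annotation: Iterable[str],
    library,
    grid: Sequence[ScenarioConfig] | None = None,
    *,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    max_set_size: int = DEFAULT_MAX_SET_SIZE,
    deg_fdr: float = 0.05,
    keep_tables: dict | None = None,
) -> list[SignedResultSet]:
    """Run every scenario of the grid on one dataset.

    ORA scenarios query the up- and down-regulated DEG lists separately
    against the configured background; FCS scenarios run the rank test once
    and sign the results. Statistical work is delegated to
    :mod:`enrichbench.core`; this function only orchestrates, so identical
    inputs give identical outputs.

    Parameters
    ----------
    de : DataFrame
        DE table over the detected genes (index gene id; log2fc, p, fdr).
    detected, annotation : iterables of gene ids
        The detection-filtered universe and the full annotation universe;
        ``detected`` must be a subset of ``annotation``.
    keep_tables : dict, optional
        If given, filled with the per-scenario full result tables (keyed by
        label) for writing to disk.
    """
    detected = frozenset(detected)
    annotation = frozenset(annotation)
    if not detected <= annotation:
        raise ValueError("detected genes must be a subset of the annotation")
    missing = frozenset(de.index) - detected
    if missing:
        raise ValueError(
            f"{len(missing)} DE-table gene(s) are not in the detected set"
        )
    if grid is None:
        grid = canonical_grid()
    labels = [c.label for c in grid]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate scenario labels in grid: {labels}")

    up, down = deg_lists(de, deg_fdr)
    backgrounds = {
        "detected": BackgroundSpec("detected", detected),
        "whole_annotation": BackgroundSpec("whole_annotation", annotation),
    }

    # memoise the expensive computations: FCS once, ORA once per background
    fcs_table: pd.DataFrame | None = None
    ora_tables: dict[str, pd.DataFrame] = {}

    results = []
    for cfg in grid:
        if cfg.method == "fcs":
            if fcs_table is None:
                fcs_table = fcs_rank_test(de, library, min_set_size)
            table = fcs_table
        else:
            if cfg.background_mode not in ora_tables:
                parts = []
                for direction, query in (("up", up), ("down", down)):
                    if not query:
                        continue
                    parts.append(
                        ora_test(
                            query,
                            backgrounds[cfg.background_mode],
                            library,
                            min_set_size,
                            max_set_size,
                            direction=direction,
                        )
                    )
                ora_tables[cfg.background_mode] = (
                    pd.concat(parts, ignore_index=True)
                    if parts
                    else pd.DataFrame(columns=["set", "direction", "p", "fdr"])
                )
            table = ora_tables[cfg.background_mode]
        results.append(
            significant_sets(table, cfg.significance_mode, cfg.alpha, label=cfg.label)
        )
        if keep_tables is not None:
            keep_tables[cfg.label] = table
    return results


def jaccard(a: SignedResultSet, b: SignedResultSet, *, signed: bool = True) -> float:
    """Jaccard index |A & B| / |A | B| between two result collections.

    Computed over signed (set, direction) pairs by default; ``signed=False``
    pools directions first. When both collections are empty the index is
    undefined and NaN is returned (never 0 or 1).
    """
    A = a.members if signed else {(s, "") for s in a.unsigned()}
    B = b.members if signed else {(s, "") for s in b.unsigned()}
    union = A | B
    if not union:
        return UNDEFINED
    return len(A & B) / len(union)


def jaccard_matrix(
    collections: Sequence[SignedResultSet], *, signed: bool = True
) -> pd.DataFrame:
    """Symmetric matrix of pairwise Jaccard indices, labelled by scenario.

    Diagonal entries are 1 (NaN for an empty collection, where self-overlap
    is undefined).
    """
    if len(collections) < 2:
        raise ValueError("need at least 2 collections")
    labels = [c.label for c in collections]
    m = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for i, a in enumerate(collections):
        for j, b in enumerate(collections):
            if j < i:
                continue
            m.iloc[i, j] = m.iloc[j, i] = jaccard(a, b, signed=signed)
    return m


def erroneous_fraction(nominal: SignedResultSet, adjusted: SignedResultSet) -> float:
    """Fraction of nominal-threshold calls that vanish under FDR control.

    ``(|nominal| - |adjusted|) / |nominal|``. Both arguments must come from
    the same run thresholded two ways, so the adjusted calls are a subset of
    the nominal ones; anything else signals mismatched runs and raises.
    Undefined (NaN) when the nominal collection is empty.
    """
    if not adjusted.members <= nominal.members:
        raise ValueError(
            "adjusted calls are not a subset of nominal calls; the two "
            "collections do not come from the same run"
        )
    if not nominal.members:
        return UNDEFINED
    return (len(nominal) - len(adjusted)) / len(nominal)


def overlap_counts(collections: Sequence[SignedResultSet]) -> pd.DataFrame:
    """Counts of every intersection region among 2 or 3 collections.

    The regions partition the union (3 regions for two collections, 7 for
    three), so the counts sum to ``|union|``. For more collections report
    pairwise instead.
    """
    if not 2 <= len(collections) <= 3:
        raise ValueError("overlap regions are reported for 2 or 3 collections only")
    labels = [c.label for c in collections]
    sets = [c.members for c in collections]
    rows = []
    n = len(sets)
    for r in range(1, n + 1):
        for idx in _combinations(range(n), r):
            inside = frozenset.intersection(*[sets[i] for i in idx])
            outside = frozenset().union(*[sets[i] for i in range(n) if i not in idx]) if r < n else frozenset()
            region = inside - outside
            rows.append(
                {"region": " & ".join(labels[i] for i in idx), "count": len(region)}
            )
    return pd.DataFrame(rows)
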