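"""Specificity–flexibility rank correlation, difference maps, convergence.

The central claim under test, for any protease with substrate data and a
conformational ensemble, is that pocket-wise binding-site flexibility tracks
pocket-wise substrate promiscuity.  Both sides are reduced to one number per
sub-pocket (cleavage entropy vs a flexibility/interaction metric) and
compared by the Spearman rank correlation coefficient ρ, computed with
midranks for ties; with typically only six pockets, an optional exact
permutation p-value is available instead of any large-sample approximation.

Difference maps (complex minus unbound, negative = rigidified on binding)
and block-wise convergence summaries (metric recomputed on contiguous
trajectory blocks, rank stability across blocks) complete the report.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .interface_analysis import PocketMetricTable, SubPocketDefinition, pocket_average
from .trajectory_io import FrameEnsemble, ResidueID, split_blocks

logger = logging.getLogger(__name__)

__all__ = [
    "SpearmanResult",
    "DifferenceMap",
    "SpecificityFlexibilityReport",
    "BlockConvergenceReport",
    "spearman_rho",
    "exact_permutation_pvalue",
    "correlate_specificity",
    "difference_map",
    "block_convergence",
]


@dataclass
class SpearmanResult:
    """Spearman ρ with the midrank vectors it was computed from.

    ``rho`` is NaN with ``undefined=True`` when either vector has zero rank
    variance (all-tied input) — undefined, deliberately not reported as 0.
    """

    rho: float
    n: int
    ranks_x: np.ndarray
    ranks_y: np.ndarray
    undefined: bool = False
    p_exact: float | None = None

    def __post_init__(self) -> None:
        if not self.undefined and not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError(f"rho {self.rho} outside [-1, 1]")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with midranks for ties.

    ρ is the Pearson correlation of the two midrank vectors; when no ties
    are present this equals the classical ``1 − 6Σd²/(n(n²−1))``.  Requires
    at least 3 paired observations with no missing values (drop incomplete
    pairs beforehand and report n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("Spearman correlation needs at least 3 paired observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values must be removed (pairwise) before correlation")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    vx = (sx**2).sum()
    vy = (sy**2).sum()
    if vx == 0.0 or vy == 0.0:
        logger.warning("zero rank variance; Spearman rho undefined")
        return SpearmanResult(float("nan"), n, rx, ry, undefined=True)
    rho = float((sx * sy).sum() / np.sqrt(vx * vy))
    return SpearmanResult(rho, n, rx, ry)


def exact_permutation_pvalue(result: SpearmanResult) -> float:
    """Two-sided exact permutation p-value for |ρ| (all n! permutations).

    Feasible for the pocket-level case (n = 6 → 720 permutations); refuses
    n > 8.
    """
    if result.undefined:
        raise ValueError("p-value undefined for zero rank variance")
    n = result.n
    if n > 8:
        raise ValueError("exact permutation test limited to n <= 8")
    rx = result.ranks_x
    ry = result.ranks_y
    sx = rx - rx.mean()
    denom = np.sqrt((sx**2).sum())
    observed = abs(result.rho)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        py = ry[list(perm)]
        sy = py - py.mean()
        rho = (sx * sy).sum() / (denom * np.sqrt((sy**2).sum()))
        if abs(rho) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


@dataclass
class DifferenceMap:
    """Residue-wise metric difference, complex minus unbound.

    Negative values mean the residue is *rigidified* (lower B-factor or
    entropy) upon substrate binding; positive values mean mobilisation.
    """

    metric_name: str
    delta_by_residue: dict[ResidueID, float]


def difference_map(
    complex_profile: Mapping[ResidueID, float],
    unbound_profile: Mapping[ResidueID, float],
    metric_name: str = "metric",
) -> DifferenceMap:
    """Delta = complex − unbound over the residues shared by both profiles."""
    shared = [r for r in complex_profile if r in unbound_profile]
    if not shared:
        raise ValueError("profiles share no residues; cannot form a difference map")
    delta = {r: float(complex_profile[r]) - float(unbound_profile[r]) for r in shared}
    return DifferenceMap(metric_name=metric_name, delta_by_residue=delta)


@dataclass
class SpecificityFlexibilityReport:
    """Pocket-wise metric table with Spearman ρ of each metric vs specificity."""

    pocket_table: pd.DataFrame  # pockets x metrics (incl. cleavage_entropy)
    correlations: dict[str, SpearmanResult]
    pockets_used: dict[str, list[str]] = field(default_factory=dict)
    block_tables: dict[str, list[PocketMetricTable]] = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Specificity vs flexibility (Spearman rank correlation)"]
        for name, res in self.correlations.items():
            if res.undefined:
                lines.append(f"  {name}: rho undefined (zero rank variance), n={res.n}")
            else:
                p = f", p_exact={res.p_exact:.3f}" if res.p_exact is not None else ""
                lines.append(f"  {name}: rho={res.rho:+.3f}, n={res.n}{p}")
        return "\n".join(lines)


def correlate_specificity(
    specificity_by_pocket: Mapping[str, float],
    metric_tables: Iterable[PocketMetricTable],
    with_exact_p: bool = False,
) -> SpecificityFlexibilityReport:
    """Rank-correlate pocket-wise metrics against cleavage entropy.

    Pockets missing a metric value (NaN) are excluded pairwise with a
    warning; a metric with fewer than 3 complete pairs is skipped.  The
    report records exactly which pockets entered each correlation.
    """
    pockets = sorted(specificity_by_pocket)
    spec = {lab: float(specificity_by_pocket[lab]) for lab in pockets}

    columns: dict[str, dict[str, float]] = {"cleavage_entropy": spec}
    correlations: dict[str, SpearmanResult] = {}
    pockets_used: dict[str, list[str]] = {}
    for table in metric_tables:
        name = table.metric_name
        columns[name] = {lab: table.value_by_pocket.get(lab, float("nan")) for lab in pockets}
        complete = [lab for lab in pockets
                    if np.isfinite(columns[name][lab]) and np.isfinite(spec[lab])]
        if len(complete) < len(pockets):
            logger.warning("metric %r missing in pockets %s; excluded pairwise",
                           name, sorted(set(pockets) - set(complete)))
        if len(complete) < 3:
            logger.warning("metric %r has %d complete pairs (<3); skipped", name, len(complete))
            continue
        res = spearman_rho([spec[lab] for lab in complete],
                           [columns[name][lab] for lab in complete])
        if with_exact_p and not res.undefined:
            res.p_exact = exact_permutation_pvalue(res)
        correlations[name] = res
        pockets_used[name] = complete

    pocket_table = pd.DataFrame(columns, index=pockets)
    pocket_table.index.name = "pocket"
    return SpecificityFlexibilityReport(
        pocket_table=pocket_table,
        correlations=correlations,
        pockets_used=pockets_used,
    )


@dataclass
class BlockConvergenceReport:
    """Per-block pocket tables plus rank stability vs the full trajectory.

    ``pair_agreement[(a, b)]`` is the fraction of blocks whose pocket means
    reproduce the full-trajectory order of pockets a and b.
    """

    full_table: PocketMetricTable
    block_tables: list[PocketMetricTable | None]
    pair_agreement: dict[tuple[str, str], float]
    failed_blocks: list[int] = field(default_factory=list)

    def rank_stability(self) -> float:
        """Mean pairwise agreement over all pocket pairs."""
        vals = [v for v in self.pair_agreement.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")


def block_convergence(
    ensemble: FrameEnsemble,
    metric_fn: Callable[[FrameEnsemble], Mapping[ResidueID, float]],
    pockets: SubPocketDefinition,
    n_blocks: int = 10,
    metric_name: str = "metric",
) -> BlockConvergenceReport:
    """Recompute a pocket metric on contiguous trajectory blocks.

    ``metric_fn`` maps an ensemble to a residue-wise profile; it is applied
    to the full trajectory and to each of ``n_blocks`` contiguous blocks
    (errors in one block are logged and leave a None entry without aborting
    the others).  The summary reports, per pocket pair, the fraction of
    blocks preserving the full-trajectory rank order of that pair.
    """
    if n_blocks < 2:
        raise ValueError("block convergence needs at least 2 blocks")
    full = pocket_average(metric_fn(ensemble), pockets, metric_name=metric_name)
    tables: list[PocketMetricTable | None] = []
    failed: list[int] = []
    for bi, block in enumerate(split_blocks(ensemble, n_blocks)):
        try:
            tables.append(pocket_average(metric_fn(block), pockets, metric_name=metric_name))
        except Exception as exc:
            logger.warning("block %d failed: %s", bi, exc)
            tables.append(None)
            failed.append(bi)

    labels = [lab for lab in full.value_by_pocket if np.isfinite(full.value_by_pocket[lab])]
    agreement: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(labels, 2):
        ref_sign = np.sign(full.value_by_pocket[a] - full.value_by_pocket[b])
        if ref_sign == 0:
            agreement[(a, b)] = float("nan")
            continue
        ok = 0
        tot = 0
        for t in tables:
            if t is None:
                continue
            va, vb = t.value_by_pocket.get(a), t.value_by_pocket.get(b)
            if va is None or vb is None or not (np.isfinite(va) and np.isfinite(vb)):
                continue
            tot += 1
            if np.sign(va - vb) == ref_sign:
                ok += 1
        agreement[(a, b)] = ok / tot if tot else float("nan")
    return BlockConvergenceReport(
        full_table=full, block_tables=tables,
        pair_agreement=agreement, failed_blocks=failed,
    )
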