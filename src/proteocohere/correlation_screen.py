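"""Stage-wise correlation matrices and the correlation-difference hub screen.

For each disease stage a Pearson correlation matrix over the gene panel is
computed with 1/n (population) moments.  Difference matrices against the
control stage (dR = R_stage - R_CON) are screened over their strict upper
triangle: entries exceeding mean + k*sigma (default k = 2, upper one-sided)
flag gene pairs, flagged pairs map to gene sets, and the intersection of the
three stage gene sets yields the hub gene set Omega.  A standalone one-sample
t-test and the normal-coverage calibration used to justify the 2-sigma cutoff
are provided alongside.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .data_io import STAGES, ExpressionMatrix

Pair = tuple[str, str]


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal Pearson matrix over a gene panel at one stage."""

    values: np.ndarray
    gene_ids: list[str]
    stage: str | None
    n_samples: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        g = len(self.gene_ids)
        if self.values.shape != (g, g):
            raise ValueError("correlation matrix shape does not match gene_ids")
        finite = self.values[np.isfinite(self.values)]
        if np.abs(self.values - self.values.T)[np.isfinite(self.values)].max(initial=0) > 1e-12:
            raise ValueError("correlation matrix is not symmetric within 1e-12")
        diag = np.diag(self.values)
        if np.abs(diag[np.isfinite(diag)] - 1).max(initial=0) > 1e-12:
            raise ValueError("correlation matrix diagonal must be 1")
        if finite.size and (finite.min() < -1 - 1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("correlation entries must lie in [-1, 1]")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def eigenvalues(self) -> np.ndarray:
        """Descending real eigenvalues (symmetric decomposition)."""
        return np.linalg.eigvalsh(self.values)[::-1]


@dataclass
class DifferenceMatrix:
    """Elementwise dR = R_stage - R_CON with zero diagonal."""

    values: np.ndarray
    gene_ids: list[str]
    stage_pair: tuple[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.abs(np.diag(self.values)).max(initial=0) > 1e-12:
            raise ValueError("difference matrix diagonal must be 0")

    def upper_triangle(self) -> np.ndarray:
        """Strict upper-triangle multiset, row-major order."""
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


@dataclass
class StageScreen:
    """2-sigma screen outcome for one difference matrix."""

    stage: str
    threshold: float
    mean: float
    sigma: float
    k: float
    sidedness: str
    flagged_pairs: set[Pair]
    gene_set: set[str]
    degenerate: bool = False


@dataclass
class ScreenResult:
    """Per-stage screens plus the three-way hub intersection Omega."""

    screens: dict[str, StageScreen]
    omega: tuple[str, ...]
    intersection_mode: str = "genes"

    def to_dict(self) -> dict:
        return {
            "intersection_mode": self.intersection_mode,
            "omega": list(self.omega),
            "stages": {
                s: {
                    "threshold": sc.threshold,
                    "mean": sc.mean,
                    "sigma": sc.sigma,
                    "k": sc.k,
                    "sidedness": sc.sidedness,
                    "degenerate": sc.degenerate,
                    "flagged_pairs": sorted(map(list, sc.flagged_pairs)),
                    "gene_set": sorted(sc.gene_set),
                }
                for s, sc in self.screens.items()
            },
        }


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean: float
    ref_mean: float
    s: float
    alpha: float

    @property
    def reject(self) -> bool:
        return self.p < self.alpha


# -- operations ---------------------------------------------------------------

def pearson_matrix(
    m: ExpressionMatrix, stage: str | None = None, mode: str = "strict"
) -> CorrelationMatrix:
    """Pearson correlation matrix over genes, 1/n covariance and population sd.

    ``stage`` restricts to that stage's samples first.  Genes with zero
    variance are an error in strict mode; in lenient mode their row/column is
    NaN and they are reported via the returned matrix's NaN pattern.
    """
    if stage is not None:
        m = m.restrict_stage(stage)
        label = stage
    else:
        labels = set(m.stage.values())
        label = labels.pop() if len(labels) == 1 else None
    if m.n_samples < 2:
        raise ValueError("pearson_matrix needs at least 2 samples")
    x = m.values
    centered = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)  # population convention, as in the 1/n covariance below
    zero = np.flatnonzero(sd == 0)
    if zero.size and mode == "strict":
        names = [m.gene_ids[i] for i in zero]
        raise ValueError(f"zero-variance gene(s): {names}")
    cov = centered @ centered.T / m.n_samples
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.outer(sd, sd)
    r = np.clip(r, -1.0, 1.0)
    if zero.size:
        r[zero, :] = np.nan
        r[:, zero] = np.nan
    np.fill_diagonal(r, 1.0)
    if zero.size:
        r[zero, zero] = 1.0
    return CorrelationMatrix(values=r, gene_ids=list(m.gene_ids),
                             stage=label, n_samples=m.n_samples)


def difference_matrix(
    r_stage: CorrelationMatrix, r_con: CorrelationMatrix
) -> DifferenceMatrix:
    """dR = R_stage - R_CON, elementwise; gene order must match exactly."""
    if r_stage.gene_ids != r_con.gene_ids:
        raise ValueError("gene order mismatch between stage and control matrices")
    if r_con.stage != "CON":
        raise ValueError(f"reference matrix must be the CON stage, got {r_con.stage!r}")
    return DifferenceMatrix(
        values=r_stage.values - r_con.values,
        gene_ids=list(r_stage.gene_ids),
        stage_pair=(r_stage.stage or "?", "CON"),
    )


def two_sigma_gene_screen(
    d: DifferenceMatrix,
    k: float = 2.0,
    sidedness: str = "upper",
    min_pair_count: int = 1,
) -> StageScreen:
    """Flag upper-triangle entries beyond mean + k*sigma (population sigma).

    ``sidedness='upper'`` flags x > mean + k*sigma; ``'two_sided'`` flags
    |x - mean| > k*sigma.  Ties exactly at the threshold are not flagged.  A
    gene enters the gene set if it belongs to at least ``min_pair_count``
    flagged pairs.  Zero spread returns an empty, degenerate-flagged screen.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if sidedness not in ("upper", "two_sided"):
        raise ValueError("sidedness must be 'upper' or 'two_sided'")
    if min_pair_count < 1:
        raise ValueError("min_pair_count must be >= 1")
    g = len(d.gene_ids)
    if g < 2:
        raise ValueError("need at least 2 genes to screen")
    vals = d.upper_triangle()
    mean = float(vals.mean())
    sigma = float(vals.std())  # population convention
    stage = d.stage_pair[0]
    if sigma == 0:
        return StageScreen(stage=stage, threshold=mean, mean=mean, sigma=0.0, k=k,
                           sidedness=sidedness, flagged_pairs=set(), gene_set=set(),
                           degenerate=True)
    threshold = mean + k * sigma
    iu, ju = np.triu_indices(g, k=1)
    if sidedness == "upper":
        hit = vals > threshold
    else:
        hit = np.abs(vals - mean) > k * sigma
    flagged = {(d.gene_ids[i], d.gene_ids[j]) for i, j in zip(iu[hit], ju[hit])}
    counts: dict[str, int] = {}
    for a, b in flagged:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    genes = {gn for gn, c in counts.items() if c >= min_pair_count}
    return StageScreen(stage=stage, threshold=threshold, mean=mean, sigma=sigma,
                       k=k, sidedness=sidedness, flagged_pairs=flagged, gene_set=genes)


def hub_intersection(gene_sets: Sequence[Iterable[str]]) -> tuple[str, ...]:
    """Intersection of exactly three stage gene sets, sorted deterministically."""
    sets = [set(s) for s in gene_sets]
    if len(sets) != 3:
        raise ValueError(f"expected exactly 3 gene sets (INC, MOD, SEV), got {len(sets)}")
    return tuple(sorted(sets[0] & sets[1] & sets[2]))


def screen_stages(
    m: ExpressionMatrix,
    k: float = 2.0,
    sidedness: str = "upper",
    min_pair_count: int = 1,
    intersection_mode: str = "genes",
) -> ScreenResult:
    """Run the full stage-wise screen: R per stage, dR vs CON, 2-sigma flags, Omega.

    ``intersection_mode='genes'`` intersects the per-stage gene sets (default);
    ``'pairs'`` intersects the flagged pair sets first and collects the genes
    of the surviving pairs.
    """
    if intersection_mode not in ("genes", "pairs"):
        raise ValueError("intersection_mode must be 'genes' or 'pairs'")
    r_con = pearson_matrix(m, "CON")
    screens: dict[str, StageScreen] = {}
    for stage in ("INC", "MOD", "SEV"):
        r_stage = pearson_matrix(m, stage)
        d = difference_matrix(r_stage, r_con)
        screens[stage] = two_sigma_gene_screen(d, k=k, sidedness=sidedness,
                                               min_pair_count=min_pair_count)
    if intersection_mode == "genes":
        omega = hub_intersection([screens[s].gene_set for s in ("INC", "MOD", "SEV")])
    else:
        common = (screens["INC"].flagged_pairs
                  & screens["MOD"].flagged_pairs
                  & screens["SEV"].flagged_pairs)
        omega = tuple(sorted(set(itertools.chain.from_iterable(common))))
    return ScreenResult(screens=screens, omega=omega, intersection_mode=intersection_mode)


def one_sample_t_test(
    sample: Sequence[float], ref_mean: float, alpha: float = 0.05
) -> TTestResult:
    """Two-sided one-sample t-test of the sample mean against ``ref_mean``.

    t = (x_bar - mu) / (s / sqrt(n)) with s the 1/(n-1) standard deviation,
    df = n - 1.
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    s = float(x.std(ddof=1))
    if s == 0:
        raise ValueError("zero sample spread: t statistic undefined")
    mean = float(x.mean())
    t = (mean - ref_mean) / (s / np.sqrt(n))
    df = n - 1
    p = float(2 * stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, p=p, mean=mean, ref_mean=float(ref_mean),
                       s=s, alpha=alpha)


def gaussian_coverage(k: float) -> float:
    """Probability mass of a normal distribution within mean +/- k*sd.

    Independent of the mean and sd; k=1,2,3 give 0.6826, 0.9544, 0.9974 --
    the calibration behind the 2-sigma screening cutoff (~p < 0.05 two-sided).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    return float(1 - 2 * stats.norm.sf(k))
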