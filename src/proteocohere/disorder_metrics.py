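"""Network coordination and disorder metrics for the hub gene network.

Three quantities summarise how tightly a small correlation network is
coordinated at each disease stage:

* **system determinant** -- det(R) of the hub correlation matrix.  Geometrically
  the (hyper)volume spanned by the gene vectors: 1 for orthogonal (uncorrelated)
  genes, 0 for a degenerate, fully coordinated network.
* **system entropy** -- Shannon entropy of the eigenvalue occupancy vector
  P_i = lambda_i^2 / sum(lambda_j^2) of R.  log2(g) bits when all axes carry
  equal weight (identity matrix), 0 when one correlation axis dominates.
* **determinant entropy** -- enumerate all C(n, dim) sample subsets of a stage,
  compute det(R) on each subset, histogram the resulting multiset with bin
  width a = sigma(pooled multiset)/10 and take the Shannon entropy of the
  occupied bins.  Measures how dispersed network coordination is across
  subsamples.

All three decrease as intersubunit coupling rises, which is the stage-wise
signature the analysis looks for.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .correlation_screen import CorrelationMatrix, pearson_matrix
from .data_io import ExpressionMatrix

_EIG_CLIP_TOL = 1e-8
_DET_CLIP_TOL = 1e-10


@dataclass
class EigenSpectrum:
    """Descending eigenvalues of a correlation matrix and their squared-weight
    occupancy vector P_i = lambda_i^2 / sum(lambda_j^2)."""

    eigenvalues: np.ndarray
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        if abs(self.occupancy.sum() - 1.0) > 1e-12:
            raise ValueError("occupancy vector must sum to 1")
        if (self.occupancy < 0).any():
            raise ValueError("occupancy entries must be nonnegative")


@dataclass
class SubsetDeterminantSet:
    """Determinants of the hub correlation matrix over all sample subsets of
    one stage at a fixed subset size (``dim``)."""

    group: str
    dim: int
    values: np.ndarray          # defined determinants only
    n_subsets: int              # C(n_group, dim)
    n_undefined: int = 0        # subsets with a zero-variance gene, excluded

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size + self.n_undefined != self.n_subsets:
            raise ValueError("values + undefined must cover every subset")


@dataclass
class GroupHistogram:
    """Histogram of one group's determinant multiset: half-open bins of shared
    width anchored at the group minimum, last bin closed."""

    group: str
    bin_width: float
    origin: float
    edges: np.ndarray           # n_bins + 1 edges
    counts: np.ndarray          # per-bin counts (zero bins retained here)
    entropy: float              # Shannon entropy over occupied bins, bits
    degenerate: bool = False


@dataclass
class DisorderSummary:
    """Per-stage coordination/disorder metrics for the hub network."""

    determinant: dict[str, float]
    system_entropy: dict[str, float]
    determinant_entropy: dict[int, dict[str, float]]  # dim -> stage -> H
    hub_genes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "hub_genes": list(self.hub_genes),
            "determinant": self.determinant,
            "system_entropy": self.system_entropy,
            "determinant_entropy": {
                str(dim): h for dim, h in self.determinant_entropy.items()
            },
        }


# -- operations ----------------------------------------------------------------

def _check_valid(r: CorrelationMatrix) -> np.ndarray:
    v = r.values
    if not np.isfinite(v).all():
        raise ValueError("correlation matrix contains undefined entries")
    if np.abs(v - v.T).max() > 1e-10:
        raise ValueError("correlation matrix asymmetric beyond tolerance")
    return v


def system_determinant(r: CorrelationMatrix) -> float:
    """det(R); tiny negative values from numerical noise are clipped to 0."""
    v = _check_valid(r)
    det = float(np.linalg.det(v))
    if -_DET_CLIP_TOL < det < 0:
        det = 0.0
    return det


def shannon_entropy(p: np.ndarray) -> float:
    """-sum p_i log2 p_i with the 0*log(0) := 0 convention."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum()) + 0.0


def system_entropy(r: CorrelationMatrix) -> tuple[EigenSpectrum, float]:
    """Eigenvalue-occupancy entropy H(P) of a correlation matrix.

    Eigenvalues within -1e-8 of zero are clipped to 0 before squaring; more
    negative eigenvalues indicate an invalid matrix and raise.
    """
    v = _check_valid(r)
    lam = np.linalg.eigvalsh(v)[::-1]
    if lam.min() < -_EIG_CLIP_TOL:
        raise ValueError(
            f"matrix is not positive semidefinite (min eigenvalue {lam.min():.3g})"
        )
    lam = np.clip(lam, 0.0, None)
    total = float((lam ** 2).sum())
    if total == 0:
        raise ValueError("all-zero eigenvalue spectrum")
    occupancy = lam ** 2 / total
    return EigenSpectrum(eigenvalues=lam, occupancy=occupancy), shannon_entropy(occupancy)


def subset_determinants(
    m: ExpressionMatrix,
    dim: int,
    stage: str | None = None,
    hub_genes: Sequence[str] | None = None,
) -> SubsetDeterminantSet:
    """det(R) over every sample subset of size ``dim`` (lexicographic order).

    ``m`` is restricted to ``hub_genes`` (if given) and ``stage`` (if given)
    first.  For each of the C(n, dim) subsets the Pearson matrix over the hub
    genes is computed on those samples only.  Subsets where a gene has zero
    variance yield an undefined determinant: excluded from ``values`` and
    counted in ``n_undefined``.
    """
    if hub_genes is not None:
        m = m.subset_genes(list(hub_genes))
    if stage is not None:
        m = m.restrict_stage(stage)
    n = m.n_samples
    if m.n_genes < 2:
        raise ValueError("need at least 2 hub genes")
    if dim < 2:
        raise ValueError("dim must be at least 2")
    if dim > n:
        raise ValueError(f"dim={dim} exceeds the group's {n} samples")
    group = stage if stage is not None else (m.stage.get(m.sample_ids[0]) or "?")
    x = m.values
    dets: list[float] = []
    n_undefined = 0
    for subset in combinations(range(n), dim):
        sub = x[:, subset]
        sd = sub.std(axis=1)
        if (sd == 0).any():
            n_undefined += 1
            continue
        centered = sub - sub.mean(axis=1, keepdims=True)
        r = (centered @ centered.T / dim) / np.outer(sd, sd)
        r = np.clip(r, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        det = float(np.linalg.det(r))
        # rank-deficient subsets (dim <= g) are singular by construction; snap
        # the ~1e-16 float residue to an exact zero so downstream histograms
        # see the degenerate multiset for what it is
        if abs(det) <= 1e-12:
            det = 0.0
        dets.append(det)
    return SubsetDeterminantSet(
        group=group, dim=dim, values=np.asarray(dets),
        n_subsets=math.comb(n, dim), n_undefined=n_undefined,
    )


def _histogram(values: np.ndarray, a: float, group: str,
               degenerate: bool = False) -> GroupHistogram:
    lo = float(values.min())
    hi = float(values.max())
    if hi == lo or degenerate:
        edges = np.array([lo, max(hi, lo + (a if a > 0 else 1.0))])
        counts = np.array([values.size])
        return GroupHistogram(group=group, bin_width=a, origin=lo, edges=edges,
                             counts=counts, entropy=0.0,
                             degenerate=degenerate or hi == lo)
    n_bins = max(1, math.ceil((hi - lo) / a))
    idx = np.floor((values - lo) / a).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # values at hi fall into the closed last bin
    counts = np.bincount(idx, minlength=n_bins)
    p = counts[counts > 0] / values.size
    edges = lo + a * np.arange(n_bins + 1)
    return GroupHistogram(group=group, bin_width=a, origin=lo, edges=edges,
                          counts=counts, entropy=shannon_entropy(p))


def determinant_entropy(
    groups: Mapping[str, SubsetDeterminantSet],
    bin_width_override: float | None = None,
) -> dict[str, GroupHistogram]:
    """Histogram entropy of each group's determinant multiset.

    The shared bin width is a = sigma(pooled multiset of all groups)/10 with
    the population (1/n) standard deviation, unless overridden.  Per group,
    bins of width a span [min, max] anchored at the group minimum (last bin
    closed); zero-frequency bins are dropped before the Shannon entropy.  A
    zero pooled spread with no override means all values coincide: every
    group's entropy is 0 and histograms carry a degenerate flag.
    """
    if not groups:
        raise ValueError("no groups given")
    dims = {s.dim for s in groups.values()}
    if len(dims) > 1:
        raise ValueError(f"groups must share a subset size, got dims {sorted(dims)}")
    for name, s in groups.items():
        if s.values.size == 0:
            raise ValueError(f"group {name!r} has no defined determinants")
    pooled = np.concatenate([s.values for s in groups.values()])
    if bin_width_override is not None:
        if bin_width_override <= 0:
            raise ValueError("bin_width_override must be positive")
        a = float(bin_width_override)
        degenerate = False
    else:
        a = float(pooled.std()) / 10.0  # population sd of the pooled multiset
        degenerate = a == 0.0
    return {
        name: _histogram(s.values, a, group=name, degenerate=degenerate)
        for name, s in groups.items()
    }


def disorder_summary(
    m: ExpressionMatrix,
    hub_genes: Sequence[str],
    dims: Sequence[int] = (3, 4, 5),
    stages: Sequence[str] = ("CON", "INC", "MOD", "SEV"),
) -> DisorderSummary:
    """Full per-stage disorder report for a hub gene set.

    Note: when ``dim <= len(hub_genes)`` every subset determinant is exactly 0
    (a correlation matrix from dim samples has centered rank <= dim - 1), so
    the determinant entropy at such dims is degenerate by construction; it is
    computed and reported honestly.
    """
    hub = m.subset_genes(list(hub_genes))
    determinant: dict[str, float] = {}
    entropy: dict[str, float] = {}
    per_dim: dict[int, dict[str, float]] = {}
    for stage in stages:
        r = pearson_matrix(hub, stage)
        determinant[stage] = system_determinant(r)
        entropy[stage] = system_entropy(r)[1]
    for dim in dims:
        sets = {s: subset_determinants(hub, dim, stage=s) for s in stages}
        hists = determinant_entropy(sets)
        per_dim[dim] = {s: hists[s].entropy for s in stages}
    return DisorderSummary(determinant=determinant, system_entropy=entropy,
                           determinant_entropy=per_dim, hub_genes=tuple(hub_genes))
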