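"""Expression-matrix I/O and preprocessing.

Expression data are genes x samples tables (TSV/CSV, first column gene ids,
header row sample ids).  Disease-severity stage labels (CON / INC / MOD / SEV)
are supplied externally through a sample->stage mapping, never inferred from
sample ids.  Preprocessing covers the transforms used on microarray series:
log2, per-sample z-scoring (population standard deviation), and quantile
normalization as the between-array step.  Every applied transform is recorded
in the matrix provenance so downstream results are auditable.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import GenePanel

STAGES = ("CON", "INC", "MOD", "SEV")

_TRANSFORMS = ("log2", "zscore_by_sample", "quantile_normalize")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with ids, stage labels and provenance."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    stage: dict[str, str] = field(default_factory=dict)  # sample_id -> stage
    provenance: list[str] = field(default_factory=lambda: ["raw"])

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dupes = sorted({i for i in ids if i in seen or seen.add(i)})
                raise ValueError(f"duplicate {name} ids: {dupes}")
        unknown = sorted(set(self.stage) - set(self.sample_ids))
        if unknown:
            raise ValueError(f"stage labels for unknown samples: {unknown}")
        bad = sorted({s for s in self.stage.values() if s not in STAGES})
        if bad:
            raise ValueError(f"unknown stage labels {bad}; expected {STAGES}")

    # -- convenience ---------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def stage_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in STAGES}
        for lab in self.stage.values():
            counts[lab] += 1
        return {s: n for s, n in counts.items() if n}

    def row(self, gene_id: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None
        return self.values[i]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            values=self.values[:, idx].copy(),
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            stage={s: self.stage[s] for s in sample_ids if s in self.stage},
            provenance=list(self.provenance),
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.gene_ids]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return ExpressionMatrix(
            values=self.values[idx].copy(),
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            stage=dict(self.stage),
            provenance=list(self.provenance),
        )

    def restrict_stage(self, stage: str) -> "ExpressionMatrix":
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        ids = [s for s in self.sample_ids if self.stage.get(s) == stage]
        if not ids:
            raise ValueError(f"no samples labelled {stage}")
        return self.subset_samples(ids)


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates (MMSE cognitive score, NFT burden, ...)."""

    sample_ids: list[str]
    mmse: np.ndarray | None = None
    nft: np.ndarray | None = None
    braak: np.ndarray | None = None
    pmi: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for name in ("mmse", "nft", "braak", "pmi"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (n,):
                    raise ValueError(f"{name} length {v.shape} != {n} samples")
                setattr(self, name, v)
        if self.mmse is not None:
            ok = np.isnan(self.mmse) | ((self.mmse >= 0) & (self.mmse <= 30))
            if not ok.all():
                raise ValueError("MMSE values must lie in [0, 30]")
        if self.nft is not None:
            ok = np.isnan(self.nft) | (self.nft >= 0)
            if not ok.all():
                raise ValueError("NFT values must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for name in ("mmse", "nft", "braak", "pmi"):
            v = getattr(self, name)
            if v is not None:
                cols[name.upper() if name in ("mmse", "nft", "pmi") else "Braak"] = v
        return pd.DataFrame(cols, index=pd.Index(self.sample_ids, name="sample_id"))

    def column(self, name: str) -> np.ndarray:
        v = getattr(self, name.lower())
        if v is None:
            raise KeyError(f"clinical column {name!r} not present")
        return v


# -- readers / writers -------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    first = path.read_text().splitlines()
    if not first or not first[0].strip():
        raise ValueError(f"empty expression table: {path}")
    sep = "\t" if "\t" in first[0] else ","
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str)


def read_expression_table(
    path: str | Path, stage_map: Mapping[str, str] | None = None
) -> ExpressionMatrix:
    """Read a genes x samples TSV/CSV table into an :class:`ExpressionMatrix`.

    ``stage_map`` maps sample ids to CON/INC/MOD/SEV; unmapped samples carry
    no stage label.  Duplicate gene ids and non-numeric cells are errors.
    """
    df = _read_table(path)
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate gene ids in {path}: {dupes}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell at gene {df.index[i]!r}, sample {col!r}: {raw!r}"
                ) from None
    stage = {}
    if stage_map:
        stage = {s: stage_map[s] for s in df.columns if s in stage_map}
    return ExpressionMatrix(
        values=values,
        gene_ids=list(df.index),
        sample_ids=list(df.columns),
        stage=stage,
        provenance=["raw"],
    )


def write_expression_table(m: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    m.to_frame().to_csv(path, sep=sep, index_label="gene_id", float_format="%.17g")


def read_stage_map(path: str | Path) -> dict[str, str]:
    """Read a TSV with header ``sample_id\\tstage`` into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "stage"} <= set(df.columns):
        raise ValueError("stage map needs columns 'sample_id' and 'stage'")
    return dict(zip(df["sample_id"], df["stage"]))


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read a TSV with header sample_id, MMSE, NFT[, Braak, PMI]."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("clinical table needs a 'sample_id' column")
    lower = {c.lower(): c for c in df.columns}
    kwargs = {}
    for name in ("mmse", "nft", "braak", "pmi"):
        if name in lower:
            kwargs[name] = df[lower[name]].to_numpy(dtype=float)
    return ClinicalTable(sample_ids=[str(s) for s in df["sample_id"]], **kwargs)


def write_clinical_table(t: ClinicalTable, path: str | Path) -> None:
    t.to_frame().to_csv(path, sep="\t", float_format="%.17g")


# -- preprocessing -----------------------------------------------------------

def _log2(values: np.ndarray, offset: float) -> np.ndarray:
    shifted = values + offset
    if (shifted <= 0).any():
        n = int((shifted <= 0).sum())
        raise ValueError(
            f"log2 undefined: {n} values <= 0 after offset {offset}; "
            "supply a positive log_offset"
        )
    return np.log2(shifted)


def _zscore_by_sample(values: np.ndarray, sample_ids: Sequence[str]) -> np.ndarray:
    mean = values.mean(axis=0)
    sd = values.std(axis=0)  # population (1/n) convention
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [sample_ids[j] for j in zero]
        raise ValueError(f"zero-variance sample column(s) under z-score: {names}")
    return (values - mean) / sd


def _quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Make every column's empirical distribution the mean-of-sorted-rows
    reference; tied values receive the average of the reference values their
    ranks span."""
    n_genes = values.shape[0]
    reference = np.sort(values, axis=0).mean(axis=1)
    df = pd.DataFrame(values)
    ranks = df.rank(axis=0, method="average").to_numpy()
    return np.interp(ranks, np.arange(1, n_genes + 1), reference)


def preprocess(
    m: ExpressionMatrix,
    steps: Iterable[str],
    log_offset: float = 0.0,
) -> ExpressionMatrix:
    """Apply transforms in the given order, extending provenance.

    Steps: ``log2`` (base-2 log after adding ``log_offset``),
    ``zscore_by_sample`` (center/scale each sample column, population sd),
    ``quantile_normalize`` (between-array step: identical column distributions).
    """
    if log_offset < 0:
        raise ValueError("log_offset must be nonnegative")
    values = m.values.copy()
    prov = list(m.provenance)
    for step in steps:
        if step not in _TRANSFORMS:
            raise ValueError(f"unknown step {step!r}; valid steps: {_TRANSFORMS}")
        if step == "log2":
            values = _log2(values, log_offset)
            prov.append("log2" if log_offset == 0 else f"log2(+{log_offset:g})")
        elif step == "zscore_by_sample":
            values = _zscore_by_sample(values, m.sample_ids)
            prov.append("zscore_by_sample")
        else:
            values = _quantile_normalize(values)
            prov.append("quantile_normalize")
    return replace(m, values=values, provenance=prov,
                   gene_ids=list(m.gene_ids), sample_ids=list(m.sample_ids),
                   stage=dict(m.stage))


# -- panel subsetting --------------------------------------------------------

def collapse_and_subset(
    m: ExpressionMatrix,
    panel: GenePanel,
    collapse_rule: str = "max_mean",
    symbol_map: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Collapse probe-level rows to panel symbols and order rows by the panel.

    ``symbol_map`` maps row ids (e.g. probe ids) to gene symbols; rows without
    a mapping keep their own id as symbol.  When several rows map to one
    symbol the ``max_mean`` rule keeps the row with greatest mean expression
    (the common microarray convention).
    """
    if collapse_rule != "max_mean":
        raise ValueError(f"unknown collapse rule {collapse_rule!r}")
    symbol_of = lambda g: symbol_map.get(g, g) if symbol_map else g
    rows_for: dict[str, list[int]] = {}
    for i, g in enumerate(m.gene_ids):
        rows_for.setdefault(symbol_of(g), []).append(i)
    missing = [s for s in panel.symbols if s not in rows_for]
    if missing:
        raise ValueError(f"panel symbols absent from table: {missing}")
    keep = []
    for s in panel.symbols:
        idx = rows_for[s]
        means = m.values[idx].mean(axis=1)
        keep.append(idx[int(np.argmax(means))])
    return ExpressionMatrix(
        values=m.values[keep].copy(),
        gene_ids=list(panel.symbols),
        sample_ids=list(m.sample_ids),
        stage=dict(m.stage),
        provenance=list(m.provenance) + [f"collapse:{collapse_rule};panel:{len(panel)}"],
    )


def exclude_by_pmi(
    m: ExpressionMatrix, clinical: ClinicalTable, pmi_threshold: float
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop samples whose postmortem interval exceeds ``pmi_threshold`` hours.

    Returns the filtered matrix and the list of excluded sample ids.  Samples
    without a PMI value are kept.
    """
    if clinical.pmi is None:
        return m, []
    pmi = dict(zip(clinical.sample_ids, clinical.pmi))
    excluded = [
        s for s in m.sample_ids
        if s in pmi and np.isfinite(pmi[s]) and pmi[s] > pmi_threshold
    ]
    if not excluded:
        return m, []
    kept = [s for s in m.sample_ids if s not in excluded]
    return m.subset_samples(kept), excluded
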