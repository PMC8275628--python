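"""In-memory containers for ploidy-resolved single-nucleus count data.

The central object is :class:`CountMatrix`: a dense nuclei x features matrix of
non-negative integer read counts together with a feature table (gene name,
ERCC spike-in flag, gene length in kilobases) and a nucleus metadata table
(ploidy gate, plate, animal, ERCC dilution group, technical-replicate flag).
Normalized expression lives in :class:`NormalizedMatrix`, which additionally
records the ERCC size factors and transform flags that produced it, so every
downstream result carries full provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PLOIDY_LEVELS = ("2n", "4n", "8n", "16n")

#: columns required in the feature table (indexed by feature_id)
FEATURE_COLUMNS = ("gene_name", "is_ercc", "length_kb")
#: columns required in the nucleus table (indexed by nucleus_id)
NUCLEUS_COLUMNS = ("ploidy", "plate_id", "animal_id", "dilution_group", "is_technical_replicate")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what} ids: {dups}")


@dataclass
class CountMatrix:
    """Nuclei x features raw count matrix with aligned metadata tables.

    Parameters
    ----------
    counts
        Dense ``(n_nuclei, n_features)`` array of non-negative integers.
    features
        DataFrame indexed by ``feature_id`` with columns ``gene_name``,
        ``is_ercc`` (bool) and ``length_kb`` (gene length in kilobases,
        strictly positive for endogenous genes).
    nuclei
        DataFrame indexed by ``nucleus_id`` with columns ``ploidy``,
        ``plate_id``, ``animal_id``, ``dilution_group`` and
        ``is_technical_replicate``.
    """

    counts: np.ndarray
    features: pd.DataFrame
    nuclei: pd.DataFrame

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D nuclei x features matrix")
        if counts.shape != (len(self.nuclei), len(self.features)):
            raise ValueError(
                f"counts shape {counts.shape} does not match metadata "
                f"({len(self.nuclei)} nuclei, {len(self.features)} features)"
            )
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            if counts.size and not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError("counts must be integral")
            counts = counts.astype(np.int64)
        self.counts = counts

        _check_unique(self.features.index, "feature")
        _check_unique(self.nuclei.index, "nucleus")
        for col in FEATURE_COLUMNS:
            if col not in self.features.columns:
                raise ValueError(f"feature table missing column {col!r}")
        for col in NUCLEUS_COLUMNS:
            if col not in self.nuclei.columns:
                raise ValueError(f"nucleus table missing column {col!r}")
        self.features = self.features.copy()
        self.features["is_ercc"] = self.features["is_ercc"].astype(bool)
        endo = ~self.features["is_ercc"].to_numpy()
        lengths = self.features["length_kb"].to_numpy(dtype=float)
        if np.any(~(lengths[endo] > 0)):
            raise ValueError("length_kb must be > 0 for all endogenous genes")

    # -- convenience views ---------------------------------------------------

    @property
    def n_nuclei(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    @property
    def is_ercc(self) -> np.ndarray:
        """Boolean mask over features; True for ERCC spike-ins."""
        return self.features["is_ercc"].to_numpy()

    @property
    def endogenous_counts(self) -> np.ndarray:
        return self.counts[:, ~self.is_ercc]

    @property
    def ercc_counts(self) -> np.ndarray:
        return self.counts[:, self.is_ercc]

    def subset(
        self,
        nucleus_mask: np.ndarray | None = None,
        feature_mask: np.ndarray | None = None,
    ) -> "CountMatrix":
        """Return a new CountMatrix restricted to the masked rows/columns."""
        nmask = np.ones(self.n_nuclei, bool) if nucleus_mask is None else np.asarray(nucleus_mask)
        fmask = np.ones(self.n_features, bool) if feature_mask is None else np.asarray(feature_mask)
        return CountMatrix(
            counts=self.counts[np.ix_(nmask, fmask)],
            features=self.features.loc[fmask].copy(),
            nuclei=self.nuclei.loc[nmask].copy(),
        )

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), self.features.copy(), self.nuclei.copy())


@dataclass
class SizeFactorTable:
    """Per-nucleus ERCC size factors.

    ``table`` is indexed by nucleus_id with columns ``sf`` (positive real) and
    ``dilution_group``.  By construction size factors average to one within
    each dilution group.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not {"sf", "dilution_group"} <= set(self.table.columns):
            raise ValueError("size factor table needs columns 'sf' and 'dilution_group'")
        sf = self.table["sf"].to_numpy(dtype=float)
        if np.any(~(sf > 0)):
            raise ValueError("size factors must be strictly positive")
        means = self.table.groupby("dilution_group", observed=True)["sf"].mean()
        if not np.allclose(means.to_numpy(), 1.0, rtol=1e-9, atol=1e-9):
            raise ValueError(f"size factors must average to 1 per dilution group, got {means.to_dict()}")

    @property
    def sf(self) -> pd.Series:
        return self.table["sf"]

    def align(self, nucleus_ids: pd.Index) -> np.ndarray:
        missing = nucleus_ids.difference(self.table.index)
        if len(missing):
            raise ValueError(f"no size factor for nuclei: {list(missing[:5])}")
        return self.table.loc[nucleus_ids, "sf"].to_numpy(dtype=float)


@dataclass
class NormalizedMatrix:
    """ERCC-normalized (optionally log/batch-corrected) expression.

    Only endogenous genes are kept.  Before the log transform the per-nucleus
    totals obey the normalization contract
    ``sum_j values[i, j] == scale_constant * sf_i``.
    """

    values: np.ndarray
    genes: pd.DataFrame
    nuclei: pd.DataFrame
    size_factors: SizeFactorTable
    scale_constant: float = 10_000.0
    is_log: bool = False
    is_batch_corrected: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.nuclei), len(self.genes)):
            raise ValueError("values shape does not match metadata tables")
        if not np.all(np.isfinite(values)):
            raise ValueError("normalized values must be finite")
        if not self.is_log and values.size and values.min() < 0:
            raise ValueError("normalized (non-log) values must be non-negative")
        self.values = values
        if not self.scale_constant > 0:
            raise ValueError("scale_constant must be positive")

    @property
    def n_nuclei(self) -> int:
        return self.values.shape[0]

    @property
    def gene_names(self) -> pd.Index:
        return pd.Index(self.genes["gene_name"])

    def gene_index(self, gene_names: list[str]) -> np.ndarray:
        """Column positions of the given gene names (error if any missing)."""
        lookup = pd.Index(self.genes["gene_name"])
        pos = lookup.get_indexer(gene_names)
        if np.any(pos < 0):
            missing = [g for g, p in zip(gene_names, pos) if p < 0]
            raise KeyError(f"genes not in matrix: {missing}")
        return pos

    def subset_nuclei(self, mask: np.ndarray) -> "NormalizedMatrix":
        mask = np.asarray(mask)
        return dataclasses.replace(
            self, values=self.values[mask], nuclei=self.nuclei.loc[mask].copy()
        )

    def copy(self) -> "NormalizedMatrix":
        return dataclasses.replace(self, values=self.values.copy(), nuclei=self.nuclei.copy())


@dataclass
class FilterReport:
    """Ordered record of the QC filter cascade.

    ``steps`` is a list of ``(step_name, n_nuclei_kept, n_features_kept)``
    tuples beginning with the input dimensions; counts are monotone
    non-increasing across steps.
    """

    steps: list[tuple[str, int, int]] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def add(self, name: str, n_nuclei: int, n_features: int) -> None:
        if self.steps:
            _, prev_n, prev_f = self.steps[-1]
            if n_nuclei > prev_n or n_features > prev_f:
                raise ValueError("filter report counts must be non-increasing")
        self.steps.append((name, int(n_nuclei), int(n_features)))

    def to_json(self) -> str:
        return json.dumps(
            {
                "steps": [
                    {"step": s, "n_nuclei": n, "n_features": f} for s, n, f in self.steps
                ],
                "thresholds": self.thresholds,
            },
            indent=2,
        )

    def __str__(self) -> str:  # human-readable cascade
        lines = ["QC filter cascade:"]
        for name, n, f in self.steps:
            lines.append(f"  {name:<28s} {n:>6d} nuclei x {f:>6d} features")
        return "\n".join(lines)
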