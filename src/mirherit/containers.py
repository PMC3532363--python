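"""In-memory containers shared across the analysis stages.

All containers are thin, validated wrappers around pandas objects so that
every stage can rely on consistent indexing (genes x samples, miRNAs x
samples, SNPs x samples) without re-checking identifiers.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .exceptions import ParameterError

VALID_ROLES = frozenset({"father", "mother", "child", "unrelated"})

CONVENTIONAL = "conventional"
MIRTRON = "mirtron"


class ExpressionMatrix:
    """Normalized gene expression, genes in rows, samples in columns.

    Parameters
    ----------
    values
        DataFrame of non-negative, finite expression values indexed by gene
        identifier with sample identifiers as columns.
    sample_meta
        DataFrame indexed by sample identifier with at least a ``population``
        column and a ``role`` column (father / mother / child / unrelated).
    """

    def __init__(self, values: pd.DataFrame, sample_meta: pd.DataFrame):
        if values.index.has_duplicates:
            raise ParameterError("duplicate gene identifiers")
        if values.columns.has_duplicates:
            raise ParameterError("duplicate sample identifiers")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ParameterError("expression values must be finite")
        if (arr < 0).any():
            raise ParameterError("expression values must be non-negative")
        missing_meta = values.columns.difference(sample_meta.index)
        if len(missing_meta):
            raise ParameterError(
                f"samples missing from metadata: {list(missing_meta[:5])}"
            )
        if "population" not in sample_meta.columns or "role" not in sample_meta.columns:
            raise ParameterError("sample_meta needs 'population' and 'role' columns")
        bad_roles = set(sample_meta["role"]) - VALID_ROLES
        if bad_roles:
            raise ParameterError(f"unknown sample roles: {sorted(bad_roles)}")
        self.values = values.astype(float)
        self.sample_meta = sample_meta.loc[values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def population(self) -> pd.Series:
        return self.sample_meta["population"]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = self.values.index.intersection(pd.Index(genes))
        return ExpressionMatrix(self.values.loc[keep], self.sample_meta)

    def drop_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = self.values.index.difference(pd.Index(genes))
        return ExpressionMatrix(self.values.loc[keep], self.sample_meta)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<ExpressionMatrix {self.n_genes} genes x {self.n_samples} samples>"


@dataclass(frozen=True)
class TargetSet:
    """One miRNA's predicted target genes."""

    mirna_id: str
    genes: frozenset
    mirna_class: str = CONVENTIONAL
    provenance: str = "simulated"

    def __post_init__(self):
        if not self.genes:
            raise ParameterError(f"target set for {self.mirna_id} is empty")
        if self.mirna_class not in (CONVENTIONAL, MIRTRON):
            raise ParameterError(f"unknown miRNA class {self.mirna_class!r}")

    def __len__(self) -> int:
        return len(self.genes)


class TargetSetCollection:
    """Ordered collection of miRNA target sets, conventional or mirtron."""

    def __init__(self, sets: Iterable[TargetSet]):
        self._sets: dict[str, TargetSet] = {}
        for ts in sets:
            if ts.mirna_id in self._sets:
                raise ParameterError(f"duplicate miRNA identifier {ts.mirna_id}")
            self._sets[ts.mirna_id] = ts

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[TargetSet]:
        return iter(self._sets.values())

    def __contains__(self, mirna_id: str) -> bool:
        return mirna_id in self._sets

    def __getitem__(self, mirna_id: str) -> TargetSet:
        return self._sets[mirna_id]

    @property
    def mirna_ids(self) -> list[str]:
        return list(self._sets)

    def classes(self) -> pd.Series:
        return pd.Series({m: ts.mirna_class for m, ts in self._sets.items()})

    def mirtrons(self) -> list[str]:
        return [m for m, ts in self._sets.items() if ts.mirna_class == MIRTRON]

    def conventional(self) -> list[str]:
        return [m for m, ts in self._sets.items() if ts.mirna_class == CONVENTIONAL]

    def set_sizes(self) -> pd.Series:
        return pd.Series({m: len(ts) for m, ts in self._sets.items()})

    def gene_universe(self) -> set:
        out: set = set()
        for ts in self._sets.values():
            out |= ts.genes
        return out

    def membership_counts(self) -> pd.Series:
        """Number of target sets containing each targeted gene."""
        counts: dict = {}
        for ts in self._sets.values():
            for g in ts.genes:
                counts[g] = counts.get(g, 0) + 1
        return pd.Series(counts, dtype=int)

    def restrict_to(self, genes: Iterable[str]) -> "TargetSetCollection":
        """Intersect every set with ``genes``; drops sets left empty."""
        keep = set(genes)
        out = []
        for ts in self._sets.values():
            g = ts.genes & keep
            if g:
                out.append(TargetSet(ts.mirna_id, frozenset(g), ts.mirna_class, ts.provenance))
        return TargetSetCollection(out)


@dataclass
class REScoreMatrix:
    """Per-miRNA, per-sample RE-scores and the per-sample mean RE-score.

    ``re`` is miRNAs x samples; ``mean_re`` is the arithmetic mean over the
    miRNA rows for each sample; ``n_targets_used`` records how many targets of
    each miRNA were present in the expression matrix when scoring.
    """

    re: pd.DataFrame
    n_targets_used: pd.Series
    mean_re: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.mean_re is None:
            self.mean_re = self.re.mean(axis=0)
        self.mean_re.name = "mean_re"

    @property
    def mirna_ids(self) -> pd.Index:
        return self.re.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.re.columns


class TrioTable:
    """Father / mother / child sample identifiers, one row per trio."""

    COLUMNS = ("trio_id", "father", "mother", "child")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ParameterError(f"trio table missing columns {missing}")
        ids = pd.concat([table["father"], table["mother"], table["child"]])
        if ids.duplicated().any():
            raise ParameterError("a sample appears in more than one trio role")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def fathers(self) -> pd.Series:
        return self.table["father"]

    @property
    def mothers(self) -> pd.Series:
        return self.table["mother"]

    @property
    def children(self) -> pd.Series:
        return self.table["child"]

    def all_samples(self) -> list[str]:
        out: list[str] = []
        for _, row in self.table.iterrows():
            out.extend([row["father"], row["mother"], row["child"]])
        return out


class GenotypeMatrix:
    """Additive minor-allele counts, SNPs x samples, NaN for missing.

    ``meta`` is indexed by SNP id with columns ``chrom``, ``pos`` (1-based),
    ``ref``, ``alt`` and an optional ``region_gene`` label (e.g. DROSHA).
    """

    def __init__(self, codes: pd.DataFrame, meta: pd.DataFrame):
        if codes.index.has_duplicates:
            raise ParameterError("duplicate SNP identifiers")
        arr = codes.to_numpy(dtype=float)
        valid = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ParameterError("genotype codes must be 0, 1, 2 or missing")
        missing_meta = codes.index.difference(meta.index)
        if len(missing_meta):
            raise ParameterError(f"SNPs missing metadata: {list(missing_meta[:5])}")
        if (meta.loc[codes.index, "pos"] <= 0).any():
            raise ParameterError("positions must be positive 1-based integers")
        self.codes = codes.astype(float)
        self.meta = meta.loc[codes.index]
        if "region_gene" not in self.meta.columns:
            self.meta = self.meta.assign(region_gene=pd.NA)

    @property
    def snp_ids(self) -> pd.Index:
        return self.codes.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.codes.columns

    @property
    def n_snps(self) -> int:
        return self.codes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.codes.shape[1]

    def subset_snps(self, snps: Iterable[str]) -> "GenotypeMatrix":
        keep = self.codes.index.intersection(pd.Index(snps))
        return GenotypeMatrix(self.codes.loc[keep], self.meta)

    def subset_samples(self, samples: Iterable[str]) -> "GenotypeMatrix":
        keep = self.codes.columns.intersection(pd.Index(samples))
        return GenotypeMatrix(self.codes[keep], self.meta)

    def restrict_to_genes(self, genes: Iterable[str]) -> "GenotypeMatrix":
        """Keep SNPs whose region_gene label is in ``genes`` (candidate scan)."""
        wanted = set(genes)
        mask = self.meta["region_gene"].isin(wanted)
        return GenotypeMatrix(self.codes.loc[mask.to_numpy()], self.meta)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<GenotypeMatrix {self.n_snps} SNPs x {self.n_samples} samples>"
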