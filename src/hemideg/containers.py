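"""Core validated containers shared across the pipeline.

Counts are stored as pandas DataFrames (genes x samples / genes x cells) so
that downstream code can rely on label alignment; validation happens once,
at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


def _check_unique(ids, kind: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {kind} identifier(s): {dup[:5]}")


@dataclass
class CountMatrix:
    """Nonnegative integer gene x sample expression counts.

    Parameters
    ----------
    counts : DataFrame
        Genes in rows, samples in columns. Must be nonnegative and integral
        unless ``allow_rounding`` is set, in which case values within 1e-6 of
        an integer are rounded and anything else rejected.
    """

    counts: pd.DataFrame
    allow_rounding: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "sample")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(~np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite count at gene {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        rounded = np.rint(values)
        if not np.allclose(values, rounded, atol=1e-6, rtol=0):
            if not self.allow_rounding:
                r, c = np.argwhere(np.abs(values - rounded) > 1e-6)[0]
                raise ValidationError(
                    f"non-integer count at gene {self.counts.index[r]!r}, "
                    f"sample {self.counts.columns[c]!r} "
                    "(pass allow_rounding=True to round estimates)"
                )
        self.counts = pd.DataFrame(
            rounded.astype(np.int64),
            index=self.counts.index.astype(str),
            columns=self.counts.columns.astype(str),
        )

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)])

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(samples)])

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, CountMatrix) and self.counts.equals(other.counts)


REQUIRED_DESIGN_COLUMNS = ("sample_id", "region", "condition", "side", "subject")


@dataclass
class SampleDesign:
    """Per-sample factors (region, condition, side, subject).

    The condition reference level is ``Sham`` when present (otherwise the
    first level in file order), so a positive condition effect reads
    "up in SNL". The side reference is ``Right``, so a positive side effect
    reads "Left vs Right".
    """

    table: pd.DataFrame
    condition_reference: str = field(default="", repr=False)
    side_reference: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"design table missing column(s): {missing}")
        _check_unique(self.table["sample_id"], "sample")
        self.table = self.table.astype(str).reset_index(drop=True)
        cond_levels = self.table["condition"].drop_duplicates().tolist()
        side_levels = self.table["side"].drop_duplicates().tolist()
        if not self.condition_reference:
            self.condition_reference = (
                "Sham" if "Sham" in cond_levels else cond_levels[0]
            )
        if not self.side_reference:
            self.side_reference = "Right" if "Right" in side_levels else side_levels[0]
        for region, sub in self.table.groupby("region"):
            if sub["condition"].nunique() != 2:
                raise ValidationError(
                    f"region {region!r}: condition must have exactly 2 levels, "
                    f"found {sorted(sub['condition'].unique())}"
                )
            if sub["side"].nunique() != 2:
                raise ValidationError(
                    f"region {region!r}: side must have exactly 2 levels, "
                    f"found {sorted(sub['side'].unique())}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def regions(self) -> list[str]:
        return self.table["region"].drop_duplicates().tolist()

    def for_region(self, region: str) -> "SampleDesign":
        sub = self.table[self.table["region"] == region]
        if sub.empty:
            raise ValidationError(f"no samples for region {region!r}")
        return SampleDesign(
            sub.copy(),
            condition_reference=self.condition_reference,
            side_reference=self.side_reference,
        )

    def check_cells(self, min_per_cell: int = 2) -> None:
        """Require every (condition, side) cell to hold >= min_per_cell samples."""
        sizes = self.table.groupby(["condition", "side"]).size()
        if len(sizes) < 4 or (sizes < min_per_cell).any():
            small = sizes[sizes < min_per_cell] if len(sizes) == 4 else sizes
            raise ValidationError(
                "two-factor model needs >= "
                f"{min_per_cell} samples in every condition x side cell; got "
                f"{sizes.to_dict()}"
            )

    def match(self, counts: CountMatrix) -> None:
        if set(self.sample_ids) != set(counts.sample_ids):
            only_d = set(self.sample_ids) - set(counts.sample_ids)
            only_c = set(counts.sample_ids) - set(self.sample_ids)
            raise ValidationError(
                f"design/count sample mismatch: design-only={sorted(only_d)[:5]}, "
                f"counts-only={sorted(only_c)[:5]}"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets: list of (term_id, term_name, frozenset of gene ids)."""

    terms: list[tuple[str, str, frozenset]]

    def __post_init__(self) -> None:
        _check_unique([t[0] for t in self.terms], "term")
        for term_id, _, members in self.terms:
            if not members:
                raise ValidationError(f"term {term_id!r} has no member genes")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)


@dataclass
class ReferenceMatrix:
    """Cluster-labeled single-cell-like reference counts (genes x cells)."""

    counts: pd.DataFrame
    cell_labels: pd.Series  # cell_id -> cell-type name

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "cell")
        self.cell_labels = self.cell_labels.astype(str)
        missing = [c for c in self.counts.columns if c not in self.cell_labels.index]
        if missing:
            raise ValidationError(f"cells without a label: {missing[:5]}")
        self.cell_labels = self.cell_labels.loc[self.counts.columns]
        if self.cell_labels.nunique() < 2:
            raise ValidationError("reference must contain >= 2 distinct cell types")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("reference counts must be nonnegative")

    @property
    def cell_types(self) -> list[str]:
        return self.cell_labels.drop_duplicates().tolist()
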