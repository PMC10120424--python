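"""Core domain types.

The package works with four kinds of objects:

* :class:`VariantRecord` — a single-nucleotide variant (SNV) with genomic
  coordinates and, for training data, a binary class label
  (1 = pathogenic, 0 = proxy-benign).
* :class:`FeatureMatrix` — per-variant numeric annotations with an explicit
  missingness mask and per-feature metadata (category + imputation policy).
* :class:`CytobandMap` — cytogenetic band intervals, the unit of fold
  assignment in leakage-aware cross-validation.
* :class:`ScoreTrack` — a sorted, position-indexed table of per-position
  pathogenicity scores supporting point and range lookup.

Coordinate conventions: variants and score tracks are 1-based (VCF style);
cytoband intervals are 0-based half-open (BED style). Mapping a variant into
a band therefore uses ``pos - 1`` against ``[start, end)``. Chromosome names
are opaque strings — no "chr" prefix harmonisation is attempted.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FEATURE_CATEGORIES",
    "IMPUTATION_POLICIES",
    "VariantRecord",
    "FeatureMeta",
    "FeatureMatrix",
    "CytobandMap",
    "ScoreTrack",
]

#: Broad annotation categories the feature set draws from.
FEATURE_CATEGORIES = (
    "sequence composition",
    "epigenetics",
    "conservation",
    "population variance",
    "regulatory regions",
)

#: Constant imputation policies for missing feature values.
IMPUTATION_POLICIES = ("zero", "genome-mean", "one")


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One labeled (or unlabeled query) single-nucleotide variant.

    ``pos`` is 1-based. ``label`` is 1 for pathogenic, 0 for proxy-benign,
    ``None`` for query variants without a class.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    label: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(
                f"only SNVs are supported: ref={self.ref!r} alt={self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True, slots=True)
class FeatureMeta:
    """Name, broad category and imputation policy of one feature."""

    name: str
    category: str
    imputation: str

    def __post_init__(self) -> None:
        if self.category not in FEATURE_CATEGORIES:
            raise ValueError(
                f"unknown feature category {self.category!r} for {self.name!r}; "
                f"expected one of {FEATURE_CATEGORIES}"
            )
        if self.imputation not in IMPUTATION_POLICIES:
            raise ValueError(
                f"unknown imputation policy {self.imputation!r} for {self.name!r}; "
                f"expected one of {IMPUTATION_POLICIES}"
            )


class FeatureMatrix:
    """Variants × features matrix with an explicit missingness mask.

    Every cell is either a finite float or flagged missing in ``mask``;
    after imputation the mask is all-``False``.
    """

    def __init__(
        self,
        values: np.ndarray,
        mask: np.ndarray,
        metadata: Sequence[FeatureMeta],
    ) -> None:
        values = np.asarray(values, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if values.shape != mask.shape:
            raise ValueError(
                f"values shape {values.shape} != mask shape {mask.shape}"
            )
        if values.shape[1] != len(metadata):
            raise ValueError(
                f"{values.shape[1]} feature columns but {len(metadata)} metadata entries"
            )
        if not np.all(np.isfinite(values[~mask])):
            raise ValueError("non-missing cells must all be finite")
        self.values = values
        self.mask = mask
        self.metadata = list(metadata)

    @property
    def feature_names(self) -> list[str]:
        return [m.name for m in self.metadata]

    @property
    def n_variants(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def is_imputed(self) -> bool:
        return not bool(self.mask.any())

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), self.mask.copy(), self.metadata)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"FeatureMatrix({self.n_variants} variants x {self.n_features} features, "
            f"{int(self.mask.sum())} missing cells)"
        )


class CytobandMap:
    """Cytogenetic band intervals: (chrom, start, end, name), BED coordinates.

    Per chromosome, intervals must be sorted and non-overlapping. Band names
    must be unique genome-wide (they key fold assignment).
    """

    def __init__(self, records: Iterable[tuple[str, int, int, str]]) -> None:
        records = list(records)
        if not records:
            raise ValueError("empty cytoband list")
        names = [r[3] for r in records]
        if len(set(names)) != len(names):
            raise ValueError("band names must be unique")
        self.records = records
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, name in records:
            if not 0 <= start < end:
                raise ValueError(f"bad interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end, name))
        for chrom, ivals in by_chrom.items():
            starts = np.array([i[0] for i in ivals])
            ends = np.array([i[1] for i in ivals])
            if not (np.all(np.diff(starts) > 0) and np.all(ends[:-1] <= starts[1:])):
                raise ValueError(
                    f"intervals on {chrom} must be sorted and non-overlapping"
                )
            self._by_chrom[chrom] = (starts, ends, [i[2] for i in ivals])

    @property
    def band_names(self) -> list[str]:
        return [r[3] for r in self.records]

    def band_of(self, chrom: str, pos: int) -> str:
        """Band containing the 1-based position ``pos``.

        Raises ``KeyError`` if the position falls outside every band.
        """
        try:
            starts, ends, names = self._by_chrom[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} has no cytobands") from None
        p = pos - 1  # 1-based position vs 0-based half-open intervals
        i = int(np.searchsorted(starts, p, side="right")) - 1
        if i < 0 or p >= ends[i]:
            raise KeyError(f"position {chrom}:{pos} maps to no cytoband")
        return names[i]

    def bands_of(self, variants: Sequence[VariantRecord]) -> list[str]:
        return [self.band_of(v.chrom, v.pos) for v in variants]


class ScoreTrack:
    """Sorted per-position score records with point/range lookup.

    Records are ``(chrom, pos, score)`` with 1-based positions, one record
    per position, score in [0, 1]. Written as a sorted TSV; a ``.gz`` path
    triggers bgzip compression and tabix indexing so the file interoperates
    with htslib tooling.
    """

    def __init__(self, chroms: Sequence[str], positions: np.ndarray, scores: np.ndarray):
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        chroms = list(chroms)
        positions = np.asarray(positions, dtype=np.int64)
        scores = np.asarray(scores, dtype=float)
        if not (len(chroms) == len(positions) == len(scores)):
            raise ValueError("chroms, positions and scores must align")
        if len(scores) and (scores.min() < 0.0 or scores.max() > 1.0):
            raise ValueError("scores must lie in [0, 1]")
        order = np.lexsort((positions, np.asarray(chroms, dtype=object)))
        self.chroms = [chroms[i] for i in order]
        self.positions = positions[order]
        self.scores = scores[order]
        for chrom in dict.fromkeys(self.chroms):
            sel = np.array([c == chrom for c in self.chroms])
            pos, sc = self.positions[sel], self.scores[sel]
            if np.any(np.diff(pos) == 0):
                dup = int(pos[np.where(np.diff(pos) == 0)[0][0]])
                raise ValueError(f"duplicate position {chrom}:{dup} in score track")
            self._index[chrom] = (pos, sc)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, float]]) -> "ScoreTrack":
        records = list(records)
        return cls(
            [r[0] for r in records],
            np.array([r[1] for r in records], dtype=np.int64),
            np.array([r[2] for r in records], dtype=float),
        )

    def __len__(self) -> int:
        return len(self.positions)

    def to_records(self) -> list[tuple[str, int, float]]:
        return [
            (c, int(p), float(s))
            for c, p, s in zip(self.chroms, self.positions, self.scores)
        ]

    def lookup(self, chrom: str, start: int, end: int) -> list[tuple[int, float]]:
        """All (pos, score) records with ``start <= pos <= end`` (1-based,
        inclusive). Unknown chromosome yields an empty list, not an error."""
        if chrom not in self._index:
            return []
        pos, sc = self._index[chrom]
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="right"))
        return [(int(p), float(s)) for p, s in zip(pos[lo:hi], sc[lo:hi])]

    def write(self, path: str | os.PathLike, precision: int = 3) -> str:
        """Write the track as a sorted TSV ``chrom<TAB>pos<TAB>score``.

        Scores are serialized at ``precision`` decimals (default 3, matching
        the granularity of published whole-genome tracks). A ``.gz`` suffix
        produces a bgzip-compressed, tabix-indexed file.
        """
        path = os.fspath(path)
        compress = path.endswith(".gz")
        plain = path[:-3] if compress else path
        with open(plain, "w") as fh:
            for chrom, pos, score in zip(self.chroms, self.positions, self.scores):
                fh.write(f"{chrom}\t{pos}\t{score:.{precision}f}\n")
        if compress:
            import pysam

            pysam.tabix_compress(plain, path, force=True)
            os.remove(plain)
            pysam.tabix_index(path, seq_col=0, start_col=1, end_col=1, force=True)
        return path

    @classmethod
    def read(cls, path: str | os.PathLike) -> "ScoreTrack":
        path = os.fspath(path)
        opener = gzip.open if path.endswith(".gz") else open
        chroms: list[str] = []
        positions: list[int] = []
        scores: list[float] = []
        with opener(path, "rt") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 columns")
                chroms.append(parts[0])
                positions.append(int(parts[1]))
                scores.append(float(parts[2]))
        return cls(chroms, np.array(positions, dtype=np.int64), np.array(scores))
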