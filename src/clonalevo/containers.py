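"""In-memory containers shared across modules.

Genotype codes follow the single-cell DNA-seq convention: 0 wild type,
1 heterozygous mutant, 2 homozygous mutant (LOH), 3 missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

WT, HET, HOM, MISSING = 0, 1, 2, 3
VALID_CODES = frozenset({WT, HET, HOM, MISSING})


def _as_ids(ids: Sequence[str] | None, n: int, prefix: str) -> tuple[str, ...]:
    if ids is None:
        return tuple(f"{prefix}{i}" for i in range(n))
    ids = tuple(str(x) for x in ids)
    if len(ids) != n:
        raise ValueError(f"expected {n} {prefix} ids, got {len(ids)}")
    return ids


@dataclass
class GenotypeMatrix:
    """Per-cell x per-locus categorical genotype codes with metadata."""

    codes: np.ndarray
    cell_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]
    locus_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]
    sample_id: str = "sample"
    timepoint: str | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D (cells x loci) array")
        if self.codes.size == 0:
            raise ValueError("empty genotype matrix")
        bad = set(np.unique(self.codes)) - VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes present: {sorted(bad)}")
        self.cell_ids = _as_ids(self.cell_ids, self.codes.shape[0], "cell")
        self.locus_ids = _as_ids(self.locus_ids, self.codes.shape[1], "locus")

    @property
    def n_cells(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]

    @property
    def binary_view(self) -> bool:
        """True when no homozygous code is present."""
        return not bool((self.codes == HOM).any())

    def to_binary(self) -> "GenotypeMatrix":
        """Collapse homozygous calls into the mutant state (2 -> 1)."""
        codes = self.codes.copy()
        codes[codes == HOM] = HET
        return replace(self, codes=codes)

    def select_cells(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return replace(
            self,
            codes=self.codes[mask],
            cell_ids=tuple(np.asarray(self.cell_ids, dtype=object)[mask]),
        )

    def complete_cells(self) -> "GenotypeMatrix":
        """Cells with no missing genotype."""
        mask = ~(self.codes == MISSING).any(axis=1)
        if not mask.any():
            raise ValueError("no cell has a complete genotype")
        return self.select_cells(mask)


@dataclass
class ReadCountMatrix:
    """Per-cell x per-locus sequencing depth and alternate-allele counts."""

    depth: np.ndarray
    alt: np.ndarray
    cell_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]
    locus_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]
    locus_class: tuple[str, ...] = field(default=None)  # type: ignore[assignment]
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        if self.depth.shape != self.alt.shape or self.depth.ndim != 2:
            raise ValueError("depth and alt must be 2-D arrays of equal shape")
        if (self.depth < 0).any() or (self.alt < 0).any():
            raise ValueError("read counts must be non-negative")
        if (self.alt > self.depth).any():
            raise ValueError("alt count exceeds depth")
        self.cell_ids = _as_ids(self.cell_ids, self.depth.shape[0], "cell")
        self.locus_ids = _as_ids(self.locus_ids, self.depth.shape[1], "locus")
        if self.locus_class is None:
            self.locus_class = tuple("somatic" for _ in self.locus_ids)
        else:
            self.locus_class = tuple(self.locus_class)
            if len(self.locus_class) != self.depth.shape[1]:
                raise ValueError("locus_class length mismatch")
            unknown = set(self.locus_class) - {"somatic", "snp"}
            if unknown:
                raise ValueError(f"unknown locus classes: {sorted(unknown)}")

    @property
    def n_cells(self) -> int:
        return self.depth.shape[0]

    @property
    def n_loci(self) -> int:
        return self.depth.shape[1]

    def loci_of_class(self, cls: str) -> np.ndarray:
        return np.array([c == cls for c in self.locus_class])
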