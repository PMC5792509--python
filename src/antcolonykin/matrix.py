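"""Core containers: biallelic genotype matrices and allele frequency panels.

Genotype calls are encoded as small integers:

====  ==========================
code  meaning
====  ==========================
0     homozygous reference
1     heterozygous
2     homozygous alternate
-1    missing
====  ==========================

A :class:`GenotypeMatrix` is individuals x loci, each individual tagged with a
species, a tree (colony) id, and a caste (``worker`` or ``queen``).  Queens are
carried through the pipeline but handled specially downstream (excluded from,
or included in, relatedness averaging depending on whether they were recovered
as mothers of the sampled workers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

#: two-character genotype strings used by the TSV dialect
CALL_TO_STR = {HOM_REF: "AA", HET: "AB", HOM_ALT: "BB", MISSING: "--"}
STR_TO_CALL = {v: k for k, v in CALL_TO_STR.items()}

CASTES = ("worker", "queen")


@dataclass
class AlleleFrequencies:
    """Per-locus population frequency of the reference allele.

    Parameters
    ----------
    p : ndarray
        Reference-allele frequency per locus, each strictly inside (0, 1).
        The alternate-allele frequency is ``1 - p``.
    loci : ndarray of str
        Locus identifiers, same length as ``p``.
    """

    p: np.ndarray
    loci: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.loci = np.asarray(self.loci, dtype=object)
        if self.p.ndim != 1 or self.p.shape != self.loci.shape:
            raise ValueError("p and loci must be 1-D arrays of equal length")
        if self.p.size == 0:
            raise ValueError("empty frequency panel")
        if np.any((self.p <= 0.0) | (self.p >= 1.0)):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")

    @property
    def n_loci(self) -> int:
        return self.p.size

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequency per locus."""
        return np.minimum(self.p, 1.0 - self.p)


@dataclass
class GenotypeMatrix:
    """Rectangular matrix of biallelic genotype calls with individual labels."""

    calls: np.ndarray  # (n_individuals, n_loci) int8
    ids: np.ndarray  # individual ids, unique
    species: np.ndarray
    tree: np.ndarray
    caste: np.ndarray  # 'worker' | 'queen'
    loci: np.ndarray  # locus ids, unique
    #: queens recovered as mothers of sampled workers; excluded from
    #: relatedness averaging (others, e.g. sister queens, are kept)
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        for name in ("ids", "species", "tree", "caste", "loci"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x loci)")
        n, m = self.calls.shape
        if n == 0:
            raise ValueError("genotype matrix has no individuals")
        for name, arr in (("ids", self.ids), ("species", self.species),
                          ("tree", self.tree), ("caste", self.caste)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per individual")
        if self.loci.shape != (m,):
            raise ValueError("loci must have one entry per column")
        if len(set(self.ids)) != n:
            raise ValueError("duplicated individual ids")
        if len(set(self.loci)) != m:
            raise ValueError("duplicated locus ids")
        bad = set(self.caste) - set(CASTES)
        if bad:
            raise ValueError(f"unknown caste labels: {sorted(bad)}")
        valid = {HOM_REF, HET, HOM_ALT, MISSING}
        if not set(np.unique(self.calls)).issubset(valid):
            raise ValueError("calls contain codes outside {-1, 0, 1, 2}")
        if self.excluded is None:
            self.excluded = np.zeros(n, dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)
            if self.excluded.shape != (n,):
                raise ValueError("excluded must have one flag per individual")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def completeness(self) -> float:
        """Fraction of individual x locus cells with a called genotype."""
        return float(np.mean(self.calls != MISSING))

    def row_index(self, ind_id) -> int:
        idx = np.flatnonzero(self.ids == ind_id)
        if idx.size != 1:
            raise KeyError(f"unknown individual id: {ind_id!r}")
        return int(idx[0])

    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            calls=self.calls[index],
            ids=self.ids[index],
            species=self.species[index],
            tree=self.tree[index],
            caste=self.caste[index],
            loci=self.loci,
            excluded=self.excluded[index],
        )

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            calls=self.calls[:, index],
            ids=self.ids,
            species=self.species,
            tree=self.tree,
            caste=self.caste,
            loci=self.loci[index],
            excluded=self.excluded,
        )

    def subset_species(self, species) -> "GenotypeMatrix":
        return self.take_individuals(np.flatnonzero(self.species == species))

    def subset_tree(self, tree) -> "GenotypeMatrix":
        return self.take_individuals(np.flatnonzero(self.tree == tree))

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "species": self.species,
                "tree": self.tree,
                "caste": self.caste,
                "excluded": self.excluded,
            }
        )

    @staticmethod
    def concat(matrices: list["GenotypeMatrix"]) -> "GenotypeMatrix":
        """Stack matrices over individuals; loci must agree exactly."""
        if not matrices:
            raise ValueError("nothing to concatenate")
        first = matrices[0]
        for m in matrices[1:]:
            if not np.array_equal(m.loci, first.loci):
                raise ValueError("locus sets differ between matrices")
        return GenotypeMatrix(
            calls=np.concatenate([m.calls for m in matrices]),
            ids=np.concatenate([m.ids for m in matrices]),
            species=np.concatenate([m.species for m in matrices]),
            tree=np.concatenate([m.tree for m in matrices]),
            caste=np.concatenate([m.caste for m in matrices]),
            loci=first.loci,
            excluded=np.concatenate([m.excluded for m in matrices]),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.calls, other.calls)
            and np.array_equal(self.ids, other.ids)
            and np.array_equal(self.species, other.species)
            and np.array_equal(self.tree, other.tree)
            and np.array_equal(self.caste, other.caste)
            and np.array_equal(self.loci, other.loci)
            and np.array_equal(self.excluded, other.excluded)
        )
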