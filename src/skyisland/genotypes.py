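"""Diploid biallelic genotype matrices with population/group labels.

Genotypes are stored as alternate-allele dosages (0, 1, 2) in a float
array with ``nan`` marking missing calls.  Individuals are rows, loci are
columns.  Each individual belongs to a population; populations may be
nested in groups (e.g. species or mountain ranges) for hierarchical
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix"]


@dataclass
class GenotypeMatrix:
    """Individuals x loci dosage matrix with hierarchical labels.

    Parameters
    ----------
    genotypes
        Float array of shape ``(n_individuals, n_loci)`` holding alt-allele
        counts in {0, 1, 2} with ``nan`` for missing genotypes.
    individual_ids, locus_ids
        Unique labels for rows / columns.
    population
        Population label per individual.
    group
        Optional higher-level label per individual (constant within a
        population).
    """

    genotypes: np.ndarray
    individual_ids: list[str]
    population: list[str]
    group: list[str] | None = None
    locus_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x loci)")
        n, L = self.genotypes.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length mismatch")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual_ids must be unique")
        if len(self.population) != n:
            raise ValueError("population length mismatch")
        if self.locus_ids is None:
            self.locus_ids = [f"locus_{j}" for j in range(L)]
        if len(self.locus_ids) != L:
            raise ValueError("locus_ids length mismatch")
        valid = np.isnan(self.genotypes) | np.isin(self.genotypes, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("genotype entries must be 0, 1, 2 or missing (nan)")
        if self.group is not None:
            if len(self.group) != n:
                raise ValueError("group length mismatch")
            mapping: dict[str, str] = {}
            for pop, grp in zip(self.population, self.group):
                if mapping.setdefault(pop, grp) != grp:
                    raise ValueError(f"population {pop!r} spans multiple groups")

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        return list(dict.fromkeys(self.population))

    @property
    def groups(self) -> list[str]:
        if self.group is None:
            raise ValueError("no group labels attached")
        return list(dict.fromkeys(self.group))

    def population_of(self, pop: str) -> np.ndarray:
        """Row indices of individuals in population ``pop``."""
        return np.flatnonzero(np.asarray(self.population) == pop)

    def group_of_population(self, pop: str) -> str:
        if self.group is None:
            raise ValueError("no group labels attached")
        idx = self.population_of(pop)
        return self.group[idx[0]]

    def subset_individuals(self, indices: np.ndarray) -> "GenotypeMatrix":
        indices = np.asarray(indices)
        return GenotypeMatrix(
            genotypes=self.genotypes[indices],
            individual_ids=[self.individual_ids[i] for i in indices],
            population=[self.population[i] for i in indices],
            group=None if self.group is None else [self.group[i] for i in indices],
            locus_ids=list(self.locus_ids),
        )

    def subset_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            genotypes=self.genotypes[:, mask],
            individual_ids=list(self.individual_ids),
            population=list(self.population),
            group=None if self.group is None else list(self.group),
            locus_ids=[lid for lid, keep in zip(self.locus_ids, mask) if keep],
        )

    def labels_frame(self) -> pd.DataFrame:
        """Individual / population / group labels as a DataFrame."""
        data = {"individual": self.individual_ids, "population": self.population}
        if self.group is not None:
            data["group"] = self.group
        return pd.DataFrame(data)
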