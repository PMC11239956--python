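"""Aligned DNA sequence container for barcode analyses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SequenceAlignment", "IUPAC_CODES", "UNAMBIGUOUS"]

UNAMBIGUOUS = set("ACGT")
# IUPAC nucleotide codes plus gap characters accepted on input.
IUPAC_CODES = set("ACGTRYSWKMBDHVN-?")


@dataclass
class SequenceAlignment:
    """Equal-length DNA sequences with optional species labels.

    Sequences are upper-case strings over the IUPAC alphabet (gaps ``-``
    or ``?`` allowed).  ``species`` carries one label per sequence; barcode
    summaries that contrast intra- vs inter-specific distances require it.
    """

    ids: list[str]
    sequences: list[str]
    species: list[str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            offenders = [
                i for i, s in zip(self.ids, self.sequences)
                if len(s) != len(self.sequences[0])
            ]
            raise ValueError(f"ragged alignment; offending ids: {offenders}")
        for i, s in zip(self.ids, self.sequences):
            bad = set(s) - IUPAC_CODES
            if bad:
                raise ValueError(f"illegal characters {sorted(bad)} in sequence {i!r}")
        if self.species is not None and len(self.species) != len(self.ids):
            raise ValueError("species labels length mismatch")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def to_array(self) -> np.ndarray:
        """Alignment as a (n, L) array of single characters."""
        return np.array([list(s) for s in self.sequences], dtype="U1")

    def species_of(self, idx: int) -> str:
        if self.species is None:
            raise ValueError("no species labels attached")
        return self.species[idx]
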