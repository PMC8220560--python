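"""HLA allele names, aligned β-chain residue vectors, and amino-acid motifs.

HLA class II alleles are named ``GENE*FF:FF(:FF)`` (e.g. ``DRB1*04:01``).
Protein-level analyses key on the first two fields, which determine the
mature-chain amino-acid sequence; three-field names are collapsed by
truncation.  Residues are indexed on the DRB1 β-chain numbering: the mature
chain runs β1..β237 and the signal peptide occupies −29..−1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "MISSING",
    "AlleleName",
    "ResiduePosition",
    "Motif",
    "AlleleCatalog",
    "parse_allele_name",
    "load_alignment",
    "motif_of",
]

#: marker for an unknown / uncovered residue
MISSING = "."

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

_NAME_RE = re.compile(r"^\s*([A-Z][A-Z0-9]*)\*(\d+(?::\d+)*)\s*$")

SIGNAL_MIN, MATURE_MAX = -29, 237


class AlleleParseError(ValueError):
    """Raised when an allele name does not follow GENE*FF:FF(:FF) syntax."""


@dataclass(frozen=True, order=True)
class AlleleName:
    """A parsed HLA allele name (gene plus 1–3 numeric fields)."""

    gene: str
    fields: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.fields:
            raise AlleleParseError("allele name needs at least one field")

    @property
    def canonical(self) -> str:
        return f"{self.gene}*{':'.join(self.fields)}"

    def truncate(self, n_fields: int = 2) -> "AlleleName":
        """Collapse to the leading ``n_fields`` fields (protein resolution)."""
        return AlleleName(self.gene, self.fields[:n_fields])

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical


def parse_allele_name(text: str) -> AlleleName:
    """Parse ``"DRB1*04:01"``-style text into an :class:`AlleleName`.

    Raises
    ------
    AlleleParseError
        If the separator ``*`` is absent or a field is non-numeric; the
        message names the offending token.
    """
    m = _NAME_RE.match(text)
    if m is None:
        raise AlleleParseError(f"malformed allele name: {text!r}")
    gene, rest = m.group(1), m.group(2)
    return AlleleName(gene, tuple(rest.split(":")))


@dataclass(frozen=True, order=True)
class ResiduePosition:
    """β-chain residue index; negative indices address the signal peptide."""

    index: int

    def __post_init__(self) -> None:
        if not (SIGNAL_MIN <= self.index <= MATURE_MAX) or self.index == 0:
            raise ValueError(
                f"β-position {self.index} outside {SIGNAL_MIN}..{MATURE_MAX} (no 0)"
            )

    @property
    def label(self) -> str:
        return f"β{self.index}"

    @property
    def is_signal_peptide(self) -> bool:
        return self.index < 0

    def __str__(self) -> str:  # pragma: no cover
        return self.label


@dataclass(frozen=True)
class Motif:
    """Ordered residues an allele carries at a chosen set of β-positions."""

    positions: tuple[ResiduePosition, ...]
    residues: str

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.residues):
            raise ValueError("motif positions and residues differ in length")
        if MISSING in self.residues:
            raise ValueError("motif may not contain missing residues")

    def __str__(self) -> str:  # pragma: no cover
        return self.residues


@dataclass
class AlleleCatalog:
    """Aligned per-allele residue vectors on a shared β-position axis."""

    positions: tuple[ResiduePosition, ...]
    alleles: dict[AlleleName, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.positions)
        for name, vec in self.alleles.items():
            if len(vec) != n:
                raise ValueError(
                    f"{name.canonical}: vector length {len(vec)} != {n} positions"
                )

    def __contains__(self, allele: AlleleName) -> bool:
        return allele in self.alleles

    def __len__(self) -> int:
        return len(self.alleles)

    @property
    def names(self) -> list[AlleleName]:
        return list(self.alleles)

    def position_index(self, pos: ResiduePosition) -> int:
        try:
            return self.positions.index(pos)
        except ValueError:
            raise KeyError(f"position {pos.label} not in catalog") from None

    def residue(self, allele: AlleleName, pos: ResiduePosition) -> str:
        return self.alleles[allele][self.position_index(pos)]

    def mature_positions(self) -> tuple[ResiduePosition, ...]:
        return tuple(p for p in self.positions if not p.is_signal_peptide)

    def to_frame(self) -> pd.DataFrame:
        """Allele × position residue grid."""
        return pd.DataFrame(
            {p.label: [self.alleles[a][i] for a in self.alleles]
             for i, p in enumerate(self.positions)},
            index=[a.canonical for a in self.alleles],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="allele")

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, vec in self.alleles.items():
                fh.write(f">{name.canonical}\n{vec}\n")


def load_alignment(fasta_path: str | Path, posmap_path: str | Path) -> AlleleCatalog:
    """Load an aligned protein FASTA plus its β-position map sidecar.

    The sidecar is a single-column TSV (header ``beta_position``) giving the
    β-chain index of every alignment column.  Record ids are allele names;
    any character outside the 20-letter amino-acid code becomes the missing
    marker.

    Raises
    ------
    ValueError
        On a record/position-map length mismatch or a duplicate allele name.
    """
    posmap = pd.read_csv(posmap_path, sep="\t")
    if "beta_position" not in posmap.columns:
        raise ValueError("position map must have a 'beta_position' column")
    positions = tuple(ResiduePosition(int(i)) for i in posmap["beta_position"])

    alleles: dict[AlleleName, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        name = parse_allele_name(rec.id)
        seq = str(rec.seq).upper()
        if len(seq) != len(positions):
            raise ValueError(
                f"{name.canonical}: sequence length {len(seq)} != "
                f"position map length {len(positions)}"
            )
        if name in alleles:
            raise ValueError(f"duplicate allele name {name.canonical}")
        alleles[name] = "".join(c if c in AMINO_ACIDS else MISSING for c in seq)
    return AlleleCatalog(positions=positions, alleles=alleles)


def motif_of(
    catalog: AlleleCatalog,
    allele: AlleleName,
    positions: Sequence[ResiduePosition],
) -> Motif:
    """Read the allele's residues at ``positions``, in the given order.

    Raises
    ------
    ValueError
        If the allele has a missing residue at a requested position; the
        message flags the position.
    """
    if allele not in catalog:
        raise KeyError(f"{allele.canonical} not in catalog")
    residues = []
    for pos in positions:
        aa = catalog.residue(allele, pos)
        if aa == MISSING:
            raise ValueError(
                f"{allele.canonical} has no residue at {pos.label}"
            )
        residues.append(aa)
    return Motif(tuple(positions), "".join(residues))


def positions_from_indices(indices: Iterable[int]) -> tuple[ResiduePosition, ...]:
    """Convenience: build a position tuple from raw β indices."""
    return tuple(ResiduePosition(int(i)) for i in indices)
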