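"""Individual-strand base composition of assembled sequences.

Chargaff's second parity rule (PR2) states that within a *single* strand of
double-stranded DNA, [A] ~ [T] and [G] ~ [C] for sufficiently long sequences.
This module counts bases on the strand as given, aggregates counts across
sequences (chromosome -> genome), and computes skew / parity-deviation
metrics used to assess PR2.

Conventions
-----------
* Soft-masked (lowercase) bases count as their uppercase base: masking is
  annotation, not composition.
* ``N`` and every other non-ACGT IUPAC symbol are excluded from the
  denominator; composition fractions are over counted A/C/G/T only.
* Composition is always reported on the strand as given in the input; no
  strand normalization is attempted.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SequenceComposition",
    "ParityMetrics",
    "count_bases",
    "aggregate_composition",
    "parity_metrics",
    "read_fasta_composition",
    "composition_table",
    "reverse_complement",
]


@dataclass(frozen=True)
class SequenceComposition:
    """Base counts for one sequence (or an aggregate of sequences)."""

    seq_id: str
    n_a: int
    n_c: int
    n_g: int
    n_t: int
    n_excluded: int
    length: int

    def __post_init__(self) -> None:
        counts = (self.n_a, self.n_c, self.n_g, self.n_t, self.n_excluded)
        if any(c < 0 for c in counts) or self.length < 0:
            raise ValueError("negative base count")
        if sum(counts) != self.length:
            raise ValueError(
                f"{self.seq_id!r}: counts sum to {sum(counts)} but length is {self.length}"
            )

    @property
    def n_counted(self) -> int:
        """Number of unambiguous A/C/G/T bases (the fraction denominator)."""
        return self.length - self.n_excluded

    @property
    def has_fractions(self) -> bool:
        return self.n_counted > 0

    def fraction(self, base: str) -> float:
        """Fraction of counted bases equal to ``base`` (one of A/C/G/T)."""
        if not self.has_fractions:
            raise ValueError(f"{self.seq_id!r}: no counted bases, fractions undefined")
        n = {"A": self.n_a, "C": self.n_c, "G": self.n_g, "T": self.n_t}[base.upper()]
        return n / self.n_counted

    @property
    def fractions(self) -> dict[str, float]:
        return {b: self.fraction(b) for b in "ACGT"}


@dataclass(frozen=True)
class ParityMetrics:
    """Strand-skew and PR2-deviation summaries of one composition.

    ``pr2_deviation = |[A]-[T]| + |[G]-[C]|`` is an implementation choice of
    a scalar PR2 statistic (PR2 itself is a qualitative rule); it is 0 iff
    the strand satisfies PR2 exactly.
    """

    at_skew: float
    gc_skew: float
    pr2_deviation: float


def count_bases(sequence: str, seq_id: str = "") -> SequenceComposition:
    """Tally A/C/G/T on the given strand of ``sequence`` (case-insensitive).

    Ambiguity codes (including N) go to ``n_excluded``. An empty sequence
    yields all-zero counts with undefined fractions.
    """
    s = sequence.upper()
    n_a = s.count("A")
    n_c = s.count("C")
    n_g = s.count("G")
    n_t = s.count("T")
    length = len(s)
    return SequenceComposition(
        seq_id=seq_id,
        n_a=n_a,
        n_c=n_c,
        n_g=n_g,
        n_t=n_t,
        n_excluded=length - (n_a + n_c + n_g + n_t),
        length=length,
    )


def aggregate_composition(
    parts: Iterable[SequenceComposition], seq_id: str = "aggregate"
) -> SequenceComposition:
    """Field-wise sum of compositions, e.g. chromosomes -> genome.

    Raises on an empty list and on duplicate ``seq_id`` (double counting).
    """
    parts = list(parts)
    if not parts:
        raise ValueError("cannot aggregate an empty list of compositions")
    ids = [p.seq_id for p in parts]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate seq_id(s) in aggregate: {dupes}")
    return SequenceComposition(
        seq_id=seq_id,
        n_a=sum(p.n_a for p in parts),
        n_c=sum(p.n_c for p in parts),
        n_g=sum(p.n_g for p in parts),
        n_t=sum(p.n_t for p in parts),
        n_excluded=sum(p.n_excluded for p in parts),
        length=sum(p.length for p in parts),
    )


def parity_metrics(comp: SequenceComposition) -> ParityMetrics:
    """AT skew, GC skew and PR2 deviation of one composition.

    ``at_skew = (nA - nT)/(nA + nT)`` (0 when nA + nT == 0), analogously for
    GC. Raises if the composition has no counted bases.
    """
    if not comp.has_fractions:
        raise ValueError(f"{comp.seq_id!r}: all bases excluded, parity undefined")
    at = comp.n_a + comp.n_t
    gc = comp.n_g + comp.n_c
    at_skew = (comp.n_a - comp.n_t) / at if at else 0.0
    gc_skew = (comp.n_g - comp.n_c) / gc if gc else 0.0
    f = comp.fractions
    pr2 = abs(f["A"] - f["T"]) + abs(f["G"] - f["C"])
    return ParityMetrics(at_skew=at_skew, gc_skew=gc_skew, pr2_deviation=pr2)


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta_composition(path: str | Path) -> list[SequenceComposition]:
    """Per-record base composition of a (possibly gzipped) multi-FASTA file."""

    def _iter() -> Iterator[SequenceComposition]:
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                yield count_bases(str(rec.seq), seq_id=rec.id)

    comps = list(_iter())
    if not comps:
        raise ValueError(f"no FASTA records in {path}")
    return comps


def composition_table(comps: Iterable[SequenceComposition]) -> pd.DataFrame:
    """Tabulate compositions with fractions and parity metrics (TSV-ready)."""
    rows = []
    for c in comps:
        row: dict[str, object] = {
            "seq_id": c.seq_id,
            "length": c.length,
            "n_a": c.n_a,
            "n_c": c.n_c,
            "n_g": c.n_g,
            "n_t": c.n_t,
            "n_excluded": c.n_excluded,
        }
        if c.has_fractions:
            f = c.fractions
            m = parity_metrics(c)
            row.update(
                frac_a=f["A"], frac_c=f["C"], frac_g=f["G"], frac_t=f["T"],
                at_skew=m.at_skew, gc_skew=m.gc_skew, pr2_deviation=m.pr2_deviation,
            )
        else:
            row.update(
                frac_a=float("nan"), frac_c=float("nan"), frac_g=float("nan"),
                frac_t=float("nan"), at_skew=float("nan"), gc_skew=float("nan"),
                pr2_deviation=float("nan"),
            )
        rows.append(row)
    return pd.DataFrame(rows)
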