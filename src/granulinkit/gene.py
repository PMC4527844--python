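"""Gene models: coding DNA with ordered exon spans.

Internally every coordinate is 0-based half-open on the spliced coding
sequence (CDS).  Conversion to the 1-based inclusive convention of GFF3/TSV
exon tables happens only at the format boundary (:func:`read_exon_tsv`,
:func:`write_exon_tsv`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .errors import CoordinateError, SequenceParseError

DNA_ALPHABET = set("ACGT")


@dataclass
class GeneModel:
    """A coding sequence partitioned into ordered exon spans.

    Parameters
    ----------
    gene_id:
        Identifier carried through to all outputs.
    cds:
        Spliced coding DNA (no introns), uppercase ``ACGT``.
    exons:
        Ordered, contiguous, non-overlapping ``(start, end)`` spans that
        partition ``[0, len(cds))``; 0-based half-open CDS coordinates.
    """

    gene_id: str
    cds: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        bad = set(self.cds) - DNA_ALPHABET
        if bad:
            raise SequenceParseError(
                f"{self.gene_id}: non-ACGT characters in CDS: {sorted(bad)}"
            )
        if len(self.cds) % 3 != 0:
            raise CoordinateError(
                f"{self.gene_id}: CDS length {len(self.cds)} is not a multiple of 3"
            )
        if not self.exons:
            self.exons = [(0, len(self.cds))]
        pos = 0
        for i, (s, e) in enumerate(self.exons):
            if s != pos or e <= s:
                raise CoordinateError(
                    f"{self.gene_id}: exon {i} span ({s}, {e}) does not tile the CDS"
                )
            pos = e
        if pos != len(self.cds):
            raise CoordinateError(
                f"{self.gene_id}: exons end at {pos}, CDS length {len(self.cds)}"
            )

    @property
    def protein(self) -> str:
        """Conceptual translation of the CDS (no trailing stop expected)."""
        aa = str(Seq(self.cds).translate())
        if aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa:
            raise SequenceParseError(f"{self.gene_id}: internal stop codon in CDS")
        return aa

    def exon_of_codon(self, residue: int) -> int:
        """Index of the exon containing the first base of codon ``residue``."""
        base = 3 * residue
        if not 0 <= base < len(self.cds):
            raise CoordinateError(
                f"{self.gene_id}: residue {residue} outside the CDS"
            )
        for i, (s, e) in enumerate(self.exons):
            if s <= base < e:
                return i
        raise CoordinateError(f"{self.gene_id}: no exon covers base {base}")

    def exon_protein_span(self, exon_index: int) -> tuple[int, int]:
        """Half-open residue interval whose codons the exon touches."""
        s, e = self.exons[exon_index]
        return s // 3, (e + 2) // 3

    def exon_boundaries_protein(self) -> list[int]:
        """Internal exon boundaries expressed as residue indices.

        Only codon-aligned boundaries map exactly; a boundary inside a codon
        is attributed to the codon it interrupts.
        """
        return [e // 3 if e % 3 == 0 else e // 3 for _, e in self.exons[:-1]]


def read_exon_tsv(path) -> dict[str, list[tuple[int, int]]]:
    """Read a 5-column exon table (seq_id, exon_index, start, end, phase).

    Coordinates are 1-based inclusive on the CDS, as in GFF3.  Returns
    0-based half-open spans keyed by sequence id.
    """
    out: dict[str, list[tuple[int, tuple[int, int]]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise CoordinateError(f"malformed exon row: {line!r}")
            seq_id, idx, start, end = parts[0], int(parts[1]), int(parts[2]), int(parts[3])
            out.setdefault(seq_id, []).append((idx, (start - 1, end)))
    return {
        k: [span for _, span in sorted(v)] for k, v in out.items()
    }


def write_exon_tsv(genes: list[GeneModel], path) -> None:
    """Write exon spans as a 5-column TSV (1-based inclusive, phase 0-2)."""
    with open(path, "w") as fh:
        fh.write("# seq_id\texon_index\tstart\tend\tphase (1-based inclusive CDS coordinates)\n")
        for g in genes:
            for i, (s, e) in enumerate(g.exons):
                fh.write(f"{g.gene_id}\t{i}\t{s + 1}\t{e}\t{s % 3}\n")
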