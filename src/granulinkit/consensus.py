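"""Multi-threshold consensus sequences with residue-class fallback.

For each alignment column and identity threshold the consensus symbol is,
in order of preference: the single residue reaching the threshold
(uppercase), the most specific physico-chemical class whose members jointly
reach it (lowercase symbol), or a dot.  Frequencies are computed over the
non-gap entries of the column; a column that is at least half gaps renders
a dot regardless.  Ties between equally frequent residues break
alphabetically.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from importlib import resources

from .align import GAP, AnchoredAlignment
from .errors import ConfigError

DEFAULT_THRESHOLDS = (50, 60, 70, 80, 90, 100)


@dataclass(frozen=True)
class ResidueClass:
    symbol: str
    name: str
    members: frozenset[str]


class ResidueClassHierarchy:
    """Ordered residue classes; evaluation order is fixed and documented
    in the packaged asset (most specific first)."""

    def __init__(self, classes: list[ResidueClass]):
        if not classes or any(not c.members for c in classes):
            raise ConfigError("every residue class must be non-empty")
        self.classes = classes

    @classmethod
    def default(cls) -> "ResidueClassHierarchy":
        with resources.files("granulinkit.data").joinpath(
                "residue_classes.json").open() as fh:
            data = json.load(fh)
        return cls([ResidueClass(c["symbol"], c["name"], frozenset(c["members"]))
                    for c in data["classes"]])


@dataclass
class ConsensusRow:
    threshold_pct: int
    symbols: str


def column_consensus(column: str, threshold_pct: int,
                     hierarchy: ResidueClassHierarchy | None = None) -> str:
    """Consensus symbol for one alignment column at one identity threshold."""
    if not 0 < threshold_pct <= 100:
        raise ConfigError(f"threshold {threshold_pct} outside (0, 100]")
    if not column:
        raise ConfigError("empty column")
    if hierarchy is None:
        hierarchy = ResidueClassHierarchy.default()
    entries = list(column.upper())
    non_gap = [ch for ch in entries if ch not in (GAP, ".")]
    if 2 * len(non_gap) <= len(entries):
        return "."
    counts = Counter(non_gap)
    total = len(non_gap)
    thr = threshold_pct / 100.0
    best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if best[1] / total >= thr:
        return best[0].upper()
    for klass in hierarchy.classes:
        agg = sum(c for ch, c in counts.items() if ch in klass.members)
        if agg / total >= thr:
            return klass.symbol
    return "."


def multi_threshold_consensus(
    aln: AnchoredAlignment,
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS,
    hierarchy: ResidueClassHierarchy | None = None,
) -> list[ConsensusRow]:
    """One consensus row per threshold, in the given order (default 50..100
    by 10, i.e. six rows)."""
    if hierarchy is None:
        hierarchy = ResidueClassHierarchy.default()
    cols = [aln.column(i) for i in range(aln.width)]
    return [
        ConsensusRow(t, "".join(column_consensus(c, t, hierarchy) for c in cols))
        for t in thresholds
    ]


def plurality_consensus(aln: AnchoredAlignment) -> str:
    """The most frequent residue per column (ties alphabetical, gaps
    ignored; all-gap columns render a gap).  This is the concrete-residue
    consensus used when a downstream stage needs an actual sequence, e.g.
    distance trees between module consensus sequences."""
    out = []
    for i in range(aln.width):
        counts = Counter(ch for ch in aln.column(i).upper()
                         if ch not in (GAP, "."))
        if not counts:
            out.append(GAP)
        else:
            out.append(min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0])
    return "".join(out)


def render_text(rows: list[ConsensusRow], aln: AnchoredAlignment | None = None) -> str:
    """Plain-text block of aligned consensus rows (highest threshold last)."""
    out = []
    if aln is not None:
        for lab, row in aln.rows:
            out.append(f"{lab:<12} {row}")
        out.append("")
    for r in rows:
        out.append(f"{r.threshold_pct:>3}% {r.symbols}")
    return "\n".join(out) + "\n"


_DEFAULT_COLORS = {
    "C": "#f2d12b", "-": "#d04040", "+": "#4060d0", "c": "#a060c0",
    "p": "#40a0a0", "h": "#808040", "s": "#90b090", "u": "#b0d0b0",
    "o": "#70b0d0", "l": "#a0a060", "a": "#c08040", "t": "#b0b0b0",
}


def render_html(rows: list[ConsensusRow], colors: dict[str, str] | None = None) -> str:
    """Minimal HTML rendering with per-category colours (cosmetic only)."""
    colors = {**_DEFAULT_COLORS, **(colors or {})}
    body = []
    for r in rows:
        cells = "".join(
            f'<span style="background:{colors[ch]}">{ch}</span>'
            if ch in colors else ch
            for ch in r.symbols
        )
        body.append(f"<div><b>{r.threshold_pct}%</b> <code>{cells}</code></div>")
    return ("<html><body style='font-family:monospace'>"
            + "\n".join(body) + "</body></html>\n")
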