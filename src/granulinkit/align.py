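"""Motif-anchored alignment of granulin modules and half-modules.

The conserved cysteines are pinned to fixed alignment columns; gaps are
confined to the variable inter-cysteine regions.  Within each region the
width is the maximum observed length and shorter sequences receive one
contiguous gap block.  The gap column is chosen against a per-region
position-frequency profile built from the sequences that fill the region
exactly (the majority rule of a compact, minimum-gap alignment); ties break
toward the leftmost column.  Sequences of a variant form lacking a cysteine
of the canonical pattern carry the ``-`` placeholder at that anchor column.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import AlignmentError
from .motif import C_SLOTS, N_SLOTS, SLOT_ORDER, ModuleHit, MotifSpec, scan_protein

GAP = "-"


@dataclass
class AnchorUnit:
    """One motif-bearing sequence prepared for anchored alignment."""

    label: str
    seq: str
    cys: list[int]        # positions of present anchors, relative to seq
    slots: list[str]      # canonical slot name per anchor, same order

    def __post_init__(self) -> None:
        if not self.cys:
            raise AlignmentError(f"sequence {self.label!r} carries no motif")
        for pos, slot in zip(self.cys, self.slots):
            if not (0 <= pos < len(self.seq)) or self.seq[pos] != "C":
                raise AlignmentError(
                    f"{self.label}: anchor {slot} at {pos} is not a cysteine"
                )

    @property
    def side(self) -> str:
        in_n = any(s in N_SLOTS for s in self.slots)
        in_c = any(s in C_SLOTS for s in self.slots)
        return "full" if (in_n and in_c) else ("N" if in_n else "C")


def unit_from_hit(label: str, protein: str, hit: ModuleHit,
                  side: str = "full") -> AnchorUnit:
    """Build an alignment unit from a scanned hit (full module or one half)."""
    if side == "full":
        span = hit.span
        keep = N_SLOTS | C_SLOTS
    elif side == "N":
        if hit.n_half_span is None:
            raise AlignmentError(f"{label}: hit has no N-half")
        span, keep = hit.n_half_span, N_SLOTS
    elif side == "C":
        if hit.c_half_span is None:
            raise AlignmentError(f"{label}: hit has no C-half")
        span, keep = hit.c_half_span, C_SLOTS
    else:
        raise AlignmentError(f"unknown side {side!r}")
    s, e = span
    cys, slots = [], []
    for pos, slot in zip(hit.cys_positions, hit.slots):
        if slot in keep and s <= pos < e:
            cys.append(pos - s)
            slots.append(slot)
    return AnchorUnit(label, protein[s:e], cys, slots)


@dataclass
class AnchoredAlignment:
    """Gapped block with pinned cysteine anchor columns."""

    rows: list[tuple[str, str]]
    anchor_columns: dict[str, int]
    region_gap_positions: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def width(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.rows]

    def ungapped(self, label: str) -> str:
        for lab, row in self.rows:
            if lab == label:
                return row.replace(GAP, "")
        raise KeyError(label)

    def column(self, i: int) -> str:
        return "".join(row[i] for _, row in self.rows)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for lab, row in self.rows:
                fh.write(f">{lab}\n{row}\n")

    def to_phylip(self, path) -> None:
        """Relaxed PHYLIP: full names, two-space separator."""
        with open(path, "w") as fh:
            fh.write(f" {len(self.rows)} {self.width}\n")
            pad = max(len(lab) for lab, _ in self.rows) + 2
            for lab, row in self.rows:
                fh.write(lab.ljust(pad) + row + "\n")


def align_anchored(units: list[AnchorUnit],
                   spec: MotifSpec | None = None) -> AnchoredAlignment:
    """Align motif-bearing sequences by pinning their cysteine anchors.

    All units must be of the same side (N, C or full) and share the first
    and last anchor slot; interior anchors may be absent in variant forms
    and are rendered as ``-`` placeholders in those rows.
    """
    if not units:
        raise AlignmentError("no sequences to align")
    sides = {u.side for u in units}
    if len(sides) > 1:
        raise AlignmentError(f"mixed sides in input: {sorted(sides)}")

    used = [s for s in SLOT_ORDER if any(s in u.slots for u in units)]
    first_slot, last_slot = used[0], used[-1]
    for u in units:
        if u.slots[0] != first_slot or u.slots[-1] != last_slot:
            raise AlignmentError(
                f"{u.label}: outermost anchors {u.slots[0]}/{u.slots[-1]} do not "
                f"match the set ({first_slot}/{last_slot})"
            )

    # -- region widths ------------------------------------------------------
    nregions = len(used) - 1
    widths = [0] * nregions

    def present_pairs(u):
        """(slot-index pairs in `used`, residue count between) for unit u."""
        idx = {s: u.cys[i] for i, s in enumerate(u.slots)}
        out = []
        order = [s for s in used if s in idx]
        for a, b in zip(order, order[1:]):
            out.append((used.index(a), used.index(b), idx[b] - idx[a] - 1))
        return out

    for u in units:
        for ia, ib, count in present_pairs(u):
            if ib == ia + 1:
                widths[ia] = max(widths[ia], count)
    # capacity fix-up for rows spanning absent interior anchors
    for u in units:
        for ia, ib, count in present_pairs(u):
            if ib > ia + 1:
                cap = sum(widths[ia:ib])
                if cap < count:
                    widths[ib - 1] += count - cap

    lead = max(u.cys[0] for u in units)
    trail = max(len(u.seq) - u.cys[-1] - 1 for u in units)

    # -- column coordinates --------------------------------------------------
    anchor_cols: dict[str, int] = {}
    col = lead
    region_start = [0] * nregions
    for i, slot in enumerate(used):
        anchor_cols[slot] = col
        col += 1
        if i < nregions:
            region_start[i] = col
            col += widths[i]
    total = col + trail

    # -- profiles from rows that fill a region exactly ----------------------
    profiles: list[list[Counter]] = [
        [Counter() for _ in range(widths[i])] for i in range(nregions)
    ]
    for u in units:
        for ia, ib, count in present_pairs(u):
            if ib == ia + 1 and count == widths[ia]:
                a_pos = u.cys[u.slots.index(used[ia])]
                for k in range(count):
                    profiles[ia][k][u.seq[a_pos + 1 + k]] += 1

    def modal(counter: Counter) -> str | None:
        if not counter:
            return None
        return min(counter.items(), key=lambda kv: (-kv[1], kv[0]))[0]

    region_modal = [[modal(c) for c in prof] for prof in profiles]

    # -- render rows ---------------------------------------------------------
    rows: list[tuple[str, str]] = []
    gap_record: dict[str, dict[str, int]] = {}
    for u in units:
        row = [GAP] * total
        idx = {s: u.cys[i] for i, s in enumerate(u.slots)}
        # leading flank, right-aligned against the first anchor
        nlead = u.cys[0]
        for k in range(nlead):
            row[lead - nlead + k] = u.seq[k]
        # trailing flank, left-aligned after the last anchor
        last_pos = u.cys[-1]
        for k, ch in enumerate(u.seq[last_pos + 1:]):
            row[anchor_cols[last_slot] + 1 + k] = ch
        # anchors
        for slot, pos in idx.items():
            row[anchor_cols[slot]] = u.seq[pos]
        # inter-anchor stretches
        for ia, ib, count in present_pairs(u):
            a_pos = idx[used[ia]]
            stretch = u.seq[a_pos + 1: a_pos + 1 + count]
            cols = []      # (global col, modal residue or None, forced_gap)
            for r in range(ia, ib):
                if r > ia:
                    cols.append((anchor_cols[used[r]], "C", True))
                for k in range(widths[r]):
                    cols.append((region_start[r] + k, region_modal[r][k], False))
            deficit = len(cols) - count
            if deficit == 0 and not any(f for _, _, f in cols):
                for (c, _, _), ch in zip(cols, stretch):
                    row[c] = ch
                continue
            if deficit < 0:
                raise AlignmentError(
                    f"{u.label}: {count} residues exceed the "
                    f"{len(cols)} columns between {used[ia]} and {used[ib]}"
                )
            forced = [j for j, (_, _, f) in enumerate(cols) if f]
            best = None
            for start in range(len(cols) - deficit + 1):
                block = range(start, start + deficit)
                if any(j not in block for j in forced):
                    continue
                score = 0
                ri = 0
                for j, (c, m, _) in enumerate(cols):
                    if j in block:
                        continue
                    if m is not None and stretch[ri] != m:
                        score += 1
                    ri += 1
                if best is None or score < best[0]:
                    best = (score, start)
            if best is None:
                raise AlignmentError(
                    f"{u.label}: no contiguous gap placement covers the absent "
                    f"anchor columns between {used[ia]} and {used[ib]}"
                )
            _, start = best
            ri = 0
            for j, (c, _, _) in enumerate(cols):
                if start <= j < start + deficit:
                    row[c] = GAP
                else:
                    row[c] = stretch[ri]
                    ri += 1
            if deficit:
                key = f"{used[ia]}..{used[ib]}"
                gap_record.setdefault(key, {})[u.label] = cols[start][0]
        rows.append((u.label, "".join(row)))

    return AnchoredAlignment(rows, anchor_cols, gap_record)


def align_sequences(labeled_seqs: list[tuple[str, str]],
                    spec: MotifSpec | None = None,
                    side: str = "full") -> AnchoredAlignment:
    """Scan each labelled sequence and anchor-align its (single) motif."""
    if spec is None:
        spec = MotifSpec.default()
    units = []
    for label, seq in labeled_seqs:
        hits = scan_protein(seq, spec, sequence_id=label)
        if not hits:
            raise AlignmentError(f"sequence {label!r} carries no motif")
        units.append(unit_from_hit(label, seq, hits[0], side=side))
    return align_anchored(units, spec)


def strip_columns(aln: AnchoredAlignment,
                  drop_anchor_cys: bool = True) -> AnchoredAlignment:
    """Remove the conserved anchor cysteine columns (identity when unset)."""
    if not drop_anchor_cys:
        return AnchoredAlignment(list(aln.rows), dict(aln.anchor_columns),
                                 dict(aln.region_gap_positions))
    drop = set(aln.anchor_columns.values())
    rows = [(lab, "".join(ch for i, ch in enumerate(row) if i not in drop))
            for lab, row in aln.rows]
    return AnchoredAlignment(rows, {}, {})
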