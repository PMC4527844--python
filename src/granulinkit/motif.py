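"""Detection of granulin cysteine motifs in protein sequences.

The granulin module is defined by a conserved pattern of 12 cysteines with
four adjacent double-Cys pairs::

    C1 .. C2 .. C3C4 .. C5C6 | C7C8 .. C9C10 .. C11 .. C12
    `------- N-half -------'   `------- C-half --------'

Detection is deterministic pattern matching over the cysteine positions of a
sequence: no profile scores, no HMMs.  Variant forms are supported as
explicit patterns:

``g``
    canonical 12-Cys module (6 + 6 per half).
``g_star``
    the 10-Cys form common in tetrapod progranulins; modelled here with the
    two variable single cysteines (C2 and C11) absent, 5 + 5 per half.
``g_dquote``
    form missing the first double Cys (C3C4); 4 + 6.
``g_breve``
    plant-type form carrying an additional double Cys in the N-half; 8 + 6.
``p`` / ``q``
    unpaired N-half (paragranulin) / unpaired C-half.

The N/C junction of a module lies ``nhalf_tail`` residues beyond the second
double Cys (C5C6); paragranulins keep one extra tail residue.  Module spans
include ``flank_n``/``flank_c`` residues around the outermost cysteines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .errors import ConfigError, CoordinateError, SequenceParseError
from .gene import GeneModel

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: canonical anchor slot order, including the plant-form extra pair Ca/Cb
SLOT_ORDER = [
    "C1", "C2", "Ca", "Cb", "C3", "C4", "C5", "C6",
    "C7", "C8", "C9", "C10", "C11", "C12",
]
N_SLOTS = {"C1", "C2", "Ca", "Cb", "C3", "C4", "C5", "C6"}
C_SLOTS = {"C7", "C8", "C9", "C10", "C11", "C12"}


def _load_default_spacing() -> dict:
    with resources.files("granulinkit.data").joinpath("motif_spacing.json").open() as fh:
        return json.load(fh)


@dataclass
class MotifSpec:
    """Spacing rules and boundary conventions for motif detection.

    ``inter_cys_spacing`` holds inclusive (min, max) residue-count ranges for
    the seven inter-cysteine regions of the canonical motif.  The defaults
    ship as a package data asset and accept every supported module form.
    """

    inter_cys_spacing: list[tuple[int, int]]
    extra_pair_spacing: list[tuple[int, int]]
    flank_n: int = 2
    flank_c: int = 2
    nhalf_tail: int = 4
    paragranulin_tail: int = 5
    lenient_x: bool = False

    def __post_init__(self) -> None:
        if len(self.inter_cys_spacing) != 7:
            raise ConfigError("inter_cys_spacing must list 7 ranges")
        for lo, hi in list(self.inter_cys_spacing) + list(self.extra_pair_spacing):
            if lo < 0 or lo > hi:
                raise ConfigError(f"empty or negative spacing range ({lo}, {hi})")
        if min(self.flank_n, self.flank_c, self.nhalf_tail, self.paragranulin_tail) < 0:
            raise ConfigError("flank and tail counts must be >= 0")

    @classmethod
    def default(cls, **overrides) -> "MotifSpec":
        data = _load_default_spacing()
        kwargs = dict(
            inter_cys_spacing=[tuple(r) for r in data["inter_cys_spacing"]],
            extra_pair_spacing=[tuple(r) for r in data["extra_pair_spacing"]],
            flank_n=data["flank_n"],
            flank_c=data["flank_c"],
            nhalf_tail=data["nhalf_tail"],
            paragranulin_tail=data["paragranulin_tail"],
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    # -- pattern construction -------------------------------------------------

    def _patterns(self) -> list[tuple[str, list[list[str]], list[tuple[int, int]]]]:
        r = self.inter_cys_spacing
        ra, rb = self.extra_pair_spacing

        def merge(a, b, absent):
            # a gap spanning `absent` missing cysteines between two regions
            return (a[0] + b[0] + absent, a[1] + b[1] + absent)

        g = (
            "g",
            [["C1"], ["C2"], ["C3", "C4"], ["C5", "C6"],
             ["C7", "C8"], ["C9", "C10"], ["C11"], ["C12"]],
            list(r),
        )
        g_star = (
            "g_star",
            [["C1"], ["C3", "C4"], ["C5", "C6"],
             ["C7", "C8"], ["C9", "C10"], ["C12"]],
            [merge(r[0], r[1], 1), r[2], r[3], r[4], merge(r[5], r[6], 1)],
        )
        g_dquote = (
            "g_dquote",
            [["C1"], ["C2"], ["C5", "C6"],
             ["C7", "C8"], ["C9", "C10"], ["C11"], ["C12"]],
            [r[0], merge(r[1], r[2], 2), r[3], r[4], r[5], r[6]],
        )
        g_breve = (
            "g_breve",
            [["C1"], ["C2"], ["Ca", "Cb"], ["C3", "C4"], ["C5", "C6"],
             ["C7", "C8"], ["C9", "C10"], ["C11"], ["C12"]],
            [r[0], ra, rb, r[2], r[3], r[4], r[5], r[6]],
        )
        p = (
            "p",
            [["C1"], ["C2"], ["C3", "C4"], ["C5", "C6"]],
            [r[0], r[1], r[2]],
        )
        q = (
            "q",
            [["C7", "C8"], ["C9", "C10"], ["C11"], ["C12"]],
            [r[4], r[5], r[6]],
        )
        return [g, g_star, g_dquote, g_breve, p, q]


@dataclass
class ModuleHit:
    """One detected granulin motif (full module or unpaired half)."""

    sequence_id: str
    cys_positions: list[int]
    variant: str
    span: tuple[int, int]
    n_half_span: tuple[int, int] | None
    c_half_span: tuple[int, int] | None
    slots: list[str] = field(default_factory=list)

    @property
    def n_cys_count(self) -> int:
        return sum(1 for s in self.slots if s in N_SLOTS)

    @property
    def c_cys_count(self) -> int:
        return sum(1 for s in self.slots if s in C_SLOTS)

    def slot_position(self, slot: str) -> int | None:
        try:
            return self.cys_positions[self.slots.index(slot)]
        except ValueError:
            return None


@dataclass
class HalfModule:
    """One N- or C-half of a detected module, with optional coding DNA."""

    parent: ModuleHit
    side: str  # "N" or "C"
    span: tuple[int, int]
    protein_seq: str
    coding_seq: str | None = None
    label: str | None = None

    @property
    def cys_relative(self) -> list[int]:
        s = self.span[0]
        keep = N_SLOTS if self.side == "N" else C_SLOTS
        return [p - s for p, sl in zip(self.parent.cys_positions, self.parent.slots)
                if sl in keep]

    @property
    def slots(self) -> list[str]:
        keep = N_SLOTS if self.side == "N" else C_SLOTS
        return [sl for sl in self.parent.slots if sl in keep]


def classify_variant(n_cys: int, c_cys: int) -> str:
    """Variant tag from per-half cysteine counts.

    Classification never uses the positional identity of a missing cysteine,
    only counts: 6+6 -> g, 5+5 -> g_star, 4+6 -> g_dquote, 8+6 -> g_breve,
    an unpaired N-half -> p, an unpaired C-half -> q.  Any other combination
    is reported as ``nonconforming`` (never silently dropped).
    """
    if n_cys == 6 and c_cys == 6:
        return "g"
    if n_cys == 5 and c_cys == 5:
        return "g_star"
    if n_cys == 4 and c_cys == 6:
        return "g_dquote"
    if n_cys == 8 and c_cys == 6:
        return "g_breve"
    if n_cys > 0 and c_cys == 0:
        return "p"
    if n_cys == 0 and c_cys > 0:
        return "q"
    return f"nonconforming(n={n_cys},c={c_cys})"


def _match_at(seq, cand, start_idx, groups, gaps, lenient_budget):
    """Try to bind ``groups`` to candidate positions starting at ``start_idx``.

    Candidates are positions of C (and, in lenient mode, X).  Cysteines must
    be consumed in order; an X candidate may either serve as a cysteine
    (budget permitting) or be skipped.  Returns the list of bound positions
    or None.
    """

    def rec(idx, gi, mi, prev, budget, bound):
        if gi == len(groups):
            return bound
        if idx >= len(cand):
            return None
        pos = cand[idx]
        is_x = seq[pos] == "X"
        # option 1: bind this candidate to the current slot
        ok = True
        if mi == 0 and gi > 0:
            lo, hi = gaps[gi - 1]
            ok = lo <= pos - prev - 1 <= hi
        elif mi > 0:
            ok = pos == prev + 1
        if ok and (not is_x or budget > 0):
            nb = budget - 1 if is_x else budget
            nmi, ngi = (0, gi + 1) if mi + 1 == len(groups[gi]) else (mi + 1, gi)
            res = rec(idx + 1, ngi, nmi, pos, nb, bound + [pos])
            if res is not None:
                return res
        # option 2: an X that is not part of the motif may be skipped
        if is_x:
            return rec(idx + 1, gi, mi, prev, budget, bound)
        return None

    return rec(start_idx, 0, 0, -10**9, lenient_budget, [])


def scan_protein(seq: str, spec: MotifSpec | None = None,
                 sequence_id: str = "seq") -> list[ModuleHit]:
    """Detect granulin motifs in ``seq``, left to right, non-overlapping.

    Full-module patterns are tried first (g, g_star, g_dquote, g_breve); a
    six-cysteine N-half with valid spacing but no completing C-half is
    reported as variant ``p``, an orphan C-half as ``q``.
    """
    if spec is None:
        spec = MotifSpec.default()
    seq = seq.upper()
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise SequenceParseError(f"{sequence_id}: invalid residues {sorted(bad)}")
    if not seq:
        return []

    budget = 1 if spec.lenient_x else 0
    allowed = "CX" if spec.lenient_x else "C"
    cand = [i for i, ch in enumerate(seq) if ch in allowed]
    patterns = spec._patterns()

    hits: list[ModuleHit] = []
    i = 0
    while i < len(cand):
        matched = None
        for variant, groups, gaps in patterns:
            bound = _match_at(seq, cand, i, groups, gaps, budget)
            if bound is not None:
                slots = [s for grp in groups for s in grp]
                matched = (variant, slots, bound)
                break
        if matched is None:
            i += 1
            continue
        variant, slots, bound = matched
        hit = _build_hit(sequence_id, seq, variant, slots, bound, spec)
        hits.append(hit)
        # advance past every candidate consumed by (or skipped inside) the hit
        last = bound[-1]
        while i < len(cand) and cand[i] <= last:
            i += 1
    return hits


def _build_hit(sequence_id, seq, variant, slots, bound, spec) -> ModuleHit:
    first, last = bound[0], bound[-1]
    start = max(0, first - spec.flank_n)
    if variant == "p":
        end = min(len(seq), last + spec.paragranulin_tail + 1)
    else:
        end = min(len(seq), last + spec.flank_c + 1)
    n_span = c_span = None
    if variant not in ("p", "q"):
        junction = _default_junction(slots, bound, spec)
        n_span = (start, junction)
        c_span = (junction, end)
    elif variant == "p":
        n_span = (start, end)
    else:
        c_span = (start, end)
    n_cys = sum(1 for s in slots if s in N_SLOTS)
    c_cys = sum(1 for s in slots if s in C_SLOTS)
    tag = classify_variant(n_cys, c_cys)
    return ModuleHit(
        sequence_id=sequence_id,
        cys_positions=list(bound),
        variant=tag if variant not in ("p", "q") else variant,
        span=(start, end),
        n_half_span=n_span,
        c_half_span=c_span,
        slots=list(slots),
    )


def _default_junction(slots, bound, spec) -> int:
    # the junction lies nhalf_tail residues beyond the second double Cys (C5C6)
    c6 = bound[slots.index("C6")]
    return c6 + spec.nhalf_tail + 1


def extract_half_modules(
    hit: ModuleHit,
    seq: str,
    gene: GeneModel | None = None,
    spec: MotifSpec | None = None,
) -> tuple[HalfModule | None, HalfModule | None]:
    """Split a hit into its N- and C-half modules.

    Without a gene model the junction falls ``nhalf_tail`` residues beyond
    the second double Cys (one more for paragranulins).  When a gene model is
    supplied and an exon boundary falls between C6 and C7, that boundary is
    the junction (the closest one to the default, if several).
    """
    if spec is None:
        spec = MotifSpec.default()
    if gene is not None:
        prot = gene.protein
        if len(prot) != len(seq):
            raise CoordinateError(
                f"{hit.sequence_id}: gene model translates to {len(prot)} residues, "
                f"protein has {len(seq)}"
            )

    start, end = hit.span
    if hit.variant == "p" or (hit.n_cys_count and not hit.c_cys_count):
        c6 = hit.slot_position("C6") or hit.cys_positions[-1]
        n_end = min(len(seq), c6 + spec.paragranulin_tail + 1)
        n = _make_half(hit, "N", (start, n_end), seq, gene)
        return n, None
    if hit.variant == "q" or (hit.c_cys_count and not hit.n_cys_count):
        return None, _make_half(hit, "C", (start, end), seq, gene)

    junction = _default_junction(hit.slots, hit.cys_positions, spec)
    if gene is not None:
        c6 = hit.slot_position("C6")
        c7 = hit.slot_position("C7")
        inside = [b for b in gene.exon_boundaries_protein() if c6 < b <= c7]
        if inside:
            junction = min(inside, key=lambda b: (abs(b - junction), b))
    n = _make_half(hit, "N", (start, junction), seq, gene)
    c = _make_half(hit, "C", (junction, end), seq, gene)
    return n, c


def _make_half(hit, side, span, seq, gene) -> HalfModule:
    s, e = span
    coding = gene.cds[3 * s: 3 * e] if gene is not None else None
    return HalfModule(parent=hit, side=side, span=span,
                      protein_seq=seq[s:e], coding_seq=coding)


def write_hits_tsv(hits: list[ModuleHit], path) -> None:
    """Write a hit table (0-based half-open spans, documented in the header)."""
    with open(path, "w") as fh:
        fh.write("# seq_id\tmodule_index\tvariant\tspan_start\tspan_end\t"
                 "cys_positions (0-based half-open spans)\n")
        counters: dict[str, int] = {}
        for h in hits:
            k = counters.get(h.sequence_id, 0)
            counters[h.sequence_id] = k + 1
            fh.write(
                f"{h.sequence_id}\t{k}\t{h.variant}\t{h.span[0]}\t{h.span[1]}\t"
                + ",".join(map(str, h.cys_positions)) + "\n"
            )
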