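"""Exon-structure token strings and the splicing grammar for module architecture.

Gene exon structure is written as hyphen-separated tokens over half-module
symbols: ``s`` signal, ``n``/``c`` N- and C-half modules (with modifiers
``*`` for the 5-Cys form, ``"`` for the 4-Cys N-half and ``ň`` for the
plant-type N-half), ``x`` non-granulin segments, ``y`` short exons and ``t``
a short terminal coding sequence.  Hyphens mark introns; parentheses mark
fragments of one half split across exons.

The splicing grammar turns the flattened half-symbol stream into a protein
module architecture: an n-type symbol immediately followed by a c-type
symbol yields one full module, a dangling n-type symbol a paragranulin
``p``, an unpaired c-type symbol a ``q`` half-module.  Complete modules can
therefore be built as N/C, N/CN, CN/CN or CN/C exon combinations, so the
derived architecture is invariant to where the introns fall.
"""

from __future__ import annotations

import unicodedata
import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .errors import ArchitectureParseError, UnsupportedStructureError
from .gene import GeneModel
from .motif import ModuleHit

KINDS = set("sncxyt")
MODIFIERS = {"*", '"', "ň"}
#: full-module symbols of the protein architecture notation
FULL_MODULE_SYMBOLS = ("g", "g*", 'g"', "ğ")

_QUOTE_MAP = {"“": '"', "”": '"', "‘": '"', "’": '"',
              "ʼ": '"', "`": '"', "´": '"'}


@dataclass(frozen=True)
class ExonSymbol:
    kind: str
    modifier: str = ""
    fragment: bool = False

    def render(self) -> str:
        if self.kind == "n" and self.modifier == "ň":
            return "ň"
        return self.kind + self.modifier


@dataclass
class ExonTokenString:
    """Tokenized exon structure; one token per exon, hyphens are introns."""

    tokens: list[list[ExonSymbol]]

    def serialize(self) -> str:
        out = []
        for tok in self.tokens:
            text = ""
            for sym in tok:
                r = sym.render()
                text += f"({r})" if sym.fragment else r
            out.append(text)
        return "-".join(out)

    def half_symbol_stream(self) -> list[tuple[str, str]]:
        """Flatten tokens, merging split (parenthesized) fragments."""
        flat = [s for tok in self.tokens for s in tok]
        stream: list[tuple[str, str, bool]] = []
        for sym in flat:
            if stream and stream[-1][0] == sym.kind and (stream[-1][2] or sym.fragment):
                kind, mod, _ = stream[-1]
                stream[-1] = (kind, mod or sym.modifier, sym.fragment)
            else:
                stream.append((sym.kind, sym.modifier, sym.fragment))
        return [(k, m) for k, m, _ in stream]


def tokenize(serialized: str) -> ExonTokenString:
    """Parse a serialized exon-structure string (case-insensitive).

    Unknown symbols raise :class:`ArchitectureParseError` naming the
    character and its offset.
    """
    if not serialized or not serialized.strip():
        raise ArchitectureParseError("empty exon-structure string")
    text = unicodedata.normalize("NFC", serialized.strip().lower())
    text = "".join(_QUOTE_MAP.get(ch, ch) for ch in text)
    tokens: list[list[ExonSymbol]] = []
    offset = -1
    for raw_tok in text.split("-"):
        symbols: list[ExonSymbol] = []
        in_frag = False
        for ch in raw_tok:
            offset += 1
            if ch == "(":
                in_frag = True
            elif ch == ")":
                in_frag = False
            elif ch == "ň":
                symbols.append(ExonSymbol("n", "ň", in_frag))
            elif ch in KINDS:
                symbols.append(ExonSymbol(ch, "", in_frag))
            elif ch in MODIFIERS:
                if not symbols or symbols[-1].kind not in "nc":
                    raise ArchitectureParseError(
                        f"modifier {ch!r} at offset {offset} follows no n/c symbol"
                    )
                prev = symbols[-1]
                symbols[-1] = ExonSymbol(prev.kind, ch, prev.fragment)
            elif ch.isspace():
                continue
            else:
                raise ArchitectureParseError(
                    f"unknown symbol {ch!r} at offset {offset}"
                )
        offset += 1  # the hyphen
        if not symbols:
            raise ArchitectureParseError(f"empty exon token in {serialized!r}")
        tokens.append(symbols)
    return ExonTokenString(tokens)


@dataclass
class ModuleArchitecture:
    """Ordered protein module structure derived from an exon token string."""

    modules: list[str]
    mixed_variant_notes: list[str] = field(default_factory=list)

    def serialize(self) -> str:
        return "-".join(self.modules)

    def matches(self, printed: str) -> bool:
        """Case-insensitive comparison with a printed module-structure string."""
        norm = unicodedata.normalize("NFC", printed.strip().lower())
        norm = "".join(_QUOTE_MAP.get(ch, ch) for ch in norm)
        return norm == unicodedata.normalize("NFC", self.serialize())

    @property
    def full_modules(self) -> int:
        return sum(1 for m in self.modules if m in FULL_MODULE_SYMBOLS)

    @property
    def half_modules(self) -> int:
        return sum(1 for m in self.modules if m in ("p", "q"))

    @property
    def total(self) -> float:
        return self.full_modules + 0.5 * self.half_modules


_N_MOD_TO_MODULE = {"": "g", "*": "g*", '"': 'g"', "ň": "ğ"}


def _combine_halves(n_mod: str, c_mod: str, notes: list[str]) -> str:
    if (n_mod, c_mod) in {("", ""), ("*", "*"), ('"', ""), ("ň", "")}:
        return _N_MOD_TO_MODULE[n_mod]
    # unattested pairing, e.g. n*+c: keep the module, record both annotations
    notes.append(f"mixed-variant module from n{n_mod}+c{c_mod}")
    warnings.warn(f"mixed-variant half pairing n{n_mod}+c{c_mod}", stacklevel=3)
    return _N_MOD_TO_MODULE[n_mod]


def derive_architecture(exons: ExonTokenString) -> ModuleArchitecture:
    """Apply the splicing grammar to a tokenized exon structure.

    The stream is scanned left to right ignoring intron positions: ``s``,
    ``y`` and ``t`` emit nothing; runs of ``x`` emit a single ``x`` and break
    any pending n/c pairing; an n-type symbol pairs with an immediately
    following c-type symbol into a full module, otherwise it emits ``p``;
    a c-type symbol with no pending n-half emits ``q``.
    """
    modules: list[str] = []
    notes: list[str] = []
    pending: str | None = None  # modifier of the pending N-half

    def flush_pending():
        nonlocal pending
        if pending is not None:
            modules.append("p")
            pending = None

    for kind, mod in exons.half_symbol_stream():
        if kind in ("s", "y", "t"):
            continue
        if kind == "x":
            flush_pending()
            if not modules or modules[-1] != "x":
                modules.append("x")
            continue
        if kind == "n":
            flush_pending()
            pending = mod
        else:  # kind == "c"
            if pending is None:
                modules.append("q")
            else:
                modules.append(_combine_halves(pending, mod, notes))
                pending = None
    flush_pending()
    return ModuleArchitecture(modules, notes)


def module_counts(arch: ModuleArchitecture) -> tuple[int, int, float]:
    """(full, half, total) module bookkeeping; total = full + half / 2."""
    return arch.full_modules, arch.half_modules, arch.total


#: codon-length threshold separating short "y" exons from non-granulin "x" exons
Y_THRESHOLD_CODONS = 15
#: codon allowance for the signal-bearing first exon before it is flagged "sx"
SIGNAL_ALLOWANCE_CODONS = 30


def annotate_gene(
    gene: GeneModel,
    hits: list[ModuleHit],
    y_threshold: int = Y_THRESHOLD_CODONS,
) -> ExonTokenString:
    """Classify each exon of ``gene`` by the motif cysteines it covers.

    Each detected half-module must lie within a single exon (its cysteines
    must not be split across an intron); exons covering several whole halves
    produce concatenated tokens such as ``cn`` or ``ncnc``.  The first exon
    carries the signal prefix ``s``.  Exons covering no motif cysteine
    become ``y`` when at most ``y_threshold`` codons long, else ``x``.
    """
    halves: list[tuple[int, int, str, str]] = []  # (first_cys, last_cys, kind, mod)
    for hit in hits:
        n_slots = [(p, s) for p, s in zip(hit.cys_positions, hit.slots)
                   if s in {"C1", "C2", "Ca", "Cb", "C3", "C4", "C5", "C6"}]
        c_slots = [(p, s) for p, s in zip(hit.cys_positions, hit.slots)
                   if s in {"C7", "C8", "C9", "C10", "C11", "C12"}]
        if n_slots:
            mod = {6: "", 5: "*", 4: '"', 8: "ň"}.get(len(n_slots), "")
            halves.append((n_slots[0][0], n_slots[-1][0], "n", mod))
        if c_slots:
            mod = "*" if len(c_slots) == 5 else ""
            halves.append((c_slots[0][0], c_slots[-1][0], "c", mod))

    per_exon: dict[int, list[ExonSymbol]] = {}
    for first, last, kind, mod in halves:
        e1 = gene.exon_of_codon(first)
        e2 = gene.exon_of_codon(last)
        if e1 != e2:
            raise UnsupportedStructureError(
                f"{gene.gene_id}: half-module cysteines at {first}..{last} are "
                f"split across exons {e1} and {e2}"
            )
        per_exon.setdefault(e1, []).append(ExonSymbol(kind, mod))

    tokens: list[list[ExonSymbol]] = []
    for i, (s, e) in enumerate(gene.exons):
        syms = per_exon.get(i, [])
        codons = (e - s) // 3
        if i == 0:
            tok = [ExonSymbol("s")] + syms
            if not syms and codons > SIGNAL_ALLOWANCE_CODONS:
                tok.append(ExonSymbol("x"))
            tokens.append(tok)
        elif syms:
            tokens.append(syms)
        else:
            tokens.append([ExonSymbol("y" if codons <= y_threshold else "x")])
    return ExonTokenString(tokens)


def load_architecture_table() -> pd.DataFrame:
    """Packaged regression table of curated exon/module structures."""
    with resources.files("granulinkit.data").joinpath("architectures.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")
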