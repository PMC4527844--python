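"""Synthetic progranulin-like gene families with known ground truth.

The generator builds a coding sequence realizing an exon-structure token
string (cysteine codons placed by a spacing profile, everything else drawn
uniformly), then evolves it over a star or random phylogeny under a
two-parameter (transition/transversion) nucleotide model with per-module
rate multipliers.  Substitutions that would destroy an anchored motif
cysteine, create a new cysteine, or introduce a stop codon are rejected, so
the module architecture of every descendant is invariant by construction.

Defaults emulate the study conditions of the mammalian progranulin family:
37 species, the ``sn-n*-c*-n-c-n-c-n-cn-cn-cn-c`` exon architecture
(7 full modules plus the paragranulin), and a spacing profile calibrated so
the half-module coding sets reproduce the mammalian length arithmetic
(all eight N-half sets 90 bases and all seven C-half sets 75 bases after
the declarative trims).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import dendropy
import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .architecture import ExonSymbol, ModuleArchitecture, derive_architecture, tokenize
from .errors import ConfigError, UnsupportedStructureError
from .gene import GeneModel, write_exon_tsv

MAMMALIAN_ARCHITECTURE = "sn-n*-c*-n-c-n-c-n-cn-cn-cn-c"

NON_CYS_AA = "ADEFGHIKLMNPQRSTVWY"
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for aa in _CODONS_BY_AA:
    _CODONS_BY_AA[aa].sort()

_VARIANT_FROM_MODS = {("", ""): "g", ("*", "*"): "g_star",
                      ('"', ""): "g_dquote", ("ň", ""): "g_breve"}
_MODULE_SYMBOL = {"g": "g", "g_star": "g*", "g_dquote": 'g"', "g_breve": "ğ"}


class SpacingProfile:
    """Residue counts for the variable regions of each half-module layout."""

    def __init__(self, data: dict):
        self.data = data

    @classmethod
    def default(cls) -> "SpacingProfile":
        with resources.files("granulinkit.data").joinpath(
                "mammalian_profile.json").open() as fh:
            return cls(json.load(fh))

    def __getattr__(self, key):
        try:
            return self.data[key]
        except KeyError:
            raise AttributeError(key) from None

    def n_regions(self, module_ordinal: int | None, paragranulin: bool) -> list[int]:
        if paragranulin:
            return list(self.data["paragranulin"])
        over = self.data.get("n_overrides", {})
        if module_ordinal is not None and str(module_ordinal) in over:
            return list(over[str(module_ordinal)])
        return list(self.data["n_default"])

    def c_regions(self, module_ordinal: int | None) -> list[int]:
        over = self.data.get("c_overrides", {})
        if module_ordinal is not None and str(module_ordinal) in over:
            return list(over[str(module_ordinal)])
        return list(self.data["c_default"])


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic family.

    ``module_rate_multipliers`` maps module ordinals (1-based; 0 is the
    paragranulin) to relative substitution rates; everything outside the
    modules evolves at the global rate.
    """

    architecture: str = MAMMALIAN_ARCHITECTURE
    n_species: int = 37
    phylogeny: str = "star"       # "star" or "random"
    height: float = 0.3           # root-to-tip expected substitutions/site
    global_rate: float = 1.0
    kappa: float = 2.0            # transition/transversion rate ratio
    module_rate_multipliers: dict[int, float] = field(default_factory=dict)
    spacing: SpacingProfile = field(default_factory=SpacingProfile.default)
    flank_n: int = 2
    flank_c: int = 2
    nhalf_tail: int = 4
    paragranulin_tail: int = 5

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.module_rate_multipliers.values()):
            raise ConfigError("rate multipliers must be > 0")
        if self.n_species < 2:
            raise ConfigError("family generation needs n_species >= 2")
        if self.phylogeny not in ("star", "random"):
            raise ConfigError(f"unknown phylogeny {self.phylogeny!r}")


@dataclass
class Segment:
    """One layout unit of the template protein (coordinates in residues)."""

    kind: str                    # signal | linker | nhalf | chalf | x | y | tail
    start: int
    end: int
    module: int | None = None    # full-module ordinal; None for p/q and non-motif
    set_name: str | None = None  # p, n1.., c1.., q
    variant: str | None = None
    cys: list[int] = field(default_factory=list)
    slots: list[str] = field(default_factory=list)

    def shifted(self, offset: int) -> "Segment":
        return Segment(self.kind, self.start + offset, self.end + offset,
                       self.module, self.set_name, self.variant,
                       [c + offset for c in self.cys], list(self.slots))


@dataclass
class GroundTruth:
    """Generator-side record of everything a pipeline should recover."""

    units: list[Segment]
    exon_boundaries: list[int]   # internal boundaries, protein coordinates
    token_string: str
    architecture: ModuleArchitecture

    @property
    def halves(self) -> list[Segment]:
        return [u for u in self.units if u.kind in ("nhalf", "chalf")]

    def half_sets(self, gene: GeneModel) -> dict[str, tuple[str, str]]:
        """set_name -> (protein, coding DNA) for every half-module."""
        prot = gene.protein
        out = {}
        for u in self.halves:
            out[u.set_name] = (prot[u.start:u.end], gene.cds[3 * u.start:3 * u.end])
        return out

    def module_spans(self) -> dict[int, tuple[int, int]]:
        spans: dict[int, tuple[int, int]] = {}
        for u in self.halves:
            if u.module is None:
                continue
            s, e = spans.get(u.module, (u.start, u.end))
            spans[u.module] = (min(s, u.start), max(e, u.end))
        return spans


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def _half_layouts(cfg: GeneratorConfig, n_mod: str, module_ordinal, paired: bool):
    """Relative cysteine layout of one N-half: (length, cys offsets, slots)."""
    sp = cfg.spacing
    tail = cfg.nhalf_tail if paired else cfg.paragranulin_tail
    if n_mod == "ň":
        r1, _, r3 = sp.n_regions(module_ordinal, not paired)
        ga, gb = sp.n_breve_extra
        gaps = [r1, ga, gb, r3]
        groups = [["C1"], ["C2"], ["Ca", "Cb"], ["C3", "C4"], ["C5", "C6"]]
    else:
        r1, r2, r3 = sp.n_regions(module_ordinal, not paired)
        gaps = [r1, r2, r3]
        groups = [["C1"], ["C2"], ["C3", "C4"], ["C5", "C6"]]
    absent = {"*": {"C2"}, '"': {"C3", "C4"}}.get(n_mod, set())
    pos = cfg.flank_n
    cys, slots = [], []
    for gi, grp in enumerate(groups):
        if gi > 0:
            pos += gaps[gi - 1]
        for s in grp:
            if s not in absent:
                cys.append(pos)
                slots.append(s)
            pos += 1
    length = pos + tail
    return length, cys, slots


def _chalf_layout(cfg: GeneratorConfig, c_mod: str, module_ordinal):
    sp = cfg.spacing
    r4, r5, r6, r7 = sp.c_regions(module_ordinal)
    if r4 <= cfg.nhalf_tail:
        raise ConfigError("C5C6-C7C8 spacing must exceed the N-half tail")
    gaps = [r5, r6, r7]
    groups = [["C7", "C8"], ["C9", "C10"], ["C11"], ["C12"]]
    absent = {"*": {"C11"}}.get(c_mod, set())
    pos = r4 - cfg.nhalf_tail
    cys, slots = [], []
    for gi, grp in enumerate(groups):
        if gi > 0:
            pos += gaps[gi - 1]
        for s in grp:
            if s not in absent:
                cys.append(pos)
                slots.append(s)
            pos += 1
    length = pos + cfg.flank_c
    return length, cys, slots


def build_template(cfg: GeneratorConfig,
                   rng: np.random.Generator) -> tuple[GeneModel, GroundTruth]:
    """Realize an exon token string as a gene model with known truth.

    Supports architectures over ``s``, ``n``, ``c``, ``x`` and ``y`` tokens
    (with half-module modifiers); split-fragment parentheses and terminal
    ``t`` tokens cannot be generated.
    """
    exons = tokenize(cfg.architecture)
    flat: list[tuple[int, str, str]] = []
    for ti, tok in enumerate(exons.tokens):
        for sym in tok:
            if sym.fragment or sym.kind == "t":
                raise UnsupportedStructureError(
                    "the generator does not support split-fragment or "
                    "terminal-t tokens"
                )
            flat.append((ti, sym.kind, sym.modifier))

    # grammar walk: decide the fate (pairing, ordinal, set name) of each symbol
    roles: list[dict] = [{} for _ in flat]
    pending: int | None = None
    module_ord = 0
    p_count = q_count = 0
    arch_symbols: list[str] = []

    def close_pending(idx=None):
        nonlocal pending, p_count
        if pending is not None:
            p_count += 1
            roles[pending] = {"kind": "nhalf", "module": None, "paired": False,
                              "set": "p" if p_count == 1 else f"p{p_count}",
                              "variant": "p"}
            arch_symbols.append("p")
            pending = None

    for i, (_, kind, mod) in enumerate(flat):
        if kind in ("s", "y"):
            roles[i] = {"kind": "signal" if kind == "s" else "y"}
        elif kind == "x":
            close_pending()
            roles[i] = {"kind": "x"}
            if not arch_symbols or arch_symbols[-1] != "x":
                arch_symbols.append("x")
        elif kind == "n":
            close_pending()
            pending = i
        else:  # c
            if pending is None:
                q_count += 1
                roles[i] = {"kind": "chalf", "module": None, "paired": False,
                            "set": "q" if q_count == 1 else f"q{q_count}",
                            "variant": "q"}
                arch_symbols.append("q")
            else:
                module_ord += 1
                n_mod = flat[pending][2]
                variant = _VARIANT_FROM_MODS.get((n_mod, mod))
                if variant is None:
                    variant = _VARIANT_FROM_MODS.get((n_mod, ""), "g")
                roles[pending] = {"kind": "nhalf", "module": module_ord,
                                  "paired": True, "set": f"n{module_ord}",
                                  "variant": variant, "n_mod": n_mod}
                roles[i] = {"kind": "chalf", "module": module_ord,
                            "paired": True, "set": f"c{module_ord}",
                            "variant": variant, "c_mod": mod}
                arch_symbols.append(_MODULE_SYMBOL[variant])
                pending = None
    close_pending()
    architecture = ModuleArchitecture(arch_symbols)

    # lay out segments left to right
    sp = cfg.spacing
    units: list[Segment] = []
    sym_to_seg: list[int | None] = [None] * len(flat)
    pos = 0

    def add(seg: Segment) -> int:
        nonlocal pos
        units.append(seg)
        pos = seg.end
        return len(units) - 1

    prev_half_module: int | None = None
    for i, (_, kind, mod) in enumerate(flat):
        role = roles[i]
        rkind = role.get("kind")
        needs_linker = bool(units)
        if rkind == "chalf" and role["paired"] and prev_half_module == role["module"]:
            needs_linker = False  # contiguous at the N/C junction
        if needs_linker:
            add(Segment("linker", pos, pos + sp.linker_len))
        if rkind == "signal":
            sym_to_seg[i] = add(Segment("signal", pos, pos + sp.signal_len))
        elif rkind == "y":
            sym_to_seg[i] = add(Segment("y", pos, pos + sp.y_len))
        elif rkind == "x":
            sym_to_seg[i] = add(Segment("x", pos, pos + sp.x_len))
        elif rkind == "nhalf":
            length, cys, slots = _half_layouts(
                cfg, role.get("n_mod", "" if role["paired"] else ""),
                role["module"], role["paired"])
            seg = Segment("nhalf", pos, pos + length, role["module"],
                          role["set"], role["variant"],
                          [pos + c for c in cys], slots)
            sym_to_seg[i] = add(seg)
            prev_half_module = role["module"] if role["paired"] else None
        elif rkind == "chalf":
            length, cys, slots = _chalf_layout(cfg, role.get("c_mod", ""),
                                               role["module"])
            seg = Segment("chalf", pos, pos + length, role["module"],
                          role["set"], role["variant"],
                          [pos + c for c in cys], slots)
            sym_to_seg[i] = add(seg)
            prev_half_module = None
    add(Segment("tail", pos, pos + sp.tail_len))
    total = pos

    # exon boundaries between consecutive tokens
    boundaries: list[int] = []
    for i in range(len(flat) - 1):
        if flat[i][0] == flat[i + 1][0]:
            continue
        a, b = units[sym_to_seg[i]], units[sym_to_seg[i + 1]]
        ra, rb = roles[i], roles[i + 1]
        if (ra.get("kind") == "nhalf" and rb.get("kind") == "chalf"
                and ra.get("paired") and ra.get("module") == rb.get("module")):
            boundaries.append(a.end)  # the module junction
        else:
            boundaries.append(b.start - (sp.linker_len - sp.linker_split))

    # residues and codons
    protein = [""] * total
    cys_positions = set()
    for u in units:
        for c in u.cys:
            cys_positions.add(c)
    non_cys = rng.choice(list(NON_CYS_AA), size=total)
    for i in range(total):
        protein[i] = "C" if i in cys_positions else str(non_cys[i])
    protein[0] = "M" if units[0].kind == "signal" else protein[0]
    codons = []
    for aa in protein:
        opts = _CODONS_BY_AA[aa]
        codons.append(opts[rng.integers(len(opts))])
    cds = "".join(codons)

    spans = []
    prev = 0
    for b in boundaries:
        spans.append((3 * prev, 3 * b))
        prev = b
    spans.append((3 * prev, 3 * total))
    gene = GeneModel("template", cds, spans)
    truth = GroundTruth(units, boundaries, exons.serialize(), architecture)
    return gene, truth


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _site_rates(cds_len: int, truth: GroundTruth, cfg: GeneratorConfig) -> np.ndarray:
    rates = np.full(cds_len, cfg.global_rate)
    for u in truth.halves:
        key = u.module if u.module is not None else 0
        mult = cfg.module_rate_multipliers.get(key, 1.0)
        rates[3 * u.start:3 * u.end] = cfg.global_rate * mult
    return rates


def _evolve_cds(cds: str, branch_len: float, rates: np.ndarray,
                kappa: float, rng: np.random.Generator) -> str:
    """K2P jump-chain simulation with per-site rates and codon constraints.

    Proposals that would create a stop codon, create a new cysteine, or
    remove an anchored cysteine are rejected (discarded events), so
    cysteine content is invariant.
    """
    seq = list(cds)
    n_events = rng.poisson(rates * branch_len)
    p_ts = kappa / (kappa + 2.0)
    fwd = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)
    for site in np.nonzero(n_events)[0]:
        codon_start = 3 * (site // 3)
        for _ in range(n_events[site]):
            old = seq[site]
            if rng.random() < p_ts:
                new = _TS_PARTNER[old]
            else:
                new = _TV_PARTNERS[old][rng.integers(2)]
            codon = seq[codon_start:codon_start + 3]
            codon[site - codon_start] = new
            codon = "".join(codon)
            if codon in stops:
                continue
            old_codon = "".join(seq[codon_start:codon_start + 3])
            if (fwd[codon] == "C") != (fwd[old_codon] == "C"):
                continue
            seq[site] = new
    return "".join(seq)


def _star_tree(names: list[str], height: float) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace(names)
    tree = dendropy.Tree(taxon_namespace=tns)
    for name in names:
        nd = dendropy.Node(taxon=tns.get_taxon(name))
        nd.edge.length = height
        tree.seed_node.add_child(nd)
    tree.is_rooted = False
    return tree


def _random_ultrametric_tree(names: list[str], height: float,
                             rng: np.random.Generator) -> dendropy.Tree:
    """Coalescent-style random binary topology scaled to the given height."""
    tns = dendropy.TaxonNamespace(names)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = []
    for name in names:
        nd = dendropy.Node(taxon=tns.get_taxon(name))
        nd._h = 0.0
        nodes.append(nd)
    h = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        h += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = dendropy.Node()
        parent._h = h
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
        nodes = [nd for t, nd in enumerate(nodes) if t not in (i, j)] + [parent]
    root = nodes[0]
    scale = height / root._h
    for nd in root.preorder_iter():
        if nd.parent_node is not None:
            nd.edge.length = (nd.parent_node._h - nd._h) * scale
    tree.seed_node = root
    return tree


@dataclass
class SyntheticFamily:
    """A simulated species family sharing one template architecture."""

    species: dict[str, GeneModel]
    truth: GroundTruth
    tree: dendropy.Tree
    config: GeneratorConfig

    def proteins(self) -> dict[str, str]:
        return {name: g.protein for name, g in self.species.items()}

    def half_set_alignments(self) -> dict[str, list[tuple[str, str]]]:
        """set_name -> [(species, coding DNA)] using the ground-truth spans
        (identical across species: the simulation introduces no indels)."""
        out: dict[str, list[tuple[str, str]]] = {}
        for name, gene in self.species.items():
            for set_name, (_, dna) in self.truth.half_sets(gene).items():
                out.setdefault(set_name, []).append((name, dna))
        return out

    def module_protein_sets(self) -> dict[int, list[tuple[str, str]]]:
        out: dict[int, list[tuple[str, str]]] = {}
        spans = self.truth.module_spans()
        for name, gene in self.species.items():
            prot = gene.protein
            for mod, (s, e) in spans.items():
                out.setdefault(mod, []).append((name, prot[s:e]))
        return out

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "family_dna.fasta", "w") as fh:
            for name, g in self.species.items():
                fh.write(f">{name}\n{g.cds}\n")
        with open(outdir / "family_protein.fasta", "w") as fh:
            for name, g in self.species.items():
                fh.write(f">{name}\n{g.protein}\n")
        write_exon_tsv(list(self.species.values()), outdir / "family_exons.tsv")
        truth = {
            "token_string": self.truth.token_string,
            "architecture": self.truth.architecture.serialize(),
            "exon_boundaries": self.truth.exon_boundaries,
            "halves": [
                {"set": u.set_name, "kind": u.kind, "module": u.module,
                 "variant": u.variant, "start": u.start, "end": u.end,
                 "cys": u.cys}
                for u in self.truth.halves
            ],
        }
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
        with open(outdir / "tree.nwk", "w") as fh:
            fh.write(self.tree.as_string(schema="newick"))


def evolve_family(template: GeneModel, truth: GroundTruth,
                  cfg: GeneratorConfig,
                  rng: np.random.Generator) -> SyntheticFamily:
    """Simulate the template along a phylogeny into a species family."""
    names = [f"sp{i + 1:02d}" for i in range(cfg.n_species)]
    if cfg.phylogeny == "star":
        tree = _star_tree(names, cfg.height)
    else:
        tree = _random_ultrametric_tree(names, cfg.height, rng)
    rates = _site_rates(len(template.cds), truth, cfg)

    species: dict[str, GeneModel] = {}

    def walk(node, seq):
        for child in node.child_nodes():
            child_seq = _evolve_cds(seq, child.edge.length or 0.0, rates,
                                    cfg.kappa, rng)
            if child.is_leaf():
                species[child.taxon.label] = GeneModel(
                    child.taxon.label, child_seq, list(template.exons))
            else:
                walk(child, child_seq)

    walk(tree.seed_node, template.cds)
    ordered = {name: species[name] for name in names}
    return SyntheticFamily(ordered, truth, tree, cfg)


# ---------------------------------------------------------------------------
# tandem duplication
# ---------------------------------------------------------------------------

def tandem_duplicate(gene: GeneModel, truth: GroundTruth, module_index: int,
                     copies: int, rng: np.random.Generator,
                     mutations_per_copy: int = 0) -> tuple[GeneModel, GroundTruth]:
    """Duplicate one full module in place, ``copies`` times.

    The duplicated region is the module plus its preceding linker, so the
    local exon pattern (separate N/C exons or a CN chain) is replicated.
    ``mutations_per_copy`` protein-changing substitutions are applied to
    each copy to emulate tandem repeats of nearly identical modules.
    """
    if copies < 1:
        raise ConfigError("copies must be >= 1")
    n_units = [u for u in truth.units if u.kind == "nhalf" and u.module == module_index]
    c_units = [u for u in truth.units if u.kind == "chalf" and u.module == module_index]
    if not n_units or not c_units:
        raise ConfigError(
            f"module {module_index} is not a full module (half-modules "
            "cannot be tandem-duplicated)"
        )
    nh, ch = n_units[0], c_units[0]
    nh_idx = next(i for i, u in enumerate(truth.units) if u is nh)
    prev = truth.units[nh_idx - 1]
    if nh_idx == 0 or prev.kind != "linker":
        raise UnsupportedStructureError(
            "module has no preceding linker to carry in duplication"
        )
    src_start = prev.start
    src_end = ch.end
    unit_len = src_end - src_start
    total_len = copies * unit_len

    cds = gene.cds
    insert_cds = cds[3 * src_start:3 * src_end] * copies
    new_cds = cds[:3 * src_end] + insert_cds + cds[3 * src_end:]

    # exon boundaries
    new_b = []
    for b in truth.exon_boundaries:
        new_b.append(b + total_len if b >= src_end else b)
    for k in range(copies):
        for b in truth.exon_boundaries:
            if src_start < b <= src_end:
                new_b.append(src_end + k * unit_len + (b - src_start))
    new_b = sorted(set(new_b))

    # units: shift the suffix, renumber later modules, insert the copies
    new_units: list[Segment] = []
    for u in truth.units:
        if u.end <= src_end:
            new_units.append(u)
        else:
            shifted = u.shifted(total_len)
            if shifted.module is not None and shifted.module > module_index:
                shifted.module += copies
                side = "n" if shifted.kind == "nhalf" else "c"
                shifted.set_name = f"{side}{shifted.module}"
            new_units.append(shifted)
    inserted: list[Segment] = []
    src_units = [u for u in truth.units if src_start <= u.start < src_end]
    for k in range(copies):
        off = src_end + k * unit_len - src_start
        for u in src_units:
            cp = u.shifted(off)
            if cp.module is not None:
                cp.module = module_index + 1 + k
                side = "n" if cp.kind == "nhalf" else "c"
                cp.set_name = f"{side}{cp.module}"
            inserted.append(cp)
    idx = max(i for i, u in enumerate(new_units) if u.end <= src_end)
    new_units = new_units[:idx + 1] + inserted + new_units[idx + 1:]

    # architecture bookkeeping
    symbol = _MODULE_SYMBOL[nh.variant]
    arch = list(truth.architecture.modules)
    full_seen = 0
    at = None
    for i, s in enumerate(arch):
        if s in _MODULE_SYMBOL.values():
            full_seen += 1
            if full_seen == module_index:
                at = i
                break
    arch = arch[:at + 1] + [symbol] * copies + arch[at + 1:]

    # near-identity: protein-changing point mutations inside each copy
    cds_list = list(new_cds)
    protected = set()
    for u in new_units:
        protected.update(u.cys)
    fwd = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)
    linker_part = nh.start - src_start
    for k in range(copies):
        applied = 0
        attempts = 0
        while applied < mutations_per_copy and attempts < 10000:
            attempts += 1
            # mutate the module portion only, never the copied linker
            site = int(rng.integers(3 * (src_end + k * unit_len + linker_part),
                                    3 * (src_end + (k + 1) * unit_len)))
            codon_start = 3 * (site // 3)
            old_codon = "".join(cds_list[codon_start:codon_start + 3])
            base = "ACGT"[rng.integers(4)]
            if base == cds_list[site]:
                continue
            codon = list(old_codon)
            codon[site - codon_start] = base
            codon = "".join(codon)
            if codon in stops or fwd[codon] == fwd[old_codon]:
                continue
            if fwd[codon] == "C" or fwd[old_codon] == "C":
                continue
            cds_list[site] = base
            applied += 1
    new_cds = "".join(cds_list)

    spans = []
    prev = 0
    for b in new_b:
        spans.append((3 * prev, 3 * b))
        prev = b
    spans.append((3 * prev, len(new_cds)))
    new_gene = GeneModel(gene.gene_id, new_cds, spans)
    new_truth = GroundTruth(new_units, new_b,
                            _token_string_from_truth(new_units, new_b, spans),
                            ModuleArchitecture(arch))
    return new_gene, new_truth


def _token_string_from_truth(units: list[Segment], boundaries: list[int],
                             spans: list[tuple[int, int]]) -> str:
    """Reconstruct the exon token string from ground-truth coordinates."""
    edges = [0] + list(boundaries) + [spans[-1][1] // 3]
    tokens: list[list[ExonSymbol]] = []
    halves = [u for u in units if u.kind in ("nhalf", "chalf")]
    for e in range(len(edges) - 1):
        lo, hi = edges[e], edges[e + 1]
        syms: list[ExonSymbol] = []
        for u in halves:
            if u.cys and lo <= u.cys[0] < hi:
                if u.kind == "nhalf":
                    mod = {6: "", 5: "*", 4: '"', 8: "ň"}[len(u.cys)]
                    syms.append(ExonSymbol("n", mod))
                else:
                    syms.append(ExonSymbol("c", "*" if len(u.cys) == 5 else ""))
        if e == 0:
            syms = [ExonSymbol("s")] + syms
        elif not syms:
            has_x = any(u.kind == "x" and lo <= u.start < hi for u in units)
            syms = [ExonSymbol("x" if has_x else "y")]
        tokens.append(syms)
    from .architecture import ExonTokenString
    return ExonTokenString(tokens).serialize()


def random_architecture(rng: np.random.Generator) -> str:
    """A random exon token string from the generator-supported grammar.

    Produces architectures over s/n/c/x/y tokens with variant modifiers,
    leading/trailing paragranulins, orphan C-halves and random intron
    placement (any regrouping of the half-symbol stream is a valid gene
    structure, so intron positions are drawn freely; x and y segments
    always occupy their own exon).
    """
    stream: list[str] = []          # half symbols in order, e.g. "n*", "c"
    if rng.random() < 0.15:
        stream.append("q")          # orphan C-half at the start
    if rng.random() < 0.35:
        stream.append("p")
    n_modules = int(rng.integers(1, 7))
    for _ in range(n_modules):
        v = rng.random()
        if v < 0.7:
            stream.extend(["n", "c"])
        elif v < 0.85:
            stream.extend(["n*", "c*"])
        else:
            stream.extend(['n"', "c"])
        if rng.random() < 0.12:
            stream.append("x")
        if rng.random() < 0.1:
            stream.append("p")
    if rng.random() < 0.2:
        stream.append("p")

    tokens: list[str] = []
    current = "s"
    for sym in stream:
        if sym in ("x", "y"):
            if current:
                tokens.append(current)
            tokens.append(sym)
            current = ""
            continue
        half = {"p": "n", "q": "c"}.get(sym, sym)
        if current and rng.random() < 0.55:
            tokens.append(current)
            current = ""
        current += half
    if current:
        tokens.append(current)
    return "-".join(tokens)


# ---------------------------------------------------------------------------
# small simulators used as statistical oracles
# ---------------------------------------------------------------------------

def jukes_cantor_pair(n_sites: int, t: float,
                      rng: np.random.Generator) -> tuple[str, str]:
    """An aligned DNA pair at Jukes-Cantor distance t (closed form)."""
    anc = rng.integers(4, size=n_sites)
    p_diff = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    change = rng.random(n_sites) < p_diff
    shift = rng.integers(1, 4, size=n_sites)
    des = np.where(change, (anc + shift) % 4, anc)
    alpha = "ACGT"
    return ("".join(alpha[i] for i in anc), "".join(alpha[i] for i in des))


def markov_chain_triple(n_sites: int, t1: float, t2: float,
                        rng: np.random.Generator) -> tuple[str, str, str]:
    """A -> B -> C chain of Jukes-Cantor steps (for additivity checks)."""
    a, b = jukes_cantor_pair(n_sites, t1, rng)
    bi = np.array(["ACGT".index(ch) for ch in b])
    p_diff = 0.75 * (1.0 - np.exp(-4.0 * t2 / 3.0))
    change = rng.random(n_sites) < p_diff
    shift = rng.integers(1, 4, size=n_sites)
    ci = np.where(change, (bi + shift) % 4, bi)
    return a, b, "".join("ACGT"[i] for i in ci)
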