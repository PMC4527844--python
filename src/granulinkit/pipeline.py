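"""End-to-end orchestration: scan -> annotate -> align -> distances ->
summaries -> consensus -> trees, with a manifest for reproducibility.

Internal coordinates are 0-based half-open everywhere; conversion to
1-based inclusive happens only in GFF3/TSV writers.  All randomness flows
from the single seed in the run configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .align import align_anchored, align_sequences, strip_columns, unit_from_hit
from .architecture import annotate_gene, derive_architecture
from .consensus import (DEFAULT_THRESHOLDS, multi_threshold_consensus,
                        plurality_consensus, render_text)
from .distances import (DistanceMatrix, apply_trims, load_mammalian_trims,
                        pairwise_matrix, variability_summary)
from .errors import ConfigError, GranulinError
from .motif import MotifSpec, extract_half_modules, scan_protein, write_hits_tsv
from .synthetic import (MAMMALIAN_ARCHITECTURE, GeneratorConfig, build_template,
                        evolve_family)
from .trees import neighbor_joining, write_newick

log = logging.getLogger("granulinkit")

_RUNCONFIG_KEYS = {
    "architecture", "n_species", "phylogeny", "height", "global_rate",
    "kappa", "module_rate_multipliers", "seed", "outdir", "thresholds",
    "trims", "stages", "edit_directives", "log_level",
}
_ALL_STAGES = ("scan", "annotate", "align", "distances", "consensus", "trees")


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    outdir: str
    seed: int = 0
    architecture: str = MAMMALIAN_ARCHITECTURE
    n_species: int = 37
    phylogeny: str = "star"
    height: float = 0.3
    global_rate: float = 1.0
    kappa: float = 2.0
    module_rate_multipliers: dict = field(default_factory=dict)
    thresholds: tuple = DEFAULT_THRESHOLDS
    trims: str = "mammalian"      # "mammalian" | "none"
    stages: tuple = _ALL_STAGES
    edit_directives: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _RUNCONFIG_KEYS
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "outdir" not in data:
            raise ConfigError("configuration must name an outdir")
        cfg = cls(**data)
        cfg.module_rate_multipliers = {
            int(k): float(v) for k, v in dict(cfg.module_rate_multipliers).items()
        }
        cfg.thresholds = tuple(cfg.thresholds)
        cfg.stages = tuple(cfg.stages)
        bad = set(cfg.stages) - set(_ALL_STAGES)
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")
        if cfg.edit_directives is not None and not Path(cfg.edit_directives).exists():
            raise ConfigError(f"edit directives file not found: {cfg.edit_directives}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def param_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def label_half_module(species_abbrev: str, module_number: int | None,
                      side: str, is_last_of_long_form: bool = False,
                      is_five_cys: bool = False,
                      is_unpaired: bool = False) -> str:
    """Half-module labels following the tree-figure conventions.

    Paired halves are ``ABBR_NN`` with a trailing ``z`` on the last module
    of a long-form progranulin and ``*`` for 5-Cys forms; unpaired N-halves
    (paragranulins) are ``ABBR_p`` and unpaired C-halves ``ABBR_q``.
    """
    if is_unpaired:
        return f"{species_abbrev}_{'p' if side.upper() == 'N' else 'q'}"
    if module_number is None or module_number < 1:
        raise ConfigError("paired half-modules need a module number >= 1")
    label = f"{species_abbrev}_{module_number:02d}"
    if is_last_of_long_form:
        label += "z"
    if is_five_cys:
        label += "*"
    return label


def _named_halves(protein, gene, hits, spec):
    """(set_name, HalfModule) pairs per hit, with ordinal set names."""
    out = []
    module_ord = p_count = q_count = 0
    for hit in hits:
        n, c = extract_half_modules(hit, protein, gene, spec)
        if n is not None and c is not None:
            module_ord += 1
            out.append((f"n{module_ord}", hit, n))
            out.append((f"c{module_ord}", hit, c))
        elif n is not None:
            p_count += 1
            out.append(("p" if p_count == 1 else f"p{p_count}", hit, n))
        elif c is not None:
            q_count += 1
            out.append(("q" if q_count == 1 else f"q{q_count}", hit, c))
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full pipeline on a synthetic family; returns the manifest.

    Stage failures abort with the stage name; outputs produced so far are
    retained next to a ``FAILED_<stage>`` marker file.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    spec = MotifSpec.default()
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "param_hash": cfg.param_hash(),
        "outputs": {},
    }

    def emit(name: str) -> Path:
        path = outdir / name
        return path

    def register(path: Path) -> None:
        manifest["outputs"][path.name] = hashlib.sha256(
            path.read_bytes()).hexdigest()[:16]

    stage = "simulate"
    try:
        gcfg = GeneratorConfig(
            architecture=cfg.architecture, n_species=cfg.n_species,
            phylogeny=cfg.phylogeny, height=cfg.height,
            global_rate=cfg.global_rate, kappa=cfg.kappa,
            module_rate_multipliers=cfg.module_rate_multipliers,
        )
        template, truth = build_template(gcfg, rng)
        family = evolve_family(template, truth, gcfg, rng)
        family.write(outdir)
        for name in ("family_dna.fasta", "family_protein.fasta",
                     "family_exons.tsv", "ground_truth.json", "tree.nwk"):
            register(outdir / name)
        proteins = family.proteins()

        stage = "scan"
        all_hits = {}
        if "scan" in cfg.stages:
            flat = []
            for name, prot in proteins.items():
                hits = scan_protein(prot, spec, sequence_id=name)
                all_hits[name] = hits
                flat.extend(hits)
            write_hits_tsv(flat, emit("hits.tsv"))
            register(emit("hits.tsv"))

        stage = "annotate"
        if "annotate" in cfg.stages:
            with open(emit("architectures.tsv"), "w") as fh:
                fh.write("# species\texon_tokens\tmodule_structure\ttotal_modules\n")
                for name, gene in family.species.items():
                    tok = annotate_gene(gene, all_hits[name])
                    arch = derive_architecture(tok)
                    fh.write(f"{name}\t{tok.serialize()}\t"
                             f"{arch.serialize()}\t{arch.total}\n")
            register(emit("architectures.tsv"))

        stage = "align"
        half_dna_sets: dict[str, list[tuple[str, str]]] = {}
        module_units: dict[int, list] = {}
        if "align" in cfg.stages:
            half_units: dict[str, list] = {}
            for name, gene in family.species.items():
                prot = proteins[name]
                for set_name, hit, hm in _named_halves(prot, gene, all_hits[name], spec):
                    half_units.setdefault(set_name, []).append(
                        unit_from_hit(name, prot, hit, side=hm.side))
                    half_dna_sets.setdefault(set_name, []).append(
                        (name, hm.coding_seq))
                module_ord = 0
                for hit in all_hits[name]:
                    if hit.n_half_span and hit.c_half_span:
                        module_ord += 1
                        module_units.setdefault(module_ord, []).append(
                            unit_from_hit(name, prot, hit, side="full"))
            for set_name, units in sorted(half_units.items()):
                aln = align_anchored(units, spec)
                aln.to_fasta(emit(f"aln_{set_name}.fasta"))
                register(emit(f"aln_{set_name}.fasta"))
                with open(emit(f"aln_{set_name}.gaps.json"), "w") as fh:
                    json.dump(aln.region_gap_positions, fh, indent=1, sort_keys=True)
                register(emit(f"aln_{set_name}.gaps.json"))

        stage = "distances"
        module_alns = {m: align_anchored(u, spec) for m, u in module_units.items()}
        if "distances" in cfg.stages:
            trims = load_mammalian_trims() if cfg.trims == "mammalian" else {}
            trimmed = apply_trims(half_dna_sets, trims)
            half_order = sorted(
                trimmed, key=lambda s: (s[0] != "p", s[0] != "n", s[0] != "c",
                                        int(s[1:]) if s[1:].isdigit() else 0))
            summaries = []
            for set_name in half_order:
                dm = pairwise_matrix(trimmed[set_name], metric="logdet")
                dm.to_phylip(emit(f"dist_{set_name}.phy"))
                register(emit(f"dist_{set_name}.phy"))
                summaries.append((set_name, dm))
            for m, aln in sorted(module_alns.items()):
                dm = pairwise_matrix(aln.rows, metric="jtt_ml")
                dm.to_phylip(emit(f"dist_m{m}.phy"))
                register(emit(f"dist_m{m}.phy"))
                summaries.append((f"m{m}", dm))
            variability_summary(summaries).to_csv(emit("variability.tsv"), sep="\t")
            register(emit("variability.tsv"))

        stage = "consensus"
        module_consensus: dict[int, str] = {}
        if "consensus" in cfg.stages:
            with open(emit("consensus.txt"), "w") as fh:
                for m, aln in sorted(module_alns.items()):
                    rows = multi_threshold_consensus(aln, cfg.thresholds)
                    fh.write(f"== module {m} ==\n")
                    fh.write(render_text(rows))
                    fh.write("\n")
                    module_consensus[m] = plurality_consensus(aln)
            register(emit("consensus.txt"))

        stage = "trees"
        if "trees" in cfg.stages and len(module_consensus) >= 3:
            labeled = [(f"m{m}", s.replace("-", ""))
                       for m, s in sorted(module_consensus.items())]
            aln = align_sequences(labeled, spec, side="full")
            dm = pairwise_matrix(aln.rows, metric="jtt_ml", fast=False)
            write_newick(neighbor_joining(dm), emit("module_consensus_nj.nwk"))
            register(emit("module_consensus_nj.nwk"))
            stripped = strip_columns(aln, drop_anchor_cys=True)
            dm2 = pairwise_matrix(stripped.rows, metric="jtt_ml", fast=False)
            write_newick(neighbor_joining(dm2),
                         emit("module_consensus_nj_nocys.nwk"))
            register(emit("module_consensus_nj_nocys.nwk"))
    except GranulinError as exc:
        (outdir / f"FAILED_{stage}").write_text(str(exc) + "\n")
        raise GranulinError(f"stage {stage!r} failed: {exc}") from exc

    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()[:16]
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("pipeline complete: %s (%d outputs)", outdir,
             len(manifest["outputs"]))
    return manifest
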