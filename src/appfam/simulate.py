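"""Synthetic gene families with known evolutionary truth.

The generator emulates, at desk scale, a multi-clade gene family like the
amyloid precursor protein family: a known rooted tree whose major clades
play the role of the family members (APP, APLP1, APLP2, APL-1, APPL-1),
domain-structured rate variation (conserved vs variable regions), planted
clade-diagnostic substitutions (known synapomorphies), and planted
hydrophobic, β-prone segments at known coordinates (known amyloidogenic
regions).  Everything planted is recorded in a :class:`TruthBundle` so that
downstream tree building, synapomorphy calling and aggregation scoring can
be checked against ground truth.

Sequences evolve site-independently under a uniform-exchange model (any
residue mutates to any other with equal probability); per-domain rate
multipliers scale the substitution probability per branch.  Planted columns
are frozen against further change so the truth stays assertable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import write_alignment, write_domain_map, write_fasta
from .trees import Node, PhyloTree, write_newick
from .types import (AA_ALPHABET, AlignedMatrix, DomainInterval, DomainMap,
                    KNOWN_GENE_LABELS, SequenceRecord)

#: residue weights used for planted aggregation-prone stretches
HYDROPHOBIC_WEIGHTS = {
    "I": 0.20, "V": 0.20, "L": 0.20, "F": 0.15, "A": 0.10,
    "M": 0.08, "W": 0.04, "Y": 0.03,
}

#: polar-leaning background used when amyloid plants must stand out
POLAR_WEIGHTS = {
    "S": 0.14, "T": 0.12, "N": 0.10, "Q": 0.10, "D": 0.10, "E": 0.10,
    "K": 0.10, "R": 0.08, "G": 0.08, "H": 0.04, "P": 0.04,
}

_DEFAULT_CLADES = ("APL-1", "APPL-1", "APP", "APLP2", "APLP1")


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for one simulated family.

    Defaults give a 16-tip family (4 clades × 4 species) over 300 columns
    with 0.25 expected substitutions per site across the whole tree — low
    enough homoplasy that parsimony should recover the planted history.
    """

    n_clades: int = 4
    tips_per_clade: int = 4
    sequence_length: int = 300
    rate: float = 0.25  # expected substitutions/site over the whole tree
    seed: int = 0
    clade_names: tuple[str, ...] | None = None
    domain_rates: dict[str, float] = field(default_factory=dict)
    # (name, start, end) on the root sequence, 0-based half-open
    domains: list[tuple[str, int, int]] | None = None
    # clade name -> list of (column, derived_state or None)
    planted_synapomorphies: dict[str, list[tuple[int, str | None]]] = \
        field(default_factory=dict)
    # list of (clade name or tip id, position, motif length)
    amyloid_plants: list[tuple[str, int, int]] = field(default_factory=list)
    motif_weights: dict[str, float] = \
        field(default_factory=lambda: dict(HYDROPHOBIC_WEIGHTS))
    background_weights: dict[str, float] | None = None
    # attach a basal outgroup tip OUT_01 (never planted), mirroring how a
    # distant single-copy homolog roots the real family tree
    add_outgroup: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.rate <= 0:
            raise ConfigError("rate must be > 0")
        if self.clade_names is None:
            self.clade_names = _DEFAULT_CLADES[: self.n_clades]
        if len(self.clade_names) != self.n_clades:
            raise ConfigError("clade_names length must equal n_clades")
        for mult in self.domain_rates.values():
            if mult < 0:
                raise ConfigError("domain rate multipliers must be >= 0")
        for name, start, end in (self.domains or ()):
            if not 0 <= start < end <= self.sequence_length:
                raise ConfigError(
                    f"domain {name!r} interval ({start}, {end}) outside "
                    "the sequence")
        cols = [c for plants in self.planted_synapomorphies.values()
                for c, _ in plants]
        if len(cols) != len(set(cols)):
            raise ConfigError("planted synapomorphy columns collide")
        for c in cols:
            if not 0 <= c < self.sequence_length:
                raise ConfigError(f"planted column {c} outside sequence")


@dataclass
class PlantedSynapomorphy:
    clade: str
    node_id: str
    column: int
    ancestral: str
    derived: str


@dataclass
class AmyloidPlant:
    taxon_id: str
    start: int
    end: int
    motif: str


@dataclass
class TruthBundle:
    """Everything a simulation promised, for later verification."""

    tree: PhyloTree
    records: list[SequenceRecord]
    alignment: AlignedMatrix
    domain_map: DomainMap
    synapomorphies: list[PlantedSynapomorphy]
    amyloid_plants: list[AmyloidPlant]
    mutation_log: list[tuple[str, int, str, str]]  # (child node id, col, from, to)
    config: SimulationConfig

    def write(self, outdir) -> dict[str, str]:
        """Emit the bundle as plain-text files; returns {name: path}."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "sequences": outdir / "sequences.fasta",
            "alignment": outdir / "alignment.fasta",
            "tree": outdir / "true_tree.nwk",
            "domain_map": outdir / "domain_map.tsv",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.records, paths["sequences"])
        write_alignment(self.alignment, paths["alignment"],
                        records={r.id: r for r in self.records})
        write_newick(self.tree, paths["tree"])
        write_domain_map(self.domain_map, paths["domain_map"])
        truth = {
            "synapomorphies": [
                {"clade": s.clade, "node_id": s.node_id, "column": s.column,
                 "ancestral": s.ancestral, "derived": s.derived}
                for s in self.synapomorphies
            ],
            "amyloid_plants": [
                {"taxon_id": p.taxon_id, "start": p.start, "end": p.end,
                 "motif": p.motif}
                for p in self.amyloid_plants
            ],
            "clades": {
                name: sorted(self.clade_tips(name))
                for name in self.config.clade_names
            },
            "n_mutations": len(self.mutation_log),
            "seed": self.config.seed,
        }
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return {k: str(v) for k, v in paths.items()}

    def clade_tips(self, clade_name: str) -> list[str]:
        return [r.id for r in self.records
                if r.id.startswith(clade_name + "_")]


# ----------------------------------------------------------------------
# tree simulation
# ----------------------------------------------------------------------

def simulate_tree(n_tips: int, seed: int, mode: str = "yule",
                  labels: list[str] | None = None) -> PhyloTree:
    """Random binary rooted tree with exponential (Yule) branch lengths."""
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if mode != "yule":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    tree = _yule(n_tips, rng)
    tips = tree.tips()
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_tips)]
    if len(labels) != n_tips:
        raise ValueError("labels length must equal n_tips")
    for node, lab in zip(tips, labels):
        node.label = lab
    tree.assign_ids()
    return tree


def _yule(n_tips: int, rng: np.random.Generator) -> PhyloTree:
    root = Node()
    active = []
    for _ in range(2):
        child = root.add_child(Node(length=0.0))
        active.append(child)
    while len(active) < n_tips:
        dt = rng.exponential(1.0 / len(active))
        for node in active:
            node.length += dt
        split = active.pop(int(rng.integers(len(active))))
        for _ in range(2):
            active.append(split.add_child(Node(length=0.0)))
    dt = rng.exponential(1.0 / len(active))
    for node in active:
        node.length += dt
    for i, node in enumerate(active):
        node.label = f"_tmp{i}"
    return PhyloTree(root)


def simulate_family_tree(config: SimulationConfig, rng: np.random.Generator
                         ) -> PhyloTree:
    """Tree whose designated clades are guaranteed monophyletic.

    A Yule backbone over the clades carries one Yule subtree per clade;
    the total tree length is normalised to 1 so ``config.rate`` reads as
    expected substitutions per site across the whole tree.
    """
    n, k = config.n_clades, config.tips_per_clade
    if n >= 3:
        backbone = _yule(n, rng)
    else:
        root = Node()
        for _ in range(n):
            root.add_child(Node(length=1.0))
        backbone = None
        backbone_root = root
    stubs = backbone.tips() if n >= 3 else backbone_root.children
    for clade_name, stub in zip(config.clade_names, stubs):
        if k == 1:
            stub.label = f"{clade_name}_01"
            continue
        sub = _yule(max(k, 3), rng) if k >= 3 else None
        if k == 2:
            for i in range(2):
                stub.add_child(Node(label=f"{clade_name}_{i + 1:02d}",
                                    length=float(rng.exponential(0.5))))
        else:
            for i, tip in enumerate(sub.tips()):
                tip.label = f"{clade_name}_{i + 1:02d}"
            stub.children = sub.root.children
            for c in stub.children:
                c.parent = stub
        stub.label = None
    family_root = backbone.root if n >= 3 else backbone_root
    if config.add_outgroup:
        new_root = Node()
        new_root.add_child(Node(label="OUT_01",
                                length=float(rng.exponential(1.0)) + 0.5))
        family_root.length = float(rng.exponential(0.5)) + 0.1
        new_root.add_child(family_root)
        family_root = new_root
    tree = PhyloTree(family_root)
    total = sum(node.length or 0.0 for node in tree.postorder()
                if node is not tree.root)
    for node in tree.postorder():
        if node.length is not None:
            node.length = node.length / total
    tree.assign_ids()
    return tree


# ----------------------------------------------------------------------
# sequence evolution
# ----------------------------------------------------------------------

def _draw_weighted(rng, weights: dict[str, float], size: int) -> str:
    letters = sorted(weights)
    p = np.array([weights[l] for l in letters], dtype=float)
    p /= p.sum()
    return "".join(rng.choice(list(letters), size=size, p=p))


def plant_amyloid_motif(record: SequenceRecord, position: int, length: int,
                        seed=None, weights: dict[str, float] | None = None,
                        ) -> tuple[SequenceRecord, AmyloidPlant]:
    """Overwrite a window with a hydrophobic, β-prone stretch.

    Returns the modified record and a truth entry with the coordinates and
    the motif that was written.  ``seed`` may be an integer or an existing
    numpy Generator.
    """
    if position < 0 or position + length > record.length:
        raise ValueError(
            f"window ({position}, {position + length}) out of range for "
            f"record of length {record.length}")
    if length == 0:
        return record, AmyloidPlant(record.id, position, position, "")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    motif = _draw_weighted(rng, weights or HYDROPHOBIC_WEIGHTS, length)
    res = record.residues
    new = res[:position] + motif + res[position + length:]
    return record.with_residues(new), AmyloidPlant(
        record.id, position, position + length, motif)


def _site_multipliers(config: SimulationConfig) -> np.ndarray:
    mult = np.ones(config.sequence_length)
    for name, start, end in (config.domains or ()):
        m = config.domain_rates.get(name)
        if m is not None:
            mult[start:end] = m
    return mult


def evolve_family(tree: PhyloTree, config: SimulationConfig) -> TruthBundle:
    """Evolve sequences down ``tree`` and assemble the truth bundle.

    Planted diagnostic substitutions are applied on the stem branch of each
    designated clade; their columns are frozen everywhere else so each
    planted state is present in exactly that clade's tips.
    """
    rng = np.random.default_rng(config.seed)
    L = config.sequence_length
    alpha = np.array(list(AA_ALPHABET))
    tree = tree.copy()
    tree.assign_ids()

    for name in config.planted_synapomorphies:
        if name not in config.clade_names:
            raise ConfigError(f"planted clade {name!r} is not a family clade")

    # root sequence
    bg = config.background_weights
    if bg:
        root_seq = np.array(list(_draw_weighted(rng, bg, L)))
    else:
        root_seq = alpha[rng.integers(len(alpha), size=L)]

    mult = _site_multipliers(config)
    frozen = np.zeros(L, dtype=bool)
    planted_truth: list[PlantedSynapomorphy] = []
    stem_plants: dict[str, list[tuple[int, str]]] = {}
    for clade_name, plants in config.planted_synapomorphies.items():
        node = tree.find_monophyletic(
            [t for t in tree.tip_labels() if t.startswith(clade_name + "_")])
        todo = []
        for col, derived in plants:
            ancestral = str(root_seq[col])
            if derived is None:
                choices = [a for a in AA_ALPHABET if a != ancestral]
                derived = str(rng.choice(choices))
            if derived == ancestral:
                raise ConfigError(
                    f"planted derived state at column {col} equals the "
                    "ancestral state")
            frozen[col] = True
            todo.append((col, derived))
            planted_truth.append(PlantedSynapomorphy(
                clade_name, node.id, col, ancestral, derived))
        stem_plants[node.id] = todo

    mutation_log: list[tuple[str, int, str, str]] = []
    seqs: dict[int, np.ndarray] = {id(tree.root): root_seq}
    for node in tree.preorder():
        if node is tree.root:
            continue
        seq = seqs[id(node.parent)].copy()
        blen = node.length or 0.0
        p = 1.0 - np.exp(-config.rate * mult * blen)
        hit = (rng.random(L) < p) & ~frozen
        for col in np.nonzero(hit)[0]:
            old = seq[col]
            choices = alpha[alpha != old]
            new = choices[rng.integers(len(choices))]
            seq[col] = new
            mutation_log.append((node.id, int(col), str(old), str(new)))
        for col, derived in stem_plants.get(node.id, ()):
            mutation_log.append((node.id, col, str(seq[col]), derived))
            seq[col] = derived
        seqs[id(node)] = seq

    # assemble tip records; clade name doubles as the gene-family label
    records = []
    for tip in tree.tips():
        if "_" in tip.label:
            clade, suffix = tip.label.rsplit("_", 1)
            species = "species_" + suffix
        else:
            clade, species = tip.label, tip.label
        gene = clade if clade in KNOWN_GENE_LABELS else "other"
        records.append(SequenceRecord(
            id=tip.label, taxon=species,
            residues="".join(seqs[id(tip)]), gene_label=gene))

    # amyloid plants (applied to finished tip sequences); one motif is
    # drawn per plant spec and shared by all targeted tips, emulating a
    # conserved aggregation-prone region
    plants: list[AmyloidPlant] = []
    by_id = {r.id: i for i, r in enumerate(records)}
    for target, pos, length in config.amyloid_plants:
        if target == "*":
            ids = [r.id for r in records]
        else:
            ids = [r.id for r in records
                   if r.id == target or r.id.startswith(target + "_")]
        if not ids:
            raise ConfigError(f"amyloid plant target {target!r} matches no tip")
        motif = _draw_weighted(rng, config.motif_weights, length)
        for rid in ids:
            rec = records[by_id[rid]]
            if pos < 0 or pos + length > rec.length:
                raise ConfigError(
                    f"plant window ({pos}, {pos + length}) out of range")
            res = rec.residues
            records[by_id[rid]] = rec.with_residues(
                res[:pos] + motif + res[pos + length:])
            plants.append(AmyloidPlant(rid, pos, pos + length, motif))

    alignment = AlignedMatrix([r.id for r in records],
                              [r.residues for r in records])
    # simulated sequences are indel-free, so root coordinates equal every
    # tip's coordinates; anchor the map on the first record
    entries = [DomainInterval(n, s0, e0, allow_overlap=True)
               for n, s0, e0 in (config.domains or [("whole", 0, L)])]
    dmap = DomainMap(records[0].id, entries)
    return TruthBundle(tree=tree, records=records, alignment=alignment,
                       domain_map=dmap, synapomorphies=planted_truth,
                       amyloid_plants=plants, mutation_log=mutation_log,
                       config=config)


def planted_recovery(bundle: TruthBundle, table, est_tree) -> tuple[int, int]:
    """Count planted synapomorphies recovered at the correct node.

    A plant is recovered when its clade is monophyletic on the estimated
    (rooted) tree and the synapomorphy table holds an entry at that
    clade's node, at the planted column, with the planted derived state.
    Returns (recovered, total planted).
    """
    if any(n.id is None for n in est_tree.postorder()):
        est_tree.assign_ids()
    by_key = {(e.node_id, e.column, e.derived) for e in table.entries}
    found = 0
    for s in bundle.synapomorphies:
        tips = [t for t in bundle.clade_tips(s.clade)
                if t in set(est_tree.tip_labels())]
        if len(tips) < 2:
            continue
        try:
            node = est_tree.find_monophyletic(tips)
        except (ValueError, KeyError):
            continue
        if (node.id, s.column, s.derived) in by_key:
            found += 1
    return found, len(bundle.synapomorphies)


def simulate_family(config: SimulationConfig) -> TruthBundle:
    """Convenience wrapper: family tree + evolution from one config/seed."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_family_tree(config, rng)
    return evolve_family(tree, config)
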