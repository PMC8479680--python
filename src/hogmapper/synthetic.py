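"""Synthetic gene families with known subfamily truth.

Generates a reference database plus a leave-one-out query proteome whose true
family and sub-HOG labels are known by construction, so placement logic can be
tested end to end without any external resource.

The model: one ultrametric species tree (depth 1) shared by all families; a
gene lineage enters each family at the root and duplicates along the species
tree as a Poisson birth process.  Every duplication spawns a pair of nested
sub-HOGs (binary, capped at ``depth_max`` nesting), mirroring the fact that
subfamilies are defined by duplication events.  Sequences evolve by i.i.d.
per-site replacement from a background amino-acid frequency vector — a site
substitutes along a branch of length ``t`` with probability ``1 - exp(-r t)``,
the replacement drawn from the background (possibly the same residue).
Post-duplication daughter branches are accelerated by ``rate_boost`` and one
of the two further by ``asymmetry``, reproducing the accelerated and
asymmetric evolution of duplicated proteins that makes closest-sequence
assignment go wrong.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .reference_db import (
    CANONICAL_ALPHABET,
    HOGHierarchy,
    Protein,
    ReferenceDB,
    remove_species,
    write_reference,
)

#: Swiss-Prot-like amino-acid background frequencies in canonical order
#: (ACDEFGHIKLMNPQRSTVWY); normalized at use.
BACKGROUND_FREQS = np.array([
    8.25, 1.38, 5.45, 6.72, 3.86, 7.07, 2.27, 5.91, 5.80, 9.65,
    2.41, 4.06, 4.74, 3.93, 5.53, 6.63, 5.35, 6.86, 1.10, 2.92,
])
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()


@dataclass
class SimParams:
    """Generator settings.

    Defaults are the rate-asymmetric benchmark conditions: 50 families over 8
    species, a duplication rate of 1.2 expected events per root-to-tip gene
    lineage (calibrated so that over-specific closest-sequence configurations
    make up >= 20% of queries, the regime the benchmark targets) with at most
    3 nested sub-HOG levels, 150-residue roots, a base substitution rate of
    0.15 expected substitution events per site per unit of tree depth, and
    strong post-duplication acceleration (x4) with 3-fold rate asymmetry
    between daughter lineages.
    """

    n_families: int = 50
    n_species: int = 8
    duplication_rate: float = 1.2
    depth_max: int = 3
    root_length: int = 150
    subst_rate: float = 0.15
    rate_boost: float = 4.0
    asymmetry: float = 3.0
    indel_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duplication_rate", "subst_rate", "rate_boost", "indel_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.asymmetry < 1:
            raise ValueError("asymmetry must be >= 1")


# -- species tree --------------------------------------------------------


@dataclass
class SpeciesNode:
    name: str
    height: float                      # distance from the tips (ultrametric)
    children: list["SpeciesNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


def make_species_tree(n_species: int, rng: np.random.Generator) -> SpeciesNode:
    """Random-topology ultrametric species tree of depth 1.

    Join heights are evenly spaced, so total root-to-tip depth is exactly 1
    and all tips are contemporaneous.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    nodes = [SpeciesNode(f"S{i + 1}", 0.0) for i in range(n_species)]
    join = 1
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        h = join / (n_species - 1)
        nodes.append(SpeciesNode(f"anc{join}", h, [a, b]))
        join += 1
    return nodes[0]


def species_branches(root: SpeciesNode) -> list[tuple[float, float]]:
    """(start_depth_from_root, end_depth_from_root) of every branch."""
    out: list[tuple[float, float]] = []
    H = root.height

    def walk(node: SpeciesNode) -> None:
        for ch in node.children:
            out.append((H - node.height, H - ch.height))
            walk(ch)

    walk(root)
    return out


def expected_duplications(root: SpeciesNode, rate: float) -> float:
    """Closed-form mean duplication count for the uncapped birth process.

    A gene lineage entering a species branch at depth ``t0`` carries an
    expected ``exp(rate * t0)`` copies, so the expected duplications on the
    branch ``[t0, t1]`` total ``exp(rate*t1) - exp(rate*t0)``; summed over
    the branches of the species tree.
    """
    return float(
        sum(np.exp(rate * t1) - np.exp(rate * t0) for t0, t1 in species_branches(root))
    )


# -- gene tree -----------------------------------------------------------


@dataclass
class GeneNode:
    """Node of a simulated gene tree.

    ``branch_length`` is the segment length to the parent (species-tree
    units); ``rate_mult`` the rate multiplier on that segment (post-
    duplication daughter segments carry boost and asymmetry).  Tips carry a
    ``species``; every node carries the HOG its lineage belongs to.
    """

    id: str
    branch_length: float
    rate_mult: float
    hog_id: str
    species: str | None = None
    is_duplication: bool = False
    children: list["GeneNode"] = field(default_factory=list)

    def tips(self) -> list["GeneNode"]:
        if not self.children:
            return [self]
        return [t for c in self.children for t in c.tips()]


def simulate_family(
    params: SimParams,
    family_seed: int,
    species_tree: SpeciesNode | None = None,
    family_id: str = "F0000",
) -> tuple[GeneNode, list[tuple[str, str | None, str]]]:
    """Simulate one family's gene tree and its HOG hierarchy rows.

    Duplications fall as a Poisson process of rate ``duplication_rate`` along
    every gene lineage, capped once a lineage's HOG nesting reaches
    ``depth_max``; each duplication spawns two child sub-HOGs.  The returned
    hierarchy rows are ``(hog_id, parent_id_or_None, level)``.
    """
    rng = np.random.default_rng(family_seed)
    if species_tree is None:
        species_tree = make_species_tree(params.n_species, rng)
    hog_rows: list[tuple[str, str | None, str]] = [(family_id, None, "root")]
    hog_children: dict[str, int] = {family_id: 0}
    hog_depth = {family_id: 0}
    counter = [0]

    def new_hog(parent: str) -> str:
        hog_children[parent] += 1
        hid = f"{parent}.{hog_children[parent]}"
        hog_rows.append((hid, parent, f"dup{hog_depth[parent] + 1}"))
        hog_children[hid] = 0
        hog_depth[hid] = hog_depth[parent] + 1
        return hid

    def gene_id() -> str:
        counter[0] += 1
        return f"{family_id}g{counter[0]}"

    def descend(sp: SpeciesNode, remaining: float, hog: str, mult: float) -> GeneNode:
        """Evolve one gene lineage from ``remaining`` above ``sp`` down to it."""
        if hog_depth[hog] < params.depth_max and params.duplication_rate > 0:
            wait = rng.exponential(1.0 / params.duplication_rate)
        else:
            wait = np.inf
        if wait < remaining:
            node = GeneNode(gene_id(), wait, mult, hog, is_duplication=True)
            h1, h2 = new_hog(hog), new_hog(hog)
            m1, m2 = params.rate_boost, params.rate_boost * params.asymmetry
            if rng.random() < 0.5:
                m1, m2 = m2, m1
            node.children = [
                descend(sp, remaining - wait, h1, m1),
                descend(sp, remaining - wait, h2, m2),
            ]
            return node
        node = GeneNode(gene_id(), remaining, mult, hog)
        if sp.is_leaf:
            node.species = sp.name
            return node
        node.children = [
            descend(ch, sp.height - ch.height, hog, 1.0) for ch in sp.children
        ]
        return node

    root = descend(species_tree, 0.0, family_id, 1.0)
    return root, hog_rows


def evolve_sequences(
    tree: GeneNode,
    params: SimParams,
    rng: np.random.Generator,
    root_sequence: np.ndarray | None = None,
) -> dict[str, str]:
    """Evolve sequences down a gene tree; returns tip id -> sequence.

    The root sequence is drawn i.i.d. from the background frequencies unless
    given.  Along a branch of length ``t`` with rate multiplier ``m`` every
    site is redrawn from the background with probability
    ``1 - exp(-subst_rate * m * t)``; indel events (0.5/0.5 insertion or
    deletion of 1–5 background residues) occur at ``indel_rate`` per site per
    unit branch length.
    """
    alphabet = np.frombuffer(CANONICAL_ALPHABET.encode(), dtype=np.uint8)
    if root_sequence is None:
        root_sequence = rng.choice(20, size=params.root_length, p=BACKGROUND_FREQS)
    out: dict[str, str] = {}

    def walk(node: GeneNode, seq: np.ndarray) -> None:
        t = node.branch_length * node.rate_mult
        if t > 0 and len(seq):
            p = 1.0 - np.exp(-params.subst_rate * t)
            hit = rng.random(len(seq)) < p
            seq = seq.copy()
            seq[hit] = rng.choice(20, size=int(hit.sum()), p=BACKGROUND_FREQS)
            n_indel = rng.poisson(params.indel_rate * node.branch_length * len(seq))
            for _ in range(n_indel):
                span = int(rng.integers(1, 6))
                pos = int(rng.integers(0, len(seq) + 1))
                if rng.random() < 0.5 and len(seq) > span:
                    seq = np.delete(seq, slice(pos, pos + span))
                else:
                    ins = rng.choice(20, size=span, p=BACKGROUND_FREQS)
                    seq = np.insert(seq, pos, ins)
        if not node.children:
            out[node.id] = alphabet[seq].tobytes().decode()
        for ch in node.children:
            walk(ch, seq)

    walk(tree, np.asarray(root_sequence))
    return out


# -- fixtures ------------------------------------------------------------


@dataclass
class FixtureTruth:
    """Ground truth emitted with a fixture.

    ``hog_of``/``species_of``/``family_of`` cover every simulated protein.
    ``reference_hog_of`` maps each *query* protein to its most specific HOG
    that survives in the leave-one-out reference (its own HOG, or the nearest
    ancestor whose subtree still has reference members).
    """

    species_of: dict[str, str]
    family_of: dict[str, str]
    hog_of: dict[str, str]
    reference_hog_of: dict[str, str]
    gene_trees: dict[str, GeneNode]


@dataclass
class Fixture:
    reference: ReferenceDB
    full: ReferenceDB
    queries: list[tuple[str, str]]      # (protein id, sequence)
    query_species: str
    truth: FixtureTruth


def make_fixture(params: SimParams, k: int = 6) -> Fixture:
    """Simulate a full database and split off one species as the query set.

    Species ``S1`` is the designated query proteome: the reference database
    excludes it (with empty HOG subtrees pruned), exactly the leave-one-out
    protocol used for benchmarking.  Deterministic under ``params.seed``.
    """
    if params.n_species < 3:
        raise ValueError("need n_species >= 3 for a leave-one-out fixture")
    master = np.random.default_rng(params.seed)
    tree_rng = np.random.default_rng(master.integers(2**31))
    species_tree = make_species_tree(params.n_species, tree_rng)

    proteins: dict[str, Protein] = {}
    all_rows: list[tuple[str, str | None, str]] = []
    trees: dict[str, GeneNode] = {}
    species_of: dict[str, str] = {}
    family_of: dict[str, str] = {}
    hog_of: dict[str, str] = {}
    for f in range(params.n_families):
        fam_id = f"F{f:04d}"
        fam_seed = int(master.integers(2**31))
        root, rows = simulate_family(params, fam_seed, species_tree, fam_id)
        seq_rng = np.random.default_rng(int(master.integers(2**31)))
        seqs = evolve_sequences(root, params, seq_rng)
        all_rows.extend(rows)
        trees[fam_id] = root
        per_species: dict[str, int] = {}
        for tip in root.tips():
            sp = tip.species
            per_species[sp] = per_species.get(sp, 0) + 1
            pid = f"{sp}_{fam_id}_{per_species[sp]}"
            proteins[pid] = Protein(pid, sp, seqs[tip.id], tip.hog_id)
            species_of[pid] = sp
            family_of[pid] = fam_id
            hog_of[pid] = tip.hog_id

    hierarchy = HOGHierarchy(all_rows)
    full = ReferenceDB(proteins, hierarchy, k=k)
    query_species = "S1"
    reference = remove_species(full, query_species)
    queries = sorted(
        (p.id, p.sequence) for p in full.proteins.values() if p.species == query_species
    )
    ref_hog_of: dict[str, str] = {}
    for pid, _ in queries:
        h = hog_of[pid]
        while h not in reference.hierarchy:
            h = hierarchy.parent(h)
        ref_hog_of[pid] = h
    truth = FixtureTruth(species_of, family_of, hog_of, ref_hog_of, trees)
    return Fixture(reference, full, queries, query_species, truth)


def write_fixture(fix: Fixture, out_dir: str | Path) -> dict[str, Path]:
    """Write reference FASTA + hierarchy, query FASTA and truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference_fasta": out / "reference.fa",
        "hierarchy": out / "hierarchy.tsv",
        "query_fasta": out / "query.fa",
        "truth": out / "truth.tsv",
    }
    write_reference(fix.reference, paths["reference_fasta"], paths["hierarchy"])
    with open(paths["query_fasta"], "w") as fh:
        for pid, seq in fix.queries:
            fh.write(f">{pid} species={fix.query_species}\n{seq}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("# protein_id\tspecies\tfamily_id\thog_id\treference_hog_id\n")
        for pid, _ in fix.queries:
            t = fix.truth
            fh.write(
                f"{pid}\t{t.species_of[pid]}\t{t.family_of[pid]}\t"
                f"{t.hog_of[pid]}\t{t.reference_hog_of[pid]}\n"
            )
    return paths
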