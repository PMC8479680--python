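"""Reference data model: proteins, HOG hierarchies and the reference database.

A *hierarchical orthologous group* (HOG) is a set of proteins descending from a
single speciation event.  HOGs nest: the top-level HOG of a family (the
*root-HOG*) is the family itself, and every duplication event below it defines
nested sub-HOGs (subfamilies).  The reference database pairs a set of proteins
-- each labelled with its species and its most specific HOG -- with the forest
of HOG parent/child links.

Canonical on-disk formats are deliberately plain: FASTA for sequences (record
description may carry ``species=<label>``) and a flat TSV for the hierarchy
with two kinds of rows::

    protein_id <TAB> hog_id                     # membership rows (2 columns)
    hog_id <TAB> parent_hog_id|NA <TAB> level   # HOG rows (3 columns)

Lines starting with ``#`` are comments.  Both row kinds may live in one file
or in two separate files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids in alphabetical order.  The ordering matters:
#: k-mer integer codes are base-20 digits ranked by this string.
CANONICAL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_CANONICAL_SET = frozenset(CANONICAL_ALPHABET)


def sanitize_sequence(seq: str) -> str:
    """Uppercase a raw sequence.

    Non-canonical residues (X, B, Z, J, U, O, ``*``, gap characters, ...) are
    retained in the stored sequence; indexing and querying skip every k-mer
    window that touches one, so they never contribute counts.
    """
    return seq.upper()


def noncanonical_count(seq: str) -> int:
    return sum(1 for c in seq if c not in _CANONICAL_SET)


@dataclass(frozen=True)
class Protein:
    """A reference protein with its most specific HOG membership."""

    id: str
    species: str
    sequence: str
    hog_id: str


@dataclass(frozen=True)
class HOG:
    """One hierarchical orthologous group.

    ``parent_id is None`` marks a root-HOG (= family); ``family_id`` is the id
    of the root-HOG at the top of this HOG's parent path (its own id for a
    root-HOG).
    """

    id: str
    parent_id: str | None
    family_id: str
    level: str = ""


class HierarchyError(ValueError):
    """Raised for malformed hierarchies (cycles, dangling links, ...)."""


class HOGHierarchy:
    """Forest of HOGs with parent/child links and per-node depths.

    Parameters
    ----------
    rows
        Iterable of ``(hog_id, parent_id_or_None, level)`` triples.
    """

    def __init__(self, rows: Iterable[tuple[str, str | None, str]]):
        parents: dict[str, str | None] = {}
        levels: dict[str, str] = {}
        for hog_id, parent_id, level in rows:
            if hog_id in parents:
                raise HierarchyError(f"duplicate HOG id {hog_id!r}")
            parents[hog_id] = parent_id
            levels[hog_id] = level
        for hog_id, parent_id in parents.items():
            if parent_id is not None and parent_id not in parents:
                raise HierarchyError(
                    f"HOG {hog_id!r} has unknown parent {parent_id!r}"
                )
        self._parents = parents
        self.children: dict[str, list[str]] = {h: [] for h in parents}
        for hog_id, parent_id in parents.items():
            if parent_id is not None:
                self.children[parent_id].append(hog_id)
        for kids in self.children.values():
            kids.sort()
        self.depth: dict[str, int] = {}
        self._family: dict[str, str] = {}
        self._resolve_roots()
        self.hogs: dict[str, HOG] = {
            h: HOG(h, parents[h], self._family[h], levels[h]) for h in parents
        }

    def _resolve_roots(self) -> None:
        for start in self._parents:
            if start in self.depth:
                continue
            path = []
            node: str | None = start
            on_path = set()
            while node is not None and node not in self.depth:
                if node in on_path:
                    cycle = path[path.index(node):]
                    raise HierarchyError(
                        "cyclic parent links among HOGs {%s}" % ", ".join(sorted(cycle))
                    )
                on_path.add(node)
                path.append(node)
                node = self._parents[node]
            if node is None:
                base_depth, family = -1, path[-1]
            else:
                base_depth, family = self.depth[node], self._family[node]
            for i, h in enumerate(reversed(path)):
                self.depth[h] = base_depth + 1 + i
            # reversed() above walks root-most first
            for h in path:
                self._family[h] = family

    # -- queries ---------------------------------------------------------

    def __contains__(self, hog_id: str) -> bool:
        return hog_id in self._parents

    def __len__(self) -> int:
        return len(self._parents)

    def parent(self, hog_id: str) -> str | None:
        return self._parents[hog_id]

    def family_of(self, hog_id: str) -> str:
        return self._family[hog_id]

    @property
    def roots(self) -> list[str]:
        return sorted(h for h, p in self._parents.items() if p is None)

    def subtree(self, hog_id: str) -> Iterator[str]:
        """Yield ``hog_id`` and every descendant (preorder)."""
        if hog_id not in self._parents:
            raise KeyError(hog_id)
        stack = [hog_id]
        while stack:
            h = stack.pop()
            yield h
            stack.extend(reversed(self.children[h]))

    def leaves(self, hog_id: str) -> list[str]:
        return [h for h in self.subtree(hog_id) if not self.children[h]]

    def path_to_root(self, hog_id: str) -> list[str]:
        """HOG ids from ``hog_id`` up to (and including) its root-HOG."""
        if hog_id not in self._parents:
            raise KeyError(hog_id)
        path = [hog_id]
        while (p := self._parents[path[-1]]) is not None:
            path.append(p)
        return path

    def rows(self) -> list[tuple[str, str | None, str]]:
        return [
            (h.id, h.parent_id, h.level) for h in
            (self.hogs[k] for k in sorted(self.hogs))
        ]


def is_ancestor(hierarchy: HOGHierarchy, a: str, b: str) -> bool:
    """True iff HOG ``a`` is a *strict* ancestor of HOG ``b``.

    Strict: ``is_ancestor(h, h)`` is False.  HOGs in different families are
    never ancestors of one another.  Express "ancestral or equal" as
    ``is_ancestor(a, b) or a == b`` at call sites.
    """
    if a not in hierarchy or b not in hierarchy:
        raise KeyError(f"unknown HOG id {a if a not in hierarchy else b!r}")
    if a == b:
        return False
    node = hierarchy.parent(b)
    while node is not None:
        if node == a:
            return True
        node = hierarchy.parent(node)
    return False


@dataclass
class ReferenceDB:
    """Validated reference database: proteins plus their HOG hierarchy."""

    proteins: dict[str, Protein]
    hierarchy: HOGHierarchy
    k: int = 6
    alphabet: str = CANONICAL_ALPHABET

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        for p in self.proteins.values():
            if len(p.sequence) < 1:
                raise ValueError(f"empty sequence for protein {p.id!r}")
            if p.hog_id not in self.hierarchy:
                raise HierarchyError(
                    f"protein {p.id!r} maps to unknown HOG {p.hog_id!r}"
                )

    # -- convenience -----------------------------------------------------

    @property
    def species(self) -> list[str]:
        return sorted({p.species for p in self.proteins.values()})

    def proteome(self, species: str) -> list[Protein]:
        return [p for p in self.proteins.values() if p.species == species]

    def members_by_hog(self) -> dict[str, list[str]]:
        """Map each HOG id to ids of proteins whose *most specific* HOG it is."""
        out: dict[str, list[str]] = {h: [] for h in self.hierarchy.hogs}
        for p in self.proteins.values():
            out[p.hog_id].append(p.id)
        return out

    def subtree_member_counts(self) -> dict[str, int]:
        """Number of member proteins anywhere in each HOG's subtree."""
        exact = {h: len(v) for h, v in self.members_by_hog().items()}
        counts = dict(exact)
        order = sorted(self.hierarchy.hogs, key=lambda h: -self.hierarchy.depth[h])
        for h in order:
            p = self.hierarchy.parent(h)
            if p is not None:
                counts[p] += counts[h]
        return counts


def most_specific_hog(db: ReferenceDB, protein_id: str) -> str:
    """Return the id of the most specific HOG containing ``protein_id``."""
    try:
        return db.proteins[protein_id].hog_id
    except KeyError:
        raise KeyError(f"unknown protein id {protein_id!r}") from None


def remove_species(db: ReferenceDB, species: str) -> ReferenceDB:
    """Leave-one-out removal of a whole proteome.

    Drops every protein of ``species`` and prunes HOGs whose entire subtree is
    left without member proteins.  Family ids of surviving HOGs are unchanged.
    Used to build benchmark references in which the query species is absent.
    """
    if species not in db.species:
        raise KeyError(f"species {species!r} not present in database")
    kept = {pid: p for pid, p in db.proteins.items() if p.species != species}
    tmp = ReferenceDB(kept, db.hierarchy, k=db.k, alphabet=db.alphabet)
    counts = tmp.subtree_member_counts()
    rows = [
        (h, p, lv)
        for (h, p, lv) in db.hierarchy.rows()
        if counts[h] >= 1
    ]
    return ReferenceDB(kept, HOGHierarchy(rows), k=db.k, alphabet=db.alphabet)


# -- I/O -----------------------------------------------------------------


def _parse_hierarchy_lines(
    lines: Iterable[str],
) -> tuple[list[tuple[str, str]], list[tuple[str, str | None, str]]]:
    memberships: list[tuple[str, str]] = []
    hog_rows: list[tuple[str, str | None, str]] = []
    for raw in lines:
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 2:
            memberships.append((parts[0], parts[1]))
        elif len(parts) == 3:
            parent = None if parts[1] in ("NA", "") else parts[1]
            hog_rows.append((parts[0], parent, parts[2]))
        else:
            raise ValueError(f"malformed hierarchy line: {line!r}")
    return memberships, hog_rows


def load_reference(
    fasta_paths: Sequence[str | Path],
    hierarchy_path: str | Path | Sequence[str | Path],
    k: int = 6,
) -> ReferenceDB:
    """Load and validate a reference database from FASTA + hierarchy TSV.

    ``hierarchy_path`` may be a single file mixing membership and HOG rows, or
    a sequence of files whose rows are concatenated.
    """
    if isinstance(hierarchy_path, (str, Path)):
        hierarchy_paths = [hierarchy_path]
    else:
        hierarchy_paths = list(hierarchy_path)
    memberships: list[tuple[str, str]] = []
    hog_rows: list[tuple[str, str | None, str]] = []
    for hp in hierarchy_paths:
        with open(hp) as fh:
            m, h = _parse_hierarchy_lines(fh)
        memberships.extend(m)
        hog_rows.extend(h)
    hierarchy = HOGHierarchy(hog_rows)
    hog_of = dict(memberships)

    proteins: dict[str, Protein] = {}
    dropped_residues = 0
    for fp in fasta_paths:
        for rec in SeqIO.parse(str(fp), "fasta"):
            pid = rec.id
            if pid in proteins:
                raise ValueError(f"duplicate protein id {pid!r}")
            if pid not in hog_of:
                raise HierarchyError(
                    f"protein {pid!r} has no HOG membership in the hierarchy table"
                )
            species = ""
            for tok in rec.description.split():
                if tok.startswith("species="):
                    species = tok[len("species="):]
            seq = sanitize_sequence(str(rec.seq))
            dropped_residues += noncanonical_count(seq)
            proteins[pid] = Protein(pid, species, seq, hog_of[pid])
    if dropped_residues:
        logger.info(
            "%d non-canonical residues retained but excluded from k-mer windows",
            dropped_residues,
        )
    logger.info("loaded %d proteins, %d HOGs", len(proteins), len(hierarchy))
    return ReferenceDB(proteins, hierarchy, k=k)


def write_reference(
    db: ReferenceDB, fasta_path: str | Path, hierarchy_path: str | Path
) -> None:
    """Write a database back to the canonical FASTA + TSV formats."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description=f"species={p.species}")
        for p in (db.proteins[k] for k in sorted(db.proteins))
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(hierarchy_path, "w") as fh:
        fh.write("# hog_id\tparent|NA\tlevel\n")
        for h, parent, level in db.hierarchy.rows():
            fh.write(f"{h}\t{parent if parent is not None else 'NA'}\t{level}\n")
        fh.write("# protein_id\thog_id\n")
        for pid in sorted(db.proteins):
            fh.write(f"{pid}\t{db.proteins[pid].hog_id}\n")
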