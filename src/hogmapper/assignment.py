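"""Query assignment to families and subfamilies.

Each query is reduced to its set of distinct canonical k-mers, matched against
the k-mer table for a coarse per-family hit count, and the counts are
normalized into scores in [0, 1] that discount the hits expected by chance
given the query's k-mer count and the family's k-mer repertoire size.  The
winning family's assignment is then refined down the HOG tree along the
highest-scoring root-to-leaf path, stopping as soon as a child's
excess-similarity score drops below the subfamily threshold — an unsure
placement falls back to a more general HOG rather than guessing deeper.

Scores: with ``n`` distinct query k-mers, ``x`` of which hit a HOG whose
k-mer repertoire holds ``m`` distinct k-mers, the expected chance hits are
``E = n * p`` with ``p = 1 - (1 - 20**-k)**m`` (per-k-mer hit probability
under a uniform background; an amino-acid-frequency background is available
via ``background="aa_freq"``), and::

    score = max(0, (x - E) / (n - E))

At the family level ``m`` counts the family's table entries; at the
subfamily level ``x`` and ``m`` are restricted to entries whose ancestral HOG
lies inside the candidate's subtree, so the score captures similarity in
excess of what is already explained by more ancestral HOGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .kmer_table import ALPHABET_SIZE, KmerTable
from .reference_db import CANONICAL_ALPHABET, ReferenceDB

DEFAULT_THETA_FAMILY = 0.05
DEFAULT_THETA_SUB = 0.1
DEFAULT_TOP_N_FAMILIES = 100


@dataclass
class QueryProfile:
    """Distinct canonical k-mers of one query with their offsets."""

    query_id: str
    kmer_codes: np.ndarray          # sorted distinct int64 codes
    positions: dict[int, list[int]]  # code -> query offsets
    length: int
    k: int

    @property
    def n(self) -> int:
        return len(self.kmer_codes)


@dataclass
class FamilyHit:
    family_id: str
    x: int
    score: float | None = None


@dataclass
class QueryResult:
    """Final placement of one query.

    ``path_hogs``/``path_scores`` record the chosen root-to-leaf path (root
    excluded, shallow to deep) and the per-HOG subfamily scores along it; the
    reported ``subfamily_id`` is the deepest prefix of that path whose scores
    all pass the subfamily threshold, falling back to the root-HOG itself.
    """

    query_id: str
    family_id: str | None
    family_score: float
    subfamily_id: str | None
    subfamily_score: float
    overlap: float
    path_hogs: list[str] = field(default_factory=list)
    path_scores: list[float] = field(default_factory=list)


def profile_query(
    sequence: str, k: int, query_id: str = "", alphabet: str = CANONICAL_ALPHABET
) -> QueryProfile:
    """Collect the distinct canonical k-mers of a query sequence.

    Windows containing a non-canonical residue are skipped; a sequence shorter
    than ``k`` yields an empty profile (and, downstream, no assignment).
    """
    seq = sequence.upper()
    rank = {c: i for i, c in enumerate(alphabet)}
    positions: dict[int, list[int]] = {}
    a = len(alphabet)
    for i in range(len(seq) - k + 1):
        code = 0
        ok = True
        for c in seq[i:i + k]:
            r = rank.get(c)
            if r is None:
                ok = False
                break
            code = code * a + r
        if ok:
            positions.setdefault(code, []).append(i)
    codes = np.array(sorted(positions), dtype=np.int64)
    return QueryProfile(query_id, codes, positions, len(seq), k)


def _entry_rows(profile: QueryProfile, table: KmerTable) -> tuple[np.ndarray, ...]:
    """Flattened table entries hit by the profile's k-mers.

    Returns (kmer_index_of_entry, family_idx, hog_idx) arrays, one row per
    (query k-mer, family) table entry.
    """
    codes = profile.kmer_codes
    if len(codes) == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e.astype(np.int32), e.astype(np.int32)
    starts = table.index[codes]
    ends = table.index[codes + 1]
    lens = (ends - starts).astype(np.int64)
    total = int(lens.sum())
    if total == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e.astype(np.int32), e.astype(np.int32)
    which = np.repeat(np.arange(len(codes)), lens)
    offset = np.concatenate(([0], np.cumsum(lens)[:-1]))
    flat = np.repeat(starts - offset, lens) + np.arange(total)
    return which, table.fam_of_entry[flat], table.hog_of_entry[flat]


def coarse_family_hits(profile: QueryProfile, table: KmerTable) -> list[FamilyHit]:
    """Per-family count of query k-mers with a table entry (families with
    at least one hit only)."""
    _, fams, _ = _entry_rows(profile, table)
    counts = np.bincount(fams, minlength=len(table.family_ids))
    return [
        FamilyHit(table.family_ids[i], int(counts[i]))
        for i in np.nonzero(counts)[0]
    ]


def _hit_probability(m: float, k: int, background_p: float | None = None) -> float:
    """P(a random k-mer hits a repertoire of m distinct k-mers)."""
    per = background_p if background_p is not None else ALPHABET_SIZE ** (-k)
    return 1.0 - (1.0 - per) ** m


def _excess_score(x: float, n: int, m: float, k: int, background_p: float | None) -> float:
    if n == 0:
        return 0.0
    e = n * _hit_probability(m, k, background_p)
    if n - e <= 0 or x <= e:
        return 0.0
    return min(1.0, (x - e) / (n - e))


def family_score(
    hit: FamilyHit,
    profile: QueryProfile,
    table: KmerTable,
    background_p: float | None = None,
) -> float:
    """Normalized excess similarity between the query and one family."""
    m = int(table.entries_per_family[table.family_index[hit.family_id]])
    return _excess_score(hit.x, profile.n, m, table.k, background_p)


def mean_kmer_hit_probability(db: ReferenceDB) -> float:
    """Per-k-mer background probability from reference residue frequencies.

    Alternative to the uniform ``20**-k`` background: the probability that a
    random reference k-mer equals a random query k-mer when residues are drawn
    i.i.d. from the empirical amino-acid frequencies, ``(sum_a f_a^2)**k``.
    Compensates composition bias (low-complexity, biased proteomes).
    """
    counts = np.zeros(len(CANONICAL_ALPHABET))
    idx = {c: i for i, c in enumerate(CANONICAL_ALPHABET)}
    for p in db.proteins.values():
        for c in p.sequence:
            if c in idx:
                counts[idx[c]] += 1
    freqs = counts / counts.sum()
    return float((freqs**2).sum() ** db.k)


def assign_family(
    profile: QueryProfile,
    table: KmerTable,
    theta_family: float = DEFAULT_THETA_FAMILY,
    top_n: int = DEFAULT_TOP_N_FAMILIES,
    background_p: float | None = None,
) -> tuple[str | None, float]:
    """Pick the best-scoring family among the top candidates by raw hits.

    Scores are computed only for the ``top_n`` families with the highest
    coarse hit count ``x`` (ties at the cutoff all included).  Returns
    ``(None, 0.0)`` when no candidate reaches ``theta_family``.
    """
    hits = coarse_family_hits(profile, table)
    if not hits:
        return None, 0.0
    hits.sort(key=lambda h: (-h.x, h.family_id))
    if len(hits) > top_n:
        cutoff = hits[top_n - 1].x
        hits = [h for h in hits if h.x >= cutoff]
    best_id, best_score = None, -1.0
    for h in hits:
        s = family_score(h, profile, table, background_p)
        if s > best_score or (s == best_score and (best_id is None or h.family_id < best_id)):
            best_id, best_score = h.family_id, s
    if best_score < theta_family:
        return None, 0.0
    return best_id, best_score


def subtree_hit_counts(
    profile: QueryProfile, table: KmerTable, family_id: str
) -> dict[str, int]:
    """Per-HOG count of query k-mers attributed inside each HOG's subtree.

    ``x_root`` equals the family's coarse hit count; counts are monotone
    non-increasing from parent to child.
    """
    hierarchy = table.hierarchy
    fam_idx = table.family_index[family_id]
    _, fams, hogs = _entry_rows(profile, table)
    sel = hogs[fams == fam_idx]
    exact = np.bincount(sel, minlength=len(table.hog_ids))
    counts: dict[str, int] = {}
    order = sorted(
        hierarchy.subtree(family_id), key=lambda h: -hierarchy.depth[h]
    )
    for h in order:
        c = int(exact[table.hog_index[h]])
        c += sum(counts[ch] for ch in hierarchy.children[h])
        counts[h] = c
    return counts


def _subfamily_path(
    profile: QueryProfile,
    table: KmerTable,
    family_id: str,
    background_p: float | None = None,
) -> tuple[list[str], list[float]]:
    """Highest-scoring root-to-leaf path and per-HOG subfamily scores.

    The path score of a root-to-leaf path is the *sum* of the subfamily
    scores of its non-root HOGs; ties go to the lexicographically smallest
    leaf id.  The chosen path is truncated after its deepest HOG with at
    least one attributed query k-mer: a HOG without any evidence is never an
    acceptable assignment, whatever the threshold.  Returns (non-root path
    hogs shallow->deep, their scores); both empty when the family has no
    sub-HOGs or the path's first child has no evidence.
    """
    hierarchy = table.hierarchy
    counts = subtree_hit_counts(profile, table, family_id)
    n = profile.n
    scores: dict[str, float] = {}
    for h in counts:
        if h == family_id:
            continue
        m_h = int(table.subtree_entries_per_hog[table.hog_index[h]])
        scores[h] = _excess_score(counts[h], n, m_h, table.k, background_p)
    if not scores:
        return [], []
    # accumulate path sums root -> leaf
    best_leaf, best_sum = None, -np.inf
    sums: dict[str, float] = {family_id: 0.0}
    for h in sorted(scores, key=lambda x: (hierarchy.depth[x], x)):
        sums[h] = sums[hierarchy.parent(h)] + scores[h]
        if not hierarchy.children[h]:
            if sums[h] > best_sum or (sums[h] == best_sum and h < best_leaf):
                best_leaf, best_sum = h, sums[h]
    path = [h for h in reversed(hierarchy.path_to_root(best_leaf)) if h != family_id]
    while path and counts[path[-1]] == 0:
        path.pop()
    return path, [scores[h] for h in path]


def assign_subfamily(
    profile: QueryProfile,
    table: KmerTable,
    family_id: str,
    theta_sub: float = DEFAULT_THETA_SUB,
    background_p: float | None = None,
) -> tuple[str, float]:
    """Refine a family assignment to the most specific acceptable sub-HOG.

    Descends the best root-to-leaf path while each child's score passes
    ``theta_sub``; if the first child already fails, the root-HOG itself is
    reported with the family score (an under-specific, never wrong, answer).
    """
    path, scores = _subfamily_path(profile, table, family_id, background_p)
    depth = 0
    while depth < len(path) and scores[depth] >= theta_sub:
        depth += 1
    if depth == 0:
        fs = family_score(
            FamilyHit(family_id, subtree_hit_counts(profile, table, family_id)[family_id]),
            profile,
            table,
            background_p,
        )
        return family_id, fs
    return path[depth - 1], scores[depth - 1]


def overlap_score(profile: QueryProfile, table: KmerTable, family_id: str) -> float:
    """Fraction of query residues covered by family-matching unique k-mers.

    Counts offsets inside at least one window of a k-mer that (a) has a table
    entry for the family and (b) occurs exactly once in the query; k-mers with
    multiple query occurrences are ignored.  Low values flag partial (e.g.
    domain-level) matches.
    """
    if profile.length == 0:
        return 0.0
    fam_idx = table.family_index[family_id]
    which, fams, _ = _entry_rows(profile, table)
    hit_kmers = set(profile.kmer_codes[which[fams == fam_idx]])
    covered = np.zeros(profile.length, dtype=bool)
    for code in hit_kmers:
        offs = profile.positions[int(code)]
        if len(offs) != 1:
            continue
        covered[offs[0]:offs[0] + profile.k] = True
    return float(covered.sum()) / profile.length


def assign_query(
    sequence: str,
    table: KmerTable,
    query_id: str = "",
    theta_family: float = DEFAULT_THETA_FAMILY,
    theta_sub: float = DEFAULT_THETA_SUB,
    top_n: int = DEFAULT_TOP_N_FAMILIES,
    background_p: float | None = None,
) -> QueryResult:
    """Full per-query pipeline: profile, family, subfamily, overlap."""
    profile = profile_query(sequence, table.k, query_id, table.alphabet)
    fam, fam_score = assign_family(profile, table, theta_family, top_n, background_p)
    if fam is None:
        return QueryResult(query_id, None, fam_score, None, 0.0, 0.0)
    path, path_scores = _subfamily_path(profile, table, fam, background_p)
    depth = 0
    while depth < len(path) and path_scores[depth] >= theta_sub:
        depth += 1
    if depth == 0:
        sub, sub_score = fam, fam_score
    else:
        sub, sub_score = path[depth - 1], path_scores[depth - 1]
    ov = overlap_score(profile, table, fam)
    return QueryResult(query_id, fam, fam_score, sub, sub_score, ov, path, path_scores)


def search(
    queries: str | Path | Iterable[tuple[str, str]],
    table: KmerTable,
    theta_family: float = DEFAULT_THETA_FAMILY,
    theta_sub: float = DEFAULT_THETA_SUB,
    top_n: int = DEFAULT_TOP_N_FAMILIES,
    background_p: float | None = None,
) -> list[QueryResult]:
    """Assign every query in a FASTA file or an ``(id, sequence)`` iterable.

    Results come back in input order, one per query.
    """
    if isinstance(queries, (str, Path)):
        from Bio import SeqIO

        items = [(r.id, str(r.seq)) for r in SeqIO.parse(str(queries), "fasta")]
    else:
        items = list(queries)
    return [
        assign_query(seq, table, qid, theta_family, theta_sub, top_n, background_p)
        for qid, seq in items
    ]


def results_to_tsv(results: Sequence[QueryResult], path: str | Path) -> None:
    """Write results as TSV (6 decimal places, ``NA`` for unassigned)."""
    with open(path, "w") as fh:
        fh.write(
            "query_id\tfamily_id\tfamily_score\tsubfamily_id\t"
            "subfamily_score\toverlap_score\n"
        )
        for r in results:
            fam = r.family_id if r.family_id is not None else "NA"
            sub = r.subfamily_id if r.subfamily_id is not None else "NA"
            fh.write(
                f"{r.query_id}\t{fam}\t{r.family_score:.6f}\t{sub}\t"
                f"{r.subfamily_score:.6f}\t{r.overlap:.6f}\n"
            )
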