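"""Evolutionarily informed k-mer table.

The table maps every k-mer occurring in the reference proteins to, per family
(root-HOG), a single *ancestral HOG*: the last common ancestor (LCA) of the
most specific HOGs of all family members containing that k-mer.  Shared k-mers
are thereby attributed to the subfamily in which they plausibly arose — a
k-mer found in two sibling sub-HOGs is credited to their parent, a k-mer
private to one sub-HOG stays with that sub-HOG.  Attributing homoplastic
k-mers (independent origins) to an ancestor errs on the general side, which
is the conservative direction for subfamily placement.

Construction goes through a suffix array over the concatenated reference
sequences (one sentinel per protein), so that all suffixes starting with the
same k-mer are adjacent; the finished table is stored in compressed sparse row
(CSR) form: a dense offset index of length ``20**k + 1`` plus a flat buffer of
``(family, ancestral HOG)`` entries sorted by k-mer code then family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference_db import CANONICAL_ALPHABET, HOGHierarchy, ReferenceDB

ALPHABET_SIZE = len(CANONICAL_ALPHABET)

_RANK = {c: i for i, c in enumerate(CANONICAL_ALPHABET)}


def encode_kmer(kmer: str, alphabet: str = CANONICAL_ALPHABET) -> int:
    """Encode a canonical k-mer as a base-20 integer.

    Digits are alphabet ranks, most significant first, so with the
    alphabetically ordered canonical alphabet ``AA`` -> 0, ``AC`` -> 1, ...,
    ``YY`` -> 20**2 - 1.  Bijective on canonical k-mers of fixed length.
    """
    a = len(alphabet)
    rank = _RANK if alphabet == CANONICAL_ALPHABET else {
        c: i for i, c in enumerate(alphabet)
    }
    code = 0
    for c in kmer:
        try:
            code = code * a + rank[c]
        except KeyError:
            raise ValueError(f"non-canonical residue {c!r} in k-mer {kmer!r}") from None
    return code


def decode_kmer(code: int, k: int, alphabet: str = CANONICAL_ALPHABET) -> str:
    """Inverse of :func:`encode_kmer`."""
    a = len(alphabet)
    if not 0 <= code < a**k:
        raise ValueError(f"code {code} out of range for k={k}")
    out = []
    for _ in range(k):
        code, r = divmod(code, a)
        out.append(alphabet[r])
    return "".join(reversed(out))


# -- suffix array --------------------------------------------------------


@dataclass
class SuffixArray:
    """Suffix array over the concatenation of all reference sequences.

    ``text`` holds one byte per position: 0 for sentinels (protein terminators
    and non-canonical residues), ``rank + 1`` for canonical residues.  The
    sentinel therefore sorts before every residue and no k-mer window is ever
    read across one.
    """

    text: np.ndarray            # int8, 0 = sentinel, 1..20 = residue rank + 1
    sa: np.ndarray              # int64 permutation of [0, len(text))
    starts: np.ndarray          # int64 start offset of each protein in text
    protein_ids: list[str]      # parallel to starts

    def owner(self, offset: int) -> str:
        """Protein id owning a text offset (sentinel offsets belong to the
        protein they terminate)."""
        i = int(np.searchsorted(self.starts, offset, side="right")) - 1
        return self.protein_ids[i]

    def suffix_prefix(self, rank_pos: int, length: int) -> np.ndarray:
        off = int(self.sa[rank_pos])
        return self.text[off:off + length]


def _encode_text(sequences: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate sequences into the sentinel-delimited int8 text."""
    total = sum(len(s) for s in sequences) + len(sequences)
    text = np.zeros(total, dtype=np.int8)
    starts = np.zeros(len(sequences), dtype=np.int64)
    pos = 0
    for i, s in enumerate(sequences):
        starts[i] = pos
        vals = np.frombuffer(s.encode("ascii", "replace"), dtype=np.uint8)
        enc = np.zeros(len(vals), dtype=np.int8)
        for c, r in _RANK.items():
            enc[vals == ord(c)] = r + 1
        text[pos:pos + len(s)] = enc
        pos += len(s) + 1  # leave one 0 sentinel after each protein
    return text, starts


def _suffix_sort(vals: np.ndarray) -> np.ndarray:
    """Manber–Myers prefix doubling via numpy lexsort."""
    n = len(vals)
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = vals.astype(np.int64)
    step = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - step] = rank[step:]
        sa = np.lexsort((key2, rank))
        changed = (rank[sa[1:]] != rank[sa[:-1]]) | (key2[sa[1:]] != key2[sa[:-1]])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[sa[0]] = 0
        new_rank[sa[1:]] = np.cumsum(changed)
        if new_rank[sa[-1]] == n - 1 or step >= n:
            return sa
        rank = new_rank
        step *= 2


def build_suffix_array(db: ReferenceDB) -> SuffixArray:
    """Build the suffix array over all concatenated reference proteins."""
    if not db.proteins:
        raise ValueError("cannot build a suffix array over an empty database")
    ids = sorted(db.proteins)
    seqs = [db.proteins[i].sequence for i in ids]
    text, starts = _encode_text(seqs)
    sa = _suffix_sort(text)
    return SuffixArray(text=text, sa=sa, starts=starts, protein_ids=ids)


def _kmer_range(sa: SuffixArray, target: np.ndarray) -> tuple[int, int]:
    """Binary-search the SA slice of suffixes whose k-prefix equals ``target``."""
    n = len(sa.sa)
    k = len(target)
    tt = tuple(int(x) for x in target)

    def prefix(i: int) -> tuple:
        return tuple(int(x) for x in sa.suffix_prefix(i, k))

    # lower bound: first suffix with prefix >= target
    lo, hi = 0, n
    while lo < hi:
        mid = (lo + hi) // 2
        if prefix(mid) < tt:
            lo = mid + 1
        else:
            hi = mid
    first = lo
    # upper bound: first suffix with prefix > target
    lo, hi = first, n
    while lo < hi:
        mid = (lo + hi) // 2
        if prefix(mid) <= tt:
            lo = mid + 1
        else:
            hi = mid
    return first, lo


def kmer_occurrences(sa: SuffixArray, kmer: str) -> set[str]:
    """All proteins containing at least one occurrence of ``kmer``.

    Found via two binary searches over the suffix array (lexicographic range
    of suffixes starting with the k-mer), never a linear scan.
    """
    target = np.array([_RANK[c] + 1 for c in kmer], dtype=np.int8)
    first, last = _kmer_range(sa, target)
    offs = sa.sa[first:last]
    idx = np.searchsorted(sa.starts, offs, side="right") - 1
    return {sa.protein_ids[i] for i in np.unique(idx)}


# -- LCA -----------------------------------------------------------------


def lca_hog(hierarchy: HOGHierarchy, hog_ids) -> str:
    """Deepest HOG whose subtree contains every id in ``hog_ids``.

    All ids must belong to one family; an id counts as inside its own subtree,
    so ``lca_hog(h, {h}) == h``.  Computed by iterated pairwise depth-table
    walks — hierarchies are shallow so no preprocessing is warranted.
    """
    ids = list(hog_ids)
    if not ids:
        raise ValueError("lca_hog requires a non-empty id set")
    fams = {hierarchy.family_of(h) for h in ids}
    if len(fams) > 1:
        raise ValueError(f"LCA undefined across families {sorted(fams)}")
    cur = ids[0]
    for h in ids[1:]:
        a, b = cur, h
        da, db_ = hierarchy.depth[a], hierarchy.depth[b]
        while da > db_:
            a = hierarchy.parent(a)
            da -= 1
        while db_ > da:
            b = hierarchy.parent(b)
            db_ -= 1
        while a != b:
            a = hierarchy.parent(a)
            b = hierarchy.parent(b)
        cur = a
    return cur


# -- the table -----------------------------------------------------------


@dataclass
class KmerTable:
    """CSR k-mer -> (family, ancestral HOG) table plus per-HOG statistics.

    ``index`` has length ``20**k + 1``; entries for k-mer code ``c`` live at
    ``buffer[index[c]:index[c+1]]``.  ``fam_of_entry``/``hog_of_entry`` are
    parallel int32 arrays of indices into ``family_ids``/``hog_ids``.
    """

    k: int
    alphabet: str
    index: np.ndarray           # int64, len 20**k + 1
    fam_of_entry: np.ndarray    # int32 -> family_ids
    hog_of_entry: np.ndarray    # int32 -> hog_ids
    family_ids: list[str]
    hog_ids: list[str]
    entries_per_family: np.ndarray      # m_F: distinct k-mers with an entry for F
    exact_entries_per_hog: np.ndarray   # entries whose ancestral HOG is exactly h
    subtree_entries_per_hog: np.ndarray  # m_h: entries inside subtree(h)
    hierarchy: HOGHierarchy = field(repr=False)

    def __post_init__(self) -> None:
        self.family_index = {f: i for i, f in enumerate(self.family_ids)}
        self.hog_index = {h: i for i, h in enumerate(self.hog_ids)}

    @property
    def n_entries(self) -> int:
        return len(self.fam_of_entry)

    def entries_for_code(self, code: int) -> tuple[np.ndarray, np.ndarray]:
        s, e = int(self.index[code]), int(self.index[code + 1])
        return self.fam_of_entry[s:e], self.hog_of_entry[s:e]

    def entries_for_kmer(self, kmer: str) -> list[tuple[str, str]]:
        f, h = self.entries_for_code(encode_kmer(kmer, self.alphabet))
        return [(self.family_ids[i], self.hog_ids[j]) for i, j in zip(f, h)]


def _window_codes(text: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes of all valid k-mer windows in ``text``.

    Returns (positions, codes); a window is valid iff it contains no sentinel
    (and hence no non-canonical residue) — windows never span two proteins.
    """
    n = len(text)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    m = n - k + 1
    valid = np.ones(m, dtype=bool)
    codes = np.zeros(m, dtype=np.int64)
    for i in range(k):
        col = text[i:i + m].astype(np.int64)
        valid &= col >= 1
        codes = codes * ALPHABET_SIZE + (col - 1)
    pos = np.nonzero(valid)[0]
    return pos, codes[pos]


def build_kmer_table(db: ReferenceDB, k: int | None = None) -> KmerTable:
    """Precompute the full evolutionarily informed k-mer table.

    For every (k-mer, family) pair such that some family member contains the
    k-mer, exactly one buffer entry is emitted: the family plus the LCA of the
    most specific HOGs of the members containing it.
    """
    if k is None:
        k = db.k
    hierarchy = db.hierarchy
    sa = build_suffix_array(db)

    pos, codes = _window_codes(sa.text, k)
    # walk the suffix array: suffixes sharing a k-prefix are contiguous, so
    # taking valid window offsets in SA order yields codes already grouped
    valid = np.zeros(len(sa.text), dtype=bool)
    valid[pos] = True
    code_at = np.full(len(sa.text), -1, dtype=np.int64)
    code_at[pos] = codes
    sa_pos = sa.sa[valid[sa.sa]]
    codes = code_at[sa_pos]

    owner_idx = np.searchsorted(sa.starts, sa_pos, side="right") - 1

    family_ids = hierarchy.roots
    hog_ids = sorted(hierarchy.hogs)
    fam_index = {f: i for i, f in enumerate(family_ids)}
    hog_index = {h: i for i, h in enumerate(hog_ids)}

    prot_hog = np.array(
        [hog_index[db.proteins[pid].hog_id] for pid in sa.protein_ids],
        dtype=np.int64,
    )
    hog_fam = np.array(
        [fam_index[hierarchy.family_of(h)] for h in hog_ids], dtype=np.int64
    )

    occ_hog = prot_hog[owner_idx]
    occ_fam = hog_fam[occ_hog]

    # unique (code, family, most-specific-hog) triples, sorted by code then family
    tri = np.stack([codes, occ_fam, occ_hog], axis=1)
    tri = np.unique(tri, axis=0)

    if len(tri):
        change = (np.diff(tri[:, 0]) != 0) | (np.diff(tri[:, 1]) != 0)
        bounds = np.concatenate(([0], np.nonzero(change)[0] + 1, [len(tri)]))
    else:
        bounds = np.array([0])
    codes_arr = tri[bounds[:-1], 0].astype(np.int64)
    fam_arr = tri[bounds[:-1], 1].astype(np.int32)
    hog_arr = np.empty(len(bounds) - 1, dtype=np.int32)
    for g in range(len(bounds) - 1):
        lo, hi = bounds[g], bounds[g + 1]
        if hi - lo == 1:
            hog_arr[g] = tri[lo, 2]
        else:
            group = {hog_ids[int(h)] for h in tri[lo:hi, 2]}
            hog_arr[g] = hog_index[lca_hog(hierarchy, group)]

    size = ALPHABET_SIZE**k
    counts = np.bincount(codes_arr, minlength=size)
    index = np.zeros(size + 1, dtype=np.int64)
    np.cumsum(counts, out=index[1:])

    m_f = np.bincount(fam_arr, minlength=len(family_ids)).astype(np.int64)
    exact = np.bincount(hog_arr, minlength=len(hog_ids)).astype(np.int64)
    subtree = exact.copy()
    for h in sorted(hog_ids, key=lambda x: -hierarchy.depth[x]):
        p = hierarchy.parent(h)
        if p is not None:
            subtree[hog_index[p]] += subtree[hog_index[h]]

    return KmerTable(
        k=k,
        alphabet=db.alphabet,
        index=index,
        fam_of_entry=fam_arr,
        hog_of_entry=hog_arr,
        family_ids=family_ids,
        hog_ids=hog_ids,
        entries_per_family=m_f,
        exact_entries_per_hog=exact,
        subtree_entries_per_hog=subtree,
        hierarchy=hierarchy,
    )
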