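"""Single-file serialization of a reference database plus its k-mer table.

One HDF5 container with a versioned header; written by ``hogmapper mkdb`` and
read back by ``hogmapper search``.  The suffix array is a construction
intermediate and is never serialized.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .kmer_table import KmerTable
from .reference_db import HOGHierarchy, Protein, ReferenceDB

FORMAT_NAME = "hogmapper-db"
FORMAT_VERSION = 1

_STR = h5py.string_dtype(encoding="utf-8")


def _write_strings(group: h5py.Group, name: str, values) -> None:
    group.create_dataset(name, data=np.array(list(values), dtype=object), dtype=_STR)


def _read_strings(group: h5py.Group, name: str) -> list[str]:
    return [v.decode() if isinstance(v, bytes) else str(v) for v in group[name][()]]


def save_database(path: str | Path, db: ReferenceDB, table: KmerTable | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = FORMAT_NAME
        f.attrs["version"] = FORMAT_VERSION
        f.attrs["k"] = db.k
        f.attrs["alphabet"] = db.alphabet

        g = f.create_group("hierarchy")
        rows = db.hierarchy.rows()
        _write_strings(g, "hog_id", (r[0] for r in rows))
        _write_strings(g, "parent_id", (r[1] if r[1] is not None else "" for r in rows))
        _write_strings(g, "level", (r[2] for r in rows))

        g = f.create_group("proteins")
        pids = sorted(db.proteins)
        _write_strings(g, "id", pids)
        _write_strings(g, "species", (db.proteins[p].species for p in pids))
        _write_strings(g, "sequence", (db.proteins[p].sequence for p in pids))
        _write_strings(g, "hog_id", (db.proteins[p].hog_id for p in pids))

        if table is not None:
            g = f.create_group("kmer_table")
            g.attrs["k"] = table.k
            g.create_dataset("index", data=table.index, compression="gzip")
            g.create_dataset("fam_of_entry", data=table.fam_of_entry)
            g.create_dataset("hog_of_entry", data=table.hog_of_entry)
            _write_strings(g, "family_ids", table.family_ids)
            _write_strings(g, "hog_ids", table.hog_ids)
            g.create_dataset("entries_per_family", data=table.entries_per_family)
            g.create_dataset("exact_entries_per_hog", data=table.exact_entries_per_hog)
            g.create_dataset(
                "subtree_entries_per_hog", data=table.subtree_entries_per_hog
            )


def load_database(path: str | Path) -> tuple[ReferenceDB, KmerTable | None]:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != FORMAT_NAME:
            raise ValueError(f"{path} is not a {FORMAT_NAME} container")
        if int(f.attrs["version"]) != FORMAT_VERSION:
            raise ValueError(f"unsupported container version {f.attrs['version']}")
        k = int(f.attrs["k"])
        alphabet = str(f.attrs["alphabet"])

        g = f["hierarchy"]
        rows = [
            (h, p if p else None, lv)
            for h, p, lv in zip(
                _read_strings(g, "hog_id"),
                _read_strings(g, "parent_id"),
                _read_strings(g, "level"),
            )
        ]
        hierarchy = HOGHierarchy(rows)

        g = f["proteins"]
        proteins = {
            pid: Protein(pid, sp, seq, hog)
            for pid, sp, seq, hog in zip(
                _read_strings(g, "id"),
                _read_strings(g, "species"),
                _read_strings(g, "sequence"),
                _read_strings(g, "hog_id"),
            )
        }
        db = ReferenceDB(proteins, hierarchy, k=k, alphabet=alphabet)

        table = None
        if "kmer_table" in f:
            g = f["kmer_table"]
            table = KmerTable(
                k=int(g.attrs["k"]),
                alphabet=alphabet,
                index=g["index"][()],
                fam_of_entry=g["fam_of_entry"][()],
                hog_of_entry=g["hog_of_entry"][()],
                family_ids=_read_strings(g, "family_ids"),
                hog_ids=_read_strings(g, "hog_ids"),
                entries_per_family=g["entries_per_family"][()],
                exact_entries_per_hog=g["exact_entries_per_hog"][()],
                subtree_entries_per_hog=g["subtree_entries_per_hog"][()],
                hierarchy=hierarchy,
            )
    return db, table
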