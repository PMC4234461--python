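"""Ordered key-value store contract and backends.

Tables and indexes need only a small contract from their storage engine:
byte-string keys mapped to byte-string values, duplicate keys allowed,
iteration in ascending lexicographic byte order, point lookup and range
scans.  Any embedded B-tree style store satisfies this; the package ships
two backends:

* :class:`SqliteKVStore` — the on-disk default, one SQLite file per
  database.  SQLite compares BLOBs with memcmp, which is exactly the byte
  order the contract requires.
* :class:`MemoryKVStore` — a sorted in-memory list, used by tests and as a
  executable statement of the contract.

Stores are written once (``put`` then ``finalise``) and read many times,
mirroring the table lifecycle.
"""

from __future__ import annotations

import bisect
import os
import sqlite3

from .errors import TableStateError

_BATCH = 20000


class SqliteKVStore:
    """Ordered KV store backed by a single SQLite file.

    Duplicate keys are stored as distinct (key, value) pairs; scans order
    by key then value, so index entries with equal keys come back in
    ascending row-position order for free.
    """

    def __init__(self, path, mode: str = "r"):
        self.path = str(path)
        self.mode = mode
        if mode == "w":
            if os.path.exists(self.path):
                raise TableStateError(f"refusing to overwrite {self.path}")
            self._conn = sqlite3.connect(self.path)
            self._conn.execute("PRAGMA journal_mode=OFF")
            self._conn.execute("PRAGMA synchronous=OFF")
            self._conn.execute(
                "CREATE TABLE kv (k BLOB NOT NULL, v BLOB NOT NULL)"
            )
            self._pending = []
            self._finalised = False
        elif mode == "r":
            if not os.path.exists(self.path):
                raise TableStateError(f"no such database: {self.path}")
            self._conn = sqlite3.connect(self.path)
            self._pending = None
            self._finalised = True
        else:
            raise ValueError(f"bad mode {mode!r}")

    # -- write side ----------------------------------------------------------

    def put(self, key: bytes, value: bytes) -> None:
        if self.mode != "w" or self._finalised:
            raise TableStateError("store is not writable")
        self._pending.append((key, value))
        if len(self._pending) >= _BATCH:
            self._flush()

    def _flush(self) -> None:
        if self._pending:
            self._conn.executemany(
                "INSERT INTO kv (k, v) VALUES (?, ?)", self._pending
            )
            self._pending.clear()

    def finalise(self) -> None:
        if self.mode != "w" or self._finalised:
            raise TableStateError("store is not writable")
        self._flush()
        self._conn.execute("CREATE INDEX kv_order ON kv (k, v)")
        self._conn.commit()
        self._finalised = True
        self.mode = "r"

    # -- read side -----------------------------------------------------------

    def __len__(self) -> int:
        (n,) = self._conn.execute("SELECT COUNT(*) FROM kv").fetchone()
        return n

    def get(self, key: bytes) -> list:
        """All values stored under ``key``, ascending."""
        cur = self._conn.execute(
            "SELECT v FROM kv WHERE k = ? ORDER BY v", (key,)
        )
        return [row[0] for row in cur]

    def count(self, key: bytes) -> int:
        (n,) = self._conn.execute(
            "SELECT COUNT(*) FROM kv WHERE k = ?", (key,)
        ).fetchone()
        return n

    def scan(self, start: bytes | None = None, stop: bytes | None = None):
        """Yield (key, value) pairs with start <= key < stop, in order."""
        sql = "SELECT k, v FROM kv"
        clauses, args = [], []
        if start is not None:
            clauses.append("k >= ?")
            args.append(start)
        if stop is not None:
            clauses.append("k < ?")
            args.append(stop)
        if clauses:
            sql += " WHERE " + " AND ".join(clauses)
        sql += " ORDER BY k, v"
        yield from self._conn.execute(sql, args)

    def distinct(self):
        """Yield (key, count) per distinct key, ascending."""
        yield from self._conn.execute(
            "SELECT k, COUNT(*) FROM kv GROUP BY k ORDER BY k"
        )

    def min_key(self) -> bytes | None:
        row = self._conn.execute(
            "SELECT k FROM kv ORDER BY k LIMIT 1"
        ).fetchone()
        return None if row is None else row[0]

    def max_key(self) -> bytes | None:
        row = self._conn.execute(
            "SELECT k FROM kv ORDER BY k DESC LIMIT 1"
        ).fetchone()
        return None if row is None else row[0]

    def close(self) -> None:
        if self.mode == "w" and not self._finalised:
            self._conn.close()
            return
        self._conn.close()


class MemoryKVStore:
    """Reference in-memory backend: a list of (key, value) pairs kept sorted."""

    def __init__(self):
        self._pairs = []
        self._finalised = False

    def put(self, key: bytes, value: bytes) -> None:
        if self._finalised:
            raise TableStateError("store is not writable")
        self._pairs.append((key, value))

    def finalise(self) -> None:
        if self._finalised:
            raise TableStateError("store already finalised")
        self._pairs.sort()
        self._finalised = True

    def __len__(self) -> int:
        return len(self._pairs)

    def get(self, key: bytes) -> list:
        lo = bisect.bisect_left(self._pairs, (key, b""))
        out = []
        for k, v in self._pairs[lo:]:
            if k != key:
                break
            out.append(v)
        return out

    def count(self, key: bytes) -> int:
        return len(self.get(key))

    def scan(self, start: bytes | None = None, stop: bytes | None = None):
        lo = 0
        if start is not None:
            lo = bisect.bisect_left(self._pairs, (start, b""))
        for k, v in self._pairs[lo:]:
            if stop is not None and k >= stop:
                break
            yield k, v

    def distinct(self):
        prev, n = None, 0
        for k, _ in self._pairs:
            if k == prev:
                n += 1
            else:
                if prev is not None:
                    yield prev, n
                prev, n = k, 1
        if prev is not None:
            yield prev, n

    def min_key(self):
        return self._pairs[0][0] if self._pairs else None

    def max_key(self):
        return self._pairs[-1][0] if self._pairs else None

    def close(self) -> None:
        pass
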