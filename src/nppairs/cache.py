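"""Local curation store: the artifact's single source of truth.

A small SQLite-backed key-value store keyed by ``(kind, raw value)`` where
*kind* names the object family (``"structure"``, ``"organism"``,
``"reference"``, ``"harmonized"``, ``"exported"``).  Each raw value is curated
once; later passes over the same value are served from the store, and the
knowledge-base exporter uses it to avoid re-emitting rows it already exported.
"""

from __future__ import annotations

import json
import sqlite3
from typing import Any


class CurationCache:
    """Relational file-based store; pass ``":memory:"`` for an ephemeral one."""

    def __init__(self, path: str = ":memory:") -> None:
        self._conn = sqlite3.connect(path)
        self._conn.execute(
            "CREATE TABLE IF NOT EXISTS store ("
            " kind TEXT NOT NULL, key TEXT NOT NULL, payload TEXT NOT NULL,"
            " PRIMARY KEY (kind, key))"
        )
        self._conn.commit()

    def get(self, kind: str, key: str) -> Any | None:
        row = self._conn.execute(
            "SELECT payload FROM store WHERE kind = ? AND key = ?", (kind, key)
        ).fetchone()
        return None if row is None else json.loads(row[0])

    def put(self, kind: str, key: str, payload: Any) -> None:
        self._conn.execute(
            "INSERT OR REPLACE INTO store (kind, key, payload) VALUES (?, ?, ?)",
            (kind, key, json.dumps(payload)),
        )
        self._conn.commit()

    def contains(self, kind: str, key: str) -> bool:
        row = self._conn.execute(
            "SELECT 1 FROM store WHERE kind = ? AND key = ?", (kind, key)
        ).fetchone()
        return row is not None

    def close(self) -> None:
        self._conn.close()
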