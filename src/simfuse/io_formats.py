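"""Readers and writers for the flat-file formats used throughout simfuse.

Formats
-------
Profile table
    TSV/CSV with a header row of feature names (e.g. cell-line names) and
    compound identifiers in the first column.  Cells hold real numbers;
    the tokens ``""``, ``NA``, ``na``, ``nan`` and ``NaN`` mark missing
    values.
Fingerprint file
    Two columns: compound id and fingerprint, either as a raw bitstring
    (``10110...``) or as hexadecimal digits.  Hex digits expand
    most-significant-bit first, so ``f0`` becomes ``11110000``.
Edge list
    Two columns: compound id, target id.  Duplicate rows collapse to a
    single edge; the compound and target universes are inferred from the
    file.
Matrix file
    TSV with identical row and column label sets; round-trips losslessly
    to better than 12 significant digits.
Config file
    A flat JSON object of run parameters (eta, k, seed, tolerances,
    linkage, ...).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

NA_TOKENS = frozenset({"", "NA", "na", "nan", "NaN", "NAN"})

__all__ = [
    "CompoundProfileSet",
    "FingerprintSet",
    "BipartiteNetwork",
    "read_profiles",
    "read_fingerprints",
    "read_edge_list",
    "read_matrix",
    "write_matrix",
    "read_config",
    "write_config",
]


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)
    return ids


@dataclass
class CompoundProfileSet:
    """Real-valued activity profiles (compounds x features), NaN = missing."""

    compound_ids: list[str]
    features: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.compound_ids = _check_unique(self.compound_ids, "compound")
        self.features = [str(f) for f in self.features]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compound_ids), len(self.features)):
            raise ValueError(
                f"profile matrix shape {self.values.shape} does not match "
                f"{len(self.compound_ids)} compounds x {len(self.features)} features"
            )

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compound_ids, columns=self.features)


@dataclass
class FingerprintSet:
    """Binary structural fingerprints (compounds x bit_length)."""

    compound_ids: list[str]
    bits: np.ndarray
    bit_length: int = 0

    def __post_init__(self) -> None:
        self.compound_ids = _check_unique(self.compound_ids, "compound")
        self.bits = np.asarray(self.bits)
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.compound_ids):
            raise ValueError("fingerprint matrix must be 2-D with one row per compound")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprint entries must all be 0 or 1")
        self.bits = self.bits.astype(np.uint8)
        if self.bit_length == 0:
            self.bit_length = self.bits.shape[1]
        elif self.bit_length != self.bits.shape[1]:
            raise ValueError(
                f"declared bit_length {self.bit_length} != matrix width {self.bits.shape[1]}"
            )

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)


@dataclass
class BipartiteNetwork:
    """Compound-target interaction edges (a bipartite graph)."""

    compound_ids: list[str]
    target_ids: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.compound_ids = _check_unique(self.compound_ids, "compound")
        self.target_ids = _check_unique(self.target_ids, "target")
        compounds = set(self.compound_ids)
        targets = set(self.target_ids)
        self.edges = {(str(c), str(t)) for c, t in self.edges}
        for c, t in self.edges:
            if c not in compounds:
                raise ValueError(f"edge references undeclared compound {c!r}")
            if t not in targets:
                raise ValueError(f"edge references undeclared target {t!r}")

    def targets_of(self, compound: str) -> set[str]:
        return {t for c, t in self.edges if c == compound}


def read_profiles(path: str | Path, delimiter: str = "\t") -> CompoundProfileSet:
    """Read a profile table; first column = compound id, header = features."""
    path = Path(path)
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, keep_default_na=False)
    ids = _check_unique(raw.index, "compound")
    features = [str(c) for c in raw.columns]
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            token = str(cell).strip()
            if token in NA_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(token)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {token!r} at compound {ids[i]!r}, "
                    f"feature {features[j]!r} in {path}"
                ) from None
    return CompoundProfileSet(ids, features, values)


def _hex_to_bits(s: str) -> list[int]:
    out: list[int] = []
    for ch in s:
        v = int(ch, 16)
        out.extend((v >> b) & 1 for b in (3, 2, 1, 0))
    return out


def read_fingerprints(
    path: str | Path, format: str = "bitstring", delimiter: str = "\t"
) -> FingerprintSet:
    """Read a 2-column fingerprint file (id, bitstring-or-hex)."""
    if format not in ("bitstring", "hex"):
        raise ValueError(f"unknown fingerprint format {format!r}")
    path = Path(path)
    ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split(delimiter)
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        cid, fp = parts[0].strip(), parts[1].strip()
        if format == "bitstring":
            if set(fp) - {"0", "1"}:
                raise ValueError(f"{path}:{lineno}: non-binary character in fingerprint")
            row = [int(c) for c in fp]
        else:
            try:
                row = _hex_to_bits(fp)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-hex character in fingerprint") from None
        if rows and len(row) != len(rows[0]):
            raise ValueError(
                f"{path}:{lineno}: fingerprint length {len(row)} differs from "
                f"previous length {len(rows[0])}"
            )
        ids.append(cid)
        rows.append(row)
    bits = np.asarray(rows, dtype=np.uint8) if rows else np.zeros((0, 0), dtype=np.uint8)
    return FingerprintSet(ids, bits)


def read_edge_list(path: str | Path, delimiter: str = "\t") -> BipartiteNetwork:
    """Read a 2-column compound-target edge list; duplicates collapse."""
    path = Path(path)
    compounds: list[str] = []
    targets: list[str] = []
    seen_c: set[str] = set()
    seen_t: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.rstrip("\n").split(delimiter)]
        if len(parts) != 2 or not all(parts):
            raise ValueError(f"{path}:{lineno}: expected 2 non-empty columns")
        c, t = parts
        if c not in seen_c:
            seen_c.add(c)
            compounds.append(c)
        if t not in seen_t:
            seen_t.add(t)
            targets.append(t)
        edges.add((c, t))
    return BipartiteNetwork(compounds, targets, edges)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a labeled square matrix as TSV, lossless to >=12 digits."""
    if matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"matrix is not square: {matrix.shape}")
    matrix.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labeled square matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"matrix file {path} is not square: {df.shape}")
    return df


def read_config(path: str | Path) -> dict:
    """Read a flat JSON config (eta, k, seed, tolerances, linkage ...)."""
    with open(path) as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must hold a single JSON object")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")
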