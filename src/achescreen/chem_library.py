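"""Compound records, fingerprints, Tanimoto similarity and neighbor search.

A :class:`Library` is the local stand-in for a large compound collection
(a diversity set, a vendor catalogue, a public database): an ordered list of
:class:`CompoundRecord` objects sharing one descriptor dimensionality and one
fingerprint length.  Similarity queries against it use the Tanimoto
coefficient on fixed-length bitsets; the fingerprint source is pluggable
(a chemistry backend deriving Morgan bits from SMILES, or synthetic bitsets
from :mod:`achescreen.synthetic_data`), so the search engine is testable
without any particular toolkit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Activity",
    "CompoundRecord",
    "Library",
    "read_compound_table",
    "write_compound_table",
    "read_fingerprint_sidecar",
    "write_fingerprint_sidecar",
    "fingerprint_from_smiles",
    "tanimoto",
    "neighbor_search",
]

_ACTIVITY_UNITS = {"nM": 1e-9, "uM": 1e-6, "M": 1.0}
_ACTIVITY_KINDS = ("Ki", "IC50")


@dataclass(frozen=True)
class Activity:
    """A measured inhibition constant: positive value, unit, and kind."""

    value: float
    unit: str
    kind: str

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"activity value must be positive, got {self.value}")
        if self.unit not in _ACTIVITY_UNITS:
            raise ValueError(f"unknown activity unit {self.unit!r}")
        if self.kind not in _ACTIVITY_KINDS:
            raise ValueError(f"unknown activity kind {self.kind!r}")

    @property
    def molar(self) -> float:
        """Value converted to mol/l (exact factors 1e-9 / 1e-6)."""
        return self.value * _ACTIVITY_UNITS[self.unit]


@dataclass
class CompoundRecord:
    """One compound: identity, structure, descriptors, fingerprint, labels.

    ``dg_exp`` and ``dg_pred`` are binding free energies in kcal/mol
    (negative = favourable).  ``source_round`` records in which search round
    the compound entered the working set (0 = initial library).
    """

    id: str
    smiles: str | None = None
    features: np.ndarray | None = None
    fingerprint: np.ndarray | None = None
    dg_pred: float | None = None
    dg_exp: float | None = None
    activity: Activity | None = None
    source_round: int = 0

    def __post_init__(self) -> None:
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=float)
        if self.fingerprint is not None:
            self.fingerprint = np.asarray(self.fingerprint, dtype=bool)
        if self.source_round < 0:
            raise ValueError("source_round must be >= 0")


class Library:
    """Ordered collection of compound records with consistent shapes.

    Enforces unique ids and, where present, a common feature dimension and
    fingerprint length across records.
    """

    def __init__(self, records: Iterable[CompoundRecord]):
        self.records: list[CompoundRecord] = list(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate compound id {rec.id!r} in library")
            seen.add(rec.id)
        self._check_dim("features", self.feature_dim)
        self._check_dim("fingerprint", self.fp_bits)
        self._by_id = {rec.id: rec for rec in self.records}

    def _check_dim(self, attr: str, expected: int | None) -> None:
        for rec in self.records:
            val = getattr(rec, attr)
            if val is not None and len(val) != expected:
                raise ValueError(
                    f"inconsistent {attr} length for {rec.id!r}: "
                    f"{len(val)} != {expected}"
                )

    @property
    def feature_dim(self) -> int | None:
        for rec in self.records:
            if rec.features is not None:
                return int(len(rec.features))
        return None

    @property
    def fp_bits(self) -> int | None:
        for rec in self.records:
            if rec.fingerprint is not None:
                return int(len(rec.fingerprint))
        return None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __getitem__(self, cid: str) -> CompoundRecord:
        return self._by_id[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self._by_id

    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def feature_matrix(self) -> np.ndarray:
        missing = [r.id for r in self.records if r.features is None]
        if missing:
            raise ValueError(f"records lacking features: {missing}")
        return np.vstack([r.features for r in self.records])

    def fingerprint_matrix(self) -> np.ndarray:
        missing = [r.id for r in self.records if r.fingerprint is None]
        if missing:
            raise ValueError(f"records lacking fingerprints: {missing}")
        return np.vstack([r.fingerprint for r in self.records])

    def with_predictions(self, dg_pred: Sequence[float]) -> "Library":
        if len(dg_pred) != len(self.records):
            raise ValueError("prediction length mismatch")
        return Library(
            replace(rec, dg_pred=float(p)) for rec, p in zip(self.records, dg_pred)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "id": rec.id,
                    "smiles": rec.smiles,
                    "dg_pred": rec.dg_pred,
                    "dg_exp": rec.dg_exp,
                    "activity_value": rec.activity.value if rec.activity else None,
                    "activity_unit": rec.activity.unit if rec.activity else None,
                    "activity_kind": rec.activity.kind if rec.activity else None,
                    "source_round": rec.source_round,
                }
            )
        return pd.DataFrame(rows)


_DEFAULT_DIALECT = {
    "id": "id",
    "smiles": "smiles",
    "activity_value": "activity_value",
    "activity_unit": "activity_unit",
    "activity_kind": "activity_kind",
    "dg_exp": "dg_exp",
}


def read_compound_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> Library:
    """Read a UTF-8 CSV compound table into a :class:`Library`.

    ``dialect`` maps logical column roles (``id``, ``smiles``,
    ``activity_value``, ``activity_unit``, ``activity_kind``, ``dg_exp``) to
    the file's actual header names.  Rows whose activity cells fail to parse
    keep ``activity=None`` rather than being dropped; row order is preserved.

    Raises
    ------
    ValueError
        If the id column is missing or an id occurs twice (the duplicate id
        is named in the message).
    """
    cols = dict(_DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    path = Path(path)
    records: list[CompoundRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or cols["id"] not in reader.fieldnames:
            raise ValueError(f"missing required id column {cols['id']!r} in {path}")
        for row in reader:
            cid = row[cols["id"]].strip()
            activity = _parse_activity(row, cols)
            dg_exp = _parse_float(row.get(cols["dg_exp"]))
            smiles = row.get(cols["smiles"]) or None
            records.append(
                CompoundRecord(
                    id=cid, smiles=smiles, activity=activity, dg_exp=dg_exp
                )
            )
    return Library(records)


def _parse_float(raw: str | None) -> float | None:
    if raw is None or raw.strip() == "":
        return None
    try:
        return float(raw)
    except ValueError:
        return None


def _parse_activity(row: Mapping[str, str], cols: Mapping[str, str]) -> Activity | None:
    value = _parse_float(row.get(cols["activity_value"]))
    unit = (row.get(cols["activity_unit"]) or "").strip()
    kind = (row.get(cols["activity_kind"]) or "").strip()
    if value is None or value <= 0 or unit not in _ACTIVITY_UNITS or kind not in _ACTIVITY_KINDS:
        return None
    return Activity(value=value, unit=unit, kind=kind)


def write_compound_table(library: Library, path: str | Path) -> None:
    """Write a library back to the CSV dialect read by :func:`read_compound_table`."""
    library.to_frame().to_csv(path, index=False)


def write_fingerprint_sidecar(library: Library, path: str | Path) -> None:
    """Write ``id<TAB>hex-bitset`` lines, one per record with a fingerprint."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in library.records:
            if rec.fingerprint is None:
                continue
            packed = np.packbits(rec.fingerprint.astype(np.uint8))
            fh.write(f"{rec.id}\t{packed.tobytes().hex()}\n")


def read_fingerprint_sidecar(path: str | Path, n_bits: int) -> dict[str, np.ndarray]:
    """Read the ``id<TAB>hex`` sidecar written by :func:`write_fingerprint_sidecar`."""
    out: dict[str, np.ndarray] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            cid, hexed = line.split("\t")
            bits = np.unpackbits(np.frombuffer(bytes.fromhex(hexed), dtype=np.uint8))
            out[cid] = bits[:n_bits].astype(bool)
    return out


def fingerprint_from_smiles(smiles: str, n_bits: int = 2048, radius: int = 2) -> np.ndarray:
    """Morgan (circular) fingerprint of a SMILES string as a boolean bitset."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=bool)
    arr[list(fp.GetOnBits())] = True
    return arr


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two equal-length bitsets.

    Two all-zero fingerprints are identical objects and score 1.0 by
    convention.
    """
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(a & b)) / union


def _bulk_tanimoto(seed_fps: np.ndarray, lib_fps: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto matrix (n_seeds x n_lib) on boolean matrices."""
    seed_fps = seed_fps.astype(np.float32)
    lib_fps = lib_fps.astype(np.float32)
    inter = seed_fps @ lib_fps.T
    pop_s = seed_fps.sum(axis=1, keepdims=True)
    pop_l = lib_fps.sum(axis=1, keepdims=True)
    union = pop_s + pop_l.T - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return sim


def neighbor_search(
    library: Library,
    seeds: Iterable[CompoundRecord],
    sim_cutoff: float,
) -> list[CompoundRecord]:
    """All library records with Tanimoto >= ``sim_cutoff`` to at least one seed.

    Seeds themselves (matched by id) are excluded — the search reports newly
    identified compounds only.  The result is deduplicated by id and sorted
    by id, so it does not depend on library record order.
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("neighbor_search requires at least one seed")
    if not 0.0 <= sim_cutoff <= 1.0:
        raise ValueError(f"sim_cutoff must be in [0, 1], got {sim_cutoff}")
    seed_ids = {s.id for s in seeds}
    for s in seeds:
        if s.fingerprint is None:
            raise ValueError(f"seed {s.id!r} lacks a fingerprint")
        if library.fp_bits is not None and len(s.fingerprint) != library.fp_bits:
            raise ValueError(
                f"seed {s.id!r} fingerprint length {len(s.fingerprint)} "
                f"incompatible with library fp_bits {library.fp_bits}"
            )
    candidates = [r for r in library.records if r.id not in seed_ids]
    if not candidates:
        return []
    lib_fps = np.vstack([r.fingerprint for r in candidates])
    seed_fps = np.vstack([s.fingerprint for s in seeds])
    sim = _bulk_tanimoto(seed_fps, lib_fps)
    keep = (sim >= sim_cutoff).any(axis=0)
    hits = [r for r, k in zip(candidates, keep) if k]
    return sorted(hits, key=lambda r: r.id)
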