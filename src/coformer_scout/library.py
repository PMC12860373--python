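"""Coformer library data model, CSV I/O and reproducible train/test splitting.

A *coformer library* is an ordered collection of candidate partner molecules,
each described by a SMILES string, a small set of physicochemical descriptors
(molecular weight, hydrogen-bond-donor count, topological polar surface area),
a tyrosinase-inhibitory bioactivity score scaled to [0, 1], and — for training
data — a binary suitability label (1 = forms a good supramolecular partner
with the active compound, 0 = does not).

The on-disk format is a plain UTF-8 CSV with a mandatory header and fixed
column names ``id, smiles, mw, hbd, tpsa, tyr_inhib, label`` so that files
interchange bit-exactly between the CLI and the library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoformerRecord",
    "CoformerLibrary",
    "DataSplit",
    "LibraryFormatError",
    "LibraryValidationError",
    "read_library",
    "write_library",
    "split_library",
    "COLUMNS",
]

#: Fixed CSV column order.
COLUMNS = ("id", "smiles", "mw", "hbd", "tpsa", "tyr_inhib", "label")

#: Descriptor columns that may be absent and later computed from SMILES.
DESCRIPTOR_COLUMNS = ("mw", "hbd", "tpsa")


class LibraryFormatError(ValueError):
    """Raised when a library file is structurally malformed (missing columns...)."""


class LibraryValidationError(ValueError):
    """Raised when a record violates a domain invariant (bad label, dup id...)."""


@dataclass(frozen=True)
class CoformerRecord:
    """One candidate coformer molecule.

    Parameters
    ----------
    id : str
        Unique identifier within a library.
    smiles : str
        SMILES structure string (non-empty).
    mw : float or None
        Molecular weight in g/mol (> 0). ``None`` marks "to be computed".
    hbd : int or None
        Hydrogen-bond-donor count (N/O atoms bearing >= 1 H), integer >= 0.
    tpsa : float or None
        Topological polar surface area in Å² (>= 0, Ertl scheme).
    tyr_inhib : float or None
        Tyrosinase-inhibitory potential score scaled to [0, 1]. Supplied
        annotation, never computed from structure.
    label : int or None
        Binary suitability (1 suitable, 0 unsuitable); ``None`` for
        unlabeled candidate-pool records.
    descriptor_source : str
        ``"supplied"`` or ``"computed"``.
    """

    id: str
    smiles: str
    mw: float | None = None
    hbd: int | None = None
    tpsa: float | None = None
    tyr_inhib: float | None = None
    label: int | None = None
    descriptor_source: str = "supplied"

    def __post_init__(self) -> None:
        if not self.id:
            raise LibraryValidationError("record id must be non-empty")
        if not self.smiles:
            raise LibraryValidationError(f"record {self.id!r}: smiles must be non-empty")
        if self.mw is not None and not (math.isfinite(self.mw) and self.mw > 0):
            raise LibraryValidationError(f"record {self.id!r}: mw must be finite and > 0, got {self.mw}")
        if self.hbd is not None:
            if self.hbd != int(self.hbd) or self.hbd < 0:
                raise LibraryValidationError(f"record {self.id!r}: hbd must be a non-negative integer, got {self.hbd}")
        if self.tpsa is not None and not (math.isfinite(self.tpsa) and self.tpsa >= 0):
            raise LibraryValidationError(f"record {self.id!r}: tpsa must be finite and >= 0, got {self.tpsa}")
        if self.tyr_inhib is not None and not (0.0 <= self.tyr_inhib <= 1.0):
            raise LibraryValidationError(
                f"record {self.id!r}: tyr_inhib must lie in [0, 1], got {self.tyr_inhib}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise LibraryValidationError(f"record {self.id!r}: label must be 0 or 1, got {self.label}")
        if self.descriptor_source not in ("supplied", "computed"):
            raise LibraryValidationError(
                f"record {self.id!r}: descriptor_source must be 'supplied' or 'computed'"
            )

    @property
    def has_descriptors(self) -> bool:
        return None not in (self.mw, self.hbd, self.tpsa)

    def with_descriptors(self, mw: float, hbd: int, tpsa: float) -> "CoformerRecord":
        return replace(self, mw=mw, hbd=hbd, tpsa=tpsa, descriptor_source="computed")


@dataclass
class CoformerLibrary:
    """Ordered, id-unique collection of :class:`CoformerRecord`."""

    records: list[CoformerRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise LibraryValidationError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CoformerRecord]:
        return iter(self.records)

    def __getitem__(self, key: int | str) -> CoformerRecord:
        if isinstance(key, str):
            for rec in self.records:
                if rec.id == key:
                    return rec
            raise KeyError(key)
        return self.records[key]

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    @property
    def labels(self) -> np.ndarray:
        """Label vector; raises if any record is unlabeled."""
        out = []
        for rec in self.records:
            if rec.label is None:
                raise LibraryValidationError(f"record {rec.id!r} is unlabeled")
            out.append(rec.label)
        return np.asarray(out, dtype=int)

    def subset(self, ids: Sequence[str]) -> "CoformerLibrary":
        """Sub-library holding the given ids, in the order given."""
        return CoformerLibrary([self[i] for i in ids], metadata=dict(self.metadata))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "id": rec.id,
                    "smiles": rec.smiles,
                    "mw": rec.mw,
                    "hbd": rec.hbd,
                    "tpsa": rec.tpsa,
                    "tyr_inhib": rec.tyr_inhib,
                    "label": rec.label,
                }
            )
        return pd.DataFrame(rows, columns=list(COLUMNS))


@dataclass(frozen=True)
class DataSplit:
    """Reproducible disjoint train/test partition of a library by record id."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int
    stratified: bool

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise LibraryValidationError(f"train/test overlap: {sorted(overlap)[:5]}")


def _parse_cell(row_no: int, rec_id: str, name: str, raw, caster):
    """Parse one optional numeric cell; '' / NaN mean missing."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return None
    try:
        return caster(raw)
    except (TypeError, ValueError) as exc:
        raise LibraryValidationError(
            f"row {row_no} (id {rec_id!r}): cannot parse {name}={raw!r}"
        ) from exc


def _cast_label(raw) -> int:
    val = float(raw)
    if val not in (0.0, 1.0):
        raise ValueError(f"label must be 0 or 1, got {raw!r}")
    return int(val)


def _cast_hbd(raw) -> int:
    val = float(raw)
    if val != int(val):
        raise ValueError(f"hbd must be an integer, got {raw!r}")
    return int(val)


def read_library(path: str | Path) -> CoformerLibrary:
    """Read a coformer library from CSV.

    Requires columns ``id`` and ``smiles``; descriptor and label columns are
    optional (missing cells are marked for later computation). Malformed rows
    are rejected with the 1-based data-row number in the message.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"id": str, "smiles": str},
        keep_default_na=True,
        float_precision="round_trip",
    )
    missing = {"id", "smiles"} - set(df.columns)
    if missing:
        raise LibraryFormatError(f"{path}: missing required column(s) {sorted(missing)}")

    records: list[CoformerRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        rec_id = row_d.get("id")
        if rec_id is None or (isinstance(rec_id, float) and math.isnan(rec_id)):
            raise LibraryValidationError(f"row {i}: missing id")
        rec_id = str(rec_id)
        smiles = row_d.get("smiles")
        if smiles is None or (isinstance(smiles, float) and math.isnan(smiles)):
            raise LibraryValidationError(f"row {i} (id {rec_id!r}): missing smiles")
        try:
            rec = CoformerRecord(
                id=rec_id,
                smiles=str(smiles),
                mw=_parse_cell(i, rec_id, "mw", row_d.get("mw"), float),
                hbd=_parse_cell(i, rec_id, "hbd", row_d.get("hbd"), _cast_hbd),
                tpsa=_parse_cell(i, rec_id, "tpsa", row_d.get("tpsa"), float),
                tyr_inhib=_parse_cell(i, rec_id, "tyr_inhib", row_d.get("tyr_inhib"), float),
                label=_parse_cell(i, rec_id, "label", row_d.get("label"), _cast_label),
            )
        except LibraryValidationError as exc:
            raise LibraryValidationError(f"row {i}: {exc}") from None
        records.append(rec)
    return CoformerLibrary(records, metadata={"source": str(path)})


def write_library(lib: CoformerLibrary, path: str | Path) -> Path:
    """Write a library as UTF-8 CSV with the fixed column order."""
    path = Path(path)
    df = lib.to_frame()
    # integers render without a trailing .0 so round-trips are textual too
    df["hbd"] = df["hbd"].astype("Int64")
    df["label"] = df["label"].astype("Int64")
    df.to_csv(path, index=False, encoding="utf-8")
    return path


def split_library(
    lib: CoformerLibrary,
    train_size: int,
    seed: int = 0,
    stratified: bool = True,
) -> DataSplit:
    """Partition a library into ``train_size`` training and the remaining
    test records, deterministically under ``seed``.

    With ``stratified=True`` (default) the class proportions of the training
    set match the library's within rounding; this requires every record to be
    labeled. The unstratified mode permutes uniformly and does not need labels.
    """
    n = len(lib)
    if not 0 <= train_size <= n:
        raise ValueError(f"train_size must be in [0, {n}], got {train_size}")
    rng = np.random.default_rng(seed)
    ids = np.asarray(lib.ids, dtype=object)

    if stratified:
        y = lib.labels
        train_idx: list[int] = []
        # largest-remainder apportionment of train_size across classes
        classes, counts = np.unique(y, return_counts=True)
        exact = counts * train_size / n
        base = np.floor(exact).astype(int)
        rem = train_size - base.sum()
        order = np.argsort(-(exact - base), kind="stable")
        for j in order[:rem]:
            base[j] += 1
        for cls, take in zip(classes, base):
            members = np.flatnonzero(y == cls)
            perm = rng.permutation(members)
            train_idx.extend(perm[:take].tolist())
        train_idx_arr = np.sort(np.asarray(train_idx, dtype=int))
    else:
        perm = rng.permutation(n)
        train_idx_arr = np.sort(perm[:train_size])

    mask = np.zeros(n, dtype=bool)
    mask[train_idx_arr] = True
    return DataSplit(
        train_ids=tuple(ids[mask].tolist()),
        test_ids=tuple(ids[~mask].tolist()),
        seed=seed,
        stratified=stratified,
    )
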