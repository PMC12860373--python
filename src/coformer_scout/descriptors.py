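"""Molecular descriptors, SMILES encoding and library featurization.

The screening model consumes five predictive variables per candidate:
molecular weight (MW), hydrogen-bond-donor count (HBD), topological polar
surface area (TPSA, Ertl fragment scheme), a supplied tyrosinase-inhibitory
score, and the SMILES structure itself. A raw string cannot feed a numeric
network, so the SMILES is realized as a fixed-length vector of hashed
circular-substructure fragment counts (radius <= 2), a standard,
deterministic encoding that behaves well at small sample sizes.

Descriptor computation delegates to RDKit. The tyrosinase score is an
experimental annotation and is never derived from structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from rdkit import Chem
from rdkit.Chem import Descriptors as _RD
from rdkit.Chem import rdFingerprintGenerator, rdMolDescriptors

from .library import CoformerLibrary, CoformerRecord

__all__ = [
    "DescriptorSet",
    "SmilesEncoding",
    "FeatureMatrix",
    "SmilesParseError",
    "compute_descriptors",
    "encode_smiles",
    "CoformerFeaturizer",
    "featurize_library",
    "DEFAULT_FEATURES",
]

DEFAULT_FEATURES = ("mw", "hbd", "tpsa", "tyr_inhib", "smiles_enc")

_SCALAR_FEATURES = ("mw", "hbd", "tpsa", "tyr_inhib")


class SmilesParseError(ValueError):
    """Raised for SMILES strings RDKit cannot parse; carries the input."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


@dataclass(frozen=True)
class DescriptorSet:
    """MW (g/mol), HBD (count) and TPSA (Å²) for one molecule."""

    mw: float
    hbd: int
    tpsa: float


@dataclass(frozen=True)
class SmilesEncoding:
    """Hashed circular-fragment count vector for one molecule."""

    counts: tuple[int, ...]
    k: int
    canonical_smiles: str

    def __post_init__(self) -> None:
        assert len(self.counts) == self.k
        assert all(c >= 0 for c in self.counts)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def compute_descriptors(smiles: str) -> DescriptorSet:
    """Compute MW, HBD and TPSA from a SMILES string.

    MW sums standard atomic weights including implicit hydrogens; HBD counts
    N/O atoms bearing at least one hydrogen; TPSA follows the Ertl
    fragment-contribution scheme.
    """
    mol = _mol_from_smiles(smiles)
    return DescriptorSet(
        mw=float(_RD.MolWt(mol)),
        hbd=int(rdMolDescriptors.CalcNumHBD(mol)),
        tpsa=float(_RD.TPSA(mol)),
    )


def _mix_hash(fragment_id: int, seed: int, k: int) -> int:
    # Fibonacci-style multiplicative mix so the seed reshuffles buckets
    return ((fragment_id ^ (seed * 0x9E3779B1 + 0x85EBCA6B)) * 0x9E3779B1) % (2**64) % k


def encode_smiles(smiles: str, k: int = 32, seed: int = 0) -> SmilesEncoding:
    """Encode a molecule as ``k`` hashed circular-fragment counts.

    The molecule is canonicalized, its circular substructure environments of
    radius <= 2 are enumerated (with multiplicity), and each fragment
    identifier is hashed into one of ``k`` buckets. The vector is invariant
    to how the input SMILES was written and deterministic for a fixed
    (molecule, k, seed).
    """
    if k < 8:
        raise ValueError(f"k must be >= 8, got {k}")
    mol = _mol_from_smiles(smiles)
    canonical = Chem.MolToSmiles(mol)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2)
    sparse = gen.GetSparseCountFingerprint(mol)
    counts = [0] * k
    for frag_id, mult in sparse.GetNonzeroElements().items():
        counts[_mix_hash(int(frag_id), seed, k)] += int(mult)
    return SmilesEncoding(counts=tuple(counts), k=k, canonical_smiles=canonical)


@dataclass
class FeatureMatrix:
    """Z-scored design matrix with its column schema and scaling parameters.

    ``X[i, j]`` is record ``ids[i]``'s value of ``columns[j]`` after
    centering by ``means[j]`` and dividing by ``sds[j]`` (sample sd, n-1;
    constant columns have sd stored as 0 and map to all-zeros).
    """

    X: np.ndarray
    columns: tuple[str, ...]
    ids: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray


def _record_raw_row(
    rec: CoformerRecord, features: Sequence[str], k: int, seed: int
) -> list[float]:
    rec_eff = rec
    needs_desc = any(f in _SCALAR_FEATURES[:3] for f in features)
    if needs_desc and not rec.has_descriptors:
        try:
            d = compute_descriptors(rec.smiles)
        except SmilesParseError as exc:
            raise ValueError(
                f"record {rec.id!r}: descriptors missing and not computable ({exc})"
            ) from exc
        rec_eff = rec.with_descriptors(d.mw, d.hbd, d.tpsa)
    row: list[float] = []
    for feat in features:
        if feat == "smiles_enc":
            row.extend(encode_smiles(rec_eff.smiles, k=k, seed=seed).counts)
        elif feat in _SCALAR_FEATURES:
            val = getattr(rec_eff, feat)
            if val is None:
                raise ValueError(f"record {rec.id!r}: missing descriptor {feat!r}")
            row.append(float(val))
        else:
            raise ValueError(f"unknown feature {feat!r}")
    return row


class CoformerFeaturizer:
    """Transformer turning a coformer library into a z-scored design matrix.

    scikit-learn-style: :meth:`fit` learns per-column means and sample
    standard deviations on a (training) library, :meth:`transform` applies
    them to any library with the same feature spec. ``smiles_enc`` expands
    into ``k`` hashed fragment-count columns.

    Parameters
    ----------
    features : sequence of str
        Ordered feature spec; any of ``mw, hbd, tpsa, tyr_inhib, smiles_enc``.
    k : int
        Number of hash buckets for the SMILES encoding.
    seed : int
        Hash-mixing seed for the SMILES encoding.
    """

    def __init__(self, features: Sequence[str] = DEFAULT_FEATURES, k: int = 32, seed: int = 0):
        self.features = tuple(features)
        self.k = int(k)
        self.seed = int(seed)

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"features": self.features, "k": self.k, "seed": self.seed}

    def set_params(self, **params) -> "CoformerFeaturizer":
        for key, val in params.items():
            if key not in ("features", "k", "seed"):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, tuple(val) if key == "features" else int(val))
        return self

    # -- core --------------------------------------------------------------
    def _column_names(self) -> tuple[str, ...]:
        cols: list[str] = []
        for feat in self.features:
            if feat == "smiles_enc":
                cols.extend(f"smiles_enc_{j:02d}" for j in range(self.k))
            else:
                cols.append(feat)
        return tuple(cols)

    def _raw_matrix(self, lib: CoformerLibrary) -> tuple[np.ndarray, tuple[str, ...]]:
        rows = [_record_raw_row(rec, self.features, self.k, self.seed) for rec in lib]
        ids = tuple(lib.ids)
        ncol = len(self._column_names())
        X = np.asarray(rows, dtype=float).reshape(len(rows), ncol)
        return X, ids

    def fit(self, lib: CoformerLibrary) -> "CoformerFeaturizer":
        X, _ = self._raw_matrix(lib)
        if X.shape[0] == 0:
            raise ValueError("cannot fit featurizer on an empty library")
        self.columns_ = self._column_names()
        self.means_ = X.mean(axis=0)
        self.sds_ = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        return self

    def transform(self, lib: CoformerLibrary) -> FeatureMatrix:
        if not hasattr(self, "means_"):
            raise RuntimeError("featurizer is not fitted")
        X, ids = self._raw_matrix(lib)
        safe_sd = np.where(self.sds_ > 0, self.sds_, 1.0)
        Z = (X - self.means_) / safe_sd
        Z[:, self.sds_ == 0] = 0.0
        return FeatureMatrix(
            X=Z, columns=self.columns_, ids=ids, means=self.means_.copy(), sds=self.sds_.copy()
        )

    def fit_transform(self, lib: CoformerLibrary) -> FeatureMatrix:
        return self.fit(lib).transform(lib)

    def transform_raw(self, raw: np.ndarray) -> np.ndarray:
        """Apply the fitted scaling to an already-assembled raw row/matrix."""
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        safe_sd = np.where(self.sds_ > 0, self.sds_, 1.0)
        Z = (raw - self.means_) / safe_sd
        Z[:, self.sds_ == 0] = 0.0
        return Z


def featurize_library(
    lib: CoformerLibrary,
    features: Sequence[str] = DEFAULT_FEATURES,
    k: int = 32,
    seed: int = 0,
) -> tuple[FeatureMatrix, CoformerFeaturizer]:
    """Fit a featurizer on ``lib`` and return (matrix, fitted featurizer).

    Rows follow library order; columns follow the feature spec order. The
    fitted featurizer carries the normalization parameters for reuse at
    prediction time.
    """
    featurizer = CoformerFeaturizer(features=features, k=k, seed=seed)
    return featurizer.fit_transform(lib), featurizer
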