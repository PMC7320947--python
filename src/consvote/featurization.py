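"""Multi-block molecular featurization with filtering and standardization.

Three feature families mirror a common QSAR setup: a physicochemical /
topological descriptor block, a combined circular (ECFP) + 2D pharmacophore
fingerprint block, and an externally computed block (e.g. protein--ligand
interaction fingerprints with docking scores) that is ingested rather than
produced.  Every block then passes the same hygiene: constant columns and
near-duplicate columns (|Pearson r| above a limit, default 0.997) are
dropped, and surviving columns are z-scored with statistics fit on training
rows only.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDConfig
from rdkit.Chem import AllChem, ChemicalFeatures, Descriptors
from rdkit.Chem.Pharm2D import Generate
from rdkit.Chem.Pharm2D.SigFactory import SigFactory

BLOCK_NAMES = ("descriptors_123d", "ecfp_pfp", "ifp_ds", "custom")

DEFAULT_CORR_LIMIT = 0.997


class FeaturizationError(ValueError):
    """Raised when a molecule cannot be featurized; carries the compound id."""

    def __init__(self, message: str, compound_id: str | None = None):
        super().__init__(message)
        self.compound_id = compound_id


@dataclass
class FeatureBlock:
    """Named numeric feature matrix, rows aligned to a compound list."""

    block_name: str
    ids: list[str]
    columns: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.ids), len(self.columns)):
            raise ValueError(
                f"block '{self.block_name}': matrix shape "
                f"{self.values.shape} != ({len(self.ids)}, "
                f"{len(self.columns)})")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.columns)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, block_name: str = "custom"
                   ) -> "FeatureBlock":
        return cls(block_name=block_name, ids=[str(i) for i in df.index],
                   columns=[str(c) for c in df.columns],
                   values=df.to_numpy(dtype=np.float64))

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "compound_id"
        df.to_csv(path)


def _mol(smiles: str, compound_id: str | None = None) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None:
        raise FeaturizationError(
            f"unparseable SMILES {smiles!r}"
            + (f" (compound {compound_id})" if compound_id else ""),
            compound_id=compound_id)
    return mol


# ---------------------------------------------------------------------------
# ECFP (Morgan) fingerprints


def compute_ecfp(smiles: str, n_bits: int = 1024, diameter: int = 4,
                 diameter_is_radius: bool = False,
                 compound_id: str | None = None) -> np.ndarray:
    """Hashed circular fingerprint (ECFP) as a 0/1 vector.

    ``diameter=4`` follows the ECFP4 convention (atom environments up to
    radius 2).  Some descriptor packages call the same parameter a "radius";
    set ``diameter_is_radius=True`` to interpret the number literally as the
    Morgan radius.
    """
    mol = _mol(smiles, compound_id)
    radius = diameter if diameter_is_radius else diameter // 2
    gen = AllChem.GetMorganGenerator(radius=radius, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in gen.GetFingerprint(mol).GetOnBits():
        arr[bit] = 1
    return arr


# ---------------------------------------------------------------------------
# Physicochemical / topological descriptor block

#: RDKit's full 2D descriptor list; 3D descriptors would need conformers,
#: which are out of scope, so the "1,2,3D" block name is kept only as a label.
_DESCRIPTOR_NAMES: list[str] | None = None


def descriptor_names() -> list[str]:
    global _DESCRIPTOR_NAMES
    if _DESCRIPTOR_NAMES is None:
        _DESCRIPTOR_NAMES = [name for name, _ in Descriptors.descList]
    return list(_DESCRIPTOR_NAMES)


def compute_descriptor_block(smiles: str, compound_id: str | None = None
                             ) -> dict[str, float]:
    """Named physicochemical/topological descriptors for one molecule.

    Raises :class:`FeaturizationError` if the SMILES does not parse or any
    descriptor comes back non-finite, so callers can exclude and log the row.
    """
    mol = _mol(smiles, compound_id)
    vals = Descriptors.CalcMolDescriptors(mol)
    bad = [k for k, v in vals.items() if not np.isfinite(v)]
    if bad:
        raise FeaturizationError(
            f"non-finite descriptors {bad[:5]} for {smiles!r}"
            + (f" (compound {compound_id})" if compound_id else ""),
            compound_id=compound_id)
    return {k: float(v) for k, v in vals.items()}


# ---------------------------------------------------------------------------
# 2D pharmacophore-pair fingerprints

_SIG_FACTORY: SigFactory | None = None

#: unit-width topological distance bins; finer than the common 3-bin scheme so
#: positional isomers (e.g. para vs meta substitution) map to different bits
_PHARM_BINS = [(1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7), (7, 8),
               (8, 100)]


def _sig_factory() -> SigFactory:
    global _SIG_FACTORY
    if _SIG_FACTORY is None:
        fdef = os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
        feat_factory = ChemicalFeatures.BuildFeatureFactory(fdef)
        sig = SigFactory(feat_factory, minPointCount=2, maxPointCount=2,
                         skipFeats=("ZnBinder", "LumpedHydrophobe"))
        sig.SetBins(_PHARM_BINS)
        sig.Init()
        _SIG_FACTORY = sig
    return _SIG_FACTORY


def pharmacophore_fp_size() -> int:
    return _sig_factory().GetSigSize()


def compute_pharmacophore_fp(smiles: str, compound_id: str | None = None
                             ) -> np.ndarray:
    """2D pharmacophore-pair fingerprint as a 0/1 vector.

    Encodes pairs of typed features (donor, acceptor, aromatic, hydrophobe,
    positive/negative ionizable) at binned topological (bond-path) distances.
    Molecules without typed features (plain alkanes) give the zero vector.
    """
    mol = _mol(smiles, compound_id)
    sig = _sig_factory()
    fp = Generate.Gen2DFingerprint(mol, sig)
    arr = np.zeros(sig.GetSigSize(), dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


# ---------------------------------------------------------------------------
# Block assembly over a compound list


def build_descriptor_block(ids: Sequence[str], smiles: Sequence[str]
                           ) -> tuple[FeatureBlock, list[tuple[str, str]]]:
    """Descriptor block over many compounds; failed rows excluded and logged.

    Returns the block plus ``(compound_id, reason)`` pairs for excluded rows.
    """
    names = descriptor_names()
    rows, kept, failed = [], [], []
    for cid, smi in zip(ids, smiles):
        try:
            vals = compute_descriptor_block(smi, compound_id=cid)
        except FeaturizationError as exc:
            failed.append((cid, str(exc)))
            continue
        rows.append([vals[n] for n in names])
        kept.append(cid)
    block = FeatureBlock("descriptors_123d", kept, names,
                         np.asarray(rows, dtype=np.float64).reshape(
                             len(kept), len(names)))
    return block, failed


def build_ecfp_pfp_block(ids: Sequence[str], smiles: Sequence[str],
                         n_bits: int = 1024, diameter: int = 4
                         ) -> tuple[FeatureBlock, list[tuple[str, str]]]:
    """Combined ECFP + pharmacophore fingerprint block."""
    rows, kept, failed = [], [], []
    for cid, smi in zip(ids, smiles):
        try:
            ecfp = compute_ecfp(smi, n_bits=n_bits, diameter=diameter,
                                compound_id=cid)
            pfp = compute_pharmacophore_fp(smi, compound_id=cid)
        except FeaturizationError as exc:
            failed.append((cid, str(exc)))
            continue
        rows.append(np.concatenate([ecfp, pfp]))
        kept.append(cid)
    cols = ([f"ecfp_{i}" for i in range(n_bits)]
            + [f"pfp_{i}" for i in range(pharmacophore_fp_size())])
    block = FeatureBlock("ecfp_pfp", kept, cols,
                         np.asarray(rows, dtype=np.float64).reshape(
                             len(kept), len(cols)))
    return block, failed


# ---------------------------------------------------------------------------
# Constant / correlation filtering


def filter_features(block: FeatureBlock,
                    corr_limit: float = DEFAULT_CORR_LIMIT
                    ) -> tuple[FeatureBlock, list[str]]:
    """Drop constant columns, then near-duplicate columns.

    A single left-to-right pass keeps a column only if its absolute Pearson
    correlation with every previously kept column stays below ``corr_limit``;
    of any correlated pair the later column (by column order) is dropped.
    """
    X = block.values
    if X.shape[0] < 1:
        raise ValueError("cannot filter an empty block")
    # max == min is the exact constancy test; a std of ~1e-15 from float
    # accumulation must still count as constant
    nonconst = np.ptp(X, axis=0) > 0
    sd = X.std(axis=0)
    dropped = [c for c, keep in zip(block.columns, nonconst) if not keep]

    idx = np.flatnonzero(nonconst)
    if idx.size == 0:
        raise ValueError(
            f"block '{block.block_name}': all columns constant, nothing "
            "survives filtering")
    if X.shape[0] == 1:
        # single row: correlation undefined; constants already removed
        kept_idx = list(idx)
    else:
        Z = (X[:, idx] - X[:, idx].mean(axis=0)) / sd[idx]
        corr = np.abs(Z.T @ Z) / X.shape[0]
        kept_idx = []
        for j_pos, j in enumerate(idx):
            if all(corr[j_pos, k_pos] < corr_limit
                   for k_pos in _positions(kept_idx, idx)):
                kept_idx.append(j)
            else:
                dropped.append(block.columns[j])
    if not kept_idx:
        raise ValueError(
            f"block '{block.block_name}': all columns dropped by the "
            "correlation filter")
    filtered = FeatureBlock(block.block_name, list(block.ids),
                            [block.columns[j] for j in kept_idx],
                            X[:, kept_idx])
    return filtered, dropped


def _positions(kept_idx: list[int], idx: np.ndarray) -> list[int]:
    pos = {j: p for p, j in enumerate(idx)}
    return [pos[j] for j in kept_idx]


# ---------------------------------------------------------------------------
# Standardization (training rows only)


@dataclass
class StandardizationModel:
    """Per-column z-score parameters learned on training rows."""

    columns: list[str]
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        if np.any(self.sd <= 0):
            bad = [c for c, s in zip(self.columns, self.sd) if s <= 0]
            raise ValueError(
                f"zero-variance columns at fit time (should have been "
                f"filtered): {bad[:5]}")

    def to_json(self, path: str | Path) -> None:
        obj = {c: {"mean": float(m), "sd": float(s)}
               for c, m, s in zip(self.columns, self.mean, self.sd)}
        Path(path).write_text(json.dumps(obj, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "StandardizationModel":
        obj = json.loads(Path(path).read_text())
        cols = list(obj)
        return cls(cols, np.array([obj[c]["mean"] for c in cols]),
                   np.array([obj[c]["sd"] for c in cols]))


def fit_standardizer(block: FeatureBlock,
                     train_mask: np.ndarray | None = None
                     ) -> StandardizationModel:
    """Fit per-column mean/sd on the training rows only (population sd)."""
    X = block.values
    if train_mask is not None:
        train_mask = np.asarray(train_mask, dtype=bool)
        X = X[train_mask]
    return StandardizationModel(list(block.columns), X.mean(axis=0),
                                X.std(axis=0))


def apply_standardizer(model: StandardizationModel, block: FeatureBlock
                       ) -> FeatureBlock:
    """Apply a fitted standardizer unchanged to any rows (train/test/external)."""
    if list(block.columns) != list(model.columns):
        missing = set(model.columns) - set(block.columns)
        extra = set(block.columns) - set(model.columns)
        raise ValueError(
            f"column schema mismatch: missing={sorted(missing)[:5]}, "
            f"extra={sorted(extra)[:5]}")
    Z = (block.values - model.mean) / model.sd
    return FeatureBlock(block.block_name, list(block.ids),
                        list(block.columns), Z)


# ---------------------------------------------------------------------------
# External feature ingestion


def load_external_features(path: str | Path,
                           compound_ids: Sequence[str] | None = None,
                           block_name: str = "ifp_ds",
                           ) -> tuple[FeatureBlock, list[str]]:
    """Ingest an externally computed numeric feature table (CSV).

    First column (or a ``compound_id`` column) holds ids; all remaining
    columns must be numeric.  When ``compound_ids`` is given, the block is
    restricted to (and ordered by) the matching ids and the unmatched ids
    from the file are returned.
    """
    df = pd.read_csv(path)
    id_col = ("compound_id" if "compound_id" in df.columns
              else df.columns[0])
    ids = df[id_col].astype(str).tolist()
    numeric = df.drop(columns=[id_col])
    if numeric.shape[1] == 0:
        raise ValueError(f"{path}: no numeric feature columns")
    for col in numeric.columns:
        coerced = pd.to_numeric(numeric[col], errors="coerce")
        if coerced.isna().any() and not numeric[col].isna().all():
            row = int(coerced.isna().idxmax())
            raise ValueError(
                f"{path}: non-numeric cell at row {row + 2}, "
                f"column '{col}'")
        numeric[col] = coerced
    block = FeatureBlock(block_name, ids,
                         [str(c) for c in numeric.columns],
                         numeric.to_numpy(dtype=np.float64))
    unmatched: list[str] = []
    if compound_ids is not None:
        wanted = [str(c) for c in compound_ids]
        have = {cid: i for i, cid in enumerate(block.ids)}
        unmatched = [cid for cid in block.ids if cid not in set(wanted)]
        rows = [have[cid] for cid in wanted if cid in have]
        keep_ids = [cid for cid in wanted if cid in have]
        block = FeatureBlock(block_name, keep_ids, block.columns,
                             block.values[rows])
    return block, unmatched
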