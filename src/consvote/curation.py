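"""Bioassay curation and MaxMin-balanced dataset construction.

Activity tables from high-throughput screens (e.g. PubChem bioassays for
CYP 2C9 inhibition) arrive with missing structures, inconclusive calls and
duplicated compounds.  This module applies the standard elimination rules,
then balances the two classes by keeping every active and selecting an
equally sized, structurally diverse subset of inactives with the greedy
MaxMin algorithm on fingerprint Tanimoto distances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from ._utils import rng_from

RDLogger.DisableLog("rdApp.*")  # suppress per-molecule parse chatter


class Outcome(str, Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"
    INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class CompoundRecord:
    """One assay entry: compound id, SMILES, activity outcome, source tag."""

    compound_id: str
    smiles: str
    outcome: Outcome
    source: str = ""


@dataclass
class CurationLog:
    """Audit counts for one curation pass; counts reconcile by construction."""

    n_input: int = 0
    n_no_smiles: int = 0
    n_inconclusive: int = 0
    n_duplicates: int = 0
    n_output: int = 0

    def validate(self) -> None:
        counts = asdict(self)
        if any(v < 0 for v in counts.values()):
            raise ValueError(f"negative curation counts: {counts}")
        expected = (self.n_input - self.n_no_smiles - self.n_inconclusive
                    - self.n_duplicates)
        if self.n_output != expected:
            raise ValueError(
                f"curation counts do not reconcile: {counts} (expected "
                f"n_output={expected})")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


class CurationWarning(UserWarning):
    pass


def canonical_smiles(smiles: str) -> str | None:
    """Canonical structure key, or None when the SMILES does not parse."""
    if not smiles or not smiles.strip():
        return None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def curate(records: Sequence[CompoundRecord],
           keep_concordant_duplicates: bool = False,
           ) -> tuple[list[CompoundRecord], CurationLog]:
    """Apply the elimination rules and return survivors plus an audit log.

    Rules, in order: drop records with an empty or unparseable SMILES; drop
    inconclusive outcomes; drop duplicated structures.  The duplicate key is
    the canonicalized SMILES, so equivalent encodings of one structure
    collide.  By default *all* copies of a duplicated structure are removed,
    whatever their labels; with ``keep_concordant_duplicates=True`` one copy
    survives when every copy carries the same label (discordant groups are
    still removed entirely).

    Returns the curated records (input order preserved) and a
    :class:`CurationLog` whose counts reconcile exactly.
    """
    records = list(records)
    log = CurationLog(n_input=len(records))

    keyed: list[tuple[CompoundRecord, str]] = []
    for rec in records:
        key = canonical_smiles(rec.smiles)
        if key is None:
            log.n_no_smiles += 1
            continue
        if rec.outcome == Outcome.INCONCLUSIVE:
            log.n_inconclusive += 1
            continue
        keyed.append((rec, key))

    counts: dict[str, int] = {}
    label_sets: dict[str, set[Outcome]] = {}
    for rec, key in keyed:
        counts[key] = counts.get(key, 0) + 1
        label_sets.setdefault(key, set()).add(rec.outcome)

    out: list[CompoundRecord] = []
    seen: set[str] = set()
    for rec, key in keyed:
        if counts[key] == 1:
            out.append(rec)
            continue
        if (keep_concordant_duplicates and len(label_sets[key]) == 1
                and key not in seen):
            seen.add(key)
            out.append(rec)
        else:
            log.n_duplicates += 1

    log.n_output = len(out)
    log.validate()
    if records and not out:
        warnings.warn("curation eliminated every input record",
                      CurationWarning, stacklevel=2)
    return out, log


# ---------------------------------------------------------------------------
# MaxMin diversity selection


def _as_bool_matrix(pool: Sequence) -> np.ndarray:
    fps = np.asarray([np.asarray(fp, dtype=bool) for fp in pool])
    if fps.ndim != 2:
        raise ValueError("fingerprints must share a common length")
    return fps


def tanimoto_distance_matrix(fps: np.ndarray) -> np.ndarray:
    """All-pairs 1 - Tanimoto similarity for boolean fingerprint rows.

    Two all-zero fingerprints are treated as identical (distance 0).
    """
    fps = fps.astype(np.float64)
    inter = fps @ fps.T
    popcnt = fps.sum(axis=1)
    union = popcnt[:, None] + popcnt[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    return 1.0 - sim


def maxmin_select(pool: Sequence, k: int, seed: int,
                  first: int | None = None) -> list[int]:
    """Greedy MaxMin diversity pick of ``k`` fingerprints from ``pool``.

    The first pick is a uniformly random index from the seeded RNG (or
    ``first`` when pinned explicitly); each subsequent pick maximizes the
    minimum Tanimoto distance to the already selected set, with ties broken
    toward the lowest index.
    """
    if len(pool) == 0:
        raise ValueError("empty fingerprint pool")
    if not 1 <= k <= len(pool):
        raise ValueError(f"k={k} outside [1, {len(pool)}]")
    fps = _as_bool_matrix(pool)
    n = fps.shape[0]
    if first is None:
        rng = rng_from(seed, "maxmin-first-pick")
        first = int(rng.integers(n))

    dist = tanimoto_distance_matrix(fps)
    selected = [first]
    min_dist = dist[first].copy()
    min_dist[first] = -np.inf
    for _ in range(k - 1):
        # argmax returns the lowest index among ties
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, dist[nxt])
        min_dist[nxt] = -np.inf
    return selected


def balance(actives: Sequence[CompoundRecord],
            inactives: Sequence[CompoundRecord],
            seed: int,
            fingerprints: Sequence | None = None,
            ) -> list[CompoundRecord]:
    """Balance classes 1:1: all actives plus a MaxMin-diverse inactive subset.

    ``fingerprints`` (optional) supplies one bit vector per inactive; when
    omitted, ECFP4/1024 fingerprints are computed from the inactive SMILES.
    If there are fewer inactives than actives, everything is kept and an
    imbalance warning is issued.
    """
    actives, inactives = list(actives), list(inactives)
    if len(inactives) < len(actives):
        warnings.warn(
            f"cannot balance: {len(inactives)} inactives < "
            f"{len(actives)} actives; keeping all records",
            CurationWarning, stacklevel=2)
        return actives + inactives
    if len(actives) == 0:
        return []
    if fingerprints is None:
        from .featurization import compute_ecfp
        fingerprints = [compute_ecfp(rec.smiles, compound_id=rec.compound_id)
                        for rec in inactives]
    idx = maxmin_select(fingerprints, k=len(actives), seed=seed)
    return actives + [inactives[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# I/O: PubChem-style assay CSV and curated .smi files

#: accepted aliases for the required columns (lower-cased match)
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "compound_id": ("compound_id", "pubchem_cid", "cid", "id"),
    "smiles": ("smiles", "pubchem_ext_datasource_smiles", "canonical_smiles"),
    "outcome": ("outcome", "pubchem_activity_outcome", "activity_outcome",
                "activity"),
}

_OUTCOME_VALUES = {
    "active": Outcome.ACTIVE,
    "inactive": Outcome.INACTIVE,
    "inconclusive": Outcome.INCONCLUSIVE,
    "unspecified": Outcome.INCONCLUSIVE,
}


def _resolve_column(df: pd.DataFrame, field_name: str,
                    mapping: dict[str, str] | None) -> str:
    if mapping and field_name in mapping:
        return mapping[field_name]
    lowered = {c.lower(): c for c in df.columns}
    for alias in COLUMN_ALIASES[field_name]:
        if alias in lowered:
            return lowered[alias]
    raise ValueError(
        f"no column found for '{field_name}' (looked for "
        f"{COLUMN_ALIASES[field_name]}); use a column mapping")


def read_assay_csv(path: str | Path, source: str = "",
                   column_mapping: dict[str, str] | None = None,
                   ) -> list[CompoundRecord]:
    """Read an activity table (CSV) into :class:`CompoundRecord` rows.

    Required columns ``compound_id``, ``smiles`` and ``outcome`` are located
    case-insensitively, accepting PubChem-style aliases; an explicit
    ``column_mapping`` (field -> column name) overrides the aliases.
    Outcome values are matched case-insensitively.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = {f: _resolve_column(df, f, column_mapping)
            for f in ("compound_id", "smiles", "outcome")}
    records = []
    for i, row in df.iterrows():
        raw = row[cols["outcome"]].strip().lower()
        if raw not in _OUTCOME_VALUES:
            raise ValueError(
                f"{path}, row {i + 2}: unrecognized outcome {raw!r}")
        records.append(CompoundRecord(
            compound_id=row[cols["compound_id"]].strip(),
            smiles=row[cols["smiles"]].strip(),
            outcome=_OUTCOME_VALUES[raw],
            source=source))
    return records


def write_smi(records: Sequence[CompoundRecord], path: str | Path) -> None:
    """Write whitespace-delimited ``smiles  id`` lines (.smi convention)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles} {rec.compound_id}\n")


def read_smi(path: str | Path) -> list[tuple[str, str]]:
    """Read a .smi file into (id, smiles) pairs."""
    out = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        smiles = parts[0]
        cid = parts[1] if len(parts) > 1 else smiles
        out.append((cid, smiles))
    return out
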