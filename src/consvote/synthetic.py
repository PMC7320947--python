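"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the pipeline's input surfaces:

* :func:`gen_feature_dataset` — class-conditional Gaussian feature blocks
  with a planted block structure (informative dimensions shifted between
  classes, within-block correlation through a shared latent factor, label
  noise), emulating a multi-block QSAR table.
* :func:`gen_probability_matrix` — correlated multi-model probability
  matrices from a logistic link over a Gaussian latent score, with
  controllable discrimination, inter-model correlation and per-model
  miscalibration.
* :func:`gen_toy_smiles` — small assay tables drawn from a packaged list of
  200 valid drug-like SMILES, with planted duplicates, an empty-SMILES row
  and inconclusive rows, to exercise curation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._utils import rng_from
from .consensus import ProbabilityMatrix
from .curation import CompoundRecord, Outcome
from .featurization import FeatureBlock


@dataclass
class BlockSpec:
    """Shape of one synthetic feature block."""

    name: str
    dim: int
    informative_dim: int
    class_separation: float = 1.0
    within_block_correlation: float = 0.3

    def __post_init__(self):
        if not 0 <= self.informative_dim <= self.dim:
            raise ValueError("informative_dim must lie in [0, dim]")
        if not 0 <= self.within_block_correlation < 1:
            raise ValueError("within_block_correlation must lie in [0, 1)")


def default_blocks(class_separation: float = 1.8) -> list[BlockSpec]:
    """Three blocks mirroring the interaction-fingerprint / fingerprint /
    descriptor structure: one weaker, two stronger signal carriers."""
    return [
        BlockSpec("ifp_ds", dim=30, informative_dim=4,
                  class_separation=0.85 * class_separation),
        BlockSpec("ecfp_pfp", dim=60, informative_dim=10,
                  class_separation=class_separation),
        BlockSpec("descriptors_123d", dim=40, informative_dim=8,
                  class_separation=class_separation),
    ]


@dataclass
class SyntheticSpec:
    """Conditions for a two-class multi-block feature table.

    Defaults give balanced classes, three correlated blocks, 8% label noise
    and a shared per-compound difficulty latent — a regime where reasonable
    learners reach held-out AUC around 0.75–0.85, comparable to large
    bioassay models, while models trained on different blocks stay
    correlated enough for unanimity voting to keep about half the compounds.
    """

    n: int = 3000
    blocks: list[BlockSpec] = field(default_factory=default_blocks)
    class_balance: float = 0.5
    label_noise: float = 0.08
    #: sd of a per-compound latent shared by the informative dimensions of
    #: every block: compounds that look active look active in every
    #: representation, so models trained on different blocks make correlated
    #: errors (as real molecular representations do)
    shared_difficulty: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie in (0, 1)")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if self.n < 1:
            raise ValueError("n must be positive")


def gen_feature_dataset(spec: SyntheticSpec
                        ) -> tuple[dict[str, FeatureBlock], np.ndarray]:
    """Class-conditional Gaussian blocks plus (possibly noisy) labels.

    For each block, every column is ``sqrt(rho)*g + sqrt(1-rho)*eps`` with a
    row-shared latent factor ``g`` (within-block correlation ``rho``) and
    unit marginal variance; the first ``informative_dim`` columns are
    additionally shifted by ``class_separation`` for true actives plus a
    per-compound difficulty latent shared across blocks (see
    :class:`SyntheticSpec.shared_difficulty`).  Returned labels equal the
    true class flipped independently with probability ``label_noise``.
    Fully determined by ``spec.seed``.
    """
    rng = rng_from(spec.seed, "features")
    y_true = (rng.random(spec.n) < spec.class_balance).astype(int)
    difficulty = spec.shared_difficulty * rng.standard_normal((spec.n, 1))
    ids = [f"CMPD{i:06d}" for i in range(spec.n)]
    blocks: dict[str, FeatureBlock] = {}
    for b in spec.blocks:
        g = rng.standard_normal((spec.n, 1))
        eps = rng.standard_normal((spec.n, b.dim))
        rho = b.within_block_correlation
        X = np.sqrt(rho) * g + np.sqrt(1 - rho) * eps
        X[:, :b.informative_dim] += (b.class_separation * y_true[:, None]
                                     + difficulty)
        cols = [f"{b.name}_f{j}" for j in range(b.dim)]
        blocks[b.name] = FeatureBlock(b.name, ids, cols, X)
    flip = rng.random(spec.n) < spec.label_noise
    labels = np.where(flip, 1 - y_true, y_true)
    return blocks, labels


@dataclass
class SyntheticProbSpec:
    """Conditions for a correlated multi-model probability matrix."""

    n: int = 2000
    m_models: int = 4
    discrimination: float | Sequence[float] = 1.2
    inter_model_correlation: float = 0.5
    miscalibration: float | Sequence[float] = 0.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.m_models < 2:
            raise ValueError("m_models must be >= 2")
        if not 0 <= self.inter_model_correlation < 1:
            raise ValueError("inter_model_correlation must lie in [0, 1)")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie in (0, 1)")

    def per_model(self, value) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=np.float64),
                              (self.m_models,)).copy()
        return arr


def gen_probability_matrix(spec: SyntheticProbSpec) -> ProbabilityMatrix:
    """Correlated per-model probabilities via a logistic link.

    Each model's latent score is ``disc_m*(y-1/2) + sqrt(c)*shared +
    sqrt(1-c)*noise_m + offset_m`` with a row-shared standard normal
    ``shared`` (inter-model noise correlation ``c``); probabilities are the
    logistic of the score.  Discrimination controls each model's AUC
    (``AUC = Phi(disc / sqrt(2))`` for the unpooled model); the offset
    miscalibrates a model without changing its ranking.
    """
    rng = rng_from(spec.seed, "probabilities")
    disc = spec.per_model(spec.discrimination)
    offset = spec.per_model(spec.miscalibration)
    y = (rng.random(spec.n) < spec.class_balance).astype(int)
    shared = rng.standard_normal((spec.n, 1))
    noise = rng.standard_normal((spec.n, spec.m_models))
    c = spec.inter_model_correlation
    score = (disc[None, :] * (y[:, None] - 0.5)
             + np.sqrt(c) * shared + np.sqrt(1 - c) * noise
             + offset[None, :])
    probs = 1.0 / (1.0 + np.exp(-score))
    ids = [f"CMPD{i:06d}" for i in range(spec.n)]
    names = [f"model_{j}" for j in range(spec.m_models)]
    return ProbabilityMatrix(ids, names, probs, y)


# ---------------------------------------------------------------------------
# Toy SMILES assay tables

_SUBSTITUENTS = ("O", "N", "Cl", "F", "C(=O)O", "C(=O)N", "OC", "C#N", "S",
                 "Br")
_SCAFFOLDS = ("c1ccc({sub})cc1", "c1ccc({sub})nc1")

#: 200 valid, drug-like aromatic SMILES: benzene/pyridine scaffolds with one
#: polar substituent and an alkyl chain of 0..9 carbons.
TOY_SMILES: tuple[str, ...] = tuple(
    ("C" * chain) + scaffold.format(sub=sub)
    for scaffold in _SCAFFOLDS
    for sub in _SUBSTITUENTS
    for chain in range(10))


def gen_toy_smiles(n: int, seed: int = 0) -> list[CompoundRecord]:
    """Deterministic toy assay table exercising every curation rule.

    Rows are drawn (without replacement where possible) from the packaged
    SMILES list with random active/inactive outcomes.  For n >= 6 the table
    plants one empty-SMILES row, one inconclusive row and one duplicate pair
    (the same structure encoded twice, once as its kekulized SMILES, with
    conflicting labels).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng_from(seed, "toy-smiles")
    picks = rng.choice(len(TOY_SMILES), size=min(n, len(TOY_SMILES)),
                       replace=False)
    if n > len(TOY_SMILES):
        extra = rng.choice(len(TOY_SMILES), size=n - len(TOY_SMILES),
                           replace=True)
        picks = np.concatenate([picks, extra])
    records = [
        CompoundRecord(compound_id=f"TOY{i:04d}", smiles=TOY_SMILES[j],
                       outcome=(Outcome.ACTIVE if rng.random() < 0.5
                                else Outcome.INACTIVE),
                       source="toy")
        for i, j in enumerate(picks)]
    if n >= 6:
        from rdkit import Chem
        records[0] = CompoundRecord("TOY_EMPTY", "", Outcome.ACTIVE, "toy")
        records[1] = CompoundRecord("TOY_INCONCL", TOY_SMILES[int(picks[1])],
                                    Outcome.INCONCLUSIVE, "toy")
        dup = TOY_SMILES[int(picks[2])]
        mol = Chem.MolFromSmiles(dup)
        Chem.Kekulize(mol, clearAromaticFlags=True)
        alt = Chem.MolToSmiles(mol, kekuleSmiles=True)
        records[2] = CompoundRecord("TOY_DUP_A", dup, Outcome.ACTIVE, "toy")
        records[3] = CompoundRecord("TOY_DUP_B", alt, Outcome.INACTIVE, "toy")
    return records
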